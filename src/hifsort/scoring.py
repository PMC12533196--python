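"""Reference-scaled program scoring, dedifferentiation scoring, and bulk
sample scoring.

Scaled scores put genotypes on a common, interpretable axis: after the affine
transform the reference cohort (e.g. ConKO, or ConKO-early) has median 0 and
the target cohort (e.g. VKO, or VKO-late) has median +1 for up programs and
-1 for down programs — so intermediate genotypes read directly as fractions
of the full Vhl-dependent response.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .annotate import MarkerSet, binned_control_score

__all__ = [
    "score_and_scale",
    "dedifferentiation_score",
    "score_bulk_samples",
    "enrichment_of_markers",
]


def score_and_scale(
    adata: ad.AnnData,
    programs: Mapping[str, Sequence[str]],
    reference: str,
    target: str,
    direction: str,
    genotype_col: str = "genotype",
    identity_col: str = "identity",
    reference_timepoint: str | None = None,
    target_timepoint: str | None = None,
    n_bins: int = 100,
    n_ctrl: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Score a program per identity, scale to the reference/target anchors,
    then amalgamate identities.

    ``programs`` maps identity label -> gene list (programs are defined per
    identity).  Raw scores come from the binned-control method.  Per
    identity, with ``m_r`` / ``m_t`` the raw-score medians of the reference
    and target anchor cohorts, the scaled score is
    ``(s - m_r) / (m_t - m_r) * sign`` with sign +1 for 'up' and -1 for
    'down' — so the reference median is exactly 0 and the target median is
    exactly +1 (up) or -1 (down) within every identity.  Identities whose
    anchors coincide are skipped with a warning.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    sign = 1.0 if direction == "up" else -1.0
    pieces = []
    for identity, genes in programs.items():
        mask = (adata.obs[identity_col] == identity).to_numpy()
        if mask.sum() == 0:
            warnings.warn(f"no cells of identity {identity!r}; skipped", stacklevel=2)
            continue
        sub = adata[mask].copy()
        raw = binned_control_score(sub, genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
        geno = sub.obs[genotype_col].astype(str)
        tp = sub.obs["timepoint"].astype(str) if "timepoint" in sub.obs else None
        ref_mask = (geno == reference).to_numpy()
        tgt_mask = (geno == target).to_numpy()
        if reference_timepoint is not None and tp is not None:
            ref_mask &= (tp == reference_timepoint).to_numpy()
        if target_timepoint is not None and tp is not None:
            tgt_mask &= (tp == target_timepoint).to_numpy()
        if ref_mask.sum() == 0 or tgt_mask.sum() == 0:
            raise ValueError(
                f"identity {identity!r}: reference or target anchor cohort empty"
            )
        m_r = float(np.median(raw.to_numpy()[ref_mask]))
        m_t = float(np.median(raw.to_numpy()[tgt_mask]))
        if m_t == m_r:
            warnings.warn(
                f"identity {identity!r}: anchor medians coincide; scaling "
                "undefined, identity skipped",
                stacklevel=2,
            )
            continue
        scaled = (raw - m_r) / (m_t - m_r) * sign
        piece = pd.DataFrame(
            {
                "cell_id": raw.index,
                "identity": identity,
                "raw_score": raw.to_numpy(),
                "scaled_score": scaled.to_numpy(),
                "median_ref": m_r,
                "median_target": m_t,
                "sign": sign,
            }
        )
        piece["genotype"] = geno.to_numpy()
        if tp is not None:
            piece["timepoint"] = tp.to_numpy()
        pieces.append(piece)
    if not pieces:
        raise ValueError("no identity could be scored")
    out = pd.concat(pieces, ignore_index=True)
    out.attrs["reference"] = reference
    out.attrs["target"] = target
    out.attrs["direction"] = direction
    return out


def dedifferentiation_score(
    adata: ad.AnnData,
    marker_sets: Sequence[MarkerSet],
    cell_type_col: str = "cell_type",
    sex_col: str = "sex",
    n_bins: int = 100,
    n_ctrl: int = 50,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score each PT segment's cells with their own (sex-matched) marker set.

    Reduced marker scores in a genotype indicate loss of segment identity
    (dedifferentiation).  Returns the per-cell table and per-genotype medians.
    """
    pieces = []
    for ms in marker_sets:
        if ms.cell_type is None:
            warnings.warn(f"marker set {ms.name!r} has no cell type; skipped", stacklevel=2)
            continue
        mask = (adata.obs[cell_type_col] == ms.cell_type).to_numpy()
        if ms.sex is not None:
            mask &= (adata.obs[sex_col] == ms.sex).to_numpy()
        if mask.sum() == 0:
            continue
        sub = adata[mask].copy()
        raw = binned_control_score(sub, ms.genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
        pieces.append(
            pd.DataFrame(
                {
                    "cell_id": raw.index,
                    "marker_set": ms.name,
                    "cell_type": ms.cell_type,
                    "score": raw.to_numpy(),
                    "genotype": sub.obs["genotype"].astype(str).to_numpy(),
                }
            )
        )
    if not pieces:
        raise ValueError("no cell type could be scored")
    per_cell = pd.concat(pieces, ignore_index=True)
    medians = (
        per_cell.groupby("genotype", observed=True)["score"].median().rename("median_score")
    ).reset_index()
    return per_cell, medians


def score_bulk_samples(expr: pd.DataFrame, gene_set) -> pd.Series:
    """Summed z-score of a gene set per bulk sample.

    Each gene (row of ``expr``, samples in columns) is z-scaled across all
    samples (mean 0, SD 1, ddof=1); scaled values of set genes are summed per
    sample.  Zero-variance genes are dropped with a warning.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    genes = [g for g in gene_set if g in expr.index]
    if not genes:
        raise ValueError("gene set empty after intersection with expression matrix")
    sub = expr.loc[genes].astype(float)
    sd = sub.std(axis=1, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance genes dropped from bulk scoring",
            stacklevel=2,
        )
        sub = sub.loc[~zero_var]
        sd = sd.loc[~zero_var]
        if sub.empty:
            raise ValueError("all set genes have zero variance")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    return z.sum(axis=0).rename("score")


def enrichment_of_markers(down_set, marker_universe, all_genes) -> float:
    """Upper-tail hypergeometric p for over-representation of markers in a set.

    P(overlap >= observed) drawing |down_set| genes from |all_genes| of which
    |marker_universe| are markers.
    """
    universe = set(all_genes)
    if not universe:
        raise ValueError("empty gene universe")
    down = set(down_set) & universe
    markers = set(marker_universe) & universe
    k = len(down & markers)
    return float(hypergeom.sf(k - 1, len(universe), len(markers), len(down)))
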