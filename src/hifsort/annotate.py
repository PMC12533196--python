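"""Marker derivation, rank-ceiling signature scoring, cell-type assignment,
and binned-control module scoring.

Two scoring methods are provided, matching their field-standard definitions:

* ``rank_signature_score`` — a Mann-Whitney-style score of the per-cell ranks
  of signature genes clipped at a ceiling (UCell's AUC score).  Scores for
  different signatures are comparable within the same cell, which is what
  makes argmax cell-type assignment sound.
* ``binned_control_score`` — signature mean expression minus the mean of
  expression-matched control genes drawn from average-expression bins
  (Seurat's AddModuleScore).  Scores for one signature are comparable across
  cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "MarkerSet",
    "derive_markers",
    "rank_signature_score",
    "assign_cell_type",
    "binned_control_score",
    "assign_pt_class",
    "log_normalize",
]


@dataclass(frozen=True)
class MarkerSet:
    """A named marker gene list; ``sex`` restricts the set to cells of that
    sex (sexually dimorphic PT segments get separate male/female lists)."""

    name: str
    genes: tuple[str, ...]
    cell_type: str | None = None
    sex: str | None = None  # None = unisex, else 'M' or 'F'
    note: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            warnings.warn(f"marker set {self.name!r} is empty", stacklevel=2)

    @property
    def label(self) -> str:
        return self.cell_type if self.cell_type is not None else self.name


def derive_markers(
    ref_de: pd.DataFrame,
    name: str = "markers",
    l2fc_min: float = 1.0,
    pct_in_min: float = 0.5,
    pct_out_max: float = 0.2,
    **kwargs,
) -> MarkerSet:
    """Select marker genes from a reference DE table.

    ``ref_de`` must have columns ``l2fc``, ``pct_in`` (fraction of cells of
    the marked type expressing the gene) and ``pct_out``; genes pass when
    l2fc > l2fc_min, pct_in > pct_in_min and pct_out < pct_out_max (all
    strict).  The gene id is the table index.
    """
    for col in ("l2fc", "pct_in", "pct_out"):
        if col not in ref_de.columns:
            raise ValueError(f"reference DE table lacks column {col!r}")
    mask = (
        (ref_de["l2fc"] > l2fc_min)
        & (ref_de["pct_in"] > pct_in_min)
        & (ref_de["pct_out"] < pct_out_max)
    )
    genes = tuple(ref_de.index[mask].astype(str))
    if not genes:
        warnings.warn(f"no genes pass the marker thresholds for {name!r}", stacklevel=2)
    return MarkerSet(name=name, genes=genes, **kwargs)


def _dense(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    return np.asarray(X, dtype=float)


def rank_signature_score(
    adata: ad.AnnData,
    marker_sets,
    max_rank: int = 1500,
) -> pd.DataFrame:
    """Rank-ceiling (UCell-style) score per cell for each marker set.

    Genes are ranked per cell by descending expression (average ranks for
    ties, so unexpressed genes share the bottom average rank); signature-gene
    ranks are clipped at ``max_rank`` + 1, and with U = sum(clipped ranks) -
    n(n+1)/2 the score is 1 - U / (n * max_rank), which lies in [0, 1].
    """
    if isinstance(marker_sets, MarkerSet):
        marker_sets = [marker_sets]
    if max_rank >= adata.n_vars:
        raise ValueError(
            f"max_rank={max_rank} must be smaller than the number of genes "
            f"({adata.n_vars})"
        )
    X = _dense(adata)
    ranks = rankdata(-X, axis=1, method="average")
    gene_pos = {g: i for i, g in enumerate(adata.var.index)}

    out = {}
    for ms in marker_sets:
        present = [gene_pos[g] for g in ms.genes if g in gene_pos]
        missing = len(ms.genes) - len(present)
        if missing:
            warnings.warn(
                f"{missing} marker genes of {ms.name!r} absent from matrix",
                stacklevel=2,
            )
        n = len(present)
        if n == 0:
            raise ValueError(f"no genes of marker set {ms.name!r} in matrix")
        if n > max_rank:
            raise ValueError(
                f"marker set {ms.name!r} ({n} genes) exceeds max_rank={max_rank}"
            )
        r = np.minimum(ranks[:, present], max_rank + 1)
        u = r.sum(axis=1) - n * (n + 1) / 2.0
        out[ms.name] = 1.0 - u / (n * max_rank)
    scores = pd.DataFrame(out, index=adata.obs.index)
    scores.attrs["method"] = "rank_ceiling"
    scores.attrs["max_rank"] = max_rank
    return scores


def assign_cell_type(
    scores: pd.DataFrame,
    marker_sets,
    sex: pd.Series | None = None,
) -> pd.DataFrame:
    """Argmax cell-type label per cell, honouring sex-specific marker sets.

    For each cell only sets whose ``sex`` is None or equal to the cell's sex
    compete.  Exact ties go to the lexicographically first label and are
    flagged (not fatal).  Returns a frame with columns ``cell_type`` and
    ``tie``.
    """
    by_name = {ms.name: ms for ms in marker_sets}
    missing = [n for n in by_name if n not in scores.columns]
    if missing:
        raise ValueError(f"scores lack columns for marker sets {missing}")

    labels = pd.Series(index=scores.index, dtype=object)
    ties = pd.Series(False, index=scores.index)
    sex_values = [None] if sex is None else sorted(pd.Series(sex).unique())
    for sx in sex_values:
        if sex is None:
            cells = scores.index
        else:
            cells = scores.index[(sex == sx).to_numpy()]
        applicable = sorted(
            n for n, ms in by_name.items() if ms.sex is None or ms.sex == sx
        )
        if not applicable:
            raise ValueError(f"no applicable marker sets for sex {sx!r}")
        sub = scores.loc[cells, applicable]
        best = sub.idxmax(axis=1)  # first (lexicographically) on ties
        maxval = sub.max(axis=1)
        tie = (sub.eq(maxval, axis=0)).sum(axis=1) > 1
        labels.loc[cells] = best.map(lambda n: by_name[n].label)
        ties.loc[cells] = tie
    return pd.DataFrame({"cell_type": labels, "tie": ties})


def log_normalize(adata: ad.AnnData, scale: float = 1e4) -> np.ndarray:
    """log1p of counts scaled to ``scale`` per cell (cached in adata.layers)."""
    key = "lognorm"
    if key in adata.layers:
        return np.asarray(adata.layers[key])
    X = _dense(adata)
    total = X.sum(axis=1, keepdims=True)
    total[total == 0] = 1.0
    ln = np.log1p(X / total * scale)
    try:
        adata.layers[key] = ln
    except Exception:  # view: caching is best-effort
        pass
    return ln


def binned_control_score(
    adata: ad.AnnData,
    gene_set,
    n_bins: int = 100,
    n_ctrl: int = 50,
    seed: int = 0,
    lognorm: np.ndarray | None = None,
) -> pd.Series:
    """Binned-control module score per cell (AddModuleScore-style).

    Genes are binned into ``n_bins`` equal-frequency bins by their average
    log-normalized expression across cells; each signature gene contributes
    ``n_ctrl`` control genes sampled (seeded, without replacement; with
    replacement plus a warning when a bin is too small) from its own bin.
    The score is mean(signature) - mean(unique controls) per cell.  The drawn
    control genes are recorded in ``.attrs['control_genes']``.
    """
    genes = [g for g in gene_set if g in adata.var.index]
    if not genes:
        raise ValueError("gene set empty after intersection with matrix genes")
    if lognorm is None:
        lognorm = log_normalize(adata)
    gene_pos = {g: i for i, g in enumerate(adata.var.index)}

    data_avg = lognorm.mean(axis=0)
    order_rank = rankdata(data_avg, method="ordinal") - 1  # 0..n_genes-1
    n_genes = adata.n_vars
    n_bins_eff = min(n_bins, n_genes)
    bin_of = (order_rank * n_bins_eff // n_genes).astype(int)
    bin_members: dict[int, np.ndarray] = {
        b: np.flatnonzero(bin_of == b) for b in np.unique(bin_of)
    }

    rng = np.random.default_rng(seed)
    ctrl_idx: set[int] = set()
    for g in genes:
        b = bin_of[gene_pos[g]]
        pool = bin_members[b]
        if len(pool) < n_ctrl:
            warnings.warn(
                f"bin of gene {g!r} has {len(pool)} genes < n_ctrl={n_ctrl}; "
                "sampling with replacement",
                stacklevel=2,
            )
            drawn = rng.choice(pool, size=n_ctrl, replace=True)
        else:
            drawn = rng.choice(pool, size=n_ctrl, replace=False)
        ctrl_idx.update(int(i) for i in drawn)

    sig_idx = [gene_pos[g] for g in genes]
    ctrl = sorted(ctrl_idx)
    score = lognorm[:, sig_idx].mean(axis=1) - lognorm[:, ctrl].mean(axis=1)
    out = pd.Series(score, index=adata.obs.index, name="score")
    out.attrs["method"] = "binned_control"
    out.attrs["params"] = {"n_bins": n_bins, "n_ctrl": n_ctrl, "seed": seed}
    out.attrs["control_genes"] = [adata.var.index[i] for i in ctrl]
    return out


def assign_pt_class(score_a: pd.Series, threshold: float = 0.125) -> pd.Series:
    """Class A iff the module-A score strictly exceeds ``threshold``, else B."""
    return pd.Series(
        np.where(score_a > threshold, "A", "B"), index=score_a.index, name="pt_class"
    )
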