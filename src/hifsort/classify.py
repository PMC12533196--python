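"""The decision ledger turning knockout contrasts into Vhl-dependence,
HIFalpha-isoform specificity and early/adaptive temporal classes.

A gene is *Vhl*-dependent when it is robustly (|L2FC| > 1) and significantly
(padj < 0.05) regulated in VKO vs ConKO.  For each knockout contrast X in
{VHKO, VEKO, VHEKO} vs VKO the gene is X-dependent when it is significantly
regulated in X in the direction opposite to its VKO-vs-ConKO change AND the
magnitude of its L2FC in X is more than half (strict) of the magnitude of
its VKO-vs-ConKO L2FC.  The three dependence flags map to the isoform
category:

=============  =============  ===================  ==================
Hif1a-dep.     Epas1-dep.     Hif1a/Epas1-dep.     category
=============  =============  ===================  ==================
yes            yes            (any)                HIF1A_or_HIF2A
yes            no             (any)                HIF1A_alone
no             yes            (any)                HIF2A_alone
no             no             yes                  HIF1A_plus_HIF2A
no             no             no                   ambiguous
=============  =============  ===================  ==================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .de import call_regulated

__all__ = [
    "categorize",
    "classify_dependence",
    "classify_temporal",
    "pool_categories",
    "PooledSets",
    "anticorrelation_diagnostic",
]


def categorize(hif1a: bool, epas1: bool, hif1a_epas1: bool) -> str:
    """Pure, total mapping from the three dependence flags to the category."""
    if hif1a and epas1:
        return "HIF1A_or_HIF2A"
    if hif1a:
        return "HIF1A_alone"
    if epas1:
        return "HIF2A_alone"
    if hif1a_epas1:
        return "HIF1A_plus_HIF2A"
    return "ambiguous"


def _dependence_flag(
    l2fc_vko: pd.Series,
    l2fc_x: pd.Series,
    padj_x: pd.Series,
    alpha: float,
    half: float,
) -> pd.Series:
    """Significant, opposite-direction regulation with more-than-half magnitude."""
    opposite = np.sign(l2fc_x) == -np.sign(l2fc_vko)
    sig = padj_x < alpha
    big = l2fc_x.abs() > half * l2fc_vko.abs()
    return sig & opposite & big


def classify_dependence(
    de_vko_con: pd.DataFrame,
    de_vhko_vko: pd.DataFrame,
    de_veko_vko: pd.DataFrame,
    de_vheko_vko: pd.DataFrame,
    l2fc_min: float = 1.0,
    alpha: float = 0.05,
    half_fraction: float = 0.5,
    identity: str | None = None,
) -> pd.DataFrame:
    """Per-gene dependence calls for one PT identity.

    All four DE tables must be indexed by the same genes.  Only
    Vhl-dependent genes receive a category; the table nevertheless carries
    every gene with its flags and the underlying contrast L2FCs.
    """
    contrasts = {
        "vhko": de_vhko_vko,
        "veko": de_veko_vko,
        "vheko": de_vheko_vko,
    }
    genes = de_vko_con.index
    for name, de in contrasts.items():
        if not genes.equals(de.index):
            raise ValueError(f"contrast {name!r} indexed by different genes")

    up, down = call_regulated(de_vko_con, l2fc_min=l2fc_min, alpha=alpha)
    vhl_dep = genes.isin(up | down)
    direction = pd.Series(
        np.where(de_vko_con["l2fc"] > 0, "up", "down"), index=genes
    )

    flags = {}
    for name, de in contrasts.items():
        flags[name] = _dependence_flag(
            de_vko_con["l2fc"], de["l2fc"], de["padj"], alpha, half_fraction
        )

    category = [
        categorize(bool(flags["vhko"][g]), bool(flags["veko"][g]), bool(flags["vheko"][g]))
        if dep
        else None
        for g, dep in zip(genes, vhl_dep)
    ]
    out = pd.DataFrame(
        {
            "direction": direction,
            "vhl_dependent": vhl_dep,
            "hif1a_dependent": flags["vhko"] & vhl_dep,
            "epas1_dependent": flags["veko"] & vhl_dep,
            "hif1a_epas1_dependent": flags["vheko"] & vhl_dep,
            "category": pd.Series(category, index=genes, dtype=object),
            "l2fc_vko_con": de_vko_con["l2fc"],
            "padj_vko_con": de_vko_con["padj"],
            "l2fc_vhko_vko": de_vhko_vko["l2fc"],
            "padj_vhko_vko": de_vhko_vko["padj"],
            "l2fc_veko_vko": de_veko_vko["l2fc"],
            "padj_veko_vko": de_veko_vko["padj"],
            "l2fc_vheko_vko": de_vheko_vko["l2fc"],
            "padj_vheko_vko": de_vheko_vko["padj"],
        },
        index=genes,
    )
    out["identity"] = identity
    return out


def classify_temporal(
    de_vko_con_early: pd.DataFrame,
    de_vko_late_early: pd.DataFrame,
    de_con_late_early: pd.DataFrame,
    l2fc_min: float = 1.0,
    alpha: float = 0.05,
    identity: str | None = None,
) -> pd.DataFrame:
    """Early vs adaptive regulation labels per gene.

    Early: regulated in VKO vs ConKO at the early timepoint.  Adaptive:
    regulated late vs early in VKO and not late vs early in ConKO.  Genes in
    both sets are labelled ``both_excluded`` and must be dropped from program
    scoring; everything else is ``none``.
    """
    genes = de_vko_con_early.index
    for de in (de_vko_late_early, de_con_late_early):
        if not genes.equals(de.index):
            raise ValueError("temporal contrasts indexed by different genes")

    e_up, e_dn = call_regulated(de_vko_con_early, l2fc_min, alpha)
    v_up, v_dn = call_regulated(de_vko_late_early, l2fc_min, alpha)
    c_up, c_dn = call_regulated(de_con_late_early, l2fc_min, alpha)
    early = e_up | e_dn
    adaptive = (v_up | v_dn) - (c_up | c_dn)

    def lab(g):
        if g in early and g in adaptive:
            return "both_excluded"
        if g in early:
            return "early"
        if g in adaptive:
            return "adaptive"
        return "none"

    out = pd.DataFrame(
        {
            "temporal": [lab(g) for g in genes],
            "early_direction": ["up" if g in e_up else "down" if g in e_dn else None for g in genes],
            "adaptive_direction": ["up" if g in v_up else "down" if g in v_dn else None for g in genes],
        },
        index=genes,
    )
    out["identity"] = identity
    return out


@dataclass
class PooledSets:
    """HIFalpha-isoform-specific gene sets pooled across PT identities."""

    hif1a: dict[str, set[str]]  # direction -> genes
    hif2a: dict[str, set[str]]
    conflicts: pd.DataFrame  # genes specific to different isoforms in different identities

    @property
    def n_conflicts(self) -> int:
        return len(self.conflicts)


def pool_categories(calls_by_identity: dict[str, pd.DataFrame]) -> PooledSets:
    """Union isoform-specific calls across identities; genes called
    HIF1A_alone in one identity and HIF2A_alone in another (same direction)
    go to the conflict report and are excluded from both pooled sets."""
    h1: dict[str, set[str]] = {"up": set(), "down": set()}
    h2: dict[str, set[str]] = {"up": set(), "down": set()}
    where: dict[tuple[str, str, str], list[str]] = {}
    for identity, calls in calls_by_identity.items():
        called = calls.loc[calls["vhl_dependent"]]
        for gene, row in called.iterrows():
            cat, d = row["category"], row["direction"]
            if cat == "HIF1A_alone":
                h1[d].add(gene)
                where.setdefault((gene, d, "HIF1A"), []).append(identity)
            elif cat == "HIF2A_alone":
                h2[d].add(gene)
                where.setdefault((gene, d, "HIF2A"), []).append(identity)
    conflict_rows = []
    for d in ("up", "down"):
        for gene in sorted(h1[d] & h2[d]):
            conflict_rows.append(
                {
                    "gene": gene,
                    "direction": d,
                    "hif1a_identities": ",".join(where.get((gene, d, "HIF1A"), [])),
                    "hif2a_identities": ",".join(where.get((gene, d, "HIF2A"), [])),
                }
            )
            h1[d].discard(gene)
            h2[d].discard(gene)
    conflicts = pd.DataFrame(
        conflict_rows, columns=["gene", "direction", "hif1a_identities", "hif2a_identities"]
    )
    return PooledSets(hif1a=h1, hif2a=h2, conflicts=conflicts)


def anticorrelation_diagnostic(
    de_vheko_vko: pd.DataFrame,
    de_vko_con: pd.DataFrame,
    genes,
) -> float:
    """Spearman rho between the two L2FC vectors over a gene subset.

    Near-total anti-correlation (rho < -0.8) over HIFalpha-dependent genes
    indicates that the Vhl-regulated transcriptome is reversed by combined
    isoform loss.
    """
    genes = [g for g in genes if g in de_vheko_vko.index and g in de_vko_con.index]
    if len(genes) < 10:
        raise ValueError("need at least 10 genes for the diagnostic")
    a = de_vheko_vko.loc[genes, "l2fc"].to_numpy()
    b = de_vko_con.loc[genes, "l2fc"].to_numpy()
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        raise ValueError("constant L2FC vector; correlation undefined")
    rho, _ = spearmanr(a, b)
    return float(rho)
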