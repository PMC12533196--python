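"""Over-representation analysis on gene-set collections and permutation GSEA.

ORA is a one-sided Fisher/hypergeometric upper-tail test of the 2x2 overlap
table with BH adjustment across sets; collections can be size-bounded (the
conventional 50..1000 window) and filtered by an exclusion list.  GSEA uses
the weighted Kolmogorov-Smirnov running sum (weight exponent 1 on the
absolute ranking statistic) with a seeded gene-label permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "ora",
    "gsea",
    "GseaResult",
    "average_member_l2fc",
    "cluster_terms",
]


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> ..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *map(str, genes)]) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class GeneSetCollection:
    """Named gene sets with optional size bounds and exclusions."""

    sets: dict[str, list[str]]
    min_size: int = 50
    max_size: int = 1000
    excluded: tuple[str, ...] = ()

    @classmethod
    def from_gmt(cls, path, **kwargs) -> "GeneSetCollection":
        return cls(sets=read_gmt(path), **kwargs)

    def filtered(self, universe=None, apply_bounds: bool = True) -> dict[str, set[str]]:
        """Sets intersected with the universe, size-bounded, exclusions removed."""
        uni = set(universe) if universe is not None else None
        out = {}
        for name, genes in self.sets.items():
            if name in self.excluded:
                continue
            g = set(genes) if uni is None else set(genes) & uni
            if apply_bounds and not (self.min_size <= len(g) <= self.max_size):
                continue
            out[name] = g
        return out


def ora(
    query,
    collection: GeneSetCollection | Mapping[str, Sequence[str]],
    universe,
    apply_bounds: bool = True,
) -> pd.DataFrame:
    """One-sided over-representation test of a query set against a collection.

    For each set the upper-tail hypergeometric probability of the observed
    overlap or greater (equivalently a one-sided Fisher exact test on the
    2x2 table) is computed; BH adjustment runs across the tested sets.
    """
    universe = set(universe)
    query = set(query) & universe
    if not query:
        raise ValueError("query set is empty (after intersection with universe)")
    if not isinstance(collection, GeneSetCollection):
        collection = GeneSetCollection(
            sets={k: list(v) for k, v in collection.items()}
        )
    sets = collection.filtered(universe=universe, apply_bounds=apply_bounds)
    rows = []
    N, n = len(universe), len(query)
    for name in sorted(sets):
        members = sets[name]
        K = len(members)
        overlap = sorted(query & members)
        a = len(overlap)
        p = float(hypergeom.sf(a - 1, N, K, n))
        rows.append(
            {
                "set": name,
                "set_size": K,
                "overlap": a,
                "overlap_genes": ",".join(overlap),
                "p": p,
            }
        )
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "overlap_genes", "p"])
    if len(out):
        out["padj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    else:
        out["padj"] = []
    return out


@dataclass
class GseaResult:
    es: float
    nes: float
    p: float
    n_hits: int
    n_perm: int
    null_es: np.ndarray = field(repr=False)


def _es_from_positions(pos: np.ndarray, w: np.ndarray, n_genes: int) -> float:
    """Signed maximal deviation of the weighted KS running sum.

    ``pos`` are sorted 0-based positions of set members in the ranked list,
    ``w`` their (non-negative) weights.  Extrema occur at a hit or just
    before the next hit, so only O(k) candidates need checking.
    """
    k = len(pos)
    W = w.sum()
    if W == 0:
        w = np.ones(k)
        W = float(k)
    n_miss = n_genes - k
    cumw = np.cumsum(w) / W
    i = np.arange(1, k + 1)
    miss_at_hit = (pos + 1 - i) / n_miss  # misses seen up to and incl. position pos[j]
    dev_top = cumw - miss_at_hit  # just after each hit
    miss_before = (pos - (i - 1)) / n_miss  # misses up to just before each hit
    dev_bottom = np.concatenate([[0.0], cumw[:-1]]) - miss_before
    candidates = np.concatenate([dev_top, dev_bottom])
    best = candidates[np.argmax(np.abs(candidates))]
    return float(best)


def gsea(
    ranked: pd.Series,
    gene_set,
    n_perm: int = 10_000,
    seed: int = 0,
    weight: float = 1.0,
    min_hits: int = 5,
) -> GseaResult:
    """Weighted-KS gene set enrichment on a ranked list.

    ``ranked`` maps gene -> ranking statistic (e.g. L2FC); it is sorted in
    decreasing order internally.  ES is the signed maximal deviation of the
    running sum with hit increments |stat|^weight.  The null permutes gene
    labels (``n_perm`` draws, seeded); NES divides ES by the mean |null ES|
    of the same sign, and the p-value is two-sided over all null ES with +1
    correction.
    """
    if ranked.index.duplicated().any():
        raise ValueError("ranked list contains duplicate genes")
    ranked = ranked.sort_values(ascending=False)
    stats = np.abs(ranked.to_numpy(dtype=float)) ** weight
    n_genes = len(ranked)
    hit_mask = ranked.index.isin(set(gene_set))
    pos = np.flatnonzero(hit_mask)
    k = len(pos)
    if k == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if k < min_hits:
        raise ValueError(f"only {k} set genes in the ranked list (< {min_hits})")
    if k == n_genes:
        raise ValueError("gene set covers the whole ranked list")
    es = _es_from_positions(pos, stats[pos], n_genes)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        p = np.sort(rng.choice(n_genes, size=k, replace=False))
        null[b] = _es_from_positions(p, stats[p], n_genes)
    p_two = (1.0 + np.sum(np.abs(null) >= abs(es))) / (1.0 + n_perm)
    same_sign = null[np.sign(null) == np.sign(es)]
    denom = np.mean(np.abs(same_sign)) if len(same_sign) else np.mean(np.abs(null))
    nes = es / denom if denom > 0 else np.nan
    return GseaResult(es=es, nes=float(nes), p=float(p_two), n_hits=k, n_perm=n_perm, null_es=null)


def average_member_l2fc(
    gene_set,
    de_tables: Sequence[pd.DataFrame],
    regulated_by: Sequence[pd.DataFrame] | None = None,
    l2fc_min: float = 1.0,
    alpha: float = 0.05,
) -> tuple[float, pd.DataFrame]:
    """Mean L2FC of set members pooled over identities where each member is
    Vhl-regulated.

    ``de_tables`` supply the L2FC values to average (one per identity, e.g.
    VHKO-vs-VKO); ``regulated_by`` (same length; defaults to ``de_tables``)
    supply the tables in which membership of the regulated set is assessed
    (e.g. VKO-vs-ConKO).  A member contributes one value per identity in
    which it is regulated.
    """
    from .de import call_regulated

    if regulated_by is None:
        regulated_by = de_tables
    if len(regulated_by) != len(de_tables):
        raise ValueError("de_tables and regulated_by must align")
    values = []
    for de, reg in zip(de_tables, regulated_by):
        up, down = call_regulated(reg, l2fc_min=l2fc_min, alpha=alpha)
        regulated = up | down
        for g in gene_set:
            if g in regulated and g in de.index:
                values.append({"gene": g, "l2fc": float(de.loc[g, "l2fc"])})
    pooled = pd.DataFrame(values, columns=["gene", "l2fc"])
    if pooled.empty:
        warnings.warn("no regulated members; average L2FC undefined", stacklevel=2)
        return float("nan"), pooled
    return float(pooled["l2fc"].mean()), pooled


def cluster_terms(profiles: pd.DataFrame) -> list[str]:
    """Order enriched terms by Ward-linkage hierarchical clustering of their
    member-gene L2FC profiles (Euclidean distances); returns the leaf order."""
    if len(profiles) < 3:
        return list(profiles.index)
    Z = linkage(profiles.to_numpy(dtype=float), method="ward")
    return [profiles.index[i] for i in leaves_list(Z)]
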