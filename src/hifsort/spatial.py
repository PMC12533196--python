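"""Tagged-cell abundance and clonal neighborhood statistics in tissue tables.

Each row of a tissue table is one nucleus with centroid coordinates in
micrometres, a region label, nucleus area, and marker intensities or flags.
The clonality statistic is, for every tagged (tdTomato-positive) cell, the
number of other tagged cells within a fixed internuclear radius (default
16 um, inclusive); its per-mouse frequency distribution over the bins
{0,1,2,3,4,>=5} indexes clonal expansion independently of the initial
recombination rate.  Distributions are compared by one-way MANOVA with
Wilks' lambda (Rao's F approximation), medians by Kruskal-Wallis with Dunn's
post-hoc z tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import f as f_dist, kruskal, norm, rankdata

__all__ = [
    "filter_nuclei",
    "call_positive",
    "positive_fraction",
    "neighbor_counts",
    "NeighborStats",
    "coverage_fraction",
    "wilks_manova",
    "compare_distributions",
    "compare_medians",
]

DEFAULT_BINS = (0, 1, 2, 3, 4)  # plus an implicit >=5 bin


def filter_nuclei(
    table: pd.DataFrame, min_area: float = 15.0, max_area: float = 200.0
) -> pd.DataFrame:
    """Drop nuclei with area < min_area or > max_area (bounds inclusive:
    the exclusions are strict, so a nucleus of exactly 15 or 200 um^2 stays)."""
    area = table["nucleus_area_um2"]
    return table.loc[(area >= min_area) & (area <= max_area)].copy()


def call_positive(
    table: pd.DataFrame, channel: str = "tdtomato", threshold: float = 0.5
) -> pd.Series:
    """Positivity flags for a marker channel: intensity strictly above the
    (configured, logged) threshold.  If the table already carries a
    ``{channel}_pos`` flag column it is used; carrying both the flag and the
    intensity is ambiguous and an error."""
    flag_col, int_col = f"{channel}_pos", f"{channel}_intensity"
    has_flag, has_int = flag_col in table.columns, int_col in table.columns
    if has_flag and has_int:
        raise ValueError(
            f"table carries both {flag_col!r} and {int_col!r}; provide one"
        )
    if has_flag:
        return table[flag_col].astype(bool)
    if not has_int:
        raise ValueError(f"no {int_col!r} or {flag_col!r} column")
    out = table[int_col] > threshold
    out.name = flag_col
    out.attrs["threshold"] = threshold
    return out


def positive_fraction(
    table: pd.DataFrame,
    positive: pd.Series,
    by: tuple[str, ...] = ("mouse", "region"),
) -> pd.DataFrame:
    """(#positive)/(#nuclei) per group (default mouse x region)."""
    df = table.assign(_pos=positive.astype(bool).to_numpy())
    g = df.groupby(list(by), observed=True)["_pos"]
    out = g.agg(n_nuclei="size", n_positive="sum").reset_index()
    out["fraction"] = out["n_positive"] / out["n_nuclei"]
    return out


@dataclass
class NeighborStats:
    """Per-tagged-cell neighbor counts and per-mouse summaries."""

    per_cell: pd.DataFrame  # cell_id, mouse, n_neighbors
    per_mouse: pd.DataFrame  # mouse, freq_0..freq_4, freq_5plus, mean_count, n_tagged
    r_um: float
    bins: tuple[int, ...]


def _bin_counts(counts: np.ndarray, bins: tuple[int, ...]) -> dict[str, int]:
    out = {f"freq_{b}": int(np.sum(counts == b)) for b in bins}
    out[f"freq_{bins[-1] + 1}plus"] = int(np.sum(counts > bins[-1]))
    return out


def neighbor_counts(
    table: pd.DataFrame,
    positive: pd.Series,
    r_um: float = 16.0,
    bins: tuple[int, ...] = DEFAULT_BINS,
) -> NeighborStats:
    """Count, for each tagged cell, the other tagged cells within Euclidean
    distance <= r_um (the focal cell excluded), per mouse.

    Uses a k-d tree; results equal the all-pairs computation exactly.
    """
    if r_um <= 0:
        raise ValueError("radius must be positive")
    pos = positive.astype(bool).to_numpy()
    per_cell_rows = []
    per_mouse_rows = []
    for mouse, sub in table.assign(_pos=pos).groupby("mouse", observed=True):
        tagged = sub.loc[sub["_pos"]]
        if tagged.empty:
            per_mouse_rows.append(
                {"mouse": mouse, **_bin_counts(np.array([]), bins), "mean_count": np.nan, "n_tagged": 0}
            )
            continue
        xy = tagged[["x_um", "y_um"]].to_numpy(dtype=float)
        tree = cKDTree(xy)
        counts = np.array(
            [len(nb) - 1 for nb in tree.query_ball_point(xy, r=r_um)], dtype=int
        )
        for cid, c in zip(tagged["cell_id"], counts):
            per_cell_rows.append({"cell_id": cid, "mouse": mouse, "n_neighbors": int(c)})
        per_mouse_rows.append(
            {
                "mouse": mouse,
                **_bin_counts(counts, bins),
                "mean_count": float(counts.mean()),
                "n_tagged": int(len(counts)),
            }
        )
    per_cell = pd.DataFrame(per_cell_rows, columns=["cell_id", "mouse", "n_neighbors"])
    per_mouse = pd.DataFrame(per_mouse_rows)
    return NeighborStats(per_cell=per_cell, per_mouse=per_mouse, r_um=r_um, bins=bins)


def coverage_fraction(table: pd.DataFrame, positive: pd.Series, r_um: float = 16.0) -> float:
    """Fraction of tagged cells with at least one neighbor of any type within
    r_um — the diagnostic motivating the neighborhood radius."""
    xy = table[["x_um", "y_um"]].to_numpy(dtype=float)
    tree = cKDTree(xy)
    pos_idx = np.flatnonzero(positive.astype(bool).to_numpy())
    if len(pos_idx) == 0:
        raise ValueError("no tagged cells")
    n_any = np.array(
        [len(nb) - 1 for nb in tree.query_ball_point(xy[pos_idx], r=r_um)]
    )
    return float(np.mean(n_any >= 1))


# ---------------------------------------------------------------------------
# statistics


def wilks_manova(X: np.ndarray, labels) -> dict:
    """One-way MANOVA: Wilks' lambda = det(E)/det(E+H) with Rao's F approximation.

    ``X`` is observations x variables; ``labels`` the group of each row.
    Raises on a (numerically) singular within-group matrix E with guidance
    to merge variables/bins.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    n, p = X.shape
    g = len(groups)
    if g < 2:
        raise ValueError("need at least 2 groups")
    if any(np.sum(labels == grp) < 2 for grp in groups):
        raise ValueError("every group needs at least 2 observations (mice)")
    grand = X.mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for grp in groups:
        sub = X[labels == grp]
        m = sub.mean(axis=0)
        d = (m - grand)[:, None]
        H += len(sub) * d @ d.T
        R = sub - m
        E += R.T @ R
    sign, logdet_E = np.linalg.slogdet(E)
    sign2, logdet_T = np.linalg.slogdet(E + H)
    if sign <= 0 or not np.isfinite(logdet_E):
        raise ValueError(
            "within-group covariance matrix is singular; merge neighbor-count "
            "bins (or drop variables) and retry"
        )
    lam = float(np.exp(logdet_E - logdet_T))

    # Rao's F approximation
    q = g - 1
    v = n - g
    t = np.sqrt((p**2 * q**2 - 4) / (p**2 + q**2 - 5)) if (p**2 + q**2 - 5) > 0 else 1.0
    df1 = p * q
    df2 = t * (v - (p - q + 1) / 2.0) - (p * q - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    F = (1.0 - lam_t) / lam_t * df2 / df1
    pval = float(f_dist.sf(F, df1, df2)) if df2 > 0 else float("nan")
    return {"wilks_lambda": lam, "F": float(F), "df1": float(df1), "df2": float(df2), "p": pval}


def compare_distributions(
    freq: pd.DataFrame,
    groups: pd.Series,
    pairs: list[tuple[str, str]] | None = None,
    drop_last: bool = True,
) -> pd.DataFrame:
    """Compare per-mouse neighbor-count frequency distributions between groups.

    ``freq`` holds one row per mouse with the frequency-bin columns; rows are
    converted to proportions and (because proportions are compositional) the
    last bin is dropped before MANOVA.  With ``pairs`` given, a two-group
    MANOVA runs per pair and p-values are Bonferroni-adjusted over the pairs;
    otherwise a single overall MANOVA row is returned.
    """
    counts = freq.to_numpy(dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("a mouse has no tagged cells; drop it before comparing")
    props = counts / totals
    if drop_last:
        # drop the redundant last bin; keep dropping while the dropped tail
        # carries no mass anywhere (the compositional constraint persists)
        k = props.shape[1] - 1
        while k > 1 and np.allclose(props[:, :k].sum(axis=1), 1.0):
            k -= 1
        props = props[:, :k]
    # zero-variance bins contribute nothing and make E singular
    varying = props.std(axis=0) > 0
    if varying.sum() == 0:
        raise ValueError("all frequency bins are constant across mice")
    props = props[:, varying]
    groups = pd.Series(groups).astype(str).reset_index(drop=True)

    rows = []
    if pairs is None:
        res = wilks_manova(props, groups.to_numpy())
        rows.append({"comparison": "overall", **res, "p_adj": res["p"]})
    else:
        for a, b in pairs:
            mask = groups.isin([a, b]).to_numpy()
            res = wilks_manova(props[mask], groups[mask].to_numpy())
            rows.append({"comparison": f"{a}_vs_{b}", **res})
        m = len(pairs)
        for r in rows:
            r["p_adj"] = min(1.0, r["p"] * m)
    return pd.DataFrame(rows)


def compare_medians(
    values,
    groups,
    pairs: list[tuple[str, str]] | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis H (tie-corrected) plus Dunn's pairwise post-hoc z tests.

    Dunn's z uses the rank-mean difference with the standard tie term; the
    pairwise p-values are Bonferroni-adjusted over the requested pairs (all
    pairs by default).
    """
    values = np.asarray(values, dtype=float)
    groups = pd.Series(groups).astype(str).reset_index(drop=True)
    levels = sorted(groups.unique())
    if len(values) < 3:
        raise ValueError("need at least 3 observations")
    samples = [values[(groups == lev).to_numpy()] for lev in levels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("a group is empty")
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    if np.all(values == values[0]):
        H, p_kw = 0.0, 1.0
    else:
        H, p_kw = kruskal(*samples)

    N = len(values)
    ranks = rankdata(values)
    rank_mean = {lev: ranks[(groups == lev).to_numpy()].mean() for lev in levels}
    n_of = {lev: int((groups == lev).sum()) for lev in levels}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (N - 1))

    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1 :]]
    rows = []
    for a, b in pairs:
        if a not in n_of or b not in n_of:
            raise ValueError(f"unknown group in pair ({a}, {b})")
        se = np.sqrt((N * (N + 1) / 12.0 - tie_term) * (1.0 / n_of[a] + 1.0 / n_of[b]))
        z = (rank_mean[a] - rank_mean[b]) / se if se > 0 else 0.0
        p = 2.0 * norm.sf(abs(z))
        rows.append({"pair": f"{a}_vs_{b}", "z": float(z), "p": float(p)})
    m = len(pairs)
    for r in rows:
        r["p_adj"] = min(1.0, r["p"] * m)
    return float(H), float(p_kw), pd.DataFrame(rows)
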