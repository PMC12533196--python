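"""Nucleus filters, positivity calls, neighbor counts vs brute force, and the
MANOVA / Kruskal-Wallis-Dunn statistics against hand computations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hifsort.sim import SpatialSimConfig, simulate_spatial
from hifsort.spatial import (
    call_positive,
    compare_distributions,
    compare_medians,
    coverage_fraction,
    filter_nuclei,
    neighbor_counts,
    positive_fraction,
    wilks_manova,
)


def _table(xy, tagged=None, mouse="m1"):
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "region": "cortex_om",
            "nucleus_area_um2": 50.0,
            "mouse": mouse,
        }
    ), pd.Series(tagged if tagged is not None else [True] * n)


# ---------------------------------------------------------------------------
# filters and positivity


def test_area_bounds_inclusive():
    t = pd.DataFrame(
        {"nucleus_area_um2": [14.9, 15.0, 100.0, 200.0, 200.1],
         "cell_id": list("abcde")}
    )
    kept = filter_nuclei(t)
    assert kept["cell_id"].tolist() == ["b", "c", "d"]


def test_positive_threshold_strict():
    t = pd.DataFrame({"tdtomato_intensity": [0.0, 0.5, 0.50001, 1.0]})
    pos = call_positive(t, "tdtomato", 0.5)
    assert pos.tolist() == [False, False, True, True]


def test_positive_all_when_threshold_zero():
    t = pd.DataFrame({"tdtomato_intensity": [0.1, 0.9]})
    assert call_positive(t, "tdtomato", 0.0).all()


def test_mixed_flag_and_intensity_rejected():
    t = pd.DataFrame({"tdtomato_intensity": [0.1], "tdtomato_pos": [True]})
    with pytest.raises(ValueError, match="both"):
        call_positive(t, "tdtomato", 0.5)


def test_positive_fraction_arithmetic():
    t = pd.DataFrame(
        {"mouse": ["m1"] * 10, "region": ["papilla"] * 10}
    )
    pos = pd.Series([True] * 3 + [False] * 7)
    out = positive_fraction(t, pos)
    assert out["fraction"].iloc[0] == pytest.approx(0.3)


def test_planted_tag_fraction_recovered():
    cfg = SpatialSimConfig(n_cells=2000, tag_fraction=0.3, seed=1)
    table, _ = simulate_spatial(cfg)
    pos = call_positive(table, "tdtomato", 0.5)
    frac = positive_fraction(table, pos)["fraction"].iloc[0]
    assert abs(frac - 0.3) < 4 * np.sqrt(0.3 * 0.7 / 2000)


def test_elimination_lowers_late_papilla_fraction():
    """HIF1A-intact Vhl-null papilla: tagged fraction drops late vs early."""
    def frac(timepoint, seed):
        cfg = SpatialSimConfig(
            region="papilla", n_cells=1500, genotype="VKO", timepoint=timepoint,
            seed=seed,
        )
        t, _ = simulate_spatial(cfg)
        return (t["tdtomato_intensity"] > 0.5).mean()

    assert frac("late", 3) < frac("early", 3) * 0.75


# ---------------------------------------------------------------------------
# neighbor counts


def test_pair_within_radius():
    t, pos = _table([[0, 0], [10, 0]])
    stats = neighbor_counts(t, pos, r_um=16)
    assert stats.per_cell["n_neighbors"].tolist() == [1, 1]


def test_pair_beyond_radius():
    t, pos = _table([[0, 0], [16.01, 0]])
    stats = neighbor_counts(t, pos, r_um=16)
    assert stats.per_cell["n_neighbors"].tolist() == [0, 0]


def test_counts_symmetric_and_exclude_focal():
    rng = np.random.default_rng(0)
    t, pos = _table(rng.uniform(0, 100, size=(60, 2)))
    stats = neighbor_counts(t, pos, r_um=16)
    xy = t[["x_um", "y_um"]].to_numpy()
    d = np.sqrt(((xy[:, None] - xy[None, :]) ** 2).sum(-1))
    within = (d <= 16)
    assert np.array_equal(
        stats.per_cell["n_neighbors"].to_numpy(), within.sum(1) - 1
    )
    assert np.array_equal(within, within.T)


def test_kdtree_equals_bruteforce_on_random_tables():
    """Spatial-index path equals the O(n^2) all-pairs scan exactly."""
    rng = np.random.default_rng(7)
    for rep in range(50):
        n = rng.integers(20, 200)
        xy = rng.uniform(0, 300, size=(n, 2))
        tagged = rng.random(n) < 0.5
        t, _ = _table(xy)
        stats = neighbor_counts(t, pd.Series(tagged), r_um=16)
        sub = xy[tagged]
        d2 = ((sub[:, None] - sub[None, :]) ** 2).sum(-1)
        brute = (d2 <= 16**2).sum(1) - 1
        assert np.array_equal(stats.per_cell["n_neighbors"].to_numpy(), brute)


def test_bruteforce_equality_large():
    rng = np.random.default_rng(11)
    xy = rng.uniform(0, 1000, size=(2000, 2))
    t, pos = _table(xy)
    stats = neighbor_counts(t, pos, r_um=16)
    d2 = ((xy[:, None] - xy[None, :]) ** 2).sum(-1)
    brute = (d2 <= 16**2).sum(1) - 1
    assert np.array_equal(stats.per_cell["n_neighbors"].to_numpy(), brute)


def test_frequency_vector_sums_to_tagged_cells():
    rng = np.random.default_rng(2)
    t, _ = _table(rng.uniform(0, 200, size=(100, 2)))
    tagged = pd.Series(rng.random(100) < 0.4)
    stats = neighbor_counts(t, tagged, r_um=16)
    freq_cols = [c for c in stats.per_mouse.columns if c.startswith("freq_")]
    assert stats.per_mouse[freq_cols].sum(axis=1).iloc[0] == tagged.sum()


def test_invalid_radius_rejected():
    t, pos = _table([[0, 0]])
    with pytest.raises(ValueError, match="radius"):
        neighbor_counts(t, pos, r_um=0)


def test_coverage_diagnostic_high_on_dense_cortex():
    """Nearly every tagged cell in a dense simulated cortex field has some
    neighbor within 16 um (the radius-selection rationale)."""
    cfg = SpatialSimConfig(n_cells=2000, seed=5)
    table, _ = simulate_spatial(cfg)
    pos = call_positive(table, "tdtomato", 0.5)
    assert coverage_fraction(table, pos, r_um=16.0) > 0.9


# ---------------------------------------------------------------------------
# MANOVA / Wilks


def test_wilks_null_lambda_near_one():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(60, 3))
    labels = ["a"] * 30 + ["b"] * 30
    res = wilks_manova(X, labels)
    assert res["wilks_lambda"] > 0.8
    assert res["p"] > 0.05


def test_wilks_matches_hand_determinants():
    """2-group, 2-variable toy: Lambda = det(E)/det(E+H) evaluated by hand."""
    g1 = np.array([[2.0, 3.0], [4.0, 5.0], [6.0, 4.0]])
    g2 = np.array([[5.0, 8.0], [7.0, 9.0], [9.0, 10.0]])
    X = np.vstack([g1, g2])
    labels = ["a"] * 3 + ["b"] * 3
    # hand computation with explicit 2x2 determinants
    m1, m2, grand = g1.mean(0), g2.mean(0), X.mean(0)
    H = 3 * np.outer(m1 - grand, m1 - grand) + 3 * np.outer(m2 - grand, m2 - grand)
    E = np.zeros((2, 2))
    for g, m in ((g1, m1), (g2, m2)):
        for row in g:
            E += np.outer(row - m, row - m)
    det = lambda M: M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
    expected = det(E) / det(E + H)
    res = wilks_manova(X, labels)
    assert res["wilks_lambda"] == pytest.approx(expected, rel=1e-12)


def test_wilks_matches_statsmodels_manova():
    """Independent cross-check of Lambda and the F-test against statsmodels."""
    from statsmodels.multivariate.manova import MANOVA

    rng = np.random.default_rng(9)
    X = rng.normal(size=(24, 3))
    X[12:] += [0.8, 0.0, -0.5]
    labels = np.array(["a"] * 12 + ["b"] * 12)
    res = wilks_manova(X, labels)
    df = pd.DataFrame(X, columns=["v1", "v2", "v3"])
    df["group"] = labels
    mv = MANOVA.from_formula("v1 + v2 + v3 ~ group", data=df)
    tab = mv.mv_test().results["group"]["stat"]
    assert res["wilks_lambda"] == pytest.approx(tab.loc["Wilks' lambda", "Value"], rel=1e-8)
    assert res["p"] == pytest.approx(tab.loc["Wilks' lambda", "Pr > F"], rel=1e-6)


def test_singular_within_matrix_rejected():
    X = np.zeros((6, 3))  # no within-group variation at all
    with pytest.raises(ValueError, match="merge"):
        wilks_manova(X, ["a"] * 3 + ["b"] * 3)


def test_compare_distributions_pairwise_bonferroni():
    rng = np.random.default_rng(4)
    freq = pd.DataFrame(
        rng.integers(5, 40, size=(12, 4)),
        columns=["freq_0", "freq_1", "freq_2", "freq_3plus"],
    )
    groups = pd.Series(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
    out = compare_distributions(freq, groups, pairs=[("a", "b"), ("a", "c")])
    assert len(out) == 2
    assert (out["p_adj"] >= out["p"] - 1e-15).all()
    assert (out["p_adj"] <= np.minimum(1.0, out["p"] * 2) + 1e-15).all()


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn


def test_kruskal_wallis_classic_h():
    """Groups {1,2,3}, {4,5,6}, {7,8,9}: H = 7.2 by the direct rank formula."""
    values = [1, 2, 3, 4, 5, 6, 7, 8, 9]
    groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
    H, p, dunn = compare_medians(values, groups)
    assert H == pytest.approx(7.2)
    assert set(dunn["pair"]) == {"a_vs_b", "a_vs_c", "b_vs_c"}


def test_all_equal_values_h_zero():
    H, p, _ = compare_medians([5.0] * 9, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
    assert H == 0.0 and p == 1.0


def test_dunn_z_matches_direct_formula_no_ties():
    values = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9], dtype=float)
    groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
    _, _, dunn = compare_medians(values, groups, pairs=[("a", "c")])
    # rank means: a -> 2, c -> 8; se = sqrt(N(N+1)/12 * (1/3+1/3))
    se = np.sqrt(9 * 10 / 12 * (2 / 3))
    assert dunn["z"].iloc[0] == pytest.approx((2 - 8) / se)


def test_kw_null_p_uniform():
    rng = np.random.default_rng(8)
    ps = []
    for rep in range(500):
        values = rng.normal(size=12)
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        _, p, _ = compare_medians(values, groups)
        ps.append(p)
    from scipy.stats import kstest

    assert kstest(ps, "uniform").pvalue > 0.01


def test_empty_group_rejected():
    with pytest.raises(ValueError):
        compare_medians([1.0, 2.0, 3.0], ["a", "a", "a"])
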