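"""Marker derivation, rank-ceiling scoring, cell-type assignment and
binned-control scoring against hand-computed oracles and planted truth."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

import anndata as ad

from hifsort.annotate import (
    MarkerSet,
    assign_cell_type,
    assign_pt_class,
    binned_control_score,
    derive_markers,
    log_normalize,
    rank_signature_score,
)


def _adata(X, gene_ids=None, **obs_cols):
    X = np.asarray(X)
    obs = pd.DataFrame(index=[f"c{i}" for i in range(X.shape[0])])
    for k, v in obs_cols.items():
        obs[k] = v
    genes = gene_ids or [f"g{i}" for i in range(X.shape[1])]
    var = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    return ad.AnnData(X=X, obs=obs, var=var)


# ---------------------------------------------------------------------------
# derive_markers


@pytest.mark.parametrize(
    "l2fc,pct_in,pct_out,included",
    [
        (1.5, 0.6, 0.1, True),   # all thresholds passed
        (1.5, 0.5, 0.1, False),  # pct_in boundary is strict
        (1.0, 0.6, 0.1, False),  # l2fc boundary is strict
        (1.5, 0.6, 0.2, False),  # pct_out boundary is strict
    ],
)
def test_marker_thresholds_strict(l2fc, pct_in, pct_out, included):
    table = pd.DataFrame(
        {"l2fc": [l2fc], "pct_in": [pct_in], "pct_out": [pct_out]}, index=["gene"]
    )
    ms = derive_markers(table)
    assert ("gene" in ms.genes) is included


def test_marker_toy_exact_subset():
    table = pd.DataFrame(
        {
            "l2fc": [2.0, 1.2, 0.5, 3.0, 1.1],
            "pct_in": [0.9, 0.55, 0.9, 0.4, 0.7],
            "pct_out": [0.05, 0.19, 0.1, 0.1, 0.25],
        },
        index=[f"g{i}" for i in range(5)],
    )
    # manual rule application: g0 passes; g1 passes; g2 fails l2fc; g3 fails
    # pct_in; g4 fails pct_out
    assert set(derive_markers(table).genes) == {"g0", "g1"}


# ---------------------------------------------------------------------------
# rank_signature_score


def test_rank_score_maximal_when_signature_tops_ranking():
    X = np.zeros((1, 30))
    X[0, :3] = [30, 20, 10]  # signature genes take ranks 1..3
    a = _adata(X)
    ms = MarkerSet("s", ("g0", "g1", "g2"))
    s = rank_signature_score(a, ms, max_rank=10)
    assert s["s"].iloc[0] == pytest.approx(1.0)


def test_rank_score_near_zero_when_all_clipped():
    X = np.zeros((1, 30))
    X[0, 10:20] = 5  # other genes expressed; signature unexpressed
    a = _adata(X)
    ms = MarkerSet("s", ("g0", "g1", "g2"))
    s = rank_signature_score(a, ms, max_rank=10)
    assert abs(s["s"].iloc[0]) <= 1.0 / 10 + 1e-12


def test_rank_score_matches_direct_formula():
    """20-gene x 1-cell toy with hand-assigned ranks, n=3, max_rank=10."""
    X = np.zeros((1, 20))
    X[0] = np.arange(20, 0, -1)  # g0 rank 1, g1 rank 2, ...
    a = _adata(X)
    ms = MarkerSet("s", ("g1", "g4", "g14"))  # ranks 2, 5, 15 -> clipped 11
    s = rank_signature_score(a, ms, max_rank=10)
    u = (2 + 5 + 11) - 3 * 4 / 2
    expected = 1 - u / (3 * 10)
    assert s["s"].iloc[0] == pytest.approx(expected)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    hnp.arrays(
        np.float64,
        shape=(4, 25),
        elements=st.floats(0, 50, allow_nan=False),
    )
)
def test_rank_score_bounded_on_arbitrary_expression(X):
    """The rank-ceiling score stays in [0, 1] whatever the expression values."""
    a = _adata(X)
    ms = MarkerSet("s", ("g0", "g1", "g2"))
    s = rank_signature_score(a, ms, max_rank=12)
    assert ((s["s"] >= -1e-9) & (s["s"] <= 1 + 1e-9)).all()


def test_rank_score_invariant_to_monotone_transform():
    rng = np.random.default_rng(0)
    X = rng.poisson(3.0, size=(40, 60)).astype(float)
    a1 = _adata(X)
    a2 = _adata(np.expm1(X / 2))  # strictly increasing transform
    ms = MarkerSet("s", tuple(f"g{i}" for i in range(8)))
    s1 = rank_signature_score(a1, ms, max_rank=30)
    s2 = rank_signature_score(a2, ms, max_rank=30)
    np.testing.assert_allclose(s1["s"], s2["s"])


def test_rank_score_contract_errors():
    a = _adata(np.ones((2, 20)))
    with pytest.raises(ValueError, match="max_rank"):
        rank_signature_score(a, MarkerSet("s", ("g0",)), max_rank=25)
    with pytest.raises(ValueError, match="no genes"):
        rank_signature_score(a, MarkerSet("s", ("absent",)), max_rank=10)
    with pytest.raises(ValueError, match="exceeds"):
        rank_signature_score(a, MarkerSet("s", tuple(f"g{i}" for i in range(8))), max_rank=5)


# ---------------------------------------------------------------------------
# assign_cell_type


def test_argmax_assignment_and_tie_flag():
    scores = pd.DataFrame(
        {"PT_S1": [0.8, 0.5], "PT_S2": [0.3, 0.5]}, index=["c0", "c1"]
    )
    sets = [MarkerSet("PT_S1", ("a",)), MarkerSet("PT_S2", ("b",))]
    out = assign_cell_type(scores, sets)
    assert out.loc["c0", "cell_type"] == "PT_S1"
    # exact tie: lexicographically first label, flagged
    assert out.loc["c1", "cell_type"] == "PT_S1"
    assert bool(out.loc["c1", "tie"]) and not bool(out.loc["c0", "tie"])


def test_sex_specific_sets_respected():
    scores = pd.DataFrame(
        {"PT_S2_M": [0.9, 0.9], "PT_S2_F": [0.95, 0.95], "PT_S1": [0.1, 0.92]},
        index=["c0", "c1"],
    )
    sets = [
        MarkerSet("PT_S2_M", ("a",), cell_type="PT_S2", sex="M"),
        MarkerSet("PT_S2_F", ("b",), cell_type="PT_S2", sex="F"),
        MarkerSet("PT_S1", ("c",), cell_type="PT_S1"),
    ]
    sex = pd.Series(["M", "M"], index=scores.index)
    out = assign_cell_type(scores, sets, sex=sex)
    # the female set never competes for male cells
    assert out.loc["c0", "cell_type"] == "PT_S2"
    assert out.loc["c1", "cell_type"] == "PT_S1"


def test_assignment_recovers_planted_identities(study):
    a = study.res["adata"]
    acc = (a.obs["cell_type"] == a.obs["true_cell_type"]).mean()
    assert acc >= 0.95


# ---------------------------------------------------------------------------
# binned_control_score


def test_self_control_degenerate_toy_scores_zero():
    """With one bin containing only the signature genes, controls equal the
    signature and scores vanish."""
    X = np.array([[4.0, 6.0], [1.0, 3.0], [5.0, 5.0]])
    a = _adata(X)
    s = binned_control_score(a, ["g0", "g1"], n_bins=1, n_ctrl=2, seed=0)
    np.testing.assert_allclose(s.to_numpy(), 0.0, atol=1e-12)


def test_binned_control_matches_hand_computation():
    """6-gene toy, 2 bins, n_ctrl=1: recompute the score from the recorded
    control draw."""
    rng = np.random.default_rng(5)
    X = rng.poisson([1, 2, 3, 10, 20, 30], size=(4, 6)).astype(float)
    a = _adata(X)
    sig = ["g1", "g4"]
    s = binned_control_score(a, sig, n_bins=2, n_ctrl=1, seed=42)
    controls = s.attrs["control_genes"]
    ln = log_normalize(a)
    pos = {g: i for i, g in enumerate(a.var.index)}
    expected = ln[:, [pos[g] for g in sig]].mean(axis=1) - ln[
        :, [pos[g] for g in controls]
    ].mean(axis=1)
    np.testing.assert_allclose(s.to_numpy(), expected)


def test_random_signatures_center_on_zero(study):
    """Expectation ~0 for random gene sets: |mean| < 3 SE over 50 draws."""
    adata = study.adata[study.adata.obs["genotype"] == "ConKO"][:400].copy()
    rng = np.random.default_rng(1)
    means = []
    for k in range(50):
        genes = rng.choice(adata.var.index.to_numpy(), size=20, replace=False)
        s = binned_control_score(adata, genes, n_bins=25, n_ctrl=25, seed=k)
        means.append(s.mean())
    means = np.asarray(means)
    assert abs(means.mean()) < 3 * means.std(ddof=1) / np.sqrt(len(means))


def test_planted_program_separates_genotypes(study):
    """Planted up-program genes score higher in VKO than ConKO cells."""
    truth = study.truth
    genes = truth.loc[truth["program"] == "hif_independent_early_up", "gene"]
    mask = study.adata.obs["timepoint"] == "late"
    sub = study.adata[mask.to_numpy()].copy()
    s = binned_control_score(sub, genes, n_bins=25, n_ctrl=25, seed=3)
    geno = sub.obs["genotype"]
    assert s[(geno == "VKO").to_numpy()].median() > s[(geno == "ConKO").to_numpy()].median()


# ---------------------------------------------------------------------------
# assign_pt_class


def test_class_threshold_strict():
    s = pd.Series({"c0": 0.2, "c1": 0.125, "c2": -0.4})
    out = assign_pt_class(s)
    assert out.tolist() == ["A", "B", "B"]


def test_all_zero_matrix_all_class_b():
    a = _adata(np.zeros((5, 40)))
    s = binned_control_score(a, ["g0", "g1"], n_bins=1, n_ctrl=2, seed=0)
    assert (assign_pt_class(s) == "B").all()


def test_class_recovery_on_planted_modules(study):
    a = study.res["adata"]
    acc = (a.obs["pt_class"] == a.obs["true_class"]).mean()
    assert acc >= 0.95
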