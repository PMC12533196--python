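"""The dependence ledger: rule instantiations, the exhaustive truth table
against an independently coded brute-force evaluator, temporal labels,
pooling and the anti-correlation diagnostic."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from hifsort.classify import (
    anticorrelation_diagnostic,
    categorize,
    classify_dependence,
    classify_temporal,
    pool_categories,
)

# ---------------------------------------------------------------------------
# brute-force oracle: a literal, independent restatement of the rules


def oracle_call(l2fc_vko, padj_vko, contrasts, l2fc_min=1.0, alpha=0.05):
    """contrasts: {'vhko'|'veko'|'vheko': (l2fc, padj)} -> (vhl_dep, category).

    Written as plain nested conditionals, independent of the vectorized
    implementation under test.
    """
    vhl_dep = abs(l2fc_vko) > l2fc_min and padj_vko < alpha
    if not vhl_dep:
        return False, None
    dep = {}
    for name, (l2fc, padj) in contrasts.items():
        opposite = (l2fc_vko > 0 and l2fc < 0) or (l2fc_vko < 0 and l2fc > 0)
        more_than_half = abs(l2fc) > 0.5 * abs(l2fc_vko)
        dep[name] = padj < alpha and opposite and more_than_half
    if dep["vhko"] and dep["veko"]:
        cat = "HIF1A_or_HIF2A"
    elif dep["vhko"]:
        cat = "HIF1A_alone"
    elif dep["veko"]:
        cat = "HIF2A_alone"
    elif dep["vheko"]:
        cat = "HIF1A_plus_HIF2A"
    else:
        cat = "ambiguous"
    return True, cat


def _de(l2fc, padj):
    genes = [f"g{i}" for i in range(len(l2fc))]
    return pd.DataFrame({"l2fc": l2fc, "padj": padj}, index=genes)


def run_classifier(rows):
    """rows: list of (vko, vhko, veko, vheko) with each a (l2fc, padj) pair."""
    cols = list(zip(*rows))
    tables = [_de([r[0] for r in c], [r[1] for r in c]) for c in cols]
    return classify_dependence(*tables)


# ---------------------------------------------------------------------------
# rule instantiations


def test_hif1a_alone_instantiation():
    """Up gene fully reversed by Hif1a loss, untouched by Epas1 loss."""
    calls = run_classifier(
        [(((2.0), 0.001), (-1.2, 0.01), (-0.3, 0.4), (-1.8, 0.001))]
    )
    row = calls.iloc[0]
    assert row["vhl_dependent"]
    assert row["category"] == "HIF1A_alone"
    assert row["hif1a_dependent"] and not row["epas1_dependent"]


def test_half_magnitude_boundary_is_strict():
    """|l2fc| = 0.9 against a VKO effect of 2.0: 0.9 > 1.0 is false."""
    calls = run_classifier(
        [((2.0, 0.001), (-0.9, 0.001), (-0.3, 0.4), (-1.8, 0.001))]
    )
    row = calls.iloc[0]
    assert not row["hif1a_dependent"]
    assert row["category"] == "HIF1A_plus_HIF2A"


def test_same_sign_knockout_effect_never_counts():
    """A knockout effect in the same direction as the VKO effect is not
    dependence, however large or significant."""
    calls = run_classifier(
        [((2.0, 0.001), (1.8, 0.0001), (-0.2, 0.9), (-0.2, 0.9))]
    )
    row = calls.iloc[0]
    assert not row["hif1a_dependent"]
    assert row["category"] == "ambiguous"


def test_category_function_total_over_flag_lattice():
    for h1, h2, both in itertools.product([False, True], repeat=3):
        cat = categorize(h1, h2, both)
        assert cat in {
            "HIF1A_alone", "HIF2A_alone", "HIF1A_or_HIF2A",
            "HIF1A_plus_HIF2A", "ambiguous",
        }


def exhaustive_cases():
    """All significance/sign/magnitude combinations for the three knockout
    contrasts, for an up- and a down-regulated Vhl-dependent gene."""
    # knockout contrast states: (sig, big) x sign relative to the VKO effect
    states = [
        (-1.2, 0.01),   # significant, > half magnitude, opposite
        (-0.6, 0.01),   # significant, < half magnitude, opposite
        (-1.2, 0.50),   # not significant, opposite
        (1.2, 0.01),    # significant, big, same sign
        (0.6, 0.50),    # not significant, same sign
    ]
    for vko_l2fc in (2.0, -2.0):
        sign = 1.0 if vko_l2fc > 0 else -1.0
        for combo in itertools.product(states, repeat=3):
            # states are written for an up gene; mirror the signs for a down gene
            row = tuple((l2 if sign > 0 else -l2, p) for l2, p in combo)
            yield ((vko_l2fc, 0.001), *row)


def test_exhaustive_truth_table_matches_oracle():
    cases = list(exhaustive_cases())
    calls = run_classifier(cases)
    for i, case in enumerate(cases):
        vko, vhko, veko, vheko = case
        dep, cat = oracle_call(vko[0], vko[1], {"vhko": vhko, "veko": veko, "vheko": vheko})
        row = calls.iloc[i]
        assert bool(row["vhl_dependent"]) == dep, f"case {case}"
        got = row["category"] if row["vhl_dependent"] else None
        assert got == cat, f"case {case}: {got} != {cat}"


def test_non_vhl_dependent_gene_gets_no_category():
    calls = run_classifier([((0.5, 0.001), (-1.0, 0.01), (-1.0, 0.01), (-1.0, 0.01))])
    row = calls.iloc[0]
    assert not row["vhl_dependent"] and row["category"] is None


# ---------------------------------------------------------------------------
# temporal classification


def _tde(**genes):
    idx = list(genes)
    return pd.DataFrame(
        {
            "l2fc": [genes[g][0] for g in idx],
            "padj": [genes[g][1] for g in idx],
        },
        index=idx,
    )


def test_temporal_definitions():
    # gene a: up in VKO-vs-ConKO early only -> early
    # gene b: up late-vs-early in VKO only -> adaptive
    # gene c: up late-vs-early in both VKO and ConKO -> none
    # gene d: both early and adaptive -> both_excluded
    early = _tde(a=(2.0, 0.01), b=(0.1, 0.9), c=(0.1, 0.9), d=(2.0, 0.01))
    vko_t = _tde(a=(0.1, 0.9), b=(2.0, 0.01), c=(2.0, 0.01), d=(2.0, 0.01))
    con_t = _tde(a=(0.1, 0.9), b=(0.1, 0.9), c=(2.0, 0.01), d=(0.1, 0.9))
    out = classify_temporal(early, vko_t, con_t)
    assert out.loc["a", "temporal"] == "early"
    assert out.loc["b", "temporal"] == "adaptive"
    assert out.loc["c", "temporal"] == "none"
    assert out.loc["d", "temporal"] == "both_excluded"


def test_temporal_recovery_on_planted_programs(study):
    from hifsort.evaluate import temporal_recovery

    rec = temporal_recovery(study.res["calls"], study.truth).set_index("timing")
    assert rec.loc["adaptive", "sensitivity"] >= 0.8
    assert rec.loc["early", "mislabel_rate"] <= 0.05


# ---------------------------------------------------------------------------
# pooling


def _call_frame(rows):
    df = pd.DataFrame(
        rows, columns=["gene", "direction", "vhl_dependent", "category"]
    ).set_index("gene")
    return df


def test_pooling_union_and_conflicts():
    s1 = _call_frame([("a", "up", True, "HIF1A_alone"), ("b", "up", True, "HIF2A_alone")])
    s3 = _call_frame([("a", "up", True, "HIF2A_alone"), ("c", "up", True, "HIF1A_alone")])
    pooled = pool_categories({"PT_S1_A": s1, "PT_S3_B": s3})
    # 'a' conflicts (HIF1A in S1, HIF2A in S3, same direction) -> excluded
    assert pooled.n_conflicts == 1
    assert pooled.conflicts.iloc[0]["gene"] == "a"
    assert pooled.hif1a["up"] == {"c"}
    assert pooled.hif2a["up"] == {"b"}


def test_pooling_no_conflicts_on_consistent_planting(study):
    assert study.res["pooled"].n_conflicts == 0


# ---------------------------------------------------------------------------
# anticorrelation diagnostic


def test_perfect_reversal_gives_minus_one():
    rng = np.random.default_rng(0)
    l1 = rng.normal(size=30)
    a = pd.DataFrame({"l2fc": -l1}, index=[f"g{i}" for i in range(30)])
    b = pd.DataFrame({"l2fc": l1}, index=[f"g{i}" for i in range(30)])
    assert anticorrelation_diagnostic(a, b, a.index) == pytest.approx(-1.0)


def test_independent_vectors_uncorrelated():
    rng = np.random.default_rng(1)
    hits = 0
    for rep in range(40):
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        a = pd.DataFrame({"l2fc": x}, index=[f"g{i}" for i in range(200)])
        b = pd.DataFrame({"l2fc": y}, index=a.index)
        if abs(anticorrelation_diagnostic(a, b, a.index)) < 0.2:
            hits += 1
    assert hits >= 38  # >= 95% of replicates


def test_constant_vector_flagged():
    a = pd.DataFrame({"l2fc": np.ones(20)}, index=[f"g{i}" for i in range(20)])
    b = pd.DataFrame({"l2fc": np.arange(20.0)}, index=a.index)
    with pytest.raises(ValueError, match="constant"):
        anticorrelation_diagnostic(a, b, a.index)


def test_planted_hif_dependent_genes_anticorrelate(study):
    """Fully HIF-dependent planted genes show near-total anti-correlation of
    the HIFalpha-codeletion contrast against the Vhl contrast (rho < -0.8)."""
    truth = study.truth
    dep = truth.loc[
        truth["isoform_truth"] != "HIF_independent", "gene"
    ].tolist()
    identity = study.res["identities"][0]
    t = study.res["de"][identity]
    rho = anticorrelation_diagnostic(
        t["VHEKO_vs_VKO_late"], t["VKO_vs_ConKO_late"], dep
    )
    assert rho < -0.8
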