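"""Recovery metrics of classification ledgers against planted ground truth."""

from __future__ import annotations

import pandas as pd

__all__ = ["category_recovery", "temporal_recovery"]


def category_recovery(
    calls_by_identity: dict[str, pd.DataFrame], truth: pd.DataFrame
) -> pd.DataFrame:
    """Per-category sensitivity and the HIF1A_alone <-> HIF2A_alone confusion.

    A planted gene counts as recovered when at least one identity in its
    scope calls it Vhl-dependent with the correct category (planted
    ``HIF_independent`` genes map to the ledger's ``ambiguous``).  Confusion
    counts planted HIF1A_alone genes called HIF2A_alone (or vice versa) in
    any identity.
    """
    expected = {
        "HIF1A_alone": "HIF1A_alone",
        "HIF2A_alone": "HIF2A_alone",
        "HIF1A_or_HIF2A": "HIF1A_or_HIF2A",
        "HIF1A_plus_HIF2A": "HIF1A_plus_HIF2A",
        "HIF_independent": "ambiguous",
    }
    rows = []
    for cat, want in expected.items():
        sub = truth.loc[truth["isoform_truth"] == cat]
        if sub.empty:
            continue
        n = len(sub)
        hit = 0
        confused = 0
        cross = {"HIF1A_alone": "HIF2A_alone", "HIF2A_alone": "HIF1A_alone"}.get(cat)
        for gene in sub["gene"]:
            got = []
            for calls in calls_by_identity.values():
                if gene in calls.index and calls.loc[gene, "vhl_dependent"]:
                    got.append(calls.loc[gene, "category"])
            if want in got:
                hit += 1
            if cross is not None and cross in got:
                confused += 1
        rows.append(
            {
                "isoform_truth": cat,
                "n_planted": n,
                "n_recovered": hit,
                "sensitivity": hit / n,
                "n_confused": confused,
                "confusion": confused / n,
            }
        )
    return pd.DataFrame(rows)


def temporal_recovery(
    calls_by_identity: dict[str, pd.DataFrame], truth: pd.DataFrame
) -> pd.DataFrame:
    """Recovery of planted early/adaptive timing from the temporal labels."""
    rows = []
    for timing in ("early", "adaptive"):
        sub = truth.loc[truth["timing"] == timing]
        if sub.empty:
            continue
        n = len(sub)
        hit = 0
        mislabeled = 0
        other = "adaptive" if timing == "early" else "early"
        for gene in sub["gene"]:
            got = []
            for calls in calls_by_identity.values():
                if "temporal" in calls.columns and gene in calls.index:
                    got.append(calls.loc[gene, "temporal"])
            if timing in got:
                hit += 1
            if other in got and timing not in got:
                mislabeled += 1
        rows.append(
            {
                "timing": timing,
                "n_planted": n,
                "n_recovered": hit,
                "sensitivity": hit / n,
                "n_mislabeled": mislabeled,
                "mislabel_rate": mislabeled / n,
            }
        )
    return pd.DataFrame(rows)
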