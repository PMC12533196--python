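"""Shared fixtures: one study-scale synthetic cohort analysed end-to-end
(session-scoped — several test modules and the acceptance checks reuse it)."""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from hifsort.pipeline import PipelineConfig, analyze_cohort
from hifsort.sim import module_genes, simulate_counts, study_config, study_marker_sets

STUDY_SEED = 11


@pytest.fixture(scope="session")
def study():
    """The bundled study conditions, simulated and analysed once.

    5 genotypes x 2 timepoints x 4 mice, 200 cells per mouse per identity,
    planted |L2FC| = 2 programs of 40 genes per isoform category.
    """
    cfg = study_config(seed=STUDY_SEED)
    adata, truth = simulate_counts(cfg)
    res = analyze_cohort(
        adata.copy(),
        study_marker_sets(cfg),
        module_genes(cfg, "A"),
        PipelineConfig(seed=STUDY_SEED),
    )
    return SimpleNamespace(cfg=cfg, adata=adata, truth=truth, res=res)


@pytest.fixture()
def toy_adata():
    """A tiny hand-checkable cohort: 4 cells x 6 genes with full metadata."""
    import anndata as ad

    X = np.array(
        [
            [5, 0, 1, 0, 2, 0],
            [0, 3, 0, 1, 0, 0],
            [2, 2, 2, 2, 2, 2],
            [0, 0, 0, 0, 0, 9],
        ]
    )
    obs = pd.DataFrame(
        {
            "mouse": ["m1", "m1", "m2", "m2"],
            "sex": ["M", "M", "F", "F"],
            "genotype": ["VKO", "VKO", "ConKO", "ConKO"],
            "timepoint": ["late"] * 4,
        },
        index=[f"c{i}" for i in range(4)],
    )
    var = pd.DataFrame(index=pd.Index([f"g{i}" for i in range(6)], name="gene_id"))
    var["mito_flag"] = [False, False, False, False, False, True]
    return ad.AnnData(X=X, obs=obs, var=var)
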