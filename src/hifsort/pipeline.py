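"""Configuration-driven orchestration of the full analysis.

``analyze_cohort`` runs the in-memory chain qc -> annotate -> pseudobulk DE
(all contrasts x identities) -> dependence/temporal classification ->
pooling -> reference-scaled program scoring, and returns every intermediate
table.  ``run_pipeline`` wraps it with file I/O, YAML configuration, a
logger, and a reproducibility manifest (parameters, seeds, parameter hash,
package versions).  Stage outputs are pure functions of (inputs, config,
seed), so rerunning a config reproduces every table byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import anndata as ad
import pandas as pd
import yaml

from . import __version__
from .annotate import (
    MarkerSet,
    assign_cell_type,
    assign_pt_class,
    binned_control_score,
    rank_signature_score,
)
from .classify import classify_dependence, classify_temporal, pool_categories
from .de import aggregate_pseudobulk, estimate_size_factors, fit_de
from .io import QCParams, apply_qc, read_matrix
from .scoring import score_and_scale

log = logging.getLogger("hifsort")

ISOFORM_CONTRASTS = (
    ("VKO", "ConKO"),
    ("VHKO", "VKO"),
    ("VEKO", "VKO"),
    ("VHEKO", "VKO"),
)


@dataclass
class PipelineConfig:
    """All stage parameters for one run; see docs/methods.md for semantics."""

    # input: either a simulation seed (synthetic cohort) or matrix paths
    simulate: bool = True
    mtx_path: str | None = None
    genes_path: str | None = None
    meta_path: str | None = None
    # QC
    min_genes_per_cell: int = 200
    max_mito_fraction: float = 0.5
    max_genes_factor: float = 3.0
    # annotation
    max_rank: int = 500
    class_threshold: float = 0.125
    # control-gene binning scaled to the synthetic transcriptome size
    # (~1.2k genes); on a genome-wide matrix use the standard 100 / 50
    n_bins: int = 25
    n_ctrl: int = 25
    # DE / classification
    l2fc_min: float = 1.0
    alpha: float = 0.05
    min_cells_per_mouse: int = 10
    # misc
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def param_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def annotate_cohort(
    adata: ad.AnnData,
    marker_sets: list[MarkerSet],
    module_a: list[str],
    config: PipelineConfig,
) -> ad.AnnData:
    """Assign cell type (rank-ceiling argmax) and PT class (binned-control
    module-A score against the class threshold); writes obs columns
    cell_type, pt_class, identity."""
    scores = rank_signature_score(adata, marker_sets, max_rank=config.max_rank)
    assigned = assign_cell_type(scores, marker_sets, sex=adata.obs["sex"])
    adata.obs["cell_type"] = assigned["cell_type"].to_numpy()
    adata.obs["cell_type_tie"] = assigned["tie"].to_numpy()
    score_a = binned_control_score(
        adata, module_a, n_bins=config.n_bins, n_ctrl=config.n_ctrl, seed=config.seed
    )
    adata.obs["module_a_score"] = score_a.to_numpy()
    adata.obs["pt_class"] = assign_pt_class(score_a, config.class_threshold).to_numpy()
    adata.obs["identity"] = (
        adata.obs["cell_type"].astype(str) + "_" + adata.obs["pt_class"].astype(str)
    )
    return adata


def viable_identities(
    adata: ad.AnnData, min_cells: int = 10, min_mice: int = 2
) -> list[str]:
    """Identity strata in which every genotype x timepoint keeps at least
    ``min_mice`` mice with ``min_cells`` cells — the strata where all
    contrasts are estimable.  Tiny spurious strata born of mis-assignment
    are dropped here."""
    obs = adata.obs
    out = []
    for identity, sub in obs.groupby("identity", observed=True):
        counts = (
            sub.groupby(["genotype", "timepoint", "mouse"], observed=True)
            .size()
            .reset_index(name="n")
        )
        ok = counts[counts["n"] >= min_cells]
        mice_per_arm = ok.groupby(["genotype", "timepoint"], observed=True)["mouse"].nunique()
        n_arms_expected = obs["genotype"].nunique() * obs["timepoint"].nunique()
        if len(mice_per_arm) == n_arms_expected and (mice_per_arm >= min_mice).all():
            out.append(str(identity))
    return sorted(out)


def de_all_contrasts(
    adata: ad.AnnData, identities: list[str], config: PipelineConfig
) -> dict[str, dict[str, pd.DataFrame]]:
    """Pseudobulk DE for every identity: the four isoform contrasts at the
    late timepoint and the three temporal contrasts."""
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for identity in identities:
        pb = aggregate_pseudobulk(
            adata, identity, min_cells=config.min_cells_per_mouse
        )
        estimate_size_factors(pb)
        tables: dict[str, pd.DataFrame] = {}
        for target, ref in ISOFORM_CONTRASTS:
            tables[f"{target}_vs_{ref}_late"] = fit_de(
                pb, contrast=("genotype", target, ref), subset={"timepoint": "late"}
            )
        tables["VKO_vs_ConKO_early"] = fit_de(
            pb, contrast=("genotype", "VKO", "ConKO"), subset={"timepoint": "early"}
        )
        for geno in ("VKO", "ConKO"):
            tables[f"{geno}_late_vs_early"] = fit_de(
                pb,
                contrast=("timepoint", "late", "early"),
                subset={"genotype": geno},
            )
        out[identity] = tables
    return out


def classify_all(
    de_tables: dict[str, dict[str, pd.DataFrame]], config: PipelineConfig
) -> dict[str, pd.DataFrame]:
    """Dependence + temporal calls per identity, merged into one ledger."""
    calls = {}
    for identity, t in de_tables.items():
        dep = classify_dependence(
            t["VKO_vs_ConKO_late"],
            t["VHKO_vs_VKO_late"],
            t["VEKO_vs_VKO_late"],
            t["VHEKO_vs_VKO_late"],
            l2fc_min=config.l2fc_min,
            alpha=config.alpha,
            identity=identity,
        )
        tem = classify_temporal(
            t["VKO_vs_ConKO_early"],
            t["VKO_late_vs_early"],
            t["ConKO_late_vs_early"],
            l2fc_min=config.l2fc_min,
            alpha=config.alpha,
            identity=identity,
        )
        dep["temporal"] = tem["temporal"]
        calls[identity] = dep
    return calls


def programs_from_calls(
    calls: dict[str, pd.DataFrame], category: str, direction: str
) -> dict[str, list[str]]:
    """Per-identity gene lists for one isoform category and direction,
    excluding genes flagged as both early and adaptive."""
    out = {}
    for identity, df in calls.items():
        mask = (
            df["vhl_dependent"]
            & (df["category"] == category)
            & (df["direction"] == direction)
        )
        if "temporal" in df.columns:
            mask &= df["temporal"] != "both_excluded"
        genes = list(df.index[mask])
        if genes:
            out[identity] = genes
    return out


def analyze_cohort(
    adata: ad.AnnData,
    marker_sets: list[MarkerSet],
    module_a: list[str],
    config: PipelineConfig,
) -> dict:
    """The full in-memory analysis; returns a dict of stage outputs."""
    log.info("qc: %d cells in", adata.n_obs)
    qc_params = QCParams(
        min_genes_per_cell=config.min_genes_per_cell,
        max_mito_fraction=config.max_mito_fraction,
        max_genes_factor=config.max_genes_factor,
    )
    adata, removal = apply_qc(adata, qc_params)
    log.info("qc: %d cells retained", adata.n_obs)

    adata = annotate_cohort(adata, marker_sets, module_a, config)
    identities = viable_identities(adata, min_cells=config.min_cells_per_mouse)
    log.info("annotate: identities %s", identities)

    de_tables = de_all_contrasts(adata, identities, config)
    calls = classify_all(de_tables, config)
    pooled = pool_categories(calls)
    log.info(
        "classify: pooled HIF1A up/down %d/%d, HIF2A up/down %d/%d, conflicts %d",
        len(pooled.hif1a["up"]),
        len(pooled.hif1a["down"]),
        len(pooled.hif2a["up"]),
        len(pooled.hif2a["down"]),
        pooled.n_conflicts,
    )

    scores = {}
    for cat, direction, name in (
        ("HIF1A_alone", "up", "HIF1A_up"),
        ("HIF2A_alone", "up", "HIF2A_up"),
        ("HIF2A_alone", "down", "HIF2A_down"),
    ):
        programs = programs_from_calls(calls, cat, direction)
        if not programs:
            continue
        scores[name] = score_and_scale(
            adata,
            programs,
            reference="ConKO",
            target="VKO",
            direction=direction,
            reference_timepoint="early",
            target_timepoint="late",
            n_bins=config.n_bins,
            n_ctrl=config.n_ctrl,
            seed=config.seed,
        )

    return {
        "adata": adata,
        "qc_removal": removal,
        "identities": identities,
        "de": de_tables,
        "calls": calls,
        "pooled": pooled,
        "scores": scores,
    }


def run_pipeline(
    config: PipelineConfig,
    outdir,
    marker_sets: list[MarkerSet] | None = None,
    module_a: list[str] | None = None,
) -> Path:
    """File-level pipeline entry point; writes tables and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        from .sim import module_genes, simulate_counts, study_config, study_marker_sets

        sim_cfg = study_config(seed=config.seed)
        adata, truth = simulate_counts(sim_cfg)
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        marker_sets = marker_sets or study_marker_sets(sim_cfg)
        module_a = module_a or module_genes(sim_cfg, "A")
    else:
        if not (config.mtx_path and config.genes_path and config.meta_path):
            raise ValueError("non-simulated runs need mtx/genes/meta paths")
        if marker_sets is None or module_a is None:
            raise ValueError("non-simulated runs need marker_sets and module_a")
        adata = read_matrix(config.mtx_path, config.genes_path, config.meta_path)

    res = analyze_cohort(adata, marker_sets, module_a, config)

    all_calls = pd.concat(
        [df.assign(gene=df.index) for df in res["calls"].values()], ignore_index=True
    )
    cols = [
        "gene", "identity", "direction", "vhl_dependent", "hif1a_dependent",
        "epas1_dependent", "hif1a_epas1_dependent", "category", "temporal",
        "l2fc_vko_con", "padj_vko_con", "l2fc_vhko_vko", "l2fc_veko_vko",
        "l2fc_vheko_vko",
    ]
    all_calls[cols].to_csv(outdir / "calls.tsv", sep="\t", index=False)
    res["pooled"].conflicts.to_csv(outdir / "conflicts.tsv", sep="\t", index=False)
    for name, tab in res["scores"].items():
        tab.to_csv(outdir / f"scores_{name}.tsv", sep="\t", index=False)
    for identity, tables in res["de"].items():
        for label, de in tables.items():
            de.assign(gene=de.index).to_csv(
                outdir / f"de_{identity}_{label}.tsv", sep="\t", index=False
            )

    manifest = {
        "package": "hifsort",
        "version": __version__,
        "seed": config.seed,
        "param_hash": config.param_hash,
        "parameters": config.to_dict(),
        "n_cells_post_qc": int(res["adata"].n_obs),
        "identities": res["identities"],
        "n_conflicts": int(res["pooled"].n_conflicts),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
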