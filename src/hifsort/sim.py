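"""Synthetic single-cell cohorts and tissue point patterns with known ground truth.

The generator emulates the study design this package analyses: tamoxifen-induced
*Vhl* inactivation in mouse proximal tubule (PT), alone or combined with loss of
the HIFalpha isoform genes *Hif1a* and/or *Epas1*, profiled by scRNA-seq of
tdTomato-tagged cells and by slide-scanner quantification of tagged nuclei in
tissue.  Counts are negative-binomial with a gene-level dispersion (Var =
mu + alpha * mu^2), per-cell library factors, a per-mouse random effect that
creates the within-mouse correlation motivating pseudo-bulking, sex-dimorphic
genes, PT segment / Class A-B identity structure, and planted gene programs
whose isoform dependence and early/adaptive timing are known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "PlantedProgram",
    "SimConfig",
    "SpatialSimConfig",
    "simulate_counts",
    "simulate_spatial",
    "study_config",
    "study_marker_sets",
    "module_genes",
    "VHL_NULL_GENOTYPES",
    "ISOFORM_CATEGORIES",
]

#: genotypes in which Vhl is biallelically inactivated in tagged cells
VHL_NULL_GENOTYPES = frozenset({"VKO", "VHKO", "VEKO", "VHEKO"})

ISOFORM_CATEGORIES = (
    "HIF1A_alone",
    "HIF2A_alone",
    "HIF1A_or_HIF2A",
    "HIF1A_plus_HIF2A",
    "HIF_independent",
)


@dataclass(frozen=True)
class PlantedProgram:
    """A block of genes with a known Vhl-dependent effect.

    ``isoform_truth`` fully determines which Vhl-null genotypes express the
    effect: a gene is affected whenever the isoform combination it requires is
    still intact.  ``timing='adaptive'`` restricts the effect to the late
    timepoint; ``'early'`` effects are present at both timepoints (early
    changes persist).
    """

    name: str
    gene_ids: tuple[str, ...]
    direction: str  # 'up' | 'down'
    base_l2fc: float  # magnitude of the VKO-vs-ConKO log2 fold change
    isoform_truth: str  # one of ISOFORM_CATEGORIES
    timing: str = "early"  # 'early' | 'adaptive'
    identity_scope: tuple[str, ...] | None = None  # None -> all identities
    #: per-gene magnitude spread: gene magnitudes drawn uniformly in
    #: base_l2fc +/- l2fc_jitter (real programs have heterogeneous effects)
    l2fc_jitter: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.l2fc_jitter < self.base_l2fc:
            raise ValueError("l2fc_jitter must lie in [0, base_l2fc)")
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")
        if self.isoform_truth not in ISOFORM_CATEGORIES:
            raise ValueError(f"unknown isoform_truth {self.isoform_truth!r}")
        if self.timing not in ("early", "adaptive"):
            raise ValueError(f"timing must be 'early' or 'adaptive', got {self.timing!r}")
        if self.base_l2fc <= 0:
            raise ValueError("base_l2fc is a magnitude and must be positive")

    @property
    def signed_l2fc(self) -> float:
        return self.base_l2fc if self.direction == "up" else -self.base_l2fc

    def active(self, genotype: str, timepoint: str) -> bool:
        """Whether the planted effect is expressed in this genotype/timepoint."""
        if genotype not in VHL_NULL_GENOTYPES:
            return False
        if self.timing == "adaptive" and timepoint != "late":
            return False
        hif1a_intact = genotype in ("VKO", "VEKO")
        hif2a_intact = genotype in ("VKO", "VHKO")
        truth = self.isoform_truth
        if truth == "HIF1A_alone":
            return hif1a_intact
        if truth == "HIF2A_alone":
            return hif2a_intact
        if truth == "HIF1A_or_HIF2A":
            # loss of either isoform reverses the regulation
            return hif1a_intact and hif2a_intact
        if truth == "HIF1A_plus_HIF2A":
            # only combined loss reverses it
            return hif1a_intact or hif2a_intact
        return True  # HIF_independent: Vhl loss suffices


@dataclass
class SimConfig:
    """Design of a simulated cohort.

    ``cells_per_mouse`` is the number of cells each mouse contributes to each
    identity stratum.  ``identities`` are (PT segment, class) pairs, e.g.
    ``("PT_S1", "A")``.  Mice are independent between timepoints (separate
    early and late cohorts, as in the underlying experimental design).
    """

    n_mice_per_genotype: int = 4
    genotypes: tuple[str, ...] = ("ConKO", "VKO", "VHKO", "VEKO", "VHEKO")
    timepoints: tuple[str, ...] = ("early", "late")
    cells_per_mouse: int = 200
    genes_total: int = 1200
    identities: tuple[tuple[str, str], ...] = (("PT_S1", "A"), ("PT_S2", "B"))
    planted_programs: tuple[PlantedProgram, ...] = ()
    nb_dispersion: float = 0.3
    library_size_lognorm: tuple[float, float] = (0.0, 0.3)
    n_marker_genes: int = 30
    n_module_genes: int = 30
    n_mito_genes: int = 10
    n_sex_genes: int = 20
    sex_effect_l2fc: float = 1.5
    mouse_random_effect_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.cells_per_mouse < 1:
            raise ValueError("cells_per_mouse must be >= 1")
        seen: dict[str, set[str]] = {"up": set(), "down": set()}
        for prog in self.planted_programs:
            overlap = seen[prog.direction].intersection(prog.gene_ids)
            if overlap:
                raise ValueError(
                    f"planted gene sets overlap within direction {prog.direction!r}: "
                    f"{sorted(overlap)[:5]}"
                )
            seen[prog.direction].update(prog.gene_ids)

    @property
    def identity_labels(self) -> list[str]:
        return [f"{ct}_{cl}" for ct, cl in self.identities]


# ---------------------------------------------------------------------------
# gene architecture


def _structural_genes(config: SimConfig) -> dict[str, list[str]]:
    """Named gene blocks: markers per PT segment (S2/S3 sex-dimorphic),
    class modules A/B, mitochondrial genes, sex-effect genes."""
    blocks: dict[str, list[str]] = {}
    nm = config.n_marker_genes
    cell_types = sorted({ct for ct, _ in config.identities})
    for ct in cell_types:
        short = ct.lower()
        if ct == "PT_S1":
            blocks[f"mk_{short}"] = [f"mk_{short}_{i:03d}" for i in range(nm)]
        else:
            # sexually dimorphic segments: shared core + sex-specific markers
            n_common = max(nm - 10, 1)
            blocks[f"mk_{short}_common"] = [f"mk_{short}_c{i:03d}" for i in range(n_common)]
            blocks[f"mk_{short}_m"] = [f"mk_{short}_m{i:03d}" for i in range(10)]
            blocks[f"mk_{short}_f"] = [f"mk_{short}_f{i:03d}" for i in range(10)]
    blocks["module_a"] = [f"modA_{i:03d}" for i in range(config.n_module_genes)]
    blocks["module_b"] = [f"modB_{i:03d}" for i in range(config.n_module_genes)]
    blocks["mito"] = [f"mt-{i:02d}" for i in range(config.n_mito_genes)]
    blocks["sex"] = [f"sexg_{i:03d}" for i in range(config.n_sex_genes)]
    return blocks


def _gene_table(config: SimConfig) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    blocks = _structural_genes(config)
    planted = [g for prog in config.planted_programs for g in prog.gene_ids]
    structural = [g for genes in blocks.values() for g in genes]
    named = list(dict.fromkeys(structural + planted))
    n_bg = config.genes_total - len(named)
    if n_bg < 0:
        raise ValueError(
            f"genes_total={config.genes_total} too small for "
            f"{len(named)} structural + planted genes"
        )
    background = [f"bg_{i:04d}" for i in range(n_bg)]
    genes = named + background
    var = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    var["mito_flag"] = var.index.str.startswith("mt-")
    return var, blocks


def study_marker_sets(config: SimConfig):
    """Marker sets matching the generator's gene architecture, in the shape
    the annotation stage consumes (S1 unisex; S2/S3 sex-specific)."""
    from .annotate import MarkerSet

    blocks = _structural_genes(config)
    sets = []
    cell_types = sorted({ct for ct, _ in config.identities})
    for ct in cell_types:
        short = ct.lower()
        if ct == "PT_S1":
            sets.append(MarkerSet(name=ct, genes=tuple(blocks[f"mk_{short}"]), cell_type=ct))
        else:
            common = blocks[f"mk_{short}_common"]
            for sex, tag in (("M", "m"), ("F", "f")):
                sets.append(
                    MarkerSet(
                        name=f"{ct}_{sex}",
                        genes=tuple(common + blocks[f"mk_{short}_{tag}"]),
                        cell_type=ct,
                        sex=sex,
                    )
                )
    return sets


def module_genes(config: SimConfig, which: str) -> list[str]:
    """Gene list of PT class module 'A' or 'B'."""
    return _structural_genes(config)[f"module_{which.lower()}"]


# ---------------------------------------------------------------------------
# count simulation


def simulate_counts(config: SimConfig) -> tuple[ad.AnnData, pd.DataFrame]:
    """Draw a cohort of NB counts with planted, fully-known effects.

    Returns
    -------
    adata
        cells x genes AnnData; ``obs`` carries mouse, sex, genotype,
        timepoint and the true identity labels; ``var`` carries ``mito_flag``.
    truth
        one row per planted gene: program, direction, l2fc magnitude,
        isoform category, timing and identity scope.
    """
    rng = np.random.default_rng(config.seed)
    var, blocks = _gene_table(config)
    genes = var.index.to_numpy()
    n_genes = len(genes)
    gene_idx = {g: i for i, g in enumerate(genes)}

    # per-gene baseline means (log-normal); structural genes get floors so
    # their planted multiplicative effects are detectable
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    planted_genes = [g for p in config.planted_programs for g in p.gene_ids]
    for gset, floor in (
        (blocks.get("module_a", []), 1.0),
        (blocks.get("module_b", []), 1.0),
        (blocks["sex"], 1.0),
        (planted_genes, 2.0),
    ):
        for g in gset:
            base[gene_idx[g]] = max(base[gene_idx[g]], floor)
    for name, gset in blocks.items():
        if name.startswith("mk_"):
            for g in gset:
                base[gene_idx[g]] = max(base[gene_idx[g]], 1.0)
    base[var["mito_flag"].to_numpy()] *= 20.0  # high mitochondrial content of RTE cells

    # multiplier masks per identity / class / sex
    marker_mult: dict[tuple[str, str], np.ndarray] = {}
    cell_types = sorted({ct for ct, _ in config.identities})
    for ct in cell_types:
        short = ct.lower()
        for sex in ("M", "F"):
            mult = np.ones(n_genes)
            if ct == "PT_S1":
                own = blocks[f"mk_{short}"]
            else:
                own = blocks[f"mk_{short}_common"] + blocks[f"mk_{short}_{sex.lower()}"]
            for g in own:
                mult[gene_idx[g]] = 8.0
            marker_mult[(ct, sex)] = mult
    class_mult = {}
    for cl, block in (("A", "module_a"), ("B", "module_b")):
        mult = np.ones(n_genes)
        for g in blocks[block]:
            mult[gene_idx[g]] = 4.0
        class_mult[cl] = mult
    sex_mult = np.ones(n_genes)
    for g in blocks["sex"]:
        sex_mult[gene_idx[g]] = 2.0 ** config.sex_effect_l2fc  # elevated in males

    # planted effect per (genotype, timepoint, identity); per-gene magnitudes
    # drawn once so every genotype expresses the same effect size
    prog_idx = []
    gene_l2fc: dict[tuple[str, str], float] = {}
    for p in config.planted_programs:
        idx = np.array([gene_idx[g] for g in p.gene_ids])
        sign = 1.0 if p.direction == "up" else -1.0
        if p.l2fc_jitter > 0:
            mags = p.base_l2fc + rng.uniform(
                -p.l2fc_jitter, p.l2fc_jitter, size=len(idx)
            )
        else:
            mags = np.full(len(idx), p.base_l2fc)
        signed = sign * mags
        for g, v in zip(p.gene_ids, signed):
            gene_l2fc[(g, p.direction)] = float(v)
        prog_idx.append((idx, signed, p))

    def planted_mult(genotype: str, timepoint: str, identity: str) -> np.ndarray:
        mult = np.ones(n_genes)
        for idx, signed, prog in prog_idx:
            scope = prog.identity_scope
            if scope is not None and identity not in scope:
                continue
            if prog.active(genotype, timepoint):
                mult[idx] = 2.0**signed
        return mult

    r = 1.0 / config.nb_dispersion
    meanlog, sdlog = config.library_size_lognorm
    sexes = ("M", "F")

    X_blocks: list[np.ndarray] = []
    obs_rows: list[dict] = []
    for timepoint in config.timepoints:
        for genotype in config.genotypes:
            for m in range(config.n_mice_per_genotype):
                mouse = f"{genotype}_{timepoint}_m{m + 1}"
                sex = sexes[m % 2]
                mouse_factor = rng.lognormal(0.0, config.mouse_random_effect_sd)
                for (ct, cl) in config.identities:
                    identity = f"{ct}_{cl}"
                    n_cells = config.cells_per_mouse
                    mu_gene = (
                        base
                        * marker_mult[(ct, sex)]
                        * class_mult[cl]
                        * (sex_mult if sex == "M" else 1.0)
                        * planted_mult(genotype, timepoint, identity)
                        * mouse_factor
                    )
                    lib = rng.lognormal(meanlog, sdlog, size=n_cells)
                    mu = mu_gene[None, :] * lib[:, None]
                    lam = rng.gamma(shape=r, scale=mu * config.nb_dispersion)
                    counts = rng.poisson(lam).astype(np.int32)
                    X_blocks.append(counts)
                    for i in range(n_cells):
                        obs_rows.append(
                            {
                                "cell_id": f"{mouse}_{identity}_c{i:04d}",
                                "mouse": mouse,
                                "sex": sex,
                                "genotype": genotype,
                                "timepoint": timepoint,
                                "true_cell_type": ct,
                                "true_class": cl,
                                "true_identity": identity,
                            }
                        )

    X = np.vstack(X_blocks)
    obs = pd.DataFrame(obs_rows).set_index("cell_id")
    adata = ad.AnnData(X=X, obs=obs, var=var.copy())

    truth = pd.DataFrame(
        [
            {
                "gene": g,
                "program": p.name,
                "direction": p.direction,
                "l2fc": gene_l2fc[(g, p.direction)],
                "isoform_truth": p.isoform_truth,
                "timing": p.timing,
                "identity_scope": ",".join(p.identity_scope) if p.identity_scope else "all",
            }
            for p in config.planted_programs
            for g in p.gene_ids
        ]
    )
    return adata, truth


def study_config(seed: int = 0, **overrides) -> SimConfig:
    """The bundled study conditions: 5 genotypes x 2 timepoints x 4 mice,
    200 cells per mouse per identity, 40 planted genes per isoform category
    at |L2FC| = 2, plus HIF2A-specific adaptive and down programs."""
    programs = []
    for k, cat in enumerate(ISOFORM_CATEGORIES):
        tag = cat.lower()
        programs.append(
            PlantedProgram(
                name=f"{tag}_early_up",
                gene_ids=tuple(f"pg_{tag}_up_{i:03d}" for i in range(40)),
                direction="up",
                base_l2fc=2.0,
                isoform_truth=cat,
                timing="early",
                l2fc_jitter=0.5,
            )
        )
    programs.append(
        PlantedProgram(
            name="hif2a_adaptive_up",
            gene_ids=tuple(f"pg_h2ad_up_{i:03d}" for i in range(30)),
            direction="up",
            base_l2fc=2.0,
            isoform_truth="HIF2A_alone",
            timing="adaptive",
            l2fc_jitter=0.5,
        )
    )
    programs.append(
        PlantedProgram(
            name="hif2a_adaptive_down",
            gene_ids=tuple(f"pg_h2ad_dn_{i:03d}" for i in range(30)),
            direction="down",
            base_l2fc=2.0,
            isoform_truth="HIF2A_alone",
            timing="adaptive",
            l2fc_jitter=0.5,
        )
    )
    programs.append(
        PlantedProgram(
            name="hif2a_early_down",
            gene_ids=tuple(f"pg_h2a_dn_{i:03d}" for i in range(30)),
            direction="down",
            base_l2fc=2.0,
            isoform_truth="HIF2A_alone",
            timing="early",
            l2fc_jitter=0.5,
        )
    )
    cfg = dict(planted_programs=tuple(programs), seed=seed)
    cfg.update(overrides)
    return SimConfig(**cfg)


def simulate_pseudobulk(
    n_genes: int,
    seed: int,
    n_per_group: int = 4,
    nb_dispersion: float = 0.05,
    mean_lognorm: tuple[float, float] = (5.0, 1.5),
    size_factor_sdlog: float = 0.25,
    planted_l2fc: float | None = None,
    n_planted: int = 1,
):
    """Direct pseudobulk-level NB counts for DE calibration studies.

    Emulates mouse-level summed counts: per-gene means log-normal (median
    ~150 counts), moderate sample-level NB dispersion (sums over hundreds of
    cells leave replicate-level biological variation as the dominant
    overdispersion source), and log-normal size factors.  Sexes are balanced
    across the two genotype groups.  With ``planted_l2fc`` the first
    ``n_planted`` genes carry that log2 effect in the VKO group.

    Returns a :class:`~hifsort.de.PseudobulkTable`.
    """
    from .de import PseudobulkTable

    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    mu = rng.lognormal(*mean_lognorm, size=n_genes)
    sf = rng.lognormal(0.0, size_factor_sdlog, size=n)
    M = mu[:, None] * sf[None, :]
    if planted_l2fc is not None:
        M[:n_planted, n_per_group:] = M[:n_planted, n_per_group:] * 2.0**planted_l2fc
    r = 1.0 / nb_dispersion
    C = rng.poisson(rng.gamma(shape=r, scale=M * nb_dispersion))
    samples = [f"s{i}" for i in range(n)]
    counts = pd.DataFrame(C, index=[f"g{i:05d}" for i in range(n_genes)], columns=samples)
    meta = pd.DataFrame(
        {
            "mouse": samples,
            "sex": ["M", "F"] * n_per_group,
            "genotype": ["ConKO"] * n_per_group + ["VKO"] * n_per_group,
            "timepoint": "late",
        },
        index=pd.Index(samples, name="sample"),
    )
    return PseudobulkTable(counts=counts, meta=meta)


# ---------------------------------------------------------------------------
# spatial simulation


@dataclass
class SpatialSimConfig:
    """One simulated tissue field for one mouse.

    Clonal expansion (daughters placed within ``daughter_placement_radius_um``
    of their tagged parent) acts in the cortex/outer medulla at the late
    timepoint; elimination of tagged cells acts in the papilla at the late
    timepoint.  Per-genotype magnitudes are free parameters of the generator.
    """

    region: str = "cortex_om"  # 'papilla' | 'cortex_om'
    field_size_um: tuple[float, float] = (500.0, 500.0)
    n_cells: int = 2000
    tag_fraction: float = 0.3
    genotype: str = "VKO"
    timepoint: str = "early"
    mouse: str = "VKO_early_m1"
    clone_expansion_rate: Mapping[str, float] = field(
        default_factory=lambda: {"VKO": 1.0, "VHKO": 0.4, "VEKO": 0.0, "VHEKO": 0.0}
    )
    elimination_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"VKO": 0.5, "VHKO": 0.0, "VEKO": 0.5, "VHEKO": 0.0}
    )
    daughter_placement_radius_um: float = 16.0
    min_spacing_um: float = 5.0
    nucleus_area_range_um2: tuple[float, float] = (20.0, 150.0)
    ki67_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"VKO": 0.05, "VHKO": 0.04, "VEKO": 0.02, "VHEKO": 0.02}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region not in ("papilla", "cortex_om"):
            raise ValueError(f"unknown region {self.region!r}")
        if not 0.0 < self.tag_fraction < 1.0:
            raise ValueError("tag_fraction must lie in (0, 1)")
        w, h = self.field_size_um
        # hard-disc packing feasibility at the requested minimum spacing
        if self.n_cells * np.pi * (self.min_spacing_um / 2.0) ** 2 > 0.55 * w * h:
            raise ValueError(
                "field too small to place n_cells at the minimum nuclear spacing"
            )


def _place_points(rng, n: int, width: float, height: float, min_spacing: float) -> np.ndarray:
    """Uniform positions with hard-core rejection at min_spacing (grid-backed)."""
    from scipy.spatial import cKDTree

    pts: list[np.ndarray] = []
    batch = max(4 * n, 256)
    attempts = 0
    while len(pts) < n:
        cand = rng.uniform([0, 0], [width, height], size=(batch, 2))
        for p in cand:
            if len(pts) >= n:
                break
            if pts:
                arr = np.asarray(pts)
                # local check against recent points is insufficient; full check
                d2 = np.min(np.sum((arr - p) ** 2, axis=1))
                if d2 < min_spacing**2:
                    continue
            pts.append(p)
        attempts += 1
        if attempts > 200:
            raise ValueError("could not place points at the requested spacing")
    return np.asarray(pts[:n])


def simulate_spatial(config: SpatialSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a per-nucleus tissue table plus the parent->daughter truth map.

    Returns a table with columns cell_id, x_um, y_um, region, nucleus_area_um2,
    tdtomato_intensity, ki67_intensity, mouse, genotype, timepoint; and a truth
    frame mapping daughter cell ids to their tagged parents.
    """
    rng = np.random.default_rng(config.seed)
    w, h = config.field_size_um
    pos = _place_points(rng, config.n_cells, w, h, config.min_spacing_um)
    tagged = rng.random(config.n_cells) < config.tag_fraction

    ids = [f"{config.mouse}_n{i:05d}" for i in range(config.n_cells)]
    rows = pd.DataFrame(
        {"cell_id": ids, "x_um": pos[:, 0], "y_um": pos[:, 1], "tagged": tagged}
    )
    parent_map: list[dict] = []

    late = config.timepoint == "late"
    vhl_null = config.genotype in VHL_NULL_GENOTYPES

    if late and vhl_null and config.region == "papilla":
        elim = float(config.elimination_fraction.get(config.genotype, 0.0))
        if elim > 0:
            drop = rows["tagged"] & (rng.random(len(rows)) < elim)
            rows = rows.loc[~drop].reset_index(drop=True)

    if late and vhl_null and config.region == "cortex_om":
        rate = float(config.clone_expansion_rate.get(config.genotype, 0.0))
        if rate > 0:
            daughters = []
            tagged_rows = rows.loc[rows["tagged"]]
            n_daughters = rng.poisson(rate, size=len(tagged_rows))
            d_i = 0
            for (idx, parent), k in zip(tagged_rows.iterrows(), n_daughters):
                for _ in range(int(k)):
                    theta = rng.uniform(0, 2 * np.pi)
                    rad = config.daughter_placement_radius_um * np.sqrt(rng.uniform())
                    x = np.clip(parent["x_um"] + rad * np.cos(theta), 0, w)
                    y = np.clip(parent["y_um"] + rad * np.sin(theta), 0, h)
                    cid = f"{config.mouse}_d{d_i:05d}"
                    daughters.append(
                        {"cell_id": cid, "x_um": x, "y_um": y, "tagged": True}
                    )
                    parent_map.append({"daughter": cid, "parent": parent["cell_id"]})
                    d_i += 1
            if daughters:
                rows = pd.concat([rows, pd.DataFrame(daughters)], ignore_index=True)

    n = len(rows)
    amin, amax = config.nucleus_area_range_um2
    rows["region"] = config.region
    rows["nucleus_area_um2"] = rng.uniform(amin, amax, size=n)
    # intensities: tagged nuclei bright in the tdTomato channel; a genotype-
    # dependent minority of cells cycling (Ki67)
    td = np.where(
        rows["tagged"],
        rng.normal(0.8, 0.05, size=n),
        rng.normal(0.1, 0.05, size=n),
    )
    rows["tdtomato_intensity"] = np.clip(td, 0, 1)
    ki_frac = float(config.ki67_fraction.get(config.genotype, 0.01)) if vhl_null else 0.01
    cycling = rng.random(n) < ki_frac
    ki = np.where(cycling, rng.normal(0.8, 0.05, size=n), rng.normal(0.1, 0.05, size=n))
    rows["ki67_intensity"] = np.clip(ki, 0, 1)
    rows["mouse"] = config.mouse
    rows["genotype"] = config.genotype
    rows["timepoint"] = config.timepoint
    rows = rows.drop(columns=["tagged"])

    truth = pd.DataFrame(parent_map, columns=["daughter", "parent"])
    return rows, truth
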