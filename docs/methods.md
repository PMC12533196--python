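# Methods

This note documents the models, estimators, parameter choices and known
limitations of `hifsort`. The package analyses a genetic-epistasis design in
mouse kidney proximal tubule (PT): tamoxifen-induced *Vhl* inactivation
(reported by a tdTomato tag), alone (VKO) or combined with loss of *Hif1a*
(VHKO), *Epas1* (VEKO) or both (VHEKO), against monoallelic controls
(ConKO), sampled early (1–3 weeks) and late (4–12 months) after
recombination.

## Synthetic cohorts

The generator (`hifsort.sim`) produces single-cell counts with known ground
truth rather than emulating a particular dataset.

**Count model.** Counts are gamma-Poisson (negative binomial) with
Var = μ + αμ². The per-cell mean factorizes as
baseline(gene, identity, sex) × library factor × mouse factor × planted
effect. Defaults, chosen once as realistic for UMI-based kidney data at this
scale: gene baselines log-normal(0, 1) (≈1,900 counts/cell over 1,200
genes); cell-level dispersion α = 0.3; library factors log-normal(0, 0.3);
a per-mouse log-normal(0, 0.15) scalar that creates the within-mouse
correlation motivating pseudo-bulking; mitochondrial genes at 20× baseline
(RTE cells are mitochondria-rich, ~10% mitochondrial reads); sex-effect
genes at 2^1.5 in males.

**Structure.** Identity is (PT segment, class): marker blocks (30
genes/segment, 8× in their own segment; S2/S3 markers split into a shared
core plus 10 male- and 10 female-specific genes) and class modules A/B (30
genes, 4× in their own class) mimic the segment/class dichotomy without
copying any published list. Planted programs carry a signed log2 effect in
*Vhl*-null genotypes; which genotypes express it follows from the program's
isoform truth (e.g. HIF1A-alone ⇒ present in VKO and VEKO, absent in VHKO
and VHEKO; HIF1A+HIF2A ⇒ absent only in VHEKO), and adaptive programs act
only at the late timepoint while early programs persist. Per-gene
magnitudes are drawn uniformly in base ± jitter (study default 2.0 ± 0.5)
because real programs have heterogeneous effect sizes; the drawn value is
recorded in the truth table.

**Study conditions** (`study_config`): 5 genotypes × 2 timepoints × 4 mice,
200 cells per mouse per identity, two identities (PT_S1_A, PT_S2_B), 1,200
genes, 40 planted genes per isoform category (up, early) plus HIF2A-specific
adaptive up/down and early-down programs of 30 genes each.
`cells_per_mouse` counts cells per mouse *per identity*; early and late
cohorts are separate mice, as in the underlying design.

**Spatial fields.** Nuclei are uniform in a 500×500 μm field with a 5 μm
hard-core rejection; tagging is Bernoulli. Late dynamics: in cortex/outer
medulla each tagged cell spawns Poisson(rate) daughters uniform in a 16 μm
disc (clonal expansion); in papilla each tagged cell is removed with a
per-genotype probability (elimination). The per-genotype magnitudes are free
parameters of the generator — the underlying biology is only reported as
p-values — set once to expansion {VKO 1.0, VHKO 0.4, VEKO/VHEKO 0} and
elimination {VKO 0.5, VEKO 0.5, VHKO/VHEKO 0}, i.e. expansion requires
HIF2A, elimination requires HIF1A, with VHKO expanding at a reduced rate.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: gene–gene co-expression beyond the planted block
structure, doublets and ambient RNA, partial recombination, continuous
identity gradients, segmentation errors, and 3-D tissue. Tests demonstrate
that the stage logic is correct under the stated model, not that the model
captures every property of kidney scRNA-seq.

## Quality control

Cells are kept when detected genes > 200 (strict), mitochondrial read
fraction < 0.5 (strict), and detected genes < 3× the per-mouse median.
The median is computed on the pre-filter matrix and all thresholds are
applied jointly — the filters are a single set, not a sequence — which also
makes the operation idempotent. Mitochondrial genes are identified by a
configurable prefix list (default `mt-`) or an explicit `mito_flag`.
Setting the mitochondrial threshold to 1.0 disables that filter. Ambiguous
features (e.g. a *Vhl* exon-1 feature that cannot be assigned between
wild-type and knockout alleles) are dropped before counting.

## Annotation

**Rank-ceiling score.** Genes are ranked per cell by descending expression
(average ranks for ties; unexpressed genes share the bottom average rank,
which the ceiling makes nearly moot). Signature ranks are clipped at
maxRank + 1 and the Mann–Whitney-style score is
1 − (Σ min(rᵢ, maxRank+1) − n(n+1)/2)/(n·maxRank) ∈ [0, 1]. The standard
maxRank is 1500; the bundled analysis uses 500 because its transcriptome is
only 1,200 genes (maxRank must be below the gene count). Scores are
comparable across signatures within a cell, so identity is the argmax over
applicable sets (sex-specific S2/S3 sets compete only in cells of that sex);
exact ties go to the lexicographically first label and are flagged.

**Binned-control score.** Genes are placed into equal-frequency bins (by
average log-normalized expression, log1p of counts per 10⁴); each signature
gene draws control genes from its own bin without replacement (with
replacement plus a warning when the bin is smaller than the draw), seeded
and logged so toy examples are exactly checkable; the score is
mean(signature) − mean(unique controls). The standard parameters are 100
bins / 50 controls; the bundled pipeline uses 25/25 since 1,200 genes give
only 12 genes per bin at 100 bins. Class A is called when the module-A
score strictly exceeds 0.125 — a threshold taken as a plain parameter.

## Pseudo-bulk differential expression

Counts are summed per mouse within one identity; mice with fewer than 10
cells in the stratum are excluded with a warning. Size factors are
median-of-ratios against the geometric-mean reference over genes positive in
all samples (total-count fallback), normalized to geometric mean 1.

Each contrast is fit on the samples of its two levels only, with sex
retained as a covariate (design `~ sex + genotype`); fitting contrast-wise
rather than all genotype levels jointly keeps every stratum's model full
rank even when a genotype is missing, at the cost of contrast-specific
dispersion estimates.

**Dispersion.** Per gene, a pooled within-group method-of-moments estimate
α̂ = Σ(nᵢ−1)(vᵢ−mᵢ) / Σ(nᵢ−1)mᵢ² over the distinct design cells (floor
10⁻⁸, cap 10), then empirical-Bayes shrinkage in log space toward a trend
α(μ) = a₀ + a₁/μ fitted by non-negative least squares, with fixed prior
log-variance 0.25 and likelihood variance 2/(n−p). This captures the
behavior of reference NB-DE tools at desk scale without Cox–Reid machinery;
calibration is asserted by simulation, not by bit-level agreement with any
tool (a pre-installed DESeq2 reimplementation serves as an independent
cross-check in the tests, never as the implementation).

**Inference.** Wald z = β̂/SE on the contrast coefficient, referred to a t
distribution with n − p plus 1/prior-variance (= 4) degrees of freedom: the
plug-in dispersion makes the normal reference anti-conservative at 4 vs 4
samples, and the moderated df accounts for the information the shrinkage
adds, in the spirit of quasi-likelihood moderated tests (half the nominal
2/prior-variance, because the shrinkage target is itself estimated). Under a global-null
pseudobulk simulation (2,000 genes, 4v4, dispersion 0.05, log-normal means)
the raw p < 0.05 fraction is ≈0.05–0.06 with KS-uniform p-values, and
planted L2FC = 2 genes are recovered with near-unit power and ≈0.03 mean
bias — both recomputed by `scripts/acceptance.py`. BH adjustment runs across
all genes with no independent filtering; all-zero genes are flagged with
l2fc 0, p 1. The reference tool's `alpha` parameter affects only its
disabled filtering and is ignored. No fold-change shrinkage is applied —
the thresholds act on raw coefficients.

Genes are "regulated" when |L2FC| > 1.0 and padj < 0.05, both strict.

## Isoform and temporal classification

Dependence on a knockout contrast X ∈ {VHKO, VEKO, VHEKO} vs VKO requires
(i) padj < 0.05 in X, (ii) direction opposite to the VKO-vs-ConKO change,
and (iii) |L2FC_X| strictly greater than half of |L2FC_VKO| ("more than
half"); no |L2FC| > 1 gate applies inside the knockout contrast — the
magnitude condition is the 50% rule. The category map is a pure function of
the three flags (verified by exhaustive enumeration): both single-isoform
flags ⇒ HIF1A_or_HIF2A; one ⇒ that isoform alone; neither but the double ⇒
HIF1A_plus_HIF2A; none ⇒ ambiguous.

Temporal classes: *early* = regulated in VKO vs ConKO at the early
timepoint; *adaptive* = regulated late vs early in VKO and not in ConKO;
genes in both sets are excluded from program scoring. The same |L2FC| > 1 /
padj < 0.05 gate is applied uniformly in every contrast and exposed as a
parameter.

Pooling across identities takes the union of isoform-specific calls per
direction; genes HIF1A-specific in one identity and HIF2A-specific in
another (same direction) enter a conflict report and are excluded from both
pooled sets — conflicts are counted, not resolved.

## Program scoring and scaling

Programs are scored per identity with the binned-control method and scaled
affinely, s′ = (s − median_ref)/(median_target − median_ref) × sign, so the
reference cohort's median is exactly 0 and the target cohort's exactly +1
(up) or −1 (down) *within each identity*; identities are amalgamated after
scaling, so pooled medians keep the anchor interpretation. Anchor cohorts
are configurable (ConKO vs VKO; or ConKO-early vs VKO-late for temporal
programs). Coinciding anchors make the transform undefined; the identity is
skipped with a warning. Bulk-sample scoring z-scales each gene across all
samples (ddof 1) and sums scaled values of set genes per sample;
zero-variance genes are dropped with a warning.

## Enrichment

ORA is the upper-tail hypergeometric probability of the observed overlap or
greater (one-sided Fisher), BH-adjusted across sets; sets outside the
50–1000 size window (after intersection with the universe) are excluded
before testing, and user-supplied exclusion lists are honoured. GSEA uses
the weighted KS running sum with exponent 1 on |statistic|; ES is the signed
maximal deviation, evaluated only at hit boundaries (O(k) per permutation,
identical to the full running sum). The null permutes gene labels (default
10⁴ draws, seeded); NES = ES / mean |null ES| of the same sign, and the
p-value is two-sided over all null ES with a +1 correction — permutation
rather than analytic p-values are exact at desk scale and avoid
approximating a specific package's estimator. Enriched terms can be ordered
by Ward-linkage clustering of member-gene L2FC profiles. Ortholog mapping is
out of scope; gene ids must be pre-mapped.

## Spatial statistics

Distances are 2-D Euclidean between nucleus centroids; the neighborhood is
boundary-inclusive (≤ r, default 16 μm — "within" is documented as
inclusive). Nuclei outside 15–200 μm² are excluded (bounds inclusive, since
the exclusions are strict). Positivity is intensity strictly above a
configured, logged threshold. Neighbor counts exclude the focal cell and use
a k-d tree whose results equal the all-pairs scan exactly. Frequency bins
default to {0,1,2,3,4,≥5} and are configurable.

MANOVA treats each mouse's frequency vector as one observation: counts are
converted to proportions, the redundant last bin is dropped (continuing to
drop trailing bins that carry no mass anywhere, and zero-variance bins,
which would otherwise make the within-group matrix E singular), and
Wilks' Λ = det(E)/det(E+H) is referred to Rao's F approximation. Pairwise
comparisons are Bonferroni-adjusted over the requested pairs. Kruskal–Wallis
uses the tie-corrected H; Dunn's z uses the standard rank-mean formula with
the tie term, Bonferroni-adjusted over the requested pairs. With 4 mice per
arm the analysis drivers use coarse bins {0,1,≥2} to keep E well
conditioned.

## Problem sizes and seeds

The bundled study (16,000 cells × 1,200 genes) is sized so that the full
chain — simulation through scoring — runs in about a minute on one CPU; the
calibration studies use 2,000 null genes, 100 planted replicate strata, 50
spatial power replicates and 500 permuted-null MANOVA p-values (50
independent datasets × 10 permutations, so dataset-specific deviations of
the F approximation average out). Every sampler takes an explicit seed;
stage outputs are pure functions of (inputs, config, seed), and the pipeline
manifest records seed, parameters and a parameter hash.

## Known limitations

Gene-wise independence in the generator means the tests do not probe
correlation-induced miscalibration of the DE stage; the dispersion scheme is
a desk-scale stand-in validated by simulation, not a Cox–Reid adjusted
estimator; contrast-wise fitting gives slightly different dispersion
estimates per contrast than a joint fit; scaled scores depend on the
binned-control baseline, so genotypes with many co-regulated programs can
exceed the [0, 1] anchor range on other programs; the zero point of a
binned-control score depends on the seeded control draw, so a fixed class
threshold close to one mode of a bimodal score distribution yields
class-assignment accuracy that varies by a few percent across seeds (the
planted-category recovery downstream is insensitive to this); and the spatial model is
2-D with uniform placement, so region-specific density gradients are not
represented.
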