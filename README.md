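# hifsort

Kidney proximal-tubule (PT) cells respond to loss of the von Hippel–Lindau
tumor suppressor (*Vhl*) by stabilizing the two HIFα transcription-factor
isoforms, HIF1A (*Hif1a*) and HIF2A (*Epas1*). Which isoform drives which
transcriptional and cellular consequence can be resolved genetically: compare
*Vhl*-null cells (VKO) against controls (ConKO) and against combined
knockouts lacking *Vhl* plus *Hif1a* (VHKO), *Epas1* (VEKO) or both (VHEKO).
`hifsort` implements that analysis as a tested, reusable pipeline: from
tagged single-cell count matrices and per-nucleus tissue coordinates through
cell annotation, pseudo-bulk differential expression, an isoform-dependence
classification ledger, early/adaptive temporal calling, reference-scaled
program scoring, enrichment testing, and spatial clonal-neighborhood
statistics — together with a synthetic-data generator that stands in for the
mouse cohorts so every stage is testable without downloads.

## The core statistics

**Pseudo-bulk NB Wald test.** Counts are summed per mouse within each PT
identity (segment S1/S2/S3 × transcriptional class A/B), so mice — not cells
— are the replicates. Per gene, a negative-binomial log-link GLM with design
`~ sex + genotype` and a log size-factor offset (median-of-ratios) gives a
Wald test on the contrast coefficient; dispersion is a method-of-moments
estimate shrunk toward a fitted mean–dispersion trend, and the Wald
statistic is referred to a t distribution with residual-plus-prior degrees
of freedom. Genes with |L2FC| > 1 and BH-adjusted p < 0.05 are "regulated".

**Isoform ledger.** A *Vhl*-dependent gene (regulated in VKO vs ConKO) is
*Hif1a*-dependent if it is significantly regulated in VHKO vs VKO in the
opposite direction with more than half the VKO-vs-ConKO |L2FC| (likewise
*Epas1*- and *Hif1a/Epas1*-dependence from VEKO and VHEKO). The three flags
map to: HIF1A alone, HIF2A alone, HIF1A or HIF2A (either loss reverses),
HIF1A + HIF2A (only combined loss reverses), or ambiguous.

**Scoring.** Cell-type assignment uses rank-ceiling (UCell-style) signature
scores, `score = 1 − (Σ min(rᵢ, maxRank+1) − n(n+1)/2)/(n·maxRank)`; program
scores use binned-control (AddModuleScore-style) scores, scaled affinely so
the reference cohort has median 0 and the *Vhl*-null cohort median ±1.

**Spatial clonality.** For each tdTomato-tagged nucleus, the number of other
tagged nuclei within a 16 μm internuclear radius; per-mouse frequency
distributions are compared by one-way MANOVA with Wilks' Λ = det(E)/det(E+H)
(Rao's F), and medians by Kruskal–Wallis with Dunn's post-hoc z tests.

## Worked example

The numbered drivers under `analysis/` run the whole study on the synthetic
cohort (5 genotypes × 2 timepoints × 4 mice, 200 cells per mouse per
identity, planted programs at |L2FC| ≈ 2):

```sh
python analysis/01_simulate_cohort.py      # 16,000 cells x 1,200 genes
python analysis/02_qc_annotate.py
python analysis/03_pseudobulk_de.py
python analysis/04_classify_dependence.py
python analysis/05_score_programs.py
python analysis/07_spatial_clonality.py
```

Step 02 prints `cell-type assignment accuracy 1.000; PT class accuracy
0.983`: argmax rank scores recover the planted segments and the module-A
threshold recovers the class dichotomy. Step 04 prints a recovery table with
sensitivity 1.0 in every isoform category, `conflicts 0` (no gene called
HIF1A-specific in one identity and HIF2A-specific in another), and
`Spearman rho = -0.989` for the anti-correlation of the VHEKO-vs-VKO against
the VKO-vs-ConKO fold changes over HIF-dependent genes — combined isoform
loss reverses essentially the whole *Vhl* response. Step 05 prints median
scaled scores per genotype; on the HIF2A-specific up-program VKO-late sits
at 1.000 (by construction), ConKO-early at 0.000, VEKO at −0.47 and VHEKO at
−0.11 — *Epas1* loss alone suffices to abolish the program — while VKO-early
(0.28) vs VKO-late (1.00) shows its adaptive, time-dependent build-up. Step
07 prints the tissue statistics: the papillary tagged fraction falls from
~0.30 to ~0.17 late only in the HIF1A-intact genotypes (VKO Dunn p = 0.021,
VEKO p = 0.021, VHKO/VHEKO p = 1.0), and the cortical tagged-neighbor
distributions shift late in VKO (MANOVA p = 0.0001) and VHKO (p = 0.0009)
but not VEKO or VHEKO — clonal expansion requires HIF2A.

The `hifsort` console script exposes the same stages
(`hifsort simulate|qc|spatial|run`), and `hifsort.pipeline.run_pipeline`
runs the chain end-to-end from a YAML config, emitting a manifest with the
seed and parameter hash so any table can be reproduced byte-identically.

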