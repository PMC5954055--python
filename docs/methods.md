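# Methods

This note records the models behind each pipeline, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical decisions made where the procedures left room for choice.

## e-Karyotyping

### Model

Log2 microarray intensities are treated as gene-level expression with
additive chromosomal dosage effects: a copy-number change with fold `fc`
carried by a fraction `f` of cells shifts every probe on the chromosome by

    delta = log2(((1 - f) * 2 + f * 2 * fc) / 2)

so a full trisomy gives log2(1.5) ≈ 0.585 and a 50% mosaic trisomy
log2(1.25) ≈ 0.322. The analysis is *relative*: per-probe medians across
samples are subtracted, so an aberration is only detectable when the
affected samples are a minority at that locus.

### Preprocessing order and interpretation

1. Unannotated probes are dropped.
2. The expression floor is the 66.67th percentile of the pooled log2 value
   distribution ("upper third highest expressing probes" read as a pooled
   quantile — the simplest reading consistent with flooring individual
   values); values below it are raised to it.
3. A probe is "not expressed" in a sample when its pre-floor value is below
   the floor; probes unexpressed in more than 20% of samples are dropped.
   (The alternative reading — array detection p-values — is not available
   for simulated data; the floor reading is used throughout.)
4. Per-probe median centring.
5. The top 10% of probes by sum of squared relative values are dropped;
   ties are broken by probe label so the pipeline is deterministic.
6. Probes are sorted by (chromosome, position). Chromosomes default to
   1–22 + X; Y is excluded because mixed-sex sample sets make it
   uninformative.

Two consequences worth knowing: the variability filter preferentially
removes probes with strong relative signal, which attenuates the measured
shift of a real trisomy (≈0.43 instead of 0.585 in the default simulation);
and median centring makes normal samples appear mildly depressed on a
chromosome that is gained in another sample. Both effects are inherent to
relative expression karyotyping, not artifacts of this implementation.

### Aberration calls

The original readout is visual inspection of the 300-gene moving-average
plot. To obtain assertable calls, the statistic per (sample, chromosome) is
the mean of all window means — computed exactly as a weighted probe mean
with triangular edge weights, which makes the permutation null a single
matrix product. The null permutes the probe-to-position assignment within
the sample (the sample's own values, shuffled across all retained probe
slots); p-values are two-sided with the +1 correction and
Bonferroni-corrected across chromosomes within each sample (default
alpha = 0.01). The moving average uses stride 1 and probe ordinals
(genomic distance is ignored), matching a fixed gene-count window.

## eSNP-karyotyping

Heterozygous SNP allele counts are modelled binomially at the expressed
allele fraction: 1/2 on diploid chromosomes, 2/3 (or 1/3) on trisomies.
Filtering keeps SNPs with total depth ≥ 20; a minor-allele count ≥ 3 is
additionally required as a heterozygosity proxy — homozygous sites make the
major/minor ratio infinite and carry no imbalance information. Both
thresholds are configurable.

The track is the stride-1 moving median (window 151, odd so the median is
centred) of the major/minor ratio, paired with the moving median of
positions. Because max/min of a binomial exceeds 1 even under perfect
balance — at depth ~60 the diploid windowed ratio sits near 1.2 and is
depth-dependent — a fixed ratio cutoff would be biased. Calls therefore use
a permutation null that resamples per-SNP ratios from the sample's other
chromosomes and recomputes the full windowed statistic
(median-of-windowed-medians); a chromosome is called when its statistic
exceeds the null's (1 − alpha) quantile. Resampling at the *SNP* level
matters: under the diploid null the autocorrelation of overlapping windows
comes entirely from shared i.i.d. SNPs, so SNP-level resampling reproduces
the statistic's sampling law exactly, whereas block-shifting the already
smoothed medians yields only a handful of effectively independent null
values and an anti-conservative test.

Loss of heterozygosity (detection via SNP-density drop) is out of scope.
VCF input is accepted through cyvcf2 (AD field, bi-allelic sites only).

## EB lineage scorecard

### Normalization

Ct values above 35 are capped at 35 and non-detects set to 35 — but a
non-detect is stored as a missing value, *not* as Ct 35, because the
detected-fraction QC rule (drop samples with <33% of the expected panel
detected; strict less-than) and the cap are different rules. ΔCt scaling
subtracts the arithmetic mean Ct of ACTB and GAPDH per sample (geometric
vs arithmetic mean differs negligibly on the Ct scale). Quantile
normalization maps each sample onto the mean of the sorted per-sample
vectors; tied values share the average of their assigned targets. Finally
the values are mapped affinely onto [0, 35] (the affine parameters are
recorded in the result's provenance) and inverted as 35 − x so that larger
numbers mean stronger expression.

### Marker selection

Per directed condition and cell line, genes are ranked by mean day-16 minus
mean day-0 normalized expression (rank 1 = largest increase; ties broken by
gene label), and the median rank across lines taken. The top 15 per
condition become that lineage's markers. Because independent top-15 lists
need not be disjoint, a gene winning several conditions is assigned to the
condition where its median rank is best and the runner-up condition takes
the next-ranked gene. The undifferentiated set is the 15 genes most
consistently *down*-regulated across all four conditions (equivalently, the
worst mean rank in the rank-1-is-largest-increase orientation). Control
genes are excluded a priori. The day-0 baseline pools day-0 samples across
lines; a per-line baseline is available via the internals but pooling is
the default since day-0 material is condition-independent.

### Moderated t and lineage score

Per-gene pooled variances s²_g with d = n_A + n_B − 2 residual df are
shrunk toward a prior: s̃²_g = (d₀·s₀² + d·s²_g)/(d₀ + d), with (d₀, s₀²)
fitted by method of moments on log s²_g — the mean and excess variance of
log s² beyond the χ² sampling term identify the prior via digamma/trigamma
relations, and the trigamma equation is inverted by Newton iteration.
d₀ = 0 recovers the ordinary pooled t; d₀ = ∞ the fully shrunk limit; the
fit returns ∞ when the observed spread of log s² does not exceed the
sampling spread. If every gene has zero within-group variance the ordinary
t is used with a logged warning.

The lineage score is the parametric gene-set z-statistic

    z = (mean(t_markers) - mean(t_all)) * sqrt(m) / sd(t_all)

with the population standard deviation of the full t vector, so that m
markers exactly one sd above the global mean score sqrt(m). Under a null t
vector with random marker sets the score is approximately standard normal.

Grades: +++ for score > 3, ++ for 2 ≤ score ≤ 3, + for 1 ≤ score < 2, +/−
for score < 1. The published bin labels overlap at the integers ("1–2",
"2–3"); the half-open convention above is the unique total, non-overlapping
assignment consistent with "> 3" for the top bin. "Potential" uses the
matched directed condition at day 16 vs the pooled day-0 baseline;
"propensity" the neutral condition; a missing condition yields an `nd`
(not analyzed) entry rather than an error.

## TeratoScore

Signature derivation applies two fold filters to a normal-tissue reference
panel: a candidate gene must be >8-fold higher in its source tissue than
the mean of all other tissues, and >4-fold higher in reference teratomas
than in PSCs (both strict). Central and peripheral nervous system are
merged into one tissue group, as are small intestine and colon, since their
specific-gene expression is too similar to separate. Candidates are ranked
within each merged group by tissue-specificity fold and taken round-robin
across groups until 100 genes are collected — the round-robin keeps every
tissue group represented, which the per-tissue reporting requires; if fewer
candidates exist, all are returned with a logged shortfall.

Scoring expresses each signature gene as 100 × FPKM / reference level
(reference = mean FPKM in the source tissue; genes with zero reference are
dropped with a warning; ≥80% of signature genes must be present). Tissue
group and lineage values are arithmetic means of member-gene percentages.
The unified grade is (m_ecto × m_meso × m_endo × m_exem)/100 — four
factors, three germ layers plus extra-embryonic membranes; with balanced
per-lineage means around 10% this puts balanced teratomas around 100 and
single tissues near zero, and the product structure is what makes the grade
a *balance* measure. Classification is balanced-trilineage iff grade > 10
(strict); lineages below 4% of reference are flagged as distinctly low.

The undifferentiated-marker screen reports, per sample, the mean over a
ten-gene PSC/yolk-sac marker panel of 100 × FPKM / mean PSC FPKM, and flags
samples strictly above the cohort mean — a cohort-relative threshold rather
than a fixed percentage, since the absolute level is a property of the
cohort analysed.

## Projection-based pluripotency scoring

The trained model (basis matrix B of k non-negative components over genes,
score-weight vector w, stored H9 reference r, thresholds) is an *input*;
the synthetic generator provides a toy model whose H9 reference lies in the
basis span. The platform correction is
shift = rowwise-mean(study H9 profiles) − r on the aligned gene set
(alignment requires ≥95% of model genes). Samples are corrected as
x' = x − shift and projected by unconstrained ordinary least squares
h = argmin ‖x' − Bh‖₂ — the non-negativity of the original multiplicative
update is relaxed because the corrected data are no longer non-negative.
Pluripotency = w·h; Novelty = the model's affine calibration of the
residual RMS (identity by default — the published novelty scale belongs to
the original trained model, so the calibration and both thresholds live in
the model file). Pass requires Pluripotency ≥ 20 and Novelty < 1.67; both
threshold comparisons use ≥ on the flagging side. A line passes when any
replicate passes; novelty spread above a configurable delta (default 0.5)
is annotated as replicate disagreement.

## Synthetic data

The generators produce the statistical structure the analyses key on, not
biologically realistic transcriptomes:

* **Probe matrices** — bimodal probe populations (expressed ~N(9.5, 1),
  background ~N(6.5, 0.8) on log2 scale, 60% expressed) so the top-third
  floor retains an expressed subset; i.i.d. Gaussian measurement noise
  (sd 0.30 log2 units); dosage shifts applied per the mosaic formula; 2% of
  probes unannotated to exercise the removal rule.
* **SNP tables** — negative-binomial depth (mean 60, size 4; a None size
  gives constant depth) and binomial allele counts at fraction 1/2 or 2/3;
  positions strictly increasing.
* **Ct time courses** — per-gene baselines around Ct 24–26 (controls ~16),
  linear-in-time effects reaching the planted day-16 effect size, Gaussian
  replicate noise (sd 0.30 Ct); Ct above 33 becomes a non-detect; optional
  low-quality samples with ~70% knock-outs. The default panel has 190 genes:
  2 controls, 15 planted responders per lineage (with a small within-set
  effect gradient so ranks are unambiguous), 15 consistently down-regulated
  pluripotency genes, 128 null background genes.
* **Tissue panels / teratomas** — 14 tissues across the four lineages, 12
  private genes each at FPKM 100 in the source tissue and 0.5 elsewhere
  (specificity ≫ the 8-fold rule), 10 undifferentiated markers at 100 in
  PSCs, 30 housekeeping genes at 50 everywhere; teratomas are convex
  mixtures of tissue signatures (weights normalised to sum 1) optionally
  blended with a PSC fraction, under multiplicative log-normal noise
  (sd 0.30 natural log).
* **Projection models** — block-structured non-negative lognormal bases
  (well conditioned), score weights mapping a pure pluripotency loading to
  30 and differentiation loadings to −5, H9 reference equal to the
  pluripotency component.

Noise magnitudes are minimal standard models (Gaussian on log2/Ct scales,
log-normal multiplicative on FPKM, overdispersed counts for coverage) set
once at field-typical values. Determinism: every generator draws from its
own tagged stream derived from the configuration seed, so identical
configurations give byte-identical outputs regardless of call order.

What passing on these data does **not** show: robustness to probe-level
cross-hybridisation, GC and batch effects, allele-specific expression and
reference-mapping bias, qPCR amplification-efficiency differences, or
compositional/length biases of real RNA-seq. The synthetic benchmark
demonstrates the *algorithmic* correctness and statistical calibration of
the pipelines, and the recoverability of planted parameters under the
models' own assumptions.

## Problem sizes used in tests and the acceptance script

Unit and acceptance tests run the pipelines at desk scale chosen for fast,
stable Monte-Carlo behaviour: e-karyotype power/null studies use 8
chromosomes × 300 probes, a 25-gene window and 1000 permutations (100
detection runs, 15 null runs); eSNP studies use the full defaults (500
SNPs/chromosome, depth mean 60, window 151); the teratoma benchmark uses
the full 14-tissue panel with 5 replicates per tissue; marker selection
uses the full 190-gene panel over 4 lines × 4 conditions × 2 replicates.
Generator defaults remain at platform-ish scale (2000 probes per
chromosome) for library use.

## Known limitations

* The e-karyotype caller tests whole chromosomes only; sub-chromosomal
  segments and integer copy-number estimation are out of scope.
* The eSNP pipeline does not use SNP density (no LOH detection) and treats
  SNPs as independent (no haplotype phasing).
* The scorecard's enrichment scale — and hence the absolute meaning of the
  grade bins — depends on the adopted parametric gene-set construction;
  scores from other enrichment variants are not directly comparable.
* TeratoScore lineage means are relative to the reference panel's
  source-tissue levels; tissues absent from the panel are invisible and can
  bias composition estimates in either direction.
* The projection scorer's novelty is on the residual-RMS scale unless the
  model file supplies a calibration; thresholds are meaningful only
  relative to the model used.
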