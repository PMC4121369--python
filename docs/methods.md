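# Methods

## The problem

A single individual in a reference cohort carries a karyotype (47,XXY) that
makes every molecular question an outlier question: there is no case group,
only one case. The package implements the resulting N-of-1 workflow —
karyotype confirmation from array evidence, per-feature outlier screens
against sex-stratified reference groups, regional aggregation of
methylation hits, global-methylation and XCI assays — together with a
generative model of the data so that each stage can be validated against
known ground truth.

## Singleton outlier statistic

For feature *i*, reference mean μ̂ᵢ and sample SD σ̂ᵢ (n−1 denominator) are
computed over the comparison group excluding the index; the index value xᵢ
gives zᵢ = (xᵢ − μ̂ᵢ)/σ̂ᵢ, a two-sided p from the standard normal, and
Bonferroni adjustment p·m within each family, where m counts only testable
features (σ̂ᵢ > 0) in that family. Zero-variance features are flagged
untestable and excluded from m.

**Calibration caveat.** The normal reference treats μ̂, σ̂ as known. At
reference sizes of ~10–45 this is markedly anti-conservative in the extreme
tails that survive Bonferroni correction: on null simulations (10 000
features, n = 20) the family-wise error rate is ≈ 0.87, not 0.05. The
default is kept because it is the field's convention for this analysis; for
calibrated inference use `use_t=True`, which applies the Crawford–Howell
singleton t-test, t = z/√(1 + 1/n), df = n − 1. That statistic is exactly
pivotal under Gaussian references, and the test suite verifies family-wise
control for it by simulation. Effect estimates (beta difference;
log2-scale difference for expression) are identical in both modes.

**Comparison policy.** Autosomal features are tested against the whole
cohort, males only and females only; X-linked features against females
only and Y-linked against males only, since only those groups share the
index's sex-chromosome dose at those loci. Bonferroni m is per family
(configurable); whether a global m was intended in the source workflow is
unknowable, and per-family is the less surprising choice when families
have very different sizes.

## Karyotype inference

Five channels, each a deliberately scalar statistic rather than a visual
check (the usual MDS sex plot is replaced by exact 1-D 2-means on the
per-sample mean X-probe beta; 2-means in one dimension is solved exactly
by enumerating split points, so clustering is deterministic):

* X methylation: higher-mean cluster = female-like (inactive-X
  intermediate methylation).
* XIST expression: 2-means high/low.
* Y signal: fraction of Y methylation probes detected (≥ 0.5, boundary
  inclusive) AND mean Y expression within 2 SD of the male (upper)
  expression cluster. With a sample-estimated cluster SD, a true male
  falls outside its own cluster's 2-SD envelope ~4.5% of the time; such
  samples degrade to indeterminate, never to the other sex.
* X-SNP heterozygosity: het calls / non-missing calls; one X ⇒ ~0, two X
  ⇒ population-level rates.
* BAF bands: 50-bin histogram peaks holding > 5% of mass and exceeding
  both neighbours; equal-height plateaus count once (a mode centred on a
  bin edge would otherwise be missed on an exact tie). Two total copies
  give 3 bands, three copies give 4 (heterozygote modes at 1/3, 2/3). In a
  47,XXY genome the three-copy situation arises where probes see X+Y
  jointly — the X-transposed region (XTR) — while unique X SNPs are
  ordinary diploid; the generator and pipeline therefore keep the two SNP
  strata separate (`region` column: "X" for het rate, "XTR" for bands).

Decision table (genotype evidence takes precedence because it is least
confounded by tissue): female-like X without Y ⇒ 46,XX; male-like X with
Y ⇒ 46,XY; female-like X with Y ⇒ 47,XXY provided genotypes — when
present — support two X copies (het rate > 0.02 or 4 bands); anything
else is indeterminate. Discordance is flagged when the call's phenotypic
sex differs from the reported sex.

## DMR aggregation

Tested probes form the grid; a region is a maximal run of consecutive
significant probes (an intervening tested-but-nonsignificant probe breaks
the run) with inter-probe gap ≤ 500 bp and span ≤ 500 bp, at least 2
probes. The 500 bp rule is ambiguous between gap and span; both are
constrained and separately configurable. Over-long runs split greedily
left to right. Member z values combine by Stouffer's method with equal
weights, Z = Σz/√k, reported as the one-sided tail Φ̄(|Z|) in the combined
direction. No probe-autocorrelation (Stouffer–Liptak–Kechris) correction
is applied — a documented simplification of the regional-combination tool
this mirrors; combined p-values are therefore optimistic when probes are
correlated. Mixed-sign regions are allowed but flagged
(`sign_consistent`). CNV overlap counts a single shared base pair
(1-based inclusive intervals; chr-prefixed and bare chromosome labels are
normalized before comparison).

## Repeat-element global methylation and XCI

Each pyrosequencing assay interrogates three CpGs; a sample's estimate is
their arithmetic mean, with fully methylated (> 90%) / unmethylated
(< 10%) control validation. The index is classified per tissue × assay by
the same |z| ≥ 2 rule used for scalar phenotypes (hypo ≤ −2, hyper ≥ +2);
the threshold is explicit configuration because the source analyses used
"significant" without naming a test. Note one published summary this rule
cannot reproduce: a cortical Alu difference reported as a striking
hypomethylation corresponds to z = −1.0 from its printed mean ± SD — a
boxplot-level claim, not a two-SD one; the acceptance test asserts the
reported pattern and that case fails honestly rather than the rule being
loosened.

XCI ratios use the undigested-normalized (Allen-style) formula:
R₁ = h1d/h1u, R₂ = h2d/h2u, ratio = R₁/(R₁+R₂), skewing = |ratio−0.5|·100.
Triplicate digests are averaged (mean peak heights) before the ratio;
MspI full-digestion controls pass when both MspI peaks are < 5% of their
undigested peaks (both thresholds configurable; neither is specified by
the assay's common description). The alternative unnormalized ratio is
available via `normalize=False`. No "normal skewing range" is built in —
published ranges come from external cohorts, so the threshold is left to
the user.

## Synthetic cohort generator

The generator is a stated world, not a tuning knob. Defaults:

* 49 reference individuals (balanced sexes) in two tissues (PFC, CER) plus
  one 47,XXY index recorded as male; tests use smaller cohorts for speed.
* Methylation betas ~ Beta(μν, (1−μ)ν) with precision ν = 400 (SD ≈ 0.025
  at mid-range betas), around bimodal baseline means; X probes half
  "island-type" (female-like mean 0.45 under XCI, male-like 0.10) and half
  escape-like (0.10 in everyone). Expression log2 intensities Gaussian
  with SD 0.05. These noise levels were fixed once, on the grounds that
  the spiked effect sizes (taken from the published tables: beta
  differences ~0.1–0.5, log2 fold changes ~0.2–0.8) were
  Bonferroni-significant in their source data, which bounds the plausible
  per-probe dispersion; they also match post-normalization array
  technical variability.
* Spikes shift only the index for "whole-cohort" targets; sex-restricted
  targets make the locus sex-dimorphic with the index resembling the
  other sex, so only the named family sees the effect.
* SNPs: B-allele counts Binomial(copies, p), BAF = count/copies + N(0,
  0.02); genotype-call error 0.005. XTR stratum copies = X+Y count.
* Repeat assays, XCI skew (7.5% PFC / 0.4% CER), brain masses and the
  index's CNV segments (one CN 4 autosomal segment, one CN 3 segment over
  a spiked region) default to the published summary values.
* Detection p and beadcounts are simulated independently (uniform / Poisson);
  dedicated bait probes exercise every QC rule deterministically, because
  at realistic random failure rates the beadcount/detection filter would
  rarely fire in a small cohort.

What the generator does **not** emulate — so a green test does not
establish robustness to it: probe-level spatial autocorrelation, batch and
chip effects, cell-composition differences, intensity-based allelic
crosstalk in BAF, linkage disequilibrium, or raw-intensity (IDAT-level)
artefacts. All randomness flows from one integer seed; identical config ⇒
byte-identical output (matrices serialize at %.17g and parse with
round-trip float precision).

## QC

Methylation probe filters apply in a declared order with first-rule-wins
attribution (counts per rule always sum to the total removed): (1) common
SNP (MAF > 5%) within 10 bp of the CG target; (2) non-CG context; (3)
blacklist (e.g. sex-chromosome cross-reactive probes); (4) beadcount < 3
in > 5% of samples or detection p > 0.05 in > 1% of samples — the cited
filtering function's documented defaults, since the source workflow names
the function but not its thresholds. Expression probes are dropped only
when undetected (p > 0.01) in every sample. Cross-tissue identity is
checked by Pearson correlation of genotyping ("rs") probe betas with a
configurable r ≥ 0.9 match threshold. Filters never alter retained
values, only membership, and are idempotent.

## Numerical and interface choices

Internal coordinates are 1-based inclusive; BED converts at the boundary
(0-based half-open). Chromosomes are normalized to unprefixed {1..22, X,
Y}. p-values are floored at the smallest positive double so reported
values stay in (0, 1]. The pipeline report carries no timestamp, making
reruns byte-identical. The CLI (`xxyomics simulate|qc|karyotype|screen|
dmr|globalmeth|xci|run|report|bafbands`) is a thin layer over the library.

## Known limitations

* Array-scale realism: probe counts default to hundreds, not 450K/HT-12
  scale; multiplicity behaviour at full scale follows the same formulas
  but is not exercised end-to-end.
* The default singleton p-values are anti-conservative (see above).
* Mosaicism and aneuploidies other than 47,XXY (45,X; 48,XXYY; …) are out
  of scope; they surface as indeterminate calls at best.
* Stouffer combination ignores inter-probe correlation.
* The gene-set outlier report is descriptive (directions per gene × tissue
  × comparison); it deliberately claims no aggregate statistic.
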