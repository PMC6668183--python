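# Methods

## Per-CpG binomial regression

The response at each CpG is the pair (methylated reads, unmethylated
reads) over the samples with an unmasked observation, modelled as a
grouped binomial with logit link and fit by iteratively reweighted least
squares (IRLS).  The p-value of the phenotype coefficient is a two-sided
normal (Wald) test; likelihood-ratio tests are deliberately not offered.
For the two-group, no-covariate design the maximum-likelihood estimate is
the difference of pooled logits with standard error
sqrt(1/(n₀p₀q₀) + 1/(n₁p₁q₁)); the test suite verifies the IRLS against
this closed form to 1e-8 and against an independent GLM implementation
with covariates.

Numerical choices:

- Convergence: max |Δβ| < 1e-10, at most 50 iterations; fitted
  probabilities clipped to [1e-12, 1 − 1e-12].
- Non-convergence or (quasi-)separation — |β| of the *predictor* above 15
  on the logit scale — yields `converged = False`; such CpGs are excluded
  from FDR computation and from DMR calling.  The separation check covers
  only the predictor coefficient: the intercept plus the four
  cell-proportion covariates are nearly collinear by construction
  (proportions sum to one), so nuisance coefficients can legitimately take
  extreme offsetting values while the fit and the Wald test of interest
  are well conditioned.
- Constant non-intercept columns are pruned per CpG (a sample subset can
  make a covariate constant); a design still rank-deficient afterwards
  raises an error naming the collinear columns.
- Smoking enters as two indicators (current, past; never = reference);
  sex as an M indicator; basophil is dropped from the five cell fractions
  to restore full rank against the intercept.
- The ordinal dose model treats ACPA negative/medium/high as a numeric
  0/1/2 covariate with a single slope.
- A plain binomial variance is assumed.  When more than 10% of tested
  CpGs show Pearson χ²/df > 2 a warning reports likely overdispersion;
  the generator's beta-binomial option exists to exercise exactly this
  case.

Alongside the model coefficient, each result row carries `methdiff`, the
difference of coverage-pooled methylation ratios (Σmeth/Σtotal) between
the contrast and reference groups (positive vs negative for models I/II;
high vs negative for the dose model; cases vs rest for III/V).

## Filtering

CpG rules, applied in order with each removal attributed to the first
violated rule: (1) sex-chromosome CpGs are dropped; (2) observations with
total reads below 15 are *masked* — treated as missing by every
downstream model, not merely ignored by the sample-count rule, since
shallow observations carry little measurement accuracy; (3) CpGs with
fewer than 30 samples at ≥ 15x are dropped; (4) CpGs whose unmasked
methylation ratios have zero standard deviation (or fewer than two
unmasked observations, where a standard deviation is undefined) are
dropped.  Both thresholds are configurable; filtering is idempotent and
the per-rule report reconciles exactly with input and output counts.

SNP rules: bi-allelic records only; calls below 10x set missing; SNPs
kept when the post-masking call rate exceeds 70%.

## Storey q-values and genomic control

π₀(λ) = #{p > λ}/(m(1 − λ)) is computed on λ = 0.05, 0.10, …, 0.90,
smoothed, evaluated at λ = 0.90 and clamped to (0, 1].  The smoother is a
least-squares fit on a natural cubic-spline basis with 3 degrees of
freedom (boundary knots at the grid ends, interior knots at the grid
terciles) — a fixed-df regression approximation of the reference
smoothing-spline smoother; the suite cross-checks π₀ and the q-values
against the R reference implementation on a mixed p-value sample.
q-values are the monotone step-up transform q₍ᵢ₎ = min_{j≥i} π₀·m·p₍ⱼ₎/j,
capped at 1.  Passing `pi0=1` reproduces Benjamini–Hochberg.  The
genomic-control factor is the median of the χ²₁ quantile transform of the
p-values divided by the null median (≈ 0.4549).

## DMR calling

Seeds are CpGs with q below the significance threshold (default 0.01).
Candidate regions are closed intervals [seed − 200 bp, seed + 200 bp],
merged per chromosome when they touch or overlap.  Within a candidate
region the tested CpGs are scanned in position order and maximal runs are
extracted in which every CpG has nominal p < 0.01 and the same sign of
effect; a CpG failing either condition breaks the run.  Runs with at
least three members and at least one seed are emitted.  Choices where the
procedure was genuinely open:

- "Consecutive" means adjacent in the ordered list of *tested* CpGs;
  untested CpGs cannot break a run, because runs are defined over the
  analysis set.
- A run may span the merged windows of several seeds but must contain at
  least one seed of its own, since regions are built around significant
  sites.
- A CpG exactly on a window boundary is inside the candidate region.
- `mean_methdiff` averages the per-CpG pooled group differences across
  members (rather than differencing per-group pooled means over the whole
  region).

The caller is verified against an exhaustive brute-force enumerator of
all maximal qualifying runs on 1000 random instances.

## Directional (dose) filtering

For each candidate CpG the coverage-pooled group means are computed for
ACPA-negative, medium, high and RA.  The direction is hyper (hypo) when
the three ACPA means strictly increase (decrease); RA-consistency then
requires the RA mean to extend the trend beyond the high group with a
weak inequality (the disease group may plateau).  Both comparators are
configurable.  Directional DMRs are obtained by re-running the caller on
the directional, RA-consistent DMC subset.

## cis-meQTL mapping and gDMR/ngDMR classification

The scan reproduces an additive linear model of the per-sample
methylation *ratio* on alt-allele dosage with no covariates, for every
SNP–CpG pair within 250 kb (a 500-kb window).  CpGs enter the scan when
observed (any reads) in more than half the cohort and when their ratio
variance lies in the top half of those candidates; this selection is
intentionally looser than the EWAS depth filter — a per-observation 15x
mask at a mean coverage of 15x would leave almost no CpG above a 50%
call-rate rule.  Pairs with constant dosage or constant methylation among
the pairwise-complete observations are skipped and counted.  P-values are
Benjamini–Hochberg corrected; the genome-wide subset at p < 5e-8 is also
flagged.

For genotype adjustment, each significant DMC's lead meQTL (smallest
meQTL p at q < 0.01; ties broken by distance, then position) contributes
its dosage as an extra covariate in a refit of the original binomial
model, dropping samples missing that dosage; a lead with more than 30%
missing dosages falls through to the next candidate, and a DMC with no
usable meQTL keeps its unadjusted result.  A DMC "remains significant"
when its Bonferroni-adjusted p (multiplied by the number of refitted
DMCs) stays below 0.01 with an unchanged direction; BH correction is
available by flag.  A DMR is untestable when no member CpG has a
significant meQTL; otherwise it is ngDMR when ≥ 3 consecutive members
remain significant with a common direction (the membership criteria
re-satisfied — a per-member "any" rule is available by flag), else gDMR.

## Feature annotation, enrichment and replication

CGI-relative classes follow the distance to the nearest island edge:
inside → CGI, within 2 kb outside → shore, 2–4 kb → shelf, beyond →
open sea; the four classes partition every CpG.  Promoters are TSS1500
windows: 1500 bp upstream of a transcription start site (strand-aware,
including the TSS); an analogous 1500-bp downstream window flags
transcription end sites.  A CpG is intergenic when it lies in no gene
body, TSS1500 or TES window.  All other tracks (exons, first exons,
introns, UTRs, autoimmune-SNP windows) set independent flags, and
arbitrary user BED tracks can be tested the same way.

Enrichment is per CpG — the background is the set of all testable CpGs —
with a two-sided Fisher exact test and fold change (k/n)/(K/N); fold
below one is depletion and no correction is applied across features.  The
Fisher p is verified against exhaustive hypergeometric tail enumeration.

Replication restricts both cohorts to their common tested CpGs.  A
discovery DMC replicates when the validation p is below 0.05 with the
same direction.  Fold enrichment compares the significance overlap
(direction-agnostic) with its expectation under independence,
n_disc · n_val / n_common, with an upper-tail hypergeometric p; requiring
direction agreement in the overlap would halve the null expectation and
break the calibration of the fold at 1 under independence.  A discovery
DMR replicates when at least one validation CpG inside its interval is
nominally significant in the DMR's direction.

## The synthetic study generator

The generator emulates a targeted bisulfite-sequencing (MCC-Seq-like)
whole-blood study: 66 ACPA-negative, 45 medium-positive and 18
high-positive subjects plus 8 self-reported RA subjects (137 in all, the
RA group all female, two of the RA subjects ACPA-negative), ACPA
optical-density values drawn log-normally within the ≤ 20 / 20–60 / > 60
OD bands, ages uniform over 40–70, smoking 20/42/38% current/past/never,
and blood-cell proportions Dirichlet-distributed around a realistic
differential (57.5% neutrophils, 30% lymphocytes).  Coverage is negative
binomial with mean 15 and size 3 (real capture coverage is
overdispersed); a chrX block (2% of CpGs) exists solely to exercise the
exclusion filter.  CpG positions mix clustered islands (40% of CpGs in
10-CpG clusters, which also define the CGI annotation track) with
dispersed background; baseline methylation is bimodal (islands
hypomethylated, background hypermethylated) except at planted sites,
which are drawn mid-range so that logit-scale effects are visible as
ratio differences.

Planted effects, all recorded in `GroundTruth`:

- **Dose regions** (default 20 islands): ±1.0 logit per ordinal ACPA
  step.  RA subjects are simulated at dose 3 — the disease extends the
  ordinal trend, which is what the directional/RA-consistency analysis is
  designed to detect.  Each dose region also carries an ACPA-independent
  cis-meQTL SNP (allele frequency uniform 0.2–0.5, slope 0.9 logit per
  allele) so that genuine regions are genetically *testable* and classify
  as ngDMR rather than untestable.
- **Genotype-confounded regions** (default 20 islands): methylation is
  driven only by a nearby SNP at 2.0 logit per alt allele, whose allele
  frequency rises 0.2 → 0.35 → 0.5 across the ACPA groups.  The slope is
  chosen so the genotype-induced apparent dose effect (≈ 0.6 logit over
  the full ACPA range) is detectable by the unadjusted model, which is
  the premise of the gDMR testbed; genotype adjustment removes it.
- **Cell-driven CpGs** (default 200): 1.0 logit per unit of centred
  neutrophil fraction; with `cell_acpa_shift > 0` the neutrophil mean
  rises with ACPA dose, creating the confounding that distinguishes the
  unadjusted from the cell-adjusted model.
- **Plain cis-meQTLs** (default 50): single background CpGs driven at
  ±1.5 logit per allele by a SNP within 50 kb.

Genotypes are Hardy–Weinberg draws at the per-group allele frequency with
2% missingness and negative-binomial read depth (mean 30); linkage
disequilibrium between SNPs is deliberately not modelled.  Methylated
reads are binomial, or beta-binomial when an intra-CpG correlation
`overdispersion_rho` > 0 is requested (default 0: the real data's
overdispersion is unknown, and the calibration checks assume the pure
binomial).  An independent validation cohort (default 9 cases vs 13
controls, emulating a small sorted-cell replication sample) shares the
genome and planted truth, with cases at dose 2.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: read-level artefacts (bisulfite conversion
error, mapping bias, strand effects), spatial correlation of methylation
beyond the planted islands, LD structure, relatedness or population
structure, batch effects, and cell-proportion measurement error.  The
calibration results certify the statistics under the stated generative
model, not robustness to these artefacts.

## Problem sizes and runtime

Default sizes were chosen to keep a full pipeline run comfortable on a
single core while leaving every stage non-trivial: 50,000 CpGs across 10
autosomes plus chrX, 137 subjects at 15x, ~270 SNPs.  The complete
simulate → filter → EWAS → DMR → meQTL → classify chain runs in well
under a minute at these sizes; the calibration study uses 5,000 CpGs.
The acceptance script (`scripts/acceptance.py`) re-runs the null
calibration, the default planted study, the meQTL slope recovery and the
validation replication from scratch at these sizes.

## Known limitations

- The binomial GLM ignores extra-binomial variation; with real data a
  quasi-binomial or beta-binomial variance would temper the Wald tests
  (the dispersion warning flags this).
- `mean_methdiff` uses coverage-pooled ratios, which weight deeply
  covered samples more than a per-sample mean would.
- The meQTL scan is covariate-free by design; population structure in
  real data would call for at least genotype PCs.
- DMR boundaries are reported at member-CpG positions, not extended to
  window edges.
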