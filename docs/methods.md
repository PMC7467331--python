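# Methods

This note documents the statistical models, the default parameters and the
numerical choices behind `pedmut`, and what the synthetic-cohort validation
does and does not establish.

## Candidate filtering

A candidate DNM is a biallelic SNV at which the child is heterozygous and
both parents homozygous reference. The filter battery is conjunctive, so the
surviving set is order-independent; the per-filter tally is reported in a
fixed presentation order only. Thresholds (module `dnm_filters`,
`FilterConfig`):

| filter | rule | default |
|---|---|---|
| site quality | QUAL strictly greater | 100 |
| GATK hard filters | QD>2, FS<60, MQ>40, MQRankSum>−12.5, ReadPosRankSum>−8, SOR<3 | — |
| trio depth | two-sided exact Poisson test vs the member's mean depth, p > threshold in all three members | 2×10⁻⁴ |
| child genotype | GQ > 40; ALT allelic depth strictly > 3 | — |
| allele balance | two-sided exact binomial vs 0.5, pass iff p ≥ 0.05 | — |
| parents | ALT depth 0 in ≥ 1 parent; GQ > 40 in both | — |
| panels | absent from known-variant panels and from unrelated families (same chrom, pos, ALT) | — |
| clusters | chains of calls < 100 bp apart; clusters of ≥ 3 removed | — |

Conventions worth stating exactly: all two-sided exact p-values are
`min(1, 2·min(lower tail, upper tail))` with the observed point in both
tails; "fewer than 100 bp" is strict (`|Δpos| < 100`), and clustering chains
nearest neighbours rather than testing all pairs in a window; the allele
balance boundary `p = 0.05` counts as a pass; rank-sum annotations
(MQRankSum, ReadPosRankSum) that callers omit at sites without both alleles
in parental reads pass their hard filter rather than being treated as
missing data. A candidate missing any genuinely required metric is rejected
under a separate `missing_metric` reason so that data problems never
masquerade as filter decisions.

Doublets (2-DNM clusters) are retained but labelled, because they carry a
different false discovery rate than singlets and are pooled separately
downstream.

## Error rates

**FNR.** Simulated Mendelian violations (real transmitted variants with the
heterozygous parent swapped for a homozygous substitute, or reads edited to
carry a synthetic allele) are pushed through the same filters; the failing
fraction is the per-trio FNR, with a Clopper–Pearson interval. The
3-haplotype screen for insertion simulations fails a site when pairing it
with an eligible nearby heterozygous SNP (ALT depth ≥ 3, allele-balance
p > 0.05) reveals ≥ 3 haplotypes, each supported by ≥ 2 reads; with no
eligible comparison SNP the site passes vacuously and is flagged untested.

**FDR.** The transmission model treats each true DNM called in F1 `i` as
observed in its `j`-th F2 independently with probability `q_{i,j}`,
estimated as the observed fraction among simulated, filter-passing DNMs for
that pair (biological transmission and calling power are not separately
identifiable, so `q` parameterizes their product). For pedigrees with a
loop through an inbred sire the simulated transmission probability is
inflated; `q̃` is multiplied by 0.5/0.625 = 0.8. The number of true DNMs `w`
is estimated by exhaustive integer grid search of the binomial (one F2) or
multinomial (two F2s) likelihood over `w ∈ [z_total, y]`. In the
two-F2 multinomial the unobserved-in-both category count is taken as
`w − z_B − z_C − z_D`, which is computable precisely because spurious calls
are assumed never to transmit. Exact likelihood ties (they occur whenever
`z/q` is an integer) are resolved to the smaller `w` — the larger, more
conservative FDR — with a 1×10⁻⁹ log-likelihood tolerance so floating-point
noise cannot flip the choice. Doublets get one pooled FDR across trios (a
doublet transmits only if both members do), using the arithmetic mean of
`q` over all F1–F2 pairs. Trios without an F2 receive an FDR imputed from
the ordinary least-squares regression of known FDRs on F1 mean coverage,
clamped to [0, 1]; with no coverage variation the mean FDR is used, with a
warning.

## Phasing consensus

Read-backed and transmission evidence are combined per DNM: a single source
sets the call; agreement confirms it; read-backed/transmission disagreement
discards the DNM (treating it as error); when two F2s disagree, a
read-backed call arbitrates, otherwise the DNM is discarded. Ambiguous
read-backed haplotypes (conflicting informative SNPs) never set a consensus.
Partial-linkage DNMs — observed in one of two F2s sharing the haplotype,
the signature of a post-zygotic origin — follow the transmitted haplotype
unless discordant with read-backed evidence. Transmission calls flip to the
opposite background only when a recombination event with probability > 50%
lies before the first informative SNP on *both* sides of the DNM. A
transmission call is never inferred for a DNM absent from the F2 even when
the haplotype is informative; such rows stay unphased.

## Counts, regressions and rates

The adjusted count formula (README) shrinks calls by `(1 − FDR)`, scales up
for missed mutations (divide by `1 − FNR`) and from the surveyed territory
to the haploid genome (divide by `O/H`); `int` rounds half away from zero
(truncation would bias counts downward). Degenerate error rates
(FDR or FNR = 1) produce a zero count with a warning rather than an
undefined value. The per-trio phased fraction `a^s` uses transmitted phased
DNMs when an F2 exists and read-backed calls otherwise; unphased DNMs are
apportioned by `a^s` (a normalization approach, as opposed to modelling
unphased mutations in the likelihood).

Age models are Poisson with identity link — the age effect is additive, and
a log link would misspecify it — fitted by maximum likelihood (IRLS with an
ordinary-least-squares start; fits are rejected with diagnostics on
non-convergence or non-positive fitted means). Point estimates and
log-likelihoods (used by every LR test) are pure ML. The *covariance* used
for Wald intervals is, by default, scaled by the Pearson dispersion
estimate, floored at 1: error-adjusted counts are not Poisson — the
estimated FDR, FNR and phased fraction enter multiplicatively and add real
variance — and an unscaled covariance demonstrably under-covers (in
replicate-cohort experiments, slope coverage drops from ~95% to ~80%
without the scaling). For pure Poisson data the floor leaves the classical
intervals intact. `dispersion=None` restores the unscaled ML covariance.

Rate CIs are percentile intervals over 1,000 parametric draws of
`(β0, β1)` from each fit's normal approximation; yearly rates and rate
ratios reuse the same draws so uncertainty propagates coherently. α from
counts uses the 50 cM block bootstrap: the genome is partitioned into
contiguous blocks by the genetic map (the final partial block of each
chromosome kept as its own block), blocks are resampled with replacement
1,000 times, and the 2.5–97.5 percentile range is reported. The bootstrap
refuses to run with fewer than two non-empty blocks. A zero maternal count
reports α as infinite rather than failing.

Compartment rates (orthologous/non-orthologous × repetitive/non-repetitive)
pool trios with weights `(1 − FDR_i)/(1 − FNR_i)` over diploid compartment
sizes; the pairwise equal-rate test is the exact conditional binomial
(counts split by compartment size under the null), two-sided by tail
doubling, applied to the raw integer counts.

## Comparative tests

Cell-division bookkeeping: stage 1 (zygote to sex differentiation) 16
divisions, stage 2 to birth 21 (male) / 15 (female), no male divisions from
birth to puberty, and `(G_m − puberty)·365/cycle + 4` post-pubertal
divisions from spermatogonial stem-cell cycling (16-day cycle in humans,
11-day in baboons). These yield the replicative-null constants the LR tests
target (e.g. a 474/217 ≈ 2.2-fold α difference between humans and baboons).
Constrained fits profile the nuisance parameters by multi-start Nelder–Mead
(starts at the free MLE and at neutral fallbacks; best likelihood kept;
boundary optima flagged); LR statistics are clamped at 0 and referred to
χ²₁.

The cross-mammal regression of male bias on mean paternal age is performed
on the paternal-fraction scale `α/(1+α)` by default: the fraction is the
bounded quantity on which studies of very different α precision are
comparable, and the raw-ratio scale (available via `scale="alpha"`) lets
single high-α species dominate. The divergence-time grid computes
`T = K/μ_y` over paternal generation times and paternal-to-maternal
generation-time ratios (`G_f = G_m/ratio`).

The 2×2 chi-square applies the Yates continuity correction by default
(matching the convention of common statistical environments for 2×2
tables); the spectrum-comparison chi-squares use no continuity correction,
and fall back to Fisher's exact test on zero-margin tables, flagged. The
forward variable selection stopping threshold is 0.05.

## Synthetic cohorts

`synthetic_cohort.CohortSpec` defaults define the study conditions: 12
focal F1s (0/1/2 F2s with probabilities 0/0.7/0.3); paternal
intercept/slope 8.0 DNMs / 1.35 DNMs·yr⁻¹ and maternal 2.4 / 0.37 on the
full-count scale, giving ~51 paternal and ~13 maternal expected DNMs and a
male bias near 4 at conception ages (32.0, 28.2); `q` uniform in
(0.40, 0.55); per-trio FDR 0.20 and FNR 0.10; 4% of true DNMs in co-located
doublets (one mutational event: shared parent and transmission fate) and
0.25 artifact triplet clusters per trio that never transmit; a 7-type
mutation spectrum resembling a great-ape DNM spectrum. Parental ages are
recorded at conception and used directly as the regression covariate. The
miniature genome is two 10 Mb chromosomes, fully callable and orthologous
(`O = H`; the `O/H` and compartment scalings are exercised separately in
unit tests), with 1,750 cM of genetic length per chromosome so the 50 cM
block bootstrap sees ~70 blocks, as on a real genome. Genotype metrics at
simulated sites are drawn to sit comfortably inside (or, for injected
defects, outside) the filter thresholds; they are configurable stand-ins,
not estimates of any real sequencing run. Output is a deterministic
function of the spec, via per-component substreams of one seed.

What the generator does *not* emulate: read-mapping error (and hence
position-dependent FDR/FNR), mosaicism (allele balance at true sites is
centred on 0.5), joint-genotyping artifacts beyond their net effect
`q ≠ 0.5`, sequence-context-dependent mutation clustering, and indels.
Passing validation therefore demonstrates the correctness and calibration
of the *inference chain* under its own assumptions, not robustness to every
real-data pathology.

## Validation problem sizes

The replicate-cohort calibration experiment uses 500 cohorts of 50 trios
(an asymptotic regime chosen for Wald intervals; per-trio counts stay at
study scale) with 1,000 simulated sites per trio for each error-rate table,
1,000 coefficient draws and 1,000 bootstrap replicates — about seven
minutes on one CPU. Coverage of the 95% intervals for the two age-effect
slopes, the per-generation rate and α is required to fall in 90–98%.
The α interval runs a few points below nominal (~93%): the count ratio
carries the usual `α(1+α)/n_maternal` upward bias and right skew that a
percentile interval does not correct — visible in the miss pattern, which
is predominantly on the low side. This is a property of the estimator
itself, shared with the published procedure, and is left as is rather than
papered over with an ad hoc correction.

## Known limitations

* FDR and FNR are treated as fixed once estimated everywhere except through
  the dispersion scaling; their uncertainty is not propagated into the
  rate CIs draw by draw.
* The exponential maternal-age model is evaluated only with externally
  supplied parameters (AIC with zero free parameters); the package does not
  fit it.
* X and Y chromosomes, indels and 96-type context spectra are out of scope
  (trinucleotide context is stored but only the 7- and 5-type schemes are
  computed).
* VCF import expects single-sample-per-role biallelic records with
  GT/AD/DP/GQ and the GATK hard-filter INFO keys; anything richer should be
  pre-tabulated.
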