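# Methods

This note documents the statistical models implemented in `pqtlmr`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the package's known limitations.

## Two-sample MR model

All estimators operate on summary data: per-variant marginal effect
estimates and standard errors for an exposure (plasma protein level, SD
units) from one cohort and an outcome (binary disease on the log-odds
scale, or a quantitative trait) from another. The causal effect theta is
interpreted per 1-SD higher exposure.

- **Wald ratio** (1 instrument): theta = beta_Y/beta_X with first-order
  delta SE |se_Y/beta_X|. The first-order form ignores exposure-side
  uncertainty; it is the convention of the established two-sample
  frameworks and the default here, with the second-order SE
  sqrt(se_Y^2/beta_X^2 + beta_Y^2 se_X^2/beta_X^4) available behind a flag.
- **IVW**: weighted regression of beta_Y on beta_X through the origin,
  weights 1/se_Y^2. The dispatch rule is fixed-effect for up to three
  instruments and multiplicative random effects (SE scaled by
  max(1, sqrt(Q/df))) above three; truncation at 1 means the MRE SE never
  undercuts the fixed-effect SE. Under exact homogeneity this truncation
  makes the MRE test mildly conservative (null rejection ~ 3.9% at nominal
  5% with 10 instruments); the fixed-effect variant is exactly calibrated
  and is the one used in the calibration suite.
- **Correlated-instrument IVW**: generalised least squares with residual
  covariance Omega = diag(se_Y) R diag(se_Y), R the LD correlation
  submatrix. If Omega's smallest eigenvalue falls below 1e-8 a ridge of
  1e-6 is added to the diagonal before solving — correlated instruments
  selected at r^2 just under the clumping threshold can make Omega nearly
  singular.
- **MR-Egger**: weighted regression with a free intercept after orienting
  all pairs to beta_X >= 0 (the fit is not invariant to allele
  orientation; this is the established convention). SEs use multiplicative
  over-dispersion with df = k - 2, truncated below at 1. The intercept and
  its p-value test directional pleiotropy. Egger requires spread in
  instrument strengths: with identical beta_X the slope and intercept are
  not separately identified, and the intercept absorbs the causal effect.
- **MR-PRESSO**: the observed weighted residual sum of squares of
  leave-one-out IVW predictions is compared against a parametric bootstrap
  (default 1000 draws, mandatory seed) that redraws both sides from their
  standard errors under the no-pleiotropy model. Per-instrument outlier
  p-values use the per-observation analogue with Bonferroni correction;
  when outliers are found, a distortion p compares the outlier-corrected
  estimate with estimates after removing equally many instruments at
  random. Monte-Carlo p-values have resolution 1/(n_sim+1). The distortion
  construction in the original release is under-documented; the
  permutation-style null used here follows the published description and
  is an approximation.
- **Contamination mixture**: per-instrument ratio estimates are modelled
  as valid N(theta, se_j^2) or invalid N(0, se_j^2 + psi^2); the profile
  log-likelihood (taking the better class per instrument) is maximised
  over a grid of 2001 points spanning the ratio-estimate range widened by
  3x the largest SE. psi defaults to 1.5x the SD of the ratio estimates
  (the method's recommended heuristic). The 95% CI inverts the
  likelihood-ratio test at chi2_1(0.95); the reported SE is the CI
  half-width over 1.96, so it is approximate when the profile is
  asymmetric.

Cochran's Q uses the same weights as IVW; I^2 = max(0, (Q - df)/Q). All
p-values are two-sided normal unless stated.

## Harmonization

Records are matched on rsid with a chrom:pos consistency check when both
sides carry coordinates (rsids are the only identifier reliably present
across sources). Outcome effects are re-expressed for the exposure's
effect allele, negating beta and complementing EAF on a flip; opposite
strand codings are reconciled by reverse complement. Palindromic (A/T,
C/G) variants are dropped by default; the `infer_by_eaf` policy keeps them
when both EAFs lie outside [0.42, 0.58] and uses the minor-allele side to
resolve the strand. Indels match by exact allele-string equality — no
left-alignment normalisation is attempted, a documented limitation.
Coordinates are 1-based fully-closed throughout.

## Instrument selection

Greedy clumping: candidates at p <= 5e-8 are taken best-p-first (ties
broken by chromosome, position, rsid so results are independent of input
row order); each index variant absorbs remaining candidates with r^2 >=
0.1 within +/-1 Mb. Variants absent from the LD matrix are excluded with a
warning rather than assumed independent. Cis status means within +/-1 Mb
of the gene *body* (anchoring on the gene body rather than the TSS; the
choice matters only for long genes). Instrument strength uses the
summary-data approximations F = (beta/se)^2 and R^2 = F/(F + n - 2).

## Colocalization

Per-variant evidence is the Wakefield log-ABF,
0.5*log(1-r) + 0.5*r*z^2 with r = W^2/(W^2 + se^2). The effect-size prior
SD W defaults to 0.15 for quantitative traits and 0.2 for binary traits
(the classical coloc convention), configurable. Regions are filtered to
MAF >= 0.01 (MAF = min(EAF, 1-EAF)) and INFO >= 0.8.

Two traits: exact enumeration of H0-H4 with priors p1 = p2 = 1e-4 and
p12 = 1e-5 under the uniform/default mode, or p12 = p1*(1-gamma) under the
conservative trait-level mode (gamma default 0.98, i.e. 1 in 500,000
variants causal for two traits).

More than two traits: the model assumes at most one causal variant per
trait and sums, exactly, over all assignments of traits to shared-variant
blocks, with distinct blocks constrained to distinct variants (computed by
Mobius inclusion-exclusion over merged blocks, so the two-trait case
reproduces the five-hypothesis enumeration to machine precision). A block
of s traits costs prior p1 * f^(s-1), where f = 1-gamma (conservative) or
p12/p1 (uniform). The posterior that all supplied traits share one variant
is the decision quantity; when it falls below the 0.7 threshold, the trait
whose removal most improves the remainder is peeled off greedily and the
search recurses on both parts, emitting maximal clusters of >= 2 traits.
This greedy elimination is a deliberate simplification of branch-and-bound
subset selection: it is exact for the evidence of any candidate subset and
only heuristic in which subsets it visits, which suffices for the small
trait panels (<= ~8) this pipeline analyses. Conditional on
colocalization, the per-variant posterior share is the normalised product
of ABFs, and its maximum identifies the candidate shared variant.
Increasing gamma can only shrink shared-block weights relative to split
configurations, so the colocalization posterior is monotone non-increasing
in gamma.

The single-causal-variant assumption is the main modelling restriction:
regions harbouring multiple independent causal signals can fail to
colocalize even when one signal is shared (a recognised source of false
negatives). No multi-causal extension is attempted.

## Mediation

All mediation arithmetic is on the linear/log-odds scale; odds ratios are
logged on ingestion (the product method is incoherent on the OR scale).
Indirect = beta_EM * beta_MO with delta SE; proportion = indirect /
beta_EO. Flags mark sign mismatches between indirect and total effects,
proportions outside [-1, 1], and unstable ratios (total-effect |z| < 2),
for which the delta-method ratio CI is unreliable. The ratio CI treats
numerator and denominator as independent, which is approximate because the
total and the exposure-mediator effects derive from the same instrument
region.

## Phenome-wide screen

Phenotypes with fewer than 500 cases are excluded ("fewer than" read
literally: exactly 500 is retained). Significance uses
alpha / n_proteins / n_phenotypes with the post-filter phenotype count
unless a fixed denominator is supplied. Direction: an effect pointing the
same way as the protein's reference effect on stroke is *beneficial* (an
intervention normalising the protein for stroke would move this phenotype
favourably too), opposite is *deleterious*, and a missing or zero stroke
reference yields *not_applicable*.

## Pipeline

Thresholds are always recomputed from manifest counts (0.05/n_proteins for
the primary screen, 0.05/n_risk_factors for step-1 MR, layered Bonferroni
for the phenome screen) — never hard-coded. Each primary row carries four
gates: causal p <= alpha_primary, Q p >= 0.05, Egger-intercept p >= 0.05,
PRESSO global p >= 0.05. Egger runs only with >= 3 instruments and PRESSO
with >= 4; a gate whose test could not run passes with an annotation
rather than failing the protein, mirroring the conditional application of
these tests. The gates are evaluated jointly and all reported; no ordering
among them is imposed. Trans-inclusive hits instrumented by variants on a
configurable flagged-locus list are annotated rather than promoted.
Reverse MR instruments the outcome and flags hits whose reverse estimate
clears the primary threshold. Mediation is computed only for triples where
step 1, step 2 and the total effect all pass. Reports serialise every
table with threshold provenance and hash deterministically; stages that
did not run appear as explicit "skipped" markers. Per-stage seeds are
derived from the run seed by hashing stage labels, so adding a stage never
shifts another stage's stream.

## Synthetic data

Summary statistics are simulated directly from the standard multivariate
normal model for LD-correlated marginal estimates: with joint per-allele
effects b and LD correlation R (AR(1), r_jk = rho^|j-k|), the exposure
estimates are MVN(R b, D R D), D = diag(se), se_j = 1/sqrt(2 maf_j (1 -
maf_j) n). Outcome marginal means are theta * (R b) plus per-variant
pleiotropy draws (none, balanced, or directional); binary-outcome SEs use
the asymptotic logistic approximation, dividing by sqrt(case_frac * (1 -
case_frac)). Defaults mirror the motivating design: a ~5,000-sample
proteomics cohort against a ~447,000-sample disease GWAS with ~9% cases.
Every simulation stores a truth record (theta, causal indices, pleiotropy
draws) so estimators are always scored against stored truth.

What the generator does *not* emulate: realistic human LD panels (AR(1)
only), winner's-curse inflation from instrument discovery in the same
data, sample overlap between cohorts, allele-frequency mismatches between
populations, or the absolute calibration of log-odds effects against a
liability-scale model. Passing tests therefore demonstrate correctness of
the estimators and the decision logic under the assumed sampling model,
not robustness to those real-data complications.

### Monte-Carlo validation conditions

The validation suites fix their scenarios once:

- *Calibration*: 1000 null datasets, 10 independent instruments of
  moderate strength (per-IV F > 30), fixed-effect IVW — the exactly
  calibrated variant (see above for the MRE's conservatism).
- *Recovery*: 500 datasets per effect (theta = -0.2 and 0.3), 10
  independent strong instruments (per-allele effect 0.8 SD, n = 20,000,
  per-IV F in the hundreds) so that the ~1/F regression-dilution bias of
  summary-data MR is negligible against the Monte-Carlo error of the mean.
- *Egger recovery*: 500 datasets, 50 instruments with strengths spread
  over 0.2-0.8 SD (the spread identifies the intercept), directional
  pleiotropy mean 0.05, SD 0.02.
- *Mediation recovery*: 300 replicates of the chain beta_EM = 0.2,
  beta_MO = 0.5, direct = 0.1 (true proportion 0.5), independent variants
  so LD-shadow instruments cannot introduce selection bias.
- *End-to-end panel*: five labelled proteins; the per-protein verdict
  accuracy averaged over seeded replicates is the reported metric, since
  the sensitivity gates operate at a nominal 5% level and a conjunction of
  all verdicts in a replicate would be dominated by those designed false
  failures.

The panel generator plants small causal log-odds effects (0.1 per SD,
the scale typical of protein-disease effects) with large cis-pQTL
instrument effects, and gives the pleiotropic protein eight instruments so
that its directional pleiotropy (mean 0.05, SD 0.05) is detectable by the
heterogeneity and intercept gates. The reverse-causal protein is given
both a forward signal and a strong outcome-to-protein effect so that the
reverse-MR stage — not the forward screen — must eliminate it.

## Numerical choices

- Clump ties at equal p broken by (chromosome, position, rsid).
- Harmonization EAF-inference threshold 0.42.
- Colocalization sums computed in log space with logsumexp; the
  inclusion-exclusion terms use signed logsumexp and drop numerically
  degenerate (non-positive) partition weights.
- PRESSO requires an explicit seed; the pipeline derives per-stage seeds
  by SHA-256 of (run seed, stage labels) reduced mod 2^31.
- GLS ridge 1e-6 when Omega's minimum eigenvalue < 1e-8.
- Monte-Carlo p-values are never exactly zero (floor 1/(n_sim+1)); normal
  p-values are floored at the smallest positive double.

## Limitations

- Single-causal-variant colocalization only; no conditional analysis or
  fine-mapping.
- No weighted-median or mode-based estimators; reverse MR plays the
  directionality-check role instead of Steiger filtering.
- Harmonization does not lift over genome builds, decompose multi-allelic
  records, or normalise indels.
- The LD matrix is an input (or simulated); the package never derives LD
  from genotype panels.
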