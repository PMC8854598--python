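# Methods

`ceranet` implements the inference machinery of a network-coupled lipidomics
survival analysis: it links a data-driven conditional-independence network of
(dihydro)ceramides to time-to-event cardiometabolic endpoints in a
case-cohort design, then quantifies mediation of diet exposures and runs a
single-instrument Mendelian randomization.  Because subject-level data of the
motivating study design are not public, the package ships a first-class
synthetic-cohort generator that encodes the statistical structure the
analysis assumes, together with the ground truth needed for recovery testing.

## The synthetic cohort generator

**Metabolite panel.**  Log-scale concentrations follow a linear-Gaussian
structural equation model on a directed acyclic graph.  The default
`elongation_chain` topology links consecutive acyl-chain lengths within each
lipid class (fatty-acid elongation) and same-chain-length dihydroceramide →
ceramide pairs (desaturation), mimicking the product–substrate structure
such networks recover from real lipidomics panels; edge weights default to
U(0.3, 0.6), bounded away from zero for faithfulness.  Raw concentrations
are the exponentiated log values with per-metabolite intercepts spread over
~0.2–40 nM, producing the right-tailed distributions the log-z transform is
designed for.  Noise variances are 1 on the log scale; this is larger than
typical assay scatter but is irrelevant downstream because every analysis
works on z-scores.

**Confounding.**  An observed standard-normal confounder ("adiposity",
loading 0.2 on every metabolite, log-HR 0.3 per unit on the hazard) plus a
binary sex covariate (log-HR 0.2) let the tests verify that covariate
adjustment removes confounder-induced bias.  Note a consequence used by the
tests: because a shared loading is a common cause of *all* metabolites, the
metabolite-only population skeleton is complete; d-separation structure is
only present in the structural (noise-only) covariance, which
`implied_log_covariance(truth, structural_only=True)` exposes for
population-oracle checks.  At realistic loadings and sample sizes the
induced partial correlations are far below the detection threshold, so
sample skeletons recover the DAG skeleton.

**Events.**  Each endpoint has a Weibull baseline hazard on the age axis
(shape 5, rising steeply with age as cardiometabolic incidence does).
Subjects enter at a baseline age drawn U(35, 65) — the recruitment window —
and event ages are drawn conditional on being event-free at entry (inverse
cumulative-hazard sampling), giving left truncation by construction;
administrative censoring occurs at entry + 10 years by default.  The Weibull
scale is calibrated by bisection on the realized draws to hit a configurable
case fraction (default 12%, range ~5–40%); the calibration uses the same
exponential draws as the final simulation, so it is deterministic given the
seed.  Endpoints are simulated as independent processes; competing risks are
out of scope because the analyses treat endpoints separately.

**Diet, genetics, repeats.**  Diet exposures are standard normal and act on
their designated mediator metabolites (log-scale shift per unit) plus a
direct log-HR on the hazard.  The genetic instrument is a binomial(2, MAF)
dosage whose per-allele effect is specified in SD units of the target
metabolite and converted internally to the log scale using the target's
instrument-free SD (the residual attenuation from the instrument's own
variance contribution is < 1% at default settings).  Repeat measurements for
a pilot subset add log-scale noise with variance `2·s²_b·(1−icc)/icc` to a
duplicated measurement, which makes the expected one-way ICC equal the
target.

**What the generator does not emulate** — assay batch effects, limits of
detection, genotyping error, FFQ measurement error, non-proportional
hazards, informative censoring, competing risks.  Passing recovery tests
therefore demonstrates correctness of the estimators under their assumed
models, not robustness to those violations.

## Preprocessing

Concentrations are natural-log transformed and z-scaled per column with the
sample SD (denominator n−1), so every hazard ratio downstream is per 1 SD of
the log concentration (any log base gives identical z-scores).  Subjects
with missing or non-positive values in an involved column are excluded from
the analyses using that column, with the reason recorded.  Reliability of
repeat measurements uses the one-way random-effects ICC,
(MSB − MSW)/(MSB + MSW) for pairs, computed on the log scale; the estimator
choice (one-way rather than two-way) is a documented decision — with one
repeat per subject and no rater structure, the one-way model is the natural
fit.  Classes follow Rosner's cutoffs: < 0.40 poor, 0.40–0.75 fair to good,
> 0.75 excellent.  Full-order partial correlations come from the precision
matrix, ρ_ij·rest = −Ω_ij/√(Ω_ii Ω_jj), which the tests verify against the
regression-residual definition to 1e-8.

## Skeleton estimation (stable PC)

Conditional independence is tested by the Fisher z statistic
√(n−|S|−3)·|atanh r| with a two-sided normal p-value at alpha = 0.05
(two-sidedness assumed; the direction of a partial correlation is not
informative here).  The stable (order-independent) PC variant is used:
neighbor sets are frozen at the start of each conditioning-size level and
edge deletions are applied only at level end, so the output is invariant to
column order (asserted over 20 random permutations).  Internally nodes are
processed in sorted-name order, making sepset records deterministic too.
The maximum conditioning-set size is unlimited by default (the panels are
small); a cap is available.  Only the undirected skeleton is produced —
the direct-effect search consumes adjacency, not orientations.

## Prentice-weighted case-cohort Cox estimation

Age is the time scale: subjects are at risk from entry age to exit age.
The case-cohort design is handled by the Prentice pseudolikelihood risk-set
construction: subcohort members are at risk over their full observed
interval, while cases outside the subcohort enter the risk set 1e-6 years
before their own event age (weight-1 time-splitting; equivalent to the
Prentice pseudolikelihood, and exactly the standard partial likelihood when
the subcohort is the whole cohort — asserted to 1e-8).  Barlow-style
weighting is deliberately not used.  Variance is always the robust sandwich
estimator built from score residuals, since the pseudolikelihood invalidates
the model-based variance; ties use Efron's approximation (ages are
continuous, so ties are rare, but the tied path is exact and checked).

The solver is a vectorized Newton iteration with step-halving written for
this package's simulation loads (bootstrap and recovery studies run tens of
thousands of fits): beta-independent index structures (sort orders, unique
event times, tie groups) are computed once per fit and only the
exponential-weighted cumulative sums are recomputed per iteration.
Coefficients, naive SEs and robust SEs are validated in the test suite
against frozen `survival::coxph` reference values (agreement to 8 digits on
seeded fixtures, with and without ties) and against lifelines coefficients.
Near rank-deficient design matrices (condition number > 1e10) are rejected
with a diagnostic; non-convergence raises rather than returning silently.

An optional stratification by baseline-age band (default 5-year bands, off
by default) is provided because "age as the time scale" and "age as strata"
describe different implementations of the same intent; the time-scale
treatment is primary.

The single-lipid screen fits one model per metabolite per specification
(e.g. minimal: sex; full: all confounders plus the log-z class totals) and
applies Benjamini–Hochberg FDR within each endpoint-and-model family at
q < 0.05.  Class totals are computed by summing raw nM concentrations within
class and log-z transforming the sum.

## Network-coupled direct-effect classification

For each metabolite, all 2^d subsets of its skeleton neighbors (excluding
any previously selected effectors, which are always adjusted) define
sub-models on top of the fixed confounder set; enumeration refuses degrees
above 2^10 sub-models (configurable) since the target networks are sparse.
A metabolite is a **direct effector** if its coefficient is significant
(p < alpha = 0.05, uncorrected by design) with one common sign across every
sub-model; **none** if no sub-model is significant; **ambiguous** otherwise.
The three-way split extends the binary published rule for honest reporting;
sign consistency is sign-only, with no magnitude or CI-overlap requirement
(the natural reading of directional consistency).  Newly selected effectors
join the fixed set together at round end (batch update) rather than greedily
mid-round — this makes the selection order-invariant, which a greedy update
would not be — and the loop repeats until a round selects nothing
(termination in at most p rounds since the fixed set grows monotonically).
Established effectors can only confound, not mediate, the remaining
candidates, which is why they move to the fixed adjustment set.  Finally all
selected metabolites enter one joint Cox model, giving mutually adjusted
hazard ratios.  With an empty skeleton the first round reduces exactly to
the confounder-adjusted single-metabolite screen (asserted in tests).

## Mediation: proportion explainable

Candidate mediators are disease-related metabolites (their outcome direction
is taken from the joint model, which makes selection reproducible from
pipeline state) regressed on the exposure with confounder adjustment in the
representative subcohort; a candidate is selected when its one-sided p is
< 0.05 in the mediation-consistent direction, i.e. when
sign(exposure→metabolite)·sign(metabolite→disease) matches
sign(exposure→disease).  The proportion explainable is the difference-method
attenuation on the log-HR scale, PE = 100·(1 − β_adjusted/β_total); the
point estimate is never truncated (negative values mean amplification), the
reported interval's upper bound is capped at 100%.  Total effects with
|β_total| below 0.01 are rejected as undefined mediation; inside bootstrap
replicates the floor is disabled because the interval quantiles absorb
occasional near-zero denominators.  A first-order delta-method SE for the
point estimate is provided (treating the two fits as independent unless a
covariance is supplied); the primary interval is a bias-corrected
accelerated bootstrap: subjects resampled with replacement at a two-thirds
sampling fraction, B = 1000 by default, both Cox models refit per replicate,
bias correction from the bootstrap distribution and acceleration from a
grouped jackknife (20 groups by default, the standard device for expensive
statistics).  Simple subject resampling is the default; a case/non-case
stratified option exists because the published protocol does not state
whether resampling respected the design.  Diet-exposure hazard ratios are
reported per 2 exposure SDs (configurable), matching how such intakes are
conventionally scaled; PE itself is scale-invariant.

The designed-mediation benchmark (`mediation_benchmark_truth`) solves the
exposure→mediator coefficient in closed form so that the mediated path
contributes exactly half of the total log-HR; Cox non-collapsibility makes
the attainable PE deviate from 50% only at the ~1–2% level for the default
effect sizes and case fractions, well inside the coverage tolerances used.

## Mendelian randomization

The small-scale association routine fits additive-dosage least squares for
continuous standardized phenotypes (beta per allele in SD units) and
logistic regression for binary outcomes (log-odds per allele), after a MAF
filter to [0.05, 0.5].  Instrument selection takes the lowest-p association
below the suggestive threshold 1e-5 **among SNPs available in the external
replication data**, with lexicographic tie-break.  Harmonization aligns the
outcome's effect allele with the exposure's, negating the outcome beta when
the coding is swapped; palindromic pairs (A/T, C/G) are flagged, not
dropped, since the single-instrument setting makes strand ambiguity a
reviewer decision.  The Wald ratio is β_outcome/β_exposure with the
first-order SE = SE_outcome/|β_exposure| — chosen because it reproduces the
published cross-cohort SEs from the printed betas (the SE ratios across
cohorts equal the inverse exposure-beta ratios to within print rounding);
a second-order SE propagating the exposure uncertainty is available behind
a flag.  The shipped summary tables for the rs680379/Cer22:0 worked example
carry reconstructed (synthetic) allele labels: the sources print betas
without alleles, and the sign pattern fixes which cohorts share an effect
allele.  The outcome-study association is recovered from the published
EUROSPAN Wald-ratio row as β_outcome = WR·β_exposure, since it is not
printed directly.

## Pipeline

A single declarative configuration (YAML or `RunConfig`) drives all stages
in dependency order; every alpha used anywhere (network 0.05, direct-effect
0.05, FDR 0.05, GWAS-suggestive 1e-5) is a config key.  The panel
standardization and skeleton are fit on the random subcohort (the
representative sample) and applied to the case-cohort rows.  Each stage
writes a tab-separated table plus a JSON manifest (stage, seed, counts, wall
time); with fixed seeds all result tables are byte-identical across re-runs
(the manifest's wall-clock fields are the only non-reproducible output).
The CLI (`ceranet`) exposes per-stage subcommands and an `all` runner as a
thin layer over the library.

## Problem sizes and numerical choices

The recovery studies in the test suite use cohorts of n = 4000–20000 with
case fractions 5–15%, 100–200 replicates for bias/power/false-selection
rates, B = 100 bootstrap replicates with 10 jackknife groups for
interval-coverage experiments (the full B = 1000 / 20-group protocol is used
for single-run intervals in the acceptance script); these sizes give
Monte-Carlo error comfortably inside the asserted tolerances while keeping
the default run reproducible on one CPU.  Newton convergence requires
max|gradient| < 1e-8 with relative log-likelihood change < 1e-10; linear
predictors are clipped at ±200 before exponentiation; |r| = 1 in the Fisher
z test is declared dependent with p = 0 rather than overflowing; BH q-values
come from statsmodels.  Known limitations: no competing risks,
time-varying covariates or spline baselines; no multi-instrument MR
estimators or pleiotropy tests (single-instrument setting); no imputation of
metabolite values; PC output is a skeleton only.
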