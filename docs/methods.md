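# Methods

This note documents the models, defaults, and design choices behind
`meanbands`, and what the synthetic-data experiments do and do not show.

## Analysis model

For each outcome the analysis data are, per design cell *g* (condition ×
sex × cohort; G = 8) a matrix of students × 6 waves of covariate-adjusted
POMS scores, assumed complete (imputation happens first). The model is a
multiple-group multivariate normal with an unconstrained covariance per
group and a mean structure tied by a constraint scheme: cells sharing a
rank share one mean parameter. Only the means carry substantive
hypotheses; leaving the covariances saturated keeps the constrained
solutions interpretationally comparable across schemes and makes the
likelihood-ratio statistic a pure test of the mean constraints.

**Estimation.** For fixed means the ML covariance is `S_g + d_g d_g'`
(`S_g` the divide-by-n sample covariance, `d_g` the mean residual), so the
covariances can be profiled out exactly. The rank means then minimize
`sum_g n_g log(1 + d_g' S_g^{-1} d_g)`, which we do with a damped Newton
iteration (analytic gradient and Hessian, Armijo backtracking, a
Gauss-Newton fallback direction when the Hessian loses definiteness, and
two deterministic starts — the S-weighted GLS solution and the n-weighted
cell-mean projection — because the profiled objective flattens for
far-away groups and can have spurious local optima under gross
misspecification). Convergence is declared at a relative log-likelihood
change below 1e-8 with a 500-iteration cap. Degenerate inputs fail loudly:
groups smaller than the wave count, singular sample covariances, and
non-convergence all raise.

**Fit statistics.** The model chi-square is the likelihood-ratio deviance
against the saturated-means model, df = 6G − R. RMSEA uses the
multiple-group convention `sqrt(max(chi2 − df, 0)/(df n)) · sqrt(G)` (0 by
convention at df = 0); SRMR is the RMS of mean residuals standardized by
the observed cell SD — with saturated covariances the covariance residuals
vanish identically, so only mean residuals contribute. Rank separation
uses signed Wald z statistics `(m_r − m_s)/SE` from the inverse
information; the sign convention matches ascending rank order.

## Banding search

Model selection proceeds exactly as in the trial's strategy: saturated
model → baseline equivalence across all groups (relaxed stepwise to
within-sex, within-cohort, within sex × cohort when the difference test
rejects; relaxation order is a choice, the source states "gender and/or
cohort" without one) → iterative merging of statistically similar means.
A proposal is accepted only if the difference test against the last
accepted scheme is non-significant at alpha = 0.05 *and* all adjacent
ranks of the proposal separate by Wald test; non-separated adjacent ranks
are merged and the merge re-tested. The default proposal rule
(`GapRule(threshold=0.5, mode="threshold")`) chains sorted rank means with
adjacent gaps under 0.5 POMS — single linkage cut at the threshold. The
published account names the idea ("bands of magnitude") but not the rule;
the formal rule is our stand-in, and a greedy smallest-gap-first mode is
provided. The default attempt cap of five mirrors the published search
budget; hitting it warns rather than fails.

On multiply imputed data the search fits every candidate scheme to all m
datasets and decides on pooled statistics. Difference decisions default
to a **D1 pooled-parameter constraint test** (the added equalities are
linear constraints on the parent's Rubin-pooled rank means): at this
trial's missing-information fractions (~0.6) with m in the tens, the D2
combination of likelihood-ratio statistics collapses toward p = 1 and
cannot reject even gross misfits, a known weakness of D2. D2 remains
implemented, reported, and switchable (`diff_method="d2"`).

The full pipeline proposes greedily (one guarded merge per attempt, cap
60) rather than by one-shot threshold chaining: with realistic imputation
noise the 41 free means after the baseline step interleave across true
band boundaries, and a single chained proposal is either rejected as a
whole or silently bridges bands. One-merge-at-a-time with D1 guards
degrades gracefully instead.

## Imputation

Missing responses are imputed by chained equations with proper normal
draws: for each incomplete column, a Bayesian linear regression on (a)
design-cell dummies saturated in condition × sex × cohort × wave — the
analysis model estimates exactly those cell means, so the imputation model
must span them, (b) encoded covariates, (c) the first k principal-component
scores of the remaining auxiliary block (k = 4 by default), and (d) the
other outcome items, drawn parameters first, then values. Ordinal items
use type-1 predictive-mean matching with 5 donors: round-and-clamp of
continuous draws (available as `ordinal_method="round"`) inflates the rare
upper categories when ~95% of responses sit at the scale floor, which
biased synthetic cell means upward by 0.5–1.5 POMS. The variables being
imputed are excluded from their own auxiliary block — otherwise their
mean-filled values leak into the scores and the imputation degenerates to
a perfect fit with no residual variance.

Pooling follows Rubin's rules (`T = W + (1 + 1/m) B`, Barnard–Rubin df
when a complete-data df is supplied). The production default of m = 100
completed datasets is a config knob; tests and the shipped pipeline run at
m = 3–10 for speed, which changes Monte-Carlo error but not the rules.

## Outcome preparation

Composites are item averages; POMS maps the 1–4 response metric to 0–100
relative to the possible extremes. Covariate adjustment is a per-wave OLS
pre-regression of the POMS outcome on race/ethnicity, age, survey date,
guardianship, and witnessing violence — never condition — plus school
terms. Schools are nested in condition, so raw school dummies would absorb
the treatment contrast; we center each school indicator within its arm,
making every school column exactly orthogonal to the condition contrast
(the adjustment then removes within-arm school variation while leaving the
arm difference untouched, and a guard raises if the design could express
the contrast). Adjusted scores are `intercept + residual`, anchoring the
scale at meaningful covariate zero points: age 11.93 (the sample mean),
survey date 0 (study start), reference categories elsewhere. Residuals are
winsorized at ±3.29 SD (two-sided p < .001 under normality) — the source
says "corrected for outliers" without naming the correction; winsorization
is our documented choice and the bound is configurable. On heavily skewed
outcomes winsorization (and zero-point anchoring) shifts adjusted means
below the raw-scale trajectories; baseline adjusted means can legitimately
be negative.

## Synthetic trial generator

The generator emulates the trial's structure: 22 DM / 24 SC schools, cell
sizes equal to the published N column (total 3301), six waves, 1 SV item
per direction and 6/7 SH items, ordinal 1–4 responses. A student's latent
propensity for an outcome at a wave is

    cell location + school effect + person effect + wave effect
    + covariate effects,

each item adding its own noise before thresholding into four categories.
The cell location is found by numerically inverting the expected-POMS
function (a sum of normal tail probabilities, with the witness effect
handled as the two-point mixture it is), so the population mean of the
POMS-scored response equals the configured trajectory exactly; default
trajectories are the published model-estimated mean grids (the one
negative printed baseline, −0.04, is floored at 0.05 POMS since a
thresholded response cannot have negative expected POMS).

Variance shares on the unit latent scale and the threshold spacings were
calibrated once by simulation so the default configuration reproduces the
observed anchors — lifetime any-endorsement prevalence 3/6/29/47% for SV
perpetration/victimization and SH perpetration/victimization, SH composite
reliability in the .64–.83 band — and then frozen
(`trial_synth.CALIBRATED`). The school share defaults to 0.02 (a typical
school-clustering magnitude for behavioral outcomes; the source reports no
ICC). Missingness is MAR by construction: late entry (only 40% present at
baseline), a per-wave exit hazard of 0.15, covariate-dependent wave
nonresponse, and 2% item spot missingness, jointly targeting the reported
~65% overall missingness. No probability ever depends on the masked
response value, which the tests verify by regressing missingness on the
held response.

Covariate distributions match the reported composition where stated (50%
black non-Hispanic, 31% Hispanic; age 11.93 ± 0.57); guardianship,
witnessing violence, and survey-date jitter are parametric placeholders
with simple defaults. Outcomes are generated independently of each other —
real SV/SH responses correlate across outcomes, so cross-outcome analyses
of the synthetic data are out of scope. The generator injects trajectories
directly; it does not model program mechanisms or norm diffusion.

## What the experiments show — and don't

- *Oracle agreement* (20 random well-specified instances): the Newton
  fitter reaches the same maximized likelihood as a generic optimizer to
  1e-6 relative. Under arbitrary misspecification the profiled likelihood
  is multimodal and no method is guaranteed the global optimum.
- *Band recovery* (50 runs, 1,000 students/cell, residual SD 0.5 POMS):
  the search recovers the published SV-perpetration partition ≥ 90% of the
  time. This checks the algorithm under conditions where the bands are
  statistically resolvable; at the trial's real noise and missingness the
  cell-mean standard errors (~0.6 POMS) are of the same order as the band
  gaps, and no selection procedure could recover them reliably from one
  synthetic replication.
- *Coverage* (200 replications, m = 10): Rubin-pooled 95% intervals for a
  cell mean under MAR masking cover the truth at 95 ± 3%. The experiment
  uses a continuous outcome; ordinal PMM imputation adds discreteness that
  the coverage claim does not cover.
- *Calibration* (full default trial): prevalences land within ~1–2 points
  of the SV anchors and ~1–5 points of the SH anchors; per-wave alphas
  fluctuate with the complete-case count, so the band claim is about the
  across-wave average.

Passing these does not show that the pipeline recovers the *published*
chi-squares, RMSEA/SRMR, or rank means — those depend on the unavailable
trial data and are covered only through the printed-grid fixtures and the
properties above.

## Numerical conventions

Reported numbers are rounded half-up to the published precision (2
decimals for POMS, whole percents for RRR) only at the reporting boundary.
Effect averages exclude the baseline wave (both arms are constrained to
baseline equivalence, so baseline cells carry no effect information);
final-wave summaries average all four sex × cohort groups including
zero-effect groups — these are the only conventions under which the
printed derived numbers are recoverable from the printed grids. Cells with
non-positive SC means are excluded from RRR (logged in the summary).
Two derived numbers are not exactly recoverable from printed-precision
inputs (the SH difference-range endpoints and two RRR summaries differ by
one unit in the last digit); the fixtures carry the printed values and the
summaries report what the arithmetic gives.
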