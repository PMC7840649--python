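# meanbands

Outcome-evaluation pipeline for cluster-randomized prevention trials whose
analysis models are **multiple-group mean structures with equality
constraints** ("banding"). The package re-implements, as tested and
reusable components, the evaluation machinery of a school-randomized teen
dating violence prevention trial: 46 middle schools assigned to a
comprehensive multi-component prevention condition (DM, 22 schools) or a
standard-of-care program (SC, 24 schools), two cohorts entering 6th grade
a year apart, and six survey waves (fall/spring of grades 6–8) measuring
sexual violence (SV) and sexual harassment (SH) victimization and
perpetration on 1–4 ordinal items.

It is written for methodologists and trial analysts who want to study or
reuse this evaluation strategy: because the trial's raw data are not
deposited, a calibrated synthetic-trial generator stands in for them, and
the published model-estimated mean grids ship as fixtures so the
effect-summary stage can be verified against the printed results.

## The model

Outcomes are item-average composites rescaled to **POMS** (percent of
maximum score): `POMS = 100 (x − 1)/(4 − 1)` for a 1–4 scale. After
multiple imputation and a covariate pre-adjustment step, each of the
G = 8 design cells (condition × sex × cohort) contributes a 6-wave outcome
vector modeled as multivariate normal,

    y_g ~ N(mu_g, Sigma_g),     mu_gt = m_{r(g,t)},

with saturated per-group covariances Sigma_g and a *constraint scheme*
r(g,t) mapping each (group, wave) cell to one of R shared mean parameters
("ranks"). Fitting is maximum likelihood; with the covariances profiled
out (`Sigma_g = S_g + d_g d_g'` at the optimum) the deviance against the
saturated-means model is

    chi2 = sum_g n_g log(1 + d_g' S_g^{-1} d_g),   df = 6G − R,

minimized over the rank means by a damped Newton iteration. Model fit is
summarized by RMSEA `sqrt(max(chi2 − df, 0)/(df n)) · sqrt(G)` and SRMR
(root mean square of SD-standardized mean residuals); nested schemes are
compared by chi-square difference tests, and rank separation by signed
Wald z statistics from the inverse information.

The **banding search** starts from baseline equivalence across all groups
(relaxed to within-sex/cohort if the difference test rejects), then
repeatedly merges statistically similar means into bands, accepting a
coarser scheme only when the difference test shows no significant
decrement *and* all adjacent ranks remain Wald-separated.

Upstream, missing responses (the trial's missingness is heavy — typically
65%+) are multiply imputed by chained proper normal models whose
predictors include principal-component auxiliary scores; estimates are
pooled with Rubin's rules, likelihood-ratio statistics with D2, and
constraint tests on pooled parameters with D1. Downstream, model-estimated
mean grids become effect summaries: per-cell POMS differences `SC − DM`
and relative risk reductions `RRR = 100 (SC − DM)/SC`, averaged over the
20 post-baseline cells and over the four sex × cohort groups at the final
wave.

## Worked example

Effect summaries straight from the packaged mean-grid fixture for SV
perpetration:

```bash
meanbands effects --outcome sv_perpetration
```

```json
{
  "sv_perpetration": {
    "avg_diff": 0.16,
    "diff_range": [0.0, 1.24],
    "avg_rrr": 6.0,
    "rrr_range": [0.0, 45.0],
    "final_wave_avg_rrr": 13.0,
    "final_wave_rrr_range": [0.0, 30.0]
  }
}
```

Reading: across the 20 post-baseline cells the DM arm scores on average
0.16 POMS lower than SC (largest single-cell gap 1.24 POMS), a 6% average
relative risk reduction that peaks at 45%; by spring of 8th grade the
four-group average reduction is 13%.

The same numbers from the library:

```python
from meanbands import printed_grid, summarize

summary = summarize(printed_grid("sv_perpetration"))
print(summary.rounded()["avg_diff"])   # 0.16
```

A full synthetic-trial run (simulate → impute → adjust → search → effects):

```bash
meanbands all --outdir out/ --seed 1
```

writes per-outcome model results and mean grids, a plain-text report in
the layout of the published tables, and a manifest with checksums; the run
is byte-reproducible from the config and seed.

## Layout

- `src/meanbands/trial_synth.py` — synthetic trial generator (latent-threshold ordinal responses, school clustering, MAR missingness) and its calibration report
- `src/meanbands/imputation.py` — PCA auxiliary scores, chained proper imputation (PMM for ordinal items), Rubin / D2 pooling
- `src/meanbands/outcome_prep.py` — composites, POMS, covariate adjustment with within-arm-centered school terms, winsorization
- `src/meanbands/mean_structure.py` — constrained-means ML fits, fit indices, Wald tests, D1 constraint tests, pooling
- `src/meanbands/constraint_search.py` — baseline-equivalence step and the iterative banding search
- `src/meanbands/effects.py` — mean-grid fixtures, POMS differences, relative risk reductions
- `src/meanbands/pipeline.py`, `cli.py` — orchestration, reports, manifests, the `meanbands` command
- `docs/methods.md` — modeling assumptions, parameter defaults, and known limitations
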