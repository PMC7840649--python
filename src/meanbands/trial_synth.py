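"""Synthetic cluster-randomized trial generator.

No raw data from the trial are deposited, so every downstream stage is
exercised on synthetic tables that reproduce the trial's *statistical*
structure: 46 schools randomized to two arms (22 DM / 24 SC), two cohorts
entering 6th grade a year apart, six survey waves (fall/spring of grades
6-8), ordinal 1-4 item responses (1 item per SV direction, 6/7 items for
SH victimization/perpetration), school clustering, and heavy MAR
missingness from late entry, early exit, and wave nonresponse.

Responses follow a latent-threshold model: a student's latent propensity
for an outcome at a wave is the cell's location parameter plus school,
person, wave, and covariate effects; each item adds its own noise and is
cut into the four ordinal categories at fixed thresholds. The location
parameter is found by numerically inverting the expected-POMS function,
so the *population* mean of the POMS-scored response equals the
configured trajectory value exactly — trajectories with a known band
structure can therefore be recovered by the downstream model search.

Default thresholds and variance shares were calibrated once, by
simulation under the default configuration, so that lifetime
any-endorsement prevalences land near the observed anchors (3% SV
perpetration, 6% SV victimization, 29% SH perpetration, 47% SH
victimization) and Cronbach's alpha for the SH composites falls in the
observed .64-.83 band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.stats import norm

from .design import (
    COHORTS,
    GROUP_SIZES,
    GROUPS,
    ITEM_COUNTS,
    N_WAVES,
    ORDINAL_MAX,
    ORDINAL_MIN,
    OUTCOMES,
)
from .outcome_prep import item_columns


class ConfigurationError(ValueError):
    """Inconsistent simulation configuration (e.g., students without schools)."""


def latent_to_ordinal(latent_value, thresholds):
    """Cut a latent value into ordinal categories 1..4.

    Returns ``1 + number of thresholds below the latent value``; the three
    thresholds must be strictly ascending. Accepts scalars or arrays.
    """
    thr = np.asarray(thresholds, dtype=float)
    if thr.shape != (3,) or not np.all(np.diff(thr) > 0):
        raise ValueError("need exactly 3 strictly ascending thresholds")
    arr = np.asarray(latent_value, dtype=float)
    # a latent exactly on a threshold has not crossed it
    out = 1 + (arr[..., None] > thr).sum(axis=-1)
    return int(out) if np.isscalar(latent_value) else out


def expected_poms(delta, thresholds, noise_sd: float):
    """Population mean POMS of a thresholded latent N(delta, noise_sd^2).

    POMS of a single 1-4 item is (100/3) * (category - 1), and the expected
    category exceedances are normal tail probabilities at each threshold.
    """
    thr = np.asarray(thresholds, dtype=float)
    d = np.asarray(delta, dtype=float)
    p = norm.sf((thr - d[..., None]) / noise_sd).sum(axis=-1)
    out = 100.0 / 3.0 * p
    return float(out) if np.isscalar(delta) else out


def invert_poms_mean(target: float, thresholds, noise_sd: float) -> float:
    """Latent location whose expected POMS equals ``target`` (0 < target < 100)."""
    if not 0 < target < 100:
        raise ValueError(f"target POMS mean must be in (0, 100), got {target}")
    f = lambda d: expected_poms(d, thresholds, noise_sd) - target
    lo, hi = -50.0, 50.0
    return float(brentq(f, lo, hi, xtol=1e-10))


@dataclass(frozen=True)
class OutcomeParams:
    """Latent-response model for one outcome.

    Variance shares (school/person/wave/item) refer to the unit-variance
    latent scale and must sum to 1; ``school_icc`` is the between-school
    share of total latent variance. ``trajectories`` maps each design cell
    to its 6-wave true mean on the POMS scale; values below ``min_mean``
    (adjusted means can print as -0.04) are floored before inversion,
    since a thresholded response cannot have a negative expected POMS.
    """

    n_items: int
    thresholds: tuple[float, float, float]
    trajectories: dict  # (condition, sex, cohort) -> tuple of 6 POMS means
    school_icc: float = 0.02
    person_share: float = 0.45
    wave_share: float = 0.12
    min_mean: float = 0.05

    @property
    def item_share(self) -> float:
        return max(1.0 - self.school_icc - self.person_share - self.wave_share, 0.0)

    def validate(self, name: str) -> None:
        if self.n_items < 1:
            raise ConfigurationError(f"{name}: need at least one item")
        if not 0 <= self.school_icc < 1:
            raise ConfigurationError(f"{name}: school_icc must be in [0, 1)")
        if self.school_icc + self.person_share + self.wave_share > 1 + 1e-9:
            raise ConfigurationError(f"{name}: variance shares exceed 1")
        thr = np.asarray(self.thresholds)
        if not np.all(np.diff(thr) > 0):
            raise ConfigurationError(f"{name}: thresholds must ascend")
        missing = [g for g in GROUPS if g not in self.trajectories]
        if missing:
            raise ConfigurationError(f"{name}: trajectories missing for {missing}")


@dataclass(frozen=True)
class CovariateModel:
    """Covariate distributions and their (latent-scale) outcome effects.

    Race/ethnicity and age match the reported sample composition; the
    guardianship split, witnessing-violence rate, and survey-date jitter
    are parametric placeholders — the source reports no distribution for
    them — kept simple and documented here.
    """

    race_probs: dict = field(default_factory=lambda: {
        "black_nh": 0.50, "hispanic": 0.31, "other": 0.19})
    guardianship_probs: dict = field(default_factory=lambda: {
        "two_parent": 0.55, "single_parent": 0.35, "other": 0.10})
    age_mean: float = 11.93
    age_sd: float = 0.57
    witness_p: float = 0.40
    #: latent-SD-scale outcome effects; adjusted away downstream
    witness_beta: float = 0.30
    age_beta: float = 0.10
    date_jitter_sd: float = 10.0

    @property
    def effect_variance(self) -> float:
        return (self.witness_beta**2 * self.witness_p * (1 - self.witness_p)
                + (self.age_beta * self.age_sd) ** 2)


@dataclass(frozen=True)
class MissingnessParams:
    """MAR missingness: late entry, early exit, wave nonresponse, spot missing.

    Every probability depends only on design labels and observed
    covariates, never on the response values themselves. Defaults target
    the trial's reported overall missingness (around 65%).
    """

    entry_probs: tuple = (0.40, 0.14, 0.13, 0.12, 0.11, 0.10)
    exit_hazard: float = 0.15
    nonresponse_base: float = 0.28
    nonresponse_witness: float = 0.5  # logit shift for witnesses of violence
    nonresponse_age: float = 0.2  # logit shift per year above the mean age
    item_rate: float = 0.02

    @classmethod
    def none(cls) -> "MissingnessParams":
        return cls(entry_probs=(1.0, 0, 0, 0, 0, 0), exit_hazard=0.0,
                   nonresponse_base=0.0, nonresponse_witness=0.0,
                   nonresponse_age=0.0, item_rate=0.0)

    def validate(self) -> None:
        p = np.asarray(self.entry_probs)
        if len(p) != N_WAVES or abs(p.sum() - 1) > 1e-9 or np.any(p < 0):
            raise ConfigurationError("entry_probs must be a length-6 probability vector")
        for v in (self.exit_hazard, self.nonresponse_base, self.item_rate):
            if not 0 <= v < 1:
                raise ConfigurationError("missingness rates must be in [0, 1)")


def _default_trajectories(outcome: str) -> dict:
    from .effects import printed_grid  # local import: effects has no synth dep

    grid = printed_grid(outcome)
    return {g: tuple(grid.means[i]) for i, g in enumerate(GROUPS)}


#: Calibrated threshold spacings and variance shares per outcome (see the
#: module docstring; frozen from a one-off simulation calibration).
CALIBRATED = {
    "sv_perpetration": dict(thresholds=(2.0, 2.12, 2.25), person_share=0.68,
                            wave_share=0.10, school_icc=0.02),
    "sv_victimization": dict(thresholds=(2.0, 2.13, 2.30), person_share=0.66,
                             wave_share=0.10, school_icc=0.02),
    "sh_victimization": dict(thresholds=(2.0, 2.12, 2.30), person_share=0.42,
                             wave_share=0.10, school_icc=0.02),
    "sh_perpetration": dict(thresholds=(2.0, 2.20, 2.45), person_share=0.45,
                            wave_share=0.12, school_icc=0.02),
}


def default_outcome_params(outcome: str) -> OutcomeParams:
    cal = CALIBRATED[outcome]
    return OutcomeParams(
        n_items=ITEM_COUNTS[outcome],
        trajectories=_default_trajectories(outcome),
        **cal,
    )


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a synthetic trial; reproducible from ``seed``."""

    n_schools_dm: int = 22
    n_schools_sc: int = 24
    group_sizes: dict = field(default_factory=lambda: dict(GROUP_SIZES))
    outcomes: dict = field(default_factory=lambda: {
        o: default_outcome_params(o) for o in OUTCOMES})
    covariates: CovariateModel = field(default_factory=CovariateModel)
    missingness: MissingnessParams = field(default_factory=MissingnessParams)
    seed: int = 0

    def validate(self) -> None:
        if self.n_schools_dm < 1 or self.n_schools_sc < 1:
            raise ConfigurationError("each arm needs at least one school")
        for cell, n in self.group_sizes.items():
            if cell not in GROUPS:
                raise ConfigurationError(f"unknown design cell {cell}")
            if n < 1:
                raise ConfigurationError(f"non-positive cell size for {cell}")
        arm_n = {"DM": self.n_schools_dm, "SC": self.n_schools_sc}
        for arm in ("DM", "SC"):
            total = sum(n for (c, _, _), n in self.group_sizes.items() if c == arm)
            if total > 0 and arm_n[arm] < 1:
                raise ConfigurationError(f"cannot place {arm} students: no schools")
        for name, params in self.outcomes.items():
            params.validate(name)
        self.missingness.validate()


# ---------------------------------------------------------------------------
# YAML round-trip

def _cell_key(cell) -> str:
    c, s, coh = cell
    return f"{c}-{s}-{coh}"


def _parse_cell(key: str):
    c, s, coh = key.split("-")
    return (c, s, int(coh))


def config_to_dict(cfg: SimConfig) -> dict:
    return {
        "n_schools_dm": cfg.n_schools_dm,
        "n_schools_sc": cfg.n_schools_sc,
        "seed": cfg.seed,
        "group_sizes": {_cell_key(k): int(v) for k, v in cfg.group_sizes.items()},
        "outcomes": {
            name: {
                "n_items": p.n_items,
                "thresholds": list(p.thresholds),
                "school_icc": p.school_icc,
                "person_share": p.person_share,
                "wave_share": p.wave_share,
                "min_mean": p.min_mean,
                "trajectories": {_cell_key(k): list(map(float, v))
                                 for k, v in p.trajectories.items()},
            } for name, p in cfg.outcomes.items()
        },
        "covariates": {
            "race_probs": dict(cfg.covariates.race_probs),
            "guardianship_probs": dict(cfg.covariates.guardianship_probs),
            "age_mean": cfg.covariates.age_mean,
            "age_sd": cfg.covariates.age_sd,
            "witness_p": cfg.covariates.witness_p,
            "witness_beta": cfg.covariates.witness_beta,
            "age_beta": cfg.covariates.age_beta,
            "date_jitter_sd": cfg.covariates.date_jitter_sd,
        },
        "missingness": {
            "entry_probs": list(cfg.missingness.entry_probs),
            "exit_hazard": cfg.missingness.exit_hazard,
            "nonresponse_base": cfg.missingness.nonresponse_base,
            "nonresponse_witness": cfg.missingness.nonresponse_witness,
            "nonresponse_age": cfg.missingness.nonresponse_age,
            "item_rate": cfg.missingness.item_rate,
        },
    }


def config_from_dict(d: dict) -> SimConfig:
    outcomes = {
        name: OutcomeParams(
            n_items=o["n_items"],
            thresholds=tuple(o["thresholds"]),
            school_icc=o.get("school_icc", 0.05),
            person_share=o["person_share"],
            wave_share=o["wave_share"],
            min_mean=o.get("min_mean", 0.05),
            trajectories={_parse_cell(k): tuple(v)
                          for k, v in o["trajectories"].items()},
        ) for name, o in d["outcomes"].items()
    }
    return SimConfig(
        n_schools_dm=d.get("n_schools_dm", 22),
        n_schools_sc=d.get("n_schools_sc", 24),
        group_sizes={_parse_cell(k): int(v) for k, v in d["group_sizes"].items()},
        outcomes=outcomes,
        covariates=CovariateModel(**d.get("covariates", {})),
        missingness=MissingnessParams(
            **{**d.get("missingness", {}),
               "entry_probs": tuple(d.get("missingness", {}).get(
                   "entry_probs", MissingnessParams().entry_probs))}),
        seed=d.get("seed", 0),
    )


def save_config(cfg: SimConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


def load_config(path: str | Path) -> SimConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# generation

COVARIATE_COLS = ("race_ethnicity", "age", "survey_date", "guardianship",
                  "witness_violence")

#: Covariate zero points for downstream adjustment: sample-mean age, study
#: start date, majority/reference categories.
DEFAULT_ZERO_POINTS = {
    "race_ethnicity": "black_nh",
    "age": 11.93,
    "survey_date": 0.0,
    "guardianship": "two_parent",
    "witness_violence": 0.0,
}


def _assign_students(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    arm_schools = {
        "SC": [f"SC{i:02d}" for i in range(1, cfg.n_schools_sc + 1)],
        "DM": [f"DM{i:02d}" for i in range(1, cfg.n_schools_dm + 1)],
    }
    counters = {"SC": 0, "DM": 0}
    sid = 0
    for cell in GROUPS:
        n = cfg.group_sizes.get(cell, 0)
        cond, sex, cohort = cell
        for _ in range(n):
            school = arm_schools[cond][counters[cond] % len(arm_schools[cond])]
            counters[cond] += 1
            rows.append({"student_id": sid, "school_id": school,
                         "condition": cond, "sex": sex, "cohort": cohort})
            sid += 1
    return pd.DataFrame(rows)


def _draw_covariates(students: pd.DataFrame, cov: CovariateModel,
                     rng: np.random.Generator) -> pd.DataFrame:
    n = len(students)
    out = students.copy()
    races = list(cov.race_probs)
    out["race_ethnicity"] = rng.choice(races, size=n, p=[cov.race_probs[r] for r in races])
    guards = list(cov.guardianship_probs)
    out["guardianship"] = rng.choice(
        guards, size=n, p=[cov.guardianship_probs[g] for g in guards])
    out["age"] = rng.normal(cov.age_mean, cov.age_sd, size=n)
    out["witness_violence"] = (rng.random(n) < cov.witness_p).astype(int)
    return out


def generate_trial(config: SimConfig, keep_complete: bool = False,
                   keep_latent: bool = False):
    """Generate a masked long-format trial table.

    With ``keep_complete`` the pre-mask table is returned alongside; with
    ``keep_latent`` (requires ``keep_complete``) a dict of per-outcome
    latent propensity matrices (students x waves, before item noise) is
    appended — used to verify the variance decomposition directly.

    The single seed is consumed in a fixed order — school assignment,
    covariates, then per outcome (in config order) school/person/wave/item
    effects, then missingness — so identical configs give byte-identical
    tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    students = _assign_students(config, rng)
    students = _draw_covariates(students, config.covariates, rng)
    n_students = len(students)

    # long skeleton: student x wave
    long = students.loc[students.index.repeat(N_WAVES)].reset_index(drop=True)
    long["wave"] = np.tile(np.arange(N_WAVES), n_students)
    cohort_shift = np.where(long["cohort"] == 4, 365, 0)
    long["survey_date"] = (cohort_shift + long["wave"] * 182
                           + rng.normal(0, config.covariates.date_jitter_sd,
                                        len(long))).round(0)

    cov = config.covariates
    cov_effect = (cov.witness_beta * (students["witness_violence"] - cov.witness_p)
                  + cov.age_beta * (students["age"] - cov.age_mean)).to_numpy()
    noise_sd = float(np.sqrt(1.0 + cov.effect_variance))

    group_of = np.array([GROUPS.index((r.condition, r.sex, r.cohort))
                         for r in students.itertuples()])
    schools = students["school_id"].to_numpy()
    school_list = pd.unique(schools)
    school_idx = pd.Series(np.arange(len(school_list)), index=school_list)[schools].to_numpy()

    latents: dict[str, np.ndarray] = {}
    for name, params in config.outcomes.items():
        # latent locations per (cell, wave), matching the target POMS means
        delta = np.empty((len(GROUPS), N_WAVES))
        for gi, cell in enumerate(GROUPS):
            for t in range(N_WAVES):
                target = max(params.trajectories[cell][t], params.min_mean)
                delta[gi, t] = invert_poms_mean(target, params.thresholds, noise_sd)
        u_school = rng.normal(0, np.sqrt(params.school_icc), len(school_list))
        a_person = rng.normal(0, np.sqrt(params.person_share), n_students)
        w_wave = rng.normal(0, np.sqrt(params.wave_share), (n_students, N_WAVES))
        base = (delta[group_of][:, :]  # (students, waves)
                + u_school[school_idx][:, None]
                + a_person[:, None]
                + cov_effect[:, None]
                + w_wave)
        if keep_latent:
            latents[name] = base.copy()
        item_sd = np.sqrt(params.item_share)
        for j, col in enumerate(item_columns(name, params.n_items)):
            latent = base + rng.normal(0, item_sd, base.shape)
            long[col] = latent_to_ordinal(latent, params.thresholds).ravel().astype(float)

    complete = long.copy()

    # masking: every probability depends only on design and covariates
    mp = config.missingness
    entry = rng.choice(N_WAVES, size=n_students, p=np.asarray(mp.entry_probs))
    if mp.exit_hazard > 0:
        stay = rng.random((n_students, N_WAVES)) >= mp.exit_hazard
        extra = np.argmin(np.cumprod(stay, axis=1), axis=1)
        extra = np.where(np.all(stay, axis=1), N_WAVES, extra)
        exit_wave = np.minimum(entry + extra, N_WAVES - 1)
    else:
        exit_wave = np.full(n_students, N_WAVES - 1)
    if mp.nonresponse_base > 0:
        logit0 = np.log(mp.nonresponse_base / (1 - mp.nonresponse_base))
        lin = (logit0
               + mp.nonresponse_witness * students["witness_violence"].to_numpy()
               + mp.nonresponse_age * (students["age"].to_numpy() - cov.age_mean))
        p_nr = 1 / (1 + np.exp(-lin))
        nonresp = rng.random((n_students, N_WAVES)) < p_nr[:, None]
    else:
        nonresp = np.zeros((n_students, N_WAVES), dtype=bool)
    waves = np.tile(np.arange(N_WAVES), n_students)
    ent = np.repeat(entry, N_WAVES)
    ext = np.repeat(exit_wave, N_WAVES)
    absent = (waves < ent) | (waves > ext) | nonresp.ravel()

    all_items = [c for name, p in config.outcomes.items()
                 for c in item_columns(name, p.n_items)]
    long.loc[absent, all_items] = np.nan
    if mp.item_rate > 0:
        spot = rng.random((len(long), len(all_items))) < mp.item_rate
        vals = long[all_items].to_numpy()
        vals[spot] = np.nan
        long[all_items] = vals

    if keep_complete and keep_latent:
        return long, complete, latents
    if keep_complete:
        return long, complete
    return long


def synthesize_outcome_grid(cell_means: np.ndarray, n_per_cell: int, sd: float,
                            seed: int, labels=None):
    """Gaussian outcome grid with the given true cell means.

    Generates adjusted-outcome-scale data directly (independent waves,
    common residual SD) — the workhorse for constraint-search recovery
    experiments where the ordinal layer is irrelevant.
    """
    from .outcome_prep import OutcomeGrid

    cell_means = np.asarray(cell_means, dtype=float)
    G, T = cell_means.shape
    rng = np.random.default_rng(seed)
    data = tuple(cell_means[g] + rng.normal(0, sd, (n_per_cell, T))
                 for g in range(G))
    labels = tuple(labels) if labels is not None else tuple(range(G))
    return OutcomeGrid(outcome="synthetic", labels=labels, data=data)


# ---------------------------------------------------------------------------
# calibration report

def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha of an (n x k) item matrix (complete rows only)."""
    items = np.asarray(items, dtype=float)
    items = items[~np.isnan(items).any(axis=1)]
    n, k = items.shape
    if k < 2 or n < 3:
        return float("nan")
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return float("nan")
    return float(k / (k - 1) * (1 - items.var(axis=0, ddof=1).sum() / total_var))


def calibration_report(table: pd.DataFrame,
                       item_counts: dict | None = None) -> dict:
    """Summary used to check the generator against its observed-data anchors.

    Per outcome: lifetime prevalence of any endorsement (any observed
    response above 'never', among students with any observed response) and
    per-wave Cronbach's alpha (NaN for single-item outcomes or all-missing
    waves); plus per-wave and overall missingness of the item cells.
    """
    item_counts = dict(ITEM_COUNTS) if item_counts is None else item_counts
    report: dict = {"prevalence": {}, "alpha": {}, "missingness": {}}
    all_cols: list[str] = []
    for name, k in item_counts.items():
        cols = [c for c in item_columns(name, k) if c in table.columns]
        if not cols:
            continue
        all_cols += cols
        vals = table[cols]
        endorsed = (vals > ORDINAL_MIN).any(axis=1)
        seen = vals.notna().any(axis=1)
        per_student = pd.DataFrame({
            "student_id": table["student_id"], "endorsed": endorsed, "seen": seen,
        }).groupby("student_id").any()
        denom = per_student["seen"].sum()
        report["prevalence"][name] = (
            float(per_student["endorsed"].sum() / denom) if denom else float("nan"))
        if len(cols) >= 2:
            report["alpha"][name] = {
                int(w): cronbach_alpha(sub[cols].to_numpy())
                for w, sub in table.groupby("wave")
            }
        else:
            report["alpha"][name] = None
    miss = table[all_cols].isna()
    report["missingness"]["per_wave"] = {
        int(w): float(miss.loc[idx].to_numpy().mean())
        for w, idx in table.groupby("wave").groups.items()}
    report["missingness"]["overall"] = float(miss.to_numpy().mean())
    return report
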