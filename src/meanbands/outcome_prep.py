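"""Outcome preparation: composites, POMS rescaling, covariate adjustment.

Each completed (imputed) dataset is turned into analysis-ready outcomes in
three steps, mirroring the trial's pre-analysis strategy:

1. item responses (ordinal 1-4) are averaged into a composite per outcome;
2. the composite is rescaled to POMS — percent of the *possible* maximum,
   0 for "lowest category on every item" through 100 for the highest;
3. per wave, the POMS outcome is regressed on covariates (with meaningful
   zero points) plus school terms, and the intercept-anchored, outlier-
   corrected residual becomes the adjusted outcome.

School indicators are centered within each trial arm before entering the
regression. Schools are nested in condition, so raw school dummies could
absorb the treatment contrast; centering within arm makes every school
column orthogonal to the condition indicator, and the arm difference
passes through the adjustment untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import GROUPS, N_WAVES, ORDINAL_MAX, ORDINAL_MIN

#: Two-sided p < .001 under normality; the default outlier-correction bound.
DEFAULT_WINSOR_Z = 3.29


def composite(items) -> float:
    """Item-average composite of ordinal responses (non-missing values)."""
    arr = np.asarray(items, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("composite requires at least one non-missing item")
    return float(arr.mean())


def poms(raw, min_cat: float = ORDINAL_MIN, max_cat: float = ORDINAL_MAX):
    """Percent-of-maximum rescaling: 100 (raw - min) / (max - min).

    ``raw`` may be a scalar or array on the original response metric. Values
    outside [min_cat, max_cat] indicate an upstream bug and raise.
    """
    if not min_cat < max_cat:
        raise ValueError("min_cat must be below max_cat")
    arr = np.asarray(raw, dtype=float)
    if np.any((arr < min_cat) | (arr > max_cat)):
        raise ValueError(f"raw scores outside [{min_cat}, {max_cat}]")
    out = 100.0 * (arr - min_cat) / (max_cat - min_cat)
    return float(out) if np.isscalar(raw) else out


def winsorize(residuals, z: float = DEFAULT_WINSOR_Z) -> np.ndarray:
    """Clamp values beyond mean +/- z SD to the boundary.

    Both moments come from the *original* vector, so a single pass fully
    determines the correction. A zero-SD vector is returned unchanged.
    """
    if z <= 0:
        raise ValueError("z must be positive")
    arr = np.asarray(residuals, dtype=float)
    mu = arr.mean()
    sd = arr.std(ddof=1) if arr.size > 1 else 0.0
    if sd == 0:
        return arr.copy()
    return np.clip(arr, mu - z * sd, mu + z * sd)


def _encode_covariates(covariates: pd.DataFrame, zero_points: dict) -> np.ndarray:
    """Design columns for the covariates, zeroed at their meaningful origins.

    Continuous covariates are shifted by their zero point; categorical
    covariates become dummies with the zero-point category as reference.
    Every covariate must have a zero point so the adjusted scores keep an
    interpretable POMS origin.
    """
    cols = []
    for name in covariates.columns:
        if name not in zero_points:
            raise ValueError(f"no zero point supplied for covariate {name!r}")
        col = covariates[name]
        zp = zero_points[name]
        if pd.api.types.is_numeric_dtype(col) and not isinstance(zp, str):
            cols.append(np.asarray(col, dtype=float) - float(zp))
        else:
            levels = [lv for lv in pd.unique(col) if lv != zp]
            if zp not in set(pd.unique(col)) and len(levels) == col.nunique():
                raise ValueError(
                    f"zero-point category {zp!r} absent from covariate {name!r}")
            for lv in sorted(map(str, levels)):
                cols.append((col.astype(str) == lv).to_numpy(dtype=float))
    if not cols:
        return np.empty((len(covariates), 0))
    return np.column_stack(cols)


def _school_terms(school_ids: np.ndarray, conditions: np.ndarray) -> np.ndarray:
    """School indicator columns centered within their trial arm.

    For a school s in arm a, the column is 1[school = s] - share_a(s) on
    arm-a rows and 0 elsewhere; one school per arm is dropped (the centered
    dummies of an arm sum to zero). Each column then has zero mean within
    both arms, hence zero covariance with the condition contrast.
    """
    cols = []
    for arm in np.unique(conditions):
        in_arm = conditions == arm
        schools = np.unique(school_ids[in_arm])
        for s in schools[:-1]:
            col = np.zeros(len(school_ids))
            ind = (school_ids == s).astype(float)
            col[in_arm] = ind[in_arm] - ind[in_arm].mean()
            cols.append(col)
    return np.column_stack(cols) if cols else np.empty((len(school_ids), 0))


def covariate_adjust(outcomes, covariates: pd.DataFrame, school_ids,
                     conditions, zero_points: dict,
                     winsor_z: float | None = DEFAULT_WINSOR_Z) -> np.ndarray:
    """Covariate- and school-adjusted outcomes for one wave.

    Fits OLS of the POMS outcome on encoded covariates plus within-arm-
    centered school terms (condition itself is never a predictor), then
    returns ``intercept + winsorized residual`` so the adjusted score sits
    on the POMS scale at the covariate zero points. Raises if the design
    would absorb the condition contrast.
    """
    y = np.asarray(outcomes, dtype=float)
    school_ids = np.asarray(school_ids)
    conditions = np.asarray(conditions)
    X = np.column_stack([
        np.ones(len(y)),
        _encode_covariates(covariates, zero_points),
        _school_terms(school_ids, conditions),
    ])

    # guard: the condition contrast must not lie in the span of the design
    arm = (conditions == conditions[0]).astype(float)
    coef_a, res_a, *_ = np.linalg.lstsq(X, arm, rcond=None)
    arm_resid = arm - X @ coef_a
    if arm_resid @ arm_resid < 1e-8 * max(arm.var() * len(arm), 1e-12):
        raise ValueError(
            "covariate/school encoding absorbs the treatment contrast; "
            "check that school terms are centered within arm")

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    if winsor_z is not None:
        resid = winsorize(resid, winsor_z)
    return beta[0] + resid


@dataclass(frozen=True)
class OutcomeGrid:
    """Adjusted POMS outcomes per design cell: one (students x waves) matrix each.

    ``labels`` fixes the group order; for full trial data it is the
    canonical 8-cell order of :data:`meanbands.design.GROUPS`, but any
    subset or synthetic grouping works (the mean-structure fitter only
    needs the matrices).
    """

    outcome: str
    labels: tuple
    data: tuple  # tuple of (n_g x T) float arrays

    def __post_init__(self):
        data = tuple(np.asarray(a, dtype=float) for a in self.data)
        if len(data) != len(self.labels):
            raise ValueError("one data matrix per label required")
        T = data[0].shape[1]
        for a in data:
            if a.ndim != 2 or a.shape[1] != T:
                raise ValueError("all groups must share the same wave count")
            if np.isnan(a).any():
                raise ValueError("OutcomeGrid requires complete data (impute first)")
        object.__setattr__(self, "data", data)

    @property
    def n_waves(self) -> int:
        return self.data[0].shape[1]

    @property
    def n_groups(self) -> int:
        return len(self.labels)

    def n_per_group(self) -> np.ndarray:
        return np.array([a.shape[0] for a in self.data])

    def group_means(self) -> np.ndarray:
        return np.stack([a.mean(axis=0) for a in self.data])

    def group_covariances(self) -> np.ndarray:
        """ML (divide-by-n) covariance per group."""
        return np.stack([np.cov(a.T, ddof=0) for a in self.data])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, a in zip(self.labels, self.data):
            for i in range(a.shape[0]):
                for t in range(a.shape[1]):
                    rows.append({"group": str(label), "student": i, "wave": t,
                                 "value": a[i, t]})
        return pd.DataFrame(rows)


def item_columns(outcome: str, n_items: int) -> list[str]:
    """Column names used for an outcome's ordinal items in a trial table."""
    return [f"{outcome}_i{j}" for j in range(1, n_items + 1)]


def prepare_outcome_grid(table: pd.DataFrame, outcome: str, n_items: int,
                         covariate_cols: list[str], zero_points: dict,
                         winsor_z: float | None = DEFAULT_WINSOR_Z,
                         adjust: bool = True) -> OutcomeGrid:
    """Composite -> POMS -> per-wave covariate adjustment -> OutcomeGrid.

    ``table`` is one *completed* long-format trial table (student x wave
    rows, no missing analysis values).
    """
    cols = item_columns(outcome, n_items)
    df = table.copy()
    raw = df[cols].mean(axis=1)
    df["_poms"] = poms(raw.to_numpy())
    if adjust:
        adjusted = np.empty(len(df))
        for wave, idx in df.groupby("wave").groups.items():
            sub = df.loc[idx]
            adjusted[df.index.get_indexer(idx)] = covariate_adjust(
                sub["_poms"], sub[covariate_cols], sub["school_id"],
                sub["condition"], zero_points, winsor_z=winsor_z)
        df["_adj"] = adjusted
    else:
        df["_adj"] = df["_poms"]

    wide = df.pivot_table(index=["condition", "sex", "cohort", "student_id"],
                          columns="wave", values="_adj")
    if wide.isna().any().any():
        raise ValueError("incomplete student x wave coverage; impute first")
    mats, labels = [], []
    for cond, sex, cohort in GROUPS:
        try:
            block = wide.loc[(cond, sex, cohort)]
        except KeyError:
            continue
        labels.append((cond, sex, cohort))
        mats.append(block.to_numpy()[:, :N_WAVES])
    return OutcomeGrid(outcome=outcome, labels=tuple(labels), data=tuple(mats))
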