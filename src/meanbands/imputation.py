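"""Multiple imputation with principal-component auxiliary scores.

Missingness in the survey tables is treated as MAR and handled before any
modelling: the auxiliary information in the table (covariates, design
labels, and the item responses themselves) is compressed into a handful of
principal-component scores, which then feed a chained normal-model
imputation. Draws are *proper* — each imputed value reflects both residual
noise and parameter uncertainty — so Rubin's rules give valid pooled
variances. Ordinal items are imputed on the continuous scale and rounded
and clamped back to the 1-4 response range.

Also here: Rubin's rules for scalar estimates (with Barnard-Rubin
small-sample degrees of freedom) and the D2 combination of chi-square fit
statistics across imputations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .design import ORDINAL_MAX, ORDINAL_MIN

DESIGN_COLS = ("condition", "sex", "cohort", "wave")


def _numeric_block(table: pd.DataFrame, exclude: Sequence[str] = ()) -> pd.DataFrame:
    """Numeric encoding of every usable column.

    Strings and low-cardinality integer columns (design labels such as
    wave or cohort) become dummies; everything else enters linearly.
    """
    drop = set(exclude) | {"student_id", "school_id"}
    cols = {}
    for name in table.columns:
        if name in drop:
            continue
        col = table[name]
        as_dummies = not pd.api.types.is_numeric_dtype(col) or (
            pd.api.types.is_integer_dtype(col) and col.nunique() <= 8
            and col.nunique() > 2)
        if as_dummies:
            for lv in sorted(col.astype(str).unique())[1:]:
                cols[f"{name}_{lv}"] = (col.astype(str) == lv).astype(float)
        else:
            cols[name] = col.astype(float)
    return pd.DataFrame(cols, index=table.index)


def auxiliary_scores(table: pd.DataFrame, k: int,
                     exclude: Sequence[str] = ()) -> np.ndarray:
    """First k principal-component scores of the auxiliary block.

    The block is every encodable column of the table except ``exclude``,
    mean-filled where missing and standardized; constant columns are
    dropped. Scores are centered (zero column means). Asking for more
    components than the block's rank raises with the achievable rank in
    the message.

    When the scores feed an imputation model, ``exclude`` must contain the
    variables being imputed — otherwise their own (mean-filled) values
    leak into the scores and the imputation model degenerates to a perfect
    fit with no residual variance.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    block = _numeric_block(table, exclude=exclude)
    X = block.to_numpy(dtype=float)
    mu = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(mu, inds[1])
    sd = X.std(axis=0)
    keep = sd > 0
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    rank = np.linalg.matrix_rank(X)
    if k > rank:
        raise ValueError(f"requested {k} components but the auxiliary block has rank {rank}")
    scores = PCA(n_components=k, svd_solver="full").fit_transform(X)
    return scores


def _pmm_draw(yhat_obs: np.ndarray, yobs: np.ndarray, yhat_mis: np.ndarray,
              rng: np.random.Generator, n_donors: int = 5) -> np.ndarray:
    """Type-1 predictive-mean matching: each missing value takes the
    observed response of one of the ``n_donors`` cases whose predicted
    mean is closest to the (parameter-drawn) predicted mean of the
    missing case."""
    order = np.argsort(yhat_obs)
    sorted_hat = yhat_obs[order]
    nobs = len(yobs)
    d = min(n_donors, nobs)
    pos = np.searchsorted(sorted_hat, yhat_mis)
    # candidate window around the insertion point, clipped to the range
    offs = np.arange(-d, d)
    cand = np.clip(pos[:, None] + offs[None, :], 0, nobs - 1)
    dist = np.abs(sorted_hat[cand] - yhat_mis[:, None])
    nearest = np.argpartition(dist, d - 1, axis=1)[:, :d]
    pick = nearest[np.arange(len(yhat_mis)), rng.integers(0, d, len(yhat_mis))]
    return yobs[order[np.take_along_axis(cand, pick[:, None], axis=1).ravel()]]


@dataclass
class ImputationStack:
    """m completed copies of a trial table plus their provenance."""

    datasets: list[pd.DataFrame]
    m: int
    n_aux_components: int
    seed: int
    imputed_columns: tuple[str, ...]

    def __post_init__(self):
        if self.m != len(self.datasets):
            raise ValueError("m must equal the number of datasets")


def impute(table: pd.DataFrame, m: int, k: int, seed: int, *,
           columns: Sequence[str] | None = None,
           ordinal: Sequence[str] | None = None,
           n_cycles: int = 5, ordinal_method: str = "pmm") -> ImputationStack:
    """Chained proper normal-model imputation of the listed columns.

    Parameters
    ----------
    table
        Long-format trial table; ``columns`` defaults to every numeric
        column with missing values (excluding identifiers).
    m
        Number of completed datasets (>= 2).
    k
        Number of auxiliary principal-component scores in the predictor set.
    seed
        Governs all draws; same seed, same stack.
    columns, ordinal
        Which columns to impute, and which of those are 1-4 ordinal items.
        ``ordinal`` defaults to all imputed columns.
    n_cycles
        Chained-equation sweeps per dataset.
    ordinal_method
        How ordinal items are mapped back to the response scale:
        ``"pmm"`` (default) draws each missing value from the observed
        donors with the closest predicted means, which preserves the
        (highly skewed) marginal distribution; ``"round"`` rounds and
        clamps the continuous draw, which is simpler but inflates rare
        categories when most responses sit at the scale floor.
    """
    if ordinal_method not in ("pmm", "round"):
        raise ValueError("ordinal_method must be 'pmm' or 'round'")
    if m < 2:
        raise ValueError("multiple imputation needs m >= 2")
    if columns is None:
        columns = [c for c in table.columns
                   if c not in ("student_id", "school_id")
                   and pd.api.types.is_numeric_dtype(table[c])
                   and table[c].isna().any()]
    columns = list(columns)
    ordinal = set(columns if ordinal is None else ordinal)
    empty = [c for c in columns if table[c].notna().sum() == 0]
    if empty:
        raise ValueError(f"columns with no observed values cannot be imputed: {empty}")

    rng = np.random.default_rng(seed)
    miss = {c: table[c].isna().to_numpy() for c in columns}
    any_missing = any(v.any() for v in miss.values())

    if not any_missing:
        return ImputationStack([table.copy() for _ in range(m)], m, k, seed,
                               tuple(columns))

    scores = auxiliary_scores(table, k, exclude=columns)
    base_df = _numeric_block(table, exclude=columns)
    # saturated design-cell dummies: the downstream analysis models a free
    # mean per (condition, sex, cohort, wave) cell, so the imputation model
    # must be able to represent exactly that structure (congeniality)
    if all(c in table.columns for c in DESIGN_COLS):
        cell = (table["condition"].astype(str) + "|" + table["sex"].astype(str)
                + "|" + table["cohort"].astype(str) + "|" + table["wave"].astype(str))
        levels = sorted(cell.unique())
        for lv in levels[1:]:
            base_df[f"cell_{lv}"] = (cell == lv).astype(float)
    base = base_df.to_numpy(dtype=float)
    X_fixed = np.column_stack([np.ones(len(table)), base, scores])
    # drop collinear fixed columns once, via QR pivoting on the thin matrix
    q, r = np.linalg.qr(X_fixed)
    keep = np.abs(np.diag(r)) > 1e-10 * abs(r[0, 0])
    X_fixed = X_fixed[:, keep]

    datasets = []
    values0 = {c: table[c].to_numpy(dtype=float) for c in columns}
    for _ in range(m):
        vals = {c: v.copy() for c, v in values0.items()}
        # initialize missing entries from the observed distribution
        for c in columns:
            obs = vals[c][~miss[c]]
            if miss[c].any():
                vals[c][miss[c]] = rng.choice(obs, size=miss[c].sum(), replace=True)
        for _cycle in range(n_cycles):
            for c in columns:
                mask = miss[c]
                if not mask.any():
                    continue
                others = [o for o in columns if o != c]
                X = np.column_stack([X_fixed] + [vals[o] for o in others]) \
                    if others else X_fixed
                yobs, Xobs = vals[c][~mask], X[~mask]
                nobs, p = Xobs.shape
                XtX = Xobs.T @ Xobs + 1e-8 * np.eye(p)
                beta_hat = np.linalg.solve(XtX, Xobs.T @ yobs)
                resid = yobs - Xobs @ beta_hat
                dof = max(nobs - p, 1)
                sigma2 = (resid @ resid) / rng.chisquare(dof)
                cov = sigma2 * np.linalg.inv(XtX)
                beta = rng.multivariate_normal(beta_hat, cov, method="cholesky")
                if c in ordinal and ordinal_method == "pmm":
                    vals[c][mask] = _pmm_draw(Xobs @ beta_hat, yobs,
                                              X[mask] @ beta, rng)
                else:
                    vals[c][mask] = X[mask] @ beta + rng.normal(
                        0, np.sqrt(sigma2), size=mask.sum())
        done = table.copy()
        for c in columns:
            v = vals[c]
            if c in ordinal and ordinal_method == "round":
                v = np.clip(np.rint(v), ORDINAL_MIN, ORDINAL_MAX)
            done[c] = v
        datasets.append(done)
    return ImputationStack(datasets, m, k, seed, tuple(columns))


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules combination of an estimate across m imputations."""

    estimate: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))

    def confint(self, level: float = 0.95) -> tuple[float, float]:
        half = stats.t.ppf(0.5 + level / 2, self.df) * self.se if np.isfinite(self.df) \
            else stats.norm.ppf(0.5 + level / 2) * self.se
        return self.estimate - half, self.estimate + half


def rubin_pool(estimates: Sequence[float], variances: Sequence[float],
               df_com: float | None = None) -> PooledEstimate:
    """Pool per-imputation estimates and variances.

    Q-bar is the mean estimate, W the mean within variance, B the between
    variance, T = W + (1 + 1/m) B. Degrees of freedom follow Rubin's
    large-sample formula, or Barnard-Rubin when the complete-data df
    ``df_com`` is supplied.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = len(q)
    if m < 2:
        raise ValueError("between-imputation variance needs m >= 2")
    if len(u) != m or np.any(u < 0):
        raise ValueError("need one non-negative variance per estimate")
    qbar = q.mean()
    W = u.mean()
    B = q.var(ddof=1)
    T = W + (1 + 1 / m) * B
    if B == 0:
        df = np.inf
    else:
        lam = (1 + 1 / m) * B / T
        df = (m - 1) / lam**2
        if df_com is not None:
            df_obs = (df_com + 1) / (df_com + 3) * df_com * (1 - lam)
            df = 1 / (1 / df + 1 / df_obs)
    return PooledEstimate(float(qbar), float(W), float(B), float(T), float(df), m)


class PooledChisq(NamedTuple):
    statistic: float  # D2, on the F scale
    p: float
    mean_chisq: float  # naive average, reported for transparency
    df1: int
    df2: float


def pool_fit_statistics(chisqs: Sequence[float], df: int) -> PooledChisq:
    """D2 combination of chi-square statistics across imputations.

    The m statistics are averaged and recalibrated through their square
    roots (Li-Raghunathan-Rubin); the result refers to an F(df, df2)
    distribution. The naive mean chi-square is returned alongside.
    """
    x = np.asarray(chisqs, dtype=float)
    m = len(x)
    if m < 2:
        raise ValueError("pooling needs m >= 2 statistics")
    if np.any(x < 0):
        raise ValueError("chi-square statistics must be non-negative")
    if df == 0:
        if np.any(x > 0):
            raise ValueError("df = 0 with nonzero chi-square statistics")
        return PooledChisq(0.0, 1.0, 0.0, 0, np.inf)
    xbar = x.mean()
    r = (1 + 1 / m) * np.sqrt(x).var(ddof=1)
    D2 = (xbar / df - (m + 1) / (m - 1) * r) / (1 + r)
    D2 = max(D2, 0.0)
    if r == 0:
        # no between-imputation spread: F(df, inf) == chi-square/df
        return PooledChisq(float(D2), float(stats.chi2.sf(D2 * df, df)), float(xbar),
                           df, np.inf)
    df2 = df ** (-3 / m) * (m - 1) * (1 + 1 / r) ** 2
    return PooledChisq(float(D2), float(stats.f.sf(D2, df, df2)), float(xbar),
                       df, float(df2))
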