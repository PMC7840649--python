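"""Multiple-group mean-structure models with equality constraints.

The analysis model is deliberately minimal: for each design group *g* the
6-wave outcome vector is multivariate normal with an unconstrained
("saturated") covariance matrix and a mean vector whose entries are tied
across (group, wave) cells by a :class:`ConstraintScheme` — cells sharing
a rank share one mean parameter. Covariate adjustment happens upstream,
so the means are the only structured part of the model and constrained
solutions stay interpretationally comparable.

Fitting exploits that, for fixed means, the ML covariance has the closed
form ``Sigma_g = S_g + d_g d_g'`` (``S_g`` the group's ML sample
covariance, ``d_g`` the mean residual). Substituting it back profiles the
covariances out of the likelihood, leaving the rank means to minimize
``sum_g n_g log(1 + d_g' S_g^-1 d_g)``; a damped Newton iteration with
analytic gradient and Hessian solves that in a handful of steps (the
fixed point coincides with the classical alternating GLS-mean /
covariance-update scheme, which converges only linearly). The model
chi-square is the likelihood-ratio statistic against the saturated-means
model; RMSEA and SRMR use multiple-group conventions; rank separation is
tested with signed Wald z statistics from the inverse information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats


class ConvergenceError(RuntimeError):
    """Raised when the alternating ML fit fails to converge; carries the trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


def _canonical_ranks(ranks: np.ndarray) -> np.ndarray:
    """Relabel ranks to 1..R in order of first appearance (row-major)."""
    out = np.zeros_like(ranks)
    mapping: dict[int, int] = {}
    for idx, r in enumerate(ranks.ravel()):
        if r not in mapping:
            mapping[r] = len(mapping) + 1
        out.ravel()[idx] = mapping[r]
    return out


@dataclass(frozen=True)
class ConstraintScheme:
    """Assignment of each (group, wave) cell to a shared-mean rank.

    ``ranks`` is a (G, T) integer array with contiguous values 1..R; cells
    with equal rank are constrained to a common mean. Two schemes are
    compared as partitions of the cell set, so the labelling itself is
    canonicalized to first-appearance order.
    """

    ranks: np.ndarray

    def __post_init__(self):
        ranks = np.asarray(self.ranks, dtype=int)
        if ranks.ndim != 2:
            raise ValueError("ranks must be a (groups x waves) array")
        labels = np.unique(ranks)
        if labels.min() != 1 or labels.max() != len(labels):
            ranks = _canonical_ranks(ranks)
        else:
            ranks = _canonical_ranks(ranks)  # normalize label order too
        ranks.setflags(write=False)
        object.__setattr__(self, "ranks", ranks)

    @classmethod
    def saturated(cls, n_groups: int, n_waves: int) -> "ConstraintScheme":
        return cls(np.arange(1, n_groups * n_waves + 1).reshape(n_groups, n_waves))

    @classmethod
    def from_values(cls, values: np.ndarray, tol: float = 0.0) -> "ConstraintScheme":
        """Build the scheme whose bands are the distinct values of a grid.

        Values closer than ``tol`` are merged (single linkage on the
        sorted values), which turns a printed mean grid into its implied
        constraint scheme.
        """
        values = np.asarray(values, dtype=float)
        flat = values.ravel()
        order = np.argsort(flat, kind="stable")
        band = np.zeros(flat.size, dtype=int)
        current = 1
        band[order[0]] = current
        for prev, nxt in zip(order[:-1], order[1:]):
            if flat[nxt] - flat[prev] > tol:
                current += 1
            band[nxt] = current
        return cls(band.reshape(values.shape))

    @property
    def n_groups(self) -> int:
        return self.ranks.shape[0]

    @property
    def n_waves(self) -> int:
        return self.ranks.shape[1]

    @property
    def n_ranks(self) -> int:
        return int(self.ranks.max())

    @property
    def df(self) -> int:
        """Constrained-away mean parameters: cells minus free means."""
        return self.ranks.size - self.n_ranks

    def partition(self) -> frozenset:
        cells = [tuple(zip(*np.nonzero(self.ranks == r))) for r in range(1, self.n_ranks + 1)]
        return frozenset(frozenset(c) for c in cells)

    def same_partition(self, other: "ConstraintScheme") -> bool:
        return self.partition() == other.partition()

    def coarsens(self, other: "ConstraintScheme") -> bool:
        """True if every block of ``other`` lies inside one block of self.

        A coarser scheme has fewer free means and is the *nested* model in
        a likelihood-ratio comparison.
        """
        if self.ranks.shape != other.ranks.shape:
            return False
        # other's blocks must refine self's: cells sharing a rank in other
        # must share a rank in self.
        for r in range(1, other.n_ranks + 1):
            mask = other.ranks == r
            if len(np.unique(self.ranks[mask])) > 1:
                return False
        return True

    def merge(self, r: int, s: int) -> "ConstraintScheme":
        """Scheme with ranks r and s tied to one mean."""
        ranks = np.array(self.ranks)
        ranks[ranks == max(r, s)] = min(r, s)
        return ConstraintScheme(ranks)

    def design_matrix(self) -> np.ndarray:
        """(G*T) x R indicator matrix A with mu = A m."""
        flat = self.ranks.ravel()
        A = np.zeros((flat.size, self.n_ranks))
        A[np.arange(flat.size), flat - 1] = 1.0
        return A

    def relabelled_by(self, values: Sequence[float]) -> "ConstraintScheme":
        """Relabel so rank 1 has the smallest value (table convention)."""
        order = np.argsort(np.asarray(values))
        new_label = np.empty(self.n_ranks, dtype=int)
        new_label[order] = np.arange(1, self.n_ranks + 1)
        return ConstraintScheme(new_label[self.ranks - 1])


@dataclass
class MeanModelFit:
    """Result of a constrained-means maximum-likelihood fit."""

    scheme: ConstraintScheme
    rank_means: np.ndarray  # (R,)
    rank_mean_cov: np.ndarray  # (R, R), inverse information
    group_covariances: np.ndarray  # (G, T, T)
    loglik: float
    loglik_saturated: float
    chisq: float
    df: int
    n_per_group: np.ndarray
    n_iter: int
    converged: bool
    trace: list[float] = field(default_factory=list, repr=False)

    @property
    def n_total(self) -> int:
        return int(self.n_per_group.sum())

    @property
    def n_groups(self) -> int:
        return self.scheme.n_groups

    def cell_means(self) -> np.ndarray:
        """Model-estimated mean for every (group, wave) cell."""
        return self.rank_means[self.scheme.ranks - 1]

    def rank_order_by_mean(self) -> "MeanModelFit":
        """Relabel ranks in ascending mean order, permuting estimates to match."""
        order = np.argsort(self.rank_means)
        scheme = self.scheme.relabelled_by(self.rank_means)
        return MeanModelFit(
            scheme=scheme,
            rank_means=self.rank_means[order],
            rank_mean_cov=self.rank_mean_cov[np.ix_(order, order)],
            group_covariances=self.group_covariances,
            loglik=self.loglik,
            loglik_saturated=self.loglik_saturated,
            chisq=self.chisq,
            df=self.df,
            n_per_group=self.n_per_group,
            n_iter=self.n_iter,
            converged=self.converged,
            trace=self.trace,
        )


def _suffstats(grid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-group (n, mean vector, ML covariance) from an OutcomeGrid."""
    n = grid.n_per_group()
    ybar = grid.group_means()
    S = grid.group_covariances()
    return n, ybar, S


def profile_loglik(m: np.ndarray, scheme: ConstraintScheme,
                   n: np.ndarray, ybar: np.ndarray, S: np.ndarray) -> float:
    """Log-likelihood at rank means ``m`` with covariances profiled out.

    For fixed means the ML covariance is ``S_g + d_g d_g'``; substituting
    it back gives a function of the means alone, which both the production
    fit and the brute-force oracle in the tests maximize.
    """
    G, T = scheme.ranks.shape
    mu = np.asarray(m)[scheme.ranks - 1]
    total = 0.0
    for g in range(G):
        d = ybar[g] - mu[g]
        sign, logdet = np.linalg.slogdet(S[g] + np.outer(d, d))
        if sign <= 0:
            return -np.inf
        total += -0.5 * n[g] * (T * np.log(2 * np.pi) + logdet + T)
    return float(total)


def fit_constrained(grid, scheme: ConstraintScheme, *, covariance: str = "saturated",
                    tol: float = 1e-8, max_iter: int = 500) -> MeanModelFit:
    """ML fit of the constrained-means multiple-group normal model.

    Parameters
    ----------
    grid
        An :class:`~meanbands.outcome_prep.OutcomeGrid` (complete data).
    scheme
        Equality-constraint scheme over the (group, wave) cells.
    covariance
        ``"saturated"`` (default) estimates a free covariance matrix per
        group; ``"spherical"`` forces ``sigma^2 I`` per group (used for
        closed-form checks).
    tol
        Relative log-likelihood change declaring convergence.
    max_iter
        Iteration cap; exceeding it raises :class:`ConvergenceError`.
    """
    if covariance not in ("saturated", "spherical"):
        raise ValueError(f"unknown covariance structure {covariance!r}")
    n, ybar, S = _suffstats(grid)
    G, T = scheme.ranks.shape
    if len(n) != G:
        raise ValueError(f"scheme has {G} groups but grid has {len(n)}")
    if covariance == "saturated" and np.any(n <= T):
        raise ValueError("each group needs n > number of waves for a saturated covariance")
    for g in range(G):
        if covariance == "saturated" and np.linalg.matrix_rank(S[g]) < T:
            raise np.linalg.LinAlgError(f"singular sample covariance in group {g}")

    A = scheme.design_matrix()
    R = scheme.n_ranks
    blocks = A.reshape(G, T, R)

    # Profiled objective: f(m) = sum_g n_g k_g log(c_g + d_g' M_g d_g) with
    #   saturated:  k = 1, c = 1,        M = S^-1
    #   spherical:  k = T, c = trace(S), M = I
    # and loglik = ll_sat - 0.5 * sum_g n_g k_g log(1 + q_g / c_g).
    if covariance == "saturated":
        M = np.stack([np.linalg.inv(S[g]) for g in range(G)])
        k = np.ones(G)
        c = np.ones(G)
    else:
        M = np.stack([np.eye(T)] * G)
        k = np.full(G, float(T))
        c = np.array([np.trace(S[g]) for g in range(G)])
    AtMA = np.stack([blocks[g].T @ M[g] @ blocks[g] for g in range(G)])

    def deviance(m):
        mu = m[scheme.ranks - 1]
        d = ybar - mu
        q = np.einsum("gi,gij,gj->g", d, M, d)
        return float(np.sum(n * k * np.log1p(q / c))), d, q

    def grad_hess(d, q):
        grad = np.zeros(R)
        H = np.zeros((R, R))
        Hpos = np.zeros((R, R))  # Gauss-Newton part, always positive definite
        for g in range(G):
            u = blocks[g].T @ (M[g] @ d[g])
            w = n[g] * k[g] / (c[g] + q[g])
            grad += -2.0 * w * u
            Hpos += 2.0 * w * AtMA[g]
            H += 2.0 * w * AtMA[g] - 4.0 * w / (c[g] + q[g]) * np.outer(u, u)
        return grad, H, Hpos

    # Two starts guard against local optima of the profiled likelihood
    # (log(1 + q) flattens for far-away groups): the S-weighted GLS
    # solution and the n-weighted projection of the raw cell means.
    info0 = np.einsum("g,gij->ij", n.astype(float), AtMA)
    rhs0 = np.zeros(R)
    for g in range(G):
        rhs0 += n[g] * blocks[g].T @ (M[g] @ ybar[g])
    start_gls = np.linalg.solve(info0, rhs0)
    wts = np.repeat(n, T).astype(float)
    start_proj = np.linalg.lstsq(A * np.sqrt(wts)[:, None],
                                 ybar.ravel() * np.sqrt(wts), rcond=None)[0]
    starts = [start_gls]
    if not np.allclose(start_proj, start_gls, atol=1e-10):
        starts.append(start_proj)
    m = min(starts, key=lambda s: deviance(s)[0])

    f, d, q = deviance(m)
    trace = [f]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad, H, Hpos = grad_hess(d, q)
        step = None
        try:
            cand = np.linalg.solve(H, -grad)
            if grad @ cand < 0:  # Newton direction, only if descent
                step = cand
        except np.linalg.LinAlgError:
            pass
        if step is None:  # Gauss-Newton fallback: guaranteed descent
            step = np.linalg.solve(Hpos, -grad)
        slope = grad @ step
        alpha, ok = 1.0, False
        while alpha >= 1e-12:  # Armijo backtracking on the deviance
            f_new, d_new, q_new = deviance(m + alpha * step)
            if f_new <= f + 1e-4 * alpha * slope:
                ok = True
                break
            alpha *= 0.5
        if not ok:  # no admissible step: gradient numerically zero
            converged = bool(np.linalg.norm(grad) <= 1e-6 * (abs(f) + 1.0))
            break
        m = m + alpha * step
        done = abs(f - f_new) <= tol * (abs(f) + 1e-12)
        f, d, q = f_new, d_new, q_new
        trace.append(f)
        if done:
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"no convergence in {max_iter} iterations", trace)

    mu = m[scheme.ranks - 1]
    if covariance == "saturated":
        Sigma = np.stack([S[g] + np.outer(d[g], d[g]) for g in range(G)])
    else:
        Sigma = np.stack([((c[g] + q[g]) / T) * np.eye(T) for g in range(G)])

    # observed information of the rank means at the optimum
    info = np.zeros((R, R))
    for g in range(G):
        W = n[g] * np.linalg.inv(Sigma[g])
        info += blocks[g].T @ W @ blocks[g]
    rank_mean_cov = np.linalg.inv(info)

    ll_sat = 0.0
    for g in range(G):
        if covariance == "saturated":
            sign, logdet = np.linalg.slogdet(S[g])
            ll_sat += -0.5 * n[g] * (T * np.log(2 * np.pi) + logdet + T)
        else:
            s2 = np.trace(S[g]) / T
            ll_sat += -0.5 * n[g] * (T * np.log(2 * np.pi) + T * np.log(s2) + T)
    chisq = max(float(f), 0.0)  # deviance vs saturated means
    ll = float(ll_sat) - 0.5 * chisq

    return MeanModelFit(
        scheme=scheme,
        rank_means=m,
        rank_mean_cov=rank_mean_cov,
        group_covariances=Sigma,
        loglik=ll,
        loglik_saturated=float(ll_sat),
        chisq=float(chisq),
        df=scheme.df,
        n_per_group=np.asarray(n),
        n_iter=it,
        converged=converged,
        trace=trace,
    )


def chisq_pvalue(stat: float, df: int) -> float:
    """Upper-tail chi-square probability; the difference-test p value."""
    if stat < 0:
        raise ValueError("chi-square statistic must be non-negative")
    if df == 0:
        if stat == 0:
            return 1.0
        raise ValueError("df = 0 is only defined for a zero statistic")
    return float(stats.chi2.sf(stat, df))


def chisq_diff(nested: MeanModelFit, parent: MeanModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio difference test of a coarser scheme against its parent."""
    if not nested.scheme.coarsens(parent.scheme):
        raise ValueError("difference test requires the first scheme to coarsen the second")
    stat = nested.chisq - parent.chisq
    if stat < -1e-6:
        raise ValueError(f"nested model fits better than parent (diff {stat}); fits inconsistent")
    stat = max(stat, 0.0)
    df = nested.df - parent.df
    if df == 0:
        return stat, 0, 1.0 if stat < 1e-8 else chisq_pvalue(stat, df)
    return stat, df, chisq_pvalue(stat, df)


def rmsea(chisq: float, df: int, n_total: int, n_groups: int) -> float:
    """Multiple-group RMSEA: sqrt(max(chi2 - df, 0) / (df n)) * sqrt(G).

    By convention the saturated model (df = 0) reports 0.
    """
    if df == 0:
        return 0.0
    if n_total <= 1:
        raise ValueError("n_total must exceed 1")
    return float(np.sqrt(max(chisq - df, 0.0) / (df * n_total)) * np.sqrt(n_groups))


def srmr(fit: MeanModelFit, grid) -> float:
    """Standardized root-mean-square residual of the mean structure.

    With saturated group covariances the covariance residuals vanish
    identically, so only the mean residuals (observed cell mean minus
    model mean, standardized by the observed cell SD) enter the RMS.
    """
    n, ybar, S = _suffstats(grid)
    sd = np.sqrt(np.stack([np.diag(S[g]) for g in range(len(n))]))
    if np.any(sd <= 0):
        raise ValueError("zero observed SD in some cell; SRMR undefined")
    resid = (ybar - fit.cell_means()) / sd
    return float(np.sqrt(np.mean(resid**2)))


@dataclass(frozen=True)
class WaldResult:
    contrast: tuple[int, int]
    statistic: float
    p: float


def wald_separation(fit: MeanModelFit, r: int, s: int) -> WaldResult:
    """Signed Wald z test of rank separation: (m_r - m_s) / SE(m_r - m_s)."""
    if r == s:
        raise ValueError("contrast requires two distinct ranks")
    R = len(fit.rank_means)
    for k in (r, s):
        if not 1 <= k <= R:
            raise ValueError(f"rank {k} outside 1..{R}")
    i, j = r - 1, s - 1
    V = fit.rank_mean_cov
    var = V[i, i] + V[j, j] - 2 * V[i, j]
    if var <= 0:
        raise ValueError("non-positive variance for the rank contrast")
    z = (fit.rank_means[i] - fit.rank_means[j]) / np.sqrt(var)
    return WaldResult(contrast=(r, s), statistic=float(z), p=float(2 * stats.norm.sf(abs(z))))


def constraint_matrix(nested: ConstraintScheme, parent: ConstraintScheme) -> np.ndarray:
    """Rows expressing the extra equalities a nested scheme imposes on the
    parent's rank means (one row per constrained-away parameter)."""
    if not nested.coarsens(parent):
        raise ValueError("first scheme must coarsen the second")
    rows = []
    Rp = parent.n_ranks
    for b in range(1, nested.n_ranks + 1):
        members = np.unique(parent.ranks[nested.ranks == b])
        for a, c in zip(members[:-1], members[1:]):
            row = np.zeros(Rp)
            row[a - 1], row[c - 1] = 1.0, -1.0
            rows.append(row)
    return np.array(rows) if rows else np.empty((0, Rp))


def d1_constraint_test(fits: Sequence[MeanModelFit],
                       nested: ConstraintScheme) -> tuple[float, int, float, float]:
    """Pooled-parameter (D1) test of the equality constraints a nested
    scheme adds, combined across imputations.

    Returns ``(statistic, df1, df2, p)`` with an F(df1, df2) reference.
    Unlike chi-square (D2) pooling, D1 keeps its power when the fraction
    of missing information is large, so it is the default decision rule
    for the banding search on multiply imputed data.
    """
    parent = fits[0].scheme
    L = constraint_matrix(nested, parent)
    kk = L.shape[0]
    if kk == 0:
        return 0.0, 0, np.inf, 1.0
    m = len(fits)
    qs = np.stack([f.rank_means for f in fits])
    Ws = np.stack([f.rank_mean_cov for f in fits])
    d = L @ qs.mean(axis=0)
    W = L @ Ws.mean(axis=0) @ L.T
    if m > 1:
        B = L @ np.cov(qs.T, ddof=1).reshape(qs.shape[1], qs.shape[1]) @ L.T
        r1 = (1 + 1 / m) * np.trace(np.linalg.solve(W, B)) / kk
    else:
        r1 = 0.0
    D1 = float(d @ np.linalg.solve(W, d) / (kk * (1 + r1)))
    if r1 == 0:
        return D1, kk, np.inf, float(stats.chi2.sf(D1 * kk, kk))
    t = kk * (m - 1)
    if t > 4:
        df2 = 4 + (t - 4) * (1 + (1 - 2 / t) / r1) ** 2
    else:
        df2 = t * (1 + 1 / kk) * (1 + 1 / r1) ** 2 / 2
    return D1, kk, float(df2), float(stats.f.sf(D1, kk, df2))


@dataclass
class PooledMeanModel:
    """Rubin-pooled rank means/covariance and D2-pooled fit across imputations."""

    scheme: ConstraintScheme
    rank_means: np.ndarray
    rank_mean_cov: np.ndarray  # total covariance T = W + (1 + 1/m) B
    within_cov: np.ndarray
    between_cov: np.ndarray
    m: int
    chisq_mean: float
    df: int
    pooled_chisq_p: float
    n_per_group: np.ndarray

    def wald(self, r: int, s: int) -> WaldResult:
        proxy = MeanModelFit(
            scheme=self.scheme, rank_means=self.rank_means,
            rank_mean_cov=self.rank_mean_cov,
            group_covariances=np.empty(0), loglik=np.nan, loglik_saturated=np.nan,
            chisq=self.chisq_mean, df=self.df, n_per_group=self.n_per_group,
            n_iter=0, converged=True,
        )
        return wald_separation(proxy, r, s)


def pool_fits(fits: Sequence[MeanModelFit]) -> PooledMeanModel:
    """Combine per-imputation fits: Rubin's rules for the rank means and
    their covariance, D2 pooling for the model chi-square."""
    from .imputation import pool_fit_statistics  # local import avoids cycles

    if len(fits) < 1:
        raise ValueError("need at least one fit")
    scheme = fits[0].scheme
    for f in fits[1:]:
        if not f.scheme.same_partition(scheme):
            raise ValueError("all fits must share one constraint scheme")
    m = len(fits)
    means = np.stack([f.rank_means for f in fits])
    qbar = means.mean(axis=0)
    W = np.mean([f.rank_mean_cov for f in fits], axis=0)
    if m > 1:
        B = np.cov(means.T, ddof=1).reshape(len(qbar), len(qbar))
        total = W + (1 + 1 / m) * B
    else:
        B = np.zeros_like(W)
        total = W
    df = fits[0].df
    if df > 0 and m > 1:
        p = pool_fit_statistics([f.chisq for f in fits], df).p
    else:
        p = 1.0 if df == 0 else chisq_pvalue(fits[0].chisq, df)
    return PooledMeanModel(
        scheme=scheme, rank_means=qbar, rank_mean_cov=total,
        within_cov=W, between_cov=B, m=m,
        chisq_mean=float(np.mean([f.chisq for f in fits])),
        df=df, pooled_chisq_p=float(p), n_per_group=fits[0].n_per_group,
    )
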