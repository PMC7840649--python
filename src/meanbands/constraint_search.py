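"""Iterative banding search for an optimal constraint scheme.

The model-selection procedure mirrors the trial's analysis strategy:

1. fit the saturated-means model (every cell free);
2. impose baseline equivalence — all groups share one fall-6th-grade
   mean — and keep it if the chi-square difference test shows no
   significant decrement; on a violation, relax stepwise to baseline
   equivalence within sex, within cohort, then within sex x cohort;
3. repeatedly propose coarser schemes by merging free means that sit in
   the same "band" of magnitude (adjacent fitted means closer than a gap
   threshold), accepting a proposal only if (a) the difference test
   against the last accepted scheme is non-significant and (b) post hoc
   Wald tests separate all adjacent ranks of the proposal — adjacent
   ranks that fail to separate are merged and the merge re-tested;
4. stop when no merge is possible, a proposal is rejected, or the
   attempt cap (default five, after the published search budget) is hit.

The search is fully deterministic given the data grid and configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .design import GROUPS
from .mean_structure import (
    ConstraintScheme,
    MeanModelFit,
    PooledMeanModel,
    WaldResult,
    chisq_diff,
    chisq_pvalue,
    fit_constrained,
    pool_fits,
    wald_separation,
)

BASELINE_LEVELS = ("all", "within_sex", "within_cohort", "within_sex_and_cohort")


def baseline_scheme(groups=GROUPS, level: str = "all", n_waves: int = 6) -> ConstraintScheme:
    """Saturated scheme with wave-0 cells merged at the requested level.

    ``groups`` is the ordered list of (condition, sex, cohort) labels; only
    sex and cohort matter for the merge. ``level="all"`` ties all groups'
    baseline means (R = G*T - G + 1 for one shared baseline), the other
    levels tie baselines within sex, cohort, or sex x cohort.
    """
    if level not in BASELINE_LEVELS:
        raise ValueError(f"level must be one of {BASELINE_LEVELS}")
    G = len(groups)
    ranks = np.arange(1, G * n_waves + 1).reshape(G, n_waves)

    def key(label):
        _, sex, cohort = label
        if level == "all":
            return 0
        if level == "within_sex":
            return sex
        if level == "within_cohort":
            return cohort
        return (sex, cohort)

    for k in {key(g) for g in groups}:
        members = [i for i, g in enumerate(groups) if key(g) == k]
        for i in members[1:]:
            ranks[i, 0] = ranks[members[0], 0]
    return ConstraintScheme(ranks)


@dataclass(frozen=True)
class GapRule:
    """How free means are grouped into bands.

    ``threshold`` is an absolute POMS gap; ``mode="threshold"`` merges every
    run of sorted means whose adjacent gaps all fall below it (single
    linkage), ``mode="greedy"`` merges only the single smallest gap per
    proposal.
    """

    threshold: float = 0.5
    mode: str = "threshold"

    def __post_init__(self):
        if self.mode not in ("threshold", "greedy"):
            raise ValueError("mode must be 'threshold' or 'greedy'")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


def propose_bands(fit, gap_rule: GapRule = GapRule()) -> tuple[ConstraintScheme, bool]:
    """Coarser scheme merging rank means that fall in one magnitude band.

    ``fit`` is anything exposing ``rank_means`` and ``scheme`` (a single
    fit, a pooled model, or a fit bundle). Returns ``(scheme, changed)``;
    when no gap falls below the rule the current scheme comes back
    unchanged with ``changed=False``.
    """
    means = fit.rank_means
    R = len(means)
    if R == 1:
        return fit.scheme, False
    order = np.argsort(means)
    gaps = np.diff(means[order])
    band_of_sorted = np.zeros(R, dtype=int)
    if gap_rule.mode == "threshold":
        b = 0
        for i, gap in enumerate(gaps):
            if gap >= gap_rule.threshold:
                b += 1
            band_of_sorted[i + 1] = b
    else:  # greedy: merge only the smallest gap, if below threshold
        j = int(np.argmin(gaps))
        if gaps[j] >= gap_rule.threshold:
            return fit.scheme, False
        band_of_sorted[:] = np.arange(R)
        band_of_sorted[j + 1:] -= 1
    if band_of_sorted[-1] == R - 1:
        return fit.scheme, False
    band_of_rank = np.empty(R, dtype=int)
    band_of_rank[order] = band_of_sorted + 1
    return ConstraintScheme(band_of_rank[fit.scheme.ranks - 1]), True


def adjacent_walds(fit) -> list[WaldResult]:
    """Wald separation tests between consecutive ranks in mean order.

    ``fit`` may be a single :class:`MeanModelFit` or a Rubin-pooled
    :class:`PooledMeanModel`.
    """
    order = np.argsort(fit.rank_means)
    if isinstance(fit, PooledMeanModel):
        test = fit.wald
    else:
        test = lambda r, s: wald_separation(fit, r, s)
    return [test(int(order[i]) + 1, int(order[i + 1]) + 1)
            for i in range(len(order) - 1)]


@dataclass
class _Bundle:
    """A scheme fitted to one or all m imputed grids, with pooled views."""

    fits: list[MeanModelFit]
    pooled: PooledMeanModel | None  # None when m == 1

    @property
    def scheme(self) -> ConstraintScheme:
        return self.fits[0].scheme

    @property
    def rank_means(self) -> np.ndarray:
        return self.pooled.rank_means if self.pooled else self.fits[0].rank_means

    @property
    def summary(self):
        """What lands in the trace: the fit itself, or its pooled version."""
        return self.pooled if self.pooled else self.fits[0]


def _fit_bundle(grids, scheme, covariance) -> _Bundle:
    fits = [fit_constrained(g, scheme, covariance=covariance) for g in grids]
    pooled = pool_fits(fits) if len(fits) > 1 else None
    return _Bundle(fits, pooled)


def _diff_test(nested: _Bundle, parent: _Bundle,
               method: str = "d1") -> tuple[float, int, float]:
    """Difference test between bundles, as a (statistic, df, p) triple.

    Single dataset: the plain likelihood-ratio chi-square test. Multiple
    imputations: ``"d1"`` (default) tests the added equality constraints
    on the Rubin-pooled parent parameters — it keeps its power when the
    missing-information fraction is high; ``"d2"`` pools the
    per-imputation likelihood-ratio statistics instead.
    """
    from .imputation import pool_fit_statistics

    per_imp = [chisq_diff(nf, pf) for nf, pf in zip(nested.fits, parent.fits)]
    df = per_imp[0][1]
    if len(per_imp) == 1:
        return per_imp[0]
    if df == 0:
        mean_stat = float(np.mean([d[0] for d in per_imp]))
        return mean_stat, 0, 1.0 if mean_stat < 1e-8 else chisq_pvalue(mean_stat, 0)
    if method == "d1":
        from .mean_structure import d1_constraint_test

        stat, k, _, p = d1_constraint_test(parent.fits, nested.scheme)
        return stat, k, p
    if method == "d2":
        stats_ = [d[0] for d in per_imp]
        return float(np.mean(stats_)), df, pool_fit_statistics(stats_, df).p
    raise ValueError("diff method must be 'd1' or 'd2'")


@dataclass
class SearchAttempt:
    scheme: ConstraintScheme
    fit: MeanModelFit | PooledMeanModel | None
    diff: tuple[float, int, float] | None  # vs last accepted fit
    walds: list[WaldResult] = field(default_factory=list)
    accepted: bool = False
    reason: str = ""


@dataclass
class SearchTrace:
    attempts: list[SearchAttempt]
    saturated_fit: MeanModelFit | PooledMeanModel
    final_fit: MeanModelFit | PooledMeanModel
    baseline_level: str | None
    capped: bool = False

    @property
    def final_scheme(self) -> ConstraintScheme:
        return self.final_fit.scheme

    @property
    def n_attempts(self) -> int:
        return len(self.attempts)

    def accepted_fits(self) -> list[MeanModelFit]:
        return [a.fit for a in self.attempts if a.accepted]


def search(grid, *, alpha: float = 0.05, gap_rule: GapRule = GapRule(),
           attempt_cap: int = 5, covariance: str = "saturated",
           diff_method: str = "d1") -> SearchTrace:
    """Run the banding model-selection procedure.

    ``grid`` is a single OutcomeGrid or a sequence of them (one per
    imputed dataset). With several grids every candidate scheme is fit to
    each dataset and the decisions use pooled statistics: D2-combined
    difference tests and Rubin-pooled Wald separations — model selection
    then respects the true (post-missingness) information in the data.
    """
    grids = list(grid) if isinstance(grid, (list, tuple)) else [grid]
    g0 = grids[0]
    labels = g0.labels if all(isinstance(l, tuple) for l in g0.labels) else None
    sat = _fit_bundle(grids, ConstraintScheme.saturated(g0.n_groups, g0.n_waves),
                      covariance)
    attempts: list[SearchAttempt] = []
    accepted = sat
    baseline_level = None
    capped = False

    def out_of_budget() -> bool:
        nonlocal capped
        if len(attempts) >= attempt_cap:
            capped = True
            warnings.warn("banding search hit the attempt cap", stacklevel=3)
            return True
        return False

    # stage 2: baseline equivalence, relaxed stepwise on fit decrement
    levels = BASELINE_LEVELS if labels is not None else ("all",)
    groups = labels if labels is not None else GROUPS[: g0.n_groups]
    for level in levels:
        scheme = baseline_scheme(groups, level, g0.n_waves)
        cand = _fit_bundle(grids, scheme, covariance)
        diff = _diff_test(cand, sat, diff_method)
        ok = diff[2] >= alpha
        attempts.append(SearchAttempt(
            scheme=scheme, fit=cand.summary, diff=diff, accepted=ok,
            reason=f"baseline equivalence ({level}): diff p = {diff[2]:.3f}"))
        if ok:
            accepted = cand
            baseline_level = level
            break
        if out_of_budget():
            return SearchTrace(attempts, sat.summary, accepted.summary,
                               baseline_level, capped)

    # stage 3: banding proposals
    while not out_of_budget():
        proposal, changed = propose_bands(accepted, gap_rule)
        if not changed:
            break
        cand = _fit_bundle(grids, proposal, covariance)
        diff = _diff_test(cand, accepted, diff_method)
        if diff[2] < alpha:
            attempts.append(SearchAttempt(
                scheme=proposal, fit=cand.summary, diff=diff,
                walds=adjacent_walds(cand.summary), accepted=False,
                reason=f"rejected: significant fit decrement (p = {diff[2]:.4f})"))
            break
        # Wald-driven merging: tie any adjacent ranks that fail to separate
        walds = adjacent_walds(cand.summary)
        merged_note = ""
        while cand.scheme.n_ranks > 1:
            weak = [w for w in walds if w.p >= alpha]
            if not weak:
                break
            worst = max(weak, key=lambda w: w.p)
            cand = _fit_bundle(grids, cand.scheme.merge(*worst.contrast), covariance)
            diff = _diff_test(cand, accepted, diff_method)
            merged_note = " after merging non-separated ranks"
            if diff[2] < alpha:
                break
            walds = adjacent_walds(cand.summary)
        if diff[2] < alpha:
            attempts.append(SearchAttempt(
                scheme=cand.scheme, fit=cand.summary, diff=diff,
                walds=adjacent_walds(cand.summary), accepted=False,
                reason=f"rejected{merged_note}: fit decrement (p = {diff[2]:.4f})"))
            break
        attempts.append(SearchAttempt(
            scheme=cand.scheme, fit=cand.summary, diff=diff,
            walds=adjacent_walds(cand.summary), accepted=True,
            reason=f"bands accepted{merged_note}: diff p = {diff[2]:.3f}, "
                   f"R = {cand.scheme.n_ranks}"))
        accepted = cand

    return SearchTrace(attempts, sat.summary, accepted.summary, baseline_level, capped)
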