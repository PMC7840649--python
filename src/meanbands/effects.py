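"""Effect summaries from model-estimated mean grids.

The end product of the evaluation pipeline is, per outcome, an 8-group x
6-wave grid of model-estimated covariate-adjusted POMS means. This module
turns such a grid into the two effect metrics reported for the trial:

* the POMS difference ``SC - DM`` per sex x cohort x wave cell, and
* the relative risk reduction ``RRR = 100 * (SC - DM) / SC`` (percent),
  i.e. the percent reduction in the intervention arm's model-estimated
  score relative to the standard-of-care arm.

Summaries average over the twenty post-baseline cells (4 sex x cohort
groups x waves 1-5); the baseline wave is excluded because both arms are
constrained to baseline equivalence, so baseline cells carry no effect
information and would only dilute the averages. Final-wave (spring 8th
grade) summaries average over the four sex x cohort groups, including
groups with zero estimated effect.

Printed mean grids for the four trial outcomes ship with the package as
CSV fixtures and can be loaded with :func:`printed_grid`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .design import GROUPS, N_WAVES, SEXES, COHORTS, WAVE_LABELS, group_index

FINAL_WAVE = N_WAVES - 1


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention of the printed tables).

    Python's built-in ``round`` rounds half to even; the reported numbers
    use ordinary half-up rounding, so make that explicit.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MeanGrid:
    """Model-estimated POMS means for all 8 design cells at all 6 waves."""

    outcome: str
    means: np.ndarray  # shape (8, 6), canonical group order
    n: np.ndarray  # shape (8,), per-cell sample sizes

    def __post_init__(self):
        means = np.asarray(self.means, dtype=float)
        n = np.asarray(self.n)
        if means.shape != (len(GROUPS), N_WAVES):
            raise ValueError(f"mean grid must be {len(GROUPS)}x{N_WAVES}, got {means.shape}")
        if n.shape != (len(GROUPS),):
            raise ValueError("need one sample size per design cell")
        if not np.all(np.isfinite(means)):
            bad = [
                (GROUPS[g], WAVE_LABELS[t])
                for g, t in zip(*np.nonzero(~np.isfinite(means)))
            ]
            raise ValueError(f"missing cells in mean grid: {bad}")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "n", np.asarray(n, dtype=int))

    def value(self, condition: str, sex: str, cohort: int, wave: int) -> float:
        return float(self.means[group_index(condition, sex, cohort), wave])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.means, columns=list(WAVE_LABELS))
        df.insert(0, "condition", [g[0] for g in GROUPS])
        df.insert(1, "sex", [g[1] for g in GROUPS])
        df.insert(2, "cohort", [g[2] for g in GROUPS])
        df.insert(3, "n", self.n)
        return df

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_printed_grid(path: str | Path, outcome: str | None = None) -> MeanGrid:
    """Read a mean-grid CSV (schema: condition,sex,cohort,n,<6 wave columns>)."""
    df = pd.read_csv(path)
    required = ["condition", "sex", "cohort", "n", *WAVE_LABELS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df[~df.apply(lambda r: (r.condition, r.sex, int(r.cohort)) in GROUPS, axis=1)]
    if len(bad):
        raise ValueError(f"{path}: rows with unknown design cells:\n{bad}")
    means = np.full((len(GROUPS), N_WAVES), np.nan)
    n = np.zeros(len(GROUPS), dtype=int)
    for _, row in df.iterrows():
        g = group_index(row.condition, row.sex, int(row.cohort))
        means[g] = [row[w] for w in WAVE_LABELS]
        n[g] = int(row.n)
    name = outcome if outcome is not None else Path(path).stem
    return MeanGrid(outcome=name, means=means, n=n)


def printed_grid(outcome: str) -> MeanGrid:
    """Load the packaged fixture grid for one of the four trial outcomes."""
    ref = resources.files("meanbands.data").joinpath(f"{outcome}.csv")
    with resources.as_file(ref) as path:
        if not path.exists():
            raise KeyError(f"no packaged mean grid for outcome {outcome!r}")
        return load_printed_grid(path, outcome=outcome)


def printed_model_results() -> pd.DataFrame:
    """Constrained-model fit statistics (chi-square, df, RMSEA, SRMR) per outcome."""
    ref = resources.files("meanbands.data").joinpath("model_results.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def rrr(sc_mean: float, dm_mean: float) -> float:
    """Relative risk reduction in percent: 100 * (SC - DM) / SC.

    Negative values (DM worse than SC) are legitimate. A non-positive SC
    mean makes the ratio meaningless (adjusted POMS scores can dip below
    zero); the caller is expected to exclude such cells, so this raises.
    """
    if sc_mean <= 0:
        raise ValueError(f"RRR undefined for non-positive SC mean {sc_mean}")
    return 100.0 * (sc_mean - dm_mean) / sc_mean


@dataclass
class EffectSummary:
    """POMS differences and relative risk reductions derived from a MeanGrid.

    All aggregate fields are unrounded; :meth:`rounded` applies the printed
    precision (2 decimals for POMS differences, whole percent for RRR).
    """

    outcome: str
    cells: pd.DataFrame  # sex, cohort, wave, sc, dm, diff, rrr (NaN = excluded)
    avg_diff: float
    diff_range: tuple[float, float]
    avg_rrr: float
    rrr_range: tuple[float, float]
    final_wave_avg_rrr: float
    final_wave_rrr_range: tuple[float, float]
    excluded_cells: list = field(default_factory=list)

    def rounded(self) -> dict:
        r = round_half_up
        return {
            "avg_diff": r(self.avg_diff, 2),
            "diff_range": (r(self.diff_range[0], 2), r(self.diff_range[1], 2)),
            "avg_rrr": r(self.avg_rrr),
            "rrr_range": (r(self.rrr_range[0]), r(self.rrr_range[1])),
            "final_wave_avg_rrr": r(self.final_wave_avg_rrr),
            "final_wave_rrr_range": (
                r(self.final_wave_rrr_range[0]),
                r(self.final_wave_rrr_range[1]),
            ),
        }


def summarize(grid: MeanGrid) -> EffectSummary:
    """Compute POMS differences and RRRs over the post-baseline cells.

    Cells where the SC mean is non-positive contribute no RRR and are
    listed in ``excluded_cells``; their POMS difference still counts.
    """
    rows = []
    excluded = []
    for sex in SEXES:
        for cohort in COHORTS:
            for wave in range(1, N_WAVES):
                sc = grid.value("SC", sex, cohort, wave)
                dm = grid.value("DM", sex, cohort, wave)
                diff = sc - dm
                if sc > 0:
                    cell_rrr = rrr(sc, dm)
                else:
                    cell_rrr = math.nan
                    excluded.append((sex, cohort, wave))
                rows.append(
                    {"sex": sex, "cohort": cohort, "wave": wave,
                     "sc": sc, "dm": dm, "diff": diff, "rrr": cell_rrr}
                )
    cells = pd.DataFrame(rows)
    final = cells[cells.wave == FINAL_WAVE]
    return EffectSummary(
        outcome=grid.outcome,
        cells=cells,
        avg_diff=float(cells["diff"].mean()),
        diff_range=(float(cells["diff"].min()), float(cells["diff"].max())),
        avg_rrr=float(cells["rrr"].mean()),
        rrr_range=(float(cells["rrr"].min()), float(cells["rrr"].max())),
        final_wave_avg_rrr=float(final["rrr"].mean()),
        final_wave_rrr_range=(float(final["rrr"].min()), float(final["rrr"].max())),
        excluded_cells=excluded,
    )
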