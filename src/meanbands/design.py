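"""Canonical trial design labels shared across the pipeline.

The evaluation design crosses two trial arms (DM = comprehensive
multi-component prevention condition, SC = standard-of-care comparison),
two sexes, and two entry cohorts, observed at six survey waves
(fall/spring of grades 6-8). The eight condition x sex x cohort cells
are the "groups" of every multiple-group mean model downstream.
"""

from __future__ import annotations

CONDITIONS = ("SC", "DM")
SEXES = ("F", "M")
COHORTS = (3, 4)
N_WAVES = 6

WAVE_LABELS = ("fall_6", "spring_6", "fall_7", "spring_7", "fall_8", "spring_8")

#: Canonical group order (matches the row order of the published mean grids).
GROUPS = (
    ("SC", "F", 3),
    ("SC", "M", 3),
    ("DM", "F", 3),
    ("DM", "M", 3),
    ("SC", "F", 4),
    ("SC", "M", 4),
    ("DM", "F", 4),
    ("DM", "M", 4),
)

N_GROUPS = len(GROUPS)

#: Default per-cell sample sizes (analytic sample of the trial: 3301 students).
GROUP_SIZES = {
    ("SC", "F", 3): 428,
    ("SC", "M", 3): 401,
    ("DM", "F", 3): 444,
    ("DM", "M", 3): 399,
    ("SC", "F", 4): 418,
    ("SC", "M", 4): 392,
    ("DM", "F", 4): 460,
    ("DM", "M", 4): 359,
}

OUTCOMES = (
    "sv_perpetration",
    "sv_victimization",
    "sh_victimization",
    "sh_perpetration",
)

#: Number of ordinal items per outcome composite.
ITEM_COUNTS = {
    "sv_perpetration": 1,
    "sv_victimization": 1,
    "sh_victimization": 6,
    "sh_perpetration": 7,
}

ORDINAL_MIN = 1
ORDINAL_MAX = 4


def group_index(condition: str, sex: str, cohort: int) -> int:
    """Position of a design cell in the canonical group order."""
    return GROUPS.index((condition, sex, int(cohort)))
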