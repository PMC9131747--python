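"""Health-state space and age-band helpers shared by all model components.

The disease process is represented by 12 mutually exclusive states: a
healthy state, five diagnosed cancer stages (carcinoma in situ through
stage IV), one post-treatment maintenance state per cancer stage, and an
absorbing death state.
"""

from __future__ import annotations

from enum import IntEnum


class HealthState(IntEnum):
    """The 12 model states, in the canonical matrix row/column order."""

    NORMAL = 0
    CIS = 1
    STAGE_I = 2
    STAGE_II = 3
    STAGE_III = 4
    STAGE_IV = 5
    MAINT_CIS = 6
    MAINT_I = 7
    MAINT_II = 8
    MAINT_III = 9
    MAINT_IV = 10
    DEATH = 11

    @property
    def is_cancer_stage(self) -> bool:
        return HealthState.CIS <= self <= HealthState.STAGE_IV

    @property
    def is_maintenance(self) -> bool:
        return HealthState.MAINT_CIS <= self <= HealthState.MAINT_IV


N_STATES = 12

#: Diagnosed cancer stages in severity order.
STAGES = (
    HealthState.CIS,
    HealthState.STAGE_I,
    HealthState.STAGE_II,
    HealthState.STAGE_III,
    HealthState.STAGE_IV,
)

#: Maintenance partner of each cancer stage.
MAINTENANCE_OF = {
    HealthState.CIS: HealthState.MAINT_CIS,
    HealthState.STAGE_I: HealthState.MAINT_I,
    HealthState.STAGE_II: HealthState.MAINT_II,
    HealthState.STAGE_III: HealthState.MAINT_III,
    HealthState.STAGE_IV: HealthState.MAINT_IV,
}

STAGE_OF_MAINTENANCE = {m: s for s, m in MAINTENANCE_OF.items()}

#: Stage labels as used in configuration files and tables.
STAGE_LABELS = {
    HealthState.CIS: "CIS",
    HealthState.STAGE_I: "StageI",
    HealthState.STAGE_II: "StageII",
    HealthState.STAGE_III: "StageIII",
    HealthState.STAGE_IV: "StageIV",
}

LABEL_TO_STAGE = {v: k for k, v in STAGE_LABELS.items()}

STATE_NAMES = [
    "Normal",
    "CIS",
    "StageI",
    "StageII",
    "StageIII",
    "StageIV",
    "MaintCIS",
    "MaintI",
    "MaintII",
    "MaintIII",
    "MaintIV",
    "Death",
]


class AgeBandError(ValueError):
    """Raised when an age falls outside the banded parameter tables."""


def band_key(age: int, bands: list[str]) -> str:
    """Return the ``"lo-hi"`` band label enclosing ``age``.

    ``bands`` are strings like ``"50-54"``; bands are inclusive on both
    ends and must not overlap.
    """
    for label in bands:
        lo, hi = parse_band(label)
        if lo <= age <= hi:
            return label
    raise AgeBandError(f"age {age} outside banded range {bands[0]}..{bands[-1]}")


def parse_band(label: str) -> tuple[int, int]:
    lo, hi = label.split("-")
    return int(lo), int(hi)


def validate_band_partition(bands: list[str], lower: int, upper: int) -> list[str]:
    """Check that band labels partition [lower, upper]; return problems."""
    problems = []
    parsed = sorted(parse_band(b) for b in bands)
    if not parsed:
        return [f"no age bands supplied for [{lower}, {upper}]"]
    if parsed[0][0] != lower:
        problems.append(f"first band starts at {parsed[0][0]}, expected {lower}")
    if parsed[-1][1] != upper:
        problems.append(f"last band ends at {parsed[-1][1]}, expected {upper}")
    for (alo, ahi), (blo, bhi) in zip(parsed, parsed[1:]):
        if blo != ahi + 1:
            problems.append(f"gap or overlap between {alo}-{ahi} and {blo}-{bhi}")
    return problems
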