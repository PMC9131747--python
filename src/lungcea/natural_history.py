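"""Age-, sex- and smoking-adjusted annual transition structure.

Assembles the 12-state annual transition matrix: healthy occupants face
banded background mortality and smoking-adjusted cancer incidence (split
across diagnosed stages by the active screening overlay), diagnosed
stages progress/die per the published one-year probabilities with the
complement moving to the stage's maintenance state, and maintenance
states are quasi-absorbing under background mortality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .parameters import INCIDENCE_BANDS, MORTALITY_BANDS, ParameterSet, STAGE_KEYS
from .states import (
    AgeBandError,
    HealthState,
    MAINTENANCE_OF,
    N_STATES,
    STAGES,
    STATE_NAMES,
    band_key,
)

ROW_SUM_TOL = 1e-12
PACK_YEAR_THRESHOLDS = (None, 20, 30)


class TransitionError(ValueError):
    """A transition row could not be assembled consistently."""


@dataclass(frozen=True)
class ScreeningContext:
    """Overlay the screening module supplies to the matrix builder.

    ``relative_risk`` scales incidence for the smoking-exposure stratum;
    ``entry_split`` is the probability vector over diagnosed stages for
    incident cancers this cycle (detection-weighted when screening is
    active, the clinical-presentation vector otherwise).
    """

    relative_risk: float
    entry_split: tuple[float, ...]  # over (CIS, I, II, III, IV)

    def __post_init__(self):
        if len(self.entry_split) != 5:
            raise TransitionError("entry_split must have 5 stage components")
        if abs(sum(self.entry_split) - 1.0) > 1e-9:
            raise TransitionError(
                f"entry_split sums to {sum(self.entry_split)} != 1"
            )


@dataclass(frozen=True)
class TransitionMatrix:
    """Annual transition matrix at one age, with its state order."""

    age: int
    probs: np.ndarray  # (12, 12)

    states = tuple(STATE_NAMES)

    def __post_init__(self):
        p = self.probs
        if p.shape != (N_STATES, N_STATES):
            raise TransitionError(f"matrix shape {p.shape} != (12, 12)")
        if (p < -1e-15).any() or (p > 1 + 1e-15).any():
            raise TransitionError("entries outside [0, 1]")
        bad = np.abs(p.sum(axis=1) - 1.0) > 1e-9
        if bad.any():
            idx = int(np.argmax(bad))
            raise TransitionError(
                f"row {STATE_NAMES[idx]} sums to {p[idx].sum():.15f} != 1"
            )

    def to_table(self) -> str:
        """Plain-text audit dump in fixed state order."""
        header = "state\t" + "\t".join(STATE_NAMES)
        lines = [header]
        for i, name in enumerate(STATE_NAMES):
            lines.append(name + "\t" + "\t".join(f"{x:.10g}" for x in self.probs[i]))
        return "\n".join(lines)


def rate_to_probability(rate_per_100k: float, params: ParameterSet) -> float:
    """Convert a per-100,000 annual rate to an annual probability.

    Default is direct division (rare-event approximation); the
    ``exponential`` mode uses ``1 - exp(-rate)``.
    """
    rate = rate_per_100k / 100_000.0
    if params.rate_conversion == "exponential":
        return 1.0 - math.exp(-rate)
    return min(rate, 1.0)


def adjusted_incidence(
    age: int,
    sex: str,
    pack_year_threshold: int | None,
    params: ParameterSet,
) -> float:
    """Annual probability of incident lung cancer for a healthy person.

    Banded general-population incidence is multiplied by the relative
    risk attached to the smoking-exposure threshold (1 when ``None``).
    """
    if sex not in ("female", "male"):
        raise ValueError(f"unknown sex code {sex!r}")
    if pack_year_threshold not in PACK_YEAR_THRESHOLDS:
        raise ValueError(f"pack-year threshold must be one of {PACK_YEAR_THRESHOLDS}")
    band = band_key(age, INCIDENCE_BANDS)  # raises outside 50-74
    rate = params.incidence_per_100k[band][sex]
    rr = {None: 1.0, 20: params.rr_20py, 30: params.rr_30py}[pack_year_threshold]
    return min(rate_to_probability(rate, params) * rr, 1.0)


def incidence_for_rr(age: int, sex: str, relative_risk: float, params: ParameterSet) -> float:
    """Incidence with an explicit relative risk; 0 beyond the banded range.

    The incidence table stops at the screening stop age; older ages carry
    no incident-cancer mass (diagnosed cases continue to be followed).
    """
    try:
        band = band_key(age, INCIDENCE_BANDS)
    except AgeBandError:
        if age > params.max_age or age < 50:
            raise
        return 0.0
    rate = params.incidence_per_100k[band][sex]
    return min(rate_to_probability(rate, params) * relative_risk, 1.0)


def background_mortality(age: int, params: ParameterSet) -> float:
    """Annual all-cause death probability for the enclosing age band."""
    if age > params.max_age:
        raise AgeBandError(f"age {age} beyond horizon {params.max_age}")
    band = band_key(age, MORTALITY_BANDS)
    p = params.allcause_mort[band]
    if params.subtract_lc_mortality and band in params.lc_mort_per_100k:
        p = max(p - rate_to_probability(params.lc_mort_per_100k[band], params), 0.0)
    return p


def stage_transition_row(stage: HealthState | str, params: ParameterSet) -> dict[HealthState, float]:
    """Annual destinations of a diagnosed stage.

    Worse stages and death receive the published probabilities; the
    remaining mass moves to the stage's maintenance partner.
    """
    from .states import LABEL_TO_STAGE, STAGE_LABELS

    if isinstance(stage, str):
        stage = LABEL_TO_STAGE[stage]
    if not stage.is_cancer_stage:
        raise ValueError(f"{stage!r} is not a cancer stage")
    key = STAGE_LABELS[stage]
    row: dict[HealthState, float] = {}
    for dst_key, p in params.stage_prog[key].items():
        row[LABEL_TO_STAGE[dst_key]] = p
    row[HealthState.DEATH] = params.stage_death[key]
    total = sum(row.values())
    if total > 1.0 + 1e-12:
        raise TransitionError(
            f"{key}: progression + death = {total} > 1, no mass left for maintenance"
        )
    row[MAINTENANCE_OF[stage]] = 1.0 - total
    return row


def stage_block(params: ParameterSet) -> np.ndarray:
    """(5, 12) array of the CIS..IV transition rows (age-independent)."""
    block = np.zeros((5, N_STATES))
    for i, stage in enumerate(STAGES):
        for dst, p in stage_transition_row(stage, params).items():
            block[i, dst] = p
    return block


def build_transition_matrix(
    age: int,
    sex: str,
    strategy_context: ScreeningContext,
    params: ParameterSet,
) -> TransitionMatrix:
    """Assemble the full 12-state annual matrix for one age and stratum.

    Row sums are asserted to 1e-9 at construction; assembly never
    renormalizes silently.
    """
    p_mort = background_mortality(age, params)
    p_inc = incidence_for_rr(age, sex, strategy_context.relative_risk, params)
    if p_mort + p_inc > 1.0:
        raise TransitionError(
            f"age {age}: mortality {p_mort} + incidence {p_inc} exceeds 1"
        )

    m = np.zeros((N_STATES, N_STATES))
    # healthy row: competing incidence and death, residual self-loop
    m[HealthState.NORMAL, HealthState.DEATH] = p_mort
    for i, stage in enumerate(STAGES):
        m[HealthState.NORMAL, stage] = p_inc * strategy_context.entry_split[i]
    m[HealthState.NORMAL, HealthState.NORMAL] = 1.0 - p_mort - p_inc

    m[1:6, :] = stage_block(params)

    recur = params.maintenance_recurrence
    for stage, maint in MAINTENANCE_OF.items():
        m[maint, HealthState.DEATH] = p_mort
        m[maint, stage] = (1.0 - p_mort) * recur
        m[maint, maint] = (1.0 - p_mort) * (1.0 - recur)

    m[HealthState.DEATH, HealthState.DEATH] = 1.0
    return TransitionMatrix(age=age, probs=m)
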