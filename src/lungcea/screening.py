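"""Screening strategies and the per-cycle screening overlay.

Eight policies are compared: two tools (low-dose CT alone, or low-dose
CT with a plasma biomarker triaging CT-positive nodules), two
frequencies (annual, one-time), and two smoking-exposure eligibility
thresholds (20 or 30 pack-years).  The overlay decides who is tested in
a cycle, how incident cancers split between screen detection and
clinical presentation, and what the testing pathway costs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .natural_history import ScreeningContext, incidence_for_rr
from .parameters import ParameterSet, STAGE_KEYS

LDCT = "LDCT"
LDCT_MSC = "LDCT_MSC"
ANNUAL = "annual"
ONCE = "once"


class StrategyError(KeyError):
    pass


@dataclass(frozen=True)
class StrategyDefinition:
    """One screening policy: tool x frequency x eligibility threshold."""

    id: int
    tool: str
    frequency: str
    pack_years: int
    start_age: int = 50
    stop_age: int = 74

    @property
    def label(self) -> str:
        freq = "annually" if self.frequency == ANNUAL else "once"
        tool = "LDCT" if self.tool == LDCT else "LDCT+MSC"
        return f"{tool} {freq}, >= {self.pack_years} pack-years"

    def relative_risk(self, params: ParameterSet) -> float:
        return {20: params.rr_20py, 30: params.rr_30py}[self.pack_years]

    def eligible_fraction(self, params: ParameterSet) -> float:
        return {
            20: params.eligible_fraction_20py,
            30: params.eligible_fraction_30py,
        }[self.pack_years]

    def sensitivity(self, params: ParameterSet) -> float:
        return params.sens_ldct if self.tool == LDCT else params.sens_msc_conj

    def specificity(self, params: ParameterSet) -> float:
        return params.spec_ldct if self.tool == LDCT else params.spec_msc_conj

    def active(self, age: int, cycle_index: int) -> bool:
        """Is a test offered this cycle?  Testing stops at ``stop_age``."""
        if age > self.stop_age:
            return False
        if self.frequency == ONCE:
            return cycle_index == 0
        return True


_CATALOG = (
    StrategyDefinition(0, LDCT, ANNUAL, 30),
    StrategyDefinition(1, LDCT, ONCE, 30),
    StrategyDefinition(2, LDCT, ANNUAL, 20),
    StrategyDefinition(3, LDCT, ONCE, 20),
    StrategyDefinition(4, LDCT_MSC, ANNUAL, 30),
    StrategyDefinition(5, LDCT_MSC, ONCE, 30),
    StrategyDefinition(6, LDCT_MSC, ANNUAL, 20),
    StrategyDefinition(7, LDCT_MSC, ONCE, 20),
)


def strategy_catalog() -> list[StrategyDefinition]:
    """The eight comparator policies, ids 0-7 (0 is the reference)."""
    return list(_CATALOG)


def get_strategy(strategy_id: int) -> StrategyDefinition:
    for s in _CATALOG:
        if s.id == strategy_id:
            return s
    raise StrategyError(f"no strategy with id {strategy_id}")


def catalog_table() -> str:
    lines = ["id\ttool\tfrequency\tpack_years"]
    for s in _CATALOG:
        lines.append(f"{s.id}\t{s.tool}\t{s.frequency}\t{s.pack_years}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# test-performance arithmetic


@dataclass(frozen=True)
class ScreenCycleResult:
    """2x2 classification fractions of one screened group plus costs."""

    tp: float
    fn: float
    fp: float
    tn: float
    stage_entry: tuple[float, ...]
    expected_cost: float

    def __post_init__(self):
        total = self.tp + self.fn + self.fp + self.tn
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"classification fractions sum to {total} != 1")


def _tool_sens_spec(tool: str, params: ParameterSet) -> tuple[float, float]:
    if tool == LDCT:
        return params.sens_ldct, params.spec_ldct
    if tool == LDCT_MSC:
        return params.sens_msc_conj, params.spec_msc_conj
    raise StrategyError(f"unknown tool {tool!r}")


def screen_classification(prevalence: float, tool: str, params: ParameterSet):
    """(tp, fn, fp, tn) fractions of the screened group."""
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError(f"prevalence {prevalence} outside [0, 1]")
    sens, spec = _tool_sens_spec(tool, params)
    tp = prevalence * sens
    fn = prevalence * (1.0 - sens)
    fp = (1.0 - prevalence) * (1.0 - spec)
    tn = (1.0 - prevalence) * spec
    return tp, fn, fp, tn


def detected_stage_distribution(tool: str, params: ParameterSet) -> np.ndarray:
    """Stage-at-detection probability vector (CIS, I, II, III, IV)."""
    table = params.detect_stage_ldct if tool == LDCT else params.detect_stage_ldct_msc
    if tool not in (LDCT, LDCT_MSC):
        raise StrategyError(f"unknown tool {tool!r}")
    vec = np.array([table[k] for k in STAGE_KEYS])
    if abs(vec.sum() - 1.0) > 1e-9:
        raise ValueError(f"stage distribution for {tool} sums to {vec.sum()} != 1")
    return vec


def clinical_stage_distribution(params: ParameterSet) -> np.ndarray:
    """Stage distribution for cancers presenting outside screening."""
    vec = np.array([params.clinical_stage_dist[k] for k in STAGE_KEYS])
    if abs(vec.sum() - 1.0) > 1e-9:
        raise ValueError(f"clinical stage distribution sums to {vec.sum()} != 1")
    return vec


def diagnosis_cost(params: ParameterSet) -> float:
    """One-off workup cost of a confirmed diagnosis."""
    return params.cost_prediag + params.cost_biopsy


def cycle_screening_cost(prevalence: float, tool: str, params: ParameterSet) -> float:
    """Expected testing-pathway cost per screened healthy person.

    Every screenee pays for the CT scan.  Under the conjunctive pathway
    the biomarker assay is charged to CT-positives only (the assay is a
    triage of conspicuous nodules), while final classification uses the
    joint operating characteristics.  False positives receive the
    prediagnosis workup (optionally biopsy too); true positives receive
    prediagnosis plus biopsy.
    """
    tp, fn, fp, tn = screen_classification(prevalence, tool, params)
    cost = params.cost_ldct
    if tool == LDCT_MSC:
        if params.msc_cost_all_screened:
            cost += params.cost_msc
        else:
            # CT positivity governed by the CT-alone operating characteristics
            p_ldct_pos = prevalence * params.sens_ldct + (1.0 - prevalence) * (
                1.0 - params.spec_ldct
            )
            cost += p_ldct_pos * params.cost_msc
    fp_cost = params.cost_prediag + (params.cost_biopsy if params.fp_workup_biopsy else 0.0)
    cost += fp * fp_cost
    cost += tp * diagnosis_cost(params)
    return cost


def screen_cycle_result(prevalence: float, tool: str, params: ParameterSet) -> ScreenCycleResult:
    tp, fn, fp, tn = screen_classification(prevalence, tool, params)
    return ScreenCycleResult(
        tp=tp,
        fn=fn,
        fp=fp,
        tn=tn,
        stage_entry=tuple(detected_stage_distribution(tool, params)),
        expected_cost=cycle_screening_cost(prevalence, tool, params),
    )


# ---------------------------------------------------------------------------
# per-cycle overlay


@dataclass(frozen=True)
class OverlayResult:
    """Entry flows out of the healthy state and attached per-capita costs.

    All quantities are per occupant of the healthy state at cycle start.
    ``detected`` / ``clinical`` are stage-entry probability masses (not
    conditional distributions); ``screening_cost`` covers tests and
    positive/false-positive workup; ``entry_cost`` covers clinical-route
    diagnosis and treatment initiation for all entrants.
    """

    active: bool
    incidence: float
    detected: np.ndarray  # (5,) flows into stages via screening
    clinical: np.ndarray  # (5,) flows into stages via clinical presentation
    screening_cost: float
    entry_cost: float

    @property
    def entry_split(self) -> np.ndarray:
        """Conditional stage distribution of this cycle's incident cancers."""
        total = self.detected + self.clinical
        s = total.sum()
        return total / s if s > 0 else total

    def context(self, relative_risk: float) -> ScreeningContext:
        split = self.entry_split
        if split.sum() == 0:
            split = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
        return ScreeningContext(relative_risk=relative_risk, entry_split=tuple(split))


def apply_screening_overlay(
    age: int,
    sex: str,
    strategy: StrategyDefinition | None,
    cycle_index: int,
    relative_risk: float,
    params: ParameterSet,
) -> OverlayResult:
    """Resolve one cycle's screening behaviour for one stratum.

    In an active screening cycle a fraction equal to the tool's (joint)
    sensitivity of this cycle's incident cancers is screen-detected and
    enters stages per the tool's stage-at-detection vector; the remainder
    — and all incident cancer in non-screening cycles or unscreened
    strata — enters via the clinical-presentation vector.  Treatment
    cost attaches at stage entry; clinical entrants also pay the
    diagnostic workup (screen-detected workup is inside the screening
    cost).  An inactive cycle returns zero screening flows and costs.
    """
    p_inc = incidence_for_rr(age, sex, relative_risk, params)
    clin_dist = clinical_stage_distribution(params)
    treat = np.array([params.cost_treat[k] for k in STAGE_KEYS])

    active = strategy is not None and strategy.active(age, cycle_index)
    if active:
        sens = strategy.sensitivity(params)
        det_dist = detected_stage_distribution(strategy.tool, params)
        detected = p_inc * sens * det_dist
        clinical = p_inc * (1.0 - sens) * clin_dist
        screening_cost = cycle_screening_cost(p_inc, strategy.tool, params)
    else:
        detected = np.zeros(5)
        clinical = p_inc * clin_dist
        screening_cost = 0.0

    entry_cost = float(
        detected @ treat + clinical @ treat + clinical.sum() * diagnosis_cost(params)
    )
    return OverlayResult(
        active=active,
        incidence=p_inc,
        detected=detected,
        clinical=clinical,
        screening_cost=screening_cost,
        entry_cost=entry_cost,
    )
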