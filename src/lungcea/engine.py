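"""Cohort-trace engine: run cohorts cycle by cycle and accumulate
discounted costs, life-years and QALYs.

Event order within a cycle is fixed: screening, then incidence and
diagnosis, then progression/death, with state payoffs accrued on
start-of-cycle occupancy.  One-off costs (testing, diagnostic workup,
treatment initiation) attach to entry flows; maintenance costs and
utilities attach to occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .natural_history import build_transition_matrix
from .parameters import ParameterSet, STAGE_KEYS
from .screening import StrategyDefinition, apply_screening_overlay
from .states import HealthState, N_STATES

TRACE_TOL = 1e-10


class EngineError(RuntimeError):
    pass


class ConfigurationError(ValueError):
    pass


def discount_factor(cycle_index: int, rate: float) -> float:
    """Present-value weight of cycle ``cycle_index``: (1 + rate)^-t."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    if rate <= -1:
        raise ValueError("discount rate must exceed -1")
    return (1.0 + rate) ** (-cycle_index)


@dataclass(frozen=True)
class CohortSpec:
    """One simulated birth cohort entering the model in a fixed year."""

    entry_age: int
    size: float = 10_000.0
    entry_year: int = 2021

    def __post_init__(self):
        if not 50 <= self.entry_age <= 74:
            raise ConfigurationError(
                f"entry age {self.entry_age} outside the screened range 50-74"
            )
        if self.size <= 0:
            raise ConfigurationError("cohort size must be positive")

    @property
    def birth_year(self) -> int:
        return self.entry_year - self.entry_age


#: Default population: 8 cohorts of 10,000 entering in 2021, birth years
#: evenly spread over 1947-1971 (80,000 simulated people in total).
DEFAULT_BIRTH_YEARS = (1947, 1950, 1954, 1957, 1961, 1964, 1968, 1971)


def default_cohorts(size: float = 10_000.0, entry_year: int = 2021) -> list[CohortSpec]:
    return [
        CohortSpec(entry_age=entry_year - by, size=size, entry_year=entry_year)
        for by in DEFAULT_BIRTH_YEARS
    ]


def single_age_cohorts(start_age: int, total: float = 80_000.0) -> list[CohortSpec]:
    """All simulated persons entering at one screening start age."""
    return [CohortSpec(entry_age=start_age, size=total)]


@dataclass
class CohortTrace:
    """Per-cycle state-occupancy fractions for one cohort."""

    entry_age: int
    occupancy: np.ndarray  # (cycles, 12)

    def __post_init__(self):
        occ = self.occupancy
        if occ.ndim != 2 or occ.shape[1] != N_STATES:
            raise EngineError(f"trace shape {occ.shape} invalid")
        drift = np.abs(occ.sum(axis=1) - 1.0)
        if drift.max() > TRACE_TOL:
            raise EngineError(f"trace mass drift {drift.max():.3e} exceeds {TRACE_TOL}")
        death = occ[:, HealthState.DEATH]
        if np.any(np.diff(death) < -1e-12):
            raise EngineError("death occupancy must be non-decreasing")
        normal = occ[:, HealthState.NORMAL]
        if np.any(np.diff(normal) > 1e-12):
            raise EngineError("healthy occupancy must be non-increasing")

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0]

    def ages(self) -> np.ndarray:
        return self.entry_age + np.arange(self.n_cycles)

    def to_table(self) -> str:
        from .states import STATE_NAMES

        lines = ["cycle\tage\t" + "\t".join(STATE_NAMES)]
        for t, age in enumerate(self.ages()):
            row = "\t".join(f"{x:.10g}" for x in self.occupancy[t])
            lines.append(f"{t}\t{age}\t{row}")
        return "\n".join(lines)


@dataclass(frozen=True)
class StrategyOutcome:
    """Discounted totals for one strategy, per person and population-scaled."""

    strategy_id: int | None
    cost: float  # CNY per person
    life_years: float
    qalys: float
    population: float = 1.0

    def __post_init__(self):
        if min(self.cost, self.life_years, self.qalys) < 0:
            raise EngineError("outcomes must be non-negative")
        if self.qalys > self.life_years + 1e-9:
            raise EngineError("QALYs cannot exceed life-years")

    # presentation units used by the published base-case table
    @property
    def cost_millions(self) -> float:
        return self.cost * self.population / 1e6

    @property
    def ly_10k(self) -> float:
        return self.life_years * self.population / 1e4

    @property
    def qaly_10k(self) -> float:
        return self.qalys * self.population / 1e4

    def scaled(self, weight: float, population: float | None = None) -> "StrategyOutcome":
        return StrategyOutcome(
            self.strategy_id,
            self.cost * weight,
            self.life_years * weight,
            self.qalys * weight,
            self.population if population is None else population,
        )


def combine_outcomes(
    parts: list[tuple[float, StrategyOutcome]],
    strategy_id: int | None,
    population: float,
) -> StrategyOutcome:
    """Weighted mixture of per-person outcomes (weights sum to 1)."""
    wsum = sum(w for w, _ in parts)
    if abs(wsum - 1.0) > 1e-9:
        raise ConfigurationError(f"mixture weights sum to {wsum} != 1")
    return StrategyOutcome(
        strategy_id,
        sum(w * o.cost for w, o in parts),
        sum(w * o.life_years for w, o in parts),
        sum(w * o.qalys for w, o in parts),
        population,
    )


# ---------------------------------------------------------------------------
# generic chain runner (shared accrual convention; used by oracle tests too)


def run_chain(
    transition: np.ndarray,
    n_cycles: int,
    state_costs: np.ndarray,
    state_utilities: np.ndarray,
    discount_rate: float = 0.0,
    start: int | np.ndarray = 0,
    death_states: np.ndarray | None = None,
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Propagate a start distribution through a fixed matrix.

    Returns the (n_cycles, n) trace and (cost, life-years, QALY) totals
    accrued on start-of-cycle occupancy with geometric discounting.
    ``death_states`` marks states excluded from life-year accrual
    (default: states with no utility and a self-loop of 1).
    """
    n = transition.shape[0]
    occ = np.zeros(n)
    if np.isscalar(start):
        occ[int(start)] = 1.0
    else:
        occ = np.asarray(start, dtype=float).copy()
    if death_states is None:
        death_states = (np.diag(transition) == 1.0) & (state_utilities == 0.0)
    alive = ~death_states

    trace = np.zeros((n_cycles, n))
    cost = ly = qaly = 0.0
    for t in range(n_cycles):
        trace[t] = occ
        beta = discount_factor(t, discount_rate)
        cost += beta * float(occ @ state_costs)
        ly += beta * float(occ[alive].sum())
        qaly += beta * float(occ @ state_utilities)
        if t < n_cycles - 1:
            occ = occ @ transition
    return trace, (cost, ly, qaly)


def accumulate_outcomes(
    trace: np.ndarray,
    state_costs: np.ndarray,
    state_utilities: np.ndarray,
    discount_rate: float = 0.0,
    discount_effects: bool = True,
    death_index: int = int(HealthState.DEATH),
) -> tuple[float, float, float]:
    """Discounted dot products of a trace with per-cycle state payoffs.

    One-off entry costs are attached to flows by the cohort runner, not
    here.
    """
    trace = np.asarray(trace, dtype=float)
    n_cycles, n = trace.shape
    if len(state_costs) != n or len(state_utilities) != n:
        raise ConfigurationError("payoff vectors must cover every state")
    t = np.arange(n_cycles)
    disc_c = (1.0 + discount_rate) ** (-t)
    disc_e = disc_c if discount_effects else np.ones(n_cycles)
    cost = float(disc_c @ (trace @ state_costs))
    alive = 1.0 - trace[:, death_index]
    ly = float(disc_e @ alive)
    qaly = float(disc_e @ (trace @ state_utilities))
    return cost, ly, qaly


# ---------------------------------------------------------------------------
# production cohort runner


@dataclass
class ArmResult:
    trace: np.ndarray  # (cycles, 12)
    cost: float
    life_years: float
    qalys: float


def _run_arm(
    entry_age: int,
    sex: str,
    relative_risk: float,
    strategy: StrategyDefinition | None,
    params: ParameterSet,
) -> ArmResult:
    """Run one homogeneous stratum (one sex, one exposure/screening arm)."""
    n_cycles = params.max_age - entry_age + 1
    rate = params.discount_rate
    util = params.utility_vector()
    maint = params.maintenance_cost_vector()
    treat = np.array([params.cost_treat[k] for k in STAGE_KEYS])
    # expected treatment-initiation cost charged when a stage row sends
    # mass onward to a worse stage
    prog_cost = np.zeros(5)
    for i, src in enumerate(STAGE_KEYS):
        prog_cost[i] = sum(
            p * params.cost_treat[dst] for dst, p in params.stage_prog[src].items()
        )

    occ = np.zeros(N_STATES)
    occ[HealthState.NORMAL] = 1.0
    trace = np.zeros((n_cycles, N_STATES))
    cost = ly = qaly = 0.0
    matrix_cache: dict = {}

    for t in range(n_cycles):
        age = entry_age + t
        trace[t] = occ
        if abs(occ.sum() - 1.0) > 1e-9:
            raise EngineError(f"cycle {t}: occupancy drift {occ.sum() - 1.0:.3e}")

        disc_c = discount_factor(t, rate)
        disc_e = disc_c if params.discount_effects else 1.0
        w = 0.5 if params.half_cycle_correction and t in (0, n_cycles - 1) else 1.0
        ly += w * disc_e * (1.0 - occ[HealthState.DEATH])
        qaly += w * disc_e * float(occ @ util)
        cost += w * disc_c * float(occ @ maint)

        if t == n_cycles - 1:
            break

        overlay = apply_screening_overlay(age, sex, strategy, t, relative_risk, params)
        cost += disc_c * occ[HealthState.NORMAL] * (
            overlay.screening_cost + overlay.entry_cost
        )
        cost += disc_c * float(occ[1:6] @ prog_cost)

        key = (age // 5, overlay.active)
        if key not in matrix_cache:
            matrix_cache[key] = build_transition_matrix(
                age, sex, overlay.context(relative_risk), params
            ).probs
        occ = occ @ matrix_cache[key]

    return ArmResult(trace=trace, cost=cost, life_years=ly, qalys=qaly)


def _arm_mixture(
    cohort: CohortSpec,
    strategy: StrategyDefinition | None,
    params: ParameterSet,
    arm_cache: dict | None = None,
):
    """Weighted (sex x eligibility) strata making up one cohort."""
    if arm_cache is None:
        arm_cache = {}
    parts = []  # (weight, key, arm args)
    for sex, w_sex in (("male", params.male_fraction), ("female", 1 - params.male_fraction)):
        if w_sex == 0:
            continue
        if strategy is None:
            parts.append((w_sex, (cohort.entry_age, sex, 1.0, None)))
        else:
            ef = strategy.eligible_fraction(params)
            rr = strategy.relative_risk(params)
            if ef > 0:
                parts.append(
                    (
                        w_sex * ef,
                        (cohort.entry_age, sex, rr, (strategy.tool, strategy.frequency)),
                    )
                )
            if ef < 1:
                parts.append((w_sex * (1 - ef), (cohort.entry_age, sex, 1.0, None)))
    results = []
    for weight, key in parts:
        if key not in arm_cache:
            entry_age, sex, rr, scr = key
            arm_strategy = strategy if scr is not None else None
            arm_cache[key] = _run_arm(entry_age, sex, rr, arm_strategy, params)
        results.append((weight, arm_cache[key]))
    return results


def run_cohort(
    cohort: CohortSpec,
    strategy: StrategyDefinition | None,
    params: ParameterSet,
    arm_cache: dict | None = None,
) -> tuple[CohortTrace, StrategyOutcome]:
    """Run one cohort under one strategy (or the no-screening sentinel).

    Returns the mixture trace over (sex x eligibility) strata and the
    per-person discounted outcome scaled to the cohort population.
    """
    parts = _arm_mixture(cohort, strategy, params, arm_cache)
    occupancy = sum(w * r.trace for w, r in parts)
    trace = CohortTrace(entry_age=cohort.entry_age, occupancy=occupancy)
    outcome = StrategyOutcome(
        strategy.id if strategy is not None else None,
        sum(w * r.cost for w, r in parts),
        sum(w * r.life_years for w, r in parts),
        sum(w * r.qalys for w, r in parts),
        population=cohort.size,
    )
    return trace, outcome


def run_strategy(
    strategy: StrategyDefinition | None,
    cohorts: list[CohortSpec],
    params: ParameterSet,
    arm_cache: dict | None = None,
) -> StrategyOutcome:
    """Population-weighted aggregate outcome over cohorts."""
    if not cohorts:
        raise ConfigurationError("cohort list must be non-empty")
    ages = [c.entry_age for c in cohorts]
    if len(set(ages)) != len(ages):
        raise ConfigurationError(f"overlapping cohort definitions: entry ages {ages}")
    if arm_cache is None:
        arm_cache = {}
    total = sum(c.size for c in cohorts)
    parts = []
    for cohort in cohorts:
        _, outcome = run_cohort(cohort, strategy, params, arm_cache)
        parts.append((cohort.size / total, outcome))
    return combine_outcomes(
        parts, strategy.id if strategy is not None else None, population=total
    )


def evaluate_strategies(
    strategies: list[StrategyDefinition],
    cohorts: list[CohortSpec],
    params: ParameterSet,
) -> dict[int, StrategyOutcome]:
    """Run several strategies sharing unscreened-stratum computations."""
    arm_cache: dict = {}
    return {
        s.id: run_strategy(s, cohorts, params, arm_cache) for s in strategies
    }
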