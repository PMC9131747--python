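"""Deterministic and probabilistic sensitivity analysis.

One-way sweeps feed the tornado ranking, the PSA re-evaluates the full
model on independently drawn parameter vectors (index-seeded, so any
execution order reproduces the same samples), and the threshold search
bisects a monotone ICER-vs-parameter relationship to a target
willingness-to-pay value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cea import ICERResult, pairwise_icer
from .engine import CohortSpec, StrategyOutcome, evaluate_strategies
from .parameters import (
    DistributionSpec,
    ParameterSet,
    SamplingError,
    get_param,
    sample_parameter_set,
    set_param,
    validate_parameter_set,
)
from .screening import StrategyDefinition, get_strategy

#: Virtual sweep path scaling both test unit costs by a common factor.
SCREENING_COST_SCALE = "screening_cost_scale"


class SweepError(ValueError):
    pass


class ThresholdError(RuntimeError):
    pass


@dataclass(frozen=True)
class SweepSpec:
    """One-way sweep definition over a parameter path."""

    path: str
    low: float
    high: float
    n_points: int = 11
    mode: str = "absolute"  # or "fraction": low/high are +/- fractions of base

    def __post_init__(self):
        if self.low > self.high:
            raise SweepError(f"{self.path}: low {self.low} > high {self.high}")
        if self.n_points < 2:
            raise SweepError(f"{self.path}: need at least 2 grid points")
        if self.mode not in ("absolute", "fraction"):
            raise SweepError(f"{self.path}: unknown sweep mode {self.mode!r}")

    def grid(self, params: ParameterSet) -> np.ndarray:
        if self.mode == "fraction":
            base = _get(params, self.path)
            return base * (1.0 + np.linspace(self.low, self.high, self.n_points))
        return np.linspace(self.low, self.high, self.n_points)


def default_sweeps(params: ParameterSet, cost_fraction: float = 0.30) -> list[SweepSpec]:
    """The published univariate-analysis parameter list (8 sweeps)."""
    f = cost_fraction
    return [
        SweepSpec(SCREENING_COST_SCALE, 1 - f, 1 + f),
        SweepSpec("maintenance_fraction", -f, f, mode="fraction"),
        SweepSpec("discount_rate", 0.0, 0.08),
        SweepSpec("cpi_rate", -f, f, mode="fraction"),
        SweepSpec("sens_ldct", 0.63, 0.95),
        SweepSpec("spec_ldct", 0.65, 0.97),
        SweepSpec("sens_msc_conj", 0.41, 0.98),
        SweepSpec("spec_msc_conj", 0.81, 0.99),
    ]


def _get(params: ParameterSet, path: str) -> float:
    if path == SCREENING_COST_SCALE:
        return 1.0
    return float(get_param(params, path))


def _with_value(params: ParameterSet, path: str, value: float) -> ParameterSet:
    """Copy of ``params`` with one (possibly virtual) path substituted."""
    out = params.copy()
    if path == SCREENING_COST_SCALE:
        out.cost_ldct = params.cost_ldct * value
        out.cost_msc = params.cost_msc * value
    else:
        set_param(out, path, value)
    violations = validate_parameter_set(out)
    if violations:
        raise SweepError(f"{path}={value}: {violations[0]}")
    return out


def resolve_pair(pair) -> tuple[StrategyDefinition, StrategyDefinition]:
    a, b = pair
    if not isinstance(a, StrategyDefinition):
        a = get_strategy(int(a))
    if not isinstance(b, StrategyDefinition):
        b = get_strategy(int(b))
    return a, b


def icer_for_pair(
    pair, cohorts: list[CohortSpec], params: ParameterSet
) -> ICERResult:
    """Run both strategies of a pair and compare them."""
    intervention, comparator = resolve_pair(pair)
    outcomes = evaluate_strategies([intervention, comparator], cohorts, params)
    return pairwise_icer(outcomes[intervention.id], outcomes[comparator.id])


@dataclass(frozen=True)
class SweepPoint:
    value: float
    icer: float | None
    delta_cost: float
    delta_qaly: float


def one_way_sweep(
    spec: SweepSpec, pair, cohorts: list[CohortSpec], params: ParameterSet
) -> list[SweepPoint]:
    """Recompute the pair ICER along one parameter grid.

    The base parameter set is never mutated (verified by digest).
    """
    digest_before = params.digest()
    points = []
    for value in spec.grid(params):
        result = icer_for_pair(pair, cohorts, _with_value(params, spec.path, float(value)))
        points.append(
            SweepPoint(float(value), result.icer, result.delta_cost, result.delta_qaly)
        )
    if params.digest() != digest_before:
        raise SweepError(f"{spec.path}: sweep mutated the base parameter set")
    return points


@dataclass(frozen=True)
class TornadoRow:
    path: str
    low_value: float
    high_value: float
    icer_min: float
    icer_max: float

    @property
    def width(self) -> float:
        return self.icer_max - self.icer_min


def tornado_table(
    sweeps: list[SweepSpec], pair, cohorts: list[CohortSpec], params: ParameterSet
) -> tuple[float | None, list[TornadoRow]]:
    """Base-case ICER plus one row per sweep, ranked by bar width."""
    if not sweeps:
        raise SweepError("tornado requires at least one sweep")
    base = icer_for_pair(pair, cohorts, params)
    rows = []
    for spec in sweeps:
        points = one_way_sweep(spec, pair, cohorts, params)
        icers = [p.icer for p in points if p.icer is not None]
        if not icers:
            raise SweepError(f"{spec.path}: ICER undefined over the whole sweep")
        rows.append(
            TornadoRow(
                spec.path,
                points[0].value,
                points[-1].value,
                min(icers),
                max(icers),
            )
        )
    rows.sort(key=lambda r: -r.width)
    return base.icer, rows


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass(frozen=True)
class PSASample:
    """One PSA draw: the sampled vector's digest plus all its outcomes."""

    index: int
    seed: int
    params_digest: str
    outcomes: dict[int, StrategyOutcome]


def run_psa(
    n_iter: int,
    seed: int,
    dist_table: dict[str, DistributionSpec],
    strategies: list[StrategyDefinition],
    cohorts: list[CohortSpec],
    params: ParameterSet,
    max_failure_fraction: float = 0.01,
    callback=None,
) -> list[PSASample]:
    """Full model evaluation on ``n_iter`` independently sampled vectors.

    Draw ``i`` uses generator seed ``(seed, i)``, so samples are
    replayable individually and in any order.  More than
    ``max_failure_fraction`` of draws failing validation aborts the run
    (a mis-specified distribution table, not sampling noise).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    samples: list[PSASample] = []
    failures = 0
    allowed = max(1, int(max_failure_fraction * n_iter))
    for i in range(n_iter):
        try:
            drawn = sample_parameter_set(params, dist_table, np.random.default_rng([seed, i]))
        except SamplingError:
            failures += 1
            if failures > allowed:
                raise SamplingError(
                    f"{failures}/{i + 1} PSA draws failed validation; "
                    "check the distribution table"
                )
            continue
        outcomes = evaluate_strategies(strategies, cohorts, drawn)
        sample = PSASample(i, seed, drawn.digest(), outcomes)
        samples.append(sample)
        if callback is not None:
            callback(sample)
    return samples


# ---------------------------------------------------------------------------
# threshold search


def threshold_search(
    path: str,
    target: float,
    pair,
    bounds: tuple[float, float],
    cohorts: list[CohortSpec],
    params: ParameterSet,
    param_tol: float = 1e-6,
    icer_tol: float = 1.0,
    n_monotone_check: int = 9,
    icer_fn=None,
) -> float:
    """Parameter value at which the pair ICER crosses ``target``.

    Pre-checks that the ICER is monotone over ``bounds`` on a coarse
    grid and that the target is bracketed by the endpoint ICERs, then
    bisects.  Deterministic: no randomness anywhere.  ``icer_fn``
    replaces the model evaluation with a custom value -> ICER map
    (used for oracle cross-checks).
    """
    lo, hi = bounds
    if lo >= hi:
        raise ThresholdError(f"invalid bounds ({lo}, {hi})")

    def f(x: float) -> float:
        if icer_fn is not None:
            return float(icer_fn(x))
        result = icer_for_pair(pair, cohorts, _with_value(params, path, x))
        if result.icer is None:
            raise ThresholdError(f"ICER undefined at {path}={x}")
        return result.icer

    grid = np.linspace(lo, hi, n_monotone_check)
    values = [f(float(x)) for x in grid]
    diffs = np.diff(values)
    if not ((diffs >= -icer_tol).all() or (diffs <= icer_tol).all()):
        raise ThresholdError(
            f"ICER is not monotone in {path} over {bounds}: sampled {values}"
        )
    f_lo, f_hi = values[0], values[-1]
    if not (min(f_lo, f_hi) <= target <= max(f_lo, f_hi)):
        raise ThresholdError(
            f"target {target} not bracketed: ICER({lo})={f_lo}, ICER({hi})={f_hi}"
        )

    increasing = f_hi >= f_lo
    a, b = lo, hi
    while b - a > param_tol:
        mid = 0.5 * (a + b)
        fm = f(mid)
        if abs(fm - target) <= icer_tol:
            return mid
        if (fm < target) == increasing:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)
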