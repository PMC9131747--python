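"""Cost-effectiveness outputs: ICERs, dominance labels, efficiency
frontier, net monetary benefit, and acceptability curves.

Conventions: a strategy *dominates* the comparator when it costs no more
and yields more QALYs (or costs less at equal QALYs); negative ICERs are
reported signed, as the published table prints them, but carry a
dominance label so the sign cannot be misread.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .engine import StrategyOutcome

COMPARATOR = "comparator"
DOMINANT = "dominant"
DOMINATED = "dominated"
EXTENDED_DOMINATED = "extended_dominated"
NONDOMINATED = "nondominated"

#: Default willingness-to-pay grid: 0 to 250,000 CNY/QALY in 2,500 steps,
#: covering 1x-3x per-capita GDP.
DEFAULT_WTP_GRID = tuple(np.arange(0, 250_001, 2_500, dtype=float))


@dataclass(frozen=True)
class ICERResult:
    """Pairwise incremental comparison of one strategy vs a comparator."""

    strategy_id: int | None
    comparator_id: int | None
    delta_cost: float
    delta_qaly: float
    icer: float | None  # None when delta_qaly == 0 (undefined, no division)
    label: str

    @property
    def defined(self) -> bool:
        return self.icer is not None


def pairwise_icer(
    intervention: StrategyOutcome, comparator: StrategyOutcome
) -> ICERResult:
    """Incremental cost per QALY of ``intervention`` over ``comparator``.

    Uses population-scaled totals; both outcomes must describe the same
    population.
    """
    if abs(intervention.population - comparator.population) > 1e-9:
        raise ValueError(
            "pairwise comparison requires outcomes on the same population"
        )
    dc = (intervention.cost - comparator.cost) * intervention.population
    dq = (intervention.qalys - comparator.qalys) * intervention.population

    if dq > 0 and dc <= 0:
        label = DOMINANT
    elif dq < 0 and dc >= 0:
        label = DOMINATED
    elif dq == 0 and dc == 0:
        label = COMPARATOR
    elif dq == 0:
        label = DOMINANT if dc < 0 else DOMINATED
    else:
        label = NONDOMINATED
    icer = dc / dq if dq != 0 else None
    return ICERResult(
        intervention.strategy_id, comparator.strategy_id, dc, dq, icer, label
    )


def net_monetary_benefit(
    outcome: StrategyOutcome, comparator: StrategyOutcome, wtp: float
) -> float:
    """NMB = wtp * dQALY - dCost (population-scaled, CNY)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    dq = (outcome.qalys - comparator.qalys) * outcome.population
    dc = (outcome.cost - comparator.cost) * outcome.population
    return wtp * dq - dc


# ---------------------------------------------------------------------------
# efficiency frontier


@dataclass
class FrontierRow:
    strategy_id: int | None
    cost: float
    qaly: float
    label: str
    incremental_icer: float | None = None  # vs previous frontier point


def efficiency_frontier(outcomes: Sequence[StrategyOutcome]) -> list[FrontierRow]:
    """Label every strategy and compute the efficient frontier.

    Strategies are sorted by cost (ties broken by QALY then id); strictly
    dominated points are removed first, then extended-dominated points —
    those whose incremental ratio exceeds that of the next
    more-effective alternative — iteratively, until frontier ICERs
    strictly increase.
    """
    if len(outcomes) < 2:
        raise ValueError("frontier needs at least 2 strategies")
    rows = [
        FrontierRow(
            o.strategy_id,
            o.cost * o.population,
            o.qalys * o.population,
            NONDOMINATED,
        )
        for o in outcomes
    ]
    order = sorted(
        rows, key=lambda r: (r.cost, -r.qaly, r.strategy_id if r.strategy_id is not None else -1)
    )

    # strict dominance: some other strategy has <= cost and >= qaly, one strict
    for r in order:
        for s in order:
            if s is r:
                continue
            if (
                s.cost <= r.cost
                and s.qaly >= r.qaly
                and (s.cost < r.cost or s.qaly > r.qaly)
            ):
                r.label = DOMINATED
                break

    # extended dominance on the survivors
    while True:
        frontier = [r for r in order if r.label == NONDOMINATED]
        changed = False
        for i in range(1, len(frontier) - 1):
            prev, cur, nxt = frontier[i - 1], frontier[i], frontier[i + 1]
            icer_cur = _seg_icer(prev, cur)
            icer_nxt = _seg_icer(cur, nxt)
            if icer_cur is not None and icer_nxt is not None and icer_cur >= icer_nxt:
                cur.label = EXTENDED_DOMINATED
                changed = True
                break
        if not changed:
            break

    frontier = [r for r in order if r.label == NONDOMINATED]
    for prev, cur in zip(frontier, frontier[1:]):
        cur.incremental_icer = _seg_icer(prev, cur)
    return order


def _seg_icer(a: FrontierRow, b: FrontierRow) -> float | None:
    dq = b.qaly - a.qaly
    if dq == 0:
        return None
    return (b.cost - a.cost) / dq


# ---------------------------------------------------------------------------
# acceptability curves


def ceac(
    psa_samples: Iterable,
    strategy_id: int,
    comparator_id: int,
    wtp_grid: Sequence[float] = DEFAULT_WTP_GRID,
    mode: str = "nmb",
) -> np.ndarray:
    """Probability the strategy is cost-effective vs the comparator.

    For each willingness-to-pay value, counts the fraction of PSA
    samples favouring the strategy.  ``mode="nmb"`` counts samples with
    positive incremental net monetary benefit (the unambiguous reading
    of "ICER below threshold", which also counts dominant draws);
    ``mode="icer"`` literally counts defined ICERs below the threshold.
    """
    samples = list(psa_samples)
    if not samples:
        raise ValueError("CEAC requires at least one PSA sample")
    if not len(wtp_grid):
        raise ValueError("CEAC requires a non-empty WTP grid")
    if mode not in ("nmb", "icer"):
        raise ValueError(f"unknown CEAC mode {mode!r}")

    dq = np.empty(len(samples))
    dc = np.empty(len(samples))
    for i, sample in enumerate(samples):
        a = sample.outcomes[strategy_id]
        b = sample.outcomes[comparator_id]
        dq[i] = (a.qalys - b.qalys) * a.population
        dc[i] = (a.cost - b.cost) * a.population

    wtp = np.asarray(wtp_grid, dtype=float)
    if mode == "nmb":
        wins = wtp[:, None] * dq[None, :] - dc[None, :] > 0
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            icer = np.where(dq != 0, dc / dq, np.inf)
        wins = (dq != 0) & (icer[None, :] < wtp[:, None])
    return wins.mean(axis=1)
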