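"""Synthetic chains and independent oracles for engine verification.

The oracles (fundamental-matrix closed form, first-order
microsimulation) deliberately share no transition-assembly or accrual
code with the production engine, so agreement between the two routes is
evidence rather than tautology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (
    ParameterSet,
    SamplingError,
    STAGE_KEYS,
    SIMPLEX_FIELDS,
    validate_parameter_set,
)


@dataclass(frozen=True)
class ToyChain:
    """Small absorbing chain with per-state payoffs.

    The last state is absorbing and reachable from every transient state
    in one step (so truncation error decays geometrically).
    """

    transition: np.ndarray  # (n, n), row-stochastic
    costs: np.ndarray  # (n,)
    utilities: np.ndarray  # (n,)
    seed: int

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]

    @property
    def absorbing(self) -> np.ndarray:
        return np.isclose(np.diag(self.transition), 1.0)


def make_toy_chain(
    n_states: int, seed: int, min_absorb: float = 0.05
) -> ToyChain:
    """Random valid absorbing chain; same seed gives the same chain."""
    if not 2 <= n_states <= 6:
        raise ValueError("toy chains support 2-6 states")
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.ones(n_states), size=n_states)
    # guarantee direct absorption mass from every transient state
    p[:, -1] = np.maximum(p[:, -1], min_absorb)
    p /= p.sum(axis=1, keepdims=True)
    p[-1] = 0.0
    p[-1, -1] = 1.0
    costs = rng.uniform(0, 100, size=n_states)
    utilities = rng.uniform(0, 1, size=n_states)
    costs[-1] = 0.0
    utilities[-1] = 0.0
    return ToyChain(transition=p, costs=costs, utilities=utilities, seed=seed)


def geometric_chain(p_death: float = 0.5, cost: float = 0.0, utility: float = 1.0) -> ToyChain:
    """The 2-state alive/dead chain used in closed-form engine checks."""
    t = np.array([[1 - p_death, p_death], [0.0, 1.0]])
    return ToyChain(
        transition=t,
        costs=np.array([cost, 0.0]),
        utilities=np.array([utility, 0.0]),
        seed=0,
    )


def closed_form_expected_payoff(
    chain: ToyChain, discount_factor: float = 1.0
) -> dict[str, np.ndarray]:
    """Expected discounted totals per transient start state.

    With ``Q`` the transient block and ``beta`` the per-cycle discount
    factor, expected discounted cycles-in-state are the rows of
    ``(I - beta Q)^-1``; payoffs follow by dot products.  Valid when the
    spectral radius of ``beta Q`` is below 1.
    """
    absorbing = chain.absorbing
    transient = ~absorbing
    q = chain.transition[np.ix_(transient, transient)]
    beta = float(discount_factor)
    radius = np.max(np.abs(np.linalg.eigvals(beta * q)))
    if radius >= 1:
        raise ValueError(f"spectral radius {radius} >= 1, series diverges")
    n = np.linalg.inv(np.eye(q.shape[0]) - beta * q)
    return {
        "visits": n,
        "cost": n @ chain.costs[transient],
        "life_years": n @ np.ones(q.shape[0]),
        "qaly": n @ chain.utilities[transient],
    }


def microsim_trace(
    chain: ToyChain,
    n_individuals: int,
    seed: int,
    n_cycles: int = 60,
    start: int = 0,
) -> dict[str, np.ndarray]:
    """First-order simulation of individual paths through a chain.

    Returns per-cycle empirical occupancy fractions with their binomial
    standard errors.  Fully vectorized over individuals; same seed gives
    identical traces.
    """
    if n_individuals < 1:
        raise ValueError("need at least one simulated individual")
    rng = np.random.default_rng(seed)
    n = chain.n_states
    cdf = np.cumsum(chain.transition, axis=1)
    state = np.full(n_individuals, start, dtype=np.int64)
    occupancy = np.zeros((n_cycles, n))
    for t in range(n_cycles):
        occupancy[t] = np.bincount(state, minlength=n) / n_individuals
        if t < n_cycles - 1:
            u = rng.random(n_individuals)
            state = (u[:, None] > cdf[state]).sum(axis=1)
    se = np.sqrt(occupancy * (1 - occupancy) / n_individuals)
    return {"occupancy": occupancy, "se": se}


def microsim_payoffs(
    chain: ToyChain,
    n_individuals: int,
    seed: int,
    n_cycles: int = 60,
    discount_rate: float = 0.0,
    start: int = 0,
) -> dict[str, float]:
    """Mean discounted per-person payoffs from simulated paths, with SEs."""
    rng = np.random.default_rng(seed)
    n = chain.n_states
    cdf = np.cumsum(chain.transition, axis=1)
    absorbing = chain.absorbing
    state = np.full(n_individuals, start, dtype=np.int64)
    cost = np.zeros(n_individuals)
    ly = np.zeros(n_individuals)
    qaly = np.zeros(n_individuals)
    for t in range(n_cycles):
        beta = (1.0 + discount_rate) ** (-t)
        cost += beta * chain.costs[state]
        ly += beta * (~absorbing[state]).astype(float)
        qaly += beta * chain.utilities[state]
        if absorbing[state].all():
            break  # absorbed paths accrue nothing further
        if t < n_cycles - 1:
            u = rng.random(n_individuals)
            state = (u[:, None] > cdf[state]).sum(axis=1)
    out = {}
    for name, v in (("cost", cost), ("life_years", ly), ("qaly", qaly)):
        out[name] = float(v.mean())
        out[name + "_se"] = float(v.std(ddof=1) / np.sqrt(n_individuals))
    return out


def microsim_cohort_trace(
    entry_age: int,
    sex: str,
    relative_risk: float,
    strategy,
    params: ParameterSet,
    n_individuals: int,
    seed: int,
) -> dict[str, np.ndarray]:
    """First-order simulation of one cohort stratum of the full model.

    Samples individual paths through the same per-age matrices the
    cohort engine multiplies, providing a sampling-based check of the
    trace propagation.  Returns occupancy fractions and binomial SEs.
    """
    from .natural_history import build_transition_matrix
    from .screening import apply_screening_overlay

    if n_individuals < 1:
        raise ValueError("need at least one simulated individual")
    rng = np.random.default_rng(seed)
    n_cycles = params.max_age - entry_age + 1
    n = 12
    state = np.zeros(n_individuals, dtype=np.int64)
    occupancy = np.zeros((n_cycles, n))
    for t in range(n_cycles):
        occupancy[t] = np.bincount(state, minlength=n) / n_individuals
        if t == n_cycles - 1:
            break
        age = entry_age + t
        overlay = apply_screening_overlay(age, sex, strategy, t, relative_risk, params)
        matrix = build_transition_matrix(
            age, sex, overlay.context(relative_risk), params
        ).probs
        cdf = np.cumsum(matrix, axis=1)
        u = rng.random(n_individuals)
        state = (u[:, None] > cdf[state]).sum(axis=1)
    se = np.sqrt(occupancy * (1 - occupancy) / n_individuals)
    return {"occupancy": occupancy, "se": se}


def perturb_parameters(
    params: ParameterSet, scale: float, seed: int
) -> ParameterSet:
    """Multiplicative jitter of magnitude <= ``scale`` on numeric inputs.

    Probabilities are clipped to [0, 1] and simplex vectors renormalized
    afterwards, so any jittered set remains valid.  ``scale = 0`` is the
    identity.
    """
    if scale < 0:
        raise ValueError("scale must be >= 0")
    if scale == 0:
        return params.copy()
    rng = np.random.default_rng(seed)
    out = params.copy()

    def jitter(x: float) -> float:
        return x * (1.0 + rng.uniform(-scale, scale))

    for band, by_sex in out.incidence_per_100k.items():
        for sex in by_sex:
            by_sex[sex] = min(jitter(by_sex[sex]), 100_000.0)
    out.rr_20py = jitter(out.rr_20py)
    out.rr_30py = jitter(out.rr_30py)
    for name in ("sens_ldct", "spec_ldct", "sens_msc_conj", "spec_msc_conj"):
        setattr(out, name, float(np.clip(jitter(getattr(out, name)), 0.0, 1.0)))
    for band in out.allcause_mort:
        out.allcause_mort[band] = float(np.clip(jitter(out.allcause_mort[band]), 0, 1))
    for band in out.lc_mort_per_100k:
        out.lc_mort_per_100k[band] = min(jitter(out.lc_mort_per_100k[band]), 100_000.0)
    for src in STAGE_KEYS:
        for dst in out.stage_prog[src]:
            out.stage_prog[src][dst] = float(np.clip(jitter(out.stage_prog[src][dst]), 0, 1))
        out.stage_death[src] = float(np.clip(jitter(out.stage_death[src]), 0, 1))
        total = out.stage_death[src] + sum(out.stage_prog[src].values())
        if total > 1.0:
            out.stage_death[src] /= total
            for dst in out.stage_prog[src]:
                out.stage_prog[src][dst] /= total
        out.utility[src] = float(np.clip(jitter(out.utility[src]), 0, 1))
        out.cost_treat[src] = max(jitter(out.cost_treat[src]), 0.0)
    for name in ("cost_ldct", "cost_msc", "cost_prediag", "cost_biopsy"):
        setattr(out, name, max(jitter(getattr(out, name)), 0.0))
    out.maintenance_fraction = float(np.clip(jitter(out.maintenance_fraction), 0, 1))
    for name in SIMPLEX_FIELDS:
        vec = getattr(out, name)
        for key in vec:
            vec[key] = float(np.clip(jitter(vec[key]), 0, 1))
        total = sum(vec.values())
        if total <= 0:
            raise SamplingError(f"{name}: jittered vector collapsed to zero")
        for key in vec:
            vec[key] /= total

    violations = validate_parameter_set(out)
    if violations:
        raise SamplingError(f"perturbed set invalid: {violations[0]}")
    return out
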