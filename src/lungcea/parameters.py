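"""Typed, validated model inputs and their sampling distributions.

The complete input vector (incidence, test performance, transition
probabilities, utilities, costs, settings) lives in a single
:class:`ParameterSet`.  The packaged defaults in ``data/defaults.yaml``
reproduce the published input table; fields the analysis needs but the
source never printed are shipped as clearly labelled fixture defaults.

Probabilistic sensitivity analysis draws each uncertain field from a
beta (probabilities, utilities) or gamma (costs, relative risks)
distribution parameterized by method of moments from a (mean, se) pair.
"""

from __future__ import annotations

import copy
import hashlib
import importlib.resources
import json
import math
from dataclasses import MISSING as dataclass_MISSING
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Any, Iterator

import numpy as np
import yaml

from .states import (
    HealthState,
    LABEL_TO_STAGE,
    STAGE_LABELS,
    validate_band_partition,
)

SCHEMA_VERSION = 1

STAGE_KEYS = ["CIS", "StageI", "StageII", "StageIII", "StageIV"]
INCIDENCE_BANDS = ["50-54", "55-59", "60-64", "65-69", "70-74"]
MORTALITY_BANDS = INCIDENCE_BANDS + ["75-79"]
SEXES = ("female", "male")

#: Fields holding probability vectors that must lie on the unit simplex.
SIMPLEX_FIELDS = ("detect_stage_ldct", "detect_stage_ldct_msc", "clinical_stage_dist")


class ParameterError(ValueError):
    """Base class for parameter loading/validation problems."""


class MissingParameterError(ParameterError):
    def __init__(self, keys):
        self.keys = sorted(keys)
        super().__init__(f"missing required parameter(s): {', '.join(self.keys)}")


class UnknownParameterError(ParameterError):
    def __init__(self, keys):
        self.keys = sorted(keys)
        super().__init__(f"unknown parameter key(s): {', '.join(self.keys)}")


class ValidationError(ParameterError):
    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        msg = "; ".join(str(v) for v in violations)
        super().__init__(f"invalid parameter set: {msg}")


class SamplingError(ParameterError):
    """A PSA draw could not be repaired into a valid parameter set."""


@dataclass(frozen=True)
class Violation:
    """A single validation failure: which field, what value, which rule."""

    field: str
    value: Any
    rule: str

    def __str__(self) -> str:
        return f"{self.field}={self.value!r} violates: {self.rule}"


@dataclass
class ParameterSet:
    """Complete model input vector.

    Rates are stored exactly as published (per 100,000 person-years);
    conversion to annual probabilities happens at the point of use.
    Costs are CNY at the 2018 price level.
    """

    incidence_per_100k: dict[str, dict[str, float]]
    rr_20py: float
    rr_30py: float
    detect_stage_ldct: dict[str, float]
    detect_stage_ldct_msc: dict[str, float]
    sens_ldct: float
    spec_ldct: float
    sens_msc_conj: float
    spec_msc_conj: float
    allcause_mort: dict[str, float]
    lc_mort_per_100k: dict[str, float]
    stage_prog: dict[str, dict[str, float]]
    stage_death: dict[str, float]
    utility: dict[str, float]
    utility_normal: float
    utility_death: float
    cost_ldct: float
    cost_msc: float
    cost_prediag: float
    cost_biopsy: float
    cost_treat: dict[str, float]
    maintenance_fraction: float
    discount_rate: float
    discount_effects: bool
    cycle_length: float
    max_age: int
    stop_screen_age: int
    wtp_gdp: float
    price_year: int
    cpi_rate: float
    eligible_fraction_20py: float
    eligible_fraction_30py: float
    clinical_stage_dist: dict[str, float]
    male_fraction: float
    rate_conversion: str = "linear"
    maintenance_recurrence: float = 0.0
    fp_workup_biopsy: bool = False
    msc_cost_all_screened: bool = False
    subtract_lc_mortality: bool = False
    half_cycle_correction: bool = False
    schema_version: int = SCHEMA_VERSION

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return copy.deepcopy({f.name: getattr(self, f.name) for f in fields(self)})

    @classmethod
    def from_dict(cls, raw: dict) -> "ParameterSet":
        known = {f.name for f in fields(cls)}
        required = {f.name for f in fields(cls) if f.default is dataclass_MISSING}
        unknown = set(raw) - known
        if unknown:
            raise UnknownParameterError(unknown)
        missing = required - set(raw)
        if missing:
            raise MissingParameterError(missing)
        return cls(**copy.deepcopy(raw))

    def copy(self) -> "ParameterSet":
        return ParameterSet.from_dict(self.to_dict())

    def digest(self) -> str:
        """Stable content hash, used to prove sweeps restore the base set."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    # -- convenience accessors ---------------------------------------

    def stage_utility(self, state: HealthState) -> float:
        """Utility weight for any of the 12 states.

        Maintenance states inherit the utility of their partner stage.
        """
        from .states import STAGE_OF_MAINTENANCE

        if state is HealthState.NORMAL:
            return self.utility_normal
        if state is HealthState.DEATH:
            return self.utility_death
        if state.is_maintenance:
            state = STAGE_OF_MAINTENANCE[state]
        return self.utility[STAGE_LABELS[state]]

    def utility_vector(self) -> np.ndarray:
        return np.array([self.stage_utility(HealthState(i)) for i in range(12)])

    def treat_cost_vector(self) -> np.ndarray:
        """Per-state one-off treatment cost charged at stage entry."""
        v = np.zeros(12)
        for key, st in LABEL_TO_STAGE.items():
            v[st] = self.cost_treat[key]
        return v

    def maintenance_cost_vector(self) -> np.ndarray:
        """Per-state annual maintenance cost (non-zero on maintenance states)."""
        from .states import MAINTENANCE_OF

        v = np.zeros(12)
        for stage, maint in MAINTENANCE_OF.items():
            v[maint] = maintenance_cost(stage, self)
        return v


def maintenance_cost(stage: HealthState | str, params: ParameterSet) -> float:
    """Annual follow-up cost after treatment of ``stage``.

    Defined as ``maintenance_fraction`` (default 10%) of the one-off
    treatment cost for that stage.
    """
    if isinstance(stage, str):
        if stage not in LABEL_TO_STAGE:
            raise ParameterError(f"{stage!r} is not a cancer stage")
        key = stage
    else:
        if not stage.is_cancer_stage:
            raise ParameterError(f"{stage.name} is not a cancer stage")
        key = STAGE_LABELS[stage]
    return params.maintenance_fraction * params.cost_treat[key]


# ---------------------------------------------------------------------------
# loading / validation


def default_parameter_path() -> Path:
    return Path(str(importlib.resources.files("lungcea") / "data" / "defaults.yaml"))


def load_parameter_set(config_source: str | Path | dict | None = None) -> ParameterSet:
    """Load and validate a parameter set.

    ``config_source`` may be a YAML file path, an already-parsed mapping,
    or ``None`` for the packaged defaults.  Unknown keys and missing keys
    are hard errors; so is any validation failure.
    """
    if config_source is None:
        config_source = default_parameter_path()
    if isinstance(config_source, (str, Path)):
        path = Path(config_source)
        if not path.exists():
            raise ParameterError(f"parameter file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = copy.deepcopy(dict(config_source))
    if not isinstance(raw, dict):
        raise ParameterError("parameter config must be a mapping")
    params = ParameterSet.from_dict(raw)
    violations = validate_parameter_set(params)
    if violations:
        raise ValidationError(violations)
    return params


def save_parameter_set(params: ParameterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def _check_prob(name: str, value: float, out: list[Violation]) -> None:
    if not (0.0 <= value <= 1.0):
        out.append(Violation(name, value, "probability must lie in [0, 1]"))


def validate_parameter_set(params: ParameterSet) -> list[Violation]:
    """Return every invariant violation (empty list means valid)."""
    v: list[Violation] = []

    for band in INCIDENCE_BANDS:
        for sex in SEXES:
            rate = params.incidence_per_100k.get(band, {}).get(sex)
            if rate is None:
                v.append(Violation(f"incidence_per_100k.{band}.{sex}", None, "missing"))
            elif not (0 <= rate <= 100_000):
                v.append(
                    Violation(
                        f"incidence_per_100k.{band}.{sex}",
                        rate,
                        "rate must lie in [0, 100000]",
                    )
                )
    for name in ("rr_20py", "rr_30py"):
        if getattr(params, name) <= 0:
            v.append(Violation(name, getattr(params, name), "relative risk must be > 0"))

    for name in SIMPLEX_FIELDS:
        vec = getattr(params, name)
        missing = set(STAGE_KEYS) - set(vec)
        if missing:
            v.append(Violation(name, sorted(missing), "missing stage entries"))
            continue
        for key in STAGE_KEYS:
            _check_prob(f"{name}.{key}", vec[key], v)
        total = sum(vec[key] for key in STAGE_KEYS)
        if abs(total - 1.0) > 1e-9:
            v.append(Violation(name, total, f"sums to {total} != 1"))

    for name in ("sens_ldct", "spec_ldct", "sens_msc_conj", "spec_msc_conj"):
        _check_prob(name, getattr(params, name), v)

    v.extend(
        Violation("allcause_mort", b, p)
        for b, p in _band_problems(params.allcause_mort, MORTALITY_BANDS, 50, 79)
    )
    for band in MORTALITY_BANDS:
        if band in params.allcause_mort:
            _check_prob(f"allcause_mort.{band}", params.allcause_mort[band], v)
    v.extend(
        Violation("lc_mort_per_100k", b, p)
        for b, p in _band_problems(params.lc_mort_per_100k, INCIDENCE_BANDS, 50, 74)
    )

    for src in STAGE_KEYS:
        row = params.stage_prog.get(src)
        if row is None:
            v.append(Violation(f"stage_prog.{src}", None, "missing row"))
            continue
        for dst, p in row.items():
            if dst not in STAGE_KEYS or STAGE_KEYS.index(dst) <= STAGE_KEYS.index(src):
                v.append(Violation(f"stage_prog.{src}", dst, "progression must go to a worse stage"))
            _check_prob(f"stage_prog.{src}.{dst}", p, v)
        death = params.stage_death.get(src)
        if death is None:
            v.append(Violation(f"stage_death.{src}", None, "missing"))
            continue
        _check_prob(f"stage_death.{src}", death, v)
        total_out = death + sum(row.values())
        if total_out > 1.0 + 1e-12:
            v.append(
                Violation(
                    f"stage_prog.{src}+stage_death.{src}",
                    total_out,
                    "death + progression exceeds 1",
                )
            )

    for key in STAGE_KEYS:
        u = params.utility.get(key)
        if u is None:
            v.append(Violation(f"utility.{key}", None, "missing"))
        else:
            _check_prob(f"utility.{key}", u, v)
    _check_prob("utility_normal", params.utility_normal, v)
    _check_prob("utility_death", params.utility_death, v)

    for name in ("cost_ldct", "cost_msc", "cost_prediag", "cost_biopsy"):
        if getattr(params, name) < 0:
            v.append(Violation(name, getattr(params, name), "cost must be >= 0"))
    for key in STAGE_KEYS:
        c = params.cost_treat.get(key)
        if c is None:
            v.append(Violation(f"cost_treat.{key}", None, "missing"))
        elif c < 0:
            v.append(Violation(f"cost_treat.{key}", c, "cost must be >= 0"))

    _check_prob("maintenance_fraction", params.maintenance_fraction, v)
    _check_prob("maintenance_recurrence", params.maintenance_recurrence, v)
    _check_prob("male_fraction", params.male_fraction, v)
    _check_prob("eligible_fraction_20py", params.eligible_fraction_20py, v)
    _check_prob("eligible_fraction_30py", params.eligible_fraction_30py, v)
    if params.eligible_fraction_30py > params.eligible_fraction_20py + 1e-12:
        v.append(
            Violation(
                "eligible_fraction_30py",
                params.eligible_fraction_30py,
                "30 pack-year smokers are a subset of 20 pack-year smokers",
            )
        )

    if params.discount_rate < 0:
        v.append(Violation("discount_rate", params.discount_rate, "must be >= 0"))
    if params.cycle_length <= 0:
        v.append(Violation("cycle_length", params.cycle_length, "must be > 0"))
    if params.stop_screen_age > params.max_age:
        v.append(Violation("stop_screen_age", params.stop_screen_age, "exceeds max_age"))
    if params.rate_conversion not in ("linear", "exponential"):
        v.append(Violation("rate_conversion", params.rate_conversion, "unknown mode"))
    return v


def _band_problems(table: dict, bands: list[str], lo: int, hi: int):
    missing = [b for b in bands if b not in table]
    for b in missing:
        yield b, "missing band"
    if not missing:
        for p in validate_band_partition(list(table), lo, hi):
            yield "-", p


# ---------------------------------------------------------------------------
# PSA distributions


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution for one uncertain input.

    ``family`` is ``"beta"``, ``"gamma"`` or ``"point"``; ``mean`` and
    ``se`` are on the natural scale of the target (an optional ``scale``
    maps a unit-interval beta draw onto, e.g., a per-100,000 rate).
    """

    family: str
    mean: float
    se: float
    scale: float = 1.0

    def __post_init__(self):
        if self.family not in ("beta", "gamma", "point"):
            raise ParameterError(f"unknown distribution family {self.family!r}")
        if self.se < 0:
            raise ParameterError("se must be >= 0")
        if self.family == "point" and self.se != 0:
            raise ParameterError("point distribution requires se = 0")
        if self.se > 0:
            unit_mean = self.mean / self.scale
            if self.family == "beta" and not (0 < unit_mean < 1):
                raise ParameterError(
                    f"beta requires mean/scale in (0,1), got {unit_mean}"
                )
            if self.family == "gamma" and self.mean <= 0:
                raise ParameterError(f"gamma requires mean > 0, got {self.mean}")

    @property
    def shape_params(self) -> tuple[float, float]:
        """Method-of-moments (alpha, beta) or (shape, scale) parameters."""
        if self.family == "beta":
            m = self.mean / self.scale
            var = (self.se / self.scale) ** 2
            if var >= m * (1 - m):
                raise ParameterError(
                    f"beta variance {var} >= mean(1-mean) = {m * (1 - m)}"
                )
            c = m * (1 - m) / var - 1.0
            return m * c, (1 - m) * c
        if self.family == "gamma":
            shape = (self.mean / self.se) ** 2
            scale = self.se**2 / self.mean
            return shape, scale
        raise ParameterError("point distribution has no shape parameters")

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "point" or self.se == 0:
            return self.mean
        a, b = self.shape_params
        if self.family == "beta":
            return float(rng.beta(a, b)) * self.scale
        return float(rng.gamma(a, b))


def make_distribution(
    family: str, mean: float, se: float, scale: float = 1.0
) -> DistributionSpec:
    """Build a method-of-moments sampling spec; ``se = 0`` is a point mass."""
    if se == 0:
        return DistributionSpec("point", mean, 0.0, scale)
    return DistributionSpec(family, mean, se, scale)


#: Width of a symmetric 95% interval in standard errors.
_Z95_WIDTH = 2 * 1.959963984540054

#: Deterministic-sweep ranges used to calibrate test-performance SEs.
_SENS_SPEC_RANGES = {
    "sens_ldct": (0.63, 0.95),
    "spec_ldct": (0.65, 0.97),
    "sens_msc_conj": (0.41, 0.98),
    "spec_msc_conj": (0.81, 0.99),
}


def default_distribution_table(
    params: ParameterSet,
    cost_se_fraction: float = 0.25,
    prob_se_fraction: float = 0.10,
) -> dict[str, DistributionSpec]:
    """Distribution per PSA-varied field, keyed by parameter path.

    The published table names the families (beta for probabilities and
    utilities, gamma for costs) but not the standard errors; defaults are
    ``cost_se_fraction`` of the mean for gamma fields and, for beta fields,
    either the value implied by the printed deterministic range (test
    sensitivity/specificity) or ``prob_se_fraction`` of the mean.  Relative
    risks exceed 1 and therefore use gamma despite the printed family.
    Zero-valued means are kept as point masses.
    """

    def beta(path, mean, se=None, scale=1.0):
        if mean <= 0 or mean / scale >= 1:
            return make_distribution("point", mean, 0.0, scale)
        if se is None:
            se = prob_se_fraction * mean
        se = min(se, 0.999 * scale * math.sqrt((mean / scale) * (1 - mean / scale)))
        return make_distribution("beta", mean, se, scale)

    def gamma(path, mean, frac):
        if mean <= 0:
            return make_distribution("point", mean, 0.0)
        return make_distribution("gamma", mean, frac * mean)

    table: dict[str, DistributionSpec] = {}
    for band in INCIDENCE_BANDS:
        for sex in SEXES:
            path = f"incidence_per_100k.{band}.{sex}"
            rate = params.incidence_per_100k[band][sex]
            table[path] = beta(path, rate, scale=100_000.0)
    table["rr_20py"] = gamma("rr_20py", params.rr_20py, prob_se_fraction)
    table["rr_30py"] = gamma("rr_30py", params.rr_30py, prob_se_fraction)
    for name in ("detect_stage_ldct", "detect_stage_ldct_msc"):
        vec = getattr(params, name)
        for key in STAGE_KEYS:
            table[f"{name}.{key}"] = beta(f"{name}.{key}", vec[key])
    for name, (lo, hi) in _SENS_SPEC_RANGES.items():
        table[name] = beta(name, getattr(params, name), se=(hi - lo) / _Z95_WIDTH)
    for band in MORTALITY_BANDS:
        table[f"allcause_mort.{band}"] = beta(
            f"allcause_mort.{band}", params.allcause_mort[band]
        )
    for band in INCIDENCE_BANDS:
        table[f"lc_mort_per_100k.{band}"] = beta(
            f"lc_mort_per_100k.{band}", params.lc_mort_per_100k[band], scale=100_000.0
        )
    for src in STAGE_KEYS:
        for dst, p in params.stage_prog[src].items():
            table[f"stage_prog.{src}.{dst}"] = beta(f"stage_prog.{src}.{dst}", p)
        table[f"stage_death.{src}"] = beta(
            f"stage_death.{src}", params.stage_death[src]
        )
    for key in STAGE_KEYS:
        table[f"utility.{key}"] = beta(f"utility.{key}", params.utility[key])
    for name in ("cost_ldct", "cost_msc", "cost_prediag", "cost_biopsy"):
        table[name] = gamma(name, getattr(params, name), cost_se_fraction)
    for key in STAGE_KEYS:
        table[f"cost_treat.{key}"] = gamma(
            f"cost_treat.{key}", params.cost_treat[key], cost_se_fraction
        )
    table["maintenance_fraction"] = beta(
        "maintenance_fraction", params.maintenance_fraction
    )
    return table


def point_mass_table(params: ParameterSet) -> dict[str, DistributionSpec]:
    """Degenerate distribution table: every PSA draw returns the base case."""
    return {
        path: make_distribution("point", spec.mean, 0.0, spec.scale)
        for path, spec in default_distribution_table(params).items()
    }


# ---------------------------------------------------------------------------
# parameter paths


def get_param(params: ParameterSet, path: str):
    """Resolve a dotted path like ``"cost_treat.StageI"``."""
    obj: Any = params
    for part in path.split("."):
        if isinstance(obj, dict):
            if part not in obj:
                raise ParameterError(f"path {path!r}: no key {part!r}")
            obj = obj[part]
        else:
            if not hasattr(obj, part):
                raise ParameterError(f"path {path!r}: no field {part!r}")
            obj = getattr(obj, part)
    return obj


def set_param(params: ParameterSet, path: str, value) -> None:
    """Set a dotted path in place (callers copy first when needed)."""
    parts = path.split(".")
    obj: Any = params
    for part in parts[:-1]:
        if isinstance(obj, dict):
            if part not in obj:
                raise ParameterError(f"path {path!r}: no key {part!r}")
            obj = obj[part]
        else:
            if not hasattr(obj, part):
                raise ParameterError(f"path {path!r}: no field {part!r}")
            obj = getattr(obj, part)
    last = parts[-1]
    if isinstance(obj, dict):
        if last not in obj:
            raise ParameterError(f"path {path!r}: no key {last!r}")
        obj[last] = value
    else:
        if not hasattr(obj, last):
            raise ParameterError(f"path {path!r}: no field {last!r}")
        setattr(obj, last, value)


# ---------------------------------------------------------------------------
# PSA sampling


def sample_parameter_set(
    params: ParameterSet,
    dist_table: dict[str, DistributionSpec],
    rng_seed: int | np.random.Generator,
) -> ParameterSet:
    """Draw one PSA parameter vector.

    Fields are drawn independently in sorted path order (so a seed fully
    determines the draw), simplex-valued stage-distribution vectors are
    renormalized after element-wise draws, and stage outflow rows whose
    death + progression mass exceeds 1 are proportionally rescaled.  The
    result must re-validate or a :class:`SamplingError` is raised.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    out = params.copy()
    for path in sorted(dist_table):
        set_param(out, path, dist_table[path].sample(rng))

    for name in SIMPLEX_FIELDS:
        vec = getattr(out, name)
        total = sum(vec.values())
        if total <= 0:
            raise SamplingError(f"{name}: drawn vector sums to {total}, cannot renormalize")
        if abs(total - 1.0) > 1e-12:
            for key in vec:
                vec[key] = vec[key] / total

    for src in STAGE_KEYS:
        row = out.stage_prog[src]
        total_out = out.stage_death[src] + sum(row.values())
        if total_out > 1.0:
            # proportional repair keeps relative hazards, caps total at 1
            factor = 1.0 / total_out
            out.stage_death[src] *= factor
            for dst in row:
                row[dst] *= factor

    violations = validate_parameter_set(out)
    if violations:
        raise SamplingError(
            f"sampled set failed validation: {violations[0]}"
        )
    return out


def iter_psa_parameter_sets(
    params: ParameterSet,
    dist_table: dict[str, DistributionSpec],
    seed: int,
    n_iter: int,
) -> Iterator[tuple[int, ParameterSet]]:
    """Index-seeded PSA draws: draw ``i`` uses generator seed ``(seed, i)``.

    Draw order therefore never affects results.
    """
    for i in range(n_iter):
        yield i, sample_parameter_set(params, dist_table, np.random.default_rng([seed, i]))
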