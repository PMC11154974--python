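"""Model inputs: loading, validation and sampling-distribution fitting.

The base case compares endovascular treatment (EVT) alone against EVT plus
intravenous thrombolysis (IVT) for acute ischemic stroke.  Inputs are the
3-month modified Rankin Scale (mRS) outcome proportions per arm, first-year
transition probabilities between the independent (mRS 0-2) and dependent
(mRS 3-5) states, an annual recurrence rate, direct treatment costs with
95% intervals, annual post-hospitalisation costs, an indirect human-capital
cost valued through disability-adjusted life years (DALYs), health-state
utilities, and economic settings (3% annual discounting, quarterly cycles,
willingness-to-pay bounds of RMB 90,620 and 271,860 per QALY).

For probabilistic sensitivity analysis the printed means and 95% intervals
are turned into sampling distributions by method of moments: Gamma for
costs, Beta for utilities and the recurrence rate, Dirichlet for the
outcome/transition simplexes.  Intervals are read as symmetric normal-theory
ranges, sd = (hi - lo) / 3.92.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "CI_WIDTH_IN_SD",
    "ConfigurationError",
    "ValidationError",
    "ValueWithCI",
    "MRSDistribution",
    "TransitionInputs",
    "ArmParameters",
    "CostParameters",
    "UtilityParameters",
    "EconomicSettings",
    "DistributionSpec",
    "ModelParameters",
    "load_parameters",
    "parameters_from_dict",
    "annual_to_cycle_probability",
    "residual_death_probability",
    "gamma_from_mean_ci",
    "beta_from_mean_ci",
    "dirichlet_from_proportions",
    "compute_indirect_cost",
]

#: Width of a symmetric 95% interval in units of the standard deviation.
CI_WIDTH_IN_SD = 3.92

SIMPLEX_TOL = 1e-9

ARM_KEYS = ("evt", "evt_ivt")

INDIRECT_MODES = ("excluded", "lump_sum", "per_death")


class ConfigurationError(Exception):
    """A required configuration key is missing or not parseable."""


class ValidationError(ValueError):
    """A parameter value violates its documented bounds."""


def _get(cfg: Mapping, *keys: str, prefix: str = "") -> Any:
    """Walk a nested mapping, raising a ConfigurationError naming the path."""
    node: Any = cfg
    trail: list[str] = [prefix] if prefix else []
    for key in keys:
        trail.append(str(key))
        if not isinstance(node, Mapping) or key not in node:
            raise ConfigurationError(
                "missing configuration key '%s'" % ".".join(trail)
            )
        node = node[key]
    return node


def _number(value: Any, name: str) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigurationError(f"key '{name}' is not numeric: {value!r}")
    return float(value)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ValueWithCI:
    """A point estimate with an optional 95% interval bracketing the mean."""

    mean: float
    lo: float | None = None
    hi: float | None = None

    def validate(self, name: str, lower: float = 0.0,
                 upper: float = math.inf) -> None:
        if not (lower <= self.mean <= upper):
            raise ValidationError(
                f"{name}.mean = {self.mean} outside [{lower}, {upper}]")
        if (self.lo is None) != (self.hi is None):
            raise ValidationError(
                f"{name}: interval needs both bounds or neither")
        if self.lo is not None and self.hi is not None:
            if not (self.lo <= self.mean <= self.hi):
                raise ValidationError(
                    f"{name}: interval [{self.lo}, {self.hi}] does not "
                    f"bracket the mean {self.mean}")
            if self.lo < lower or self.hi > upper:
                raise ValidationError(
                    f"{name}: interval outside [{lower}, {upper}]")

    def scaled(self, factor: float) -> "ValueWithCI":
        """Return a copy with mean and bounds multiplied by ``factor``."""
        return ValueWithCI(
            self.mean * factor,
            None if self.lo is None else self.lo * factor,
            None if self.hi is None else self.hi * factor,
        )

    def to_dict(self) -> dict:
        out = {"mean": self.mean}
        if self.lo is not None:
            out["lo"] = self.lo
            out["hi"] = self.hi
        return out


@dataclass
class MRSDistribution:
    """Probabilities over {mRS 0-2, mRS 3-5, death} at the 3-month mark."""

    p_good: float
    p_poor: float
    p_dead: float

    def validate(self, name: str = "mrs_3m") -> None:
        for label, p in (("p_good", self.p_good), ("p_poor", self.p_poor),
                         ("p_dead", self.p_dead)):
            if not (0.0 <= p <= 1.0):
                raise ValidationError(
                    f"{name}.{label} = {p} outside [0, 1]")
        total = self.p_good + self.p_poor + self.p_dead
        if abs(total - 1.0) > SIMPLEX_TOL:
            raise ValidationError(
                f"{name}: probabilities sum to {total!r}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_good, self.p_poor, self.p_dead])

    def to_dict(self) -> dict:
        return {"good": self.p_good, "poor": self.p_poor, "dead": self.p_dead}


@dataclass
class TransitionInputs:
    """First-year quarterly transition probabilities and annual recurrence.

    Death is not an input: it is the residual mass of each row (see
    :func:`residual_death_probability`).
    """

    p_good_to_good: float
    p_good_to_poor: float
    p_poor_to_good: float
    p_poor_to_poor: float
    recurrence_annual: float

    def validate(self, name: str = "transitions") -> None:
        for label, p in (
                ("p_good_to_good", self.p_good_to_good),
                ("p_good_to_poor", self.p_good_to_poor),
                ("p_poor_to_good", self.p_poor_to_good),
                ("p_poor_to_poor", self.p_poor_to_poor)):
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"{name}.{label} = {p} outside [0, 1]")
        if self.p_good_to_good + self.p_good_to_poor > 1.0 + SIMPLEX_TOL:
            raise ValidationError(f"{name}: mRS 0-2 outflows exceed 1")
        if self.p_poor_to_good + self.p_poor_to_poor > 1.0 + SIMPLEX_TOL:
            raise ValidationError(f"{name}: mRS 3-5 outflows exceed 1")
        if not (0.0 <= self.recurrence_annual < 1.0):
            raise ValidationError(
                f"{name}.recurrence_annual = {self.recurrence_annual} "
                "outside [0, 1)")

    def to_dict(self) -> dict:
        return {
            "good_to_good": self.p_good_to_good,
            "good_to_poor": self.p_good_to_poor,
            "poor_to_good": self.p_poor_to_good,
            "poor_to_poor": self.p_poor_to_poor,
            "recurrence_annual": self.recurrence_annual,
        }


@dataclass
class ArmParameters:
    """Per-arm inputs: 3-month outcomes and direct treatment costs."""

    name: str
    label: str
    mrs_3m: MRSDistribution
    direct_treatment: ValueWithCI
    components: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        self.mrs_3m.validate(f"{self.name}.mrs_3m")
        self.direct_treatment.validate(f"{self.name}.direct_treatment")
        total = 0.0
        for key, value in self.components.items():
            if value < 0:
                raise ValidationError(
                    f"{self.name}.components.{key} = {value} is negative")
            total += value
        if total > self.direct_treatment.mean + 1e-6:
            raise ValidationError(
                f"{self.name}: component sum {total} exceeds direct "
                f"treatment mean {self.direct_treatment.mean}")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "mrs_3m": self.mrs_3m.to_dict(),
            "direct_treatment": self.direct_treatment.to_dict(),
            "components": dict(self.components),
        }


@dataclass
class CostParameters:
    """Shared cost inputs (RMB): post-hospitalisation, indirect, DALYs."""

    post_hosp_annual_good: ValueWithCI
    post_hosp_annual_poor: ValueWithCI
    indirect_total: float
    dalys: float
    value_per_daly: float

    def validate(self) -> None:
        self.post_hosp_annual_good.validate("costs.post_hosp_annual_good")
        self.post_hosp_annual_poor.validate("costs.post_hosp_annual_poor")
        for label, value in (("indirect_total", self.indirect_total),
                             ("dalys", self.dalys),
                             ("value_per_daly", self.value_per_daly)):
            if value < 0:
                raise ValidationError(f"costs.{label} = {value} is negative")

    def to_dict(self) -> dict:
        return {
            "post_hosp_annual_good": self.post_hosp_annual_good.to_dict(),
            "post_hosp_annual_poor": self.post_hosp_annual_poor.to_dict(),
            "indirect_total": self.indirect_total,
            "dalys": self.dalys,
            "value_per_daly": self.value_per_daly,
        }


@dataclass
class UtilityParameters:
    """Health-state utilities on the 0 (death) to 1 (full health) scale."""

    u_good: ValueWithCI
    u_poor: ValueWithCI
    u_recurrent: ValueWithCI
    u_dead: float = 0.0

    def validate(self) -> None:
        self.u_good.validate("utilities.good", 0.0, 1.0)
        self.u_poor.validate("utilities.poor", 0.0, 1.0)
        self.u_recurrent.validate("utilities.recurrent", 0.0, 1.0)
        if self.u_dead != 0.0:
            raise ValidationError(
                f"utilities.dead = {self.u_dead}; death utility must be 0")

    def to_dict(self) -> dict:
        return {
            "good": self.u_good.to_dict(),
            "poor": self.u_poor.to_dict(),
            "dead": self.u_dead,
            "recurrent": self.u_recurrent.to_dict(),
        }


@dataclass
class EconomicSettings:
    """Discounting, cycle structure, WTP thresholds and run caps."""

    discount_annual: float = 0.03
    cycle_length: float = 0.25
    wtp_low: float = 90620.0
    wtp_high: float = 271860.0
    termination_mortality: float = 0.99
    max_cycles: int = 200
    base_year: int = 2023
    median_age_evt: float = 71.0
    median_age_evt_ivt: float = 70.0

    @property
    def cycles_per_year(self) -> int:
        return int(round(1.0 / self.cycle_length))

    def validate(self) -> None:
        if not (0.0 <= self.discount_annual < 1.0):
            raise ValidationError(
                f"economics.discount_annual = {self.discount_annual} "
                "outside [0, 1)")
        if self.cycle_length <= 0:
            raise ValidationError("economics.cycle_length must be positive")
        if self.wtp_low > self.wtp_high:
            raise ValidationError(
                f"economics.wtp_low {self.wtp_low} exceeds wtp_high "
                f"{self.wtp_high}")
        if not (0.0 < self.termination_mortality < 1.0):
            raise ValidationError(
                "economics.termination_mortality must lie in (0, 1)")
        if self.max_cycles < 1:
            raise ValidationError("economics.max_cycles must be >= 1")

    def to_dict(self) -> dict:
        return {
            "discount_annual": self.discount_annual,
            "cycle_length_years": self.cycle_length,
            "wtp_low": self.wtp_low,
            "wtp_high": self.wtp_high,
            "termination_mortality": self.termination_mortality,
            "max_cycles": self.max_cycles,
            "base_year": self.base_year,
            "median_age_evt": self.median_age_evt,
            "median_age_evt_ivt": self.median_age_evt_ivt,
        }


@dataclass
class DistributionSpec:
    """A fitted sampling distribution for probabilistic sensitivity analysis.

    ``family`` is one of ``gamma`` (parameters ``shape``, ``scale``),
    ``beta`` (``alpha``, ``beta``) or ``dirichlet`` (``concentration``).
    """

    family: str
    parameters: dict[str, Any]
    n_eff: float | None = None

    def mean(self):
        if self.family == "gamma":
            return self.parameters["shape"] * self.parameters["scale"]
        if self.family == "beta":
            a, b = self.parameters["alpha"], self.parameters["beta"]
            return a / (a + b)
        if self.family == "dirichlet":
            conc = np.asarray(self.parameters["concentration"], dtype=float)
            return conc / conc.sum()
        raise ValidationError(f"unknown family {self.family!r}")

    def sd(self):
        if self.family == "gamma":
            return math.sqrt(self.parameters["shape"]) * self.parameters["scale"]
        if self.family == "beta":
            a, b = self.parameters["alpha"], self.parameters["beta"]
            return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1.0)))
        if self.family == "dirichlet":
            conc = np.asarray(self.parameters["concentration"], dtype=float)
            total = conc.sum()
            p = conc / total
            return np.sqrt(p * (1.0 - p) / (total + 1.0))
        raise ValidationError(f"unknown family {self.family!r}")

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "gamma":
            return rng.gamma(self.parameters["shape"],
                             self.parameters["scale"], size=size)
        if self.family == "beta":
            return rng.beta(self.parameters["alpha"],
                            self.parameters["beta"], size=size)
        if self.family == "dirichlet":
            return rng.dirichlet(
                np.asarray(self.parameters["concentration"], dtype=float),
                size=size)
        raise ValidationError(f"unknown family {self.family!r}")


@dataclass
class ModelParameters:
    """The complete validated parameter set for both treatment arms."""

    evt: ArmParameters
    evt_ivt: ArmParameters
    transitions: TransitionInputs
    costs: CostParameters
    utilities: UtilityParameters
    economics: EconomicSettings
    n_eff_dirichlet: float = 600.0
    recurrence_interval_frac: float = 0.20
    indirect_mode: str = "per_death"
    transitions_are_annual: bool = False

    def arm(self, key: str) -> ArmParameters:
        if key not in ARM_KEYS:
            raise KeyError(f"unknown arm {key!r}; expected one of {ARM_KEYS}")
        return getattr(self, key)

    def validate(self) -> None:
        self.evt.validate()
        self.evt_ivt.validate()
        self.transitions.validate()
        self.costs.validate()
        self.utilities.validate()
        self.economics.validate()
        if self.indirect_mode not in INDIRECT_MODES:
            raise ValidationError(
                f"model_options.indirect_mode = {self.indirect_mode!r}; "
                f"expected one of {INDIRECT_MODES}")
        if self.n_eff_dirichlet <= 0:
            raise ValidationError("psa.n_eff_dirichlet must be positive")
        if not (0.0 < self.recurrence_interval_frac < 1.0):
            raise ValidationError(
                "psa.recurrence_interval_frac must lie in (0, 1)")

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)

    def to_dict(self) -> dict:
        return {
            "arms": {"evt": self.evt.to_dict(),
                     "evt_ivt": self.evt_ivt.to_dict()},
            "transitions": self.transitions.to_dict(),
            "costs": self.costs.to_dict(),
            "utilities": self.utilities.to_dict(),
            "economics": self.economics.to_dict(),
            "psa": {"n_eff_dirichlet": self.n_eff_dirichlet,
                    "recurrence_interval_frac": self.recurrence_interval_frac},
            "model_options": {"indirect_mode": self.indirect_mode,
                              "transitions_are_annual":
                                  self.transitions_are_annual},
        }


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _value_with_ci(node: Any, name: str) -> ValueWithCI:
    if isinstance(node, Mapping):
        mean = _number(_get(node, "mean"), f"{name}.mean")
        lo = node.get("lo")
        hi = node.get("hi")
        return ValueWithCI(mean,
                           None if lo is None else _number(lo, f"{name}.lo"),
                           None if hi is None else _number(hi, f"{name}.hi"))
    return ValueWithCI(_number(node, name))


def _arm_from_dict(key: str, node: Mapping) -> ArmParameters:
    mrs = _get(node, "mrs_3m", prefix=f"arms.{key}")
    dist = MRSDistribution(
        _number(_get(mrs, "good"), f"arms.{key}.mrs_3m.good"),
        _number(_get(mrs, "poor"), f"arms.{key}.mrs_3m.poor"),
        _number(_get(mrs, "dead"), f"arms.{key}.mrs_3m.dead"),
    )
    components = {
        str(name): _number(value, f"arms.{key}.components.{name}")
        for name, value in _get(node, "components", prefix=f"arms.{key}").items()
    }
    return ArmParameters(
        name=key,
        label=str(node.get("label", key)),
        mrs_3m=dist,
        direct_treatment=_value_with_ci(_get(node, "direct_treatment", prefix=f"arms.{key}"),
                                        f"arms.{key}.direct_treatment"),
        components=components,
    )


def parameters_from_dict(cfg: Mapping) -> ModelParameters:
    """Build and validate :class:`ModelParameters` from a nested mapping."""
    arms = {key: _arm_from_dict(key, _get(cfg, "arms", key))
            for key in ARM_KEYS}

    tr = _get(cfg, "transitions")
    transitions = TransitionInputs(
        p_good_to_good=_number(_get(tr, "good_to_good", prefix="transitions"),
                               "transitions.good_to_good"),
        p_good_to_poor=_number(_get(tr, "good_to_poor", prefix="transitions"),
                               "transitions.good_to_poor"),
        p_poor_to_good=_number(_get(tr, "poor_to_good", prefix="transitions"),
                               "transitions.poor_to_good"),
        p_poor_to_poor=_number(_get(tr, "poor_to_poor", prefix="transitions"),
                               "transitions.poor_to_poor"),
        recurrence_annual=_number(_get(tr, "recurrence_annual", prefix="transitions"),
                                  "transitions.recurrence_annual"),
    )

    co = _get(cfg, "costs")
    indirect_total = _number(_get(co, "indirect_total", prefix="costs"),
                             "costs.indirect_total")
    dalys = _number(_get(co, "dalys", prefix="costs"), "costs.dalys")
    if "value_per_daly" in co:
        value_per_daly = _number(co["value_per_daly"], "costs.value_per_daly")
    else:
        # Back-solved so that value_per_daly * dalys reproduces the printed
        # indirect-cost total exactly.
        value_per_daly = indirect_total / dalys if dalys > 0 else 0.0
    costs = CostParameters(
        post_hosp_annual_good=_value_with_ci(
            _get(co, "post_hosp_annual_good", prefix="costs"), "costs.post_hosp_annual_good"),
        post_hosp_annual_poor=_value_with_ci(
            _get(co, "post_hosp_annual_poor", prefix="costs"), "costs.post_hosp_annual_poor"),
        indirect_total=indirect_total,
        dalys=dalys,
        value_per_daly=value_per_daly,
    )

    ut = _get(cfg, "utilities")
    utilities = UtilityParameters(
        u_good=_value_with_ci(_get(ut, "good", prefix="utilities"), "utilities.good"),
        u_poor=_value_with_ci(_get(ut, "poor", prefix="utilities"), "utilities.poor"),
        u_recurrent=_value_with_ci(_get(ut, "recurrent", prefix="utilities"),
                                   "utilities.recurrent"),
        u_dead=_number(_get(ut, "dead", prefix="utilities"), "utilities.dead"),
    )

    ec = _get(cfg, "economics")
    economics = EconomicSettings(
        discount_annual=_number(_get(ec, "discount_annual", prefix="economics"),
                                "economics.discount_annual"),
        cycle_length=_number(_get(ec, "cycle_length_years", prefix="economics"),
                             "economics.cycle_length_years"),
        wtp_low=_number(_get(ec, "wtp_low", prefix="economics"), "economics.wtp_low"),
        wtp_high=_number(_get(ec, "wtp_high", prefix="economics"), "economics.wtp_high"),
        termination_mortality=_number(_get(ec, "termination_mortality", prefix="economics"),
                                      "economics.termination_mortality"),
        max_cycles=int(_number(_get(ec, "max_cycles", prefix="economics"),
                               "economics.max_cycles")),
        base_year=int(_number(_get(ec, "base_year", prefix="economics"), "economics.base_year")),
        median_age_evt=_number(_get(ec, "median_age_evt", prefix="economics"),
                               "economics.median_age_evt"),
        median_age_evt_ivt=_number(_get(ec, "median_age_evt_ivt", prefix="economics"),
                                   "economics.median_age_evt_ivt"),
    )

    psa = cfg.get("psa", {}) or {}
    options = cfg.get("model_options", {}) or {}
    params = ModelParameters(
        evt=arms["evt"],
        evt_ivt=arms["evt_ivt"],
        transitions=transitions,
        costs=costs,
        utilities=utilities,
        economics=economics,
        n_eff_dirichlet=float(psa.get("n_eff_dirichlet", 600.0)),
        recurrence_interval_frac=float(
            psa.get("recurrence_interval_frac", 0.20)),
        indirect_mode=str(options.get("indirect_mode", "per_death")),
        transitions_are_annual=bool(
            options.get("transitions_are_annual", False)),
    )
    params.validate()
    return params


def load_parameters(config_path: str | Path | None = None) -> ModelParameters:
    """Load and validate model parameters from a YAML configuration file.

    With ``config_path=None`` the bundled base-case configuration (the
    published model-input table) is used.
    """
    if config_path is None:
        text = (resources.files("strokecea") / "data" /
                "table1_base_case.yaml").read_text(encoding="utf-8")
    else:
        path = Path(config_path)
        if not path.exists():
            raise ConfigurationError(f"configuration file not found: {path}")
        text = path.read_text(encoding="utf-8")
    try:
        cfg = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # pragma: no cover - parser detail
        raise ConfigurationError(f"could not parse configuration: {exc}")
    if not isinstance(cfg, Mapping):
        raise ConfigurationError("configuration root must be a mapping")
    return parameters_from_dict(cfg)


# ---------------------------------------------------------------------------
# Probability plumbing
# ---------------------------------------------------------------------------

def annual_to_cycle_probability(p_annual: float, cycles_per_year: int) -> float:
    """Convert an annual event probability to a per-cycle probability.

    Uses the constant-hazard identity ``1 - (1 - p)**(1 / cycles_per_year)``
    so that compounding the per-cycle probability over a year recovers the
    annual probability.
    """
    if not (0.0 <= p_annual < 1.0):
        raise ValidationError(
            f"annual probability {p_annual} outside [0, 1)")
    if cycles_per_year < 1:
        raise ValidationError("cycles_per_year must be >= 1")
    return 1.0 - (1.0 - p_annual) ** (1.0 / cycles_per_year)


def residual_death_probability(row_out: Sequence[float]) -> float:
    """Death probability as the unallocated remainder of a transition row."""
    total = float(sum(row_out))
    if total > 1.0 + SIMPLEX_TOL:
        raise ValidationError(
            f"transition outflows sum to {total}, above 1")
    return max(0.0, 1.0 - total)


# ---------------------------------------------------------------------------
# Moment-matched distribution fits
# ---------------------------------------------------------------------------

def gamma_from_mean_ci(mean: float, lo: float, hi: float) -> DistributionSpec:
    """Moment-matched Gamma from a mean and symmetric 95% interval."""
    if not (0.0 < lo < mean < hi):
        raise ValidationError(
            f"gamma fit needs 0 < lo < mean < hi, got ({mean}, {lo}, {hi})")
    sd = (hi - lo) / CI_WIDTH_IN_SD
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return DistributionSpec("gamma", {"shape": shape, "scale": scale})


def beta_from_mean_ci(mean: float, lo: float, hi: float) -> DistributionSpec:
    """Moment-matched Beta from a mean and symmetric 95% interval."""
    if not (0.0 < lo < mean < hi < 1.0):
        raise ValidationError(
            f"beta fit needs 0 < lo < mean < hi < 1, got "
            f"({mean}, {lo}, {hi})")
    sd = (hi - lo) / CI_WIDTH_IN_SD
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise ValidationError(
            f"beta fit infeasible: variance {var} >= mean(1-mean) "
            f"{mean * (1.0 - mean)}")
    nu = mean * (1.0 - mean) / var - 1.0
    return DistributionSpec(
        "beta", {"alpha": mean * nu, "beta": (1.0 - mean) * nu})


def dirichlet_from_proportions(props: Sequence[float] | MRSDistribution,
                               n_eff: float) -> DistributionSpec:
    """Dirichlet with concentrations ``n_eff * p_i`` (floored at 1e-6*n_eff).

    ``n_eff`` acts as an effective sample size: the marginal means equal the
    input proportions and the spread shrinks as ``n_eff`` grows.
    """
    if n_eff <= 0:
        raise ValidationError("dirichlet n_eff must be positive")
    if isinstance(props, MRSDistribution):
        p = props.as_array()
    else:
        p = np.asarray(props, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
        raise ValidationError(
            f"proportions {p.tolist()} are not on the simplex")
    conc = np.maximum(n_eff * p, 1e-6 * n_eff)
    return DistributionSpec(
        "dirichlet", {"concentration": tuple(conc.tolist())}, n_eff=n_eff)


def compute_indirect_cost(dalys: float, value_per_daly: float,
                          discount_annual: float = 0.0) -> float:
    """Human-capital value of a DALY stream, optionally discounted.

    With ``discount_annual=0`` this is simply ``dalys * value_per_daly``.
    Otherwise each healthy-life year lost is valued at the end of its year
    and discounted at the annual rate; a fractional final year is prorated.
    """
    if dalys < 0 or value_per_daly < 0 or discount_annual < 0:
        raise ValidationError(
            "indirect-cost inputs must be non-negative")
    if discount_annual == 0.0:
        return dalys * value_per_daly
    whole = int(math.floor(dalys))
    frac = dalys - whole
    total = sum(value_per_daly * (1.0 + discount_annual) ** (-t)
                for t in range(1, whole + 1))
    if frac > 0:
        total += frac * value_per_daly * (1.0 + discount_annual) ** (
            -(whole + 1))
    return total
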