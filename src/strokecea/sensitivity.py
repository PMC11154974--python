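"""Deterministic (tornado) and probabilistic sensitivity analyses.

One-way analysis perturbs a single scalar input by a symmetric fraction
(default +/-20%) while holding everything else fixed, recomputes the
lifetime ICER at both endpoints, and reports entries sorted by the span of
the two ICERs.  Probabilities that live on a simplex are perturbed in
their named component with the residual death mass re-normalised.

The probabilistic sensitivity analysis (PSA) jointly resamples every
uncertain parameter from its fitted distribution -- Gamma for costs, Beta
for utilities and the recurrence rate, Dirichlet for the 3-month outcome
triples and the first-year transition rows (death as the residual
component) -- and reruns both arms for each draw.  One parameter draw is
shared across the 3-month, 1-year and lifetime horizons within an
iteration.  The recurrence rate has no printed interval; a symmetric
+/-20% range around 9.6% is used to fit its Beta distribution.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import cea
from .cohort_model import evaluate_arm_horizons, HORIZONS
from .params import (
    MRSDistribution,
    ModelParameters,
    ValidationError,
    beta_from_mean_ci,
    dirichlet_from_proportions,
    gamma_from_mean_ci,
)

__all__ = [
    "OWSAEntry",
    "PSAResult",
    "DEFAULT_OWSA_PARAMETERS",
    "one_way_sensitivity",
    "fit_psa_distributions",
    "sample_psa_parameters",
    "run_psa",
    "probability_cost_effective",
]

log = logging.getLogger(__name__)

CEAC_GRID = np.arange(0.0, 300001.0, 5000.0)


# ---------------------------------------------------------------------------
# One-way sensitivity (tornado)
# ---------------------------------------------------------------------------

def _clip(value: float, name: str, lo: float, hi: float) -> float:
    if value < lo or value > hi:
        clipped = min(max(value, lo), hi)
        log.warning("%s perturbed to %g; clipped to [%g, %g]",
                    name, value, lo, hi)
        return clipped
    return value


def _scale_direct(arm_key: str):
    def get(p: ModelParameters) -> float:
        return p.arm(arm_key).direct_treatment.mean

    def apply(p: ModelParameters, f: float) -> None:
        arm = p.arm(arm_key)
        arm.direct_treatment = arm.direct_treatment.scaled(f)
        arm.components = {k: v * f for k, v in arm.components.items()}
    return get, apply


def _scale_post_hosp(which: str):
    attr = f"post_hosp_annual_{which}"

    def get(p: ModelParameters) -> float:
        return getattr(p.costs, attr).mean

    def apply(p: ModelParameters, f: float) -> None:
        setattr(p.costs, attr, getattr(p.costs, attr).scaled(f))
    return get, apply


def _scale_indirect():
    def get(p: ModelParameters) -> float:
        return p.costs.indirect_total

    def apply(p: ModelParameters, f: float) -> None:
        p.costs.indirect_total *= f
        p.costs.value_per_daly *= f
    return get, apply


def _scale_utility(which: str):
    def get(p: ModelParameters) -> float:
        if which == "dead":
            return p.utilities.u_dead
        return getattr(p.utilities, f"u_{which}").mean

    def apply(p: ModelParameters, f: float) -> None:
        if which == "dead":
            p.utilities.u_dead = _clip(p.utilities.u_dead * f,
                                       "utilities.dead", 0.0, 1.0)
            return
        attr = f"u_{which}"
        scaled = getattr(p.utilities, attr).scaled(f)
        scaled.mean = _clip(scaled.mean, f"utilities.{which}", 0.0, 1.0)
        scaled.lo = None if scaled.lo is None else max(scaled.lo, 0.0)
        scaled.hi = None if scaled.hi is None else min(scaled.hi, 1.0)
        setattr(p.utilities, attr, scaled)
    return get, apply


def _scale_recurrence():
    def get(p: ModelParameters) -> float:
        return p.transitions.recurrence_annual

    def apply(p: ModelParameters, f: float) -> None:
        p.transitions.recurrence_annual = _clip(
            p.transitions.recurrence_annual * f,
            "transitions.recurrence_annual", 0.0, 1.0 - 1e-9)
    return get, apply


def _scale_discount():
    def get(p: ModelParameters) -> float:
        return p.economics.discount_annual

    def apply(p: ModelParameters, f: float) -> None:
        p.economics.discount_annual = _clip(
            p.economics.discount_annual * f,
            "economics.discount_annual", 0.0, 1.0 - 1e-9)
    return get, apply


def _scale_transition(row: str):
    # Perturb the named stay probability; the death mass is the residual of
    # the row, so re-normalisation is automatic.
    stay, move = (("p_good_to_good", "p_good_to_poor") if row == "good"
                  else ("p_poor_to_poor", "p_poor_to_good"))

    def get(p: ModelParameters) -> float:
        return getattr(p.transitions, stay)

    def apply(p: ModelParameters, f: float) -> None:
        other = getattr(p.transitions, move)
        setattr(p.transitions, stay,
                _clip(getattr(p.transitions, stay) * f,
                      f"transitions.{stay}", 0.0, 1.0 - other))
    return get, apply


#: Registry of scalar-perturbable parameters: name -> (getter, applier).
PERTURBATIONS: dict[str, tuple[Callable, Callable]] = {
    "direct_treatment_evt": _scale_direct("evt"),
    "direct_treatment_evt_ivt": _scale_direct("evt_ivt"),
    "post_hosp_annual_good": _scale_post_hosp("good"),
    "post_hosp_annual_poor": _scale_post_hosp("poor"),
    "indirect_cost": _scale_indirect(),
    "utility_good": _scale_utility("good"),
    "utility_poor": _scale_utility("poor"),
    "utility_dead": _scale_utility("dead"),
    "utility_recurrent": _scale_utility("recurrent"),
    "recurrence_annual": _scale_recurrence(),
    "discount_rate": _scale_discount(),
    "p_good_to_good": _scale_transition("good"),
    "p_poor_to_poor": _scale_transition("poor"),
}

#: The quantities the tornado varies by default.
DEFAULT_OWSA_PARAMETERS = (
    "direct_treatment_evt",
    "direct_treatment_evt_ivt",
    "post_hosp_annual_good",
    "post_hosp_annual_poor",
    "indirect_cost",
    "utility_good",
    "utility_poor",
    "utility_dead",
    "utility_recurrent",
    "recurrence_annual",
    "discount_rate",
)


@dataclass
class OWSAEntry:
    parameter: str
    low_value: float
    high_value: float
    icer_at_low: float | str
    icer_at_high: float | str
    span: float


def _icer_at(params: ModelParameters, horizon: str):
    a = evaluate_arm_horizons("evt", params, (horizon,))[horizon]
    b = evaluate_arm_horizons("evt_ivt", params, (horizon,))[horizon]
    return cea.icer(b[0], a[0], b[1], a[1])


def one_way_sensitivity(params: ModelParameters,
                        parameter_list: Sequence[str] | None = None,
                        perturbation: float = 0.20,
                        horizon: str = "lifetime") -> list[OWSAEntry]:
    """Tornado analysis: ICER at +/-``perturbation`` per parameter.

    Returns entries sorted by descending span of the two endpoint ICERs.
    """
    if perturbation < 0 or perturbation >= 1:
        raise ValidationError(
            f"perturbation {perturbation} outside [0, 1)")
    names = tuple(parameter_list or DEFAULT_OWSA_PARAMETERS)
    entries = []
    for name in names:
        if name not in PERTURBATIONS:
            raise ValidationError(
                f"unknown OWSA parameter {name!r}; known: "
                f"{sorted(PERTURBATIONS)}")
        get, apply = PERTURBATIONS[name]
        results = []
        for factor in (1.0 - perturbation, 1.0 + perturbation):
            perturbed = params.copy()
            apply(perturbed, factor)
            results.append((get(perturbed), _icer_at(perturbed, horizon)))
        (low_value, icer_low), (high_value, icer_high) = results
        if isinstance(icer_low, str) or isinstance(icer_high, str):
            span = float("inf")
        else:
            span = abs(icer_high - icer_low)
        entries.append(OWSAEntry(name, low_value, high_value,
                                 icer_low, icer_high, span))
    entries.sort(key=lambda e: e.span, reverse=True)
    return entries


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def fit_psa_distributions(params: ModelParameters) -> dict:
    """Fit every PSA sampling distribution from the base-case inputs."""
    tr = params.transitions
    frac = params.recurrence_interval_frac
    rec = tr.recurrence_annual
    n_eff = params.n_eff_dirichlet
    fits = {
        "post_hosp_good": gamma_from_mean_ci(
            params.costs.post_hosp_annual_good.mean,
            params.costs.post_hosp_annual_good.lo,
            params.costs.post_hosp_annual_good.hi),
        "post_hosp_poor": gamma_from_mean_ci(
            params.costs.post_hosp_annual_poor.mean,
            params.costs.post_hosp_annual_poor.lo,
            params.costs.post_hosp_annual_poor.hi),
        "u_good": beta_from_mean_ci(params.utilities.u_good.mean,
                                    params.utilities.u_good.lo,
                                    params.utilities.u_good.hi),
        "u_poor": beta_from_mean_ci(params.utilities.u_poor.mean,
                                    params.utilities.u_poor.lo,
                                    params.utilities.u_poor.hi),
        "u_recurrent": beta_from_mean_ci(params.utilities.u_recurrent.mean,
                                         params.utilities.u_recurrent.lo,
                                         params.utilities.u_recurrent.hi),
        "recurrence": beta_from_mean_ci(rec, rec * (1 - frac),
                                        rec * (1 + frac)),
        "row_good": dirichlet_from_proportions(
            (tr.p_good_to_good, tr.p_good_to_poor,
             1.0 - tr.p_good_to_good - tr.p_good_to_poor), n_eff),
        "row_poor": dirichlet_from_proportions(
            (tr.p_poor_to_good, tr.p_poor_to_poor,
             1.0 - tr.p_poor_to_good - tr.p_poor_to_poor), n_eff),
    }
    for key in ("evt", "evt_ivt"):
        arm = params.arm(key)
        fits[f"direct_{key}"] = gamma_from_mean_ci(
            arm.direct_treatment.mean, arm.direct_treatment.lo,
            arm.direct_treatment.hi)
        fits[f"mrs_{key}"] = dirichlet_from_proportions(arm.mrs_3m, n_eff)
    return fits


def sample_psa_parameters(params: ModelParameters,
                          rng: np.random.Generator,
                          fits: Mapping | None = None) -> ModelParameters:
    """Draw one joint parameter set; all other inputs stay at base case."""
    fits = fits or fit_psa_distributions(params)
    sampled = params.copy()
    for key in ("evt", "evt_ivt"):
        arm = sampled.arm(key)
        direct = float(fits[f"direct_{key}"].sample(rng))
        ratio = direct / arm.direct_treatment.mean
        arm.direct_treatment = arm.direct_treatment.scaled(ratio)
        arm.components = {k: v * ratio for k, v in arm.components.items()}
        mrs = fits[f"mrs_{key}"].sample(rng)
        arm.mrs_3m = MRSDistribution(*map(float, mrs))
    row_good = fits["row_good"].sample(rng)
    row_poor = fits["row_poor"].sample(rng)
    sampled.transitions.p_good_to_good = float(row_good[0])
    sampled.transitions.p_good_to_poor = float(row_good[1])
    sampled.transitions.p_poor_to_good = float(row_poor[0])
    sampled.transitions.p_poor_to_poor = float(row_poor[1])
    sampled.transitions.recurrence_annual = float(
        fits["recurrence"].sample(rng))
    co = sampled.costs
    co.post_hosp_annual_good = co.post_hosp_annual_good.scaled(
        float(fits["post_hosp_good"].sample(rng))
        / co.post_hosp_annual_good.mean)
    co.post_hosp_annual_poor = co.post_hosp_annual_poor.scaled(
        float(fits["post_hosp_poor"].sample(rng))
        / co.post_hosp_annual_poor.mean)
    ut = sampled.utilities
    for attr, key in (("u_good", "u_good"), ("u_poor", "u_poor"),
                      ("u_recurrent", "u_recurrent")):
        value = float(fits[key].sample(rng))
        spec = getattr(ut, attr)
        spec.mean = value
    return sampled


@dataclass
class PSAResult:
    """CE-plane samples and probability-cost-effective summaries."""

    samples: dict[str, pd.DataFrame]
    n_iterations: int
    seed: int | None
    prob_evt_alone_ce: dict[tuple[str, float], float]
    ceac: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for horizon, df in self.samples.items():
            frame = df.copy()
            frame.insert(0, "horizon", horizon)
            frames.append(frame)
        return pd.concat(frames, ignore_index=True)


def probability_cost_effective(samples: pd.DataFrame | Mapping,
                               wtp: float) -> float:
    """Fraction of draws in which EVT alone is the cost-effective choice.

    A draw favours EVT alone when the incremental net monetary benefit of
    EVT + IVT (``delta_effect * wtp - delta_cost``, deltas oriented
    EVT + IVT minus EVT alone) is strictly negative; ties go to EVT + IVT.
    """
    dc = np.asarray(samples["delta_cost"], dtype=float)
    de = np.asarray(samples["delta_effect"], dtype=float)
    if dc.size == 0:
        raise ValueError("no PSA samples supplied")
    return float(np.mean(de * wtp - dc < 0.0))


def run_psa(params: ModelParameters, n_iterations: int = 10000,
            seed: int | None = None,
            horizons: Iterable[str] = HORIZONS,
            wtp_values: Iterable[float] | None = None,
            ceac_grid: Sequence[float] | None = None) -> PSAResult:
    """Monte Carlo PSA: draw parameters, rerun both arms, summarise.

    Each iteration draws one joint parameter set and evaluates both arms at
    every requested horizon.  ``probability_cost_effective`` is reported
    per (horizon, WTP) and a cost-effectiveness acceptability curve is
    evaluated on a WTP grid (default 0 to 300,000 in steps of 5,000).
    """
    if n_iterations < 1:
        raise ValidationError("n_iterations must be >= 1")
    horizons = tuple(horizons)
    if wtp_values is None:
        wtp_values = (params.economics.wtp_low, params.economics.wtp_high)
    wtp_values = tuple(float(w) for w in wtp_values)
    grid = CEAC_GRID if ceac_grid is None else np.asarray(ceac_grid, float)

    rng = np.random.default_rng(seed)
    fits = fit_psa_distributions(params)
    store = {h: {"cost_evt": np.empty(n_iterations),
                 "qaly_evt": np.empty(n_iterations),
                 "cost_evt_ivt": np.empty(n_iterations),
                 "qaly_evt_ivt": np.empty(n_iterations)}
             for h in horizons}
    for i in range(n_iterations):
        draw = sample_psa_parameters(params, rng, fits)
        a = evaluate_arm_horizons("evt", draw, horizons)
        b = evaluate_arm_horizons("evt_ivt", draw, horizons)
        for h in horizons:
            store[h]["cost_evt"][i], store[h]["qaly_evt"][i] = a[h]
            store[h]["cost_evt_ivt"][i], store[h]["qaly_evt_ivt"][i] = b[h]

    samples = {}
    for h in horizons:
        df = pd.DataFrame(store[h])
        df.insert(0, "draw", np.arange(n_iterations))
        df["delta_cost"] = df["cost_evt_ivt"] - df["cost_evt"]
        df["delta_effect"] = df["qaly_evt_ivt"] - df["qaly_evt"]
        samples[h] = df

    prob = {(h, w): probability_cost_effective(samples[h], w)
            for h in horizons for w in wtp_values}

    rows = []
    for h in horizons:
        dc = samples[h]["delta_cost"].to_numpy()
        de = samples[h]["delta_effect"].to_numpy()
        for w in grid:
            p_ivt = float(np.mean(de * w - dc >= 0.0))
            rows.append({"horizon": h, "wtp": float(w),
                         "p_evt_ivt": p_ivt,
                         "p_evt_alone": 1.0 - p_ivt})
    ceac = pd.DataFrame(rows)
    return PSAResult(samples=samples, n_iterations=n_iterations, seed=seed,
                     prob_evt_alone_ce=prob, ceac=ceac)
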