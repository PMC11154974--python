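"""Decision tree plus quarterly Markov cohort engine.

The first 90 days are modelled as a decision tree: every patient in an arm
incurs that arm's direct treatment cost at cycle 0 (undiscounted) and ends
the quarter distributed over {mRS 0-2, mRS 3-5, death} according to the
arm's 3-month outcome proportions.  Survivors then enter a Markov cohort
with four states:

* ``GOOD``      -- independent (mRS 0-2)
* ``POOR``      -- dependent (mRS 3-5)
* ``RECURRENT`` -- a one-cycle tunnel for recurrent stroke; occupants incur
  the arm's full direct treatment cost again (re-treatment follows the
  first-stroke pattern) and the recurrent-stroke utility, then exit into
  the arm's initial 3-month outcome distribution, including its death mass
* ``DEAD``      -- absorbing

Cycles are three months.  During the first year both the independent and
dependent states may improve or deteriorate per the first-year transition
row; afterwards dependent patients can only remain, recur, or die, while
independent patients keep the first-occurrence row.  Death probabilities
are the residual mass of each printed row (0.021/cycle from GOOD,
0.052/cycle from POOR), reused after year 1 as an all-cause proxy.  The
annual recurrence rate (9.6%) is converted to a per-cycle probability and
competes with the within-row moves: a row is the printed row scaled by
(1 - r) plus probability r of entering the tunnel.

Costs accrue as quarterly post-hospitalisation costs for GOOD/POOR, the
full direct treatment cost for RECURRENT, and (in the default
``per_death`` indirect mode) the indirect human-capital cost at each death
occurring after model entry.  QALYs accrue as cycle-length times the
occupancy-weighted utility.  Both streams are discounted at 3% per year;
cycle 0 is undiscounted and there is no half-cycle correction, so the
3-month cost of an arm equals its direct treatment cost exactly.

A lifetime run stops at the first cycle where cumulative mortality reaches
99% (safety cap: ``max_cycles``, default 200 cycles = 50 years).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .params import (
    MRSDistribution,
    ModelParameters,
    ValidationError,
    annual_to_cycle_probability,
    residual_death_probability,
)

__all__ = [
    "HealthState",
    "CohortTrace",
    "ArmOutcome",
    "DecisionTreeResult",
    "CycleAccrual",
    "discount_factor",
    "run_decision_tree",
    "build_transition_matrix",
    "recurrence_redistribution",
    "accrue_cycle",
    "run_markov",
    "evaluate_arm_horizons",
]


class HealthState(IntEnum):
    GOOD = 0
    POOR = 1
    RECURRENT = 2
    DEAD = 3


N_STATES = 4

HORIZONS = ("3m", "1y", "lifetime")


def discount_factor(elapsed_years: float, rate: float) -> float:
    """Present-value factor ``(1 + rate) ** -elapsed_years``."""
    if rate < 0:
        raise ValidationError(f"discount rate {rate} is negative")
    if elapsed_years < 0:
        raise ValidationError(f"elapsed time {elapsed_years} is negative")
    return (1.0 + rate) ** (-elapsed_years)


@dataclass
class DecisionTreeResult:
    cost: float
    qaly: float
    end_distribution: MRSDistribution


class CycleAccrual(NamedTuple):
    cost: float
    qaly: float
    cost_undiscounted: float
    qaly_undiscounted: float


@dataclass
class CohortTrace:
    """Per-cycle record of occupancies and cost/QALY increments."""

    cycles: list[int] = field(default_factory=list)
    years: list[float] = field(default_factory=list)
    occupancy: list[np.ndarray] = field(default_factory=list)
    cost_undiscounted: list[float] = field(default_factory=list)
    qaly_undiscounted: list[float] = field(default_factory=list)
    cost_discounted: list[float] = field(default_factory=list)
    qaly_discounted: list[float] = field(default_factory=list)

    def append(self, cycle: int, years: float, occ: np.ndarray,
               acc: CycleAccrual) -> None:
        self.cycles.append(cycle)
        self.years.append(years)
        self.occupancy.append(np.asarray(occ, dtype=float).copy())
        self.cost_undiscounted.append(acc.cost_undiscounted)
        self.qaly_undiscounted.append(acc.qaly_undiscounted)
        self.cost_discounted.append(acc.cost)
        self.qaly_discounted.append(acc.qaly)

    @property
    def cumulative_mortality(self) -> list[float]:
        return [float(o[HealthState.DEAD]) for o in self.occupancy]

    def to_dataframe(self) -> pd.DataFrame:
        occ = np.asarray(self.occupancy)
        return pd.DataFrame({
            "cycle": self.cycles,
            "years": self.years,
            "occ_good": occ[:, HealthState.GOOD],
            "occ_poor": occ[:, HealthState.POOR],
            "occ_recurrent": occ[:, HealthState.RECURRENT],
            "occ_dead": occ[:, HealthState.DEAD],
            "cost_increment": self.cost_undiscounted,
            "qaly_increment": self.qaly_undiscounted,
            "cost_increment_discounted": self.cost_discounted,
            "qaly_increment_discounted": self.qaly_discounted,
            "cumulative_mortality": self.cumulative_mortality,
        })


@dataclass
class ArmOutcome:
    """Discounted totals and trace for one arm at one horizon."""

    arm: str
    horizon: str
    cost: float
    qaly: float
    cycles_run: int
    cumulative_mortality: float
    terminated: bool
    trace: CohortTrace | None = None


# ---------------------------------------------------------------------------
# Decision tree (cycle 0)
# ---------------------------------------------------------------------------

def run_decision_tree(arm_key: str,
                      params: ModelParameters) -> DecisionTreeResult:
    """First-quarter expected cost, QALY and end-of-quarter distribution.

    Every branch incurs the arm's direct treatment cost, undiscounted; the
    quarter's QALY is cycle-length times the outcome-weighted utility.
    """
    arm = params.arm(arm_key)
    u = params.utilities
    cl = params.economics.cycle_length
    dist = arm.mrs_3m
    qaly = cl * (dist.p_good * u.u_good.mean
                 + dist.p_poor * u.u_poor.mean
                 + dist.p_dead * u.u_dead)
    return DecisionTreeResult(cost=arm.direct_treatment.mean, qaly=qaly,
                              end_distribution=dist)


# ---------------------------------------------------------------------------
# Transition structure
# ---------------------------------------------------------------------------

def recurrence_redistribution(arm_key: str,
                              params: ModelParameters) -> MRSDistribution:
    """Exit distribution of the recurrent-stroke tunnel.

    Recurrent strokes are re-treated with the same strategy as the first
    stroke, so tunnel occupants redistribute to the arm's initial 3-month
    outcome proportions (including the death mass).
    """
    return params.arm(arm_key).mrs_3m


def _row_probabilities(params: ModelParameters) -> tuple:
    """Per-cycle (stay, move, die) masses for the GOOD and POOR rows."""
    tr = params.transitions
    n = params.economics.cycles_per_year
    g2g, g2p = tr.p_good_to_good, tr.p_good_to_poor
    p2g, p2p = tr.p_poor_to_good, tr.p_poor_to_poor
    if params.transitions_are_annual:
        # Scenario switch: printed rows read as annual; convert outflows and
        # take the stay probability as the residual.
        g2p = annual_to_cycle_probability(g2p, n)
        p2g = annual_to_cycle_probability(p2g, n)
        d_good = annual_to_cycle_probability(
            residual_death_probability((tr.p_good_to_good,
                                        tr.p_good_to_poor)), n)
        d_poor = annual_to_cycle_probability(
            residual_death_probability((tr.p_poor_to_good,
                                        tr.p_poor_to_poor)), n)
        g2g = 1.0 - g2p - d_good
        p2p = 1.0 - p2g - d_poor
    else:
        d_good = residual_death_probability((g2g, g2p))
        d_poor = residual_death_probability((p2g, p2p))
    return (g2g, g2p, d_good), (p2g, p2p, d_poor)


def build_transition_matrix(arm_key: str, params: ModelParameters,
                            phase: str) -> np.ndarray:
    """4x4 per-cycle transition matrix for ``phase``.

    ``first_year`` applies the printed first-year rows to both living
    states; ``post_first_year`` freezes the dependent state (remain, recur
    or die only) while the independent state keeps its first-occurrence
    row.  Recurrence competes with every within-row move: each living row
    is the printed row scaled by ``(1 - r)`` plus mass ``r`` into the
    one-cycle tunnel.  The tunnel exits into the arm's initial 3-month
    distribution and death is absorbing.
    """
    if phase not in ("first_year", "post_first_year"):
        raise ValidationError(f"unknown phase {phase!r}")
    (g2g, g2p, d_good), (p2g, p2p, d_poor) = _row_probabilities(params)
    r = annual_to_cycle_probability(params.transitions.recurrence_annual,
                                    params.economics.cycles_per_year)
    mrs = recurrence_redistribution(arm_key, params)

    m = np.zeros((N_STATES, N_STATES))
    m[HealthState.GOOD] = [g2g * (1 - r), g2p * (1 - r), r, d_good * (1 - r)]
    if phase == "first_year":
        m[HealthState.POOR] = [p2g * (1 - r), p2p * (1 - r), r,
                               d_poor * (1 - r)]
    else:
        m[HealthState.POOR] = [0.0, (1.0 - d_poor) * (1 - r), r,
                               d_poor * (1 - r)]
    m[HealthState.RECURRENT] = [mrs.p_good, mrs.p_poor, 0.0, mrs.p_dead]
    m[HealthState.DEAD] = [0.0, 0.0, 0.0, 1.0]

    sums = m.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-9):
        raise ValidationError(
            f"transition rows do not sum to 1: {sums.tolist()}")
    return m


# ---------------------------------------------------------------------------
# Accrual
# ---------------------------------------------------------------------------

def accrue_cycle(state_occupancy, arm_key: str, params: ModelParameters,
                 cycle_index: int, death_increment: float = 0.0
                 ) -> CycleAccrual:
    """Cost and QALY increments for one Markov cycle.

    ``death_increment`` is the fraction of the cohort dying during this
    cycle; in the ``per_death`` indirect mode it triggers the indirect
    human-capital cost.  Increments are discounted at the cycle's elapsed
    years (``cycle_index * cycle_length``).
    """
    occ = np.asarray(state_occupancy, dtype=float)
    if occ.shape != (N_STATES,):
        raise ValidationError(
            f"occupancy must have {N_STATES} entries, got {occ.shape}")
    if np.any(occ < -1e-12) or abs(occ.sum() - 1.0) > 1e-9:
        raise ValidationError(
            f"occupancy {occ.tolist()} is not on the simplex")

    arm = params.arm(arm_key)
    co = params.costs
    u = params.utilities
    cl = params.economics.cycle_length

    cost = cl * (occ[HealthState.GOOD] * co.post_hosp_annual_good.mean
                 + occ[HealthState.POOR] * co.post_hosp_annual_poor.mean)
    cost += occ[HealthState.RECURRENT] * arm.direct_treatment.mean
    if params.indirect_mode == "per_death":
        cost += death_increment * co.indirect_total

    qaly = cl * (occ[HealthState.GOOD] * u.u_good.mean
                 + occ[HealthState.POOR] * u.u_poor.mean
                 + occ[HealthState.RECURRENT] * u.u_recurrent.mean
                 + occ[HealthState.DEAD] * u.u_dead)

    df = discount_factor(cycle_index * cl,
                         params.economics.discount_annual)
    return CycleAccrual(cost * df, qaly * df, cost, qaly)


# ---------------------------------------------------------------------------
# Cohort run
# ---------------------------------------------------------------------------

def _markov_cycles(params: ModelParameters, horizon) -> int | None:
    """Number of Markov cycles after the decision tree; None = lifetime."""
    if horizon == "3m":
        return 0
    if horizon == "1y":
        return params.economics.cycles_per_year - 1
    if horizon == "lifetime":
        return None
    if isinstance(horizon, int) and horizon >= 0:
        return horizon
    raise ValidationError(f"unknown horizon {horizon!r}")


def run_markov(arm_key: str, params: ModelParameters,
               horizon="lifetime", keep_trace: bool = True) -> ArmOutcome:
    """Run one arm through the decision tree and Markov cohort.

    ``horizon`` is ``"3m"`` (decision tree only), ``"1y"`` (tree plus three
    quarterly cycles), ``"lifetime"`` (until cumulative mortality reaches
    the termination threshold, capped at ``max_cycles``), or an explicit
    number of Markov cycles.
    """
    ec = params.economics
    tree = run_decision_tree(arm_key, params)
    dist = tree.end_distribution
    occ = np.array([dist.p_good, dist.p_poor, 0.0, dist.p_dead])

    cost = tree.cost
    qaly = tree.qaly
    if params.indirect_mode == "lump_sum":
        # One undiscounted lump per cohort member at model entry; identical
        # in both arms, so it cancels from every incremental quantity.
        cost += params.costs.indirect_total

    trace = CohortTrace() if keep_trace else None
    if trace is not None:
        trace.append(0, 0.0, occ,
                     CycleAccrual(tree.cost, tree.qaly, tree.cost, tree.qaly))

    n_cycles = _markov_cycles(params, horizon)
    lifetime = n_cycles is None
    m_first = build_transition_matrix(arm_key, params, "first_year")
    m_post = build_transition_matrix(arm_key, params, "post_first_year")
    first_cycles = ec.cycles_per_year - 1  # cycle 0 covered the first quarter

    k = 0
    terminated = False
    while True:
        if lifetime:
            if occ[HealthState.DEAD] >= ec.termination_mortality:
                terminated = True
                break
            if k >= ec.max_cycles:
                break
        elif k >= n_cycles:
            break
        k += 1
        m = m_first if k <= first_cycles else m_post
        new_occ = occ @ m
        death_inc = new_occ[HealthState.DEAD] - occ[HealthState.DEAD]
        acc = accrue_cycle(new_occ, arm_key, params, k, death_inc)
        cost += acc.cost
        qaly += acc.qaly
        occ = new_occ
        if trace is not None:
            trace.append(k, k * ec.cycle_length, occ, acc)

    horizon_label = horizon if isinstance(horizon, str) else f"{horizon}cyc"
    return ArmOutcome(arm=arm_key, horizon=horizon_label, cost=cost,
                      qaly=qaly, cycles_run=k,
                      cumulative_mortality=float(occ[HealthState.DEAD]),
                      terminated=terminated or not lifetime,
                      trace=trace)


def evaluate_arm_horizons(arm_key: str, params: ModelParameters,
                          horizons: Iterable[str] = HORIZONS
                          ) -> dict[str, tuple[float, float]]:
    """Discounted (cost, QALY) totals at several nested horizons, one pass.

    Because the 3-month, 1-year and lifetime horizons are prefixes of the
    same cohort trajectory, a single lifetime sweep yields all three;
    this is the fast path used by the sensitivity analyses.
    """
    horizons = tuple(horizons)
    for h in horizons:
        if h not in HORIZONS:
            raise ValidationError(f"unknown horizon {h!r}")
    ec = params.economics
    tree = run_decision_tree(arm_key, params)
    dist = tree.end_distribution
    occ = np.array([dist.p_good, dist.p_poor, 0.0, dist.p_dead])
    cost = tree.cost
    qaly = tree.qaly
    if params.indirect_mode == "lump_sum":
        cost += params.costs.indirect_total

    out: dict[str, tuple[float, float]] = {}
    if "3m" in horizons:
        out["3m"] = (cost, qaly)
    need_markov = ("1y" in horizons) or ("lifetime" in horizons)
    if not need_markov:
        return out

    m_first = build_transition_matrix(arm_key, params, "first_year").tolist()
    m_post = build_transition_matrix(arm_key, params, "post_first_year").tolist()
    first_cycles = ec.cycles_per_year - 1
    lifetime = "lifetime" in horizons
    year_cycles = first_cycles

    # Scalar accrual constants (same arithmetic as accrue_cycle, inlined
    # because this loop dominates the PSA runtime).
    arm = params.arm(arm_key)
    co = params.costs
    u = params.utilities
    cl = ec.cycle_length
    c_good = cl * co.post_hosp_annual_good.mean
    c_poor = cl * co.post_hosp_annual_poor.mean
    c_rec = arm.direct_treatment.mean
    c_death = co.indirect_total if params.indirect_mode == "per_death" else 0.0
    q_good = cl * u.u_good.mean
    q_poor = cl * u.u_poor.mean
    q_rec = cl * u.u_recurrent.mean
    beta = (1.0 + ec.discount_annual) ** (-cl)

    g, p, rec, dead = (float(occ[0]), float(occ[1]), float(occ[2]),
                       float(occ[3]))
    df = 1.0
    k = 0
    while True:
        if dead >= ec.termination_mortality or k >= ec.max_cycles:
            break
        if not lifetime and k >= year_cycles:
            break
        k += 1
        m = m_first if k <= first_cycles else m_post
        g2 = g * m[0][0] + p * m[1][0] + rec * m[2][0]
        p2 = g * m[0][1] + p * m[1][1] + rec * m[2][1]
        rec2 = g * m[0][2] + p * m[1][2]
        dead2 = g * m[0][3] + p * m[1][3] + rec * m[2][3] + dead
        df *= beta
        cost += df * (c_good * g2 + c_poor * p2 + c_rec * rec2
                      + c_death * (dead2 - dead))
        qaly += df * (q_good * g2 + q_poor * p2 + q_rec * rec2)
        g, p, rec, dead = g2, p2, rec2, dead2
        if k == year_cycles and "1y" in horizons:
            out["1y"] = (cost, qaly)
    if "1y" in horizons and "1y" not in out:
        # Cohort hit termination within the first year; totals to date apply.
        out["1y"] = (cost, qaly)
    if lifetime:
        out["lifetime"] = (cost, qaly)
    return out
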