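"""Cost-effectiveness arithmetic: ICER, CER, net monetary benefit, verdicts.

The comparison is oriented as EVT + IVT (strategy B) versus EVT alone
(strategy A): incremental quantities are B minus A.  A strategy is
cost-effective at a willingness-to-pay (WTP) threshold when its
incremental net monetary benefit is non-negative; when the signs of the
cost and effect differences make the ratio uninterpretable, a dominance
flag replaces the ICER.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Union

from .cohort_model import ArmOutcome

__all__ = [
    "DOMINANT",
    "DOMINATED",
    "UNDEFINED",
    "COST_EFFECTIVE",
    "NOT_COST_EFFECTIVE",
    "icer",
    "cer",
    "nmb",
    "verdict",
    "CEAResult",
    "compare_arms",
]

#: Strategy B is cheaper and more effective (ICER uninterpretable).
DOMINANT = "dominant"
#: Strategy B is costlier and less effective.
DOMINATED = "dominated"
#: Effect difference is exactly zero.
UNDEFINED = "undefined"
COST_EFFECTIVE = "cost-effective"
NOT_COST_EFFECTIVE = "not cost-effective"

ICERValue = Union[float, str]


def icer(cost_b: float, cost_a: float,
         effect_b: float, effect_a: float) -> ICERValue:
    """Incremental cost-effectiveness ratio of B versus A, or a flag.

    Returns ``(cost_b - cost_a) / (effect_b - effect_a)`` when the effects
    differ; :data:`DOMINANT` when B is cheaper and more effective,
    :data:`DOMINATED` when B is costlier and less effective, and
    :data:`UNDEFINED` when the effect difference is exactly zero.
    """
    dc = cost_b - cost_a
    de = effect_b - effect_a
    if de == 0.0:
        return UNDEFINED
    if dc < 0.0 and de > 0.0:
        return DOMINANT
    if dc > 0.0 and de < 0.0:
        return DOMINATED
    return dc / de


def cer(cost: float, effect: float) -> float:
    """Average cost-effectiveness ratio, cost per unit of effect."""
    if effect <= 0.0:
        raise ValueError(f"effect must be positive for a CER, got {effect}")
    return cost / effect


def nmb(cost: float, effect: float, wtp: float) -> float:
    """Net monetary benefit ``effect * wtp - cost``."""
    if wtp < 0.0:
        raise ValueError(f"willingness-to-pay {wtp} is negative")
    return effect * wtp - cost


def verdict(delta_cost: float, delta_effect: float, wtp: float) -> str:
    """Classify strategy B against A at one WTP threshold.

    Dominance short-circuits the ratio; otherwise B is cost-effective iff
    its incremental net monetary benefit is >= 0 (ties count as
    cost-effective).
    """
    if delta_cost < 0.0 and delta_effect > 0.0:
        return DOMINANT
    if delta_cost > 0.0 and delta_effect < 0.0:
        return DOMINATED
    inmb = nmb(delta_cost, delta_effect, wtp)
    return COST_EFFECTIVE if inmb >= 0.0 else NOT_COST_EFFECTIVE


@dataclass
class CEAResult:
    """Incremental and per-arm cost-effectiveness quantities at one horizon."""

    horizon: str
    cost_evt: float
    qaly_evt: float
    cost_evt_ivt: float
    qaly_evt_ivt: float
    delta_cost: float
    delta_effect: float
    icer: ICERValue
    cer_evt: float
    cer_evt_ivt: float
    nmb_per_wtp: dict[float, dict[str, float]] = field(default_factory=dict)
    verdict_per_wtp: dict[float, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "horizon": self.horizon,
            "evt": {"cost": self.cost_evt, "qaly": self.qaly_evt,
                    "cer": self.cer_evt},
            "evt_ivt": {"cost": self.cost_evt_ivt, "qaly": self.qaly_evt_ivt,
                        "cer": self.cer_evt_ivt},
            "delta_cost": self.delta_cost,
            "delta_effect": self.delta_effect,
            "icer": self.icer,
            "nmb": {str(w): v for w, v in self.nmb_per_wtp.items()},
            "verdict": {str(w): v for w, v in self.verdict_per_wtp.items()},
        }


def compare_arms(evt: ArmOutcome, evt_ivt: ArmOutcome,
                 wtp_values: Iterable[float]) -> CEAResult:
    """Full incremental comparison of EVT + IVT versus EVT alone."""
    if evt.horizon != evt_ivt.horizon:
        raise ValueError(
            f"horizon mismatch: {evt.horizon!r} vs {evt_ivt.horizon!r}")
    dc = evt_ivt.cost - evt.cost
    de = evt_ivt.qaly - evt.qaly
    result = CEAResult(
        horizon=evt.horizon,
        cost_evt=evt.cost,
        qaly_evt=evt.qaly,
        cost_evt_ivt=evt_ivt.cost,
        qaly_evt_ivt=evt_ivt.qaly,
        delta_cost=dc,
        delta_effect=de,
        icer=icer(evt_ivt.cost, evt.cost, evt_ivt.qaly, evt.qaly),
        cer_evt=cer(evt.cost, evt.qaly),
        cer_evt_ivt=cer(evt_ivt.cost, evt_ivt.qaly),
    )
    for wtp in wtp_values:
        result.nmb_per_wtp[float(wtp)] = {
            "evt": nmb(evt.cost, evt.qaly, wtp),
            "evt_ivt": nmb(evt_ivt.cost, evt_ivt.qaly, wtp),
            "incremental": nmb(dc, de, wtp),
        }
        result.verdict_per_wtp[float(wtp)] = verdict(dc, de, wtp)
    return result
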