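"""Synthetic hospital-information-system (HIS) discharge records.

The study cohort was extracted from a ten-year hospital database: 42,554
ischemic-stroke discharges (ICD-10 code I63 and sub-codes), of which 3,449
carried an endovascular-treatment (EVT) primary operation code (00.6 and
its sub-codes, or 39.74) and 30 of those additionally carried the
intravenous-thrombolysis code I99.1 in operation positions 2-6.  The real
records are confidential, so this module generates seeded synthetic
records that are exactly recoverable by the same extraction rules, and
implements those rules plus the cost-input estimator.

Per-record direct-cost components (operative treatment, operative
materials, medicine, nursing, and a residual "other") are drawn from
log-normal distributions -- non-negative and right-skewed, as
administrative cost data are.  Each arm's components share one coefficient
of variation, chosen so that the sampling distribution of the cohort mean
matches the published 95% interval of the arm's direct treatment cost at
the configured cohort size.  Code planting is deterministic (counts are
exact by construction); costs are stochastic.  Admission dates are
provenance only and never enter the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .params import (
    CI_WIDTH_IN_SD,
    ModelParameters,
    ValidationError,
    load_parameters,
)

__all__ = [
    "HISFixtureConfig",
    "CostEstimate",
    "generate_his",
    "extract_evt_cohorts",
    "estimate_cost_inputs",
    "residual_other_cost",
    "COST_COLUMNS",
    "OP_COLUMNS",
]

#: EVT primary operation codes: 00.6 with sub-codes, plus 39.74.
EVT_PRIMARY_PREFIX = "00.6"
EVT_PRIMARY_EXACT = "39.74"
IVT_CODE = "I99.1"

OP_COLUMNS = [f"op{i}" for i in range(1, 7)]
COST_COMPONENTS = ["operative_treatment", "operative_materials",
                   "medicine", "nursing", "other"]
COST_COLUMNS = [f"cost_{c}" for c in COST_COMPONENTS]

_EVT_CODE_POOL = ["00.6", "00.61", "00.62", "00.63", "00.64", "00.65",
                  "39.74"]
_NON_EVT_CODE_POOL = ["99.18", "38.91", "88.41", "89.52", "99.29", "03.31"]
_ICD10_POOL = ["I63", "I63.0", "I63.3", "I63.4", "I63.5", "I63.8", "I63.9"]


def residual_other_cost(total_mean: float,
                        component_means: Sequence[float]) -> float:
    """Unitemised "various associated costs": total minus named components."""
    residual = float(total_mean) - float(sum(component_means))
    if residual < -1e-9:
        raise ValidationError(
            f"component sum {sum(component_means)} exceeds total "
            f"{total_mean}")
    return max(residual, 0.0)


@dataclass
class ArmCostTarget:
    """Target cohort-level cost moments for one arm of the generator."""

    n: int
    component_means: dict[str, float]
    ci_lo: float
    ci_hi: float

    @property
    def total_mean(self) -> float:
        return sum(self.component_means.values())

    @property
    def patient_sd(self) -> float:
        # The printed interval is a 95% CI of the cohort mean at size n;
        # the patient-level sd follows from sd_mean * sqrt(n).
        sd_mean = (self.ci_hi - self.ci_lo) / CI_WIDTH_IN_SD
        return sd_mean * math.sqrt(self.n)


@dataclass
class HISFixtureConfig:
    """Cohort sizes, date range and cost targets for the generator."""

    n_total: int = 42554
    n_evt: int = 3449
    n_evt_ivt: int = 30
    n_ivt_only: int = 800          # I63 patients thrombolysed without EVT
    date_start: str = "2013-01-01"
    date_end: str = "2023-09-30"
    non_evt_cost_mean: float = 10740.0   # typical IS hospitalisation, RMB
    non_evt_cost_cv: float = 1.0
    evt: ArmCostTarget | None = None
    evt_ivt: ArmCostTarget | None = None

    def validate(self) -> None:
        if not (0 <= self.n_evt_ivt <= self.n_evt <= self.n_total):
            raise ValidationError(
                f"cohort sizes must nest: EVT+IVT ({self.n_evt_ivt}) <= "
                f"EVT ({self.n_evt}) <= total ({self.n_total})")
        if self.n_ivt_only < 0:
            raise ValidationError("n_ivt_only must be non-negative")

    @classmethod
    def from_parameters(cls, params: ModelParameters | None = None,
                        **overrides) -> "HISFixtureConfig":
        """Build the default fixture from the base-case cost inputs."""
        if params is None:
            params = load_parameters()
        cfg = cls(**overrides)
        for key, n_default in (("evt", cfg.n_evt), ("evt_ivt", cfg.n_evt_ivt)):
            if getattr(cfg, key) is None:
                arm = params.arm(key)
                comp = dict(arm.components)
                comp["other"] = residual_other_cost(
                    arm.direct_treatment.mean, list(comp.values()))
                setattr(cfg, key, ArmCostTarget(
                    n=n_default,
                    component_means=comp,
                    ci_lo=arm.direct_treatment.lo,
                    ci_hi=arm.direct_treatment.hi))
        cfg.validate()
        return cfg


def _lognormal_components(rng: np.random.Generator, target: ArmCostTarget,
                          n_rows: int) -> dict[str, np.ndarray]:
    """Draw per-record component costs hitting the target moments.

    All components share one coefficient of variation c, solved so the
    per-record total has the target patient-level variance:
    sum(c^2 m_i^2) = sd_patient^2.  Each drawn column is then standardised
    to its target mean -- the published cohort means are observed
    quantities, so the synthetic cohort reproduces them exactly while the
    patient-level spread still reproduces the published 95% interval
    through the normal-theory estimator.
    """
    means = np.array([target.component_means[c] for c in COST_COMPONENTS])
    cv = target.patient_sd / math.sqrt(float(np.sum(means ** 2)))
    sigma2 = math.log1p(cv * cv)
    sigma = math.sqrt(sigma2)
    out = {}
    for comp, mean in zip(COST_COMPONENTS, means):
        mu = math.log(mean) - sigma2 / 2.0
        draws = rng.lognormal(mu, sigma, size=n_rows)
        if n_rows > 0 and draws.mean() > 0:
            draws *= mean / draws.mean()
        out[comp] = draws
    return out


def generate_his(fixture_config: HISFixtureConfig | None = None,
                 seed: int = 0,
                 params: ModelParameters | None = None) -> pd.DataFrame:
    """Generate a seeded synthetic HIS discharge table.

    Returns a DataFrame with one row per discharge: ``patient_id``,
    ``icd10``, ``op1``..``op6`` (position 1 = primary operation code),
    ``admission_date``, one ``cost_*`` column per component and
    ``cost_total``.  Identical seeds give identical tables.
    """
    cfg = fixture_config or HISFixtureConfig.from_parameters(params)
    cfg.validate()
    if cfg.evt is None or cfg.evt_ivt is None:
        cfg = HISFixtureConfig.from_parameters(
            params, **{f.name: getattr(cfg, f.name)
                       for f in cfg.__dataclass_fields__.values()
                       if f.name not in ("evt", "evt_ivt")})
    rng = np.random.default_rng(seed)
    n = cfg.n_total
    n_evt, n_ivt = cfg.n_evt, cfg.n_evt_ivt
    n_other = n - n_evt

    icd10 = rng.choice(_ICD10_POOL, size=n)
    ops = np.full((n, 6), "", dtype=object)

    # Rows [0, n_evt) are the EVT set; of those, [0, n_ivt) also got IVT.
    ops[:n_evt, 0] = rng.choice(_EVT_CODE_POOL, size=n_evt)
    ivt_positions = rng.integers(1, 6, size=n_ivt)  # columns 2..6
    for row, pos in enumerate(ivt_positions):
        ops[row, pos] = IVT_CODE
    ops[n_evt:, 0] = rng.choice(_NON_EVT_CODE_POOL, size=n_other)
    # Some non-EVT stroke patients are thrombolysed without surgery: they
    # carry I99.1 in a secondary slot but must not be extracted.
    n_ivt_only = min(cfg.n_ivt_only, n_other)
    ivt_only_rows = n_evt + np.arange(n_ivt_only)
    for row, pos in zip(ivt_only_rows, rng.integers(1, 6, size=n_ivt_only)):
        ops[row, pos] = IVT_CODE

    # Sparse additional secondary codes for realism.
    extra = rng.random((n, 4)) < 0.15
    filler = rng.choice(_NON_EVT_CODE_POOL, size=(n, 4))
    for j in range(4):
        col = ops[:, 1 + j]
        mask = extra[:, j] & (col == "")
        col[mask] = filler[mask, j]

    costs = {c: np.empty(n) for c in COST_COLUMNS}
    evt_only_slice = slice(n_ivt, n_evt)
    draws_ivt = _lognormal_components(rng, cfg.evt_ivt, n_ivt)
    draws_evt = _lognormal_components(rng, cfg.evt, n_evt - n_ivt)
    for comp in COST_COMPONENTS:
        costs[f"cost_{comp}"][:n_ivt] = draws_ivt[comp]
        costs[f"cost_{comp}"][evt_only_slice] = draws_evt[comp]
    # Non-EVT strokes: cheaper medical admissions, mostly medicine/nursing.
    shares = {"operative_treatment": 0.05, "operative_materials": 0.05,
              "medicine": 0.55, "nursing": 0.15, "other": 0.20}
    sigma2 = math.log1p(cfg.non_evt_cost_cv ** 2)
    sigma = math.sqrt(sigma2)
    for comp in COST_COMPONENTS:
        mean = cfg.non_evt_cost_mean * shares[comp]
        mu = math.log(mean) - sigma2 / 2.0
        costs[f"cost_{comp}"][n_evt:] = rng.lognormal(mu, sigma,
                                                      size=n_other)

    start = pd.Timestamp(cfg.date_start)
    end = pd.Timestamp(cfg.date_end)
    offsets = rng.integers(0, (end - start).days + 1, size=n)
    dates = (start + pd.to_timedelta(offsets, unit="D")).strftime("%Y-%m-%d")

    frame = pd.DataFrame({
        "patient_id": [f"P{i:07d}" for i in range(n)],
        "icd10": icd10,
        **{OP_COLUMNS[j]: ops[:, j] for j in range(6)},
        "admission_date": dates,
    })
    for col in COST_COLUMNS:
        frame[col] = np.round(costs[col], 2)
    frame["cost_total"] = frame[COST_COLUMNS].sum(axis=1)

    # Shuffle rows so arm membership is not positional in the output.
    order = rng.permutation(n)
    return frame.iloc[order].reset_index(drop=True)


def _is_evt_primary(code: str) -> bool:
    return code == EVT_PRIMARY_EXACT or code.startswith(EVT_PRIMARY_PREFIX)


def extract_evt_cohorts(records: pd.DataFrame
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the study's extraction rules to a discharge table.

    The EVT set contains records whose primary operation code is 00.6, any
    00.6 sub-code, or 39.74; the EVT + IVT subset additionally carries
    I99.1 in any of operation positions 2-6.  Returns
    ``(evt_only, evt_ivt)`` -- a disjoint partition of the EVT set.
    """
    if records.empty:
        return records.copy(), records.copy()
    primary = records["op1"].astype(str)
    evt_mask = primary.map(_is_evt_primary)
    evt_set = records[evt_mask]
    secondary = evt_set[OP_COLUMNS[1:]].astype(str)
    ivt_mask = (secondary == IVT_CODE).any(axis=1)
    return evt_set[~ivt_mask].copy(), evt_set[ivt_mask].copy()


@dataclass
class CostEstimate:
    """Normal-theory mean and CI of direct treatment costs in a cohort."""

    mean: float
    ci_lo: float
    ci_hi: float
    n: int
    component_means: dict[str, float] = field(default_factory=dict)


def estimate_cost_inputs(cohort: pd.DataFrame,
                         ci_level: float = 0.95) -> CostEstimate:
    """Mean and normal-theory CI of the per-record total cost."""
    n = len(cohort)
    if n < 2:
        raise ValidationError(
            f"need at least 2 records to estimate costs, got {n}")
    totals = cohort["cost_total"].to_numpy(dtype=float)
    mean = float(totals.mean())
    sd = float(totals.std(ddof=1))
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    half = z * sd / math.sqrt(n)
    components = {
        comp: float(cohort[f"cost_{comp}"].mean())
        for comp in COST_COMPONENTS if f"cost_{comp}" in cohort
    }
    return CostEstimate(mean=mean, ci_lo=mean - half, ci_hi=mean + half,
                        n=n, component_means=components)
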