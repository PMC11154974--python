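# Methods

## Model structure and assumptions

The model is a 3-month decision tree followed by a discrete-time Markov
cohort with quarterly cycles and four states: GOOD (independent, mRS 0–2),
POOR (dependent, mRS 3–5), RECURRENT (a one-cycle tunnel for recurrent
stroke) and DEAD (absorbing). The decision tree is cycle 0: every patient
incurs the arm's direct treatment cost, undiscounted, and the quarter's
QALY is cycle-length times the outcome-weighted utility of the arm's
3-month mRS proportions. Survivors enter the chain in their 3-month
states.

Key structural choices, made where the published description is silent:

- **Death as residual mass.** The first-year transition rows list only
  GOOD/POOR destinations (0.955/0.024 from GOOD, 0.029/0.919 from POOR);
  the per-cycle death probabilities are the residuals, 0.021 and 0.052.
  After year 1 the same residuals serve as all-cause mortality proxies.
- **First-year rows are per-cycle.** The printed "in first year"
  probabilities are applied every quarter of year 1 (cycles 1–3; cycle 0
  is the decision tree). A config switch `transitions_are_annual` instead
  converts them through the constant-hazard map
  p_cycle = 1 − (1 − p_annual)^(1/4) for scenario analysis.
- **Post-year-1 freezing.** Dependent patients can only remain, recur or
  die after the first year; independent patients keep the
  first-occurrence row.
- **Recurrence.** The 9.6% annual recurrence rate is converted to a
  per-cycle probability r ≈ 0.0249 that competes with the printed row:
  each living row is the printed row scaled by (1 − r) plus mass r into
  the tunnel. Tunnel occupants accrue the recurrent-stroke utility
  (0.20), pay the arm's full direct treatment cost (re-treatment follows
  the first-stroke pattern), and exit into the arm's initial 3-month
  distribution — including its death mass, so recurrent strokes kill at
  the first-stroke rate.
- **No half-cycle correction.** Treatment costs fall at cycle start and
  state costs/utilities are valued at end-of-cycle occupancy. This keeps
  the 3-month cost of each arm exactly equal to its direct-cost input.
- **Termination.** Lifetime runs stop at the first cycle with cumulative
  mortality ≥ 99% (reached at cycle ~111–113, i.e. ≈28 years), with a
  safety cap of 200 cycles (50 years).

## Indirect costs

Only a total (RMB 57,595.37) and a DALY figure (7.95) are published; the
per-DALY value (RMB 7,244.70/yr) is back-solved so the product is exact.
Three accrual modes are supported via `indirect_mode`:

- `per_death` (default): the indirect total is charged, discounted, at
  each cohort member's death from cycle 1 onward. This gives the small
  but nonzero ICER sensitivity the tornado shows for indirect costs.
  Deaths inside the decision tree are not charged, keeping the 3-month
  cost equal to the direct-cost input.
- `lump_sum`: charged once per patient at entry in both arms; cancels
  from every incremental quantity.
- `excluded`: omitted.

## Sensitivity analyses

**One-way (tornado).** Each scalar input is set to base × 0.8 and
base × 1.2 with everything else fixed, and the lifetime ICER recomputed.
Perturbing a probability that lives on a simplex rescales the named
component and lets the residual death mass re-normalise; values are
clipped to their domains with a logged warning. The default parameter
list covers both direct treatment costs, both post-hospitalisation costs,
the indirect cost, the four utilities, the recurrence rate and the
discount rate.

**Probabilistic.** Distributions are fitted from printed means and 95%
intervals by method of moments, reading intervals as symmetric
normal-theory ranges (sd = (hi − lo)/3.92): Gamma for costs, Beta for
utilities and the recurrence rate, Dirichlet for the 3-month outcome
triples and the first-year transition rows (death as the residual third
component). Two values have no printed spread: the recurrence rate uses
a symmetric ±20% range (0.0768–0.1152) for its Beta fit, and the
Dirichlet effective sample size defaults to 600 (the order of a
meta-analysis arm) — both are config knobs, not calibrated values. Each
of the 10,000 iterations draws one joint parameter set, evaluates both
arms at the 3-month, 1-year and lifetime horizons in a single cohort
sweep, and records (ΔC, ΔE). EVT alone counts as cost-effective in a
draw when the incremental net monetary benefit of EVT + IVT is strictly
negative (ties, a measure-zero event, go to EVT + IVT). The CEAC is
evaluated on a WTP grid from 0 to 300,000 in steps of 5,000.

Because the two arms' sampled direct-cost ranges barely overlap
(86,766–130,161 vs 69,891–72,769) while the sampled QALY differences are
small, the probability that EVT alone is cost-effective at RMB
90,620/QALY computes to ≈99.7% (lifetime) and ≈100% (3-month, 1-year),
a few points above the published 96.89/97.90/97.43% — the sampling
spread that produced the published ~2–3% of contrary draws is not
derivable from the printed inputs. No calibration is performed to close
this gap; the knobs above are documented instead.

## Synthetic hospital records

The real cost database is confidential, so `synthetic_his` generates
seeded discharge records that the published extraction rules recover
exactly: 42,554 I63* admissions; 3,449 with an EVT primary operation code
(prefix 00.6, or 39.74); 30 of those with I99.1 in operation positions
2–6. Code planting is deterministic (counts exact by construction); the
fixture also plants I99.1 on ~800 non-surgical records to exercise the
"primary code first" rule. Per-record cost components are log-normal
(non-negative, right-skewed) with a common per-arm coefficient of
variation chosen so the normal-theory 95% CI of the cohort mean matches
the published interval at the configured cohort size; each drawn column
is then standardised to the published component mean, which is an
observed quantity of the real cohort. Admission dates are uniform over
2013-01-01 to 2023-09-30 and are provenance only.

What the generator does *not* emulate: clinical covariates, within-record
cost correlations, temporal cost inflation, and any linkage between costs
and outcomes (effectiveness inputs come from trial meta-analysis, not the
HIS). Passing recovery tests therefore shows the estimation pipeline is
correct, not that real hospital data would yield these numbers.

## Numerical choices

- Probabilities are validated to their simplexes at 1e-9; occupancy mass
  is conserved to the same tolerance each cycle.
- Monetary values are 2023 RMB throughout; no inflation indexing or
  currency conversion.
- The fast evaluation path (`evaluate_arm_horizons`) computes all three
  horizons in one cohort sweep with scalar arithmetic; it is verified
  against the general `run_markov` engine in the test suite, and the
  cohort engine itself is validated against a 100,000-patient
  individual-level microsimulation oracle (agreement within 3 standard
  errors).
- PSA and generator runs are fully determined by (config, seed) via
  numpy's `default_rng`; identical seeds give bit-identical outputs.

## Known limitations and reported discrepancies

- The published 3-month QALYs (0.15/0.16) are not reproducible from the
  printed utilities and proportions (a fully independent cohort caps at
  0.25 × 0.76 = 0.19, and the printed proportions give 0.1116/0.1145);
  this package reports the accrual-rule values and surfaces the
  difference rather than reconciling it silently. Likewise the published
  lifetime cost/QALY cells depend on unstated post-year-1 mortality and
  indirect-cost mechanics; under the defaults above the lifetime ICER
  computes to RMB 731,580.75/QALY against the published 696,399.30 —
  same side of every decision threshold.
- No age/sex life tables, time-varying utilities, multi-way frontiers or
  value-of-information analysis; the model is a two-strategy quarterly
  chain with fixed probabilities, as specified.
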