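# strokecea

A decision-analytic cost-effectiveness model comparing **endovascular
treatment (EVT) alone** against **EVT plus intravenous thrombolysis (IVT)**
for acute ischemic stroke, from the Chinese healthcare perspective (2023
RMB, Shandong Peninsula inputs). It is aimed at health economists and
methodologists who want a tested, scriptable re-implementation of this
class of stroke evaluation: a 3-month decision tree feeding a quarterly
recurrent-stroke Markov cohort, incremental cost-effectiveness analysis
against willingness-to-pay (WTP) thresholds, a ±20% tornado analysis, and
a 10,000-iteration Monte Carlo probabilistic sensitivity analysis (PSA).
Because the underlying hospital cost database is confidential, the package
also ships a seeded synthetic hospital-record generator that reproduces
the published cohort-extraction and cost-estimation procedures.

## The model

Patients enter a decision tree for the first 90 days: each arm incurs its
direct treatment cost *C*ₐ and distributes over three modified Rankin
Scale (mRS) outcomes — good (mRS 0–2), poor (mRS 3–5) or death (mRS 6).
Survivors then cycle quarterly through a four-state Markov chain
{GOOD, POOR, RECURRENT, DEAD}, where RECURRENT is a one-cycle tunnel:
recurrent strokes (annual rate 9.6%, converted to a per-cycle probability
*r* = 1 − (1 − 0.096)^¼) are re-treated with the same strategy at full cost
and exit into the arm's initial 3-month outcome distribution. Death
probabilities are the residual mass of the published first-year rows;
after year 1, dependent patients can no longer improve. The run ends when
cumulative mortality reaches 99%.

Discounted quarterly accruals (discount rate 3%/yr, cycle length Δ = 0.25):

- QALY increment: Δ·(π_G·u_G + π_P·u_P + π_R·u_R), with utilities
  u_G = 0.76, u_P = 0.21, u_R = 0.20, u_death = 0;
- cost increment: Δ·(π_G·7385 + π_P·11350) + π_R·Cₐ, plus the indirect
  human-capital cost (RMB 57,595.37 = 7.95 DALYs × RMB 7,244.70) at death.

Strategies are compared by ICER = ΔC/ΔE, per-arm cost-effectiveness
ratios, and net monetary benefit E·λ − C at WTP thresholds λ of 1× and 3×
regional GDP per capita (RMB 90,620 and 271,860 per QALY). The PSA
resamples costs (Gamma), utilities and the recurrence rate (Beta), and the
outcome/transition simplexes (Dirichlet), all fitted by method of moments
from the published means and 95% intervals.

## Worked example

```bash
strokecea run-base-case
```

prints (abridged):

```
 horizon  strategy      cost  qaly_full_precision       cer        icer  verdict_wtp_271860
      3m EVT alone  71329.86               0.1116 639301.10
      3m EVT + IVT 108463.60               0.1145 947588.63 12857943.21  not cost-effective
      1y EVT alone  85474.53               0.4177 204640.74
      1y EVT + IVT 124891.75               0.4283 291632.78  3729458.59  not cost-effective
lifetime EVT alone 184241.02               2.3202  79407.12
lifetime EVT + IVT 240482.99               2.3971 100323.09   731580.75  not cost-effective
```

Reading the lifetime rows: EVT alone accumulates a discounted RMB
184,241.02 and 2.3202 QALYs per patient before 99% of the cohort has died;
adding IVT costs RMB 56,241.97 more and gains 0.0769 QALYs, an ICER of RMB
731,580.75 per QALY — far above the 3×GDP threshold of RMB 271,860, so
EVT + IVT is not cost-effective at any horizon. The 3-month costs equal
the direct-treatment inputs exactly because every branch incurs them
undiscounted at cycle 0.

Other subcommands: `run-owsa` (tornado CSV — the two direct treatment
costs dominate the ICER's sensitivity), `run-psa` (CE-plane, CEAC and
summary; at λ = RMB 90,620/QALY EVT alone is the cost-effective choice in
≈99.7% of 10,000 lifetime iterations), `simulate-his` (synthetic discharge
records: 42,554 stroke admissions of which the primary-code filter
00.6*/39.74 extracts 3,449 EVT patients and the secondary-code rule I99.1
flags 30 EVT + IVT patients), and `validate-config`.

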