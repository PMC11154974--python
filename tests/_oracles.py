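"""Independent oracles used by several test modules.

The microsimulation re-implements the cohort rules at the individual
level: each simulated patient walks the four-state chain one transition at
a time, accruing the same per-cycle costs and QALYs.  Averaging over many
patients must reproduce the cohort model's expected discounted totals
(within Monte Carlo error), which checks the matrix bookkeeping of the
cohort engine against a brute-force path simulation.
"""

import numpy as np

from strokecea import build_transition_matrix, run_markov
from strokecea.cohort_model import HealthState


def microsimulate_arm(arm_key, params, n_patients, seed, n_cycles=None):
    """Individual-level Monte Carlo run of one arm.

    Returns (mean_cost, mean_qaly, se_cost, se_qaly).  ``n_cycles`` limits
    the Markov phase; by default it matches the cohort model's own
    lifetime stopping cycle so both compute the same horizon.
    """
    if n_cycles is None:
        n_cycles = run_markov(arm_key, params, "lifetime",
                              keep_trace=False).cycles_run
    ec = params.economics
    arm = params.arm(arm_key)
    u = params.utilities
    co = params.costs
    cl = ec.cycle_length

    rng = np.random.default_rng(seed)
    dist = arm.mrs_3m
    states = rng.choice(4, size=n_patients,
                        p=[dist.p_good, dist.p_poor, 0.0, dist.p_dead])
    cost = np.full(n_patients, arm.direct_treatment.mean)
    if params.indirect_mode == "lump_sum":
        cost += co.indirect_total
    qaly = np.where(states == HealthState.GOOD, cl * u.u_good.mean,
                    np.where(states == HealthState.POOR,
                             cl * u.u_poor.mean, 0.0))

    m_first = build_transition_matrix(arm_key, params, "first_year")
    m_post = build_transition_matrix(arm_key, params, "post_first_year")
    cum_first = np.cumsum(m_first, axis=1)
    cum_post = np.cumsum(m_post, axis=1)
    first_cycles = ec.cycles_per_year - 1

    c_state = np.array([cl * co.post_hosp_annual_good.mean,
                        cl * co.post_hosp_annual_poor.mean,
                        arm.direct_treatment.mean, 0.0])
    q_state = np.array([cl * u.u_good.mean, cl * u.u_poor.mean,
                        cl * u.u_recurrent.mean, 0.0])
    indirect = (co.indirect_total if params.indirect_mode == "per_death"
                else 0.0)

    for k in range(1, n_cycles + 1):
        cum = cum_first if k <= first_cycles else cum_post
        alive = states != HealthState.DEAD
        if not alive.any():
            break
        uvals = rng.random(n_patients)
        new_states = (uvals[alive, None] >
                      cum[states[alive]][:, :-1]).sum(axis=1)
        died = new_states == HealthState.DEAD
        df = (1.0 + ec.discount_annual) ** (-k * cl)
        cost[alive] += df * (c_state[new_states] + indirect * died)
        qaly[alive] += df * q_state[new_states]
        states[alive] = new_states

    return (cost.mean(), qaly.mean(),
            cost.std(ddof=1) / np.sqrt(n_patients),
            qaly.std(ddof=1) / np.sqrt(n_patients))
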