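"""Independent enumerate-and-sum oracle for the Markov cohort model.

Implemented with explicit per-cycle transition matrices and row-vector
algebra — deliberately a different mechanism from the engine's scalar
flow ledger — so the two can cross-check each other on small instances.
"""

import numpy as np

NC, C, T, E = range(4)


def oracle_totals(
    cohort_size,
    rows,  # list of (prob_caries, prob_exit, baseline_dmft)
    effect,
    annual_cost,
    discount_rate,
    prob_untreated,
    prob_recurrence,
    dmft_growth,
    exit_first=True,
):
    """Discounted (total_cost, total_dmft) via matrix propagation."""
    v = np.array([float(cohort_size), 0.0, 0.0, 0.0])
    total_cost = 0.0
    total_dmft = 0.0
    for t, (p_car, p_exit, dmft_base) in enumerate(rows):
        exit_m = np.eye(4)
        for s in (NC, C, T):
            exit_m[s, s] = 1.0 - p_exit
            exit_m[s, E] = p_exit

        onset = p_car * (1.0 - effect)
        morb = np.eye(4)
        morb[NC, NC] = 1.0 - onset
        morb[NC, C] = onset
        morb[C, C] = prob_untreated
        morb[C, T] = 1.0 - prob_untreated
        morb[T, C] = prob_recurrence
        morb[T, T] = 1.0 - prob_recurrence

        df = (1.0 + discount_rate) ** (-t)
        if exit_first:
            v_mid = v @ exit_m
            entrants = v_mid[NC] * onset
            v_new = v_mid @ morb
            living = v_new[:E].sum()
        else:
            entrants = v[NC] * onset
            v_new = (v @ morb) @ exit_m
            living = v[:E].sum()
        total_cost += annual_cost * living * df
        total_dmft += entrants * dmft_base * (1.0 + dmft_growth) ** t * df
        v = v_new
    return total_cost, total_dmft
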