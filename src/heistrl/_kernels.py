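"""Compiled inner loop for choice likelihoods.

The hierarchical fitter evaluates the sequential likelihood thousands of
times; this module holds a numba-compiled replica of the update equations in
:mod:`heistrl.learner` operating on pre-encoded integer arrays.  A test
asserts its equivalence to the readable Python path.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def loglik_kernel(
    cond, ctx, free, missed, choice_dark, state_heist, gain, alpha, beta, w, flexible
):
    p_spec = np.full(4, 0.5)
    p_ind = np.full(2, 0.5)
    ll = 0.0
    for t in range(cond.shape[0]):
        if missed[t] == 1:
            continue
        c = cond[t]  # 0 dependent, 1 independent
        if flexible and c == 1:
            w_eff = 1.0 - w
        else:
            w_eff = w
        p_hat = w_eff * p_ind[c] + (1.0 - w_eff) * p_spec[ctx[t]]
        if free[t] == 1:
            r = 1.0 if gain[t] == 1 else -1.0
            # q_dark - q_light = r * (2 p_hat - 1)
            z = beta * r * (2.0 * p_hat - 1.0)
            if z > 35.0:
                p_dark = 1.0
            elif z < -35.0:
                p_dark = 0.0
            else:
                p_dark = 1.0 / (1.0 + np.exp(-z))
            p_choice = p_dark if choice_dark[t] == 1 else 1.0 - p_dark
            if p_choice < 1e-300:
                p_choice = 1e-300
            ll += np.log(p_choice)
        x = 1.0 if choice_dark[t] == state_heist[t] else 0.0
        delta = x - p_hat
        p_ind[c] = min(max(p_ind[c] + w_eff * alpha * delta, 0.0), 1.0)
        k = ctx[t]
        p_spec[k] = min(max(p_spec[k] + (1.0 - w_eff) * alpha * delta, 0.0), 1.0)
    return ll
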