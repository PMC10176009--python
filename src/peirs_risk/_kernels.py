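"""Compiled inner loop for the session log-likelihood.

The hierarchical EM fit evaluates the likelihood tens of thousands of
times, so the trial loop is jitted with numba.  The pure-python replay
in :mod:`.model_core` serves as the readable reference implementation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

Q_INIT = 50.0
S_INIT = 5.0
N_STIM = 8


@njit(cache=True)
def session_loglik_kernel(alpha_q, alpha_s, beta, gamma0, gamma1, use_gamma,
                          chosen, other, reward, set_base):
    q = np.full(N_STIM, Q_INIT)
    s = np.full(N_STIM, S_INIT)
    ll = 0.0
    for t in range(chosen.shape[0]):
        c = chosen[t]
        o = other[t]
        if o >= 0:
            if use_gamma:
                b = set_base[t]
                q_all = 0.25 * (q[b] + q[b + 1] + q[b + 2] + q[b + 3])
                dc = 0.5 * (q[c] + q[o]) - q_all
                u_c = q[c] + gamma0 * s[c] + gamma1 * dc * s[c]
                u_o = q[o] + gamma0 * s[o] + gamma1 * dc * s[o]
            else:
                u_c = q[c]
                u_o = q[o]
            x = beta * (u_c - u_o)
            # stable log-sigmoid
            if x < -35.0:
                ll += x
            else:
                ll += -np.log1p(np.exp(-x))
        r = reward[t]
        pe = r - q[c]
        s[c] += alpha_s * (abs(pe) - s[c])
        q[c] += alpha_q * pe
    return ll
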