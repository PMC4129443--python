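"""Compiled inner loop for the choice log-likelihood.

Model fitting evaluates the sequential likelihood thousands of times per
optimizer run, so the trial loop is JIT-compiled.  The kernel replays the
value/learning-rate recursion over observed (choice, outcome) pairs exactly
as the pure-Python agent does; equivalence is enforced by tests against a
straight-line reference implementation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: Per-trial choice probabilities are clipped to
#: [P_FLOOR, 1 - P_FLOOR] inside the log, preventing -inf at extreme beta
#: without materially moving optima.
P_FLOOR = 1e-12


@njit(cache=False)
def nll_sessions(
    choices0: np.ndarray,   # int64, 0-based choices, all sessions concatenated
    outcomes: np.ndarray,   # float64, same length
    offsets: np.ndarray,    # int64, session start indices, length n_sessions+1
    alpha0: float,
    beta: float,
    eta: float,
) -> float:
    """Summed negative log-likelihood over sessions; state resets per session."""
    total = 0.0
    for s in range(offsets.size - 1):
        q0 = 0.0
        q1 = 0.0
        alpha = alpha0
        for t in range(offsets[s], offsets[s + 1]):
            x = beta * (q0 - q1)
            if x >= 0.0:
                p_opt1 = 1.0 / (1.0 + np.exp(-x))
            else:
                e = np.exp(x)
                p_opt1 = e / (1.0 + e)
            a = choices0[t]
            p = p_opt1 if a == 0 else 1.0 - p_opt1
            if p < P_FLOOR:
                p = P_FLOOR
            elif p > 1.0 - P_FLOOR:
                p = 1.0 - P_FLOOR
            total -= np.log(p)
            r = outcomes[t]
            if a == 0:
                d = r - q0
                q0 += alpha * d
            else:
                d = r - q1
                q1 += alpha * d
            if d < 0.0:
                d = -d
            alpha = eta * d + (1.0 - eta) * alpha
    return total
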