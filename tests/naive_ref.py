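"""Deliberately naive straight-line reference for the choice models.

Scalar math only, no package internals: replays the value / learning-rate
recursion over a recorded (choice, outcome) sequence and returns the
per-trial probability of the observed choice and the summed negative log
likelihood.  Serves as the independent oracle for the production
implementations (vectorized simulator traces and the compiled likelihood
kernel).
"""

import math


def replay_choice_probs(choices, outcomes, alpha0, beta, eta):
    """Per-trial P(observed choice) and P(option 1) under the hybrid recursion.

    choices are 1/2, outcomes 0/1.  Q starts at (0, 0), alpha(1) = alpha0;
    the chosen value moves by alpha(t) * (R - Q), then
    alpha(t+1) = eta |delta| + (1 - eta) alpha(t).
    """
    q = [0.0, 0.0]
    alpha = alpha0
    p_obs, p_opt1 = [], []
    for a, r in zip(choices, outcomes):
        x = beta * (q[0] - q[1])
        p1 = 1.0 / (1.0 + math.exp(-x)) if x >= 0 else \
            math.exp(x) / (1.0 + math.exp(x))
        p_opt1.append(p1)
        p_obs.append(p1 if a == 1 else 1.0 - p1)
        i = int(a) - 1
        delta = r - q[i]
        q[i] = q[i] + alpha * delta
        alpha = eta * abs(delta) + (1.0 - eta) * alpha
    return p_obs, p_opt1


def negative_log_likelihood(choices, outcomes, alpha0, beta, eta):
    p_obs, _ = replay_choice_probs(choices, outcomes, alpha0, beta, eta)
    return -sum(math.log(p) for p in p_obs)
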