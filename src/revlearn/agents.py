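"""Generative decision models: Q-learning and the hybrid RW/PH agent.

Both agents track a value Q_a(t) per option and choose by a softmax on the
value difference.  The chosen option's value moves toward the outcome by a
fraction alpha(t) of the reward-prediction error delta(t) = R(t) - Q_a(t);
the unchosen value never changes.  Standard Q-learning keeps alpha constant
(the Rescorla-Wagner rule); the hybrid agent additionally lets the learning
rate track the recent magnitude of prediction errors (Pearce-Hall
associability),

    alpha(t+1) = eta * |delta(t)| + (1 - eta) * alpha(t),

so big surprises speed up subsequent learning.  eta = 0 recovers standard
Q-learning exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit

from .task import TaskConfig, advantage_schedule

__all__ = [
    "MODELS",
    "AgentParams",
    "AgentState",
    "Session",
    "softmax_prob",
    "update_value",
    "update_alpha",
    "simulate_session",
    "simulate_batch",
]

#: Recognized model identifiers.  ``qlearning`` is the eta = 0 special case
#: of ``hybrid``.
MODELS = ("qlearning", "hybrid")


@dataclass(frozen=True)
class AgentParams:
    """Agent parameters (alpha0, beta, eta).

    alpha0 : initial learning rate, in [0, 1].  For Q-learning this is the
        (constant) learning rate alpha; for the hybrid agent alpha(1) = alpha0.
    beta : softmax inverse temperature, >= 0.  Larger beta means more
        exploitative (deterministic) choice.
    eta : learning-rate plasticity, in [0, 1].  Weight of the most recent
        absolute prediction error in the learning rate.  eta = 0 freezes the
        rate, i.e. standard Q-learning.
    """

    alpha0: float
    beta: float
    eta: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha0 <= 1.0:
            raise ValueError(f"alpha0 must lie in [0, 1], got {self.alpha0}")
        if not self.beta >= 0.0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError(f"eta must lie in [0, 1], got {self.eta}")


@dataclass(frozen=True)
class AgentState:
    """Latent state entering a trial: values, current rate, trial index (1-based)."""

    q_values: tuple[float, float] = (0.0, 0.0)
    alpha_t: float = 0.0
    trial: int = 1


@dataclass
class Session:
    """One participant-block of choices and outcomes, the unit of fitting.

    ``choices`` take values in {1, 2}; ``outcomes`` in {reward, loss}
    encoding (1/0).  Simulated sessions additionally carry latent traces:
    per-trial choice probability of option 1, Q values entering each trial,
    and the learning rate alpha(t) in effect on each trial.
    """

    choices: np.ndarray
    outcomes: np.ndarray
    participant_id: str = "sim"
    block: int = 1
    p_option1: Optional[np.ndarray] = None
    q_values: Optional[np.ndarray] = None
    alpha: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.choices = np.asarray(self.choices, dtype=np.int8)
        self.outcomes = np.asarray(self.outcomes, dtype=np.float64)
        if self.choices.shape != self.outcomes.shape:
            raise ValueError("choices and outcomes must have equal length")
        if not np.isin(self.choices, (1, 2)).all():
            raise ValueError("choices must take values in {1, 2}")

    @property
    def n_trials(self) -> int:
        return int(self.choices.size)


def softmax_prob(q_values, beta: float) -> float:
    """Probability of choosing option 1 given a pair of Q values.

    P(a = 1) = 1 / (1 + exp(-beta * (Q1 - Q2))); P(a = 2) is the complement.
    Overflow-safe for arbitrarily large ``beta * (Q1 - Q2)`` (saturates at
    0 or 1, never NaN).
    """
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    q1, q2 = q_values
    return float(expit(beta * (q1 - q2)))


def update_value(state: AgentState, choice: int, outcome: float) -> AgentState:
    """Apply the error-driven value update for the chosen option.

    Q_chosen <- Q_chosen + alpha(t) * (R(t) - Q_chosen); the unselected
    option's value is unchanged.  ``state.alpha_t`` must be the rate in
    effect for this trial.
    """
    if choice not in (1, 2):
        raise ValueError(f"choice must be 1 or 2, got {choice}")
    if not 0.0 <= outcome <= 1.0:
        raise ValueError(f"outcome must lie in [0, 1], got {outcome}")
    q = list(state.q_values)
    i = choice - 1
    q[i] = q[i] + state.alpha_t * (outcome - q[i])
    return dataclasses.replace(state, q_values=(q[0], q[1]), trial=state.trial + 1)


def update_alpha(alpha_t: float, eta: float, pred_error: float) -> float:
    """Pearce-Hall associability update for the next trial's learning rate.

    alpha(t+1) = eta * |delta(t)| + (1 - eta) * alpha(t).  A convex
    combination, so the result stays in [0, 1] whenever its inputs do.
    The rate used on trial t thus depends only on errors from trials < t.
    """
    return eta * abs(pred_error) + (1.0 - eta) * alpha_t


def simulate_session(
    params: AgentParams,
    config: TaskConfig = TaskConfig(),
    rng: Optional[np.random.Generator] = None,
    *,
    model: str = "hybrid",
    participant_id: str = "sim",
    block: int = 1,
    outcome_table: Optional[np.ndarray] = None,
) -> Session:
    """Simulate one session of the reversal-learning task.

    Per-trial order: (1) choice probability from the current Q values,
    (2) sample the choice, (3) draw the outcome, (4) update the chosen Q
    with alpha(t), (5) update alpha(t+1) from |delta(t)|.  Q starts at
    (0, 0) and alpha(1) = alpha0.

    ``model="qlearning"`` forces eta = 0, making the run definitionally
    identical to a hybrid run with eta = 0 and the same seed.
    ``outcome_table`` optionally supplies pre-drawn outcomes per
    (trial, option) from :func:`revlearn.task.pregenerate_outcomes`.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}, expected one of {MODELS}")
    if rng is None:
        rng = np.random.default_rng()
    eta = 0.0 if model == "qlearning" else params.eta

    n = config.n_trials
    adv = advantage_schedule(config)
    choices = np.empty(n, dtype=np.int8)
    outcomes = np.empty(n, dtype=np.float64)
    p1_trace = np.empty(n, dtype=np.float64)
    q_trace = np.empty((n, 2), dtype=np.float64)
    a_trace = np.empty(n, dtype=np.float64)

    q1 = q2 = 0.0
    alpha = params.alpha0
    for t in range(n):
        p1 = float(expit(params.beta * (q1 - q2)))
        q_trace[t] = (q1, q2)
        a_trace[t] = alpha
        p1_trace[t] = p1
        choice = 1 if rng.random() < p1 else 2
        if outcome_table is not None:
            r = float(outcome_table[t, choice - 1])
        else:
            p_rew = config.p_reward_adv if choice == adv[t] else config.p_reward_dis
            r = config.reward_value if rng.random() < p_rew else config.loss_value
        if choice == 1:
            delta = r - q1
            q1 += alpha * delta
        else:
            delta = r - q2
            q2 += alpha * delta
        alpha = eta * abs(delta) + (1.0 - eta) * alpha
        choices[t] = choice
        outcomes[t] = r
    return Session(
        choices=choices,
        outcomes=outcomes,
        participant_id=participant_id,
        block=block,
        p_option1=p1_trace,
        q_values=q_trace,
        alpha=a_trace,
    )


def simulate_batch(
    params: AgentParams,
    config: TaskConfig,
    n_sessions: int,
    rng: np.random.Generator,
    *,
    model: str = "hybrid",
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate many independent sessions at once (vectorized over sessions).

    Returns ``(choices, outcomes)`` arrays of shape ``(n_sessions, n_trials)``
    with choices in {1, 2}.  Same generative process as
    :func:`simulate_session`, trading latent traces for speed; used by the
    parameter sweeps where only choices matter.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}, expected one of {MODELS}")
    eta = 0.0 if model == "qlearning" else params.eta
    n_t = config.n_trials
    adv = advantage_schedule(config)

    q = np.zeros((n_sessions, 2))
    alpha = np.full(n_sessions, params.alpha0)
    choices = np.empty((n_sessions, n_t), dtype=np.int8)
    outcomes = np.empty((n_sessions, n_t), dtype=np.float64)
    rows = np.arange(n_sessions)
    for t in range(n_t):
        p1 = expit(params.beta * (q[:, 0] - q[:, 1]))
        c = np.where(rng.random(n_sessions) < p1, 1, 2).astype(np.int8)
        p_rew = np.where(c == adv[t], config.p_reward_adv, config.p_reward_dis)
        r = np.where(rng.random(n_sessions) < p_rew,
                     config.reward_value, config.loss_value)
        delta = r - q[rows, c - 1]
        q[rows, c - 1] += alpha * delta
        alpha = eta * np.abs(delta) + (1.0 - eta) * alpha
        choices[:, t] = c
        outcomes[:, t] = r
    return choices, outcomes
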