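"""Probabilistic reversal-learning environment.

A two-option bandit in which one option is *advantageous* (rewarded with
probability ``p_reward_adv``) and the other disadvantageous (rewarded with
probability ``1 - p_reward_adv``).  After ``reversal_trial`` trials the
contingencies swap, without any signal to the agent.  Outcomes are encoded
as R = 1 (reward) / R = 0 (loss); this encoding is exactly what enters the
value-update equations, any monetary framing is presentation only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "TaskConfig",
    "advantageous_option",
    "advantage_schedule",
    "draw_outcome",
    "pregenerate_outcomes",
]


@dataclass(frozen=True)
class TaskConfig:
    """Contingency schedule and trial counts for one session.

    Parameters
    ----------
    n_trials
        Total number of trials (default 160).
    reversal_trial
        Trials ``1..reversal_trial`` use the initial contingency
        (option 1 advantageous); trial ``reversal_trial + 1`` onward uses
        the reversed one.  Must satisfy ``0 < reversal_trial < n_trials``.
    p_reward_adv
        Reward probability of the currently advantageous option; the
        disadvantageous option rewards with the complementary probability.
        Difficulty levels used throughout: 0.8, 0.7 (default), 0.6,
        i.e. reward:loss ratios 80:20, 70:30, 60:40.
    reward_value, loss_value
        Outcome encoding entering the update equations, R(t) in {1, 0}.
    """

    n_trials: int = 160
    reversal_trial: int = 80
    p_reward_adv: float = 0.7
    reward_value: float = 1.0
    loss_value: float = 0.0

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise ValueError(f"n_trials must be >= 2, got {self.n_trials}")
        if not 0 < self.reversal_trial < self.n_trials:
            raise ValueError(
                "reversal_trial must satisfy 0 < reversal_trial < n_trials, "
                f"got reversal_trial={self.reversal_trial}, n_trials={self.n_trials}"
            )
        if not 0.5 < self.p_reward_adv <= 1.0:
            raise ValueError(
                f"p_reward_adv must lie in (0.5, 1], got {self.p_reward_adv}"
            )

    @property
    def p_reward_dis(self) -> float:
        """Reward probability of the disadvantageous option."""
        return 1.0 - self.p_reward_adv

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "TaskConfig":
        known = {k: d[k] for k in ("n_trials", "reversal_trial", "p_reward_adv",
                                   "reward_value", "loss_value") if k in d}
        return cls(**known)  # type: ignore[arg-type]


def _check_trial(trial: int, config: TaskConfig) -> None:
    if not 1 <= trial <= config.n_trials:
        raise ValueError(
            f"trial index must lie in 1..{config.n_trials} (1-based), got {trial}"
        )


def advantageous_option(trial: int, config: TaskConfig = TaskConfig()) -> int:
    """Return which option (1 or 2) is advantageous on a 1-based trial.

    Option 1 starts advantageous; the label flips exactly once, after
    ``config.reversal_trial`` trials.
    """
    _check_trial(trial, config)
    return 1 if trial <= config.reversal_trial else 2


def advantage_schedule(config: TaskConfig = TaskConfig()) -> np.ndarray:
    """Advantageous option for every trial, shape ``(n_trials,)``, values {1, 2}."""
    trials = np.arange(1, config.n_trials + 1)
    return np.where(trials <= config.reversal_trial, 1, 2).astype(np.int8)


def draw_outcome(
    choice: int,
    trial: int,
    config: TaskConfig,
    rng: np.random.Generator,
) -> float:
    """Sample the outcome of choosing ``choice`` on ``trial``.

    Returns ``reward_value`` with probability ``p_reward_adv`` if the choice
    equals the currently advantageous option, else with the complementary
    probability; ``loss_value`` otherwise.  Outcomes are drawn independently
    per trial, so they do not depend on earlier choices.
    """
    _check_trial(trial, config)
    if choice not in (1, 2):
        raise ValueError(f"choice must be 1 or 2, got {choice}")
    p = config.p_reward_adv if choice == advantageous_option(trial, config) \
        else config.p_reward_dis
    return config.reward_value if rng.random() < p else config.loss_value


def pregenerate_outcomes(
    config: TaskConfig, rng: np.random.Generator
) -> np.ndarray:
    """Pre-drawn outcome table, shape ``(n_trials, 2)``.

    ``table[t - 1, a - 1]`` is the outcome option ``a`` would deliver on
    trial ``t``.  Optional alternative to on-line sampling: statistically
    equivalent for every analysis here (outcomes are independent of the
    agent's choices either way) but convenient for frozen fixtures.
    """
    adv = advantage_schedule(config)
    p = np.where(adv[:, None] == np.array([1, 2]), config.p_reward_adv,
                 config.p_reward_dis)
    draws = rng.random((config.n_trials, 2))
    return np.where(draws < p, config.reward_value, config.loss_value)
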