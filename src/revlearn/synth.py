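"""Synthetic behavioral cohorts, the response-bias index, and recovery scoring.

The human-style dataset this package targets — 15 participants, one
160-trial block of a 70:30 reversal task with the switch after trial 80 —
is emulated by simulating known agents, so that every fitting and
model-comparison routine can be validated end to end: the generating
parameters ride along as ground truth and :func:`recovery_report` scores
estimates against them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .agents import MODELS, AgentParams, Session, simulate_session
from .task import TaskConfig

__all__ = [
    "HUMAN_LIKE_QLEARNING",
    "HUMAN_LIKE_HYBRID",
    "Cohort",
    "generate_cohort",
    "human_emulation_cohort",
    "response_bias",
    "recovery_report",
]

#: Representative group-level estimates for human reversal-learning
#: behavior: slow learning, mildly exploitative choice.  Used as the
#: default generating parameters of the human-emulation preset.
HUMAN_LIKE_QLEARNING = AgentParams(alpha0=0.114, beta=2.584, eta=0.0)
HUMAN_LIKE_HYBRID = AgentParams(alpha0=0.018, beta=2.601, eta=0.004)

ParamSpec = Union[
    AgentParams,
    Sequence[AgentParams],
    Mapping[str, tuple[float, float]],
    Callable[[np.random.Generator], AgentParams],
]


@dataclass
class Cohort:
    """A set of simulated participants with their generating ground truth.

    ``truth`` has one row per participant: participant_id, model, alpha0,
    beta, eta.  Serialization keeps data and ground truth side by side so a
    recovery analysis can always be rerun from files.
    """

    sessions: list[Session]
    truth: pd.DataFrame
    config: TaskConfig
    seed: int

    @property
    def n_participants(self) -> int:
        return len(self.sessions)

    def to_files(self, data_path: str | Path, truth_path: str | Path) -> None:
        from .io import write_sessions

        write_sessions(self.sessions, data_path)
        self.truth.to_csv(truth_path, index=False)

    @classmethod
    def from_files(
        cls, data_path: str | Path, truth_path: str | Path,
        config: TaskConfig, seed: int = -1,
    ) -> "Cohort":
        from .io import read_sessions

        return cls(sessions=read_sessions(data_path),
                   truth=pd.read_csv(truth_path,
                                     dtype={"participant_id": str}),
                   config=config, seed=seed)


def _draw_params(
    spec: ParamSpec, n: int, rng: np.random.Generator
) -> list[AgentParams]:
    if isinstance(spec, AgentParams):
        return [spec] * n
    if callable(spec):
        return [spec(rng) for _ in range(n)]
    if isinstance(spec, Mapping):
        unknown = set(spec) - {"alpha0", "beta", "eta"}
        if unknown:
            raise ValueError(f"unknown parameter names in distribution: {unknown}")
        out = []
        for _ in range(n):
            kw = {"alpha0": 0.0, "beta": 0.0, "eta": 0.0}
            for name, rng_pair in spec.items():
                lo, hi = rng_pair
                if not lo <= hi:
                    raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
                kw[name] = float(lo + rng.random() * (hi - lo))
            out.append(AgentParams(**kw))
        return out
    spec = list(spec)
    if len(spec) != n:
        raise ValueError(
            f"need {n} parameter sets for {n} participants, got {len(spec)}")
    return spec


def generate_cohort(
    n_participants: int = 15,
    model: str = "hybrid",
    params: ParamSpec = HUMAN_LIKE_HYBRID,
    config: TaskConfig = TaskConfig(),
    seed: int = 0,
) -> Cohort:
    """Simulate ``n_participants`` independent single-block sessions.

    ``params`` may be a single :class:`AgentParams` (shared by everyone), a
    per-participant sequence, a mapping of parameter name to a uniform
    (low, high) draw range, or a callable ``rng -> AgentParams``.  Fully
    reproducible from ``seed``; participant i uses the sub-stream
    ``(seed, i)``.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}, expected one of {MODELS}")
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    param_rng = np.random.default_rng([seed, 10_000])
    param_list = _draw_params(params, n_participants, param_rng)

    sessions, rows = [], []
    for i, p in enumerate(param_list):
        pid = f"P{i + 1:02d}"
        rng = np.random.default_rng([seed, i])
        sessions.append(simulate_session(p, config, rng, model=model,
                                         participant_id=pid))
        rows.append({"participant_id": pid, "model": model,
                     "alpha0": p.alpha0, "beta": p.beta,
                     "eta": 0.0 if model == "qlearning" else p.eta})
    return Cohort(sessions=sessions, truth=pd.DataFrame(rows),
                  config=config, seed=seed)


def human_emulation_cohort(
    seed: int = 0,
    model: str = "hybrid",
    params: Optional[ParamSpec] = None,
) -> Cohort:
    """The default human-study emulation: 15 participants, 70:30, reversal at 80."""
    if params is None:
        params = HUMAN_LIKE_HYBRID if model == "hybrid" else HUMAN_LIKE_QLEARNING
    return generate_cohort(n_participants=15, model=model, params=params,
                           config=TaskConfig(), seed=seed)


def response_bias(
    session: Session, config: TaskConfig = TaskConfig()
) -> tuple[float, float]:
    """Rate of choosing the advantageous stimulus in each task phase.

    Returns ``(pre, post)``: the fraction of pre-reversal trials choosing
    the initially advantageous option (option 1) and the fraction of
    post-reversal trials choosing the newly advantageous option (option 2).
    """
    if session.n_trials != config.n_trials:
        raise ValueError(
            f"session has {session.n_trials} trials, config expects "
            f"{config.n_trials}")
    cut = config.reversal_trial
    pre = float(np.mean(session.choices[:cut] == 1))
    post = float(np.mean(session.choices[cut:] == 2))
    return pre, post


def recovery_report(
    cohort: Cohort, individual_fits: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Score per-participant estimates against the cohort's ground truth.

    ``individual_fits`` is the tidy table from
    :func:`revlearn.fitting.group_and_individual_fits` (one row per
    participant x model).  Returns ``{"parameters": ..., "selection": ...}``:
    a per-parameter bias/RMSE table for the generating model's fits, and a
    model-selection table giving the fraction of participants for which
    AIC and BIC prefer each model (the generating model's row is the
    recovery rate).
    """
    gen_model = cohort.truth["model"].iloc[0]
    fits = individual_fits[individual_fits.model == gen_model]
    merged = fits.merge(cohort.truth, on="participant_id",
                        suffixes=("_hat", "_true"))
    if len(merged) != cohort.n_participants:
        raise ValueError("fits do not cover every cohort participant")

    names = ["alpha0", "beta"] + (["eta"] if gen_model == "hybrid" else [])
    rows = []
    for name in names:
        err = merged[f"{name}_hat"] - merged[f"{name}_true"]
        rows.append({"parameter": name,
                     "truth_mean": merged[f"{name}_true"].mean(),
                     "bias": err.mean(),
                     "rmse": float(np.sqrt(np.mean(err ** 2)))})
    param_table = pd.DataFrame(rows)

    wide = individual_fits.pivot(index="participant_id", columns="model")
    sel_rows = []
    for crit in ("aic", "bic"):
        pref_h = (wide[(crit, "hybrid")] < wide[(crit, "qlearning")]).mean()
        sel_rows.append({"criterion": crit,
                         "frac_prefer_hybrid": float(pref_h),
                         "frac_prefer_qlearning": float(1.0 - pref_h),
                         "generating_model": gen_model,
                         "recovery_rate": float(pref_h if gen_model == "hybrid"
                                                else 1.0 - pref_h)})
    return {"parameters": param_table, "selection": pd.DataFrame(sel_rows)}
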