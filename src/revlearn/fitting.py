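"""Maximum-likelihood fitting and model comparison.

The likelihood of a parameter set is obtained by replaying the value and
learning-rate recursions forward over the *observed* choices and outcomes
(Q initialized at zero, alpha(1) = alpha0) and accumulating the log softmax
probability of each observed choice,

    L = sum_t ln P(a(t)).

Models are compared by AIC = -2L + 2k, BIC = -2L + k ln N (N = total trials
entering the likelihood), and — since Q-learning is the eta = 0 special
case of the hybrid model — by a nested likelihood-ratio test with statistic
2 (L_hybrid - L_qlearning).  Because the null pins eta to the boundary of
its admissible range, the chi-square(1) reference is conservative; a
boundary-corrected 0.5 chi2_0 + 0.5 chi2_1 mixture is available as an
option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._kernels import nll_sessions
from .agents import MODELS, AgentParams, Session

__all__ = [
    "DEFAULT_BOUNDS",
    "FitResult",
    "LRTResult",
    "FitTables",
    "negative_log_likelihood",
    "information_criteria",
    "fit_model",
    "fit_both",
    "likelihood_ratio_test",
    "group_and_individual_fits",
]

#: Default box bounds for the optimizer.  beta's upper bound mirrors the
#: simulation grid and is configurable upward: individual fits of human
#: data can land well above 20.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha0": (0.0, 1.0),
    "beta": (0.0, 50.0),
    "eta": (0.0, 1.0),
}

_N_PARAMS = {"qlearning": 2, "hybrid": 3}


@dataclass
class FitResult:
    """Maximum-likelihood fit of one model to one dataset."""

    model: str
    params: AgentParams
    log_likelihood: float
    aic: float
    bic: float
    n_params: int
    n_obs: int
    converged: bool
    n_restarts: int
    restart_nlls: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))


@dataclass
class LRTResult:
    """Nested likelihood-ratio test of hybrid (alternative) vs Q-learning (null)."""

    statistic: float
    df: int
    p_value: float
    raw_statistic: float  # unclipped 2*(L_alt - L_null); negative on optimizer failure
    boundary_corrected: bool = False


def _as_sessions(sessions: Session | Sequence[Session]) -> list[Session]:
    if isinstance(sessions, Session):
        return [sessions]
    out = list(sessions)
    if not out:
        raise ValueError("at least one session is required")
    return out


def _stack(sessions: list[Session]):
    choices0 = np.concatenate([s.choices for s in sessions]).astype(np.int64) - 1
    outcomes = np.concatenate([s.outcomes for s in sessions]).astype(np.float64)
    lengths = np.array([s.n_trials for s in sessions], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    return choices0, outcomes, offsets


def negative_log_likelihood(
    params: AgentParams,
    sessions: Session | Sequence[Session],
    model: str = "hybrid",
) -> float:
    """-L for one or more sessions (log-likelihoods sum; state resets per session)."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}, expected one of {MODELS}")
    eta = 0.0 if model == "qlearning" else params.eta
    choices0, outcomes, offsets = _stack(_as_sessions(sessions))
    return float(nll_sessions(choices0, outcomes, offsets,
                              params.alpha0, params.beta, eta))


def information_criteria(L: float, k: int, N: int) -> tuple[float, float]:
    """(AIC, BIC) from a maximized log-likelihood L with k parameters, N points.

    AIC = -2L + 2k; BIC = -2L + k ln N (natural log).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if N < 1:
        raise ValueError("N must be >= 1")
    return -2.0 * L + 2.0 * k, -2.0 * L + k * np.log(N)


def fit_model(
    sessions: Session | Sequence[Session],
    model: str = "hybrid",
    bounds: Optional[dict[str, tuple[float, float]]] = None,
    n_restarts: int = 10,
    seed: Optional[int] = None,
    extra_starts: Sequence[Sequence[float]] = (),
) -> FitResult:
    """Fit one model by bounded MLE with random multistart.

    ``n_restarts`` initial points are drawn uniformly within the bounds
    (plus any ``extra_starts``, e.g. a nested model's solution); each is
    refined by L-BFGS-B and the best optimum is returned.  AIC/BIC use
    N = total trials across sessions.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}, expected one of {MODELS}")
    sess = _as_sessions(sessions)
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    names = ["alpha0", "beta"] + (["eta"] if model == "hybrid" else [])
    box = [b[n] for n in names]
    choices0, outcomes, offsets = _stack(sess)
    eta_fixed = 0.0

    def objective(x: np.ndarray) -> float:
        eta = x[2] if model == "hybrid" else eta_fixed
        return float(nll_sessions(choices0, outcomes, offsets,
                                  float(x[0]), float(x[1]), eta))

    rng = np.random.default_rng(seed)
    lo = np.array([lo_ for lo_, _ in box])
    hi = np.array([hi_ for _, hi_ in box])
    # Interior anchor points guard against stalls on the alpha0 = 0 plateau,
    # where the likelihood is flat in beta and quasi-Newton steps can die.
    anchors = [np.array([a, bt, 0.05][:len(box)], dtype=float)
               for a in (0.1, 0.4) for bt in (2.0, 8.0)]
    starts = [np.clip(x0, lo, hi) for x0 in anchors]
    starts += [lo + rng.random(len(box)) * (hi - lo) for _ in range(n_restarts)]
    starts += [np.clip(np.asarray(s, dtype=float), lo, hi) for s in extra_starts]
    if not starts:
        raise ValueError("n_restarts must be >= 1 (or provide extra_starts)")

    best = None
    restart_nlls = []
    any_converged = False
    for x0 in starts:
        res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=box)
        restart_nlls.append(res.fun)
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if not any_converged:
        warnings.warn("no optimizer restart reported convergence; "
                      "returning best point found", RuntimeWarning)

    x = best.x
    params = AgentParams(
        alpha0=float(np.clip(x[0], 0.0, 1.0)),
        beta=float(max(x[1], 0.0)),
        eta=float(np.clip(x[2], 0.0, 1.0)) if model == "hybrid" else 0.0,
    )
    L = -float(best.fun)
    N = int(offsets[-1])
    k = _N_PARAMS[model]
    aic, bic = information_criteria(L, k, N)
    return FitResult(
        model=model, params=params, log_likelihood=L, aic=aic, bic=bic,
        n_params=k, n_obs=N, converged=any_converged,
        n_restarts=len(starts), restart_nlls=np.array(restart_nlls),
    )


def fit_both(
    sessions: Session | Sequence[Session],
    bounds: Optional[dict[str, tuple[float, float]]] = None,
    n_restarts: int = 10,
    seed: Optional[int] = None,
) -> dict[str, FitResult]:
    """Fit Q-learning then hybrid, seeding the hybrid search at the nested optimum.

    Starting one hybrid restart from (alpha0_q, beta_q, eta=0) guarantees
    max-L(hybrid) >= max-L(qlearning) up to optimizer tolerance, which keeps
    the likelihood-ratio statistic non-negative.
    """
    fq = fit_model(sessions, "qlearning", bounds=bounds,
                   n_restarts=n_restarts, seed=seed)
    fh = fit_model(sessions, "hybrid", bounds=bounds,
                   n_restarts=n_restarts, seed=None if seed is None else seed + 1,
                   extra_starts=[[fq.params.alpha0, fq.params.beta, 0.0]])
    return {"qlearning": fq, "hybrid": fh}


def likelihood_ratio_test(
    fit_null: FitResult,
    fit_alt: FitResult,
    boundary_correction: bool = False,
) -> LRTResult:
    """Nested LRT: statistic 2 (L_alt - L_null), df = k_alt - k_null.

    The p-value uses chi-square(df); with ``boundary_correction`` (df = 1
    only) the 0.5 chi2_0 + 0.5 chi2_1 mixture appropriate when the tested
    parameter sits on its boundary under the null.  A negative statistic
    (possible when optimization of the alternative failed) is clipped to 0
    for the p-value and preserved in ``raw_statistic``.
    """
    if fit_alt.n_params <= fit_null.n_params:
        raise ValueError("alternative model must have more parameters than the null")
    if fit_alt.n_obs != fit_null.n_obs:
        raise ValueError("fits compare different datasets (n_obs differ)")
    raw = 2.0 * (fit_alt.log_likelihood - fit_null.log_likelihood)
    stat = raw
    if raw < 0:
        warnings.warn(
            f"negative LRT statistic ({raw:.3g}): the alternative fit did not "
            "reach the null's likelihood; clipping to 0", RuntimeWarning)
        stat = 0.0
    df = fit_alt.n_params - fit_null.n_params
    if boundary_correction:
        if df != 1:
            raise ValueError("boundary correction implemented for df = 1 only")
        p = 1.0 if stat == 0.0 else 0.5 * stats.chi2.sf(stat, 1)
    else:
        p = float(stats.chi2.sf(stat, df))
    return LRTResult(statistic=stat, df=df, p_value=float(p),
                     raw_statistic=raw, boundary_corrected=boundary_correction)


@dataclass
class FitTables:
    """Group and per-participant fit tables plus the individual summary."""

    group: dict[str, FitResult]
    group_lrt: LRTResult
    individual: pd.DataFrame
    individual_summary: pd.DataFrame


def _fit_row(fit: FitResult, participant: str) -> dict:
    return {
        "participant_id": participant,
        "model": fit.model,
        "log_likelihood": fit.log_likelihood,
        "aic": fit.aic,
        "bic": fit.bic,
        "alpha0": fit.params.alpha0,
        "beta": fit.params.beta,
        "eta": fit.params.eta if fit.model == "hybrid" else np.nan,
        "n_obs": fit.n_obs,
        "converged": fit.converged,
    }


def group_and_individual_fits(
    sessions: Sequence[Session],
    expected_trials: Optional[int] = 160,
    bounds: Optional[dict[str, tuple[float, float]]] = None,
    n_restarts: int = 10,
    seed: Optional[int] = None,
) -> FitTables:
    """Fit both models in group (pooled) and individual mode.

    Group mode estimates a single parameter set from the pooled likelihood
    of all sessions (N = participants x trials); individual mode fits each
    participant separately and summarizes the estimates as mean +/- SD,
    with per-participant LRT p-values and AIC/BIC differences.
    """
    sess = _as_sessions(sessions)
    if expected_trials is not None:
        bad = [(s.participant_id, s.n_trials) for s in sess
               if s.n_trials != expected_trials]
        if bad:
            raise ValueError(
                f"{len(bad)} session(s) with missing trials "
                f"(expected {expected_trials}): {bad}")

    group = fit_both(sess, bounds=bounds, n_restarts=n_restarts, seed=seed)
    group_lrt = likelihood_ratio_test(group["qlearning"], group["hybrid"])

    rows = []
    for i, s in enumerate(sess):
        sub_seed = None if seed is None else seed + 101 * (i + 1)
        fits = fit_both(s, bounds=bounds, n_restarts=n_restarts, seed=sub_seed)
        lrt = likelihood_ratio_test(fits["qlearning"], fits["hybrid"])
        for m in MODELS:
            row = _fit_row(fits[m], s.participant_id)
            row["lrt_p"] = lrt.p_value if m == "hybrid" else np.nan
            rows.append(row)
    individual = pd.DataFrame(rows)
    summary = (individual
               .groupby("model")[["log_likelihood", "aic", "bic",
                                  "alpha0", "beta", "eta"]]
               .agg(["mean", "std"]))
    return FitTables(group=group, group_lrt=group_lrt,
                     individual=individual, individual_summary=summary)
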