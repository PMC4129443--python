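"""Functional-significance study: performance grids over (alpha0, beta, eta).

The central question: when does a plastic learning rate (eta > 0) help?
We sweep the agent parameters, score each cell by the proportion of
advantageous choices over the whole session, and compare hybrid slices
(eta > 0) against the Q-learning slice (eta = 0) — per-cell differences and,
across the grid, the fraction of cells beating the Q-learning median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agents import AgentParams, Session, simulate_batch
from .task import TaskConfig, advantage_schedule

__all__ = [
    "SweepGrid",
    "SweepResult",
    "REGIONS",
    "advantageous_proportion",
    "run_sweep",
    "median_exceedance_fraction",
    "exemplar_traces",
    "plot_sweep_heatmap",
]

#: Exemplar (alpha0, beta) cells: (i) slow/exploitative mistuning,
#: (ii) well-tuned, (iii) fast/exploitative mistuning.
REGIONS: dict[str, tuple[float, float]] = {
    "i": (0.15, 45.0),
    "ii": (0.65, 25.0),
    "iii": (0.95, 45.0),
}


def _full_eta_axis() -> tuple[float, ...]:
    fine = np.round(np.arange(0.0, 0.1 + 1e-9, 0.01), 2)
    coarse = np.round(np.arange(0.1, 1.0 + 1e-9, 0.1), 1)
    return tuple(np.unique(np.concatenate([fine, coarse])))


@dataclass(frozen=True)
class SweepGrid:
    """Axes and repetition count of a parameter sweep.

    The full-scale default matches the study design: alpha0 from 0 to 1 in
    steps of 0.05, beta from 0 to 50 in steps of 1, eta from 0 to 0.1 in
    steps of 0.01 then 0.1 to 1 in steps of 0.1 (deduplicated), 1000
    repetitions per cell.  :meth:`reduced` gives an 11 x 11 profile suited
    to test-scale runs; the full grid is a long-running mode.
    """

    alpha0_values: tuple[float, ...] = tuple(np.round(np.arange(0, 1.0001, 0.05), 2))
    beta_values: tuple[float, ...] = tuple(float(b) for b in range(0, 51))
    eta_values: tuple[float, ...] = field(default_factory=_full_eta_axis)
    n_reps: int = 1000
    difficulty: float = 0.7

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    @classmethod
    def reduced(
        cls,
        eta_values: tuple[float, ...] = (0.0, 0.3),
        n_reps: int = 200,
        difficulty: float = 0.7,
    ) -> "SweepGrid":
        """11 x 11 (alpha0, beta) grid for quick qualitative runs."""
        return cls(
            alpha0_values=tuple(np.round(np.linspace(0, 1, 11), 2)),
            beta_values=tuple(np.round(np.linspace(0, 50, 11), 1)),
            eta_values=tuple(eta_values),
            n_reps=n_reps,
            difficulty=difficulty,
        )


@dataclass
class SweepResult:
    """Tidy per-cell results of :func:`run_sweep`.

    ``table`` columns: alpha0, beta, eta, difficulty, prop_advantageous,
    mc_se (Monte-Carlo standard error of the cell mean), n_reps.
    """

    table: pd.DataFrame
    grid: SweepGrid
    config: TaskConfig
    seed: int

    def cell(self, alpha0: float, beta: float, eta: float) -> pd.Series:
        t = self.table
        m = (np.isclose(t.alpha0, alpha0) & np.isclose(t.beta, beta)
             & np.isclose(t.eta, eta))
        if m.sum() != 1:
            raise KeyError(f"no unique cell ({alpha0}, {beta}, {eta})")
        return t[m].iloc[0]

    def eta_slice(self, eta: float) -> pd.DataFrame:
        m = np.isclose(self.table.eta, eta)
        if not m.any():
            raise KeyError(f"eta level {eta} not in sweep")
        return self.table[m].reset_index(drop=True)


def advantageous_proportion(session: Session, config: TaskConfig) -> float:
    """Fraction of trials choosing the currently advantageous option.

    Scored against the contingency in force on each trial, i.e. over both
    task phases combined.
    """
    if session.n_trials != config.n_trials:
        raise ValueError(
            f"session has {session.n_trials} trials, config expects {config.n_trials}"
        )
    adv = advantage_schedule(config)
    return float(np.mean(session.choices == adv))


def _cell_proportions(
    alpha0: float, beta: float, eta: float,
    config: TaskConfig, n_reps: int, rng: np.random.Generator,
) -> np.ndarray:
    params = AgentParams(alpha0=alpha0, beta=beta, eta=eta)
    choices, _ = simulate_batch(params, config, n_reps, rng)
    adv = advantage_schedule(config)
    return (choices == adv[None, :]).mean(axis=1)


def run_sweep(
    grid: SweepGrid,
    config: TaskConfig | None = None,
    seed: int = 0,
) -> SweepResult:
    """Average advantageous-choice proportion for every (alpha0, beta, eta) cell.

    Each cell runs ``grid.n_reps`` independent sessions.  Per-cell RNG
    streams are derived from ``(seed, alpha0 index, beta index, eta index)``,
    so any cell is reproducible in isolation and a sweep is deterministic
    given the master seed.  ``grid.difficulty`` overrides the config's
    reward probability.
    """
    if config is None:
        config = TaskConfig()
    config = TaskConfig(
        n_trials=config.n_trials,
        reversal_trial=config.reversal_trial,
        p_reward_adv=grid.difficulty,
        reward_value=config.reward_value,
        loss_value=config.loss_value,
    )
    rows = []
    for ei, eta in enumerate(grid.eta_values):
        for ai, alpha0 in enumerate(grid.alpha0_values):
            for bi, beta in enumerate(grid.beta_values):
                rng = np.random.default_rng([seed, ai, bi, ei])
                props = _cell_proportions(alpha0, beta, eta, config,
                                          grid.n_reps, rng)
                rows.append((alpha0, beta, eta, grid.difficulty,
                             props.mean(),
                             props.std(ddof=1) / np.sqrt(grid.n_reps)
                             if grid.n_reps > 1 else np.nan,
                             grid.n_reps))
    table = pd.DataFrame(rows, columns=[
        "alpha0", "beta", "eta", "difficulty",
        "prop_advantageous", "mc_se", "n_reps"])
    return SweepResult(table=table, grid=grid, config=config, seed=seed)


def median_exceedance_fraction(
    sweep_hybrid: pd.DataFrame, sweep_q: pd.DataFrame
) -> float:
    """Fraction of hybrid cells strictly above the Q-learning median.

    The median is taken across all (alpha0, beta) cells of the eta = 0
    slice; the returned fraction counts the hybrid slice's cells strictly
    exceeding it.  Both slices must cover the same (alpha0, beta) grid at
    the same difficulty.
    """
    for df in (sweep_hybrid, sweep_q):
        if not {"alpha0", "beta", "prop_advantageous"} <= set(df.columns):
            raise ValueError("expected tidy sweep slices with alpha0/beta/"
                             "prop_advantageous columns")
    key_h = sweep_hybrid.sort_values(["alpha0", "beta"])[["alpha0", "beta"]]
    key_q = sweep_q.sort_values(["alpha0", "beta"])[["alpha0", "beta"]]
    if key_h.shape != key_q.shape or not np.allclose(key_h.values, key_q.values):
        raise ValueError("hybrid and Q-learning slices cover different grids")
    if ("difficulty" in sweep_hybrid and "difficulty" in sweep_q and
            not np.isclose(sweep_hybrid.difficulty.iloc[0],
                           sweep_q.difficulty.iloc[0])):
        raise ValueError("hybrid and Q-learning slices differ in difficulty")
    med = float(np.median(sweep_q.prop_advantageous))
    return float(np.mean(sweep_hybrid.prop_advantageous > med))


def exemplar_traces(
    eta: float,
    config: TaskConfig | None = None,
    seed: int = 0,
    regions: dict[str, tuple[float, float]] | None = None,
    n_runs: int = 1,
) -> pd.DataFrame:
    """Per-trial P(choose option 1) and alpha(t) traces at the exemplar cells.

    For each named region, ``n_runs`` independent sessions are simulated and
    the traces averaged (``n_runs=1`` gives a single typical run).  Tidy
    output columns: region, trial, p_option1, alpha, eta.
    """
    from .agents import simulate_session

    if config is None:
        config = TaskConfig()
    if regions is None:
        regions = REGIONS
    frames = []
    for ri, (name, (alpha0, beta)) in enumerate(sorted(regions.items())):
        params = AgentParams(alpha0=alpha0, beta=beta, eta=eta)
        p1 = np.zeros(config.n_trials)
        al = np.zeros(config.n_trials)
        for r in range(n_runs):
            rng = np.random.default_rng([seed, ri, r])
            s = simulate_session(params, config, rng)
            p1 += s.p_option1
            al += s.alpha
        frames.append(pd.DataFrame({
            "region": name,
            "trial": np.arange(1, config.n_trials + 1),
            "p_option1": p1 / n_runs,
            "alpha": al / n_runs,
            "eta": eta,
        }))
    return pd.concat(frames, ignore_index=True)


def plot_sweep_heatmap(result: SweepResult, eta: float, ax=None):
    """Heat map of advantageous-choice proportion over (beta, alpha0) at one eta."""
    import matplotlib.pyplot as plt

    df = result.eta_slice(eta)
    pivot = df.pivot(index="alpha0", columns="beta", values="prop_advantageous")
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(pivot.values, origin="lower", aspect="auto",
                   extent=[min(pivot.columns), max(pivot.columns),
                           min(pivot.index), max(pivot.index)],
                   vmin=0.4, vmax=1.0, cmap="viridis")
    ax.set_xlabel(r"$\beta$ (inverse temperature)")
    ax.set_ylabel(r"$\alpha_0$ (initial learning rate)")
    ax.set_title(rf"$\eta$ = {eta:g}, difficulty {result.grid.difficulty:g}")
    ax.figure.colorbar(im, ax=ax, label="prop. advantageous")
    return ax
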