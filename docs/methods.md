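# Methods

## Task model

The environment is a two-option probabilistic reversal-learning task.
A session has `n_trials = 160` trials; option 1 is advantageous for
trials 1–80 (reward probability `p_reward_adv`, default 0.7), and the
contingency reverses from trial 81 onward. The disadvantageous option
always rewards with the complementary probability, so the reward:loss
ratios are 80:20, 70:30 or 60:40 at the three supported difficulty
levels. Outcomes enter the learning equations as R ∈ {1, 0}; any
monetary framing of reward and loss is presentation only.

Outcomes are drawn *online*: an independent Bernoulli draw on the chosen
option at choice time. Because outcome draws never depend on the
agent's history, this is statistically equivalent to pre-generating a
reward schedule per option; a pre-generated mode
(`task.pregenerate_outcomes`) exists for frozen fixtures and for studies
that want identical outcome tables across agents. Trial indices are
1-based in every interface.

## Agents

Both agents maintain a value per option, start at Q = (0, 0), and choose
option 1 with probability `1 / (1 + exp(−β (Q₁ − Q₂)))` (computed with
the sign-split logistic, so extreme β·ΔQ saturates to 0/1 instead of
overflowing). Per trial, in order: compute the choice probability,
sample the choice, draw the outcome, update the chosen option's value by
`α(t) · (R(t) − Q)`, and finally update the learning rate
`α(t+1) = η |δ(t)| + (1 − η) α(t)`. The rate in effect on trial t
therefore depends only on errors from earlier trials. The unchosen
value never changes. With Q initialized at 0 and R ∈ {0, 1}, both Q and
α(t) remain in [0, 1] by induction (the update is a convex combination);
a property-based test simulates this at scale.

Initialization at Q = (0, 0) is used for simulation as well as fitting,
keeping the generative model and the likelihood replay identical.
`model="qlearning"` forces η = 0; a regression test asserts that a
Q-learning run and an η = 0 hybrid run with the same seed are
bit-identical, which pins the nesting relation the likelihood-ratio test
relies on.

Ties (Q₁ = Q₂) need no special handling: the softmax returns 0.5 and the
choice is sampled.

## Parameter sweep (functional significance)

`sweep.run_sweep` scores every (α₀, β, η) cell by the proportion of
advantageous choices over the whole 160-trial session (both phases;
no windowing) averaged over `n_reps` independent sessions. The
full-scale grid is α₀ ∈ {0, 0.05, …, 1}, β ∈ {0, 1, …, 50},
η ∈ {0, 0.01, …, 0.1, 0.2, …, 1} (20 deduplicated levels) at 1000
repetitions per cell — the study design, exposed as a long-running mode
(~3 × 10⁹ agent-trials). Day-to-day runs use `SweepGrid.reduced()`:
11 × 11 (α₀, β) cells at 100–200 repetitions. Grid endpoints β = 0 and
α₀ = 0 are included; both are degenerate but well defined (random
choice; no learning — though an η > 0 agent escapes α₀ = 0 after its
first nonzero prediction error).

Per-cell RNG streams derive from `(master seed, α₀ index, β index,
η index)`, so single cells are reproducible in isolation and whole
sweeps are deterministic given the master seed. Cell means carry their
Monte-Carlo standard error (sample SD / √n_reps).

The difficulty analysis summarizes a sweep by the fraction of hybrid
cells whose performance strictly exceeds the *median of the η = 0 slice*
across all (α₀, β) cells (`median_exceedance_fraction`). The median is
always taken on the η = 0 slice, per-difficulty; no pooled-across-η
variant is computed. One caveat found during validation: on the coarse
11 × 11 grid this fraction saturates near 110/121 at every difficulty
(the quantization exceeds the difficulty effect), so ordering claims
across difficulties are evaluated on the full 21 × 51 grid, where they
are stable across seeds at 100 repetitions per cell.

Exemplar cells used throughout: region (i) α₀ = 0.15, β = 45 (slow,
exploitative — mistuned), region (ii) α₀ = 0.65, β = 25 (well tuned),
region (iii) α₀ = 0.95, β = 45 (fast, exploitative — mistuned). At
70:30 and 20,000 repetitions per cell this implementation gives
advantageous-choice proportions of ≈0.51/0.80 (region i, η = 0 vs 0.3),
≈0.86/0.85 (region ii) and ≈0.797/0.803 (region iii). The region-iii
benefit of plasticity at η = 0.3 is real but small (+0.006, ≈5 SE at
that repetition count; it grows to +0.058 at η = 0.7 and turns negative
at η = 1); tests of that cell therefore run at 20,000 repetitions, the
smallest round count that resolves the effect beyond 3 Monte-Carlo SE.
At the well-tuned cell η = 1 costs ≈0.09 — plasticity overdone makes
choice effectively random.

## Likelihood and fitting

The log-likelihood of a parameter set replays the recursion forward over
the *observed* choices and outcomes (Q = 0 start, α(1) = α₀) and sums
`ln P(observed choice)` per trial; multiple sessions sum with state
reset. Per-trial probabilities are clipped to [1e−12, 1 − 1e−12]
inside the log — this prevents −∞ at extreme β and leaves optima
essentially untouched, but it does make the likelihood exactly flat in β
once every trial's probability saturates (β ≳ 28 on deterministic data),
so "β as large as possible" fits legitimately terminate anywhere on that
plateau. The inner loop is JIT-compiled (numba); its correctness is
pinned to a deliberately naive straight-line Python replay to 1e−10.

Optimization is bounded L-BFGS-B on −L with a multistart: four fixed
interior anchor points (α₀ ∈ {0.1, 0.4} × β ∈ {2, 8}, η = 0.05) plus
`n_restarts` uniform random draws within bounds (default 10), keeping
the best optimum. The anchors matter: the likelihood has a plateau at
α₀ = 0 (β unidentifiable there), and purely random multistarts
occasionally stall on it, which silently corrupts downstream
likelihood-ratio statistics. Default bounds are α₀, η ∈ [0, 1],
β ∈ [0, 50]; the β ceiling mirrors the simulation grid and is
configurable upward, since individual human fits can exceed it.

`fit_both` fits Q-learning first and seeds one hybrid restart at
(α̂₀, β̂, η = 0), enforcing max-L(hybrid) ≥ max-L(qlearning) up to
optimizer tolerance.

Model comparison: AIC = −2L + 2k, BIC = −2L + k ln N with natural logs
and N = total trials entering the likelihood (group mode:
participants × trials, e.g. 15 × 160 = 2400). The nested LRT uses
statistic 2(L_hybrid − L_qlearning) against χ²(1) by default. Because
η = 0 lies on the boundary of its range, the χ²(1) reference is
conservative (simulated type-I error ≈ 0.02–0.03 at nominal 0.05, group
scale); the boundary-corrected 0.5 χ²₀ + 0.5 χ²₁ mixture is available
via `boundary_correction=True`. Negative statistics (possible when the
alternative's optimizer fails) warn, are clipped to 0 for the p-value,
and keep the raw value for diagnostics.

Group mode pools all sessions into one likelihood; individual mode fits
each participant separately and reports estimates as mean ± SD plus
per-participant LRT p-values and AIC/BIC differences.

## Synthetic cohorts and recovery

`human_emulation_cohort` generates the default validation dataset:
15 participants × one 160-trial block at 70:30 with reversal after 80 —
the structure of the behavioral study this pipeline targets, whose raw
data are not public. Default generating parameters are the group-level
estimates typical of human reversal learning (hybrid α₀ = 0.018,
β = 2.601, η = 0.004; Q-learning α = 0.114, β = 2.584). With the hybrid
defaults the simulated response biases (fraction of advantageous choices
before/after reversal) come out near 67%/65%, close to the ~70%/61%
reported for humans on this task — a qualitative sanity check, not a
fitting target. Only single-block cohorts are generated; multi-block
designs with fresh stimuli per block (and any carry-over of task-set
learning across blocks) are not modeled.

Per-participant parameters can be fixed, listed, drawn uniformly from
ranges, or produced by a callable. Ground truth is always retained and
serialized next to the data, and `recovery_report` scores fits against
it (per-parameter bias and RMSE, plus the fraction of participants for
which AIC/BIC select the generating model).

What the generator does *not* emulate about real data: reaction times,
left/right stimulus position, lapses and attention drifts, inter-trial
dependencies beyond the model, and individual differences unless a
parameter distribution is requested. Recovery results on these cohorts
therefore certify the estimator under correct model specification, not
robustness to the many ways human data violate it.

Monte-Carlo study sizes (chosen to give stable verdicts at interactive
runtimes): parameter recovery uses 20 replicate cohorts of 15 × 160
trials from Q-learning (α = 0.3, β = 5) — mid-range, behaviorally
plausible values — with median recovery within ±0.05 (α) and ±1.0 (β);
model recovery uses 50 replicates per generator (hybrid η = 0.3 vs
Q-learning, same α/β); LRT calibration uses 500 null replicates at
group scale. The acceptance script mirrors these at slightly reduced
counts (10 recovery replicates, 200 null replicates) to stay fast.

## Numerical choices, degenerate inputs, limitations

- All randomness flows through `numpy.random.Generator`; every entry
  point takes an explicit seed, and derived sub-streams use structured
  seed sequences, so artifacts are reproducible byte-for-byte.
- β = 0 is valid everywhere (uniform choice; −L = T ln 2 exactly).
  p_reward_adv = 1 is a valid degenerate task.
- Session files are plain CSV with validation that names the offending
  row; domain violations, trial-numbering gaps and duplicate trials are
  distinct error classes.
- η is weakly identified from a single 160-trial session, especially
  when small; per-participant η estimates are noisy and recovery is
  asserted only at group scale. This mirrors the general experience
  that associability parameters need pooled data.
- The sweep's full-scale grid is expensive by design; nothing caches
  intermediate results. Use the reduced profile unless reproducing the
  full maps.
- Fitted β̂ values at the [0, 50] bound indicate likelihood saturation
  (near-deterministic data), not a converged interior estimate; the
  plateau above β ≈ 28 under probability flooring makes the exact
  location within the plateau arbitrary.
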