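# revlearn

Dual-process reinforcement learning in probabilistic reversal tasks:
simulation, parameter sweeps, and trial-by-trial maximum-likelihood model
fitting.

## The problem

In a probabilistic reversal-learning task a decision maker repeatedly
chooses between two options. One option is *advantageous* — it pays a
reward (R = 1) with probability 0.7 and a loss (R = 0) with probability
0.3 — the other is its mirror image. After 80 of 160 trials the
contingencies silently swap. Doing well requires two conflicting skills:
discriminating the better option quickly, yet sticking with it through
occasional losses.

`revlearn` implements and compares two generative accounts of this
behavior:

* **Standard Q-learning** (Rescorla–Wagner value update, constant
  learning rate):

  ```
  Q_a(t+1) = Q_a(t) + α (R(t) − Q_a(t))        (chosen option only)
  ```

* **Hybrid model** (Rescorla–Wagner value update plus Pearce–Hall
  associability): the learning rate itself tracks recent surprise,

  ```
  Q_a(t+1) = Q_a(t) + α(t) (R(t) − Q_a(t))
  α(t+1)   = η |R(t) − Q_a(t)| + (1 − η) α(t),     α(1) = α₀
  ```

  so large prediction errors speed up subsequent learning. η = 0
  recovers standard Q-learning exactly.

Both models choose by a softmax on the value difference,
`P(a=1) = 1 / (1 + exp(−β (Q₁ − Q₂)))`, with inverse temperature β.

The package answers two questions. *Functional significance*: sweeping
(α₀, β, η) over the task shows that learning-rate plasticity makes
behavior robust to parameter mistuning — a hybrid agent rescues cells
where constant-rate Q-learning fails, and the advantage grows with task
difficulty (60:40 contingencies vs 80:20). *Explanatory power*: fitting
both models to choice data by maximum likelihood, with AIC/BIC and a
nested likelihood-ratio test (statistic `2(L_hybrid − L_qlearning)` vs
χ²(1)), asks whether the extra plasticity parameter is warranted by
behavior. The package is aimed at computational-cognitive-modeling
researchers who need a validated, seedable reference pipeline for these
analyses — including synthetic cohorts with ground truth for parameter
and model recovery studies.

## Worked example

Simulate a synthetic 15-participant cohort (160 trials each, 70:30
contingency, reversal at trial 80) from the hybrid model at
human-plausible parameters, then fit both models to its choices:

```python
import numpy as np
import revlearn as rl

cohort = rl.human_emulation_cohort(seed=7)
biases = np.array([rl.response_bias(s, cohort.config) for s in cohort.sessions])
print(f"response bias pre/post reversal: "
      f"{biases[:,0].mean():.2f} / {biases[:,1].mean():.2f}")

fits = rl.fit_both(cohort.sessions, n_restarts=10, seed=1)
for name, f in fits.items():
    p = f.params
    print(f"{name:9s}  L = {f.log_likelihood:8.1f}  AIC = {f.aic:7.1f}  "
          f"BIC = {f.bic:7.1f}  alpha0 = {p.alpha0:.3f}  beta = {p.beta:.2f}"
          + (f"  eta = {p.eta:.3f}" if name == "hybrid" else ""))
lrt = rl.likelihood_ratio_test(fits["qlearning"], fits["hybrid"])
print(f"LRT: chi2({lrt.df}) = {lrt.statistic:.2f}, p = {lrt.p_value:.3f}")
```

prints

```
response bias pre/post reversal: 0.70 / 0.64
qlearning  L =  -1418.8  AIC =  2841.5  BIC =  2853.1  alpha0 = 0.107  beta = 2.46
hybrid     L =  -1401.5  AIC =  2809.0  BIC =  2826.3  alpha0 = 0.024  beta = 2.57  eta = 0.003
LRT: chi2(1) = 34.56, p = 0.000
```

The cohort chooses the advantageous stimulus ~70% of the time before the
reversal and ~64% after it. The group fit (one parameter set pooled over
all 15 × 160 trials) recovers parameters close to the generating values
(α₀ = 0.018, β = 2.601, η = 0.004), and all three comparisons — lower
AIC, lower BIC, significant likelihood ratio — correctly prefer the
hybrid generator over the constant-rate null.

The same operations are available from the shell:

```bash
revlearn simulate --model hybrid --alpha0 0.65 --beta 25 --eta 0.3 --seed 1 --out s.csv
revlearn fit s.csv --model both --mode group
revlearn sweep --difficulty 0.7 --eta 0,0.3 --reps 200 --seed 1 --out sweep.csv
revlearn recover --preset human-emulation --seed 7 --out-dir recovery/
```

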