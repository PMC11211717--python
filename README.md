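# wmdrift

Working-memory behavior in a visuospatial delayed match-to-sample task,
modeled as a diffusing point estimate read out through a decision
threshold — with the full estimation pipeline around it: task simulation,
cross-entropy model fitting, BIC model comparison, parameter recovery,
signal-detection summaries, an optimal-threshold analysis, composite
neuropsychological scores, and temporal-generalization decoding metrics.
Everything runs on synthetic data with recorded ground truth, so the
machinery that separates *memory stability* from *response strategy* can be
validated end to end.

## Who this is for

Researchers in computational psychophysics and cognitive aging who want a
tested, seedable reference implementation of the DMS modeling pipeline:
simulate cohorts, check what is and is not recoverable at realistic trial
counts, and reuse the metrics on their own data tables.

## The model

A sample location held in memory diffuses during the delay T, so the
across-trial SD of the trace is σ_T = σ_mem·√T. At test, the decision
variable x = |memory − test| follows a folded normal centred on the true
sample-test distance Δ. A logistic decision function with inflection δ
(the decision threshold), slope σ_dec and lapse asymptotes θ maps x onto
p("different"); a hazard λ lets the trace vanish entirely (guessing). The
choice probability is

p(different | T, Δ) = θ_mem,T · ½ + (1 − θ_mem,T) · Σ_x DF(x) · pdf(x | Δ, σ_T),
  with θ_mem,T = 1 − e^(−λT).

Six nested variants (all free σ_mem and δ; plus θ, λ, σ_dec in
combinations) are fit by minimizing the cross-entropy of binary responses
with a seedable particle swarm, and compared by BIC = 2·CE + k·ln n.
See `docs/methods.md` for the full account.

## Worked example

```python
from wmdrift.task import generate_trials
from wmdrift.model import ModelParams, simulate_responses
from wmdrift.fitting import fit_variant
from wmdrift.pso import PSOConfig

truth = ModelParams(sigma_mem=4.2856, delta_thresh=11.137, theta=0.0203)
trials = generate_trials(3, rng_seed=1)            # 3 blocks = 189 trials
responses = simulate_responses(truth, trials, rng_seed=2)

fit = fit_variant(responses, variant=2,
                  optimizer_config=PSOConfig(n_particles=30, max_iter=300,
                                             patience=60, n_restarts=2),
                  rng_seed=3)
print(round(fit.params.sigma_mem, 3), round(fit.params.delta_thresh, 3),
      round(fit.params.theta, 4))
print(round(fit.ce, 2), round(fit.bic, 2))
```

prints

```
4.114 11.854 0.0136
72.03 159.79
```

i.e. from a single 189-trial dataset the fit recovers the generating memory
noise (4.29 deg·s^-1/2) and threshold (11.14 deg) to within the sampling
precision such a dataset affords; the cross-entropy (nats) and its BIC are
reported alongside.

The numbered scripts under `analysis/` run the full pipeline narrative —
cohort simulation, behavioral summaries, model comparison (the lapse
variant wins on data where it is the ground truth), per-variant parameter
recovery, the optimal-threshold sweep (r ≈ 0.996 between memory noise and
the accuracy-maximizing threshold), cognitive composites and
temporal-generalization tests — and write their tables under `results/`.

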