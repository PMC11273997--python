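# latentlink

Factor-score and item-link recovery on small item-response tables:
a linear factor-analysis baseline side by side with a variational
autoencoder (VAE), evaluated on simulated data with known structure, plus a
generic mode for arbitrary numeric tables.

## The problem

Psychometric measurement models relate observed indicators `x` to latent
factor scores `ξ` through

```
x_j = τ_j + f_j(Λ_j, ξ) + ε_j,        ε_j ~ N(0, σ²_j),
```

where the per-item link `f_j` is usually assumed linear, `f = Λ ξ`. When
some items instead follow a bounded nonlinear link — here the sigmoid
`f(Λ, ξ) = 1 / (1 + exp(−3 ξ Λ))` — a linear factor analysis misestimates
those items' loadings, misreconstructs their values and degrades the factor
scores. A VAE makes no linearity assumption: a probabilistic encoder maps
items to a latent mean `μ_z|x` and log-variance, a reparameterized draw
`z = μ + σ ε` feeds a decoder that reconstructs the items, and the loss is
the reconstruction error plus the closed-form KL divergence between the
diagonal-Gaussian posterior and a standard-normal prior. The latent means
serve as factor-score estimates, and the fitted link between latent score
and reconstructed item — recovered by least squares under a linear or
sigmoidal family — estimates each item's loading and link shape.

The package implements:

- `latentlink.simulate` — the generative recipes: one or two independent
  standard-normal factors, 8 indicators per factor with loadings 0.8,
  intercepts 0, residual variance 0.20, and 0/1/4 sigmoidal items per
  factor; lossless CSV/JSON round trip.
- `latentlink.fa_baseline` — maximum-likelihood factor analysis on the
  covariance metric, Bartlett (ML) factor scores, linear reconstruction.
- `latentlink.vae` — the VAE (items → 4 ReLU units → q means + q
  log-variances → 4 ReLU units → items) trained with Adam (lr 0.001, 100
  epochs) under 10-fold cross-validation, keeping the fold with the best
  held-out reconstruction; plain numpy with hand-written gradients, fully
  seeded.
- `latentlink.link_fit` — least-squares link fitting (OLS for the linear
  family, nonlinear least squares for the sigmoid) with asymptotic standard
  errors, a representability check for the bounded sigmoid, and AICc-based
  link classification.
- `latentlink.metrics` — MAE/RMSE of score recovery, pooled explained
  variance of item reconstruction, and numeric density summaries including
  a Monte-Carlo-calibrated unimodality (dip) flag.
- `latentlink.experiments` — the six-condition benchmark
  ({1, 2 factors} × {0, 1, 4 sigmoidal items per factor}) and the generic
  CSV mode, behind a `latentlink` CLI.

## Worked example

```python
import numpy as np
from latentlink import simulate, experiments, ExperimentConfig

spec = simulate.make_spec(n_sigmoid_per_factor=1)   # items 1-7 linear, item 8 sigmoidal
ds = simulate.simulate_dataset(spec, n_subjects=1000, seed=0, name="one_sigmoid")
res = experiments.run_condition(ds, ExperimentConfig(master_seed=0))

print(res.fa.link_table.round(3).to_string(index=False))
print("FA  EV %.3f MAE %.3f" % (res.fa.explained_variance, res.fa.report.mae))
print("VAE EV %.3f MAE %.3f" % (res.vae.explained_variance, res.vae.report.mae))
```

prints

```
 item  family  loading    se  converged   sse
    1  linear    0.806 0.000       True 0.175
    2  linear    0.795 0.001       True 0.756
    3  linear    0.778 0.001       True 0.783
    4  linear    0.781 0.000       True 0.213
    5  linear    0.785 0.000       True 0.253
    6  linear    0.831 0.000       True 0.215
    7  linear    0.808 0.001       True 0.775
    8 sigmoid      NaN   NaN      False 7.591
FA  EV 0.774 MAE 0.165
VAE EV 0.760 MAE 0.163
```

The linear items' loadings are recovered near the generating 0.8. Item 8
was generated through the sigmoid link: the bounded sigmoid family cannot
describe FA's unbounded *linear* reconstruction of that item
(`converged = False`, the table's missing cell). Explained variance is the
pooled 1 − RSS/TSS of item reconstruction; MAE is the mean absolute error
between true and estimated (aligned) factor scores. Under this residual
variance (0.20) the metrics of both methods sit close together near their
theoretical ceiling: explained variance is capped near 0.79 for *any*
one-factor reconstruction, and the optimal reconstruction of the sigmoidal
item is smoothed toward linearity by posterior score uncertainty, so the
sigmoid-family fit on the VAE reconstruction is frequently flagged
unrepresentable as well — `docs/methods.md` works through both effects.

From the shell, the same machinery:

```
latentlink run-benchmark --seed 1 --outdir results/bench
latentlink simulate --condition 1f_4sigmoid --n 1000 --seed 2 --outdir data/
latentlink run-generic data/responses.csv --factors 1 --outdir results/generic
```

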