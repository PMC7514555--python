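# pffcens

Inference for the **inverse Weibull distribution** and its **Shannon
entropy** under **progressive first-failure censoring**.

In a progressive first-failure experiment, `n` groups of `k` identical
units are placed on test; at the *i*-th observed group-minimum failure the
failing group plus `R[i]` further surviving groups are withdrawn, stopping
at the `m`-th failure. The package provides:

- `pffcens.distribution` — inverse Weibull CDF/PDF/quantile/hazard, the
  closed-form Shannon entropy and its gradient;
- `pffcens.sampling` — censoring-scheme shorthand parsing (`"(25,0*24)"`,
  `"((1,0)*2)"`) and reproducible sample generation;
- `pffcens.mle_inference` — censored log-likelihood, score, observed
  information, profile-likelihood MLE, delta-method entropy variance,
  plain and log-transformed asymptotic confidence intervals, and the
  Kolmogorov–Smirnov statistic for complete data;
- `pffcens.lindley_bayes` — Bayes point estimates under squared-error,
  Linex and general-entropy losses via the two-parameter Lindley
  approximation (Gamma prior on the scale, 1/α prior on the shape);
- `pffcens.importance_bayes` — importance-sampling posterior draws,
  weighted Bayes estimates under the three losses, and highest posterior
  density (HPD) credible intervals;
- `pffcens.simulation_study` — a Monte Carlo harness reporting EV/MSE of
  estimators and average length / coverage of interval methods, with MC
  standard errors;
- `pffcens.interface` — dataset I/O plus the guinea-pig survival-time
  fixtures (`guinea_complete`, `guinea_ff36`, `guinea_R1/R2/R3`).

## CLI

```sh
# goodness of fit on the complete 72-observation fixture
pffcens gof guinea_complete --output json

# MLE + confidence intervals on a censored fixture (scheme attached)
pffcens fit guinea_R1 --level 0.95 --ci both --output json

# ... or on your own file with an explicit scheme
pffcens fit times.txt --k 2 --n 36 --scheme "(18,0*17)" --output json

# Bayes estimates: Lindley approximation or importance sampling (+ HPD)
pffcens bayes guinea_R1 --method lindley --loss linex --p 1
pffcens bayes guinea_R1 --method is --seed 7 --m-draws 5000 --hpd-level 0.95

# Monte Carlo study; schemes file has lines like "1,50,(25,0*24)"
pffcens simulate --alpha 2 --lam 1 --schemes-file schemes.txt \
    --reps 1000 --seed 11 --out-dir results/study
```

Data files are one positive time per line (or a single-column CSV with an
optional header). All randomness requires an explicit seed.

## Notes

- Entropy is in nats; all logs are natural.
- The log-likelihood excludes the combinatorial ordering constant by
  default (`include_constant=True` adds it); the constant does not affect
  estimation.
- Heavy censoring (e.g. schemes ending in a large removal) degrades the
  importance sampler's effective sample size; weights are computed in log
  space and the simulation harness reports per-cell MC standard errors so
  such cells remain interpretable.
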