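# beliefsim

Belief-updating analysis pipeline for feedback-learning experiments in
which participants repeatedly report a probability judgment about a binary
fact (e.g., "am I in the more popular half?") across 20 trials of binary
feedback.

Beliefs are modeled as Beta distributions and each reported probability as
a single draw from the current belief distribution. Four update models are
registered:

| id | update rule      | bias | free parameters        |
|----|------------------|------|------------------------|
| 1  | Bayesian         | yes  | alpha0, beta0, omega   |
| 2  | Bayesian         | no   | alpha0, beta0          |
| 3  | Rescorla-Wagner  | yes  | mu0, nu, eta, b        |
| 4  | Rescorla-Wagner  | no   | mu0, nu, eta           |

On top of the models the package provides:

- **fitting** — per-run MAP estimation (multi-start bounded optimization
  with Normal/HalfNormal priors) and BIC.
- **model_selection** — variational random-effects model comparison with
  Monte-Carlo exceedance probabilities, model-recovery confusion matrices,
  and posterior-predictive update checks (KS test).
- **synthetic_data** — a cohort generator that plants a known effect
  structure (depression-specific affect -> lower prior belief,
  anxiety-specific affect -> negative updating bias, a positive
  prior-mean/bias "confirmation" coupling, weakly depression-linked
  popularity) through a Gaussian copula, plus a fixed 95-item bifactor-style
  loadings matrix and Likert item-response simulation.
- **factor_scores** — Anderson-Rubin scoring (identity score covariance)
  from a fixed loadings matrix.
- **stats_analysis** — directional-error exclusion, model-agnostic belief
  indices, permutation correlation tests, Benjamini-Hochberg FDR, joint
  regressions with permutation coefficient-difference tests, and a linear
  bootstrap mediation (ACME).

## CLI

```sh
beliefsim simulate --out cohort_dir/ --seed 7          # synthetic cohort
beliefsim simulate --config cfg.yaml --out cohort_dir/
beliefsim fit --trajectories cohort_dir/trajectories.csv --out fits.csv
beliefsim compare --fits fits.csv --out comparison.json
beliefsim analyze --fits fits.csv --cohort cohort_dir/cohort.csv \
    --trajectories cohort_dir/trajectories.csv --out report.json
```

`simulate` writes `trajectories.csv`, `cohort.csv`, `items.csv`,
`loadings.csv` and `config.yaml`. `analyze` produces a JSON report with
the 12-test correlation family (3 factors x 4 parameters, FDR-corrected),
the confirmation-bias correlation, joint regressions with
coefficient-difference permutation tests, the popularity mediation block,
and the exclusion summary.

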