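# twinace

Bivariate liability-threshold ACE twin models for binary phenotypes.

`twinace` is for behaviour-genetics researchers who work with the
classical twin design and two correlated binary lifetime outcomes — the
motivating case is regular smoking initiation (RSI) and cannabis
initiation (CI) measured in multi-country twin registers. Raw register
data are confidential, so the package pairs the full inferential
pipeline with a synthetic-data generator that reproduces the assumed
statistical structure exactly: every stage is testable end-to-end
without any real data.

## The model

A binary trait is the indicator that a latent standard-normal liability
exceeds a threshold τ (so prevalence = 1 − Φ(τ), and τ reads as a
z-score). Per trait, liability variance splits into additive genetic
(A), shared environmental (C) and unique environmental (E) parts with
A + C + E = 1; cross-trait components cov_a, cov_c, cov_e generate the
covariance between the two liabilities. For a twin pair the implied
4 × 4 normal correlation matrix has

    within person, cross trait:   rP  = cov_a + cov_c + cov_e
    cross twin, same trait:       αA + C          (α = 1 MZ, ½ DZ)
    cross twin, cross trait:      α·cov_a + cov_c

and the decomposed correlations are rX = cov_x / √(X₁X₂), with
rP = rA√(A₁A₂) + rC√(C₁C₂) + rE√(E₁E₂). Components are estimated
directly (the direct-symmetric convention), so they may go negative; a
negative component makes the corresponding rX inestimable (reported
NA). Models are fitted by full-information maximum likelihood over
exact response patterns (single responders contribute marginals),
optionally with a linear age effect on the liability mean, unstratified
or stratified by group × sex, with equality-constraint likelihood-ratio
tests and profile-likelihood confidence intervals. See
`docs/methods.md` for the numerical details.

## Worked example

Simulate a scaled-down three-cohort study (a large Dutch-style register
with opposite-sex pairs, a Finnish-style register, and a same-sex-only
US-style register), then describe, correlate and fit:

```bash
twinace --seed 7 simulate --out demo.csv --scale 0.1
# wrote 1082 pairs to demo.csv (truth: demo.truth.json)

twinace --seed 7 --out-dir out describe --data demo.csv
#       group sex trait  n_yes   n  prevalence
#     finland   F   rsi    144 311    0.463023
#     finland   F    ci     83 311    0.266881
# ...
# netherlands   M    ci    136 498    0.273092

twinace --seed 7 --out-dir out twincor --data demo.csv
#                    MZ_M  DZ_M  MZ_F  DZ_F  DZ_OS
# trait group
# rsi   finland      0.87  0.86  0.80  0.26   0.62
#       minnesota    0.83  0.67  0.86  0.72    NaN
#       netherlands  0.91  0.70  0.78  0.37   0.69
# ...

twinace --seed 7 --out-dir out fit --data demo.csv --fix-betas --n-starts 2
# -2lnL = 4745.42, 11 free parameters, AIC = 4767.42
```

Reading the output: prevalences differ by cohort by construction (the
generating thresholds invert each cohort's lifetime prevalence, e.g.
cannabis initiation is far more common in the Minnesota-style group).
Monozygotic cross-twin correlations exceed same-sex dizygotic ones —
the signature of additive genetic variance (MZ ≈ A + C, DZ ≈ ½A + C) —
and the same-sex-only cohort has no opposite-sex cell (NaN). The fit
line reports the deviance, the conventional free-parameter count
(13 for the unstratified model; 11 here because the age slopes are
dropped) and the parameter-penalized AIC; per-stratum estimates land in
`out/fit.json` and a formatted report in `out/report.{tsv,json,md}`. At
this small scale (≈1,100 pairs) the A/C split is noisy — the fitted
pooled estimates were A = (0.40, 0.17), C = (0.43, 0.63) against
generating values A = (0.47, 0.28), C = (0.34, 0.51); the recovery
simulations in the test suite use 10,000 pairs, where the estimator is
accurate to a few hundredths.

Country and sex comparisons (2-df and 1-df likelihood-ratio tests) run
through `twinace compare --data demo.csv --parameter tau_rsi --mode
across_country_within_sex`, or programmatically via
`twinace.equality_test_suite`.

## Layout

- `src/twinace/data.py` — pair records, CSV I/O, config-driven
  binarization (example configs under `examples/recode/`), prevalence
  and fourfold tables
- `src/twinace/simulate.py` — synthetic twin studies + truth sidecars
- `src/twinace/tetrachoric.py` — thresholds, tetrachoric ML, twin
  correlation tables
- `src/twinace/liability.py` — covariance algebra, pattern
  probabilities, full-information likelihood
- `src/twinace/fitting.py` — ML fitting, constraints, LRTs, profile CIs
- `src/twinace/report.py` — deterministic TSV/JSON/markdown reports
- `src/twinace/cli.py` — the `twinace` command
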