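# Methods

## The model

`twinace` implements the bivariate liability-threshold ACE model for two
binary phenotypes measured on twin pairs — here lifetime regular smoking
initiation (RSI) and lifetime cannabis initiation (CI). Each observed
response is the indicator that a latent standard-normal liability
exceeds a threshold τ (a z-score): prevalence = 1 − Φ(τ). Per trait the
liability variance decomposes into additive genetic (A), shared
environmental (C) and unique environmental (E) components with
A + C + E = 1; the two traits' liabilities covary through cross-trait
components cov_a, cov_c, cov_e on the same standardized scale.

For a pair, the 4-vector (twin1-RSI, twin1-CI, twin2-RSI, twin2-CI) is
multivariate normal with unit diagonal and

- within-person cross-trait covariance cov_a + cov_c + cov_e (= rP),
- cross-twin same-trait covariance αA + C, α = 1 (MZ) or 0.5 (DZ),
- cross-twin cross-trait covariance α·cov_a + cov_c.

Derived factor correlations are r_X = cov_x / √(X₁X₂), defined only
when both components are positive; the phenotypic correlation obeys
rP = rA√(A₁A₂) + rC√(C₁C₂) + rE√(E₁E₂) when all components are
positive.

Components are parameterized directly ("direct symmetric"): point
estimates may be negative, and the only hard constraint is positive
definiteness of the implied MZ and DZ covariance matrices. This avoids
the upward bias of dropping non-significant components, at the cost of
wide A/C intervals — binary twin data separate A from C weakly, which
is visible throughout the recovery simulations.

An optional linear age effect shifts the liability mean, equivalently
the effective threshold: τ(age) = τ − β·(age − age_ref). The reference
age defaults to the weighted mean age of the analyzed sample so τ stays
interpretable as a z-score at the average age. Age is treated as a
pair-level covariate (twins share their age).

### Opposite-sex pairs

Sex-stratified models give males and females separate parameter sets.
The cross-twin block of an opposite-sex DZ pair bridges the two sets
component-wise with a geometric mean, weighted 0.5 for A:
0.5·√(A_m A_f) + √(C_m C_f), and likewise for the cross-trait
components. This embeds the assumption that the same genetic and shared
environmental factors act in both sexes with cross-sex correlation 1
(no qualitative sex limitation); the package does not implement
sex-specific factors. When a component is negative the geometric mean
is undefined; the arithmetic mean is substituted with a logged warning.
That fallback makes the likelihood non-differentiable where a component
crosses zero — see Optimization below.

## Likelihood

The full-information likelihood sums log pair-pattern probabilities.
Complete pairs contribute 4-dimensional rectangle probabilities of the
implied normal; missing responses (item non-response, or an absent
co-twin) are integrated out exactly by dropping dimensions, so single
responders contribute 1- or 2-dimensional marginals and all data are
used. Identical patterns within (group, zygosity, sexes, age) are
aggregated with multiplicities before integration; aggregation keys
include age (rounded to 0.1 y) only when an age slope is active, so it
is exact whenever β = 0 or ages are discrete at that resolution. Twin
order within same-sex pairs is canonicalized before aggregation;
exchange symmetry makes this exact and renders the likelihood exactly
invariant to within-pair ordering.

### Rectangle probabilities

Deterministic and bit-reproducible by construction:

- d = 1: difference of normal CDFs.
- d = 2: Owen's-T closed form (absolute accuracy ~1e-14).
- d = 3, 4: the first d − 2 variables are mapped to the unit cube by
  the sequential-conditioning (separation-of-variables) substitution;
  conditional on them the remaining two variables form a bivariate
  normal whose rectangle probability is evaluated exactly via Owen's T.
  The residual smooth integral uses a tensor Gauss–Legendre rule whose
  nodes pass through a quintic smoothstep, which suppresses the
  endpoint derivative blow-up introduced by infinite bounds. With the
  default 16 nodes per dimension the absolute error is ~1e-8 (12 nodes
  ~1e-7, 8 nodes ~2e-5); fitting may use fewer nodes since nested-model
  deviance differences cancel most of the integration bias.

## Estimation

Maximum likelihood by multi-start L-BFGS-B. The unit-variance
constraint is eliminated internally by substituting E = 1 − A − C per
trait; reported free-parameter counts nevertheless follow the
conventional bookkeeping in which A, C and E are all counted and the
unit sum is a constraint: 13 parameters for the unstratified model
(2 thresholds + 2 age slopes + 6 variance components + 3 cross-trait
components), 78 for the six-group (3 countries × 2 sexes) model. Both
counts are reported in `FitResult`.

Equality constraints tie named parameters across strata (the device
behind 2-df country tests and 1-df sex tests). Constraints may also
target derived quantities (rA, rC, rE, rP), imposed by reparameterizing
the corresponding covariance, e.g. cov_a = rA·√(A₁A₂) with components
floored at 1e-6 inside the square root.

Start values: thresholds from observed prevalences; A and C from
Falconer-style contrasts of double-entered MZ/DZ tetrachorics when at
least 30 complete pairs per zygosity exist (defaults A = 0.40,
C = 0.25 otherwise); cross-trait covariances split the within-person
tetrachoric proportionally to the √(X₁X₂) shares. Additional starts are
seeded jitter around these. Bounds: variance components in [−1, 1.5],
covariances and derived correlations in [−1, 1], thresholds in [−4, 4],
age slopes in [−0.5, 0.5]/y.

Positive definiteness is enforced by a smooth quadratic hinge barrier
that activates when the smallest implied eigenvalue drops below 0.005,
backed by a hard penalty outside the PD region. The hinge keeps line
searches away from the cliff; its influence on estimates is negligible
unless the optimum itself is nearly singular. Because the opposite-sex
bridge switches branch at component = 0, the objective is kinked there
and an optimum may sit exactly on the kink; L-BFGS-B then reports a
line-search failure at the solution. The fitter restarts from the
failure point with a fresh Hessian and accepts the fit when successive
restarts improve the objective by less than 1e-6 — the diagnostics
record whether convergence was regular or kink-accepted.

Likelihood-ratio tests use deviance differences with df equal to the
difference in conventional parameter counts, and raw p-values (no
multiplicity adjustment). AIC is parameter-penalized: −2lnL + 2k with k
the conventional count. Profile 95% intervals solve
"constrained deviance = minimum + 3.8415" by stepwise bracketing plus
Brent root-finding; derived targets are profiled through the
equality-constrained reparameterization; a bound whose search fails is
flagged unconverged and rendered as "-", never fabricated.

## The synthetic-data generator

`simulate_pairs` mirrors the generative model exactly: per pair one
draw from the implied 4-dimensional normal, dichotomized at the
(age-adjusted) thresholds; ages are shared within pair; same-sex pairs
are female with a configurable probability and may use a separate
female parameter set; opposite-sex pairs are male-first and use the
bridged cross-twin block. Optional independent missingness per
phenotype and single-responder pairs exercise the full-information
path. Group streams are seeded from the master seed keyed by the group
label (CRC32), so group content is invariant to group order.

`three_cohort_spec` reproduces the three-register design the analysis
targets: individual counts 12,987 / 5,888 / 2,742; female shares 67.2 /
56.9 / 55.2%; MZ shares 47.0 / 32.2 / 62.2%; opposite-sex DZ shares
25.3 / 35.5 / 0% (the US register recruited same-sex pairs only);
truncated-normal age laws matching each register's mean, SD and range;
thresholds at the per-country lifetime prevalences (RSI 33.2 / 47.5 /
44.7%, CI 29.5 / 25.7 / 62.9%). The variance/covariance structure is
the pooled estimate (A = 0.47/0.28, C = 0.34/0.51, rA = 0.74,
rC = 0.47, rE = 0.48) shared across countries and sexes, and age slopes
default to zero: per-group published component sets do not pin down the
cross-trait covariances (some decomposed correlations are inestimable),
so a shared structure is the defensible default. An odd individual
count is honoured by one single-responder pair. What the generator does
*not* emulate: item-level response options and skip-outs (generation is
at the binarized level), cohort/period effects, assortative mating,
sibling interaction, and real heterogeneity of variance components
across countries — passing recovery tests therefore validates the
inferential machinery under the model's own assumptions, not the
model's adequacy for any real register.

## Calibration studies (test suite)

- **Parameter recovery**: 5,000 MZ + 5,000 DZ pairs from the pooled
  configuration, refit unstratified; A(RSI), C(CI) and rA return within
  ±0.06 / ±0.10. Over replications the estimator is unbiased but the
  A/C split has sampling SD ≈ 0.05 at this size — the binary-data
  confounding noted above.
- **LRT size**: 200 replicates of a three-group design (600 MZ + 400 DZ
  pairs per group) generated with identical parameters; the 2-df
  threshold-equality test rejects at the nominal 5% (observed 0.045).
  To keep 200 replicates tractable the truly-equal covariance structure
  is held at its generating values while nuisance thresholds are
  estimated; this leaves the null distribution of the threshold test
  unchanged.
- **Profile coverage**: 200 replicates at 4,000 pairs; membership of
  the true A(RSI) in the 95% profile interval is evaluated via the
  equivalent deviance-at-truth criterion (observed coverage 0.965).

## Known limitations

- No dominance (ADE), no sibling/parental extensions, no qualitative
  sex limitation, no polychoric (>2 category) estimation.
- The opposite-sex arithmetic-mean fallback for negative components is
  pragmatic; estimates near component = 0 inherit a kinked likelihood.
- Stratified-model degrees of freedom follow parameter counts; data-row
  based df conventions used elsewhere in the literature can differ and
  are not reproduced.
- Aggregation with active age slopes rounds ages to 0.1 y; likelihoods
  with continuous ages are approximated at that resolution.
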