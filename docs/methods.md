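# Methods

## Setting

A method-comparison study yields paired differences `d_1, …, d_n`, assumed
independent and identically distributed with continuous distribution
function `F`. The 95% limits of agreement (LoA) are the interval meant to
bracket 95% of the population of differences. The classical estimate is
`d̄ ± 1.96 s_d` (the multiplier is the conventional constant 1.96, not a
normal or t quantile refinement); the nonparametric alternative estimates
the 2.5% and 97.5% quantiles of `F` directly.

## Quantile estimators

All six nonparametric estimators are L-statistics
`Q̂(p) = Σ_{i=1}^n W_i X_{(i)}` with weights that depend only on `(n, p)`.
The package therefore exposes the weight vectors
(`nploa.quantile_weights(est, n, p)`) and evaluates a whole simulation cell
as a single matrix product of the sorted-sample matrix with two weight
vectors.

- **Sample quantile (`sq`).** With `h = p(n+1)`, `r = ⌊h⌋`, `α = h − r`:
  `Q̂ = (1−α)X_{(r)} + αX_{(r+1)}`. Defined only for `1 ≤ h ≤ n`; at the
  LoA levels this means `n ≥ 39`. (The formula is well defined from
  `n = 39`; some practice guidance quotes `n ≥ 40`, which is the same rule
  stated conservatively.)
- **Harrell–Davis (`hd`).** `W_i = I_{i/n}(a, b) − I_{(i−1)/n}(a, b)` with
  `a = p(n+1)`, `b = (1−p)(n+1)` and `I_x(a, b)` the *regularized*
  incomplete beta function (the Beta(a, b) CDF). The regularized form is
  essential: the weights then telescope to exactly 1, making the estimator
  a weighted average.
- **Bernstein polynomial (`bp`).** `W_i = B(i−1; n−1, p)`, the binomial
  pmf with `n−1` trials; full support, so the weights sum to 1 exactly.
- **Harrell–Davis with level-crossing weights (`hdlc`).** The empirical
  distribution is re-weighted: boundary observations receive mass
  `w_1 = w_n = ½(1 − (n−2)/√(n(n−1)))` and interior observations
  `1/√(n(n−1))`. These masses satisfy `2w_1 + (n−2)w_int = 1` identically.
  The Harrell–Davis construction is then applied over the cumulative grid
  `q_0 = 0, q_1, …, q_n = 1`. The boundary/interior split is the unique
  reading of this weighting scheme under which the masses are a probability
  vector, and the weights are verified in the tests against independent
  numerical quadrature of the Beta density over the `q` partition.
- **Sfakianakis–Verginis, first form (`sv`).** Interior order statistics
  receive `½(B(i; n, p) + B(i−1; n, p))`; the three smallest and largest
  order statistics carry boundary corrections in `B(0)`, `B(1)`, `B(n−1)`,
  `B(n)`. The corrections cancel algebraically so the implied weights sum
  to 1 (verified to 1e−10 in tests rather than asserted at run time: the
  identity is exact, only floating point intervenes).
- **Navruz–Özdemir (`no`).** The bulk term gives `X_{(i+1)}` the blend
  `B(i; n, p)(1−p) + B(i+1; n, p)p` for `i = 1..n−2`, with boundary terms
  on `X_{(1..3)}` and `X_{(n−2..n)}`. The weights again sum to 1 exactly,
  and the estimator is exactly symmetric under `p ↔ 1−p` with sample
  reversal — both properties are enforced by tests for all six estimators.

`sv` and `no` address `X_{(1)}..X_{(3)}` and `X_{(n−2)}..X_{(n)}` as
distinct terms, so the package requires `n ≥ 5` for them (no smaller
minimum is inherent in the formulas, but below 5 the boundary groups
overlap and the formulas double-count). `hdlc` needs `n ≥ 2`, `ba` needs
`n ≥ 2`, `hd`/`bp` are defined from `n = 1`.

Ties in the data receive no special treatment (order statistics are used
as-is), and unsorted input is sorted on construction of `OrderedSample`.

Negative boundary weights (in `sv` and `no`) raise the theoretical
possibility of crossed limits (lower > upper). For sorted data this cannot
actually occur at the sample sizes of interest — every suffix sum of
`w_lower − w_upper` is non-positive, and a sorted sample is a non-negative
combination of step vectors plus a constant — but the code keeps a
defensive `CrossedLimitsWarning` and the simulation clamps coverage at 0.

## Bootstrap confidence intervals

`bootstrap_loa_ci` implements the percentile bootstrap: resample the
differences with replacement `n_boot` times (default 2000), recompute both
limits on each resample, and take the `(1±level)/2` empirical quantiles of
each limit separately (default level 0.95). The percentile variant is the
minimal defensible choice; BCa or studentized intervals are out of scope.
Because resamples have the original sample size, an estimator defined on
the data is defined on every resample. An outer-simulation test shows the
95% interval for the lower limit covers the true quantile in roughly 90% of
repetitions at `n = 100` under normal data — percentile intervals at
extreme quantiles run somewhat below nominal, which is expected behavior,
and the interval is reported as uncertainty quantification, not as an
exact-level procedure.

## Simulation engine

For each cell (distribution × `n` × estimator) the engine simulates
`replicates` trials (default 5000). Per trial it draws `n` values, forms
the LoA, and computes the coverage `c = F(upper) − F(lower)` with the exact
CDF — never an empirical approximation. Summaries per cell: mean, median,
quartiles and 5% quantile of the coverage distribution (quantiles by the
linear-interpolation definition, `h = (m−1)p + 1`, the type-7 rule that is
the default in most statistical environments), Tukey whisker values for
boxplots, and the error of the lower/upper estimates against the exact
2.5%/97.5% quantiles.

Two error summaries are computed: the root mean squared error (`rmse_*`
columns) and the mean absolute error (`mae_*` columns). The shipped table
mirrors (`table2.csv`, `table3.csv`) report the mean absolute error:
tail-quantile estimates under skewed distributions have heavily
right-skewed error distributions, and the MAE is the materially more
stable cell summary (for reference, RMSE exceeds MAE by ~25% under a
normal error law and by considerably more under skew). The RMSE view of
the same tables is available via
`nploa.error_table(results, which, metric="rmse")`.

The benchmark table (`table1.csv`) reports, per estimator and `n`, the 5%
quantile of the coverage distribution minimized over the six distributions
— a worst-case variability measure — except for the classical `ba`
analysis, which reports its value under the standard normal only: under
non-normal distributions `ba` is asymptotically inconsistent (its limiting
coverage under Beta(2,2) is 0.960, under the lognormal 0.962), so a
worst-case across distributions would conflate estimator variability with
model misspecification.

### Study distributions

Six reference distributions spanning symmetric, skewed, bounded and
heavy-tailed shapes: standard normal; lognormal (log-sd 1); Beta(2,5);
Beta(2,2); chi-squared with 4 df; Exponential(rate 1). CDFs and quantiles
come from scipy's exact implementations; samplers use numpy `Generator`
native methods and are validated against the CDFs by Kolmogorov–Smirnov
tests at 100 000 draws. The lognormal log-mean is configurable
(`lognormal_meanlog`, default 0): coverage results are invariant to it
(every estimator is location-scale equivariant, and the lognormal family is
a log-location family), but error magnitudes scale by `e^meanlog`.

### Seeding and determinism

Each cell owns a `numpy.random.SeedSequence` keyed on
`(seed, distribution code, n, estimator code)`, spawned into one child
stream per replicate. Results are therefore invariant to execution order
and safe to parallelize, and a study re-run with the same config and seed
reproduces every output CSV byte-identically (tested).

### What the generator emulates — and what it does not

The simulated trials are iid draws of the paired differences themselves:
constant bias, constant variance, no relationship between difference and
measurement magnitude, no ties, no rounding, no outlier contamination
beyond what the six shapes produce. Passing coverage results therefore
speak to estimator behavior under clean violations of normality only; they
say nothing about drifting bias, heteroscedastic differences (which call
for transformation or regression approaches before any LoA estimation),
repeated measures per subject, or digit-preference artifacts in real
instruments.

## Problem sizes used in the shipped checks

The acceptance checks run the coverage cells at the study's native 5000
replicates per cell (a few seconds per estimator across all six
distributions at `n = 50`, thanks to the weight-matrix formulation). The
`n = 1000` convergence property is checked at 1000 replicates per cell,
where the Monte-Carlo standard error of a mean coverage (~0.0002) is
negligible against the 0.01 tolerance. The scaled-down 500-replicate study
configuration exists for quick interactive runs; all published-scale
numbers in the README were produced at 5000.

## Known limitations

- Exact parametric confidence intervals for the classical LoA are not
  implemented (the bootstrap serves both classical and nonparametric
  limits).
- Only the first Sfakianakis–Verginis estimator is provided.
- The level-crossing weighting is implemented in its normalized reading
  (above); alternative readings that do not form a probability vector are
  not supported.
- User-supplied distributions beyond the six are not part of the tested
  surface.
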