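# nploa — nonparametric limits of agreement for method comparison studies

When two methods measure the same continuous quantity on the same subjects,
a Bland–Altman analysis summarizes their agreement through the paired
differences `d_i = m1_i − m2_i`: the bias is `d̄` and the classical 95%
limits of agreement (LoA) are

```
LoA = d̄ ± 1.96 · s_d
```

with `s_d` the sample standard deviation of the differences. Those limits
are only valid when the differences are roughly normal with constant bias
and variance. When they are not — and neither a transformation nor a
regression approach rescues the analysis — the LoA must instead be the
nonparametrically estimated 2.5% and 97.5% quantiles of the differences.

Estimating such extreme tail quantiles from modest samples is hard, and the
choice of quantile estimator matters. `nploa` implements six estimators,
all L-statistics `Q̂(p) = Σᵢ Wᵢ X₍ᵢ₎` over the order statistics
`X₍₁₎ ≤ … ≤ X₍ₙ₎` with weights depending only on `(n, p)`:

| id     | estimator | weights |
|--------|-----------|---------|
| `sq`   | sample quantile | `(1−α)X₍ᵣ₎ + αX₍ᵣ₊₁₎`, `r = ⌊p(n+1)⌋`, `α = p(n+1) − r` |
| `hd`   | Harrell–Davis | increments of the Beta(`p(n+1)`, `(1−p)(n+1)`) CDF over `i/n` |
| `bp`   | Bernstein polynomial | binomial masses `B(i−1; n−1, p)` |
| `hdlc` | Harrell–Davis, level-crossing | as `hd`, over a re-weighted empirical CDF |
| `sv`   | Sfakianakis–Verginis (SV1) | averaged adjacent binomial masses + boundary terms |
| `no`   | Navruz–Özdemir | blended binomial masses + boundary terms |

plus the classical analysis as `ba`. The `sq` estimator needs
`1 ≤ p(n+1) ≤ n`, i.e. `n ≥ 39` at the LoA levels; `sv`/`no` need `n ≥ 5`.

A Monte-Carlo engine quantifies how trustworthy each choice is: for a known
generating distribution `F` it simulates many samples, estimates the LoA on
each, and evaluates the coverage probability

```
c = F(upper LoA) − F(lower LoA)
```

whose distribution across replicates (median, mean, quartiles, 5% quantile)
tells you how often a study of size `n` would report limits that actually
bracket ≈95% of the population of differences. The engine also reports the
error of each tail-quantile estimate against the exact quantile. Headline
finding, reproducible with one command (below): at `n = 50` the simple `sq`
estimator is the most reliable choice, `hd` and `sv` catch up by
`n ≈ 150`, and the classical `ba` limits are asymptotically wrong under
non-normal differences.

## Worked example

Generate a synthetic method-comparison data set whose differences are
exponential (rate 1) — strongly skewed, so the classical limits are
inappropriate — and estimate nonparametric LoA with bootstrap confidence
intervals:

```sh
nploa make-fixture --kind paired-data --distribution exp_1 --n 100 --seed 42 --out pairs.csv
nploa estimate-loa --input pairs.csv --estimator sq --boot 2000 --level 0.95 --seed 7
```

which prints

```json
{
  "estimator": "sq",
  "lower": 0.047234565300000364,
  "upper": 3.538239605624995,
  "n": 100,
  "n_dropped": 0,
  "ci_lower": [0.021139760000000507, 0.0744512822749999],
  "ci_upper": [2.3586842596900013, 5.309882795]
}
```

The estimated limits `[0.047, 3.54]` are the 2.5% and 97.5% sample
quantiles of the 100 differences (the true Exponential(1) quantiles are
0.025 and 3.69); the percentile-bootstrap 95% intervals show the upper
limit is, as always for tail quantiles at this sample size, much less
precisely estimated than the lower one. With `--estimator ba` the same data
give limits `bias ± 1.96 s` — symmetric about the mean and negative on the
left, which is exactly the pathology the nonparametric limits avoid.

The same analysis from Python:

```python
import nploa
data = nploa.read_paired_data("pairs.csv")
pair = nploa.nonparametric_loa(data.diffs, "sq")   # LoAPair(lower=…, upper=…)
ci = nploa.bootstrap_loa_ci(data.diffs, "sq", n_boot=2000, seed=7)
```

## Running the simulation study

`configs/full_study.yaml` encodes the full design: six distributions
(standard normal; lognormal; Beta(2,5); Beta(2,2); χ²₄; Exponential(1)),
sample sizes 50(50)200, 250(250)1000, all seven analyses, 5000 replicates
per cell:

```sh
nploa run-study --config configs/full_study.yaml --out study_out        # ~2 min
nploa run-study --config configs/full_study.yaml --reps 500 --out quick # ~10 s
```

Outputs: `results.csv` (tidy, one row per cell), `table1.csv` (worst-case
5% coverage quantiles by estimator and n), `table2.csv`/`table3.csv` (mean
absolute error of the 2.5%/97.5% quantile estimates by n, estimator and
distribution), `boxplot_data.csv`, optional PNG boxplots (`--plot`), and a
`manifest.json` that records config, seed and version — re-running with the
manifest as `--config` reproduces every CSV byte for byte.

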