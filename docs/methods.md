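# Methods

## Model and estimators

For each probe, duplicate measurements form an n subjects × 2
replicates layout, modelled as a two-way random-effects design:

```
y_ij = mu + b_i + r_j + e_ij,
b_i ~ N(0, sigma_b^2),  r_j ~ N(0, sigma_r^2),  e_ij ~ N(0, sigma_w^2)
```

with `b_i` the subject effect, `r_j` a replicate/plate effect and
`e_ij` measurement noise. Reliability is the between-subject share of
variance, `sigma_b^2 / (sigma_b^2 + sigma_w^2)`, estimated by the
single-measure absolute-agreement ICC

```
ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))
```

from the ANOVA mean squares (`MSR` subjects, `MSC` replicates, `MSE`
residual). *Absolute agreement* means a systematic offset between
replicates (MSC) counts against reliability, unlike the consistency
variant. The estimator is implemented directly from sums of squares;
an external reliability package (pingouin) is used in the test suite
only, as an independent cross-check on the same inputs.

Method-of-moments variance components are `sigma_w^2 = MSE` and
`sigma_b^2 = max(0, (MSR - MSE)/k)`, truncated at zero. Negative ICC
estimates themselves are *retained* (they occur when within-subject
disagreement exceeds between-subject spread and are informative).

### Limits of agreement and the modified ICC

Bland–Altman limits of agreement for the paired differences
d = replicate1 − replicate2 are `mean(d) ± z * sd(d)` with z = 1.96 by
default (configurable); `sd(d)` uses the n−1 denominator. The
half-width `HoLA = z * sd(d)` measures absolute disagreement on the
beta scale, and the modified ICC is

```
mICC = ICC - HoLA.
```

ICC is scale-free while HoLA carries the units of the measurements, so
mICC is deliberately a *penalised score*, not a variance ratio: a probe
needs both good rank agreement and small absolute disagreement to score
highly. Under pure within-subject noise, `E[HoLA] -> z * sqrt(2 *
sigma_w^2)` for large n (`expected_hola`), which the simulation tests
verify by Monte Carlo.

### Classification

Both statistics are banded as Poor / Fair / Good / Excellent with
cutpoints 0.4, 0.6, 0.75. The boundary convention is explicit in
`ClassificationScheme` because the conventional band descriptions leave
the boundaries ambiguous: we use Poor < 0.4 ≤ Fair < 0.6 ≤ Good ≤ 0.75
< Excellent, i.e. each cutpoint belongs to the upper band except 0.75,
which closes the Good band. Values of mICC are classified raw (no
clamping of negatives), with the same cutpoints as ICC. Probes whose
statistics are undefined (zero total variance, or fewer complete pairs
than `min_pairs`) get the separate label `Undefined` and are excluded
from summaries and cross-tabulations.

## Data handling

- **Pairing.** The sample sheet (CSV: `sample_id`, `subject_id`,
  `replicate`, optional `plate`) is resolved into one pair per subject.
  Subjects with ≠ 2 replicates are excluded with a warning (error in
  strict mode). `require_cross_plate` (default off, since general users
  may lack plate metadata) drops subjects whose replicates share a
  plate, so that plate effects appear in the within-pair differences
  rather than being confounded away.
- **Missingness.** Probes missing in more than `max_missing_frac`
  (default 5%, inclusive threshold) of samples are removed up front.
  Within a retained probe, pairs with either replicate missing are
  dropped pairwise-complete and the surviving count is reported as
  `n_pairs`; probes below `min_pairs` (default 3) complete pairs get
  missing statistics.
- **Per-probe mean/SD.** `mean_beta` averages all paired samples;
  `sd_beta` is computed after selecting one replicate per subject
  uniformly at random, so duplicates do not artificially halve the
  spread. The selection uses a single recorded seed (default 0) and
  depends only on that seed and the subject order, making the output
  reproducible; the seed is logged by the CLI.
- **Scale.** Computations accept any scalar scale; range checking to
  [0, 1] happens only when reading a beta matrix and can be disabled
  for M-values (ICC estimates are known to be very similar on either
  scale).

## Synthetic duplicates

`simulate_duplicates` draws

```
y_pij = clip(mu_p + b_pi + shift_p * 1[j=2] + e_pij, 1e-6, 1 - 1e-6)
```

with per-probe `mu`, `sigma_b^2`, `sigma_w^2` and an additive plate
shift applied to replicate 2 only — the simplest mechanism that makes
cross-plate duplicates less reliable than same-plate ones, mirroring
the plate effect seen in real duplicate data. The generator works on
the beta scale with clipping rather than through a logit-scale model:
this keeps the closed forms (`true ICC = sigma_b^2 / (sigma_b^2 +
sigma_w^2)`, `E[HoLA] = z*sqrt(2 sigma_w^2)`) exact away from the
boundaries, at the cost of biased truth near 0 or 1. The generator
warns when more than half the values clip, and the boundary bias is
itself used as a directional test (probes with extreme `mu` recover
lower ICCs than mid-range probes, matching the p(1−p)/n mean–variance
relationship of a proportion).

Default design constants are 69 subject pairs (the duplicate-study
design size) and, in `SyntheticTruth.constant`, a mid-range probe with
`mu = 0.5`, `sigma_b^2 = 0.04`, `sigma_w^2 = 0.01` (true ICC 0.8) —
values typical of a variable, well-behaved CpG in whole blood.

What the generator does **not** emulate: probe-type chemistry
differences, spatial/CpG-island structure, correlated probes, beta-value
heteroscedasticity beyond clipping, or missingness mechanisms. Passing
parameter-recovery tests therefore shows the estimators are correct
under the stated sampling model, not that array data meet that model.

## Comparisons

- Cross-study agreement: Spearman correlation (average ranks for ties)
  of two probe → ICC vectors over their shared probes, and a class
  cross-tabulation with row percentages (1 decimal) and overall percent
  concordance = 100 · trace/total (2 decimals). `CrossTab.from_counts`
  accepts an already-tabulated count matrix, e.g. a published table.
- Group contrasts (e.g. probes with vs without an mQTL) use a two-sided
  Wilcoxon rank-sum test: exact enumeration of all assignments when
  both groups have ≤ 10 probes (average ranks handle ties), otherwise
  the normal approximation with tie correction. This is a deliberate
  simplification relative to mixed-effects models with chromosome /
  gene / co-methylation random effects: the rank test treats probes as
  exchangeable and will be anti-conservative when probes are spatially
  correlated. Medians per group are reported alongside the p-value.
- Stratified summaries report per-stratum counts and mean/median
  ICC/mICC, either by an annotation column (probe type, island
  relation, TSS group, arbitrary flags) or by mean-beta deciles
  [0, 0.1), …, [0.9, 1] (last bin closed).

## Numerical choices

- The residual sum of squares is accumulated directly from residuals
  (not by subtracting SSR + SSC from the total), so perfect duplicate
  agreement yields MSE = 0 and ICC = 1 exactly.
- ICC is reported missing when its denominator is exactly zero (all
  values identical); no epsilon thresholding is applied elsewhere.
- Reliability tables serialize floats at 6 significant digits with
  missing as `NA`; the format round-trips losslessly at that precision
  and class labels exactly.
- Exact rank-sum enumeration compares deviations with a 1e-9 slack so
  ties in the permutation distribution are counted as at-least-as-extreme.

## Problem sizes in the test suite

Validation simulations use 200 probes × 500 subjects for ICC/HoLA
recovery (tolerances ±0.02 on ICC, ±5% on HoLA), 100 probes × 2000
subjects for variance-component recovery (±15% relative), and
100 probes × 200 subjects for the plate-shift direction check — sizes
at which the Monte-Carlo error of the mean across probes is an order of
magnitude below each tolerance.

## Known limitations

- mICC mixes a unitless ratio with a scale-dependent penalty; comparing
  mICC across measurement scales (beta vs M) is not meaningful.
- The exact rank-sum mode enumerates C(n1+n2, n1) assignments and is
  restricted to groups of ≤ 10 for that reason.
- The per-probe scan is a plain Python loop over probes; it is fast to
  a few hundred thousand probes but makes no attempt at chunked or
  parallel execution for full-array workloads.
- No preprocessing (normalization, dye-bias correction, detection-p
  masking) is provided; inputs are assumed preprocessed.
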