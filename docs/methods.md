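# Methods

## Model

The package scores an individual's regional metric value against a
normative cohort using the distribution's own percentiles instead of a
Gaussian assumption. For ROI *j* with normative column *x·j* of size *n*:

* **median** *m_j*: middle order statistic; for even *n*, the mean of the
  two central order statistics.
* **percentile edges** *x_j5*, *x_j95*: linear interpolation between
  adjacent order statistics at fractional index `h = 1 + (p/100)(n - 1)`
  (numpy's default `"linear"` quantile method).
* **tail denominators** `d5 = m_j − x_j5`, `d95 = x_j95 − m_j`.

An individual value *x* maps to

```
P = −c (m_j − x)/d5   if x < m_j,    P = +c (x − m_j)/d95   if x > m_j,    P = 0 at the median,
```

with `c = 1.645`, the standard-normal Z value at the 5th/95th
percentiles, so Pscores and Z scores are directly comparable. Each tail
is normalized separately: the score is a rescaled percentile position,
not a moment-based standardization, so it is invariant to any positive
affine transform of the data and monotone in *x* within a column.

### Exact tail counts

With the linear-interpolation edge rule, a tie-free column of length *n*
has exactly `floor(h)` values strictly below the 5th edge, where
`h = 1 + 0.05 (n − 1)` (and `h − 1` when `h` is an integer and the edge
sits exactly on an order statistic), and symmetrically above the 95th
edge: 48 for n = 960 (h = 48.95), 46 for n = 912 (h = 46.55), 5 for
n = 100 (h = 5.95), 48 for n = 961 (h = 49 exactly). Concatenated over 48 ROIs this
gives 2304/46080, 2208/43776 and 240/4800 scores per tail — 5% up to the
granularity of the order statistics — independent of the generating
distribution and of the subsample drawn. This is the property the test
suite and the acceptance script measure. The even-*n* median rule
likewise forces an exact 50/50 positive/negative sign split for tie-free
even-*n* columns.

Percentile ranks (`p_ij = 100·#{x ≤ x_ij}/n`, ties sharing the maximal
count) are exposed as their own transformer/score method; the deviation
score itself uses only the median and the edges.

## Scoring methods compared

* `pscore` — the percentile deviation score above.
* `zscore` — `(x − mean)/SD` with the **n − 1** sample SD (conventional
  for a normative reference; `scipy.stats.zscore(ddof=1)` is the
  cross-check in the tests). Mean-0/SD-1 per column, but tail shares
  track the skew of the raw data.
* `log` — natural log of strictly positive values. Base e is a pure
  rescaling choice; no shape conclusion depends on it. Log output is not
  on the Z/P scale and is excluded from tail comparisons.

Degenerate columns (`d5 = 0`, `d95 = 0`, or zero SD) raise a
`DegenerateDistributionError` naming the ROI rather than producing NaNs:
silent NaNs would corrupt the tail counts the audit is about. Values
exactly at the median score 0 and are counted in neither sign bucket
(reported separately), which is also the natural reading of near-tied
published tail counts that differ by one.

## Extreme-value audit

Scores are concatenated column-major (participants fastest) into one
vector per metric; counts use **strict** inequalities (`> +1.645`,
`< −1.645`). Records store full-precision percentages; the CSV writer
rounds to one decimal at presentation time only (so 2208/43776 = 5.04%
prints as 5.0). The threshold, the scale constant and the tail
probabilities (5, 95) are configurable with those defaults.

## Subsampling reliability ("bootstrap")

`bootstrap_audit` draws `size` participants **without replacement** per
iteration (the procedure is repeated subsampling; a classical
with-replacement mode exists behind `replace=True`, off by default),
rescores the subsample against its *own* medians and edges, and audits
each iteration. Per-iteration seeds come from
`SeedSequence([master_seed, iteration])`, so iterations are independent
streams and any single iteration can be re-run from its pair. For
tie-free parents, the percentile-deviation tail share is 5/100 per ROI in
every iteration — mean 5.0%, SD 0 across iterations — while Z-score tail
shares inherit the parent's skew in every subsample.

## Synthetic cohorts

`generate_hcp_like_cohort` emulates the *shape* of a large healthy
young-adult diffusion study: four diffusion-tensor metrics (FA, MD, AD,
RD) at 960 participants and five mean-apparent-propagator metrics (PA,
RTAP, RTOP, RTPP, NG) at 912, each 48 white-matter ROIs. Skew directions
follow what such cohorts show: FA/PA/NG negative, MD/RD/RTAP/RTOP/RTPP
positive, AD approximately symmetric. Families are skew-normal with slant
±6 (sample skewness ≈ ±0.85 — strong enough that the Z-score imbalance is
obvious at these sample sizes) and Gaussian for AD; per-ROI locations and
scales are drawn once per ROI from metric-specific ranges set at
literature-plausible magnitudes (e.g. MD ≈ 0.65–0.9 × 10⁻³ mm²/s,
FA ≈ 0.35–0.65). Only the skew directions are empirically anchored; no
numeric fidelity to any real cohort's per-ROI means or variances is
claimed, and none is needed — the audited tail counts are
distribution-free by construction. What the generator does **not**
emulate: inter-ROI and inter-metric correlation, site/protocol effects,
age structure, measurement noise floors, or outliers from pathology. Tests
passing on these cohorts therefore demonstrate the score's distributional
mechanics, not performance on any particular real dataset.

Columns are tie-free with probability one (continuous families); the
generator asserts per-column distinctness and redraws on the measure-zero
collision event. `positive_support` guarantees strictly positive values
(log-transformable) via a positive shift of any offending column — an
affine change that alters neither skew direction nor any score. An
optional free-water-contamination mode mixes in a small fraction of
participants with inflated MD/RD and deflated FA (isotropic fast
diffusion), exaggerating the natural skew directions; off by default,
for demonstration.

## Numerical and design choices

* Edge estimator: linear interpolation between closest order statistics —
  chosen because it pins the strictly-beyond-edge counts exactly (above);
  other quantile conventions (nearest-rank, Hazen, …) shift counts by ±1.
* Determinism: all randomness flows through numpy `Generator`s seeded via
  `SeedSequence`; per-metric generator streams are keyed with a CRC-32 of
  the metric name so they are process-independent.
* Score CSVs are written at 17 significant digits and read back with
  round-trip float parsing, so file round trips are bit-exact; rounding
  is presentation-layer only.
* Heatmap bins: cut points 0, ±1, ±1.65, ±2, ±2.5, ±3, ±∞, right-closed
  on the positive side (1.65 falls in `(1, 1.65]`) and mirrored below
  zero; edges and palette are configurable — the defaults beyond ±1.65
  are this package's choice.
* Estimator shape: scoring is a fit/transform operation (learn reference
  medians/edges, score new individuals), so the scorers are scikit-learn
  transformers and compose with pipelines; `*_table` functions wrap them
  to preserve participant/ROI labels.
* `score_individual(..., leave_self_in=False)` gives a leave-one-out
  score for reference members; the default includes the member, matching
  the full-table scoring.
* Input validation: N ≥ 3 is a hard floor; N < 20 logs a warning because
  5th/95th edges from so few points carry large uncertainty (percentile
  resolution is 100/N %).

## Problem sizes used in tests and the acceptance script

The acceptance script scores full 960 × 48 and 912 × 48 cohorts (a few
hundred milliseconds each), runs the 20-iteration size-100 subsampling
audit, and evaluates edge anchoring on a 501-point column; the test suite
uses the same full-size tables where exact counts are asserted and
smaller tables (≤ 10⁴ cells) for structural and property tests, with two
100 000-point draws for the Gaussian-limit and skewness checks. The
entire suite runs in well under a minute on one CPU.

## Known limitations

* Percentile edges from small references are noisy even though the tail
  *counts* stay balanced: the score of a given individual can vary
  considerably across references of n ≈ 50–100.
* The 5th/95th anchoring is a choice; more extreme edges would be noisier
  still. An area-based (CDF-integral) variant would avoid point anchoring
  but is out of scope here.
* Real cohorts contain ties (quantized pipelines, rounded exports); ties
  break the exact-count guarantee in proportion to their number. The
  audit still runs; only the by-construction exactness is lost.
* Scores beyond the edges extrapolate linearly in percentile-edge units;
  a |P| of 4 should be read as "far out in the tail", not as a calibrated
  normal quantile.
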