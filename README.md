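# pscore

Percentile-based deviation scores for assessing individuals against
**skewed** normative distributions of ROI-summarized quantitative MRI
metrics (or any participants × regions table of continuous measurements).

## The problem

Normative comparison usually means a Z score,
`Z = (x - mean) / SD`, which implicitly assumes the reference
distribution is Gaussian. ROI-averaged diffusion-MRI metrics are
systematically skewed — anisotropy measures (FA, PA, NG) to the left,
diffusivity and propagator measures (MD, RD, RTAP, RTOP, RTPP) to the
right — so Z scores place the wrong share of perfectly healthy people
beyond the nominal 5th/95th percentile boundaries (±1.645). A clinician
flagging |Z| > 1.645 then over-calls one tail and under-calls the other.

## The Pscore

For participant *i* and ROI *j* with normative column median *m_j* and
linearly interpolated percentile edges *x_j5*, *x_j95*:

```
d_ij = x_ij - m_j
P_ij = -1.645 · (m_j - x_ij) / (m_j - x_j5)     if x_ij < m_j
P_ij = +1.645 · (x_ij - m_j) / (x_j95 - m_j)    if x_ij > m_j
P_ij = 0                                        if x_ij = m_j
```

Each tail is normalized by its own median-to-edge distance, so a value at
the 95th-percentile edge scores exactly +1.645 regardless of the shape of
the distribution. On a tie-free normative cohort this forces exactly 5%
of scores beyond each ±1.645 boundary and a 50/50 positive/negative
split — by construction, for any continuous distribution and any sample
size, including small ones (n ≈ 100).

## Worked example

```python
import numpy as np
from pscore import (MetricSpec, generate_metric_table, pscore_table,
                    audit_table, score_individual)

# tie-free negatively skewed cohort: 960 participants × 48 ROIs
spec = MetricSpec("FA", "skew_normal", "negative", -6.0, (0.35, 0.65), (0.02, 0.05))
cohort = generate_metric_table(spec, 960, 48, seed=42)

for method in ("zscore", "pscore"):
    r = audit_table(cohort, method)
    print(f"{method}: {r.nev_gt95} > +1.645, {r.nev_lt5} < -1.645 of {r.n_total}"
          f"  ({r.pev_gt95:.1f}% / {r.pev_lt5:.1f}%)")

# score a new individual sitting at every ROI's 95th-percentile edge
edges = np.percentile(cohort.values, 95, axis=0)
print(score_individual(edges, cohort, method="pscore").iloc[:2].round(3).tolist())
```

prints

```
zscore: 228 > +1.645, 3271 < -1.645 of 46080  (0.5% / 7.1%)
pscore: 2304 > +1.645, 2304 < -1.645 of 46080  (5.0% / 5.0%)
[1.645, 1.645]
```

The Z scores of this left-skewed cohort flag 7.1% of healthy values as
extreme-low but only 0.5% as extreme-high; the Pscores restore the exact
5%/5% balance (2304 = 48 × 48 ROIs), and an individual on the
95th-percentile edge scores exactly +1.645 in every ROI.

The scorers are scikit-learn transformers, so a reference can be fitted
once and reused:

```python
from pscore import PscoreScaler
scaler = PscoreScaler().fit(cohort.data)   # learns medians and edges
scores = scaler.transform(new_individuals) # scores against the reference
```

## Command line

```bash
pscore simulate --preset hcp-like --seed 7 -o synthetic/   # 9 metric CSVs
pscore score synthetic/FA.csv -o scores/                   # P/Z score CSVs
pscore audit synthetic/*.csv -o imbalance.csv              # tail-imbalance table
pscore bootstrap synthetic/PA.csv --size 100 --iterations 20 --seed 11 -o bs/
pscore report synthetic/FA.csv --roi WM-ROI-01 -o figures/ # panels + heatmap
```

Every run writes a JSON manifest (config, seeds, input checksums) so any
output is re-derivable from the manifest alone.

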