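# seqdta

Exact group sequential interim monitoring for diagnostic test accuracy (DTA)
studies.

Prospective DTA studies compare an index test against a reference standard
and report two co-primary proportions: sensitivity (the true positive rate)
and specificity (the true negative rate). When early evidence shows a test
cannot reach a clinically useful accuracy — a regulator's target product
profile, say — stopping the study for futility saves participants, money and
time. `seqdta` implements an adaptation of the exact group sequential method
for this setting: planning stagewise stopping boundaries, evaluating accrued
2×2 data at each interim look, computing exact operating characteristics,
and estimating them by simulation. It is aimed at trial statisticians
planning or running single-cohort DTA studies with a small number of
pre-specified interim analyses.

## The method

Group sequential methods for one binomial proportion assume the monitored
proportion is below 0.5, so each accuracy endpoint is monitored through its
complement: the false-negative rate *p* = 1 − sensitivity (over
disease-positive participants) or the false-positive rate 1 − specificity
(over disease-negatives). With *p₀* the minimally acceptable accuracy and
*p_t = 1 − p₀* the threshold error rate, the hypotheses per endpoint are

    H₀: p ≤ p_t     vs.     H₁: p > p_t

and rejecting H₀ stops the study for futility. At an analysis with
cumulative endpoint-group size *n_g*, the futility boundary is the smallest
failure count that rejects,

    r_g = ⌊ n_g·p_t + 0.5 + z₁₋α · √( n_G·p_t(1−p_t) ) ⌋ + 1,

anchored to the planned final group size *n_G*, so interim looks demand
stronger evidence than the final one. On the accuracy scale the boundary is
1 − r_g/n_g: stop when the estimated sensitivity (or specificity) is at or
below it; when r_g > n_g stopping is impossible and the boundary prints as a
dash. Interim analyses may be scheduled by total participants recruited or
by disease-positive cases observed; an assumed prevalence converts between
the two and sets the anchors. By default the study stops when **either**
endpoint crosses its futility boundary; early stopping for efficacy
(rarely appropriate in DTA studies) is available but requires both
endpoints and explicit configuration. Because the anchored construction is
approximate, the package also computes the *exact* stagewise stopping
probabilities, type I error and expected sample size by forward recursion
over the binomial failure-count process.

## Worked example

A planned 200-participant study at an assumed prevalence of 35% (70
expected positives, 130 negatives), requiring sensitivity ≥ 75% and
specificity ≥ 90% at one-sided α = 0.05 per endpoint, with interim looks
after 15, 25 and 50 disease-positive cases:

```python
import seqdta as sq
from seqdta.datasets import example_cohort, simulated_design

design = simulated_design("by_positives")
results = sq.monitor(design, example_cohort(1))
print(sq.render_text(sq.report_table(results)))
```

```
N (N_pos) Sensitivity (boundary) Specificity (boundary)     Sens decision     Spec decision          Decision
  46 (15)              67% (27%)              81% (68%)          Continue          Continue          Continue
  63 (25)              60% (48%)              84% (74%)          Continue          Continue          Continue
 128 (50)              56% (62%)              82% (82%) Stop for futility Stop for futility Stop for futility
```

Each row is one reached analysis: the 15th positive case arrived with the
46th participant, where the estimated sensitivity 67% sat above its 27%
boundary and the study continued. At the third look both estimates are at
or below their boundaries — specificity exactly on it, 82% vs 82%, which
stops (decisions are made on integer failure counts, so an estimate equal
to its boundary always stops) — and the study terminates for futility.

The exact operating characteristics of the sensitivity endpoint:

```python
ep = design.sens_endpoint
bs = sq.boundary_set(ep)
sq.exact_type_I_error(bs, ep)           # 0.0613
sq.expected_sample_size(bs, ep.p_t)     # 69.3 positives
sq.expected_sample_size(bs, 0.40)       # 52.7 positives
```

The anchored construction runs slightly above the nominal 0.05 here
(exactly 0.0613); a test with a true FNR of 0.40 would on average need only
52.7 instead of 70 positive cases before the study stops.

The same operations are available from a shell. A design document is a
small YAML file:

```yaml
prevalence: 0.35
schedule: by_positives     # or by_total
interim_points: [15, 25, 50]
target: 70                 # positives (by_positives) or participants (by_total)
alpha: 0.05
sensitivity_p0: 0.75
specificity_p0: 0.90
futility_rule: either
```

```sh
seqdta design --config design.yaml                    # boundary tables + exact OCs
seqdta monitor --config design.yaml --data accrual.csv  # exit 3 when a boundary is crossed
seqdta simulate --config design.yaml --sensitivity 0.65 --specificity 0.85 \
    --replicates 10000 --seed 1
```

`accrual.csv` has columns `order,reference,index` (0/1 coded, recruitment
order), plus an optional `day` column when results become available in
batches — in that case analyses happen at the first batch boundary at or
past each milestone, so looks can overshoot their scheduled points.

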