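# Methods

## Model and monitoring procedure

A single-cohort DTA study recruits participants sequentially; each receives
the index test and a reference standard assumed to reveal true disease
status. The data at any accrual point form a 2×2 table (TP, FN, TN, FP).
Sensitivity and specificity are monitored as co-primary endpoints through
their complementary error rates — the false-negative rate over the
disease-positive group and the false-positive rate over the disease-negative
group — because the exact group sequential construction assumes the
monitored proportion is below 0.5. Each endpoint tests

    H0: p <= p_t    against    H1: p > p_t,    p_t = 1 - p0,

one-sided at level `alpha`, where `p0` is the minimally acceptable accuracy.
Rejection at any analysis stops the study for futility.

**Boundary construction.** At an analysis with cumulative endpoint-group
size `n_g`, the futility count is

    r_g = floor( n_g * p_t + 0.5 + z_{1-alpha} * sqrt( n_G * p_t * (1 - p_t) ) ) + 1,

a Fleming-type construction in which the normal-deviate term is evaluated
at the planned final group size `n_G` (the *anchor*) rather than at `n_g`.
Anchoring makes interim boundaries uniformly more demanding than the final
one: on the accuracy scale, every defined interim boundary `1 - r_g/n_g`
lies strictly below `p0`, and the final boundary is the closest to it.
When `r_g > n_g` no outcome can stop at that stage; such boundaries are
reported as dashes. The construction is approximate: the attained type I
error is near, not exactly at, the nominal level (0.0613 at nominal 0.05
for the 15/25/50/70 worked-example plan), which is why the exact recursion
below is exposed for verification instead of re-solving boundaries to hit
`alpha` exactly.

**Exact operating characteristics.** The cumulative failure count across
stages is a sum of independent binomial increments. `stagewise_probabilities`
propagates its distribution stage by stage: convolve the surviving mass with
the binomial probability mass of the incremental group, harvest the mass at
or beyond `r_g` (and at or below the efficacy count, when enabled) as the
stopping probability, and continue with the remainder. This yields exact
stagewise stopping probabilities, the exact type I error (the futility-stop
probability at `p = p_t`, the supremum over H0 by monotonicity in `p`), and
the expected terminal group size. The recursion is validated against an
independent oracle that exhaustively enumerates every ordered Bernoulli
outcome sequence for designs with final group sizes up to 12.

**Bivariate combination.** The two endpoints are monitored independently at
the same participant cuts, each at its own one-sided `alpha` with no
cross-endpoint multiplicity adjustment. The default study-level rule stops
for futility when *either* endpoint crosses (a test must usually meet both
accuracy requirements to be useful, so failing one suffices); a *both* rule
is available. Early stopping for efficacy — disabled by default, as it is
rarely appropriate in a DTA study — always requires both endpoints.

**Scheduling and overshoot.** Interim points are defined either by total
participants (`by_total`) or by observed disease-positive cases
(`by_positives`). An analysis uses all data available when its milestone is
first crossed; when records carry a `day` batch column, the cut falls at the
first batch boundary at or past the milestone, so the analysed group can
overshoot the milestone (e.g. 52 cases at a 50-case look). Boundaries are
always computed at the *observed* group sizes while staying anchored to the
*planned* final sizes, including when observed accrual overshoots the plan
itself. Decisions compare integer failure counts (`failures >= r_g`),
which is equivalent to comparing the accuracy estimate with the boundary
with equality stopping; rounded percentages are display artifacts and never
enter decisions. An endpoint with no accrued participants is not evaluable
and never contributes to stopping. After a stop, later scheduled analyses
are not evaluated.

## Parameters that matter

| parameter | meaning | default / convention |
| --- | --- | --- |
| `p0` (per endpoint) | minimally acceptable sensitivity or specificity | none — study-specific, e.g. a target product profile |
| `alpha` | one-sided type I error per endpoint | 0.05, no multiplicity adjustment across endpoints |
| `prevalence` | assumed disease prevalence | links participant targets to endpoint-group anchors; treated as the exact decimal written |
| interim points | scheduled looks | at most 5 analyses recommended (warning beyond); first look late enough for estimates to be meaningful |
| `futility_rule` | either / both | `either` |
| efficacy (`p_a`, `beta`) | acceptance boundary parameters | disabled; mirrored construction `a_g = ceil(n_g*p_a - 0.5 - z_{1-beta}*sqrt(n_G*p_a*(1-p_a))) - 1`, final stage forced to `r_G - 1` so the last analysis always terminates |

Sample-size re-estimation (`reestimate_target`) preserves the originally
required number of positives under a prevalence observed mid-study:
`by_total` targets become `ceil(required_positives / observed_prevalence)`
(computed over exact rationals so re-estimating at the assumed prevalence is
the identity); `by_positives` targets are already the requirement, so only
the prevalence — hence the negatives anchor and the expected total
recruitment — changes.

## Synthetic data

`simulate_cohort` draws participants in recruitment order: disease status
Bernoulli(prevalence), then the index result Bernoulli(sensitivity) for
positives and Bernoulli(1 − specificity) for negatives. The default worked
scenario is prevalence 35%, sensitivity 65%, specificity 85% with a
200-participant plan. `simulate_oc` replays the full monitoring schedule
over independent replicate cohorts (vectorised across replicates; every
milestone is evaluated at its exact crossing, since per-day batching is a
property of real data flow, not of the generator). All randomness flows
from one root seed through a single numpy `Generator` consumed in fixed
chunked order, so results are bit-reproducible for a given version.

What the generator does **not** emulate: imperfect or delayed reference
standards, accuracy drifting with covariates or time, batched data
availability, missing results and non-evaluable samples, or correlation
between multiple index tests. Tests passing on these cohorts therefore
demonstrate the correctness of the boundary arithmetic and decision logic
under the idealised single-gate Bernoulli model, not robustness of the
design to those real-world features.

The shipped example cohorts (`datasets.example_cohort`) are deterministic
reconstructions: they reproduce the per-stage marginal counts (total N,
positives, TP, TN at every analysis cut of both schedules) of two reference
realisations of the scenario above, with a fixed within-segment record
order (negatives before positives, so positive-count milestones are crossed
exactly at their checkpoints). Interim decisions and boundaries depend only
on these counts, not on the record-by-record draw. The case-study cohorts
(`datasets.raptor_cohort`) are likewise synthetic reconstructions: the
positive-group counts follow the published interim sensitivities of the two
point-of-care SARS-CoV-2 tests, while the negative-group sizes are chosen
to be consistent with the published specificity estimates and boundaries
(the underlying raw negative counts are not in the main published record).

## Numerical choices

- Binomial masses come from `scipy.stats.binom.pmf`; the recursion carries a
  dense probability vector over failure counts, conserving total mass to
  1e-12 (asserted in tests over a grid of true error rates).
- Boundary counts use IEEE floor on `n*p_t + 0.5 + deviate`; the deviate is
  irrational for all practical designs, so the floor is stable. Accuracy
  boundaries are stored as exact `Fraction`s.
- Display rounding is half-to-even, computed exactly over rationals (e.g. a
  boundary of 12.5% prints as 12%, an estimate of 87.5% as 88%), with 0 or
  1 decimal places selectable. Planning projections (expected group sizes
  from prevalence) round half away from zero.
- `p_t >= 0.5` and more than five analyses violate method assumptions but
  are soft failures: construction proceeds with a warning.
- Degenerate inputs: empty accrual yields no analyses; an endpoint with a
  zero denominator is not evaluable; a single-stage design reduces to the
  one-sample critical value; `p = 0` and `p = 1` are handled exactly.

## Problem sizes used in the checked examples

Oracle-equivalence checks enumerate all `2^n_G` outcome paths for designs
with `n_G <= 12` and up to three analyses. The exact-vs-Monte-Carlo
agreement check uses 50,000 replicate cohorts of 300 participants (a size
at which the 70-positive final milestone is reached with probability
~1 − 10⁻⁵, so censored replicates are negligible) and a 3-standard-error
band. Simulator fidelity is checked on one cohort of 100,000 participants.

## Known limitations

- The attained type I error of the anchored construction deviates from the
  nominal level, especially with many looks or small anchors; check it with
  `exact_type_I_error` before fixing a design.
- Interim estimates from studies stopped early are biased; no
  bias-corrected terminal estimates or confidence intervals are provided.
- The two endpoints are treated marginally; no joint (bivariate) error-rate
  control, no alpha-spending for continuous monitoring, no imperfect
  reference-standard adjustment, no multi-test drop-the-loser designs.
- The efficacy construction mirrors the futility one by symmetry and is
  validated only against the enumeration oracle, not against any published
  worked example.
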