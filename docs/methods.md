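# Methods

`accelcal` re-implements, as a tested pipeline, a cut-point calibration
study for wrist-worn accelerometers in preschool-aged children: epochs
of hip-worn vector-magnitude (VM) counts are labeled with a published
hip reference, three procedures derive wrist cut points from the paired
wrist counts, and the derived sets are evaluated against the hip
reference at the epoch level and as daily activity estimates.

## The classification model

Physical-activity intensity is a four-level ordinal scale — sedentary
behavior (SB), light (LPA), moderate (MPA) and vigorous (VPA) activity;
MVPA = MPA ∪ VPA.  A cut-point set is three ordered integer thresholds
(t₁, t₂, t₃) on the counts-per-minute (cpm) axis defining the partition
[0, t₁], [t₁+1, t₂], [t₂+1, t₃], [t₃+1, ∞).  Cut points live on the
integer cpm grid because published sets print adjacent bounds that
differ by exactly 1 cpm.  The shipped hip reference is the Butte
preschool set (820 / 3908 / 6112).  Its published VPA description
("greater than 6113") conflicts with the MPA upper bound 6112 by one
count; we take VPA = ≥ 6113 cpm so that classification is total and
gapless.  A partial wrist reference (Johansson) ships with only its
MVPA floor (16 716 cpm) fixed; its SB bound must be supplied by the
user, and the pipeline then classifies on the 3-level SB/LPA/MVPA
scale for that column only.

## Preprocessing

* **Vector magnitude.**  VM = √(x² + y² + z²) per epoch, rounded
  half-up to an integer (device exports are integral; the rule is
  stated so it is testable).
* **Re-integration.**  Coarser epochs are sums of constituent epochs; a
  trailing partial window is dropped with a warning.  The default
  analysis grid is 15-s epochs converted to cpm by ×4 — the only grid
  that reproduces the study-scale epoch totals (1200 epochs per 5-h
  day); a 60-s grid is a config switch.
* **Non-wear.**  The Choi zero-run rule on a 60-s grid derived from the
  data: ≥ 90 consecutive zero-count minutes, allowing embedded nonzero
  interruptions of ≤ 2 min when flanked by ≥ 30 zero minutes on both
  sides (the canonical parameterization; the interruption minutes count
  as non-wear).  The minute mask is expanded back to the source grid.
* **Alignment.**  Hip and wrist series of one participant-day are
  matched on epoch index within the day; only epochs worn on both
  placements enter the analysis.
* **Exclusion.**  A day is invalid when it contributes no matched worn
  epochs.  A participant is excluded when every enrolled day is invalid
  or when invalid days form a run longer than three days.  The source
  protocol's stated rule ("missing … for more than 3 consecutive 5-hour
  days") cannot literally trigger in a 3-day collection; this reading
  preserves its intent (drop participants without usable data) while
  remaining well defined for longer protocols.

## The three calibrators

**ROC threshold search.**  The ordinal scale is split into its three
cumulative dichotomies — SB vs above, (SB ∪ LPA) vs above, everything
vs VPA — and each is scanned over the observed unique wrist cpm values
with the predicate cpm > t ("positive" = the higher-intensity side, so
sensitivity is the detection rate of activity above the boundary).  The
selected threshold minimizes |sensitivity − specificity|, with ties
broken toward the smallest t (and a 10⁻¹² float tolerance so that
rationally equal differences at different thresholds tie).  The scan
over observed values is exact: both rates are piecewise constant
between observed values.  Thresholds are fitted independently and can
cross on pathological data; crossing raises an error naming all three.

**Cumulative-logit (proportional-odds) regression.**  P(Y ≤ k | x) =
σ(αₖ − βx) with three increasing intercepts and one slope on wrist cpm.
The fit is maximum likelihood on the explicit log-likelihood (analytic
gradient, L-BFGS-B, thresholds parameterized as a base plus
log-increments to enforce ordering, predictor standardized internally).
A small ridge λβ² (default λ = 10⁻⁶ on the standardized slope) keeps
the optimum finite on quasi-separable data, where the unpenalized MLE
diverges.  Each epoch is assigned its argmax-probability class — with a
single positive-slope predictor the argmax classes form contiguous cpm
intervals — and cut points follow the max/min rule: t₁ = max cpm
assigned SB, t₂ = min cpm assigned MPA − 1, t₃ = min cpm assigned
VPA − 1.  A class with no argmax assignments raises an explicit
"empty predicted class" error rather than producing a degenerate set.

**Univariate k-means (k = 4).**  k is fixed a priori (four intensity
states).  The default solver is an exact dynamic program over the
sorted unique values (weighted by multiplicity, divide-and-conquer
minimization, O(k·u·log u)): deterministic, seed-free, globally optimal
within-cluster sum of squares, and equal values always share a cluster.
Lloyd iterations (scikit-learn k-means++ with 10 seeded restarts) are
available as an option and can only match or exceed the DP's WCSS.
Cluster upper bounds, in centroid order, become the cut points —
the max-within-category rule, so when an optimal boundary falls in a
gap between observed values the reported bound is the largest observed
value of the lower cluster.

## Agreement and daily estimates

Confusion matrices use reference labels as rows.  Per class we report
one-vs-rest sensitivity, specificity, FPR = 100 − specificity, FNR =
100 − sensitivity, and a Cohen kappa computed on the one-vs-rest
binarized labelings (the only construction that yields one kappa per
class); overall blocks report correct-classification % (trace/total)
and multiclass kappa, both on the 4-level scale and with MPA and VPA
merged.  Undefined ratios (0/0) are reported as explicit `undefined`
markers (NaN in machine output), never silently as 0 or 100.

Daily estimates are minutes per intensity level per participant-day
(epochs × epoch length), summarized per method as mean (sample SD)
across participant-days; the percent column divides by mean *wear*
minutes, not the scheduled day length, since worn time is the
denominator that makes the shares a partition.  Method-vs-reference
differences use a paired percentile bootstrap over participant-days
(2000 resamples, seeded); "no difference" means the 95% interval covers
zero.  An analysis-of-covariance comparison was deliberately not
implemented: no covariate specification is available, so the paired
bootstrap is the package's reproducible substitute.

## The synthetic-data generator

No public dataset pairs hip and wrist epoch counts for this design, so
the generator produces data with exactly the structure the analysis
assumes:

* **States.**  A sticky 4-state Markov chain at 15-s resolution,
  P = ρI + (1−ρ)·1πᵀ, whose stationary distribution is π by
  construction.  Defaults: π = (64.2, 28.0, 5.5, 2.3)% — the observed
  preschool-day occupancy — and ρ = 0.9, i.e. mean bout length
  1/(1−ρ) = 10 epochs (2.5 min), emulating short-burst preschool
  activity.
* **Hip counts.**  Per-state lognormal cpm draws, integerized to
  per-epoch counts: SB lognormal(median 120 cpm, σ 0.85) with a 25%
  point mass at zero; LPA (1790, 0.30); MPA (4900, 0.11); VPA
  (9500, 0.15).  Medians sit at the geometric centers of the Butte
  intervals; spreads were chosen once so that (i) Butte labeling of
  hip counts agrees with the generating state on ≈ 99% of epochs and
  (ii) the hip-*labeled* class shares stay centered on the occupancy
  targets (boundary leakage shifts shares by < 0.5 points).
* **Wrist linkage.**  wrist = round(g(hip) · e^ε), with g(x) = 3.2x by
  default (published wrist SB bounds sit near 3× their hip analogues;
  any strictly increasing g is accepted) and ε ~ N(0, σ²), σ = 0.2 —
  multiplicative device noise with unit median.  With σ = 0 the linkage
  is exactly round(3.2 · hip).
* **Pure mode.**  For noise-free recovery checks, each state's counts
  are clipped strictly *inside* its Butte interval, shrunk toward the
  interval center by 25% per side (SB keeps its zero floor; VPA is
  capped at 3× its lower bound).  The shrinkage leaves genuine gaps
  between class supports; without it, clipped mass piles up at interval
  edges, adjacent classes touch, and no unsupervised method could be
  expected to find the boundaries.
* **Non-wear.**  Per participant-day, with probability 0.05, one
  whole-minute-aligned zero block of 90–180 min on both placements
  (removal events in this design take both devices off together), its
  location logged as ground truth for the detector.
* **Scale.**  34 participants × 3 days × 300 min of 15-s epochs =
  122 400 scheduled epochs (the study scale; its printed one-epoch
  deficit, 122 399, is a data artifact the simulator does not imitate).

All randomness flows from one master seed through named substreams
(CRC-keyed `SeedSequence` children), so stages are independently
reproducible and identical configs give byte-identical output.

**What the generator does not emulate:** device-axis raw signals and
orientation, dominant/nondominant wrist effects, day-of-week and
weather effects, autocorrelated count noise within bouts, the real
study's much weaker hip–wrist coupling (its epoch-level agreement was
~60–72%; the synthetic linkage is far cleaner), and behavioral
non-compliance beyond the all-or-nothing device-refusal used for the
recruitment-funnel replica.  Passing recovery tests therefore show the
*procedures* are implemented correctly and behave as designed under
known structure — not that wrist cut points transfer to real children.

## Numerical choices

* Rounding is half-up everywhere a printed table or integer export is
  imitated (VM, percentages, count integerization); `numpy`'s default
  half-to-even is never relied on for reported values.
* ROC ties: smallest qualifying threshold, 1e-12 comparison tolerance.
* Cumulative-logit: predictor standardized; convergence accepted on
  gradient tolerance or iteration cap (quasi-separable fits plateau at
  large finite slopes; the induced integer cut points are stable long
  before).  Statsmodels' `OrderedModel` is used in the test suite as an
  independent oracle for the same likelihood, never in the pipeline.
* k-means DP compares costs with a 1e-12 guard so equal-cost splits
  resolve toward the smaller index deterministically.
* Empty classes, single-member classes and 0/0 rates are flagged
  (n = 0 rows, NaN SD, `undefined` markers) rather than raised, except
  where a downstream contract would be violated (calibration requires
  all four supervised classes; OLR requires four nonempty predicted
  classes).

## Problem sizes

Default verification sizes were chosen to keep the full suite fast
while leaving estimator noise well below the tolerances they are
checked against: recovery checks use 50 000 epochs, occupancy checks
use one study-scale replicate (122 400 epochs), detector checks use 100
simulated days, and oracle-equivalence checks use 100–200 randomized
trials each.

## Known limitations

* The Johansson column cannot be validated beyond its MVPA floor
  without the user supplying that calibration's SB bound.
* The exclusion rule's literal reading is undefined for 3-day
  protocols (see above); longer-protocol behavior follows the stated
  run-length rule.
* `compare_methods` bootstraps participant-days as exchangeable units;
  it does not model within-participant clustering.
* The cumulative-logit calibrator inherits the proportional-odds
  assumption; on data violating it (e.g. heavily imbalanced real
  classes) its argmax classes can empty out, which the pipeline
  surfaces as an error rather than repairing.
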