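# Methods

## Scope and model

`curveval` evaluates a binary classifier that assigns each instance a
real-valued score, higher meaning "more likely positive". The decision
rule at threshold *t* is `score >= t -> predicted positive`; sweeping *t*
from above the maximum score (everything negative) down past the minimum
(everything positive) yields one confusion matrix per distinct score
value, bracketed by the two trivial classifiers. Every curve family is a
deterministic function of that sweep, so the sweep — with its tie and
missing-score policies — is the single source of truth.

## Tie handling

A block of instances sharing one score has no internal ordering, so the
sweep cannot pass through its interior unambiguously. Three policies are
offered:

- `upper`: the block's positives are counted before any of its negatives
  (the optimistic corner),
- `lower`: negatives first (pessimistic),
- `average` (default): only the block's end point is emitted, so curves
  traverse the block along the straight chord.

`average` is the default because it matches the pair-counting
(Mann–Whitney) convention of weighting tied positive–negative pairs by
one half; the suite verifies that the average-policy trapezoidal AUC
equals brute-force pair counting exactly, and that for a single tie block
it is the arithmetic mean of the upper and lower AUCs. Ranking is stable:
tied scores keep their order of occurrence in the input, lowest score =
rank 1.

## Missing scores

Instances without scores (e.g. removed by a pre-filter) are imputed with
one shared default value, fixed at `min(observed) − 1`. Any value
strictly below the observed minimum is equivalent — the sweep only sees
the rank structure — so the constant is chosen for reproducibility, not
tuned. The imputed instances form a terminal tie block; under the average
policy the ROC curve therefore continues linearly from the last scored
point to (1, 1), which is the intended semantics of "default values for
the unscored tail".

## Degenerate measures

Precision at a threshold with no positive predictions is undefined and is
reported as missing (`None`), never silently 0 or 1: fabricating a value
at the extreme threshold would invent performance that was never
measured. MCC with a zero factor in its denominator is reported as 0, the
conventional limit. F-beta with precision = recall = 0 is defined as 0.
The F-beta numerator uses the standard coefficient (1 + β²). A confusion
matrix with an empty class raises unless partial measures are explicitly
requested.

## PR interpolation and AUC(PRC)

Between supports A = (TP_A, FP_A) and B = (TP_B, FP_B) the interpolation
variable x ∈ [0, TP_B − TP_A] counts *added* true positives; false
positives accrue at the segment's local skew (FP_B − FP_A)/(TP_B − TP_A),
giving

    precision(x) = (TP_A + x) / (TP_A + x + FP_A + skew · x).

Both endpoints reproduce A and B exactly, and at every integer x the
formula equals TP/(TP+FP) computed directly from the interpolated counts
(asserted in the suite). Segments with constant TP are vertical in PR
space — a precision drop at fixed recall — and are connected without
interpolation.

AUC(PRC) densifies each segment at `steps_per_tp` sub-steps per unit true
positive (default 1, the natural resolution of count interpolation) and
applies trapezoids on the densified points. Precision at recall 0 is not
observable; the curve is anchored at (0, p₁), where p₁ is the x → 0 limit
of the first segment out of the origin support — the precision of the
first positive-yielding threshold, or 0 when the top of the ranking is
pure false positives. This anchor choice only affects the first 1/P of
the recall axis.

The PRC baseline is y = P/(P+N); the suite checks that the AUC(PRC) of
random scores at 1000/10000 lands within 0.008 of it — three Monte-Carlo
standard deviations, the spread measured over 30 independent draws at
that design.

## CROC

The exponential magnifier f(x) = (1 − e^(−αx))/(1 − e^(−α)) fixes the
endpoints and expands small FPRs. The default strength is α = 7, under
which f(0.5) ≈ 0.971 and f(0.16) ≈ 0.67 — i.e. two thirds of the
transformed axis show the first 16 % of false-positive rates. Straight
ROC segments map to curved arcs, so each segment is densified (100
interior points by default; 20 in the simulator, where segments are
already short) before transformation, and the AUC is the trapezoidal area
over the transformed x. The transformed diagonal matches direct numeric
quadrature of 1 − ∫f to 1e-6 in the suite.

## Cost curves

Operating conditions combine priors and misclassification costs into
PCF(+) = p(+)C(−|+) / (p(+)C(−|+) + p(−)C(+|−)); each threshold is the
line NE[C] = FNR·PCF + FPR·(1 − PCF), and the classifier's curve is the
lower envelope of its lines over a uniform PCF grid (default 1000
points). The sweep's trivial end elements contribute the lines PCF and
1 − PCF, so the envelope never exceeds min(PCF, 1 − PCF); being a lower
envelope of lines it is concave, which the suite asserts via second
differences. This is the standard normalized-expected-cost formulation;
with equal costs and priors the value at PCF = 0.5 is half the minimum of
FPR + FNR, the best balanced error rate.

## Simulator

Score distributions per performance level:

| level | positives | negatives | expected AUC(ROC) |
|-------|-----------|-----------|-------------------|
| Rand  | N(0, 1)   | N(0, 1)   | 0.5 |
| ER−   | Beta(4, 1)| Beta(1, 1)| E[Beta(4,1)] = 0.8 |
| ER+   | Beta(1, 1)| Beta(1, 4)| 1 − E[Beta(1,4)] = 0.8 |
| Excel | N(3, 1)   | N(0, 1)   | Φ(3/√2) ≈ 0.983 |
| Perf  | 1         | 0         | 1 |

ER− and ER+ share the same AUC by construction but differ in where the
positives concentrate: Beta(4,1) positives against a uniform background
crowd the top *and* carry a long low tail (poor early retrieval), while
uniform positives against Beta(1,4) negatives dominate early. Defaults
are 1000 positives with 1000 (balanced) or 10 000 (imbalanced) negatives
and 1000 iterations.

Aggregation evaluates each iteration's curve on a common grid of 1000
equal-width bins — at bin *centers*, a choice made once since edges vs
centers is underdetermined — using each family's own interpolation
semantics (linear along ROC/CROC polylines, count interpolation for PRC,
the envelope minimum for cost curves), then takes the per-bin median
across iterations; medians rather than means avoid smearing crossing
curves. AUCs are aggregated the same way.

Randomness: one root seed spawns an independent child stream per
iteration (`numpy.random.SeedSequence`), so results are bitwise
reproducible and independent of evaluation order. The test suite runs the
designs at 100 iterations, which already pins the median AUC to ±0.01;
`scripts/acceptance.py` uses the full 1000.

What the simulator emulates — and does not: scores are i.i.d. within
class, so there is no instance correlation, no score miscalibration
drift, no label noise, and no classifier-specific score granularity
(apart from the Perf level's full tie blocks). Passing simulation tests
therefore demonstrates correctness of the evaluation machinery under
clean sampling assumptions, not robustness of any classifier on real
data.

## Numerical choices

- Areas are plain trapezoids (`numpy.trapezoid`) on non-decreasing x;
  unsorted x is rejected, never silently sorted.
- The ROC convex hull is a monotone-chain upper hull with a 1e-12
  cross-product tolerance so exactly collinear rate triples (ratios of
  small integers) are dropped deterministically.
- Curve TSV exports print 17 significant digits, so write → read round
  trips are exact; JSON sidecars use sorted keys for diffability.
- Consecutive duplicate curve points are collapsed keeping the first
  occurrence; cosmetic only, areas unchanged.

## Known limitations

- Binary classification only; no instance weights, no multi-class
  generalizations, no probability calibration.
- No confidence bands on curves or AUCs.
- Partial-area summaries (e.g. early-retrieval-restricted AUC) are not
  provided; CROC covers that use case.
- The recall-0 anchor of the PR curve is a modelling convention (limit of
  the first segment); alternative conventions differ by at most 1/P in
  area.
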