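# curveval

Model-wide evaluation of binary classifiers, with first-class support for
class-imbalanced data.

Single-threshold measures such as accuracy or sensitivity describe a
classifier at one cutoff and can look identical on balanced and heavily
imbalanced datasets even when the practical performance differs wildly.
`curveval` computes the measures that do react to imbalance (precision,
MCC, F-beta) and the four model-wide curve families used to compare
classifiers across all thresholds:

- **ROC** — TPR = TP/P against FPR = FP/N, with explicit tie policies,
  missing-score defaults, trapezoidal AUC and the ROC convex hull;
- **PRC** — precision TP/(TP+FP) against recall TP/P, with the *correct
  non-linear interpolation* between points. Walking from support A to B,
  after `x` additional true positives the precision is

  ```
  y = (TP_A + x) / (TP_A + x + FP_A + (FP_B - FP_A) * x / (TP_B - TP_A))
  ```

  a hyperbolic arc, not a straight line. The PRC baseline is the moving
  line y = P/(P+N): 0.5 for balanced data, ~0.09 at a 1:10 ratio — which
  is exactly why PRC exposes imbalance that ROC hides;
- **CROC** — ROC with the FPR axis expanded near zero through the
  exponential magnifier f(x) = (1 − e^(−αx))/(1 − e^(−α)) (default α = 7)
  for early-retrieval emphasis;
- **cost curves** — each ROC point becomes the line
  NE[C] = FNR·PCF(+) + FPR·(1 − PCF(+)) over operating points
  PCF(+) = p(+)C(−|+)/(p(+)C(−|+) + p(−)C(+|−)); the classifier's curve is
  the lower envelope of its lines.

A built-in simulator draws scores for five canonical performance levels
(Rand, ER−, ER+, Excel, Perf; normal/Beta mixtures down to constants),
repeats the sample → rank → sweep → evaluate cycle, and aggregates curves
across iterations by binned medians.

## Worked example

The classic imbalanced confusion matrix TP=3, FN=2, FP=6, TN=9 (5
positives among 20 instances):

```python
from curveval import ConfusionMatrix, compute_measures

m = compute_measures(ConfusionMatrix(tp=3, fn=2, fp=6, tn=9))
for k, v in m.as_dict().items():
    print(f"{k:5s} {v:.2f}")
```

```
acc   0.60
err   0.40
sn    0.60
sp    0.60
fpr   0.40
prec  0.33
mcc   0.17
f0.5  0.37
f1    0.43
f2    0.52
```

Accuracy, sensitivity and specificity (0.60 each) are identical to the
balanced counterpart (TP=6, FN=4, FP=4, TN=6) — only precision, MCC and
the F-scores reveal that two thirds of the positive predictions are wrong.

Curves from the command line, using the built-in 20-instance worked
example (one mixed tie block, five missing scores):

```sh
curveval fixture worked_example --out wk.tsv
curveval evaluate wk.tsv --curves roc,prc,croc --hull --out out/
cat out/summary.json
```

```json
{
  "croc": {"auc": 0.419803158389926, "params": {"alpha": 7.0, "tie_policy": "average"}},
  "prc":  {"auc": 0.7834249084249083, "baseline": 0.5,
           "params": {"steps_per_tp": 1, "tie_policy": "average"}},
  "roc":  {"auc": 0.8049999999999999, "params": {"tie_policy": "average"}}
}
```

Missing scores were imputed with one shared default below the observed
minimum, so the ROC curve runs straight to (1, 1); the average tie policy
crosses the tie block along its chord (AUC 0.805, convex hull 0.84 in
`out/roc_hull.tsv`); the PRC area 0.783 sits above its 0.5 baseline.

Simulations:

```sh
curveval simulate --level ER- --n-pos 1000 --n-neg 10000 \
    --iters 1000 --seed 42 --out sim/ --plot
```

writes per-family binned-median curve TSVs, a JSON AUC summary and an
optional multi-panel plot.

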