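# fuzzypima

Interpretable fuzzy rule-based classification of two-class clinical tabular
data, built around extreme-example projection and histogram fuzzification.
The package targets datasets shaped like the public Pima Indians diabetes
file (eight non-negative numeric features per patient plus a binary
diabetic/non-diabetic outcome), and is aimed at researchers who need a
classifier whose every decision can be read off a pair of membership
curves rather than a black-box score.

## Method

Let `A0 ∈ R^{n×k}` and `A1 ∈ R^{m×k}` hold the class-0 (healthy) and
class-1 (sick) training records after each feature column is rescaled by
its maximum, `x̂ = x / max(x)`. The pipeline is:

1. **Extreme pair.** Compute the inter-class Euclidean distance matrix
   `d_ij = ‖x_i − y_j‖₂` and take the maximizing pair `(x_p, y_q)` — the
   healthy and sick records that are farthest apart. Ties break row-major.
2. **Projection.** Classifier 1 projects every record onto `x_p`
   (`U_0 = A0·x_pᵀ`, `U_1 = A1·x_pᵀ`); classifier 2 onto `y_q`
   (`V_0`, `V_1`). The similarity is the raw dot product.
3. **Scaling.** Each class vector is rescaled to sum to a constant α
   (default: the class size, so each scaled vector has mean 1):
   `Û_c = α U_c / ΣU_c`. The constant `α/ΣU_c` is stored so test
   projections land on the same axis; the choice of α does not change
   predicted labels when the membership functions are data-derived.
4. **Fuzzification.** Each class's scaled projections are binned into a
   histogram and divided by the modal count, giving a fuzzy set `h_c(z)`
   with height exactly 1 over the projection axis z.
5. **Membership functions.** Either trapezoids placed on configured
   thresholds (defaults `[0.2, 0.4, 0.8]` over `[0, 1.4]` for classifier 1
   and `0.5` for classifier 2) or, in auto mode, trapezoids built on the
   λ-cut `{z : h_c(z) ≥ λ}` of each class histogram (λ = 0.5 by default).
   Per-class trapezoids are aggregated by fuzzy union (pointwise maximum)
   into one healthy aggregate `Ã0` and one sick aggregate `Ã1`.
6. **Decision rule.** For a record with projection t, evaluated at
   `z = t × scale_c` per class:
   `if μ_Ã0(x) ≥ μ_Ã1(x) then "x is healthy" else "x is sick"`.
7. **Evaluation.** Confusion matrix (sick = positive) and accuracy, recall,
   precision and F-measure, rendered as percentages at two decimals.

A seeded synthetic module generates two-cluster tables (truncated
Gaussians) and a 768-row structural stand-in for the Pima file, so the
whole pipeline is testable without any download.

## Worked example

```sh
python examples/metrics_from_published_counts.py
```

prints, from the two classifiers' test-set confusion counts
(TP=113, FN=5, FP=8, TN=242 and TP=106, FN=12, FP=5, TN=245 over
368 predictions):

```
              Performance Measure   Percentage
Classifier 1  Accuracy                  96.47%
              Recall                    95.76%
              Precision                 93.39%
              F-measure                 94.56%
Classifier 2  Accuracy                  95.38%
              Recall                    89.83%
              Precision                 95.50%
              F-measure                 92.58%

Classifier 1 said 'yes' 121 times and 'no' 247 times out of 368 predictions.
```

Accuracy is the fraction of all 368 calls that were correct; recall the
fraction of the 118 true diabetics caught; precision the fraction of "yes"
calls that were right; F-measure their harmonic mean.

`python examples/two_cluster_recovery.py` fits both classifiers end-to-end
on synthetic clusters five standard deviations apart and prints held-out
confusion matrices (≈ 99% accuracy); `python examples/inspect_fuzzy_model.py`
shows the interpretable internals — scales, λ-cut intervals and per-record
membership grades.

## Command line

```sh
fuzzypima simulate --preset pima-like --seed 1 --output data.csv
fuzzypima fit --input data.csv --outdir run/            # paper-default thresholds
fuzzypima fit --input data.csv --outdir run/ --thresholds auto --lambda 0.5
fuzzypima predict --model run/model1.json --input new.csv --output preds.csv
fuzzypima evaluate --models run/ --input run/test.csv
```

`fit` writes `model1.json`/`model2.json` (fully self-describing and
byte-reproducible), a split manifest, the held-out `test.csv` and a fit
report. The default split takes the first 250 healthy and 150 sick rows
for training (deterministic "linear sampling"). If you have the real Pima
CSV, `fuzzypima fit --input pima.csv --outdir run/` runs the same pipeline
on it; exact reproduction of published headline numbers is not promised,
since the original study leaves λ, bin count and membership-function
shapes under-specified.

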