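# Methods

## Model

The classifier is a fuzzy rule-based system over a one-dimensional
projection of the feature space. After max-division normalization
(`x̂_j = x_j / max_i x_ij`, per feature column j), the training data is
partitioned into the healthy matrix `A0` (n×k) and sick matrix `A1` (m×k).
The *extreme pair* `(x_p, y_q)` maximizes the inter-class Euclidean
distance `d_ij = ‖x_i − y_j‖₂`; each of the two classifiers projects all
records onto one extreme example by a raw dot product. (The construction
is often labelled a cosine-amplitude similarity; no division by vector
magnitudes is performed here — the projection is the plain dot product,
which is what makes the downstream scaling constants meaningful.)

Each class's projection vector is rescaled to sum to a constant
(`Û_c = α_c U_c / ΣU_c`); the stored constant `scale_c = α_c / ΣU_c` maps
any later projection t onto the training axis as `z = t · scale_c`. The
scaled projections are binned into a histogram whose heights are divided
by the modal count, yielding a fuzzy set with maximum membership exactly 1.
Membership functions (MFs) are trapezoids with linear shoulders, aggregated
per class by fuzzy union (pointwise maximum, computed exactly on the merged
knot set including crossing points). A record is classified sick only when
its sick membership strictly exceeds its healthy membership; ties —
including records whose projection falls outside both supports, which are
logged as uncovered — go to healthy.

### Assumptions

- Features are non-negative, finite, and bounded (normalization by the
  column maximum is only meaningful then).
- Class structure is expressible along a single projection direction
  anchored at an extreme example. This is a strong assumption; it holds
  for data with a dominant between-class axis and degrades for multi-modal
  or strongly anisotropic classes.
- The training class balance is informative: the default scaling constants
  (class sizes) give each scaled class mean 1, so the two classes are
  discriminated by the *ratio* of their mean raw projections, which sets
  the offset between the two z-axis mappings of one test record.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `SplitSpec` | 250 / 150 | training rows per class, taken first-in-file-order ("linear sampling"); the 500/268 clinical table then leaves a 368-row test set with 118 positives |
| `normalization` | `global` | column maxima fitted on the whole table before splitting (the study's order of operations); `train-only` fits them on training rows only (leakage-safe; test values may then exceed 1 and are clipped with a warning) |
| `threshold_mode` | `paper` | `paper`: trapezoids on configured thresholds — `[0.2, 0.4, 0.8]` over the `[0, 1.4]` axis for classifier 1, `0.5` for classifier 2 (figure-read values published as defaults); `auto`: λ-cut-derived |
| `lam` (λ) | 0.5 | cut level for auto mode, in (0, 1]. 0.5 is the conventional cut and the level at which classifier 2's published threshold sits |
| `bins` | 20 | histogram bins per class, over `[0, max observed]` of that class's scaled projections |
| `shoulder` | one bin width | half-width of the trapezoid shoulders (dimensionless, on the z axis) |
| `alpha0/alpha1/beta0/beta1` | class sizes | scaling constants; any positive value gives identical predictions in auto mode |
| `segment_assignment_c1/_c2` | alternation | paper-mode mapping of axis segments to classes, starting from the class with the lower median scaled projection; an explicit 0/1 list overrides it |

Thresholds in paper mode split the axis into consecutive segments, one
trapezoid each; the published account derives three sick and two healthy
MFs from three thresholds without stating the assignment, so the
assignment is configuration, not inference — only the per-class unions
matter to the decision rule.

## Numerical choices

- Extreme-pair ties break row-major (smallest p, then smallest q), making
  fits bit-reproducible.
- Histogram bins are half-open with the last bin closed, so the maximal
  value lands in the final bin.
- The fuzzy union is exact for the MF shapes the fitter constructs
  (continuous trapezoids, or axis-clipped trapezoids sharing one axis);
  union knots include all pairwise crossing points, so linear
  interpolation between knots equals the pointwise maximum everywhere.
- Scaled projections sum to their α within relative 1e-9 (checked in
  tests); model JSON uses shortest-round-trip decimal floats, so
  save → load → save is byte-identical.
- Degenerate inputs fail loudly rather than silently: zero-maximum
  columns, single-class tables, empty λ-cuts (the error advises a smaller
  λ), zero-sum projection vectors (possible only for orthogonal extreme
  geometries), and metrics with zero denominators, which are reported as
  explicit `undefined` markers rather than 0.

### Scale invariance

In auto mode every derived quantity — axis range, bin width, cut
intervals, shoulders and the test-time mapping `z = t · scale_c` — scales
linearly with the α constants, so predicted labels are invariant to them
(verified over random rescalings in the acceptance tests). In paper mode
the thresholds and the `[0, 1.4]` axis are fixed numbers defined relative
to the default mean-1 scaling; overriding α there changes where records
fall against those fixed thresholds, which is why the CLI treats λ and
manual thresholds as mutually exclusive modes.

## Synthetic data

`simulate(SimSpec(...))` draws each class from a spherical Gaussian
truncated at zero. Truncation is by resampling, not clipping, to avoid a
point mass at 0 (this shifts moments slightly for centers near zero).
Defaults mirror the study conditions: class sizes 500/268, eight features,
unit spread, centers exactly five within-class standard deviations apart
along the all-ones diagonal. Randomness uses numpy's counter-based Philox
generator: same seed, same table, on any platform.

`pima_like(seed)` is a *structural* stand-in for the real clinical file:
768 rows, canonical header, published per-feature ranges, 500/268 class
balance — but features are independent uniforms, so it carries no signal
and accuracy on it is meaningless. It exists to exercise parsing,
splitting and plumbing. Consequently, passing tests demonstrate correct
mechanics and recovery on separable synthetic structure, not clinical
performance on the real Pima data; reproducing the published headline
accuracies requires the real file and the under-specified λ/bins/MF-shape
settings of the original study.

## Problem sizes

The test suite and the acceptance script run the full pipeline on
768-row tables (384 training / 384 held-out for two-cluster data; 400/368
for the clinical split) and 20 replicate seeds for the recovery check;
the whole suite completes in about a second.

## Known limitations

- One projection direction per classifier: no feature selection, no
  multi-directional ensembles, and the two classifiers are never combined.
- Only Euclidean distance and max-union aggregation; no Mamdani/Sugeno
  inference, no t-norm options, no rule optimization.
- No imputation of physiologically impossible zeros in Pima-format data;
  records are taken as printed.
- Uncovered records (zero membership in both classes) default to healthy;
  with heavily imbalanced or long-tailed sick classes this biases recall
  downward — inspect the uncovered-instance log line when it appears.
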