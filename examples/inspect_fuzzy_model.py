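"""Look inside a fitted fuzzy classifier: histograms, λ-cut, rule memberships.

Fits on synthetic two-cluster data, prints the pieces a clinician-facing
explanation would use — the projection scales, the λ-cut intervals and a
few per-record membership grades — then round-trips the model through its
JSON file.
"""

import numpy as np

from fuzzypima import (
    FitConfig,
    FuzzyClassifierModel,
    SimSpec,
    SplitSpec,
    classify,
    fit_pipeline,
    simulate,
)

result = fit_pipeline(
    simulate(SimSpec(seed=4)),
    split=SplitSpec(250, 134),
    config=FitConfig(threshold_mode="auto"),
)
model = result.model1
profile = model.profile

print(f"classifier {model.classifier_id}")
print(f"  projection scales: class-0 {profile.scale0:.4f}, class-1 {profile.scale1:.4f}")
print(f"  lambda = {model.region.lam}: sick region(s) on the z axis:")
for lo, hi in model.region.intervals:
    print(f"    [{lo:.3f}, {hi:.3f}]")

feats, labels = result.test.stacked()
print("  sample test records (label | mu_healthy, mu_sick -> prediction):")
for i in (0, 1, len(labels) - 2, len(labels) - 1):
    label, mu_h, mu_s = classify(feats[i], model)
    print(
        f"    actual {labels[i]} | mu_h={mu_h:.2f}, mu_s={mu_s:.2f} -> {label}"
    )
# The decision rule is interpretable: a record is called sick only when its
# sick-membership grade strictly exceeds its healthy grade.

model.save("/tmp/model1.json")
reloaded = FuzzyClassifierModel.load("/tmp/model1.json")
assert np.array_equal(reloaded.predict(feats), model.predict(feats))
print("model JSON round-trip: predictions identical")
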