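"""Derive the four performance scores from test-set confusion counts.

Feeds the two classifiers' published test-set confusion matrices
(368 predictions: 250 healthy, 118 diabetic) through the evaluation module
and prints the scores as a Table-style report.
"""

from fuzzypima import ConfusionMatrix, metrics
from fuzzypima.evaluation import format_report_table

reports = {
    "Classifier 1": metrics(ConfusionMatrix(tp=113, fn=5, fp=8, tn=242)),
    "Classifier 2": metrics(ConfusionMatrix(tp=106, fn=12, fp=5, tn=245)),
}

print(format_report_table(reports))
print()
cm1 = ConfusionMatrix(tp=113, fn=5, fp=8, tn=242)
print(
    f"Classifier 1 said 'yes' {cm1.predicted_positives} times and "
    f"'no' {cm1.predicted_negatives} times out of {cm1.total} predictions."
)
# Accuracy counts all correct calls; recall is the fraction of true diabetics
# caught; precision the fraction of 'yes' calls that were right; F-measure
# their harmonic mean.
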