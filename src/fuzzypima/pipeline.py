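"""End-to-end orchestration: normalize → partition → split → fit → evaluate.

These helpers are the importable layer behind the command-line interface;
examples, tests and the acceptance script call them directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import ConfusionMatrix, MetricsReport, confusion, metrics
from .fuzzy import FitConfig, FuzzyClassifierModel, fit
from .tabular import (
    ClassPartition,
    LabelledTable,
    SplitSpec,
    linear_split,
    normalize_features,
    partition_by_class,
    split_indices,
)

__all__ = ["FitResult", "fit_pipeline", "evaluate_partition", "evaluate_models"]


@dataclass(frozen=True)
class FitResult:
    model1: FuzzyClassifierModel
    model2: FuzzyClassifierModel
    train: ClassPartition
    test: ClassPartition
    feature_max: np.ndarray
    indices: dict[str, list[int]]

    @property
    def models(self) -> tuple[FuzzyClassifierModel, FuzzyClassifierModel]:
        return self.model1, self.model2


def fit_pipeline(
    table: LabelledTable,
    split: SplitSpec = SplitSpec(),
    normalization: str = "global",
    config: FitConfig = FitConfig(),
) -> FitResult:
    """Run the full training pipeline on a raw labelled table.

    ``normalization="global"`` rescales by whole-dataset column maxima
    before splitting (the study's order of operations); ``"train-only"``
    fits the maxima on the training rows alone (leakage-safe), in which
    case test features may slightly exceed 1 and are clipped at
    prediction time.
    """
    if normalization not in ("global", "train-only"):
        raise ValueError("normalization must be 'global' or 'train-only'")
    indices = split_indices(table.labels, split)
    if normalization == "global":
        normalized, fmax = normalize_features(table)
        partition = partition_by_class(normalized, feature_max=fmax)
        train, test = linear_split(partition, split)
    else:
        raw_partition = partition_by_class(table)
        raw_train, raw_test = linear_split(raw_partition, split)
        fmax = np.vstack([raw_train.a0, raw_train.a1]).max(axis=0)
        if (fmax <= 0).any():
            raise ValueError("a training column has non-positive maximum")
        train = ClassPartition(
            raw_train.a0 / fmax, raw_train.a1 / fmax,
            feature_max=fmax, attribute_names=table.attribute_names,
        )
        test = ClassPartition(
            raw_test.a0 / fmax, raw_test.a1 / fmax,
            feature_max=fmax, attribute_names=table.attribute_names,
        )
    model1, model2 = fit(train, config)
    return FitResult(model1, model2, train, test, fmax, indices)


def evaluate_partition(
    model: FuzzyClassifierModel, test: ClassPartition
) -> tuple[ConfusionMatrix, MetricsReport]:
    """Confusion matrix and scores of one model on a normalized test partition."""
    features, actual = test.stacked()
    predicted = model.predict(features)
    cm = confusion(predicted, actual)
    return cm, metrics(cm)


def evaluate_models(
    models: tuple[FuzzyClassifierModel, FuzzyClassifierModel],
    test: ClassPartition,
) -> dict[str, tuple[ConfusionMatrix, MetricsReport]]:
    return {
        f"Classifier {model.classifier_id}": evaluate_partition(model, test)
        for model in models
    }
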