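"""Seeded generators of Pima-like two-class tables.

Two generators cover testing needs without any external download:

* :func:`simulate` draws two labelled clusters from spherical Gaussians
  truncated at zero (negatives are resampled, not clipped, to avoid a point
  mass at 0) — the controllable-geometry generator used for recovery tests.
* :func:`pima_like` emits a 768-row structural stand-in for the public Pima
  Indians file: canonical header, published per-feature ranges, 500/268
  class sizes.  Features are independent and uniform, so it mimics shape and
  ranges only, never the real data's joint distribution.

Randomness uses numpy's counter-based Philox generator, so a given seed
yields the same stream on every platform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tabular import PIMA_FEATURES, LabelledTable

__all__ = ["SimSpec", "simulate", "pima_like"]


def _default_center0(k: int) -> np.ndarray:
    return np.full(k, 5.0)


@dataclass(frozen=True)
class SimSpec:
    """Geometry of the two-cluster generator.

    Defaults mirror the study conditions: class sizes 500/268 (the Pima
    class balance), eight features, unit within-class spread, and cluster
    centers exactly five standard deviations apart.
    """

    n0: int = 500
    n1: int = 268
    k: int = 8
    center0: tuple[float, ...] | None = None
    center1: tuple[float, ...] | None = None
    spread: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n0 < 1 or self.n1 < 1:
            raise ValueError("class sizes must be >= 1")
        if self.k < 1:
            raise ValueError("need at least one feature")
        if self.spread <= 0:
            raise ValueError("spread must be positive")
        c0 = (
            _default_center0(self.k)
            if self.center0 is None
            else np.asarray(self.center0, dtype=float)
        )
        if self.center1 is None:
            # five within-class standard deviations along the all-ones diagonal
            c1 = c0 + 5.0 * self.spread / np.sqrt(self.k)
        else:
            c1 = np.asarray(self.center1, dtype=float)
        if c0.shape != (self.k,) or c1.shape != (self.k,):
            raise ValueError("centers must have k entries")
        if (c0 < 0).any() or (c1 < 0).any():
            raise ValueError("centers must be non-negative")
        object.__setattr__(self, "center0", tuple(c0.tolist()))
        object.__setattr__(self, "center1", tuple(c1.tolist()))

    @property
    def separation(self) -> float:
        """Inter-center Euclidean distance in units of the within-class spread."""
        delta = np.asarray(self.center1) - np.asarray(self.center0)
        return float(np.linalg.norm(delta) / self.spread)


def _truncated_gaussian(
    rng: np.random.Generator, center: np.ndarray, spread: float, size: int
) -> np.ndarray:
    """Spherical Gaussian cluster truncated at 0 by resampling negatives."""
    draws = rng.normal(center, spread, size=(size, center.size))
    bad = draws < 0
    while bad.any():
        draws[bad] = rng.normal(np.broadcast_to(center, draws.shape)[bad], spread)
        bad = draws < 0
    return draws


def simulate(spec: SimSpec) -> LabelledTable:
    """Draw a labelled two-cluster table; deterministic given ``spec.seed``."""
    rng = np.random.Generator(np.random.Philox(spec.seed))
    c0 = np.asarray(spec.center0, dtype=float)
    c1 = np.asarray(spec.center1, dtype=float)
    a0 = _truncated_gaussian(rng, c0, spec.spread, spec.n0)
    a1 = _truncated_gaussian(rng, c1, spec.spread, spec.n1)
    features = np.vstack([a0, a1])
    labels = np.concatenate([np.zeros(spec.n0, int), np.ones(spec.n1, int)])
    names = tuple(f"feat_{i + 1}" for i in range(spec.k))
    return LabelledTable(features, labels, names)


#: Published per-feature ranges of the Pima dataset; integer-valued features
#: are drawn as integers.
_PIMA_RANGES: dict[str, tuple[float, float, bool]] = {
    "Pregnancies": (0, 17, True),
    "Glucose": (0, 199, True),
    "BloodPressure": (0, 122, True),
    "SkinThickness": (0, 99, True),
    "Insulin": (0, 846, True),
    "BMI": (0.0, 67.1, False),
    "DiabetesPedigreeFunction": (0.0078, 2.42, False),
    "Age": (21, 81, True),
}

PIMA_N_CLASS0 = 500
PIMA_N_CLASS1 = 268


def pima_like(seed: int = 0) -> LabelledTable:
    """A 768-row structural stand-in for the Pima Indians diabetes file.

    Synthetic: features are independent uniforms within the published
    ranges, so classification accuracy on it is meaningless — it exists to
    exercise format handling, splitting and the pipeline plumbing.
    """
    rng = np.random.Generator(np.random.Philox(seed))
    total = PIMA_N_CLASS0 + PIMA_N_CLASS1
    columns = []
    for name in PIMA_FEATURES:
        lo, hi, integer = _PIMA_RANGES[name]
        if integer:
            columns.append(rng.integers(int(lo), int(hi) + 1, size=total).astype(float))
        else:
            columns.append(rng.uniform(lo, hi, size=total))
    features = np.column_stack(columns)
    labels = np.concatenate(
        [np.zeros(PIMA_N_CLASS0, int), np.ones(PIMA_N_CLASS1, int)]
    )
    order = rng.permutation(total)
    return LabelledTable(features[order], labels[order], PIMA_FEATURES)
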