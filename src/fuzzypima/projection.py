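"""Extreme-example projection: the vector-algebra core of both classifiers.

The inter-class Euclidean distance matrix locates the *extreme pair* — the
class-0 record x_p and class-1 record y_q at maximal distance.  Every record
is then projected onto an extreme example by a plain dot product (the
"cosine amplitude" similarity as used here is unnormalized), and each
class's projection vector is rescaled so it sums to a chosen constant
(default: the class record count, giving mean 1).  The multiplicative scale
constant of each class is stored so test-time projections land on the same
axis as the training histograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .tabular import ClassPartition

__all__ = [
    "ExtremePair",
    "ProjectionProfile",
    "distance_matrix",
    "find_extremes",
    "project",
    "scale_projection",
    "fit_profiles",
]


@dataclass(frozen=True)
class ExtremePair:
    """The maximally distant cross-class record pair (x_p from A0, y_q from A1)."""

    p: int
    q: int
    x_p: np.ndarray
    y_q: np.ndarray
    d: float


@dataclass(frozen=True)
class ProjectionProfile:
    """Projections of both training classes onto one extreme-example direction.

    ``raw0``/``raw1`` are the dot-product vectors of the class-0 and class-1
    training matrices with ``direction``; ``scaled0 = scale0 * raw0`` (and
    likewise for class 1) where ``scale_c = alpha_c / sum(raw_c)``.  A model
    reloaded from disk keeps only ``direction`` and the scale constants, so
    the vector fields may be ``None``.
    """

    direction: np.ndarray
    scale0: float
    scale1: float
    alpha0: float
    alpha1: float
    raw0: np.ndarray | None = None
    raw1: np.ndarray | None = None
    scaled0: np.ndarray | None = None
    scaled1: np.ndarray | None = None


def distance_matrix(a0: np.ndarray, a1: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances: entry (i, j) = ||A0[i] - A1[j]||_2."""
    a0 = np.atleast_2d(np.asarray(a0, dtype=float))
    a1 = np.atleast_2d(np.asarray(a1, dtype=float))
    if a0.shape[1] != a1.shape[1]:
        raise ValueError(
            f"feature dimensions differ: {a0.shape[1]} vs {a1.shape[1]}"
        )
    return cdist(a0, a1, metric="euclidean")


def find_extremes(d: np.ndarray) -> tuple[int, int, float]:
    """Indices (p, q) of a maximal distance entry and its value.

    Ties are broken row-major: smallest p first, then smallest q.
    """
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValueError("distance matrix is empty")
    flat = int(np.argmax(d))  # argmax scans row-major, giving the tie rule
    p, q = np.unravel_index(flat, d.shape)
    return int(p), int(q), float(d[p, q])


def project(a: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Dot product of every row of ``a`` with ``direction`` (no magnitude scaling)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    direction = np.asarray(direction, dtype=float)
    if a.shape[1] != direction.shape[0]:
        raise ValueError(
            f"cannot project {a.shape[1]}-feature rows onto a "
            f"{direction.shape[0]}-vector"
        )
    return a @ direction


def scale_projection(
    raw: np.ndarray, alpha: float
) -> tuple[np.ndarray, float]:
    """Rescale a projection vector to sum to ``alpha``.

    Returns the scaled vector and the constant ``alpha / sum(raw)`` so that
    later (test-time) projections can be mapped onto the same axis.
    """
    raw = np.asarray(raw, dtype=float)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    total = float(raw.sum())
    if total <= 0:
        raise ValueError("projection vector sums to zero; cannot rescale")
    constant = alpha / total
    return raw * constant, constant


def fit_profiles(
    train: ClassPartition,
    alpha0: float | None = None,
    alpha1: float | None = None,
    beta0: float | None = None,
    beta1: float | None = None,
) -> tuple[ProjectionProfile, ProjectionProfile, ExtremePair]:
    """Locate the extreme pair and build both classifiers' projection profiles.

    Classifier 1 projects onto the class-0 extreme x_p, classifier 2 onto the
    class-1 extreme y_q.  Scaling constants default to the class record
    counts (alpha0 = beta0 = n, alpha1 = beta1 = m), so each scaled training
    vector has mean 1; any positive override leaves downstream predicted
    labels unchanged when histogram axes are data-derived.
    """
    if train.n == 0 or train.m == 0:
        raise ValueError("both training classes must be non-empty")
    d = distance_matrix(train.a0, train.a1)
    p, q, dist = find_extremes(d)
    extremes = ExtremePair(
        p=p, q=q, x_p=train.a0[p].copy(), y_q=train.a1[q].copy(), d=dist
    )

    def _profile(direction: np.ndarray, a0c: float, a1c: float) -> ProjectionProfile:
        raw0 = project(train.a0, direction)
        raw1 = project(train.a1, direction)
        scaled0, scale0 = scale_projection(raw0, a0c)
        scaled1, scale1 = scale_projection(raw1, a1c)
        return ProjectionProfile(
            direction=np.asarray(direction, dtype=float),
            scale0=scale0,
            scale1=scale1,
            alpha0=float(a0c),
            alpha1=float(a1c),
            raw0=raw0,
            raw1=raw1,
            scaled0=scaled0,
            scaled1=scaled1,
        )

    profile1 = _profile(
        extremes.x_p,
        train.n if alpha0 is None else alpha0,
        train.m if alpha1 is None else alpha1,
    )
    profile2 = _profile(
        extremes.y_q,
        train.n if beta0 is None else beta0,
        train.m if beta1 is None else beta1,
    )
    return profile1, profile2, extremes
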