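"""Histogram fuzzification, λ-cuts, membership functions and the decision rules.

Scaled projections of each training class are binned into a height-normalized
histogram (maximum membership exactly 1), which is read as a fuzzy set over
the projection axis z.  Membership functions are trapezoids — either placed
on figure-read thresholds ("paper" mode: [0.2, 0.4, 0.8] on [0, 1.4] for
classifier 1 and 0.5 for classifier 2) or derived automatically from λ-cuts
of the class histograms ("auto" mode).  Per-class trapezoids are aggregated
by fuzzy union (pointwise maximum) into one healthy and one sick membership
function; a record is classified sick only when its sick membership strictly
exceeds its healthy membership.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .projection import ExtremePair, ProjectionProfile, fit_profiles, project
from .tabular import ClassPartition

__all__ = [
    "MODEL_FORMAT_VERSION",
    "FuzzyHistogram",
    "IntervalSet",
    "MembershipFunction",
    "FitConfig",
    "FuzzyClassifierModel",
    "build_histogram",
    "lambda_cut",
    "mf_from_thresholds",
    "mf_from_cut",
    "aggregate_union",
    "classify",
    "fit",
]

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = "1.0"


@dataclass(frozen=True)
class FuzzyHistogram:
    """A height-normalized histogram read as a fuzzy set over the z axis."""

    bin_edges: np.ndarray
    memberships: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        mems = np.asarray(self.memberships, dtype=float)
        if edges.ndim != 1 or mems.ndim != 1 or mems.size != edges.size - 1:
            raise ValueError("need len(memberships) == len(bin_edges) - 1")
        if not (np.diff(edges) > 0).all():
            raise ValueError("bin edges must be strictly increasing")
        if (mems < 0).any() or (mems > 1).any():
            raise ValueError("memberships must lie in [0, 1]")
        if mems.size and mems.max() != 1.0:
            raise ValueError("a fuzzy histogram must have maximum membership 1")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "memberships", mems)

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass(frozen=True)
class IntervalSet:
    """Disjoint closed intervals on the z axis produced by a λ-cut."""

    intervals: tuple[tuple[float, float], ...]
    lam: float

    def __post_init__(self) -> None:
        ivs = tuple((float(a), float(b)) for a, b in self.intervals)
        for a, b in ivs:
            if a > b:
                raise ValueError(f"interval [{a}, {b}] has lo > hi")
        for (_, b), (a2, _) in zip(ivs, ivs[1:]):
            if a2 <= b:
                raise ValueError("intervals must be disjoint and sorted")
        object.__setattr__(self, "intervals", ivs)

    def contains(self, z: float) -> bool:
        return any(a <= z <= b for a, b in self.intervals)


@dataclass(frozen=True)
class MembershipFunction:
    """Piecewise-linear membership function: linear between knots, 0 outside."""

    z: np.ndarray
    mu: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        mu = np.asarray(self.mu, dtype=float)
        if z.ndim != 1 or z.shape != mu.shape or z.size < 1:
            raise ValueError("knots must be parallel non-empty 1-D arrays")
        if not (np.diff(z) > 0).all():
            raise ValueError("knot positions must be strictly increasing")
        if (mu < 0).any() or (mu > 1).any():
            raise ValueError("memberships must lie in [0, 1]")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "mu", mu)

    def __call__(self, at: float | np.ndarray) -> float | np.ndarray:
        at = np.asarray(at, dtype=float)
        vals = np.interp(at, self.z, self.mu)
        vals = np.where((at < self.z[0]) | (at > self.z[-1]), 0.0, vals)
        return float(vals) if vals.ndim == 0 else vals

    @property
    def knots(self) -> list[tuple[float, float]]:
        return list(zip(self.z.tolist(), self.mu.tolist()))


def build_histogram(
    values: Sequence[float] | np.ndarray,
    bins: int = 20,
    range: tuple[float, float] | None = None,
) -> FuzzyHistogram:
    """Bin values and divide counts by the modal count (height normalization).

    Bins are half-open with the last bin closed, so a value equal to the
    upper edge lands in the final bin.  An explicit ``range`` must cover all
    values; by default the axis spans [0, max(values)].
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot build a histogram from no values")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    if range is None:
        lo = min(0.0, float(values.min()))
        hi = float(values.max())
        if hi <= lo:
            hi = lo + 1.0  # degenerate all-equal-at-lo input: unit-width axis
        range = (lo, hi)
    lo, hi = float(range[0]), float(range[1])
    if hi <= lo:
        raise ValueError("range upper bound must exceed lower bound")
    if (values < lo).any() or (values > hi).any():
        bad = values[(values < lo) | (values > hi)][0]
        raise ValueError(f"value {bad} outside the explicit range [{lo}, {hi}]")
    counts, edges = np.histogram(values, bins=bins, range=(lo, hi))
    return FuzzyHistogram(edges, counts / counts.max())


def lambda_cut(h: FuzzyHistogram, lam: float) -> IntervalSet:
    """Crisp region {z : membership(z) >= λ}, adjacent qualifying bins merged."""
    if not 0 < lam <= 1:
        raise ValueError("lambda must lie in (0, 1]")
    keep = h.memberships >= lam
    intervals: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(keep):
        if flag and start is None:
            start = h.bin_edges[i]
        elif not flag and start is not None:
            intervals.append((start, h.bin_edges[i]))
            start = None
    if start is not None:
        intervals.append((start, h.bin_edges[-1]))
    return IntervalSet(tuple(intervals), lam)


def _clip_trapezoid(
    lo: float, hi: float, shoulder: float, axis: tuple[float, float] | None
) -> MembershipFunction:
    """Trapezoid with plateau [lo, hi] and linear shoulders, clipped to the axis."""
    z = [lo - shoulder, lo, hi, hi + shoulder]
    mu = [0.0, 1.0, 1.0, 0.0]
    if axis is not None:
        zmin, zmax = axis
        knots_z, knots_mu = [], []
        raw = MembershipFunction(_dedupe(z), _dedupe_mu(z, mu))
        for zz, mm in zip(z, mu):
            if zmin <= zz <= zmax:
                knots_z.append(zz)
                knots_mu.append(mm)
        if not knots_z or knots_z[0] > zmin:
            knots_z.insert(0, zmin)
            knots_mu.insert(0, float(raw(zmin)))
        if knots_z[-1] < zmax:
            knots_z.append(zmax)
            knots_mu.append(float(raw(zmax)))
        z, mu = knots_z, knots_mu
    return MembershipFunction(_dedupe(z), _dedupe_mu(z, mu))


def _dedupe(z: Sequence[float]) -> np.ndarray:
    out = [z[0]]
    for v in z[1:]:
        if v > out[-1]:
            out.append(v)
    return np.asarray(out, dtype=float)


def _dedupe_mu(z: Sequence[float], mu: Sequence[float]) -> np.ndarray:
    out_z, out_mu = [z[0]], [mu[0]]
    for v, m in zip(z[1:], mu[1:]):
        if v > out_z[-1]:
            out_z.append(v)
            out_mu.append(m)
        else:
            out_mu[-1] = max(out_mu[-1], m)  # coincident knots: keep the higher
    return np.asarray(out_mu, dtype=float)


def mf_from_thresholds(
    thresholds: Sequence[float],
    axis: tuple[float, float],
    shoulder: float,
) -> list[MembershipFunction]:
    """One trapezoidal membership function per axis segment between thresholds.

    ``thresholds`` split ``axis`` into len(thresholds)+1 consecutive
    segments; each segment's trapezoid has membership 1 on the segment and
    linear shoulders of half-width ``shoulder`` (clipped at the axis ends).
    """
    thresholds = [float(t) for t in thresholds]
    zmin, zmax = float(axis[0]), float(axis[1])
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    if thresholds and (thresholds[0] <= zmin or thresholds[-1] >= zmax):
        raise ValueError("thresholds must lie strictly inside the axis")
    if shoulder <= 0:
        raise ValueError("shoulder width must be positive")
    cuts = [zmin, *thresholds, zmax]
    return [
        _clip_trapezoid(a, b, shoulder, (zmin, zmax))
        for a, b in zip(cuts, cuts[1:])
    ]


def mf_from_cut(cut: IntervalSet, shoulder: float) -> MembershipFunction:
    """Union of trapezoids built on a λ-cut's intervals (μ=1 inside, linear shoulders)."""
    if not cut.intervals:
        raise ValueError(
            "the lambda-cut is empty: no histogram bin reaches the cut level; "
            "retry with a smaller lambda"
        )
    if shoulder <= 0:
        raise ValueError("shoulder width must be positive")
    pieces = [_clip_trapezoid(a, b, shoulder, None) for a, b in cut.intervals]
    return aggregate_union(pieces)


def aggregate_union(mfs: Sequence[MembershipFunction]) -> MembershipFunction:
    """Fuzzy union: the exact piecewise-linear pointwise maximum.

    The result's knots are the merged input knots plus every crossing point
    of two input functions, so evaluation agrees with max() everywhere for
    continuous inputs (endpoints at 0, or axis-clipped inputs sharing one
    axis — the only shapes the fitting procedure constructs).
    """
    if not mfs:
        raise ValueError("need at least one membership function")
    if len(mfs) == 1:
        return mfs[0]
    grid = np.unique(np.concatenate([mf.z for mf in mfs]))
    crossings: list[float] = []
    vals = np.array([[mf(z) for mf in mfs] for z in grid])
    for s in range(grid.size - 1):
        a, b = grid[s], grid[s + 1]
        fa, fb = vals[s], vals[s + 1]
        for i in range(len(mfs)):
            for j in range(i + 1, len(mfs)):
                da, db = fa[i] - fa[j], fb[i] - fb[j]
                if da * db < 0:
                    t = da / (da - db)
                    crossings.append(float(a + t * (b - a)))
    allz = np.unique(np.concatenate([grid, np.asarray(crossings, dtype=float)]))
    mu = np.max(np.column_stack([mf(allz) for mf in mfs]), axis=1)
    return MembershipFunction(allz, np.clip(mu, 0.0, 1.0))


@dataclass(frozen=True)
class FitConfig:
    """Tunable parameters of the fitting procedure.

    threshold_mode
        "paper": trapezoids on the published figure-read thresholds
        ([0.2, 0.4, 0.8] over the [0, 1.4] axis for classifier 1; 0.5 for
        classifier 2).  "auto": trapezoids derived from λ-cuts of the class
        histograms (fully data-driven; predictions are then invariant to the
        α/β scale constants).
    lam
        λ-cut level in (0, 1]; 0.5 by default (the conventional cut, and the
        level at which classifier 2's published threshold sits).
    bins
        Histogram bin count per class (default 20).
    shoulder
        Trapezoid shoulder half-width; ``None`` means one bin width.
    segment_assignment_c1 / _c2
        Per-segment class labels (0 healthy / 1 sick) for "paper" mode;
        ``None`` alternates starting from the class whose scaled training
        projections have the lower median.
    """

    threshold_mode: str = "paper"
    lam: float = 0.5
    bins: int = 20
    axis_c1: tuple[float, float] = (0.0, 1.4)
    thresholds_c1: tuple[float, ...] = (0.2, 0.4, 0.8)
    thresholds_c2: tuple[float, ...] = (0.5,)
    shoulder: float | None = None
    segment_assignment_c1: tuple[int, ...] | None = None
    segment_assignment_c2: tuple[int, ...] | None = None
    alpha0: float | None = None
    alpha1: float | None = None
    beta0: float | None = None
    beta1: float | None = None

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("paper", "auto"):
            raise ValueError("threshold_mode must be 'paper' or 'auto'")
        if not 0 < self.lam <= 1:
            raise ValueError("lam must lie in (0, 1]")
        if self.bins < 1:
            raise ValueError("bins must be >= 1")

    def to_dict(self) -> dict:
        # JSON-canonical form (tuples become lists) so the in-memory config
        # echo matches a saved-and-reloaded model file exactly
        return json.loads(json.dumps(asdict(self)))


@dataclass
class FuzzyClassifierModel:
    """One fitted classifier: projection direction, fuzzy sets, decision rule."""

    classifier_id: int
    profile: ProjectionProfile
    mf_healthy: MembershipFunction
    mf_sick: MembershipFunction
    hist_healthy: FuzzyHistogram
    hist_sick: FuzzyHistogram
    region: IntervalSet
    config: dict
    extreme_indices: tuple[int, int]
    feature_max: np.ndarray | None = None
    attribute_names: tuple[str, ...] | None = None

    # -- prediction ---------------------------------------------------------

    def memberships(self, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Healthy and sick membership grades for normalized records (rows)."""
        feats = np.atleast_2d(np.asarray(features, dtype=float))
        if feats.shape[1] != self.profile.direction.shape[0]:
            raise ValueError(
                f"records have {feats.shape[1]} features, model expects "
                f"{self.profile.direction.shape[0]}"
            )
        if (feats < 0).any():
            raise ValueError("normalized features must be non-negative")
        if (feats > 1).any():
            logger.warning(
                "clipping %d feature value(s) above 1 (test exceeds training maxima)",
                int((feats > 1).sum()),
            )
            feats = np.minimum(feats, 1.0)
        t = project(feats, self.profile.direction)
        mu_h = np.asarray(self.mf_healthy(t * self.profile.scale0))
        mu_s = np.asarray(self.mf_sick(t * self.profile.scale1))
        return np.atleast_1d(mu_h), np.atleast_1d(mu_s)

    def predict(self, features: np.ndarray) -> np.ndarray:
        """0/1 labels for normalized records; healthy wins ties (μ_h >= μ_s → 0)."""
        mu_h, mu_s = self.memberships(features)
        uncovered = (mu_h == 0) & (mu_s == 0)
        if uncovered.any():
            logger.info(
                "%d uncovered instance(s): zero membership in both classes, "
                "classified healthy by the tie rule",
                int(uncovered.sum()),
            )
        return (mu_s > mu_h).astype(int)

    def region_diagnostic(self, features: np.ndarray) -> np.ndarray:
        """Crisp single-cut test: is the projection inside the λ-cut region?

        For classifier 1 the region is the sick (class-1) cut; for
        classifier 2 the healthy (class-0) cut.  Exposed as a diagnostic
        only — the decision rule is the membership comparison.
        """
        feats = np.minimum(np.atleast_2d(np.asarray(features, dtype=float)), 1.0)
        t = project(feats, self.profile.direction)
        scale = (
            self.profile.scale1 if self.classifier_id == 1 else self.profile.scale0
        )
        return np.array([self.region.contains(z) for z in np.atleast_1d(t * scale)])

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "classifier_id": self.classifier_id,
            "direction": self.profile.direction.tolist(),
            "scale0": self.profile.scale0,
            "scale1": self.profile.scale1,
            "alpha0": self.profile.alpha0,
            "alpha1": self.profile.alpha1,
            "extreme_indices": list(self.extreme_indices),
            "hist_healthy": {
                "bin_edges": self.hist_healthy.bin_edges.tolist(),
                "memberships": self.hist_healthy.memberships.tolist(),
            },
            "hist_sick": {
                "bin_edges": self.hist_sick.bin_edges.tolist(),
                "memberships": self.hist_sick.memberships.tolist(),
            },
            "mf_healthy": {"knots": self.mf_healthy.knots},
            "mf_sick": {"knots": self.mf_sick.knots},
            "region": {
                "intervals": [list(iv) for iv in self.region.intervals],
                "lam": self.region.lam,
            },
            "config": self.config,
            "feature_max": (
                None if self.feature_max is None else self.feature_max.tolist()
            ),
            "attribute_names": (
                None if self.attribute_names is None else list(self.attribute_names)
            ),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "FuzzyClassifierModel":
        if data.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format {data.get('format_version')!r}"
            )

        def _mf(entry: dict) -> MembershipFunction:
            knots = entry["knots"]
            return MembershipFunction(
                np.array([k[0] for k in knots]), np.array([k[1] for k in knots])
            )

        profile = ProjectionProfile(
            direction=np.asarray(data["direction"], dtype=float),
            scale0=float(data["scale0"]),
            scale1=float(data["scale1"]),
            alpha0=float(data["alpha0"]),
            alpha1=float(data["alpha1"]),
        )
        return cls(
            classifier_id=int(data["classifier_id"]),
            profile=profile,
            mf_healthy=_mf(data["mf_healthy"]),
            mf_sick=_mf(data["mf_sick"]),
            hist_healthy=FuzzyHistogram(
                np.asarray(data["hist_healthy"]["bin_edges"]),
                np.asarray(data["hist_healthy"]["memberships"]),
            ),
            hist_sick=FuzzyHistogram(
                np.asarray(data["hist_sick"]["bin_edges"]),
                np.asarray(data["hist_sick"]["memberships"]),
            ),
            region=IntervalSet(
                tuple(tuple(iv) for iv in data["region"]["intervals"]),
                float(data["region"]["lam"]),
            ),
            config=dict(data["config"]),
            extreme_indices=tuple(data["extreme_indices"]),
            feature_max=(
                None
                if data.get("feature_max") is None
                else np.asarray(data["feature_max"], dtype=float)
            ),
            attribute_names=(
                None
                if data.get("attribute_names") is None
                else tuple(data["attribute_names"])
            ),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def load(cls, path: str | Path) -> "FuzzyClassifierModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def classify(
    record: np.ndarray, model: FuzzyClassifierModel
) -> tuple[int, float, float]:
    """Classify one normalized record: (label, μ_healthy, μ_sick)."""
    mu_h, mu_s = model.memberships(np.atleast_2d(record))
    label = 0 if mu_h[0] >= mu_s[0] else 1
    return label, float(mu_h[0]), float(mu_s[0])


def _default_assignment(
    scaled0: np.ndarray, scaled1: np.ndarray, n_segments: int
) -> tuple[int, ...]:
    """Alternate class labels across segments, starting from the lower-median class."""
    first = 0 if np.median(scaled0) <= np.median(scaled1) else 1
    return tuple((first + i) % 2 for i in range(n_segments))


def _build_classifier(
    classifier_id: int,
    profile: ProjectionProfile,
    extremes: ExtremePair,
    config: FitConfig,
    feature_max: np.ndarray | None,
    attribute_names: tuple[str, ...] | None,
) -> FuzzyClassifierModel:
    h0 = build_histogram(profile.scaled0, bins=config.bins)
    h1 = build_histogram(profile.scaled1, bins=config.bins)
    # §-3.3-style single-cut region: sick histogram for classifier 1,
    # healthy histogram for classifier 2 (kept as a diagnostic).
    region = lambda_cut(h1 if classifier_id == 1 else h0, config.lam)

    if config.threshold_mode == "paper":
        if classifier_id == 1:
            axis = (float(config.axis_c1[0]), float(config.axis_c1[1]))
            thresholds = config.thresholds_c1
            assignment = config.segment_assignment_c1
        else:
            hi = float(max(profile.scaled0.max(), profile.scaled1.max()))
            axis = (0.0, hi)
            thresholds = config.thresholds_c2
            assignment = config.segment_assignment_c2
        shoulder = (
            config.shoulder
            if config.shoulder is not None
            else (axis[1] - axis[0]) / config.bins
        )
        segments = mf_from_thresholds(thresholds, axis, shoulder)
        if assignment is None:
            assignment = _default_assignment(
                profile.scaled0, profile.scaled1, len(segments)
            )
        if len(assignment) != len(segments):
            raise ValueError(
                f"segment assignment has {len(assignment)} entries for "
                f"{len(segments)} segments"
            )
        healthy = [s for s, c in zip(segments, assignment) if c == 0]
        sick = [s for s, c in zip(segments, assignment) if c == 1]
        if not healthy or not sick:
            raise ValueError("each class needs at least one segment")
        mf_healthy = aggregate_union(healthy)
        mf_sick = aggregate_union(sick)
    else:  # auto: λ-cut both class histograms
        mf_healthy = mf_from_cut(lambda_cut(h0, config.lam), h0.bin_width)
        mf_sick = mf_from_cut(lambda_cut(h1, config.lam), h1.bin_width)

    return FuzzyClassifierModel(
        classifier_id=classifier_id,
        profile=profile,
        mf_healthy=mf_healthy,
        mf_sick=mf_sick,
        hist_healthy=h0,
        hist_sick=h1,
        region=region,
        config=config.to_dict(),
        extreme_indices=(extremes.p, extremes.q),
        feature_max=feature_max,
        attribute_names=attribute_names,
    )


def fit(
    train: ClassPartition, config: FitConfig = FitConfig()
) -> tuple[FuzzyClassifierModel, FuzzyClassifierModel]:
    """Fit both fuzzy classifiers on a normalized training partition."""
    profile1, profile2, extremes = fit_profiles(
        train,
        alpha0=config.alpha0,
        alpha1=config.alpha1,
        beta0=config.beta0,
        beta1=config.beta1,
    )
    names = train.attribute_names
    fmax = train.feature_max
    model1 = _build_classifier(1, profile1, extremes, config, fmax, names)
    model2 = _build_classifier(2, profile2, extremes, config, fmax, names)
    return model1, model2
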