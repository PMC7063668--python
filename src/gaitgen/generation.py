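"""Trajectory reconstruction: predicted gait features -> continuous full cycle.

Predicted features are arranged as time-ordered knots (relative time in % of
the gait cycle, value, velocity per %) and joined by piecewise cubics.  Each
segment satisfies four constraints — position and velocity at both bounding
knots — giving the classic cubic Hermite spline, obtained here by solving the
4x4 linear system in local normalized time tau = (t - t0)/(t1 - t0):

    s(0) = s0,  s'(0) = v0*dt,  s(1) = s1,  s'(1) = v1*dt.

Segments join consecutive features within the cycle; one extra closing
segment from the last knot to the first knot shifted by +100% makes the
reconstruction periodic and C1 across the initial-contact wrap, which a
cyclic robot reference requires.

Knots whose predicted velocity is not modelled get a periodic three-point
finite-difference tangent (Catmull-Rom style); knots predicted closer than
0.5% of the cycle are merged by value averaging before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .events import CHANNEL_NAMES, GaitCycle
from .exceptions import AlignmentError, GaitgenError, OrderingError
from .regression import ModelSet

__all__ = [
    "FeatureKnot",
    "SplineSegment",
    "GeneratedGait",
    "fit_segment",
    "knots_from_features",
    "knots_from_models",
    "generate_from_features",
    "generate_gait",
    "average_baseline",
]

MERGE_TOLERANCE = 0.5  # % of cycle below which adjacent knots merge

_HERMITE_SYSTEM = np.array(
    [
        [1.0, 0.0, 0.0, 0.0],
        [0.0, 1.0, 0.0, 0.0],
        [1.0, 1.0, 1.0, 1.0],
        [0.0, 1.0, 2.0, 3.0],
    ]
)


@dataclass
class FeatureKnot:
    """(time %, value, velocity per %) — velocity None means 'impute later'."""

    t: float
    s: float
    v: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.t <= 100.0:
            raise GaitgenError(f"knot time {self.t} outside [0, 100]")


@dataclass(frozen=True)
class SplineSegment:
    """One cubic between two knots, coefficients in local normalized time."""

    t_start: float
    t_end: float
    coefficients: np.ndarray  # a0..a3

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise GaitgenError("segment must have t_end > t_start")
        object.__setattr__(
            self, "coefficients", np.asarray(self.coefficients, dtype=float)
        )

    def __call__(self, t) -> np.ndarray:
        tau = (np.asarray(t, dtype=float) - self.t_start) / (self.t_end - self.t_start)
        a0, a1, a2, a3 = self.coefficients
        return a0 + tau * (a1 + tau * (a2 + tau * a3))

    def velocity(self, t) -> np.ndarray:
        """Derivative with respect to percent (not local time)."""
        dt = self.t_end - self.t_start
        tau = (np.asarray(t, dtype=float) - self.t_start) / dt
        _, a1, a2, a3 = self.coefficients
        return (a1 + tau * (2.0 * a2 + tau * 3.0 * a3)) / dt


def fit_segment(k0: FeatureKnot, k1: FeatureKnot) -> SplineSegment:
    """The unique cubic matching both knots' position and velocity."""
    dt = k1.t - k0.t
    if dt <= 0:
        raise GaitgenError(f"knots not strictly ordered in time ({k0.t} >= {k1.t})")
    if k0.v is None or k1.v is None:
        raise GaitgenError("both knots need velocities; impute before fitting")
    rhs = np.array([k0.s, k0.v * dt, k1.s, k1.v * dt])
    coeffs = np.linalg.solve(_HERMITE_SYSTEM, rhs)
    return SplineSegment(t_start=k0.t, t_end=k1.t, coefficients=coeffs)


@dataclass
class GeneratedGait:
    """A generated reference gait: channels on a percent grid plus provenance."""

    percent: np.ndarray
    channels: dict[str, np.ndarray]
    duration: float
    knots: dict[str, list[FeatureKnot]] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.percent = np.asarray(self.percent, dtype=float)
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}


# ---------------------------------------------------------------------------
# knot assembly


def _merge_knots(knots: list[FeatureKnot], min_gap: float = MERGE_TOLERANCE) -> list[FeatureKnot]:
    knots = sorted(knots, key=lambda k: k.t)
    merged: list[FeatureKnot] = []
    for k in knots:
        if merged and k.t - merged[-1].t < min_gap:
            prev = merged[-1]
            vs = [v for v in (prev.v, k.v) if v is not None]
            merged[-1] = FeatureKnot(
                t=(prev.t + k.t) / 2.0,
                s=(prev.s + k.s) / 2.0,
                v=float(np.mean(vs)) if vs else None,
            )
        else:
            merged.append(k)
    # wrap: a knot within min_gap of the cycle end collides with the first one
    if len(merged) >= 2 and (100.0 - merged[-1].t) + merged[0].t < min_gap:
        last = merged.pop()
        first = merged[0]
        vs = [v for v in (first.v, last.v) if v is not None]
        merged[0] = FeatureKnot(
            t=first.t, s=(first.s + last.s) / 2.0, v=float(np.mean(vs)) if vs else None
        )
    return merged


def _impute_velocities(knots: list[FeatureKnot]) -> list[FeatureKnot]:
    """Periodic three-point tangents for knots without a modelled velocity."""
    n = len(knots)
    out = []
    for i, k in enumerate(knots):
        if k.v is not None:
            out.append(k)
            continue
        prev, nxt = knots[(i - 1) % n], knots[(i + 1) % n]
        tp = prev.t - 100.0 if i == 0 else prev.t
        tn = nxt.t + 100.0 if i == n - 1 else nxt.t
        out.append(FeatureKnot(t=k.t, s=k.s, v=(nxt.s - prev.s) / (tn - tp)))
    return out


def knots_from_features(
    features: Mapping[str, float],
    channels: Sequence[str] = CHANNEL_NAMES,
    min_gap: float = MERGE_TOLERANCE,
    zero_extreme_velocity: bool = True,
) -> dict[str, list[FeatureKnot]]:
    """Per-channel ordered knots from a flat feature mapping.

    Event knots sit at 0% (e1) and at the cumulative phase durations
    (e2 = DSP1, e3 = DSP1+SSP1, e4 = DSP1+SSP1+DSP2); extreme knots at their
    predicted relative timings.  ``d``-prefixed features supply velocities
    where present; the rest are imputed periodically.  Extremes are
    stationary points, so their tangents are pinned to zero by default
    (``zero_extreme_velocity=False`` uses the ``d<ch>f*`` features instead),
    which keeps the reconstructed extremum exactly at the knot.
    """
    try:
        e2 = features["dsp1"]
        e3 = e2 + features["ssp1"]
        e4 = e3 + features["dsp2"]
    except KeyError as exc:
        raise GaitgenError(f"missing phase-duration feature: {exc}") from exc
    if not (0.0 < e2 < e3 < e4 < 100.0):
        raise OrderingError(
            f"predicted event timings out of order: e2={e2:.2f}, e3={e3:.2f}, e4={e4:.2f}"
        )

    out: dict[str, list[FeatureKnot]] = {}
    for ch in channels:
        knots = []
        for i, t in enumerate((0.0, e2, e3, e4), start=1):
            knots.append(
                FeatureKnot(t=t, s=features[f"{ch}e{i}"], v=features.get(f"d{ch}e{i}"))
            )
        for f in ("f1", "f2"):
            t = features[f"t{ch}{f}"] % 100.0
            v = 0.0 if zero_extreme_velocity else features.get(f"d{ch}{f}")
            knots.append(FeatureKnot(t=t, s=features[f"{ch}{f}"], v=v))
        knots = _merge_knots(knots, min_gap)
        if len(knots) < 2 or any(
            b.t - a.t <= 0 for a, b in zip(knots, knots[1:])
        ):
            raise OrderingError(f"channel {ch!r}: knots not strictly increasing after merge")
        out[ch] = _impute_velocities(knots)
    return out


def knots_from_models(
    models: ModelSet,
    params: Mapping[str, float],
    channels: Sequence[str] = CHANNEL_NAMES,
    guard_frac: float | None = 0.1,
    min_gap: float = MERGE_TOLERANCE,
) -> dict[str, list[FeatureKnot]]:
    """Predict every modelled feature at a subject's MP/SPs and build knots."""
    predicted = {name: models.predict(name, params, guard_frac=guard_frac) for name in models.models}
    return knots_from_features(predicted, channels=channels, min_gap=min_gap)


# ---------------------------------------------------------------------------
# sampling


def _closing_segment(last: FeatureKnot, first: FeatureKnot) -> SplineSegment:
    """Segment from the last knot to the first knot shifted by +100%."""
    t_end = first.t + 100.0
    dt = t_end - last.t
    rhs = np.array([last.s, last.v * dt, first.s, first.v * dt])
    return SplineSegment(
        t_start=last.t, t_end=t_end, coefficients=np.linalg.solve(_HERMITE_SYSTEM, rhs)
    )


def _sample_channel(knots: list[FeatureKnot], percent: np.ndarray) -> np.ndarray:
    segments = [fit_segment(a, b) for a, b in zip(knots, knots[1:])]
    first, last = knots[0], knots[-1]
    closing = _closing_segment(last, first) if last.t < 100.0 else None

    ends = np.array([s.t_end for s in segments])
    values = np.empty_like(percent)
    for i, q in enumerate(percent):
        if q < first.t or q > last.t:
            # wrap region handled by the closing segment (shift pre-IC samples)
            if closing is None:
                raise GaitgenError("no closing segment to cover the wrap region")
            values[i] = closing(q + 100.0 if q < first.t else q)
        else:
            j = min(int(np.searchsorted(ends, q)), len(segments) - 1)
            values[i] = segments[j](q)
    return values


def generate_from_features(
    features: Mapping[str, float],
    channels: Sequence[str] = CHANNEL_NAMES,
    n_points: int = 101,
    duration: float | None = None,
    provenance: dict | None = None,
) -> GeneratedGait:
    """Reconstruct a full periodic cycle directly from a feature mapping."""
    knots = knots_from_features(features, channels=channels)
    percent = np.linspace(0.0, 100.0, n_points)
    out = {ch: _sample_channel(k, percent) for ch, k in knots.items()}
    return GeneratedGait(
        percent=percent,
        channels=out,
        duration=float(features["cycle"]) if duration is None and "cycle" in features else float(duration or np.nan),
        knots=knots,
        provenance=provenance or {},
    )


def generate_gait(
    models: ModelSet,
    params: Mapping[str, float],
    channels: Sequence[str] = CHANNEL_NAMES,
    n_points: int = 101,
    guard_frac: float | None = 0.1,
) -> GeneratedGait:
    """Full pipeline tail: predict features for a subject and reconstruct."""
    predicted = {name: models.predict(name, params, guard_frac=guard_frac) for name in models.models}
    gait = generate_from_features(
        predicted,
        channels=channels,
        n_points=n_points,
        provenance={"params": dict(params), "n_models": len(models.models)},
    )
    return gait


def average_baseline(cycles: Iterable[GaitCycle]) -> GeneratedGait:
    """Pointwise-mean trajectory across cycles — the traditional baseline.

    Averaging across subjects smooths inter-subject timing differences, so
    peak amplitudes of the averaged trajectory are generally smaller than the
    individual peaks; it serves as the comparison baseline for the parametric
    generator.
    """
    cycles = list(cycles)
    if len(cycles) < 2:
        raise GaitgenError("need at least two cycles to average")
    grid = cycles[0].percent
    names = list(cycles[0].channels)
    for c in cycles[1:]:
        if c.percent.shape != grid.shape or not np.allclose(c.percent, grid):
            raise AlignmentError("cycles are not on a common percent grid")
        if set(c.channels) != set(names):
            raise AlignmentError("cycles do not share channel names")
    channels = {ch: np.mean([c.channels[ch] for c in cycles], axis=0) for ch in names}
    return GeneratedGait(
        percent=grid.copy(),
        channels=channels,
        duration=float(np.mean([c.duration for c in cycles])),
        provenance={"method": "average", "n_cycles": len(cycles)},
    )
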