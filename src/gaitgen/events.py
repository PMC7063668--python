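"""Gait events, stride segmentation, cycle normalization and foot progression angle.

Events follow the standard stride structure (one stride of the concerned leg):

    IC  --- OTO --- OIC --- TO --- next IC
    |  DSP1  |  SSP1 |  DSP2 |  swing  |

where IC/TO are initial contact and toe-off of the concerned leg and OTO/OIC
the contralateral events.  Phase durations are expressed in percent of the
gait cycle and always sum to 100.

Event detection is kinematic (no force plates): foot contact is declared while
the heel (for IC) or toe (for TO) vertical position sits below a configurable
threshold above its stance level; the entry/exit crossing times are refined by
linearly extrapolating the local vertical velocity down to stance level, which
recovers the touchdown/lift-off instant to sub-sample accuracy when the marker
height changes roughly linearly near contact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import (
    CoverageError,
    GaitgenError,
    InsufficientDataError,
    WindowError,
)
from .frames import MarkerSeries

__all__ = [
    "GaitEventSet",
    "PhaseDurations",
    "GaitCycle",
    "detect_contacts",
    "detect_events",
    "phase_durations",
    "segment_normalize",
    "compute_fpa",
]

CHANNEL_NAMES = ("X", "Y", "Z", "A1", "A2", "A3")


@dataclass(frozen=True)
class GaitEventSet:
    """Event times in seconds for one stride of the concerned leg."""

    ic: float
    oto: float
    oic: float
    to: float
    next_ic: float

    def __post_init__(self) -> None:
        seq = (self.ic, self.oto, self.oic, self.to, self.next_ic)
        if not all(np.isfinite(seq)):
            raise GaitgenError("gait event times must be finite")
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise GaitgenError(f"gait events out of order: {seq}")

    def as_percent(self) -> dict[str, float]:
        """Event timings as percent of the gait cycle (ic = 0)."""
        cycle = self.next_ic - self.ic
        return {
            "ic": 0.0,
            "oto": 100.0 * (self.oto - self.ic) / cycle,
            "oic": 100.0 * (self.oic - self.ic) / cycle,
            "to": 100.0 * (self.to - self.ic) / cycle,
        }


@dataclass(frozen=True)
class PhaseDurations:
    """Cycle duration (s) and sub-phase durations (% of gait cycle)."""

    cycle: float
    dsp1: float
    ssp1: float
    dsp2: float
    swing: float

    def __post_init__(self) -> None:
        parts = (self.dsp1, self.ssp1, self.dsp2, self.swing)
        if abs(sum(parts) - 100.0) > 1e-9:
            raise GaitgenError("phase percentages must sum to 100")
        if not all(0.0 < p < 100.0 for p in parts):
            raise GaitgenError("phase percentages must lie in (0, 100)")


@dataclass
class GaitCycle:
    """One stride, time-normalized onto a uniform percent grid.

    ``channels`` maps channel names (ACP X/Y/Z in cm, AJA A1/A2/A3 in deg) to
    arrays on the grid; ``events`` holds event timings in percent of the cycle
    with ``ic`` pinned at 0.
    """

    percent: np.ndarray
    channels: dict[str, np.ndarray]
    events: dict[str, float]
    duration: float
    speed: float = float("nan")

    def __post_init__(self) -> None:
        self.percent = np.asarray(self.percent, dtype=float)
        if self.percent[0] != 0.0 or self.percent[-1] != 100.0:
            raise GaitgenError("percent grid must start at 0 and end at 100")
        n = len(self.percent)
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        for name, v in self.channels.items():
            if v.shape != (n,):
                raise GaitgenError(f"channel '{name}' length does not match grid")
        pct = [self.events[k] for k in ("ic", "oto", "oic", "to") if k in self.events]
        if any(not (0.0 <= p < 100.0) for p in pct) or any(
            a >= b for a, b in zip(pct, pct[1:])
        ):
            raise GaitgenError(f"event percents out of order or range: {self.events}")


def _vertical(series: MarkerSeries, up_axis: int) -> np.ndarray:
    return series.positions[:, up_axis]


def _lowpass(z: np.ndarray, t: np.ndarray, cutoff_hz: float) -> np.ndarray:
    """Zero-phase Butterworth low-pass; passthrough when the rate is too low."""
    from scipy.signal import butter, filtfilt

    fs = 1.0 / float(np.median(np.diff(t)))
    if cutoff_hz <= 0 or cutoff_hz >= 0.45 * fs or len(z) < 12:
        return z
    b, a = butter(2, cutoff_hz / (fs / 2.0))
    return filtfilt(b, a, z)


def _debounce(below: np.ndarray, min_samples: int) -> np.ndarray:
    """Remove contact/flight runs shorter than ``min_samples``."""
    out = below.copy()
    for target in (True, False):  # drop short contacts first, then short flights
        edges = np.flatnonzero(np.diff(out.astype(int))) + 1
        bounds = np.concatenate([[0], edges, [len(out)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            if out[a] == target and (b - a) < min_samples:
                out[a:b] = not target
    return out


def _contact_intervals(
    z: np.ndarray,
    t: np.ndarray,
    threshold_frac: float,
    smooth_cutoff_hz: float = 12.0,
    min_phase_s: float = 0.15,
) -> tuple[np.ndarray, np.ndarray]:
    """Entry and exit times of below-threshold (contact) intervals.

    Stance level is the 10th percentile of the vertical position; the threshold
    sits ``threshold_frac`` of the way from stance level to the maximum.
    Crossings are located by linear interpolation, then refined by
    extrapolating the local slope from the crossing down to stance level.
    """
    z = _lowpass(np.asarray(z, dtype=float), t, smooth_cutoff_hz)
    level = np.percentile(z, 10)
    amp = z.max() - level
    if amp <= 0:
        raise InsufficientDataError("marker shows no vertical excursion (no gait)")
    thr = level + threshold_frac * amp

    fs = 1.0 / float(np.median(np.diff(t)))
    below = _debounce(z < thr, max(int(round(min_phase_s * fs)), 1))
    d = np.diff(below.astype(int))
    entries_idx = np.nonzero(d == 1)[0]  # crossing between i and i+1, downward
    exits_idx = np.nonzero(d == -1)[0]  # upward

    def cross_time(i: int) -> float:
        z0, z1 = z[i], z[i + 1]
        if z1 == z0:
            return float(t[i])
        return float(t[i] + (thr - z0) / (z1 - z0) * (t[i + 1] - t[i]))

    def slope(j0: int, j1: int) -> float:
        j0, j1 = max(j0, 0), min(j1, len(z) - 1)
        if j1 <= j0:
            return 0.0
        return float((z[j1] - z[j0]) / (t[j1] - t[j0]))

    # one-sided slopes on the airborne side of the crossing, so the flat
    # stance region never dilutes the extrapolation
    entries = []
    for i in entries_idx:
        tc, s = cross_time(i), slope(i - 1, i)
        entries.append(tc + (thr - level) / abs(s) if s < 0 else tc)
    exits = []
    for i in exits_idx:
        tc, s = cross_time(i), slope(i + 1, i + 2)
        exits.append(tc - (thr - level) / abs(s) if s > 0 else tc)
    return np.asarray(entries), np.asarray(exits)


def detect_contacts(
    heel: MarkerSeries,
    toe: MarkerSeries,
    up_axis: int = 2,
    threshold_frac: float = 0.08,
) -> tuple[np.ndarray, np.ndarray]:
    """Initial-contact and toe-off times (s) for one leg.

    IC comes from heel-height contact entries, TO from toe-height contact
    exits.  ``threshold_frac`` is the contact threshold as a fraction of the
    marker's vertical excursion above stance level.
    """
    ics, _ = _contact_intervals(_vertical(heel, up_axis), heel.times, threshold_frac)
    _, tos = _contact_intervals(_vertical(toe, up_axis), toe.times, threshold_frac)
    if len(ics) < 2:
        raise InsufficientDataError(f"detected {len(ics)} initial contacts; need at least 2")
    return ics, tos


def detect_events(
    heel: MarkerSeries,
    toe: MarkerSeries,
    opp_heel: MarkerSeries,
    opp_toe: MarkerSeries,
    up_axis: int = 2,
    threshold_frac: float = 0.08,
) -> list[GaitEventSet]:
    """Segment complete strides of the concerned leg into event sets.

    Opposite-leg events (OTO, OIC) are taken from the contralateral heel/toe
    markers.  Strides whose five events cannot be ordered are dropped.
    """
    ics, tos = detect_contacts(heel, toe, up_axis, threshold_frac)
    o_ics, o_tos = detect_contacts(opp_heel, opp_toe, up_axis, threshold_frac)

    events: list[GaitEventSet] = []
    for ic, next_ic in zip(ics[:-1], ics[1:]):
        def _first_in(cands: np.ndarray) -> float | None:
            inside = cands[(cands > ic) & (cands < next_ic)]
            return float(inside[0]) if len(inside) else None

        oto, oic, to = _first_in(o_tos), _first_in(o_ics), _first_in(tos)
        if None in (oto, oic, to):
            continue
        try:
            events.append(GaitEventSet(float(ic), oto, oic, to, float(next_ic)))
        except GaitgenError:
            continue
    if not events:
        raise InsufficientDataError("no complete stride with ordered events found")
    return events


def phase_durations(ev: GaitEventSet) -> PhaseDurations:
    """Cycle duration and DSP1/SSP1/DSP2/swing percentages for one stride."""
    cycle = ev.next_ic - ev.ic
    if cycle <= 0:
        raise GaitgenError("non-positive cycle duration")
    return PhaseDurations(
        cycle=cycle,
        dsp1=100.0 * (ev.oto - ev.ic) / cycle,
        ssp1=100.0 * (ev.oic - ev.oto) / cycle,
        dsp2=100.0 * (ev.to - ev.oic) / cycle,
        swing=100.0 * (ev.next_ic - ev.to) / cycle,
    )


def segment_normalize(
    channels: dict[str, tuple[np.ndarray, np.ndarray]],
    ev: GaitEventSet,
    n_points: int = 101,
    speed: float = float("nan"),
) -> GaitCycle:
    """Resample channels over one stride onto a uniform percent grid.

    ``channels`` maps channel name to ``(times, values)`` pairs; every channel
    must cover ``[ic, next_ic]``.  Linear interpolation; 101 points by default
    so integer percents are exact grid nodes.
    """
    if n_points < 2:
        raise GaitgenError("n_points must be >= 2")
    pct = np.linspace(0.0, 100.0, n_points)
    t_grid = ev.ic + (pct / 100.0) * (ev.next_ic - ev.ic)
    out: dict[str, np.ndarray] = {}
    for name, (t, v) in channels.items():
        t = np.asarray(t, dtype=float)
        v = np.asarray(v, dtype=float)
        if t[0] > ev.ic + 1e-9 or t[-1] < ev.next_ic - 1e-9:
            raise CoverageError(f"channel '{name}' does not cover the stride")
        out[name] = np.interp(t_grid, t, v)
    return GaitCycle(
        percent=pct,
        channels=out,
        events=ev.as_percent(),
        duration=ev.next_ic - ev.ic,
        speed=speed,
    )


def compute_fpa(
    heel: MarkerSeries,
    toe: MarkerSeries,
    ev: GaitEventSet,
    forward=(1.0, 0.0, 0.0),
    up=(0.0, 0.0, 1.0),
    side: str = "right",
    window: tuple[float, float] | None = None,
) -> float:
    """Foot progression angle (deg, toe-out positive) over the foot-flat window.

    The heel->toe vector is projected onto the laboratory transverse plane and
    its signed angle to the forward axis is averaged over the foot-flat window,
    approximated by default as [OTO, OIC].  ``side`` fixes the toe-out sign
    (outward is lateral to the stance leg).
    """
    if side not in ("right", "left"):
        raise GaitgenError("side must be 'right' or 'left'")
    fwd = np.asarray(forward, dtype=float)
    fwd = fwd / np.linalg.norm(fwd)
    upv = np.asarray(up, dtype=float)
    upv = upv / np.linalg.norm(upv)
    lateral = np.cross(fwd, upv)  # right-hand side of the lab
    if side == "left":
        lateral = -lateral

    t0, t1 = window if window is not None else (ev.oto, ev.oic)
    if not (ev.ic <= t0 < t1 <= ev.to):
        raise WindowError(f"foot-flat window ({t0}, {t1}) not inside stance")
    mask = (heel.times >= t0) & (heel.times <= t1)
    if not np.any(mask):
        raise WindowError("foot-flat window contains no samples")
    foot = toe.positions[mask] - heel.positions[mask]
    ang = np.degrees(np.arctan2(foot @ lateral, foot @ fwd))
    return float(np.mean(ang))
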