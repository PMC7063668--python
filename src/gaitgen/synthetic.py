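"""Synthetic treadmill gait with embedded ground truth.

No public motion-capture dataset accompanies the method, so every pipeline
stage is exercised against simulated trials whose ground truth is known by
construction:

* a cohort of subjects with Gaussian structure parameters (height, foot
  length/width, foot progression angle) inside physiological ranges;
* per-channel gait trajectories built from two phase-locked harmonics of the
  gait cycle, with amplitudes programmed to depend on the motion and
  structure parameters (stride-scaled X, height/speed-scaled Z, FPA-scaled Y
  and A2/A3, speed/foot-length-scaled A1) and cycle duration decreasing with
  speed;
* marker-level trials (Helen Hayes pelvis triad, hip/knee/ankle centers,
  heel/toe of both feet) consistent with the programmed events, the
  programmed FPA and a moving, gently yawing pelvis, plus iid Gaussian
  marker noise (default SD 0.2 cm, emulating jitter of a 100 Hz capture).

Harmonic phases place each channel's global extremes mid-way between
gait-event knots (~25-35% and ~75-85% of the cycle); see the methods note
for why this keeps the downstream spline benchmark well conditioned.

All randomness flows through explicit integer seeds / numpy Generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .events import CHANNEL_NAMES, GaitCycle, GaitEventSet
from .exceptions import GaitgenError, InsufficientDataError
from .frames import MarkerSeries

__all__ = [
    "CohortParams",
    "SyntheticSubject",
    "SyntheticTrial",
    "cycle_duration",
    "stance_fraction",
    "simulate_subject",
    "simulate_cohort",
    "simulate_trial",
    "simulate_cycles",
    "simulate_feature_table",
    "default_feature_effects",
]

SPEEDS_KMH = (3.0, 3.5, 4.0, 4.5, 5.0)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def cycle_duration(speed_kmh: float, height_cm: float) -> float:
    """Gait cycle duration (s): shorter at higher speed, longer for taller subjects."""
    return 1.06 * (height_cm / 168.8) ** 0.45 * (4.0 / speed_kmh) ** 0.42


def stance_fraction(speed_kmh: float) -> float:
    """Stance fraction of the cycle: 0.60 at 4 km/h, decreasing mildly with speed."""
    return 0.60 - 0.012 * (speed_kmh - 4.0)


@dataclass
class CohortParams:
    """Distributions of the structure parameters across the simulated cohort."""

    height_mean: float = 168.8
    height_sd: float = 5.64
    foot_length_mean: float = 25.0
    foot_length_sd: float = 1.5
    foot_width_mean: float = 9.5
    foot_width_sd: float = 0.8
    fpa_mean: float = 7.0
    fpa_sd: float = 4.0
    phase_jitter_sd: float = 0.003  # cycles (subject template vs cohort template)
    amplitude_jitter_sd: float = 0.015  # relative (subject template)


@dataclass
class SyntheticSubject:
    """One simulated participant with fixed structure parameters.

    ``phase_jitter`` and ``amp_jitter`` hold small per-channel deviations from
    the cohort template so that subjects differ in shape, not only in the
    programmed parameter dependencies.
    """

    height: float
    foot_length: float
    foot_width: float
    fpa_true: float
    phase_jitter: dict[str, float] = field(default_factory=dict)
    amp_jitter: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (150.0 <= self.height <= 195.0):
            raise GaitgenError(f"height {self.height} outside physiological range")
        if not (20.0 <= self.foot_length <= 30.0):
            raise GaitgenError(f"foot length {self.foot_length} outside range")
        if not (-5.0 <= self.fpa_true <= 20.0):
            raise GaitgenError(f"FPA {self.fpa_true} outside range")

    @property
    def params(self) -> dict[str, float]:
        return {
            "height": self.height,
            "fpa": self.fpa_true,
            "foot_length": self.foot_length,
            "foot_width": self.foot_width,
        }

    # -- programmed channel amplitudes ------------------------------------
    def stride_length_cm(self, speed_kmh: float) -> float:
        return speed_kmh / 3.6 * 100.0 * cycle_duration(speed_kmh, self.height)

    def amplitudes(self, speed_kmh: float) -> dict[str, float]:
        """Primary-harmonic amplitude of each channel at one speed."""
        j = self.amp_jitter
        return {
            "X": 0.21 * self.stride_length_cm(speed_kmh) * (1 + j.get("X", 0.0)),
            "Y": (1.5 + 0.08 * self.fpa_true) * (1 + j.get("Y", 0.0)),
            "Z": (2.0 + 0.30 * (speed_kmh - 4.0) + 0.05 * (self.height - 168.8))
            * (1 + j.get("Z", 0.0)),
            "A1": (12.0 + 1.1 * (speed_kmh - 4.0) + 0.25 * (self.foot_length - 25.0))
            * (1 + j.get("A1", 0.0)),
            "A2": (3.0 + 0.12 * self.fpa_true) * (1 + j.get("A2", 0.0)),
            "A3": (2.5 + 0.15 * (self.foot_width - 9.5)) * (1 + j.get("A3", 0.0)),
        }

    def offsets(self) -> dict[str, float]:
        """Cycle-mean value of each channel (hip-frame; x posterior, y left, z down)."""
        return {
            "X": 2.0,
            "Y": -(0.05 * self.height + 0.2 * self.foot_width),
            "Z": 0.47 * self.height,
            "A1": 1.5,
            "A2": 0.8,
            "A3": -1.5 + 0.30 * self.fpa_true,
        }

    def channel_functions(self, speed_kmh: float) -> dict[str, Callable[[np.ndarray], np.ndarray]]:
        """Analytic hip-frame ACP (cm) and AJA (deg) as functions of cycle phase in [0, 1)."""
        amp = self.amplitudes(speed_kmh)
        off = self.offsets()
        pj = self.phase_jitter

        # primary-harmonic peak phases, chosen mid-gap between event knots
        peaks = {"X": 0.78, "Y": 0.78, "Z": 0.32, "A1": 0.75, "A2": 0.27, "A3": 0.77}
        second = {"X": 0.06, "Y": 0.0, "Z": 0.15, "A1": 0.20, "A2": 0.0, "A3": 0.0}

        def make(ch: str) -> Callable[[np.ndarray], np.ndarray]:
            p = peaks[ch] + pj.get(ch, 0.0)
            a, b, o = amp[ch], second[ch] * amp[ch], off[ch]

            def f(phi):
                phi = np.asarray(phi, dtype=float)
                return (
                    o
                    + a * np.cos(2 * np.pi * (phi - p))
                    + b * np.cos(4 * np.pi * (phi - p) + 0.8)
                )

            return f

        return {ch: make(ch) for ch in CHANNEL_NAMES}

    # -- ground-truth cycles and features ---------------------------------
    def event_phases(self, speed_kmh: float) -> dict[str, float]:
        c = stance_fraction(speed_kmh)
        return {"ic": 0.0, "oto": c - 0.5, "oic": 0.5, "to": c}

    def true_cycle(self, speed_kmh: float, n_points: int = 101) -> GaitCycle:
        """Noise-free normalized cycle straight from the analytic channels."""
        pct = np.linspace(0.0, 100.0, n_points)
        funcs = self.channel_functions(speed_kmh)
        ev = self.event_phases(speed_kmh)
        return GaitCycle(
            percent=pct,
            channels={ch: f(pct / 100.0) for ch, f in funcs.items()},
            events={k: 100.0 * v for k, v in ev.items()},
            duration=cycle_duration(speed_kmh, self.height),
            speed=speed_kmh,
        )

    def true_features(self, speed_kmh: float, resolution: int = 20001) -> dict[str, float]:
        """Programmed feature values: events analytically, extremes by dense sampling."""
        funcs = self.channel_functions(speed_kmh)
        ev = self.event_phases(speed_kmh)
        phi = np.linspace(0.0, 1.0, resolution)
        out: dict[str, float] = {}
        for ch, f in funcs.items():
            for i, key in enumerate(("ic", "oto", "oic", "to"), start=1):
                out[f"{ch}e{i}"] = float(f(ev[key]))
            v = f(phi[:-1])
            i1, i2 = int(np.argmin(v)), int(np.argmax(v))
            out[f"{ch}f1"], out[f"t{ch}f1"] = float(v[i1]), float(100.0 * phi[i1])
            out[f"{ch}f2"], out[f"t{ch}f2"] = float(v[i2]), float(100.0 * phi[i2])
        c = stance_fraction(speed_kmh)
        out["cycle"] = cycle_duration(speed_kmh, self.height)
        out["dsp1"] = 100.0 * (c - 0.5)
        out["ssp1"] = 100.0 * (1.0 - c)
        out["dsp2"] = 100.0 * (c - 0.5)
        return out


def simulate_subject(seed, cohort: CohortParams | None = None) -> SyntheticSubject:
    """Draw one subject; deterministic for a fixed seed."""
    cohort = cohort or CohortParams()
    rng = _rng(seed)
    height = float(np.clip(rng.normal(cohort.height_mean, cohort.height_sd), 150.0, 195.0))
    fl = float(np.clip(rng.normal(cohort.foot_length_mean, cohort.foot_length_sd), 20.0, 30.0))
    fw = float(np.clip(rng.normal(cohort.foot_width_mean, cohort.foot_width_sd), 7.0, 12.5))
    fpa = float(np.clip(rng.normal(cohort.fpa_mean, cohort.fpa_sd), -5.0, 20.0))
    pj = {ch: float(rng.normal(0.0, cohort.phase_jitter_sd)) for ch in CHANNEL_NAMES}
    aj = {ch: float(rng.normal(0.0, cohort.amplitude_jitter_sd)) for ch in CHANNEL_NAMES}
    return SyntheticSubject(
        height=height,
        foot_length=fl,
        foot_width=fw,
        fpa_true=fpa,
        phase_jitter=pj,
        amp_jitter=aj,
        seed=int(seed) if np.isscalar(seed) and not isinstance(seed, np.random.Generator) else 0,
    )


def simulate_cohort(n_subjects: int, seed, cohort: CohortParams | None = None) -> list[SyntheticSubject]:
    rng = _rng(seed)
    return [simulate_subject(rng, cohort) for _ in range(n_subjects)]


# ---------------------------------------------------------------------------
# marker-level trials


@dataclass
class SyntheticTrial:
    """One treadmill trial: marker series, angle series and all ground truth."""

    speed: float
    markers: dict[str, MarkerSeries]
    aja: dict[str, tuple[np.ndarray, np.ndarray]]
    events_true: list[GaitEventSet]
    fpa_true: float
    acp_true: MarkerSeries
    true_cycle: GaitCycle
    true_features: dict[str, float]
    cycle_duration: float
    stance_frac: float


def _foot_marker_tracks(
    phi: np.ndarray, c: float, s_st: float, lift: float, ground: float
) -> tuple[np.ndarray, np.ndarray]:
    """Forward position and height of a foot marker over cycle phase.

    Stance [0, c): linear backward belt travel at ground height; swing: smooth
    cosine return forward with a half-sine vertical lift (linear near
    touchdown, so contact detection can extrapolate to the exact instant).
    """
    phi = np.mod(phi, 1.0)
    stance = phi < c
    x = np.empty_like(phi)
    z = np.empty_like(phi)
    x[stance] = s_st * (0.5 - phi[stance] / c)
    z[stance] = ground
    u = (phi[~stance] - c) / (1.0 - c)
    x[~stance] = s_st * (-0.5 + 0.5 * (1.0 - np.cos(np.pi * u)))
    z[~stance] = ground + lift * np.sin(np.pi * u)
    return x, z


def simulate_trial(
    subject: SyntheticSubject,
    speed_kmh: float,
    duration: float = 10.0,
    noise_sd: float = 0.2,
    seed=0,
    fs: float = 100.0,
) -> SyntheticTrial:
    """Synthesize one treadmill trial at ``fs`` Hz with marker noise.

    The concerned leg is the right one; left-leg heel/toe markers are phase
    shifted by half a cycle.  Marker positions are in cm in a world frame with
    x forward (belt direction), y left, z up.
    """
    if not 1.0 < speed_kmh < 8.0:
        raise GaitgenError(f"speed {speed_kmh} km/h outside supported range")
    T = cycle_duration(speed_kmh, subject.height)
    if duration < 2.0 * T:
        raise InsufficientDataError("trial must contain at least two gait cycles")
    rng = _rng(seed)

    t = np.arange(0.0, duration, 1.0 / fs)
    t0 = 0.35 * T  # first IC after trial start
    phi = (t - t0) / T
    c = stance_fraction(speed_kmh)

    # pelvis pose: origin oscillates, frame yaws gently about vertical
    hip_height = 0.53 * subject.height
    origin = np.column_stack(
        [
            0.4 * np.sin(2 * np.pi * phi + 0.3),
            0.8 * np.sin(2 * np.pi * phi),
            hip_height + 1.2 * np.sin(4 * np.pi * phi),
        ]
    )
    yaw = np.radians(3.0) * np.sin(2 * np.pi * phi)
    cy, sy = np.cos(yaw), np.sin(yaw)
    # frame axes in world: x posterior, y left, z down, yawed about world z
    x_ax = np.column_stack([-cy, -sy, np.zeros_like(yaw)])
    y_ax = np.column_stack([-sy, cy, np.zeros_like(yaw)])
    z_ax = np.tile([0.0, 0.0, -1.0], (len(t), 1))

    def place(fx: float, fy: float, fz: float) -> np.ndarray:
        return origin + fx * x_ax + fy * y_ax + fz * z_ax

    half_pw = 12.0 + 0.3 * (subject.height - 168.8) / 5.64
    markers: dict[str, np.ndarray] = {
        "R.Asis": place(0.0, -half_pw, 0.0),
        "L.Asis": place(0.0, half_pw, 0.0),
        "V.Sacral": place(9.0, 0.0, 0.0),
    }
    hjc = place(0.0, -9.0, 8.0)
    markers["R.HJC"] = hjc

    funcs = subject.channel_functions(speed_kmh)
    acp = np.column_stack([funcs[ch](phi) for ch in ("X", "Y", "Z")])
    ajc = hjc + acp[:, 0:1] * x_ax + acp[:, 1:2] * y_ax + acp[:, 2:3] * z_ax
    markers["R.AJC"] = ajc
    markers["R.KJC"] = 0.55 * hjc + 0.45 * ajc + np.array([0.0, 0.0, 2.0])

    # feet
    belt_cm_s = speed_kmh / 3.6 * 100.0
    s_st = belt_cm_s * c * T
    theta = np.radians(subject.fpa_true)
    horiz = subject.foot_length - 4.0  # heel-marker to toe-marker distance
    for side, shift, y0, lat in (("R", 0.0, -11.0, -1.0), ("L", 0.5, 11.0, 1.0)):
        xh, zh = _foot_marker_tracks(phi + shift, c, s_st, lift=10.0, ground=3.0)
        heel = np.column_stack([xh, np.full_like(xh, y0), zh])
        _, zt = _foot_marker_tracks(phi + shift, c, s_st, lift=6.0, ground=2.0)
        toe = heel + np.array([horiz * np.cos(theta), lat * horiz * np.sin(theta), 0.0])
        toe[:, 2] = zt
        markers[f"{side}.Heel"] = heel
        markers[f"{side}.Toe"] = toe

    marker_series = {
        name: MarkerSeries(name=name, times=t, positions=pos + rng.normal(0.0, noise_sd, pos.shape))
        for name, pos in markers.items()
    }

    aja = {ch: (t, funcs[ch](phi)) for ch in ("A1", "A2", "A3")}

    # ground-truth events for every complete right stride inside the trial
    events_true = []
    k = 0
    while t0 + (k + 1) * T <= t[-1]:
        ic = t0 + k * T
        events_true.append(
            GaitEventSet(
                ic=ic,
                oto=ic + (c - 0.5) * T,
                oic=ic + 0.5 * T,
                to=ic + c * T,
                next_ic=ic + T,
            )
        )
        k += 1
    if len(events_true) < 1:
        raise InsufficientDataError("trial too short for a complete stride")

    return SyntheticTrial(
        speed=speed_kmh,
        markers=marker_series,
        aja=aja,
        events_true=events_true,
        fpa_true=subject.fpa_true,
        acp_true=MarkerSeries(name="ACP_true", times=t, positions=acp),
        true_cycle=subject.true_cycle(speed_kmh),
        true_features=subject.true_features(speed_kmh),
        cycle_duration=T,
        stance_frac=c,
    )


# ---------------------------------------------------------------------------
# cycle-level simulation (fast path for cohort studies)


def simulate_cycles(
    subject: SyntheticSubject,
    speed_kmh: float,
    n_strides: int = 3,
    noise_sd_pos: float = 0.3,
    noise_sd_ang: float = 0.5,
    seed=0,
    n_points: int = 101,
    stride_phase_sd: float = 0.006,
    stride_amp_sd: float = 0.03,
) -> list[GaitCycle]:
    """Noisy normalized cycles drawn around the subject's true cycle.

    Skips the marker stage entirely.  Each stride gets its own small phase
    shift and amplitude scale (stride-to-stride variability), then iid
    Gaussian noise per grid point (cm for positions, deg for angles)
    emulating residual measurement error after normalization.
    """
    rng = _rng(seed)
    base = subject.true_cycle(speed_kmh, n_points=n_points)
    funcs = subject.channel_functions(speed_kmh)
    offsets = subject.offsets()
    phi = base.percent / 100.0
    cycles = []
    for _ in range(n_strides):
        dphi = float(rng.normal(0.0, stride_phase_sd))
        scale = float(rng.normal(1.0, stride_amp_sd))
        channels = {}
        for ch, f in funcs.items():
            sd = noise_sd_pos if ch in ("X", "Y", "Z") else noise_sd_ang
            template = offsets[ch] + scale * (f(phi + dphi) - offsets[ch])
            channels[ch] = template + rng.normal(0.0, sd, phi.shape)
        cycles.append(
            GaitCycle(
                percent=base.percent.copy(),
                channels=channels,
                events=dict(base.events),
                duration=base.duration * float(rng.normal(1.0, 0.01)),
                speed=speed_kmh,
            )
        )
    return cycles


# ---------------------------------------------------------------------------
# feature-table-level simulation (for regression studies)


def default_feature_effects() -> dict[str, dict]:
    """Programmed feature-vs-parameter dependencies for regression studies.

    Each entry: intercept plus polynomial coefficients on centered predictors
    (speed centered at 4 km/h, cubic; structure parameters centered at their
    cohort means, linear) and the true predictor set implied by them.
    """
    return {
        "featA": {"intercept": 10.0, "v": (1.5, 0.0, 0.8)},
        "featB": {"intercept": -3.0, "height": 0.5},
        "featC": {"intercept": 25.0, "v": (2.0, 0.0, 0.6), "height": 0.4},
        "featD": {"intercept": 5.0, "fpa": 0.6, "foot_length": 0.9},
        "featE": {"intercept": 0.0},
        "featF": {"intercept": 12.0, "foot_width": 1.2},
    }


_CENTERS = {"v": 4.0, "height": 168.8, "fpa": 7.0, "foot_length": 25.0, "foot_width": 9.5}


def simulate_feature_table(
    n_subjects: int = 25,
    speeds: Sequence[float] = SPEEDS_KMH,
    seed=0,
    noise_frac: float = 0.1,
    effects: Mapping[str, Mapping] | None = None,
    cohort: CohortParams | None = None,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """A cohort feature table with known dependencies and scaled noise.

    Noise SD per feature is ``noise_frac`` times the range of its systematic
    part over the cohort (unit SD for pure-noise features).  Returns the tidy
    table (one row per subject x speed) and the true predictor set per
    feature.
    """
    effects = effects or default_feature_effects()
    rng = _rng(seed)
    subjects = simulate_cohort(n_subjects, rng, cohort)
    rows = []
    for i, s in enumerate(subjects):
        for v in speeds:
            rows.append({"subject": f"S{i:03d}", "v": float(v), **s.params})
    df = pd.DataFrame(rows)

    truth: dict[str, set[str]] = {}
    for name, eff in effects.items():
        systematic = np.full(len(df), float(eff.get("intercept", 0.0)))
        used: set[str] = set()
        for var, coefs in eff.items():
            if var == "intercept":
                continue
            x = df[var].to_numpy(dtype=float) - _CENTERS[var]
            coefs = np.atleast_1d(coefs)
            for k, ck in enumerate(coefs, start=1):
                if ck != 0.0:
                    systematic = systematic + ck * x**k
                    used.add(var)
        span = float(np.ptp(systematic))
        sd = noise_frac * span if span > 0 else 1.0
        df[name] = systematic + rng.normal(0.0, sd, len(df))
        truth[name] = used
    return df, truth
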