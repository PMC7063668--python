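"""Scalar gait features extracted from normalized cycles.

Per channel (ACP X/Y/Z, AJA A1/A2/A3) the default feature set is:

* ``<ch>e1..<ch>e4`` — channel value at the four gait events
  (e1 = initial contact = 0%, e2 = opposite toe-off, e3 = opposite initial
  contact, e4 = toe-off),
* ``<ch>f1`` / ``<ch>f2`` — global minimum / maximum over the cycle, with
  their relative timings ``t<ch>f1`` / ``t<ch>f2`` (% of cycle; ties broken
  by earliest occurrence),
* ``d<ch>e1..e4``, ``d<ch>f1``, ``d<ch>f2`` — channel derivative with respect
  to percent (central differences on the grid) at events and extremes,

plus the phase features ``cycle`` (s), ``dsp1``, ``ssp1``, ``dsp2`` (%).
Velocities are per-percent so they stay comparable across walking speeds;
multiply by ``100 / cycle`` for per-second units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .events import CHANNEL_NAMES, GaitCycle
from .exceptions import SchemaError

__all__ = [
    "GaitFeature",
    "SP_COLUMNS",
    "PHASE_FEATURES",
    "extract_event_amplitudes",
    "extract_extremes",
    "extract_velocities",
    "extract_all",
    "feature_names",
    "build_feature_table",
]

SP_COLUMNS = ("height", "fpa", "foot_length", "foot_width")
PHASE_FEATURES = ("cycle", "dsp1", "ssp1", "dsp2")
EVENT_KEYS = ("ic", "oto", "oic", "to")  # e1..e4


@dataclass(frozen=True)
class GaitFeature:
    """One named scalar feature: e.g. ('Z', 'f1', -82.1, 'cm')."""

    channel: str
    kind: str
    value: float
    units: str

    @property
    def name(self) -> str:
        if self.kind.startswith("t_"):
            return f"t{self.channel}{self.kind[2:]}"
        if self.kind.startswith("d_"):
            return f"d{self.channel}{self.kind[2:]}"
        return f"{self.channel}{self.kind}"


def _channel_units(channel: str) -> str:
    return "cm" if channel in ("X", "Y", "Z") else "deg"


def _event_percents(cycle: GaitCycle) -> list[float]:
    return [cycle.events[k] for k in EVENT_KEYS]


def extract_event_amplitudes(cycle: GaitCycle) -> list[GaitFeature]:
    """Channel values at the four gait events (e1..e4), read off the grid."""
    pcts = _event_percents(cycle)
    out = []
    for ch, v in cycle.channels.items():
        u = _channel_units(ch)
        for i, p in enumerate(pcts, start=1):
            out.append(GaitFeature(ch, f"e{i}", float(np.interp(p, cycle.percent, v)), u))
    return out


def extract_extremes(cycle: GaitCycle) -> list[GaitFeature]:
    """Global minimum (f1) and maximum (f2) per channel, with relative timings."""
    out = []
    for ch, v in cycle.channels.items():
        u = _channel_units(ch)
        i1, i2 = int(np.argmin(v)), int(np.argmax(v))  # argmin/argmax: earliest tie
        out.append(GaitFeature(ch, "f1", float(v[i1]), u))
        out.append(GaitFeature(ch, "t_f1", float(cycle.percent[i1]) % 100.0, "%"))
        out.append(GaitFeature(ch, "f2", float(v[i2]), u))
        out.append(GaitFeature(ch, "t_f2", float(cycle.percent[i2]) % 100.0, "%"))
    return out


def extract_velocities(cycle: GaitCycle) -> list[GaitFeature]:
    """Per-percent channel derivatives at the events and at the extremes."""
    pcts = _event_percents(cycle)
    out = []
    for ch, v in cycle.channels.items():
        u = _channel_units(ch) + "/%"
        dv = np.gradient(v, cycle.percent)
        for i, p in enumerate(pcts, start=1):
            out.append(GaitFeature(ch, f"d_e{i}", float(np.interp(p, cycle.percent, dv)), u))
        i1, i2 = int(np.argmin(v)), int(np.argmax(v))
        out.append(GaitFeature(ch, "d_f1", float(dv[i1]), u))
        out.append(GaitFeature(ch, "d_f2", float(dv[i2]), u))
    return out


def extract_all(
    cycle: GaitCycle,
    amplitudes: bool = True,
    extremes: bool = True,
    velocities: bool = True,
    phases: bool = True,
) -> dict[str, float]:
    """All features of one cycle as a flat name -> value mapping."""
    feats: list[GaitFeature] = []
    if amplitudes:
        feats += extract_event_amplitudes(cycle)
    if extremes:
        feats += extract_extremes(cycle)
    if velocities:
        feats += extract_velocities(cycle)
    out = {f.name: f.value for f in feats}
    if phases:
        out["cycle"] = cycle.duration
        out["dsp1"] = cycle.events["oto"]
        out["ssp1"] = cycle.events["oic"] - cycle.events["oto"]
        out["dsp2"] = cycle.events["to"] - cycle.events["oic"]
    return out


def feature_names(
    channels: Iterable[str] = CHANNEL_NAMES, velocities: bool = True, phases: bool = True
) -> list[str]:
    """The default feature enumeration, in extraction order."""
    names: list[str] = []
    for ch in channels:
        names += [f"{ch}e{i}" for i in range(1, 5)]
        names += [f"{ch}f1", f"t{ch}f1", f"{ch}f2", f"t{ch}f2"]
        if velocities:
            names += [f"d{ch}e{i}" for i in range(1, 5)] + [f"d{ch}f1", f"d{ch}f2"]
    if phases:
        names += list(PHASE_FEATURES)
    return names


def build_feature_table(
    cycles: Iterable[tuple[str, float, GaitCycle]],
    subjects: Mapping[str, Mapping[str, float]] | pd.DataFrame,
    velocities: bool = True,
) -> pd.DataFrame:
    """Aggregate cycle features into a tidy cohort table.

    Parameters
    ----------
    cycles:
        Iterable of ``(subject_id, speed_kmh, GaitCycle)``; features are
        averaged over strides within each subject x speed cell.
    subjects:
        Per-subject structure parameters; must provide ``height``, ``fpa``,
        ``foot_length`` and ``foot_width`` (FPA is computed upstream from the
        subject's trials).

    Returns
    -------
    DataFrame with one row per subject x speed, columns ``subject``, ``v``
    (speed, km/h), the SP columns and every extracted feature.
    """
    if isinstance(subjects, pd.DataFrame):
        subjects = subjects.set_index("subject").to_dict("index") if "subject" in subjects else subjects.to_dict("index")
    rows = []
    for subject, speed, cyc in cycles:
        if subject not in subjects:
            raise SchemaError(f"no structure parameters for subject {subject!r}")
        meta = subjects[subject]
        missing = [c for c in SP_COLUMNS if c not in meta or not np.isfinite(meta[c])]
        if missing:
            raise SchemaError(f"subject {subject!r} missing SP column(s): {missing}")
        row = {"subject": subject, "v": float(speed)}
        row.update({c: float(meta[c]) for c in SP_COLUMNS})
        row.update(extract_all(cyc, velocities=velocities))
        rows.append(row)
    if not rows:
        raise SchemaError("no cycles supplied")
    df = pd.DataFrame(rows)
    keys = ["subject", "v"] + list(SP_COLUMNS)
    return df.groupby(keys, as_index=False, sort=True).mean()
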