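"""Readers and writers: TRC marker files, wide CSV dialect, tables and JSON artifacts.

All positions are cm internally; TRC files commonly store mm, so the readers
take a ``units`` override or honour the Units field of the TRC header.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .events import GaitEventSet
from .exceptions import SchemaError
from .frames import MarkerSeries
from .generation import GeneratedGait
from .regression import ModelSet

__all__ = [
    "read_trc",
    "write_trc",
    "read_markers_csv",
    "write_markers_csv",
    "write_events_csv",
    "write_generated_gait",
    "read_generated_gait",
    "save_model_set",
    "load_model_set",
]

_UNIT_TO_CM = {"mm": 0.1, "cm": 1.0, "m": 100.0}


def read_trc(path, units: str | None = None) -> dict[str, MarkerSeries]:
    """Read a TRC marker file into labelled series (positions converted to cm)."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 6:
        raise SchemaError(f"{path}: truncated TRC file")
    header_keys = lines[1].split("\t")
    header_vals = lines[2].split("\t")
    header = dict(zip(header_keys, header_vals))
    file_units = units or header.get("Units", "mm")
    if file_units not in _UNIT_TO_CM:
        raise SchemaError(f"{path}: unknown units {file_units!r}")
    scale = _UNIT_TO_CM[file_units]

    labels = [c for c in lines[3].split("\t")[2:] if c]
    data = np.loadtxt([ln for ln in lines[5:] if ln.strip()], delimiter="\t")
    times = data[:, 1]
    out = {}
    for i, name in enumerate(labels):
        cols = data[:, 2 + 3 * i : 5 + 3 * i] * scale
        out[name] = MarkerSeries(name=name, times=times, positions=cols)
    return out


def write_trc(path, markers: Mapping[str, MarkerSeries], units: str = "cm") -> None:
    """Write labelled marker series as a TRC file (default: keep cm)."""
    scale = 1.0 / _UNIT_TO_CM[units]
    names = list(markers)
    times = markers[names[0]].times
    rate = 1.0 / float(np.mean(np.diff(times))) if len(times) > 1 else 0.0
    n = len(times)
    lines = [
        f"PathFileType\t4\t(X/Y/Z)\t{Path(path).name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\tOrigDataStartFrame\tOrigNumFrames",
        f"{rate:.2f}\t{rate:.2f}\t{n}\t{len(names)}\t{units}\t{rate:.2f}\t1\t{n}",
        "Frame#\tTime\t" + "\t".join(f"{nm}\t\t" for nm in names),
        "\t\t" + "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(len(names))),
    ]
    for k in range(n):
        row = [str(k + 1), f"{times[k]:.6f}"]
        for nm in names:
            row += [f"{v * scale:.6f}" for v in markers[nm].positions[k]]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_markers_csv(path, units: str = "cm") -> dict[str, MarkerSeries]:
    """Wide CSV dialect: a ``time`` column plus ``<marker>_X/_Y/_Z`` triples."""
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise SchemaError(f"{path}: wide marker CSV requires a 'time' column")
    scale = _UNIT_TO_CM[units]
    names = sorted({c[:-2] for c in df.columns if c.endswith("_X")})
    out = {}
    for nm in names:
        missing = [f"{nm}_{ax}" for ax in "XYZ" if f"{nm}_{ax}" not in df.columns]
        if missing:
            raise SchemaError(f"{path}: marker {nm!r} missing columns {missing}")
        pos = df[[f"{nm}_{ax}" for ax in "XYZ"]].to_numpy(dtype=float) * scale
        out[nm] = MarkerSeries(name=nm, times=df["time"].to_numpy(dtype=float), positions=pos)
    return out


def write_markers_csv(path, markers: Mapping[str, MarkerSeries]) -> None:
    names = list(markers)
    data = {"time": markers[names[0]].times}
    for nm in names:
        for j, ax in enumerate("XYZ"):
            data[f"{nm}_{ax}"] = markers[nm].positions[:, j]
    pd.DataFrame(data).to_csv(path, index=False)


def write_events_csv(path, events: list[GaitEventSet]) -> None:
    """Stride events in seconds and in percent of the cycle."""
    rows = []
    for i, ev in enumerate(events):
        pct = ev.as_percent()
        rows.append(
            {
                "stride": i,
                "ic_s": ev.ic,
                "oto_s": ev.oto,
                "oic_s": ev.oic,
                "to_s": ev.to,
                "next_ic_s": ev.next_ic,
                "oto_pct": pct["oto"],
                "oic_pct": pct["oic"],
                "to_pct": pct["to"],
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_generated_gait(csv_path, gait: GeneratedGait) -> None:
    """Generated trajectory as CSV plus a JSON sidecar with provenance."""
    data = {"percent": gait.percent}
    data.update(gait.channels)
    pd.DataFrame(data).to_csv(csv_path, index=False)
    sidecar = {
        "cycle_duration_s": None if np.isnan(gait.duration) else gait.duration,
        "provenance": gait.provenance,
        "knots": {
            ch: [{"t": k.t, "s": k.s, "v": k.v} for k in knots]
            for ch, knots in gait.knots.items()
        },
    }
    Path(str(csv_path) + ".json").write_text(json.dumps(sidecar, indent=2))


def read_generated_gait(csv_path) -> GeneratedGait:
    df = pd.read_csv(csv_path)
    if "percent" not in df.columns:
        raise SchemaError(f"{csv_path}: generated gait CSV requires 'percent'")
    sidecar_path = Path(str(csv_path) + ".json")
    duration = float("nan")
    provenance: dict = {}
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        duration = sidecar.get("cycle_duration_s") or float("nan")
        provenance = sidecar.get("provenance", {})
    return GeneratedGait(
        percent=df["percent"].to_numpy(dtype=float),
        channels={c: df[c].to_numpy(dtype=float) for c in df.columns if c != "percent"},
        duration=duration,
        provenance=provenance,
    )


def save_model_set(path, models: ModelSet) -> None:
    Path(path).write_text(models.to_json())


def load_model_set(path) -> ModelSet:
    return ModelSet.from_json(Path(path).read_text())
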