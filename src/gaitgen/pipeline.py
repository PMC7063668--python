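"""End-to-end orchestration: markers -> cycles -> features -> models -> generated gait.

``process_trial`` runs the per-trial stages (hip-frame ACP, event detection,
stride normalization, FPA); ``run_pipeline`` executes a full synthetic-cohort
study from a config mapping and writes every artifact to disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from . import features as feat
from .events import CHANNEL_NAMES, GaitCycle, compute_fpa, detect_events, segment_normalize
from .exceptions import SchemaError
from .frames import MarkerSeries, acp_in_hip
from .generation import average_baseline, generate_gait
from .io import save_model_set, write_generated_gait
from .metrics import ValidationReport, correlation, rmse
from .regression import fit_model_set, fpa_speed_independence
from .synthetic import SyntheticSubject, simulate_cohort, simulate_cycles, simulate_subject

log = logging.getLogger("gaitgen")

__all__ = ["process_trial", "run_pipeline", "validate_generated"]

_MARKER_ROLES = {
    "right": {"heel": "R.Heel", "toe": "R.Toe", "opp_heel": "L.Heel", "opp_toe": "L.Toe",
              "hjc": "R.HJC", "ajc": "R.AJC"},
    "left": {"heel": "L.Heel", "toe": "L.Toe", "opp_heel": "R.Heel", "opp_toe": "R.Toe",
             "hjc": "L.HJC", "ajc": "L.AJC"},
}


def process_trial(
    markers: Mapping[str, MarkerSeries],
    aja: Mapping[str, tuple[np.ndarray, np.ndarray]],
    speed: float,
    leg: str = "right",
    n_points: int = 101,
    threshold_frac: float = 0.08,
) -> tuple[list[GaitCycle], float]:
    """Per-trial pipeline: returns normalized cycles and the mean FPA (deg)."""
    roles = _MARKER_ROLES[leg]
    required = ["R.Asis", "L.Asis", "V.Sacral"] + list(roles.values())
    missing = [m for m in required if m not in markers]
    if missing:
        raise SchemaError(f"trial missing marker(s): {missing}")

    acp = acp_in_hip(
        ajc=markers[roles["ajc"]],
        rasis=markers["R.Asis"],
        lasis=markers["L.Asis"],
        sacral=markers["V.Sacral"],
        hjc=markers[roles["hjc"]],
    )
    events = detect_events(
        markers[roles["heel"]],
        markers[roles["toe"]],
        markers[roles["opp_heel"]],
        markers[roles["opp_toe"]],
        threshold_frac=threshold_frac,
    )
    channels = {
        "X": (acp.times, acp.positions[:, 0]),
        "Y": (acp.times, acp.positions[:, 1]),
        "Z": (acp.times, acp.positions[:, 2]),
        "A1": aja["A1"],
        "A2": aja["A2"],
        "A3": aja["A3"],
    }
    cycles, fpas = [], []
    for ev in events:
        cycles.append(segment_normalize(channels, ev, n_points=n_points, speed=speed))
        fpas.append(compute_fpa(markers[roles["heel"]], markers[roles["toe"]], ev, side=leg))
    return cycles, float(np.mean(fpas))


def validate_generated(
    generated,
    true_cycles_by_speed: Mapping[float, GaitCycle],
    baseline_by_speed: Mapping[float, object] | None = None,
    channels=CHANNEL_NAMES,
) -> ValidationReport:
    """RMSE/correlation of one generated gait against per-speed true cycles."""
    rmse_speed: dict[str, dict[float, float]] = {ch: {} for ch in channels}
    corr_speed: dict[str, dict[float, float]] = {ch: {} for ch in channels}
    base_rmse: dict[str, list[float]] = {ch: [] for ch in channels}
    for speed, true_cycle in true_cycles_by_speed.items():
        gen = generated[speed] if isinstance(generated, Mapping) else generated
        for ch in channels:
            rmse_speed[ch][speed] = rmse(true_cycle.channels[ch], gen.channels[ch])
            corr_speed[ch][speed] = correlation(true_cycle.channels[ch], gen.channels[ch])
            if baseline_by_speed is not None:
                base_rmse[ch].append(
                    rmse(true_cycle.channels[ch], baseline_by_speed[speed].channels[ch])
                )
    return ValidationReport(
        rmse_channel={ch: float(np.mean(list(d.values()))) for ch, d in rmse_speed.items()},
        corr_channel={ch: float(np.mean(list(d.values()))) for ch, d in corr_speed.items()},
        rmse_speed=rmse_speed,
        corr_speed=corr_speed,
        baseline_rmse_channel={
            ch: float(np.mean(v)) for ch, v in base_rmse.items() if v
        },
    )


_REQUIRED_KEYS = ("seed", "output_dir", "cohort")


def run_pipeline(config: Mapping) -> dict[str, str]:
    """Run simulate -> extract -> fit -> generate -> validate from a config mapping.

    Deterministic for a fixed ``seed``.  Writes ``features.csv``,
    ``models.json``, ``gait_heldout.csv`` (+ JSON sidecar), ``fpa_report.json``,
    ``validation.json`` and ``pipeline.log`` into ``output_dir`` and returns
    the artifact paths.
    """
    for key in _REQUIRED_KEYS:
        if key not in config:
            raise SchemaError(f"pipeline config missing required key {key!r}")
    cohort_cfg = dict(config["cohort"])
    for key in ("n_subjects", "speeds"):
        if key not in cohort_cfg:
            raise SchemaError(f"pipeline config missing required key 'cohort.{key}'")

    out = Path(config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    try:
        seed = int(config["seed"])
        cfg_hash = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
        log.info("pipeline start: seed=%d config_hash=%s", seed, cfg_hash)
        rng = np.random.default_rng(seed)

        speeds = [float(v) for v in cohort_cfg["speeds"]]
        n_sub = int(cohort_cfg["n_subjects"])
        n_strides = int(cohort_cfg.get("n_strides", 3))
        noise_pos = float(cohort_cfg.get("noise_sd_pos", 0.3))
        noise_ang = float(cohort_cfg.get("noise_sd_ang", 0.5))

        # simulate
        subjects = simulate_cohort(n_sub, rng)
        cycles_by = {}
        all_cycles = []
        for i, s in enumerate(subjects):
            sid = f"S{i:03d}"
            for v in speeds:
                cyc = simulate_cycles(s, v, n_strides, noise_pos, noise_ang, seed=rng)
                cycles_by[(sid, v)] = cyc
                all_cycles += [(sid, v, c) for c in cyc]
        meta = {f"S{i:03d}": s.params for i, s in enumerate(subjects)}
        log.info("simulated %d subjects x %d speeds x %d strides", n_sub, len(speeds), n_strides)

        # extract
        fit_cfg = dict(config.get("fit", {}))
        use_velocities = bool(fit_cfg.get("velocities", False))
        table = feat.build_feature_table(all_cycles, meta, velocities=use_velocities)
        table.to_csv(out / "features.csv", index=False)
        log.info("feature table: %d rows x %d cols", *table.shape)

        # FPA-vs-speed report on per-speed FPA measurements (true FPA + noise)
        fpa_rows = [
            {"subject": f"S{i:03d}", "v": v, "fpa": s.fpa_true + float(rng.normal(0, 0.8))}
            for i, s in enumerate(subjects)
            for v in speeds
        ]
        fpa_rep = fpa_speed_independence(pd.DataFrame(fpa_rows))
        (out / "fpa_report.json").write_text(
            json.dumps(
                {
                    "pairs": fpa_rep.pairs,
                    "pvalues": fpa_rep.pvalues,
                    "threshold": fpa_rep.threshold,
                    "any_significant": fpa_rep.any_significant,
                },
                indent=2,
            )
        )

        # fit
        names = feat.feature_names(velocities=use_velocities)
        models = fit_model_set(
            table,
            names,
            alpha=float(fit_cfg.get("alpha", 0.05)),
            coding=fit_cfg.get("coding", "scaled"),
            unit=fit_cfg.get("unit", "subject"),
        )
        save_model_set(out / "models.json", models)
        n_const = sum(1 for m in models.models.values() if not m.terms)
        log.info("fitted %d feature models (%d constant)", len(models.models), n_const)

        # generate for a held-out subject
        gen_cfg = dict(config.get("generate", {}))
        heldout = simulate_subject(int(gen_cfg.get("subject_seed", seed + 10_000)))
        n_points = int(gen_cfg.get("n_points", 101))
        generated = {}
        for v in speeds:
            params = {"v": v, **heldout.params}
            generated[v] = generate_gait(models, params, n_points=n_points, guard_frac=None)
        write_generated_gait(out / "gait_heldout.csv", generated[speeds[len(speeds) // 2]])

        # validate against the held-out subject's true cycles, vs averaging baseline
        true_by_speed = {v: heldout.true_cycle(v, n_points=n_points) for v in speeds}
        baseline_by_speed = {
            v: average_baseline([c for (sid, vv, c) in all_cycles if vv == v]) for v in speeds
        }
        report = validate_generated(generated, true_by_speed, baseline_by_speed)
        per_speed_rmse = [
            float(np.mean([report.rmse_speed[ch][v] for ch in CHANNEL_NAMES])) for v in speeds
        ]
        rho = float(_sstats.spearmanr(speeds, per_speed_rmse).statistic) if len(speeds) > 2 else 0.0
        payload = report.to_dict()
        payload["speed_trend_spearman"] = rho
        (out / "validation.json").write_text(json.dumps(payload, indent=2))
        log.info("validation: mean RMSE per channel %s", report.rmse_channel)

        return {
            "features": str(out / "features.csv"),
            "models": str(out / "models.json"),
            "gait": str(out / "gait_heldout.csv"),
            "fpa_report": str(out / "fpa_report.json"),
            "validation": str(out / "validation.json"),
            "log": str(out / "pipeline.log"),
        }
    finally:
        log.removeHandler(handler)
        handler.close()
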