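"""Validation metrics: RMSE and Pearson correlation between trajectories."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import AlignmentError, UndefinedCorrelationError

__all__ = ["rmse", "correlation", "ValidationReport"]


def rmse(actual, generated) -> float:
    """Root mean square pointwise difference of two equal-length series."""
    a = np.asarray(actual, dtype=float)
    g = np.asarray(generated, dtype=float)
    if a.shape != g.shape:
        raise AlignmentError(f"series lengths differ: {a.shape} vs {g.shape}")
    return float(np.sqrt(np.mean((a - g) ** 2)))


def correlation(actual, generated) -> float:
    """Pearson correlation; undefined (error) for zero-variance input."""
    a = np.asarray(actual, dtype=float)
    g = np.asarray(generated, dtype=float)
    if a.shape != g.shape:
        raise AlignmentError(f"series lengths differ: {a.shape} vs {g.shape}")
    if np.ptp(a) == 0 or np.ptp(g) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant series")
    return float(np.corrcoef(a, g)[0, 1])


@dataclass
class ValidationReport:
    """Per-channel fit quality of generated trajectories, with per-speed breakdown.

    ``rmse_channel``/``corr_channel`` average over speeds; ``rmse_speed`` maps
    ``channel -> {speed: value}``.  ``baseline_delta`` is baseline RMSE minus
    generated RMSE per channel (positive = parametric generation wins).
    """

    rmse_channel: dict[str, float]
    corr_channel: dict[str, float]
    rmse_speed: dict[str, dict[float, float]] = field(default_factory=dict)
    corr_speed: dict[str, dict[float, float]] = field(default_factory=dict)
    baseline_rmse_channel: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in self.rmse_channel.values():
            if v < 0:
                raise ValueError("RMSE must be non-negative")
        for v in self.corr_channel.values():
            if not -1.0 - 1e-12 <= v <= 1.0 + 1e-12:
                raise ValueError("correlation must lie in [-1, 1]")

    @property
    def baseline_delta(self) -> dict[str, float]:
        return {
            ch: self.baseline_rmse_channel[ch] - self.rmse_channel[ch]
            for ch in self.baseline_rmse_channel
        }

    def to_dict(self) -> dict:
        return {
            "rmse_channel": self.rmse_channel,
            "corr_channel": self.corr_channel,
            "rmse_speed": {c: {str(s): v for s, v in d.items()} for c, d in self.rmse_speed.items()},
            "corr_speed": {c: {str(s): v for s, v in d.items()} for c, d in self.corr_speed.items()},
            "baseline_rmse_channel": self.baseline_rmse_channel,
            "baseline_delta": self.baseline_delta,
        }
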