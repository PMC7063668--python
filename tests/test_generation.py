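"""Cubic Hermite segments, knot assembly and full-cycle reconstruction."""

import numpy as np
import pytest

from gaitgen.events import GaitCycle
from gaitgen.exceptions import AlignmentError, GaitgenError, OrderingError
from gaitgen.features import extract_all
from gaitgen.generation import (
    FeatureKnot,
    average_baseline,
    fit_segment,
    generate_from_features,
    generate_gait,
    knots_from_features,
)
from gaitgen.metrics import rmse
from gaitgen.regression import ModelSet, RegressionModel
from gaitgen.synthetic import simulate_subject


class TestFitSegment:
    def test_canonical_hermite_step(self):
        seg = fit_segment(FeatureKnot(0, 0, 0), FeatureKnot(1, 1, 0))
        np.testing.assert_allclose(seg.coefficients, [0, 0, 3, -2], atol=1e-12)
        t = np.linspace(0, 1, 11)
        np.testing.assert_allclose(seg(t), 3 * t**2 - 2 * t**3, atol=1e-12)

    def test_constant_segment(self):
        seg = fit_segment(FeatureKnot(0, 4.2, 0), FeatureKnot(1, 4.2, 0))
        np.testing.assert_allclose(seg.coefficients, [4.2, 0, 0, 0], atol=1e-12)

    def test_boundary_constraints_random_knots(self, rng):
        for _ in range(100):
            t0, dt = rng.uniform(0, 50), rng.uniform(0.5, 40)
            k0 = FeatureKnot(t0, rng.normal(0, 10), rng.normal(0, 2))
            k1 = FeatureKnot(t0 + dt, rng.normal(0, 10), rng.normal(0, 2))
            seg = fit_segment(k0, k1)
            assert seg(k0.t) == pytest.approx(k0.s, abs=1e-9)
            assert seg(k1.t) == pytest.approx(k1.s, abs=1e-9)
            assert seg.velocity(k0.t) == pytest.approx(k0.v, abs=1e-9)
            assert seg.velocity(k1.t) == pytest.approx(k1.v, abs=1e-9)

    def test_agrees_with_polynomial_interpolation_oracle(self, rng):
        """Independent oracle: solve the global-time Vandermonde system directly."""
        for _ in range(20):
            t0, t1 = 10.0, 10.0 + rng.uniform(1, 30)
            s0, s1, v0, v1 = rng.normal(0, 5, 4)
            A = np.array(
                [
                    [1, t0, t0**2, t0**3],
                    [0, 1, 2 * t0, 3 * t0**2],
                    [1, t1, t1**2, t1**3],
                    [0, 1, 2 * t1, 3 * t1**2],
                ]
            )
            c = np.linalg.solve(A, [s0, v0, s1, v1])
            seg = fit_segment(FeatureKnot(t0, s0, v0), FeatureKnot(t1, s1, v1))
            t = np.linspace(t0, t1, 33)
            np.testing.assert_allclose(seg(t), c @ [np.ones_like(t), t, t**2, t**3], atol=1e-9)

    def test_coincident_knot_times_rejected(self):
        with pytest.raises(GaitgenError):
            fit_segment(FeatureKnot(5, 0, 0), FeatureKnot(5, 1, 0))


def _features(dsp1=10.0, ssp1=40.0, dsp2=10.0, ch="X", **over):
    f = {
        "dsp1": dsp1, "ssp1": ssp1, "dsp2": dsp2, "cycle": 1.1,
        f"{ch}e1": 0.0, f"{ch}e2": 3.0, f"{ch}e3": -1.0, f"{ch}e4": -4.0,
        f"{ch}f1": -5.0, f"t{ch}f1": 75.0, f"{ch}f2": 4.0, f"t{ch}f2": 30.0,
    }
    f.update(over)
    return f


class TestKnots:
    def test_event_knots_at_cumulative_phases(self):
        knots = knots_from_features(_features(), channels=("X",))["X"]
        ts = [k.t for k in knots]
        assert ts == sorted(ts)
        assert {0.0, 10.0, 50.0, 60.0, 75.0, 30.0} == set(ts)

    def test_near_coincident_knots_merged(self):
        knots = knots_from_features(_features(**{"tXf2": 10.3}), channels=("X",))["X"]
        ts = [k.t for k in knots]
        assert len(ts) == 5  # f2 merged into e2
        merged = [k for k in knots if abs(k.t - 10.15) < 1e-9]
        assert merged and merged[0].s == pytest.approx((3.0 + 4.0) / 2)

    def test_unorderable_phases_rejected(self):
        with pytest.raises(OrderingError):
            knots_from_features(_features(dsp1=60.0, ssp1=30.0, dsp2=20.0), channels=("X",))

    def test_velocities_imputed_when_not_modelled(self):
        knots = knots_from_features(_features(), channels=("X",))["X"]
        assert all(k.v is not None for k in knots)


class TestGenerate:
    def test_reconstruction_passes_through_knots(self):
        feats = _features()
        gait = generate_from_features(feats, channels=("X",), n_points=1001)
        knots = gait.knots["X"]
        for k in knots:
            assert np.interp(k.t, gait.percent, gait.channels["X"]) == pytest.approx(
                k.s, abs=1e-6
            )

    def test_periodic_closure_and_c1(self):
        gait = generate_from_features(_features(), channels=("X",), n_points=2001)
        x, p = gait.channels["X"], gait.percent
        assert x[0] == pytest.approx(x[-1], abs=1e-6)
        slope_start = (x[1] - x[0]) / (p[1] - p[0])
        slope_end = (x[-1] - x[-2]) / (p[-1] - p[-2])
        assert slope_start == pytest.approx(slope_end, abs=1e-2)

    def test_c1_at_interior_knots(self):
        gait = generate_from_features(_features(), channels=("X",), n_points=10001)
        x, p = gait.channels["X"], gait.percent
        d = np.gradient(x, p)
        # numerical derivative stays bounded and continuous (no jumps > step-scale)
        assert np.max(np.abs(np.diff(d))) < 0.05

    def test_single_harmonic_reconstruction_error(self):
        """Knots at events+extremes of one harmonic keep RMSE below 5% of amplitude."""
        pct = np.linspace(0, 100, 101)
        amp = 10.0
        signal = amp * np.cos(2 * np.pi * (pct - 78.0) / 100)
        cyc = GaitCycle(
            percent=pct, channels={"X": signal},
            events={"ic": 0.0, "oto": 10.0, "oic": 50.0, "to": 60.0},
            duration=1.0, speed=4.0,
        )
        feats = extract_all(cyc, velocities=True)
        gait = generate_from_features(feats, channels=("X",), n_points=101)
        assert rmse(signal, gait.channels["X"]) < 0.05 * amp

    def test_constant_models_yield_mean_knots(self):
        feats = _features()
        models = ModelSet(
            models={
                k: RegressionModel(feature=k, intercept=v, terms=[], scaling={}, loocv_mse=0.0)
                for k, v in feats.items()
            }
        )
        gait = generate_gait(models, {"v": 4.0}, channels=("X",))
        assert gait.duration == pytest.approx(1.1)
        knot_values = sorted(k.s for k in gait.knots["X"])
        assert knot_values == sorted([0.0, 3.0, -1.0, -4.0, -5.0, 4.0])


class TestAverageBaseline:
    def _cycle(self, values):
        pct = np.linspace(0, 100, 101)
        return GaitCycle(
            percent=pct, channels={"X": np.asarray(values, float)},
            events={"ic": 0.0, "oto": 10.0, "oic": 50.0, "to": 60.0},
            duration=1.0, speed=4.0,
        )

    def test_identical_cycles_unchanged(self):
        pct = np.linspace(0, 100, 101)
        v = np.sin(2 * np.pi * pct / 100)
        out = average_baseline([self._cycle(v), self._cycle(v)])
        np.testing.assert_allclose(out.channels["X"], v, atol=1e-12)

    def test_timing_spread_shrinks_peak(self):
        """Averaging cycles with shifted peaks lowers the averaged peak amplitude."""
        pct = np.linspace(0, 100, 101)
        a = np.exp(-0.5 * ((pct - 30) / 6) ** 2)
        b = np.exp(-0.5 * ((pct - 50) / 6) ** 2)
        out = average_baseline([self._cycle(a), self._cycle(b)])
        assert out.channels["X"].max() < (a.max() + b.max()) / 2

    def test_mismatched_grids_rejected(self):
        c1 = self._cycle(np.zeros(101))
        pct = np.linspace(0, 100, 51)
        c2 = GaitCycle(
            percent=pct, channels={"X": np.zeros(51)},
            events={"ic": 0.0, "oto": 10.0, "oic": 50.0, "to": 60.0},
            duration=1.0, speed=4.0,
        )
        with pytest.raises(AlignmentError):
            average_baseline([c1, c2])


def test_extract_generate_extract_fixed_point():
    """Event/extreme features survive a generate -> re-extract round trip."""
    subject = simulate_subject(2)
    cyc = subject.true_cycle(4.0)  # events at integer percents at 4 km/h
    feats = extract_all(cyc, velocities=True)
    gait = generate_from_features(feats)
    re_cycle = GaitCycle(
        percent=gait.percent, channels=gait.channels, events=cyc.events,
        duration=feats["cycle"], speed=4.0,
    )
    feats2 = extract_all(re_cycle, velocities=False)
    for ch in cyc.channels:
        for kind in ("e1", "e2", "e3", "e4", "f1", "f2"):
            assert feats2[f"{ch}{kind}"] == pytest.approx(feats[f"{ch}{kind}"], abs=1e-6)
        for kind in ("f1", "f2"):
            assert feats2[f"t{ch}{kind}"] == pytest.approx(feats[f"t{ch}{kind}"], abs=1e-6)
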