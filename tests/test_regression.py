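"""Screening, LOOCV model selection, prediction and the FPA-vs-speed test."""

import numpy as np
import pandas as pd
import pytest

from gaitgen.exceptions import ExtrapolationWarning, GaitgenError, PowerWarning
from gaitgen.regression import (
    PREDICTORS,
    ModelSet,
    PredictorSpec,
    RegressionModel,
    anova_screen,
    fpa_speed_independence,
    loocv_mse,
    predict_feature,
    select_model,
)
from gaitgen.synthetic import simulate_feature_table

SPEEDS = (3.0, 3.5, 4.0, 4.5, 5.0)


def _table(n_subjects=25, seed=0, columns=None):
    """A bare cohort grid (subject x speed with SP draws, no features)."""
    df, _ = simulate_feature_table(n_subjects=n_subjects, seed=seed, effects={})
    if columns:
        for k, v in columns.items():
            df[k] = v
    return df


class TestScreen:
    def test_speed_effect_detected(self):
        rng = np.random.default_rng(0)
        df = _table(seed=1)
        df["y"] = 2.0 + 3.0 * df["v"] + rng.normal(0, 0.1, len(df))
        assert anova_screen(df, "y") == ["v"]

    def test_perfect_height_dependence(self):
        df = _table(seed=2)
        df["y"] = df["height"].copy()
        assert anova_screen(df, "y") == ["height"]

    def test_pure_noise_screens_empty(self):
        empties = 0
        for seed in range(20):
            df = _table(seed=seed)
            df["y"] = np.random.default_rng(seed + 1000).normal(0, 1, len(df))
            empties += anova_screen(df, "y") == []
        assert empties >= 18  # family-wise alpha = 0.05

    def test_constant_feature_screens_empty(self):
        df = _table(columns={"y": 7.0})
        assert anova_screen(df, "y") == []

    def test_masked_second_parameter_found(self):
        """Forward residual screening finds an SP hidden behind a stronger one."""
        rng = np.random.default_rng(3)
        df = _table(seed=3)
        df["y"] = 0.8 * df["fpa"] + 0.9 * df["foot_length"] + rng.normal(0, 0.5, len(df))
        assert set(anova_screen(df, "y")) == {"fpa", "foot_length"}


class TestLoocv:
    def test_perfect_linear_model_zero_mse(self):
        df = _table(seed=4)
        df["y"] = 1.0 + 0.5 * df["v"]
        assert loocv_mse(df, "y", {"v": 1}) < 1e-12

    def test_empty_spec_equals_heldout_mean_oracle(self):
        rng = np.random.default_rng(5)
        df = _table(n_subjects=8, seed=5)
        df["y"] = rng.normal(0, 1, len(df))
        got = loocv_mse(df, "y", {})
        errs = []
        for s in sorted(df["subject"].unique()):
            tr, te = df[df["subject"] != s], df[df["subject"] == s]
            errs.append(te["y"].to_numpy() - tr["y"].mean())
        assert got == pytest.approx(float(np.mean(np.concatenate(errs) ** 2)), rel=1e-12)

    def test_matches_brute_force_refit_oracle_bitwise(self):
        """Subject-wise LOOCV equals an independently coded refit-per-fold oracle."""
        rng = np.random.default_rng(6)
        df = _table(n_subjects=6, seed=6)
        df["y"] = 1.0 + 0.4 * df["v"] + 0.1 * df["height"] + rng.normal(0, 0.3, len(df))
        spec = {"v": 2, "height": 1}

        # oracle: documented design layout, full-table scaling, lstsq per fold
        cols = [np.ones(len(df))]
        for var in PREDICTORS:
            if var not in spec:
                continue
            x = df[var].to_numpy(dtype=float)
            coded = (x - np.mean(x)) / np.std(x, ddof=0)
            for k in range(1, spec[var] + 1):
                cols.append(coded**k)
        X = np.column_stack(cols)
        y = df["y"].to_numpy(dtype=float)
        keys = df["subject"].to_numpy()
        errs = []
        for s in sorted(pd.unique(keys)):
            test = keys == s
            beta = np.linalg.lstsq(X[~test], y[~test], rcond=None)[0]
            errs.append(y[test] - X[test] @ beta)
        oracle = float(np.mean(np.concatenate(errs) ** 2))

        assert loocv_mse(df, "y", spec) == oracle  # bitwise

    def test_overfit_noise_spec_worse_than_mean(self):
        worse = 0
        for seed in range(10):
            df = _table(n_subjects=25, seed=seed + 50)
            df["y"] = np.random.default_rng(seed).normal(0, 1, len(df))
            full = {v: 3 for v in PREDICTORS}
            worse += loocv_mse(df, "y", full) > loocv_mse(df, "y", {})
        assert worse >= 8


class TestSelectModel:
    def test_cubic_speed_recovery(self):
        rng = np.random.default_rng(7)
        df = _table(seed=7)
        df["y"] = 1.0 + 0.5 * (df["v"] - 4.0) ** 3 + rng.normal(0, 0.05, len(df))
        m = select_model(df, "y")
        assert m.variables == ("v",)
        assert max(k for v, k, _ in m.terms) == 3

    def test_noise_feature_falls_back_to_exact_mean(self):
        df = _table(seed=8)
        df["y"] = np.random.default_rng(8).normal(0, 1, len(df))
        m = select_model(df, "y", screened=[])
        assert m.terms == []
        assert m.intercept == float(np.mean(df["y"].to_numpy()))
        assert predict_feature(m, {"v": 4.0}) == m.intercept

    def test_linear_height_slope_sign(self):
        rng = np.random.default_rng(9)
        df = _table(seed=9)
        df["y"] = 3.0 - 0.4 * df["height"] + rng.normal(0, 0.3, len(df))
        m = select_model(df, "y")
        assert m.variables == ("height",)
        assert all(k == 1 for _, k, _ in m.terms)
        assert m.terms[0][2] < 0

    def test_noise_predictors_never_improve_selected_mse(self):
        """Offering extra noise predictors cannot beat the true model's LOOCV MSE."""
        hurt = 0
        for seed in range(8):
            rng = np.random.default_rng(seed + 200)
            df = _table(seed=seed + 200)
            df["y"] = 2.0 + 1.2 * (df["v"] - 4.0) + rng.normal(0, 0.2, len(df))
            m_true = select_model(df, "y", screened=["v"])
            m_extra = select_model(df, "y", screened=list(PREDICTORS))
            hurt += m_extra.loocv_mse > m_true.loocv_mse + 1e-9
        assert hurt <= 1


class TestPredict:
    def test_raw_coding_arithmetic(self):
        m = RegressionModel(
            feature="f", intercept=2.0, terms=[("v", 1, 3.0)],
            scaling={"v": (0.0, 1.0)}, loocv_mse=0.0, coding="raw",
        )
        assert predict_feature(m, {"v": 4.0}, guard_frac=None) == pytest.approx(14.0)

    def test_extrapolation_warning(self):
        m = RegressionModel(
            feature="f", intercept=0.0, terms=[("v", 1, 1.0)],
            scaling={"v": (4.0, 1.0)}, loocv_mse=0.0,
            training_range={"v": (3.0, 5.0)},
        )
        with pytest.warns(ExtrapolationWarning):
            predict_feature(m, {"v": 7.0})

    def test_missing_parameter_rejected(self):
        m = RegressionModel(
            feature="f", intercept=0.0, terms=[("v", 1, 1.0)],
            scaling={"v": (0.0, 1.0)}, loocv_mse=0.0,
        )
        with pytest.raises(GaitgenError):
            predict_feature(m, {"height": 170.0})


def test_predictor_spec_validation():
    with pytest.raises(GaitgenError):
        PredictorSpec("v", 4)
    with pytest.raises(GaitgenError):
        PredictorSpec("bmi", 1)


def test_model_set_json_round_trip():
    df = _table(seed=10)
    rng = np.random.default_rng(10)
    df["y"] = 1.0 + 0.7 * (df["v"] - 4.0) + rng.normal(0, 0.1, len(df))
    m = select_model(df, "y")
    ms = ModelSet(models={"y": m}, cohort_stats={"v": {"mean": 4.0, "sd": 0.7}})
    back = ModelSet.from_json(ms.to_json())
    assert back["y"].terms == m.terms
    assert back["y"].intercept == m.intercept
    assert back["y"].loocv_mse == m.loocv_mse
    assert back["y"].scaling == m.scaling


class TestFpaSpeedIndependence:
    def _fpa_table(self, n=25, seed=0, shift_speed=None, shift=5.0):
        rng = np.random.default_rng(seed)
        base = rng.normal(7, 4, n)
        rows = []
        for i in range(n):
            for v in SPEEDS:
                f = base[i] + rng.normal(0, 0.8)
                if shift_speed is not None and v == shift_speed:
                    f += shift
                rows.append({"subject": f"S{i}", "v": v, "fpa": f})
        return pd.DataFrame(rows)

    def test_null_rarely_significant(self):
        hits = 0
        for seed in range(20):
            hits += fpa_speed_independence(self._fpa_table(seed=seed)).any_significant
        assert hits <= 2

    def test_shifted_speed_detected(self):
        rep = fpa_speed_independence(self._fpa_table(seed=1, shift_speed=4.0))
        sig_pairs = [p for p, s in zip(rep.pairs, rep.significant) if s]
        assert (3.5, 4.0) in sig_pairs and (4.0, 4.5) in sig_pairs

    def test_few_subjects_power_warning(self):
        with pytest.warns(PowerWarning):
            fpa_speed_independence(self._fpa_table(n=2, seed=0))

    def test_bonferroni_threshold(self):
        rep = fpa_speed_independence(self._fpa_table(seed=2), m_comparisons=66)
        assert rep.threshold == pytest.approx(0.05 / 66)
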