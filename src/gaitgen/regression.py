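"""Per-feature polynomial regression on the motion and structure parameters.

Each gait feature Y is modelled as

    Y = b0 + sum_i  B_i * R_i(x)

where the R_i are coded powers of the predictors (walking speed ``v`` and the
structure parameters ``height``, ``fpa``, ``foot_length``, ``foot_width``)
up to order three per variable.  Coding is centered-and-scaled by default,
R = ((x - mean) / sd)**k, which keeps order-3 design matrices well
conditioned; raw powers are available with ``coding="raw"``.

Model selection is a faithful small-scale exhaustive search:

1. *Screening* — a predictor enters the search only if it shows a significant
   one-way effect on the feature at alpha = 0.05 (walking speed as a
   within-subject factor, continuous structure parameters by correlation
   test; a rank-based fallback replaces each test when residual normality is
   rejected).
2. *Enumeration* — every order combination 0..3 over the screened predictors
   (order 0 = excluded) is fitted on the full table; polynomials are
   hierarchical (order k includes powers 1..k) and a candidate is discarded
   unless each variable's highest-order coefficient is significant at alpha
   (a pure cubic dependence has a null quadratic coefficient, so testing
   every power would reject the true model).  The intercept-only (cohort
   mean) model is always a candidate.
3. *Selection* — among surviving candidates, the one with the least
   leave-one-subject-out cross-validated MSE wins; all rows of a held-out
   subject leave together, so the score measures generalization to a new
   person.

Design-matrix layout (needed to reproduce fits exactly): an intercept column
of ones, then for each variable in the canonical order
``("v", "height", "fpa", "foot_length", "foot_width")`` the coded powers
1..order in ascending order.  Fits use ``numpy.linalg.lstsq``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    EstimationError,
    ExtrapolationWarning,
    GaitgenError,
    PowerWarning,
    RankDeficiencyWarning,
)

__all__ = [
    "PREDICTORS",
    "PredictorSpec",
    "RegressionModel",
    "ModelSet",
    "anova_screen",
    "loocv_mse",
    "select_model",
    "predict_feature",
    "fit_model_set",
    "fpa_speed_independence",
    "FpaSpeedReport",
]

PREDICTORS = ("v", "height", "fpa", "foot_length", "foot_width")
MAX_ORDER = 3


@dataclass(frozen=True)
class PredictorSpec:
    """One predictor with its polynomial order (1..3; 0 means excluded)."""

    variable: str
    order: int

    def __post_init__(self) -> None:
        if self.variable not in PREDICTORS:
            raise GaitgenError(f"unknown predictor {self.variable!r}")
        if not 0 <= self.order <= MAX_ORDER:
            raise GaitgenError(f"order must be 0..{MAX_ORDER}, got {self.order}")


def _normalize_spec(spec) -> dict[str, int]:
    """Accept a mapping var->order or an iterable of PredictorSpec."""
    if isinstance(spec, Mapping):
        items = [PredictorSpec(v, o) for v, o in spec.items()]
    else:
        items = [s if isinstance(s, PredictorSpec) else PredictorSpec(*s) for s in spec]
    out = {}
    for s in items:
        if s.variable in out:
            raise GaitgenError(f"duplicate predictor {s.variable!r}")
        if s.order > 0:
            out[s.variable] = s.order
    return {v: out[v] for v in PREDICTORS if v in out}


@dataclass
class RegressionModel:
    """A fitted per-feature polynomial model in coded predictors.

    ``terms`` is a list of ``(variable, power, coefficient)``; ``scaling``
    maps variables to the (mean, sd) used for coding (sd = 1 for raw coding).
    A model with no terms predicts the cohort mean exactly.
    """

    feature: str
    intercept: float
    terms: list[tuple[str, int, float]]
    scaling: dict[str, tuple[float, float]]
    loocv_mse: float
    term_pvalues: dict[str, float] = field(default_factory=dict)
    training_range: dict[str, tuple[float, float]] = field(default_factory=dict)
    coding: str = "scaled"
    n_obs: int = 0

    def __post_init__(self) -> None:
        if self.loocv_mse < 0:
            raise GaitgenError("loocv_mse must be non-negative")

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(sorted({v for v, _, _ in self.terms}, key=PREDICTORS.index))

    def predict(self, params: Mapping[str, float], guard_frac: float | None = 0.1) -> float:
        return predict_feature(self, params, guard_frac=guard_frac)

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "intercept": self.intercept,
            "terms": [list(t) for t in self.terms],
            "scaling": {k: list(v) for k, v in self.scaling.items()},
            "loocv_mse": self.loocv_mse,
            "term_pvalues": self.term_pvalues,
            "training_range": {k: list(v) for k, v in self.training_range.items()},
            "coding": self.coding,
            "n_obs": self.n_obs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionModel":
        return cls(
            feature=d["feature"],
            intercept=float(d["intercept"]),
            terms=[(v, int(p), float(c)) for v, p, c in d["terms"]],
            scaling={k: (float(a), float(b)) for k, (a, b) in d["scaling"].items()},
            loocv_mse=float(d["loocv_mse"]),
            term_pvalues={k: float(v) for k, v in d.get("term_pvalues", {}).items()},
            training_range={k: (float(a), float(b)) for k, (a, b) in d.get("training_range", {}).items()},
            coding=d.get("coding", "scaled"),
            n_obs=int(d.get("n_obs", 0)),
        )


@dataclass
class ModelSet:
    """Map feature id -> RegressionModel plus cohort predictor statistics."""

    models: dict[str, RegressionModel]
    cohort_stats: dict[str, dict[str, float]] = field(default_factory=dict)

    def __getitem__(self, feature: str) -> RegressionModel:
        return self.models[feature]

    def __contains__(self, feature: str) -> bool:
        return feature in self.models

    def predict(self, feature: str, params: Mapping[str, float], guard_frac=0.1) -> float:
        return self.models[feature].predict(params, guard_frac=guard_frac)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {
                "cohort_stats": self.cohort_stats,
                "models": {k: m.to_dict() for k, m in self.models.items()},
            },
            indent=indent,
        )

    @classmethod
    def from_json(cls, text: str) -> "ModelSet":
        d = json.loads(text)
        return cls(
            models={k: RegressionModel.from_dict(m) for k, m in d["models"].items()},
            cohort_stats=d.get("cohort_stats", {}),
        )


# ---------------------------------------------------------------------------
# design matrices and plain OLS


def _scaling(table: pd.DataFrame, variables: Iterable[str], coding: str) -> dict[str, tuple[float, float]]:
    out = {}
    for v in variables:
        x = table[v].to_numpy(dtype=float)
        if coding == "raw":
            out[v] = (0.0, 1.0)
        else:
            sd = float(np.std(x, ddof=0))
            out[v] = (float(np.mean(x)), sd if sd > 0 else 1.0)
    return out


def _design(
    table: pd.DataFrame, spec: dict[str, int], scaling: Mapping[str, tuple[float, float]]
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    n = len(table)
    cols = [np.ones(n)]
    labels: list[tuple[str, int]] = []
    for v in PREDICTORS:
        if v not in spec:
            continue
        m, s = scaling[v]
        coded = (table[v].to_numpy(dtype=float) - m) / s
        for k in range(1, spec[v] + 1):
            cols.append(coded**k)
            labels.append((v, k))
    return np.column_stack(cols), labels


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares fit returning (coefficients, two-sided t-test p-values)."""
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p or n <= p:
        return beta, np.full(p, np.nan)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - p)
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=n - p)
    return beta, pvals


# ---------------------------------------------------------------------------
# screening


def _speed_effect_pvalue(table: pd.DataFrame, feature: str, alpha: float) -> float:
    """Within-subject one-way effect of speed; Friedman fallback on non-normality."""
    centered = table[feature] - table.groupby("subject")[feature].transform("mean")
    groups = [g.to_numpy() for _, g in centered.groupby(table["v"]) if len(g) > 1]
    if len(groups) < 2:
        return 1.0
    resid = centered - centered.groupby(table["v"]).transform("mean")
    normal = True
    r = resid.to_numpy()
    if len(r) >= 8 and np.ptp(r) > 0:
        normal = stats.shapiro(r).pvalue >= alpha
    if normal:
        return float(stats.f_oneway(*groups).pvalue)
    pivot = table.pivot_table(index="subject", columns="v", values=feature)
    pivot = pivot.dropna()
    if pivot.shape[0] < 3 or pivot.shape[1] < 3:
        return float(stats.f_oneway(*groups).pvalue)
    return float(stats.friedmanchisquare(*[pivot[c].to_numpy() for c in pivot.columns]).pvalue)


def _sp_effect_pvalue(x: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Correlation screen of a per-subject structure parameter; Spearman fallback."""
    if len(np.unique(x)) < 3 or np.ptp(y) == 0:
        return 1.0
    normal = True
    if len(y) >= 8:
        slope, intercept = np.polyfit(x, y, 1)
        r = y - (slope * x + intercept)
        if np.ptp(r) > 0:
            normal = stats.shapiro(r).pvalue >= alpha
    if normal:
        return float(stats.pearsonr(x, y).pvalue)
    return float(stats.spearmanr(x, y).pvalue)


def anova_screen(
    table: pd.DataFrame, feature: str, alpha: float = 0.05, family_adjust: bool = True
) -> list[str]:
    """Predictors with a significant one-way effect on the feature.

    Speed is screened as a within-subject factor (subject-mean-centered
    one-way ANOVA, Friedman when residual normality is rejected).  Structure
    parameters are screened by a forward residual correlation test on
    subject-level means (Spearman fallback when residual normality is
    rejected): after each predictor is admitted it is regressed out, so one
    strong structure parameter cannot mask another.  ``alpha`` is controlled
    family-wise over the five candidate predictors by Bonferroni (per-test
    alpha/5) unless ``family_adjust`` is False, so a pure-noise feature
    screens to the empty set with probability about 1 - alpha.  A constant
    feature always screens to the empty set.
    """
    y = table[feature].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        return []
    candidates = [p for p in PREDICTORS if p in table.columns]
    thresh = alpha / len(candidates) if family_adjust else alpha
    selected = []
    if "v" in candidates and len(np.unique(table["v"])) >= 3:
        if _speed_effect_pvalue(table, feature, alpha) < thresh:
            selected.append("v")

    sps = [p for p in PREDICTORS[1:] if p in candidates]
    per_subject = table.groupby("subject").agg(
        {feature: "mean", **{sp: "first" for sp in sps}}
    )
    ys = per_subject[feature].to_numpy(dtype=float)
    chosen_sps: list[str] = []
    while True:
        remaining = [sp for sp in sps if sp not in chosen_sps]
        if not remaining:
            break
        if chosen_sps:
            Xs = np.column_stack(
                [np.ones(len(ys))] + [per_subject[sp].to_numpy(dtype=float) for sp in chosen_sps]
            )
            beta, _, _, _ = np.linalg.lstsq(Xs, ys, rcond=None)
            resid = ys - Xs @ beta
        else:
            resid = ys
        pvals = {
            sp: _sp_effect_pvalue(per_subject[sp].to_numpy(dtype=float), resid, alpha)
            for sp in remaining
        }
        best = min(pvals, key=pvals.get)
        if pvals[best] >= thresh:
            break
        chosen_sps.append(best)
    return selected + [p for p in PREDICTORS if p in chosen_sps]


# ---------------------------------------------------------------------------
# cross-validation and selection


def loocv_mse(
    table: pd.DataFrame,
    feature: str,
    spec,
    coding: str = "scaled",
    unit: str = "subject",
) -> float:
    """Leave-one-out cross-validated MSE of a candidate predictor spec.

    With ``unit="subject"`` (default) all rows of one subject are held out
    together; ``unit="trial"`` leaves out single rows.  Scaling constants are
    computed once on the full table so every fold shares the same coding.
    Rank-deficient training folds are skipped with a warning; if every fold
    is skipped an :class:`EstimationError` is raised.
    """
    spec = _normalize_spec(spec)
    scaling = _scaling(table, spec, coding)
    X, _ = _design(table, spec, scaling)
    y = table[feature].to_numpy(dtype=float)
    if unit == "subject":
        keys = table["subject"].to_numpy()
    elif unit == "trial":
        keys = np.arange(len(table))
    else:
        raise GaitgenError("unit must be 'subject' or 'trial'")

    errors = []
    for fold in sorted(pd.unique(keys)):
        test = keys == fold
        Xtr, ytr = X[~test], y[~test]
        if np.linalg.matrix_rank(Xtr) < X.shape[1]:
            warnings.warn(
                f"skipping rank-deficient fold {fold!r} for feature {feature!r}",
                RankDeficiencyWarning,
                stacklevel=2,
            )
            continue
        beta, _, _, _ = np.linalg.lstsq(Xtr, ytr, rcond=None)
        errors.append(y[test] - X[test] @ beta)
    if not errors:
        raise EstimationError(f"all LOOCV folds skipped for feature {feature!r}")
    return float(np.mean(np.concatenate(errors) ** 2))


def select_model(
    table: pd.DataFrame,
    feature: str,
    alpha: float = 0.05,
    screened: Sequence[str] | None = None,
    max_order: int = MAX_ORDER,
    coding: str = "scaled",
    unit: str = "subject",
) -> RegressionModel:
    """Exhaustive LOOCV model selection for one gait feature.

    Candidates are all order combinations 0..``max_order`` over the screened
    predictors; a candidate survives only if each variable's highest-order
    coefficient is significant at ``alpha`` in the full-data fit (lower
    powers ride along hierarchically).  The intercept-only model is always a
    candidate, so selection can never fail.  Least LOOCV MSE wins (ties:
    fewer terms).
    """
    if screened is None:
        screened = anova_screen(table, feature, alpha)
    screened = [v for v in PREDICTORS if v in screened]
    y = table[feature].to_numpy(dtype=float)
    scaling_all = _scaling(table, PREDICTORS, coding)
    training_range = {
        v: (float(table[v].min()), float(table[v].max())) for v in PREDICTORS if v in table
    }

    best: tuple[float, int, dict[str, int]] | None = None
    mean_mse = loocv_mse(table, feature, {}, coding=coding, unit=unit)
    best = (mean_mse, 0, {})

    for orders in product(range(max_order + 1), repeat=len(screened)):
        spec = {v: o for v, o in zip(screened, orders) if o > 0}
        if not spec:
            continue
        X, labels = _design(table, spec, scaling_all)
        if len(table) <= X.shape[1] or np.linalg.matrix_rank(X) < X.shape[1]:
            continue
        _, pvals = _ols(X, y)
        top = [i for i, (v, k) in enumerate(labels) if k == spec[v]]
        top_p = pvals[1:][top]
        if np.any(~np.isfinite(top_p)) or np.any(top_p >= alpha):
            continue
        mse = loocv_mse(table, feature, spec, coding=coding, unit=unit)
        nterms = len(labels)
        if mse < best[0] or (mse == best[0] and nterms < best[1]):
            best = (mse, nterms, spec)

    mse, _, spec = best
    X, labels = _design(table, spec, scaling_all)
    beta, pvals = _ols(X, y)
    if not spec:
        beta = np.array([float(np.mean(y))])
        pvals = np.array([np.nan])
    return RegressionModel(
        feature=feature,
        intercept=float(beta[0]),
        terms=[(v, k, float(b)) for (v, k), b in zip(labels, beta[1:])],
        scaling={v: scaling_all[v] for v in spec},
        loocv_mse=mse,
        term_pvalues={f"{v}^{k}": float(p) for (v, k), p in zip(labels, pvals[1:])},
        training_range=training_range,
        coding=coding,
        n_obs=len(table),
    )


def predict_feature(
    model: RegressionModel, params: Mapping[str, float], guard_frac: float | None = 0.1
) -> float:
    """Evaluate b0 + sum of coded terms at a subject's MP/SP values.

    Emits :class:`ExtrapolationWarning` (not fatal) when a predictor lies more
    than ``guard_frac`` of the training range outside it.
    """
    value = model.intercept
    for v, k, coef in model.terms:
        if v not in params:
            raise GaitgenError(f"missing parameter {v!r} for feature {model.feature!r}")
        m, s = model.scaling[v]
        value += coef * ((float(params[v]) - m) / s) ** k
        if guard_frac is not None and v in model.training_range:
            lo, hi = model.training_range[v]
            span = (hi - lo) or 1.0
            if not (lo - guard_frac * span <= float(params[v]) <= hi + guard_frac * span):
                warnings.warn(
                    f"{v}={params[v]} outside training range [{lo}, {hi}] "
                    f"for feature {model.feature!r}",
                    ExtrapolationWarning,
                    stacklevel=2,
                )
    return float(value)


def fit_model_set(
    table: pd.DataFrame,
    features: Sequence[str],
    alpha: float = 0.05,
    coding: str = "scaled",
    unit: str = "subject",
) -> ModelSet:
    """Select a model per feature and bundle them with cohort statistics."""
    models = {f: select_model(table, f, alpha=alpha, coding=coding, unit=unit) for f in features}
    stats_ = {
        v: {"mean": float(table[v].mean()), "sd": float(table[v].std(ddof=0))}
        for v in PREDICTORS
        if v in table
    }
    return ModelSet(models=models, cohort_stats=stats_)


# ---------------------------------------------------------------------------
# FPA vs speed


@dataclass
class FpaSpeedReport:
    """Adjacent-speed-pair Wilcoxon tests of the foot progression angle."""

    pairs: list[tuple[float, float]]
    pvalues: list[float]
    threshold: float
    n_subjects: int
    m_comparisons: int

    @property
    def significant(self) -> list[bool]:
        return [p < self.threshold for p in self.pvalues]

    @property
    def any_significant(self) -> bool:
        return any(self.significant)


def fpa_speed_independence(
    table: pd.DataFrame,
    alpha: float = 0.05,
    m_comparisons: int | None = None,
    fpa_column: str = "fpa",
) -> FpaSpeedReport:
    """Paired Wilcoxon signed-rank tests of FPA between adjacent speeds.

    ``table`` needs per-trial FPA measurements in columns ``subject``, ``v``
    and ``fpa_column``.  The Bonferroni-corrected threshold defaults to
    alpha / (number of adjacent pairs); pass ``m_comparisons`` to correct
    over a larger family.
    """
    pivot = table.pivot_table(index="subject", columns="v", values=fpa_column).dropna()
    speeds = sorted(pivot.columns)
    if len(speeds) < 2:
        raise GaitgenError("need at least two speeds for adjacent-pair tests")
    n = pivot.shape[0]
    if n < 6:
        warnings.warn(
            f"only {n} subject(s): Wilcoxon tests are underpowered", PowerWarning, stacklevel=2
        )
    pairs, pvals = [], []
    for v1, v2 in zip(speeds[:-1], speeds[1:]):
        d = pivot[v2].to_numpy() - pivot[v1].to_numpy()
        if np.all(d == 0) or n < 2:
            p = 1.0
        else:
            p = float(stats.wilcoxon(pivot[v1].to_numpy(), pivot[v2].to_numpy()).pvalue)
        pairs.append((float(v1), float(v2)))
        pvals.append(p)
    m = m_comparisons if m_comparisons is not None else len(pairs)
    return FpaSpeedReport(
        pairs=pairs, pvalues=pvals, threshold=alpha / m, n_subjects=n, m_comparisons=m
    )
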