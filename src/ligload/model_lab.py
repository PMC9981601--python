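"""Failure-load regression: training, feature selection, model selection.

The protocol mirrors standard small-cohort imaging-biomarker practice:

1. subject-stratified 80/20 split (both limbs of an animal stay together);
2. recursive feature elimination with fivefold cross-validation (RFE-CV):
   fit on all candidates, average feature importance over folds, drop the
   least important feature, repeat down to a floor of 3 features;
3. hyperparameter optimization by random-search fivefold CV over the full
   search space, then a local grid-search CV around the random-search
   winner (each hyperparameter moved ±1 notch on its lattice with the
   others held fixed), scored by CV mean absolute error;
4. evaluation on the withheld test set: MAE with a percentile-bootstrap 95%
   confidence interval, and paired comparison of per-sample absolute errors
   between models via the exact Wilcoxon signed-rank test.

Model families: a multivariate linear benchmark (OLS, fixed features) and
SVM / random forest / AdaBoost / XGBoost regressors.  All features are
z-scored with statistics frozen from the training table; the reference
travels with the fitted model so later cohorts are scaled identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from scipy import stats
from sklearn.ensemble import AdaBoostRegressor, RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .features import (
    CANDIDATE_FEATURES,
    StandardizationReference,
    standardize,
)
from .relaxometry import ValidationError

__all__ = [
    "FAMILIES",
    "LM_BENCHMARK_FEATURES",
    "ModelSpec",
    "RfeResult",
    "EvaluationResult",
    "ComparisonResult",
    "FailureLoadModel",
    "FailureLoadResults",
    "split_by_subject",
    "rfe_cv",
    "optimize_model",
    "evaluate_mae",
    "compare_paired",
    "default_search_space",
]

log = logging.getLogger(__name__)

FAMILIES = ("LM", "SVM", "RF", "AdaBoost", "XGBoost")

#: Benchmark linear model features: sub-volume proportions 1 and 4, CSA and
#: limb type — the conventional size-normalized linear predictor set.
LM_BENCHMARK_FEATURES = ("prop1", "prop4", "csa", "limb_type")

TARGET = "failure_load"


def _log_lattice(lo: float, hi: float, n: int) -> tuple[float, ...]:
    return tuple(float(x) for x in np.geomspace(lo, hi, n))


def _int_log_lattice(lo: int, hi: int, n: int) -> tuple[int, ...]:
    vals = np.unique(np.rint(np.geomspace(lo, hi, n)).astype(int))
    return tuple(int(v) for v in vals)


#: Initial hyperparameter search space per family.  Each entry is an ordered
#: lattice (log-spaced for scale parameters, linear otherwise) spanning the
#: declared range; categorical options are listed verbatim.  "MSE"/"MAE"
#: and "Auto"/"Square Root"/"Log_2" are mapped to the names the scikit-learn
#: backend accepts (squared_error/absolute_error; 1.0/"sqrt"/"log2").
def default_search_space(family: str) -> dict[str, tuple]:
    if family == "SVM":
        return {
            "C": _log_lattice(0.1, 1000.0, 9),
            "kernel": ("rbf", "poly", "sigmoid", "linear"),
            "degree": (1, 2, 3, 4, 5, 6),
            "gamma": _log_lattice(1e-4, 1.0, 9),
        }
    if family == "RF":
        return {
            "n_estimators": _int_log_lattice(100, 2000, 8),
            "criterion": ("squared_error", "absolute_error"),
            "max_depth": (5, 10, 20, 35, 50, 75, 100),
            "max_features": (1.0, "sqrt", "log2"),
            "min_samples_leaf": (1, 2, 3, 4, 5),
            "min_samples_split": (2, 4, 6, 8, 10),
            "bootstrap": (True, False),
        }
    if family == "AdaBoost":
        return {
            "n_estimators": _int_log_lattice(100, 2000, 8),
            "learning_rate": (0.1, 0.2, 0.5, 1.0, 1.5, 2.0),
            "loss": ("linear", "square", "exponential"),
        }
    if family == "XGBoost":
        return {
            "n_estimators": _int_log_lattice(100, 2000, 8),
            "max_depth": (5, 10, 20, 35, 50, 75, 100),
            "booster": ("gblinear", "dart"),
            "gamma": (0.0, 1.0, 5.0, 20.0, 50.0, 100.0, 200.0),
            "learning_rate": _log_lattice(0.01, 0.7, 7),
            "reg_alpha": (0.0, 1.0, 5.0, 20.0, 50.0, 100.0, 200.0),
            "reg_lambda": (0.0, 1.0, 5.0, 20.0, 50.0, 100.0, 200.0),
        }
    if family == "LM":
        return {}
    raise ValidationError(f"unknown model family {family!r}")


@dataclass
class ModelSpec:
    """A model family plus its hyperparameter search space."""

    family: str
    search_space: dict[str, tuple] = field(default_factory=dict)
    fixed_features: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown model family {self.family!r}")
        if not self.search_space and self.family != "LM":
            self.search_space = default_search_space(self.family)
        if self.family == "LM":
            self.search_space = {}
            if self.fixed_features is None:
                self.fixed_features = LM_BENCHMARK_FEATURES


def _make_estimator(family: str, params: Mapping, random_state: int):
    if family == "SVM":
        return SVR(**params)
    if family == "RF":
        return RandomForestRegressor(**params, random_state=random_state, n_jobs=1)
    if family == "AdaBoost":
        return AdaBoostRegressor(**params, random_state=random_state)
    if family == "XGBoost":
        return XGBRegressor(
            **params, random_state=random_state, n_jobs=1, verbosity=0,
        )
    raise ValidationError(f"no estimator backend for family {family!r}")


class _OLSEstimator:
    """Minimal sklearn-style wrapper around a statsmodels OLS fit."""

    def __init__(self) -> None:
        self.result_ = None

    def fit(self, X, y):
        self.result_ = sm.OLS(np.asarray(y, float),
                              sm.add_constant(np.asarray(X, float),
                                              has_constant="add")).fit()
        return self

    def predict(self, X):
        return np.asarray(
            self.result_.predict(
                sm.add_constant(np.asarray(X, float), has_constant="add")))


# ---------------------------------------------------------------------------
# split / feature selection / optimization
# ---------------------------------------------------------------------------

def split_by_subject(
    records: pd.DataFrame,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random split stratified by subject: paired limbs never separate."""
    if not 0 < test_fraction < 1:
        raise ValidationError("test_fraction must be in (0, 1)")
    subjects = records["subject_id"].unique()
    if subjects.size < 2:
        raise ValidationError("need at least 2 subjects to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(subjects)
    n_test = int(round(test_fraction * subjects.size))
    n_test = min(max(n_test, 1), subjects.size - 1)
    test_ids = set(order[:n_test])
    is_test = records["subject_id"].isin(test_ids)
    return records[~is_test].copy(), records[is_test].copy()


@dataclass
class RfeResult:
    """Outcome of recursive feature elimination with cross-validation."""

    selected: tuple[str, ...]
    elimination_order: tuple[str, ...]  # first-dropped first
    importances: dict[str, float]       # fold-averaged, at each feature's final round

    def ranking(self) -> list[str]:
        """Features from most to least important (survivors first)."""
        surv = sorted(self.selected, key=lambda f: -self.importances[f])
        return surv + list(reversed(self.elimination_order))


def _fold_permutation_importance(
    est, X_val: np.ndarray, y_val: np.ndarray,
    n_repeats: int, rng: np.random.Generator,
) -> np.ndarray:
    """Validation-fold permutation importance, one batched predict call.

    Importance of a feature is the mean increase in validation MSE when that
    feature's column is shuffled; redundant proxies of features still in the
    model score near zero, which is what recursive elimination needs.
    """
    n, p = X_val.shape
    base_mse = float(np.mean((est.predict(X_val) - y_val) ** 2))
    stacked = np.tile(X_val, (p * n_repeats, 1, 1))
    k = 0
    for j in range(p):
        for _ in range(n_repeats):
            stacked[k, :, j] = X_val[rng.permutation(n), j]
            k += 1
    preds = est.predict(stacked.reshape(-1, p)).reshape(p * n_repeats, n)
    mse = np.mean((preds - y_val[None, :]) ** 2, axis=1)
    return mse.reshape(p, n_repeats).mean(axis=1) - base_mse


def _cv_importances(
    X: np.ndarray, y: np.ndarray, feats: list[str],
    estimator_factory, k_folds: int, rng_state: int,
    n_repeats: int = 5,
) -> np.ndarray:
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=rng_state)
    imp = np.zeros(len(feats))
    for fold, (tr, va) in enumerate(kf.split(X)):
        est = estimator_factory(rng_state + fold)
        est.fit(X[tr], y[tr])
        rng = np.random.default_rng(rng_state + 1000 + fold)
        imp += _fold_permutation_importance(est, X[va], y[va], n_repeats, rng)
    return imp / k_folds


def rfe_cv(
    train: pd.DataFrame,
    estimator_spec: ModelSpec | None = None,
    k_folds: int = 5,
    min_features: int = 3,
    seed: int = 0,
    candidates: Sequence[str] = CANDIDATE_FEATURES,
    n_estimators: int = 300,
    max_features: float | str = 0.33,
) -> RfeResult:
    """Recursive feature elimination with k-fold cross-validated importances.

    At each round a random forest is fitted on each training fold and
    feature importance is measured by *permutation on the held-out fold*
    (mean increase in validation MSE when one feature column is shuffled),
    averaged over folds; the least important feature is eliminated, until
    ``min_features`` remain.  Cross-validated permutation importance —
    rather than in-sample impurity decrease — is used because impurity
    importance dilutes across correlated proxies and cannot tell an exact
    determinant from its correlates; validation-fold permutation scores a
    redundant proxy near zero.  The forest uses the classical m-try of
    about one third of the features per split, which decorrelates trees.
    """
    candidates = [c for c in candidates if c in train.columns]
    if min_features < 1:
        raise ValidationError("min_features must be >= 1")
    if min_features > len(candidates):
        raise ValidationError(
            f"min_features={min_features} exceeds {len(candidates)} candidates")
    if k_folds < 2:
        raise ValidationError("k_folds must be >= 2")
    spec = estimator_spec or ModelSpec("RF")
    if spec.family != "RF":
        raise ValidationError("only an RF base estimator is supported for RFE-CV")

    ref = StandardizationReference.from_table(train, source="rfe")
    z = standardize(train, ref)
    y = z[TARGET].to_numpy(float)
    root = np.random.SeedSequence(seed)
    state = int(root.generate_state(1)[0] % (2**31 - 1))

    def factory(rs: int):
        return RandomForestRegressor(n_estimators=n_estimators,
                                     max_features=max_features,
                                     random_state=rs, n_jobs=1)

    remaining = list(candidates)
    dropped: list[str] = []
    final_importance: dict[str, float] = {}
    rnd = 0
    while len(remaining) > min_features:
        X = z[remaining].to_numpy(float)
        imp = _cv_importances(X, y, remaining, factory, k_folds, state + 97 * rnd)
        worst = int(np.argmin(imp))
        final_importance.update(dict(zip(remaining, imp)))
        dropped.append(remaining.pop(worst))
        rnd += 1
    X = z[remaining].to_numpy(float)
    imp = _cv_importances(X, y, remaining, factory, k_folds, state + 97 * rnd)
    final_importance.update(dict(zip(remaining, imp)))
    return RfeResult(tuple(remaining), tuple(dropped), final_importance)


def _cv_mae(X: np.ndarray, y: np.ndarray, family: str, params: Mapping,
            k_folds: int, rng_state: int) -> float:
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=rng_state)
    maes = []
    for fold, (tr, va) in enumerate(kf.split(X)):
        est = _make_estimator(family, params, rng_state + fold)
        est.fit(X[tr], y[tr])
        maes.append(float(np.mean(np.abs(est.predict(X[va]) - y[va]))))
    return float(np.mean(maes))


def _local_grid(space: Mapping[str, tuple], winner: Mapping) -> list[dict]:
    """Axis-aligned ±1-notch neighbourhood of the winner.

    A notch is only meaningful on an ordered lattice, so categorical axes
    (kernels, losses, boolean flags) are kept at the random-search winner.
    """
    grid = [dict(winner)]
    for name, lattice in space.items():
        if not all(isinstance(v, (int, float)) and not isinstance(v, bool)
                   for v in lattice):
            continue
        i = lattice.index(winner[name])
        for j in (i - 1, i + 1):
            if 0 <= j < len(lattice):
                cand = dict(winner)
                cand[name] = lattice[j]
                grid.append(cand)
    return grid


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

@dataclass
class EvaluationResult:
    """Test-set MAE with percentile-bootstrap CI and per-sample errors."""

    mae: float
    mae_ci: tuple[float, float]
    errors: np.ndarray
    n_test: int

    def __str__(self) -> str:
        lo, hi = self.mae_ci
        return f"MAE {self.mae:.1f} N (95% CI {lo:.1f}, {hi:.1f}; n={self.n_test})"


@dataclass
class ComparisonResult:
    """Paired comparison of two models' test-set absolute errors."""

    statistic: float
    p_value: float
    percent_decrease: float
    percent_decrease_ci: tuple[float, float]
    n: int

    def __str__(self) -> str:
        lo, hi = self.percent_decrease_ci
        return (f"{self.percent_decrease:.0f}% MAE decrease "
                f"(95% CI {lo:.0f}–{hi:.0f}%), Wilcoxon W={self.statistic:.1f}, "
                f"p={self.p_value:.3g}")


class FailureLoadModel:
    """A failure-load regressor specified against a training table.

    Parameters
    ----------
    train : DataFrame
        Feature table with a ``failure_load`` column (one row per limb).
    family : str
        One of LM, SVM, RF, AdaBoost, XGBoost.
    features : sequence of str, optional
        Predictors to use.  Defaults to the RFE-CV survivors for ML
        families and to the fixed benchmark set for LM.
    spec : ModelSpec, optional
        Overrides family/search space (for narrowed search spaces).

    ``fit`` runs the full optimization protocol and returns a
    :class:`FailureLoadResults`.
    """

    def __init__(
        self,
        train: pd.DataFrame,
        family: str = "RF",
        features: Sequence[str] | None = None,
        spec: ModelSpec | None = None,
    ) -> None:
        if TARGET not in train.columns:
            raise ValidationError(f"training table lacks {TARGET!r}")
        self.train = train.reset_index(drop=True)
        self.spec = spec or ModelSpec(family)
        self.features = tuple(features) if features is not None else None

    def fit(
        self,
        n_random: int = 60,
        k_folds: int = 5,
        seed: int = 0,
        rfe_min_features: int = 3,
        grid_search: bool = True,
    ) -> "FailureLoadResults":
        """Select features (if not fixed), optimize hyperparameters, refit."""
        features = self.features
        rfe_result = None
        if features is None:
            if self.spec.family == "LM":
                features = tuple(self.spec.fixed_features)
            else:
                rfe_result = rfe_cv(self.train, k_folds=k_folds,
                                    min_features=rfe_min_features, seed=seed)
                features = rfe_result.selected
        return optimize_model(
            self.train, self.spec, features,
            n_random=n_random, k_folds=k_folds, seed=seed,
            rfe_result=rfe_result, grid_search=grid_search,
        )


def optimize_model(
    train: pd.DataFrame,
    spec: ModelSpec,
    features: Sequence[str],
    n_random: int = 60,
    k_folds: int = 5,
    seed: int = 0,
    rfe_result: RfeResult | None = None,
    grid_search: bool = True,
) -> "FailureLoadResults":
    """RS-CV → local GS-CV hyperparameter optimization, then a final refit.

    Random search draws ``n_random`` lattice points scored by k-fold CV mean
    absolute error; grid search then explores the ±1-notch axis-aligned
    neighbourhood of the winner (skippable with ``grid_search=False`` for a
    reduced, random-search-only protocol).  The LM benchmark has no search
    space and is fitted directly by OLS.
    """
    features = tuple(features)
    if not features:
        raise ValidationError("features must be non-empty")
    missing = [f for f in features if f not in train.columns]
    if missing:
        raise ValidationError(f"training table lacks features {missing}")
    if spec.family != "LM" and not spec.search_space:
        raise ValidationError(f"empty search space for family {spec.family}")

    cont = [f for f in features if f != "limb_type"]
    ref = StandardizationReference.from_table(train, features=cont,
                                              source="porcine-train")
    z = standardize(train, ref)
    X = z[list(features)].to_numpy(float)
    y = z[TARGET].to_numpy(float)

    root = np.random.SeedSequence(seed)
    state = int(root.generate_state(1)[0] % (2**31 - 1))

    if spec.family == "LM":
        est = _OLSEstimator().fit(X, y)
        return FailureLoadResults(spec.family, features, {}, est, ref, seed,
                                  cv_mae=None, rfe_result=rfe_result)

    if n_random < 1:
        raise ValidationError("n_random must be >= 1")
    rng = np.random.default_rng(root.spawn(1)[0])
    names = list(spec.search_space)
    seen: set[tuple] = set()
    best_params, best_score = None, np.inf
    for _ in range(n_random):
        params = {n: spec.search_space[n][rng.integers(len(spec.search_space[n]))]
                  for n in names}
        key = tuple(params[n] for n in names)
        if key in seen:
            continue
        seen.add(key)
        score = _cv_mae(X, y, spec.family, params, k_folds, state)
        if score < best_score:
            best_params, best_score = params, score

    if grid_search:
        for params in _local_grid(spec.search_space, best_params):
            key = tuple(params[n] for n in names)
            if key in seen:
                continue
            seen.add(key)
            score = _cv_mae(X, y, spec.family, params, k_folds, state)
            if score < best_score:
                best_params, best_score = params, score

    est = _make_estimator(spec.family, best_params, state).fit(X, y)
    return FailureLoadResults(spec.family, features, dict(best_params), est,
                              ref, seed, cv_mae=best_score,
                              rfe_result=rfe_result)


class FailureLoadResults:
    """A fitted failure-load regressor plus everything needed to reuse it.

    Carries the winning hyperparameters, the selected features, the frozen
    training standardization reference, and the training seed; offers
    prediction on new tables, test-set evaluation and a text summary.
    """

    def __init__(self, family, features, params, estimator, reference,
                 seed, cv_mae=None, rfe_result=None) -> None:
        self.family = family
        self.selected_features = tuple(features)
        self.params = dict(params)
        self.estimator = estimator
        self.reference = reference
        self.seed = seed
        self.cv_mae = cv_mae
        self.rfe_result = rfe_result

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Predict failure load (N); features are standardized with the
        frozen training reference before prediction."""
        missing = [f for f in self.selected_features if f not in table.columns]
        if missing:
            raise ValidationError(f"table lacks features {missing}")
        z = standardize(table, self.reference)
        return np.asarray(
            self.estimator.predict(z[list(self.selected_features)].to_numpy(float)),
            dtype=float)

    def evaluate(self, test: pd.DataFrame, n_boot: int = 2000,
                 seed: int = 0) -> EvaluationResult:
        return evaluate_mae(self, test, n_boot=n_boot, seed=seed)

    def summary(self) -> str:
        lines = [
            f"Failure-load model: {self.family}",
            f"  features: {', '.join(self.selected_features)}",
        ]
        if self.params:
            lines.append("  hyperparameters: "
                         + ", ".join(f"{k}={v}" for k, v in sorted(self.params.items())))
        if self.cv_mae is not None:
            lines.append(f"  CV MAE: {self.cv_mae:.1f} N")
        if self.family == "LM" and isinstance(self.estimator, _OLSEstimator):
            r = self.estimator.result_
            coefs = ", ".join(
                f"{n}={c:.1f}" for n, c in zip(
                    ["const", *self.selected_features], r.params))
            lines.append(f"  OLS coefficients (z-scale): {coefs}")
        lines.append(f"  standardization reference: {self.reference.source}")
        lines.append(f"  training seed: {self.seed}")
        return "\n".join(lines)

    # --- persistence -----------------------------------------------------
    def save(self, path: str | Path) -> Path:
        """Serialize the estimator plus a YAML manifest alongside it."""
        path = Path(path)
        joblib.dump(self, path)
        manifest = {
            "format_version": 1,
            "family": self.family,
            "features": list(self.selected_features),
            "hyperparameters": {k: (v if not isinstance(v, (np.generic,)) else v.item())
                                for k, v in self.params.items()},
            "reference": {"source": self.reference.source,
                          "means": self.reference.means,
                          "sds": self.reference.sds},
            "seed": int(self.seed),
        }
        Path(str(path) + ".manifest.yaml").write_text(yaml.safe_dump(manifest))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "FailureLoadResults":
        obj = joblib.load(path)
        if not isinstance(obj, cls):
            raise ValidationError(f"{path} does not contain a FailureLoadResults")
        return obj


def evaluate_mae(
    model: FailureLoadResults,
    test: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
) -> EvaluationResult:
    """Test-set mean absolute error with a percentile-bootstrap 95% CI."""
    if len(test) == 0:
        raise ValidationError("test table is empty")
    pred = model.predict(test)
    errors = np.abs(pred - test[TARGET].to_numpy(float))
    mae = float(errors.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, errors.size, size=(n_boot, errors.size))
    boot = errors[idx].mean(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return EvaluationResult(mae, (float(lo), float(hi)), errors, int(errors.size))


def compare_paired(
    errors_a: Sequence[float],
    errors_b: Sequence[float],
    n_boot: int = 2000,
    seed: int = 0,
) -> ComparisonResult:
    """Wilcoxon signed-rank on paired absolute errors + percent MAE decrease.

    Exact two-sided p for small samples (no zero differences/ties), normal
    approximation otherwise; zero differences are dropped (Wilcoxon's
    rule).  Percent decrease is (1 − MAE_b/MAE_a)·100 with a paired
    bootstrap CI.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("error vectors must have equal length")
    if a.size < 5:
        raise ValidationError("need at least 5 paired errors")
    d = a - b
    if np.all(d == 0):
        w, p = 0.0, 1.0
    else:
        nz = d[d != 0]
        method = "exact" if (nz.size <= 25 and
                             np.unique(np.abs(nz)).size == nz.size) else "approx"
        res = stats.wilcoxon(a, b, zero_method="wilcox", method=method)
        w, p = float(res.statistic), float(res.pvalue)
    pct = (1.0 - b.mean() / a.mean()) * 100.0
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, a.size, size=(n_boot, a.size))
    boot = (1.0 - b[idx].mean(axis=1) / a[idx].mean(axis=1)) * 100.0
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return ComparisonResult(w, p, float(pct), (float(lo), float(hi)), int(a.size))
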