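"""Penalized-regression epigenetic clocks with nested leave-one-out CV.

Three clock types predict chronological age (days) from per-site features:

* ``elasticnet_levels`` — elastic net (mixing 0.5) on genome-wide
  methylation fractions;
* ``ridge_dms`` — ridge (mixing 0) on fractions at differentially
  methylated sites only;
* ``elasticnet_entropy`` — elastic net on per-site binary entropies at
  differentially methylated sites.

Training is a nested leave-one-out cross-validation: the outer loop holds
out one sample at a time for unbiased performance estimation, and within
each outer fold an inner leave-one-out loop picks the penalty strength
(lambda) minimizing held-out squared error over a 100-point log-spaced
grid anchored at the smallest lambda that zeroes every elastic-net
coefficient.  Ties in inner error resolve toward the larger (sparser)
lambda.  The deployed model is refit on all training samples at the lambda
chosen by a full-training LOOCV.  Features are standardized inside each
fold; coefficients are reported on the original feature scale.

``EpigeneticClock`` follows the scikit-learn estimator contract (``fit`` /
``predict`` / ``get_params``), so it composes with sklearn model-selection
tooling; the module-level functions are thin wrappers used by the
pipeline.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import ElasticNet, enet_path

try:  # fast inner-CV loop: the Cython coordinate-descent core
    from sklearn.linear_model import _cd_fast as _cd
except Exception:  # pragma: no cover - public-API fallback below
    _cd = None
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .entropy import GroupComparison, compare_groups, site_entropy
from .io import MethylationMatrix, Sample, SiteKey

logger = logging.getLogger(__name__)

#: glmnet-style mixing parameter for each clock type.
CLOCK_MIXING = {
    "elasticnet_levels": 0.5,
    "ridge_dms": 0.0,
    "elasticnet_entropy": 0.5,
}

#: Which feature source each clock type consumes.
CLOCK_FEATURES = {
    "elasticnet_levels": "levels",
    "ridge_dms": "dms_levels",
    "elasticnet_entropy": "dms_entropy",
}


# ---------------------------------------------------------------------------
# penalized path primitives (glmnet parameterization:
# (1/2n)||y - Xw||^2 + lambda * [rho ||w||_1 + (1 - rho)/2 ||w||^2])
# ---------------------------------------------------------------------------

_RIDGE_L1_FLOOR = 1e-3  # lambda_max anchor when the mixing is 0


def lambda_grid(X: np.ndarray, y: np.ndarray, l1_ratio: float,
                n_lambda: int = 100, min_ratio: float | None = None) -> np.ndarray:
    """Decreasing log-spaced penalty grid from lambda_max.

    lambda_max = max|X'y| / (n * rho) is the smallest penalty with an
    all-zero elastic-net solution on centered, standardized data; for ridge
    (rho = 0) the anchor uses rho floored at 1e-3, the usual convention.
    ``min_ratio`` defaults to 0.01 when p > n and 1e-4 otherwise (the
    glmnet convention: with more features than samples the unpenalized end
    of the path is saturated and worthless).
    """
    n, p = X.shape
    if min_ratio is None:
        if l1_ratio == 0:
            # the rho floor inflates lambda_max ~1000x for ridge; a much
            # deeper floor is needed to reach useful penalties, and the
            # closed-form SVD path makes the long grid free
            min_ratio = 1e-7
        else:
            min_ratio = 0.01 if p > n else 1e-4
    rho = max(l1_ratio, _RIDGE_L1_FLOOR)
    lam_max = float(np.max(np.abs(X.T @ y))) / (n * rho)
    if lam_max <= 0 or not np.isfinite(lam_max):
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _coef_path(X: np.ndarray, y: np.ndarray, lambdas: np.ndarray,
               l1_ratio: float, tol: float = 1e-3) -> np.ndarray:
    """Coefficient path on centered/standardized data; (p, n_lambda)."""
    if l1_ratio > 0:
        _, coefs, _ = enet_path(X, y, l1_ratio=l1_ratio, alphas=lambdas, tol=tol)
        return coefs
    # closed-form ridge path via one SVD
    n = X.shape[0]
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    uty = U.T @ y
    shrink = s[:, None] / (s[:, None] ** 2 + n * lambdas[None, :])
    return Vt.T @ (shrink * uty[:, None])


def _fold_standardize(X: np.ndarray, standardize: bool):
    m = X.mean(axis=0)
    if standardize:
        s = X.std(axis=0)
        s = np.where(s > 0, s, 1.0)
    else:
        s = np.ones(X.shape[1])
    return (X - m) / s, m, s


def _fit_at_lambda(Z: np.ndarray, yc: np.ndarray, lam: float, l1_ratio: float,
                   tol: float) -> np.ndarray:
    """Single-penalty solution on centered/standardized data."""
    if l1_ratio > 0:
        est = ElasticNet(alpha=lam, l1_ratio=l1_ratio, fit_intercept=False,
                         tol=tol, max_iter=10_000)
        est.fit(Z, yc)
        return est.coef_
    return _coef_path(Z, yc, np.array([lam]), 0.0)[:, 0]


# Inner-CV grid points examined past the running MSE minimum before the
# descent stops: the held-out error is in practice U-shaped in lambda, and
# the dense small-lambda tail is by far the most expensive to fit.
_LAMBDA_PATIENCE = 15


def _loocv_lambda(X: np.ndarray, y: np.ndarray, l1_ratio: float,
                  n_lambda: int, min_ratio: float | None, standardize: bool,
                  tol: float = 1e-3):
    """Pick lambda by leave-one-out MSE; ties go to the larger lambda.

    The grid is walked from the largest penalty down with warm-started
    solvers shared across folds; once every fold's held-out error has been
    rising for ``_LAMBDA_PATIENCE`` grid points past the minimum the rest
    of the path is skipped (its MSE is recorded as +inf).

    Returns (chosen_lambda, grid, per-lambda MSE).
    """
    n = X.shape[0]
    Z_all, _, _ = _fold_standardize(X, standardize)
    grid = lambda_grid(Z_all, y - y.mean(), l1_ratio, n_lambda, min_ratio)

    folds = []
    for i in range(n):
        tr = np.arange(n) != i
        Z, m, s = _fold_standardize(X[tr], standardize)
        ym = y[tr].mean()
        zi = (X[i] - m) / s
        folds.append((np.asfortranarray(Z), np.ascontiguousarray(y[tr] - ym), ym, zi, y[i]))

    mse = np.full(n_lambda, np.inf)
    if l1_ratio == 0:
        # ridge: the closed-form SVD path makes the whole grid cheap
        sse = np.zeros(n_lambda)
        for Z, yc, ym, zi, yi in folds:
            coefs = _coef_path(Z, yc, grid, 0.0)
            sse += (ym + zi @ coefs - yi) ** 2
        mse[:] = sse / n
        best = int(np.argmin(mse + 1e-12 * np.arange(n_lambda)))
        return float(grid[best]), grid, mse

    p = X.shape[1]
    state = [np.zeros(p) for _ in folds]
    best = 0
    if _cd is not None:
        # warm-started descent down the grid, one solver call per fold/lambda
        rng_cd = np.random.RandomState(0)  # unused under cyclic selection
        for j, lam in enumerate(grid):
            sse = 0.0
            for k, (Z, yc, ym, zi, yi) in enumerate(folds):
                n_tr = Z.shape[0]
                w, _, _, _ = _cd.enet_coordinate_descent(
                    state[k], lam * l1_ratio * n_tr,
                    lam * (1.0 - l1_ratio) * n_tr,
                    Z, yc, 10_000, tol, rng_cd, 0, 0, 1,
                )
                state[k] = w
                sse += (ym + zi @ w - yi) ** 2
            mse[j] = sse / n
            if mse[j] < mse[best]:
                best = j
            elif j - best >= _LAMBDA_PATIENCE:
                break
        return float(grid[best]), grid, mse
    for start in range(0, n_lambda, 10):  # pragma: no cover - fallback path
        sub = grid[start:start + 10]
        sse = np.zeros(sub.size)
        for k, (Z, yc, ym, zi, yi) in enumerate(folds):
            _, coefs, _ = enet_path(
                Z, yc, l1_ratio=l1_ratio, alphas=sub, coef_init=state[k],
                check_input=False, tol=tol,
            )
            state[k] = np.ascontiguousarray(coefs[:, -1])
            sse += (ym + zi @ coefs - yi) ** 2
        mse[start:start + sub.size] = sse / n
        best = int(np.argmin(mse[: start + sub.size]
                             + 1e-12 * np.arange(start + sub.size)))
        if start + sub.size - 1 - best >= _LAMBDA_PATIENCE:
            break
    return float(grid[best]), grid, mse


class EpigeneticClock(RegressorMixin, BaseEstimator):
    """Penalized linear age predictor trained by nested LOOCV.

    Parameters
    ----------
    clock_type : {"elasticnet_levels", "ridge_dms", "elasticnet_entropy"}
        Fixes the elastic-net mixing (0.5 for elastic net, 0 for ridge) and
        documents the intended feature source; the estimator itself accepts
        any numeric feature matrix.
    n_lambda : int
        Size of the penalty grid.
    lambda_min_ratio : float
        Ratio of the smallest to the largest grid value.
    standardize : bool
        Standardize features within each fold (coefficients are returned on
        the original scale either way).

    Attributes
    ----------
    coef_ : ndarray of shape (n_features_in_,)
        Coefficients on the original feature scale (zero for dropped or
        unselected features).
    intercept_ : float
    lambda_ : float
        Penalty chosen by full-training LOOCV and used for the final refit.
    cv_predictions_ : ndarray
        Outer-LOOCV (out-of-fold) age predictions for the training samples.
    cv_mae_, cv_mre_, cv_r_ : float
        Cross-validated mean absolute error (days), mean relative error
        (%), and Pearson correlation of ``cv_predictions_`` vs the ages.
    per_fold_feature_counts_ : list of int
        Nonzero-coefficient count in each outer fold's model.
    per_fold_lambdas_ : list of float
    """

    def __init__(self, clock_type: str = "elasticnet_levels", n_lambda: int = 100,
                 lambda_min_ratio: float | None = None, standardize: bool = True,
                 tol: float = 1e-3):
        self.clock_type = clock_type
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.standardize = standardize
        self.tol = tol

    @property
    def mixing(self) -> float:
        return CLOCK_MIXING[self.clock_type]

    def fit(self, X, y):
        if self.clock_type not in CLOCK_MIXING:
            raise ValueError(
                f"unknown clock_type {self.clock_type!r}; "
                f"expected one of {sorted(CLOCK_MIXING)}"
            )
        feature_names = None
        if hasattr(X, "columns"):
            feature_names = np.asarray(X.columns, dtype=object)
        X, y = check_X_y(X, y, y_numeric=True)
        y = y.astype(float)
        if X.shape[0] < 3:
            raise ValueError("need at least 3 training samples for nested LOOCV")
        if np.ptp(y) == 0:
            raise ValueError("constant-age training set: the clock is unidentifiable")
        self.n_features_in_ = X.shape[1]
        if feature_names is not None:
            self.feature_names_in_ = feature_names

        variances = X.var(axis=0)
        keep = variances > 0
        n_dropped = int((~keep).sum())
        if n_dropped:
            warnings.warn(
                f"dropping {n_dropped} zero-variance feature(s) before penalized fit"
            )
        if not keep.any():
            raise ValueError("all features have zero variance")
        self.kept_mask_ = keep
        Xk = X[:, keep]
        rho = self.mixing
        n = X.shape[0]

        # outer LOOCV: unbiased training-performance estimate + fold metadata
        cv_pred = np.empty(n)
        fold_counts: list[int] = []
        fold_lambdas: list[float] = []
        fold_selected: list[np.ndarray] = []
        for i in range(n):
            tr = np.arange(n) != i
            lam, grid, _ = _loocv_lambda(
                Xk[tr], y[tr], rho, self.n_lambda, self.lambda_min_ratio,
                self.standardize, tol=self.tol,
            )
            Z, m, s = _fold_standardize(Xk[tr], self.standardize)
            ym = y[tr].mean()
            w = _fit_at_lambda(Z, y[tr] - ym, lam, rho, self.tol)
            zi = (Xk[i] - m) / s
            cv_pred[i] = ym + zi @ w
            fold_counts.append(int(np.count_nonzero(w)) if rho > 0 else Xk.shape[1])
            fold_lambdas.append(lam)
            fold_selected.append(np.flatnonzero(keep)[w != 0] if rho > 0
                                 else np.flatnonzero(keep))

        # final refit at the lambda chosen on the full training set
        lam, grid, mse = _loocv_lambda(
            Xk, y, rho, self.n_lambda, self.lambda_min_ratio, self.standardize,
            tol=self.tol,
        )
        Z, m, s = _fold_standardize(Xk, self.standardize)
        ym = y.mean()
        w_std = _fit_at_lambda(Z, y - ym, lam, rho, self.tol)
        w_orig = w_std / s
        coef_full = np.zeros(self.n_features_in_)
        coef_full[keep] = w_orig
        self.coef_ = coef_full
        self.intercept_ = float(ym - m @ w_orig)
        self.lambda_ = lam
        self.lambda_path_ = grid
        self.cv_mse_path_ = mse
        self.cv_predictions_ = cv_pred
        self.cv_mae_, self.cv_mre_, self.cv_r_ = evaluate_predictions(cv_pred, y)
        self.per_fold_feature_counts_ = fold_counts
        self.per_fold_lambdas_ = fold_lambdas
        self.per_fold_selected_ = fold_selected
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        if hasattr(X, "columns") and hasattr(self, "feature_names_in_"):
            missing = [c for c in self.feature_names_in_ if c not in X.columns]
            if missing:
                raise ValueError(
                    f"{len(missing)} model feature(s) missing from input, e.g. "
                    f"{missing[:5]}"
                )
            X = X.loc[:, list(self.feature_names_in_)]
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return self.intercept_ + X @ self.coef_

    @property
    def selected_mask_(self) -> np.ndarray:
        check_is_fitted(self, "coef_")
        return self.coef_ != 0


# ---------------------------------------------------------------------------
# wrappers and pipeline-facing dataclasses
# ---------------------------------------------------------------------------


@dataclass
class ClockSpec:
    """Configuration of one clock type."""

    clock_type: str
    n_lambda: int = 100
    lambda_min_ratio: float | None = None
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.clock_type not in CLOCK_MIXING:
            raise ValueError(f"unknown clock_type {self.clock_type!r}")

    @property
    def mixing(self) -> float:
        return CLOCK_MIXING[self.clock_type]

    @property
    def feature_source(self) -> str:
        return CLOCK_FEATURES[self.clock_type]


@dataclass
class ClockModel:
    """A trained clock: selected sites, weights and training metadata."""

    spec: ClockSpec
    feature_names: list[str]
    coefficients: np.ndarray
    intercept: float
    chosen_lambda: float
    per_fold_feature_counts: list[int]
    per_fold_lambdas: list[float]
    training_metrics: dict[str, float]
    estimator: EpigeneticClock | None = field(default=None, repr=False)

    @property
    def selected_sites(self) -> list[str]:
        return [n for n, c in zip(self.feature_names, self.coefficients) if c != 0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "clock_type": self.spec.clock_type,
                "n_lambda": self.spec.n_lambda,
                "lambda_min_ratio": self.spec.lambda_min_ratio,
                "standardize": self.spec.standardize,
                "feature_names": list(map(str, self.feature_names)),
                "coefficients": [float(c) for c in self.coefficients],
                "intercept": float(self.intercept),
                "chosen_lambda": float(self.chosen_lambda),
                "per_fold_feature_counts": list(self.per_fold_feature_counts),
                "per_fold_lambdas": [float(x) for x in self.per_fold_lambdas],
                "training_metrics": self.training_metrics,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ClockModel":
        d = json.loads(text)
        spec = ClockSpec(
            d["clock_type"], d["n_lambda"], d["lambda_min_ratio"], d["standardize"]
        )
        return cls(
            spec=spec,
            feature_names=list(d["feature_names"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            chosen_lambda=float(d["chosen_lambda"]),
            per_fold_feature_counts=list(d["per_fold_feature_counts"]),
            per_fold_lambdas=list(d["per_fold_lambdas"]),
            training_metrics=dict(d["training_metrics"]),
        )


def split_train_test(
    manifest: Sequence[Sample], n_train: int, seed: int
) -> tuple[list[str], list[str]]:
    """Random train/test split stratified by age group.

    Per-group training quotas follow proportional (largest-remainder)
    allocation; the draw is deterministic given the seed.
    """
    total = len(manifest)
    if not 0 < n_train < total:
        raise ValueError(f"n_train must lie in (0, {total}), got {n_train}")
    rng = np.random.default_rng(seed)
    groups: dict[str, list[str]] = {}
    for s in manifest:
        groups.setdefault(s.group, []).append(s.sample_id)

    names = list(groups)
    sizes = np.array([len(groups[g]) for g in names])
    exact = n_train * sizes / total
    base = np.floor(exact).astype(int)
    remainder = n_train - base.sum()
    if remainder > 0:
        frac = exact - base
        order = np.lexsort((rng.random(len(names)), -frac))
        for g_idx in order[:remainder]:
            base[g_idx] += 1
    if np.any(base > sizes):
        raise ValueError(
            "stratified split infeasible: a group's training quota exceeds its size "
            f"(groups {dict(zip(names, sizes))}, quotas {dict(zip(names, base))})"
        )

    train: list[str] = []
    for g, k in zip(names, base):
        ids = groups[g]
        chosen = rng.choice(len(ids), size=k, replace=False)
        train.extend(ids[i] for i in sorted(chosen))
    train_set = set(train)
    train_ordered = [s.sample_id for s in manifest if s.sample_id in train_set]
    test_ordered = [s.sample_id for s in manifest if s.sample_id not in train_set]
    return train_ordered, test_ordered


def assemble_features(
    matrix: MethylationMatrix,
    spec: ClockSpec | str,
    dms: Sequence[SiteKey] | None = None,
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Samples x features matrix for a clock type.

    ``elasticnet_levels`` uses every matrix site's fraction; ``ridge_dms``
    restricts to the DMS set; ``elasticnet_entropy`` takes per-site binary
    entropy at the DMS.  Feature columns keep the matrix's deterministic
    site order.
    """
    clock_type = spec.clock_type if isinstance(spec, ClockSpec) else spec
    source = CLOCK_FEATURES[clock_type]
    if source == "levels":
        rows = list(range(matrix.n_sites))
        keys = matrix.sites
    else:
        if not dms:
            raise ValueError(f"clock type {clock_type!r} requires a non-empty DMS set")
        index = matrix.site_index()
        dms_set = set(dms)
        keys = [k for k in matrix.sites if k in dms_set]  # matrix order
        rows = [index[k] for k in keys]
    values = matrix.fractions[rows, :].T  # samples x features
    if source == "dms_entropy":
        values = site_entropy(values)
    df = pd.DataFrame(values, index=matrix.sample_ids,
                      columns=[str(k) for k in keys])
    if sample_ids is not None:
        missing = [s for s in sample_ids if s not in df.index]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        df = df.loc[list(sample_ids)]
    return df


def train_clock(
    features: pd.DataFrame,
    ages_days: Sequence[float],
    spec: ClockSpec | str,
    seed: int = 0,
) -> ClockModel:
    """Fit one clock by nested LOOCV and package it as a ``ClockModel``.

    The procedure is deterministic; ``seed`` is accepted for interface
    symmetry with the stochastic stages and recorded nowhere.
    """
    if isinstance(spec, str):
        spec = ClockSpec(spec)
    est = EpigeneticClock(
        clock_type=spec.clock_type, n_lambda=spec.n_lambda,
        lambda_min_ratio=spec.lambda_min_ratio, standardize=spec.standardize,
    )
    est.fit(features, np.asarray(ages_days, dtype=float))
    return ClockModel(
        spec=spec,
        feature_names=[str(c) for c in features.columns],
        coefficients=est.coef_.copy(),
        intercept=est.intercept_,
        chosen_lambda=est.lambda_,
        per_fold_feature_counts=list(est.per_fold_feature_counts_),
        per_fold_lambdas=list(est.per_fold_lambdas_),
        training_metrics={
            "cv_mae_days": est.cv_mae_,
            "cv_mre_percent": est.cv_mre_,
            "cv_pearson_r": est.cv_r_,
        },
        estimator=est,
    )


def predict_age(model: ClockModel, features: pd.DataFrame) -> np.ndarray:
    """Apply a trained clock; predictions are not clamped."""
    missing = [c for c in model.feature_names if c not in features.columns]
    if missing:
        raise ValueError(
            f"{len(missing)} model feature(s) missing from input, e.g. {missing[:5]}"
        )
    X = features.loc[:, model.feature_names].to_numpy(dtype=float)
    return model.intercept + X @ model.coefficients


def evaluate_predictions(
    predicted: Sequence[float], true_ages: Sequence[float]
) -> tuple[float, float, float]:
    """(MAE in days, MRE in % of chronological age, Pearson r)."""
    pred = np.asarray(predicted, dtype=float)
    true = np.asarray(true_ages, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("prediction/age length mismatch")
    if pred.size < 2:
        raise ValueError("need at least 2 samples")
    if np.any(true <= 0):
        raise ValueError("true ages must be positive")
    mae = float(np.mean(np.abs(pred - true)))
    mre = float(100.0 * np.mean(np.abs(pred - true) / true))
    if np.ptp(pred) == 0 or np.ptp(true) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(pred, true).statistic)
    return mae, mre, r


@dataclass
class PermutationResult:
    p_value: float
    observed: float
    statistic: str
    null_values: np.ndarray


def permutation_test(
    features: pd.DataFrame,
    ages_days: Sequence[float],
    spec: ClockSpec | str,
    n_perm: int = 100,
    seed: int = 0,
    statistic: str = "mae",
) -> PermutationResult:
    """Does the clock beat age-shuffled data?

    The observed statistic is the outer-LOOCV value from nested training
    (MAE by default; ``mre`` and ``r`` available); each permutation
    shuffles the ages and reruns the full nested procedure.  The add-one
    estimator ``p = (1 + #{perm at least as good}) / (n_perm + 1)`` keeps p
    strictly positive.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if statistic not in ("mae", "mre", "r"):
        raise ValueError(f"unknown permutation statistic {statistic!r}")
    ages = np.asarray(ages_days, dtype=float)
    rng = np.random.default_rng(seed)

    def _stat(model: ClockModel) -> float:
        m = model.training_metrics
        return {
            "mae": m["cv_mae_days"], "mre": m["cv_mre_percent"],
            "r": m["cv_pearson_r"],
        }[statistic]

    observed = _stat(train_clock(features, ages, spec))
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = _stat(train_clock(features, rng.permutation(ages), spec))
    if statistic == "r":
        better = np.sum(null >= observed)
    else:
        better = np.sum(null <= observed)
    p = (1 + int(better)) / (n_perm + 1)
    return PermutationResult(float(p), float(observed), statistic, null)


@dataclass
class StabilityResult:
    mean_features: float
    cv_percent: float               # sample-SD convention (ddof=1)
    cv_percent_population: float    # population-SD convention (ddof=0)
    is_ridge: bool = False
    note: str = ""


def feature_stability(model: ClockModel) -> StabilityResult:
    """Mean and coefficient of variation of per-fold selected-feature counts."""
    counts = np.asarray(model.per_fold_feature_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("no per-fold feature counts recorded")
    if model.spec.mixing == 0:
        return StabilityResult(
            mean_features=float(counts.mean()), cv_percent=0.0,
            cv_percent_population=0.0, is_ridge=True,
            note="ridge models do not perform feature selection",
        )
    if counts.size < 2:
        raise ValueError("CV of feature counts undefined with a single fold")
    mean = float(counts.mean())
    return StabilityResult(
        mean_features=mean,
        cv_percent=float(100.0 * counts.std(ddof=1) / mean),
        cv_percent_population=float(100.0 * counts.std(ddof=0) / mean),
    )


@dataclass
class ArmResult:
    arm: str
    mean_predicted_age: float
    delta_vs_control: float     # mean(treated) - mean(control), days
    p_vs_control: float
    younger: bool


@dataclass
class DecelerationResult:
    chronological_age_days: float
    control_mean_predicted_age: float
    omnibus: GroupComparison
    arms: list[ArmResult]


def age_deceleration_test(
    model: ClockModel,
    control_features: pd.DataFrame,
    treated_features_by_arm: Mapping[str, pd.DataFrame],
    chronological_age_days: float,
) -> DecelerationResult:
    """Is any treated arm's predicted epigenetic age below control?

    All samples share one chronological age; arms are compared with the
    gated group test (ANOVA/Tukey or Kruskal/Mann-Whitney) on predicted
    ages, and each arm reports its post hoc p-value against control and the
    sign of the difference.
    """
    if len(control_features) < 3:
        raise ValueError("control arm needs at least 3 samples")
    preds = {"control": predict_age(model, control_features)}
    for arm, feats in treated_features_by_arm.items():
        if len(feats) < 3:
            raise ValueError(f"arm {arm!r} needs at least 3 samples")
        preds[arm] = predict_age(model, feats)
    omnibus = compare_groups({g: list(v) for g, v in preds.items()})
    control_mean = float(np.mean(preds["control"]))
    arms = []
    for arm in treated_features_by_arm:
        mean_pred = float(np.mean(preds[arm]))
        delta = mean_pred - control_mean
        arms.append(
            ArmResult(
                arm=arm, mean_predicted_age=mean_pred, delta_vs_control=delta,
                p_vs_control=omnibus.pairwise_p("control", arm),
                younger=delta < 0,
            )
        )
    return DecelerationResult(
        chronological_age_days=float(chronological_age_days),
        control_mean_predicted_age=control_mean,
        omnibus=omnibus,
        arms=arms,
    )
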