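"""Comparison regressors: stepwise multiple linear regression and elastic net.

All baselines are judged under the identical CV harness (one shared fold
partition, pooled out-of-fold Pearson correlation and MAE), so differences
in the comparison table reflect the methods, not the evaluation.

The elastic-net objective is

    min over (b0, b)   (1/2M) sum_i (y_i - b0 - x_i'b)^2 + lambda * P_alpha(b),
    P_alpha(b) = alpha * ||b||_1 + (1 - alpha) * ||b||_2^2 / 2,

which maps exactly onto scikit-learn's ``ElasticNet(alpha=lambda,
l1_ratio=alpha)``. alpha = 1 is the LASSO, alpha = 0 ridge regression; the
ridge limit is solved in closed form (coefficients (X'X + M*lambda*I)^-1 X'y
on centered data) and lambda = 0 reduces to ordinary least squares.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet

from .cohort import Cohort
from .errors import ConfigError, UndefinedCorrelationError
from .ga import GAConfig, run_ibcga
from .regression import CVResult, kfold_indices, mean_absolute_error, pearson_cc

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = tuple(np.logspace(-3, 2, 50))


@dataclass
class LinearModel:
    """Sparse linear predictor: intercept + per-selected-feature coefficients."""

    intercept: float
    coefficients: np.ndarray
    selected_features: list[str]

    def predict(self, cohort: Cohort) -> np.ndarray:
        idx = [cohort.feature_index(f) for f in self.selected_features]
        return self.intercept + cohort.X[:, idx] @ self.coefficients


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray] | None:
    """Least-squares fit with intercept via orthogonal decomposition.

    Returns None on rank deficiency (caller drops the offending candidate).
    """
    A = np.column_stack([np.ones(len(y)), X])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        return None
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(coef[0]), coef[1:]


def _cv_linear(X: np.ndarray, y: np.ndarray, folds, fit) -> CVResult | None:
    """Pooled out-of-fold metrics for a linear fitter ``fit(X, y) -> (b0, b)``."""
    preds = np.empty(len(y))
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        fitted = fit(X[train_idx], y[train_idx])
        if fitted is None:
            return None
        b0, b = fitted
        preds[test_idx] = b0 + X[test_idx] @ b
    try:
        cc = pearson_cc(y, preds)
    except UndefinedCorrelationError:
        return None
    return CVResult(cc=cc, mae=mean_absolute_error(y, preds), per_sample_pred=preds)


def stepwise_mlr(cohort: Cohort, max_features: int = 30, cv_seed: int = 0,
                 k: int = 10) -> tuple[LinearModel, CVResult]:
    """Forward stepwise multiple linear regression selected by CV correlation.

    Starting from the empty model, repeatedly add the feature that maximizes
    the pooled CV Pearson correlation of the OLS fit; stop when no addition
    improves the correlation or ``max_features`` is reached. An intercept-only
    model (predicting mean(y)) is returned — with a warning — if no feature
    helps at all.
    """
    folds = kfold_indices(cohort.M, k, cv_seed)
    selected: list[int] = []
    best_cv: CVResult | None = None
    best_cc = -np.inf
    while len(selected) < max_features:
        best_step = None
        for j in range(cohort.n):
            if j in selected:
                continue
            cols = selected + [j]
            res = _cv_linear(cohort.X[:, cols], cohort.y, folds,
                             lambda A, b: _ols(A, b))
            if res is not None and (best_step is None or res.cc > best_step[1].cc):
                best_step = (j, res)
        if best_step is None or best_step[1].cc <= best_cc:
            break
        selected.append(best_step[0])
        best_cv = best_step[1]
        best_cc = best_cv.cc

    if not selected:
        logger.warning("no feature improves over the intercept-only model")
        mean_y = float(cohort.y.mean())
        model = LinearModel(mean_y, np.empty(0), [])
        preds = np.full(cohort.M, mean_y)
        return model, CVResult(cc=0.0, mae=mean_absolute_error(cohort.y, preds),
                               per_sample_pred=preds)

    b0, b = _ols(cohort.X[:, selected], cohort.y)
    model = LinearModel(b0, b, [cohort.feature_names[j] for j in selected])
    return model, best_cv


def _enet_fit(X, y, lam: float, alpha: float) -> tuple[float, np.ndarray]:
    """One elastic-net solve; closed forms for the lambda=0 and alpha=0 limits."""
    if lam == 0:
        fitted = _ols(X, y)
        if fitted is None:  # fall back to minimum-norm solution
            A = np.column_stack([np.ones(len(y)), X])
            coef = np.linalg.pinv(A) @ y
            return float(coef[0]), coef[1:]
        return fitted
    if alpha == 0:
        # ridge: (X'X + M*lam*I)^-1 X'y on centered data, intercept from means
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        M = len(y)
        b = np.linalg.solve(Xc.T @ Xc + M * lam * np.eye(X.shape[1]), Xc.T @ yc)
        return float(y.mean() - X.mean(axis=0) @ b), b
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est = ElasticNet(alpha=lam, l1_ratio=alpha, max_iter=100_000, tol=1e-10)
        est.fit(X, y)
    return float(est.intercept_), est.coef_


def elastic_net(cohort: Cohort, alpha: float = 0.5,
                lambda_grid=DEFAULT_LAMBDA_GRID, cv_seed: int = 0,
                k: int = 10) -> tuple[LinearModel, CVResult]:
    """Elastic-net regression with lambda chosen by CV correlation.

    ``alpha`` is the L1/L2 mix: 1 = LASSO, 0 = ridge. The model refitted on
    the full cohort at the winning lambda is returned; features with nonzero
    coefficients count as selected.
    """
    lambda_grid = list(lambda_grid)
    if not lambda_grid:
        raise ConfigError("empty lambda grid")
    if not (0 <= alpha <= 1):
        raise ConfigError("alpha must lie in [0, 1]")
    folds = kfold_indices(cohort.M, k, cv_seed)
    best: tuple[float, float, CVResult] | None = None  # (cc, lam, cv)
    for lam in lambda_grid:
        res = _cv_linear(cohort.X, cohort.y, folds,
                         lambda A, b: _enet_fit(A, b, lam, alpha))
        if res is None:
            continue
        if best is None or res.cc > best[0]:
            best = (res.cc, lam, res)
    if best is None:
        raise UndefinedCorrelationError(
            "every lambda produced constant predictions (grid too aggressive)")
    _, lam, cv = best
    b0, b = _enet_fit(cohort.X, cohort.y, lam, alpha)
    nz = np.flatnonzero(np.abs(b) > 1e-12)
    model = LinearModel(b0, b[nz], [cohort.feature_names[j] for j in nz])
    logger.info("elastic net alpha=%.2f chose lambda=%.4g with %d features",
                alpha, lam, len(nz))
    return model, cv


def compare_methods(cohort: Cohort, cfg: GAConfig, max_features: int = 30,
                    lambda_grid=DEFAULT_LAMBDA_GRID,
                    enet_alpha: float = 0.5) -> pd.DataFrame:
    """Head-to-head comparison table of all methods on one cohort.

    Runs stepwise MLR, elastic net, LASSO, ridge, the full GA selector, and
    the GA restricted to each baseline's selected feature count (for a fair
    same-size comparison). All methods share the CV partition derived from
    ``cfg.cv_seed``.
    """
    rows = []

    def add(method: str, n_feat, cv: CVResult) -> None:
        rows.append({"Method": method, "Features_selected": n_feat,
                     "Correlation_coefficient": cv.cc, "Mean_absolute_error": cv.mae})

    mlr_model, mlr_cv = stepwise_mlr(cohort, max_features, cfg.cv_seed, cfg.k_folds)
    add("Stepwise multiple linear regression", len(mlr_model.selected_features), mlr_cv)
    for label, a in [("Elastic net", enet_alpha), ("LASSO", 1.0), ("Ridge regression", 0.0)]:
        model, cv = elastic_net(cohort, a, lambda_grid, cfg.cv_seed, cfg.k_folds)
        add(label, len(model.selected_features), cv)

    full = run_ibcga(cohort, cfg)
    add("GA-SVR", full.m, CVResult(full.fitness, full.mae, None))

    fair_sizes = sorted({len(mlr_model.selected_features),
                         rows[1]["Features_selected"]})  # stepwise + elastic net
    for size in fair_sizes:
        if size < 1 or size == full.m:
            continue
        res = run_ibcga(cohort, replace(cfg, r_start=size, r_end=size))
        add(f"GA-SVR-{size}", res.m, CVResult(res.fitness, res.mae, None))

    return pd.DataFrame(rows)
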