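"""Lasso temporal-regression decoder of alertness.

The comparison method to template projection: an L1-penalized linear
regression from voxel or ROI time series (rows = volumes) to the EEG
alertness index, trained on temporally concatenated resting-state scans
with k-fold cross-validation over a log-spaced lambda grid, then applied
to task scans. ROI extraction from an integer-labeled parcellation serves
as the dimensionality-reduction front end.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold

from .datatypes import AlertnessIndex, FMRIScan, ROITimeseries

__all__ = ["extract_roi_timeseries", "fit_lasso", "predict_alertness",
           "LassoAlertnessDecoder"]

logger = logging.getLogger(__name__)


def extract_roi_timeseries(scan: FMRIScan, atlas: np.ndarray) -> ROITimeseries:
    """Region-mean time series from an integer-labeled parcellation.

    Per region (label > 0), the mean series over in-mask voxels carrying
    that label. Labels with no in-mask voxels are absent from the output
    (logged).
    """
    atlas = np.asarray(atlas)
    if atlas.shape != scan.mask.shape:
        raise ValueError("atlas grid must match the scan grid")
    labels = np.unique(atlas)
    labels = labels[labels > 0]
    cols, kept = [], []
    for label in labels:
        sel = (atlas == label) & scan.mask
        if not sel.any():
            logger.info("atlas label %s has no in-mask voxels; dropped", label)
            continue
        cols.append(scan.data[sel].mean(axis=0))
        kept.append(label)
    if not cols:
        raise ValueError("no atlas labels fall inside the scan mask")
    return ROITimeseries(matrix=np.column_stack(cols),
                         region_ids=np.asarray(kept))


class LassoAlertnessDecoder(BaseEstimator, RegressorMixin):
    """Cross-validated lasso from BOLD features to the EEG alertness index.

    Features are standardized on the training rows (centering and scale
    stored, never refit on test data); a coordinate-descent lasso is fit
    over a log-spaced lambda grid and the lambda minimizing mean k-fold CV
    error is selected, then the model is refit on all training rows.

    Parameters
    ----------
    k_folds : int
        Cross-validation folds (rows shuffled; a ``blocked`` option keeps
        temporally contiguous folds for autocorrelated rows).
    n_lambdas : int
        Grid size; lambdas span 4 decades down from the null-model lambda.
    blocked : bool
        Use contiguous (blocked) folds instead of shuffled rows.
    seed : int
        Fold-assignment seed.

    Attributes
    ----------
    coef_ : ndarray — lasso coefficients on the standardized scale.
    intercept_ : float
    lambda_ : float — selected penalty.
    cv_curve_ : ndarray, (n_lambdas, 2) — lambda and mean CV error.
    feature_mean_, feature_scale_ : ndarray — training scaling record.
    """

    def __init__(self, k_folds: int = 10, n_lambdas: int = 50,
                 blocked: bool = False, seed: int = 0,
                 lambda_grid: np.ndarray | None = None):
        self.k_folds = k_folds
        self.n_lambdas = n_lambdas
        self.blocked = blocked
        self.seed = seed
        self.lambda_grid = lambda_grid

    def _lambda_grid(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        if self.lambda_grid is not None:
            return np.asarray(self.lambda_grid, float)
        lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / X.shape[0]
        return np.geomspace(lam_max, lam_max * 1e-4, self.n_lambdas)

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        if X.shape[0] != y.size:
            raise ValueError("feature rows must match target length")
        if self.k_folds < 2:
            raise ValueError("k_folds must be at least 2")
        if y.std() == 0:
            raise ValueError("target is constant; nothing to decode")
        self.feature_mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        self.feature_scale_ = np.where(scale == 0, 1.0, scale)
        Xs = (X - self.feature_mean_) / self.feature_scale_

        grid = self._lambda_grid(Xs, y)
        if self.blocked:
            folds = list(KFold(self.k_folds).split(Xs))
        else:
            folds = list(KFold(self.k_folds, shuffle=True,
                               random_state=self.seed).split(Xs))
        cv_err = np.zeros(grid.size)
        for train, test in folds:
            model = Lasso(warm_start=True, max_iter=2000, tol=1e-4)
            for i, lam in enumerate(grid):
                model.set_params(alpha=lam)
                model.fit(Xs[train], y[train])
                pred = model.predict(Xs[test])
                cv_err[i] += np.mean((pred - y[test]) ** 2)
        cv_err /= len(folds)
        best = int(np.argmin(cv_err))
        self.lambda_ = float(grid[best])
        self.cv_curve_ = np.column_stack([grid, cv_err])
        final = Lasso(alpha=self.lambda_, max_iter=50000,
                      tol=1e-10 if self.lambda_ < 1e-8 else 1e-6)
        final.fit(Xs, y)
        self.coef_ = final.coef_
        self.intercept_ = float(final.intercept_)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "coef_"):
            raise AttributeError("decoder is not fitted")
        X = np.asarray(X, float)
        if X.shape[1] != self.coef_.size:
            raise ValueError(f"expected {self.coef_.size} features, "
                             f"got {X.shape[1]}")
        Xs = (X - self.feature_mean_) / self.feature_scale_
        return self.intercept_ + Xs @ self.coef_


def fit_lasso(features: np.ndarray, target: np.ndarray, k_folds: int = 10,
              n_lambdas: int = 50, seed: int = 0) -> LassoAlertnessDecoder:
    """Fit the cross-validated lasso decoder (thin estimator wrapper)."""
    return LassoAlertnessDecoder(k_folds=k_folds, n_lambdas=n_lambdas,
                                 seed=seed).fit(features, target)


def predict_alertness(model: LassoAlertnessDecoder, features: np.ndarray,
                      tr: float = 2.1) -> AlertnessIndex:
    """Predicted alertness series for a task feature matrix.

    The prediction is an unbounded regression output (its target is the
    hemodynamic EEG index), so it carries the ``fmri_lasso`` kind rather
    than the correlation-bounded ``fmri`` kind. Training-time feature
    scaling is applied from the stored record, never refit on test data.
    """
    pred = model.predict(features)
    return AlertnessIndex(values=pred, tr=tr, kind="fmri_lasso",
                          lineage=("lasso_prediction",))
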