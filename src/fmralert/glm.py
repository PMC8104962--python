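"""Voxelwise GLM of auditory-evoked responses with alertness covariates.

Event regressors are unit impulses at the TR nearest each onset, convolved
with the canonical HRF; hit and miss trials form separate regressors (the
miss column is a covariate of no interest). Alertness indices may be added
as mean-centered covariates. Per-scan OLS beta/t maps feed a group-level
voxelwise one-sample t-test.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .datatypes import AlertnessIndex, DesignMatrix, FMRIScan, GLMResult
from .hrf import HRFSpec, default_hrf

__all__ = ["build_design", "fit_glm", "group_level"]


def _event_column(onsets: np.ndarray, kernel: np.ndarray, n_volumes: int,
                  tr: float) -> np.ndarray:
    stick = np.zeros(n_volumes)
    for onset in onsets:
        if not (0.0 <= onset < n_volumes * tr):
            raise ValueError(f"onset {onset:.1f} s outside the scan")
        # nearest TR, clipped so an onset in the final half-TR maps to the
        # last acquired volume
        i = min(int(round(onset / tr)), n_volumes - 1)
        stick[i] += 1.0
    return np.convolve(stick, kernel)[:n_volumes]


def build_design(hit_onsets: np.ndarray, miss_onsets: np.ndarray,
                 covariates: dict[str, AlertnessIndex] | None = None,
                 hrf: HRFSpec | None = None, n_volumes: int = 700,
                 tr: float = 2.1) -> DesignMatrix:
    """Assemble the task design matrix.

    Columns: HRF-convolved hit and miss event trains (onsets snapped to
    the nearest TR), mean-centered alertness covariates, and an intercept.
    An empty miss condition is dropped with a warning; rank deficiency
    raises naming the offending columns.
    """
    if hrf is None:
        hrf = default_hrf()
    kernel = hrf.kernel(tr)
    columns, names = [], []
    columns.append(_event_column(np.asarray(hit_onsets, float), kernel,
                                 n_volumes, tr))
    names.append("hits")
    miss_onsets = np.asarray(miss_onsets, float)
    if miss_onsets.size:
        columns.append(_event_column(miss_onsets, kernel, n_volumes, tr))
        names.append("misses")
    else:
        warnings.warn("no miss onsets; miss regressor dropped", stacklevel=2)
    for name, cov in (covariates or {}).items():
        if len(cov) != n_volumes:
            raise ValueError(f"covariate '{name}' length {len(cov)} != "
                             f"{n_volumes} volumes")
        columns.append(cov.values - cov.values.mean())
        names.append(name)
    columns.append(np.ones(n_volumes))
    names.append("intercept")
    return DesignMatrix(columns=np.column_stack(columns), names=names, tr=tr)


def fit_glm(scan: FMRIScan, design: DesignMatrix) -> GLMResult:
    """Ordinary least squares per masked voxel.

    Returns betas, residual variance (dof = volumes - rank) and
    per-regressor t statistics. Voxels with zero residual variance get
    t = 0 for zero betas and +/-inf otherwise.
    """
    if scan.n_volumes != design.n_volumes:
        raise ValueError(f"scan has {scan.n_volumes} volumes but design has "
                         f"{design.n_volumes} rows")
    X = design.columns
    Y = scan.masked_series().T                     # (T, n_vox)
    n, k = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = n - rank
    resvar = (resid ** 2).sum(axis=0) / dof
    xtx_inv_diag = np.diag(np.linalg.inv(X.T @ X))
    se = np.sqrt(np.outer(xtx_inv_diag, resvar))   # (k, n_vox)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.where(beta == 0, 0.0,
                                                 np.sign(beta) * np.inf))
    shape = scan.mask.shape
    beta_maps = np.zeros(shape + (k,))
    t_maps = np.zeros(shape + (k,))
    rv_map = np.zeros(shape)
    beta_maps[scan.mask] = beta.T
    t_maps[scan.mask] = t.T
    rv_map[scan.mask] = resvar
    return GLMResult(beta=beta_maps, residual_var=rv_map, t=t_maps,
                     dof=int(dof), names=list(design.names),
                     mask=scan.mask.copy())


def group_level(betas: list[np.ndarray], mask: np.ndarray | None = None
                ) -> np.ndarray:
    """Voxelwise one-sample t-test of per-scan beta maps against zero.

    Returns the group t map (df = n_scans - 1). Voxels with zero
    between-scan variance and nonzero mean are flagged with +/-inf.
    """
    if len(betas) < 2:
        raise ValueError("group-level test requires at least 2 scans")
    stack = np.stack([np.asarray(b, float) for b in betas])
    if mask is None:
        mask = np.ones(stack.shape[1:], dtype=bool)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    # treat numerically-zero between-scan variance as degenerate
    degenerate = sd <= 1e-12 * np.maximum(np.abs(mean), 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(~degenerate, mean / (sd / np.sqrt(n)),
                     np.where(mean == 0, 0.0, np.sign(mean) * np.inf))
    t[~mask] = 0.0
    return t


def group_p(t_map: np.ndarray, n_scans: int) -> np.ndarray:
    """Two-tailed p map for a group t map with df = n_scans - 1."""
    return 2.0 * stats.t.sf(np.abs(t_map), n_scans - 1)
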