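"""Template projection: the fMRI alertness index and its evaluation.

Projecting the vigilance template onto each successive (temporally
z-scored) volume of a scan — a spatial Pearson correlation per volume —
yields the fMRI alertness index. Agreement with the EEG alertness index is
quantified by lagged temporal cross-correlation, against a permutation
null built from mismatched EEG-fMRI scan pairings.

The :class:`TemplateVigilanceDecoder` estimator wraps the train/apply
cycle in scikit-learn fit/predict form.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import (
    AlertnessIndex,
    CrossCorrFunction,
    FMRIScan,
    PermutationNull,
    SplitPlan,
    ThresholdedTemplate,
    VigilanceTemplate,
)
from .template import build_template, threshold_template, voxelwise_correlation

__all__ = [
    "zscore_scan",
    "project_template",
    "cross_correlate",
    "permutation_null",
    "evaluate_split",
    "TemplateVigilanceDecoder",
]

logger = logging.getLogger(__name__)


def zscore_scan(scan: FMRIScan) -> FMRIScan:
    """Temporally z-score every masked voxel series (mean 0, sd 1).

    Zero-variance voxels are set to 0 (count logged); mask and affine
    pass through unchanged. Idempotent.
    """
    if scan.n_volumes < 2:
        raise ValueError("z-scoring requires at least 2 volumes")
    series = scan.masked_series()
    mean = series.mean(axis=1, keepdims=True)
    sd = series.std(axis=1, keepdims=True)
    flat = sd.ravel() == 0
    n_deg = int(flat.sum())
    if n_deg:
        logger.info("zscore_scan: %d zero-variance voxels set to 0", n_deg)
    z = (series - mean) / np.where(sd == 0, 1.0, sd)
    z[flat] = 0.0
    data = np.zeros_like(scan.data)
    data[scan.mask] = z
    return FMRIScan(data=data, tr=scan.tr, mask=scan.mask.copy(),
                    affine=scan.affine.copy(), scan_id=scan.scan_id)


def project_template(scan: FMRIScan,
                     template: VigilanceTemplate | ThresholdedTemplate
                     ) -> AlertnessIndex:
    """fMRI alertness index: spatial correlation of template and each volume.

    For each volume t, the value is the Pearson correlation between the
    template weights and the volume's intensities over the projection
    support (the template's retained voxels intersected with the scan
    mask). Output length equals the volume count; values lie in [-1, 1].
    """
    if template.values.shape != scan.mask.shape:
        raise ValueError("template and scan grids differ")
    support = template.support & scan.mask
    n_vox = int(support.sum())
    if n_vox < 3:
        raise ValueError(
            f"degenerate projection support: {n_vox} overlapping voxels")
    w = template.values[support]
    w = w - w.mean()
    w_norm = np.sqrt((w ** 2).sum())
    if w_norm == 0:
        raise ValueError("template is constant over the projection support")
    vols = scan.data[support]                      # (n_vox, n_volumes)
    vols = vols - vols.mean(axis=0, keepdims=True)
    v_norm = np.sqrt((vols ** 2).sum(axis=0))
    denom = np.where(v_norm == 0, 1.0, w_norm * v_norm)
    r = (w @ vols) / denom
    r[v_norm == 0] = 0.0
    return AlertnessIndex(values=np.clip(r, -1.0, 1.0), tr=scan.tr,
                          kind="fmri", lineage=(f"project:{scan.scan_id}",))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    d = np.sqrt((x ** 2).sum() * (y ** 2).sum())
    if d == 0:
        return 0.0
    return float(np.clip((x * y).sum() / d, -1.0, 1.0))


def cross_correlate(a: AlertnessIndex | np.ndarray,
                    b: AlertnessIndex | np.ndarray,
                    max_lag: int = 10) -> CrossCorrFunction:
    """Lagged Pearson correlation between two equal-length series.

    At positive lag L the first series leads: r(L) = corr(a[:-L], b[L:]),
    so a peak at +L means ``b`` reproduces ``a`` delayed by L samples.
    Lag 0 is simultaneity.
    """
    av = a.values if isinstance(a, AlertnessIndex) else np.asarray(a, float)
    bv = b.values if isinstance(b, AlertnessIndex) else np.asarray(b, float)
    if av.size != bv.size:
        raise ValueError(f"length mismatch: {av.size} vs {bv.size}")
    n = av.size
    if max_lag >= n / 2:
        raise ValueError("max_lag must be below half the series length")
    lags = np.arange(-max_lag, max_lag + 1)
    values = np.empty(lags.size)
    for i, lag in enumerate(lags):
        if lag >= 0:
            seg_a, seg_b = av[:n - lag] if lag else av, bv[lag:]
        else:
            seg_a, seg_b = av[-lag:], bv[:n + lag]
        values[i] = _pearson(seg_a, seg_b)
    return CrossCorrFunction(lags=lags, values=values)


def _sample_derangement(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform random derangement of ``range(n)`` by rejection sampling."""
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def pairwise_crosscorr_matrix(fmri_indices, eeg_indices, max_lag: int
                              ) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs cross-correlation curves, (n_scans, n_scans, n_lags)."""
    n_common = min(min(len(f) for f in fmri_indices),
                   min(len(e) for e in eeg_indices))
    n = len(fmri_indices)
    lags = np.arange(-max_lag, max_lag + 1)
    curves = np.empty((n, n, lags.size))
    for i in range(n):
        fi = np.asarray(fmri_indices[i].values
                        if isinstance(fmri_indices[i], AlertnessIndex)
                        else fmri_indices[i])[:n_common]
        for j in range(n):
            ej = np.asarray(eeg_indices[j].values
                            if isinstance(eeg_indices[j], AlertnessIndex)
                            else eeg_indices[j])[:n_common]
            curves[i, j] = cross_correlate(fi, ej, max_lag).values
    return curves, lags


def permutation_null(fmri_indices, eeg_indices, max_lag: int = 10,
                     n_perm: int = 1000, seed: int = 0) -> PermutationNull:
    """Null cross-correlation from mismatched EEG-fMRI pairings.

    Each draw pairs every fMRI alertness index with the EEG index of a
    *different* scan (a random derangement — shuffling the assignment
    between scans with no self-pairs), computes the per-pair lagged
    cross-correlation, and stores the across-pair mean curve. Scans of
    unequal length are truncated to the common minimum.
    """
    n = len(fmri_indices)
    if n != len(eeg_indices):
        raise ValueError("need one EEG index per fMRI index")
    if n < 3:
        raise ValueError("permutation null requires at least 3 scans")
    rng = np.random.default_rng(seed)
    curves, lags = pairwise_crosscorr_matrix(fmri_indices, eeg_indices, max_lag)
    draws = np.empty((n_perm, lags.size))
    rows = np.arange(n)
    for p in range(n_perm):
        perm = _sample_derangement(rng, n)
        draws[p] = curves[rows, perm].mean(axis=0)
    return PermutationNull(draws=draws, lags=lags, seed=seed)


def evaluate_split(scans: dict[str, FMRIScan],
                   eeg_indices: dict[str, AlertnessIndex],
                   plan: SplitPlan, max_lag: int = 10, n_perm: int = 1000,
                   seed: int = 0,
                   template: VigilanceTemplate | ThresholdedTemplate | None = None,
                   threshold_fraction: float | None = None,
                   threshold_mode: str = "both",
                   ) -> tuple[dict[str, CrossCorrFunction], PermutationNull,
                              VigilanceTemplate | ThresholdedTemplate]:
    """Train a template on the plan's train scans, evaluate on its test scans.

    The template is built only from the train scans (each correlated with
    its own EEG alertness index), optionally thresholded, then projected
    onto each z-scored test scan; each resulting fMRI alertness index is
    cross-correlated with that scan's EEG index. The permutation null
    shuffles the EEG-fMRI assignment between test scans (derangements).

    Returns ``(curves_by_scan, null, template)``. Train/test overlap is a
    structural error of the :class:`SplitPlan` itself (leakage guard).
    """
    missing = (plan.train_scan_ids | plan.test_scan_ids) - set(scans)
    if missing:
        raise KeyError(f"scan ids not provided: {sorted(missing)}")
    if template is None:
        maps = [voxelwise_correlation(scans[sid], eeg_indices[sid])
                for sid in sorted(plan.train_scan_ids)]
        template = build_template(maps)
        if threshold_fraction is not None:
            template = threshold_template(template, threshold_fraction,
                                          threshold_mode)
    test_ids = sorted(plan.test_scan_ids)
    fmri_idx, eeg_idx, curves = [], [], {}
    for sid in test_ids:
        fmri = project_template(zscore_scan(scans[sid]), template)
        fmri_idx.append(fmri)
        eeg_idx.append(eeg_indices[sid])
        n_common = min(len(fmri), len(eeg_indices[sid]))
        curves[sid] = cross_correlate(fmri.values[:n_common],
                                      eeg_indices[sid].values[:n_common],
                                      max_lag)
    null = permutation_null(fmri_idx, eeg_idx, max_lag=max_lag,
                            n_perm=n_perm, seed=seed)
    return curves, null, template


class TemplateVigilanceDecoder(BaseEstimator, TransformerMixin):
    """Vigilance-template decoder in scikit-learn fit/predict form.

    ``fit`` builds the group template from training scans and their EEG
    alertness indices; ``predict`` (= ``transform``) projects it onto new
    scans to produce fMRI alertness indices without EEG.

    Parameters
    ----------
    threshold_fraction : float or None
        If set, sparsify the fitted template to this per-sign fraction of
        strongest voxels.
    threshold_mode : {'both', 'positive', 'negative'}
        Which sign(s) to retain when thresholding.
    zscore : bool
        Temporally z-score scans before projection (the standard pipeline).

    Attributes
    ----------
    template_ : VigilanceTemplate or ThresholdedTemplate
        The fitted (possibly sparsified) group template.
    n_scans_ : int
        Number of training scans.
    """

    def __init__(self, threshold_fraction: float | None = None,
                 threshold_mode: str = "both", zscore: bool = True):
        self.threshold_fraction = threshold_fraction
        self.threshold_mode = threshold_mode
        self.zscore = zscore

    def fit(self, X: list[FMRIScan], y: list[AlertnessIndex]):
        if len(X) == 0 or len(X) != len(y):
            raise ValueError("fit requires one EEG alertness index per scan")
        maps = [voxelwise_correlation(scan, idx) for scan, idx in zip(X, y)]
        template = build_template(maps)
        if self.threshold_fraction is not None:
            template = threshold_template(template, self.threshold_fraction,
                                          self.threshold_mode)
        self.template_ = template
        self.n_scans_ = len(X)
        return self

    def transform(self, X) -> list[AlertnessIndex] | AlertnessIndex:
        if not hasattr(self, "template_"):
            raise AttributeError("decoder is not fitted")
        single = isinstance(X, FMRIScan)
        scans = [X] if single else list(X)
        out = []
        for scan in scans:
            if self.zscore:
                scan = zscore_scan(scan)
            out.append(project_template(scan, self.template_))
        return out[0] if single else out

    def predict(self, X):
        return self.transform(X)

    def score(self, X, y, max_lag: int = 10) -> float:
        """Mean peak cross-correlation against reference indices."""
        pred = self.transform(X)
        if isinstance(pred, AlertnessIndex):
            pred, y = [pred], [y]
        peaks = []
        for p, ref in zip(pred, y):
            n = min(len(p), len(ref))
            peaks.append(cross_correlate(p.values[:n], ref.values[:n],
                                         max_lag).peak_value)
        return float(np.mean(peaks))
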