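"""Vigilance-template construction and sparsification.

The template is the voxelwise Pearson correlation between each training
scan's BOLD series and its EEG alertness index, Fisher-Z transformed and
averaged across scans. Thresholding retains only the top fraction of
positive and/or negative voxels by magnitude, for testing how small a
voxel set still decodes arousal.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .datatypes import (
    AlertnessIndex,
    CorrelationMap,
    FMRIScan,
    ThresholdedTemplate,
    VigilanceTemplate,
)

__all__ = [
    "voxelwise_correlation",
    "build_template",
    "threshold_template",
    "THRESHOLD_FRACTIONS",
]

logger = logging.getLogger(__name__)

#: Retention-fraction grid of the sparsification experiment.
THRESHOLD_FRACTIONS = (1.0, 0.8, 0.6, 0.4, 0.2, 0.1, 0.05, 0.01)

_FISHER_CLAMP = 1.0 - 1e-7


def voxelwise_correlation(scan: FMRIScan, index: AlertnessIndex) -> CorrelationMap:
    """Pearson r between every masked voxel series and the alertness index.

    Zero-variance voxels get r = 0; their count is logged.
    """
    if len(index) != scan.n_volumes:
        raise ValueError(
            f"index length {len(index)} != scan volumes {scan.n_volumes}")
    series = scan.masked_series()
    x = series - series.mean(axis=1, keepdims=True)
    y = index.values - index.values.mean()
    y_norm = np.sqrt((y ** 2).sum())
    x_norm = np.sqrt((x ** 2).sum(axis=1))
    degenerate = (x_norm == 0) | (y_norm == 0)
    denom = np.where(degenerate, 1.0, x_norm * y_norm)
    r = (x @ y) / denom
    r[degenerate] = 0.0
    n_deg = int(degenerate.sum())
    if n_deg:
        logger.info("voxelwise_correlation: %d zero-variance voxels set to r=0",
                    n_deg)
    values = np.zeros(scan.mask.shape)
    values[scan.mask] = np.clip(r, -1.0, 1.0)
    return CorrelationMap(values=values, mask=scan.mask.copy(),
                          source_scan_id=scan.scan_id)


def build_template(maps: list[CorrelationMap]) -> VigilanceTemplate:
    """Fisher-Z transform each correlation map and average across scans.

    The output mask is the intersection of the contributing masks.
    Correlations with |r| = 1 (degenerate voxels) are clamped to
    1 - 1e-7 before atanh, with a warning.
    """
    if not maps:
        raise ValueError("build_template requires at least one map")
    shape = maps[0].values.shape
    for m in maps:
        if m.values.shape != shape:
            raise ValueError("correlation maps must share a grid")
    mask = np.logical_and.reduce([m.mask for m in maps])
    stack = np.stack([m.values[mask] for m in maps])
    if np.any(np.abs(stack) >= 1.0):
        warnings.warn("|r| = 1 encountered; clamping before Fisher-Z",
                      stacklevel=2)
        stack = np.clip(stack, -_FISHER_CLAMP, _FISHER_CLAMP)
    z = np.arctanh(stack).mean(axis=0)
    values = np.zeros(shape)
    values[mask] = z
    return VigilanceTemplate(values=values, mask=mask, n_scans=len(maps),
                             lineage=tuple(m.source_scan_id for m in maps))


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5))


def _top_by_magnitude(values: np.ndarray, candidates: np.ndarray,
                      fraction: float) -> np.ndarray:
    """Flat indices of the top ``fraction`` of ``candidates`` by |value|.

    Ties are broken by (|value| descending, flat voxel index ascending),
    via a stable sort — deterministic across platforms.
    """
    flat_idx = np.flatnonzero(candidates.ravel())
    if flat_idx.size == 0:
        return flat_idx
    k = max(1, _round_half_away(fraction * flat_idx.size))
    mags = np.abs(values.ravel()[flat_idx])
    order = np.argsort(-mags, kind="stable")
    return flat_idx[order[:k]]


def threshold_template(template: VigilanceTemplate | ThresholdedTemplate,
                       fraction: float, mode: str = "both"
                       ) -> ThresholdedTemplate:
    """Keep only the strongest ``fraction`` of voxels of the requested sign.

    ``mode='positive'`` keeps the top fraction of positive voxels by value,
    ``'negative'`` the top fraction of negative voxels by magnitude, and
    ``'both'`` keeps both sets (the fraction applies per sign). All other
    voxels are zeroed; template values are not re-normalized. If no voxel
    of a requested sign exists the result for that sign is empty, with a
    warning.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    if mode not in ("positive", "negative", "both"):
        raise ValueError("mode must be positive, negative or both")
    values = template.values
    support = template.support
    retained = np.zeros(values.shape, dtype=bool)
    flat_retained = retained.ravel()
    for sign in (1, -1):
        if (sign > 0 and mode == "negative") or (sign < 0 and mode == "positive"):
            continue
        candidates = support & (np.sign(values) == sign)
        if not candidates.any():
            warnings.warn(f"no {'positive' if sign > 0 else 'negative'} "
                          "voxels to threshold", stacklevel=2)
            continue
        flat_retained[_top_by_magnitude(values, candidates, fraction)] = True
    out = np.where(retained, values, 0.0)
    return ThresholdedTemplate(values=out, retained=retained,
                               retained_fraction=fraction, mode=mode)
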