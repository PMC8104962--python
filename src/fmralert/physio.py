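"""Low-frequency physiological nuisance regression.

Respiratory variation (RV) is the sliding-window standard deviation of the
respiration belt waveform; heart rate (HR) is 60 over the windowed mean
inter-beat interval of the pulse (PPG) waveform, both evaluated in a 6 s
window centered on each TR. Zero-meaned RV and HR are convolved with the
published respiration and cardiac response functions, augmented with
temporal and dispersion derivatives, band-pass filtered, and regressed out
of every voxel series.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.signal import butter, find_peaks, sosfiltfilt

from .datatypes import FMRIScan, PhysioRegressors
from .hrf import crf_kernel, rrf_kernel

__all__ = ["compute_rv", "compute_hr", "build_physio_basis", "regress_out"]

logger = logging.getLogger(__name__)

#: Peak-detector settings: minimum height percentile and refractory period.
PEAK_HEIGHT_PERCENTILE = 60.0
PEAK_MIN_DISTANCE_S = 0.25


def _window_bounds(i: int, tr: float, window: float, fs: float, n: int
                   ) -> tuple[int, int]:
    """Sample range of a ``window``-s window centered on TR midpoint i."""
    center = (i + 0.5) * tr
    lo = max(0, int(np.floor((center - window / 2) * fs)))
    hi = min(n, int(np.ceil((center + window / 2) * fs)) + 1)
    return lo, hi


def compute_rv(resp: np.ndarray, fs: float, tr: float, n_volumes: int,
               window: float = 6.0) -> np.ndarray:
    """Respiratory variation: windowed sd of the belt waveform per TR.

    The window is centered on each TR midpoint and clipped to the
    available data at the edges.
    """
    resp = np.asarray(resp, float)
    if window <= 0:
        raise ValueError("window must be positive")
    if resp.size < window * fs:
        raise ValueError("waveform shorter than one window")
    rv = np.empty(n_volumes)
    for i in range(n_volumes):
        lo, hi = _window_bounds(i, tr, window, fs, resp.size)
        rv[i] = resp[lo:hi].std()
    return rv


def compute_hr(ppg: np.ndarray, fs: float, tr: float, n_volumes: int,
               window: float = 6.0) -> np.ndarray:
    """Heart rate (beats/min): 60 / windowed mean inter-beat interval.

    Pulse peaks are local maxima above the 60th amplitude percentile with
    a 0.25 s refractory period. For each TR, beats whose inter-beat
    midpoints fall in the 6 s window centered on that TR contribute; TRs
    whose window holds fewer than 2 beats inherit the nearest valid value
    (logged).
    """
    ppg = np.asarray(ppg, float)
    min_dist = max(1, int(round(PEAK_MIN_DISTANCE_S * fs)))
    height = np.percentile(ppg, PEAK_HEIGHT_PERCENTILE)
    peaks, _ = find_peaks(ppg, height=height, distance=min_dist)
    if peaks.size < 2:
        raise ValueError("no detectable beats in the PPG waveform")
    beat_times = peaks / fs
    ibi = np.diff(beat_times)
    ibi_mid = (beat_times[:-1] + beat_times[1:]) / 2.0

    hr = np.full(n_volumes, np.nan)
    for i in range(n_volumes):
        center = (i + 0.5) * tr
        sel = np.abs(ibi_mid - center) <= window / 2
        if sel.sum() >= 1:
            hr[i] = 60.0 / ibi[sel].mean()
    invalid = ~np.isfinite(hr)
    if invalid.all():
        raise ValueError("no window contained enough beats")
    if invalid.any():
        logger.info("compute_hr: %d windows inherit nearest valid HR",
                    int(invalid.sum()))
        valid_idx = np.flatnonzero(~invalid)
        for i in np.flatnonzero(invalid):
            hr[i] = hr[valid_idx[np.argmin(np.abs(valid_idx - i))]]
    return hr


def _derivative_columns(x: np.ndarray, kernel_fn, tr: float,
                        n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Response, temporal-derivative and dispersion-derivative columns."""
    kernel = kernel_fn(tr)
    base = np.convolve(x, kernel)[:n]
    temporal = np.gradient(base, tr)
    # Dispersion derivative: numerical sensitivity to a 1% time-constant
    # perturbation, normalized by the perturbation.
    kernel_pert = kernel_fn(tr, tau_scale=1.01)
    disp = (np.convolve(x, kernel_pert)[:n] - base) / 0.01
    return base, temporal, disp


def build_physio_basis(rv: np.ndarray, hr: np.ndarray, tr: float,
                       band: tuple[float, float] | None = (0.01, 0.2)
                       ) -> PhysioRegressors:
    """Six-column physiological nuisance basis.

    Zero-meaned RV convolved with the respiration response function and
    zero-meaned HR convolved with the cardiac response function, each with
    a temporal derivative (finite difference) and a dispersion derivative
    (1% time-constant sensitivity); all columns band-pass filtered
    (``band=None`` disables) and re-centered.
    """
    rv = np.asarray(rv, float)
    hr = np.asarray(hr, float)
    if rv.size != hr.size:
        raise ValueError("rv and hr must have equal length")
    n = rv.size
    cols = []
    names = []
    for x, kfn, tag in ((rv - rv.mean(), rrf_kernel, "rv"),
                        (hr - hr.mean(), crf_kernel, "hr")):
        base, temporal, disp = _derivative_columns(x, kfn, tr, n)
        cols += [base, temporal, disp]
        names += [f"{tag}_rrf" if tag == "rv" else f"{tag}_crf",
                  f"{tag}_temporal_deriv", f"{tag}_dispersion_deriv"]
    basis = np.column_stack(cols)
    if band is not None:
        lo, hi = band
        nyq = 1.0 / (2.0 * tr)
        if not (0 < lo < hi < nyq):
            raise ValueError("band must satisfy 0 < low < high < Nyquist")
        sos = butter(4, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
        basis = sosfiltfilt(sos, basis, axis=0, padlen=min(n - 1, 24))
    basis = basis - basis.mean(axis=0, keepdims=True)
    return PhysioRegressors(rv=rv, hr=hr, basis=basis, names=names)


def regress_out(scan: FMRIScan, basis: PhysioRegressors | np.ndarray
                ) -> FMRIScan:
    """Project the physiological basis (plus intercept) out of every voxel.

    Returns the residual scan; residuals are orthogonal to every basis
    column, and the operation is idempotent (a projection).
    """
    B = basis.basis if isinstance(basis, PhysioRegressors) else np.asarray(basis)
    if B.shape[0] != scan.n_volumes:
        raise ValueError(f"basis rows {B.shape[0]} != scan volumes "
                         f"{scan.n_volumes}")
    X = np.column_stack([B, np.ones(B.shape[0])])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("physiological basis is rank deficient")
    Y = scan.masked_series().T
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = (Y - X @ beta).T
    data = np.zeros_like(scan.data)
    data[scan.mask] = resid
    return FMRIScan(data=data, tr=scan.tr, mask=scan.mask.copy(),
                    affine=scan.affine.copy(), scan_id=scan.scan_id)
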