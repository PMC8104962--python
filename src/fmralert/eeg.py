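"""EEG alertness index: per-TR alpha/theta rms ratio and its
hemodynamically filtered version.

The index is the rms amplitude in the alpha band (8-12 Hz) divided by the
rms amplitude in the theta band (3-7 Hz), computed over the average of
posterior channels within the EEG interval of each fMRI volume. Higher
values index higher alertness. For comparison with BOLD, the ratio is
mean-centered, convolved with the canonical double-gamma HRF and band-pass
filtered (nominal cutoffs 0.01-0.2 Hz) to match the bandwidth of fMRI.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .datatypes import AlertnessIndex, EEGRecording
from .hrf import HRFSpec, default_hrf

__all__ = [
    "ALPHA_BAND",
    "THETA_BAND",
    "compute_alpha_theta_ratio",
    "align_to_fmri",
    "hemodynamic_filter",
    "eeg_alertness_index",
]

ALPHA_BAND = (8.0, 12.0)
THETA_BAND = (3.0, 7.0)


def _band_rms(spectrum: np.ndarray, freqs: np.ndarray,
              band: tuple[float, float]) -> float:
    """rms amplitude of the band-limited signal (inclusive band edges).

    By Parseval, the rms of the signal restricted to a band is
    proportional to the root summed squared magnitude over the band's
    bins; the window-length constant cancels in the alpha/theta ratio.
    """
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.sqrt(np.sum(np.abs(spectrum[sel]) ** 2)))


def compute_alpha_theta_ratio(eeg: EEGRecording, tr: float, n_volumes: int,
                              channels: list[str] | None = None,
                              log: bool = False) -> AlertnessIndex:
    """Per-TR alpha/theta rms ratio over the selected channels.

    For each volume's EEG window the selected channels are averaged, the
    window is Hann-tapered, and rms amplitudes in 8-12 Hz and 3-7 Hz are
    taken from the magnitude of the discrete spectrum (inclusive band
    edges). The plain ratio is returned by default; ``log=True`` returns
    its natural log.

    Parameters
    ----------
    eeg : EEGRecording
    tr : float
        fMRI repetition time, seconds; defines the window length.
    n_volumes : int
        Number of windows (volumes) to compute.
    channels : list of str, optional
        Channel subset; defaults to all channels in the recording.
    """
    if channels is None:
        channels = list(eeg.channel_names)
    missing = [c for c in channels if c not in eeg.channel_names]
    if missing:
        raise KeyError(f"channels not in recording: {missing}")
    if eeg.duration + 1e-9 < n_volumes * tr:
        raise ValueError(
            f"EEG covers {eeg.duration:.1f} s but {n_volumes} volumes "
            f"x {tr} s = {n_volumes * tr:.1f} s are required")
    window_len = int(round(tr * eeg.fs))
    if window_len < 2 * eeg.fs / 3.0:
        warnings.warn("TR window shorter than 2 cycles of 3 Hz; "
                      "theta estimates will be coarse", stacklevel=2)
    rows = [eeg.channel_names.index(c) for c in channels]
    mean_trace = eeg.samples[rows].mean(axis=0)
    taper = np.hanning(window_len)
    freqs = np.fft.rfftfreq(window_len, d=1.0 / eeg.fs)

    starts = np.round(np.arange(n_volumes) * tr * eeg.fs).astype(int)
    segs = mean_trace[starts[:, None] + np.arange(window_len)]
    spectra = np.fft.rfft(segs * taper, axis=1)
    alpha_sel = (freqs >= ALPHA_BAND[0]) & (freqs <= ALPHA_BAND[1])
    theta_sel = (freqs >= THETA_BAND[0]) & (freqs <= THETA_BAND[1])
    alpha = np.sqrt(np.sum(np.abs(spectra[:, alpha_sel]) ** 2, axis=1))
    theta = np.sqrt(np.sum(np.abs(spectra[:, theta_sel]) ** 2, axis=1))
    with np.errstate(divide="ignore"):
        values = np.where(theta > 0, alpha / theta, np.inf)
    if log:
        values = np.log(values)
    return AlertnessIndex(values=values, tr=tr, kind="raw_eeg",
                          lineage=("alpha_theta_ratio",))


def align_to_fmri(index: AlertnessIndex, n_drop: int = 7) -> AlertnessIndex:
    """Drop the first ``n_drop`` entries (pre-steady-state volumes)."""
    if n_drop < 0:
        raise ValueError("n_drop must be non-negative")
    if len(index) <= n_drop:
        raise ValueError(
            f"index of length {len(index)} cannot drop {n_drop} entries")
    return index.with_values(index.values[n_drop:], step=f"drop_first_{n_drop}")


def hemodynamic_filter(index: AlertnessIndex, hrf: HRFSpec | None = None,
                       band: tuple[float, float] | None = (0.01, 0.2)
                       ) -> AlertnessIndex:
    """Mean-center, convolve with the HRF, and band-pass the EEG index.

    The index is mean-centered, convolved with the causal HRF kernel
    sampled at the TR (full convolution truncated to the input length),
    then band-pass filtered with a zero-phase 4th-order Butterworth
    (``band=None`` disables the band-pass). The output is re-centered so
    its mean is zero to numerical tolerance.
    """
    if hrf is None:
        hrf = default_hrf()
    x = index.values - index.values.mean()
    kernel = hrf.kernel(index.tr)
    y = np.convolve(x, kernel)[:x.size]
    if band is not None:
        lo, hi = band
        nyq = 1.0 / (2.0 * index.tr)
        if not (0 < lo < hi):
            raise ValueError("band must satisfy 0 < low < high")
        if hi >= nyq:
            raise ValueError(f"band high {hi} Hz is at/above Nyquist {nyq:.4g} Hz")
        sos = butter(4, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
        y = sosfiltfilt(sos, y, padlen=min(y.size - 1, 24))
    y = y - y.mean()
    return AlertnessIndex(values=y, tr=index.tr, kind="hemodynamic_eeg",
                          lineage=index.lineage + ("hemodynamic_filter",))


def eeg_alertness_index(eeg: EEGRecording, tr: float, n_volumes: int,
                        channels: list[str] | None = None, n_drop: int = 0,
                        hrf: HRFSpec | None = None,
                        band: tuple[float, float] | None = (0.01, 0.2)
                        ) -> AlertnessIndex:
    """Convenience pipeline: ratio -> alignment -> hemodynamic filter."""
    raw = compute_alpha_theta_ratio(eeg, tr, n_volumes, channels)
    if n_drop:
        raw = align_to_fmri(raw, n_drop)
    return hemodynamic_filter(raw, hrf=hrf, band=band)
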