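"""Coupled synthetic EEG-fMRI-behavior-physiology generator.

Emulates a simultaneous EEG-fMRI session with a sustained-attention
auditory task: a slow latent arousal process simultaneously (i) scales EEG
alpha power up and theta power down, (ii) drives a spatially patterned,
hemodynamically lagged BOLD signal, (iii) lowers miss probability and
shortens reaction times before each stimulus, and (iv) modulates
respiratory depth and heart rate. Every downstream stage of the pipeline
is therefore testable against a known ground truth.

Defaults mirror the acquisition the pipeline targets: 700 volumes at
TR 2.1 s (24.5 min), EEG at 250 Hz over six posterior channels, trials at
long randomized inter-stimulus intervals (about 33 per scan, roughly a
quarter of them misses).

All randomness flows from a single master seed through
``numpy.random.SeedSequence`` spawning; identical seed and parameters
regenerate every member of a world bit-for-bit.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, lfilter, sosfiltfilt

from .datatypes import (
    EEGRecording,
    FMRIScan,
    LatentArousal,
    PhysioSignals,
    SyntheticWorld,
    TrialTable,
)
from .hrf import HRFSpec, default_hrf

__all__ = [
    "POSTERIOR_CHANNELS",
    "generate_latent_arousal",
    "synthesize_eeg",
    "synthesize_fmri",
    "synthesize_behavior",
    "synthesize_physio",
    "make_true_template",
    "make_task_weights",
    "make_world",
    "simulate_cohort",
    "Cohort",
]

#: Posterior channel montage used for the alpha/theta alertness index.
POSTERIOR_CHANNELS = ["P3", "P4", "Pz", "O1", "O2", "Oz"]

#: Geometry constant for the deterministic magnitude variation of the true
#: template. Not a simulation seed: the template is a fixed property of the
#: synthetic anatomy, shared by every scan of a cohort.
_TEMPLATE_GEOMETRY_SEED = 12345

_RT_FLOOR_MS = 150.0
_MISS_RT_MS = 5000.0


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from a master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s & 0x7FFFFFFF) for s in state]


def generate_latent_arousal(n_volumes: int, tr: float, cutoff_hz: float = 0.02,
                            amplitude: float = 1.0, seed: int = 0) -> LatentArousal:
    """Slow latent arousal: low-pass-filtered Gaussian noise, standardized.

    White Gaussian noise on the volume grid is zero-phase low-pass filtered
    (4th-order Butterworth, forward-backward) at ``cutoff_hz``, standardized
    to zero mean and unit variance, then scaled by ``amplitude``.
    """
    if n_volumes < 8:
        raise ValueError("n_volumes must be at least 8")
    if tr <= 0:
        raise ValueError("tr must be positive")
    nyquist = 1.0 / (2.0 * tr)
    if not (0.0 < cutoff_hz < nyquist):
        raise ValueError(
            f"cutoff_hz must lie in (0, {nyquist:.4g}) for tr={tr}")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n_volumes)
    sos = butter(4, cutoff_hz / nyquist, output="sos")
    padlen = min(n_volumes - 1, 24)
    x = sosfiltfilt(sos, white, padlen=padlen)
    sd = x.std()
    if sd > 0:
        x = (x - x.mean()) / sd
    return LatentArousal(values=amplitude * x, tr=tr, seed=seed)


def _upsample_hold(latent: LatentArousal, n_samples: int, fs: float) -> np.ndarray:
    """Zero-order hold of the latent onto a fine sample grid.

    Each TR window carries a constant latent value, so per-TR band
    amplitudes are exactly stationary within a window.
    """
    t = np.arange(n_samples) / fs
    idx = np.minimum((t / latent.tr).astype(int), len(latent) - 1)
    return latent.values[idx]


def synthesize_eeg(latent: LatentArousal, fs: float = 250.0,
                   channels: list[str] | None = None,
                   alpha_gain: float = 0.5, theta_gain: float = 0.5,
                   noise_sd: float = 0.5, seed: int = 0) -> EEGRecording:
    """EEG whose alpha (10 Hz) envelope rises and theta (5 Hz) envelope
    falls with the latent arousal state.

    Each channel is ``exp(alpha_gain * z(t)) * sin(2*pi*10*t + phi_a)``
    plus ``exp(-theta_gain * z(t)) * sin(2*pi*5*t + phi_t)`` plus white
    noise, where ``z`` is the latent held constant within each TR. The
    exponential envelopes are strictly positive, and the per-TR log
    alpha/theta ratio is linear in the latent with slope
    ``alpha_gain + theta_gain``.
    """
    if channels is None:
        channels = list(POSTERIOR_CHANNELS)
    if fs < 50:
        raise ValueError("fs must be at least 50 Hz to resolve 3-12 Hz bands")
    if alpha_gain < 0 or theta_gain < 0:
        raise ValueError("gains must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n_samples = int(round(len(latent) * latent.tr * fs))
    t = np.arange(n_samples) / fs
    z = _upsample_hold(latent, n_samples, fs)
    env_alpha = np.exp(alpha_gain * z)
    env_theta = np.exp(-theta_gain * z)
    samples = np.empty((len(channels), n_samples))
    for c in range(len(channels)):
        phi_a, phi_t = rng.uniform(0, 2 * np.pi, size=2)
        samples[c] = (env_alpha * np.sin(2 * np.pi * 10.0 * t + phi_a)
                      + env_theta * np.sin(2 * np.pi * 5.0 * t + phi_t))
    if noise_sd > 0:
        samples += noise_sd * rng.standard_normal(samples.shape)
    return EEGRecording(samples=samples, fs=fs, channel_names=list(channels))


def synthesize_fmri(latent: LatentArousal, true_template: np.ndarray,
                    hrf: HRFSpec | None = None, noise_sd: float = 1.0,
                    ar_coeff: float = 0.3, drift_order: int = 0,
                    seed: int = 0, mask: np.ndarray | None = None,
                    scan_id: str = "",
                    task_onsets: np.ndarray | None = None,
                    task_weights: np.ndarray | None = None,
                    task_amp: float = 0.0) -> FMRIScan:
    """Arousal-coupled BOLD: voxel series = weight * (HRF (*) latent) + noise.

    The HRF-convolved latent is rescaled to unit variance so that template
    weights are in SNR units relative to ``noise_sd`` (stationary AR(1)
    noise of standard deviation ``noise_sd``). Optional polynomial drift
    (Legendre basis, per-voxel random coefficients of scale ``noise_sd``)
    and an optional event-locked task activation (``task_amp`` times
    HRF-convolved stick functions at ``task_onsets`` on ``task_weights``
    voxels) can be added.
    """
    if hrf is None:
        hrf = default_hrf()
    true_template = np.asarray(true_template, dtype=float)
    if true_template.ndim != 3:
        raise ValueError("true_template must be a 3D weight volume")
    if mask is None:
        mask = true_template != 0
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != true_template.shape:
        raise ValueError(
            f"grid mismatch: template {true_template.shape} vs mask {mask.shape}")
    if not (-1.0 < ar_coeff < 1.0):
        raise ValueError("|ar_coeff| must be < 1")
    n = len(latent)
    tr = latent.tr
    rng = np.random.default_rng(seed)

    kernel = hrf.kernel(tr)
    hemo = np.convolve(latent.values, kernel)[:n]
    sd = hemo.std()
    if sd > 0:
        hemo = hemo / sd

    data = np.zeros(true_template.shape + (n,))
    weights = np.where(mask, true_template, 0.0)
    nz = weights != 0
    data[nz] = weights[nz, None] * hemo

    if task_amp != 0.0 and task_onsets is not None and task_weights is not None:
        task_weights = np.asarray(task_weights, dtype=float)
        if task_weights.shape != true_template.shape:
            raise ValueError("task_weights grid mismatch")
        stick = np.zeros(n)
        for onset in np.asarray(task_onsets, dtype=float):
            if 0.0 <= onset < n * tr:
                i = min(int(round(onset / tr)), n - 1)
                stick[i] += 1.0
        evoked = np.convolve(stick, kernel)[:n]
        tz = task_weights != 0
        data[tz] += task_amp * task_weights[tz, None] * evoked

    n_masked = int(mask.sum())
    if drift_order > 0:
        # Legendre drift basis on [-1, 1]; constant term excluded.
        x = np.linspace(-1.0, 1.0, n)
        basis = np.polynomial.legendre.legvander(x, drift_order)[:, 1:]
        coeffs = rng.standard_normal((n_masked, drift_order)) * noise_sd
        data[mask] += coeffs @ basis.T
    if noise_sd > 0:
        innov = rng.standard_normal((n_masked, n))
        innov *= noise_sd * np.sqrt(1.0 - ar_coeff ** 2)
        data[mask] += lfilter([1.0], [1.0, -ar_coeff], innov, axis=-1)
    return FMRIScan(data=data, tr=tr, mask=mask, scan_id=scan_id)


def synthesize_behavior(latent: LatentArousal,
                        isi_range: tuple[float, float] = (30.0, 60.0),
                        miss_intercept: float = -1.2, miss_slope: float = 1.5,
                        rt_base: float = 565.0, rt_slope: float = 100.0,
                        rt_sd: float = 150.0, seed: int = 0,
                        pre_window: float = 5.0,
                        scan_id: str = "") -> TrialTable:
    """Auditory detection trials coupled to the pre-stimulus latent state.

    Onsets are drawn with inter-stimulus intervals uniform in ``isi_range``.
    Per trial, with ``z`` the mean latent over the ``pre_window`` seconds
    before onset: miss probability is ``logistic(miss_intercept -
    miss_slope * z)`` and, for responses, reaction time is ``rt_base -
    rt_slope * z`` plus Gaussian noise, floored at 150 ms. Simulated
    responses slower than 5 s are recorded as non-responses (misses).
    """
    lo, hi = float(isi_range[0]), float(isi_range[1])
    if lo > hi:
        raise ValueError("isi_range min must not exceed max")
    if rt_sd < 0:
        raise ValueError("rt_sd must be non-negative")
    duration = len(latent) * latent.tr
    if lo > duration:
        raise ValueError("isi_range must fit within the scan duration")
    rng = np.random.default_rng(seed)
    onsets = []
    t = float(rng.uniform(lo, hi))
    while t < duration - 1.0:
        onsets.append(t)
        t += float(rng.uniform(lo, hi))
    onsets = np.asarray(onsets)

    grid = np.arange(len(latent)) * latent.tr
    pre = np.array([_pre_stimulus_mean(latent.values, grid, o, pre_window)
                    for o in onsets])
    from scipy.special import expit
    p_miss = expit(miss_intercept - miss_slope * pre)
    missed = rng.uniform(size=onsets.size) < p_miss
    rt = rt_base - rt_slope * pre + rt_sd * rng.standard_normal(onsets.size)
    rt = np.maximum(rt, _RT_FLOOR_MS)
    too_slow = rt > _MISS_RT_MS
    responded = ~missed & ~too_slow
    rt = np.where(responded, rt, np.nan)
    return TrialTable(onsets=onsets, responded=responded, rt=rt, scan_id=scan_id)


def _pre_stimulus_mean(values: np.ndarray, grid: np.ndarray, onset: float,
                       window: float) -> float:
    sel = (grid >= onset - window) & (grid <= onset)
    if not sel.any():
        sel = np.argmin(np.abs(grid - onset))
    return float(values[sel].mean())


def synthesize_physio(latent: LatentArousal, fs: float = 50.0,
                      resp_freq: float = 0.25, base_hr: float = 65.0,
                      hr_slope: float = 5.0, seed: int = 0,
                      resp_amp_slope: float = 0.3,
                      resp_noise_sd: float = 0.05,
                      ppg_noise_sd: float = 0.02) -> PhysioSignals:
    """Respiration belt and PPG waveforms modulated by the latent state.

    The belt signal is a sinusoid at ``resp_freq`` whose amplitude is
    ``1 + resp_amp_slope * z(t)`` (clipped at 0.1). The PPG is a sharp
    periodic pulse train whose instantaneous rate is ``base_hr +
    hr_slope * z(t)`` beats/min (phase integration, von-Mises-shaped
    pulses), so inter-beat intervals track ``60 / rate``.
    """
    if fs < 20:
        raise ValueError("fs must be at least 20 Hz")
    if base_hr <= 0:
        raise ValueError("base_hr must be positive")
    rng = np.random.default_rng(seed)
    n_samples = int(round(len(latent) * latent.tr * fs))
    t = np.arange(n_samples) / fs
    z = _upsample_hold(latent, n_samples, fs)

    amp = np.maximum(1.0 + resp_amp_slope * z, 0.1)
    resp = amp * np.sin(2 * np.pi * resp_freq * t)
    if resp_noise_sd > 0:
        resp = resp + resp_noise_sd * rng.standard_normal(n_samples)

    rate_hz = (base_hr + hr_slope * z) / 60.0
    if np.any(rate_hz <= 0):
        raise ValueError("instantaneous heart rate must stay positive")
    phase = np.cumsum(rate_hz) / fs
    ppg = np.exp(8.0 * (np.cos(2 * np.pi * phase) - 1.0))
    if ppg_noise_sd > 0:
        ppg = ppg + ppg_noise_sd * rng.standard_normal(n_samples)
    return PhysioSignals(resp=resp, fs_resp=fs, ppg=ppg, fs_ppg=fs)


def make_true_template(shape: tuple[int, int, int] = (16, 16, 12)
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth arousal weight volume and brain mask.

    A small ellipsoidal "brain": an outer cortex-like shell of negative
    weights (BOLD falls with rising arousal over most of gray matter), a
    small central ventricle-like core of positive weights, and a neutral
    zero-weight zone in between that carries only noise. Negative voxels
    heavily outnumber positive ones. Weight magnitudes vary smoothly and
    deterministically (fixed geometry constant) so magnitude thresholding
    is meaningful. Returns ``(weights, mask)``.
    """
    nx, ny, nz = shape
    ix, iy, iz = np.indices(shape)
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    r = np.sqrt(((ix - cx) / (0.47 * nx)) ** 2
                + ((iy - cy) / (0.47 * ny)) ** 2
                + ((iz - cz) / (0.47 * nz)) ** 2)
    mask = r <= 1.0
    rng = np.random.default_rng(_TEMPLATE_GEOMETRY_SEED)
    magnitude = 0.5 + rng.uniform(size=shape)
    weights = np.zeros(shape)
    # Core large enough that even a 1% retention keeps a projectable
    # (>= 3 voxel) positive set at this grid size.
    core = r <= 0.58
    shell = (r >= 0.70) & mask
    weights[core] = magnitude[core]
    weights[shell] = -magnitude[shell]
    return weights, mask


def make_task_weights(shape: tuple[int, int, int] = (16, 16, 12)) -> np.ndarray:
    """Task-activation weight volume: bilateral cortical blocks.

    Voxels are chosen from the negative (cortex-like) shell of
    :func:`make_true_template` near the lateral extremes (auditory-cortex
    placement), so genuine task activation rides on top of the arousal
    signal there — the arousal confound overlaps true task voxels, while
    the rest of the shell stays confound-only.
    """
    weights, mask = make_true_template(shape)
    ny = shape[1]
    iy = np.indices(shape)[1]
    lateral = (weights < 0) & ((iy <= ny * 0.2) | (iy >= ny * 0.8))
    out = np.zeros(shape)
    out[lateral] = 1.0
    return out


def make_world(n_volumes: int = 700, tr: float = 2.1,
               shape: tuple[int, int, int] = (16, 16, 12),
               cutoff_hz: float = 0.02, amplitude: float = 1.0,
               snr: float = 1.0, ar_coeff: float = 0.3, drift_order: int = 0,
               eeg_fs: float = 250.0, alpha_gain: float = 0.5,
               theta_gain: float = 0.5, eeg_noise_sd: float = 0.5,
               with_trials: bool = True, with_physio: bool = False,
               with_eeg: bool = True,
               evoked_gain: float = 0.0, evoked_ceiling: float = 1.0,
               task_amp: float = 0.0,
               hr_slope: float = 5.0, resp_amp_slope: float = 0.3,
               seed: int = 0, scan_id: str = "") -> SyntheticWorld:
    """Assemble one coupled scan session from a single master seed.

    ``snr`` rescales the template weights relative to unit-variance voxel
    noise. With ``evoked_gain > 0`` each stimulus adds a gamma-shaped
    arousal bump whose amplitude is ``evoked_gain * max(0, evoked_ceiling -
    pre-stimulus latent)`` — drowsier trials rebound more, as after an
    alerting stimulus — and the bumped latent drives EEG, fMRI and physio.
    ``task_amp`` adds genuine event-locked activation on the task voxels
    of :func:`make_task_weights`.
    """
    seeds = _child_seeds(seed, 5)
    latent = generate_latent_arousal(n_volumes, tr, cutoff_hz, amplitude,
                                     seed=seeds[0])
    weights, mask = make_true_template(shape)
    hrf = default_hrf()

    trials = None
    if with_trials:
        trials = synthesize_behavior(latent, seed=seeds[3], scan_id=scan_id)

    driver = latent
    if evoked_gain > 0 and trials is not None and len(trials) > 0:
        driver = _add_evoked_bumps(latent, trials, evoked_gain, evoked_ceiling)

    eeg = None
    if with_eeg:
        eeg = synthesize_eeg(driver, fs=eeg_fs, alpha_gain=alpha_gain,
                             theta_gain=theta_gain, noise_sd=eeg_noise_sd,
                             seed=seeds[1])
    scan = synthesize_fmri(
        driver, snr * weights, hrf=hrf, noise_sd=1.0, ar_coeff=ar_coeff,
        drift_order=drift_order, seed=seeds[2], mask=mask, scan_id=scan_id,
        task_onsets=trials.onsets if (trials is not None and task_amp != 0) else None,
        task_weights=make_task_weights(shape) if task_amp != 0 else None,
        task_amp=task_amp)
    physio = None
    if with_physio:
        physio = synthesize_physio(driver, hr_slope=hr_slope,
                                   resp_amp_slope=resp_amp_slope,
                                   seed=seeds[4])
    params = dict(n_volumes=n_volumes, tr=tr, shape=shape, cutoff_hz=cutoff_hz,
                  amplitude=amplitude, snr=snr, ar_coeff=ar_coeff,
                  drift_order=drift_order, eeg_fs=eeg_fs,
                  alpha_gain=alpha_gain, theta_gain=theta_gain,
                  eeg_noise_sd=eeg_noise_sd, with_trials=with_trials,
                  with_eeg=with_eeg,
                  with_physio=with_physio, evoked_gain=evoked_gain,
                  evoked_ceiling=evoked_ceiling, task_amp=task_amp,
                  hr_slope=hr_slope, resp_amp_slope=resp_amp_slope,
                  seed=seed, scan_id=scan_id)
    return SyntheticWorld(latent=driver, true_template=weights, mask=mask,
                          eeg=eeg, scan=scan, trials=trials, physio=physio,
                          params=params)


def _add_evoked_bumps(latent: LatentArousal, trials: TrialTable,
                      gain: float, ceiling: float) -> LatentArousal:
    """Add a stimulus-locked arousal rebound, larger for drowsier trials."""
    tr = latent.tr
    n = len(latent)
    t_k = np.arange(0.0, 10.0 + tr / 2, tr)
    kernel = t_k * np.exp(-t_k / 2.0)
    kernel /= kernel.max()
    grid = np.arange(n) * tr
    values = latent.values.copy()
    for onset in trials.onsets:
        pre = _pre_stimulus_mean(latent.values, grid, onset, 5.0)
        amp = gain * max(0.0, ceiling - pre)
        i0 = int(np.ceil(onset / tr))
        k = values[i0:i0 + kernel.size].size
        if k > 0:
            values[i0:i0 + k] += amp * kernel[:k]
    return LatentArousal(values=values, tr=tr, seed=latent.seed)


class Cohort:
    """A simulated multi-subject cohort: one rest and one task scan each.

    The true template geometry is shared across subjects (it is anatomy);
    latent processes, noise, trials and physiology are per scan.
    """

    def __init__(self, rest: list[SyntheticWorld], task: list[SyntheticWorld]):
        self.rest = rest
        self.task = task
        self.true_template = rest[0].true_template if rest else task[0].true_template
        self.mask = rest[0].mask if rest else task[0].mask

    @property
    def n_subjects(self) -> int:
        return len(self.task)


def simulate_cohort(n_subjects: int = 12, seed: int = 0,
                    task_eeg: bool = True, **world_kwargs) -> Cohort:
    """Simulate ``n_subjects`` subjects, each with a rest and a task scan.

    Rest scans carry no trials (they train the template); task scans carry
    the auditory detection task. ``task_eeg=False`` skips synthesizing the
    task scans' EEG for analyses that never read it. Keyword arguments are
    forwarded to :func:`make_world`.
    """
    seeds = _child_seeds(seed, 2 * n_subjects)
    rest, task = [], []
    for i in range(n_subjects):
        kw = dict(world_kwargs)
        kw_task = dict(world_kwargs)
        kw.update(with_trials=False)
        rest.append(make_world(seed=seeds[2 * i], scan_id=f"sub{i:02d}_rest", **kw))
        kw_task.setdefault("with_trials", True)
        kw_task.setdefault("with_eeg", task_eeg)
        task.append(make_world(seed=seeds[2 * i + 1],
                               scan_id=f"sub{i:02d}_task", **kw_task))
    return Cohort(rest, task)
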