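"""Hemodynamic and physiological impulse-response kernels.

The canonical double-gamma HRF follows the conventional parameterisation
(response peak 6 s, undershoot peak 16 s, unit dispersions, peak:undershoot
amplitude ratio 6, 32 s support). The respiration response function (RRF)
and cardiac response function (CRF) are the published closed forms used for
low-frequency physiological nuisance modelling:

    RRF(t) = 0.6 t^2.1 exp(-t/1.6) - 0.0023 t^3.54 exp(-t/4.25)
    CRF(t) = 0.6 t^2.7 exp(-t/1.6) - 16/sqrt(18*pi) exp(-(t-12)^2/18)

with t in seconds. Coefficients are pinned here as module constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as _gamma

__all__ = ["HRFSpec", "default_hrf", "rrf_kernel", "crf_kernel"]

# Respiration response function coefficients (Birn et al., 2008,
# "The respiration response function"). Time constants in seconds.
RRF_COEFFS = {"a1": 0.6, "p1": 2.1, "tau1": 1.6,
              "a2": 0.0023, "p2": 3.54, "tau2": 4.25}

# Cardiac response function coefficients (Chang, Cunningham & Glover, 2009,
# "Influence of heart rate on the BOLD signal").
CRF_COEFFS = {"a1": 0.6, "p1": 2.7, "tau1": 1.6,
              "gauss_center": 12.0, "gauss_var": 9.0}


@dataclass(frozen=True)
class HRFSpec:
    """Canonical double-gamma hemodynamic response function.

    Parameters
    ----------
    peak_delay, undershoot_delay : float
        Delays of response and undershoot, seconds.
    peak_dispersion, undershoot_dispersion : float
        Gamma dispersions (scale parameters), seconds.
    ratio : float
        Peak-to-undershoot amplitude ratio.
    length : float
        Kernel support, seconds.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 6.0
    length: float = 32.0

    def __post_init__(self) -> None:
        if min(self.peak_delay, self.undershoot_delay, self.peak_dispersion,
               self.undershoot_dispersion, self.ratio, self.length) <= 0:
            raise ValueError("all HRF parameters must be positive")

    def kernel(self, dt: float) -> np.ndarray:
        """Evaluate the kernel on a grid of spacing ``dt`` seconds.

        The kernel is the difference of two gamma densities; it is finite
        and integrates (sums x dt) to a positive value.
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        t = np.arange(0.0, self.length + dt / 2, dt)
        peak = _gamma.pdf(t, self.peak_delay / self.peak_dispersion,
                          scale=self.peak_dispersion)
        under = _gamma.pdf(t, self.undershoot_delay / self.undershoot_dispersion,
                           scale=self.undershoot_dispersion)
        h = peak - under / self.ratio
        if not np.all(np.isfinite(h)):
            raise ValueError("HRF kernel is not finite")
        if h.sum() * dt <= 0:
            raise ValueError("HRF kernel must integrate to a positive value")
        return h


def default_hrf() -> HRFSpec:
    """The canonical double-gamma HRF with conventional parameters."""
    return HRFSpec()


def rrf_kernel(dt: float, length: float = 60.0, tau_scale: float = 1.0) -> np.ndarray:
    """Respiration response function sampled every ``dt`` s over ``length`` s.

    ``tau_scale`` multiplies both time constants; used to form the
    dispersion-derivative column by numerical sensitivity.
    """
    c = RRF_COEFFS
    t = np.arange(0.0, length + dt / 2, dt)
    return (c["a1"] * t ** c["p1"] * np.exp(-t / (c["tau1"] * tau_scale))
            - c["a2"] * t ** c["p2"] * np.exp(-t / (c["tau2"] * tau_scale)))


def crf_kernel(dt: float, length: float = 60.0, tau_scale: float = 1.0) -> np.ndarray:
    """Cardiac response function sampled every ``dt`` s over ``length`` s."""
    c = CRF_COEFFS
    t = np.arange(0.0, length + dt / 2, dt)
    gauss_amp = 16.0 / np.sqrt(2.0 * np.pi * c["gauss_var"])
    return (c["a1"] * t ** c["p1"] * np.exp(-t / (c["tau1"] * tau_scale))
            - gauss_amp * np.exp(-(t - c["gauss_center"] * tau_scale) ** 2
                                 / (2.0 * c["gauss_var"])))
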