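"""Core containers shared across the pipeline.

Everything is a plain dataclass over numpy arrays: a 4D BOLD scan with its
mask and affine, an alertness index sampled on the volume grid, a voxelwise
vigilance template, trial tables, and the small result records produced by
the statistical operations. Containers validate their invariants on
construction so downstream code can assume them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LatentArousal",
    "EEGRecording",
    "AlertnessIndex",
    "FMRIScan",
    "CorrelationMap",
    "VigilanceTemplate",
    "ThresholdedTemplate",
    "TrialTable",
    "TrialSegments",
    "PhysioSignals",
    "PhysioRegressors",
    "CrossCorrFunction",
    "PermutationNull",
    "SplitPlan",
    "StatResult",
    "DesignMatrix",
    "GLMResult",
    "ROITimeseries",
    "SyntheticWorld",
]


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass
class LatentArousal:
    """Ground-truth slow arousal process on the fMRI volume grid.

    Unitless, standardized (zero mean, unit variance) before amplitude
    scaling; one value per volume. Only the synthetic generator produces
    this — in real data the latent state is what the pipeline estimates.
    """

    values: np.ndarray
    tr: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = _as_float_array(self.values, "latent values")
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("latent values must be a non-empty 1D series")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class EEGRecording:
    """Multichannel EEG: channels x samples, with sampling rate in Hz."""

    samples: np.ndarray
    fs: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if np.isnan(self.samples).any():
            raise ValueError("EEG contains NaN samples; reject at load")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError("channel_names length must match channel count")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs


VALID_INDEX_KINDS = ("raw_eeg", "hemodynamic_eeg", "fmri", "fmri_lasso")


@dataclass
class AlertnessIndex:
    """One alertness value per fMRI volume (or per fine-grid point).

    ``kind`` records provenance: ``raw_eeg`` is the per-TR alpha/theta rms
    ratio, ``hemodynamic_eeg`` the mean-centered HRF-convolved band-passed
    version of it, ``fmri`` the template-projection estimate (a spatial
    correlation, hence bounded by [-1, 1]), and ``fmri_lasso`` the
    unbounded lasso-regression estimate.
    """

    values: np.ndarray
    tr: float
    kind: str
    lineage: tuple = ()

    def __post_init__(self) -> None:
        self.values = _as_float_array(self.values, "alertness values")
        if self.values.ndim != 1:
            raise ValueError("alertness index must be 1D")
        if self.kind not in VALID_INDEX_KINDS:
            raise ValueError(f"kind must be one of {VALID_INDEX_KINDS}")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.kind == "fmri" and self.values.size:
            if np.max(np.abs(self.values)) > 1 + 1e-9:
                raise ValueError("fmri alertness values must lie in [-1, 1]")
        if self.kind == "hemodynamic_eeg" and self.values.size:
            sd = self.values.std()
            if sd > 0 and abs(self.values.mean()) > 1e-8 * sd:
                raise ValueError("hemodynamic_eeg index must be zero-mean")

    def __len__(self) -> int:
        return self.values.size

    def with_values(self, values: np.ndarray, *, kind: str | None = None,
                    tr: float | None = None, step: str = "") -> "AlertnessIndex":
        lineage = self.lineage + ((step,) if step else ())
        return AlertnessIndex(values, tr if tr is not None else self.tr,
                              kind if kind is not None else self.kind, lineage)


@dataclass
class FMRIScan:
    """4D BOLD series (x, y, z, t) with mask, affine and repetition time."""

    data: np.ndarray
    tr: float
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("scan data must be 4D (x, y, z, t)")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match the spatial grid")
        if self.data.shape[3] < 8:
            raise ValueError("a scan needs at least 8 volumes")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not np.all(np.isfinite(self.data[self.mask])):
            raise ValueError("masked voxel series must be finite")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def masked_series(self) -> np.ndarray:
        """Masked voxel series as (n_voxels, n_volumes)."""
        return self.data[self.mask]


@dataclass
class CorrelationMap:
    """Voxelwise Pearson r between BOLD and an alertness index."""

    values: np.ndarray
    mask: np.ndarray
    source_scan_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        inside = self.values[self.mask]
        if inside.size and np.max(np.abs(inside)) > 1 + 1e-9:
            raise ValueError("|r| must be <= 1 inside the mask")
        if np.any(self.values[~self.mask] != 0):
            raise ValueError("values must be zero outside the mask")


@dataclass
class VigilanceTemplate:
    """Group vigilance template: Fisher-Z averaged correlation map."""

    values: np.ndarray
    mask: np.ndarray
    n_scans: int = 1
    lineage: tuple = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("template must be finite inside the mask")

    @property
    def support(self) -> np.ndarray:
        """Boolean grid of voxels used for projection."""
        return self.mask


@dataclass
class ThresholdedTemplate:
    """Sparsified template: zeros everywhere except the retained voxel set."""

    values: np.ndarray
    retained: np.ndarray
    retained_fraction: float
    mode: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.retained = np.asarray(self.retained, dtype=bool)
        if self.values.shape != self.retained.shape:
            raise ValueError("values and retained shapes differ")
        if self.mode not in ("positive", "negative", "both"):
            raise ValueError("mode must be positive, negative or both")
        if np.any(self.values[~self.retained] != 0):
            raise ValueError("values must be zero outside the retained set")

    @property
    def support(self) -> np.ndarray:
        return self.retained

    @property
    def mask(self) -> np.ndarray:
        return self.retained


@dataclass
class TrialTable:
    """Per-trial stimulus onsets, responses and reaction times.

    ``rt`` is in milliseconds and NaN where no button press occurred.
    ``labels`` is filled by :func:`fmralert.behavior.classify_trials`.
    """

    onsets: np.ndarray
    responded: np.ndarray
    rt: np.ndarray
    scan_id: str = ""
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.responded = np.asarray(self.responded, dtype=bool)
        self.rt = np.asarray(self.rt, dtype=float)
        n = self.onsets.size
        if self.responded.size != n or self.rt.size != n:
            raise ValueError("onsets, responded and rt must have equal length")
        if n > 1 and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        with np.errstate(invalid="ignore"):
            if np.any(self.rt[np.isfinite(self.rt)] <= 0):
                raise ValueError("reaction times must be positive where present")

    def __len__(self) -> int:
        return self.onsets.size

    def to_frame(self) -> pd.DataFrame:
        """BIDS-style events frame (onset s, response_time s)."""
        return pd.DataFrame({
            "onset": self.onsets,
            "duration": np.zeros(len(self)),
            "trial_type": self.labels if self.labels is not None
            else np.where(self.responded, "hit", "miss"),
            "response_time": self.rt / 1000.0,
        })


@dataclass
class TrialSegments:
    """Event-locked alertness segments: trials x relative-time grid."""

    matrix: np.ndarray
    offsets: np.ndarray
    trial_labels: np.ndarray
    scan_ids: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("segment matrix must be 2D")
        if self.matrix.shape[1] != self.offsets.size:
            raise ValueError("offset grid must match segment columns")
        if self.matrix.shape[0] != len(self.trial_labels):
            raise ValueError("one label per retained trial required")

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0]


@dataclass
class PhysioSignals:
    """Respiration-belt and pulse (PPG) waveforms with sampling rates."""

    resp: np.ndarray
    fs_resp: float
    ppg: np.ndarray
    fs_ppg: float

    def __post_init__(self) -> None:
        self.resp = np.asarray(self.resp, dtype=float)
        self.ppg = np.asarray(self.ppg, dtype=float)
        if self.fs_resp <= 0 or self.fs_ppg <= 0:
            raise ValueError("sampling rates must be positive")


@dataclass
class PhysioRegressors:
    """Per-TR RV and HR series with their 6-column nuisance basis.

    The basis holds RV convolved with the respiration response function
    and HR convolved with the cardiac response function, each with
    temporal and dispersion derivative columns; all zero-mean.
    """

    rv: np.ndarray
    hr: np.ndarray
    basis: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rv = np.asarray(self.rv, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        self.basis = np.asarray(self.basis, dtype=float)
        if self.basis.ndim != 2 or self.basis.shape[1] != 6:
            raise ValueError("physio basis must have exactly 6 columns")
        sd = self.basis.std(axis=0)
        means = np.abs(self.basis.mean(axis=0))
        if np.any(means > 1e-8 * np.maximum(sd, 1e-300)):
            raise ValueError("basis columns must be zero-mean")


@dataclass
class CrossCorrFunction:
    """Lagged Pearson cross-correlation between two alertness indices.

    Positive lag means the first argument leads the second (the second
    series reproduces the first after a delay). Lag 0 is simultaneity.
    """

    lags: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.size != self.values.size:
            raise ValueError("lags and values must align")
        if self.values.size and np.nanmax(np.abs(self.values)) > 1 + 1e-9:
            raise ValueError("cross-correlation values must lie in [-1, 1]")

    @property
    def peak_lag(self) -> int:
        return int(self.lags[int(np.nanargmax(self.values))])

    @property
    def peak_value(self) -> float:
        return float(np.nanmax(self.values))


@dataclass
class PermutationNull:
    """Null cross-correlation curves from mismatched EEG-fMRI pairings."""

    draws: np.ndarray
    lags: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        self.lags = np.asarray(self.lags, dtype=int)
        if self.draws.ndim != 2 or self.draws.shape[1] != self.lags.size:
            raise ValueError("draws must be (n_perm, n_lags)")

    @property
    def n_perm(self) -> int:
        return self.draws.shape[0]

    def peak_percentile(self, q: float) -> float:
        """Percentile of the per-draw peak (max over lags) distribution."""
        return float(np.percentile(self.draws.max(axis=1), q))


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint train/test scan partition for template evaluation."""

    train_scan_ids: frozenset
    test_scan_ids: frozenset
    direction: str = "rest_to_task"

    def __post_init__(self) -> None:
        train = frozenset(self.train_scan_ids)
        test = frozenset(self.test_scan_ids)
        object.__setattr__(self, "train_scan_ids", train)
        object.__setattr__(self, "test_scan_ids", test)
        if train & test:
            raise ValueError(
                f"train/test leakage: shared scan ids {sorted(train & test)}")
        if not train or not test:
            raise ValueError("train and test sets must be non-empty")


@dataclass
class StatResult:
    """Outcome of a paired t-test, two-sample t-test or one-way ANOVA."""

    test: str
    statistic: float
    df: float
    p: float
    effect_size: float | None = None
    posthoc: pd.DataFrame | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")


@dataclass
class DesignMatrix:
    """GLM design: volumes x regressors, full column rank, with intercept."""

    columns: np.ndarray
    names: list[str]
    tr: float

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.ndim != 2:
            raise ValueError("design must be 2D")
        if len(self.names) != self.columns.shape[1]:
            raise ValueError("one name per column required")
        if "intercept" not in self.names:
            raise ValueError("an intercept column is required")
        rank = np.linalg.matrix_rank(self.columns)
        if rank < self.columns.shape[1]:
            raise ValueError(
                f"design is rank deficient (rank {rank} < {self.columns.shape[1]}); "
                f"columns: {self.names}")

    @property
    def n_volumes(self) -> int:
        return self.columns.shape[0]


@dataclass
class GLMResult:
    """Per-voxel OLS betas, residual variance and t maps, one per regressor."""

    beta: np.ndarray          # (x, y, z, n_regressors)
    residual_var: np.ndarray  # (x, y, z)
    t: np.ndarray             # (x, y, z, n_regressors)
    dof: int
    names: list[str]
    mask: np.ndarray

    def beta_map(self, name: str) -> np.ndarray:
        return self.beta[..., self.names.index(name)]

    def t_map(self, name: str) -> np.ndarray:
        return self.t[..., self.names.index(name)]


@dataclass
class ROITimeseries:
    """Region-mean BOLD series: volumes x regions, from a labeled atlas."""

    matrix: np.ndarray
    region_ids: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.region_ids = np.asarray(self.region_ids)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != self.region_ids.size:
            raise ValueError("matrix columns must match region_ids")


@dataclass
class SyntheticWorld:
    """One simulated scan session with its full generating record.

    The ``params`` dict together with the master seed is sufficient to
    regenerate every member bit-for-bit.
    """

    latent: LatentArousal
    true_template: np.ndarray
    mask: np.ndarray
    eeg: EEGRecording | None
    scan: FMRIScan
    trials: TrialTable | None
    physio: PhysioSignals | None
    params: dict

    def replace(self, **kwargs) -> "SyntheticWorld":
        return dataclasses.replace(self, **kwargs)
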