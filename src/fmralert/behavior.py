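"""Event-locked behavioral analysis of alertness indices.

Alertness time courses are interpolated to a fine grid, cut into segments
around each stimulus onset, classified by behavioral outcome (fast hit /
slow hit / miss), averaged over pre- and post-stimulus intervals, and
compared across trial types with paired t-tests and one-way ANOVA with
Tukey-Kramer post hoc comparisons.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AlertnessIndex, StatResult, TrialSegments, TrialTable

__all__ = [
    "interpolate_index",
    "extract_segments",
    "classify_trials",
    "interval_mean",
    "paired_test",
    "two_sample_test",
    "anova_tukey",
    "PRE_INTERVAL",
    "POST_INTERVAL",
    "MISS_RT_MS",
]

logger = logging.getLogger(__name__)

PRE_INTERVAL = (-5.0, 0.0)
POST_INTERVAL = (0.0, 10.0)

#: Responses slower than this count as misses.
MISS_RT_MS = 5000.0


def interpolate_index(index: AlertnessIndex, factor: float = 2.5
                      ) -> AlertnessIndex:
    """Linear interpolation onto a grid of spacing tr / factor.

    With tr = 2.1 s and factor 2.5 this is the 0.84 s fine grid used for
    event alignment. Original samples are reproduced exactly wherever the
    fine grid coincides with the original one.
    """
    if factor <= 1:
        raise ValueError("interpolation factor must exceed 1")
    dt = index.tr / factor
    n_fine = int(np.floor((len(index) - 1) * factor + 1e-9)) + 1
    t_orig = np.arange(len(index)) * index.tr
    t_fine = np.arange(n_fine) * dt
    values = np.interp(t_fine, t_orig, index.values)
    return index.with_values(values, tr=dt, step=f"interp_x{factor}")


def extract_segments(index_fine: AlertnessIndex, trials: TrialTable,
                     window: tuple[float, float] = (-5.0, 10.0)
                     ) -> TrialSegments:
    """Cut event-locked segments of the fine-grid index around each onset.

    The relative-time grid covers the closed window with points k * dt for
    k from floor(window[0]/dt) to ceil(window[1]/dt) (outermost points
    chosen to cover the window edges). Each segment value is the fine-grid
    sample nearest to onset + offset, so values equal index values at
    those absolute times exactly. Trials whose window extends beyond the
    recording are dropped and logged. Requires classified trials.
    """
    if not (-60.0 <= window[0] < window[1] <= 60.0):
        raise ValueError("window must be an increasing pair within [-60, 60] s")
    if trials.labels is None:
        raise ValueError("trials must be classified before segment extraction")
    dt = index_fine.tr
    ks = np.arange(int(np.floor(window[0] / dt)),
                   int(np.ceil(window[1] / dt)) + 1)
    offsets = ks * dt
    n = len(index_fine)
    rows, labels, kept = [], [], []
    for i, onset in enumerate(trials.onsets):
        idx = np.round(onset / dt).astype(int) + ks
        if idx[0] < 0 or idx[-1] >= n:
            logger.info("dropping trial at t=%.1f s: window outside recording",
                        onset)
            continue
        rows.append(index_fine.values[idx])
        labels.append(trials.labels[i])
        kept.append(i)
    if not rows:
        logger.warning("no retainable trials in %s", trials.scan_id)
        matrix = np.empty((0, offsets.size))
    else:
        matrix = np.vstack(rows)
    return TrialSegments(matrix=matrix, offsets=offsets,
                         trial_labels=np.asarray(labels, dtype=object),
                         scan_ids=np.full(len(labels), trials.scan_id,
                                          dtype=object))


def classify_trials(trials: TrialTable, threshold_mode: str = "pooled_median",
                    pooled_rt: np.ndarray | None = None) -> TrialTable:
    """Label each trial fast_hit / slow_hit / miss.

    A miss is no button press or a response slower than 5 s. In
    ``pooled_median`` mode, hits at or above the pooled-median reaction
    time are slow and below it fast (ties to slow, logged; the pooled
    threshold is the median of ``pooled_rt``, normally all subjects'
    pooled hit RTs). In ``subject_decile`` mode only each scan's fastest
    10% (fast_hit) and slowest 10% (slow_hit) of hits are labeled; the
    rest of the hits stay 'hit'.
    """
    rt = trials.rt
    is_miss = ~trials.responded | ~np.isfinite(rt) | (rt > MISS_RT_MS)
    labels = np.full(len(trials), "miss", dtype=object)
    hit_idx = np.flatnonzero(~is_miss)

    if threshold_mode == "pooled_median":
        if pooled_rt is None or len(pooled_rt) == 0:
            raise ValueError("pooled_median mode requires pooled_rt")
        threshold = float(np.median(pooled_rt))
        ties = hit_idx[rt[hit_idx] == threshold]
        if ties.size:
            logger.info("%d RT(s) exactly at threshold %.1f ms assigned slow",
                        ties.size, threshold)
        labels[hit_idx] = np.where(rt[hit_idx] < threshold,
                                   "fast_hit", "slow_hit")
    elif threshold_mode == "subject_decile":
        labels[hit_idx] = "hit"
        if hit_idx.size:
            hit_rt = rt[hit_idx]
            k = max(1, int(np.floor(0.1 * hit_idx.size)))
            order = np.argsort(hit_rt, kind="stable")
            labels[hit_idx[order[:k]]] = "fast_hit"
            labels[hit_idx[order[-k:]]] = "slow_hit"
    else:
        raise ValueError("threshold_mode must be pooled_median or subject_decile")
    return TrialTable(onsets=trials.onsets, responded=trials.responded,
                      rt=trials.rt, scan_id=trials.scan_id, labels=labels)


def interval_mean(segments: TrialSegments,
                  interval: tuple[float, float] = PRE_INTERVAL
                  ) -> pd.DataFrame:
    """Average segments over an interval, per trial, then per class per scan.

    Grid points with offsets in the closed interval are averaged within
    each trial; trial values are then averaged across trials of each class
    within each scan, yielding one value per (scan, class). Classes absent
    from a scan are simply absent from the output (such scans drop out of
    paired contrasts involving that class).
    """
    lo, hi = interval
    sel = (segments.offsets >= lo) & (segments.offsets <= hi)
    if not sel.any():
        raise ValueError("interval contains no grid points")
    per_trial = segments.matrix[:, sel].mean(axis=1)
    df = pd.DataFrame({"scan_id": segments.scan_ids,
                       "label": segments.trial_labels,
                       "value": per_trial})
    return (df.groupby(["scan_id", "label"], sort=True)["value"]
              .mean().reset_index())


def paired_values(means: pd.DataFrame, label_a: str, label_b: str
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Per-scan paired values for two trial classes (scans having both)."""
    wide = means.pivot(index="scan_id", columns="label", values="value")
    if label_a not in wide.columns or label_b not in wide.columns:
        return np.array([]), np.array([])
    both = wide[[label_a, label_b]].dropna()
    return both[label_a].to_numpy(), both[label_b].to_numpy()


def paired_test(a: np.ndarray, b: np.ndarray,
                d_convention: str = "diff_sd") -> StatResult:
    """Two-tailed paired t-test with Cohen's d.

    d is mean(diff)/sd(diff) by default (``d_convention='diff_sd'``) or
    mean(diff)/pooled sd (``'pooled'``). A zero-variance nonzero
    difference yields an infinite t, flagged degenerate with p = 0.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size != b.size or a.size < 2:
        raise ValueError("paired test needs equal-length samples, n >= 2")
    diff = a - b
    n = diff.size
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return StatResult("paired_t", 0.0, n - 1, 1.0, effect_size=0.0)
        t = np.inf if diff.mean() > 0 else -np.inf
        return StatResult("paired_t", t, n - 1, 0.0,
                          effect_size=np.sign(diff.mean()) * np.inf,
                          degenerate=True)
    t = diff.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    if d_convention == "diff_sd":
        d = diff.mean() / sd
    elif d_convention == "pooled":
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
        d = diff.mean() / pooled if pooled > 0 else np.inf * np.sign(diff.mean())
    else:
        raise ValueError("d_convention must be diff_sd or pooled")
    return StatResult("paired_t", float(t), n - 1, float(p),
                      effect_size=float(d))


def two_sample_test(a: np.ndarray, b: np.ndarray) -> StatResult:
    """Two-tailed independent-samples t-test with pooled-sd Cohen's d."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    t, p = stats.ttest_ind(a, b)
    pooled = np.sqrt(((a.size - 1) * a.var(ddof=1)
                      + (b.size - 1) * b.var(ddof=1))
                     / (a.size + b.size - 2))
    d = (a.mean() - b.mean()) / pooled if pooled > 0 else np.nan
    return StatResult("two_sample_t", float(t), a.size + b.size - 2,
                      float(p), effect_size=float(d))


def anova_tukey(groups: dict[str, np.ndarray] | list[np.ndarray]) -> StatResult:
    """One-way ANOVA across trial-type groups with Tukey-Kramer post hoc.

    Returns the F statistic with (k-1, N-k) degrees of freedom, its p
    value, and a table of all pairwise comparisons with family-wise
    adjusted p values (Tukey-Kramer handles unequal group sizes).
    """
    if isinstance(groups, dict):
        names = list(groups)
        arrays = [np.asarray(groups[k], float) for k in names]
    else:
        arrays = [np.asarray(g, float) for g in groups]
        names = [f"group{i}" for i in range(len(arrays))]
    if len(arrays) < 2 or any(g.size < 2 for g in arrays):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 values each")
    f, p = stats.f_oneway(*arrays)
    k = len(arrays)
    n_total = sum(g.size for g in arrays)
    if not np.isfinite(f):  # identical groups: zero between & within variance
        f, p = 0.0, 1.0
    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    values = np.concatenate(arrays)
    labels = np.concatenate([[name] * g.size for name, g in zip(names, arrays)])
    tukey = pairwise_tukeyhsd(values, labels)
    posthoc = pd.DataFrame(tukey.summary().data[1:],
                           columns=tukey.summary().data[0])
    return StatResult("one_way_anova", float(f), (k - 1, n_total - k),
                      float(p), posthoc=posthoc)
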