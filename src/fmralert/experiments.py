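"""End-to-end cohort experiments on synthetic data.

These functions wire the full pipeline together on simulated cohorts:
template recovery against the permutation null, template sparsification,
trial-locked behavioral contrasts, GLM covariate benefit, the effect of
physiological-noise removal, lasso-versus-template comparison, and null
calibration of the statistical tests. They are the package's reference
experiments; the acceptance script and the heavier tests call them.
"""

from __future__ import annotations

import numpy as np

from . import behavior as bh
from . import glm as glm_mod
from .datatypes import AlertnessIndex, SplitPlan, SyntheticWorld
from .eeg import eeg_alertness_index
from .physio import build_physio_basis, compute_hr, compute_rv, regress_out
from .projection import (
    TemplateVigilanceDecoder,
    cross_correlate,
    evaluate_split,
    permutation_null,
    project_template,
    zscore_scan,
)
from .synthetic import (
    Cohort,
    make_task_weights,
    make_true_template,
    simulate_cohort,
)
from .template import THRESHOLD_FRACTIONS

__all__ = [
    "world_eeg_index",
    "template_recovery",
    "sparsification_curves",
    "behavior_contrasts",
    "behavior_replication",
    "glm_covariate_benefit",
    "physio_removal_effect",
    "lasso_vs_template",
    "anova_type_i_rate",
    "group_t_type_i_rate",
    "make_block_atlas",
]


def world_eeg_index(world: SyntheticWorld) -> AlertnessIndex:
    """Hemodynamic EEG alertness index of a synthetic world's recording."""
    return eeg_alertness_index(world.eeg, tr=world.latent.tr,
                               n_volumes=len(world.latent))


def _cohort_indices(worlds) -> dict[str, AlertnessIndex]:
    return {w.scan.scan_id: world_eeg_index(w) for w in worlds}


def template_recovery(seed: int = 0, n_subjects: int = 12,
                      direction: str = "rest_to_task", max_lag: int = 10,
                      n_perm: int = 1000, cohort: Cohort | None = None,
                      **world_kwargs) -> dict:
    """Train-on-one-condition, test-on-the-other template evaluation.

    Builds the vigilance template from the training scans of a simulated
    cohort, projects it on the held-out scans, and compares the mean
    cross-correlation curve with the EEG index against the derangement
    permutation null. Returns observed and null summary numbers.
    """
    if cohort is None:
        cohort = simulate_cohort(n_subjects=n_subjects, seed=seed,
                                 **world_kwargs)
    if direction == "rest_to_task":
        train, test = cohort.rest, cohort.task
    elif direction == "task_to_rest":
        train, test = cohort.task, cohort.rest
    else:
        raise ValueError("direction must be rest_to_task or task_to_rest")
    scans = {w.scan.scan_id: w.scan for w in train + test}
    indices = {**_cohort_indices(train), **_cohort_indices(test)}
    plan = SplitPlan(frozenset(w.scan.scan_id for w in train),
                     frozenset(w.scan.scan_id for w in test),
                     direction=direction)
    curves, null, template = evaluate_split(scans, indices, plan,
                                            max_lag=max_lag, n_perm=n_perm,
                                            seed=seed)
    mean_curve = np.mean([c.values for c in curves.values()], axis=0)
    return {
        "mean_peak_r": float(mean_curve.max()),
        "mean_peak_lag": int(null.lags[int(mean_curve.argmax())]),
        "per_scan_peaks": [c.peak_value for c in curves.values()],
        "null_p95": null.peak_percentile(95.0),
        "null_mean": float(null.draws.mean()),
        "curves": curves,
        "null": null,
        "template": template,
        "cohort": cohort,
    }


def sparsification_curves(seed: int = 0, n_subjects: int = 12,
                          fractions=THRESHOLD_FRACTIONS, max_lag: int = 10,
                          cohort: Cohort | None = None,
                          **world_kwargs) -> dict:
    """Mean peak EEG-fMRI correlation versus template retention fraction.

    Evaluates joint (positive+negative), positive-only and negative-only
    sparsified templates built from the rest scans and applied to the task
    scans, mirroring the template-thresholding experiment.
    """
    if cohort is None:
        cohort = simulate_cohort(n_subjects=n_subjects, seed=seed,
                                 **world_kwargs)
    decoder = TemplateVigilanceDecoder()
    rest_scans = [w.scan for w in cohort.rest]
    rest_idx = [world_eeg_index(w) for w in cohort.rest]
    decoder.fit(rest_scans, rest_idx)
    task_z = [zscore_scan(w.scan) for w in cohort.task]
    task_idx = [world_eeg_index(w) for w in cohort.task]

    from .template import threshold_template
    out = {m: [] for m in ("both", "positive", "negative")}
    for mode in out:
        for frac in fractions:
            tpl = threshold_template(decoder.template_, frac, mode)
            peaks = []
            for scan, ref in zip(task_z, task_idx):
                fmri = project_template(scan, tpl)
                n = min(len(fmri), len(ref))
                peaks.append(cross_correlate(fmri.values[:n], ref.values[:n],
                                             max_lag).peak_value)
            out[mode].append(float(np.mean(peaks)))
    return {"fractions": list(fractions), "mean_peak_r": out}


def behavior_contrasts(seed: int = 0, n_subjects: int = 12,
                       cohort: Cohort | None = None,
                       template=None, **world_kwargs) -> dict:
    """Pre-stimulus fMRI-alertness contrasts across behavioral outcomes.

    Template from rest scans; fMRI alertness index on each task scan,
    interpolated 2.5-fold, segmented around stimulus onsets, classified at
    the cohort's pooled-median reaction time, averaged over the
    pre-stimulus interval per class per scan, and compared with paired
    t-tests (hits vs misses, fast vs slow hits).
    """
    if cohort is None:
        cohort = simulate_cohort(n_subjects=n_subjects, seed=seed,
                                 **world_kwargs)
    if template is None:
        decoder = TemplateVigilanceDecoder()
        decoder.fit([w.scan for w in cohort.rest],
                    [world_eeg_index(w) for w in cohort.rest])
        template = decoder.template_

    pooled_rt = np.concatenate([
        w.trials.rt[w.trials.responded & np.isfinite(w.trials.rt)]
        for w in cohort.task if w.trials is not None])
    segs, pre_rows = [], []
    for w in cohort.task:
        fmri = project_template(zscore_scan(w.scan), template)
        fine = bh.interpolate_index(fmri, 2.5)
        trials = bh.classify_trials(w.trials, "pooled_median", pooled_rt)
        segs.append(bh.extract_segments(fine, trials))
    matrix = np.vstack([s.matrix for s in segs])
    labels = np.concatenate([s.trial_labels for s in segs])
    scan_ids = np.concatenate([s.scan_ids for s in segs])
    from .datatypes import TrialSegments
    pooled = TrialSegments(matrix=matrix, offsets=segs[0].offsets,
                           trial_labels=labels, scan_ids=scan_ids)
    pre = bh.interval_mean(pooled, bh.PRE_INTERVAL)
    post = bh.interval_mean(pooled, bh.POST_INTERVAL)

    def _contrast(means, a, b):
        va, vb = bh.paired_values(means, a, b)
        if va.size < 2:
            return None
        return bh.paired_test(va, vb)

    hit = pre.copy()
    hit["label"] = hit["label"].replace({"fast_hit": "hit", "slow_hit": "hit"})
    hit = hit.groupby(["scan_id", "label"], sort=True)["value"].mean().reset_index()
    return {
        "hit_vs_miss": _contrast(hit, "hit", "miss"),
        "fast_vs_slow": _contrast(pre, "fast_hit", "slow_hit"),
        "fast_vs_slow_post": _contrast(post, "fast_hit", "slow_hit"),
        "pre_means": pre,
        "post_means": post,
        "segments": pooled,
        "n_trials": int(matrix.shape[0]),
    }


def behavior_replication(n_cohorts: int = 50, seed: int = 0,
                         n_subjects: int = 12, alpha: float = 0.05,
                         **world_kwargs) -> dict:
    """Fraction of simulated cohorts reproducing the behavioral effects.

    Success per cohort: pre-stimulus fMRI alertness greater for hits than
    misses and for fast than slow hits, each with paired-test p < alpha.
    """
    rng_seeds = np.random.SeedSequence(seed).generate_state(n_cohorts)
    world_kwargs.setdefault("task_eeg", False)  # task EEG never read here
    world_kwargs.setdefault("eeg_fs", 125.0)
    hm_ok, fs_ok = [], []
    for s in rng_seeds:
        res = behavior_contrasts(seed=int(s & 0x7FFFFFFF),
                                 n_subjects=n_subjects, **world_kwargs)
        hm = res["hit_vs_miss"]
        fs = res["fast_vs_slow"]
        hm_ok.append(hm is not None and hm.statistic > 0 and hm.p < alpha)
        fs_ok.append(fs is not None and fs.statistic > 0 and fs.p < alpha)
    return {"hit_vs_miss_rate": float(np.mean(hm_ok)),
            "fast_vs_slow_rate": float(np.mean(fs_ok)),
            "n_cohorts": n_cohorts}


def glm_covariate_benefit(n_cohorts: int = 50, seed: int = 0,
                          n_subjects: int = 12, task_amp: float = 0.5,
                          evoked_gain: float = 0.8, **world_kwargs) -> dict:
    """Effect of the fMRI alertness covariate on group task-GLM t maps.

    Each cohort's task scans carry genuine event-locked activation on the
    task voxels plus a stimulus-evoked arousal rebound that drives the
    arousal template pattern — a task-correlated confound. Group t maps
    for the hit regressor are computed without and with the fMRI alertness
    index (projected from a rest-scan template) as a covariate. Success:
    the median t over true task voxels rises, and the median t over
    confound-only (template, non-task) voxels shrinks in magnitude.
    """
    rng_seeds = np.random.SeedSequence(seed).generate_state(n_cohorts)
    shape = world_kwargs.get("shape", (16, 16, 12))
    task_w = make_task_weights(shape) != 0
    true_w, _ = make_true_template(shape)
    confound_vox = (true_w < 0) & ~task_w

    task_up, confound_shrink = [], []
    med_with, med_without = [], []
    for s in rng_seeds:
        world_kwargs.setdefault("eeg_fs", 125.0)
        cohort = simulate_cohort(n_subjects=n_subjects, seed=int(s & 0x7FFFFFFF),
                                 task_amp=task_amp, evoked_gain=evoked_gain,
                                 task_eeg=False, **world_kwargs)
        decoder = TemplateVigilanceDecoder()
        decoder.fit([w.scan for w in cohort.rest],
                    [world_eeg_index(w) for w in cohort.rest])
        betas_plain, betas_cov = [], []
        for w in cohort.task:
            trials = w.trials
            hits = trials.onsets[trials.responded]
            misses = trials.onsets[~trials.responded]
            n_vol = w.scan.n_volumes
            d0 = glm_mod.build_design(hits, misses, None, n_volumes=n_vol,
                                      tr=w.scan.tr)
            fmri_idx = project_template(zscore_scan(w.scan), decoder.template_)
            d1 = glm_mod.build_design(hits, misses,
                                      {"fmri_alertness": fmri_idx},
                                      n_volumes=n_vol, tr=w.scan.tr)
            betas_plain.append(glm_mod.fit_glm(w.scan, d0).beta_map("hits"))
            betas_cov.append(glm_mod.fit_glm(w.scan, d1).beta_map("hits"))
        t0 = glm_mod.group_level(betas_plain, cohort.mask)
        t1 = glm_mod.group_level(betas_cov, cohort.mask)
        m0, m1 = np.median(t0[task_w]), np.median(t1[task_w])
        c0, c1 = np.median(t0[confound_vox]), np.median(t1[confound_vox])
        task_up.append(m1 > m0)
        confound_shrink.append(abs(c1) < abs(c0))
        med_without.append(m0)
        med_with.append(m1)
    return {"task_t_up_rate": float(np.mean(task_up)),
            "confound_shrink_rate": float(np.mean(confound_shrink)),
            "median_task_t_without": float(np.mean(med_without)),
            "median_task_t_with": float(np.mean(med_with)),
            "n_cohorts": n_cohorts}


def _physio_basis_for(world: SyntheticWorld):
    physio = world.physio
    n_vol = world.scan.n_volumes
    rv = compute_rv(physio.resp, physio.fs_resp, world.scan.tr, n_vol)
    hr = compute_hr(physio.ppg, physio.fs_ppg, world.scan.tr, n_vol)
    return build_physio_basis(rv, hr, world.scan.tr)


def physio_removal_effect(n_cohorts: int = 50, seed: int = 0,
                          n_subjects: int = 12, max_lag: int = 10,
                          **world_kwargs) -> dict:
    """Does regressing out RV/HR change EEG-fMRI correspondence?

    In these cohorts respiration depth and heart rate share the latent
    arousal driver with BOLD, so the physiological regressors carry
    arousal information; removing them is expected to *lower* the mean
    peak EEG-fMRI cross-correlation of the template method.
    """
    world_kwargs.setdefault("with_physio", True)
    world_kwargs.setdefault("eeg_fs", 125.0)
    rng_seeds = np.random.SeedSequence(seed).generate_state(n_cohorts)
    reduced, peaks_raw, peaks_clean = [], [], []
    for s in rng_seeds:
        cohort = simulate_cohort(n_subjects=n_subjects,
                                 seed=int(s & 0x7FFFFFFF), **world_kwargs)
        rest_idx = [world_eeg_index(w) for w in cohort.rest]
        task_idx = [world_eeg_index(w) for w in cohort.task]

        def _mean_peak(rest_scans, task_scans):
            decoder = TemplateVigilanceDecoder()
            decoder.fit(rest_scans, rest_idx)
            peaks = []
            for scan, ref in zip(task_scans, task_idx):
                fmri = project_template(zscore_scan(scan), decoder.template_)
                n = min(len(fmri), len(ref))
                peaks.append(cross_correlate(fmri.values[:n], ref.values[:n],
                                             max_lag).peak_value)
            return float(np.mean(peaks))

        raw = _mean_peak([w.scan for w in cohort.rest],
                         [w.scan for w in cohort.task])
        clean = _mean_peak(
            [regress_out(w.scan, _physio_basis_for(w)) for w in cohort.rest],
            [regress_out(w.scan, _physio_basis_for(w)) for w in cohort.task])
        reduced.append(clean < raw)
        peaks_raw.append(raw)
        peaks_clean.append(clean)
    return {"reduced_rate": float(np.mean(reduced)),
            "mean_peak_raw": float(np.mean(peaks_raw)),
            "mean_peak_removed": float(np.mean(peaks_clean)),
            "n_cohorts": n_cohorts}


def make_block_atlas(shape=(16, 16, 12), mask=None,
                     block=(4, 4, 4)) -> np.ndarray:
    """Integer-labeled parcellation: contiguous rectangular blocks."""
    if mask is None:
        _, mask = make_true_template(shape)
    ix, iy, iz = np.indices(shape)
    labels = (1 + (ix // block[0])
              + (iy // block[1]) * int(np.ceil(shape[0] / block[0]))
              + (iz // block[2]) * int(np.ceil(shape[0] / block[0]))
              * int(np.ceil(shape[1] / block[1])))
    atlas = np.where(mask, labels, 0)
    return atlas


def lasso_vs_template(seed: int = 0, n_subjects: int = 4, max_lag: int = 10,
                      cohort: Cohort | None = None, **world_kwargs) -> dict:
    """ROI-lasso and voxel-lasso decoders versus template projection.

    All three are trained on the rest scans (lasso on temporally
    concatenated features against the concatenated EEG index) and
    evaluated by mean peak cross-correlation with the ground-truth latent
    arousal on the task scans. Runs at reduced spatial/temporal size: the
    voxel-feature lasso path is by far the most expensive fit in the
    package.
    """
    import warnings as _warnings

    from sklearn.exceptions import ConvergenceWarning

    from .lasso import LassoAlertnessDecoder, extract_roi_timeseries
    if cohort is None:
        world_kwargs.setdefault("n_volumes", 200)
        world_kwargs.setdefault("shape", (10, 10, 8))
        world_kwargs.setdefault("eeg_fs", 125.0)
        cohort = simulate_cohort(n_subjects=n_subjects, seed=seed,
                                 **world_kwargs)
    atlas = make_block_atlas(cohort.mask.shape, cohort.mask)
    rest_idx = [world_eeg_index(w) for w in cohort.rest]
    refs = [w.latent for w in cohort.task]

    roi_rest = np.vstack([extract_roi_timeseries(w.scan, atlas).matrix
                          for w in cohort.rest])
    vox_rest = np.vstack([w.scan.masked_series().T for w in cohort.rest])
    y = np.concatenate([idx.values for idx in rest_idx])
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", ConvergenceWarning)
        roi_model = LassoAlertnessDecoder(n_lambdas=30, seed=seed).fit(
            roi_rest, y)
        vox_model = LassoAlertnessDecoder(n_lambdas=30, seed=seed).fit(
            vox_rest, y)

    decoder = TemplateVigilanceDecoder()
    decoder.fit([w.scan for w in cohort.rest], rest_idx)

    def _peaks(pred_fn):
        peaks = []
        for w, ref in zip(cohort.task, refs):
            pred = pred_fn(w)
            n = min(pred.size, len(ref))
            peaks.append(cross_correlate(ref.values[:n], pred[:n],
                                         max_lag).peak_value)
        return float(np.mean(peaks))

    return {
        "template": _peaks(lambda w: project_template(
            zscore_scan(w.scan), decoder.template_).values),
        "lasso_roi": _peaks(lambda w: roi_model.predict(
            extract_roi_timeseries(w.scan, atlas).matrix)),
        "lasso_voxel": _peaks(lambda w: vox_model.predict(
            w.scan.masked_series().T)),
    }


def anova_type_i_rate(n_reps: int = 2000, n_per_group: int = 12,
                      alpha: float = 0.05, seed: int = 0) -> float:
    """Empirical type-I rate of the one-way ANOVA under the null."""
    rng = np.random.default_rng(seed)
    from scipy.stats import f_oneway
    hits = 0
    for _ in range(n_reps):
        g = rng.standard_normal((3, n_per_group))
        _, p = f_oneway(*g)
        hits += p < alpha
    return hits / n_reps


def group_t_type_i_rate(n_scans: int = 12, n_voxels: int = 20000,
                        alpha: float = 0.05, seed: int = 0) -> float:
    """Empirical voxelwise type-I rate of the group one-sample t-test."""
    from scipy.stats import t as t_dist
    rng = np.random.default_rng(seed)
    betas = [rng.standard_normal(n_voxels) for _ in range(n_scans)]
    t_map = glm_mod.group_level(betas)
    crit = t_dist.ppf(1 - alpha / 2, n_scans - 1)
    return float(np.mean(np.abs(t_map) > crit))
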