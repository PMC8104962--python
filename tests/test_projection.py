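"""Template projection, cross-correlation and the permutation null."""

import numpy as np
import pytest
from sklearn.base import clone

from fmralert.datatypes import (
    AlertnessIndex,
    FMRIScan,
    SplitPlan,
    VigilanceTemplate,
)
from fmralert.experiments import world_eeg_index
from fmralert.projection import (
    TemplateVigilanceDecoder,
    cross_correlate,
    evaluate_split,
    permutation_null,
    project_template,
    zscore_scan,
)


def _scan(data, mask=None):
    data = np.asarray(data, float)
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    return FMRIScan(data=data, tr=2.1, mask=mask)


def _template(values):
    values = np.asarray(values, float)
    return VigilanceTemplate(values=values,
                             mask=np.ones(values.shape, dtype=bool))


class TestZscoreScan:
    def test_definition_and_metadata(self, tiny_world):
        z = zscore_scan(tiny_world.scan)
        series = z.masked_series()
        assert np.abs(series.mean(axis=1)).max() < 1e-10
        assert np.abs(series.std(axis=1) - 1.0).max() < 1e-10
        np.testing.assert_array_equal(z.mask, tiny_world.scan.mask)
        np.testing.assert_array_equal(z.affine, tiny_world.scan.affine)

    def test_idempotence(self, tiny_world):
        once = zscore_scan(tiny_world.scan)
        twice = zscore_scan(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-10)

    def test_zero_variance_voxels_zeroed(self):
        data = np.zeros((2, 2, 1, 8))
        data[0, 0, 0] = np.arange(8.0)
        data[0, 1, 0] = 4.0  # constant voxel
        z = zscore_scan(_scan(data))
        assert np.all(z.data[0, 1, 0] == 0.0)
        assert z.data[0, 0, 0].std() == pytest.approx(1.0)


class TestProjectTemplate:
    def test_affine_image_of_template_gives_unit_correlation(self, rng):
        tpl_vals = rng.normal(0, 1, (3, 3, 2))
        data = np.empty((3, 3, 2, 8))
        for t in range(8):
            data[..., t] = 2.0 * tpl_vals + 5.0
        idx = project_template(_scan(data), _template(tpl_vals))
        np.testing.assert_allclose(idx.values, 1.0, atol=1e-12)

    def test_negated_volume_gives_minus_one(self, rng):
        tpl_vals = rng.normal(0, 1, (3, 3, 2))
        data = np.stack([-tpl_vals] * 8, axis=-1)
        idx = project_template(_scan(data), _template(tpl_vals))
        np.testing.assert_allclose(idx.values, -1.0, atol=1e-12)

    def test_four_voxel_toy_matches_hand_formula(self):
        w = np.array([2.0, -1.0, 0.0, 1.0])
        v = np.array([1.0, 0.0, 1.0, 2.0])
        tpl = _template(w.reshape(4, 1, 1))
        data = np.tile(v.reshape(4, 1, 1, 1), (1, 1, 1, 8))
        idx = project_template(_scan(data), tpl)
        n = 4
        num = n * (w * v).sum() - w.sum() * v.sum()
        den = np.sqrt(n * (w ** 2).sum() - w.sum() ** 2) * \
            np.sqrt(n * (v ** 2).sum() - v.sum() ** 2)
        assert idx.values[0] == pytest.approx(num / den, abs=1e-12)

    def test_scan_affine_rescaling_invariance(self, tiny_world, rng):
        tpl = _template(rng.normal(0, 1, tiny_world.scan.mask.shape))
        tpl.mask[:] = True
        a = project_template(tiny_world.scan, tpl).values
        rescaled = FMRIScan(data=3.7 * tiny_world.scan.data + 11.0,
                            tr=2.1, mask=tiny_world.scan.mask)
        b = project_template(rescaled, tpl).values
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_degenerate_support_rejected(self):
        tpl_vals = np.zeros((3, 3, 2))
        tpl_vals[0, 0, 0] = 1.0
        tpl = VigilanceTemplate(values=tpl_vals, mask=tpl_vals != 0)
        data = np.zeros((3, 3, 2, 8))
        with pytest.raises(ValueError, match="degenerate"):
            project_template(_scan(data), tpl)


class TestCrossCorrelate:
    def test_identity_peak_at_zero(self, rng):
        x = rng.standard_normal(200)
        cc = cross_correlate(x, x, 10)
        assert cc.peak_lag == 0
        assert cc.peak_value == pytest.approx(1.0)

    def test_delayed_copy_peaks_at_positive_lag(self, rng):
        a = rng.standard_normal(700)
        b = np.roll(a, 3)  # b reproduces a three samples later: a leads
        cc = cross_correlate(a, b, 10)
        assert cc.peak_lag == 3

    def test_independent_noise_bounded(self):
        n = 700
        ok = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            cc = cross_correlate(rng.standard_normal(n),
                                 rng.standard_normal(n), 10)
            ok += np.max(np.abs(cc.values)) < 4 / np.sqrt(n)
        assert ok >= 95

    def test_argument_swap_mirrors_lags(self, rng):
        a = rng.standard_normal(300)
        b = rng.standard_normal(300)
        ab = cross_correlate(a, b, 8)
        ba = cross_correlate(b, a, 8)
        np.testing.assert_allclose(ab.values, ba.values[::-1], atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_correlate(np.zeros(10), np.zeros(12), 2)


class TestPermutationNull:
    def test_grand_null_mean_near_zero(self):
        rng = np.random.default_rng(0)
        fmri = [rng.standard_normal(700) for _ in range(12)]
        eeg = [rng.standard_normal(700) for _ in range(12)]
        null = permutation_null(fmri, eeg, max_lag=5, n_perm=1000, seed=1)
        assert np.abs(null.draws.mean(axis=0)).max() < 0.01

    def test_three_scan_derangements_enumerated(self):
        # For 3 scans only two derangements exist: (1,2,0) and (2,0,1).
        # Brute-force enumeration oracle: every draw's mean curve must
        # equal one of the two explicitly computed pairings.
        rng = np.random.default_rng(3)
        fmri = [rng.standard_normal(100) for _ in range(3)]
        eeg = [rng.standard_normal(100) for _ in range(3)]
        null = permutation_null(fmri, eeg, max_lag=3, n_perm=50, seed=9)
        expected = []
        for perm in ([1, 2, 0], [2, 0, 1]):
            curves = [cross_correlate(fmri[i], eeg[perm[i]], 3).values
                      for i in range(3)]
            expected.append(np.mean(curves, axis=0))
        for draw in null.draws:
            assert any(np.allclose(draw, e, atol=1e-12) for e in expected)

    def test_seed_determinism(self, rng):
        fmri = [rng.standard_normal(100) for _ in range(4)]
        eeg = [rng.standard_normal(100) for _ in range(4)]
        a = permutation_null(fmri, eeg, 3, n_perm=20, seed=5)
        b = permutation_null(fmri, eeg, 3, n_perm=20, seed=5)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_too_few_scans_rejected(self, rng):
        xs = [rng.standard_normal(50) for _ in range(2)]
        with pytest.raises(ValueError):
            permutation_null(xs, xs, 3)


class TestEvaluateSplit:
    def test_leakage_guard_is_structural(self):
        with pytest.raises(ValueError, match="leakage"):
            SplitPlan(frozenset({"a", "b"}), frozenset({"b", "c"}))

    def test_rest_to_task_beats_null(self, small_cohort):
        scans = {w.scan.scan_id: w.scan
                 for w in small_cohort.rest + small_cohort.task}
        indices = {w.scan.scan_id: world_eeg_index(w)
                   for w in small_cohort.rest + small_cohort.task}
        plan = SplitPlan(frozenset(w.scan.scan_id for w in small_cohort.rest),
                         frozenset(w.scan.scan_id for w in small_cohort.task))
        curves, null, _ = evaluate_split(scans, indices, plan, max_lag=8,
                                         n_perm=200, seed=0)
        mean_peak = np.mean([c.values for c in curves.values()],
                            axis=0).max()
        assert mean_peak > null.peak_percentile(95.0)

    def test_task_to_rest_direction_also_beats_null(self, small_cohort):
        scans = {w.scan.scan_id: w.scan
                 for w in small_cohort.rest + small_cohort.task}
        indices = {w.scan.scan_id: world_eeg_index(w)
                   for w in small_cohort.rest + small_cohort.task}
        plan = SplitPlan(frozenset(w.scan.scan_id for w in small_cohort.task),
                         frozenset(w.scan.scan_id for w in small_cohort.rest),
                         direction="task_to_rest")
        curves, null, _ = evaluate_split(scans, indices, plan, max_lag=8,
                                         n_perm=200, seed=0)
        mean_peak = np.mean([c.values for c in curves.values()],
                            axis=0).max()
        assert mean_peak > null.peak_percentile(95.0)


class TestTemplateVigilanceDecoder:
    def test_sklearn_params_and_clone(self):
        dec = TemplateVigilanceDecoder(threshold_fraction=0.1,
                                       threshold_mode="positive")
        params = dec.get_params()
        assert params["threshold_fraction"] == 0.1
        dec2 = clone(dec)
        assert dec2.get_params() == params

    def test_fit_predict_shapes(self, small_cohort):
        dec = TemplateVigilanceDecoder()
        dec.fit([w.scan for w in small_cohort.rest],
                [world_eeg_index(w) for w in small_cohort.rest])
        assert dec.n_scans_ == 4
        pred = dec.predict(small_cohort.task[0].scan)
        assert pred.kind == "fmri"
        assert len(pred) == small_cohort.task[0].scan.n_volumes

    def test_unfitted_predict_raises(self, tiny_world):
        with pytest.raises(AttributeError):
            TemplateVigilanceDecoder().predict(tiny_world.scan)
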