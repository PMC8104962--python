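"""Event-locked segmentation, trial classification and statistics."""

import numpy as np
import pandas as pd
import pytest

from fmralert.behavior import (
    anova_tukey,
    classify_trials,
    extract_segments,
    interpolate_index,
    interval_mean,
    paired_test,
    paired_values,
    two_sample_test,
)
from fmralert.datatypes import AlertnessIndex, TrialTable


def _index(values, tr=2.1, kind="raw_eeg"):
    return AlertnessIndex(np.asarray(values, float), tr, kind)


def _trials(onsets, rt_ms, scan_id="s0"):
    rt = np.asarray(rt_ms, float)
    return TrialTable(onsets=np.asarray(onsets, float),
                      responded=np.isfinite(rt), rt=rt, scan_id=scan_id)


class TestInterpolateIndex:
    def test_fine_grid_spacing_is_084s(self):
        out = interpolate_index(_index(np.arange(10.0)), 2.5)
        assert out.tr == pytest.approx(0.84)

    def test_constant_input_stays_constant(self):
        out = interpolate_index(_index(np.full(20, 3.3)), 2.5)
        np.testing.assert_allclose(out.values, 3.3)

    def test_linear_ramp_reproduced_exactly(self):
        ramp = np.arange(50.0) * 0.7 - 3.0
        out = interpolate_index(_index(ramp), 2.5)
        t_fine = np.arange(len(out)) * out.tr
        np.testing.assert_allclose(out.values, t_fine / 2.1 * 0.7 - 3.0,
                                   atol=1e-12)

    def test_factor_at_most_one_rejected(self):
        with pytest.raises(ValueError):
            interpolate_index(_index(np.arange(5.0)), 1.0)


class TestExtractSegments:
    def _fine(self, n=1750):
        # 0.84 s grid covering ~1470 s
        return AlertnessIndex(np.arange(n, dtype=float), 0.84, "raw_eeg")

    def _classified(self, onsets, rt):
        trials = _trials(onsets, rt)
        return classify_trials(trials, "pooled_median",
                               pooled_rt=[500.0, 600.0])

    def test_window_covering_rule_row_length(self):
        # floor(-5/0.84)=-6 .. ceil(10/0.84)=12 -> 19 grid points covering
        # the closed [-5, 10] s window.
        segs = extract_segments(self._fine(), self._classified([100.0], [400.0]))
        assert segs.matrix.shape == (1, 19)
        assert segs.offsets[0] <= -5.0 <= segs.offsets[1]
        assert segs.offsets[-2] <= 10.0 <= segs.offsets[-1]

    def test_boundary_trial_dropped(self):
        segs = extract_segments(self._fine(),
                                self._classified([2.0, 100.0], [400.0, 700.0]))
        assert segs.n_trials == 1

    def test_values_are_exact_fine_grid_samples(self):
        fine = self._fine()
        segs = extract_segments(fine, self._classified([100.0], [400.0]))
        # direct-indexing oracle: nearest grid sample for each offset
        ks = np.arange(-6, 13)
        expected = fine.values[np.round(100.0 / 0.84).astype(int) + ks]
        np.testing.assert_array_equal(segs.matrix[0], expected)

    def test_unclassified_trials_rejected(self):
        with pytest.raises(ValueError):
            extract_segments(self._fine(), _trials([100.0], [400.0]))


class TestClassifyTrials:
    def test_pooled_median_565_fast(self):
        out = classify_trials(_trials([10.0], [400.0]), "pooled_median",
                              pooled_rt=np.array([565.0, 500.0, 630.0]))
        assert out.labels[0] == "fast_hit"

    def test_response_slower_than_5s_is_miss(self):
        out = classify_trials(_trials([10.0, 20.0], [6000.0, 400.0]),
                              "pooled_median", pooled_rt=[500.0])
        assert out.labels[0] == "miss"

    def test_pooled_median_splits_310_hits_155_155(self, rng):
        rt = rng.uniform(200, 1500, 310)
        assert np.unique(rt).size == 310
        onsets = np.arange(310) * 10.0
        out = classify_trials(_trials(onsets, rt), "pooled_median",
                              pooled_rt=rt)
        labels = pd.Series(out.labels).value_counts()
        assert labels["fast_hit"] == 155
        assert labels["slow_hit"] == 155

    def test_tie_at_threshold_goes_slow(self):
        out = classify_trials(_trials([1.0], [565.0]), "pooled_median",
                              pooled_rt=[565.0])
        assert out.labels[0] == "slow_hit"

    def test_label_partition_and_count_conservation(self, rng):
        n = 200
        rt = np.where(rng.uniform(size=n) < 0.2, np.nan,
                      rng.uniform(200, 6000, n))
        out = classify_trials(_trials(np.arange(n) * 8.0, rt),
                              "pooled_median",
                              pooled_rt=rt[np.isfinite(rt) & (rt < 5000)])
        counts = pd.Series(out.labels).value_counts()
        assert set(counts.index) <= {"fast_hit", "slow_hit", "miss"}
        assert counts.sum() == n

    def test_subject_decile_mode(self, rng):
        rt = rng.uniform(300, 900, 50)
        out = classify_trials(_trials(np.arange(50) * 8.0, rt),
                              "subject_decile")
        labels = pd.Series(out.labels).value_counts()
        assert labels["fast_hit"] == 5
        assert labels["slow_hit"] == 5
        assert labels["hit"] == 40


class TestIntervalMean:
    def _segments(self, matrices, labels, scan_ids):
        from fmralert.datatypes import TrialSegments
        offsets = np.arange(-6, 13) * 0.84
        return TrialSegments(matrix=np.asarray(matrices, float),
                             offsets=offsets,
                             trial_labels=np.asarray(labels, dtype=object),
                             scan_ids=np.asarray(scan_ids, dtype=object))

    def test_constant_segments_give_constant_means(self):
        segs = self._segments([np.full(19, 2.5)] * 3,
                              ["fast_hit", "slow_hit", "miss"],
                              ["s0", "s0", "s0"])
        means = interval_mean(segs, (-5.0, 0.0))
        assert np.allclose(means["value"], 2.5)

    def test_single_trial_direct_sum_oracle(self, rng):
        row = rng.standard_normal(19)
        segs = self._segments([row], ["miss"], ["s0"])
        means = interval_mean(segs, (-5.0, 0.0))
        offsets = segs.offsets
        sel = (offsets >= -5.0) & (offsets <= 0.0)
        assert means["value"].iloc[0] == pytest.approx(
            row[sel].sum() / sel.sum(), abs=1e-12)

    def test_scan_without_misses_absent_from_paired_contrast(self, rng):
        rows = [rng.standard_normal(19) for _ in range(3)]
        segs = self._segments(rows, ["fast_hit", "miss", "fast_hit"],
                              ["s0", "s0", "s1"])
        means = interval_mean(segs, (-5.0, 0.0))
        a, b = paired_values(means, "fast_hit", "miss")
        assert a.size == 1  # only s0 has both classes


class TestPairedTest:
    def test_identical_samples_null(self):
        res = paired_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p == 1.0
        assert res.effect_size == 0.0

    def test_zero_variance_difference_degenerate(self):
        res = paired_test([5.0, 6.0, 7.0], [4.0, 5.0, 6.0])
        assert np.isinf(res.statistic)
        assert res.p == 0.0
        assert res.degenerate

    def test_matches_textbook_formula(self, rng):
        a = rng.standard_normal(10)
        b = rng.standard_normal(10)
        res = paired_test(a, b)
        d = a - b
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(10))
        from scipy.stats import t as t_dist
        p_manual = 2 * t_dist.sf(abs(t_manual), 9)
        assert res.statistic == pytest.approx(t_manual, abs=1e-10)
        assert res.p == pytest.approx(p_manual, abs=1e-10)
        assert res.df == 9
        assert res.effect_size == pytest.approx(d.mean() / d.std(ddof=1),
                                                abs=1e-12)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            paired_test([1.0], [2.0])


class TestAnovaTukey:
    def test_identical_groups_give_zero_f(self):
        res = anova_tukey([[1.0, 2, 3], [1.0, 2, 3], [1.0, 2, 3]])
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_worked_example_matches_mean_square_formula(self, rng):
        groups = [rng.standard_normal(4) + m for m in (0.0, 0.5, 1.0)]
        res = anova_tukey(groups)
        grand = np.concatenate(groups).mean()
        ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_manual = (ss_between / 2) / (ss_within / 9)
        assert res.statistic == pytest.approx(f_manual, abs=1e-10)
        assert res.df == (2, 9)
        assert res.posthoc is not None and len(res.posthoc) == 3

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey([[1.0, 2.0], [3.0], [4.0, 5.0]])


class TestTwoSampleTest:
    def test_matches_scipy_and_reports_pooled_d(self, rng):
        a = rng.standard_normal(12) + 1.0
        b = rng.standard_normal(9)
        res = two_sample_test(a, b)
        from scipy.stats import ttest_ind
        t, p = ttest_ind(a, b)
        assert res.statistic == pytest.approx(t)
        assert res.p == pytest.approx(p)
        assert res.df == 19
        assert res.effect_size > 0
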