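"""Generator-level checks: determinism, coupling structure, constraints."""

import numpy as np
import pytest

from fmralert.eeg import compute_alpha_theta_ratio
from fmralert.synthetic import (
    generate_latent_arousal,
    make_task_weights,
    make_true_template,
    make_world,
    synthesize_behavior,
    synthesize_eeg,
    synthesize_fmri,
    synthesize_physio,
)
from fmralert.template import voxelwise_correlation
from fmralert.hrf import default_hrf


class TestLatentArousal:
    def test_zero_amplitude_gives_all_zero_series(self):
        lat = generate_latent_arousal(700, 2.1, 0.02, amplitude=0.0, seed=3)
        assert np.all(lat.values == 0.0)

    def test_seed_determinism(self):
        a = generate_latent_arousal(700, 2.1, 0.02, seed=7)
        b = generate_latent_arousal(700, 2.1, 0.02, seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_slow_process_has_high_lag1_autocorrelation(self):
        # Monte-Carlo oracle: average empirical lag-1 autocorrelation over
        # many seeds; a 0.02 Hz process sampled at TR 2.1 s is very smooth.
        acs = []
        for seed in range(100):
            x = generate_latent_arousal(700, 2.1, 0.02, seed=seed).values
            acs.append(np.corrcoef(x[:-1], x[1:])[0, 1])
        assert np.mean(acs) > 0.9

    def test_standardized_to_unit_variance(self):
        x = generate_latent_arousal(500, 2.1, 0.02, seed=0).values
        assert abs(x.mean()) < 1e-12
        assert abs(x.std() - 1.0) < 1e-12

    @pytest.mark.parametrize("cutoff", [0.0, 0.25, 0.5])
    def test_cutoff_outside_open_nyquist_interval_rejected(self, cutoff):
        with pytest.raises(ValueError):
            generate_latent_arousal(100, 2.1, cutoff)

    def test_too_few_volumes_rejected(self):
        with pytest.raises(ValueError):
            generate_latent_arousal(4, 2.1, 0.02)


class TestSynthesizeEEG:
    def test_duration_arithmetic(self, latent):
        eeg = synthesize_eeg(latent, fs=250.0, seed=0)
        assert eeg.samples.shape[1] == int(round(200 * 2.1 * 250))

    def test_full_scan_sample_count(self):
        lat = generate_latent_arousal(700, 2.1, 0.02, seed=0)
        eeg = synthesize_eeg(lat, fs=250.0, seed=0)
        assert eeg.samples.shape[1] == 367500

    def test_constant_latent_noiseless_ratio_is_stationary(self):
        from fmralert.datatypes import LatentArousal
        lat = LatentArousal(values=np.full(60, 0.4), tr=2.1)
        eeg = synthesize_eeg(lat, fs=125.0, noise_sd=0.0, seed=1)
        ratio = compute_alpha_theta_ratio(eeg, 2.1, 60).values
        # Spectral leakage varies slightly with window phase; the ratio
        # must still be essentially constant across TRs.
        assert ratio.std() / ratio.mean() < 0.02

    def test_strong_coupling_log_ratio_tracks_latent(self, latent):
        # Downstream index operation as oracle.
        eeg = synthesize_eeg(latent, fs=125.0, alpha_gain=0.5,
                             theta_gain=0.5, noise_sd=0.0, seed=2)
        log_ratio = compute_alpha_theta_ratio(eeg, 2.1, 200, log=True).values
        r = np.corrcoef(log_ratio, latent.values)[0, 1]
        assert r > 0.8

    def test_negative_gain_rejected(self, latent):
        with pytest.raises(ValueError):
            synthesize_eeg(latent, alpha_gain=-0.1)

    def test_low_sampling_rate_rejected(self, latent):
        with pytest.raises(ValueError):
            synthesize_eeg(latent, fs=40.0)


class TestSynthesizeFMRI:
    def test_noiseless_single_voxel_equals_scaled_hemodynamic_latent(self, latent):
        tpl = np.zeros((4, 4, 3))
        tpl[1, 2, 1] = 2.0
        scan = synthesize_fmri(latent, tpl, noise_sd=0.0, drift_order=0, seed=0)
        kernel = default_hrf().kernel(2.1)
        expected = np.convolve(latent.values, kernel)[:200]
        expected = 2.0 * expected / expected.std()
        np.testing.assert_allclose(scan.data[1, 2, 1], expected, atol=1e-10)

    def test_sign_recovery_at_unit_snr(self):
        # voxelwise_correlation as oracle, over 20 seeds.
        weights, mask = make_true_template((10, 10, 8))
        kernel = default_hrf().kernel(2.1)
        rates = []
        for seed in range(20):
            lat = generate_latent_arousal(200, 2.1, 0.02, seed=seed)
            scan = synthesize_fmri(lat, weights, noise_sd=1.0, seed=seed,
                                   mask=mask)
            hemo = np.convolve(lat.values, kernel)[:200]
            from fmralert.datatypes import AlertnessIndex
            idx = AlertnessIndex(hemo - hemo.mean(), 2.1, "hemodynamic_eeg")
            cmap = voxelwise_correlation(scan, idx)
            nz = weights != 0
            rates.append(np.mean(np.sign(cmap.values[nz]) == np.sign(weights[nz])))
        assert np.mean(rates) > 0.95

    def test_seed_determinism(self, latent, small_template):
        weights, mask = small_template
        a = synthesize_fmri(latent, weights, seed=9, mask=mask)
        b = synthesize_fmri(latent, weights, seed=9, mask=mask)
        np.testing.assert_array_equal(a.data, b.data)

    def test_grid_mismatch_rejected(self, latent):
        with pytest.raises(ValueError, match="grid mismatch"):
            synthesize_fmri(latent, np.ones((4, 4, 3)),
                            mask=np.ones((5, 5, 3), dtype=bool))

    def test_explosive_ar_rejected(self, latent, small_template):
        weights, mask = small_template
        with pytest.raises(ValueError):
            synthesize_fmri(latent, weights, ar_coeff=1.0, mask=mask)


class TestSynthesizeBehavior:
    def test_uncoupled_null_has_no_latent_miss_association(self):
        pre_all, miss_all = [], []
        seed = 0
        while len(pre_all) < 10000:
            lat = generate_latent_arousal(700, 2.1, 0.02, seed=seed)
            trials = synthesize_behavior(lat, miss_slope=0.0, rt_slope=0.0,
                                         isi_range=(4.0, 8.0), seed=seed)
            grid = np.arange(700) * 2.1
            for onset, resp in zip(trials.onsets, trials.responded):
                sel = (grid >= onset - 5) & (grid <= onset)
                pre_all.append(lat.values[sel].mean())
                miss_all.append(0.0 if resp else 1.0)
            seed += 1
        r = np.corrcoef(pre_all, miss_all)[0, 1]
        assert abs(r) < 0.1

    def test_fast_half_trials_have_higher_prestimulus_latent(self):
        wins = 0
        for seed in range(100):
            lat = generate_latent_arousal(200, 2.1, 0.02, seed=seed)
            trials = synthesize_behavior(lat, rt_slope=100.0, miss_slope=0.0,
                                         isi_range=(6.0, 12.0), seed=seed + 1)
            hits = trials.responded & np.isfinite(trials.rt)
            if hits.sum() < 4:
                continue
            grid = np.arange(200) * 2.1
            pre = np.array([lat.values[(grid >= o - 5) & (grid <= o)].mean()
                            for o in trials.onsets[hits]])
            rt = trials.rt[hits]
            median = np.median(rt)
            fast, slow = pre[rt < median], pre[rt >= median]
            if fast.size and slow.size:
                wins += fast.mean() > slow.mean()
        assert wins >= 95

    def test_isi_constraint(self, latent):
        trials = synthesize_behavior(latent, isi_range=(10.0, 20.0), seed=3)
        gaps = np.diff(trials.onsets)
        assert np.all((gaps >= 10.0) & (gaps <= 20.0))

    def test_invalid_isi_range_rejected(self, latent):
        with pytest.raises(ValueError):
            synthesize_behavior(latent, isi_range=(20.0, 10.0))

    def test_miss_rate_increases_with_coupling_slope(self):
        # Coupling monotonicity over a 3-point slope grid, 100 seeds.
        rates = []
        for slope in (0.0, 1.5, 3.0):
            misses = total = 0
            for seed in range(100):
                lat = generate_latent_arousal(100, 2.1, 0.02, seed=seed,
                                              amplitude=1.0)
                tr = synthesize_behavior(lat, miss_slope=slope,
                                         miss_intercept=-1.2,
                                         isi_range=(5.0, 10.0), seed=seed)
                misses += (~tr.responded).sum()
                total += len(tr)
            rates.append(misses / total)
        # With a negative intercept, widening the slope strictly raises the
        # marginal miss rate (scale-mixture argument).
        assert rates[0] < rates[1] < rates[2]


class TestSynthesizePhysio:
    def test_unmodulated_heart_rate_is_constant(self, latent):
        from fmralert.physio import compute_hr
        physio = synthesize_physio(latent, hr_slope=0.0, resp_amp_slope=0.0,
                                   ppg_noise_sd=0.0, seed=0)
        hr = compute_hr(physio.ppg, physio.fs_ppg, 2.1, 200)
        assert hr.std() < 0.5

    def test_respiratory_variation_tracks_latent(self, latent):
        from fmralert.physio import compute_rv
        physio = synthesize_physio(latent, resp_amp_slope=0.5,
                                   resp_noise_sd=0.0, seed=0)
        rv = compute_rv(physio.resp, physio.fs_resp, 2.1, 200)
        r = np.corrcoef(rv, latent.values)[0, 1]
        assert r > 0.7

    def test_seed_determinism(self, latent):
        a = synthesize_physio(latent, seed=4)
        b = synthesize_physio(latent, seed=4)
        np.testing.assert_array_equal(a.resp, b.resp)
        np.testing.assert_array_equal(a.ppg, b.ppg)

    def test_nonpositive_heart_rate_rejected(self, latent):
        with pytest.raises(ValueError):
            synthesize_physio(latent, base_hr=0.0)


class TestWorldAssembly:
    def test_full_world_regeneration_is_exact(self):
        kw = dict(n_volumes=100, shape=(8, 8, 6), eeg_fs=125.0,
                  with_physio=True, seed=11)
        a, b = make_world(**kw), make_world(**kw)
        np.testing.assert_array_equal(a.latent.values, b.latent.values)
        np.testing.assert_array_equal(a.eeg.samples, b.eeg.samples)
        np.testing.assert_array_equal(a.scan.data, b.scan.data)
        np.testing.assert_array_equal(a.trials.onsets, b.trials.onsets)
        np.testing.assert_array_equal(a.trials.rt, b.trials.rt)
        np.testing.assert_array_equal(a.physio.ppg, b.physio.ppg)
        assert a.params == b.params

    def test_template_geometry_sign_structure(self):
        weights, mask = make_true_template()
        assert (weights < 0).sum() > 3 * (weights > 0).sum() > 0
        assert not weights[~mask].any()

    def test_task_voxels_lie_in_negative_shell(self):
        weights, _ = make_true_template()
        task = make_task_weights()
        assert task.any()
        assert np.all(weights[task != 0] < 0)
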