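"""Spectral pipeline: referencing, epochs, TFR, masking rules, window stats."""

import numpy as np
import pandas as pd
import pytest

import kinestim as ks
from kinestim.ecog_beta import (
    EpochsTFR,
    baseline_zscore,
    beta_window_stats,
    common_average_reference,
    epoch_around_events,
    interpolate_for_plot,
    mask_stim_artifacts,
    match_speed_sample,
    median_fill_for_cluster,
    morlet_tfr,
)

FS = 250.0
SPEC = ks.EpochSpec(sample_rate=FS)


class TestReferencing:
    def test_identical_channels_reference_to_zero(self):
        out = common_average_reference(np.ones((2, 50)))
        assert np.allclose(out, 0.0)

    def test_constant_channels_one_and_three(self):
        out = common_average_reference(
            np.vstack([np.ones(10), 3 * np.ones(10)])
        )
        assert np.allclose(out[0], -1.0)
        assert np.allclose(out[1], 1.0)

    def test_referenced_channels_sum_to_zero(self):
        rng = np.random.default_rng(0)
        out = common_average_reference(rng.normal(size=(6, 100)), exclude={5})
        assert out.shape == (5, 100)
        assert np.allclose(out.sum(axis=0), 0.0, atol=1e-12)

    def test_all_excluded_rejected(self):
        with pytest.raises(ValueError):
            common_average_reference(np.ones((3, 10)), exclude={0, 1, 2})


class TestEpoching:
    def test_two_second_window_around_event(self):
        sig = np.arange(10 * int(FS), dtype=float)
        epochs, times, kept = epoch_around_events(sig, FS, [5.0], SPEC)
        assert epochs.shape == (1, int(2 * FS) + 1)
        assert times[0] == pytest.approx(-1.0)
        assert times[-1] == pytest.approx(1.0)
        assert epochs[0, 0] == pytest.approx(4.0 * FS)

    def test_edge_events_dropped_with_warning(self):
        sig = np.zeros(int(3 * FS))
        with pytest.warns(UserWarning, match="dropped 1"):
            _, _, kept = epoch_around_events(sig, FS, [0.5, 1.5], SPEC)
        assert list(kept) == [1]

    def test_no_valid_events_rejected(self):
        with pytest.raises(ValueError):
            epoch_around_events(np.zeros(100), FS, [0.01], SPEC)


class TestMorletTFR:
    def test_zero_signal_gives_zero_power(self):
        tfr = morlet_tfr(np.zeros((2, 501)), FS, [10.0, 25.0])
        assert np.nanmax(tfr.power) == 0.0

    def test_frequency_selectivity_for_pure_25hz(self):
        t = np.arange(int(2 * FS) + 1) / FS
        sig = np.sin(2 * np.pi * 25.0 * t)
        tfr = morlet_tfr(sig[None, :], FS, [10.0, 25.0, 60.0])
        mid = sig.size // 2
        p10, p25, p60 = tfr.power[0, :, mid]
        assert p25 > 10 * p10
        assert p25 > 10 * p60

    def test_amplitude_doubling_quadruples_power(self):
        t = np.arange(int(2 * FS) + 1) / FS
        sig = np.sin(2 * np.pi * 25.0 * t)
        tfr1 = morlet_tfr(sig[None, :], FS, [25.0])
        tfr2 = morlet_tfr(2 * sig[None, :], FS, [25.0])
        mid = sig.size // 2
        assert tfr2.power[0, 0, mid] == pytest.approx(4 * tfr1.power[0, 0, mid])

    def test_wavelet_edges_masked(self):
        tfr = morlet_tfr(np.random.default_rng(1).normal(size=(1, 501)), FS, [20.0])
        assert tfr.mask[0, 0, 0]
        assert tfr.mask[0, 0, -1]
        assert not tfr.mask[0, 0, 250]

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            morlet_tfr(np.zeros((1, 100)), FS, [200.0])

    def test_agrees_with_mne_reference_implementation(self):
        """Independent oracle: same band-limited signal through MNE."""
        mne = pytest.importorskip("mne")
        rng = np.random.default_rng(2)
        epochs = rng.normal(size=(3, 601))
        freqs = np.array([15.0, 25.0, 35.0])
        ours = morlet_tfr(epochs, FS, freqs)
        theirs = mne.time_frequency.tfr_array_morlet(
            epochs[:, None, :], FS, freqs, n_cycles=4.0, output="power", zero_mean=False
        )[:, 0]
        sel = ~ours.mask
        r = np.corrcoef(ours.power[sel], theirs[sel])[0, 1]
        assert r > 0.99


class TestBaselineZscore:
    def _tfr_with_step(self, step=2.0):
        rng = np.random.default_rng(3)
        n_t = int(2 * FS) + 1
        power = rng.normal(10.0, 1.0, size=(4, 2, n_t))
        times = np.linspace(-1, 1, n_t)
        power[:, :, times > 0.4] += step  # +2 baseline-SD injected step
        mask = np.zeros_like(power, dtype=bool)
        return EpochsTFR(power=power, mask=mask, times=times, freqs=np.array([20.0, 30.0]))

    def test_baseline_window_has_mean_zero_sd_one(self):
        z = baseline_zscore(self._tfr_with_step())
        sel = (z.times >= -0.4) & (z.times <= -0.1)
        base = z.power[:, :, sel]
        np.testing.assert_allclose(base.mean(axis=2), 0.0, atol=1e-9)
        np.testing.assert_allclose(base.std(axis=2), 1.0, atol=1e-9)

    def test_injected_step_recovered_in_baseline_sd_units(self):
        z = baseline_zscore(self._tfr_with_step(step=2.0))
        late = z.power[:, :, z.times > 0.45]
        assert np.nanmean(late) == pytest.approx(2.0, abs=0.35)

    def test_zero_variability_trial_is_masked(self):
        tfr = self._tfr_with_step()
        tfr.power[0, 0, :] = 5.0  # constant power row
        z = baseline_zscore(tfr)
        assert z.mask[0, 0].all()
        assert np.isnan(z.power[0, 0]).all()


class TestSpeedMatching:
    def test_greedy_trace_of_the_worked_example(self):
        idx = match_speed_sample([10.0, 20.0], [9.0, 11.0, 19.0, 30.0], seed=0)
        chosen = sorted(np.array([9.0, 11.0, 19.0, 30.0])[idx])
        assert chosen in ([9.0, 19.0], [11.0, 19.0])

    def test_identical_distributions_match_immediately(self):
        rng = np.random.default_rng(4)
        stim = rng.normal(1000, 100, 30)
        pool = rng.normal(1000, 100, 60)
        idx = match_speed_sample(stim, pool, seed=1)
        assert len(idx) == 30
        assert len(set(idx)) == 30  # without replacement

    def test_small_pool_rejected(self):
        with pytest.raises(ValueError):
            match_speed_sample([1.0, 2.0, 3.0], [1.0, 2.0])

    def test_hopeless_pool_raises_matching_failure(self):
        with pytest.raises(RuntimeError, match="matching failed"):
            match_speed_sample(
                np.full(20, 1000.0), np.full(25, 5000.0), seed=2, max_retries=2
            )


def _flat_tfr(n_trials=10, n_t=None):
    n_t = n_t or int(2 * FS) + 1
    times = np.linspace(-1, 1, n_t)
    power = np.zeros((n_trials, 3, n_t))
    mask = np.zeros_like(power, dtype=bool)
    return EpochsTFR(
        power=power, mask=mask, times=times, freqs=np.array([20.0, 25.0, 30.0])
    )


class TestArtifactMasking:
    def test_65ms_window_around_each_edge(self):
        tfr = _flat_tfr(n_trials=1)
        events = pd.DataFrame(
            {"time_s": [0.0], "stimulated": [True], "stim_on_s": [0.10], "stim_off_s": [0.40]}
        )
        out = mask_stim_artifacts(tfr, events)
        on_masked = out.mask[0, 0, (tfr.times >= 0.036) & (tfr.times <= 0.164)]
        assert on_masked.all()
        assert not out.mask[0, 0, np.abs(tfr.times - 0.25) < 0.01].any()
        off_masked = out.mask[0, 0, (tfr.times >= 0.336) & (tfr.times <= 0.464)]
        assert off_masked.all()

    def test_no_stimulated_trials_is_identity(self):
        tfr = _flat_tfr(n_trials=3)
        events = pd.DataFrame(
            {"time_s": [0.0] * 3, "stimulated": [False] * 3,
             "stim_on_s": [np.nan] * 3, "stim_off_s": [np.nan] * 3}
        )
        out = mask_stim_artifacts(tfr, events)
        assert not out.mask.any()

    def test_edge_outside_epoch_warned_and_ignored(self):
        tfr = _flat_tfr(n_trials=1)
        events = pd.DataFrame(
            {"time_s": [0.0], "stimulated": [True], "stim_on_s": [0.10], "stim_off_s": [5.0]}
        )
        with pytest.warns(UserWarning, match="outside the epoch"):
            out = mask_stim_artifacts(tfr, events)
        assert out.mask[0].any()

    def test_masked_sample_count_bookkeeping(self):
        tfr = _flat_tfr(n_trials=1)
        events = pd.DataFrame(
            {"time_s": [0.0], "stimulated": [True], "stim_on_s": [0.10], "stim_off_s": [0.40]}
        )
        out = mask_stim_artifacts(tfr, events)
        per_edge = int(out.mask[0, 0].sum())
        # two edges x (2 x 0.065 s) x sample rate, within one sample each
        expected = 2 * (2 * 0.065 * FS)
        assert abs(per_edge - expected) <= 4


class TestMedianFillRule:
    def _masked_fraction_tfr(self, n_masked, n_trials=50):
        tfr = _flat_tfr(n_trials=n_trials, n_t=21)
        tfr.power += np.arange(n_trials)[:, None, None]  # distinct values
        tfr.mask[:n_masked, :, 10] = True
        tfr.power[tfr.mask] = np.nan
        return tfr

    def test_fourteen_percent_is_median_replaced(self):
        tfr = self._masked_fraction_tfr(7)  # 7/50 = 14%
        filled, valid = median_fill_for_cluster(tfr)
        assert valid[0, 10]
        med = np.median(np.arange(7, 50))
        assert np.allclose(filled[:7, 0, 10], med)

    def test_sixteen_percent_is_excluded(self):
        tfr = self._masked_fraction_tfr(8)  # 8/50 = 16%
        _, valid = median_fill_for_cluster(tfr)
        assert not valid[0, 10]

    def test_interpolation_is_for_plots_only_and_fills_gaps(self):
        tfr = self._masked_fraction_tfr(7)
        interp = interpolate_for_plot(tfr)
        assert np.isfinite(interp[:7, 0, 10]).all()
        # the statistics path still sees NaN at the masked samples
        assert np.isnan(tfr.power[:7, 0, 10]).all()


class TestWindowStats:
    def test_identical_groups_are_nonsignificant(self):
        rng = np.random.default_rng(5)
        tfr = _flat_tfr(n_trials=30, n_t=201)
        tfr.power = rng.normal(size=tfr.power.shape)
        stim = np.arange(30) < 15
        res = beta_window_stats(tfr, stim, SPEC, n_perm=500, cluster_n_perm=100, seed=6)
        assert res.stim_window_test.p_value > 0.05
        assert res.post_window_test.p_value > 0.05

    def test_injected_window_effects_detected_with_signs(self):
        rng = np.random.default_rng(7)
        tfr = _flat_tfr(n_trials=40, n_t=401)
        tfr.power = rng.normal(size=tfr.power.shape)
        stim = np.arange(40) < 20
        in_stim_win = (tfr.times >= 0.13) & (tfr.times <= 0.30)
        in_post_win = (tfr.times >= 0.41) & (tfr.times <= 1.00)
        tfr.power[np.ix_(stim, [True] * 3, in_stim_win)] -= 1.5
        tfr.power[np.ix_(stim, [True] * 3, in_post_win)] += 1.0
        res = beta_window_stats(tfr, stim, SPEC, n_perm=500, cluster_n_perm=200, seed=8)
        assert res.stim_window_test.statistic < 0
        assert res.stim_window_test.p_value < 0.05
        assert res.post_window_test.statistic > 0
        assert res.post_window_test.p_value < 0.05
        signs = {c["sign"] for c in res.cluster.significant()}
        assert {1, -1} <= signs

    def test_fully_masked_window_makes_trial_missing(self):
        tfr = _flat_tfr(n_trials=4, n_t=201)
        in_stim_win = (tfr.times >= 0.13) & (tfr.times <= 0.30)
        tfr.mask[0][:, in_stim_win] = True
        tfr.power[tfr.mask] = np.nan
        from kinestim.ecog_beta import _window_trial_means

        means = _window_trial_means(tfr, (20.0, 35.0), (0.13, 0.30))
        assert np.isnan(means[0])
        assert np.isfinite(means[1:]).all()
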