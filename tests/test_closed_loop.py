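"""Controller emulation: speed smoothing, peak detection, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import kinestim as ks
from kinestim.closed_loop import (
    calibrate_peak_time_percentile,
    classify_speed,
    compute_online_speed,
    detect_peak_three_decreasing,
    evaluate_controller,
    run_closed_loop_session,
)


def _trace(x, y=None, fs=62.0):
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    return pd.DataFrame(
        {
            "time_s": np.arange(x.size) / fs,
            "x_px": x,
            "y_px": y,
            "trial_index": np.zeros(x.size, dtype=int),
        }
    )


class TestOnlineSpeed:
    def test_constant_position_gives_zero_speed(self):
        sp = compute_online_speed(_trace(np.full(20, 5.0)))
        assert np.allclose(sp, 0.0)

    def test_ten_pixels_per_sample_at_62hz(self):
        # 10 px x 62 Hz = 620 px/s, steady state of the 6-sample mean
        sp = compute_online_speed(_trace(10.0 * np.arange(20)))
        assert np.allclose(sp, 620.0)

    def test_diagonal_step_uses_euclidean_norm(self):
        # one (3, 4) px step in 1/62 s -> 5 px x 62 Hz = 310 px/s
        sp = compute_online_speed(_trace([0, 3], [0, 4]))
        assert sp[0] == pytest.approx(310.0)

    def test_head_averages_over_available_samples(self):
        inst = np.array([62.0, 124.0])  # 1 px then 2 px steps
        sp = compute_online_speed(_trace([0, 1, 3]))
        assert sp[0] == pytest.approx(inst[0])
        assert sp[1] == pytest.approx(inst.mean())

    def test_duplicate_timestamps_rejected(self):
        tr = _trace([0, 1, 2])
        tr.loc[1, "time_s"] = tr.loc[0, "time_s"]
        with pytest.raises(ValueError, match="strictly increasing"):
            compute_online_speed(tr)


class TestPeakDetector:
    def test_fires_after_three_decreasing_values(self):
        det = detect_peak_three_decreasing([1, 3, 5, 4, 3, 2])
        assert det == (5, 5.0)

    def test_monotone_rise_never_fires(self):
        assert detect_peak_three_decreasing([1, 2, 3, 4, 5, 6]) is None

    def test_tie_resets_the_decreasing_run(self):
        # 5->4 counts, the 4->4 tie resets, then 4->3->2->1 completes the run
        det = detect_peak_three_decreasing([1, 3, 5, 4, 4, 3, 2, 1])
        assert det == (7, 5.0)

    def test_fires_at_most_once_and_reports_running_max(self):
        det = detect_peak_three_decreasing([9, 8, 7, 6, 10, 9, 8, 7])
        assert det == (3, 9.0)

    def test_arm_threshold_ignores_low_speed_noise(self):
        # dwell wiggles below the arm threshold must not fire the rule
        seg = [30, 20, 10, 5, 900, 1500, 900, 700, 500]
        det = detect_peak_three_decreasing(seg, arm_threshold=800.0)
        assert det == (8, 1500.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=100.0, allow_nan=False),
            min_size=4,
            max_size=30,
        )
    )
    def test_matches_bruteforce_reference(self, speeds):
        """Detector equals a literal re-statement of the rule."""

        def brute(seq):
            run = 0
            for i in range(1, len(seq)):
                run = run + 1 if seq[i] < seq[i - 1] else 0
                if run == 3:
                    return i, max(seq[: i + 1])
            return None

        assert detect_peak_three_decreasing(speeds) == brute(speeds)


class TestPercentileCalibration:
    def test_linear_interpolation_on_arithmetic_sequence(self):
        latencies = np.round(np.arange(0.1, 3.21, 0.1), 10)
        assert calibrate_peak_time_percentile(latencies, 80) == pytest.approx(2.58)

    def test_constant_latencies_return_the_constant(self):
        assert calibrate_peak_time_percentile([0.4] * 32, 80) == pytest.approx(0.4)
        assert calibrate_peak_time_percentile([0.4] * 32, 15) == pytest.approx(0.4)

    def test_short_calibration_set_warns(self):
        with pytest.warns(UserWarning, match="31"):
            calibrate_peak_time_percentile(np.linspace(0.1, 3.1, 31), 80)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            calibrate_peak_time_percentile([0.5], 80)
        with pytest.raises(ValueError):
            calibrate_peak_time_percentile([0.5, 0.6], 0)


class TestClassification:
    @pytest.mark.parametrize(
        "peak,prev1,prev2,label",
        [
            (5, 3, 4, "fast"),
            (2, 3, 4, "slow"),
            (3.5, 3, 4, "intermediate"),
            (4, 4, 3, "intermediate"),  # tie is not strict exceedance
            (3, 3, 3, "intermediate"),
        ],
    )
    def test_strict_two_back_rule(self, peak, prev1, prev2, label):
        assert classify_speed(peak, prev1, prev2) == label

    def test_iid_peaks_classified_fast_one_third_of_the_time(self):
        # the last of three exchangeable values is the strict max w.p. 1/3
        rng = np.random.default_rng(1)
        v = rng.lognormal(0, 0.1, 10_000)
        labels = ks.closed_loop.offline_two_back_labels(v, block_length=10_000)
        frac_fast = np.mean(np.asarray(labels) == "fast")
        frac_slow = np.mean(np.asarray(labels) == "slow")
        assert frac_fast == pytest.approx(1 / 3, abs=0.015)
        assert frac_slow == pytest.approx(1 / 3, abs=0.015)


class TestClosedLoopSession:
    def test_session_shape_and_block_reset(self, small_session, small_protocol):
        _, _, session = small_session
        mv = session.movements
        assert len(mv) == small_protocol.n_blocks * small_protocol.block_length
        firsts = mv[mv["movement_index"] % small_protocol.block_length < 2]
        assert (firsts["label"] == "unclassified").all()
        assert not firsts["stimulated"].any()

    def test_no_stim_outside_stim_blocks(self, small_session):
        _, _, session = small_session
        assert set(session.stim_events["block"]) <= {1, 3}
        recovery = session.movements[session.movements["block"].isin([2, 4])]
        assert not recovery["stimulated"].any()

    def test_at_most_one_burst_per_movement_and_exact_duration(
        self, small_session, small_protocol
    ):
        _, _, session = small_session
        ev = session.stim_events
        assert ev["movement_index"].is_unique
        assert np.allclose(ev["duration_s"], 0.300)

    def test_empty_stim_blocks_emit_no_bursts(self, small_session):
        trace, _, _ = small_session
        proto = ks.StimProtocol(
            block_length=24, stim_blocks=(), condition_order=()
        )
        session = run_closed_loop_session(trace, proto)
        assert len(session.stim_events) == 0

    def test_short_trace_rejected(self, small_session):
        trace, _, _ = small_session
        with pytest.raises(ValueError, match="requires"):
            run_closed_loop_session(trace, ks.StimProtocol())

    def test_noiseless_stim_set_matches_offline_oracle(
        self, small_protocol, noiseless_model
    ):
        ts = ks.synthetic_data.generate_target_sequence(96, seed=31)
        trace, truth = ks.synthetic_data.generate_kinematics(
            ts, noiseless_model, small_protocol, seed=32
        )
        session = run_closed_loop_session(trace, small_protocol, truth=truth)
        offline = ks.closed_loop.offline_two_back_labels(
            truth.movements["true_peak_speed"].to_numpy(),
            small_protocol.block_length,
        )
        expected = {
            m
            for m in range(96)
            if offline[m]
            == small_protocol.block_condition(m // small_protocol.block_length + 1)
        }
        assert set(session.stim_events["movement_index"]) == expected

    def test_detection_latency_at_least_three_sampling_intervals(
        self, small_protocol, noiseless_model
    ):
        ts = ks.synthetic_data.generate_target_sequence(96, seed=33)
        trace, truth = ks.synthetic_data.generate_kinematics(
            ts, noiseless_model, small_protocol, seed=34
        )
        session = run_closed_loop_session(trace, small_protocol, truth=truth)
        lat = session.movements["detection_latency_s"].dropna()
        assert (lat >= 3 / 62.0 - 1e-9).all()

    def test_percentile_time_detector_runs(self, small_session, small_protocol):
        trace, truth, _ = small_session
        session = run_closed_loop_session(
            trace,
            small_protocol,
            detector="percentile_time",
            peak_time_threshold=0.4,
            truth=truth,
        )
        assert session.movements["online_peak_px_s"].notna().mean() > 0.9


class TestControllerAudit:
    def test_noiseless_accuracy_is_exact(self, small_protocol, noiseless_model):
        ts = ks.synthetic_data.generate_target_sequence(96, seed=35)
        trace, truth = ks.synthetic_data.generate_kinematics(
            ts, noiseless_model, small_protocol, seed=36
        )
        session = run_closed_loop_session(trace, small_protocol, truth=truth)
        assert evaluate_controller(session, truth, reference="trace").accuracy == 1.0
        assert evaluate_controller(session, truth, reference="truth").accuracy == 1.0

    def test_total_stim_time_arithmetic(self, small_session):
        _, truth, session = small_session
        audit = evaluate_controller(session, truth)
        assert audit.total_stim_time_s == pytest.approx(
            0.300 * len(session.stim_events)
        )

    def test_trend_asymmetry_slows_exceed_fasts(self):
        # any strictly decreasing trend makes fast rarer than slow
        rng = np.random.default_rng(2)
        v = rng.lognormal(0, 0.1, 20_000) * 0.998 ** np.arange(20_000)
        labels = np.asarray(
            ks.closed_loop.offline_two_back_labels(v, block_length=20_000)
        )
        assert np.mean(labels == "fast") < 1 / 3 < np.mean(labels == "slow")
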