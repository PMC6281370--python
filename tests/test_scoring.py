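"""EMG conditioning, threshold, segmentation and twitch detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from precereb import (
    AnalysisConfig,
    EventTrain,
    SampledSignal,
    ValidationError,
    detect_twitches,
    detect_wake_onsets,
    estimate_threshold,
    rectify_smooth,
    score_session,
    segment_states,
)
from precereb.model import Bout


def _sig(samples, rate=1000.0, rectified=False, channel="nuchal"):
    return SampledSignal(channel, rate, np.asarray(samples, float),
                         rectified=rectified)


class TestRectifySmooth:
    def test_zero_in_zero_out(self):
        out = rectify_smooth(_sig(np.zeros(100)), 0.01)
        np.testing.assert_array_equal(out.samples, 0)
        assert out.rectified

    def test_tiny_tau_is_rectification(self):
        x = np.sin(np.linspace(0, 20, 2000))
        out = rectify_smooth(_sig(x), 1e-9)
        np.testing.assert_allclose(out.samples, np.abs(x), atol=1e-9)

    def test_step_response_matches_rc_closed_form(self):
        rate, tau = 1000.0, 0.1
        x = np.ones(1000)
        out = rectify_smooth(_sig(x, rate), tau)
        t = (np.arange(1000) + 1) / rate  # causal filter: sample n sees n+1 inputs
        expected = 1 - np.exp(-t / tau)
        np.testing.assert_allclose(out.samples, expected, atol=5e-3)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValidationError):
            rectify_smooth(_sig(np.ones(10)), 0.0)


class TestThreshold:
    def test_square_wave_midpoint(self):
        # alternating 1-s segments at 10 and 2 -> threshold (10+2)/2 = 6
        x = np.concatenate([np.full(1000, 10.0 if i % 2 else 2.0)
                            for i in range(12)])
        est = estimate_threshold(_sig(x, rectified=True))
        assert est.threshold == pytest.approx(6.0)
        assert est.mean_high == pytest.approx(10.0)
        assert est.threshold == (est.mean_high + est.mean_atonia) / 2

    def test_constant_signal_rejected(self):
        with pytest.raises(ValidationError, match="distinguish"):
            estimate_threshold(_sig(np.ones(20000), rectified=True))

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValidationError, match="too short"):
            estimate_threshold(_sig(np.ones(3000), rectified=True))

    def test_manual_segments_used_exactly(self):
        x = np.concatenate([np.full(2000, 8.0), np.full(2000, 2.0)])
        est = estimate_threshold(_sig(x, rectified=True),
                                 manual_segments={"high": [(0.0, 1.0)],
                                                  "atonia": [(2.5, 3.5)]})
        assert est.threshold == pytest.approx(5.0)
        with pytest.raises(ValidationError, match="overlap"):
            estimate_threshold(_sig(x, rectified=True),
                               manual_segments={"high": [(0.0, 1.0), (0.5, 1.5)],
                                                "atonia": [(2.5, 3.5)]})

    def test_recovers_midpoint_on_synthetic_session(self, noisy_session, config):
        from precereb.scoring import rectify_smooth as rs
        sig = rs(noisy_session.emg_channel("nuchal"), config.smooth_tau)
        est = estimate_threshold(sig)
        # true class means are ~wake_level and ~atonia_level
        expected = (10.0 + 1.0) / 2
        assert abs(est.threshold - expected) / expected < 0.05


class TestSegmentation:
    def test_always_above_is_single_aw(self):
        s = segment_states(_sig(np.full(5000, 9.0), rectified=True), [], 5.0)
        assert len(s) == 1 and s.intervals[0].label == "AW"
        assert s.intervals[0].duration == pytest.approx(5.0)

    def test_sleep_split_at_first_twitch(self):
        x = np.concatenate([np.full(10000, 9.0), np.full(10000, 1.0)])
        tw = EventTrain("twitch_nuchal", [13.0], 20.0)
        s = segment_states(_sig(x, rectified=True), [tw], 5.0)
        labels = [(round(b.start), round(b.end), b.label) for b in s.intervals]
        assert labels == [(0, 10, "AW"), (10, 13, "BQ"), (13, 20, "AS")]

    def test_short_dip_merged_into_wake(self):
        x = np.concatenate([np.full(5000, 9.0), np.full(500, 1.0),
                            np.full(5000, 9.0)])
        s = segment_states(_sig(x, rectified=True), [], 5.0, min_bout=1.0)
        assert len(s) == 1 and s.intervals[0].label == "AW"

    def test_intervals_tile_span_disjointly(self, noise_free_session, config):
        scored = score_session(noise_free_session, config)
        ivs = scored.states.intervals
        assert ivs[0].start == 0.0
        for a, b in zip(ivs, ivs[1:]):
            assert a.end == pytest.approx(b.start)
        assert ivs[-1].end == pytest.approx(noise_free_session.duration)


class TestTwitchDetection:
    def test_flat_atonia_yields_no_twitches(self):
        sig = _sig(np.ones(20000), rectified=True)
        det = detect_twitches(sig, [Bout(0, 20, "BQ")], k=3.0)
        assert len(det.onsets) == 0
        assert det.baseline == pytest.approx(1.0)

    def test_transient_during_wake_not_counted(self):
        x = np.full(30000, 1.0)
        x[5000:5060] = 8.0    # transient inside the wake epoch [0, 10 s)
        sig = _sig(x, rectified=True)
        det = detect_twitches(sig, [Bout(10.0, 30.0, "BQ")], k=3.0)
        assert len(det.onsets) == 0

    def test_empty_sleep_mask_rejected(self):
        with pytest.raises(ValidationError, match="sleep mask"):
            detect_twitches(_sig(np.ones(100), rectified=True), [], 3.0)

    def test_refractory_merges_nearby_crossings(self):
        x = np.full(20000, 1.0)
        x[5000:5030] = 8.0
        x[5100:5130] = 8.0    # 100 ms later: inside the refractory period
        sig = _sig(x, rectified=True)
        det = detect_twitches(sig, [Bout(0, 20, "BQ")], 3.0, refractory=0.2)
        assert len(det.onsets) == 1

    def test_raising_k_never_increases_detections(self):
        rng = np.random.default_rng(0)
        x = np.abs(rng.normal(1.0, 0.3, 50000))
        x[10000:10050] += 9.0
        sig = _sig(x, rectified=True)
        counts = [len(detect_twitches(sig, [Bout(0, 50, "BQ")], k).onsets)
                  for k in (1.5, 2.0, 3.0, 5.0, 9.0)]
        assert counts == sorted(counts, reverse=True)


class TestFullScoring:
    def test_noise_free_recovery_exact(self, noise_free_session, config):
        """States within one sample; twitch precision = recall = 1."""
        scored = score_session(noise_free_session, config)
        gt = noise_free_session.ground_truth
        dt = 1.0 / noise_free_session.emg[0].rate
        assert len(scored.states) == len(gt.true_states)
        for a, b in zip(scored.states.intervals, gt.true_states.intervals):
            assert a.label == b.label
            assert abs(a.start - b.start) <= dt + 1e-9
            assert abs(a.end - b.end) <= dt + 1e-9
        for m, truth in gt.true_twitches.items():
            det = scored.event_train(f"twitch_{m}")
            assert len(det) == len(truth)
            np.testing.assert_allclose(det.times, truth.times, atol=2 * dt)

    def test_detected_twitches_lie_in_as(self, noise_free_session, config):
        scored = score_session(noise_free_session, config)
        as_bouts = scored.states.bouts("AS")
        for ev in scored.events:
            if not ev.label.startswith("twitch_"):
                continue
            for t in ev.times:
                assert any(b.start <= t < b.end for b in as_bouts)

    def test_wake_onsets_recovered(self, noise_free_session, config):
        scored = score_session(noise_free_session, config)
        gt = noise_free_session.ground_truth
        det = scored.event_train("wake_onset")
        dt = 1.0 / noise_free_session.emg[0].rate
        assert len(det) == len(gt.true_wake_onsets)
        np.testing.assert_allclose(det.times, gt.true_wake_onsets.times,
                                   atol=2 * dt)

    def test_no_wake_session_has_empty_onsets(self):
        sig = _sig(np.ones(20000), rate=1000.0, rectified=True)
        states = segment_states(sig, [], 5.0)
        onsets = detect_wake_onsets(sig, states, 5.0)
        assert len(onsets) == 0


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_smoothing_preserves_nonnegativity_and_scale(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, 500)
    out = rectify_smooth(_sig(x, rate=250.0), tau=0.02)
    assert np.all(out.samples >= 0)
    assert out.samples.max() <= np.abs(x).max() + 1e-12
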