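"""PSTH construction, jitter surrogates, bands, classification, pooling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from precereb import (
    AnalysisConfig,
    EventTrain,
    SpikeTrain,
    ValidationError,
    area_under_curve,
    build_psth,
    classify_response,
    evoked_response,
    jitter_band_test,
    jitter_surrogates,
    normalize_and_average,
    pool_units,
    select_strongest_muscle,
    simultaneous_bands,
    smooth_psth,
)
from precereb.model import Bout, StateIntervals
from precereb.perievent import Psth, jitter_surrogate_counts
from precereb.synthetic import UnitSpec, poisson_train, simulate_unit_spikes

from conftest import psth_oracle, random_pair


def _mk_psth(counts, bin_width=0.01, n_events=10):
    counts = np.asarray(counts, float)
    half = counts.size // 2
    edges = bin_width * np.arange(-half, counts.size - half + 1)
    return Psth("tw", edges, counts, n_events, unit_ids=("u",))


class TestBuildPsth:
    def test_spikes_at_event_times_fill_first_positive_bin(self):
        ev = EventTrain("tw", [10.0, 20.0, 30.0], 60.0)
        sp = SpikeTrain("u", [10.0, 20.0, 30.0])
        psth = build_psth(sp, ev, 1.0, 0.01)
        assert psth.counts.sum() == 3
        assert psth.counts[np.searchsorted(psth.edges, 0.0)] == 3

    def test_no_spikes_gives_zero_histogram(self):
        ev = EventTrain("tw", [10.0], 60.0)
        psth = build_psth(SpikeTrain("u", []), ev, 1.0, 0.01)
        assert psth.counts.sum() == 0
        assert np.all(psth.rate == 0)

    def test_empty_events_is_error(self):
        with pytest.raises(ValidationError, match="empty"):
            build_psth(SpikeTrain("u", [1.0]), EventTrain("tw", [], 60.0))

    def test_misaligned_bin_width_rejected(self):
        ev = EventTrain("tw", [10.0], 60.0)
        with pytest.raises(ValidationError, match="edge"):
            build_psth(SpikeTrain("u", [1.0]), ev, 1.0, 0.003)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ev, sp = random_pair(rng)
        psth = build_psth(sp, ev, 1.0, 0.005)
        np.testing.assert_array_equal(
            psth.counts, psth_oracle(sp.times, ev.times, psth.edges))

    def test_truncated_edge_events_counted(self):
        ev = EventTrain("tw", [0.2, 50.0], 60.0)
        psth = build_psth(SpikeTrain("u", [0.1]), ev, 1.0, 0.01)
        assert psth.n_truncated == 1
        assert psth.counts.sum() == 1  # lag -0.1 still lands in the window


class TestJitterSurrogates:
    def test_count_and_cell_preserved(self):
        rng = np.random.default_rng(0)
        ev = EventTrain("tw", np.unique(rng.uniform(0, 100, 80)), 100.0)
        surr = jitter_surrogates(ev, 0.5, 20, 1)
        cells = np.floor(ev.times / 0.5)
        for s in surr:
            assert len(s) == len(ev)
            np.testing.assert_array_equal(np.sort(np.floor(s.times / 0.5)),
                                          np.sort(cells))

    def test_tiny_delta_keeps_events_in_place(self):
        ev = EventTrain("tw", [10.0, 20.0], 100.0)
        surr = jitter_surrogates(ev, 1e-6, 5, 2)
        for s in surr:
            np.testing.assert_allclose(s.times, ev.times, atol=1e-6)

    def test_deterministic_under_seed(self):
        ev = EventTrain("tw", [10.0, 20.0, 33.0], 100.0)
        a = jitter_surrogates(ev, 0.5, 3, 42)
        b = jitter_surrogates(ev, 0.5, 3, 42)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.times, y.times)

    def test_fast_counts_match_per_surrogate_builds(self):
        rng = np.random.default_rng(3)
        ev, sp = random_pair(rng, n_events=40)
        edges = build_psth(sp, ev, 1.0, 0.01).edges
        X = jitter_surrogate_counts(sp, ev, edges, 0.5, 50,
                                    np.random.default_rng(9))
        trains = jitter_surrogates(ev, 0.5, 50, np.random.default_rng(9))
        for i, tr in enumerate(trains):
            np.testing.assert_array_equal(
                X[i], psth_oracle(sp.times, tr.times, edges))

    def test_surrogate_average_flattens_locked_peak(self):
        duration = 1000.0
        rng = np.random.default_rng(5)
        states = StateIntervals((Bout(0, duration, "AS"),))
        ev = EventTrain("tw", np.unique(poisson_train(1.0, 0, duration, rng)),
                        duration)
        spk = simulate_unit_spikes(UnitSpec.from_archetype("cd", "u"),
                                   states, ev.times, duration, rng)
        psth = build_psth(spk, ev, 1.0, 0.005)
        X = jitter_surrogate_counts(spk, ev, psth.edges, 0.5, 1000, rng)
        mean_surr = X.mean(axis=0)
        ratio_obs = psth.counts.max() / psth.counts.mean()
        ratio_surr = mean_surr.max() / mean_surr.mean()
        assert ratio_obs >= 2 * ratio_surr


class TestSimultaneousBands:
    def test_degenerate_identical_surrogates_never_breach(self):
        psth = _mk_psth([3, 3, 3, 3])
        X = np.tile(psth.counts, (200, 1))
        bands = simultaneous_bands(psth, X, 0.05)
        assert not bands.any_breach(psth.counts)

    def test_bands_nest_with_alpha(self):
        rng = np.random.default_rng(1)
        ev, sp = random_pair(rng, n_events=100, n_spikes=2000, duration=300.0)
        psth = build_psth(sp, ev, 1.0, 0.01)
        X = jitter_surrogate_counts(sp, ev, psth.edges, 0.5, 1000, rng)
        b05 = simultaneous_bands(psth, X, 0.05)
        b01 = simultaneous_bands(psth, X, 0.01)
        assert np.all(b01.upper >= b05.upper)
        assert np.all(b01.lower <= b05.lower)

    def test_too_few_surrogates_rejected(self):
        psth = _mk_psth([1, 2, 3, 4])
        with pytest.raises(ValidationError, match="surrogates"):
            simultaneous_bands(psth, np.ones((50, 4)), 0.01)

    def test_analysis_span_restricts_tested_bins(self):
        psth = _mk_psth(np.zeros(100))
        rng = np.random.default_rng(2)
        X = rng.poisson(5, size=(500, 100)).astype(float)
        bands = simultaneous_bands(psth, X, 0.05, analysis_span=(-0.25, 0.25))
        outside = (psth.centers <= -0.25) | (psth.centers >= 0.25)
        assert np.all(np.isinf(bands.upper[outside]))
        assert not np.any(bands.breach_upper(X[0])[outside])


class TestClassification:
    def test_all_zero_psth_has_no_windows(self, config):
        psth = _mk_psth(np.zeros(100))
        X = np.zeros((200, 100))
        bands = simultaneous_bands(psth, X, 0.05)
        rc = classify_response(psth, bands, config)
        assert rc.significant_windows == frozenset()
        assert not rc.significant

    def test_archetypes_assigned_their_latency_windows(self, config):
        """cd -> +-10 ms; sensory -> reafferent with breach latency in
        (10, 60] ms; both with the peak in the intended window."""
        duration = 2500.0
        states = StateIntervals((Bout(0, duration, "AS"),))
        rng = np.random.default_rng(11)
        ev = EventTrain("tw", np.unique(poisson_train(0.8, 0, duration, rng)),
                        duration)
        cfg = config.with_(bin_width=0.005)
        for archetype, want in (("cd", "cd"), ("sensory", "reafferent")):
            spk = simulate_unit_spikes(
                UnitSpec.from_archetype(archetype, "u"), states, ev.times,
                duration, rng)
            psth, bands = jitter_band_test(
                spk, ev, window=1.0, bin_width=0.005, delta=0.5,
                n_surrogates=1000, alpha=0.01, rng=rng)
            rc = classify_response(psth, bands, cfg)
            assert want in rc.significant_windows
            assert rc.primary_window == want
            if archetype == "cd":
                assert abs(rc.peak_lag) < 0.010
            else:
                assert 0.010 < rc.first_breach_lag <= 0.060


class TestMuscleSelectionAndPooling:
    def _rc(self, sig):
        from precereb.perievent import ResponseClass
        return ResponseClass("u", "tw", frozenset({"cd"} if sig else ()),
                             frozenset(), "cd" if sig else None, 0.0, 0.0)

    def test_single_significant_muscle_chosen(self):
        per = {"forelimb": (self._rc(True), _mk_psth([0, 8, 0, 0]))}
        assert select_strongest_muscle(per) == "forelimb"

    def test_highest_peak_rate_wins(self):
        per = {"nuchal": (self._rc(True), _mk_psth([0, 12, 0, 0])),
               "forelimb": (self._rc(True), _mk_psth([0, 8, 0, 0]))}
        assert select_strongest_muscle(per) == "nuchal"

    def test_tie_breaks_deterministically_by_muscle_order(self):
        tie = {"hindlimb": (self._rc(True), _mk_psth([0, 8, 0, 0])),
               "forelimb": (self._rc(True), _mk_psth([0, 8, 0, 0]))}
        assert select_strongest_muscle(tie) == "forelimb"

    def test_no_significant_muscle_returns_none(self):
        per = {"nuchal": (self._rc(False), _mk_psth([0, 1, 0, 0]))}
        assert select_strongest_muscle(per) is None

    def test_pooling_one_unit_is_identity_and_counts_add(self):
        rng = np.random.default_rng(4)
        pairs = [random_pair(rng, n_events=60, n_spikes=500, duration=200.0)
                 for _ in range(3)]
        pairs = [(sp, ev) for ev, sp in pairs]
        pooled, _ = pool_units(pairs, bin_width=0.01, n_surrogates=200,
                               alpha=0.05, rng=1)
        total = sum(build_psth(sp, ev, 1.0, 0.01).counts for sp, ev in pairs)
        np.testing.assert_array_equal(pooled.counts, total)
        assert pooled.n_events == sum(len(ev) for _, ev in pairs)
        one, _ = pool_units(pairs[:1], bin_width=0.01, n_surrogates=200,
                            alpha=0.05, rng=1)
        np.testing.assert_array_equal(
            one.counts, build_psth(pairs[0][0], pairs[0][1], 1.0, 0.01).counts)

    def test_pooled_cd_units_breach_cd_window(self, config):
        duration = 400.0
        states = StateIntervals((Bout(0, duration, "AS"),))
        rng = np.random.default_rng(6)
        pairs = []
        for i in range(10):
            ev = EventTrain("tw", np.unique(poisson_train(0.5, 0, duration, rng)),
                            duration)
            spk = simulate_unit_spikes(
                UnitSpec.from_archetype("cd", f"u{i}"), states, ev.times,
                duration, rng)
            pairs.append((spk, ev))
        pooled, bands = pool_units(pairs, bin_width=0.005, n_surrogates=1000,
                                   alpha=0.01, rng=rng)
        rc = classify_response(pooled, bands, config)
        assert "cd" in rc.significant_windows


class TestNormalizeSmoothAuc:
    def test_single_unit_normalized_mean_with_zero_sem(self):
        p = _mk_psth([0, 4, 2, 0])
        mean, sem, n, excl = normalize_and_average([p])
        np.testing.assert_allclose(mean, [0, 1, 0.5, 0])
        np.testing.assert_array_equal(sem, 0)
        assert n == 1 and not excl

    def test_identical_units_have_zero_sem(self):
        p = _mk_psth([0, 4, 2, 0])
        mean, sem, n, _ = normalize_and_average([p, p])
        np.testing.assert_allclose(mean, [0, 1, 0.5, 0])
        np.testing.assert_allclose(sem, 0)

    def test_mean_sem_match_direct_arithmetic(self):
        rng = np.random.default_rng(8)
        ps = [_mk_psth(rng.poisson(5, 20) + 1) for _ in range(5)]
        mean, sem, n, _ = normalize_and_average(ps)
        M = np.vstack([p.rate / p.rate.max() for p in ps])
        np.testing.assert_allclose(mean, M.mean(axis=0))
        np.testing.assert_allclose(sem, M.std(axis=0, ddof=1) / np.sqrt(5))

    def test_zero_peak_units_excluded(self):
        good, bad = _mk_psth([0, 2, 0, 0]), _mk_psth([0, 0, 0, 0])
        mean, _, n, excl = normalize_and_average([good, bad])
        assert n == 1 and excl == ["u"]
        with pytest.raises(ValidationError, match="zero peak"):
            normalize_and_average([bad])

    def test_smoothing_zero_in_zero_out_and_mass_conserved(self):
        assert np.all(smooth_psth(_mk_psth(np.zeros(50))) == 0)
        p = _mk_psth(np.r_[np.zeros(24), 10.0, np.zeros(25)])
        sm = smooth_psth(p, tau=0.01)
        assert abs(sm.sum() - p.rate.sum()) / p.rate.sum() < 0.01
        peak = np.argmax(sm)
        assert np.all(np.diff(sm[:peak + 1]) >= -1e-12)
        assert np.all(np.diff(sm[peak:]) <= 1e-12)
        causal = smooth_psth(p, tau=0.01, causal=True)
        assert causal[23] == 0 and causal[26] > 0

    def test_smoothing_matches_direct_convolution(self):
        rng = np.random.default_rng(9)
        p = _mk_psth(rng.poisson(4, 40))
        sm = smooth_psth(p, tau=0.02)
        lags = np.arange(-12, 13) * 0.01
        k = np.exp(-np.abs(lags) / 0.02)
        k /= k.sum()
        np.testing.assert_allclose(sm, np.convolve(p.rate, k, "same"))

    def test_auc_zero_full_and_oracle(self):
        p = _mk_psth(np.zeros(100))
        assert area_under_curve(p, (-0.01, 0.01)) == 0
        rng = np.random.default_rng(10)
        q = _mk_psth(rng.poisson(3, 100), n_events=25)
        assert area_under_curve(q, (-0.5, 0.5)) == pytest.approx(
            q.counts.sum() / 25)
        lo, hi = 0.02, 0.2
        mask = (q.edges[:-1] >= lo - 1e-9) & (q.edges[1:] <= hi + 1e-9)
        assert area_under_curve(q, (lo, hi)) == pytest.approx(
            q.counts[mask].sum() / 25)
        assert area_under_curve(q, (lo, hi), per_event=False) == pytest.approx(
            q.counts[mask].sum())

    def test_misaligned_auc_window_rejected(self):
        with pytest.raises(ValidationError, match="aligned"):
            area_under_curve(_mk_psth(np.ones(100)), (-0.013, 0.01))


class TestEvokedResponse:
    def test_sensory_archetype_latency_in_expected_range(self):
        duration = 400.0
        states = StateIntervals((Bout(0, duration, "BQ"),))
        rng = np.random.default_rng(12)
        stim = EventTrain("stim_forelimb", np.arange(30) * 6.0 + 5.0, duration)
        spec = UnitSpec.from_archetype("sensory", "u", gain_scale=3.0,
                                       base_rate_by_state={"BQ": 2.0})
        spk = simulate_unit_spikes(spec, states, stim.times + 0.010,
                                   duration, rng)
        _, _, latency = evoked_response(spk, stim, n_surrogates=1000,
                                        alpha=0.05, rng=rng)
        assert latency is not None and 0.020 < latency <= 0.060

    def test_unresponsive_unit_has_no_latency(self):
        duration = 400.0
        rng = np.random.default_rng(13)
        stim = EventTrain("stim", np.arange(30) * 6.0 + 5.0, duration)
        spk = SpikeTrain("u", np.sort(rng.uniform(0, duration, 2000)))
        psth, bands, latency = evoked_response(spk, stim, n_surrogates=500,
                                               alpha=0.05, rng=rng)
        assert latency is None

    def test_too_few_stimulations_rejected_and_short_intervals_warned(self, caplog):
        stim = EventTrain("stim", np.arange(5) * 6.0, 60.0)
        with pytest.raises(ValidationError, match="stimulation"):
            evoked_response(SpikeTrain("u", [1.0]), stim)
        import logging
        stim2 = EventTrain("stim", np.arange(20) * 2.0 + 1.0, 60.0)
        with caplog.at_level(logging.WARNING, logger="precereb"):
            evoked_response(SpikeTrain("u", np.linspace(0, 59, 300)), stim2,
                            n_surrogates=200, alpha=0.05, rng=0)
        assert any("interval" in r.message for r in caplog.records)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_psth_total_counts_equal_pair_count_in_window(seed):
    rng = np.random.default_rng(seed)
    ev, sp = random_pair(rng, n_events=20, n_spikes=100, duration=30.0)
    psth = build_psth(sp, ev, 1.0, 0.01)
    lags = sp.times[None, :] - ev.times[:, None]
    n_pairs = np.sum((lags >= -0.5) & (lags < 0.5))
    assert psth.counts.sum() == n_pairs
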