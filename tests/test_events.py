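"""Event detection: immobility gating, envelope standardization, threshold
rules, pairing, bursts, per-event features, pathological events."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hippolfp as h
from hippolfp.dsp import bandpass, smoothed_envelope
from hippolfp.events import envelope_sd
from hippolfp.synth import _windowed_tone

from helpers import (add_burst, brute_force_burst_kinds, burst_background,
                     naive_detect_ripples)

RATE = 1034.0


def _speed(values, frame_rate=50.0):
    t = np.arange(len(values)) / frame_rate
    return h.SpeedTrace(t, np.asarray(values, dtype=float), frame_rate)


class TestImmobility:
    def test_long_slow_low_theta_bout_is_one_period(self):
        speed = _speed(np.full(3000, 0.5))
        ratio = np.full(3000, 0.5)
        periods = h.find_immobility_periods(speed, ratio, h.DetectionParams())
        assert len(periods) == 1
        assert periods[0].start_s == pytest.approx(0.0)
        assert periods[0].end_s == pytest.approx(60.0, abs=0.05)

    def test_ten_second_bout_is_too_short(self):
        v = np.full(3000, 5.0)
        v[1000:1500] = 0.5  # 10 s below threshold
        periods = h.find_immobility_periods(_speed(v), np.full(3000, 0.5),
                                            h.DetectionParams())
        assert periods == []

    def test_speed_above_threshold_gives_no_periods(self):
        periods = h.find_immobility_periods(_speed(np.full(3000, 2.0)),
                                            np.full(3000, 0.5),
                                            h.DetectionParams())
        assert periods == []

    def test_high_theta_ratio_blocks_immobility(self):
        periods = h.find_immobility_periods(_speed(np.full(3000, 0.5)),
                                            np.full(3000, 5.0),
                                            h.DetectionParams())
        assert periods == []

    def test_empty_speed_trace_raises(self):
        with pytest.raises(h.InsufficientDataError):
            h.find_immobility_periods(_speed([]), np.array([]),
                                      h.DetectionParams())


class TestEnvelopeSd:
    def test_baseline_standardization_identity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(int(60 * RATE))
        _, env = envelope_sd(x, RATE, (150.0, 250.0), [(0.0, 60.0)], 4.0)
        assert abs(env.mean()) < 0.05
        assert env.std() == pytest.approx(1.0, abs=0.05)

    def test_scaling_outside_baseline_scales_in_sd_units(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(int(30 * RATE))
        x2 = x.copy()
        x2[int(20 * RATE):] *= 2.0
        _, e1 = envelope_sd(x, RATE, (150.0, 250.0), [(0.0, 10.0)], 4.0)
        _, e2 = envelope_sd(x2, RATE, (150.0, 250.0), [(0.0, 10.0)], 4.0)
        # undo the (shared) baseline standardization: raw envelope doubles
        env = smoothed_envelope(bandpass(x, RATE, (150.0, 250.0)), RATE, 4.0)
        base = env[: int(10 * RATE)]
        mu, sd = base.mean(), base.std()
        seg = slice(int(22 * RATE), int(28 * RATE))
        np.testing.assert_allclose(e2[seg] * sd + mu, 2 * (e1[seg] * sd + mu),
                                   rtol=1e-3)

    def test_six_sd_burst_measures_between_five_and_seven(self):
        x = burst_background(seed=5)
        x = add_burst(x, RATE, 15.0, 60, 180.0, 6.0)
        _, env = envelope_sd(x, RATE, (150.0, 250.0), [(0.0, 30.0)], 4.0)
        peak = env[int(14.9 * RATE):int(15.1 * RATE)].max()
        assert 5.0 <= peak <= 7.0

    def test_zero_variance_baseline_raises(self):
        with pytest.raises(h.HippolfpError):
            envelope_sd(np.zeros(int(5 * RATE)), RATE, (150.0, 250.0),
                        [(0.0, 5.0)], 4.0)


class TestRippleDetection:
    def test_matches_naive_oracle_on_noise(self):
        x = burst_background(seed=9)
        for thresh, min_ms in ((3.0, 15.0), (2.0, 5.0)):
            params = h.DetectionParams(ripple_thresh_sd=thresh,
                                       ripple_min_ms=min_ms)
            _, env = envelope_sd(x, RATE, params.ripple_band, [(0.0, 30.0)],
                                 params.ripple_smooth_ms)
            expected = naive_detect_ripples(env, RATE, [(0.0, 30.0)],
                                            thresh=thresh, min_ms=min_ms)
            got = h.detect_ripples(x, RATE, [(0.0, 30.0)], params)
            assert [(round(e.start_s * RATE), round(e.end_s * RATE))
                    for e in got] == expected

    @pytest.mark.parametrize("gap_ms,n_expected", [(30, 1), (50, 2)])
    def test_merge_rule_on_close_bursts(self, gap_ms, n_expected):
        x = burst_background(seed=0)
        half = (gap_ms + 30) * 1e-3 / 2.0
        x = add_burst(x, RATE, 15.0 - half, 30, 200.0, 10.0)
        x = add_burst(x, RATE, 15.0 + half, 30, 200.0, 10.0)
        events = [e for e in h.detect_ripples(x, RATE, [(0.0, 30.0)])
                  if 14.6 < e.peak_s < 15.4]
        assert len(events) == n_expected

    def test_ten_ms_burst_is_rejected(self):
        x = burst_background(seed=0)
        x = add_burst(x, RATE, 15.0, 10, 200.0, 8.0)
        events = [e for e in h.detect_ripples(x, RATE, [(0.0, 30.0)])
                  if 14.8 < e.peak_s < 15.2]
        assert events == []

    def test_events_confined_to_immobility(self, swr_session, swr_detections):
        cfg, rec, *_ = swr_session
        imm, ripples, _, _ = swr_detections
        for e in ripples:
            assert any(p[0] <= e.peak_s <= p[1] for p in imm)
        for a, b in zip(ripples, ripples[1:]):
            assert a.end_s <= b.start_s  # non-overlapping, sorted

    def test_no_immobility_returns_empty(self):
        assert h.detect_ripples(np.zeros(1000), RATE, []) == []


class TestSpwDetection:
    def _spw_background(self, seed=0):
        rng = np.random.default_rng(seed)
        return bandpass(rng.standard_normal(int(30 * RATE)), RATE,
                        (2.0, 60.0)) * 2.0

    def _add_bump(self, x, t, dur_ms, amp_z, window="hann"):
        env = smoothed_envelope(bandpass(x, RATE, (4.0, 50.0)), RATE, 10.0)
        amp = (env.mean() + amp_z * env.std()) / 0.6
        i0, w = _windowed_tone(RATE, t, dur_ms * 1e-3, 0.0, amp, x.size,
                               invert_bump=True, window=window)
        out = x.copy()
        out[i0:i0 + w.size] += w
        return out

    def test_hundred_ms_deflection_detected(self):
        x = self._add_bump(self._spw_background(), 15.0, 100, 4.0)
        hits = [e for e in h.detect_spws(x, RATE, [(0.0, 30.0)])
                if e.start_s < 15.0 < e.end_s]
        assert len(hits) == 1
        assert 20.0 <= hits[0].duration_ms <= 400.0

    def test_ten_ms_deflection_rejected(self):
        x = self._add_bump(self._spw_background(), 15.0, 10, 3.0)
        assert [e for e in h.detect_spws(x, RATE, [(0.0, 30.0)])
                if abs((e.start_s + e.end_s) / 2 - 15.0) < 0.05] == []

    def test_five_hundred_ms_deflection_rejected(self):
        x = self._add_bump(self._spw_background(), 15.0, 560, 6.0,
                           window="tukey")
        assert [e for e in h.detect_spws(x, RATE, [(0.0, 30.0)])
                if e.start_s < 15.0 < e.end_s] == []


class TestPairing:
    def _ripple(self, s, e):
        return h.RippleEvent(start_s=s, end_s=e, peak_s=(s + e) / 2,
                             peak_power_sd=5.0)

    def _spw(self, s, e):
        return h.SpwEvent(start_s=s, end_s=e, amplitude_sd=3.0)

    def test_contained_ripple_pairs(self):
        swrs = h.pair_swr([self._ripple(10.00, 10.06)],
                          [self._spw(9.98, 10.10)])
        assert len(swrs) == 1

    def test_non_overlapping_ripple_is_discarded(self):
        assert h.pair_swr([self._ripple(10.0, 10.06)],
                          [self._spw(11.0, 11.1)]) == []

    def test_tie_goes_to_maximal_overlap(self):
        rip = self._ripple(10.0, 10.06)
        spw_a = self._spw(9.99, 10.03)   # 30 ms overlap
        spw_b = self._spw(10.05, 10.30)  # 10 ms overlap
        swrs = h.pair_swr([rip], [spw_a, spw_b])
        assert swrs[0].spw is spw_a

    def test_session_pairing_recovers_injections(self, swr_session,
                                                 swr_detections):
        _, _, _, _, gt = swr_session
        _, _, _, swrs = swr_detections
        truth = gt.of_type("swr")["peak_s"].to_numpy()
        detected = np.array([e.peak_s for e in swrs])
        recall = np.mean([np.abs(detected - p).min() < 0.05 for p in truth])
        assert recall > 0.9


class TestBursts:
    def test_doublet_and_singlets_and_triplet(self):
        def groups_for(peaks):
            swrs = [h.SwrEvent(
                ripple=h.RippleEvent(p - 0.02, p + 0.02, p, 5.0),
                spw=h.SpwEvent(p - 0.03, p + 0.03, 3.0)) for p in peaks]
            return h.classify_bursts(swrs)

        assert [g.kind for g in groups_for([0.0, 0.10])] == ["doublet"]
        assert [g.kind for g in groups_for([0.0, 0.25, 0.50])] == ["singlet"] * 3
        assert [g.kind for g in groups_for([0.0, 0.15, 0.30])] == ["triplet"]

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0.0, 30.0), min_size=0, max_size=40))
    def test_partition_matches_brute_force_chaining(self, peaks):
        peaks = sorted(set(round(p, 3) for p in peaks))
        swrs = [h.SwrEvent(
            ripple=h.RippleEvent(p - 0.01, p + 0.01, p, 5.0),
            spw=h.SpwEvent(p - 0.02, p + 0.02, 3.0)) for p in peaks]
        groups = h.classify_bursts(swrs)
        assert sorted(len(g.members) for g in groups) == \
            sorted(brute_force_burst_kinds(peaks))
        assert sum(len(g.members) for g in groups) == len(peaks)


class TestRippleFeatures:
    def test_pure_tone_burst_frequency_and_cycles(self):
        x = burst_background(seed=4, sd_uv=0.5)
        x = add_burst(x, RATE, 15.0, 50, 200.0, 12.0)
        events = [e for e in h.detect_ripples(x, RATE, [(0.0, 30.0)])
                  if 14.9 < e.peak_s < 15.1]
        ev = h.ripple_features(events[0], x, RATE)
        assert ev.peak_freq_hz == pytest.approx(200.0, abs=3.0)
        # boundary trimming (1 SD crossings) and the 25%-amplitude peak guard
        # shave the burst tails, so check cycles against the measured
        # duration x frequency rather than the nominal 50 ms window
        assert abs(ev.n_cycles - ev.duration_ms * 1e-3 * 200.0) <= 2
        assert 35.0 <= ev.duration_ms <= 55.0
        assert ev.duration_ms == pytest.approx((ev.end_s - ev.start_s) * 1e3)

    def test_envelope_peak_is_linear_in_amplitude(self):
        base = np.zeros(int(20 * RATE))
        p1, _ = h.inject_swr(base, base, RATE, 10.0, ripple_amp_uv=50.0,
                             spw_amp_uv=0.0)
        p2, _ = h.inject_swr(base, base, RATE, 10.0, ripple_amp_uv=100.0,
                             spw_amp_uv=0.0)
        e1 = smoothed_envelope(bandpass(p1, RATE, (150.0, 250.0)), RATE, 4.0)
        e2 = smoothed_envelope(bandpass(p2, RATE, (150.0, 250.0)), RATE, 4.0)
        assert e2.max() == pytest.approx(2 * e1.max(), rel=0.05)


class TestFastRipples:
    def _make(self, n_cycles, amp_z=8.0, seed=2, contaminate=False):
        rng = np.random.default_rng(seed)
        band = (250.0, 0.95 * RATE / 2)
        x = bandpass(rng.standard_normal(int(30 * RATE)), RATE,
                     (200.0, 500.0)) * 1.0
        env = smoothed_envelope(bandpass(x, RATE, band), RATE, 4.0)
        amp = (env.mean() + amp_z * env.std()) / 0.8
        dur_ms = n_cycles / 300.0 * 1e3
        i0, w = _windowed_tone(RATE, 15.0, dur_ms * 1e-3, 300.0, amp, x.size,
                               window="tukey")
        x[i0:i0 + w.size] += w
        if contaminate:
            i0, w = _windowed_tone(RATE, 15.0, 0.08, 100.0, 10 * amp, x.size)
            x[i0:i0 + w.size] += w
        return x

    def test_ten_cycle_burst_detected(self):
        x = self._make(10, amp_z=12.0)
        hits = [e for e in h.detect_fast_ripples(x, RATE, [(0.0, 30.0)])
                if 14.9 < e.peak_s < 15.1]
        assert len(hits) == 1
        assert hits[0].n_peaks >= 6

    def test_five_cycle_burst_rejected(self):
        x = self._make(5)
        assert [e for e in h.detect_fast_ripples(x, RATE, [(0.0, 30.0)])
                if 14.9 < e.peak_s < 15.1] == []

    def test_low_frequency_dominated_candidate_rejected(self):
        x = self._make(10, contaminate=True)
        assert [e for e in h.detect_fast_ripples(x, RATE, [(0.0, 30.0)])
                if 14.9 < e.peak_s < 15.1] == []

    def test_band_truncation_warns(self):
        x = self._make(10)
        with pytest.warns(UserWarning, match="truncated"):
            h.detect_fast_ripples(x, RATE, [(0.0, 30.0)])

    def test_truncation_opt_out_raises(self):
        with pytest.raises(h.ParameterError):
            h.detect_fast_ripples(np.zeros(int(5 * RATE)), RATE,
                                  [(0.0, 5.0)], allow_band_truncation=False)


class TestIeds:
    def test_injected_transient_detected(self):
        rng = np.random.default_rng(6)
        x = bandpass(rng.standard_normal(int(30 * RATE)), RATE, (1.0, 200.0)) * 3.0
        band_env = smoothed_envelope(bandpass(x, RATE, (60.0, 80.0)), RATE, 10.0)
        raw_env = smoothed_envelope(x, RATE, 10.0)
        amp = 1.3 * max(band_env.mean() + 7 * band_env.std(),
                        raw_env.mean() + 7 * raw_env.std())
        x2 = h.inject_transient(x, RATE, 15.0, 70.0, 40.0, amp)
        hits = [e for e in h.detect_ieds(x2, RATE, [(0.0, 30.0)])
                if 14.9 < e.peak_s < 15.1]
        assert len(hits) == 1

    def test_narrowband_oscillation_without_raw_deflection_rejected(self):
        # strong 60-80 Hz content buried under a large theta background:
        # filtered envelope crosses 5 SD but the raw envelope does not
        rng = np.random.default_rng(7)
        t = np.arange(int(30 * RATE)) / RATE
        x = 200.0 * np.sin(2 * np.pi * 8.0 * t) + \
            bandpass(rng.standard_normal(t.size), RATE, (1.0, 200.0)) * 3.0
        band_env = smoothed_envelope(bandpass(x, RATE, (60.0, 80.0)), RATE, 10.0)
        amp = (band_env.mean() + 7 * band_env.std()) / 0.7
        x2 = h.inject_transient(x, RATE, 15.0, 70.0, 40.0, amp)
        assert [e for e in h.detect_ieds(x2, RATE, [(0.0, 30.0)])
                if 14.9 < e.peak_s < 15.1] == []

    def test_quiet_signal_has_no_events(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(int(20 * RATE))
        assert h.detect_ieds(x, RATE, [(0.0, 20.0)]) == []


class TestSessionFeatures:
    def test_incidence_is_count_over_time(self):
        swrs = [object()] * 45
        assert h.swr_incidence(swrs, [(0.0, 100.0)]) == pytest.approx(0.45)
        assert h.swr_incidence([], [(0.0, 100.0)]) == 0.0
        with pytest.raises(h.InsufficientDataError):
            h.swr_incidence(swrs, [])

    def test_session_incidence_matches_manifest(self, swr_session,
                                                swr_detections):
        _, _, _, _, gt = swr_session
        imm, _, _, swrs = swr_detections
        detected = h.swr_incidence(swrs, imm)
        manifest = len(gt.of_type("swr")) / 600.0
        assert detected == pytest.approx(manifest, rel=0.05)

    def test_correlation_perfect_linear_relations(self):
        def swr(spw_amp, rip_pow):
            return h.SwrEvent(
                ripple=h.RippleEvent(0.0, 0.1, 0.05, rip_pow),
                spw=h.SpwEvent(0.0, 0.1, spw_amp))

        pos = [swr(a, 2 * a) for a in (1.0, 2.0, 3.0, 4.0)]
        neg = [swr(a, -a + 10) for a in (1.0, 2.0, 3.0)]
        assert h.spw_ripple_correlation(pos) == pytest.approx(1.0)
        assert h.spw_ripple_correlation(neg) == pytest.approx(-1.0)

    def test_correlation_matches_textbook_formula(self):
        rng = np.random.default_rng(3)
        amp = rng.uniform(2.5, 6.0, 50)
        power = 1.5 * amp + rng.normal(scale=0.5, size=50)
        swrs = [h.SwrEvent(ripple=h.RippleEvent(0, 0.1, 0.05, p),
                           spw=h.SpwEvent(0, 0.1, a))
                for a, p in zip(amp, power)]
        r = h.spw_ripple_correlation(swrs)
        expected = (np.mean(amp * power) - amp.mean() * power.mean()) / \
            (amp.std() * power.std())
        assert r == pytest.approx(expected, abs=1e-12)

    def test_correlation_needs_three_events(self):
        with pytest.raises(h.InsufficientDataError):
            h.spw_ripple_correlation([])
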