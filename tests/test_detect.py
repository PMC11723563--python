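"""Detector: filters, envelope, both threshold stages, artifact rejection.

Stage oracles here are deliberately naive loop implementations, independent
of the vectorized package code.
"""

import numpy as np
import pytest

import hfoscale as h
from hfoscale.core import Recording
from hfoscale.detect import (
    DetectorParams,
    detect_hfos,
    preprocess,
    reject_artifacts,
    rms_envelope,
    stage1_candidates,
    stage2_qualify,
)
from conftest import match_events

FS = 1000.0


# ---------------------------------------------------------------------------
# independent oracles


def brute_stage1(env, fs, params):
    t1_ref = env
    sd = float(np.std(t1_ref))
    if sd == 0:
        return []
    t1 = float(np.mean(t1_ref)) + params.n_sd * sd
    runs, start = [], None
    for i, v in enumerate(env):
        if v > t1 and start is None:
            start = i
        elif v <= t1 and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(env)))
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] < params.merge_gap * fs:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return [(s, e) for s, e in merged if e - s >= params.min_duration * fs]


def brute_stage2_keep(xf, cand, params):
    r = np.abs(xf)
    sd = float(np.std(r))
    if sd == 0:
        return False
    t2 = float(np.mean(r)) + params.n_sd * sd
    count, prev = 0, False
    for v in r[cand[0]:cand[1]]:
        cur = v > t2
        if cur and not prev:
            count += 1
        prev = cur
    return count >= params.min_peaks


def random_envelope(rng, n=1000):
    """Positive envelope-like array with occasional supra-threshold bursts."""
    base = rng.gamma(2.0, 1.0, size=n)
    for _ in range(rng.integers(0, 6)):
        i = int(rng.integers(0, n - 30))
        base[i:i + int(rng.integers(3, 30))] += rng.uniform(5, 25)
    return base


# ---------------------------------------------------------------------------


class TestPreprocess:
    def _tone(self, f0, dur=10.0):
        t = np.arange(int(FS * dur)) / FS
        return Recording(np.sin(2 * np.pi * f0 * t)[None, :], FS, ["E00"])

    def _rms_mid(self, rec):
        x = rec.data[0]
        mid = x[len(x) // 4: -len(x) // 4]
        return np.sqrt(np.mean(mid**2))

    def test_line_harmonic_notched_in_ripple_band(self):
        out = preprocess(self._tone(180.0), "ripple")
        assert self._rms_mid(out) < 0.01 * np.sqrt(0.5)

    def test_passband_tone_preserved(self):
        out = preprocess(self._tone(140.0), "ripple")
        ratio = self._rms_mid(out) / np.sqrt(0.5)
        assert 10 ** (-1 / 20) < ratio <= 1.01  # within 1 dB

    def test_stopband_attenuation_at_least_40_db(self):
        out = preprocess(self._tone(300.0), "ripple")
        assert self._rms_mid(out) < 0.01 * np.sqrt(0.5)

    def test_fr_band_at_nyquist_edge_accepted(self):
        # fs=1000 with FR 250-500: upper edge == Nyquist, high-pass fallback
        out = preprocess(self._tone(350.0), "fast_ripple")
        assert self._rms_mid(out) > 0.8 * np.sqrt(0.5)

    def test_too_low_fs_rejected(self):
        rec = Recording(np.zeros((1, 100)), 100.0, ["E00"])
        with pytest.raises(ValueError):
            preprocess(rec, "ripple")


class TestRmsEnvelope:
    def test_constant_signal_gives_absolute_value(self):
        env = rms_envelope(np.full(100, -3.0), FS, 0.003)
        np.testing.assert_allclose(env, 3.0)

    def test_zeros_give_zeros(self):
        assert not rms_envelope(np.zeros(50), FS, 0.003).any()

    def test_matches_brute_force_sliding_rms(self, rng):
        t = np.arange(1000) / FS
        x = np.sin(2 * np.pi * 100 * t) + rng.normal(size=1000)
        w = 3
        env = rms_envelope(x, FS, 0.003)
        for i in range(len(x)):
            lo, hi = max(0, i - w // 2), min(len(x), i - w // 2 + w)
            assert env[i] == pytest.approx(np.sqrt(np.mean(x[lo:hi] ** 2)))

    def test_subsample_window_rejected(self):
        with pytest.raises(ValueError):
            rms_envelope(np.zeros(10), 100.0, 0.003)


class TestStage1:
    def test_subthreshold_envelope_yields_nothing(self):
        env = np.ones(1000) + 0.01 * np.sin(np.arange(1000))
        params = DetectorParams()
        assert stage1_candidates(env, FS, params) == []

    def test_run_shorter_than_minimum_duration_rejected(self):
        env = np.ones(1000)
        env[0:500:2] = 1.2  # alternation supplies variance; stays sub-threshold
        env[600:604] = 10.0  # one 4 ms supra-threshold run at 1 kHz
        assert stage1_candidates(env, FS, DetectorParams()) == []

    def test_zero_variance_segment_skipped(self):
        assert stage1_candidates(np.ones(100), FS, DetectorParams()) == []

    def test_matches_exhaustive_scanner_on_random_envelopes(self):
        rng = np.random.default_rng(7)
        params = DetectorParams()
        for _ in range(100):
            env = random_envelope(rng)
            assert stage1_candidates(env, FS, params) == brute_stage1(env, FS, params)


class TestStage2:
    def _segment_with_spikes(self, k):
        """Low-level jitter with k well-separated rectified excursions."""
        rng = np.random.default_rng(1)
        x = 0.1 * rng.normal(size=1000)
        for j in range(k):
            i = 300 + 12 * j
            x[i: i + 4] = [5.0, 9.0, 9.0, 5.0]
        return x

    def test_five_peaks_rejected_six_accepted(self):
        params = DetectorParams()
        cand = [(290, 290 + 12 * 7)]
        assert stage2_qualify(self._segment_with_spikes(5), cand, FS, params) == []
        kept = stage2_qualify(self._segment_with_spikes(6), cand, FS, params)
        assert len(kept) == 1 and kept[0].n_peaks == 6

    def test_burst_peak_count_tracks_rectified_rate(self):
        # 60 ms at 140 Hz: ~2 * f0 * d = 16.8 rectified half-waves
        rng = np.random.default_rng(2)
        t = np.arange(1000) / FS
        x = 0.05 * rng.normal(size=1000)
        sl = slice(400, 460)
        x[sl] += 10 * np.sin(2 * np.pi * 140 * t[sl])
        kept = stage2_qualify(x, [(400, 460)], FS, DetectorParams())
        assert len(kept) == 1
        assert 13 <= kept[0].n_peaks <= 20

    def test_candidate_without_suprathreshold_samples_rejected(self):
        x = np.random.default_rng(3).normal(size=1000)
        x[100:120] = 0.0
        assert stage2_qualify(x, [(100, 120)], FS, DetectorParams()) == []

    def test_matches_exhaustive_scanner_on_random_segments(self):
        rng = np.random.default_rng(11)
        params = DetectorParams()
        for _ in range(100):
            x = rng.normal(size=1000) * rng.uniform(0.5, 3)
            for _ in range(rng.integers(0, 4)):
                i = int(rng.integers(0, 900))
                x[i:i + int(rng.integers(10, 80))] += rng.uniform(4, 15)
            cands = [(int(a), int(a) + int(b)) for a, b in
                     zip(rng.integers(0, 900, 3), rng.integers(10, 100, 3))]
            kept = {(e.start, e.end) for e in stage2_qualify(x, cands, FS, params)}
            expected = {c for c in cands if brute_stage2_keep(x, c, params)}
            assert kept == expected


class TestArtifactRejection:
    def _burst_record(self, seed=0, n=60_000):
        rng = np.random.default_rng(seed)
        t = np.arange(n) / FS
        x = rng.normal(0, 2.0, size=n)
        sl = slice(30_000, 30_050)
        x[sl] += 40 * np.sin(2 * np.pi * 300 * t[: 50])
        return Recording(x[None, :], FS, ["E00"])

    def test_car_coincident_event_removed(self):
        rec = self._burst_record()
        without_car = detect_hfos(rec, "fast_ripple")
        assert len(without_car) >= 1
        # the CAR carries the identical burst -> everything must go
        with_car = detect_hfos(rec, "fast_ripple", car_signal=rec.data[0].copy())
        assert with_car == []

    def test_dc_step_ringing_removed(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1.0, size=60_000)
        x[30_000:] += 200.0  # DC shift
        rec = Recording(x[None, :], FS, ["E00"])
        raw = detect_hfos(rec, "fast_ripple", reject=False)
        near_step = [e for e in raw if abs(e.start - 30_000) < 200]
        assert near_step  # band-pass ringing is detected...
        kept = detect_hfos(rec, "fast_ripple")
        assert all(abs(e.start - 30_000) >= 200 for e in kept)  # ...and rejected

    def test_genuine_bursts_survive_rejection(self, snr5_batch):
        for rec, _ in snr5_batch:
            raw = detect_hfos(rec, "fast_ripple", reject=False)
            kept = reject_artifacts(raw, rec, None, "fast_ripple")
            assert len(kept) >= 0.95 * len(raw)


class TestDetectHfos:
    def test_detection_is_deterministic(self, short_record):
        rec, events = short_record
        again = detect_hfos(rec, "fast_ripple")
        assert [(e.start, e.end) for e in again] == [(e.start, e.end) for e in events]

    def test_gain_invariance_under_tenfold_scaling(self, short_record):
        rec, events = short_record
        scaled = rec.copy_with(rec.data * 10.0)
        events10 = detect_hfos(scaled, "fast_ripple")
        assert [(e.channel, e.start, e.end) for e in events10] == \
               [(e.channel, e.start, e.end) for e in events]

    def test_raising_threshold_multiplier_shrinks_candidate_coverage(self, short_record):
        # with merging disabled, the samples covered by stage-1 candidates
        # are nested as the threshold multiplier rises (event counts alone
        # are not monotone: merging/splitting of runs breaks them)
        rec, _ = short_record
        env = rms_envelope(preprocess(rec, "fast_ripple").data[0], rec.fs, 0.003)
        prev = None
        for s in (2.5, 3.0, 3.5, 4.0):
            params = DetectorParams(n_sd=s, merge_gap=1e-4)
            cover = set()
            for a, b in stage1_candidates(env, rec.fs, params):
                cover.update(range(a, b))
            if prev is not None:
                assert cover <= prev
            prev = cover

    def test_recall_on_high_snr_injections(self, snr5_batch):
        hits = total = 0
        durs = []
        for rec, events in snr5_batch:
            a, b, d = match_events(rec, events)
            hits += a
            total += b
            durs.extend(d)
        assert hits / total >= 0.9
        med_err = np.median(np.abs(np.asarray(durs) / 0.05 - 1.0))
        assert med_err <= 0.25
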