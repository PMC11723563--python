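"""Shared fixtures: small simulated records, SNR-controlled fixtures.

Expensive simulations are session-scoped so the suite stays fast.  The
in-band background RMS of the default generator (fast-ripple band) was
measured once at 4.08 uV; SNR-controlled fixtures set the pulse amplitude
as a multiple of that.
"""

from __future__ import annotations

import numpy as np
import pytest

import hfoscale as h
from hfoscale import dists

FR_INBAND_BG_RMS = 4.08  # uV, default background filtered to 250-500 Hz


def snr5_config(seed: int) -> h.SimulationConfig:
    """2-minute FR record with full-coverage, fixed-duration SNR-5 bursts."""
    return h.default_config(
        duration=120.0,
        seed=seed,
        dist_K=dists.constant(5 * FR_INBAND_BG_RMS),
        dist_rho=dists.uniform(1.0, 3.0),
        dist_d=dists.constant(0.05),
        dist_f0=dists.uniform(260.0, 400.0),
    )


def match_events(rec, events):
    """(hits, total, recovered durations) against the injected train."""
    hits, total, durs = 0, 0, []
    for pulse in rec.ground_truth[0].trains[0].pulses:
        total += 1
        matched = [e for e in events
                   if pulse.onset <= (e.start_s + e.end_s) / 2 <= pulse.offset]
        if matched:
            hits += 1
            durs.append(sum(e.duration_s for e in matched))
    return hits, total, durs


@pytest.fixture(scope="session")
def snr5_batch():
    """Four SNR-5 records with their detections (FR band, defaults)."""
    out = []
    for seed in range(4):
        rec = h.simulate_recording(snr5_config(seed))
        events = h.detect_hfos(rec, "fast_ripple")
        out.append((rec, events))
    return out


@pytest.fixture(scope="session")
def short_record():
    """One 60-s default FR record (mixed SNRs) with its detections."""
    cfg = h.default_config(duration=60.0, seed=42)
    rec = h.simulate_recording(cfg)
    return rec, h.detect_hfos(rec, "fast_ripple")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
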