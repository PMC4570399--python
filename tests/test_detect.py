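"""NEO detection: operator algebra, thresholding, alignment and the brute-force oracle."""

import numpy as np
import pytest

from ghasort import (
    DetectorConfig,
    GenConfig,
    Recording,
    auto_threshold,
    detect_all,
    detect_channel,
    generate_recording,
    make_templates,
    neo,
)
from ghasort.cluster import match_detections

from conftest import insert_template


# ---------------------------------------------------------------------------
# the operator itself


def test_neo_direct_substitution():
    assert neo(np.array([0.0, 2.0, 0.0]))[1] == 4.0


def test_neo_constant_trace_vanishes():
    psi = neo(np.full(50, 3.7))
    assert np.allclose(psi[1:-1], 0.0)
    assert psi[0] == psi[-1] == 0.0


def test_neo_sinusoid_closed_form():
    """For s_k = A sin(w k) the operator is the constant A^2 sin^2(w)."""
    A, w = 1.0, 0.2
    k = np.arange(2000)
    psi = neo(A * np.sin(w * k))
    assert np.allclose(psi[1:-1], A**2 * np.sin(w) ** 2, atol=1e-9)


def test_neo_requires_three_samples():
    with pytest.raises(ValueError):
        neo(np.array([1.0, 2.0]))


# ---------------------------------------------------------------------------
# thresholding


def test_auto_threshold_constant_values():
    assert auto_threshold(np.full(10, 2.5), c_mult=1.0) == pytest.approx(2.5)


def test_auto_threshold_degenerate_all_zero_warns():
    with pytest.warns(UserWarning, match="degenerate"):
        assert auto_threshold(np.zeros(3), c_mult=8.0) == 0.0


def test_auto_threshold_law_of_large_numbers():
    rng = np.random.default_rng(0)
    v = rng.uniform(0, 1, size=1_000_000)
    assert auto_threshold(v, c_mult=2.0) == pytest.approx(1.0, rel=0.02)


# ---------------------------------------------------------------------------
# channel detection


def test_noiseless_single_spike_detected_and_aligned():
    tpl = make_templates(1, 64, seed=3)[0]
    cfg = DetectorConfig(gamma=0.05)
    trace = insert_template(2000, tpl, [700])
    spikes = detect_channel(trace, cfg)
    assert len(spikes) == 1
    sp = spikes[0]
    assert sp.peak_index == 700
    assert sp.waveform[cfg.peak_offset] == trace[700] == pytest.approx(1.0)
    assert sp.waveform.size == cfg.m


def test_threshold_above_global_max_yields_nothing():
    tpl = make_templates(1, 64, seed=3)[0]
    trace = insert_template(2000, tpl, [700])
    assert detect_channel(trace, DetectorConfig(gamma=1e6)) == []


def test_two_well_separated_spikes():
    tpl = make_templates(1, 64, seed=5)[0]
    peaks = [400, 400 + 5 * 64]
    trace = insert_template(2000, tpl, peaks)
    spikes = detect_channel(trace, DetectorConfig(gamma=0.05))
    assert [sp.peak_index for sp in spikes] == peaks


def test_accepted_hits_respect_dead_time():
    rng = np.random.default_rng(11)
    cfg = DetectorConfig()
    for _ in range(20):
        trace = rng.standard_normal(3000)
        hits = [sp.peak_index for sp in detect_channel(trace, cfg)]
        assert all(b - a >= cfg.dead_time for a, b in zip(hits, hits[1:]))


# ---------------------------------------------------------------------------
# multi-channel merge


def test_single_channel_recording_equals_detect_channel():
    tpl = make_templates(1, 64, seed=5)[0]
    trace = insert_template(4000, tpl, [500, 1500])
    cfg = DetectorConfig(gamma=0.05)
    rec = Recording(channels=trace[None, :], rs=24_000)
    merged = detect_all(rec, cfg)
    single = detect_channel(trace, cfg)
    assert [s.peak_index for s in merged] == [s.peak_index for s in single]


def test_simultaneous_hits_ordered_by_channel():
    tpl = make_templates(1, 64, seed=5)[0]
    trace = insert_template(2000, tpl, [600])
    rec = Recording(channels=np.vstack([trace, trace]), rs=24_000)
    spikes = detect_all(rec, DetectorConfig(gamma=0.05))
    assert [sp.channel for sp in spikes] == [0, 1]
    assert spikes[0].detect_time < spikes[1].detect_time


def test_four_channels_merged_in_time_order():
    tpl = make_templates(1, 64, seed=5)[0]
    peaks = [1200, 300, 900, 600]
    traces = np.vstack([insert_template(2000, tpl, [k]) for k in peaks])
    rec = Recording(channels=traces, rs=24_000)
    spikes = detect_all(rec, DetectorConfig(gamma=0.05))
    assert [sp.peak_index for sp in spikes] == sorted(peaks)
    assert [sp.channel for sp in spikes] == [1, 3, 2, 0]


# ---------------------------------------------------------------------------
# brute-force oracle equivalence and sensitivity


def brute_force_detect(trace, cfg):
    """Literal scan: evaluate the operator at every sample, apply the same rules."""
    s = np.asarray(trace, dtype=np.float64)
    n = s.size
    psi = np.zeros(n)
    for k in range(1, n - 1):
        psi[k] = s[k] ** 2 - s[k - 1] * s[k + 1]
    gamma = cfg.gamma if cfg.gamma is not None else cfg.c_mult * psi.mean()
    hits = []
    last = -np.inf
    for k in range(n):
        if not psi[k] > gamma:
            continue
        lo, hi = max(0, k - cfg.dead_time), min(n, k + cfg.dead_time + 1)
        if s[k] != max(s[lo:hi]):
            continue
        start = k - cfg.peak_offset
        if start < 0 or start + cfg.m > n:
            continue
        if k - last < cfg.dead_time:
            continue
        hits.append(k)
        last = k
    return hits


def test_detect_channel_equals_brute_force_scan():
    rng = np.random.default_rng(42)
    tpl = make_templates(1, 64, seed=9)[0]
    cfg = DetectorConfig()
    for trial in range(100):
        trace = rng.standard_normal(600) * 0.3
        for k in rng.integers(40, 560, size=rng.integers(0, 4)):
            start = int(k) - tpl.peak_index
            if 0 <= start <= 600 - 64:
                trace[start : start + 64] += tpl.waveform
        got = [sp.peak_index for sp in detect_channel(trace, cfg)]
        assert got == brute_force_detect(trace, cfg)


def test_detection_sensitivity_across_snr():
    """>= 95% of true peaks recovered (+/-3 samples) at 10 dB; non-increasing with noise."""
    rates = {}
    for snr in (10.0, 8.0, 6.0):
        hit, total = 0, 0
        for trial in range(20):
            cfg = GenConfig(n_neurons=2, snr_db=snr, duration_s=5.0, seed=100 + trial)
            rec, gt = generate_recording(cfg)
            spikes = detect_all(rec)
            midx, _, _, miss = match_detections(spikes, gt)
            hit += len(midx)
            total += len(gt.events)
        rates[snr] = hit / total
    assert rates[10.0] >= 0.95
    se = 0.02  # Monte-Carlo slack on ~1500 events
    assert rates[10.0] >= rates[8.0] - se
    assert rates[8.0] >= rates[6.0] - se
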