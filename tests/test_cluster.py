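"""Fuzzy c-means, CSR scoring and the end-to-end evaluation protocol."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from ghasort import GenConfig, TrainConfig, csr, evaluate_pipeline, fcm, match_detections
from ghasort.detect import DetectedSpike
from ghasort.synthgen import GroundTruth, make_templates


# ---------------------------------------------------------------------------
# fuzzy c-means


def test_single_cluster_closed_form():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((40, 3))
    res = fcm(X, k=1, seed=0)
    assert np.allclose(res.centers[0], X.mean(axis=0), atol=1e-6)
    assert np.allclose(res.memberships, 1.0)


def test_well_separated_clouds_are_split_perfectly():
    rng = np.random.default_rng(1)
    a = rng.standard_normal((60, 2)) * 0.1 + [0, 0]
    b = rng.standard_normal((60, 2)) * 0.1 + [10, 10]
    X = np.vstack([a, b])
    res = fcm(X, k=2, seed=1)
    # brute-force nearest-center reference
    d = np.linalg.norm(X[:, None, :] - res.centers[None], axis=2)
    assert np.array_equal(res.hard_labels, np.argmin(d, axis=1))
    assert len(set(res.hard_labels[:60])) == 1
    assert len(set(res.hard_labels[60:])) == 1
    assert res.hard_labels[0] != res.hard_labels[-1]


def test_memberships_normalized_and_objective_monotone():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((80, 2))
    res = fcm(X, k=3, seed=2)
    assert np.allclose(res.memberships.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(res.memberships >= 0) and np.all(res.memberships <= 1)
    diffs = np.diff(res.objective_trace)
    assert np.all(diffs <= 1e-8 * max(1.0, res.objective_trace[0]))


def test_fcm_is_deterministic_given_seed():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((50, 2))
    a = fcm(X, k=2, seed=7)
    b = fcm(X, k=2, seed=7)
    assert np.array_equal(a.hard_labels, b.hard_labels)
    assert a.objective == b.objective


def test_fcm_validates_arguments():
    X = np.zeros((3, 2))
    with pytest.raises(ValueError):
        fcm(X, k=5)
    with pytest.raises(ValueError):
        fcm(X, k=2, fuzzifier=1.0)


# ---------------------------------------------------------------------------
# CSR scoring


def test_identical_labels_score_100():
    y = np.array([0, 1, 0, 1, 2])
    assert csr(y, y).csr_percent == 100.0


def test_permuted_cluster_ids_score_100():
    true = np.array([0, 0, 1, 1, 2, 2])
    pred = np.array([2, 2, 0, 0, 1, 1])
    assert csr(pred, true).csr_percent == 100.0


def test_confusion_matrix_best_assignment():
    """Confusion [[40,10],[10,40]] over n=100 gives 80% under the diagonal matching."""
    true = np.repeat([0, 1], 50)
    pred = np.concatenate([np.repeat(0, 40), np.repeat(1, 10),
                           np.repeat(0, 10), np.repeat(1, 40)])
    rep = csr(pred, true)
    assert rep.csr_percent == pytest.approx(80.0)
    assert rep.confusion.tolist() == [[40, 10], [10, 40]]


def test_exhaustive_matching_agrees_with_hungarian():
    rng = np.random.default_rng(4)
    for _ in range(20):
        k_t, k_p = rng.integers(2, 5, size=2)
        true = rng.integers(0, k_t, size=60)
        pred = rng.integers(0, k_p, size=60)
        rep = csr(pred, true)
        conf = rep.confusion
        r, c = linear_sum_assignment(-conf)
        assert rep.csr_percent == pytest.approx(100.0 * conf[r, c].sum() / 60)


def test_csr_bounded_and_unmatchable_sizes_rejected():
    with pytest.raises(ValueError):
        csr(np.arange(9), np.arange(9))  # more than 8 labels per side


# ---------------------------------------------------------------------------
# detection-to-truth matching


def _spike(channel, peak):
    return DetectedSpike(channel=channel, peak_index=peak, waveform=np.zeros(4))


def test_match_detections_window_and_false_alarms():
    tpl = make_templates(1, 64, seed=0)
    gt = GroundTruth(events=[(0, 0, 100), (0, 0, 300)], templates=tpl)
    spikes = [_spike(0, 102), _spike(0, 250), _spike(0, 301)]
    midx, labels, fa, miss = match_detections(spikes, gt, window=3)
    assert midx.tolist() == [0, 2]
    assert labels.tolist() == [0, 0]
    assert fa == 1 and miss == 0


def test_match_detections_each_truth_used_once():
    tpl = make_templates(1, 64, seed=0)
    gt = GroundTruth(events=[(0, 0, 100)], templates=tpl)
    spikes = [_spike(0, 100), _spike(0, 101)]
    midx, _, fa, miss = match_detections(spikes, gt, window=3)
    assert len(midx) == 1 and fa == 1 and miss == 0


# ---------------------------------------------------------------------------
# end-to-end protocol


def test_noiseless_two_neuron_pipeline_is_perfect():
    """In the separable high-SNR limit every isolated spike is classified
    correctly (spikes from different neurons may superpose; the summed
    waveform belongs to neither class and is excluded here)."""
    from ghasort import detect_all, extract_features, generate_recording, train

    for seed in (1, 2, 3, 4, 5):
        cfg = GenConfig(n_neurons=2, duration_s=5.0, snr_db=60.0, seed=seed)
        rec, gt = generate_recording(cfg)
        spikes = detect_all(rec)
        midx, labels, fa, miss = match_detections(spikes, gt)
        # the only permissible misses are spikes suppressed by a colliding
        # event within the detector dead time
        assert miss <= 5
        X = np.array([sp.waveform for sp in spikes])
        ws = train(X, p=2, cfg=TrainConfig(seed=seed))
        feats = extract_features(X, ws)[midx]
        peaks = sorted(t for _, _, t in gt.events)
        isolated_peaks = {
            t for i, t in enumerate(peaks)
            if (i == 0 or t - peaks[i - 1] >= cfg.m)
            and (i == len(peaks) - 1 or peaks[i + 1] - t >= cfg.m)
        }
        iso = np.array(
            [spikes[i].peak_index in isolated_peaks or
             any(abs(spikes[i].peak_index - t) <= 3 for t in isolated_peaks)
             for i in midx]
        )
        res = fcm(feats, k=2, seed=seed)
        rep = csr(res.hard_labels, np.asarray(labels))
        mapped = np.array([rep.matching[c] for c in res.hard_labels])
        assert np.array_equal(mapped[iso], np.asarray(labels)[iso])


def test_float_backend_not_worse_than_fixed_by_more_than_a_point():
    """Paired seeds: double-precision features cluster at least as well as
    quantized ones, within one point."""
    seeds = (1, 2, 3)
    kw = dict(k=3, snrs=(6.0,), seeds=seeds)
    base = GenConfig(n_neurons=3)
    df_f = evaluate_pipeline(base, train_cfg=TrainConfig(backend="float"), **kw)
    df_x = evaluate_pipeline(base, train_cfg=TrainConfig(backend="fixed17"), **kw)
    for s in seeds:
        f = df_f[df_f.seed == s]["csr_percent"].iloc[0]
        x = df_x[df_x.seed == s]["csr_percent"].iloc[0]
        assert f >= x - 1.0
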