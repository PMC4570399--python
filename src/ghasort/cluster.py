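"""Fuzzy c-means clustering of feature vectors and classification scoring.

Spike-sorting quality is scored as the classification success rate
(CSR): the fraction of spikes assigned to the right neuron, maximized
over all injective cluster-to-neuron label assignments (cluster ids are
arbitrary).  Feature vectors are clustered with fuzzy c-means (FCM),
alternating soft-membership and center updates that minimize

    J = sum_ik  u_ik**f * ||x_i - c_k||**2,   sum_k u_ik = 1,

with fuzzifier f > 1.  The end-to-end evaluation mirrors the standard
benchmark protocol: synthesize recordings at several SNRs, detect,
train the Hebbian feature extractor, project, cluster, and score
detections matched to ground-truth peaks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .detect import DetectorConfig, detect_all
from .gha import TrainConfig, extract_features, train
from .synthgen import GenConfig, GroundTruth, generate_recording

__all__ = [
    "ClusterResult",
    "CSRReport",
    "fcm",
    "csr",
    "match_detections",
    "evaluate_pipeline",
]


@dataclass
class ClusterResult:
    memberships: np.ndarray    # (n, k), rows sum to 1
    centers: np.ndarray        # (k, p)
    hard_labels: np.ndarray    # (n,)
    objective: float
    objective_trace: np.ndarray
    n_iter: int


@dataclass
class CSRReport:
    csr_percent: float
    confusion: np.ndarray      # (k_true, k_pred)
    matching: dict[int, int]   # cluster id -> true label


def _fcm_once(
    X: np.ndarray, k: int, fuzzifier: float, tol: float, max_iter: int,
    rng: np.random.Generator,
) -> ClusterResult:
    n = X.shape[0]
    # initial centers: k distinct data points
    for _ in range(32):
        centers = X[rng.choice(n, size=k, replace=False)].astype(np.float64)
        if len({tuple(c) for c in centers}) == k:
            break
    else:
        raise RuntimeError("could not draw k distinct initial centers")
    expo = 2.0 / (fuzzifier - 1.0)
    obj_trace = []
    U = None
    for it in range(max_iter):
        d2 = cdist(X, centers, metric="sqeuclidean")
        d2 = np.maximum(d2, 1e-300)
        inv = d2 ** (-expo / 2.0)
        U = inv / inv.sum(axis=1, keepdims=True)
        Uf = U**fuzzifier
        new_centers = (Uf.T @ X) / Uf.sum(axis=0)[:, None]
        obj_trace.append(float(np.sum(Uf * cdist(X, new_centers, metric="sqeuclidean"))))
        shift = float(np.max(np.abs(new_centers - centers)))
        centers = new_centers
        if shift < tol:
            break
    return ClusterResult(
        memberships=U,
        centers=centers,
        hard_labels=np.argmax(U, axis=1),
        objective=obj_trace[-1],
        objective_trace=np.asarray(obj_trace),
        n_iter=len(obj_trace),
    )


def fcm(
    features: np.ndarray,
    k: int,
    fuzzifier: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int | None = None,
    n_init: int = 5,
) -> ClusterResult:
    """Fuzzy c-means with several seeded restarts, keeping the best objective."""
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("features must be (n, p)")
    n = X.shape[0]
    if not (1 <= k <= n):
        raise ValueError("need n >= k >= 1")
    if fuzzifier <= 1.0:
        raise ValueError("fuzzifier must be > 1")
    rng = np.random.default_rng(seed)
    best: ClusterResult | None = None
    for _ in range(n_init):
        res = _fcm_once(X, k, fuzzifier, tol, max_iter, rng)
        if best is None or res.objective < best.objective:
            best = res
    return best


def csr(hard_labels: np.ndarray, true_labels: np.ndarray) -> CSRReport:
    """Classification success rate under the best injective label matching.

    The matching is exhaustive over all injective assignments of cluster
    ids to true labels (intended for k <= 8).
    """
    pred = np.asarray(hard_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError("label arrays must have equal length")
    true_ids = sorted(set(true.tolist()))
    pred_ids = sorted(set(pred.tolist()))
    if len(true_ids) > 8 or len(pred_ids) > 8:
        raise ValueError("exhaustive matching supports at most 8 labels per side")
    conf = np.zeros((len(true_ids), len(pred_ids)), dtype=np.int64)
    t_pos = {t: i for i, t in enumerate(true_ids)}
    p_pos = {c: j for j, c in enumerate(pred_ids)}
    for t, c in zip(true, pred):
        conf[t_pos[t], p_pos[c]] += 1
    # exhaustive injective assignment, smaller side onto the larger
    best_correct = -1
    best_map: dict[int, int] = {}
    if len(pred_ids) <= len(true_ids):
        for perm in itertools.permutations(range(len(true_ids)), len(pred_ids)):
            correct = sum(conf[perm[j], j] for j in range(len(pred_ids)))
            if correct > best_correct:
                best_correct = correct
                best_map = {pred_ids[j]: true_ids[perm[j]] for j in range(len(pred_ids))}
    else:
        for perm in itertools.permutations(range(len(pred_ids)), len(true_ids)):
            correct = sum(conf[i, perm[i]] for i in range(len(true_ids)))
            if correct > best_correct:
                best_correct = correct
                best_map = {pred_ids[perm[i]]: true_ids[i] for i in range(len(true_ids))}
    return CSRReport(
        csr_percent=100.0 * best_correct / max(len(true), 1),
        confusion=conf,
        matching=best_map,
    )


def match_detections(
    spikes, gt: GroundTruth, window: int = 3
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Pair detections with ground-truth peaks within +/- window samples.

    Greedy in time order, each true event used at most once.  Returns
    (matched detection indices, their true neuron labels, n_false_alarms,
    n_misses).
    """
    matched_idx: list[int] = []
    labels: list[int] = []
    used: set[tuple[int, int]] = set()
    by_channel: dict[int, list[tuple[int, int]]] = {}
    for c, nid, t in gt.events:
        by_channel.setdefault(c, []).append((t, nid))
    for c in by_channel:
        by_channel[c].sort()
    false_alarms = 0
    for i, sp in enumerate(spikes):
        evs = by_channel.get(sp.channel, [])
        best = None
        for t, nid in evs:
            if (sp.channel, t) in used:
                continue
            d = abs(t - sp.peak_index)
            if d <= window and (best is None or d < best[0]):
                best = (d, t, nid)
        if best is None:
            false_alarms += 1
        else:
            used.add((sp.channel, best[1]))
            matched_idx.append(i)
            labels.append(best[2])
    misses = len(gt.events) - len(matched_idx)
    return np.asarray(matched_idx, dtype=np.int64), np.asarray(labels), false_alarms, misses


def evaluate_pipeline(
    gen_cfg: GenConfig | None = None,
    detector_cfg: DetectorConfig | None = None,
    train_cfg: TrainConfig | None = None,
    k: int | None = None,
    snrs: tuple[float, ...] = (6.0, 8.0, 10.0),
    seeds: tuple[int, ...] = (1, 2, 3, 4, 5),
    match_window: int = 3,
) -> pd.DataFrame:
    """End-to-end CSR evaluation: generate -> detect -> train -> project -> FCM -> CSR.

    Returns one row per (snr_db, seed) with the CSR on matched spikes,
    detection counts, false alarms and misses; false alarms are excluded
    from the clustered set and reported separately.  Aggregate with
    ``df.groupby("snr_db")["csr_percent"].mean()``.
    """
    gen_cfg = gen_cfg or GenConfig()
    detector_cfg = detector_cfg or DetectorConfig()
    train_cfg = train_cfg or TrainConfig()
    k = k if k is not None else gen_cfg.n_neurons
    rows = []
    for snr in snrs:
        for seed in seeds:
            cfg = replace(gen_cfg, snr_db=snr, seed=int(seed))
            rec, gt = generate_recording(cfg)
            spikes = detect_all(rec, detector_cfg)
            midx, labels, fa, miss = match_detections(spikes, gt, window=match_window)
            row = {
                "snr_db": snr, "seed": int(seed), "backend": train_cfg.backend,
                "n_detected": len(spikes), "n_matched": len(midx),
                "false_alarms": fa, "misses": miss,
                "csr_percent": np.nan,
            }
            if len(midx) >= max(k, 2):
                X = np.array([sp.waveform for sp in spikes])
                tc = replace(train_cfg, seed=int(seed))
                ws = train(X, p=2, cfg=tc)
                feats = extract_features(X, ws)[midx]
                labs = np.asarray(labels)
                res = fcm(feats, k=k, seed=int(seed))
                row["csr_percent"] = csr(res.hard_labels, labs).csr_percent
            rows.append(row)
    return pd.DataFrame(rows)
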