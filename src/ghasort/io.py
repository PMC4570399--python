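"""CSV/JSON writers and readers for detections, weights and features."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .detect import DetectedSpike
from .gha import WeightSet

__all__ = [
    "write_spikes_csv",
    "read_spikes_csv",
    "write_weights",
    "read_weights",
    "write_features_csv",
    "write_events_json",
]


def write_spikes_csv(spikes: list[DetectedSpike], path: str | Path) -> Path:
    """Detected spikes: channel, peak_index, detect_time, m waveform columns."""
    path = Path(path)
    if spikes:
        m = spikes[0].waveform.size
        rows = [
            [sp.channel, sp.peak_index, sp.detect_time, *sp.waveform.tolist()]
            for sp in spikes
        ]
        cols = ["channel", "peak_index", "detect_time"] + [f"s{i}" for i in range(m)]
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    else:
        pd.DataFrame(columns=["channel", "peak_index", "detect_time"]).to_csv(
            path, index=False
        )
    return path


def read_spikes_csv(path: str | Path) -> list[DetectedSpike]:
    df = pd.read_csv(path)
    wave_cols = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
    wave_cols.sort(key=lambda c: int(c[1:]))
    return [
        DetectedSpike(
            channel=int(r["channel"]),
            peak_index=int(r["peak_index"]),
            detect_time=int(r["detect_time"]),
            waveform=np.asarray([r[c] for c in wave_cols], dtype=np.float64),
        )
        for _, r in df.iterrows()
    ]


def write_weights(ws: WeightSet, csv_path: str | Path) -> Path:
    """Weight vectors as CSV (p rows x m columns) plus a JSON metadata sidecar."""
    csv_path = Path(csv_path)
    np.savetxt(csv_path, ws.weights, delimiter=",")
    meta = {"channel": ws.channel, "n_updates": ws.n_updates, "backend": ws.backend}
    csv_path.with_suffix(csv_path.suffix + ".json").write_text(json.dumps(meta))
    return csv_path


def read_weights(csv_path: str | Path) -> WeightSet:
    csv_path = Path(csv_path)
    W = np.atleast_2d(np.loadtxt(csv_path, delimiter=","))
    meta_path = csv_path.with_suffix(csv_path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return WeightSet(
        weights=W,
        channel=meta.get("channel", 0),
        n_updates=meta.get("n_updates", 0),
        backend=meta.get("backend", "float"),
    )


def write_features_csv(features: np.ndarray, path: str | Path, labels=None) -> Path:
    path = Path(path)
    F = np.asarray(features, dtype=np.float64)
    cols = {f"y{j}": F[:, j] for j in range(F.shape[1])}
    if labels is not None:
        cols["label"] = np.asarray(labels)
    pd.DataFrame(cols).to_csv(path, index=False)
    return path


def write_events_json(spikes: list[DetectedSpike], path: str | Path) -> Path:
    path = Path(path)
    payload = [
        {"channel": sp.channel, "peak_index": sp.peak_index, "detect_time": sp.detect_time}
        for sp in spikes
    ]
    path.write_text(json.dumps(payload))
    return path
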