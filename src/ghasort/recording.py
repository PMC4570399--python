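"""Multi-channel extracellular recording container and raw int16 disk format.

Traces are held as a float64 array of shape (M, n_samples).  On disk a
recording is interleaved little-endian int16 frames (sample 0 of every
channel, then sample 1, ...) with a JSON sidecar carrying the sampling
rate, channel count, the float scale factor and provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Recording", "write_recording", "read_recording"]


@dataclass
class Recording:
    channels: np.ndarray            # (M, n_samples) float64
    rs: float = 24_000.0            # samples/s
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=np.float64))
        if self.rs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rs


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write interleaved little-endian int16 frames plus a ``.json`` sidecar.

    The scale factor maps ints back to volts-equivalent floats:
    ``trace = ints * scale``.  Returns the binary path; the sidecar sits
    next to it with extension ``.json``.
    """
    path = Path(path)
    peak = float(np.max(np.abs(rec.channels))) if rec.channels.size else 0.0
    scale = peak / 32767.0 if peak > 0 else 1.0
    ints = np.round(rec.channels / scale).astype("<i2")
    ints.T.reshape(-1).tofile(path)  # interleaved frames
    sidecar = {
        "rs": rec.rs,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "scale": scale,
        "dtype": "int16",
        "byte_order": "little",
        "layout": "interleaved-frames",
        "meta": rec.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    side = json.loads(sidecar_path.read_text())
    raw = np.fromfile(path, dtype="<i2")
    M, n = side["n_channels"], side["n_samples"]
    if raw.size != M * n:
        raise ValueError(
            f"{path}: expected {M * n} int16 samples, found {raw.size} "
            f"(truncated at byte offset {raw.size * 2})"
        )
    traces = raw.reshape(n, M).T.astype(np.float64) * side["scale"]
    return Recording(channels=traces, rs=side["rs"], meta=side.get("meta", {}))
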