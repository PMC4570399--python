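"""Spike detection by the nonlinear energy operator, with peak alignment.

The nonlinear energy operator (NEO) of a sampled trace s is

    psi_k = s_k**2 - s_{k-1} * s_{k+1},

large when the signal has simultaneously high amplitude and high
frequency, which makes a simple threshold gamma on psi an effective and
cheap spike detector.  A hit at sample k additionally requires s_k to be
the maximum of the raw trace over a +/- dead_time window (peak
refinement), and hits closer than dead_time to the previously accepted
hit on the same channel are suppressed (earliest wins).  The emitted
waveform is the m-sample window placing the peak at a fixed offset,
which aligns spikes across detections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d

__all__ = [
    "DetectorConfig",
    "DetectedSpike",
    "neo",
    "auto_threshold",
    "detect_channel",
    "detect_all",
]


@dataclass
class DetectorConfig:
    """Detection settings.

    ``gamma`` is an absolute NEO threshold; when None it is derived as
    ``c_mult * mean(psi)`` over the trace.  ``peak_offset`` is where the
    peak sits inside the emitted m-window (m/4 pre-peak samples by
    default, capturing the depolarization onset).  ``dead_time`` both
    refines the peak (local-max test) and suppresses duplicate hits for
    one spike.
    """

    m: int = 64
    peak_offset: int = 16
    gamma: float | None = None
    c_mult: float = 8.0
    dead_time: int = 32

    def __post_init__(self) -> None:
        if not (0 <= self.peak_offset < self.m):
            raise ValueError("need 0 <= peak_offset < m")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be > 0 when given")
        if self.dead_time < 1:
            raise ValueError("dead_time must be >= 1")
        if self.c_mult <= 0:
            raise ValueError("c_mult must be > 0")


@dataclass
class DetectedSpike:
    """One aligned detection: where it peaked and its m-sample waveform."""

    channel: int
    peak_index: int
    waveform: np.ndarray
    detect_time: int = 0


def neo(trace: np.ndarray) -> np.ndarray:
    """Nonlinear energy operator of a trace; endpoints defined as 0."""
    s = np.asarray(trace, dtype=np.float64)
    if s.ndim != 1 or s.size < 3:
        raise ValueError("trace must be 1-D with at least 3 samples")
    psi = np.zeros_like(s)
    psi[1:-1] = s[1:-1] ** 2 - s[:-2] * s[2:]
    return psi


def auto_threshold(neo_values: np.ndarray, c_mult: float = 8.0) -> float:
    """Data-driven threshold: a multiple of the mean NEO energy.

    Returns 0.0 (with a warning) for an all-zero input, in which case
    nothing can exceed the threshold.
    """
    v = np.asarray(neo_values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("neo_values must be nonempty")
    if c_mult <= 0:
        raise ValueError("c_mult must be > 0")
    gamma = c_mult * float(np.mean(v))
    if gamma == 0.0:
        warnings.warn("degenerate threshold: mean NEO energy is zero", stacklevel=2)
    return gamma


def detect_channel(
    trace: np.ndarray, cfg: DetectorConfig | None = None, channel: int = 0
) -> list[DetectedSpike]:
    """Detect and align spikes on one channel.

    A candidate k needs psi_k > gamma and trace[k] equal to the maximum
    of the raw trace over [k - dead_time, k + dead_time] (clipped to the
    trace bounds).  Candidates whose aligned window would overrun the
    trace are discarded before suppression bookkeeping; surviving hits
    closer than dead_time to the previous accepted hit are suppressed.
    """
    cfg = cfg or DetectorConfig()
    s = np.asarray(trace, dtype=np.float64)
    if s.size < cfg.m:
        raise ValueError(f"trace shorter than the spike window m={cfg.m}")
    psi = neo(s)
    gamma = cfg.gamma if cfg.gamma is not None else auto_threshold(psi, cfg.c_mult)
    if gamma <= 0:
        return []
    local_max = maximum_filter1d(s, size=2 * cfg.dead_time + 1, mode="constant",
                                 cval=-np.inf)
    candidates = np.flatnonzero((psi > gamma) & (s == local_max))
    spikes: list[DetectedSpike] = []
    last = -np.inf
    for k in candidates:
        start = k - cfg.peak_offset
        if start < 0 or start + cfg.m > s.size:
            continue
        if k - last < cfg.dead_time:
            continue
        spikes.append(
            DetectedSpike(
                channel=channel,
                peak_index=int(k),
                waveform=s[start : start + cfg.m].copy(),
            )
        )
        last = k
    return spikes


def detect_all(recording, cfg: DetectorConfig | None = None) -> list[DetectedSpike]:
    """Detect on every channel and merge in round-robin service order.

    Spikes are ordered by peak sample time, ties broken by channel index
    ascending; ``detect_time`` is the global round-robin sample counter
    ``peak_index * M + channel``.
    """
    cfg = cfg or DetectorConfig()
    M = recording.n_channels
    spikes: list[DetectedSpike] = []
    for ch in range(M):
        spikes.extend(detect_channel(recording.channels[ch], cfg, channel=ch))
    for sp in spikes:
        sp.detect_time = sp.peak_index * M + sp.channel
    spikes.sort(key=lambda sp: sp.detect_time)
    return spikes
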