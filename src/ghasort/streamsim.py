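"""Behavioral emulation of the shared multi-channel spike-sorting datapath.

All channels are sampled round-robin, one sample per clock cycle, so the
sample k of channel h is fetched at cycle ``floor(k * rc/rs) + h``.  A
detection hit writes the channel's single-spike memory unit -- if an
unserviced spike is still there it is overwritten (discarded for
training) and its stale queue entry removed -- and appends the channel
index to a FIFO of channels awaiting feature-extraction service.  One
shared server drains the FIFO first-come-first-serve, holding each spike
for ``latency_P`` cycles.

This reproduces the overwrite/discard accounting that the closed-form
capacity model (:mod:`ghasort.capacity`) bounds: with worst-case traffic
(every channel firing at the minimum peak gap Q) no spike is discarded
for M <= Mmax, and at least one is for M = Mmax + 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detect import DetectorConfig, detect_all

__all__ = [
    "StreamEvent",
    "StreamResult",
    "SpikeBufferState",
    "simulate_hits",
    "worst_case_hits",
    "run_stream",
    "busy_fraction",
]


@dataclass
class StreamEvent:
    t_cycles: int
    kind: str  # sample_in | hit | gha_start | gha_done | overwrite
    channel: int


@dataclass
class SpikeBufferState:
    """One-spike-per-channel memory plus the pending-channel FIFO."""

    n_channels: int
    memory_units: list = field(init=False)
    pending_fifo: list[int] = field(default_factory=list)
    overwritten_count: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.memory_units = [None] * self.n_channels
        self.overwritten_count = np.zeros(self.n_channels, dtype=np.int64)


@dataclass
class StreamResult:
    events: list[StreamEvent]
    discarded: np.ndarray          # per channel
    serviced: int
    pending: int
    hits: int
    total_cycles: int
    M: int
    latency_P: int
    rc: float
    rs: float


def simulate_hits(
    hit_cycles: list[tuple[int, int]],
    M: int,
    latency_P: int,
    total_cycles: int | None = None,
) -> StreamResult:
    """Event-driven queue simulation over a list of (cycle, channel) hits.

    Hits must be sorted by cycle (ties in arrival order).  A service
    start scheduled at or before a new arrival's cycle is processed
    first, so an overwrite arriving in the same cycle as the service
    start of that channel's spike finds the slot already drained.
    """
    if latency_P < 1:
        raise ValueError("latency_P must be >= 1")
    state = SpikeBufferState(M)
    log: list[StreamEvent] = []
    server_free = 0
    serviced = 0
    horizon = total_cycles if total_cycles is not None else np.inf

    def start_services(up_to: float) -> None:
        nonlocal server_free, serviced
        while state.pending_fifo:
            ch, arr = state.pending_fifo[0][0], state.pending_fifo[0][1]
            start = max(server_free, arr)
            if start > up_to or start >= horizon:
                break
            state.pending_fifo.pop(0)
            state.memory_units[ch] = None
            server_free = start + latency_P
            serviced += 1
            log.append(StreamEvent(int(start), "gha_start", ch))
            log.append(StreamEvent(int(server_free), "gha_done", ch))

    last_cycle = 0
    for cyc, ch in hit_cycles:
        start_services(up_to=cyc)
        log.append(StreamEvent(int(cyc), "hit", ch))
        if state.memory_units[ch] is not None:
            # unserviced spike overwritten: drop stale queue entry,
            # re-enqueue at the tail (most-recent semantics)
            state.overwritten_count[ch] += 1
            state.pending_fifo = [e for e in state.pending_fifo if e[0] != ch]
            log.append(StreamEvent(int(cyc), "overwrite", ch))
        state.memory_units[ch] = cyc
        state.pending_fifo.append((ch, cyc))
        last_cycle = max(last_cycle, cyc)
    # drain
    start_services(up_to=horizon)
    pending = len(state.pending_fifo)
    hits = sum(1 for e in log if e.kind == "hit")
    total = int(horizon) if np.isfinite(horizon) else int(max(last_cycle, server_free))
    # event log ordering can interleave at equal cycles; sort stably by time
    log.sort(key=lambda e: e.t_cycles)
    return StreamResult(
        events=log,
        discarded=state.overwritten_count.copy(),
        serviced=serviced,
        pending=pending,
        hits=hits,
        total_cycles=total,
        M=M,
        latency_P=latency_P,
        rc=float("nan"),
        rs=float("nan"),
    )


def worst_case_hits(
    M: int,
    Q: int,
    rs: float,
    rc: float,
    latency_P: int | None = None,
    n_bursts: int | None = None,
) -> list[tuple[int, int]]:
    """Adversarial traffic: every channel fires with peak gap exactly Q samples.

    Burst ``b`` places one hit per channel at cycle
    ``floor(b*Q*rc/rs) + h``.  When ``n_bursts`` is None and
    ``latency_P`` is given, enough bursts are generated for any
    sustained service deficit to surface as an overwrite: the backlog
    grows by ``d = M*P - Q*rc/rs`` cycles per burst, so an overwrite
    must occur within about ``(Q*rc/rs)/d`` bursts when ``d > 0``.
    """
    cpp = rc / rs  # cycles per sampling period
    if M > cpp:
        raise ValueError("round-robin fetch infeasible: M exceeds rc/rs")
    if n_bursts is None:
        n_bursts = 8
        if latency_P is not None:
            x = Q * cpp
            d = M * latency_P - x
            if d > 0:
                n_bursts = int(np.ceil(x / d)) + 4
    hits = []
    for b in range(n_bursts):
        base = int(np.floor(b * Q * cpp))
        for h in range(M):
            hits.append((base + h, h))
    return hits


def run_stream(
    recording,
    detector_cfg: DetectorConfig | None = None,
    rc: float = 1e6,
    latency_P: int = 40,
) -> StreamResult:
    """Detect spikes on a recording and replay them through the datapath model.

    A hit is issued at the cycle where the last sample of the aligned
    m-window is fetched for that channel, i.e. sample
    ``peak_index + m - 1 - peak_offset``.
    """
    detector_cfg = detector_cfg or DetectorConfig()
    M, rs = recording.n_channels, recording.rs
    if rc < M * rs:
        raise ValueError(
            f"clock rate rc={rc:g} below the round-robin fetch requirement "
            f"M*rs={M * rs:g}: one sample per channel per sampling period"
        )
    spikes = detect_all(recording, detector_cfg)
    cpp = rc / rs
    hit_cycles = []
    for sp in spikes:
        k_issue = sp.peak_index + detector_cfg.m - 1 - detector_cfg.peak_offset
        hit_cycles.append((int(np.floor(k_issue * cpp)) + sp.channel, sp.channel))
    hit_cycles.sort(key=lambda e: e[0])
    total_cycles = int(np.ceil(recording.n_samples * cpp))
    res = simulate_hits(hit_cycles, M, latency_P, total_cycles=total_cycles)
    res.rc = rc
    res.rs = rs
    return res


def busy_fraction(result: StreamResult) -> dict[str, float]:
    """Active-cycle fractions for the main components (idle/active accounting).

    The detection buffer shifts during the M fetch cycles of each
    sampling period; the spike buffer is active one cycle per write
    (hit) and per service start; the feature-extraction server is busy
    latency_P cycles per serviced spike.
    """
    if not result.events and result.hits == 0 and result.serviced == 0:
        raise ValueError("empty event log")
    total = max(result.total_cycles, 1)
    gha_busy = min(result.serviced * result.latency_P, total)
    neo = min(result.M * result.rs / result.rc, 1.0) if np.isfinite(result.rc) else float("nan")
    spike_buf = min((result.hits + result.serviced) / total, 1.0)
    return {
        "neo_buffer": neo,
        "spike_buffer": spike_buf,
        "gha_server": gha_busy / total,
    }
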