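"""Closed-form capacity and latency model of the shared spike-sorting datapath.

A single detection/feature-extraction core is time-multiplexed over ``M``
channels.  Three quantities bound how many channels the core can serve
without ever discarding a detected spike:

* the per-spike latency ``P`` of the Hebbian feature-extraction circuit,
  in clock cycles, which depends on the segment length ``L`` used to
  stream the m-dimensional vectors through the arithmetic units;
* the clock rate ``rc`` (period ``Tc``) relative to the sampling rate
  ``rs`` (period ``Ts``) -- one sample per channel must be fetched per
  sampling period, so ``M * Tc <= Ts``;
* the minimum inter-peak gap ``Q`` (in samples) between successive
  detected spikes on one channel -- with a one-spike buffer per channel,
  the backlog of at most ``M`` spikes must drain within ``Q * Ts``,
  so ``M * P * Tc <= Q * Ts``.

The gap constraint binds when ``Q < P``; otherwise the fetch constraint
does.  Hence ``Mmax = floor((Q/P) * Ts/Tc)`` if ``Q < P`` else
``floor(Ts/Tc)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import pandas as pd

__all__ = [
    "CapacityParams",
    "latency_cycles",
    "neo_limit",
    "max_channels",
    "capacity_table",
]

#: Fixed pipeline overhead of the feature-extraction datapath, in cycles.
OVERHEAD_CYCLES = 8


def latency_cycles(m: int, p: int, L: int) -> int:
    """Per-spike latency ``P`` of the segment-streamed GHA datapath.

    The m-dimensional spike and each of the ``p`` weight vectors are
    streamed through the arithmetic units in ``b = m/L`` segments: the
    sum-of-products stage needs ``p*b`` segment-cycles to form the
    feature vector and the weight-update stage another ``p*b``, plus a
    fixed ``OVERHEAD_CYCLES``-cycle overhead:  ``P = 2*p*b + 8``.

    The constant 2 and the 8-cycle overhead are calibrated for the
    reference design (m=64, p=2); extrapolation to other ``p`` follows
    the same formula but has no hardware reference point.
    """
    if m <= 0 or p <= 0 or L <= 0:
        raise ValueError("m, p and L must be positive")
    if m % L != 0:
        raise ValueError(f"segment length L={L} must divide m={m}")
    b = m // L
    return 2 * p * b + OVERHEAD_CYCLES


def neo_limit(rs: float, rc: float) -> int:
    """Channel bound imposed by round-robin sample fetching.

    The detection buffer must fetch one sample from each of the ``M``
    channels within one sampling period, one per clock cycle, so
    ``M <= floor(Ts/Tc) = floor(rc/rs)``.
    """
    if rs <= 0 or rc <= 0:
        raise ValueError("rates must be positive")
    return math.floor(Fraction(rc) / Fraction(rs))


def max_channels(Q: int, P: int, rs: float, rc: float) -> int:
    """Largest channel count with guaranteed zero discarded spikes.

    ``Q`` is the minimum number of samples between peaks of successive
    detected spikes on one channel, ``P`` the per-spike service latency
    in cycles.  When ``Q < P`` the service backlog binds first,
    otherwise the round-robin fetch limit does.
    """
    if Q < 1 or P < 1:
        raise ValueError("Q and P must be >= 1")
    if rs <= 0 or rc <= 0:
        raise ValueError("rates must be positive")
    if Q < P:
        return math.floor(Fraction(Q) * Fraction(rc) / (Fraction(P) * Fraction(rs)))
    return neo_limit(rs, rc)


def capacity_table(
    Q_list,
    L_list,
    rc_list,
    rs: float = 24_000.0,
    m: int = 64,
    p: int = 2,
) -> pd.DataFrame:
    """Mmax for every combination of gap ``Q``, segment length ``L`` and clock ``rc``.

    Returns a DataFrame indexed by (Q, L, P) with one column per clock
    rate, suitable for direct CSV export.
    """
    rows = []
    index = []
    for Q in Q_list:
        for L in L_list:
            P = latency_cycles(m, p, L)
            index.append((Q, L, P))
            rows.append({rc: max_channels(Q, P, rs, rc) for rc in rc_list})
    idx = pd.MultiIndex.from_tuples(index, names=["Q", "L", "P"])
    cols = [f"rc={rc:g}" for rc in rc_list]
    table = pd.DataFrame([[r[rc] for rc in rc_list] for r in rows], index=idx, columns=cols)
    return table


@dataclass(frozen=True)
class CapacityParams:
    """Operating point of the multiplexed datapath, with derived quantities."""

    rs: float = 24_000.0
    rc: float = 1e6
    Q: int = 16
    m: int = 64
    p: int = 2
    L: int = 8
    M: int = 1

    def __post_init__(self) -> None:
        if self.rs <= 0 or self.rc <= 0:
            raise ValueError("rates must be positive")
        if self.Q < 1:
            raise ValueError("Q must be >= 1")
        if self.m % self.L != 0:
            raise ValueError("L must divide m")
        if self.M < 1:
            raise ValueError("M must be >= 1")

    @property
    def Ts(self) -> float:
        return 1.0 / self.rs

    @property
    def Tc(self) -> float:
        return 1.0 / self.rc

    @property
    def P(self) -> int:
        return latency_cycles(self.m, self.p, self.L)

    @property
    def Mmax(self) -> int:
        return max_channels(self.Q, self.P, self.rs, self.rc)
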