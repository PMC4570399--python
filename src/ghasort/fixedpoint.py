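"""Emulation of the 17-bit fixed-point arithmetic used by the hardware datapath.

Values live on a signed two's-complement grid with ``frac_bits``
fractional bits; the default Q1.16 format (17 bits total, 16 fractional)
represents multiples of 2**-16 in [-1, 1 - 2**-16].  Normalized spike
samples and synaptic weights fit this range; sums of products are
accumulated in a wider format with extra integer guard bits before being
written back.

All values are held as Python/NumPy doubles that are exact multiples of
the grid step -- products of two 16-fractional-bit values need 32
mantissa bits and are therefore exact in IEEE doubles, so the emulation
is bit-faithful for the formats of interest here (frac_bits <= 26).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["FixedFormat", "quantize", "fixed_mac", "accumulator_format"]


@dataclass(frozen=True)
class FixedFormat:
    """Signed fixed-point format: ``total_bits`` with ``frac_bits`` fractional."""

    total_bits: int = 17
    frac_bits: int = 16
    rounding: str = "nearest-even"  # or "truncate"
    overflow: str = "saturate"      # or "wrap"

    def __post_init__(self) -> None:
        if not (1 <= self.frac_bits <= self.total_bits - 1):
            raise ValueError("need 1 <= frac_bits <= total_bits - 1")
        if self.rounding not in ("nearest-even", "truncate"):
            raise ValueError(f"unknown rounding mode {self.rounding!r}")
        if self.overflow not in ("saturate", "wrap"):
            raise ValueError(f"unknown overflow mode {self.overflow!r}")

    @property
    def lsb(self) -> float:
        return 2.0 ** (-self.frac_bits)

    @property
    def int_min(self) -> int:
        return -(2 ** (self.total_bits - 1))

    @property
    def int_max(self) -> int:
        return 2 ** (self.total_bits - 1) - 1

    @property
    def min_value(self) -> float:
        return self.int_min * self.lsb

    @property
    def max_value(self) -> float:
        return self.int_max * self.lsb


def accumulator_format(fmt: FixedFormat, guard_bits: int = 6) -> FixedFormat:
    """Widened format for multi-term accumulation: same grid, more headroom."""
    if guard_bits < 0:
        raise ValueError("guard_bits must be >= 0")
    return replace(fmt, total_bits=fmt.total_bits + guard_bits)


def quantize(v, fmt: FixedFormat):
    """Snap ``v`` onto the fixed-point grid of ``fmt``.

    Round-to-nearest-even (or truncation toward minus infinity), then
    saturation to the representable range (or two's-complement wrap).
    Accepts scalars or arrays; returns the same shape as floats that are
    exact grid multiples.
    """
    x = np.asarray(v, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("cannot quantize non-finite values")
    scaled = x * (2.0 ** fmt.frac_bits)
    if fmt.rounding == "nearest-even":
        ints = np.round(scaled)
    else:
        ints = np.floor(scaled)
    if fmt.overflow == "saturate":
        ints = np.clip(ints, fmt.int_min, fmt.int_max)
    else:
        span = float(2 ** fmt.total_bits)
        ints = (ints - fmt.int_min) % span + fmt.int_min
    out = ints * fmt.lsb
    if np.isscalar(v) or np.ndim(v) == 0:
        return float(out)
    return out


def fixed_mac(a, b, acc, fmt: FixedFormat, acc_fmt: FixedFormat | None = None):
    """One multiply-accumulate step of the sum-of-products unit.

    The product of two grid values is formed exactly, re-quantized onto
    the accumulator grid, and added with saturating semantics.
    """
    if acc_fmt is None:
        acc_fmt = accumulator_format(fmt)
    prod = np.asarray(a, dtype=np.float64) * np.asarray(b, dtype=np.float64)
    return quantize(np.asarray(acc, dtype=np.float64) + quantize(prod, acc_fmt), acc_fmt)
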