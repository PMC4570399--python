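"""Generalized Hebbian algorithm (Sanger's rule) for incremental PCA on spikes.

Given detected spike waveforms x of dimension m, the rule trains p
synaptic weight vectors w_j that converge to the leading eigenvectors of
the (uncentered) correlation matrix of the input stream, without ever
forming that matrix.  In service mode the feature vector is simply
y_j = <w_j, x>.

The per-presentation update is

    w_ji <- w_ji + eta * y_j * z_ji,
    z_0  = x,   z_j = z_{j-1} - y_j * w_j,

which is algebraically identical to the textbook form

    w_ji <- w_ji + eta * (y_j x_i - y_j * sum_{k<=j} w_ki y_k)

but needs only a running residual z, the factorization the hardware
datapath implements.  Note the update of w_j uses z_j itself (the
residual *after* subtracting y_j w_j), and the whole feature vector y is
computed from the pre-update weights.

Two numeric backends are provided: double-precision floats and an
emulation of the 17-bit fixed-point hardware datapath (see
:mod:`ghasort.fixedpoint`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .capacity import latency_cycles
from .fixedpoint import FixedFormat, accumulator_format, quantize

__all__ = [
    "WeightSet",
    "TrainConfig",
    "project",
    "project_fixed",
    "gha_update",
    "gha_update_fixed",
    "gha_update_segmented",
    "init_weights",
    "train",
    "extract_features",
    "normalize_spikes",
]


@dataclass
class WeightSet:
    """State of one channel's trained feature extractor: p weight vectors of length m."""

    weights: np.ndarray  # shape (p, m)
    channel: int = 0
    n_updates: int = 0
    backend: str = "float"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 2 or self.weights.shape[0] < 1:
            raise ValueError("weights must be a (p, m) array with p >= 1")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    @property
    def m(self) -> int:
        return self.weights.shape[1]


@dataclass
class TrainConfig:
    """Training hyper-parameters.

    eta is the learning rate; if ``tau`` is set, a 1/(1 + n/tau) decay
    is applied per presentation.  ``L`` is the segment length of the
    streamed datapath (must divide m); it does not change the result,
    only the modeled latency.  ``backend`` selects double-precision
    floats or the 17-bit fixed-point emulation.
    """

    eta: float = 0.02
    tau: float | None = 2000.0
    epochs: int = 30
    L: int = 8
    seed: int = 0
    backend: str = "float"
    fixed_format: FixedFormat = field(default_factory=FixedFormat)
    guard_bits: int = 6

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.backend not in ("float", "fixed17"):
            raise ValueError(f"unknown backend {self.backend!r}")


def project(x: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Service-mode feature vector: y_j = <w_j, x>."""
    x = np.asarray(x, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    if x.shape[-1] != W.shape[1]:
        raise ValueError("dimension mismatch between x and W")
    return np.array([np.dot(W[j], x) for j in range(W.shape[0])])


def gha_update(x: np.ndarray, W: np.ndarray, eta: float) -> np.ndarray:
    """One Hebbian presentation; returns the updated (p, m) weight matrix.

    y is computed from the pre-update W; the residual z is peeled one
    component at a time and each w_j is moved toward y_j * z_j.
    """
    x = np.asarray(x, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    y = project(x, W)
    z = x.copy()
    Wn = W.copy()
    for j in range(W.shape[0]):
        z = z - y[j] * W[j]
        Wn[j] = W[j] + eta * y[j] * z
    if not np.all(np.isfinite(Wn)):
        raise FloatingPointError(
            "non-finite weights after update; reduce the learning rate eta"
        )
    return Wn


def gha_update_segmented(
    x: np.ndarray, W: np.ndarray, eta: float, L: int
) -> tuple[np.ndarray, int]:
    """Segment-streamed update: identical arithmetic per segment, plus a cycle count.

    The m-vectors are processed in b = m/L segments, as the hardware
    fetches them from its buffers.  Segmentation only reorders the
    additions of the inner products, so the result matches
    :func:`gha_update` to floating round-off (bit-identical when L=m).
    The returned cycle count follows the calibrated latency model.
    """
    x = np.asarray(x, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    p, m = W.shape
    if m % L != 0:
        raise ValueError(f"segment length L={L} must divide m={m}")
    b = m // L
    # sum-of-products stage, one segment per cycle
    y = np.empty(p)
    for j in range(p):
        acc = 0.0
        for s in range(b):
            acc += np.dot(W[j, s * L : (s + 1) * L], x[s * L : (s + 1) * L])
        y[j] = acc
    # weight-update stage, one segment per cycle
    z = x.copy()
    Wn = W.copy()
    for j in range(p):
        for s in range(b):
            sl = slice(s * L, (s + 1) * L)
            z[sl] = z[sl] - y[j] * W[j, sl]
            Wn[j, sl] = W[j, sl] + eta * y[j] * z[sl]
    if not np.all(np.isfinite(Wn)):
        raise FloatingPointError(
            "non-finite weights after update; reduce the learning rate eta"
        )
    return Wn, latency_cycles(m, p, L)


# ---------------------------------------------------------------------------
# fixed-point backend


def _sop_fixed(x, W, fmt: FixedFormat, acc_fmt: FixedFormat) -> np.ndarray:
    """Feature vector with exact products re-quantized into a wide accumulator.

    Grid multiples sum exactly in doubles, so as long as no running
    partial sum leaves the accumulator range the sequential saturating
    accumulation equals a plain sum; the element-wise loop is only
    needed when a partial sum would saturate.
    """
    p = W.shape[0]
    y = np.empty(p)
    for j in range(p):
        prods = quantize(W[j] * x, acc_fmt)
        partial = np.cumsum(prods)
        if np.all(np.abs(partial) <= acc_fmt.max_value):
            y[j] = partial[-1] if partial.size else 0.0
        else:
            acc = 0.0
            for v in prods:
                acc = quantize(acc + v, acc_fmt)
            y[j] = acc
    return y


def project_fixed(
    x: np.ndarray,
    W: np.ndarray,
    fmt: FixedFormat | None = None,
    guard_bits: int = 6,
) -> np.ndarray:
    """Service-mode projection through the quantized datapath."""
    fmt = fmt or FixedFormat()
    acc_fmt = accumulator_format(fmt, guard_bits)
    xq = quantize(np.asarray(x, dtype=np.float64), fmt)
    Wq = quantize(np.asarray(W, dtype=np.float64), fmt)
    return _sop_fixed(xq, Wq, fmt, acc_fmt)


def gha_update_fixed(
    x: np.ndarray,
    W: np.ndarray,
    eta: float,
    fmt: FixedFormat | None = None,
    guard_bits: int = 6,
) -> np.ndarray:
    """Hebbian update with samples, weights and intermediates on the fixed grid.

    Weights and the residual z are stored in the base format (saturating
    at +/-1 for Q1.16); the feature values y and partial sums live in a
    wider accumulator with integer guard bits.
    """
    fmt = fmt or FixedFormat()
    acc_fmt = accumulator_format(fmt, guard_bits)
    xq = quantize(np.asarray(x, dtype=np.float64), fmt)
    Wq = quantize(np.asarray(W, dtype=np.float64), fmt)
    etaq = quantize(float(eta), acc_fmt)
    y = _sop_fixed(xq, Wq, fmt, acc_fmt)
    z = xq.copy()
    Wn = Wq.copy()
    for j in range(Wq.shape[0]):
        z = quantize(z - quantize(y[j] * Wq[j], acc_fmt), fmt)
        delta = quantize(etaq * quantize(y[j] * z, acc_fmt), acc_fmt)
        Wn[j] = quantize(Wq[j] + delta, fmt)
    return Wn


# ---------------------------------------------------------------------------
# training


def normalize_spikes(spikes: np.ndarray, headroom: float = 1.0 - 2.0 ** -16) -> np.ndarray:
    """Scale a spike set into [-1, 1) by its global peak magnitude.

    Required by the fixed-point backend's Q1.16 range; applied in float
    mode too so the two backends see identical inputs.
    """
    spikes = np.asarray(spikes, dtype=np.float64)
    peak = np.max(np.abs(spikes))
    if peak == 0:
        return spikes.copy()
    return spikes * (headroom / peak)


def init_weights(p: int, m: int, seed: int) -> np.ndarray:
    """Small random initial weights, i.i.d. uniform(-0.01, 0.01)."""
    rng = np.random.default_rng(seed)
    return rng.uniform(-0.01, 0.01, size=(p, m))


def train(
    spikes: np.ndarray,
    p: int,
    cfg: TrainConfig | None = None,
    channel: int = 0,
    normalize: bool = True,
) -> WeightSet:
    """Train p weight vectors over a spike set in stream order.

    ``spikes`` is an (N, m) array of aligned waveforms.  Each epoch
    presents the spikes in their stream (detection) order; training is
    order dependent, but a fixed seed and order make it bit
    reproducible.
    """
    cfg = cfg or TrainConfig()
    X = np.asarray(spikes, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("need at least one spike of shape (N, m)")
    if normalize:
        X = normalize_spikes(X)
    m = X.shape[1]
    W = init_weights(p, m, cfg.seed)
    fmt = cfg.fixed_format
    if cfg.backend == "fixed17":
        W = quantize(W, fmt)
    n = 0
    for _ in range(cfg.epochs):
        for x in X:
            eta_n = cfg.eta if cfg.tau is None else cfg.eta / (1.0 + n / cfg.tau)
            if cfg.backend == "fixed17":
                W = gha_update_fixed(x, W, eta_n, fmt, cfg.guard_bits)
            else:
                W = gha_update(x, W, eta_n)
            n += 1
    return WeightSet(weights=W, channel=channel, n_updates=n, backend=cfg.backend)


def extract_features(
    spikes: np.ndarray, ws: WeightSet | np.ndarray, normalize: bool = True
) -> np.ndarray:
    """Feature vectors (N, p) for a spike set under a trained WeightSet.

    Uses the backend recorded in the WeightSet so that features from a
    fixed-point-trained extractor also flow through the quantized
    datapath.
    """
    W = ws.weights if isinstance(ws, WeightSet) else np.asarray(ws, dtype=np.float64)
    backend = ws.backend if isinstance(ws, WeightSet) else "float"
    X = np.asarray(spikes, dtype=np.float64)
    if normalize:
        X = normalize_spikes(X)
    if backend == "fixed17":
        return np.array([project_fixed(x, W) for x in X])
    return np.array([project(x, W) for x in X])
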