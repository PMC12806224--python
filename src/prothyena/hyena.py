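"""The Hyena operator: gated causal long convolutions with implicit filters.

The order-N operator computes

    y = x_N . (h_N * ( ... x_1 . (h_1 * v) ... ))

where v, x_1..x_N are projections of the input (dense layer + depthwise
causal short convolution), ``*`` is causal long convolution and ``.`` is
element-wise gating. Each long convolution by a causal filter h equals
multiplication by the lower-triangular Toeplitz matrix T_h with
(T_h)_{ij} = h(i - j); it is evaluated in O(L log L) by FFT. The filter taps
are not free parameters: a small network of the (sinusoidally featurized)
time index emits them, modulated by a learnable exponential decay window, so
the parameter count is independent of sequence length.

This module exposes both the trainable :class:`HyenaOperator` and a
functional numpy surface (:func:`toeplitz_conv_reference`,
:func:`causal_fft_conv`, :func:`gate`, :func:`hyena_forward`) used as the
exactness oracle path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, fft_causal_conv_kernel
from .nn import Module, Parameter, Linear

__all__ = ["HyenaFilter", "HyenaOperator", "toeplitz_matrix",
           "toeplitz_conv_reference", "causal_fft_conv", "gate",
           "project_inputs", "generate_filters", "hyena_forward",
           "FFT_CONV_TOLERANCE"]

#: relative agreement required between the FFT path and the Toeplitz oracle
FFT_CONV_TOLERANCE = 1e-5

N_TIME_FEATURES = 8          # sinusoidal features of the normalized time index
FILTER_HIDDEN = 32           # width of the two hidden layers of the filter net
SHORT_CONV_WIDTH = 3         # depthwise causal short-convolution taps


# ----------------------------------------------------------------- oracle path

def toeplitz_matrix(h: np.ndarray) -> np.ndarray:
    """Build the L x L lower-triangular Toeplitz matrix of a causal filter."""
    h = np.asarray(h, dtype=np.float64)
    L = h.shape[0]
    i = np.arange(L)
    lag = i[:, None] - i[None, :]
    T = np.where(lag >= 0, h[np.clip(lag, 0, L - 1)], 0.0)
    return T


def toeplitz_conv_reference(h: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Causal convolution by explicit Toeplitz matrix multiply, O(L^2).

    ``h``: (L,) one filter for all channels, or (L, D) per-channel taps.
    ``v``: (L, D). Serves as the exactness oracle for the FFT path.
    """
    h = np.asarray(h, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    L, D = v.shape
    if h.shape[0] != L:
        raise ValueError(f"filter has {h.shape[0]} taps, expected {L}")
    if h.ndim == 1:
        return toeplitz_matrix(h) @ v
    out = np.empty_like(v)
    for d in range(D):
        out[:, d] = toeplitz_matrix(h[:, d]) @ v[:, d]
    return out


def causal_fft_conv(h: np.ndarray, v: np.ndarray) -> np.ndarray:
    """FFT-based causal convolution, numerically equal to the Toeplitz oracle.

    Zero-pads to >= 2L so circular convolution realizes the linear causal one;
    never materializes an L x L matrix. Accepts ``h`` of shape (L,) or (L, D)
    and ``v`` of shape (L, D).
    """
    h = np.asarray(h, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    L, D = v.shape
    if h.shape[0] != L:
        raise ValueError(f"filter has {h.shape[0]} taps, expected {L}")
    if h.ndim == 1:
        h = np.repeat(h[:, None], D, axis=1)
    return fft_causal_conv_kernel(h, v)


def gate(x_k: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Element-wise gating: multiplication by diag(x_k) per channel."""
    x_k = np.asarray(x_k, dtype=np.float64)
    u = np.asarray(u, dtype=np.float64)
    if x_k.shape != u.shape:
        raise ValueError(f"gate shape mismatch: {x_k.shape} vs {u.shape}")
    return x_k * u


# -------------------------------------------------------------- trainable path

def _time_features(L: int) -> np.ndarray:
    """Sinusoidal features of the normalized time index, shape (L, 8)."""
    t = np.arange(L, dtype=np.float64) / max(L, 1)
    feats = [np.ones(L), t]
    for j in (1, 2, 3):
        feats.append(np.sin(2 * np.pi * j * t))
        feats.append(np.cos(2 * np.pi * j * t))
    return np.stack(feats, axis=1)


class HyenaFilter(Module):
    """Implicit filter generator h_t = gamma(theta(t)).

    A two-hidden-layer sine-activated network of the time index emits taps
    for all N filters and D channels at once; a per-filter learnable
    exponential decay window localizes them. Parameter count does not depend
    on the sequence length L.
    """

    def __init__(self, order: int, dim: int, rng: np.random.Generator):
        self.order = order
        self.dim = dim
        self.lin1 = Linear(N_TIME_FEATURES, FILTER_HIDDEN, rng, std=1.0)
        self.lin2 = Linear(FILTER_HIDDEN, FILTER_HIDDEN, rng, std=0.3)
        self.lin3 = Linear(FILTER_HIDDEN, order * dim, rng, std=0.1)
        # decay rates (softplus-positive) per filter-channel
        self.decay = Parameter(rng.normal(1.0, 0.3, size=(order * dim,)))

    def forward(self, L: int) -> Tensor:
        """Return filter taps of shape (L, order * dim)."""
        feats = Tensor(_time_features(L))
        h = self.lin1(feats).sin()
        h = self.lin2(h).sin()
        h = self.lin3(h)
        t = Tensor(np.arange(L, dtype=np.float64)[:, None] / max(L, 1))
        window = (-(self.decay.softplus()) * t * 5.0).exp()
        return h * window

    def taps(self, L: int) -> np.ndarray:
        """Filters as (order, L, dim) numpy array (no grad), for inspection."""
        flat = self.forward(L).data
        return flat.reshape(L, self.order, self.dim).transpose(1, 0, 2)


class HyenaOperator(Module):
    """Order-N Hyena mixer mapping (B, L, D) -> (B, L, D), causal end-to-end."""

    def __init__(self, dim: int, order: int, rng: np.random.Generator):
        self.dim = dim
        self.order = order
        self.in_proj = Linear(dim, (order + 1) * dim, rng)
        self.short_conv = Parameter(
            rng.normal(0.0, 0.02, size=(SHORT_CONV_WIDTH, (order + 1) * dim)))
        # identity-leaning short conv: tap 0 starts near 1
        self.short_conv.data[0] += 1.0
        self.filter = HyenaFilter(order, dim, rng)
        self.out_proj = Linear(dim, dim, rng)

    def projections(self, x: Tensor) -> list[Tensor]:
        """Return [v, x_1, ..., x_N], each (B, L, D)."""
        z = self.in_proj(x).depthwise_causal_conv(self.short_conv)
        D = self.dim
        return [z[:, :, k * D:(k + 1) * D] for k in range(self.order + 1)]

    def forward(self, x: Tensor) -> Tensor:
        B, L, D = x.shape
        streams = self.projections(x)
        v, gates = streams[0], streams[1:]
        h = self.filter.forward(L)  # (L, N*D)
        u = v
        for k in range(self.order):
            hk = h[:, k * D:(k + 1) * D]
            u = gates[k] * u.fft_causal_conv(hk)
        return self.out_proj(u)


# --------------------------------------------- functional operation interfaces

@dataclass
class HyenaProjections:
    v: np.ndarray
    gates: list  # x_1 .. x_N


def project_inputs(x: np.ndarray, op: HyenaOperator) -> HyenaProjections:
    """Numpy surface for the projection step (dense + causal short conv)."""
    x = np.atleast_3d(np.asarray(x, dtype=np.float64))
    if x.ndim == 3 and x.shape[-1] != op.dim:
        raise ValueError(f"input width {x.shape[-1]} != operator dim {op.dim}")
    streams = op.projections(Tensor(x))
    return HyenaProjections(v=streams[0].data,
                            gates=[s.data for s in streams[1:]])


def generate_filters(L: int, op: HyenaOperator) -> np.ndarray:
    """Filters for length L as (order, L, dim); deterministic given params."""
    if L < 1:
        raise ValueError("L must be >= 1")
    return op.filter.taps(L)


def hyena_forward(x: np.ndarray, op: HyenaOperator) -> np.ndarray:
    """Numpy surface for the full operator on a single (L, D) input."""
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 2
    if single:
        x = x[None]
    y = op.forward(Tensor(x)).data
    return y[0] if single else y
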