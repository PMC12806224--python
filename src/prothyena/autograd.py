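"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: a :class:`Tensor` wraps a float64
``numpy.ndarray`` and records, for every operation, a closure that propagates
the upstream gradient to its inputs. ``Tensor.backward()`` runs the closures in
reverse topological order. The operation set is exactly what the sequence
models in this package need — dense algebra, element-wise nonlinearities,
softmax / cross-entropy, layer normalization, embedding lookup, depthwise and
dilated convolutions, FFT-based causal long convolution and rotary position
rotation — each with an analytically derived backward pass.

Everything is double precision. Gradients follow numpy broadcasting rules:
a gradient flowing into a broadcast operand is summed back to that operand's
shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "fft_causal_conv_kernel"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = tuple(_prev)

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.grad is not None})"

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = grad.copy() if grad.base is not None else grad
        else:
            self.grad = self.grad + grad

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            stack = [(node, False)]
            while stack:
                n, expanded = stack.pop()
                if expanded:
                    topo.append(n)
                    continue
                if id(n) in seen:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n._prev:
                    stack.append((p, False))

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    @staticmethod
    def _make(data, parents) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req,
                     _prev=tuple(p for p in parents if p.requires_grad))
        return out

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor._make(self.data + other.data, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._make(-self.data, (self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor._make(self.data * other.data, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor._make(self.data / other.data, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data ** 2, other.data.shape))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor._make(self.data @ other.data, (self, other))

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = backward
        return out

    def __getitem__(self, idx):
        out = Tensor._make(self.data[idx], (self,))
        fancy = any(isinstance(i, (np.ndarray, list)) for i in
                    (idx if isinstance(idx, tuple) else (idx,)))

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                if fancy:
                    np.add.at(full, idx, g)  # repeated indices accumulate
                else:
                    full[idx] += g
                self._accumulate(full)

        out._backward = backward
        return out

    # ------------------------------------------------------------ shape moves
    def reshape(self, *shape):
        out = Tensor._make(self.data.reshape(*shape), (self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = backward
        return out

    def transpose(self, *axes):
        axes = axes or None
        out = Tensor._make(np.transpose(self.data, axes), (self,))

        def backward(g):
            if self.requires_grad:
                inv = np.argsort(axes) if axes else None
                self._accumulate(np.transpose(g, inv))

        out._backward = backward
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def backward(g):
            if self.requires_grad:
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # --------------------------------------------------------- nonlinearities
    def exp(self):
        y = np.exp(self.data)
        out = Tensor._make(y, (self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * y)

        out._backward = backward
        return out

    def log(self):
        out = Tensor._make(np.log(self.data), (self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = backward
        return out

    def sin(self):
        out = Tensor._make(np.sin(self.data), (self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * np.cos(self.data))

        out._backward = backward
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor._make(y, (self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - y * y))

        out._backward = backward
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor._make(self.data * mask, (self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = backward
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor._make(y, (self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * y * (1.0 - y))

        out._backward = backward
        return out

    def gelu(self):
        # tanh approximation; exact enough for training, cheap to differentiate
        x = self.data
        c = np.sqrt(2.0 / np.pi)
        x2 = x * x
        inner = c * (x + 0.044715 * x2 * x)
        t = np.tanh(inner)
        y = 0.5 * x * (1.0 + t)
        out = Tensor._make(y, (self,))

        def backward(g):
            if self.requires_grad:
                dt = (1.0 - t * t) * c * (1.0 + 3 * 0.044715 * x2)
                self._accumulate(g * (0.5 * (1.0 + t) + 0.5 * x * dt))

        out._backward = backward
        return out

    def softplus(self):
        y = np.logaddexp(0.0, self.data)
        out = Tensor._make(y, (self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / (1.0 + np.exp(-self.data)))

        out._backward = backward
        return out

    # ----------------------------------------------------------- fused blocks
    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor._make(y, (self,))

        def backward(g):
            if self.requires_grad:
                dot = (g * y).sum(axis=axis, keepdims=True)
                self._accumulate(y * (g - dot))

        out._backward = backward
        return out

    def layer_norm(self, gain: "Tensor", bias: "Tensor", eps: float = 1e-5):
        """Normalize over the last axis, then scale and shift."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out = Tensor._make(xhat * gain.data + bias.data, (self, gain, bias))

        def backward(g):
            n = x.shape[-1]
            if gain.requires_grad:
                gain._accumulate(
                    _unbroadcast(g * xhat, gain.data.shape))
            if bias.requires_grad:
                bias._accumulate(_unbroadcast(g, bias.data.shape))
            if self.requires_grad:
                gx = g * gain.data
                self._accumulate(inv / n * (
                    n * gx
                    - gx.sum(axis=-1, keepdims=True)
                    - xhat * (gx * xhat).sum(axis=-1, keepdims=True)))

        out._backward = backward
        return out

    def cross_entropy(self, targets: np.ndarray, mask: np.ndarray):
        """Mean token-level negative log-likelihood.

        ``self`` holds logits of shape (..., V); ``targets`` integer ids of the
        matching leading shape; ``mask`` selects (weight 1) the positions that
        enter the mean. Returns a scalar Tensor.
        """
        logits = self.data
        targets = np.asarray(targets)
        mask = np.asarray(mask, dtype=np.float64)
        total = mask.sum()
        if total <= 0:
            raise ValueError("cross_entropy: mask selects no positions")
        zmax = logits.max(axis=-1, keepdims=True)
        z = logits - zmax
        lse = np.log(np.exp(z).sum(axis=-1)) + zmax[..., 0]
        picked = np.take_along_axis(logits, targets[..., None], axis=-1)[..., 0]
        loss = float(((lse - picked) * mask).sum() / total)
        out = Tensor._make(np.array(loss), (self,))

        def backward(g):
            if self.requires_grad:
                p = np.exp(logits - zmax)
                p /= p.sum(axis=-1, keepdims=True)
                onehot_sub = p
                np.subtract.at(
                    onehot_sub.reshape(-1, logits.shape[-1]),
                    (np.arange(targets.size), targets.reshape(-1)), 1.0)
                self._accumulate(
                    onehot_sub * (mask[..., None] * (float(g) / total)))

        out._backward = backward
        return out

    # ------------------------------------------------------------ convolution
    def depthwise_causal_conv(self, kernel: "Tensor"):
        """Per-channel causal FIR filter.

        ``self``: (B, L, C); ``kernel``: (w, C), tap j applies to lag j.
        """
        x, k = self.data, kernel.data
        w = k.shape[0]
        y = np.zeros_like(x)
        for j in range(w):
            if j == 0:
                y += k[0] * x
            else:
                y[:, j:, :] += k[j] * x[:, :-j, :]
        out = Tensor._make(y, (self, kernel))

        def backward(g):
            if kernel.requires_grad:
                gk = np.empty_like(k)
                for j in range(w):
                    if j == 0:
                        gk[0] = (g * x).sum(axis=(0, 1))
                    else:
                        gk[j] = (g[:, j:, :] * x[:, :-j, :]).sum(axis=(0, 1))
                kernel._accumulate(gk)
            if self.requires_grad:
                gx = np.zeros_like(x)
                for j in range(w):
                    if j == 0:
                        gx += k[0] * g
                    else:
                        gx[:, :-j, :] += k[j] * g[:, j:, :]
                self._accumulate(gx)

        out._backward = backward
        return out

    def fft_causal_conv(self, h: "Tensor"):
        """Causal long convolution along the sequence axis via FFT.

        ``self``: (B, L, C) input; ``h``: (L, C) causal filter taps (lag 0..L-1).
        Output position t mixes input positions <= t only. Equivalent to
        multiplying each channel by the lower-triangular Toeplitz matrix of h.
        """
        v, taps = self.data, h.data
        L = v.shape[1]
        if taps.shape[0] != L:
            raise ValueError(
                f"filter has {taps.shape[0]} taps, expected sequence length {L}")
        y = fft_causal_conv_kernel(taps, v)
        out = Tensor._make(y, (self, h))
        nfft = _nfft(L)

        def backward(g):
            G = np.fft.rfft(g, n=nfft, axis=1)
            if self.requires_grad:
                H = np.fft.rfft(taps, n=nfft, axis=0)
                gv = np.fft.irfft(np.conj(H)[None] * G, n=nfft, axis=1)[:, :L]
                self._accumulate(gv)
            if h.requires_grad:
                V = np.fft.rfft(v, n=nfft, axis=1)
                gh = np.fft.irfft(
                    (np.conj(V) * G).sum(axis=0), n=nfft, axis=0)[:L]
                h._accumulate(gh)

        out._backward = backward
        return out

    def conv1d_same(self, weight: "Tensor", bias: "Tensor", dilation: int = 1):
        """Full (channel-mixing) 1-D convolution with zero 'same' padding.

        ``self``: (B, L, Cin); ``weight``: (w, Cin, Cout); ``bias``: (Cout,).
        Tap j reads input at offset (j - w//2) * dilation.
        """
        x, W = self.data, weight.data
        w = W.shape[0]
        B, L, _ = x.shape
        y = np.zeros((B, L, W.shape[2]))
        offsets = [(j - w // 2) * dilation for j in range(w)]
        for j, off in enumerate(offsets):
            src = _shift_slice(x, off)
            y += src @ W[j]
        y += bias.data
        out = Tensor._make(y, (self, weight, bias))

        def backward(g):
            if bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 1)))
            if weight.requires_grad:
                gW = np.empty_like(W)
                for j, off in enumerate(offsets):
                    src = _shift_slice(x, off)
                    gW[j] = np.einsum("blc,bld->cd", src, g)
                weight._accumulate(gW)
            if self.requires_grad:
                gx = np.zeros_like(x)
                for j, off in enumerate(offsets):
                    contrib = g @ W[j].T
                    _shift_add(gx, contrib, -off)
                self._accumulate(gx)

        out._backward = backward
        return out

    def rotary(self, cos: np.ndarray, sin: np.ndarray):
        """Apply a rotary position rotation over the last axis (pairs).

        ``self``: (..., L, d) with d even; ``cos``/``sin``: (L, d//2)
        position-wise angles. Parameter-free and orthogonal per position.
        """
        x = self.data
        d = x.shape[-1]
        x1, x2 = x[..., : d // 2], x[..., d // 2:]
        y = np.concatenate([x1 * cos - x2 * sin, x1 * sin + x2 * cos], axis=-1)
        out = Tensor._make(y, (self,))

        def backward(g):
            if self.requires_grad:
                g1, g2 = g[..., : d // 2], g[..., d // 2:]
                gx = np.concatenate(
                    [g1 * cos + g2 * sin, -g1 * sin + g2 * cos], axis=-1)
                self._accumulate(gx)

        out._backward = backward
        return out


# --------------------------------------------------------------- numpy kernels

def _nfft(L: int) -> int:
    n = 1
    while n < 2 * L:
        n <<= 1
    return n


def fft_causal_conv_kernel(h: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Causal linear convolution of filter ``h`` (L, C) with ``v`` (..., L, C).

    Zero-pads to a power of two >= 2L so the circular convolution realizes the
    linear one; never materializes an L x L matrix.
    """
    L = v.shape[-2]
    nfft = _nfft(L)
    H = np.fft.rfft(h, n=nfft, axis=-2)
    V = np.fft.rfft(v, n=nfft, axis=-2)
    y = np.fft.irfft(H * V, n=nfft, axis=-2)
    return y[..., :L, :]


def _shift_slice(x: np.ndarray, off: int) -> np.ndarray:
    """Return x shifted so output position t reads x[t + off], zero padded."""
    out = np.zeros_like(x)
    if off == 0:
        return x
    if off > 0:
        out[:, :-off, :] = x[:, off:, :]
    else:
        out[:, -off:, :] = x[:, :off, :]
    return out


def _shift_add(acc: np.ndarray, x: np.ndarray, off: int) -> None:
    if off == 0:
        acc += x
    elif off > 0:
        acc[:, :-off, :] += x[:, off:, :]
    else:
        acc[:, -off:, :] += x[:, :off, :]
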