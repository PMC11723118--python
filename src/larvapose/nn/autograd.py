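"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the keypoint networks need: 2-D
convolution (arbitrary rectangular kernels, stride, padding), batch
normalization, ReLU, elementwise add, axis means, concatenation / slicing,
nearest-neighbour upsampling and a fused mean-squared-error loss.
Convolutions are evaluated as a sum of shifted tensordot contractions over
the kernel taps, which keeps memory flat (no full im2col buffer) and is fast
for the small rectangular kernels (1xN / Nx1 / 3x3) used here.

Gradients accumulate into ``Tensor.grad``; ``Tensor.backward()`` runs the
tape in reverse topological order.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs are deep for big networks
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=DTYPE))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# elementwise / structural ops

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data
    out = Tensor(out_data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(g)

    out._backward = backward
    return out


def add_many(tensors: list[Tensor]) -> Tensor:
    out = Tensor(sum(t.data for t in tensors), parents=tuple(tensors))

    def backward(g):
        for t in tensors:
            if t.requires_grad:
                t._accumulate(g)

    out._backward = backward
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    out._backward = backward
    return out


def mean_axis(x: Tensor, axis: int) -> Tensor:
    """Mean over one axis (no keepdims)."""
    n = x.data.shape[axis]
    out = Tensor(x.data.mean(axis=axis), parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.repeat(np.expand_dims(g / n, axis), n, axis=axis))

    out._backward = backward
    return out


def reshape(x: Tensor, shape) -> Tensor:
    out = Tensor(x.data.reshape(shape), parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g.reshape(x.data.shape))

    out._backward = backward
    return out


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def backward(g):
        pos = 0
        for t, size in zip(tensors, sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(pos, pos + size)
                t._accumulate(g[tuple(sl)])
            pos += size

    out._backward = backward
    return out


def narrow(x: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Contiguous slice along one axis."""
    sl = [slice(None)] * x.data.ndim
    sl[axis] = slice(start, start + length)
    sl = tuple(sl)
    out = Tensor(x.data[sl], parents=(x,))

    def backward(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            full[sl] = g
            x._accumulate(full)

    out._backward = backward
    return out


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    """Nearest-neighbour upsampling of an (N, C, H, W) map by an integer factor."""
    out_data = x.data.repeat(factor, axis=2).repeat(factor, axis=3)
    out = Tensor(out_data, parents=(x,))

    def backward(g):
        if x.requires_grad:
            N, C, H, W = x.data.shape
            g5 = g.reshape(N, C, H, factor, W, factor)
            x._accumulate(g5.sum(axis=(3, 5)))

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# convolution

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: tuple[int, int] = (1, 1),
           padding: tuple[int, int] = (0, 0)) -> Tensor:
    """2-D cross-correlation of (N, Cin, H, W) with (Cout, Cin, kh, kw).

    Zero padding (ph, pw) on both sides; output spatial size
    (H + 2 ph - kh) // sh + 1, likewise for width.
    """
    sh, sw = stride
    ph, pw = padding
    N, Cin, H, W = x.data.shape
    Cout, Cin_w, kh, kw = w.data.shape
    if Cin != Cin_w:
        raise ValueError(f"conv2d channel mismatch: input {Cin}, weight {Cin_w}")
    Ho = (H + 2 * ph - kh) // sh + 1
    Wo = (W + 2 * pw - kw) // sw + 1
    xpad = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data

    out_data = np.zeros((N, Ho, Wo, Cout), dtype=DTYPE)
    for i in range(kh):
        for j in range(kw):
            patch = xpad[:, :, i:i + sh * Ho:sh, j:j + sw * Wo:sw]
            # (N, Cin, Ho, Wo) x (Cout, Cin) -> (N, Ho, Wo, Cout)
            out_data += np.tensordot(patch, w.data[:, :, i, j], axes=([1], [1]))
    out_data = np.ascontiguousarray(out_data.transpose(0, 3, 1, 2))
    if b is not None:
        out_data += b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, parents=parents)

    def backward(g):
        g_nhwc = g.transpose(0, 2, 3, 1)  # (N, Ho, Wo, Cout)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            dw = np.empty_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    patch = xpad[:, :, i:i + sh * Ho:sh, j:j + sw * Wo:sw]
                    # (N, Ho, Wo, Cout) x (N, Cin, Ho, Wo) -> (Cout, Cin)
                    dw[:, :, i, j] = np.tensordot(
                        g_nhwc, patch, axes=([0, 1, 2], [0, 2, 3]))
            w._accumulate(dw)
        if x.requires_grad:
            dxpad = np.zeros_like(xpad)
            for i in range(kh):
                for j in range(kw):
                    # (N, Ho, Wo, Cout) x (Cout, Cin) -> (N, Ho, Wo, Cin)
                    contrib = np.tensordot(g_nhwc, w.data[:, :, i, j], axes=([3], [0]))
                    dxpad[:, :, i:i + sh * Ho:sh, j:j + sw * Wo:sw] += (
                        contrib.transpose(0, 3, 1, 2))
            if ph or pw:
                dxpad = dxpad[:, :, ph:ph + H, pw:pw + W]
            x._accumulate(dxpad)

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# batch normalization

def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                running_mean: np.ndarray, running_var: np.ndarray,
                training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Channelwise batch normalization of an (N, C, H, W) tensor.

    In training mode batch statistics are used and the running buffers are
    updated in place; in evaluation mode the running buffers are used and
    the backward pass reduces to a per-channel affine map.
    """
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu = running_mean
        var = running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv_std[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    out = Tensor(out_data, parents=(x, gamma, beta))

    def backward(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gs = g * gamma.data[None, :, None, None]
            if training:
                m = g.shape[0] * g.shape[2] * g.shape[3]
                sum_gs = gs.sum(axis=(0, 2, 3))
                sum_gs_xhat = (gs * xhat).sum(axis=(0, 2, 3))
                dx = (inv_std[None, :, None, None] / m) * (
                    m * gs
                    - sum_gs[None, :, None, None]
                    - xhat * sum_gs_xhat[None, :, None, None]
                )
            else:
                dx = gs * inv_std[None, :, None, None]
            x._accumulate(dx)

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# loss

def mse(pred: Tensor, target: np.ndarray, denom: float) -> Tensor:
    """Sum of squared differences divided by ``denom`` (a scalar tensor)."""
    diff = pred.data - np.asarray(target, dtype=DTYPE)
    out = Tensor(np.asarray((diff ** 2).sum() / denom), parents=(pred,))

    def backward(g):
        if pred.requires_grad:
            pred._accumulate((2.0 / denom) * diff * g)

    out._backward = backward
    return out
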