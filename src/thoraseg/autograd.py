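"""A small reverse-mode autodiff engine for 3D segmentation networks.

Implements exactly the operations the U-Net variants need — 3D
convolution (stride 1 or 2) via im2col, stride-2 transposed convolution,
per-channel PReLU, instance normalization, channel concatenation,
sigmoid, and a soft Dice loss with closed-form gradient — together with
an Adam optimizer supporting gradient accumulation.  Tensors carry a
(C, D, H, W) layout; batching is physical batch 1 throughout, matching
the training regime.

Every op's backward pass is verified against central finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "conv3d",
    "conv_transpose3d",
    "prelu",
    "instance_norm",
    "concat",
    "sigmoid",
    "dice_loss_t",
    "Adam",
]


class Tensor:
    """A node in the computation graph.

    Leaf tensors created with ``requires_grad=True`` are parameters;
    interior nodes record a backward closure and their parents.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, seed: np.ndarray | float = 1.0) -> None:
        """Reverse-mode sweep from this node (typically the scalar loss)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.broadcast_to(
            np.asarray(seed, dtype=np.float32), self.data.shape
        ).copy()
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _node(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    t = Tensor(data)
    t._parents = tuple(p for p in parents if isinstance(p, Tensor))
    t._backward = backward
    return t


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = g.astype(np.float32, copy=True)
    else:
        t.grad += g


# ---------------------------------------------------------------------------
# Convolution


def _shift_slices(k: int, stride: int, out_sp: tuple[int, int, int]):
    """Per-kernel-offset view slices into the padded input."""
    for a in range(k):
        for b in range(k):
            for c in range(k):
                yield (a, b, c), (
                    slice(None),
                    slice(a, a + (out_sp[0] - 1) * stride + 1, stride),
                    slice(b, b + (out_sp[1] - 1) * stride + 1, stride),
                    slice(c, c + (out_sp[2] - 1) * stride + 1, stride),
                )


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 1) -> Tensor:
    """3D convolution, x: (Ci, D, H, W), w: (Co, Ci, k, k, k), b: (Co,).

    Implemented as k^3 shifted GEMMs over the padded input — one matrix
    product per kernel offset — which keeps memory traffic contiguous;
    the input gradient is a view-based scatter of the same products.
    """
    ci_x = x.data.shape[0]
    co, ci, k = w.data.shape[0], w.data.shape[1], w.data.shape[2]
    if ci_x != ci:
        raise ValueError(f"conv3d channel mismatch: input has {ci_x}, weight expects {ci}")
    in_sp = x.data.shape[1:]
    xp = np.pad(x.data, ((0, 0),) + ((pad, pad),) * 3) if pad else x.data
    out_sp = tuple((n + 2 * pad - k) // stride + 1 for n in in_sp)
    n_out = int(np.prod(out_sp))
    w2 = w.data.reshape(co, ci, k * k * k)
    out2 = np.zeros((co, n_out), dtype=np.float32)
    for (a, bb, c), sl in _shift_slices(k, stride, out_sp):
        xs = np.ascontiguousarray(xp[sl]).reshape(ci, n_out)
        out2 += w2[:, :, (a * k + bb) * k + c] @ xs
    out = out2.reshape((co,) + out_sp)
    if b is not None:
        out = out + b.data[:, None, None, None]

    def backward(grad: np.ndarray) -> None:
        g2 = np.ascontiguousarray(grad).reshape(co, n_out)
        need_x = x.requires_grad or bool(x._parents)
        gw = np.empty_like(w.data) if w.requires_grad else None
        gxp = np.zeros_like(xp) if need_x else None
        for (a, bb, c), sl in _shift_slices(k, stride, out_sp):
            if gw is not None:
                xs = np.ascontiguousarray(xp[sl]).reshape(ci, n_out)
                gw[:, :, a, bb, c] = g2 @ xs.T
            if gxp is not None:
                contrib = (w2[:, :, (a * k + bb) * k + c].T @ g2).reshape(
                    (ci,) + out_sp
                )
                gxp[sl] += contrib
        if gw is not None:
            _accum(w, gw)
        if b is not None and b.requires_grad:
            _accum(b, g2.sum(axis=1))
        if need_x:
            if pad:
                inner = (slice(None),) + tuple(slice(pad, pad + n) for n in in_sp)
                _accum(x, gxp[inner])
            else:
                _accum(x, gxp)

    return _node(out, (x, w) + ((b,) if b is not None else ()), backward)


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Stride-2, kernel-2 transposed conv: exact 2x spatial upsampling.

    x: (Ci, D, H, W), w: (Ci, Co, 2, 2, 2) -> (Co, 2D, 2H, 2W).
    """
    ci, d, h, wd = x.data.shape
    if w.data.shape[0] != ci:
        raise ValueError(f"conv_transpose3d channel mismatch: {ci} vs {w.data.shape[0]}")
    co = w.data.shape[1]
    out = np.einsum("idhw,ioabc->odahbwc", x.data, w.data, optimize=True)
    out = out.reshape(co, 2 * d, 2 * h, 2 * wd)
    if b is not None:
        out = out + b.data[:, None, None, None]

    def backward(grad: np.ndarray) -> None:
        g = grad.reshape(co, d, 2, h, 2, wd, 2)
        if w.requires_grad:
            _accum(w, np.einsum("idhw,odahbwc->ioabc", x.data, g, optimize=True))
        if b is not None and b.requires_grad:
            _accum(b, grad.sum(axis=(1, 2, 3)))
        _accum(x, np.einsum("odahbwc,ioabc->idhw", g, w.data, optimize=True))

    return _node(out, (x, w) + ((b,) if b is not None else ()), backward)


# ---------------------------------------------------------------------------
# Pointwise / normalization


def prelu(x: Tensor, alpha: Tensor) -> Tensor:
    """Per-channel parametric ReLU; alpha: (C,)."""
    a = alpha.data[:, None, None, None]
    pos = x.data > 0
    out = np.where(pos, x.data, a * x.data)

    def backward(grad: np.ndarray) -> None:
        if alpha.requires_grad:
            _accum(alpha, np.where(pos, 0.0, grad * x.data).sum(axis=(1, 2, 3)))
        _accum(x, np.where(pos, grad, grad * a))

    return _node(out, (x, alpha), backward)


def instance_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize each channel over its spatial extent (no affine terms;
    the following PReLU slope and conv biases absorb scale/shift)."""
    xd = x.data
    mu = xd.mean(axis=(1, 2, 3), keepdims=True)
    var = xd.var(axis=(1, 2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = (xd - mu) * inv

    def backward(grad: np.ndarray) -> None:
        m = grad.mean(axis=(1, 2, 3), keepdims=True)
        my = (grad * y).mean(axis=(1, 2, 3), keepdims=True)
        _accum(x, inv * (grad - m - y * my))

    return _node(y, (x,), backward)


def concat(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate along the channel axis."""
    na = a.data.shape[0]
    out = np.concatenate([a.data, b.data], axis=0)

    def backward(grad: np.ndarray) -> None:
        _accum(a, grad[:na])
        _accum(b, grad[na:])

    return _node(out, (a, b), backward)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))

    def backward(grad: np.ndarray) -> None:
        _accum(x, grad * y * (1.0 - y))

    return _node(y, (x,), backward)


def dice_loss_t(prob: Tensor, target: np.ndarray, eps: float = 1e-5) -> Tensor:
    """Soft Dice loss 1 - (2*sum(p*g)+eps)/(sum(p)+sum(g)+eps), in [0, 1]."""
    g = np.asarray(target, dtype=np.float32)
    if g.shape != prob.data.shape:
        raise ValueError(f"dice_loss shape mismatch: {prob.data.shape} vs {g.shape}")
    p = prob.data
    num = 2.0 * float((p * g).sum()) + eps
    den = float(p.sum()) + float(g.sum()) + eps
    loss = 1.0 - num / den

    def backward(grad: np.ndarray) -> None:
        # d/dp_i [1 - num/den] = -(2 g_i den - num) / den^2
        _accum(prob, float(grad) * (num - 2.0 * g * den) / (den * den))

    return _node(np.float32(loss), (prob,), backward)


# ---------------------------------------------------------------------------
# Optimizer


class Adam:
    """Adam with first/second moment bias correction.

    Gradients may be accumulated over several backward passes before a
    step; the caller normalizes them (mean over the virtual batch) so the
    effective learning rate is independent of the accumulation count.
    """

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
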