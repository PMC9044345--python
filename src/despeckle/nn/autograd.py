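"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine is deliberately small: a :class:`Tensor` wrapping an ndarray plus
exactly the operations the denoising networks need — 2-D convolution, batch
normalization, ReLU, 2x2 max-pooling, factor-2 pixel shuffle, channel
concatenation, border padding/cropping, and the loss heads (L1 sum, squared-L2
sum, mean binary cross-entropy on logits).  Each operation records a closure
that scatters the upstream gradient to its parents; ``Tensor.backward`` walks
the graph in reverse topological order.

Feature maps use the channels-last NHWC layout ``(batch, height, width,
channels)`` and convolution weights are ``(kh, kw, in_ch, out_ch)``: a 2-D
convolution is then one GEMM per kernel offset on slices whose innermost axes
are contiguous, which is the memory-friendly formulation for a CPU BLAS.  All
computation is plain deterministic numpy, so two forward passes with identical
weights and inputs are bitwise identical.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "conv2d",
    "batchnorm2d",
    "relu",
    "maxpool2x2",
    "pixel_shuffle2",
    "concat",
    "add",
    "pad_bottom_right_reflect",
    "crop",
    "mean",
    "l1_sum",
    "squared_error_sum",
    "bce_with_logits_mean",
]


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray, own: bool = False) -> None:
        # own=True signals g is a freshly allocated array not shared with any
        # other consumer, so it can be adopted without a defensive copy
        if self.grad is None:
            if own and g.dtype == self.data.dtype:
                self.grad = g
            else:
                self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Back-propagate from this tensor (default seed gradient: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # an interior node's gradient is fully consumed by its closure;
                # dropping it promptly halves the backward pass's peak memory
                node.grad = None
        # release the graph: the closures and parent links are spent, and
        # severing them lets the whole step's tensors free by refcount instead
        # of waiting for the cycle collector (keeps training memory flat)
        for node in topo:
            node._backward = None
            node._parents = ()

    # scalar arithmetic, enough to combine loss terms
    def __add__(self, other: "Tensor") -> "Tensor":
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)

        return Tensor(out_data, self.requires_grad or other.requires_grad, (self, other), bw)

    def __mul__(self, scalar: float) -> "Tensor":
        s = float(scalar)
        out_data = self.data * s

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * s)

        return Tensor(out_data, self.requires_grad, (self,), bw)

    __rmul__ = __mul__

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, requires_grad={self.requires_grad})"


def _as_pad4(padding) -> tuple[int, int, int, int]:
    """(top, bottom, left, right)."""
    if isinstance(padding, int):
        return (padding, padding, padding, padding)
    return tuple(int(p) for p in padding)  # type: ignore[return-value]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, padding=0) -> Tensor:
    """2-D cross-correlation, NHWC layout.

    Computed as one batched matrix product per kernel offset on strided views
    of the padded input — no im2col materialization.  The input gradient of a
    stride-1 convolution is again a stride-1 convolution (flipped kernel,
    complementary padding), so the backward pass reuses the same formulation.
    """
    pt, pb, pl, pr = _as_pad4(padding)
    xd = x.data
    n, h, wd_, c = xd.shape
    kh, kw, ci, co = w.data.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input has {c}, weight expects {ci}")
    xp = np.pad(xd, ((0, 0), (pt, pb), (pl, pr), (0, 0))) if (pt or pb or pl or pr) else xd
    hp, wp = xp.shape[1], xp.shape[2]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    if ho < 1 or wo < 1:
        raise ValueError(f"conv2d: input {h}x{wd_} too small for kernel {kh}x{kw} with padding {padding}")
    wd = w.data
    out = np.zeros((n, ho, wo, co), dtype=xd.dtype)
    if b is not None:
        out += b.data
    for i in range(kh):
        for j in range(kw):
            out += np.matmul(xp[:, i : i + stride * ho : stride, j : j + stride * wo : stride, :], wd[i, j])

    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    if not req:
        parents = (x, w) if b is None else (x, w, b)
        return Tensor(out, False, parents, None)

    def bw(g):
        if w.requires_grad:
            dw = np.empty_like(wd)
            for i in range(kh):
                for j in range(kw):
                    xv = xp[:, i : i + stride * ho : stride, j : j + stride * wo : stride, :]
                    dw[i, j] = np.matmul(xv.transpose(0, 1, 3, 2), g).sum(axis=(0, 1))
            w._accumulate(dw, own=True)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1, 2)), own=True)
        if x.requires_grad:
            if stride == 1 and pt < kh and pb < kh and pl < kw and pr < kw:
                # transposed-kernel convolution of the upstream gradient
                gp = np.pad(g, ((0, 0), (kh - 1 - pt, kh - 1 - pb), (kw - 1 - pl, kw - 1 - pr), (0, 0)))
                dx = np.zeros_like(xd)
                for i in range(kh):
                    for j in range(kw):
                        dx += np.matmul(gp[:, i : i + h, j : j + wd_, :], wd[kh - 1 - i, kw - 1 - j].T)
                x._accumulate(dx, own=True)
            else:
                dxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, i : i + stride * ho : stride, j : j + stride * wo : stride, :] += np.matmul(
                            g, wd[i, j].T
                        )
                if pt or pb or pl or pr:
                    dxp = dxp[:, pt : hp - pb, pl : wp - pr, :]
                x._accumulate(dxp, own=not (pt or pb or pl or pr))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out, req, parents, bw)


def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization (NHWC, statistics over N, H, W).

    In training mode normalizes with batch statistics and updates the running
    estimates in place (unbiased variance, exponential moving average); in
    evaluation mode uses the running estimates, making the forward pass a
    deterministic affine map.
    """
    xd = x.data
    n, h, w, c = xd.shape
    flat = xd.reshape(-1, c)
    if training:
        m = flat.mean(axis=0)
        var = flat.var(axis=0)
        cnt = flat.shape[0]
        running_mean *= 1 - momentum
        running_mean += momentum * m
        running_var *= 1 - momentum
        running_var += momentum * var * (cnt / max(cnt - 1, 1))
    else:
        m = running_mean.astype(xd.dtype)
        var = running_var.astype(xd.dtype)
    ivar = (1.0 / np.sqrt(var + eps)).astype(xd.dtype)
    xhat = (flat - m.astype(xd.dtype)) * ivar
    out = (gamma.data * xhat + beta.data).reshape(xd.shape)

    def bw(g):
        gf = g.reshape(-1, c)
        if gamma.requires_grad:
            gamma._accumulate((gf * xhat).sum(axis=0), own=True)
        if beta.requires_grad:
            beta._accumulate(gf.sum(axis=0), own=True)
        if x.requires_grad:
            dxhat = gf * gamma.data
            if training:
                mu1 = dxhat.mean(axis=0)
                mu2 = (dxhat * xhat).mean(axis=0)
                dx = ivar * (dxhat - mu1 - xhat * mu2)
            else:
                dx = dxhat * ivar
            x._accumulate(dx.reshape(xd.shape), own=True)

    req = x.requires_grad or gamma.requires_grad or beta.requires_grad
    return Tensor(out, req, (x, gamma, beta), bw)


def relu(x: Tensor) -> Tensor:
    out = np.maximum(x.data, 0)

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * (out > 0), own=True)

    return Tensor(out, x.requires_grad, (x,), bw)


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max-pooling with stride 2; spatial dims must be even."""
    n, h, w, c = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 requires even spatial dims, got {h}x{w}")
    h2, w2 = h // 2, w // 2
    windows = np.ascontiguousarray(
        x.data.reshape(n, h2, 2, w2, 2, c).transpose(0, 1, 3, 5, 2, 4)
    ).reshape(n, h2, w2, c, 4)
    idx = windows.argmax(axis=-1)
    out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        if x.requires_grad:
            scatter = np.zeros_like(windows)
            np.put_along_axis(scatter, idx[..., None], g[..., None], axis=-1)
            dx = (
                scatter.reshape(n, h2, w2, c, 2, 2)
                .transpose(0, 1, 4, 2, 5, 3)
                .reshape(n, h, w, c)
            )
            x._accumulate(np.ascontiguousarray(dx), own=True)

    return Tensor(out, x.requires_grad, (x,), bw)


def pixel_shuffle2(x: Tensor) -> Tensor:
    """Rearrange (N, H, W, 4C) -> (N, 2H, 2W, C); a bijection of values."""
    n, h, w, c4 = x.data.shape
    if c4 % 4:
        raise ValueError(f"pixel_shuffle2 needs channels divisible by 4, got {c4}")
    c = c4 // 4
    out = (
        x.data.reshape(n, h, w, 2, 2, c)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(n, 2 * h, 2 * w, c)
    )

    def bw(g):
        if x.requires_grad:
            dx = (
                g.reshape(n, h, 2, w, 2, c)
                .transpose(0, 1, 3, 2, 4, 5)
                .reshape(n, h, w, c4)
            )
            x._accumulate(np.ascontiguousarray(dx), own=True)

    return Tensor(np.ascontiguousarray(out), x.requires_grad, (x,), bw)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(out, any(t.requires_grad for t in tensors), tuple(tensors), bw)


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError(f"add shape mismatch: {a.data.shape} vs {b.data.shape}")
    return a + b


def pad_bottom_right_reflect(x: Tensor, pad_bottom: int, pad_right: int) -> Tensor:
    """Reflection-pad the bottom/right borders by 0 or 1 pixel each (NHWC).

    Used to make odd spatial dims even before pooling; the gradient is
    scattered back onto the mirrored source pixels.
    """
    if pad_bottom not in (0, 1) or pad_right not in (0, 1):
        raise ValueError("only 0/1 pixel reflection padding is supported")
    if pad_bottom == 0 and pad_right == 0:
        return x
    n, h, w, c = x.data.shape
    if (pad_bottom and h < 2) or (pad_right and w < 2):
        raise ValueError("cannot reflect-pad an image smaller than 2 pixels")
    out = np.pad(x.data, ((0, 0), (0, pad_bottom), (0, pad_right), (0, 0)), mode="reflect")

    def bw(g):
        if x.requires_grad:
            dx = g[:, :h, :w, :].copy()
            if pad_bottom:
                dx[:, h - 2, :, :] += g[:, h, :w, :]
            if pad_right:
                dx[:, :, w - 2, :] += g[:, :h, w, :]
            if pad_bottom and pad_right:
                dx[:, h - 2, w - 2, :] += g[:, h, w, :]
            x._accumulate(dx, own=True)

    return Tensor(out, x.requires_grad, (x,), bw)


def crop(x: Tensor, height: int, width: int) -> Tensor:
    """Crop the top-left ``height x width`` window (inverse of border padding)."""
    n, h, w, c = x.data.shape
    if height > h or width > w:
        raise ValueError(f"cannot crop {h}x{w} to {height}x{width}")
    out = x.data[:, :height, :width, :]

    def bw(g):
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            dx[:, :height, :width, :] = g
            x._accumulate(dx, own=True)

    return Tensor(np.ascontiguousarray(out), x.requires_grad, (x,), bw)


def mean(x: Tensor) -> Tensor:
    out = x.data.mean()

    def bw(g):
        if x.requires_grad:
            x._accumulate(np.full_like(x.data, g / x.data.size), own=True)

    return Tensor(np.asarray(out, dtype=x.data.dtype), x.requires_grad, (x,), bw)


def l1_sum(pred: Tensor, target: Tensor) -> Tensor:
    """Sum of absolute differences (the literal L1 formula)."""
    diff = pred.data - target.data
    out = np.abs(diff).sum()

    def bw(g):
        s = np.sign(diff)
        if pred.requires_grad:
            pred._accumulate(g * s, own=True)
        if target.requires_grad:
            target._accumulate(-g * s, own=True)

    return Tensor(np.asarray(out, dtype=pred.data.dtype), pred.requires_grad or target.requires_grad, (pred, target), bw)


def squared_error_sum(a: Tensor, b: Tensor) -> Tensor:
    """Squared Euclidean norm of the difference, summed over all elements."""
    diff = a.data - b.data
    out = np.square(diff).sum()

    def bw(g):
        if a.requires_grad:
            a._accumulate(2.0 * g * diff, own=True)
        if b.requires_grad:
            b._accumulate(-2.0 * g * diff, own=True)

    return Tensor(np.asarray(out, dtype=a.data.dtype), a.requires_grad or b.requires_grad, (a, b), bw)


def bce_with_logits_mean(logits: Tensor, target: float | np.ndarray) -> Tensor:
    """Numerically stable binary cross-entropy on raw logits, mean-reduced.

    Uses max(z, 0) - z*y + log(1 + exp(-|z|)); the gradient is
    (sigmoid(z) - y) / n.
    """
    z = logits.data
    if not np.all(np.isfinite(z)):
        raise FloatingPointError("non-finite logits in bce_with_logits_mean (training diverged?)")
    y = np.asarray(target, dtype=z.dtype)
    losses = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out = losses.mean()

    def bw(g):
        if logits.requires_grad:
            sig = 1.0 / (1.0 + np.exp(-z))
            logits._accumulate(g * (sig - y) / z.size, own=True)

    return Tensor(np.asarray(out, dtype=z.dtype), logits.requires_grad, (logits,), bw)
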