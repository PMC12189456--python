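"""Neural-network primitives: convolution, resampling, softmax, losses.

Array-level forward helpers (``conv2d_forward`` etc.) are shared between the
differentiable :class:`~gcsaseg.nn.tensor.Tensor` ops and the plain-NumPy
functional attention API, so there is exactly one convolution implementation
in the package.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, _sigmoid


# ---------------------------------------------------------------------------
# array-level conv machinery (shared by Tensor op and functional API)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, padding: int,
            groups: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Return columns of shape (N, G, Ho*Wo, (C/G)*kh*kw) and (Ho, Wo)."""
    n, c, h, w = x.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    hp, wp = x.shape[2], x.shape[3]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    # (N, C, Ho, Wo, kh, kw) -> (N, G, Ho*Wo, (C/G)*kh*kw)
    cg = c // groups
    win = win.reshape(n, groups, cg, ho, wo, kh, kw)
    col = win.transpose(0, 1, 3, 4, 2, 5, 6).reshape(n, groups, ho * wo, cg * kh * kw)
    return np.ascontiguousarray(col), (ho, wo)


def _col2im(dcol: np.ndarray, x_shape: tuple[int, ...], kh: int, kw: int,
            stride: int, padding: int, groups: int,
            out_hw: tuple[int, int]) -> np.ndarray:
    """Adjoint of :func:`_im2col`; scatter column gradients back to the input."""
    n, c, h, w = x_shape
    ho, wo = out_hw
    cg = c // groups
    dwin = dcol.reshape(n, groups, ho, wo, cg, kh, kw).transpose(0, 1, 4, 5, 6, 2, 3)
    dwin = dwin.reshape(n, c, kh, kw, ho, wo)
    hp, wp = h + 2 * padding, w + 2 * padding
    dxp = np.zeros((n, c, hp, wp), dtype=dcol.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + ho * stride:stride, j:j + wo * stride:stride] += dwin[:, :, i, j]
    if padding:
        return dxp[:, :, padding:-padding, padding:-padding]
    return dxp


def conv2d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None,
                   stride: int = 1, padding: int = 0, groups: int = 1) -> np.ndarray:
    """Plain-array 2-D cross-correlation in NCHW layout.

    ``w`` has shape (C_out, C_in/groups, kh, kw).
    """
    n, c, _, _ = x.shape
    cout, cg, kh, kw = w.shape
    if c != cg * groups:
        raise ValueError(f"conv2d: input has {c} channels, kernel expects {cg * groups}")
    col, (ho, wo) = _im2col(x, kh, kw, stride, padding, groups)
    wg = w.reshape(groups, cout // groups, cg * kh * kw)
    out = col @ wg.transpose(0, 2, 1)          # (N, G, Ho*Wo, Cout/G)
    out = out.transpose(0, 1, 3, 2).reshape(n, cout, ho, wo)
    if b is not None:
        out = out + b[None, :, None, None]
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, groups: int = 1) -> Tensor:
    """Differentiable 2-D convolution (cross-correlation)."""
    n, c, _, _ = x.shape
    cout, cg, kh, kw = w.shape
    if c != cg * groups:
        raise ValueError(f"conv2d: input has {c} channels, kernel expects {cg * groups}")
    col, (ho, wo) = _im2col(x.data, kh, kw, stride, padding, groups)
    wg = w.data.reshape(groups, cout // groups, cg * kh * kw)
    out = col @ wg.transpose(0, 2, 1)
    out = np.ascontiguousarray(out.transpose(0, 1, 3, 2)).reshape(n, cout, ho, wo)
    if b is not None:
        out += b.data[None, :, None, None]
    x_shape = x.data.shape
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gg = g.reshape(n, groups, cout // groups, ho * wo).transpose(0, 1, 3, 2)
        if w.requires_grad:
            dw = np.einsum("nglk,nglo->gok", col, gg, optimize=True)
            w._accumulate(dw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcol = gg @ wg                      # (N, G, Ho*Wo, Cg*kh*kw)
            x._accumulate(_col2im(dcol, x_shape, kh, kw, stride, padding,
                                  groups, (ho, wo)))

    return Tensor._make(out, parents, backward)


# ---------------------------------------------------------------------------
# bilinear resampling
# ---------------------------------------------------------------------------

def _bilinear_coeffs(n_in: int, n_out: int):
    """Source indices/weights for align_corners=False bilinear resampling."""
    scale = n_in / n_out
    src = (np.arange(n_out, dtype=np.float64) + 0.5) * scale - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(np.intp)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = src - i0
    w0 = 1.0 - w1
    return i0, i1, w0, w1


def bilinear_resize_forward(x: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    n, c, h, w = x.shape
    if (h, w) == (out_h, out_w):
        return x
    y0, y1, wy0, wy1 = _bilinear_coeffs(h, out_h)
    x0, x1, wx0, wx1 = _bilinear_coeffs(w, out_w)
    dt = x.dtype
    out = (x[:, :, y0[:, None], x0[None, :]] * (wy0[:, None] * wx0[None, :]).astype(dt)
           + x[:, :, y0[:, None], x1[None, :]] * (wy0[:, None] * wx1[None, :]).astype(dt)
           + x[:, :, y1[:, None], x0[None, :]] * (wy1[:, None] * wx0[None, :]).astype(dt)
           + x[:, :, y1[:, None], x1[None, :]] * (wy1[:, None] * wx1[None, :]).astype(dt))
    return out


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Differentiable bilinear resampling (align_corners=False)."""
    n, c, h, w = x.shape
    out = bilinear_resize_forward(x.data, out_h, out_w)
    if (h, w) == (out_h, out_w):
        return x * 1.0  # still a node, keeps the graph uniform
    y0, y1, wy0, wy1 = _bilinear_coeffs(h, out_h)
    x0, x1, wx0, wx1 = _bilinear_coeffs(w, out_w)

    def backward(g):
        dt = g.dtype
        dx = np.zeros((n * c, h * w), dtype=dt)
        gf = g.reshape(n * c, out_h * out_w)
        rows = np.arange(n * c)[:, None]
        for yi, xi, wy, wx in ((y0, x0, wy0, wx0), (y0, x1, wy0, wx1),
                               (y1, x0, wy1, wx0), (y1, x1, wy1, wx1)):
            idx = (yi[:, None] * w + xi[None, :]).ravel()
            vals = gf * (wy[:, None] * wx[None, :]).astype(dt).ravel()
            np.add.at(dx, (rows, idx[None, :]), vals)
        x._accumulate(dx.reshape(n, c, h, w))

    return Tensor._make(out, (x,), backward)


# ---------------------------------------------------------------------------
# softmax family
# ---------------------------------------------------------------------------

def softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    e = (x - m).exp()
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean pixelwise cross-entropy of ``logits`` (N, K, ...) vs integer targets.

    The gradient ``(softmax - onehot)/n`` is implemented analytically for
    numerical stability.
    """
    x = logits.data
    m = x.max(axis=1, keepdims=True)
    e = np.exp(x - m)
    z = e.sum(axis=1, keepdims=True)
    logp = (x - m) - np.log(z)
    idx = np.expand_dims(np.asarray(target, dtype=np.intp), 1)
    picked = np.take_along_axis(logp, idx, axis=1)
    n = picked.size
    loss = np.asarray(-picked.sum() / n, dtype=x.dtype)

    def backward(g):
        p = e / z
        onehot = np.zeros_like(p)
        np.put_along_axis(onehot, idx, 1.0, axis=1)
        logits._accumulate((p - onehot) * (float(g) / n))

    return Tensor._make(loss, (logits,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-6) -> Tensor:
    """Layer normalization over the trailing axis."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / (var + eps).sqrt() * gamma + beta
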