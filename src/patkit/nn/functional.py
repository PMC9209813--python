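"""Convolution primitives (forward and backward) on NumPy arrays.

Layout is NCHW throughout.  Convolutions are implemented as im2col gathers
followed by BLAS matmuls; the input-gradient pass is expressed as another
convolution on the zero-stuffed output gradient, so no scatter-add is
needed.  Transposed convolution reuses the same machinery (it *is* the
input-gradient of a strided convolution).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def conv_out_size(n: int, k: int, s: int, d: int, p: int) -> int:
    return (n + 2 * p - d * (k - 1) - 1) // s + 1


def im2col(xp: np.ndarray, k: int, s: int, d: int, ho: int, wo: int) -> np.ndarray:
    """(N, C, Hp, Wp) padded input -> (N, C*k*k, ho*wo) patch matrix.

    Built from a sliding-window view (stride and dilation are plain view
    slices), so the only copy is the final layout change for the matmul.
    """
    n, c = xp.shape[:2]
    win = d * (k - 1) + 1
    v = sliding_window_view(xp, (win, win), axis=(2, 3))
    v = v[:, :, ::s, ::s, ::d, ::d]  # (N, C, ho, wo, k, k)
    return v.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo)


def conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray | None, s: int = 1,
           d: int = 1, p: int = 0, return_cols: bool = False):
    """Cross-correlation of (N,C,H,W) with (O,C,k,k) weights."""
    n, c, h, wd = x.shape
    o, _, k, _ = w.shape
    ho = conv_out_size(h, k, s, d, p)
    wo = conv_out_size(wd, k, s, d, p)
    if k == 1 and s == 1 and p == 0:
        cols = x.reshape(n, c, h * wd)
    else:
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = im2col(xp, k, s, d, ho, wo)
    y = np.matmul(w.reshape(o, -1), cols)
    if b is not None:
        y += b[:, None]
    y = y.reshape(n, o, ho, wo)
    return (y, cols) if return_cols else y


def conv2d_dw(cols: np.ndarray, dy: np.ndarray, w_shape: tuple) -> np.ndarray:
    """Weight gradient from cached patch matrix and output gradient."""
    n, o = dy.shape[:2]
    dy_mat = dy.reshape(n, o, -1)
    dw = np.einsum("nop,ncp->oc", dy_mat, cols, optimize=True)
    return dw.reshape(w_shape)


def _stuff_and_pad(dy: np.ndarray, s: int, pl: int, pr: int) -> np.ndarray:
    """Insert stride zeros and apply asymmetric padding."""
    n, o, ho, wo = dy.shape
    if s > 1:
        up = np.zeros((n, o, (ho - 1) * s + 1, (wo - 1) * s + 1), dtype=dy.dtype)
        up[:, :, ::s, ::s] = dy
    else:
        up = dy
    if pl or pr:
        up = np.pad(up, ((0, 0), (0, 0), (pl, pr), (pl, pr)))
    return up


def conv2d_dx(dy: np.ndarray, w: np.ndarray, s: int, d: int, p: int,
              h: int, wd: int) -> np.ndarray:
    """Input gradient of :func:`conv2d` for an (h, wd) spatial input."""
    o, c, k, _ = w.shape
    if k == 1 and s == 1 and p == 0:
        n = dy.shape[0]
        dx = np.matmul(w.reshape(o, c).T, dy.reshape(n, o, -1))
        return dx.reshape(n, c, h, wd)
    hu = (dy.shape[2] - 1) * s + 1
    pl = d * (k - 1) - p
    if pl < 0:
        raise ValueError("unsupported geometry: padding exceeds kernel reach")
    pr = h + d * (k - 1) - hu - pl
    up = _stuff_and_pad(dy, s, pl, pr)
    wf = np.ascontiguousarray(w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
    return conv2d(up, wf, None, s=1, d=d, p=0)


def conv_transpose2d(x: np.ndarray, w: np.ndarray, b: np.ndarray | None,
                     s: int = 2, p: int = 1, op: int = 1, return_cols: bool = False):
    """Transposed convolution; weights are (Cin, Cout, k, k).

    Output spatial size is ``(H-1)*s - 2p + k + op`` (2H for the 3x3,
    stride-2, pad-1, output-pad-1 configuration used in the decoders).
    """
    cin, cout, k, _ = w.shape
    n, c, h, wd = x.shape
    if c != cin:
        raise ValueError("channel mismatch in transposed convolution")
    h_out = (h - 1) * s - 2 * p + k + op
    w_out = (wd - 1) * s - 2 * p + k + op
    pl = k - 1 - p
    if pl < 0:
        raise ValueError("unsupported geometry: padding exceeds kernel size")
    pr = h_out + (k - 1) - ((h - 1) * s + 1) - pl
    up = _stuff_and_pad(x, s, pl, pr)
    wc = np.ascontiguousarray(w.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
    y, cols = conv2d(up, wc, b, s=1, d=1, p=0, return_cols=True)
    assert y.shape[2:] == (h_out, w_out)
    return (y, cols) if return_cols else y


def conv_transpose2d_dw(cols: np.ndarray, dy: np.ndarray, w_shape: tuple) -> np.ndarray:
    cin, cout, k, _ = w_shape
    dwc = conv2d_dw(cols, dy, (cout, cin, k, k))
    return np.ascontiguousarray(dwc.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])


def conv_transpose2d_dx(dy: np.ndarray, w: np.ndarray, s: int, p: int) -> np.ndarray:
    """Input gradient of :func:`conv_transpose2d` = strided conv with w."""
    return conv2d(dy, np.ascontiguousarray(w), None, s=s, d=1, p=p)


def batchnorm_forward(x, gamma, beta, running_mean, running_var,
                      training: bool, momentum: float = 0.1, eps: float = 1e-5):
    """Per-channel batch normalization; returns (y, cache)."""
    if training:
        mean = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
    y = gamma[None, :, None, None] * xhat + beta[None, :, None, None]
    return y, (xhat, inv_std)


def batchnorm_backward(dy, gamma, cache):
    """Standard batch-norm backward over the (N, H, W) statistics axes."""
    xhat, inv_std = cache
    m = dy.shape[0] * dy.shape[2] * dy.shape[3]
    dgamma = np.einsum("nchw,nchw->c", dy, xhat, optimize=True)
    dbeta = dy.sum(axis=(0, 2, 3))
    dx = (gamma * inv_std)[None, :, None, None] / m * (
        m * dy
        - dbeta[None, :, None, None]
        - xhat * dgamma[None, :, None, None]
    )
    return dx, dgamma, dbeta
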