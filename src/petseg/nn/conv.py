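"""3-D convolution primitives (im2col-based) with hand-written adjoints.

Layout convention: feature maps are ``(batch, channels, x, y, z)``; dense
convolution weights are ``(out_ch, in_ch, kx, ky, kz)`` and transposed
convolution weights ``(in_ch, out_ch, kx, ky, kz)``.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, make


def _triple(v) -> tuple[int, int, int]:
    if np.isscalar(v):
        return (int(v),) * 3
    t = tuple(int(x) for x in v)
    assert len(t) == 3
    return t


def _im2col(xp: np.ndarray, kernel, stride):
    """Sliding windows of a padded (B, C, X, Y, Z) array.

    Returns ``cols`` of shape (B*L, C*k^3) plus the output spatial dims.
    """
    kd, kh, kw = kernel
    sd, sh, sw = stride
    win = sliding_window_view(xp, (kd, kh, kw), axis=(2, 3, 4))[:, :, ::sd, ::sh, ::sw]
    b, c, do, ho, wo = win.shape[:5]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
        b * do * ho * wo, c * kd * kh * kw
    )
    return cols, (do, ho, wo)


def _col2im(gcols: np.ndarray, xp_shape, out_dims, kernel, stride) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add columns back onto the padded grid."""
    b, c = xp_shape[0], xp_shape[1]
    do, ho, wo = out_dims
    kd, kh, kw = kernel
    sd, sh, sw = stride
    g = gcols.reshape(b, do, ho, wo, c, kd, kh, kw).transpose(0, 4, 1, 2, 3, 5, 6, 7)
    out = np.zeros(xp_shape, dtype=gcols.dtype)
    for i in range(kd):
        for j in range(kh):
            for k in range(kw):
                out[
                    :,
                    :,
                    i : i + do * sd : sd,
                    j : j + ho * sh : sh,
                    k : k + wo * sw : sw,
                ] += g[..., i, j, k]
    return out


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, stride=1, padding=0) -> Tensor:
    """Dense 3-D cross-correlation ``x * w + b``."""
    stride, padding = _triple(stride), _triple(padding)
    B, Cin, D, H, W = x.data.shape
    Cout, Cin2, kd, kh, kw = w.data.shape
    if Cin != Cin2:
        raise ValueError(f"channel mismatch: input {Cin} vs weight {Cin2}")
    pd, ph, pw = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
    cols, (Do, Ho, Wo) = _im2col(xp, (kd, kh, kw), stride)
    Wm = w.data.reshape(Cout, -1)
    out = cols @ Wm.T
    if b is not None:
        out += b.data
    out = np.ascontiguousarray(
        out.reshape(B, Do, Ho, Wo, Cout).transpose(0, 4, 1, 2, 3)
    )

    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gm = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1)).reshape(-1, Cout)
        if w.requires_grad:
            w.accumulate((gm.T @ cols).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b.accumulate(gm.sum(axis=0))
        if x.requires_grad:
            if stride == (1, 1, 1) and all(k - 1 - p >= 0 for k, p in zip((kd, kh, kw), padding)):
                # stride-1 input gradient is itself a convolution with the
                # flipped, channel-transposed kernel — matmul beats scatter
                wf = w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
                qd, qh, qw = kd - 1 - pd, kh - 1 - ph, kw - 1 - pw
                gp = np.pad(g, ((0, 0), (0, 0), (qd, qd), (qh, qh), (qw, qw)))
                gcols_x, _ = _im2col(gp, (kd, kh, kw), (1, 1, 1))
                gx = (gcols_x @ wf.reshape(Cin, -1).T).reshape(B, D, H, W, Cin)
                x.accumulate(np.ascontiguousarray(gx.transpose(0, 4, 1, 2, 3)))
            else:
                gcols = gm @ Wm
                gxp = _col2im(gcols, xp.shape, (Do, Ho, Wo), (kd, kh, kw), stride)
                x.accumulate(gxp[:, :, pd : pd + D, ph : ph + H, pw : pw + W])

    return make(out, parents, bwd)


def conv_transpose3d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride=2,
    padding=1,
    output_padding=1,
) -> Tensor:
    """Transposed 3-D convolution (adjoint of a strided convolution).

    With the default ``k=3, stride=2, padding=1, output_padding=1`` each
    spatial dimension exactly doubles.
    """
    stride, padding, output_padding = (
        _triple(stride),
        _triple(padding),
        _triple(output_padding),
    )
    B, Cin, D, H, W = x.data.shape
    Cin2, Cout, kd, kh, kw = w.data.shape
    if Cin != Cin2:
        raise ValueError(f"channel mismatch: input {Cin} vs weight {Cin2}")
    sd, sh, sw = stride
    pd, ph, pw = padding
    od, oh, ow = output_padding
    Dout = (D - 1) * sd - 2 * pd + kd + od
    Hout = (H - 1) * sh - 2 * ph + kh + oh
    Wout = (W - 1) * sw - 2 * pw + kw + ow

    Wm = w.data.reshape(Cin, Cout * kd * kh * kw)
    x_flat = np.ascontiguousarray(x.data.transpose(0, 2, 3, 4, 1)).reshape(-1, Cin)
    cols = x_flat @ Wm  # (B*L, Cout*k^3)
    outp_shape = (B, Cout, Dout + 2 * pd, Hout + 2 * ph, Wout + 2 * pw)
    outp = _col2im(cols, outp_shape, (D, H, W), (kd, kh, kw), stride)
    out = np.ascontiguousarray(outp[:, :, pd : pd + Dout, ph : ph + Hout, pw : pw + Wout])
    if b is not None:
        out += b.data.reshape(1, Cout, 1, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gp = np.pad(g, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
        gcols, dims = _im2col(gp, (kd, kh, kw), stride)
        assert dims == (D, H, W)
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3, 4)))
        if w.requires_grad:
            w.accumulate((x_flat.T @ gcols).reshape(w.data.shape))
        if x.requires_grad:
            gx = (gcols @ Wm.T).reshape(B, D, H, W, Cin).transpose(0, 4, 1, 2, 3)
            x.accumulate(np.ascontiguousarray(gx))

    return make(out, parents, bwd)


def maxpool2(x: Tensor) -> Tensor:
    """2x2x2 max pooling; requires even spatial dims.  Gradient at ties is
    split equally among the tied voxels."""
    B, C, D, H, W = x.data.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {(D, H, W)}")
    xr = x.data.reshape(B, C, D // 2, 2, H // 2, 2, W // 2, 2)
    out = xr.max(axis=(3, 5, 7))

    def bwd(g):
        ob = out[:, :, :, None, :, None, :, None]
        mask = (xr == ob).astype(x.data.dtype)
        counts = mask.sum(axis=(3, 5, 7), keepdims=True)
        gr = g[:, :, :, None, :, None, :, None] * mask / counts
        x.accumulate(gr.reshape(x.data.shape))

    return make(np.ascontiguousarray(out), (x,), bwd)


def trilinear_kernel(channels: int, dtype=np.float32) -> np.ndarray:
    """Fixed per-channel 4x4x4 transposed-conv kernel whose application with
    stride 2 / padding 1 / no output padding performs x2 trilinear upsampling
    (half-voxel aligned).  Shape ``(C, C, 4, 4, 4)`` with zero cross-channel
    terms."""
    k1 = np.array([0.25, 0.75, 0.75, 0.25], dtype=dtype)
    k3 = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
    w = np.zeros((channels, channels, 4, 4, 4), dtype=dtype)
    for c in range(channels):
        w[c, c] = k3
    return w


def upsample2_trilinear(x: Tensor, kernel: np.ndarray | None = None) -> Tensor:
    """x2 trilinear upsampling implemented as a fixed-weight transposed
    convolution (no learnable parameters)."""
    C = x.data.shape[1]
    if kernel is None or kernel.shape[0] != C:
        kernel = trilinear_kernel(C, dtype=x.data.dtype)
    return conv_transpose3d(
        x, Tensor(kernel.astype(x.data.dtype)), None, stride=2, padding=1, output_padding=0
    )
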