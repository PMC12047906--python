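"""Fused direct 3D convolution kernels (numba-compiled).

Same-padded, stride-1, odd-kernel correlation plus its two adjoints
(gradient w.r.t. input and w.r.t. weights), written as cache-friendly row
loops so the inner dimension vectorises.  These avoid materialising the
im2col patch matrix, whose memory traffic dominates a GEMM-based
implementation at segmentation-sized volumes.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_OPTS = dict(cache=True, fastmath=True, boundscheck=False)


@njit(**_OPTS)
def _corr3d(xp: np.ndarray, w: np.ndarray, out: np.ndarray) -> None:
    """out[o,d,h,v] = sum_c,i,j,l xp[c,d+i,h+j,v+l] * w[o,c,i,j,l].

    ``xp`` is the already-padded input (C, D+k-1, H+k-1, W+k-1); ``out``
    must be zero-initialised (O, D, H, W).  Specialised k=3 inner loop:
    the three taps along the contiguous axis are fused into one pass so
    each input row is streamed once per (c, i, j).
    """
    n_out, n_in = w.shape[0], w.shape[1]
    k = w.shape[2]
    d_sz, h_sz, w_sz = out.shape[1], out.shape[2], out.shape[3]
    for o in range(n_out):
        for dd in range(d_sz):
            for hh in range(h_sz):
                acc = out[o, dd, hh]
                for c in range(n_in):
                    for i in range(k):
                        for j in range(k):
                            row = xp[c, dd + i, hh + j]
                            if k == 3:
                                w0 = w[o, c, i, j, 0]
                                w1 = w[o, c, i, j, 1]
                                w2 = w[o, c, i, j, 2]
                                for vv in range(w_sz):
                                    acc[vv] += w0 * row[vv] + w1 * row[vv + 1] + w2 * row[vv + 2]
                            else:
                                for l in range(k):
                                    wv = w[o, c, i, j, l]
                                    for vv in range(w_sz):
                                        acc[vv] += wv * row[vv + l]


@njit(**_OPTS)
def _corr3d_dw(xp: np.ndarray, dy: np.ndarray, dw: np.ndarray) -> None:
    """dw[o,c,i,j,l] += sum_dhv dy[o,d,h,v] * xp[c,d+i,h+j,v+l]."""
    n_out, n_in = dw.shape[0], dw.shape[1]
    k = dw.shape[2]
    d_sz, h_sz, w_sz = dy.shape[1], dy.shape[2], dy.shape[3]
    for o in range(n_out):
        for c in range(n_in):
            for dd in range(d_sz):
                for hh in range(h_sz):
                    dyrow = dy[o, dd, hh]
                    for i in range(k):
                        for j in range(k):
                            xrow = xp[c, dd + i, hh + j]
                            if k == 3:
                                s0 = np.float32(0.0)
                                s1 = np.float32(0.0)
                                s2 = np.float32(0.0)
                                for vv in range(w_sz):
                                    dv = dyrow[vv]
                                    s0 += dv * xrow[vv]
                                    s1 += dv * xrow[vv + 1]
                                    s2 += dv * xrow[vv + 2]
                                dw[o, c, i, j, 0] += s0
                                dw[o, c, i, j, 1] += s1
                                dw[o, c, i, j, 2] += s2
                            else:
                                for l in range(k):
                                    s = np.float32(0.0)
                                    for vv in range(w_sz):
                                        s += dyrow[vv] * xrow[vv + l]
                                    dw[o, c, i, j, l] += s


def conv3d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    k = w.shape[2]
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    out = np.zeros((w.shape[0],) + x.shape[1:], dtype=np.float32)
    _corr3d(xp, w, out)
    return out + b.reshape(-1, 1, 1, 1)


def conv3d_backward_input(dy: np.ndarray, w: np.ndarray, x_shape) -> np.ndarray:
    # correlate dy with the spatially flipped, in/out-swapped kernel
    k = w.shape[2]
    p = k // 2
    wt = np.ascontiguousarray(w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
    dyp = np.pad(dy, ((0, 0), (p, p), (p, p), (p, p)))
    dx = np.zeros(x_shape, dtype=np.float32)
    _corr3d(dyp, wt, dx)
    return dx


def conv3d_backward_weights(x: np.ndarray, dy: np.ndarray, dw: np.ndarray) -> None:
    k = dw.shape[2]
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    _corr3d_dw(xp, dy, dw)
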