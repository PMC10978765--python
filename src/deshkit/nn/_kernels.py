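"""Fused numba kernels for the 3D convolution forward/backward passes.

The pure-NumPy shifted-GEMM path in :mod:`deshkit.nn.layers` is the
reference implementation; these kernels compute the same quantities with a
single pass over the volume (the two paths are cross-checked in the test
suite).  When numba is unavailable the layers fall back to the GEMM path.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True, fastmath=True)
def conv3d_forward(xp, w, out):  # pragma: no cover - numba-compiled
    """xp (C, Dp, Hp, Wp) zero-padded input; w (C, k, k, k, F); out (F, D, H, W).

    Row-wise accumulation: for each output row (d, h, :) the contribution of
    one (channel, offset, filter) triple is an AXPY over the contiguous
    fastest axis, which vectorises well.
    """
    c_in = xp.shape[0]
    k = w.shape[1]
    f_out = w.shape[4]
    d_out, h_out, w_out = out.shape[1], out.shape[2], out.shape[3]
    buf = np.empty((f_out, w_out), dtype=np.float32)
    for d in range(d_out):
        for h in range(h_out):
            buf[:, :] = 0.0
            for c in range(c_in):
                for od in range(k):
                    for oh in range(k):
                        row = xp[c, d + od, h + oh]
                        for ow in range(k):
                            for f in range(f_out):
                                wv = w[c, od, oh, ow, f]
                                for i in range(w_out):
                                    buf[f, i] += wv * row[ow + i]
            for f in range(f_out):
                for i in range(w_out):
                    out[f, d, h, i] = buf[f, i]


@njit(cache=True, fastmath=True)
def conv3d_weight_grad(xp, dy, dw):  # pragma: no cover - numba-compiled
    """dw (C, k, k, k, F) += correlation of padded input with output grad."""
    c_in = xp.shape[0]
    k = dw.shape[1]
    f_out = dw.shape[4]
    d_out, h_out, w_out = dy.shape[1], dy.shape[2], dy.shape[3]
    for d in range(d_out):
        for h in range(h_out):
            for c in range(c_in):
                for od in range(k):
                    for oh in range(k):
                        row = xp[c, d + od, h + oh]
                        for ow in range(k):
                            for f in range(f_out):
                                drow = dy[f, d, h]
                                s = np.float32(0.0)
                                for i in range(w_out):
                                    s += row[ow + i] * drow[i]
                                dw[c, od, oh, ow, f] += s
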