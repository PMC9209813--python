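"""Numba-compiled inner loops for the forward projector and beamformer.

Both kernels are exact restatements of the vectorized NumPy paths in
:mod:`patkit.forward` and :mod:`patkit.recon`; they exist purely because the
pixel-by-detector loops are memory-bound in NumPy.  Import degrades
gracefully so the package works (slower) without a working numba.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco


@njit(cache=True)
def ring_project(px, py, w, detx, dety, bin_mm, n_time, out):
    """Bin pixel mass into time-of-flight bins (linear interpolation)."""
    for d in range(detx.size):
        for i in range(px.size):
            dx = px[i] - detx[d]
            dy = py[i] - dety[d]
            f = np.sqrt(dx * dx + dy * dy) / bin_mm
            i0 = int(f)
            if i0 > n_time - 1:
                continue
            frac = f - i0
            out[d, i0] += (1.0 - frac) * w[i]
            if i0 + 1 < n_time:
                out[d, i0 + 1] += frac * w[i]


@njit(cache=True)
def ring_project_segments(px, py, w, ax, ay, bx, by, bin_mm, n_time, out):
    """Aperture sub-elements as segments: each pixel's mass is spread
    uniformly (in time of flight) over short sub-spans of the segment.

    Each segment is refined into 4 internal sub-spans so the uniform-in-f
    approximation of the flat-element integral is second-order accurate.
    """
    refine = 4
    for d in range(ax.size):
        for i in range(px.size):
            wm = w[i] / refine
            for m in range(refine):
                t0 = m / refine
                t1 = (m + 1) / refine
                sx0 = ax[d] + t0 * (bx[d] - ax[d])
                sy0 = ay[d] + t0 * (by[d] - ay[d])
                sx1 = ax[d] + t1 * (bx[d] - ax[d])
                sy1 = ay[d] + t1 * (by[d] - ay[d])
                dx0 = px[i] - sx0
                dy0 = py[i] - sy0
                dx1 = px[i] - sx1
                dy1 = py[i] - sy1
                f0 = np.sqrt(dx0 * dx0 + dy0 * dy0) / bin_mm
                f1 = np.sqrt(dx1 * dx1 + dy1 * dy1) / bin_mm
                lo = min(f0, f1)
                hi = max(f0, f1)
                if hi - lo < 1e-9:
                    i0 = int(lo)
                    if i0 > n_time - 1:
                        continue
                    frac = lo - i0
                    out[d, i0] += (1.0 - frac) * wm
                    if i0 + 1 < n_time:
                        out[d, i0 + 1] += frac * wm
                    continue
                dens = wm / (hi - lo)
                j0 = int(lo)
                j1 = min(int(hi), n_time - 1)
                for j in range(j0, j1 + 1):
                    a = lo if lo > j else j
                    b = hi if hi < j + 1 else j + 1
                    if b > a:
                        out[d, j] += dens * (b - a)


@njit(cache=True)
def das_sum(s, detx, dety, c_mm, px, py, out):
    """Delay-and-sum with linear interpolation between time samples."""
    n_pos, n_time = s.shape
    for d in range(n_pos):
        sx = detx[d]
        sy = dety[d]
        row = s[d]
        for p in range(px.size):
            dx = px[p] - sx
            dy = py[p] - sy
            tau = np.sqrt(dx * dx + dy * dy) / c_mm
            i0 = int(tau)
            if 0 <= i0 < n_time - 1:
                frac = tau - i0
                out[p] += (1.0 - frac) * row[i0] + frac * row[i0 + 1]
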