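"""Delay-and-sum beamforming, bipolar normalization, and training pairs.

The reconstructed image is a plain (unapodized) delay-and-sum over all
detector positions,

    I(x) = sum_d  s_d( |x - r_d| / c ),

with linear interpolation between time samples, evaluated on a fixed
128 x 128 pixel grid covering the 40 mm imaging region (0.3125 mm pitch).
Images are bipolar; :func:`normalize` rescales them affinely to [0, 1],
preserving the bipolar structure as an offset rather than clipping it.

:func:`make_pair` produces one (sparse input, dense ground truth) training
pair: the input is the reconstruction of a short noisy finite-aperture scan,
the ground truth the reconstruction of a dense, noise-free, ideal
point-detector scan of the same phantom.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _fast
from .forward import Medium, Sinogram, Transducer, plan_scan, simulate_sinogram
from .grid import IMAGING_DIAMETER_MM, RECON_SIZE, Preset
from .phantoms import PressureMap

__all__ = ["ReconImage", "das_reconstruct", "normalize", "make_pair"]


@dataclass(frozen=True)
class ReconImage:
    """Cross-sectional PAT image on the fixed 128 x 128 output grid."""

    values: np.ndarray
    pitch_mm: float
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("reconstruction must be a square 2D image")


def _output_coords(n: int, fov_mm: float) -> np.ndarray:
    return (np.arange(n) - (n - 1) / 2.0) * (fov_mm / n)


def das_reconstruct(
    sinogram: Sinogram,
    out_size: int = RECON_SIZE,
    fov_mm: float = IMAGING_DIAMETER_MM,
    medium: Medium = Medium(),
    dtype=np.float64,
    backend: str = "auto",
) -> ReconImage:
    """Delay-and-sum of a sinogram onto the output grid.

    Delays falling outside the recorded window contribute zero.  The
    ``numpy`` backend is the fully vectorized reference; ``numba`` runs the
    identical arithmetic as a compiled loop (``auto`` prefers it).  The
    computation dtype is configurable; float32 roughly halves the cost of
    dataset generation without visible effect on the normalized images.
    """
    if backend not in ("auto", "numpy", "numba"):
        raise ValueError(f"unknown backend {backend!r}")
    s = np.ascontiguousarray(sinogram.values, dtype=dtype)
    n_pos, n_time = s.shape
    det = sinogram.geometry.positions_mm.astype(dtype)
    if det.shape[0] != n_pos:
        raise ValueError("sinogram rows inconsistent with scan geometry")
    if sinogram.dt <= 0:
        raise ValueError("invalid time step")

    c_mm = medium.c * sinogram.dt * 1e3  # mm per time sample
    coords = _output_coords(out_size, fov_mm).astype(dtype)
    px = np.ascontiguousarray(np.broadcast_to(coords[None, :], (out_size, out_size)).ravel())
    py = np.ascontiguousarray(np.broadcast_to(coords[:, None], (out_size, out_size)).ravel())

    image = np.zeros(out_size * out_size, dtype=dtype)
    if backend == "numba" or (backend == "auto" and _fast.HAVE_NUMBA):
        if not _fast.HAVE_NUMBA:
            raise RuntimeError("numba backend requested but numba is unavailable")
        _fast.das_sum(s, np.ascontiguousarray(det[:, 0]), np.ascontiguousarray(det[:, 1]),
                      dtype(c_mm), px, py, image)
        return ReconImage(image.reshape(out_size, out_size), fov_mm / out_size, normalized=False)
    chunk = max(1, int(8e6 / px.size))
    for k in range(0, n_pos, chunk):
        d = det[k : k + chunk]
        tau = (
            np.sqrt((px[None, :] - d[:, None, 0]) ** 2 + (py[None, :] - d[:, None, 1]) ** 2)
            / c_mm
        )
        i0 = np.floor(tau).astype(np.int64)
        frac = (tau - i0).astype(dtype)
        valid = (i0 >= 0) & (i0 < n_time - 1)
        i0[~valid] = 0
        rows = s[k : k + d.shape[0]]
        gathered = (1.0 - frac) * np.take_along_axis(rows, i0, axis=1)
        gathered += frac * np.take_along_axis(rows, i0 + 1, axis=1)
        gathered[~valid] = 0.0
        image += gathered.sum(axis=0)
    return ReconImage(image.reshape(out_size, out_size), fov_mm / out_size, normalized=False)


def normalize(image: ReconImage) -> ReconImage:
    """Affine rescale to [0, 1]: (A - Amin) / (Amax - Amin).

    Zero pressure maps to -Amin/(Amax - Amin), so the bipolar structure is
    preserved as an offset.  Constant images have no defined rescaling.
    """
    amin = float(image.values.min())
    amax = float(image.values.max())
    if amax <= amin:
        raise ValueError("constant image cannot be normalized")
    return replace(image, values=(image.values - amin) / (amax - amin), normalized=True)


def make_pair(
    p0: PressureMap,
    preset: Preset,
    seed: int,
    scan_time_input: float | None = None,
    *,
    dtype=np.float64,
) -> tuple[ReconImage, ReconImage]:
    """One (sparse input X, dense ground truth Ygt) pair for a phantom.

    The input scan duration is drawn from the preset's admissible scan times
    unless given; its SNR is drawn from the preset's range.  The ground
    truth uses the preset's dense ideal-point-detector scan, noise-free.
    Deterministic for fixed (phantom, preset, seed).
    """
    rng = np.random.default_rng(seed)
    if scan_time_input is None:
        scan_time_input = float(rng.choice(preset.input_scan_times))
    snr_lo, snr_hi = preset.snr_db
    snr = float(rng.uniform(snr_lo, snr_hi)) if snr_hi > snr_lo else float(snr_lo)
    noise_seed = int(rng.integers(2**31))

    geo_in = plan_scan(
        scan_time_input, preset.prr, preset.n_ust, preset.scan_radius_mm, preset.averaging_factor
    )
    tr_in = Transducer(preset.fc_mhz, preset.fractional_bandwidth, preset.aperture_mm, ideal=False)
    sino_in = simulate_sinogram(p0, geo_in, tr_in, snr_db=snr, seed=noise_seed)
    x = normalize(das_reconstruct(sino_in, dtype=dtype))

    geo_gt = plan_scan(
        preset.gt_duration, preset.prr, preset.n_ust, preset.scan_radius_mm, preset.averaging_factor
    )
    tr_gt = Transducer(preset.fc_mhz, preset.fractional_bandwidth, ideal=True)
    sino_gt = simulate_sinogram(p0, geo_gt, tr_gt, snr_db=np.inf)
    y = normalize(das_reconstruct(sino_gt, dtype=dtype))
    return x, y
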