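"""Shared fixtures: small grids, phantoms and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from patkit.forward import Medium, Sinogram
from patkit.grid import ImageGrid, preset_1ust
from patkit.phantoms import PressureMap


@pytest.fixture(scope="session")
def grid_1ust() -> ImageGrid:
    return preset_1ust().grid


@pytest.fixture(scope="session")
def small_grid() -> ImageGrid:
    """Coarse 82 mm grid for fast simulation tests."""
    return ImageGrid(82, 82, 1.0)


@pytest.fixture()
def centred_point(grid_1ust) -> PressureMap:
    values = np.zeros((grid_1ust.ny, grid_1ust.nx))
    values[grid_1ust.ny // 2, grid_1ust.nx // 2] = 1.0
    return PressureMap(grid_1ust, values)


def das_oracle(
    sinogram: Sinogram, out_size: int, fov_mm: float, medium: Medium = Medium()
) -> np.ndarray:
    """Brute-force per-pixel / per-detector delay-and-sum double loop."""
    s = sinogram.values
    det = sinogram.geometry.positions_mm
    c_mm = medium.c * sinogram.dt * 1e3
    coords = (np.arange(out_size) - (out_size - 1) / 2.0) * (fov_mm / out_size)
    out = np.zeros((out_size, out_size))
    for iy in range(out_size):
        for ix in range(out_size):
            acc = 0.0
            for d in range(det.shape[0]):
                tau = np.hypot(coords[ix] - det[d, 0], coords[iy] - det[d, 1]) / c_mm
                i0 = int(np.floor(tau))
                if 0 <= i0 < s.shape[1] - 1:
                    frac = tau - i0
                    acc += (1.0 - frac) * s[d, i0] + frac * s[d, i0 + 1]
            out[iy, ix] = acc
    return out


def dft2_oracle(img: np.ndarray) -> np.ndarray:
    """Direct double-sum unnormalized 2D DFT (O(N^4); tiny images only)."""
    m, n = img.shape
    out = np.zeros((m, n), dtype=complex)
    for u in range(m):
        for v in range(n):
            acc = 0.0 + 0.0j
            for a in range(m):
                for b in range(n):
                    acc += img[a, b] * np.exp(-2j * np.pi * (u * a / m + v * b / n))
            out[u, v] = acc
    return out
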