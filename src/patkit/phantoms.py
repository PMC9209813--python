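"""Numerical initial-pressure phantoms for circular-scan PAT simulation.

Three families are generated, mirroring the simulated training corpus:

* **point targets** -- small discs (default 0.5 mm diameter, the calibre of a
  pencil-lead target) at random non-overlapping positions with random
  strengths; five per phantom for training, nine for the held-out test shape;
* **triangles** -- thin (1-pixel) triangle outlines, the numerical analogue
  of a horsehair phantom, with random centre, rotation and side length;
* **vessels** -- a procedural branching structure emulating the cerebral
  venous sinuses of a rodent brain: one smooth trunk crossing the imaging
  disc plus lateral branches, each with a Gaussian cross-section and an
  independent magnitude.

All generators are pure functions of (grid, parameters, seed), and all
phantom mass lies inside the centred 40 mm imaging disc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line

from .grid import IMAGING_DIAMETER_MM, ImageGrid

__all__ = [
    "PressureMap",
    "PlacementError",
    "gen_point_phantom",
    "gen_triangle_phantom",
    "gen_vessel_phantom",
    "gen_phantom",
    "FAMILIES",
]

FAMILIES = ("points", "triangle", "vessel")

#: retry budget for rejection-sampled point placement
PLACEMENT_RETRIES = 1000


class PlacementError(RuntimeError):
    """Raised when non-overlapping placement cannot be achieved."""


@dataclass(frozen=True)
class PressureMap:
    """Initial pressure distribution p0 >= 0 on a physical grid."""

    grid: ImageGrid
    values: np.ndarray  # (ny, nx), non-negative

    def __post_init__(self) -> None:
        if self.values.shape != (self.grid.ny, self.grid.nx):
            raise ValueError("values shape does not match grid")
        if np.any(self.values < 0):
            raise ValueError("initial pressure must be non-negative")

    @property
    def mask(self) -> np.ndarray:
        return self.values > 0

    def n_components(self) -> int:
        """Connected components of the support (8-connectivity)."""
        _, n = ndimage.label(self.mask, structure=np.ones((3, 3)))
        return int(n)


def _disc_radius(diameter_mm: float = IMAGING_DIAMETER_MM) -> float:
    return diameter_mm / 2.0


def _pixel_centres(grid: ImageGrid) -> tuple[np.ndarray, np.ndarray]:
    x, y = grid.coords()
    return np.meshgrid(x, y, indexing="xy")


def _clip_to_disc(grid: ImageGrid, values: np.ndarray) -> np.ndarray:
    values = values.copy()
    values[~grid.imaging_disc_mask()] = 0.0
    return values


def gen_point_phantom(
    grid: ImageGrid,
    n_points: int,
    seed: int,
    *,
    point_diameter_mm: float = 0.5,
    strength_range: tuple[float, float] = (0.5, 1.0),
) -> PressureMap:
    """Discs at random non-overlapping positions inside the imaging disc.

    Each disc's strength is drawn independently from ``strength_range``.
    Raises :class:`PlacementError` if non-overlapping placement fails after
    ``PLACEMENT_RETRIES`` rejection-sampling attempts.
    """
    if n_points < 0:
        raise ValueError("n_points must be >= 0")
    rng = np.random.default_rng(seed)
    values = np.zeros((grid.ny, grid.nx))
    if n_points == 0:
        return PressureMap(grid, values)

    r_pt = point_diameter_mm / 2.0
    r_max = _disc_radius() - r_pt - grid.dx  # keep discs fully inside
    min_sep = point_diameter_mm + 2.0 * grid.dx  # non-touching after rasterization

    centres: list[tuple[float, float]] = []
    attempts = 0
    while len(centres) < n_points:
        if attempts >= PLACEMENT_RETRIES:
            raise PlacementError(
                f"could not place {n_points} non-overlapping points "
                f"after {PLACEMENT_RETRIES} attempts"
            )
        attempts += 1
        rad = r_max * np.sqrt(rng.uniform())
        ang = rng.uniform(0.0, 2.0 * np.pi)
        cx, cy = rad * np.cos(ang), rad * np.sin(ang)
        if all((cx - px) ** 2 + (cy - py) ** 2 >= min_sep**2 for px, py in centres):
            centres.append((cx, cy))

    xx, yy = _pixel_centres(grid)
    for cx, cy in centres:
        strength = rng.uniform(*strength_range)
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_pt**2
        if not mask.any():  # sub-pixel disc: light the nearest pixel
            j = int(np.clip(round(cx / grid.dx + (grid.nx - 1) / 2), 0, grid.nx - 1))
            i = int(np.clip(round(cy / grid.dx + (grid.ny - 1) / 2), 0, grid.ny - 1))
            mask = np.zeros_like(mask)
            mask[i, j] = True
        values[mask] = strength
    return PressureMap(grid, _clip_to_disc(grid, values))


def _mm_to_px(grid: ImageGrid, x_mm: np.ndarray, y_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    col = x_mm / grid.dx + (grid.nx - 1) / 2.0
    row = y_mm / grid.dx + (grid.ny - 1) / 2.0
    return row, col


def triangle_vertices(
    centre: tuple[float, float], side_mm: float, rotation_rad: float
) -> np.ndarray:
    """Vertices (mm) of an equilateral triangle; rotation is about its centroid."""
    circum = side_mm / np.sqrt(3.0)
    angles = rotation_rad + np.array([0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0])
    return np.column_stack(
        [centre[0] + circum * np.cos(angles), centre[1] + circum * np.sin(angles)]
    )


def rasterize_triangle(
    grid: ImageGrid, vertices: np.ndarray, strength: float, filled: bool = False
) -> np.ndarray:
    """Rasterize a triangle outline (1-pixel edges) or filled interior."""
    values = np.zeros((grid.ny, grid.nx))
    if filled:
        from skimage.draw import polygon

        rr_f, cc_f = _mm_to_px(grid, vertices[:, 0], vertices[:, 1])
        rr, cc = polygon(rr_f, cc_f, shape=values.shape)
        values[rr, cc] = strength
        return values
    for a in range(3):
        b = (a + 1) % 3
        r0, c0 = _mm_to_px(grid, vertices[a, 0], vertices[a, 1])
        r1, c1 = _mm_to_px(grid, vertices[b, 0], vertices[b, 1])
        rr, cc = draw_line(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))
        keep = (rr >= 0) & (rr < grid.ny) & (cc >= 0) & (cc < grid.nx)
        values[rr[keep], cc[keep]] = strength
    return values


def gen_triangle_phantom(
    grid: ImageGrid,
    seed: int,
    *,
    side_range_mm: tuple[float, float] = (8.0, 24.0),
    strength_range: tuple[float, float] = (0.5, 1.0),
    filled: bool = False,
) -> PressureMap:
    """One random hollow triangle, fully inside the imaging disc."""
    if side_range_mm[1] / np.sqrt(3.0) >= _disc_radius():
        raise ValueError("triangle size bounds exceed the imaging disc")
    rng = np.random.default_rng(seed)
    side = rng.uniform(*side_range_mm)
    rotation = rng.uniform(0.0, 2.0 * np.pi)
    circum = side / np.sqrt(3.0)
    r_max = _disc_radius() - circum - grid.dx
    rad = r_max * np.sqrt(rng.uniform())
    ang = rng.uniform(0.0, 2.0 * np.pi)
    centre = (rad * np.cos(ang), rad * np.sin(ang))
    strength = rng.uniform(*strength_range)
    verts = triangle_vertices(centre, side, rotation)
    return PressureMap(grid, _clip_to_disc(grid, rasterize_triangle(grid, verts, strength, filled)))


def _smooth_profile(
    grid: ImageGrid, mask: np.ndarray, width_mm: float, magnitude: float
) -> np.ndarray:
    """Give a thin rasterized path a Gaussian cross-section (FWHM = width)."""
    sigma_px = max(width_mm / grid.dx / 2.355, 0.4)
    blurred = ndimage.gaussian_filter(mask.astype(float), sigma_px, truncate=3.0)
    peak = blurred.max()
    if peak <= 0:
        return np.zeros_like(blurred)
    out = magnitude * blurred / peak
    out[out < 0.135 * magnitude] = 0.0  # support ends ~2 sigma off the ridge
    return out


def _draw_polyline(grid: ImageGrid, pts_mm: np.ndarray) -> np.ndarray:
    mask = np.zeros((grid.ny, grid.nx), dtype=bool)
    rr_f, cc_f = _mm_to_px(grid, pts_mm[:, 0], pts_mm[:, 1])
    for k in range(len(pts_mm) - 1):
        rr, cc = draw_line(
            int(round(rr_f[k])), int(round(cc_f[k])), int(round(rr_f[k + 1])), int(round(cc_f[k + 1]))
        )
        keep = (rr >= 0) & (rr < grid.ny) & (cc >= 0) & (cc < grid.nx)
        mask[rr[keep], cc[keep]] = True
    return mask


def gen_vessel_phantom(
    grid: ImageGrid,
    seed: int,
    *,
    n_branches_range: tuple[int, int] = (2, 6),
    width_range_mm: tuple[float, float] = (0.3, 1.0),
    magnitude_range: tuple[float, float] = (0.5, 1.0),
    magnitude_scale: float = 1.0,
) -> PressureMap:
    """Sinus-like branching vessel: a smooth trunk with lateral branches.

    The trunk is a quadratic Bezier curve crossing the imaging disc; branches
    leave the trunk at random stations and angles.  Each segment is drawn
    with a Gaussian cross-section of random width and magnitude; the global
    orientation and position are randomized through the trunk endpoints.
    ``magnitude_scale`` scales the whole map (0 gives an empty phantom).
    """
    rng = np.random.default_rng(seed)
    disc_r = _disc_radius()

    # trunk: endpoints on opposite sides of the disc, pulled inwards
    theta = rng.uniform(0.0, 2.0 * np.pi)
    span = rng.uniform(0.75, 0.9) * disc_r
    p0 = np.array([span * np.cos(theta), span * np.sin(theta)])
    p1 = -p0 + rng.normal(0.0, 0.1 * disc_r, 2)
    ctrl = rng.normal(0.0, 0.3 * disc_r, 2)  # bows the trunk
    t = np.linspace(0.0, 1.0, 200)[:, None]
    trunk = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * ctrl + t**2 * p1

    trunk_width = rng.uniform(0.6, 1.0) * width_range_mm[1]
    layers = [
        _smooth_profile(grid, _draw_polyline(grid, trunk), trunk_width, rng.uniform(*magnitude_range))
    ]

    tangent = np.gradient(trunk, axis=0)
    n_branches = int(rng.integers(n_branches_range[0], n_branches_range[1] + 1))
    for _ in range(n_branches):
        station = int(rng.integers(20, len(trunk) - 20))
        base = trunk[station]
        tang_ang = np.arctan2(tangent[station, 1], tangent[station, 0])
        side = rng.choice([-1.0, 1.0])
        ang = tang_ang + side * rng.uniform(np.pi / 6.0, np.pi / 2.0)
        length = rng.uniform(0.2, 0.6) * disc_r
        curl = rng.normal(0.0, 0.3)  # gentle curvature of the branch
        s = np.linspace(0.0, 1.0, 80)
        bx = base[0] + length * s * np.cos(ang + curl * s)
        by = base[1] + length * s * np.sin(ang + curl * s)
        pts = np.column_stack([bx, by])
        layers.append(
            _smooth_profile(
                grid,
                _draw_polyline(grid, pts),
                rng.uniform(*width_range_mm),
                rng.uniform(*magnitude_range),
            )
        )

    values = magnitude_scale * np.max(layers, axis=0)
    return PressureMap(grid, _clip_to_disc(grid, values))


def gen_phantom(family: str, grid: ImageGrid, seed: int, **kwargs) -> PressureMap:
    """Dispatch by family name (``points``/``triangle``/``vessel``)."""
    if family == "points":
        return gen_point_phantom(grid, kwargs.pop("n_points", 5), seed, **kwargs)
    if family == "triangle":
        return gen_triangle_phantom(grid, seed, **kwargs)
    if family == "vessel":
        return gen_vessel_phantom(grid, seed, **kwargs)
    raise ValueError(f"unknown phantom family {family!r}; choose from {FAMILIES}")
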