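"""Circular-scan PA forward model: geometry planning and A-line simulation.

In a homogeneous lossless medium the pressure recorded by a point detector
at ``r_d`` from an initial pressure ``p0`` is proportional to

    p(r_d, t)  ~  d/dt [ t * M(p0)(r_d, c t) ]

where ``M`` is the circular-mean operator (mean of ``p0`` over the circle of
radius ``ct`` centred on the detector).  Since ``t * M`` is, up to constants,
the line integral of ``p0`` over that circle, the simulator reduces to a
ring-sum of the phantom's nonzero pixels followed by a time derivative.
Band-limited detection is modelled by convolution with a Gaussian-modulated
impulse response; a finite flat aperture is modelled by averaging point
sub-elements spread along the tangent of the scan circle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from . import _fast
from .grid import IMAGING_DIAMETER_MM, N_TIME, SOUND_SPEED, TIME_STEP
from .phantoms import PressureMap

__all__ = [
    "Transducer",
    "Medium",
    "ScanGeometry",
    "Sinogram",
    "plan_scan",
    "transducer_eir",
    "add_noise",
    "simulate_sinogram",
]


@dataclass(frozen=True)
class Transducer:
    """Single-element detector model.

    ``ideal`` marks a point detector with delta impulse response (used for
    ground-truth scans); otherwise the element is band-limited with centre
    frequency ``fc_mhz`` and has a flat aperture of width ``aperture_mm``
    tangent to the scan circle.
    """

    fc_mhz: float = 2.25
    fractional_bandwidth: float = 0.7
    aperture_mm: float = 13.0
    ideal: bool = False

    def __post_init__(self) -> None:
        if self.fc_mhz <= 0:
            raise ValueError("central frequency must be positive")
        if not 0 < self.fractional_bandwidth < 2:
            raise ValueError("fractional bandwidth must be in (0, 2)")
        if self.aperture_mm < 0:
            raise ValueError("aperture must be >= 0")

    @property
    def effective_aperture_mm(self) -> float:
        return 0.0 if self.ideal else self.aperture_mm


@dataclass(frozen=True)
class Medium:
    c: float = SOUND_SPEED  # m/s
    homogeneous: bool = True


@dataclass(frozen=True)
class ScanGeometry:
    """Detector positions of one circular scan.

    With ``n_ust`` transducers the circle is divided into equal angular
    sectors and each transducer sweeps its own sector, contributing
    ``positions_per_ust`` uniformly spaced positions.
    """

    scan_radius_mm: float
    n_ust: int
    positions_per_ust: int
    duration_s: float
    prr_hz: float

    @property
    def n_positions(self) -> int:
        return self.n_ust * self.positions_per_ust

    @property
    def angles(self) -> np.ndarray:
        sector = 2.0 * np.pi / self.n_ust
        per = self.positions_per_ust
        out = np.empty(self.n_positions)
        for u in range(self.n_ust):
            out[u * per : (u + 1) * per] = u * sector + np.arange(per) * sector / per
        return out

    @property
    def positions_mm(self) -> np.ndarray:
        """(n_positions, 2) detector centre coordinates in mm."""
        a = self.angles
        return self.scan_radius_mm * np.column_stack([np.cos(a), np.sin(a)])


@dataclass(frozen=True)
class Sinogram:
    """Per-position A-lines with sampling metadata; t=0 at laser firing."""

    values: np.ndarray  # (n_positions, n_time)
    dt: float  # s
    geometry: ScanGeometry
    transducer: Transducer

    @property
    def n_time(self) -> int:
        return self.values.shape[1]


def plan_scan(
    duration_s: float,
    prr_hz: float,
    n_ust: int = 1,
    scan_radius_mm: float = 37.0,
    averaging_factor: float = 1.0,
) -> ScanGeometry:
    """Derive detector positions from scan duration, PRR and UST count.

    ``averaging_factor`` is the number of fired pulses binned into one
    retained detector position (1 for the 1-UST system; 2.5 for the 8-UST
    presets, whose 0.3 s / 600-pulse fast scan keeps 240 positions).
    """
    if duration_s <= 0 or prr_hz <= 0:
        raise ValueError("duration and PRR must be positive")
    if n_ust < 1:
        raise ValueError("need at least one transducer")
    if duration_s * prr_hz < 1:
        raise ValueError("no pulses fired during the scan window")
    per_ust = int(round(duration_s * prr_hz / averaging_factor / n_ust))
    if per_ust < 1:
        raise ValueError("scan too short for even one position per transducer")
    return ScanGeometry(scan_radius_mm, n_ust, per_ust, duration_s, prr_hz)


def transducer_eir(
    transducer: Transducer, dt: float = TIME_STEP, n_time: int = N_TIME
) -> np.ndarray:
    """Zero-phase Gaussian-modulated impulse response of the transducer.

    The amplitude spectrum is Gaussian, peaking at the centre frequency with
    a -6 dB full width of ``fractional_bandwidth * fc``; it is normalized to
    unit peak spectral magnitude.  Ideal transducers get a delta kernel.
    """
    if transducer.ideal:
        return np.array([1.0])
    fc = transducer.fc_mhz * 1e6
    nyquist = 1.0 / (2.0 * dt)
    if fc >= nyquist:
        raise ValueError(f"centre frequency {fc:.3g} Hz is at/above Nyquist {nyquist:.3g} Hz")
    # -6 dB full width (amplitude halves) of a Gaussian: 2*sigma_f*sqrt(2 ln 2)
    sigma_f = transducer.fractional_bandwidth * fc / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
    half = int(np.ceil(4.0 * sigma_t / dt))
    t = np.arange(-half, half + 1) * dt
    kernel = np.cos(2.0 * np.pi * fc * t) * np.exp(-(t**2) / (2.0 * sigma_t**2))
    nfft = max(4096, 4 * kernel.size)
    kernel /= np.abs(np.fft.rfft(kernel, nfft)).max()
    return kernel


def add_noise(values: np.ndarray, snr_db: float, seed: int) -> np.ndarray:
    """Additive white Gaussian noise at an rms-defined SNR.

    SNR is ``20 log10(rms_signal / rms_noise)``; ``snr_db=inf`` is the
    identity.  All-zero input has undefined signal power and is rejected.
    """
    if np.isinf(snr_db):
        return values.copy()
    rms = np.sqrt(np.mean(values**2))
    if rms == 0:
        raise ValueError("cannot set an SNR for an all-zero signal")
    noise_rms = rms / 10.0 ** (snr_db / 20.0)
    rng = np.random.default_rng(seed)
    return values + noise_rms * rng.standard_normal(values.shape)


def _detector_segments(
    geometry: ScanGeometry, transducer: Transducer, n_subelements: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """Partition each flat aperture into tangential sub-element segments.

    Returns the segment endpoint arrays (n_positions * n_subelements, 2).
    The segments tile the active element exactly, so summing their
    contributions with weight 1/n_subelements integrates over the aperture.
    """
    centres = geometry.positions_mm
    ap = transducer.effective_aperture_mm
    a = geometry.angles
    tangents = np.column_stack([-np.sin(a), np.cos(a)])
    edges = np.linspace(-ap / 2.0, ap / 2.0, n_subelements + 1)
    starts = centres[:, None, :] + edges[:-1, None] * tangents[:, None, :]
    ends = centres[:, None, :] + edges[1:, None] * tangents[:, None, :]
    return starts.reshape(-1, 2), ends.reshape(-1, 2), n_subelements


def _ring_projection(
    px_xy_mm: np.ndarray,
    weights: np.ndarray,
    det_xy_mm: np.ndarray,
    c: float,
    dt: float,
    n_time: int,
) -> np.ndarray:
    """Bin phantom pixel mass into time-of-flight bins for each detector point.

    Linear (hat) interpolation between adjacent bins keeps the operator exact
    on fractional arrival times.  Returns (n_det_points, n_time).
    """
    n_det = det_xy_mm.shape[0]
    bin_mm = c * dt * 1e3  # radial bin width in mm
    if _fast.HAVE_NUMBA:
        out = np.zeros((n_det, n_time))
        _fast.ring_project(
            np.ascontiguousarray(px_xy_mm[:, 0]),
            np.ascontiguousarray(px_xy_mm[:, 1]),
            np.ascontiguousarray(weights),
            np.ascontiguousarray(det_xy_mm[:, 0]),
            np.ascontiguousarray(det_xy_mm[:, 1]),
            bin_mm,
            n_time,
            out,
        )
        return out
    out = np.zeros(n_det * (n_time + 1))
    # chunk detectors so the distance matrix stays small
    chunk = max(1, int(8e6 / max(len(weights), 1)))
    for s in range(0, n_det, chunk):
        d = det_xy_mm[s : s + chunk]
        dist = np.sqrt(
            (px_xy_mm[None, :, 0] - d[:, None, 0]) ** 2
            + (px_xy_mm[None, :, 1] - d[:, None, 1]) ** 2
        )
        f = dist / bin_mm
        i0 = np.floor(f).astype(np.int64)
        frac = f - i0
        w = np.broadcast_to(weights, f.shape).copy()
        late = i0 > n_time - 1  # arrival outside the recording window
        w[late] = 0.0
        i0[late] = 0
        rows = (np.arange(s, s + d.shape[0])[:, None]) * (n_time + 1)
        flat0 = (rows + i0).ravel()
        out += np.bincount(flat0, ((1.0 - frac) * w).ravel(), minlength=out.size)
        out += np.bincount(flat0 + 1, (frac * w).ravel(), minlength=out.size)
    return out.reshape(n_det, n_time + 1)[:, :n_time]


def _segment_projection(
    px_xy_mm: np.ndarray,
    weights: np.ndarray,
    starts_mm: np.ndarray,
    ends_mm: np.ndarray,
    c: float,
    dt: float,
    n_time: int,
) -> np.ndarray:
    """Aperture segments: spread each pixel's mass over the time-of-flight
    span of every sub-element segment (uniform within the span)."""
    n_det = starts_mm.shape[0]
    bin_mm = c * dt * 1e3
    out = np.zeros((n_det, n_time))
    if _fast.HAVE_NUMBA:
        _fast.ring_project_segments(
            np.ascontiguousarray(px_xy_mm[:, 0]),
            np.ascontiguousarray(px_xy_mm[:, 1]),
            np.ascontiguousarray(weights),
            np.ascontiguousarray(starts_mm[:, 0]),
            np.ascontiguousarray(starts_mm[:, 1]),
            np.ascontiguousarray(ends_mm[:, 0]),
            np.ascontiguousarray(ends_mm[:, 1]),
            bin_mm,
            n_time,
            out,
        )
        return out
    # fallback: subdivide each segment into point samples
    n_pts = 4
    t = (np.arange(n_pts) + 0.5) / n_pts
    for k in range(n_pts):
        pts = starts_mm + t[k] * (ends_mm - starts_mm)
        out += _ring_projection(px_xy_mm, weights, pts, c, dt, n_time)
    return out / n_pts


def simulate_sinogram(
    p0: PressureMap,
    geometry: ScanGeometry,
    transducer: Transducer,
    medium: Medium = Medium(),
    snr_db: float = np.inf,
    seed: int = 0,
    *,
    dt: float = TIME_STEP,
    n_time: int = N_TIME,
    n_subelements: int = 9,
) -> Sinogram:
    """Simulate band-limited, finite-aperture, noisy A-lines from ``p0``."""
    if geometry.n_positions < 1:
        raise ValueError("empty scan geometry")
    reach_mm = medium.c * dt * n_time * 1e3
    if geometry.scan_radius_mm + IMAGING_DIAMETER_MM > reach_mm:
        raise ValueError("recording window too short to cover the imaging region")

    iy, ix = np.nonzero(p0.values)
    empty = iy.size == 0
    if empty and np.isfinite(snr_db):
        raise ValueError("cannot set an SNR for an all-zero phantom")

    if empty:
        signal = np.zeros((geometry.n_positions, n_time))
    else:
        x_mm, y_mm = p0.grid.coords()
        px = np.column_stack([x_mm[ix], y_mm[iy]])
        weights = p0.values[iy, ix] * p0.grid.dx**2  # pixel mass
        if transducer.effective_aperture_mm > 0.0 and n_subelements >= 1:
            starts, ends, n_sub = _detector_segments(geometry, transducer, n_subelements)
            ring = _segment_projection(px, weights, starts, ends, medium.c, dt, n_time)
            ring = ring.reshape(geometry.n_positions, n_sub, n_time).mean(axis=1)
        else:
            ring = _ring_projection(px, weights, geometry.positions_mm, medium.c, dt, n_time)
        signal = np.gradient(ring, dt, axis=1)
        kernel = transducer_eir(transducer, dt, n_time)
        if kernel.size > 1:
            signal = fftconvolve(signal, kernel[None, :], mode="same", axes=1)
        if np.isfinite(snr_db):
            signal = add_noise(signal, snr_db, seed)
    return Sinogram(signal, dt, geometry, transducer)
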