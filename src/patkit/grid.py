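"""Computational grids and system presets for circular-scan PAT simulation.

The simulation domain is an 82 x 82 mm square grid; the imaging region (where
phantom absorbers may live) is a centred disc of 40 mm diameter.  Two system
presets are provided: a single rotating transducer driven by a 10 Hz laser
(``1ust``) and an eight-transducer system driven by a 2 kHz pulsed laser diode
(``8ust``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: side length of the simulation domain, mm
DOMAIN_MM = 82.0
#: diameter of the imaging region (centred disc), mm
IMAGING_DIAMETER_MM = 40.0
#: speed of sound in the homogeneous medium, m/s
SOUND_SPEED = 1500.0
#: temporal sampling step of every A-line, s
TIME_STEP = 40e-9
#: number of recorded time samples per A-line
N_TIME = 1500
#: side of the reconstructed image, pixels
RECON_SIZE = 128


@dataclass(frozen=True)
class ImageGrid:
    """Square pixel grid with physical coordinates centred on the scan axis."""

    nx: int
    ny: int
    dx: float  # mm / pixel

    def __post_init__(self) -> None:
        if self.nx <= 0 or self.ny <= 0 or self.dx <= 0:
            raise ValueError("grid dimensions and spacing must be positive")

    @property
    def extent_mm(self) -> tuple[float, float]:
        return (self.nx * self.dx, self.ny * self.dx)

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-centre coordinates (x, y) in mm, origin at grid centre."""
        x = (np.arange(self.nx) - (self.nx - 1) / 2.0) * self.dx
        y = (np.arange(self.ny) - (self.ny - 1) / 2.0) * self.dx
        return x, y

    def imaging_disc_mask(self, diameter_mm: float = IMAGING_DIAMETER_MM) -> np.ndarray:
        """Boolean mask of pixels inside the centred imaging disc."""
        x, y = self.coords()
        xx, yy = np.meshgrid(x, y, indexing="xy")
        return xx**2 + yy**2 <= (diameter_mm / 2.0) ** 2


def grid_1ust() -> ImageGrid:
    """82 x 82 mm domain at 0.2 mm/pixel (410 x 410) for the 1-UST system."""
    return ImageGrid(410, 410, 0.2)


def grid_8ust() -> ImageGrid:
    """82 x 82 mm domain at 0.1 mm/pixel (820 x 820) for the 8-UST system."""
    return ImageGrid(820, 820, 0.1)


@dataclass(frozen=True)
class Preset:
    """Acquisition preset bundling grid, laser and transducer parameters.

    ``input_scan_times`` are the admissible sparse-scan durations (seconds)
    from which dataset generation draws; ``gt_duration`` defines the dense
    ideal-point-detector ground-truth scan.  ``snr_db`` is a (low, high)
    range; a single-valued range encodes a fixed SNR.
    """

    name: str
    grid: ImageGrid
    n_ust: int
    prr: float  # laser pulse repetition rate, Hz
    averaging_factor: float  # fired pulses per retained detector position
    fc_mhz: float  # transducer centre frequency, MHz
    fractional_bandwidth: float
    aperture_mm: float  # active element width of the physical transducer
    snr_db: tuple[float, float]
    input_scan_times: tuple[float, ...]
    gt_duration: float  # s; with prr/averaging gives the ground-truth positions
    scan_radius_mm: float = 37.0
    n_phantoms: int = 1500  # full-scale dataset size

    @property
    def gt_positions(self) -> int:
        return int(round(self.gt_duration * self.prr / self.averaging_factor))


def preset_1ust() -> Preset:
    """Single-UST system: 10 Hz laser, 2.25 MHz / 70% bw / 13 mm transducer.

    Sparse inputs use 1-5 s scans (10-50 positions) at 40 dB SNR; ground
    truth uses an 8 min scan (4800 ideal point-detector positions).
    """
    return Preset(
        name="1ust",
        grid=grid_1ust(),
        n_ust=1,
        prr=10.0,
        averaging_factor=1.0,
        fc_mhz=2.25,
        fractional_bandwidth=0.7,
        aperture_mm=13.0,
        snr_db=(40.0, 40.0),
        input_scan_times=(1.0, 2.0, 3.0, 4.0, 5.0),
        gt_duration=480.0,
        n_phantoms=1500,
    )


def preset_8ust() -> Preset:
    """Eight-UST system: 2 kHz PLD, 5 MHz / 70% bw transducers.

    The fast scan lasts 0.3 s; with the preset averaging factor of 2.5 the
    600 fired pulses yield 240 retained detector positions (30 per UST).
    Ground truth uses 1600 ideal positions; SNR of the sparse inputs is
    drawn uniformly from 10-20 dB.
    """
    return Preset(
        name="8ust",
        grid=grid_8ust(),
        n_ust=8,
        prr=2000.0,
        averaging_factor=2.5,
        fc_mhz=5.0,
        fractional_bandwidth=0.7,
        aperture_mm=13.0,
        snr_db=(10.0, 20.0),
        input_scan_times=(0.3,),
        gt_duration=2.0,
        n_phantoms=500,
    )


_PRESETS = {"1ust": preset_1ust, "8ust": preset_8ust}


def get_preset(name: str) -> Preset:
    try:
        return _PRESETS[name]()
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}") from None
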