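"""ANSI skin maximum-permissible-exposure (MPE) calculator, 700-1050 nm.

Implements the two closed-form limits that govern pulsed near-infrared
illumination of skin in this wavelength window and the derived per-pulse
budget for a continuous scan of duration ``t`` at pulse repetition rate
``prr``:

* single-pulse fluence limit      ``20 * 10^(2(lambda-700)/1000)``  mJ/cm^2
* extended-exposure fluence limit ``1.1 * 10^(2(lambda-700)/1000) * t^0.25``  J/cm^2
* per-pulse limit in a scan       extended limit / number of pulses

Compliance requires the delivered per-pulse fluence to stay below both the
single-pulse limit and the per-pulse share of the extended limit.
"""

from __future__ import annotations

from dataclasses import dataclass

WAVELENGTH_RANGE_NM = (700.0, 1050.0)


def _check_wavelength(wavelength_nm: float) -> None:
    lo, hi = WAVELENGTH_RANGE_NM
    if not lo <= wavelength_nm <= hi:
        raise ValueError(
            f"wavelength {wavelength_nm} nm outside the {lo:.0f}-{hi:.0f} nm validity range"
        )


def _ca(wavelength_nm: float) -> float:
    """Wavelength correction factor 10^(2(lambda-700)/1000)."""
    return 10.0 ** (2.0 * (wavelength_nm - 700.0) / 1000.0)


def mpe_single_pulse(wavelength_nm: float) -> float:
    """Single-pulse skin MPE in mJ/cm^2."""
    _check_wavelength(wavelength_nm)
    return 20.0 * _ca(wavelength_nm)


def mpe_exposure(wavelength_nm: float, duration_s: float) -> float:
    """Extended-exposure skin MPE in J/cm^2 for an illumination of ``duration_s``."""
    _check_wavelength(wavelength_nm)
    if duration_s <= 0:
        raise ValueError("exposure duration must be positive")
    return 1.1 * _ca(wavelength_nm) * duration_s**0.25


def mpe_per_pulse_in_scan(wavelength_nm: float, duration_s: float, prr_hz: float) -> float:
    """Per-pulse fluence budget in mJ/cm^2 during a scan at ``prr_hz``.

    The extended-exposure limit is divided equally across the
    ``duration_s * prr_hz`` pulses fired during the scan.
    """
    n_pulses = duration_s * prr_hz
    if n_pulses < 1:
        raise ValueError("fewer than one pulse in the exposure window")
    return 1000.0 * mpe_exposure(wavelength_nm, duration_s) / n_pulses


@dataclass(frozen=True)
class ExposureQuery:
    """A laser-exposure scenario to be checked against the ANSI limits."""

    wavelength_nm: float
    duration_s: float
    prr_hz: float
    fluence_mj_cm2: float  # delivered per-pulse fluence


@dataclass(frozen=True)
class ComplianceReport:
    compliant: bool
    fluence_mj_cm2: float
    limit_single_pulse: float  # mJ/cm^2
    limit_per_pulse_in_scan: float  # mJ/cm^2

    @property
    def binding_limit(self) -> float:
        return min(self.limit_single_pulse, self.limit_per_pulse_in_scan)

    @property
    def margin_mj_cm2(self) -> float:
        """Headroom below the binding limit (negative when non-compliant)."""
        return self.binding_limit - self.fluence_mj_cm2


def check_compliance(query: ExposureQuery) -> ComplianceReport:
    """True iff the per-pulse fluence is within both limits (<= convention)."""
    single = mpe_single_pulse(query.wavelength_nm)
    per_pulse = mpe_per_pulse_in_scan(query.wavelength_nm, query.duration_s, query.prr_hz)
    ok = query.fluence_mj_cm2 <= min(single, per_pulse)
    return ComplianceReport(ok, query.fluence_mj_cm2, single, per_pulse)
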