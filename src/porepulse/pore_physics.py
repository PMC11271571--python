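"""Closed-form physics of a solid-state micropore sensor.

A cylindrical pore of diameter ``d`` and length ``h`` filled with an
electrolyte of resistivity ``rho`` has total resistance

.. math::

    R = \\frac{4 h \\rho}{\\pi d^2} + \\frac{\\rho}{d},

the cylindrical channel term plus the access resistance of the electrolyte
converging on the two pore mouths.  Together with a quadratic bead-size to
blockade-amplitude calibration (the blockade of a Coulter-type micropore
scales with particle volume per unit pore length, hence with the square of
the particle diameter for particles shorter than the channel), this fixes
everything needed to turn raw pulse amplitudes into particle sizes.

Internally everything is SI; the interface mirrors the units the field
prints (nA, nm, ms, µL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "InvalidGeometryError",
    "PoreGeometry",
    "MeasurementConfig",
    "SizeCalibration",
    "DEFAULT_PORE",
    "DEFAULT_CALIBRATION",
    "PBS_RESISTIVITY_OHM_M",
    "PSA_MOLAR_MASS_G_PER_MOL",
    "pore_resistance",
    "baseline_current",
    "hydrostatic_pressure",
    "mass_conc_to_molar",
    "fit_size_calibration",
    "min_detectable_diameter",
]

#: Resistivity of 1x phosphate-buffered saline (conductivity ~1.6 S/m).
PBS_RESISTIVITY_OHM_M = 0.625

#: Molar mass of prostate-specific antigen, g/mol (1 ng/mL = 29.4 pM).
PSA_MOLAR_MASS_G_PER_MOL = 34_000.0


class InvalidGeometryError(ValueError):
    """Raised when a pore geometry violates its physical invariants."""


@dataclass(frozen=True)
class PoreGeometry:
    """Pore geometry and electrolyte, SI units.

    Parameters
    ----------
    diameter_m : float
        Pore diameter in metres (> 0).
    thickness_m : float
        Membrane thickness (pore length) in metres (>= 0).
    resistivity_ohm_m : float
        Electrolyte resistivity in ohm-metres (> 0).
    """

    diameter_m: float
    thickness_m: float = 50e-9
    resistivity_ohm_m: float = PBS_RESISTIVITY_OHM_M

    def __post_init__(self) -> None:
        if not (self.diameter_m > 0):
            raise InvalidGeometryError(f"pore diameter must be > 0, got {self.diameter_m}")
        if self.thickness_m < 0:
            raise InvalidGeometryError(f"membrane thickness must be >= 0, got {self.thickness_m}")
        if not (self.resistivity_ohm_m > 0):
            raise InvalidGeometryError(
                f"electrolyte resistivity must be > 0, got {self.resistivity_ohm_m}"
            )


#: 1.2 µm pore in a 50 nm silicon-nitride membrane, 1x PBS.
DEFAULT_PORE = PoreGeometry(diameter_m=1.2e-6)


@dataclass(frozen=True)
class MeasurementConfig:
    """Electrical and fluidic settings of one measurement run.

    ``height_difference_m`` is the liquid-level difference L between the cis
    and trans chambers; positive L drives flow cis -> trans.  ``voltage_v``
    may be 0 for pressure-only transport.
    """

    voltage_v: float = 0.1
    duration_s: float = 600.0
    sampling_rate_hz: float = 250_000.0
    cis_volume_ul: float = 18.0
    trans_volume_ul: float = 15.0
    height_difference_m: float = 3e-3
    fluid_density_kg_m3: float = 1000.0
    gravity_m_s2: float = 9.81

    def __post_init__(self) -> None:
        if not (self.sampling_rate_hz > 0):
            raise ValueError("sampling_rate_hz must be > 0")
        if not (self.duration_s > 0):
            raise ValueError("duration_s must be > 0")
        if not math.isfinite(self.voltage_v):
            raise ValueError("voltage_v must be finite")


@dataclass(frozen=True)
class SizeCalibration:
    """Quadratic bead-size <-> pulse-amplitude calibration.

    ``amplitude_nA = quad_coeff_na_per_nm2 * diameter_nm**2`` with no
    intercept; ``noise_sigma_na`` is the baseline current noise and
    ``detect_k`` the multiple of it defining the detection floor.
    """

    quad_coeff_na_per_nm2: float
    noise_sigma_na: float = 0.21
    detect_k: float = 5.0

    def __post_init__(self) -> None:
        if not (self.quad_coeff_na_per_nm2 > 0):
            raise ValueError("quad_coeff_na_per_nm2 must be > 0")
        if self.noise_sigma_na < 0:
            raise ValueError("noise_sigma_na must be >= 0")
        if self.detect_k < 1:
            raise ValueError("detect_k must be >= 1")

    def predicted_amplitude_na(self, diameter_nm):
        """Mode blockade amplitude (nA) for a bead of the given diameter (nm)."""
        d = np.asarray(diameter_nm, dtype=float)
        out = self.quad_coeff_na_per_nm2 * d**2
        return float(out) if np.isscalar(diameter_nm) else out

    def diameter_from_amplitude_nm(self, amplitude_na):
        """Inverse of :meth:`predicted_amplitude_na` (nm from nA)."""
        a = np.asarray(amplitude_na, dtype=float)
        out = np.sqrt(a / self.quad_coeff_na_per_nm2)
        return float(out) if np.isscalar(amplitude_na) else out


#: Anchored to a 1.5 nA mode for 300 nm beads.
DEFAULT_CALIBRATION = SizeCalibration(quad_coeff_na_per_nm2=1.5 / 300.0**2)


def pore_resistance(geom: PoreGeometry) -> float:
    """Total pore resistance in ohms: channel term plus access term.

    Strictly decreasing in diameter, strictly increasing in thickness and
    resistivity; equals ``rho/d`` for a zero-thickness membrane.
    """
    d, h, rho = geom.diameter_m, geom.thickness_m, geom.resistivity_ohm_m
    return 4.0 * h * rho / (math.pi * d**2) + rho / d


def baseline_current(geom: PoreGeometry, voltage_v: float) -> float:
    """Open-pore ionic current in amperes, ``V / R``; exactly linear in V."""
    if not math.isfinite(voltage_v):
        raise ValueError("voltage must be finite")
    return voltage_v / pore_resistance(geom)


def hydrostatic_pressure(cfg: MeasurementConfig) -> float:
    """Hydrostatic pressure in Pa from the chamber height difference.

    ``rho_fluid * g * L``, signed: positive values drive fluid from the cis
    to the trans chamber, negative the reverse.
    """
    return cfg.fluid_density_kg_m3 * cfg.gravity_m_s2 * cfg.height_difference_m


def mass_conc_to_molar(mass_conc_g_per_ml: float, molar_mass_g_per_mol: float) -> float:
    """Convert a mass concentration (g/mL) to molarity (mol/L).

    ``mass_conc * 1000 / molar_mass``; e.g. 1 ng/mL of a 34 kDa protein is
    29.4 pM.
    """
    if not (molar_mass_g_per_mol > 0):
        raise ValueError("molar mass must be > 0")
    if mass_conc_g_per_ml < 0:
        raise ValueError("mass concentration must be >= 0")
    return mass_conc_g_per_ml * 1000.0 / molar_mass_g_per_mol


def fit_size_calibration(
    pairs, noise_sigma_na: float = 0.21, detect_k: float = 5.0
) -> SizeCalibration:
    """Least-squares fit of ``amplitude = a * diameter**2`` through the origin.

    Parameters
    ----------
    pairs : sequence of (diameter_nm, amplitude_na)
        Histogram-mode amplitudes for beads of known diameter; at least one
        pair, all entries positive.

    Returns
    -------
    SizeCalibration
        With ``quad_coeff_na_per_nm2 = sum(y * d^2) / sum(d^4)``.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("at least one (diameter, amplitude) pair is required")
    d = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if np.any(d <= 0) or np.any(y <= 0):
        raise ValueError("diameters and amplitudes must be positive")
    a = float(np.sum(y * d**2) / np.sum(d**4))
    return SizeCalibration(
        quad_coeff_na_per_nm2=a, noise_sigma_na=noise_sigma_na, detect_k=detect_k
    )


def min_detectable_diameter(cal: SizeCalibration) -> float:
    """Smallest bead diameter (nm) whose amplitude clears the detection floor.

    Solves ``a * d**2 = detect_k * noise_sigma``; 0 for a noiseless trace.
    Scales as the square root of the noise level.
    """
    return math.sqrt(cal.detect_k * cal.noise_sigma_na / cal.quad_coeff_na_per_nm2)
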