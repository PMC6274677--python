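"""Temperature and energy scales for melting-diagram analysis.

Wide-line NMR melting diagrams are interpreted on the *fundamental
temperature* scale, i.e. the thermal-energy scale T_f = k_B·T (per
molecule) or T_f = R·T (per mole).  Its dimensionless version,
normalized to the melting point of bulk ice,

    T_fn = T / 273.15 K,

puts every sample on a common energy axis where bulk ice melts at
T_fn = 1.  The Waugh–Fedin relation links the temperature at which a
molecular motion starts to the activation-energy barrier that had been
blocking it,

    E_0m = c · R · T   [kJ/mol],

with a dimensionless proportionality constant c.  The constant is
calibrated from the melting of bulk ice: inserting ice's latent heat
(6.01 kJ/mol) at 273.15 K gives c ≈ 2.65, equivalent to ~5.3 degrees of
freedom per water molecule under equipartition (½·k_B·T each) — a
sensible number for a rotating (not translating) electric dipole.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

#: Offset between the Celsius and kelvin scales, used everywhere.
CELSIUS_OFFSET = 273.15


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants used by the energy-scale conversions.

    The gas constant default is 8.317 J/(mol·K) — the value the field's
    worked examples are computed with — rather than the CODATA 8.314;
    override it if strict SI agreement matters more than matching the
    published numbers.  All constants are overridable per run.
    """

    boltzmann: float = 1.381e-23  # J/K
    gas_constant: float = 8.317  # J/(mol·K)
    ice_melt_temperature: float = CELSIUS_OFFSET  # K
    ice_melt_heat: float = 6.01  # kJ/mol

    def __post_init__(self):
        for name in ("boltzmann", "gas_constant", "ice_melt_temperature", "ice_melt_heat"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"PhysicalConstants.{name} must be strictly positive")

    @property
    def rt_at_ice_melt_kj_mol(self) -> float:
        """R·T at the ice melting point in kJ/mol (≈ 2.272)."""
        return self.gas_constant * self.ice_melt_temperature / 1000.0

    def to_json_dict(self) -> dict:
        return {
            "R": self.gas_constant,
            "k_B": self.boltzmann,
            "ice_melt_heat_kJmol": self.ice_melt_heat,
            "T_melt_K": self.ice_melt_temperature,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "PhysicalConstants":
        return cls(
            boltzmann=d.get("k_B", cls.boltzmann),
            gas_constant=d.get("R", cls.gas_constant),
            ice_melt_temperature=d.get("T_melt_K", cls.ice_melt_temperature),
            ice_melt_heat=d.get("ice_melt_heat_kJmol", cls.ice_melt_heat),
        )

    @classmethod
    def from_json(cls, text: str) -> "PhysicalConstants":
        return cls.from_json_dict(json.loads(text))


DEFAULT_CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class EnergyCalibration:
    """Waugh–Fedin proportionality constant c and derived quantities.

    ``c`` is kept at full precision for all downstream arithmetic;
    ``c_rounded`` is the 2-decimal value used in printed tables.
    """

    c: float
    constants: PhysicalConstants = field(default=DEFAULT_CONSTANTS)

    def __post_init__(self):
        if not self.c > 0:
            raise InvalidInputError("EnergyCalibration.c must be strictly positive")

    @property
    def degrees_of_freedom(self) -> float:
        """Equipartition degrees of freedom of the mobile unit, 2·c."""
        return 2.0 * self.c

    @property
    def c_rounded(self) -> float:
        return round(self.c, 2)

    def to_json_dict(self) -> dict:
        return {"c": self.c, "degrees_of_freedom": self.degrees_of_freedom,
                "constants": self.constants.to_json_dict()}


def celsius_to_kelvin(t_celsius):
    return np.asarray(t_celsius, dtype=float) + CELSIUS_OFFSET if np.ndim(t_celsius) else float(t_celsius) + CELSIUS_OFFSET


def kelvin_to_celsius(t_kelvin):
    return np.asarray(t_kelvin, dtype=float) - CELSIUS_OFFSET if np.ndim(t_kelvin) else float(t_kelvin) - CELSIUS_OFFSET


def _check_nonnegative_temperature(t_kelvin) -> np.ndarray:
    t = np.asarray(t_kelvin, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError(f"absolute temperature must be >= 0 K, got {t_kelvin!r}")
    return t


def normalized_fundamental_temperature(t_kelvin, constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """Dimensionless fundamental temperature T_fn = T / 273.15.

    Accepts scalars or arrays of absolute temperature in kelvin.
    """
    t = _check_nonnegative_temperature(t_kelvin)
    out = t / constants.ice_melt_temperature
    return float(out) if np.ndim(t_kelvin) == 0 else out


def fundamental_temperature_molar(t_kelvin, constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """Molar fundamental temperature R·T in kJ/mol (2.272 at 273.15 K)."""
    t = _check_nonnegative_temperature(t_kelvin)
    out = constants.gas_constant * t / 1000.0
    return float(out) if np.ndim(t_kelvin) == 0 else out


def excitation_energy_molar(t_kelvin, cal: EnergyCalibration):
    """Waugh–Fedin molar excitation energy E_0m = c·R·T in kJ/mol."""
    t = _check_nonnegative_temperature(t_kelvin)
    out = cal.c * cal.constants.gas_constant * t / 1000.0
    return float(out) if np.ndim(t_kelvin) == 0 else out


def excitation_energy_atomic(t_kelvin, cal: EnergyCalibration):
    """Per-molecule excitation energy E_0a = c·k_B·T in joules.

    The same relation as :func:`excitation_energy_molar` expressed per
    molecule instead of per mole.
    """
    t = _check_nonnegative_temperature(t_kelvin)
    out = cal.c * cal.constants.boltzmann * t
    return float(out) if np.ndim(t_kelvin) == 0 else out


def calibrate_c(latent_heat: float | None = None, t_melt: float | None = None,
                constants: PhysicalConstants = DEFAULT_CONSTANTS) -> EnergyCalibration:
    """Calibrate the Waugh–Fedin constant from a first-order transition.

    Solves E = c·R·T for c, by default using the latent heat of bulk ice
    at its melting point: c = 6.01 kJ/mol / (R · 273.15 K) ≈ 2.645,
    printed as 2.65.

    Parameters
    ----------
    latent_heat : kJ/mol, defaults to the constants' ice melting heat.
    t_melt : kelvin, defaults to the constants' ice melting temperature.
    """
    if latent_heat is None:
        latent_heat = constants.ice_melt_heat
    if t_melt is None:
        t_melt = constants.ice_melt_temperature
    if not (latent_heat > 0 and t_melt > 0):
        raise InvalidInputError("latent_heat and t_melt must be strictly positive")
    c = latent_heat * 1000.0 / (constants.gas_constant * t_melt)
    return EnergyCalibration(c=c, constants=constants)


def onset_celsius_from_t_fn(t_fn: float, constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Convert a normalized fundamental temperature back to °C."""
    if t_fn < 0 or math.isnan(t_fn):
        raise InvalidInputError("t_fn must be >= 0")
    return t_fn * constants.ice_melt_temperature - CELSIUS_OFFSET
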