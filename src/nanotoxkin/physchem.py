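"""Physical constants, the water-viscosity law, Stokes-Einstein transport,
and unit conversions between laboratory and model units.

All computation inside the package is in SI units (m, s, kg, K, J,
particles/m^3).  Laboratory units -- ug/mL for nanoparticle mass
concentration, cells/mL for cell density, degrees Celsius, minutes -- are
accepted only at interfaces and converted immediately on entry.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "BOLTZMANN",
    "PhysicalConstants",
    "CONSTANTS",
    "MediumState",
    "ParticleSpec",
    "CellSpec",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
    "minutes_to_seconds",
    "water_viscosity",
    "mutual_diffusion_coefficient",
    "hydrodynamic_diameter",
    "mass_to_number_density",
    "cells_per_ml_to_per_m3",
    "VISCOSITY_A",
    "VISCOSITY_B",
    "VISCOSITY_C",
]

#: Boltzmann constant, J/K (2019 SI exact value).
BOLTZMANN: float = 1.380649e-23

# Empirical liquid-water viscosity law eta = A * 10^(B / (T - C)),
# valid for liquid water roughly 273-320 K.
VISCOSITY_A: float = 2.414e-5  # Pa s
VISCOSITY_B: float = 247.8  # K
VISCOSITY_C: float = 140.0  # K

#: Validity window of the viscosity fit (liquid water near ambient pressure).
_VISCOSITY_WINDOW = (273.0, 320.0)


@dataclass(frozen=True)
class PhysicalConstants:
    """Single source of physical constants for the whole package."""

    boltzmann_constant: float = BOLTZMANN  # J/K


#: Shared immutable constants instance.
CONSTANTS = PhysicalConstants()


def celsius_to_kelvin(temperature_c: float) -> float:
    return temperature_c + 273.15


def kelvin_to_celsius(temperature_k: float) -> float:
    return temperature_k - 273.15


def minutes_to_seconds(time_min: float) -> float:
    return time_min * 60.0


def water_viscosity(
    temperature: float,
    viscosity_a: float = VISCOSITY_A,
    viscosity_b: float = VISCOSITY_B,
    viscosity_c: float = VISCOSITY_C,
) -> float:
    """Dynamic viscosity of water, Pa s, from the empirical three-constant law.

    eta(T) = A * 10^(B / (T - C)) with T in kelvin.  Strictly decreasing in
    T above C.  Outside the liquid-water validity window (273-320 K) a
    warning is emitted; the value is still returned because the law is an
    empirical fit, not a hard physical bound.

    Parameters
    ----------
    temperature : float
        Absolute temperature, K.  Must exceed ``viscosity_c``.

    Returns
    -------
    float
        Viscosity in Pa s.
    """
    if not math.isfinite(temperature):
        raise ValueError(f"temperature must be finite, got {temperature!r}")
    if temperature <= viscosity_c:
        raise ValueError(
            f"temperature {temperature} K must exceed the law's singular point "
            f"C = {viscosity_c} K"
        )
    if not (_VISCOSITY_WINDOW[0] <= temperature <= _VISCOSITY_WINDOW[1]):
        warnings.warn(
            f"temperature {temperature} K is outside the liquid-water "
            f"validity window {_VISCOSITY_WINDOW}; viscosity is extrapolated",
            stacklevel=2,
        )
    return viscosity_a * 10.0 ** (viscosity_b / (temperature - viscosity_c))


@dataclass(frozen=True)
class MediumState:
    """Aqueous incubation medium at a fixed temperature.

    The viscosity is derived from the water law at construction and cached;
    the dataclass is immutable so ``viscosity`` can never drift out of sync
    with ``temperature``.
    """

    temperature: float  # K
    viscosity_a: float = VISCOSITY_A
    viscosity_b: float = VISCOSITY_B
    viscosity_c: float = VISCOSITY_C
    viscosity: float = field(init=False)  # Pa s, derived

    def __post_init__(self) -> None:
        eta = water_viscosity(
            self.temperature, self.viscosity_a, self.viscosity_b, self.viscosity_c
        )
        object.__setattr__(self, "viscosity", eta)

    @classmethod
    def from_celsius(cls, temperature_c: float, **kwargs) -> "MediumState":
        return cls(temperature=celsius_to_kelvin(temperature_c), **kwargs)


@dataclass(frozen=True)
class ParticleSpec:
    """A spherical nanoparticle species.

    ``bulk_density`` is the effective mass density used for the mass-to-count
    conversion.  The default 350 kg/m^3 is the effective (not solid-silver,
    ~10,490 kg/m^3) density of the studied colloidal silver preparation; it
    is a configurable field, never hard-coded downstream.
    """

    radius: float = 35e-9  # m
    bulk_density: float = 350.0  # kg/m^3

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise ValueError(f"particle radius must be > 0, got {self.radius}")
        if not (self.bulk_density > 0):
            raise ValueError(f"bulk density must be > 0, got {self.bulk_density}")

    @property
    def mass(self) -> float:
        """Single-particle mass, kg."""
        return self.bulk_density * (4.0 / 3.0) * math.pi * self.radius**3


@dataclass(frozen=True)
class CellSpec:
    """A spherical cell species (macrophage by default)."""

    radius: float = 5e-6  # m
    number_concentration: float = 5e11  # cells/m^3 (= 5e5 cells/mL)

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise ValueError(f"cell radius must be > 0, got {self.radius}")
        if self.number_concentration < 0:
            raise ValueError(
                f"cell concentration must be >= 0, got {self.number_concentration}"
            )

    @classmethod
    def from_per_ml(cls, cells_per_ml: float, radius: float = 5e-6) -> "CellSpec":
        return cls(radius=radius, number_concentration=cells_per_ml_to_per_m3(cells_per_ml))


def mutual_diffusion_coefficient(
    radius_a: float, radius_b: float, medium: MediumState
) -> float:
    """Mutual (pair) diffusion coefficient of two spheres, m^2/s.

    D = (kB T / 6 pi eta) (1/rA + 1/rB), i.e. the sum of the two
    single-particle Stokes-Einstein coefficients: the relative coordinate of
    an independently diffusing pair diffuses with D = DA + DB.
    """
    if not (radius_a > 0 and radius_b > 0):
        raise ValueError(f"radii must be > 0, got {radius_a}, {radius_b}")
    kT = CONSTANTS.boltzmann_constant * medium.temperature
    return kT / (6.0 * math.pi * medium.viscosity) * (1.0 / radius_a + 1.0 / radius_b)


def hydrodynamic_diameter(diffusion_coefficient: float, medium: MediumState) -> float:
    """Hydrodynamic diameter, m: the diameter of the sphere that diffuses
    with the given coefficient in this medium (the DLS observable).

    d_H = kB T / (3 pi eta D); exact inverse of the single-sphere
    diameter -> diffusion-coefficient map.
    """
    if not (diffusion_coefficient > 0):
        raise ValueError(
            f"diffusion coefficient must be > 0, got {diffusion_coefficient}"
        )
    kT = CONSTANTS.boltzmann_constant * medium.temperature
    return kT / (3.0 * math.pi * medium.viscosity * diffusion_coefficient)


def mass_to_number_density(
    mass_concentration_ug_per_ml: float, particle: ParticleSpec
) -> float:
    """Convert a nanoparticle mass concentration (ug/mL) to particles/m^3.

    c[ug/mL] * 1000 gives mass per m^3 in units of (ug/mL -> 1e-9 kg / 1e-6
    m^3 = 1e-3 kg/m^3); dividing by the single-particle mass
    rho (4/3) pi r^3 yields the number density.  Exactly linear in the
    concentration and scaling as r^-3.
    """
    if mass_concentration_ug_per_ml < 0:
        raise ValueError(
            f"mass concentration must be >= 0, got {mass_concentration_ug_per_ml}"
        )
    mass_per_m3 = mass_concentration_ug_per_ml * 1e-3  # kg/m^3
    return mass_per_m3 / particle.mass


def cells_per_ml_to_per_m3(concentration_per_ml: float) -> float:
    """Convert cells/mL to cells/m^3 (factor 1e6)."""
    if concentration_per_ml < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration_per_ml}")
    return concentration_per_ml * 1e6
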