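"""AOD-modulated death kinetics and the analytic dead-cell time course.

Two lumped reactions drive cell death: diffusive encounter of nanoparticle
and cell (rate constant k1, from the Smoluchowski module), followed by the
ROS-vs-antioxidant-defence (AOD) outcome of the encounter, folded into a
single effective rate constant

    k2 = k1 exp(g(P2)),

where P2 in (0, 1] is the probability that an encounter kills the cell
despite the AOD system.  The link comes from an Arrhenius argument: the
first reaction's activation energy is the particle's mean kinetic energy
Eact1 = (3/2) kB T, the second's is Eact2 = Eact1 / P2, and
k2/k1 = exp((Eact1 - Eact2)/(kB T)), giving

    g(P2) = 3 (P2 - 1) / (2 P2)        ("corrected", the default)

so that k2 <= k1 with equality at P2 = 1 (no defence).  The alternative
sign convention g = (3 - 3 P2)/(2 P2) ("printed") is retained for audits;
under it k2 >= k1, which with realistic parameters saturates the damage in
seconds and cannot reproduce hour-scale assays.  The two conventions obey
the exact duality k2_printed * k2_corrected = k1^2.

With second-order mass-action encounter kinetics the dead-cell count obeys

    dN/dt = k2 (CA0 - N)(CB0 - (CB0/CA0) N),   N(0) = 0,

whose closed-form solution is the hyperbola

    N(t) = CA0 CB0 k2 t / (CB0 k2 t + 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .physchem import (
    CellSpec,
    CONSTANTS,
    MediumState,
    ParticleSpec,
    celsius_to_kelvin,
    kelvin_to_celsius,
    mass_to_number_density,
)
from .smoluchowski import (
    PairDiffusionSystem,
    integrated_rate,
    stationary_rate_constant,
)

__all__ = [
    "CONVENTIONS",
    "P2_FLOOR",
    "AodSurvivalModel",
    "ExperimentCondition",
    "activation_energy_first",
    "activation_energy_second",
    "log_rate_modifier",
    "second_rate_constant",
    "death_ode_rhs",
    "damaged_count",
    "damaged_fraction",
    "predict_timecourse",
]

CONVENTIONS = ("corrected", "printed")

#: Lower bound on P2: keeps exp(g(P2)) finite (|g| <= ~1500 at the floor).
P2_FLOOR = 1e-3


@dataclass(frozen=True)
class AodSurvivalModel:
    """Lumped antioxidant-defence survival model.

    Parameters
    ----------
    death_probability : float or mapping
        P2, the probability in (floor, 1] that a nanoparticle-cell
        encounter kills the cell.  A mapping keyed by temperature in
        degrees Celsius gives a per-temperature profile.
    sign_convention : {"corrected", "printed"}
        Sign of the Arrhenius exponent linking k2 to k1 (see module
        docstring).
    p2_floor : float
        Configurable lower admissible bound for P2.
    """

    death_probability: float | Mapping[float, float]
    sign_convention: str = "corrected"
    p2_floor: float = P2_FLOOR

    def __post_init__(self) -> None:
        if self.sign_convention not in CONVENTIONS:
            raise ValueError(
                f"sign_convention must be one of {CONVENTIONS}, "
                f"got {self.sign_convention!r}"
            )
        if isinstance(self.death_probability, Mapping):
            for t, p in self.death_probability.items():
                self._check_p2(p, f"P2 at {t} degC")
        else:
            self._check_p2(self.death_probability, "P2")

    def _check_p2(self, p2: float, label: str) -> None:
        if not (self.p2_floor <= p2 <= 1.0):
            raise ValueError(
                f"{label} must lie in [{self.p2_floor}, 1], got {p2}"
            )

    def p2(self, temperature: float | None = None) -> float:
        """P2 for the given absolute temperature (K).

        Scalar models ignore the temperature; mapping models require an
        exact match of the Celsius key (no interpolation).
        """
        if not isinstance(self.death_probability, Mapping):
            return float(self.death_probability)
        if temperature is None:
            raise ValueError("a temperature is required for a per-temperature model")
        t_c = round(kelvin_to_celsius(temperature), 6)
        for key, value in self.death_probability.items():
            if abs(key - t_c) < 1e-6:
                return float(value)
        raise KeyError(f"no P2 recorded for {t_c} degC")


@dataclass(frozen=True)
class ExperimentCondition:
    """One incubation condition: temperature, species, and their densities."""

    temperature: float  # K
    nanoparticle_density: float  # particles/m^3 (CB0)
    particle: ParticleSpec = field(default_factory=ParticleSpec)
    cell: CellSpec = field(default_factory=CellSpec)
    cell_density: float | None = None  # cells/m^3 (CA0); default from cell spec

    def __post_init__(self) -> None:
        if self.nanoparticle_density < 0:
            raise ValueError(
                f"nanoparticle density must be >= 0, got {self.nanoparticle_density}"
            )
        if self.cell_density is None:
            object.__setattr__(self, "cell_density", self.cell.number_concentration)
        if self.cell_density < 0:
            raise ValueError(f"cell density must be >= 0, got {self.cell_density}")

    @classmethod
    def from_lab_units(
        cls,
        temperature_c: float,
        agnp_ug_per_ml: float,
        particle: ParticleSpec | None = None,
        cell: CellSpec | None = None,
    ) -> "ExperimentCondition":
        """Build from the laboratory units of the assay (degC, ug/mL)."""
        particle = particle if particle is not None else ParticleSpec()
        cell = cell if cell is not None else CellSpec()
        return cls(
            temperature=celsius_to_kelvin(temperature_c),
            nanoparticle_density=mass_to_number_density(agnp_ug_per_ml, particle),
            particle=particle,
            cell=cell,
        )

    def pair_system(self, medium: MediumState) -> PairDiffusionSystem:
        if self.nanoparticle_density <= 0:
            raise ValueError("pair system requires a positive nanoparticle density")
        return PairDiffusionSystem.from_species(
            self.cell, self.particle, medium, self.nanoparticle_density
        )


def activation_energy_first(temperature: float) -> float:
    """Activation energy of the encounter reaction, J: the mean kinetic
    energy of the diffusing particle, (3/2) kB T."""
    if not (temperature > 0):
        raise ValueError(f"temperature must be > 0 K, got {temperature}")
    return 1.5 * CONSTANTS.boltzmann_constant * temperature


def activation_energy_second(p2: float, temperature: float) -> float:
    """Effective activation energy of the death reaction, J: Eact1 / P2.

    The weaker the defence penetration probability P2, the higher the
    barrier; equal to Eact1 exactly when P2 = 1.
    """
    if not (0.0 < p2 <= 1.0):
        raise ValueError(f"P2 must lie in (0, 1], got {p2}")
    return activation_energy_first(temperature) / p2


def log_rate_modifier(p2: float, convention: str = "corrected") -> float:
    """Arrhenius log-ratio g(P2) = ln(k2/k1) under the given convention."""
    if convention == "corrected":
        return 3.0 * (p2 - 1.0) / (2.0 * p2)
    if convention == "printed":
        return (3.0 - 3.0 * p2) / (2.0 * p2)
    raise ValueError(f"unknown convention {convention!r}")


def second_rate_constant(
    condition: ExperimentCondition,
    medium: MediumState,
    model: AodSurvivalModel,
) -> float:
    """Effective death rate constant k2 = k1 exp(g(P2)), m^3/s.

    k1 is the stationary Smoluchowski constant 4 pi R D for the condition's
    geometry in the given medium.  Raises for P2 below the model's floor
    (the exponential would overflow/underflow meaninglessly).
    """
    p2 = model.p2(condition.temperature)
    if p2 < model.p2_floor:
        raise ValueError(f"P2 = {p2} below the admissible floor {model.p2_floor}")
    k1 = stationary_rate_constant(condition.pair_system(medium))
    return k1 * math.exp(log_rate_modifier(p2, model.sign_convention))


def death_ode_rhs(
    dead_count: float, k2: float, condition: ExperimentCondition
) -> float:
    """Right-hand side of the dead-cell balance, cells/(m^3 s):

    dN/dt = k2 (CA0 - N)(CB0 - (CB0/CA0) N).
    """
    ca0 = condition.cell_density
    cb0 = condition.nanoparticle_density
    if dead_count < 0 or dead_count > ca0 * (1.0 + 1e-12):
        raise ValueError(f"dead count must lie in [0, CA0], got {dead_count}")
    return k2 * (ca0 - dead_count) * (cb0 - (cb0 / ca0) * dead_count)


def damaged_count(
    time: float | np.ndarray, k2: float, condition: ExperimentCondition
) -> float | np.ndarray:
    """Closed-form dead-cell count N(t) = CA0 CB0 k2 t / (CB0 k2 t + 1),
    cells/m^3.  Monotone from N(0) = 0 toward N(inf) = CA0."""
    return condition.cell_density * damaged_fraction(
        time, k2, condition.nanoparticle_density
    )


def damaged_fraction(
    time: float | np.ndarray, k2: float, nanoparticle_density: float
) -> float | np.ndarray:
    """Damaged-cell fraction N(t)/CA0 = x/(x + 1) with x = CB0 k2 t.

    Independent of the cell density; in [0, 1) for finite time.
    """
    t = np.asarray(time, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    x = nanoparticle_density * k2 * t
    out = x / (x + 1.0)
    return float(out) if np.isscalar(time) else out


def predict_timecourse(
    times: np.ndarray,
    condition: ExperimentCondition,
    medium: MediumState,
    model: AodSurvivalModel,
    transient_k1: bool = False,
) -> np.ndarray:
    """Predicted damaged fraction at each time (seconds).

    Composes viscosity -> Stokes-Einstein D -> k1 -> k2(P2) -> the
    hyperbolic time course.  With ``transient_k1`` the time-dependent
    encounter rate replaces 4 pi R D; the separable ODE then yields the
    same hyperbola with CB0 k2 t replaced by CB0 integral k2(t') dt'
    (finite despite the t -> 0 divergence of the transient rate).
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        return np.empty(0)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    system = condition.pair_system(medium)
    p2 = model.p2(condition.temperature)
    factor = math.exp(log_rate_modifier(p2, model.sign_convention))
    if not transient_k1:
        k2 = stationary_rate_constant(system) * factor
        return damaged_fraction(t, k2, condition.nanoparticle_density)
    x = np.array(
        [
            condition.nanoparticle_density
            * factor
            * integrated_rate(ti, system, transient=True)
            for ti in t
        ]
    )
    return x / (x + 1.0)
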