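"""Diffusion-controlled pair kinetics around an absorbing sphere.

The model: nanoparticles (B) diffuse toward a much larger cell (A); contact
at the reaction radius R = rA + rB is irreversible ("black sphere"
absorbing boundary).  The closed-form concentration field around one cell,

    W(r, t) = W0 [1 - (R/r) erfc((r - R) / (2 sqrt(D t)))],

yields the classic Smoluchowski rate constant with its transient correction,

    k1(t) = 4 pi R D (1 + R / sqrt(pi D t)),    k1(inf) = 4 pi R D.

A radial finite-difference solver of the same initial/boundary-value
problem is provided as an independent numerical oracle for validating the
closed form; it never feeds the downstream kinetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded
from scipy.special import erfc

from .physchem import MediumState, ParticleSpec, CellSpec, mutual_diffusion_coefficient

__all__ = [
    "PairDiffusionSystem",
    "RadialGrid",
    "OracleSolution",
    "SolverError",
    "pair_probability",
    "transient_rate_constant",
    "stationary_rate_constant",
    "radial_diffusion_oracle",
]

# erfc underflows to denormals around x ~ 27; beyond this the depletion term
# is exactly zero at double precision, so clamp W to W0.
_ERFC_CLAMP = 26.0


class SolverError(RuntimeError):
    """Raised when the finite-difference oracle detects instability."""


@dataclass(frozen=True)
class PairDiffusionSystem:
    """Geometry, mobility, and far-field supply of one reacting pair.

    Attributes
    ----------
    reaction_radius : float
        Contact radius R = rA + rB, m.
    diffusion_coefficient : float
        Mutual diffusion coefficient D = DA + DB, m^2/s.
    far_field_concentration : float
        Bulk nanoparticle number density W0, particles/m^3.
    """

    reaction_radius: float  # m
    diffusion_coefficient: float  # m^2/s
    far_field_concentration: float  # particles/m^3

    def __post_init__(self) -> None:
        for name in ("reaction_radius", "diffusion_coefficient", "far_field_concentration"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be positive and finite, got {v}")

    @classmethod
    def from_species(
        cls,
        cell: CellSpec,
        particle: ParticleSpec,
        medium: MediumState,
        far_field_concentration: float,
    ) -> "PairDiffusionSystem":
        """Build R and D from the two species' radii and the medium."""
        return cls(
            reaction_radius=cell.radius + particle.radius,
            diffusion_coefficient=mutual_diffusion_coefficient(
                cell.radius, particle.radius, medium
            ),
            far_field_concentration=far_field_concentration,
        )

    @property
    def diffusion_time(self) -> float:
        """Characteristic time R^2 / D, s."""
        return self.reaction_radius**2 / self.diffusion_coefficient


def pair_probability(
    distance: float | np.ndarray, time: float, system: PairDiffusionSystem
) -> float | np.ndarray:
    """Nanoparticle concentration W(r, t) around one absorbing cell.

    Returns W0 [1 - (R/r) erfc((r - R)/(2 sqrt(D t)))], which solves the
    radial diffusion equation with W(R, t) = 0, W(inf, t) = W0 and uniform
    initial condition W(r, 0) = W0.  At t = 0 the uniform initial profile
    is returned (W0 for r > R).  Values lie in [0, W0].
    """
    r = np.asarray(distance, dtype=float)
    R = system.reaction_radius
    W0 = system.far_field_concentration
    if np.any(r < R * (1.0 - 1e-12)):
        raise ValueError("distance must be >= the reaction radius R")
    if time < 0:
        raise ValueError(f"time must be >= 0, got {time}")
    if time == 0.0:
        out = np.where(r > R, W0, 0.0)
        return float(out) if np.isscalar(distance) else out
    arg = (r - R) / (2.0 * math.sqrt(system.diffusion_coefficient * time))
    depletion = np.where(arg > _ERFC_CLAMP, 0.0, (R / r) * erfc(np.minimum(arg, _ERFC_CLAMP)))
    out = W0 * (1.0 - depletion)
    return float(out) if np.isscalar(distance) else out


def transient_rate_constant(
    time: float | np.ndarray, system: PairDiffusionSystem
) -> float | np.ndarray:
    """Time-dependent Smoluchowski rate constant, m^3/s.

    k1(t) = 4 pi R D (1 + R / sqrt(pi D t)).  Strictly decreasing in t,
    approaching 4 pi R D; the t -> 0 divergence reflects the reaction of
    initially adjacent pairs and is excluded from the domain.
    """
    t = np.asarray(time, dtype=float)
    if np.any(t <= 0):
        raise ValueError("time must be > 0 for the transient rate constant")
    R, D = system.reaction_radius, system.diffusion_coefficient
    out = 4.0 * math.pi * R * D * (1.0 + R / np.sqrt(math.pi * D * t))
    return float(out) if np.isscalar(time) else out


def stationary_rate_constant(system: PairDiffusionSystem) -> float:
    """Stationary Smoluchowski rate constant k1 = 4 pi R D, m^3/s."""
    return 4.0 * math.pi * system.reaction_radius * system.diffusion_coefficient


def integrated_rate(time: float, system: PairDiffusionSystem, transient: bool) -> float:
    """Integral of k1 over [0, t], m^3: 4 pi R D (t + 2 R sqrt(t/(pi D)))
    with the transient term, 4 pi R D t without.

    The transient integral is finite even though k1(t) diverges at t -> 0;
    it feeds the time-dependent generalisation of the death kinetics.
    """
    if time < 0:
        raise ValueError(f"time must be >= 0, got {time}")
    R, D = system.reaction_radius, system.diffusion_coefficient
    base = 4.0 * math.pi * R * D
    if not transient:
        return base * time
    return base * (time + 2.0 * R * math.sqrt(time / (math.pi * D)))


@dataclass(frozen=True)
class RadialGrid:
    """Discretisation for the finite-difference oracle.

    ``node_positions`` must be strictly increasing with the first node at
    the reaction radius; the outer boundary must sit far enough out
    (>= 20 R) that the far-field condition is a good approximation over the
    solve horizon.  ``time_step`` is the maximum step of the implicit
    integrator; early steps are geometrically ramped from a much smaller
    value to resolve the initial boundary-layer transient.
    """

    node_positions: np.ndarray  # m, first node = R
    time_step: float  # s, maximum step
    outer_radius: float = field(init=False)

    def __post_init__(self) -> None:
        r = np.asarray(self.node_positions, dtype=float)
        object.__setattr__(self, "node_positions", r)
        if r.ndim != 1 or r.size < 10:
            raise ValueError("grid needs at least 10 nodes")
        if np.any(np.diff(r) <= 0):
            raise ValueError("node positions must be strictly increasing")
        if not (self.time_step > 0):
            raise ValueError(f"time step must be > 0, got {self.time_step}")
        object.__setattr__(self, "outer_radius", float(r[-1]))
        if self.outer_radius < 20.0 * r[0]:
            raise ValueError("outer radius must be >= 20 reaction radii")

    @classmethod
    def logarithmic(
        cls,
        system: PairDiffusionSystem,
        n_nodes: int = 600,
        outer_factor: float = 50.0,
        steps_per_diffusion_time: float = 400.0,
    ) -> "RadialGrid":
        """Log-spaced grid from R to ``outer_factor`` R.

        Log spacing concentrates nodes in the thin depletion layer next to
        the absorbing sphere where the profile curvature is largest.
        """
        R = system.reaction_radius
        nodes = R * np.logspace(0.0, math.log10(outer_factor), n_nodes)
        dt = system.diffusion_time / steps_per_diffusion_time
        return cls(node_positions=nodes, time_step=dt)


@dataclass(frozen=True)
class OracleSolution:
    """Numerical solution of the radial absorbing-sphere problem."""

    node_positions: np.ndarray  # m
    times: np.ndarray  # s, end of every accepted step
    profile: np.ndarray  # W at the final time, particles/m^3
    flux: np.ndarray  # 4 pi R^2 D dW/dr at r = R, particles/s, per time
    profiles: dict  # requested snapshot time -> W array

    def rate_constant(self, times: np.ndarray | None = None) -> np.ndarray:
        """Effective rate constant flux / W0 at the step times (or
        log-interpolated at the requested times), m^3/s."""
        w0 = self.profile_far_field
        if times is None:
            return self.flux / w0
        lk = np.interp(np.log(times), np.log(self.times), np.log(self.flux / w0))
        return np.exp(lk)

    @property
    def profile_far_field(self) -> float:
        return float(self.profile[-1])

    def to_frame(self):
        """Final profile as a tidy DataFrame (columns r_m, t_s, W)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "r_m": self.node_positions,
                "t_s": float(self.times[-1]),
                "W": self.profile,
            }
        )


def _second_derivative_weights(r: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Three-point second-derivative weights on a non-uniform grid."""
    hl = r[1:-1] - r[:-2]
    hr = r[2:] - r[1:-1]
    wl = 2.0 / (hl * (hl + hr))
    wc = -2.0 / (hl * hr)
    wr = 2.0 / (hr * (hl + hr))
    return wl, wc, wr


def radial_diffusion_oracle(
    system: PairDiffusionSystem,
    grid: RadialGrid | None = None,
    horizon: float | None = None,
    snapshot_times: tuple[float, ...] = (),
) -> OracleSolution:
    """Integrate the radial diffusion problem numerically.

    Solves dW/dt = D (d2W/dr2 + (2/r) dW/dr) with W(R, t) = 0 (absorbing),
    W(r_outer, t) = W0 (far field) and W(r, 0) = W0, via the substitution
    omega = r W which reduces the operator to a plain 1-D second
    derivative.  Crank-Nicolson time stepping with backward-Euler startup
    (Rannacher smoothing of the initial corner discontinuity) and a
    geometric ramp of the step size; boundary flux by one-sided three-point
    differencing of omega at r = R.

    Returns the final profile, the flux time series, and optional profile
    snapshots, for comparison against the closed-form field and rate.
    """
    if grid is None:
        grid = RadialGrid.logarithmic(system)
    if horizon is None:
        horizon = 10.0 * system.diffusion_time
    if not (horizon > 0):
        raise ValueError(f"horizon must be > 0, got {horizon}")

    r = grid.node_positions
    n = r.size
    D = system.diffusion_coefficient
    W0 = system.far_field_concentration
    R = float(r[0])

    # omega = r W: omega(R) = 0, omega(outer) = r_outer W0, omega(r,0) = r W0.
    omega = r * W0
    omega[0] = 0.0

    wl, wc, wr = _second_derivative_weights(r)

    snapshots_left = sorted(set(float(s) for s in snapshot_times))
    profiles: dict[float, np.ndarray] = {}

    times: list[float] = []
    fluxes: list[float] = []

    # One-sided three-point derivative of omega at the first node.
    h1 = r[1] - r[0]
    h2 = r[2] - r[0]
    d0 = -(h1 + h2) / (h1 * h2)
    d1 = h2 / (h1 * (h2 - h1))
    d2 = -h1 / (h2 * (h2 - h1))

    def boundary_flux(om: np.ndarray) -> float:
        # j = 4 pi R^2 D dW/dr|R = 4 pi R D domega/dr|R  (omega(R) = 0)
        domega = d0 * om[0] + d1 * om[1] + d2 * om[2]
        return 4.0 * math.pi * R * D * domega

    def step(om: np.ndarray, dt: float, theta: float) -> np.ndarray:
        """One theta-scheme step (theta=1 backward Euler, 0.5 CN)."""
        # interior operator L om = D * (wl om[i-1] + wc om[i] + wr om[i+1])
        rhs = om.copy()
        if theta < 1.0:
            lom = D * (wl * om[:-2] + wc * om[1:-1] + wr * om[2:])
            rhs[1:-1] += dt * (1.0 - theta) * lom
        # boundary rows: identity (Dirichlet)
        ab = np.zeros((3, n))
        ab[1, 0] = 1.0
        ab[1, -1] = 1.0
        rhs[0] = 0.0
        rhs[-1] = r[-1] * W0
        ab[1, 1:-1] = 1.0 - dt * theta * D * wc
        ab[0, 2:] = -dt * theta * D * wr
        ab[2, :-2] = -dt * theta * D * wl
        return solve_banded((1, 1), ab, rhs)

    t = 0.0
    dt_max = grid.time_step
    dt = dt_max / 1000.0
    n_startup = 8  # backward-Euler steps to damp the corner singularity
    k = 0
    while t < horizon * (1.0 - 1e-12):
        dt_eff = min(dt, horizon - t)
        # hit pending snapshot times exactly
        if snapshots_left and t + dt_eff > snapshots_left[0] - 1e-15 * horizon:
            dt_eff = min(dt_eff, snapshots_left[0] - t)
        theta = 1.0 if k < n_startup else 0.5
        if dt_eff > 1e-30:
            omega = step(omega, dt_eff, theta)
            t += dt_eff
            k += 1
            times.append(t)
            fluxes.append(boundary_flux(omega))
        if snapshots_left and abs(t - snapshots_left[0]) <= 1e-12 * horizon:
            W = omega / r
            W[0] = 0.0
            profiles[snapshots_left.pop(0)] = W
        dt = min(dt * 1.25, dt_max)

    W = omega / r
    W[0] = 0.0

    # Stability contract: W within [0, W0] up to tolerance and non-decreasing
    # outward (the depletion hole can only deepen toward the sink).
    tol = 1e-3 * W0
    if np.any(W < -tol) or np.any(W > W0 * (1.0 + 1e-3)):
        raise SolverError("oracle profile left the admissible range [0, W0]")
    if np.any(np.diff(W) < -tol):
        raise SolverError("oracle profile is non-monotone in r")

    return OracleSolution(
        node_positions=r,
        times=np.asarray(times),
        profile=W,
        flux=np.asarray(fluxes),
        profiles=profiles,
    )
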