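"""Least-squares inference of the encounter-lethality probability P2.

The observable is a damage time course: the fraction of cells with
compromised membranes at a handful of incubation times, for one
(temperature, nanoparticle concentration) condition.  The kinetic model
predicts

    f(t; P2) = x / (x + 1),    x = CB0 k2(P2) t,

with every physical constant (viscosity, diffusion, k1) derived from the
condition, leaving P2 as the single free parameter per series.  This module
fits P2 by ordinary least squares on the fraction scale, in the
statsmodels idiom: build a :class:`MembraneDamageModel` from the data, call
``fit()``, and read estimates, standard errors, and diagnostics off the
returned :class:`MembraneDamageResults`.

Goodness of fit is the coefficient of determination R^2 = 1 - SSres/SStot.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .kinetics import (
    AodSurvivalModel,
    ExperimentCondition,
    activation_energy_second,
    damaged_fraction,
    log_rate_modifier,
)
from .physchem import (
    CellSpec,
    MediumState,
    ParticleSpec,
    celsius_to_kelvin,
    kelvin_to_celsius,
    mass_to_number_density,
    minutes_to_seconds,
)
from .smoluchowski import stationary_rate_constant

__all__ = [
    "DamageTimeCourse",
    "MembraneDamageModel",
    "MembraneDamageResults",
    "r_squared",
    "fit_p2",
    "p2_from_fraction",
    "activation_energy_profile",
]


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination R^2 = 1 - SSres / SStot.

    May be negative (a model worse than the mean); equals 1 iff the
    predictions are exact.  Raises if the lengths differ, fewer than two
    points are given, or the observations are all identical (SStot = 0).
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("observed and predicted must be 1-D of equal length")
    if y.size < 2:
        raise ValueError("R^2 requires at least two points")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: observations are all identical")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class DamageTimeCourse:
    """One observed damage series at fixed temperature and concentration.

    ``fraction`` always holds the damaged fraction per time point; when the
    raw counts are present the fraction is required to equal
    damaged/counted.
    """

    time_min: np.ndarray
    fraction: np.ndarray
    temperature: float  # K
    nanoparticle_density: float  # particles/m^3
    cells_counted: np.ndarray | None = None
    cells_damaged: np.ndarray | None = None
    label: str = ""
    approximate: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        f = np.asarray(self.fraction, dtype=float)
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "fraction", f)
        if t.ndim != 1 or t.shape != f.shape:
            raise ValueError("time and fraction must be 1-D of equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(t < 0):
            raise ValueError("times must be >= 0")
        if np.any((f < 0) | (f > 1)):
            raise ValueError("fractions must lie in [0, 1]")
        if (self.cells_counted is None) != (self.cells_damaged is None):
            raise ValueError("counts require both cells_counted and cells_damaged")
        if self.cells_counted is not None:
            n = np.asarray(self.cells_counted, dtype=int)
            d = np.asarray(self.cells_damaged, dtype=int)
            object.__setattr__(self, "cells_counted", n)
            object.__setattr__(self, "cells_damaged", d)
            if n.shape != t.shape or d.shape != t.shape:
                raise ValueError("count arrays must match the time grid")
            if np.any(d < 0) or np.any(d > n):
                raise ValueError("need 0 <= cells_damaged <= cells_counted")
            if np.any(n <= 0):
                raise ValueError("cells_counted must be positive")
            if not np.allclose(f, d / n, atol=1e-9):
                raise ValueError("fraction must equal cells_damaged / cells_counted")
        if self.nanoparticle_density < 0:
            raise ValueError("nanoparticle density must be >= 0")

    @property
    def n_points(self) -> int:
        return int(self.time_min.size)

    @property
    def temperature_celsius(self) -> float:
        return kelvin_to_celsius(self.temperature)

    @classmethod
    def from_counts(
        cls,
        time_min: Sequence[float],
        cells_counted: Sequence[int],
        cells_damaged: Sequence[int],
        temperature: float,
        nanoparticle_density: float,
        label: str = "",
    ) -> "DamageTimeCourse":
        n = np.asarray(cells_counted, dtype=int)
        d = np.asarray(cells_damaged, dtype=int)
        return cls(
            time_min=np.asarray(time_min, dtype=float),
            fraction=d / n,
            temperature=temperature,
            nanoparticle_density=nanoparticle_density,
            cells_counted=n,
            cells_damaged=d,
            label=label,
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        particle: ParticleSpec | None = None,
        label: str = "",
    ) -> "DamageTimeCourse":
        """Build from a tidy frame with columns ``temperature_C``,
        ``agnp_ug_per_ml``, ``time_min`` and either counts
        (``cells_counted``, ``cells_damaged``) or ``fraction_damaged``.

        The frame must describe a single condition (one temperature, one
        concentration); the nanoparticle number density is derived from the
        mass concentration via the particle spec.
        """
        required = {"temperature_C", "agnp_ug_per_ml", "time_min"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        for col in ("temperature_C", "agnp_ug_per_ml"):
            if df[col].nunique() != 1:
                raise ValueError(f"a time course needs a single {col}; got several")
        particle = particle if particle is not None else ParticleSpec()
        df = df.sort_values("time_min")
        temperature = celsius_to_kelvin(float(df["temperature_C"].iloc[0]))
        density = mass_to_number_density(float(df["agnp_ug_per_ml"].iloc[0]), particle)
        if {"cells_counted", "cells_damaged"} <= set(df.columns):
            return cls.from_counts(
                df["time_min"].to_numpy(),
                df["cells_counted"].to_numpy(),
                df["cells_damaged"].to_numpy(),
                temperature,
                density,
                label=label,
            )
        if "fraction_damaged" in df.columns:
            return cls(
                time_min=df["time_min"].to_numpy(dtype=float),
                fraction=df["fraction_damaged"].to_numpy(dtype=float),
                temperature=temperature,
                nanoparticle_density=density,
                label=label,
            )
        raise ValueError(
            "need either cells_counted/cells_damaged or fraction_damaged columns"
        )

    def to_dataframe(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "temperature_C": kelvin_to_celsius(self.temperature),
                "time_min": self.time_min,
                "fraction_damaged": self.fraction,
            }
        )
        if self.cells_counted is not None:
            out["cells_counted"] = self.cells_counted
            out["cells_damaged"] = self.cells_damaged
        return out


def p2_from_fraction(
    fraction: float,
    time_min: float,
    condition: ExperimentCondition,
    medium: MediumState,
    convention: str = "corrected",
) -> float:
    """Closed-form P2 from a single damage observation.

    Inverts the hyperbola for the rate constant,
    k2 = f / ((1 - f) CB0 t), then solves g(P2) = ln(k2/k1):
    P2 = 3 / (3 - 2 g) (corrected) or 3 / (3 + 2 g) (printed).

    Only meaningful when the implied P2 lands in (0, 1]; values outside are
    returned as computed so the caller can detect inconsistency.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    if not (time_min > 0):
        raise ValueError(f"time must be > 0, got {time_min}")
    t = minutes_to_seconds(time_min)
    k2 = fraction / ((1.0 - fraction) * condition.nanoparticle_density * t)
    k1 = stationary_rate_constant(condition.pair_system(medium))
    g = math.log(k2 / k1)
    if convention == "corrected":
        return 3.0 / (3.0 - 2.0 * g)
    if convention == "printed":
        return 3.0 / (3.0 + 2.0 * g)
    raise ValueError(f"unknown convention {convention!r}")


class MembraneDamageModel:
    """Single-parameter kinetic model of a membrane-damage time course.

    Parameters
    ----------
    timecourse : DamageTimeCourse
        The observed series; at least two points are required to fit.
    medium : MediumState, optional
        Defaults to water at the series temperature.
    condition : ExperimentCondition, optional
        Physical condition (densities, species).  Defaults to the standard
        assay geometry at the series' temperature and nanoparticle density.
    convention : {"corrected", "printed"}
        Sign convention of the Arrhenius exponent (see kinetics module).
    time_window : (float, float), optional
        Restrict the fit to times within [lo, hi] minutes — e.g. to exclude
        a late-time oxidative-stress regime the model does not describe.
    weights : array-like, optional
        Per-point least-squares weights; default is plain (unweighted)
        least squares.  ``weights="inverse_variance"`` uses binomial
        counting weights n / (f (1 - f)) from the recorded counts.
    """

    #: admissible P2 range for the optimiser
    p2_bounds = (1e-3, 1.0)

    def __init__(
        self,
        timecourse: DamageTimeCourse,
        medium: MediumState | None = None,
        condition: ExperimentCondition | None = None,
        convention: str = "corrected",
        time_window: tuple[float, float] | None = None,
        weights=None,
    ):
        if convention not in ("corrected", "printed"):
            raise ValueError(f"unknown convention {convention!r}")
        self.timecourse = timecourse
        self.medium = medium if medium is not None else MediumState(timecourse.temperature)
        if condition is None:
            condition = ExperimentCondition(
                temperature=timecourse.temperature,
                nanoparticle_density=timecourse.nanoparticle_density,
            )
        self.condition = condition
        self.convention = convention

        mask = np.ones(timecourse.n_points, dtype=bool)
        if time_window is not None:
            lo, hi = time_window
            mask &= (timecourse.time_min >= lo) & (timecourse.time_min <= hi)
        self._mask = mask
        self.times_min = timecourse.time_min[mask]
        self.endog = timecourse.fraction[mask]
        if self.endog.size < 2:
            raise ValueError("fitting requires at least two points in the window")
        if condition.nanoparticle_density <= 0:
            raise ValueError("fitting requires a positive nanoparticle density")

        if isinstance(weights, str):
            if weights != "inverse_variance":
                raise ValueError(f"unknown weighting scheme {weights!r}")
            if timecourse.cells_counted is None:
                raise ValueError("inverse-variance weighting requires counts")
            n = timecourse.cells_counted[mask].astype(float)
            f = np.clip(self.endog, 1e-6, 1 - 1e-6)
            self.weights = n / (f * (1.0 - f))
        elif weights is not None:
            w = np.asarray(weights, dtype=float)[mask]
            if np.any(w < 0):
                raise ValueError("weights must be non-negative")
            self.weights = w
        else:
            self.weights = np.ones_like(self.endog)

        self._k1 = stationary_rate_constant(condition.pair_system(self.medium))
        self._t_s = minutes_to_seconds(self.times_min)
        self.counts = (
            timecourse.cells_counted[mask]
            if timecourse.cells_counted is not None
            else None
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        particle: ParticleSpec | None = None,
        cell: CellSpec | None = None,
        **kwargs,
    ) -> "MembraneDamageModel":
        """Build model and condition from a tidy one-condition DataFrame."""
        particle = particle if particle is not None else ParticleSpec()
        cell = cell if cell is not None else CellSpec()
        tc = DamageTimeCourse.from_dataframe(df, particle=particle)
        condition = ExperimentCondition(
            temperature=tc.temperature,
            nanoparticle_density=tc.nanoparticle_density,
            particle=particle,
            cell=cell,
        )
        return cls(tc, condition=condition, **kwargs)

    # -- model maths -------------------------------------------------------

    def k2(self, p2: float) -> float:
        return self._k1 * math.exp(log_rate_modifier(p2, self.convention))

    def predict(self, p2: float, times_min: np.ndarray | None = None) -> np.ndarray:
        """Predicted damaged fractions at the given times (minutes)."""
        t_s = self._t_s if times_min is None else minutes_to_seconds(
            np.asarray(times_min, dtype=float)
        )
        return damaged_fraction(t_s, self.k2(p2), self.condition.nanoparticle_density)

    def _ssr(self, p2: float) -> float:
        resid = self.endog - self.predict(p2)
        return float(np.sum(self.weights * resid**2))

    # -- fitting -----------------------------------------------------------

    def fit(self, xatol: float = 1e-12, n_grid: int = 256) -> "MembraneDamageResults":
        """Estimate P2 by least squares.

        A coarse log-spaced scan of the admissible interval brackets the
        minimum, then bounded scalar minimisation (on log P2, tolerance
        ``xatol``) refines it.  Fully deterministic: identical inputs give
        bitwise-identical estimates.
        """
        lo, hi = self.p2_bounds
        at_bound = False
        if np.all(self.endog == 0.0):
            warnings.warn(
                "all observed fractions are zero; P2 is reported at the lower "
                "floor and is not identified",
                stacklevel=2,
            )
            p2_hat = lo
            at_bound = True
        else:
            log_grid = np.linspace(math.log(lo), math.log(hi), n_grid)
            ssr_grid = np.array([self._ssr(math.exp(u)) for u in log_grid])
            i = int(np.argmin(ssr_grid))
            u_lo = log_grid[max(i - 1, 0)]
            u_hi = log_grid[min(i + 1, n_grid - 1)]
            res = minimize_scalar(
                lambda u: self._ssr(math.exp(u)),
                bounds=(u_lo, u_hi),
                method="bounded",
                options={"xatol": xatol},
            )
            p2_hat = math.exp(res.x)
            if p2_hat <= lo * (1 + 1e-6) or p2_hat >= hi * (1 - 1e-9):
                p2_hat = min(max(p2_hat, lo), hi)
                at_bound = True
        return MembraneDamageResults(model=self, p2_hat=p2_hat, at_bound=at_bound)


@dataclass(frozen=True)
class MembraneDamageResults:
    """Fit results: point estimate, uncertainty, and diagnostics."""

    model: MembraneDamageModel
    p2_hat: float
    at_bound: bool
    k2_hat: float = field(init=False)
    eact2_hat: float = field(init=False)  # J
    fittedvalues: np.ndarray = field(init=False)
    resid: np.ndarray = field(init=False)
    rsquared: float = field(init=False)
    bse: float = field(init=False)  # delta-method SE of p2_hat

    def __post_init__(self) -> None:
        m = self.model
        object.__setattr__(self, "k2_hat", m.k2(self.p2_hat))
        object.__setattr__(
            self,
            "eact2_hat",
            activation_energy_second(self.p2_hat, m.condition.temperature),
        )
        fitted = m.predict(self.p2_hat)
        object.__setattr__(self, "fittedvalues", fitted)
        object.__setattr__(self, "resid", m.endog - fitted)
        try:
            r2 = r_squared(m.endog, fitted)
        except ValueError:
            r2 = float("nan")  # degenerate series (all-identical observations)
        object.__setattr__(self, "rsquared", r2)
        object.__setattr__(self, "bse", self._delta_se())

    def _delta_se(self) -> float:
        """Delta-method standard error of p2_hat from the fit Jacobian.

        df/dP2 = t CB0 (dk2/dP2) / (x + 1)^2 with dk2/dP2 = k2 g'(P2);
        g'(P2) = +-3/(2 P2^2) depending on the convention.

        When per-point cell counts are available, the known binomial
        sampling variances f(1 - f)/n enter a heteroscedasticity-consistent
        sandwich, var = sum(J^2 sigma^2) / (sum J^2)^2; otherwise the
        residual variance (n - 1 degrees of freedom, one fitted parameter)
        is used and intervals fall back to a Student-t quantile.
        """
        m = self.model
        n = m.endog.size
        if self.at_bound:
            return float("nan")
        sign = 1.0 if m.convention == "corrected" else -1.0
        gprime = sign * 3.0 / (2.0 * self.p2_hat**2)
        x = m.condition.nanoparticle_density * self.k2_hat * m._t_s
        jac = (m._t_s * m.condition.nanoparticle_density * self.k2_hat * gprime) / (
            (x + 1.0) ** 2
        )
        if m.counts is not None:
            f = np.clip(self.fittedvalues, 1e-12, 1 - 1e-12)
            sigma2 = f * (1.0 - f) / m.counts.astype(float)
            denom = float(np.sum(jac**2))
            if denom <= 0:
                return float("nan")
            object.__setattr__(self, "_se_known_variance", True)
            return math.sqrt(float(np.sum(jac**2 * sigma2)) / denom**2)
        if n < 3:
            return float("nan")
        jtj = float(np.sum(m.weights * jac**2))
        if jtj <= 0:
            return float("nan")
        s2 = float(np.sum(m.weights * self.resid**2)) / (n - 1)
        object.__setattr__(self, "_se_known_variance", False)
        return math.sqrt(s2 / jtj)

    # -- statsmodels-flavoured accessors ----------------------------------

    @property
    def params(self) -> np.ndarray:
        return np.array([self.p2_hat])

    @property
    def nobs(self) -> int:
        return int(self.model.endog.size)

    @property
    def convention(self) -> str:
        return self.model.convention

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        """Wald-type interval for P2, clipped to the admissible range.

        With counting data the sampling variance is known (binomial), so a
        normal quantile applies; without counts the residual-variance SE
        gets a Student-t quantile with n - 1 degrees of freedom, the usual
        small-sample choice for a nonlinear least-squares interval.
        """
        from scipy.stats import norm, t as t_dist

        if not math.isfinite(self.bse):
            return (float("nan"), float("nan"))
        if getattr(self, "_se_known_variance", False):
            z = norm.ppf(1.0 - alpha / 2.0)
        else:
            z = t_dist.ppf(1.0 - alpha / 2.0, self.nobs - 1)
        lo, hi = self.model.p2_bounds
        return (
            max(self.p2_hat - z * self.bse, lo),
            min(self.p2_hat + z * self.bse, hi),
        )

    def predict(self, times_min) -> np.ndarray:
        return self.model.predict(self.p2_hat, np.asarray(times_min, dtype=float))

    def to_dict(self) -> dict:
        """JSON-ready summary record."""
        return {
            "label": self.model.timecourse.label,
            "temperature_C": round(self.model.timecourse.temperature_celsius, 4),
            "p2_hat": self.p2_hat,
            "p2_se": self.bse,
            "k2_hat_m3_per_s": self.k2_hat,
            "eact2_hat_J": self.eact2_hat,
            "r_squared": self.rsquared,
            "convention": self.convention,
            "n_points": self.nobs,
            "at_bound": self.at_bound,
        }

    def summary(self) -> str:
        m = self.model
        ci = self.conf_int()
        lines = [
            "Membrane damage kinetics: single-parameter least squares",
            "=" * 58,
            f"Condition:    {m.timecourse.temperature_celsius:.1f} degC, "
            f"CB0 = {m.condition.nanoparticle_density:.3e} /m^3",
            f"Convention:   {m.convention}",
            f"N points:     {self.nobs}",
            "-" * 58,
            f"P2 (death probability)   {self.p2_hat:12.5g}   SE {self.bse:10.3g}",
            f"  95% CI                 [{ci[0]:.5g}, {ci[1]:.5g}]",
            f"k2                       {self.k2_hat:12.5g}   m^3/s",
            f"Eact2                    {self.eact2_hat:12.5g}   J",
            f"R^2                      {self.rsquared:12.5g}",
        ]
        if self.at_bound:
            lines.append("WARNING: estimate at the boundary of the admissible range")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed points and fitted hyperbola (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        ax.plot(m.times_min, m.endog, "o", label="observed")
        tt = np.linspace(0, float(m.times_min.max()) * 1.05, 200)
        ax.plot(tt, self.predict(tt), "-", label=f"fit (P2={self.p2_hat:.3g})")
        ax.set_xlabel("time, min")
        ax.set_ylabel("damaged fraction")
        ax.legend()
        return ax


def fit_p2(
    timecourse: DamageTimeCourse,
    medium: MediumState | None = None,
    condition: ExperimentCondition | None = None,
    convention: str = "corrected",
    time_window: tuple[float, float] | None = None,
    weights=None,
) -> MembraneDamageResults:
    """Convenience wrapper: build a MembraneDamageModel and fit it."""
    return MembraneDamageModel(
        timecourse,
        medium=medium,
        condition=condition,
        convention=convention,
        time_window=time_window,
        weights=weights,
    ).fit()


def activation_energy_profile(fits: Iterable) -> pd.DataFrame:
    """Tabulate the effective death activation energy across temperatures.

    Accepts MembraneDamageResults objects or (temperature_K, p2) pairs and
    returns a DataFrame with columns temperature_K, temperature_C, p2,
    eact2_J, sorted by temperature, with ``attrs['argmax_temperature_C']``
    and ``attrs['argmin_temperature_C']`` identifying the extremes.
    """
    rows = []
    for item in fits:
        if isinstance(item, MembraneDamageResults):
            t_k = item.model.timecourse.temperature
            p2 = item.p2_hat
        else:
            t_k, p2 = item
        rows.append(
            {
                "temperature_K": float(t_k),
                "temperature_C": kelvin_to_celsius(float(t_k)),
                "p2": float(p2),
                "eact2_J": activation_energy_second(float(p2), float(t_k)),
            }
        )
    if len(rows) < 2:
        raise ValueError("a profile needs fits at >= 2 temperatures")
    temps = [r["temperature_K"] for r in rows]
    if len(set(round(t, 9) for t in temps)) != len(temps):
        raise ValueError("duplicate temperatures in the profile input")
    out = pd.DataFrame(rows).sort_values("temperature_K", ignore_index=True)
    out.attrs["argmax_temperature_C"] = float(
        out.loc[out["eact2_J"].idxmax(), "temperature_C"]
    )
    out.attrs["argmin_temperature_C"] = float(
        out.loc[out["eact2_J"].idxmin(), "temperature_C"]
    )
    return out
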