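"""Impeller Reynolds number, power-number correlation, power draw and energy.

The impeller power number follows the two-parameter laminar/transition
correlation ``P0 = K1/Re + K2``; power draw is the standard
``P = P0 * rho * N**3 * D**5``.  Cumulative energy is a trapezoidal
integral of power over time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import DegenerateFitError, InvalidInputError

WH_PER_MJ = 1.0e6 / 3600.0  # 277.78 Wh in one MJ


@dataclass(frozen=True)
class ReactorGeometry:
    """Stirred-tank dimensions and fluid density.

    Defaults describe a 2.5 L bench bioreactor: 130 mm tank, 70 mm
    three-blade pitched impeller with 20 mm blade width, 980 mL working
    volume.  Density defaults to 1000 kg/m3 (the rig works on a
    1.0 kg ~ 980 mL basis; configurable).
    """

    tank_diameter: float = 0.130
    impeller_diameter: float = 0.070
    blade_width: float = 0.020
    working_volume: float = 9.8e-4
    fluid_density: float = 1000.0

    def __post_init__(self) -> None:
        if not 0 < self.impeller_diameter < self.tank_diameter:
            raise InvalidInputError(
                "need 0 < impeller_diameter < tank_diameter, got "
                f"{self.impeller_diameter} vs {self.tank_diameter}"
            )
        if not self.working_volume > 0:
            raise InvalidInputError(f"working volume must be > 0, got {self.working_volume}")
        if not self.fluid_density > 0:
            raise InvalidInputError(f"fluid density must be > 0, got {self.fluid_density}")


@dataclass(frozen=True)
class PowerCorrelation:
    """Parameters of the power-number correlation ``P0 = k1/Re + k2``."""

    k1: float
    k2: float

    def __post_init__(self) -> None:
        if self.k1 < 0:
            raise InvalidInputError(f"k1 must be >= 0, got {self.k1}")
        if not self.k2 > 0:
            raise InvalidInputError(f"k2 must be > 0, got {self.k2}")


@dataclass(frozen=True)
class PowerObservation:
    """One motor-power measurement: loaded vessel vs idle (air) baseline."""

    impeller_speed: float  # rpm
    motor_power_loaded: float  # W
    motor_power_air: float  # W

    def __post_init__(self) -> None:
        if not self.motor_power_loaded >= self.motor_power_air >= 0:
            raise InvalidInputError(
                "need motor_power_loaded >= motor_power_air >= 0, got "
                f"{self.motor_power_loaded} / {self.motor_power_air}"
            )


class FittedCorrelation(NamedTuple):
    """Least-squares fit result with a residual summary.

    ``k1``/``k2`` are the raw estimates (noise can push them outside the
    physical range); :meth:`correlation` converts to a validated
    :class:`PowerCorrelation`.
    """

    k1: float
    k2: float
    n_points: int
    rss: float

    @property
    def correlation(self) -> PowerCorrelation:
        return PowerCorrelation(k1=self.k1, k2=self.k2)


class EnergySeries(NamedTuple):
    """Cumulative energy in both Wh and MJ (element 0 is 0)."""

    wh: np.ndarray
    mj: np.ndarray


def reynolds_number(density, impeller_speed, impeller_diameter, viscosity):
    """Impeller Reynolds number ``rho * N * D**2 / mu`` (N in rev/s)."""
    viscosity = np.asarray(viscosity, dtype=float)
    if np.any(viscosity <= 0):
        raise InvalidInputError("viscosity must be > 0")
    if density <= 0 or impeller_diameter <= 0:
        raise InvalidInputError("density and impeller diameter must be > 0")
    if np.any(np.asarray(impeller_speed) <= 0):
        raise InvalidInputError("impeller speed must be > 0 for a Reynolds number")
    re = density * impeller_speed * impeller_diameter**2 / viscosity
    return float(re) if np.ndim(re) == 0 else re


def power_number(re, corr: PowerCorrelation):
    """Power number from the correlation ``k1/Re + k2``; decreasing in Re."""
    re = np.asarray(re, dtype=float)
    if np.any(re <= 0):
        raise InvalidInputError("Reynolds number must be > 0")
    p0 = corr.k1 / re + corr.k2
    return float(p0) if p0.ndim == 0 else p0


def fit_power_correlation(
    observations: Sequence[tuple[float, float]], weights: str | None = None
) -> FittedCorrelation:
    """Least squares of P0 against 1/Re.

    The correlation is linear in its parameters in the transformed
    variable ``x = 1/Re``, so the fit is a linear regression
    ``P0 = k1 * x + k2``.  By default the regression is unweighted.
    ``weights="relative"`` minimises relative residuals instead (each
    residual divided by the observed P0), which is the consistent choice
    when the measurement noise is multiplicative.

    Parameters
    ----------
    observations : sequence of (re, p0) pairs
        At least two observations with distinct Reynolds numbers.
    weights : None or "relative"
    """
    obs = np.asarray(observations, dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 2 or obs.shape[0] < 2:
        raise DegenerateFitError("need at least 2 (re, p0) observations")
    re, p0 = obs[:, 0], obs[:, 1]
    if np.any(re <= 0):
        raise InvalidInputError("all Reynolds numbers must be > 0")
    x = 1.0 / re
    if np.ptp(x) == 0:
        raise DegenerateFitError("all Reynolds numbers identical: slope unidentifiable")
    design = np.column_stack([x, np.ones_like(x)])
    if weights is None:
        w = np.ones_like(p0)
    elif weights == "relative":
        if np.any(p0 <= 0):
            raise InvalidInputError("relative weighting requires positive P0 observations")
        w = 1.0 / p0
    else:
        raise InvalidInputError(f"unknown weighting scheme {weights!r}")
    coef, _, _, _ = np.linalg.lstsq(design * w[:, None], p0 * w, rcond=None)
    k1, k2 = float(coef[0]), float(coef[1])
    rss = float(np.sum((p0 - design @ coef) ** 2))
    return FittedCorrelation(k1=k1, k2=k2, n_points=len(re), rss=rss)


def net_fluid_power(obs: PowerObservation) -> float:
    """Power dissipated to the fluid: loaded draw minus the air baseline."""
    return obs.motor_power_loaded - obs.motor_power_air


def impeller_power(p0, density, impeller_speed, impeller_diameter):
    """Impeller power draw ``P = P0 * rho * N**3 * D**5`` in W (N in rev/s)."""
    p0 = np.asarray(p0, dtype=float)
    if np.any(p0 < 0) or density < 0 or impeller_diameter < 0:
        raise InvalidInputError("power number, density and diameter must be >= 0")
    if np.any(np.asarray(impeller_speed) < 0):
        raise InvalidInputError("impeller speed must be >= 0")
    p = p0 * density * np.asarray(impeller_speed, dtype=float) ** 3 * impeller_diameter**5
    return float(p) if np.ndim(p) == 0 else p


def volumetric_power(power, geometry: ReactorGeometry):
    """Power per unit working volume, W/m3."""
    p = np.asarray(power, dtype=float) / geometry.working_volume
    return float(p) if np.ndim(p) == 0 else p


def cumulative_energy(times, powers) -> EnergySeries:
    """Trapezoidal cumulative energy of a power series.

    Parameters
    ----------
    times : array-like, hours, strictly increasing
    powers : array-like, W, non-negative, same length

    Returns
    -------
    EnergySeries
        Cumulative energy at each time point, in Wh and MJ; first
        element is 0 and the series is non-decreasing.
    """
    t = np.asarray(times, dtype=float)
    p = np.asarray(powers, dtype=float)
    if t.shape != p.shape or t.ndim != 1:
        raise InvalidInputError("times and powers must be 1-D arrays of equal length")
    if t.size < 1:
        raise InvalidInputError("need at least one time point")
    if np.any(np.diff(t) <= 0):
        raise InvalidInputError("times must be strictly increasing")
    if np.any(p < 0):
        raise InvalidInputError("powers must be >= 0")
    wh = cumulative_trapezoid(p, t, initial=0.0)
    return EnergySeries(wh=wh, mj=wh * 3600.0 / 1.0e6)
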