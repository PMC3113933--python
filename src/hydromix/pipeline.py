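"""End-to-end trajectory computation and downstream statistical fits.

One trajectory chains the component models at every time point:

    conversion -> WIS -> viscosity at the impeller shear rate -> Reynolds
    number -> power number -> power draw -> cumulative energy.

On top of trajectories the module provides the time-averaged volumetric
power, the energy saving from a higher enzyme load, a full second-order
response surface of conversion against (total energy, time), and the
long-format conversion/energy frontier table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateFitError, InvalidInputError
from .mixing_power import (
    PowerCorrelation,
    ReactorGeometry,
    cumulative_energy,
    impeller_power,
    power_number,
    reynolds_number,
    volumetric_power,
)
from .rheology import RheologyModel, apparent_viscosity, average_shear_rate
from .synthetic_data import (
    ConversionModelParams,
    HydrolysisConditions,
    SlurryComposition,
    conversion_curve,
    wis_from_conversion,
)

log = logging.getLogger(__name__)

TRAJECTORY_COLUMNS = [
    "time_h",
    "conversion",
    "wis_pct",
    "shear_rate_per_s",
    "viscosity_pa_s",
    "reynolds",
    "power_number",
    "power_w",
    "volumetric_power_w_m3",
    "cumulative_energy_wh",
    "cumulative_energy_kwh_m3",
]


@dataclass(frozen=True)
class ProcessTrajectory:
    """Joined time series of the full rheology-power chain."""

    conditions: HydrolysisConditions
    geometry: ReactorGeometry
    time_h: np.ndarray
    conversion: np.ndarray
    wis_pct: np.ndarray
    shear_rate_per_s: np.ndarray
    viscosity_pa_s: np.ndarray
    reynolds: np.ndarray
    power_number: np.ndarray
    power_w: np.ndarray
    volumetric_power_w_m3: np.ndarray
    cumulative_energy_wh: np.ndarray
    cumulative_energy_kwh_m3: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in TRAJECTORY_COLUMNS})


@dataclass(frozen=True)
class ResponseSurface:
    """Full second-order polynomial X = b0 + b1*E + b2*t + b3*E^2 + b4*t^2 + b5*E*t."""

    coefficients: tuple[float, float, float, float, float, float]
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0:
            raise InvalidInputError(f"R^2 must be in [0, 1], got {self.r_squared}")

    def predict(self, energy, time):
        e = np.asarray(energy, dtype=float)
        t = np.asarray(time, dtype=float)
        b = self.coefficients
        x = b[0] + b[1] * e + b[2] * t + b[3] * e**2 + b[4] * t**2 + b[5] * e * t
        return float(x) if np.ndim(x) == 0 else x


def run_trajectory(
    cond: HydrolysisConditions,
    geometry: ReactorGeometry,
    rheology: RheologyModel,
    correlation: PowerCorrelation,
    composition: SlurryComposition,
    conv_params: ConversionModelParams,
    grid,
) -> ProcessTrajectory:
    """Compute the full process trajectory for one condition.

    ``composition.wis0`` is overridden by ``cond.wis_initial`` for the
    WIS bookkeeping, so the same base composition can serve several
    conditions.  A zero impeller speed yields zero power and energy
    everywhere (viscosity, Re and P0 are undefined and reported as NaN).
    """
    grid = np.asarray(grid, dtype=float)
    curve = conversion_curve(conv_params, cond, grid)
    comp_run = replace(composition, wis0=cond.wis_initial)
    x = curve.conversion
    wis = wis_from_conversion(x, comp_run)

    n_rps = cond.impeller_speed / 60.0
    if cond.impeller_speed == 0:
        # unstirred limit: shear and power vanish; mu, Re, P0 are undefined
        nan = np.full_like(grid, np.nan)
        zeros = np.zeros_like(grid)
        return ProcessTrajectory(
            conditions=cond,
            geometry=geometry,
            time_h=grid,
            conversion=x,
            wis_pct=wis,
            shear_rate_per_s=zeros,
            viscosity_pa_s=nan,
            reynolds=nan,
            power_number=nan,
            power_w=zeros,
            volumetric_power_w_m3=zeros,
            cumulative_energy_wh=zeros,
            cumulative_energy_kwh_m3=zeros,
        )

    shear = average_shear_rate(n_rps, rheology)
    mu = apparent_viscosity(shear, wis, rheology)
    re = reynolds_number(geometry.fluid_density, n_rps, geometry.impeller_diameter, mu)
    p0 = power_number(re, correlation)
    power = impeller_power(p0, geometry.fluid_density, n_rps, geometry.impeller_diameter)
    pv = volumetric_power(power, geometry)
    energy = cumulative_energy(grid, power)
    return ProcessTrajectory(
        conditions=cond,
        geometry=geometry,
        time_h=grid,
        conversion=x,
        wis_pct=wis,
        shear_rate_per_s=np.full_like(grid, shear),
        viscosity_pa_s=mu,
        reynolds=re,
        power_number=p0,
        power_w=power,
        volumetric_power_w_m3=pv,
        cumulative_energy_wh=energy.wh,
        cumulative_energy_kwh_m3=energy.wh / 1000.0 / geometry.working_volume,
    )


def mean_volumetric_power(traj: ProcessTrajectory) -> float:
    """Time-averaged power per working volume, W/m3.

    Identically ``E_total / (duration * volume)`` with the trapezoidal
    cumulative energy.
    """
    duration = traj.time_h[-1] - traj.time_h[0]
    if duration <= 0:
        raise InvalidInputError("trajectory duration must be > 0")
    return float(
        traj.cumulative_energy_wh[-1] / duration / traj.geometry.working_volume
    )


def energy_reduction_from_enzyme(
    traj_low: ProcessTrajectory, traj_high: ProcessTrajectory
) -> float:
    """Percent energy saved by the higher enzyme load at equal speed.

    ``100 * (E_low - E_high) / E_low`` at the final time point.
    """
    if traj_low.conditions.impeller_speed != traj_high.conditions.impeller_speed:
        raise InvalidInputError("trajectories must share the impeller speed")
    if traj_low.time_h.shape != traj_high.time_h.shape or not np.allclose(
        traj_low.time_h, traj_high.time_h
    ):
        raise InvalidInputError("trajectories must share the time grid")
    e_low = traj_low.cumulative_energy_wh[-1]
    e_high = traj_high.cumulative_energy_wh[-1]
    if e_low <= 0:
        raise InvalidInputError("reference trajectory has zero total energy")
    return float(100.0 * (e_low - e_high) / e_low)


def fit_response_surface(points: Sequence[tuple[float, float, float]]) -> ResponseSurface:
    """OLS fit of conversion against (total energy, time), second order.

    ``points`` are (total energy input, time, conversion) triples; at
    least 6 are required and the quadratic design must have full rank.
    A response with zero variance is reported as R^2 = 0 by convention.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 6:
        raise DegenerateFitError("need at least 6 (energy, time, conversion) points")
    e, t, x = pts[:, 0], pts[:, 1], pts[:, 2]
    design = np.column_stack([np.ones_like(e), e, t, e**2, t**2, e * t])
    coef, _, rank, _ = np.linalg.lstsq(design, x, rcond=None)
    if rank < 6:
        raise DegenerateFitError(
            f"design matrix rank {rank} < 6: factor levels insufficient for a "
            "second-order surface"
        )
    resid = x - design @ coef
    rss = float(resid @ resid)
    tss = float(np.sum((x - x.mean()) ** 2))
    r2 = 0.0 if tss == 0.0 else max(0.0, 1.0 - rss / tss)
    return ResponseSurface(
        coefficients=tuple(float(c) for c in coef), r_squared=r2, n_points=len(x)
    )


def conversion_energy_frontier(
    trajectories: Sequence[ProcessTrajectory],
    times: Sequence[float] = (24.0, 48.0, 96.0),
) -> pd.DataFrame:
    """Tidy table of conversion vs cumulative energy at selected times.

    All trajectories must share the time grid.  Times that are not grid
    points are linearly interpolated (logged).
    """
    if not trajectories:
        raise InvalidInputError("need at least one trajectory")
    grid = trajectories[0].time_h
    for traj in trajectories[1:]:
        if traj.time_h.shape != grid.shape or not np.allclose(traj.time_h, grid):
            raise InvalidInputError("all trajectories must share the time grid")
    rows = []
    for t_sel in times:
        if not np.any(np.isclose(grid, t_sel)):
            log.info("time %g h not on the grid; interpolating linearly", t_sel)
        for traj in trajectories:
            rows.append(
                {
                    "speed_rpm": traj.conditions.impeller_speed,
                    "enzyme_load_fpu_per_g": traj.conditions.enzyme_load,
                    "time_h": float(t_sel),
                    "conversion": float(np.interp(t_sel, grid, traj.conversion)),
                    "cumulative_energy_wh": float(
                        np.interp(t_sel, grid, traj.cumulative_energy_wh)
                    ),
                }
            )
    return pd.DataFrame(rows)
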