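"""Default, anchor-calibrated model parameters.

Only a handful of quantitative constraints on the slurry model are
available, so the defaults are pinned to them:

* conversion generator: the four anchor conversions in
  :data:`hydromix.synthetic_data.DEFAULT_ANCHORS`;
* power-number correlation: (K1, K2) = (346.7, 1.27);
* rheology: apparent viscosity 2.0 Pa s at 12% WIS and 50 1/s pins the
  prefactor ``a``; the flow-behaviour index is fixed at n_PL = 0.5
  (mid-range shear thinning, typical of pretreated-softwood slurries)
  and the WIS exponent ``b`` is then solved numerically so that the
  96-h time-averaged volumetric power of the reference run (500 rpm,
  20 FPU/g glucan, 10% initial WIS) equals 1.5 kW/m3.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from .mixing_power import PowerCorrelation, ReactorGeometry
from .rheology import RheologyModel, calibrate_rheology
from .synthetic_data import (
    ConversionModelParams,
    HydrolysisConditions,
    SlurryComposition,
    calibrate_conversion_model,
    dilute_slurry,
)

#: Fitted correlation parameters for the bench rig.
DEFAULT_CORRELATION = PowerCorrelation(k1=346.7, k2=1.27)

#: Viscosity anchor: 2.0 Pa s at 12% WIS, shear rate 50 1/s.
VISCOSITY_ANCHOR = {"viscosity": 2.0, "wis": 12.0, "shear": 50.0}

#: Power anchor: mean volumetric power of the reference 96-h run, W/m3.
MEAN_POWER_ANCHOR_W_M3 = 1500.0

DEFAULT_N_PL = 0.5

REFERENCE_CONDITIONS = HydrolysisConditions(
    impeller_speed=500.0, enzyme_load=20.0, wis_initial=10.0, duration=96.0
)


def default_geometry() -> ReactorGeometry:
    return ReactorGeometry()


@lru_cache(maxsize=1)
def default_conversion_params() -> ConversionModelParams:
    """Conversion generator calibrated to the printed anchor conversions."""
    return calibrate_conversion_model()


@lru_cache(maxsize=1)
def default_composition() -> SlurryComposition:
    """Pretreated slurry (13% WIS) diluted to the 10% working content."""
    return dilute_slurry(SlurryComposition(), target_wis=10.0).composition


def default_time_grid(duration: float = 96.0, step: float = 0.5) -> np.ndarray:
    return np.arange(0.0, duration + step / 2, step)


def _mean_power_for_b(b: float) -> float:
    # local import: pipeline imports nothing from this module
    from .pipeline import mean_volumetric_power, run_trajectory

    model = calibrate_rheology(
        VISCOSITY_ANCHOR["viscosity"],
        VISCOSITY_ANCHOR["wis"],
        VISCOSITY_ANCHOR["shear"],
        b=b,
        n_pl=DEFAULT_N_PL,
    )
    traj = run_trajectory(
        REFERENCE_CONDITIONS,
        default_geometry(),
        model,
        DEFAULT_CORRELATION,
        default_composition(),
        default_conversion_params(),
        default_time_grid(),
    )
    return mean_volumetric_power(traj)


@lru_cache(maxsize=1)
def default_rheology() -> RheologyModel:
    """Rheology whose reference-run mean power meets the power anchor.

    The mean volumetric power decreases monotonically in ``b`` (a larger
    exponent makes the viscosity fall faster as WIS declines), so a
    bracketing root find on ``b`` is well posed.
    """
    b = brentq(
        lambda bb: _mean_power_for_b(bb) - MEAN_POWER_ANCHOR_W_M3, 0.5, 40.0, xtol=1e-10
    )
    return calibrate_rheology(
        VISCOSITY_ANCHOR["viscosity"],
        VISCOSITY_ANCHOR["wis"],
        VISCOSITY_ANCHOR["shear"],
        b=b,
        n_pl=DEFAULT_N_PL,
    )
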