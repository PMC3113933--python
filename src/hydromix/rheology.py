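"""Power-law rheology of lignocellulose slurries in a stirred tank.

The slurry is modelled as a shear-thinning Ostwald-de Waele fluid whose
consistency index depends on the water-insoluble-solids (WIS) content:

    K_PL(WIS) = a * WIS**b          [Pa s**n]
    mu(gamma, WIS) = K_PL(WIS) * gamma**(n_PL - 1)

with the average shear rate in the vessel approximated by the Metzner-Otto
relation ``gamma_avg = K_s * N`` (N in rev/s).  WIS is expressed in percent
(wt/wt) at every interface and used as the raw number (e.g. 10, 12) inside
the formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

#: Metzner-Otto constant reported for Rushton turbines, used here as the
#: default for the pitched-blade impeller as well.
DEFAULT_METZNER_OTTO = 11.5


@dataclass(frozen=True)
class RheologyModel:
    """Apparent-viscosity model ``mu = a * WIS**b * gamma**(n_pl - 1)``.

    Parameters
    ----------
    a : float
        Consistency-index prefactor, Pa s**n per (WIS %)**b.  Must be > 0.
    b : float
        WIS exponent (dimensionless).  Must be >= 0 (> 0 for a physically
        solids-dependent slurry; 0 is allowed for the degenerate constant
        case used in tests).
    n_pl : float
        Flow-behaviour index; 0 < n_pl <= 1 (shear-thinning or Newtonian).
        Held constant over a hydrolysis trajectory.
    k_s : float
        Metzner-Otto constant, > 0.
    """

    a: float
    b: float
    n_pl: float
    k_s: float = DEFAULT_METZNER_OTTO

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise InvalidInputError(f"prefactor a must be > 0, got {self.a}")
        if self.b < 0:
            raise InvalidInputError(f"WIS exponent b must be >= 0, got {self.b}")
        if not 0 < self.n_pl <= 1:
            raise InvalidInputError(
                f"flow-behaviour index n_pl must be in (0, 1], got {self.n_pl}"
            )
        if not self.k_s > 0:
            raise InvalidInputError(f"Metzner-Otto constant k_s must be > 0, got {self.k_s}")


def average_shear_rate(impeller_speed: float, model: RheologyModel) -> float:
    """Average shear rate (1/s) in the vessel for a given impeller speed.

    Parameters
    ----------
    impeller_speed : float
        Impeller speed in rev/s (not rpm).  Must be >= 0.
    """
    if impeller_speed < 0:
        raise InvalidInputError(f"impeller speed must be >= 0, got {impeller_speed}")
    return model.k_s * impeller_speed


def consistency_index(wis: float, model: RheologyModel) -> float:
    """Consistency index K_PL (Pa s**n) at a given WIS content (% wt/wt)."""
    if not wis > 0:
        raise InvalidInputError(f"WIS must be > 0, got {wis}")
    return model.a * wis**model.b


def apparent_viscosity(shear_rate, wis, model: RheologyModel):
    """Apparent viscosity (Pa s) at given shear rate (1/s) and WIS (%).

    Accepts scalars or numpy arrays for ``shear_rate`` and ``wis``.
    Shear rate must be strictly positive: the power law diverges at zero
    shear for n_pl < 1, so zero is rejected rather than clamped.
    """
    shear_rate = np.asarray(shear_rate, dtype=float)
    wis_arr = np.asarray(wis, dtype=float)
    if np.any(shear_rate <= 0):
        raise InvalidInputError("shear rate must be > 0 (power law diverges at 0)")
    if np.any(wis_arr <= 0):
        raise InvalidInputError("WIS must be > 0")
    k_pl = model.a * wis_arr**model.b
    mu = k_pl * shear_rate ** (model.n_pl - 1.0)
    return float(mu) if mu.ndim == 0 else mu


def calibrate_rheology(
    anchor_viscosity: float,
    anchor_wis: float,
    anchor_shear: float,
    b: float,
    n_pl: float,
    k_s: float = DEFAULT_METZNER_OTTO,
) -> RheologyModel:
    """Pin the prefactor ``a`` so the model passes through one measured point.

    Solves ``a = mu * gamma**(1 - n_pl) / wis**b`` so that
    ``apparent_viscosity(anchor_shear, anchor_wis) == anchor_viscosity``
    exactly (to floating-point precision).
    """
    if not (anchor_viscosity > 0 and anchor_wis > 0 and anchor_shear > 0):
        raise InvalidInputError("all calibration anchors must be > 0")
    a = anchor_viscosity * anchor_shear ** (1.0 - n_pl) / anchor_wis**b
    return RheologyModel(a=a, b=b, n_pl=n_pl, k_s=k_s)
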