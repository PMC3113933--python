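"""Synthetic inputs for the hydrolysis pipeline.

Everything the analysis consumes can be generated here without external
data: saturating conversion trajectories calibrated to a small set of
anchor conversions, slurry composition and dilution stoichiometry, noisy
glucose sampling, and power-number observations scattered around a given
P0-Re correlation.

Conversion generator
--------------------
Conversion is modelled as a saturating exponential with multiplicatively
separable impeller-speed and enzyme-load effects:

    X(t; N, E) = min(1, (E/E_ref)**p * (c0 + c1*N)) * (1 - exp(-t/tau))

with N in rpm, E in FPU/g glucan and t in hours.  This is the simplest
form that passes through the four default anchors, is monotone in all
three arguments, and gives an (exactly) linear speed-conversion
relationship at fixed time.  ``tau`` is shared across conditions, since
only one condition has anchors at two times.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import CalibrationError, InvalidInputError
from .mixing_power import PowerCorrelation, power_number

log = logging.getLogger(__name__)

#: Mass ratio of glucose to anhydroglucose (180.16/162.14 molar masses):
#: one water molecule is added per glucosyl unit on hydrolysis.
HYDRATION_FACTOR = 180.0 / 162.0

#: Printed anchor conversions: (rpm, FPU/g glucan, hours, conversion).
DEFAULT_ANCHORS: tuple[tuple[float, float, float, float], ...] = (
    (500.0, 20.0, 48.0, 0.57),
    (25.0, 20.0, 48.0, 0.26),
    (500.0, 20.0, 96.0, 0.72),
    (500.0, 10.0, 96.0, 0.54),
)


@dataclass(frozen=True)
class SlurryComposition:
    """Composition of the pretreated slurry (solids + liquid fraction).

    ``wis0`` is the WIS content in % wt/wt; ``glucan_frac_of_wis`` the
    glucan share of the insoluble solids; ``initial_liquid_glucose`` the
    dissolved glucose in the (undiluted) liquid phase, g/L.  Remaining
    compositional assay values ride along as metadata.
    """

    wis0: float = 13.0
    glucan_frac_of_wis: float = 0.48
    initial_liquid_glucose: float = 29.8
    solids_meta: dict = field(
        default_factory=lambda: {"mannan": 0.019, "galactan": 0.008, "xylan": 0.005, "lignin": 0.450}
    )
    liquid_meta: dict = field(
        default_factory=lambda: {"mannose_g_L": 30.3, "galactose_g_L": 5.1, "xylose_g_L": 9.9}
    )

    def __post_init__(self) -> None:
        if not 0 < self.wis0 <= 100:
            raise InvalidInputError(f"wis0 must be in (0, 100], got {self.wis0}")
        if not 0 <= self.glucan_frac_of_wis <= 1:
            raise InvalidInputError(
                f"glucan_frac_of_wis must be in [0, 1], got {self.glucan_frac_of_wis}"
            )
        if self.initial_liquid_glucose < 0:
            raise InvalidInputError("initial_liquid_glucose must be >= 0")


@dataclass(frozen=True)
class HydrolysisConditions:
    """One experimental condition: speed, enzyme load, initial WIS, duration."""

    impeller_speed: float  # rpm
    enzyme_load: float  # FPU/g glucan
    wis_initial: float = 10.0  # % wt/wt
    duration: float = 96.0  # h

    def __post_init__(self) -> None:
        # 0 rpm is admitted as the unstirred limit (powers identically zero)
        if not 0 <= self.impeller_speed <= 1000:
            raise InvalidInputError(f"impeller speed must be in [0, 1000] rpm, got {self.impeller_speed}")
        if not self.enzyme_load > 0:
            raise InvalidInputError(f"enzyme load must be > 0, got {self.enzyme_load}")
        if not 0 < self.wis_initial <= 20:
            raise InvalidInputError(f"initial WIS must be in (0, 20] %, got {self.wis_initial}")
        if not self.duration > 0:
            raise InvalidInputError(f"duration must be > 0, got {self.duration}")


@dataclass(frozen=True)
class ConversionModelParams:
    """Calibrated parameters of the saturating conversion generator."""

    tau: float  # h
    c0: float  # speed-response intercept
    c1: float  # speed-response slope, per rpm
    p: float  # enzyme-load exponent
    e_ref: float = 20.0  # reference load, FPU/g glucan
    speed_range: tuple[float, float] = (25.0, 500.0)  # calibrated box, rpm
    load_range: tuple[float, float] = (10.0, 20.0)  # calibrated box, FPU/g

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise InvalidInputError(f"tau must be > 0, got {self.tau}")
        if self.p < 0:
            raise InvalidInputError(f"enzyme exponent p must be >= 0, got {self.p}")
        for n in self.speed_range:
            amp = self.c0 + self.c1 * n
            if not 0 < amp <= 1:
                raise InvalidInputError(
                    f"speed response c0 + c1*N = {amp:.4f} outside (0, 1] at N = {n} rpm"
                )

    def amplitude(self, impeller_speed: float, enzyme_load: float) -> float:
        """Asymptotic conversion for a condition (clipped to 1)."""
        return min(
            1.0,
            (enzyme_load / self.e_ref) ** self.p * (self.c0 + self.c1 * impeller_speed),
        )

    def conversion(self, t, impeller_speed: float, enzyme_load: float):
        t = np.asarray(t, dtype=float)
        x = self.amplitude(impeller_speed, enzyme_load) * (1.0 - np.exp(-t / self.tau))
        return float(x) if x.ndim == 0 else x


class ConversionCurve(NamedTuple):
    """Time-stamped conversion under one (speed, load) condition."""

    times: np.ndarray  # h
    conversion: np.ndarray  # fraction of initial glucan
    conditions: HydrolysisConditions


class DilutionResult(NamedTuple):
    composition: SlurryComposition
    water_added_per_kg: float  # kg water per kg undiluted slurry


def enzyme_dose(
    load: float, cellulase_activity: float = 95.0, bg_activity: float = 590.0
) -> tuple[float, float]:
    """Enzyme preparation mass and beta-glucosidase dose per g glucan.

    Parameters
    ----------
    load : float
        Cellulase dose, FPU per g glucan.
    cellulase_activity : float
        FPU per g of enzyme preparation.
    bg_activity : float
        Beta-glucosidase IU per g of enzyme preparation.

    Returns
    -------
    (g preparation per g glucan, IU beta-glucosidase per g glucan)
    """
    if cellulase_activity <= 0 or bg_activity <= 0:
        raise InvalidInputError("enzyme activities must be > 0")
    if load < 0:
        raise InvalidInputError(f"enzyme load must be >= 0, got {load}")
    prep_mass = load / cellulase_activity
    return prep_mass, prep_mass * bg_activity


def dilute_slurry(composition: SlurryComposition, target_wis: float) -> DilutionResult:
    """Dilute the slurry with water to a lower WIS content.

    Solids are conserved; per kg of slurry, ``w`` kg of water satisfies
    ``wis0/(1 + w) = target``.  Dissolved species are diluted by the
    liquid-volume ratio (liquid density taken as 1 kg/L).
    """
    if not 0 < target_wis <= composition.wis0:
        raise InvalidInputError(
            f"target WIS must be in (0, {composition.wis0}], got {target_wis}"
        )
    water = composition.wis0 / target_wis - 1.0
    liquid0 = 1.0 - composition.wis0 / 100.0  # kg liquid per kg slurry
    dilution_ratio = liquid0 / (liquid0 + water)
    diluted = replace(
        composition,
        wis0=target_wis,
        initial_liquid_glucose=composition.initial_liquid_glucose * dilution_ratio,
        liquid_meta={k: v * dilution_ratio for k, v in composition.liquid_meta.items()},
    )
    return DilutionResult(composition=diluted, water_added_per_kg=water)


def _solve_tau(t1: float, t2: float, x1: float, x2: float) -> float:
    """Time constant from two conversions of the same condition.

    Solves (1 - exp(-t1/tau)) / (1 - exp(-t2/tau)) = x1/x2 by bisection.
    Feasible ratios lie strictly between t1/t2 (tau -> inf) and 1 (tau -> 0).
    """
    ratio = x1 / x2
    if not t1 / t2 < ratio < 1.0:
        raise CalibrationError(
            f"conversion ratio {ratio:.4f} at times ({t1}, {t2}) h infeasible for a "
            f"shared saturating exponential (must lie in ({t1 / t2:.4f}, 1))"
        )

    def f(tau: float) -> float:
        return math.expm1(-t1 / tau) / math.expm1(-t2 / tau) - ratio

    return brentq(f, 1e-3, 1e5, xtol=1e-12, rtol=1e-14)


def calibrate_conversion_model(
    anchors: Sequence[tuple[float, float, float, float]] = DEFAULT_ANCHORS,
    tol: float = 0.005,
) -> ConversionModelParams:
    """Fit the conversion generator so every anchor is matched.

    Anchors are (rpm, FPU/g glucan, hours, conversion) tuples.  The set
    must span at least two speeds, two loads and two times, and contain
    one condition observed at two times (identifying ``tau``).  The
    remaining parameters follow in closed form; every anchor must then be
    reproduced within ``tol`` (0.5 percentage points by default).
    """
    anchors = [tuple(map(float, a)) for a in anchors]
    if len(anchors) < 4:
        raise CalibrationError("need at least 4 anchors")
    speeds = sorted({a[0] for a in anchors})
    loads = sorted({a[1] for a in anchors})
    times = {a[2] for a in anchors}
    if len(speeds) < 2 or len(loads) < 2 or len(times) < 2:
        raise CalibrationError("anchors must span >= 2 speeds, >= 2 loads and >= 2 times")
    for n, e, t, x in anchors:
        if not (0 < x < 1 and t > 0):
            raise CalibrationError(f"anchor ({n}, {e}, {t}, {x}) out of range")

    # tau from the first condition observed at two distinct times
    by_condition: dict[tuple[float, float], list[tuple[float, float]]] = {}
    for n, e, t, x in anchors:
        by_condition.setdefault((n, e), []).append((t, x))
    tau = None
    for pts in by_condition.values():
        if len(pts) >= 2:
            (t1, x1), (t2, x2) = sorted(pts)[:2]
            if x2 <= x1:
                raise CalibrationError("anchors non-monotone in time at fixed condition")
            tau = _solve_tau(t1, t2, x1, x2)
            break
    if tau is None:
        raise CalibrationError("no condition with anchors at two times; tau unidentifiable")

    # asymptotic amplitude implied by each anchor
    amp = {
        (n, e): x / -math.expm1(-t / tau)
        for n, e, t, x in anchors
    }

    # reference load = the load observed at the most distinct speeds
    def n_speeds(load: float) -> int:
        return len({n for (n, e) in amp if e == load})

    e_ref = max(loads, key=n_speeds)
    ref = [(n, a) for (n, e), a in amp.items() if e == e_ref]
    if len({n for n, _ in ref}) < 2:
        raise CalibrationError("reference load needs anchors at >= 2 speeds")
    design = np.array([[1.0, n] for n, _ in ref])
    coef, _, _, _ = np.linalg.lstsq(design, np.array([a for _, a in ref]), rcond=None)
    c0, c1 = float(coef[0]), float(coef[1])

    # enzyme exponent from off-reference anchors
    p_vals = [
        math.log(a / (c0 + c1 * n)) / math.log(e / e_ref)
        for (n, e), a in amp.items()
        if e != e_ref and c0 + c1 * n > 0
    ]
    if not p_vals:
        raise CalibrationError("no off-reference-load anchor; enzyme exponent unidentifiable")
    p = float(np.mean(p_vals))
    if p < 0:
        raise CalibrationError(f"anchors imply a negative enzyme exponent ({p:.3f})")

    params = ConversionModelParams(
        tau=tau,
        c0=c0,
        c1=c1,
        p=p,
        e_ref=e_ref,
        speed_range=(speeds[0], speeds[-1]),
        load_range=(loads[0], loads[-1]),
    )
    for n, e, t, x in anchors:
        err = abs(params.conversion(t, n, e) - x)
        if err > tol:
            raise CalibrationError(
                f"anchor ({n} rpm, {e} FPU, {t} h, {x}) missed by {err:.4f} (> {tol})"
            )
    return params


def conversion_curve(
    params: ConversionModelParams, cond: HydrolysisConditions, grid
) -> ConversionCurve:
    """Evaluate the calibrated generator on a time grid.

    Conditions outside the calibrated (speed, load) box are evaluated
    anyway but logged as extrapolations.
    """
    t = np.asarray(grid, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise InvalidInputError("grid must be a non-empty 1-D array")
    if np.any(np.diff(t) < 0):
        raise InvalidInputError("grid must be sorted")
    if t[0] < 0 or t[-1] > cond.duration:
        raise InvalidInputError(
            f"grid must lie within [0, {cond.duration}] h, got [{t[0]}, {t[-1]}]"
        )
    lo_n, hi_n = params.speed_range
    lo_e, hi_e = params.load_range
    if not (lo_n <= cond.impeller_speed <= hi_n and lo_e <= cond.enzyme_load <= hi_e):
        log.warning(
            "condition (%g rpm, %g FPU/g) outside calibrated box %s x %s; extrapolating",
            cond.impeller_speed,
            cond.enzyme_load,
            params.speed_range,
            params.load_range,
        )
    x = params.conversion(t, cond.impeller_speed, cond.enzyme_load)
    return ConversionCurve(times=t, conversion=np.atleast_1d(x), conditions=cond)


def wis_from_conversion(x, composition: SlurryComposition):
    """WIS content (% wt/wt) after a given glucan conversion.

    On a constant-total-mass basis the anhydroglucan mass leaves the
    solids (the hydration water comes from the liquid), so
    ``wis(x) = wis0 * (1 - glucan_frac * x)``.
    """
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise InvalidInputError("conversion must be in [0, 1]")
    wis = composition.wis0 * (1.0 - composition.glucan_frac_of_wis * x)
    return float(wis) if wis.ndim == 0 else wis


def glucan_load_g_per_l(composition: SlurryComposition) -> float:
    """Initial insoluble glucan per litre of slurry (density ~ 1 kg/L)."""
    return composition.wis0 * 10.0 * composition.glucan_frac_of_wis


def glucose_from_conversion(x, composition: SlurryComposition):
    """Liquid glucose concentration (g/L) implied by a glucan conversion.

    ``c(x) = c_init + x * glucan_load * 180/162``; exactly invertible by
    :func:`conversion_from_glucose`.
    """
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise InvalidInputError("conversion must be in [0, 1]")
    c = composition.initial_liquid_glucose + x * glucan_load_g_per_l(composition) * HYDRATION_FACTOR
    return float(c) if c.ndim == 0 else c


def conversion_from_glucose(conc, composition: SlurryComposition):
    """Inverse of :func:`glucose_from_conversion` (no [0, 1] clipping)."""
    c = np.asarray(conc, dtype=float)
    x = (c - composition.initial_liquid_glucose) / (
        glucan_load_g_per_l(composition) * HYDRATION_FACTOR
    )
    return float(x) if x.ndim == 0 else x


def sample_noisy_glucose(
    curve: ConversionCurve,
    composition: SlurryComposition,
    cv: float = 0.04,
    seed: int | None = None,
) -> np.ndarray:
    """Noisy glucose concentrations for a conversion curve.

    Multiplicative Gaussian noise with coefficient of variation ``cv``
    (default 0.04, the assay repeatability bound); reproducible for a
    fixed seed.
    """
    if cv < 0:
        raise InvalidInputError(f"cv must be >= 0, got {cv}")
    conc = glucose_from_conversion(curve.conversion, composition)
    if cv == 0:
        return np.asarray(conc, dtype=float).copy()
    rng = np.random.default_rng(seed)
    return conc * (1.0 + rng.normal(0.0, cv, size=np.shape(conc)))


def simulate_power_observations(
    corr: PowerCorrelation,
    re_grid,
    noise_cv: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Scatter power-number observations around a P0-Re correlation.

    Returns an (n, 2) array of (re, p0) pairs with multiplicative
    Gaussian noise of coefficient of variation ``noise_cv`` on P0.
    """
    re = np.asarray(re_grid, dtype=float)
    if np.any(re <= 0):
        raise InvalidInputError("Reynolds numbers must be > 0")
    if noise_cv < 0:
        raise InvalidInputError(f"noise_cv must be >= 0, got {noise_cv}")
    p0 = power_number(re, corr)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        p0 = p0 * (1.0 + rng.normal(0.0, noise_cv, size=re.shape))
    return np.column_stack([re, p0])
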