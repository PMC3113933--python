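"""Config loading, CSV/JSON surfaces and deterministic report writing.

File conventions: comma-separated, '.' decimal, UTF-8, ``#``-prefixed
comment lines carrying metadata (tool version, config hash, seed).
Times are in hours and impeller speeds in rpm at every file surface.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .defaults import (
    DEFAULT_CORRELATION,
    default_rheology,
)
from .errors import ConfigError, InvalidInputError
from .mixing_power import PowerCorrelation, ReactorGeometry
from .rheology import RheologyModel, calibrate_rheology
from .synthetic_data import HydrolysisConditions, SlurryComposition, dilute_slurry

log = logging.getLogger(__name__)

_GEOMETRY_KEYS = {
    "tank_diameter_m": "tank_diameter",
    "impeller_diameter_m": "impeller_diameter",
    "blade_width_m": "blade_width",
    "working_volume_m3": "working_volume",
    "fluid_density_kg_m3": "fluid_density",
}
_RHEOLOGY_KEYS = {"a", "b", "n_pl", "k_s", "anchor"}
_ANCHOR_KEYS = {"viscosity_pa_s", "wis_pct", "shear_rate_per_s"}
_CORRELATION_KEYS = {"k1", "k2"}
_COMPOSITION_KEYS = {
    "wis0_pct",
    "glucan_frac_of_wis",
    "initial_liquid_glucose_g_l",
    "dilute_to_wis_pct",
}
_CONDITION_KEYS = {"speed_rpm", "enzyme_load_fpu_per_g", "duration_h"}
_GRID_KEYS = {"duration_h", "step_h"}
_NOISE_KEYS = {"glucose_cv", "power_cv"}
_TOP_KEYS = {"seed", "geometry", "rheology", "correlation", "composition", "conditions", "grid", "noise"}


@dataclass(frozen=True)
class RunConfig:
    """Fully validated run configuration with defaults applied."""

    geometry: ReactorGeometry
    rheology: RheologyModel
    correlation: PowerCorrelation
    composition: SlurryComposition  # diluted, as charged to the reactor
    base_composition: SlurryComposition  # as pretreated, before dilution
    conditions: tuple[HydrolysisConditions, ...]
    grid: np.ndarray
    glucose_cv: float
    power_cv: float
    seed: int
    config_hash: str


def config_hash(raw: dict) -> str:
    """Stable short hash of the raw config mapping."""
    blob = json.dumps(raw, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _reject_unknown(block: dict, allowed, path: str) -> None:
    unknown = set(block) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in '{path}'")


def _require_mapping(obj, path: str) -> dict:
    if not isinstance(obj, dict):
        raise ConfigError(f"'{path}' must be a mapping, got {type(obj).__name__}")
    return obj


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Every block is optional and falls back to the documented defaults;
    unknown keys anywhere are rejected with the offending field path.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raise ConfigError(f"config file {path} is empty: expected at least one of {sorted(_TOP_KEYS)}")
    raw = _require_mapping(raw, "<root>")
    _reject_unknown(raw, _TOP_KEYS, "<root>")

    geo_block = _require_mapping(raw.get("geometry", {}), "geometry")
    _reject_unknown(geo_block, _GEOMETRY_KEYS, "geometry")
    geo_kwargs = {}
    for file_key, field_name in _GEOMETRY_KEYS.items():
        if file_key in geo_block:
            geo_kwargs[field_name] = _number(geo_block[file_key], f"geometry.{file_key}")
    try:
        geometry = ReactorGeometry(**geo_kwargs)
    except InvalidInputError as exc:
        raise ConfigError(f"geometry: {exc}") from exc

    comp_block = _require_mapping(raw.get("composition", {}), "composition")
    _reject_unknown(comp_block, _COMPOSITION_KEYS, "composition")
    try:
        base_comp = SlurryComposition(
            wis0=_number(comp_block.get("wis0_pct", 13.0), "composition.wis0_pct"),
            glucan_frac_of_wis=_number(
                comp_block.get("glucan_frac_of_wis", 0.48), "composition.glucan_frac_of_wis"
            ),
            initial_liquid_glucose=_number(
                comp_block.get("initial_liquid_glucose_g_l", 29.8),
                "composition.initial_liquid_glucose_g_l",
            ),
        )
        target = _number(comp_block.get("dilute_to_wis_pct", 10.0), "composition.dilute_to_wis_pct")
        composition = dilute_slurry(base_comp, target).composition
    except InvalidInputError as exc:
        raise ConfigError(f"composition: {exc}") from exc

    corr_block = _require_mapping(raw.get("correlation", {}), "correlation")
    _reject_unknown(corr_block, _CORRELATION_KEYS, "correlation")
    try:
        correlation = PowerCorrelation(
            k1=_number(corr_block.get("k1", DEFAULT_CORRELATION.k1), "correlation.k1"),
            k2=_number(corr_block.get("k2", DEFAULT_CORRELATION.k2), "correlation.k2"),
        )
    except InvalidInputError as exc:
        raise ConfigError(f"correlation: {exc}") from exc

    rheology = _build_rheology(_require_mapping(raw.get("rheology", {}), "rheology"))

    grid_block = _require_mapping(raw.get("grid", {}), "grid")
    _reject_unknown(grid_block, _GRID_KEYS, "grid")
    duration = _number(grid_block.get("duration_h", 96.0), "grid.duration_h")
    step = _number(grid_block.get("step_h", 0.5), "grid.step_h")
    if duration <= 0 or step <= 0 or step > duration:
        raise ConfigError(f"grid: need 0 < step_h <= duration_h, got {step} / {duration}")
    grid = np.arange(0.0, duration + step / 2, step)

    cond_list = raw.get(
        "conditions",
        [
            {"speed_rpm": n, "enzyme_load_fpu_per_g": e}
            for e in (10.0, 20.0)
            for n in (25.0, 75.0, 150.0, 300.0, 500.0)
        ],
    )
    if not isinstance(cond_list, list) or not cond_list:
        raise ConfigError("'conditions' must be a non-empty list")
    conditions = []
    for i, c in enumerate(cond_list):
        c = _require_mapping(c, f"conditions[{i}]")
        _reject_unknown(c, _CONDITION_KEYS, f"conditions[{i}]")
        for req in ("speed_rpm", "enzyme_load_fpu_per_g"):
            if req not in c:
                raise ConfigError(f"conditions[{i}]: missing required key '{req}'")
        try:
            conditions.append(
                HydrolysisConditions(
                    impeller_speed=_number(c["speed_rpm"], f"conditions[{i}].speed_rpm"),
                    enzyme_load=_number(
                        c["enzyme_load_fpu_per_g"], f"conditions[{i}].enzyme_load_fpu_per_g"
                    ),
                    wis_initial=composition.wis0,
                    duration=_number(c.get("duration_h", duration), f"conditions[{i}].duration_h"),
                )
            )
        except InvalidInputError as exc:
            raise ConfigError(f"conditions[{i}]: {exc}") from exc

    noise_block = _require_mapping(raw.get("noise", {}), "noise")
    _reject_unknown(noise_block, _NOISE_KEYS, "noise")
    glucose_cv = _number(noise_block.get("glucose_cv", 0.04), "noise.glucose_cv")
    power_cv = _number(noise_block.get("power_cv", 0.05), "noise.power_cv")
    if glucose_cv < 0 or power_cv < 0:
        raise ConfigError("noise: coefficients of variation must be >= 0")

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError(f"seed must be an integer, got {seed!r}")

    cfg = RunConfig(
        geometry=geometry,
        rheology=rheology,
        correlation=correlation,
        composition=composition,
        base_composition=base_comp,
        conditions=tuple(conditions),
        grid=grid,
        glucose_cv=glucose_cv,
        power_cv=power_cv,
        seed=seed,
        config_hash=config_hash(raw),
    )
    log.debug("effective config: %s", cfg)
    return cfg


def _number(value, path: str) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError(f"'{path}' must be a number, got {value!r}")
    return float(value)


def _build_rheology(block: dict) -> RheologyModel:
    _reject_unknown(block, _RHEOLOGY_KEYS, "rheology")
    anchor = _require_mapping(
        block.get("anchor", {"viscosity_pa_s": 2.0, "wis_pct": 12.0, "shear_rate_per_s": 50.0}),
        "rheology.anchor",
    )
    _reject_unknown(anchor, _ANCHOR_KEYS, "rheology.anchor")
    n_pl = _number(block.get("n_pl", 0.5), "rheology.n_pl")
    k_s = _number(block.get("k_s", 11.5), "rheology.k_s")
    a = block.get("a")
    b = block.get("b")
    try:
        if a is None and b is None and not block.get("anchor"):
            # nothing pinned by the user: use the package-calibrated default
            model = default_rheology()
            return RheologyModel(a=model.a, b=model.b, n_pl=model.n_pl, k_s=k_s)
        if b is None:
            raise ConfigError("rheology: 'b' is required when 'a' or 'anchor' is given")
        b = _number(b, "rheology.b")
        if a is None:
            return calibrate_rheology(
                _number(anchor.get("viscosity_pa_s", 2.0), "rheology.anchor.viscosity_pa_s"),
                _number(anchor.get("wis_pct", 12.0), "rheology.anchor.wis_pct"),
                _number(anchor.get("shear_rate_per_s", 50.0), "rheology.anchor.shear_rate_per_s"),
                b=b,
                n_pl=n_pl,
                k_s=k_s,
            )
        return RheologyModel(a=_number(a, "rheology.a"), b=b, n_pl=n_pl, k_s=k_s)
    except InvalidInputError as exc:
        raise ConfigError(f"rheology: {exc}") from exc


# ---------------------------------------------------------------------------
# CSV surfaces

CONVERSION_COLUMNS = ["time_h", "conversion", "glucose_g_L"]
POWER_COLUMNS = ["rpm", "motor_power_loaded_W", "motor_power_air_W"]


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"file not found: {path}")
    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    return df


def _check_numeric(df: pd.DataFrame, columns, path) -> pd.DataFrame:
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise InvalidInputError(
                f"{path}: non-numeric value {df.loc[bad[0], col]!r} in column '{col}', row {bad[0]}"
            )
        df[col] = coerced
    if df[columns].isna().any().any():
        raise InvalidInputError(f"{path}: missing values are not allowed")
    return df


def read_timeseries_csv(path) -> pd.DataFrame:
    """Read a conversion time series or a power-measurement table.

    Dispatches on the header: a ``time_h`` column marks a time series
    (sorted by time, duplicate times rejected); ``re, p0`` marks direct
    power-number observations; otherwise the motor-power table columns
    ``rpm, motor_power_loaded_W, motor_power_air_W`` are required.
    """
    df = _read_csv(path)
    if {"re", "p0"} <= set(df.columns):
        return _check_numeric(df, ["re", "p0"], path)
    if "time_h" in df.columns:
        # narrow tables must be conversion fixtures; wide ones (trajectory
        # exports and the like) are validated generically
        if len(df.columns) <= len(CONVERSION_COLUMNS):
            missing = [c for c in CONVERSION_COLUMNS if c not in df.columns]
            if missing:
                raise InvalidInputError(f"{path}: missing column(s) {missing}")
        df = _check_numeric(df, list(df.columns), path)
        df = df.sort_values("time_h", kind="stable").reset_index(drop=True)
        dup = df["time_h"].duplicated()
        if dup.any():
            raise InvalidInputError(
                f"{path}: duplicate time {df.loc[dup.idxmax(), 'time_h']} h in column 'time_h'"
            )
        return df
    missing = [c for c in POWER_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing column(s) {missing}")
    return _check_numeric(df, POWER_COLUMNS, path)


def metadata_header(cfg_hash: str, seed: int) -> str:
    return f"# hydromix v{__version__} config_hash={cfg_hash} seed={seed}\n"


def write_csv(df: pd.DataFrame, path, cfg_hash: str = "-", seed: int = 0) -> Path:
    """Write a dataframe with the standard metadata comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(metadata_header(cfg_hash, seed))
        df.to_csv(fh, index=False, float_format="%.12g")
    return path


def write_json(obj: dict, path, cfg_hash: str = "-", seed: int = 0) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"meta": {"tool": f"hydromix v{__version__}", "config_hash": cfg_hash, "seed": seed}}
    payload.update(obj)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path


def write_report(results: dict, out_dir, cfg_hash: str = "-", seed: int = 0) -> list[Path]:
    """Write a deterministic file set for a completed run.

    ``results`` maps file stems to pandas DataFrames (written as CSV) or
    plain dicts (written as JSON).  Identical inputs yield byte-identical
    files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for stem in sorted(results):
        obj = results[stem]
        if isinstance(obj, pd.DataFrame):
            written.append(write_csv(obj, out_dir / f"{stem}.csv", cfg_hash, seed))
        elif isinstance(obj, dict):
            written.append(write_json(obj, out_dir / f"{stem}.json", cfg_hash, seed))
        else:
            raise InvalidInputError(f"unsupported result type for '{stem}': {type(obj).__name__}")
    return written
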