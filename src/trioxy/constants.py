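"""Physical constants and default parameter values for the CO2 Δ17O budget.

Every entry carries its value, units, an uncertainty where one is adopted,
and the *semantics* of that uncertainty: ``standard_error`` (error of a
sample mean, the kind the steady-state budget propagates),
``standard_deviation`` (spread of single measurements), ``range`` (hard
bounds sampled uniformly in the Monte Carlo), or ``fixed`` (no uncertainty
assigned).  Configuration files (YAML or JSON) may override any entry;
see :func:`load_config`.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Any

import yaml

ERROR_TYPES = {"standard_error", "standard_deviation", "range", "fixed"}

PERMIL = 1e-3

# Three-isotope exponents (dimensionless slopes in ln(1+d17) vs ln(1+d18))
LAMBDA_REFERENCE = 0.516        # transpiration slope at 75% RH; the reporting convention
LAMBDA_WATER_CO2 = 0.5229       # water-CO2 isotopic equilibration
LAMBDA_METEORIC = 0.528         # global meteoric water line
LAMBDA_DIFFUSION = 0.5185       # molecular diffusion of CO2 in air

#: Default parameter table. ``error`` is on the same scale as ``value``;
#: for ``range`` entries ``value`` holds (low, high).
DEFAULTS: dict[str, dict[str, Any]] = {
    "lambda_0": {"value": LAMBDA_REFERENCE, "units": "1", "error": None, "error_type": "fixed",
                 "note": "reporting convention; transpiration slope at RH=75%"},
    "lambda_water_co2": {"value": LAMBDA_WATER_CO2, "units": "1", "error": None, "error_type": "fixed"},
    "lambda_meteoric": {"value": LAMBDA_METEORIC, "units": "1", "error": None, "error_type": "fixed"},
    "lambda_trans": {"value": 0.516, "units": "1", "error": 0.004, "error_type": "standard_error",
                     "note": "at RH = 75 +/- 5%"},
    "lambda_diff": {"value": LAMBDA_DIFFUSION, "units": "1", "error": None, "error_type": "fixed"},
    "rh": {"value": 0.75, "units": "1", "error": 0.05, "error_type": "standard_error",
           "note": "globally averaged near-surface relative humidity"},
    # Sensitivity of leaf-water-equilibrated CO2 Delta-17O to relative humidity.
    # Two published figures exist; the smaller one describes the process, the
    # larger one is what enters the error budget.
    "rh_sensitivity": {"value": 0.015, "units": "permil per 0.05 RH", "error": None, "error_type": "fixed"},
    "rh_sensitivity_error_budget": {"value": 0.017, "units": "permil per 0.05 RH", "error": None,
                                    "error_type": "fixed"},
    "alpha18_15C": {"value": 1.043, "units": "1", "error": None, "error_type": "fixed",
                    "note": "18O water-CO2 equilibrium fractionation at 15 C (land)"},
    "alpha18_20C": {"value": 1.042, "units": "1", "error": None, "error_type": "fixed",
                    "note": "18O water-CO2 equilibrium fractionation at 20 C (ocean)"},
    # Water pools (logarithmic Delta-17O at lambda = 0.516)
    "cap17_meteoric_water": {"value": -0.046, "units": "permil", "error": 0.005,
                             "error_type": "standard_error",
                             "note": "0.032 +/- 0.003 permil at lambda = 0.528"},
    "cap17_ocean_water": {"value": 0.000, "units": "permil", "error": 0.001, "error_type": "standard_error"},
    "d18_meteoric_water": {"value": -6.5, "units": "permil", "error": None, "error_type": "fixed",
                           "note": "makes the printed (0.032@0.528, -0.046@0.516) pair consistent"},
    "d18_ocean_water": {"value": 0.42, "units": "permil", "error": None, "error_type": "fixed",
                        "note": "consistent with the printed (-0.005@0.528, 0.000@0.516) pair"},
    "cap17_anthropogenic": {"value": -0.21, "units": "permil", "error": 0.001, "error_type": "standard_error",
                            "note": "combustion CO2 inherits air-O2 Delta-17O; never recomputed"},
    # Linear-convention endmembers (lambda = 0.516) used directly by the budget
    "d_leaf": {"value": -0.009, "units": "permil", "error": 0.006, "error_type": "standard_error"},
    "d_respiration": {"value": 0.019, "units": "permil", "error": 0.006, "error_type": "standard_error"},
    "d_soil": {"value": 0.019, "units": "permil", "error": 0.006, "error_type": "standard_error"},
    "d_ocean": {"value": 0.075, "units": "permil", "error": 0.001, "error_type": "standard_error"},
    "d_anthropogenic": {"value": -0.286, "units": "permil", "error": 0.001, "error_type": "standard_error"},
    # delta-18O values assumed per CO2 pool for log<->linear conversion
    # (reverse-engineered so the printed linear constants are reproduced)
    "d18_leaf_co2": {"value": 46.2, "units": "permil", "error": None, "error_type": "fixed"},
    "d18_soil_co2": {"value": 43.6, "units": "permil", "error": None, "error_type": "fixed"},
    "d18_ocean_co2": {"value": 42.0, "units": "permil", "error": None, "error_type": "fixed"},
    "d18_anthropogenic_co2": {"value": 24.5, "units": "permil", "error": None, "error_type": "fixed"},
    # Troposphere
    "cap_a": {"value": 0.326, "units": "permil", "error": 0.005, "error_type": "standard_error",
              "note": "four-site mean Delta-17O of tropospheric CO2; single-site sd 0.039"},
    "cap_a_sd": {"value": 0.039, "units": "permil", "error": None, "error_type": "fixed",
                 "note": "single-measurement spread of Delta-17O"},
    "d18_a": {"value": 41.0, "units": "permil", "error": None, "error_type": "fixed",
              "note": "tropospheric CO2 d18O used for the log->linear conversion"},
    # Fluxes
    "f_ao": {"value": 90.0, "units": "PgC/yr", "error": 6.0, "error_type": "standard_error",
             "note": "air->ocean gross flux (= ocean->air at steady state)"},
    "f_anth": {"value": 9.4, "units": "PgC/yr", "error": 0.8, "error_type": "standard_error"},
    "strat_isoflux": {"value": 50.0, "units": "permil PgC/yr", "error": 3.0, "error_type": "standard_error",
                      "note": "F_st x (D_st - D_a), taken as a given input"},
    "m_atm": {"value": 828.0, "units": "PgC", "error": 10.0, "error_type": "standard_error",
              "note": "atmospheric CO2 mass loading"},
    "nep": {"value": 10.0, "units": "PgC/yr", "error": None, "error_type": "fixed"},
    # Kinetic fractionations (18O) and their unknown exponents
    "eps_leaf": {"value": -7.4, "units": "permil", "error": None, "error_type": "fixed"},
    "eps_soil": {"value": -7.2, "units": "permil", "error": None, "error_type": "fixed"},
    "eps_ocean": {"value": 0.8, "units": "permil", "error": None, "error_type": "fixed"},
    "lambda_kinetic_range": {"value": (0.50, 0.53), "units": "1", "error": None, "error_type": "range"},
    # Plant-uptake scenario parameters
    "kappa_c": {"value": (1.33, 2.97), "units": "1", "error": None, "error_type": "range",
                "note": "stomatal conductance measure Cc/(Ca-Cc); 2.93 also quoted once"},
    "theta_eq": {"value": (0.70, 0.78), "units": "1", "error": None, "error_type": "range",
                 "note": "degree of CO2 hydration in stomata"},
    "leaf_respiration_factor": {"value": 0.88, "units": "1", "error": None, "error_type": "fixed"},
    "uptake_ratio": {"value": (2, 1, 1), "units": "1", "error": None, "error_type": "fixed",
                     "note": "F_la : F_r : F_s partition of the terrestrial flux"},
}


def default_config() -> dict[str, dict[str, Any]]:
    """A deep copy of the default parameter table."""
    return copy.deepcopy(DEFAULTS)


def value(config: dict | None, key: str) -> Any:
    """Look up a constant's value in ``config`` (falling back to defaults)."""
    cfg = config if config is not None else DEFAULTS
    return cfg[key]["value"]


def error(config: dict | None, key: str) -> Any:
    cfg = config if config is not None else DEFAULTS
    return cfg[key]["error"]


class ConfigError(ValueError):
    """Raised when a configuration file is missing keys or malformed."""


def validate_config(config: dict) -> None:
    """Check that every entry carries a value, units and a known error type."""
    missing = sorted(set(DEFAULTS) - set(config))
    if missing:
        raise ConfigError(f"configuration missing keys: {missing}")
    for key, entry in config.items():
        if not isinstance(entry, dict) or "value" not in entry:
            raise ConfigError(f"entry {key!r} must be a mapping with a 'value'")
        if "units" not in entry:
            raise ConfigError(f"entry {key!r} missing 'units'")
        if entry.get("error_type") not in ERROR_TYPES:
            raise ConfigError(
                f"entry {key!r} has error_type {entry.get('error_type')!r}; "
                f"expected one of {sorted(ERROR_TYPES)}")


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML/JSON constants file, overlaying the defaults.

    The file may supply a subset of keys; each supplied entry may itself be
    partial (e.g. only ``value``) and is merged into the default entry.
    """
    config = default_config()
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        for key, entry in data.items():
            if key not in config:
                raise ConfigError(f"{path}: unknown constant {key!r}")
            if isinstance(entry, dict):
                merged = dict(config[key])
                merged.update(entry)
                if isinstance(merged.get("value"), list):
                    merged["value"] = tuple(merged["value"])
                config[key] = merged
            else:
                config[key]["value"] = entry
    validate_config(config)
    return config


def save_config(config: dict, path: str | Path) -> None:
    """Write a constants table to YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    serializable = {
        k: {kk: (list(vv) if isinstance(vv, tuple) else vv) for kk, vv in e.items()}
        for k, e in config.items()
    }
    if path.suffix == ".json":
        path.write_text(json.dumps(serializable, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(serializable, sort_keys=True))


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration, for output provenance headers."""
    canon = json.dumps(
        {k: {kk: (list(vv) if isinstance(vv, tuple) else vv) for kk, vv in e.items()}
         for k, e in config.items()},
        sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
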