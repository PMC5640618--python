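"""Core triple-oxygen-isotope algebra.

All δ and Δ values are handled in per mil (‰) vs V-SMOW and converted to
absolute fractions only inside logarithms.  Two Δ17O conventions coexist:

* logarithmic: ``Δ17O = ln(1 + δ17O) − λ·ln(1 + δ18O)`` — the standard
  reporting form, insensitive to mass-dependent fractionation along slope λ;
* linear: ``Δ = δ17O − λ·δ18O`` — the form that is conserved under flux
  mixing and therefore the one the steady-state budget consumes.

The module provides both a typed scalar API (``DeltaPair``/``CapDelta``)
and array-friendly low-level functions (``cap17_log`` etc.) used by the
station-statistics and Monte Carlo layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import LAMBDA_REFERENCE, LAMBDA_WATER_CO2, PERMIL

__all__ = [
    "DeltaPair", "LambdaConvention", "CapDelta", "WaterPool",
    "cap17_log", "cap17_linear", "d17_from_cap_log", "log_to_linear_value",
    "linear_to_log_value", "rescale_lambda_value",
    "cap_delta_log", "cap_delta_linear", "log_to_linear", "linear_to_log",
    "rescale_lambda", "equilibrate_water_to_co2", "transpiration_shift",
    "transpiration_cap_shift",
]


def _check_delta(x, name: str = "delta") -> None:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {x!r}")
    if np.any(arr <= -1000.0):
        raise ValueError(f"{name} must exceed -1000 permil (physical bound), got {x!r}")


def _lam(lam) -> float:
    lam = lam.lam if isinstance(lam, LambdaConvention) else float(lam)
    if not 0.50 <= lam <= 0.53:
        raise ValueError(f"three-isotope exponent {lam} outside [0.50, 0.53]")
    return lam


@dataclass(frozen=True)
class DeltaPair:
    """A (δ17O, δ18O) pair in ‰ vs V-SMOW."""
    d17: float
    d18: float

    def __post_init__(self):
        _check_delta(self.d17, "d17")
        _check_delta(self.d18, "d18")


@dataclass(frozen=True)
class LambdaConvention:
    """A three-isotope exponent with a human-readable label."""
    lam: float
    label: str = ""

    def __post_init__(self):
        if not 0.50 <= self.lam <= 0.53:
            raise ValueError(f"lambda {self.lam} outside [0.50, 0.53]")


@dataclass(frozen=True)
class CapDelta:
    """A Δ17O value (‰) tagged with its λ convention and functional form."""
    value: float
    lam: float = LAMBDA_REFERENCE
    form: str = "logarithmic"

    def __post_init__(self):
        if self.form not in ("logarithmic", "linear"):
            raise ValueError(f"form must be 'logarithmic' or 'linear', got {self.form!r}")


@dataclass(frozen=True)
class WaterPool:
    """A water reservoir: its δ18O and logarithmic Δ17O."""
    name: str
    d18: float
    cap: CapDelta = field(default_factory=lambda: CapDelta(0.0))

    def __post_init__(self):
        _check_delta(self.d18, "d18")
        if self.cap.form != "logarithmic":
            raise ValueError("WaterPool.cap must be in the logarithmic form")


# ---------------------------------------------------------------------------
# low-level array-friendly functions (values in permil, lam a plain float)

def cap17_log(d17, d18, lam: float = LAMBDA_REFERENCE):
    """Logarithmic Δ17O (‰) of a δ pair."""
    _check_delta(d17, "d17"); _check_delta(d18, "d18")
    lam = _lam(lam)
    return (np.log1p(np.asarray(d17, float) * PERMIL)
            - lam * np.log1p(np.asarray(d18, float) * PERMIL)) / PERMIL


def cap17_linear(d17, d18, lam: float = LAMBDA_REFERENCE):
    """Linear Δ (‰) of a δ pair."""
    _check_delta(d17, "d17"); _check_delta(d18, "d18")
    return np.asarray(d17, float) - _lam(lam) * np.asarray(d18, float)


def d17_from_cap_log(cap, d18, lam: float = LAMBDA_REFERENCE):
    """Invert the logarithmic definition for δ17O (‰) given Δ17O and δ18O."""
    _check_delta(d18, "d18")
    lam = _lam(lam)
    return np.expm1(np.asarray(cap, float) * PERMIL
                    + lam * np.log1p(np.asarray(d18, float) * PERMIL)) / PERMIL


def log_to_linear_value(cap, d18, lam: float = LAMBDA_REFERENCE):
    """Convert a logarithmic Δ17O (‰) to the linear Δ at the same λ and δ18O."""
    d17 = d17_from_cap_log(cap, d18, lam)
    return d17 - _lam(lam) * np.asarray(d18, float)


def linear_to_log_value(cap, d18, lam: float = LAMBDA_REFERENCE):
    """Convert a linear Δ (‰) to the logarithmic Δ17O at the same λ and δ18O."""
    _check_delta(d18, "d18")
    lam = _lam(lam)
    d17 = np.asarray(cap, float) + lam * np.asarray(d18, float)
    return (np.log1p(d17 * PERMIL) - lam * np.log1p(np.asarray(d18, float) * PERMIL)) / PERMIL


def rescale_lambda_value(cap, lam_from: float, lam_to: float, d18):
    """Re-express a logarithmic Δ17O (‰) under a different λ.

    Exact algebraic identity: Δ17O(λ2) = Δ17O(λ1) + (λ1 − λ2)·ln(1 + δ18O).
    """
    _check_delta(d18, "d18")
    lam_from, lam_to = _lam(lam_from), _lam(lam_to)
    return (np.asarray(cap, float)
            + (lam_from - lam_to) * np.log1p(np.asarray(d18, float) * PERMIL) / PERMIL)


# ---------------------------------------------------------------------------
# typed scalar operations

def cap_delta_log(pair: DeltaPair, lam=LAMBDA_REFERENCE) -> CapDelta:
    """Δ17O in the logarithmic convention."""
    lam = _lam(lam)
    return CapDelta(float(cap17_log(pair.d17, pair.d18, lam)), lam, "logarithmic")


def cap_delta_linear(pair: DeltaPair, lam=LAMBDA_REFERENCE) -> CapDelta:
    """Δ in the linear convention (the mass-conserving form)."""
    lam = _lam(lam)
    return CapDelta(float(cap17_linear(pair.d17, pair.d18, lam)), lam, "linear")


def log_to_linear(cap: CapDelta, d18: float) -> CapDelta:
    """Bridge the two conventions at fixed λ, given the pool's δ18O."""
    if cap.form != "logarithmic":
        raise ValueError("log_to_linear expects a logarithmic CapDelta")
    if d18 is None:
        raise ValueError("d18 of the pool is required")
    return CapDelta(float(log_to_linear_value(cap.value, d18, cap.lam)), cap.lam, "linear")


def linear_to_log(cap: CapDelta, d18: float) -> CapDelta:
    if cap.form != "linear":
        raise ValueError("linear_to_log expects a linear CapDelta")
    if d18 is None:
        raise ValueError("d18 of the pool is required")
    return CapDelta(float(linear_to_log_value(cap.value, d18, cap.lam)), cap.lam, "logarithmic")


def rescale_lambda(cap: CapDelta, lam_to, d18: float) -> CapDelta:
    """Re-express a logarithmic Δ17O under another λ convention."""
    if cap.form != "logarithmic":
        raise ValueError("rescale_lambda operates on logarithmic values")
    if d18 is None:
        raise ValueError("d18 of the pool is required")
    lam_to = _lam(lam_to)
    return CapDelta(float(rescale_lambda_value(cap.value, cap.lam, lam_to, d18)),
                    lam_to, "logarithmic")


def equilibrate_water_to_co2(water: WaterPool, alpha18: float,
                             lam_ref: float = LAMBDA_REFERENCE,
                             lam_eq: float = LAMBDA_WATER_CO2) -> tuple[CapDelta, float]:
    """Δ17O of CO2 equilibrated with a water pool.

    Water–CO2 oxygen exchange follows the equilibration slope λ_eq = 0.5229,
    so in the λ_ref convention the CO2 anomaly is displaced from the water's:

        Δ17O(CO2) = (λ_eq − λ_ref)·ln(α18) + Δ17O(water)

    Returns the CO2 CapDelta (logarithmic, λ_ref) and the CO2 δ18O implied
    by the fractionation factor, δ18O(CO2) = α18·(1 + δ18O(water)) − 1.
    """
    if alpha18 <= 0:
        raise ValueError(f"alpha18 must be positive, got {alpha18}")
    lam_ref = _lam(lam_ref)
    cap = (lam_eq - lam_ref) * np.log(alpha18) / PERMIL + water.cap.value
    d18_co2 = (alpha18 * (1.0 + water.d18 * PERMIL) - 1.0) / PERMIL
    return CapDelta(float(cap), lam_ref, "logarithmic"), float(d18_co2)


def transpiration_cap_shift(rh: float, sensitivity: float = 0.015,
                            signed: bool = True) -> float:
    """Δ17O shift (‰) of leaf-water-equilibrated CO2 away from RH = 75%.

    Linearized: |shift| = ``sensitivity`` ‰ per 0.05 deviation in relative
    humidity.  Only the magnitude is physically constrained; the sign
    convention (positive above 75% RH) is a documented choice and the shift
    is normally used symmetrically, as an uncertainty term.
    """
    if not 0.0 < rh <= 1.0:
        raise ValueError(f"relative humidity {rh} outside (0, 1]")
    shift = sensitivity * (rh - 0.75) / 0.05
    return shift if signed else abs(shift)


def transpiration_shift(water: WaterPool, rh: float, sensitivity: float = 0.015,
                        signed: bool = True) -> CapDelta:
    """Apply the transpiration relative-humidity shift to a water pool."""
    shift = transpiration_cap_shift(rh, sensitivity, signed)
    return replace(water.cap, value=water.cap.value + shift)
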