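"""Steady-state Δ isoflux budget of tropospheric CO2.

At steady state the isofluxes (flux × linear-Δ difference from the
atmosphere) from the terrestrial biosphere, ocean, anthropogenic emissions
and the stratosphere sum to zero:

    F_land·(Δ_land − Δ_a) + F_ao·(Δ_o − Δ_a) + F_anth·(Δ_anth − Δ_a)
        + F_st·(Δ_st − Δ_a) = 0,

where Δ_land = (Δ_l + Δ_s)/2 under the 2:1:1 leaf:respiration:soil split of
the terrestrial flux and the stratospheric isoflux F_st·(Δ_st − Δ_a) is an
external input.  Solving for the one unknown gives the terrestrial cycling
flux F_land, and the oxygen-isotope residence time follows as
τ = M / (F_land + F_ao).

The budget is solved in the *linear* Δ convention, which is conserved
under mixing; a diagnostic mode re-runs it with the logarithmic Δ17O to
quantify the bias that convention would introduce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import constants as C
from .endmembers import EndmemberSet, build_default_endmembers, land_composite
from .iso_algebra import log_to_linear_value

__all__ = [
    "BudgetInputs", "BudgetSolution", "KineticTerms",
    "DegenerateBudgetError", "NonPhysicalFluxError",
    "solve_f_land", "solve_f_land_vectorized", "isoflux_decomposition",
    "budget_curves", "kinetic_bound", "invert_for_cap_a",
]


class DegenerateBudgetError(ValueError):
    """Atmospheric Δ does not exceed the land composite: no physical solution."""


class NonPhysicalFluxError(ValueError):
    """The solved terrestrial flux is negative: inconsistent inputs."""


@dataclass(frozen=True)
class BudgetInputs:
    """Inputs of the steady-state budget (defaults: the headline analysis)."""
    cap_a_log: float = 0.326        # tropospheric Delta-17O, permil (logarithmic)
    d18_a: float = 41.0             # tropospheric CO2 d18O, permil, for the conversion
    f_ao: float = 90.0              # air-ocean gross flux, PgC/yr
    f_anth: float = 9.4             # anthropogenic flux, PgC/yr
    strat_isoflux: float = 50.0     # F_st x (D_st - D_a), permil PgC/yr
    m_atm: float = 828.0            # atmospheric CO2 mass, PgC
    endmembers: EndmemberSet = field(default_factory=build_default_endmembers)
    uptake_ratio: tuple = (2, 1, 1)  # F_la : F_r : F_s

    def __post_init__(self):
        if self.f_ao < 0 or self.f_anth < 0 or self.strat_isoflux < 0:
            raise ValueError("fluxes and the stratospheric isoflux must be >= 0")
        if self.m_atm <= 0:
            raise ValueError("atmospheric mass must be positive")

    @property
    def cap_a_linear(self) -> float:
        """Linear Δ of tropospheric CO2 implied by (cap_a_log, d18_a)."""
        return float(log_to_linear_value(self.cap_a_log, self.d18_a))

    @classmethod
    def from_config(cls, config: dict, **overrides) -> "BudgetInputs":
        kwargs = dict(
            cap_a_log=C.value(config, "cap_a"), d18_a=C.value(config, "d18_a"),
            f_ao=C.value(config, "f_ao"), f_anth=C.value(config, "f_anth"),
            strat_isoflux=C.value(config, "strat_isoflux"), m_atm=C.value(config, "m_atm"),
            endmembers=build_default_endmembers(config),
            uptake_ratio=tuple(C.value(config, "uptake_ratio")))
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass(frozen=True)
class BudgetSolution:
    f_land: float               # terrestrial cycling flux, PgC/yr
    f_sur: float                # total surface flux F_land + F_ao, PgC/yr
    tau: float                  # oxygen-isotope residence time, yr
    f_la: float                 # leaf-to-air flux, PgC/yr
    f_r: float                  # respiration flux, PgC/yr
    f_s: float                  # soil invasion flux, PgC/yr
    isofluxes: dict             # per-source, permil PgC/yr; sums to 0
    cap_a_linear: float         # linear Delta-a actually used, permil
    convention: str             # "linear" (default) or "logarithmic" (diagnostic)
    inputs: BudgetInputs


def _budget_deltas(inputs: BudgetInputs, convention: str):
    ems = inputs.endmembers
    if convention == "linear":
        da = inputs.cap_a_linear
        dl, ds = ems.linear("leaf"), ems.linear("soil")
        do, danth = ems.linear("ocean"), ems.linear("anthropogenic")
    elif convention == "logarithmic":
        # Diagnostic mode only: the logarithmic form is not conserved under
        # mixing, so this quantifies the convention bias.
        da = inputs.cap_a_log
        dl, ds = ems.log("leaf"), ems.log("soil")
        do, danth = ems.log("ocean"), ems.log("anthropogenic")
    else:
        raise ValueError(f"convention must be 'linear' or 'logarithmic', got {convention!r}")
    return da, dl, ds, do, danth


def solve_f_land(inputs: BudgetInputs | None = None,
                 convention: str = "linear") -> BudgetSolution:
    """Solve the steady-state budget for the terrestrial flux.

    Closed form:
        F_land = [S + F_ao·(Δo − Δa) + F_anth·(Δanth − Δa)] / (Δa − (Δl + Δs)/2)

    Raises
    ------
    DegenerateBudgetError
        if Δa is not strictly above the land composite (denominator ≤ 0).
    NonPhysicalFluxError
        if the solved flux is negative (inconsistent inputs).
    """
    if inputs is None:
        inputs = BudgetInputs()
    da, dl, ds, do, danth = _budget_deltas(inputs, convention)
    land = 0.5 * (dl + ds)
    denom = da - land
    if denom <= 0:
        raise DegenerateBudgetError(
            f"atmospheric Delta ({da:.4f}) must exceed the land composite ({land:.4f})")
    numer = inputs.strat_isoflux + inputs.f_ao * (do - da) + inputs.f_anth * (danth - da)
    f_land = numer / denom
    if f_land < -1e-9:
        raise NonPhysicalFluxError(f"solved F_land = {f_land:.2f} PgC/yr is negative")
    f_land = max(f_land, 0.0)  # absorb float round-off at an exactly zero numerator

    rla, rr, rs = inputs.uptake_ratio
    total = rla + rr + rs
    f_la, f_r, f_s = (f_land * r / total for r in inputs.uptake_ratio)
    f_sur = f_land + inputs.f_ao
    isofluxes = {
        "terrestrial": f_land * (land - da),
        "oceanic": inputs.f_ao * (do - da),
        "anthropogenic": inputs.f_anth * (danth - da),
        "stratospheric": inputs.strat_isoflux,
    }
    return BudgetSolution(f_land=f_land, f_sur=f_sur, tau=inputs.m_atm / f_sur,
                          f_la=f_la, f_r=f_r, f_s=f_s, isofluxes=isofluxes,
                          cap_a_linear=da if convention == "linear" else inputs.cap_a_linear,
                          convention=convention, inputs=inputs)


def solve_f_land_vectorized(da, dl, ds, do, danth, f_ao, f_anth, strat):
    """Array closed form for F_land over draws of linear Δ values and fluxes.

    Degenerate or negative solutions come back as NaN (callers count them);
    no exceptions, so this is safe inside Monte Carlo loops.
    """
    da, dl, ds = np.asarray(da, float), np.asarray(dl, float), np.asarray(ds, float)
    denom = da - 0.5 * (dl + ds)
    numer = np.asarray(strat, float) + np.asarray(f_ao, float) * (do - da) \
        + np.asarray(f_anth, float) * (danth - da)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_land = np.where(denom > 0, numer / denom, np.nan)
    return np.where(f_land >= 0, f_land, np.nan)


def isoflux_decomposition(sol: BudgetSolution) -> pd.DataFrame:
    """Per-source isofluxes (‰·PgC/yr) at a solved budget; they sum to zero."""
    df = pd.DataFrame({"isoflux_permil_PgC_yr": sol.isofluxes})
    df.index.name = "source"
    total = df["isoflux_permil_PgC_yr"].sum()
    df.loc["sum"] = total
    return df


def budget_curves(inputs: BudgetInputs | None = None,
                  cap_a_grid=None, convention: str = "linear") -> pd.DataFrame:
    """Solve the budget along a grid of tropospheric Δ17O values.

    Grid rows that violate the budget preconditions are flagged in the
    ``degenerate`` column (with NaN outputs), never dropped silently.
    """
    if inputs is None:
        inputs = BudgetInputs()
    if cap_a_grid is None:
        cap_a_grid = np.arange(0.28, 0.421, 0.002)
    rows = []
    for cap in np.asarray(cap_a_grid, float):
        row = {"cap_a_log_permil": float(cap), "degenerate": False}
        try:
            sol = solve_f_land(replace(inputs, cap_a_log=float(cap)), convention)
            row.update(f_land_PgC_yr=sol.f_land, f_ocean_PgC_yr=inputs.f_ao,
                       tau_yr=sol.tau,
                       **{f"isoflux_{k}": v for k, v in sol.isofluxes.items()})
        except (DegenerateBudgetError, NonPhysicalFluxError):
            row["degenerate"] = True
            row.update(f_land_PgC_yr=math.nan, f_ocean_PgC_yr=inputs.f_ao, tau_yr=math.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def invert_for_cap_a(inputs: BudgetInputs, f_land: float) -> tuple[float, float]:
    """Linear and logarithmic atmospheric Δ implied by a given F_land.

    Forward companion of :func:`solve_f_land`, used for synthetic-recovery
    checks: the budget is linear in Δa, so the inversion is closed-form.
    """
    ems = inputs.endmembers
    land = land_composite(ems)
    numer = (inputs.strat_isoflux + inputs.f_ao * ems.linear("ocean")
             + inputs.f_anth * ems.linear("anthropogenic") + f_land * land)
    da_linear = numer / (f_land + inputs.f_ao + inputs.f_anth)
    from .iso_algebra import linear_to_log_value
    return float(da_linear), float(linear_to_log_value(da_linear, inputs.d18_a))


@dataclass(frozen=True)
class KineticTerms:
    """Inputs for bounding the kinetic (non-equilibrium) isoflux terms.

    The budget neglects (F_la − F_al)·ε_l·(λ_l − λ0) + F_r·ε_s·(λ_s − λ0)
    + F_ao·ε_o·(λ_o − λ0).  ε values are the 18O kinetic fractionations;
    the λ exponents of these pathways are unknown within [0.50, 0.53].
    The leaf flux here is the NET flux F_la − F_al.
    """
    f_leaf_net: float = 10.0
    f_resp: float = 90.0
    f_ao: float = 90.0
    eps_leaf: float = -7.4
    eps_soil: float = -7.2
    eps_ocean: float = 0.8
    lam_leaf: float = 0.529
    lam_soil: float = 0.529
    lam_ocean: float = 0.529
    lam_0: float = 0.516

    def __post_init__(self):
        for lam in (self.lam_leaf, self.lam_soil, self.lam_ocean):
            if not 0.50 <= lam <= 0.53:
                raise ValueError(f"kinetic lambda {lam} outside [0.50, 0.53]")


def kinetic_bound(kt: KineticTerms | None = None) -> dict[str, float]:
    """Each neglected kinetic isoflux term (‰·PgC/yr) and their total."""
    if kt is None:
        kt = KineticTerms()
    terms = {
        "leaf": kt.f_leaf_net * kt.eps_leaf * (kt.lam_leaf - kt.lam_0),
        "soil": kt.f_resp * kt.eps_soil * (kt.lam_soil - kt.lam_0),
        "ocean": kt.f_ao * kt.eps_ocean * (kt.lam_ocean - kt.lam_0),
    }
    terms["total"] = sum(terms.values())
    return terms
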