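"""Sensitivity scans of the budget and GPP inversion.

Four one-dimensional scans, each re-solving the relevant stage along a
grid with everything else frozen at the defaults:

* ocean-flux partition (F_ao grid → F_land/F_sur, τ),
* stratospheric isoflux,
* soil invasion at fixed F_land (two uptake-scenario curves),
* southern-hemisphere Δ17O under simple two-hemisphere averaging.

Every scan's baseline row reproduces the headline solution exactly, and
scans are pure functions of their inputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from .gpp_inversion import UptakeScenario, gpp_given_fs
from .steady_budget import (BudgetInputs, DegenerateBudgetError,
                            NonPhysicalFluxError, solve_f_land)

__all__ = ["scan_ocean_partition", "scan_strat_isoflux", "scan_soil_invasion",
           "scan_sh_delta", "SouthernHemisphereCaveat"]


class SouthernHemisphereCaveat(UserWarning):
    """Sign caveat of the southern-hemisphere Δ17O scan (see scan_sh_delta)."""


def _scan_budget(inputs: BudgetInputs, field: str, grid) -> pd.DataFrame:
    baseline = solve_f_land(inputs)
    rows = []
    for v in np.asarray(grid, float):
        row = {field: float(v), "degenerate": False}
        try:
            sol = solve_f_land(replace(inputs, **{field: float(v)}))
            row.update(f_land_PgC_yr=sol.f_land, f_sur_PgC_yr=sol.f_sur,
                       land_fraction=sol.f_land / sol.f_sur, tau_yr=sol.tau,
                       delta_tau_yr=sol.tau - baseline.tau)
        except (DegenerateBudgetError, NonPhysicalFluxError):
            row.update(degenerate=True, f_land_PgC_yr=math.nan,
                       f_sur_PgC_yr=math.nan, land_fraction=math.nan,
                       tau_yr=math.nan, delta_tau_yr=math.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def scan_ocean_partition(inputs: BudgetInputs | None = None,
                         f_ao_grid=None) -> pd.DataFrame:
    """Re-solve the budget over a grid of ocean fluxes.

    Reports the land/surface partition F_land/F_sur and the residence-time
    change relative to the default ocean flux.  The ocean isoflux is small,
    so τ responds weakly: ±50% in F_ao moves τ by only ~0.1 yr.
    """
    if inputs is None:
        inputs = BudgetInputs()
    if f_ao_grid is None:
        f_ao_grid = np.arange(45.0, 136.0, 5.0)
    return _scan_budget(inputs, "f_ao", f_ao_grid)


def scan_strat_isoflux(inputs: BudgetInputs | None = None,
                       strat_grid=None) -> pd.DataFrame:
    """Re-solve the budget over a grid of stratospheric isofluxes.

    τ is more sensitive here: a 10% change in the stratospheric isoflux
    moves the residence time by ~0.2 yr (computed ≈0.17 at the defaults).
    """
    if inputs is None:
        inputs = BudgetInputs()
    if strat_grid is None:
        strat_grid = np.arange(40.0, 61.0, 1.0)
    return _scan_budget(inputs, "strat_isoflux", strat_grid)


def scan_soil_invasion(f_land: float = 345.0,
                       fs_grid=None,
                       scenarios: tuple[UptakeScenario, ...] = (
                           UptakeScenario(kappa_c=1.33, theta_eq=0.78),
                           UptakeScenario(kappa_c=2.97, theta_eq=0.70),
                       )) -> pd.DataFrame:
    """GPP as a function of prescribed soil invasion at fixed F_land.

    One curve per uptake scenario; across the scenario pair and the full
    0 ≤ F_s ≤ F_land range, GPP spans roughly 0–200 PgC/yr.
    """
    if fs_grid is None:
        fs_grid = np.arange(0.0, f_land + 1e-9, 5.0)
    rows = []
    for sc in scenarios:
        for fs in np.asarray(fs_grid, float):
            rows.append({"f_s_PgC_yr": float(fs), "kappa_c": sc.kappa_c,
                         "theta_eq": sc.theta_eq,
                         "gpp_PgC_yr": gpp_given_fs(f_land, float(fs), sc)})
    return pd.DataFrame(rows)


def scan_sh_delta(inputs: BudgetInputs | None = None,
                  sh_grid=None,
                  sc: UptakeScenario | None = None,
                  f_s: float = 110.0) -> pd.DataFrame:
    """Budget and GPP as a function of southern-hemisphere Δ17O.

    The measured Δ17O comes from northern-hemisphere sites; here the global
    atmospheric value is taken as the arithmetic two-hemisphere mean before
    the standard inversion (no interhemispheric transport model).  GPP uses
    the frozen scenario (κ_c = 1.33, θ_eq = 0.78) with prescribed soil
    invasion.

    Caveat (flagged per row and warned once): under this straightforward
    averaging recipe a *higher* SH Δ17O at fixed stratospheric isoflux
    *lowers* the solved terrestrial flux and hence GPP.  Published
    statements of the opposite sign rest on a mechanism not specified here;
    this scan reports only what the averaging model computes.
    """
    if inputs is None:
        inputs = BudgetInputs()
    if sc is None:
        sc = UptakeScenario(kappa_c=1.33, theta_eq=0.78)
    nh = inputs.cap_a_log
    if sh_grid is None:
        sh_grid = np.arange(nh - 0.02, nh + 0.0201, 0.005)
    warnings.warn(
        "southern-hemisphere scan uses simple two-hemisphere averaging; the "
        "sign of the GPP response differs from published sensitivity "
        "statements (see docs/methods.md)", SouthernHemisphereCaveat,
        stacklevel=2)
    rows = []
    for sh in np.asarray(sh_grid, float):
        global_cap = 0.5 * (nh + float(sh))
        row = {"sh_cap17_permil": float(sh), "global_cap17_permil": global_cap,
               "degenerate": False, "averaging_caveat": True}
        try:
            sol = solve_f_land(replace(inputs, cap_a_log=global_cap))
            fs_row = min(f_s, sol.f_land)
            row.update(f_land_PgC_yr=sol.f_land, tau_yr=sol.tau,
                       gpp_PgC_yr=gpp_given_fs(sol.f_land, fs_row, sc))
        except (DegenerateBudgetError, NonPhysicalFluxError):
            row.update(degenerate=True, f_land_PgC_yr=math.nan,
                       tau_yr=math.nan, gpp_PgC_yr=math.nan)
        rows.append(row)
    return pd.DataFrame(rows)
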