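"""End-to-end pipeline: stations → budget → GPP → Monte Carlo → sensitivity.

``run_pipeline`` composes all stages into one machine-readable report with
the seed and a configuration hash embedded for provenance.  Each stage
failure aborts with the stage name attached.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import constants as C
from .endmembers import build_default_endmembers
from .gpp_inversion import UptakeScenario, solve_gpp
from .sensitivity import scan_ocean_partition, scan_strat_isoflux
from .station_stats import site_summary, multi_site_average, read_measurements
from .steady_budget import BudgetInputs, solve_f_land
from .synthetic_data import generate_four_site_suite
from .uncertainty_mc import MCConfig, propagate_f_land_se, run_monte_carlo

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("trioxy")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                log.info("stage %s", name)
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(name, exc) from exc
        return wrapper
    return deco


@_stage("stations")
def _stations_stage(config, seed, measurement_paths):
    if measurement_paths:
        tables = {Path(p).stem: read_measurements(p) for p in measurement_paths}
    else:
        tables = generate_four_site_suite(seed=seed)
    summaries = {name: site_summary(df) for name, df in tables.items()}
    cap_mean, cap_se = multi_site_average(
        [s.stats.loc["D17O_permil", "mean"] for s in summaries.values()])
    return tables, summaries, cap_mean, cap_se


@_stage("budget")
def _budget_stage(config, cap_mean):
    inputs = BudgetInputs.from_config(config, cap_a_log=cap_mean)
    sol = solve_f_land(inputs)
    prop = propagate_f_land_se(inputs)
    return inputs, sol, prop


@_stage("gpp")
def _gpp_stage(config, f_land):
    kappa_lo, _ = C.value(config, "kappa_c")
    _, theta_hi = C.value(config, "theta_eq")
    sc = UptakeScenario(kappa_c=kappa_lo, theta_eq=theta_hi,
                        nep=C.value(config, "nep"),
                        leaf_respiration_factor=C.value(config, "leaf_respiration_factor"))
    return solve_gpp(f_land, sc)


@_stage("montecarlo")
def _mc_stage(config, seed, f_land, f_land_se, inputs, n_draws):
    sc = UptakeScenario(nep=C.value(config, "nep"),
                        leaf_respiration_factor=C.value(config, "leaf_respiration_factor"))
    return run_monte_carlo(MCConfig(n_draws=n_draws, seed=seed),
                           f_land_mean=f_land, f_land_se=f_land_se,
                           kappa_range=C.value(config, "kappa_c"),
                           theta_range=C.value(config, "theta_eq"),
                           sc=sc, inputs=inputs)


@_stage("sensitivity")
def _sensitivity_stage(inputs):
    ocean = scan_ocean_partition(inputs, f_ao_grid=[inputs.f_ao * 0.5, inputs.f_ao,
                                                    inputs.f_ao * 1.5])
    strat = scan_strat_isoflux(inputs, strat_grid=[inputs.strat_isoflux,
                                                   inputs.strat_isoflux * 1.1])
    return {
        "delta_tau_ocean_plus50pct_yr": float(ocean["delta_tau_yr"].iloc[-1]),
        "delta_tau_ocean_minus50pct_yr": float(ocean["delta_tau_yr"].iloc[0]),
        "delta_tau_strat_plus10pct_yr": float(strat["delta_tau_yr"].iloc[-1]),
    }


def run_pipeline(config: dict | None = None, seed: int = 0,
                 measurement_paths: list | None = None,
                 mc_draws: int = 125_000,
                 out: str | Path | None = None) -> dict:
    """Run the full analysis chain and return a JSON-serializable report.

    Without ``measurement_paths`` a synthetic four-site suite is generated
    (seeded).  The report embeds the seed and configuration hash.
    """
    config = config if config is not None else C.default_config()
    C.validate_config(config)

    tables, summaries, cap_mean, cap_se = _stations_stage(config, seed, measurement_paths)
    inputs, sol, prop = _budget_stage(config, cap_mean)
    gpp = _gpp_stage(config, sol.f_land)
    mc = _mc_stage(config, seed, sol.f_land, prop.se, inputs, mc_draws)
    sens = _sensitivity_stage(inputs)

    report = {
        "provenance": {"seed": seed, "config_hash": C.config_hash(config),
                       "package": "trioxy"},
        "stations": {
            name: {"n": s.n,
                   "mean_D17O_permil": float(s.stats.loc["D17O_permil", "mean"]),
                   "mean_d18O_permil": float(s.stats.loc["d18O_permil", "mean"]),
                   "rma_slope": s.regression.slope,
                   "rma_slope_se": s.regression.slope_se}
            for name, s in summaries.items()},
        "multi_site": {"cap_a_permil": cap_mean, "cap_a_se_permil": cap_se},
        "budget": {"f_land_PgC_yr": sol.f_land, "f_land_se_PgC_yr": prop.se,
                   "f_sur_PgC_yr": sol.f_sur, "tau_yr": sol.tau,
                   "cap_a_linear_permil": sol.cap_a_linear,
                   "isofluxes_permil_PgC_yr": {k: float(v)
                                               for k, v in sol.isofluxes.items()}},
        "gpp": {"gpp_PgC_yr": gpp.gpp, "f_s_PgC_yr": gpp.f_s,
                "kappa_c": gpp.scenario.kappa_c, "theta_eq": gpp.scenario.theta_eq,
                "nep_PgC_yr": gpp.scenario.nep},
        "monte_carlo": {"n_draws": mc.n_draws, "n_rejected": mc.n_rejected,
                        "converged": mc.converged,
                        "summary": {q: {k: float(v) for k, v in row.items()}
                                    for q, row in mc.summary.iterrows()}},
        "sensitivity": sens,
    }
    if out is not None:
        Path(out).write_text(json.dumps(report, indent=2))
    return report
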