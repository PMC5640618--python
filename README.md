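# trioxy

Triple-oxygen-isotope (Δ17O) budget analysis of tropospheric CO2.

Atmospheric CO2 exchanges oxygen isotopes with leaf, soil and ocean water,
with stratospheric photochemistry and fossil-fuel combustion as the other
major controls. The triple-oxygen anomaly

    Δ17O = ln(1 + δ17O) − λ · ln(1 + δ18O),      λ = 0.516

(with δ values vs V-SMOW) is erased toward a low value by water exchange
and pushed up by the stratospheric influx, so the observed tropospheric
Δ17O fixes the gross CO2 cycling flux between the atmosphere and the
terrestrial biosphere. `trioxy` implements that analysis end to end, for
isotope biogeochemists and carbon-cycle modellers:

- **isotope algebra** (`iso_algebra`): Δ17O in the logarithmic and the
  mass-conserving linear convention Δ = δ17O − λ·δ18O, λ rescaling,
  water–CO2 equilibration, transpiration relative-humidity shifts;
- **source endmembers** (`endmembers`): terrestrial
  (≈0.244 ‰), oceanic (≈0.284 ‰) and anthropogenic (−0.21 ‰) CO2 pools in
  both conventions;
- **steady-state budget** (`steady_budget`): solves the isoflux balance

      F_land·(Δ_land − Δ_a) + F_ao·(Δ_o − Δ_a) + F_anth·(Δ_anth − Δ_a)
          + F_st·(Δ_st − Δ_a) = 0

  for the terrestrial flux F_land and the oxygen-isotope residence time
  τ = M/(F_land + F_ao), with isoflux decomposition, Δ17O sweeps and a
  bound on the neglected kinetic terms;
- **GPP inversion** (`gpp_inversion`): 0.88·GPP = (F_land − F_s)/(θ_eq·κ_c + 1)
  with GPP = NEP + F_s, giving gross primary productivity and soil invasion;
- **uncertainty** (`uncertainty_mc`): analytic σf² = Σ(∂f/∂xi)²σi²
  propagation with contribution tables, plus a seeded Monte Carlo over the
  uptake-scenario space (κ_c ~ U(1.33, 2.97), θ_eq ~ U(0.70, 0.78));
- **sensitivity scans** (`sensitivity`), **station statistics**
  (`station_stats`: site summaries, unweighted multi-site averaging,
  reduced-major-axis slope fits, λ rescaling) and a **synthetic station
  generator** (`synthetic_data`) emulating the four-site observation set
  (455 records).

## Worked example

```python
from trioxy import BudgetInputs, UptakeScenario, solve_f_land, solve_gpp

sol = solve_f_land(BudgetInputs())      # Δ17O_a = 0.326 ‰, F_ao = 90 PgC/yr, ...
res = solve_gpp(sol.f_land, UptakeScenario(kappa_c=1.33, theta_eq=0.78, nep=10.0))
print(sol.f_land, sol.tau, res.gpp, res.f_s)
```

Running `python examples/02_budget_and_gpp.py` prints:

```
terrestrial flux F_land = 339 PgC/yr (leaf 170 + respiration 85 + soil 85)
residence time tau = 1.93 yr (M = 828 PgC over F_sur = 429 PgC/yr)
...
GPP = 125.2 PgC/yr, soil invasion F_s = 115.2 PgC/yr
```

F_land ≈ 339 PgC/yr is the gross terrestrial cycling flux implied by the
observed anomaly (345 ± 70 at two significant figures once uncertainties
are attached); τ ≈ 1.9 yr is how long an oxygen atom in atmospheric CO2
survives before surface exchange resets it; GPP ≈ 130 and soil invasion
≈ 120 PgC/yr (two significant figures) partition that flux under the
standard uptake scenario. The other `examples/` scripts walk through the
isotope algebra, uncertainty budgets, synthetic stations and sensitivity
scans; a thin CLI (`trioxy budget`, `trioxy gpp`, `trioxy montecarlo`,
`trioxy simulate`, ...) wraps the same functions for shell use.

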