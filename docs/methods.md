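# Methods

## Model and assumptions

`trioxy` treats the troposphere as a single well-mixed CO2 reservoir at
steady state. Each surface process contributes an *isoflux*, the product of
a gross mass flux (PgC yr⁻¹) and the difference between the source's linear
oxygen anomaly Δ = δ17O − λ·δ18O and the atmosphere's. At steady state the
terrestrial, oceanic, anthropogenic and stratospheric isofluxes sum to
zero; the terrestrial flux F_land is the single unknown and is obtained in
closed form. The residence time is τ = M/(F_land + F_ao) with M the
atmospheric CO2 carbon mass.

Key assumptions, in decreasing order of consequence:

- **Linear convention for the budget.** The logarithmic Δ17O is the
  reporting convention, but only the linear Δ is conserved under flux
  mixing, so the budget is solved in linear Δ throughout. A diagnostic
  `convention="logarithmic"` mode exists solely to show the bias the wrong
  convention would introduce (it inflates F_land by well over 100 PgC yr⁻¹
  at the defaults); its output is reported, never asserted against any
  external figure.
- **λ = 0.516 reference.** Chosen because plant transpiration at the
  global-mean 75% relative humidity follows this slope, so transpiration
  drops out of the terrestrial endmember. The cost is an RH sensitivity:
  the anomaly of leaf-water-equilibrated CO2 moves by ~0.015 ‰ per 0.05 RH
  (0.017 ‰ per 0.05 in the error budget — both figures circulate; the
  package keeps them as separate named constants and uses the larger in
  propagation, which is the conservative choice).
- **2:1:1 flux partition.** F_land splits into leaf exchange, respiration
  and soil invasion as F_la ≈ 2F_r ≈ 2F_s, making the effective terrestrial
  endmember the mean of the leaf and soil linear values. The ratio is a
  configurable input.
- **Kinetic terms neglected.** The non-equilibrium terms
  (F_la−F_al)·ε_l·(λ_l−λ0) + F_r·ε_s·(λ_s−λ0) + F_ao·ε_o·(λ_o−λ0) are
  dropped; `kinetic_bound` reports them for any chosen net fluxes and λ
  values. With the leaf term taken on the *net* leaf flux (the reading the
  balance equation itself supports) each term stays below ~1 ‰ PgC yr⁻¹
  even at extreme λ = 0.529; for *gross* fluxes of several hundred
  PgC yr⁻¹ the bound would not hold, which is why the implementation
  exposes the fluxes explicitly rather than hard-coding a verdict.
- **Steady state, one box.** No seasonality, no time stepping, no
  latitude-resolved transport. The only interhemispheric construct is the
  two-hemisphere arithmetic average in the southern-hemisphere scan (below).

## Parameters

All defaults live in `trioxy.constants.DEFAULTS`, each with units and an
uncertainty *semantics* tag (`standard_error` for errors of sample means —
what the budget propagation consumes; `standard_deviation` for
single-measurement spreads; `range` for uniformly sampled scenario bounds;
`fixed`). The main ones:

| parameter | default | role |
|---|---|---|
| Δ17O_a | 0.326 ± 0.005 ‰ (se); 0.039 ‰ single-measurement sd | tropospheric anomaly (four-site mean) |
| δ18O_a | 41.0 ‰ | converts Δ17O_a to linear Δ_a; between the Taipei mean (40.65) and marine background (~41.5); all outputs carry the value used, and moving it across 40.65–41.5 shifts F_land by less than ±25 PgC yr⁻¹ |
| Δ17O_mw, Δ17O_ow | −0.046, 0.000 ‰ | water-pool anomalies at λ = 0.516; the meteoric δ18O default −6.5 ‰ is the value that makes the published (0.032 ‰ @ 0.528 / −0.046 ‰ @ 0.516) pair exactly consistent |
| α18(15 °C), α18(20 °C) | 1.043, 1.042 | water–CO2 18O equilibration on land and ocean; no temperature interpolation beyond these two values |
| linear endmembers Δ_l, Δ_r=Δ_s, Δ_o, Δ_anth | −0.009, 0.019, 0.075, −0.286 ‰ | published constants (default); a `computed` mode derives them from per-pool assumed δ18O (46.2/43.6/42.0/24.5 ‰, reverse-engineered to reproduce the constants and flagged as such). The soil value 0.019 ‰ is *not* derivable from mean meteoric water at 15 °C (that would give ≈0.09 ‰); the printed constant is used without guessing the discrepancy's origin |
| F_ao, F_anth | 90 ± 6, 9.4 ± 0.8 PgC yr⁻¹ | gross air–ocean and anthropogenic fluxes |
| F_st·(Δ_st − Δ_a) | 50 ± 3 ‰ PgC yr⁻¹ | stratospheric isoflux, taken as a given input (no photochemistry model) |
| M | 828 ± 10 PgC | atmospheric CO2 mass |
| κ_c, θ_eq | U(1.33, 2.97), U(0.70, 0.78) | uptake-scenario ranges (κ_c's upper bound is quoted once as 2.93 and twice as 2.97; 2.97 adopted); headline scenario κ_c = 1.33, θ_eq = 0.78 |
| NEP, leaf-respiration factor | 10 PgC yr⁻¹, 0.88 | close the GPP system via GPP = NEP + F_s and 0.88·GPP = F_al − F_la |

## Uncertainty machinery

`propagate_se` implements first-order propagation with central differences
(step 10⁻⁶ of each input's scale) and reports per-input variance shares.
For F_land at the default standard errors this gives ≈58 PgC yr⁻¹
(reference scale: the published ±70), dominated by the transpiration-RH
term (~67% of the variance, applied as a common shift of both terrestrial
endmembers) and the stratospheric isoflux (~18%); τ propagates to ±0.26 yr
(published: ±0.3). The published error shares (~30% transpiration, ~1/3
measurements, remainder stratospheric) are not exactly reproducible from
the printed inputs; the contribution table makes the package's own budget
transparent instead. In single-measurement mode only the Δ17O_a spread
(0.039 ‰) has a published value; the other inputs retain their
standard-error spreads, so the resulting ≈150 PgC yr⁻¹ is a lower bound on
the single-measurement error and no published single-measurement figure is
asserted.

The Monte Carlo draws (F_land, κ_c, θ_eq) and pushes them through the GPP
closed form. The default layout is 125 000 independent joint draws —
statistically equivalent for means and spreads to a 500³ per-variable
factorial, which is also available as an exact separable-moment
`factorial` mode; a `coupled` mode re-solves the budget per draw of Δ17O_a,
the endmembers and the fluxes instead of drawing F_land ~ N(345, 70)
directly. Draws with negative F_land or GPP are rejected and counted.
Convergence is checked by comparing half-sample to full-sample means within
two MC standard errors. One `numpy.random.default_rng` generator per run;
the seed is embedded in every output.

## Synthetic data

The generator emulates what the pipeline statistically consumes, not the
atmosphere: CO2 and δ13C come from two-endmember conservative mixing
(background −8.47 ‰; polluted endmember −28 ‰, a typical fossil/respired
value chosen here, not a published one), with the diurnal cycle represented
only through the mixing-fraction distribution; δ18O is Gaussian at the
site's observed mean/spread; δ17O sits on a three-isotope line of slope
0.518 with the intercept solved so the site-mean Δ17O hits its target, plus
instrument noise (0.05 ‰ on δ18O, 0.01 ‰ on Δ17O). Per-site sample counts
(210/85/120/40, totalling 455) and the non-Taipei δ18O means are
plausible choices — only the totals and Taipei's moments are published —
and all are configurable. What passing round-trip tests show is therefore
that the *estimators* (site summaries, RMA slope, multi-site mean, the
budget/GPP chain) recover the generating parameters at realistic noise;
they cannot validate transport, seasonality, or real between-site
structure, none of which the generator contains. The generated Δ17O
within-site spread (~0.01 ‰) is the instrument component only, smaller
than the observed ~0.04 ‰ spatiotemporal scatter; site *means*, which are
all the downstream chain uses, are unaffected.

## Numerical choices

- All δ/Δ algebra in double precision, values in ‰, converted to absolute
  fractions only inside logarithms (`log1p`/`expm1` for small-argument
  accuracy); no rounding until display.
- The budget solver is the exact closed form; a brute-force root search is
  used as an independent cross-check in the tests, not in the solver.
- Degenerate budgets (Δ_a at or below the land composite) raise a typed
  error; grid scans flag such rows instead of dropping them. A solved flux
  within −10⁻⁹ of zero is clamped to zero (float round-off at an exactly
  cancelling numerator); anything more negative raises.
- The transpiration shift is implemented signed (positive above 75% RH) for
  continuity, but is consumed symmetrically, as an uncertainty term.
- RMA (geometric-mean) regression: slope = sign(r)·sd(y)/sd(x), intercept
  through the means, slope se = |slope|·√((1−r²)/n); an OLS mode is
  provided alongside. The station outlier rule (δ18O < 38.5 ‰) applies to
  the slope fit only, never to the means.
- The multi-site mean is the unweighted mean of site means with se = sd/√n
  (n = number of sites); the "1-σ standard deviation of the range" phrase
  attached to published site spreads is interpreted as the ordinary sample
  standard deviation.

## Southern-hemisphere scan caveat

`scan_sh_delta` forms the global anomaly as the arithmetic mean of the
northern-hemisphere value and a scanned southern-hemisphere value, then
re-solves the standard budget. Under this recipe a higher SH Δ17O *raises*
the global anomaly and therefore *lowers* the solved F_land and GPP.
Published sensitivity statements for this scan have the opposite sign and
rest on a mechanism that is not specified; the scan therefore emits a
`SouthernHemisphereCaveat` warning, flags every row, and its published
values are not asserted anywhere in the test suite.

## Known limitations

- No time-dependent solution: seasonal amplitude (~0.05 ‰) and trend
  information are invisible to this model.
- The stratospheric isoflux is an opaque input; F_st and Δ_st are never
  separated.
- Linear endmembers rest on published constants whose underlying δ18O
  values are partly unstated (see the soil-value note above).
- The GPP inversion is a scalar stomatal budget: no canopy structure, no
  C3/C4 areal weighting beyond κ_c, no mechanistic soil-invasion model.
- Problem sizes used in the shipped tests and the reproduction script
  (125 000 Monte Carlo draws, 455-record synthetic stations, ~20-point
  scan grids) are the package's defaults and complete in seconds; all are
  parameters if larger runs are wanted.
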