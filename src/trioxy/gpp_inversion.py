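"""Gross primary productivity from the terrestrial cycling flux.

The isotopically visible leaf exchange relates to GPP through the stomatal
retro-diffusion budget

    0.88·GPP = F_al − F_la = (F_land − F_s) / (θ_eq·κ_c + 1),

where κ_c = C_c/(C_a − C_c) measures stomatal conductance, θ_eq the degree
of CO2 hydration (carbonic-anhydrase catalysed equilibration) inside
stomata, and 0.88 accounts for leaf respiration.  Closing the system with
GPP = NEP + F_r and the high-hydration assumption F_s = F_r gives the
closed form

    GPP = (F_land + NEP) / (0.88·(θ_eq·κ_c + 1) + 1),   F_s = GPP − NEP.

``gpp_given_fs`` decouples soil invasion for sensitivity scans.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["UptakeScenario", "GPPResult", "kappa_from_cc_ratio", "solve_gpp", "gpp_given_fs"]


@dataclass(frozen=True)
class UptakeScenario:
    """A plant-uptake scenario: (κ_c, θ_eq, NEP, leaf-respiration factor)."""
    kappa_c: float = 1.33
    theta_eq: float = 0.78
    nep: float = 10.0
    leaf_respiration_factor: float = 0.88

    def __post_init__(self):
        if self.kappa_c <= 0:
            raise ValueError(f"kappa_c must be positive, got {self.kappa_c}")
        if not 0 < self.theta_eq <= 1:
            raise ValueError(f"theta_eq {self.theta_eq} outside (0, 1]")
        if not 0 < self.leaf_respiration_factor <= 1:
            raise ValueError("leaf_respiration_factor must lie in (0, 1]")

    @property
    def retro_factor(self) -> float:
        """θ_eq·κ_c + 1: the retro-diffusion enhancement of leaf exchange."""
        return self.theta_eq * self.kappa_c + 1.0


@dataclass(frozen=True)
class GPPResult:
    gpp: float   # PgC/yr
    f_s: float   # soil invasion, PgC/yr
    f_r: float   # respiration, PgC/yr (= f_s under the F_s = F_r closure)
    scenario: UptakeScenario
    f_land: float


def kappa_from_cc_ratio(cc_over_ca: float) -> float:
    """Stomatal conductance measure κ_c = r/(1−r) from r = C_c/C_a.

    C_c is the chloroplast CO2 concentration at the hydration site, C_a the
    ambient one.  A global average r = 0.57 gives κ_c ≈ 1.33; C3 plants
    (r = 2/3) give 2.0 and C4 plants (r = 1/3) give 0.5.
    """
    if not 0.0 < cc_over_ca < 1.0:
        raise ValueError(f"Cc/Ca ratio must lie in (0, 1), got {cc_over_ca}")
    return cc_over_ca / (1.0 - cc_over_ca)


def solve_gpp(f_land: float, sc: UptakeScenario | None = None) -> GPPResult:
    """GPP and soil invasion under the F_s = F_r closure.

    Requires F_land ≥ NEP.  Near that limit the two constraints cannot both
    hold with a nonnegative soil invasion, so F_s is clamped at the
    degenerate edge F_s = 0 (the closed-form GPP is still returned).
    """
    if sc is None:
        sc = UptakeScenario()
    if f_land < sc.nep:
        raise ValueError(f"F_land ({f_land}) must be >= NEP ({sc.nep})")
    a = sc.leaf_respiration_factor
    gpp = (f_land + sc.nep) / (a * sc.retro_factor + 1.0)
    if gpp <= 0:
        raise ValueError(f"non-positive solution (GPP={gpp:.3f}): inconsistent scenario")
    f_s = max(gpp - sc.nep, 0.0)
    return GPPResult(gpp=gpp, f_s=f_s, f_r=f_s, scenario=sc, f_land=f_land)


def gpp_given_fs(f_land: float, f_s: float, sc: UptakeScenario | None = None) -> float:
    """GPP with soil invasion prescribed (decoupled from the F_s = F_r closure)."""
    if sc is None:
        sc = UptakeScenario()
    if not 0.0 <= f_s <= f_land:
        raise ValueError(f"soil invasion {f_s} outside [0, F_land={f_land}]")
    return (f_land - f_s) / (sc.leaf_respiration_factor * sc.retro_factor)
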