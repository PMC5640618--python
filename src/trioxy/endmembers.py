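"""CO2 source endmembers for the tropospheric Δ17O budget.

Each endmember (leaf, respiration, soil, ocean, anthropogenic) carries its
Δ17O in both conventions at λ = 0.516: the logarithmic value computed from
first principles (water pool + water–CO2 equilibration), and the linear
value the budget consumes.  Linear values default to the published
constants (Δl = −0.009, Δr = Δs = 0.019, Δo = 0.075, Δanth = −0.286 ‰)
because the δ18O values behind the terrestrial ones are not stated; a
``computed`` mode derives them from per-pool assumed δ18O instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import constants as C
from .iso_algebra import (CapDelta, WaterPool, equilibrate_water_to_co2,
                          log_to_linear_value)

__all__ = ["CO2Endmember", "EndmemberSet", "build_default_endmembers", "land_composite"]

_NAMES = ("leaf", "respiration", "soil", "ocean", "anthropogenic")


@dataclass(frozen=True)
class CO2Endmember:
    """One CO2 source pool's Δ17O in both conventions (λ = 0.516, ‰)."""
    name: str
    cap_log: float
    cap_linear: float
    d18_assumed: float | None = None
    provenance: str = "computed"  # computed | printed-constant | reverse-engineered


@dataclass
class EndmemberSet:
    members: dict[str, CO2Endmember] = field(default_factory=dict)

    def __getitem__(self, name: str) -> CO2Endmember:
        try:
            return self.members[name]
        except KeyError:
            raise KeyError(f"endmember {name!r} missing; have {sorted(self.members)}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.members

    def linear(self, name: str) -> float:
        return self[name].cap_linear

    def log(self, name: str) -> float:
        return self[name].cap_log

    def to_frame(self) -> pd.DataFrame:
        rows = [{"name": m.name, "cap17_log_permil": m.cap_log,
                 "cap_linear_permil": m.cap_linear, "d18_assumed_permil": m.d18_assumed,
                 "provenance": m.provenance} for m in self.members.values()]
        return pd.DataFrame(rows).set_index("name")

    def to_dict(self) -> dict:
        return {m.name: {"cap_log": m.cap_log, "cap_linear": m.cap_linear,
                         "d18_assumed": m.d18_assumed, "provenance": m.provenance}
                for m in self.members.values()}

    @classmethod
    def from_dict(cls, data: dict) -> "EndmemberSet":
        return cls({name: CO2Endmember(name=name, **entry) for name, entry in data.items()})


def build_default_endmembers(config: dict | None = None,
                             linear_mode: str = "printed") -> EndmemberSet:
    """Construct the default endmember set.

    Logarithmic Δ17O values are always computed from first principles:
    terrestrial pools from meteoric water equilibrated at 15 °C (≈0.244 ‰),
    the ocean pool from ocean water at 20 °C (≈0.284 ‰); the anthropogenic
    value is the configured air-O2 anomaly (−0.21 ‰) and is never recomputed.

    ``linear_mode='printed'`` (default) takes the linear Δ values as the
    published constants; ``'computed'`` converts each pool's logarithmic
    value using its assumed δ18O (reverse-engineered defaults).
    """
    if linear_mode not in ("printed", "computed"):
        raise ValueError(f"linear_mode must be 'printed' or 'computed', got {linear_mode!r}")
    cfg = config if config is not None else C.DEFAULTS
    for key in ("cap17_meteoric_water", "cap17_ocean_water", "cap17_anthropogenic",
                "alpha18_15C", "alpha18_20C"):
        if key not in cfg:
            raise C.ConfigError(f"configuration missing {key!r}")

    mw = WaterPool("meteoric", C.value(cfg, "d18_meteoric_water"),
                   CapDelta(C.value(cfg, "cap17_meteoric_water")))
    ow = WaterPool("ocean", C.value(cfg, "d18_ocean_water"),
                   CapDelta(C.value(cfg, "cap17_ocean_water")))
    land_cap, _ = equilibrate_water_to_co2(mw, C.value(cfg, "alpha18_15C"))
    ocean_cap, _ = equilibrate_water_to_co2(ow, C.value(cfg, "alpha18_20C"))
    anth_cap = C.value(cfg, "cap17_anthropogenic")

    log_values = {"leaf": land_cap.value, "respiration": land_cap.value,
                  "soil": land_cap.value, "ocean": ocean_cap.value,
                  "anthropogenic": anth_cap}
    printed_linear = {"leaf": C.value(cfg, "d_leaf"),
                      "respiration": C.value(cfg, "d_respiration"),
                      "soil": C.value(cfg, "d_soil"),
                      "ocean": C.value(cfg, "d_ocean"),
                      "anthropogenic": C.value(cfg, "d_anthropogenic")}
    d18_assumed = {"leaf": C.value(cfg, "d18_leaf_co2"),
                   "respiration": C.value(cfg, "d18_soil_co2"),
                   "soil": C.value(cfg, "d18_soil_co2"),
                   "ocean": C.value(cfg, "d18_ocean_co2"),
                   "anthropogenic": C.value(cfg, "d18_anthropogenic_co2")}

    members = {}
    for name in _NAMES:
        if linear_mode == "printed":
            lin, prov = printed_linear[name], "printed-constant"
            d18 = None
        else:
            d18 = d18_assumed[name]
            lin = float(log_to_linear_value(log_values[name], d18))
            prov = "reverse-engineered"
        members[name] = CO2Endmember(name, log_values[name], lin, d18, prov)
    return EndmemberSet(members)


def land_composite(ems: EndmemberSet) -> float:
    """Linear Δ (‰) of the terrestrial source as the budget sees it.

    The terrestrial flux enters the steady-state budget as the mean of the
    leaf and soil/respiration endmembers, reflecting the 2:1:1 partition of
    F_land into leaf exchange, respiration and soil invasion.
    """
    return 0.5 * (ems.linear("leaf") + ems.linear("soil"))
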