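"""Triple-isotope algebra: conventions, conversions, and water-CO2 equilibration.

Builds the two terrestrial/oceanic source anomalies from first principles
and shows how the logarithmic and linear conventions relate.
"""

from trioxy import (CapDelta, DeltaPair, WaterPool, cap_delta_log,
                    equilibrate_water_to_co2, log_to_linear, rescale_lambda)

# A typical tropospheric CO2 sample: d17O = 21.107, d18O = 40.65 permil vs V-SMOW.
cap = cap_delta_log(DeltaPair(d17=21.107, d18=40.65), 0.516)
print(f"sample Delta-17O (logarithmic, lambda=0.516): {cap.value:.4f} permil")

# Meteoric water is reported on the 0.528 meteoric line; rescale to 0.516.
mw_at_516 = rescale_lambda(CapDelta(0.032, lam=0.528), 0.516, d18=-6.5)
print(f"meteoric water at lambda=0.516:               {mw_at_516.value:.4f} permil")

# Equilibrate meteoric water with CO2 at 15 C (alpha18 = 1.043): the
# terrestrial source endmember. Ocean water at 20 C gives the oceanic one.
land, land_d18 = equilibrate_water_to_co2(WaterPool("meteoric", -6.5, CapDelta(-0.046)), 1.043)
ocean, _ = equilibrate_water_to_co2(WaterPool("ocean", 0.42, CapDelta(0.000)), 1.042)
print(f"terrestrial CO2 endmember: {land.value:.4f} permil (d18O ~ {land_d18:.1f})")
print(f"oceanic CO2 endmember:     {ocean.value:.4f} permil")

# The budget needs the mass-conserving linear form; convert at the pool's d18O.
print(f"oceanic endmember, linear: {log_to_linear(CapDelta(0.284), 42.0).value:.4f} permil")
# Land sits ~0.04 permil below ocean: the anomaly is more sensitive to
# terrestrial than to oceanic exchange.
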