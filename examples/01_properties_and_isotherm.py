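"""Tissue property models and water sub-models.

Evaluates the composition- and temperature-dependent thermophysical
properties of shrimp tissue (water + protein mixture), the sorption
isotherm linking moisture to water activity, and the vapor-pressure and
latent-heat correlations used by the boundary conditions.
"""

import numpy as np

from shrimpdry import (
    Composition,
    SorptionIsotherm,
    latent_heat,
    mixture_conductivity,
    mixture_density,
    mixture_heat_capacity,
    saturation_pressure,
    solids_concentration,
    wet_basis,
)

X0 = 3.64  # fresh shrimp moisture, kg water / kg solids
comp = Composition.from_dry_basis(X0, c_s=solids_concentration(X0))
print(f"fresh tissue: X_db = {X0} kg/kg -> {wet_basis(X0)*100:.1f} % wet basis, "
      f"water mass fraction {comp.x_w:.3f}")
for T in (25.0, 46.0, 60.0):
    print(f"  at {T:4.0f} °C: rho = {mixture_density(comp, T):7.1f} kg/m3, "
          f"c_p = {mixture_heat_capacity(comp, T):6.0f} J/(kg K), "
          f"k = {mixture_conductivity(comp, T):.3f} W/(m K)")

print("\nsorption isotherm (60 °C parameter set):")
iso = SorptionIsotherm.for_air_temperature(60)
for X in (3.64, 1.0, 0.3, 0.1):
    print(f"  a_w({X:4.2f} kg/kg) = {float(iso.water_activity(X)):.3f}")
print("a_w ~ 1 while the surface is wet (constant-rate drying); it falls as")
print("the surface dries, throttling the evaporative flux.")

print("\nwater sub-models:")
for T in (25.0, 46.0, 60.0, 100.0):
    print(f"  {T:5.1f} °C: Psat = {saturation_pressure(T+273.15)/1e3:7.2f} kPa, "
          f"latent heat = {latent_heat(T)/1e6:.3f} MJ/kg")
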