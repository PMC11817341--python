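"""Parametric sensitivity of the drying process.

Sweeps the joint (h_T, h_m) transfer-coefficient multiplier and the air
humidity around the 60 °C baseline on a coarse equal-volume cylinder and
prints how the time to reach 1 kg/kg moisture, the plateau temperature
and the maximum drying rate respond.
"""

import shrimpdry as sd
from shrimpdry.analysis import SensitivitySpec, sensitivity_sweep
from shrimpdry.geometry import build_cylinder_geometry, generate_mesh

mesh = generate_mesh(build_cylinder_geometry(), 3e-3)
cfg = sd.baseline_config(60, max_time_step=30.0, output_interval=300.0)
spec = SensitivitySpec(D_multipliers=(0.5, 1.0, 2.0),
                       transfer_multipliers=(0.5, 1.0, 2.0, 3.0),
                       rh_levels=(5.0, 20.0, 40.0))
table = sensitivity_sweep(mesh, cfg, spec)
print(table.to_string(index=False,
                      formatters={"time_to_target_min": "{:.0f}".format,
                                  "plateau_T_C": "{:.1f}".format,
                                  "max_rate_per_min": "{:.3f}".format,
                                  "final_Xdb": "{:.2f}".format}))
print("\nFaster air transfer (larger h_T, h_m) shortens drying with strongly")
print("diminishing returns beyond ~2x: internal moisture diffusion becomes")
print("limiting.  Drier air (lower RH) both cools the plateau (more")
print("evaporative cooling) and shortens drying.")
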