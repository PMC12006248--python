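"""Predict ablation coverage and invert a measured lesion to a threshold.

Solves the two-needle conduction problem, reports what fraction of a
spherical tumor sees a field at or above the lethal threshold, sweeps the
voltage-to-distance ratio, and shows the in vitro inverse: from a measured
lesion area back to the lethal E-field value.
"""

import numpy as np

from ablaquant import field as F

# in vivo-like configuration: 0.4 mm needles, 4 mm apart, 600 V (1500 V/cm)
electrodes = F.ElectrodePair(spacing_mm=4.0, diameter_mm=0.4,
                             exposure_mm=4.0, applied_voltage_v=600.0)
print("voltage-to-distance ratio:",
      F.voltage_to_distance_ratio(600.0, 4.0), "V/cm")

schedule = F.burst_schedule((2, 5, 2, 5), 100.0, 200, 1.0)
print(f"2-5-2-5 waveform: {schedule.cycles_per_burst} cycles/burst, "
      f"{schedule.total_energized_us:.0f} us energized over "
      f"{schedule.total_duration_s:.0f} s")

# coarse grid keeps this demo quick; 0.1 mm reproduces the reference number
domain = F.two_needle_tumor_domain(tumor_volume_mm3=142.0, grid_step_mm=0.2)
solution = F.solve_field(domain, electrodes)
pred = F.ablation_metrics(solution, lethal_threshold_v_per_cm=1077.0,
                          region="tumor")
print(f"tumor coverage at 1077 V/cm: {pred.coverage_percent:.1f}% "
      f"({pred.ablated_measure:.1f} of {pred.region_measure:.1f} mm^3)")

curve = F.coverage_curve(domain, electrodes, [500, 1000, 1500, 2000, 3000],
                         lethal_threshold_v_per_cm=1077.0, region="tumor")
print("\ncoverage vs voltage-to-distance ratio:")
print(curve.to_string(index=False))

# quasi-2D (extruded) model of the subcutaneous configuration, where the
# conductor spans the tumor depth; reproduces treatment-planning coverage
domain2d = F.two_needle_tumor_domain(grid_step_mm=0.05, dimensionality=2)
sol2d = F.solve_field(domain2d, electrodes)
ext = F.extruded_ablation_metrics(sol2d, 1077.0, tumor_volume_mm3=142.0)
print(f"\nextruded cross-section coverage: {ext.coverage_percent:.2f}%")

# in vitro inverse: lesion area -> lethal threshold (hydrogel well geometry)
hydrogel = F.TissueDomain(((-9.0, 9.0), (-9.0, 9.0)),
                          (F.Region("full", 0.5, "hydrogel"),), 0.05, 2)
in_vitro = F.ElectrodePair(spacing_mm=3.0, diameter_mm=0.9,
                           exposure_mm=2.0, applied_voltage_v=500.0)
sol_iv = F.solve_field(hydrogel, in_vitro)
measured_area_mm2 = 8.0
threshold = F.invert_threshold(sol_iv, measured_area_mm2)
print(f"\nmeasured {measured_area_mm2:.1f} mm^2 lesion -> lethal threshold "
      f"{threshold:.0f} V/cm")
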