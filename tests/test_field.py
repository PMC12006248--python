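"""Electric-field model: geometry bookkeeping, solver physics, inversion."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ablaquant import field as F
from ablaquant.errors import (InconsistentWaveformError, InvalidGeometryError,
                              InvalidRegionError, OutOfRangeError)


class TestVoltageToDistance:
    @pytest.mark.parametrize("voltage,spacing,expected", [
        (600.0, 4.0, 1500.0),
        (500.0, 3.0, 5000.0 / 3.0),
        (0.0, 4.0, 0.0),
    ])
    def test_ratio(self, voltage, spacing, expected):
        assert F.voltage_to_distance_ratio(voltage, spacing) == pytest.approx(expected)

    def test_rejects_nonpositive_spacing(self):
        with pytest.raises(InvalidGeometryError):
            F.voltage_to_distance_ratio(600.0, 0.0)


class TestBurstSchedule:
    def test_canonical_2525_scheme(self):
        s = F.burst_schedule((2, 5, 2, 5), 100.0, 200, 1.0)
        assert s.cycles_per_burst == 25
        assert s.total_energized_us == 20000.0
        assert s.total_duration_s == pytest.approx(200.0)

    def test_single_cycle(self):
        assert F.burst_schedule((2, 5, 2, 5), 4.0, 1, 1.0).cycles_per_burst == 1

    def test_indivisible_energized_time(self):
        with pytest.raises(InconsistentWaveformError):
            F.burst_schedule((2, 5, 2, 5), 101.0, 1, 1.0)


class TestGeometryValidation:
    def test_spacing_must_exceed_diameter(self):
        with pytest.raises(InvalidGeometryError):
            F.ElectrodePair(spacing_mm=0.3, diameter_mm=0.4)

    def test_grid_must_resolve_electrode(self):
        dom = F.TissueDomain(((-12.0, 12.0),) * 2,
                             (F.Region("full", 0.5, "bg"),), 0.3, 2)
        with pytest.raises(InvalidGeometryError):
            F.solve_field(dom, F.ElectrodePair(diameter_mm=0.4))

    def test_box_margin_enforced(self):
        dom = F.TissueDomain(((-5.0, 5.0),) * 2,
                             (F.Region("full", 0.5, "bg"),), 0.1, 2)
        with pytest.raises(InvalidGeometryError):
            F.solve_field(dom, F.ElectrodePair(spacing_mm=4.0))


class TestSolver:
    def test_zero_voltage_gives_zero_field(self, small_field_2d):
        _, domain, electrodes = small_field_2d
        from dataclasses import replace
        sol = F.solve_field(domain, replace(electrodes, applied_voltage_v=0.0))
        assert sol.e_magnitude_v_per_cm.max() == 0.0

    def test_linearity_in_voltage(self, small_field_2d):
        sol1, domain, electrodes = small_field_2d
        from dataclasses import replace
        sol2 = F.solve_field(domain, replace(
            electrodes, applied_voltage_v=2 * electrodes.applied_voltage_v))
        mask = sol1.e_magnitude_v_per_cm > 1.0
        ratio = sol2.e_magnitude_v_per_cm[mask] / sol1.e_magnitude_v_per_cm[mask]
        assert np.allclose(ratio, 2.0, rtol=1e-4)

    def test_discrete_maximum_principle(self, small_field_2d):
        sol, _, electrodes = small_field_2d
        vh = electrodes.applied_voltage_v / 2
        assert sol.potential_v.max() <= vh + 1e-3
        assert sol.potential_v.min() >= -vh - 1e-3

    def test_converged_residual(self, small_field_2d):
        sol, _, _ = small_field_2d
        assert sol.residual <= 1e-6
        assert sol.e_magnitude_v_per_cm.min() >= 0.0

    def test_heterogeneous_regions_solve(self):
        dom = F.TissueDomain(((-6.0, 6.0),) * 2,
                             (F.Region("full", 0.1, "fat"),
                              F.Region("sphere", 0.5, "tumor",
                                       center_mm=(0.0, 0.0), radius_mm=2.0)),
                             0.1, 2)
        el = F.ElectrodePair(spacing_mm=2.0, applied_voltage_v=100.0)
        sol = F.solve_field(dom, el)
        assert sol.residual <= 1e-6

    def test_matches_analytic_two_wire_solution(self):
        """FDM |E| vs the closed-form bipolar (two-cylinder) field."""
        spacing, diam, volts = 4.0, 0.4, 600.0
        half = 48.0
        dom = F.TissueDomain(((-half, half),) * 2,
                             (F.Region("full", 0.5, "bg"),), 0.05, 2)
        el = F.ElectrodePair(spacing_mm=spacing, diameter_mm=diam,
                             applied_voltage_v=volts)
        sol = F.solve_field(dom, el)
        a, c = diam / 2, spacing / 2
        s = np.sqrt(c * c - a * a)
        k = (volts / 2) / np.arccosh(c / a)
        x, y = sol.axes_mm
        X, Y = np.meshgrid(x, y, indexing="ij")
        r1x, r1y, r2x, r2y = X - s, Y, X + s, Y
        r1, r2 = r1x ** 2 + r1y ** 2, r2x ** 2 + r2y ** 2
        e_an = np.sqrt((k * (r1x / r1 - r2x / r2)) ** 2
                       + (k * (r1y / r1 - r2y / r2)) ** 2) * 10.0
        dist = np.minimum(np.hypot(X - c, Y), np.hypot(X + c, Y))
        sel = (dist >= diam + a) & (np.hypot(X, Y) <= 1.5 * spacing)
        rel = np.abs(sol.e_magnitude_v_per_cm - e_an) / e_an
        assert rel[sel].max() < 0.02


class TestAblationMetrics:
    def test_zero_threshold_full_coverage(self, small_field_3d):
        sol, _, _ = small_field_3d
        assert F.ablation_metrics(sol, 0.0, "tumor").coverage_percent == 100.0

    def test_threshold_above_max_zero_coverage(self, small_field_3d):
        sol, _, _ = small_field_3d
        t = sol.e_magnitude_v_per_cm.max() + 1.0
        assert F.ablation_metrics(sol, t, "tumor").coverage_percent == 0.0

    def test_coverage_monotone_in_threshold(self, small_field_3d):
        sol, _, _ = small_field_3d
        covs = [F.ablation_metrics(sol, t, "tumor").coverage_percent
                for t in (200, 500, 1000, 2000)]
        assert all(a >= b for a, b in zip(covs, covs[1:]))

    def test_unknown_region_label(self, small_field_3d):
        sol, _, _ = small_field_3d
        with pytest.raises(InvalidRegionError):
            F.ablation_metrics(sol, 100.0, "no_such_region")

    def test_coverage_curve_monotone_and_consistent(self, small_field_3d):
        _, domain, electrodes = small_field_3d
        curve = F.coverage_curve(domain, electrodes, [500, 1500, 3000],
                                 lethal_threshold_v_per_cm=1077.0,
                                 region="tumor")
        cov = curve["coverage_percent"].to_numpy()
        assert np.all(np.diff(cov) >= 0)
        # single-ratio consistency against a direct solve
        from dataclasses import replace
        v = 1500.0 * electrodes.spacing_mm / 10.0
        sol = F.solve_field(domain, replace(electrodes, applied_voltage_v=v))
        direct = F.ablation_metrics(sol, 1077.0, "tumor").coverage_percent
        assert curve[curve.ratio_v_per_cm == 1500].coverage_percent.iloc[0] == \
            pytest.approx(direct, abs=0.5)

    def test_huge_ratio_saturates_coverage(self, small_field_3d):
        _, domain, electrodes = small_field_3d
        curve = F.coverage_curve(domain, electrodes, [1e6],
                                 lethal_threshold_v_per_cm=1077.0,
                                 region="tumor")
        assert curve.coverage_percent.iloc[0] == pytest.approx(100.0)


class TestInvertThreshold:
    def test_round_trip_identity(self, small_field_2d):
        sol, _, _ = small_field_2d
        e = sol.e_magnitude_v_per_cm
        h2 = sol.grid_step_mm ** 2
        t0 = 400.0
        area = float((e >= t0).sum()) * h2
        trec = F.invert_threshold(sol, area)
        # within one grid quantile of |E|
        flat = np.sort(e.ravel())
        idx = np.searchsorted(flat, t0)
        quantile_gap = abs(float(flat[min(idx + 1, flat.size - 1)])
                           - float(flat[max(idx - 1, 0)]))
        assert abs(trec - t0) <= max(quantile_gap, 1e-6)

    def test_full_domain_returns_min(self, small_field_2d):
        sol, _, _ = small_field_2d
        total = sol.e_magnitude_v_per_cm.size * sol.grid_step_mm ** 2
        assert F.invert_threshold(sol, total) == pytest.approx(
            float(sol.e_magnitude_v_per_cm.min()))

    def test_linearity_of_recovered_threshold(self, small_field_2d):
        sol1, domain, electrodes = small_field_2d
        from dataclasses import replace
        sol2 = F.solve_field(domain, replace(
            electrodes, applied_voltage_v=2 * electrodes.applied_voltage_v))
        area = 3.0
        t1, t2 = F.invert_threshold(sol1, area), F.invert_threshold(sol2, area)
        assert t2 / t1 == pytest.approx(2.0, rel=1e-3)

    @pytest.mark.parametrize("bad_area", [0.0, -1.0, 1e9])
    def test_out_of_range_areas(self, small_field_2d, bad_area):
        sol, _, _ = small_field_2d
        with pytest.raises(OutOfRangeError):
            F.invert_threshold(sol, bad_area)


class TestHelpers:
    def test_sphere_radius_volume_round_trip(self):
        r = F.sphere_radius_for_volume(142.0)
        assert 4.0 / 3.0 * np.pi * r ** 3 == pytest.approx(142.0)

    @given(st.floats(1.0, 500.0), st.floats(1.0, 20.0))
    def test_ratio_scales_linearly(self, v, d):
        assert F.voltage_to_distance_ratio(2 * v, d) == pytest.approx(
            2 * F.voltage_to_distance_ratio(v, d))

    def test_yaml_config_round_trip(self, tmp_path):
        cfg = tmp_path / "solve.yaml"
        cfg.write_text("""
electrodes: {spacing_mm: 2.0, diameter_mm: 0.4, exposure_mm: 2.0, applied_voltage_v: 300.0}
regions:
  - {shape: full, conductivity_s_per_m: 0.5, label: bg}
grid:
  bounds_mm: [[-6.0, 6.0], [-6.0, 6.0]]
  step_mm: 0.1
  dimensionality: 2
""")
        domain, electrodes = F.load_domain_config(cfg)
        assert domain.dimensionality == 2
        assert electrodes.spacing_mm == 2.0
        sol = F.solve_field(domain, electrodes)
        assert sol.residual <= 1e-6

    def test_save_load_field(self, small_field_2d, tmp_path):
        sol, _, _ = small_field_2d
        F.save_field(sol, tmp_path / "field")
        back = F.load_field(tmp_path / "field.npz")
        assert np.array_equal(back["potential_v"], sol.potential_v)
        assert np.array_equal(back["e_magnitude_v_per_cm"],
                              sol.e_magnitude_v_per_cm)
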