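"""Phantom generators: determinism, ground-truth bookkeeping, physical limits."""

import numpy as np
import pytest

from cryomap import (
    PressureModel,
    fit_calibration,
    simulate_calibration_table,
    simulate_calcium_movie,
    simulate_press_frames,
)
from cryomap.exceptions import DomainError, GeometryError, PhysicalLimitError
from cryomap.synthetic_data import (
    CalciumPhantomSpec,
    PressPhantomSpec,
    contact_pressure_kpa,
)


class TestPressPhantom:
    def test_zero_force_leaves_frames_identical(self, mesh, pattern):
        v0, v, truth = simulate_press_frames(
            PressPhantomSpec(force_N=0.0, noise_sd_relative=0.0), mesh, pattern
        )
        assert np.array_equal(v0.values, v.values)
        assert np.all(truth.per_element_pressure == 0.0)

    def test_truth_pressure_is_force_over_presser_area(self, mesh, pattern):
        _, _, truth = simulate_press_frames(PressPhantomSpec(force_N=0.1), mesh, pattern)
        nominal = 0.1 / (np.pi * 0.0015**2) / 1e3  # kPa
        assert nominal == pytest.approx(14.147, abs=0.01)
        inside = truth.per_element_pressure > 0
        assert inside.any()
        assert np.allclose(truth.per_element_pressure[inside], nominal)
        # footprint elements sit under the 3 mm presser at (7.5, 0)
        d = np.linalg.norm(mesh.element_centroids[inside] - [7.5, 0.0], axis=1)
        assert d.max() <= 1.5

    def test_stronger_press_perturbs_voltages_more(self, mesh, pattern):
        v0a, va, _ = simulate_press_frames(PressPhantomSpec(force_N=0.1), mesh, pattern)
        v0b, vb, _ = simulate_press_frames(PressPhantomSpec(force_N=0.01), mesh, pattern)
        assert np.linalg.norm(va.values - v0a.values) > np.linalg.norm(
            vb.values - v0b.values
        )

    def test_deterministic_under_seed(self, mesh, pattern):
        spec = PressPhantomSpec(force_N=0.05, noise_sd_relative=0.01, seed=9)
        a = simulate_press_frames(spec, mesh, pattern)
        b = simulate_press_frames(spec, mesh, pattern)
        assert np.array_equal(a[0].values, b[0].values)
        assert np.array_equal(a[1].values, b[1].values)

    def test_overload_raises_physical_limit(self, mesh, pattern):
        with pytest.raises(PhysicalLimitError):
            simulate_press_frames(PressPhantomSpec(force_N=0.12), mesh, pattern)

    def test_footprint_outside_disk_rejected(self, mesh, pattern):
        with pytest.raises(GeometryError):
            simulate_press_frames(
                PressPhantomSpec(press_center_mm=(14.5, 0.0)), mesh, pattern
            )


class TestCalibrationTable:
    def test_noiseless_table_recovers_slope_exactly(self):
        table, truth = simulate_calibration_table(PressureModel(), noise_sd=0.0)
        fit = fit_calibration(table["pressure_kPa"], table["variation"])
        assert fit.slope == pytest.approx(truth["slope_kPa"], rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_seeded_noise_slope_within_5_percent(self):
        table, truth = simulate_calibration_table(
            PressureModel(), n_points=15, noise_sd=0.01, seed=4
        )
        fit = fit_calibration(table["pressure_kPa"], table["variation"])
        assert fit.slope == pytest.approx(truth["slope_kPa"], rel=0.05)
        assert fit.r_squared < 1.0

    def test_too_few_points_rejected(self):
        with pytest.raises(DomainError):
            simulate_calibration_table(PressureModel(), n_points=2)


class TestCalciumPhantom:
    def test_bit_identical_under_seed(self):
        spec = CalciumPhantomSpec(
            grid=(16, 16), pixel_size_mm=1.875, duration_s=2.0, noise_sd=0.01, seed=5
        )
        m1, _ = simulate_calcium_movie(spec)
        m2, _ = simulate_calcium_movie(spec)
        assert np.array_equal(m1.frames, m2.frames)

    def test_truth_at_slope_matches_conduction_velocity(self):
        spec = CalciumPhantomSpec(
            grid=(32, 32), pixel_size_mm=0.9375, duration_s=2.0, noise_sd=0.0, seed=0
        )
        _, truth = simulate_calcium_movie(spec)
        ok = np.isfinite(truth["at_ms"])
        slope = np.polyfit(
            truth["distance_to_pacing_mm"][ok], truth["at_ms"][ok] / 1e3, 1
        )[0]
        assert slope == pytest.approx(1.0 / spec.conduction_velocity_mm_s, rel=1e-6)

    def test_full_lesion_matches_lesion_area(self):
        from cryomap import build_isochrone_maps

        spec = CalciumPhantomSpec(
            grid=(60, 60), pixel_size_mm=0.5, duration_s=3.0, noise_sd=0.005,
            seed=6, lesion_amplitude_factor=0.0, lesion_edge_mm=0.01,
        )
        movie, truth = simulate_calcium_movie(spec)
        iso = build_isochrone_maps(movie)
        undetectable = (movie.disk_mask & ~iso.detectable_mask).sum()
        lesion_px = truth["lesion_mask"].sum()
        assert undetectable == pytest.approx(lesion_px, rel=0.10)

    def test_no_lesion_full_coverage(self):
        from cryomap import build_isochrone_maps

        spec = CalciumPhantomSpec(
            grid=(24, 24), pixel_size_mm=1.25, duration_s=3.0, noise_sd=0.005, seed=7
        )
        movie, _ = simulate_calcium_movie(spec)
        assert build_isochrone_maps(movie).coverage == pytest.approx(1.0, abs=0.02)

    def test_invalid_specs_rejected(self):
        with pytest.raises(DomainError):
            CalciumPhantomSpec(duration_s=-1.0)
        with pytest.raises(DomainError):
            CalciumPhantomSpec(lesion_amplitude_factor=1.5)
        with pytest.raises(DomainError):
            CalciumPhantomSpec(lesion_center_mm=(20.0, 0.0))


def test_contact_pressure_closed_form():
    # 0.1 N over a 3 mm circle: 0.1 / (pi * (1.5e-3)^2) Pa = 14.15 kPa
    assert contact_pressure_kpa(0.1, 3.0) == pytest.approx(14.147, abs=0.01)
    assert contact_pressure_kpa(0.01, 3.0) == pytest.approx(1.4147, abs=0.001)
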