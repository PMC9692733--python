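"""Linear conductance-pressure model, calibration, press localization, ICP."""

import numpy as np
import pytest

from cryomap import (
    PressureModel,
    conductance_to_pressure,
    delta_k_to_pressure,
    estimate_press_location,
    fit_calibration,
    icp_rigid_2d,
    pressure_from_strain,
    procrustes_error,
    strain_to_delta_k,
)
from cryomap.eit_reconstruction import ConductanceMap
from cryomap.exceptions import (
    CalibrationError,
    DomainError,
    InsufficientDataError,
    NoPressError,
)
from cryomap.pipeline import default_press_grid


class TestLinearModel:
    def test_zero_strain_zero_change(self):
        assert strain_to_delta_k(0.0, PressureModel()) == 0.0
        assert pressure_from_strain(0.0, PressureModel()) == 0.0

    def test_unit_geometry_reduces_to_strain(self):
        model = PressureModel(sigma0=1.0, L1_mm=1.0, L2_mm=1.0, d0_mm=1.0)
        assert strain_to_delta_k(0.25, model) == pytest.approx(0.25)

    def test_general_geometry(self):
        model = PressureModel(sigma0=2.0, L1_mm=4.0, L2_mm=2.0, d0_mm=3.0)
        assert strain_to_delta_k(0.1, model) == pytest.approx(0.3)

    def test_printed_modulus_pressure(self):
        assert pressure_from_strain(0.5, PressureModel(E_kPa=16.0)) == pytest.approx(8.0)

    def test_round_trip_identity(self):
        model = PressureModel(E_kPa=16.0, sigma0=2.0, L1_mm=3.0, L2_mm=1.5, d0_mm=4.0)
        for eps in (0.05, 0.2, 0.45):
            dk = strain_to_delta_k(eps, model)
            assert delta_k_to_pressure(dk, model) == pytest.approx(
                pressure_from_strain(eps, model), abs=1e-12
            )

    def test_strain_domain_checked(self):
        with pytest.raises(DomainError):
            strain_to_delta_k(1.0, PressureModel())
        with pytest.raises(DomainError):
            pressure_from_strain(-0.1, PressureModel())


class TestCalibrationFit:
    def test_exact_line_recovered(self):
        dk = np.linspace(0.01, 0.3, 15)
        fit = fit_calibration(3.0 * dk, dk)
        assert fit.slope == pytest.approx(3.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.n_points == 15

    def test_noisy_line_slope_within_5_percent(self, rng):
        dk = np.linspace(0.01, 0.3, 15)
        p = 3.0 * dk + 0.01 * rng.standard_normal(15)
        fit = fit_calibration(p, dk)
        assert fit.slope == pytest.approx(3.0, rel=0.05)
        assert fit.r_squared < 1.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(CalibrationError):
            fit_calibration([1.0, 2.0], [0.1, 0.2])
        with pytest.raises(CalibrationError):
            fit_calibration([1.0, 1.0, 1.0], [0.1, 0.1, 0.1])


class TestConductanceToPressure:
    def test_zero_map_gives_zero_pressure(self, mesh):
        fit = fit_calibration([1.0, 2.0, 3.0], [0.1, 0.2, 0.3])
        cmap = ConductanceMap(np.zeros(mesh.n_elements), mesh, lam=0.1)
        pmap = conductance_to_pressure(cmap, fit)
        assert np.all(pmap.per_element_pressure == 0.0)

    def test_uniform_scaling_and_tensile_clipping(self, mesh):
        fit = fit_calibration([5.0, 10.0, 15.0], [0.1, 0.2, 0.3])  # slope 50 kPa
        var = np.full(mesh.n_elements, -0.1)
        var[:10] = 0.05  # tensile artifact
        pmap = conductance_to_pressure(ConductanceMap(var, mesh, lam=0.1), fit)
        assert np.allclose(pmap.per_element_pressure[10:], 5.0)
        assert np.all(pmap.per_element_pressure[:10] == 0.0)
        assert np.all(pmap.per_element_pressure >= 0.0)


class TestPressLocation:
    def test_constructed_minimum_region_located(self, mesh):
        var = np.zeros(mesh.n_elements)
        d = np.linalg.norm(mesh.element_centroids - [7.5, 0.0], axis=1)
        nearest = np.argsort(d)[:6]
        var[nearest] = -0.2
        loc = estimate_press_location(ConductanceMap(var, mesh, lam=0.1))
        assert sorted(loc.region_elements) == sorted(int(i) for i in nearest)
        mean_diameter = np.sqrt(4 * mesh.element_areas.mean() / np.pi)
        assert np.hypot(loc.point[0] - 7.5, loc.point[1]) < 1.5 * mean_diameter

    def test_central_symmetric_press(self, mesh):
        d = np.linalg.norm(mesh.element_centroids, axis=1)
        var = -np.exp(-(d**2) / 4.0)
        loc = estimate_press_location(ConductanceMap(var, mesh, lam=0.1))
        assert np.hypot(*loc.point) < 0.5

    def test_featureless_map_rejected(self, mesh):
        with pytest.raises(NoPressError):
            estimate_press_location(
                ConductanceMap(np.full(mesh.n_elements, -0.1), mesh, lam=0.1)
            )


class TestRigidRegistration:
    def test_identical_sets_identity(self):
        pts = default_press_grid()
        res = icp_rigid_2d(pts, pts)
        assert res.mean_error == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(2), atol=1e-9)
        assert np.allclose(res.translation, 0.0, atol=1e-9)

    def test_known_transform_recovered(self):
        intended = default_press_grid()
        theta = np.deg2rad(10.0)
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        detected = (intended - [1.0, 2.0]) @ R  # detected = R^-1 (intended - t)
        res = icp_rigid_2d(detected, intended)
        assert np.max(res.residuals) < 1e-9
        # closed-form Procrustes with known correspondence agrees
        pro = procrustes_error(detected, intended)
        assert np.max(pro.residuals) < 1e-9
        assert np.allclose(res.rotation, pro.rotation, atol=1e-9)

    def test_jittered_points_match_rayleigh_mean(self):
        # isotropic Gaussian jitter (sd sigma) makes point distances
        # Rayleigh-distributed with mean sigma * sqrt(pi / 2)
        sigma = 0.5
        intended = default_press_grid()
        rng = np.random.default_rng(42)
        means = [
            icp_rigid_2d(intended + sigma * rng.standard_normal(intended.shape), intended).mean_error
            for _ in range(100)
        ]
        assert np.mean(means) == pytest.approx(sigma * np.sqrt(np.pi / 2), rel=0.25)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            icp_rigid_2d([[0.0, 0.0]], [[1.0, 1.0]])
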