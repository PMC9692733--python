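"""End-to-end study workflows built from the individual modules.

These helpers chain phantom generation, forward simulation, reconstruction
and calibration the way the physical sensor was characterized: press with
known forces, reconstruct the conductance map, read out the press-region
response, fit the pressure/response line, and quantify spatial accuracy over
a grid of press sites.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .eit_reconstruction import (
    DEFAULT_NOSER_EXPONENT,
    ConductanceMap,
    Jacobian,
    reconstruct,
)
from .pressure_mapping import (
    CalibrationFit,
    IcpResult,
    PressLocation,
    estimate_press_location,
    fit_calibration,
    icp_rigid_2d,
    procrustes_error,
)
from .sensor_model import SensorMesh, StimPattern
from .synthetic_data import PressPhantomSpec, contact_pressure_kpa, simulate_press_frames

__all__ = [
    "reconstruct_press",
    "press_response",
    "calibrate_from_press_phantoms",
    "LocalizationStudy",
    "localization_study",
    "default_press_grid",
]


def reconstruct_press(
    spec: PressPhantomSpec,
    mesh: SensorMesh,
    pattern: StimPattern,
    jac: Jacobian,
    lam: float | None = None,
    noser_exponent: float = DEFAULT_NOSER_EXPONENT,
) -> ConductanceMap:
    """Simulate a press and reconstruct its conductance-variation map."""
    v0, v, _ = simulate_press_frames(spec, mesh, pattern)
    return reconstruct(v, v0, jac, lam=lam, noser_exponent=noser_exponent)


def press_response(cmap: ConductanceMap) -> float:
    """Scalar sensor response to a press: mean conductance reduction
    (``-variation``) over the located six-element press region."""
    loc = estimate_press_location(cmap)
    region = np.asarray(loc.region_elements)
    return float(-cmap.per_element_variation[region].mean())


def calibrate_from_press_phantoms(
    forces_N,
    mesh: SensorMesh,
    pattern: StimPattern,
    jac: Jacobian,
    base_spec: PressPhantomSpec | None = None,
    lam: float | None = None,
) -> CalibrationFit:
    """Calibrate pressure versus reconstructed response from simulated presses.

    For each force the phantom is pressed at the base spec's location, the
    conductance map reconstructed and the press-region response extracted;
    the (response, pressure) pairs are then fit by ordinary least squares.
    This mirrors the physical calibration: the fitted slope absorbs the
    amplitude scaling of the one-step reconstruction.
    """
    if base_spec is None:
        base_spec = PressPhantomSpec()
    pressures, responses = [], []
    for i, f in enumerate(forces_N):
        spec = replace(base_spec, force_N=float(f), seed=base_spec.seed + i)
        cmap = reconstruct_press(spec, mesh, pattern, jac, lam=lam)
        responses.append(press_response(cmap))
        pressures.append(contact_pressure_kpa(f, spec.presser_diameter_mm))
    return fit_calibration(pressures, responses)


def default_press_grid(n_angles: int = 5, radii_mm=(2.5, 5.0, 7.5, 10.0)) -> np.ndarray:
    """Grid of press sites spread over the sensing disk (20 by default)."""
    pts = []
    for k, r in enumerate(radii_mm):
        for a in range(n_angles):
            # stagger angles ring to ring so sites do not line up radially
            theta = 2.0 * np.pi * (a + 0.5 * (k % 2)) / n_angles
            pts.append((r * np.cos(theta), r * np.sin(theta)))
    return np.asarray(pts)


@dataclass
class LocalizationStudy:
    """Spatial-accuracy summary over a grid of press sites."""

    intended: np.ndarray
    detected: np.ndarray
    icp: IcpResult
    procrustes: IcpResult

    @property
    def mean_error_mm(self) -> float:
        return self.icp.mean_error

    @property
    def sd_error_mm(self) -> float:
        return self.icp.sd_error


def localization_study(
    mesh: SensorMesh,
    pattern: StimPattern,
    jac: Jacobian,
    sites_mm: np.ndarray | None = None,
    force_N: float = 0.1,
    noise_sd_relative: float = 0.0,
    seed: int = 0,
    lam: float | None = None,
) -> LocalizationStudy:
    """Press at each site, reconstruct, localize, and align detected to intended.

    The spatial sensing error is the mean +/- SD of the per-site distances
    after rigid ICP alignment of detected onto intended locations; the
    known-correspondence Procrustes error is reported alongside because the
    hardware study's pairing convention is not recorded.
    """
    if sites_mm is None:
        sites_mm = default_press_grid()
    detected = []
    for i, (x, y) in enumerate(sites_mm):
        spec = PressPhantomSpec(
            press_center_mm=(float(x), float(y)),
            force_N=force_N,
            noise_sd_relative=noise_sd_relative,
            seed=seed + i,
        )
        cmap = reconstruct_press(spec, mesh, pattern, jac, lam=lam)
        loc: PressLocation = estimate_press_location(cmap)
        detected.append(loc.point)
    detected = np.asarray(detected)
    return LocalizationStudy(
        intended=np.asarray(sites_mm),
        detected=detected,
        icp=icp_rigid_2d(detected, sites_mm),
        procrustes=procrustes_error(detected, sites_mm),
    )
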