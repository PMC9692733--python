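"""Conductance-to-pressure conversion, calibration fits, press localization, ICP.

The sensing model treats an infinitesimal block of the hydrogel layer (length
``L1`` along the current, width ``L2``, thickness ``d0``, bulk conductivity
``sigma0``) under vertical compressive strain ``eps``.  By Pouillet's law the
conductance change is linear in the strain,

    delta_k = sigma0 * eps * L2 * d0 / L1,

and within the linear region of the stress-strain curve the applied pressure
is ``p = E * eps`` with ``E`` the approximated Young's modulus (~16 kPa for
the ionic hydrogel).  Chaining the two gives the linear pressure/conductance
relation that is calibrated empirically and then applied element-wise to a
reconstructed conductance-variation map.

Press localization follows the hardware convention: the six elements with the
lowest conductance variation form the press region and its area-weighted
centroid is the press location.  Spatial accuracy against intended press sites
is quantified with a 2-D rigid iterative-closest-point alignment (and, for
known correspondences, a closed-form Procrustes fit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .eit_reconstruction import ConductanceMap
from .exceptions import (
    CalibrationError,
    DomainError,
    InsufficientDataError,
    NoPressError,
)
from .sensor_model import SensorMesh

__all__ = [
    "PressureModel",
    "CalibrationFit",
    "PressureMap",
    "PressLocation",
    "IcpResult",
    "strain_to_delta_k",
    "pressure_from_strain",
    "delta_k_to_pressure",
    "fit_calibration",
    "conductance_to_pressure",
    "estimate_press_location",
    "icp_rigid_2d",
    "procrustes_error",
]

log = logging.getLogger(__name__)


@dataclass
class PressureModel:
    """Material and geometry constants of the linear pressure model.

    ``E_kPa`` is the approximated Young's modulus in the linear compression
    region (~16 kPa at 50% compressive strain for the ionic hydrogel);
    ``L1_mm``/``L2_mm``/``d0_mm`` are the dimensions of the infinitesimal
    region (length along current flow, width, thickness); ``slope`` is the
    calibrated pressure-per-unit-conductance-variation ratio once known.
    """

    E_kPa: float = 16.0
    sigma0: float = 1.0
    L1_mm: float = 1.0
    L2_mm: float = 1.0
    d0_mm: float = 4.0
    slope: float | None = None

    def __post_init__(self) -> None:
        if self.E_kPa <= 0:
            raise DomainError(f"E_kPa must be positive, got {self.E_kPa}")
        if self.d0_mm <= 0:
            raise DomainError(f"d0_mm must be positive, got {self.d0_mm}")
        if self.L1_mm <= 0 or self.L2_mm <= 0:
            raise DomainError("L1_mm and L2_mm must be positive")
        if self.slope is not None and not np.isfinite(self.slope):
            raise DomainError("slope must be finite")


@dataclass(frozen=True)
class CalibrationFit:
    """Ordinary-least-squares pressure-vs-variation calibration."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int


@dataclass
class PressureMap:
    """Per-element pressure in kPa on the sensing mesh."""

    per_element_pressure: np.ndarray
    mesh: SensorMesh

    def __post_init__(self) -> None:
        self.per_element_pressure = np.asarray(self.per_element_pressure, dtype=float)


@dataclass(frozen=True)
class PressLocation:
    """Estimated press site: centroid of the lowest-conductance region."""

    point: tuple[float, float]
    region_elements: tuple[int, ...]


def strain_to_delta_k(eps: float, model: PressureModel) -> float:
    """Conductance change of the infinitesimal block under strain ``eps``.

    ``delta_k = sigma0 * eps * L2 * d0 / L1`` (Pouillet's law with constant
    bulk conductivity; valid for ``0 <= eps < 1``).
    """
    if not 0.0 <= eps < 1.0:
        raise DomainError(f"compressive strain must lie in [0, 1), got {eps}")
    return model.sigma0 * eps * model.L2_mm * model.d0_mm / model.L1_mm


def pressure_from_strain(eps: float, model: PressureModel) -> float:
    """Pressure (kPa) at strain ``eps`` in the linear region: ``p = E * eps``."""
    if not 0.0 <= eps < 1.0:
        raise DomainError(f"compressive strain must lie in [0, 1), got {eps}")
    return model.E_kPa * eps


def delta_k_to_pressure(delta_k: float, model: PressureModel) -> float:
    """Pressure (kPa) from a conductance change: ``p = E L1 / (sigma0 L2 d0) * delta_k``."""
    return model.E_kPa * model.L1_mm / (model.sigma0 * model.L2_mm * model.d0_mm) * delta_k


def fit_calibration(pressures, variations) -> CalibrationFit:
    """Least-squares line through (conductance variation, pressure) pairs.

    ``variations`` is the magnitude of the relative conductance reduction; the
    fitted ``slope`` converts variation to pressure (kPa).
    """
    p = np.asarray(pressures, dtype=float)
    v = np.asarray(variations, dtype=float)
    if p.shape != v.shape:
        raise CalibrationError("pressures and variations differ in length")
    if len(p) < 3:
        raise CalibrationError(f"need at least 3 calibration points, got {len(p)}")
    if np.ptp(v) == 0 or np.ptp(p) == 0:
        raise CalibrationError("degenerate calibration data (zero variance)")
    res = stats.linregress(v, p)
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(p),
    )


def conductance_to_pressure(cmap: ConductanceMap, fit: CalibrationFit) -> PressureMap:
    """Scale a conductance-variation map to pressure, element-wise.

    Compression reduces conductance, so pressure is ``slope * max(0, -var)``;
    positive (tensile) reconstruction artifacts are clipped to zero and
    logged.  The calibration intercept is ignored here so that a zero map
    yields exactly zero pressure.
    """
    if not np.isfinite(fit.slope):
        raise CalibrationError("calibration slope is not finite")
    var = cmap.per_element_variation
    n_clipped = int(np.sum(var > 0))
    if n_clipped:
        log.debug("clipped %d tensile elements to zero pressure", n_clipped)
    pressure = fit.slope * np.clip(-var, 0.0, None)
    return PressureMap(per_element_pressure=pressure, mesh=cmap.mesh)


def estimate_press_location(
    cmap: ConductanceMap, n_region_elements: int = 6
) -> PressLocation:
    """Locate the press as the centroid of the lowest-conductance region.

    The ``n_region_elements`` (default six, jointly about one presser
    footprint in area) elements with the most negative variation are selected
    — ties broken by lower element index — and the press location is their
    area-weighted centroid.
    """
    var = cmap.per_element_variation
    if len(var) < n_region_elements:
        raise NoPressError("map has fewer elements than the press region size")
    if np.ptp(var) == 0:
        raise NoPressError("featureless conductance map: no press detected")
    order = np.argsort(var, kind="stable")  # ascending; stable => index tie-break
    region = np.sort(order[:n_region_elements])
    areas = cmap.mesh.element_areas[region]
    centroids = cmap.mesh.element_centroids[region]
    point = (areas[:, None] * centroids).sum(axis=0) / areas.sum()
    return PressLocation(point=(float(point[0]), float(point[1])), region_elements=tuple(int(e) for e in region))


# --------------------------------------------------------------------------- #
# rigid 2-D registration
# --------------------------------------------------------------------------- #


@dataclass
class IcpResult:
    """Rigid alignment of detected onto intended press sites."""

    rotation: np.ndarray  # (2, 2)
    translation: np.ndarray  # (2,)
    residuals: np.ndarray  # per-point distances after alignment, mm
    mean_error: float
    sd_error: float
    n_iterations: int = field(default=0)

    def transform(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def _kabsch_2d(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form rigid (rotation + translation, no scale) fit src -> dst."""
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    H = (src - mu_s).T @ (dst - mu_d)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = mu_d - R @ mu_s
    return R, t


def icp_rigid_2d(
    detected,
    intended,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> IcpResult:
    """Iterative-closest-point rigid alignment of detected onto intended sites.

    Alternates nearest-neighbour correspondence with a closed-form SVD
    (Kabsch) transform estimate until the mean squared residual changes by
    less than ``tol``.  Residual statistics are computed after alignment and
    define the spatial sensing error (mean +/- SD of per-point distances).
    """
    det = np.atleast_2d(np.asarray(detected, dtype=float))
    int_ = np.atleast_2d(np.asarray(intended, dtype=float))
    if len(det) < 2 or len(int_) < 2:
        raise InsufficientDataError("ICP needs at least 2 points in each set")
    tree = cKDTree(int_)
    R = np.eye(2)
    t = int_.mean(axis=0) - det.mean(axis=0)  # centroid pre-alignment
    prev_mse = np.inf
    n_it = 0
    for n_it in range(1, max_iter + 1):
        moved = det @ R.T + t
        dist, idx = tree.query(moved)
        R, t = _kabsch_2d(det, int_[idx])
        mse = float(np.mean(dist**2))
        if abs(prev_mse - mse) < tol:
            break
        prev_mse = mse
    moved = det @ R.T + t
    dist, _ = tree.query(moved)
    return IcpResult(
        rotation=R,
        translation=t,
        residuals=dist,
        mean_error=float(dist.mean()),
        sd_error=float(dist.std(ddof=1)) if len(dist) > 1 else 0.0,
        n_iterations=n_it,
    )


def procrustes_error(detected, intended) -> IcpResult:
    """Rigid alignment error with *known* one-to-one correspondence.

    Same transform model as :func:`icp_rigid_2d` but with the pairing fixed by
    position in the input lists; reported alongside ICP because the study's
    pairing convention is not recorded.
    """
    det = np.atleast_2d(np.asarray(detected, dtype=float))
    int_ = np.atleast_2d(np.asarray(intended, dtype=float))
    if det.shape != int_.shape or len(det) < 2:
        raise InsufficientDataError("need matched point sets of length >= 2")
    R, t = _kabsch_2d(det, int_)
    moved = det @ R.T + t
    dist = np.linalg.norm(moved - int_, axis=1)
    return IcpResult(
        rotation=R,
        translation=t,
        residuals=dist,
        mean_error=float(dist.mean()),
        sd_error=float(dist.std(ddof=1)) if len(dist) > 1 else 0.0,
        n_iterations=1,
    )
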