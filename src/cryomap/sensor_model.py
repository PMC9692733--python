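"""Circular hydrogel EIT sensor: geometry, meshing, drive patterns, forward model.

The sensing element is a thin disk of ionic hydrogel with ``n`` electrodes
evenly spaced on its boundary.  Current is injected through adjacent electrode
pairs and differential voltages are read from all other adjacent pairs (the
"adjacent-adjacent" protocol), giving ``n (n - 3)`` four-probe measurements per
frame.  Because the hydrogel layer is thin relative to its diameter, the
forward problem is modelled as a 2-D sheet: the quasi-static potential ``u``
satisfies ``div(sigma_s grad u) = 0`` with sheet conductance
``sigma_s = sigma * d0`` (bulk conductivity times layer thickness), solved with
linear (P1) finite elements on a triangulated disk.

Electrodes are modelled as short boundary arcs; the drive current is split
evenly over the arc nodes and electrode voltage is the arithmetic mean of the
arc-node potentials.  With this symmetric choice the discrete system inherits
the reciprocity of the continuous problem exactly.  The 20 kHz excitation
carrier is not simulated: the DC solution stands for the RMS amplitude of the
AC measurement, a documented acquisition convention (see
:func:`excitation_periods`).

Coordinates are millimetres, origin at the disk centre, x-axis through
electrode 0, angles counterclockwise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .exceptions import DimensionError, DomainError, GeometryError, MeshError, SolverError

__all__ = [
    "SensorGeometry",
    "SensorMesh",
    "StimPattern",
    "ConductivityField",
    "VoltageFrame",
    "generate_stim_pattern",
    "build_mesh",
    "forward_solve",
    "excitation_periods",
]


def _cross2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """z-component of the cross product of stacked 2-vectors."""
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class SensorGeometry:
    """Physical dimensions of the circular pressure sensor.

    Parameters
    ----------
    radius_mm:
        Radius of the circular sensing region (default 15 mm, i.e. the 30 mm
        diameter hydrogel well).
    thickness_mm:
        Thickness ``d0`` of the hydrogel layer (default 4 mm).
    n_electrodes:
        Number of boundary electrodes (default 8).
    presser_diameter_mm:
        Diameter of the cylindrical presser / catheter tip (default 3 mm).
    electrode_arc_deg:
        Angular width of each electrode contact arc.  The hardware value is
        not known; it is exposed as configuration rather than guessed.
    """

    radius_mm: float = 15.0
    thickness_mm: float = 4.0
    n_electrodes: int = 8
    presser_diameter_mm: float = 3.0
    electrode_arc_deg: float = 9.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise GeometryError(f"radius_mm must be positive, got {self.radius_mm}")
        if self.thickness_mm <= 0:
            raise GeometryError(f"thickness_mm must be positive, got {self.thickness_mm}")
        if self.n_electrodes < 4:
            raise GeometryError(f"need at least 4 electrodes, got {self.n_electrodes}")
        if not 0 < self.presser_diameter_mm < self.radius_mm:
            raise GeometryError(
                "presser_diameter_mm must lie in (0, radius_mm), got "
                f"{self.presser_diameter_mm}"
            )


@dataclass(frozen=True)
class StimPattern:
    """Ordered list of (drive pair, measure pair) electrode index tuples."""

    n_electrodes: int
    entries: tuple[tuple[tuple[int, int], tuple[int, int]], ...]

    def __len__(self) -> int:
        return len(self.entries)

    def rotated(self, shift: int) -> "StimPattern":
        """Pattern with every electrode index shifted by ``shift`` (mod n)."""
        n = self.n_electrodes
        ent = tuple(
            (
                ((d0 + shift) % n, (d1 + shift) % n),
                ((m0 + shift) % n, (m1 + shift) % n),
            )
            for (d0, d1), (m0, m1) in self.entries
        )
        return StimPattern(n, ent)

    def swapped(self) -> "StimPattern":
        """Pattern with drive and measure pairs exchanged (reciprocity check)."""
        return StimPattern(
            self.n_electrodes, tuple((m, d) for d, m in self.entries)
        )


@dataclass
class SensorMesh:
    """Triangulated sensing disk with boundary electrode node sets.

    Attributes
    ----------
    nodes:
        ``(n_nodes, 2)`` array of node coordinates in mm.
    triangles:
        ``(n_elements, 3)`` array of node indices, counterclockwise.
    electrode_nodes:
        One integer array of boundary node indices per electrode.
    geometry:
        The :class:`SensorGeometry` the mesh was built from.
    """

    nodes: np.ndarray
    triangles: np.ndarray
    electrode_nodes: list[np.ndarray]
    geometry: SensorGeometry
    element_areas: np.ndarray = field(init=False)
    element_centroids: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        p = self.nodes[self.triangles]
        cross = _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        if np.any(cross <= 0):
            # enforce CCW orientation; a vanishing cross product is degenerate
            flip = cross < 0
            self.triangles[flip] = self.triangles[flip][:, [0, 2, 1]]
            p = self.nodes[self.triangles]
            cross = _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        if np.any(cross <= 1e-12):
            raise MeshError("triangulation contains a (near-)zero-area element")
        self.element_areas = 0.5 * cross
        self.element_centroids = p.mean(axis=1)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    def to_json(self) -> str:
        payload = {
            "nodes": self.nodes.tolist(),
            "triangles": self.triangles.tolist(),
            "electrode_nodes": [e.tolist() for e in self.electrode_nodes],
            "geometry": {
                "radius_mm": self.geometry.radius_mm,
                "thickness_mm": self.geometry.thickness_mm,
                "n_electrodes": self.geometry.n_electrodes,
                "presser_diameter_mm": self.geometry.presser_diameter_mm,
                "electrode_arc_deg": self.geometry.electrode_arc_deg,
            },
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "SensorMesh":
        payload = json.loads(text)
        return cls(
            nodes=np.asarray(payload["nodes"], dtype=float),
            triangles=np.asarray(payload["triangles"], dtype=np.int64),
            electrode_nodes=[np.asarray(e, dtype=np.int64) for e in payload["electrode_nodes"]],
            geometry=SensorGeometry(**payload["geometry"]),
        )


@dataclass
class ConductivityField:
    """Per-element bulk conductivity in S/m over a :class:`SensorMesh`."""

    per_element_conductivity: np.ndarray
    sigma0: float = 1.0

    def __post_init__(self) -> None:
        self.per_element_conductivity = np.asarray(
            self.per_element_conductivity, dtype=float
        )
        if self.sigma0 <= 0:
            raise DomainError(f"sigma0 must be positive, got {self.sigma0}")
        if np.any(self.per_element_conductivity <= 0):
            raise DomainError("all element conductivities must be positive")

    @classmethod
    def homogeneous(cls, mesh: SensorMesh, sigma0: float = 1.0) -> "ConductivityField":
        return cls(np.full(mesh.n_elements, sigma0), sigma0=sigma0)


@dataclass
class VoltageFrame:
    """One EIT refresh: an RMS voltage per stimulation-pattern entry."""

    values: np.ndarray
    pattern: StimPattern
    drive_current_mA: float = 0.8
    frequency_kHz: float = 20.0  # metadata only; the carrier is not simulated

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.pattern):
            raise DimensionError(
                f"frame has {len(self.values)} values for a pattern of length "
                f"{len(self.pattern)}"
            )


# --------------------------------------------------------------------------- #
# operations
# --------------------------------------------------------------------------- #


def generate_stim_pattern(n_electrodes: int) -> StimPattern:
    """Adjacent-adjacent stimulation/measurement pattern for ``n`` electrodes.

    For each of the ``n`` adjacent drive pairs ``(d, d+1)`` (counterclockwise,
    in increasing ``d``), voltage is measured across every adjacent pair
    ``(m, m+1)`` that shares no electrode with the drive pair, in increasing
    ``m``.  The result has ``n (n - 3)`` entries (40 for 8 electrodes).
    """
    if n_electrodes < 4:
        raise GeometryError(
            f"adjacent pattern needs at least 4 electrodes, got {n_electrodes}"
        )
    n = n_electrodes
    entries = []
    for d in range(n):
        drive = (d, (d + 1) % n)
        for m in range(n):
            meas = (m, (m + 1) % n)
            if set(meas) & set(drive):
                continue
            entries.append((drive, meas))
    return StimPattern(n, tuple(entries))


def _mesh_layout(target_elements: int, n_electrodes: int) -> tuple[int, int]:
    """Choose (nodes-per-ring increment m, ring count R) with m*R^2 elements.

    ``m`` is constrained to a multiple of ``n_electrodes`` so that the node set
    of every ring — and hence the whole mesh — is invariant under rotation by
    one electrode spacing, and the boundary ring contains a node at every
    electrode angle.
    """
    n = n_electrodes
    best: tuple[int, int, int] | None = None  # (|err|, m, R)
    for rings in range(2, 65):
        q = max(1, round(target_elements / (n * rings * rings)))
        for qq in (q - 1, q, q + 1):
            if qq < 1:
                continue
            m = n * qq
            err = abs(m * rings * rings - target_elements)
            cand = (err, m, rings)
            if best is None or cand[0] < best[0] or (cand[0] == best[0] and rings > best[2]):
                best = cand
    assert best is not None
    _, m, rings = best
    return m, rings


def build_mesh(geometry: SensorGeometry, target_elements: int = 576) -> SensorMesh:
    """Triangulate the sensing disk with ~``target_elements`` elements.

    A structured concentric-ring triangulation is used: ring ``k`` of ``R``
    carries ``m k`` nodes at radius ``r k / R``, and adjacent rings are
    stitched by an angular sweep, giving exactly ``m R^2`` positively oriented
    triangles.  ``m`` is a multiple of the electrode count, so the mesh is
    exactly symmetric under rotation by one electrode spacing and boundary
    nodes coincide with the electrode angles (electrode 0 at angle 0, i.e.
    due east, counterclockwise ordering).

    With the default geometry and ``target_elements=576`` the element count is
    exactly 576 and the mean element area is ~1.23 mm^2.
    """
    if target_elements < 64:
        raise GeometryError(f"target_elements must be >= 64, got {target_elements}")
    m, rings = _mesh_layout(target_elements, geometry.n_electrodes)
    if abs(m * rings * rings - target_elements) > 0.1 * target_elements:
        raise MeshError(
            f"no ring layout within 10% of {target_elements} elements for "
            f"{geometry.n_electrodes} electrodes"
        )
    r = geometry.radius_mm

    nodes: list[tuple[float, float]] = [(0.0, 0.0)]
    ring_index: list[np.ndarray] = [np.array([0])]
    for k in range(1, rings + 1):
        cnt = m * k
        ang = 2.0 * np.pi * np.arange(cnt) / cnt
        rad = r * k / rings
        idx = np.arange(len(nodes), len(nodes) + cnt)
        nodes.extend(zip(rad * np.cos(ang), rad * np.sin(ang)))
        ring_index.append(idx)

    triangles: list[tuple[int, int, int]] = []
    # central fan
    inner1 = ring_index[1]
    for j in range(len(inner1)):
        triangles.append((0, inner1[j], inner1[(j + 1) % len(inner1)]))
    # ring bands: angular sweep advancing whichever ring has the smaller next angle
    for k in range(2, rings + 1):
        inner, outer = ring_index[k - 1], ring_index[k]
        p, q = len(inner), len(outer)
        i = j = 0
        while i < p or j < q:
            # exact integer comparison of (i+1)/p vs (j+1)/q keeps the
            # diagonal choice identical in every sector (exact n-fold symmetry)
            next_inner = (i + 1) * q if i < p else np.inf
            next_outer = (j + 1) * p if j < q else np.inf
            if next_outer <= next_inner:
                triangles.append((outer[j % q], outer[(j + 1) % q], inner[i % p]))
                j += 1
            else:
                triangles.append((outer[j % q], inner[(i + 1) % p], inner[i % p]))
                i += 1

    boundary = ring_index[-1]
    n_bnd = len(boundary)
    bnd_angles = 2.0 * np.pi * np.arange(n_bnd) / n_bnd
    half_arc = math.radians(geometry.electrode_arc_deg) / 2.0
    electrode_nodes: list[np.ndarray] = []
    for e in range(geometry.n_electrodes):
        center = 2.0 * np.pi * e / geometry.n_electrodes
        delta = np.angle(np.exp(1j * (bnd_angles - center)))
        sel = np.where(np.abs(delta) <= half_arc + 1e-12)[0]
        if len(sel) == 0:
            sel = np.array([int(np.argmin(np.abs(delta)))])
        electrode_nodes.append(boundary[np.sort(sel)])

    return SensorMesh(
        nodes=np.asarray(nodes, dtype=float),
        triangles=np.asarray(triangles, dtype=np.int64),
        electrode_nodes=electrode_nodes,
        geometry=geometry,
    )


# --------------------------------------------------------------------------- #
# finite-element forward model
# --------------------------------------------------------------------------- #


def element_gradients(mesh: SensorMesh) -> np.ndarray:
    """Per-element gradient operators: ``(n_elements, 2, 3)``.

    ``G[e] @ u[tri[e]]`` is the (constant) gradient of the P1 field on
    element ``e``, in 1/mm.
    """
    p = mesh.nodes[mesh.triangles]  # (M, 3, 2)
    x, y = p[..., 0], p[..., 1]
    area2 = 2.0 * mesh.element_areas
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    grad = np.stack([b, c], axis=1)  # (M, 2, 3)
    return grad / area2[:, None, None]


def assemble_stiffness(mesh: SensorMesh, field_: ConductivityField) -> sp.csc_matrix:
    """Assemble the P1 stiffness matrix with sheet conductance ``sigma * d0``."""
    sigma = field_.per_element_conductivity
    if len(sigma) != mesh.n_elements:
        raise DimensionError(
            f"field has {len(sigma)} values for a mesh of {mesh.n_elements} elements"
        )
    d0_m = mesh.geometry.thickness_mm * 1e-3
    grad = element_gradients(mesh)  # (M, 2, 3)
    # local stiffness: sigma_s * A * grad^T grad  (dimensionless geometry factor)
    local = np.einsum("mki,mkj->mij", grad, grad) * (
        sigma * d0_m * mesh.element_areas
    )[:, None, None]
    tri = mesh.triangles
    rows = np.repeat(tri, 3, axis=1).ravel()
    cols = np.tile(tri, (1, 3)).ravel()
    K = sp.coo_matrix(
        (local.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    ).tocsc()
    return K


def _electrode_injection(mesh: SensorMesh, electrode: int) -> np.ndarray:
    """Unit-current injection vector for one electrode (split over arc nodes)."""
    vec = np.zeros(mesh.n_nodes)
    nodes = mesh.electrode_nodes[electrode]
    vec[nodes] = 1.0 / len(nodes)
    return vec


class ForwardOperator:
    """Factorized forward solver for a fixed mesh and conductivity field.

    Solves the grounded system once and reuses the factorization across all
    drive pairs of a pattern.  Grounding fixes the (rotation-invariant) centre
    node; only potential differences are ever reported, so the gauge choice is
    immaterial.
    """

    def __init__(self, mesh: SensorMesh, field_: ConductivityField):
        self.mesh = mesh
        self.field = field_
        K = assemble_stiffness(mesh, field_).tolil()
        ground = 0  # centre node
        K[ground, :] = 0.0
        K[:, ground] = 0.0
        K[ground, ground] = 1.0
        try:
            self._lu = spla.splu(K.tocsc())
        except RuntimeError as exc:  # pragma: no cover - defensive
            raise SolverError(f"singular finite-element system: {exc}") from exc
        self._ground = ground
        self._cache: dict[tuple[int, int], np.ndarray] = {}

    def pair_field(self, pair: tuple[int, int], current_A: float = 1.0) -> np.ndarray:
        """Nodal potential for current ``current_A`` driven in at ``pair[0]``, out at ``pair[1]``."""
        key = (int(pair[0]), int(pair[1]))
        if key not in self._cache:
            rhs = _electrode_injection(self.mesh, key[0]) - _electrode_injection(
                self.mesh, key[1]
            )
            rhs[self._ground] = 0.0
            u = self._lu.solve(rhs)
            if not np.all(np.isfinite(u)):
                raise SolverError("forward solution is not finite")
            self._cache[key] = u
        return current_A * self._cache[key]

    def electrode_voltage(self, u: np.ndarray, pair: tuple[int, int]) -> float:
        hi = u[self.mesh.electrode_nodes[pair[0]]].mean()
        lo = u[self.mesh.electrode_nodes[pair[1]]].mean()
        return float(hi - lo)


def forward_solve(
    mesh: SensorMesh,
    field_: ConductivityField,
    pattern: StimPattern,
    current_mA: float = 0.8,
) -> VoltageFrame:
    """Solve the forward conductivity problem for every pattern entry.

    Returns the differential electrode voltages (volts) for a drive current of
    ``current_mA``.  Deterministic for fixed inputs.
    """
    if pattern.n_electrodes != mesh.geometry.n_electrodes:
        raise DimensionError(
            f"pattern is for {pattern.n_electrodes} electrodes, mesh has "
            f"{mesh.geometry.n_electrodes}"
        )
    op = ForwardOperator(mesh, field_)
    current_A = current_mA * 1e-3
    values = np.empty(len(pattern))
    for i, (drive, meas) in enumerate(pattern.entries):
        u = op.pair_field(drive, current_A)
        values[i] = op.electrode_voltage(u, meas)
    return VoltageFrame(values=values, pattern=pattern, drive_current_mA=current_mA)


def excitation_periods(
    n_samples: int = 100, sampling_khz: float = 400.0, carrier_khz: float = 20.0
) -> float:
    """Carrier periods covered by one RMS estimation window.

    The acquisition convention: each four-probe measurement samples
    ``n_samples`` ADC values at ``sampling_khz`` and reduces them to an RMS
    amplitude.  The window length times the carrier frequency gives the number
    of whole excitation periods averaged over (5.0 for the defaults: 100
    samples at 400 kHz with a 20 kHz carrier).
    """
    if n_samples <= 0 or sampling_khz <= 0 or carrier_khz <= 0:
        raise DomainError("sample count and frequencies must be positive")
    return (n_samples / sampling_khz) * carrier_khz
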