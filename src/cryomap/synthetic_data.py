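"""Ground-truth generators for every input the analysis pipeline consumes.

Three families of phantoms are produced, each with a machine-readable truth
record and full determinism under a fixed seed:

* **Press phantoms** — a cylindrical presser (3 mm, the cryocatheter tip
  diameter) pushed onto the 30 mm sensing disk with a known force (0.1 N
  "normal therapy", 0.01 N "failed contact").  The contact pressure implies a
  compressive strain ``eps = p / E`` which, by the linear conductance model,
  reduces the conductivity of the footprint elements by the factor
  ``(1 - eps)``; baseline and loaded voltage frames are then obtained from the
  finite-element forward model, optionally with relative Gaussian measurement
  noise.
* **Calibration tables** — (pressure, conductance-variation) pairs on the
  linear model line with seeded noise, emulating the force-probe sweep used to
  calibrate the physical sensor.
* **Calcium movies** — 80 x 80 px, 500 frames/s fluorescence stacks of a
  paced disk.  Each pixel fires a transient train delayed by its distance to
  the pacing site over the conduction velocity; the waveform is a
  double-exponential ``(1 - exp(-t/tau_up)) * exp(-t/tau_down)``, the minimal
  shape with separate release and uptake rates.  An optional circular lesion
  (default 3 mm at 7.5 mm from centre, mirroring the catheter position)
  scales the local transient amplitude by ``lesion_amplitude_factor`` with a
  configurable soft edge.  The truth record carries per-pixel activation
  times, CaD80 and amplitude, computed from the analytic waveform by a dense
  brute-force oracle.

Waveform kinetics defaults (``tau_up`` 0.08 s, ``tau_down`` 0.48 s, relative
amplitude 0.05, conduction velocity 150 mm/s) emulate the testbed tissue: an
observable steady-state CaD80 near 0.68 s under 1 Hz pacing, an uptake rate
near 0.1 /s on the F/F0 scale with the release rate several-fold faster, and
a transient that recovers to 20% within one pacing cycle everywhere on the
disk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .calcium_mapping import CalciumMovie, RadialProfile
from .exceptions import DomainError, GeometryError, PhysicalLimitError
from .pressure_mapping import PressureMap, PressureModel
from .sensor_model import (
    ConductivityField,
    SensorMesh,
    StimPattern,
    VoltageFrame,
    forward_solve,
)

__all__ = [
    "PressPhantomSpec",
    "CalciumPhantomSpec",
    "simulate_press_frames",
    "simulate_calibration_table",
    "simulate_calcium_movie",
    "simulate_condition_profiles",
    "contact_pressure_kpa",
]

#: Contact forces of the study conditions, in newtons.
NORMAL_THERAPY_FORCE_N = 0.1
FAILED_CONTACT_FORCE_N = 0.01


def contact_pressure_kpa(force_N: float, presser_diameter_mm: float) -> float:
    """Nominal contact pressure: force over the presser cross-section, in kPa."""
    r_m = presser_diameter_mm / 2.0 * 1e-3
    return force_N / (math.pi * r_m**2) / 1e3


# --------------------------------------------------------------------------- #
# press phantoms
# --------------------------------------------------------------------------- #


@dataclass
class PressPhantomSpec:
    """A point press by the catheter-sized presser on the sensing disk."""

    press_center_mm: tuple[float, float] = (7.5, 0.0)
    presser_diameter_mm: float = 3.0
    force_N: float = NORMAL_THERAPY_FORCE_N
    model: PressureModel = field(default_factory=PressureModel)
    noise_sd_relative: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.force_N < 0:
            raise DomainError(f"force must be non-negative, got {self.force_N}")


def simulate_press_frames(
    spec: PressPhantomSpec,
    mesh: SensorMesh,
    pattern: StimPattern,
    current_mA: float = 0.8,
) -> tuple[VoltageFrame, VoltageFrame, PressureMap]:
    """Baseline and loaded voltage frames plus the ground-truth pressure map.

    The truth pressure equals ``force / presser area`` inside the footprint
    (elements whose centroid lies under the presser) and zero outside.  The
    implied strain ``eps = p / E`` must stay below 1; footprint conductivity
    is scaled by ``(1 - eps)``.  Independent seeded Gaussian noise of SD
    ``noise_sd_relative * |v|`` is added per measurement to both frames.
    """
    geom = mesh.geometry
    cx, cy = spec.press_center_mm
    if math.hypot(cx, cy) + spec.presser_diameter_mm / 2.0 > geom.radius_mm:
        raise GeometryError("press footprint extends outside the sensing disk")
    pressure_kpa = contact_pressure_kpa(spec.force_N, spec.presser_diameter_mm)
    eps = pressure_kpa / spec.model.E_kPa
    if eps >= 1.0:
        raise PhysicalLimitError(
            f"force {spec.force_N} N implies compressive strain {eps:.2f} >= 1"
        )
    d = np.linalg.norm(mesh.element_centroids - [cx, cy], axis=1)
    footprint = d <= spec.presser_diameter_mm / 2.0
    if not footprint.any():
        raise GeometryError("press footprint covers no mesh element")

    sigma0 = spec.model.sigma0
    sigma = np.full(mesh.n_elements, sigma0)
    sigma[footprint] *= 1.0 - eps
    v0 = forward_solve(mesh, ConductivityField.homogeneous(mesh, sigma0), pattern, current_mA)
    v = forward_solve(mesh, ConductivityField(sigma, sigma0=sigma0), pattern, current_mA)

    if spec.noise_sd_relative > 0:
        rng = np.random.default_rng(spec.seed)
        v0 = VoltageFrame(
            v0.values + spec.noise_sd_relative * np.abs(v0.values) * rng.standard_normal(len(v0.values)),
            pattern,
            drive_current_mA=current_mA,
        )
        v = VoltageFrame(
            v.values + spec.noise_sd_relative * np.abs(v.values) * rng.standard_normal(len(v.values)),
            pattern,
            drive_current_mA=current_mA,
        )
    truth = PressureMap(
        per_element_pressure=np.where(footprint, pressure_kpa, 0.0), mesh=mesh
    )
    return v0, v, truth


# --------------------------------------------------------------------------- #
# calibration tables
# --------------------------------------------------------------------------- #


def simulate_calibration_table(
    model: PressureModel,
    n_points: int = 15,
    # default scatter chosen so an n=15 sweep yields R^2 ~ 0.983, the level
    # observed on the physical sensor bench
    noise_sd: float = 0.03,
    seed: int = 0,
    force_range_N: tuple[float, float] = (FAILED_CONTACT_FORCE_N, NORMAL_THERAPY_FORCE_N),
    presser_diameter_mm: float = 3.0,
) -> tuple[dict, dict]:
    """(pressure, conductance-variation) calibration pairs with seeded noise.

    Forces sweep the study's contact range (0.01-0.1 N by default) with the
    3 mm presser; the variation is the relative conductance reduction
    ``eps = p / E`` plus Gaussian noise of SD ``noise_sd``.  Returns the table
    (dict of columns) and a truth record with the generating slope (``E`` in
    kPa per unit variation).
    """
    if n_points < 3:
        raise DomainError(f"need at least 3 calibration points, got {n_points}")
    rng = np.random.default_rng(seed)
    forces = np.linspace(force_range_N[0], force_range_N[1], n_points)
    pressures = np.array([contact_pressure_kpa(f, presser_diameter_mm) for f in forces])
    variations = pressures / model.E_kPa + noise_sd * rng.standard_normal(n_points)
    table = {
        "force_N": forces,
        "pressure_kPa": pressures,
        "variation": variations,
        "presser_diameter_mm": np.full(n_points, presser_diameter_mm),
    }
    truth = {"slope_kPa": model.E_kPa, "noise_sd": noise_sd, "seed": seed}
    return table, truth


# --------------------------------------------------------------------------- #
# calcium movies
# --------------------------------------------------------------------------- #


@dataclass
class CalciumPhantomSpec:
    """A paced, propagating calcium-transient movie with an optional lesion."""

    grid: tuple[int, int] = (80, 80)
    frame_rate_hz: float = 500.0
    duration_s: float = 15.0
    pacing_hz: float = 1.0
    pacing_site_mm: tuple[float, float] = (-12.0, 0.0)
    conduction_velocity_mm_s: float = 150.0
    upstroke_tau_s: float = 0.08
    decay_tau_s: float = 0.48
    amplitude: float = 0.05  # peak transient amplitude relative to baseline
    baseline_counts: float = 1000.0
    background_counts: float = 50.0
    disk_radius_mm: float = 15.0
    pixel_size_mm: float = 0.375
    lesion_center_mm: tuple[float, float] = (7.5, 0.0)
    lesion_diameter_mm: float = 3.0
    lesion_amplitude_factor: float = 1.0  # 1 = no lesion, 0 = fully silenced
    lesion_edge_mm: float = 0.3
    noise_sd: float = 0.0  # relative to baseline_counts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.pacing_hz <= 0 or self.frame_rate_hz <= 0:
            raise DomainError("durations and rates must be positive")
        if not 0.0 <= self.lesion_amplitude_factor <= 1.0:
            raise DomainError("lesion_amplitude_factor must lie in [0, 1]")
        lx, ly = self.lesion_center_mm
        if math.hypot(lx, ly) > self.disk_radius_mm:
            raise DomainError("lesion centre lies outside the disk")


def _pixel_coords_mm(spec: CalciumPhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-centre coordinates in mm (x east, y up, origin at image centre)."""
    h, w = spec.grid
    rows = np.arange(h)
    cols = np.arange(w)
    x = (cols - (w - 1) / 2.0) * spec.pixel_size_mm
    y = ((h - 1) / 2.0 - rows) * spec.pixel_size_mm
    return np.meshgrid(x, y)[0], np.tile(y[:, None], (1, w))


def _waveform_landmarks(
    tau_up: float,
    tau_down: float,
    period_s: float,
    dt: float = 2e-5,
    n_history: int = 10,
) -> dict:
    """Brute-force dense-time landmarks of the transient waveform.

    Landmarks are measured on the *periodic steady state* — the superposition
    of the current beat with the decaying tails of ``n_history`` preceding
    beats — because at 1 Hz pacing the observable transient rides on the
    previous beat's tail, which raises the diastolic floor and shortens the
    apparent CaD80 relative to an isolated transient.
    """
    t = np.arange(0.0, period_s, dt)
    peak = float(((1.0 - np.exp(-t / tau_up)) * np.exp(-t / tau_down)).max())
    w = np.zeros_like(t)
    for k in range(n_history + 1):
        tk = t + k * period_s
        w += (1.0 - np.exp(-tk / tau_up)) * np.exp(-tk / tau_down)
    w /= peak  # unit isolated-beat peak; steady-state peak is slightly higher
    base = float(w.min())
    amp = float(w.max() - base)
    ipk = int(np.argmax(w))
    lvl50 = base + 0.5 * amp
    lvl20 = base + 0.2 * amp
    below = np.nonzero(w[: ipk + 1] < lvl50)[0]
    i50 = int(below[-1]) + 1 if len(below) else 0
    rec = np.nonzero(w[ipk:] <= lvl20)[0]
    t20 = t[ipk + rec[0]] if len(rec) else float("nan")
    return {
        "peak_scale": peak,
        "steady_baseline": base,
        "steady_amplitude": amp,
        "t_peak_s": float(t[ipk]),
        "t50_rise_s": float(t[i50]),
        "t20_decay_s": float(t20),
        "cad80_ms": float((t20 - t[i50]) * 1e3),
    }


def simulate_calcium_movie(spec: CalciumPhantomSpec) -> tuple[CalciumMovie, dict]:
    """Generate a paced propagating-transient movie and its truth record.

    Per-pixel activation is delayed by ``distance(pacing site) / conduction
    velocity``; each beat adds the double-exponential waveform scaled to the
    pixel amplitude; lesion pixels are scaled by ``lesion_amplitude_factor``
    (sigmoid edge of width ``lesion_edge_mm``); seeded Gaussian noise is added
    to every pixel of every frame.  The truth record stores per-pixel AT (ms,
    relative to each pacing onset), CaD80 (ms, from the dense-time waveform
    oracle), amplitude maps, the lesion mask and the pacing onsets.
    """
    h, w = spec.grid
    fs = spec.frame_rate_hz
    n_frames = int(round(spec.duration_s * fs))
    X, Y = _pixel_coords_mm(spec)
    rr = np.hypot(X, Y)
    disk = rr <= spec.disk_radius_mm

    px, py = spec.pacing_site_mm
    delay = np.hypot(X - px, Y - py) / spec.conduction_velocity_mm_s  # s

    lx, ly = spec.lesion_center_mm
    d_lesion = np.hypot(X - lx, Y - ly)
    if spec.lesion_amplitude_factor < 1.0:
        from scipy.special import expit

        edge = max(spec.lesion_edge_mm, 1e-6)
        inside = expit(-(d_lesion - spec.lesion_diameter_mm / 2.0) / edge)
        amp_factor = 1.0 - (1.0 - spec.lesion_amplitude_factor) * inside
    else:
        amp_factor = np.ones_like(d_lesion)
    amplitude = spec.amplitude * amp_factor * disk

    lm = _waveform_landmarks(spec.upstroke_tau_s, spec.decay_tau_s, 1.0 / spec.pacing_hz)
    period = 1.0 / spec.pacing_hz
    onsets = np.arange(0.0, spec.duration_s - 1e-9, period)

    # beat train on a fine grid, then shift per pixel by its conduction delay
    max_delay = float(delay[disk].max()) if disk.any() else 0.0
    dt_fine = 1.0 / fs / 4.0
    t_fine = np.arange(-max_delay - period, spec.duration_s + period, dt_fine)
    train = np.zeros_like(t_fine)
    for t0 in onsets:
        tau = t_fine - t0
        m = tau > 0
        train[m] += (
            (1.0 - np.exp(-tau[m] / spec.upstroke_tau_s))
            * np.exp(-tau[m] / spec.decay_tau_s)
            / lm["peak_scale"]
        )

    t_frames = np.arange(n_frames) / fs
    frames = np.empty((n_frames, h, w), dtype=np.float32)
    flat_delay = delay.ravel()
    flat_amp = amplitude.ravel()
    base = np.where(disk, spec.baseline_counts, spec.background_counts).ravel()
    buf = np.empty((h * w, n_frames), dtype=np.float32)
    for j in range(h * w):
        if flat_amp[j] > 0:
            wave = np.interp(t_frames - flat_delay[j], t_fine, train)
            buf[j] = base[j] * (1.0 + flat_amp[j] * wave)
        else:
            buf[j] = base[j]
    frames[:] = buf.T.reshape(n_frames, h, w)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        frames += (spec.noise_sd * spec.baseline_counts) * rng.standard_normal(
            frames.shape
        ).astype(np.float32)

    movie = CalciumMovie(
        frames=frames,
        frame_rate_hz=fs,
        pixel_size_mm=spec.pixel_size_mm,
        disk_mask=disk,
        pacing_onset_times_s=onsets.tolist(),
    )
    truth = {
        "at_ms": np.where(disk, (delay + lm["t50_rise_s"]) * 1e3, np.nan),
        "cad80_ms": np.where(disk & (amplitude > 0), lm["cad80_ms"], np.nan),
        "amplitude": amplitude,
        "delay_s": np.where(disk, delay, np.nan),
        "lesion_mask": disk & (d_lesion <= spec.lesion_diameter_mm / 2.0),
        "pacing_onsets_s": onsets,
        "conduction_velocity_mm_s": spec.conduction_velocity_mm_s,
        "waveform": lm,
        "distance_to_pacing_mm": np.where(disk, np.hypot(X - px, Y - py), np.nan),
    }
    return movie, truth


# --------------------------------------------------------------------------- #
# condition-level radial profiles
# --------------------------------------------------------------------------- #

#: Lesion depth (fractional calcium-intensity suppression at the lesion core)
#: per experimental condition.
CONDITION_LESION_DEPTH = {
    "normal_therapy": 0.85,
    "failed_contact": 0.35,
    "force_only": 0.0,
}
CONDITION_FORCE_N = {
    "normal_therapy": NORMAL_THERAPY_FORCE_N,
    "failed_contact": FAILED_CONTACT_FORCE_N,
    "force_only": NORMAL_THERAPY_FORCE_N,
}


def simulate_condition_profiles(
    condition: str,
    seed: int = 0,
    press_radius_mm: float = 7.5,
    r_max_mm: float = 12.0,
    n_pressure: int = 121,
    n_calcium: int = 61,
    pressure_noise_rel: float = 0.02,
    calcium_noise_sd: float = 0.03,
    press_width_mm: float = 1.3,
    lesion_width_mm: float = 1.5,
) -> tuple[RadialProfile, RadialProfile, RadialProfile]:
    """Paired (pressure, pre-calcium, post-calcium) radial profiles.

    The pressure profile is a Gaussian bump of the condition's nominal contact
    pressure at the catheter radius; the post-ablation calcium profile is the
    flat pre-ablation intensity suppressed by the condition's lesion depth at
    the same radius.  Pressure sampling is denser than calcium sampling, as
    for the recorded maps versus the radial image series.

    Conditions: ``"normal_therapy"`` (0.1 N, deep lesion), ``"failed_contact"``
    (0.01 N, shallow lesion), ``"force_only"`` (0.1 N, no lesion).
    """
    if condition not in CONDITION_LESION_DEPTH:
        raise DomainError(
            f"unknown condition {condition!r}; expected one of "
            f"{sorted(CONDITION_LESION_DEPTH)}"
        )
    rng = np.random.default_rng(seed)
    depth = CONDITION_LESION_DEPTH[condition]
    peak_kpa = contact_pressure_kpa(CONDITION_FORCE_N[condition], 3.0)

    r_p = np.linspace(0.0, r_max_mm, n_pressure)
    p = peak_kpa * np.exp(-((r_p - press_radius_mm) ** 2) / (2.0 * press_width_mm**2))
    p = np.clip(p + pressure_noise_rel * peak_kpa * rng.standard_normal(n_pressure), 0.0, None)

    r_c = np.linspace(0.0, r_max_mm, n_calcium)
    pre = 0.9 + calcium_noise_sd * rng.standard_normal(n_calcium)
    suppression = depth * np.exp(-((r_c - press_radius_mm) ** 2) / (2.0 * lesion_width_mm**2))
    post = pre * (1.0 - suppression) + calcium_noise_sd * rng.standard_normal(n_calcium)

    return (
        RadialProfile(r_p, p, label=f"pressure ({condition})"),
        RadialProfile(r_c, pre, label="calcium pre-ablation"),
        RadialProfile(r_c, post, label=f"calcium post-ablation ({condition})"),
    )
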