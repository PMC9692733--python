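"""Readers and writers for the package's on-disk formats.

Meshes go to JSON; voltage frames, stimulation patterns, conductance and
pressure maps, calibration tables, traces and radial profiles go to CSV
(pandas); movies go to multi-page TIFF (tifffile); map renderings go to PNG
(matplotlib tripcolor).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .calcium_mapping import CalciumMovie, CalciumTrace, RadialProfile
from .eit_reconstruction import ConductanceMap
from .exceptions import DimensionError
from .pressure_mapping import PressureMap
from .sensor_model import SensorMesh, StimPattern, VoltageFrame, generate_stim_pattern

__all__ = [
    "save_mesh",
    "load_mesh",
    "save_voltage_frame",
    "load_voltage_frame",
    "save_map",
    "load_map_values",
    "render_map",
    "save_trace",
    "save_profile",
    "load_profile",
    "save_movie",
    "load_movie",
    "save_calibration_table",
    "load_calibration_table",
]


def save_mesh(mesh: SensorMesh, path) -> None:
    Path(path).write_text(mesh.to_json())


def load_mesh(path) -> SensorMesh:
    return SensorMesh.from_json(Path(path).read_text())


def save_voltage_frame(frame: VoltageFrame, path) -> None:
    rows = [
        {
            "drive_a": d[0],
            "drive_b": d[1],
            "meas_a": m[0],
            "meas_b": m[1],
            "voltage_v": v,
            "drive_current_mA": frame.drive_current_mA,
            "frequency_kHz": frame.frequency_kHz,
        }
        for (d, m), v in zip(frame.pattern.entries, frame.values)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_voltage_frame(path) -> VoltageFrame:
    df = pd.read_csv(path)
    n = int(max(df[["drive_a", "drive_b", "meas_a", "meas_b"]].to_numpy().max() + 1, 4))
    pattern = generate_stim_pattern(n)
    expected = [
        (int(r.drive_a), int(r.drive_b), int(r.meas_a), int(r.meas_b))
        for r in df.itertuples()
    ]
    got = [(d[0], d[1], m[0], m[1]) for d, m in pattern.entries]
    if expected != got:
        raise DimensionError("CSV rows do not follow the adjacent pattern order")
    return VoltageFrame(
        values=df["voltage_v"].to_numpy(),
        pattern=pattern,
        drive_current_mA=float(df["drive_current_mA"].iloc[0]),
        frequency_kHz=float(df["frequency_kHz"].iloc[0]),
    )


def save_map(map_, path, column: str | None = None) -> None:
    """Write a per-element map (conductance variation or pressure) to CSV."""
    if isinstance(map_, ConductanceMap):
        col = column or "variation"
        values = map_.per_element_variation
    elif isinstance(map_, PressureMap):
        col = column or "pressure_kPa"
        values = map_.per_element_pressure
    else:
        raise TypeError(f"unsupported map type {type(map_)!r}")
    pd.DataFrame({"element": np.arange(len(values)), col: values}).to_csv(
        path, index=False
    )


def load_map_values(path) -> np.ndarray:
    df = pd.read_csv(path)
    value_col = [c for c in df.columns if c != "element"][0]
    return df.sort_values("element")[value_col].to_numpy()


def render_map(map_, path, title: str = "", cmap: str = "viridis") -> None:
    """Render a per-element map as a PNG of the triangulated disk."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mesh = map_.mesh
    if isinstance(map_, ConductanceMap):
        values = map_.per_element_variation
    else:
        values = map_.per_element_pressure
    fig, ax = plt.subplots(figsize=(5, 5))
    tpc = ax.tripcolor(
        mesh.nodes[:, 0], mesh.nodes[:, 1], mesh.triangles, facecolors=values, cmap=cmap
    )
    fig.colorbar(tpc, ax=ax, shrink=0.8)
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_trace(trace: CalciumTrace, path) -> None:
    pd.DataFrame({"time_s": trace.time_s, "f_over_f0": trace.f_over_f0}).to_csv(
        path, index=False
    )


def save_profile(profile: RadialProfile, path) -> None:
    pd.DataFrame({"radius_mm": profile.radii_mm, "value": profile.values}).to_csv(
        path, index=False
    )


def load_profile(path, label: str = "") -> RadialProfile:
    df = pd.read_csv(path)
    return RadialProfile(
        radii_mm=df["radius_mm"].to_numpy(), values=df["value"].to_numpy(), label=label
    )


def save_movie(movie: CalciumMovie, path) -> None:
    import tifffile

    tifffile.imwrite(
        path,
        movie.frames.astype(np.float32),
        metadata={
            "frame_rate_hz": movie.frame_rate_hz,
            "pixel_size_mm": movie.pixel_size_mm,
        },
    )


def load_movie(
    path, frame_rate_hz: float = 500.0, pixel_size_mm: float = 0.375, disk_mask=None
) -> CalciumMovie:
    import tifffile

    frames = tifffile.imread(path)
    return CalciumMovie(
        frames=frames,
        frame_rate_hz=frame_rate_hz,
        pixel_size_mm=pixel_size_mm,
        disk_mask=disk_mask,
    )


def save_calibration_table(table: dict, path) -> None:
    pd.DataFrame(table).to_csv(path, index=False)


def load_calibration_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Return (pressures_kPa, variations) from a calibration CSV.

    Accepts either a ``pressure_kPa`` column or ``force_N`` plus
    ``presser_diameter_mm`` (pressure is then force over presser area).
    """
    df = pd.read_csv(path)
    if "pressure_kPa" in df.columns:
        p = df["pressure_kPa"].to_numpy()
    else:
        r_m = df["presser_diameter_mm"].to_numpy() / 2.0 * 1e-3
        p = df["force_N"].to_numpy() / (np.pi * r_m**2) / 1e3
    return p, df["variation"].to_numpy()
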