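"""Calcium-transient analysis of fluorescence movies of paced cardiac disks.

A movie is an ``(n_frames, height, width)`` fluorescence stack (typically
80 x 80 px at 500 frames/s) of a disk of cardiomyocytes paced at ~1 Hz.  This
module extracts normalized traces (F/F0), per-transient upstroke and
downstroke velocities, per-pixel transient duration at 80% repolarization
(CaD80) and activation time at 50% depolarization (AT), the detectable-signal
coverage fraction, and radial intensity profiles used to compare the calcium
response with the applied-pressure distribution.

Conventions (documented choices where the field has no single standard):

* F0 is the mean of the lowest decile of a trace — robust to the pacing duty
  cycle and to drifting baselines.
* CaD80 runs from activation (50% of the upstroke amplitude) to the time the
  signal has recovered to 20% of the peak amplitude above baseline, with
  linear interpolation between frames.
* Upstroke/downstroke velocities are the maxima of the (Savitzky-Golay
  smoothed) time derivative of F/F0 during rise and decay, averaged over
  detected transients; the mean-derivative alternative is selectable.
* Per-pixel maps are computed on the beat-averaged transient (beats aligned
  on pacing onsets), which suppresses uncorrelated pixel noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, signal

from .exceptions import (
    DomainError,
    NoTransientError,
    ProfileError,
    RoiError,
)

__all__ = [
    "CalciumMovie",
    "CalciumTrace",
    "TransientStats",
    "IsochroneMap",
    "RadialProfile",
    "extract_trace",
    "transient_stats",
    "cad80",
    "activation_time",
    "build_isochrone_maps",
    "radial_profile",
    "radial_profile_from_mesh",
]


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #


@dataclass
class CalciumMovie:
    """Fluorescence image stack of the cardiac disk.

    ``frames`` has shape ``(n_frames, height, width)``; ``disk_mask`` marks
    the pixels belonging to the disk; ``pacing_onset_times_s`` optionally
    records the 1 Hz pacing stimulus times (estimated from the global mean
    trace when absent).
    """

    frames: np.ndarray
    frame_rate_hz: float = 500.0
    pixel_size_mm: float = 0.375
    disk_mask: np.ndarray | None = None
    pacing_onset_times_s: Sequence[float] | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise DomainError("frames must be a (time, height, width) stack")
        if self.frame_rate_hz <= 0:
            raise DomainError("frame_rate_hz must be positive")
        if self.disk_mask is None:
            self.disk_mask = np.ones(self.frames.shape[1:], dtype=bool)
        else:
            self.disk_mask = np.asarray(self.disk_mask, dtype=bool)
            if self.disk_mask.shape != self.frames.shape[1:]:
                raise DomainError("disk_mask shape does not match the frames")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.frames.shape[0]) / self.frame_rate_hz

    @property
    def center_px(self) -> tuple[float, float]:
        """(row, col) centroid of the disk mask."""
        r, c = np.nonzero(self.disk_mask)
        return float(r.mean()), float(c.mean())


@dataclass
class CalciumTrace:
    """Normalized fluorescence time series F/F0."""

    time_s: np.ndarray
    f_over_f0: np.ndarray
    baseline_f0: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.f_over_f0 = np.asarray(self.f_over_f0, dtype=float)
        if self.baseline_f0 <= 0:
            raise DomainError("baseline_f0 must be positive")


@dataclass(frozen=True)
class TransientStats:
    """Average transient kinetics of a trace (units 1/s on F/F0)."""

    upstroke_velocity_per_s: float
    downstroke_velocity_per_s: float
    peak_amplitude: float
    n_transients: int


@dataclass
class IsochroneMap:
    """Per-pixel CaD80 and activation-time maps with a detectability mask."""

    cad80_ms: np.ndarray
    at_ms: np.ndarray
    detectable_mask: np.ndarray
    coverage: float


@dataclass
class RadialProfile:
    """Values sampled along a disk radius at increasing radial positions."""

    radii_mm: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.radii_mm = np.asarray(self.radii_mm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.radii_mm.shape != self.values.shape:
            raise DomainError("radii and values differ in length")
        if np.any(self.radii_mm < 0) or np.any(np.diff(self.radii_mm) <= 0):
            raise DomainError("radii must be non-negative and strictly increasing")


# --------------------------------------------------------------------------- #
# traces
# --------------------------------------------------------------------------- #


def extract_trace(movie: CalciumMovie, roi: np.ndarray) -> CalciumTrace:
    """Spatially averaged, baseline-normalized trace of a region of interest.

    ``roi`` is a boolean mask over the image; it must be non-empty and lie
    inside the disk mask.  F0 is the mean of the lowest decile of the raw
    trace.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != movie.frames.shape[1:]:
        raise RoiError("roi shape does not match the frames")
    if not roi.any():
        raise RoiError("empty roi")
    if np.any(roi & ~movie.disk_mask):
        raise RoiError("roi extends outside the disk mask")
    raw = movie.frames[:, roi].mean(axis=1).astype(float)
    decile = np.quantile(raw, 0.1)
    f0 = float(raw[raw <= decile].mean())
    if f0 <= 0:
        raise RoiError(f"non-positive baseline fluorescence F0={f0}")
    return CalciumTrace(time_s=movie.times_s, f_over_f0=raw / f0, baseline_f0=f0)


def _smooth(y: np.ndarray, window: int, polyorder: int) -> np.ndarray:
    if window >= len(y):
        window = len(y) - 1 if (len(y) - 1) % 2 else len(y) - 2
    if window <= polyorder:
        return y
    return signal.savgol_filter(y, window, polyorder)


def transient_stats(
    trace: CalciumTrace,
    prominence: float = 0.2,
    smooth_window: int = 11,
    polyorder: int = 1,
    method: str = "max",
) -> TransientStats:
    """Upstroke/downstroke velocities and amplitude, averaged over transients.

    Transients are peaks of F/F0 with the given prominence.  For each one the
    upstroke velocity is the maximum of the smoothed derivative between the
    preceding trough and the peak, the downstroke velocity the maximum of the
    negated derivative between the peak and the following trough
    (``method="mean"`` averages the derivative over the same windows instead).

    The default smoothing is a moving average (Savitzky-Golay, polynomial
    order 1, window 11): its kernel is non-negative, so the derivative of a
    linear segment is recovered exactly.  Higher polynomial orders preserve
    sharper peaks but their negative kernel lobes overshoot derivative maxima
    at transient feet by ~10%.
    """
    y = trace.f_over_f0
    t = trace.time_s
    if method not in ("max", "mean"):
        raise DomainError(f"unknown velocity method {method!r}")
    peaks, _ = signal.find_peaks(y, prominence=prominence)
    if len(peaks) == 0:
        raise NoTransientError("no calcium transient detected")
    ys = _smooth(y, smooth_window, polyorder)
    dt = float(np.median(np.diff(t)))
    dydt = np.gradient(ys, dt)

    ups, downs, amps = [], [], []
    bounds = np.concatenate(([0], peaks, [len(y) - 1]))
    for k, p in enumerate(peaks):
        lo = bounds[k] if k == 0 else int(peaks[k - 1] + np.argmin(y[peaks[k - 1] : p + 1]))
        hi = (
            len(y) - 1
            if k == len(peaks) - 1
            else int(p + np.argmin(y[p : peaks[k + 1] + 1]))
        )
        rise = dydt[lo : p + 1]
        decay = dydt[p : hi + 1]
        if method == "max":
            ups.append(rise.max(initial=0.0))
            downs.append((-decay).max(initial=0.0))
        else:
            ups.append(max(float(np.mean(rise)), 0.0))
            downs.append(max(float(np.mean(-decay)), 0.0))
        amps.append(y[p] - min(y[lo], y[hi]))
    return TransientStats(
        upstroke_velocity_per_s=float(np.mean(ups)),
        downstroke_velocity_per_s=float(np.mean(downs)),
        peak_amplitude=float(np.mean(amps)),
        n_transients=len(peaks),
    )


# --------------------------------------------------------------------------- #
# per-pixel landmarks
# --------------------------------------------------------------------------- #


def _crossing_time(t: np.ndarray, y: np.ndarray, i: int, level: float) -> float:
    """Linear-interpolated time where ``y`` crosses ``level`` between i-1 and i."""
    if i == 0:
        return float(t[0])
    y0, y1 = y[i - 1], y[i]
    if y1 == y0:
        return float(t[i])
    frac = (level - y0) / (y1 - y0)
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def _landmarks(
    y: np.ndarray, frame_rate_hz: float, min_amplitude: float
) -> tuple[float, float] | None:
    """(activation_time_s, recovery_time_s) of the dominant transient, or None.

    Activation: last upward crossing of 50% amplitude before the peak.
    Recovery: first drop to 20% of amplitude above baseline after the peak.
    Baseline is the trace minimum (noise robustness is delegated to the
    beat-averaging and smoothing applied upstream); returns None for flat
    pixels or when the signal never recovers to 20% within the window.
    """
    y = np.asarray(y, dtype=float)
    t = np.arange(len(y)) / frame_rate_hz
    peak = int(np.argmax(y))
    base = float(y.min())
    amp = float(y[peak] - base)
    if amp <= min_amplitude or amp <= 0:
        return None
    lvl50 = base + 0.5 * amp
    lvl20 = base + 0.2 * amp
    before = y[: peak + 1]
    below = np.nonzero(before < lvl50)[0]
    if len(below) == 0:
        t_act = float(t[0])
    else:
        i = int(below[-1]) + 1
        t_act = _crossing_time(t, y, i, lvl50)
    after = y[peak:]
    rec = np.nonzero(after <= lvl20)[0]
    if len(rec) == 0:
        return None
    # noise-robust recovery time: first passage below the 20% level and last
    # exceedance above it bracket the true crossing with opposite first-order
    # biases; their midpoint cancels the bias (they coincide on a monotone decay)
    j_first = peak + int(rec[0])
    above = np.nonzero(after > lvl20)[0]
    t_first = _crossing_time(t, y, j_first, lvl20)
    j_last = peak + int(above[-1]) + 1
    if j_last >= len(y):
        t_last = float(t[-1])
    else:
        t_last = _crossing_time(t, y, j_last, lvl20)
    t_rec = 0.5 * (t_first + t_last)
    return t_act, t_rec


def cad80(
    pixel_trace: np.ndarray, frame_rate_hz: float, min_amplitude: float = 1e-9
) -> float | None:
    """Transient duration at 80% repolarization, in ms.

    Measured from activation (50% of the upstroke amplitude) to recovery to
    20% of the peak amplitude above baseline, linearly interpolated between
    frames.  Returns ``None`` (excluded pixel) for flat traces or traces that
    never repolarize to 20% within the window.
    """
    lm = _landmarks(pixel_trace, frame_rate_hz, min_amplitude)
    if lm is None:
        return None
    t_act, t_rec = lm
    return (t_rec - t_act) * 1e3


def activation_time(
    pixel_trace: np.ndarray,
    frame_rate_hz: float,
    reference_time_s: float = 0.0,
    min_amplitude: float = 1e-9,
) -> float | None:
    """Time of 50% depolarization relative to ``reference_time_s``, in ms.

    The first upward crossing of half the transient amplitude during the
    upstroke, linearly interpolated; ``None`` when no crossing exists.
    """
    y = np.asarray(pixel_trace, dtype=float)
    t = np.arange(len(y)) / frame_rate_hz
    peak = int(np.argmax(y))
    base = float(y.min())
    amp = float(y[peak] - base)
    if amp <= min_amplitude or amp <= 0:
        return None
    lvl50 = base + 0.5 * amp
    above = np.nonzero(y[: peak + 1] >= lvl50)[0]
    if len(above) == 0:
        return None
    t_cross = _crossing_time(t, y, int(above[0]), lvl50)
    return (t_cross - reference_time_s) * 1e3


# --------------------------------------------------------------------------- #
# isochrone maps
# --------------------------------------------------------------------------- #


def _estimate_pacing_onsets(mean_trace: np.ndarray, frame_rate_hz: float) -> np.ndarray:
    """Beat onsets (s) from the global mean trace: 50% crossings before peaks."""
    y = mean_trace
    prom = 0.3 * float(np.ptp(y))
    if prom <= 0:
        return np.array([])
    peaks, _ = signal.find_peaks(y, prominence=prom)
    if len(peaks) == 0:
        return np.array([])
    t = np.arange(len(y)) / frame_rate_hz
    decile = np.quantile(y, 0.1)
    base = float(y[y <= decile].mean())
    onsets = []
    for p in peaks:
        lvl = base + 0.5 * (y[p] - base)
        below = np.nonzero(y[: p + 1] < lvl)[0]
        if len(below):
            onsets.append(_crossing_time(t, y, int(below[-1]) + 1, lvl))
    return np.asarray(onsets)


def build_isochrone_maps(
    movie: CalciumMovie,
    detectability_threshold: float = 3.0,
    amplitude_floor_frac: float = 0.1,
    smooth_window: int = 11,
    polyorder: int = 3,
) -> IsochroneMap:
    """Per-pixel CaD80 and activation-time maps with coverage.

    Beats are aligned on the pacing onsets (given, or estimated from the
    global mean trace) and averaged per pixel; CaD80 and AT (relative to the
    beat onset) are then measured on the mean beat.  A pixel is *detectable*
    when its mean-beat amplitude is at least ``detectability_threshold`` times
    its frame-to-frame noise SD and at least ``amplitude_floor_frac`` of the
    95th-percentile amplitude over the disk (the absolute floor keeps
    signal-free pixels out of noiseless synthetic movies).  Coverage is the
    detectable fraction of the disk mask.
    """
    frames = movie.frames.astype(float)
    n_t, h, w = frames.shape
    mask = movie.disk_mask
    flat = frames.reshape(n_t, -1)
    midx = np.nonzero(mask.ravel())[0]
    traces = flat[:, midx]  # (T, P)

    if movie.pacing_onset_times_s is not None and len(movie.pacing_onset_times_s) > 0:
        onsets = np.asarray(movie.pacing_onset_times_s, dtype=float)
    else:
        onsets = _estimate_pacing_onsets(traces.mean(axis=1), movie.frame_rate_hz)
    fs = movie.frame_rate_hz
    if len(onsets) >= 2:
        period = float(np.median(np.diff(onsets)))
    else:
        period = n_t / fs if len(onsets) <= 1 else float(onsets[0])
        onsets = onsets if len(onsets) else np.array([0.0])
    beat_len = int(round(period * fs))
    beat_len = max(2, min(beat_len, n_t))

    # average complete beats, aligned on onsets; the first paced beat is
    # discarded when possible (it lacks the preceding beat's diastolic tail
    # and so differs from the periodic steady state)
    segs = []
    for t0 in onsets:
        i0 = int(round(t0 * fs))
        if 0 <= i0 and i0 + beat_len <= n_t:
            segs.append(traces[i0 : i0 + beat_len])
    if len(segs) >= 2:
        segs = segs[1:]
    if not segs:
        segs = [traces[:beat_len]]
    mean_beat = np.mean(segs, axis=0)  # (L, P)

    # temporal smoothing of the mean beat stabilizes the slow-decay landmarks
    # and keeps noise maxima out of the amplitude estimate
    if smooth_window > polyorder and mean_beat.shape[0] > smooth_window:
        smooth_beat = signal.savgol_filter(mean_beat, smooth_window, polyorder, axis=0)
    else:
        smooth_beat = mean_beat

    # per-pixel noise from first differences of the raw trace
    noise_sd = np.std(np.diff(traces, axis=0), axis=0) / np.sqrt(2.0)
    base = np.quantile(smooth_beat, 0.1, axis=0)
    amp = smooth_beat.max(axis=0) - base
    floor = amplitude_floor_frac * float(np.quantile(amp, 0.95))
    detectable = amp >= np.maximum(detectability_threshold * noise_sd, floor)

    cad = np.full(h * w, np.nan)
    at = np.full(h * w, np.nan)
    for j in np.nonzero(detectable)[0]:
        yb = smooth_beat[:, j]
        d = cad80(yb, fs)
        a = activation_time(yb, fs, reference_time_s=0.0)
        if d is not None:
            cad[midx[j]] = d
        else:
            detectable[j] = False
            continue
        if a is not None:
            at[midx[j]] = a

    det_mask = np.zeros(h * w, dtype=bool)
    det_mask[midx[detectable]] = True
    coverage = float(det_mask.sum() / mask.sum())
    return IsochroneMap(
        cad80_ms=cad.reshape(h, w),
        at_ms=at.reshape(h, w),
        detectable_mask=det_mask.reshape(h, w),
        coverage=coverage,
    )


# --------------------------------------------------------------------------- #
# radial profiles
# --------------------------------------------------------------------------- #


def radial_profile(
    image: np.ndarray,
    center_px: tuple[float, float],
    angle_rad: float,
    n_samples: int,
    window_mm: float,
    pixel_size_mm: float,
    mask: np.ndarray | None = None,
    r_max_mm: float | None = None,
    normalize: bool = False,
    label: str = "",
) -> RadialProfile:
    """Mean image values in windows along a radial ray from the disk centre.

    ``center_px`` is (row, col); the ray points at ``angle_rad``
    (counterclockwise from the +x / east direction, y up).  ``n_samples``
    positions are spaced evenly from ``window_mm/2`` to ``r_max_mm``; at each
    one the mean over a square window of side ``window_mm`` (bilinear
    sampling, NaN-ignoring) is recorded.  With ``normalize=True`` values are
    scaled by the profile maximum (F/F_max convention).
    """
    img = np.asarray(image, dtype=float)
    if mask is None:
        mask = np.isfinite(img)
    cy, cx = center_px
    if not (0 <= cy < img.shape[0] and 0 <= cx < img.shape[1]):
        raise ProfileError("center lies outside the image")
    drow = -np.sin(angle_rad)
    dcol = np.cos(angle_rad)
    if r_max_mm is None:
        # walk outwards until the ray exits the image or the mask
        step = pixel_size_mm / 2.0
        r = 0.0
        while True:
            rr = cy + drow * (r + step) / pixel_size_mm
            cc = cx + dcol * (r + step) / pixel_size_mm
            ir, ic = int(round(rr)), int(round(cc))
            if not (0 <= ir < img.shape[0] and 0 <= ic < img.shape[1]) or not mask[ir, ic]:
                break
            r += step
        r_max_mm = r
    r0 = window_mm / 2.0
    if r_max_mm <= r0:
        raise ProfileError("ray exits the mask before the first sample")
    radii = np.linspace(r0, r_max_mm, n_samples)

    half = window_mm / 2.0
    n_off = max(1, int(round(window_mm / pixel_size_mm)))
    offs = np.linspace(-half, half, 2 * n_off + 1)
    du, dv = np.meshgrid(offs, offs, indexing="ij")  # window grid in mm

    values = np.empty(n_samples)
    for i, r in enumerate(radii):
        rows = cy + (drow * r + du) / pixel_size_mm
        cols = cx + (dcol * r + dv) / pixel_size_mm
        samp = ndimage.map_coordinates(
            np.nan_to_num(img, nan=0.0), [rows.ravel(), cols.ravel()], order=1, mode="nearest"
        )
        wgt = ndimage.map_coordinates(
            (mask & np.isfinite(img)).astype(float),
            [rows.ravel(), cols.ravel()],
            order=1,
            mode="nearest",
        )
        values[i] = samp.sum() / wgt.sum() if wgt.sum() > 0 else np.nan
    if normalize:
        vmax = np.nanmax(values)
        if vmax > 0:
            values = values / vmax
    return RadialProfile(radii_mm=radii, values=values, label=label)


def radial_profile_from_mesh(
    per_element_values: np.ndarray,
    mesh,
    angle_rad: float,
    n_samples: int,
    window_mm: float = 1.5,
    label: str = "",
) -> RadialProfile:
    """Radial profile of a per-element mesh map (pressure or conductance).

    At each radial position the mean of the elements whose centroid lies
    within ``window_mm/2`` of the sample point is taken (falling back to the
    nearest centroid when the window is empty).
    """
    from scipy.spatial import cKDTree

    vals = np.asarray(per_element_values, dtype=float)
    if len(vals) != mesh.n_elements:
        raise DomainError("values do not match the mesh")
    r_edge = mesh.geometry.radius_mm
    r0 = window_mm / 2.0
    radii = np.linspace(r0, r_edge - r0, n_samples)
    direction = np.array([np.cos(angle_rad), np.sin(angle_rad)])
    tree = cKDTree(mesh.element_centroids)
    values = np.empty(n_samples)
    for i, r in enumerate(radii):
        pt = r * direction
        idx = tree.query_ball_point(pt, window_mm / 2.0)
        if idx:
            values[i] = vals[idx].mean()
        else:
            _, j = tree.query(pt)
            values[i] = vals[j]
    return RadialProfile(radii_mm=radii, values=values, label=label)
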