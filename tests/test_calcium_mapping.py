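"""Calcium traces, transient kinetics, CaD80/AT landmarks, isochrone maps, profiles."""

import numpy as np
import pytest

from cryomap import (
    CalciumMovie,
    CalciumTrace,
    activation_time,
    build_isochrone_maps,
    cad80,
    extract_trace,
    radial_profile,
    transient_stats,
)
from cryomap.exceptions import NoTransientError, ProfileError, RoiError
from cryomap.synthetic_data import CalciumPhantomSpec, simulate_calcium_movie

FS = 500.0  # frames per second of the optical-mapping cameras


@pytest.fixture(scope="module")
def small_movie():
    """40 x 40 px, 4 s paced phantom with mild noise."""
    spec = CalciumPhantomSpec(
        grid=(40, 40), pixel_size_mm=0.75, duration_s=4.0, noise_sd=0.005, seed=3
    )
    return simulate_calcium_movie(spec)


class TestExtractTrace:
    def test_constant_movie_normalizes_to_one(self):
        movie = CalciumMovie(np.full((50, 8, 8), 7.0), frame_rate_hz=FS)
        roi = np.zeros((8, 8), bool)
        roi[2:5, 2:5] = True
        trace = extract_trace(movie, roi)
        assert np.allclose(trace.f_over_f0, 1.0)
        assert trace.baseline_f0 == pytest.approx(7.0)

    def test_known_peak_over_baseline(self):
        # transient train with baseline b and peak 2b -> F/F0 peak ~ 2
        t = np.arange(int(4 * FS)) / FS
        pulse = np.clip(np.sin(2 * np.pi * 1.0 * t), 0.0, None) ** 4
        b = 120.0
        frames = (b * (1.0 + pulse))[:, None, None] * np.ones((1, 6, 6))
        trace = extract_trace(CalciumMovie(frames, frame_rate_hz=FS), np.ones((6, 6), bool))
        assert trace.f_over_f0.max() == pytest.approx(2.0, rel=0.02)

    def test_roi_validation(self, small_movie):
        movie, _ = small_movie
        with pytest.raises(RoiError):
            extract_trace(movie, np.zeros(movie.disk_mask.shape, bool))
        outside = np.zeros(movie.disk_mask.shape, bool)
        outside[0, 0] = True  # image corner, off the disk
        with pytest.raises(RoiError):
            extract_trace(movie, outside)


def piecewise_linear_trace(rise_s, fall_s, fs=100.0, pad_s=1.0):
    t_r = np.arange(0, rise_s, 1 / fs)
    t_f = np.arange(0, fall_s, 1 / fs)
    y = np.concatenate(
        [
            np.ones(int(pad_s * fs)),
            1.0 + t_r / rise_s,
            2.0 - t_f / fall_s,
            np.ones(int(pad_s * fs)),
        ]
    )
    t = np.arange(len(y)) / fs
    return CalciumTrace(time_s=t, f_over_f0=y, baseline_f0=1.0)


class TestTransientStats:
    def test_piecewise_linear_velocities(self):
        # rise 0 -> 1 over 2 s and fall over 4 s: velocities 0.5 and 0.25 /s
        stats = transient_stats(piecewise_linear_trace(2.0, 4.0))
        assert stats.upstroke_velocity_per_s == pytest.approx(0.5, rel=0.02)
        assert stats.downstroke_velocity_per_s == pytest.approx(0.25, rel=0.02)
        assert stats.n_transients == 1

    def test_symmetric_pulse_has_equal_velocities(self):
        stats = transient_stats(piecewise_linear_trace(3.0, 3.0))
        assert stats.upstroke_velocity_per_s == pytest.approx(
            stats.downstroke_velocity_per_s, rel=0.01
        )

    def test_flat_trace_rejected(self):
        flat = CalciumTrace(np.arange(100) / FS, np.ones(100), 1.0)
        with pytest.raises(NoTransientError):
            transient_stats(flat)


class TestCad80:
    def test_linear_decay_closed_form(self):
        # instantaneous rise at t=0, linear decay to baseline over 1000 ms:
        # 80% repolarization at 800 ms
        t = np.arange(int(1.5 * FS)) / FS
        y = np.clip(1.0 - t / 1.0, 0.0, None)
        assert cad80(y, FS) == pytest.approx(800.0, abs=2.0)

    def test_exponential_decay_closed_form(self):
        # recovery to 20% of an exponential with tau = 500 ms at tau * ln 5
        # (window long enough that the trace reaches its baseline)
        tau = 0.5
        t = np.arange(int(5.0 * FS)) / FS
        y = np.exp(-t / tau)
        assert cad80(y, FS) == pytest.approx(tau * np.log(5.0) * 1e3, abs=2.0)

    def test_flat_pixel_excluded_not_raised(self):
        assert cad80(np.zeros(500), FS) is None

    def test_never_recovering_pixel_excluded(self):
        t = np.arange(int(1.0 * FS)) / FS
        y = np.minimum(t / 0.05, 1.0)  # rises, never repolarizes
        assert cad80(y, FS) is None


class TestActivationTime:
    def test_step_at_100_ms(self):
        y = np.zeros(200)
        y[50:] = 1.0  # step at exactly 100 ms at 500 fps
        assert activation_time(y, FS) == pytest.approx(100.0, abs=2.0)

    def test_linear_ramp_midpoint(self):
        t = np.arange(200) / FS
        y = np.clip(t / 0.2, 0.0, 1.0)
        assert activation_time(y, FS) == pytest.approx(100.0, abs=2.0)

    def test_relative_to_reference(self):
        y = np.zeros(200)
        y[50:] = 1.0
        assert activation_time(y, FS, reference_time_s=0.05) == pytest.approx(50.0, abs=2.0)

    def test_flat_pixel_undefined(self):
        assert activation_time(np.zeros(200), FS) is None


class TestIsochroneMaps:
    def test_uniform_movie_full_coverage_constant_cad80(self):
        spec = CalciumPhantomSpec(
            grid=(24, 24),
            pixel_size_mm=1.25,
            duration_s=4.0,
            conduction_velocity_mm_s=1e6,  # effectively simultaneous activation
            noise_sd=0.0,
            seed=0,
        )
        movie, truth = simulate_calcium_movie(spec)
        iso = build_isochrone_maps(movie)
        assert iso.coverage == pytest.approx(1.0)
        vals = iso.cad80_ms[np.isfinite(iso.cad80_ms)]
        assert np.ptp(vals) < 2.0  # one frame interval across identical pixels
        # smoothing distortion keeps the pipeline within 2% of the dense oracle
        assert np.median(vals) == pytest.approx(truth["waveform"]["cad80_ms"], rel=0.02)

    def test_half_disk_without_signal_halves_coverage(self, small_movie, rng):
        movie, _ = small_movie
        frames = movie.frames.copy()
        rows = np.arange(40)
        lower = (19.5 - rows) < 0  # image rows below the horizontal midline
        base = np.where(movie.disk_mask, 1000.0, 50.0)
        flat = base[None] + 5.0 * rng.standard_normal(frames.shape)
        frames[:, lower, :] = flat[:, lower, :].astype(np.float32)
        silenced = CalciumMovie(
            frames, movie.frame_rate_hz, movie.pixel_size_mm, movie.disk_mask,
            movie.pacing_onset_times_s,
        )
        iso = build_isochrone_maps(silenced)
        assert iso.coverage == pytest.approx(0.5, abs=0.02)

    def test_lesion_silences_region_at_catheter_site(self):
        spec = CalciumPhantomSpec(
            grid=(40, 40), pixel_size_mm=0.75, duration_s=4.0, noise_sd=0.005,
            seed=3, lesion_amplitude_factor=0.0,
        )
        movie, truth = simulate_calcium_movie(spec)
        iso = build_isochrone_maps(movie)
        undetectable = movie.disk_mask & ~iso.detectable_mask
        assert undetectable.any()
        rows, cols = np.nonzero(undetectable)
        x = (cols - 19.5) * 0.75
        y = (19.5 - rows) * 0.75
        assert np.hypot(x.mean() - 7.5, y.mean()) < 1.0

    def test_coverage_monotone_in_threshold(self, small_movie):
        movie, _ = small_movie
        coverages = [
            build_isochrone_maps(movie, detectability_threshold=thr).coverage
            for thr in (1.0, 3.0, 10.0, 40.0)
        ]
        assert all(0.0 <= c <= 1.0 for c in coverages)
        assert all(a >= b for a, b in zip(coverages, coverages[1:]))

    def test_wavefront_speed_recovered_from_at_map(self, small_movie):
        movie, truth = small_movie
        iso = build_isochrone_maps(movie)
        ok = np.isfinite(iso.at_ms) & np.isfinite(truth["distance_to_pacing_mm"])
        slope = np.polyfit(
            truth["distance_to_pacing_mm"][ok], iso.at_ms[ok] / 1e3, 1
        )[0]
        assert slope == pytest.approx(1.0 / truth["conduction_velocity_mm_s"], rel=0.05)


class TestRadialProfile:
    def test_constant_image_flat_profile(self):
        prof = radial_profile(
            np.full((41, 41), 3.0), (20, 20), angle_rad=0.7, n_samples=8,
            window_mm=1.0, pixel_size_mm=0.5, r_max_mm=8.0,
        )
        assert np.allclose(prof.values, 3.0)

    def test_distance_image_reproduces_radii(self):
        px = 0.375
        rows, cols = np.mgrid[0:81, 0:81]
        img = np.hypot((cols - 40) * px, (40 - rows) * px)
        prof = radial_profile(
            img, (40, 40), angle_rad=0.0, n_samples=10, window_mm=0.75,
            pixel_size_mm=px, r_max_mm=12.0,
        )
        assert np.max(np.abs(prof.values - prof.radii_mm)) < px / 2

    def test_normalized_profile_peaks_at_one(self):
        rows, cols = np.mgrid[0:41, 0:41]
        img = np.exp(-((cols - 30.0) ** 2 + (rows - 20.0) ** 2) / 20.0)
        prof = radial_profile(
            img, (20, 20), 0.0, 12, window_mm=1.0, pixel_size_mm=0.75,
            r_max_mm=14.0, normalize=True,
        )
        assert prof.values.max() == pytest.approx(1.0)

    def test_ray_leaving_mask_immediately_rejected(self):
        img = np.ones((21, 21))
        mask = np.zeros((21, 21), bool)
        mask[10, 10] = True  # only the centre pixel is valid
        with pytest.raises(ProfileError):
            radial_profile(img, (10, 10), 0.0, 5, window_mm=2.0, pixel_size_mm=1.0, mask=mask)
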