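# Methods

This note records the models implemented in `cryomap`, the assumptions they
make, the parameter choices that matter, and what the synthetic benchmarks
do — and do not — establish about real recordings.

## Sensor forward model

The sensing element is a thin circular layer of ionic hydrogel (radius
15 mm, thickness d₀ = 4 mm) with `n = 8` copper electrodes evenly spaced on
the boundary. Because the layer is thin relative to its diameter and the
bulk conductivity σ₀ of the ionic hydrogel is deformation-independent, the
electrical problem is treated as a two-dimensional sheet: the potential
satisfies ∇·(σ_s∇u) = 0 with sheet conductance σ_s = σ·d₀, discretized with
linear (P1) finite elements. The 20 kHz excitation carrier is not
simulated; the DC solution stands for the RMS amplitude that the
acquisition electronics report (each reading averages 100 samples at
400 kHz, i.e. exactly five carrier periods).

*Mesh.* A structured concentric-ring triangulation is used: ring k of R
carries m·k nodes, giving exactly m·R² positively oriented triangles. m is
constrained to a multiple of the electrode count so that the mesh is
*exactly* invariant under rotation by one electrode spacing and a boundary
node falls on every electrode angle; diagonal tie-breaks during ring
stitching are decided in exact integer arithmetic so the symmetry holds to
machine precision. For the default target of 576 elements the layout is
m = 16, R = 6 (96 boundary nodes, mean element area ≈ 1.23 mm²). The
polygonal boundary under-covers the disk by sin(x)/x with x = 2π/96, about
0.07% — well inside the 2% budget used by the mesh-conservation checks.

*Electrodes.* Each electrode is a short boundary arc (default 9°, i.e.
three boundary nodes at the default discretization); drive current is split
evenly over the arc nodes and the electrode potential is the arc-node mean.
This symmetric choice makes discrete reciprocity exact. Contact impedance
is not modelled (no complete-electrode model): the hardware's contact
properties are unknown, and difference imaging cancels stationary electrode
effects to first order. The arc width is configuration, not physics.

*Patterns.* Adjacent stimulation with adjacent measurement, skipping
measurement pairs that share a drive electrode: n(n−3) = 40 entries for 8
electrodes, enumerated drive-major, both indices increasing
counterclockwise from electrode 0 (east).

## Difference imaging

Reconstruction is the standard one-step linearized Gauss–Newton update for
difference EIT:

    Δσ = (JᵀJ + λ²R)⁻¹ Jᵀ (v − v₀),   R = diag(JᵀJ)ᵖ

with J the adjoint-field Jacobian at the homogeneous baseline (validated
against finite differences to <10⁻³ relative error) and the output reported
as the relative conductance variation Δσ/σ₀, negative under compression.
Identical frames give an exactly zero map and the estimate is linear in
(v − v₀) by construction.

Two hyperparameters are free because the hardware study does not state its
values:

* **NOSER exponent p (default 0.25).** The classic prior (p = 1) and the
  common variant (p = 0.5) both over-penalize the high-sensitivity boundary
  elements of this point-arc electrode model, dragging reconstructions of
  off-centre presses roughly 2 mm toward the disk centre. A design scan
  over p ∈ {0.25, 0.5, 1}, λ-fraction ∈ {10⁻², 10⁻¹, 1} and electrode arcs
  {9°, 22.5°} (presses at radii 2.5–10 mm, with and without measurement
  noise) showed the flattened depth weighting p = 0.25 removes most of the
  radial bias: mean error over a 20-site grid 0.72 ± 0.49 mm, and the
  radial profile of a press at 7.5 mm peaks within 0.2 mm of the true
  radius. Both classic values remain selectable.
* **Regularization weight λ.** Default λ² = f·tr(JᵀJ)/tr(R) with f = 0.1 —
  the penalty trace is a fixed fraction of the data-term trace, which makes
  λ independent of the physical scaling of J (for p = 1 it reduces to
  λ² = f). Localization was insensitive to f over 10⁻⁴…0.3 in the design
  scan; map amplitude, as always in one-step imaging, is λ-dependent and is
  absorbed by calibration.

## Pressure model and calibration

For an infinitesimal block of the conductive layer (length L₁ along the
current, width L₂, thickness d₀), Pouillet's law with constant σ₀ gives a
conductance change linear in the vertical compressive strain ε:
Δk = σ₀εL₂d₀/L₁. Within the linear elastic region (ε < 0.5) the pressure is
p = Eε with E ≈ 16 kPa, so pressure is linear in the conductance variation;
the two forms round-trip algebraically to machine precision.

Two calibration routes are provided and deliberately kept distinct:

* `fit_calibration` on a (pressure, variation) table — the material-model
  line; its slope recovers E.
* `calibrate_from_press_phantoms` — press the simulated sensor at known
  forces, reconstruct, read the mean conductance reduction over the located
  six-element press region, and regress pressure on that response. This is
  the route a physical bench uses, and its slope absorbs the amplitude
  scaling of the one-step reconstruction (the reconstructed variation under
  a press is a factor of several smaller than the local material change).
  With it, a held-out 0.1 N press reads back within ~20% of the nominal
  14.1 kPa contact pressure.

Pressure maps clip positive (tensile) reconstructed variations to zero —
the model covers compression only — and the clip count is logged. Press
localization takes the six most-negative elements (ties broken by element
index for determinism; six elements ≈ one presser footprint in area) and
returns their area-weighted centroid. Spatial accuracy is summarized as the
mean ± SD of per-site distances after rigid ICP alignment (nearest-neighbour
correspondence, closed-form SVD update, centroid pre-alignment,
tolerance 10⁻⁸, ≤100 iterations); because the pairing convention of a
physical gantry run may be known, the known-correspondence Procrustes error
is reported alongside.

## Calcium optical mapping

Traces are spatial means over a region of interest, normalized by
F₀ = mean of the lowest decile of the trace (robust to pacing duty cycle).
Upstroke/downstroke velocities are maxima of the smoothed d(F/F₀)/dt during
rise and decay, averaged over detected transients. The smoothing is
Savitzky–Golay with window 11 and polynomial order 1 — i.e. a moving
average. Order 1 is deliberate: higher-order kernels have negative side
lobes that overshoot the derivative maximum by ~10% at the foot of a
transient, so a piecewise-linear pulse would not return its exact slopes.
A mean-derivative variant is selectable.

Per-pixel landmarks use a minimum-referenced amplitude: activation is the
last upward crossing of 50% of (peak − min) before the peak; CaD80 runs
from activation to recovery at 20% of the amplitude above the minimum, both
linearly interpolated between frames. The recovery time is the midpoint of
the first passage below the 20% level and the last exceedance above it —
the two bracket the true crossing with opposite first-order noise biases
and coincide exactly on monotone decays, so closed-form templates are
unaffected while the estimator stays stable on slow, noisy decays.

Isochrone maps are computed on the beat-averaged transient: beats are
aligned on pacing onsets (taken from the movie metadata, or estimated as
50%-rise crossings of the global mean trace), the first paced beat is
discarded when more than one complete beat exists (it lacks the preceding
beat's diastolic tail and so differs from the periodic steady state), and
the average beat is Savitzky–Golay smoothed (window 11, order 3) before
landmark extraction. A pixel is *detectable* when its mean-beat amplitude
is at least 3× its frame-to-frame noise SD and at least 10% of the disk's
95th-percentile amplitude; the absolute floor keeps signal-free pixels out
of noiseless synthetic movies, and coverage (detectable fraction of the
disk) is monotone non-increasing in the threshold by construction.

Radial profiles average the image over square windows centred at evenly
spaced positions along a ray from the disk centre, with bilinear sampling
and NaN-aware weighting; mesh-valued maps (pressure, conductance) are
sampled by averaging element centroids within the window radius. Calcium
profiles can be normalized to the disk maximum (F/F_max).

## Pressure–calcium correlation

Each calcium sample is paired with the pressure sample at the nearest
radius (ties toward the smaller radius; calcium sampling is the sparser of
the two, and the direction is configurable) and Pearson's ρ is computed
over the matched pairs. The pairing is a function of the radii alone.
Condition reports add per-radius pre/post intensity changes and two
qualitative flags: ρ < −0.5 (lesion co-located with contact) and |ρ| < 0.3
(pressure unrelated to the calcium response). Significance testing of
pre/post changes is deliberately left to standard statistical routines.

## Synthetic data: what it emulates, and what it does not

*Press phantoms* invert the pressure model: truth pressure is force over
presser area inside the 3 mm footprint (0.1 N ⇒ 14.1 kPa ⇒ ε = 0.88;
0.01 N ⇒ 1.41 kPa), footprint element conductivity is scaled by (1 − ε),
and frames come from the forward model with optional relative Gaussian
measurement noise on both frames independently. The perturbation is
footprint-only: no lateral mechanical coupling is modelled, because the
linear model is local and no continuum-mechanics description of the layer
is available. Note ε = 0.88 for the normal-therapy force is far outside
the linear elastic region — the generator applies the linear model as
stated, which is one reason reconstructed amplitudes need the
sensor-response calibration.

*Calibration tables* place (pressure, variation) pairs on the model line
over the study's force range (0.01–0.1 N) with Gaussian scatter of SD 0.03
strain units, chosen analytically (σ² = var(ε)·(1 − R²)/R²) so that an
n = 15 sweep exhibits R² ≈ 0.983, the scatter level a physical sensor
bench shows.

*Calcium movies* give every pixel a transient train delayed by
distance-to-pacing-site over the conduction velocity. The waveform is the
minimal two-rate shape (1 − e^(−t/τ_up))·e^(−t/τ_down). Defaults: τ_up
80 ms, τ_down 480 ms, amplitude 5% of baseline, conduction velocity
150 mm/s (human iPSC-derived monolayer range; the 30 mm disk activates
within ~0.18 s of each 1 Hz pacing stimulus), pixel noise 0.5% of baseline,
15 s at 500 frames/s on an 80 × 80 grid. At 1 Hz a 480 ms decay does not
finish between beats, so each transient rides on the previous tail; the
truth record therefore evaluates CaD80/AT on the *periodic steady-state*
waveform by a dense-time (0.02 ms) brute-force oracle, which is what the
beat-averaged measurement estimates. The steady-state CaD80 of the default
kinetics is ≈ 682 ms. With a 5% amplitude the same kinetics put the
measured uptake rate near 0.1 s⁻¹ with release several-fold faster; a
double exponential cannot simultaneously reproduce both reported
trace-velocity magnitudes and this CaD80 at 1 Hz, and the optical-mapping
quantities were prioritized. Lesions scale local amplitude by a factor in
[0, 1] inside a 3 mm disk at (7.5, 0) mm — the catheter position — with a
sigmoid edge of configurable width (default 0.3 mm; real lesion edge
sharpness is unknown, so it is a parameter rather than an assertion).

*Condition profiles* generate paired pressure/calcium radial profiles at
the statistic level (Gaussian pressure bump at 7.5 mm scaled to the
condition's contact pressure; flat calcium suppressed by a condition-
specific lesion depth of 0.85 / 0.35 / 0 for normal therapy / failed
contact / force only). Calcium is sampled at 61 radii over 0–12 mm —
dense enough that a null correlation concentrates below |ρ| = 0.3 — and
pressure at 121.

What passing tests show: the estimators recover the generators' known
parameters (localization < 2 mm noiseless, calibration slope to 1%/5%,
CaD80/AT to closed forms within one 2 ms frame and to generator truth
within 5%, condition signs in ≥95% of replicates). What they do not show:
robustness to motion, photobleaching, heterogeneous tissue excitability
(real disks had detectable signal over only about half their area —
coverage of the homogeneous phantom is ~100% by design), electrode drift,
temperature dependence of the hydrogel conductance, or viscoelastic
creep — none of which the generators model.

## Numerical choices and degenerate inputs

* Forward system grounded at the centre node (rotation-invariant gauge);
  factorized once per conductivity field and reused across drive pairs.
* Jacobian rows reuse the adjacent-pair fields (measure pairs are drive
  pairs), so one factorization yields the whole matrix.
* Zero-area triangles, non-positive conductivities, empty ROIs, flat maps
  (no press), flat traces (no transient), all-equal calibration tables and
  sub-minimal point sets raise typed exceptions rather than returning
  NaNs; never-repolarizing or flat pixels are excluded from isochrone maps
  rather than raised.
* All generators are bit-deterministic under a fixed seed
  (`numpy.random.default_rng`); derived seeds stay below 2³¹.

## Problem sizes

The shipped configuration mirrors the hardware scales throughout: 576
elements, 40 measurements, 80 × 80 px movies at 500 frames/s. Unit tests
run reduced variants (40 × 40 movies, 2–8 s of pacing) chosen to keep the
estimators in the same operating regime (≥2 averaged steady-state beats);
the acceptance script runs the full-scale configuration.

## Known limitations

* One-step linearized reconstruction: amplitudes are calibration-dependent
  and large conductivity contrasts (deep presses) are outside the
  linearization; only difference imaging is supported, not absolute EIT.
* Point-arc electrode model without contact impedance; 3-D effects of the
  layered silicone/hydrogel stack are not modelled.
* The press-location estimator assumes a single press; multi-site contact
  would need connected-component analysis before centroiding.
* Pacing-onset estimation from the global trace assumes a dominant paced
  rhythm; strongly ectopic or fibrillatory activity would need external
  onset annotations.
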