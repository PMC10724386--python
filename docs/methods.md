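# Methods

This note documents the models, numerical choices and known limitations of
the `hvmudi` pipeline, in the order the data flow through it.

## Acquisition model and conventions

All arrays are indexed `(x, z, t, angle)`: `x` lateral, `z` axial depth
(increasing away from the transducer), `t` slow time at the effective frame
rate `FR = PRF / NA`, angles ordered as configured. Flow direction `θ_D` is
measured from the +z axis toward +x, so purely descending flow has
`θ_D = 0` and broadside flow toward +x has `θ_D = 90°`. The per-angle
axial-velocity projection is `v_axial(θᵢ) = v·cos(θ_D + θᵢ)`, and the
unambiguous axial velocity is `c·FR / (4 f_c)` (4.8125 mm/s at 40 MHz,
FR = 500 Hz).

Reference configuration (`reference_acquisition_config`): f_c = 40 MHz,
PRF = 3500 Hz, seven tilt angles −3°..+3° in 1° steps (FR = 500 Hz),
c = 1540 m/s, pixel pitch 19.25 µm (half a wavelength). Ensemble length
defaults to 200 compounded frames (0.4 s at 500 Hz) and is configurable.

## Phantom simulator

The simulator works directly in image space: the estimators downstream
consume only inter-frame phase and temporal spectra, so acoustic
propagation and beamforming add nothing to what the pipeline can be tested
against, at considerable cost. Three components are summed per angle:

* **Blood**: a frozen complex circular-Gaussian speckle field (spatially
  smoothed to a 1 px correlation length, unit mean power inside the tube)
  advanced at each tilt angle by the analytic phase increment
  `∅ᵢ = 4π f_c v cos(θ_D + θᵢ) / (c·FR)` per frame. Plug profile by
  default; parabolic optional.
* **Clutter**: five separable components (spatially smooth complex field ×
  complex tone), mode frequencies spread over [0, 10] Hz as
  `f_k = 10·(k/4)²` Hz and powers decaying 20 dB per mode, total power
  30 dB above blood. This mimics the steep spectral decay of quasi-static
  tissue and confines the clutter's Casorati energy to five singular
  components by construction. A flat 0–10 Hz clutter spectrum at 30 dB
  would fully overlap the slow-flow Doppler band (a 1.8 mm/s broadside
  flow projects at ≤ 4.9 Hz) and make the validation scene unrecoverable
  by any temporal filter.
* **Noise**: circular white complex noise at 20 dB below the per-voxel
  blood power.

What the simulator deliberately does *not* model: scatterer translation
(speckle decorrelation and transit-time spectral broadening), depth
attenuation, aliasing correction, and any point-spread function beyond the
speckle correlation length. Passing tests therefore demonstrate the
correctness of the estimator chain under the stated signal model, not
robustness to decorrelation — the phase model is exact in the simulator,
so accuracy results are upper bounds on real-data performance.

Plug flow has one consequence worth naming: every in-tube voxel shares the
same temporal signature, so the blood contributes exactly *one* singular
component to each Casorati block, and broadside geometry makes that
component's mean Doppler frequency ≈ 0. This is the hardest case for any
frequency-based clutter/blood discrimination and shapes several choices
below.

## Block-wise SVD filter and adaptive thresholds

Blocks are 64×64 pixels (border blocks shifted inward to keep full size),
90 % overlap, recombined with a separable Hann taper normalized pixel-wise
(an exact partition of unity, so pass-through filtering reproduces the
input bit-for-bit up to rounding). Each block's decomposition is computed
through the temporal Gram matrix `AᴴA` (N_t × N_t), which is exact and an
order of magnitude cheaper than a full SVD when rows ≫ columns; the
filtered block is the projection `A V_δ V_δᴴ`.

Threshold selection per block, on `y = log₁₀ σ_k`:

* **Noise plateau** `T_H`: first order where the 5-point moving slope of
  `y` exceeds −0.01 per order. If that happens at the start of the curve
  the block is noise-dominated and the thresholds fall back to
  `(T_L, T_H) = (2, N_t)`.
* **Turning point**: the clutter knee is the order lying deepest below the
  chord drawn from the first order to the plateau; the turning point is
  the next order. (A second-difference sign-change rule was evaluated and
  found unstable on realistic spectra: the curvature sign at the
  clutter/blood boundary flips from block to block.) Curves with no sag
  below the chord, or whose knee coincides with the plateau corner, carry
  no clutter-shelf information; the turning point is then 1 and the
  frequency criterion below decides alone.
* **`T_L`**: the smallest order at or after the turning point whose
  temporal singular vector has a mean Doppler frequency (lag-1
  autocorrelation, `f = FR·arg(Σ v[t+1]v*[t])/2π`) above the clutter band
  parameter `f_clutter` (default 10 Hz). If no such order exists before
  the plateau — the generic case for broadside flow, whose compounded
  mean Doppler is ≈ 0 — `T_L` is the turning point itself: for such flows
  the magnitude curve is the only discriminating information available.

## Adaptive high-pass cutoff

The cutoff handed to the vector-flow stage starts from the lag-1 frequency
of the `T_L`-th singular vector and is floored at

* 1.25 × the largest mean Doppler frequency in the *rejected* subspace
  (orders < `T_L`): the temporal filter must clear the frequencies of what
  the SVD classified as clutter, and
* 1.5 spectral bins (`1.5·FR/N_t`, 3.75 Hz at the reference conditions):
  lag-1 frequencies on an N_t-sample vector are meaningless below the
  record's spectral resolution, and a Butterworth design with near-zero
  normalized cutoff is numerically ill-posed.

For asymmetric (non-broadside) blood spectra the first term dominates and
the rule reduces to "frequency of the first retained vector". The global
cutoff is the median of per-block cutoffs; cutoff estimation tiles with
50 % overlap (the 90 % overlap only matters for artifact-free image
reconstruction, not for a scalar median) and per-block values are logged.

## Temporal high-pass and phase estimation

The fifth-order Butterworth high-pass is applied forward-backward
(zero-phase) along slow time, per angle and voxel, with maximal edge
padding. At clutter-scale cutoffs the filter's settling transient spans
roughly `FR/f_cut` samples — a sizable fraction of a 200-frame ensemble —
and measurably biases the lag-1 phase of near-cutoff tones (up to 15 % in
frequency). The pipeline therefore drops an *edge guard* of `N_t/5` frames
at each end of the filtered series before phase estimation; the
time-resolved output length is `(N_t − 2·guard) − window + 1`. A
frequency-domain application of the squared Butterworth magnitude response
is available (`HighPassSpec(mode="fft")`); it is transient-free but lets
off-bin narrowband clutter leak through the circular spectrum, so it is
not the default.

The lag-1 phase is computed per voxel and angle over the full (guarded)
ensemble, or over a sliding window (default exposed as a parameter,
10 frames = 20 ms when time-resolved traces are wanted). The magnitude of
the lag-1 autocorrelation is retained as a coherence weight.

## Multibeam least squares

The model `v_axial(θᵢ) = a·cosθᵢ − b·sinθᵢ` (`a = v·cosθ_D`,
`b = v·sinθ_D`) is solved per voxel by weighted linear least squares via
the 2×2 normal equations, with design columns normalized first: at a ±3°
tilt span the raw columns differ by a factor ~19 in norm and the lateral
component is recovered from an 0.1-radian baseline, so conditioning
matters. Voxels whose weighted normal matrix has a condition number above
10⁶ are flagged invalid.

The full pipeline weights each angle's equation by its lag-1 coherence
`|R₁|`. This matters because the adaptive high-pass removes the blood
tone at angles whose projected Doppler falls below the cutoff (including
the 0° angle at broadside, whose projection is zero anyway); the lag-1
phase of filtered noise is essentially uniform on (−π, π], and without
weighting those angles inject near-Nyquist pseudo-velocities into the
slope fit. Plain unweighted least squares remains the default of
`solve_vector` itself.

No phase unwrapping is attempted: projections that would alias are the
user's responsibility to avoid (the simulator warns).

## Vessel enhancement

Bowler-hat: grey openings by disks of radius 1..r_max versus the maximum
over a line bank (length 2r+1, 12 orientations over 180°); the output is
the maximum over radii of the line−disk difference, clipped at zero. The
orientation bank's upper half is constructed as the exact 90° rotation of
its lower half, and each line element is point-symmetric by construction,
which makes the transform exactly equivariant under quarter-turn
rotations (naive rounding of rotated line coordinates breaks this at
half-integer ties). Default r_max = 30 px with the 180° span.

Vesselness: Gaussian-derivative Hessians at σ ∈ {1.0, 1.5, 2.0} px
(σ²-normalized; derivative kernels corrected to sum exactly to zero so a
flat field maps to exactly zero), eigenvalue response with α = 2, β = 1,
maximum over scales. The enhanced image is the *vesselness-weighted*
bowler-hat response (their product): background must be both bright after
the morphological bank and curvilinear to survive, and the two
suppressions compound. Because α is an absolute number while image gain
is arbitrary, the bowler-hat response is first rescaled so its peak
Hessian norm equals 2α — the standard vesselness calibration in which the
brightest structure scores 1 − e⁻² on the structureness factor.

Binarization keeps pixels within 3 dB of the enhanced image's maximum
(`I > I_max/10^{3/10}`); the skeleton is a medial-axis thinning, and
skeleton orientations come from the principal axis of the 7×7 local
skeleton neighborhood.

## Quantification

* **Density**: vessel-pixel percentage of the ROI.
* **Diameter**: intensity sampled by bilinear interpolation along the
  normal to the local skeleton orientation, initial segment one
  wavelength long, grown by 10 µm per iteration (up to 30 iterations)
  until two half-maximum crossings bracket the peak; crossings located by
  linear interpolation. The growth budget spans vessels several hundred
  µm wide — a 10-iteration budget cannot span a 280 µm vessel given the
  38.5 µm initial segment. Unresolved pixels are excluded from means.
* **Trajectories / SOAM**: velocity components are Gaussian-smoothed
  (σ = 2 px), trajectories integrated with the explicit first-order
  update `P ← P + v(P)/FR` (bilinear lookup) until mask exit, sub-floor
  speed, or a length cap; SOAM sums the bending angle at every interior
  point and divides by the full path length. Trajectories with fewer than
  three points are undefined and excluded.
* **Pulsatility index**: (max − min)/mean of the signed speed along the
  vessel's mean flow direction, so reversals deepen the minimum; zero
  mean → undefined.
* **Reversal ratio**: after the same σ = 2 px smoothing, a pixel reverses
  when the sign-change count of its horizontal *or* vertical velocity
  over time reaches 3 ("more than two times"); frames at exactly zero
  never count as a change (the last nonzero sign is carried forward).
* **Classification**: per connected component, mean axial velocity beyond
  ±5 % of the component's mean speed ⇒ penetrating arteriole (descending)
  or ascending venule; otherwise unclassified. Per-class statistics are
  computed per component and averaged weighted by pixel count.

## Validation campaign and problem sizes

The in-silico twin of the flow-phantom experiment uses a 128×128 grid
(19.25 µm pitch), a 280 µm tube at mid-depth perpendicular to the beam,
plug flow at the eight presets 1.8..14.4 mm/s, clutter 30 dB above blood,
SNR 20 dB, 200 frames, four seeded repetitions — 32 simulated acquisitions
in total, a few minutes single-core. Under these conditions the maximum
preset-averaged relative error of the in-tube mean speed is ~3 % and the
circular-mean direction is within a fraction of a degree of broadside
(`scripts/acceptance.py` recomputes both). Unit and property tests use
smaller grids (32–96 px) and shorter ensembles (24–150 frames); the
spectral-resolution floor scales accordingly (`1.5·FR/N_t`).

## Known limitations

* The clutter/blood boundary in the singular spectrum is genuinely
  ambiguous for broadside plug flow (blood is rank-1 with ≈ 0 mean
  Doppler); the chord-knee rule resolves it under the simulator's
  conditions but has no optimality claim on in-vivo spectra.
* FWHM diameters on single-realization speckle images carry grain at the
  speckle correlation scale; practical use should measure on a smoothed
  or enhanced image (the test suite smooths the echo amplitude with a
  2 px Gaussian, which preserves a top-hat's half-maximum positions).
* The vesselness scale range (σ ≤ 2 px) targets few-pixel vessels; much
  wider structures respond only at their edges unless scales are widened.
* Velocities whose per-angle projections alias are flagged, not
  corrected.
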