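# hvmudi — high-resolution vector micro-Doppler imaging

`hvmudi` is a contrast-free processing pipeline for ultrafast plane-wave
ultrasound that turns raw per-angle IQ ensembles into enhanced vascular
images, per-voxel vector velocity fields, and hemodynamic statistics of the
microcirculation (vascular density, vessel diameter, tortuosity,
pulsatility, flow reversal). It is aimed at preclinical cerebrovascular
imaging — micro-vessels of tens to hundreds of µm carrying flows of a few
mm/s — where contrast agents are undesirable and both high spatial and high
temporal (hundreds of Hz) resolution are needed at once.

## The method

An acquisition transmits plane waves at `NA` tilt angles θ₁..θ_NA at pulse
repetition frequency PRF, giving an effective compounded frame rate
`FR = PRF / NA` (e.g. 3500 Hz / 7 angles = 500 Hz). The pipeline has four
stages:

1. **Block-wise SVD clutter filtering.** The compounded series is tiled
   into 64×64-pixel blocks with 90 % overlap; each block's Casorati matrix
   is decomposed as `A = U Δ Vᴴ`. Low singular orders carry tissue
   clutter, trailing orders electronic noise; the retained band
   `T_L..T_H` is chosen adaptively per block from the singular-value
   magnitude curve and the mean Doppler frequency (lag-1 autocorrelation)
   of each temporal singular vector. Filtered blocks are recombined with
   Hann weights and the per-pixel temporal power sum gives the power
   Doppler image. The same decomposition yields an adaptive high-pass
   cutoff frequency from the first retained singular vector.
2. **Vessel enhancement.** A bowler-hat transform (maximum difference
   between a directional line-opening bank and disk openings, radii
   1..r_max) suppresses blobs and flat background; Hessian vesselness
   (eigenvalues λ₁, λ₂ of the Gaussian-scale Hessian, |λ₂| ≥ |λ₁|)

   Δσ = 0 if λ₂ > 0, else exp(−(λ₁/λ₂)²/2β²)·(1 − exp(−(λ₁²+λ₂²)/2α²))

   with α = 2, β = 1 scores curvilinear structure. Binarizing the final
   enhanced image within a 3 dB dynamic range of its maximum yields the
   vascular mask; medial-axis thinning gives the centerline.
3. **Multibeam vector Doppler.** Per angle, a fifth-order zero-phase
   Butterworth high-pass with the adaptive cutoff removes residual
   clutter; the lag-1 autocorrelation phase ∅ maps to axial velocity
   `v_axial = c·FR·∅ / (4π f_c)`, and the per-angle projections
   `v_axial(θᵢ) = v·cos(θ_D + θᵢ)` are solved for speed `v` and direction
   `θ_D` by linear least squares over all angles.
4. **Quantification.** Density = vessel pixels / ROI pixels × 100 %;
   diameter by full-width-at-half-maximum normal to the centerline; SOAM
   tortuosity = Σ bending angles / path length along flow trajectories;
   pulsatility index = (max − min)/mean of the velocity trace; reversal
   ratio = fraction of vessel pixels whose velocity component sign flips
   more than twice; penetrating arterioles vs ascending venules by the
   sign of the mean axial flow.

Because no public raw IQ data exist for this kind of acquisition, the
package ships a phantom simulator (`hvmudi.phantom`) that reproduces the
validation experiment of the method — a straight 280 µm microtube
perpendicular to the beam with steady flow of 1.8–14.4 mm/s — by advancing
frozen blood speckle with the analytic multibeam phase model and adding
quasi-static tissue clutter (30 dB above blood) and white noise (20 dB
SNR), plus fixture scenarios with analytically known hemodynamic metrics.

## Worked example

```python
import numpy as np
from hvmudi.phantom import (ClutterSpec, NoiseSpec, microtube_scene,
                            reference_acquisition_config, simulate_iq)
from hvmudi.core_io import compound, effective_frame_rate
from hvmudi.clutter_svd import estimate_cutoff
from hvmudi.vector_doppler import hvmudi_vector_flow

cfg = reference_acquisition_config()          # 40 MHz, PRF 3500 Hz, 7 angles
print(f"effective frame rate: {effective_frame_rate(cfg):.0f} Hz")

scene = microtube_scene(7.2e-3, 128, 128, cfg)   # 280 µm tube, 7.2 mm/s
ensemble, truth = simulate_iq(scene, ClutterSpec(), NoiseSpec(), cfg,
                              n_frames=200, seed=1)
cutoff, _ = estimate_cutoff(compound(ensemble))
print(f"adaptive high-pass cutoff: {cutoff:.2f} Hz")

field = hvmudi_vector_flow(ensemble, mask=truth.mask, cutoff_hz=cutoff)
sel = truth.mask[:, :, None] & field.valid
speed = field.speed[sel].mean()
direction = np.rad2deg(np.angle(np.exp(1j * field.direction[sel]).mean()))
print(f"in-tube mean speed: {speed*1e3:.2f} mm/s (preset 7.20)")
print(f"in-tube mean direction: {direction:.1f} deg (preset 90)")
```

Output:

```
effective frame rate: 500 Hz
adaptive high-pass cutoff: 3.75 Hz
in-tube mean speed: 7.03 mm/s (preset 7.20)
in-tube mean direction: 90.0 deg (preset 90)
```

The recovered in-tube mean speed is within a few percent of the pump
preset and the direction matches the broadside geometry — despite tissue
clutter a thousand times stronger than the blood echo.

A command-line interface mirrors the library:

```bash
hvmudi simulate --velocity 7.2e-3 --seed 1 --out iq.h5
hvmudi filter   --iq iq.h5 --out run1          # power image + threshold log
hvmudi vectorflow --iq iq.h5 --cutoff auto --out field.h5
hvmudi metrics  --field field.h5 --mask run1_mask.tiff --out metrics.csv
```

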