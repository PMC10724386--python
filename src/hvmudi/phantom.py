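"""Synthetic flow-phantom and fixture generators.

Two independent roles:

* :func:`simulate_iq` emulates the straight-microtube flow experiment at the
  raw-data level: per-angle IQ ensembles containing blood speckle advanced by
  the analytic multibeam Doppler phase, quasi-static tissue clutter, and
  white electronic noise.  Acoustic propagation is deliberately bypassed —
  the downstream estimators consume only inter-frame phase and temporal
  spectra, so speckle is generated directly in image space and advanced by
  the phase model the estimators invert.
* :func:`synth_vector_field` emits masks and vector fields with analytically
  known density, diameter, tortuosity, pulsatility and reversal structure,
  as ground truth for the hemodynamic metrics.

The tissue clutter model is a sum of ``n_modes`` separable components
(spatially smooth complex field x complex tone), with mode frequencies spread
over ``[0, max_temporal_frequency_hz]`` and powers decaying 20 dB per mode —
the steep spectral decay of quasi-static tissue.  By construction the
clutter's Casorati energy is confined to ``n_modes`` singular components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .core_io import AcquisitionConfig, IQEnsemble
from .errors import ConfigError, SceneError
from .vector_doppler import VectorField

__all__ = [
    "FlowScene",
    "ClutterSpec",
    "NoiseSpec",
    "PhantomTruth",
    "reference_acquisition_config",
    "microtube_scene",
    "simulate_iq",
    "SyntheticScene",
    "MetricsTruth",
    "synth_vector_field",
    "SCENARIOS",
]

#: Preset velocities of the microtube experiment, m/s (1.8 .. 14.4 mm/s).
MICROTUBE_VELOCITIES_M_S = tuple(np.round(np.arange(1, 9) * 1.8e-3, 10))


@dataclass(frozen=True)
class FlowScene:
    """Straight-tube flow scene.

    ``tube_axis`` is a 2-D segment ((x0, z0), (x1, z1)) in meters; voxels
    within ``inner_diameter_m / 2`` of the (infinite) tube line are blood.
    ``flow_direction_deg`` follows the vector-Doppler convention (measured
    from +z toward +x; 90° = purely lateral, toward +x).
    """

    tube_axis: tuple[tuple[float, float], tuple[float, float]]
    inner_diameter_m: float = 280e-6
    preset_velocity_m_s: float = 7.2e-3
    flow_direction_deg: float = 90.0
    profile: str = "plug"

    def __post_init__(self) -> None:
        if self.inner_diameter_m <= 0:
            raise SceneError("tube diameter must be positive")
        if self.profile not in ("plug", "parabolic"):
            raise SceneError(f"unknown flow profile {self.profile!r}")
        (x0, z0), (x1, z1) = self.tube_axis
        if x0 == x1 and z0 == z1:
            raise SceneError("tube axis endpoints coincide")


@dataclass(frozen=True)
class ClutterSpec:
    """Tissue-clutter model parameters.

    ``amplitude_db_above_blood`` is the total clutter power relative to the
    per-voxel blood power, in dB.  Temporal content is confined below
    ``max_temporal_frequency_hz`` (must stay under FR/2).
    """

    amplitude_db_above_blood: float = 30.0
    max_temporal_frequency_hz: float = 10.0
    spatial_correlation_length_px: float = 10.0
    n_modes: int = 5
    db_per_mode: float = 20.0


@dataclass(frozen=True)
class NoiseSpec:
    """Electronic noise level: blood power over noise power, dB."""

    snr_db: float = 20.0


@dataclass
class PhantomTruth:
    """Ground truth exported with a simulated ensemble."""

    mask: np.ndarray          # in-tube voxels, (N_x, N_z) bool
    speed: np.ndarray         # preset speed map, m/s
    direction_deg: float      # flow direction θ_D
    phase_per_frame: np.ndarray  # per-angle inter-frame phase, (N_x, N_z, NA)


def reference_acquisition_config(
    n_angles: int = 7,
    prf_hz: float = 3500.0,
    center_frequency_hz: float = 40e6,
    pixel_pitch_m: tuple[float, float] = (19.25e-6, 19.25e-6),
) -> AcquisitionConfig:
    """40 MHz / PRF 3500 Hz / 7 angles from −3° to +3° (FR = 500 Hz).

    The default pixel pitch is half a wavelength at 40 MHz.
    """
    half = (n_angles - 1) / 2
    angles = tuple(float(a - half) for a in range(n_angles))
    return AcquisitionConfig(
        center_frequency_hz=center_frequency_hz,
        prf_hz=prf_hz,
        tilt_angles_deg=angles,
        pixel_pitch_m=pixel_pitch_m,
    )


def microtube_scene(
    preset_velocity_m_s: float,
    n_x: int,
    n_z: int,
    config: AcquisitionConfig,
    inner_diameter_m: float = 280e-6,
    profile: str = "plug",
) -> FlowScene:
    """280 µm tube crossing the image horizontally at mid-depth, flow toward +x
    (perpendicular to the beam, as in the microtube experiment)."""
    px, pz = config.pixel_pitch_m
    zc = (n_z / 2) * pz
    return FlowScene(
        tube_axis=((0.0, zc), ((n_x - 1) * px, zc)),
        inner_diameter_m=inner_diameter_m,
        preset_velocity_m_s=preset_velocity_m_s,
        flow_direction_deg=90.0,
        profile=profile,
    )


def _scene_geometry(
    scene: FlowScene, n_x: int, n_z: int, config: AcquisitionConfig
) -> tuple[np.ndarray, np.ndarray]:
    """In-tube mask and speed map on the pixel grid."""
    px, pz = config.pixel_pitch_m
    (x0, z0), (x1, z1) = scene.tube_axis
    xs = np.arange(n_x)[:, None] * px
    zs = np.arange(n_z)[None, :] * pz
    # distance from each voxel to the tube line
    dx, dz = x1 - x0, z1 - z0
    norm = np.hypot(dx, dz)
    dist = np.abs((xs - x0) * dz - (zs - z0) * dx) / norm
    radius = scene.inner_diameter_m / 2.0
    mask = dist <= radius
    if not mask.any():
        raise SceneError("tube does not intersect the imaging grid")
    if scene.inner_diameter_m <= 2 * pz:
        raise SceneError("tube diameter must exceed twice the axial pixel pitch")
    if scene.profile == "plug":
        speed = np.where(mask, scene.preset_velocity_m_s, 0.0)
    else:  # parabolic, preset = centerline peak
        speed = np.where(
            mask, scene.preset_velocity_m_s * (1.0 - (dist / radius) ** 2), 0.0
        )
    return mask, speed


def _complex_smooth_field(
    rng: np.random.Generator, shape: tuple[int, int], sigma_px: float
) -> np.ndarray:
    f = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    if sigma_px > 0:
        f = gaussian_filter(f.real, sigma_px) + 1j * gaussian_filter(f.imag, sigma_px)
    # renormalize to unit mean power
    p = np.mean(np.abs(f) ** 2)
    return f / np.sqrt(p) if p > 0 else f


def simulate_iq(
    scene: FlowScene,
    clutter: ClutterSpec,
    noise: NoiseSpec,
    config: AcquisitionConfig,
    n_frames: int = 200,
    seed: int = 0,
    shape: tuple[int, int] = (128, 128),
    speckle_sigma_px: float = 1.0,
) -> tuple[IQEnsemble, PhantomTruth]:
    """Simulate a per-angle IQ ensemble for a tube-flow scene.

    Inside the tube each voxel carries a fixed complex speckle value advanced
    per angle θ_i by the analytic inter-frame phase

        ∅_i = 4 π f_c v cos(θ_D + θ_i) / (c FR).

    Clutter and noise are added everywhere.  Identical seeds give identical
    ensembles.  Per-angle phases beyond ±π raise an aliasing *warning* only.
    """
    n_x, n_z = shape
    na = config.n_angles
    fr = config.frame_rate_hz
    rng = np.random.default_rng(seed)
    mask, speed = _scene_geometry(scene, n_x, n_z, config)

    # per-angle inter-frame phase increment map
    theta_d = np.deg2rad(scene.flow_direction_deg)
    theta_i = np.deg2rad(np.asarray(config.tilt_angles_deg))
    proj = np.cos(theta_d + theta_i)  # (NA,)
    phase_rate = (
        4.0 * np.pi * config.center_frequency_hz / (config.sound_speed_m_s * fr)
    ) * speed[:, :, None] * proj[None, None, :]
    if np.max(np.abs(phase_rate)) > np.pi:
        warnings.warn(
            "preset velocity exceeds the unambiguous projection limit; "
            "per-angle phases will alias",
            stacklevel=2,
        )

    # blood speckle: unit mean power inside the tube, zero outside
    speckle = _complex_smooth_field(rng, (n_x, n_z), speckle_sigma_px)
    speckle = np.where(mask, speckle, 0.0).astype(np.complex64)

    t = np.arange(n_frames, dtype=np.float32)
    data = np.empty((n_x, n_z, n_frames, na), dtype=np.complex64)
    for i in range(na):
        rot = np.exp(1j * phase_rate[:, :, i, None].astype(np.float32) * t)
        data[:, :, :, i] = speckle[:, :, None] * rot

    # clutter: separable low-rank modes sampled on the PRF time base
    total_clutter = 10.0 ** (clutter.amplitude_db_above_blood / 10.0)
    k = np.arange(clutter.n_modes)
    rel = 10.0 ** (-clutter.db_per_mode * k / 10.0)
    mode_power = total_clutter * rel / rel.sum()
    denom = max(clutter.n_modes - 1, 1)
    mode_freq = clutter.max_temporal_frequency_hz * (k / denom) ** 2
    if clutter.max_temporal_frequency_hz >= fr / 2:
        raise ConfigError("clutter band must stay below FR/2")
    tau = (t[:, None] * na + np.arange(na)[None, :]) / config.prf_hz  # (N_t, NA)
    for p_k, f_k in zip(mode_power, mode_freq):
        g = _complex_smooth_field(rng, (n_x, n_z), clutter.spatial_correlation_length_px)
        psi = rng.uniform(0, 2 * np.pi)
        tone = np.exp(1j * (2 * np.pi * f_k * tau + psi)).astype(np.complex64)
        data += (np.sqrt(p_k) * g.astype(np.complex64))[:, :, None, None] * tone[None, None, :, :]

    # circular white electronic noise
    sigma2 = 10.0 ** (-noise.snr_db / 10.0)
    sz = (n_x, n_z, n_frames, na)
    data += np.sqrt(sigma2 / 2.0) * (
        rng.standard_normal(sz, dtype=np.float32)
        + 1j * rng.standard_normal(sz, dtype=np.float32)
    )

    truth = PhantomTruth(
        mask=mask,
        speed=speed,
        direction_deg=scene.flow_direction_deg,
        phase_per_frame=phase_rate,
    )
    return IQEnsemble(data, config), truth


# ---------------------------------------------------------------------------
# direct synthetic masks / vector fields for metric-level tests
# ---------------------------------------------------------------------------

@dataclass
class MetricsTruth:
    """Analytically known metric values for a synthetic scenario.

    Fields are ``None`` when the scenario does not pin that metric down.
    """

    density_percent: float | None = None
    mean_diameter_m: float | None = None
    soam: float | None = None
    pulsatility_index: float | None = None
    reversal_ratio: float | None = None
    centerline: np.ndarray | None = None  # polyline in meters, for SOAM oracles


@dataclass
class SyntheticScene:
    """Mask + vector field + ground truth emitted by a named scenario."""

    mask: np.ndarray
    field: VectorField
    pixel_pitch_m: tuple[float, float]
    frame_rate_hz: float
    truth: MetricsTruth


def _field_from_components(vx: np.ndarray, vz: np.ndarray, mask: np.ndarray, fr: float) -> VectorField:
    speed = np.hypot(vx, vz)
    direction = np.arctan2(vx, vz)  # θ_D from +z toward +x
    valid = np.broadcast_to(mask[:, :, None], speed.shape) & (speed > 0)
    return VectorField(
        speed=speed, direction=direction, valid=valid, frame_rate_hz=fr
    )


def _straight_vessel(rng: np.random.Generator) -> SyntheticScene:
    # 10 px wide, full-length horizontal vessel in a 100x100 frame: 10% density
    n, w, pitch, fr, frames = 100, 10, 10e-6, 500.0, 20
    z0 = 45
    mask = np.zeros((n, n), dtype=bool)
    mask[:, z0 : z0 + w] = True
    vx = np.where(mask, 5e-3, 0.0)[:, :, None] * np.ones(frames)
    vz = np.zeros_like(vx)
    truth = MetricsTruth(
        density_percent=100.0 * w / n,
        mean_diameter_m=w * pitch,
        soam=0.0,
        pulsatility_index=0.0,
        reversal_ratio=0.0,
    )
    return SyntheticScene(mask, _field_from_components(vx, vz, mask, fr), (pitch, pitch), fr, truth)


def _l_bend(rng: np.random.Generator) -> SyntheticScene:
    # L-shaped vessel: one right-angle bend; SOAM = (π/2) / path length
    n, w, pitch, fr, frames = 100, 5, 10e-6, 500.0, 10
    mask = np.zeros((n, n), dtype=bool)
    x0, x1, zc = 10, 70, 20
    z1 = 80
    half = w // 2
    mask[x0 : x1 + 1, zc - half : zc + half + 1] = True   # arm along +x
    mask[x1 - half : x1 + half + 1, zc : z1 + 1] = True   # arm along +z
    vx = np.zeros((n, n))
    vz = np.zeros((n, n))
    vx[x0 : x1 + 1, zc - half : zc + half + 1] = 3e-3
    vz[x1 - half : x1 + half + 1, zc : z1 + 1] = 3e-3
    vx[x1 - half : x1 + half + 1, zc : z1 + 1][:, 1:] = 0.0  # bend region flows axially
    vx3 = vx[:, :, None] * np.ones(frames)
    vz3 = vz[:, :, None] * np.ones(frames)
    # analytic centerline polyline (unit-pixel steps), in meters
    pts = [(x, zc) for x in range(x0, x1 + 1)] + [(x1, z) for z in range(zc + 1, z1 + 1)]
    centerline = np.asarray(pts, dtype=float) * pitch
    path_len = ((x1 - x0) + (z1 - zc)) * pitch
    truth = MetricsTruth(
        soam=(np.pi / 2) / path_len,
        centerline=centerline,
    )
    return SyntheticScene(mask, _field_from_components(vx3, vz3, mask, fr), (pitch, pitch), fr, truth)


def _pulsatile_trace(rng: np.random.Generator) -> SyntheticScene:
    # speed trace 2 + sin(2πk/n) (mm/s) over one full period: PI = (3-1)/2 = 1
    n, pitch, fr, frames = 60, 10e-6, 500.0, 40
    mask = np.zeros((n, n), dtype=bool)
    mask[:, 28:33] = True
    k = np.arange(frames)
    trace = (2.0 + np.sin(2 * np.pi * k / frames)) * 1e-3
    vx = mask[:, :, None] * trace[None, None, :]
    vz = np.zeros_like(vx)
    truth = MetricsTruth(pulsatility_index=1.0, reversal_ratio=0.0)
    return SyntheticScene(mask, _field_from_components(vx, vz, mask, fr), (pitch, pitch), fr, truth)


def _reversing_trace(rng: np.random.Generator) -> SyntheticScene:
    # two far-apart vessels; the smaller (40% of vessel pixels) reverses with
    # exactly 3 sign changes, the larger flows steadily: reversal ratio 0.40
    n, pitch, fr, frames = 100, 10e-6, 500.0, 8
    mask = np.zeros((n, n), dtype=bool)
    rev = np.zeros((n, n), dtype=bool)
    rev[10:18, 10:15] = True          # 8 x 5 = 40 px
    steady = np.zeros((n, n), dtype=bool)
    steady[60:72, 70:75] = True       # 12 x 5 = 60 px
    mask = rev | steady
    pattern = np.array([1, 1, -1, -1, 1, 1, -1, -1], dtype=float)  # 3 sign changes
    vx = np.zeros((n, n, frames))
    vx[rev] = 2e-3 * pattern
    vx[steady] = 2e-3
    vz = np.zeros_like(vx)
    truth = MetricsTruth(reversal_ratio=0.40)
    return SyntheticScene(mask, _field_from_components(vx, vz, mask, fr), (pitch, pitch), fr, truth)


def _y_junction(rng: np.random.Generator) -> SyntheticScene:
    # trunk splitting into two diagonal branches; density known by count
    n, pitch, fr, frames = 100, 10e-6, 500.0, 10
    mask = np.zeros((n, n), dtype=bool)
    mask[0:50, 48:53] = True  # trunk along x
    for d in range(50):       # branches, 45 degrees
        x = 50 + d
        if x >= n:
            break
        for half in range(3):
            for zb in (48 - d, 52 + d):
                z = zb + (half - 1)
                if 0 <= z < n:
                    mask[x, z] = True
    vx = np.where(mask, 4e-3, 0.0)[:, :, None] * np.ones(frames)
    vz = np.zeros_like(vx)
    truth = MetricsTruth(density_percent=100.0 * mask.sum() / mask.size)
    return SyntheticScene(mask, _field_from_components(vx, vz, mask, fr), (pitch, pitch), fr, truth)


SCENARIOS = {
    "straight_vessel": _straight_vessel,
    "L_bend": _l_bend,
    "pulsatile_trace": _pulsatile_trace,
    "reversing_trace": _reversing_trace,
    "Y_junction": _y_junction,
}


def synth_vector_field(scenario: str, seed: int = 0) -> SyntheticScene:
    """Generate the named fixture scenario with its analytic ground truth."""
    if scenario not in SCENARIOS:
        raise ConfigError(
            f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}"
        )
    return SCENARIOS[scenario](np.random.default_rng(seed))
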