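"""Hemodynamic quantification from the vascular mask and vector field.

Metrics:

* vascular density — vessel-pixel fraction of an ROI, percent;
* vessel diameter — full width at half maximum of the enhanced intensity
  sampled normal to the centerline, grown in 10 µm increments when the
  half-maximum crossings fall outside the initial one-wavelength segment;
* SOAM tortuosity — sum of the in-plane bending angles along a flow
  trajectory divided by its path length (rad/m);
* pulsatility index — (max − min)/mean of the signed velocity trace along
  the vessel's mean flow direction, so reversals deepen the minimum;
* reversal-flow ratio — fraction of vessel pixels whose horizontal or
  vertical velocity component changes sign more than twice over time;
* arteriole/venule classification — by the sign of the time-averaged axial
  velocity per connected vessel component (+z descending = penetrating
  arteriole, ascending = venule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label

from .errors import ConfigError, DataError
from .vector_doppler import VectorField

logger = logging.getLogger("hvmudi")

__all__ = [
    "vascular_density",
    "vessel_diameters",
    "trajectories_from_field",
    "soam",
    "pulsatility_index",
    "reversal_flow_ratio",
    "classify_vessels",
    "render_flow",
    "metrics_report",
]

PENETRATING_ARTERIOLE = "penetrating_arteriole"
ASCENDING_VENULE = "ascending_venule"
UNCLASSIFIED = "unclassified"


def vascular_density(mask: np.ndarray, roi: np.ndarray) -> float:
    """Vessel-pixel percentage of the ROI: 100 · |mask ∧ roi| / |roi|."""
    mask = np.asarray(mask, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ConfigError("ROI is empty")
    return 100.0 * int((mask & roi).sum()) / n_roi


def _profile_fwhm(profile: np.ndarray, step_m: float) -> float | None:
    """FWHM of a sampled cross-section, crossings by linear interpolation;
    None when fewer than two half-maximum crossings exist."""
    n = len(profile)
    ic = int(np.argmax(profile))
    half = profile[ic] / 2.0
    if profile[ic] <= 0:
        return None
    left = None
    for i in range(ic, 0, -1):
        if profile[i - 1] < half <= profile[i]:
            frac = (profile[i] - half) / (profile[i] - profile[i - 1])
            left = i - frac
            break
    right = None
    for i in range(ic, n - 1):
        if profile[i + 1] < half <= profile[i]:
            frac = (profile[i] - half) / (profile[i] - profile[i + 1])
            right = i + frac
            break
    if left is None or right is None:
        return None
    return (right - left) * step_m


def vessel_diameters(
    enhanced: np.ndarray,
    skeleton: np.ndarray,
    orientation: np.ndarray,
    pixel_pitch_m: tuple[float, float],
    wavelength_m: float,
    growth_step_m: float = 10e-6,
    max_growth: int = 30,
) -> dict[tuple[int, int], float]:
    """FWHM diameter at each centerline pixel, in meters.

    The enhanced intensity is sampled (bilinear) along the segment normal to
    the local vascular orientation, centered on the skeleton pixel, with an
    initial half-length of one wavelength; if fewer than two half-maximum
    crossings are found the segment size grows by ``growth_step_m`` (up to
    ``max_growth`` times — the default budget spans vessels a few hundred
    µm wide) before the pixel is declared unresolved and skipped.  Pixels
    with undefined orientation are skipped with a log entry.
    """
    enhanced = np.asarray(enhanced, dtype=float)
    skeleton = np.asarray(skeleton, dtype=bool)
    px, pz = pixel_pitch_m
    step_m = min(px, pz) / 2.0
    out: dict[tuple[int, int], float] = {}
    for x, z in np.argwhere(skeleton):
        ang = orientation[x, z]
        if not np.isfinite(ang):
            logger.debug("skeleton pixel (%d,%d): undefined orientation, skipped", x, z)
            continue
        # normal to the vessel axis, in physical space
        nx_m, nz_m = -np.sin(ang), np.cos(ang)
        half_len = wavelength_m
        diam = None
        for _ in range(max_growth + 1):
            n_steps = max(int(np.ceil(half_len / step_m)), 2)
            ts = np.arange(-n_steps, n_steps + 1) * step_m
            xs = x + ts * nx_m / px
            zs = z + ts * nz_m / pz
            prof = ndimage.map_coordinates(
                enhanced, np.vstack([xs, zs]), order=1, mode="constant", cval=0.0
            )
            diam = _profile_fwhm(prof, step_m)
            if diam is not None:
                break
            half_len += growth_step_m / 2.0  # segment size grows by one step
        if diam is not None:
            out[(int(x), int(z))] = diam
    return out


def _smooth_components(vx: np.ndarray, vz: np.ndarray, sigma: float = 2.0):
    """2-D Gaussian smoothing (σ in px) of each component, frame by frame."""
    if sigma <= 0:
        return vx, vz
    sig = (sigma, sigma, 0) if vx.ndim == 3 else (sigma, sigma)
    return ndimage.gaussian_filter(vx, sig), ndimage.gaussian_filter(vz, sig)


def trajectories_from_field(
    field: VectorField,
    mask: np.ndarray,
    pixel_pitch_m: tuple[float, float],
    max_len: int = 500,
    speed_floor_m_s: float = 1e-5,
    smooth_sigma: float = 2.0,
    seeds: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Integrate flow trajectories from vessel pixels, in physical units.

    The time-averaged velocity components are Gaussian-smoothed (σ = 2 px),
    then each seed advances by the explicit first-order update
    ``P_{k+1} = P_k + v(P_k) / FR`` with bilinear velocity lookup,
    terminating on mask exit, sub-floor speed, or ``max_len`` points.
    Returns one (n, 2) array of (x, z) positions in meters per seed.
    """
    mask = np.asarray(mask, dtype=bool)
    fr = field.frame_rate_hz or 500.0
    vx = field.vx.mean(axis=2)
    vz = field.vz.mean(axis=2)
    vx, vz = _smooth_components(vx, vz, smooth_sigma)
    px, pz = pixel_pitch_m
    dt = 1.0 / fr
    if seeds is None:
        seeds = np.argwhere(mask)
    trajs: list[np.ndarray] = []
    for sx, sz in seeds:
        if not (0 <= sx < mask.shape[0] and 0 <= sz < mask.shape[1]) or not mask[int(sx), int(sz)]:
            continue
        p = np.array([float(sx), float(sz)])  # pixel coordinates
        pts = [p.copy()]
        for _ in range(max_len - 1):
            ix, iz = int(round(p[0])), int(round(p[1]))
            if not (0 <= ix < mask.shape[0] and 0 <= iz < mask.shape[1]) or not mask[ix, iz]:
                break
            v = np.array(
                [
                    ndimage.map_coordinates(vx, [[p[0]], [p[1]]], order=1)[0],
                    ndimage.map_coordinates(vz, [[p[0]], [p[1]]], order=1)[0],
                ]
            )
            if np.hypot(*v) < speed_floor_m_s:
                break
            p = p + v * dt / np.array([px, pz])
            pts.append(p.copy())
        trajs.append(np.asarray(pts) * np.array([px, pz]))
    return trajs


def soam(trajectory: np.ndarray) -> float | None:
    """Sum-of-angles tortuosity of a trajectory, rad per meter.

    The in-plane bending angle is accumulated at every interior point and
    divided by the total path length.  Trajectories with fewer than 3 points
    are undefined (returns None rather than raising).
    """
    P = np.asarray(trajectory, dtype=float)
    if P.ndim != 2 or P.shape[0] < 3:
        return None
    steps = np.diff(P, axis=0)
    lengths = np.linalg.norm(steps, axis=1)
    if np.any(lengths == 0):
        keep = lengths > 0
        steps = steps[keep]
        lengths = lengths[keep]
        if len(steps) < 2:
            return None
    units = steps / lengths[:, None]
    cosang = np.clip(np.sum(units[:-1] * units[1:], axis=1), -1.0, 1.0)
    total_angle = float(np.sum(np.arccos(cosang)))
    total_len = float(np.sum(lengths))
    return total_angle / total_len if total_len > 0 else None


def pulsatility_index(trace: np.ndarray) -> float | None:
    """(max − min) / mean of a (signed) velocity trace; None for zero mean."""
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise DataError("empty velocity trace")
    mean = trace.mean()
    if mean == 0:
        return None
    return float((trace.max() - trace.min()) / mean)


def _signed_changes(component: np.ndarray) -> np.ndarray:
    """Per-pixel count of sign changes over time; exact zeros do not count."""
    s = np.sign(component)
    # carry the last nonzero sign forward so zeros never create a change
    out = np.zeros(component.shape[:-1], dtype=int)
    prev = np.zeros(component.shape[:-1])
    for t in range(component.shape[-1]):
        cur = s[..., t]
        flip = (cur != 0) & (prev != 0) & (cur != prev)
        out += flip.astype(int)
        prev = np.where(cur != 0, cur, prev)
    return out


def reversal_flow_ratio(
    field: VectorField,
    mask: np.ndarray,
    smooth_sigma: float = 2.0,
    min_changes: int = 3,
) -> float | None:
    """Fraction of vessel pixels with reversing flow.

    After σ = 2 px spatial smoothing of each component, a pixel reverses when
    its horizontal *or* vertical velocity sign-change count over time reaches
    ``min_changes`` (the "more than two times" rule).  Requires ≥ 4 frames;
    an empty region returns None.
    """
    mask = np.asarray(mask, dtype=bool)
    if field.speed.shape[-1] < 4:
        raise DataError("need at least 4 frames to assess flow reversal")
    if not mask.any():
        return None
    vx, vz = _smooth_components(field.vx, field.vz, smooth_sigma)
    ch = np.maximum(_signed_changes(vx), _signed_changes(vz))
    reversal = (ch >= min_changes) & mask
    return float(reversal.sum() / mask.sum())


def classify_vessels(
    field: VectorField, mask: np.ndarray, eps_fraction: float = 0.05
) -> dict[int, str]:
    """Classify each connected vessel component by mean axial flow sign.

    Descending (+z) mean flow marks a penetrating arteriole, ascending an
    ascending venule; components whose |mean axial velocity| stays within
    ``eps_fraction`` of their mean speed remain unclassified.  Returns
    {component label: class}; labels follow ``skimage.measure.label``.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = label(mask, connectivity=2)
    vz_mean = field.vz.mean(axis=2)
    speed_mean = field.speed.mean(axis=2)
    out: dict[int, str] = {}
    for lab in range(1, labels.max() + 1):
        sel = labels == lab
        mz = vz_mean[sel].mean()
        eps = eps_fraction * speed_mean[sel].mean()
        if mz > eps:
            out[lab] = PENETRATING_ARTERIOLE
        elif mz < -eps:
            out[lab] = ASCENDING_VENULE
        else:
            out[lab] = UNCLASSIFIED
    return out


def render_flow(
    field: VectorField,
    mask: np.ndarray,
    mode: str = "hsv",
    seed: int = 0,
    n_frames: int | None = None,
    max_speed: float | None = None,
    particle_density: float = 0.10,
) -> list[np.ndarray]:
    """Render the vector field as an image sequence.

    ``hsv`` maps direction to hue on a 360° wheel and |v| to saturation
    (clipped at ``max_speed``); ``particles`` advects a seeded particle
    cloud, eliminating particles that leave the flow region and respawning
    to keep the particle count at or above ``particle_density`` of the
    region; ``arrows`` draws speed-scaled arrows.  Deterministic for a fixed
    seed.  Returns a list of (N_x, N_z, 3) float RGB frames.
    """
    from matplotlib.colors import hsv_to_rgb

    mask = np.asarray(mask, dtype=bool)
    nt = field.speed.shape[-1]
    if n_frames is None:
        n_frames = nt
    if max_speed is None:
        max_speed = float(field.speed[mask].max()) if mask.any() else 1.0
        if max_speed == 0:
            max_speed = 1.0
    rng = np.random.default_rng(seed)

    def hsv_frame(t: int) -> np.ndarray:
        h = (field.direction[..., t % nt] % (2 * np.pi)) / (2 * np.pi)
        s = np.clip(field.speed[..., t % nt] / max_speed, 0, 1)
        v = mask.astype(float)
        return hsv_to_rgb(np.stack([h, s * mask, v], axis=-1))

    if mode == "hsv":
        return [hsv_frame(t) for t in range(n_frames)]

    if mode == "arrows":
        frames = []
        stride = max(min(mask.shape) // 16, 1)
        for t in range(n_frames):
            img = hsv_frame(t)
            for x in range(0, mask.shape[0], stride):
                for z in range(0, mask.shape[1], stride):
                    if not mask[x, z]:
                        continue
                    ln = field.speed[x, z, t % nt] / max_speed * stride
                    dx = int(round(ln * np.sin(field.direction[x, z, t % nt])))
                    dz = int(round(ln * np.cos(field.direction[x, z, t % nt])))
                    xe, ze = np.clip(x + dx, 0, mask.shape[0] - 1), np.clip(
                        z + dz, 0, mask.shape[1] - 1
                    )
                    img[xe, ze] = [1.0, 1.0, 1.0]
            frames.append(img)
        return frames

    if mode == "particles":
        region = np.argwhere(mask)
        n_target = max(int(np.ceil(particle_density * len(region))), 1)
        idx = rng.choice(len(region), size=n_target, replace=False)
        pos = region[idx].astype(float)
        fr = field.frame_rate_hz or 500.0
        frames = []
        for t in range(n_frames):
            tt = t % nt
            vx = field.vx[..., tt]
            vz = field.vz[..., tt]
            vpx = np.stack(
                [
                    ndimage.map_coordinates(vx, pos.T, order=1),
                    ndimage.map_coordinates(vz, pos.T, order=1),
                ],
                axis=1,
            )
            pos = pos + vpx / fr / 1e-5  # display advection scale: px per frame
            ix = np.clip(np.round(pos[:, 0]).astype(int), 0, mask.shape[0] - 1)
            iz = np.clip(np.round(pos[:, 1]).astype(int), 0, mask.shape[1] - 1)
            inside = mask[ix, iz] & (pos[:, 0] >= 0) & (pos[:, 0] < mask.shape[0]) \
                & (pos[:, 1] >= 0) & (pos[:, 1] < mask.shape[1])
            pos = pos[inside]
            # respawn to maintain density
            if len(pos) < n_target:
                idx = rng.choice(len(region), size=n_target - len(pos), replace=True)
                pos = np.vstack([pos, region[idx].astype(float)])
            img = np.zeros(mask.shape + (3,))
            ix = np.round(pos[:, 0]).astype(int)
            iz = np.round(pos[:, 1]).astype(int)
            sp = np.stack(
                [
                    ndimage.map_coordinates(field.speed[..., tt], pos.T, order=1),
                    np.zeros(len(pos)),
                ],
                axis=1,
            )[:, 0]
            img[ix, iz, :] = np.clip(sp / max_speed, 0.1, 1.0)[:, None]
            frames.append(img)
        return frames

    raise ConfigError(f"unknown render mode {mode!r}")


def metrics_report(
    mask: np.ndarray,
    field: VectorField,
    rois: dict[str, np.ndarray],
    enhanced: np.ndarray | None = None,
    skeleton: np.ndarray | None = None,
    orientation: np.ndarray | None = None,
    pixel_pitch_m: tuple[float, float] = (19.25e-6, 19.25e-6),
    wavelength_m: float = 38.5e-6,
) -> pd.DataFrame:
    """Assemble the per-ROI metrics table (one row per ROI x metric).

    Per-class statistics (pulsatility index, reversal ratio) are computed
    per connected component and averaged weighted by component pixel count.
    """
    rows = []
    classes = classify_vessels(field, mask)
    labels = label(np.asarray(mask, dtype=bool), connectivity=2)
    for name, roi in rois.items():
        roi = np.asarray(roi, dtype=bool)
        rows.append((name, "density_percent", "all", vascular_density(mask, roi)))
        if enhanced is not None and skeleton is not None and orientation is not None:
            sk_roi = np.asarray(skeleton, dtype=bool) & roi
            diams = vessel_diameters(
                enhanced, sk_roi, orientation, pixel_pitch_m, wavelength_m
            )
            if diams:
                rows.append((name, "mean_diameter_m", "all", float(np.mean(list(diams.values())))))
        trajs = trajectories_from_field(field, mask & roi, pixel_pitch_m, max_len=100)
        soams = [s for s in (soam(t) for t in trajs) if s is not None]
        if soams:
            rows.append((name, "soam_rad_per_m", "all", float(np.mean(soams))))
        for cls in (PENETRATING_ARTERIOLE, ASCENDING_VENULE):
            labs = [lab for lab, c in classes.items() if c == cls]
            pis, revs, wts = [], [], []
            for lab in labs:
                sel = (labels == lab) & roi
                if not sel.any():
                    continue
                # signed speed along the component's mean direction
                vx_c = field.vx[sel].mean(axis=0)
                vz_c = field.vz[sel].mean(axis=0)
                mean_dir = np.array([vx_c.mean(), vz_c.mean()])
                nrm = np.linalg.norm(mean_dir)
                if nrm == 0:
                    continue
                signed = (vx_c * mean_dir[0] + vz_c * mean_dir[1]) / nrm
                pi = pulsatility_index(signed)
                rev = (
                    reversal_flow_ratio(field, sel)
                    if field.speed.shape[-1] >= 4
                    else None
                )
                w = int(sel.sum())
                if pi is not None:
                    pis.append(pi); wts.append(w)
                if rev is not None:
                    revs.append((rev, w))
            if pis:
                rows.append((name, "pulsatility_index", cls, float(np.average(pis, weights=wts))))
            if revs:
                r, w = zip(*revs)
                rows.append((name, "reversal_ratio", cls, float(np.average(r, weights=w))))
    return pd.DataFrame(rows, columns=["roi", "metric", "vessel_class", "value"])
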