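"""Acquisition metadata, IQ containers, coherent compounding and HDF5 I/O.

Data layout convention used by every module downstream:

* axis 0 — ``x``, lateral position (increasing with element index),
* axis 1 — ``z``, axial depth (increasing away from the transducer),
* axis 2 — ``t``, slow time (compounded frames at the effective frame rate),
* axis 3 — ``angle``, plane-wave tilt, ordered as ``tilt_angles_deg``.

A positive tilt angle steers the transmitted wavefront toward +x.  All
indices are 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import h5py
import numpy as np

from .errors import ConfigError, DataError, FormatError

logger = logging.getLogger("hvmudi")

__all__ = [
    "AcquisitionConfig",
    "IQEnsemble",
    "CompoundedSeries",
    "effective_frame_rate",
    "compound",
    "read_iq",
    "write_iq",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Transmit/physics constants of an ultrafast plane-wave acquisition.

    Parameters
    ----------
    center_frequency_hz : float
        Transducer center (operational) frequency ``f_c`` in Hz.
    prf_hz : float
        Pulse repetition frequency across successive tilted transmits.
    tilt_angles_deg : tuple of float
        Plane-wave tilt angles, strictly increasing, at least one entry.
        The effective (compounded) frame rate is ``prf_hz / len(angles)``.
    sound_speed_m_s : float
        Speed of sound ``c`` in m/s (default 1540, soft tissue).
    pixel_pitch_m : (float, float)
        Lateral and axial pixel pitch in meters.
    """

    center_frequency_hz: float
    prf_hz: float
    tilt_angles_deg: tuple[float, ...]
    sound_speed_m_s: float = 1540.0
    pixel_pitch_m: tuple[float, float] = (19.25e-6, 19.25e-6)

    def __post_init__(self) -> None:
        object.__setattr__(self, "tilt_angles_deg", tuple(float(a) for a in self.tilt_angles_deg))
        object.__setattr__(
            self, "pixel_pitch_m", tuple(float(p) for p in self.pixel_pitch_m)
        )
        if self.center_frequency_hz <= 0:
            raise ConfigError("center_frequency_hz must be positive")
        if self.prf_hz <= 0:
            raise ConfigError("prf_hz must be positive")
        if len(self.tilt_angles_deg) < 1:
            raise ConfigError("at least one tilt angle is required")
        diffs = np.diff(self.tilt_angles_deg)
        if len(diffs) and not np.all(diffs > 0):
            raise ConfigError("tilt_angles_deg must be strictly increasing")
        if self.sound_speed_m_s <= 0:
            raise ConfigError("sound_speed_m_s must be positive")
        if any(p <= 0 for p in self.pixel_pitch_m):
            raise ConfigError("pixel_pitch_m entries must be positive")

    @property
    def n_angles(self) -> int:
        return len(self.tilt_angles_deg)

    @property
    def frame_rate_hz(self) -> float:
        """Effective compounded frame rate ``FR = PRF / NA``."""
        return effective_frame_rate(self)

    @property
    def wavelength_m(self) -> float:
        """Acoustic wavelength ``λ = c / f_c``."""
        return self.sound_speed_m_s / self.center_frequency_hz

    @property
    def nyquist_axial_velocity_m_s(self) -> float:
        """Axial speed at which the inter-frame phase reaches π (aliasing limit)."""
        return self.sound_speed_m_s * self.frame_rate_hz / (4.0 * self.center_frequency_hz)


def effective_frame_rate(config: AcquisitionConfig) -> float:
    """Compounded frame rate in Hz: PRF divided by the number of tilt angles.

    One compounded frame consumes one transmit per angle, so an acquisition
    at PRF 3500 Hz with 7 angles yields 500 Hz.
    """
    na = config.n_angles
    if na < 1:
        raise ConfigError("angle count must be >= 1")
    return config.prf_hz / na


def _check_finite(data: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(data)):
        raise DataError(f"{what} contains non-finite values")


@dataclass
class IQEnsemble:
    """Per-angle complex IQ movie, shape ``(N_x, N_z, N_t, NA)``."""

    data: np.ndarray
    config: AcquisitionConfig

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise DataError(f"IQ ensemble must be 4-D, got {self.data.ndim}-D")
        if any(s < 1 for s in self.data.shape):
            raise DataError("all IQ ensemble extents must be >= 1")
        if self.data.shape[3] != self.config.n_angles:
            raise DataError(
                f"angle extent {self.data.shape[3]} does not match config "
                f"angle count {self.config.n_angles}"
            )
        _check_finite(self.data, "IQ ensemble")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]


@dataclass
class CompoundedSeries:
    """Coherently compounded IQ series, shape ``(N_x, N_z, N_t)``."""

    data: np.ndarray
    config: AcquisitionConfig

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DataError(f"compounded series must be 3-D, got {self.data.ndim}-D")
        _check_finite(self.data, "compounded series")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    @property
    def frame_period_s(self) -> float:
        return 1.0 / self.config.frame_rate_hz


def compound(ensemble: IQEnsemble) -> CompoundedSeries:
    """Coherent plane-wave compounding: complex sum over the angle axis."""
    out = ensemble.data.sum(axis=3)
    logger.info(
        "compound: %s -> %s (NA=%d)", ensemble.shape, out.shape, ensemble.config.n_angles
    )
    return CompoundedSeries(out, ensemble.config)


# HDF5 container layout: dataset "iq" (complex, x,z,t,angle) + one attribute
# per AcquisitionConfig field.
_SCALAR_ATTRS = ("center_frequency_hz", "prf_hz", "sound_speed_m_s")
_ARRAY_ATTRS = ("tilt_angles_deg", "pixel_pitch_m")


def write_iq(ensemble: IQEnsemble, path) -> None:
    """Write an IQ ensemble to a self-describing HDF5 container."""
    cfg = ensemble.config
    with h5py.File(path, "w") as f:
        f.create_dataset("iq", data=np.asarray(ensemble.data, dtype=np.complex64))
        for key in _SCALAR_ATTRS:
            f.attrs[key] = float(getattr(cfg, key))
        for key in _ARRAY_ATTRS:
            f.attrs[key] = np.asarray(getattr(cfg, key), dtype=np.float64)


def read_iq(path) -> IQEnsemble:
    """Read an IQ ensemble written by :func:`write_iq`.

    Raises
    ------
    FormatError
        If the "iq" dataset or any metadata attribute is missing, or the
        angle extent disagrees with the tilt-angle list.
    """
    with h5py.File(path, "r") as f:
        if "iq" not in f:
            raise FormatError('container lacks required dataset "iq"')
        for key in _SCALAR_ATTRS + _ARRAY_ATTRS:
            if key not in f.attrs:
                raise FormatError(f'container lacks required attribute "{key}"')
        data = f["iq"][()]
        if data.ndim != 4:
            raise FormatError(f'dataset "iq" must be 4-D, got {data.ndim}-D')
        angles = tuple(float(a) for a in np.atleast_1d(f.attrs["tilt_angles_deg"]))
        if data.shape[3] != len(angles):
            raise FormatError(
                f"angle extent {data.shape[3]} does not match tilt_angles_deg "
                f"length {len(angles)}"
            )
        cfg = AcquisitionConfig(
            center_frequency_hz=float(f.attrs["center_frequency_hz"]),
            prf_hz=float(f.attrs["prf_hz"]),
            tilt_angles_deg=angles,
            sound_speed_m_s=float(f.attrs["sound_speed_m_s"]),
            pixel_pitch_m=tuple(float(p) for p in np.atleast_1d(f.attrs["pixel_pitch_m"])),
        )
    return IQEnsemble(data, cfg)
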