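"""Block-wise SVD clutter filtering with adaptive thresholds.

The compounded IQ series is tiled into square spatial blocks, each block is
reshaped into a Casorati matrix ``A`` (space x time) and decomposed as
``A = U Δ Vᴴ``.  Low orders capture the high-amplitude, slowly varying tissue
clutter; the trailing orders capture electronic noise.  The blood band is
retained by reconstructing ``A_f = U_δ Δ_δ V_δᴴ`` with ``δ = T_L..T_H``, where
both thresholds are chosen per block from the singular-value magnitude curve
and from the mean Doppler frequency of each temporal singular vector.

Thresholds ``T_L``/``T_H`` are 1-based singular orders (``1 <= T_L < T_H <=
N_t``), matching the usual notation of SVD clutter filters.

The adaptive high-pass cutoff handed to the vector-Doppler stage is derived
from the lag-1 autocorrelation frequency of the first retained temporal
singular vector, floored so that it clears the frequency content of the
*rejected* clutter subspace (see :func:`adaptive_cutoff`).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np

from .core_io import CompoundedSeries
from .errors import ConfigError, ThresholdError

logger = logging.getLogger("hvmudi")

__all__ = [
    "CasoratiBlock",
    "SVDDecomposition",
    "SVDThresholds",
    "decompose",
    "mean_doppler_frequency",
    "adaptive_thresholds",
    "adaptive_cutoff",
    "filter_block",
    "blockwise_filter",
    "estimate_cutoff",
    "power_image",
]


@dataclass
class CasoratiBlock:
    """Space-time (Casorati) matrix of one spatial block.

    ``matrix`` has ``n_x * n_z`` rows (space, x-major) and ``N_t`` columns
    (time); ``origin`` is the (x0, z0) corner of the block in the parent
    image.
    """

    matrix: np.ndarray
    origin: tuple[int, int] = (0, 0)
    block_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ConfigError("Casorati matrix must be 2-D")
        if self.block_shape is not None:
            nx, nz = self.block_shape
            if nx * nz != self.matrix.shape[0]:
                raise ConfigError(
                    f"block shape {self.block_shape} inconsistent with "
                    f"{self.matrix.shape[0]} rows"
                )


@dataclass
class SVDDecomposition:
    """SVD of a Casorati matrix: ``A = U diag(s) Vᴴ``.

    ``singular_values`` are non-negative and non-increasing; ``V`` holds the
    temporal singular vectors as columns.  ``U`` may be ``None`` for
    decompositions computed through the temporal Gram matrix, which is all
    the block-wise filter needs (the reconstruction is then the projection
    ``A V_δ V_δᴴ``).
    """

    U: np.ndarray | None
    singular_values: np.ndarray
    V: np.ndarray
    matrix: np.ndarray | None = None

    @property
    def rank_extent(self) -> int:
        return len(self.singular_values)


def decompose(block: CasoratiBlock) -> SVDDecomposition:
    """Exact (thin) complex SVD of a Casorati block."""
    A = block.matrix
    if A.shape[1] < 2:
        raise ConfigError("Casorati matrix needs at least 2 time samples")
    U, s, Vh = np.linalg.svd(A, full_matrices=False)
    return SVDDecomposition(U=U, singular_values=s, V=Vh.conj().T, matrix=A)


def _decompose_gram(A: np.ndarray) -> SVDDecomposition:
    """Thin decomposition via the N_t x N_t temporal Gram matrix.

    Much cheaper than a full SVD when rows >> columns (the block-wise filter
    regime: 4096 rows, a few hundred frames).
    """
    G = A.conj().T @ A
    w, V = np.linalg.eigh(G)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    V = V[:, order]
    return SVDDecomposition(U=None, singular_values=np.sqrt(w), V=V, matrix=A)


def mean_doppler_frequency(v: np.ndarray, frame_rate_hz: float) -> float:
    """Mean Doppler frequency of a temporal vector via lag-1 autocorrelation.

    ``f = FR * arg(sum_t v[t+1] conj(v[t])) / (2 pi)``; signed, in
    ``(-FR/2, FR/2]``.  Invariant to global scaling of ``v``.
    """
    v = np.asarray(v).ravel()
    if v.size < 2:
        raise ConfigError("need at least 2 samples for a lag-1 frequency")
    r1 = np.sum(v[1:] * np.conj(v[:-1]))
    return frame_rate_hz * float(np.angle(r1)) / (2.0 * np.pi)


def _turning_point(log_mag: np.ndarray, plateau: int) -> int:
    """0-based order where the steep clutter decay of the log-magnitude
    curve ends.

    The clutter knee is located as the order lying deepest *below* the
    chord drawn from the first order to the noise plateau (for the convex,
    decelerating decay of clutter-dominated spectra the knee is the point
    of maximal sag); the turning point — the first non-clutter order — is
    the next order.  Curves with no usable knee (concave decay, or the sag
    minimum sitting at the plateau corner itself: no dominant clutter
    shelf) return 1, rejecting only the leading order and leaving the
    frequency criterion to locate the blood band.
    """
    if plateau < 2 or len(log_mag) < 3:
        return 0
    k = np.arange(plateau + 1)
    chord = log_mag[0] + (log_mag[plateau] - log_mag[0]) * k / plateau
    sag = log_mag[: plateau + 1] - chord
    if sag.min() >= -1e-12:
        return 1
    turning = min(int(np.argmin(sag)) + 1, plateau - 1)
    return turning if turning < plateau - 1 else 1


def _noise_plateau(log_mag: np.ndarray, tol: float, window: int) -> int:
    """First 0-based index where the ``window``-point moving slope of the
    log-magnitude curve flattens above ``-tol`` (per order)."""
    n = len(log_mag)
    if n <= window:
        return n - 1
    for k in range(n - window):
        slope = (log_mag[k + window - 1] - log_mag[k]) / (window - 1)
        if slope > -tol:
            return k
    return n - 1


@dataclass
class SVDThresholds:
    """Retained singular-order range (1-based, inclusive) and derived cutoff."""

    T_L: int
    T_H: int
    cutoff_frequency_hz: float = 0.0

    def __post_init__(self) -> None:
        if not (1 <= self.T_L < self.T_H):
            raise ThresholdError(f"need 1 <= T_L < T_H, got ({self.T_L}, {self.T_H})")

    @property
    def retained_slice(self) -> slice:
        return slice(self.T_L - 1, self.T_H)


def adaptive_thresholds(
    dec: SVDDecomposition,
    frame_rate_hz: float,
    f_clutter_hz: float = 10.0,
    plateau_tol: float = 0.01,
    plateau_window: int = 5,
) -> SVDThresholds:
    """Choose the retained singular-order range for one block.

    ``T_H`` is the first order at which the log-magnitude singular-value
    curve flattens into the noise plateau.  ``T_L`` is the smallest order at
    or after the first turning point of that curve whose temporal singular
    vector has a mean Doppler frequency above ``f_clutter_hz``; if no such
    order exists before the plateau (typical when the blood band itself sits
    inside the clutter band, e.g. broadside flow), ``T_L`` falls back to the
    turning point itself.  Degenerate curves fall back to ``(2, N_t)``.
    """
    s = dec.singular_values
    K = len(s)
    if K < 2:
        raise ThresholdError("decomposition has fewer than 2 singular values")
    eps = max(float(s[0]), 1.0) * 1e-12
    log_mag = np.log10(np.maximum(s, eps))

    n_nonzero = int(np.sum(s > eps))
    if n_nonzero <= 3:
        # (near-)degenerate curve: keep everything with nonzero energy
        turning = 0
        plateau = max(n_nonzero, 1)
    else:
        plateau = _noise_plateau(log_mag, plateau_tol, plateau_window)
        if plateau <= 1:
            # the curve flattens from the start (noise-dominated block):
            # stated fallback
            return SVDThresholds(T_L=2, T_H=K)
        turning = _turning_point(log_mag, plateau)

    # Find the first order in [turning, plateau) whose vector frequency
    # clears the clutter band; fall back to the turning point itself when
    # the whole pre-plateau band sits inside the clutter band (broadside
    # flow has near-zero mean Doppler but still lives past the turning).
    t_l = None
    for k in range(turning, min(plateau, K)):
        f_k = abs(mean_doppler_frequency(dec.V[:, k], frame_rate_hz))
        if f_k > f_clutter_hz:
            t_l = k
            break
    if t_l is None:
        t_l = turning
    # convert to 1-based orders; T_H is the last retained order (inclusive)
    T_L = t_l + 1
    T_H = min(max(plateau, T_L + 1), K)
    if not (1 <= T_L < T_H <= K):
        T_L, T_H = 2, K  # stated fallback
    thr = SVDThresholds(T_L=T_L, T_H=T_H)
    logger.debug("adaptive_thresholds: T_L=%d T_H=%d (K=%d)", T_L, T_H, K)
    return thr


def adaptive_cutoff(
    dec: SVDDecomposition,
    thresholds: SVDThresholds,
    frame_rate_hz: float,
    n_frames: int | None = None,
    reject_margin: float = 1.25,
) -> float:
    """High-pass cutoff from the lag-1 frequency of the T_L-th singular vector.

    The raw estimate ``|f(T_L)|`` is floored at

    * ``reject_margin`` times the largest mean Doppler frequency found in the
      *rejected* clutter subspace (orders ``< T_L``): the subsequent temporal
      high-pass must clear everything the SVD classified as clutter, and
    * 1.5 spectral bins, ``1.5 FR / N_t``: lag-1 frequencies of an N_t-sample
      vector are not meaningful below the spectral resolution, and a
      Butterworth design with a near-zero normalized cutoff is ill-posed.

    For asymmetric (non-broadside) blood spectra the T_L term dominates and
    this reduces to the plain first-retained-vector rule.  The result is
    clipped to just below FR/2.
    """
    if dec.V.shape[0] < 2:
        raise ConfigError("temporal singular vectors are too short")
    f_tl = abs(mean_doppler_frequency(dec.V[:, thresholds.T_L - 1], frame_rate_hz))
    f_rej = 0.0
    for k in range(thresholds.T_L - 1):
        f_rej = max(f_rej, abs(mean_doppler_frequency(dec.V[:, k], frame_rate_hz)))
    if n_frames is None:
        n_frames = dec.V.shape[0]
    floor = 1.5 * frame_rate_hz / n_frames
    f_cut = max(f_tl, reject_margin * f_rej, floor)
    return min(f_cut, 0.499 * frame_rate_hz)


def filter_block(dec: SVDDecomposition, thresholds: SVDThresholds) -> np.ndarray:
    """Reconstruct the clutter-filtered Casorati matrix ``A_f = U_δ Δ_δ V_δᴴ``."""
    sl = thresholds.retained_slice
    if sl.start >= sl.stop:
        raise ThresholdError("empty retained range")
    V_d = dec.V[:, sl]
    if dec.U is not None:
        return (dec.U[:, sl] * dec.singular_values[sl]) @ V_d.conj().T
    if dec.matrix is None:
        raise ThresholdError("Gram-based decomposition lacks the source matrix")
    # projection onto the retained temporal subspace: A V_δ V_δᴴ
    return (dec.matrix @ V_d) @ V_d.conj().T


def _block_starts(extent: int, block: int, stride: int) -> np.ndarray:
    """Start offsets of sliding blocks; the last block is shifted inward to
    keep full size (no zero padding)."""
    if extent <= block:
        return np.array([0])
    starts = list(range(0, extent - block + 1, max(stride, 1)))
    if starts[-1] != extent - block:
        starts.append(extent - block)
    return np.asarray(starts)


def _taper(n: int) -> np.ndarray:
    # Hann taper with strictly positive endpoints so that pixel-wise
    # normalization is a partition of unity even at the image border.
    return np.hanning(n + 2)[1:-1] + 1e-6


@dataclass
class BlockRecord:
    """Per-block adaptive parameters, for the threshold log."""

    x0: int
    z0: int
    T_L: int
    T_H: int
    cutoff_hz: float


def blockwise_filter(
    series: CompoundedSeries,
    block_size: int = 64,
    overlap: float = 0.90,
    f_clutter_hz: float = 10.0,
    thresholds_fn=None,
) -> tuple[CompoundedSeries, list[BlockRecord]]:
    """Sliding-block SVD filter with Hann-weighted recombination.

    Each block gets its own adaptive thresholds; overlapping filtered blocks
    are averaged with a separable Hann taper normalized pixel-wise (weights
    sum to 1 everywhere), which removes the grid-pattern artifacts a hard
    tiling would imprint.

    ``thresholds_fn(dec, frame_rate_hz) -> SVDThresholds`` overrides the
    adaptive threshold rule (e.g. fixed ranges for comparisons).
    """
    if not (0.0 <= overlap < 1.0):
        raise ConfigError(f"overlap must be in [0, 1), got {overlap}")
    t0 = time.perf_counter()
    data = series.data
    nx, nz, nt = data.shape
    bx = min(block_size, nx)
    bz = min(block_size, nz)
    stride_x = max(int(round(bx * (1.0 - overlap))), 1)
    stride_z = max(int(round(bz * (1.0 - overlap))), 1)
    fr = series.config.frame_rate_hz

    out = np.zeros_like(data, dtype=np.complex128)
    weight = np.zeros((nx, nz), dtype=np.float64)
    w2d = np.outer(_taper(bx), _taper(bz))
    records: list[BlockRecord] = []

    for x0 in _block_starts(nx, bx, stride_x):
        for z0 in _block_starts(nz, bz, stride_z):
            blk = data[x0 : x0 + bx, z0 : z0 + bz, :]
            A = blk.reshape(bx * bz, nt)
            dec = _decompose_gram(A)
            if thresholds_fn is not None:
                thr = thresholds_fn(dec, fr)
            else:
                thr = adaptive_thresholds(dec, fr, f_clutter_hz=f_clutter_hz)
            f_cut = adaptive_cutoff(dec, thr, fr, n_frames=nt)
            Af = filter_block(dec, thr).reshape(bx, bz, nt)
            out[x0 : x0 + bx, z0 : z0 + bz, :] += Af * w2d[:, :, None]
            weight[x0 : x0 + bx, z0 : z0 + bz] += w2d
            records.append(BlockRecord(int(x0), int(z0), thr.T_L, thr.T_H, f_cut))

    out /= weight[:, :, None]
    logger.info(
        "blockwise_filter: %s, %d blocks (block=%d, overlap=%.2f), %.2f s",
        data.shape, len(records), block_size, overlap, time.perf_counter() - t0,
    )
    return CompoundedSeries(out, series.config), records


def estimate_cutoff(
    series: CompoundedSeries,
    block_size: int = 64,
    overlap: float = 0.5,
    f_clutter_hz: float = 10.0,
) -> tuple[float, list[BlockRecord]]:
    """Global adaptive high-pass cutoff: median of per-block cutoffs.

    Runs the block decomposition and threshold selection without
    reconstructing filtered blocks.  A moderate 50% overlap gives enough
    block diversity for a robust median; the dense 90% overlap only matters
    for artifact-free image reconstruction.
    """
    if not (0.0 <= overlap < 1.0):
        raise ConfigError(f"overlap must be in [0, 1), got {overlap}")
    t0 = time.perf_counter()
    data = series.data
    nx, nz, nt = data.shape
    bx = min(block_size, nx)
    bz = min(block_size, nz)
    stride_x = max(int(round(bx * (1.0 - overlap))), 1)
    stride_z = max(int(round(bz * (1.0 - overlap))), 1)
    fr = series.config.frame_rate_hz

    records: list[BlockRecord] = []
    for x0 in _block_starts(nx, bx, stride_x):
        for z0 in _block_starts(nz, bz, stride_z):
            A = data[x0 : x0 + bx, z0 : z0 + bz, :].reshape(bx * bz, nt)
            dec = _decompose_gram(A)
            thr = adaptive_thresholds(dec, fr, f_clutter_hz=f_clutter_hz)
            f_cut = adaptive_cutoff(dec, thr, fr, n_frames=nt)
            records.append(BlockRecord(int(x0), int(z0), thr.T_L, thr.T_H, f_cut))
    cutoff = float(np.median([r.cutoff_hz for r in records]))
    logger.info(
        "estimate_cutoff: %d blocks, median cutoff %.2f Hz, %.2f s",
        len(records), cutoff, time.perf_counter() - t0,
    )
    return cutoff, records


def power_image(series: CompoundedSeries | np.ndarray) -> np.ndarray:
    """Power Doppler image: per-pixel sum of |signal|^2 along time."""
    data = series.data if isinstance(series, CompoundedSeries) else np.asarray(series)
    return np.sum(np.abs(data) ** 2, axis=-1)
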