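"""Windowed 3D cross-correlation velocimetry.

Estimates the tissue displacement between consecutive breath phases by tiling
each volume into overlapping cubic interrogation windows and locating the
cross-correlation peak of every window pair. The default geometry — 64^3
windows with 50% overlap, giving one vector per 32^3 region — matches the
standard XV processing configuration; every vector is expressed in voxels per
frame.

The correlation engine is a deliberately transparent baseline: spectral
(FFT) cross-correlation with window-mean subtraction, three-point Gaussian
sub-voxel peak interpolation per axis, peak-ratio validation, and local-median
infill of rejected vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ShapeError, SizingError, VoxelGrid3D

__all__ = ["DisplacementField", "estimate_displacements", "accumulate_fields"]


@dataclass
class DisplacementField:
    """Per-phase displacement vectors on the XV grid.

    ``vectors`` has shape ``(nz, ny, nx, 3)`` with components ``(dz, dy, dx)``
    in voxels/frame. ``grid_origin`` is the fine-voxel coordinate of the first
    window centre and ``grid_stride`` the spacing between window centres, so
    vector ``(i, j, k)`` sits at ``origin + stride * (i, j, k)`` in the source
    volume. ``valid`` marks vectors with sufficient mask coverage; ``filled``
    marks vectors replaced by the median of their valid neighbours after
    failing the correlation peak-ratio test.
    """

    vectors: np.ndarray
    valid: np.ndarray
    peak_quality: np.ndarray
    grid_origin: tuple[float, float, float]
    grid_stride: int
    phase_index: int = 0
    window_size: int = 64
    filled: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]  # type: ignore[return-value]

    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)


def _grid_positions(extent: int, window: int, stride: int) -> np.ndarray:
    n = (extent - window) // stride + 1
    return np.arange(n) * stride


def _subvoxel_offset(corr: np.ndarray, peak: tuple[int, int, int]) -> np.ndarray:
    """Per-axis 3-point Gaussian (fallback parabolic) peak refinement."""
    offsets = np.zeros(3)
    c0 = corr[peak]
    for ax in range(3):
        lo = list(peak)
        hi = list(peak)
        lo[ax] = (lo[ax] - 1) % corr.shape[ax]
        hi[ax] = (hi[ax] + 1) % corr.shape[ax]
        cm, cp = corr[tuple(lo)], corr[tuple(hi)]
        if not (np.isfinite(cm) and np.isfinite(cp)):
            continue
        if cm > 0 and cp > 0 and c0 > 0 and (cm != c0 or cp != c0):
            denom = 2.0 * (np.log(cm) + np.log(cp) - 2.0 * np.log(c0))
            if denom != 0:
                offsets[ax] = (np.log(cm) - np.log(cp)) / denom
                continue
        denom = 2.0 * (cm + cp - 2.0 * c0)
        if denom != 0:
            offsets[ax] = (cm - cp) / denom
    return np.clip(offsets, -1.0, 1.0)


def _peak_and_quality(
    corr: np.ndarray, exclusion_radius: int = 3, peak: tuple[int, int, int] | None = None
) -> tuple[tuple[int, int, int], float]:
    """Locate the tallest correlation peak; ties broken toward zero shift.

    Quality is the conventional PIV peak-ratio detectability: the tallest
    peak over the tallest value outside its neighbourhood. The exclusion
    neighbourhood must cover the correlation-peak width (set by the speckle
    grain), otherwise the main peak's own shoulder masquerades as a second
    peak.
    """
    if peak is None:
        cmax = corr.max()
        # candidate ties within floating slack; choose smallest wrapped shift
        slack = 1e-12 * max(1.0, abs(cmax))
        cand = np.argwhere(corr >= cmax - slack)
        shape = np.array(corr.shape)
        wrapped = np.where(cand > shape // 2, cand - shape, cand)
        best = cand[np.argmin((wrapped**2).sum(axis=1))]
        peak = tuple(int(v) for v in best)
    cmax = corr[peak]

    masked = corr.copy()
    r = exclusion_radius
    sl = [np.arange(p - r, p + r + 1) % n for p, n in zip(peak, corr.shape)]
    masked[np.ix_(*sl)] = -np.inf
    second = masked.max()
    if second <= 0:
        quality = np.inf
    else:
        quality = float(cmax / second)
    return peak, quality


def _correlate_window(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Linear cross-correlation C(d) = mean over overlap of b(x+d) a(x).

    Windows are mean-subtracted and zero-padded to twice their size so no
    wrap-around contaminates the peak; shifts beyond half the window size
    are suppressed (vectors are bounded by window/2 by construction).

    Returns the overlap-normalised plane (an unbiased covariance per shift,
    used to locate and refine the peak) together with the raw plane (used
    for the peak-ratio quality: normalisation would inflate noise at
    small-overlap shifts and mimic a competing peak).
    """
    w = np.array(a.shape)
    a = a - a.mean()
    b = b - b.mean()
    padded = tuple(2 * n for n in w)
    axes = (0, 1, 2)
    fa = np.fft.rfftn(a, s=padded, axes=axes)
    fb = np.fft.rfftn(b, s=padded, axes=axes)
    raw = np.fft.irfftn(fb * np.conj(fa), s=padded, axes=axes)
    # overlap count per (wrapped) shift, and a half-window search limit
    corr = raw
    for ax, n in enumerate(w):
        d = np.fft.fftfreq(2 * n) * 2 * n  # wrapped shifts -n..n-1
        ov = np.clip(n - np.abs(d), 0, None)
        ov[np.abs(d) > n // 2] = 0.0
        shape = [1, 1, 1]
        shape[ax] = 2 * n
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.where(ov.reshape(shape) > 0, corr / np.maximum(ov.reshape(shape), 1e-300), -np.inf)
        raw = np.where(ov.reshape(shape) > 0, raw, -np.inf)
    return corr, raw


def _window_vector(
    va: np.ndarray, vb: np.ndarray, start: tuple[int, int, int], window: int
) -> tuple[np.ndarray | None, float]:
    """Two-pass window correlation: integer peak first, then a re-correlation
    with the second window offset by that integer shift (clamped to the
    volume), so integer displacements resolve exactly and the sub-voxel
    refinement always operates about a centred peak."""
    sl_a = tuple(slice(s, s + window) for s in start)
    a = va[sl_a]
    corr, _raw = _correlate_window(a, vb[sl_a])
    if not np.any(np.isfinite(corr) & (corr > 0)):
        return None, 0.0
    peak, _ = _peak_and_quality(corr)
    d0 = _wrap_shift(peak, corr.shape)

    shape = va.shape
    shifted = [int(np.clip(start[ax] + d0[ax], 0, shape[ax] - window)) for ax in range(3)]
    applied = np.array([shifted[ax] - start[ax] for ax in range(3)], dtype=float)
    sl_b = tuple(slice(s, s + window) for s in shifted)
    corr2, raw2 = _correlate_window(a, vb[sl_b])
    if not np.any(np.isfinite(corr2) & (corr2 > 0)):
        return None, 0.0
    peak2, _ = _peak_and_quality(corr2)
    _, q = _peak_and_quality(raw2, peak=peak2)
    residual = _wrap_shift(peak2, corr2.shape) + _subvoxel_offset(corr2, peak2)
    return applied + residual, q


def _wrap_shift(peak: tuple[int, int, int], shape: tuple[int, ...]) -> np.ndarray:
    out = np.array(peak, dtype=float)
    for ax, n in enumerate(shape):
        if out[ax] > n // 2:
            out[ax] -= n
    return out


def estimate_displacements(
    volumes: list[VoxelGrid3D] | list[np.ndarray],
    window_size: int = 64,
    overlap_fraction: float = 0.5,
    mask: np.ndarray | VoxelGrid3D | None = None,
    min_peak_ratio: float = 1.2,
    min_mask_coverage: float = 0.5,
) -> list[DisplacementField]:
    """Estimate per-phase displacement fields for consecutive volume pairs.

    Parameters
    ----------
    volumes:
        Time-ordered volumes of identical shape (>= 2).
    window_size:
        Cubic interrogation window edge in voxels (default 64).
    overlap_fraction:
        Fractional overlap between successive windows (default 0.5, i.e. the
        vector grid stride is ``window_size * (1 - overlap_fraction)``).
    mask:
        Optional binary lung mask on the fine grid. Vectors are computed for
        every window, but windows with less than ``min_mask_coverage``
        in-mask fraction are flagged invalid (``valid`` False) so masked
        statistics exclude them; they take no part in infill.
    min_peak_ratio:
        Vectors whose first/second correlation-peak ratio falls below this
        threshold are replaced by the local median of valid neighbours and
        marked in ``filled``.

    Returns
    -------
    list of DisplacementField, one per consecutive pair, ``phase_index`` set
    to the index of the earlier volume.
    """
    arrays = [v.data if isinstance(v, VoxelGrid3D) else np.asarray(v) for v in volumes]
    if len(arrays) < 2:
        raise ShapeError("need at least two volumes")
    shape = arrays[0].shape
    for a in arrays[1:]:
        if a.shape != shape:
            raise ShapeError(f"volume shapes differ: {a.shape} vs {shape}")
    if window_size < 8:
        raise SizingError("window_size must be >= 8")
    if not (0 <= overlap_fraction < 1):
        raise ValueError("overlap_fraction must be in [0, 1)")
    if any(window_size > n for n in shape):
        raise SizingError(f"window {window_size} exceeds volume extent {shape}")

    stride = int(round(window_size * (1.0 - overlap_fraction)))
    stride = max(stride, 1)
    if mask is not None:
        mask = mask.data if isinstance(mask, VoxelGrid3D) else np.asarray(mask)
        mask = mask.astype(bool)
        if mask.shape != shape:
            raise ShapeError("mask shape differs from volume shape")

    starts = [_grid_positions(n, window_size, stride) for n in shape]
    grid_shape = tuple(len(s) for s in starts)
    origin = tuple((window_size - 1) / 2.0 for _ in range(3))

    # Precompute per-window mask coverage once.
    if mask is not None:
        coverage = np.zeros(grid_shape)
        for i, z0 in enumerate(starts[0]):
            for j, y0 in enumerate(starts[1]):
                for k, x0 in enumerate(starts[2]):
                    win = mask[z0 : z0 + window_size, y0 : y0 + window_size, x0 : x0 + window_size]
                    coverage[i, j, k] = win.mean()
        valid = coverage >= min_mask_coverage
    else:
        valid = np.ones(grid_shape, dtype=bool)

    fields: list[DisplacementField] = []
    for p in range(len(arrays) - 1):
        va, vb = arrays[p], arrays[p + 1]
        vectors = np.full(grid_shape + (3,), np.nan)
        quality = np.full(grid_shape, np.nan)
        reject = np.zeros(grid_shape, dtype=bool)
        for i, z0 in enumerate(starts[0]):
            for j, y0 in enumerate(starts[1]):
                for k, x0 in enumerate(starts[2]):
                    vec, q = _window_vector(va, vb, (z0, y0, x0), window_size)
                    if vec is None:
                        reject[i, j, k] = True
                        quality[i, j, k] = 0.0
                        continue
                    vectors[i, j, k] = vec
                    quality[i, j, k] = q
                    if q < min_peak_ratio:
                        reject[i, j, k] = True

        filled = np.zeros(grid_shape, dtype=bool)
        if reject.any():
            vectors, filled = _fill_rejected(vectors, reject)

        fields.append(
            DisplacementField(
                vectors=vectors,
                valid=valid.copy(),
                peak_quality=quality,
                grid_origin=origin,
                grid_stride=stride,
                phase_index=p,
                window_size=window_size,
                filled=filled,
            )
        )
    return fields


def _fill_rejected(
    vectors: np.ndarray, reject: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Replace rejected vectors with the component-wise median of trusted
    3x3x3 neighbours; iterate so isolated clusters fill from the outside in.

    Every rejected vector is repaired, inside the mask or out: downstream
    volume integration interpolates the field just outside the lung, so a
    wild low-quality vector anywhere near the boundary would leak into the
    estimates."""
    out = vectors.copy()
    good = ~reject & np.isfinite(vectors).all(axis=-1)
    filled = np.zeros(reject.shape, dtype=bool)
    pending = reject.copy()
    for _ in range(int(np.prod(reject.shape))):
        if not pending.any():
            break
        progressed = False
        idx = np.argwhere(pending)
        new_good = good.copy()
        for i, j, k in idx:
            zsl = slice(max(i - 1, 0), i + 2)
            ysl = slice(max(j - 1, 0), j + 2)
            xsl = slice(max(k - 1, 0), k + 2)
            nb = good[zsl, ysl, xsl]
            if nb.any():
                vals = out[zsl, ysl, xsl][nb]
                out[i, j, k] = np.median(vals, axis=0)
                filled[i, j, k] = True
                pending[i, j, k] = False
                new_good[i, j, k] = True
                progressed = True
        good = new_good
        if not progressed:
            # isolated rejected region with no valid neighbours anywhere
            out[pending] = 0.0
            filled |= pending
            pending[:] = False
    return out, filled


def accumulate_fields(fields: list[DisplacementField], upto_phase: int | None = None) -> np.ndarray:
    """Sum per-frame vectors on the fixed XV grid from breath start.

    ``upto_phase`` is the exclusive end index into ``fields``; ``None`` sums
    all. Summation on the fixed grid assumes per-frame displacements are small
    relative to the window (no Lagrangian tracking).
    """
    if not fields:
        raise ShapeError("no fields to accumulate")
    stop = len(fields) if upto_phase is None else upto_phase
    total = np.zeros_like(fields[0].vectors)
    for f in fields[:stop]:
        v = np.where(np.isfinite(f.vectors), f.vectors, 0.0)
        total = total + v
    return total
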