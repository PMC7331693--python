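"""Whole-lung volume/time curve and expiratory time constant.

The inspired air volume at each breath phase is the sum over the lung of the
regional volume change (fractional expansion x XV-voxel volume) accumulated
since breath start, divided by the total (mask-derived) lung volume — the
*fractional volume*. Its maximum is the fractional tidal volume, and the
expiratory time constant tau is the time from peak inspiration until a fixed
fraction (default 67%) of the tidal volume has been expired.

A literal "magnitude-sum" index (sum of displacement-vector magnitudes,
normalised the same way) is computed alongside for comparison; it tracks
overall tissue motion but is not dimensionally a volume, so the signed
volume-change integral is the primary estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import NormalizationError, ShapeError
from .expansion import jacobian_expansion, _extend_nearest
from .velocimetry import DisplacementField

__all__ = ["VolumeTimeCurve", "volume_time_curve", "expiratory_time_constant"]

#: fraction of tidal volume defining tau; the conventional value ~ 1 - 1/sqrt(2)
DEFAULT_EXPIRED_THRESHOLD = 0.67


@dataclass
class VolumeTimeCurve:
    """Fractional inspired volume per breath phase.

    ``fractional_volume[0]`` is 0 by construction (breath-start reference).
    ``tau`` is filled in by :func:`expiratory_time_constant`.
    """

    times: np.ndarray
    fractional_volume: np.ndarray
    expired_threshold: float = DEFAULT_EXPIRED_THRESHOLD
    tau: float | None = None
    tau_censored: bool = False
    magnitude_index: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fractional_volume = np.asarray(self.fractional_volume, dtype=float)
        if self.times.shape != self.fractional_volume.shape:
            raise ShapeError("times and fractional_volume differ in length")

    @property
    def n_phases(self) -> int:
        return len(self.times)

    @property
    def tidal_fraction(self) -> float:
        return float(np.max(self.fractional_volume))

    @property
    def peak_phase(self) -> int:
        """Phase of maximum fractional volume; ties broken to the earlier phase."""
        return int(np.argmax(self.fractional_volume))


def volume_time_curve(
    fields: list[DisplacementField],
    mask: np.ndarray,
    total_lung_volume: float,
    voxel_size: float = 1.0,
    times: np.ndarray | None = None,
    fine_mask: np.ndarray | None = None,
    flux_margin: int = 4,
) -> VolumeTimeCurve:
    """Integrate regional volume change into a global volume/time curve.

    Two signed estimators of the inspired volume are available:

    * ``regional`` — sum of (fractional expansion x XV-voxel volume) over the
      XV-grid mask; exact when the lung occupies whole XV voxels but lossy at
      coarse grids, where boundary flux is smeared across partially covered
      windows.
    * ``flux`` (used when ``fine_mask`` is given) — by the divergence
      theorem the same integral of signed volume change equals the outward
      displacement flux through the fine-resolution lung surface; the field
      is interpolated onto the mask boundary faces and the flux summed
      (plus a small volumetric correction for the nonlinear det-vs-div
      difference). The displacement is continuous across the lung edge, so
      this keeps the boundary contribution that coarse-grid integration
      smears away; it is the primary estimator whenever the fine
      segmentation mask is available.

    Parameters
    ----------
    fields:
        Per-frame displacement fields over the whole breath (``n_phases - 1``
        of them), voxels/frame on a common XV grid.
    mask:
        Binary lung mask on the XV grid.
    total_lung_volume:
        Mask-derived lung volume in mm^3 (see :func:`xvlung.preprocess.lung_volume`).
    voxel_size:
        Fine-voxel edge length (mm).
    times:
        Physical time of each phase (seconds). Defaults to frame index.
    fine_mask:
        Optional fine-grid lung mask enabling the flux estimator.
    """
    if total_lung_volume <= 0:
        raise NormalizationError("total_lung_volume must be positive")
    mask = np.asarray(mask, dtype=bool)
    if fields and mask.shape != fields[0].grid_shape:
        raise ShapeError("mask must live on the XV grid")
    n_phases = len(fields) + 1
    if times is None:
        times = np.arange(n_phases, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(times) != n_phases:
        raise ShapeError("need one time point per phase (len(fields) + 1)")

    stride = fields[0].grid_stride if fields else 1
    origin = fields[0].grid_origin if fields else (0.0, 0.0, 0.0)
    xv_voxel_volume = (stride * voxel_size) ** 3
    if fine_mask is not None:
        fine_mask = np.asarray(fine_mask, dtype=bool)
        fine_coords = np.meshgrid(
            *(np.arange(n, dtype=float) for n in fine_mask.shape), indexing="ij"
        )
        coarse_coords = [
            (fine_coords[ax] - origin[ax]) / float(stride) for ax in range(3)
        ]
        # Flux surface: the mask dilated a few voxels outward. The
        # displacement kinks exactly at the lung surface (expansion steps to
        # zero), which a coarse-grid field cannot resolve; a few voxels out
        # the field is smooth and, the bordering tissue being incompressible,
        # carries the same net flux.
        flux_mask = ndimage.binary_dilation(
            fine_mask, iterations=flux_margin
        ) if flux_margin > 0 else fine_mask
        faces = _boundary_faces(flux_mask)  # per-axis (face coords, sign)

    frac = np.zeros(n_phases)
    mag = np.zeros(n_phases)
    u = np.zeros_like(fields[0].vectors) if fields else None
    for p, f in enumerate(fields, start=1):
        v = np.where(np.isfinite(f.vectors), f.vectors, 0.0)
        u = u + v
        finite = np.isfinite(f.vectors).all(axis=-1)
        ufill = _extend_nearest(u, finite) if not finite.all() else u
        if fine_mask is not None:
            flux = 0.0
            for ax in range(3):
                coords, sign = faces[ax]
                if coords.shape[1] == 0:
                    continue
                cc = [(coords[a] - origin[a]) / float(stride) for a in range(3)]
                ua = ndimage.map_coordinates(ufill[..., ax], cc, order=3, mode="nearest")
                flux += float((sign * ua).sum())
            # nonlinear correction: det(I + grad u) - 1 minus div u is smooth
            # and small, so coarse reconstruction suffices for it
            u_up = np.stack(
                [
                    ndimage.map_coordinates(
                        ufill[..., ax], coarse_coords, order=3, mode="nearest"
                    )
                    for ax in range(3)
                ],
                axis=-1,
            )
            det_m1 = jacobian_expansion(u_up, spacing=1.0)
            div = sum(
                np.gradient(u_up[..., ax], 1.0, axis=ax) for ax in range(3)
            )
            correction = float((det_m1 - div)[flux_mask].sum())
            frac[p] = (flux + correction) * voxel_size**3 / total_lung_volume
        else:
            exp_map = jacobian_expansion(ufill, spacing=float(stride))
            frac[p] = exp_map[mask].sum() * xv_voxel_volume / total_lung_volume
        mag[p] = (
            np.linalg.norm(ufill, axis=-1)[mask].sum() * xv_voxel_volume / total_lung_volume
        )
    return VolumeTimeCurve(
        times=times,
        fractional_volume=frac,
        magnitude_index=mag,
        meta={
            "stride": stride,
            "xv_voxel_volume": xv_voxel_volume,
            "estimator": "flux" if fine_mask is not None else "regional",
        },
    )


def _boundary_faces(mask: np.ndarray) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Outward boundary faces of a binary mask, per normal axis.

    Returns ``{axis: (coords, sign)}`` where ``coords`` is a (3, n_faces)
    array of face-centre voxel coordinates (half-integer along the normal)
    and ``sign`` the outward normal orientation (+1/-1).
    """
    out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for ax in range(3):
        pad = [(0, 0)] * 3
        pad[ax] = (1, 1)
        m = np.pad(mask, pad)
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(0, -1)
        sl_hi[ax] = slice(1, None)
        # +ax faces: voxel in mask, neighbour above not
        plus = m[tuple(sl_lo)] & ~m[tuple(sl_hi)]
        minus = ~m[tuple(sl_lo)] & m[tuple(sl_hi)]
        coords_list, signs = [], []
        for arr, sign, shift in ((plus, +1.0, 0.5), (minus, -1.0, 0.5)):
            idx = np.argwhere(arr).astype(float)
            idx[:, ax] += shift - 1.0  # un-pad and move to the face centre
            coords_list.append(idx.T)
            signs.append(np.full(idx.shape[0], sign))
        coords = np.concatenate(coords_list, axis=1)
        sign = np.concatenate(signs)
        out[ax] = (coords, sign)
    return out


def expiratory_time_constant(
    curve: VolumeTimeCurve, threshold: float | None = None
) -> float:
    """Time from peak inspiration to the expiration of ``threshold`` x tidal volume.

    The crossing is located by linear interpolation between the bracketing
    phases. If expiration never reaches the threshold within the sampled
    breath, tau is censored at the expiration duration and flagged.

    The result is stored on ``curve.tau`` (and ``curve.tau_censored``) and
    returned in seconds.
    """
    if threshold is None:
        threshold = curve.expired_threshold
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    v = curve.fractional_volume
    t = curve.times
    peak = curve.peak_phase
    if len(v) - 1 - peak < 2:
        raise ShapeError("need at least two phases after peak inspiration")
    tidal = v[peak]
    if tidal <= 0:
        raise NormalizationError("tidal volume is zero; tau undefined")

    expired = (tidal - v[peak:]) / tidal
    te = t[peak:] - t[peak]
    crossing = np.nonzero(expired >= threshold)[0]
    if crossing.size == 0:
        tau = float(te[-1])
        curve.tau = tau
        curve.tau_censored = True
        curve.expired_threshold = threshold
        warnings.warn(
            f"expired fraction never reached {threshold:.2f}; "
            "tau censored at the expiration duration",
            stacklevel=2,
        )
        return tau
    i = int(crossing[0])
    if i == 0 or expired[i] == threshold:
        tau = float(te[i])
    else:
        f0, f1 = expired[i - 1], expired[i]
        tau = float(te[i - 1] + (threshold - f0) / (f1 - f0) * (te[i] - te[i - 1]))
    curve.tau = tau
    curve.tau_censored = False
    curve.expired_threshold = threshold
    return tau
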