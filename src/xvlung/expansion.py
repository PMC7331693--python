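"""Regional fractional-expansion maps from accumulated displacement fields.

Fractional expansion of an XV region of interest is (change in ROI volume) /
(ROI volume) over the breath — a unitless quantity. Given the displacement
``u`` accumulated from breath start to peak inspiration, the local volume
ratio of the warp ``x -> x + u(x)`` is ``det(J)`` with ``J = I + grad(u)``,
so the map stores ``det(J) - 1`` per XV voxel, restricted to the lung mask.

Gradients use central differences on the XV grid (one-sided at array edges),
which makes the map exact for affine displacement fields: a uniform dilation
``u = alpha * x`` yields ``(1 + alpha)^3 - 1`` everywhere in the interior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import PropagationError, ShapeError
from .velocimetry import DisplacementField, accumulate_fields

__all__ = ["ExpansionMap", "fractional_expansion", "apply_exclusion", "jacobian_expansion"]


@dataclass
class ExpansionMap:
    """Fractional expansion values on the XV grid, defined inside ``mask``.

    ``voxel_volume`` is the physical volume (mm^3) of one XV voxel, i.e.
    ``(grid_stride * fine_voxel_size)^3``.
    """

    values: np.ndarray
    mask: np.ndarray
    voxel_volume: float = 1.0
    exclusion: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ShapeError("values and mask shapes differ")
        if self.exclusion is not None:
            self.exclusion = np.asarray(self.exclusion, dtype=bool)
            if self.exclusion.shape != self.mask.shape:
                raise ShapeError("exclusion and mask shapes differ")

    @property
    def effective_mask(self) -> np.ndarray:
        if self.exclusion is None:
            return self.mask
        return self.mask & ~self.exclusion

    def in_mask_values(self) -> np.ndarray:
        """Flat array of expansion values inside the (exclusion-reduced) mask."""
        return self.values[self.effective_mask]

    @property
    def n_values(self) -> int:
        return int(self.effective_mask.sum())


def jacobian_expansion(u: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """det(I + grad u) - 1 for a displacement array of shape (nz, ny, nx, 3).

    ``u`` and ``spacing`` must share units (displacement in fine voxels with
    spacing = XV-grid stride in fine voxels, or both in mm).
    """
    if u.ndim != 4 or u.shape[-1] != 3:
        raise ShapeError("displacement array must have shape (nz, ny, nx, 3)")
    J = np.empty(u.shape[:3] + (3, 3))
    for comp in range(3):
        grads = np.gradient(u[..., comp], spacing, axis=(0, 1, 2))
        for ax in range(3):
            J[..., comp, ax] = grads[ax]
    J += np.eye(3)
    return np.linalg.det(J) - 1.0


def fractional_expansion(
    fields: list[DisplacementField],
    mask: np.ndarray,
    peak_phase: int | None = None,
    voxel_size: float = 1.0,
) -> ExpansionMap:
    """Accumulate displacement to peak inspiration and map local volume change.

    Parameters
    ----------
    fields:
        Per-frame displacement fields from breath start onward, in
        voxels/frame on a common XV grid.
    mask:
        Binary lung mask on the XV grid.
    peak_phase:
        Exclusive end index into ``fields`` (the number of frames summed to
        reach peak inspiration). ``None`` accumulates all supplied fields.
    voxel_size:
        Physical edge of one fine voxel (mm); the XV voxel volume becomes
        ``(stride * voxel_size)^3``.
    """
    if not fields:
        raise ShapeError("need at least one displacement field")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != fields[0].grid_shape:
        raise ShapeError("mask must live on the XV grid")

    stop = len(fields) if peak_phase is None else peak_phase
    raw = np.zeros_like(fields[0].vectors)
    for f in fields[:stop]:
        raw = raw + f.vectors
    finite = np.isfinite(raw).all(axis=-1)
    # Vectors flagged invalid by the estimator (insufficient mask coverage)
    # are NaN by design and are re-filled from neighbours below; NaN at a
    # vector the estimator declared valid is an upstream defect.
    declared_valid = np.ones(mask.shape, dtype=bool)
    for f in fields[:stop]:
        declared_valid &= f.valid
    bad = ~finite & mask & declared_valid
    if bad.any():
        voxels = np.argwhere(bad)[:10]
        raise PropagationError(
            f"non-finite displacement inside mask at voxels {voxels.tolist()}"
        )

    # extend in-mask vectors outward (nearest neighbour) before taking
    # gradients: border derivatives then use lung values only, the discrete
    # analogue of one-sided differences at the mask edge, instead of mixing
    # with the (near-static) exterior
    source = finite & mask
    if not source.any():
        source = finite
    u = _extend_nearest(raw, source)
    stride = fields[0].grid_stride
    values = jacobian_expansion(u, spacing=float(stride))
    values = np.where(mask, values, np.nan)
    return ExpansionMap(
        values=values,
        mask=mask,
        voxel_volume=(stride * voxel_size) ** 3,
        meta={"stride": stride, "peak_phase": peak_phase},
    )


def _extend_nearest(u: np.ndarray, mask: np.ndarray) -> np.ndarray:
    if mask.all():
        return u
    if not mask.any():
        return np.zeros_like(u)
    _, idx = ndimage.distance_transform_edt(~mask, return_indices=True)
    return u[idx[0], idx[1], idx[2]]


def apply_exclusion(emap: ExpansionMap, exclusion: np.ndarray) -> ExpansionMap:
    """Remove a region (e.g. the mainstem bronchi) from the analysis mask.

    Exclusion voxels outside the current mask are ignored with a warning;
    downstream histograms and statistics see only ``mask & ~exclusion``.
    """
    exclusion = np.asarray(exclusion, dtype=bool)
    if exclusion.shape != emap.mask.shape:
        raise ShapeError("exclusion grid differs from map grid")
    outside = exclusion & ~emap.mask
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} exclusion voxels fall outside the mask; "
            "using the intersection",
            stacklevel=2,
        )
    combined = exclusion & emap.mask
    if emap.exclusion is not None:
        combined = combined | emap.exclusion
    return ExpansionMap(
        values=emap.values,
        mask=emap.mask,
        voxel_volume=emap.voxel_volume,
        exclusion=combined,
        meta=dict(emap.meta),
    )
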