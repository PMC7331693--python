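"""Core containers and exceptions shared across the XV analysis chain.

Axis convention throughout the package: arrays are indexed ``(z, y, x)`` with
``z`` running cranial -> caudal, ``y`` dorsal -> ventral and ``x`` left ->
right, 0-based voxel indices. Vector components are stored in the same
``(dz, dy, dx)`` order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VoxelGrid3D",
    "XVError",
    "SizingError",
    "ShapeError",
    "ConfigurationError",
    "BoundaryError",
    "SegmentationError",
    "PropagationError",
    "NormalizationError",
    "FitFailureError",
    "DegenerateCohortError",
]


class XVError(Exception):
    """Base class for all errors raised by this package."""


class SizingError(XVError):
    """An input volume or grid is too small for the requested operation."""


class ShapeError(XVError):
    """Mismatched array shapes between inputs that must be aligned."""


class ConfigurationError(XVError):
    """An invalid or inconsistent configuration value."""


class BoundaryError(XVError):
    """A requested warp or crop would leave the image domain."""


class SegmentationError(XVError):
    """Lung or bone segmentation failed on the given volume."""


class PropagationError(XVError):
    """Non-finite displacement values inside the analysis mask."""


class NormalizationError(XVError):
    """A normalising denominator (lung volume, littermate IQR) is invalid."""


class FitFailureError(XVError):
    """The least-squares model fit failed to converge from every start."""

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


class DegenerateCohortError(XVError):
    """A cohort whose normalisation population is empty or degenerate."""


@dataclass
class VoxelGrid3D:
    """A 3D scalar image with isotropic voxel spacing.

    Parameters
    ----------
    data:
        3D array, axis order ``(z, y, x)``.
    voxel_size:
        Physical edge length of one voxel in millimetres.
    """

    data: np.ndarray
    voxel_size: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ShapeError(f"VoxelGrid3D requires a 3D array, got ndim={self.data.ndim}")
        if self.voxel_size <= 0:
            raise ConfigurationError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(self.voxel_size) ** 3

    def copy(self) -> "VoxelGrid3D":
        return VoxelGrid3D(self.data.copy(), self.voxel_size, dict(self.meta))
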