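"""Core spatial containers shared by every pipeline stage.

All physical coordinates in this package are LPS millimetres (the native
convention of ITK and of DICOM), and voxel indices are 0-based with the
voxel-center convention: voxel (i, j, k) of a :class:`ScalarVolume` sits at

    x = origin + direction @ (spacing * (i, j, k))

Arrays are indexed ``values[i, j, k]`` with axis order matching the columns
of ``direction`` (i.e. index axis 0 moves along the first physical axis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["ScalarVolume", "FiducialSet"]


@dataclass
class ScalarVolume:
    """A 3D scalar image with physical geometry.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values, indexed (i, j, k).
    spacing : array-like of 3 floats
        Voxel size in mm along each index axis; strictly positive.
    origin : array-like of 3 floats
        Physical position (LPS mm) of voxel (0, 0, 0).
    direction : (3, 3) array-like, optional
        Orthonormal direction cosine matrix; columns are the physical
        directions of the index axes. Defaults to identity.
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={self.values.ndim}")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        if self.origin.shape != (3,):
            raise ValueError("origin must have 3 components")
        if self.direction.shape != (3, 3) or not np.allclose(
            self.direction.T @ self.direction, np.eye(3), atol=1e-6
        ):
            raise ValueError("direction must be a 3x3 orthonormal matrix")
        if not self._axis_aligned():
            logger.warning(
                "volume direction matrix is not axis-aligned; distances are "
                "computed in physical coordinates so results are unaffected"
            )

    def _axis_aligned(self) -> bool:
        return bool(np.allclose(np.abs(self.direction), np.eye(3), atol=1e-6))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def index_to_physical(self, indices) -> np.ndarray:
        """Map (continuous) voxel indices, shape (..., 3), to LPS mm."""
        idx = np.asarray(indices, dtype=float)
        return self.origin + (idx * self.spacing) @ self.direction.T

    def physical_to_index(self, points) -> np.ndarray:
        """Map LPS mm points, shape (..., 3), to continuous voxel indices."""
        pts = np.asarray(points, dtype=float)
        return ((pts - self.origin) @ self.direction) / self.spacing

    def contains_point(self, point, tol: float = 0.5) -> bool:
        """True if the physical point lies inside the voxel lattice.

        ``tol`` extends the lattice by a fraction of a voxel beyond the
        outermost voxel centers (0.5 = the voxel faces).
        """
        idx = self.physical_to_index(point)
        lo = -tol
        hi = np.array(self.shape) - 1 + tol
        return bool(np.all(idx >= lo) and np.all(idx <= hi))

    def with_values(self, values: np.ndarray) -> "ScalarVolume":
        """Same grid geometry, new voxel values (shape must match)."""
        if values.shape != self.values.shape:
            raise ValueError("replacement values must match the grid shape")
        return ScalarVolume(values, self.spacing.copy(), self.origin.copy(), self.direction.copy())


@dataclass
class FiducialSet:
    """Ordered physical-space landmarks anchoring the duct.

    The first point marks the duct head (P0) and the last the tail; at
    least two points are required.
    """

    points: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if len(self.points) < 2:
            raise ValueError(
                f"a fiducial set needs at least 2 points (duct head and tail), got {len(self.points)}"
            )
        if self.labels is not None and len(self.labels) != len(self.points):
            raise ValueError("labels, when given, must match the number of points")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def head(self) -> np.ndarray:
        return self.points[0]

    @property
    def tail(self) -> np.ndarray:
        return self.points[-1]
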