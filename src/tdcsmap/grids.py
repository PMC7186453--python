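"""Voxel grid geometry.

All geometry is expressed in millimetres in a fixed axis-aligned,
right-handed scanner frame with +z along the main field B0.  The grid is
fully described by its shape (voxels), spacing (mm) and the world position
of the centre of voxel (0, 0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel lattice.

    Parameters
    ----------
    shape
        Number of voxels along (x, y, z).
    spacing
        Voxel size in mm along (x, y, z).
    origin
        World coordinates (mm) of the centre of voxel index (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (3.4, 3.4, 5.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("shape, spacing and origin must be length-3")
        if any(int(n) < 1 for n in self.shape):
            raise ValueError(f"shape must be >= 1 on all axes, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be > 0 on all axes, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size of the grid (mm) along each axis."""
        return tuple((n - 1) * s for n, s in zip(self.shape, self.spacing))

    def center(self) -> np.ndarray:
        """World coordinates (mm) of the geometric centre of the lattice."""
        return np.asarray(self.origin) + 0.5 * np.asarray(self.extent)

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape ``(*shape, 3)``."""
        axes = [
            self.origin[i] + self.spacing[i] * np.arange(self.shape[i])
            for i in range(3)
        ]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        return np.stack([xx, yy, zz], axis=-1)

    def affine(self) -> np.ndarray:
        """NIfTI-style 4x4 affine mapping voxel indices to mm."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing
        aff[:3, 3] = self.origin
        return aff

    @classmethod
    def from_affine(cls, shape, affine: np.ndarray) -> "VoxelGrid":
        """Build a grid from an axis-aligned NIfTI affine.

        Raises ``ValueError`` for oblique (rotated/sheared) affines, which
        this toolbox does not support.
        """
        affine = np.asarray(affine, dtype=float)
        rot = affine[:3, :3]
        off_diag = rot - np.diag(np.diag(rot))
        if np.any(np.abs(off_diag) > 1e-4):
            raise ValueError(
                "oblique affine not supported: only axis-aligned grids are handled"
            )
        spacing = np.diag(rot)
        if np.any(spacing <= 0):
            raise ValueError("affine must have positive diagonal scales")
        return cls(
            shape=tuple(int(n) for n in shape[:3]),
            spacing=tuple(spacing),
            origin=tuple(affine[:3, 3]),
        )

    def matches(self, other: "VoxelGrid", tol: float = 1e-4) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )
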