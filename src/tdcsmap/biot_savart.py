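"""Biot-Savart forward simulation of current-induced Bz fields.

A direct current confined to a known path (an insulated wire, in the
phantom case) induces a static magnetic field.  MRI phase is sensitive only
to the component of that field along the scanner's main field axis (+z),
so this module computes Bz per milliampere of applied current on a voxel
grid, using the exact closed form for the field of a finite straight
segment:

    B = (mu0 I / 4 pi d) (cos theta_1 - cos theta_2) phi_hat

where d is the perpendicular distance from the field point to the segment
axis, theta_1/theta_2 are the angles between the segment direction and the
vectors from the endpoints to the field point, and phi_hat is the
azimuthal direction given by the right-hand rule.

Units are mm for geometry, mA for current and nT for field throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grids import VoxelGrid

logger = logging.getLogger(__name__)

# mu0/4pi = 1e-7 T*m/A; with geometry in mm, current in mA and field in nT
# the prefactor works out to 1e-7 * 1e-3 * 1e3 * 1e9 = 100.
_K_NT_MM_MA = 100.0
# mu0/2pi in the same unit system (infinite-wire closed form).
_K2_NT_MM_MA = 200.0


@dataclass
class CurrentPath:
    """Polyline current path: ordered vertices (mm) carrying a signed current (mA)."""

    vertices: np.ndarray
    current: float = 1.0
    closed: bool = False

    def __post_init__(self) -> None:
        self.vertices = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array of mm coordinates")
        if len(self.vertices) < 2:
            raise ValueError("a current path needs at least 2 vertices")
        self.current = float(self.current)

    def segments(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (starts, ends) arrays of straight segments, shape (m, 3)."""
        starts = self.vertices[:-1]
        ends = self.vertices[1:]
        if self.closed:
            starts = np.vstack([starts, self.vertices[-1]])
            ends = np.vstack([ends, self.vertices[0]])
        lengths = np.linalg.norm(ends - starts, axis=1)
        if np.any(lengths == 0):
            raise ValueError("degenerate zero-length segment in current path")
        return starts, ends


@dataclass
class FieldMap:
    """Per-voxel Bz in nT per mA of applied current, with a validity mask."""

    grid: VoxelGrid
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError("values shape does not match grid shape")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape does not match values shape")
        if self.mask.any() and not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite Bz values inside the mask")

    @property
    def is_empty(self) -> bool:
        return not self.mask.any()


def analytic_infinite_wire_bz(
    offset_y: float, offset_z: float, current: float = 1.0
) -> float:
    """Bz (nT) of an infinite straight wire along +x, at transverse offset (mm).

    The field of an infinite wire is purely azimuthal with magnitude
    mu0*I/(2 pi d); its z-component at offset (dy, dz) from the wire is
    (mu0 I / 2 pi) * dy / (dy^2 + dz^2).  Serves as the closed-form oracle
    for the straight-wire phantom.
    """
    d2 = offset_y**2 + offset_z**2
    if d2 == 0:
        raise ValueError("offset must be nonzero: field diverges on the wire")
    return _K2_NT_MM_MA * current * offset_y / d2


def _segment_bz(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Exact Bz of one unit-current (1 mA) segment at an array of points (mm)."""
    e = b - a
    length = np.linalg.norm(e)
    e = e / length
    r1 = points - a
    r2 = points - b
    # e x r1 == e x r2 (r1 - r2 is parallel to e); its magnitude is the
    # perpendicular distance d, its direction the azimuthal unit * d.
    cross_z = e[0] * r1[..., 1] - e[1] * r1[..., 0]
    d2 = np.linalg.norm(np.cross(e, r1), axis=-1) ** 2
    cos1 = r1 @ e / np.linalg.norm(r1, axis=-1)
    cos2 = r2 @ e / np.linalg.norm(r2, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bz = _K_NT_MM_MA * cross_z / d2 * (cos1 - cos2)
    return np.where(d2 > 0, bz, 0.0)


def _segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Euclidean distance from each point to the segment [a, b]."""
    e = b - a
    length = np.linalg.norm(e)
    t = np.clip((points - a) @ e / length**2, 0.0, 1.0)
    closest = a + t[..., None] * e
    return np.linalg.norm(points - closest, axis=-1)


def biot_savart_bz(
    path: CurrentPath, grid: VoxelGrid, min_distance: float | None = None
) -> FieldMap:
    """Bz per mA at every voxel centre of ``grid`` induced by ``path``.

    Each straight segment contributes via the exact finite-segment closed
    form; contributions sum over segments.  Voxels whose centre lies closer
    than ``min_distance`` to any segment are masked out (the field diverges
    on the wire and real acquisitions show artifacts there).

    Parameters
    ----------
    min_distance
        Exclusion radius in mm; default is half the smallest voxel spacing.
    """
    if min_distance is None:
        min_distance = 0.5 * min(grid.spacing)
    if min_distance <= 0:
        raise ValueError("min_distance must be > 0")
    points = grid.voxel_centers()
    starts, ends = path.segments()
    bz = np.zeros(grid.shape, dtype=float)
    dist = np.full(grid.shape, np.inf)
    for a, b in zip(starts, ends):
        bz += _segment_bz(points, a, b)
        np.minimum(dist, _segment_distance(points, a, b), out=dist)
    bz *= path.current
    mask = dist >= min_distance
    bz[~mask] = 0.0
    if not mask.any():
        logger.warning("biot_savart_bz: all voxels within min_distance; empty field map")
    return FieldMap(grid=grid, values=bz, mask=mask)


def phantom_fixture(
    grid: VoxelGrid,
    wire_radius: float | None = None,
    min_distance: float | None = None,
    span_factor: float = 40.0,
    cylinder_mask: bool = True,
) -> tuple[CurrentPath, FieldMap]:
    """Straight-wire water-phantom geometry and its simulated field.

    A horizontal insulated wire runs along +x through the middle of a
    cylindrical water bottle.  The wire extends ``span_factor`` times the
    grid extent beyond the grid on both sides, so inside the grid the field
    is indistinguishable from the infinite-wire closed form.  The resulting
    Bz pattern is bipolar: positive on one side of the wire, negative on
    the other (right-hand rule), antisymmetric in y about the wire plane.

    Parameters
    ----------
    wire_radius
        Physical wire radius (mm) used only to enlarge the near-wire
        exclusion; the current is treated as a line current.
    cylinder_mask
        Restrict the mask to a cylindrical water volume coaxial with the
        wire (radius = half the smaller transverse grid extent).
    """
    center = grid.center()
    half_span = span_factor * max(grid.extent)
    vertices = np.array(
        [
            [center[0] - half_span, center[1], center[2]],
            [center[0] + half_span, center[1], center[2]],
        ]
    )
    path = CurrentPath(vertices=vertices, current=1.0)
    if min_distance is None:
        min_distance = 0.5 * min(grid.spacing)
    exclusion = max(min_distance, wire_radius or 0.0)
    field = biot_savart_bz(path, grid, min_distance=exclusion)
    if cylinder_mask:
        points = grid.voxel_centers()
        dy = points[..., 1] - center[1]
        dz = points[..., 2] - center[2]
        radius = 0.5 * min(grid.extent[1], grid.extent[2]) + 1e-9
        inside = dy**2 + dz**2 <= radius**2
        field.mask &= inside
        field.values[~field.mask] = 0.0
    return path, field
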