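"""4D phase unwrapping for dual-echo EPI time series.

MR phase is measured modulo 2 pi; at a BOLD-optimal second echo (26 ms) the
current- and B0-induced phase accrual spans several cycles, so the stored
phase wraps.  This module restores the continuous phase using three anchors:

* spatial continuity - quality-guided region growth within each volume,
  where the quality score penalizes local wrapped-phase derivative variance;
* the short first echo (11 ms) - wraps are rare at TE1, and for
  field-inhomogeneity-dominated phase the echo-2 phase is predicted by the
  echo-1 phase scaled by TE2/TE1, which anchors the absolute cycle count of
  the first echo-2 volume;
* temporal continuity - successive volumes differ by less than half a cycle
  for realistic current steps, so later volumes are unwrapped per voxel
  against the previous volume.

Voxels whose echo-2 phase disagrees with the TE-ratio prediction by more
than pi/2 after cycle correction are flagged; a series with more than 20%
flagged voxels is rejected as unusable (excessive phase wraps).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .acquisition import TWO_PI, DualEchoSeries, wrap_phase
from .grids import VoxelGrid


class ExcessivePhaseWrapsError(ValueError):
    """Raised when too many voxels fail the dual-echo consistency check."""


@dataclass
class PhaseSeries:
    """Unwrapped 4D phase (radians, unbounded) with quality and flags."""

    values: np.ndarray
    grid: VoxelGrid
    mask: np.ndarray
    quality: np.ndarray | None = None
    flags: np.ndarray | None = None
    scan_boundaries: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.values.ndim != 4:
            raise ValueError("values must be a 4D (x, y, z, t) array")
        if self.values.shape[:3] != tuple(self.grid.shape):
            raise ValueError("values spatial shape does not match grid")
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_volumes(self) -> int:
        return self.values.shape[3]


_NEIGHBOR_OFFSETS = [
    (1, 0, 0), (-1, 0, 0),
    (0, 1, 0), (0, -1, 0),
    (0, 0, 1), (0, 0, -1),
]


def quality_map(wrapped: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Per-voxel phase quality in [0, 1] from wrapped second differences.

    The wrapped forward difference along each axis estimates the true phase
    gradient wherever the field is smooth; its change from one voxel to the
    next (the second difference) is large at noise spikes and aliased
    regions.  The score is 1 / (1 + sum over axes of squared second
    differences), so a constant volume scores exactly 1 and the score is
    invariant under a global phase offset.
    """
    wrapped = np.asarray(wrapped, dtype=float)
    if mask is None:
        mask = np.ones(wrapped.shape, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    pdv = np.zeros(wrapped.shape)
    for axis in range(3):
        if wrapped.shape[axis] < 3:
            continue
        grad = wrap_phase(np.diff(wrapped, axis=axis))
        d2 = np.diff(grad, axis=axis)  # second difference, centred at voxel i
        interior = [slice(None)] * 3
        interior[axis] = slice(1, wrapped.shape[axis] - 1)
        contrib = np.zeros(wrapped.shape)
        contrib[tuple(interior)] = d2**2
        pdv += contrib
    score = 1.0 / (1.0 + pdv)
    score[~mask] = 0.0
    return score


def _grow_component(
    out: np.ndarray,
    comp_mask: np.ndarray,
    quality: np.ndarray,
    seed: tuple[int, int, int],
) -> None:
    """Quality-ordered region growth over one connected component, in place.

    Each newly grown voxel is shifted by the 2 pi multiple bringing it
    nearest to the mean of its already-unwrapped neighbours.
    """
    shape = out.shape
    visited = np.zeros(shape, dtype=bool)
    nbr_sum = np.zeros(shape)
    nbr_count = np.zeros(shape, dtype=np.int32)
    heap: list[tuple[float, int, tuple[int, int, int]]] = []
    counter = 0

    def push_neighbors(v: tuple[int, int, int]) -> None:
        nonlocal counter
        for dx, dy, dz in _NEIGHBOR_OFFSETS:
            n = (v[0] + dx, v[1] + dy, v[2] + dz)
            if not (0 <= n[0] < shape[0] and 0 <= n[1] < shape[1] and 0 <= n[2] < shape[2]):
                continue
            if not comp_mask[n] or visited[n]:
                continue
            nbr_sum[n] += out[v]
            nbr_count[n] += 1
            counter += 1
            heapq.heappush(heap, (-quality[n], counter, n))

    visited[seed] = True
    push_neighbors(seed)
    while heap:
        _, _, v = heapq.heappop(heap)
        if visited[v]:
            continue
        mean = nbr_sum[v] / nbr_count[v]
        out[v] += TWO_PI * np.round((mean - out[v]) / TWO_PI)
        visited[v] = True
        push_neighbors(v)


def unwrap_spatial(
    wrapped: np.ndarray,
    mask: np.ndarray | None = None,
    seed_voxel: tuple[int, int, int] | None = None,
    quality: np.ndarray | None = None,
) -> np.ndarray:
    """Spatially unwrap one 3D phase volume by quality-guided region growth.

    Growth starts from ``seed_voxel`` (default: the highest-quality voxel)
    and proceeds in decreasing quality order; disconnected mask components
    are each grown from their own best seed.  The output is congruent to
    the input modulo 2 pi at every voxel.
    """
    wrapped = np.asarray(wrapped, dtype=float)
    if mask is None:
        mask = np.ones(wrapped.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if quality is None:
        quality = quality_map(wrapped, mask)
    out = wrapped.copy()
    labels, n_comp = ndimage.label(mask)
    for comp in range(1, n_comp + 1):
        comp_mask = labels == comp
        if seed_voxel is not None and comp_mask[tuple(seed_voxel)]:
            seed = tuple(int(i) for i in seed_voxel)
        else:
            flat = np.argmax(np.where(comp_mask, quality, -np.inf))
            seed = tuple(int(i) for i in np.unravel_index(flat, wrapped.shape))
        _grow_component(out, comp_mask, quality, seed)
    return out


def unwrap_dual_echo(
    series: DualEchoSeries,
    mask: np.ndarray | None = None,
    flag_threshold: float = np.pi / 2,
    reject_fraction: float = 0.2,
    scan_boundaries: tuple[int, ...] = (),
) -> PhaseSeries:
    """Unwrap the echo-2 phase time series using both echoes and time.

    Volume 1 of echo 1 is unwrapped spatially; the first echo-2 volume is
    then unwrapped toward the TE2/TE1-scaled echo-1 prediction (a global
    constant offset between prediction and data is estimated circularly and
    removed first, since the echo-1 unwrap is only defined up to a global
    cycle), followed by one spatial-consistency pass.  Subsequent volumes
    are unwrapped per voxel against the previous volume, assuming less than
    half a cycle of change per TR.

    Raises
    ------
    ExcessivePhaseWrapsError
        If more than ``reject_fraction`` of masked voxels disagree with the
        dual-echo prediction by more than ``flag_threshold`` after cycle
        correction - such a series is unusable.
    """
    if mask is None:
        mask = np.ones(series.grid.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")

    te_ratio = series.params.te2 / series.params.te1

    ph1_0 = unwrap_spatial(series.phase_e1[..., 0], mask)
    # pin the echo-1 global cycle so the prediction is well-scaled
    med = np.median(ph1_0[mask])
    ph1_0 -= TWO_PI * np.round(med / TWO_PI)
    prediction = ph1_0 * te_ratio

    wrapped2 = series.phase_e2[..., 0]
    # global (non-cycle) offset between prediction and echo-2 phase,
    # estimated on the circle; absorbs the prediction's fractional-cycle
    # offset and any global phase not proportional to TE
    delta = np.angle(np.mean(np.exp(1j * (prediction[mask] - wrapped2[mask]))))
    prediction = prediction - delta

    k = np.round((prediction - wrapped2) / TWO_PI)
    vol2 = wrapped2 + TWO_PI * k
    quality = quality_map(wrapped2, mask)
    vol2 = _consistency_pass(vol2, mask, quality)
    residual = np.abs(vol2 - prediction)
    flags = (residual > flag_threshold) & mask
    frac = flags.sum() / mask.sum()
    if frac > reject_fraction:
        raise ExcessivePhaseWrapsError(
            f"{100 * frac:.1f}% of masked voxels failed the dual-echo "
            f"consistency check (limit {100 * reject_fraction:.0f}%): "
            "series rejected for excessive phase wraps"
        )

    n_t = series.n_volumes
    values = np.empty(series.phase_e2.shape, dtype=float)
    values[..., 0] = vol2
    for t in range(1, n_t):
        w = series.phase_e2[..., t]
        values[..., t] = w + TWO_PI * np.round((values[..., t - 1] - w) / TWO_PI)

    # global cycle convention: masked median of volume 1 in (-pi, pi]
    med = np.median(values[..., 0][mask])
    values -= TWO_PI * np.round(med / TWO_PI)

    return PhaseSeries(
        values=values,
        grid=series.grid,
        mask=mask,
        quality=quality,
        flags=flags,
        scan_boundaries=tuple(scan_boundaries),
    )


def _consistency_pass(
    volume: np.ndarray, mask: np.ndarray, quality: np.ndarray
) -> np.ndarray:
    """One spatial pass over an already-unwrapped volume.

    Region growth that only applies 2 pi corrections where a voxel
    disagrees with its grown neighbours; a no-op on consistent volumes.
    """
    out = volume.copy()
    labels, n_comp = ndimage.label(mask)
    for comp in range(1, n_comp + 1):
        comp_mask = labels == comp
        flat = np.argmax(np.where(comp_mask, quality, -np.inf))
        seed = tuple(int(i) for i in np.unravel_index(flat, volume.shape))
        _grow_component(out, comp_mask, quality, seed)
    return out


def detect_level_shifts(
    phase: PhaseSeries,
    scan_boundaries: tuple[int, ...] | None = None,
    n_sigma: float = 3.0,
) -> tuple[np.ndarray, list[int]]:
    """Detect abrupt between-scan phase offsets and build step regressors.

    The across-mask mean phase is tracked over volumes; a scan boundary
    whose jump exceeds ``n_sigma`` times the robust SD (1.4826 x MAD) of
    ordinary volume-to-volume jumps gets a 0/1 step column for the GLM.

    Returns
    -------
    columns : (n_volumes, n_detected) float array
    boundaries : list of volume indices where a step was placed
    """
    if scan_boundaries is None:
        scan_boundaries = phase.scan_boundaries
    n_t = phase.n_volumes
    for b in scan_boundaries:
        if not 0 < b < n_t:
            raise ValueError(f"scan boundary {b} outside series of {n_t} volumes")
    mean_phase = phase.values[phase.mask].mean(axis=0)
    diffs = np.diff(mean_phase)
    within = np.ones(diffs.size, dtype=bool)
    for b in scan_boundaries:
        within[b - 1] = False
    ref = diffs[within] if within.any() else diffs
    robust_sd = 1.4826 * np.median(np.abs(ref - np.median(ref)))
    threshold = n_sigma * robust_sd
    columns = []
    detected = []
    for b in scan_boundaries:
        if np.abs(diffs[b - 1]) > threshold:
            col = np.zeros(n_t)
            col[b:] = 1.0
            columns.append(col)
            detected.append(int(b))
    cols = np.column_stack(columns) if columns else np.zeros((n_t, 0))
    return cols, detected
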