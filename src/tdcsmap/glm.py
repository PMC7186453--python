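"""Per-voxel general linear models for field and magnitude estimation.

The unwrapped echo-2 phase time series is modelled voxelwise as a linear
function of the applied current plus nuisance terms (intercept, per-scan
linear trend, optional motion parameters, global signal and between-scan
level-shift steps).  The slope of the current regressor, in rad/mA, is the
current-induced phase per milliampere; dividing by gamma * TE2 converts it
to the induced field per milliampere (nT/mA):

    Bz [nT/mA] = slope [rad/mA] / (gamma * TE2) * 1e9

The echo-2 magnitude is modelled with the same design to quantify
current-locked magnitude (BOLD-confound) changes, reported as percent
signal change per mA with Bonferroni family-wise error control.

Ordinary least squares is used throughout (no autocorrelation
prewhitening), a deliberate simplification for block designs with long
blocks relative to TR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .acquisition import AcquisitionParams, CurrentWaveform
from .grids import VoxelGrid
from .unwrap import PhaseSeries, detect_level_shifts

logger = logging.getLogger(__name__)


@dataclass
class DesignMatrix:
    """Named GLM design; ``current`` is the regressor of interest."""

    frame: pd.DataFrame
    dropped: tuple[str, ...] = ()

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def column_index(self, name: str) -> int:
        if name not in self.frame.columns:
            raise KeyError(
                f"design has no '{name}' column (dropped: {list(self.dropped)})"
            )
        return self.frame.columns.get_loc(name)


@dataclass
class FieldEstimate:
    """GLM output: induced field per mA and its uncertainty."""

    slope: np.ndarray  # nT/mA
    slope_rad: np.ndarray  # rad/mA
    se: np.ndarray  # nT/mA
    residual_sd: np.ndarray  # rad
    mask: np.ndarray
    grid: VoxelGrid
    design_columns: tuple[str, ...] = ()


@dataclass
class MagnitudeEstimate:
    """Magnitude GLM output: percent signal change per mA and significance."""

    pct_per_mA: np.ndarray
    t_stat: np.ndarray
    p: np.ndarray
    p_fwe: np.ndarray
    mask: np.ndarray
    grid: VoxelGrid


def detrend_linear(series: PhaseSeries) -> PhaseSeries:
    """Remove a per-voxel least-squares line, separately per scan segment.

    Idempotent; preserves block contrasts that are balanced against the
    trend.  The mask, quality and flags are carried through unchanged.
    """
    values = series.values
    n_t = values.shape[3]
    if n_t < 3:
        raise ValueError("need at least 3 volumes to detrend")
    edges = [0, *series.scan_boundaries, n_t]
    out = values.copy()
    flat = out.reshape(-1, n_t)
    for i in range(len(edges) - 1):
        seg = slice(edges[i], edges[i + 1])
        t = np.arange(edges[i + 1] - edges[i], dtype=float)
        X = np.column_stack([np.ones_like(t), t - t.mean()])
        hat = X @ np.linalg.pinv(X)
        flat[:, seg] = flat[:, seg] - flat[:, seg] @ hat.T
    return PhaseSeries(
        values=flat.reshape(values.shape),
        grid=series.grid,
        mask=series.mask,
        quality=series.quality,
        flags=series.flags,
        scan_boundaries=series.scan_boundaries,
    )


def build_design(
    waveform: CurrentWaveform,
    motion: np.ndarray | pd.DataFrame | None = None,
    global_signal: np.ndarray | None = None,
    shifts: np.ndarray | None = None,
) -> DesignMatrix:
    """Assemble the GLM design around the applied-current predictor.

    Columns: intercept, one centred linear trend per scan, the current
    waveform (mA), and the supplied nuisance columns (6 motion parameters,
    global signal, level-shift steps).  All-zero columns are dropped with a
    log record; a rank-deficient design is rejected with the offending
    columns named.
    """
    n_t = waveform.n_volumes
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n_t)}
    for i, (start, stop) in enumerate(waveform.scan_segments()):
        trend = np.zeros(n_t)
        seg = np.arange(stop - start, dtype=float)
        trend[start:stop] = seg - seg.mean()
        cols[f"trend_scan{i}"] = trend
    cols["current"] = waveform.currents.copy()
    if global_signal is not None:
        gs = np.asarray(global_signal, dtype=float).ravel()
        if gs.size != n_t:
            raise ValueError("global_signal length does not match waveform")
        cols["global_signal"] = gs - gs.mean()
    if motion is not None:
        mot = np.asarray(motion, dtype=float)
        if mot.shape[0] != n_t:
            raise ValueError("motion table rows do not match waveform volumes")
        if mot.ndim != 2 or mot.shape[1] != 6:
            raise ValueError("motion table must have 6 columns")
        for i in range(6):
            cols[f"motion_{i}"] = mot[:, i] - mot[:, i].mean()
    if shifts is not None:
        shifts = np.atleast_2d(np.asarray(shifts, dtype=float))
        if shifts.shape[0] != n_t:
            shifts = shifts.T
        if shifts.size and shifts.shape[0] != n_t:
            raise ValueError("shift columns length does not match waveform")
        for i in range(shifts.shape[1]):
            cols[f"shift_{i}"] = shifts[:, i]

    dropped = [name for name, c in cols.items() if np.max(np.abs(c)) < 1e-10]
    for name in dropped:
        logger.info("build_design: dropping (numerically) all-zero column %r", name)
        del cols[name]

    frame = pd.DataFrame(cols)
    X = frame.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        offenders = _collinear_columns(frame)
        raise ValueError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {offenders}"
        )
    return DesignMatrix(frame=frame, dropped=tuple(dropped))


def _collinear_columns(frame: pd.DataFrame) -> list[str]:
    """Name columns linearly dependent on their predecessors."""
    offenders = []
    X = frame.to_numpy(dtype=float)
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
            offenders.append(frame.columns[j])
    return offenders


def _ols(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized OLS of Y (t, v) on X (t, p): beta, se, residual sd."""
    n_t, n_p = X.shape
    if n_t <= n_p:
        raise ValueError(f"fewer volumes ({n_t}) than design columns ({n_p})")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y  # (p, v)
    resid = Y - X @ beta
    dof = n_t - n_p
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    return beta, se, np.sqrt(sigma2)


def fit_phase_glm(
    phase: PhaseSeries, design: DesignMatrix, params: AcquisitionParams
) -> FieldEstimate:
    """Estimate the induced field per mA from unwrapped phase by OLS.

    The current-column coefficient (rad/mA) and its standard error are
    converted to nT/mA via gamma * TE2.
    """
    X = design.matrix
    if X.shape[0] != phase.n_volumes:
        raise ValueError("design rows do not match number of volumes")
    c = design.column_index("current")
    mask = phase.mask
    Y = phase.values[mask].T  # (t, v)
    beta, se, resid_sd = _ols(X, Y)

    rad_to_nt = 1e9 / (params.gamma * params.te2)
    shape = phase.values.shape[:3]
    slope_rad = np.zeros(shape)
    slope_rad[mask] = beta[c]
    slope_nt = slope_rad * rad_to_nt
    se_map = np.zeros(shape)
    se_map[mask] = se[c] * rad_to_nt
    rsd = np.zeros(shape)
    rsd[mask] = resid_sd
    return FieldEstimate(
        slope=slope_nt,
        slope_rad=slope_rad,
        se=se_map,
        residual_sd=rsd,
        mask=mask,
        grid=phase.grid,
        design_columns=tuple(design.columns),
    )


def fit_magnitude_glm(
    magnitude_e2: np.ndarray,
    design: DesignMatrix,
    mask: np.ndarray | None = None,
    grid: VoxelGrid | None = None,
    fwe_alpha: float = 0.05,
) -> MagnitudeEstimate:
    """Model the echo-2 magnitude on the design; report %-change per mA.

    Per-voxel OLS slope of magnitude on the current column, scaled by the
    voxel's mean magnitude into percent per mA; family-wise error control
    over masked voxels by Bonferroni correction.  Voxels with zero mean
    magnitude are excluded from the mask.
    """
    if magnitude_e2.ndim != 4:
        raise ValueError("magnitude series must be 4D")
    if grid is None:
        grid = VoxelGrid(shape=magnitude_e2.shape[:3], spacing=(1.0, 1.0, 1.0))
    if mask is None:
        mask = np.ones(magnitude_e2.shape[:3], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    X = design.matrix
    if X.shape[0] != magnitude_e2.shape[3]:
        raise ValueError("design rows do not match number of volumes")
    c = design.column_index("current")

    mean_mag = magnitude_e2.mean(axis=3)
    usable = mask & (mean_mag != 0)
    n_dropped = int(mask.sum() - usable.sum())
    if n_dropped:
        logger.info("fit_magnitude_glm: excluding %d zero-mean voxels", n_dropped)
    Y = magnitude_e2[usable].T
    beta, se, _ = _ols(X, Y)
    dof = X.shape[0] - X.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_vals = beta[c] / se[c]
    p_vals = 2.0 * stats.t.sf(np.abs(t_vals), dof)
    n_test = usable.sum()
    p_fwe_vals = np.minimum(p_vals * n_test, 1.0)

    shape = magnitude_e2.shape[:3]
    pct = np.zeros(shape)
    pct[usable] = 100.0 * beta[c] / mean_mag[usable]
    t_map = np.zeros(shape)
    t_map[usable] = t_vals
    p_map = np.ones(shape)
    p_map[usable] = p_vals
    p_fwe = np.ones(shape)
    p_fwe[usable] = p_fwe_vals
    return MagnitudeEstimate(
        pct_per_mA=pct, t_stat=t_map, p=p_map, p_fwe=p_fwe, mask=usable, grid=grid
    )


def estimate_field_from_series(
    series,
    waveform: CurrentWaveform,
    mask: np.ndarray | None = None,
    motion: np.ndarray | None = None,
    include_global_signal: bool = True,
    scan_boundaries: tuple[int, ...] | None = None,
) -> FieldEstimate:
    """End-to-end field estimation: unwrap, build nuisance design, fit.

    Convenience pipeline used by the command-line tool: dual-echo
    unwrapping, between-scan level-shift detection, design assembly
    (intercept, per-scan trends, current, optional motion and global
    signal, detected shift steps) and the phase GLM.
    """
    from .unwrap import unwrap_dual_echo  # local import to keep layering clear

    if scan_boundaries is None:
        scan_boundaries = waveform.scan_boundaries
    phase = unwrap_dual_echo(series, mask, scan_boundaries=scan_boundaries)
    shift_cols, _ = detect_level_shifts(phase, scan_boundaries)
    gs = phase.values[phase.mask].mean(axis=0) if include_global_signal else None
    design = build_design(
        waveform,
        motion=motion,
        global_signal=gs,
        shifts=shift_cols if shift_cols.size else None,
    )
    return fit_phase_glm(phase, design, series.params)
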