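"""Validation statistics for field maps and current-locked BOLD effects.

Covers every comparison used to validate concurrent current mapping:
spatial Pearson correlation against a simulated reference, linear
regression over progressively restricted field ranges (sensitivity), paired
t-tests of per-subject mean field strengths, voxelwise test-retest ICC,
cluster-thresholded masks and their DICE overlap, and a two-stage
(dual-regression-style) test of component timecourses against the applied
current waveform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .acquisition import CurrentWaveform, convolve_hrf, double_gamma_hrf
from .biot_savart import FieldMap


def _masked_pair(a: FieldMap, b: FieldMap, mask: np.ndarray | None):
    if not a.grid.matches(b.grid):
        raise ValueError("field maps are on different grids")
    joint = a.mask & b.mask
    if mask is not None:
        joint &= np.asarray(mask, dtype=bool)
    return a.values[joint], b.values[joint], joint


def spatial_pearson(
    a: FieldMap, b: FieldMap, mask: np.ndarray | None = None
) -> tuple[float, float]:
    """Pearson r (and two-tailed p) between two field maps over a mask."""
    x, y, _ = _masked_pair(a, b, mask)
    if x.size < 3:
        raise ValueError("need at least 3 masked voxels")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the maps")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def range_regression(
    measured: FieldMap,
    reference: FieldMap,
    mask: np.ndarray | None = None,
    bounds: Sequence[float] = (np.inf, 10.0, 5.0, 1.0),
) -> pd.DataFrame:
    """OLS of measured on reference over progressively weaker field ranges.

    For each bound (descending, nT) only voxels with |reference| <= bound
    are kept; slope near 1 and intercept near 0 across rows demonstrates
    accuracy down to weak fields.  Rows with fewer than 3 voxels are
    flagged (``computed`` False) rather than fitted.
    """
    bounds = list(bounds)
    finite = [b for b in bounds if np.isfinite(b)]
    if any(b <= 0 for b in finite):
        raise ValueError("bounds must be positive")
    if list(bounds) != sorted(bounds, reverse=True):
        raise ValueError("bounds must be in descending order")
    x_all, y_all, _ = _masked_pair(measured, reference, mask)
    rows = []
    for bound in bounds:
        sel = np.abs(y_all) <= bound
        n = int(sel.sum())
        if n < 3:
            rows.append(
                dict(bound=bound, n_voxels=n, slope=np.nan, intercept=np.nan,
                     pearson_r=np.nan, p=np.nan, computed=False)
            )
            continue
        fit = stats.linregress(y_all[sel], x_all[sel])
        rows.append(
            dict(bound=bound, n_voxels=n, slope=float(fit.slope),
                 intercept=float(fit.intercept), pearson_r=float(fit.rvalue),
                 p=float(fit.pvalue), computed=True)
        )
    return pd.DataFrame(rows)


def paired_mean_field_test(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float]:
    """Paired two-sided t-test of per-subject mean field strengths.

    Returns (mean difference a - b, two-tailed p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    if np.all(diff == diff[0]):
        # degenerate zero-variance difference: the t statistic is 0/0 for a
        # zero mean (no evidence of a difference) and +/-inf otherwise
        return float(diff[0]), 1.0 if diff[0] == 0 else 0.0
    res = stats.ttest_rel(a, b)
    return float(np.mean(a - b)), float(res.pvalue)


def icc(
    test: FieldMap, retest: FieldMap, mask: np.ndarray | None = None
) -> float:
    """Voxelwise test-retest ICC(2,1).

    Two-way random-effects, absolute-agreement, single-measurement
    intraclass correlation, with voxels as the measured targets and the two
    sessions as raters:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    from the row (voxel), column (session) and residual mean squares of the
    two-way ANOVA decomposition.
    """
    x, y, _ = _masked_pair(test, retest, mask)
    if x.size < 3:
        raise ValueError("need at least 3 masked voxels")
    data = np.column_stack([x, y])  # (n, k)
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = data - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("zero total variance: ICC undefined")
    return float((msr - mse) / denom)


def threshold_cluster_mask(
    p_map: np.ndarray, p_threshold: float, min_cluster: int = 1
) -> np.ndarray:
    """Binary mask of voxels below ``p_threshold`` in clusters of
    at least ``min_cluster`` voxels (26-connected components)."""
    sig = np.asarray(p_map) < p_threshold
    if min_cluster <= 1:
        return sig
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, n = ndimage.label(sig, structure=structure)
    if n == 0:
        return sig
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= min_cluster)
    keep = keep[keep != 0]
    return np.isin(labels, keep)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """DICE overlap 2|a & b| / (|a| + |b|) between binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    total = a.sum() + b.sum()
    if total == 0:
        raise ValueError("both masks are empty: DICE undefined")
    return float(2.0 * np.logical_and(a, b).sum() / total)


@dataclass
class GroupBoldResult:
    """Group test of component-timecourse dependence on applied current."""

    betas: np.ndarray  # per-subject normalized signal change per mA
    mean: float
    t_stat: float
    p: float


def extract_component_timecourse(
    data: np.ndarray, component_map: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Stage-1 regression: project each volume onto a spatial component map.

    The map is variance-normalized over the mask; the timecourse is the
    least-squares coefficient of each volume's voxel pattern on the map,
    so a one-voxel map returns that voxel's timecourse up to scale.
    """
    if data.ndim != 4:
        raise ValueError("data must be a 4D series")
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    m = np.asarray(component_map, dtype=float)[mask]
    sd = m.std()
    if not m.any():
        raise ValueError("component map is zero over the mask")
    if sd > 0:
        m = m / sd
    Y = data[mask]  # (v, t)
    return (m @ Y) / (m @ m)


def component_current_test(
    data: Sequence[np.ndarray],
    component_map: np.ndarray,
    waveform: CurrentWaveform,
    hrf: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    convolve: bool = True,
    normalize: str = "baseline",
) -> GroupBoldResult:
    """Two-stage test of a component's BOLD dependence on the current.

    Stage 1 extracts each subject's component timecourse by spatial
    regression; stage 2 regresses that timecourse on the (optionally
    HRF-convolved) current waveform.  With ``normalize='baseline'`` the
    per-subject effect is slope/intercept - the fractional signal change
    per mA relative to the zero-current baseline; ``'zscore'`` instead
    z-scores the timecourse first.  A one-sample two-tailed t-test across
    subjects gives the group significance.
    """
    if len(data) < 2:
        raise ValueError("need at least 2 subjects")
    if hrf is None:
        hrf = double_gamma_hrf(waveform.tr)
    regressor = convolve_hrf(waveform.currents, hrf) if convolve else waveform.currents
    X = np.column_stack([np.ones(waveform.n_volumes), regressor])
    betas = []
    for subject in data:
        if subject.shape[3] != waveform.n_volumes:
            raise ValueError("subject series length does not match waveform")
        tc = extract_component_timecourse(subject, component_map, mask)
        if normalize == "zscore":
            sd = tc.std()
            if sd == 0:
                raise ValueError("constant timecourse cannot be z-scored")
            coef, *_ = np.linalg.lstsq(X, (tc - tc.mean()) / sd, rcond=None)
            betas.append(coef[1])
        elif normalize == "baseline":
            coef, *_ = np.linalg.lstsq(X, tc, rcond=None)
            if coef[0] == 0:
                raise ValueError("zero baseline: normalized change undefined")
            betas.append(coef[1] / coef[0])
        else:
            raise ValueError("normalize must be 'baseline' or 'zscore'")
    betas = np.asarray(betas)
    res = stats.ttest_1samp(betas, 0.0)
    return GroupBoldResult(
        betas=betas,
        mean=float(betas.mean()),
        t_stat=float(res.statistic),
        p=float(res.pvalue),
    )
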