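"""Intravoxel-dephasing confound models for current-locked BOLD changes.

A current-induced field gradient across a voxel dephases spins within the
voxel and so changes the magnitude signal, mimicking BOLD.  With phi the
across-voxel phase spread at the BOLD echo,

    phi = gamma * |grad Bz| * TE2        (|grad Bz| in T per voxel),

two closed-form bounds on the fractional signal change are used:

    Model #1:  fS = 1 - cos(phi/2)            (maximum inhomogeneity:
                                               two half-voxel compartments)
    Model #2:  fS = 1 - sin(phi/2) / (phi/2)  (linear spread of the field
                                               across the voxel)

Both vanish as phi -> 0 and Model #1 >= Model #2 (a uniform linear spread
dephases less than the same span concentrated at the extremes).  Comparing
fS against the observed per-mA signal change bounds how much of an apparent
BOLD effect dephasing could explain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .acquisition import AcquisitionParams
from .biot_savart import FieldMap


@dataclass
class ConfoundEstimate:
    """Dephasing confound relative to an observed per-mA signal change."""

    label: str
    grad_worst: float  # nT per voxel, per mA
    phi: float  # rad, per mA
    fs_model1: float
    fs_model2: float
    observed_per_mA: float
    ratio_model1: float
    ratio_model2: float
    flagged: bool = False


def gradient_magnitude(field: FieldMap) -> np.ndarray:
    """Euclidean norm of the per-axis field differences, nT per voxel step.

    Central differences in the interior, one-sided at the edges; singleton
    axes contribute zero.  The unit is nT per voxel (not per mm): the
    dephasing span relevant to intravoxel signal loss is the field
    difference across one voxel.
    """
    values = field.values
    grads = []
    for axis in range(3):
        if values.shape[axis] < 2:
            continue
        grads.append(np.gradient(values, axis=axis))
    if not grads:
        return np.zeros(values.shape)
    return np.sqrt(np.sum([g**2 for g in grads], axis=0))


def worst_case_gradient(
    field: FieldMap, region: np.ndarray | None = None, percentile: float = 100.0
) -> float:
    """Worst-case |grad Bz| (nT/voxel per mA) over an analysis region.

    ``percentile`` < 100 gives a robust alternative to the strict maximum.
    """
    grad = gradient_magnitude(field)
    sel = field.mask if region is None else (field.mask & np.asarray(region, bool))
    if not sel.any():
        raise ValueError("empty analysis region")
    return float(np.percentile(grad[sel], percentile))


def confound_fraction(phi: np.ndarray | float, model: int) -> np.ndarray | float:
    """Fractional signal change from intravoxel dephasing span ``phi`` (rad)."""
    phi_arr = np.asarray(phi, dtype=float)
    if np.any(phi_arr < 0):
        raise ValueError("phi must be >= 0")
    half = phi_arr / 2.0
    if model == 1:
        out = 1.0 - np.cos(half)
    elif model == 2:
        # sinc handles the removable singularity at phi = 0 exactly
        out = 1.0 - np.sinc(half / np.pi)
    else:
        raise ValueError("model must be 1 or 2")
    return out if np.ndim(phi) else float(out)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not np.isfinite(x):
        return x
    return float(np.format_float_positional(
        x, precision=sig, unique=False, fractional=False, trim="k"
    ))


def confound_table(
    grad_worst: float,
    observed: list[tuple[str, float]],
    params: AcquisitionParams | None = None,
) -> list[ConfoundEstimate]:
    """Confound-to-observed ratios for a set of observed per-mA changes.

    ``grad_worst`` is the worst-case across-voxel field difference in nT
    per mA; phi = gamma * grad_worst * 1e-9 * TE2.  Each row reports both
    model ratios |fS / observed| rounded to 2 significant figures.  Rows
    with a zero observed change are flagged (ratio undefined).
    """
    if params is None:
        params = AcquisitionParams()
    phi = params.gamma * grad_worst * 1e-9 * params.te2
    fs1 = confound_fraction(phi, 1)
    fs2 = confound_fraction(phi, 2)
    rows = []
    for label, change in observed:
        flagged = change == 0
        r1 = np.nan if flagged else round_sig(fs1 / abs(change))
        r2 = np.nan if flagged else round_sig(fs2 / abs(change))
        rows.append(
            ConfoundEstimate(
                label=label,
                grad_worst=grad_worst,
                phi=phi,
                fs_model1=fs1,
                fs_model2=fs2,
                observed_per_mA=change,
                ratio_model1=r1,
                ratio_model2=r2,
                flagged=flagged,
            )
        )
    return rows


def confound_frame(rows: list[ConfoundEstimate]) -> pd.DataFrame:
    """Tabular view of confound estimates (one row per dataset)."""
    return pd.DataFrame(
        {
            "dataset": [r.label for r in rows],
            "observed_per_mA": [r.observed_per_mA for r in rows],
            "ratio_model1": [r.ratio_model1 for r in rows],
            "ratio_model2": [r.ratio_model2 for r in rows],
            "phi_rad": [r.phi for r in rows],
            "flagged": [r.flagged for r in rows],
        }
    )
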