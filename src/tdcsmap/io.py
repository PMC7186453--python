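"""Readers and writers: NIfTI-1 volumes, TSV waveforms/reports, JSON config.

Conventions: field maps are float32 NIfTI in nT/mA with the grid geometry
in an axis-aligned affine; phase volumes are float32 radians in [-pi, pi)
(scanner integer-scaled phase is accepted read-only via a declared scale);
waveforms are TSV with columns volume_index, time_s, current_mA (plus an
optional scan_index used to recover scan boundaries).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .acquisition import AcquisitionParams, CurrentWaveform, DualEchoSeries, wrap_phase
from .biot_savart import CurrentPath, FieldMap
from .grids import VoxelGrid

logger = logging.getLogger(__name__)

try:
    __version__ = version("tdcsmap")
except PackageNotFoundError:  # pragma: no cover
    __version__ = "unknown"


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def _load_axis_aligned(path: str | Path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    grid = VoxelGrid.from_affine(data.shape, img.affine)
    return data, grid


def write_volume(data: np.ndarray, grid: VoxelGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), grid.affine())
    nib.save(img, str(path))


def write_field_map(field: FieldMap, path: str | Path, mask_path: str | Path | None = None) -> None:
    write_volume(field.values, field.grid, path)
    if mask_path is not None:
        write_volume(field.mask.astype(np.float32), field.grid, mask_path)


def read_field_map(path: str | Path, mask_path: str | Path | None = None) -> FieldMap:
    values, grid = _load_axis_aligned(path)
    if mask_path is not None:
        mask_data, mask_grid = _load_axis_aligned(mask_path)
        if not grid.matches(mask_grid):
            raise ValueError(f"mask grid in {mask_path} does not match {path}")
        mask = mask_data > 0.5
    else:
        mask = np.isfinite(values)
    values = np.where(np.isfinite(values), values, 0.0)
    return FieldMap(grid=grid, values=values, mask=mask)


def read_mask(path: str | Path) -> np.ndarray:
    data, _ = _load_axis_aligned(path)
    return data > 0.5


def write_series(series: DualEchoSeries, prefix: str | Path) -> dict[str, Path]:
    """Write a dual-echo series as four NIfTI files plus a params JSON."""
    prefix = Path(prefix)
    paths = {}
    for name in ("magnitude_e1", "phase_e1", "magnitude_e2", "phase_e2"):
        p = prefix.parent / f"{prefix.name}_{name}.nii.gz"
        write_volume(getattr(series, name), series.grid, p)
        paths[name] = p
    p = prefix.parent / f"{prefix.name}_params.json"
    write_params(series.params, p)
    paths["params"] = p
    return paths


def read_series(
    mag1: str | Path,
    ph1: str | Path,
    mag2: str | Path,
    ph2: str | Path,
    params: AcquisitionParams | None = None,
    phase_scale: float | None = None,
) -> DualEchoSeries:
    """Assemble a DualEchoSeries from four 4D NIfTI files.

    ``phase_scale`` declares the radians-per-stored-unit factor for
    integer-scaled scanner phase (e.g. pi/4096 for values in
    [-4096, 4095]); float radian phase needs no scale.  Shapes and affines
    must agree within 1e-4 mm across the four files.
    """
    arrays = {}
    grids = {}
    for key, path in (("magnitude_e1", mag1), ("phase_e1", ph1),
                      ("magnitude_e2", mag2), ("phase_e2", ph2)):
        arrays[key], grids[key] = _load_axis_aligned(path)
        if arrays[key].ndim == 3:
            arrays[key] = arrays[key][..., None]
        if arrays[key].ndim != 4:
            raise ValueError(f"{path}: expected a 4D volume")
    ref_key = "magnitude_e1"
    for key, path in (("phase_e1", ph1), ("magnitude_e2", mag2), ("phase_e2", ph2)):
        if arrays[key].shape != arrays[ref_key].shape:
            raise ValueError(
                f"shape mismatch: {mag1} has {arrays[ref_key].shape}, "
                f"{path} has {arrays[key].shape}"
            )
        if not grids[key].matches(grids[ref_key]):
            raise ValueError(f"affine mismatch between {mag1} and {path}")
    for key in ("phase_e1", "phase_e2"):
        ph = arrays[key]
        if phase_scale is not None:
            ph = ph * phase_scale
        arrays[key] = wrap_phase(ph)
    if params is None:
        params = AcquisitionParams()
    return DualEchoSeries(
        magnitude_e1=arrays["magnitude_e1"],
        magnitude_e2=arrays["magnitude_e2"],
        phase_e1=arrays["phase_e1"],
        phase_e2=arrays["phase_e2"],
        grid=grids[ref_key],
        params=params,
    )


# ---------------------------------------------------------------------------
# TSV waveforms and reports
# ---------------------------------------------------------------------------

_WAVEFORM_COLUMNS = ("volume_index", "time_s", "current_mA")


def write_waveform(waveform: CurrentWaveform, path: str | Path) -> None:
    scan_index = np.zeros(waveform.n_volumes, dtype=int)
    for i, (start, stop) in enumerate(waveform.scan_segments()):
        scan_index[start:stop] = i
    frame = pd.DataFrame(
        {
            "volume_index": np.arange(waveform.n_volumes),
            "time_s": waveform.times,
            "current_mA": waveform.currents,
            "scan_index": scan_index,
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_waveform(path: str | Path) -> CurrentWaveform:
    frame = pd.read_csv(path, sep="\t")
    if frame.empty:
        raise ValueError(f"{path}: empty waveform file")
    missing = [c for c in _WAVEFORM_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    extra = [c for c in frame.columns if c not in (*_WAVEFORM_COLUMNS, "scan_index")]
    if extra:
        logger.warning("read_waveform: ignoring extra columns %s in %s", extra, path)
    vol = frame["volume_index"].to_numpy()
    if vol[0] != 0 or np.any(np.diff(vol) != 1):
        raise ValueError(f"{path}: volume_index must increase by 1 from 0")
    times = frame["time_s"].to_numpy(dtype=float)
    tr = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
    boundaries: tuple[int, ...] = ()
    if "scan_index" in frame.columns:
        scan = frame["scan_index"].to_numpy()
        boundaries = tuple(int(i) for i in np.flatnonzero(np.diff(scan) != 0) + 1)
    return CurrentWaveform(
        currents=frame["current_mA"].to_numpy(dtype=float),
        tr=tr,
        scan_boundaries=boundaries,
    )


def read_motion(path: str | Path) -> np.ndarray:
    """Read a 6-column motion-parameter table (TSV, optional header)."""
    frame = pd.read_csv(path, sep="\t")
    mot = frame.to_numpy(dtype=float)
    if mot.ndim != 2 or mot.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 motion columns, got {mot.shape}")
    return mot


def write_report(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV report with a software-version header comment."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# tdcsmap {__version__}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# JSON: params, paths, grids, run config
# ---------------------------------------------------------------------------

def write_params(params: AcquisitionParams, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(params), fh, indent=2)


def read_params(path: str | Path) -> AcquisitionParams:
    with open(path) as fh:
        return AcquisitionParams(**json.load(fh))


def write_current_path(cpath: CurrentPath, path: str | Path) -> None:
    payload = {
        "vertices": np.asarray(cpath.vertices).tolist(),
        "current": cpath.current,
        "closed": cpath.closed,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_current_path(path: str | Path) -> CurrentPath:
    with open(path) as fh:
        payload = json.load(fh)
    return CurrentPath(
        vertices=np.asarray(payload["vertices"], dtype=float),
        current=float(payload.get("current", 1.0)),
        closed=bool(payload.get("closed", False)),
    )


def write_grid(grid: VoxelGrid, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"shape": grid.shape, "spacing": grid.spacing, "origin": grid.origin},
            fh,
            indent=2,
        )


def read_grid(path: str | Path) -> VoxelGrid:
    with open(path) as fh:
        payload = json.load(fh)
    return VoxelGrid(
        shape=tuple(payload["shape"]),
        spacing=tuple(payload.get("spacing", (3.4, 3.4, 5.0))),
        origin=tuple(payload.get("origin", (0.0, 0.0, 0.0))),
    )


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of one pipeline run; round-trips via JSON."""

    params: AcquisitionParams = dataclasses.field(default_factory=AcquisitionParams)
    waveform_path: str | None = None
    mask_path: str | None = None
    bounds: tuple[float, ...] = (10.0, 5.0, 1.0)
    seed: int = 0
    out_prefix: str = "tdcsmap_run"

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        logger.info("run config: %s (seed=%d)", json.dumps(payload), self.seed)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = json.load(fh)
        payload["params"] = AcquisitionParams(**payload.get("params", {}))
        payload["bounds"] = tuple(payload.get("bounds", (10.0, 5.0, 1.0)))
        return cls(**payload)
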