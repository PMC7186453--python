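"""Synthetic dual-echo EPI acquisition.

Generates 4D magnitude+phase time series in which a known current-induced
field map Bz (nT/mA) is encoded in the MR phase,

    phi(v, t, e) = (omega0(v) + gamma * Bz(v) * I(t) * 1e-9) * TE_e
                   + drift * t + shift(scan(t)),   stored mod 2 pi,

with gamma the proton gyromagnetic ratio, I(t) the per-volume applied
current (mA) and omega0 a smooth static off-resonance (rad/s) playing the
role of B0 inhomogeneity.  Complex Gaussian noise is added to the complex
signal, and an optional BOLD-like effect multiplies the echo-2 magnitude
(the BOLD-weighted echo) inside a region, after convolution of the current
waveform with a haemodynamic response function.

The generator keeps the noise-free unwrapped phase as ground truth so that
unwrapping and model fitting can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

from .biot_savart import FieldMap
from .grids import VoxelGrid

#: Proton gyromagnetic ratio, rad/s/T.
GAMMA_PROTON = 2.6752218744e8

TWO_PI = 2.0 * np.pi


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap phase to the canonical storage interval [-pi, pi)."""
    w = np.mod(np.asarray(phi, dtype=float) + np.pi, TWO_PI) - np.pi
    # np.mod can round up to exactly 2*pi for tiny negative inputs
    return np.where(w >= np.pi, -np.pi, w)


@dataclass
class AcquisitionParams:
    """Dual-echo EPI acquisition parameters (seconds, rad/s/T)."""

    tr: float = 4.0
    te1: float = 0.011
    te2: float = 0.026
    gamma: float = GAMMA_PROTON
    baseline_magnitude: float = 100.0
    complex_noise_sd: float = 0.0
    drift_slope: float = 0.0  # rad per volume, instrumental phase drift
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.te1 < self.te2):
            raise ValueError("echo times must satisfy 0 < te1 < te2")
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.complex_noise_sd < 0:
            raise ValueError("complex_noise_sd must be >= 0")

    def phase_per_nt(self, echo: int = 2) -> float:
        """Phase (rad) accrued at the given echo per nT of induced field."""
        te = self.te2 if echo == 2 else self.te1
        return self.gamma * 1e-9 * te


@dataclass
class CurrentWaveform:
    """Per-volume applied current (mA) realizing a block design."""

    currents: np.ndarray
    tr: float
    scan_boundaries: tuple[int, ...] = ()
    block_length: float | None = None

    def __post_init__(self) -> None:
        self.currents = np.asarray(self.currents, dtype=float).ravel()
        if self.currents.size < 1:
            raise ValueError("waveform must contain at least one volume")
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        bounds = tuple(int(b) for b in self.scan_boundaries)
        if list(bounds) != sorted(bounds):
            raise ValueError("scan_boundaries must be sorted")
        if any(b <= 0 or b >= self.currents.size for b in bounds):
            raise ValueError("scan_boundaries must lie strictly inside the series")
        self.scan_boundaries = bounds

    @property
    def n_volumes(self) -> int:
        return self.currents.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr

    def scan_segments(self) -> list[tuple[int, int]]:
        """(start, stop) volume index pairs, one per scan."""
        edges = [0, *self.scan_boundaries, self.n_volumes]
        return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]

    def negated(self) -> "CurrentWaveform":
        return CurrentWaveform(
            currents=-self.currents,
            tr=self.tr,
            scan_boundaries=self.scan_boundaries,
            block_length=self.block_length,
        )


@dataclass
class BoldInjection:
    """Multiplicative BOLD-like effect on the echo-2 magnitude.

    ``effect_per_mA`` is the fractional signal change per mA at the plateau
    of the HRF-convolved current waveform; negative values emulate the
    inhibitory response seen under the cathode.
    """

    region_mask: np.ndarray
    effect_per_mA: float = -0.15
    hrf: np.ndarray | None = None  # sampled at TR; built on demand if None


def double_gamma_hrf(tr: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at TR, normalized to unit sum.

    Positive lobe peaking at 6 s, undershoot at 16 s with amplitude ratio
    6:1.  Unit sum makes the convolved waveform plateau at the block's
    current level, so injected effects are expressed per mA.
    """
    if tr <= 0:
        raise ValueError("tr must be > 0")
    t = np.arange(0, duration + tr / 2, tr)
    peak = stats.gamma.pdf(t, a=7.0, scale=1.0)
    undershoot = stats.gamma.pdf(t, a=17.0, scale=1.0)
    h = peak - undershoot / 6.0
    total = h.sum()
    if total <= 0:
        raise ValueError("HRF must integrate to a positive value")
    return h / total


def convolve_hrf(currents: np.ndarray, hrf: np.ndarray) -> np.ndarray:
    """Causal convolution of a per-volume waveform with an HRF, same length."""
    return np.convolve(np.asarray(currents, dtype=float), hrf)[: len(currents)]


@dataclass
class DualEchoSeries:
    """4D dual-echo magnitude and wrapped-phase time series."""

    magnitude_e1: np.ndarray
    magnitude_e2: np.ndarray
    phase_e1: np.ndarray
    phase_e2: np.ndarray
    grid: VoxelGrid
    params: AcquisitionParams
    truth: dict | None = None  # noise-free unwrapped phase per echo, if synthetic

    def __post_init__(self) -> None:
        shapes = {
            a.shape
            for a in (self.magnitude_e1, self.magnitude_e2, self.phase_e1, self.phase_e2)
        }
        if len(shapes) != 1:
            raise ValueError("all four series must share one (x, y, z, t) shape")
        shape = shapes.pop()
        if shape[:3] != tuple(self.grid.shape):
            raise ValueError("series spatial shape does not match grid")
        for name in ("phase_e1", "phase_e2"):
            ph = getattr(self, name)
            if ph.size and (ph.min() < -np.pi or ph.max() >= np.pi):
                raise ValueError(f"{name} must be wrapped to [-pi, pi)")

    @property
    def n_volumes(self) -> int:
        return self.magnitude_e1.shape[3]


def make_waveform(
    levels: Sequence[float],
    order: int | Sequence[Sequence[float]] = 0,
    block_length: float = 90.0,
    tr: float = 2.0,
    n_scans: int = 1,
    scan_length: float | None = None,
) -> CurrentWaveform:
    """Build a pseudo-random block-design current waveform.

    Each scan holds the given current levels in a seeded pseudo-random
    order, each level for ``block_length`` seconds; scans are concatenated
    and their boundaries recorded.  If ``scan_length`` exceeds one pass
    through the levels, further shuffled passes are appended (last block
    truncated if needed).

    Parameters
    ----------
    order
        Integer seed for the per-scan shuffles, or an explicit list of
        per-scan level sequences.
    """
    levels = list(levels)
    if not levels:
        raise ValueError("levels must be non-empty")
    if block_length < tr:
        raise ValueError("block_length must be >= tr")
    if abs(block_length / tr - round(block_length / tr)) > 1e-9:
        raise ValueError("block_length must be a multiple of tr")
    vols_per_block = int(round(block_length / tr))
    if scan_length is None:
        scan_length = block_length * len(levels)
    vols_per_scan = int(round(scan_length / tr))
    blocks_per_scan = int(np.ceil(vols_per_scan / vols_per_block))

    if isinstance(order, (int, np.integer)):
        rng = np.random.default_rng(int(order))
        scan_levels = []
        for _ in range(n_scans):
            seq: list[float] = []
            while len(seq) < blocks_per_scan:
                seq.extend(rng.permutation(levels).tolist())
            scan_levels.append(seq[:blocks_per_scan])
    else:
        scan_levels = [list(s) for s in order]
        if len(scan_levels) != n_scans:
            raise ValueError("explicit order must give one level sequence per scan")

    chunks = []
    boundaries = []
    offset = 0
    for seq in scan_levels:
        scan = np.repeat(np.asarray(seq, dtype=float), vols_per_block)[:vols_per_scan]
        if offset > 0:
            boundaries.append(offset)
        chunks.append(scan)
        offset += scan.size
    return CurrentWaveform(
        currents=np.concatenate(chunks),
        tr=tr,
        scan_boundaries=tuple(boundaries),
        block_length=block_length,
    )


def _smooth_offresonance(
    grid: VoxelGrid,
    rng: np.random.Generator,
    sd_rad_per_s: float,
    smooth_vox: float,
    max_te: float,
) -> np.ndarray:
    """Seeded smooth static off-resonance map omega0 (rad/s).

    Scaled to the target spatial SD, then rescaled down if necessary so
    that no neighbouring voxels differ by more than pi/2 of phase at the
    longest echo - a shimmed B0 field is spatially smooth, and synthetic
    data violating this would be physically un-unwrappable.
    """
    if sd_rad_per_s == 0:
        return np.zeros(grid.shape)
    raw = rng.standard_normal(grid.shape)
    smooth = ndimage.gaussian_filter(raw, sigma=smooth_vox, mode="nearest")
    s = smooth.std()
    if s == 0:  # degenerate tiny grid
        return np.zeros(grid.shape)
    omega0 = smooth * (sd_rad_per_s / s)
    max_step = max(
        np.abs(np.diff(omega0, axis=axis)).max()
        for axis in range(3)
        if omega0.shape[axis] > 1
    )
    limit = 0.5 * np.pi / max_te
    if max_step > limit:
        omega0 *= limit / max_step
    return omega0


def simulate_series(
    field: FieldMap,
    waveform: CurrentWaveform,
    params: AcquisitionParams,
    injection: BoldInjection | None = None,
    level_shifts: Sequence[float] | None = None,
    b0_sd_rad_per_s: float = 120.0,
    b0_smooth_vox: float = 3.0,
) -> DualEchoSeries:
    """Encode a field map into dual-echo magnitude+phase series.

    The noise-free complex signal per voxel v, volume t and echo e is

        baseline * exp(i [ omega0(v) TE_e + gamma Bz(v) I(t) 1e-9 TE_e
                           + drift t + shift(scan(t)) ])

    with complex Gaussian noise of sd ``params.complex_noise_sd`` added to
    the real and imaginary parts, and the phase wrapped to [-pi, pi).  If
    ``injection`` is given, the echo-2 magnitude is additionally scaled by
    (1 + effect_per_mA * (I conv hrf)(t)) inside the region.

    Parameters
    ----------
    level_shifts
        One constant phase offset (rad) per scan, emulating the abrupt
        between-scan jumps seen in long sessions; defaults to all zero.
    """
    if params.complex_noise_sd < 0:
        raise ValueError("complex_noise_sd must be >= 0")
    grid = field.grid
    n_t = waveform.n_volumes
    rng = np.random.default_rng(params.seed)

    omega0 = _smooth_offresonance(
        grid, rng, b0_sd_rad_per_s, b0_smooth_vox, max_te=params.te2
    )

    segments = waveform.scan_segments()
    if level_shifts is None:
        level_shifts = [0.0] * len(segments)
    if len(level_shifts) != len(segments):
        raise ValueError("need one level shift per scan")
    shift_t = np.zeros(n_t)
    for (start, stop), s in zip(segments, level_shifts):
        shift_t[start:stop] = s

    t_idx = np.arange(n_t)
    common_t = params.drift_slope * t_idx + shift_t  # (t,)
    currents = waveform.currents

    truth: dict[str, np.ndarray] = {}
    out: dict[str, np.ndarray] = {}
    for echo, te in ((1, params.te1), (2, params.te2)):
        rate = omega0[..., None] + params.gamma * 1e-9 * field.values[..., None] * currents
        phase_true = rate * te + common_t  # (x, y, z, t)
        mag_true = np.full(phase_true.shape, float(params.baseline_magnitude))
        if echo == 2 and injection is not None:
            hrf = injection.hrf
            if hrf is None:
                hrf = double_gamma_hrf(params.tr)
            response = 1.0 + injection.effect_per_mA * convolve_hrf(currents, hrf)
            region = np.asarray(injection.region_mask, dtype=bool)
            if region.shape != tuple(grid.shape):
                raise ValueError("injection region mask does not match grid")
            mag_true = np.where(region[..., None], mag_true * response, mag_true)
        signal = mag_true * np.exp(1j * phase_true)
        if params.complex_noise_sd > 0:
            noise = params.complex_noise_sd * (
                rng.standard_normal(signal.shape)
                + 1j * rng.standard_normal(signal.shape)
            )
            signal = signal + noise
        truth[f"phase_e{echo}"] = phase_true
        out[f"magnitude_e{echo}"] = np.abs(signal)
        out[f"phase_e{echo}"] = wrap_phase(np.angle(signal))

    return DualEchoSeries(
        magnitude_e1=out["magnitude_e1"],
        magnitude_e2=out["magnitude_e2"],
        phase_e1=out["phase_e1"],
        phase_e2=out["phase_e2"],
        grid=grid,
        params=params,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Human-like cohort fixture: bilateral montage emulation
# ---------------------------------------------------------------------------

def bilateral_field(
    grid: VoxelGrid, amplitude: float = 2.0, sigma_frac: float = 0.18
) -> tuple[FieldMap, np.ndarray, np.ndarray]:
    """Two-lobe field emulating a bilateral C3/C4 electrode montage.

    Returns the field map plus the boolean 'anodal' (positive lobe) and
    'cathodal' (negative lobe) patch masks.  The lobes are Gaussian, of
    opposite sign, centred laterally left/right in the upper part of the
    volume, with peak |Bz| = ``amplitude`` nT/mA.
    """
    idx = np.indices(grid.shape).astype(float)
    frac = [idx[i] / max(grid.shape[i] - 1, 1) for i in range(3)]
    sigma = sigma_frac

    def lobe(cx: float, cy: float, cz: float) -> np.ndarray:
        d2 = (frac[0] - cx) ** 2 + (frac[1] - cy) ** 2 + (frac[2] - cz) ** 2
        return np.exp(-d2 / (2 * sigma**2))

    anodal_pattern = lobe(0.75, 0.5, 0.7)
    cathodal_pattern = lobe(0.25, 0.5, 0.7)
    values = amplitude * (anodal_pattern - cathodal_pattern)
    mask = np.ones(grid.shape, dtype=bool)
    anodal_mask = anodal_pattern > 0.5
    cathodal_mask = cathodal_pattern > 0.5
    return FieldMap(grid=grid, values=values, mask=mask), anodal_mask, cathodal_mask


def cohort_fixture(
    n_subjects: int,
    seed: int,
    grid: VoxelGrid | None = None,
    effect_per_mA: float = -0.15,
    effect_jitter_sd: float = 0.05,
    amplitude: float = 2.0,
    amplitude_jitter_sd: float = 0.2,
    snr: float = 50.0,
    levels: Sequence[float] = (0.0, 1.0, 1.5, 2.0),
    tr: float = 2.0,
    block_length: float = 90.0,
    n_scans: int = 2,
    scan_length: float = 720.0,
) -> list[tuple[DualEchoSeries, FieldMap, CurrentWaveform]]:
    """Synthetic human-like cohort under a bilateral montage.

    Every subject shares the block-design waveform (fixed pseudo-random
    level order, as in a multi-subject protocol) and the bilateral two-lobe
    field pattern, with a subject-specific lognormal amplitude jitter.  A
    BOLD-like effect (fractional signal change per mA, HRF-convolved) is
    injected into the echo-2 magnitude under the 'cathodal' patch; the
    per-subject effect is ``effect_per_mA`` plus Gaussian jitter of sd
    ``effect_jitter_sd``, emulating inter-subject variability of the BOLD
    response.  Each subject's realized effect is recorded in
    ``series.truth['bold_effect_per_mA']``.  Complex noise is set from
    ``snr`` (baseline magnitude / noise sd).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if grid is None:
        grid = VoxelGrid(shape=(16, 16, 10), spacing=(3.4, 3.4, 4.0))
    rng = np.random.default_rng(seed)
    waveform = make_waveform(
        levels,
        order=int(rng.integers(2**31)),
        block_length=block_length,
        tr=tr,
        n_scans=n_scans,
        scan_length=scan_length,
    )
    out = []
    for _ in range(n_subjects):
        jitter = float(np.exp(rng.normal(0.0, amplitude_jitter_sd)))
        field, _, cathodal = bilateral_field(grid, amplitude=amplitude * jitter)
        params = AcquisitionParams(
            tr=tr,
            complex_noise_sd=100.0 / snr if snr > 0 else 0.0,
            seed=int(rng.integers(2**31)),
        )
        effect = effect_per_mA + (
            float(rng.normal(0.0, effect_jitter_sd)) if effect_jitter_sd > 0 else 0.0
        )
        injection = BoldInjection(
            region_mask=cathodal,
            effect_per_mA=effect,
            hrf=double_gamma_hrf(tr),
        )
        series = simulate_series(field, waveform, params, injection=injection)
        series.truth["bold_effect_per_mA"] = effect
        out.append((series, field, waveform))
    return out
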