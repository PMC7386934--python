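"""Nuisance modeling and removal for spinal-cord BOLD time series.

Physiological noise from the cardiac and respiratory cycles dominates
spinal-cord fMRI.  This module assigns a cardiac and a respiratory phase to
every slice acquisition (RETROICOR-style), expands them into a slice-specific
harmonic + interaction regressor basis (16 + 16 columns), extracts per-slice
CSF principal components from the spinal canal (5 columns), flags bulk-motion
volumes by intensity DVARS with a box-plot cutoff, high-pass filters with a
discrete-cosine basis, regresses the nuisance set out voxelwise, applies
slice-timing correction, mask-normalized Gaussian smoothing, and TSNR QC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

logger = logging.getLogger(__name__)

N_HARMONICS = 4          # principal frequency + next three harmonics
N_CSF_COMPONENTS = 5
HIGHPASS_CUTOFF_S = 100.0
SMOOTH_FWHM_MM = 2.0

__all__ = [
    "PhaseAssignment",
    "NuisanceSet",
    "assign_phases",
    "physio_basis",
    "csf_pca",
    "dvars_outliers",
    "highpass",
    "regress_nuisance",
    "slice_timing_correct",
    "smooth",
    "tsnr_map",
]

TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# Phase assignment
# ---------------------------------------------------------------------------

@dataclass
class PhaseAssignment:
    """Cardiac and respiratory phase (radians, [0, 2pi)) per (slice, volume)."""

    cardiac_phase: np.ndarray  # (n_slices, n_volumes)
    resp_phase: np.ndarray     # (n_slices, n_volumes)

    def __post_init__(self) -> None:
        for p in (self.cardiac_phase, self.resp_phase):
            if np.any(p < 0) or np.any(p >= TWO_PI):
                raise ValueError("phases must lie in [0, 2*pi)")


def cardiac_phase_at(times: np.ndarray, peak_times: np.ndarray) -> np.ndarray:
    """Cardiac phase: linear 0..2pi between successive R-peaks.

    ``phase(t) = 2*pi * (t - p_prev) / (p_next - p_prev)``.
    """
    times = np.asarray(times, dtype=float)
    peaks = np.asarray(peak_times, dtype=float)
    if np.any(np.diff(peaks) <= 0):
        raise ValueError("peak_times must be strictly increasing")
    idx = np.searchsorted(peaks, times, side="right")
    if np.any(idx == 0) or np.any(idx >= len(peaks)):
        raise ValueError("slice times outside cardiac peak coverage")
    prev = peaks[idx - 1]
    nxt = peaks[idx]
    phase = TWO_PI * (times - prev) / (nxt - prev)
    return np.mod(phase, TWO_PI)


def respiratory_phase_at(
    times: np.ndarray, samples: np.ndarray, sampling_rate: float,
    n_bins: int = 100,
) -> np.ndarray:
    """Respiratory phase by amplitude-histogram equalization.

    The phase combines where the instantaneous amplitude sits in the
    amplitude histogram with the sign of the amplitude derivative
    (inspiration vs expiration):
    ``phase = pi * H(a) / H_total * sign(da/dt)``, mapped to [0, 2pi).
    """
    samples = np.asarray(samples, dtype=float)
    t_samp = np.arange(len(samples)) / sampling_rate
    if times.min() < t_samp[0] - 1e-9 or times.max() > t_samp[-1] + 1e-9:
        raise ValueError("slice times outside respiratory trace coverage")
    # light smoothing stabilizes the derivative sign
    win = max(int(round(sampling_rate * 0.5)), 1)
    sm = ndimage.uniform_filter1d(samples, win)
    a = np.interp(times, t_samp, sm)
    da = np.interp(times, t_samp, np.gradient(sm) * sampling_rate)
    edges = np.linspace(sm.min(), sm.max() + 1e-12, n_bins + 1)
    hist, _ = np.histogram(sm, bins=edges)
    cum = np.concatenate([[0], np.cumsum(hist)]).astype(float)
    frac = np.interp(a, edges, cum / cum[-1])
    phase = np.pi * frac * np.where(da >= 0, 1.0, -1.0)
    return np.mod(phase, TWO_PI)


def assign_phases(
    cardiac, resp, slice_times: np.ndarray, tr: float, n_volumes: int,
) -> PhaseAssignment:
    """Assign cardiac/respiratory phase to each slice acquisition event.

    ``cardiac`` and ``resp`` are physiological traces (see
    :class:`cordmap.cordsim.PhysioTrace`); slice z is acquired at
    ``v * tr + slice_times[z]`` for volume v.
    """
    slice_times = np.asarray(slice_times, dtype=float)
    acq = (np.arange(n_volumes)[None, :] * tr) + slice_times[:, None]
    card = cardiac_phase_at(acq.ravel(), cardiac.peak_times).reshape(acq.shape)
    rsp = respiratory_phase_at(
        acq.ravel(), resp.samples, resp.sampling_rate
    ).reshape(acq.shape)
    return PhaseAssignment(cardiac_phase=card, resp_phase=rsp)


# ---------------------------------------------------------------------------
# Regressor construction
# ---------------------------------------------------------------------------

def physio_basis(phases: PhaseAssignment) -> tuple[np.ndarray, list[str]]:
    """Slice-specific RETROICOR basis: 16 harmonic + 16 interaction columns.

    Harmonics: sin/cos(k*phi_c) and sin/cos(k*phi_r) for k = 1..4
    (16 columns).  Interactions: sin/cos(k*phi_c + phi_r) and
    sin/cos(k*phi_c - phi_r) for k = 1..4 (16 more).

    Returns ``(block, labels)`` with ``block`` of shape
    ``(n_slices, n_volumes, 32)``.
    """
    pc = phases.cardiac_phase
    pr = phases.resp_phase
    cols, labels = [], []
    for k in range(1, N_HARMONICS + 1):
        cols += [np.sin(k * pc), np.cos(k * pc)]
        labels += [f"card_sin{k}", f"card_cos{k}"]
        cols += [np.sin(k * pr), np.cos(k * pr)]
        labels += [f"resp_sin{k}", f"resp_cos{k}"]
    for k in range(1, N_HARMONICS + 1):
        for sign, tag in ((1.0, "p"), (-1.0, "m")):
            arg = k * pc + sign * pr
            cols += [np.sin(arg), np.cos(arg)]
            labels += [f"inter_sin{k}{tag}", f"inter_cos{k}{tag}"]
    return np.stack(cols, axis=-1), labels


def csf_pca(
    bold: np.ndarray, canal_mask: np.ndarray,
    n_components: int = N_CSF_COMPONENTS,
) -> tuple[np.ndarray, list[list[str]]]:
    """Per-slice leading principal components of the spinal-canal CSF signal.

    For every slice with canal voxels, returns the first ``n_components``
    principal-component time courses (mean-centered, unit norm, ordered by
    explained variance).  Slices with fewer voxels than components get fewer
    columns; the remainder is zero-filled and flagged in the labels.

    Returns ``(block, labels)``: block ``(n_slices, T, n_components)``.
    """
    nx, ny, nz, t = bold.shape
    block = np.zeros((nz, t, n_components))
    labels: list[list[str]] = []
    for z in range(nz):
        m = canal_mask[:, :, z]
        lab = []
        nvox = int(m.sum())
        if nvox == 0:
            raise ValueError(f"canal mask empty on slice {z}")
        x = bold[:, :, z, :][m].T.astype(float)          # (T, nvox)
        x = x - x.mean(axis=0)
        if not np.any(x):
            warnings.warn(f"slice {z}: constant CSF signal, no components",
                          stacklevel=2)
            labels.append([])
            continue
        k = min(n_components, nvox, t - 1)
        if k < n_components:
            warnings.warn(
                f"slice {z}: only {k} CSF components available "
                f"({nvox} canal voxels)", stacklevel=2)
        u, s, _ = np.linalg.svd(x, full_matrices=False)
        for j in range(k):
            pc = u[:, j]
            pc = pc - pc.mean()
            nrm = np.linalg.norm(pc)
            if nrm > 0:
                pc = pc / nrm
            # sign convention: largest-magnitude sample positive
            if pc[np.argmax(np.abs(pc))] < 0:
                pc = -pc
            block[z, :, j] = pc
            lab.append(f"csf_pc{j + 1}")
        labels.append(lab)
    return block, labels


# ---------------------------------------------------------------------------
# DVARS outlier detection
# ---------------------------------------------------------------------------

def dvars_outliers(
    bold: np.ndarray, mask: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Intensity DVARS series with box-plot outlier flags.

    DVARS_t = RMS over mask voxels of (I_t - I_{t-1}), defined for
    t = 1..T-1 (index 0 is set to 0 and excluded from the threshold).
    Volume t is flagged when DVARS_t exceeds Q3 + 1.5*IQR of the series;
    a step change at volume s perturbs the differences at s and s+1, so
    both adjacent volumes are flagged.

    Returns ``(flags, onehot, dvars)`` where ``flags`` is the sorted array of
    flagged volume indices and ``onehot`` is (T, n_flagged).
    """
    if not mask.any():
        raise ValueError("empty mask")
    t = bold.shape[-1]
    if t < 3:
        raise ValueError("need at least 3 volumes")
    ts = bold[mask.astype(bool)].astype(float)          # (V, T)
    d = np.diff(ts, axis=1)
    dvars = np.zeros(t)
    dvars[1:] = np.sqrt(np.mean(d**2, axis=0))
    q1, q3 = np.percentile(dvars[1:], [25, 75])
    thresh = q3 + 1.5 * (q3 - q1)
    flags = np.flatnonzero(dvars > thresh)
    onehot = np.zeros((t, len(flags)))
    for j, f in enumerate(flags):
        onehot[f, j] = 1.0
    return flags, onehot, dvars


# ---------------------------------------------------------------------------
# Temporal filtering
# ---------------------------------------------------------------------------

def dct_highpass_basis(n: int, tr: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine drift basis: components with period > ``cutoff_s``.

    Component k (k >= 1) has period 2*n*tr/k; K = floor(2*n*tr/cutoff)
    components are returned, orthonormal, constant excluded.
    """
    k_max = int(np.floor(2.0 * n * tr / cutoff_s))
    t = np.arange(n)
    basis = np.empty((n, k_max))
    for k in range(1, k_max + 1):
        basis[:, k - 1] = np.cos(np.pi * k * (t + 0.5) / n)
    basis /= np.linalg.norm(basis, axis=0, keepdims=True)
    return basis


def highpass(
    series: np.ndarray, cutoff_s: float = HIGHPASS_CUTOFF_S, tr: float = 2.0,
) -> np.ndarray:
    """High-pass filter by projecting out slow discrete-cosine components.

    Operates on the leading time axis of shape (T,) or (T, ...); the
    temporal mean is re-added after filtering.
    """
    if cutoff_s <= 2 * tr:
        raise ValueError("cutoff must exceed 2*TR")
    x = np.asarray(series, dtype=float)
    flat = x.reshape(x.shape[0], -1)
    mean = flat.mean(axis=0)
    basis = dct_highpass_basis(x.shape[0], tr, cutoff_s)
    resid = flat - mean
    resid = resid - basis @ (basis.T @ resid)
    return (resid + mean).reshape(x.shape)


# ---------------------------------------------------------------------------
# Nuisance regression
# ---------------------------------------------------------------------------

@dataclass
class NuisanceSet:
    """Slice-specific nuisance regressors plus global outlier columns.

    ``physio_block``: (n_slices, T, 32); ``csf_block``: (n_slices, T, <=5);
    ``outlier_block``: (T, n_outliers) one-hot columns shared by all slices.
    """

    physio_block: np.ndarray
    csf_block: np.ndarray
    outlier_block: np.ndarray | None = None
    labels: dict = field(default_factory=dict)

    def slice_design(self, z: int) -> np.ndarray:
        parts = [self.physio_block[z], self.csf_block[z]]
        if self.outlier_block is not None and self.outlier_block.shape[1]:
            parts.append(self.outlier_block)
        return np.concatenate(parts, axis=1)


def regress_nuisance(
    bold: np.ndarray, nuisance: NuisanceSet, mask: np.ndarray | None = None,
    protect: np.ndarray | None = None,
) -> np.ndarray:
    """Voxelwise least-squares removal of the slice-specific nuisance set.

    Each voxel is regressed on its own slice's nuisance block (plus an
    intercept); the residual is returned with the voxel mean restored.
    Ill-conditioned blocks trigger a warning; the SVD-based least squares
    solve acts as the pseudo-inverse fallback.

    ``protect`` (T, k) is an optional signal subspace — typically the task
    design — that the nuisance block is orthogonalized against first, so
    chance correlation between nuisance columns and the task cannot drain
    task variance from the data.
    """
    out = bold.astype(np.float32).copy()
    nz, t = bold.shape[2], bold.shape[3]
    if protect is not None:
        protect = np.asarray(protect, dtype=float)
        q, _ = np.linalg.qr(protect - protect.mean(axis=0))
    for z in range(nz):
        if mask is not None:
            m = mask[:, :, z].astype(bool)
            if not m.any():
                continue
        else:
            m = np.ones(bold.shape[:2], dtype=bool)
        x = nuisance.slice_design(z)
        if x.shape[0] != t:
            raise ValueError("nuisance block length mismatch")
        if protect is not None:
            x = x - q @ (q.T @ x)
        xc = np.column_stack([np.ones(t), x])
        cond = np.linalg.cond(xc)
        if cond > 1e8:
            warnings.warn(
                f"slice {z}: nuisance block condition number {cond:.2g}; "
                "using pseudo-inverse", stacklevel=2)
        y = out[:, :, z, :][m].T.astype(float)           # (T, V)
        beta, *_ = np.linalg.lstsq(xc, y, rcond=None)
        resid = y - xc[:, 1:] @ beta[1:]                 # keep the mean
        out[:, :, z, :][m] = resid.T.astype(np.float32)
    return out


# ---------------------------------------------------------------------------
# Slice-timing correction
# ---------------------------------------------------------------------------

def slice_timing_correct(
    bold: np.ndarray, slice_times: np.ndarray, tr: float,
    method: str = "sinc",
) -> np.ndarray:
    """Temporal resampling of each slice to the volume midpoint.

    Slice z's samples sit at ``v*tr + slice_times[z]``; they are resampled
    to ``(v + 1/2)*tr``.  ``method='sinc'`` applies the shift as a Fourier
    phase ramp on the reflect-padded series (exact for band-limited
    signals, no amplitude attenuation); ``method='linear'`` uses two-point
    interpolation with edge clamping.
    """
    if method not in ("sinc", "linear"):
        raise ValueError("method must be 'sinc' or 'linear'")
    t = bold.shape[-1]
    out = np.empty_like(bold, dtype=np.float32)
    grid = np.arange(t, dtype=float)
    pad = min(32, t // 4)
    for z in range(bold.shape[2]):
        # shift in volume units; target = source grid + delta
        delta = (0.5 * tr - slice_times[z]) / tr
        sl = bold[:, :, z, :]
        if method == "linear":
            src = np.clip(grid + delta, 0, t - 1)
            lo = np.floor(src).astype(int)
            hi = np.minimum(lo + 1, t - 1)
            w = (src - lo).astype(np.float32)
            out[:, :, z, :] = sl[..., lo] * (1 - w) + sl[..., hi] * w
        else:
            padded = np.concatenate(
                [sl[..., pad:0:-1], sl, sl[..., -2:-pad - 2:-1]], axis=-1)
            n = padded.shape[-1]
            freqs = np.fft.rfftfreq(n)
            shifted = np.fft.irfft(
                np.fft.rfft(padded, axis=-1)
                * np.exp(2j * np.pi * freqs * delta), n=n, axis=-1)
            out[:, :, z, :] = shifted[..., pad:pad + t]
    return out


# ---------------------------------------------------------------------------
# Smoothing and QC
# ---------------------------------------------------------------------------

def smooth(
    bold: np.ndarray, mask: np.ndarray, fwhm_mm: float = SMOOTH_FWHM_MM,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 3.0),
) -> np.ndarray:
    """Mask-normalized Gaussian smoothing restricted to ``mask``.

    The kernel is Gaussian with the given FWHM in millimetres; smoothing is
    normalized by the smoothed mask so edge voxels are not diluted by
    outside-mask zeros.  Voxels outside the mask pass through unchanged.
    """
    if not mask.any():
        raise ValueError("empty mask")
    if fwhm_mm < min(voxel_size_mm[:2]):
        raise ValueError("FWHM below in-plane voxel size")
    sigma_vox = tuple(
        fwhm_mm / (np.sqrt(8 * np.log(2)) * v) for v in voxel_size_mm
    )
    m = mask.astype(float)
    wm = ndimage.gaussian_filter(m, sigma_vox)
    single = bold.ndim == 3
    vols = bold[..., None] if single else bold
    out = vols.astype(np.float32).copy()
    inside = mask.astype(bool)
    for v in range(vols.shape[-1]):
        num = ndimage.gaussian_filter(vols[..., v] * m, sigma_vox)
        sm = np.divide(num, wm, out=np.zeros_like(num), where=wm > 1e-12)
        out[..., v][inside] = sm[inside]
    return out[..., 0] if single else out


def tsnr_map(
    bold: np.ndarray, mask: np.ndarray,
) -> tuple[np.ndarray, float, int]:
    """Temporal SNR: voxel temporal mean / SD of the linearly detrended series.

    Returns ``(tsnr_volume, mean_tsnr_in_mask, n_excluded)``; zero-variance
    voxels are excluded from the mean and counted.
    """
    if bold.shape[-1] < 10:
        raise ValueError("need at least 10 volumes for TSNR")
    m = mask.astype(bool)
    ts = bold[m].astype(float)                           # (V, T)
    mean = ts.mean(axis=1)
    det = signal.detrend(ts, axis=1)
    sd = det.std(axis=1, ddof=1)
    tsnr = np.zeros(ts.shape[0])
    ok = sd > 1e-10 * np.maximum(1.0, np.abs(mean))
    tsnr[ok] = mean[ok] / sd[ok]
    n_excl = int((~ok).sum())
    if n_excl:
        logger.info("tsnr_map: excluded %d zero-variance voxels", n_excl)
    vol = np.zeros(bold.shape[:3])
    vol[m] = tsnr
    return vol, float(tsnr[ok].mean()) if ok.any() else float("nan"), n_excl
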