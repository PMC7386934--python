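"""Template-space spinal-cord phantom and synthetic BOLD run generator.

Stands in for the study's raw data: an elliptical cord with a concentric
gray-matter core and a surrounding CSF ring on a coarse template-like grid,
partitioned into left/right and dorsal/ventral hemicords and three segment
levels (C5 superior, C6, C7 inferior; z increases superiorly).  Synthetic
runs carry a block-design activation of known location and amplitude
(defaults emulate a 450-volume TR=2 s run with ~0.7% signal change), cardiac
(~1 Hz) and respiratory (~0.25 Hz) quasi-periodic noise phase-locked to
generated physiological traces, slow drift, white noise, and optional
whole-volume spike artifacts for outlier-detection testing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .denoise import cardiac_phase_at, respiratory_phase_at
from .protocol import (
    HRFSpec,
    StimulationProtocol,
    generate_protocol,
    task_regressor,
    task_regressor_at,
)

__all__ = [
    "CordPhantomSpec",
    "CordAtlas",
    "GroundTruth",
    "PhysioTrace",
    "BOLDRun",
    "NoiseSpec",
    "CohortSpec",
    "build_atlas",
    "simulate_physio",
    "simulate_run",
    "make_lateralized_truth",
    "simulate_cohort_subject",
    "generate_cohort",
    "interleaved_slice_times",
]


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CordPhantomSpec:
    """Phantom geometry and run-length parameters.

    The default grid (24 x 24 x 48 voxels at 1 x 1 x 3 mm) is deliberately
    coarser than the 0.5 mm isotropic template it emulates so a full cohort
    runs in seconds.  ``segment_z_bounds`` are half-open voxel-z intervals;
    z increases superiorly, so C5 (the most superior segment) owns the top
    interval.
    """

    grid_shape: tuple[int, int, int] = (24, 24, 48)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 3.0)
    cord_radii: tuple[float, float] = (4.0, 3.0)   # mm, (x, y) semi-axes
    gm_fraction: float = 0.2
    segment_z_bounds: dict = field(default_factory=lambda: {
        "C7": (0, 16), "C6": (16, 32), "C5": (32, 48),
    })
    canal_margin: float = 2.5                       # mm CSF ring width
    n_volumes: int = 450
    tr: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 < self.gm_fraction < 1.0):
            raise ValueError("gm_fraction must be in (0, 1)")
        nz = self.grid_shape[2]
        ivs = sorted(self.segment_z_bounds.values())
        if ivs[0][0] != 0 or ivs[-1][1] != nz:
            raise ValueError("segment intervals must cover the z-extent")
        for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
            if a1 != b0:
                raise ValueError("segment intervals must be contiguous and disjoint")


@dataclass
class CordAtlas:
    """Named binary compartment masks on a shared voxel grid.

    Masks: cord, left_hemicord, right_hemicord, dorsal_hemicord,
    ventral_hemicord, C5, C6, C7, gm, wm, canal_csf.  Left/right,
    dorsal/ventral, gm/wm each partition the cord exactly; C5|C6|C7 cover it;
    the CSF ring is disjoint from the cord.  The white matter is more than
    three times the volume of the gray matter, as in the real cord.
    """

    masks: dict[str, np.ndarray]
    grid_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def validate(self) -> None:
        m = self.masks
        cord = m["cord"]
        if not cord.any():
            raise ValueError("empty cord mask")
        pairs = [("left_hemicord", "right_hemicord"),
                 ("dorsal_hemicord", "ventral_hemicord"), ("gm", "wm")]
        for a, b in pairs:
            if np.any(m[a] & m[b]):
                raise ValueError(f"{a} and {b} overlap")
            if not np.array_equal(m[a] | m[b], cord):
                raise ValueError(f"{a} | {b} != cord")
        seg = m["C5"] | m["C6"] | m["C7"]
        if not np.array_equal(seg, cord):
            raise ValueError("segments do not cover the cord")
        if np.any(m["canal_csf"] & cord):
            raise ValueError("CSF ring intersects the cord")
        for name, mask in m.items():
            if not mask.any():
                raise ValueError(f"empty compartment {name}")
        if m["wm"].sum() <= 3 * m["gm"].sum():
            raise ValueError("WM volume must exceed 3x GM volume")


def build_atlas(spec: CordPhantomSpec = CordPhantomSpec()) -> CordAtlas:
    """Rasterize the phantom geometry into compartment masks.

    The cord is an ellipse per axial slice; gray matter is a concentric inner
    ellipse scaled so its area fraction equals ``gm_fraction`` (a stand-in
    for the GM butterfly, sufficient for count-based statistics); the spinal
    canal CSF is an elliptical ring of width ``canal_margin`` around the
    cord.  Left = lower x index, dorsal = higher y index.
    """
    nx, ny, nz = spec.grid_shape
    dx, dy, dz = spec.voxel_size
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    x = (np.arange(nx) - cx) * dx
    y = (np.arange(ny) - cy) * dy
    xx, yy = np.meshgrid(x, y, indexing="ij")
    rx, ry = spec.cord_radii
    if rx + spec.canal_margin > (nx * dx) / 2 or ry + spec.canal_margin > (ny * dy) / 2:
        raise ValueError("grid too small for cord plus CSF ring")

    r2 = (xx / rx) ** 2 + (yy / ry) ** 2
    cord2d = r2 <= 1.0
    s = np.sqrt(spec.gm_fraction)
    gm2d = ((xx / (s * rx)) ** 2 + (yy / (s * ry)) ** 2) <= 1.0
    ring2d = (((xx / (rx + spec.canal_margin)) ** 2
               + (yy / (ry + spec.canal_margin)) ** 2) <= 1.0) & ~cord2d
    left2d = cord2d & (np.arange(nx)[:, None] < cx)
    dorsal2d = cord2d & (np.arange(ny)[None, :] > cy)

    def stack(m2d):
        return np.repeat(m2d[:, :, None], nz, axis=2)

    masks = {
        "cord": stack(cord2d),
        "left_hemicord": stack(left2d),
        "right_hemicord": stack(cord2d & ~left2d),
        "dorsal_hemicord": stack(dorsal2d),
        "ventral_hemicord": stack(cord2d & ~dorsal2d),
        "gm": stack(gm2d & cord2d),
        "wm": stack(cord2d & ~gm2d),
        "canal_csf": stack(ring2d),
    }
    cord3d = masks["cord"]
    for seg, (z0, z1) in spec.segment_z_bounds.items():
        m = np.zeros_like(cord3d)
        m[:, :, z0:z1] = cord3d[:, :, z0:z1]
        masks[seg] = m
    affine = np.diag([dx, dy, dz, 1.0])
    atlas = CordAtlas(masks=masks, grid_shape=spec.grid_shape,
                      voxel_size=spec.voxel_size, affine=affine)
    atlas.validate()
    return atlas


# ---------------------------------------------------------------------------
# Physiological traces
# ---------------------------------------------------------------------------

@dataclass
class PhysioTrace:
    """Sampled physiological signal (cardiac or respiratory).

    Cardiac traces carry the R-peak times; the respiratory phase is later
    derived from the sampled amplitude itself.
    """

    samples: np.ndarray
    sampling_rate: float
    kind: str                       # "cardiac" | "respiratory"
    peak_times: np.ndarray | None = None

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate

    def to_tsv(self, path) -> None:
        t = np.arange(len(self.samples)) / self.sampling_rate
        np.savetxt(path, np.column_stack([t, self.samples]),
                   delimiter="\t", header="time_s\tamplitude", comments="")

    def header(self) -> dict:
        return {"sampling_rate": self.sampling_rate, "kind": self.kind}


def _jittered_onsets(rate_hz: float, jitter: float, duration: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Cycle onset times with per-cycle period jitter, covering [0, duration]
    with one extra cycle on each side so phase interpolation never runs out."""
    period = 1.0 / rate_hz
    n = int(np.ceil(duration * rate_hz * (1.5 + 3 * jitter))) + 4
    periods = period * (1.0 + jitter * rng.standard_normal(n))
    if np.any(periods <= 0):
        raise ValueError("rate_jitter produced a non-positive cycle period")
    onsets = np.concatenate([[0.0], np.cumsum(periods)])
    if onsets[-1] < duration + 2 * period:
        raise RuntimeError("cycle generation fell short of the run duration")
    return onsets


def simulate_physio(
    duration_s: float,
    cardiac_rate_hz: float = 1.0,
    resp_rate_hz: float = 0.25,
    rate_jitter: float = 0.05,
    seed: int = 0,
    sampling_rate: float = 20.0,
) -> tuple[PhysioTrace, PhysioTrace]:
    """Quasi-periodic cardiac and respiratory traces with period jitter.

    Cardiac: pulse-like waveform with recorded peak times.  Respiratory:
    raised-cosine cycles with per-cycle amplitude jitter, giving a realistic
    amplitude distribution for histogram-equalized phase assignment.
    Deterministic under a fixed seed.
    """
    if cardiac_rate_hz <= 0 or resp_rate_hz <= 0:
        raise ValueError("rates must be positive")
    rng = np.random.default_rng(seed)
    margin = 2.0 / resp_rate_hz
    t = np.arange(0.0, duration_s + margin, 1.0 / sampling_rate)

    card_peaks = _jittered_onsets(cardiac_rate_hz, rate_jitter,
                                  duration_s + margin, rng)
    phase = np.interp(t, card_peaks, np.arange(len(card_peaks)))
    frac = np.mod(phase, 1.0)
    # sharp systolic upstroke, exponential decay
    card = np.exp(-((frac - 0.15) ** 2) / (2 * 0.05**2)) + 0.3 * np.cos(
        2 * np.pi * frac)
    cardiac = PhysioTrace(samples=card, sampling_rate=sampling_rate,
                          kind="cardiac", peak_times=card_peaks)

    resp_on = _jittered_onsets(resp_rate_hz, rate_jitter, duration_s + margin,
                               rng)
    rphase = np.interp(t, resp_on, np.arange(len(resp_on)))
    cyc = np.floor(rphase).astype(int)
    amp = 1.0 + 0.15 * rng.standard_normal(cyc.max() + 1)
    resp = amp[cyc] * 0.5 * (1.0 - np.cos(2 * np.pi * np.mod(rphase, 1.0)))
    respiratory = PhysioTrace(samples=resp, sampling_rate=sampling_rate,
                              kind="respiratory", peak_times=None)
    return cardiac, respiratory


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Known activation: where it is, how strong, and the target statistics.

    ``amplitude`` is the peak signal change in percent of baseline (the
    study-scale default is ~0.71%).  ``true_lr_index`` / ``true_dv_index``
    are the laterality indices realized by the voxel mask; ``true_cog_z``
    the z center of gravity of the active voxels.
    """

    mask: np.ndarray
    amplitude: float
    true_lr_index: float
    true_dv_index: float
    true_cog_z: float
    active_compartments: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        for v in (self.true_lr_index, self.true_dv_index):
            if not (-1.0 <= v <= 1.0):
                raise ValueError("indices must lie in [-1, 1]")

    def summary(self) -> dict:
        return {
            "amplitude_pct": self.amplitude,
            "true_lr_index": self.true_lr_index,
            "true_dv_index": self.true_dv_index,
            "true_cog_z": self.true_cog_z,
            "n_active_voxels": int(self.mask.sum()),
            "active_compartments": self.active_compartments,
            "seed": self.seed,
        }


def _blob(idx: np.ndarray, n: int, center: np.ndarray,
          scale: np.ndarray) -> np.ndarray:
    d = np.linalg.norm((idx - center) * scale, axis=1)
    return idx[np.argsort(d, kind="stable")[:n]]


def make_lateralized_truth(
    atlas: CordAtlas,
    segment: str = "C6",
    lr_index: float = 0.3,
    dv_index: float = 0.0,
    n_voxels: int = 320,
    amplitude: float = 0.71,
    z_offset: float = 0.0,
    seed: int = 0,
) -> GroundTruth:
    """Construct a compact activation mask realizing target LR/DV indices.

    One contiguous blob per hemicord (sizes set by the LR target) is grown
    from a seed point inside the segment; the dorsal-ventral balance is
    steered by shifting the blob centers along y until the realized DV
    index matches the target as closely as the voxel grid allows.
    Contiguous blobs straddling the dorsal/ventral boundary mimic the
    spread of real activity better than four disjoint quadrant patches.
    """
    if segment not in atlas.masks:
        raise ValueError(f"segment {segment!r} not in atlas")
    fl = (1.0 + lr_index) / 2.0
    side_counts = {"left_hemicord": int(round(fl * n_voxels))}
    side_counts["right_hemicord"] = n_voxels - side_counts["left_hemicord"]
    scale = np.asarray(atlas.voxel_size)
    seg = atlas[segment]
    dorsal = atlas["dorsal_hemicord"]

    def realize(dy: float) -> np.ndarray:
        m = np.zeros(atlas.grid_shape, dtype=bool)
        for hemi, n in side_counts.items():
            if n == 0:
                continue
            cand = np.argwhere(atlas[hemi] & seg)
            if len(cand) < n:
                raise ValueError(
                    f"{hemi} in {segment} has {len(cand)} voxels, need {n}")
            center = cand.mean(axis=0) + np.array([0.0, dy, z_offset])
            m[tuple(_blob(cand, n, center, scale).T)] = True
        return m

    def dv_of(m: np.ndarray) -> float:
        nd = int((m & dorsal).sum())
        tot = int(m.sum())
        return (2 * nd - tot) / tot if tot else 0.0

    lo, hi = -float(atlas.grid_shape[1]), float(atlas.grid_shape[1])
    for _ in range(40):                       # dv_of is monotone in dy
        mid = 0.5 * (lo + hi)
        if dv_of(realize(mid)) < dv_index:
            lo = mid
        else:
            hi = mid
    best = min((realize(d) for d in (lo, hi, 0.5 * (lo + hi))),
               key=lambda m: abs(dv_of(m) - dv_index))
    mask = best

    n_l = int((mask & atlas["left_hemicord"]).sum())
    n_r = int((mask & atlas["right_hemicord"]).sum())
    n_d = int((mask & atlas["dorsal_hemicord"]).sum())
    n_v = int((mask & atlas["ventral_hemicord"]).sum())
    zs = np.argwhere(mask)[:, 2]
    return GroundTruth(
        mask=mask,
        amplitude=amplitude,
        true_lr_index=(n_l - n_r) / max(n_l + n_r, 1),
        true_dv_index=(n_d - n_v) / max(n_d + n_v, 1),
        true_cog_z=float(zs.mean()) if len(zs) else float("nan"),
        active_compartments=[segment],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# BOLD simulation
# ---------------------------------------------------------------------------

@dataclass
class NoiseSpec:
    """Noise amplitudes, all in percent of baseline except ``white_sd``.

    Defaults are chosen so the phantom's pre-smoothing TSNR lands near the
    mid-20s observed in cervical-cord acquisitions: baseline 100, white
    noise SD 4.  Cardiac contamination is strongest near the canal
    (``canal_boost``); drift sits above the 100 s high-pass cutoff.
    """

    white_sd: float = 4.0
    cardiac_pct: float = 1.0
    resp_pct: float = 0.5
    canal_boost: float = 3.0
    drift_pct: float = 1.0
    drift_period_s: float = 300.0
    spike_volumes: tuple[int, ...] = ()
    spike_pct: float = 5.0

    @classmethod
    def off(cls) -> "NoiseSpec":
        return cls(white_sd=0.0, cardiac_pct=0.0, resp_pct=0.0,
                   drift_pct=0.0, spike_volumes=())


@dataclass
class BOLDRun:
    """A synthetic 4D BOLD acquisition with its acquisition metadata."""

    data: np.ndarray                      # (x, y, z, t), float32
    tr: float
    slice_times: np.ndarray               # (nz,) seconds within the TR
    protocol: StimulationProtocol
    physio: tuple[PhysioTrace, PhysioTrace]
    motion_params: np.ndarray             # (t, 6)
    baseline_map: np.ndarray              # (x, y, z)
    truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        if self.data.shape[-1] != self.protocol.n_volumes:
            raise ValueError("volume count does not match the protocol")


def interleaved_slice_times(n_slices: int, tr: float) -> np.ndarray:
    """Acquisition time of each slice within the TR, interleaved order
    (even-index slices first, then odd)."""
    order = list(range(0, n_slices, 2)) + list(range(1, n_slices, 2))
    times = np.empty(n_slices)
    for pos, z in enumerate(order):
        times[z] = pos * tr / n_slices
    return times


def simulate_run(
    atlas: CordAtlas,
    protocol: StimulationProtocol,
    truth: GroundTruth,
    physio: tuple[PhysioTrace, PhysioTrace],
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    hrf: HRFSpec = HRFSpec(),
) -> BOLDRun:
    """Generate one BOLD run: baseline x (1 + task + physio + drift) + white
    noise + optional spike volumes.

    The task term is the amplitude-scaled, HRF-convolved block regressor
    (normalized to unit peak so ``(max-baseline)/baseline`` equals the
    injected fractional amplitude at the response plateau), restricted to the
    ground-truth voxels.  The physiological term is phase-locked to the
    generated traces at each voxel's slice acquisition time, with a fixed
    random phase offset per voxel and amplitude largest in and near the
    canal, so a RETROICOR basis built from the same traces can capture it.
    """
    if truth.mask.shape != atlas.grid_shape:
        raise ValueError("truth mask grid does not match atlas")
    if not np.array_equal(truth.mask & atlas["cord"], truth.mask):
        raise ValueError("truth voxels fall outside the cord")
    cardiac, resp = physio
    nx, ny, nz = atlas.grid_shape
    n_vol = protocol.n_volumes
    if cardiac.duration_s < protocol.duration_s:
        raise ValueError("physio traces shorter than the run")
    rng = np.random.default_rng(seed)

    baseline = np.full(atlas.grid_shape, 50.0, dtype=np.float64)
    baseline[atlas["cord"]] = 100.0
    baseline[atlas["canal_csf"]] = 120.0

    slice_times = interleaved_slice_times(nz, protocol.tr)
    data = np.ones((nx, ny, nz, n_vol), dtype=np.float64)

    # task term on truth voxels, evaluated at each slice's acquisition time
    ev_peak = task_regressor(protocol, hrf, sides=("left", "right")).max()
    frac = truth.amplitude / 100.0
    t_acq = (np.arange(n_vol)[None, :] * protocol.tr
             + slice_times[:, None])                          # (nz, T)
    ev_by_slice = task_regressor_at(
        protocol, t_acq.ravel(), hrf).reshape(t_acq.shape) / ev_peak
    truth_z = np.argwhere(truth.mask)[:, 2]
    data[truth.mask] += frac * ev_by_slice[truth_z]

    tissue = atlas["cord"] | atlas["canal_csf"]
    if noise.cardiac_pct > 0 or noise.resp_pct > 0:
        acq = (np.arange(n_vol)[None, :] * protocol.tr
               + slice_times[:, None])                       # (nz, T)
        phi_c = cardiac_phase_at(acq.ravel(), cardiac.peak_times
                                 ).reshape(acq.shape)
        phi_r = respiratory_phase_at(acq.ravel(), resp.samples,
                                     resp.sampling_rate).reshape(acq.shape)
        vox = np.argwhere(tissue)
        in_canal = atlas["canal_csf"][tuple(vox.T)]
        # cardiac contamination decays with distance from the canal
        from scipy.ndimage import distance_transform_edt
        depth = distance_transform_edt(
            atlas["cord"][:, :, 0], sampling=atlas.voxel_size[:2])
        w = np.exp(-depth / 2.0)
        card_amp = np.where(in_canal, noise.canal_boost,
                            w[vox[:, 0], vox[:, 1]]) * noise.cardiac_pct / 100
        resp_amp = np.full(len(vox), noise.resp_pct / 100)
        th_c = rng.uniform(0, 2 * np.pi, len(vox))
        th_r = rng.uniform(0, 2 * np.pi, len(vox))
        zi = vox[:, 2]
        physio_term = (card_amp[:, None] * np.cos(phi_c[zi] + th_c[:, None])
                       + resp_amp[:, None] * np.cos(phi_r[zi] + th_r[:, None]))
        data[tissue] += physio_term

    if noise.drift_pct > 0:
        t_vol = (np.arange(n_vol) + 0.5) * protocol.tr
        ph0 = rng.uniform(0, 2 * np.pi)
        drift = (noise.drift_pct / 100.0) * np.cos(
            2 * np.pi * t_vol / noise.drift_period_s + ph0)
        data[tissue] += drift[None, :]

    data *= baseline[..., None]
    if noise.white_sd > 0:
        data += noise.white_sd * rng.standard_normal(data.shape)
    for v in noise.spike_volumes:
        data[..., v] += (noise.spike_pct / 100.0) * baseline

    # small synthetic rigid-motion trace used only as GLM covariates;
    # stationary AR(1) so covariate power is homogeneous across trials
    eps = rng.standard_normal((n_vol, 6))
    motion = np.empty((n_vol, 6))
    motion[0] = eps[0]
    for v in range(1, n_vol):
        motion[v] = 0.9 * motion[v - 1] + eps[v]
    motion *= 0.05 / motion.std(axis=0, keepdims=True).clip(1e-9)
    return BOLDRun(
        data=data.astype(np.float32),
        tr=protocol.tr,
        slice_times=slice_times,
        protocol=protocol,
        physio=physio,
        motion_params=motion,
        baseline_map=baseline,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Between-subject distributions for a simulated cohort.

    Per subject, the activation amplitude, LR/DV laterality targets and a
    superior-inferior jitter of the activation blob are drawn from normal
    distributions with the stated means and SDs.  Defaults give a cohort of
    left-lateralized (mean LR +0.3) activations at ~0.71% signal change in
    the C6 segment, the configuration used by the recovery tests.
    """

    mean_amplitude_pct: float = 0.71
    amplitude_sd_pct: float = 0.05
    mean_lr: float = 0.3
    lr_sd: float = 0.1
    mean_dv: float = 0.0
    dv_sd: float = 0.1
    segment: str = "C6"
    n_active_voxels: int = 320
    cog_jitter_vox: float = 1.5
    noise: NoiseSpec = field(default_factory=NoiseSpec)


def _subject_seed(seed: int, subject: int, stream: int = 0) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(subject, stream))
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_cohort_subject(
    atlas: CordAtlas,
    protocol: StimulationProtocol,
    cohort: CohortSpec,
    subject: int,
    seed: int,
) -> BOLDRun:
    """Deterministically generate subject ``subject`` of a cohort.

    ``protocol`` serves as the template for timing; the left/right block
    order is re-pseudorandomized per subject (as in the study, to reduce
    order effects), so design-order idiosyncrasies decorrelate across the
    cohort.
    """
    protocol = generate_protocol(
        n_trials=protocol.n_trials, block_s=protocol.block_s,
        tr=protocol.tr, seed=_subject_seed(seed, subject, 4),
        site=protocol.site)
    rng = np.random.default_rng(_subject_seed(seed, subject, 0))
    amp = max(rng.normal(cohort.mean_amplitude_pct, cohort.amplitude_sd_pct),
              0.05)
    lr = float(np.clip(rng.normal(cohort.mean_lr, cohort.lr_sd), -0.95, 0.95))
    dv = float(np.clip(rng.normal(cohort.mean_dv, cohort.dv_sd), -0.95, 0.95))
    z_off = rng.normal(0.0, cohort.cog_jitter_vox)
    truth = make_lateralized_truth(
        atlas, segment=cohort.segment, lr_index=lr, dv_index=dv,
        n_voxels=cohort.n_active_voxels, amplitude=amp, z_offset=z_off,
        seed=_subject_seed(seed, subject, 1),
    )
    physio = simulate_physio(
        duration_s=protocol.duration_s, seed=_subject_seed(seed, subject, 2))
    return simulate_run(
        atlas, protocol, truth, physio, cohort.noise,
        seed=_subject_seed(seed, subject, 3))


def generate_cohort(
    n_subjects: int,
    out_dir,
    between_subject_spec: CohortSpec = CohortSpec(),
    seed: int = 0,
    phantom_spec: CordPhantomSpec = CordPhantomSpec(),
    protocol: StimulationProtocol | None = None,
) -> dict:
    """Write a full synthetic cohort to disk and return its manifest.

    Per subject: BOLD NIfTI, physio TSV + JSON headers, ground-truth JSON.
    Shared: atlas mask NIfTIs, protocol JSON, manifest JSON (with a content
    hash over the per-subject ground truths for regeneration checks).
    """
    import nibabel as nib

    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = build_atlas(phantom_spec)
    if protocol is None:
        protocol = generate_protocol(tr=phantom_spec.tr, seed=seed)

    atlas_dir = out / "atlas"
    atlas_dir.mkdir(exist_ok=True)
    for name, mask in atlas.masks.items():
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), atlas.affine),
                 atlas_dir / f"{name}.nii.gz")
    (out / "protocol.json").write_text(protocol.to_json())

    entries = []
    for s in range(n_subjects):
        run = simulate_cohort_subject(atlas, protocol, between_subject_spec,
                                      s, seed)
        sdir = out / f"sub-{s + 1:02d}"
        sdir.mkdir(exist_ok=True)
        nib.save(nib.Nifti1Image(run.data, atlas.affine), sdir / "bold.nii.gz")
        np.savetxt(sdir / "motion.tsv", run.motion_params, delimiter="\t")
        for trace, stem in zip(run.physio, ("cardiac", "respiratory")):
            trace.to_tsv(sdir / f"{stem}.tsv")
            (sdir / f"{stem}.json").write_text(json.dumps(trace.header()))
        np.savetxt(sdir / "cardiac_peaks.txt", run.physio[0].peak_times)
        (sdir / "truth.json").write_text(
            json.dumps(run.truth.summary(), sort_keys=True))
        entries.append({"subject": f"sub-{s + 1:02d}",
                        **run.truth.summary()})
    digest = hashlib.sha256(
        json.dumps(entries, sort_keys=True).encode()).hexdigest()
    manifest = {
        "n_subjects": n_subjects,
        "seed": seed,
        "cohort_spec": {k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in asdict(between_subject_spec).items()},
        "subjects": entries,
        "truth_hash": digest,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest
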