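"""Stimulation protocol and trialwise task design construction.

The experiment is a block design: each trial is 15 s of rest, then 15 s of
left-sided and 15 s of right-sided tactile stimulation, with the left/right
order pseudorandomized per trial.  Twenty trials at TR = 2 s give a 900 s run
of 450 volumes.  Each stimulation block is modeled as its own explanatory
variable (trialwise modeling), convolved with a gamma hemodynamic response
function with mean lag 6 s and standard deviation 3 s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StimulationProtocol",
    "HRFSpec",
    "DesignMatrix",
    "generate_protocol",
    "gamma_hrf",
    "build_design",
    "task_regressor",
]


# ---------------------------------------------------------------------------
# Protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulationProtocol:
    """Block-design stimulation protocol.

    ``order[i]`` is ``"LR"`` or ``"RL"`` and gives the side order of the two
    stimulation blocks that follow the i-th rest block.
    """

    n_trials: int = 20
    block_s: float = 15.0
    tr: float = 2.0
    order: tuple[str, ...] = ()
    site: str = "lateral_shoulder"

    def __post_init__(self) -> None:
        if len(self.order) != self.n_trials:
            raise ValueError("order must have one LR/RL flag per trial")
        if any(o not in ("LR", "RL") for o in self.order):
            raise ValueError("order flags must be 'LR' or 'RL'")

    @property
    def trial_duration_s(self) -> float:
        return 3.0 * self.block_s

    @property
    def duration_s(self) -> float:
        return self.n_trials * self.trial_duration_s

    @property
    def n_volumes(self) -> int:
        return int(round(self.duration_s / self.tr))

    def block_onsets(self, side: str) -> np.ndarray:
        """Onset times (s) of the ``side`` ('left'|'right') blocks, one per trial."""
        first = "L" if side == "left" else "R"
        onsets = []
        for i, o in enumerate(self.order):
            start = i * self.trial_duration_s + self.block_s
            onsets.append(start if o[0] == first else start + self.block_s)
        return np.asarray(onsets)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_trials": self.n_trials,
                "block_s": self.block_s,
                "tr": self.tr,
                "order": list(self.order),
                "site": self.site,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "StimulationProtocol":
        d = json.loads(text)
        return cls(
            n_trials=d["n_trials"],
            block_s=d["block_s"],
            tr=d["tr"],
            order=tuple(d["order"]),
            site=d["site"],
        )


def generate_protocol(
    n_trials: int = 20,
    block_s: float = 15.0,
    tr: float = 2.0,
    seed: int = 0,
    site: str = "lateral_shoulder",
) -> StimulationProtocol:
    """Generate a pseudorandomized, balanced protocol.

    The left/right order flags are balanced to within one trial and never
    repeat more than three times consecutively.
    """
    if block_s <= 0 or tr <= 0:
        raise ValueError("block_s and tr must be positive")
    duration = n_trials * 3.0 * block_s
    if abs(duration / tr - round(duration / tr)) > 1e-9:
        raise ValueError(
            f"run duration {duration} s is not divisible by tr={tr}")
    rng = np.random.default_rng(seed)
    n_lr = n_trials // 2 + (n_trials % 2) * int(rng.integers(2))
    while True:
        flags = ["LR"] * n_lr + ["RL"] * (n_trials - n_lr)
        rng.shuffle(flags)
        # reject runs of > 3 identical consecutive flags
        run, ok = 1, True
        for a, b in zip(flags, flags[1:]):
            run = run + 1 if a == b else 1
            if run > 3:
                ok = False
                break
        if ok:
            return StimulationProtocol(
                n_trials=n_trials, block_s=block_s, tr=tr,
                order=tuple(flags), site=site,
            )


# ---------------------------------------------------------------------------
# Hemodynamic response function
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HRFSpec:
    """Gamma HRF: phase shift, standard deviation, and mean lag (seconds).

    A gamma density with mean ``mean_lag_s`` and SD ``sd_s`` has shape
    ``(mean/sd)**2`` and scale ``sd**2/mean``; the defaults give shape 4 and
    scale 1.5 s.  The kernel is normalized to unit peak so a convolved block
    regressor plateaus at a height interpretable on the stimulus scale.
    """

    phase_s: float = 0.0
    sd_s: float = 3.0
    mean_lag_s: float = 6.0
    dt: float = 0.1

    def __post_init__(self) -> None:
        if self.sd_s <= 0 or self.mean_lag_s <= 0 or self.dt <= 0:
            raise ValueError("sd_s, mean_lag_s and dt must be positive")

    @property
    def shape(self) -> float:
        return (self.mean_lag_s / self.sd_s) ** 2

    @property
    def scale(self) -> float:
        return self.sd_s**2 / self.mean_lag_s


def gamma_hrf(spec: HRFSpec = HRFSpec()) -> np.ndarray:
    """Sampled gamma response kernel, unit peak, sampled at ``spec.dt``.

    Support is truncated at the 0.9999 quantile of the gamma distribution.
    """
    t_max = stats.gamma.ppf(0.9999, spec.shape, scale=spec.scale)
    t = np.arange(0.0, t_max + spec.phase_s + spec.dt, spec.dt)
    h = stats.gamma.pdf(t - spec.phase_s, spec.shape, scale=spec.scale)
    h[t < spec.phase_s] = 0.0
    peak = h.max()
    if peak <= 0:
        raise ValueError("degenerate HRF kernel")
    return h / peak


def _convolved_evs(
    onsets: Sequence[float], block_s: float, protocol: StimulationProtocol,
    hrf: HRFSpec,
) -> np.ndarray:
    """Convolve per-trial boxcars with the HRF, sampled at volume midpoints.

    EVs are built on a fine grid (``hrf.dt``) and decimated at volume
    midpoints ``(v + 1/2) * TR``.
    """
    dt = hrf.dt
    kernel = gamma_hrf(hrf)
    n_fine = int(round(protocol.duration_s / dt))
    t_vol = (np.arange(protocol.n_volumes) + 0.5) * protocol.tr
    idx = np.clip(np.round(t_vol / dt).astype(int), 0, n_fine - 1)
    evs = np.empty((len(onsets), protocol.n_volumes))
    for j, onset in enumerate(onsets):
        box = np.zeros(n_fine)
        i0 = int(round(onset / dt))
        i1 = min(int(round((onset + block_s) / dt)), n_fine)
        box[i0:i1] = 1.0
        conv = np.convolve(box, kernel)[:n_fine] * dt
        evs[j] = conv[idx]
    return evs


def task_regressor(
    protocol: StimulationProtocol, hrf: HRFSpec = HRFSpec(),
    sides: Sequence[str] = ("left", "right"),
) -> np.ndarray:
    """Single HRF-convolved regressor for the union of all blocks of ``sides``.

    Used by the simulator to inject activation and by percent-signal-change
    scaling (its peak height defines the effect-size unit).
    """
    onsets = np.sort(np.concatenate([protocol.block_onsets(s) for s in sides]))
    return _convolved_evs(onsets, protocol.block_s, protocol, hrf).sum(axis=0)


def trial_evs_at(
    protocol: StimulationProtocol, side: str, times: np.ndarray,
    hrf: HRFSpec = HRFSpec(),
) -> np.ndarray:
    """Per-trial convolved EVs for one side, sampled at arbitrary times.

    Supports slice-timing-aware designs where each slice's regressors are
    evaluated at its true acquisition times.
    """
    dt = hrf.dt
    kernel = gamma_hrf(hrf)
    n_fine = int(round(protocol.duration_s / dt))
    t_fine = np.arange(n_fine) * dt
    times = np.asarray(times, dtype=float)
    onsets = protocol.block_onsets(side)
    out = np.empty((len(onsets), len(times)))
    for j, onset in enumerate(onsets):
        box = np.zeros(n_fine)
        i0 = int(round(onset / dt))
        i1 = min(int(round((onset + protocol.block_s) / dt)), n_fine)
        box[i0:i1] = 1.0
        conv = np.convolve(box, kernel)[:n_fine] * dt
        out[j] = np.interp(times, t_fine, conv)
    return out


def task_regressor_at(
    protocol: StimulationProtocol, times: np.ndarray,
    hrf: HRFSpec = HRFSpec(), sides: Sequence[str] = ("left", "right"),
) -> np.ndarray:
    """Union task regressor evaluated at arbitrary acquisition times.

    Lets the simulator honor per-slice acquisition timing.
    """
    dt = hrf.dt
    kernel = gamma_hrf(hrf)
    n_fine = int(round(protocol.duration_s / dt))
    box = np.zeros(n_fine)
    for s in sides:
        for onset in protocol.block_onsets(s):
            i0 = int(round(onset / dt))
            i1 = min(int(round((onset + protocol.block_s) / dt)), n_fine)
            box[i0:i1] = 1.0
    conv = np.convolve(box, kernel)[:n_fine] * dt
    t_fine = np.arange(n_fine) * dt
    return np.interp(np.asarray(times, dtype=float), t_fine, conv)


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Trialwise design: task EVs, their temporal derivatives, and covariates.

    ``matrix`` columns are named; ``task_columns`` lists the columns carrying
    the stimulation effects (everything else is a covariate of no interest).
    """

    matrix: pd.DataFrame
    task_columns: list[str]
    volume_times: np.ndarray

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.matrix.columns if c not in self.task_columns]

    @property
    def values(self) -> np.ndarray:
        return self.matrix.to_numpy()

    def contrast_vector(self, weights: dict[str, float]) -> np.ndarray:
        c = np.zeros(self.matrix.shape[1])
        cols = list(self.matrix.columns)
        for name, w in weights.items():
            c[cols.index(name)] = w
        return c

    def to_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t", index=False, float_format="%.8g")


def build_design(
    protocol: StimulationProtocol,
    hrf: HRFSpec = HRFSpec(),
    motion_params: np.ndarray | None = None,
    outlier_flags: Sequence[int] | None = None,
    nuisance_block: np.ndarray | None = None,
    nuisance_labels: Sequence[str] | None = None,
) -> DesignMatrix:
    """Assemble the trialwise design matrix.

    Columns: one EV per left trial and per right trial (HRF-convolved
    boxcars), their temporal derivatives (finite differences), six motion
    parameters, one-hot columns for flagged outlier volumes, and any extra
    nuisance block.  Raises on rank deficiency, naming offending columns.
    """
    n_vol = protocol.n_volumes
    cols: dict[str, np.ndarray] = {}
    task_cols: list[str] = []
    for side in ("left", "right"):
        evs = _convolved_evs(protocol.block_onsets(side), protocol.block_s,
                             protocol, hrf)
        for i in range(protocol.n_trials):
            name = f"{side}_trial_{i + 1:02d}"
            if not np.any(evs[i]):
                raise ValueError(f"all-zero task column {name}")
            cols[name] = evs[i]
            task_cols.append(name)
    for name in list(task_cols):
        cols["d_" + name] = np.gradient(cols[name])
    if motion_params is not None:
        motion_params = np.asarray(motion_params, dtype=float)
        if motion_params.shape != (n_vol, 6):
            raise ValueError("motion_params must be (n_volumes, 6)")
        for j in range(6):
            cols[f"motion_{j + 1}"] = motion_params[:, j]
    for t in sorted(set(outlier_flags or ())):
        onehot = np.zeros(n_vol)
        onehot[t] = 1.0
        cols[f"outlier_{t:03d}"] = onehot
    if nuisance_block is not None:
        nuisance_block = np.atleast_2d(np.asarray(nuisance_block, dtype=float))
        if nuisance_block.shape[0] != n_vol:
            nuisance_block = nuisance_block.T
        labels = list(nuisance_labels or [])
        if not labels:
            labels = [f"nuisance_{j}" for j in range(nuisance_block.shape[1])]
        for j, lab in enumerate(labels):
            cols[lab] = nuisance_block[:, j]

    df = pd.DataFrame(cols)
    x = df.to_numpy()
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify offending columns by greedy QR-based elimination
        bad = _deficient_columns(x, list(df.columns))
        raise ValueError(f"rank-deficient design; offending columns: {bad}")
    t_vol = (np.arange(n_vol) + 0.5) * protocol.tr
    return DesignMatrix(matrix=df, task_columns=task_cols, volume_times=t_vol)


def _deficient_columns(x: np.ndarray, names: list[str]) -> list[str]:
    keep: list[int] = []
    bad: list[str] = []
    for j in range(x.shape[1]):
        trial = keep + [j]
        if np.linalg.matrix_rank(x[:, trial]) == len(trial):
            keep.append(j)
        else:
            bad.append(names[j])
    return bad
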