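"""Spatial localization statistics for spinal-cord activation maps.

Quantifies where supra-threshold activity sits in the cord: voxel counts per
compartment (hemicords, segments, gray/white matter), left-right and
dorsal-ventral laterality indices, the superior-inferior center of gravity,
the gray/white activation ratio, across-subject consistency maps, and the
nonparametric and paired tests used to compare them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

COMPARTMENTS = ("left_hemicord", "right_hemicord", "dorsal_hemicord",
                "ventral_hemicord", "C5", "C6", "C7", "gm", "wm")

__all__ = [
    "ActivationSummary",
    "ConsistencyMap",
    "compartment_counts",
    "laterality_indices",
    "cog_z",
    "gmwm_ratio",
    "gmwm_ratio_from_percent",
    "consistency_map",
    "wilcoxon_median",
    "paired_compare",
    "correlate",
    "summarize_activation",
]


# ---------------------------------------------------------------------------
# Counts and indices
# ---------------------------------------------------------------------------

def compartment_counts(active_mask: np.ndarray, atlas) -> dict[str, int]:
    """Active-voxel counts per compartment plus the cord total.

    Raises if any active voxel lies outside the cord; the partition
    identities (left+right = dorsal+ventral = gm+wm = C5+C6+C7 = total) hold
    by construction and are asserted.
    """
    active = active_mask.astype(bool)
    cord = atlas["cord"].astype(bool)
    if np.any(active & ~cord):
        raise ValueError("active voxels outside the cord mask")
    counts = {name: int((active & atlas[name]).sum()) for name in COMPARTMENTS}
    counts["total"] = int(active.sum())
    for a, b in (("left_hemicord", "right_hemicord"),
                 ("dorsal_hemicord", "ventral_hemicord"), ("gm", "wm")):
        assert counts[a] + counts[b] == counts["total"]
    assert counts["C5"] + counts["C6"] + counts["C7"] == counts["total"]
    return counts


def laterality_indices(counts: dict[str, int]) -> tuple[float, float]:
    """Left-right and dorsal-ventral laterality indices.

    LR = (left - right) / (left + right): +1.0 means all active voxels in
    the left hemicord, -1.0 all in the right.  DV likewise with dorsal
    positive.  With no active voxels the index is undefined and NaN is
    returned (such subjects are excluded from group tests).
    """
    total = counts["total"]
    if total == 0:
        logger.info("laterality_indices: no active voxels; indices undefined")
        return float("nan"), float("nan")
    lr = (counts["left_hemicord"] - counts["right_hemicord"]) / total
    dv = (counts["dorsal_hemicord"] - counts["ventral_hemicord"]) / total
    return float(lr), float(dv)


def cog_z(z_map: np.ndarray, active_mask: np.ndarray,
          weighted: bool = True) -> float:
    """Superior-inferior center of gravity of the active voxels (voxel-z).

    Z-score-weighted by default: sum(z_i * Z_i) / sum(Z_i) over active
    voxels; ``weighted=False`` gives the unweighted centroid.  Greater
    values are more superior.  Empty mask -> NaN.
    """
    active = active_mask.astype(bool)
    if not active.any():
        logger.info("cog_z: empty active mask")
        return float("nan")
    zs = np.argwhere(active)[:, 2].astype(float)
    if not weighted:
        return float(zs.mean())
    w = np.asarray(z_map)[active].astype(float)
    if np.any(w < 0):
        raise ValueError("negative weights in Z-weighted COG")
    if w.sum() <= 0:
        return float(zs.mean())
    return float((zs * w).sum() / w.sum())


def gmwm_ratio(counts: dict[str, int], atlas) -> float:
    """Ratio of percent gray-matter to percent white-matter activation.

    (gm_active / gm_total) / (wm_active / wm_total); accounts for the white
    matter being more than three times the gray-matter volume.  Undefined
    (NaN) when no white-matter voxels are active.
    """
    gm_total = int(atlas["gm"].sum())
    wm_total = int(atlas["wm"].sum())
    if gm_total == 0 or wm_total == 0:
        raise ValueError("atlas GM/WM compartments empty")
    if counts["wm"] == 0:
        logger.info("gmwm_ratio: no active WM voxels; ratio undefined")
        return float("nan")
    return gmwm_ratio_from_percent(100.0 * counts["gm"] / gm_total,
                                   100.0 * counts["wm"] / wm_total)


def gmwm_ratio_from_percent(pct_gm: float, pct_wm: float) -> float:
    """Gray/white activation ratio from the two percentages directly."""
    if pct_wm == 0:
        return float("nan")
    return pct_gm / pct_wm


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass
class ActivationSummary:
    """Per-subject, per-contrast localization summary row."""

    subject: str
    contrast: str
    counts: dict[str, int]
    lr_index: float
    dv_index: float
    cog_z: float
    gmwm_ratio: float

    def as_row(self) -> dict:
        row = {"subject": self.subject, "contrast": self.contrast,
               "lr_index": self.lr_index, "dv_index": self.dv_index,
               "cog_z": self.cog_z, "gmwm_ratio": self.gmwm_ratio}
        row.update({f"n_{k}": v for k, v in self.counts.items()})
        return row


def summarize_activation(statmap, atlas, subject: str = "",
                         z_thresh: float = 2.3,
                         weighted_cog: bool = True) -> ActivationSummary:
    """Threshold a stat map (uncorrected Z rule unless already thresholded)
    and compute the full localization summary."""
    if statmap.active is None:
        statmap = statmap.threshold(z_thresh)
    active_vol = statmap.active_mask_volume() & atlas["cord"].astype(bool)
    counts = compartment_counts(active_vol, atlas)
    lr, dv = laterality_indices(counts)
    z_vol = statmap.volume("z")
    return ActivationSummary(
        subject=subject,
        contrast=statmap.name,
        counts=counts,
        lr_index=lr,
        dv_index=dv,
        cog_z=cog_z(z_vol, active_vol, weighted=weighted_cog),
        gmwm_ratio=gmwm_ratio(counts, atlas),
    )


def summaries_to_frame(summaries: list[ActivationSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.as_row() for s in summaries])


# ---------------------------------------------------------------------------
# Consistency maps
# ---------------------------------------------------------------------------

@dataclass
class ConsistencyMap:
    """Per-voxel count of subjects whose binarized activation covers it."""

    overlap: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        if self.overlap.max(initial=0) > self.n_subjects or \
                self.overlap.min(initial=0) < 0:
            raise ValueError("overlap outside [0, n_subjects]")

    @property
    def max_overlap(self) -> int:
        return int(self.overlap.max())

    @property
    def max_location(self) -> tuple[int, ...]:
        return tuple(int(i) for i in
                     np.unravel_index(np.argmax(self.overlap),
                                      self.overlap.shape))


def consistency_map(subject_masks: list[np.ndarray]) -> ConsistencyMap:
    """Voxelwise sum of binarized subject activation masks."""
    shapes = {m.shape for m in subject_masks}
    if len(shapes) != 1:
        raise ValueError("subject masks are not on a common grid")
    overlap = np.sum([m.astype(np.int32) for m in subject_masks], axis=0)
    return ConsistencyMap(overlap=overlap, n_subjects=len(subject_masks))


# ---------------------------------------------------------------------------
# Statistical tests
# ---------------------------------------------------------------------------

def wilcoxon_median(values, h0_median: float = 0.0,
                    method: str = "auto") -> tuple[float, float]:
    """Wilcoxon signed-rank test of the median against ``h0_median``.

    NaN values (undefined indices) are dropped pairwise; exact null
    enumeration for n <= 12 without ties, normal approximation with tie and
    continuity correction otherwise.  Returns (z_statistic, two-sided p);
    the z statistic carries the sign of the shift.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)] - h0_median
    x = x[x != 0.0]
    n = len(x)
    if n == 0:
        raise ValueError("all values tie with the hypothesized median")
    if n < 5:
        raise ValueError("need at least 5 non-tied values")
    if method == "auto":
        has_rank_ties = len(np.unique(np.abs(x))) < n
        method = "exact" if (n <= 12 and not has_rank_ties) else "approx"
    res_p = stats.wilcoxon(x, alternative="two-sided", method=method,
                           correction=(method == "approx"))
    # signed normal statistic from the approximate form, its sign taken
    # from the signed-rank sum so a positive shift yields a positive z
    res_z = stats.wilcoxon(x, alternative="two-sided", method="approx",
                           correction=True)
    ranks = stats.rankdata(np.abs(x))
    t_signed = float(np.sum(np.sign(x) * ranks))
    z = float(np.copysign(abs(res_z.zstatistic), t_signed))
    return z, float(res_p.pvalue)


def paired_compare(a, b) -> tuple[float, float]:
    """Two-tailed paired t-test; returns (t, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if len(a) < 3:
        raise ValueError("need at least 3 complete pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0) and not np.allclose(d.mean(), 0):
        raise ValueError("zero variance of paired differences")
    if np.allclose(d, 0):
        return 0.0, 1.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def correlate(x, y) -> tuple[float, float]:
    """Two-tailed Pearson correlation; returns (r, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
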