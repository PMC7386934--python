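"""Prewhitened voxelwise GLM, contrasts, fixed effects and cluster inference.

Each voxel's time series is fit by ordinary least squares, an AR(1)
coefficient is estimated from the residuals, the model is refit after
whitening (one Cochrane-Orcutt iteration), and contrasts are propagated to
Z maps.  Subject- and group-level maps are inverse-variance-weighted fixed
effects.  Cluster-extent correction uses a Monte-Carlo max-cluster-extent
null with smoothness matched to the residual FWHM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .protocol import DesignMatrix

logger = logging.getLogger(__name__)

Z_THRESHOLD = 2.3          # voxelwise threshold (p < 0.01, uncorrected)
CLUSTER_ALPHA = 0.05

__all__ = [
    "GLMFit",
    "ContrastSpec",
    "StatMap",
    "fit_glm",
    "contrast_z",
    "trial_copes",
    "fixed_effects",
    "cluster_threshold",
    "estimate_smoothness",
    "percent_signal_change",
    "sign_flip_group_test",
]


# ---------------------------------------------------------------------------
# Model fit
# ---------------------------------------------------------------------------

@dataclass
class GLMFit:
    """Voxelwise prewhitened least-squares fit.

    ``betas`` is (n_columns + 1, V) -- the last row is the intercept added
    internally.  ``cov_by_bin`` maps each AR(1) bin to the whitened
    ``(X'X)^-1``; ``bin_index`` assigns every voxel to its bin.
    """

    betas: np.ndarray
    sigma2: np.ndarray
    dof: int
    ar1: np.ndarray
    column_names: list[str]
    cov_by_bin: dict[int, np.ndarray]
    bin_index: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.dof <= 0:
            raise ValueError("non-positive degrees of freedom")
        if np.any(self.sigma2 < 0):
            raise ValueError("negative residual variance")


@dataclass(frozen=True)
class ContrastSpec:
    """Named contrast over task columns; zero on covariates of no interest."""

    name: str
    weights: dict[str, float]

    @classmethod
    def side_mean(cls, side: str, n_trials: int = 20) -> "ContrastSpec":
        w = {f"{side}_trial_{i + 1:02d}": 1.0 / n_trials
             for i in range(n_trials)}
        return cls(name="L" if side == "left" else "R", weights=w)

    @classmethod
    def side_difference(cls, first: str, second: str,
                        n_trials: int = 20) -> "ContrastSpec":
        w = {f"{first}_trial_{i + 1:02d}": 1.0 / n_trials
             for i in range(n_trials)}
        w.update({f"{second}_trial_{i + 1:02d}": -1.0 / n_trials
                  for i in range(n_trials)})
        name = ("L>R" if first == "left" else "R>L")
        return cls(name=name, weights=w)


@dataclass
class StatMap:
    """Voxelwise contrast map with thresholding metadata.

    Values are stored flat over the analysis-mask voxels; ``volume()``
    scatters any field back onto the 3D grid.
    """

    z: np.ndarray
    cope: np.ndarray
    varcope: np.ndarray
    mask: np.ndarray
    name: str = ""
    z_thresh: float | None = None
    cluster_alpha: float | None = None
    correction: str = "none"
    active: np.ndarray | None = None      # flat boolean over mask voxels

    def volume(self, which: str = "z") -> np.ndarray:
        vol = np.zeros(self.mask.shape)
        vol[self.mask.astype(bool)] = getattr(self, which)
        return vol

    def active_mask_volume(self) -> np.ndarray:
        vol = np.zeros(self.mask.shape, dtype=bool)
        if self.active is not None:
            vol[self.mask.astype(bool)] = self.active
        return vol

    def threshold(self, z_thresh: float = Z_THRESHOLD) -> "StatMap":
        """Uncorrected voxelwise threshold (subject-level rule)."""
        out = StatMap(**{**self.__dict__})
        out.active = self.z > z_thresh
        out.z_thresh = z_thresh
        out.correction = "uncorrected"
        return out


def _whiten(x: np.ndarray, rho: float) -> np.ndarray:
    out = x.astype(float).copy()
    out[1:] = x[1:] - rho * x[:-1]
    out[0] = x[0] * np.sqrt(max(1.0 - rho**2, 1e-12))
    return out


def fit_glm(
    data: np.ndarray,
    design: DesignMatrix,
    mask: np.ndarray | None = None,
    ar_bin_width: float = 0.01,
    dof_loss: int = 0,
) -> GLMFit:
    """Voxelwise AR(1)-prewhitened GLM.

    ``data`` is 4D (x, y, z, t) with ``mask`` selecting analysis voxels, or
    already flat (T, V).  An intercept column is appended internally.  The
    AR(1) coefficient is estimated from OLS residuals per voxel, discretized
    into bins of width ``ar_bin_width``, and voxels sharing a bin are refit
    together under the common whitening transform.

    ``dof_loss`` counts noise dimensions already projected out of the data
    upstream (high-pass basis, pre-regressed nuisance columns); it is
    subtracted from the residual degrees of freedom so the variance estimate
    stays unbiased.
    """
    if data.ndim == 4:
        if mask is None:
            raise ValueError("mask required for 4D data")
        y = data[mask.astype(bool)].T.astype(float)        # (T, V)
    else:
        y = np.asarray(data, dtype=float)
    x = design.values
    names = list(design.matrix.columns)
    t, p = x.shape
    if y.shape[0] != t:
        raise ValueError("data/design volume mismatch")
    xc = np.column_stack([x, np.ones(t)])
    names = names + ["intercept"]
    pc = xc.shape[1]
    if np.linalg.matrix_rank(xc) < pc:
        from .protocol import _deficient_columns
        bad = _deficient_columns(xc, names)
        raise ValueError(f"rank-deficient design; offending columns: {bad}")
    if t <= pc:
        raise ValueError("fewer volumes than design columns")

    beta_ols, *_ = np.linalg.lstsq(xc, y, rcond=None)
    resid = y - xc @ beta_ols
    num = np.sum(resid[1:] * resid[:-1], axis=0)
    den = np.sum(resid**2, axis=0)
    rho = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    # OLS residuals of a design with many smooth columns carry a spurious
    # negative lag-1 autocorrelation of order p/T; subtract its exact
    # white-noise expectation tr(A.M)/tr(M) (M the residual projector, A
    # the symmetrized lag-1 shift) before whitening
    q, _ = np.linalg.qr(xc)
    bias = -np.sum(q[:-1] * q[1:]) / (t - pc)
    rho = np.clip(rho - bias, -0.95, 0.95)

    bins = np.round(rho / ar_bin_width).astype(int)
    v = y.shape[1]
    betas = np.empty((pc, v))
    sigma2 = np.empty(v)
    cov_by_bin: dict[int, np.ndarray] = {}
    dof = t - pc - dof_loss
    if dof <= 0:
        raise ValueError("no residual degrees of freedom left")
    for b in np.unique(bins):
        sel = bins == b
        r = b * ar_bin_width
        xw = _whiten(xc, r)
        yw = np.empty((t, int(sel.sum())))
        ysel = y[:, sel]
        yw[1:] = ysel[1:] - r * ysel[:-1]
        yw[0] = ysel[0] * np.sqrt(max(1.0 - r**2, 1e-12))
        bw, *_ = np.linalg.lstsq(xw, yw, rcond=None)
        rw = yw - xw @ bw
        betas[:, sel] = bw
        sigma2[sel] = np.sum(rw**2, axis=0) / dof
        cov_by_bin[b] = np.linalg.inv(xw.T @ xw)
    return GLMFit(betas=betas, sigma2=sigma2, dof=dof, ar1=rho,
                  column_names=names, cov_by_bin=cov_by_bin,
                  bin_index=bins, mask=mask)


# ---------------------------------------------------------------------------
# Contrasts
# ---------------------------------------------------------------------------

def _t_to_z(t_stat: np.ndarray, dof: int) -> np.ndarray:
    """Map t statistics to standard-normal Z preserving tail probability."""
    t_stat = np.asarray(t_stat, dtype=float)
    z = np.where(
        t_stat >= 0,
        stats.norm.isf(stats.t.sf(t_stat, dof)),
        -stats.norm.isf(stats.t.sf(-t_stat, dof)),
    )
    return np.clip(z, -40, 40)


def contrast_z(fit: GLMFit, contrast: ContrastSpec,
               mask: np.ndarray | None = None) -> StatMap:
    """Contrast estimate, variance and Z map for one contrast.

    cope = c'beta; varcope = sigma^2 * c' (Xw'Xw)^-1 c with the voxel's own
    whitening; Z via the normal transform of the t statistic at the model's
    degrees of freedom.
    """
    c = np.zeros(len(fit.column_names))
    for name, w in contrast.weights.items():
        if name not in fit.column_names:
            raise ValueError(f"contrast names unknown column {name!r}")
        c[fit.column_names.index(name)] = w
    cope = c @ fit.betas
    quad = {b: float(c @ m @ c) for b, m in fit.cov_by_bin.items()}
    cfac = np.array([quad[b] for b in fit.bin_index])
    varcope = fit.sigma2 * cfac
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(varcope > 0, cope / np.sqrt(varcope), 0.0)
    z = _t_to_z(t_stat, fit.dof)
    m = fit.mask if mask is None else mask
    if m is None:
        m = np.ones((len(cope), 1, 1), dtype=bool)  # synthetic flat grid
    return StatMap(z=z, cope=cope, varcope=varcope, mask=np.asarray(m),
                   name=contrast.name)


def trial_copes(fit: GLMFit, side: str, n_trials: int = 20,
                mask: np.ndarray | None = None) -> list[StatMap]:
    """Per-trial contrast maps for one side (unit weight on each trial EV)."""
    maps = []
    for i in range(n_trials):
        spec = ContrastSpec(name=f"{side}_trial_{i + 1:02d}",
                            weights={f"{side}_trial_{i + 1:02d}": 1.0})
        maps.append(contrast_z(fit, spec, mask=mask))
    return maps


# ---------------------------------------------------------------------------
# Fixed effects
# ---------------------------------------------------------------------------

def fixed_effects(copes: list[np.ndarray] | list[StatMap],
                  varcopes: list[np.ndarray] | None = None,
                  mask: np.ndarray | None = None,
                  name: str = "") -> StatMap:
    """Inverse-variance-weighted fixed-effects combination.

    cope* = sum(cope/var) / sum(1/var); var* = 1 / sum(1/var);
    Z = cope* / sqrt(var*), treated as standard normal.
    """
    if varcopes is None:
        statmaps = copes
        if len(statmaps) < 1:
            raise ValueError("need at least one input map")
        mask = statmaps[0].mask if mask is None else mask
        name = name or statmaps[0].name
        copes = [s.cope for s in statmaps]
        varcopes = [s.varcope for s in statmaps]
    copes = [np.asarray(c, dtype=float) for c in copes]
    varcopes = [np.asarray(v, dtype=float) for v in varcopes]
    for v in varcopes:
        if np.any(v <= 0):
            raise ValueError("zero or negative varcope input")
    w = np.stack([1.0 / v for v in varcopes])
    cstar = (np.stack(copes) * w).sum(axis=0) / w.sum(axis=0)
    vstar = 1.0 / w.sum(axis=0)
    z = cstar / np.sqrt(vstar)
    if mask is None:
        mask = np.ones((len(cstar), 1, 1), dtype=bool)
    return StatMap(z=np.clip(z, -40, 40), cope=cstar, varcope=vstar,
                   mask=np.asarray(mask), name=name)


# ---------------------------------------------------------------------------
# Cluster-extent correction
# ---------------------------------------------------------------------------

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def estimate_smoothness(resid: np.ndarray, mask: np.ndarray) -> float:
    """Estimate effective smoothness (FWHM in voxels) from residual maps.

    Classic gradient-variance estimator: for each axis the ratio of the
    variance of spatial first differences to the field variance gives the
    axis FWHM; the geometric mean over axes is returned.  ``resid`` is
    (x, y, z) or (x, y, z, n); the estimate is averaged over maps.
    """
    if resid.ndim == 3:
        resid = resid[..., None]
    m = mask.astype(bool)
    fwhms = []
    for axis in range(3):
        shifted = np.roll(m, -1, axis=axis)
        pair = m & shifted & (np.arange(m.shape[axis]) < m.shape[axis] - 1
                              ).reshape([-1 if a == axis else 1
                                         for a in range(3)])
        if pair.sum() < 10:
            continue
        d = np.diff(resid, axis=axis)
        sl = [slice(None)] * 3
        sl[axis] = slice(0, m.shape[axis] - 1)
        dm = pair[tuple(sl)]
        dvar = np.mean(d[dm] ** 2)
        var = np.mean(resid[m] ** 2)
        ratio = dvar / (2.0 * var)
        if 0 < ratio < 1:
            fwhm = np.sqrt(-2.0 * np.log(2.0) / np.log(1.0 - ratio))
            fwhms.append(min(fwhm, 10.0))
        else:
            fwhms.append(0.5)
    return float(np.exp(np.mean(np.log(np.maximum(fwhms, 1e-3))))) if fwhms \
        else 0.5


def _max_cluster_extent(z_vol: np.ndarray, mask: np.ndarray,
                        z_thresh: float) -> int:
    supra = (z_vol > z_thresh) & mask
    if not supra.any():
        return 0
    labels, n = ndimage.label(supra, structure=_STRUCT26)
    if n == 0:
        return 0
    return int(np.max(ndimage.sum_labels(supra, labels,
                                         index=np.arange(1, n + 1))))


def _smooth_null(shape: tuple, mask: np.ndarray, fwhm_vox: float,
                 rng: np.random.Generator) -> np.ndarray:
    field_ = rng.standard_normal(shape)
    if fwhm_vox > 0.1:
        sigma = fwhm_vox / np.sqrt(8 * np.log(2))
        field_ = ndimage.gaussian_filter(field_, sigma)
    sd = field_[mask].std()
    return field_ / max(sd, 1e-12)


def cluster_threshold(
    statmap: StatMap,
    z_thresh: float = Z_THRESHOLD,
    alpha: float = CLUSTER_ALPHA,
    n_null: int = 500,
    fwhm_vox: float = 1.0,
    seed: int = 0,
    statistic: str = "extent",
) -> StatMap:
    """Cluster-extent correction by Monte-Carlo max-statistic null.

    Supra-threshold 26-connected clusters are retained when their extent
    (or mass, per ``statistic``) exceeds the (1 - alpha) quantile of the
    max-cluster statistic over ``n_null`` smoothness-matched Gaussian null
    fields on the analysis mask.
    """
    if n_null < 100:
        raise ValueError("n_null < 100 gives an unstable null distribution")
    if statistic not in ("extent", "mass"):
        raise ValueError("statistic must be 'extent' or 'mass'")
    mask = statmap.mask.astype(bool)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_null)
    for i in range(n_null):
        f = _smooth_null(mask.shape, mask, fwhm_vox, rng)
        if statistic == "extent":
            null_max[i] = _max_cluster_extent(f, mask, z_thresh)
        else:
            supra = (f > z_thresh) & mask
            labels, n = ndimage.label(supra, structure=_STRUCT26)
            null_max[i] = 0 if n == 0 else np.max(
                ndimage.sum_labels(f - z_thresh, labels,
                                   index=np.arange(1, n + 1)))
    crit = np.quantile(null_max, 1.0 - alpha)

    z_vol = statmap.volume("z")
    supra = (z_vol > z_thresh) & mask
    active_vol = np.zeros_like(supra)
    labels, n = ndimage.label(supra, structure=_STRUCT26)
    for lab in range(1, n + 1):
        cl = labels == lab
        val = cl.sum() if statistic == "extent" else np.sum(
            z_vol[cl] - z_thresh)
        if val > crit:
            active_vol |= cl
    out = StatMap(z=statmap.z, cope=statmap.cope, varcope=statmap.varcope,
                  mask=statmap.mask, name=statmap.name,
                  z_thresh=z_thresh, cluster_alpha=alpha,
                  correction=f"cluster-{statistic}")
    out.active = active_vol[mask]
    logger.info("cluster_threshold[%s]: critical %s %.1f, %d active voxels",
                statmap.name, statistic, crit, int(out.active.sum()))
    return out


# ---------------------------------------------------------------------------
# Effect-size QC and group alternative
# ---------------------------------------------------------------------------

def percent_signal_change(
    cope: np.ndarray, ev_peak: float, baseline: np.ndarray,
) -> tuple[np.ndarray, int]:
    """Percent signal change: 100 * cope * EV peak height / baseline.

    ``ev_peak`` is the maximum of the (convolved) regressor the cope refers
    to, so the product is the peak modeled signal excursion.  Non-positive
    baseline voxels are excluded (returned count) and set to NaN.
    """
    baseline = np.asarray(baseline, dtype=float)
    bad = baseline <= 0
    psc = np.full(np.shape(cope), np.nan)
    ok = ~bad
    psc[ok] = 100.0 * np.asarray(cope)[ok] * ev_peak / baseline[ok]
    n_bad = int(bad.sum())
    if n_bad:
        logger.info("percent_signal_change: %d non-positive baseline voxels",
                    n_bad)
    return psc, n_bad


def sign_flip_group_test(
    copes: np.ndarray, n_perm: int = 1000, seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sample sign-flip permutation test across subjects (per voxel).

    A principled nonparametric alternative to mixed-effects group modeling:
    under the null of a symmetric zero-centered subject distribution, the
    per-subject cope signs are exchangeable.  Returns (t_map, p_map),
    two-sided, based on the max-free voxelwise permutation distribution.
    """
    copes = np.asarray(copes, dtype=float)       # (n_subjects, V)
    n = copes.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)

    def tstat(x):
        sd = x.std(axis=0, ddof=1)
        return np.divide(x.mean(axis=0), sd / np.sqrt(n),
                         out=np.zeros(x.shape[1]), where=sd > 0)

    t_obs = tstat(copes)
    count = np.ones_like(t_obs)
    for _ in range(n_perm):
        flips = rng.choice([-1.0, 1.0], size=(n, 1))
        count += np.abs(tstat(copes * flips)) >= np.abs(t_obs)
    return t_obs, count / (n_perm + 1)
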