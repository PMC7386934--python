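"""End-to-end orchestration: simulate -> design -> denoise -> GLM -> report.

The subject pipeline mirrors the study's processing order: DVARS outlier
flagging on the raw series, high-pass filtering (100 s) of data and
nuisance regressors, slice-specific RETROICOR + CSF-PCA nuisance
regression, slice-timing correction, mask-normalized smoothing (2 mm FWHM),
trialwise prewhitened GLM with motion and outlier covariates, fixed-effects
combination of the 20 trial estimates per side, and localization summaries.
Group analysis combines subject maps by fixed effects with Monte-Carlo
cluster-extent correction and tabulates the localization statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import denoise as dn
from . import glm as gl
from . import spatial as sp
from . import temporal as te
from .cordsim import BOLDRun, CordAtlas
from .protocol import HRFSpec, build_design, task_regressor

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "SubjectResult", "analyze_subject",
           "run_group", "write_subject_bundle"]


@dataclass(frozen=True)
class PipelineConfig:
    """Stage parameters; defaults are the study-scale printed values.

    TR 2 s / 450 volumes live in the protocol; here: voxelwise Z threshold
    2.3, cluster alpha 0.05, 100 s high-pass, 2 mm smoothing FWHM, 4
    physiological harmonics, 5 CSF components.
    """

    z_thresh: float = 2.3
    cluster_alpha: float = 0.05
    highpass_cutoff_s: float = 100.0
    smooth_fwhm_mm: float = 2.0
    n_harmonics: int = 4
    n_csf_components: int = 5
    n_null: int = 500
    weighted_cog: bool = True
    regress_physio: bool = True
    regress_csf: bool = True
    orthogonalize_nuisance: bool = True
    nuisance_in_glm: bool = False
    do_smooth: bool = True
    do_slice_timing: bool = True
    slice_timing_method: str = "sinc"
    cluster_statistic: str = "extent"
    seed: int = 0

    def provenance(self) -> dict:
        return {"config": asdict(self)}


@dataclass
class SubjectResult:
    """All per-subject artifacts the group stage consumes."""

    subject: str
    maps: dict                      # contrast name -> StatMap (L, R, L>R, R>L)
    summaries: list                 # ActivationSummary per contrast
    trial_series: dict              # contrast -> TrialSetSeries (L, R)
    psc: dict                       # side -> mean percent signal change
    qc: dict                        # TSNR, outliers, smoothness
    design_frame: pd.DataFrame | None = None
    trial_maps: dict | None = None  # side -> list of 20 per-trial StatMaps

    def summary_frame(self) -> pd.DataFrame:
        return sp.summaries_to_frame(self.summaries)


def _difference_map(a: gl.StatMap, b: gl.StatMap, name: str) -> gl.StatMap:
    cope = a.cope - b.cope
    var = a.varcope + b.varcope
    z = np.clip(cope / np.sqrt(var), -40, 40)
    return gl.StatMap(z=z, cope=cope, varcope=var, mask=a.mask, name=name)


def analyze_subject(
    run: BOLDRun,
    atlas: CordAtlas,
    config: PipelineConfig = PipelineConfig(),
    subject: str = "sub-01",
) -> SubjectResult:
    """Run the full subject-level pipeline on one BOLD run."""
    cord = atlas["cord"].astype(bool)
    canal = atlas["canal_csf"].astype(bool)
    protocol = run.protocol
    t = protocol.n_volumes

    # --- outlier detection on the raw series -------------------------------
    flags, _, dvars = dn.dvars_outliers(run.data, cord)
    logger.info("%s: %d DVARS outlier volumes", subject, len(flags))

    # --- QC before denoising ----------------------------------------------
    _, tsnr_raw, _ = dn.tsnr_map(run.data, cord)

    # --- design (built early: the task subspace is protected during
    # nuisance regression, and every column gets the data's high-pass) -----
    design = build_design(protocol, HRFSpec(),
                          motion_params=run.motion_params,
                          outlier_flags=flags.tolist())
    design.matrix.iloc[:, :] = dn.highpass(
        design.matrix.to_numpy(), config.highpass_cutoff_s, protocol.tr)
    task_block = design.matrix[
        [c for c in design.matrix.columns
         if c in design.task_columns or c.startswith("d_")]].to_numpy()

    # --- nuisance construction --------------------------------------------
    data = run.data.astype(np.float32)
    analysis = cord | canal
    data_hp = dn.highpass(
        np.moveaxis(data, -1, 0), config.highpass_cutoff_s, protocol.tr)
    data_hp = np.moveaxis(data_hp, 0, -1).astype(np.float32)
    n_hp = dn.dct_highpass_basis(t, protocol.tr,
                                 config.highpass_cutoff_s).shape[1]
    dof_loss = n_hp

    nuis = None
    if config.regress_physio or config.regress_csf:
        blocks = []
        nz = atlas.grid_shape[2]
        if config.regress_physio:
            phases = dn.assign_phases(run.physio[0], run.physio[1],
                                      run.slice_times, protocol.tr, t)
            physio_block, _ = dn.physio_basis(phases)
        else:
            physio_block = np.zeros((nz, t, 0))
        if config.regress_csf:
            csf_block, _ = dn.csf_pca(run.data, canal,
                                      config.n_csf_components)
        else:
            csf_block = np.zeros((nz, t, 0))
        nuis = dn.NuisanceSet(
            physio_block=dn.highpass(
                np.moveaxis(physio_block, 1, 0), config.highpass_cutoff_s,
                protocol.tr).transpose(1, 0, 2)
            if physio_block.shape[-1] else physio_block,
            csf_block=dn.highpass(
                np.moveaxis(csf_block, 1, 0), config.highpass_cutoff_s,
                protocol.tr).transpose(1, 0, 2)
            if csf_block.shape[-1] else csf_block,
        )
        if config.nuisance_in_glm:
            denoised = data_hp       # nuisance enters the GLM design instead
        else:
            denoised = dn.regress_nuisance(
                data_hp, nuis, mask=analysis,
                protect=task_block if config.orthogonalize_nuisance else None)
            dof_loss += nuis.physio_block.shape[-1] + nuis.csf_block.shape[-1]
    else:
        denoised = data_hp

    if config.do_slice_timing and not config.nuisance_in_glm:
        # in the joint-GLM path the design is evaluated at each slice's own
        # acquisition times instead of resampling the data
        denoised = dn.slice_timing_correct(denoised, run.slice_times,
                                           protocol.tr,
                                           method=config.slice_timing_method)
    if config.do_smooth:
        denoised = dn.smooth(denoised, cord, config.smooth_fwhm_mm,
                             atlas.voxel_size)
    _, tsnr_final, _ = dn.tsnr_map(denoised, cord)

    # --- GLM ---------------------------------------------------------------
    if config.nuisance_in_glm and nuis is not None:
        trial_maps, resid_fwhm = _fit_slicewise(
            denoised, cord, design, nuis, protocol, dof_loss,
            run.slice_times, config.highpass_cutoff_s)
    else:
        fit = gl.fit_glm(denoised, design, mask=cord, dof_loss=dof_loss)
        # residual smoothness for the group-level cluster null
        resid_fwhm = _residual_smoothness(denoised, cord, fit, design)
        trial_maps = {side: gl.trial_copes(fit, side, protocol.n_trials, cord)
                      for side in ("left", "right")}
    # subject-level side maps: inverse-variance fixed effects over the 20
    # trial estimates, the same operator as the group level.  Note this
    # treats the trial copes as independent although they come from one
    # fit; the exact mean-of-trials contrast is available via
    # ContrastSpec.side_mean for calibration studies.
    map_l = gl.fixed_effects(trial_maps["left"], name="L")
    map_r = gl.fixed_effects(trial_maps["right"], name="R")
    maps = {
        "L": map_l,
        "R": map_r,
        "L>R": _difference_map(map_l, map_r, "L>R"),
        "R>L": _difference_map(map_r, map_l, "R>L"),
    }

    summaries = [
        sp.summarize_activation(m, atlas, subject=subject,
                                z_thresh=config.z_thresh,
                                weighted_cog=config.weighted_cog)
        for m in maps.values()
    ]

    # --- percent signal change over active voxels --------------------------
    ev_peak = float(task_regressor(protocol).max())
    baseline = denoised.mean(axis=-1)[cord]
    psc = {}
    for side, m in (("left", map_l), ("right", map_r)):
        psc_vox, _ = gl.percent_signal_change(m.cope, ev_peak, baseline)
        active = m.z > config.z_thresh
        psc[side] = float(np.nanmean(psc_vox[active])) if active.any() \
            else float("nan")

    if protocol.n_trials == te.N_SETS * te.TRIALS_PER_SET:
        trial_series = {
            name: te.trial_sets(trial_maps[side], config.z_thresh,
                                subject=subject, contrast=name)
            for side, name in (("left", "L"), ("right", "R"))
        }
    else:
        logger.info("%s: %d trials, skipping five-set temporal analysis",
                    subject, protocol.n_trials)
        trial_series = {}

    qc = {
        "tsnr_raw": tsnr_raw,
        "tsnr_final": tsnr_final,
        "n_outliers": int(len(flags)),
        "outlier_volumes": [int(f) for f in flags],
        "max_dvars": float(dvars.max()),
        "residual_fwhm_vox": resid_fwhm,
        "mean_abs_motion_mm": float(np.abs(run.motion_params[:, :3]).mean()),
    }
    return SubjectResult(subject=subject, maps=maps, summaries=summaries,
                         trial_series=trial_series, psc=psc, qc=qc,
                         design_frame=design.matrix, trial_maps=trial_maps)


def _fit_slicewise(
    denoised: np.ndarray, cord: np.ndarray, design, nuis,
    protocol, dof_loss: int, slice_times: np.ndarray, cutoff_s: float,
    n_resid_samples: int = 10,
) -> tuple[dict, float]:
    """Joint task + slice-nuisance GLM, fit slice by slice.

    Alternative to pre-regressing the nuisance set: each slice's voxels are
    fit with a slice-timing-aware task design (EVs evaluated at the slice's
    true acquisition times) extended by that slice's nuisance columns, so
    task and physiological variance are attributed jointly and task betas
    are unbiased.  Returns per-side trial StatMap lists (full cord-voxel
    length) and the residual-smoothness estimate.
    """
    from .protocol import DesignMatrix, trial_evs_at

    coords = np.argwhere(cord)
    v_total = len(coords)
    t = denoised.shape[-1]
    n_tr = protocol.n_trials
    y_all = denoised[cord]                       # (V, T)
    sides = ("left", "right")
    copes = {s: np.zeros((n_tr, v_total)) for s in sides}
    varcs = {s: np.zeros((n_tr, v_total)) for s in sides}
    resid_idx = np.linspace(0, t - 1, n_resid_samples).astype(int)
    resid_vols = np.zeros(cord.shape + (n_resid_samples,))
    covar_cols = [c for c in design.matrix.columns
                  if c not in design.task_columns
                  and not c.startswith("d_")]
    for z in np.unique(coords[:, 2]):
        sel = coords[:, 2] == z
        y = y_all[sel].T.astype(float)
        acq = np.arange(t) * protocol.tr + slice_times[int(z)]
        cols: dict[str, np.ndarray] = {}
        for side in sides:
            evs = trial_evs_at(protocol, side, acq)
            for i in range(n_tr):
                cols[f"{side}_trial_{i + 1:02d}"] = evs[i]
        for name in list(cols):
            cols["d_" + name] = np.gradient(cols[name])
        task_block = dn.highpass(np.column_stack(list(cols.values())),
                                 cutoff_s, protocol.tr)
        ext = pd.DataFrame(task_block, columns=list(cols))
        for c in covar_cols:
            ext[c] = design.matrix[c].to_numpy()
        block = nuis.slice_design(int(z))
        # drop nuisance columns with no post-filter content (aliased
        # harmonics can collapse to near-constants killed by the high-pass)
        norms = np.linalg.norm(block - block.mean(axis=0), axis=0)
        block = block[:, norms > 1e-6 * max(norms.max(), 1.0)]
        for j in range(block.shape[1]):
            ext[f"slice_nuis_{j}"] = block[:, j]
        dm = DesignMatrix(matrix=ext, task_columns=design.task_columns,
                          volume_times=design.volume_times)
        fit = gl.fit_glm(y, dm, dof_loss=dof_loss)
        for side in sides:
            for i, m in enumerate(gl.trial_copes(fit, side, n_tr)):
                copes[side][i, sel] = m.cope
                varcs[side][i, sel] = m.varcope
        x = np.column_stack([dm.values, np.ones(t)])
        res = y - x @ fit.betas
        vol_sel = tuple(coords[sel].T)
        for j, ti in enumerate(resid_idx):
            resid_vols[..., j][vol_sel] = res[ti]
    trial_maps = {
        side: [gl.StatMap(
            z=np.divide(copes[side][i], np.sqrt(varcs[side][i]),
                        out=np.zeros(v_total),
                        where=varcs[side][i] > 0),
            cope=copes[side][i], varcope=varcs[side][i], mask=cord,
            name=f"{side}_trial_{i + 1:02d}")
            for i in range(n_tr)]
        for side in sides
    }
    return trial_maps, gl.estimate_smoothness(resid_vols, cord)


def _residual_smoothness(data: np.ndarray, mask: np.ndarray, fit,
                         design, n_samples: int = 10) -> float:
    """Spatial FWHM (voxels) of GLM residuals at a few sampled time points."""
    x = np.column_stack([design.values, np.ones(design.values.shape[0])])
    y = data[mask].T
    resid = y - x @ fit.betas
    idx = np.linspace(0, resid.shape[0] - 1, n_samples).astype(int)
    vols = np.zeros(mask.shape + (n_samples,))
    for j, i in enumerate(idx):
        v = np.zeros(mask.shape)
        v[mask] = resid[i]
        vols[..., j] = v
    return gl.estimate_smoothness(vols, mask)


# ---------------------------------------------------------------------------
# Group level
# ---------------------------------------------------------------------------

def run_group(
    results: list[SubjectResult],
    atlas: CordAtlas,
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """Group fixed-effects maps, localization tables, consistency, trend.

    Returns a report dict: per-contrast cluster-corrected group summaries
    (counts, GM/WM block as in a group localization table), subject-level
    index statistics (median, IQR, Wilcoxon vs 0; GM/WM ratio vs 1),
    consistency-map maxima, and the linear trend test.
    """
    if len(results) < 2:
        raise ValueError("group analysis needs at least 2 subjects")
    cord = atlas["cord"].astype(bool)
    fwhm = float(np.mean([r.qc["residual_fwhm_vox"] for r in results]))
    report: dict = {"n_subjects": len(results),
                    "residual_fwhm_vox": fwhm,
                    "contrasts": {}}
    group_maps = {}
    for name in ("L", "R", "L>R", "R>L"):
        g = gl.fixed_effects([r.maps[name] for r in results], name=name)
        g = gl.cluster_threshold(
            g, z_thresh=config.z_thresh, alpha=config.cluster_alpha,
            n_null=config.n_null, fwhm_vox=fwhm, seed=config.seed,
            statistic=config.cluster_statistic)
        group_maps[name] = g
        summ = sp.summarize_activation(g, atlas, subject="group",
                                       z_thresh=config.z_thresh,
                                       weighted_cog=config.weighted_cog)
        counts = summ.counts
        gm_total, wm_total = int(atlas["gm"].sum()), int(atlas["wm"].sum())
        entry = {
            "n_active": counts["total"],
            "mean_z": float(g.z[g.active].mean()) if g.active.any() else 0.0,
            "counts": counts,
            "lr_index": summ.lr_index,
            "dv_index": summ.dv_index,
            "cog_z": summ.cog_z,
            "pct_gm": 100.0 * counts["gm"] / gm_total,
            "pct_wm": 100.0 * counts["wm"] / wm_total,
            "gmwm_ratio": summ.gmwm_ratio,
        }
        # subject-level index statistics (Wilcoxon vs 0; ratio vs 1)
        subj = [next(s for s in r.summaries if s.contrast == name)
                for r in results]
        lr = np.array([s.lr_index for s in subj])
        dv = np.array([s.dv_index for s in subj])
        ratios = np.array([s.gmwm_ratio for s in subj])
        entry["subject_level"] = {
            "n_lr_positive": int(np.nansum(lr > 0)),
            "median_lr": float(np.nanmedian(lr)),
            "iqr_lr": float(np.nanpercentile(lr, 75)
                            - np.nanpercentile(lr, 25)),
            "median_dv": float(np.nanmedian(dv)),
            "median_gmwm": float(np.nanmedian(ratios)),
            "median_cog_z": float(np.nanmedian([s.cog_z for s in subj])),
        }
        for label, vals, h0 in (("lr", lr, 0.0), ("dv", dv, 0.0),
                                ("gmwm", ratios, 1.0)):
            try:
                z, p = sp.wilcoxon_median(vals, h0)
                entry["subject_level"][f"wilcoxon_{label}_z"] = z
                entry["subject_level"][f"wilcoxon_{label}_p"] = p
            except ValueError as e:
                entry["subject_level"][f"wilcoxon_{label}_p"] = None
                logger.info("wilcoxon %s (%s): %s", label, name, e)
        cmap = sp.consistency_map(
            [r.maps[name].threshold(config.z_thresh).active_mask_volume()
             for r in results])
        entry["consistency_max"] = cmap.max_overlap
        entry["consistency_max_location"] = list(cmap.max_location)
        report["contrasts"][name] = entry

    report["trend"] = {}
    if all(r.trial_series for r in results):
        for name in ("L", "R"):
            trend = te.linear_trend([r.trial_series[name] for r in results],
                                    field="n_active")
            report["trend"][name] = {
                "t": trend.t_stat, "p": trend.p_value,
                "significant": bool(trend.significant),
            }
    report["mean_psc"] = {
        side: float(np.nanmean([r.psc[side] for r in results]))
        for side in ("left", "right")
    }
    report["group_maps"] = group_maps
    report["provenance"] = config.provenance()
    return report


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_subject_bundle(result: SubjectResult, atlas: CordAtlas,
                         out_dir) -> None:
    """Write the per-subject artifacts: design TSV, summaries TSV, Z-map
    NIfTIs, and the QC report JSON."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if result.design_frame is not None:
        result.design_frame.to_csv(out / "design.tsv", sep="\t", index=False,
                                   float_format="%.8g")
    result.summary_frame().to_csv(out / "activation_summary.tsv", sep="\t",
                                  index=False)
    for name, m in result.maps.items():
        safe = name.replace(">", "_gt_")
        nib.save(nib.Nifti1Image(m.volume("z").astype(np.float32),
                                 atlas.affine),
                 out / f"zmap_{safe}.nii.gz")
    if result.trial_series:
        pd.concat([s.as_frame() for s in result.trial_series.values()]
                  ).to_csv(out / "trial_sets.tsv", sep="\t", index=False)
    (out / "qc.json").write_text(json.dumps(
        {**result.qc, "psc": result.psc}, indent=2, sort_keys=True))


def write_group_report(report: dict, atlas: CordAtlas, out_dir) -> None:
    """Write group JSON report and cluster-corrected Z/active-mask NIfTIs."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    maps = report.pop("group_maps", {})
    for name, m in maps.items():
        safe = name.replace(">", "_gt_")
        nib.save(nib.Nifti1Image(m.volume("z").astype(np.float32),
                                 atlas.affine),
                 out / f"group_zmap_{safe}.nii.gz")
        nib.save(nib.Nifti1Image(
            m.active_mask_volume().astype(np.uint8), atlas.affine),
            out / f"group_active_{safe}.nii.gz")
    (out / "group_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=float))
    report["group_maps"] = maps
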