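"""End-to-end orchestration: simulate -> register -> segment -> volumes ->
rates -> stats, with per-stage caching and a report generator.

The longitudinal scheme is deliberately baseline-anchored: one nonlinear
warp is fitted on the baseline session and reapplied to all four images
(T1/T2 at baseline and follow-up), with the follow-up session first mapped
onto baseline via a rigid transform.  This is the classic two-timepoint
design; it is asymmetry-bias-prone (the follow-up images undergo one more
interpolation) and documented as such in the methods note.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_stats import AncovaSpec, fit_rate_ancova
from .image import BrainImage
from .morphometry import (
    annualized_rates,
    integrate_volumes,
    modulate,
    smooth,
    years_between,
)
from .phantom import (
    DEFAULT_CONTRAST,
    HIPPO_L,
    HIPPO_R,
    CohortDesign,
    PhantomTemplate,
    build_phantom_template,
    generate_cohort,
)
from .registration import (
    DCTWarp,
    RigidTransform,
    TransformChain,
    apply_chain,
    dct_normalize,
    jacobian_map,
    rigid_align,
)
from .segmentation import (
    IntracranialMasks,
    PriorSet,
    compute_intracranial,
    estimate_tissue_fractions,
    fit_intensity_model,
    optimized_csf,
    segment_tissues,
)

__all__ = ["PipelineConfig", "process_subject_pair", "run_pipeline", "write_report"]


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, with every default materialized."""

    out_dir: str = "longvbm_run"
    design: CohortDesign = field(default_factory=CohortDesign)
    template_shape: tuple = (48, 48, 48)
    template_voxel_mm: float = 1.0
    n_parcels: int = 12
    dct_k: int = 8
    reg_weight: float = 1e6
    dct_max_iter: int = 24
    dct_levels: int = 2
    rigid_levels: int = 2
    fwhm_mm: float = 12.0
    icv_threshold: float = 0.5
    alpha: float = 0.05
    fwe_mode: str = "permutation"
    n_perm: int = 500
    seed: int = 0
    # phantom T1/T2 pairs are synthesized on a shared grid per session, so
    # within-session coregistration can be skipped; set False to run it
    assume_within_session_coregistered: bool = True
    make_rate_maps: bool = False
    # fixed-point passes subtracting measured anatomical change from the
    # session bias-ratio fit (removes the atrophy leak to second order)
    bias_refine_passes: int = 1
    baseline_bias_correction: bool = False
    # probabilistic-ROI softening compensating interpolation point-spread
    roi_soft_fwhm_mm: float = 1.5

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_json(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _poly_basis_points(points: np.ndarray, extent: np.ndarray) -> np.ndarray:
    """Quadratic monomial basis at world points, coords normalized by extent."""
    x, y, z = (points[..., i].ravel() / extent[i] for i in range(3))
    one = np.ones_like(x)
    return np.stack([one, x, y, z, x * y, x * z, y * z, x * x, y * y, z * z], axis=1)


def remove_session_bias(
    img: BrainImage,
    priors: PriorSet,
    class_params: dict,
    channel: int,
    min_pred: float = 0.1,
) -> BrainImage:
    """Estimate and divide out one session's smooth multiplicative bias.

    The intensity model predicts each voxel as the prior-fraction mixture
    of class means, so the log of observed/predicted over the brain is the
    bias field plus noise and anatomy misfit; a quadratic polynomial fitted
    to block-aggregated ratios captures the smooth bias.  Valid where the
    priors describe the session's anatomy (the baseline of a longitudinal
    pair); the other session is then matched to the corrected baseline.
    """
    mu = np.asarray(class_params["mu"], dtype=float)
    bg = np.clip(1 - priors.gm.data - priors.wm.data - priors.csf.data, 0, 1)
    pred = (mu[0, channel] * priors.gm.data + mu[1, channel] * priors.wm.data
            + mu[2, channel] * priors.csf.data + mu[3, channel] * bg
            ).astype(np.float64)
    y = img.data.astype(np.float64).ravel()
    sel = (pred.ravel() > min_pred) & (y > min_pred / 2)
    if sel.sum() < 200:
        return img
    idx3 = np.stack(np.unravel_index(np.flatnonzero(sel), img.shape), axis=1)
    bs = 6
    block_id = (
        (idx3[:, 0] // bs) * 10000 + (idx3[:, 1] // bs) * 100 + idx3[:, 2] // bs
    )
    _, inv = np.unique(block_id, return_inverse=True)
    ysum = np.bincount(inv, weights=y[sel])
    psum = np.bincount(inv, weights=pred.ravel()[sel])
    cnt = np.bincount(inv)
    pts = img.world_coords().reshape(-1, 3)[sel]
    cx = np.stack(
        [np.bincount(inv, weights=pts[:, i]) / cnt for i in range(3)], axis=1
    )
    ok = cnt >= 10
    if ok.sum() < 12:
        return img
    ext = np.abs(img.world_coords().reshape(-1, 3)).max(axis=0)
    ext[ext == 0] = 1.0
    P = _poly_basis_points(cx[ok], ext)
    logr = np.log(ysum[ok] / psum[ok])
    w = np.sqrt(cnt[ok])
    coef, *_ = np.linalg.lstsq(P * w[:, None], logr * w, rcond=None)
    field = np.exp(
        _poly_basis_points(img.world_coords().reshape(-1, 3), ext) @ coef
    ).reshape(img.shape)
    return img.like(img.data / field)


def match_session_bias(
    follow: BrainImage,
    base: BrainImage,
    rigid: RigidTransform,
    priors: PriorSet,
    known_change: BrainImage | None = None,
    stable_purity: float = 0.98,
    min_intensity: float = 0.1,
) -> BrainImage:
    """Flatten the follow-up session onto the baseline's bias field.

    Scanner bias differs between sessions; left uncorrected it corrupts
    longitudinal tissue-fraction differences and displaces same-contrast
    registration optima.  The two sessions are compared in the halfway
    frame (symmetric interpolation), the log intensity ratio is aggregated
    over blocks of longitudinally stable voxels (prior-pure WM and the CSF
    rim) and fitted as a low-order polynomial, which is then divided out
    of the follow-up image in its own frame.  The baseline's own bias, now
    shared by both sessions, cancels in the longitudinal rate difference.

    Stable rim voxels still carry a small GM-prior tail whose genuine
    atrophy leaks into the fit and rescales measured rates.
    ``known_change`` — a baseline-frame map of the anticipated
    log-intensity ratio due to true anatomical change, available after a
    first measurement pass — is subtracted from the observed ratio before
    fitting, removing that leak to second order (fixed-point refinement).
    """
    from .registration import apply_chain

    # Compare the sessions in the halfway frame: each image is resampled
    # exactly once through a half-magnitude transform, so both sides of the
    # ratio carry identical interpolation smoothing.  Resampling only one
    # side would dim thin structures (the CSF rim) on that side alone and
    # the fit would misread it as a bias gradient.
    from scipy.spatial.transform import Rotation as _Rot

    rv = _Rot.from_euler("xyz", rigid.rotations).as_rotvec()
    R_h = _Rot.from_rotvec(0.5 * rv).as_matrix()
    t_h = np.linalg.solve(np.eye(3) + R_h, rigid.translations)
    half = RigidTransform(_Rot.from_matrix(R_h).as_euler("xyz"), t_h)
    f_img = apply_chain(follow, half, "spline-3", target=base)
    b_img = apply_chain(base, half.inverse(), "spline-3", target=base)
    wm_m = apply_chain(priors.wm, half.inverse(), "nearest", target=base).data
    csf_m = apply_chain(priors.csf, half.inverse(), "nearest", target=base).data
    gm_near = apply_chain(
        smooth(priors.gm, 3.0), half.inverse(), "trilinear", target=base
    ).data
    chg = None
    if known_change is not None:
        chg = apply_chain(
            known_change, half.inverse(), "trilinear", target=base
        ).data.astype(np.float64).ravel()
    # deep WM voxels must keep a buffer from any GM structure: atrophy
    # signal spreads about a voxel beyond GM borders (interpolation), and
    # a hippocampus-adjacent WM block would tilt the whole fitted field.
    # The CSF-rim component keeps the periphery supported.
    stable = ((wm_m >= stable_purity) & (gm_near <= 0.02)) | (
        csf_m >= 0.9 * float(priors.csf.data.max())
    )
    f = f_img.data.astype(np.float64).ravel()
    b = b_img.data.astype(np.float64).ravel()
    sel = stable.ravel() & (b > min_intensity) & (f > min_intensity)
    if sel.sum() < 50:
        return follow  # not enough stable support; leave uncorrected
    # aggregate stable voxels into spatial blocks and fit the log-ratio of
    # block SUMS: per-voxel log-ratios of noisy intensities carry a Jensen
    # bias (the resampled follow-up is smoother than the native baseline)
    # that the ill-conditioned unmixing would amplify; block sums are
    # effectively noise-free
    shape = np.asarray(base.shape)
    bs = 6  # block edge, voxels
    idx3 = np.stack(np.unravel_index(np.flatnonzero(sel), base.shape), axis=1)
    block_id = (
        (idx3[:, 0] // bs) * 10000 + (idx3[:, 1] // bs) * 100 + idx3[:, 2] // bs
    )
    uniq, inv = np.unique(block_id, return_inverse=True)
    fsum = np.bincount(inv, weights=f[sel])
    bsum = np.bincount(inv, weights=b[sel])
    cnt = np.bincount(inv)
    pts_sel = base.world_coords().reshape(-1, 3)[sel]
    cx = np.stack(
        [np.bincount(inv, weights=pts_sel[:, i]) / cnt for i in range(3)], axis=1
    )
    ok = cnt >= 10
    if ok.sum() < 12:
        return follow
    ext = np.abs(base.world_coords().reshape(-1, 3)).max(axis=0)
    ext[ext == 0] = 1.0
    P = _poly_basis_points(cx[ok], ext)
    logr = np.log(fsum[ok] / bsum[ok])
    if chg is not None:
        # remove the anticipated anatomical-change component (b-weighted
        # block mean) so only scanner bias remains in the fitted ratio
        csum = np.bincount(inv, weights=(chg * b)[sel])
        logr = logr - (csum / np.maximum(bsum, 1e-12))[ok]
    w = np.sqrt(cnt[ok])
    coef, *_ = np.linalg.lstsq(P * w[:, None], logr * w, rcond=None)
    # evaluate the fitted log-ratio at the follow-frame voxel positions:
    # voxel x of the follow frame sits at half^-1(x) in the halfway frame
    pts_follow = follow.world_coords().reshape(-1, 3)
    pts_mid = half.inverse().apply(pts_follow)
    ratio = np.exp(
        _poly_basis_points(pts_mid, ext) @ coef
    ).reshape(follow.shape)
    return follow.like(follow.data / ratio)


def process_subject_pair(
    t1b: BrainImage,
    t2b: BrainImage,
    t1f: BrainImage,
    t2f: BrainImage,
    priors: PriorSet,
    parcellation: BrainImage,
    config: PipelineConfig | None = None,
    subject_id: str = "",
    date_baseline: str | None = None,
    date_followup: str | None = None,
):
    """Full single-subject chain; returns (vol_base, vol_follow, rates, info).

    Stages: (optional) within-session T2->T1 rigid alignment, inter-session
    T1 rigid alignment, mono-spectral segmentation of the baseline T1,
    nonlinear normalization of its GM map to the GM prior, reapplication of
    the single warp to all four images, per-session mono- and multi-spectral
    segmentation in template space, common intracranial intersection and
    optimized CSF, Jacobian modulation, and volume/rate integration.
    """
    cfg = config or PipelineConfig()
    info: dict = {}

    if not cfg.assume_within_session_coregistered:
        # cross-contrast alignments (pull-backs resampling T2 onto T1 grids)
        r_t2b = rigid_align(t2b, t1b, cost="nmi", levels=cfg.rigid_levels)
        t2b = apply_chain(t2b, r_t2b, "spline-3", target=t1b)
        r_t2f = rigid_align(t2f, t1f, cost="nmi", levels=cfg.rigid_levels)
        t2f = apply_chain(t2f, r_t2f, "spline-3", target=t1f)
        info["t2_alignments"] = [r_t2b, r_t2f]

    # The head position at baseline is arbitrary, so the template priors
    # are first brought into the baseline frame by a rigid fit of the
    # baseline T1 against a synthetic template T1 (priors mixed with
    # nominal class contrasts); the joint log-bias field absorbs scanner
    # bias and any global contrast scale.
    tpl_t1 = priors.gm.like(
        DEFAULT_CONTRAST["t1"]["gm"] * priors.gm.data
        + DEFAULT_CONTRAST["t1"]["wm"] * priors.wm.data
        + DEFAULT_CONTRAST["t1"]["csf"] * priors.csf.data
        + DEFAULT_CONTRAST["t1"]["bg"]
        * np.clip(1 - priors.gm.data - priors.wm.data - priors.csf.data, 0, 1)
    )
    rigid_b = rigid_align(
        t1b, tpl_t1, cost="ssd", levels=cfg.rigid_levels, bias_poly=True
    )
    info["rigid_base_to_template"] = rigid_b
    priors_native = PriorSet(
        *(apply_chain(priors.as_dict()[t], rigid_b, "trilinear")
          for t in ("gm", "wm", "csf")),
        subsample=priors.subsample,
    )

    # The baseline's own smooth bias is estimable because the priors
    # describe its anatomy; removing it (densely supported fit) stops
    # local bias from corrupting the ill-conditioned unmixing.
    if cfg.baseline_bias_correction:
        model0 = fit_intensity_model([t1b, t2b], priors_native)
        t1b = remove_session_bias(t1b, priors_native, model0, 0)
        t2b = remove_session_bias(t2b, priors_native, model0, 1)

    # The intensity model (class means per channel) is calibrated once, on
    # the (corrected) baseline session in native space, and reused
    # everywhere: class means are space-invariant, and holding them fixed
    # across sessions prevents longitudinal change being absorbed into
    # the means.
    intensity_model = fit_intensity_model([t1b, t2b], priors_native)
    info["intensity_model"] = intensity_model

    # inter-session T1 alignment with a jointly estimated log-bias ratio
    # field (session bias displaces a plain SSD optimum by degrees), then
    # bias-ratio matching of the sessions on longitudinally stable tissue
    rigid = rigid_align(
        t1f, t1b, cost="ssd", levels=cfg.rigid_levels, bias_poly=True
    )
    info["rigid_follow_to_base"] = rigid

    frac_native = estimate_tissue_fractions([t1b, t2b], priors_native, intensity_model)

    # One warp per subject, fitted on the baseline GM map and reapplied to
    # all four images.  The GM fraction map is used as the source: its
    # partial-volume profile matches the soft prior, unlike the saturated
    # EM posterior.
    warp = dct_normalize(
        frac_native.gm, priors.gm, K=cfg.dct_k,
        regularization_weight=cfg.reg_weight,
        levels=cfg.dct_levels, max_iter=cfg.dct_max_iter,
    )
    info["warp"] = warp

    chain_base = TransformChain([warp])
    chain_follow = TransformChain([warp, rigid])
    nt1b = apply_chain(t1b, chain_base, "spline-3")
    nt2b = apply_chain(t2b, chain_base, "spline-3")
    frac_b = estimate_tissue_fractions([nt1b, nt2b], priors, intensity_model)
    multi_b = segment_tissues([nt1b, nt2b], priors, mode="multi")

    mu = np.asarray(intensity_model["mu"], dtype=float)
    t1f_raw, t2f_raw = t1f, t2f
    known = [None, None]  # per-channel anticipated log-ratio maps
    for it in range(1 + max(0, cfg.bias_refine_passes)):
        # bias-ratio matching of the sessions on longitudinally stable
        # tissue; on refinement passes the previously measured anatomical
        # change is subtracted from the fitted ratio
        t1f = match_session_bias(t1f_raw, t1b, rigid, priors_native, known[0])
        t2f = match_session_bias(t2f_raw, t2b, rigid, priors_native, known[1])
        nt1f = apply_chain(t1f, chain_follow, "spline-3")
        nt2f = apply_chain(t2f, chain_follow, "spline-3")

        # template-space segmentations: multi-spectral EM posteriors give
        # the intracranial masks; quantification uses linear unmixing with
        # the baseline-calibrated intensity model
        multi_f = segment_tissues([nt1f, nt2f], priors, mode="multi")
        frac_f = estimate_tissue_fractions([nt1f, nt2f], priors, intensity_model)
        if it >= max(0, cfg.bias_refine_passes):
            break
        # Anticipated log-intensity change of the follow-up session from
        # the pass-1 *parcel rates* applied to the GM priors (a voxelwise
        # fraction difference would re-inject its own resampling
        # artefacts).  GM loss is mass transfer to CSF, so the intensity
        # response per channel is d_gm * (mu_gm - mu_csf).
        dt_years = years_between(date_baseline, date_followup)
        lab = parcellation.data.astype(int)
        gm_b_sum = {l: float(frac_b.gm.data[lab == l].sum())
                    for l in np.unique(lab)}
        gm_f_sum = {l: float(frac_f.gm.data[lab == l].sum())
                    for l in np.unique(lab)}
        tot_b = sum(v for l, v in gm_b_sum.items() if l != 0)
        tot_f = sum(v for l, v in gm_f_sum.items() if l != 0)
        global_rel = (tot_f - tot_b) / max(tot_b, 1e-9)
        rel = np.full(lab.shape, global_rel)
        for l in gm_b_sum:
            if l != 0 and gm_b_sum[l] > 1e-9:
                rel[lab == l] = (gm_f_sum[l] - gm_b_sum[l]) / gm_b_sum[l]
        d_gm = priors.gm.data.astype(np.float64) * np.clip(rel, -0.3, 0.3)
        pb = priors.as_dict()
        bgp = np.clip(
            1 - pb["gm"].data - pb["wm"].data - pb["csf"].data, 0, 1
        ).astype(np.float64)
        back = DCTWarp(
            np.linalg.inv(warp.affine_part), np.zeros((4, 4, 4, 3)),
            warp.grid_shape, warp.grid_affine,
        )
        for c in range(2):
            pred = (pb["gm"].data * mu[0, c] + pb["wm"].data * mu[1, c]
                    + pb["csf"].data * mu[2, c] + bgp * mu[3, c])
            ratio = priors.gm.like(
                d_gm * (mu[0, c] - mu[2, c]) / np.maximum(pred, 0.1)
                * (pred > 0.1)
            )
            # interpolation spreads the anatomical signal by about a
            # voxel into adjacent stable tissue; convolve the prediction
            # so the fit sees it where the data does
            known[c] = apply_chain(smooth(ratio, 1.2), back, "trilinear")

    icv: IntracranialMasks = compute_intracranial(
        multi_b, multi_f, threshold=cfg.icv_threshold
    )

    # tissue volumes are integrated within the common intracranial space;
    # the same mask applies to both sessions, so masking cannot bias rates
    def masked(tm):
        cm = icv.common.data
        return type(tm)(
            gm=tm.gm.like(tm.gm.data * cm), wm=tm.wm.like(tm.wm.data * cm),
            csf=tm.csf.like(tm.csf.data * cm), provenance=tm.provenance,
            class_params=tm.class_params,
        )

    opt_b = optimized_csf(icv, masked(frac_b))
    opt_f = optimized_csf(icv, masked(frac_f))

    jac = jacobian_map(warp)
    info["jacobian"] = jac

    def modulated(tm):
        return type(tm)(
            gm=modulate(tm.gm, jac), wm=modulate(tm.wm, jac),
            csf=modulate(tm.csf, jac), provenance=tm.provenance + "-modulated",
        )

    mod_b, mod_f = modulated(opt_b), modulated(opt_f)
    vol_b = integrate_volumes(
        mod_b, parcellation, subject_id=subject_id, session="baseline",
        scan_date=date_baseline, roi_soft_fwhm_mm=cfg.roi_soft_fwhm_mm,
    )
    vol_f = integrate_volumes(
        mod_f, parcellation, subject_id=subject_id, session="follow-up",
        scan_date=date_followup, roi_soft_fwhm_mm=cfg.roi_soft_fwhm_mm,
    )
    rates = annualized_rates(
        vol_b, vol_f,
        base_map=mod_b.gm if cfg.make_rate_maps else None,
        follow_map=mod_f.gm if cfg.make_rate_maps else None,
        fwhm_mm=cfg.fwhm_mm,
    )
    return vol_b, vol_f, rates, info


# --------------------------------------------------------------------------
# cohort-level runner
# --------------------------------------------------------------------------

def _volumes_row(v) -> dict:
    row = {
        "subject_id": v.subject_id, "session": v.session,
        "gm_cm3": v.gm_cm3, "wm_cm3": v.wm_cm3, "csf_cm3": v.csf_cm3,
        "tiv_cm3": v.tiv_cm3, "scan_date": v.scan_date,
        "hippo_cm3": v.hippo_cm3,
    }
    for l, val in sorted(v.parcel_gm_cm3.items()):
        row[f"gm_cm3_parcel{l}"] = val
    return row


def _rates_row(r) -> dict:
    row = {
        "subject_id": r.subject_id, "delta_t_years": r.delta_t_years,
        "dgm_cm3_per_yr": r.dgm_cm3_per_yr, "dgm_pct_per_yr": r.dgm_pct_per_yr,
        "dhippo_cm3_per_yr": r.dhippo_cm3_per_yr,
        "dhippo_pct_per_yr": r.dhippo_pct_per_yr,
    }
    for l, val in sorted(r.parcel_pct_per_yr.items()):
        row[f"rate_pct_parcel{l}"] = val
    for l, val in sorted(r.parcel_cm3_per_yr.items()):
        row[f"rate_cm3_parcel{l}"] = val
    return row


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on the configured synthetic cohort, with caching.

    Each stage writes its outputs plus the config hash; a stage whose
    outputs already exist for the same hash is skipped.  Returns the run
    manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    manifest_path = out / "run_manifest.json"
    manifest = {"config_hash": h, "seed": config.seed, "stages": {}}

    template = build_phantom_template(
        config.template_shape, config.template_voxel_mm,
        config.n_parcels, seed=config.design.seed,
    )

    # ---- stage: simulate
    cohort_dir = out / "cohort"
    stamp = cohort_dir / "manifest.json"
    if stamp.exists() and json.loads(stamp.read_text()).get("config_hash") == h:
        manifest["stages"]["simulate"] = "cached"
    else:
        m = generate_cohort(template, config.design, cohort_dir, overwrite=True)
        m["config_hash"] = h
        stamp.write_text(json.dumps(m, indent=2))
        manifest["stages"]["simulate"] = "run"

    cov = pd.read_csv(cohort_dir / "covariates.tsv", sep="\t")
    priors = PriorSet.from_template(template)

    # ---- stage: per-subject registration/segmentation/volumes/rates
    vol_path, rate_path = out / "volumes.tsv", out / "rates.tsv"
    hash_path = out / "stage_hash.json"
    cached = (
        vol_path.exists() and rate_path.exists() and hash_path.exists()
        and json.loads(hash_path.read_text()).get("config_hash") == h
    )
    if cached:
        manifest["stages"]["subjects"] = "cached"
        vols = pd.read_csv(vol_path, sep="\t")
        rates = pd.read_csv(rate_path, sep="\t")
    else:
        vrows, rrows = [], []
        for _, rec in cov.iterrows():
            sid = rec["subject_id"]
            imgs = [
                BrainImage.load(cohort_dir / f"{sid}_ses-{ses}_{ch}.nii")
                for ses, ch in (("base", "T1"), ("base", "T2"),
                                ("follow", "T1"), ("follow", "T2"))
            ]
            try:
                vb, vf, rr, _ = process_subject_pair(
                    *imgs, priors, template.parcellation, config,
                    subject_id=sid, date_baseline=rec["date_baseline"],
                    date_followup=rec["date_followup"],
                )
            except Exception as e:  # halt with the failing subject id
                raise RuntimeError(f"stage 'subjects' failed for {sid}: {e}") from e
            vrows += [_volumes_row(vb), _volumes_row(vf)]
            rrows.append(_rates_row(rr))
        vols = pd.DataFrame(vrows)
        rates = pd.DataFrame(rrows)
        vols.to_csv(vol_path, sep="\t", index=False, float_format="%.6g")
        rates.to_csv(rate_path, sep="\t", index=False, float_format="%.6g")
        hash_path.write_text(json.dumps({"config_hash": h}))
        manifest["stages"]["subjects"] = "run"

    # ---- stage: statistics
    stats_path = out / "stats.json"
    merged = rates.merge(cov, on="subject_id")
    base_tiv = vols[vols.session == "baseline"][["subject_id", "tiv_cm3"]]
    merged = merged.merge(base_tiv, on="subject_id")
    results = {}
    for resp in ("dgm_cm3_per_yr", "dhippo_cm3_per_yr"):
        try:
            fit = fit_rate_ancova(merged, AncovaSpec(response=resp))
            results[resp] = {
                "effects_p": {k: float(fit.effects.loc[k, "p"])
                              for k in ("sex", "age", "sex:age")
                              if k in fit.effects.index},
                "n": fit.n,
            }
        except ValueError as e:
            results[resp] = {"error": str(e)}
    results["cohort_mean"] = {
        "dgm_cm3_per_yr": float(rates["dgm_cm3_per_yr"].mean()),
        "dgm_pct_per_yr": float(rates["dgm_pct_per_yr"].mean()),
        "dhippo_cm3_per_yr": float(rates["dhippo_cm3_per_yr"].mean()),
        "dhippo_pct_per_yr": float(rates["dhippo_pct_per_yr"].mean()),
    }
    stats_path.write_text(json.dumps(results, indent=2))
    manifest["stages"]["stats"] = "run"

    manifest["artifacts"] = {
        "cohort": str(cohort_dir), "volumes": str(vol_path),
        "rates": str(rate_path), "stats": str(stats_path),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def write_report(run_dir: str | Path, with_figures: bool = True) -> Path:
    """Markdown report (cohort summary, ROI rate table, optional figures).

    All numbers are read back from the stage TSVs so the report cannot
    drift from the pipeline outputs.
    """
    run_dir = Path(run_dir)
    cov = pd.read_csv(run_dir / "cohort" / "covariates.tsv", sep="\t")
    rates = pd.read_csv(run_dir / "rates.tsv", sep="\t")
    stats = json.loads((run_dir / "stats.json").read_text())

    lines = ["# longvbm run report", ""]
    lines.append("## Cohort summary")
    lines.append("")
    lines.append("| sex | n | age mean | education mean | hypertension % |")
    lines.append("|---|---|---|---|---|")
    for sex, grp in cov.groupby("sex"):
        lines.append(
            f"| {sex} | {len(grp)} | {grp.age.mean():.6g} | "
            f"{grp.education_years.mean():.6g} | "
            f"{100 * grp.hypertension.mean():.6g} |"
        )
    lines.append("")
    lines.append("## Annualized rates (cohort means)")
    lines.append("")
    for k, v in stats["cohort_mean"].items():
        lines.append(f"- {k}: {v:.6g}")
    lines.append("")
    lines.append("## ROI rates (%/yr, cohort means)")
    lines.append("")
    lines.append("| parcel | rate %/yr |")
    lines.append("|---|---|")
    roi_cols = [c for c in rates.columns if c.startswith("rate_pct_parcel")]
    for c in roi_cols:
        lines.append(f"| {c.replace('rate_pct_parcel', '')} | "
                     f"{rates[c].mean():.6g} |")
    lines.append("")

    if with_figures:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        figdir = run_dir / "figures"
        figdir.mkdir(exist_ok=True)
        merged = rates.merge(cov, on="subject_id")
        fig, ax = plt.subplots(figsize=(5, 4))
        for sex, mk in (("M", "o"), ("F", "s")):
            g = merged[merged.sex == sex]
            ax.scatter(g.age, g.dgm_cm3_per_yr, s=8, marker=mk, label=sex)
        ax.set_xlabel("age (years)")
        ax.set_ylabel("annualized GM rate (cm$^3$/yr)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(figdir / "rate_vs_age.png", dpi=100)
        plt.close(fig)
        lines.append(f"![rate vs age](figures/rate_vs_age.png)")
        lines.append("")

    path = run_dir / "report.md"
    path.write_text("\n".join(lines))
    return path
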