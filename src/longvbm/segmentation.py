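"""Prior-guided tissue classification and the optimized intracranial scheme.

Tissue maps come from an EM fit of one Gaussian per tissue class per channel
(plus an explicit uniform-prior background class), with the spatial priors
entering the posterior multiplicatively at each E-step.  Mono-spectral mode
uses T1 only; multi-spectral mode uses T1 and T2 jointly (channels treated
as conditionally independent given the class).

The intracranial scheme mirrors an aging-cohort optimization: per-session
intracranial masks are the binarized GM+WM+CSF sums from the multi-spectral
segmentations, their voxelwise intersection defines a common intracranial
space (total intracranial volume assumed constant across sessions), and the
optimized CSF map is that common space minus the mono-spectral GM+WM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import BrainImage
from .phantom import PhantomTemplate

__all__ = [
    "TissueMaps",
    "PriorSet",
    "IntracranialMasks",
    "segment_tissues",
    "fit_intensity_model",
    "estimate_tissue_fractions",
    "build_priors",
    "compute_intracranial",
    "optimized_csf",
]

TISSUES = ("gm", "wm", "csf")


@dataclass
class TissueMaps:
    """GM/WM/CSF probability lattices for one session."""

    gm: BrainImage
    wm: BrainImage
    csf: BrainImage
    provenance: str = "mono"  # mono | multi | optimized-csf | fractions | *-modulated
    log_likelihood: list | None = None
    class_params: dict | None = None  # fitted Gaussians: mu/var (class, channel)

    def __post_init__(self):
        if "modulated" in self.provenance or "fraction" in self.provenance:
            # Jacobian-scaled maps are densities; unmixed fractions are kept
            # unclipped so that volume integrals stay unbiased under noise
            return
        total = self.gm.data + self.wm.data + self.csf.data
        if float(total.max()) > 1.0 + 1e-5:
            raise ValueError("tissue probabilities must sum to <= 1 per voxel")

    def as_dict(self) -> dict[str, BrainImage]:
        return {"gm": self.gm, "wm": self.wm, "csf": self.csf}

    def hard_labels(self) -> np.ndarray:
        """argmax labels: 0 background, 1 gm, 2 wm, 3 csf."""
        stack = np.stack(
            [1.0 - (self.gm.data + self.wm.data + self.csf.data),
             self.gm.data, self.wm.data, self.csf.data]
        )
        return np.argmax(stack, axis=0)


@dataclass
class PriorSet:
    """Tissue priors in template space, with subsample provenance."""

    gm: BrainImage
    wm: BrainImage
    csf: BrainImage
    subsample: dict | None = None  # ids and matching summary

    def as_dict(self) -> dict[str, BrainImage]:
        return {"gm": self.gm, "wm": self.wm, "csf": self.csf}

    @classmethod
    def from_template(cls, template: PhantomTemplate) -> "PriorSet":
        tp = template.tissue_priors
        return cls(tp["gm"], tp["wm"], tp["csf"], subsample=None)


@dataclass
class IntracranialMasks:
    """Per-session and common intracranial masks on the reference grid."""

    session_base: BrainImage
    session_follow: BrainImage
    common: BrainImage


def segment_tissues(
    channels: BrainImage | list[BrainImage],
    priors: PriorSet,
    mode: str = "mono",
    max_iter: int = 50,
    tol: float = 1e-6,
    prior_weight: float = 1.0,
    class_params: dict | None = None,
) -> TissueMaps:
    """EM tissue classification with spatial priors.

    Each class has one Gaussian per channel; posteriors are
    likelihood x prior^prior_weight, renormalized per voxel with an explicit
    background class (prior = 1 - GM - WM - CSF).  The observed-data
    log-likelihood is non-decreasing over iterations; convergence is a
    relative change below ``tol`` or ``max_iter`` iterations.

    When ``class_params`` (e.g. from :func:`fit_intensity_model`) is given,
    the Gaussians are held fixed and a single E-step computes the Bayes
    posterior under the calibrated model — the preferred classification
    when the intensity model is known, since free EM lets thin-structure
    class means drift into partial-volume mixtures.
    """
    if isinstance(channels, BrainImage):
        channels = [channels]
    if mode == "mono":
        channels = channels[:1]
    elif mode != "multi":
        raise ValueError("mode must be 'mono' or 'multi'")
    ref = channels[0]
    for ch in channels[1:]:
        if not ch.same_grid(ref):
            raise ValueError("channels must share one grid")
    for t in TISSUES:
        if priors.as_dict()[t].shape != ref.shape:
            raise ValueError("priors must be on the channel grid")

    Y = np.stack([c.data.astype(np.float64).ravel() for c in channels])  # (C, N)
    n_ch, N = Y.shape
    pri = np.stack(
        [priors.as_dict()[t].data.astype(np.float64).ravel() for t in TISSUES]
    )
    bg = np.clip(1.0 - pri.sum(axis=0), 1e-6, 1.0)
    pri = np.concatenate([pri, bg[None]], axis=0)  # (4, N)
    pri = np.clip(pri, 1e-6, 1.0) ** prior_weight

    data_var = Y.var(axis=1)
    var_floor = 1e-6 * np.maximum(data_var, 1e-12)
    if class_params is not None:
        mu = np.asarray(class_params["mu"], dtype=float)[:, :n_ch].copy()
        var = np.maximum(
            np.asarray(class_params["var"], dtype=float)[:, :n_ch], var_floor
        )
        max_iter = 1  # fixed model: one E-step, no refitting
    else:
        # init from prior-weighted moments
        mu = np.empty((4, n_ch))
        var = np.empty((4, n_ch))
        for k in range(4):
            wsum = pri[k].sum()
            mu[k] = (pri[k] * Y).sum(axis=1) / wsum
            var[k] = np.maximum(
                (pri[k] * (Y - mu[k][:, None]) ** 2).sum(axis=1) / wsum,
                var_floor,
            )
        # uninformative (e.g. flat) priors leave all class means equal, a
        # symmetric fixed point of EM; break ties by intensity quantiles
        for c in range(n_ch):
            if np.ptp(mu[:, c]) < 1e-6 * max(np.sqrt(data_var[c]), 1e-12):
                mu[:, c] = np.quantile(Y[c], [0.625, 0.875, 0.375, 0.125])
                var[:, c] = np.maximum(data_var[c] / 16.0, var_floor[c])

    ll_trace: list[float] = []
    post = None
    for _ in range(max_iter):
        # E-step
        log_lik = np.zeros((4, N))
        for k in range(4):
            for c in range(n_ch):
                log_lik[k] -= 0.5 * (
                    np.log(2 * np.pi * var[k, c]) + (Y[c] - mu[k, c]) ** 2 / var[k, c]
                )
        log_joint = log_lik + np.log(pri)
        m = log_joint.max(axis=0)
        joint = np.exp(log_joint - m)
        norm = joint.sum(axis=0)
        post = joint / norm
        ll = float((np.log(norm) + m).sum())
        ll_trace.append(ll)
        if len(ll_trace) > 1 and abs(ll - ll_trace[-2]) <= tol * abs(ll_trace[-2]):
            break
        # M-step
        for k in range(4):
            wsum = max(post[k].sum(), 1e-12)
            mu[k] = (post[k] * Y).sum(axis=1) / wsum
            var[k] = np.maximum(
                (post[k] * (Y - mu[k][:, None]) ** 2).sum(axis=1) / wsum, var_floor
            )

    shape = ref.shape
    maps = {t: post[i].reshape(shape) for i, t in enumerate(TISSUES)}
    return TissueMaps(
        gm=ref.like(maps["gm"]), wm=ref.like(maps["wm"]), csf=ref.like(maps["csf"]),
        provenance=mode, log_likelihood=ll_trace,
        class_params={"classes": (*TISSUES, "bg"), "mu": mu, "var": var},
    )


def fit_intensity_model(
    channels: BrainImage | list[BrainImage],
    priors: PriorSet,
    ridge: float = 1e-6,
) -> dict:
    """Class mean intensities by regressing voxels on prior tissue fractions.

    Under the partial-volume model the intensity of every voxel is a convex
    combination of the class means weighted by its tissue fractions, so the
    means are identified by a single least-squares regression of the image
    on the spatial prior fractions — thin structures (e.g. a CSF rim that
    never reaches full purity) are handled correctly, where a pure-voxel
    average would be contaminated.  Calibrate on the session whose anatomy
    the priors describe (the baseline), then reuse the model for both
    sessions of a longitudinal pair so real change is not absorbed into the
    class means.
    """
    if isinstance(channels, BrainImage):
        channels = [channels]
    Y = np.stack([c.data.astype(np.float64).ravel() for c in channels])
    pri = np.stack(
        [priors.as_dict()[t].data.astype(np.float64).ravel() for t in TISSUES]
    )
    bg = np.clip(1.0 - pri.sum(axis=0), 0.0, 1.0)
    F = np.vstack([pri, bg[None]])  # (4, N) prior fractions
    G = F @ F.T + ridge * np.eye(4)
    mu = np.linalg.solve(G, F @ Y.T)  # (4, C)
    # per-class residual variance, prior-weighted
    resid = Y - mu.T @ F
    var = np.maximum((F @ (resid**2).T) / F.sum(axis=1)[:, None], 1e-12)
    return {"classes": (*TISSUES, "bg"), "mu": mu, "var": var}


def estimate_tissue_fractions(
    channels: BrainImage | list[BrainImage],
    priors: PriorSet,
    class_params: dict,
) -> TissueMaps:
    """Per-voxel tissue volume fractions by multispectral linear unmixing.

    Models each voxel intensity vector as a convex combination of the class
    mean intensities in ``class_params`` (from :func:`fit_intensity_model`
    or :func:`segment_tissues`).  With two channels plus the sum-to-one
    constraint, exactly three classes are identifiable per voxel; since
    background and deep tissue never co-occur, each voxel drops the class
    with the smallest spatial prior and solves the exact 3x3 system, so
    sub-voxel tissue change is recovered linearly instead of being
    saturated away by classification.  Fractions are returned unclipped
    (mean-unbiased under noise); clip or argmax them for masks and labels.

    For longitudinal pairs, fit ``class_params`` on one session and reuse
    them for both, so real tissue change is not absorbed into class means.
    """
    if isinstance(channels, BrainImage):
        channels = [channels]
    if len(channels) < 2:
        raise ValueError("fraction unmixing needs two channels (T1 and T2)")
    ref = channels[0]
    Y = np.stack([c.data.astype(np.float64).ravel() for c in channels])  # (C,N)
    n_ch, N = Y.shape
    mu = np.asarray(class_params["mu"], dtype=float)[:, :n_ch]  # (4, C)
    pri = np.stack(
        [priors.as_dict()[t].data.astype(np.float64).ravel() for t in TISSUES]
    )
    bg_pri = np.clip(1.0 - pri.sum(axis=0), 0.0, 1.0)

    # Class support per voxel: where background is negligible all three
    # tissues are admitted (atrophy can create CSF anywhere in GM, so CSF
    # must never be dropped there); toward the brain edge background
    # replaces WM, which never borders the skull.  Choosing instead by
    # smallest prior would drop CSF in parcel interiors and GM next to
    # deep structures, silently erasing longitudinal signal; ignoring
    # background at the rim would fabricate tissue there.
    drop = np.where(bg_pri < 0.01, 3, 1)  # 3 = bg, 1 = wm
    frac = np.zeros((4, N))
    # far outside the head the model is pure background by construction;
    # solving there only amplifies out-of-field artefacts
    pure_bg = bg_pri >= 0.999
    frac[3, pure_bg] = 1.0
    rhs = np.vstack([Y, np.ones(N)])  # (C+1, N)
    for d in range(4):
        sel = (drop == d) & ~pure_bg
        if not sel.any():
            continue
        keep = [k for k in range(4) if k != d]
        M3 = np.vstack([mu[keep].T, np.ones(3)])  # (C+1, 3)
        if M3.shape[0] == 3:
            sol = np.linalg.solve(M3, rhs[:, sel])
        else:
            sol = np.linalg.lstsq(M3, rhs[:, sel], rcond=None)[0]
        frac[keep[0], sel], frac[keep[1], sel], frac[keep[2], sel] = sol

    shape = ref.shape
    return TissueMaps(
        gm=ref.like(frac[0].reshape(shape)),
        wm=ref.like(frac[1].reshape(shape)),
        csf=ref.like(frac[2].reshape(shape)),
        provenance="fractions",
        class_params=class_params,
    )


# --------------------------------------------------------------------------
# cohort-specific priors
# --------------------------------------------------------------------------

def _standardize(df: pd.DataFrame, cols) -> np.ndarray:
    X = df[list(cols)].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


def select_matched_subsample(
    covariates: pd.DataFrame,
    n_per_sex: int,
    matching_vars=("age", "hypertension", "education_years"),
    caliper_sd: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sex subsample whose matching-variable means track the full cohort.

    Greedy on the running mean: within each sex, subjects are added one at
    a time, each time choosing the candidate that brings the subsample's
    standardized mean vector closest to the full-sex mean (plain
    nearest-to-mean ranking fails for binary variables such as
    hypertension).  Fails if any selected-vs-full mean difference exceeds
    ``caliper_sd`` pooled SDs.
    """
    picks = []
    for sex, grp in covariates.groupby("sex"):
        if len(grp) < n_per_sex:
            raise ValueError(
                f"cannot draw {n_per_sex} subjects of sex {sex}: only {len(grp)}"
            )
        Z = _standardize(grp, matching_vars)
        chosen: list[int] = []
        remaining = list(range(len(grp)))
        run = np.zeros(Z.shape[1])
        for k in range(n_per_sex):
            cand = np.asarray(remaining)
            dist = (((run + Z[cand]) / (k + 1)) ** 2).sum(axis=1)
            best = int(cand[np.argmin(dist)])
            chosen.append(best)
            remaining.remove(best)
            run += Z[best]
        sel = grp.iloc[chosen]
        # at small n the subsample mean cannot beat its own sampling error,
        # so the caliper is floored at ~1.5 standard errors
        eff_caliper = max(caliper_sd, 1.5 / np.sqrt(n_per_sex))
        for v in matching_vars:
            sd = covariates[v].std(ddof=1) or 1.0
            diff = abs(sel[v].mean() - grp[v].mean()) / sd
            if diff > eff_caliper:
                raise ValueError(
                    f"matching infeasible: |mean diff| for '{v}' (sex {sex}) "
                    f"is {diff:.2f} pooled SD > caliper {eff_caliper:.2f}"
                )
        picks.append(sel)
    rng = np.random.default_rng(seed)
    out = pd.concat(picks).sort_values("subject_id").reset_index(drop=True)
    return out


def build_priors(
    cohort_dir,
    template: PhantomTemplate,
    n_per_sex: int,
    matching_vars=("age", "hypertension", "education_years"),
    seed: int = 0,
    smooth_fwhm_mm: float = 2.0,
) -> PriorSet:
    """Cohort-specific tissue priors from a demographically matched subsample.

    Each selected subject's baseline session is segmented into tissue
    fractions with the template's bootstrap priors (intensity model
    calibrated per subject), nonlinearly normalized to the template GM
    prior, and the warped tissue maps are averaged voxelwise and smoothed.
    """
    from pathlib import Path

    from .morphometry import smooth
    from .registration import apply_chain, dct_normalize

    cohort_dir = Path(cohort_dir)
    cov = pd.read_csv(cohort_dir / "covariates.tsv", sep="\t")
    sel = select_matched_subsample(cov, n_per_sex, matching_vars, seed=seed)
    boot = PriorSet.from_template(template)
    sums = {t: np.zeros(template.shape, np.float64) for t in TISSUES}
    for sid in sel["subject_id"]:
        t1 = BrainImage.load(cohort_dir / f"{sid}_ses-base_T1.nii")
        t2 = BrainImage.load(cohort_dir / f"{sid}_ses-base_T2.nii")
        model = fit_intensity_model([t1, t2], boot)
        tm = estimate_tissue_fractions([t1, t2], boot, model)
        warp = dct_normalize(tm.gm, template.tissue_priors["gm"], levels=1,
                             max_iter=16, affine_stage=False)
        for t in TISSUES:
            warped = apply_chain(tm.as_dict()[t], warp).data.astype(np.float64)
            sums[t] += np.clip(warped, 0.0, 1.0)
    n = len(sel)
    mk = lambda a: smooth(
        BrainImage((a / n).astype(np.float32), template.affine), smooth_fwhm_mm
    )
    return PriorSet(
        mk(sums["gm"]), mk(sums["wm"]), mk(sums["csf"]),
        subsample={"ids": sel["subject_id"].tolist(), "n_per_sex": n_per_sex,
                   "matching_vars": list(matching_vars)},
    )


# --------------------------------------------------------------------------
# intracranial space
# --------------------------------------------------------------------------

def compute_intracranial(
    tm_base: TissueMaps, tm_follow: TissueMaps, threshold: float = 0.5
) -> IntracranialMasks:
    """Session masks = binarized GM+WM+CSF; common mask = their intersection."""
    if tm_base.gm.shape != tm_follow.gm.shape:
        raise ValueError("sessions must be on the same grid")

    def mask(tm):
        s = tm.gm.data + tm.wm.data + tm.csf.data
        return (s >= threshold).astype(np.float32)

    mb, mf = mask(tm_base), mask(tm_follow)
    common = mb * mf
    if common.sum() == 0:
        raise ValueError("empty common intracranial mask: alignment likely broken")
    aff = tm_base.gm.affine
    return IntracranialMasks(
        BrainImage(mb, aff), BrainImage(mf, aff), BrainImage(common, aff)
    )


def optimized_csf(common: IntracranialMasks, mono_tm: TissueMaps) -> TissueMaps:
    """CSF = clip(common - GM - WM, 0, 1); GM/WM pass through from mono.

    GM and WM keep the T1-only (mono-spectral) estimates; only CSF — and
    hence TIV — uses the common intracranial space.
    """
    if common.common.shape != mono_tm.gm.shape:
        raise ValueError("grids do not match")
    csf = np.clip(
        common.common.data - mono_tm.gm.data - mono_tm.wm.data, 0.0, 1.0
    )
    prov = "optimized-csf"
    if "fraction" in mono_tm.provenance:
        prov += "-fractions"
    return TissueMaps(
        gm=mono_tm.gm, wm=mono_tm.wm, csf=mono_tm.gm.like(csf),
        provenance=prov, class_params=mono_tm.class_params,
    )
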