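"""Synthetic two-timepoint T1/T2 brain phantoms with known atrophy truth.

The generator emulates a community cohort of healthy older adults scanned
twice roughly 3.6 years apart: concentric tissue shells (CSF rim, grey-matter
ribbon, white-matter core) with two deep grey-matter blobs standing in for
the hippocampi, an AAL-style angular parcellation of the cortical ribbon,
region-specific annualized grey-matter loss with a female excess multiplier
and a hippocampus-specific age acceleration, a rigid inter-session
misalignment, smooth multiplicative bias fields, and additive Gaussian noise.

Atrophy is applied in template space as probability-mass transfer from GM to
CSF, so the per-voxel tissue sum — and hence total intracranial volume — is
conserved by construction and ground-truth volumes are exact.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import truncnorm

from .image import BrainImage, default_affine

__all__ = [
    "HIPPO_L",
    "HIPPO_R",
    "PhantomTemplate",
    "CohortDesign",
    "SubjectRecord",
    "TruthRecord",
    "build_phantom_template",
    "sample_cohort_covariates",
    "simulate_subject_pair",
    "simulate_rate_table",
    "generate_cohort",
]

# Reserved parcellation labels for the two hippocampi.
HIPPO_L = 101
HIPPO_R = 102

# Mean intensity per tissue per channel (arbitrary scanner units).  WM is the
# brightest tissue on T1, CSF the brightest on T2, as in spoiled-gradient T1
# and fast spin-echo T2 contrasts.
DEFAULT_CONTRAST = {
    "t1": {"gm": 0.70, "wm": 1.00, "csf": 0.25, "bg": 0.02},
    "t2": {"gm": 0.55, "wm": 0.40, "csf": 1.00, "bg": 0.02},
}

# Normalized ellipsoid radii of the shell boundaries (fractions of the brain
# radius): ventricular CSF cavity, WM core, GM ribbon, CSF rim, skull edge.
_R_VENT = 0.30
_R_WM = 0.60
_R_GM = 0.84
_R_CSF = 1.00


@dataclass
class PhantomTemplate:
    """Template-space geometry shared by every simulated subject."""

    shape: tuple[int, int, int]
    voxel_size_mm: np.ndarray
    tissue_priors: dict[str, BrainImage]  # keys: gm, wm, csf
    parcellation: BrainImage  # integer labels; HIPPO_L / HIPPO_R reserved
    contrast_table: dict[str, dict[str, float]]

    @property
    def affine(self) -> np.ndarray:
        return self.tissue_priors["gm"].affine

    @property
    def voxel_volume(self) -> float:
        return self.tissue_priors["gm"].voxel_volume

    def parcel_labels(self) -> list[int]:
        labs = np.unique(self.parcellation.data.astype(int))
        return [int(l) for l in labs if l != 0]

    def parcel_gm_volumes(self) -> dict[int, float]:
        """Ground-truth GM volume (cm^3) per parcel from the priors."""
        gm = self.tissue_priors["gm"].data.astype(np.float64)
        lab = self.parcellation.data.astype(int)
        vv = self.voxel_volume / 1000.0
        return {l: float(gm[lab == l].sum() * vv) for l in self.parcel_labels()}


def _sigmoid(t: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(t, -40, 40)))


def build_phantom_template(
    shape=(48, 48, 48),
    voxel_size_mm=1.0,
    n_parcels: int = 12,
    seed: int = 0,
    edge_mm: float = 0.3,
) -> PhantomTemplate:
    """Build the concentric-shell phantom template.

    The brain is an asymmetric ellipsoid: a CSF rim, a GM ribbon, a WM
    core and a central ventricular CSF cavity, with soft (sigmoid)
    boundaries of half-width ``edge_mm`` so priors are smooth; two
    spherical deep-GM blobs in the WM carry the reserved hippocampus
    labels.  The cortical ribbon is split into ``n_parcels - 2`` angular
    sectors.

    Deterministic for a fixed seed (the seed rotates the sector origin).
    """
    shape = tuple(int(s) for s in np.broadcast_to(shape, (3,)))
    if min(shape) < 32:
        raise ValueError(
            f"grid {shape} too small: at least 32 voxels per axis are needed "
            "to contain the CSF rim, GM ribbon and WM core"
        )
    if n_parcels < 12:
        raise ValueError("n_parcels must be >= 12")
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    affine = default_affine(shape, vs)

    # world coordinates and normalized ellipsoid radius
    grid = np.stack(
        np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1
    )
    world = grid @ np.diag(vs) + affine[:3, 3]
    half_fov = np.asarray(shape) * vs / 2.0
    # distinct per-axis radii: rotations must be identifiable from shape.
    # Kept under 0.8 of the field of view so inter-session offsets of a few
    # mm cannot push the head outside the acquisition grid.
    radii = np.array([0.80, 0.70, 0.76]) * half_fov  # brain radius per axis, mm
    rho = np.sqrt(((world / radii) ** 2).sum(axis=-1))

    # signed distances (mm) from each shell boundary: (threshold - rho)
    # divided by |grad rho| so the sigmoid edge has the stated physical
    # width everywhere on the ellipsoid (a constant radial scale would
    # bias the soft-prior integrals by ~1%)
    rad_scale = float(np.mean(radii))
    grad_rho = np.sqrt(((world / radii**2) ** 2).sum(axis=-1)) / np.maximum(
        rho, 1e-6
    )
    inv_g = 1.0 / np.maximum(grad_rho, 1.0 / (2.0 * rad_scale))
    d_csf = (_R_CSF - rho) * inv_g
    d_gm = (_R_GM - rho) * inv_g
    d_wm = (_R_WM - rho) * inv_g

    d_vent = (_R_VENT - rho) * inv_g

    in_brain = _sigmoid(d_csf / edge_mm)
    in_gm_core = _sigmoid(d_gm / edge_mm)
    in_wm_core = _sigmoid(d_wm / edge_mm)
    in_vent = _sigmoid(d_vent / edge_mm)

    # a central CSF cavity stands in for the ventricles: without a pure-CSF
    # reservoir the thin cortical rim would be all partial volume
    csf = (in_brain - in_gm_core) + in_vent
    gm = in_gm_core - in_wm_core
    wm = in_wm_core - in_vent

    # hippocampi: two deep spheres straddling the midline inside the WM core
    hip_r = 0.16 * rad_scale
    centers = np.array(
        [[-0.33 * radii[0], -0.15 * radii[1], -0.10 * radii[2]],
         [+0.33 * radii[0], -0.15 * radii[1], -0.10 * radii[2]]]
    )
    hip_masks = []
    for c in centers:
        d = np.sqrt(((world - c) ** 2).sum(axis=-1))
        hip_masks.append(_sigmoid((hip_r - d) / edge_mm))
    hip_total = np.clip(hip_masks[0] + hip_masks[1], 0, 1)
    # inside the hippocampi the tissue is grey matter
    gm_new = gm + (wm + csf) * hip_total
    wm = wm * (1 - hip_total)
    csf = csf * (1 - hip_total)
    gm = gm_new

    # parcellation of the GM ribbon into angular sectors
    rng = np.random.default_rng(seed)
    theta0 = rng.uniform(0, 2 * np.pi)
    n_cort = n_parcels - 2
    m_az = int(np.ceil(n_cort / 2))
    az = np.mod(np.arctan2(world[..., 1], world[..., 0]) - theta0, 2 * np.pi)
    az_bin = np.minimum((az / (2 * np.pi) * m_az).astype(int), m_az - 1)
    el_bin = (world[..., 2] >= 0).astype(int)
    labels = 1 + az_bin + m_az * el_bin
    if 2 * m_az > n_cort:  # odd sector count: merge the last into its peer
        labels[labels > n_cort] = n_cort
    # parcels cover substantive GM only: faint sigmoid tails are excluded
    # so atrophy (applied parcelwise) spares voxels that border the
    # longitudinally stable CSF rim
    labels = np.where(gm > 0.25, labels, 0)
    hipL = hip_masks[0] > 0.5
    hipR = hip_masks[1] > 0.5
    labels[hipL] = HIPPO_L
    labels[hipR] = HIPPO_R

    mk = lambda a: BrainImage(a.astype(np.float32), affine)
    return PhantomTemplate(
        shape=shape,
        voxel_size_mm=vs,
        tissue_priors={"gm": mk(gm), "wm": mk(wm), "csf": mk(csf)},
        parcellation=BrainImage(labels.astype(np.float32), affine),
        contrast_table={k: dict(v) for k, v in DEFAULT_CONTRAST.items()},
    )


# --------------------------------------------------------------------------
# cohort design and covariates
# --------------------------------------------------------------------------

@dataclass
class CohortDesign:
    """Population parameters of the simulated cohort.

    Defaults reproduce the study-entry characteristics of a large French
    community cohort of 65-82 year-olds: 430:742 male:female, age 72 +/- 4,
    hypertension 83.8% in men and 69.5% in women, hormone-replacement
    therapy in about a third of women, and education 10.7 +/- 4.6 (men) vs
    9.2 +/- 4.0 (women) years.  Rates are in %/year (negative = loss);
    the acceleration coefficients are in %/year of rate per year of age.
    """

    n_subjects: int = 120
    seed: int = 0
    female_fraction: float = 742 / 1172
    age_mean: dict = field(default_factory=lambda: {"M": 72.0, "F": 72.3})
    age_sd: dict = field(default_factory=lambda: {"M": 4.0, "F": 3.9})
    age_bounds: tuple[float, float] = (65.0, 82.0)
    hypertension_p: dict = field(default_factory=lambda: {"M": 0.838, "F": 0.695})
    hrt_p_women: float = 166 / 491
    education: dict = field(
        default_factory=lambda: {"M": (10.7, 4.6), "F": (9.2, 4.0)}
    )
    education_bounds: tuple[float, float] = (0.0, 17.0)
    followup_mean_yr: float = 3.6
    followup_sd_yr: float = 0.3
    followup_bounds_yr: tuple[float, float] = (3.0, 4.5)
    # atrophy model ------------------------------------------------------
    base_rates: dict | None = None  # parcel label -> %/yr in male at age 65
    sex_multiplier: float = 1.4  # female rates = base * multiplier
    hippo_accel: float = -0.03  # %/yr of extra loss rate per year past 65
    global_accel: float = 0.0
    hrt_rate_benefit_pct: float = 0.14  # slower loss (%/yr) in treated women
    subject_rate_sd: float = 0.5  # shared %/yr jitter across parcels
    parcel_rate_sd: float = 0.1  # independent per-parcel %/yr jitter
    # imaging nuisances --------------------------------------------------
    rigid_rot_max_deg: float = 3.0
    rigid_trans_max_mm: float = 3.0
    bias_coef_sd: float = 0.05
    noise_frac: float = 0.02  # sigma as fraction of the brightest tissue mean

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        for p in (self.female_fraction, self.hrt_p_women, *self.hypertension_p.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        lo, hi = self.age_bounds
        if lo < 65.0 or hi > 82.0:
            raise ValueError("age bounds must lie within [65, 82]")

    def resolve_base_rates(self, template: PhantomTemplate) -> dict[int, float]:
        """Per-parcel base rates, filling defaults for a given template.

        Cortical parcels span -0.2 to -1.1 %/yr; the hippocampi start at
        -0.67 %/yr, which with the female multiplier and age acceleration
        yields a cohort-mean hippocampal loss near -1 %/yr.
        """
        if self.base_rates is not None:
            return {int(k): float(v) for k, v in self.base_rates.items()}
        labels = template.parcel_labels()
        cort = [l for l in labels if l not in (HIPPO_L, HIPPO_R)]
        vals = np.linspace(-0.2, -1.1, len(cort))
        rates = {l: float(v) for l, v in zip(sorted(cort), vals)}
        rates[HIPPO_L] = rates[HIPPO_R] = -0.67
        return rates

    def accel_for(self, label: int) -> float:
        return self.hippo_accel if label in (HIPPO_L, HIPPO_R) else self.global_accel


@dataclass
class SubjectRecord:
    """Covariates and scan timing for one subject."""

    subject_id: str
    sex: str  # 'M' or 'F'
    age: float  # at baseline
    education_years: float
    hypertension: bool
    hrt: bool
    date_baseline: str  # ISO dates
    date_followup: str

    @property
    def followup_years(self) -> float:
        d0 = _dt.date.fromisoformat(self.date_baseline)
        d1 = _dt.date.fromisoformat(self.date_followup)
        return (d1 - d0).days / 365.25


@dataclass
class TruthRecord:
    """Ground truth stored alongside each simulated subject pair."""

    subject_id: str
    followup_years: float
    parcel_rates_pct: dict[int, float]  # %/yr actually applied (post-clip)
    global_rate_cm3: float
    global_rate_pct: float
    hippo_rate_cm3: float
    hippo_rate_pct: float
    baseline_gm_cm3: float
    baseline_hippo_cm3: float
    baseline_parcel_cm3: dict[int, float]
    rigid_rotations_deg: tuple[float, float, float]
    rigid_translations_mm: tuple[float, float, float]
    bias_coef_sd: float
    noise_sigma: dict[str, float]
    clipped_parcels: list[int]
    base_rotations_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    base_translations_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.followup_years <= 0:
            raise ValueError("follow-up interval must be positive")


def _trunc_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_cohort_covariates(design: CohortDesign) -> list[SubjectRecord]:
    """Draw subject covariates and scan dates from the cohort design."""
    rng = np.random.default_rng(design.seed)
    n = design.n_subjects
    sexes = np.where(rng.random(n) < design.female_fraction, "F", "M")
    records = []
    for i in range(n):
        s = sexes[i]
        age = float(
            _trunc_normal(rng, design.age_mean[s], design.age_sd[s],
                          *design.age_bounds, size=1)[0]
        )
        mu_e, sd_e = design.education[s]
        edu = float(
            np.clip(np.round(rng.normal(mu_e, sd_e)), *design.education_bounds)
        )
        hyp = bool(rng.random() < design.hypertension_p[s])
        hrt = bool(s == "F" and rng.random() < design.hrt_p_women)
        dt_yr = float(
            _trunc_normal(rng, design.followup_mean_yr, design.followup_sd_yr,
                          *design.followup_bounds_yr, size=1)[0]
        )
        d0 = _dt.date(1999, 6, 1) + _dt.timedelta(days=int(rng.integers(0, 480)))
        d1 = d0 + _dt.timedelta(days=int(round(dt_yr * 365.25)))
        records.append(
            SubjectRecord(
                subject_id=f"sub-{i:04d}", sex=str(s), age=age,
                education_years=edu, hypertension=hyp, hrt=hrt,
                date_baseline=d0.isoformat(), date_followup=d1.isoformat(),
            )
        )
    return records


def subject_parcel_rates(
    design: CohortDesign,
    base_rates: dict[int, float],
    record: SubjectRecord,
    rng: np.random.Generator,
) -> tuple[dict[int, float], list[int]]:
    """True applied %/yr rate per parcel for one subject.

    rate_p = base_p * (sex multiplier if female) + accel_p * (age - 65)
             + shared jitter + parcel jitter, clipped to <= 0.
    """
    shared = rng.normal(0.0, design.subject_rate_sd)
    rates, clipped = {}, []
    for label, base in base_rates.items():
        r = base * (design.sex_multiplier if record.sex == "F" else 1.0)
        r += design.accel_for(label) * (record.age - 65.0)
        if record.hrt:
            r += design.hrt_rate_benefit_pct
        r += shared + rng.normal(0.0, design.parcel_rate_sd)
        if r > 0:
            clipped.append(label)
            r = 0.0
        rates[label] = float(r)
    return rates, clipped


# --------------------------------------------------------------------------
# image synthesis
# --------------------------------------------------------------------------

def _bias_field(world: np.ndarray, coefs: np.ndarray, extent: np.ndarray) -> np.ndarray:
    """exp(second-order 3D polynomial) multiplicative bias field."""
    x, y, z = (world[..., i] / extent[i] for i in range(3))
    monomials = [x, y, z, x * y, x * z, y * z, x * x, y * y, z * z]
    logb = np.zeros(world.shape[:-1])
    for c, m in zip(coefs, monomials):
        logb += c * m
    return np.exp(logb)


def _resample_rigid(data: np.ndarray, affine: np.ndarray, rot_deg, trans_mm):
    """Resample ``data`` as seen in a session frame rigidly offset from the
    template frame: output voxel x holds the value at R(world(x))."""
    from .registration import RigidTransform  # local import: no cycle at load

    T = RigidTransform(np.deg2rad(np.asarray(rot_deg)), np.asarray(trans_mm))
    shape = data.shape
    grid = np.stack(
        np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    world = grid @ affine[:3, :3].T + affine[:3, 3]
    mapped = T.apply(world)
    inv = np.linalg.inv(affine)
    vox = mapped @ inv[:3, :3].T + inv[:3, 3]
    out = ndimage.map_coordinates(
        data.astype(np.float64), vox.T, order=3, mode="constant", cval=0.0
    )
    return out.reshape(shape)


def simulate_subject_pair(
    template: PhantomTemplate,
    record: SubjectRecord,
    design: CohortDesign,
    seed: int,
):
    """Simulate the four images (T1/T2 x baseline/follow-up) for one subject.

    Returns ``(t1_base, t2_base, t1_follow, t2_follow, truth)``.  Follow-up
    tissue is the baseline tissue with parcelwise GM loss transferred to CSF,
    viewed through a small rigid inter-session offset; both sessions get
    independent bias fields and noise.
    """
    if record.followup_years <= 0:
        raise ValueError("follow-up interval must be positive")
    rng = np.random.default_rng(seed)
    affine = template.affine
    gm0 = template.tissue_priors["gm"].data.astype(np.float64)
    wm0 = template.tissue_priors["wm"].data.astype(np.float64)
    csf0 = template.tissue_priors["csf"].data.astype(np.float64)
    labels = template.parcellation.data.astype(int)

    base_rates = design.resolve_base_rates(template)
    rates, clipped = subject_parcel_rates(design, base_rates, record, rng)
    dt = record.followup_years

    factor = np.ones_like(gm0)
    for label, r in rates.items():
        factor[labels == label] = max(0.0, 1.0 + r * dt / 100.0)
    gm1 = gm0 * factor
    csf1 = csf0 + (gm0 - gm1)  # lost GM mass becomes CSF: TIV conserved
    wm1 = wm0

    vv = template.voxel_volume / 1000.0  # cm^3 per voxel
    parcel_base = {l: float(gm0[labels == l].sum() * vv) for l in base_rates}
    parcel_fol = {l: float(gm1[labels == l].sum() * vv) for l in base_rates}
    gm_b, gm_f = float(gm0.sum() * vv), float(gm1.sum() * vv)
    hip_b = parcel_base[HIPPO_L] + parcel_base[HIPPO_R]
    hip_f = parcel_fol[HIPPO_L] + parcel_fol[HIPPO_R]

    # Per-session head positioning.  The follow-up session carries the full
    # rigid inter-session offset; the baseline gets a sub-voxel jitter so
    # both scans share the same interpolation smoothing (a baseline sampled
    # exactly on the template grid would be artificially sharper than the
    # resampled follow-up, biasing longitudinal differences).
    jit = 0.5 * float(np.min(template.voxel_size_mm))
    if design.rigid_rot_max_deg == 0 and design.rigid_trans_max_mm == 0:
        jit = 0.0
    rot_b = np.zeros(3)
    tra_b = rng.uniform(-jit, jit, 3)
    rot = rng.uniform(-design.rigid_rot_max_deg, design.rigid_rot_max_deg, 3)
    tra = rng.uniform(-design.rigid_trans_max_mm, design.rigid_trans_max_mm, 3)

    def compose(gm, wm, csf, channel, session_rot, session_tra):
        mu = template.contrast_table[channel]
        bg = np.clip(1.0 - gm - wm - csf, 0.0, 1.0)
        img = mu["gm"] * gm + mu["wm"] * wm + mu["csf"] * csf + mu["bg"] * bg
        if np.any(session_rot) or np.any(session_tra):
            img = _resample_rigid(img, affine, session_rot, session_tra)
        if design.bias_coef_sd > 0:
            coefs = rng.normal(0.0, design.bias_coef_sd, 9)
            world = template.tissue_priors["gm"].world_coords()
            extent = np.asarray(template.shape) * template.voxel_size_mm / 2.0
            img = img * _bias_field(world, coefs, extent)
        sigma = design.noise_frac * max(mu["gm"], mu["wm"], mu["csf"])
        if sigma > 0:
            img = img + rng.normal(0.0, sigma, img.shape)
        return BrainImage(img.astype(np.float32), affine), sigma

    t1b, sig1 = compose(gm0, wm0, csf0, "t1", rot_b, tra_b)
    t2b, sig2 = compose(gm0, wm0, csf0, "t2", rot_b, tra_b)
    t1f, _ = compose(gm1, wm1, csf1, "t1", rot, tra)
    t2f, _ = compose(gm1, wm1, csf1, "t2", rot, tra)

    truth = TruthRecord(
        subject_id=record.subject_id,
        followup_years=dt,
        parcel_rates_pct=rates,
        global_rate_cm3=(gm_f - gm_b) / dt,
        global_rate_pct=100.0 * (gm_f - gm_b) / dt / gm_b,
        hippo_rate_cm3=(hip_f - hip_b) / dt,
        hippo_rate_pct=100.0 * (hip_f - hip_b) / dt / hip_b,
        baseline_gm_cm3=gm_b,
        baseline_hippo_cm3=hip_b,
        baseline_parcel_cm3=parcel_base,
        rigid_rotations_deg=tuple(rot),
        rigid_translations_mm=tuple(tra),
        base_rotations_deg=tuple(rot_b),
        base_translations_mm=tuple(tra_b),
        bias_coef_sd=design.bias_coef_sd,
        noise_sigma={"t1": sig1, "t2": sig2},
        clipped_parcels=clipped,
    )
    return t1b, t2b, t1f, t2f, truth


def simulate_rate_table(
    template: PhantomTemplate,
    design: CohortDesign,
    records: list[SubjectRecord] | None = None,
    head_size_cv: float = 0.05,
) -> pd.DataFrame:
    """Cohort rate table straight from the atrophy model (no imaging).

    Gives, per subject, the true annualized global and hippocampal rates in
    cm^3/yr and %/yr plus covariates, with log-normal head-size variation
    scaling all volumes (so TIV varies across subjects as in real cohorts).
    Baseline volumes carry the cross-sectional imprint of aging: the
    atrophy-rate model integrated from age 65 to the subject's baseline
    age (linear in age for constant rates, quadratic where the rate
    accelerates), anchored so the cohort-mean-age subject is unscaled.
    Useful for statistical-layer studies where the imaging chain is not
    the question.
    """
    if records is None:
        records = sample_cohort_covariates(design)
    rng = np.random.default_rng(design.seed + 1)
    base_rates = design.resolve_base_rates(template)
    parcel_vol = template.parcel_gm_volumes()
    gm_tot = sum(parcel_vol.values())
    wm_tot = template.tissue_priors["wm"].integral() / 1000.0
    csf_tot = template.tissue_priors["csf"].integral() / 1000.0
    anchor_age = 72.0

    def cumulative_loss_pct(label: int, sex: str, age: float) -> float:
        # integral of the %/yr rate from 65 to the given age
        mult = design.sex_multiplier if sex == "F" else 1.0
        base = base_rates[label] * mult
        acc = design.accel_for(label)
        return base * (age - 65.0) + 0.5 * acc * (age - 65.0) ** 2

    rows = []
    for rec in records:
        scale = float(np.exp(rng.normal(0.0, head_size_cv)))
        rates, _ = subject_parcel_rates(design, base_rates, rec, rng)
        base_v = {}
        for l, v in parcel_vol.items():
            rel = (cumulative_loss_pct(l, rec.sex, rec.age)
                   - cumulative_loss_pct(l, rec.sex, anchor_age)) / 100.0
            base_v[l] = v * scale * (1.0 + rel)
        d_gm = sum(rates[l] / 100.0 * base_v[l] for l in rates)
        hip_v = base_v[HIPPO_L] + base_v[HIPPO_R]
        d_hip = sum(rates[l] / 100.0 * base_v[l] for l in (HIPPO_L, HIPPO_R))
        gm_v = sum(base_v.values()) + (gm_tot - sum(parcel_vol.values())) * scale
        rows.append(
            {
                "subject_id": rec.subject_id,
                "sex": rec.sex,
                "age": rec.age,
                "education_years": rec.education_years,
                "hypertension": int(rec.hypertension),
                "hrt": int(rec.hrt),
                "followup_years": rec.followup_years,
                "tiv_cm3": (gm_tot + wm_tot + csf_tot) * scale,
                "gm_baseline_cm3": gm_v,
                "hippo_baseline_cm3": hip_v,
                "dgm_cm3_per_yr": d_gm,
                "dhippo_cm3_per_yr": d_hip,
                "dgm_pct_per_yr": 100.0 * d_gm / gm_v,
                "dhippo_pct_per_yr": 100.0 * d_hip / hip_v,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# cohort generation on disk
# --------------------------------------------------------------------------

def covariates_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": r.subject_id, "sex": r.sex, "age": r.age,
            "education_years": r.education_years,
            "hypertension": int(r.hypertension), "hrt": int(r.hrt),
            "date_baseline": r.date_baseline, "date_followup": r.date_followup,
            "followup_years": r.followup_years,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def truth_frame(truths: list[TruthRecord]) -> pd.DataFrame:
    rows = []
    for t in truths:
        row = {
            "subject_id": t.subject_id,
            "followup_years": t.followup_years,
            "global_rate_cm3": t.global_rate_cm3,
            "global_rate_pct": t.global_rate_pct,
            "hippo_rate_cm3": t.hippo_rate_cm3,
            "hippo_rate_pct": t.hippo_rate_pct,
            "baseline_gm_cm3": t.baseline_gm_cm3,
            "baseline_hippo_cm3": t.baseline_hippo_cm3,
        }
        for l, r in sorted(t.parcel_rates_pct.items()):
            row[f"rate_pct_parcel{l}"] = r
        rows.append(row)
    return pd.DataFrame(rows)


def generate_cohort(
    template: PhantomTemplate,
    design: CohortDesign,
    out_dir: str | Path,
    overwrite: bool = False,
) -> dict:
    """Write a full synthetic cohort (NIfTI quadruples + TSVs + manifest)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("seed") != design.seed and not overwrite:
            raise FileExistsError(
                f"{manifest_path} exists with seed {old.get('seed')} != "
                f"{design.seed}; pass overwrite=True to replace it"
            )
    records = sample_cohort_covariates(design)
    truths, files = [], []
    for i, rec in enumerate(records):
        sub_seed = subject_seed(design.seed, i)
        t1b, t2b, t1f, t2f, truth = simulate_subject_pair(
            template, rec, design, sub_seed
        )
        for img, tag in [(t1b, "ses-base_T1"), (t2b, "ses-base_T2"),
                         (t1f, "ses-follow_T1"), (t2f, "ses-follow_T2")]:
            p = out / f"{rec.subject_id}_{tag}.nii"
            img.save(p)
            files.append(p.name)
        truths.append(truth)
    covariates_frame(records).to_csv(out / "covariates.tsv", sep="\t", index=False)
    truth_frame(truths).to_csv(
        out / "truth.tsv", sep="\t", index=False, float_format="%.10g"
    )
    manifest = {
        "seed": design.seed,
        "n_subjects": design.n_subjects,
        "design": _design_json(design),
        "files": files,
        "covariates": "covariates.tsv",
        "truth": "truth.tsv",
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def subject_seed(master_seed: int, index: int) -> int:
    """Stable per-subject seed below 2^31 derived from the master seed."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


def _design_json(design: CohortDesign) -> dict:
    d = dataclasses.asdict(design)
    if d.get("base_rates") is not None:
        d["base_rates"] = {str(k): v for k, v in d["base_rates"].items()}
    return d
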