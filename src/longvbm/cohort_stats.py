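"""Cohort-level statistics for annualized atrophy rates.

Implements the analysis layer of a longitudinal morphometry study:

* full-factorial ANCOVA for sex, age and their interaction on scalar rates,
  with education, hypertension and TIV as covariates (type-III partial
  tests, sum-to-zero sex coding, age centered at 65);
* linear-vs-quadratic age models for baseline volumes;
* voxelwise GLM on rate maps with family-wise-error control by max-statistic
  permutation (Freedman-Lane residual permutation) or Bonferroni;
* a shifting-window cross-sectional slope estimator (1-year age bins) to
  check regression-attenuation bias against OLS;
* greedy caliper matching for treated-vs-untreated comparisons (HRT).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .image import BrainImage

__all__ = [
    "AncovaSpec",
    "AncovaResult",
    "QuadraticAgeFit",
    "FweMapResult",
    "fit_rate_ancova",
    "fit_quadratic_age",
    "voxelwise_glm_fwe",
    "shifting_window_slope",
    "matched_subsample_compare",
]


@dataclass
class AncovaSpec:
    """Design of the full-factorial sex x age ANCOVA."""

    response: str
    covariates: tuple = ("education_years", "hypertension", "tiv_cm3")
    age_center: float = 65.0
    sex_col: str = "sex"
    age_col: str = "age"


@dataclass
class AncovaResult:
    params: pd.Series
    bse: pd.Series
    effects: pd.DataFrame  # F, df, p per effect (type III)
    n: int
    model: object = None

    def p(self, effect: str) -> float:
        return float(self.effects.loc[effect, "p"])

    def coef(self, name: str) -> float:
        return float(self.params[name])


def _prepare(df: pd.DataFrame, spec: AncovaSpec) -> pd.DataFrame:
    cols = [spec.response, spec.sex_col, spec.age_col, *spec.covariates]
    d = df[cols].dropna().copy()
    d["age_c"] = d[spec.age_col] - spec.age_center
    # numeric checks for a clean rank-deficiency diagnosis
    for c in (spec.response, "age_c", *spec.covariates):
        if np.asarray(d[c], dtype=float).std() == 0:
            raise ValueError(
                f"design is rank deficient: column '{c}' is constant; "
                "drop it from the model"
            )
    return d


def fit_rate_ancova(df: pd.DataFrame, spec: AncovaSpec) -> AncovaResult:
    """Full-factorial ANCOVA: response ~ sex * age + covariates.

    Sex is sum-to-zero coded and age centered, so the main effects are
    interpretable in the presence of the interaction; effect tests are
    type-III partial F tests.  Complete cases only; deterministic.
    """
    d = _prepare(df, spec)
    n_params = 4 + len(spec.covariates)  # intercept, sex, age, sex:age + covs
    if len(d) <= n_params:
        raise ValueError("more parameters than observations")
    cov_terms = " + ".join(spec.covariates)
    formula = f"{spec.response} ~ C({spec.sex_col}, Sum) * age_c"
    if cov_terms:
        formula += " + " + cov_terms
    fit = smf.ols(formula, data=d).fit()
    aov = sm.stats.anova_lm(fit, typ=3)
    effects = pd.DataFrame(
        {
            "F": aov["F"],
            "df": aov["df"],
            "p": aov["PR(>F)"],
        }
    )
    rename = {
        f"C({spec.sex_col}, Sum)": "sex",
        "age_c": "age",
        f"C({spec.sex_col}, Sum):age_c": "sex:age",
    }
    effects = effects.rename(index=rename)
    return AncovaResult(
        params=fit.params, bse=fit.bse, effects=effects, n=len(d), model=fit
    )


@dataclass
class QuadraticAgeFit:
    """Linear and quadratic-in-age fits of a baseline volume."""

    beta0: float
    beta1: float  # per year of (centered) age
    beta2: float  # per year^2
    beta2_se: float
    beta2_p: float
    linear_beta1: float
    linear_beta1_se: float
    linear_beta1_p: float
    covariate_params: pd.Series = field(default_factory=pd.Series)
    n: int = 0


def fit_quadratic_age(df: pd.DataFrame, spec: AncovaSpec) -> QuadraticAgeFit:
    """Baseline-volume age model with and without a quadratic term.

    Fits response ~ sex*age + covariates (linear) and the same plus age^2
    (quadratic, on centered age), and tests the quadratic coefficient
    against zero.
    """
    d = _prepare(df, spec)
    d["age_c2"] = d["age_c"] ** 2
    cov_terms = " + ".join(spec.covariates)
    base = f"{spec.response} ~ C({spec.sex_col}, Sum) * age_c"
    if cov_terms:
        base += " + " + cov_terms
    lin = smf.ols(base, data=d).fit()
    quad = smf.ols(base + " + age_c2", data=d).fit()
    return QuadraticAgeFit(
        beta0=float(quad.params["Intercept"]),
        beta1=float(quad.params["age_c"]),
        beta2=float(quad.params["age_c2"]),
        beta2_se=float(quad.bse["age_c2"]),
        beta2_p=float(quad.pvalues["age_c2"]),
        linear_beta1=float(lin.params["age_c"]),
        linear_beta1_se=float(lin.bse["age_c"]),
        linear_beta1_p=float(lin.pvalues["age_c"]),
        covariate_params=quad.params[list(spec.covariates)],
        n=len(d),
    )


# --------------------------------------------------------------------------
# voxelwise GLM with FWE control
# --------------------------------------------------------------------------

@dataclass
class FweMapResult:
    stat_map: np.ndarray  # t per voxel (masked voxels only, or full grid)
    corrected_threshold: float
    suprathreshold: np.ndarray  # boolean, same layout as stat_map
    corrected_p: np.ndarray
    mode: str
    n_perm: int | None
    seed: int | None
    mask: np.ndarray | None = None


def _tstats(Y: np.ndarray, X: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Contrast t-statistic per column of Y for design X."""
    n, p = X.shape
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    res = Y - X @ beta
    dof = n - p
    sigma2 = (res**2).sum(axis=0) / dof
    cvc = float(c @ np.linalg.inv(X.T @ X) @ c)
    se = np.sqrt(np.maximum(sigma2 * cvc, 1e-300))
    return (c @ beta) / se


def voxelwise_glm_fwe(
    maps,
    design: np.ndarray | pd.DataFrame,
    contrast,
    alpha: float = 0.05,
    mode: str = "permutation",
    n_perm: int = 1000,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> FweMapResult:
    """Voxelwise GLM contrast with family-wise error control.

    ``maps`` is an (n_subjects, n_voxels) array, or a list of BrainImage
    (flattened through ``mask`` when given).  FWE modes:

    * ``permutation`` — max-|t| null by Freedman-Lane: the reduced model
      (contrast columns removed) is fitted, its residuals are permuted
      (sign-flipped when the reduced model is empty, i.e. a one-sample
      test), and the full-model |t| is recomputed; the corrected p of a
      voxel is the rank of its |t| in the max-null.
    * ``bonferroni`` — parametric two-sided p times the voxel count.
    """
    imgs = None
    if isinstance(maps, (list, tuple)) and isinstance(maps[0], BrainImage):
        imgs = maps
        if mask is None:
            mask = np.ones(imgs[0].shape, dtype=bool)
        Y = np.stack([im.data[mask].astype(np.float64) for im in imgs])
    else:
        Y = np.asarray(maps, dtype=np.float64)
        if mask is not None and Y.ndim > 2:
            Y = Y.reshape(Y.shape[0], -1)[:, np.asarray(mask).ravel()]
    if Y.size == 0 or Y.shape[1] == 0:
        raise ValueError("analysis mask is empty")
    X = np.asarray(design, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    c = np.asarray(contrast, dtype=np.float64).reshape(-1)
    n, V = Y.shape
    t_obs = _tstats(Y, X, c)

    if mode == "bonferroni":
        dof = n - X.shape[1]
        p_unc = 2 * sps.t.sf(np.abs(t_obs), dof)
        p_corr = np.minimum(p_unc * V, 1.0)
        thr = sps.t.isf(alpha / (2 * V), dof)
        supra = np.abs(t_obs) >= thr
        return FweMapResult(t_obs, float(thr), supra, p_corr, mode, None, None, mask)
    if mode != "permutation":
        raise ValueError("mode must be 'permutation' or 'bonferroni'")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")

    rng = np.random.default_rng(seed)
    keep = np.abs(c) > 0
    Z = X[:, ~keep]  # reduced model
    if Z.shape[1] > 0:
        pinvZ = np.linalg.pinv(Z)
        gamma = pinvZ @ Y
        Yhat_red = Z @ gamma
        res_red = Y - Yhat_red
    else:
        Yhat_red = np.zeros_like(Y)
        res_red = Y

    max_null = np.empty(n_perm)
    for b in range(n_perm):
        if Z.shape[1] > 0:
            perm = rng.permutation(n)
            Ystar = Yhat_red + res_red[perm]
        else:
            signs = rng.choice([-1.0, 1.0], size=n)
            Ystar = signs[:, None] * res_red
        tb = _tstats(Ystar, X, c)
        max_null[b] = np.abs(tb).max()

    abs_t = np.abs(t_obs)
    p_corr = (1 + (max_null[None, :] >= abs_t[:, None]).sum(axis=1)) / (n_perm + 1)
    thr = float(np.quantile(max_null, 1 - alpha))
    supra = abs_t >= thr
    return FweMapResult(t_obs, thr, supra, p_corr, mode, n_perm, seed, mask)


# --------------------------------------------------------------------------
# shifting-window slope
# --------------------------------------------------------------------------

@dataclass
class WindowSlope:
    window_slope: float  # cm^3 / yr from adjacent-bin mean differences
    window_se: float
    ols_slope: float
    ols_se: float
    bin_centers: np.ndarray
    bin_means: np.ndarray
    bin_counts: np.ndarray
    skipped_bins: list


def shifting_window_slope(
    volumes: np.ndarray, ages: np.ndarray, window_years: float = 1.0
) -> WindowSlope:
    """Cross-sectional slope from consecutive fixed-width age windows.

    Bins the cohort into ``window_years``-wide age windows, averages the
    volume per window, and estimates the slope as the mean of adjacent-bin
    differences (scaled by the bin-centre gap when interior bins are empty
    and skipped).  The ordinary least-squares slope is returned alongside
    for the attenuation comparison.
    """
    volumes = np.asarray(volumes, dtype=float)
    ages = np.asarray(ages, dtype=float)
    lo = np.floor(ages.min())
    edges = np.arange(lo, ages.max() + window_years, window_years)
    idx = np.clip(np.digitize(ages, edges) - 1, 0, len(edges) - 1)
    centers, means, counts, skipped = [], [], [], []
    for b in range(len(edges)):
        m = idx == b
        if m.sum() == 0:
            if 0 < b < len(edges) - 1:
                skipped.append(float(edges[b] + window_years / 2))
            continue
        centers.append(edges[b] + window_years / 2)
        means.append(volumes[m].mean())
        counts.append(int(m.sum()))
    if len(means) < 2:
        raise ValueError("need at least 2 non-empty age windows")
    centers = np.asarray(centers)
    means = np.asarray(means)
    gaps = np.diff(centers)
    diffs = np.diff(means) / gaps  # per-year differences across adjacent bins
    w_slope = float(diffs.mean())
    w_se = float(diffs.std(ddof=1) / np.sqrt(len(diffs))) if len(diffs) > 1 else float("nan")

    X = sm.add_constant(ages)
    ols = sm.OLS(volumes, X).fit()
    return WindowSlope(
        window_slope=w_slope, window_se=w_se,
        ols_slope=float(ols.params[1]), ols_se=float(ols.bse[1]),
        bin_centers=centers, bin_means=means,
        bin_counts=np.asarray(counts), skipped_bins=skipped,
    )


# --------------------------------------------------------------------------
# matched-subsample comparison
# --------------------------------------------------------------------------

@dataclass
class MatchedComparison:
    effect: float  # mean(group1) - mean(group0) on the response, post-match
    se: float
    p: float
    n_treated: int
    n_control: int
    smd_post: dict  # standardized mean differences after matching
    matched_index: pd.Index


def matched_subsample_compare(
    df: pd.DataFrame,
    response: str,
    group_flag: str,
    matching_vars=("age", "hypertension", "education_years"),
    caliper_sd: float = 0.25,
    max_ratio: int = 2,
    seed: int = 0,
) -> MatchedComparison:
    """Greedy caliper matching, then the group effect on the response.

    Subjects with ``group_flag`` == 1 are matched to unused controls whose
    standardized matching variables all lie within ``caliper_sd`` SD; up to
    ``max_ratio`` controls per treated subject.  Fails if fewer than 10
    matched treated subjects remain or any post-match standardized mean
    difference reaches 0.1.
    """
    d = df.dropna(subset=[response, group_flag, *matching_vars]).copy()
    g = d[group_flag].astype(int).to_numpy()
    if g.sum() == 0 or (1 - g).sum() == 0:
        raise ValueError("both groups must be non-empty")
    X = d[list(matching_vars)].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd

    rng = np.random.default_rng(seed)
    treated = np.flatnonzero(g == 1)
    controls = set(np.flatnonzero(g == 0))
    order = rng.permutation(len(treated))
    matched_t, matched_c = [], []
    for _ in range(max_ratio):
        newly = []
        for ti in treated[order]:
            best, best_d = None, np.inf
            for ci in controls:
                dvec = np.abs(Z[ti] - Z[ci])
                if (dvec <= caliper_sd).all():
                    dist = float((dvec**2).sum())
                    if dist < best_d:
                        best, best_d = ci, dist
            if best is not None:
                controls.discard(best)
                newly.append((ti, best))
        matched_t.extend(t for t, _ in newly)
        matched_c.extend(c for _, c in newly)
        if not newly:
            break
    t_ids = sorted(set(matched_t))
    if len(t_ids) < 10:
        raise ValueError(f"matching left only {len(t_ids)} treated subjects (<10)")
    rows = np.array(t_ids + matched_c)
    sub = d.iloc[rows]
    gsub = sub[group_flag].astype(int)

    smd = {}
    for j, v in enumerate(matching_vars):
        m1 = sub.loc[gsub == 1, v].mean()
        m0 = sub.loc[gsub == 0, v].mean()
        smd[v] = float((m1 - m0) / sd[j])
    worst = max(abs(x) for x in smd.values())
    if worst >= 0.1:
        raise ValueError(
            f"post-match imbalance too large (max |SMD| = {worst:.3f} >= 0.1)"
        )

    y1 = sub.loc[gsub == 1, response].to_numpy(dtype=float)
    y0 = sub.loc[gsub == 0, response].to_numpy(dtype=float)
    effect = float(y1.mean() - y0.mean())
    se = float(np.sqrt(y1.var(ddof=1) / len(y1) + y0.var(ddof=1) / len(y0)))
    tt = sps.ttest_ind(y1, y0, equal_var=False)
    return MatchedComparison(
        effect=effect, se=se, p=float(tt.pvalue),
        n_treated=len(y1), n_control=len(y0),
        smd_post=smd, matched_index=sub.index,
    )
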