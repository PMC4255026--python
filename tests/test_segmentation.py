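"""EM tissue classification, intensity model, fraction unmixing, ICV scheme."""

import numpy as np
import pandas as pd
import pytest

from longvbm import (
    CohortDesign,
    compute_intracranial,
    generate_cohort,
    optimized_csf,
    sample_cohort_covariates,
    segment_tissues,
    simulate_subject_pair,
)
from longvbm.image import BrainImage, default_affine
from longvbm.segmentation import (
    PriorSet,
    TissueMaps,
    build_priors,
    estimate_tissue_fractions,
    fit_intensity_model,
    select_matched_subsample,
)


def _truth_labels(template):
    tp = template.tissue_priors
    stack = np.stack(
        [1 - (tp["gm"].data + tp["wm"].data + tp["csf"].data),
         tp["gm"].data, tp["wm"].data, tp["csf"].data]
    )
    return np.argmax(stack, axis=0)


def _dice(a, b):
    return 2 * (a & b).sum() / max(a.sum() + b.sum(), 1)


def _subject_images(template, **design_kw):
    design = CohortDesign(n_subjects=1, seed=1, **design_kw)
    rec = sample_cohort_covariates(design)[0]
    return simulate_subject_pair(template, rec, design, 11)


class TestSegmentTissues:
    def test_loglik_monotone_and_posteriors_normalized(self, template, priors):
        t1b, t2b, *_ = _subject_images(template)
        tm = segment_tissues([t1b, t2b], priors, mode="multi")
        ll = np.array(tm.log_likelihood)
        assert (np.diff(ll) >= -1e-6 * np.abs(ll[:-1])).all()
        total = tm.gm.data + tm.wm.data + tm.csf.data
        assert total.max() <= 1 + 1e-6 and total.min() >= -1e-6

    def test_noise_free_hard_labels_match_truth(self, template):
        """With well-separated contrasts (hard-edged tissue regions, no
        partial volume) the EM hard labels reproduce the generating tissue
        at Dice > 0.95 per tissue."""
        truth = _truth_labels(template)
        ct = template.contrast_table
        onehot = [(truth == k).astype(np.float32) for k in range(4)]
        aff = template.affine
        chans = []
        for ch in ("t1", "t2"):
            mus = [ct[ch]["bg"], ct[ch]["gm"], ct[ch]["wm"], ct[ch]["csf"]]
            chans.append(BrainImage(
                sum(m * o for m, o in zip(mus, onehot)), aff))
        hard_priors = PriorSet(
            BrainImage(onehot[1], aff), BrainImage(onehot[2], aff),
            BrainImage(onehot[3], aff),
        )
        tm = segment_tissues(chans, hard_priors, mode="multi")
        lab = tm.hard_labels()
        for k, name in ((1, "gm"), (2, "wm"), (3, "csf")):
            assert _dice(truth == k, lab == k) > 0.95, name

    def test_uniform_priors_bayes_posterior_on_toy_lattice(self):
        """Three well-separated intensity blocks under flat priors: the EM
        posteriors must equal the hand-computed Bayes rule, which is a hard
        assignment of each block to its own class."""
        vals = (0.1, 0.4, 0.6, 0.9)
        data = np.zeros((12, 12, 12), np.float32)
        data[:3], data[3:6], data[6:9], data[9:] = vals
        img = BrainImage(data, default_affine(data.shape, 1.0))
        flat = BrainImage(np.full(data.shape, 0.25, np.float32), img.affine)
        priors = PriorSet(flat, flat, flat)
        tm = segment_tissues(img, priors, mode="mono")
        post = np.stack([tm.gm.data, tm.wm.data, tm.csf.data,
                         1 - tm.gm.data - tm.wm.data - tm.csf.data])
        # hand-computed Bayes rule: with flat priors and four separated
        # intensities, each block is claimed entirely by one class
        winners = set()
        for sl in (slice(0, 3), slice(3, 6), slice(6, 9), slice(9, None)):
            block = post[:, sl].reshape(4, -1)
            winner = int(block.mean(axis=1).argmax())
            winners.add(winner)
            assert block[winner].min() > 0.999
        assert len(winners) == 4  # a distinct class per intensity

    def test_constant_image_returns_priors(self, template, priors):
        img = BrainImage(np.full(template.shape, 0.5, np.float32),
                         template.affine)
        tm = segment_tissues(img, priors, mode="mono")
        bg = np.clip(1 - priors.gm.data - priors.wm.data - priors.csf.data,
                     1e-6, 1)
        norm = priors.gm.data + priors.wm.data + priors.csf.data + bg
        assert np.allclose(tm.gm.data, priors.gm.data / norm, atol=1e-3)

    def test_grid_mismatch_rejected(self, template, priors):
        img = BrainImage(np.zeros((24, 24, 24), np.float32))
        with pytest.raises(ValueError):
            segment_tissues(img, priors)

    def test_mode_validated(self, template_t1, priors):
        with pytest.raises(ValueError):
            segment_tissues(template_t1, priors, mode="dual")


class TestIntensityModelAndFractions:
    def test_model_recovers_contrast_table(self, template, priors):
        t1b, t2b, *_ = _subject_images(
            template, noise_frac=0.0, bias_coef_sd=0.0,
            rigid_rot_max_deg=0.0, rigid_trans_max_mm=0.0,
            subject_rate_sd=0.0, parcel_rate_sd=0.0,
        )
        m = fit_intensity_model([t1b, t2b], priors)
        ct = template.contrast_table
        expected = np.array([[ct["t1"][t], ct["t2"][t]]
                             for t in ("gm", "wm", "csf", "bg")])
        assert np.abs(np.asarray(m["mu"]) - expected).max() < 1e-3

    def test_fractions_exact_on_synthetic_mixture(self):
        """Unmixing is the exact inverse of mixture composition inside the
        brain (two channels + sum-to-one = three tissue fractions)."""
        rng = np.random.default_rng(0)
        shape = (10, 10, 10)
        f = rng.dirichlet([2, 2, 2], size=np.prod(shape))  # gm, wm, csf
        mu = np.array([[0.7, 0.55], [1.0, 0.4], [0.25, 1.0], [0.02, 0.02]])
        y = f @ mu[:3]
        aff = default_affine(shape, 1.0)
        chans = [BrainImage(y[:, c].reshape(shape).astype(np.float32), aff)
                 for c in range(2)]
        pri = PriorSet(
            *(BrainImage(f[:, i].reshape(shape).astype(np.float32), aff)
              for i in range(3))
        )
        tm = estimate_tissue_fractions(
            chans, pri, {"classes": ("gm", "wm", "csf", "bg"), "mu": mu}
        )
        est = np.stack([tm.gm.data.ravel(), tm.wm.data.ravel(),
                        tm.csf.data.ravel()], axis=1)
        assert np.abs(est - f).max() < 2e-3  # float32 image storage

    def test_fraction_unmixing_needs_two_channels(self, template_t1, priors):
        with pytest.raises(ValueError):
            estimate_tissue_fractions(template_t1, priors, {"mu": np.eye(4)})


class TestMatchedSubsample:
    @pytest.fixture()
    def cov(self):
        recs = sample_cohort_covariates(CohortDesign(n_subjects=200, seed=9))
        return pd.DataFrame(
            [{"subject_id": r.subject_id, "sex": r.sex, "age": r.age,
              "hypertension": int(r.hypertension),
              "education_years": r.education_years} for r in recs]
        )

    def test_means_match_cohort(self, cov):
        sel = select_matched_subsample(cov, n_per_sex=30)
        for sex in ("M", "F"):
            full = cov[cov.sex == sex]
            sub = sel[sel.sex == sex]
            assert len(sub) == 30
            d = abs(sub.age.mean() - full.age.mean()) / cov.age.std(ddof=1)
            assert d < 0.25

    def test_deterministic(self, cov):
        a = select_matched_subsample(cov, 20, seed=5)
        b = select_matched_subsample(cov, 20, seed=5)
        assert list(a.subject_id) == list(b.subject_id)

    def test_too_few_subjects_rejected(self, cov):
        n_men = (cov.sex == "M").sum()
        with pytest.raises(ValueError, match="cannot draw"):
            select_matched_subsample(cov, n_per_sex=n_men + 1)


def test_build_priors_self_consistency(template, tmp_path):
    """Priors built from a noise-free cohort generated from the template
    correlate with the template's own priors at r > 0.95 per tissue."""
    design = CohortDesign(
        n_subjects=6, seed=2, noise_frac=0.0, bias_coef_sd=0.0,
        rigid_rot_max_deg=0.0, rigid_trans_max_mm=0.0,
        subject_rate_sd=0.0, parcel_rate_sd=0.0,
    )
    generate_cohort(template, design, tmp_path / "c")
    ps = build_priors(tmp_path / "c", template, n_per_sex=2, seed=0)
    for t in ("gm", "wm", "csf"):
        a = ps.as_dict()[t].data.ravel().astype(np.float64)
        b = template.tissue_priors[t].data.ravel().astype(np.float64)
        r = np.corrcoef(a, b)[0, 1]
        assert r > 0.95, t


class TestIntracranial:
    def _tm(self, gm, wm, csf, aff):
        mk = lambda a: BrainImage(a.astype(np.float32), aff)
        return TissueMaps(mk(gm), mk(wm), mk(csf), provenance="multi")

    def test_identical_sessions_idempotent(self, template, priors):
        t1b, t2b, *_ = _subject_images(template)
        tm = segment_tissues([t1b, t2b], priors, mode="multi")
        icv = compute_intracranial(tm, tm)
        assert np.array_equal(icv.common.data, icv.session_base.data)

    def test_subset_session_wins(self):
        aff = default_affine((16, 16, 16), 1.0)
        a = np.zeros((16, 16, 16))
        a[2:14, 2:14, 2:14] = 1.0
        b = np.zeros_like(a)
        b[4:12, 4:12, 4:12] = 1.0
        icv = compute_intracranial(
            self._tm(a, 0 * a, 0 * a, aff), self._tm(b, 0 * b, 0 * b, aff)
        )
        assert np.array_equal(icv.common.data, icv.session_follow.data)

    def test_intersection_bounded_by_sessions(self):
        rng = np.random.default_rng(4)
        aff = default_affine((12, 12, 12), 1.0)
        a = (rng.random((12, 12, 12)) > 0.4).astype(float)
        b = (rng.random((12, 12, 12)) > 0.4).astype(float)
        icv = compute_intracranial(
            self._tm(a, 0 * a, 0 * a, aff), self._tm(b, 0 * b, 0 * b, aff)
        )
        n = icv.common.data.sum()
        assert n <= min(a.sum(), b.sum())
        assert n == (a.astype(bool) & b.astype(bool)).sum()

    def test_empty_intersection_rejected(self):
        aff = default_affine((8, 8, 8), 1.0)
        a = np.zeros((8, 8, 8)); a[:2] = 1.0
        b = np.zeros((8, 8, 8)); b[6:] = 1.0
        with pytest.raises(ValueError, match="empty"):
            compute_intracranial(
                self._tm(a, 0 * a, 0 * a, aff), self._tm(b, 0 * b, 0 * b, aff)
            )


class TestOptimizedCsf:
    def test_csf_zero_when_tissue_fills_mask(self):
        aff = default_affine((8, 8, 8), 1.0)
        gm = np.full((8, 8, 8), 0.6, np.float32)
        wm = np.full((8, 8, 8), 0.4, np.float32)
        mk = lambda a: BrainImage(np.asarray(a, np.float32), aff)
        tm = TissueMaps(mk(gm), mk(wm), mk(np.zeros_like(gm)))
        icv = compute_intracranial(tm, tm)
        out = optimized_csf(icv, tm)
        assert np.allclose(out.csf.data, 0.0, atol=1e-6)
        assert np.array_equal(out.gm.data, tm.gm.data)  # GM passes through

    def test_all_csf_ball_closed_form(self):
        aff = default_affine((16, 16, 16), 1.0)
        ball = np.zeros((16, 16, 16), np.float32)
        ball[4:12, 4:12, 4:12] = 1.0
        mk = lambda a: BrainImage(np.asarray(a, np.float32), aff)
        z = np.zeros_like(ball)
        tm = TissueMaps(mk(z), mk(z), mk(ball))
        icv = compute_intracranial(tm, tm)
        out = optimized_csf(icv, TissueMaps(mk(z), mk(z), mk(z)))
        assert out.csf.data.sum() == ball.sum()

    def test_tiv_bounding_invariant(self, template, priors):
        """Common-mask TIV never exceeds either session's own volume."""
        t1b, t2b, t1f, t2f, _ = _subject_images(template)
        tb = segment_tissues([t1b, t2b], priors, mode="multi")
        tf = segment_tissues([t1f, t2f], priors, mode="multi")
        icv = compute_intracranial(tb, tf)
        common = icv.common.data.sum()
        assert common <= icv.session_base.data.sum()
        assert common <= icv.session_follow.data.sum()
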