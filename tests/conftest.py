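"""Shared fixtures: one small phantom template and derived objects."""

import numpy as np
import pytest

from longvbm import CohortDesign, build_phantom_template, sample_cohort_covariates
from longvbm.image import BrainImage
from longvbm.phantom import DEFAULT_CONTRAST
from longvbm.segmentation import PriorSet


@pytest.fixture(scope="session")
def template():
    return build_phantom_template(shape=(48, 48, 48), voxel_size_mm=1.0,
                                  n_parcels=12, seed=7)


@pytest.fixture(scope="session")
def priors(template):
    return PriorSet.from_template(template)


@pytest.fixture(scope="session")
def template_t1(template):
    """Noise-free synthetic T1 of the template (priors mixed with contrasts)."""
    tp = template.tissue_priors
    mu = DEFAULT_CONTRAST["t1"]
    bg = np.clip(1 - tp["gm"].data - tp["wm"].data - tp["csf"].data, 0, 1)
    data = (mu["gm"] * tp["gm"].data + mu["wm"] * tp["wm"].data
            + mu["csf"] * tp["csf"].data + mu["bg"] * bg)
    return BrainImage(data, template.affine)


@pytest.fixture()
def clean_design(template):
    """All nuisances off, fixed per-parcel rates, no jitter."""
    return CohortDesign(
        n_subjects=2, seed=1, noise_frac=0.0, bias_coef_sd=0.0,
        rigid_rot_max_deg=0.0, rigid_trans_max_mm=0.0,
        subject_rate_sd=0.0, parcel_rate_sd=0.0,
    )


@pytest.fixture()
def clean_records(clean_design):
    return sample_cohort_covariates(clean_design)
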