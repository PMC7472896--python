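"""Shared fixtures: small deterministic synthetic grids and cohorts."""
import numpy as np
import pytest

import lesionparc as lp


@pytest.fixture(scope="session")
def small_mask():
    """~2.7k-voxel ellipsoidal mask at 4 mm."""
    return lp.default_brain_mask((20, 24, 20), 4.0)


@pytest.fixture(scope="session")
def small_atlas(small_mask):
    vol = small_mask.volume
    tree, atlas = lp.make_vascular_atlas(
        vol.grid_shape, vol.affine, small_mask, 8, seed=1
    )
    return tree, atlas


@pytest.fixture(scope="session")
def small_cohort(small_mask, small_atlas):
    """40-patient abnormality cohort with default study conditions."""
    tree, atlas = small_atlas
    lesions = lp.simulate_patient_lesions(
        tree, atlas, lp.CohortSpec(n_patients=40, seed=2)
    )
    return lesions


@pytest.fixture(scope="session")
def small_matrix(small_mask, small_cohort):
    return lp.assemble_lesion_matrix(small_cohort, small_mask)


@pytest.fixture(scope="session")
def small_binary_matrix(small_mask, small_cohort):
    binary = [
        v.with_data((np.asarray(v.data) > 0.5).astype(np.uint8), role="binary")
        for v in small_cohort
    ]
    return lp.assemble_lesion_matrix(binary, small_mask, center=False)
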