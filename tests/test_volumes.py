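"""Imaging data model: I/O, smoothing, abnormality maps, binarisation,
clusters and geometry."""
import numpy as np
import pytest
from scipy.stats import norm

import lesionparc as lp
from lesionparc.volumes import FWHM_TO_SIGMA, Volume


def _random_affine():
    return np.diag([2.0, 2.0, 2.5, 1.0])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("dtype", [np.float32, np.uint8])
def test_nifti_round_trip_bit_exact(tmp_path, dtype):
    rng = np.random.default_rng(0)
    data = (rng.random((8, 8, 8)) * 10).astype(dtype)
    affine = np.diag([1.0, 2.0, 3.0, 1.0])
    affine[:3, 3] = [-4, -8, -12]
    vol = Volume(data, affine)
    path = tmp_path / "v.nii.gz"
    lp.write_volume(vol, path)
    back = lp.read_volume(path)
    assert back.grid_shape == (8, 8, 8)
    np.testing.assert_array_equal(back.data, data)
    np.testing.assert_allclose(back.affine, affine)


def test_read_rejects_4d(tmp_path):
    import nibabel as nib

    img = nib.Nifti1Image(np.zeros((4, 4, 4, 2), dtype=np.float32), np.eye(4))
    nib.save(img, tmp_path / "v4.nii")
    with pytest.raises(ValueError, match="4 dim"):
        lp.read_volume(tmp_path / "v4.nii")


def test_volume_invariants():
    with pytest.raises(ValueError, match="3-D"):
        Volume(np.zeros((4, 4)), np.eye(4))
    with pytest.raises(ValueError, match="invertible"):
        Volume(np.zeros((4, 4, 4)), np.diag([1, 1, 0, 1]))
    with pytest.raises(ValueError, match="abnormality"):
        Volume(np.full((4, 4, 4), 1.5), np.eye(4), "abnormality")
    with pytest.raises(ValueError, match="binary"):
        Volume(np.full((4, 4, 4), 2.0), np.eye(4), "binary")


# ---------------------------------------------------------------------------
# Gaussian smoothing
# ---------------------------------------------------------------------------

def test_smooth_fwhm_zero_is_identity():
    rng = np.random.default_rng(1)
    vol = Volume(rng.random((10, 10, 10)), _random_affine())
    out = lp.gaussian_smooth(vol, 0.0)
    np.testing.assert_array_equal(out.data, vol.data)


def test_smooth_constant_unchanged():
    vol = Volume(np.full((12, 12, 12), 3.7), _random_affine())
    out = lp.gaussian_smooth(vol, 8.0)
    np.testing.assert_allclose(out.data, 3.7, atol=1e-9)


def test_smooth_impulse_matches_gaussian_closed_form():
    """Unit impulse at 1-mm voxels, FWHM 8 -> separable normal density."""
    n = 41
    data = np.zeros((n, n, n))
    c = n // 2
    data[c, c, c] = 1.0
    vol = Volume(data, np.eye(4))
    out = lp.gaussian_smooth(vol, 8.0)
    sigma = 8.0 / FWHM_TO_SIGMA
    # independent closed form: product of discretised 1-D normal densities
    for offset in [(0, 0, 0), (3, 0, 0), (2, 2, 1), (0, 5, 4)]:
        expected = np.prod([norm.pdf(d, scale=sigma) for d in offset])
        got = out.data[c + offset[0], c + offset[1], c + offset[2]]
        assert abs(got - expected) < 1e-6


def test_smooth_preserves_total_sum():
    rng = np.random.default_rng(2)
    vol = Volume(rng.random((16, 14, 12)), _random_affine())
    out = lp.gaussian_smooth(vol, 10.0)
    assert abs(out.data.sum() - vol.data.sum()) < 1e-6 * vol.data.sum()


def test_smooth_commutes_with_interior_translation():
    rng = np.random.default_rng(3)
    data = np.zeros((24, 24, 24))
    data[8:14, 8:14, 8:14] = rng.random((6, 6, 6))
    vol = Volume(data, np.eye(4))
    shifted = Volume(np.roll(data, 1, axis=0), np.eye(4))
    a = lp.gaussian_smooth(vol, 4.0).data
    b = lp.gaussian_smooth(shifted, 4.0).data
    np.testing.assert_allclose(np.roll(a, 1, axis=0)[4:20, 4:20, 4:20],
                               b[4:20, 4:20, 4:20], atol=1e-9)


def test_smooth_negative_fwhm_rejected():
    vol = Volume(np.zeros((4, 4, 4)), np.eye(4))
    with pytest.raises(ValueError):
        lp.gaussian_smooth(vol, -1.0)


# ---------------------------------------------------------------------------
# Abnormality maps
# ---------------------------------------------------------------------------

def _controls(rng, shape=(6, 6, 6), n=5, affine=None):
    affine = np.eye(4) if affine is None else affine
    return [Volume(rng.random(shape) + 2.0, affine) for _ in range(n)]


def test_abnormality_zero_at_control_mean():
    rng = np.random.default_rng(4)
    controls = _controls(rng)
    mean = np.mean([c.data for c in controls], axis=0)
    patient = Volume(mean, np.eye(4))
    abn = lp.abnormality_from_controls(patient, controls)
    np.testing.assert_allclose(abn.data, 0.0, atol=1e-12)


def test_abnormality_known_deviations():
    """1-sigma and 2-sigma deviations give 2*Phi(z)-1 = 0.6827 / 0.9545."""
    rng = np.random.default_rng(5)
    controls = _controls(rng)
    stack = np.stack([c.data for c in controls])
    mu, sd = stack.mean(0), stack.std(0, ddof=1)
    patient_data = mu.copy()
    patient_data[0, 0, 0] += 1.0 * sd[0, 0, 0]
    patient_data[1, 1, 1] += 2.0 * sd[1, 1, 1]
    patient_data[2, 2, 2] -= 10.0 * sd[2, 2, 2]
    abn = lp.abnormality_from_controls(Volume(patient_data, np.eye(4)), controls)
    assert abs(abn.data[0, 0, 0] - 0.6826894921) < 1e-6
    assert abs(abn.data[1, 1, 1] - 0.9544997361) < 1e-6
    assert abn.data[2, 2, 2] > 0.999
    assert abn.data[1, 1, 1] > abn.data[0, 0, 0]


def test_abnormality_shift_invariant():
    rng = np.random.default_rng(6)
    controls = _controls(rng)
    patient = Volume(rng.random((6, 6, 6)) + 2.0, np.eye(4))
    a = lp.abnormality_from_controls(patient, controls)
    shifted_controls = [Volume(c.data + 5.0, np.eye(4)) for c in controls]
    b = lp.abnormality_from_controls(
        Volume(patient.data + 5.0, np.eye(4)), shifted_controls
    )
    np.testing.assert_allclose(a.data, b.data, atol=1e-9)


def test_abnormality_requires_three_controls():
    rng = np.random.default_rng(7)
    controls = _controls(rng, n=2)
    with pytest.raises(ValueError, match="3 control"):
        lp.abnormality_from_controls(controls[0], controls)


# ---------------------------------------------------------------------------
# Binarisation
# ---------------------------------------------------------------------------

def _flood_fill_components(mask, connectivity=26):
    """Independent oracle: BFS connected components with explicit offsets."""
    offs = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                order = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((di, dj, dk))
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    coords = np.argwhere(mask)
    mask_set = set(map(tuple, coords))
    for start in map(tuple, coords):
        if seen[start]:
            continue
        comp = []
        stack = [start]
        seen[start] = True
        while stack:
            cur = stack.pop()
            comp.append(cur)
            for o in offs:
                nxt = (cur[0] + o[0], cur[1] + o[1], cur[2] + o[2])
                if nxt in mask_set and not seen[nxt]:
                    seen[nxt] = True
                    stack.append(nxt)
        comps.append(comp)
    return comps


def test_binarize_empty_map():
    abn = Volume(np.zeros((8, 8, 8)), np.eye(4), "abnormality")
    out = lp.binarize_lesion(abn)
    assert out.data.sum() == 0


@pytest.mark.parametrize("n_vox,survives", [(100, False), (101, True)])
def test_binarize_extent_rule_is_strict(n_vox, survives):
    """A cluster of exactly 100 voxels is removed; 101 survive."""
    data = np.zeros((30, 30, 30))
    flat = np.unravel_index(np.arange(n_vox), (5, 5, 5))
    data[flat[0] + 2, flat[1] + 2, flat[2] + 2] = 0.6
    abn = Volume(data, np.eye(4), "abnormality")
    out = lp.binarize_lesion(abn)
    assert (out.data.sum() > 0) == survives
    if survives:
        assert out.data.sum() == n_vox


def test_binarize_matches_flood_fill_oracle():
    rng = np.random.default_rng(8)
    data = (rng.random((14, 14, 14)) < 0.35) * 0.8
    abn = Volume(data, np.eye(4), "abnormality")
    cfg = lp.LesionIdentificationConfig(min_cluster_voxels=4, connectivity=26)
    out = lp.binarize_lesion(abn, cfg)
    comps = _flood_fill_components(data > 0.5, 26)
    expected = np.zeros((14, 14, 14), dtype=bool)
    for comp in comps:
        if len(comp) > 4:
            for c in comp:
                expected[c] = True
    np.testing.assert_array_equal(out.data.astype(bool), expected)


def test_binarize_idempotent():
    rng = np.random.default_rng(9)
    data = (rng.random((12, 12, 12)) < 0.4) * 0.9
    abn = Volume(data, np.eye(4), "abnormality")
    cfg = lp.LesionIdentificationConfig(min_cluster_voxels=2)
    once = lp.binarize_lesion(abn, cfg)
    twice = lp.binarize_lesion(
        Volume(once.data.astype(float), np.eye(4), "abnormality"), cfg
    )
    np.testing.assert_array_equal(once.data, twice.data)


# ---------------------------------------------------------------------------
# Overlap maps
# ---------------------------------------------------------------------------

def test_overlap_identical_and_disjoint():
    a = Volume((np.arange(64).reshape(4, 4, 4) < 10).astype(np.uint8),
               np.eye(4), "binary")
    b = Volume((np.arange(64).reshape(4, 4, 4) >= 54).astype(np.uint8),
               np.eye(4), "binary")
    same = lp.overlap_map([a, a])
    assert same.data.max() == 2
    assert np.array_equal(same.data > 0, a.data > 0)
    disjoint = lp.overlap_map([a, b])
    assert disjoint.data.max() == 1


def test_overlap_matches_loop_oracle():
    rng = np.random.default_rng(10)
    vols = [
        Volume((rng.random((6, 6, 6)) < 0.5).astype(np.uint8), np.eye(4), "binary")
        for _ in range(5)
    ]
    out = lp.overlap_map(vols)
    expected = np.zeros((6, 6, 6), dtype=int)
    for v in vols:
        for idx in np.ndindex(6, 6, 6):
            expected[idx] += int(v.data[idx])
    np.testing.assert_array_equal(out.data, expected)


# ---------------------------------------------------------------------------
# Cluster extraction
# ---------------------------------------------------------------------------

def test_extract_single_voxel_cluster_com():
    data = np.zeros((10, 10, 10))
    data[3, 4, 5] = 2.0
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = [-10, -10, -10]
    vol = Volume(data, affine)
    mask, table = lp.extract_clusters(vol, 1.0, 0)
    assert len(table) == 1
    expected_mm = affine[:3, :3] @ [3, 4, 5] + affine[:3, 3]
    np.testing.assert_allclose(
        table.loc[0, ["com_x_mm", "com_y_mm", "com_z_mm"]].astype(float),
        expected_mm,
    )
    assert table.loc[0, "n_voxels"] == 1
    assert table.loc[0, "volume_mm3"] == pytest.approx(8.0)


def test_extract_extent_filter_drops_small_blob():
    """Blobs of 600 and 150 voxels with min 500 -> only the 600 blob."""
    data = np.zeros((40, 40, 40))
    flat = np.unravel_index(np.arange(600), (10, 10, 10))
    data[flat[0], flat[1], flat[2]] = 1.0
    flat2 = np.unravel_index(np.arange(150), (6, 6, 6))
    data[flat2[0] + 25, flat2[1] + 25, flat2[2] + 25] = 1.0
    vol = Volume(data, np.eye(4))
    _, table = lp.extract_clusters(vol, 0.5, 500)
    assert list(table["n_voxels"]) == [600]


def test_extract_symmetric_pair_com_at_midpoint():
    data = np.zeros((8, 8, 8))
    data[2, 2, 2] = 1.0
    data[2, 2, 3] = 1.0
    vol = Volume(data, np.eye(4))
    _, table = lp.extract_clusters(vol, 0.5, 0)
    np.testing.assert_allclose(
        table.loc[0, ["com_x_mm", "com_y_mm", "com_z_mm"]].astype(float),
        [2.0, 2.0, 2.5],
    )


def test_extract_partitions_suprathreshold_set():
    rng = np.random.default_rng(11)
    data = rng.normal(size=(12, 12, 12))
    vol = Volume(data, np.eye(4))
    mask, table = lp.extract_clusters(vol, 1.0, 0)
    assert mask.data.astype(bool).sum() == (data > 1.0).sum()
    assert table["n_voxels"].sum() == (data > 1.0).sum()
    np.testing.assert_array_equal(mask.data.astype(bool), data > 1.0)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def test_euclidean_displacement():
    assert lp.euclidean_displacement([0, 0, 0], [0, 0, 0]) == 0.0
    assert lp.euclidean_displacement([0, 0, 0], [3, 4, 0]) == pytest.approx(5.0)
    rng = np.random.default_rng(12)
    a, b = rng.normal(size=3), rng.normal(size=3)
    expected = sum((x - y) ** 2 for x, y in zip(a, b)) ** 0.5
    assert lp.euclidean_displacement(a, b) == pytest.approx(expected)
    assert lp.euclidean_displacement(a, b) == lp.euclidean_displacement(b, a)


def test_centre_of_mass_largest_cluster_option():
    data = np.zeros((20, 10, 10), dtype=np.uint8)
    data[1:4, 1:4, 1:4] = 1     # 27 voxels
    data[15, 5, 5] = 1          # singleton far away
    vol = Volume(data, np.eye(4), "binary")
    pooled = lp.centre_of_mass_mm(vol)
    largest = lp.centre_of_mass_mm(vol, largest_cluster_only=True)
    np.testing.assert_allclose(largest, [2.0, 2.0, 2.0])
    assert pooled[0] > largest[0]
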