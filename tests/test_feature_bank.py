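"""Feature-bank oracles: counts, first-order arithmetic, shape geometry,
texture matrices against brute-force implementations, filter responses."""

import itertools

import numpy as np
import pytest

from habitat_radiomics.features import (
    FeatureBankConfig,
    count_features,
    extract_region_features,
    feature_names,
    filter_images,
    firstorder_features,
    log_filter,
    shape_features,
    wavelet_subbands,
)
from habitat_radiomics.features.matrices import (
    OFFSETS_13,
    discretize,
    glcm_features,
    glcm_matrices,
    gldm_entries,
    glrlm_entries,
    glszm_entries,
    ngtdm_features,
)


class TestCounts:
    def test_full_bank_is_1037(self):
        assert count_features(FeatureBankConfig()) == 1037

    def test_shape_only(self):
        cfg = FeatureBankConfig(families=("shape",), filters=("original",))
        assert count_features(cfg) == 14

    def test_intensity_families_on_original(self):
        cfg = FeatureBankConfig(
            families=("firstorder", "glcm", "gldm", "glrlm", "glszm", "ngtdm"),
            filters=("original",),
        )
        assert count_features(cfg) == 93  # 18+24+14+16+16+5

    def test_names_unique_and_match_count(self):
        for cfg in (FeatureBankConfig(), FeatureBankConfig(filters=("original",))):
            names = feature_names(cfg)
            assert len(names) == count_features(cfg)
            assert len(set(names)) == len(names)


class TestFirstOrder:
    def test_toy_region_arithmetic(self):
        vol = np.zeros((3, 3, 3))
        mask = np.zeros((3, 3, 3), bool)
        vol[0, 0, :3] = [2, 4, 9]
        mask[0, 0, :3] = True
        f = firstorder_features(vol, mask, voxel_volume=1.0)
        assert f["Mean"] == pytest.approx(5.0)
        assert f["Median"] == pytest.approx(4.0)
        assert f["Minimum"] == 2.0
        assert f["Maximum"] == 9.0
        assert f["Range"] == 7.0
        assert f["Energy"] == pytest.approx(4 + 16 + 81)

    def test_entropy_invariant_to_affine_rescale(self, rng):
        vol = rng.normal(size=(8, 8, 8))
        mask = np.ones((8, 8, 8), bool)
        base = firstorder_features(vol, mask, 1.0)["Entropy"]
        scaled = firstorder_features(3.5 * vol + 11.0, mask, 1.0)["Entropy"]
        assert scaled == pytest.approx(base, abs=1e-9)

    def test_constant_region_degenerate_stats(self):
        vol = np.full((4, 4, 4), 7.0)
        mask = np.ones((4, 4, 4), bool)
        f = firstorder_features(vol, mask, 1.0)
        assert f["Variance"] == 0.0
        assert f["Skewness"] == 0.0
        assert f["Uniformity"] == pytest.approx(1.0)


class TestShape:
    def test_cube_sphericity_closed_form(self):
        # ideal cube: (36 pi V^2)^(1/3) / A = 6^(2/3) pi^(1/3) / 6 ~ 0.806;
        # the marching-cubes mesh chamfers corners, so compare loosely
        mask = np.zeros((16, 16, 16), bool)
        mask[3:13, 3:13, 3:13] = True
        f = shape_features(mask, (1.0, 1.0, 1.0))
        assert f["Sphericity"] == pytest.approx(0.806, rel=0.06)
        assert f["VoxelVolume"] == pytest.approx(1000.0)

    def test_digital_sphere_volume_and_area(self):
        r = 9.0
        g = np.indices((24, 24, 24)).astype(float) - 11.5
        mask = (g**2).sum(axis=0) <= r**2
        f = shape_features(mask, (1.0, 1.0, 1.0))
        assert f["MeshVolume"] == pytest.approx(4 / 3 * np.pi * r**3, rel=0.05)
        # marching cubes overestimates the area of a digitized sphere
        # (staircase effect), so the band is one-sided and loose
        assert f["SurfaceArea"] == pytest.approx(4 * np.pi * r**2, rel=0.12)
        assert f["Sphericity"] == pytest.approx(1.0, rel=0.1)
        assert f["Maximum3DDiameter"] == pytest.approx(2 * r, rel=0.1)
        assert f["Elongation"] == pytest.approx(1.0, rel=0.05)

    def test_anisotropic_spacing_scales_volume(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True
        iso = shape_features(mask, (1.0, 1.0, 1.0))
        aniso = shape_features(mask, (2.0, 1.0, 1.0))
        assert aniso["VoxelVolume"] == pytest.approx(2 * iso["VoxelVolume"])


def brute_force_glcm(disc, off, levels):
    """Naive voxel-loop co-occurrence counting (symmetric, normalized)."""
    index = {g: i for i, g in enumerate(levels)}
    G = len(levels)
    P = np.zeros((G, G))
    nz, ny, nx = disc.shape
    for z, y, x in itertools.product(range(nz), range(ny), range(nx)):
        if disc[z, y, x] == 0:
            continue
        z2, y2, x2 = z + off[0], y + off[1], x + off[2]
        if 0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx and disc[z2, y2, x2] > 0:
            P[index[disc[z, y, x]], index[disc[z2, y2, x2]]] += 1
    P = P + P.T
    return P / P.sum() if P.sum() else P


class TestTextureMatrices:
    def test_glcm_matches_brute_force(self, rng):
        vol = rng.normal(size=(5, 5, 5))
        mask = rng.uniform(size=(5, 5, 5)) > 0.3
        mask[2, 2, 2] = True
        disc = discretize(vol, mask, 4)
        P, levels = glcm_matrices(disc)
        for ai, off in enumerate(OFFSETS_13):
            expected = brute_force_glcm(disc, off, list(levels.astype(int)))
            np.testing.assert_allclose(P[ai], expected, atol=1e-12)

    def test_glcm_direction_average_rotation_invariant(self, rng):
        vol = rng.normal(size=(6, 6, 6))
        mask = np.ones((6, 6, 6), bool)
        disc = discretize(vol, mask, 8)
        rot = np.rot90(disc, k=1, axes=(0, 1))
        f1 = glcm_features(disc)
        f2 = glcm_features(rot)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], abs=1e-9), k

    def test_constant_region_conventions(self):
        disc = np.zeros((4, 4, 4), dtype=np.int32)
        disc[1:3, 1:3, 1:3] = 1  # single gray level
        f = glcm_features(disc)
        assert f["Correlation"] == 1.0
        assert f["MCC"] == 1.0
        assert f["Imc1"] == 0.0
        assert f["InverseVariance"] == 0.0
        assert f["JointEnergy"] == pytest.approx(1.0)

    def test_glrlm_runs_on_striped_volume(self):
        # two levels in alternating 2-voxel stripes along axis 2
        disc = np.zeros((1, 1, 6), dtype=np.int32)
        disc[0, 0] = [1, 1, 2, 2, 1, 1]
        iv, jv, cv = glrlm_entries(disc, (0, 0, 1))
        runs = dict(zip(zip(iv, jv), cv))
        assert runs == {(1.0, 2.0): 2.0, (2.0, 2.0): 1.0}

    def test_glrlm_perpendicular_direction_sees_unit_runs(self):
        disc = np.zeros((1, 1, 6), dtype=np.int32)
        disc[0, 0] = [1, 1, 2, 2, 1, 1]
        iv, jv, cv = glrlm_entries(disc, (1, 0, 0))  # across the stripe axis
        assert set(jv) == {1.0}
        assert cv.sum() == 6

    def test_glszm_zones_hand_example(self):
        disc = np.zeros((3, 3, 3), dtype=np.int32)
        disc[0, 0, 0] = 1
        disc[2, 2, 2] = 1  # two separate single-voxel zones of level 1
        disc[0, 2, 0] = 2
        disc[0, 2, 1] = 2  # one 2-voxel zone of level 2
        iv, jv, cv = glszm_entries(disc)
        zones = dict(zip(zip(iv, jv), cv))
        assert zones == {(1.0, 1.0): 2.0, (2.0, 2.0): 1.0}

    def test_gldm_dependence_counts(self):
        # 2x2x1 block of one level: every voxel has 3 equal neighbors -> j=4
        disc = np.zeros((3, 3, 3), dtype=np.int32)
        disc[0:2, 0:2, 0] = 5
        iv, jv, cv = gldm_entries(disc)
        assert dict(zip(zip(iv, jv), cv)) == {(5.0, 4.0): 4.0}

    def test_ngtdm_two_level_hand_example(self):
        # single voxel of level 2 surrounded by level 1 in a 3x3x3 region
        disc = np.ones((3, 3, 3), dtype=np.int32)
        disc[1, 1, 1] = 2
        f = ngtdm_features(disc)
        # s_2 = |2 - 1| = 1 (all 26 neighbors are level 1)
        # s_1: each level-1 voxel deviates from its neighborhood mean by 1/n_i
        assert f["Coarseness"] > 0
        assert f["Contrast"] > 0
        assert f["Busyness"] > 0


class TestFilters:
    def test_constant_volume_subbands(self):
        vol = np.full((8, 8, 8), 3.0)
        bands = wavelet_subbands(vol)
        assert len(bands) == 8
        lll = bands["wavelet-LLL"]
        assert np.allclose(lll, lll.flat[0])  # constant up to filter gain
        for name, band in bands.items():
            if name != "wavelet-LLL":
                assert np.allclose(band, 0.0, atol=1e-10), name

    def test_constant_volume_log_response_near_zero(self):
        # the sampled derivative kernel does not sum exactly to zero, so the
        # response to a constant is ~1e-3 of the input value, not exactly 0
        vol = np.full((16, 16, 16), 5.0)
        out = log_filter(vol, (1, 1, 1), 3.0)
        assert np.all(np.abs(out[4:12, 4:12, 4:12]) < 0.01 * 5.0)

    def test_impulse_log_response_matches_kernel(self):
        """LoG of a unit impulse ~ sampled scale-normalized LoG kernel."""
        n = 33
        vol = np.zeros((n, n, n))
        vol[n // 2, n // 2, n // 2] = 1.0
        sigma = 3.0
        out = log_filter(vol, (1, 1, 1), sigma)
        g = np.indices((n, n, n)).astype(float) - n // 2
        r2 = (g**2).sum(axis=0)
        gauss = np.exp(-r2 / (2 * sigma**2)) / (2 * np.pi * sigma**2) ** 1.5
        kernel = sigma**2 * gauss * (r2 - 3 * sigma**2) / sigma**4
        # compare on the central region where truncation effects are small
        c = slice(n // 2 - 6, n // 2 + 7)
        np.testing.assert_allclose(out[c, c, c], kernel[c, c, c], atol=2e-4)

    def test_filter_images_layout(self):
        vol = np.random.default_rng(0).normal(size=(10, 10, 10))
        out = filter_images(vol, (1, 1, 1))
        assert len(out) == 11
        assert set(out) == set(FeatureBankConfig().filters)


class TestRegionExtraction:
    def test_vector_length_matches_count_identity(self, rng):
        cfg = FeatureBankConfig(filters=("original", "log-sigma-3mm"))
        vol = rng.normal(size=(12, 12, 12))
        mask = np.zeros((12, 12, 12), bool)
        mask[3:9, 3:9, 3:9] = True
        filtered = filter_images(vol, (1, 1, 1))
        fv = extract_region_features(filtered, mask, (1, 1, 1), cfg)
        assert len(fv.values) == count_features(cfg)
        assert fv.missing is None
        assert all(np.isfinite(v) for v in fv.values.values())

    def test_small_region_flagged_missing_not_silent_nan(self, rng):
        cfg = FeatureBankConfig(filters=("original",), min_region_voxels=10)
        vol = rng.normal(size=(8, 8, 8))
        mask = np.zeros((8, 8, 8), bool)
        mask[0, 0, :3] = True
        fv = extract_region_features(filter_images(vol, (1, 1, 1)), mask, (1, 1, 1), cfg)
        assert fv.missing is not None
        assert len(fv.values) == count_features(cfg)
        assert all(np.isnan(v) for v in fv.values.values())

    def test_reproducible_bit_for_bit(self, rng):
        cfg = FeatureBankConfig(filters=("original",))
        vol = rng.normal(size=(10, 10, 10))
        mask = np.zeros((10, 10, 10), bool)
        mask[2:8, 2:8, 2:8] = True
        filtered = filter_images(vol, (1, 1, 1))
        a = extract_region_features(filtered, mask, (1, 1, 1), cfg)
        b = extract_region_features(filtered, mask, (1, 1, 1), cfg)
        assert a.values == b.values
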