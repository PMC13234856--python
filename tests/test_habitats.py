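"""Extract-then-pool habitat generation: window features, SLIC pooling,
silhouette-driven K selection, nearest-centroid assignment."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from habitat_radiomics.habitats import (
    HabitatModel,
    assign_habitats,
    fit_habitat_model,
    slic_supervoxels,
    voxel_feature_maps,
)
from habitat_radiomics.synthetic import MpMRIStudy


def _study(volumes: dict, mask: np.ndarray) -> MpMRIStudy:
    return MpMRIStudy(
        patient_id="T1",
        sequences={k: (v, (1.0, 1.0, 1.0)) for k, v in volumes.items()},
        tumor_mask=mask,
        tumor_mask_rater2=mask,
        clinical=None,
    )


class TestVoxelFeatureMaps:
    def test_constant_image_channels(self):
        mask = np.zeros((7, 7, 7), bool)
        mask[1:6, 1:6, 1:6] = True
        vols = {s: np.full((7, 7, 7), 2.5) for s in ("T2WI", "DWI", "DCE")}
        vfm = voxel_feature_maps(_study(vols, mask), window=3)
        for i, name in enumerate(vfm.names):
            ch = vfm.channels[..., i][mask]
            if name.endswith("_mean"):
                np.testing.assert_allclose(ch, 2.5, atol=1e-12)
            elif name.endswith("_sd"):
                np.testing.assert_allclose(ch, 0.0, atol=1e-9)

    def test_mean_channel_matches_brute_force(self, rng):
        mask = np.ones((5, 5, 5), bool)
        vol = rng.normal(size=(5, 5, 5))
        vols = {s: vol for s in ("T2WI", "DWI", "DCE")}
        vfm = voxel_feature_maps(_study(vols, mask), window=3)
        mean_idx = vfm.names.index("T2WI_mean")
        for z, y, x in [(2, 2, 2), (0, 0, 0), (4, 2, 1)]:
            zz = slice(max(z - 1, 0), z + 2)
            yy = slice(max(y - 1, 0), y + 2)
            xx = slice(max(x - 1, 0), x + 2)
            expected = vol[zz, yy, xx].mean()
            assert vfm.channels[z, y, x, mean_idx] == pytest.approx(expected)

    def test_entropy_peaks_at_two_value_interface(self):
        mask = np.ones((7, 7, 7), bool)
        vol = np.zeros((7, 7, 7))
        vol[:, :, 4:] = 10.0  # plane interface at x=4
        vols = {s: vol for s in ("T2WI", "DWI", "DCE")}
        vfm = voxel_feature_maps(_study(vols, mask), window=3)
        ent = vfm.channels[..., vfm.names.index("T2WI_entropy")]
        assert ent[3, 3, 4] > ent[3, 3, 1]
        assert ent[3, 3, 4] > ent[3, 3, 6]

    def test_window_validation(self):
        mask = np.ones((5, 5, 5), bool)
        vols = {s: np.zeros((5, 5, 5)) for s in ("T2WI", "DWI", "DCE")}
        with pytest.raises(ValueError):
            voxel_feature_maps(_study(vols, mask), window=4)
        with pytest.raises(ValueError):
            voxel_feature_maps(_study(vols, mask), window=7)


class TestSlicPooling:
    def _vfm(self, rng, shape=(12, 12, 12)):
        mask = np.zeros(shape, bool)
        mask[2:-2, 2:-2, 2:-2] = True
        vols = {s: rng.normal(size=shape) for s in ("T2WI", "DWI", "DCE")}
        return voxel_feature_maps(_study(vols, mask), window=3), mask

    def test_single_supervoxel_equals_tumor_mean(self, rng):
        vfm, mask = self._vfm(rng)
        sv = slic_supervoxels(vfm, n_supervoxels=1)
        assert sv.pooled.shape[0] == 1
        np.testing.assert_allclose(
            sv.pooled.iloc[0].to_numpy(), vfm.channels[mask].mean(axis=0), atol=1e-12
        )

    def test_pooling_linearity_identity(self, rng):
        """Pooled vector is exactly the mean of member voxel vectors."""
        vfm, mask = self._vfm(rng)
        sv = slic_supervoxels(vfm, n_supervoxels=6)
        for i in sv.pooled.index:
            sel = sv.label_volume == i
            np.testing.assert_allclose(
                sv.pooled.loc[i].to_numpy(),
                vfm.channels[sel].mean(axis=0),
                atol=1e-12,
            )

    def test_partition_covers_mask_with_connected_pieces(self, rng):
        from scipy import ndimage

        vfm, mask = self._vfm(rng)
        sv = slic_supervoxels(vfm, n_supervoxels=8)
        assert ((sv.label_volume > 0) == mask).all()
        for i in sv.pooled.index:
            _, n = ndimage.label(sv.label_volume == i, structure=np.ones((3, 3, 3)))
            assert n == 1

    def test_homogeneous_sphere_volume_spread(self, rng):
        g = np.indices((20, 20, 20)).astype(float) - 9.5
        mask = (g**2).sum(axis=0) <= 8**2
        vols = {s: rng.normal(0, 0.01, size=(20, 20, 20)) for s in ("T2WI", "DWI", "DCE")}
        vfm = voxel_feature_maps(_study(vols, mask), window=3)
        # a homogeneous image has no feature structure, so judge the purely
        # geometric regularity at a compactness that ignores the noise floor
        sv = slic_supervoxels(vfm, n_supervoxels=8, compactness=1.0)
        counts = sv.counts
        assert counts.max() / counts.min() < 3.0

    def test_mask_smaller_than_request_rejected(self, rng):
        vfm, mask = self._vfm(rng)
        with pytest.raises(ValueError):
            slic_supervoxels(vfm, n_supervoxels=10**6)


def _blob_svsets(rng, centers, n_per=30, sd=0.05):
    """Fake supervoxel sets whose pooled vectors form Gaussian blobs."""
    names = [f"{s}_{f}" for s in ("T2WI", "DWI", "DCE") for f in ("mean", "sd", "entropy")]
    rows = []
    for c in centers:
        rows.append(rng.normal(c, sd, size=(n_per, len(names))))
    pooled = pd.DataFrame(np.vstack(rows), columns=names)
    pooled.index = np.arange(1, len(pooled) + 1)

    class FakeSV:
        pass

    sv = FakeSV()
    sv.pooled = pooled
    return [sv]


class TestFitHabitatModel:
    def test_three_blobs_select_k3(self, rng):
        centers = [np.r_[np.zeros(8), 0.0], np.r_[np.ones(8) * 2, 0.0], np.r_[np.ones(8) * -2, 4.0]]
        model = fit_habitat_model(_blob_svsets(rng, centers), seed=0)
        assert model.K == 3

    def test_two_blobs_select_k2(self, rng):
        centers = [np.zeros(9), np.ones(9) * 3]
        model = fit_habitat_model(_blob_svsets(rng, centers), seed=0)
        assert model.K == 2

    def test_identical_supervoxels_rejected(self, rng):
        centers = [np.zeros(9)]
        svs = _blob_svsets(rng, centers, n_per=40, sd=0.0)
        with pytest.raises(ValueError, match="zero variance"):
            fit_habitat_model(svs, seed=0)

    def test_silhouette_matches_hand_computed_six_points(self):
        """Mean silhouette of a 6-point, 2-cluster example, by definition."""
        from sklearn.metrics import silhouette_score

        pts = np.array([[0.0], [0.5], [1.0], [10.0], [10.5], [11.0]])
        labels = np.array([0, 0, 0, 1, 1, 1])
        # hand computation: for x=0: a = mean(0.5, 1.0) = 0.75;
        # b = mean(10, 10.5, 11) = 10.5; s = (10.5 - 0.75) / 10.5
        expected = []
        for i, x in enumerate(pts.ravel()):
            own = [abs(x - y) for j, y in enumerate(pts.ravel()) if labels[j] == labels[i] and j != i]
            other = [abs(x - y) for j, y in enumerate(pts.ravel()) if labels[j] != labels[i]]
            a, b = np.mean(own), np.mean(other)
            expected.append((b - a) / max(a, b))
        assert silhouette_score(pts, labels) == pytest.approx(np.mean(expected))

    def test_same_seed_reproducible(self, rng):
        centers = [np.zeros(9), np.ones(9) * 3]
        svs = _blob_svsets(rng, centers)
        m1 = fit_habitat_model(svs, seed=5)
        m2 = fit_habitat_model(svs, seed=5)
        np.testing.assert_array_equal(m1.centroids, m2.centroids)

    def test_ordering_by_dce_mean(self, rng):
        """Habitat 1 must have the lowest centroid DCE local-mean intensity."""
        centers = [np.r_[np.zeros(6), 5.0, 0, 0], np.r_[np.ones(6), -5.0, 0, 0]]
        model = fit_habitat_model(_blob_svsets(rng, centers), seed=0)
        assert model.ordering_statistic == sorted(model.ordering_statistic)


class TestAssignment:
    def test_training_supervoxels_keep_their_cluster(self, rng):
        centers = [np.zeros(9), np.ones(9) * 4]
        svs = _blob_svsets(rng, centers, n_per=25)
        model = fit_habitat_model(svs, seed=0)

        class SV:
            pass

        sv = SV()
        sv.pooled = svs[0].pooled
        sv.label_volume = np.zeros((1, 1, len(sv.pooled)), dtype=np.int64)
        sv.label_volume[0, 0, :] = sv.pooled.index.to_numpy()
        sv.patient_id = "T"
        hm = assign_habitats(sv, model)
        labels = hm.label_volume[0, 0, :]
        # the first 25 pooled vectors share one habitat, the rest the other
        assert len(set(labels[:25])) == 1 and len(set(labels[25:])) == 1
        assert labels[0] != labels[-1]
        # idempotence
        hm2 = assign_habitats(sv, model)
        np.testing.assert_array_equal(hm.label_volume, hm2.label_volume)

    def test_supervoxel_at_centroid(self, rng):
        centers = [np.zeros(9), np.ones(9) * 4]
        model = fit_habitat_model(_blob_svsets(rng, centers), seed=0)

        class SV:
            pass

        sv = SV()
        raw_centroid = model.centroids[0] * model.scaler_sd + model.scaler_mean
        sv.pooled = pd.DataFrame([raw_centroid], columns=model.channel_names, index=[1])
        sv.label_volume = np.ones((1, 1, 1), dtype=np.int64)
        sv.patient_id = "T"
        assert assign_habitats(sv, model).label_volume[0, 0, 0] == 1

    def test_schema_mismatch_rejected(self, rng):
        centers = [np.zeros(9), np.ones(9) * 4]
        model = fit_habitat_model(_blob_svsets(rng, centers), seed=0)

        class SV:
            pass

        sv = SV()
        sv.pooled = pd.DataFrame(np.zeros((2, 3)), columns=list("abc"), index=[1, 2])
        sv.label_volume = np.ones((1, 1, 2), dtype=np.int64)
        with pytest.raises(ValueError, match="channels"):
            assign_habitats(sv, model)


def hungarian_agreement(truth, predicted, k):
    """Best-permutation per-voxel agreement between two label maps."""
    conf = np.zeros((k, k))
    for t in range(1, k + 1):
        for p in range(1, k + 1):
            conf[t - 1, p - 1] = np.sum((truth == t) & (predicted == p))
    rows, cols = linear_sum_assignment(-conf)
    return conf[rows, cols].sum() / np.sum(truth > 0)


class TestPlantedRecovery:
    def test_assignment_recovers_planted_partition(self):
        """Fitted habitats agree with the generator's planted 3-habitat
        partition above 0.8 after the best label matching (strong-contrast
        cohort: identical habitat signatures in both classes)."""
        from habitat_radiomics.habitats import build_habitat_maps
        from habitat_radiomics.preprocess import preprocess_study
        from habitat_radiomics.synthetic import SyntheticConfig, generate_cohort

        config = SyntheticConfig(
            n_patients=10,
            grid_shape=(40, 40, 40),
            alnm_habitat_effect={"dce_mean_shift": 0.0, "noise_scale": 1.0},
            seed=1,
        )
        cohort = generate_cohort(config)
        cohort.studies = [preprocess_study(s) for s in cohort.studies]
        model, maps, _ = build_habitat_maps(cohort, seed=0, mm3_per_supervoxel=150.0)
        agreements = []
        for s in cohort.studies:
            truth = s.truth["habitat_map"]
            pred = maps[s.patient_id].label_volume
            agreements.append(hungarian_agreement(truth, pred, max(model.K, 3)))
        assert np.mean(agreements) > 0.8
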