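import numpy as np
import pytest

from ctseg import (
    BinaryMask,
    CTVolume,
    LesionConfig,
    candidate_lesion_map,
    combine_masks,
    denoise_clusters,
    remove_paraventricular,
    subtract_nonlesion,
)
from ctseg.region_maps import LabelPartition, NonLesionMaps


def full_domain(shape, spacing=(1.0, 1.0, 1.0)):
    return BinaryMask(np.ones(shape, bool), spacing)


class TestCandidateMap:
    def test_uniform_parenchyma_gives_empty_candidate(self):
        vol = CTVolume(np.full((5, 5, 5), 34.0))
        out = candidate_lesion_map(vol, full_domain(vol.shape))
        assert out.count() == 0

    def test_uniform_lesion_intensity_gives_full_candidate(self):
        vol = CTVolume(np.full((5, 5, 5), 14.0))
        out = candidate_lesion_map(vol, full_domain(vol.shape))
        assert out.data.all()

    def test_lesion_blob_recovered_from_parenchyma(self, rng):
        data = np.full((14, 14, 10), 40.0)
        truth = np.zeros(data.shape, bool)
        truth[4:9, 4:9, 3:7] = True
        data[truth] = 22.0  # transformed-scale chronic lesion intensity
        vol = CTVolume(data + rng.normal(0, 1, data.shape))
        out = candidate_lesion_map(vol, full_domain(vol.shape))
        assert (out.data & truth).sum() / truth.sum() >= 0.9


class TestSubtractNonlesion:
    def _maps(self, h, s, v, spacing=(1.0, 1.0, 1.0)):
        return NonLesionMaps(BinaryMask(h, spacing), BinaryMask(s, spacing), BinaryMask(v, spacing))

    def test_disjoint_maps_leave_candidate_unchanged(self):
        shape = (4, 4, 4)
        cand = np.zeros(shape, bool)
        cand[0] = True
        other = np.zeros(shape, bool)
        other[2] = True
        out = subtract_nonlesion(BinaryMask(cand), self._maps(other, other, other))
        assert np.array_equal(out.data, cand)

    def test_candidate_inside_ventricles_removed_entirely(self):
        shape = (4, 4, 4)
        cand = np.zeros(shape, bool)
        cand[1, 1, :] = True
        vent = np.ones(shape, bool)
        empty = np.zeros(shape, bool)
        out = subtract_nonlesion(BinaryMask(cand), self._maps(empty, empty, vent))
        assert out.count() == 0

    def test_matches_elementwise_composition_on_random_masks(self, rng):
        shape = (6, 6, 6)
        cand = rng.uniform(size=shape) < 0.5
        h, s, v = (rng.uniform(size=shape) < 0.3 for _ in range(3))
        out = subtract_nonlesion(BinaryMask(cand), self._maps(h, s, v))
        np.testing.assert_array_equal(out.data, cand & ~(h | s | v))


class TestParaventricularRemoval:
    def _setup(self):
        shape = (13, 12, 5)
        vol = CTVolume(np.zeros(shape), midsagittal_index=6)
        vent = np.zeros(shape, bool)
        vent[3:5, 3:6, 1:4] = True   # left ventricle
        vent[8:10, 3:6, 1:4] = True  # right ventricle
        return vol, BinaryMask(vent)

    def test_unilateral_component_retained(self):
        vol, vent = self._setup()
        mask = np.zeros(vol.shape, bool)
        mask[5, 3:6, 1:4] = True  # medial of left ventricle, one hemisphere only
        out = remove_paraventricular(BinaryMask(mask), vent, vol)
        assert out.count() == mask.sum()

    def test_midline_crossing_medial_component_removed(self):
        vol, vent = self._setup()
        mask = np.zeros(vol.shape, bool)
        mask[5:8, 4, 2] = True  # hugs medial walls and crosses column 6
        out = remove_paraventricular(BinaryMask(mask), vent, vol)
        assert out.count() == 0

    def test_empty_ventricle_mask_leaves_input_unchanged(self, rng):
        vol = CTVolume(np.zeros((9, 9, 5)), midsagittal_index=4)
        mask = BinaryMask(rng.uniform(size=vol.shape) < 0.3)
        out = remove_paraventricular(mask, BinaryMask(np.zeros(vol.shape, bool)), vol)
        assert np.array_equal(out.data, mask.data)

    def test_lateral_crossing_component_far_from_ventricles_retained(self):
        vol, vent = self._setup()
        mask = np.zeros(vol.shape, bool)
        mask[5:8, 10, 4] = True  # crosses midline but >4 mm from ventricles
        out = remove_paraventricular(BinaryMask(mask), vent, vol)
        assert out.count() == mask.sum()


class TestCombineMasks:
    def test_empty_inputs_give_empty_output(self):
        shape = (6, 6, 3)
        vol = CTVolume(np.random.default_rng(0).uniform(0, 40, shape))
        empty = BinaryMask(np.zeros(shape, bool))
        out = combine_masks(empty, empty, vol)
        assert out.count() == 0

    def test_half_filled_region_promoted_whole(self):
        shape = (10, 1, 1)
        labels = np.ones(shape, dtype=np.int32)
        part = LabelPartition(labels=labels)
        m1 = np.zeros(shape, bool)
        m1[:3] = True
        m2 = np.zeros(shape, bool)
        m2[3:5] = True  # union = 5 of 10
        vol = CTVolume(np.zeros(shape[:2] + (2,))[:, :, :1] * 0 + np.zeros(shape))
        out = combine_masks(BinaryMask(m1), BinaryMask(m2), CTVolume(np.zeros(shape)), part=part)
        assert out.data.all()

    def test_union_of_complete_regions_unchanged(self, rng):
        labels = rng.integers(1, 4, (8, 8, 2)).astype(np.int32)
        part = LabelPartition(labels=labels)
        mask = BinaryMask(labels == 2)
        out = combine_masks(mask, mask, CTVolume(np.zeros(labels.shape)), part=part)
        assert np.array_equal(out.data, mask.data)


class TestDenoiseClusters:
    def test_small_cluster_removed(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[1, 1, 1:3] = True  # 2 voxels < default 5
        out = denoise_clusters(BinaryMask(mask))
        assert out.count() == 0

    def test_large_single_plane_cluster_removed(self):
        mask = np.zeros((16, 16, 8), bool)
        mask[1:15, 1:15, 3] = True  # 196 voxels in one axial plane > 100
        out = denoise_clusters(BinaryMask(mask))
        assert out.count() == 0

    def test_multi_plane_cluster_retained(self):
        mask = np.zeros((10, 10, 8), bool)
        mask[2:7, 2:7, 2:5] = True  # 75 voxels across 3 planes
        out = denoise_clusters(BinaryMask(mask))
        assert out.count() == 75

    def test_small_single_plane_cluster_retained(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[1:4, 1:4, 2] = True  # 9 voxels, one plane, under the cap
        out = denoise_clusters(BinaryMask(mask))
        assert out.count() == 9


class TestResultInvariants:
    def test_volume_of_ten_voxels_at_4mm(self):
        mask = np.zeros((6, 6, 6), bool)
        mask.ravel()[:10] = True
        bm = BinaryMask(mask, (4.0, 4.0, 4.0))
        assert bm.volume_ml() == pytest.approx(0.64)

    def test_final_mask_inside_domain(self, lesioned_result, brain_domain):
        assert not (lesioned_result.mask.data & ~brain_domain.data).any()

    def test_volume_matches_count_times_voxel_volume(self, lesioned_result):
        m = lesioned_result.mask
        assert lesioned_result.volume_ml == pytest.approx(m.count() * np.prod(m.spacing) / 1000.0)

    def test_analysis_grid_outputs_share_lattice(self, lesioned_result):
        assert lesioned_result.mask_mni4.shape == lesioned_result.zeta_mni4.shape
        assert np.allclose(lesioned_result.mask_mni4.spacing, lesioned_result.zeta_mni4.spacing)

    def test_provenance_records_every_stage(self, lesioned_result):
        stages = [p["stage"] for p in lesioned_result.provenance]
        for s in ("clamp_and_strip", "tv_denoise", "sulci_map", "ventricle_map",
                  "candidate_lesion_map", "mask1", "zeta_map", "mask2",
                  "combine_masks", "denoise_clusters", "result"):
            assert s in stages


class TestMonotoneRecovery:
    def test_larger_lesion_never_recovers_less_volume(self):
        from ctseg import PhantomConfig, make_cohort, make_phantom, segment_chronic_lesions
        from ctseg.phantom import LesionSpec

        cohort = make_cohort(8, PhantomConfig(shape=(40, 40, 40)), seed=21)
        volumes = []
        for r in (9.0, 13.0):
            spec = LesionSpec(center_mm=(-26.0, 6.0, 2.0), radii_mm=(r, r, r))
            vol, _ = make_phantom(PhantomConfig(shape=(40, 40, 40), lesion_specs=(spec,), seed=9))
            res = segment_chronic_lesions(vol, cohort)
            volumes.append(res.volume_ml)
        assert volumes[1] >= volumes[0]
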