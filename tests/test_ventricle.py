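import numpy as np
import pytest
from scipy.spatial.distance import cdist

from chopct import phantom as ph
from chopct import ventricle as vent
from chopct._morph import ball_open
from chopct.types import BinaryMask, PointCloud, RigidTransform, VolumeImage
from chopct.ventricle import SegmentationParams

from conftest import dice, digitized_ball


def hausdorff_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """O(N^2) brute force: full pairwise distance matrix."""
    d = cdist(a, b)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def rotation_matrix(axis, angle_deg):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


class TestPreprocess:
    def test_constant_image_unchanged(self):
        img = VolumeImage(np.full((8, 8, 8), 7.0), 1.0)
        out = vent.preprocess(img, SegmentationParams())
        assert np.array_equal(out.voxels, img.voxels)

    def test_salt_voxel_removed(self):
        vox = np.full((9, 9, 9), 10.0)
        vox[4, 4, 4] = 1000.0
        out = vent.preprocess(VolumeImage(vox, 1.0), SegmentationParams(median_window=3))
        assert np.all(out.voxels == 10.0)

    def test_crop(self):
        img = VolumeImage(np.zeros((20, 20, 20)), 1.0)
        p = SegmentationParams(crop_box=((0, 10), (0, 10), (0, 10)))
        assert vent.preprocess(img, p).shape == (10, 10, 10)

    def test_crop_outside_rejected(self):
        img = VolumeImage(np.zeros((5, 5, 5)), 1.0)
        p = SegmentationParams(crop_box=((0, 10), (0, 5), (0, 5)))
        with pytest.raises(ValueError, match="crop_box"):
            vent.preprocess(img, p)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            SegmentationParams(median_window=4)


class TestThresholdLow:
    def test_bimodal_exact_separation(self):
        vox = np.full((6, 6, 6), 120.0)
        vox[:2] = 40.0
        mask = vent.threshold_low(VolumeImage(vox, 1.0), SegmentationParams())
        assert np.array_equal(mask.voxels, vox == 40.0)

    def test_constant_image_empty_with_warning(self):
        img = VolumeImage(np.full((5, 5, 5), 3.0), 1.0)
        with pytest.warns(UserWarning, match="constant"):
            mask = vent.threshold_low(img, SegmentationParams())
        assert mask.count() == 0

    def test_phantom_covers_lumen(self, phantom_out):
        mask = vent.threshold_low(phantom_out.image, SegmentationParams())
        truth = phantom_out.ventricle_truth
        covered = np.count_nonzero(mask.voxels & truth.voxels) / truth.count()
        assert covered >= 0.95


class TestSeparateComponents:
    def test_bridge_severed(self):
        vox = np.zeros((20, 20, 48), bool)
        a = digitized_ball(6).voxels
        vox[2:19, 2:19, 2:19] = a
        vox[2:19, 2:19, 28:45] = a
        vox[10, 10, 10:40] = True  # 1-voxel bridge
        m = BinaryMask(vox, 1.0)
        comps = vent.separate_components(m, SegmentationParams(separation_radius=2))
        assert len(comps) == 2

    def test_single_ball_one_component(self):
        m = digitized_ball(6)
        comps = vent.separate_components(m, SegmentationParams(separation_radius=2))
        assert len(comps) == 1
        assert np.array_equal(comps[0].voxels, ball_open(m.voxels, 2))

    def test_sorted_descending(self):
        vox = np.zeros((16, 16, 40), bool)
        vox[2:15, 2:15, 2:15] = digitized_ball(5, pad=1).voxels
        vox[4:13, 4:13, 25:34] = digitized_ball(3, pad=1).voxels
        comps = vent.separate_components(BinaryMask(vox, 1.0), SegmentationParams())
        counts = [c.count() for c in comps]
        assert counts == sorted(counts, reverse=True)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            vent.separate_components(
                BinaryMask(np.zeros((4, 4, 4), bool), 1.0), SegmentationParams()
            )

    def test_opening_removes_all_warns(self):
        vox = np.zeros((8, 8, 8), bool)
        vox[4, 4, 4] = True
        with pytest.warns(UserWarning, match="removed all"):
            comps = vent.separate_components(
                BinaryMask(vox, 1.0), SegmentationParams(separation_radius=3)
            )
        assert comps == []


class TestMaskToPointCloud:
    def test_single_voxel_coordinates(self):
        vox = np.zeros((5, 5, 5), bool)
        vox[2, 3, 4] = True
        pc = vent.mask_to_pointcloud(BinaryMask(vox, 0.004))
        assert np.allclose(pc.points, [[0.008, 0.012, 0.016]])

    def test_count_matches(self, phantom_out):
        pc = vent.mask_to_pointcloud(phantom_out.plexus_truth)
        assert len(pc) == phantom_out.plexus_truth.count()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            vent.mask_to_pointcloud(BinaryMask(np.zeros((3, 3, 3), bool), 1.0))


class TestHausdorff:
    def test_identical_zero(self):
        rng = np.random.default_rng(0)
        pc = PointCloud(rng.normal(size=(50, 3)))
        assert vent.hausdorff(pc, pc) == 0.0

    def test_three_four_five(self):
        a = PointCloud([[0.0, 0.0, 0.0]])
        b = PointCloud([[0.0, 3.0, 4.0]])
        assert vent.hausdorff(a, b) == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(200, 3))
        b = rng.normal(size=(200, 3)) + 0.5
        assert vent.hausdorff(PointCloud(a), PointCloud(b)) == pytest.approx(
            hausdorff_oracle(a, b), abs=0.0
        )

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(3)
        a = PointCloud(rng.normal(size=(80, 3)))
        b = PointCloud(rng.normal(size=(120, 3)))
        dab = vent.hausdorff(a, b)
        dba = vent.hausdorff(b, a)
        assert dab == dba >= 0


class TestIcp:
    def test_identity_on_equal_clouds(self):
        rng = np.random.default_rng(0)
        pc = PointCloud(rng.uniform(size=(100, 3)))
        transform, rmse = vent.icp_register(pc, pc, SegmentationParams())
        assert rmse == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(transform.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(transform.translation, 0, atol=1e-9)

    def test_recovers_known_rigid_motion(self):
        rng = np.random.default_rng(1)
        src = rng.uniform(size=(300, 3))
        R = rotation_matrix([0, 0, 1], 10.0)
        t = np.array([1.0, 0.0, 0.0])
        dst = src @ R.T + t
        transform, rmse = vent.icp_register(
            PointCloud(src), PointCloud(dst), SegmentationParams()
        )
        assert np.linalg.norm(transform.rotation - R) < 1e-3
        assert np.linalg.norm(transform.translation - t) < 1e-3
        assert rmse < 1e-6

    @pytest.mark.parametrize("seed", range(10))
    def test_random_rotations_up_to_30_deg(self, seed):
        rng = np.random.default_rng(seed)
        src = rng.uniform(size=(200, 3))
        axis = rng.normal(size=3)
        angle = rng.uniform(-30, 30)
        R = rotation_matrix(axis, angle)
        t = rng.uniform(-0.5, 0.5, 3)
        dst = src @ R.T + t
        transform, _ = vent.icp_register(
            PointCloud(src), PointCloud(dst), SegmentationParams()
        )
        assert np.linalg.norm(transform.rotation - R) < 1e-3
        assert np.linalg.norm(transform.translation - t) < 1e-3

    def test_subsampled_source_low_rmse(self, phantom_out):
        pc = vent.mask_to_pointcloud(phantom_out.plexus_truth)
        sub = PointCloud(pc.points[::2])
        _, rmse = vent.icp_register(sub, pc, SegmentationParams())
        assert rmse <= phantom_out.plexus_truth.voxel_size_mm

    def test_too_few_points_rejected(self):
        pc = PointCloud([[0, 0, 0], [1, 1, 1]])
        with pytest.raises(ValueError):
            vent.icp_register(pc, pc, SegmentationParams())


class TestSelectVentricle:
    def test_truth_beats_decoy(self, default_spec, phantom_out):
        p = SegmentationParams()
        low = vent.threshold_low(phantom_out.image, p)
        comps = vent.separate_components(low, p)
        assert len(comps) >= 2
        jitter = RigidTransform(rotation_matrix([0, 0, 1], 5.0), np.array([2.0, 0, 0]))
        reference = ph.generate_reference_ventricle(default_spec, jitter, grow=1)
        selected = vent.select_ventricle(comps, reference, p)
        assert dice(selected, phantom_out.ventricle_truth) >= 0.8

    def test_single_candidate_returned(self, phantom_out):
        cand = phantom_out.ventricle_truth
        out = vent.select_ventricle([cand], phantom_out.ventricle_truth, SegmentationParams())
        assert out is cand

    def test_no_candidates_rejected(self, phantom_out):
        with pytest.raises(ValueError):
            vent.select_ventricle([], phantom_out.ventricle_truth, SegmentationParams())


class TestActiveContour:
    def test_zero_iterations_identity(self, phantom_out):
        p = SegmentationParams(ac_iterations=0)
        out = vent.refine_active_contour(
            phantom_out.image, phantom_out.ventricle_truth, p
        )
        assert np.array_equal(out.voxels, phantom_out.ventricle_truth.voxels)

    def test_dilated_init_recovers_truth(self, noiseless_out):
        from chopct._morph import ball_dilate

        init = BinaryMask(
            ball_dilate(noiseless_out.ventricle_truth.voxels, 2),
            noiseless_out.ventricle_truth.voxel_size_mm,
        )
        out = vent.refine_active_contour(
            noiseless_out.image, init, SegmentationParams(ac_iterations=10)
        )
        assert dice(out, noiseless_out.ventricle_truth) >= 0.95

    def test_truth_init_stable(self, phantom_out):
        out = vent.refine_active_contour(
            phantom_out.image, phantom_out.ventricle_truth, SegmentationParams()
        )
        assert dice(out, phantom_out.ventricle_truth) >= 0.95

    def test_empty_mask_rejected(self, phantom_out):
        empty = BinaryMask(np.zeros(phantom_out.image.shape, bool), 0.004)
        with pytest.raises(ValueError):
            vent.refine_active_contour(phantom_out.image, empty, SegmentationParams())
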