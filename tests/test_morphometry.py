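import itertools
import math

import numpy as np
import pytest

from chopct import morphometry as mm
from chopct import phantom as ph
from chopct.types import BinaryMask

from conftest import digitized_ball, digitized_ellipsoid


def crofton_oracle_3dir(mask: BinaryMask) -> float:
    """Brute-force per-line run counting, axis directions, weight 1/3 each."""
    vox = mask.voxels
    vs = mask.voxel_size_mm
    lam = vs / vs**3
    total = 0.0
    for axis in range(3):
        chi = 0
        moved = np.moveaxis(vox, axis, 0)
        for i, j in itertools.product(range(moved.shape[1]), range(moved.shape[2])):
            line = moved[:, i, j]
            # count runs of consecutive foreground along the line
            chi += sum(1 for k, g in itertools.groupby(line) if k)
        total += (1.0 / 3.0) / lam * chi
    return 4.0 * total


class TestVolume:
    def test_printed_formula(self):
        vox = np.zeros((10, 10, 10), bool)
        vox.flat[:1000] = True
        assert mm.compute_volume(BinaryMask(vox, 0.004)) == pytest.approx(6.4e-5)

    def test_empty_zero(self):
        assert mm.compute_volume(BinaryMask(np.zeros((4, 4, 4), bool), 1.0)) == 0.0

    def test_additivity(self):
        a = np.zeros((6, 6, 6), bool)
        b = np.zeros((6, 6, 6), bool)
        a[:2] = True
        b[4:] = True
        va = mm.compute_volume(BinaryMask(a, 0.5))
        vb = mm.compute_volume(BinaryMask(b, 0.5))
        assert mm.compute_volume(BinaryMask(a | b, 0.5)) == pytest.approx(va + vb)


class TestCroftonArea:
    def test_empty_zero(self):
        assert mm.crofton_area(BinaryMask(np.zeros((4, 4, 4), bool), 1.0)) == 0.0

    def test_sphere_within_5_percent(self):
        mask = digitized_ball(20)
        area = mm.crofton_area(mask)
        assert area == pytest.approx(4 * math.pi * 20**2, rel=0.05)

    def test_sphere_convergence(self):
        errs = []
        for r in (8, 16, 32):
            area = mm.crofton_area(digitized_ball(r))
            errs.append(abs(area - 4 * math.pi * r**2) / (4 * math.pi * r**2))
        assert errs[-1] < errs[0]

    def test_cuboid_equals_oracle_exactly(self):
        vox = np.zeros((12, 14, 16), bool)
        vox[2:9, 3:11, 4:13] = True
        mask = BinaryMask(vox, 0.5)
        assert mm.crofton_area(mask) == pytest.approx(crofton_oracle_3dir(mask), abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_masks_equal_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(8, 30, size=3))
        vox = rng.random(shape) < rng.uniform(0.1, 0.6)
        mask = BinaryMask(vox, float(rng.uniform(0.5, 2.0)))
        assert mm.crofton_area(mask) == pytest.approx(crofton_oracle_3dir(mask), rel=1e-12)

    def test_13_directions_more_accurate_on_sphere(self):
        mask = digitized_ball(16)
        truth = 4 * math.pi * 16**2
        e3 = abs(mm.crofton_area(mask, 3) - truth)
        e13 = abs(mm.crofton_area(mask, 13) - truth)
        assert e13 <= e3

    def test_invalid_directions(self):
        with pytest.raises(ValueError):
            mm.crofton_area(digitized_ball(4), directions=5)


class TestOrientationAngle:
    def test_aligned_zero_degrees(self):
        mask = digitized_ellipsoid((30, 10, 10), direction=(0, 0, 1))
        res = mm.orientation_angle(mask, u=(0, 0, 1))
        assert res.angle_deg == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_ninety_degrees(self):
        mask = digitized_ellipsoid((30, 10, 10), direction=(0, 0, 1))
        res = mm.orientation_angle(mask, u=(0, 1, 0))
        assert res.angle_deg == pytest.approx(90.0, abs=1e-9)

    @pytest.mark.parametrize("theta", [0, 15, 30, 45, 60, 90])
    def test_rotation_recovery(self, theta):
        # leading axis rotated by theta in the xz-plane
        d = (math.sin(math.radians(theta)), 0.0, math.cos(math.radians(theta)))
        mask = digitized_ellipsoid((45, 15, 15), direction=d, shape=(110, 110, 110))
        res = mm.orientation_angle(mask, u=(0, 0, 1))
        assert res.angle_deg == pytest.approx(theta, abs=2.0)

    def test_eigenvalues_descending(self):
        mask = digitized_ellipsoid((30, 14, 7), direction=(0, 0, 1))
        res = mm.orientation_angle(mask)
        assert res.eigenvalues[0] >= res.eigenvalues[1] >= res.eigenvalues[2] >= 0

    def test_scale_invariance(self):
        mask1 = digitized_ellipsoid((30, 10, 10), direction=(0, 0, 1))
        mask2 = BinaryMask(mask1.voxels, 5.0)
        a1 = mm.orientation_angle(mask1, u=(0, 1, 1)).angle_deg
        a2 = mm.orientation_angle(mask2, u=(0, 1, 1)).angle_deg
        assert a1 == pytest.approx(a2, abs=1e-9)

    def test_degenerate_rejected(self):
        vox = np.zeros((5, 5, 5), bool)
        vox[2, 2, 2] = True
        with pytest.raises(ValueError):
            mm.orientation_angle(BinaryMask(vox, 1.0))

    def test_zero_axis_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            mm.orientation_angle(digitized_ball(5), u=(0, 0, 0))


class TestProportion:
    def test_printed_formula(self):
        assert mm.proportion_in_ventricle(1.0, 3.0) == pytest.approx(0.25)

    def test_extremes(self):
        assert mm.proportion_in_ventricle(0.0, 2.0) == 0.0
        assert mm.proportion_in_ventricle(2.0, 0.0) == 1.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            mm.proportion_in_ventricle(0.0, 0.0)


class TestSplitByPlane:
    def test_ball_mid_plane_half_half(self):
        mask = digitized_ball(10)
        centre = (np.array(mask.shape) - 1) / 2 * mask.voxel_size_mm
        rostral, caudal = mm.split_by_plane(mask, centre, (1.0, 0.0, 0.0))
        total = mask.count()
        # symmetric up to the one-voxel layer on the plane
        layer = np.count_nonzero(
            mask.voxels[(mask.shape[0] - 1) // 2]
        )
        assert abs(rostral.count() - caudal.count()) <= layer

    def test_exact_volume_conservation(self):
        rng = np.random.default_rng(0)
        vox = rng.random((15, 15, 15)) < 0.4
        mask = BinaryMask(vox, 0.7)
        r, c = mm.split_by_plane(mask, (5.0, 5.0, 5.0), (1.0, 2.0, -0.5))
        assert r.count() + c.count() == mask.count()
        assert not np.any(r.voxels & c.voxels)

    def test_plane_outside_bbox(self):
        mask = digitized_ball(5)
        r, c = mm.split_by_plane(mask, (-100.0, 0.0, 0.0), (1.0, 0.0, 0.0))
        assert r.count() == mask.count()
        assert c.count() == 0

    def test_zero_normal_rejected(self):
        with pytest.raises(ValueError):
            mm.split_by_plane(digitized_ball(3), (0, 0, 0), (0, 0, 0))


class TestLateralMeasures:
    @staticmethod
    def _measure(out):
        centre = (np.array(out.plexus_truth.shape) - 1) / 2 * 0.004
        return mm.lateral_measures(
            out.plexus_truth,
            out.ventricle_truth,
            midline_point_mm=centre,
            midline_normal_mm=(0.0, 0.0, 1.0),
        )

    def test_mirror_symmetry(self, noiseless_out):
        lm = self._measure(noiseless_out)
        assert abs(lm.left_length_mm - lm.right_length_mm) <= 2 * 0.004

    def test_longer_branches_measured_longer(self):
        short = ph.generate_embryo_phantom(
            ph.PhantomSpec(noise_sigma=0, branch_length_frac=0.4)
        )
        long = ph.generate_embryo_phantom(
            ph.PhantomSpec(noise_sigma=0, branch_length_frac=0.8)
        )
        lm_s = self._measure(short)
        lm_l = self._measure(long)
        assert lm_l.total_length_mm > lm_s.total_length_mm

    def test_plexus_within_ventricle_extent(self, noiseless_out):
        lm = self._measure(noiseless_out)
        assert lm.total_length_mm <= lm.ventricle_length_mm
        assert lm.total_length_mm >= lm.central_length_mm

    def test_empty_side_flagged(self):
        vox = np.zeros((10, 10, 10), bool)
        vox[4:6, 4:6, 6:9] = True  # everything on one side of x-midline
        mask = BinaryMask(vox, 1.0)
        with pytest.warns(UserWarning, match="side is empty"):
            lm = mm.lateral_measures(
                mask, mask, (4.5, 4.5, 0.0), (0.0, 0.0, 1.0)
            )
        assert lm.left_length_mm == 0.0
        assert math.isnan(lm.left_angle_deg)


class TestBuildReport:
    def test_phantom_report_all_finite(self, noiseless_out):
        rep = mm.build_report(
            noiseless_out.plexus_truth, noiseless_out.ventricle_truth
        )
        for name in (
            "volume_mm3",
            "surface_area_mm2",
            "outgrowth_angle_deg",
            "ventricle_volume_mm3",
            "proportion",
            "rostral_volume_mm3",
            "caudal_volume_mm3",
            "left_length_mm",
            "right_length_mm",
            "left_angle_deg",
            "right_angle_deg",
            "central_length_mm",
            "total_length_mm",
            "ventricle_length_mm",
        ):
            assert math.isfinite(getattr(rep, name)), name
        assert 0.0 <= rep.proportion <= 1.0

    def test_deterministic(self, noiseless_out):
        r1 = mm.build_report(noiseless_out.plexus_truth, noiseless_out.ventricle_truth)
        r2 = mm.build_report(noiseless_out.plexus_truth, noiseless_out.ventricle_truth)
        assert r1 == r2

    def test_split_conservation_in_report(self, noiseless_out):
        rep = mm.build_report(noiseless_out.plexus_truth, noiseless_out.ventricle_truth)
        assert rep.rostral_volume_mm3 + rep.caudal_volume_mm3 == pytest.approx(
            rep.volume_mm3
        )
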