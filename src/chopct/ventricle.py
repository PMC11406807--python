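"""Localization and segmentation of the 4th-ventricle lumen.

Pipeline: median-filter + crop preprocessing, low-intensity thresholding,
morphological separation into connected components, rigid ICP registration of
each candidate against a reference mask with Hausdorff-distance selection,
and active-contour refinement on the complemented grayscale image.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from ._morph import ball_open, label_components
from .types import BinaryMask, PointCloud, RigidTransform, VolumeImage

__all__ = [
    "SegmentationParams",
    "preprocess",
    "threshold_low",
    "separate_components",
    "mask_to_pointcloud",
    "icp_register",
    "hausdorff",
    "select_ventricle",
    "refine_active_contour",
]

log = logging.getLogger(__name__)


@dataclass
class SegmentationParams:
    """Tunable parameters of the ventricle localization stage."""

    median_window: int = 3
    crop_box: Optional[tuple[tuple[int, int], ...]] = None
    threshold_method: str = "otsu"  # or "percentile"
    threshold_percentile: float = 5.0
    separation_radius: float = 2.0
    connectivity: int = 26
    icp_max_iter: int = 50
    icp_tol: float = 1e-6
    ac_iterations: int = 10
    ac_smoothing: int = 1
    stage: str = "E13.5"
    hausdorff_subsample: int = 5000
    hausdorff_seed: int = 0

    def __post_init__(self) -> None:
        if self.median_window < 1 or self.median_window % 2 == 0:
            raise ValueError("median_window must be odd and >= 1")
        if not (0 < self.threshold_percentile < 100):
            raise ValueError("threshold_percentile must be in (0, 100)")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        if self.icp_max_iter < 1 or self.ac_iterations < 0:
            raise ValueError("iteration counts must be >= 1 (ac may be 0)")


def preprocess(image: VolumeImage, p: SegmentationParams) -> VolumeImage:
    """3D median filter along all three axes, then optional crop."""
    if any(p.median_window > s for s in image.shape):
        raise ValueError(
            f"median window {p.median_window} does not fit image {image.shape}"
        )
    out = ndimage.median_filter(image.voxels, size=p.median_window)
    if p.crop_box is not None:
        if len(p.crop_box) != 3:
            raise ValueError("crop_box needs one (lo, hi) pair per axis")
        slices = []
        for ax, (lo, hi) in enumerate(p.crop_box):
            if not (0 <= lo < hi <= image.shape[ax]):
                raise ValueError(
                    f"crop_box {p.crop_box} outside image of shape {image.shape}"
                )
            slices.append(slice(lo, hi))
        out = out[tuple(slices)]
    return VolumeImage(out, image.voxel_size_mm)


def threshold_low(image: VolumeImage, p: SegmentationParams) -> BinaryMask:
    """Extract low-intensity voxels (CSF-filled cavities are the darkest)."""
    vox = image.voxels
    if vox.max() == vox.min():
        warnings.warn("constant image: low-intensity mask is empty", stacklevel=2)
        return BinaryMask(np.zeros(image.shape, bool), image.voxel_size_mm)
    if p.threshold_method == "otsu":
        from skimage.filters import threshold_otsu

        thr = threshold_otsu(vox)
    elif p.threshold_method == "percentile":
        thr = np.percentile(vox, p.threshold_percentile)
    else:
        raise ValueError(f"unknown threshold_method {p.threshold_method!r}")
    return BinaryMask(vox < thr, image.voxel_size_mm)


def separate_components(mask: BinaryMask, p: SegmentationParams) -> list[BinaryMask]:
    """Morphological opening, then connected components, largest first.

    The opening severs thin false connections between the 4th ventricle and
    the rest of the ventricular system before components are computed.
    """
    if mask.count() == 0:
        raise ValueError("cannot separate an empty mask")
    opened = ball_open(mask.voxels, p.separation_radius)
    if not opened.any():
        warnings.warn("opening removed all voxels", stacklevel=2)
        return []
    labels, n = label_components(opened, p.connectivity)
    counts = np.bincount(labels.ravel())
    order = np.argsort(counts[1:])[::-1] + 1
    return [
        BinaryMask(labels == lab, mask.voxel_size_mm) for lab in order
    ]


def mask_to_pointcloud(mask: BinaryMask) -> PointCloud:
    """One point per foreground voxel centre, in (z, y, x) mm coordinates."""
    if mask.count() == 0:
        raise ValueError("cannot convert an empty mask to a point cloud")
    idx = np.argwhere(mask.voxels)
    return PointCloud(idx * mask.voxel_size_mm)


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping src onto dst (no reflection)."""
    c_src = src.mean(axis=0)
    c_dst = dst.mean(axis=0)
    H = (src - c_src).T @ (dst - c_dst)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = c_dst - R @ c_src
    return RigidTransform(R, t)


def icp_register(
    source: PointCloud, target: PointCloud, p: SegmentationParams
) -> tuple[RigidTransform, float]:
    """Point-to-point ICP: rigid transform mapping source onto target.

    Alternates nearest-neighbour matching with Kabsch alignment, starting
    from a centroid alignment.  Stops when the relative RMSE change falls
    below ``icp_tol`` or after ``icp_max_iter`` iterations.  Returns the
    final transform and RMSE (mm).
    """
    src = source.points
    dst = target.points
    if len(src) < 3 or len(dst) < 3:
        raise ValueError("ICP needs at least 3 points in each cloud")
    tree = cKDTree(dst)
    transform = RigidTransform(np.eye(3), dst.mean(axis=0) - src.mean(axis=0))
    moved = transform.apply(src)
    prev_rmse = None
    rmse = np.inf
    converged = False
    for _ in range(p.icp_max_iter):
        dists, nn = tree.query(moved)
        rmse = float(np.sqrt(np.mean(dists**2)))
        if rmse == 0.0 or (
            prev_rmse is not None
            and abs(prev_rmse - rmse) <= p.icp_tol * max(prev_rmse, 1e-30)
        ):
            converged = True
            break
        prev_rmse = rmse
        transform = _kabsch(src, dst[nn])
        moved = transform.apply(src)
    if not converged:
        log.warning("ICP did not converge in %d iterations (rmse=%g)", p.icp_max_iter, rmse)
    return transform, rmse


def hausdorff(
    a: PointCloud,
    b: PointCloud,
    subsample: Optional[int] = None,
    seed: int = 0,
) -> float:
    """Symmetric Hausdorff distance between two point clouds (mm, Euclidean).

    With ``subsample`` set, each cloud is reduced to at most that many
    seeded-random points first (tractability on voxel-dense clouds); without
    it the distance is exact.
    """
    pa, pb = a.points, b.points
    if subsample is not None:
        rng = np.random.default_rng(seed)
        if len(pa) > subsample:
            pa = pa[rng.choice(len(pa), subsample, replace=False)]
        if len(pb) > subsample:
            pb = pb[rng.choice(len(pb), subsample, replace=False)]
    ta, tb = cKDTree(pa), cKDTree(pb)
    d_ab = ta.query(pb)[0].max()
    d_ba = tb.query(pa)[0].max()
    return float(max(d_ab, d_ba))


def select_ventricle(
    candidates: list[BinaryMask], reference: BinaryMask, p: SegmentationParams
) -> BinaryMask:
    """Pick the candidate most similar to the reference ventricle mask.

    Each candidate is ICP-registered to the reference; the candidate with the
    smallest post-registration Hausdorff distance wins and is returned
    untransformed, in image space.  Ties go to the first (largest) candidate.
    """
    if not candidates:
        raise ValueError("no candidate components to select from")
    ref_cloud = mask_to_pointcloud(reference)
    rng = np.random.default_rng(p.hausdorff_seed)
    ref_pts = ref_cloud.points
    if len(ref_pts) > p.hausdorff_subsample:
        ref_pts = ref_pts[
            rng.choice(len(ref_pts), p.hausdorff_subsample, replace=False)
        ]
    ref_sub = PointCloud(ref_pts)

    best_idx, best_d = None, np.inf
    for i, cand in enumerate(candidates):
        try:
            cloud = mask_to_pointcloud(cand)
            pts = cloud.points
            if len(pts) > p.hausdorff_subsample:
                pts = pts[rng.choice(len(pts), p.hausdorff_subsample, replace=False)]
            sub = PointCloud(pts)
            transform, _ = icp_register(sub, ref_sub, p)
            moved = PointCloud(transform.apply(sub.points))
            d = hausdorff(moved, ref_sub)
        except Exception as exc:  # registration failure on one candidate
            log.warning("candidate %d registration failed: %s", i, exc)
            continue
        if d < best_d - 1e-12:
            best_idx, best_d = i, d
        elif best_idx is not None and abs(d - best_d) <= 1e-12:
            log.info("Hausdorff tie between candidates %d and %d; keeping first", best_idx, i)
    if best_idx is None:
        raise ValueError("all candidate registrations failed")
    log.info("selected candidate %d (Hausdorff %.4g mm)", best_idx, best_d)
    return candidates[best_idx]


def refine_active_contour(
    image: VolumeImage, mask: BinaryMask, p: SegmentationParams
) -> BinaryMask:
    """Chan–Vese refinement on the complemented image, seeded from the mask.

    The morphological Chan–Vese model is evolved ``ac_iterations`` steps on
    ``max(image) - image`` (the lumen is dark, so it is bright on the
    complement).  If the contour vanishes or drifts away from the input
    (Dice < 0.5), the input mask is returned with a warning.
    """
    if mask.count() == 0:
        raise ValueError("cannot refine an empty mask")
    if p.ac_iterations == 0:
        return BinaryMask(mask.voxels.copy(), mask.voxel_size_mm)
    from skimage.segmentation import morphological_chan_vese

    complement = image.voxels.max() - image.voxels
    result = morphological_chan_vese(
        complement,
        num_iter=p.ac_iterations,
        init_level_set=mask.voxels,
        smoothing=p.ac_smoothing,
    ).astype(bool)
    inter = np.count_nonzero(result & mask.voxels)
    denom = np.count_nonzero(result) + mask.count()
    dice = 2 * inter / denom if denom else 0.0
    if not result.any() or dice < 0.5:
        warnings.warn(
            "active contour vanished or diverged; returning input mask", stacklevel=2
        )
        return BinaryMask(mask.voxels.copy(), mask.voxel_size_mm)
    return BinaryMask(result, mask.voxel_size_mm)
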