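"""Plexus extraction from the localized ventricle.

The primary mask (all stages) comes from morphological closing of the
ventricle lumen: closing fills the gap the bright plexus body carves out of
the dark lumen, and subtracting the original lumen exposes that gap.  For
E13.5 a fully automatic extension based on local range analysis and an active
contour recovers the whole structure; for E15.5/E17.5 the pipeline stops at
the primary mask, which is exported for manual branch segmentation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._morph import ball_close, ball_open, label_components, largest_component
from .types import BinaryMask, VolumeImage
from .ventricle import (
    SegmentationParams,
    preprocess,
    refine_active_contour,
    select_ventricle,
    separate_components,
    threshold_low,
)

__all__ = [
    "PlexusParams",
    "primary_mask",
    "local_range",
    "segment_e13",
    "merge_manual",
    "run_pipeline",
    "PipelineResult",
]

log = logging.getLogger(__name__)


@dataclass
class PlexusParams:
    """Tunable parameters of the plexus segmentation stage."""

    closing_radius: float = 5.0
    range_window: int = 3
    opening_radius: float = 1.0
    e13_closing_radius: float = 3.0
    high_intensity_method: str = "otsu_within_mask"  # or "percentile"
    high_intensity_percentile: float = 75.0
    keep_largest: int = 1
    ac_iterations: int = 40
    ac_smoothing: int = 0
    ac_on_complement: bool = False

    def __post_init__(self) -> None:
        if self.closing_radius < 1 or self.opening_radius < 1:
            raise ValueError("radii must be >= 1")
        if self.range_window < 1 or self.range_window % 2 == 0:
            raise ValueError("range_window must be odd and >= 1")
        if self.keep_largest < 1:
            raise ValueError("keep_largest must be >= 1")


def _keep_largest_k(mask: np.ndarray, k: int, connectivity: int = 26) -> np.ndarray:
    labels, n = label_components(mask, connectivity)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = np.argsort(counts)[::-1][:k]
    return np.isin(labels, keep[counts[keep] > 0])


def _high_threshold(values: np.ndarray, p: PlexusParams) -> float:
    if p.high_intensity_method == "otsu_within_mask":
        from skimage.filters import threshold_otsu

        if values.max() == values.min():
            return values.max()  # degenerate: nothing exceeds it
        return float(threshold_otsu(values))
    if p.high_intensity_method == "percentile":
        return float(np.percentile(values, p.high_intensity_percentile))
    raise ValueError(f"unknown high_intensity_method {p.high_intensity_method!r}")


def primary_mask(
    image: VolumeImage, ventricle: BinaryMask, p: PlexusParams
) -> BinaryMask:
    """Primary plexus mask: closing gap of the lumen, high-intensity filtered.

    ``close(ventricle) - ventricle`` yields the gap region; within it, voxels
    above a high-intensity threshold are kept and the largest connected
    component(s) selected.  The output never intersects the ventricle lumen.
    """
    if ventricle.count() == 0:
        raise ValueError("ventricle mask is empty")
    closed = ball_close(ventricle.voxels, p.closing_radius)
    gap = closed & ~ventricle.voxels
    if not gap.any():
        warnings.warn("closing filled no gaps; primary mask is empty", stacklevel=2)
        return BinaryMask(np.zeros(ventricle.shape, bool), ventricle.voxel_size_mm)
    thr = _high_threshold(image.voxels[gap], p)
    bright = gap & (image.voxels > thr)
    if not bright.any():
        warnings.warn("no high-intensity voxels in the gap region", stacklevel=2)
        return BinaryMask(np.zeros(ventricle.shape, bool), ventricle.voxel_size_mm)
    kept = _keep_largest_k(bright, p.keep_largest)
    return BinaryMask(kept, ventricle.voxel_size_mm)


def local_range(image: VolumeImage, window: int = 3) -> VolumeImage:
    """Per-voxel (max - min) over a cubic neighborhood."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if any(window > s for s in image.shape):
        raise ValueError(f"window {window} does not fit image {image.shape}")
    mx = ndimage.maximum_filter(image.voxels, size=window)
    mn = ndimage.minimum_filter(image.voxels, size=window)
    return VolumeImage(mx - mn, image.voxel_size_mm)


def segment_e13(
    image: VolumeImage, primary: BinaryMask, p: PlexusParams
) -> BinaryMask:
    """Full automatic E13.5 plexus segmentation, extending the primary mask.

    Steps: local range analysis; threshold at the mean range within the
    primary mask; keep connected regions intersecting the primary mask;
    morphological closing; remove low-intensity voxels; morphological
    opening; keep the largest connected component; active-contour refinement.
    If any step empties the mask, the last nonempty stage is returned with a
    diagnostic naming the step.
    """
    if primary.count() == 0:
        raise ValueError("primary mask is empty")
    vs = primary.voxel_size_mm
    last_good = primary.voxels

    def bail(step: str) -> BinaryMask:
        warnings.warn(
            f"segment_e13: step {step!r} produced an empty mask; "
            "returning the last nonempty stage",
            stacklevel=3,
        )
        return BinaryMask(largest_component(last_good), vs)

    # 1. range image, thresholded at the mean range inside the primary mask
    rng_img = local_range(image, p.range_window).voxels
    thr = float(rng_img[primary.voxels].mean())
    high_range = rng_img > thr
    if not high_range.any():
        return bail("range-threshold")

    # 2. connected regions intersecting the primary mask
    labels, n = label_components(high_range, 26)
    hit = np.unique(labels[primary.voxels])
    hit = hit[hit > 0]
    if hit.size == 0:
        return bail("intersect-primary")
    region = np.isin(labels, hit)
    last_good = region

    # 3. morphological closing
    region = ball_close(region, p.e13_closing_radius)
    last_good = region

    # 4. remove low-intensity voxels; the primary mask is a verified plexus
    # sample, so the cut-off sits halfway between its mean intensity and the
    # global median (the surrounding-tissue level, since tissue dominates)
    prim_mean = float(image.voxels[primary.voxels].mean())
    tissue_level = float(np.median(image.voxels))
    low_cut = 0.5 * (prim_mean + tissue_level)
    bright = region & (image.voxels > low_cut)
    if not bright.any():
        return bail("remove-low-intensity")
    last_good = bright

    # 5. opening to shed voxels of other tissues
    opened = ball_open(bright, p.opening_radius)
    if not opened.any():
        return bail("opening")
    last_good = opened

    # 6. largest connected component
    main = largest_component(opened)
    last_good = main

    # 7. active contour on the (optionally complemented) grayscale image
    if p.ac_iterations > 0:
        from skimage.segmentation import morphological_chan_vese

        data = image.voxels.max() - image.voxels if p.ac_on_complement else image.voxels
        refined = morphological_chan_vese(
            data,
            num_iter=p.ac_iterations,
            init_level_set=main,
            smoothing=p.ac_smoothing,
        ).astype(bool)
        if not refined.any():
            return bail("active-contour")
        main = largest_component(refined)

    return BinaryMask(main, vs)


def merge_manual(primary: BinaryMask, branches: BinaryMask) -> tuple[BinaryMask, int]:
    """Voxelwise union of the primary mask with manual branch masks.

    Returns the merged mask and the number of voxels the branches added.
    """
    if primary.shape != branches.shape or not np.isclose(
        primary.voxel_size_mm, branches.voxel_size_mm
    ):
        raise ValueError(
            f"geometry mismatch: {primary.shape}@{primary.voxel_size_mm} vs "
            f"{branches.shape}@{branches.voxel_size_mm}"
        )
    union = primary.voxels | branches.voxels
    added = int(np.count_nonzero(union) - primary.count())
    return BinaryMask(union, primary.voxel_size_mm), added


@dataclass
class PipelineResult:
    plexus: BinaryMask
    ventricle: BinaryMask
    stage_log: list[dict] = field(default_factory=list)


def run_pipeline(
    image: VolumeImage,
    reference: BinaryMask,
    stage: str,
    seg_params: SegmentationParams | None = None,
    plexus_params: PlexusParams | None = None,
    manual_branches: BinaryMask | None = None,
) -> PipelineResult:
    """Run the full segmentation chain for one sample.

    ``stage='E13.5'`` runs preprocess → ventricle localization → primary mask
    → full automatic segmentation.  ``stage='E15.5_17.5'`` stops after the
    primary mask (optionally merging externally segmented branches).  Each
    executed stage is logged with its output-mask voxel count.
    """
    if stage not in ("E13.5", "E15.5_17.5"):
        raise ValueError(f"stage must be 'E13.5' or 'E15.5_17.5', got {stage!r}")
    sp = seg_params or SegmentationParams(stage=stage)
    pp = plexus_params or PlexusParams()
    stage_log: list[dict] = []

    def record(name: str, mask: BinaryMask | None = None, **extra) -> None:
        entry = {"stage": name, **extra}
        if mask is not None:
            entry["voxels"] = mask.count()
        stage_log.append(entry)

    def run_step(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    filtered = run_step("preprocess", preprocess, image, sp)
    record("preprocess", extra_shape=filtered.shape)

    low = run_step("threshold_low", threshold_low, filtered, sp)
    record("threshold_low", low)

    components = run_step("separate_components", separate_components, low, sp)
    record("separate_components", n_components=len(components))

    selected = run_step("select_ventricle", select_ventricle, components, reference, sp)
    record("select_ventricle", selected)

    ventricle_mask = run_step(
        "refine_active_contour", refine_active_contour, filtered, selected, sp
    )
    record("refine_active_contour", ventricle_mask)

    primary = run_step("primary_mask", primary_mask, filtered, ventricle_mask, pp)
    record("primary_mask", primary)

    if stage == "E13.5":
        final = run_step("segment_e13", segment_e13, filtered, primary, pp)
        record("segment_e13", final)
    else:
        final = primary
        if manual_branches is not None:
            final, added = run_step("merge_manual", merge_manual, primary, manual_branches)
            record("merge_manual", final, added_voxels=added)

    return PipelineResult(plexus=final, ventricle=ventricle_mask, stage_log=stage_log)
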