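"""Image-quality metrics gating segmentation."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import BinaryMask, VolumeImage

__all__ = ["CnrResult", "contrast_to_noise"]


@dataclass
class CnrResult:
    """Contrast-to-noise ratio between a foreground and a comparison region.

    ``ratio = |mean_fg - mean_bg| / sigma_bg``; ``decibels = 20*log10(ratio)``
    (amplitude convention; ``decibels_power = 10*log10(ratio)`` is also
    provided since the source convention is ambiguous).
    """

    mean_fg: float
    mean_bg: float
    sigma_bg: float
    ratio: float
    decibels: float
    decibels_power: float
    sigma_zero: bool = False


def contrast_to_noise(
    image: VolumeImage,
    fg: BinaryMask,
    bg: BinaryMask,
    population_std: bool = True,
) -> CnrResult:
    """Compute the contrast-to-noise ratio between two masked regions.

    The comparison region ``bg`` may be either adjacent tissue or background
    selected outside the specimen; the formula is the same.

    Raises on empty masks.  ``sigma_bg == 0`` yields an infinite ratio with
    the ``sigma_zero`` flag set.
    """
    for name, m in (("fg", fg), ("bg", bg)):
        if m.count() == 0:
            raise ValueError(f"{name} mask is empty")
        if m.shape != image.shape:
            raise ValueError(
                f"{name} mask shape {m.shape} does not match image {image.shape}"
            )
    fg_vals = image.voxels[fg.voxels]
    bg_vals = image.voxels[bg.voxels]
    mean_fg = float(fg_vals.mean())
    mean_bg = float(bg_vals.mean())
    sigma_bg = float(bg_vals.std(ddof=0 if population_std else 1))
    if sigma_bg == 0.0:
        ratio = math.inf if mean_fg != mean_bg else 0.0
        return CnrResult(mean_fg, mean_bg, sigma_bg, ratio, math.inf, math.inf, True)
    ratio = abs(mean_fg - mean_bg) / sigma_bg
    db20 = 20.0 * math.log10(ratio) if ratio > 0 else -math.inf
    db10 = 10.0 * math.log10(ratio) if ratio > 0 else -math.inf
    return CnrResult(mean_fg, mean_bg, sigma_bg, ratio, db20, db10)
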