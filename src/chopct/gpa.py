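"""Landmark-based shape comparison via Generalized Procrustes Analysis.

Alignment removes translation, rotation and (by default) scale; reflections
are never allowed (det(R) = +1), since anatomical landmark sets must not
mirror.  The Procrustes distance reported per sample is the sum of squared
landmark-wise differences between the aligned configuration and the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import LandmarkConfiguration

__all__ = [
    "GpaResult",
    "procrustes_pair",
    "generalized_procrustes",
    "gpa_against_reference",
    "subset_landmarks",
]


@dataclass
class GpaResult:
    mean_config: np.ndarray  # (K, 3), centered at the origin
    aligned: list[np.ndarray]
    distances: np.ndarray  # per-sample Procrustes distance (sum of squares)
    labels: list[str]
    iterations: int
    converged: bool


def _check_config(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=np.float64)
    if pts.shape[0] < 3:
        raise ValueError("shape analysis needs at least 3 landmarks")
    centered = pts - pts.mean(axis=0)
    if np.allclose(centered, 0):
        raise ValueError("degenerate configuration: all landmarks coincident")
    return pts


def _centroid_size(points: np.ndarray) -> float:
    centered = points - points.mean(axis=0)
    return float(np.sqrt((centered**2).sum()))


def _optimal_rotation(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Rotation (det = +1) minimizing ||dst - src @ R.T||, both centered."""
    H = src.T @ dst
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    return Vt.T @ np.diag([1.0, 1.0, d]) @ U.T


def procrustes_pair(
    x: LandmarkConfiguration,
    y: LandmarkConfiguration,
    allow_scale: bool = True,
) -> tuple[np.ndarray, float]:
    """Align ``y`` onto ``x``; return (aligned_y, Procrustes distance).

    ``y`` is centered, optimally rotated (and scaled, when allowed) onto the
    centered-then-restored ``x``; the distance is the sum of squared
    landmark-wise differences after alignment.
    """
    xp = _check_config(x.points)
    yp = _check_config(y.points)
    if xp.shape != yp.shape:
        raise ValueError(f"landmark counts differ: {xp.shape[0]} vs {yp.shape[0]}")
    cx, cy = xp.mean(axis=0), yp.mean(axis=0)
    xc, yc = xp - cx, yp - cy
    R = _optimal_rotation(yc, xc)
    rotated = yc @ R.T
    if allow_scale:
        s = float((rotated * xc).sum() / (yc**2).sum())
    else:
        s = 1.0
    aligned = s * rotated + cx
    dist = float(((xp - aligned) ** 2).sum())
    return aligned, dist


def generalized_procrustes(
    configs: list[LandmarkConfiguration],
    tol: float = 1e-6,
    max_iter: int = 100,
    remove_scale: bool = True,
) -> GpaResult:
    """Iterative GPA over two or more landmark configurations.

    The initial mean is the first configuration; all configurations are
    aligned to the mean, the mean is re-estimated from the aligned set, and
    the loop repeats until the mean moves less than ``tol`` (mm) or
    ``max_iter`` is reached.  Per-sample distances are computed against the
    converged mean.  With ``remove_scale`` each configuration is normalized
    to unit centroid size before alignment.
    """
    if len(configs) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    k = len(configs[0])
    shapes = []
    for c in configs:
        pts = _check_config(c.points)
        if pts.shape[0] != k:
            raise ValueError("all configurations must have the same landmark count")
        centered = pts - pts.mean(axis=0)
        if remove_scale:
            centered = centered / _centroid_size(centered)
        shapes.append(centered)

    mean = shapes[0].copy()
    iterations = 0
    converged = False
    aligned = shapes
    for iterations in range(1, max_iter + 1):
        aligned = [s @ _optimal_rotation(s, mean).T for s in shapes]
        new_mean = np.mean(aligned, axis=0)
        new_mean -= new_mean.mean(axis=0)
        if remove_scale:
            size = _centroid_size(new_mean)
            if size > 0:
                new_mean = new_mean / size
        shift = float(np.linalg.norm(new_mean - mean))
        mean = new_mean
        if shift < tol:
            converged = True
            break
    aligned = [s @ _optimal_rotation(s, mean).T for s in shapes]
    distances = np.array([float(((a - mean) ** 2).sum()) for a in aligned])
    return GpaResult(
        mean_config=mean,
        aligned=aligned,
        distances=distances,
        labels=[c.label for c in configs],
        iterations=iterations,
        converged=converged,
    )


def gpa_against_reference(
    configs: list[LandmarkConfiguration],
    reference_mean: LandmarkConfiguration,
    remove_scale: bool = True,
) -> GpaResult:
    """Single-pass alignment of each configuration to a fixed reference mean.

    No mean re-estimation takes place; distances are against the reference.
    Accepts a single configuration.
    """
    if len(configs) < 1:
        raise ValueError("need at least one configuration")
    ref = _check_config(reference_mean.points)
    k = ref.shape[0]
    mean = ref - ref.mean(axis=0)
    if remove_scale:
        mean = mean / _centroid_size(mean)
    aligned = []
    for c in configs:
        pts = _check_config(c.points)
        if pts.shape[0] != k:
            raise ValueError("landmark count differs from the reference")
        centered = pts - pts.mean(axis=0)
        if remove_scale:
            centered = centered / _centroid_size(centered)
        aligned.append(centered @ _optimal_rotation(centered, mean).T)
    distances = np.array([float(((a - mean) ** 2).sum()) for a in aligned])
    return GpaResult(
        mean_config=mean,
        aligned=aligned,
        distances=distances,
        labels=[c.label for c in configs],
        iterations=1,
        converged=True,
    )


def subset_landmarks(
    cfg: LandmarkConfiguration, indices: list[int]
) -> LandmarkConfiguration:
    """Sub-configuration at the given 0-based indices, preserving order."""
    if len(indices) < 3:
        raise ValueError("a subset needs at least 3 landmarks")
    if len(set(indices)) != len(indices):
        raise ValueError("duplicate landmark indices")
    k = len(cfg)
    for i in indices:
        if not (0 <= i < k):
            raise ValueError(f"landmark index {i} out of range [0, {k})")
    labels = (
        [cfg.point_labels[i] for i in indices] if cfg.point_labels is not None else None
    )
    return LandmarkConfiguration(
        cfg.points[list(indices)],
        label=cfg.label,
        point_labels=labels,
        coordinate_system=cfg.coordinate_system,
    )
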