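"""The quantitative morphometric criterion panel computed from final masks.

Includes voxel-count volume, Crofton-formula surface area, principal-axis
outgrowth angle, ventricle-proportion, rostrocaudal plane split, and
automated analogues of the manual transverse-plane length/angle measures.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._morph import label_components
from .types import BinaryMask, MorphometryReport

__all__ = [
    "compute_volume",
    "crofton_area",
    "orientation_angle",
    "OrientationResult",
    "proportion_in_ventricle",
    "split_by_plane",
    "lateral_measures",
    "LateralMeasures",
    "MorphometryConfig",
    "build_report",
    "CROFTON_DIRECTIONS_13",
]

log = logging.getLogger(__name__)


def compute_volume(mask: BinaryMask) -> float:
    """Volume in mm³: foreground voxel count times the voxel volume."""
    return mask.count() * mask.voxel_size_mm**3


# ---------------------------------------------------------------------------
# Crofton surface area
# ---------------------------------------------------------------------------

# 13 unsigned discrete directions of the 26-neighborhood with their spherical
# Voronoi weights (fraction of the unit sphere closest to each +-direction
# pair): 3 axes, 6 face diagonals, 4 cube diagonals.  Weights sum to 1.
_W_AXIS = 2 * 0.04577789120476977
_W_FACE = 2 * 0.03698062787608186
_W_CUBE = 2 * 0.03519563978232843
CROFTON_DIRECTIONS_13: list[tuple[tuple[int, int, int], float]] = (
    [((1, 0, 0), _W_AXIS), ((0, 1, 0), _W_AXIS), ((0, 0, 1), _W_AXIS)]
    + [
        ((1, 1, 0), _W_FACE),
        ((1, -1, 0), _W_FACE),
        ((1, 0, 1), _W_FACE),
        ((1, 0, -1), _W_FACE),
        ((0, 1, 1), _W_FACE),
        ((0, 1, -1), _W_FACE),
    ]
    + [
        ((1, 1, 1), _W_CUBE),
        ((1, 1, -1), _W_CUBE),
        ((1, -1, 1), _W_CUBE),
        ((1, -1, -1), _W_CUBE),
    ]
)

_DIRECTIONS_3 = [((1, 0, 0), 1 / 3), ((0, 1, 0), 1 / 3), ((0, 0, 1), 1 / 3)]


def _run_count(mask: np.ndarray, d: tuple[int, int, int]) -> int:
    """Number of foreground runs along all discrete lines in direction ``d``.

    A run starts at a foreground voxel whose predecessor along ``d`` is
    background (or outside the grid); counting run starts equals run-length
    encoding the lines and counting elements.
    """
    shifted = np.zeros_like(mask)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, step in enumerate(d):
        if step == 1:
            dst[ax] = slice(1, None)
            src[ax] = slice(None, -1)
        elif step == -1:
            dst[ax] = slice(None, -1)
            src[ax] = slice(1, None)
        elif step != 0:
            raise ValueError("direction components must be in {-1, 0, 1}")
    shifted[tuple(dst)] = mask[tuple(src)]
    return int(np.count_nonzero(mask & ~shifted))


def crofton_area(mask: BinaryMask, directions: int = 3) -> float:
    """Stereological (Crofton) surface-area estimate in mm².

    For each test-line direction *k*, foreground intercepts are counted by
    run-length encoding along all discrete lines parallel to *k*; the area is
    ``4 * sum_k (c_k / lambda_k) * chi_k`` where ``lambda_k`` is the line
    density (voxel spacing along *k* divided by the voxel volume) and ``c_k``
    the direction weight (1/3 each for the default 3 axis-aligned directions;
    spherical Voronoi weights for the 13-direction mode).
    """
    if directions == 3:
        dirs = _DIRECTIONS_3
    elif directions == 13:
        dirs = CROFTON_DIRECTIONS_13
    else:
        raise ValueError("directions must be 3 or 13")
    if mask.count() == 0:
        return 0.0
    vs = mask.voxel_size_mm
    voxel_volume = vs**3
    total = 0.0
    for d, c in dirs:
        spacing = math.sqrt(sum(x * x for x in d)) * vs
        lam = spacing / voxel_volume  # line density per unit area
        chi = _run_count(mask.voxels, d)
        total += (c / lam) * chi
    return 4.0 * total


# ---------------------------------------------------------------------------
# Orientation / outgrowth angle
# ---------------------------------------------------------------------------


@dataclass
class OrientationResult:
    """Principal-axis orientation of a voxel cloud against a reference axis."""

    eigenvalues: np.ndarray  # descending
    eigenvectors: np.ndarray  # rows v1, v2, v3, unit length
    reference_axis: np.ndarray
    angle_deg: float
    ambiguous: bool = False


def orientation_angle(mask: BinaryMask, u: np.ndarray = (0.0, 0.0, 1.0)) -> OrientationResult:
    """Angle between the first principal axis of the mask and axis ``u``.

    The coordinate covariance matrix of the foreground voxels (mm) is
    eigen-decomposed; eigenvalues are sorted descending and the angle between
    the leading eigenvector and ``u`` is folded to [0, 90]° (the eigenvector
    sign is arbitrary).  ``u`` is given in (z, y, x) order; the default
    ``(0, 0, 1)`` is the anatomical X (lateral) axis.
    """
    u = np.asarray(u, dtype=np.float64).reshape(3)
    nu = np.linalg.norm(u)
    if nu == 0:
        raise ValueError("reference axis must be nonzero")
    coords = np.argwhere(mask.voxels) * mask.voxel_size_mm
    if coords.shape[0] < 3:
        raise ValueError("orientation needs at least 3 foreground voxels")
    A = np.cov(coords.T)
    if np.linalg.matrix_rank(A, tol=1e-12) < 1:
        raise ValueError("degenerate voxel cloud (all voxels coincident)")
    evals, evecs = np.linalg.eigh(A)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order].T  # rows
    ambiguous = bool(np.isclose(evals[0], evals[1], rtol=1e-6))
    if ambiguous:
        warnings.warn(
            "leading eigenvalues nearly tied: principal axis is ambiguous",
            stacklevel=2,
        )
    v1 = evecs[0]
    cosang = np.clip(abs(np.dot(u, v1)) / (nu * np.linalg.norm(v1)), -1.0, 1.0)
    angle = math.degrees(math.acos(cosang))
    return OrientationResult(evals, evecs, u / nu, angle, ambiguous)


def proportion_in_ventricle(v_plexus: float, v_ventricle: float) -> float:
    """Plexus fraction of the combined plexus + ventricle volume."""
    if v_plexus < 0 or v_ventricle < 0:
        raise ValueError("volumes must be >= 0")
    total = v_plexus + v_ventricle
    if total == 0:
        raise ValueError("total volume is zero")
    return v_plexus / total


# ---------------------------------------------------------------------------
# Plane split and lateral measures
# ---------------------------------------------------------------------------


def split_by_plane(
    mask: BinaryMask, point_mm: np.ndarray, normal_mm: np.ndarray
) -> tuple[BinaryMask, BinaryMask]:
    """Partition a mask by a plane into (rostral, caudal) halves.

    Voxels with non-negative signed distance along ``normal_mm`` belong to
    the rostral half.  Volumes always sum exactly to the input volume.
    Coordinates are (z, y, x) mm.
    """
    normal = np.asarray(normal_mm, dtype=np.float64).reshape(3)
    if np.linalg.norm(normal) == 0:
        raise ValueError("plane normal must be nonzero")
    point = np.asarray(point_mm, dtype=np.float64).reshape(3)
    nz, ny, nx = mask.shape
    vs = mask.voxel_size_mm
    z, y, x = np.ogrid[:nz, :ny, :nx]
    signed = (
        (z * vs - point[0]) * normal[0]
        + (y * vs - point[1]) * normal[1]
        + (x * vs - point[2]) * normal[2]
    )
    rostral = mask.voxels & (signed >= 0)
    caudal = mask.voxels & (signed < 0)
    return BinaryMask(rostral, vs), BinaryMask(caudal, vs)


@dataclass
class LateralMeasures:
    left_length_mm: float
    right_length_mm: float
    left_angle_deg: float  # NaN when the side is empty
    right_angle_deg: float
    central_length_mm: float
    total_length_mm: float
    ventricle_length_mm: float


def _side_extent_and_angle(
    coords_mm: np.ndarray,
    centre_mm: np.ndarray,
    side: np.ndarray,
    axis_yx: np.ndarray,
) -> tuple[float, float]:
    """Max transverse-plane distance from centre and the extremal-ray angle."""
    if not side.any():
        return 0.0, float("nan")
    d_yx = coords_mm[side][:, 1:] - centre_mm[1:]
    dist = np.hypot(d_yx[:, 0], d_yx[:, 1])
    i = int(np.argmax(dist))
    ray = d_yx[i]
    nr = np.linalg.norm(ray)
    if nr == 0:
        return 0.0, float("nan")
    cosang = np.clip(abs(float(np.dot(ray, axis_yx))) / nr, -1.0, 1.0)
    return float(dist[i]), math.degrees(math.acos(cosang))


def lateral_measures(
    mask: BinaryMask,
    ventricle: BinaryMask,
    midline_point_mm: np.ndarray,
    midline_normal_mm: np.ndarray,
    body_halfwidth_mm: Optional[float] = None,
) -> LateralMeasures:
    """Automated analogue of the manual transverse-plane measurements.

    The centre is the mask centroid projected onto the midline (sagittal)
    plane.  Per side of the midline, the branch length is the maximum
    in-plane (transverse, i.e. ignoring z) distance from the centre to a mask
    voxel, and the branch angle is measured between the brain's central axis
    (the in-plane direction perpendicular to the midline normal) and the
    centre-to-extremal-voxel ray.  ``total = left + right``;
    ``central = total - (extent beyond body_halfwidth_mm per side)``;
    the ventricle length is computed identically on the ventricle mask.

    These are deterministic geometric procedures standing in for interactive
    click-measurements; they are analogues, not replications.
    """
    normal = np.asarray(midline_normal_mm, dtype=np.float64).reshape(3)
    nn = np.linalg.norm(normal)
    if nn == 0:
        raise ValueError("midline normal must be nonzero")
    normal = normal / nn
    point = np.asarray(midline_point_mm, dtype=np.float64).reshape(3)

    # central axis within the transverse (y, x) plane: perpendicular to the
    # midline normal's in-plane component
    n_yx = normal[1:]
    if np.linalg.norm(n_yx) < 1e-12:
        raise ValueError("midline plane must intersect the transverse plane")
    n_yx = n_yx / np.linalg.norm(n_yx)
    axis_yx = np.array([-n_yx[1], n_yx[0]])

    def measure(m: BinaryMask) -> tuple[float, float, float, float]:
        if m.count() == 0:
            return 0.0, 0.0, float("nan"), float("nan")
        coords = np.argwhere(m.voxels) * m.voxel_size_mm
        centroid = coords.mean(axis=0)
        centre = centroid - np.dot(centroid - point, normal) * normal
        signed = (coords - point) @ normal
        left, la = _side_extent_and_angle(coords, centre, signed < 0, axis_yx)
        right, ra = _side_extent_and_angle(coords, centre, signed >= 0, axis_yx)
        return left, right, la, ra

    left, right, left_angle, right_angle = measure(mask)
    if left == 0.0 or right == 0.0:
        warnings.warn("one midline side is empty; its angle is undefined", stacklevel=2)
    v_left, v_right, _, _ = measure(ventricle)

    total = left + right
    ventricle_length = v_left + v_right
    if body_halfwidth_mm is None:
        body_halfwidth_mm = 0.35 * ventricle_length if ventricle_length > 0 else 0.0
    beyond = max(0.0, left - body_halfwidth_mm) + max(0.0, right - body_halfwidth_mm)
    central = total - beyond
    return LateralMeasures(
        left_length_mm=left,
        right_length_mm=right,
        left_angle_deg=left_angle,
        right_angle_deg=right_angle,
        central_length_mm=central,
        total_length_mm=total,
        ventricle_length_mm=ventricle_length,
    )


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------


@dataclass
class MorphometryConfig:
    """Planes and axes (in (z, y, x) mm) for the report; all optional.

    Defaults: reference axis = anatomical X; rostrocaudal split plane =
    mid-z plane through the plexus centroid; midline = mid-x sagittal plane
    through the plexus centroid.
    """

    reference_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    split_point_mm: Optional[tuple[float, float, float]] = None
    split_normal_mm: tuple[float, float, float] = (1.0, 0.0, 0.0)
    midline_point_mm: Optional[tuple[float, float, float]] = None
    midline_normal_mm: tuple[float, float, float] = (0.0, 0.0, 1.0)
    body_halfwidth_mm: Optional[float] = None
    crofton_directions: int = 3


def build_report(
    plexus: BinaryMask,
    ventricle: BinaryMask,
    config: MorphometryConfig | None = None,
    sample: str = "",
) -> MorphometryReport:
    """Run the whole criterion panel; failed measures become NaN and are logged."""
    cfg = config or MorphometryConfig()
    report = MorphometryReport(sample=sample)

    centroid = (
        np.argwhere(plexus.voxels).mean(axis=0) * plexus.voxel_size_mm
        if plexus.count()
        else np.zeros(3)
    )
    split_point = (
        np.asarray(cfg.split_point_mm) if cfg.split_point_mm is not None else centroid
    )
    midline_point = (
        np.asarray(cfg.midline_point_mm)
        if cfg.midline_point_mm is not None
        else centroid
    )

    def attempt(name: str, fn) -> None:
        try:
            fn()
        except Exception as exc:
            log.warning("morphometry field %s failed: %s", name, exc)

    report.volume_mm3 = compute_volume(plexus)
    report.ventricle_volume_mm3 = compute_volume(ventricle)
    attempt(
        "surface_area_mm2",
        lambda: setattr(
            report, "surface_area_mm2", crofton_area(plexus, cfg.crofton_directions)
        ),
    )
    attempt(
        "outgrowth_angle_deg",
        lambda: setattr(
            report,
            "outgrowth_angle_deg",
            orientation_angle(plexus, cfg.reference_axis).angle_deg,
        ),
    )
    attempt(
        "proportion",
        lambda: setattr(
            report,
            "proportion",
            proportion_in_ventricle(report.volume_mm3, report.ventricle_volume_mm3),
        ),
    )

    def do_split() -> None:
        rostral, caudal = split_by_plane(plexus, split_point, cfg.split_normal_mm)
        report.rostral_volume_mm3 = compute_volume(rostral)
        report.caudal_volume_mm3 = compute_volume(caudal)

    attempt("rostral/caudal", do_split)

    def do_lateral() -> None:
        lm = lateral_measures(
            plexus,
            ventricle,
            midline_point,
            cfg.midline_normal_mm,
            cfg.body_halfwidth_mm,
        )
        report.left_length_mm = lm.left_length_mm
        report.right_length_mm = lm.right_length_mm
        report.left_angle_deg = lm.left_angle_deg
        report.right_angle_deg = lm.right_angle_deg
        report.central_length_mm = lm.central_length_mm
        report.total_length_mm = lm.total_length_mm
        report.ventricle_length_mm = lm.ventricle_length_mm

    attempt("lateral_measures", do_lateral)
    return report
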