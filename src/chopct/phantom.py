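"""Synthetic embryo-head micro-CT phantoms with ground-truth masks.

The phantom emulates the statistical structure the segmentation pipeline
relies on: a dark CSF-filled ventricle cavity embedded in mid-intensity
tissue, a bright convoluted plexus body inside the cavity touching its wall,
a second dark decoy cavity connected through a thin dark channel (standing in
for the rest of the ventricular system), and additive Gaussian noise at a
controllable contrast-to-noise ratio.  Geometry parameters are fixed
fractions of the grid and are deliberately not anatomically calibrated.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from .types import BinaryMask, LandmarkConfiguration, RigidTransform, VolumeImage

__all__ = [
    "PhantomSpec",
    "PhantomOutput",
    "generate_embryo_phantom",
    "generate_reference_ventricle",
    "generate_landmark_sets",
    "BASE_LANDMARKS",
    "STAGES",
]

STAGES = ("E13.5", "E15.5", "E17.5")

#: Default lateral branch extension per developmental stage, as a fraction of
#: the ventricle half-width (branches elongate into the lateral recesses as
#: the stage advances).
STAGE_BRANCH_FRAC = {"E13.5": 0.55, "E15.5": 0.75, "E17.5": 0.9}


@dataclass
class PhantomSpec:
    """Parameters controlling phantom generation.

    Intensity ordering must satisfy ``plexus_level > tissue_level >
    ventricle_level >= 0`` (the ventricle lumen is the darkest region, the
    plexus the brightest).
    """

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size_mm: float = 0.004
    tissue_level: float = 120.0
    ventricle_level: float = 40.0
    plexus_level: float = 200.0
    noise_sigma: float = 10.0
    stage: str = "E13.5"
    branch_angle_deg: float = 0.0
    branch_length_frac: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if len(self.grid_shape) != 3:
            raise ValueError("grid_shape must have 3 axes (z, y, x)")
        if any(s < 32 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be >= 32 per axis, got {self.grid_shape}")
        if not (self.plexus_level > self.tissue_level > self.ventricle_level >= 0):
            raise ValueError(
                "intensity levels must satisfy plexus > tissue > ventricle >= 0, got "
                f"({self.plexus_level}, {self.tissue_level}, {self.ventricle_level})"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be > 0")
        if self.branch_length_frac is None:
            self.branch_length_frac = STAGE_BRANCH_FRAC[self.stage]
        if not (0 < self.branch_length_frac <= 1):
            raise ValueError("branch_length_frac must be in (0, 1]")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        data = json.loads(text)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown PhantomSpec keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PhantomOutput:
    image: VolumeImage
    ventricle_truth: BinaryMask  # dark lumen of the main cavity (plexus excluded)
    plexus_truth: BinaryMask
    landmark_truth: LandmarkConfiguration
    # extras useful for testing/diagnostics
    decoy_truth: BinaryMask = None  # type: ignore[assignment]
    tissue_truth: BinaryMask = None  # type: ignore[assignment]


def _geometry(spec: PhantomSpec):
    """Build the boolean geometry masks; returns a dict of components."""
    nz, ny, nx = spec.grid_shape
    z, y, x = np.ogrid[:nz, :ny, :nx]
    cz, cy, cx = (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0

    # Cavity: bent elliptical slab.  The bend shifts the slab centre in y as a
    # quadratic function of x (curved roof of the 4th ventricle stand-in).
    az = 0.14 * nz
    ay = 0.17 * ny
    ax = 0.30 * nx
    bend = 0.08 * ny
    dx = x - cx
    yoff = bend * (dx / ax) ** 2
    dy = y - cy - yoff
    dz = z - cz
    body = (dz / az) ** 2 + (dy / ay) ** 2 + (dx / ax) ** 2 <= 1.0

    # Two cylindrical lateral recesses extending the cavity along +-x; their
    # length scales with the stage (via branch_length_frac's stage default).
    rec_r = 0.07 * min(nz, ny)
    rec_end = min(ax * (1.0 + 0.45 * spec.branch_length_frac), 0.48 * nx)
    recess = (dz**2 + dy**2 <= rec_r**2) & (np.abs(dx) <= rec_end)
    cavity = body | recess

    if cavity[0].any() or cavity[-1].any() or not cavity.any():
        raise ValueError(
            f"grid {spec.grid_shape} is too small to contain the ventricle template"
        )

    # Plexus: a medial ridge plus two tapered lateral tubes whose tips reach
    # branch_length_frac of each recess; the whole body lies inside the cavity
    # and a thin stalk attaches it to the +y cavity wall.
    half_len = spec.branch_length_frac * rec_end
    r0 = max(2.5, 0.032 * min(nz, ny, nx))
    # optional per-branch outgrowth tilt of the tube axis within the xy-plane
    tilt = np.tan(np.deg2rad(spec.branch_angle_deg)) * np.abs(dx)
    y_axis = cy + yoff + 0.45 * ay + tilt
    taper = 1.0 - 0.55 * np.minimum(np.abs(dx) / max(half_len, 1e-9), 1.0)
    tube_r = r0 * taper
    tube = (dz**2 + (y - y_axis) ** 2 <= tube_r**2) & (np.abs(dx) <= half_len)
    ridge = (dz**2 + (y - y_axis) ** 2 + (dx / 1.6) ** 2) <= (1.3 * r0) ** 2
    stalk = (dx**2 + dz**2 <= 2.1**2) & (y >= y_axis - 0.1)
    plexus = (tube | ridge | (stalk & (y - cy - yoff <= ay + 1))) & cavity

    lumen = cavity & ~plexus

    # Decoy cavity (rest of the ventricular system): a dark ball rostral to the
    # main cavity, joined to it by a thin dark channel that morphological
    # opening can sever.
    dec_r = 0.08 * min(nz, ny, nx)
    dec_cz = cz - az - dec_r - 0.08 * nz
    decoy = (z - dec_cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2 <= dec_r**2
    bridge = ((y - cy) ** 2 + (x - cx) ** 2 <= 1.4**2) & (z >= dec_cz) & (
        z <= cz
    ) & ~cavity & ~decoy

    return {
        "cavity": cavity,
        "lumen": lumen,
        "plexus": plexus,
        "decoy": decoy,
        "bridge": bridge,
        "params": dict(
            cz=cz, cy=cy, cx=cx, az=az, ay=ay, ax=ax, bend=bend,
            rec_end=rec_end, half_len=half_len, r0=r0,
        ),
    }


def _landmarks_from_geometry(geo: dict, voxel_size_mm: float) -> LandmarkConfiguration:
    """Ten labeled points on the plexus surface/axis, in (x, y, z) mm order."""
    p = geo["params"]
    cz, cy, cx = p["cz"], p["cy"], p["cx"]
    ay, ax, bend = p["ay"], p["ax"], p["bend"]
    hl, r0 = p["half_len"], p["r0"]

    def y_axis_at(dx: float) -> float:
        return cy + bend * (dx / ax) ** 2 + 0.45 * ay

    pts_zyx = [
        (cz, y_axis_at(-hl), cx - hl),          # left branch tip
        (cz, y_axis_at(hl), cx + hl),           # right branch tip
        (cz, y_axis_at(-hl / 2), cx - hl / 2),  # left mid-branch
        (cz, y_axis_at(hl / 2), cx + hl / 2),   # right mid-branch
        (cz, y_axis_at(-hl / 4), cx - hl / 4),  # left inner
        (cz, y_axis_at(hl / 4), cx + hl / 4),   # right inner
        (cz, y_axis_at(0), cx),                 # centre
        (cz, cy + ay, cx),                      # stalk attachment (wall)
        (cz - 1.3 * r0, y_axis_at(0), cx),      # ridge ventral pole
        (cz + 1.3 * r0, y_axis_at(0), cx),      # ridge dorsal pole
    ]
    labels = [
        "tip_left", "tip_right", "mid_left", "mid_right", "inner_left",
        "inner_right", "centre", "stalk", "ridge_ventral", "ridge_dorsal",
    ]
    pts_xyz = np.array([(px, py, pz) for (pz, py, px) in pts_zyx]) * voxel_size_mm
    return LandmarkConfiguration(pts_xyz, label="phantom", point_labels=labels)


def generate_embryo_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Generate a synthetic embryo-head volume with ground-truth masks.

    Identical specs (including seed) produce bit-identical arrays.
    """
    geo = _geometry(spec)
    lumen, plexus = geo["lumen"], geo["plexus"]
    dark = lumen | geo["decoy"] | geo["bridge"]

    img = np.full(spec.grid_shape, spec.tissue_level, dtype=np.float64)
    img[dark] = spec.ventricle_level
    img[plexus] = spec.plexus_level

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=spec.grid_shape)
        np.clip(img, 0.0, None, out=img)

    vs = spec.voxel_size_mm
    tissue = ~(dark | plexus)
    return PhantomOutput(
        image=VolumeImage(img, vs),
        ventricle_truth=BinaryMask(lumen, vs),
        plexus_truth=BinaryMask(plexus, vs),
        landmark_truth=_landmarks_from_geometry(geo, vs),
        decoy_truth=BinaryMask(geo["decoy"], vs),
        tissue_truth=BinaryMask(tissue, vs),
    )


def generate_reference_ventricle(
    spec: PhantomSpec,
    jitter: RigidTransform | None = None,
    grow: int = 0,
) -> BinaryMask:
    """Synthetic stand-in for an atlas 4th-ventricle reference mask.

    The ground-truth lumen is moved by ``jitter`` (a rigid transform in voxel
    units, applied about the grid centre) and optionally dilated (``grow > 0``)
    or eroded (``grow < 0``) by one voxel per unit.
    """
    from scipy import ndimage

    from ._morph import ball_dilate, ball_erode

    truth = _geometry(spec)["lumen"]
    out = truth
    if jitter is not None:
        identity_rot = np.allclose(jitter.rotation, np.eye(3))
        if identity_rot and np.allclose(jitter.translation, 0):
            out = truth.copy()
        elif identity_rot:
            out = ndimage.shift(
                truth.astype(np.uint8), jitter.translation, order=0, mode="constant"
            ).astype(bool)
        else:
            centre = (np.array(truth.shape) - 1) / 2.0
            # forward motion about the centre: o = R (i - c) + c + t;
            # affine_transform maps output -> input: i = R^T (o - c - t) + c
            rot_inv = jitter.rotation.T
            offset = centre - rot_inv @ (centre + jitter.translation)
            out = ndimage.affine_transform(
                truth.astype(np.uint8), rot_inv, offset=offset, order=0, mode="constant"
            ).astype(bool)
    else:
        out = truth.copy()
    if grow > 0:
        out = ball_dilate(out, grow)
    elif grow < 0:
        out = ball_erode(out, -grow)
    return BinaryMask(out, spec.voxel_size_mm)


#: Fixed base landmark configuration (mm) used by the landmark-set generator;
#: a 10-point asymmetric 3D constellation loosely shaped like a branched body.
BASE_LANDMARKS = np.array(
    [
        [-0.30, 0.05, 0.00],
        [0.30, 0.05, 0.00],
        [-0.15, 0.02, 0.01],
        [0.15, 0.02, -0.01],
        [-0.07, 0.00, 0.02],
        [0.07, 0.00, -0.02],
        [0.00, 0.00, 0.00],
        [0.00, 0.08, 0.00],
        [0.00, -0.02, 0.04],
        [0.02, -0.01, -0.04],
    ]
)


def _random_rotation(rng: np.random.Generator, max_angle_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(-max_angle_deg, max_angle_deg))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def generate_landmark_sets(
    n_samples: int,
    k: int = 10,
    noise_sigma_mm: float = 0.0,
    scale_range: tuple[float, float] = (0.8, 1.25),
    max_rotation_deg: float = 180.0,
    max_translation_mm: float = 1.0,
    seed: int = 0,
    base: np.ndarray | None = None,
) -> list[LandmarkConfiguration]:
    """Generate noisy, randomly similarity-transformed copies of a base shape.

    Each sample is ``base + iid Gaussian landmark noise`` followed by a random
    similarity transform (scale, rotation, translation) drawn within bounds.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if k < 3:
        raise ValueError("k must be >= 3")
    if base is None:
        base = BASE_LANDMARKS
    base = np.asarray(base, dtype=np.float64)
    if base.shape[0] < k:
        # extend deterministically with points on a helix
        t = np.linspace(0, 2 * np.pi, base.shape[0] + (k - base.shape[0]) + 1)[
            base.shape[0] + 1 :
        ]
        extra = 0.2 * np.column_stack([np.cos(t), np.sin(t), t / (2 * np.pi)])
        base = np.vstack([base, extra])
    base = base[:k]

    rng = np.random.default_rng(seed)
    out: list[LandmarkConfiguration] = []
    for i in range(n_samples):
        pts = base + rng.normal(0.0, noise_sigma_mm, size=(k, 3))
        s = rng.uniform(*scale_range)
        R = _random_rotation(rng, max_rotation_deg)
        t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
        out.append(LandmarkConfiguration(s * pts @ R.T + t, label=f"sample_{i:03d}"))
    return out
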