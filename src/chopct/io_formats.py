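"""Readers and writers for every external format the pipeline touches.

Stacks are per-slice TIFF files (one 2D transverse slice per file,
zero-padded numeric names) or a single multi-page TIFF.  Masks are written as
8-bit 0/255 TIFFs for interoperability with manual-segmentation tools.
Landmarks use the Slicer Markups fiducial CSV (.fcsv) dialect.  Meshes are
exported as STL.
"""

from __future__ import annotations

import csv
import os
import struct
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile

from .types import BinaryMask, LandmarkConfiguration, MorphometryReport, VolumeImage

__all__ = [
    "read_image_stack",
    "write_image_stack",
    "read_mask_stack",
    "export_mesh_stl",
    "read_landmarks",
    "write_landmarks",
    "write_report",
    "read_report",
]

_TIFF_EXTS = {".tif", ".tiff"}


def _slice_files(directory: Path) -> list[Path]:
    files = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in _TIFF_EXTS and p.is_file()
    )
    if not files:
        raise ValueError(f"no TIFF slices found in {directory}")
    return files


def read_image_stack(path: str | os.PathLike, voxel_size_mm: float = 1.0) -> VolumeImage:
    """Read a 3D volume from a directory of slice TIFFs or a multi-page TIFF.

    Slices are stacked along axis 0 in filename-sorted order and promoted to
    float64.  All slices must share one 2D shape and dtype.
    """
    path = Path(path)
    if path.is_dir():
        files = _slice_files(path)
        first = tifffile.imread(files[0])
        if first.ndim != 2:
            raise ValueError(f"slice {files[0].name} is not 2D (shape {first.shape})")
        slices = [first]
        for f in files[1:]:
            arr = tifffile.imread(f)
            if arr.shape != first.shape or arr.dtype != first.dtype:
                raise ValueError(
                    f"inconsistent slice {f.name}: shape {arr.shape} dtype {arr.dtype}, "
                    f"expected shape {first.shape} dtype {first.dtype}"
                )
            slices.append(arr)
        vol = np.stack(slices, axis=0)
    else:
        vol = tifffile.imread(path)
        if vol.ndim == 2:
            vol = vol[None]
        if vol.ndim != 3:
            raise ValueError(f"expected a 3D stack in {path}, got shape {vol.shape}")
    return VolumeImage(vol.astype(np.float64), voxel_size_mm)


def read_mask_stack(path: str | os.PathLike, voxel_size_mm: float = 1.0) -> BinaryMask:
    """Read a binary mask stack (any nonzero voxel is foreground)."""
    vol = read_image_stack(path, voxel_size_mm)
    return BinaryMask(vol.voxels > 0, voxel_size_mm)


def write_image_stack(
    volume: VolumeImage | BinaryMask, path: str | os.PathLike, prefix: str = "slice"
) -> list[Path]:
    """Write one TIFF per transverse slice; masks are stored as 8-bit 0/255.

    Returns the list of written files (zero-padded numeric names, so that a
    plain filename sort restores slice order).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if isinstance(volume, BinaryMask):
        data = np.where(volume.voxels, np.uint8(255), np.uint8(0))
    else:
        data = volume.voxels
    ndigits = max(4, len(str(data.shape[0] - 1)))
    written: list[Path] = []
    for i in range(data.shape[0]):
        f = path / f"{prefix}_{i:0{ndigits}d}.tif"
        tifffile.imwrite(f, data[i])
        written.append(f)
    return written


def _mesh_from_mask(mask: BinaryMask):
    from skimage import measure

    if mask.count() == 0:
        raise ValueError("cannot mesh an empty mask")
    padded = np.pad(mask.voxels.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    verts = (verts - 1.0) * mask.voxel_size_mm  # undo pad; index -> mm
    return verts, faces


def export_mesh_stl(
    mask: BinaryMask, path: str | os.PathLike, binary: bool = True
) -> tuple[int, int]:
    """Export the 0.5-level boundary surface of a mask as an STL file.

    Vertices are in mm (``index * voxel_size_mm``).  Returns
    ``(n_vertices, n_faces)``.
    """
    verts, faces = _mesh_from_mask(mask)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tri = verts[faces]  # (F, 3, 3)
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    lens = np.linalg.norm(normals, axis=1)
    lens[lens == 0] = 1.0
    normals = normals / lens[:, None]
    if binary:
        with open(path, "wb") as fh:
            fh.write(b"chopct mask surface".ljust(80, b"\0"))
            fh.write(struct.pack("<I", len(faces)))
            rec = np.zeros(
                len(faces),
                dtype=np.dtype(
                    [("n", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")]
                ),
            )
            rec["n"] = normals
            rec["v"] = tri
            fh.write(rec.tobytes())
    else:
        with open(path, "w") as fh:
            fh.write("solid chopct\n")
            for n, t in zip(normals, tri):
                fh.write(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}\n")
                fh.write("    outer loop\n")
                for v in t:
                    fh.write(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")
                fh.write("    endloop\n  endfacet\n")
            fh.write("endsolid chopct\n")
    return len(verts), len(faces)


def read_stl(path: str | os.PathLike) -> np.ndarray:
    """Read an STL file back as an (F, 3, 3) triangle-vertex array."""
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(80)
        if head[:5] == b"solid" and b"facet" in (head + fh.read(200)):
            # ASCII
            tris = []
            cur: list[list[float]] = []
            for line in path.read_text().splitlines():
                parts = line.split()
                if parts[:1] == ["vertex"]:
                    cur.append([float(p) for p in parts[1:4]])
                    if len(cur) == 3:
                        tris.append(cur)
                        cur = []
            return np.array(tris, dtype=np.float64)
        fh.seek(80)
        (n,) = struct.unpack("<I", fh.read(4))
        rec = np.frombuffer(
            fh.read(n * 50),
            dtype=np.dtype([("n", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")]),
        )
        return rec["v"].astype(np.float64)


_FCSV_HEADER = (
    "# Markups fiducial file version = 4.11\n"
    "# CoordinateSystem = {cs}\n"
    "# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID\n"
)


def read_landmarks(path: str | os.PathLike) -> LandmarkConfiguration:
    """Read a Slicer Markups fiducial CSV (.fcsv).

    Comment lines start with ``#``; data rows are ``id,x,y,z,...,label,...``.
    Point order equals file order.  A ``CoordinateSystem`` header, when
    present, is stored as metadata without any conversion.
    """
    path = Path(path)
    coord_sys = None
    points: list[list[float]] = []
    labels: list[str] = []
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "CoordinateSystem" in line and "=" in line:
                    coord_sys = line.split("=", 1)[1].strip()
                continue
            row = next(csv.reader([line]))
            if len(row) < 4:
                raise ValueError(f"{path.name}:{lineno}: malformed row (need id,x,y,z)")
            try:
                xyz = [float(row[1]), float(row[2]), float(row[3])]
            except ValueError as exc:
                raise ValueError(
                    f"{path.name}:{lineno}: non-numeric coordinate ({exc})"
                ) from None
            points.append(xyz)
            labels.append(row[11] if len(row) > 11 else row[0])
    if not points:
        raise ValueError(f"{path.name}: no landmarks")
    if len(points) < 3:
        import warnings

        warnings.warn(f"{path.name}: only {len(points)} landmarks (< 3)", stacklevel=2)
    return LandmarkConfiguration(
        np.array(points), label=path.stem, point_labels=labels, coordinate_system=coord_sys
    )


def write_landmarks(cfg: LandmarkConfiguration, path: str | os.PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cs = cfg.coordinate_system or "LPS"
    with open(path, "w", newline="") as fh:
        fh.write(_FCSV_HEADER.format(cs=cs))
        for i, (x, y, z) in enumerate(cfg.points, start=1):
            label = (
                cfg.point_labels[i - 1]
                if cfg.point_labels is not None
                else f"F-{i}"
            )
            fh.write(
                f"vtkMRMLMarkupsFiducialNode_{i},{x:.17g},{y:.17g},{z:.17g},"
                f"0,0,0,1,1,1,0,{label},,\n"
            )


_UNITS = {
    "volume_mm3": "mm3",
    "surface_area_mm2": "mm2",
    "outgrowth_angle_deg": "deg",
    "ventricle_volume_mm3": "mm3",
    "proportion": "fraction",
    "rostral_volume_mm3": "mm3",
    "caudal_volume_mm3": "mm3",
    "left_length_mm": "mm",
    "right_length_mm": "mm",
    "left_angle_deg": "deg",
    "right_angle_deg": "deg",
    "central_length_mm": "mm",
    "total_length_mm": "mm",
    "ventricle_length_mm": "mm",
}


def write_report(
    reports: Iterable[MorphometryReport], path: str | os.PathLike
) -> None:
    """Write morphometry reports as CSV: one row per sample, units in header."""
    import pandas as pd

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = MorphometryReport.field_names()
    header = [
        c if c not in _UNITS else f"{c} [{_UNITS[c]}]" for c in cols
    ]
    rows = []
    for r in reports:
        rows.append([getattr(r, c) for c in cols])
    df = pd.DataFrame(rows, columns=header)
    df.to_csv(path, index=False, na_rep="")


def read_report(path: str | os.PathLike):
    import pandas as pd

    return pd.read_csv(path)
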