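"""File formats: NIfTI-1 label volumes, STL/OBJ meshes, CSV/JSON tables.

All writers refuse to overwrite existing files unless ``force`` is given,
and all outputs are byte-deterministic for a fixed input (no timestamps,
fixed headers, fixed float formatting) so pipeline reruns hash identically.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .reconstruct import Contour, ProfileStack, TriMesh
from .volume import VoxelLabelVolume

FLOAT_FORMAT = "%.6f"
_STL_HEADER = b"cordmorph binary STL".ljust(80, b"\0")


class OverwriteError(FileExistsError):
    """Target exists and ``force`` was not given."""


def _check_overwrite(path: str | Path, force: bool) -> Path:
    p = Path(path)
    if p.exists() and not force:
        raise OverwriteError(f"refusing to overwrite existing file: {p}")
    p.parent.mkdir(parents=True, exist_ok=True)
    return p


# ---------------------------------------------------------------------------
# NIfTI label volumes
# ---------------------------------------------------------------------------

def read_label_volume(path: str | Path) -> VoxelLabelVolume:
    """Load a NIfTI-1 label volume.

    Requires an integer data type and an axis-aligned (diagonal, positive)
    affine; oblique or sheared affines are rejected because the package's
    world model is ``origin + index·spacing``.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        raise TypeError(f"label volume must be integer-typed, got {data.dtype}")
    if data.ndim != 3:
        raise ValueError("label volume must be 3D")
    aff = np.asarray(img.affine, dtype=float)
    rot = aff[:3, :3]
    if np.any(np.abs(rot - np.diag(np.diag(rot))) > 1e-6):
        raise ValueError("oblique affine not supported: expected a diagonal "
                         "voxel-to-world matrix")
    spacing = np.diag(rot)
    if np.any(spacing <= 0):
        raise ValueError("affine must have positive diagonal spacing")
    origin = aff[:3, 3]
    return VoxelLabelVolume(array=data, spacing=tuple(spacing),
                            origin=tuple(origin))


def write_label_volume(volume: VoxelLabelVolume, path: str | Path,
                       force: bool = False) -> Path:
    """Save as uncompressed NIfTI-1 (byte-deterministic)."""
    p = _check_overwrite(path, force)
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = volume.spacing
    aff[:3, 3] = volume.origin
    img = nib.Nifti1Image(np.asarray(volume.array, dtype=np.uint8), aff)
    img.header.set_qform(aff, code=1)
    img.header.set_sform(aff, code=1)
    nib.save(img, str(p))
    return p


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def _face_normals(mesh: TriMesh) -> np.ndarray:
    v = mesh.vertices
    f = mesh.faces
    n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    length = np.linalg.norm(n, axis=1, keepdims=True)
    length[length == 0] = 1.0
    return n / length


def write_stl(mesh: TriMesh, path: str | Path, binary: bool = True,
              force: bool = False) -> Path:
    """Write STL; the binary dialect (default) is byte-stable across runs."""
    p = _check_overwrite(path, force)
    normals = _face_normals(mesh).astype("<f4")
    tris = mesh.vertices[mesh.faces].astype("<f4")  # (F, 3, 3)
    if binary:
        with open(p, "wb") as fh:
            fh.write(_STL_HEADER)
            fh.write(struct.pack("<I", len(mesh.faces)))
            rec = np.zeros(len(mesh.faces),
                           dtype=[("n", "<f4", 3), ("v", "<f4", (3, 3)),
                                  ("attr", "<u2")])
            rec["n"] = normals
            rec["v"] = tris
            fh.write(rec.tobytes())
    else:
        with open(p, "w", newline="\n") as fh:
            fh.write("solid cordmorph\n")
            for nrm, tri in zip(normals, tris):
                fh.write("facet normal %.6e %.6e %.6e\n" % tuple(nrm))
                fh.write(" outer loop\n")
                for vx in tri:
                    fh.write("  vertex %.6e %.6e %.6e\n" % tuple(vx))
                fh.write(" endloop\nendfacet\n")
            fh.write("endsolid cordmorph\n")
    return p


def read_stl(path: str | Path) -> TriMesh:
    """Read binary or ASCII STL into an indexed TriMesh.

    Triangle order and per-triangle vertex order are preserved, so
    write→read→write is byte-stable for the binary dialect.
    """
    p = Path(path)
    with open(p, "rb") as fh:
        head = fh.read(80)
        if head[:5] == b"solid" and _looks_ascii(p):
            tris = _read_ascii_stl(p)
        else:
            (count,) = struct.unpack("<I", fh.read(4))
            rec = np.frombuffer(fh.read(count * 50),
                                dtype=[("n", "<f4", 3), ("v", "<f4", (3, 3)),
                                       ("attr", "<u2")])
            tris = rec["v"].astype(np.float64)
    flat = tris.reshape(-1, 3)
    vertices, inverse = np.unique(flat, axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3)
    return TriMesh(vertices=vertices, faces=faces, provenance=f"stl:{p.name}")


def _looks_ascii(p: Path) -> bool:
    try:
        with open(p, "r", errors="strict") as fh:
            fh.read(512)
        return True
    except UnicodeDecodeError:
        return False


def _read_ascii_stl(p: Path) -> np.ndarray:
    verts: list[list[float]] = []
    with open(p) as fh:
        for line in fh:
            parts = line.split()
            if parts and parts[0] == "vertex":
                verts.append([float(x) for x in parts[1:4]])
    if len(verts) % 3:
        raise ValueError(f"malformed ASCII STL: {p}")
    return np.asarray(verts).reshape(-1, 3, 3)


def write_obj(mesh: TriMesh, path: str | Path, force: bool = False) -> Path:
    p = _check_overwrite(path, force)
    with open(p, "w", newline="\n") as fh:
        fh.write("# cordmorph OBJ export\n")
        for v in mesh.vertices:
            fh.write("v %.6f %.6f %.6f\n" % tuple(v))
        for f in mesh.faces:
            fh.write("f %d %d %d\n" % tuple(f + 1))
    return p


# ---------------------------------------------------------------------------
# tables, profiles, manifests
# ---------------------------------------------------------------------------

def write_csv(table: pd.DataFrame, path: str | Path, force: bool = False) -> Path:
    p = _check_overwrite(path, force)
    table.to_csv(p, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")
    return p


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_profiles_csv(stack: ProfileStack, path: str | Path,
                       force: bool = False) -> Path:
    table = pd.DataFrame(stack.to_table(),
                         columns=["z", "point_index", "x", "y"])
    table["point_index"] = table["point_index"].astype(int)
    return write_csv(table, path, force=force)


def read_profiles_csv(path: str | Path) -> ProfileStack:
    df = pd.read_csv(path)
    contours = []
    for z, grp in df.groupby("z", sort=True):
        grp = grp.sort_values("point_index")
        contours.append(Contour(z=float(z),
                                points=grp[["x", "y"]].to_numpy(float)))
    return ProfileStack(contours=contours, n_points=len(contours[0].points))


def write_json(obj: dict, path: str | Path, force: bool = False) -> Path:
    p = _check_overwrite(path, force)
    with open(p, "w", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return p


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_manifest(path: str | Path, seed: int, force: bool = False,
                   **extra) -> Path:
    """Run manifest; records the seed and any extra parameters (no
    timestamps, to keep reruns byte-identical)."""
    payload = {"seed": int(seed), **extra}
    return write_json(payload, path, force=force)
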