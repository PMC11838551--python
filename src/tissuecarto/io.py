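"""File formats: Wavefront OBJ meshes (with UV) and multi-page TIFF volumes.

OBJ carries ``v``/``vn``/``vt`` records and faces as ``f v/vt/vn``; the UV
layer uses its own vertex list so seams (one 3D vertex, several UV corners)
round-trip exactly. Volumes are written as multi-page TIFFs with the axis
order ``(channel, z, y, x)`` recorded in the metadata, plus a JSON sidecar
holding the voxel spacing — spacing is never guessed from pixel counts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .mesh import TriangleMesh, TriangleMeshUV
from .volume import BinaryMask, VolumetricImage

_FLOAT_FMT = "{:.8f}"


# -- OBJ ------------------------------------------------------------------


def write_obj(path: str | Path, mesh: TriangleMesh) -> None:
    """Write a mesh (optionally with normals and UV) as Wavefront OBJ."""
    path = Path(path)
    lines: list[str] = ["# tissuecarto OBJ"]
    for v in mesh.vertices:
        lines.append("v " + " ".join(_FLOAT_FMT.format(x) for x in v))
    has_uv = isinstance(mesh, TriangleMeshUV) and len(mesh.uv_vertices) > 0
    if has_uv:
        for vt in mesh.uv_vertices:
            lines.append("vt " + " ".join(_FLOAT_FMT.format(x) for x in vt))
    has_vn = mesh.vertex_normals is not None
    if has_vn:
        for vn in mesh.vertex_normals:
            lines.append("vn " + " ".join(_FLOAT_FMT.format(x) for x in vn))
    for fi, f in enumerate(mesh.faces):
        parts = []
        for corner in range(3):
            vi = f[corner] + 1
            if has_uv:
                ti = mesh.uv_faces[fi, corner] + 1
                if has_vn:
                    parts.append(f"{vi}/{ti}/{vi}")
                else:
                    parts.append(f"{vi}/{ti}")
            elif has_vn:
                parts.append(f"{vi}//{vi}")
            else:
                parts.append(str(vi))
        lines.append("f " + " ".join(parts))
    path.write_text("\n".join(lines) + "\n")


def read_obj(path: str | Path) -> TriangleMesh | TriangleMeshUV:
    """Read OBJ; returns :class:`TriangleMeshUV` when ``vt`` records exist.

    Polygonal faces are fan-triangulated. Raises ``ValueError`` on malformed
    records.
    """
    path = Path(path)
    vertices: list[list[float]] = []
    uvs: list[list[float]] = []
    normals: list[list[float]] = []
    faces: list[list[int]] = []
    uv_faces: list[list[int]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        tag = tokens[0]
        try:
            if tag == "v":
                vertices.append([float(t) for t in tokens[1:4]])
            elif tag == "vt":
                uvs.append([float(t) for t in tokens[1:3]])
            elif tag == "vn":
                normals.append([float(t) for t in tokens[1:4]])
            elif tag == "f":
                corner_v, corner_t = [], []
                for tok in tokens[1:]:
                    fields = tok.split("/")
                    corner_v.append(int(fields[0]) - 1)
                    if len(fields) > 1 and fields[1]:
                        corner_t.append(int(fields[1]) - 1)
                if len(corner_v) < 3:
                    raise ValueError("face with fewer than 3 corners")
                for k in range(1, len(corner_v) - 1):
                    faces.append([corner_v[0], corner_v[k], corner_v[k + 1]])
                    if corner_t:
                        uv_faces.append([corner_t[0], corner_t[k], corner_t[k + 1]])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed OBJ record: {raw!r}") from exc
    if not vertices:
        raise ValueError(f"{path}: no vertices found")
    verts = np.asarray(vertices, float)
    face_arr = np.asarray(faces, int).reshape(-1, 3)
    vn = None
    if normals and len(normals) == len(vertices):
        vn = np.asarray(normals, float)
        lens = np.linalg.norm(vn, axis=1, keepdims=True)
        lens[lens == 0] = 1.0
        vn = vn / lens
    if uvs and uv_faces:
        return TriangleMeshUV(
            vertices=verts,
            faces=face_arr,
            vertex_normals=vn,
            uv_vertices=np.asarray(uvs, float),
            uv_faces=np.asarray(uv_faces, int).reshape(-1, 3),
        )
    return TriangleMesh(vertices=verts, faces=face_arr, vertex_normals=vn)


# -- TIFF volumes ---------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(path: str | Path, image: VolumetricImage) -> None:
    """Write ``(channel, z, y, x)`` volume as multi-page TIFF + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(
        path,
        image.data.astype(np.float32),
        metadata={"axes": "CZYX"},
    )
    meta = {
        "axes": "CZYX",
        "spacing_um_zyx": [float(s) for s in image.spacing],
        "channel_names": image.channel_names,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_volume(
    path: str | Path, spacing: np.ndarray | None = None
) -> VolumetricImage:
    """Read a volume; spacing from argument or the JSON sidecar (required)."""
    path = Path(path)
    data = tifffile.imread(path)
    channel_names = None
    if spacing is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValueError(
                f"no spacing given and no sidecar {sidecar.name}; spacing is never guessed"
            )
        meta = json.loads(sidecar.read_text())
        spacing = np.asarray(meta["spacing_um_zyx"], float)
        channel_names = meta.get("channel_names")
    if data.ndim == 3:
        data = data[None]
    return VolumetricImage(data=data, spacing=spacing, channel_names=channel_names)


def write_mask(path: str | Path, mask: BinaryMask) -> None:
    path = Path(path)
    tifffile.imwrite(path, mask.data.astype(np.uint8), metadata={"axes": "ZYX"})
    _sidecar_path(path).write_text(
        json.dumps({"axes": "ZYX", "spacing_um_zyx": [float(s) for s in mask.spacing]})
    )


def read_mask(path: str | Path, spacing: np.ndarray | None = None) -> BinaryMask:
    path = Path(path)
    data = tifffile.imread(path)
    if spacing is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValueError(f"no spacing given and no sidecar {sidecar.name}")
        spacing = np.asarray(json.loads(sidecar.read_text())["spacing_um_zyx"], float)
    return BinaryMask(data=data > 0, spacing=spacing)


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    dtype = np.uint16 if labels.max() < 2**16 else np.uint32
    tifffile.imwrite(Path(path), labels.astype(dtype))


def read_labels(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path)))
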