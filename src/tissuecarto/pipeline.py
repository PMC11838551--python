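"""Pipeline orchestration: segment → mesh → unwrap → project → analyze.

Each stage terminates in a single file of standardized type (TIFF mask, OBJ
mesh with UV, TIFF projection stack, distortion TIFF), so any stage's output
can be replaced by an externally produced file of the same format and the
run resumed — stages are skipped when their output already exists unless
``force`` is set.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np

from . import alignment, analysis, io, projection, segmentation, unwrap
from .config import ProjectConfig
from .mesh import TriangleMesh, TriangleMeshUV


def _log(log_path: Path, entry: dict) -> None:
    entry = {"time": time.strftime("%Y-%m-%d %H:%M:%S"), **entry}
    with log_path.open("a") as fh:
        fh.write(json.dumps(entry) + "\n")


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def frame_paths(config: ProjectConfig, frame_id: int) -> dict[str, Path]:
    root = Path(config.project_root)
    out = root / config.output_dir
    stem = f"frame_{frame_id:04d}"
    return {
        "image": root / config.image_template.format(frame=frame_id),
        "input_mesh": root / config.mesh_template.format(frame=frame_id),
        "mask": out / f"{stem}_mask.tif",
        "mesh": out / f"{stem}_mesh.obj",
        "projection": out / f"{stem}_projection.tif",
        "distortion": out / f"{stem}_distortion.tif",
        "log": out / "run.log",
        "residuals": out / "residuals.csv",
    }


def _unwrap_mesh(config: ProjectConfig, mesh: TriangleMesh) -> TriangleMeshUV:
    u = config.unwrap
    center = u.center if u.center is not None else mesh.vertices.mean(axis=0).tolist()
    if u.method == "axis":
        return unwrap.uv_axis_projection(mesh, np.asarray(u.axis))
    if u.method == "spherical":
        return unwrap.uv_spherical(
            mesh, center=np.asarray(center), pole_axis=np.asarray(u.axis),
            meridian_axis=np.asarray(u.meridian_axis),
        )
    if u.method == "cylindrical":
        point = u.axis_point if u.axis_point is not None else center
        return unwrap.uv_cylindrical(
            mesh, axis_point=np.asarray(point), axis_dir=np.asarray(u.axis),
            meridian_axis=np.asarray(u.meridian_axis),
        )
    if u.method == "harmonic":
        return unwrap.uv_harmonic_disk(mesh)
    raise ValueError(f"unwrap method {u.method!r} needs an existing UV map")


def run_frame(
    config: ProjectConfig, frame_id: int, force: bool = False
) -> dict[str, Path]:
    """Run the single-frame pipeline; returns the artifact paths.

    Stages whose output file already exists are skipped unless ``force``.
    A missing input raises with the stage and path named.
    """
    paths = frame_paths(config, frame_id)
    paths["mask"].parent.mkdir(parents=True, exist_ok=True)
    log = paths["log"]

    if not paths["image"].exists():
        raise FileNotFoundError(
            f"stage 'segment': missing input image {paths['image']}"
        )
    image = io.read_volume(paths["image"], spacing=np.asarray(config.spacing))

    # segment
    if force or not paths["mask"].exists():
        t0 = time.time()
        seg = config.segmentation
        mask = segmentation.binarize_volume(
            image, channel=seg.channel, threshold=seg.threshold,
            closing_radius=seg.closing_radius, smooth_sigma=seg.smooth_sigma,
        )
        if seg.levelset_iterations > 0:
            mask = segmentation.refine_mask_levelset(
                mask, image, channel=seg.channel,
                iterations=seg.levelset_iterations,
            )
        io.write_mask(paths["mask"], mask)
        _log(log, {"stage": "segment", "frame": frame_id,
                   "wall_s": round(time.time() - t0, 3),
                   "input": _hash_file(paths["image"])})
    mask = io.read_mask(paths["mask"], spacing=np.asarray(config.spacing))

    # mesh
    if force or not paths["mesh"].exists():
        t0 = time.time()
        if paths["input_mesh"].exists():
            mesh = io.read_obj(paths["input_mesh"])
        else:
            m = config.meshing
            mesh = segmentation.mask_to_mesh(
                mask, level=m.level, smooth_sigma=m.smooth_sigma
            )
            if m.taubin_iterations:
                mesh = segmentation.smooth_mesh(mesh, m.taubin_iterations)
        if not isinstance(mesh, TriangleMeshUV):
            mesh = _unwrap_mesh(config, mesh)
        io.write_obj(paths["mesh"], mesh)
        _log(log, {"stage": "mesh+unwrap", "frame": frame_id,
                   "wall_s": round(time.time() - t0, 3)})
    mesh = io.read_obj(paths["mesh"])
    if not isinstance(mesh, TriangleMeshUV):
        raise ValueError(f"stage 'project': mesh {paths['mesh']} has no UV map")

    # project
    if force or not paths["projection"].exists():
        t0 = time.time()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            proj = projection.pullback(
                image, mesh, tuple(config.grid_shape), offsets=list(config.offsets)
            )
        projection.write_pullback(paths["projection"].with_suffix(""), proj)
        _log(log, {"stage": "project", "frame": frame_id,
                   "wall_s": round(time.time() - t0, 3),
                   "warnings": [str(w.message) for w in caught]})

    # analyze: distortion raster
    if force or not paths["distortion"].exists():
        t0 = time.time()
        dist = analysis.area_distortion(
            mesh, grid_shape=tuple(config.grid_shape), skip_degenerate=True
        )
        import tifffile

        tifffile.imwrite(paths["distortion"], dist.raster.astype(np.float32))
        _log(log, {"stage": "analyze", "frame": frame_id,
                   "wall_s": round(time.time() - t0, 3)})
    return paths


def run_sequence(config: ProjectConfig, force: bool = False) -> dict[int, dict]:
    """Mesh every frame, propagate the reference UV map, project all frames.

    Per-frame alignment residuals are written to ``residuals.csv``.
    """
    if config.reference_frame is None:
        raise ValueError("run_sequence requires reference_frame in the config")
    if len(config.frames) == 1:
        return {config.frames[0]: run_frame(config, config.frames[0], force=force)}

    # stage 1: segment + mesh every frame (reference gets its UV here)
    meshes: dict[int, TriangleMesh] = {}
    images = {}
    all_paths = {}
    for fid in config.frames:
        paths = frame_paths(config, fid)
        paths["mask"].parent.mkdir(parents=True, exist_ok=True)
        all_paths[fid] = paths
        if not paths["image"].exists():
            raise FileNotFoundError(f"stage 'segment': missing input {paths['image']}")
        image = io.read_volume(paths["image"], spacing=np.asarray(config.spacing))
        images[fid] = image
        if paths["input_mesh"].exists():
            mesh = io.read_obj(paths["input_mesh"])
        else:
            seg = config.segmentation
            mask = segmentation.binarize_volume(
                image, channel=seg.channel, threshold=seg.threshold,
                closing_radius=seg.closing_radius, smooth_sigma=seg.smooth_sigma,
            )
            mesh = segmentation.mask_to_mesh(mask)
        meshes[fid] = mesh

    ref_id = config.reference_frame
    ref_mesh = meshes[ref_id]
    if not isinstance(ref_mesh, TriangleMeshUV):
        ref_mesh = _unwrap_mesh(config, ref_mesh)

    frames = [
        alignment.Frame(mesh=(ref_mesh if fid == ref_id else meshes[fid]))
        for fid in config.frames
    ]
    seq = alignment.SurfaceSequence(
        frames=frames, reference_index=config.frames.index(ref_id)
    )
    a = config.alignment
    kwargs: dict = {}
    if a.method == "shrinkwrap":
        kwargs = {"iterations": a.iterations, "smooth_per_iter": a.smooth_per_iter,
                  "allow_scale": a.allow_scale}
    elif a.method == "moebius":
        kwargs = {"rotation_grid": a.rotation_grid}
    elif a.method == "rigid":
        kwargs = {"allow_scale": a.allow_scale}
    out_seq = alignment.propagate_sequence(seq, method=a.method, **kwargs)

    residual_rows = ["frame,rms_residual_um"]
    for fid, frame in zip(config.frames, out_seq.frames):
        paths = all_paths[fid]
        io.write_obj(paths["mesh"], frame.mesh)
        proj = projection.pullback(
            images[fid], frame.mesh, tuple(config.grid_shape),
            offsets=list(config.offsets),
        )
        projection.write_pullback(paths["projection"].with_suffix(""), proj)
        residual_rows.append(f"{fid},{frame.residual}")
        _log(paths["log"], {"stage": "propagate+project", "frame": fid,
                            "residual_um": frame.residual})
    res_path = all_paths[config.frames[0]]["residuals"]
    res_path.write_text("\n".join(residual_rows) + "\n")
    return all_paths
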