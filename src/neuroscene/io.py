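"""File formats and declarative scene configs.

Readers and writers for the formats the toolkit exchanges with the
outside world: OBJ surfaces, NIfTI-1 volumes, CSV tables for sources and
connectivity, plain-text hypnograms, annotation CSVs, and raster image
export (PNG/JPG/TIFF, GIF animations). A JSON scene config describes a
whole figure declaratively — objects, computations, subplot placements,
cameras — and :func:`run_scene` executes it headlessly.

CSV dialect everywhere: comma separator, mandatory header row, UTF-8,
``.`` decimal point.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v2 as imageio
import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image

from .colors import ColorSpec, map_colors
from .connect import ConnectivityGraph, color_edges, select_edges
from .mesh import TriMesh, make_synthetic_brain
from .scene import Camera, Drawable, Scene, autocrop, camera_preset, render
from .signal import Hypnogram
from .sources import SourceSet, marker_radii, project_data
from .volume import LabeledVolume, ScalarVolume, extract_roi_mesh, make_synthetic_atlas

__all__ = [
    "read_obj",
    "write_obj",
    "read_nifti",
    "write_nifti",
    "read_sources_csv",
    "write_sources_csv",
    "read_connect_csv",
    "write_connect_csv",
    "read_hypnogram",
    "write_hypnogram",
    "read_annotations",
    "write_annotations",
    "save_image",
    "save_gif",
    "SceneConfigError",
    "load_scene_config",
    "run_scene",
]


# ---------------------------------------------------------------------------
# OBJ surfaces (v/f subset; 1-based indices on disk, 0-based in memory)


def read_obj(path) -> TriMesh:
    """Read a triangulated OBJ file (``v`` and ``f`` records only)."""
    vertices, faces = [], []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if parts[0] == "v":
                if len(parts) < 4:
                    raise ValueError(f"{path}:{ln}: vertex needs 3 coordinates")
                vertices.append([float(p) for p in parts[1:4]])
            elif parts[0] == "f":
                if len(parts) != 4:
                    raise ValueError(f"{path}:{ln}: only triangular faces supported")
                idx = [int(p.split("/")[0]) for p in parts[1:4]]
                if any(i < 1 for i in idx):
                    raise ValueError(
                        f"{path}:{ln}: OBJ face indices are 1-based; got {idx}"
                    )
                faces.append([i - 1 for i in idx])
    return TriMesh(vertices=np.asarray(vertices), faces=np.asarray(faces, dtype=np.int64))


def write_obj(mesh: TriMesh, path) -> None:
    """Write a mesh as OBJ; round-trips through :func:`read_obj` to 1e-6."""
    with open(path, "w", encoding="utf-8") as fh:
        for x, y, z in mesh.vertices:
            fh.write(f"v {x:.6f} {y:.6f} {z:.6f}\n")
        for a, b, c in mesh.faces + 1:
            fh.write(f"f {a} {b} {c}\n")


# ---------------------------------------------------------------------------
# NIfTI volumes


def _nifti_affine(img) -> np.ndarray:
    """Affine with a stated priority: sform if valid, else qform, else error."""
    sform, scode = img.get_sform(coded=True)
    if scode > 0:
        return sform
    qform, qcode = img.get_qform(coded=True)
    if qcode > 0:
        return qform
    raise ValueError("NIfTI file has neither a valid sform nor qform affine")


def read_nifti(path, kind: str = "scalar"):
    """Read a NIfTI-1 volume as a :class:`ScalarVolume` or :class:`LabeledVolume`.

    ``kind='labeled'`` requires integer-valued data; the label table is
    built from the distinct nonzero labels (``roi_<id>`` names) and can
    be replaced from a 2-column ``id,name`` CSV afterwards.
    """
    img = nib.load(str(path))
    affine = _nifti_affine(img)
    data = np.asanyarray(img.dataobj)
    if kind == "scalar":
        return ScalarVolume(data=np.asarray(data, dtype=float), affine=affine)
    if kind == "labeled":
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr), atol=0):
                raise ValueError(f"{path}: labeled volume requires integer labels")
            arr = np.round(arr).astype(np.int64)
        arr = arr.astype(np.int64)
        table = {int(i): f"roi_{int(i)}" for i in np.unique(arr) if i != 0}
        return LabeledVolume(labels=arr, affine=affine, table=table)
    raise ValueError(f"kind must be 'scalar' or 'labeled', got {kind!r}")


def write_nifti(vol, path) -> None:
    """Write a scalar or labeled volume as NIfTI-1 (sform set)."""
    data = vol.labels if isinstance(vol, LabeledVolume) else vol.data
    img = nib.Nifti1Image(np.asarray(data), vol.affine)
    img.set_sform(vol.affine, code=2)
    img.set_qform(vol.affine, code=2)
    nib.save(img, str(path))


def read_label_table(path) -> dict[int, str]:
    """2-column ``id,name`` CSV -> label table dict."""
    df = pd.read_csv(path)
    _need_columns(df, ["id", "name"], path)
    return {int(r.id): str(r.name) for r in df.itertuples()}


def write_label_table(table: dict[int, str], path) -> None:
    pd.DataFrame(sorted(table.items()), columns=["id", "name"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# CSV tables


def _need_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_sources_csv(path) -> SourceSet:
    """Sources CSV with columns x,y,z and optional data,text,mask."""
    df = pd.read_csv(path)
    _need_columns(df, ["x", "y", "z"], path)
    return SourceSet(
        pos=df[["x", "y", "z"]].to_numpy(dtype=float),
        data=df["data"].to_numpy(dtype=float) if "data" in df else None,
        text=df["text"].to_numpy(dtype=object) if "text" in df else None,
        mask=df["mask"].to_numpy(dtype=bool) if "mask" in df else None,
    )


def write_sources_csv(src: SourceSet, path) -> None:
    df = pd.DataFrame(src.pos, columns=["x", "y", "z"])
    if src.data is not None:
        df["data"] = src.data
    if src.text is not None:
        df["text"] = src.text
    if src.mask is not None:
        df["mask"] = src.mask
    df.to_csv(path, index=False)


def read_connect_csv(path, pos: np.ndarray | None = None) -> ConnectivityGraph:
    """Connectivity CSV: square matrix with node-name header row/column,
    or a 3-column ``i,j,weight`` edge list.

    For the edge-list form, ``pos`` (or a square inferred from max index)
    supplies node positions; for the matrix form ``pos`` must be given
    by the caller (node names are kept only as a column order).
    """
    df = pd.read_csv(path, index_col=0)
    if set(df.columns) == {"j", "weight"} or list(df.columns) == ["j", "weight"]:
        # edge list with index column i
        df = pd.read_csv(path)
    if {"i", "j", "weight"}.issubset(df.columns):
        n = int(max(df["i"].max(), df["j"].max())) + 1
        w = np.full((n, n), np.nan)
        for r in df.itertuples():
            w[int(r.i), int(r.j)] = r.weight
            w[int(r.j), int(r.i)] = r.weight
        if pos is None:
            pos = np.zeros((n, 3))
        return ConnectivityGraph(pos=pos, weights=w)
    w = df.to_numpy(dtype=float)
    if w.shape[0] != w.shape[1]:
        raise ValueError(f"{path}: connectivity matrix must be square, got {w.shape}")
    if pos is None:
        pos = np.zeros((w.shape[0], 3))
    return ConnectivityGraph(pos=pos, weights=w)


def write_connect_csv(g: ConnectivityGraph, path, names=None) -> None:
    names = names or [f"node_{i}" for i in range(g.n_nodes)]
    pd.DataFrame(g.weights, index=names, columns=names).to_csv(path)


# ---------------------------------------------------------------------------
# hypnogram & annotations


def read_hypnogram(path) -> Hypnogram:
    """Plain-text hypnogram: one stage code per line.

    An optional ``#epoch_s=<seconds>`` header line sets the epoch
    length; without it the conventional 30 s is used.
    """
    epoch_s = 30.0
    stages = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line[1:].strip().startswith("epoch_s"):
                    epoch_s = float(line.split("=", 1)[1])
                continue
            stages.append(int(line))
    return Hypnogram(stages=np.asarray(stages, dtype=np.int64), epoch_s=epoch_s)


def write_hypnogram(h: Hypnogram, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#epoch_s={h.epoch_s:g}\n")
        fh.writelines(f"{int(s)}\n" for s in h.stages)


def read_annotations(path) -> pd.DataFrame:
    """Annotation CSV with required columns signal,time_s,text."""
    df = pd.read_csv(path)
    _need_columns(df, ["signal", "time_s", "text"], path)
    return df[["signal", "time_s", "text"]]


def write_annotations(records, path) -> None:
    """Write (signal, time_s, text) records (or an AnnotationTable)."""
    rows = getattr(records, "records", records)
    pd.DataFrame(rows, columns=["signal", "time_s", "text"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# images


def _to_uint8(img: np.ndarray) -> np.ndarray:
    return (np.clip(np.asarray(img, dtype=float), 0, 1) * 255).round().astype(np.uint8)


def save_image(img: np.ndarray, path) -> None:
    """Save a float RGBA image as PNG/JPG/TIFF (by extension)."""
    path = Path(path)
    arr = _to_uint8(img)
    if path.suffix.lower() in (".jpg", ".jpeg"):
        arr = arr[..., :3]
    Image.fromarray(arr).save(path)


def save_gif(frames, path, fps: float = 10.0) -> None:
    """Save a frame sequence as an animated GIF."""
    imageio.mimsave(str(path), [_to_uint8(f) for f in frames], duration=1.0 / fps, loop=0)


# ---------------------------------------------------------------------------
# scene configs


class SceneConfigError(ValueError):
    """Config validation failure; the message names the offending key path."""


def _req(d: dict, key: str, path: str, types=None):
    if key not in d:
        raise SceneConfigError(f"{path}.{key}: required key missing")
    v = d[key]
    if types is not None and not isinstance(v, types):
        raise SceneConfigError(
            f"{path}.{key}: expected {types}, got {type(v).__name__}"
        )
    return v


_OBJECT_TYPES = ("brain", "sources", "roi", "connectivity")


def load_scene_config(path) -> dict:
    """Load and validate a JSON scene config; errors name the bad key."""
    with open(path, encoding="utf-8") as fh:
        cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise SceneConfigError("config: top level must be a JSON object")
    canvas = _req(cfg, "canvas", "config", dict)
    _req(canvas, "width", "config.canvas", int)
    _req(canvas, "height", "config.canvas", int)
    objects = _req(cfg, "objects", "config", dict)
    for name, obj in objects.items():
        opath = f"config.objects.{name}"
        if not isinstance(obj, dict):
            raise SceneConfigError(f"{opath}: must be an object")
        otype = _req(obj, "type", opath, str)
        if otype not in _OBJECT_TYPES:
            raise SceneConfigError(
                f"{opath}.type: unknown type {otype!r}; known: {_OBJECT_TYPES}"
            )
        for key in obj:
            if key not in (
                "type", "file", "generator", "color", "cmap", "clim", "ids",
                "project", "radius_px", "lo", "hi", "nodes", "n", "subdiv",
                "gap", "n_rois", "shape",
            ):
                raise SceneConfigError(f"{opath}.{key}: unknown key")
    subplots = _req(cfg, "subplots", "config", list)
    for i, sp in enumerate(subplots):
        spath = f"config.subplots[{i}]"
        if not isinstance(sp, dict):
            raise SceneConfigError(f"{spath}: must be an object")
        _req(sp, "row", spath, int)
        _req(sp, "col", spath, int)
        names = _req(sp, "objects", spath, list)
        for name in names:
            if name not in objects:
                raise SceneConfigError(
                    f"{spath}.objects: unknown object reference {name!r}"
                )
    return cfg


def _build_color_spec(obj: dict, values=None) -> ColorSpec:
    clim = obj.get("clim")
    if clim is None and values is not None:
        finite = values[np.isfinite(values)]
        clim = (
            (float(finite.min()), float(finite.max()))
            if len(finite) and finite.min() < finite.max()
            else (0.0, 1.0)
        )
    return ColorSpec(cmap=obj.get("cmap", "viridis"), clim=clim or (0.0, 1.0))


def _build_objects(cfg: dict, base: Path, rng: np.random.Generator) -> dict[str, dict]:
    """Instantiate every config object; returns name -> {kind, payload}."""
    built: dict[str, dict] = {}
    seed = int(cfg.get("seed", 0))
    for name, obj in cfg["objects"].items():
        otype = obj["type"]
        if otype == "brain":
            if "file" in obj:
                mesh = read_obj(base / obj["file"])
            else:
                mesh = make_synthetic_brain(
                    subdiv=int(obj.get("subdiv", 3)), gap=float(obj.get("gap", 2.0)),
                    seed=seed,
                )
            built[name] = {"kind": "brain", "mesh": mesh, "spec": obj}
        elif otype == "sources":
            if "file" in obj:
                src = read_sources_csv(base / obj["file"])
            else:
                n = int(obj.get("n", 20))
                pos = rng.uniform([-60, -70, -50], [60, 70, 60], size=(n, 3))
                src = SourceSet(pos=pos, data=rng.uniform(0, 1, n))
            built[name] = {"kind": "sources", "src": src, "spec": obj}
        elif otype == "roi":
            if "file" in obj:
                atlas = read_nifti(base / obj["file"], kind="labeled")
            else:
                atlas = make_synthetic_atlas(
                    n_rois=int(obj.get("n_rois", 4)), seed=seed
                )
            ids = obj.get("ids", sorted(atlas.table))
            mesh = extract_roi_mesh(atlas, ids)
            built[name] = {"kind": "roi", "mesh": mesh, "atlas": atlas, "spec": obj}
        elif otype == "connectivity":
            nodes_name = obj.get("nodes")
            pos = built[nodes_name]["src"].pos if nodes_name in built else None
            if "file" in obj:
                g = read_connect_csv(base / obj["file"], pos=pos)
            else:
                n = len(pos) if pos is not None else 10
                if pos is None:
                    pos = rng.uniform(-50, 50, size=(n, 3))
                w = np.full((n, n), np.nan)
                iu, ju = np.triu_indices(n, k=1)
                pick = rng.random(len(iu)) < 0.2
                w[iu[pick], ju[pick]] = rng.uniform(0, 1, int(pick.sum()))
                g = ConnectivityGraph(pos=pos, weights=w)
            built[name] = {"kind": "connectivity", "graph": g, "spec": obj}
    return built


def _drawables_for(name: str, built: dict[str, dict]) -> list[Drawable]:
    entry = built[name]
    kind, spec = entry["kind"], entry["spec"]
    if kind in ("brain", "roi"):
        mesh = entry["mesh"]
        proj = spec.get("project")
        if proj:
            src = built[proj["sources"]]["src"]
            values, touched = project_data(src, mesh, radius=float(proj.get("radius", 10.0)))
            cspec = _build_color_spec(proj, values)
            vcolor = map_colors(values, cspec)
            vcolor[~touched] = (0.78, 0.78, 0.78, 1.0)
            mesh = TriMesh(
                vertices=mesh.vertices, faces=mesh.faces, hemi=mesh.hemi, vcolor=vcolor
            )
        return [Drawable(kind="mesh", mesh=mesh, color=tuple(spec.get("color", (0.78, 0.78, 0.78, 1.0))))]
    if kind == "sources":
        src = entry["src"]
        if src.data is not None:
            radii = marker_radii(src.data, 3.0, 9.0)
            cspec = _build_color_spec(spec, src.data)
            colors = map_colors(src.data, cspec)
        else:
            radii = np.full(len(src), float(spec.get("radius_px", 5.0)))
            colors = np.tile(np.asarray(spec.get("color", (1.0, 0.2, 0.2, 1.0)), dtype=float), (len(src), 1))
        return [Drawable(kind="markers", points=src.pos, radii=radii, colors=colors)]
    if kind == "connectivity":
        g = entry["graph"]
        lo = float(spec.get("lo", -np.inf))
        hi = float(spec.get("hi", np.inf))
        edges = select_edges(g, lo, hi)
        finite = g.weights[np.isfinite(g.weights)]
        cspec = _build_color_spec(spec, finite)
        cols = color_edges(g, edges, method="strength", spec=cspec)
        segs = np.array([[g.pos[i], g.pos[j]] for i, j, _ in edges]).reshape(-1, 2, 3)
        return [Drawable(kind="lines", segments=segs, colors=cols)]
    raise SceneConfigError(f"object {name!r}: unhandled kind {kind!r}")


def run_scene(config, base_dir=None, output=None, do_autocrop: bool | None = None):
    """Execute a scene config: build objects, render, write the image.

    ``config`` is a path to a JSON file or an already-validated dict.
    Returns the rendered (and possibly cropped) image array; writes it
    to ``output`` (or the config's ``output`` key) when given.
    """
    if isinstance(config, (str, Path)):
        base = Path(base_dir) if base_dir is not None else Path(config).parent
        cfg = load_scene_config(config)
    else:
        cfg = config
        base = Path(base_dir) if base_dir is not None else Path.cwd()
    rng = np.random.default_rng(int(cfg.get("seed", 0)))
    built = _build_objects(cfg, base, rng)

    background = tuple(cfg.get("background", (0.0, 0.0, 0.0, 1.0)))
    scene = Scene(background=background)
    for sp in cfg["subplots"]:
        cam_cfg = sp.get("camera", {})
        if "preset" in cam_cfg:
            camera = camera_preset(cam_cfg["preset"], zoom=float(cam_cfg.get("zoom", 1.0)))
        else:
            camera = Camera(
                azimuth=float(cam_cfg.get("azimuth", 0.0)),
                elevation=float(cam_cfg.get("elevation", 0.0)),
                zoom=float(cam_cfg.get("zoom", 1.0)),
            )
        for name in sp["objects"]:
            for drawable in _drawables_for(name, built):
                scene.add_to_subplot(
                    drawable,
                    row=sp["row"],
                    col=sp["col"],
                    row_span=int(sp.get("row_span", 1)),
                    col_span=int(sp.get("col_span", 1)),
                    camera=camera,
                )
    img = render(scene, cfg["canvas"]["width"], cfg["canvas"]["height"])
    crop = cfg.get("autocrop", False) if do_autocrop is None else do_autocrop
    if crop:
        img = autocrop(img, background)
    out = output or cfg.get("output")
    if out:
        save_image(img, base / out if not Path(out).is_absolute() else out)
    return img
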