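"""Subplot scenes and a small software rasterizer.

A :class:`Scene` is a grid of subplot cells, each holding drawables
(meshes, markers, lines, vectors, anchored images) and an orthographic
camera; cells may span several rows/columns, and superposition is simply
several drawables in one cell. Rendering is done entirely on the CPU
with a z-buffered triangle rasterizer and flat Lambert shading, so
figures can be produced headlessly (scripts, servers, CI) with
bit-identical output across runs.

Camera convention
-----------------
World coordinates are mm RAS. The view rotation is
``eye = Rx(-elevation) @ Rz(azimuth) @ (v - center)``; the camera looks
along ``-y'`` from the ``+y'`` side, the screen shows ``(x', z')`` with
``z'`` up. Hence azimuth 0 / elevation 0 is the front (anterior) view;
azimuth -90 the left view; elevation 90 the top view.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .mesh import TriMesh, vertex_normals

__all__ = [
    "Camera",
    "Drawable",
    "Scene",
    "camera_preset",
    "render",
    "autocrop",
    "animate_turntable",
]

_GRAY = (0.8, 0.8, 0.8, 1.0)


@dataclass
class Camera:
    """Orthographic camera: azimuth/elevation in degrees, zoom scale."""

    azimuth: float = 0.0
    elevation: float = 0.0
    zoom: float = 1.0
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.zoom <= 0:
            raise ValueError(f"zoom must be > 0, got {self.zoom}")

    def rotation(self) -> np.ndarray:
        """World -> eye rotation matrix."""
        az = np.deg2rad(self.azimuth)
        el = np.deg2rad(self.elevation)
        rz = np.array(
            [[np.cos(az), -np.sin(az), 0], [np.sin(az), np.cos(az), 0], [0, 0, 1]]
        )
        c, s = np.cos(-el), np.sin(-el)
        rx = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
        return rx @ rz


_PRESETS = {
    "front": (0.0, 0.0),
    "back": (180.0, 0.0),
    "left": (-90.0, 0.0),
    "right": (90.0, 0.0),
    "top": (0.0, 90.0),
    "bottom": (0.0, -90.0),
}


def camera_preset(name: str, zoom: float = 1.0, center=(0.0, 0.0, 0.0)) -> Camera:
    """Standard anatomical view: top, bottom, left, right, front, back."""
    try:
        az, el = _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; known: {', '.join(sorted(_PRESETS))}"
        ) from None
    return Camera(azimuth=az, elevation=el, zoom=zoom, center=tuple(center))


@dataclass
class Drawable:
    """One renderable primitive.

    ``kind`` selects the geometry interpretation:

    - ``mesh``: ``mesh`` (TriMesh) + optional ``face_mask``; per-vertex
      colors from ``mesh.vcolor`` or ``color``.
    - ``markers``: ``points`` (n, 3), ``radii`` px, ``colors`` (n, 4).
    - ``lines``: ``segments`` (n, 2, 3), ``colors`` (n, 2, 4) with
      endpoint color interpolation along each segment.
    - ``vectors``: ``points`` + ``directions`` (n, 3), drawn as segments
      from point to point + direction.
    - ``image``: 2D RGBA ``image`` anchored at 3D ``anchor``, drawn
      ``height_px`` tall.
    """

    kind: str
    mesh: TriMesh | None = None
    face_mask: np.ndarray | None = None
    points: np.ndarray | None = None
    directions: np.ndarray | None = None
    segments: np.ndarray | None = None
    radii: np.ndarray | float = 4.0
    colors: np.ndarray | None = None
    color: tuple = _GRAY
    image: np.ndarray | None = None
    anchor: np.ndarray | None = None
    height_px: int = 32

    def __post_init__(self) -> None:
        kinds = ("mesh", "markers", "lines", "vectors", "image")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}, got {self.kind!r}")
        need = {
            "mesh": ("mesh",),
            "markers": ("points",),
            "lines": ("segments",),
            "vectors": ("points", "directions"),
            "image": ("image", "anchor"),
        }[self.kind]
        for attr in need:
            if getattr(self, attr) is None:
                raise ValueError(f"drawable kind {self.kind!r} requires {attr!r}")
        for attr in ("points", "directions", "segments", "anchor", "image"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if not np.all(np.isfinite(v)):
                    raise ValueError(f"{attr} must be finite")
                setattr(self, attr, v)

    def world_points(self) -> np.ndarray:
        """All 3D points of the drawable (used for view fitting)."""
        if self.kind == "mesh":
            return self.mesh.vertices
        if self.kind == "markers":
            return np.atleast_2d(self.points)
        if self.kind == "lines":
            return self.segments.reshape(-1, 3)
        if self.kind == "vectors":
            p = np.atleast_2d(self.points)
            return np.vstack([p, p + np.atleast_2d(self.directions)])
        return np.atleast_2d(self.anchor)


@dataclass
class _Cell:
    row: int
    col: int
    row_span: int = 1
    col_span: int = 1
    drawables: list = field(default_factory=list)
    camera: Camera = field(default_factory=Camera)
    background: tuple = (0.0, 0.0, 0.0, 1.0)

    def footprint(self) -> set[tuple[int, int]]:
        return {
            (r, c)
            for r in range(self.row, self.row + self.row_span)
            for c in range(self.col, self.col + self.col_span)
        }


class Scene:
    """A subplot grid of drawables, the headless figure container."""

    def __init__(self, background=(0.0, 0.0, 0.0, 1.0)) -> None:
        self.background = tuple(background)
        self.cells: dict[tuple[int, int], _Cell] = {}

    def add_to_subplot(
        self,
        drawable: Drawable,
        row: int = 0,
        col: int = 0,
        row_span: int = 1,
        col_span: int = 1,
        camera: Camera | None = None,
    ) -> None:
        """Add a drawable to cell (row, col), creating the cell if absent.

        Several drawables in one cell are superimposed. A new cell whose
        footprint (including spans) overlaps a different existing cell
        raises; adding to an existing cell with mismatched spans also
        raises.
        """
        if row < 0 or col < 0:
            raise ValueError("row/col must be >= 0")
        if row_span < 1 or col_span < 1:
            raise ValueError("spans must be >= 1")
        key = (row, col)
        if key in self.cells:
            cell = self.cells[key]
            if (cell.row_span, cell.col_span) != (row_span, col_span):
                raise ValueError(
                    f"cell {key} already exists with spans "
                    f"({cell.row_span}, {cell.col_span})"
                )
        else:
            cell = _Cell(row, col, row_span, col_span, background=self.background)
            fp = cell.footprint()
            for other in self.cells.values():
                if fp & other.footprint():
                    raise ValueError(
                        f"cell ({row}, {col}) span ({row_span}, {col_span}) overlaps "
                        f"cell ({other.row}, {other.col})"
                    )
            self.cells[key] = cell
        cell.drawables.append(drawable)
        if camera is not None:
            cell.camera = camera

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of the grid, grown to cover every footprint."""
        if not self.cells:
            return (1, 1)
        rows = max(c.row + c.row_span for c in self.cells.values())
        cols = max(c.col + c.col_span for c in self.cells.values())
        return rows, cols


# ---------------------------------------------------------------------------
# rasterizer


def _blend_into(canvas, zbuf, ys, xs, depth, rgba, ztest=True):
    """Source-over blend of per-pixel RGBA where the z-test passes."""
    if len(ys) == 0:
        return
    if ztest:
        ok = depth < zbuf[ys, xs]
    else:
        ok = np.ones(len(ys), dtype=bool)
    ys, xs, depth, rgba = ys[ok], xs[ok], depth[ok], rgba[ok]
    a = rgba[:, 3:4]
    canvas[ys, xs, :3] = a * rgba[:, :3] + (1 - a) * canvas[ys, xs, :3]
    canvas[ys, xs, 3] = np.maximum(canvas[ys, xs, 3], rgba[:, 3])
    opaque = rgba[:, 3] > 0.0
    zbuf[ys[opaque], xs[opaque]] = depth[opaque]


def _raster_mesh(canvas, zbuf, draw, proj, viewport):
    mesh = draw.mesh
    pts, depth = proj(mesh.vertices)
    faces = mesh.faces
    if draw.face_mask is not None:
        faces = faces[np.asarray(draw.face_mask, dtype=bool)]
    if len(faces) == 0:
        return
    if mesh.vcolor is not None:
        vcol = mesh.vcolor
    else:
        vcol = np.tile(np.asarray(draw.color, dtype=float), (mesh.n_vertices, 1))
    # Flat Lambert headlight: light along the view axis (+y' in eye space).
    normals = vertex_normals(mesh)
    rot = proj.rotation
    n_eye = normals @ rot.T
    face_n = n_eye[faces].mean(axis=1)
    face_n /= np.maximum(np.linalg.norm(face_n, axis=1, keepdims=True), 1e-12)
    shade = 0.3 + 0.7 * np.maximum(0.0, face_n[:, 1])
    x0, y0, x1, y1 = viewport

    tri_xy = pts[faces]          # (m, 3, 2)
    tri_z = depth[faces]         # (m, 3)
    face_col = vcol[faces].mean(axis=1)
    order = np.argsort(-tri_z.mean(axis=1))  # back to front (z-buffer makes it exact)
    for fi in order:
        (ax, ay), (bx, by), (cx, cy) = tri_xy[fi]
        area = (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)
        if abs(area) < 1e-12:
            continue
        xmin = max(int(np.floor(min(ax, bx, cx))), x0)
        xmax = min(int(np.ceil(max(ax, bx, cx))), x1 - 1)
        ymin = max(int(np.floor(min(ay, by, cy))), y0)
        ymax = min(int(np.ceil(max(ay, by, cy))), y1 - 1)
        if xmin > xmax or ymin > ymax:
            continue
        gx, gy = np.meshgrid(
            np.arange(xmin, xmax + 1) + 0.5, np.arange(ymin, ymax + 1) + 0.5
        )
        w0 = ((bx - ax) * (gy - ay) - (by - ay) * (gx - ax)) / area
        w1 = ((cx - bx) * (gy - by) - (cy - by) * (gx - bx)) / area
        w2 = 1.0 - w0 - w1
        # w0 is the barycentric weight opposite vertex a? Use the
        # edge-function convention: lambda_c = w0, lambda_a = w1, lambda_b = w2.
        inside = (w0 >= 0) & (w1 >= 0) & (w2 >= 0)
        if not inside.any():
            continue
        ys = gy[inside].astype(int)
        xs = gx[inside].astype(int)
        lam_c, lam_a, lam_b = w0[inside], w1[inside], w2[inside]
        z = lam_a * tri_z[fi, 0] + lam_b * tri_z[fi, 1] + lam_c * tri_z[fi, 2]
        col = np.empty((len(ys), 4))
        col[:, :3] = face_col[fi, :3] * shade[fi]
        col[:, 3] = face_col[fi, 3]
        _blend_into(canvas, zbuf, ys, xs, z, col)


def _raster_markers(canvas, zbuf, draw, proj, viewport):
    pts3 = np.atleast_2d(draw.points)
    pts, depth = proj(pts3)
    n = len(pts3)
    radii = np.broadcast_to(np.atleast_1d(np.asarray(draw.radii, dtype=float)), (n,))
    if draw.colors is not None:
        cols = np.asarray(draw.colors, dtype=float).reshape(n, 4)
    else:
        cols = np.tile(np.asarray(draw.color, dtype=float), (n, 1))
    x0, y0, x1, y1 = viewport
    order = np.argsort(-depth)
    for i in order:
        px, py, r = pts[i, 0], pts[i, 1], max(radii[i], 0.5)
        xmin = max(int(np.floor(px - r)), x0)
        xmax = min(int(np.ceil(px + r)), x1 - 1)
        ymin = max(int(np.floor(py - r)), y0)
        ymax = min(int(np.ceil(py + r)), y1 - 1)
        if xmin > xmax or ymin > ymax:
            continue
        gx, gy = np.meshgrid(
            np.arange(xmin, xmax + 1) + 0.5, np.arange(ymin, ymax + 1) + 0.5
        )
        disc = (gx - px) ** 2 + (gy - py) ** 2 <= r * r
        ys, xs = gy[disc].astype(int), gx[disc].astype(int)
        z = np.full(len(ys), depth[i])
        rgba = np.tile(cols[i], (len(ys), 1))
        _blend_into(canvas, zbuf, ys, xs, z, rgba)


def _raster_segments(canvas, zbuf, segments, colors, proj, viewport):
    x0, y0, x1, y1 = viewport
    for seg, col in zip(segments, colors):
        (p0, p1), (c0, c1) = proj(seg), (col[0], col[1])
        a, b = p0[0], p0[1]
        za, zb = p1[0], p1[1]
        length = int(np.ceil(max(abs(b[0] - a[0]), abs(b[1] - a[1])))) + 1
        t = np.linspace(0.0, 1.0, max(length, 2))
        xs = np.round(a[0] + t * (b[0] - a[0]) - 0.5).astype(int)
        ys = np.round(a[1] + t * (b[1] - a[1]) - 0.5).astype(int)
        z = za + t * (zb - za)
        rgba = np.outer(1 - t, c0) + np.outer(t, c1)
        keep = (xs >= x0) & (xs < x1) & (ys >= y0) & (ys < y1)
        # Small depth bias so lines on a surface are not z-fought away.
        _blend_into(canvas, zbuf, ys[keep], xs[keep], z[keep] - 1e-6, rgba[keep])


def _raster_image(canvas, zbuf, draw, proj, viewport):
    img = np.asarray(draw.image, dtype=float)
    if img.ndim == 2:
        img = np.dstack([img, img, img, np.ones_like(img)])
    h_px = int(draw.height_px)
    w_px = max(int(round(h_px * img.shape[1] / img.shape[0])), 1)
    rows = (np.arange(h_px) * img.shape[0] / h_px).astype(int)
    cols = (np.arange(w_px) * img.shape[1] / w_px).astype(int)
    small = img[np.ix_(rows, cols)]
    pt, depth = proj(np.atleast_2d(draw.anchor))
    px, py, z = pt[0, 0], pt[0, 1], depth[0]
    x0, y0, x1, y1 = viewport
    ys, xs = np.meshgrid(
        np.arange(h_px) + int(py - h_px / 2), np.arange(w_px) + int(px - w_px / 2),
        indexing="ij",
    )
    keep = (xs >= x0) & (xs < x1) & (ys >= y0) & (ys < y1)
    _blend_into(
        canvas, zbuf,
        ys[keep], xs[keep],
        np.full(int(keep.sum()), z - 1e-6),
        small[keep],
    )


class _Projector:
    """Orthographic world -> pixel projection for one cell."""

    def __init__(self, camera: Camera, bounds_pts: np.ndarray, viewport) -> None:
        self.rotation = camera.rotation()
        self.center = np.asarray(camera.center, dtype=float)
        x0, y0, x1, y1 = viewport
        eye = (bounds_pts - self.center) @ self.rotation.T
        span_x = np.ptp(eye[:, 0]) if len(eye) else 1.0
        span_y = np.ptp(eye[:, 2]) if len(eye) else 1.0
        span = max(span_x, span_y, 1e-9)
        self.scale = camera.zoom * 0.9 * min(x1 - x0, y1 - y0) / span
        self.mid = (
            np.array([eye[:, 0].min() + eye[:, 0].max(),
                      eye[:, 2].min() + eye[:, 2].max()]) / 2.0
            if len(eye)
            else np.zeros(2)
        )
        self.cx, self.cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0

    def __call__(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        eye = (np.atleast_2d(pts) - self.center) @ self.rotation.T
        px = self.cx + (eye[:, 0] - self.mid[0]) * self.scale
        py = self.cy - (eye[:, 2] - self.mid[1]) * self.scale
        return np.column_stack([px, py]), -eye[:, 1]


def render(scene: Scene, width: int = 800, height: int = 600) -> np.ndarray:
    """Rasterize a scene to an (height, width, 4) float RGBA image.

    Each cell gets its viewport from the grid layout; within a cell,
    geometry is projected orthographically with the cell camera, fitted
    to 90% of the viewport and scaled by the camera zoom, then drawn
    with a z-buffer (strict nearer-wins) and flat Lambert headlight
    shading for meshes. The output is a pure function of the scene.
    """
    if width < 1 or height < 1:
        raise ValueError(f"canvas must be at least 1x1, got {width}x{height}")
    canvas = np.zeros((height, width, 4))
    canvas[:] = np.asarray(scene.background, dtype=float)
    zbuf = np.full((height, width), np.inf)
    rows, cols = scene.shape
    for cell in scene.cells.values():
        x0 = int(round(cell.col * width / cols))
        x1 = int(round((cell.col + cell.col_span) * width / cols))
        y0 = int(round(cell.row * height / rows))
        y1 = int(round((cell.row + cell.row_span) * height / rows))
        viewport = (x0, y0, x1, y1)
        canvas[y0:y1, x0:x1] = np.asarray(cell.background, dtype=float)
        pts = [d.world_points() for d in cell.drawables]
        if not pts:
            continue
        proj = _Projector(cell.camera, np.vstack(pts), viewport)
        for draw in cell.drawables:
            if draw.kind == "mesh":
                _raster_mesh(canvas, zbuf, draw, proj, viewport)
            elif draw.kind == "markers":
                _raster_markers(canvas, zbuf, draw, proj, viewport)
            elif draw.kind == "lines":
                segs = draw.segments
                cols_ = (
                    np.asarray(draw.colors, dtype=float)
                    if draw.colors is not None
                    else np.tile(np.asarray(draw.color, dtype=float), (len(segs), 2, 1))
                )
                _raster_segments(canvas, zbuf, segs, cols_, proj, viewport)
            elif draw.kind == "vectors":
                p = np.atleast_2d(draw.points)
                segs = np.stack([p, p + np.atleast_2d(draw.directions)], axis=1)
                cols_ = (
                    np.asarray(draw.colors, dtype=float)
                    if draw.colors is not None
                    else np.tile(np.asarray(draw.color, dtype=float), (len(segs), 2, 1))
                )
                _raster_segments(canvas, zbuf, segs, cols_, proj, viewport)
            elif draw.kind == "image":
                _raster_image(canvas, zbuf, draw, proj, viewport)
    return canvas


def autocrop(img: np.ndarray, background) -> np.ndarray:
    """Crop to the bounding box of pixels differing from ``background``.

    Comparison is exact; an all-background image is returned unchanged.
    Idempotent and never enlarging.
    """
    img = np.asarray(img)
    bg = np.asarray(background, dtype=img.dtype)
    nonbg = ~np.all(img == bg, axis=-1)
    if not nonbg.any():
        return img
    rows = np.flatnonzero(nonbg.any(axis=1))
    cols = np.flatnonzero(nonbg.any(axis=0))
    return img[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]


def animate_turntable(
    scene: Scene, n_frames: int = 36, degrees: float = 360.0,
    width: int = 400, height: int = 300,
) -> list[np.ndarray]:
    """Render ``n_frames`` with every camera azimuth offset stepwise.

    Frame j adds ``j * degrees / n_frames`` to each cell camera's
    azimuth; frame 0 therefore equals ``render(scene)``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    frames = []
    originals = {k: c.camera for k, c in scene.cells.items()}
    try:
        for j in range(n_frames):
            offset = j * degrees / n_frames
            for k, cell in scene.cells.items():
                cam = originals[k]
                cell.camera = replace(cam, azimuth=cam.azimuth + offset)
            frames.append(render(scene, width, height))
    finally:
        for k, cell in scene.cells.items():
            cell.camera = originals[k]
    return frames
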