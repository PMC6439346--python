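"""Triangulated brain surfaces.

Meshes live in world millimetres using the RAS convention (+x right,
+y anterior, +z superior); the hemisphere of a vertex is the sign of its
x coordinate (x < 0 is left), as in MNI space. Operations here are the
mesh-side computations the drawing layer needs: per-vertex normals for
shading, hemisphere splitting, plane-slice visibility masks, and
point-in-volume tests used to filter sources. A deterministic two-lobe
synthetic brain generator stands in for template anatomy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TriMesh",
    "vertex_normals",
    "split_hemispheres",
    "slice_mesh",
    "point_in_mesh",
    "make_icosphere",
    "make_synthetic_brain",
]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class TriMesh:
    """A triangulated surface.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex positions in world mm (RAS).
    faces : (m, 3) int array
        0-based vertex indices, counter-clockwise seen from outside.
    hemi : (n,) array of {"left", "right"}, optional
        Per-vertex hemisphere tag.
    vdata : (n,) float array, optional
        Per-vertex scalar data.
    vcolor : (n, 4) float array, optional
        Per-vertex RGBA.
    """

    vertices: np.ndarray
    faces: np.ndarray
    hemi: np.ndarray | None = None
    vdata: np.ndarray | None = None
    vcolor: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError(f"vertices must be (n, 3), got {self.vertices.shape}")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError(f"faces must be (m, 3), got {self.faces.shape}")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("vertices must be finite")
        n = len(self.vertices)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise ValueError(f"face indices must lie in [0, {n})")
        degen = (
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        )
        if np.any(degen):
            raise ValueError(
                f"{int(degen.sum())} degenerate face(s) repeat a vertex index"
            )
        for name in ("hemi", "vdata"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape != (n,):
                    raise ValueError(f"{name} must have length {n}, got {arr.shape}")
                setattr(self, name, arr)
        if self.vcolor is not None:
            self.vcolor = np.asarray(self.vcolor, dtype=float)
            if self.vcolor.shape != (n, 4):
                raise ValueError(f"vcolor must be ({n}, 4), got {self.vcolor.shape}")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_centroids(self) -> np.ndarray:
        """(m, 3) centroid of every face."""
        return self.vertices[self.faces].mean(axis=1)


def _face_normals_areas(mesh: TriMesh) -> tuple[np.ndarray, np.ndarray]:
    tri = mesh.vertices[mesh.faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    area2 = np.linalg.norm(cross, axis=1)  # 2x face area
    return cross, area2


def vertex_normals(mesh: TriMesh) -> np.ndarray:
    """Unit per-vertex normals, area-weighted over incident faces.

    The cross product of two triangle edges has magnitude twice the face
    area, so summing raw cross products per vertex is already the
    area-weighted accumulation. Vertices whose incident faces all have
    zero area (or no faces at all) get the fallback normal (0, 0, 1)
    with a warning.
    """
    cross, _ = _face_normals_areas(mesh)
    acc = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(acc, mesh.faces[:, k], cross)
    norms = np.linalg.norm(acc, axis=1)
    bad = norms < 1e-30
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} vertex normal(s) undefined (zero-area neighborhood); "
            "using (0, 0, 1)",
            stacklevel=2,
        )
        acc[bad] = (0.0, 0.0, 1.0)
        norms[bad] = 1.0
    return acc / norms[:, np.newaxis]


def _submesh(mesh: TriMesh, face_mask: np.ndarray) -> tuple[TriMesh, np.ndarray]:
    """Extract faces where ``face_mask``; returns submesh + original vertex indices."""
    faces = mesh.faces[face_mask]
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    sub = TriMesh(
        vertices=mesh.vertices[used],
        faces=remap[faces],
        hemi=None if mesh.hemi is None else mesh.hemi[used],
        vdata=None if mesh.vdata is None else mesh.vdata[used],
        vcolor=None if mesh.vcolor is None else mesh.vcolor[used],
    )
    return sub, used


def split_hemispheres(mesh: TriMesh) -> tuple[TriMesh, TriMesh, np.ndarray, np.ndarray]:
    """Split a mesh at the midsagittal plane x = 0.

    A face belongs to the left submesh when its centroid has x < 0,
    otherwise to the right; this assigns every face to exactly one side
    without duplicating midline geometry. Either side may be empty.

    Returns
    -------
    left, right : TriMesh
    left_index, right_index : int arrays
        Original vertex index of each submesh vertex.
    """
    cx = mesh.face_centroids()[:, 0] if mesh.n_faces else np.empty(0)
    left_mask = cx < 0
    left, left_idx = _submesh(mesh, left_mask)
    right, right_idx = _submesh(mesh, ~left_mask)
    return left, right, left_idx, right_idx


def slice_mesh(mesh: TriMesh, axis: str, coord: float, keep: str = "below") -> np.ndarray:
    """Face visibility mask for slicing along a world axis.

    A face stays visible iff its centroid lies on the kept side of the
    plane ``axis = coord`` (centroids exactly on the plane are kept).
    Returns a boolean mask of length ``n_faces``; no new geometry is
    created at the cut.
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of x, y, z, got {axis!r}")
    if keep not in ("below", "above"):
        raise ValueError(f"keep must be 'below' or 'above', got {keep!r}")
    c = mesh.face_centroids()[:, _AXES[axis]]
    return c <= coord if keep == "below" else c > coord


def _open_edge_count(faces: np.ndarray) -> int:
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges.sort(axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return int(np.sum(counts != 2))


def is_watertight(mesh: TriMesh) -> bool:
    """True iff every edge is shared by exactly two faces."""
    return mesh.n_faces > 0 and _open_edge_count(mesh.faces) == 0


def point_in_mesh(mesh: TriMesh, points: np.ndarray) -> np.ndarray:
    """Ray-parity containment test for a closed mesh.

    Casts one ray per query point along a fixed, slightly-jittered
    direction and counts triangle crossings (Moeller-Trumbore); odd
    parity means inside. The jitter (~1e-6) makes exact edge/vertex hits
    measure-zero in practice while keeping the test deterministic.

    Raises
    ------
    ValueError
        If the mesh is not watertight (reports the open-edge count).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[1] != 3:
        raise ValueError(f"points must be (k, 3), got {points.shape}")
    n_open = _open_edge_count(mesh.faces) if mesh.n_faces else -1
    if mesh.n_faces == 0 or n_open:
        raise ValueError(
            f"point_in_mesh requires a watertight mesh; found {max(n_open, 0)} "
            "open edge(s)"
        )

    direction = np.array([1.0, 1e-6, 2e-6])
    direction /= np.linalg.norm(direction)

    tri = mesh.vertices[mesh.faces]
    v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    # Ray direction is shared by all queries: precompute per-triangle terms.
    pvec = np.cross(direction, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > 1e-12
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)

    inside = np.empty(len(points), dtype=bool)
    for i, p in enumerate(points):
        tvec = p - v0
        u = np.einsum("ij,ij->i", tvec, pvec) * inv_det
        qvec = np.cross(tvec, e1)
        v = np.einsum("ij,j->i", qvec, direction) * inv_det
        t = np.einsum("ij,ij->i", e2, qvec) * inv_det
        hits = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-9)
        inside[i] = bool(np.sum(hits) % 2)
    return inside


# ---------------------------------------------------------------------------
# synthetic fixtures


def make_icosphere(subdiv: int = 2, radius: float = 1.0) -> TriMesh:
    """Icosahedron subdivided ``subdiv`` times and projected to a sphere.

    Vertex count is ``10 * 4**subdiv + 2``; the mesh is watertight.
    """
    if subdiv < 0:
        raise ValueError("subdiv must be >= 0")
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1)[:, np.newaxis]
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    for _ in range(subdiv):
        midpoint: dict[tuple[int, int], int] = {}
        vlist = list(verts)

        def mid(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            if key not in midpoint:
                m = vlist[a] + vlist[b]
                m = m / np.linalg.norm(m)
                midpoint[key] = len(vlist)
                vlist.append(m)
            return midpoint[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.array(vlist)
        faces = np.array(new_faces, dtype=np.int64)
    return TriMesh(vertices=verts * radius, faces=faces)


def _lobe(subdiv: int, rng: np.random.Generator) -> TriMesh:
    """One smoothly deformed icosphere lobe, roughly hemisphere-sized (mm)."""
    sphere = make_icosphere(subdiv, radius=1.0)
    v = sphere.vertices
    theta = np.arccos(np.clip(v[:, 2], -1, 1))
    phi = np.arctan2(v[:, 1], v[:, 0])
    # Low-order random angular harmonics: smooth, bounded bumpiness so the
    # radial deformation keeps the sphere topology (watertight, no folds).
    r = np.ones(len(v))
    for _ in range(4):
        l = rng.integers(1, 4)
        m = rng.integers(0, l + 1)
        amp = rng.uniform(0.02, 0.06)
        r += amp * np.cos(m * phi + rng.uniform(0, 2 * np.pi)) * np.cos(
            l * theta + rng.uniform(0, 2 * np.pi)
        )
    v = v * r[:, np.newaxis]
    # Anisotropic scale to brain-lobe proportions (mm): long in y, flat in x.
    v = v * np.array([32.0, 66.0, 48.0])
    return TriMesh(vertices=v, faces=sphere.faces.copy())


def make_synthetic_brain(subdiv: int = 3, gap: float = 2.0, seed: int = 0) -> TriMesh:
    """Two-lobe brain-like fixture mesh.

    Two independently deformed icosphere lobes are mirrored about the
    midsagittal plane and separated by ``gap`` mm along x; vertices carry
    ``left``/``right`` hemisphere tags. Each lobe is watertight and the
    output is bit-deterministic for a fixed seed.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    rng = np.random.default_rng(seed)
    right = _lobe(subdiv, rng)
    # Place the lobe's leftmost point exactly gap/2 from the midline.
    shift = gap / 2.0 - right.vertices[:, 0].min()
    rv = right.vertices + np.array([shift, 0.0, 0.0])
    lv = rv * np.array([-1.0, 1.0, 1.0])
    # Mirroring flips orientation; swap two face indices to restore CCW.
    lf = right.faces[:, [0, 2, 1]]
    n = len(rv)
    vertices = np.vstack([lv, rv])
    faces = np.vstack([lf, right.faces + n])
    hemi = np.array(["left"] * n + ["right"] * n)
    return TriMesh(vertices=vertices, faces=faces, hemi=hemi)
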