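"""Source sets: electrodes, sensors or reconstructed sources in 3D.

The projection operations solve a recurring problem with intracranial
recordings: electrode implantations differ across subjects, so
electrode-level results cannot be overlaid directly. Projecting each
source's datum onto all mesh vertices within a radius (10 mm by default)
gives a surface map comparable across subjects. Each vertex acts as a
bin accumulating data from nearby sources; here the accumulation is a
weighted mean with a linear distance taper, so a vertex near a single
source reports that source's value exactly and every projected value is
a convex combination of the contributing data.

The radius test is strict (``d < radius``): a source at exactly the
radius does not contribute, and the data projection and the repartition
count therefore agree on membership.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .mesh import TriMesh
from .volume import LabeledVolume, world_to_voxel

__all__ = [
    "SourceSet",
    "project_data",
    "project_repartition",
    "locate_sources",
    "filter_sources_by_volume",
    "marker_radii",
    "topo_map",
]


@dataclass
class SourceSet:
    """N points in world mm with optional per-source attributes.

    Parameters
    ----------
    pos : (n, 3) float array
        Positions in mm (RAS).
    data : (n,) float array, optional
        Scalar datum per source (power, t-value, ...).
    text : (n,) str array, optional
        Label per source.
    mask : (n,) bool array, optional
        True = active. Masked-out sources are excluded from projection
        but kept in the set (they render grayed, not hidden).
    color : (n, 4) float array, optional
        Per-source RGBA.
    """

    pos: np.ndarray
    data: np.ndarray | None = None
    text: np.ndarray | None = None
    mask: np.ndarray | None = None
    color: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pos = np.atleast_2d(np.asarray(self.pos, dtype=float))
        if self.pos.shape[1] != 3:
            raise ValueError(f"pos must be (n, 3), got {self.pos.shape}")
        if not np.all(np.isfinite(self.pos)):
            raise ValueError("source positions must be finite")
        n = len(self.pos)
        if self.data is not None:
            self.data = np.asarray(self.data, dtype=float)
            if self.data.shape != (n,):
                raise ValueError(f"data must have length {n}")
        if self.text is not None:
            self.text = np.asarray(self.text, dtype=object)
            if self.text.shape != (n,):
                raise ValueError(f"text must have length {n}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (n,):
                raise ValueError(f"mask must have length {n}")
        if self.color is not None:
            self.color = np.asarray(self.color, dtype=float)
            if self.color.shape != (n, 4):
                raise ValueError(f"color must be ({n}, 4)")

    def __len__(self) -> int:
        return len(self.pos)

    def active_indices(self) -> np.ndarray:
        if self.mask is None:
            return np.arange(len(self))
        return np.flatnonzero(self.mask)

    def take(self, idx: np.ndarray) -> "SourceSet":
        """Subset by source index, keeping all attached attributes."""
        idx = np.asarray(idx, dtype=np.int64)
        return SourceSet(
            pos=self.pos[idx],
            data=None if self.data is None else self.data[idx],
            text=None if self.text is None else self.text[idx],
            mask=None if self.mask is None else self.mask[idx],
            color=None if self.color is None else self.color[idx],
        )


def _neighbors(pos: np.ndarray, vertices: np.ndarray, radius: float):
    """Per-vertex lists of (source index, distance) with d < radius, strict."""
    tree = cKDTree(pos)
    hits = tree.query_ball_point(vertices, r=radius)
    for v, srcs in enumerate(hits):
        if not srcs:
            yield v, np.empty(0, dtype=np.int64), np.empty(0)
            continue
        srcs = np.asarray(srcs, dtype=np.int64)
        d = np.linalg.norm(pos[srcs] - vertices[v], axis=1)
        keep = d < radius  # query_ball_point includes d == radius
        yield v, srcs[keep], d[keep]


def project_data(
    src: SourceSet, mesh: TriMesh, radius: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Project source data onto mesh vertices within ``radius`` mm.

    For vertex v with contributing set S(v) = {i : d(i, v) < radius}
    (active sources only), the projected value is the weighted mean of
    ``data[S(v)]`` with linear taper weights ``w_i = 1 - d(i, v)/radius``;
    if all weights vanish (every contributor at distance ~radius) equal
    weights are used. Vertices with empty S(v) are untouched.

    Returns
    -------
    values : (n_vertices,) float array
        Projected value per vertex; NaN where untouched.
    touched : (n_vertices,) bool array
        True where at least one source contributed.
    """
    if src.data is None:
        raise ValueError("project_data requires src.data")
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    active = src.active_indices()
    values = np.full(mesh.n_vertices, np.nan)
    touched = np.zeros(mesh.n_vertices, dtype=bool)
    if len(active) == 0:
        return values, touched
    pos, data = src.pos[active], src.data[active]
    for v, idx, d in _neighbors(pos, mesh.vertices, radius):
        if len(idx) == 0:
            continue
        w = 1.0 - d / radius
        wsum = w.sum()
        if wsum < 1e-12:
            w = np.ones_like(w)
            wsum = w.sum()
        values[v] = float(np.dot(w, data[idx]) / wsum)
        touched[v] = True
    return values, touched


def project_repartition(src: SourceSet, mesh: TriMesh, radius: float = 10.0) -> np.ndarray:
    """Per-vertex count of sources strictly within ``radius`` mm.

    The 'cortical repartition' of a projection: how many (active)
    sources contributed to each vertex, under the same strict-radius
    rule as :func:`project_data`.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    active = src.active_indices()
    counts = np.zeros(mesh.n_vertices, dtype=np.int64)
    if len(active) == 0:
        return counts
    for v, idx, _ in _neighbors(src.pos[active], mesh.vertices, radius):
        counts[v] = len(idx)
    return counts


def locate_sources(src: SourceSet, atlas: LabeledVolume) -> pd.DataFrame:
    """Anatomical localization of each source in a labeled atlas.

    Each source is mapped to its nearest voxel; the record carries the
    label id and name found there. Sources outside the array or over
    background get id 0 and name ``"Not found"``. The returned DataFrame
    (columns: index, x, y, z, id, name) round-trips through CSV.
    """
    _, ijk = world_to_voxel(atlas.affine, src.pos)
    shape = atlas.labels.shape
    rows = []
    for n, ((x, y, z), (i, j, k)) in enumerate(zip(src.pos, ijk)):
        if all(0 <= v < s for v, s in zip((i, j, k), shape)):
            lab = int(atlas.labels[i, j, k])
        else:
            lab = 0
        name = atlas.table.get(lab, "Not found") if lab else "Not found"
        rows.append((n, x, y, z, lab, name))
    return pd.DataFrame(rows, columns=["index", "x", "y", "z", "id", "name"])


def filter_sources_by_volume(
    src: SourceSet, atlas: LabeledVolume, ids
) -> tuple[SourceSet, np.ndarray]:
    """Keep only sources located inside the given atlas regions.

    Composes :func:`locate_sources` with a label filter. Returns the
    subset and the original indices of the kept sources; the subset may
    be empty.
    """
    ids = {int(i) for i in np.atleast_1d(list(ids))}
    unknown = [i for i in sorted(ids) if i not in atlas.table]
    if unknown:
        raise KeyError(f"unknown label id(s): {unknown}")
    table = locate_sources(src, atlas)
    keep = table.index[table["id"].isin(ids)].to_numpy()
    return src.take(keep), keep


def marker_radii(data: np.ndarray, r_min: float = 5.0, r_max: float = 15.0) -> np.ndarray:
    """Map data affinely onto marker radii in [r_min, r_max] px.

    Constant data (zero range) maps every source to the midpoint radius.
    """
    if r_min > r_max:
        raise ValueError(f"need r_min <= r_max, got ({r_min}, {r_max})")
    data = np.asarray(data, dtype=float)
    lo, hi = data.min(), data.max()
    if hi == lo:
        return np.full(data.shape, (r_min + r_max) / 2.0)
    return r_min + (data - lo) / (hi - lo) * (r_max - r_min)


def topo_map(
    pos3d: np.ndarray, values: np.ndarray, grid_n: int = 64
) -> tuple[np.ndarray, np.ndarray]:
    """Topographic scalp map by inverse-distance interpolation.

    Channel positions on (or near) a head sphere are flattened by the
    azimuthal-equidistant projection about the apex (+z): a channel at
    polar angle theta from +z lands at planar radius theta / (pi/2), so
    the equator maps to the unit circle. Values are interpolated on a
    ``grid_n x grid_n`` grid over [-1, 1]^2 by inverse-distance weighting
    (power 2); pixels outside the unit disk are NaN. A pixel coincident
    with a channel gets that channel's value.

    Returns the map (row 0 = +y, anterior) and the (n, 2) projected
    channel positions.
    """
    pos3d = np.atleast_2d(np.asarray(pos3d, dtype=float))
    values = np.asarray(values, dtype=float).ravel()
    if len(pos3d) < 1:
        raise ValueError("need at least one channel")
    if len(values) != len(pos3d):
        raise ValueError("values length must match channel count")
    r = np.linalg.norm(pos3d, axis=1)
    if np.any(r < 1e-12):
        raise ValueError("channel at the head center cannot be projected")
    unit = pos3d / r[:, np.newaxis]
    theta = np.arccos(np.clip(unit[:, 2], -1.0, 1.0))
    phi = np.arctan2(unit[:, 1], unit[:, 0])
    rho = theta / (np.pi / 2.0)
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi)])

    d = np.linalg.norm(pts[:, np.newaxis, :] - pts[np.newaxis, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if d.min() < 1e-9:
        raise ValueError("duplicate projected channel positions")

    ax = np.linspace(-1.0, 1.0, grid_n)
    gx, gy = np.meshgrid(ax, ax[::-1])  # row 0 = +y
    px = np.stack([gx.ravel(), gy.ravel()], axis=1)
    dist2 = ((px[:, np.newaxis, :] - pts[np.newaxis, :, :]) ** 2).sum(axis=-1)
    exact = dist2 < 1e-18
    with np.errstate(divide="ignore"):
        w = 1.0 / dist2
    est = np.empty(len(px))
    hit = exact.any(axis=1)
    est[hit] = values[np.argmax(exact[hit], axis=1)]
    est[~hit] = (w[~hit] * values).sum(axis=1) / w[~hit].sum(axis=1)
    grid = est.reshape(grid_n, grid_n)
    grid[gx**2 + gy**2 > 1.0] = np.nan
    return grid, pts
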