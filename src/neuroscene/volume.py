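"""Labeled and scalar 3D volumes with voxel-to-world affines.

A volume couples a 3D array with an invertible 4x4 affine mapping 0-based
voxel indices (i, j, k) to world mm (RAS). Atlases are
:class:`LabeledVolume` instances (integer labels, 0 = background, plus an
id -> name table); anatomy and activation maps are
:class:`ScalarVolume`. On top of these sit the ROI computations (masking,
isosurface mesh extraction) and orthogonal cross-sections with activation
overlay, plus a synthetic blob atlas standing in for real parcellations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .colors import ColorSpec, map_colors
from .mesh import TriMesh

__all__ = [
    "LabeledVolume",
    "ScalarVolume",
    "world_to_voxel",
    "voxel_to_world",
    "roi_mask",
    "extract_roi_mesh",
    "cross_section",
    "overlay_section",
    "make_synthetic_atlas",
]


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    return affine


@dataclass
class LabeledVolume:
    """Atlas: integer label per voxel plus an id -> name table."""

    labels: np.ndarray
    affine: np.ndarray
    table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.min() < 0:
            raise ValueError("labels must be >= 0 (0 = background)")
        self.affine = _check_affine(self.affine)
        self.table = {int(k): str(v) for k, v in self.table.items()}
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.table)
        if missing:
            raise ValueError(f"labels missing from table: {sorted(missing)}")


@dataclass
class ScalarVolume:
    """Scalar 3D field (anatomy, activation) with its affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3D, got ndim={self.data.ndim}")
        self.affine = _check_affine(self.affine)


def voxel_to_world(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    """Map continuous voxel indices to world mm through the affine."""
    affine = _check_affine(affine)
    ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def world_to_voxel(affine: np.ndarray, xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map world mm to voxel indices.

    Returns the continuous indices and their nearest-integer rounding
    (ties to even, numpy convention).
    """
    affine = _check_affine(affine)
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    inv = np.linalg.inv(affine)
    cont = xyz @ inv[:3, :3].T + inv[:3, 3]
    return cont, np.rint(cont).astype(np.int64)


def roi_mask(vol: LabeledVolume, ids) -> np.ndarray:
    """Boolean mask of voxels whose label is in ``ids``."""
    ids = sorted({int(i) for i in np.atleast_1d(list(ids))})
    if not ids:
        raise ValueError("ids must be non-empty")
    unknown = [i for i in ids if i not in vol.table]
    if unknown:
        raise KeyError(f"unknown label id(s): {unknown}")
    return np.isin(vol.labels, ids)


def extract_roi_mesh(
    vol: LabeledVolume, ids, smooth_sigma: float = 1.0, level: float = 0.5
) -> TriMesh:
    """Isosurface mesh of a set of atlas regions, in world mm.

    The binary region mask is Gaussian-smoothed (``smooth_sigma`` voxels)
    and the ``level`` isosurface extracted by marching cubes; the volume
    is padded by one voxel so regions touching the array border still
    close. Vertices are mapped through the affine to world mm. The
    result is watertight.
    """
    mask = roi_mask(vol, ids)
    if not mask.any():
        raise ValueError(f"ids {sorted(set(np.atleast_1d(list(ids)).tolist()))} select no voxels")
    padded = np.pad(mask.astype(float), 1)
    if smooth_sigma > 0:
        padded = ndimage.gaussian_filter(padded, smooth_sigma)
    if not (padded.min() < level < padded.max()):
        raise ValueError(
            f"isosurface level {level} outside smoothed mask range "
            f"[{padded.min():.3g}, {padded.max():.3g}]; lower smooth_sigma"
        )
    verts, faces, _, _ = measure.marching_cubes(padded, level=level)
    verts -= 1.0  # undo padding offset
    world = voxel_to_world(vol.affine, verts)
    return TriMesh(vertices=world, faces=np.asarray(faces, dtype=np.int64))


def _ras_reoriented(data: np.ndarray, affine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Permute/flip axes so the affine is nearest-orthogonal RAS-aligned."""
    import nibabel as nib

    ornt = nib.orientations.io_orientation(affine)
    data_ras = nib.orientations.apply_orientation(data, ornt)
    affine_ras = affine @ nib.orientations.inv_ornt_aff(ornt, data.shape)
    return data_ras, affine_ras


def cross_section(vol: ScalarVolume, xyz) -> dict:
    """Orthogonal sagittal/coronal/axial slices through a world point.

    The volume is first reoriented to the nearest-orthogonal RAS axes
    (axis permutation and flips only; no resampling), then sliced at the
    voxel nearest to ``xyz``. Slices are oriented for display:

    - ``sagittal`` (constant x): rows +z -> -z, cols -y -> +y
    - ``coronal`` (constant y): rows +z -> -z, cols -x -> +x
    - ``axial``   (constant z): rows +y -> -y, cols -x -> +x

    Returns a dict with the three 2D arrays and ``crosshair``, the
    (i, j, k) voxel of the reoriented array.
    """
    data, affine = _ras_reoriented(vol.data, vol.affine)
    _, ijk = world_to_voxel(affine, xyz)
    i, j, k = (int(v) for v in ijk[0])
    for ax, (idx, size) in enumerate(zip((i, j, k), data.shape)):
        if not 0 <= idx < size:
            raise IndexError(
                f"xyz={tuple(np.atleast_1d(xyz).tolist())} maps outside the volume "
                f"on axis {'xyz'[ax]} (voxel {idx}, size {size})"
            )
    sagittal = data[i, :, :].T[::-1, :]    # (j, k) -> rows z desc, cols y asc
    coronal = data[:, j, :].T[::-1, :]     # (i, k) -> rows z desc, cols x asc
    axial = data[:, :, k].T[::-1, :]       # (i, j) -> rows y desc, cols x asc
    return {
        "sagittal": sagittal,
        "coronal": coronal,
        "axial": axial,
        "crosshair": (i, j, k),
    }


def overlay_section(anat: np.ndarray, act: np.ndarray, spec: ColorSpec) -> np.ndarray:
    """Composite an activation slice over a grayscale anatomy slice.

    Anatomy is min-max normalized to an opaque grayscale image;
    activation values are colored by ``spec`` (non-finite values get the
    ``bad`` color, by default fully transparent, so they leave the
    anatomy visible) and composited with source-over alpha blending:
    ``out = a * c_act + (1 - a) * c_anat``.
    """
    anat = np.asarray(anat, dtype=float)
    act = np.asarray(act, dtype=float)
    if anat.shape != act.shape:
        raise ValueError(f"shape mismatch: anat {anat.shape} vs act {act.shape}")
    finite = np.isfinite(anat)
    lo = anat[finite].min() if finite.any() else 0.0
    hi = anat[finite].max() if finite.any() else 1.0
    g = np.zeros_like(anat) if hi == lo else np.clip((anat - lo) / (hi - lo), 0, 1)
    g = np.where(finite, g, 0.0)
    base = np.dstack([g, g, g, np.ones_like(g)])

    over = map_colors(act.ravel(), spec).reshape(act.shape + (4,))
    a = over[..., 3:4]
    out = np.empty_like(base)
    out[..., :3] = a * over[..., :3] + (1 - a) * base[..., :3]
    out[..., 3] = 1.0
    return out


def make_synthetic_atlas(
    n_rois: int = 5,
    shape: tuple[int, int, int] = (40, 48, 40),
    seed: int = 0,
    radius_range: tuple[float, float] = (3.0, 6.0),
    affine: np.ndarray | None = None,
) -> LabeledVolume:
    """Synthetic atlas: non-overlapping spherical blobs labeled 1..n_rois.

    Blob centers and radii are drawn deterministically from ``seed``;
    regions are named ``roi_<id>``. Placement retries until the blobs
    neither overlap nor touch the array border; persistent failure (too
    many regions for the array) raises.
    """
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, dtype=np.int32)
    grid = np.indices(shape, dtype=float)
    placed: list[tuple[np.ndarray, float]] = []
    for roi in range(1, n_rois + 1):
        for _ in range(200):
            r = rng.uniform(*radius_range)
            if any(s - r - 2 <= r + 1 for s in shape):
                continue  # blob too large for the array; retry with another r
            center = np.array([rng.uniform(r + 1, s - r - 2) for s in shape])
            if all(np.linalg.norm(center - c) > r + pr + 1.5 for c, pr in placed):
                break
        else:
            raise RuntimeError(
                f"could not place {n_rois} non-overlapping blobs in shape {shape}"
            )
        d2 = sum((grid[a] - center[a]) ** 2 for a in range(3))
        labels[d2 <= r * r] = roi
        placed.append((center, r))
    if affine is None:
        # 2 mm isotropic, centered: a plausible standard-space-like affine.
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        affine[:3, 3] = -np.asarray(shape, dtype=float)  # = -(shape/2)*2mm
    table = {i: f"roi_{i}" for i in range(1, n_rois + 1)}
    return LabeledVolume(labels=labels, affine=affine, table=table)
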