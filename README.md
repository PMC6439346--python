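# neuroscene

Headless composition and rendering of neuro-oriented visual objects:
brain surface meshes, source/electrode sets, ROI atlas volumes,
connectivity graphs, multidimensional signals, and a subplot scene that
renders them to static or animated images on the CPU — no GPU, no GUI,
no display server.

## Who this is for

Researchers working with intracranial EEG, M/EEG or fMRI-derived data
who need reproducible, scriptable figures of results in 3D brain space:
electrode locations, activity projected onto a cortical surface,
region-of-interest meshes, connectivity links, sleep hypnograms and
spectral summaries — generated on a laptop, a cluster node or CI, with
bit-identical output for a fixed input.

## The core computations

**Cortical projection.** Electrode implantations differ across
subjects, so electrode-level results cannot be overlaid directly.
Each mesh vertex *v* acts as a bin accumulating data from the sources
within a radius *r* (10 mm by default, strict `d < r`):

```
value(v) = Σᵢ wᵢ·dataᵢ / Σᵢ wᵢ,   wᵢ = 1 − d(i,v)/r,   i ∈ S(v) = {i : d(i,v) < r}
```

a convex combination, so a vertex near a single source reports that
source's value exactly and projected values never leave the data range.
The *repartition* map is `|S(v)|`, the number of contributing sources
per vertex. Sources can also be localized against a labeled atlas
volume (nearest voxel through the inverse affine) and filtered by
region or by mesh containment (ray-parity test on watertight meshes).

**ROI meshing.** A region mask from a labeled volume is Gaussian-smoothed
(σ = 1 voxel), its 0.5 level set extracted by marching cubes, and the
vertices mapped through the voxel→world affine — a closed surface per
region in mm coordinates.

**Signal inspection.** An n-dimensional recording is flattened over its
non-time axes and laid out on a near-square grid: among divisor pairs
r·c = n with r ≥ c the pair minimizing r − c is chosen (104 signals →
13 × 8), with a floor(√n) fallback for elongated factorizations. Each
signal can be summarized by a Welch PSD, a Morlet-wavelet
time-frequency map (σ_t = width/2πf, unit-energy, with subtract /
divide / percent / z-score baseline normalizations), histograms, and
strict-threshold extrema detection.

**Scenes.** Drawables are placed in subplot cells with orthographic
cameras (azimuth/elevation/zoom) and rasterized with a z-buffer and
flat Lambert headlight shading; images can be auto-cropped to the
non-background bounding box and turntable animations exported as GIF.

## Worked example

```python
import numpy as np
from neuroscene import (
    make_synthetic_brain, SourceSet, project_data, project_repartition,
    grid_shape, ColorSpec, map_colors, TriMesh,
    Scene, Drawable, camera_preset, render,
)

brain = make_synthetic_brain(subdiv=3, gap=2.0, seed=0)
print(f"brain mesh: {brain.n_vertices} vertices, {brain.n_faces} faces")

rng = np.random.default_rng(0)
picks = rng.choice(brain.n_vertices, 20, replace=False)
src = SourceSet(pos=brain.vertices[picks], data=rng.uniform(0, 1, 20))

values, touched = project_data(src, brain, radius=10.0)
counts = project_repartition(src, brain, radius=10.0)
print(f"projection: {touched.sum()} of {brain.n_vertices} vertices touched")
print(f"max sources per vertex: {counts.max()}")

vcolor = map_colors(values, ColorSpec(cmap="hot", clim=(0.0, 1.0)))
vcolor[~touched] = (0.78, 0.78, 0.78, 1.0)
colored = TriMesh(vertices=brain.vertices, faces=brain.faces, vcolor=vcolor)

scene = Scene()
scene.add_to_subplot(Drawable(kind="mesh", mesh=colored), 0, 0,
                     camera=camera_preset("left"))
scene.add_to_subplot(Drawable(kind="mesh", mesh=colored), 0, 1,
                     camera=camera_preset("top"))
img = render(scene, 640, 280)
print(f"rendered image: {img.shape}")
print(f"grid for 104 signals: {grid_shape(104)}")
```

prints

```
brain mesh: 1284 vertices, 2560 faces
projection: 147 of 1284 vertices touched
max sources per vertex: 2
rendered image: (280, 640, 4)
grid for 104 signals: (13, 8)
```

147 of the 1284 vertices lie strictly within 10 mm of one of the 20
contacts; at most two contacts contribute to any single vertex at this
contact density. The image is a float RGBA array — save it with
`neuroscene.io.save_image(img, "figure.png")`.

The same figure can be described declaratively in a JSON scene config
and produced from the shell:

```bash
neuroscene demo --out gallery/          # synthetic fixtures + rendered demo
neuroscene render gallery/demo_scene.json -o figure.png --autocrop
neuroscene grid -n 104                  # -> 13 8
```

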