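# Methods

This note documents the models, conventions and numerical choices
behind `neuroscene`, in the order a figure flows through the package:
color mapping, geometry, volumes, sources, connectivity, signals, and
the scene rasterizer. It also states what the synthetic fixtures do and
do not emulate.

## Coordinate conventions

All world coordinates are millimetres in RAS orientation (+x right,
+y anterior, +z superior), the convention of standard stereotaxic
space. Voxel indices are 0-based; a volume's 4×4 affine maps voxel
(i, j, k, 1) to world (x, y, z, 1) and must be invertible. When reading
NIfTI-1 files the sform is used if its code is valid, else the qform,
else the file is rejected — a stated priority rather than a silent
fallback. Nearest-voxel rounding uses ties-to-even (IEEE default).

## Color mapping

Every data-to-color conversion uses one rule (`ColorSpec`): anchors
interpolated linearly in RGB over clamped normalized position
t = (x − lo)/(hi − lo); values strictly below `vmin` / above `vmax` get
the dedicated under/over colors; non-finite values get `bad` (default
fully transparent) so output length always equals input length.
Thresholds are **exclusive**: x = vmin still receives the colormap.
Linear RGB interpolation was chosen over perceptual spaces because it
is the simplest exactly-reproducible rule; the built-in maps (`gray`,
`hot`, `viridis`-like, `coolwarm`) are small hard-coded anchor tables.

## Meshes

Vertex normals are area-weighted sums of incident-face normals (the
raw edge cross product already carries the area weight); degenerate
neighborhoods fall back to (0, 0, 1) with a warning rather than NaN.
The hemisphere rule is the sign of x (x < 0 = left); faces are assigned
by centroid so no midline geometry is duplicated. Plane slicing returns
a face-visibility mask by the same centroid rule — the mesh never gains
vertices at the cut, which matches a visibility-mask rendering model
and keeps slicing monotone in the cut coordinate. Containment uses
ray-crossing parity (Möller–Trumbore) with a fixed jittered ray
direction (~1e-6 relative) so edge/vertex grazes are measure-zero;
the mesh must be watertight, checked eagerly by edge-incidence counts,
and the error reports how many open edges were found.

## Synthetic brain fixture

`make_synthetic_brain` builds two icosphere lobes (vertex count
10·4^subdiv + 2 each), radially modulated by four low-order random
angular harmonics with amplitudes 0.02–0.06 (smooth, fold-free, so the
sphere topology — hence watertightness — is preserved), scaled
anisotropically to 32 × 66 × 48 mm half-axes, mirrored about the
midsagittal plane and separated by `gap` mm. Defaults (subdiv 3,
gap 2 mm) give 1284 vertices / 2560 faces, enough surface density that
a 10 mm projection radius touches a realistic neighborhood. The fixture
emulates scale, bilaterality and smooth curvature of a cortical
surface; it has no sulci/gyri, so results on it say nothing about
projection behavior in deep folds where Euclidean and geodesic
distances diverge.

## Volumes and ROI meshing

The synthetic atlas places non-overlapping spherical blobs (radius 3–6
voxels by default) in a 2 mm isotropic grid with a centered affine;
placement retries are bounded and failure raises rather than returning
a partial atlas. ROI meshes are extracted by Gaussian-smoothing the
binary region mask (σ = 1 voxel) and running marching cubes at level
0.5 — σ and level are exposed because they trade surface smoothness
against volume fidelity: smoothing a radius-5-voxel ball this way keeps
the enclosed (divergence-theorem) volume within a few percent of
(4/3)πr³. The mask is padded by one voxel first so regions touching
the array border still close. Cross-sections reorient the array to the
nearest-orthogonal RAS axes (permutation and flips only — oblique
resampling is out of scope) and return display-oriented slices
(axial rows +y→−y, cols −x→+x; coronal/sagittal analogous). Activation
overlays color the activation through a `ColorSpec` and composite
source-over onto the min-max-normalized grayscale anatomy, so NaN
(transparent `bad`) leaves anatomy visible and over-threshold pixels
show the `over` color exactly.

## Source projection

The projection weight is a linear taper w = 1 − d/r over the strict
neighborhood d < r, normalized to a weighted mean. This choice (over
inverse-distance weighting, the main alternative) was made for three
properties: output bounded by the data range (convex combination),
single-source exactness (weights cancel), and smooth falloff to zero
at the radius. The degenerate case Σw < 1e-12 (all contributors at
distance ≈ r) falls back to equal weights. Strict `d < r` is used for
both the data projection and the repartition count so the two agree on
membership exactly. The spatial query uses a k-d tree; the contract is
defined by (and tested against) the O(N·V) double loop, not by the
index structure. Masked-out sources are excluded from projection but
remain in the set for rendering.

Topographic maps project channels by the azimuthal-equidistant rule
about the apex (+z), with the equator mapped to the unit circle
(ρ = θ/(π/2)), then interpolate by inverse-distance weighting with
power 2; a pixel coinciding with a channel takes that channel's value.
IDW was chosen over spline interpolation (a non-goal) for
determinism and simplicity; it does not extrapolate beyond the data
range.

## Connectivity

Display is undirected: only the upper triangle of the weight matrix is
read, NaN marks absent edges, and edges are reported in canonical
(i < j, sorted) order so the ignored lower triangle can never influence
output. The three coloring methods are: strength (both endpoints by
edge weight), count (each endpoint by its node's degree — the renderer
interpolates along the segment, giving the node-anchored gradient
look), and manual.

## Signals

The grid-layout rule: among divisor pairs r·c = n with r ≥ c, minimize
r − c; if the best pair has aspect r/c > 4 (all primes above 3 land
here), fall back to c = floor(√n), r = ceil(n/c) with trailing empty
cells. Portrait orientation (rows ≥ cols) and the aspect threshold 4
are package choices; 104 signals yield the reference 13 × 8 layout via
the exact-divisor branch. PSD is a Welch estimate (Hann window,
segments of 4 s capped at the record, 50 % overlap, density scaling).
The Morlet wavelet at frequency f has σ_t = width/(2πf) with
width = 7 cycles by default, truncated at ±4σ_t and normalized to unit
discrete energy; power maps are baseline-normalized per frequency row
(subtract / divide / percent / z-score over the baseline samples).
Extrema detection uses strict inequalities (x > upper or x < lower) and
reports maximal half-open runs. Preprocessing: demean, least-squares
detrend, truncated centered moving average, and zero-phase Butterworth
filtering (order 4, second-order sections, forward-backward).
Hypnograms use the integer stage codes Art = −1, Wake = 0, N1–N3 = 1–3,
REM = 4 at a default 30 s epoch; percentages are over all epochs
including artefact and sum to 100.

## Scene rendering

The camera is orthographic (adequate for anatomical views, and it makes
pixel-coverage tests analytic). The view transform is
eye = Rx(−elevation)·Rz(azimuth)·(v − center); the camera looks along
−y′ from +y′, the screen shows (x′, z′) with z′ up, so
azimuth 0/elevation 0 is the front view, azimuth −90 the left view,
elevation 90 the top view. Within a cell the geometry's eye-space
extent is fitted to 90 % of the viewport and multiplied by the camera
zoom — the mm→px scale is therefore content-dependent but fully
deterministic. Triangles are filled by barycentric coverage at pixel
centers with a strict nearer-wins z-buffer; shading is flat per face,
0.3 + 0.7·max(0, n·view) with a headlight (smooth shading is a
non-goal). Markers are screen-space discs at their projected depth;
lines are 1-px sampled segments with endpoint color and depth
interpolation and a small (1e-6) depth bias so lines lying on surfaces
are not z-fought away. Rendering is a pure function of the scene
description: two runs produce bit-identical arrays, which is what makes
byte-identical PNG export testable. Auto-crop compares pixels exactly
against the background color and crops to the bounding box; an
all-background image is returned unchanged, making the operation
idempotent.

## Problem sizes in tests

The default suite exercises meshes up to 2562 vertices (subdivision-4
icosphere), 100-source projections against the full double-loop oracle,
1000 random affine round trips, 8 s synthetic recordings at 256 Hz, and
≤ 200×200 px renders — sizes chosen so every oracle comparison is exact
and the whole suite runs in seconds on one core.

## Known limitations

- No perspective projection, translucency sorting, or text rendering.
- Projection distance is Euclidean, not geodesic along the cortex.
- Oblique volumes are only reoriented to the nearest orthogonal axes,
  never resampled.
- The software rasterizer has no anti-aliasing; coverage is evaluated
  at pixel centers only.
- PDF/EPS export, GPU rendering, GUIs, sleep-event detection and
  phase-amplitude coupling are out of scope.
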