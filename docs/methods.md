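# Methods

## Phantom model

Phantoms are star-shaped surfaces `r(θ,φ) = d + A·Re{Y_l^m}/max|Re{Y_l^m}|`
sampled on a latitude–longitude grid (default 128 × 256; the floor of
32 × 64 keeps the l = 10 lobes resolved with several samples per
oscillation). The normalizer `max|Re{Y}|` is the maximum over the same
grid used for meshing, so every vertex satisfies the radial law exactly;
an analytic maximum would differ only in the 4th decimal at default
resolution. `Re{Y_l^m}` uses the Condon–Shortley sign convention inside
the associated Legendre function; since the profile is normalized by
`max|Re{Y}|`, the convention affects only an azimuthal phase, not the
geometry.

Grid quads are split along their shorter diagonal (ties split along the
`(i,j)–(i+1,j+1)` diagonal) and the poles collapse to single vertices,
giving a closed genus-0 triangulation. There are no stochastic steps
anywhere in the package; identical parameters give identical vertex
arrays and byte-identical STL files.

The mid-plane cut keeps the `z ≥ 0` half (the surface is symmetric
enough at l = 10, m = 5 that the choice only fixes orientation) and caps
the planar boundary with a triangle fan around its centroid, which is
valid because every cross-section of these models is star-shaped. Base
normalization applies a single *uniform* scale factor so the maximal
horizontal extent of the base equals 50 mm. Uniform scaling (rather
than height-only scaling) was chosen because it preserves every
dimensionless feature of the model exactly, so spiculatedness is the
only shape variable that changes along the sweep.

## Emulated acquisition

The physical chain (3D print → CT scan → HU thresholding) is replaced by
deterministic rasterization: a voxel is foreground iff its center lies
inside the closed surface, decided by the parity of z-ray crossings.
The ray grid is offset by a fixed sub-nanometre amount so mesh edges are
never hit exactly. Foreground is reduced to its largest 6-connected
component (spiculation tips rasterized at 2 mm slices detach into
islets that must not generate stray surfaces), and the grid is padded
with a one-voxel background border so isosurfaces are always closed. An
optional Gaussian-blur + 0.5-threshold mode emulates partial-volume
blur; it is off by default to keep the chain parameter-free.

Default spacings are 0.68 mm in-plane with 0.6 mm or 2 mm slices.
Resampling interpolates trilinearly onto a 1 mm³ grid sharing the mask
origin and re-binarizes at 0.5 (ties map to foreground). Volume
equalization and volume rescaling are pure homotheties realized by
recomputing the voxel spacing (and origin) — the arrays are untouched,
so the equalized M1 mesh volume lands exactly on the reference.

## Surface reconstruction

* **M1** — marching cubes on the 0/1 field at isovalue 0.9. On a binary
  field this places vertices 90 % of the way from background toward
  foreground centers, i.e. the surface is deliberately *shrunk* by about
  0.4 voxel relative to the mid-level. Consequence: M1 mesh volume is
  8–20 % below the voxel-count volume on the suite (most for the most
  spiculated models, whose surface is largest). Voxel counting estimates
  the mid-level set, so all mesh-vs-count consistency checks in the test
  suite mesh at isovalue 0.5, where agreement is within 0.3 % on the
  suite and the rasterized-solid oracles.
* **M2** — one smoothing pass that displaces vertices along their
  normals by `quantity × 0.01 × mean-edge-length × (normalized umbrella
  mean curvature)`. The exact operator of the original toolbox is
  unpublished; this operator is this package's own definition with the
  matching parameters (quantity 5, one iteration). High-curvature
  spicules move most; a constant-curvature sphere barely shrinks.
* **M3** — one isotropic remeshing pass: split edges > 4/3 × target,
  collapse edges < 4/5 × target (skipping collapses that violate the
  manifold link condition or would create over-long edges), valence-
  regularizing flips, tangential relaxation, and projection back onto
  the input surface (exact closest point among KD-tree candidates).
  Target edge length is 2 (millimetres — meshes live in mm; the value is
  configurable). Edges are processed in sorted order, so the pass is
  deterministic.
* **M4** — concave hull via the alpha complex of the Delaunay
  tetrahedralization of the M1 vertex cloud. Shrink factor 1 maps to the
  smallest alpha (bisection over the sorted circumradius scale) whose
  complex is face-connected, uses every coverable point, and has an
  edge-manifold boundary; shrink 0 is the convex hull. Flat sliver tets
  on lattice-aligned points get half their diameter as a finite
  circumradius proxy. On highly spiculated masks the manifold condition
  forces a large alpha, so the M4 boundary bridges spicules and behaves
  erratically — reproducing the known pathology of this method; the
  report flags M4 values > 3 MAD from the M1–M3 consensus.

A note on hull areas: the convex hull minimizes surface area only among
*convex* enclosures. A two-lobed point cloud's tight concave boundary
can have less area than its hull; on the suite masks the ordering
hull ≤ M4 ≤ M1 does hold and is asserted there.

## Features and statistics

All nine features derive from the triangulation itself: volume by the
divergence theorem (signed tetrahedra), area as the triangle-area sum,
hull area from the convex hull of the mesh vertices — never voxel
counting, keeping surface and volume mutually consistent. Compactness1
is implemented exactly as printed, `V/(√π·A^(2/3))`, which is *not*
dimensionless (it scales as s^(5/3) under homothety); a flag exposes the
dimensionless `V/(√π·A^(3/2))` variant for comparison. The algebraic
identities `SD·Sph = 1`, `C2 = Sph³`, `C3 = √Sph` hold to 1e−9 on every
computed vector and explain why these features always carry identical
rank information.

Spearman correlations use average ranks with the t-approximation
p-value and Fisher-z 95 % confidence intervals. Percent changes are
always `100·|value − reference|/|reference|` with the reference being
the designated baseline arm: the STL value, the 2 mm-slice value, the
original-grid value, the unscaled-volume value, and — for the
spiculatedness span — the most spiculated model (d = 11). For the
volume-sensitivity experiment the reconstructed surface is rescaled
homothetically (fixed topology), so dimensionless features are exactly
volume-invariant; the *volume spread* of a feature is the full span of
its values across the 25–150 % sweep as a percentage of the unscaled
value, and a feature is volume-robust when that spread is below its
spiculatedness span. Under these conventions surface-to-volume and
compactness1 classify as volume-sensitive and the five dimensionless
features as volume-robust.

## What the synthetic chain does and does not emulate

The generator reproduces the geometric content of the study conditions:
graded spiculatedness, identical 50 mm bases, anisotropic voxel grids,
partial-volume loss of thin spicules at coarse slices, islet formation,
and meshing-algorithm bias. It does not model CT physics (reconstruction
kernels, noise, HU calibration), printing materials, or segmentation
operator variability; rasterization is noise-free and deterministic.
Passing tests therefore demonstrate the *ordinal* robustness structure
(which features rank models stably, which degrade with slice thickness
or volume) rather than the exact percentage changes a physical scanner
would produce. Correlations with spiculatedness come out essentially
perfect (|ρ| ≈ 1.00, fractional concavity 0.998) because the chain is
noise-free; a physical chain adds measurement noise that lowers them
toward the ~0.98 regime.

Rank-preservation under resampling holds exactly for the seven
surface/volume-derived features; fractional concavity and volume show
adjacent swaps only between models whose values differ by < 0.3 % —
exact ties at any realistic measurement precision — and the tests treat
those as preserved.

## Numerical choices and limitations

* Trilinear binarization threshold 0.5, ties to foreground (symmetric,
  deterministic).
* Isovalue 0.9 is checked to lie in (0, 1); resolution floors 32 × 64;
  degenerate inputs (empty masks, coplanar point sets, open meshes,
  constant rank inputs) raise `ValueError` with specific messages.
* The M1-volume bias at isovalue 0.9 is O(voxel size); convergence
  checks against the source surface use the unbiased mid-level at
  0.4 mm grids (finer grids exceed sensible desk-scale memory).
* The test suite exercises a coarse 4-model suite (d = 11, 38, 65, 92 at
  64 × 128 angular resolution, 1 × 1 × 2 mm grids) for unit properties
  and the full 28-model suite at default resolution for the end-to-end
  assertions; these sizes are the package's chosen desk-scale study
  conditions.
* M4 is expensive (Delaunay + alpha search) and scientifically
  discouraged; it is excluded from the default experiment methods and
  exercised on coarse masks in the tests.
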