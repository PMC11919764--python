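# Methods

This note documents the models, conventions, numerical choices and
known limitations behind `coatlattice`. Everything quantitative
stated here is computed by the test suite or the examples; nothing is
asserted that the code does not measure.

## Pose convention

A particle pose is a position (Å, right-handed world axes) plus an
intrinsic ZYZ Euler triple (rot, tilt, psi) in degrees, composed as
R = Rz(psi)·Ry(tilt)·Rz(rot). `R` maps particle-local coordinates to
world coordinates; its columns are the particle's local axes, and
`R[:,2]` is the local z-axis, which for surface-derived particles is
the outward membrane normal. `rot` is the in-plane spin about the
local z-axis and is applied first. Canonical ranges are tilt ∈
[0, 180], rot/psi ∈ (−180, 180]; at gimbal lock (tilt = 0 or 180) the
rot/psi split is degenerate and the rot = 0 representative is used.
Round trips through the matrix form reproduce the rotation to 1e−10;
pose tables round-trip through both dialects to better than 1e−6 Å
and 1e−6°. STAR files natively carry Å coordinates; the legacy
35-column table carries voxel coordinates (columns 24–26) and Euler
angles (columns 7–9), converted on read using the pixel size, with
undocumented columns preserved opaquely. Whether STAR coordinates are
voxel- or Å-valued is ambiguous across processing stages in the wild,
so the reader takes an explicit `coords_in_voxels` flag rather than
guessing.

## Synthetic cages

The cage generator is the null model behind every geometric test: a
pseudospherical vesicle of diameter D decorated with vertices at a
target spacing L (default 300 Å, the rod length scale of outer-coat
cages) and rods at the adjacency edge midpoints. Real cages of this
kind are irregular — no global polyhedral symmetry — so the generator
aims for approximate equidistribution rather than a symmetric
polyhedron:

1. Fibonacci-lattice initialization of n points, with
   n ≈ 4πR² / (√3/2·L²) (hexagonal packing area per point).
2. Spring relaxation on the spherical-Delaunay (convex-hull) edge
   graph with rest length L. Repulsion below L is weighted 3×
   stronger than attraction above it: a sphere forces ≥ 12
   disclinations into a triangular lattice, and with symmetric
   springs the resulting strain skews the edge-length distribution
   short (modal neighbor distance ~285 Å for a 300 Å target);
   physically, contact between subunits resists compression more than
   the lattice resists stretching, and the asymmetric form centers
   the realized spacing on L (modal distance within one 10 Å bin of
   L). 500 annealed iterations; the relaxation is deterministic.
3. For small cages (n ≤ 60) the discrete spherical code cannot
   realize spacing L at exactly the area-estimate n, so n is scanned
   over a ±3 window and the configuration whose median lattice edge
   is closest to L is kept. This implements the spacing contract; it
   is not a tuning knob.

Adjacency is the hull edge set filtered to [0.6L, 1.4L]. Degree-5
vertices are created by inserting an extra adjacency edge to the
nearest non-adjacent vertex for a seeded random subset of vertices —
only degree statistics are consumed downstream, so the geometry is
left untouched. Vertex frames have z along the outward normal and x
along the first adjacency edge; rods sit at edge midpoints (projected
to the sphere) with x along the edge. Rod hinge flexibility is
modelled as a per-rod random bend (sd `rod_hinge_sd`, degrees)
recorded in ground truth; a bend b pops the rod center outward along
its local z by (e/2)·tan(b/2) for edge length e, which makes the
nearest-vertex offset in the rod frame a monotone readout of the bend
— the basis of the neighbor-mask classification test.

For a noiseless cage the vertex angle reproduces the closed form
α = 180° − 2·arcsin(L/D) to better than 1° over the tested range
D/L ∈ {2, 4, 10} (errors +0.10°, −0.70°, −0.02°); the suite stops at
D/L = 10 because vertex count grows as (D/L)² and larger ratios add
runtime without adding information — the planar generator covers the
flat limit exactly.

Corruption adds isotropic Gaussian position noise, small random
rotations (rotation-vector components ~ N(0, sd)), and junk particles
uniform in the radial shell from the membrane surface to 200 Å
outward with uniform random orientations — a stand-in for picking
false positives near membranes. `junk_fraction` is the fraction of
the final table that is junk. Ground truth is kept in a `truth`
column.

What the generators do *not* emulate: missing-wedge anisotropy of
picking error, per-tomogram defocus/contrast variation, correlated
(non-isotropic) pose errors from refinement, partial lattice
occupancy gradients, or realistic membrane density. Passing tests
therefore demonstrate the correctness of the geometry pipeline under
its stated noise model, not robustness to every experimental
pathology.

## Vertex angle α

For each vertex, neighbors with |offset| in `L_window` (default
[0.7L, 1.3L], which excludes the second lattice shell at √3·L) are
paired when their in-plane azimuths differ by 180° within
`opposite_tol` (default 30°). Each pair contributes
180° − dip_A − dip_B, where dip = arcsin(−z/|offset|) is the angle of
the neighbor offset below the tangent plane; α is the mean over
pairs. For a pair at exactly opposite azimuths this equals the 3D
angle subtended at the vertex, and it reproduces both limits exactly
(180° flat; 120° at D = 2L). The dip-based form was chosen over the
raw 3D angle between the two offset vectors because the latter
carries a systematic downward bias of roughly the mean azimuthal
mismatch within the tolerance (measured: up to −4.7° at D/L = 20 on
relaxed lattices), which would swamp the curvature signal on weakly
curved membranes; the dip-based statistic is insensitive to azimuthal
scatter. Whether the experimental statistic averages two opposite
pairs or all qualifying pairs is not nailed down in the field; the
all-pairs mean is used because it is robust to degree-5 vertices and
missing neighbors and reduces to the schematic for clean 4-way
vertices.

On noisy poses individual α values can exceed 180° (orientation noise
can tip a neighbor above the tangent plane); values are deliberately
not clamped, since clamping would bias the flat-limit estimate
downward. The α ∈ (0°, 180°] range is a property of noiseless
geometry. Junk particles that survive cleaning carry random
orientations and hence arbitrary α; robust (median) per-vesicle
aggregation is recommended and used in the examples.

The α–diameter coupling is summarized by the Pearson correlation with
the two-tailed p from t = r·√(n−2)/√(1−r²). Note that α(D) is
concave, so even noiseless per-vesicle means give r ≈ 0.90 (computed,
n = 20 vesicles over D ∈ [600, 3000] Å) rather than 1; the statistic
mirrors the linear-trendline convention of coat-flexibility analyses
rather than fitting the closed form.

## Cleaning, classification, registration

*Cleaning* keeps a particle iff at least `k_min` of its neighbors
(within `r_max`) fall in the union of expected-offset masks evaluated
in its local frame. Because vertex degree varies (4–7), the expected
first shell is tiled azimuthally: `ring_masks` places 16 balls of
radius 0.25L on the ring at lateral distance L, dipped below the
tangent plane by the population-mean curvature. With k_min = 3 this
removes ≥ 95% of 30% junk while retaining ≥ 99% of true particles in
the tested populations. Masks can also be derived from the data as
the top KDE modes of the neighbor cloud (`auto_masks`, bandwidth
0.1·median distance) when no expectation is supplied.

*Classification* assigns each particle to every mask containing its
nearest qualifying neighbor offset (ties broken by neighbor id, so
the assignment is deterministic).

*Registration* builds the vertex→inner neighbor cloud, selects
vertices whose nearest inner neighbor lies in a stated local region,
and computes the relative in-plane angle as the azimuth of the inner
particle's x-axis expressed in the vertex frame. Angles are folded
modulo 180° before a Rayleigh test on doubled angles, because the
vertex reference is treated as 2-fold pseudosymmetric and the C2
ambiguity would otherwise masquerade as bimodality. Verdict:
`registered` iff uniformity is rejected at α = 0.05 *and* the
translational cluster is tight (trace of the offset covariance below
2500 Å², i.e. ~29 Å isotropic sd — half the spread a uniform
distribution over an 80 Å selection ball would produce);
`unregistered` iff uniformity is not rejected; fewer than 10 selected
pairs is `inconclusive`.

## Density operations

Grids are ZYX-ordered float32 with isotropic voxel size and an
explicit origin; resampling is trilinear about the geometric box
center with zero fill, adequate at the 12–25 Å scales analysed here —
trilinear interpolation of a Gaussian a few voxels wide is accurate
to ~1% of peak, which bounds several tolerances below.

- *Low-pass*: raised-cosine edge (default 3 Fourier pixels) ending at
  the cutoff; the DC term is untouched so the mean is preserved.
  Exact idempotence holds for the sharp (edge 0) filter; the soft
  edge attenuates its transition band twice on reapplication.
- *Model-to-map*: one isotropic Gaussian per atom with
  σ = 0.225·resolution and amplitude = weight (the common
  simulated-map convention), evaluated over ±4σ. The caller must
  supply a grid fine enough to sample σ (≥ ~2 voxels per σ for a
  faithful profile). The classic two-step recipe — synthesize at 2 Å,
  low-pass to the working resolution — agrees with direct synthesis
  at that resolution to correlation ≈ 0.985 on a compact model; the
  residual difference is intrinsic (Gaussian vs sharp-cutoff kernel
  shapes near the cutoff), not numerical error.
- *Difference map*: both maps normalized to mean 0 / sd 1 over the
  full unmasked box (no mask is part of the contract), subtracted;
  blobs are 26-connected components above threshold (default 3 sd)
  with ≥ `min_voxels` (default 10) voxels, reported with weighted
  centroids, peaks and distances to annotated sites. Grids must
  match; resampling is out of scope.
- *Averaging*: each subvolume is resampled by the inverse particle
  rotation (and inverse translation, read from the pose position as
  an offset from box center), summed, and split into odd/even
  half-maps; C2 averages in a 180° in-plane rotated copy. No CTF or
  missing-wedge compensation is applied — rendered inputs carrying a
  wedge simply average it in.
- *FSC*: correlation per integer-radius Fourier shell; resolution at
  the first linear-interpolated crossing below the threshold (default
  0.143), or box Nyquist when the curve never drops below it.
- *Map-back*: the template is rotated per pose and accumulated at the
  particle position (subvoxel shifts folded into the interpolation);
  placements crossing the box edge are clipped with a warning.

## Pipeline and CLI

The library is the interface; a thin `typer` CLI exposes each stage
(`coatlattice convert|simulate|fit-surface|morphometry|neighbors|
alpha|clean|classify|register|diffmap|average|mapback|run`) and
`run` drives a YAML-configured simulate → clean → α → correlation
(optionally registration) pipeline whose JSON summary records the
tool version, seed and config hash; deterministic stages are
bit-identical under rerun. Exit codes: 0 ok, 1 user error, 2
internal.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
cages up to D/L = 10–12 (≤ ~520 vertices), populations of 8–20
vesicles (~500–3000 particles), 32³–64³ voxel boxes, 100 subvolumes.
These sizes were chosen because every statistic they feed saturates
well below them (e.g. the Rayleigh test discriminates at n ≈ 50; the
α closed form is met within 1° from n ≈ 13).

## Known limitations

- Cylinder fitting assumes an elongated cloud; tubes capped by
  hemispheres or shorter than ~1.5 diameters fall back to the sphere
  model by the classification rule.
- The sphere fit is algebraic (Coope); at extreme noise-to-radius
  ratios (≫ 2%) it inherits the usual mild algebraic-fit bias.
- `model_to_map` does not band-limit: on grids coarser than the
  requested resolution the Gaussian is undersampled (aliased); use a
  finer grid or synthesize coarse maps directly at the target
  resolution.
- Junk placement is implemented for spherical surfaces only.
- No CIF/mmCIF models, no multi-optics-group STAR bookkeeping, no
  CTF, no reference-free alignment: pose refinement is assumed done
  upstream.
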