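# coatlattice

Quantitative geometry of vesicle coat lattices from cryo-ET
subtomogram-averaging pose tables.

## The problem

Membrane coats such as COPII assemble two-layered lattices on budding
membranes: an inner layer of tightly packed heterotrimers against the
bilayer and an outer cage of rod-shaped tetramers whose ends converge
at vertices roughly 300 Å apart. Subtomogram averaging (STA) of such
coats yields, besides density maps, a table of refined particle poses
— one position and one orientation per subunit. Those poses carry the
architecture of the coat: how curved each membrane is, how the lattice
is ordered, how wide the angle at each cage vertex opens, whether the
two coat layers are registered to each other, and whether a fitted
atomic model leaves unexplained (e.g. cargo) density behind.

`coatlattice` implements that pose-table geometry as a tested Python
library:

- **Membrane morphometry** — sphere/cylinder fits to membrane point
  clouds, vesicle/tube classification, diameter statistics
  (homoscedastic two-tailed *t*-test with box-plot summaries).
- **Neighbor clouds** — for every particle, the positions of its
  neighbors in the particle's own local frame (x, y tangent to the
  membrane, z along the outward normal), the substrate of all lattice
  analyses.
- **Vertex angle α** — the average angle subtended below a cage vertex
  by opposite neighboring vertices. For chord length L on a sphere of
  diameter D the geometry gives α = 180° − 2·arcsin(L/D): 180° on a
  flat membrane, 120° at D = 2L. The α-vs-diameter correlation
  quantifies how the cage tracks membrane curvature.
- **Table hygiene** — neighbor-analysis cleaning against expected
  lattice offsets, duplicate removal by distance threshold, radial
  shifts along particle normals, subboxing (child coordinates placed
  relative to each parent pose).
- **Layer registration** — selects outer-coat vertices with an
  inner-coat neighbor in a fixed local region and applies a Rayleigh
  uniformity test to the relative in-plane angles (folded for the
  vertex's two-fold pseudosymmetry) to decide whether the layers are
  rotationally locked or free.
- **Density operations** — low-pass filtering, normalization,
  model-to-map synthesis (Gaussian of σ = 0.225·resolution per atom),
  difference maps with connected-component blob reports, pose-driven
  subvolume averaging with half-map FSC (resolution at 0.143), and
  template map-back.
- **Synthetic ground truth** — generators for spherical cages (with
  4-way/5-way vertices and hinge-flexible rods), planar and
  pseudohelical lattices, patchy inner-coat arrays, two-layer
  decorations with controllable registration, pose corruption
  (noise + junk), and rendered noisy subvolumes, so every stage is
  testable without experimental data.

Formats: STAR and legacy 35-column whitespace pose tables, MRC2014
volumes, PDB models. Orientations are intrinsic ZYZ Euler triples
(rot, tilt, psi) in degrees with R = Rz(psi)·Ry(tilt)·Rz(rot) mapping
particle-local to world coordinates.

## A worked example

```sh
python examples/vertex_angle_vs_curvature.py
```

prints

```
planar lattice:  mean alpha =  180.00 deg   (flat limit: 180)
D =    600 A:    mean alpha =  120.10 deg   (chord geometry: 120.00, n = 11 vertices)
D =    900 A:    mean alpha =  140.13 deg   (chord geometry: 141.06, n = 30 vertices)
D =   1500 A:    mean alpha =  156.94 deg   (chord geometry: 156.93, n = 87 vertices)
D =   3000 A:    mean alpha =  168.50 deg   (chord geometry: 168.52, n = 357 vertices)
```

Each line builds a noiseless synthetic cage at the given vesicle
diameter (vertices ~300 Å apart), measures the per-vertex angle α from
the local-frame neighbor cloud, and compares the mean with the
chord-geometry closed form — the coat opens toward 180° as the
membrane flattens. With noise and junk contamination the same
analysis runs end to end in `examples/clean_and_correlate.py`:

```
simulated 1541 particles (308 junk), kept 1225 after cleaning
alpha (5-95%) spans 146.0 - 168.3 deg across fitted diameters 600 - 2400 A
alpha vs diameter: Pearson r = 0.945, two-tailed p = 3.64e-06
```

i.e. the vertex angle correlates strongly and positively with the
fitted vesicle diameter. The other examples cover layer registration
(`layer_registration.py`), difference mapping
(`difference_mapping.py`) and subvolume averaging with FSC
(`subvolume_averaging.py`).

A thin CLI wraps the same functions (`coatlattice --help`); a YAML
config drives the full simulate → clean → α → correlation pipeline:

```sh
coatlattice run examples/pipeline_demo.yaml --out-dir demo_out
```

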