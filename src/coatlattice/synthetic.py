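"""Ground-truth coat-lattice simulators.

These generators emulate the pose tables a subtomogram-averaging
pipeline produces for coated membranes, with known ground truth so
every downstream geometric analysis can be validated end to end:

* pseudospherical vesicles decorated with cage vertices and rods at a
  target inter-vertex spacing (~300 A for the Sec13-Sec31 outer coat),
  including a controllable fraction of 5-way vertices;
* planar and tubular (pseudohelical) lattices;
* patchy inner-coat arrays with independent random patch orientation;
* two-layer (inner + outer) decorations with controllable mutual
  registration;
* pose corruption (positional/angular noise, junk contamination) and
  rendered noisy subvolumes for averaging tests.

Vertices are placed by Fibonacci-lattice initialization followed by a
spring relaxation on the spherical-Delaunay edge graph with rest
length L: real cages are irregular (no global symmetry), so an
approximately equidistributed point set with nearest-neighbor spacing
~ L is the right null model.  For a noiseless cage the vertex angle
then satisfies the chord geometry alpha = 180 - 2 arcsin(L/D) up to
discretization error (< ~1 degree for D/L >= 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, cKDTree
from scipy.spatial.transform import Rotation

from .membrane import SurfaceModel
from .particles import ParticleSet, concat, particle_set
from .pose_io import DensityMap
from .rotations import euler_to_matrix, frame_from_normal, matrix_to_euler

__all__ = [
    "CageParams",
    "PatchParams",
    "CorruptionModel",
    "CageResult",
    "make_cage",
    "make_planar_lattice",
    "make_tube_lattice",
    "make_vesicle_patches",
    "make_two_layer",
    "corrupt",
    "render_subvolumes",
]


@dataclass
class CageParams:
    """Geometry of one synthetic outer-coat cage."""

    diameter: float = 800.0  # vesicle diameter D, A
    edge_length: float = 300.0  # target inter-vertex spacing L, A
    five_way_fraction: float = 0.0
    pos_jitter_sd: float = 0.0  # A
    ang_jitter_sd: float = 0.0  # degrees
    rod_hinge_sd: float = 0.0  # degrees
    seed: int = 0
    center: tuple = (0.0, 0.0, 0.0)
    relax_iters: int = 500

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if not 0 < self.edge_length < self.diameter:
            raise ValueError("edge_length must satisfy 0 < L < D")
        if not 0 <= self.five_way_fraction <= 1:
            raise ValueError("five_way_fraction must be in [0, 1]")
        for sd in (self.pos_jitter_sd, self.ang_jitter_sd, self.rod_hinge_sd):
            if sd < 0:
                raise ValueError("jitter sds must be >= 0")


@dataclass
class PatchParams:
    """A patchy 2D lattice decoration (inner-coat style)."""

    lattice_vectors: tuple = ((110.0, 0.0), (0.0, 60.0))
    patch_count: int = 3
    subunits_per_patch: int = 12
    seed: int = 0

    def __post_init__(self):
        a, b = (np.asarray(v, float) for v in self.lattice_vectors)
        if abs(a[0] * b[1] - a[1] * b[0]) < 1e-9:
            raise ValueError("lattice vectors must be linearly independent")
        if self.patch_count < 1 or self.subunits_per_patch < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class CorruptionModel:
    """Picking-noise stand-in: Gaussian pose noise + junk contamination.

    Junk particles are placed uniformly in a radial shell between the
    membrane surface and ``junk_shell_max`` A outward, with uniform
    random orientations, mimicking false positives near membranes.
    ``junk_fraction`` is the fraction of the *final* (corrupted) set
    that is junk.
    """

    pos_noise_sd: float = 0.0  # A
    ang_noise_sd: float = 0.0  # degrees
    junk_fraction: float = 0.0
    junk_shell_max: float = 200.0  # A outward of the surface
    seed: int = 0

    def __post_init__(self):
        if self.pos_noise_sd < 0 or self.ang_noise_sd < 0:
            raise ValueError("noise sds must be >= 0")
        if not 0 <= self.junk_fraction < 1:
            raise ValueError("junk_fraction must be in [0, 1)")


@dataclass
class CageResult:
    vertices: ParticleSet
    rods: ParticleSet
    surface: SurfaceModel
    adjacency: np.ndarray  # (m, 2) vertex particle_id pairs


# ---------------------------------------------------------------------------
# sphere relaxation


def _fibonacci_sphere(n):
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.c_[np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]


def _hull_edges(points):
    hull = ConvexHull(points)
    edges = set()
    for simplex in hull.simplices:
        for a, b in ((0, 1), (1, 2), (0, 2)):
            i, j = int(simplex[a]), int(simplex[b])
            edges.add((min(i, j), max(i, j)))
    return np.array(sorted(edges), dtype=np.int64)


def _relax_on_sphere(points, radius, rest_length, iters, w_rep=3.0):
    """Spring relaxation on the spherical-Delaunay edge graph.

    Repulsion (below the rest length) is weighted ``w_rep`` times
    stronger than attraction: the 12+ disclinations a sphere forces
    into a triangular lattice would otherwise skew the edge-length
    distribution short, whereas the physical contact between coat
    subunits resists compression more than stretching.  The asymmetry
    centers the realized spacing distribution on the rest length.
    """
    p = points.copy()
    for it in range(iters):
        step = 0.3 * (1 - it / iters) ** 2 + 0.01
        edges = _hull_edges(p)
        d = p[edges[:, 0]] - p[edges[:, 1]]
        dist = np.linalg.norm(d, axis=1)
        f = (rest_length - dist) / np.maximum(dist, 1e-9)
        f = np.where(dist < rest_length, w_rep * f, f)
        disp = np.zeros_like(p)
        np.add.at(disp, edges[:, 0], (0.5 * f)[:, None] * d)
        np.add.at(disp, edges[:, 1], (-0.5 * f)[:, None] * d)
        p = p + step * disp
        p = radius * p / np.linalg.norm(p, axis=1)[:, None]
    return p


def _median_edge(points, L):
    e = _hull_edges(points)
    elen = np.linalg.norm(points[e[:, 0]] - points[e[:, 1]], axis=1)
    elen = elen[elen < 1.4 * L]  # exclude defect diagonals
    return float(np.median(elen))


def _place_vertices(radius, L, iters):
    """Relaxed quasi-uniform vertex positions with spacing ~ L.

    The hexagonal-packing estimate n = 4 pi R^2 / (sqrt(3)/2 L^2) is
    only approximate at small n, where the discrete spherical code
    cannot realize spacing L exactly; a short scan around the estimate
    keeps the configuration whose median lattice edge is closest to L.
    """
    n0 = max(4, int(round(4 * np.pi * radius**2 / ((np.sqrt(3) / 2) * L**2))))
    candidates = range(max(4, n0 - 3), n0 + 2) if n0 <= 60 else [n0]
    best = None
    for n in candidates:
        p = _relax_on_sphere(radius * _fibonacci_sphere(n), radius, L, iters)
        err = abs(_median_edge(p, L) - L)
        if best is None or err < best[0]:
            best = (err, p)
    return best[1]


def make_cage(params: CageParams) -> CageResult:
    """Generate one cage: vertex and rod pose tables, the underlying
    sphere, and the ground-truth adjacency.

    Vertex local z-axes point along the outward normal and local
    x-axes along the first adjacent edge; rods sit at edge midpoints
    (projected to the sphere) with local x along the edge.  Jitter and
    hinge flexibility are recorded in ground-truth columns
    (``degree``, ``hinge_bend``).
    """
    rng = np.random.default_rng(params.seed)
    R = params.diameter / 2.0
    L = params.edge_length
    area_per_vertex = (np.sqrt(3) / 2) * L**2
    if 4 * np.pi * R**2 / area_per_vertex > 2e5:
        raise ValueError("infeasible packing: too many vertices requested for the area")
    pts = _place_vertices(R, L, params.relax_iters)
    n = len(pts)
    edges = _hull_edges(pts)
    elen = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)
    edges = edges[(elen > 0.6 * L) & (elen < 1.4 * L)]

    # degree-5 vertices by local edge insertion in the adjacency
    degree = np.zeros(n, dtype=int)
    for a, b in edges:
        degree[a] += 1
        degree[b] += 1
    extra_edges = []
    n_five = int(round(params.five_way_fraction * n))
    if n_five:
        tree = cKDTree(pts)
        existing = {tuple(e) for e in map(tuple, edges)}
        chosen = rng.choice(n, size=min(n_five, n), replace=False)
        for v in chosen:
            # connect to the nearest vertex not already adjacent
            dists, idx = tree.query(pts[v], k=min(16, n))
            for j in np.atleast_1d(idx)[1:]:
                key = (min(v, int(j)), max(v, int(j)))
                if key not in existing:
                    existing.add(key)
                    extra_edges.append(key)
                    degree[v] += 1
                    degree[int(j)] += 1
                    break
    if extra_edges:
        edges = np.vstack([edges, np.array(extra_edges, dtype=np.int64)])

    # vertex frames: z outward, x along the first adjacent edge
    normals = pts / np.linalg.norm(pts, axis=1)[:, None]
    first_edge_dir = np.zeros((n, 3))
    for a, b in edges:
        for v, w in ((a, b), (b, a)):
            if not first_edge_dir[v].any():
                d = pts[w] - pts[v]
                d = d - (d @ normals[v]) * normals[v]
                first_edge_dir[v] = d / max(np.linalg.norm(d), 1e-12)
    inplane = np.zeros(n)
    for v in range(n):
        if first_edge_dir[v].any():
            inplane[v] = _inplane_angle(normals[v], first_edge_dir[v])
        else:
            inplane[v] = rng.uniform(-180, 180)
    rot, tilt, psi = frame_from_normal(normals, inplane)
    center = np.asarray(params.center, float)
    vertices = particle_set(
        center + pts,
        np.c_[rot, tilt, psi],
        layer="vertex",
        extra={"degree": degree},
    )

    # rods at edge midpoints, local x along the edge, hinge bend pops
    # the rod center outward along its local z
    mids = 0.5 * (pts[edges[:, 0]] + pts[edges[:, 1]])
    mids = R * mids / np.linalg.norm(mids, axis=1)[:, None]
    rod_normals = mids / R
    bends = rng.normal(0.0, params.rod_hinge_sd, size=len(edges)) if params.rod_hinge_sd else np.zeros(len(edges))
    edge_vec = pts[edges[:, 1]] - pts[edges[:, 0]]
    rod_inplane = np.zeros(len(edges))
    for k in range(len(edges)):
        d = edge_vec[k] - (edge_vec[k] @ rod_normals[k]) * rod_normals[k]
        rod_inplane[k] = _inplane_angle(rod_normals[k], d / max(np.linalg.norm(d), 1e-12))
    pop = (np.linalg.norm(edge_vec, axis=1) / 2.0) * np.tan(np.radians(np.abs(bends)) / 2.0)
    rod_pos = mids + pop[:, None] * rod_normals
    rrot, rtilt, rpsi = frame_from_normal(rod_normals, rod_inplane)
    rods = particle_set(
        center + rod_pos,
        np.c_[rrot, rtilt, rpsi],
        layer="rod",
        start_id=n,
        extra={
            "hinge_bend": bends,
            "edge_a": edges[:, 0],
            "edge_b": edges[:, 1],
        },
    )

    vertices = _jitter(vertices, params.pos_jitter_sd, params.ang_jitter_sd, rng)
    rods = _jitter(rods, params.pos_jitter_sd, params.ang_jitter_sd, rng)
    surface = SurfaceModel("sphere", center, R)
    return CageResult(vertices, rods, surface, edges.copy())


def _inplane_angle(normal, target_x):
    """In-plane rotation that aligns the local x-axis with target_x."""
    rot0, tilt0, psi0 = frame_from_normal(normal, 0.0)
    base = euler_to_matrix(rot0, tilt0, psi0)
    t = base.T @ np.asarray(target_x, float)
    return np.degrees(np.arctan2(t[1], t[0]))


def _jitter(pset: ParticleSet, pos_sd, ang_sd, rng):
    if len(pset) == 0 or (pos_sd == 0 and ang_sd == 0):
        return pset
    df = pset.df.copy()
    if pos_sd > 0:
        df[["x", "y", "z"]] = pset.positions + rng.normal(0, pos_sd, (len(pset), 3))
    if ang_sd > 0:
        small = Rotation.from_rotvec(
            np.radians(rng.normal(0, ang_sd, (len(pset), 3)))
        ).as_matrix()
        mats = small @ pset.matrices()
        rot, tilt, psi = matrix_to_euler(mats)
        df[["rot", "tilt", "psi"]] = np.c_[rot, tilt, psi]
    return ParticleSet(df, pset.pixel_size)


# ---------------------------------------------------------------------------
# planar / tubular lattices


def make_planar_lattice(spacing: float = 300.0, nx: int = 8, ny: int = 8, seed: int = 0) -> ParticleSet:
    """Hexagonal planar lattice at exact ``spacing``; the flat-membrane
    limit of a cage (vertex angle exactly 180 degrees)."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    rng = np.random.default_rng(seed)
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    x = (ix + 0.5 * (iy % 2)).ravel() * spacing
    y = iy.ravel() * spacing * np.sqrt(3) / 2
    pos = np.c_[x, y, np.zeros_like(x)]
    pos -= pos.mean(axis=0)
    inplane = rng.uniform(-180, 180, len(pos))
    rot, tilt, psi = frame_from_normal(np.tile([0.0, 0.0, 1.0], (len(pos), 1)), inplane)
    return particle_set(pos, np.c_[rot, tilt, psi], layer="vertex")


def make_tube_lattice(
    radius: float,
    length: float,
    rise: float,
    twist: float,
    n_starts: int = 1,
    seed: int = 0,
) -> tuple[ParticleSet, SurfaceModel]:
    """Pseudohelical lattice on a cylinder along z.

    Subunit k of each helical start sits at azimuth ``k * twist``
    (degrees) and height ``k * rise`` (A); starts are offset evenly in
    azimuth.  Local z-axes point along the outward radial normal,
    local x along the helical path.
    """
    if radius <= 0 or length <= 0:
        raise ValueError("radius and length must be positive")
    if rise <= 0:
        raise ValueError("degenerate spacing: rise must be positive")
    n_per = int(np.floor(length / rise)) + 1
    if n_per < 1 or n_starts < 1:
        raise ValueError("degenerate spacing")
    rng = np.random.default_rng(seed)
    positions, normals, inplane = [], [], []
    for s in range(n_starts):
        phase = 360.0 * s / n_starts
        k = np.arange(n_per)
        ang = np.radians(phase + k * twist)
        z = k * rise - length / 2.0
        nrm = np.c_[np.cos(ang), np.sin(ang), np.zeros_like(ang)]
        positions.append(radius * nrm + np.c_[np.zeros_like(z), np.zeros_like(z), z])
        normals.append(nrm)
        # helical tangent in the tangent plane
        tangent = np.c_[-np.sin(ang), np.cos(ang), np.full_like(ang, rise / max(radius * np.radians(max(abs(twist), 1e-9)), 1e-9))]
        for nv, tv in zip(nrm, tangent):
            tv = tv - (tv @ nv) * nv
            inplane.append(_inplane_angle(nv, tv / max(np.linalg.norm(tv), 1e-12)))
    pos = np.concatenate(positions)
    nrm = np.concatenate(normals)
    rot, tilt, psi = frame_from_normal(nrm, np.array(inplane))
    pset = particle_set(pos, np.c_[rot, tilt, psi], layer="inner")
    surface = SurfaceModel("cylinder", np.zeros(3), radius, axis=np.array([0.0, 0.0, 1.0]))
    return pset, surface


# ---------------------------------------------------------------------------
# patches


def make_vesicle_patches(
    diameter: float, patch: PatchParams, max_retries: int = 20
) -> tuple[ParticleSet, SurfaceModel]:
    """Locally planar lattice patches wrapped onto a sphere.

    Each patch gets a random anchor point and an independent random
    in-plane orientation; lattice offsets are wrapped by the
    exponential map (geodesic rotation), so within-patch spacing is
    preserved up to wrap distortion.  Patch membership is recorded in
    a ``patch`` column.  Overlapping patches trigger a retry, up to
    ``max_retries``.
    """
    import warnings

    rng = np.random.default_rng(patch.seed)
    R = diameter / 2.0
    a2, b2 = (np.asarray(v, float) for v in patch.lattice_vectors)
    m = patch.subunits_per_patch
    # roughly round patch: lattice points sorted by radius
    k = int(np.ceil(np.sqrt(m))) + 2
    ii, jj = np.meshgrid(np.arange(-k, k + 1), np.arange(-k, k + 1), indexing="ij")
    offsets2 = np.outer(ii.ravel(), a2) + np.outer(jj.ravel(), b2)
    offsets2 = offsets2[np.argsort(np.linalg.norm(offsets2, axis=1), kind="stable")][:m]
    patch_extent = np.linalg.norm(offsets2, axis=1).max() if m > 1 else 0.0
    if patch_extent > 0.5 * np.pi * R:
        raise ValueError("patch extent too large for the sphere")

    min_sep = 0.5 * min(np.linalg.norm(a2), np.linalg.norm(b2))
    for attempt in range(max_retries):
        anchors = _random_sphere_points(patch.patch_count, rng)
        frames = rng.uniform(0, 2 * np.pi, patch.patch_count)
        all_pos, all_patch = [], []
        for p_idx in range(patch.patch_count):
            nrm = anchors[p_idx]
            u, v = _tangent_basis(nrm)
            c, s = np.cos(frames[p_idx]), np.sin(frames[p_idx])
            e1, e2 = c * u + s * v, -s * u + c * v
            for off in offsets2:
                tangent = off[0] * e1 + off[1] * e2
                dist = np.linalg.norm(tangent)
                if dist < 1e-12:
                    pos = R * nrm
                else:
                    axis = np.cross(nrm, tangent / dist)
                    rotm = Rotation.from_rotvec(axis * (dist / R)).as_matrix()
                    pos = R * (rotm @ nrm)
                all_pos.append(pos)
                all_patch.append(p_idx)
        all_pos = np.asarray(all_pos)
        # cross-patch overlap check
        ok = True
        if patch.patch_count > 1:
            tree = cKDTree(all_pos)
            pairs = tree.query_pairs(min_sep, output_type="ndarray")
            lab = np.asarray(all_patch)
            if len(pairs) and np.any(lab[pairs[:, 0]] != lab[pairs[:, 1]]):
                ok = False
        if ok:
            break
        warnings.warn(f"overlapping patches, retry {attempt + 1}")
    nrm = all_pos / np.linalg.norm(all_pos, axis=1)[:, None]
    inplane = rng.uniform(-180, 180, len(all_pos))
    rot, tilt, psi = frame_from_normal(nrm, inplane)
    pset = particle_set(
        all_pos, np.c_[rot, tilt, psi], layer="inner", extra={"patch": all_patch}
    )
    return pset, SurfaceModel("sphere", np.zeros(3), R)


def _random_sphere_points(n, rng):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1)[:, None]


def _tangent_basis(normal):
    ref = np.array([0.0, 0.0, 1.0]) if abs(normal[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(ref, normal)
    u /= np.linalg.norm(u)
    return u, np.cross(normal, u)


# ---------------------------------------------------------------------------
# two-layer decorations


def make_two_layer(
    cage: CageParams,
    registered: bool,
    *,
    inner_offset=(0.0, 0.0, -120.0),
    inner_euler=(0.0, 0.0, 0.0),
    inner_spacing: float = 80.0,
    seed: int | None = None,
) -> tuple[ParticleSet, ParticleSet]:
    """Outer-coat vertices plus an inner-coat layer on the same sphere.

    ``registered=True`` places one inner particle per vertex at the
    fixed ``inner_offset`` (A, in the vertex local frame) with the
    fixed relative rotation ``inner_euler``; ``registered=False``
    samples an independent inner layer (random in-plane angles) on the
    sphere at the same radial depth, so the two layers share no
    translational or rotational relationship.
    """
    from .lattice import subbox
    from .membrane import sample_surface

    seed = cage.seed if seed is None else seed
    result = make_cage(cage)
    vertices = result.vertices
    if registered:
        inner = subbox(vertices, inner_offset, inner_euler, layer="inner")
    else:
        depth = abs(inner_offset[2])
        R_in = max(cage.diameter / 2.0 - depth, inner_spacing)
        sphere = SurfaceModel("sphere", np.asarray(cage.center, float), R_in)
        inner = sample_surface(sphere, inner_spacing, seed=seed + 1)
        df = inner.df.copy()
        df["layer"] = "inner"
        inner = ParticleSet(df, inner.pixel_size)
    return vertices, inner


# ---------------------------------------------------------------------------
# corruption


def corrupt(pset: ParticleSet, model: CorruptionModel, surface: SurfaceModel | None = None) -> ParticleSet:
    """Perturb true particles and append junk.

    Ground truth is retained in a ``truth`` column ("true"/"junk").
    Junk placement needs the membrane ``surface`` (uniform in the
    radial shell surface .. surface + junk_shell_max).
    """
    rng = np.random.default_rng(model.seed)
    out = _jitter(pset, model.pos_noise_sd, model.ang_noise_sd, rng)
    df = out.df.copy()
    if "truth" not in df.columns:
        df["truth"] = "true"
    sets = [ParticleSet(df, pset.pixel_size)]
    if model.junk_fraction > 0:
        if surface is None:
            raise ValueError("junk placement requires a surface model")
        n_true = len(pset)
        n_junk = int(round(model.junk_fraction * n_true / (1.0 - model.junk_fraction)))
        if n_junk:
            if surface.kind != "sphere":
                raise NotImplementedError("junk shell only implemented for spheres")
            dirs = _random_sphere_points(n_junk, rng)
            # uniform in the shell volume
            r0, r1 = surface.radius, surface.radius + model.junk_shell_max
            u = rng.uniform(size=n_junk)
            radii = (r0**3 + u * (r1**3 - r0**3)) ** (1.0 / 3.0)
            pos = surface.center + radii[:, None] * dirs
            from .rotations import random_rotations

            rot, tilt, psi = random_rotations(n_junk, rng)
            junk = particle_set(
                pos,
                np.c_[rot, tilt, psi],
                layer=df["layer"].iloc[0] if len(df) else "other",
                start_id=int(df["particle_id"].max()) + 1 if len(df) else 0,
                extra={"truth": "junk"},
            )
            sets.append(junk)
    return concat(sets)


# ---------------------------------------------------------------------------
# rendered subvolumes


def render_subvolumes(
    pset: ParticleSet,
    template: DensityMap,
    noise_sd: float = 0.0,
    wedge_half_angle: float | None = None,
    seed: int = 0,
) -> list[DensityMap]:
    """Render one noisy subvolume per particle.

    Each subvolume is the template resampled under the particle
    rotation (local density placed into world orientation:
    ``sub(x) = template(R^T x)`` about the box center) plus Gaussian
    white noise.  ``wedge_half_angle`` (degrees) optionally zeroes a
    missing wedge in Fourier space: the double wedge of directions
    within that half-angle of the z frequency axis in the kx-kz plane
    (tilt axis y), i.e. ``|kx| < |kz| tan(half_angle)``.
    """
    from .density import rotate_grid

    g = template.grid
    if not (g.shape[0] == g.shape[1] == g.shape[2]):
        raise ValueError("template must be cubic")
    rng = np.random.default_rng(seed)
    mats = pset.matrices()
    offsets = pset.positions / template.voxel_size  # in-box shifts, voxels
    out = []
    wedge_mask = _wedge_mask(g.shape[0], wedge_half_angle) if wedge_half_angle else None
    for i in range(len(pset)):
        vol = rotate_grid(g, mats[i].T, offset_xyz=-(mats[i].T @ offsets[i]))
        if wedge_mask is not None:
            f = np.fft.fftn(vol)
            f[wedge_mask] = 0.0
            vol = np.real(np.fft.ifftn(f)).astype(np.float32)
        if noise_sd > 0:
            vol = vol + rng.normal(0.0, noise_sd, vol.shape).astype(np.float32)
        out.append(DensityMap(vol, template.voxel_size, template.origin.copy()))
    return out


def _wedge_mask(n, half_angle_deg):
    k = np.fft.fftfreq(n)
    kz = k[:, None, None]
    kx = k[None, None, :]
    t = np.tan(np.radians(half_angle_deg))
    mask = np.abs(kx) < np.abs(kz) * t
    return np.broadcast_to(mask, (n, n, n))
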