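"""Membrane surface fitting and morphometry.

Coated membranes are modelled as spheres (vesicles) or cylinders
(tubes).  Surfaces are fitted to user- or simulator-supplied point
clouds; diameters are read off the fitted model (D = 2r) and compared
between experimental groups with a pooled-variance two-sample t-test,
the statistic used for vesicle-diameter comparisons in reconstitution
experiments.

Also here: the pose-table hygiene steps that precede lattice analysis
- quasi-uniform surface oversampling with membrane-normal Euler
angles, the radial shift of picked coordinates away from the membrane,
and duplicate removal by distance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial import cKDTree

from .particles import ParticleSet, particle_set
from .rotations import frame_from_normal

__all__ = [
    "SurfaceModel",
    "TwoSampleTestResult",
    "fit_sphere",
    "fit_cylinder",
    "classify_surface",
    "sample_surface",
    "shift_along_normal",
    "remove_duplicates",
    "diameter_stats",
]


@dataclass
class SurfaceModel:
    """A fitted sphere or cylinder (all lengths in Angstrom)."""

    kind: str  # "sphere" | "cylinder"
    center: np.ndarray  # sphere center, or a point on the cylinder axis
    radius: float
    axis: np.ndarray | None = None  # unit axis direction (cylinder only)
    rms_residual: float = 0.0
    object_id: int = 0

    def __post_init__(self):
        self.center = np.asarray(self.center, float)
        if self.axis is not None:
            self.axis = np.asarray(self.axis, float)
            self.axis = self.axis / np.linalg.norm(self.axis)
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be >= 0")

    @property
    def diameter(self):
        return 2.0 * self.radius

    def normals_at(self, points):
        """Outward unit normals at (n, 3) points near the surface."""
        p = np.atleast_2d(np.asarray(points, float))
        if self.kind == "sphere":
            v = p - self.center
        else:
            rel = p - self.center
            axial = rel @ self.axis
            v = rel - np.outer(axial, self.axis)
        norms = np.linalg.norm(v, axis=1)
        norms[norms == 0] = 1.0
        return v / norms[:, None]


def fit_sphere(points) -> SurfaceModel:
    """Algebraic (Coope) least-squares sphere fit.

    Solves the linear system ``2 p . c + k = |p|^2`` for center c and
    ``k = r^2 - |c|^2``; exact on noiseless data.
    """
    p = np.atleast_2d(np.asarray(points, float))
    if len(p) < 4:
        raise ValueError(f"sphere fit needs >= 4 points, got {len(p)}")
    A = np.c_[2.0 * p, np.ones(len(p))]
    b = np.sum(p**2, axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise ValueError("degenerate (coplanar or collinear) points: sphere fit is singular")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise ValueError("sphere fit produced non-positive radius")
    radius = float(np.sqrt(r2))
    resid = np.linalg.norm(p - center, axis=1) - radius
    return SurfaceModel("sphere", center, radius, rms_residual=float(np.sqrt(np.mean(resid**2))))


def fit_cylinder(points, min_elongation: float = 1.3) -> SurfaceModel:
    """Least-squares cylinder: axis seeded from the principal component,
    then point-to-axis distances refined against a common radius.

    Raises for clouds without a dominant axis (principal-axis
    elongation below ``min_elongation``), which in practice means the
    object is not tube-like.
    """
    p = np.atleast_2d(np.asarray(points, float))
    if len(p) < 6:
        raise ValueError(f"cylinder fit needs >= 6 points, got {len(p)}")
    centroid = p.mean(axis=0)
    q = p - centroid
    _, svals, vt = np.linalg.svd(q, full_matrices=False)
    if svals[1] == 0 or svals[0] / max(svals[1], 1e-12) < min_elongation:
        raise ValueError(
            f"no dominant axis (elongation {svals[0] / max(svals[1], 1e-300):.2f}); "
            "cloud is not cylinder-like"
        )
    axis0 = vt[0]

    def unpack(theta):
        ax = np.array(
            [
                np.sin(theta[1]) * np.cos(theta[0]),
                np.sin(theta[1]) * np.sin(theta[0]),
                np.cos(theta[1]),
            ]
        )
        return ax, theta[2:5]

    def residual(theta):
        ax, point = unpack(theta)
        rel = p - point
        dist = np.linalg.norm(rel - np.outer(rel @ ax, ax), axis=1)
        return dist - dist.mean()

    t0 = np.array(
        [np.arctan2(axis0[1], axis0[0]), np.arccos(np.clip(axis0[2], -1, 1)), *centroid]
    )
    sol = optimize.least_squares(residual, t0, method="lm", max_nfev=2000)
    ax, point = unpack(sol.x)
    rel = p - point
    dist = np.linalg.norm(rel - np.outer(rel @ ax, ax), axis=1)
    radius = float(dist.mean())
    if radius <= 0:
        raise ValueError("cylinder fit produced non-positive radius")
    rms = float(np.sqrt(np.mean((dist - radius) ** 2)))
    # anchor the axis point at the foot of the centroid for reproducibility
    foot = point + ((centroid - point) @ ax) * ax
    return SurfaceModel("cylinder", foot, radius, axis=ax, rms_residual=rms)


def classify_surface(points, elongation_factor: float = 1.5):
    """Label a membrane point cloud as vesicle or tube.

    Fits both models; the object is a tube iff the cylinder fit
    succeeds, beats the sphere fit on rms residual, and the cloud
    extends along the cylinder axis more than ``elongation_factor``
    times the fitted diameter.  Returns ``(label, best_model)``;
    ``("unknown", None)`` when both fits fail.
    """
    p = np.atleast_2d(np.asarray(points, float))
    sphere = cylinder = None
    try:
        sphere = fit_sphere(p)
    except ValueError:
        pass
    try:
        cylinder = fit_cylinder(p)
    except ValueError:
        pass
    if sphere is None and cylinder is None:
        return "unknown", None
    if cylinder is not None:
        axial = (p - cylinder.center) @ cylinder.axis
        extent = axial.max() - axial.min()
        is_tube = extent > elongation_factor * cylinder.diameter and (
            sphere is None or cylinder.rms_residual < sphere.rms_residual
        )
        if is_tube:
            return "tube", cylinder
    if sphere is not None:
        return "vesicle", sphere
    return "tube", cylinder


def sample_surface(surface: SurfaceModel, spacing: float, seed=0, *, length: float | None = None,
                   object_id: int | None = None) -> ParticleSet:
    """Quasi-uniform oversampling of a surface at ~``spacing`` (A).

    Every pose's local z-axis is the outward surface normal; the
    in-plane rotation is uniform random (seeded).  For cylinders the
    axial extent must be given via ``length``.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    rng = np.random.default_rng(seed)
    cell = (np.sqrt(3) / 2) * spacing**2  # area per point in a hexagonal packing
    if surface.kind == "sphere":
        area = 4 * np.pi * surface.radius**2
        n = int(round(area / cell))
        if n < 1:
            raise ValueError("spacing larger than the surface extent")
        pts = surface.center + surface.radius * _fibonacci_sphere(n)
        normals = surface.normals_at(pts)
    else:
        if length is None:
            raise ValueError("cylinder sampling needs a length")
        n_rows = max(1, int(round(length / (spacing * np.sqrt(3) / 2))))
        n_circ = max(3, int(round(2 * np.pi * surface.radius / spacing)))
        rows = []
        for i in range(n_rows):
            zoff = (i - (n_rows - 1) / 2) * spacing * np.sqrt(3) / 2
            phase = (i % 2) * np.pi / n_circ
            ang = 2 * np.pi * np.arange(n_circ) / n_circ + phase
            rows.append(np.c_[ang, np.full(n_circ, zoff)])
        ang, zoff = np.concatenate(rows).T
        u, v = _cylinder_frame(surface.axis)
        radial = np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v)
        pts = surface.center + surface.radius * radial + np.outer(zoff, surface.axis)
        normals = radial
    inplane = rng.uniform(-180.0, 180.0, size=len(pts))
    rot, tilt, psi = frame_from_normal(normals, inplane)
    return particle_set(
        pts,
        np.c_[rot, tilt, psi],
        object_id=surface.object_id if object_id is None else object_id,
    )


def _fibonacci_sphere(n):
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.c_[np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]


def _cylinder_frame(axis):
    ref = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(ref, axis)
    u /= np.linalg.norm(u)
    return u, np.cross(axis, u)


def shift_along_normal(pset: ParticleSet, distance: float) -> ParticleSet:
    """Move every particle by ``distance`` (A) along its own local
    z-axis (the membrane normal); orientations are untouched.  This is
    the radial-shift step used to seed outer-coat picking from
    membrane-level coordinates."""
    out = pset.df.copy()
    if len(pset):
        out[["x", "y", "z"]] = pset.positions + distance * pset.normals()
    return ParticleSet(out, pset.pixel_size)


def remove_duplicates(pset: ParticleSet, min_dist: float) -> ParticleSet:
    """Greedy duplicate removal at threshold ``min_dist`` (A).

    Particles are visited in descending score (ties: ascending
    particle_id) and kept iff no already-kept particle lies within
    ``min_dist``.  The classic "separation in tomogram" cleaning: its
    standard setting is a threshold of four voxels, i.e.
    ``4 * pixel_size`` in Angstrom.
    """
    if min_dist < 0:
        raise ValueError("min_dist must be >= 0")
    if len(pset) == 0 or min_dist == 0:
        return pset.copy()
    order = pset.df.sort_values(
        ["score", "particle_id"], ascending=[False, True], kind="mergesort"
    ).index.to_numpy()
    pos = pset.positions
    # prune candidate conflicts once with a KD-tree, then run the greedy
    # pass over the (much smaller) adjacency lists
    tree = cKDTree(pos)
    neigh = tree.query_ball_point(pos, min_dist)
    rank = np.empty(len(pset), dtype=np.int64)
    rank[order] = np.arange(len(order))
    kept: list[int] = []
    removed = np.zeros(len(pset), dtype=bool)
    for idx in order:
        if any(rank[j] < rank[idx] and not removed[j] for j in neigh[idx] if j != idx):
            removed[idx] = True
        else:
            kept.append(idx)
    mask = np.zeros(len(pset), dtype=bool)
    mask[kept] = True
    return pset.select(mask)


@dataclass
class TwoSampleTestResult:
    """Homoscedastic (pooled-variance) two-tailed t-test plus the
    box-plot summary of each group."""

    t: float
    df: int
    p: float
    group_a: dict = field(default_factory=dict)
    group_b: dict = field(default_factory=dict)
    degenerate: bool = False


def _box_summary(x):
    x = np.asarray(x, float)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo = x[x >= q1 - 1.5 * iqr].min()
    hi = x[x <= q3 + 1.5 * iqr].max()
    return {
        "n": int(len(x)),
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if len(x) > 1 else 0.0,
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(lo),
        "whisker_high": float(hi),
    }


def diameter_stats(group_a, group_b) -> TwoSampleTestResult:
    """Compare two sets of diameters (A) with a homoscedastic
    two-tailed t-test (df = n1 + n2 - 2)."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    dof = len(a) + len(b) - 2
    pooled_var = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / dof
    if pooled_var == 0:
        if a.mean() == b.mean():
            return TwoSampleTestResult(0.0, dof, 1.0, _box_summary(a), _box_summary(b))
        t = np.inf if a.mean() > b.mean() else -np.inf
        return TwoSampleTestResult(t, dof, 0.0, _box_summary(a), _box_summary(b), degenerate=True)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TwoSampleTestResult(float(t), dof, float(p), _box_summary(a), _box_summary(b))
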