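"""Local-frame neighbor analysis of coat lattices.

The central construction is the *neighbor cloud*: for every particle,
the positions of its neighbors expressed in that particle's own local
frame (x, y in the membrane tangent plane, z along the outward
normal).  On an ordered lattice the cloud condenses into discrete
clusters at the lattice offsets; on a disordered coat it spreads into
a diffuse cloud whose shape quantifies the flexibility of the
assembly.

From the cloud follow the downstream analyses:

* the vertex angle alpha - the average angle subtended below a vertex
  by opposite neighboring vertices (180 deg on flat membranes,
  180 - 2 arcsin(L/D) on a sphere of diameter D at spacing L) - and
  its correlation with vesicle diameter;
* lattice-based cleaning (keep particles with enough neighbors at the
  expected lattice offsets);
* neighbor-mask particle classification (e.g. rod classes by distance
  to the nearest vertex);
* subboxing (child coordinates placed relative to each parent pose);
* the inner/outer layer registration test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .particles import ParticleSet, particle_set
from .rotations import euler_to_matrix, matrix_to_euler

__all__ = [
    "RegionMask",
    "RegistrationReport",
    "neighbor_cloud",
    "lattice_clean",
    "auto_masks",
    "ring_masks",
    "vertex_alpha",
    "alpha_diameter_correlation",
    "select_by_neighbor_mask",
    "subbox",
    "layer_registration",
]


@dataclass
class RegionMask:
    """A labelled region in a particle's local frame (A units).

    ``shape`` is ``"ball"`` (center + radius) or ``"box"`` (min/max
    corners).
    """

    label: str
    shape: str = "ball"
    center: np.ndarray | None = None
    radius: float | None = None
    minimum: np.ndarray | None = None
    maximum: np.ndarray | None = None

    def __post_init__(self):
        if self.shape == "ball":
            if self.center is None or self.radius is None or self.radius <= 0:
                raise ValueError("ball mask needs a center and a positive radius")
            self.center = np.asarray(self.center, float)
        elif self.shape == "box":
            self.minimum = np.asarray(self.minimum, float)
            self.maximum = np.asarray(self.maximum, float)
            if np.any(self.maximum <= self.minimum):
                raise ValueError("degenerate box mask")
        else:
            raise ValueError(f"unknown mask shape {self.shape!r}")

    def contains(self, points):
        p = np.atleast_2d(np.asarray(points, float))
        if self.shape == "ball":
            return np.linalg.norm(p - self.center, axis=1) <= self.radius
        return np.all((p >= self.minimum) & (p <= self.maximum), axis=1)


def neighbor_cloud(
    pset: ParticleSet,
    r_max: float,
    center_layers=None,
    neighbor_layers=None,
    other: ParticleSet | None = None,
) -> pd.DataFrame:
    """Local-frame neighbor offsets for every ordered pair within
    ``r_max`` (A).

    Offsets are ``R_center^T (pos_neighbor - pos_center)``; the
    relative orientation (``rel_rot/rel_tilt/rel_psi``) is the Euler
    triple of ``R_neighbor^T R_center``, the rotation taking
    center-frame coordinates into the neighbor frame.  Pass ``other``
    to take neighbors from a second particle set (e.g. vertex centers,
    inner-coat neighbors).
    """
    if r_max <= 0:
        raise ValueError("r_max must be positive")
    cols = [
        "center_id", "neighbor_id", "dx", "dy", "dz", "dist",
        "rel_rot", "rel_tilt", "rel_psi", "center_layer", "neighbor_layer",
    ]
    nb = pset if other is None else other
    cmask = _layer_mask(pset, center_layers)
    nmask = _layer_mask(nb, neighbor_layers)
    cset, nset = pset.select(cmask), nb.select(nmask)
    if len(cset) == 0 or len(nset) == 0:
        return pd.DataFrame(columns=cols)
    cpos, npos = cset.positions, nset.positions
    pairs = cKDTree(cpos).query_ball_tree(cKDTree(npos), r_max)
    ci, ni = [], []
    same = other is None
    for i, js in enumerate(pairs):
        for j in js:
            if same and cset.df["particle_id"].iat[i] == nset.df["particle_id"].iat[j]:
                continue
            ci.append(i)
            ni.append(j)
    if not ci:
        return pd.DataFrame(columns=cols)
    ci, ni = np.asarray(ci), np.asarray(ni)
    cmats = cset.matrices()
    nmats = nset.matrices()
    delta = npos[ni] - cpos[ci]
    offsets = np.einsum("nij,nj->ni", cmats[ci].transpose(0, 2, 1), delta)
    rel = nmats[ni].transpose(0, 2, 1) @ cmats[ci]
    rrot, rtilt, rpsi = matrix_to_euler(rel)
    return pd.DataFrame(
        {
            "center_id": cset.df["particle_id"].to_numpy()[ci],
            "neighbor_id": nset.df["particle_id"].to_numpy()[ni],
            "dx": offsets[:, 0],
            "dy": offsets[:, 1],
            "dz": offsets[:, 2],
            "dist": np.linalg.norm(offsets, axis=1),
            "rel_rot": rrot,
            "rel_tilt": rtilt,
            "rel_psi": rpsi,
            "center_layer": cset.df["layer"].to_numpy()[ci],
            "neighbor_layer": nset.df["layer"].to_numpy()[ni],
        }
    )


def _layer_mask(pset, layers):
    if layers is None:
        return np.ones(len(pset), dtype=bool)
    if isinstance(layers, str):
        layers = [layers]
    return pset.df["layer"].isin(layers).to_numpy()


def lattice_clean(
    pset: ParticleSet,
    masks: list[RegionMask],
    r_max: float,
    k_min: int = 2,
    cloud: pd.DataFrame | None = None,
) -> ParticleSet:
    """Keep particles with at least ``k_min`` neighbors inside the
    union of the expected-offset ``masks`` (evaluated in each
    particle's local frame)."""
    if not masks:
        raise ValueError("masks must be non-empty")
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    if cloud is None:
        cloud = neighbor_cloud(pset, r_max)
    if len(cloud) == 0:
        return pset.select(np.zeros(len(pset), dtype=bool))
    pts = cloud[["dx", "dy", "dz"]].to_numpy()
    inside = np.zeros(len(cloud), dtype=bool)
    for mask in masks:
        inside |= mask.contains(pts)
    counts = cloud.loc[inside].groupby("center_id").size()
    good_ids = counts[counts >= k_min].index.to_numpy()
    return pset.select(good_ids)


def ring_masks(spacing: float, dip_z: float, n: int = 16, radius: float | None = None,
               label: str = "ring") -> list[RegionMask]:
    """Balls tiling the ring of expected first-shell neighbor sites.

    On a quasi-uniform lattice at ``spacing`` L the first neighbor
    shell is an annulus at lateral distance L, dipped ``dip_z`` (A,
    negative) below the tangent plane by the membrane curvature.
    Because vertex degree varies, the ring is tiled with ``n``
    azimuthally spaced balls rather than placed at fixed lattice
    azimuths.
    """
    radius = 0.25 * spacing if radius is None else radius
    return [
        RegionMask(
            label=f"{label}_{k}",
            shape="ball",
            center=(
                spacing * np.cos(2 * np.pi * k / n),
                spacing * np.sin(2 * np.pi * k / n),
                dip_z,
            ),
            radius=radius,
        )
        for k in range(n)
    ]


def auto_masks(
    cloud: pd.DataFrame,
    n_masks: int = 4,
    bandwidth: float | None = None,
    mask_radius: float | None = None,
    min_separation: float | None = None,
) -> list[RegionMask]:
    """Derive expected-offset masks as the top density modes of a
    neighbor cloud (Gaussian KDE; defaults scale with the median
    neighbor distance)."""
    if len(cloud) < 2:
        raise ValueError("cloud too small for mask derivation")
    pts = cloud[["dx", "dy", "dz"]].to_numpy()
    scale = float(np.median(cloud["dist"]))
    bandwidth = bandwidth or 0.1 * scale
    mask_radius = mask_radius or 0.3 * scale
    min_separation = min_separation or 0.5 * scale
    sample = pts[:: max(1, len(pts) // 4000)]
    kde = stats.gaussian_kde(sample.T, bw_method=bandwidth / max(sample.std(), 1e-9))
    dens = kde(pts.T)
    order = np.argsort(dens)[::-1]
    centers = []
    for idx in order:
        p = pts[idx]
        if all(np.linalg.norm(p - c) >= min_separation for c in centers):
            centers.append(p)
        if len(centers) == n_masks:
            break
    return [
        RegionMask(label=f"mode_{i}", shape="ball", center=c, radius=mask_radius)
        for i, c in enumerate(centers)
    ]


# ---------------------------------------------------------------------------
# vertex angle


def vertex_alpha(
    vertices: ParticleSet,
    L_window=(210.0, 390.0),
    opposite_tol: float = 30.0,
    diameters: dict | None = None,
    cloud: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-vertex angle alpha (degrees).

    For each vertex, neighbors with distance inside ``L_window`` are
    paired when their in-plane azimuths differ by 180 deg within
    ``opposite_tol``.  Each pair contributes
    ``180 - dip_A - dip_B`` where dip is the angle of the neighbor
    offset below the tangent plane; for exactly opposite pairs this is
    the 3D angle subtended at the vertex, and it is insensitive to the
    azimuthal scatter of real lattices.  alpha is the mean over pairs;
    vertices with no qualifying pair are omitted.

    ``diameters`` maps object_id -> membrane diameter (A) for the
    alpha-vs-diameter analysis; unknown diameters are NaN.
    """
    lo, hi = L_window
    if not 0 < lo < hi:
        raise ValueError("invalid L_window")
    if cloud is None:
        cloud = neighbor_cloud(vertices, hi * 1.001)
    rows = []
    if len(cloud):
        cloud = cloud[(cloud["dist"] >= lo) & (cloud["dist"] <= hi)]
    obj_by_id = dict(zip(vertices.df["particle_id"], vertices.df["object_id"]))
    for vid, grp in cloud.groupby("center_id"):
        off = grp[["dx", "dy", "dz"]].to_numpy()
        dist = grp["dist"].to_numpy()
        az = np.degrees(np.arctan2(off[:, 1], off[:, 0]))
        dip = np.degrees(np.arcsin(np.clip(-off[:, 2] / dist, -1.0, 1.0)))
        angles = []
        for a in range(len(off)):
            for b in range(a + 1, len(off)):
                sep = abs((az[a] - az[b] + 180.0) % 360.0 - 180.0)
                if abs(sep - 180.0) <= opposite_tol:
                    angles.append(180.0 - dip[a] - dip[b])
        if angles:
            obj = obj_by_id.get(vid, 0)
            d = diameters.get(obj, np.nan) if diameters else np.nan
            rows.append((vid, float(np.mean(angles)), len(angles), obj, d))
    if not rows:
        warnings.warn("no vertex with a qualifying opposite pair")
    return pd.DataFrame(rows, columns=["vertex_id", "alpha", "n_pairs", "object_id", "diameter"])


def alpha_diameter_correlation(table: pd.DataFrame):
    """Pearson correlation of alpha vs diameter with the two-tailed p
    from t = r sqrt(n-2)/sqrt(1-r^2), plus the least-squares trendline.

    Returns ``(r, p, slope, intercept)``.
    """
    tab = table.dropna(subset=["alpha", "diameter"])
    if len(tab) < 3:
        raise ValueError("need >= 3 (alpha, diameter) rows")
    a = tab["alpha"].to_numpy(float)
    d = tab["diameter"].to_numpy(float)
    if np.ptp(d) == 0 or np.ptp(a) == 0:
        raise ValueError("constant alpha or diameter: correlation undefined")
    r, p = stats.pearsonr(d, a)
    fit = stats.linregress(d, a)
    return float(r), float(p), float(fit.slope), float(fit.intercept)


# ---------------------------------------------------------------------------
# classification, subboxing


def select_by_neighbor_mask(cloud: pd.DataFrame, masks: list[RegionMask]) -> dict:
    """Assign each center particle to every mask containing its
    nearest neighbor offset (ties broken by neighbor_id).

    Returns ``{mask.label: [particle ids]}``.
    """
    out = {m.label: [] for m in masks}
    if len(cloud) == 0:
        return out
    nearest = (
        cloud.sort_values(["center_id", "dist", "neighbor_id"], kind="mergesort")
        .groupby("center_id", sort=True)
        .first()
    )
    pts = nearest[["dx", "dy", "dz"]].to_numpy()
    ids = nearest.index.to_numpy()
    for m in masks:
        sel = m.contains(pts)
        out[m.label] = ids[sel].tolist()
    return out


def subbox(
    parents: ParticleSet,
    child_offset,
    child_euler=(0.0, 0.0, 0.0),
    layer: str = "other",
    start_id: int | None = None,
) -> ParticleSet:
    """Create one child coordinate per parent at a fixed offset and
    rotation in the parent frame (subparticle extraction geometry).

    Child position = parent position + R_parent @ offset; child
    orientation = R_parent @ R_child.  A ``parent_id`` column links
    children to parents.
    """
    off = np.asarray(child_offset, float)
    mats = parents.matrices()
    pos = parents.positions + np.einsum("nij,j->ni", mats, off)
    child_m = euler_to_matrix(*child_euler)
    rot, tilt, psi = matrix_to_euler(mats @ child_m)
    if start_id is None:
        start_id = (int(parents.df["particle_id"].max()) + 1) if len(parents) else 0
    return particle_set(
        pos,
        np.c_[rot, tilt, psi],
        layer=layer,
        object_id=0,
        start_id=start_id,
        extra={"parent_id": parents.df["particle_id"].to_numpy()},
    )


# ---------------------------------------------------------------------------
# inner/outer registration


@dataclass
class RegistrationReport:
    n_selected: int
    offset_mean: np.ndarray | None
    offset_cov: np.ndarray | None
    angles: np.ndarray = field(default_factory=lambda: np.array([]))
    rayleigh_z: float = np.nan
    uniformity_p: float = np.nan
    verdict: str = "inconclusive"


def layer_registration(
    vertices: ParticleSet,
    inner: ParticleSet,
    region: RegionMask,
    r_max: float,
    c2_fold: bool = True,
    alpha_level: float = 0.05,
    cov_trace_max: float = 2500.0,
) -> RegistrationReport:
    """Test whether an inner-coat layer is registered to outer-coat
    vertices.

    For every vertex whose *nearest* inner neighbor (within ``r_max``)
    falls inside ``region`` (vertex local frame), the relative
    in-plane rotation between the two poses is collected.  Registered
    layers produce a tight translational cluster and a non-uniform
    angle distribution; a free (linker-tethered) layer produces
    uniform angles.  Uniformity is tested with a Rayleigh test on
    doubled angles (the vertex is treated as 2-fold pseudosymmetric,
    so angles are folded modulo 180 deg when ``c2_fold``).

    Verdict: ``registered`` iff uniformity is rejected at
    ``alpha_level`` AND the translational cluster is tight
    (trace of the offset covariance < ``cov_trace_max``, A^2);
    ``unregistered`` iff uniformity is not rejected; fewer than 10
    selected pairs -> ``inconclusive``.
    """
    if len(inner) == 0 or len(vertices) == 0:
        return RegistrationReport(0, None, None)
    cloud = neighbor_cloud(vertices, r_max, other=inner)
    if len(cloud) == 0:
        return RegistrationReport(0, None, None)
    nearest = (
        cloud.sort_values(["center_id", "dist", "neighbor_id"], kind="mergesort")
        .groupby("center_id", sort=True)
        .first()
        .reset_index()
    )
    sel = nearest[region.contains(nearest[["dx", "dy", "dz"]].to_numpy())]
    n = len(sel)
    if n < 10:
        return RegistrationReport(n, None, None)
    offsets = sel[["dx", "dy", "dz"]].to_numpy()
    # relative in-plane angle: azimuth of the inner x-axis seen in the
    # vertex frame.  rel maps center(vertex) frame -> neighbor(inner)
    # frame, so the inner x-axis in vertex coordinates is rel.T @ x.
    rel = euler_to_matrix(
        sel["rel_rot"].to_numpy(), sel["rel_tilt"].to_numpy(), sel["rel_psi"].to_numpy()
    )
    xin = rel.transpose(0, 2, 1) @ np.array([1.0, 0.0, 0.0])
    angles = np.degrees(np.arctan2(xin[:, 1], xin[:, 0]))
    if c2_fold:
        angles = np.mod(angles, 180.0)
        doubled = np.radians(2.0 * angles)
    else:
        doubled = np.radians(angles)
    from pingouin import circ_rayleigh

    z, p = circ_rayleigh(doubled)
    cov = np.cov(offsets.T) if n > 1 else np.zeros((3, 3))
    if p < alpha_level and np.trace(cov) < cov_trace_max:
        verdict = "registered"
    elif p >= alpha_level:
        verdict = "unregistered"
    else:
        verdict = "inconclusive"
    return RegistrationReport(
        n, offsets.mean(axis=0), cov, angles, float(z), float(p), verdict
    )
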