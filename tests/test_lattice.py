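"""Neighbor-cloud analyses: offsets, alpha, cleaning, classification,
subboxing, layer registration."""

import numpy as np
import pandas as pd
import pytest

from coatlattice import (
    CageParams,
    CorruptionModel,
    RegionMask,
    alpha_diameter_correlation,
    concat,
    corrupt,
    euler_to_matrix,
    lattice_clean,
    layer_registration,
    make_cage,
    make_planar_lattice,
    make_two_layer,
    neighbor_cloud,
    particle_set,
    select_by_neighbor_mask,
    subbox,
    vertex_alpha,
)
from coatlattice.lattice import ring_masks
from coatlattice.rotations import random_rotations


def cage_population(diams, L=300.0, seed0=0, **corrupt_kw):
    """Several cages merged into one table with per-object diameters."""
    sets, diameters = [], {}
    next_id = 0
    for obj, D in enumerate(diams):
        res = make_cage(CageParams(diameter=float(D), edge_length=L, seed=seed0 + obj,
                                   center=(3.0 * max(diams) * obj, 0.0, 0.0)))
        df = res.vertices.df.copy()
        df["particle_id"] += next_id
        df["object_id"] = obj
        vs = type(res.vertices)(df, res.vertices.pixel_size)
        if corrupt_kw:
            vs = corrupt(vs, CorruptionModel(seed=seed0 + 100 + obj, **corrupt_kw), res.surface)
        next_id = int(vs.df["particle_id"].max()) + 1
        sets.append(vs)
        diameters[obj] = float(D)
    return concat(sets), diameters


class TestNeighborCloud:
    def test_offset_in_center_local_frame(self):
        pset = particle_set(
            [[0.0, 0.0, 0.0], [300.0, 0.0, 0.0]], [[0.0, 0.0, 0.0], [0.0, 0.0, 0.0]]
        )
        cloud = neighbor_cloud(pset, 400.0)
        row = cloud[(cloud.center_id == 0)].iloc[0]
        assert np.allclose([row.dx, row.dy, row.dz], [300.0, 0.0, 0.0])

    def test_offset_respects_center_orientation(self):
        # center rotated 90 deg in-plane: the neighbor along world x
        # appears along the local -y axis
        pset = particle_set(
            [[0.0, 0.0, 0.0], [300.0, 0.0, 0.0]], [[90.0, 0.0, 0.0], [0.0, 0.0, 0.0]]
        )
        cloud = neighbor_cloud(pset, 400.0)
        row = cloud[(cloud.center_id == 0)].iloc[0]
        assert np.allclose([row.dx, row.dy, row.dz], [0.0, -300.0, 0.0], atol=1e-9)

    def test_cage_neighbors_dip_below_tangent_plane(self):
        res = make_cage(CageParams(diameter=800, edge_length=300))
        cloud = neighbor_cloud(res.vertices, 390.0)
        near = cloud[cloud.dist > 210.0]
        assert len(near)
        assert (near["dz"] < 0).mean() > 0.95
        assert abs(near["dist"].median() - 300.0) < 20.0

    def test_small_radius_gives_empty_cloud(self):
        pset = make_planar_lattice(300.0, 4, 4)
        cloud = neighbor_cloud(pset, 10.0)
        assert len(cloud) == 0

    def test_rigid_transform_equivariance(self):
        res = make_cage(CageParams(diameter=800, edge_length=300, seed=1,
                                   pos_jitter_sd=5, ang_jitter_sd=3))
        before = neighbor_cloud(res.vertices, 450.0)
        Q = euler_to_matrix(33.0, 41.0, -70.0)
        moved = res.vertices.transformed(Q, [100.0, -50.0, 20.0])
        after = neighbor_cloud(moved, 450.0)
        key = ["center_id", "neighbor_id"]
        b = before.sort_values(key)[["dx", "dy", "dz"]].to_numpy()
        a = after.sort_values(key)[["dx", "dy", "dz"]].to_numpy()
        assert np.abs(a - b).max() < 1e-9

    def test_brute_force_agreement(self, rng):
        rot, tilt, psi = random_rotations(200, rng)
        pset = particle_set(rng.uniform(0, 1500, (200, 3)), np.c_[rot, tilt, psi])
        cloud = neighbor_cloud(pset, 400.0)
        pos = pset.positions
        mats = pset.matrices()
        pairs = set()
        for i in range(200):
            for j in range(200):
                if i != j and np.linalg.norm(pos[j] - pos[i]) <= 400.0:
                    pairs.add((i, j))
        got = set(zip(cloud.center_id, cloud.neighbor_id))
        assert got == pairs
        for _, row in cloud.sample(50, random_state=0).iterrows():
            i, j = int(row.center_id), int(row.neighbor_id)
            off = mats[i].T @ (pos[j] - pos[i])
            assert np.allclose([row.dx, row.dy, row.dz], off, atol=1e-9)


class TestVertexAlpha:
    def test_planar_lattice_is_flat_limit(self):
        tab = vertex_alpha(make_planar_lattice(300.0, 8, 8))
        assert np.abs(tab["alpha"] - 180.0).max() < 1e-9

    def test_alpha_range_matches_reported_interval(self):
        # over vesicles from D = 2L upward, alpha spans [120, 180)
        alphas = []
        for D in [600.0, 1200.0, 3000.0]:
            res = make_cage(CageParams(diameter=D, edge_length=300.0))
            alphas.append(vertex_alpha(res.vertices)["alpha"].mean())
        assert abs(alphas[0] - 120.0) < 1.0
        assert all(a < 180.0 for a in alphas)
        assert np.all(np.diff(alphas) > 0)

    def test_empty_window_warns(self):
        pset = make_planar_lattice(300.0, 3, 3)
        with pytest.warns(UserWarning, match="no vertex"):
            tab = vertex_alpha(pset, L_window=(10.0, 20.0))
        assert len(tab) == 0


@pytest.fixture(scope="module")
def noiseless_population():
    diams = np.linspace(600.0, 3000.0, 20)
    return cage_population(diams)


class TestAlphaDiameterCorrelation:
    def test_noiseless_population_strongly_correlated(self, noiseless_population):
        pop, diameters = noiseless_population
        tab = vertex_alpha(pop, diameters=diameters)
        # per-vesicle pairing as in the alpha-vs-diameter plot
        per_obj = tab.groupby("object_id").agg(
            alpha=("alpha", "mean"), diameter=("diameter", "first")
        ).reset_index()
        r, p, slope, intercept = alpha_diameter_correlation(per_obj)
        assert r > 0.9
        assert p < 1e-3
        assert slope > 0
        # per-vertex rows remain strongly coupled as well
        r_v, p_v, *_ = alpha_diameter_correlation(tab)
        assert r_v > 0.8 and p_v < 1e-6

    def test_shuffled_null_loses_correlation(self, noiseless_population):
        pop, diameters = noiseless_population
        tab = vertex_alpha(pop, diameters=diameters)
        rng = np.random.default_rng(0)
        shuffled = tab.copy()
        shuffled["diameter"] = rng.permutation(shuffled["diameter"].to_numpy())
        r, p, *_ = alpha_diameter_correlation(shuffled)
        assert abs(r) < 0.3

    def test_degenerate_inputs_rejected(self):
        two = pd.DataFrame({"alpha": [120.0, 150.0], "diameter": [600.0, 1200.0]})
        with pytest.raises(ValueError):
            alpha_diameter_correlation(two)
        const = pd.DataFrame({"alpha": [120.0] * 5, "diameter": [600.0] * 5})
        with pytest.raises(ValueError):
            alpha_diameter_correlation(const)


class TestLatticeClean:
    def test_perfect_lattice_interior_kept(self):
        pset = make_planar_lattice(300.0, 8, 8)
        masks = ring_masks(300.0, 0.0)
        kept = lattice_clean(pset, masks, r_max=450.0, k_min=2)
        # interior = particles with >= 4 true neighbors at lattice range
        cloud = neighbor_cloud(pset, 320.0)
        counts = cloud.groupby("center_id").size()
        interior = counts[counts >= 4].index
        assert set(interior).issubset(set(kept.df["particle_id"]))

    def test_junk_removed_true_retained(self):
        pop, diameters = cage_population(
            np.linspace(700, 1100, 8), pos_noise_sd=5.0, ang_noise_sd=2.0, junk_fraction=0.3
        )
        L = 300.0
        dip = np.mean([np.arcsin(L / d) for d in diameters.values()])
        kept = lattice_clean(pop, ring_masks(L, -L * np.sin(dip)), r_max=450.0, k_min=3)
        kept_ids = set(kept.df["particle_id"])
        is_kept = pop.df["particle_id"].isin(kept_ids).to_numpy()
        junk = (pop.df["truth"] == "junk").to_numpy()
        assert (1 - is_kept[junk].mean()) >= 0.95  # junk removal recall
        assert is_kept[~junk].mean() >= 0.95  # true retention

    def test_isolated_particle_removed(self):
        pset = particle_set([[0.0, 0.0, 0.0]], [[0.0, 0.0, 0.0]])
        kept = lattice_clean(pset, ring_masks(300.0, 0.0), r_max=450.0, k_min=1)
        assert len(kept) == 0


class TestSelectByNeighborMask:
    def test_containment(self):
        cloud = pd.DataFrame(
            {
                "center_id": [0], "neighbor_id": [1],
                "dx": [295.0], "dy": [3.0], "dz": [-38.0],
                "dist": [np.sqrt(295.0**2 + 9.0 + 38.0**2)],
            }
        )
        mask = RegionMask("near", "ball", center=(300.0, 0.0, -40.0), radius=30.0)
        out = select_by_neighbor_mask(cloud, [mask])
        assert out["near"] == [0]

    def test_empty_mask_region(self):
        cloud = pd.DataFrame(
            {"center_id": [0], "neighbor_id": [1], "dx": [0.0], "dy": [0.0],
             "dz": [100.0], "dist": [100.0]}
        )
        mask = RegionMask("far", "ball", center=(500.0, 0.0, 0.0), radius=10.0)
        assert select_by_neighbor_mask(cloud, [mask])["far"] == []

    def test_hinge_bend_classes_recovered(self):
        # bent rods pop outward along their local z, so the nearest
        # vertex sinks deeper below the rod; masks at increasing offset
        # depth recover the generator's bend tertiles
        res = make_cage(CageParams(diameter=2400.0, edge_length=300.0,
                                   rod_hinge_sd=40.0, seed=3))
        cloud = neighbor_cloud(res.rods, 280.0, other=res.vertices)
        bends = np.abs(res.rods.df.set_index("particle_id")["hinge_bend"])
        tert = bends.quantile([1 / 3, 2 / 3]).to_numpy()
        labels = {pid: int(np.searchsorted(tert, b)) for pid, b in bends.items()}
        z_ranges = {0: (-31.0, 0.0), 1: (-60.0, -33.0), 2: (-280.0, -64.0)}
        masks = []
        for t, (zlo, zhi) in z_ranges.items():
            for tag, (x0, x1) in (("p", (110.0, 200.0)), ("m", (-200.0, -110.0))):
                masks.append(
                    RegionMask(f"t{t}_{tag}", "box",
                               minimum=(x0, -30.0, zlo), maximum=(x1, 30.0, zhi))
                )
        classes = select_by_neighbor_mask(cloud, masks)
        purities = []
        for t in range(3):
            got = classes[f"t{t}_p"] + classes[f"t{t}_m"]
            assert len(got) > 100
            purities.append(np.mean([labels[pid] == t for pid in got]))
        assert np.mean(purities) >= 0.9
        assert min(purities) >= 0.85


class TestSubbox:
    def test_identity_parent(self):
        parents = particle_set([[0.0, 0.0, 0.0]], [[0.0, 0.0, 0.0]])
        kids = subbox(parents, (0.0, 0.0, 100.0))
        assert np.allclose(kids.positions[0], [0, 0, 100])
        assert np.allclose(kids.eulers[0], [0, 0, 0])

    def test_four_children_at_azimuthal_steps(self):
        # the vertex -> rod subboxing: four new coordinates per vertex
        parents = particle_set([[0.0, 0.0, 0.0]], [[0.0, 0.0, 0.0]])
        kid_sets = [
            subbox(parents, (150.0 * np.cos(np.radians(90 * k)),
                             150.0 * np.sin(np.radians(90 * k)), -30.0), start_id=10 + k)
            for k in range(4)
        ]
        kids = concat(kid_sets)
        assert len(kids) == 4
        az = np.degrees(np.arctan2(kids.positions[:, 1], kids.positions[:, 0]))
        assert sorted(np.mod(np.round(az), 360)) == [0.0, 90.0, 180.0, 270.0]

    def test_offset_recovered_through_neighbor_cloud(self, rng):
        rot, tilt, psi = random_rotations(10, rng)
        parents = particle_set(rng.uniform(-200, 200, (10, 3)), np.c_[rot, tilt, psi])
        kids = subbox(parents, (30.0, -40.0, 100.0), (10.0, 20.0, 30.0))
        cloud = neighbor_cloud(parents, 200.0, other=kids)
        own = cloud[cloud.neighbor_id - kids.df["particle_id"].min()
                    == cloud.center_id].sort_values("center_id")
        assert len(own) == 10
        assert np.abs(own[["dx", "dy", "dz"]].to_numpy() - [30.0, -40.0, 100.0]).max() < 1e-9


class TestLayerRegistration:
    REGION = RegionMask("below", "ball", center=(0.0, 0.0, -120.0), radius=80.0)

    def test_registered_layers_detected(self):
        verts, inner = make_two_layer(
            CageParams(diameter=2400.0, edge_length=300.0, seed=3), registered=True
        )
        report = layer_registration(verts, inner, self.REGION, r_max=240.0)
        assert report.verdict == "registered"
        assert report.uniformity_p < 1e-3
        assert np.trace(report.offset_cov) < 2500.0

    def test_unregistered_layers_detected(self):
        verts, inner = make_two_layer(
            CageParams(diameter=2400.0, edge_length=300.0, seed=4),
            registered=False, inner_spacing=60.0,
        )
        report = layer_registration(verts, inner, self.REGION, r_max=240.0)
        assert report.n_selected >= 100
        assert report.verdict == "unregistered"
        assert report.uniformity_p > 0.05

    def test_empty_inner_inconclusive(self):
        verts, _ = make_two_layer(
            CageParams(diameter=1200.0, edge_length=300.0, seed=1), registered=True
        )
        empty = verts.select(np.zeros(len(verts), dtype=bool))
        report = layer_registration(verts, empty, self.REGION, r_max=240.0)
        assert report.verdict == "inconclusive"
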