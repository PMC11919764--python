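"""Voxel-space operations: filtering, normalization, synthesis,
difference mapping, averaging, FSC, map-back."""

import numpy as np
import pytest

from coatlattice import (
    AtomSet,
    DensityMap,
    average_subvolumes,
    difference_map,
    fsc,
    lowpass,
    map_back,
    model_to_map,
    normalize_map,
    particle_set,
    render_subvolumes,
)
from coatlattice.density import rotate_grid
from coatlattice.rotations import random_rotations


class TestLowpass:
    def test_all_pass_near_identity(self, blob_template):
        out = lowpass(blob_template, 2 * blob_template.voxel_size, soft_edge=0)
        assert np.abs(out.grid - blob_template.grid).max() < 1e-4

    def test_mean_preserved(self, blob_template):
        out = lowpass(blob_template, 30.0)
        assert out.grid.mean() == pytest.approx(blob_template.grid.mean(), abs=1e-6)

    def test_sharp_edge_is_idempotent(self, blob_template):
        once = lowpass(blob_template, 30.0, soft_edge=0)
        twice = lowpass(once, 30.0, soft_edge=0)
        assert np.abs(twice.grid - once.grid).max() < 1e-5

    def test_soft_edge_near_idempotent(self, blob_template, corr):
        # the raised-cosine transition band is attenuated twice, so the
        # second application only perturbs the edge band
        once = lowpass(blob_template, 30.0)
        twice = lowpass(once, 30.0)
        assert corr(twice.grid, once.grid) > 0.999

    def test_delta_becomes_radial_kernel(self):
        n = 33
        g = np.zeros((n, n, n), dtype=np.float32)
        g[16, 16, 16] = 1.0
        out = lowpass(DensityMap(g, 5.0), 25.0).grid
        # radially symmetric: equal values at equal distances on the axes
        assert out[16, 16, 20] == pytest.approx(out[16, 20, 16], rel=1e-3)
        assert out[16, 16, 20] == pytest.approx(out[20, 16, 16], rel=1e-3)
        assert np.argmax(out) == np.ravel_multi_index((16, 16, 16), out.shape)

    def test_beyond_nyquist_rejected(self, blob_template):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass(blob_template, 1.5 * blob_template.voxel_size)


class TestNormalize:
    def test_moments(self, rng):
        g = rng.normal(5.0, 2.0, (24, 24, 24)).astype(np.float32)
        out = normalize_map(DensityMap(g, 4.0))
        assert abs(out.grid.mean()) < 1e-3
        assert out.grid.std() == pytest.approx(1.0, abs=1e-3)

    def test_idempotent(self, rng):
        g = rng.normal(size=(16, 16, 16)).astype(np.float32)
        once = normalize_map(DensityMap(g, 4.0))
        twice = normalize_map(once)
        assert np.abs(twice.grid - once.grid).max() < 1e-6

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_map(DensityMap(np.full((8, 8, 8), 3.0, dtype=np.float32), 4.0))


class TestModelToMap:
    def test_single_atom_gaussian_profile(self):
        atoms = AtomSet(np.array([[16.0, 16.0, 16.0]]), ["C"])
        m = model_to_map(atoms, 1.0, (33, 33, 33), resolution=8.0, origin=(0.0, 0.0, 0.0))
        assert np.unravel_index(np.argmax(m.grid), m.grid.shape) == (16, 16, 16)
        sigma = 0.225 * 8.0
        profile = m.grid[16, 16, :]
        expected = np.exp(-((np.arange(33) - 16.0) ** 2) / (2 * sigma**2))
        assert np.abs(profile - expected).max() < 0.01 * expected.max()

    def test_two_far_atoms_linearity(self):
        one = model_to_map(AtomSet(np.array([[10.0, 10.0, 10.0]]), ["C"]),
                           1.0, (64, 64, 64), resolution=6.0, origin=(0.0, 0.0, 0.0))
        two = model_to_map(AtomSet(np.array([[10.0, 10.0, 10.0], [50.0, 50.0, 50.0]]), ["C"] * 2),
                           1.0, (64, 64, 64), resolution=6.0, origin=(0.0, 0.0, 0.0))
        assert two.grid.sum() == pytest.approx(2 * one.grid.sum(), rel=1e-6)

    def test_two_step_recipe_matches_direct_synthesis(self, rng, corr):
        # high-resolution synthesis + low-pass vs direct synthesis at
        # the target resolution, on a compact protein-like atom cloud
        pts = []
        while len(pts) < 400:
            p = rng.uniform(-12, 12, 3)
            if np.linalg.norm(p) < 12:
                pts.append(p)
        atoms = AtomSet(np.asarray(pts) + 32.0, ["C"] * 400)
        hi = model_to_map(atoms, 1.0, (64, 64, 64), resolution=2.0)
        two_step = lowpass(hi, 14.0)
        direct = model_to_map(atoms, 1.0, (64, 64, 64), resolution=14.0, origin=hi.origin)
        # the sharp-cutoff low-pass and the Gaussian synthesis kernel
        # differ near the cutoff, which bounds the agreement just
        # below 0.99 even on a noiseless model
        assert corr(two_step.grid, direct.grid) > 0.98

    def test_atoms_outside_box_rejected(self):
        atoms = AtomSet(np.array([[5.0, 5.0, 5.0], [500.0, 5.0, 5.0]]), ["C", "C"])
        with pytest.raises(ValueError, match="2 atoms|1 atoms"):
            model_to_map(atoms, 1.0, (16, 16, 16), origin=(0.0, 0.0, 0.0))


class TestDifferenceMap:
    def test_self_difference_has_no_blobs(self, blob_template):
        diff, report = difference_map(blob_template, blob_template.copy())
        assert len(report) == 0
        assert np.abs(diff.grid).max() < 1e-5

    def test_inserted_blob_recovered_within_one_voxel(self, rng, blob_template):
        n = blob_template.grid.shape[0]
        zz, yy, xx = np.indices((n, n, n))
        inserted = 6.0 * np.exp(
            -(((xx - 8) ** 2 + (yy - 20) ** 2 + (zz - 24) ** 2) / (2 * 2.0**2))
        )
        noisy_ref = DensityMap(
            blob_template.grid + rng.normal(0, 0.02, (n, n, n)).astype(np.float32),
            blob_template.voxel_size,
        )
        observed = DensityMap(
            noisy_ref.grid + inserted.astype(np.float32), blob_template.voxel_size
        )
        site = np.array([8.0, 20.0, 24.0]) * blob_template.voxel_size
        diff, report = difference_map(observed, noisy_ref, threshold=3.0, min_voxels=5,
                                      annotated_sites=[site])
        assert len(report) == 1
        centroid = report[["x", "y", "z"]].iloc[0].to_numpy()
        assert np.linalg.norm(centroid - site) <= blob_template.voxel_size
        assert report["dist_site_0"].iloc[0] <= blob_template.voxel_size
        assert report["peak_sd"].iloc[0] > 3.0

    def test_threshold_above_peak_gives_empty_report(self, rng, blob_template):
        n = blob_template.grid.shape[0]
        observed = DensityMap(
            blob_template.grid + rng.normal(0, 0.01, (n, n, n)).astype(np.float32),
            blob_template.voxel_size,
        )
        _, report = difference_map(observed, blob_template, threshold=50.0)
        assert len(report) == 0

    def test_grid_mismatch_rejected(self, blob_template):
        other = DensityMap(np.zeros((8, 8, 8), dtype=np.float32), blob_template.voxel_size)
        with pytest.raises(ValueError, match="mismatch"):
            difference_map(blob_template, other)


class TestAverage:
    def test_single_identity_returns_input(self, blob_template):
        pset = particle_set([[0.0, 0.0, 0.0]], [[0.0, 0.0, 0.0]])
        avg, _ = average_subvolumes([blob_template], pset)
        assert np.abs(avg.grid - blob_template.grid).max() < 1e-4

    def test_true_poses_reconstruct_template(self, rng, blob_template, corr):
        rot, tilt, psi = random_rotations(20, rng)
        pset = particle_set(np.zeros((20, 3)), np.c_[rot, tilt, psi])
        vols = render_subvolumes(pset, blob_template, noise_sd=0.0, seed=1)
        avg, _ = average_subvolumes(vols, pset)
        assert corr(avg.grid, blob_template.grid) > 0.99

    def test_translations_inverted(self, rng, blob_template, corr):
        rot, tilt, psi = random_rotations(15, rng)
        pos = rng.normal(0, 12.0, (15, 3))
        pset = particle_set(pos, np.c_[rot, tilt, psi])
        vols = render_subvolumes(pset, blob_template, noise_sd=0.0, seed=2)
        avg, _ = average_subvolumes(vols, pset)
        assert corr(avg.grid, blob_template.grid) > 0.99

    def test_permutation_invariance(self, rng, blob_template):
        rot, tilt, psi = random_rotations(8, rng)
        pset = particle_set(np.zeros((8, 3)), np.c_[rot, tilt, psi])
        vols = render_subvolumes(pset, blob_template, noise_sd=0.5, seed=3)
        avg1, _ = average_subvolumes(vols, pset)
        perm = [7, 2, 5, 0, 1, 6, 3, 4]
        vols_p = [vols[i] for i in perm]
        pset_p = pset.select(np.array(perm)).copy()
        # reorder rows to match permuted volumes
        import pandas as pd

        df = pset.df.iloc[perm].reset_index(drop=True)
        pset_p = type(pset)(df, pset.pixel_size)
        avg2, _ = average_subvolumes(vols_p, pset_p)
        assert np.abs(avg1.grid - avg2.grid).max() < 1e-5

    def test_c2_symmetrized_output_is_c2(self, rng, blob_template):
        rot, tilt, psi = random_rotations(4, rng)
        pset = particle_set(np.zeros((4, 3)), np.c_[rot, tilt, psi])
        vols = render_subvolumes(pset, blob_template, 0.0, seed=4)
        avg, _ = average_subvolumes(vols, pset, symmetry="C2")
        flipped = rotate_grid(avg.grid, np.diag([-1.0, -1.0, 1.0]))
        assert np.abs(avg.grid - flipped).max() < 1e-3 * np.abs(avg.grid).max()

    def test_size_mismatch_rejected(self, blob_template):
        small = DensityMap(np.zeros((8, 8, 8), dtype=np.float32), 6.0)
        pset = particle_set(np.zeros((2, 3)), np.zeros((2, 3)))
        with pytest.raises(ValueError, match="mismatch"):
            average_subvolumes([blob_template, small], pset)


class TestFsc:
    def test_self_correlation_is_one_everywhere(self, blob_template):
        curve = fsc(blob_template, blob_template)
        assert np.all(curve.correlations > 1 - 1e-6)
        assert curve.resolution == pytest.approx(2 * blob_template.voxel_size)

    def test_independent_noise_uncorrelated(self, rng):
        a = DensityMap(rng.normal(size=(32, 32, 32)).astype(np.float32), 5.0)
        b = DensityMap(rng.normal(size=(32, 32, 32)).astype(np.float32), 5.0)
        curve = fsc(a, b)
        assert np.abs(curve.correlations).mean() < 0.15

    def test_resolution_degrades_with_noise(self, rng, blob_template):
        resolutions = []
        for sd in [0.05, 0.4, 2.0]:
            noisy = DensityMap(
                blob_template.grid + rng.normal(0, sd, blob_template.grid.shape).astype(np.float32),
                blob_template.voxel_size,
            )
            resolutions.append(fsc(blob_template, noisy).resolution)
        assert resolutions[0] <= resolutions[1] <= resolutions[2]

    def test_frequencies_increasing(self, blob_template):
        curve = fsc(blob_template, blob_template)
        assert np.all(np.diff(curve.frequencies) > 0)


class TestMapBack:
    def test_single_identity_particle_centered(self, blob_template):
        n = blob_template.grid.shape[0]
        vx = blob_template.voxel_size
        center = (np.array([n, n, n]) - 1) / 2.0 * vx
        pset = particle_set([center], [[0.0, 0.0, 0.0]])
        out = map_back(blob_template, pset, (n, n, n), vx)
        assert np.abs(out.grid - blob_template.grid).max() < 1e-4

    def test_sum_conserved_without_clipping(self, rng, blob_template):
        pos = rng.uniform(300, 700, (5, 3))
        rot, tilt, psi = random_rotations(5, rng)
        pset = particle_set(pos, np.c_[rot, tilt, psi])
        out = map_back(blob_template, pset, (104, 104, 104), 10.0)
        assert out.grid.sum() == pytest.approx(5 * blob_template.grid.sum(), rel=1e-2)

    def test_empty_set_zero_map(self, blob_template):
        pset = particle_set(np.zeros((0, 3)), np.zeros((0, 3)))
        out = map_back(blob_template, pset, (32, 32, 32), 6.0)
        assert np.all(out.grid == 0)

    def test_outside_placements_warn(self, blob_template):
        pset = particle_set([[0.0, 0.0, 0.0]], [[0.0, 0.0, 0.0]])
        with pytest.warns(UserWarning, match="clipped"):
            map_back(blob_template, pset, (32, 32, 32), 6.0)


class TestRotateGrid:
    def test_spherically_symmetric_map_invariant(self, rng):
        n = 48
        zz, yy, xx = np.indices((n, n, n))
        c = (n - 1) / 2
        g = np.exp(-(((xx - c) ** 2 + (yy - c) ** 2 + (zz - c) ** 2) / (2 * 6.0**2))).astype(
            np.float32
        )
        rot, tilt, psi = random_rotations(5, rng)
        from coatlattice import euler_to_matrix

        # trilinear interpolation is second-order accurate: ~1% of peak
        # for a Gaussian a few voxels wide
        for M in euler_to_matrix(rot, tilt, psi):
            out = rotate_grid(g, M)
            assert np.abs(out - g).max() < 0.01 * g.max()
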