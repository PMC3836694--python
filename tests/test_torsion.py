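import numpy as np
import pytest

from hingescan import synth, torsion
from hingescan._vecmath import wrap_degrees
from hingescan.io import Trajectory


def vm_samples(rng, centers, kappa, n, weights=None):
    """(phi, psi) draws from a von Mises mixture; centers = [(phi, psi), ...]."""
    centers = np.asarray(centers, dtype=float)
    if weights is None:
        weights = np.full(len(centers), 1.0 / len(centers))
    pick = rng.choice(len(centers), size=n, p=weights)
    phi = np.degrees(rng.vonmises(np.radians(centers[pick, 0]), kappa))
    psi = np.degrees(rng.vonmises(np.radians(centers[pick, 1]), kappa))
    return phi, psi


class TestComputeDihedrals:
    def test_termini_are_undefined(self, small_apo_ensemble):
        traj, _, _ = small_apo_ensemble
        ts = torsion.compute_dihedrals(traj)
        assert np.all(np.isnan(ts.phi[:, 0]))
        assert np.all(np.isnan(ts.psi[:, -1]))
        defined = np.concatenate([ts.phi[:, 1:].ravel(), ts.psi[:, :-1].ravel()])
        defined = defined[np.isfinite(defined)]
        assert defined.min() >= -180.0 and defined.max() < 180.0

    def test_mirror_flips_all_signs(self):
        n = 20
        rng = np.random.default_rng(3)
        phi = rng.uniform(-170, 170, n)
        psi = rng.uniform(-170, 170, n)
        s = synth.generate_backbone(n, phi, psi)
        ts = torsion.compute_dihedrals(Trajectory(s, s.coords[None]))
        mirrored = s.coords * np.array([-1.0, 1.0, 1.0])
        tm = torsion.compute_dihedrals(Trajectory(s, mirrored[None]))
        np.testing.assert_allclose(tm.phi[0, 1:], -ts.phi[0, 1:], atol=1e-9)
        np.testing.assert_allclose(tm.psi[0, :-1], -ts.psi[0, :-1], atol=1e-9)

    def test_rigid_transform_and_scale_invariance(self):
        from scipy.spatial.transform import Rotation

        n = 15
        phi, psi = synth.background_torsions(n)
        s = synth.generate_backbone(n, phi, psi)
        ts = torsion.compute_dihedrals(Trajectory(s, s.coords[None]))
        g = Rotation.from_euler("xyz", [11, 22, 33], degrees=True).as_matrix()
        moved = (s.coords * 2.5) @ g.T + 40.0
        tm = torsion.compute_dihedrals(Trajectory(s, moved[None]))
        np.testing.assert_allclose(
            np.nan_to_num(tm.phi), np.nan_to_num(ts.phi), atol=1e-8
        )

    def test_block_seam_masked(self):
        """Dihedrals across the rigid II-B seam (a bond that stretches with
        the block motion) are masked rather than reported as garbage."""
        spec = synth.PlantSpec(n_residues=120, state="apo", seed=2)
        traj, _, _ = synth.generate_trajectory(spec, 100)
        ts = torsion.compute_dihedrals(traj)
        smap = spec.subdomain_map
        iib = smap.residues("II-B")
        first, last = iib[0], iib[-1]
        j_first = int(np.nonzero(ts.residues == first)[0][0])
        assert np.all(np.isnan(ts.phi[:, j_first]))
        assert np.all(np.isnan(ts.psi[:, j_first - 1]))
        j_after = int(np.nonzero(ts.residues == last + 1)[0][0])
        assert np.all(np.isnan(ts.phi[:, j_after]))


class TestRamaDensity:
    def test_sums_to_one_and_needs_frames(self, rng):
        phi, psi = vm_samples(rng, [(-60, -45)], 20, 200)
        grid = torsion.rama_density(phi, psi)
        assert grid.shape == (36, 36)
        assert np.isclose(grid.sum(), 1.0)
        with pytest.raises(ValueError, match="at least"):
            torsion.rama_density(phi[:10], psi[:10])

    def test_single_point_unsmoothed_single_cell(self):
        phi = np.full(100, -57.0)
        psi = np.full(100, -47.0)
        grid = torsion.rama_density(phi, psi, sigma_bins=0.0)
        assert np.count_nonzero(grid) == 1

    def test_uniform_samples_flat(self, rng):
        phi = rng.uniform(-180, 180, 100_000)
        psi = rng.uniform(-180, 180, 100_000)
        grid = torsion.rama_density(phi, psi)
        assert grid.max() / grid.min() < 2.0

    def test_wraparound_mode_is_continuous(self, rng):
        phi, psi = vm_samples(rng, [(179, -179)], 30, 5000)
        grid = torsion.rama_density(phi, psi)
        # the four corner cells all carry comparable density (no edge cliff)
        corners = [grid[0, 0], grid[0, -1], grid[-1, 0], grid[-1, -1]]
        assert min(corners) > 0.3 * max(corners)


class TestClusterTorus:
    def test_single_von_mises_one_mode(self, rng):
        phi, psi = vm_samples(rng, [(-60, -45)], 20, 5000)
        c = torsion.cluster_torus(phi, psi)
        assert c.n_modes == 1
        assert abs(c.clusters[0].phi + 60) < 5 and abs(c.clusters[0].psi + 45) < 5

    def test_balanced_mixture_two_modes(self, rng):
        phi, psi = vm_samples(rng, [(-60, -45), (-150, 160)], 20, 5000)
        c = torsion.cluster_torus(phi, psi)
        assert c.n_modes == 2
        for cl in c.clusters:
            assert 0.4 <= cl.occupancy <= 0.6

    def test_wrap_straddling_mode_not_split(self, rng):
        phi, psi = vm_samples(rng, [(175, 0)], 20, 5000)
        c = torsion.cluster_torus(phi, psi)
        assert c.n_modes == 1

    def test_minor_mode_below_floor_discarded(self, rng):
        phi, psi = vm_samples(rng, [(-60, -45), (100, 100)], 20, 5000, weights=[0.98, 0.02])
        c = torsion.cluster_torus(phi, psi, min_occupancy=0.05)
        assert c.n_modes == 1

    def test_rotation_by_90_shifts_centers_only(self, rng):
        phi, psi = vm_samples(rng, [(-60, -45), (100, 120)], 20, 4000)
        c0 = torsion.cluster_torus(phi, psi)
        c1 = torsion.cluster_torus(wrap_degrees(phi + 90), wrap_degrees(psi + 90))
        assert c1.n_modes == c0.n_modes
        occ0 = sorted(round(c.occupancy, 3) for c in c0.clusters)
        occ1 = sorted(round(c.occupancy, 3) for c in c1.clusters)
        assert occ0 == occ1
        for a, b in zip(c0.clusters, c1.clusters):
            assert abs(wrap_degrees(b.phi - a.phi - 90)) < 5
            assert abs(wrap_degrees(b.psi - a.psi - 90)) < 5

    def test_frame_order_irrelevant(self, rng):
        phi, psi = vm_samples(rng, [(-60, -45), (60, 50)], 20, 3000)
        perm = rng.permutation(phi.size)
        c0 = torsion.cluster_torus(phi, psi)
        c1 = torsion.cluster_torus(phi[perm], psi[perm])
        assert c0.n_modes == c1.n_modes
        assert [round(c.occupancy, 6) for c in c0.clusters] == [
            round(c.occupancy, 6) for c in c1.clusters
        ]


class TestMultimodalAndShifts:
    def test_planted_hinges_recovered_exactly(self):
        hinges = (
            synth.HingePlant(23, (-70, -40), (60, 50), occupancy2=0.5),
            synth.HingePlant(40, (-100, 120), (-170, -160), occupancy2=0.4),
        )
        spec = synth.PlantSpec(n_residues=120, state="apo", hinge_residues=hinges, seed=8)
        traj, _, _ = synth.generate_trajectory(spec, 800)
        cl = torsion.cluster_all_residues(torsion.compute_dihedrals(traj))
        assert torsion.multimodal_residues(cl) == {23, 40}

    def test_single_tight_mode_residue_excluded(self, rng):
        # an A191-like residue: one tight cluster -> not multimodal
        phi, psi = vm_samples(rng, [(-65, -40)], 40, 2000)
        c = torsion.cluster_torus(phi, psi)
        assert torsion.multimodal_residues({191: c}) == set()

    def test_identical_states_not_shifted(self, rng):
        phi, psi = vm_samples(rng, [(-60, -45), (60, 50)], 20, 3000)
        c = torsion.cluster_torus(phi, psi)
        calls = torsion.compare_states({1: c}, {1: c})
        assert not calls[1].shifted

    def test_occupancy_swap_is_shifted(self, rng):
        centers = [(-60, -45), (60, 50)]
        pa, sa = vm_samples(rng, centers, 20, 4000, weights=[0.9, 0.1])
        pb, sb = vm_samples(rng, centers, 20, 4000, weights=[0.1, 0.9])
        ca = torsion.cluster_torus(pa, sa)
        cb = torsion.cluster_torus(pb, sb)
        calls = torsion.compare_states({1: ca}, {1: cb})
        assert calls[1].shifted
        assert calls[1].criterion == "occupancy_delta"

    def test_extra_mode_is_unmatched_shift(self, rng):
        pa, sa = vm_samples(rng, [(-60, -45)], 20, 4000)
        pb, sb = vm_samples(rng, [(-60, -45), (120, 120)], 20, 4000)
        ca = torsion.cluster_torus(pa, sa)
        cb = torsion.cluster_torus(pb, sb)
        calls = torsion.compare_states({1: ca}, {1: cb})
        assert calls[1].shifted
        assert calls[1].criterion == "unmatched_cluster"

    def test_residue_missing_in_one_state_raises(self, rng):
        phi, psi = vm_samples(rng, [(-60, -45)], 20, 1000)
        c = torsion.cluster_torus(phi, psi)
        with pytest.raises(KeyError):
            torsion.compare_states({1: c, 2: c}, {1: c})
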