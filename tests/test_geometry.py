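import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hingescan import synth
from hingescan.geometry import (
    apply_transform,
    classify_openness,
    helix_axis,
    helix_bend_angle,
    interhelical_angle,
    openness_series,
    rmsd_series,
    superpose,
)
from hingescan.io import SubdomainMap, Trajectory, ca_indices
from hingescan.studies import make_ideal_helix_ca
from tests.conftest import make_traj_from_coords


class TestSuperpose:
    def test_identity_on_self(self, rng):
        x = rng.normal(size=(20, 3))
        R, t, rmsd = superpose(x, x)
        assert rmsd < 1e-7
        np.testing.assert_allclose(R, np.eye(3), atol=1e-7)

    def test_recovers_constructed_transform(self, rng):
        x = rng.normal(size=(30, 3))
        R0 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = x @ R0.T + np.array([5.0, 0.0, 0.0])
        R, t, rmsd = superpose(moved, x)
        assert rmsd < 1e-9
        np.testing.assert_allclose(R @ R0, np.eye(3), atol=1e-9)
        assert np.isclose(np.linalg.det(R), 1.0)

    def test_matches_quaternion_grid_oracle(self, rng):
        """The closed-form fit is within 10% of the best RMSD over a dense
        random rotation grid (383 atoms, 0.1 A noise)."""
        x = rng.normal(size=(383, 3)) * 10
        y = x + rng.normal(scale=0.1, size=x.shape)
        _, _, fitted = superpose(y, x)
        xc, yc = x - x.mean(0), y - y.mean(0)
        grid = Rotation.random(3000, random_state=7)
        best = min(
            np.sqrt(np.mean(np.sum((yc @ g.as_matrix().T - xc) ** 2, axis=1)))
            for g in grid
        )
        assert fitted <= best * 1.10
        assert fitted <= best + 1e-12  # closed form can only be better

    def test_too_few_or_collinear_atoms(self):
        with pytest.raises(ValueError, match="3 fit atoms"):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(ValueError, match="collinear"):
            superpose(line, line)

    def test_rmsd_invariant_to_rigid_premotion(self, rng):
        x = rng.normal(size=(40, 3))
        y = x + rng.normal(scale=0.3, size=x.shape)
        _, _, r1 = superpose(y, x)
        g = Rotation.random(1, random_state=0)[0].as_matrix()
        _, _, r2 = superpose(y @ g.T + 7.0, x)
        assert np.isclose(r1, r2, atol=1e-9)


class TestRmsdSeries:
    def test_identical_frames_zero(self, rng):
        coords = np.tile(rng.normal(size=(30, 3)), (5, 1, 1))
        traj = make_traj_from_coords(coords)
        out = rmsd_series(traj, coords[0], np.arange(30))
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_jittered_ensemble_has_spread(self, small_apo_ensemble):
        traj, _, _ = small_apo_ensemble
        ca = ca_indices(traj.topology)
        out = rmsd_series(traj, traj.frames[0], ca)
        assert out.std() > 0

    def test_unit_displacement_reported_exactly(self, rng):
        """Displace a report subset by 1 A along +x while fitting on a fixed
        disjoint subset: reported RMSD is exactly 1.0."""
        base = rng.normal(size=(60, 3)) * 5
        moved = base.copy()
        moved[40:] += [1.0, 0.0, 0.0]
        traj = make_traj_from_coords(moved[None])
        out = rmsd_series(traj, base, fit_idx=np.arange(40), report_idx=np.arange(40, 60))
        assert np.isclose(out[0], 1.0, atol=1e-9)


class TestOpenness:
    def test_same_group_both_sides_gives_zero(self, small_apo_ensemble):
        traj, _, _ = small_apo_ensemble
        m = SubdomainMap({"II-B": [(1, 30)]})
        series = openness_series(traj, m, mobile_group="II-B", reference_groups=("II-B",))
        np.testing.assert_allclose(series.distances, 0.0, atol=1e-9)

    def test_missing_reference_group_rejected(self, small_apo_ensemble):
        traj, _, _ = small_apo_ensemble
        with pytest.raises(ValueError):
            openness_series(traj, SubdomainMap({"II-B": [(1, 30)]}), reference_groups=("I-A",))

    def test_constructed_com_distance(self):
        """Two rigid point clouds with COMs exactly 27.3 A apart."""
        n = 40
        phi, psi = synth.background_torsions(n)
        s = synth.generate_backbone(n, phi, psi)
        m = SubdomainMap({"II-B": [(21, 40)], "I-A": [(1, 20)]})
        ca = s.coords[1::3]
        com_a, com_b = ca[:20].mean(0), ca[20:].mean(0)
        v = com_b - com_a
        shift = (27.3 - np.linalg.norm(v)) * v / np.linalg.norm(v)
        coords = s.coords.copy()
        coords[60:] += shift
        traj = Trajectory(s, np.tile(coords, (3, 1, 1)))
        series = openness_series(traj, m, reference_groups=("I-A",))
        np.testing.assert_allclose(series.distances, 27.3, atol=1e-9)

    def test_synthetic_adp_recovery(self):
        spec = synth.PlantSpec(n_residues=120, state="ADP_Pi", seed=31)
        traj, _, _ = synth.generate_trajectory(spec, 500)
        series = openness_series(traj, spec.subdomain_map)
        assert 25.9 <= series.mean <= 26.3

    def test_invariant_to_global_rigid_motion(self, small_apo_ensemble):
        traj, _, _ = small_apo_ensemble
        smap = synth.scaled_subdomain_map(60)
        d1 = openness_series(traj, smap).distances
        g = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
        moved = Trajectory(traj.topology, traj.frames @ g.T + 100.0)
        d2 = openness_series(moved, smap).distances
        np.testing.assert_allclose(d1, d2, atol=1e-9)


class TestClassifyOpenness:
    @pytest.mark.parametrize(
        "mean,label",
        [(31.9, "open"), (27.3, "closed"), (26.1, "closed"), (29.5, "closed")],
    )
    def test_published_means_and_boundary(self, mean, label):
        assert classify_openness(mean) == label

    def test_monotone(self):
        values = [20.0, 25.0, 29.5, 29.6, 35.0]
        labels = [classify_openness(v) for v in values]
        assert labels == sorted(labels, key=lambda s: s == "open")

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            classify_openness(0.0)


class TestHelixGeometry:
    def test_ideal_helix_axis_along_z(self):
        h = make_ideal_helix_ca(9)
        ax = helix_axis(h, np.arange(9))
        assert np.degrees(np.arccos(abs(ax[2]))) < 2.0
        assert np.isclose(np.linalg.norm(ax), 1.0)

    def test_axis_equivariant_under_rotation(self):
        h = make_ideal_helix_ca(11)
        R = Rotation.from_euler("zyx", [25, -40, 60], degrees=True).as_matrix()
        ax0 = helix_axis(h, np.arange(11))
        ax1 = helix_axis(h @ R.T, np.arange(11))
        assert np.degrees(np.arccos(np.clip(abs(np.dot(ax1, R @ ax0)), 0, 1))) < 0.1

    def test_short_range_rejected(self):
        h = make_ideal_helix_ca(3)
        with pytest.raises(ValueError):
            helix_axis(h, np.arange(3))

    def test_interhelical_symmetric_and_bounded(self):
        ha = make_ideal_helix_ca(9)
        hb = make_ideal_helix_ca(11) @ Rotation.from_euler("x", 75, degrees=True).as_matrix().T
        frame = np.vstack([ha, hb + [12.0, 0, 0]])
        a = interhelical_angle(frame, np.arange(9), 9 + np.arange(11))
        b = interhelical_angle(frame, 9 + np.arange(11), np.arange(9))
        assert np.isclose(a, b)
        assert 0.0 <= a <= 90.0
        assert abs(a - 75.0) < 2.0

    def test_identical_ranges_zero_orthogonal_ninety(self):
        h = make_ideal_helix_ca(12)
        frame = np.vstack([h, h @ Rotation.from_euler("x", 90, degrees=True).as_matrix().T + [15.0, 0, 0]])
        assert interhelical_angle(frame, np.arange(12), np.arange(12)) < 1e-6
        assert abs(interhelical_angle(frame, np.arange(12), 12 + np.arange(12)) - 90.0) < 1.0

    def test_bend_straight_vs_planted_kink(self):
        h = make_ideal_helix_ca(20)
        angle, bent = helix_bend_angle(h, np.arange(20), 10)
        assert angle <= 5.0 and not bent
        R = Rotation.from_euler("x", 40, degrees=True).as_matrix()
        kinked = h.copy()
        kinked[10:] = (kinked[10:] - h[10]) @ R.T + h[10]
        angle, bent = helix_bend_angle(kinked, np.arange(20), 10)
        assert abs(angle - 40.0) < 2.0
        assert bent  # default threshold 30 degrees

    def test_pivot_too_close_to_end(self):
        h = make_ideal_helix_ca(10)
        with pytest.raises(ValueError, match="pivot"):
            helix_bend_angle(h, np.arange(10), 1)
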