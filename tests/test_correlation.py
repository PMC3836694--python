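from math import comb

import numpy as np
import pytest

from hingescan import synth
from hingescan.correlation import (
    PROLINE_SWITCH,
    dcc_matrix,
    dcc_matrix_bruteforce,
    distance_to_ligand,
    partner_query,
    rank_by_ligand,
    set_enrichment,
    tally_runs,
)
from hingescan.io import Structure, Trajectory, ca_indices


def toy_traj(rng, n_res=6, n_frames=200):
    topo = synth.backbone_topology(n_res)
    frames = np.tile(topo.coords, (n_frames, 1, 1))
    frames += rng.normal(scale=0.4, size=frames.shape)
    return Trajectory(topo, frames)


class TestDccMatrix:
    def test_unit_diagonal_symmetry_bounds(self, rng):
        traj = toy_traj(rng)
        cm = dcc_matrix(traj, ca_indices(traj.topology), superpose_first=False)
        C = cm.matrix
        np.testing.assert_allclose(np.diag(C), 1.0)
        np.testing.assert_allclose(C, C.T, atol=1e-12)
        assert C.min() >= -1.0 and C.max() <= 1.0

    def test_identical_and_negated_series(self, rng):
        traj = toy_traj(rng, n_res=4)
        ca = ca_indices(traj.topology)
        dev = traj.frames[:, ca[0]] - traj.frames[:, ca[0]].mean(axis=0)
        lig_same = traj.frames[:, ca[0]].copy()
        lig_neg = traj.frames[:, ca[0]].mean(axis=0) - dev
        cm = dcc_matrix(traj, ca, [lig_same, lig_neg], ["same", "neg"], superpose_first=False)
        assert np.isclose(cm.ligand_column("same")[0], 1.0)
        assert np.isclose(cm.ligand_column("neg")[0], -1.0)

    def test_matches_bruteforce_oracle(self, rng):
        traj = toy_traj(rng, n_res=6)
        ca = ca_indices(traj.topology)
        cm = dcc_matrix(traj, ca, superpose_first=False)
        dev = traj.frames[:, ca] - traj.frames[:, ca].mean(axis=0)
        brute = dcc_matrix_bruteforce(dev)
        np.testing.assert_allclose(cm.matrix, brute, atol=1e-10)

    def test_frame_permutation_invariant(self, rng):
        traj = toy_traj(rng)
        ca = ca_indices(traj.topology)
        c0 = dcc_matrix(traj, ca, superpose_first=False).matrix
        perm = rng.permutation(traj.n_frames)
        c1 = dcc_matrix(
            Trajectory(traj.topology, traj.frames[perm]), ca, superpose_first=False
        ).matrix
        np.testing.assert_allclose(c0, c1, atol=1e-12)

    def test_zero_variance_site_flagged(self, rng):
        traj = toy_traj(rng, n_res=4)
        lig = np.ones((traj.n_frames, 3)) * 5.0  # motionless pseudo-site
        with pytest.warns(UserWarning, match="zero variance"):
            cm = dcc_matrix(traj, ca_indices(traj.topology), [lig], ["dead"],
                            superpose_first=False)
        assert cm.zero_variance == ["dead"]
        np.testing.assert_allclose(cm.ligand_column("dead"), 0.0)


class TestRankByLigand:
    def test_anticorrelation_outranks_weaker_positive(self):
        C = np.eye(3)
        C[0, 2] = C[2, 0] = -0.9
        C[1, 2] = C[2, 1] = 0.8
        from hingescan.correlation import CorrelationMatrix

        cm = CorrelationMatrix(C, np.array([101, 102]), ["lig"], [])
        assert rank_by_ligand(cm, k=2) == [101, 102]

    def test_k_larger_than_n_returns_all(self, rng):
        traj = toy_traj(rng, n_res=5)
        lig = rng.normal(size=(traj.n_frames, 3))
        cm = dcc_matrix(traj, ca_indices(traj.topology), [lig], superpose_first=False)
        assert len(rank_by_ligand(cm, k=1000)) == 5

    def test_no_ligand_site_rejected(self, rng):
        traj = toy_traj(rng)
        cm = dcc_matrix(traj, ca_indices(traj.topology), superpose_first=False)
        with pytest.raises(ValueError, match="ligand"):
            rank_by_ligand(cm)

    def test_planted_coupling_ranks_first(self):
        spec = synth.PlantSpec(
            n_residues=120, state="ATP", openness_sd=0.0, noise_sd=0.2,
            background_kappa=np.inf, coupled_residues={77: 0.9}, seed=4,
        )
        traj, lig, _ = synth.generate_trajectory(spec, 300)
        cm = dcc_matrix(traj, ca_indices(traj.topology), [lig], ["nuc"])
        assert rank_by_ligand(cm, k=5)[0] == 77


class TestTally:
    def test_threshold_behaviour(self):
        lists = [[1, 2]] * 3 + [[2]] * 7
        t = tally_runs(lists, min_runs=4)
        assert t.count_of(1) == 3 and not (1 in t.significant_residues())
        assert t.count_of(2) == 10 and 2 in t.significant_residues()

    def test_duplicate_run_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            tally_runs([[1], [2]], run_labels=["a", "a"])

    def test_degenerate_parameters_mark_everything(self, rng):
        """k = N with min_runs = 1 makes every residue significant."""
        traj = toy_traj(rng, n_res=8)
        lig = rng.normal(size=(traj.n_frames, 3))
        cm = dcc_matrix(traj, ca_indices(traj.topology), [lig], superpose_first=False)
        top = rank_by_ligand(cm, k=8)
        t = tally_runs([top], min_runs=1)
        assert t.significant_residues() == set(range(1, 9))


class TestPartnerQuery:
    def test_self_excluded_and_mutual_top(self, rng):
        topo = synth.backbone_topology(3)
        frames = np.tile(topo.coords, (100, 1, 1))
        drive = rng.normal(size=(100, 3))
        frames[:, 1] += drive  # CA res 1
        frames[:, 4] += drive  # CA res 2 moves identically
        frames[:, 7] += rng.normal(size=(100, 3))
        traj = Trajectory(topo, frames)
        cm = dcc_matrix(traj, ca_indices(traj.topology), superpose_first=False)
        partners = partner_query(cm, 1, k=2)
        assert 1 not in partners
        assert partners[0] == 2
        assert np.isclose(abs(cm.residue_row(1)[1]), 1.0)

    def test_unknown_residue(self, rng):
        traj = toy_traj(rng)
        cm = dcc_matrix(traj, ca_indices(traj.topology), superpose_first=False)
        with pytest.raises(KeyError):
            partner_query(cm, 999)

    def test_shared_driver_puts_both_in_top_list(self):
        """Residues sharing a hinge residue's driving motion (here: the
        chain-propagated torsional fluctuations around residue 70) appear in
        its top-60 partner list."""
        spec = synth.PlantSpec(n_residues=120, state="ATP", seed=6)
        traj, _, _ = synth.generate_trajectory(spec, 300)
        cm = dcc_matrix(traj, ca_indices(traj.topology))
        partners = partner_query(cm, 70, k=60)
        assert 69 in partners and 71 in partners


class TestEnrichment:
    def test_full_overlap_matches_closed_form(self):
        top60 = list(range(1, 61))
        ref = set(range(10, 18))  # 8 residues all inside the list
        overlap, p = set_enrichment(top60, ref, 383)
        assert overlap == 8
        expected = comb(60, 8) * comb(323, 0) / comb(383, 8)
        assert p == pytest.approx(expected, rel=1e-12)

    def test_disjoint_gives_p_one(self):
        overlap, p = set_enrichment([1, 2, 3], {50, 60}, 383)
        assert overlap == 0 and p == 1.0

    def test_default_reference_set(self):
        assert PROLINE_SWITCH == {70, 71, 143, 144, 145, 146, 151, 171}

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            set_enrichment([1], set(), 100)


class TestDistanceToLigand:
    def make_structure(self, extra):
        names = ["CA", "CA", "PG"]
        return Structure(
            atom_names=names,
            elements=["C", "C", "P"],
            res_numbers=np.array([1, 2, 500]),
            res_names=["GLY", "GLY", "ATP"],
            chain_ids=["A", "A", "A"],
            coords=np.array([[0.0, 0, 0], extra, [3.0, 0, 0]]),
        )

    def test_near_flag_strict_boundary(self):
        s = self.make_structure([11.0, 0.0, 0.0])
        df = distance_to_ligand(s, np.array([2]))
        d = {int(r.residue): (r.min_distance, r.near) for r in df.itertuples()}
        assert d[1] == (3.0, True)
        assert d[2][0] == pytest.approx(8.0)
        assert not d[2][1]  # exactly 8.0 A is not near

    def test_matches_bruteforce_scan(self, rng):
        n = 30
        coords = rng.normal(size=(n, 3)) * 10
        s = Structure(
            atom_names=["CA"] * n,
            elements=["C"] * n,
            res_numbers=np.arange(1, n + 1),
            res_names=["GLY"] * n,
            chain_ids=["A"] * n,
            coords=coords,
        )
        lig_idx = np.array([n - 1])
        df = distance_to_ligand(s, lig_idx)
        for row in df.itertuples():
            expect = min(
                float(np.linalg.norm(coords[i] - coords[n - 1]))
                for i in np.nonzero(s.res_numbers == row.residue)[0]
            )
            assert row.min_distance == pytest.approx(expect, abs=1e-9)

    def test_no_ligand_atoms_rejected(self, rng):
        s = self.make_structure([1.0, 0, 0])
        with pytest.raises(ValueError):
            distance_to_ligand(s, np.array([], dtype=int))
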