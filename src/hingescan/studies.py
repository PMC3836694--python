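"""Self-contained validation studies on planted synthetic ground truth.

Each study generates its own data with the package's generator, runs the
relevant analysis stages, and measures recovery of the planted truth. They
are used both by the test suite and by ``scripts/acceptance.py``. Problem
sizes (frames, runs, seeds) are the package's standing study conditions and
are reported back in every result dict.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from . import synth, torsion
from .conservation import flag_conserved, profile_from_table
from .correlation import dcc_matrix, dcc_matrix_bruteforce, rank_by_ligand, tally_runs
from .data.dnak import DNAK_HINGE_CONSERVATION, all_multimodal
from .ed import compute_ed
from .geometry import classify_openness, interhelical_angle, openness_series
from .io import Trajectory, ca_indices

# -- standing study conditions ------------------------------------------------

# hinge-recovery ensemble: 120-residue chain, three planted hinges with mode
# separations >= 60 degrees on the torus, kappa = 20; two hinges swap mode
# occupancy between the ATP and ADP+Pi states (delta = 0.6)
HINGE_PLANTS = (
    synth.HingePlant(23, (-70.0, -40.0), (60.0, 50.0), occupancy2=0.5),
    synth.HingePlant(
        70, (-70.0, -40.0), (60.0, 50.0),
        occupancy2={"apo": 0.2, "ATP": 0.2, "ADP_Pi": 0.8},
    ),
    synth.HingePlant(
        71, (-100.0, 120.0), (-170.0, -160.0),
        occupancy2={"apo": 0.8, "ATP": 0.8, "ADP_Pi": 0.2},
    ),
)
HINGE_SET = frozenset(h.residue for h in HINGE_PLANTS)
SHIFTED_SET = frozenset({70, 71})

# coupling-recovery ensemble: DnaK-length chain, torsionally quiescent so the
# only planted signal is the ligand coupling over i.i.d. jitter
COUPLED_WEIGHTS = {
    37: 0.9, 60: 0.7, 145: 0.8, 200: 0.95, 223: 0.7,
    228: 0.85, 260: 0.75, 300: 0.9, 340: 0.7, 370: 0.8,
}


def make_ideal_helix_ca(n_residues: int, rise: float = 1.5, radius: float = 2.3,
                        twist_deg: float = 100.0) -> np.ndarray:
    """CA coordinates of an ideal alpha-helix along +z."""
    t = np.radians(twist_deg) * np.arange(n_residues)
    return np.column_stack([radius * np.cos(t), radius * np.sin(t), rise * np.arange(n_residues)])


def crossed_helix_study(crossing_angle: float = 75.0) -> dict:
    """Recover a planted crossing angle from a synthetic two-helix frame.

    This is a synthetic stand-in exercising the helix-axis machinery on a
    constructed pair of ideal 9- and 11-residue helices whose principal axes
    cross at a known angle; it is not a measurement on a real structure.
    """
    ha = make_ideal_helix_ca(9)
    hb = make_ideal_helix_ca(11)
    R = Rotation.from_euler("x", crossing_angle, degrees=True).as_matrix()
    hb = hb @ R.T + np.array([10.0, 0.0, 0.0])
    frame = np.vstack([ha, hb])
    angle = interhelical_angle(frame, np.arange(9), 9 + np.arange(11))
    return {"planted_deg": crossing_angle, "recovered_deg": angle, "n": 9 + 11}


def hinge_recovery_study(
    seed: int,
    n_seeds: int = 20,
    n_residues: int = 120,
    n_runs: int = 5,
    n_frames: int = 300,
) -> dict:
    """Sensitivity / false-positive rate of multimodal and state-shift calls.

    Per replicate: three state ensembles (n_runs x n_frames each) with the
    standing hinge plants; multimodality is the union over states, shifts
    compare the ADP+Pi clustering against apo and ATP.
    """
    tp = fp = pos = neg = 0
    s_tp = s_fp = s_pos = s_neg = 0
    for i in range(n_seeds):
        base = seed + 10_000 * i
        clusterings = {}
        for j, state in enumerate(synth.STATES):
            spec = synth.PlantSpec(
                n_residues=n_residues,
                state=state,
                hinge_residues=HINGE_PLANTS,
                seed=base + 1000 * j,
            )
            runs, _ = synth.generate_ensemble(spec, n_runs, n_frames)
            frames = np.concatenate([t.frames for t, _ in runs], axis=0)
            series = torsion.compute_dihedrals(Trajectory(runs[0][0].topology, frames))
            clusterings[state] = torsion.cluster_all_residues(series)
        multimodal = set()
        for state in synth.STATES:
            multimodal |= torsion.multimodal_residues(clusterings[state])
        clustered = set(clusterings["apo"]) & set(clusterings["ATP"]) & set(clusterings["ADP_Pi"])
        tp += len(multimodal & HINGE_SET)
        pos += len(HINGE_SET)
        fp += len(multimodal - HINGE_SET)
        neg += len(clustered - HINGE_SET)
        shifted = set()
        for other in ("apo", "ATP"):
            common = set(clusterings[other]) & set(clusterings["ADP_Pi"])
            calls = torsion.compare_states(
                {r: clusterings[other][r] for r in common},
                {r: clusterings["ADP_Pi"][r] for r in common},
            )
            shifted |= {r for r, c in calls.items() if c.shifted}
        s_tp += len(shifted & SHIFTED_SET)
        s_pos += len(SHIFTED_SET)
        s_fp += len(shifted - SHIFTED_SET)
        s_neg += len(clustered - SHIFTED_SET)
    return {
        "sensitivity": tp / pos,
        "fpr": fp / neg,
        "shift_sensitivity": s_tp / s_pos,
        "shift_fpr": s_fp / s_neg,
        "n_seeds": n_seeds,
        "n_frames_per_state": n_runs * n_frames,
    }


def coupling_recovery_study(
    seed: int,
    n_replicates: int = 20,
    n_residues: int = 383,
    n_runs: int = 10,
    n_frames: int = 200,
    top_k: int = 60,
    min_runs: int = 4,
) -> dict:
    """Recovery of planted ligand-coupled residues by the top-k tally.

    The chain is torsionally quiescent (kappa = inf, openness_sd = 0) so
    CA displacements are i.i.d. jitter and the ligand coupling is the only
    planted correlation channel.
    """
    coupled = set(COUPLED_WEIGHTS)
    tp = fp = 0
    for i in range(n_replicates):
        spec = synth.PlantSpec(
            n_residues=n_residues,
            state="ATP",
            openness_sd=0.0,
            noise_sd=0.3,
            background_kappa=np.inf,
            coupled_residues=COUPLED_WEIGHTS,
            seed=seed + 10_000 * i,
        )
        runs, _ = synth.generate_ensemble(spec, n_runs, n_frames)
        tops = []
        for traj, lig in runs:
            cm = dcc_matrix(traj, ca_indices(traj.topology), [lig], ["nucleotide"])
            tops.append(rank_by_ligand(cm, top_k))
        sig = tally_runs(tops, min_runs=min_runs).significant_residues()
        tp += len(sig & coupled)
        fp += len(sig - coupled)
    return {
        "sensitivity": tp / (n_replicates * len(coupled)),
        "fpr": fp / (n_replicates * (n_residues - len(coupled))),
        "n_replicates": n_replicates,
        "n_runs": n_runs,
    }


def openness_recovery_study(seed: int, n_frames: int = 500) -> dict:
    """Recovered per-state openness means vs the planted parameters.

    The tolerance for each state is 2 * openness_sd / sqrt(n_frames) (two
    standard errors of the sample mean of the planted normal draw).
    """
    out = {"n_frames": n_frames}
    for j, state in enumerate(synth.STATES):
        spec = synth.PlantSpec(n_residues=120, state=state, seed=seed + 1000 * j)
        traj, _, truth = synth.generate_trajectory(spec, n_frames)
        series = openness_series(traj, spec.subdomain_map)
        mean_t, sd_t = truth.openness[state]
        out[state] = {
            "planted_mean": mean_t,
            "recovered_mean": series.mean,
            "recovered_sd": series.sd,
            "tolerance": 2.0 * sd_t / np.sqrt(n_frames),
            "label": series.label,
        }
    return out


def oracle_checks(seed: int) -> dict:
    """Cross-checks against independent oracles: DCC double loop, covariance
    trace conservation, closed-form hypergeometric enrichment."""
    from math import comb

    from .correlation import set_enrichment

    rng = np.random.default_rng(seed)
    # DCC vectorized vs brute force on random deviations
    dev = rng.normal(size=(200, 6, 3))
    dev -= dev.mean(axis=0)
    brute = dcc_matrix_bruteforce(dev)
    num = np.einsum("fid,fjd->ij", dev, dev)
    var = np.einsum("fid,fid->i", dev, dev)
    fast = num / np.sqrt(np.outer(var, var))
    dcc_diff = float(np.abs(fast - brute).max())
    # ED eigenvalue sum vs covariance trace on a random 10-atom ensemble
    frames = rng.normal(scale=0.5, size=(200, 10, 3)) + rng.normal(size=(1, 10, 3)) * 8
    # a 10-residue backbone topology carries 30 atoms; give every atom of a
    # residue that residue's random site coordinate and analyze the CAs
    traj = Trajectory(synth.backbone_topology(10), np.repeat(frames, 3, axis=1))
    ca = np.arange(1, 30, 3)
    res = compute_ed(traj, ca, refit=False)
    trace = float(np.trace(res.covariance))
    ed_rel = abs(float(res.eigenvalues.sum()) - trace) / trace
    # hypergeometric: all 8 reference residues inside a 60-long list, N = 383
    overlap, p = set_enrichment(list(range(1, 61)), set(range(1, 9)), 383)
    p_exact = comb(60, 8) * comb(383 - 60, 0) / comb(383, 8)
    return {
        "dcc_oracle_max_abs_diff": dcc_diff,
        "ed_eigsum_trace_rel_err": ed_rel,
        "enrichment_overlap": overlap,
        "enrichment_p": p,
        "enrichment_p_exact": p_exact,
        "enrichment_rel_err": abs(p - p_exact) / p_exact,
    }


def roundtrip_checks(seed: int, tmpdir) -> dict:
    """Torsion -> backbone -> torsion and PDB write -> read round trips."""
    from pathlib import Path

    from .io import read_trajectory, write_trajectory

    rng = np.random.default_rng(seed)
    n = 383
    phi = rng.uniform(-180.0, 180.0, n)
    psi = rng.uniform(-180.0, 180.0, n)
    s = synth.generate_backbone(n, phi, psi)
    traj = Trajectory(s, s.coords[None, :, :])
    series = torsion.compute_dihedrals(traj)
    phi_err = float(np.nanmax(np.abs(
        ((series.phi[0, 1:] - phi[1:]) + 180.0) % 360.0 - 180.0)))
    psi_err = float(np.nanmax(np.abs(
        ((series.psi[0, :-1] - psi[:-1]) + 180.0) % 360.0 - 180.0)))
    # PDB round trip at fixed-width precision
    path = Path(tmpdir) / "roundtrip.pdb"
    multi = Trajectory(s, np.stack([s.coords, s.coords + rng.normal(size=s.coords.shape)]))
    write_trajectory(multi, path)
    back = read_trajectory(path)
    pdb_err = float(np.abs(back.frames - multi.frames).max())
    return {
        "torsion_roundtrip_max_deg": max(phi_err, psi_err),
        "pdb_roundtrip_max_A": pdb_err,
        "n_residues": n,
    }


def conservation_filter_study() -> dict:
    """Apply both conservation rules to the published hinge-region table and
    intersect with the published multimodal list (candidate arithmetic)."""
    profile = profile_from_table(DNAK_HINGE_CONSERVATION)
    ident = flag_conserved(profile, 90.0, ("bacteria", "animals"), mode="identity")
    comb_ = flag_conserved(profile, 90.0, ("bacteria", "animals"), mode="combined")
    mm = all_multimodal()
    return {
        "identity_set": sorted(ident),
        "combined_set": sorted(comb_),
        "identity_candidates": sorted(ident & mm),
        "combined_candidates": sorted(comb_ & mm),
    }


def openness_classification_of_published_means() -> dict:
    """Open/closed labels of the published per-state ensemble means."""
    from .data.dnak import DNAK_OPENNESS_MEANS

    return {s: classify_openness(m) for s, m in DNAK_OPENNESS_MEANS.items()}
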