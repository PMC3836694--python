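"""Synthetic trajectories, ligand pseudo-particles and alignments with
planted, recoverable ground truth.

The generator emulates the statistical structure the analysis stages assume
for an Hsp70/DnaK-like nucleotide-binding domain:

* three nucleotide states (apo / ATP / ADP+Pi) whose subdomain II-B openness
  (COM distance to the remaining subdomains) is drawn per frame from a
  state-specific normal distribution,
* a minority of "hinge" residues whose (phi, psi) pair is drawn from a
  two-mode von Mises mixture with state-dependent mode occupancies,
* a nucleotide pseudo-particle whose fluctuations are a weighted sum of
  chosen residues' CA displacements plus isotropic noise,
* alignments with prescribed per-column identity / conservative-substitution
  percentages.

There is no physics here: no force field, no solvent, no side chains. The
backbone is rebuilt each frame from internal coordinates (ideal bond lengths
and angles, omega fixed at 180 degrees), which is exactly what the torsion
analysis assumes and nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._vecmath import place_atom
from .io import Structure, SubdomainMap, Trajectory, make_subdomain_map

STATES = ("apo", "ATP", "ADP_Pi")

# per-state openness defaults (Angstrom): apo open, nucleotide-bound closed
DEFAULT_OPENNESS_MEAN = {"apo": 32.0, "ATP": 27.3, "ADP_Pi": 26.1}

# ideal backbone internal coordinates
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA = 180.0

_HELIX = (-57.0, -47.0)
_STRAND = (-120.0, 130.0)


def background_torsions(n_residues: int, block: int = 12) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic mean (phi, psi) per residue: alternating helix/strand
    blocks, giving a crumpled (non-collinear) chain."""
    phi = np.empty(n_residues)
    psi = np.empty(n_residues)
    for i in range(n_residues):
        mode = _HELIX if (i // block) % 2 == 0 else _STRAND
        phi[i], psi[i] = mode
    return phi, psi


def build_backbone(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Rebuild N/CA/C backbone coordinates from torsions, batched over frames.

    ``phi``/``psi`` have shape (F, n) degrees; phi[:, 0] and psi[:, -1] are
    ignored (undefined at chain termini). Returns (F, 3n, 3) with atom order
    N1, CA1, C1, N2, ...
    """
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    F, n = phi.shape
    if n < 3:
        raise ValueError("need at least 3 residues to build a backbone")
    coords = np.empty((F, 3 * n, 3))
    # first residue in the xy-plane
    coords[:, 0] = [0.0, 0.0, 0.0]
    coords[:, 1] = [BOND_N_CA, 0.0, 0.0]
    th = np.radians(ANGLE_N_CA_C)
    coords[:, 2] = coords[:, 1] + BOND_CA_C * np.array([-np.cos(th), np.sin(th), 0.0])
    for i in range(n - 1):
        ni, cai, ci = 3 * i, 3 * i + 1, 3 * i + 2
        n_next = place_atom(
            coords[:, ni], coords[:, cai], coords[:, ci],
            BOND_C_N, ANGLE_CA_C_N, psi[:, i],
        )
        ca_next = place_atom(
            coords[:, cai], coords[:, ci], n_next,
            BOND_N_CA, ANGLE_C_N_CA, OMEGA,
        )
        c_next = place_atom(
            coords[:, ci], n_next, ca_next,
            BOND_CA_C, ANGLE_N_CA_C, phi[:, i + 1],
        )
        coords[:, ni + 3] = n_next
        coords[:, cai + 3] = ca_next
        coords[:, ci + 3] = c_next
    return coords


def backbone_topology(n_residues: int, res_name: str = "GLY", chain_id: str = "A") -> Structure:
    """N/CA/C-only topology for a synthetic chain."""
    names = ["N", "CA", "C"] * n_residues
    elements = ["N", "C", "C"] * n_residues
    res_numbers = np.repeat(np.arange(1, n_residues + 1), 3)
    coords0 = build_backbone(*[a[None, :] for a in background_torsions(n_residues)])[0]
    return Structure(
        atom_names=names,
        elements=elements,
        res_numbers=res_numbers,
        res_names=[res_name] * (3 * n_residues),
        chain_ids=[chain_id] * (3 * n_residues),
        coords=coords0,
    )


def generate_backbone(
    n_residues: int, phi: Sequence[float] | np.ndarray, psi: Sequence[float] | np.ndarray
) -> Structure:
    """Single structure built from per-residue (phi, psi); termini ignored."""
    if n_residues < 3:
        raise ValueError("n_residues must be >= 3")
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if phi.shape != (n_residues,) or psi.shape != (n_residues,):
        raise ValueError("phi and psi must each have length n_residues")
    topo = backbone_topology(n_residues)
    topo.coords = build_backbone(phi[None, :], psi[None, :])[0]
    return topo


def scaled_subdomain_map(n_residues: int) -> SubdomainMap:
    """DnaK subdomain decomposition rescaled to a chain of ``n_residues``.

    Boundaries are the DnaK ones scaled by n/383; the tether gap just before
    II-B is preserved (those residues stay unassigned), mirroring the default
    map's 227-229 gap.
    """
    if n_residues == 383:
        return make_subdomain_map("dnak_default")
    if n_residues < 40:
        raise ValueError("scaled subdomain map needs at least 40 residues")
    r = lambda x: round(x * n_residues / 383)
    return SubdomainMap(
        {
            "I-A": ((1, r(36)), (r(110) + 1, r(180))),
            "I-B": ((r(36) + 1, r(110)),),
            "II-A": ((r(180) + 1, r(226)), (r(310) + 1, n_residues)),
            "II-B": ((r(229) + 1, r(310)),),
        }
    )


@dataclass
class HingePlant:
    """A residue planted with a two-mode (phi, psi) von Mises mixture.

    ``occupancy2`` is the probability of drawing mode 2, either a single
    float or a per-state mapping.
    """

    residue: int
    mode1: tuple[float, float]
    mode2: tuple[float, float]
    occupancy2: float | Mapping[str, float] = 0.5
    kappa: float = 20.0

    def occ2(self, state: str) -> float:
        if isinstance(self.occupancy2, Mapping):
            return float(self.occupancy2[state])
        return float(self.occupancy2)


@dataclass
class PlantSpec:
    """Everything the trajectory generator needs for one state's ensemble."""

    n_residues: int
    state: str = "apo"
    openness_mean: float | None = None  # Angstrom; default per state
    openness_sd: float = 1.0
    hinge_residues: tuple[HingePlant, ...] = ()
    coupled_residues: Mapping[int, float] = field(default_factory=dict)
    frozen_residues: tuple[int, ...] = ()
    noise_sd: float = 0.05  # Angstrom, i.i.d. jitter on every atom
    background_kappa: float = 20.0  # may be inf (exact mean torsions)
    subdomain_map: SubdomainMap | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {self.state!r}")
        if self.openness_mean is None:
            self.openness_mean = DEFAULT_OPENNESS_MEAN[self.state]
        if self.openness_mean <= 0:
            raise ValueError("openness_mean must be positive")
        if self.subdomain_map is None:
            self.subdomain_map = scaled_subdomain_map(self.n_residues)
        hinge_set = {h.residue for h in self.hinge_residues}
        if hinge_set & set(self.frozen_residues):
            raise ValueError("a hinge residue cannot also be frozen")
        for h in self.hinge_residues:
            if not 1 <= h.residue <= self.n_residues:
                raise ValueError(f"hinge residue {h.residue} outside chain")
            if h.kappa <= 0:
                raise ValueError("hinge kappa must be positive")
            for s in STATES:
                try:
                    occ = h.occ2(s)
                except KeyError:
                    continue
                if not 0.0 <= occ <= 1.0:
                    raise ValueError("mode-2 occupancy must be in [0, 1]")
        for r in self.coupled_residues:
            if not 1 <= r <= self.n_residues:
                raise ValueError(f"coupled residue {r} outside chain")


@dataclass
class GroundTruth:
    """Planted facts stored alongside every generated ensemble."""

    hinge_residues: frozenset[int]
    occupancy2: dict[int, dict[str, float]]  # hinge residue -> state -> occ(mode 2)
    coupled: dict[int, float]  # residue -> coupling weight
    openness: dict[str, tuple[float, float]]  # state -> (mean, sd)
    n_residues: int

    def shifted_residues(self, state_a: str, state_b: str, delta_occ: float = 0.3) -> set[int]:
        """Hinges whose mode-2 occupancy differs by >= delta between states."""
        out = set()
        for r, occ in self.occupancy2.items():
            if state_a in occ and state_b in occ:
                if abs(occ[state_a] - occ[state_b]) >= delta_occ:
                    out.add(r)
        return out

    def coupled_residues(self, min_weight: float = 0.7) -> set[int]:
        return {r for r, w in self.coupled.items() if w >= min_weight}

    def to_dict(self) -> dict:
        return {
            "hinge_residues": sorted(self.hinge_residues),
            "occupancy2": {str(r): occ for r, occ in self.occupancy2.items()},
            "coupled": {str(r): w for r, w in self.coupled.items()},
            "openness": {s: list(v) for s, v in self.openness.items()},
            "n_residues": self.n_residues,
        }


def ground_truth_for(spec: PlantSpec) -> GroundTruth:
    occ = {}
    for h in spec.hinge_residues:
        occ[h.residue] = {
            s: h.occ2(s)
            for s in STATES
            if not isinstance(h.occupancy2, Mapping) or s in h.occupancy2
        }
    return GroundTruth(
        hinge_residues=frozenset(h.residue for h in spec.hinge_residues),
        occupancy2=occ,
        coupled=dict(spec.coupled_residues),
        openness={spec.state: (float(spec.openness_mean), float(spec.openness_sd))},
        n_residues=spec.n_residues,
    )


def _sample_torsions(spec: PlantSpec, n_frames: int, rng: np.random.Generator):
    n = spec.n_residues
    mu_phi, mu_psi = background_torsions(n)
    mu_phi = np.tile(mu_phi, (n_frames, 1))
    mu_psi = np.tile(mu_psi, (n_frames, 1))
    if np.isinf(spec.background_kappa):
        phi, psi = mu_phi.copy(), mu_psi.copy()
    else:
        phi = np.degrees(rng.vonmises(np.radians(mu_phi), spec.background_kappa))
        psi = np.degrees(rng.vonmises(np.radians(mu_psi), spec.background_kappa))
    for r in spec.frozen_residues:
        phi[:, r - 1] = mu_phi[:, r - 1]
        psi[:, r - 1] = mu_psi[:, r - 1]
    for h in spec.hinge_residues:
        pick2 = rng.random(n_frames) < h.occ2(spec.state)
        hp = np.where(pick2, h.mode2[0], h.mode1[0])
        hs = np.where(pick2, h.mode2[1], h.mode1[1])
        if np.isinf(h.kappa):
            phi[:, h.residue - 1] = hp
            psi[:, h.residue - 1] = hs
        else:
            phi[:, h.residue - 1] = np.degrees(rng.vonmises(np.radians(hp), h.kappa))
            psi[:, h.residue - 1] = np.degrees(rng.vonmises(np.radians(hs), h.kappa))
    return phi, psi


def generate_trajectory(
    spec: PlantSpec, n_frames: int
) -> tuple[Trajectory, np.ndarray, GroundTruth]:
    """One trajectory plus its ligand pseudo-particle series and ground truth.

    Per frame: torsions are sampled (hinges from their two-mode mixture,
    everything else from a single von Mises around the background mean), the
    backbone is rebuilt, the II-B block is rigidly translated along the line
    joining the group centers of mass so the II-B <-> rest CA COM distance is
    Normal(openness_mean, openness_sd), i.i.d. jitter is added to every atom,
    and the ligand series is the coupling-weighted sum of CA displacements of
    the coupled residues plus isotropic noise. Reproducible under the seed.
    """
    if n_frames < 10:
        raise ValueError("n_frames must be >= 10")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    phi, psi = _sample_torsions(spec, n_frames, rng)
    coords = build_backbone(phi, psi)

    smap = spec.subdomain_map
    iib = smap.residues("II-B")
    rest = smap.residues("I-A", "I-B", "II-A")
    ca_of = lambda residues: np.array([3 * (r - 1) + 1 for r in residues])
    iib_atoms = np.concatenate([[3 * (r - 1), 3 * (r - 1) + 1, 3 * (r - 1) + 2] for r in iib])
    com_iib = coords[:, ca_of(iib)].mean(axis=1)
    com_rest = coords[:, ca_of(rest)].mean(axis=1)
    v = com_iib - com_rest
    d0 = np.linalg.norm(v, axis=1)
    u = v / d0[:, None]
    target = (
        np.full(n_frames, spec.openness_mean)
        if spec.openness_sd == 0
        else rng.normal(spec.openness_mean, spec.openness_sd, n_frames)
    )
    coords[:, iib_atoms] += ((target - d0)[:, None] * u)[:, None, :]

    if spec.noise_sd > 0:
        coords += rng.normal(0.0, spec.noise_sd, coords.shape)

    ca_all = coords[:, 1::3]  # (F, n, 3)
    lig = np.zeros((n_frames, 3))
    if spec.coupled_residues:
        dev = ca_all - ca_all.mean(axis=0)
        for r, w in spec.coupled_residues.items():
            lig += w * dev[:, r - 1]
        base = ca_all[:, [r - 1 for r in spec.coupled_residues]].mean(axis=(0, 1))
    else:
        base = ca_all.mean(axis=(0, 1))
    lig += rng.normal(0.0, spec.noise_sd, (n_frames, 3)) if spec.noise_sd > 0 else 0.0
    lig += base

    topo = backbone_topology(n)
    topo.coords = coords[0].copy()
    traj = Trajectory(topo, coords, label=f"{spec.state}_seed{spec.seed}")
    return traj, lig, ground_truth_for(spec)


def generate_ensemble(
    spec: PlantSpec, n_runs: int, n_frames: int
) -> tuple[list[tuple[Trajectory, np.ndarray]], GroundTruth]:
    """Independent runs of one state; run k uses seed + k."""
    runs = []
    truth = ground_truth_for(spec)
    for k in range(n_runs):
        run_spec = PlantSpec(
            n_residues=spec.n_residues,
            state=spec.state,
            openness_mean=spec.openness_mean,
            openness_sd=spec.openness_sd,
            hinge_residues=spec.hinge_residues,
            coupled_residues=spec.coupled_residues,
            frozen_residues=spec.frozen_residues,
            noise_sd=spec.noise_sd,
            background_kappa=spec.background_kappa,
            subdomain_map=spec.subdomain_map,
            seed=spec.seed + k,
        )
        traj, lig, _ = generate_trajectory(run_spec, n_frames)
        traj.label = f"{spec.state}_run{k + 1}"
        runs.append((traj, lig))
    return runs, truth


# ---------------------------------------------------------------------------
# Alignment generation
# ---------------------------------------------------------------------------

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _blosum62():
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("BLOSUM62")


def conservative_letters(ref: str) -> list[str]:
    """Letters scoring > 0 against ``ref`` under BLOSUM62, excluding ref."""
    m = _blosum62()
    return [a for a in AA20 if a != ref and m[ref, a] > 0]


def generate_msa(
    group_sizes: Mapping[str, int],
    identity_pct: float | Sequence[float] | Mapping[str, Sequence[float]],
    conservative_pct: float | Sequence[float] | Mapping[str, Sequence[float]] = 0.0,
    reference: str | None = None,
    n_columns: int | None = None,
    seed: int = 0,
):
    """Aligned sequences with prescribed per-column, per-group conservation.

    For each column and group the number of identical and conservative rows
    is fixed exactly (rounded target percentage of the group size) and the
    rows holding them are chosen at random, so realized percentages match the
    targets to within rounding. Non-conservative cells draw from letters with
    BLOSUM62 score <= 0 (with a small fixed fraction of gaps). The reference
    sequence is row 1 and belongs to no group.

    Returns ``(alignment, truth)`` where ``alignment`` is a
    :class:`hingescan.conservation.LabeledAlignment` and ``truth`` a tidy
    DataFrame of realized percentages.
    """
    import pandas as pd

    from .conservation import LabeledAlignment

    rng = np.random.default_rng(seed)
    n_total = sum(group_sizes.values())
    if n_total < 2:
        raise ValueError("need at least 2 sequences")
    if reference is None:
        if n_columns is None:
            raise ValueError("give a reference sequence or n_columns")
        reference = "".join(rng.choice(list(AA20), n_columns))
    L = len(reference)

    def per_group(targets, name):
        if isinstance(targets, Mapping):
            return {g: np.broadcast_to(np.asarray(t, dtype=float), (L,)) for g, t in targets.items()}
        arr = np.broadcast_to(np.asarray(targets, dtype=float), (L,))
        return {g: arr for g in group_sizes}

    ident = per_group(identity_pct, "identity")
    consv = per_group(conservative_pct, "conservative")
    m = _blosum62()
    noncons_cache: dict[str, list[str]] = {}
    cons_cache: dict[str, list[str]] = {}

    rows = {g: [["?"] * L for _ in range(ng)] for g, ng in group_sizes.items()}
    truth_records = []
    for col in range(L):
        ref = reference[col]
        if ref not in cons_cache:
            cons_cache[ref] = conservative_letters(ref)
            noncons_cache[ref] = [a for a in AA20 if a != ref and m[ref, a] <= 0]
        for g, ng in group_sizes.items():
            ti, tc = float(ident[g][col]), float(consv[g][col])
            if ti < 0 or tc < 0 or ti + tc > 100.0:
                raise ValueError(
                    f"impossible targets at column {col + 1}: identity {ti}% + conservative {tc}%"
                )
            k_id = round(ti * ng / 100.0)
            k_cons = min(round(tc * ng / 100.0), ng - k_id)
            if k_cons > 0 and not cons_cache[ref]:
                raise ValueError(
                    f"no conservative letters exist for reference {ref!r} at column {col + 1}"
                )
            order = rng.permutation(ng)
            for j in order[:k_id]:
                rows[g][j][col] = ref
            for j in order[k_id : k_id + k_cons]:
                rows[g][j][col] = rng.choice(cons_cache[ref])
            for j in order[k_id + k_cons :]:
                if rng.random() < 0.1 or not noncons_cache[ref]:
                    rows[g][j][col] = "-"
                else:
                    rows[g][j][col] = rng.choice(noncons_cache[ref])
            truth_records.append(
                {
                    "column": col + 1,
                    "group": g,
                    "target_identity": ti,
                    "target_conservative": tc,
                    "realized_identity": 100.0 * k_id / ng,
                    "realized_conservative": 100.0 * k_cons / ng,
                }
            )

    ids = ["reference"]
    seqs = [reference]
    groups = {}
    for g, ng in group_sizes.items():
        for j in range(ng):
            sid = f"{g}_{j + 1}"
            ids.append(sid)
            seqs.append("".join(rows[g][j]))
            groups[sid] = g
    aln = LabeledAlignment(ids=ids, sequences=seqs, groups=groups)
    return aln, pd.DataFrame(truth_records)
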