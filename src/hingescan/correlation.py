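"""Dynamic cross-correlation (DCC) of residue motions, nucleotide-correlation
ranking and cross-run tallies, partner queries and set enrichment.

C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>) with dr the 3-vector
deviation of a site from its mean position after superposing every frame on
the run mean (CA fit). Ligand pseudo-sites (one 3-vector series per cofactor
entity) are appended as extra rows/columns. An anti-correlation of -1 counts
exactly as much as a correlation of +1 everywhere: ranking uses |C|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import hypergeom

from .ed import iterative_fit
from .io import Structure, Trajectory

# DnaK proline-switch residues, the standing enrichment reference set
PROLINE_SWITCH = frozenset({70, 71, 143, 144, 145, 146, 151, 171})


@dataclass
class CorrelationMatrix:
    matrix: np.ndarray  # (S, S), S = n_residues + n_ligand_sites
    residue_labels: np.ndarray  # (N,) residue numbers
    ligand_labels: list[str]
    zero_variance: list[str]  # labels of sites flagged with no motion

    @property
    def n_residues(self) -> int:
        return self.residue_labels.size

    def ligand_column(self, name: str) -> np.ndarray:
        j = self.n_residues + self.ligand_labels.index(name)
        return self.matrix[: self.n_residues, j]

    def residue_row(self, residue: int) -> np.ndarray:
        i = np.nonzero(self.residue_labels == residue)[0]
        if i.size == 0:
            raise KeyError(f"residue {residue} not in correlation matrix")
        return self.matrix[i[0], : self.n_residues]


def dcc_matrix(
    traj: Trajectory,
    ca_idx: np.ndarray,
    ligand_series: Sequence[np.ndarray] = (),
    ligand_labels: Sequence[str] | None = None,
    superpose_first: bool = True,
) -> CorrelationMatrix:
    """Normalized displacement cross-correlations of CA sites + ligand sites."""
    if traj.n_frames < 10:
        raise ValueError("need at least 10 frames")
    ca_idx = np.asarray(ca_idx)
    frames = traj.frames
    if superpose_first:
        frames, _ = iterative_fit(frames, ca_idx)
    sites = [frames[:, ca_idx]]  # (F, N, 3)
    labels = [str(int(r)) for r in traj.topology.res_numbers[ca_idx]]
    if ligand_labels is None:
        ligand_labels = [f"ligand{k + 1}" for k in range(len(ligand_series))]
    for s in ligand_series:
        s = np.asarray(s, dtype=float)
        if s.shape != (traj.n_frames, 3):
            raise ValueError("each ligand series must have shape (F, 3)")
        sites.append(s[:, None, :])
    X = np.concatenate(sites, axis=1)  # (F, S, 3)
    dev = X - X.mean(axis=0)
    num = np.einsum("fid,fjd->ij", dev, dev)
    var = np.einsum("fid,fid->i", dev, dev)
    zero = var <= 1e-300
    safe = np.where(zero, 1.0, var)
    C = num / np.sqrt(np.outer(safe, safe))
    all_labels = labels + list(ligand_labels)
    zero_labels = [all_labels[i] for i in np.nonzero(zero)[0]]
    if zero_labels:
        warnings.warn(f"sites with zero variance flagged: {zero_labels}")
        C[zero, :] = 0.0
        C[:, zero] = 0.0
    np.fill_diagonal(C, 1.0)
    C = np.clip(C, -1.0, 1.0)
    return CorrelationMatrix(
        matrix=C,
        residue_labels=traj.topology.res_numbers[ca_idx].astype(int),
        ligand_labels=list(ligand_labels),
        zero_variance=zero_labels,
    )


def dcc_matrix_bruteforce(dev: np.ndarray) -> np.ndarray:
    """Independent double-loop oracle on explicit deviations (F, S, 3)."""
    F, S, _ = dev.shape
    C = np.empty((S, S))
    for i in range(S):
        for j in range(S):
            num = sum(float(np.dot(dev[f, i], dev[f, j])) for f in range(F))
            vi = sum(float(np.dot(dev[f, i], dev[f, i])) for f in range(F))
            vj = sum(float(np.dot(dev[f, j], dev[f, j])) for f in range(F))
            C[i, j] = num / np.sqrt(vi * vj)
    return C


def rank_by_ligand(cm: CorrelationMatrix, k: int = 60) -> list[int]:
    """Residues ranked by max |correlation| over ligand sites; top k.

    Ties at the boundary break by ascending residue number (deterministic).
    """
    if not cm.ligand_labels:
        raise ValueError("correlation matrix has no ligand site")
    scores = np.max(
        np.abs(cm.matrix[: cm.n_residues, cm.n_residues :]), axis=1
    )
    order = sorted(range(cm.n_residues), key=lambda i: (-scores[i], cm.residue_labels[i]))
    return [int(cm.residue_labels[i]) for i in order[:k]]


@dataclass
class NucleotideTally:
    counts: pd.DataFrame  # columns: residue, count, significant
    n_runs: int
    min_runs: int

    def significant_residues(self) -> set[int]:
        return set(self.counts.loc[self.counts["significant"], "residue"].astype(int))

    def count_of(self, residue: int) -> int:
        row = self.counts.loc[self.counts["residue"] == residue, "count"]
        return int(row.iloc[0]) if len(row) else 0


def tally_runs(
    top_lists: Sequence[Sequence[int]],
    min_runs: int = 4,
    run_labels: Sequence[str] | None = None,
    universe: Sequence[int] | None = None,
) -> NucleotideTally:
    """Count, per residue, the runs whose top-k list contains it.

    Significant iff the count reaches ``min_runs``.
    """
    if len(top_lists) < 1:
        raise ValueError("need at least one run")
    if run_labels is not None and len(set(run_labels)) != len(run_labels):
        raise ValueError("duplicate run labels")
    counts: dict[int, int] = {}
    if universe is not None:
        counts = {int(r): 0 for r in universe}
    for lst in top_lists:
        for r in set(int(x) for x in lst):
            counts[r] = counts.get(r, 0) + 1
    df = pd.DataFrame(
        {
            "residue": sorted(counts),
            "count": [counts[r] for r in sorted(counts)],
        }
    )
    df["significant"] = df["count"] >= min_runs
    return NucleotideTally(counts=df, n_runs=len(top_lists), min_runs=min_runs)


def partner_query(cm: CorrelationMatrix, residue: int, k: int = 60) -> list[int]:
    """Top-k other residues by |C| with the query residue (self excluded)."""
    row = np.abs(cm.residue_row(residue))
    order = sorted(
        (i for i in range(cm.n_residues) if int(cm.residue_labels[i]) != residue),
        key=lambda i: (-row[i], cm.residue_labels[i]),
    )
    return [int(cm.residue_labels[i]) for i in order[:k]]


def set_enrichment(
    partner_list: Sequence[int], reference_set: set[int], universe_size: int
) -> tuple[int, float]:
    """Overlap and one-sided hypergeometric tail P(overlap >= observed).

    Universe of ``universe_size`` residues, ``len(partner_list)`` drawn,
    ``len(reference_set)`` marked.
    """
    if not reference_set:
        raise ValueError("reference set is empty")
    overlap = len(set(partner_list) & set(reference_set))
    p = float(
        hypergeom.sf(overlap - 1, universe_size, len(reference_set), len(set(partner_list)))
    )
    return overlap, min(p, 1.0)


def distance_to_ligand(
    structure: Structure,
    ligand_idx: np.ndarray,
    near_cutoff: float = 8.0,
) -> pd.DataFrame:
    """Per-residue minimum atom distance to the ligand atoms.

    ``near`` is strict: a residue exactly at the cutoff is not near.
    """
    ligand_idx = np.asarray(ligand_idx)
    if ligand_idx.size == 0:
        raise ValueError("no ligand atoms given")
    lig_xyz = structure.coords[ligand_idx]
    lig_set = set(int(i) for i in ligand_idx)
    rows = []
    for r in np.unique(structure.res_numbers):
        idx = [
            i
            for i in np.nonzero(structure.res_numbers == r)[0]
            if int(i) not in lig_set
        ]
        if not idx:
            continue
        d = float(cdist(structure.coords[idx], lig_xyz).min())
        rows.append({"residue": int(r), "min_distance": d, "near": d < near_cutoff})
    return pd.DataFrame(rows)
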