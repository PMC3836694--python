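"""Backbone torsion series, periodic Ramachandran densities, torus
clustering, multimodality and nucleotide-state shift calls.

phi(i) = dihedral(C'(i-1), N(i), CA(i), C'(i)) and
psi(i) = dihedral(N(i), CA(i), C'(i), N(i+1)), signed IUPAC convention in
[-180, 180). Chain-terminal residues carry NaN for the undefined angle.

Clustering is deterministic mode-seeking on the smoothed periodic (phi, psi)
density (10 degree bins, wrap-around Gaussian smoothing): local maxima under
the periodic 8-neighborhood seed the modes, maxima closer than
``merge_radius`` degrees (geodesic) are merged into the denser one, every
frame is assigned to the nearest surviving mode, and modes holding less than
``min_occupancy`` of the frames are discarded (their frames fall to the
nearest survivor). Cluster centers are the circular means of their assigned
frames. The method carries no prior on the number of clusters; its
resolution limit is the merge radius.

Dihedrals spanning a broken peptide bond (C-N distance above 2.5 A in a
frame, e.g. across a rigid-block seam of a synthetic trajectory) are masked
as undefined in that frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from ._vecmath import circular_mean_deg, dihedral, torus_distance, wrap_degrees
from .io import Trajectory

MIN_FRAMES = 50


@dataclass
class TorsionSeries:
    residues: np.ndarray  # (N,) residue numbers
    phi: np.ndarray  # (F, N) degrees, NaN where undefined
    psi: np.ndarray  # (F, N)

    def for_residue(self, residue: int) -> tuple[np.ndarray, np.ndarray]:
        j = np.nonzero(self.residues == residue)[0]
        if j.size == 0:
            raise KeyError(f"residue {residue} not in torsion series")
        return self.phi[:, j[0]], self.psi[:, j[0]]


def _backbone_index(traj: Trajectory):
    """Per-residue indices of N, CA, C atoms (NaN-safe: -1 when missing)."""
    topo = traj.topology
    residues = []
    seen = {}
    for i in range(topo.n_atoms):
        r = int(topo.res_numbers[i])
        if r not in seen:
            seen[r] = {"N": -1, "CA": -1, "C": -1}
            residues.append(r)
        name = topo.atom_names[i]
        if name in ("N", "CA", "C") and seen[r][name] == -1:
            seen[r][name] = i
    idx = np.array([[seen[r]["N"], seen[r]["CA"], seen[r]["C"]] for r in residues])
    return np.array(residues), idx


def _broken_pairs(X: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Boolean per consecutive residue pair: is the C(i)-N(i+1) bond broken?

    A peptide bond is stiff: its length barely fluctuates across frames and
    matches the other peptide bonds of the chain. A pair is flagged when its
    median length is far above the chain-typical bond length or when it
    fluctuates far more than is typical (a rigid-block seam stretches and
    compresses with the block motion). Both tests are relative to the chain's
    own statistics, so uniform scaling changes nothing.
    """
    n_pairs = idx.shape[0] - 1
    lengths = np.full((X.shape[0], n_pairs), np.nan)
    for j in range(n_pairs):
        c_j, n_next = idx[j, 2], idx[j + 1, 0]
        if c_j >= 0 and n_next >= 0:
            lengths[:, j] = np.linalg.norm(X[:, n_next] - X[:, c_j], axis=1)
    med = np.nanmedian(lengths, axis=0)
    sd = np.nanstd(lengths, axis=0)
    typical_len = np.nanmedian(med)
    typical_sd = np.nanmedian(sd)
    with np.errstate(invalid="ignore"):
        return (med > 1.5 * typical_len) | (
            sd > max(3.0 * typical_sd, 0.15 * typical_len)
        )


def compute_dihedrals(traj: Trajectory) -> TorsionSeries:
    """phi/psi time series for every residue of the trajectory.

    phi(i+1) and psi(i) both span the C(i)-N(i+1) peptide bond; where that
    bond is broken (chain break or rigid-block seam, see
    :func:`_broken_pairs`) the two angles are undefined and masked.
    """
    residues, idx = _backbone_index(traj)
    F, N = traj.n_frames, residues.size
    phi = np.full((F, N), np.nan)
    psi = np.full((F, N), np.nan)
    X = traj.frames
    broken = _broken_pairs(X, idx)
    missing = []
    for j in range(N):
        n_j, ca_j, c_j = idx[j]
        if min(n_j, ca_j, c_j) < 0:
            missing.append(int(residues[j]))
            continue
        if j > 0 and idx[j - 1, 2] >= 0 and not broken[j - 1]:
            phi[:, j] = dihedral(X[:, idx[j - 1, 2]], X[:, n_j], X[:, ca_j], X[:, c_j])
        if j < N - 1 and idx[j + 1, 0] >= 0 and not broken[j]:
            psi[:, j] = dihedral(X[:, n_j], X[:, ca_j], X[:, c_j], X[:, idx[j + 1, 0]])
    if missing:
        warnings.warn(f"residues with missing backbone atoms marked undefined: {missing}")
    # collinearity produces NaN from atan2(0,0)? guard: atan2(0,0)=0, but a
    # zero-length b2 raises in normalize; treat any non-finite as missing.
    phi[~np.isfinite(phi)] = np.nan
    psi[~np.isfinite(psi)] = np.nan
    return TorsionSeries(residues=residues, phi=phi, psi=psi)


def rama_density(
    phi: np.ndarray,
    psi: np.ndarray,
    bin_width: float = 10.0,
    sigma_bins: float = 1.0,
) -> np.ndarray:
    """Smoothed periodic (phi, psi) density grid; sums to 1.

    Smoothing wraps at +-180 degrees, so a mode straddling the boundary is
    continuous across it.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    ok = np.isfinite(phi) & np.isfinite(psi)
    if ok.sum() < MIN_FRAMES:
        raise ValueError(f"need at least {MIN_FRAMES} defined frames, got {ok.sum()}")
    nbins = int(round(360.0 / bin_width))
    edges = np.linspace(-180.0, 180.0, nbins + 1)
    h, _, _ = np.histogram2d(wrap_degrees(phi[ok]), wrap_degrees(psi[ok]), bins=(edges, edges))
    if sigma_bins > 0:
        h = ndimage.gaussian_filter(h, sigma=sigma_bins, mode="wrap")
    return h / h.sum()


@dataclass
class TorusCluster:
    phi: float  # cluster center, degrees
    psi: float
    occupancy: float
    n_frames: int


@dataclass
class TorusClustering:
    clusters: list[TorusCluster]
    n_frames: int
    min_occupancy: float
    assignments: np.ndarray | None = None  # per defined frame, cluster index

    @property
    def n_modes(self) -> int:
        return len(self.clusters)


def _persistent_maxima(density: np.ndarray, max_saddle_ratio: float) -> list[tuple[int, int]]:
    """Modes of a periodic 2-D density by topological persistence.

    Cells are swept from the highest density down, joining each cell to
    already-processed periodic 8-neighbors (union-find). When two components
    meet, the one with the lower peak dies at the saddle; it counts as a mode
    only if saddle/peak <= ``max_saddle_ratio`` (a real mode must rise well
    above the level at which it merges — shot-noise ripples on the shoulder
    of a blob die almost immediately and are discarded). The global maximum
    always survives. Peak cells are returned sorted by density descending.
    """
    nb0, nb1 = density.shape
    flat = density.ravel()
    order = sorted(range(flat.size), key=lambda k: (-flat[k], k))
    parent = {}
    peak = {}  # root -> (peak density, peak cell)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    kept: list[tuple[float, int]] = []
    for cell in order:
        if flat[cell] <= 0:
            break
        i, j = divmod(cell, nb1)
        roots = set()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                nc = ((i + di) % nb0) * nb1 + ((j + dj) % nb1)
                if nc in parent:
                    roots.add(find(nc))
        if not roots:
            parent[cell] = cell
            peak[cell] = (flat[cell], cell)
            continue
        best = max(roots, key=lambda r: peak[r][0])
        parent[cell] = best
        for r in roots:
            if r == best:
                continue
            dead_peak, dead_cell = peak[r]
            if flat[cell] / dead_peak <= max_saddle_ratio:
                kept.append((dead_peak, dead_cell))
            parent[r] = best
    # survivors (one per remaining root) always count
    for r in set(find(c) for c in parent):
        kept.append(peak[r])
    kept.sort(key=lambda t: (-t[0], t[1]))
    return [(c // nb1, c % nb1) for _, c in kept]


def cluster_torus(
    phi: np.ndarray,
    psi: np.ndarray,
    min_occupancy: float = 0.05,
    bin_width: float = 10.0,
    sigma_bins: float = 1.0,
    merge_radius: float = 30.0,
    max_saddle_ratio: float = 0.6,
) -> TorusClustering:
    """Mode-seeking clustering of one residue's (phi, psi) series.

    Persistent maxima of the smoothed periodic density seed the modes (a
    maximum only counts when the saddle at which it merges into a higher
    mode is at most ``max_saddle_ratio`` of its peak density); maxima within
    ``merge_radius`` degrees (geodesic, single linkage, denser maximum wins)
    are merged, frames go to the nearest surviving mode, modes under
    ``min_occupancy`` are dropped and their frames reassigned, and each
    cluster center is the circular mean of its frames.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    ok = np.isfinite(phi) & np.isfinite(psi)
    density = rama_density(phi, psi, bin_width=bin_width, sigma_bins=sigma_bins)
    maxima = _persistent_maxima(density, max_saddle_ratio)
    centers_deg = -180.0 + bin_width * (np.arange(density.shape[0]) + 0.5)
    peaks = [(centers_deg[i], centers_deg[j]) for i, j in maxima]  # density-desc order
    # single-linkage merge into the denser maximum
    keep: list[tuple[float, float]] = []
    for p in peaks:
        if all(torus_distance(p[0], p[1], q[0], q[1]) > merge_radius for q in keep):
            keep.append(p)
    if not keep:  # all mass in one flat cell pattern; fall back to densest cell
        i, j = np.unravel_index(int(np.argmax(density)), density.shape)
        keep = [(centers_deg[i], centers_deg[j])]
    pf, ps = wrap_degrees(phi[ok]), wrap_degrees(psi[ok])

    def assign(center_list):
        d = np.stack([torus_distance(pf, ps, cp, cq) for cp, cq in center_list], axis=1)
        return np.argmin(d, axis=1)

    assignment = assign(keep)
    surviving = [k for k in range(len(keep)) if np.mean(assignment == k) >= min_occupancy]
    if not surviving:
        surviving = [int(np.bincount(assignment).argmax())]
    keep = [keep[k] for k in surviving]
    assignment = assign(keep)
    clusters = []
    for k in range(len(keep)):
        members = assignment == k
        nk = int(members.sum())
        clusters.append(
            TorusCluster(
                phi=circular_mean_deg(pf[members]),
                psi=circular_mean_deg(ps[members]),
                occupancy=nk / pf.size,
                n_frames=nk,
            )
        )
    order = np.argsort([-c.occupancy for c in clusters], kind="stable")
    clusters = [clusters[i] for i in order]
    remap = {int(old): new for new, old in enumerate(order)}
    assignment = np.array([remap[int(a)] for a in assignment])
    return TorusClustering(
        clusters=clusters,
        n_frames=int(pf.size),
        min_occupancy=min_occupancy,
        assignments=assignment,
    )


def cluster_all_residues(
    series: TorsionSeries, min_occupancy: float = 0.05, **kwargs
) -> dict[int, TorusClustering]:
    """Torus clustering for every residue with enough defined frames."""
    out = {}
    for j, r in enumerate(series.residues):
        ok = np.isfinite(series.phi[:, j]) & np.isfinite(series.psi[:, j])
        if ok.sum() < MIN_FRAMES:
            continue
        out[int(r)] = cluster_torus(
            series.phi[:, j], series.psi[:, j], min_occupancy=min_occupancy, **kwargs
        )
    return out


def multimodal_residues(clusterings: Mapping[int, TorusClustering]) -> set[int]:
    """Residues whose torus clustering shows two or more modes."""
    return {r for r, c in clusterings.items() if c.n_modes >= 2}


@dataclass
class StateShiftCall:
    residue: int
    shifted: bool
    criterion: str  # "unmatched_cluster", "occupancy_delta", or ""
    matched: list[tuple[int, int, float, float, float]] = field(default_factory=list)
    unmatched_a: list[int] = field(default_factory=list)
    unmatched_b: list[int] = field(default_factory=list)


def compare_states(
    clusterings_a: Mapping[int, TorusClustering],
    clusterings_b: Mapping[int, TorusClustering],
    match_radius: float = 40.0,
    delta_occ: float = 0.3,
) -> dict[int, StateShiftCall]:
    """Greedy geodesic matching of per-residue cluster sets between states.

    A residue is shifted when a qualifying cluster of either state has no
    partner within ``match_radius`` degrees, or a matched pair's occupancy
    changes by at least ``delta_occ``.
    """
    only_a = set(clusterings_a) - set(clusterings_b)
    only_b = set(clusterings_b) - set(clusterings_a)
    if only_a or only_b:
        raise KeyError(
            f"residues present in one state only: {sorted(only_a | only_b)[:10]}"
        )
    calls: dict[int, StateShiftCall] = {}
    for r in sorted(clusterings_a):
        ca, cb = clusterings_a[r].clusters, clusterings_b[r].clusters
        pairs = sorted(
            (
                (torus_distance(ca[i].phi, ca[i].psi, cb[j].phi, cb[j].psi), i, j)
                for i in range(len(ca))
                for j in range(len(cb))
            )
        )
        used_a: set[int] = set()
        used_b: set[int] = set()
        matched = []
        for d, i, j in pairs:
            if d > match_radius:
                break
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            matched.append((i, j, float(d), ca[i].occupancy, cb[j].occupancy))
        unmatched_a = [i for i in range(len(ca)) if i not in used_a]
        unmatched_b = [j for j in range(len(cb)) if j not in used_b]
        criterion = ""
        if unmatched_a or unmatched_b:
            criterion = "unmatched_cluster"
        elif any(abs(oa - ob) >= delta_occ for _, _, _, oa, ob in matched):
            criterion = "occupancy_delta"
        calls[r] = StateShiftCall(
            residue=r,
            shifted=bool(criterion),
            criterion=criterion,
            matched=matched,
            unmatched_a=unmatched_a,
            unmatched_b=unmatched_b,
        )
    return calls
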