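"""Essential dynamics: covariance eigen-analysis of CA fluctuations.

Runs are concatenated and every frame is iteratively superposed onto the
ensemble mean (least-squares fit on the CA selection, repeated until the
mean moves less than a tolerance) before the 3N x 3N coordinate covariance
is formed. No mass weighting. Eigenvector signs are fixed so the largest-
magnitude component is positive, which makes mode projections reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import apply_transform, superpose
from .io import Trajectory


@dataclass
class EDResult:
    mean: np.ndarray  # (N, 3) mean CA structure after iterative fit
    covariance: np.ndarray  # (3N, 3N) Angstrom^2
    eigenvalues: np.ndarray  # descending, Angstrom^2
    eigenvectors: np.ndarray  # (3N, n_modes) columns, unit norm
    ca_idx: np.ndarray
    degenerate: bool = False  # True when the input had no motion

    @property
    def cumulative_fractions(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total <= 0:
            return np.zeros_like(self.eigenvalues)
        return np.cumsum(self.eigenvalues) / total


def iterative_fit(
    frames: np.ndarray, fit_idx: np.ndarray, tol: float = 1e-4, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Superpose every frame onto the running mean until the mean converges.

    Returns (fitted frames, mean over fit selection converged to < tol A).
    At least two passes are always performed.
    """
    frames = np.array(frames, dtype=float)
    mean = frames[0].copy()
    for it in range(max_iter):
        for f in range(frames.shape[0]):
            R, t, _ = superpose(frames[f], mean, fit_idx)
            frames[f] = apply_transform(frames[f], R, t)
        new_mean = frames.mean(axis=0)
        shift = float(np.abs(new_mean - mean).max())
        mean = new_mean
        if it >= 1 and shift < tol:
            break
    return frames, mean


def combine_runs(runs: list[Trajectory], fit_idx: np.ndarray) -> Trajectory:
    """Concatenate runs (identical topology required) and iteratively fit."""
    topo = runs[0].topology
    for r in runs[1:]:
        if (
            r.topology.n_atoms != topo.n_atoms
            or r.topology.atom_names != topo.atom_names
            or not np.array_equal(r.topology.res_numbers, topo.res_numbers)
        ):
            raise ValueError("runs have mismatching topologies")
    frames = np.concatenate([r.frames for r in runs], axis=0)
    fitted, _ = iterative_fit(frames, fit_idx)
    return Trajectory(topo, fitted, label="+".join(r.label for r in runs))


def compute_ed(traj: Trajectory, ca_idx: np.ndarray, refit: bool = True) -> EDResult:
    """Eigen-decomposition of the CA coordinate covariance.

    The trajectory is (by default) iteratively superposed first; pass
    ``refit=False`` if it already is. A motionless input is returned flagged
    with all-zero eigenvalues rather than raising.
    """
    if traj.n_frames < 2:
        raise ValueError("need more than one frame")
    ca_idx = np.asarray(ca_idx)
    if ca_idx.size < 2:
        raise ValueError("need at least 2 CA atoms")
    frames = traj.frames
    if refit:
        frames, _ = iterative_fit(frames, ca_idx)
    X = frames[:, ca_idx].reshape(traj.n_frames, -1)  # (F, 3N)
    mean = X.mean(axis=0)
    dev = X - mean
    cov = dev.T @ dev / (traj.n_frames - 1)
    if np.allclose(cov, 0.0):
        n3 = cov.shape[0]
        return EDResult(
            mean=mean.reshape(-1, 3),
            covariance=cov,
            eigenvalues=np.zeros(n3),
            eigenvectors=np.eye(n3),
            ca_idx=ca_idx,
            degenerate=True,
        )
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    # deterministic sign: largest-magnitude component positive
    for j in range(v.shape[1]):
        k = np.argmax(np.abs(v[:, j]))
        if v[k, j] < 0:
            v[:, j] = -v[:, j]
    return EDResult(
        mean=mean.reshape(-1, 3),
        covariance=cov,
        eigenvalues=w,
        eigenvectors=v,
        ca_idx=ca_idx,
    )


def cumulative_variance(ed: EDResult, k: int) -> float:
    """Fraction of total fluctuation captured by the first k modes."""
    n = ed.eigenvalues.size
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    total = ed.eigenvalues.sum()
    if total <= 0:
        return 0.0
    return float(ed.eigenvalues[:k].sum() / total)


def project(traj: Trajectory, ed: EDResult, mode: int, refit: bool = True) -> np.ndarray:
    """Per-frame projection of CA deviations onto one mode (0-based index)."""
    if not 0 <= mode < ed.eigenvectors.shape[1]:
        raise ValueError(f"mode index {mode} out of range")
    frames = traj.frames
    if refit:
        frames = np.array(frames)
        flat_mean = ed.mean.reshape(-1)
        for f in range(frames.shape[0]):
            R, t, _ = superpose(frames[f][ed.ca_idx], ed.mean, None)
            frames[f] = apply_transform(frames[f], R, t)
    X = frames[:, ed.ca_idx].reshape(frames.shape[0], -1)
    return (X - ed.mean.reshape(-1)) @ ed.eigenvectors[:, mode]


def mode_loadings(ed: EDResult, mode: int) -> np.ndarray:
    """Per-CA squared loading (|3-vector|^2) of one mode; sums to 1."""
    v = ed.eigenvectors[:, mode].reshape(-1, 3)
    return np.sum(v * v, axis=1)
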