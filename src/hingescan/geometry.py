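"""Frame superposition, RMSD series, subdomain openness and helix geometry.

Openness is the per-frame Euclidean distance between the unweighted CA
center of mass of subdomain II-B and that of the union I-A + I-B + II-A. It
needs no superposition (a distance between COMs is rigid-motion invariant).
The open/closed threshold (29.5 A by default) is the midpoint of the
apo (31.9 A) and ATP-bound (27.3 A) ensemble means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .io import SubdomainMap, Trajectory, ca_indices

OPENNESS_THRESHOLD = 29.5  # Angstrom


def superpose(
    mobile: np.ndarray, reference: np.ndarray, fit_idx: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd)`` with ``R`` a proper rotation (det +1) such that
    ``mobile @ R.T + t`` minimizes the RMSD over the fit atoms.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    fit_m = mobile if fit_idx is None else mobile[fit_idx]
    fit_r = reference if fit_idx is None else reference[fit_idx]
    if fit_m.shape[0] < 3:
        raise ValueError("need at least 3 fit atoms")
    cm, cr = fit_m.mean(axis=0), fit_r.mean(axis=0)
    a, b = fit_m - cm, fit_r - cr
    if np.linalg.matrix_rank(a, tol=1e-8) < 2:
        raise ValueError("fit atoms are collinear")
    rot, rssd = Rotation.align_vectors(b, a)
    R = rot.as_matrix()
    t = cr - cm @ R.T
    rmsd = float(rssd / np.sqrt(fit_m.shape[0]))
    return R, t, rmsd


def apply_transform(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return coords @ R.T + t


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray,
    fit_idx: np.ndarray,
    report_idx: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame RMSD (A) over ``report_idx`` after fitting on ``fit_idx``."""
    if len(fit_idx) == 0:
        raise ValueError("empty fit selection")
    report_idx = fit_idx if report_idx is None else report_idx
    if len(report_idx) == 0:
        raise ValueError("empty report selection")
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        R, t, _ = superpose(traj.frames[f], reference, fit_idx)
        moved = apply_transform(traj.frames[f], R, t)
        d = moved[report_idx] - reference[report_idx]
        out[f] = np.sqrt(np.mean(np.sum(d * d, axis=1)))
    return out


@dataclass
class OpennessSeries:
    """Per-frame II-B <-> (I-A + I-B + II-A) CA COM distances for one run."""

    distances: np.ndarray  # (F,) Angstrom
    mean: float
    sd: float
    label: str  # "open" or "closed"

    def __post_init__(self) -> None:
        if np.any(self.distances < 0):
            raise ValueError("distances must be non-negative")


def classify_openness(mean_distance: float, threshold: float = OPENNESS_THRESHOLD) -> str:
    """"open" iff the mean distance exceeds the threshold (ties are closed)."""
    if mean_distance <= 0:
        raise ValueError("mean distance must be positive")
    return "open" if mean_distance > threshold else "closed"


def openness_series(
    traj: Trajectory,
    subdomain_map: SubdomainMap,
    mobile_group: str = "II-B",
    reference_groups: tuple[str, ...] = ("I-A", "I-B", "II-A"),
    threshold: float = OPENNESS_THRESHOLD,
) -> OpennessSeries:
    """Unweighted CA COM distance between two subdomain groups, per frame."""
    topo = traj.topology
    idx_mobile = ca_indices(topo)
    res_mobile = set(subdomain_map.residues(mobile_group))
    res_ref = set(subdomain_map.residues(*[g for g in reference_groups if g in subdomain_map.groups]))
    if not res_ref:
        raise ValueError("no reference groups present in the subdomain map")
    ca = ca_indices(topo)
    resnum = topo.res_numbers[ca]
    sel_m = ca[np.isin(resnum, list(res_mobile))]
    sel_r = ca[np.isin(resnum, list(res_ref))]
    if sel_m.size == 0 or sel_r.size == 0:
        raise ValueError("a subdomain group selects no CA atoms")
    com_m = traj.frames[:, sel_m].mean(axis=1)
    com_r = traj.frames[:, sel_r].mean(axis=1)
    d = np.linalg.norm(com_m - com_r, axis=1)
    mean = float(d.mean())
    return OpennessSeries(
        distances=d,
        mean=mean,
        sd=float(d.std(ddof=1)) if d.size > 1 else 0.0,
        label=classify_openness(mean, threshold) if mean > 0 else "closed",
    )


def helix_axis(frame: np.ndarray, ca_idx: np.ndarray) -> np.ndarray:
    """Helix axis of the selected CA run, oriented N->C, unit norm.

    The axis is the null direction of the CA second differences (for an
    ideal helix every local curvature vector is exactly perpendicular to the
    axis, so the smallest principal component of the curvature set recovers
    it exactly at any helix length — a plain principal axis of the
    coordinates tilts by several degrees on short helices with fractional
    turns). Straight, curvature-free segments fall back to the first
    principal axis of the coordinates. Deterministic; no cylinder fit.
    """
    pts = np.asarray(frame, dtype=float)[ca_idx]
    if pts.shape[0] < 4:
        raise ValueError("helix axis needs at least 4 CA atoms")
    centered = pts - pts.mean(axis=0)
    if np.allclose(centered, 0.0):
        raise ValueError("degenerate helix: all atoms coincident")
    second = pts[2:] - 2.0 * pts[1:-1] + pts[:-2]
    scale = np.linalg.norm(pts[1:] - pts[:-1], axis=1).mean()
    if np.linalg.norm(second, axis=1).max() > 1e-6 * scale:
        _, s, vt = np.linalg.svd(second, full_matrices=False)
        axis = vt[-1]
    else:  # straight segment: no curvature, use the line itself
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
    if np.dot(axis, pts[-1] - pts[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def interhelical_angle(frame: np.ndarray, ca_idx_a: np.ndarray, ca_idx_b: np.ndarray) -> float:
    """Acute angle (degrees, [0, 90]) between two helix axes."""
    a = helix_axis(frame, ca_idx_a)
    b = helix_axis(frame, ca_idx_b)
    c = np.clip(abs(float(np.dot(a, b))), 0.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def helix_bend_angle(
    frame: np.ndarray,
    ca_idx: np.ndarray,
    pivot_pos: int,
    bent_threshold: float = 30.0,
) -> tuple[float, bool]:
    """Angle between the proximal and distal sub-segment axes of one helix.

    ``pivot_pos`` is the position of the pivot CA within ``ca_idx`` (0-based).
    Both sub-segments need >= 4 CA atoms. Returns (angle in degrees, bent
    flag at the configurable threshold). A straight helix scores near 0.
    """
    ca_idx = np.asarray(ca_idx)
    prox = ca_idx[: pivot_pos + 1]
    dist = ca_idx[pivot_pos:]
    if prox.size < 4 or dist.size < 4:
        raise ValueError("pivot too close to the range end (need >= 4 CA per side)")
    a = helix_axis(frame, prox)
    b = helix_axis(frame, dist)
    c = np.clip(float(np.dot(a, b)), -1.0, 1.0)
    angle = float(np.degrees(np.arccos(c)))
    return angle, angle > bent_threshold
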