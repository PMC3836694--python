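"""Low-level batched vector geometry shared by the builders and analyzers.

All functions accept arrays whose last axis is the Cartesian dimension and
broadcast over any leading axes (typically frames).
"""

from __future__ import annotations

import numpy as np


def normalize(v: np.ndarray) -> np.ndarray:
    """Unit vectors along the last axis; raises on zero-length input."""
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n == 0.0):
        raise ValueError("cannot normalize zero-length vector")
    return v / n


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Signed torsion angle a-b-c-d in degrees, IUPAC convention, [-180, 180).

    The sign flips under mirror reflection of the coordinates.
    """
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, normalize(b2))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # fold the closed upper end onto the open interval
    return np.where(ang >= 180.0, ang - 360.0, ang)


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond_length: float,
    bond_angle_deg: float | np.ndarray,
    torsion_deg: float | np.ndarray,
) -> np.ndarray:
    """Place atom D from internal coordinates (natural extension reference frame).

    D is at distance ``bond_length`` from C, with angle B-C-D equal to
    ``bond_angle_deg`` and torsion A-B-C-D equal to ``torsion_deg`` under the
    same sign convention as :func:`dihedral`.
    """
    theta = np.radians(np.asarray(bond_angle_deg))
    chi = np.radians(np.asarray(torsion_deg))
    bc = normalize(c - b)
    ab = b - a
    n = normalize(np.cross(ab, bc))
    m = np.cross(n, bc)
    st = np.sin(theta)
    d_local = (
        -np.cos(theta)[..., None] * bc
        + (st * np.cos(chi))[..., None] * m
        - (st * np.sin(chi))[..., None] * n
    )
    return c + bond_length * d_local


def wrap_degrees(angle: np.ndarray) -> np.ndarray:
    """Wrap angles (degrees) into [-180, 180)."""
    return (np.asarray(angle) + 180.0) % 360.0 - 180.0


def torus_distance(phi1, psi1, phi2, psi2) -> np.ndarray:
    """Geodesic distance in degrees on the (phi, psi) torus (flat metric)."""
    dphi = wrap_degrees(np.asarray(phi1) - np.asarray(phi2))
    dpsi = wrap_degrees(np.asarray(psi1) - np.asarray(psi2))
    return np.sqrt(dphi**2 + dpsi**2)


def circular_mean_deg(angles: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted circular mean of angles in degrees, in [-180, 180)."""
    a = np.radians(np.asarray(angles, dtype=float))
    if weights is None:
        weights = np.ones_like(a)
    s = np.sum(weights * np.sin(a))
    c = np.sum(weights * np.cos(a))
    return float(wrap_degrees(np.degrees(np.arctan2(s, c))))
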