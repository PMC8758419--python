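"""Small geometry helpers: internal-coordinate atom placement and rotations."""

from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D from internal coordinates relative to chain A-B-C.

    bond: |C-D|; angle: B-C-D; torsion: A-B-C-D.  The natural-extension
    reference frame construction; all lengths Angstrom, angles degrees.
    """
    theta = np.deg2rad(angle_deg)
    phi = np.deg2rad(torsion_deg)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond * np.array([-np.cos(theta),
                               np.sin(theta) * np.cos(phi),
                               np.sin(theta) * np.sin(phi)])
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about an arbitrary axis (Rodrigues)."""
    k = unit(np.asarray(axis, dtype=float))
    t = np.deg2rad(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def rotation_aligning(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit direction a onto unit direction b."""
    a = unit(np.asarray(a, dtype=float))
    b = unit(np.asarray(b, dtype=float))
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any perpendicular
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        return rotation_about_axis(perp, 180.0)
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K / (1 + c)


def reconstruct_amide_hydrogens(n_pos: np.ndarray, ca_pos: np.ndarray,
                                c_prev_pos: np.ndarray, nh_length: float = 1.01) -> np.ndarray:
    """Backbone amide H: along the direction opposing the bisector of the
    two N bonds (to the previous C and to CA), N-H = 1.01 Angstrom."""
    d = unit(unit(n_pos - c_prev_pos) + unit(n_pos - ca_pos))
    return n_pos + nh_length * d
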