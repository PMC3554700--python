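"""Small vector-geometry kernel: dihedrals, axis rotations, internal-coordinate
atom placement (the NeRF construction), and rigid transforms."""

from __future__ import annotations

import numpy as np


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, IUPAC sign convention,
    range (−180, 180]."""
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b3 = np.asarray(p4, float) - np.asarray(p3, float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("dihedral undefined: collinear atom triple")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / norm2)
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


def angle(p1, p2, p3) -> float:
    """Bond angle p1-p2-p3 in degrees."""
    v1 = np.asarray(p1, float) - np.asarray(p2, float)
    v2 = np.asarray(p3, float) - np.asarray(p2, float)
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def rotation_about_axis(axis, theta_deg: float) -> np.ndarray:
    """Rotation matrix about a (not necessarily unit) axis through the origin."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(theta_deg)
    c, s = np.cos(t), np.sin(t)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(axis, axis)


def rotate_about_bond(points, origin, axis, theta_deg: float) -> np.ndarray:
    """Rotate points about the line through ``origin`` along ``axis``."""
    R = rotation_about_axis(axis, theta_deg)
    pts = np.asarray(points, float)
    return (pts - origin) @ R.T + origin


def place_atom(a, b, c, bond: float, ang_deg: float, dih_deg: float) -> np.ndarray:
    """Place atom D so that |D−c| = bond, angle(D,c,b) = ang_deg and
    dihedral(a,b,c,D) = dih_deg (the NeRF internal-to-Cartesian step)."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    if np.linalg.norm(n) < 1e-10:
        raise ValueError("cannot place atom: reference atoms collinear")
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(ang_deg)
    dih = np.radians(dih_deg)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(dih),
            bond * np.sin(ang) * np.sin(dih),
        ]
    )
    basis = np.column_stack([bc, m, n])
    return c + basis @ d_local


def align_vector_rotation(v_from, v_to) -> np.ndarray:
    """Minimal rotation taking direction ``v_from`` onto ``v_to``."""
    a = np.asarray(v_from, float)
    b = np.asarray(v_to, float)
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite directions: rotate 180 deg about any perpendicular axis
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        return rotation_about_axis(perp, 180.0)
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K / (1.0 + c)
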