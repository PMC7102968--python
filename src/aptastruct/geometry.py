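"""Shared low-level geometry: dihedrals, plane fits, ring frames."""

from __future__ import annotations

import numpy as np

__all__ = ["dihedral", "angle", "plane_normal", "ring_frame"]


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, in (-180, 180]."""
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b3 = np.asarray(p4, float) - np.asarray(p3, float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = n1 @ n2
    y = m1 @ n2
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


def angle(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Angle p1-p2-p3 in degrees."""
    v1 = np.asarray(p1, float) - np.asarray(p2, float)
    v2 = np.asarray(p3, float) - np.asarray(p2, float)
    c = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def plane_normal(coords: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane through >=3 points."""
    coords = np.asarray(coords, float)
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[2]


def ring_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(centroid, unit normal) of a planar ring given its atom coordinates."""
    coords = np.asarray(coords, float)
    return coords.mean(axis=0), plane_normal(coords)


def interplanar_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Acute angle between two plane normals, degrees in [0, 90]."""
    c = abs(float(np.dot(n1, n2)) / (np.linalg.norm(n1) * np.linalg.norm(n2)))
    return float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))
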