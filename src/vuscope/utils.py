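"""Small shared helpers: rounding conventions and geometry primitives."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (0.075 -> 0.08 at 2 dp).

    Python's builtin ``round`` is banker's rounding; every user-facing number
    in this package uses half-up instead, so 0.0667 -> 0.07 and 66.67 -> 67.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place a new atom D given internal coordinates relative to atoms a-b-c.

    NeRF construction: |c-D| = ``bond``, angle b-c-D = ``angle_deg``,
    dihedral a-b-c-D = ``dihedral_deg``.
    """
    theta = np.radians(angle_deg)
    chi = np.radians(dihedral_deg)
    d_local = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(chi),
        -bond * np.sin(theta) * np.sin(chi),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def fit_plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the best-fit plane through ``points`` (SVD)."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[2] / np.linalg.norm(vt[2])
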