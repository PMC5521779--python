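"""Torsion-angle computation on 3-D point quadruples.

Signed IUPAC convention: 0 deg = cis (eclipsed), 180 deg = trans, sign
right-handed when looking from the second to the third point.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dihedral", "DegenerateGeometryError"]


class DegenerateGeometryError(ValueError):
    """Raised when four points do not define a torsion angle."""


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle of four points, in degrees within (-180, 180].

    Parameters
    ----------
    p1, p2, p3, p4 : array-like, shape (3,)
        Cartesian coordinates of the four consecutive points.

    Raises
    ------
    DegenerateGeometryError
        If consecutive points coincide or the bond vectors are collinear.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < 1e-10:
            raise DegenerateGeometryError("coincident consecutive points")

    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DegenerateGeometryError("collinear bond vectors")

    b2u = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2u))
    angle = np.degrees(np.arctan2(y, x))
    # canonical half-open interval
    if angle <= -180.0:
        angle += 360.0
    elif angle == -0.0:
        angle = 0.0
    if angle == -180.0:
        angle = 180.0
    return float(angle)
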