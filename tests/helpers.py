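"""Independent oracles used by the unit and acceptance tests.

These deliberately avoid the code paths they check: the dihedral oracle
rotates coordinates with an explicit Rodrigues matrix, and the AUC
oracle counts concordant pairs by brute force.
"""

import numpy as np


def _rotation_to_z(v: np.ndarray) -> np.ndarray:
    """Rodrigues rotation matrix taking v to the +z axis."""
    v = v / np.linalg.norm(v)
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(v, z)
    s = np.linalg.norm(axis)
    c = float(v @ z)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    axis /= s
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + s * k + (1 - c) * (k @ k)


def dihedral_oracle(p1, p2, p3, p4) -> float:
    """Torsion angle via explicit frame rotation: align the central bond
    with +z, then take the difference of the outer bonds' azimuths."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    rot = _rotation_to_z(p3 - p2)
    a = rot @ (p1 - p2)
    b = rot @ (p4 - p3)
    angle = np.degrees(np.arctan2(b[1], b[0]) - np.arctan2(a[1], a[0]))
    angle = (angle + 180.0) % 360.0 - 180.0
    if angle == -180.0:
        angle = 180.0
    return float(angle)


def auc_oracle(labels, scores) -> float:
    """Mann-Whitney AUC by exhaustive pair counting, ties worth 1/2."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))
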