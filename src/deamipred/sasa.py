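"""Solvent-accessible surface area by sphere sampling (Shrake-Rupley).

Operates on heavy atoms only, with a 1.4 A water probe and a
deterministic Fibonacci point lattice on each atomic sphere.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["VDW_RADII", "PROBE_RADIUS", "shrake_rupley", "fibonacci_sphere"]

PROBE_RADIUS = 1.4  # A, water probe

VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}
DEFAULT_RADIUS = 1.80


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice, shape (n, 3)."""
    i = np.arange(n_points, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n_points)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def shrake_rupley(
    coords: np.ndarray,
    elements: list[str],
    n_points: int = 960,
    probe: float = PROBE_RADIUS,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area in A^2.

    Parameters
    ----------
    coords : (n_atoms, 3) array of heavy-atom coordinates.
    elements : element symbol per atom, used for van der Waals radii.
    n_points : sphere-sampling density per atom.
    probe : probe radius in A.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    radii = np.array(
        [VDW_RADII.get(e.upper(), DEFAULT_RADIUS) + probe for e in elements]
    )
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    areas = np.zeros(n)
    for i in range(n):
        pts = coords[i] + radii[i] * sphere
        neighbors = tree.query_ball_point(coords[i], radii[i] + max_r)
        neighbors = [j for j in neighbors if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 > radii[j] ** 2
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
    return areas
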