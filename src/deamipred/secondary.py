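"""Secondary-structure assignment from backbone hydrogen bonds.

A reduced Kabsch-Sander scheme: backbone amide hydrogens are placed
geometrically, H-bond energies use the classic electrostatic model with
a -0.5 kcal/mol cutoff, and the detailed classes collapse to the 4-way
encoding used by the feature set: helix=1, sheet=2, coil=3, turn=4.
"""

from __future__ import annotations

import numpy as np

from .structure import ResidueRecord

__all__ = ["HBOND_ENERGY_CUTOFF", "hbond_energy_matrix", "assign_secondary_structure",
           "HELIX", "SHEET", "COIL", "TURN"]

HELIX, SHEET, COIL, TURN = 1, 2, 3, 4

HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
_COUPLING = 0.42 * 0.20 * 332.0  # q1 * q2 * electrostatic factor


def _backbone(chain: list[ResidueRecord]):
    """Extract N/CA/C/O coordinates; rows of NaN where atoms are missing."""
    n = len(chain)
    out = {k: np.full((n, 3), np.nan) for k in ("N", "CA", "C", "O")}
    for i, res in enumerate(chain):
        for k in out:
            if k in res.atoms:
                out[k][i] = res.atoms[k].coords
    return out


def hbond_energy_matrix(chain: list[ResidueRecord]) -> np.ndarray:
    """E[i, j] = energy (kcal/mol) of the N-H(i) ... O=C(j) hydrogen bond.

    The amide hydrogen of residue i is placed 1.0 A from N(i) along the
    C(i-1)->O(i-1) bond direction reversed.  Prolines have no donor; the
    first residue has no placed hydrogen.  Non-bondable pairs get 0.
    """
    n = len(chain)
    bb = _backbone(chain)
    energies = np.zeros((n, n))
    if n < 2:
        return energies

    h_pos = np.full((n, 3), np.nan)
    for i in range(1, n):
        if chain[i].name == "PRO":
            continue
        c_prev, o_prev, n_i = bb["C"][i - 1], bb["O"][i - 1], bb["N"][i]
        if np.isnan(c_prev).any() or np.isnan(o_prev).any() or np.isnan(n_i).any():
            continue
        direction = c_prev - o_prev
        norm = np.linalg.norm(direction)
        if norm < 1e-9:
            continue
        h_pos[i] = n_i + direction / norm

    for i in range(n):
        if np.isnan(h_pos[i]).any():
            continue
        for j in range(n):
            if abs(i - j) < 2:  # no bond with self or adjacent residue
                continue
            c_j, o_j = bb["C"][j], bb["O"][j]
            if np.isnan(c_j).any() or np.isnan(o_j).any():
                continue
            n_i, h_i = bb["N"][i], h_pos[i]
            r_on = np.linalg.norm(o_j - n_i)
            r_ch = np.linalg.norm(c_j - h_i)
            r_oh = np.linalg.norm(o_j - h_i)
            r_cn = np.linalg.norm(c_j - n_i)
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                energies[i, j] = -9.9  # clashing placement; treat as bonded
                continue
            energies[i, j] = _COUPLING * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
    return energies


def assign_secondary_structure(chain: list[ResidueRecord]) -> np.ndarray:
    """Per-residue 4-way code: helix=1, sheet=2, coil=3, turn=4."""
    n = len(chain)
    codes = np.full(n, COIL, dtype=int)
    if n < 3:
        return codes

    energy = hbond_energy_matrix(chain)
    # hbond[i, j]: N-H of residue i donates to C=O of residue j
    hbond = energy < HBOND_ENERGY_CUTOFF

    def turn_at(i: int, k: int) -> bool:
        """k-turn at i: C=O(i) accepts from N-H(i+k)."""
        return i + k < n and hbond[i + k, i]

    helix = np.zeros(n, dtype=bool)
    turn = np.zeros(n, dtype=bool)
    for k in (3, 4, 5):
        for i in range(n - k):
            if not turn_at(i, k):
                continue
            turn[i + 1:i + k] = True
            # two consecutive k-turns define a minimal helix (3-10/alpha/pi)
            if i + 1 + k < n and turn_at(i + 1, k):
                helix[i + 1:i + 1 + k] = True

    sheet = np.zeros(n, dtype=bool)
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            parallel = (hbond[j, i - 1] and hbond[i + 1, j]) or (
                hbond[i, j - 1] and hbond[j + 1, i]
            )
            antiparallel = (hbond[i, j] and hbond[j, i]) or (
                hbond[j + 1, i - 1] and hbond[i + 1, j - 1]
            )
            if parallel or antiparallel:
                sheet[i] = sheet[j] = True

    codes[turn] = TURN
    codes[sheet] = SHEET
    codes[helix] = HELIX
    return codes
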