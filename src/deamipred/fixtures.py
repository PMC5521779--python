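"""Deterministic synthetic data: parametric peptide structures with
prescribed geometry/B-factors, and labeled feature tables with planted
signal for model testing.

Structures are grown by internal-coordinate placement (NeRF) with ideal
bond lengths and angles; torsions are taken verbatim from the spec, so
descriptor extraction can be checked by round-trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptors import FEATURE_COLUMNS
from .sasa import fibonacci_sphere
from .structure import THREE_TO_ONE, AtomRecord, ResidueRecord, Structure, to_pdb

__all__ = [
    "PeptideSpec",
    "TableSpec",
    "build_structure",
    "build_peptide",
    "build_feature_table",
    "build_benchmark",
    "synthetic_half_life_table",
]

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# ideal backbone geometry (Engh-Huber-style constants)
BOND = {
    "N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231,
    "CA-CB": 1.530, "CB-CG": 1.516, "CG-OD1": 1.231, "CG-ND2": 1.328,
}
ANGLE = {
    "N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.8,
    "N-CA-CB": 110.5, "CA-CB-CG": 113.0, "CB-CG-OD1": 120.8, "CB-CG-ND2": 116.5,
}
OMEGA = 180.0
# improper torsion C-N-CA-CB fixing L-chirality
CB_IMPROPER = 122.6


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position D with |C-D|=bond, angle(B,C,D)=angle and
    dihedral(A,B,C,D)=torsion."""
    theta = np.radians(angle_deg)
    tau = np.radians(torsion_deg)
    d_local = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(tau),
        bond * np.sin(theta) * np.sin(tau),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


@dataclass
class PeptideSpec:
    """Recipe for a synthetic peptide structure.

    ``phi``/``psi`` may be single floats (applied to every residue) or
    per-residue sequences.  ``chi1``/``chi2`` apply to Asn residues.
    ``bfactors`` overrides individual atoms keyed by (residue index,
    atom name); other atoms get ``bfactor_default``.
    """

    sequence: str
    phi: float | list[float] = -120.0
    psi: float | list[float] = 130.0
    chi1: float = -65.0
    chi2: float = -20.0
    chain_id: str = "A"
    bfactor_default: float = 20.0
    bfactors: dict = field(default_factory=dict)
    cage: bool = False

    def __post_init__(self):
        if len(self.sequence) < 2:
            raise ValueError("sequence must have at least 2 residues")
        for aa in self.sequence:
            if aa not in ONE_TO_THREE:
                raise ValueError(f"invalid residue code {aa!r}")

    def phi_at(self, i: int) -> float:
        return self.phi[i] if isinstance(self.phi, (list, tuple)) else self.phi

    def psi_at(self, i: int) -> float:
        return self.psi[i] if isinstance(self.psi, (list, tuple)) else self.psi


def _grow_backbone(spec: PeptideSpec):
    """Return per-residue dict of backbone + side-chain atom coordinates."""
    n_res = len(spec.sequence)
    residues: list[dict[str, np.ndarray]] = []

    # residue 0 seed frame
    n0 = np.zeros(3)
    ca0 = np.array([BOND["N-CA"], 0.0, 0.0])
    theta = np.radians(ANGLE["N-CA-C"])
    c0 = ca0 + BOND["CA-C"] * np.array([-np.cos(theta), np.sin(theta), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})

    for i in range(1, n_res):
        prev = residues[i - 1]
        n_i = _place(prev["N"], prev["CA"], prev["C"],
                     BOND["C-N"], ANGLE["CA-C-N"], spec.psi_at(i - 1))
        ca_i = _place(prev["CA"], prev["C"], n_i,
                      BOND["N-CA"], ANGLE["C-N-CA"], OMEGA)
        c_i = _place(prev["C"], n_i, ca_i,
                     BOND["CA-C"], ANGLE["N-CA-C"], spec.phi_at(i))
        residues.append({"N": n_i, "CA": ca_i, "C": c_i})

    for i, res in enumerate(residues):
        res["O"] = _place(res["N"], res["CA"], res["C"],
                          BOND["C-O"], ANGLE["CA-C-O"], spec.psi_at(i) + 180.0)
        aa = spec.sequence[i]
        if aa == "G":
            continue
        res["CB"] = _place(res["C"], res["N"], res["CA"],
                           BOND["CA-CB"], ANGLE["N-CA-CB"], CB_IMPROPER)
        if aa == "N":
            res["CG"] = _place(res["N"], res["CA"], res["CB"],
                               BOND["CB-CG"], ANGLE["CA-CB-CG"], spec.chi1)
            res["OD1"] = _place(res["CA"], res["CB"], res["CG"],
                                BOND["CG-OD1"], ANGLE["CB-CG-OD1"], spec.chi2)
            res["ND2"] = _place(res["CA"], res["CB"], res["CG"],
                                BOND["CG-ND2"], ANGLE["CB-CG-ND2"], spec.chi2 + 180.0)
    return residues


def _cage_atoms(residues) -> np.ndarray:
    """Tight double shell of pseudo-carbons around the whole peptide.

    Sphere-sampling SASA has no notion of enclosed cavities, so burial
    requires the shell's probe-expanded spheres to overlap the peptide's
    own surface points: the inner shell sits ~2 A off the outermost atom
    and the lattice spacing stays well under the probe diameter.
    """
    coords = np.vstack([xyz for res in residues for xyz in res.values()])
    center = coords.mean(axis=0)
    base = np.max(np.linalg.norm(coords - center, axis=1)) + 2.0
    base = min(base, 6.0)  # keep the shell close enough to occlude the center
    shells = []
    for radius in (base, base + 2.2):
        n_shell = max(200, int(4.0 * np.pi * radius ** 2 / 1.2))
        shells.append(center + radius * fibonacci_sphere(n_shell))
    return np.vstack(shells)


def build_structure(spec: PeptideSpec) -> Structure:
    """Build the peptide as an in-memory Structure with full-precision
    coordinates (no PDB serialization rounding)."""
    grown = _grow_backbone(spec)
    chain: list[ResidueRecord] = []
    for i, placed in enumerate(grown):
        resname = ONE_TO_THREE[spec.sequence[i]]
        atoms = {}
        for name, xyz in placed.items():
            bfac = spec.bfactors.get((i, name), spec.bfactor_default)
            atoms[name] = AtomRecord(name, name[0], xyz, bfac, 1.0)
        chain.append(ResidueRecord(spec.chain_id, i + 1, resname, atoms))
    chains = {spec.chain_id: chain}

    if spec.cage:
        # burial shell: single-CA glycine pseudo-residues on a separate chain
        cage_chain = []
        for k, xyz in enumerate(_cage_atoms(grown)):
            atoms = {"CA": AtomRecord("CA", "C", xyz, spec.bfactor_default, 1.0)}
            cage_chain.append(ResidueRecord("Z", k + 1, "GLY", atoms))
        chains["Z"] = cage_chain
    return Structure(chains=chains)


def build_peptide(spec: PeptideSpec) -> str:
    """Render the peptide described by ``spec`` as PDB-format text."""
    return to_pdb(build_structure(spec))


def synthetic_half_life_table():
    """A complete, deterministic half-life table for tests and demos.

    Values are synthetic (seeded log-uniform days) with the NG-type
    motifs (Yyy = G/S/T/H) given short half-lives; they are NOT the
    experimental measurements, which must be supplied by the user.
    """
    from .halflife import XXX_RESIDUES, YYY_RESIDUES, HalfLifeTable

    rng = np.random.default_rng(42)
    entries = {}
    for x in XXX_RESIDUES:
        for y in YYY_RESIDUES:
            if y == "G":
                value = rng.uniform(1.0, 10.0)
            elif y in "STH":
                value = rng.uniform(8.0, 40.0)
            else:
                value = np.exp(rng.uniform(np.log(30.0), np.log(500.0)))
            entries[(x, y)] = round(float(value), 2)
    return HalfLifeTable(entries)


# ---------------------------------------------------------------------------
# feature tables with planted signal

# structural columns in descending planted-importance priority
_INFORMATIVE_PRIORITY = [
    "psi", "chi2", "zb_cb", "phi", "zb_ca", "chi1",
    "zb_c", "zb_cg", "psa", "pssa", "attack_distance",
]

# plausible marginal (mean, sd) per structural column
_COLUMN_MARGINALS = {
    "phi": (-100.0, 40.0), "psi": (60.0, 50.0),
    "chi1": (-60.0, 40.0), "chi2": (-10.0, 50.0),
    "zb_c": (0.0, 1.0), "zb_ca": (0.0, 1.0),
    "zb_cb": (0.0, 1.0), "zb_cg": (0.0, 1.0),
    "psa": (40.0, 18.0), "pssa": (45.0, 20.0),
    "attack_distance": (5.0, 0.9),
}


@dataclass
class TableSpec:
    """Recipe for a synthetic labeled feature table.

    ``n_informative`` structural columns (besides half_life, which is
    always informative when ``effect`` > 0) receive a class mean shift
    of ``effect`` standard deviations; the remaining columns are
    class-independent noise.
    """

    n: int
    prevalence: float
    effect: float = 2.0
    n_informative: int = 5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if self.n < 10:
            raise ValueError("need n >= 10")
        if not 0 <= self.n_informative <= len(_INFORMATIVE_PRIORITY):
            raise ValueError("n_informative out of range")
        if int(round(self.prevalence * self.n)) < 1:
            raise ValueError("prevalence yields zero positives")

    @property
    def n_positive(self) -> int:
        return int(round(self.prevalence * self.n))

    @property
    def informative_columns(self) -> list[str]:
        cols = _INFORMATIVE_PRIORITY[: self.n_informative]
        return (["half_life"] + cols) if self.effect > 0 else []

    @property
    def noise_columns(self) -> list[str]:
        return [c for c in FEATURE_COLUMNS if c not in self.informative_columns]


def _sample_half_life(rng, labels, effect):
    """Bimodal half-life: short-lived vs long-lived/999 sentinel; the
    short mode is tied to the positive class when effect > 0."""
    n = len(labels)
    values = np.empty(n)
    for i in range(n):
        short = labels[i] == 1 if effect > 0 else rng.random() < 0.2
        if short:
            values[i] = np.exp(rng.normal(np.log(6.0), 0.7))
        elif rng.random() < 0.3:
            values[i] = 999.0
        else:
            values[i] = np.exp(rng.normal(np.log(70.0), 0.9))
    return np.round(values, 3)


def build_feature_table(spec: TableSpec, rng: np.random.Generator | None = None):
    """Generate (features DataFrame with the 13 columns, labels Series)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n_pos = spec.n_positive
    labels = np.zeros(spec.n, dtype=int)
    pos_idx = rng.choice(spec.n, size=n_pos, replace=False)
    labels[pos_idx] = 1

    informative = set(spec.informative_columns)
    data = {}
    for col in FEATURE_COLUMNS:
        if col == "half_life":
            data[col] = _sample_half_life(rng, labels, spec.effect)
        elif col == "secondary_structure":
            data[col] = rng.choice([1, 2, 3, 4], size=spec.n,
                                   p=[0.35, 0.25, 0.3, 0.1])
        else:
            mu, sd = _COLUMN_MARGINALS[col]
            values = rng.normal(mu, sd, size=spec.n)
            if col in informative:
                values = values + labels * spec.effect * sd
            if col in ("psa", "pssa"):
                values = np.clip(values, 0.0, 100.0)
            elif col == "attack_distance":
                values = np.clip(values, 1.5, None)
            data[col] = np.round(values, 4)

    features = pd.DataFrame(data, columns=FEATURE_COLUMNS)
    return features, pd.Series(labels, name="deamidated")


def build_benchmark(seed: int = 20170721, effect: float = 2.0):
    """Paired train/test tables emulating the study's class proportions
    (194 sites / 28 positive train; 81 / 5 test) plus a manifest of the
    planted generating mechanism."""
    rng = np.random.default_rng(seed)
    train_spec = TableSpec(n=194, prevalence=28 / 194, effect=effect, seed=seed)
    test_spec = TableSpec(n=81, prevalence=5 / 81, effect=effect, seed=seed)
    x_train, y_train = build_feature_table(train_spec, rng=rng)
    x_test, y_test = build_feature_table(test_spec, rng=rng)
    manifest = {
        "seed": seed,
        "effect_sd": effect,
        "informative_features": train_spec.informative_columns,
        "noise_features": train_spec.noise_columns,
        "train": {"n": 194, "positives": int(y_train.sum())},
        "test": {"n": 81, "positives": int(y_test.sum())},
    }
    return (x_train, y_train), (x_test, y_test), manifest


def write_benchmark(out_dir, seed: int = 20170721):
    """Materialize the benchmark as CSV + JSON files under ``out_dir``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (xtr, ytr), (xte, yte), manifest = build_benchmark(seed)
    xtr.assign(deamidated=ytr).to_csv(out / "train.csv", index=False)
    xte.assign(deamidated=yte).to_csv(out / "test.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
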