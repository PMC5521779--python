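"""The 13-descriptor feature set for asparagine deamidation prediction.

One feature vector per Asn site: penta-peptide half-life, backbone and
side-chain torsions, 4-way secondary-structure code, z-score-normalized
B-factors of the four key carbons, percent (side-chain) solvent
accessibility, and the nucleophilic-attack C-N distance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .geometry import DegenerateGeometryError, dihedral
from .halflife import HalfLifeTable, SiteNotPredictable, lookup_half_life
from .sasa import shrake_rupley
from .secondary import assign_secondary_structure
from .structure import AsnSite, ResidueRecord, Structure

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_COLUMNS",
    "FeatureVector",
    "SiteStatus",
    "MissingAtomsError",
    "ASN_MAX_ASA_TOTAL",
    "ASN_MAX_ASA_SIDECHAIN",
    "attack_distance",
    "normalize_bfactors",
    "bfactor_descriptors",
    "site_dihedrals",
    "accessibility",
    "featurize",
    "featurize_chain",
    "features_to_frame",
]

# fixed column order of the feature table
FEATURE_COLUMNS = [
    "half_life",
    "phi",
    "psi",
    "chi1",
    "chi2",
    "secondary_structure",
    "zb_c",
    "zb_ca",
    "zb_cb",
    "zb_cg",
    "psa",
    "pssa",
    "attack_distance",
]

# Maximal accessible surface area of an Asn residue (A^2), derived from a
# fully extended Gly-Asn-Gly tripeptide with this package's SASA engine
# (960 points/atom, 1.4 A probe).  Swappable via the accessibility() /
# featurize() keyword arguments if an external reference is preferred.
ASN_MAX_ASA_TOTAL = 158.53
ASN_MAX_ASA_SIDECHAIN = 104.14

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


@dataclass
class FeatureVector:
    half_life: float  # days
    phi: float  # degrees
    psi: float  # degrees
    chi1: float  # degrees
    chi2: float  # degrees
    secondary_structure: int  # helix=1, sheet=2, coil=3, turn=4
    zb_c: float  # z-scores, dimensionless
    zb_ca: float
    zb_cb: float
    zb_cg: float
    psa: float  # percent
    pssa: float  # percent
    attack_distance: float  # A

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class SiteStatus:
    predictable: bool
    reason: str = ""

    def __post_init__(self):
        if not self.predictable and not self.reason:
            raise ValueError("unpredictable sites must carry a reason")


class MissingAtomsError(Exception):
    def __init__(self, atoms: list[str]):
        self.atoms = atoms
        super().__init__("missing atoms: " + ", ".join(atoms))


def attack_distance(asn: ResidueRecord, next_res: ResidueRecord) -> float:
    """Distance (A) from the Asn side-chain carbonyl carbon (CG) to the
    backbone amide nitrogen of residue i+1 — the nucleophilic attack
    coordinate."""
    missing = []
    if "CG" not in asn.atoms:
        missing.append("CG")
    if "N" not in next_res.atoms:
        missing.append("N(i+1)")
    if missing:
        raise MissingAtomsError(missing)
    d = float(np.linalg.norm(asn.atom_coords("CG") - next_res.atom_coords("N")))
    if d < 1e-6:
        warnings.warn("attack distance is zero: CG and N(i+1) coincide")
    return d


def normalize_bfactors(structure: Structure) -> dict[tuple, float]:
    """Z-scores of B-factors over all heavy protein atoms of the structure.

    Returns a map keyed by (chain_id, residue seq_id, atom name).  Uses
    the population standard deviation; a uniform-B structure yields all
    zeros with a warning.
    """
    keys, values = [], []
    for res in structure.iter_residues():
        for atom in res.atoms.values():
            keys.append((res.chain_id, res.seq_id, atom.name))
            values.append(atom.bfactor)
    if len(values) < 2:
        raise ValueError("need at least 2 heavy atoms for B-factor normalization")
    b = np.array(values)
    mu = b.mean()
    sigma = b.std()  # population sd
    if sigma == 0:
        warnings.warn("uniform B-factors: all z-scores set to 0")
        z = np.zeros_like(b)
    else:
        z = (b - mu) / sigma
    return dict(zip(keys, z))


def bfactor_descriptors(
    asn: ResidueRecord, zscores: dict[tuple, float]
) -> tuple[float, float, float, float]:
    """Z-scores at the Asn backbone C, CA and side-chain CB, CG atoms."""
    out = []
    missing = []
    for name in ("C", "CA", "CB", "CG"):
        key = (asn.chain_id, asn.seq_id, name)
        if key not in zscores:
            missing.append(name)
        else:
            out.append(zscores[key])
    if missing:
        raise MissingAtomsError(missing)
    return tuple(out)


def site_dihedrals(chain: list[ResidueRecord], site: AsnSite):
    """(phi, psi, chi1, chi2) in degrees for the Asn at ``site``.

    phi is None for an N-terminal Asn (no residue i-1); callers exclude
    such sites from modeling.
    """
    i = site.list_index
    asn = chain[i]
    missing = []
    for name in ("N", "CA", "C", "CB", "CG", "OD1"):
        if name not in asn.atoms:
            missing.append(name)
    next_res = chain[i + 1] if i + 1 < len(chain) else None
    if next_res is None or "N" not in next_res.atoms:
        missing.append("N(i+1)")
    if missing:
        raise MissingAtomsError(missing)

    n, ca, c = (asn.atom_coords(a) for a in ("N", "CA", "C"))
    cb, cg, od1 = (asn.atom_coords(a) for a in ("CB", "CG", "OD1"))
    n_next = next_res.atom_coords("N")

    phi = None
    if i > 0 and "C" in chain[i - 1].atoms:
        phi = dihedral(chain[i - 1].atom_coords("C"), n, ca, c)
    psi = dihedral(n, ca, c, n_next)
    chi1 = dihedral(n, ca, cb, cg)
    chi2 = dihedral(ca, cb, cg, od1)
    return phi, psi, chi1, chi2


def accessibility(
    structure: Structure,
    site_residue: ResidueRecord,
    n_points: int = 960,
    ref_total: float = ASN_MAX_ASA_TOTAL,
    ref_sidechain: float = ASN_MAX_ASA_SIDECHAIN,
    _cache: dict | None = None,
) -> tuple[float, float]:
    """(PSA, PSSA) in percent for one residue of the structure.

    Absolute areas come from sphere sampling over every heavy atom of
    the whole structure; percentages are relative to a maximal-exposure
    reference and clipped to [0, 100] with a warning when exceeded.
    """
    if _cache is not None and "areas" in _cache:
        atom_keys, areas = _cache["areas"]
    else:
        coords, elements, atom_keys = [], [], []
        for res in structure.iter_residues():
            for atom in res.atoms.values():
                coords.append(atom.coords)
                elements.append(atom.element)
                atom_keys.append((res.chain_id, res.seq_id, atom.name))
        areas = shrake_rupley(np.array(coords), elements, n_points=n_points)
        if _cache is not None:
            _cache["areas"] = (atom_keys, areas)

    total = side = 0.0
    rid = (site_residue.chain_id, site_residue.seq_id)
    for (chain_id, seq_id, name), area in zip(atom_keys, areas):
        if (chain_id, seq_id) != rid:
            continue
        total += area
        if name not in BACKBONE_NAMES:
            side += area
    psa = 100.0 * total / ref_total
    pssa = 100.0 * side / ref_sidechain
    for label, value in (("PSA", psa), ("PSSA", pssa)):
        if value > 100.0:
            warnings.warn(f"{label} ratio {value:.1f}% exceeds 100%; clipped")
    return min(psa, 100.0), min(pssa, 100.0)


def featurize(
    structure: Structure,
    chain: list[ResidueRecord],
    site: AsnSite,
    table: HalfLifeTable,
    n_points: int = 960,
    ref_total: float = ASN_MAX_ASA_TOTAL,
    ref_sidechain: float = ASN_MAX_ASA_SIDECHAIN,
    _cache: dict | None = None,
) -> FeatureVector | SiteStatus:
    """Assemble all 13 descriptors for one Asn site.

    Any unpredictable sub-result (Yyy=Q, missing atoms, N-terminal phi)
    propagates to a SiteStatus with concatenated reasons.
    """
    reasons = []
    asn = chain[site.list_index]

    half_life = None
    try:
        half_life = lookup_half_life(table, site)
    except SiteNotPredictable as exc:
        reasons.append(exc.reason)

    torsions = None
    try:
        torsions = site_dihedrals(chain, site)
        if torsions[0] is None:
            reasons.append("N-terminal Asn: phi undefined")
    except (MissingAtomsError, DegenerateGeometryError) as exc:
        reasons.append(str(exc))

    bfacs = None
    try:
        if _cache is not None and "zscores" in _cache:
            zscores = _cache["zscores"]
        else:
            zscores = normalize_bfactors(structure)
            if _cache is not None:
                _cache["zscores"] = zscores
        bfacs = bfactor_descriptors(asn, zscores)
    except (MissingAtomsError, ValueError) as exc:
        reasons.append(str(exc))

    attack = None
    try:
        attack = attack_distance(asn, chain[site.list_index + 1])
    except MissingAtomsError as exc:
        reasons.append(str(exc))

    if reasons:
        return SiteStatus(predictable=False, reason="; ".join(reasons))

    if _cache is not None and "ss" in _cache:
        ss_codes = _cache["ss"]
    else:
        ss_codes = assign_secondary_structure(chain)
        if _cache is not None:
            _cache["ss"] = ss_codes
    psa, pssa = accessibility(
        structure, asn, n_points=n_points,
        ref_total=ref_total, ref_sidechain=ref_sidechain, _cache=_cache,
    )

    phi, psi, chi1, chi2 = torsions
    return FeatureVector(
        half_life=half_life,
        phi=phi,
        psi=psi,
        chi1=chi1,
        chi2=chi2,
        secondary_structure=int(ss_codes[site.list_index]),
        zb_c=bfacs[0],
        zb_ca=bfacs[1],
        zb_cb=bfacs[2],
        zb_cg=bfacs[3],
        psa=psa,
        pssa=pssa,
        attack_distance=attack,
    )


def featurize_chain(
    structure: Structure,
    chain: list[ResidueRecord],
    sites: list[AsnSite],
    table: HalfLifeTable,
    **kwargs,
) -> list[tuple[AsnSite, FeatureVector | SiteStatus]]:
    """Featurize every site, sharing the per-structure SASA/z-score work."""
    cache: dict = {}
    return [
        (site, featurize(structure, chain, site, table, _cache=cache, **kwargs))
        for site in sites
    ]


def features_to_frame(
    results: list[tuple[AsnSite, FeatureVector | SiteStatus]],
    include_unpredictable: bool = False,
) -> pd.DataFrame:
    """Tabulate featurization results: identity columns, the 13 features
    in fixed order, and a status column."""
    rows = []
    for site, result in results:
        row = {
            "chain": site.chain_id,
            "residue": site.seq_index,
            "xxx": site.xxx or "",
            "yyy": site.yyy or "",
            "yyy2": site.yyy2 or "",
        }
        if isinstance(result, FeatureVector):
            row.update(result.as_dict())
            row["status"] = "ok"
        else:
            if not include_unpredictable:
                logger.warning(
                    "site %s/%s not predictable: %s",
                    site.chain_id, site.seq_index, result.reason,
                )
                continue
            row.update({c: np.nan for c in FEATURE_COLUMNS})
            row["status"] = result.reason
        rows.append(row)
    columns = ["chain", "residue", "xxx", "yyy", "yyy2"] + FEATURE_COLUMNS + ["status"]
    return pd.DataFrame(rows, columns=columns)
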