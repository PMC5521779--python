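"""Protein structure model: PDB parsing, chain selection, Asn site enumeration.

The parser is deliberately small and strict: fixed wwPDB v3.3 columns,
line-numbered errors, heavy protein atoms only.  Hydrogens are dropped,
waters and unmapped hetero residues are kept in a separate ligand store,
and alternate locations are resolved to the highest-occupancy conformer
(ties broken by alphabetical altloc identifier).
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "Structure",
    "AsnSite",
    "PDBParseError",
    "EmptyStructureError",
    "ChainNotFoundError",
    "read_structure",
    "to_pdb",
    "select_chain",
    "enumerate_asn_sites",
    "write_sites_csv",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# common modified residues mapped to their parent amino acid
NONSTANDARD_PARENT = {
    "MSE": "MET", "SEP": "SER", "TPO": "THR", "PTR": "TYR",
    "CSO": "CYS", "HYP": "PRO", "MLY": "LYS", "PCA": "GLU",
}

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class PDBParseError(ValueError):
    pass


class EmptyStructureError(ValueError):
    pass


class ChainNotFoundError(KeyError):
    pass


@dataclass
class AtomRecord:
    name: str
    element: str
    coords: np.ndarray
    bfactor: float
    occupancy: float
    altloc: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if self.bfactor < 0:
            raise ValueError(f"negative B-factor for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy outside [0,1] for atom {self.name}")


@dataclass
class ResidueRecord:
    chain_id: str
    seq_index: int
    name: str
    atoms: dict[str, AtomRecord] = field(default_factory=dict)
    icode: str = ""

    @property
    def seq_id(self) -> str:
        """Author residue number with insertion code as a composite key."""
        return f"{self.seq_index}{self.icode}"

    @property
    def one_letter(self) -> str | None:
        return THREE_TO_ONE.get(self.name)

    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in BACKBONE_ATOMS)

    def atom_coords(self, name: str) -> np.ndarray:
        return self.atoms[name].coords


@dataclass
class Structure:
    chains: dict[str, list[ResidueRecord]] = field(default_factory=dict)
    resolution: float | None = None
    ligands: list[ResidueRecord] = field(default_factory=list)

    def iter_residues(self):
        for residues in self.chains.values():
            yield from residues

    def iter_atoms(self):
        for res in self.iter_residues():
            yield from res.atoms.values()

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())


@dataclass
class AsnSite:
    chain_id: str
    seq_index: str  # composite author number (insertion code appended)
    xxx: str | None  # one-letter code of residue i-1
    yyy: str | None  # one-letter code of residue i+1
    yyy2: str | None  # one-letter code of residue i+2
    list_index: int = -1  # position within the selected chain residue list

    def __post_init__(self):
        # central residue is ASN by construction in enumerate_asn_sites
        pass


def _element_from_name(name: str) -> str:
    stripped = name.strip()
    if stripped[:1].isdigit():
        stripped = stripped.lstrip("0123456789")
    return stripped[:1].upper()


def _parse_atom_line(line: str, lineno: int):
    if len(line) < 54:
        raise PDBParseError(f"line {lineno}: ATOM/HETATM record too short")
    try:
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain_id = line[21].strip() or "A"
        seq_index = int(line[22:26])
        icode = line[26].strip()
        coords = np.array(
            [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        )
        occupancy = float(line[54:60]) if len(line) >= 60 and line[54:60].strip() else 1.0
        bfactor = float(line[60:66]) if len(line) >= 66 and line[60:66].strip() else 0.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed ATOM record ({exc})") from exc
    if not element:
        element = _element_from_name(name)
    return name, altloc, resname, chain_id, seq_index, icode, coords, occupancy, bfactor, element


def _resolve_altlocs(raw_atoms) -> dict[str, AtomRecord]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc."""
    by_name: dict[str, list[AtomRecord]] = {}
    for atom in raw_atoms:
        by_name.setdefault(atom.name, []).append(atom)
    resolved = {}
    for name, group in by_name.items():
        group.sort(key=lambda a: (-a.occupancy, a.altloc))
        resolved[name] = group[0]
    return resolved


def read_structure(pdb_text: str) -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Hydrogens are dropped; waters and unmapped hetero residues go to the
    ligand store; altloc groups are reduced to the highest-occupancy
    conformer.  Raises :class:`PDBParseError` with the offending line
    number on malformed records and :class:`EmptyStructureError` if no
    protein atoms remain.
    """
    resolution = None
    # (chain, seq, icode, resname) -> list of raw atoms, insertion-ordered
    residue_atoms: dict[tuple, list[AtomRecord]] = {}
    residue_kinds: dict[tuple, str] = {}  # "protein" | "ligand" | "water"
    chain_order: list[str] = []

    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        record = line[:6].strip()
        if record == "REMARK" and "RESOLUTION." in line:
            tail = line.split("RESOLUTION.", 1)[1]
            for token in tail.split():
                try:
                    resolution = float(token)
                    break
                except ValueError:
                    continue
        if record not in ("ATOM", "HETATM"):
            continue
        (name, altloc, resname, chain_id, seq_index, icode,
         coords, occupancy, bfactor, element) = _parse_atom_line(line, lineno)
        if element in ("H", "D"):
            continue
        if resname in WATER_NAMES:
            kind = "water"
        elif resname in THREE_TO_ONE:
            kind = "protein"
        elif resname in NONSTANDARD_PARENT:
            resname = NONSTANDARD_PARENT[resname]
            kind = "protein"
        else:
            kind = "ligand"
        key = (chain_id, seq_index, icode, resname)
        residue_atoms.setdefault(key, []).append(
            AtomRecord(name, element, coords, bfactor,
                       min(max(occupancy, 0.0), 1.0), altloc)
        )
        residue_kinds[key] = kind
        if kind == "protein" and chain_id not in chain_order:
            chain_order.append(chain_id)

    chains: dict[str, list[ResidueRecord]] = {c: [] for c in chain_order}
    ligands: list[ResidueRecord] = []
    for key, atoms in residue_atoms.items():
        chain_id, seq_index, icode, resname = key
        res = ResidueRecord(chain_id, seq_index, resname,
                            _resolve_altlocs(atoms), icode)
        if residue_kinds[key] == "protein":
            chains[chain_id].append(res)
        else:
            ligands.append(res)

    for residues in chains.values():
        residues.sort(key=lambda r: (r.seq_index, r.icode))

    structure = Structure(chains=chains, resolution=resolution, ligands=ligands)
    if structure.n_atoms == 0:
        raise EmptyStructureError("no protein atoms found in input")
    if resolution is not None and resolution > 2.5:
        warnings.warn(
            f"structure resolution {resolution:.2f} A is worse than 2.5 A; "
            "B-factor descriptors may be unreliable"
        )
    return structure


def to_pdb(structure: Structure) -> str:
    """Serialize a Structure back to PDB-format text (protein atoms only)."""
    lines = []
    serial = 0
    for chain_id, residues in structure.chains.items():
        for res in residues:
            for atom in res.atoms.values():
                serial += 1
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name}{atom.altloc or ' '}{res.name:>3s} "
                    f"{chain_id}{res.seq_index:4d}{res.icode or ' '}   "
                    f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
                    f"{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
                    f"          {atom.element:>2s}"
                )
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def select_chain(structure: Structure, chain_id: str | None = None) -> list[ResidueRecord]:
    """Return the working chain's residues.

    With an explicit ``chain_id`` that chain is returned; otherwise the
    chain with the most backbone-complete residues (N, CA, C, O all
    present) wins, ties broken by file order.
    """
    if not structure.chains:
        raise EmptyStructureError("structure has no protein chains")
    if chain_id is not None:
        if chain_id not in structure.chains:
            available = ", ".join(structure.chains)
            raise ChainNotFoundError(
                f"chain {chain_id!r} not present (available: {available})"
            )
        return structure.chains[chain_id]
    best_id = max(
        structure.chains,
        key=lambda c: sum(1 for r in structure.chains[c] if r.has_backbone()),
    )
    # max() keeps the first maximal key in iteration (= file) order
    return structure.chains[best_id]


def enumerate_asn_sites(chain: list[ResidueRecord]) -> list[AsnSite]:
    """One AsnSite per ASN residue that has a succeeding residue.

    A C-terminal Asn has no i+1 backbone nitrogen available for the
    nucleophilic attack and is excluded with a logged warning.
    """
    sites = []
    for i, res in enumerate(chain):
        if res.name != "ASN":
            continue
        if i + 1 >= len(chain):
            logger.warning(
                "chain %s: C-terminal Asn %s excluded (no i+1 residue)",
                res.chain_id, res.seq_id,
            )
            continue
        xxx = chain[i - 1].one_letter if i > 0 else None
        yyy = chain[i + 1].one_letter
        yyy2 = chain[i + 2].one_letter if i + 2 < len(chain) else None
        sites.append(AsnSite(res.chain_id, res.seq_id, xxx, yyy, yyy2, list_index=i))
    return sites


def write_sites_csv(sites: list[AsnSite], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["chain", "residue", "xxx", "yyy", "yyy2"])
        for s in sites:
            writer.writerow([s.chain_id, s.seq_index,
                             s.xxx or "", s.yyy or "", s.yyy2 or ""])
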