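"""Penta-peptide deamidation half-life lookup.

Half-lives of Gly-Xxx-Asn-Yyy-Gly penta-peptides (days) are supplied by
the user as a CSV keyed by the flanking residues.  The lookup applies a
fixed rule set for flanking residues that the measurement series did not
cover:

* Yyy = P  -> sentinel 999 days (proline nitrogen cannot attack)
* Yyy = Q  -> not predictable
* Yyy = N  -> shift one residue downward and look up (N, yyy2)
* Xxx in {N, Q} or missing -> fall back to Xxx = G
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

from .structure import AsnSite

__all__ = [
    "PROLINE_SENTINEL_DAYS",
    "XXX_RESIDUES",
    "YYY_RESIDUES",
    "SiteNotPredictable",
    "HalfLifeTable",
    "lookup_half_life",
    "write_template",
]

PROLINE_SENTINEL_DAYS = 999.0

# flanking-residue coverage the measurement series provides
XXX_RESIDUES = "GSTCMFYDEHKRALVIWP"
YYY_RESIDUES = "GHSADTCKMERFYWLVI"


class SiteNotPredictable(Exception):
    """The site falls outside the domain of the half-life rules."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


@dataclass
class HalfLifeTable:
    """Map (xxx, yyy) one-letter codes -> deamidation half-life in days."""

    entries: dict[tuple[str, str], float]

    def __post_init__(self):
        for (xxx, yyy), value in self.entries.items():
            if value <= 0:
                raise ValueError(
                    f"half-life for ({xxx},{yyy}) must be positive, got {value}"
                )

    @classmethod
    def from_csv(cls, path) -> "HalfLifeTable":
        entries = {}
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"xxx", "yyy", "half_life_days"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise ValueError(
                    "half-life CSV must have header xxx,yyy,half_life_days"
                )
            for row in reader:
                raw = row["half_life_days"].strip()
                if not raw or raw.upper() == "FILL_ME":
                    raise ValueError(
                        f"half-life table has a placeholder value for "
                        f"({row['xxx']},{row['yyy']}); supply measured data"
                    )
                entries[(row["xxx"].strip().upper(), row["yyy"].strip().upper())] = float(raw)
        table = cls(entries)
        table.validate_coverage()
        return table

    def validate_coverage(self) -> None:
        missing = [
            (x, y)
            for x in XXX_RESIDUES
            for y in YYY_RESIDUES
            if (x, y) not in self.entries
        ]
        if missing:
            raise ValueError(
                f"half-life table missing {len(missing)} required (Xxx,Yyy) "
                f"pairs, e.g. {missing[:5]}"
            )

    def get(self, xxx: str, yyy: str) -> float:
        try:
            return self.entries[(xxx, yyy)]
        except KeyError:
            raise KeyError(
                f"half-life table has no entry for (Xxx={xxx}, Yyy={yyy}) "
                "after substitution rules"
            ) from None


def _lookup(table: HalfLifeTable, xxx: str | None, yyy: str | None,
            yyy2: str | None) -> float:
    if yyy is None:
        raise SiteNotPredictable("no C-terminal neighbor (Yyy) available")
    if yyy == "P":
        return PROLINE_SENTINEL_DAYS
    if yyy == "Q":
        raise SiteNotPredictable("Yyy=Q has no half-life data")
    if yyy == "N":
        # shifted penta-peptide: the Asn-Asn pair is read as Xxx=N, Yyy=yyy2
        if yyy2 is None:
            raise SiteNotPredictable("Yyy=N shift rule needs residue i+2")
        return _lookup(table, "N", yyy2, None)
    if (xxx, yyy) in table.entries:
        return table.entries[(xxx, yyy)]
    if xxx is None or xxx in ("N", "Q"):
        # Xxx barely affects the half-life; fall back to glycine
        return table.get("G", yyy)
    return table.get(xxx, yyy)


def lookup_half_life(table: HalfLifeTable, site: AsnSite) -> float:
    """Half-life in days for one Asn site, or raise SiteNotPredictable."""
    return _lookup(table, site.xxx, site.yyy, site.yyy2)


def write_template(path) -> None:
    """Write a CSV template covering every required (Xxx, Yyy) pair.

    Values are placeholders and must be filled with measured half-lives
    before the table can be loaded.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["xxx", "yyy", "half_life_days"])
        for x in XXX_RESIDUES:
            for y in YYY_RESIDUES:
                writer.writerow([x, y, "FILL_ME"])
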