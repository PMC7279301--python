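"""Carbon-environment and element bookkeeping for the 20 standard residues.

Every carbon atom in a protein is assigned to one of ten chemical
environments distinguishable by their C1s core-level shift::

    C=C, CHx, C=C-N, C-C(O)O, C-OH, C-N, C=N, N-C=O, C-S, COOH

The per-residue assignment (residue-in-chain, i.e. free amino acid minus one
water) ships as a plain-text table, ``data/residue_chemistry.tsv``, so the
chemistry can be audited without reading code. The default policy: backbone
Calpha carbons are C-N, backbone carbonyls are the amide N-C=O, aromatic
ring carbons with only C/H neighbours are C=C, carbons alpha to a side-chain
carboxyl are C-C(O)O and the carboxyl carbon itself COOH, and so on — see
the table header. An alternative assignment can be supplied as a
:class:`ChemistryTable` without code changes.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from types import MappingProxyType
from typing import Mapping

#: The closed set of carbon environments; no operation emits anything else.
ENVIRONMENTS: tuple[str, ...] = (
    "C=C", "CHx", "C=C-N", "C-C(O)O", "C-OH",
    "C-N", "C=N", "N-C=O", "C-S", "COOH",
)

ELEMENTS: tuple[str, ...] = ("C", "H", "N", "O", "S")

STANDARD_RESIDUES: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWY")


class UnknownResidueError(ValueError):
    """Raised for residue codes outside the 20-letter standard alphabet."""

    def __init__(self, code: str, context: str | None = None):
        where = f" ({context})" if context else ""
        super().__init__(f"unknown residue code {code!r}{where}; expected one "
                         f"of the 20 standard one-letter codes")
        self.code = code


@dataclass(frozen=True)
class ResidueChemistry:
    """Chemistry of one residue as it sits in a peptide chain."""

    residue: str
    env_counts: Mapping[str, int]
    elements: Mapping[str, int]

    def __post_init__(self):
        if sum(self.env_counts.values()) != self.elements["C"]:
            raise ValueError(
                f"residue {self.residue}: environment counts sum to "
                f"{sum(self.env_counts.values())} but carbon count is "
                f"{self.elements['C']}")


class ChemistryTable:
    """A total residue -> chemistry mapping, loadable from a TSV file.

    The TSV format is one row per residue: code, element counts (C H N O S),
    then one column per environment in :data:`ENVIRONMENTS`.
    """

    def __init__(self, entries: Mapping[str, ResidueChemistry]):
        missing = STANDARD_RESIDUES - set(entries)
        if missing:
            raise ValueError(f"table incomplete, missing {sorted(missing)}")
        self._entries = dict(entries)

    def __getitem__(self, residue: str) -> ResidueChemistry:
        code = residue.upper()
        if code not in self._entries:
            raise UnknownResidueError(residue)
        return self._entries[code]

    def __iter__(self):
        return iter(sorted(self._entries))

    def __len__(self) -> int:
        return len(self._entries)

    @classmethod
    def from_tsv(cls, path) -> "ChemistryTable":
        entries: dict[str, ResidueChemistry] = {}
        with open(path, newline="") as fh:
            rows = [r for r in csv.reader(fh, delimiter="\t")
                    if r and not r[0].startswith("#")]
        header = rows[0]
        env_cols = header[6:]
        if set(env_cols) != set(ENVIRONMENTS):
            raise ValueError(f"environment columns {env_cols} do not match "
                             f"the closed set {ENVIRONMENTS}")
        for row in rows[1:]:
            code = row[0].upper()
            elements = dict(zip(ELEMENTS, map(int, row[1:6])))
            envs = {e: int(v) for e, v in zip(env_cols, row[6:]) if int(v)}
            entries[code] = ResidueChemistry(
                code, MappingProxyType(envs), MappingProxyType(elements))
        return cls(entries)


def _load_default() -> ChemistryTable:
    with resources.as_file(
            resources.files("xpsprot.data") / "residue_chemistry.tsv") as p:
        return ChemistryTable.from_tsv(p)


DEFAULT_TABLE: ChemistryTable = _load_default()


def residue_environment_counts(residue: str, *,
                               table: ChemistryTable = DEFAULT_TABLE,
                               context: str | None = None) -> dict[str, int]:
    """Carbon-environment counts for one in-chain residue.

    Parameters
    ----------
    residue : one-letter code (case-insensitive).
    table : alternative assignment policy; defaults to the packaged table.
    context : optional position context echoed in the rejection message.
    """
    code = residue.upper()
    if code not in STANDARD_RESIDUES:
        raise UnknownResidueError(residue, context)
    return dict(table[code].env_counts)


def residue_elements(residue: str, *,
                     table: ChemistryTable = DEFAULT_TABLE,
                     context: str | None = None) -> dict[str, int]:
    """Element counts (C, H, N, O, S) for one in-chain residue."""
    code = residue.upper()
    if code not in STANDARD_RESIDUES:
        raise UnknownResidueError(residue, context)
    return dict(table[code].elements)
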