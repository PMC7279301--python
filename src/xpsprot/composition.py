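"""Whole-protein composition: environment fractions, elemental ratios, and
the elemental surface-concentration estimator.

A protein's carbon-environment fractions are the residue-level counts summed
over the sequence and normalized by the total carbon count. Chain termini are
accounted for once per chain: the terminal carboxyl is counted as COOH
instead of a backbone amide, and the elements gain one water. For proteins of
a hundred residues or more the correction is negligible, but it makes short
peptides exact.

The elemental estimator converts a measured surface N/C atomic ratio into a
protein surface concentration using the protein's sequence-derived C/N::

    concentration (%) = (N/C)_experiment * (C/N)_protein * 100

Presentation follows the conventions used for XPS survey tables: atomic
ratios to two decimals (round half to even), percentages truncated to the
integer (28.64 -> "28%").
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from Bio import SeqIO

from .chemistry import (DEFAULT_TABLE, ELEMENTS, ENVIRONMENTS,
                        STANDARD_RESIDUES, ChemistryTable,
                        UnknownResidueError)

#: Packaged sequence fixtures (synthetic stand-ins, see each FASTA header).
PACKAGED_SEQUENCES = {
    "apoa1": "apoa1_synthetic.fasta",
    "hrang": "hrang_synthetic.fasta",
    "fibronectin": "fibronectin_synthetic.fasta",
}


@dataclass(frozen=True)
class ProteinSequence:
    id: str
    residues: str
    chain_count: int = 1

    def __post_init__(self):
        seq = self.residues.upper().replace("*", "")
        object.__setattr__(self, "residues", seq)
        if not seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        if self.chain_count < 1:
            raise ValueError("chain_count must be a positive integer")
        for pos, code in enumerate(seq, start=1):
            if code not in STANDARD_RESIDUES:
                raise UnknownResidueError(
                    code, f"record {self.id!r}, position {pos}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CompositionProfile:
    """Normalized carbon-environment fractions plus element totals."""

    env_fractions: dict[str, float]
    elements: dict[str, float]
    be_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        total = sum(self.env_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"environment fractions sum to {total}, not 1")
        if any(not 0.0 <= f <= 1.0 for f in self.env_fractions.values()):
            raise ValueError("environment fractions must lie in [0, 1]")
        unknown = set(self.env_fractions) - set(ENVIRONMENTS)
        if unknown:
            raise ValueError(f"unknown carbon environments: {sorted(unknown)}")

    def ratio(self, numerator: str, denominator: str) -> float:
        return atomic_ratio(self.elements.get(numerator, 0.0),
                            self.elements.get(denominator, 0.0))

    @property
    def c_n(self) -> float:
        return self.ratio("C", "N")

    @property
    def n_c(self) -> float:
        return self.ratio("N", "C")

    @property
    def o_c(self) -> float:
        return self.ratio("O", "C")


def read_fasta(path) -> list[ProteinSequence]:
    """Read protein sequences from a FASTA file.

    Sequences are uppercased and ``*`` stop symbols stripped; any residue
    outside the 20-letter standard alphabet is rejected with the offending
    code, record id and position.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return [ProteinSequence(rec.id, str(rec.seq)) for rec in records]


def packaged_sequence(fixture_id: str) -> ProteinSequence:
    """Load one of the packaged (synthetic stand-in) sequence fixtures."""
    try:
        name = PACKAGED_SEQUENCES[fixture_id]
    except KeyError:
        raise KeyError(f"unknown sequence fixture {fixture_id!r}; available: "
                       f"{sorted(PACKAGED_SEQUENCES)}") from None
    with resources.as_file(resources.files("xpsprot.data") / name) as p:
        return read_fasta(p)[0]


def composition_profile(seq: ProteinSequence, *,
                        include_termini: bool = True,
                        table: ChemistryTable = DEFAULT_TABLE,
                        ) -> CompositionProfile:
    """Aggregate residue chemistry into whole-protein fractions and elements.

    With ``include_termini`` (default) each chain converts one backbone
    amide carbon into COOH and gains one water; with it off the profile is
    the plain residue-in-chain sum, so concatenation is exactly
    count-additive.
    """
    env = dict.fromkeys(ENVIRONMENTS, 0)
    elements = dict.fromkeys(ELEMENTS, 0)
    for code in seq.residues:
        chem = table[code]
        for k, v in chem.env_counts.items():
            env[k] += v
        for k, v in chem.elements.items():
            elements[k] += v
    if include_termini:
        k = seq.chain_count
        if env["N-C=O"] < k:
            raise ValueError("chain_count exceeds available backbone amides")
        env["N-C=O"] -= k
        env["COOH"] += k
        elements["H"] += 2 * k
        elements["O"] += k
    total_c = elements["C"]
    fractions = {e: c / total_c for e, c in env.items() if c}
    return CompositionProfile(fractions, {k: float(v)
                                          for k, v in elements.items()})


def atomic_ratio(numerator_at_pct: float, denominator_at_pct: float) -> float:
    """Ratio of two atomic percentages (e.g. O/C or N/C from a survey)."""
    if denominator_at_pct <= 0:
        raise ValueError("denominator atomic percentage must be positive")
    return numerator_at_pct / denominator_at_pct


def eq2_concentration(nc_experiment: float, cn_protein: float, *,
                      allow_zero_nitrogen: bool = False) -> float:
    """Protein surface concentration (%) from elemental ratios.

    ``nc_experiment`` is the measured N/C atomic ratio of the protein-bearing
    surface, ``cn_protein`` the sequence-derived C/N of the protein. Zero
    measured nitrogen is only accepted via ``allow_zero_nitrogen`` (the
    instrumental detection limit makes an exact zero suspect).
    """
    if cn_protein <= 0:
        raise ValueError("protein C/N ratio must be positive")
    if nc_experiment <= 0 and not (allow_zero_nitrogen and nc_experiment == 0):
        raise ValueError("experimental N/C ratio must be positive "
                         "(pass allow_zero_nitrogen=True for an exact zero)")
    return nc_experiment * cn_protein * 100.0


def present_percent(value: float) -> str:
    """Integer-percent presentation, truncating toward zero (28.64 -> 28%)."""
    return f"{int(value)}%"


def present_ratio(value: float) -> str:
    """Two-decimal presentation for atomic ratios (round half to even)."""
    return f"{round(value, 2):.2f}"
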