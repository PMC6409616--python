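"""Nuclear genetic codes and code-aware translation.

Most budding yeasts use the standard nuclear code, but several clades have
reassigned the codon CUG: CUG-Ser yeasts (e.g. *Candida albicans* and the
Metschnikowiaceae) decode it as serine, and the CUG-Ala clade as alanine.
A coding sequence that contains no CUG codon translates identically under
all three codes — it is *degenerate* across them — which is what makes a
CUG-free selectable marker portable between clades.

This module represents complete 64-codon tables, translates coding
sequences under any of them, and verifies cross-code degeneracy.
DNA (with T) is the canonical alphabet; U on input is normalized to T.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio.Data import CodonTable as _CodonTable

from .errors import AlphabetError, FrameError

__all__ = [
    "GeneticCode",
    "CodingSequence",
    "DegeneracyReport",
    "CodonDifference",
    "STANDARD",
    "CUG_SER",
    "CUG_ALA",
    "CUG_LEU",
    "BUILTIN_CODES",
    "get_code",
    "translate",
    "count_codon",
    "degeneracy_report",
]

BASES = "ACGT"
STOP = "*"
ALL_CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)


def _standard_table() -> dict[str, str]:
    ncbi = _CodonTable.unambiguous_dna_by_id[1]
    table = dict(ncbi.forward_table)
    for codon in ncbi.stop_codons:
        table[codon] = STOP
    return table


@dataclass(frozen=True)
class GeneticCode:
    """A complete codon → amino-acid map with a named CUG assignment.

    Parameters
    ----------
    name:
        Identifier; the built-ins are ``standard``, ``cug_ser``, ``cug_ala``
        and ``cug_leu`` (an alias of the standard table used when CUG-Leu
        must be named as a candidate).
    table:
        All 64 DNA codons mapped to single-letter amino acids, ``*`` for stop.
    """

    name: str
    table: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = set(ALL_CODONS) - set(self.table)
        extra = set(self.table) - set(ALL_CODONS)
        if missing or extra:
            raise ValueError(
                f"genetic code {self.name!r} must map exactly the 64 A/C/G/T "
                f"codons (missing {sorted(missing)}, extra {sorted(extra)})"
            )
        object.__setattr__(self, "table", dict(self.table))

    def amino_acid(self, codon: str) -> str:
        return self.table[codon]

    @property
    def cug_assignment(self) -> str:
        """Amino acid assigned to the CUG (DNA: CTG) codon."""
        return self.table["CTG"]

    def synonymous_family(self, amino_acid: str) -> tuple[str, ...]:
        """All codons translating to `amino_acid` under this code, sorted."""
        return tuple(
            sorted(c for c, aa in self.table.items() if aa == amino_acid)
        )

    def with_codon(self, codon: str, amino_acid: str, name: str) -> "GeneticCode":
        table = dict(self.table)
        table[codon] = amino_acid
        return GeneticCode(name=name, table=table)

    def to_tsv(self, path) -> None:
        """Export the table as a 64-row TSV (codon, amino_acid)."""
        with open(path, "w") as fh:
            fh.write(f"# genetic code: {self.name}\n")
            fh.write("codon\tamino_acid\n")
            for codon in ALL_CODONS:
                fh.write(f"{codon}\t{self.table[codon]}\n")


STANDARD = GeneticCode("standard", _standard_table())
CUG_SER = STANDARD.with_codon("CTG", "S", "cug_ser")
CUG_ALA = STANDARD.with_codon("CTG", "A", "cug_ala")
# The CUG-Leu "alternative" is the standard assignment; the alias lets
# callers name it as an inference candidate.
CUG_LEU = GeneticCode("cug_leu", STANDARD.table)

BUILTIN_CODES: dict[str, GeneticCode] = {
    c.name: c for c in (STANDARD, CUG_SER, CUG_ALA, CUG_LEU)
}


def get_code(code: "str | GeneticCode") -> GeneticCode:
    """Resolve a code name or pass a GeneticCode through."""
    if isinstance(code, GeneticCode):
        return code
    try:
        return BUILTIN_CODES[code]
    except KeyError:
        raise KeyError(
            f"unknown genetic code {code!r}; built-ins: {sorted(BUILTIN_CODES)}"
        ) from None


_VALID = set(BASES)


def normalize_dna(seq: str, *, what: str = "sequence") -> str:
    """Uppercase, U→T, and validate the A/C/G/T alphabet."""
    norm = seq.upper().replace("U", "T")
    bad = set(norm) - _VALID
    if bad:
        raise AlphabetError(
            f"{what} contains non-ACGT characters: {sorted(bad)}"
        )
    return norm


@dataclass(frozen=True)
class CodingSequence:
    """A coding sequence read 5'→3', frame 1 assumed.

    Input is case-insensitive and may use U; it is normalized to upper-case
    DNA. Ambiguous bases (N etc.) are rejected rather than guessed at.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "seq", normalize_dna(self.seq, what=f"CDS {self.id!r}")
        )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def n_codons(self) -> int:
        self.require_frame()
        return len(self.seq) // 3

    def require_frame(self) -> None:
        if len(self.seq) % 3 != 0:
            raise FrameError(
                f"CDS {self.id!r} length {len(self.seq)} is not a multiple of 3"
            )

    def codons(self) -> list[str]:
        self.require_frame()
        return [self.seq[i : i + 3] for i in range(0, len(self.seq), 3)]


def _as_cds(cds: "CodingSequence | str") -> CodingSequence:
    if isinstance(cds, CodingSequence):
        return cds
    return CodingSequence(id="<anonymous>", seq=cds)


def translate(cds: "CodingSequence | str", code: "str | GeneticCode") -> str:
    """Translate a CDS under `code`, full length, '*' for every stop codon.

    Internal stops are reported, never raised: marker verification must see
    the complete translation under every candidate code.
    """
    cds = _as_cds(cds)
    code = get_code(code)
    table = code.table
    return "".join(table[c] for c in cds.codons())


def count_codon(cds: "CodingSequence | str", codon: str) -> int:
    """Count in-frame occurrences of `codon`; out-of-frame matches ignored."""
    cds = _as_cds(cds)
    codon = normalize_dna(codon, what="codon")
    if len(codon) != 3:
        raise ValueError(f"codon must be a triplet, got {codon!r}")
    return sum(1 for c in cds.codons() if c == codon)


@dataclass(frozen=True)
class CodonDifference:
    """One codon position translating differently between codes (1-based)."""

    codon_index: int
    codon: str
    residues: Mapping[str, str]  # code name -> amino acid


@dataclass(frozen=True)
class DegeneracyReport:
    """Cross-code degeneracy verdict for one CDS.

    `is_degenerate` is true iff the translation is identical under every
    code compared; `differences` lists each codon position (1-based, codon
    units) where the codes disagree, with the residue under each code.
    """

    cds_id: str
    code_names: tuple[str, ...]
    is_degenerate: bool
    differences: tuple[CodonDifference, ...]

    def to_dict(self) -> dict:
        return {
            "cds_id": self.cds_id,
            "codes": list(self.code_names),
            "is_degenerate": self.is_degenerate,
            "differences": [
                {
                    "codon_index": d.codon_index,
                    "codon": d.codon,
                    "residues": dict(d.residues),
                }
                for d in self.differences
            ],
        }


def degeneracy_report(
    cds: "CodingSequence | str",
    codes: Iterable["str | GeneticCode"],
) -> DegeneracyReport:
    """Compare translate(cds) under each code; report differing positions.

    An empty CDS is vacuously degenerate. Positions are 1-based in codon
    units, matching how biologists count codons.
    """
    cds = _as_cds(cds)
    resolved = [get_code(c) for c in codes]
    if len(resolved) < 2:
        raise ValueError("degeneracy requires at least two genetic codes")
    names = tuple(c.name for c in resolved)
    diffs: list[CodonDifference] = []
    for i, codon in enumerate(cds.codons()):
        residues = {c.name: c.table[codon] for c in resolved}
        if len(set(residues.values())) > 1:
            diffs.append(
                CodonDifference(codon_index=i + 1, codon=codon, residues=residues)
            )
    return DegeneracyReport(
        cds_id=cds.id,
        code_names=names,
        is_degenerate=not diffs,
        differences=tuple(diffs),
    )
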