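"""Codon-usage tables and preferred-codon maps.

A usage table tallies in-frame codon counts pooled across reference coding
sequences (typically a handful of highly expressed genes) and normalizes
them *within synonymous families* — relative synonymous codon usage — under
a chosen genetic code. The one-amino-acid-to-one-codon map consumed by the
recoder simply picks, per amino acid, the most frequent codon that is not
forbidden.

The on-disk dialect is a TSV with header ``codon  amino_acid  count
fraction`` (61–64 rows) and '#'-prefixed comment lines; a best-effort
reader for Kazusa-style whitespace tables is provided separately.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import UsageTableError
from .genetic_codes import (
    ALL_CODONS,
    CodingSequence,
    GeneticCode,
    get_code,
    normalize_dna,
)

__all__ = [
    "CodonUsageTable",
    "build_usage_table",
    "preferred_codon_map",
    "write_usage_tsv",
    "read_usage_tsv",
    "read_kazusa_table",
]


@dataclass(frozen=True)
class CodonUsageTable:
    """Per-codon counts plus per-amino-acid relative frequencies.

    `per_aa_freq[aa][codon]` is the fraction of aa's observed codons that
    are `codon`; fractions within each observed family sum to 1. Stop
    codons are tabulated under '*' but are never substituted downstream.
    """

    counts: Mapping[str, int]
    per_aa_freq: Mapping[str, Mapping[str, float]]
    code_name: str
    source_ids: tuple[str, ...] = ()

    def fraction(self, amino_acid: str, codon: str) -> float:
        return float(self.per_aa_freq.get(amino_acid, {}).get(codon, 0.0))

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())


def build_usage_table(
    cds_set: Sequence[CodingSequence],
    code: "str | GeneticCode",
) -> CodonUsageTable:
    """Tally in-frame codons across `cds_set` and normalize per family.

    Family membership (which amino acid a codon belongs to) follows `code`,
    so under cug_ser the CTG count sits in the serine family.
    """
    if not cds_set:
        raise UsageTableError("cannot build a usage table from zero sequences")
    code = get_code(code)
    counts: Counter[str] = Counter()
    for cds in cds_set:
        counts.update(cds.codons())
    per_aa: dict[str, dict[str, float]] = {}
    for codon, n in counts.items():
        per_aa.setdefault(code.table[codon], {})[codon] = float(n)
    for aa, fam in per_aa.items():
        total = sum(fam.values())
        per_aa[aa] = {c: n / total for c, n in sorted(fam.items())}
    return CodonUsageTable(
        counts=dict(counts),
        per_aa_freq=per_aa,
        code_name=code.name,
        source_ids=tuple(c.id for c in cds_set),
    )


def preferred_codon_map(
    table: CodonUsageTable,
    forbidden: Iterable[str] = (),
    code: "str | GeneticCode | None" = None,
) -> dict[str, str]:
    """One codon per amino acid: highest observed fraction, skipping forbidden.

    Ties break to the lexicographically smallest codon. Amino acids with no
    non-forbidden observations fall back to the lexicographically smallest
    non-forbidden codon of their synonymous family; a family that is
    entirely forbidden raises. Stop ('*') is excluded — stops are never
    substitution targets.
    """
    if not table.counts:
        raise UsageTableError("usage table is empty")
    code = get_code(code if code is not None else table.code_name)
    forbidden = {normalize_dna(c, what="forbidden codon") for c in forbidden}
    preferred: dict[str, str] = {}
    amino_acids = sorted(set(code.table.values()) - {"*"})
    for aa in amino_acids:
        family = code.synonymous_family(aa)
        allowed = [c for c in family if c not in forbidden]
        if not allowed:
            raise UsageTableError(
                f"every synonymous codon of {aa!r} is forbidden"
            )
        observed = {
            c: f for c, f in table.per_aa_freq.get(aa, {}).items() if c in allowed
        }
        if observed:
            # max fraction, ties to lexicographically smallest codon
            preferred[aa] = min(observed, key=lambda c: (-observed[c], c))
        else:
            preferred[aa] = allowed[0]
    return preferred


# ---------------------------------------------------------------------------
# TSV dialect

_HEADER = "codon\tamino_acid\tcount\tfraction"


def write_usage_tsv(table: CodonUsageTable, path, metadata: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# code: {table.code_name}\n")
        if table.source_ids:
            fh.write(f"# sources: {','.join(table.source_ids)}\n")
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write(_HEADER + "\n")
        code = get_code(table.code_name)
        for codon in ALL_CODONS:
            n = table.counts.get(codon, 0)
            if n == 0:
                continue
            aa = code.table[codon]
            frac = table.fraction(aa, codon)
            fh.write(f"{codon}\t{aa}\t{n}\t{frac:.6f}\n")


def read_usage_tsv(path, code: "str | GeneticCode | None" = None) -> CodonUsageTable:
    """Read the TSV dialect written by :func:`write_usage_tsv`.

    Fractions are recomputed from counts so round-trips are exact in the
    quantities that matter downstream.
    """
    counts: dict[str, int] = {}
    code_name = None
    sources: tuple[str, ...] = ()
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    body = []
    for ln in lines:
        if ln.startswith("#"):
            stripped = ln[1:].strip()
            if stripped.startswith("code:"):
                code_name = stripped.split(":", 1)[1].strip()
            elif stripped.startswith("sources:"):
                sources = tuple(
                    s for s in stripped.split(":", 1)[1].strip().split(",") if s
                )
            continue
        if ln.strip():
            body.append(ln)
    if not body:
        raise UsageTableError(f"usage table {path} has no data rows")
    if body[0].split("\t")[:2] != ["codon", "amino_acid"]:
        raise UsageTableError(f"unexpected usage-table header in {path}")
    for ln in body[1:]:
        fields = ln.split("\t")
        if len(fields) < 3:
            raise UsageTableError(f"malformed usage row: {ln!r}")
        codon = normalize_dna(fields[0], what="codon")
        counts[codon] = counts.get(codon, 0) + int(fields[2])
    resolved = get_code(code if code is not None else (code_name or "standard"))
    return _from_counts(counts, resolved, sources)


def _from_counts(
    counts: Mapping[str, int], code: GeneticCode, sources: tuple[str, ...] = ()
) -> CodonUsageTable:
    per_aa: dict[str, dict[str, float]] = {}
    for codon, n in counts.items():
        if n:
            per_aa.setdefault(code.table[codon], {})[codon] = float(n)
    for aa, fam in per_aa.items():
        total = sum(fam.values())
        per_aa[aa] = {c: v / total for c, v in sorted(fam.items())}
    return CodonUsageTable(
        counts={c: int(n) for c, n in counts.items() if n},
        per_aa_freq=per_aa,
        code_name=code.name,
        source_ids=sources,
    )


_KAZUSA_PAIR = re.compile(r"([ACGTU]{3})\s+[\d.]+\s*\(\s*(\d+)\s*\)")


def read_kazusa_table(path, code: "str | GeneticCode" = "standard") -> CodonUsageTable:
    """Best-effort reader for Kazusa-style whitespace tables.

    Expects repeated ``CODON freq/1000 (count)`` groups, RNA or DNA codons.
    Only the raw counts are used; fractions are recomputed under `code`.
    """
    with open(path) as fh:
        text = fh.read()
    pairs = _KAZUSA_PAIR.findall(text)
    if not pairs:
        raise UsageTableError(f"no Kazusa-style codon entries found in {path}")
    counts: dict[str, int] = {}
    for codon, n in pairs:
        codon = normalize_dna(codon, what="codon")
        counts[codon] = counts.get(codon, 0) + int(n)
    return _from_counts(counts, get_code(code))
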