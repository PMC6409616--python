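"""Marker recoding: CTG→TTG replacement, capped one-to-one optimization,
CUG-reintroduction controls, and cross-code verification.

The design problem: a selectable-marker ORF written for standard-code hosts
mistranslates in a CUG-Ser host at every CUG codon. The remedy is a two-step
recode — first swap every in-frame CTG for the synonymous (under the
standard code) TTG, then nudge the remaining codons toward the host's
preferred codon per amino acid, capped at a fixed number of changes. The
result is CUG-free, hence degenerate across the standard, CUG-Ser, and
CUG-Ala nuclear codes. A control gene with the original CUG codons
reintroduced tests whether codon identity (not the optimization) is what
matters in vivo.

Every substitution is recorded (1-based codon index, from, to, reason) so a
recode is auditable and replayable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .codon_usage import CodonUsageTable, preferred_codon_map
from .errors import RecodingError
from .genetic_codes import (
    CUG_ALA,
    CUG_SER,
    STANDARD,
    CodingSequence,
    DegeneracyReport,
    GeneticCode,
    count_codon,
    degeneracy_report,
    get_code,
    normalize_dna,
    translate,
)

__all__ = [
    "Substitution",
    "RecodingResult",
    "VerificationReport",
    "replace_ctg_with_ttg",
    "optimize_one_to_one",
    "reintroduce_cug",
    "verify_recoding",
    "add_homology_hooks",
]

DEGENERACY_CODES = (STANDARD, CUG_SER, CUG_ALA)

REASON_CTG = "ctg_replacement"
REASON_OPT = "usage_optimization"
REASON_REINTRO = "cug_reintroduction"

# Single-codon families plus stop: substitution is vacuous or harmful.
_NEVER_SUBSTITUTE = frozenset({"M", "W", "*"})


@dataclass(frozen=True)
class Substitution:
    """One codon change; `codon_index` is 1-based in codon units."""

    codon_index: int
    from_codon: str
    to_codon: str
    reason: str


@dataclass(frozen=True)
class RecodingResult:
    """A recoded CDS plus the auditable substitution list.

    Applying `substitutions` to `input_seq` reproduces `output_seq` exactly
    (see :meth:`replay`); `verification` is the degeneracy report of the
    output across the standard, CUG-Ser and CUG-Ala codes.
    """

    input_id: str
    input_seq: str
    output_seq: str
    substitutions: tuple[Substitution, ...]
    verification: DegeneracyReport

    @property
    def n_optimization_changes(self) -> int:
        return sum(1 for s in self.substitutions if s.reason == REASON_OPT)

    @property
    def output(self) -> CodingSequence:
        return CodingSequence(id=self.input_id, seq=self.output_seq)

    def replay(self) -> str:
        """Re-apply the substitution list to the input sequence."""
        codons = [
            self.input_seq[i : i + 3] for i in range(0, len(self.input_seq), 3)
        ]
        for sub in self.substitutions:
            idx = sub.codon_index - 1
            if codons[idx] != sub.from_codon:
                raise RecodingError(
                    f"substitution at codon {sub.codon_index} expects "
                    f"{sub.from_codon}, found {codons[idx]}"
                )
            codons[idx] = sub.to_codon
        return "".join(codons)


def _result(
    cds: CodingSequence, codons: list[str], subs: list[Substitution]
) -> RecodingResult:
    out = "".join(codons)
    return RecodingResult(
        input_id=cds.id,
        input_seq=cds.seq,
        output_seq=out,
        substitutions=tuple(subs),
        verification=degeneracy_report(
            CodingSequence(id=cds.id, seq=out), DEGENERACY_CODES
        ),
    )


def replace_ctg_with_ttg(cds: CodingSequence) -> RecodingResult:
    """Swap every in-frame CTG for TTG; nothing else changes.

    CTG→TTG is synonymous under the standard code (both leucine), so the
    donor protein is untouched; out-of-frame CTGs spanning codon
    boundaries are left alone.
    """
    codons = cds.codons()
    subs: list[Substitution] = []
    for i, codon in enumerate(codons):
        if codon == "CTG":
            codons[i] = "TTG"
            subs.append(Substitution(i + 1, "CTG", "TTG", REASON_CTG))
    return _result(cds, codons, subs)


def optimize_one_to_one(
    cds: CodingSequence,
    usage: CodonUsageTable,
    *,
    preferred: Mapping[str, str] | None = None,
    max_changes: int = 25,
    forbidden: Iterable[str] = ("CTG",),
    code: "str | GeneticCode" = CUG_SER,
) -> RecodingResult:
    """One-amino-acid-to-one-codon optimization with a change cap.

    Every codon differing from its amino acid's preferred codon is a
    candidate. Candidates are ranked by frequency gain (preferred fraction
    minus current fraction, descending; ties to the smallest codon index)
    and at most `max_changes` are applied. Positions holding a forbidden
    codon are mandatory and rank first, so the output never contains a
    forbidden codon; if the cap cannot accommodate them, the recode fails
    rather than emit a non-degenerate sequence. Met, Trp and stop codons
    are never substituted. The protein under `code` is preserved.
    """
    if max_changes < 0:
        raise RecodingError("max_changes must be non-negative")
    code = get_code(code)
    forbidden = frozenset(normalize_dna(c, what="forbidden codon") for c in forbidden)
    if preferred is None:
        preferred = preferred_codon_map(usage, forbidden, code=code)
    codons = cds.codons()

    candidates: list[tuple[float, int, str]] = []  # (-gain proxy handled via sort)
    for i, codon in enumerate(codons):
        aa = code.table[codon]
        if aa in _NEVER_SUBSTITUTE:
            if codon in forbidden:
                raise RecodingError(
                    f"forbidden codon {codon} at codon {i + 1} encodes {aa!r} "
                    "and cannot be substituted"
                )
            continue
        if aa not in preferred:
            raise RecodingError(
                f"amino acid {aa!r} (codon {i + 1}) missing from preferred map"
            )
        target = preferred[aa]
        if codon == target:
            continue
        if codon in forbidden:
            gain = math.inf
        else:
            gain = usage.fraction(aa, target) - usage.fraction(aa, codon)
        candidates.append((gain, i, target))

    candidates.sort(key=lambda t: (-t[0], t[1]))
    n_mandatory = sum(1 for g, _, _ in candidates if math.isinf(g))
    if n_mandatory > max_changes:
        raise RecodingError(
            f"{n_mandatory} forbidden codons present but max_changes="
            f"{max_changes}; run replace_ctg_with_ttg first or raise the cap"
        )
    subs: list[Substitution] = []
    for gain, i, target in candidates[:max_changes]:
        subs.append(Substitution(i + 1, codons[i], target, REASON_OPT))
        codons[i] = target
    subs.sort(key=lambda s: s.codon_index)
    return _result(cds, codons, subs)


def reintroduce_cug(
    optimized: CodingSequence, original: CodingSequence
) -> RecodingResult:
    """Put the original's CUG codons back into the optimized sequence.

    Every codon index where `original` has an in-frame CTG is set to CTG in
    the output; all other codons keep their optimized identity. This builds
    the codon-usage control genes (same optimized backbone, original CUG
    positions restored).
    """
    if len(optimized.seq) != len(original.seq):
        raise RecodingError(
            f"length mismatch: optimized {len(optimized.seq)} vs "
            f"original {len(original.seq)}"
        )
    codons = optimized.codons()
    subs: list[Substitution] = []
    for i, orig_codon in enumerate(original.codons()):
        if orig_codon == "CTG" and codons[i] != "CTG":
            subs.append(Substitution(i + 1, codons[i], "CTG", REASON_REINTRO))
            codons[i] = "CTG"
    return _result(optimized, codons, subs)


@dataclass(frozen=True)
class VerificationReport:
    """Did the recode keep the protein, drop all CUGs, and go degenerate?"""

    protein_preserved: bool
    cug_free: bool
    degenerate_all_codes: bool
    intended_protein: str
    recoded_protein: str

    def to_dict(self) -> dict:
        return {
            "protein_preserved": self.protein_preserved,
            "cug_free": self.cug_free,
            "degenerate_all_codes": self.degenerate_all_codes,
        }


def verify_recoding(
    original: CodingSequence,
    recoded: CodingSequence,
    target_code: "str | GeneticCode" = CUG_SER,
    *,
    intended_protein: str | None = None,
) -> VerificationReport:
    """Check a recode end to end.

    `protein_preserved` compares the recoded translation under the target
    (destination-host) code to the intended protein — by default the
    original's standard-code translation, the wild-type donor product.
    """
    if len(original.seq) != len(recoded.seq):
        raise RecodingError("original and recoded sequences differ in length")
    if intended_protein is None:
        intended_protein = translate(original, STANDARD)
    recoded_protein = translate(recoded, get_code(target_code))
    return VerificationReport(
        protein_preserved=recoded_protein == intended_protein,
        cug_free=count_codon(recoded, "CTG") == 0,
        degenerate_all_codes=degeneracy_report(
            recoded, DEGENERACY_CODES
        ).is_degenerate,
        intended_protein=intended_protein,
        recoded_protein=recoded_protein,
    )


def add_homology_hooks(
    marker: str, promoter: str, terminator: str, flank: int = 60
) -> str:
    """Concatenate promoter/terminator homology hooks onto a marker ORF.

    Takes the last `flank` bp of the promoter and the first `flank` bp of
    the terminator (default 60 bp hooks, as used for random-integration
    cassettes).
    """
    marker = normalize_dna(marker, what="marker")
    promoter = normalize_dna(promoter, what="promoter")
    terminator = normalize_dna(terminator, what="terminator")
    if len(promoter) < flank or len(terminator) < flank:
        raise RecodingError(
            f"promoter/terminator must be at least {flank} bp for the hooks"
        )
    return promoter[-flank:] + marker + terminator[:flank]
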