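"""Classify tRNAs with a CAG anticodon as serine- or leucine-type.

A tRNA whose anticodon is CAG reads the codon CUG; whether it charges
serine or leucine decides the species' genetic code. The two isotypes are
distinguishable from sequence-level identity elements: the discriminator
base (position 73, the unpaired nucleotide 5' of the 3'-CCA) is G in
serine tRNAs and A in leucine tRNAs, and both carry a long (type-II)
variable arm, which corroborates but does not discriminate.

Cloverleaf recognition here is a deliberate heuristic — an anticodon-loop
plus closing-stem search using canonical arm geometry — not a covariance
model; genome-wide tRNA scanning is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import NotATRNAError
from .genetic_codes import normalize_dna

__all__ = ["TRNAAnnotation", "TRNAClassification", "annotate_trna", "classify_trna_cag"]

# Watson-Crick plus GU wobble, on the DNA alphabet.
_PAIRS = {
    ("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G"),
}

# Canonical distances from the 3' end used to locate the T-arm:
# acceptor-stem 3' side (7) + T-stem 3' side (5) + T-loop (7) + T-stem 5' (5).
_TSTEM5_FROM_DISCRIMINATOR = 7 + 5 + 7 + 5

MIN_LEN, MAX_LEN = 60, 120


def _paired(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


@dataclass(frozen=True)
class TRNAAnnotation:
    """Landmarks of a putative tRNA.

    `anticodon_span` is 0-based half-open; `discriminator_base` is position
    73 — the unpaired base 5' of the 3'-CCA, or the final base when CCA is
    absent; `variable_arm_length` counts nucleotides between the anticodon
    stem's 3' side and the T-stem's 5' side.
    """

    seq: str
    anticodon_span: tuple[int, int]
    acceptor_stem_pairs: int
    has_cca: bool
    discriminator_base: str
    variable_arm_length: int
    anticodon_stem_pairs: int

    @property
    def anticodon(self) -> str:
        return self.seq[self.anticodon_span[0] : self.anticodon_span[1]]


def annotate_trna(
    seq: str,
    anticodon: str = "CAG",
    *,
    min_stem_pairs: int = 4,
    max_stem_pairs: int = 7,
) -> TRNAAnnotation:
    """Locate the anticodon and derive landmark features.

    The anticodon must occur centered in a 7-nt loop closed by a stem of at
    least `min_stem_pairs` Watson-Crick/GU pairs. Among qualifying
    placements, the longest closing stem wins, ties to the 5'-most. The
    discriminator and variable-arm length follow from canonical arm
    geometry anchored at the located anticodon and the 3' end.
    """
    seq = normalize_dna(seq, what="tRNA")
    anticodon = normalize_dna(anticodon, what="anticodon")
    if not MIN_LEN <= len(seq) <= MAX_LEN:
        raise NotATRNAError(
            f"sequence length {len(seq)} outside the {MIN_LEN}-{MAX_LEN} nt "
            "range expected of a tRNA"
        )
    if seq.endswith("CCA"):
        has_cca = True
        disc_index = len(seq) - 4
    else:
        has_cca = False
        disc_index = len(seq) - 1
    tstem5_start = disc_index - _TSTEM5_FROM_DISCRIMINATOR

    best: "tuple[int, int] | None" = None  # (stem_len, position)
    start = seq.find(anticodon)
    while start != -1:
        p = start
        # 7-nt loop: positions p-2 .. p+4; closing stem pairs (p-3-k, p+5+k)
        stem = 0
        while (
            stem < max_stem_pairs
            and p - 3 - stem >= 0
            and p + 5 + stem < len(seq)
            and _paired(seq[p - 3 - stem], seq[p + 5 + stem])
        ):
            stem += 1
        if stem >= min_stem_pairs:
            var_start = p + 5 + stem
            if tstem5_start >= var_start and (best is None or stem > best[0]):
                best = (stem, p)
        start = seq.find(anticodon, start + 1)

    if best is None:
        raise NotATRNAError(
            f"no {anticodon} anticodon in a 7-nt loop closed by a "
            f">={min_stem_pairs}-pair stem"
        )
    stem_len, p = best

    acceptor = 0
    while (
        acceptor < 7
        and acceptor < disc_index - 1 - acceptor
        and _paired(seq[acceptor], seq[disc_index - 1 - acceptor])
    ):
        acceptor += 1

    return TRNAAnnotation(
        seq=seq,
        anticodon_span=(p, p + 3),
        acceptor_stem_pairs=acceptor,
        has_cca=has_cca,
        discriminator_base=seq[disc_index],
        variable_arm_length=tstem5_start - (p + 5 + stem_len),
        anticodon_stem_pairs=stem_len,
    )


@dataclass(frozen=True)
class TRNAClassification:
    verdict: str  # "ser" | "leu" | "unknown"
    evidence: tuple[str, ...]


def classify_trna_cag(ann: TRNAAnnotation) -> TRNAClassification:
    """Serine- vs leucine-type call for a tRNA with anticodon CAG.

    The discriminator base decides: G → ser, A → leu, anything else →
    unknown. A long (>=10 nt) variable arm is consistent with both type-II
    isotypes and is recorded as corroborating evidence only.
    """
    if ann.anticodon != "CAG":
        raise ValueError(
            f"classify_trna_cag expects anticodon CAG, got {ann.anticodon}"
        )
    disc = ann.discriminator_base
    evidence = [f"discriminator base (position 73) is {disc}"]
    if disc == "G":
        verdict = "ser"
        evidence.append("G73 is the serine-tRNA discriminator identity element")
    elif disc == "A":
        verdict = "leu"
        evidence.append("A73 is the leucine-tRNA discriminator identity element")
    else:
        verdict = "unknown"
        evidence.append("discriminator is neither G (Ser) nor A (Leu)")
    if ann.variable_arm_length >= 10:
        evidence.append(
            f"long variable arm ({ann.variable_arm_length} nt, type II) — "
            "consistent with both Ser and Leu isotypes (corroborating only)"
        )
    return TRNAClassification(verdict=verdict, evidence=tuple(evidence))
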