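"""Seeded synthetic fixtures for every analysis in the toolkit.

Everything the other modules consume can be generated here without any
download: i.i.d. random genomes at a chosen GC, random ORFs, codon-usage
distributions and CDS sets drawn from them, homolog families with a planted
true CUG assignment, cloverleaf tRNAs with planted identity elements, and
genomes with planted integration cassettes. Each generator takes an
explicit seed and is byte-deterministic given it; truth records carry all
planted coordinates so downstream calls can be scored without re-derivation.

The homolog model is deliberately minimal: per column, each homolog shows
the ancestral residue with probability `conservation`, otherwise a uniform
draw over the other 19 residues — the simplest model that creates the
conserved-column signal the code-inference scorer relies on. No
phylogenetic correlation and no sequencing error are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .code_inference import CANDIDATE_RESIDUES, HomologAlignment
from .codon_usage import CodonUsageTable, build_usage_table
from .genetic_codes import (
    ALL_CODONS,
    STANDARD,
    CodingSequence,
    GeneticCode,
    get_code,
)

__all__ = [
    "random_genome",
    "random_orf",
    "random_usage_distribution",
    "generate_cds_set",
    "synthetic_usage_table",
    "FamilySpec",
    "generate_homolog_family",
    "generate_trna",
    "TRNATruth",
    "random_cassette",
    "plant_cassette",
    "InsertionTruth",
]

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
SENSE_CODONS = tuple(c for c in ALL_CODONS if STANDARD.table[c] != "*")


def _rng(seed: "int | np.random.Generator") -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_genome(length: int, gc_fraction: float, seed: "int | np.random.Generator") -> str:
    """I.i.d. random DNA with p(G)=p(C)=gc/2 and p(A)=p(T)=(1-gc)/2."""
    if length < 1:
        raise ValueError("genome length must be >= 1")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError(f"gc_fraction must be in [0,1], got {gc_fraction}")
    rng = _rng(seed)
    p_at = (1.0 - gc_fraction) / 2.0
    p_gc = gc_fraction / 2.0
    idx = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    return _BASE_BYTES[idx].tobytes().decode("ascii")


def random_orf(
    n_codons: int, seed: "int | np.random.Generator", id: str | None = None
) -> CodingSequence:
    """A random ORF: ATG, `n_codons`-2 uniform sense codons, TAA.

    `n_codons` counts every codon including start and stop.
    """
    if n_codons < 2:
        raise ValueError("an ORF needs at least start and stop codons")
    rng = _rng(seed)
    body = rng.choice(len(SENSE_CODONS), size=n_codons - 2)
    seq = "ATG" + "".join(SENSE_CODONS[i] for i in body) + "TAA"
    return CodingSequence(id=id or f"orf_{n_codons}cod", seq=seq)


def random_usage_distribution(
    seed: "int | np.random.Generator", code: "str | GeneticCode" = STANDARD
) -> dict[str, dict[str, float]]:
    """A random per-amino-acid codon distribution (flat Dirichlet per family)."""
    rng = _rng(seed)
    code = get_code(code)
    dist: dict[str, dict[str, float]] = {}
    for aa in sorted(set(code.table.values()) - {"*"}):
        family = code.synonymous_family(aa)
        weights = rng.dirichlet(np.ones(len(family)))
        dist[aa] = {c: float(w) for c, w in zip(family, weights)}
    return dist


def generate_cds_set(
    n_cds: int,
    codons_per_cds: int,
    dist: Mapping[str, Mapping[str, float]],
    seed: "int | np.random.Generator",
    code: "str | GeneticCode" = STANDARD,
) -> list[CodingSequence]:
    """CDSs whose codons are drawn from `dist` for uniformly random proteins."""
    rng = _rng(seed)
    get_code(code)  # validate
    aas = sorted(dist)
    out = []
    for k in range(n_cds):
        codons = []
        for aa_i in rng.choice(len(aas), size=codons_per_cds):
            fam = dist[aas[aa_i]]
            codon_list = sorted(fam)
            probs = np.array([fam[c] for c in codon_list])
            probs = probs / probs.sum()
            codons.append(codon_list[rng.choice(len(codon_list), p=probs)])
        out.append(CodingSequence(id=f"synthcds_{k}", seq="".join(codons)))
    return out


def synthetic_usage_table(
    seed: int,
    code: "str | GeneticCode" = STANDARD,
    n_cds: int = 30,
    codons_per_cds: int = 300,
) -> CodonUsageTable:
    """A usage table built from CDSs sampled off a random usage distribution.

    Emulates the handful-of-highly-expressed-genes tables used to guide
    marker optimization, at a size (9,000 codons) that pins family
    fractions reasonably tightly.
    """
    rng = _rng(seed)
    dist = random_usage_distribution(rng, code)
    cds_set = generate_cds_set(n_cds, codons_per_cds, dist, rng, code)
    return build_usage_table(cds_set, code)


# ---------------------------------------------------------------------------
# Homolog families

@dataclass(frozen=True)
class FamilySpec:
    """Parameters for one synthetic homolog family."""

    seed: int
    n_homologs: int = 20
    protein_length: int = 150
    conservation: float = 0.95
    n_cug_positions: int = 3
    true_code: str = "cug_ser"


def generate_homolog_family(
    spec: FamilySpec,
) -> tuple[HomologAlignment, CodingSequence, str]:
    """Build an (alignment, query CDS, true-code label) triple.

    An ancestral protein is drawn uniformly; at the designated CUG
    positions its residue is forced to whatever CUG encodes under the true
    code (S, L, or A). Homologs are sampled per column at the stated
    conservation. The query CDS back-translates the ancestral protein with
    CTG planted at the CUG positions and a uniformly random synonymous,
    CTG-free codon elsewhere.
    """
    if spec.true_code not in CANDIDATE_RESIDUES:
        raise ValueError(f"true_code must be one of {sorted(CANDIDATE_RESIDUES)}")
    if spec.n_cug_positions > spec.protein_length:
        raise ValueError("more CUG positions than protein columns")
    rng = _rng(spec.seed)
    L = spec.protein_length
    ancestral = [AMINO_ACIDS[i] for i in rng.choice(20, size=L)]
    cug_cols = sorted(rng.choice(L, size=spec.n_cug_positions, replace=False))
    cug_residue = CANDIDATE_RESIDUES[spec.true_code]
    for j in cug_cols:
        ancestral[j] = cug_residue

    homologs = []
    for h in range(spec.n_homologs):
        row = []
        for j in range(L):
            if rng.random() < spec.conservation:
                row.append(ancestral[j])
            else:
                others = [a for a in AMINO_ACIDS if a != ancestral[j]]
                row.append(others[rng.choice(19)])
        homologs.append((f"homolog_{h}", "".join(row)))

    codons = []
    cug_set = set(cug_cols)
    for j, aa in enumerate(ancestral):
        if j in cug_set:
            codons.append("CTG")
        else:
            fam = [c for c in STANDARD.synonymous_family(aa) if c != "CTG"]
            codons.append(fam[rng.choice(len(fam))])
    query = CodingSequence(
        id=f"query_{spec.true_code}_seed{spec.seed}", seq="".join(codons)
    )
    return HomologAlignment(tuple(homologs)), query, spec.true_code


# ---------------------------------------------------------------------------
# tRNAs

@dataclass(frozen=True)
class TRNATruth:
    """Planted landmark coordinates of a generated tRNA."""

    trna_type: str
    anticodon_span: tuple[int, int]
    discriminator_base: str
    discriminator_index: int
    variable_arm_span: tuple[int, int]
    anticodon_stem_pairs: int
    acceptor_stem_pairs: int


_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}
# pairing rule used by the annotator (Watson-Crick + GU), for the
# no-chance-extension check below
_STEM_PAIRS = {
    ("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G"),
}


def _rand_bases(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.choice(4, size=n))


def _wc_revcomp(s: str) -> str:
    return "".join(_WC[b] for b in reversed(s))


def generate_trna(
    trna_type: str,
    seed: "int | np.random.Generator",
    arm_length: int = 14,
    anticodon: str = "CAG",
) -> tuple[str, TRNATruth]:
    """A cloverleaf-consistent tRNA with planted identity elements.

    Layout (5'→3'): 7-bp acceptor stem 5' side, linker, D-arm (4-bp stem,
    8-nt loop), linker, anticodon arm (5-bp stem, 7-nt loop with the
    anticodon centered), variable arm of `arm_length` nt, T-arm (5-bp stem,
    7-nt loop), acceptor stem 3' side, discriminator (G for ser, A for
    leu), CCA. Watson-Crick pairing only in stems. The sequence is
    resampled until the anticodon triplet occurs nowhere else, so landmark
    recovery is unambiguous.
    """
    if trna_type not in ("ser", "leu"):
        raise ValueError("trna_type must be 'ser' or 'leu'")
    if arm_length < 10:
        raise ValueError("type-II variable arms are >=10 nt")
    rng = _rng(seed)
    disc = "G" if trna_type == "ser" else "A"
    for _ in range(200):
        acc5 = _rand_bases(rng, 7)
        link1 = _rand_bases(rng, 2)
        d5 = _rand_bases(rng, 4)
        dloop = _rand_bases(rng, 8)
        link2 = _rand_bases(rng, 1)
        ac5 = _rand_bases(rng, 5)
        acloop = _rand_bases(rng, 2) + anticodon + _rand_bases(rng, 2)
        var = _rand_bases(rng, arm_length)
        t5 = _rand_bases(rng, 5)
        tloop = _rand_bases(rng, 7)
        seq = (
            acc5 + link1 + d5 + dloop + _wc_revcomp(d5) + link2
            + ac5 + acloop + _wc_revcomp(ac5)
            + var
            + t5 + tloop + _wc_revcomp(t5)
            + _wc_revcomp(acc5) + disc + "CCA"
        )
        ac_start = len(acc5 + link1 + d5 + dloop) + 4 + len(link2) + 5 + 2
        # the planted 5-pair anticodon stem must not extend by a chance
        # pairing of its flanking bases (link2 vs first variable-arm base)
        outer_5p, outer_3p = seq[ac_start - 8], seq[ac_start + 10]
        if (outer_5p, outer_3p) in _STEM_PAIRS:
            continue
        if [p for p in range(len(seq) - 2) if seq[p : p + 3] == anticodon] == [ac_start]:
            var_start = ac_start + 5 + 5  # loop tail (2) + stem 3' (5) after anticodon
            truth = TRNATruth(
                trna_type=trna_type,
                anticodon_span=(ac_start, ac_start + 3),
                discriminator_base=disc,
                discriminator_index=len(seq) - 4,
                variable_arm_span=(var_start, var_start + arm_length),
                anticodon_stem_pairs=5,
                acceptor_stem_pairs=7,
            )
            return seq, truth
    raise RuntimeError("could not generate a tRNA with a unique anticodon placement")


# ---------------------------------------------------------------------------
# Cassette planting

@dataclass(frozen=True)
class InsertionTruth:
    """Ground truth for one planted integration."""

    position: int  # insertion point in the wild-type genome (0-based)
    cassette_span: tuple[int, int]  # span in the genome-with-insert
    cassette_length: int


def random_cassette(
    length: int,
    seed: "int | np.random.Generator",
    gc_fraction: float = 0.4,
    forbidden_sites: Sequence[str] = ("GCGC",),
) -> str:
    """A random cassette free of the given recognition sites.

    Occurrences of forbidden sites are mutated away (first base flipped)
    and the sequence rescanned until clean — mirroring how a synthetic
    cassette is designed to survive the digest intact.
    """
    rng = _rng(seed)
    seq = list(random_genome(length, gc_fraction, rng))
    for _ in range(100):
        dirty = False
        s = "".join(seq)
        for site in forbidden_sites:
            i = s.find(site)
            while i != -1:
                seq[i] = "A" if seq[i] != "A" else "T"
                dirty = True
                i = s.find(site, i + 1)
        if not dirty:
            return "".join(seq)
    raise RuntimeError("failed to scrub forbidden sites from cassette")


def plant_cassette(
    genome: str,
    cassette: str,
    position: "int | None" = None,
    seed: "int | np.random.Generator | None" = None,
    avoid_sites: Sequence[str] = (),
) -> tuple[str, InsertionTruth]:
    """Splice a cassette into a genome and record the truth.

    With `position=None` a uniform random insertion point is drawn (seed
    required). When `avoid_sites` is given and the position is random,
    positions whose junctions would create a new recognition-site
    occurrence straddling a cassette boundary are redrawn — the protocol's
    own site-free-cassette condition, enforced in genomic context. An
    explicitly requested position is honored as given.
    """
    if position is not None and not 0 <= position <= len(genome):
        raise ValueError(f"position {position} out of range for genome of {len(genome)} bp")
    rng = _rng(seed) if seed is not None else None

    def splice(pos: int) -> str:
        return genome[:pos] + cassette + genome[pos:]

    if position is not None:
        new = splice(position)
        return new, InsertionTruth(
            position=position,
            cassette_span=(position, position + len(cassette)),
            cassette_length=len(cassette),
        )
    if rng is None:
        raise ValueError("a seed is required when position is not specified")
    for _ in range(100):
        pos = int(rng.integers(0, len(genome) + 1))
        new = splice(pos)
        if not _straddles_boundary(new, pos, pos + len(cassette), avoid_sites):
            return new, InsertionTruth(
                position=pos,
                cassette_span=(pos, pos + len(cassette)),
                cassette_length=len(cassette),
            )
    raise RuntimeError("could not find a junction-clean insertion position")


def _straddles_boundary(
    seq: str, start: int, end: int, sites: Sequence[str]
) -> bool:
    for site in sites:
        k = len(site)
        for b in (start, end):
            lo = max(0, b - k + 1)
            hi = min(len(seq) - k, b - 1)
            for q in range(lo, hi + 1):
                if seq[q : q + k] == site:
                    return True
    return False
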