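"""In-silico restriction digest, inverse PCR, and junction mapping.

The insertion-site protocol: genomic DNA from a transformant carrying an
integrated cassette is digested with a frequent cutter whose recognition
site is absent from the cassette (CfoI, GCGC, expected roughly every 600 bp
at yeast-like GC content), the fragments are self-ligated into circles, and
outward-facing primers inside the cassette amplify around the circle —
yielding the two genomic flanks joined at the re-ligated cut site. Matching
the flank adjacent to a cassette terminus against the genome assembly
locates the insertion.

Coordinates are 0-based half-open internally; reports print 1-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import DigestError, JunctionError
from .genetic_codes import normalize_dna

__all__ = [
    "DigestResult",
    "InversePCRResult",
    "JunctionCall",
    "find_restriction_sites",
    "expected_site_spacing",
    "simulate_inverse_pcr",
    "map_junction",
    "verification_windows",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# CfoI (HhaI isoschizomer) recognizes GCGC and cuts GCG^C: offset 3.
DEFAULT_SITE = "GCGC"
DEFAULT_CUT_OFFSET = 3


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DigestResult:
    """Recognition-site positions and the fragment intervals they induce.

    `site_positions` are sorted 0-based starts of (possibly overlapping)
    recognition-site matches; `fragments` are half-open intervals that
    partition the sequence. On a circular sequence the wrap-around fragment
    is stored with ``end > sequence_length``; take its sequence from the
    doubled string.
    """

    site_positions: tuple[int, ...]
    fragments: tuple[tuple[int, int], ...]
    circular: bool
    cut_offset: int
    sequence_length: int

    def fragment_sequences(self, seq: str) -> list[str]:
        doubled = seq + seq
        return [doubled[a:b] for a, b in self.fragments]

    def mean_spacing(self) -> float:
        """Mean distance between consecutive site starts (needs >=2 sites)."""
        if len(self.site_positions) < 2:
            return math.nan
        diffs = [
            b - a for a, b in zip(self.site_positions, self.site_positions[1:])
        ]
        return sum(diffs) / len(diffs)


def _find_all(haystack: str, needle: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)  # overlapping occurrences allowed
    return out


def find_restriction_sites(
    seq: str,
    site: str = DEFAULT_SITE,
    circular: bool = False,
    cut_offset: int = DEFAULT_CUT_OFFSET,
) -> DigestResult:
    """Locate all occurrences of a fixed-literal recognition site.

    Overlapping occurrences are all reported. In circular mode, sites
    spanning the origin are detected too. Cutting happens `cut_offset`
    bases into the site; fragments are derived from the cut positions.
    Degenerate-base sites are unsupported.
    """
    seq = normalize_dna(seq, what="sequence")
    site_norm = site.upper().replace("U", "T")
    if set(site_norm) - set("ACGT"):
        raise DigestError(
            f"recognition site {site!r} contains degenerate bases; only "
            "fixed-literal A/C/G/T sites are supported"
        )
    if not 0 <= cut_offset <= len(site_norm):
        raise DigestError(f"cut offset {cut_offset} outside site of length {len(site_norm)}")
    L = len(seq)
    if circular:
        scan = seq + seq[: len(site_norm) - 1]
        positions = [p for p in _find_all(scan, site_norm) if p < L]
    else:
        positions = _find_all(seq, site_norm)
    positions.sort()

    cuts = sorted({(p + cut_offset) % L if circular else p + cut_offset for p in positions})
    fragments: list[tuple[int, int]] = []
    if circular:
        if not cuts:
            fragments = [(0, L)] if L else []
        else:
            for a, b in zip(cuts, cuts[1:]):
                fragments.append((a, b))
            fragments.append((cuts[-1], cuts[0] + L))  # wrap-around fragment
    else:
        prev = 0
        for c in cuts:
            fragments.append((prev, c))
            prev = c
        fragments.append((prev, L))
    return DigestResult(
        site_positions=tuple(positions),
        fragments=tuple(fragments),
        circular=circular,
        cut_offset=cut_offset,
        sequence_length=L,
    )


def expected_site_spacing(gc_fraction: float, site: str = DEFAULT_SITE) -> float:
    """Expected distance between site occurrences under an i.i.d. base model.

    Each base is drawn independently with p(G)=p(C)=gc/2 and
    p(A)=p(T)=(1-gc)/2; the expected spacing is the reciprocal of the
    per-position occurrence probability, ``1 / prod_b p(b)``. Returns
    ``inf`` when the site is impossible at the given GC.
    """
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError(f"gc_fraction must be in [0,1], got {gc_fraction}")
    site = site.upper().replace("U", "T")
    if set(site) - set("ACGT"):
        raise DigestError(f"degenerate bases in site {site!r} unsupported")
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    prob = 1.0
    for b in site:
        prob *= p_gc if b in "GC" else p_at
    return math.inf if prob == 0.0 else 1.0 / prob


@dataclass(frozen=True)
class InversePCRResult:
    """Outcome of a simulated digest/circularize/inverse-PCR run.

    `amplicon` is cassette tail + downstream flank + (re-ligated junction) +
    upstream flank + cassette head. Flanks run from the cassette boundary to
    the nearest cut on each side.
    """

    amplicon: str
    fragment: tuple[int, int]
    left_flank: str
    right_flank: str


def simulate_inverse_pcr(
    genome_with_insert: str,
    cassette_span: tuple[int, int],
    site: str = DEFAULT_SITE,
    primers: "tuple[str, str] | None" = None,
    *,
    cut_offset: int = DEFAULT_CUT_OFFSET,
    primer_length: int = 20,
) -> InversePCRResult:
    """Digest, circularize the cassette-bearing fragment, amplify outward.

    `primers` is (forward, reverse): the forward primer is a sense-strand
    substring of the cassette pointing toward its 3' end; the reverse primer
    is the reverse complement of a cassette substring near the 5' end. By
    default the terminal `primer_length` bases of the cassette serve as
    primers. The cassette must not contain the recognition site — the same
    condition the wet protocol imposes — and both primer binding sites must
    survive the digest on one fragment.
    """
    genome_with_insert = normalize_dna(genome_with_insert, what="genome")
    a, b = cassette_span
    if not 0 <= a < b <= len(genome_with_insert):
        raise DigestError(f"cassette span {cassette_span} out of range")
    cassette = genome_with_insert[a:b]
    site_norm = site.upper().replace("U", "T")
    internal = _find_all(cassette, site_norm)
    if internal:
        raise DigestError(
            f"cassette contains recognition site {site_norm} at cassette "
            f"position {internal[0]} (genome position {a + internal[0]}); "
            "inverse PCR requires a site-free cassette"
        )

    if primers is None:
        if len(cassette) < 2 * primer_length:
            raise DigestError("cassette too short for default outward primers")
        fwd = cassette[-primer_length:]
        rev = revcomp(cassette[:primer_length])
    else:
        fwd, rev = (normalize_dna(p, what="primer") for p in primers)
    f_off = cassette.rfind(fwd)
    r_off = cassette.find(revcomp(rev))
    if f_off == -1 or r_off == -1:
        raise DigestError("primer(s) not found within the cassette")
    rev_end = r_off + len(rev)
    if f_off < rev_end:
        raise DigestError(
            "primers are not outward-oriented (forward primer must lie 3' "
            "of the reverse primer's binding site)"
        )

    digest = find_restriction_sites(
        genome_with_insert, site_norm, circular=False, cut_offset=cut_offset
    )
    fwd_abs = a + f_off
    containing = None
    for fs, fe in digest.fragments:
        if fs <= fwd_abs and fwd_abs + len(fwd) <= fe:
            containing = (fs, fe)
            break
    if containing is None:
        raise DigestError("forward primer site destroyed by the digest")
    fs, fe = containing
    rev_abs = a + r_off
    if not (fs <= rev_abs and rev_abs + len(rev) <= fe):
        raise DigestError(
            "a cut separates the primer binding sites; no circular template"
        )

    circle = genome_with_insert[fs:fe]
    fwd_pos = fwd_abs - fs
    rev_end_pos = rev_abs + len(rev) - fs
    amplicon = circle[fwd_pos:] + circle[:rev_end_pos]
    return InversePCRResult(
        amplicon=amplicon,
        fragment=(fs, fe),
        left_flank=genome_with_insert[fs:a],
        right_flank=genome_with_insert[b:fe],
    )


@dataclass(frozen=True)
class JunctionCall:
    """A mapped insertion locus.

    `locus` is (contig id, 0-based insertion point, strand); the insertion
    point is the genomic coordinate of the base immediately following the
    integration site in the wild-type assembly. Status is ``unique`` iff
    exactly one genomic placement of the flank exists at `min_flank` length.
    """

    locus: "tuple[str, int, str] | None"
    flank_length_matched: int
    status: str  # "unique" | "ambiguous" | "unmapped"


def _as_contigs(genome: "str | Mapping[str, str] | Sequence[tuple[str, str]]") -> dict[str, str]:
    if isinstance(genome, str):
        return {"genome": normalize_dna(genome, what="genome")}
    if isinstance(genome, Mapping):
        return {k: normalize_dna(v, what=f"contig {k}") for k, v in genome.items()}
    return {k: normalize_dna(v, what=f"contig {k}") for k, v in genome}


def _count_matches(
    pattern: str, contigs: Mapping[str, str], max_mismatches: int
) -> list[tuple[str, int, str]]:
    """All placements of `pattern` (either strand) with <= max_mismatches."""
    hits: list[tuple[str, int, str]] = []
    for strand, pat in (("+", pattern), ("-", revcomp(pattern))):
        for cid, seq in contigs.items():
            if max_mismatches == 0:
                for p in _find_all(seq, pat):
                    hits.append((cid, p, strand))
            else:
                k = len(pat)
                for p in range(len(seq) - k + 1):
                    mm = 0
                    window = seq[p : p + k]
                    for x, y in zip(window, pat):
                        if x != y:
                            mm += 1
                            if mm > max_mismatches:
                                break
                    if mm <= max_mismatches:
                        hits.append((cid, p, strand))
    return hits


def _extend_match(flank: str, contig: str, pos: int, strand: str, from_end: bool) -> int:
    """Greedy extension of an anchored exact match, returns matched length."""
    if strand == "+":
        if not from_end:
            m = 0
            while m < len(flank) and pos + m < len(contig) and contig[pos + m] == flank[m]:
                m += 1
            return m
        m = 0
        while (
            m < len(flank)
            and pos - 1 - m >= 0
            and contig[pos - 1 - m] == flank[len(flank) - 1 - m]
        ):
            m += 1
        return m
    rc = revcomp(flank)
    if not from_end:
        # flank prefix == revcomp of contig ending at pos
        m = 0
        while m < len(rc) and pos - 1 - m >= 0 and contig[pos - 1 - m] == rc[len(rc) - 1 - m]:
            m += 1
        return m
    m = 0
    while m < len(rc) and pos + m < len(contig) and contig[pos + m] == rc[m]:
        m += 1
    return m


def map_junction(
    junction_seq: str,
    genome: "str | Mapping[str, str] | Sequence[tuple[str, str]]",
    cassette_seq: str,
    min_flank: int = 20,
    *,
    max_mismatches: int = 0,
    terminus_length: int = 20,
) -> JunctionCall:
    """Locate the insertion point from a cassette-genome junction sequence.

    The cassette portion is stripped by finding a cassette terminus
    (`terminus_length` bp) in the junction; the adjacent genomic flank is
    exact-matched (both strands; optionally with mismatches) against the
    genome. The flank immediately 3' of the cassette tail is tried first,
    falling back to the flank 5' of the cassette head. Status follows the
    number of genomic placements of the first `min_flank` bases.
    """
    junction = normalize_dna(junction_seq, what="junction")
    cassette = normalize_dna(cassette_seq, what="cassette")
    contigs = _as_contigs(genome)
    if len(cassette) < terminus_length:
        raise JunctionError("cassette shorter than the terminus probe length")

    tail = cassette[-terminus_length:]
    head = cassette[:terminus_length]
    i_tail = junction.find(tail)
    i_head = junction.rfind(head)
    if i_tail == -1 and i_head == -1:
        raise JunctionError(
            "junction sequence contains neither cassette terminus; cannot "
            "strip the cassette portion"
        )

    attempts: list[tuple[str, bool]] = []  # (flank, anchored_at_end)
    if i_tail != -1:
        attempts.append((junction[i_tail + len(tail) :], False))
    if i_head != -1:
        attempts.append((junction[:i_head], True))

    best_ambiguous = None
    for flank, from_end in attempts:
        if len(flank) < min_flank:
            continue
        probe = flank[-min_flank:] if from_end else flank[:min_flank]
        hits = _count_matches(probe, contigs, max_mismatches)
        if len(hits) == 1:
            cid, pos, strand = hits[0]
            if from_end:
                # flank's 3' end abuts the cassette head: insertion point is
                # the coordinate just past the matched probe.
                anchor = pos + min_flank if strand == "+" else pos
                matched = _extend_match(flank, contigs[cid], anchor, strand, True)
                point = anchor if strand == "+" else anchor  # anchor is the point
            else:
                anchor = pos if strand == "+" else pos + min_flank
                matched = _extend_match(flank, contigs[cid], anchor, strand, False)
                point = anchor
            return JunctionCall(
                locus=(cid, point, strand),
                flank_length_matched=matched,
                status="unique",
            )
        if len(hits) > 1:
            best_ambiguous = JunctionCall(
                locus=None, flank_length_matched=min_flank, status="ambiguous"
            )
    if best_ambiguous is not None:
        return best_ambiguous
    return JunctionCall(locus=None, flank_length_matched=0, status="unmapped")


@dataclass(frozen=True)
class VerificationWindows:
    """Flanking primer windows for secondary verification of an insertion.

    Windows of `window` bp immediately upstream and downstream of the
    insertion point; primers placed there produce a `2*window` product on
    the empty (wild-type) site and `2*window + cassette_length` when the
    cassette is present.
    """

    contig: str
    upstream: tuple[int, int]
    downstream: tuple[int, int]
    upstream_seq: str
    downstream_seq: str
    product_size_wildtype: int
    product_size_insertion: int


def verification_windows(
    genome: "str | Mapping[str, str] | Sequence[tuple[str, str]]",
    contig: str,
    position: int,
    cassette_length: int,
    window: int = 150,
) -> VerificationWindows:
    """Report the ±`window` bp verification windows around an insertion."""
    contigs = _as_contigs(genome)
    if contig not in contigs:
        raise JunctionError(f"contig {contig!r} not in genome")
    seq = contigs[contig]
    if position - window < 0 or position + window > len(seq):
        raise JunctionError(
            f"verification window of {window} bp does not fit around "
            f"position {position} on contig {contig!r}"
        )
    return VerificationWindows(
        contig=contig,
        upstream=(position - window, position),
        downstream=(position, position + window),
        upstream_seq=seq[position - window : position],
        downstream_seq=seq[position : position + window],
        product_size_wildtype=2 * window,
        product_size_insertion=2 * window + cassette_length,
    )
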