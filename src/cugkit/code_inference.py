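"""Infer how a species decodes CUG from conserved-column evidence.

The idea: translate a query CDS, align it against a set of homologous
proteins, and ask which residue the homologs show at the columns where the
query has a CUG codon. If those columns are dominated by serine, the query
species almost certainly decodes CUG as serine; leucine columns imply the
standard code; alanine columns the CUG-Ala clade.

That qualitative argument is formalized here as an additive log-probability
score. The query is translated with CTG masked as 'X' (so the unknown
residue cannot bias its own placement), globally aligned to the homolog
profile with affine gaps, and each CUG-bearing column contributes

    log[(count(residue implied by candidate) + pseudocount)
        / (depth + 20 * pseudocount)]

to each candidate code's score. The winner is called only when it leads the
runner-up by a configurable margin (in nats); otherwise the verdict is
indeterminate — the scorer may abstain but must not guess.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .errors import InferenceError
from .genetic_codes import CodingSequence, STANDARD

__all__ = [
    "HomologAlignment",
    "CodeCall",
    "align_query_to_profile",
    "infer_code",
    "CANDIDATE_RESIDUES",
]

# Residue implied at a CUG position under each candidate code.
CANDIDATE_RESIDUES: dict[str, str] = {
    "cug_ser": "S",
    "cug_leu": "L",
    "cug_ala": "A",
}

GAP = "-"
N_AMINO_ACIDS = 20  # pseudocount denominator: 20 possible residues

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = str(_BLOSUM62.alphabet)


@dataclass(frozen=True)
class HomologAlignment:
    """A pre-aligned set of homologous protein sequences.

    All rows must share one length (`n_columns`); gaps are '-'. Typically
    built from the aligned top hits of a homology search.
    """

    sequences: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise InferenceError("a homolog alignment needs at least 2 sequences")
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) != 1:
            raise InferenceError(
                f"aligned sequences have unequal lengths: {sorted(lengths)}"
            )
        object.__setattr__(
            self,
            "sequences",
            tuple((sid, seq.upper()) for sid, seq in self.sequences),
        )

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0][1])

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def column_counts(self) -> list[Counter]:
        """Per-column residue counts, gaps excluded."""
        cols: list[Counter] = [Counter() for _ in range(self.n_columns)]
        for _, seq in self.sequences:
            for j, res in enumerate(seq):
                if res != GAP:
                    cols[j][res] += 1
        return cols

    def gap_fractions(self) -> list[float]:
        n = self.n_sequences
        counts = self.column_counts()
        return [1.0 - sum(c.values()) / n for c in counts]

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "HomologAlignment":
        return cls(sequences=tuple(records))


def _profile_score_matrix(alignment: HomologAlignment) -> np.ndarray:
    """Expected BLOSUM62 score of each alphabet letter vs each column.

    Entry [j, a] = sum_r freq_jr * blosum62(a, r) over non-gap residues r of
    column j. 'X' is forced to 0 against every column so a masked query
    residue is placement-neutral.
    """
    counts = alignment.column_counts()
    n_cols = alignment.n_columns
    expected = np.zeros((n_cols, len(_ALPHABET)), dtype=float)
    index = {a: i for i, a in enumerate(_ALPHABET)}
    for j, col in enumerate(counts):
        depth = sum(col.values())
        if depth == 0:
            continue
        for res, n in col.items():
            if res not in index:
                continue
            w = n / depth
            for a_i, a in enumerate(_ALPHABET):
                expected[j, a_i] += w * _BLOSUM62[a, res]
    if "X" in index:
        expected[:, index["X"]] = 0.0
    return expected


def align_query_to_profile(
    query_protein: str,
    alignment: HomologAlignment,
    *,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> list["int | None"]:
    """Global (Needleman–Wunsch/Gotoh) alignment of a query to the profile.

    Substitution score is the expected BLOSUM62 score of the query residue
    against the column's residue frequencies; gaps are affine. Returns, per
    query residue index, the aligned column index or None; the mapping is
    strictly increasing over aligned positions. Traceback ties prefer
    match over a gap in the profile over a gap in the query, making the
    result deterministic.
    """
    if not query_protein:
        raise InferenceError("empty query protein")
    query = query_protein.upper()
    expected = _profile_score_matrix(alignment)
    index = {a: i for i, a in enumerate(_ALPHABET)}
    try:
        q_idx = [index[r] for r in query]
    except KeyError as exc:
        raise InferenceError(f"query residue {exc} not in BLOSUM62 alphabet")
    m, n = len(query), alignment.n_columns

    NEG = -math.inf
    # M: q_i aligned to col_j; IX: q_i vs gap (column skipped in profile? no:
    # IX consumes query, gap in profile); IY consumes a column, gap in query.
    M = np.full((m + 1, n + 1), NEG)
    IX = np.full((m + 1, n + 1), NEG)
    IY = np.full((m + 1, n + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        IX[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, n + 1):
        IY[0, j] = -gap_open - (j - 1) * gap_extend

    # traceback pointers: 0=M,1=IX,2=IY
    ptr_M = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptr_IX = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptr_IY = np.zeros((m + 1, n + 1), dtype=np.int8)

    S = expected[:, q_idx]  # S[j-1, i-1]
    for i in range(1, m + 1):
        Mi1, Mi, IXi1, IXi, IYi1, IYi = M[i - 1], M[i], IX[i - 1], IX[i], IY[i - 1], IY[i]
        si = S[:, i - 1]
        for j in range(1, n + 1):
            s = si[j - 1]
            best, arg = Mi1[j - 1], 0
            if IXi1[j - 1] > best:
                best, arg = IXi1[j - 1], 1
            if IYi1[j - 1] > best:
                best, arg = IYi1[j - 1], 2
            Mi[j] = best + s
            ptr_M[i, j] = arg

            open_x = Mi1[j] - gap_open
            ext_x = IXi1[j] - gap_extend
            if open_x >= ext_x:
                IXi[j], ptr_IX[i, j] = open_x, 0
            else:
                IXi[j], ptr_IX[i, j] = ext_x, 1

            open_y = Mi[j - 1] - gap_open
            ext_y = IYi[j - 1] - gap_extend
            if open_y >= ext_y:
                IYi[j], ptr_IY[i, j] = open_y, 0
            else:
                IYi[j], ptr_IY[i, j] = ext_y, 2

    mapping: list["int | None"] = [None] * m
    i, j = m, n
    state = int(np.argmax([M[m, n], IX[m, n], IY[m, n]]))
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
            continue
        if j == 0:
            i -= 1
            continue
        if state == 0:
            mapping[i - 1] = j - 1
            state = int(ptr_M[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            state = int(ptr_IX[i, j])
            i -= 1
        else:
            state = int(ptr_IY[i, j])
            j -= 1
    return mapping


@dataclass(frozen=True)
class CodeCall:
    """Result of a CUG-decoding inference.

    `cug_positions` are 1-based codon indices of in-frame CTGs in the query;
    `column_profiles` gives, per position, the homolog residue counts of the
    aligned column (None when the position was unaligned or the column was
    excluded); `scores` are the per-candidate log-scores; `verdict` is one
    of the candidate names or ``indeterminate``.
    """

    cug_positions: tuple[int, ...]
    column_profiles: tuple["Mapping[str, int] | None", ...]
    scores: Mapping[str, float]
    verdict: str
    margin: float

    def to_dict(self) -> dict:
        return {
            "cug_positions": list(self.cug_positions),
            "column_profiles": [
                dict(p) if p is not None else None for p in self.column_profiles
            ],
            "scores": dict(self.scores),
            "verdict": self.verdict,
            "margin": self.margin,
        }


def infer_code(
    query_cds: CodingSequence,
    alignment: HomologAlignment,
    candidates: "Iterable[str] | Mapping[str, str]" = ("cug_ser", "cug_leu", "cug_ala"),
    *,
    pseudocount: float = 1.0,
    margin: float = 2.0,
    max_gap_fraction: float = 0.5,
) -> CodeCall:
    """Score candidate CUG assignments from homolog-column evidence.

    The query is translated with CTG masked as 'X', aligned to the profile,
    and every aligned CUG column (unless more than `max_gap_fraction` of
    homologs are gapped there) contributes
    ``log((count + pseudocount) / (depth + 20*pseudocount))`` to each
    candidate. The verdict is the top candidate only if it leads the
    runner-up by at least `margin` nats; with no usable CUG evidence the
    verdict is indeterminate.
    """
    if isinstance(candidates, Mapping):
        cand_res = dict(candidates)
    else:
        try:
            cand_res = {name: CANDIDATE_RESIDUES[name] for name in candidates}
        except KeyError as exc:
            raise InferenceError(
                f"unknown candidate code {exc}; known: {sorted(CANDIDATE_RESIDUES)}"
            )
    if not cand_res:
        raise InferenceError("at least one candidate code is required")
    if pseudocount <= 0:
        raise InferenceError("pseudocount must be positive")

    codons = query_cds.codons()
    cug_positions = tuple(i + 1 for i, c in enumerate(codons) if c == "CTG")
    scores = {name: 0.0 for name in cand_res}

    if not cug_positions:
        return CodeCall(
            cug_positions=(),
            column_profiles=(),
            scores=scores,
            verdict="indeterminate",
            margin=margin,
        )

    masked = "".join(
        "X" if codon == "CTG" else STANDARD.table[codon] for codon in codons
    )
    mapping = align_query_to_profile(masked, alignment)
    counts = alignment.column_counts()
    gap_frac = alignment.gap_fractions()

    profiles: list["Mapping[str, int] | None"] = []
    n_scored = 0
    for pos in cug_positions:
        j = mapping[pos - 1]
        if j is None or gap_frac[j] > max_gap_fraction:
            profiles.append(None)
            continue
        col = counts[j]
        depth = sum(col.values())
        profiles.append(dict(col))
        n_scored += 1
        denom = depth + N_AMINO_ACIDS * pseudocount
        for name, res in cand_res.items():
            scores[name] += math.log((col.get(res, 0) + pseudocount) / denom)

    if n_scored == 0:
        verdict = "indeterminate"
    elif len(scores) == 1:
        verdict = next(iter(scores))
    else:
        ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        verdict = (
            ranked[0][0] if ranked[0][1] - ranked[1][1] >= margin else "indeterminate"
        )
    return CodeCall(
        cug_positions=cug_positions,
        column_profiles=tuple(profiles),
        scores=scores,
        verdict=verdict,
        margin=margin,
    )
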