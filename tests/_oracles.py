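"""Independent oracles used by the test suite.

These are deliberately separate implementations: a hand-typed standard
genetic-code table (not derived from Biopython or the library), and a
brute-force enumerator of global profile alignments for tiny inputs.
"""

from __future__ import annotations

from collections import Counter

# Hand-typed standard nuclear code, one family per line.
STANDARD_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

CUG_SER_TABLE = {**STANDARD_TABLE, "CTG": "S"}
CUG_ALA_TABLE = {**STANDARD_TABLE, "CTG": "A"}

ORACLE_TABLES = {
    "standard": STANDARD_TABLE,
    "cug_ser": CUG_SER_TABLE,
    "cug_ala": CUG_ALA_TABLE,
}


def oracle_translate(seq: str, code_name: str) -> str:
    """Plain per-codon lookup against the hand-typed tables."""
    table = ORACLE_TABLES[code_name]
    return "".join(table[seq[i : i + 3]] for i in range(0, len(seq), 3))


# ---------------------------------------------------------------------------
# Brute-force global profile alignment on tiny inputs.
#
# Enumerates every monotone path of D/X/Y moves from (0,0) to (m,n), where
# D aligns query residue i to column j, X puts the query residue against a
# gap, Y skips a column. Affine gaps: each maximal run of X (or Y) moves
# costs open + (len-1)*extend. Matching the Gotoh recurrence used by the
# library, a gap run in one direction may not directly abut one in the
# other direction (the DP passes through the match state between them).


def brute_force_align(score, m: int, n: int, gap_open: float, gap_extend: float):
    """Return (best_score, best_mapping) over all admissible paths.

    `score(i, j)` gives the substitution score of query residue i against
    column j (both 0-based). Ties resolve to the first-found path, so use
    toys with a unique optimum when asserting mappings.
    """
    best = [float("-inf"), None]

    def rec(i, j, acc, last_move, mapping):
        if i == m and j == n:
            if acc > best[0]:
                best[0] = acc
                best[1] = list(mapping)
            return
        if i < m and j < n:
            mapping[i] = j
            rec(i + 1, j + 1, acc + score(i, j), "D", mapping)
            mapping[i] = None
        if i < m and last_move != "Y":
            cost = gap_extend if last_move == "X" else gap_open
            rec(i + 1, j, acc - cost, "X", mapping)
        if j < n and last_move != "X":
            cost = gap_extend if last_move == "Y" else gap_open
            rec(i, j + 1, acc - cost, "Y", mapping)

    rec(0, 0, 0.0, "D", [None] * m)
    return best[0], best[1]


def profile_counts(rows):
    """Per-column residue counts (gaps excluded) for aligned rows."""
    n = len(rows[0])
    cols = [Counter() for _ in range(n)]
    for row in rows:
        for j, r in enumerate(row):
            if r != "-":
                cols[j][r] += 1
    return cols
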