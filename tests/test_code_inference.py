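"""Profile alignment and CUG-assignment scoring."""

import math

import pytest

from cugkit.code_inference import (
    HomologAlignment,
    _profile_score_matrix,
    _ALPHABET,
    align_query_to_profile,
    infer_code,
)
from cugkit.errors import InferenceError
from cugkit.genetic_codes import CodingSequence
from cugkit.synthetic_data import FamilySpec, generate_homolog_family

from _oracles import brute_force_align


def aln(*rows):
    return HomologAlignment(tuple((f"h{i}", r) for i, r in enumerate(rows)))


class TestHomologAlignment:
    def test_unequal_lengths_rejected(self):
        with pytest.raises(InferenceError):
            aln("MKL", "MK")

    def test_needs_two_sequences(self):
        with pytest.raises(InferenceError):
            HomologAlignment((("only", "MKL"),))

    def test_column_counts_exclude_gaps(self):
        a = aln("MK-", "MKL", "M-L")
        counts = a.column_counts()
        assert counts[0] == {"M": 3}
        assert counts[1] == {"K": 2}
        assert counts[2] == {"L": 2}
        assert a.gap_fractions() == pytest.approx([0.0, 1 / 3, 1 / 3])


class TestAlignQueryToProfile:
    def test_identity_mapping_for_exact_member(self):
        a = aln("MKLVST", "MKLVST", "MKIVST")
        mapping = align_query_to_profile("MKLVST", a)
        assert mapping == [0, 1, 2, 3, 4, 5]

    def test_internal_deletion_skips_exactly_one_column(self):
        a = aln("MKLVST", "MKLVST")
        mapping = align_query_to_profile("MKVST", a)
        assert mapping == [0, 1, 3, 4, 5]

    def test_mapping_strictly_increasing(self):
        a = aln("MKLVSTWY", "MKIVSTWY", "MQLVSTFY")
        mapping = align_query_to_profile("MKLVTWY", a)
        aligned = [j for j in mapping if j is not None]
        assert aligned == sorted(aligned) and len(set(aligned)) == len(aligned)

    @pytest.mark.parametrize(
        "rows,query",
        [
            (("MKLVST", "MKIVST", "MKLVST"), "MKLVST"),
            (("MKLVST", "MKIVST", "MKLVST"), "MKVST"),    # deletion
            (("MKLVS", "MKIVS"), "MKLWVS"),               # insertion
            (("ACDEF", "ACDEF", "ACQEF"), "ADEF"),
            (("MKYWS", "MKFWS"), "MKXWS"),                # masked residue
        ],
    )
    def test_matches_brute_force_enumeration_on_toys(self, rows, query):
        a = aln(*rows)
        expected = _profile_score_matrix(a)
        idx = {ch: i for i, ch in enumerate(_ALPHABET)}

        def score(i, j):
            return expected[j, idx[query[i]]]

        best_score, best_mapping = brute_force_align(
            score, len(query), a.n_columns, gap_open=11.0, gap_extend=1.0
        )
        mapping = align_query_to_profile(query, a)
        dp_score = sum(
            score(i, j) for i, j in enumerate(mapping) if j is not None
        )
        # reconstruct gap penalties of the DP's path for a fair comparison
        dp_total = _path_score(mapping, a.n_columns, score)
        assert dp_total == pytest.approx(best_score)
        assert mapping == best_mapping

    def test_empty_query_rejected(self):
        with pytest.raises(InferenceError):
            align_query_to_profile("", aln("MK", "MK"))


def _path_score(mapping, n_columns, score, gap_open=11.0, gap_extend=1.0):
    """Score an alignment mapping with affine gap costs (oracle convention)."""
    total = 0.0
    moves = []
    prev_col = -1
    for i, j in enumerate(mapping):
        if j is None:
            moves.append(("X", i, None))
        else:
            for skipped in range(prev_col + 1, j):
                moves.append(("Y", None, skipped))
            moves.append(("D", i, j))
            prev_col = j
    for skipped in range(prev_col + 1, n_columns):
        moves.append(("Y", None, skipped))
    run = None
    for kind, i, j in moves:
        if kind == "D":
            total += score(i, j)
            run = None
        else:
            total -= gap_extend if run == kind else gap_open
            run = kind
    return total


class TestInferCode:
    def _family(self, column_residue, n=30, n_cols=5, cug_col=2):
        rows = []
        for _ in range(n):
            row = list("MKVST"[:n_cols])
            row[cug_col] = column_residue
            rows.append("".join(row))
        return aln(*rows)

    def test_conserved_serine_column_calls_cug_ser(self):
        a = self._family("S")
        query = CodingSequence("q", "ATGAAACTGTCTACT")  # M K (CTG) S T
        call = infer_code(query, a)
        assert call.verdict == "cug_ser"
        assert call.cug_positions == (3,)

    def test_conserved_leucine_column_calls_cug_leu(self):
        a = self._family("L")
        query = CodingSequence("q", "ATGAAACTGTCTACT")
        assert infer_code(query, a).verdict == "cug_leu"

    def test_ctg_free_query_is_indeterminate(self):
        a = self._family("S")
        query = CodingSequence("q", "ATGAAATCTTCTACT")
        call = infer_code(query, a)
        assert call.verdict == "indeterminate" and call.cug_positions == ()

    def test_hand_computed_score_margin(self):
        # column {S:28, T:2}, depth 30, pseudocount 1:
        # score(ser) - score(leu) = ln(29/50) - ln(1/50) = ln 29
        rows = ["MKSST"] * 28 + ["MKTST"] * 2
        a = aln(*rows)
        query = CodingSequence("q", "ATGAAACTGTCTACT")
        call = infer_code(query, a)
        diff = call.scores["cug_ser"] - call.scores["cug_leu"]
        assert diff == pytest.approx(math.log(29))
        assert call.scores["cug_ser"] == pytest.approx(math.log(29 / 50))
        assert call.verdict == "cug_ser"  # ln 29 ~ 3.37 >= 2.0 margin

    def test_margin_below_threshold_abstains(self):
        # evenly split S/L column cannot separate the candidates
        rows = ["MKSST"] * 15 + ["MKLST"] * 15
        a = aln(*rows)
        query = CodingSequence("q", "ATGAAACTGTCTACT")
        assert infer_code(query, a).verdict == "indeterminate"

    def test_mostly_gapped_columns_excluded(self):
        rows = ["MK-ST"] * 20 + ["MKSST"] * 4
        a = aln(*rows)
        query = CodingSequence("q", "ATGAAACTGTCTACT")
        call = infer_code(query, a)
        assert call.verdict == "indeterminate"
        assert call.column_profiles == (None,)

    def test_score_monotone_in_candidate_residue_count(self):
        query = CodingSequence("q", "ATGAAACTGTCTACT")
        prev = -math.inf
        for n_ser in (5, 10, 20, 28):
            rows = ["MKSST"] * n_ser + ["MKGST"] * (30 - n_ser)
            call = infer_code(query, aln(*rows))
            assert call.scores["cug_ser"] > prev
            prev = call.scores["cug_ser"]

    def test_scores_finite_with_positive_pseudocount(self):
        rows = ["MKGST"] * 10  # candidate residues absent from the column
        call = infer_code(CodingSequence("q", "ATGAAACTGTCTACT"), aln(*rows))
        assert all(math.isfinite(v) for v in call.scores.values())

    def test_zero_pseudocount_rejected(self):
        with pytest.raises(InferenceError):
            infer_code(
                CodingSequence("q", "CTG"), self._family("S"), pseudocount=0
            )

    def test_synthetic_family_recovery_small(self):
        for true_code in ("cug_ser", "cug_leu", "cug_ala"):
            for seed in range(3):
                spec = FamilySpec(
                    seed=seed, true_code=true_code, protein_length=80,
                    conservation=0.9,
                )
                alignment, query, label = generate_homolog_family(spec)
                call = infer_code(query, alignment)
                assert call.verdict in (label, "indeterminate")
                assert call.verdict == label  # high-signal regime
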