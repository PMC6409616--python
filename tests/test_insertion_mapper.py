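"""Restriction digest, inverse-PCR simulation, junction mapping."""

import math

import pytest

from cugkit.errors import DigestError, JunctionError
from cugkit.insertion_mapper import (
    expected_site_spacing,
    find_restriction_sites,
    map_junction,
    revcomp,
    simulate_inverse_pcr,
    verification_windows,
)
from cugkit.synthetic_data import plant_cassette, random_cassette, random_genome


class TestFindSites:
    def test_single_site_two_fragments(self):
        d = find_restriction_sites("AAGCGCAA", "GCGC")
        assert d.site_positions == (2,)
        assert d.fragments == ((0, 5), (5, 8))  # cut at GCG^C

    def test_overlapping_sites_all_reported(self):
        d = find_restriction_sites("GCGCGC", "GCGC")
        assert d.site_positions == (0, 2)

    def test_circular_wraparound_site(self):
        d = find_restriction_sites("CGCAAAAG", "GCGC", circular=True)
        assert d.site_positions == (7,)

    def test_circular_matches_rotate_and_scan_oracle(self):
        # every rotation of the circle must expose the same site set
        seq = "GCGTTGCGCAATGCGGC"
        L = len(seq)
        d = find_restriction_sites(seq, "GCGC", circular=True)
        expected = set()
        for r in range(L):
            rotated = seq[r:] + seq[:r]
            for p in range(L):  # only starts within one period
                if (rotated + rotated)[p : p + 4] == "GCGC":
                    expected.add((p + r) % L)
        assert set(d.site_positions) == expected

    def test_degenerate_site_rejected(self):
        with pytest.raises(DigestError):
            find_restriction_sites("ACGT", "GCNC")

    def test_fragments_partition_linear_sequence(self):
        seq = random_genome(5000, 0.5, 3)
        d = find_restriction_sites(seq, "GCGC")
        assert len(d.fragments) == len({p + 3 for p in d.site_positions}) + 1
        assert "".join(d.fragment_sequences(seq)) == seq

    def test_fragments_partition_circular_sequence(self):
        seq = random_genome(5000, 0.5, 4)
        d = find_restriction_sites(seq, "GCGC", circular=True)
        joined = "".join(d.fragment_sequences(seq))
        # concatenation is a rotation of the input circle
        assert len(joined) == len(seq) and joined in seq + seq


class TestExpectedSpacing:
    @pytest.mark.parametrize(
        "gc,site,expected",
        [
            (0.5, "GCGC", 256.0),
            (0.5, "GCGCGC", 4096.0),
            (0.404, "GCGC", (0.202) ** -4),
        ],
    )
    def test_iid_formula(self, gc, site, expected):
        assert expected_site_spacing(gc, site) == pytest.approx(expected)

    def test_yeastlike_gc_gives_about_600bp(self):
        assert expected_site_spacing(0.404, "GCGC") == pytest.approx(601, rel=0.01)

    def test_impossible_site_reports_infinite_spacing(self):
        assert math.isinf(expected_site_spacing(0.0, "GCGC"))

    def test_observed_spacing_matches_formula_on_iid_genomes(self):
        # 1 Mb at GC 0.40, 10 seeds: mean spacing within 10% of analytic
        expected = expected_site_spacing(0.40, "GCGC")
        spacings = []
        for seed in range(10):
            g = random_genome(1_000_000, 0.40, seed)
            d = find_restriction_sites(g, "GCGC")
            spacings.append(d.mean_spacing())
        mean = sum(spacings) / len(spacings)
        assert abs(mean - expected) / expected < 0.10


class TestInversePCR:
    def _scenario(self, seed, genome_len=100_000, cassette_len=693):
        genome = random_genome(genome_len, 0.4, seed)
        cassette = random_cassette(cassette_len, seed + 10_000)
        planted, truth = plant_cassette(
            genome, cassette, seed=seed + 20_000, avoid_sites=("GCGC",)
        )
        return genome, cassette, planted, truth

    def test_amplicon_contains_both_flanks_to_nearest_sites(self):
        genome, cassette, planted, truth = self._scenario(1)
        result = simulate_inverse_pcr(planted, truth.cassette_span)
        assert result.right_flank in result.amplicon
        assert result.left_flank in result.amplicon
        # flanks run from the cassette boundary to the nearest cut
        a, b = truth.cassette_span
        fs, fe = result.fragment
        assert planted[fs:a] == result.left_flank
        assert planted[b:fe] == result.right_flank
        assert "GCGC" not in result.left_flank
        assert "GCGC" not in result.right_flank

    def test_zero_length_flank_at_adjacent_site(self):
        # the cut lands exactly on the cassette start (GCG|C with the C being
        # the cassette's first base): zero-length flank, amplicon still made
        cassette = "C" + "ATTA" * 30
        genome = "AAAA" + "GCG" + "T" * 30 + "GCGC" + "A" * 30
        pos = 7  # right after the GCG: planted[4:8] == "GCGC", cut at 7
        planted = genome[:pos] + cassette + genome[pos:]
        result = simulate_inverse_pcr(planted, (pos, pos + len(cassette)))
        assert result.left_flank == ""
        assert result.right_flank.startswith("T" * 30)
        assert result.amplicon

    def test_internal_site_rejected_with_position(self):
        cassette = "A" * 50 + "GCGC" + "T" * 50
        genome = random_genome(2000, 0.3, 7)
        planted, truth = plant_cassette(genome, cassette, position=800)
        with pytest.raises(DigestError, match="850"):
            simulate_inverse_pcr(planted, truth.cassette_span)

    def test_missing_primer_rejected(self):
        genome, cassette, planted, truth = self._scenario(2)
        with pytest.raises(DigestError):
            simulate_inverse_pcr(
                planted, truth.cassette_span, primers=("GATTACAGATTACAGATTAC", "A" * 20)
            )


class TestMapJunction:
    def test_amplicon_maps_to_planted_coordinate(self):
        genome = random_genome(100_000, 0.4, 11)
        cassette = random_cassette(693, 12)
        planted, truth = plant_cassette(genome, cassette, seed=13, avoid_sites=("GCGC",))
        amplicon = simulate_inverse_pcr(planted, truth.cassette_span).amplicon
        call = map_junction(amplicon, genome, cassette)
        assert call.status == "unique"
        assert call.locus == ("genome", truth.position, "+")
        assert call.flank_length_matched >= 20

    def test_duplicated_flank_is_ambiguous(self):
        flank = random_genome(60, 0.5, 21)
        genome = flank + random_genome(500, 0.5, 22) + flank + random_genome(500, 0.5, 23)
        cassette = "ATTA" * 20
        junction = cassette[-20:] + flank
        call = map_junction(junction, genome, cassette)
        assert call.status == "ambiguous"

    def test_short_flank_is_unmapped(self):
        genome = random_genome(10_000, 0.5, 31)
        cassette = "ATTA" * 20
        junction = cassette[-20:] + genome[500:510]  # 10 bp < min_flank 20
        call = map_junction(junction, genome, cassette, min_flank=20)
        assert call.status == "unmapped"

    def test_junction_without_cassette_rejected(self):
        with pytest.raises(JunctionError):
            map_junction(random_genome(100, 0.5, 41), "ACGT" * 100, "ATTA" * 20)

    def test_reverse_strand_flank_found(self):
        genome = random_genome(5000, 0.5, 51)
        cassette = "ATTA" * 20
        flank = revcomp(genome[1000:1060])
        junction = cassette[-20:] + flank
        call = map_junction(junction, genome, cassette)
        assert call.status == "unique"
        assert call.locus[2] == "-"

    def test_mismatch_tolerant_mode(self):
        genome = random_genome(3000, 0.5, 61)
        cassette = "ATTA" * 20
        flank = list(genome[700:740])
        flank[5] = "A" if flank[5] != "A" else "C"  # one mismatch
        junction = cassette[-20:] + "".join(flank)
        exact = map_junction(junction, genome, cassette, min_flank=30)
        tolerant = map_junction(
            junction, genome, cassette, min_flank=30, max_mismatches=2
        )
        assert exact.status == "unmapped"
        assert tolerant.status == "unique"
        assert tolerant.locus[1] == 700

    def test_end_to_end_recovery_rate(self):
        # plant -> digest -> ligate -> inverse PCR -> map, 100 seeded runs
        n_exact = 0
        for seed in range(100):
            genome = random_genome(100_000, 0.4, 1000 + seed)
            cassette = random_cassette(693, 2000 + seed)
            planted, truth = plant_cassette(
                genome, cassette, seed=3000 + seed, avoid_sites=("GCGC",)
            )
            try:
                amplicon = simulate_inverse_pcr(planted, truth.cassette_span).amplicon
                call = map_junction(amplicon, genome, cassette)
            except DigestError:
                continue
            if call.status == "unique" and call.locus[1] == truth.position:
                n_exact += 1
        assert n_exact >= 99


class TestVerificationWindows:
    def test_windows_and_product_sizes(self):
        genome = random_genome(2000, 0.5, 71)
        win = verification_windows(genome, "genome", 1000, cassette_length=693)
        assert win.upstream == (850, 1000)
        assert win.downstream == (1000, 1150)
        assert win.upstream_seq == genome[850:1000]
        assert win.product_size_wildtype == 300
        assert win.product_size_insertion == 993

    def test_window_must_fit_contig(self):
        with pytest.raises(JunctionError):
            verification_windows("ACGT" * 50, "genome", 10, 693)
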