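import dataclasses

import pytest

from saltmir import discovery
from saltmir.discovery import (
    GenomeHit,
    Thresholds,
    compute_mfei,
    count_terminal_loops,
    evaluate_hairpin,
    excise_candidates,
    find_star,
    fold,
    map_tags,
    pair_table,
)
from saltmir.published import novel_mirna_table
from saltmir.sequences import revcomp
from saltmir.synthetic import plant_hairpin


class TestFold:
    def test_homopolymer_has_no_structure(self):
        structure, mfe = fold("A" * 60)
        assert structure == "." * 60
        assert mfe == 0.0

    def test_gc_stem_folds_into_single_hairpin(self):
        seq = "G" * 15 + "C" * 5 + "A" * 8 + "G" * 5 + "C" * 15
        structure, mfe = fold(seq)
        assert mfe < -20
        assert count_terminal_loops(structure) == 1
        assert structure.count("(") == structure.count(")")

    def test_rejects_bad_symbols_and_lengths(self):
        with pytest.raises(ValueError, match="non-ACGTU"):
            fold("ACGTX" * 10)
        with pytest.raises(ValueError, match="length"):
            fold("ACGT" * 5)


class TestMfei:
    @pytest.mark.parametrize("mfe,pl,au,expected", [
        (-58.9, 99, 55.6, 1.34),
        (-53.6, 115, 71.3, 1.62),
        (-34.4, 70, 71.4, 1.72),
        (-67.7, 175, 46.3, 0.72),
    ])
    def test_published_rows_reproduced(self, mfe, pl, au, expected):
        assert round(compute_mfei(mfe, pl, 100.0 - au), 2) == expected

    def test_zero_mfe(self):
        assert compute_mfei(0.0, 100, 50.0) == 0.0

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            compute_mfei(-10, 0, 50.0)
        with pytest.raises(ValueError):
            compute_mfei(-10, 100, 0.0)

    def test_identity_holds_for_consistent_published_rows(self):
        table = novel_mirna_table()
        for row in table[table["mfei_consistent"]].itertuples():
            mfei = compute_mfei(row.mfe, row.precursor_length, 100.0 - row.au_pct)
            assert abs(mfei - row.mfei) <= 0.02


class TestStar:
    def test_perfect_stem_no_mismatches(self):
        pre, _, off = plant_hairpin(None, arm="5p", loop_len=12,
                                    duplex_mismatches=0, seed=2, mature_len=21)
        structure, _ = fold(pre)
        star = find_star(structure, off, 21)
        assert star.failure is None
        assert star.duplex_mismatches == 0
        assert star.arm == "5p"

    def test_programmed_bulges_counted(self):
        pre, _, off = plant_hairpin(None, arm="5p", loop_len=12,
                                    duplex_mismatches=3, seed=8, mature_len=22)
        structure, _ = fold(pre)
        assert find_star(structure, off, 22).duplex_mismatches == 3

    def test_loop_spanning_mature_fails(self):
        structure = "((((((((....))))))))" + "." * 30
        res = find_star(structure, 4, 12)  # spans the loop
        assert res.failure == "loop_spanning"

    def test_pair_table_balanced(self):
        with pytest.raises(ValueError):
            pair_table("(((..")


class TestEvaluateHairpin:
    def test_planted_hairpin_passes_all_criteria(self, small_genome):
        genome, truth = small_genome
        loc = truth.planted_loci[0]
        cand = evaluate_hairpin(loc.precursor_seq, loc.mature_offset,
                                len(loc.mature_seq))
        assert cand.all_pass
        assert cand.pl == len(cand.precursor_seq) == len(cand.structure)
        assert cand.au_pct + cand.gc_pct == pytest.approx(100.0, abs=0.05)
        assert cand.mfei == pytest.approx(
            (abs(cand.mfe) / cand.pl * 100) / cand.gc_pct, abs=0.005
        )

    def test_short_precursor_fails_length_criterion(self):
        # 16-bp stem + 8-nt loop: hairpin of 40 nt, below the 60-nt minimum
        stem = "GCGAGCTCCGGATCAC"
        seq = stem + "AACACAAC" + revcomp(stem)
        cand = evaluate_hairpin(seq, 0, len(stem))
        assert not cand.verdict["precursor_length"]
        assert not cand.all_pass

    def test_verdict_monotonicity(self, small_genome):
        """Relaxing any single threshold never fails a passing candidate."""
        genome, truth = small_genome
        loc = truth.planted_loci[1]
        base = Thresholds()
        assert evaluate_hairpin(loc.precursor_seq, loc.mature_offset,
                                len(loc.mature_seq), base).all_pass
        relaxed = [
            dataclasses.replace(base, min_precursor_length=40),
            dataclasses.replace(base, max_loops=3),
            dataclasses.replace(base, max_duplex_mismatches=8),
            dataclasses.replace(base, max_mfe=-5.0),
            dataclasses.replace(base, min_mfei=0.3),
            dataclasses.replace(base, min_au=0.0, max_au=100.0),
        ]
        for th in relaxed:
            assert evaluate_hairpin(loc.precursor_seq, loc.mature_offset,
                                    len(loc.mature_seq), th).all_pass


class TestMapping:
    def test_planted_mature_maps_to_truth_locus(self, small_genome):
        genome, truth = small_genome
        loc = truth.planted_loci[0]
        hits = map_tags([loc.mature_seq], genome)[loc.mature_seq]
        spans = [(h.chrom, h.strand) for h in hits]
        assert (loc.chrom, loc.strand) in spans
        match = [h for h in hits if h.strand == loc.strand][0]
        assert loc.start <= match.start and match.end <= loc.end

    def test_minus_strand_hit(self):
        genome = {"chr1": "TTTT" + revcomp("ACGGTTCAATCGGATCCGTA") + "GGGG"}
        hits = map_tags(["ACGGTTCAATCGGATCCGTA"], genome)["ACGGTTCAATCGGATCCGTA"]
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert (hits[0].start, hits[0].end) == (4, 24)

    def test_absent_tag_no_hits(self):
        genome = {"chr1": "ACGT" * 100}
        assert map_tags(["TTGAGTGCAGCGTTGATGAACC"], genome)["TTGAGTGCAGCGTTGATGAACC"] == []

    def test_multimapper_excluded(self):
        unit = "ACGGTTCAATCGGATCCGTA"
        genome = {"chr1": ("TTTT" + unit) * 30}
        assert map_tags([unit], genome, max_loci=20)[unit] == []


class TestExcision:
    def test_window_arithmetic_plus_strand(self):
        genome = {"chr1": "A" * 3000}
        hit = GenomeHit("G" * 21, "chr1", 1000, 1021, "+")
        wins = {(w.start, w.end): w for w in excise_candidates(hit, genome)}
        assert (900, 1121) in wins
        assert wins[(900, 1121)].mature_offset == 100

    def test_clipping_flagged(self):
        genome = {"chr1": "A" * 500}
        hit = GenomeHit("G" * 21, "chr1", 10, 31, "+")
        wins = excise_candidates(hit, genome)
        assert any(w.clipped for w in wins)
        assert all(w.start >= 0 for w in wins)

    def test_some_window_contains_planted_precursor(self, small_genome):
        genome, truth = small_genome
        for loc in truth.planted_loci:
            hits = map_tags([loc.mature_seq], genome)[loc.mature_seq]
            hit = [h for h in hits if h.strand == loc.strand][0]
            wins = excise_candidates(hit, genome)
            assert any(w.start <= loc.start and w.end >= loc.end for w in wins)

    def test_minus_strand_window_orientation(self):
        core = "ACGGTTCAATCGGATCCGTA"
        genome = {"chr1": "T" * 300 + revcomp(core) + "G" * 300}
        hit = map_tags([core], genome)[core][0]
        for w in excise_candidates(hit, genome):
            assert core in w.seq
            assert w.seq[w.mature_offset:w.mature_offset + len(core)] == core
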