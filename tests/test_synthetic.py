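from pathlib import Path

import numpy as np
import pytest

from saltmir import discovery, synthetic
from saltmir.sequences import revcomp
from saltmir.synthetic import (
    LIBRARIES,
    GenomeCapacityError,
    generate_genome,
    plant_hairpin,
    simulate_reads,
)


class TestPlantHairpin:
    def test_perfect_stem_pairs_every_mature_base(self):
        pre, star, off = plant_hairpin(None, arm="5p", loop_len=12,
                                       duplex_mismatches=0, seed=1, mature_len=21)
        cand = discovery.evaluate_hairpin(pre, off, 21)
        assert cand.duplex_mismatches == 0
        assert cand.arm == "5p"

    @pytest.mark.parametrize("mm,arm", [(3, "5p"), (3, "3p"), (2, "3p")])
    def test_programmed_mismatches_round_trip(self, mm, arm):
        pre, star, off = plant_hairpin(None, arm=arm, loop_len=14,
                                       duplex_mismatches=mm, seed=5, mature_len=24)
        cand = discovery.evaluate_hairpin(pre, off, 24)
        assert cand.duplex_mismatches == mm
        assert cand.arm == arm
        assert cand.all_pass

    def test_loop_below_minimum_rejected(self):
        with pytest.raises(ValueError):
            plant_hairpin(None, loop_len=4, seed=0)

    def test_precursor_at_least_60nt_and_star_overhang(self):
        pre, star, off = plant_hairpin(None, arm="5p", loop_len=12,
                                       duplex_mismatches=0, seed=9, mature_len=20)
        assert len(pre) >= 60
        assert len(star) == 22  # mature-pairing core + 2-nt 3' overhang


class TestGenerateGenome:
    def test_determinism(self):
        g1, t1 = generate_genome(1, 30_000, 0.43, 4, seed=7)
        g2, t2 = generate_genome(1, 30_000, 0.43, 4, seed=7)
        assert g1 == g2
        assert [l.mature_seq for l in t1.planted_loci] == [
            l.mature_seq for l in t2.planted_loci
        ]

    def test_matures_occur_verbatim_on_stated_strand(self, small_genome):
        genome, truth = small_genome
        for loc in truth.planted_loci:
            window = genome[loc.chrom][loc.start:loc.end]
            if loc.strand == "-":
                window = revcomp(window)
            assert loc.mature_seq in window

    def test_planted_loci_recovered_by_discovery(self, small_genome):
        genome, truth = small_genome
        tags = [l.mature_seq for l in truth.planted_loci]
        best = discovery.discover_novel(discovery.map_tags(tags, genome), genome)
        assert all(best[t] is not None and best[t].all_pass for t in tags)

    def test_no_hairpins_gives_plain_genome(self):
        genome, truth = generate_genome(1, 5_000, 0.5, 0, seed=3)
        assert truth.planted_loci == []
        assert len(genome["chr1"]) == 5_000

    def test_capacity_error(self):
        with pytest.raises(GenomeCapacityError):
            generate_genome(1, 2_000, 0.5, 10, seed=0)

    def test_programmed_rpm_bounded(self, small_genome):
        _, truth = small_genome
        for lib in LIBRARIES:
            total = sum(
                truth.library_expression[(l.name, lib)] for l in truth.planted_loci
            )
            assert total <= 1e6


class TestSimulateReads:
    def test_depth_precondition(self, small_genome):
        _, truth = small_genome
        with pytest.raises(ValueError):
            simulate_reads(truth, depth=10)

    def test_same_seed_identical_fastq(self, small_genome, tmp_path):
        genome, truth = small_genome
        p1, _ = simulate_reads(truth, 2_000, seed=4, out_dir=tmp_path / "a", genome=genome)
        p2, _ = simulate_reads(truth, 2_000, seed=4, out_dir=tmp_path / "b", genome=genome)
        for lib in LIBRARIES:
            assert Path(p1[lib]).read_bytes() == Path(p2[lib]).read_bytes()

    def test_planted_quota_matches_programmed_rpm(self, small_genome):
        genome, truth = small_genome
        _, counts = simulate_reads(truth, 50_000, seed=2, genome=genome)
        n_contam = round(truth.contaminant_fraction * 50_000)
        usable = 50_000 - n_contam
        for loc in truth.planted_loci:
            for lib in LIBRARIES:
                rpm = truth.library_expression[(loc.name, lib)]
                observed = counts[(loc.name, lib)] / usable * 1e6
                if rpm >= 100:
                    assert observed == pytest.approx(rpm, rel=0.10)

    def test_expression_ratio_between_libraries(self, small_genome):
        genome, truth = small_genome
        _, counts = simulate_reads(truth, 100_000, seed=2, genome=genome)
        loc = truth.planted_loci[0]
        rpm_cr = truth.library_expression[(loc.name, "CR")]
        rpm_tr = truth.library_expression[(loc.name, "TR")]
        ratio = counts[(loc.name, "TR")] / counts[(loc.name, "CR")]
        assert ratio == pytest.approx(rpm_tr / rpm_cr, rel=0.10)

    def test_reads_carry_adapter_readthrough(self, small_genome):
        genome, truth = small_genome
        reads, _ = simulate_reads(truth, 1_000, seed=6, genome=genome)
        for r in reads["CR"][:100]:
            assert len(r) == synthetic.READ_LENGTH
            assert truth.adapter[:8] in r


def test_make_transcriptome_plants_recoverable_sites(small_genome):
    _, truth = small_genome
    transcripts, sites = synthetic.make_transcriptome(truth.planted_loci, seed=1)
    seqs = dict(transcripts)
    for site in sites:
        if site["mismatches"] == 0:
            assert revcomp(site["mature_seq"]) in seqs[site["transcript"]]
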