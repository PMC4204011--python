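"""Genome scanner: tiling, block detection, convenience scans, fragments."""

import numpy as np
import pandas as pd
import pytest

from cpgkit.composition import NucleotideSequence
from cpgkit.design import DesignSpec, design_sequence, design_tiled_sequence
from cpgkit.scan import (
    ScanCriteria,
    find_blocks,
    random_fragments,
    scan_at_rich_cpg_rich,
    scan_gc_rich_cpg_poor,
    tile_windows,
)
from cpgkit.simulate import GenomePlantSpec, synth_genome
from conftest import brute_force_blocks, brute_force_window_stats, random_dna


def genome_of(*seqs: NucleotideSequence) -> dict[str, NucleotideSequence]:
    return {s.id: s for s in seqs}


class TestTileWindows:
    def test_partial_trailing_window_dropped(self):
        wins = tile_windows(genome_of(NucleotideSequence("c", "A" * 250)), 100)
        assert [(w.start, w.end) for w in wins] == [(0, 100), (100, 200)]

    def test_cg_repeat_window(self):
        wins = tile_windows(genome_of(NucleotideSequence("c", "CG" * 50)), 100)
        assert len(wins) == 1
        assert wins[0].cpg_count == 50
        assert wins[0].gc_fraction == 1.0

    def test_boundary_cpg_counted_in_window_with_c(self):
        bases = "A" * 99 + "C" + "G" + "A" * 99
        wins = tile_windows(genome_of(NucleotideSequence("c", bases)), 100)
        assert [w.cpg_count for w in wins] == [1, 0]

    def test_n_windows_flagged(self):
        bases = "A" * 100 + "AN" + "A" * 98
        wins = tile_windows(genome_of(NucleotideSequence("c", bases)), 100)
        assert [w.has_n for w in wins] == [False, True]

    def test_empty_genome(self):
        assert tile_windows({}, 100) == []

    def test_stats_match_brute_force_on_random_chromosomes(self, rng):
        for _ in range(100):
            bases = random_dna(rng, int(rng.integers(200, 800)), gc=rng.uniform(0.3, 0.7))
            wins = tile_windows(genome_of(NucleotideSequence("c", bases)), 100)
            for w in wins:
                gc, n_cpg = brute_force_window_stats(bases, w.start, w.end)
                assert w.gc_fraction == pytest.approx(gc)
                assert w.cpg_count == n_cpg


class TestFindBlocks:
    criteria = ScanCriteria(window_size=100, gc_max=0.50, cpg_min=5, min_block_length=500)

    def test_all_a_genome_has_no_blocks(self):
        wins = tile_windows(genome_of(NucleotideSequence("c", "A" * 2000)), 100)
        assert find_blocks(wins, self.criteria) == []

    def test_planted_block_recovered_exactly(self):
        spec = GenomePlantSpec(
            chromosome_lengths={"chr1": 5000},
            background_gc=0.40,
            background_cpg_per_100bp=1.0,
            plants=(("chr1", 2000, DesignSpec(700, 0.40, 10.0, seed=5, label="p")),),
            seed=17,
            tile_plants=100,
        )
        genome, truth = synth_genome(spec)
        blocks = find_blocks(tile_windows(genome, 100), self.criteria)
        assert [(b.chrom, b.start, b.end) for b in blocks] == [("chr1", 2000, 2700)]
        assert blocks[0].n_windows == 7

    def test_relaxing_min_block_length_only_adds_blocks(self, rng):
        genome = genome_of(
            NucleotideSequence("c", random_dna(rng, 20000, gc=0.45))
        )
        wins = tile_windows(genome, 100)
        crit = ScanCriteria(window_size=100, gc_min=0.45, min_block_length=1000)
        strict = {(b.chrom, b.start, b.end) for b in find_blocks(wins, crit)}
        relaxed_crit = ScanCriteria(window_size=100, gc_min=0.45, min_block_length=500)
        relaxed = {(b.chrom, b.start, b.end) for b in find_blocks(wins, relaxed_crit)}
        assert strict <= relaxed

    def test_n_window_breaks_run(self):
        # two passing 300-bp arms separated by one N window: no 500-bp block
        arm = ("CG" * 10 + "AT" * 40)  # 100 bp, gc 0.4, 10 CpGs: passes
        bases = arm * 3 + ("N" * 100) + arm * 3
        wins = tile_windows(genome_of(NucleotideSequence("c", bases)), 100)
        assert find_blocks(wins, self.criteria) == []
        relaxed = ScanCriteria(
            window_size=100, gc_max=0.50, cpg_min=5, min_block_length=300
        )
        blocks = find_blocks(wins, relaxed)
        assert [(b.start, b.end) for b in blocks] == [(0, 300), (400, 700)]

    def test_blocks_never_merge_across_chromosomes(self):
        arm = "CG" * 10 + "AT" * 40
        g = genome_of(
            NucleotideSequence("a", arm * 5), NucleotideSequence("b", arm * 5)
        )
        blocks = find_blocks(tile_windows(g, 100), self.criteria)
        assert [(b.chrom, b.start, b.end) for b in blocks] == [
            ("a", 0, 500),
            ("b", 0, 500),
        ]

    def test_equivalent_to_brute_force_oracle_on_random_genomes(self, rng):
        """100 random synthetic genomes: block calls identical to an
        explicit window-and-run oracle."""
        crit = ScanCriteria(
            window_size=100, gc_min=0.55, cpg_min=2, min_block_length=300
        )
        for _ in range(100):
            n_chrom = int(rng.integers(1, 4))
            bases_by_chrom = {
                f"chr{i}": random_dna(
                    rng, int(rng.integers(300, 3000)), gc=rng.uniform(0.45, 0.7)
                )
                for i in range(n_chrom)
            }
            g = genome_of(
                *(NucleotideSequence(c, b) for c, b in bases_by_chrom.items())
            )
            got = [
                (b.chrom, b.start, b.end)
                for b in find_blocks(tile_windows(g, 100), crit)
            ]
            expected = brute_force_blocks(
                bases_by_chrom,
                100,
                lambda gc, cpg, has_n: not has_n and gc >= 0.55 and cpg >= 2,
                300,
            )
            assert got == expected

    def test_blocks_disjoint_and_sorted(self, rng):
        g = genome_of(NucleotideSequence("c", random_dna(rng, 30000, gc=0.55)))
        crit = ScanCriteria(window_size=100, gc_min=0.55, min_block_length=200)
        blocks = find_blocks(tile_windows(g, 100), crit)
        assert len(blocks) > 1
        for b1, b2 in zip(blocks, blocks[1:]):
            assert b1.end <= b2.start


class TestConvenienceScans:
    def test_at_rich_cpg_rich_finds_designed_island(self):
        island = design_tiled_sequence(
            DesignSpec(1000, 0.40, 10.0, seed=2, label="chrI"), tile=100
        )
        blocks = scan_at_rich_cpg_rich(genome_of(island))
        assert [(b.chrom, b.start, b.end) for b in blocks] == [("chrI", 0, 1000)]
        assert blocks[0].mean_cpg_per_100bp == pytest.approx(10.0)

    def test_gc_rich_cpg_poor_finds_designed_island(self):
        island = design_tiled_sequence(
            DesignSpec(1000, 0.65, 1.0, seed=2, label="chrI"), tile=100
        )
        blocks = scan_gc_rich_cpg_poor(genome_of(island))
        assert [(b.chrom, b.start, b.end) for b in blocks] == [("chrI", 0, 1000)]

    def test_typical_background_yields_no_blocks(self):
        """A 40%-GC background at genome-average CpG density contains
        neither kind of atypical domain."""
        spec = GenomePlantSpec(
            chromosome_lengths={"chr1": 50000}, background_gc=0.40,
            background_cpg_per_100bp=1.0, seed=23,
        )
        genome, _ = synth_genome(spec)
        assert scan_at_rich_cpg_rich(genome) == []
        assert scan_gc_rich_cpg_poor(genome) == []

    def test_empty_input_empty_output(self):
        assert scan_at_rich_cpg_rich({}) == []


class TestRandomFragments:
    def test_zero_fragments(self):
        g = genome_of(NucleotideSequence("c", "ACGT" * 500))
        assert len(random_fragments(g, 0, 1000, seed=1)) == 0

    def test_deterministic(self):
        g = genome_of(NucleotideSequence("c", "ACGT" * 1000))
        f1 = random_fragments(g, 20, 1000, seed=9)
        f2 = random_fragments(g, 20, 1000, seed=9)
        pd.testing.assert_frame_equal(f1, f2)

    def test_short_chromosomes_skipped_and_error_when_none_fit(self):
        g = genome_of(NucleotideSequence("c", "ACGT" * 10))
        with pytest.raises(ValueError, match="no chromosome"):
            random_fragments(g, 5, 1000, seed=1)

    def test_fragments_cluster_at_background_gc(self):
        """Fragments of a homogeneous 40%-GC genome estimate its GC within
        a generous binomial interval."""
        spec = GenomePlantSpec(
            chromosome_lengths={"chr1": 60000}, background_gc=0.40,
            background_cpg_per_100bp=1.0, seed=31,
        )
        genome, _ = synth_genome(spec)
        frags = random_fragments(genome, 50, 1000, seed=4)
        # per-fragment GC is 0.40 up to sampling of a fixed-composition genome
        assert frags["gc_fraction"].mean() == pytest.approx(0.40, abs=0.02)
        assert frags["gc_fraction"].std() < 0.05
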