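"""MUM finding, block chaining, coverage and cross-genome projection."""
import numpy as np
import pytest

from denovobirth.catalog import Genome, TranscriptModel
from denovobirth.config import SyntenyConfig
from denovobirth.synteny import (FORWARD, REVERSE, MUM, SyntenyBlock,
                                 cluster_mums, find_genome_mums, find_mums,
                                 genome_coverage, project_interval, revcomp,
                                 syntenic_transcript_overlaps)

from conftest import random_dna
from oracles import brute_force_mums


def _as_tuples(mums):
    return sorted((m.pos_a, m.pos_b, m.length, m.orientation) for m in mums)


class TestFindMums:
    def test_identical_sequences_single_full_mum(self, rng):
        s = random_dna(rng, 10000)
        mums = find_mums(s, s, 20)
        fwd = [m for m in mums if m.orientation == FORWARD]
        assert _as_tuples(fwd) == [(0, 0, 10000, FORWARD)]

    def test_repeat_in_a_fails_uniqueness(self, rng):
        core = random_dna(rng, 40)
        a = random_dna(rng, 100) + core + random_dna(rng, 100) + core + random_dna(rng, 100)
        b = random_dna(rng, 50) + core + random_dna(rng, 50)
        mums = find_mums(a, b, len(core))
        assert not any(a[m.pos_a:m.end_a] == core for m in mums)

    def test_reverse_complement_match_reported_with_orientation(self, rng):
        core = random_dna(rng, 50)
        a = random_dna(rng, 80) + core + random_dna(rng, 80)
        b = random_dna(rng, 30) + revcomp(core) + random_dna(rng, 30)
        mums = find_mums(a, b, 30)
        rev = [m for m in mums if m.orientation == REVERSE]
        assert any(m.pos_a <= 80 and m.end_a >= 130 for m in rev)

    def test_mirror_symmetry(self, rng):
        a, b = random_dna(rng, 400), random_dna(rng, 400)
        seg = random_dna(rng, 30)
        a = a[:100] + seg + a[100:]
        b = b[:250] + seg + b[250:]
        ab = _as_tuples(find_mums(a, b, 12))
        ba = _as_tuples(find_mums(b, a, 12))
        assert sorted((pb, pa, l, o) for pa, pb, l, o in ab) == ba

    def test_n_never_matches(self):
        a = "ACGTACGTACGTNNNNACGTACGTACGT"
        mums = find_mums(a, a, 4)
        assert all("N" not in a[m.pos_a:m.end_a] for m in mums)

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_brute_force_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(60, 200))
        a = random_dna(rng, n)
        b = random_dna(rng, n)
        if seed % 2:  # plant homology and a uniqueness-breaking repeat
            seg = random_dna(rng, 25)
            a = a[:20] + seg + a[20:40] + seg + a[40:]
            b = b[:30] + seg + b[30:]
        got = _as_tuples(find_mums(a, b, 8))
        assert got == brute_force_mums(a, b, 8)


def _mum(pa, pb, ln, orient=FORWARD):
    return MUM(pos_a=pa, pos_b=pb, length=ln, orientation=orient)


class TestClusterMums:
    def test_small_gaps_join(self):
        blocks = cluster_mums([_mum(0, 0, 30), _mum(80, 80, 30)], SyntenyConfig())
        assert len(blocks) == 1 and len(blocks[0].mums) == 2

    def test_gap_boundary_inclusive_at_100(self):
        joined = cluster_mums([_mum(0, 0, 30), _mum(130, 130, 30)], SyntenyConfig())
        assert len(joined) == 1
        split = cluster_mums([_mum(0, 0, 30), _mum(131, 131, 30)], SyntenyConfig())
        assert len(split) == 2

    def test_gap_measured_in_both_genomes(self):
        blocks = cluster_mums([_mum(0, 0, 30), _mum(80, 300, 30)], SyntenyConfig())
        assert len(blocks) == 2   # B-gap 270 splits even though A-gap is 50

    def test_orientation_change_splits(self):
        blocks = cluster_mums([_mum(0, 0, 30), _mum(40, 40, 30, REVERSE)],
                              SyntenyConfig(outlier_diag_tol=0))
        assert len(blocks) == 2

    def test_b_monotonicity_required(self):
        blocks = cluster_mums([_mum(0, 500, 30), _mum(40, 100, 30)],
                              SyntenyConfig(outlier_diag_tol=0))
        assert len(blocks) == 2

    def test_blocks_partition_input(self):
        mums = [_mum(0, 0, 30), _mum(60, 60, 25), _mum(400, 400, 20),
                _mum(700, 1500, 20)]
        blocks = cluster_mums(mums, SyntenyConfig())
        flat = [m for b in blocks for m in b.mums]
        assert sorted(flat, key=lambda m: m.pos_a) == mums
        assert sum(len(b.mums) for b in blocks) == len(mums)

    def test_unsorted_input_fatal(self):
        with pytest.raises(ValueError, match="sorted"):
            cluster_mums([_mum(50, 0, 20), _mum(0, 50, 20)], SyntenyConfig())

    def test_isolated_off_diagonal_mum_becomes_singleton(self):
        run = [_mum(i * 60, i * 60, 30) for i in range(5)]
        noise = _mum(130, 9000, 20)
        mums = sorted(run + [noise], key=lambda m: m.pos_a)
        blocks = cluster_mums(mums, SyntenyConfig())
        sizes = sorted(len(b.mums) for b in blocks)
        assert sizes == [1, 5]   # the run survives, noise is its own block


class TestCoverageAndProjection:
    def test_identical_genomes_full_coverage(self, rng):
        s = random_dna(rng, 3000)
        g = Genome(species_id="a", chromosomes={"c": s})
        mums = find_genome_mums(g, g, 20)
        blocks = cluster_mums(mums, SyntenyConfig())
        assert genome_coverage(blocks, g) == pytest.approx(1.0)

    def test_no_blocks_zero_coverage(self, rng):
        g = Genome(species_id="a", chromosomes={"c": random_dna(rng, 1000)})
        assert genome_coverage([], g) == 0.0

    def test_overlapping_blocks_union_not_double_counted(self, rng):
        g = Genome(species_id="a", chromosomes={"c": random_dna(rng, 1000)})
        b1 = SyntenyBlock(mums=[_mum(0, 0, 500)], chrom_a="c", chrom_b="c")
        b2 = SyntenyBlock(mums=[_mum(300, 300, 500)], chrom_a="c", chrom_b="c")
        assert genome_coverage([b1, b2], g) == pytest.approx(0.8)

    def test_identity_projection(self, rng):
        s = random_dna(rng, 2000)
        mums = find_mums(s, s, 20)
        blocks = cluster_mums(sorted(mums, key=lambda m: (m.pos_a, m.pos_b)),
                              SyntenyConfig())
        proj = project_interval(blocks, (123, 456))
        assert proj == ((123, 456), FORWARD)
        # quasi-inverse: projecting back returns the original interval
        back = project_interval(blocks, proj[0])
        assert back[0] == (123, 456)

    def test_two_anchor_interpolation(self):
        block = SyntenyBlock(mums=[_mum(0, 0, 100), _mum(200, 500, 100)])
        blocks = [block]
        assert project_interval(blocks, (120, 180)) == ((100, 500), FORWARD)

    def test_interval_outside_blocks_unresolved(self):
        block = SyntenyBlock(mums=[_mum(0, 0, 100)])
        assert project_interval([block], (5000, 5100)) is None

    def test_reverse_block_projection_flips(self):
        # A [0,100) matches B [900,1000) reverse-complemented
        block = SyntenyBlock(mums=[_mum(0, 900, 100, REVERSE)])
        proj = project_interval([block], (10, 30))
        assert proj == ((970, 990), REVERSE)


class TestSyntenicOverlaps:
    def _tx(self, tid, start, end, strand="+"):
        return TranscriptModel(transcript_id=tid, gene_id=tid, chrom="c",
                               strand=strand, exons=((start, end),))

    def test_one_bp_overlap_pairs(self, rng):
        s = random_dna(rng, 2000)
        blocks = cluster_mums(find_mums(s, s, 20), SyntenyConfig())
        for b in blocks:
            b.chrom_a = b.chrom_b = "c"
        ta = self._tx("a", 100, 300)
        tb = self._tx("b", 299, 500)
        assert syntenic_transcript_overlaps([ta], [tb], blocks) == [("a", "b")]
        tb_far = self._tx("b", 300, 500)
        assert syntenic_transcript_overlaps([ta], [tb_far], blocks) == []

    def test_same_strand_requirement_default_and_off(self, rng):
        s = random_dna(rng, 2000)
        blocks = cluster_mums(find_mums(s, s, 20), SyntenyConfig())
        for b in blocks:
            b.chrom_a = b.chrom_b = "c"
        ta = self._tx("a", 100, 300, "+")
        tb = self._tx("b", 150, 350, "-")
        assert syntenic_transcript_overlaps([ta], [tb], blocks) == []
        assert syntenic_transcript_overlaps(
            [ta], [tb], blocks, require_same_strand=False) == [("a", "b")]

    def test_projection_into_gene_desert_gives_no_pairs(self, rng):
        s = random_dna(rng, 2000)
        blocks = cluster_mums(find_mums(s, s, 20), SyntenyConfig())
        for b in blocks:
            b.chrom_a = b.chrom_b = "c"
        ta = self._tx("a", 100, 300)
        assert syntenic_transcript_overlaps([ta], [self._tx("b", 1500, 1700)],
                                            blocks) == []
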