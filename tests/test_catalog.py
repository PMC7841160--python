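"""Catalog I/O, TPM normalization, redundancy merge and expression filtering."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from denovobirth.catalog import (CatalogError, ExpressionTable, Genome,
                                 TranscriptModel, compute_tpm,
                                 detection_report, filter_expressed,
                                 merge_catalogs, read_transcripts_gtf,
                                 write_transcripts_gtf)

from conftest import random_dna


@pytest.fixture
def genome(rng):
    return Genome(species_id="sp", chromosomes={"chrI": random_dna(rng, 5000)})


def _tm(tid, exons, strand="+", chrom="chrI", prov="annotated", gene=None):
    return TranscriptModel(transcript_id=tid, gene_id=gene or tid, chrom=chrom,
                           strand=strand, exons=tuple(exons), provenance=prov)


class TestGtf:
    def test_one_based_closed_conversion(self, genome, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text('chrI\t.\texon\t11\t20\t.\t+\t.\ttranscript_id "t1"; gene_id "g1";\n')
        (t,) = read_transcripts_gtf(gtf, genome)
        assert t.exons == ((10, 20),)
        assert t.strand == "+" and t.gene_id == "g1"

    def test_multi_exon_grouping(self, genome, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            'chrI\t.\texon\t31\t40\t.\t+\t.\ttranscript_id "t1"; gene_id "g1";\n'
            'chrI\t.\texon\t11\t20\t.\t+\t.\ttranscript_id "t1"; gene_id "g1";\n')
        (t,) = read_transcripts_gtf(gtf, genome)
        assert t.exons == ((10, 20), (30, 40)) and t.length == 20

    @pytest.mark.parametrize("line,msg", [
        ('chrX\t.\texon\t11\t20\t.\t+\t.\ttranscript_id "t1";\n', "unknown chromosome"),
        ('chrI\t.\texon\t11\t9999999\t.\t+\t.\ttranscript_id "t1";\n', "beyond chromosome end"),
        ('chrI\t.\texon\t11\t20\t.\t+\t.\tgene_id "g1";\n', "transcript_id"),
    ])
    def test_fatal_errors_carry_line_number(self, genome, tmp_path, line, msg):
        gtf = tmp_path / "bad.gtf"
        gtf.write_text("# header\n" + line)
        with pytest.raises(CatalogError, match=r":2:.*") as exc:
            read_transcripts_gtf(gtf, genome)
        assert msg in str(exc.value)

    def test_round_trip_identity_on_generated_catalog(self, genome, rng, tmp_path):
        transcripts = []
        pos = 10
        for i in range(50):
            n_ex = int(rng.integers(1, 5))
            exons = []
            for _ in range(n_ex):
                length = int(rng.integers(5, 40))
                exons.append((pos, pos + length))
                pos += length + int(rng.integers(2, 20))
            transcripts.append(_tm(
                f"t{i}", exons, strand="+-"[int(rng.integers(0, 2))],
                prov=("annotated", "novel")[int(rng.integers(0, 2))]))
            if pos > 4500:
                break
        path = tmp_path / "cat.gtf"
        write_transcripts_gtf(transcripts, path)
        back = read_transcripts_gtf(path, genome)
        assert set(back) == set(transcripts)
        # and a second round trip is stable
        write_transcripts_gtf(back, path)
        assert set(read_transcripts_gtf(path, genome)) == set(transcripts)


class TestTpm:
    def test_equal_rates_split_evenly(self):
        t = compute_tpm({"a": 10, "b": 10}, {"a": 100, "b": 100})
        assert t.values["a"] == pytest.approx(5e5)
        assert t.values["b"] == pytest.approx(5e5)

    def test_length_normalization(self):
        # rates 0.1 vs 0.05 -> 2:1 split of 1e6
        t = compute_tpm({"a": 10, "b": 10}, {"a": 100, "b": 200})
        assert t.values["a"] == pytest.approx(666666.6667, rel=1e-6)
        assert t.values["b"] == pytest.approx(333333.3333, rel=1e-6)

    def test_single_expressed_transcript_takes_all(self):
        t = compute_tpm({"a": 7, "b": 0}, {"a": 50, "b": 123})
        assert t.values["a"] == pytest.approx(1e6)
        assert t.values["b"] == 0.0

    def test_empty_library_fatal(self):
        with pytest.raises(CatalogError, match="empty library"):
            compute_tpm({"a": 0, "b": 0}, {"a": 10, "b": 10})

    @given(st.lists(st.tuples(st.integers(0, 10000), st.integers(1, 5000)),
                    min_size=1, max_size=30).filter(
                        lambda v: any(c > 0 for c, _ in v)))
    def test_tpm_sums_to_one_million(self, pairs):
        counts = {f"t{i}": c for i, (c, _) in enumerate(pairs)}
        lengths = {f"t{i}": l for i, (_, l) in enumerate(pairs)}
        t = compute_tpm(counts, lengths)
        assert sum(t.values.values()) == pytest.approx(1e6, rel=1e-6)


class TestMerge:
    def test_identical_novel_dropped(self):
        a = _tm("a", [(100, 200)])
        n = _tm("n", [(100, 200)], prov="novel")
        assert merge_catalogs([a], [n]) == [a]

    def test_antisense_novel_survives(self):
        a = _tm("a", [(100, 200)], strand="+")
        n = _tm("n", [(100, 200)], strand="-", prov="novel")
        merged = merge_catalogs([a], [n])
        assert {t.transcript_id for t in merged} == {"a", "n"}

    def test_one_bp_same_strand_overlap_drops(self):
        a = _tm("a", [(100, 200)])
        n = _tm("n", [(199, 300)], prov="novel")   # single shared base
        assert [t.transcript_id for t in merge_catalogs([a], [n])] == ["a"]
        n2 = _tm("n", [(200, 300)], prov="novel")  # adjacent, zero overlap
        assert {t.transcript_id for t in merge_catalogs([a], [n2])} == {"a", "n"}

    def test_intron_spanning_novel_kept_without_exonic_overlap(self):
        a = _tm("a", [(100, 150), (300, 350)])
        n = _tm("n", [(200, 250)], prov="novel")   # inside a's intron
        assert {t.transcript_id for t in merge_catalogs([a], [n])} == {"a", "n"}

    def test_duplicate_id_fatal(self):
        with pytest.raises(CatalogError, match="duplicate"):
            merge_catalogs([_tm("x", [(0, 10)])],
                           [_tm("x", [(50, 60)], prov="novel")])

    def test_idempotent(self, rng):
        annotated = [_tm(f"a{i}", [(i * 300, i * 300 + 150)]) for i in range(10)]
        novel = [_tm(f"n{i}", [(i * 300 + 100, i * 300 + 260)],
                     strand="+-"[i % 2], prov="novel") for i in range(10)]
        merged = merge_catalogs(annotated, novel)
        again = merge_catalogs(annotated,
                               [t for t in merged if t.provenance == "novel"])
        assert again == merged


class TestFilterExpressed:
    def _tables(self, normal, stress):
        return [ExpressionTable("sp", "normal", normal),
                ExpressionTable("sp", "stress", stress)]

    def test_both_conditions_pattern(self):
        t = _tm("aua1", [(0, 300)])
        kept, patterns = filter_expressed(
            [t], self._tables({"aua1": 59.0}, {"aua1": 118.0}), 15.0)
        assert kept == [t] and patterns["aua1"] == "both"

    def test_threshold_is_strict(self):
        t = _tm("t", [(0, 300)])
        kept, _ = filter_expressed([t], self._tables({"t": 15.0}, {"t": 15.0}), 15.0)
        assert kept == []

    def test_stress_only_pattern(self):
        t = _tm("t", [(0, 300)])
        kept, patterns = filter_expressed([t], self._tables({"t": 0.0}, {"t": 16.0}), 15.0)
        assert kept == [t] and patterns["t"] == "stress_only"

    def test_missing_entries_count_as_zero(self):
        t = _tm("ghost", [(0, 300)])
        kept, _ = filter_expressed([t], self._tables({}, {}), 15.0)
        assert kept == []

    @given(st.floats(0.0, 200.0), st.floats(0.0, 200.0),
           st.floats(1.0, 50.0), st.floats(0.0, 100.0))
    def test_monotone_in_threshold(self, a, b, thr, dthr):
        t = _tm("t", [(0, 300)])
        low, _ = filter_expressed([t], self._tables({"t": a}, {"t": b}), thr)
        high, _ = filter_expressed([t], self._tables({"t": a}, {"t": b}), thr + dthr)
        assert set(x.transcript_id for x in high) <= set(x.transcript_id for x in low)

    def test_detection_report_uses_floor_not_threshold(self):
        t = _tm("t", [(0, 300)])
        df = detection_report([t], self._tables({"t": 5.0}, {"t": 1.0}))
        assert bool(df.detected[0]) and not bool(df.expressed[0])
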