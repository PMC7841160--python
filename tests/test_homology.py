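"""Seed-and-extend homology search, filters, paralog grouping, hit tables."""
import numpy as np
import pytest

from denovobirth.config import HomologyConfig
from denovobirth.homology import (HomologyHit, PROGRAM_NUC, PROGRAM_TRANS,
                                  TranscriptDatabase, filter_hits,
                                  find_paralogs, read_hit_table,
                                  search_nucleotide, search_translated,
                                  write_hit_table)
from denovobirth.synteny import revcomp

from conftest import random_dna
from oracles import longest_common_substring_length

SENSE = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
         if a + b + c not in ("TAA", "TAG", "TGA")]


def _coding(rng, n_codons):
    return "ATG" + "".join(SENSE[i] for i in rng.integers(0, 61, n_codons - 1))


class TestNucleotideSearch:
    def test_self_match_full_identity(self, rng):
        seq = random_dna(rng, 500)
        db = TranscriptDatabase([("sp", "t1", seq)])
        hits = search_nucleotide("q", seq, db)
        top = hits[0]
        assert top.identity_frac == 1.0
        assert top.aln_len_nt == 500
        assert top.evalue < 1e-50

    def test_reverse_complement_never_matches(self, rng):
        seq = random_dna(rng, 500)
        db = TranscriptDatabase([("sp", "t1", seq)])
        assert search_nucleotide("q", revcomp(seq), db) == []

    def test_planted_shared_segment_found_once(self, rng):
        seg = random_dna(rng, 150)
        q = random_dna(rng, 400) + seg + random_dna(rng, 450)
        s = random_dna(rng, 250) + seg + random_dna(rng, 600)
        assert longest_common_substring_length(q, s) >= 150
        db = TranscriptDatabase([("sp", "t1", s)])
        hits = [h for h in search_nucleotide("q", q, db) if h.evalue < 0.05]
        assert len(hits) == 1
        assert hits[0].aln_len_nt >= 150

    def test_empty_database(self, rng):
        db = TranscriptDatabase([])
        assert search_nucleotide("q", random_dna(rng, 100), db) == []

    def test_evalue_monotone_decreasing_in_score(self, rng):
        base = random_dna(rng, 300)
        entries = []
        for i, mut in enumerate((0, 10, 30)):
            s = list(base)
            for p in rng.choice(300, size=mut, replace=False):
                s[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[p]]
            entries.append(("sp", f"t{i}", "".join(s)))
        db = TranscriptDatabase(entries)
        hits = {h.subject_id: h for h in search_nucleotide("q", base, db)}
        by_score = sorted(hits.values(), key=lambda h: -h.score)
        evs = [h.evalue for h in by_score]
        assert evs == sorted(evs)

    def test_pairwise_symmetry_of_significance(self, rng):
        a, b = random_dna(rng, 200), random_dna(rng, 200)
        seg = random_dna(rng, 120)
        a, b = a + seg, b + seg
        dba = TranscriptDatabase([("s", "a", a)])
        dbb = TranscriptDatabase([("s", "b", b)])
        ab = [h for h in search_nucleotide("b", b, dba) if h.evalue < 0.05]
        ba = [h for h in search_nucleotide("a", a, dbb) if h.evalue < 0.05]
        assert bool(ab) == bool(ba) == True


class TestTranslatedSearch:
    def test_synonymous_divergence_found_by_translation_only(self, rng):
        # same protein, codons re-drawn: nucleotide identity drops, aa stays
        from Bio.Seq import Seq
        protein = str(Seq(_coding(rng, 120)).translate())
        syn = {}
        for aa in set(protein):
            syn[aa] = [c for c in SENSE if str(Seq(c).translate()) == aa]
        s1 = "".join(syn[aa][0] for aa in protein)
        s2 = "".join(syn[aa][-1] for aa in protein)
        ident = np.mean([x == y for x, y in zip(s1, s2)])
        assert ident < 0.8
        db = TranscriptDatabase([("sp", "t1", s2)])
        trans = [h for h in search_translated("q", s1, db) if h.evalue < 0.05]
        assert trans and trans[0].identity_frac == 1.0

    def test_frameshifted_copy_found_in_shifted_frame(self, rng):
        core = _coding(rng, 100)
        q = random_dna(rng, 50) + core + random_dna(rng, 50)
        s = random_dna(rng, 51) + core + random_dna(rng, 49)
        db = TranscriptDatabase([("sp", "t1", s)])
        hits = [h for h in search_translated("q", q, db) if h.evalue < 0.05]
        assert hits

    def test_random_pairs_rarely_significant(self):
        hits_found = 0
        trials = 60
        for seed in range(trials):
            r = np.random.default_rng(1000 + seed)
            q = random_dna(r, 300)
            s = random_dna(r, 300)
            db = TranscriptDatabase([("sp", "t", s)])
            if [h for h in search_translated("q", q, db) if h.evalue <= 0.05]:
                hits_found += 1
        assert hits_found <= 0.05 * trials

    def test_protein_database_mode(self, rng):
        from Bio.Seq import Seq
        cds = _coding(rng, 150)
        prot = str(Seq(cds).translate())
        db = TranscriptDatabase([("og", "p1", prot)], protein=True)
        hits = search_translated("q", cds, db, program="prot_outgroup")
        assert hits and hits[0].program == "prot_outgroup"
        with pytest.raises(ValueError, match="protein database"):
            search_nucleotide("q", cds, db)


class TestFilters:
    def _hit(self, program=PROGRAM_NUC, evalue=1e-10, aln=200, strand=True):
        return HomologyHit(query_id="q", subject_species="s", subject_id="t",
                           program=program, evalue=evalue, aln_len_nt=aln,
                           identity_frac=0.9, query_strand_match=strand)

    def test_nucleotide_length_rule_is_strictly_over_100(self):
        assert filter_hits([self._hit(aln=100)]) == []
        assert filter_hits([self._hit(aln=101)]) != []

    def test_length_rule_only_applies_to_nucleotide_program(self):
        kept = filter_hits([self._hit(program=PROGRAM_TRANS, evalue=0.04, aln=60)])
        assert len(kept) == 1

    def test_evalue_boundary_strict(self):
        assert filter_hits([self._hit(evalue=0.05)]) == []
        assert filter_hits([self._hit(evalue=0.049999)]) != []

    def test_opposite_strand_hits_excluded(self):
        assert filter_hits([self._hit(strand=False)]) == []


class TestParalogs:
    def _hit(self, a, b):
        return HomologyHit(query_id=a, subject_species="f", subject_id=b,
                           program=PROGRAM_NUC, evalue=1e-20, aln_len_nt=200,
                           identity_frac=0.95)

    def test_transitive_components(self):
        groups = find_paralogs([self._hit("a", "b"), self._hit("b", "c")])
        assert groups == [{"a", "b", "c"}]

    def test_no_hits_all_singletons(self):
        groups = find_paralogs([], all_ids=["a", "b", "c"])
        assert groups == [{"a"}, {"b"}, {"c"}]

    def test_random_graph_matches_bfs_oracle(self, rng):
        ids = [f"t{i}" for i in range(30)]
        edges = [(ids[int(rng.integers(30))], ids[int(rng.integers(30))])
                 for _ in range(25)]
        hits = [self._hit(a, b) for a, b in edges if a != b]
        groups = find_paralogs(hits, all_ids=ids)
        # BFS oracle
        adj = {i: set() for i in ids}
        for a, b in edges:
            if a != b:
                adj[a].add(b)
                adj[b].add(a)
        seen, comps = set(), []
        for i in ids:
            if i in seen:
                continue
            stack, comp = [i], set()
            while stack:
                x = stack.pop()
                if x in comp:
                    continue
                comp.add(x)
                stack.extend(adj[x] - comp)
            seen |= comp
            comps.append(comp)
        assert sorted(groups, key=lambda c: sorted(c)[0]) == \
            sorted(comps, key=lambda c: sorted(c)[0])


class TestHitTable:
    def test_round_trip(self, rng, tmp_path):
        seq = random_dna(rng, 400)
        db = TranscriptDatabase([("spX", "t1", seq)])
        hits = search_nucleotide("q", seq, db)
        path = tmp_path / "hits.tsv"
        write_hit_table(hits, path)
        back = read_hit_table(path)
        assert len(back) == len(hits)
        for h1, h2 in zip(hits, back):
            assert (h2.query_id, h2.subject_species, h2.subject_id) == \
                (h1.query_id, h1.subject_species, h1.subject_id)
            assert h2.aln_len_nt == h1.aln_len_nt
            assert h2.identity_frac == pytest.approx(h1.identity_frac, abs=5e-5)
            assert h2.query_strand_match

    def test_reversed_subject_coordinates_flag_strand(self, tmp_path):
        row = "q1\tsp|t1\t97.0\t150\t4\t0\t1\t150\t600\t451\t1e-30\t250.0\n"
        path = tmp_path / "h.tsv"
        path.write_text(row)
        (h,) = read_hit_table(path)
        assert not h.query_strand_match
        assert h.identity_frac == pytest.approx(0.97)
        assert filter_hits([h]) == []

    def test_malformed_column_count_fatal(self, tmp_path):
        path = tmp_path / "h.tsv"
        path.write_text("a\tb\tc\n")
        with pytest.raises(ValueError, match=":1:"):
            read_hit_table(path)
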