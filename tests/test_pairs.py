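"""Locus-pair geometry, fold-change correlation machinery, Fisher exact."""
import math

import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from denovobirth.catalog import TranscriptModel
from denovobirth.config import PairConfig
from denovobirth.pairs import (classify_pairs, cumulative_overlap_fraction,
                               fisher_exact_2x2, log2_fold_changes,
                               paired_fc_correlation, random_pairing_null)

from oracles import exact_fisher_two_sided, spearman_rho


def _tx(tid, start, end, strand="+", chrom="c"):
    return TranscriptModel(transcript_id=tid, gene_id=tid, chrom=chrom,
                           strand=strand, exons=((start, end),))


class TestClassifyPairs:
    def test_antisense_overlap_len(self):
        pairs = classify_pairs([_tx("a", 100, 500, "+"), _tx("b", 400, 800, "-")])
        (p,) = pairs
        assert p.relation == "antisense_overlap" and p.overlap_len == 100
        assert p.overlap_fraction_a == pytest.approx(0.25)

    def test_divergent_gap_boundaries(self):
        # minus transcript with last base 1000 (end 1001), plus 5' at 1401
        pairs = classify_pairs([_tx("m", 500, 1001, "-"), _tx("p", 1400, 1800, "+")])
        (p,) = pairs
        assert p.relation == "divergent" and p.gap == 399
        pairs = classify_pairs([_tx("m", 500, 1000, "-"), _tx("p", 1400, 1800, "+")])
        assert pairs[0].gap == 400
        assert classify_pairs([_tx("m", 500, 999, "-"),
                               _tx("p", 1400, 1800, "+")]) == []

    def test_same_strand_never_pairs(self):
        assert classify_pairs([_tx("a", 100, 500), _tx("b", 400, 800)]) == []

    def test_convergent_orientation_not_divergent(self):
        # 3' ends face the gap: tail-to-tail, never a shared promoter
        assert classify_pairs([_tx("p", 100, 500, "+"),
                               _tx("m", 600, 900, "-")]) == []

    def test_zero_gap_not_divergent(self):
        assert classify_pairs([_tx("m", 100, 500, "-"),
                               _tx("p", 500, 900, "+")]) == []

    def test_symmetry_and_strand_flip_covariance(self):
        ts = [_tx("a", 100, 500, "+"), _tx("b", 400, 800, "-"),
              _tx("c", 900, 1200, "-"), _tx("d", 1300, 1600, "+")]
        fwd = {(p.id_a, p.id_b, p.relation) for p in classify_pairs(ts)}
        L = 2000
        flipped = [
            TranscriptModel(transcript_id=t.transcript_id, gene_id=t.gene_id,
                            chrom=t.chrom,
                            strand="-" if t.strand == "+" else "+",
                            exons=((L - t.end, L - t.start),))
            for t in ts]
        rev = {(p.id_a, p.id_b, p.relation) for p in classify_pairs(flipped)}
        assert fwd == rev

    def test_transcript_can_join_multiple_pairs(self):
        ts = [_tx("mid", 400, 800, "-"), _tx("a", 100, 500, "+"),
              _tx("b", 700, 1100, "+")]
        pairs = classify_pairs(ts)
        assert len(pairs) == 2
        assert all(p.relation == "antisense_overlap" for p in pairs)

    def test_relations_mutually_exclusive(self):
        ts = [_tx("a", 100, 500, "-"), _tx("b", 450, 900, "+")]
        pairs = classify_pairs(ts)
        assert len(pairs) == 1   # overlap wins; never also divergent


class TestCumulativeOverlap:
    def test_fully_nested_contributes_one(self):
        nested = _tx("n", 200, 300, "-")
        host = _tx("h", 100, 500, "+")
        assert cumulative_overlap_fraction([nested], [host]) == 1.0

    def test_disjoint_zero(self):
        assert cumulative_overlap_fraction(
            [_tx("a", 0, 100, "+")], [_tx("b", 500, 600, "-")]) == 0.0

    def test_toy_mixture(self):
        t1 = _tx("t1", 0, 100, "+")       # 87 of 100 covered
        t2 = _tx("t2", 1000, 1100, "+")   # uncovered
        cover = _tx("c", 13, 300, "-")
        assert cumulative_overlap_fraction([t1, t2], [cover]) == \
            pytest.approx(0.435)

    def test_union_no_double_counting(self):
        t = _tx("t", 0, 100, "+")
        c1 = _tx("c1", 0, 60, "-")
        c2 = _tx("c2", 40, 100, "-")
        assert cumulative_overlap_fraction([t], [c1, c2]) == 1.0


class TestLog2Fc:
    def test_aua1_style_doubling(self):
        fc = log2_fold_changes({"t": 59.0}, {"t": 118.0}, pseudocount=1.0)
        assert fc["t"] == pytest.approx(math.log2(119 / 60))

    def test_equal_and_zero(self):
        fc = log2_fold_changes({"a": 50.0, "b": 0.0}, {"a": 50.0, "b": 0.0})
        assert fc["a"] == 0.0 and fc["b"] == 0.0


class TestPairedCorrelation:
    def test_comonotone_rho_one(self):
        fcs = {f"a{i}": float(i) for i in range(12)}
        fcs.update({f"b{i}": float(i) * 2 + 1 for i in range(12)})
        pairs = [(f"a{i}", f"b{i}") for i in range(12)]
        out = paired_fc_correlation(pairs, fcs)
        assert out["rho"] == pytest.approx(1.0)

    def test_small_table_matches_rank_formula(self):
        xs = [1.2, -0.5, 0.3, 2.0, -1.1]
        ys = [0.8, -0.2, 1.5, 0.9, -2.0]
        fcs = {}
        pairs = []
        for i, (x, y) in enumerate(zip(xs, ys)):
            fcs[f"a{i}"], fcs[f"b{i}"] = x, y
            pairs.append((f"a{i}", f"b{i}"))
        out = paired_fc_correlation(pairs, fcs)
        assert out["rho"] == pytest.approx(spearman_rho(xs, ys))
        # exact permutation p: all 120 permutations enumerable by hand
        count = 0
        import itertools
        for perm in itertools.permutations(range(5)):
            r = spearman_rho(xs, [ys[j] for j in perm])
            if abs(r) >= abs(out["rho"]) - 1e-12:
                count += 1
        assert out["p_value"] == pytest.approx(count / 120)

    def test_too_few_pairs_nan(self):
        out = paired_fc_correlation([("a", "b")], {"a": 1.0, "b": 2.0})
        assert math.isnan(out["rho"]) and out["n"] == 1


class TestRandomPairingNull:
    def _setup(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        fcs = {}
        pairs = []
        for i in range(n):
            fcs[f"a{i}"] = float(rng.normal())
            fcs[f"b{i}"] = fcs[f"a{i}"] + float(rng.normal(0, 0.1))
            pairs.append((f"a{i}", f"b{i}"))
        return pairs, fcs

    def test_seeded_determinism(self):
        pairs, fcs = self._setup()
        n1 = random_pairing_null(pairs, fcs, n_perm=50, seed=3)
        n2 = random_pairing_null(pairs, fcs, n_perm=50, seed=3)
        assert (n1["rhos"] == n2["rhos"]).all()

    def test_true_partners_never_repaired(self):
        pairs, fcs = self._setup()
        null = random_pairing_null(pairs, fcs, n_perm=200, seed=1)
        obs = paired_fc_correlation(pairs, fcs)["rho"]
        assert obs > null["ci_hi"]

    def test_insufficient_pairs_fatal(self):
        pairs, fcs = self._setup(n=5)
        with pytest.raises(ValueError, match=">= 10"):
            random_pairing_null(pairs, fcs, n_perm=10, seed=0)


class TestFisher:
    def test_balanced_table(self):
        r = fisher_exact_2x2([[10, 10], [10, 10]])
        assert r.odds_ratio == pytest.approx(1.0)
        assert r.p_value == pytest.approx(1.0)

    def test_diagonal_table_exact_value(self):
        r = fisher_exact_2x2([[5, 0], [0, 5]])
        assert r.p_value == pytest.approx(2 / math.comb(10, 5), rel=1e-12)
        assert r.p_value == pytest.approx(0.00794, abs=5e-6)

    def test_haldane_correction_on_zero_cell(self):
        r = fisher_exact_2x2([[5, 0], [2, 5]])
        assert r.odds_ratio == pytest.approx((5.5 * 5.5) / (0.5 * 2.5))

    def test_all_zero_table_nan(self):
        r = fisher_exact_2x2([[0, 0], [0, 0]])
        assert math.isnan(r.p_value)

    @pytest.mark.parametrize("table", [
        [[3, 7], [9, 2]], [[1, 0], [0, 14]], [[8, 8], [2, 11]],
        [[0, 5], [5, 0]], [[12, 1], [3, 4]],
    ])
    def test_matches_enumeration_and_scipy(self, table):
        r = fisher_exact_2x2(table)
        assert r.p_value == pytest.approx(exact_fisher_two_sided(table),
                                          rel=1e-12)
        assert r.p_value == pytest.approx(scipy_fisher(table)[1], rel=1e-9)

    def test_negative_entries_fatal(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[-1, 2], [3, 4]])
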