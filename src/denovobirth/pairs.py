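"""Locus-geometry pair classification and the associated statistics.

Antisense-overlap pairs are opposite-strand transcripts whose genomic spans
intersect by >= 1 bp (no minimum overlap). Divergent pairs are
opposite-strand, non-overlapping transcripts in head-to-head orientation —
each 5' end faces the gap, consistent with a shared bidirectional
promoter — separated by 1-400 nt. Fold-change co-regulation is measured by
Spearman correlation of per-pair log2 fold changes against a
random-re-pairing null; class enrichments use a two-sided Fisher exact test
computed by hypergeometric tail summation (point-probability rule).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.stats import hypergeom, spearmanr

from .catalog import TranscriptModel
from .config import PairConfig

log = logging.getLogger(__name__)

ANTISENSE = "antisense_overlap"
DIVERGENT = "divergent"
NONE = "none"


@dataclass(frozen=True)
class PairClassification:
    id_a: str
    id_b: str
    relation: str
    overlap_len: int = 0
    gap: int = 0
    overlap_fraction_a: float = 0.0
    overlap_fraction_b: float = 0.0


def _exonic_cover(t: TranscriptModel, lo: int, hi: int) -> int:
    return sum(max(0, min(e, hi) - max(s, lo)) for s, e in t.exons)


def classify_pairs(transcripts: Sequence[TranscriptModel],
                   cfg: Optional[PairConfig] = None) -> List[PairClassification]:
    """All antisense-overlap and divergent pairs in one catalog.

    Coordinates are genomic transcript spans (first exon start to last exon
    end); ``cfg.use_exons`` switches overlap measurement to exonic bases.
    A transcript may participate in several pairs. Deterministic ordering
    by (id_a, id_b) with id_a < id_b.
    """
    cfg = cfg or PairConfig()
    out: List[PairClassification] = []
    ts = sorted(transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id))
    for i, a in enumerate(ts):
        for b in ts[i + 1:]:
            if b.chrom != a.chrom:
                break
            if b.start - a.end > cfg.max_divergent_gap:
                break
            if a.strand == b.strand:
                continue
            ov = min(a.end, b.end) - max(a.start, b.start)
            if ov >= 1:
                if cfg.use_exons:
                    lo, hi = max(a.start, b.start), min(a.end, b.end)
                    ov = min(_exonic_cover(a, lo, hi), _exonic_cover(b, lo, hi))
                    if ov < 1:
                        continue
                out.append(PairClassification(
                    id_a=min(a.transcript_id, b.transcript_id),
                    id_b=max(a.transcript_id, b.transcript_id),
                    relation=ANTISENSE, overlap_len=ov,
                    overlap_fraction_a=ov / (a.end - a.start),
                    overlap_fraction_b=ov / (b.end - b.start),
                ))
                continue
            # head-to-head: minus-strand transcript left of plus-strand one,
            # 5' ends facing across the gap
            left, right = (a, b) if a.end <= b.start else (b, a)
            if left.strand == "-" and right.strand == "+":
                gap = right.start - left.end
                if cfg.min_divergent_gap <= gap <= cfg.max_divergent_gap:
                    out.append(PairClassification(
                        id_a=min(a.transcript_id, b.transcript_id),
                        id_b=max(a.transcript_id, b.transcript_id),
                        relation=DIVERGENT, gap=gap,
                    ))
    out.sort(key=lambda p: (p.id_a, p.id_b, p.relation))
    return out


def cumulative_overlap_fraction(transcript_set: Sequence[TranscriptModel],
                                catalog: Sequence[TranscriptModel]) -> float:
    """Summed bases of the given transcripts covered by opposite-strand
    catalog transcripts, divided by their summed span lengths (per-base
    union, no double counting)."""
    total_len = 0
    covered = 0
    for t in transcript_set:
        span_lo, span_hi = t.span
        total_len += span_hi - span_lo
        intervals = []
        for other in catalog:
            if other.transcript_id == t.transcript_id:
                continue
            if other.chrom != t.chrom or other.strand == t.strand:
                continue
            lo = max(span_lo, other.start)
            hi = min(span_hi, other.end)
            if hi > lo:
                intervals.append((lo, hi))
        intervals.sort()
        cur = None
        for lo, hi in intervals:
            if cur is None:
                cur = [lo, hi]
            elif lo > cur[1]:
                covered += cur[1] - cur[0]
                cur = [lo, hi]
            else:
                cur[1] = max(cur[1], hi)
        if cur is not None:
            covered += cur[1] - cur[0]
    return covered / total_len if total_len else 0.0


def log2_fold_changes(expr_normal: Mapping[str, float],
                      expr_stress: Mapping[str, float],
                      pseudocount: float = 1.0) -> Dict[str, float]:
    """log2((TPM_stress + pc) / (TPM_normal + pc)) per transcript."""
    ids = set(expr_normal) | set(expr_stress)
    return {
        t: math.log2((expr_stress.get(t, 0.0) + pseudocount)
                     / (expr_normal.get(t, 0.0) + pseudocount))
        for t in ids
    }


def paired_fc_correlation(pairs: Sequence[Tuple[str, str]],
                          fcs: Mapping[str, float]) -> Dict[str, float]:
    """Spearman correlation of partner fold changes.

    Average ranks for ties; p-value by the large-sample t approximation,
    replaced by an exact permutation p for n < 10. NaN results for n < 3.
    """
    xs = np.array([fcs[a] for a, b in pairs if a in fcs and b in fcs])
    ys = np.array([fcs[b] for a, b in pairs if a in fcs and b in fcs])
    n = len(xs)
    if n < 3:
        return {"rho": float("nan"), "p_value": float("nan"), "n": n}
    rho, p = spearmanr(xs, ys)
    rho = float(rho)
    if n < 10:
        # exact permutation p: Spearman rho is Pearson on ranks, and ranking
        # commutes with permutation, so all n! correlations vectorize
        from scipy.stats import rankdata
        rx = rankdata(xs) - (n + 1) / 2.0
        ry = rankdata(ys) - (n + 1) / 2.0
        denom = math.sqrt((rx ** 2).sum() * (ry ** 2).sum())
        perms = np.array(list(permutations(range(n))))
        null = np.abs((ry[perms] @ rx) / denom)
        p = float((null >= abs(rho) - 1e-12).mean())
    return {"rho": rho, "p_value": float(p), "n": n}


def random_pairing_null(
    pairs: Sequence[Tuple[str, str]],
    fcs: Mapping[str, float],
    n_perm: int = 1000,
    seed: int = 0,
    forbidden: Optional[Mapping[str, Set[str]]] = None,
) -> Dict[str, object]:
    """Null distribution of rho from randomly re-paired overlapping transcripts.

    Each permutation uniformly reassigns partners among the B-side
    transcripts, rejecting assignments that re-create a true pair or pair a
    transcript with a same-locus one (``forbidden`` maps id_a to the ids it
    may never be paired with). Seeded and reproducible.
    """
    usable = [(a, b) for a, b in pairs if a in fcs and b in fcs]
    if len(usable) < 10:
        raise ValueError("random_pairing_null needs >= 10 overlapping pairs")
    a_ids = [a for a, _ in usable]
    b_ids = [b for _, b in usable]
    forb: Dict[str, Set[str]] = {a: {b} for a, b in usable}
    if forbidden:
        for k, v in forbidden.items():
            forb.setdefault(k, set()).update(v)
    rng = np.random.default_rng(seed)
    xs = np.array([fcs[a] for a in a_ids])
    ys_all = np.array([fcs[b] for b in b_ids])
    n = len(usable)
    rhos = np.empty(n_perm)
    for it in range(n_perm):
        for _attempt in range(1000):
            perm = rng.permutation(n)
            ok = all(b_ids[perm[i]] not in forb.get(a_ids[i], ())
                     and b_ids[perm[i]] != a_ids[i]
                     for i in range(n))
            if ok:
                break
        else:
            raise RuntimeError("could not find a valid random re-pairing")
        r, _ = spearmanr(xs, ys_all[perm])
        rhos[it] = r
    return {
        "rhos": rhos,
        "mean": float(rhos.mean()),
        "ci_lo": float(np.percentile(rhos, 2.5)),
        "ci_hi": float(np.percentile(rhos, 97.5)),
    }


@dataclass(frozen=True)
class EnrichmentResult:
    table: Tuple[Tuple[int, int], Tuple[int, int]]
    odds_ratio: float
    p_value: float
    label: str = ""


def fisher_exact_2x2(table: Sequence[Sequence[int]], label: str = "") -> EnrichmentResult:
    """Two-sided Fisher exact test by hypergeometric tail summation.

    Sums the probabilities of all tables with the observed margins whose
    point probability does not exceed the observed one (point-probability
    rule). The odds ratio is the sample OR with a Haldane 0.5 correction
    when any cell is zero.
    """
    (a, b), (c, d) = ((int(table[0][0]), int(table[0][1])),
                      (int(table[1][0]), int(table[1][1])))
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    n = a + b + c + d
    if n == 0:
        return EnrichmentResult(table=((a, b), (c, d)),
                                odds_ratio=float("nan"),
                                p_value=float("nan"), label=label)
    r1, c1 = a + b, a + c
    rv = hypergeom(n, c1, r1)
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    p = min(1.0, p)
    if min(a, b, c, d) == 0:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    return EnrichmentResult(table=((a, b), (c, d)), odds_ratio=float(orr),
                            p_value=p, label=label)
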