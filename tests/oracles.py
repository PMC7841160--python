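"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle re-derives an expected result by enumeration or an independent
formula, sharing no code path with the package implementation it checks.
"""
from __future__ import annotations

from fractions import Fraction
from math import comb
from typing import List, Sequence, Set, Tuple

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")
STOPS = ("TAA", "TAG", "TGA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _count_occurrences(text: str, sub: str) -> int:
    n, start = 0, 0
    while True:
        i = text.find(sub, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


def brute_force_mums(a: str, b: str, min_len: int) -> List[Tuple[int, int, int, str]]:
    """All maximal matches unique in both sequences, by full enumeration.

    Returns sorted (pos_a, pos_b, length, orientation) with pos_b on the
    forward strand of b for reverse-orientation matches. N never matches.
    """
    out: Set[Tuple[int, int, int, str]] = set()
    A = np.frombuffer(a.encode(), dtype=np.uint8)
    for orientation in ("forward", "reverse"):
        bb = b if orientation == "forward" else revcomp(b)
        B = np.frombuffer(bb.encode(), dtype=np.uint8)
        na, nb = len(a), len(bb)
        eq = (A[:, None] == B[None, :]) & (A[:, None] != ord("N")) \
            & (B[None, :] != ord("N"))
        ext = np.zeros((na + 1, nb + 1), dtype=np.int64)
        for i in range(na - 1, -1, -1):
            ext[i, :-1] = np.where(eq[i], ext[i + 1, 1:] + 1, 0)
        cand_i, cand_j = np.nonzero(ext[:na, :nb] >= min_len)
        for i, j in zip(cand_i.tolist(), cand_j.tolist()):
            if i > 0 and j > 0 and eq[i - 1, j - 1]:
                continue  # extendable to the left
            length = int(ext[i, j])
            sub = a[i:i + length]
            if _count_occurrences(a, sub) != 1:
                continue
            if _count_occurrences(bb, sub) != 1:
                continue
            pos_b = j if orientation == "forward" else len(b) - (j + length)
            out.add((i, pos_b, length, orientation))
    return sorted(out)


def brute_force_orfs(seq: str, starts: Sequence[str],
                     min_codons: int = 4) -> List[Tuple[int, int]]:
    """All (start, stop) ORFs, then a containment filter.

    Candidates: every start-codon position whose first downstream in-frame
    stop exists, with length > 3 codons (stop included). ORFs fully contained
    in a longer same-frame ORF are removed — which also enforces the
    most-upstream-start rule, since a downstream start sharing a stop is
    contained in the upstream ORF. Returns sorted (start, end) intervals.
    """
    seq = seq.upper()
    starts = set(starts)
    cands: List[Tuple[int, int, int]] = []
    for frame in range(3):
        positions = list(range(frame, len(seq) - 2, 3))
        codons = {p: seq[p:p + 3] for p in positions}
        stop_positions = [p for p in positions if codons[p] in STOPS]
        for p in positions:
            if codons[p] not in starts or codons[p] in STOPS:
                continue
            nxt = [q for q in stop_positions if q > p]
            if not nxt:
                continue
            end = min(nxt) + 3
            if (end - p) // 3 >= min_codons:
                cands.append((frame, p, end))
    kept = []
    for c in cands:
        contained = any(
            o != c and o[0] == c[0] and o[1] <= c[1] and c[2] <= o[2]
            and (o[2] - o[1]) > (c[2] - c[1])
            for o in cands
        )
        if not contained:
            kept.append((c[1], c[2]))
    return sorted(kept)


def exact_fisher_two_sided(table) -> float:
    """Two-sided Fisher p with exact rational hypergeometric probabilities
    (point-probability rule)."""
    (a, b), (c, d) = table
    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = comb(n, c1)
    support = range(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = {k: Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom)
           for k in support}
    p_obs = pmf[a]
    return float(sum(p for k, p in pmf.items() if p <= p_obs))


def longest_common_substring_length(a: str, b: str) -> int:
    """Classic DP longest common substring (homology-search oracle)."""
    na, nb = len(a), len(b)
    prev = [0] * (nb + 1)
    best = 0
    for i in range(1, na + 1):
        cur = [0] * (nb + 1)
        ai = a[i - 1]
        for j in range(1, nb + 1):
            if ai == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Average-rank Spearman rho from first principles (Pearson on ranks)."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r
    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / (vx * vy) ** 0.5


def interval_union_length(intervals: Sequence[Tuple[int, int]]) -> int:
    total = 0
    cur = None
    for s, e in sorted(intervals):
        if cur is None or s > cur[1]:
            if cur is not None:
                total += cur[1] - cur[0]
            cur = [s, e]
        else:
            cur[1] = max(cur[1], e)
    if cur is not None:
        total += cur[1] - cur[0]
    return total
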