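"""Maximal unique matches (MUMs), synteny blocks and coordinate projection.

A MUM is an exact match between two sequences that occurs exactly once in
each (respecting orientation) and cannot be extended in either direction.
MUMs are found with a generalized suffix array plus LCP array: a candidate
maximal unique pair corresponds to two adjacent suffixes from different
sequences whose LCP exceeds both neighbouring LCPs (uniqueness) and whose
preceding characters differ (left-maximality). `N` never matches: every N
is replaced by a private sentinel before indexing.

Blocks chain collinear, same-orientation MUMs greedily left to right; a
gap of at most ``max_gap`` bases (inclusive) in BOTH genomes joins two
consecutive MUMs. Transcript intervals are projected across genomes using
the per-base mapping inside MUMs where available, and the flanking-MUM
(or block-edge) anchors otherwise.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .config import SyntenyConfig
from .catalog import Genome, TranscriptModel

log = logging.getLogger(__name__)

FORWARD = "forward"
REVERSE = "reverse"

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class MUM:
    pos_a: int
    pos_b: int
    length: int
    orientation: str = FORWARD
    chrom_a: str = ""
    chrom_b: str = ""

    @property
    def end_a(self) -> int:
        return self.pos_a + self.length

    @property
    def end_b(self) -> int:
        return self.pos_b + self.length


@dataclass
class SyntenyBlock:
    mums: List[MUM]
    chrom_a: str = ""
    chrom_b: str = ""

    @property
    def orientation(self) -> str:
        return self.mums[0].orientation

    @property
    def span_a(self) -> Tuple[int, int]:
        return (min(m.pos_a for m in self.mums), max(m.end_a for m in self.mums))

    @property
    def span_b(self) -> Tuple[int, int]:
        return (min(m.pos_b for m in self.mums), max(m.end_b for m in self.mums))


def _suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n) with numpy lexsorts)."""
    n = len(codes)
    rank = np.asarray(codes, dtype=np.int64)
    sa = np.arange(n)
    k = 1
    while True:
        second = np.full(n, -1, dtype=np.int64)
        if k < n:
            second[:-k] = rank[k:]
        order = np.lexsort((second, rank))
        new_rank = np.empty(n, dtype=np.int64)
        prev_r = rank[order]
        prev_s = second[order]
        changed = np.ones(n, dtype=np.int64)
        changed[1:] = (prev_r[1:] != prev_r[:-1]) | (prev_s[1:] != prev_s[:-1])
        new_rank[order] = np.cumsum(changed) - 1
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order
        k *= 2


def _lcp_array(codes: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """Kasai: lcp[i] = LCP(suffix sa[i], suffix sa[i+1])."""
    n = len(codes)
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    lcp = np.zeros(max(n - 1, 0), dtype=np.int64)
    h = 0
    codes_l = codes.tolist()
    for i in range(n):
        r = rank[i]
        if r < n - 1:
            j = sa[r + 1]
            while i + h < n and j + h < n and codes_l[i + h] == codes_l[j + h]:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return lcp


_BASE_CODE = {"A": 1, "C": 2, "G": 3, "T": 4}


def _encode(seq: str, next_code: int) -> Tuple[np.ndarray, int]:
    """Integer codes; every N gets a fresh private code so it never matches."""
    codes = np.zeros(len(seq), dtype=np.int64)
    for base, c in _BASE_CODE.items():
        idx = np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)
        codes[idx] = c
    n_mask = codes == 0
    n_n = int(n_mask.sum())
    if n_n:
        codes[n_mask] = np.arange(next_code, next_code + n_n)
        next_code += n_n
    return codes, next_code


def _unique_maximal_pairs(codes_a: np.ndarray, codes_b: np.ndarray,
                          min_len: int) -> List[Tuple[int, int, int]]:
    """(pos_a, pos_b, length) of maximal matches unique in both sequences."""
    na, nb = len(codes_a), len(codes_b)
    if na == 0 or nb == 0:
        return []
    next_code = 5 + na + nb  # room for N codes assigned during encoding
    sep = np.array([next_code + 1], dtype=np.int64)
    text = np.concatenate([codes_a, sep, codes_b])
    n = len(text)
    sa = _suffix_array(text)
    lcp = _lcp_array(text, sa)
    out = []
    for i in range(n - 1):
        l = int(lcp[i])
        if l < min_len:
            continue
        p, q = int(sa[i]), int(sa[i + 1])
        if p == na or q == na:   # the separator suffix
            continue
        pa, qa = p < na, q < na
        if pa == qa:
            continue
        if not pa:
            p, q = q, p
        # p in A, q in B (text coords); uniqueness: neighbours share < l
        left = int(lcp[i - 1]) if i > 0 else 0
        right = int(lcp[i + 1]) if i + 1 < n - 1 else 0
        if left >= l or right >= l:
            continue
        # left-maximality
        if p > 0 and q > 0 and text[p - 1] == text[q - 1]:
            continue
        out.append((p, q - na - 1, l))
    return out


def find_mums(a: str, b: str, min_len: int = 14,
              both_strands: bool = True) -> List[MUM]:
    """All forward (and reverse-complement) MUMs of length >= min_len.

    Sorted by (pos_a, pos_b). Reverse-orientation MUM coordinates refer to
    the forward strand of B (pos_b is the leftmost matched base in B).
    """
    a, b = a.upper(), b.upper()
    ca, nxt = _encode(a, 5)
    cb, _ = _encode(b, nxt)
    mums = [MUM(pos_a=pa, pos_b=pb, length=l, orientation=FORWARD)
            for pa, pb, l in _unique_maximal_pairs(ca, cb, min_len)]
    if both_strands:
        rb = revcomp(b)
        crb, _ = _encode(rb, nxt)
        for pa, pb_rc, l in _unique_maximal_pairs(ca, crb, min_len):
            pb = len(b) - (pb_rc + l)
            mums.append(MUM(pos_a=pa, pos_b=pb, length=l, orientation=REVERSE))
    mums.sort(key=lambda m: (m.pos_a, m.pos_b, m.orientation))
    return mums


def find_genome_mums(genome_a: Genome, genome_b: Genome, min_len: int = 14,
                     both_strands: bool = True) -> List[MUM]:
    """MUMs between multi-chromosome genomes; uniqueness is genome-wide.

    Chromosomes are concatenated with private separators so a match unique
    within one chromosome but repeated elsewhere in the genome is rejected.
    """
    parts_a, offs_a = [], []
    pos = 0
    for name in sorted(genome_a.chromosomes):
        seq = genome_a.chromosomes[name]
        offs_a.append((pos, pos + len(seq), name))
        parts_a.append(seq)
        parts_a.append("N")  # becomes a private sentinel during encoding
        pos += len(seq) + 1
    parts_b, offs_b = [], []
    pos = 0
    for name in sorted(genome_b.chromosomes):
        seq = genome_b.chromosomes[name]
        offs_b.append((pos, pos + len(seq), name))
        parts_b.append(seq)
        parts_b.append("N")
        pos += len(seq) + 1
    cat_a, cat_b = "".join(parts_a), "".join(parts_b)

    def _locate(offs, p):
        for s, e, name in offs:
            if s <= p < e:
                return name, p - s
        raise AssertionError("position outside all chromosomes")

    out = []
    for m in find_mums(cat_a, cat_b, min_len=min_len, both_strands=both_strands):
        chrom_a, pa = _locate(offs_a, m.pos_a)
        chrom_b, pb = _locate(offs_b, m.pos_b)
        out.append(MUM(pos_a=pa, pos_b=pb, length=m.length,
                       orientation=m.orientation, chrom_a=chrom_a, chrom_b=chrom_b))
    out.sort(key=lambda m: (m.chrom_a, m.pos_a, m.chrom_b, m.pos_b))
    return out


def cluster_mums(mums: Sequence[MUM], cfg: Optional[SyntenyConfig] = None) -> List[SyntenyBlock]:
    """Greedy left-to-right chaining of collinear MUMs into synteny blocks.

    A MUM joins the open block iff it has the block's orientation, is
    B-monotone consistently with that orientation, and the end-to-start gap
    is <= max_gap in both genomes (inclusive; a 101-base gap splits).
    """
    cfg = cfg or SyntenyConfig()
    if any(mums[i].pos_a > mums[i + 1].pos_a for i in range(len(mums) - 1)):
        raise ValueError("cluster_mums requires input sorted by pos_a")
    chain, outliers = mums, []
    if cfg.outlier_diag_tol > 0 and len(mums) > 2:
        # an isolated match whose orientation/diagonal agrees with neither
        # flanking MUM would otherwise shatter a collinear run; it is chained
        # as its own singleton block instead
        def supported(m: MUM, n: MUM) -> bool:
            return (m.orientation == n.orientation and
                    abs((m.pos_b - m.pos_a) - (n.pos_b - n.pos_a))
                    <= cfg.outlier_diag_tol)
        chain, outliers = [], []
        for i, m in enumerate(mums):
            prev_m = mums[i - 1] if i > 0 else None
            next_m = mums[i + 1] if i + 1 < len(mums) else None
            if ((prev_m is None or not supported(m, prev_m)) and
                    (next_m is None or not supported(m, next_m))):
                outliers.append(m)
            else:
                chain.append(m)
    blocks: List[SyntenyBlock] = []
    open_block: Optional[SyntenyBlock] = None
    for m in chain:
        if open_block is not None:
            prev = open_block.mums[-1]
            ok = m.orientation == prev.orientation
            if ok:
                gap_a = m.pos_a - prev.end_a
                if m.orientation == FORWARD:
                    ok = m.pos_b >= prev.pos_b
                    gap_b = m.pos_b - prev.end_b
                else:
                    ok = m.end_b <= prev.end_b
                    gap_b = prev.pos_b - m.end_b
                ok = ok and gap_a <= cfg.max_gap and gap_b <= cfg.max_gap
            if ok:
                open_block.mums.append(m)
                continue
        open_block = SyntenyBlock(mums=[m], chrom_a=m.chrom_a, chrom_b=m.chrom_b)
        blocks.append(open_block)
    for m in outliers:
        blocks.append(SyntenyBlock(mums=[m], chrom_a=m.chrom_a, chrom_b=m.chrom_b))
    blocks.sort(key=lambda b: b.span_a)
    return blocks


def genome_coverage(blocks: Sequence[SyntenyBlock], genome_a: Genome) -> float:
    """Fraction of genome A covered by the union of block A-spans."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for b in blocks:
        by_chrom.setdefault(b.chrom_a, []).append(b.span_a)
    covered = 0
    for chrom, spans in by_chrom.items():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s > cur_e:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        covered += cur_e - cur_s
    total = genome_a.total_length
    return covered / total if total else 0.0


def _project_boundary(block: SyntenyBlock, x: int, is_end: bool) -> int:
    """B-coordinate for A-boundary x (half-open interval semantics).

    Inside a MUM the exact per-base mapping applies; otherwise the flanking
    MUM end (start boundary) / start (end boundary), falling back to the
    block edge.
    """
    fwd = block.orientation == FORWARD
    for m in block.mums:
        if m.pos_a <= x <= m.end_a:
            off = x - m.pos_a
            return m.pos_b + off if fwd else m.pos_b + (m.length - off)
    if not is_end:
        prev = [m for m in block.mums if m.end_a <= x]
        if prev:
            m = max(prev, key=lambda m: m.end_a)
            return m.end_b if fwd else m.pos_b
        return block.span_b[0] if fwd else block.span_b[1]
    nxt = [m for m in block.mums if m.pos_a >= x]
    if nxt:
        m = min(nxt, key=lambda m: m.pos_a)
        return m.pos_b if fwd else m.end_b
    return block.span_b[1] if fwd else block.span_b[0]


def _mum_coverage_of(block: SyntenyBlock, interval: Tuple[int, int]) -> int:
    s, e = interval
    return sum(max(0, min(m.end_a, e) - max(m.pos_a, s)) for m in block.mums)


def project_interval(
    blocks: Sequence[SyntenyBlock],
    interval_a: Tuple[int, int],
    chrom_a: str = "",
) -> Optional[Tuple[Tuple[int, int], str]]:
    """Project an A-interval into genome B via the containing synteny block.

    Returns ((start_b, end_b), orientation) or None when no block's A-span
    contains the interval. Among overlapping candidate blocks the one whose
    MUMs cover more of the interval wins (tie: leftmost block; logged).
    """
    s, e = interval_a
    cands = [b for b in blocks
             if b.chrom_a == chrom_a and b.span_a[0] <= s and e <= b.span_a[1]]
    if not cands:
        return None
    if len(cands) > 1:
        cands.sort(key=lambda b: (-_mum_coverage_of(b, interval_a), b.span_a[0]))
        log.debug("interval %s in %d overlapping blocks; using best MUM coverage",
                  interval_a, len(cands))
    block = cands[0]
    b1 = _project_boundary(block, s, is_end=False)
    b2 = _project_boundary(block, e, is_end=True)
    lo, hi = (b1, b2) if b1 <= b2 else (b2, b1)
    if lo == hi:
        hi = lo + 1
    return (lo, hi), block.orientation


def syntenic_transcript_overlaps(
    transcripts_a: Sequence[TranscriptModel],
    transcripts_b: Sequence[TranscriptModel],
    blocks: Sequence[SyntenyBlock],
    require_same_strand: bool = True,
) -> List[Tuple[str, str]]:
    """Pairs (id_a, id_b) of transcripts occupying the same syntenic region.

    Each A transcript's genomic span is projected into B; B transcripts whose
    span intersects the projection by >= 1 bp are potential homologues. By
    default the B transcript must lie on the same effective strand (A strand
    flipped for reverse-orientation blocks); ``require_same_strand=False``
    gives the strand-blind behaviour.
    """
    pairs = set()
    for ta in transcripts_a:
        proj = project_interval(blocks, ta.span, chrom_a=ta.chrom)
        if proj is None:
            continue
        (lo, hi), orientation = proj
        if require_same_strand:
            if orientation == FORWARD:
                want = ta.strand
            else:
                want = "-" if ta.strand == "+" else "+"
        for tb in transcripts_b:
            if tb.start < hi and lo < tb.end:
                if require_same_strand and tb.strand != want:
                    continue
                pairs.add((ta.transcript_id, tb.transcript_id))
    return sorted(pairs)


def write_blocks_tsv(blocks: Sequence[SyntenyBlock], path) -> None:
    rows = ["\t".join(["chrom_a", "start_a", "end_a", "chrom_b", "start_b",
                       "end_b", "orientation", "n_mums"])]
    for b in blocks:
        sa, sb = b.span_a, b.span_b
        rows.append("\t".join(map(str, [b.chrom_a, sa[0], sa[1], b.chrom_b,
                                        sb[0], sb[1], b.orientation, len(b.mums)])))
    with open(path, "w") as fh:
        fh.write("\n".join(rows) + "\n")
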