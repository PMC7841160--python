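"""Branch-of-origin assignment and transcript/ORF conservation classes.

Each focal transcript accumulates evidence ranks: species ranks where
sequence homology found a hit, ranks where a syntenic transcript overlaps
its projected locus, plus the ranks of every member of its intra-species
paralog group (paralog propagation: duplicated genes inherit the deepest
conservation found for any copy). The deepest rank maps to a conservation
class through configurable bins (default: ranks 0-2 de novo, 3-4
genus-specific, >= 5 conserved); any hit in the distant outgroup proteome
screen forces the conserved class regardless of rank, guarding against
multiple loss or horizontal transfer.

ORF conservation in a sister species follows the alignment rule: a
candidate ATG-to-stop ORF in the syntenic sequence counts as conserved when
its aligned span overlaps the focal ORF's span and it is at least half the
focal ORF's length. Transcript-first and ORF-first origination routes are
the fractions of shared / focal-specific translated de novo transcripts
without / with such a conserved ORF.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .config import AgeConfig
from .orfkit import OrfRecord, STOP_CODONS, CANONICAL_START

log = logging.getLogger(__name__)

DE_NOVO = "de_novo"
GENUS_SPECIFIC = "genus_specific"
CONSERVED = "conserved"

MODE_FULL = "full"
MODE_FOCAL_TX_ONLY = "focal_transcriptome_only"
MODE_ANNOTATIONS_ONLY = "annotations_only"


@dataclass
class EvidenceSet:
    transcript_id: str
    blast_species_ranks: Set[int] = field(default_factory=set)
    synteny_species_ranks: Set[int] = field(default_factory=set)
    paralog_group: Optional[frozenset] = None
    outgroup_hit: bool = False


@dataclass(frozen=True)
class AgeAssignment:
    transcript_id: str
    deepest_rank: int
    conservation_class: str
    used_blast: bool = False
    used_synteny: bool = False
    used_paralogs: bool = False
    outgroup_hit: bool = False


class ClassBins:
    """Deterministic rank -> conservation class map."""

    def __init__(self, cfg: Optional[AgeConfig] = None) -> None:
        cfg = cfg or AgeConfig()
        self.de_novo_max_rank = cfg.de_novo_max_rank
        self.genus_specific_max_rank = cfg.genus_specific_max_rank

    def __call__(self, rank: int) -> str:
        if rank < 0:
            raise ValueError(f"unknown rank {rank}")
        if rank <= self.de_novo_max_rank:
            return DE_NOVO
        if rank <= self.genus_specific_max_rank:
            return GENUS_SPECIFIC
        return CONSERVED


def assign_branch(
    evidence: EvidenceSet,
    paralog_evidence: Mapping[frozenset, Set[int]],
    bins: ClassBins,
) -> AgeAssignment:
    """Deepest rank over own homology + synteny ranks plus paralog-propagated
    ranks; rank 0 (focal-specific) when all evidence is empty; any outgroup
    hit forces the conserved class."""
    own = evidence.blast_species_ranks | evidence.synteny_species_ranks
    paralog_ranks: Set[int] = set()
    if evidence.paralog_group is not None:
        paralog_ranks = set(paralog_evidence.get(evidence.paralog_group, set()))
    ranks = own | paralog_ranks
    deepest = max(ranks) if ranks else 0
    cls = CONSERVED if evidence.outgroup_hit else bins(deepest)
    return AgeAssignment(
        transcript_id=evidence.transcript_id,
        deepest_rank=deepest,
        conservation_class=cls,
        used_blast=bool(evidence.blast_species_ranks),
        used_synteny=bool(evidence.synteny_species_ranks),
        used_paralogs=bool(paralog_ranks - own),
        outgroup_hit=evidence.outgroup_hit,
    )


def apply_outgroup_screen(evidence_sets: Iterable[EvidenceSet],
                          outgroup_hits: Set[str]) -> List[EvidenceSet]:
    """Flag transcripts with a filtered outgroup-proteome hit. Idempotent."""
    out = []
    for ev in evidence_sets:
        if ev.transcript_id in outgroup_hits:
            ev.outgroup_hit = True
        out.append(ev)
    return out


def propagate_paralog_ranks(
    evidence_sets: Sequence[EvidenceSet],
    paralog_groups: Sequence[Set[str]],
) -> Dict[frozenset, Set[int]]:
    """Union of (blast + synteny) ranks over each paralog group's members,
    and attach the group to each member's evidence."""
    by_id = {ev.transcript_id: ev for ev in evidence_sets}
    group_ranks: Dict[frozenset, Set[int]] = {}
    for group in paralog_groups:
        key = frozenset(group)
        ranks: Set[int] = set()
        for tid in group:
            ev = by_id.get(tid)
            if ev is not None:
                ranks |= ev.blast_species_ranks | ev.synteny_species_ranks
                ev.paralog_group = key
        group_ranks[key] = ranks
    return group_ranks


def compare_age_strategies(bundle, config, modes: Sequence[str] = (
        MODE_FULL, MODE_FOCAL_TX_ONLY, MODE_ANNOTATIONS_ONLY)) -> Dict[str, Dict[str, int]]:
    """Per-mode conservation-class counts on a simulated bundle.

    full: transcript catalogs (annotated + novel) everywhere;
    focal_transcriptome_only: the focal species keeps its transcriptome but
    other species contribute annotated transcripts only;
    annotations_only: annotated transcripts everywhere (novel focal
    transcripts disappear from the output entirely).
    """
    from . import pipeline  # runtime import; pipeline orchestrates the stages
    out: Dict[str, Dict[str, int]] = {}
    for mode in modes:
        assignments = pipeline.estimate_ages(bundle, config, mode=mode)
        counts = {DE_NOVO: 0, GENUS_SPECIFIC: 0, CONSERVED: 0}
        for a in assignments.values():
            counts[a.conservation_class] += 1
        out[mode] = counts
    return out


# ---------------------------------------------------------------------------
# pairwise global alignment (focal vs sister syntenic region)

MATCH_SCORE = 1.0
MISMATCH_SCORE = -1.0
GAP_OPEN = -4.0    # charged once per gap, in addition to the per-base extend
GAP_EXTEND = -1.0

_NEG = -1e9


@dataclass
class PairwiseAlignment:
    """Global alignment with a focal <-> other coordinate map.

    ``a_to_b[i]`` is the other-sequence position aligned to focal position i,
    or -1 when focal position i sits opposite a gap (and vice versa for
    ``b_to_a``).
    """

    score: float
    aligned_a: str
    aligned_b: str
    a_to_b: np.ndarray
    b_to_a: np.ndarray

    def map_interval(self, start_a: int, end_a: int) -> Optional[Tuple[int, int]]:
        """Other-sequence interval aligned to focal [start_a, end_a)."""
        idx = self.a_to_b[start_a:end_a]
        idx = idx[idx >= 0]
        if idx.size == 0:
            return None
        return int(idx.min()), int(idx.max()) + 1


def align_syntenic_region(seq_focal: str, seq_other: str,
                          cfg: Optional[AgeConfig] = None) -> PairwiseAlignment:
    """Affine-gap global alignment (match 1, mismatch -1, gap open -4,
    extend -1; a length-k gap costs -4 - k). Deterministic tie-break:
    match/mismatch > gap in other (consume focal) > gap in focal."""
    cfg = cfg or AgeConfig()
    a, b = seq_focal.upper(), seq_other.upper()
    n, m = len(a), len(b)
    if max(n, m) > cfg.max_align_len:
        raise ValueError(
            f"sequences exceed max_align_len={cfg.max_align_len}; window the region"
        )
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    sub = np.where(aa[:, None] == bb[None, :], MATCH_SCORE, MISMATCH_SCORE)
    nmask = (aa[:, None] == ord("N")) | (bb[None, :] == ord("N"))
    sub[nmask] = MISMATCH_SCORE

    # M: a[i-1] aligned to b[j-1]; X: gap in other (consume focal/a);
    # Y: gap in focal (consume other/b)
    ptr_m = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0=M,1=X,2=Y predecessor
    ptr_x = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_y = np.zeros((n + 1, m + 1), dtype=np.int8)
    M_prev = np.full(m + 1, _NEG)
    X_prev = np.full(m + 1, _NEG)
    Y_prev = np.full(m + 1, _NEG)
    M_prev[0] = 0.0
    Y_prev[1:] = GAP_OPEN + GAP_EXTEND * np.arange(1, m + 1)
    ptr_y[0, 1:] = 2
    ptr_y[0, 1] = 0
    rows_choice = []
    for i in range(1, n + 1):
        M_cur = np.full(m + 1, _NEG)
        X_cur = np.full(m + 1, _NEG)
        Y_cur = np.full(m + 1, _NEG)
        # X: vertical gap, from row i-1 same column
        candM = M_prev + GAP_OPEN + GAP_EXTEND
        candX = X_prev + GAP_EXTEND
        candY = Y_prev + GAP_OPEN + GAP_EXTEND
        X_cur = np.maximum(np.maximum(candM, candX), candY)
        ptr_x[i] = np.where(candM >= X_cur - 1e-12, 0,
                            np.where(candX >= X_cur - 1e-12, 1, 2))
        # M: diagonal
        diag_best = np.maximum(np.maximum(M_prev[:-1], X_prev[:-1]), Y_prev[:-1])
        M_cur[1:] = sub[i - 1] + diag_best
        ptr_m[i, 1:] = np.where(M_prev[:-1] >= diag_best - 1e-12, 0,
                                np.where(X_prev[:-1] >= diag_best - 1e-12, 1, 2))
        # Y: horizontal gap within the current row, via running max
        maxMX = np.maximum(M_cur, X_cur)
        shifted = maxMX[:-1] + GAP_OPEN + GAP_EXTEND - GAP_EXTEND * np.arange(m)
        run = np.maximum.accumulate(shifted)
        Y_cur[1:] = run + GAP_EXTEND * np.arange(1, m + 1)
        fromM = M_cur[:-1] + GAP_OPEN + GAP_EXTEND
        fromX = X_cur[:-1] + GAP_OPEN + GAP_EXTEND
        fromY = Y_cur[:-1] + GAP_EXTEND
        best_pred = np.maximum(np.maximum(fromM, fromX), fromY)
        Y_cur[1:] = np.maximum(Y_cur[1:], best_pred)  # identical; keeps ties exact
        ptr_y[i, 1:] = np.where(fromM >= Y_cur[1:] - 1e-12, 0,
                                np.where(fromX >= Y_cur[1:] - 1e-12, 1, 2))
        M_prev, X_prev, Y_prev = M_cur, X_cur, Y_cur
        rows_choice.append(None)
    # final matrix choice, preference M > X > Y
    finals = (M_prev[m], X_prev[m], Y_prev[m])
    score = max(finals)
    state = 0 if finals[0] >= score - 1e-12 else (1 if finals[1] >= score - 1e-12 else 2)

    # traceback needs all three pointer matrices only (scores re-derived by path)
    i, j = n, m
    ops: List[Tuple[str, int, int]] = []
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            ops.append(("M", i - 1, j - 1))
            state = int(ptr_m[i, j])
            i, j = i - 1, j - 1
        elif state == 1 and i > 0:
            ops.append(("X", i - 1, -1))
            state = int(ptr_x[i, j])
            i -= 1
        elif state == 2 and j > 0:
            ops.append(("Y", -1, j - 1))
            state = int(ptr_y[i, j])
            j -= 1
        elif i > 0:      # boundary: remaining focal prefix against gaps
            state = 1
        else:
            state = 2
    ops.reverse()
    al_a, al_b = [], []
    a_to_b = np.full(n, -1, dtype=np.int64)
    b_to_a = np.full(m, -1, dtype=np.int64)
    for op, ia, jb in ops:
        if op == "M":
            al_a.append(a[ia])
            al_b.append(b[jb])
            a_to_b[ia] = jb
            b_to_a[jb] = ia
        elif op == "X":
            al_a.append(a[ia])
            al_b.append("-")
        else:
            al_a.append("-")
            al_b.append(b[jb])
    return PairwiseAlignment(score=float(score), aligned_a="".join(al_a),
                             aligned_b="".join(al_b), a_to_b=a_to_b, b_to_a=b_to_a)


def _enumerate_atg_orfs(seq: str) -> List[Tuple[int, int]]:
    """All canonical ATG -> stop ORF intervals (0-based half-open incl. stop)."""
    seq = seq.upper()
    out = []
    for frame in range(3):
        start = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos:pos + 3]
            if codon in STOP_CODONS:
                if start is not None:
                    out.append((start, pos + 3))
                start = None
            elif start is None and codon == CANONICAL_START:
                start = pos
    return out


def classify_orf_conservation(
    focal_orf_interval: Tuple[int, int],
    alignment: PairwiseAlignment,
    other_seq: str,
    cfg: Optional[AgeConfig] = None,
) -> bool:
    """True when the other sequence holds an ATG->stop ORF whose aligned span
    overlaps the focal ORF's span and whose length is at least half the
    focal ORF's length. Unmappable focal ORFs return False with a warning."""
    cfg = cfg or AgeConfig()
    s, e = focal_orf_interval
    mapped = alignment.map_interval(s, e)
    if mapped is None:
        log.warning("focal ORF [%d,%d) aligns entirely to gaps; treating as "
                    "not conserved", s, e)
        return False
    lo, hi = mapped
    focal_len = e - s
    min_overlap = max(cfg.min_orf_overlap_positions,
                      cfg.min_orf_overlap_frac * max(hi - lo, focal_len))
    for os_, oe in _enumerate_atg_orfs(other_seq):
        if os_ < hi and lo < oe:
            overlap = min(oe, hi) - max(os_, lo)
            if overlap >= min_overlap and \
                    (oe - os_) >= cfg.orf_conserved_min_frac * focal_len:
                return True
    return False


def origination_route_fractions(
    shared_orf_conserved: Mapping[str, bool],
    focal_specific_orf_present: Mapping[str, bool],
) -> Dict[str, float]:
    """Transcript-first and ORF-first fractions.

    shared_orf_conserved: for each shared (non-focal-specific) de novo
    transcript with a translated ORF, whether the ORF is conserved in a
    sister species. transcript-first = fraction NOT conserved.
    focal_specific_orf_present: for each focal-specific translated de novo
    transcript, whether a qualifying ORF already exists in the sister
    syntenic region. ORF-first = fraction present. Empty denominators
    report NaN.
    """
    n_shared = len(shared_orf_conserved)
    n_focal = len(focal_specific_orf_present)
    tf = (sum(1 for v in shared_orf_conserved.values() if not v) / n_shared
          if n_shared else float("nan"))
    of = (sum(1 for v in focal_specific_orf_present.values() if v) / n_focal
          if n_focal else float("nan"))
    return {
        "transcript_first_fraction": tf,
        "orf_first_fraction": of,
        "n_shared": n_shared,
        "n_focal_specific": n_focal,
    }
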