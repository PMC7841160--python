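"""Seed-and-extend homology search with BLAST-style filtering.

This is a transparent ungapped surrogate for BLASTN/TBLASTX: exact k-mer
seeds (11 nt / 4 aa) on the same strand only, extended along the diagonal
to the maximal-scoring ungapped segment, with Karlin-Altschul e-values
E = K * m * n * exp(-lambda * S) using published ungapped parameters
(DNA match +1 / mismatch -2: lambda 1.33, K 0.621; BLOSUM62 ungapped:
lambda 0.3176, K 0.134). Reverse-complement matches are never seeded
(nucleotide) and only the three transcript-strand frames are translated,
mirroring the strand-specific protocol. Precomputed hit tables in the
standard 12-column tabular format can be imported instead.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .config import HomologyConfig

log = logging.getLogger(__name__)

PROGRAM_NUC = "nuc"
PROGRAM_TRANS = "trans"
PROGRAM_PROT_OUTGROUP = "prot_outgroup"

# published ungapped Karlin-Altschul parameters
_NUC_LAMBDA, _NUC_K = 1.33, 0.621
_AA_LAMBDA, _AA_K = 0.3176, 0.134
_NUC_MATCH, _NUC_MISMATCH = 1, -2

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_STOP_SCORE = -4.0


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_species: str
    subject_id: str
    program: str
    evalue: float
    aln_len_nt: int
    identity_frac: float
    query_strand_match: bool = True
    score: float = 0.0
    qstart: int = 0   # 0-based, query nt coordinates
    qend: int = 0
    sstart: int = 0
    send: int = 0

    def __post_init__(self) -> None:
        if self.evalue < 0 or self.aln_len_nt < 1:
            raise ValueError("bad hit: evalue >= 0 and aln_len_nt >= 1 required")
        if not (0 <= self.identity_frac <= 1):
            raise ValueError("identity_frac must lie in [0, 1]")


class TranscriptDatabase:
    """Indexed transcript sequences for the seed-and-extend search.

    entries: (subject_species, subject_id, sequence). Amino-acid frames are
    translated lazily on first translated search.
    """

    def __init__(self, entries: Sequence[Tuple[str, str, str]],
                 cfg: Optional[HomologyConfig] = None,
                 protein: bool = False) -> None:
        self.cfg = cfg or HomologyConfig()
        self.protein = protein
        self.entries = [(sp, tid, seq.upper()) for sp, tid, seq in entries]
        self.total_nt = sum(len(s) for _, _, s in self.entries)
        self._nuc_index: Optional[Dict[str, List[Tuple[int, int]]]] = None
        self._aa_frames: Optional[List[List[str]]] = None
        self._aa_index: Optional[Dict[str, List[Tuple[int, int, int]]]] = None
        self.total_aa = 0

    def _build_nuc_index(self) -> None:
        k = self.cfg.seed_k_nuc
        index: Dict[str, List[Tuple[int, int]]] = {}
        for ei, (_, _, seq) in enumerate(self.entries):
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos:pos + k]
                if "N" in kmer:
                    continue
                index.setdefault(kmer, []).append((ei, pos))
        self._nuc_index = index

    def _build_aa_index(self) -> None:
        k = self.cfg.seed_k_aa
        frames: List[List[str]] = []
        index: Dict[str, List[Tuple[int, int, int]]] = {}
        total = 0
        for ei, (_, _, seq) in enumerate(self.entries):
            if self.protein:
                fr = [seq]      # entries already amino acid (proteome screen)
            else:
                fr = [_translate_frame(seq, f) for f in range(3)]
            frames.append(fr)
            for f, prot in enumerate(fr):
                total += len(prot)
                for pos in range(len(prot) - k + 1):
                    word = prot[pos:pos + k]
                    if "*" in word or "X" in word:
                        continue
                    index.setdefault(word, []).append((ei, f, pos))
        self._aa_frames = frames
        self._aa_index = index
        self.total_aa = total


def _translate_frame(seq: str, frame: int) -> str:
    sub = seq[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return ""
    return str(Seq(sub).translate())


_XDROP_NUC = 20.0
_XDROP_AA = 15.0


def _xdrop_extend(scores: np.ndarray, seed_start: int, seed_end: int,
                  xdrop: float) -> Tuple[float, int, int]:
    """BLAST-style ungapped extension anchored on an exact seed.

    Extends the maximal-scoring segment left/right from the seed with an
    X-drop stop; the returned segment always contains the seed.
    """
    seed_score = float(scores[seed_start:seed_end].sum())
    best_r, run, end = 0.0, 0.0, seed_end
    for j in range(seed_end, len(scores)):
        run += float(scores[j])
        if run > best_r:
            best_r, end = run, j + 1
        elif run < best_r - xdrop:
            break
    best_l, run, start = 0.0, 0.0, seed_start
    for j in range(seed_start - 1, -1, -1):
        run += float(scores[j])
        if run > best_l:
            best_l, start = run, j
        elif run < best_l - xdrop:
            break
    return seed_score + best_l + best_r, start, end


def _nuc_evalue(score: float, m: int, n: int) -> float:
    return _NUC_K * m * n * math.exp(-_NUC_LAMBDA * score)


def _aa_evalue(score: float, m: int, n: int) -> float:
    return _AA_K * m * n * math.exp(-_AA_LAMBDA * score)


def search_nucleotide(query_id: str, query_seq: str, db: TranscriptDatabase,
                      cfg: Optional[HomologyConfig] = None) -> List[HomologyHit]:
    """Same-strand ungapped nucleotide search of one query against the database."""
    cfg = cfg or db.cfg
    if db.protein:
        raise ValueError("nucleotide search against a protein database")
    query_seq = query_seq.upper()
    k = cfg.seed_k_nuc
    if len(query_seq) < k:
        raise ValueError(f"query shorter than seed length {k}")
    if not db.entries:
        return []
    if db._nuc_index is None:
        db._build_nuc_index()
    seeds: Dict[Tuple[int, int], List[int]] = {}
    for qpos in range(len(query_seq) - k + 1):
        kmer = query_seq[qpos:qpos + k]
        if "N" in kmer:
            continue
        for ei, spos in db._nuc_index.get(kmer, ()):
            seeds.setdefault((ei, qpos - spos), []).append(qpos)
    qarr = np.frombuffer(query_seq.encode(), dtype=np.uint8)
    hits: List[HomologyHit] = []
    for (ei, diag), qpos_list in sorted(seeds.items()):
        sp, sid, sseq = db.entries[ei]
        sarr = np.frombuffer(sseq.encode(), dtype=np.uint8)
        q0 = max(0, diag)
        s0 = q0 - diag
        length = min(len(qarr) - q0, len(sarr) - s0)
        if length < k:
            continue
        qs = qarr[q0:q0 + length]
        ss = sarr[s0:s0 + length]
        match = (qs == ss) & (qs != ord("N"))
        scores = np.where(match, _NUC_MATCH, _NUC_MISMATCH).astype(np.float64)
        segments = set()
        for qpos in sorted(qpos_list):
            off = qpos - q0
            if any(a <= off < b for _, a, b in segments):
                continue
            segments.add(_xdrop_extend(scores, off, off + k, _XDROP_NUC))
        for score, a, b in sorted(segments, key=lambda t: t[1]):
            if b - a < k or score <= 0:
                continue
            ident = float(match[a:b].mean())
            if ident < cfg.min_identity:
                continue
            ev = _nuc_evalue(score, len(query_seq), db.total_nt)
            if ev > cfg.evalue_report_max:
                continue
            hits.append(HomologyHit(
                query_id=query_id, subject_species=sp, subject_id=sid,
                program=PROGRAM_NUC, evalue=ev, aln_len_nt=b - a,
                identity_frac=ident, query_strand_match=True, score=score,
                qstart=q0 + a, qend=q0 + b, sstart=s0 + a, send=s0 + b,
            ))
    hits.sort(key=lambda h: (h.evalue, h.subject_species, h.subject_id, h.qstart))
    return hits


def search_translated(query_id: str, query_seq: str, db: TranscriptDatabase,
                      cfg: Optional[HomologyConfig] = None,
                      program: str = PROGRAM_TRANS) -> List[HomologyHit]:
    """Translated search: query and subjects in the 3 forward frames only,
    4-aa exact seeds, ungapped BLOSUM62 extension."""
    cfg = cfg or db.cfg
    query_seq = query_seq.upper()
    if not db.entries:
        return []
    if db._aa_index is None:
        db._build_aa_index()
    k = cfg.seed_k_aa
    hits: List[HomologyHit] = []
    for qframe in range(3):
        qprot = _translate_frame(query_seq, qframe)
        if len(qprot) < k:
            continue
        seeds: Dict[Tuple[int, int, int], List[int]] = {}
        for qpos in range(len(qprot) - k + 1):
            word = qprot[qpos:qpos + k]
            if "*" in word or "X" in word:
                continue
            for ei, f, spos in db._aa_index.get(word, ()):
                seeds.setdefault((ei, f, qpos - spos), []).append(qpos)
        for (ei, f, diag), qpos_list in sorted(seeds.items()):
            sp, sid, _ = db.entries[ei]
            sprot = db._aa_frames[ei][f]
            q0 = max(0, diag)
            s0 = q0 - diag
            length = min(len(qprot) - q0, len(sprot) - s0)
            if length < k:
                continue
            scores = np.empty(length)
            idents = np.zeros(length, dtype=bool)
            for i in range(length):
                qa, sa = qprot[q0 + i], sprot[s0 + i]
                if qa in "*X" or sa in "*X":
                    scores[i] = _STOP_SCORE
                else:
                    scores[i] = _BLOSUM62[qa, sa]
                    idents[i] = qa == sa
            segments = set()
            for qpos in sorted(qpos_list):
                off = qpos - q0
                if any(a <= off < b for _, a, b in segments):
                    continue
                segments.add(_xdrop_extend(scores, off, off + k, _XDROP_AA))
            for score, a, b in sorted(segments, key=lambda t: t[1]):
                if b - a < k or score <= 0:
                    continue
                ident = float(idents[a:b].mean())
                ev = _aa_evalue(score, len(qprot), db.total_aa)
                if ev > cfg.evalue_report_max:
                    continue
                hits.append(HomologyHit(
                    query_id=query_id, subject_species=sp, subject_id=sid,
                    program=program, evalue=ev, aln_len_nt=3 * (b - a),
                    identity_frac=ident, query_strand_match=True, score=score,
                    qstart=qframe + 3 * (q0 + a), qend=qframe + 3 * (q0 + b),
                    sstart=f + 3 * (s0 + a), send=f + 3 * (s0 + b),
                ))
    hits.sort(key=lambda h: (h.evalue, h.subject_species, h.subject_id, h.qstart))
    return hits


def filter_hits(hits: Iterable[HomologyHit],
                cfg: Optional[HomologyConfig] = None) -> List[HomologyHit]:
    """Keep same-strand hits with e-value strictly below the cut-off; for the
    nucleotide program the alignment must additionally be over 100 nt."""
    cfg = cfg or HomologyConfig()
    out = []
    for h in hits:
        if not h.query_strand_match:
            continue
        if h.evalue >= cfg.evalue_max:
            continue
        if h.program == PROGRAM_NUC and h.aln_len_nt < cfg.min_nuc_aln_len:
            continue
        out.append(h)
    return out


def find_paralogs(focal_hits: Iterable[HomologyHit],
                  all_ids: Optional[Iterable[str]] = None) -> List[Set[str]]:
    """Connected components of the intra-species hit graph.

    Transcripts in ``all_ids`` with no hits become singleton groups.
    Self-hits are ignored.
    """
    g = nx.Graph()
    if all_ids is not None:
        g.add_nodes_from(all_ids)
    for h in focal_hits:
        if h.query_id != h.subject_id:
            g.add_edge(h.query_id, h.subject_id)
    return sorted((set(c) for c in nx.connected_components(g)),
                  key=lambda c: sorted(c)[0])


def write_hit_table(hits: Sequence[HomologyHit], path) -> None:
    """Standard 12-column tabular hit format; subject carries a species prefix."""
    with open(path, "w") as fh:
        for h in hits:
            sstart, send = (h.sstart + 1, h.send) if h.query_strand_match \
                else (h.send, h.sstart + 1)
            fh.write("\t".join(map(str, [
                h.query_id, f"{h.subject_species}|{h.subject_id}",
                f"{100 * h.identity_frac:.2f}", h.aln_len_nt,
                max(0, round(h.aln_len_nt * (1 - h.identity_frac))), 0,
                h.qstart + 1, h.qend, sstart, send,
                f"{h.evalue:.3g}", f"{h.score:.1f}",
            ])) + "\n")


def read_hit_table(path, program: str = PROGRAM_NUC) -> List[HomologyHit]:
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(fields)}")
            (qid, subject, pident, alen, _mm, _go,
             qstart, qend, sstart, send, ev, score) = fields
            if "|" in subject:
                sp, sid = subject.split("|", 1)
            else:
                sp, sid = "", subject
            s1, s2 = int(sstart), int(send)
            strand_match = s1 <= s2
            hits.append(HomologyHit(
                query_id=qid, subject_species=sp, subject_id=sid, program=program,
                evalue=float(ev), aln_len_nt=int(alen),
                identity_frac=float(pident) / 100.0,
                query_strand_match=strand_match, score=float(score),
                qstart=int(qstart) - 1, qend=int(qend),
                sstart=(s1 - 1 if strand_match else s2 - 1),
                send=(s2 if strand_match else s1),
            ))
    return hits
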