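"""ORF enumeration and ORF property scores.

ORF rule: per frame, each stop codon yields at most one ORF, beginning at
the most upstream valid start codon (canonical ATG, optionally the nine
near-cognate single-substitution neighbours) with no intervening in-frame
stop; ORFs must be longer than 3 codons counting the stop (protein >= 3 aa)
and no emitted ORF is fully contained in a longer same-frame ORF.

The hexamer coding score is the mean log2 ratio of in-frame (step 3)
hexamer frequencies in coding versus non-coding training sequence; the
isoelectric point solves the Henderson-Hasselbalch net charge for zero by
bisection on the EMBOSS pKa scale.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio.Seq import Seq

from .config import OrfConfig

STOP_CODONS = ("TAA", "TAG", "TGA")
CANONICAL_START = "ATG"

START_CANONICAL = "canonical"
START_NEAR_COGNATE = "near_cognate"

ALL_HEXAMERS = ["".join(p) for p in product("ACGT", repeat=6)]

# EMBOSS pKa scale (as published with the EMBOSS iep tool / Peptides package)
EMBOSS_PK = {
    "Nterm": 8.6, "Cterm": 3.6,
    "K": 10.8, "R": 12.5, "H": 6.5,
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
}
_POSITIVE = ("K", "R", "H")
_NEGATIVE = ("D", "E", "C", "Y")


@dataclass(frozen=True)
class OrfRecord:
    """An enumerated ORF in transcript coordinates (0-based half-open;
    end_tx points one past the stop codon)."""

    transcript_id: str
    frame: int
    start_tx: int
    end_tx: int
    start_codon: str
    start_class: str
    protein: str

    def __post_init__(self) -> None:
        if (self.end_tx - self.start_tx) % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")
        if len(self.protein) != (self.end_tx - self.start_tx) // 3 - 1:
            raise ValueError("protein length must equal codons - 1")

    @property
    def n_codons(self) -> int:
        return (self.end_tx - self.start_tx) // 3

    @property
    def orf_id(self) -> str:
        return f"{self.transcript_id}:{self.start_tx}-{self.end_tx}"


def enumerate_orfs(tx_seq: str, transcript_id: str = "",
                   cfg: Optional[OrfConfig] = None) -> List[OrfRecord]:
    """All ORFs of a transcript under the upstream-start / >3 codon rules."""
    cfg = cfg or OrfConfig()
    tx_seq = tx_seq.upper()
    starts = {CANONICAL_START}
    if cfg.allow_near_cognate:
        starts |= set(cfg.near_cognate_starts)
    records: List[OrfRecord] = []
    for frame in range(3):
        region_start: Optional[int] = None  # most upstream start since last stop
        for pos in range(frame, len(tx_seq) - 2, 3):
            codon = tx_seq[pos:pos + 3]
            if codon in STOP_CODONS:
                if region_start is not None:
                    start, end = region_start, pos + 3
                    n_codons = (end - start) // 3
                    if n_codons >= cfg.min_codons:
                        prot = str(Seq(tx_seq[start:end - 3]).translate())
                        sc = tx_seq[start:start + 3]
                        records.append(OrfRecord(
                            transcript_id=transcript_id, frame=frame,
                            start_tx=start, end_tx=end, start_codon=sc,
                            start_class=(START_CANONICAL if sc == CANONICAL_START
                                         else START_NEAR_COGNATE),
                            protein=prot,
                        ))
                region_start = None
            elif region_start is None and codon in starts:
                region_start = pos
    # containment filter: drop ORFs fully inside a longer same-frame ORF
    records.sort(key=lambda r: (r.start_tx, r.end_tx))
    kept = []
    for r in records:
        contained = any(
            o.frame == r.frame and o is not r
            and o.start_tx <= r.start_tx and r.end_tx <= o.end_tx
            and (o.end_tx - o.start_tx) > (r.end_tx - r.start_tx)
            for o in records
        )
        if not contained:
            kept.append(r)
    return kept


@dataclass(frozen=True)
class HexamerTable:
    scores: Mapping[str, float]
    pseudocount: float
    n_coding_nt: int
    n_noncoding_nt: int

    def __post_init__(self) -> None:
        if set(self.scores) != set(ALL_HEXAMERS):
            raise ValueError("hexamer table must contain all 4096 hexamers")
        if any(not math.isfinite(v) for v in self.scores.values()):
            raise ValueError("hexamer scores must be finite")


def _count_hexamers_inframe(seqs: Iterable[str]) -> Tuple[Dict[str, int], int]:
    counts = {h: 0 for h in ALL_HEXAMERS}
    total_nt = 0
    for seq in seqs:
        seq = seq.upper()
        total_nt += len(seq)
        for pos in range(0, len(seq) - 5, 3):
            hexamer = seq[pos:pos + 6]
            if hexamer in counts:
                counts[hexamer] += 1
    return counts, total_nt


def train_hexamer_table(coding_seqs: Sequence[str], noncoding_seqs: Sequence[str],
                        pseudocount: float = 1.0,
                        min_training_nt: int = 10000) -> HexamerTable:
    """log2((f_cod + eps)/(f_noncod + eps)) per hexamer, step-3 counting."""
    cod_counts, cod_nt = _count_hexamers_inframe(coding_seqs)
    non_counts, non_nt = _count_hexamers_inframe(noncoding_seqs)
    if cod_nt < min_training_nt or non_nt < min_training_nt:
        raise ValueError(
            f"insufficient training data: coding {cod_nt} nt, "
            f"noncoding {non_nt} nt (need >= {min_training_nt} each)"
        )
    n_cod = sum(cod_counts.values())
    n_non = sum(non_counts.values())
    denom_c = n_cod + pseudocount * 4096
    denom_n = n_non + pseudocount * 4096
    scores = {
        h: math.log2(((cod_counts[h] + pseudocount) / denom_c)
                     / ((non_counts[h] + pseudocount) / denom_n))
        for h in ALL_HEXAMERS
    }
    return HexamerTable(scores=scores, pseudocount=pseudocount,
                        n_coding_nt=cod_nt, n_noncoding_nt=non_nt)


def coding_score(orf_nt_seq: str, table: HexamerTable) -> float:
    """Mean hexamer score over in-frame hexamers (positions 0, 3, 6, ...);
    NaN for sequences shorter than 6 nt."""
    seq = orf_nt_seq.upper()
    if len(seq) < 6:
        return float("nan")
    vals = [table.scores[seq[p:p + 6]]
            for p in range(0, len(seq) - 5, 3) if seq[p:p + 6] in table.scores]
    if not vals:
        return float("nan")
    return sum(vals) / len(vals)


def net_charge(protein: str, pH: float,
               scale: Mapping[str, float] = EMBOSS_PK) -> float:
    """Henderson-Hasselbalch net charge at the given pH."""
    protein = protein.upper()
    charge = 1.0 / (1.0 + 10 ** (pH - scale["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (scale["Cterm"] - pH))
    for aa in _POSITIVE:
        n = protein.count(aa)
        if n:
            charge += n / (1.0 + 10 ** (pH - scale[aa]))
    for aa in _NEGATIVE:
        n = protein.count(aa)
        if n:
            charge -= n / (1.0 + 10 ** (scale[aa] - pH))
    return charge


def isoelectric_point(protein: str,
                      scale: Mapping[str, float] = EMBOSS_PK,
                      tol: float = 1e-4) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14]."""
    if not protein:
        return float("nan")
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        c = net_charge(protein, mid, scale)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def write_protein_fasta(orfs: Iterable[OrfRecord], path) -> None:
    """Predicted protein sequences, one record per ORF (id = orf_id)."""
    with open(path, "w") as fh:
        for o in orfs:
            fh.write(f">{o.orf_id} frame={o.frame} start={o.start_class}\n")
            for i in range(0, len(o.protein), 60):
                fh.write(o.protein[i:i + 60] + "\n")


def longest_translated_orf(orfs: Sequence[OrfRecord],
                           called_ids: Iterable[str]) -> Optional[OrfRecord]:
    """Longest-protein ORF among those whose orf_id is in ``called_ids``;
    ties break toward the smaller transcript start."""
    called = set(called_ids)
    cand = [o for o in orfs if o.orf_id in called]
    if not cand:
        return None
    return min(cand, key=lambda o: (-len(o.protein), o.start_tx))
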