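"""Translated-ORF calling from ribosome-profiling P-site tracks.

The caller is a transparent surrogate for periodicity/uniformity-based ORF
classification: score = periodicity x uniformity, where periodicity is the
fraction of P-sites in frame 0 of the ORF and uniformity is the normalized
Shannon entropy (PME) of counts across up to 10 equal codon bins. An ORF is
called translated when score >= 0.7, it has >= 10 P-site reads and its
protein is >= 9 aa, in at least one condition.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .config import TranslationConfig
from .orfkit import OrfRecord

log = logging.getLogger(__name__)


@dataclass
class PsiteTrack:
    """Per-position P-site counts along one transcript."""

    transcript_id: str
    counts: np.ndarray
    offset_rule: str = "length-dependent"
    n_dropped_length: int = 0
    n_dropped_bounds: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("P-site counts must be non-negative")

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class TranslationCall:
    orf_id: str
    condition: str
    n_reads: int
    frame_counts: Tuple[int, int, int]
    periodicity: float
    uniformity: float
    score: float
    called: bool


def assign_psites(
    read_alignments: Iterable[Tuple[str, int, int, int]],
    transcript_lengths: Mapping[str, int],
    cfg: Optional[TranslationConfig] = None,
) -> Dict[str, PsiteTrack]:
    """Build P-site tracks from (transcript_id, five_prime_pos, read_length,
    count) rows; P-site = 5' position + offset(read length). Reads with
    unknown lengths or P-sites outside the transcript are dropped and counted.
    """
    cfg = cfg or TranslationConfig()
    tracks = {
        tid: PsiteTrack(transcript_id=tid, counts=np.zeros(L, dtype=np.int64))
        for tid, L in transcript_lengths.items()
    }
    for tid, pos5, read_len, count in read_alignments:
        track = tracks.get(tid)
        if track is None:
            continue
        if read_len not in cfg.psite_offsets:
            track.n_dropped_length += count
            continue
        p = pos5 + cfg.psite_offsets[read_len]
        if 0 <= p < len(track.counts):
            track.counts[p] += count
        else:
            track.n_dropped_bounds += count
    dropped = sum(t.n_dropped_length for t in tracks.values())
    if dropped:
        log.info("dropped %d reads with lengths outside the offset table", dropped)
    return tracks


def psite_tracks_from_positions(
    positions: Iterable[Tuple[str, int, int]],
    transcript_lengths: Mapping[str, int],
) -> Dict[str, PsiteTrack]:
    """Pass-through mode for pre-computed P-sites (transcript_id, position, count)."""
    tracks = {
        tid: PsiteTrack(transcript_id=tid, counts=np.zeros(L, dtype=np.int64),
                        offset_rule="precomputed")
        for tid, L in transcript_lengths.items()
    }
    for tid, pos, count in positions:
        track = tracks.get(tid)
        if track is None:
            continue
        if 0 <= pos < len(track.counts):
            track.counts[pos] += count
        else:
            track.n_dropped_bounds += count
    return tracks


def _uniformity(codon_counts: np.ndarray, n_bins: int) -> float:
    """Normalized Shannon entropy over equal codon bins; 0 when no reads."""
    total = codon_counts.sum()
    if total == 0 or n_bins < 2:
        return 0.0
    n_codons = len(codon_counts)
    bin_idx = (np.arange(n_codons) * n_bins) // n_codons
    bins = np.bincount(bin_idx, weights=codon_counts, minlength=n_bins)
    p = bins / bins.sum()
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    return h / math.log(n_bins)


def score_orf(orf: OrfRecord, track: PsiteTrack,
              cfg: Optional[TranslationConfig] = None,
              condition: str = "normal") -> TranslationCall:
    """Score one ORF on one condition's track and apply the call thresholds."""
    cfg = cfg or TranslationConfig()
    counts = track.counts[orf.start_tx:orf.end_tx]
    pos = np.arange(len(counts))
    frames = pos % 3
    f = tuple(int(counts[frames == fr].sum()) for fr in range(3))
    total = sum(f)
    periodicity = f[0] / total if total else 0.0
    codon_counts = counts.reshape(-1, 3).sum(axis=1)  # frame-agnostic per-codon profile
    n_bins = min(cfg.max_uniformity_bins, orf.n_codons)
    uniformity = _uniformity(codon_counts.astype(np.float64), n_bins)
    score = periodicity * uniformity
    called = (score >= cfg.score_threshold
              and total >= cfg.min_reads
              and len(orf.protein) >= cfg.min_len_aa)
    return TranslationCall(
        orf_id=orf.orf_id, condition=condition, n_reads=total,
        frame_counts=f, periodicity=periodicity, uniformity=uniformity,
        score=score, called=called,
    )


def call_transcript_translation(
    orfs: Sequence[OrfRecord],
    calls_by_condition: Mapping[str, Sequence[TranslationCall]],
) -> Tuple[bool, List[OrfRecord]]:
    """A transcript is translated iff any of its ORFs is called in any
    condition, independent of which condition passed the expression filter.
    Returns (translated, all called ORFs)."""
    called_ids = {
        c.orf_id
        for calls in calls_by_condition.values()
        for c in calls if c.called
    }
    translated_orfs = [o for o in orfs if o.orf_id in called_ids]
    return bool(translated_orfs), translated_orfs


def sensitivity_by_expression(
    truly_translated: Iterable[str],
    called_translated: Iterable[str],
    expression: Mapping[str, float],
    bin_edges: Sequence[float],
) -> pd.DataFrame:
    """Per-TPM-bin sensitivity (called / truly translated) with exact
    binomial 95% CIs; empty bins report NaN."""
    truly = sorted(set(truly_translated))
    called = set(called_translated)
    edges = list(bin_edges)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        members = [t for t in truly if lo <= expression.get(t, 0.0) < hi]
        n = len(members)
        k = sum(1 for t in members if t in called)
        if n == 0:
            rows.append({"tpm_lo": lo, "tpm_hi": hi, "n": 0,
                         "sensitivity": float("nan"),
                         "ci_lo": float("nan"), "ci_hi": float("nan")})
        else:
            ci = binomtest(k, n).proportion_ci(confidence_level=0.95)
            rows.append({"tpm_lo": lo, "tpm_hi": hi, "n": n,
                         "sensitivity": k / n,
                         "ci_lo": ci.low, "ci_hi": ci.high})
    return pd.DataFrame(rows)
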