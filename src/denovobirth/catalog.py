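"""Genomes, transcript catalogs and expression tables.

Internal coordinates are 0-based half-open throughout; GTF input/output
converts from/to the 1-based closed convention at the boundary. Transcript
redundancy at catalog merge requires same-strand exonic overlap of at least
one base: antisense overlap never removes a novel transcript, because
antisense novel transcripts are the signal the downstream analysis measures.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")

ANNOTATED = "annotated"
NOVEL = "novel"

PATTERN_NORMAL_ONLY = "normal_only"
PATTERN_STRESS_ONLY = "stress_only"
PATTERN_BOTH = "both"


class CatalogError(ValueError):
    """Fatal catalog/expression input problem."""


@dataclass(frozen=True)
class Genome:
    """A species' chromosome sequences (uppercase A/C/G/T/N)."""

    species_id: str
    chromosomes: Mapping[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            if not seq:
                raise CatalogError(f"chromosome {name!r} is empty")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise CatalogError(
                    f"chromosome {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    @classmethod
    def from_fasta(cls, path, species_id: str) -> "Genome":
        chroms = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            chroms[rec.id] = str(rec.seq).upper()
        if not chroms:
            raise CatalogError(f"no sequences in {path}")
        return cls(species_id=species_id, chromosomes=chroms)

    def to_fasta(self, path) -> None:
        recs = [SeqRecord(Seq(seq), id=name, description="")
                for name, seq in sorted(self.chromosomes.items())]
        SeqIO.write(recs, str(path), "fasta")


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded exonic interval set on one chromosome (0-based half-open)."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    provenance: str = ANNOTATED

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise CatalogError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if self.provenance not in (ANNOTATED, NOVEL):
            raise CatalogError(f"{self.transcript_id}: bad provenance {self.provenance!r}")
        if not self.exons:
            raise CatalogError(f"{self.transcript_id}: no exons")
        prev_end = -1
        for s, e in self.exons:
            if e <= s:
                raise CatalogError(f"{self.transcript_id}: empty exon [{s},{e})")
            if s < prev_end:
                raise CatalogError(f"{self.transcript_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> Tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def sequence(self, genome: Genome) -> str:
        """Spliced transcript sequence, reverse-complemented for minus strand."""
        chrom = genome.chromosomes[self.chrom]
        seq = "".join(chrom[s:e] for s, e in self.exons)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> Dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_transcripts_gtf(path, genome: Genome) -> List[TranscriptModel]:
    """Read exon features from a GTF into TranscriptModels.

    GTF is 1-based closed; intervals are converted to 0-based half-open.
    Unknown chromosomes, out-of-range exons and missing transcript_id
    attributes are fatal, reported with the offending line number.
    """
    exons: Dict[str, List[Tuple[int, int]]] = {}
    meta: Dict[str, Tuple[str, str, str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise CatalogError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            if chrom not in genome.chromosomes:
                raise CatalogError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            start0, end0 = int(start) - 1, int(end)
            if start0 < 0 or end0 > len(genome.chromosomes[chrom]):
                raise CatalogError(f"{path}:{lineno}: exon beyond chromosome end")
            attributes = _parse_attributes(attrs)
            if "transcript_id" not in attributes:
                raise CatalogError(f"{path}:{lineno}: missing transcript_id attribute")
            tid = attributes["transcript_id"]
            gid = attributes.get("gene_id", tid)
            prov = attributes.get("provenance", ANNOTATED)
            if tid in meta and meta[tid][:3] != (chrom, strand, gid):
                raise CatalogError(
                    f"{path}:{lineno}: transcript {tid} spans chromosomes/strands"
                )
            meta[tid] = (chrom, strand, gid, prov)
            exons.setdefault(tid, []).append((start0, end0))
    out = []
    for tid, ex in exons.items():
        chrom, strand, gid, prov = meta[tid]
        out.append(TranscriptModel(
            transcript_id=tid, gene_id=gid, chrom=chrom, strand=strand,
            exons=tuple(sorted(ex)), provenance=prov,
        ))
    out.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    return out


def write_transcripts_gtf(transcripts: Iterable[TranscriptModel], path) -> None:
    rows = []
    for t in sorted(transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id)):
        for s, e in t.exons:
            attrs = (f'transcript_id "{t.transcript_id}"; gene_id "{t.gene_id}"; '
                     f'provenance "{t.provenance}";')
            rows.append("\t".join([
                t.chrom, "denovobirth", "exon", str(s + 1), str(e),
                ".", t.strand, ".", attrs,
            ]))
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


@dataclass(frozen=True)
class ExpressionTable:
    """Per-condition TPM values for one species."""

    species_id: str
    condition: str
    values: Mapping[str, float]

    def get(self, transcript_id: str) -> float:
        return float(self.values.get(transcript_id, 0.0))


def compute_tpm(counts: Mapping[str, int], lengths: Mapping[str, int],
                species_id: str = "", condition: str = "normal") -> ExpressionTable:
    """TPM_i = (c_i / L_i) / sum_j (c_j / L_j) * 1e6."""
    rates = {}
    for tid, c in counts.items():
        if c < 0:
            raise CatalogError(f"negative count for {tid}")
        L = lengths[tid]
        if L < 1:
            raise CatalogError(f"length < 1 for {tid}")
        rates[tid] = c / L
    total = sum(rates.values())
    if total == 0:
        raise CatalogError("empty library: all counts are zero")
    values = {tid: r / total * 1e6 for tid, r in rates.items()}
    return ExpressionTable(species_id=species_id, condition=condition, values=values)


def read_expression_tsv(path, species_id: str, condition: str) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t")
    if "transcript_id" not in df.columns or "tpm" not in df.columns:
        raise CatalogError(f"{path}: expected columns transcript_id, tpm")
    return ExpressionTable(
        species_id=species_id, condition=condition,
        values=dict(zip(df["transcript_id"].astype(str), df["tpm"].astype(float))),
    )


def write_expression_tsv(table: ExpressionTable, path) -> None:
    df = pd.DataFrame(sorted(table.values.items()), columns=["transcript_id", "tpm"])
    df.to_csv(path, sep="\t", index=False)


def _exonic_overlap(a: TranscriptModel, b: TranscriptModel) -> int:
    """Total exonic intersection in bases (any strand, same chromosome)."""
    if a.chrom != b.chrom:
        return 0
    total = 0
    for s1, e1 in a.exons:
        for s2, e2 in b.exons:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def merge_catalogs(annotated: Sequence[TranscriptModel],
                   novel: Sequence[TranscriptModel]) -> List[TranscriptModel]:
    """Annotated transcripts plus non-redundant novel ones.

    A novel transcript is redundant — and dropped, with the triggering
    annotated transcript logged — when it shares >= 1 bp of same-strand
    exonic overlap with any annotated transcript. Opposite-strand overlap
    never triggers removal.
    """
    seen = {t.transcript_id for t in annotated}
    dup = [t.transcript_id for t in novel if t.transcript_id in seen]
    if dup:
        raise CatalogError(f"duplicate transcript ids across catalogs: {dup[:5]}")
    by_chrom_strand: Dict[Tuple[str, str], List[TranscriptModel]] = {}
    for t in annotated:
        by_chrom_strand.setdefault((t.chrom, t.strand), []).append(t)
    merged = list(annotated)
    for t in novel:
        trigger = None
        for a in by_chrom_strand.get((t.chrom, t.strand), ()):
            if a.end <= t.start or a.start >= t.end:
                continue
            if _exonic_overlap(t, a) >= 1:
                trigger = a
                break
        if trigger is None:
            merged.append(t)
        else:
            log.info("dropping redundant novel transcript %s (overlaps annotated %s)",
                     t.transcript_id, trigger.transcript_id)
    merged.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    return merged


def filter_expressed(
    transcripts: Sequence[TranscriptModel],
    tables: Sequence[ExpressionTable],
    threshold: float = 15.0,
) -> Tuple[List[TranscriptModel], Dict[str, str]]:
    """Keep transcripts with TPM strictly above ``threshold`` in >= 1 condition.

    Returns the kept transcripts and their expression pattern
    (normal_only / stress_only / both) under the same strict threshold.
    Missing expression entries count as TPM 0 (warned once).
    """
    normal = [t for t in tables if t.condition == "normal"]
    stress = [t for t in tables if t.condition == "stress"]
    warned = False
    kept: List[TranscriptModel] = []
    patterns: Dict[str, str] = {}
    for t in transcripts:
        if not warned and not any(t.transcript_id in tab.values for tab in tables):
            log.warning("transcript %s missing from all expression tables; TPM 0 assumed",
                        t.transcript_id)
            warned = True
        n = max((tab.get(t.transcript_id) for tab in normal), default=0.0)
        s = max((tab.get(t.transcript_id) for tab in stress), default=0.0)
        n_ok, s_ok = n > threshold, s > threshold
        if not (n_ok or s_ok):
            continue
        kept.append(t)
        patterns[t.transcript_id] = (
            PATTERN_BOTH if (n_ok and s_ok)
            else PATTERN_NORMAL_ONLY if n_ok else PATTERN_STRESS_ONLY
        )
    return kept, patterns


def detection_report(
    transcripts: Sequence[TranscriptModel],
    tables: Sequence[ExpressionTable],
    expressed_threshold: float = 15.0,
    detection_floor: float = 2.0,
) -> pd.DataFrame:
    """Per-transcript detection statistics: max TPM, detected (> floor) and
    expressed (> threshold) flags. The floor is reporting-only; pipeline
    membership uses the expressed threshold."""
    rows = []
    for t in transcripts:
        mx = max((tab.get(t.transcript_id) for tab in tables), default=0.0)
        rows.append({
            "transcript_id": t.transcript_id,
            "max_tpm": mx,
            "detected": mx > detection_floor,
            "expressed": mx > expressed_threshold,
        })
    return pd.DataFrame(rows)
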