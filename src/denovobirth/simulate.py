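"""Ground-truthed synthetic clade generator.

The stated world is a rooted 6-species ladder (focal, sp1..sp4, outgroup)
sharing one ancestral chromosome. Conserved genes (plus-strand, biased codon
usage) exist in every species' annotation; planted transcripts (minus
strand, novel provenance) are DNA that exists everywhere but is transcribed
only in the birth subtree given by ``birth_branch_rank`` (0 = focal only,
r = focal plus species of rank <= r). Placements: antisense transcripts
overlap a conserved gene on the opposite strand (a translated ORF, when
planted, sits in the non-overlapping portion so the host gene's sequence
stays free); divergent transcripts sit head-to-head 1-400 nt upstream of a
gene; intergenic transcripts sit > 400 nt from any gene.

Sequences evolve down the tree by per-branch substitutions and geometric
indels confined to spacer DNA (gene and transcript loci are indel-protected
so transcript-internal coordinates stay truth-consistent). After evolution,
coding integrity is enforced per truth: conserved-gene CDSs and carried
planted ORFs are stop-repaired; where the truth says an ORF is absent in a
sister species it is stop-disrupted in all three frames (no stop-free run of
12 codons survives), encoding the transcript-first / ORF-first ground truth.

Expression is log-normal; stress log2 fold changes of antisense partners are
drawn from a Gaussian copula at the configured Spearman rho (divergent pairs
at a lower rho). Ribo-Seq P-site profiles place reads multinomially with
P(frame 0) = p_frame over uniform codon positions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .catalog import (ANNOTATED, NOVEL, ExpressionTable, Genome,
                      TranscriptModel, write_expression_tsv,
                      write_transcripts_gtf)
from .config import SimConfig
from .ribo import PsiteTrack

CHROM = "chr1"
FOCAL = "focal"
OUTGROUP = "outgroup"

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {c: i for i, c in enumerate("ACGT")}

STOPS = ("TAA", "TAG", "TGA")
SENSE_CODONS = ["".join(c) for c in
                (a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT")
                if "".join(c) not in STOPS]
# fixed codon-usage bias: pyrimidine-ending codons preferred 3:1
_CODON_W = np.array([3.0 if c[2] in "TC" else 1.0 for c in SENSE_CODONS])
_CODON_P = _CODON_W / _CODON_W.sum()


@dataclass(frozen=True)
class SpeciesTree:
    newick: str
    focal_species: str
    branch_rank: Dict[str, int]
    branch_lengths: Dict[str, float]

    def rank(self, species: str) -> int:
        return self.branch_rank[species]

    @property
    def species(self) -> List[str]:
        return sorted(self.branch_rank, key=self.branch_rank.get)


def ladder_tree(n_ladder: int, branch_length: float) -> SpeciesTree:
    """(((((focal,sp1),sp2),...),outgroup) with equal branch lengths."""
    ranks = {FOCAL: 0}
    node = f"{FOCAL}:{branch_length}"
    for k in range(1, n_ladder + 1):
        ranks[f"sp{k}"] = k
        node = f"({node},sp{k}:{branch_length}):{branch_length}"
    ranks[OUTGROUP] = n_ladder + 1
    newick = f"({node},{OUTGROUP}:{branch_length});"
    lengths = {sp: branch_length for sp in ranks}
    return SpeciesTree(newick=newick, focal_species=FOCAL,
                       branch_rank=ranks, branch_lengths=lengths)


@dataclass
class TruthRecord:
    transcript_id: str
    birth_branch_rank: int
    true_class: str
    placement: str          # intergenic | antisense_overlap | divergent
    partner_id: Optional[str]
    translated: bool
    orf_start_tx: Optional[int] = None
    orf_end_tx: Optional[int] = None
    orf_conserved_elsewhere: bool = False
    true_log2fc: float = 0.0

    def __post_init__(self) -> None:
        if (self.partner_id is not None) != (self.placement != "intergenic"):
            raise ValueError("partner_id set iff placement != intergenic")


@dataclass
class SimBundle:
    cfg: SimConfig
    tree: SpeciesTree
    genomes: Dict[str, Genome]
    catalogs: Dict[str, List[TranscriptModel]]
    truth: List[TruthRecord]
    conserved_gene_ids: List[str]
    expression: Dict[Tuple[str, str], ExpressionTable] = field(default_factory=dict)
    psite_tracks: Dict[str, Dict[str, PsiteTrack]] = field(default_factory=dict)

    @property
    def focal_catalog(self) -> List[TranscriptModel]:
        return self.catalogs[self.tree.focal_species]

    def truth_by_id(self) -> Dict[str, TruthRecord]:
        return {t.transcript_id: t for t in self.truth}


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _rand_cds(rng: np.random.Generator, n_codons: int, biased: bool = True) -> str:
    """ATG + (n_codons - 2) sense codons + stop."""
    if biased:
        idx = rng.choice(len(SENSE_CODONS), size=n_codons - 2, p=_CODON_P)
    else:
        idx = rng.integers(0, len(SENSE_CODONS), size=n_codons - 2)
    body = "".join(SENSE_CODONS[i] for i in idx)
    stop = STOPS[rng.integers(0, 3)]
    return "ATG" + body + stop


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


class _Builder:
    def __init__(self) -> None:
        self.pieces: List[str] = []
        self.pos = 0

    def emit(self, seq: str) -> Tuple[int, int]:
        start = self.pos
        if seq:
            self.pieces.append(seq)
            self.pos += len(seq)
        return (start, self.pos)

    def sequence(self) -> str:
        return "".join(self.pieces)


@dataclass
class _Locus:
    tid: str
    gene_id: str
    span: Tuple[int, int]
    strand: str
    provenance: str
    truth: Optional[TruthRecord] = None


def _planted_specs(cfg: SimConfig, rng: np.random.Generator) -> List[dict]:
    specs = []
    j = 0
    for key in sorted(cfg.n_planted):
        rank_s, placement = key.split("_", 1)
        rank = int(rank_s.replace("rank", ""))
        placement = {"antisense": "antisense_overlap"}.get(placement, placement)
        for _ in range(cfg.n_planted[key]):
            translated = bool(rng.random() < cfg.translated_fraction)
            if translated:
                if rank == 0:
                    conserved_elsewhere = bool(rng.random() < cfg.orf_first_fraction)
                elif rank <= 2:
                    conserved_elsewhere = bool(rng.random() < cfg.orf_conserved_fraction)
                else:
                    conserved_elsewhere = True
            else:
                conserved_elsewhere = False
            specs.append({
                "tid": f"tx{j:03d}", "rank": rank, "placement": placement,
                "translated": translated,
                "orf_codons": int(rng.integers(cfg.orf_len_codons_range[0],
                                               cfg.orf_len_codons_range[1] + 1)),
                "conserved_elsewhere": conserved_elsewhere,
            })
            j += 1
    return specs


def _build_ancestor(cfg: SimConfig, rng: np.random.Generator
                    ) -> Tuple[str, List[_Locus]]:
    specs = _planted_specs(cfg, rng)
    hosts = [s for s in specs if s["placement"] in ("antisense_overlap", "divergent")]
    intergenic = [s for s in specs if s["placement"] == "intergenic"]
    if len(hosts) > cfg.n_conserved_genes:
        raise ValueError(
            f"need at least {len(hosts)} conserved genes to host "
            f"antisense/divergent placements (have {cfg.n_conserved_genes})"
        )
    n_plain = cfg.n_conserved_genes - len(hosts)

    gene_cds: Dict[str, str] = {}
    units: List[Tuple[str, Optional[dict], str]] = []  # (kind, spec, gene_id)
    gi = 0
    for spec in hosts:
        units.append((spec["placement"], spec, f"g{gi:03d}"))
        gi += 1
    plain_ids = []
    for _ in range(n_plain):
        units.append(("plain", None, f"g{gi:03d}"))
        plain_ids.append(f"g{gi:03d}")
        gi += 1
    for spec in intergenic:
        units.append(("intergenic", spec, ""))
    rng.shuffle(units)

    b = _Builder()
    loci: List[_Locus] = []
    paralog_sources = plain_ids[:cfg.n_paralog_pairs]

    def new_cds(gene_id: str) -> str:
        n_codons = int(rng.integers(cfg.gene_len_codons_range[0],
                                    cfg.gene_len_codons_range[1] + 1))
        cds = _rand_cds(rng, n_codons, biased=True)
        gene_cds[gene_id] = cds
        return cds

    def make_truth(spec: dict, partner: Optional[str],
                   orf_tx: Optional[Tuple[int, int]]) -> TruthRecord:
        rank = spec["rank"]
        cls = ("de_novo" if rank <= 2 else
               "genus_specific" if rank <= 4 else "conserved")
        return TruthRecord(
            transcript_id=spec["tid"], birth_branch_rank=rank, true_class=cls,
            placement=spec["placement"], partner_id=partner,
            translated=spec["translated"],
            orf_start_tx=orf_tx[0] if orf_tx else None,
            orf_end_tx=orf_tx[1] if orf_tx else None,
            orf_conserved_elsewhere=spec["conserved_elsewhere"],
        )

    def planted_body(spec: dict) -> Tuple[str, Optional[Tuple[int, int]]]:
        """Free transcript sequence with an embedded ORF when translated."""
        if spec["translated"]:
            orf = _rand_cds(rng, spec["orf_codons"], biased=False)
            u5 = _rand_dna(rng, int(rng.integers(30, 61)))
            u3 = _rand_dna(rng, int(rng.integers(30, 61)))
            return u5 + orf + u3, (len(u5), len(u5) + len(orf))
        return _rand_dna(rng, int(rng.integers(*cfg.transcript_len_range))), None

    for kind, spec, gene_id in units:
        b.emit(_rand_dna(rng, int(rng.integers(600, 901))))
        if kind == "plain":
            span = b.emit(new_cds(gene_id))
            loci.append(_Locus(gene_id, gene_id, span, "+", ANNOTATED))
        elif kind == "divergent":
            t, orf_tx = planted_body(spec)
            span_t = b.emit(_revcomp(t))
            b.emit(_rand_dna(rng, int(rng.integers(1, 401))))
            span_g = b.emit(new_cds(gene_id))
            loci.append(_Locus(spec["tid"], spec["tid"], span_t, "-", NOVEL,
                               make_truth(spec, gene_id, orf_tx)))
            loci.append(_Locus(gene_id, gene_id, span_g, "+", ANNOTATED))
        elif kind == "antisense_overlap":
            cds = new_cds(gene_id)
            if spec["translated"]:
                free, orf_tx_free = planted_body(spec)
                ov = int(rng.integers(30, min(121, len(cds))))
            else:
                T = int(rng.integers(*cfg.transcript_len_range))
                full = rng.random() < 1 / 3
                ov = len(cds) if (full and len(cds) <= T) else \
                    int(rng.integers(1, min(T, len(cds)) + 1))
                free = _rand_dna(rng, max(0, T - ov))
                orf_tx_free = None
            free_span = b.emit(_revcomp(free))
            span_g = b.emit(cds)
            span_t = (free_span[0], span_g[0] + ov)
            orf_tx = ((ov + orf_tx_free[0], ov + orf_tx_free[1])
                      if orf_tx_free else None)
            loci.append(_Locus(spec["tid"], spec["tid"], span_t, "-", NOVEL,
                               make_truth(spec, gene_id, orf_tx)))
            loci.append(_Locus(gene_id, gene_id, span_g, "+", ANNOTATED))
        else:  # intergenic
            t, orf_tx = planted_body(spec)
            b.emit(_rand_dna(rng, int(rng.integers(450, 651))))
            span_t = b.emit(_revcomp(t))
            b.emit(_rand_dna(rng, int(rng.integers(450, 651))))
            loci.append(_Locus(spec["tid"], spec["tid"], span_t, "-", NOVEL,
                               make_truth(spec, None, orf_tx)))
    # paralog copies of plain genes (identical ancestral CDS, own locus)
    for src in paralog_sources:
        pid = f"{src}par"
        b.emit(_rand_dna(rng, int(rng.integers(600, 901))))
        span = b.emit(gene_cds[src])
        loci.append(_Locus(pid, pid, span, "+", ANNOTATED))
    b.emit(_rand_dna(rng, int(rng.integers(600, 901))))
    if b.pos > cfg.chrom_length:
        raise ValueError(
            f"genome too small to host requested gene counts: need at least "
            f"{b.pos} bases, chrom_length is {cfg.chrom_length}"
        )
    b.emit(_rand_dna(rng, cfg.chrom_length - b.pos))
    return b.sequence(), loci


# ---------------------------------------------------------------------------
# branch evolution

def _encode_seq(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    out = np.zeros(len(arr), dtype=np.uint8)
    for c, i in _CODE.items():
        out[arr == ord(c)] = i
    return out


def _decode_seq(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


def _free_gaps(bounds: np.ndarray, n: int, margin: int = 2) -> List[Tuple[int, int]]:
    spans = sorted((int(bounds[2 * i]), int(bounds[2 * i + 1]))
                   for i in range(len(bounds) // 2))
    merged: List[List[int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    gaps = []
    prev = 0
    for s, e in merged:
        if s - margin > prev + margin and (s - margin) - (prev + margin) >= 4:
            gaps.append((prev + margin, s - margin))
        prev = e
    if n - margin > prev + margin and (n - margin) - (prev + margin) >= 4:
        gaps.append((prev + margin, n - margin))
    return gaps


def _evolve_branch(seq: np.ndarray, bounds: np.ndarray, cfg: SimConfig,
                   rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    seq = seq.copy()
    bounds = bounds.copy()
    n = len(seq)
    if cfg.substitution_rate > 0:
        mask = rng.random(n) < cfg.substitution_rate
        idx = np.nonzero(mask)[0]
        if idx.size:
            seq[idx] = (seq[idx] + rng.integers(1, 4, idx.size).astype(np.uint8)) % 4
    if cfg.indel_rate > 0:
        gaps = _free_gaps(bounds, n)
        free_len = sum(e - s for s, e in gaps)
        n_events = rng.poisson(cfg.indel_rate * free_len)
        events = []
        if n_events and gaps:
            glens = np.array([e - s for s, e in gaps], dtype=float)
            for _ in range(n_events):
                gidx = rng.choice(len(gaps), p=glens / glens.sum())
                gs, ge = gaps[gidx]
                pos = int(rng.integers(gs + 1, ge - 1))
                length = int(min(rng.geometric(1.0 / cfg.indel_mean_len),
                                 ge - 1 - pos))
                if length < 1:
                    continue
                is_del = bool(rng.random() < 0.5)
                events.append((pos, length, is_del))
        for pos, length, is_del in sorted(events, reverse=True):
            if is_del:
                seq = np.delete(seq, np.s_[pos:pos + length])
                bounds[bounds > pos] -= np.minimum(
                    length, bounds[bounds > pos] - pos)
            else:
                ins = rng.integers(0, 4, length).astype(np.uint8)
                seq = np.insert(seq, pos, ins)
                bounds[bounds > pos] += length
    return seq, bounds


# ---------------------------------------------------------------------------
# coding-integrity repair / disruption

def _repair_cds(seq_s: str) -> str:
    s = list(seq_s)
    s[0:3] = "ATG"
    n_codons = len(seq_s) // 3
    for ci in range(1, n_codons - 1):
        codon = "".join(s[3 * ci:3 * ci + 3])
        if codon in STOPS:
            s[3 * ci + 1] = "C"
    last = "".join(s[3 * (n_codons - 1):3 * n_codons])
    if last not in STOPS:
        s[3 * (n_codons - 1):3 * n_codons] = "TAA"
    return "".join(s)


def _disrupt_orf(seq_s: str) -> str:
    """Plant stops so no frame keeps a stop-free run of > 9 codons.

    TAA codons are interleaved every 9 nt with a rotating frame offset, so
    plantings never overwrite one another and every frame gets a stop at
    least every 27 nt.
    """
    s = list(seq_s)
    j = 0
    while True:
        pos = 9 * j + (j % 3)
        if pos + 3 > len(s):
            break
        s[pos:pos + 3] = "TAA"
        j += 1
    return "".join(s)


def _apply_coding_integrity(seq: np.ndarray, loci: Sequence[_Locus],
                            spans: Dict[str, Tuple[int, int]],
                            species_rank: int, cfg: SimConfig) -> np.ndarray:
    seq_s = list(_decode_seq(seq))

    def write(start: int, end: int, content: str) -> None:
        seq_s[start:end] = content

    def read(start: int, end: int) -> str:
        return "".join(seq_s[start:end])

    for loc in loci:
        s, e = spans[loc.tid]
        if loc.truth is None:
            write(s, e, _repair_cds(read(s, e)))  # conserved gene CDS
            continue
        tr = loc.truth
        if not tr.translated:
            continue
        o1, o2 = tr.orf_start_tx, tr.orf_end_tx
        gs, ge = e - o2, e - o1   # minus-strand ORF genomic interval
        orf = _revcomp(read(gs, ge))
        if species_rank == 0:
            orf = _repair_cds(orf)
        elif species_rank in (1, 2):
            orf = _repair_cds(orf) if tr.orf_conserved_elsewhere else \
                _disrupt_orf(orf)
        else:
            continue
        write(gs, ge, _revcomp(orf))
    return _encode_seq("".join(seq_s))


# ---------------------------------------------------------------------------
# public operations

def simulate_clade(cfg: Optional[SimConfig] = None) -> SimBundle:
    """Generate genomes, catalogs, tree and truth; reproducible from rng_seed."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    tree = ladder_tree(cfg.n_ladder_species, cfg.substitution_rate)
    anc_seq, loci = _build_ancestor(cfg, rng)
    order = {loc.tid: i for i, loc in enumerate(loci)}
    bounds0 = np.array([x for loc in loci for x in loc.span], dtype=np.int64)
    state0 = (_encode_seq(anc_seq), bounds0)

    species_states: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    species_states[OUTGROUP] = _evolve_branch(*state0, cfg, rng)
    node = _evolve_branch(*state0, cfg, rng)
    for k in range(cfg.n_ladder_species, 0, -1):
        species_states[f"sp{k}"] = _evolve_branch(*node, cfg, rng)
        if k > 1:
            node = _evolve_branch(*node, cfg, rng)
        else:
            species_states[FOCAL] = _evolve_branch(*node, cfg, rng)

    genomes: Dict[str, Genome] = {}
    catalogs: Dict[str, List[TranscriptModel]] = {}
    truth = [loc.truth for loc in loci if loc.truth is not None]
    gene_ids = [loc.tid for loc in loci if loc.truth is None]
    for sp in tree.species:
        rank = tree.rank(sp)
        seq, bounds = species_states[sp]
        spans = {loc.tid: (int(bounds[2 * order[loc.tid]]),
                           int(bounds[2 * order[loc.tid] + 1]))
                 for loc in loci}
        seq = _apply_coding_integrity(seq, loci, spans, rank, cfg)
        genomes[sp] = Genome(species_id=sp,
                             chromosomes={CHROM: _decode_seq(seq)})
        cat = []
        for loc in loci:
            if loc.truth is not None and rank > loc.truth.birth_branch_rank:
                continue
            s, e = spans[loc.tid]
            cat.append(TranscriptModel(
                transcript_id=loc.tid, gene_id=loc.gene_id, chrom=CHROM,
                strand=loc.strand, exons=((s, e),), provenance=loc.provenance,
            ))
        cat.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
        catalogs[sp] = cat
    return SimBundle(cfg=cfg, tree=tree, genomes=genomes, catalogs=catalogs,
                     truth=truth, conserved_gene_ids=gene_ids)


def simulate_expression(bundle: SimBundle) -> None:
    """Fill per-species normal/stress TPM tables.

    Focal antisense (and divergent) partner fold changes are drawn from a
    bivariate normal whose Pearson correlation 2*sin(pi*rho/6) yields the
    configured Spearman rho; true log2 fold changes are recorded in truth.
    """
    cfg = bundle.cfg
    rng = np.random.default_rng(cfg.rng_seed + 1)
    truth_by_id = bundle.truth_by_id()
    for sp in bundle.tree.species:
        cat = bundle.catalogs[sp]
        ids = [t.transcript_id for t in cat]
        base = rng.normal(cfg.expr_log2_mean, cfg.expr_log2_sd, len(ids))
        fc = rng.normal(0.0, cfg.fc_sd, len(ids))
        if sp == bundle.tree.focal_species:
            idx = {tid: i for i, tid in enumerate(ids)}
            for tr in bundle.truth:
                if tr.partner_id is None or tr.transcript_id not in idx:
                    continue
                rho = (cfg.pair_fc_correlation
                       if tr.placement == "antisense_overlap"
                       else cfg.divergent_fc_correlation)
                r = 2.0 * math.sin(math.pi * rho / 6.0)
                cov = cfg.fc_sd ** 2 * np.array([[1.0, r], [r, 1.0]])
                z = rng.multivariate_normal([0.0, 0.0], cov)
                fc[idx[tr.partner_id]] = z[0]
                fc[idx[tr.transcript_id]] = z[1]
            for tr in bundle.truth:
                if tr.transcript_id in idx:
                    tr.true_log2fc = float(fc[idx[tr.transcript_id]])
        raw_n = np.power(2.0, base)
        raw_s = raw_n * np.power(2.0, fc)
        tpm_n = raw_n / raw_n.sum() * 1e6
        tpm_s = raw_s / raw_s.sum() * 1e6
        bundle.expression[(sp, "normal")] = ExpressionTable(
            species_id=sp, condition="normal", values=dict(zip(ids, tpm_n)))
        bundle.expression[(sp, "stress")] = ExpressionTable(
            species_id=sp, condition="stress", values=dict(zip(ids, tpm_s)))


def simulate_ribo_profile(orf_len_nt: int, translated: bool, cfg: SimConfig,
                          rng: np.random.Generator,
                          n_reads: int) -> np.ndarray:
    """Multinomial P-site counts over one ORF: frame 0 with probability
    p_frame (translated) or 1/3 (untranslated); codon positions uniform."""
    if orf_len_nt < 27:
        raise ValueError("ORF must be at least 9 codons")
    counts = np.zeros(orf_len_nt, dtype=np.int64)
    if n_reads <= 0:
        return counts
    n_codons = orf_len_nt // 3
    p0 = cfg.p_frame_translated if translated else cfg.p_frame_untranslated
    codons = rng.integers(0, n_codons, n_reads)
    frames = rng.choice(3, size=n_reads, p=[p0, (1 - p0) / 2, (1 - p0) / 2])
    np.add.at(counts, codons * 3 + frames, 1)
    return counts


def simulate_ribo_tracks(bundle: SimBundle) -> None:
    """Per-condition focal P-site tracks: reads over the planted (or gene)
    ORF for translated transcripts, uniform background otherwise."""
    cfg = bundle.cfg
    rng = np.random.default_rng(cfg.rng_seed + 2)
    truth_by_id = bundle.truth_by_id()
    focal = bundle.tree.focal_species
    for cond in ("normal", "stress"):
        expr = bundle.expression[(focal, cond)]
        tracks: Dict[str, PsiteTrack] = {}
        for t in bundle.focal_catalog:
            L = t.length
            counts = np.zeros(L, dtype=np.int64)
            tpm = expr.get(t.transcript_id)
            tr = truth_by_id.get(t.transcript_id)
            n_reads = int(rng.poisson(tpm * cfg.reads_per_tpm))
            if tr is None:
                counts[:L - L % 3] += simulate_ribo_profile(
                    L - L % 3, True, cfg, rng, n_reads)
            elif tr.translated:
                o1, o2 = tr.orf_start_tx, tr.orf_end_tx
                counts[o1:o2] += simulate_ribo_profile(
                    o2 - o1, True, cfg, rng, n_reads)
            else:
                n_bg = int(rng.poisson(
                    tpm * cfg.reads_per_tpm * cfg.background_read_factor))
                if n_bg:
                    np.add.at(counts, rng.integers(0, L, n_bg), 1)
            tracks[t.transcript_id] = PsiteTrack(
                transcript_id=t.transcript_id, counts=counts,
                offset_rule="simulated")
        bundle.psite_tracks[cond] = tracks


def simulate_bundle(cfg: Optional[SimConfig] = None) -> SimBundle:
    """simulate_clade + expression + Ribo-Seq tracks."""
    bundle = simulate_clade(cfg)
    simulate_expression(bundle)
    simulate_ribo_tracks(bundle)
    return bundle


def outgroup_proteins(bundle: SimBundle) -> List[Tuple[str, str, str]]:
    """Outgroup annotated proteins (the distant-proteome screen stand-in)."""
    genome = bundle.genomes[OUTGROUP]
    out = []
    for t in bundle.catalogs[OUTGROUP]:
        if t.provenance != ANNOTATED:
            continue
        cds = t.sequence(genome)
        prot = str(Seq(cds[:len(cds) - len(cds) % 3]).translate()).rstrip("*")
        out.append((OUTGROUP, t.transcript_id, prot.replace("*", "X")))
    return out


def write_bundle(bundle: SimBundle, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sp, genome in bundle.genomes.items():
        genome.to_fasta(outdir / f"{sp}.fa")
        write_transcripts_gtf(bundle.catalogs[sp], outdir / f"{sp}.gtf")
    for (sp, cond), table in bundle.expression.items():
        write_expression_tsv(table, outdir / f"{sp}.{cond}.tpm.tsv")
    (outdir / "tree.nwk").write_text(bundle.tree.newick + "\n")
    rows = []
    for tr in bundle.truth:
        rows.append({
            "transcript_id": tr.transcript_id,
            "birth_branch_rank": tr.birth_branch_rank,
            "true_class": tr.true_class,
            "placement": tr.placement,
            "partner_id": tr.partner_id if tr.partner_id is not None else "",
            "translated": tr.translated,
            "orf_start_tx": tr.orf_start_tx if tr.orf_start_tx is not None else -1,
            "orf_end_tx": tr.orf_end_tx if tr.orf_end_tx is not None else -1,
            "orf_conserved_elsewhere": tr.orf_conserved_elsewhere,
            "true_log2fc": tr.true_log2fc,
        })
    pd.DataFrame(rows).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    for cond, tracks in bundle.psite_tracks.items():
        with open(outdir / f"psites.{cond}.tsv", "w") as fh:
            fh.write("transcript_id\tposition\tcount\n")
            for tid in sorted(tracks):
                counts = tracks[tid].counts
                for pos in np.nonzero(counts)[0]:
                    fh.write(f"{tid}\t{int(pos)}\t{int(counts[pos])}\n")
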