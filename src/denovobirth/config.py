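"""Configuration dataclasses for every pipeline stage.

All thresholds default to the values of the study design this package
implements: transcripts count as expressed above 15 TPM, homology hits are
kept below e-value 0.05 (nucleotide hits additionally need alignments longer
than 100 nt), consecutive MUMs within 100 bases are chained into one synteny
block, and translated ORFs require score >= 0.7, >= 10 reads and >= 9 aa.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional

import yaml


@dataclass
class HomologyConfig:
    """Filters and seeding parameters for the built-in homology search."""

    evalue_max: float = 0.05
    # "over 100 nt": nucleotide alignments must be strictly longer than 100 nt
    min_nuc_aln_len: int = 101
    seed_k_nuc: int = 11
    seed_k_aa: int = 4
    min_identity: float = 0.7
    evalue_report_max: float = 10.0

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")
        if self.min_nuc_aln_len < 1:
            raise ValueError("min_nuc_aln_len must be >= 1")


@dataclass
class SyntenyConfig:
    max_gap: int = 100          # inclusive: gap <= max_gap joins two MUMs
    # smallest MUM kept: suppresses random 4^-k collisions at the ~100-kb
    # scale of the simulated genomes (use ~20 for megabase genomes)
    min_mum_length: int = 14
    # a MUM whose orientation+diagonal disagree with both flanking MUMs by
    # more than this is chained as its own singleton block rather than being
    # allowed to break a collinear run (0 disables)
    outlier_diag_tol: int = 500

    def __post_init__(self) -> None:
        if self.max_gap <= 0 or self.min_mum_length <= 0:
            raise ValueError("max_gap and min_mum_length must be > 0")


@dataclass
class TranslationConfig:
    score_threshold: float = 0.7
    min_reads: int = 10
    min_len_aa: int = 9
    # P-site = 5' position + offset(read length); standard 28-32 nt RPF offsets
    psite_offsets: Dict[int, int] = field(
        default_factory=lambda: {28: 12, 29: 12, 30: 12, 31: 13, 32: 13}
    )
    max_uniformity_bins: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.score_threshold <= 1):
            raise ValueError("score_threshold must be in (0, 1]")
        for length, off in self.psite_offsets.items():
            if off >= length:
                raise ValueError("P-site offset must be smaller than read length")


@dataclass
class AgeConfig:
    """Branch-rank class bins: 0 = focal-only branch, increasing with distance.

    Defaults mirror a 6-rank ladder: ranks 0-2 are young enough to call
    de novo, 3-4 genus-specific, and 5+ (incl. any outgroup hit) conserved.
    """

    de_novo_max_rank: int = 2
    genus_specific_max_rank: int = 4
    max_align_len: int = 20000
    min_orf_overlap_positions: int = 1
    # candidate ORF must cover this fraction of the mapped focal ORF span to
    # count as "same genomic location" (0 reduces to >=1 aligned position)
    min_orf_overlap_frac: float = 0.5
    orf_conserved_min_frac: float = 0.5   # "at least half the length"
    syntenic_flank: int = 150

    def __post_init__(self) -> None:
        if self.de_novo_max_rank >= self.genus_specific_max_rank:
            raise ValueError("de_novo_max_rank must be < genus_specific_max_rank")


@dataclass
class OrfConfig:
    # near-cognate starts: the nine single-substitution neighbours of ATG
    near_cognate_starts: tuple = (
        "GTG", "TTG", "CTG", "ACG", "AGG", "AAG", "ATA", "ATT", "ATC"
    )
    allow_near_cognate: bool = True
    min_codons: int = 4          # ">3 codons", stop codon included
    hexamer_pseudocount: float = 1.0


@dataclass
class PairConfig:
    max_divergent_gap: int = 400
    min_divergent_gap: int = 1
    log2fc_pseudocount: float = 1.0
    n_permutations: int = 1000
    use_exons: bool = False      # default: genomic spans, per the coordinate comparison


@dataclass
class SimConfig:
    """Stated world of the synthetic clade: a 6-species ladder with one
    outgroup, small single-chromosome genomes, conserved genes on the plus
    strand and planted transcripts on the minus strand."""

    n_ladder_species: int = 4           # plus focal and outgroup = 6 species
    chrom_length: int = 95000
    n_conserved_genes: int = 40
    n_paralog_pairs: int = 2
    # planted (class, placement) counts; rank 0 births are focal-specific
    n_planted: Dict[str, int] = field(default_factory=lambda: {
        "rank0_antisense": 4, "rank0_divergent": 2, "rank0_intergenic": 2,
        "rank1_antisense": 3, "rank1_divergent": 2, "rank1_intergenic": 1,
        "rank2_antisense": 3, "rank2_divergent": 1, "rank2_intergenic": 2,
        "rank3_antisense": 2, "rank3_divergent": 2, "rank3_intergenic": 1,
        "rank4_antisense": 2, "rank4_divergent": 1, "rank4_intergenic": 2,
    })
    substitution_rate: float = 0.05     # per site per branch
    indel_rate: float = 5e-4            # per site per branch, spacers only
    indel_mean_len: float = 3.0
    gene_len_codons_range: tuple = (120, 180)
    transcript_len_range: tuple = (220, 420)
    orf_len_codons_range: tuple = (40, 70)
    translated_fraction: float = 0.6
    orf_conserved_fraction: float = 0.2  # shared births whose ORF stays intact elsewhere
    orf_first_fraction: float = 0.26     # focal-specific births with a pre-existing sister ORF
    expr_log2_mean: float = 7.0
    expr_log2_sd: float = 1.5
    fc_sd: float = 1.0
    pair_fc_correlation: float = 0.7
    divergent_fc_correlation: float = 0.25
    p_frame_translated: float = 0.85
    p_frame_untranslated: float = 1.0 / 3.0
    reads_per_tpm: float = 0.02
    background_read_factor: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_frame_translated, self.p_frame_untranslated,
                  self.translated_fraction, self.orf_conserved_fraction,
                  self.orf_first_fraction):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.substitution_rate < 0 or self.indel_rate < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class PipelineConfig:
    tpm_expressed_threshold: float = 15.0
    tpm_detection_floor: float = 2.0
    rng_seed: int = 0
    homology: HomologyConfig = field(default_factory=HomologyConfig)
    synteny: SyntenyConfig = field(default_factory=SyntenyConfig)
    translation: TranslationConfig = field(default_factory=TranslationConfig)
    age: AgeConfig = field(default_factory=AgeConfig)
    orf: OrfConfig = field(default_factory=OrfConfig)
    pairs: PairConfig = field(default_factory=PairConfig)
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if self.tpm_expressed_threshold <= 0 or self.tpm_detection_floor <= 0:
            raise ValueError("TPM thresholds must be > 0")
        if self.tpm_detection_floor >= self.tpm_expressed_threshold:
            raise ValueError("detection floor must be below the expressed threshold")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["translation"]["psite_offsets"] = {
            str(k): v for k, v in d["translation"]["psite_offsets"].items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sub = {}
        for key, klass in [("homology", HomologyConfig), ("synteny", SyntenyConfig),
                           ("translation", TranslationConfig), ("age", AgeConfig),
                           ("orf", OrfConfig), ("pairs", PairConfig),
                           ("sim", SimConfig)]:
            if key in d:
                kw = dict(d.pop(key))
                if key == "translation" and "psite_offsets" in kw:
                    kw["psite_offsets"] = {int(k): v for k, v in kw["psite_offsets"].items()}
                for tup in ("near_cognate_starts", "gene_len_codons_range",
                            "transcript_len_range", "orf_len_codons_range"):
                    if tup in kw and isinstance(kw[tup], list):
                        kw[tup] = tuple(kw[tup])
                sub[key] = klass(**kw)
        return cls(**d, **sub)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
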