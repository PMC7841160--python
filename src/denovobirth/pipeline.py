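"""End-to-end orchestration: evidence gathering, age assignment, translation
calling, pair statistics and the summary report.

The pipeline consumes a bundle (simulated or loaded from files) holding the
species tree, genomes, per-species transcript catalogs, focal expression
tables and focal P-site tracks. Evidence flows: merged focal catalog ->
expression filter (> 15 TPM in >= 1 condition) -> homology + synteny +
paralog propagation + outgroup screen -> branch-of-origin classes -> ORF
enumeration/properties -> translation calls -> locus-pair statistics and
origination-route fractions -> report (TSV intermediates + report.json; the
report is a pure function of the intermediates, so regeneration from saved
tables is byte-identical).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import age as age_mod
from . import pairs as pairs_mod
from .catalog import (ANNOTATED, NOVEL, ExpressionTable, TranscriptModel,
                      filter_expressed, merge_catalogs, write_expression_tsv)
from .config import PipelineConfig
from .homology import (PROGRAM_PROT_OUTGROUP, TranscriptDatabase, filter_hits,
                       find_paralogs, search_nucleotide, search_translated)
from .orfkit import (OrfRecord, coding_score, enumerate_orfs, isoelectric_point,
                     longest_translated_orf, train_hexamer_table)
from .ribo import TranslationCall, call_transcript_translation, score_orf
from .synteny import (REVERSE, cluster_mums, find_genome_mums, project_interval,
                      revcomp, syntenic_transcript_overlaps)

log = logging.getLogger(__name__)


def _mode_catalog(catalog: Sequence[TranscriptModel], mode: str,
                  is_focal: bool) -> List[TranscriptModel]:
    if mode == age_mod.MODE_FULL:
        return list(catalog)
    if mode == age_mod.MODE_FOCAL_TX_ONLY:
        return list(catalog) if is_focal else \
            [t for t in catalog if t.provenance == ANNOTATED]
    if mode == age_mod.MODE_ANNOTATIONS_ONLY:
        return [t for t in catalog if t.provenance == ANNOTATED]
    raise ValueError(f"unknown mode {mode!r}")


def _synteny_blocks(bundle, config: PipelineConfig):
    """Per-species synteny blocks between the focal genome and each other
    species, cached on the bundle."""
    cache = getattr(bundle, "_synteny_cache", None)
    if cache is not None:
        return cache
    focal = bundle.tree.focal_species
    blocks = {}
    for sp in bundle.tree.species:
        if sp == focal:
            continue
        mums = find_genome_mums(bundle.genomes[focal], bundle.genomes[sp],
                                min_len=config.synteny.min_mum_length)
        by_pair: Dict[Tuple[str, str], list] = {}
        for m in mums:
            by_pair.setdefault((m.chrom_a, m.chrom_b), []).append(m)
        sp_blocks = []
        for pair_mums in by_pair.values():
            pair_mums.sort(key=lambda m: (m.pos_a, m.pos_b))
            sp_blocks.extend(cluster_mums(pair_mums, config.synteny))
        blocks[sp] = sp_blocks
    bundle._synteny_cache = blocks
    return blocks


def estimate_ages(bundle, config: PipelineConfig,
                  mode: str = age_mod.MODE_FULL,
                  focal_transcripts: Optional[Sequence[TranscriptModel]] = None,
                  ) -> Dict[str, age_mod.AgeAssignment]:
    """Branch-of-origin assignment for focal transcripts under a database mode."""
    focal = bundle.tree.focal_species
    focal_genome = bundle.genomes[focal]
    if focal_transcripts is None:
        focal_transcripts = _mode_catalog(bundle.catalogs[focal], mode, True)
    else:
        focal_transcripts = _mode_catalog(focal_transcripts, mode, True)
    seqs = {t.transcript_id: t.sequence(focal_genome) for t in focal_transcripts}

    db_entries = []
    sp_catalogs = {}
    for sp in bundle.tree.species:
        if sp == focal:
            continue
        cat = _mode_catalog(bundle.catalogs[sp], mode, False)
        sp_catalogs[sp] = cat
        genome = bundle.genomes[sp]
        for t in cat:
            db_entries.append((sp, t.transcript_id, t.sequence(genome)))
    db = TranscriptDatabase(db_entries, config.homology)

    evidence = {t.transcript_id: age_mod.EvidenceSet(transcript_id=t.transcript_id)
                for t in focal_transcripts}
    rank_of = bundle.tree.branch_rank
    for tid, seq in seqs.items():
        hits = search_nucleotide(tid, seq, db, config.homology)
        hits += search_translated(tid, seq, db, config.homology)
        for h in filter_hits(hits, config.homology):
            evidence[tid].blast_species_ranks.add(rank_of[h.subject_species])

    blocks = _synteny_blocks(bundle, config)
    for sp, sp_blocks in blocks.items():
        pairs = syntenic_transcript_overlaps(
            focal_transcripts, sp_catalogs[sp], sp_blocks)
        for id_a, _id_b in pairs:
            evidence[id_a].synteny_species_ranks.add(rank_of[sp])

    focal_db = TranscriptDatabase(
        [(focal, tid, s) for tid, s in seqs.items()], config.homology)
    intra_hits = []
    for tid, seq in seqs.items():
        intra_hits.extend(h for h in filter_hits(
            search_nucleotide(tid, seq, focal_db, config.homology),
            config.homology) if h.subject_id != tid)
    groups = find_paralogs(intra_hits, all_ids=list(seqs))
    evidence_list = list(evidence.values())
    group_ranks = age_mod.propagate_paralog_ranks(evidence_list, groups)

    outgroup_hits: Set[str] = set()
    prot_entries = getattr(bundle, "outgroup_protein_entries", None)
    if prot_entries is None:
        from .simulate import outgroup_proteins
        try:
            prot_entries = outgroup_proteins(bundle)
        except Exception:
            prot_entries = []
    if prot_entries:
        prot_db = TranscriptDatabase(prot_entries, config.homology, protein=True)
        for tid, seq in seqs.items():
            og = search_translated(tid, seq, prot_db, config.homology,
                                   program=PROGRAM_PROT_OUTGROUP)
            if filter_hits(og, config.homology):
                outgroup_hits.add(tid)
    age_mod.apply_outgroup_screen(evidence_list, outgroup_hits)

    bins = age_mod.ClassBins(config.age)
    return {
        ev.transcript_id: age_mod.assign_branch(ev, group_ranks, bins)
        for ev in evidence_list
    }


def _oriented_region(genome, chrom: str, lo: int, hi: int, flip: bool) -> str:
    seq = genome.chromosomes[chrom][max(0, lo):hi]
    return revcomp(seq) if flip else seq


def _project_window(blocks, win: Tuple[int, int], chrom: str):
    """Project a window, bridging across a block split when necessary.

    A locus whose interior lacks MUMs (e.g. a diverged ORF) can split the
    surrounding synteny block in two; the two window boundaries are then
    anchored in their own blocks and combined, provided the orientations
    agree and the projected region stays commensurate with the window.
    """
    proj = project_interval(blocks, win, chrom_a=chrom)
    if proj is not None:
        return proj
    p1 = project_interval(blocks, (win[0], win[0] + 1), chrom_a=chrom)
    p2 = project_interval(blocks, (win[1] - 1, win[1]), chrom_a=chrom)
    if p1 is None or p2 is None or p1[1] != p2[1]:
        return None
    lo = min(p1[0][0], p2[0][0])
    hi = max(p1[0][1], p2[0][1])
    if hi - lo > (win[1] - win[0]) + 2000:
        return None
    return (lo, hi), p1[1]


def classify_route_conservation(
    bundle, config: PipelineConfig,
    transcript: TranscriptModel,
    orf: OrfRecord,
    sister_species: Sequence[str],
) -> Optional[bool]:
    """Whether the focal ORF is conserved (same location, >= half length) in
    any sister species' syntenic region; None when no region resolves."""
    focal = bundle.tree.focal_species
    flank = config.age.syntenic_flank
    blocks = _synteny_blocks(bundle, config)
    s, e = transcript.span
    # genomic ORF interval (minus-strand transcript coordinates run rightward
    # from the span end)
    if transcript.strand == "-":
        orf_g = (e - orf.end_tx, e - orf.start_tx)
    else:
        orf_g = (s + orf.start_tx, s + orf.end_tx)
    # progressively smaller windows until one fits inside a synteny block
    windows = [(max(0, s - flank), e + flank), (s, e),
               (max(0, orf_g[0] - 30), orf_g[1] + 30), orf_g]
    any_region = False
    for sp in sister_species:
        proj = None
        for win in windows:
            proj = _project_window(blocks[sp], win, transcript.chrom)
            if proj is not None:
                break
        if proj is None:
            continue
        if transcript.strand == "-":
            off = win[1] - orf_g[1]
        else:
            off = orf_g[0] - win[0]
        orf_region = (off, off + (orf.end_tx - orf.start_tx))
        focal_region = _oriented_region(bundle.genomes[focal], transcript.chrom,
                                        win[0], win[1], transcript.strand == "-")
        (lo, hi), orientation = proj
        if hi - lo > config.age.max_align_len:
            continue
        flip = (transcript.strand == "-") != (orientation == REVERSE)
        chrom_b = next(b.chrom_b for b in blocks[sp]
                       if b.chrom_a == transcript.chrom)
        other = _oriented_region(bundle.genomes[sp], chrom_b, lo, hi, flip)
        if not other:
            continue
        any_region = True
        aln = age_mod.align_syntenic_region(focal_region, other, config.age)
        if age_mod.classify_orf_conservation(orf_region, aln, other, config.age):
            return True
    return False if any_region else None


@dataclass
class PipelineResult:
    config: PipelineConfig
    expressed: List[TranscriptModel]
    patterns: Dict[str, str]
    ages: Dict[str, age_mod.AgeAssignment]
    orfs: Dict[str, List[OrfRecord]]
    orf_props: pd.DataFrame
    calls: Dict[str, List[TranslationCall]]
    translated: Dict[str, List[OrfRecord]]
    pair_classes: list
    routes: pd.DataFrame
    tables: Dict[str, pd.DataFrame] = field(default_factory=dict)
    report: dict = field(default_factory=dict)


def run_pipeline(bundle, config: Optional[PipelineConfig] = None) -> PipelineResult:
    config = config or PipelineConfig()
    focal = bundle.tree.focal_species
    genome = bundle.genomes[focal]
    catalog = bundle.catalogs[focal]
    merged = merge_catalogs(
        [t for t in catalog if t.provenance == ANNOTATED],
        [t for t in catalog if t.provenance == NOVEL])
    tables = [bundle.expression[(focal, "normal")],
              bundle.expression[(focal, "stress")]]
    expressed, patterns = filter_expressed(
        merged, tables, threshold=config.tpm_expressed_threshold)

    ages = estimate_ages(bundle, config, focal_transcripts=expressed)

    # ORFs + properties
    coding_train = [t.sequence(genome) for t in expressed
                    if t.provenance == ANNOTATED]
    noncoding_train = _spacer_sequences(genome, catalog)
    hex_table = train_hexamer_table(coding_train, noncoding_train,
                                    pseudocount=config.orf.hexamer_pseudocount)
    orfs: Dict[str, List[OrfRecord]] = {}
    prop_rows = []
    seqs = {}
    for t in expressed:
        seq = t.sequence(genome)
        seqs[t.transcript_id] = seq
        t_orfs = enumerate_orfs(seq, t.transcript_id, config.orf)
        orfs[t.transcript_id] = t_orfs
        for o in t_orfs:
            prop_rows.append({
                "transcript_id": t.transcript_id, "orf_id": o.orf_id,
                "frame": o.frame, "start_tx": o.start_tx, "end_tx": o.end_tx,
                "start_class": o.start_class, "protein_len": len(o.protein),
                "coding_score": coding_score(seq[o.start_tx:o.end_tx - 3], hex_table),
                "isoelectric_point": isoelectric_point(o.protein),
            })
    orf_props = pd.DataFrame(prop_rows)

    # translation calls per condition
    calls: Dict[str, List[TranslationCall]] = {"normal": [], "stress": []}
    for cond in ("normal", "stress"):
        tracks = bundle.psite_tracks.get(cond, {})
        for t in expressed:
            track = tracks.get(t.transcript_id)
            if track is None:
                continue
            for o in orfs[t.transcript_id]:
                calls[cond].append(score_orf(o, track, config.translation,
                                             condition=cond))
    translated: Dict[str, List[OrfRecord]] = {}
    for t in expressed:
        is_tr, tr_orfs = call_transcript_translation(
            orfs[t.transcript_id],
            {c: [x for x in calls[c]
                 if x.orf_id.startswith(t.transcript_id + ":")]
             for c in calls})
        if is_tr:
            translated[t.transcript_id] = tr_orfs

    pair_classes = pairs_mod.classify_pairs(expressed, config.pairs)

    # origination routes for de novo transcripts with a translated ORF
    sisters = [sp for sp in bundle.tree.species
               if 1 <= bundle.tree.branch_rank[sp] <= config.age.de_novo_max_rank]
    route_rows = []
    for tid, assignment in ages.items():
        if assignment.conservation_class != age_mod.DE_NOVO:
            continue
        if tid not in translated:
            continue
        called_ids = [o.orf_id for o in translated[tid]]
        orf = longest_translated_orf(orfs[tid], called_ids)
        if orf is None:
            continue
        t = next(x for x in expressed if x.transcript_id == tid)
        conserved = classify_route_conservation(bundle, config, t, orf, sisters)
        group = "focal_specific" if assignment.deepest_rank == 0 else "shared"
        route_rows.append({
            "transcript_id": tid, "group": group,
            "orf_conserved": bool(conserved) if conserved is not None else False,
            "region_resolved": conserved is not None,
        })
    routes = pd.DataFrame(route_rows,
                          columns=["transcript_id", "group", "orf_conserved",
                                   "region_resolved"])

    result = PipelineResult(
        config=config, expressed=expressed, patterns=patterns, ages=ages,
        orfs=orfs, orf_props=orf_props, calls=calls, translated=translated,
        pair_classes=pair_classes, routes=routes,
    )
    result.tables = _intermediate_tables(result, bundle)
    result.report = build_report(result.tables, config)
    return result


def _spacer_sequences(genome, catalog: Sequence[TranscriptModel],
                      min_len: int = 50) -> List[str]:
    out = []
    for chrom, seq in genome.chromosomes.items():
        spans = sorted(t.span for t in catalog if t.chrom == chrom)
        prev = 0
        for s, e in spans:
            if s - prev >= min_len:
                out.append(seq[prev:s])
            prev = max(prev, e)
        if len(seq) - prev >= min_len:
            out.append(seq[prev:])
    return out


def _intermediate_tables(result: PipelineResult, bundle) -> Dict[str, pd.DataFrame]:
    ages_df = pd.DataFrame([{
        "transcript_id": a.transcript_id, "deepest_rank": a.deepest_rank,
        "conservation_class": a.conservation_class,
        "used_blast": a.used_blast, "used_synteny": a.used_synteny,
        "used_paralogs": a.used_paralogs, "outgroup_hit": a.outgroup_hit,
    } for a in result.ages.values()]).sort_values("transcript_id")
    meta_df = pd.DataFrame([{
        "transcript_id": t.transcript_id, "provenance": t.provenance,
        "pattern": result.patterns[t.transcript_id],
        "translated": t.transcript_id in result.translated,
    } for t in result.expressed]).sort_values("transcript_id")
    calls_rows = []
    for cond, cond_calls in result.calls.items():
        for c in cond_calls:
            calls_rows.append({
                "orf_id": c.orf_id, "condition": cond, "n_reads": c.n_reads,
                "periodicity": c.periodicity, "uniformity": c.uniformity,
                "score": c.score, "called": c.called,
            })
    calls_df = pd.DataFrame(calls_rows).sort_values(["orf_id", "condition"])
    pairs_df = pd.DataFrame([{
        "id_a": p.id_a, "id_b": p.id_b, "relation": p.relation,
        "overlap_len": p.overlap_len, "gap": p.gap,
    } for p in result.pair_classes])
    if pairs_df.empty:
        pairs_df = pd.DataFrame(columns=["id_a", "id_b", "relation",
                                         "overlap_len", "gap"])
    focal = bundle.tree.focal_species
    expr_n = bundle.expression[(focal, "normal")]
    expr_s = bundle.expression[(focal, "stress")]
    expr_df = pd.DataFrame([{
        "transcript_id": t.transcript_id,
        "tpm_normal": expr_n.get(t.transcript_id),
        "tpm_stress": expr_s.get(t.transcript_id),
    } for t in result.expressed]).sort_values("transcript_id")
    return {
        "ages": ages_df.reset_index(drop=True),
        "meta": meta_df.reset_index(drop=True),
        "orfs": result.orf_props,
        "calls": calls_df.reset_index(drop=True),
        "pairs": pairs_df,
        "expression": expr_df.reset_index(drop=True),
        "routes": result.routes,
    }


CLASSES = (age_mod.DE_NOVO, age_mod.GENUS_SPECIFIC, age_mod.CONSERVED)


def build_report(tables: Mapping[str, pd.DataFrame],
                 config: PipelineConfig) -> dict:
    """Summary report computed purely from the intermediate tables (so the
    report regenerates byte-identically from saved TSVs)."""
    for name in ("ages", "meta", "pairs", "expression", "routes"):
        if name not in tables:
            raise ValueError(f"missing pipeline stage output: {name}")
    ages = tables["ages"]
    meta = tables["meta"]
    pairs_df = tables["pairs"]
    expr = tables["expression"]
    routes = tables["routes"]
    merged = ages.merge(meta, on="transcript_id")

    report: dict = {"seed": config.rng_seed, "config": config.to_dict()}
    by_class = {}
    anti_ids = set(pairs_df.loc[pairs_df.relation == "antisense_overlap", "id_a"]) | \
        set(pairs_df.loc[pairs_df.relation == "antisense_overlap", "id_b"])
    div_ids = set(pairs_df.loc[pairs_df.relation == "divergent", "id_a"]) | \
        set(pairs_df.loc[pairs_df.relation == "divergent", "id_b"])
    for cls in CLASSES:
        sub = merged[merged.conservation_class == cls]
        n = len(sub)
        ids = set(sub.transcript_id)
        by_class[cls] = {
            "n": n,
            "n_annotated": int((sub.provenance == "annotated").sum()),
            "n_novel": int((sub.provenance == "novel").sum()),
            "patterns": {p: int((sub.pattern == p).sum())
                         for p in ("normal_only", "stress_only", "both")},
            "fraction_antisense": (len(ids & anti_ids) / n) if n else float("nan"),
            "fraction_divergent": (len(ids & div_ids) / n) if n else float("nan"),
            "fraction_translated": (float(sub.translated.mean()) if n
                                    else float("nan")),
        }
    report["classes"] = by_class

    fcs = pairs_mod.log2_fold_changes(
        dict(zip(expr.transcript_id, expr.tpm_normal)),
        dict(zip(expr.transcript_id, expr.tpm_stress)),
        pseudocount=config.pairs.log2fc_pseudocount)
    anti_pairs = [(r.id_a, r.id_b) for r in pairs_df.itertuples()
                  if r.relation == "antisense_overlap"]
    div_pairs = [(r.id_a, r.id_b) for r in pairs_df.itertuples()
                 if r.relation == "divergent"]
    report["fc_correlation"] = {
        "antisense": pairs_mod.paired_fc_correlation(anti_pairs, fcs),
        "divergent": pairs_mod.paired_fc_correlation(div_pairs, fcs),
    }
    if len(anti_pairs) >= 10:
        null = pairs_mod.random_pairing_null(
            anti_pairs, fcs, n_perm=config.pairs.n_permutations,
            seed=config.rng_seed)
        report["fc_correlation"]["antisense_null"] = {
            "mean": null["mean"], "ci_lo": null["ci_lo"], "ci_hi": null["ci_hi"],
        }

    def _enrich(label, ids_a, ids_b, prop_ids):
        table = [[len(ids_a & prop_ids), len(ids_a - prop_ids)],
                 [len(ids_b & prop_ids), len(ids_b - prop_ids)]]
        r = pairs_mod.fisher_exact_2x2(table, label=label)
        return {"table": r.table, "odds_ratio": r.odds_ratio,
                "p_value": r.p_value}

    dn_ids = set(merged.loc[merged.conservation_class == "de_novo",
                            "transcript_id"])
    young_ids = dn_ids | set(merged.loc[
        merged.conservation_class == "genus_specific", "transcript_id"])
    cons_ids = set(merged.loc[merged.conservation_class == "conserved",
                              "transcript_id"])
    stress_only_ids = set(merged.loc[merged.pattern == "stress_only",
                                     "transcript_id"])
    report["enrichment"] = {
        "de_novo_antisense_vs_conserved": _enrich(
            "de novo x antisense", dn_ids, cons_ids, anti_ids),
        "young_stress_only_vs_conserved": _enrich(
            "young x stress-only", young_ids, cons_ids, stress_only_ids),
    }

    # only loci whose sister syntenic region resolved can be classified
    shared = routes[(routes.group == "shared") & routes.region_resolved]
    focal_sp = routes[(routes.group == "focal_specific") & routes.region_resolved]
    rf = age_mod.origination_route_fractions(
        dict(zip(shared.transcript_id, shared.orf_conserved)),
        dict(zip(focal_sp.transcript_id, focal_sp.orf_conserved)))
    report["routes"] = rf
    return report


def write_outputs(result: PipelineResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in result.tables.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    from .orfkit import write_protein_fasta
    translated_orfs = [o for orfs in result.translated.values() for o in orfs]
    write_protein_fasta(translated_orfs, outdir / "proteins.fa")
    (outdir / "report.json").write_text(
        json.dumps(result.report, sort_keys=True, indent=2) + "\n")


def read_tables(outdir) -> Dict[str, pd.DataFrame]:
    outdir = Path(outdir)
    tables = {}
    for name in ("ages", "meta", "orfs", "calls", "pairs", "expression", "routes"):
        path = outdir / f"{name}.tsv"
        if not path.exists():
            raise ValueError(f"missing pipeline stage output: {name}")
        tables[name] = pd.read_csv(path, sep="\t")
    return tables
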