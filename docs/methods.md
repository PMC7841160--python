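# Methods

This note documents the models and procedures implemented in `denovobirth`,
the parameters that matter, the simulator's stated world, and the numerical
choices made where the design was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinates and catalogs

All internal coordinates are 0-based half-open; GTF input/output converts
from/to 1-based closed at the boundary. A transcript is a sorted,
non-overlapping exon set on one chromosome and strand, with
annotated/novel provenance. Catalog merging drops a novel transcript only
on ≥ 1 bp of *same-strand exonic* overlap with an annotated transcript:
antisense overlap never triggers removal, because antisense novel
transcripts are the central object of the downstream analysis.

Expression uses TPM (`TPM_i = (c_i/L_i)/Σ_j(c_j/L_j) × 1e6`). A transcript
is *expressed* at TPM strictly above 15 in at least one condition
(normal/stress); the TPM > 2 detection floor feeds only the detection
report, never pipeline membership. Missing expression entries are TPM 0
with a warning, since novel transcripts absent from one condition's table
are expected.

## Homology search (BLAST surrogate)

The built-in search is a transparent, ungapped seed-and-extend surrogate
for BLASTN/TBLASTX:

* exact k-mer seeds (11 nt; 4 aa) on the transcript strand only — the
  reverse complement is never seeded, and translated search uses only the
  three forward frames, mirroring the strand-specific protocol;
* BLAST-style X-drop extension anchored on the seed (X = 20 for DNA with
  match +1 / mismatch −2; X = 15 for BLOSUM62). The maximal segment always
  contains its seed; an earlier whole-diagonal maximum-subarray variant
  produced seedless chance segments and was replaced;
* Karlin–Altschul e-values `E = K·m·n·e^{−λS}` with published ungapped
  parameters (DNA +1/−2: λ = 1.33, K = 0.621; BLOSUM62: λ = 0.3176,
  K = 0.134). Because only seeded diagonals are extended, the realized
  chance-hit rate at a given E is below the nominal expectation — the
  surrogate is conservative;
* filters: E < 0.05 for every program (strict), plus alignment length
  > 100 nt for the nucleotide program only; hits with subject coordinates
  on the opposite strand are excluded.

Nucleotide identity within a reported segment must be ≥ 70%. Intra-species
filtered hits define paralog groups as connected components; a transcript's
age evidence is the union over its group (paralog propagation). The
distant-proteome screen reuses the translated search against a protein
database; any filtered hit forces the conserved class. Like the real
screen, it has a small chance-hit rate (~E per search by construction), so
an occasional genuine young transcript is conservatively discarded; at the
simulator's default divergence this costs ≲ 1 of 30 planted transcripts.

Imported 12-column tabular hit files bypass the surrogate; `sstart > send`
marks an opposite-strand hit, which the filters then remove.

## MUM synteny

A MUM is an exact match occurring exactly once in each genome (respecting
orientation) and non-extendable at either end. Implementation: generalized
suffix array (prefix doubling) + Kasai LCP over the concatenation; a
candidate is a pair of adjacent suffixes from different genomes whose LCP
exceeds both neighbouring LCPs (two occurrences total) and whose preceding
characters differ (left-maximality). Every `N` is replaced by a private
sentinel, so N never matches; multi-chromosome genomes are concatenated
with sentinels, making uniqueness genome-wide while blocks stay per
chromosome pair.

Chaining is greedy left-to-right: a MUM joins the open block iff it has the
block's orientation, is B-monotone for that orientation, and the
end-to-start gap is ≤ 100 bases (inclusive; 101 splits) in *both* genomes.
Two refinements proved necessary in practice:

* **minimum MUM length 14** (configurable). The threshold exists to
  suppress random 4^−k collisions; at the simulator's ~100 kb genome scale
  k = 14 keeps expected chance MUMs below a handful, whereas the ~20
  appropriate for megabase genomes starves block chaining of anchors at
  realistic divergence;
* **diagonal-outlier isolation**: a MUM whose orientation or diagonal
  (pos_b − pos_a) disagrees with both flanking MUMs by more than 500 bp is
  chained as its own singleton block instead of being allowed to break a
  collinear run. Without this, each residual chance MUM shatters the run it
  lands in. Every MUM still belongs to exactly one block.

Projection maps an A-interval through the block containing it: boundaries
inside a MUM use the exact per-base mapping (so identical genomes project
identically); otherwise the last MUM ending at or before the start / first
MUM starting at or after the end anchor the interval, falling back to the
block edge. Among overlapping candidate blocks the one whose MUMs cover
more of the interval wins. Transcripts in the second genome overlapping the
projection by ≥ 1 bp on the *same effective strand* (block-orientation
aware) are potential homologues; a strand-blind mode exists
(`require_same_strand=False`) but is not the default, because a
strand-blind rule would mark every antisense de novo transcript as
conserved via its own antisense partner.

## Age classes

Evidence ranks are integers along the focal lineage (0 = focal-only branch,
increasing with divergence; the simulator's ladder gives sp1..sp4 ranks 1–4
and the outgroup 5). `deepest_rank` is the maximum over own homology ranks,
own synteny ranks, and all paralog-group members' ranks; 0 when everything
is empty. Class bins (configurable): rank ≤ 2 de novo, 3–4 genus-specific,
≥ 5 conserved; an outgroup-proteome hit forces conserved regardless of
rank. Assignment is monotone: adding evidence can only deepen the rank.

Database modes for the strategy comparison: `full` (transcriptomes +
annotations everywhere), `focal_transcriptome_only` (other species
contribute annotations only — missing homologues inflate apparent youth),
`annotations_only` (novel focal transcripts vanish from the output).

## Translation calling

P-sites are 5′ position + a read-length offset (28–30 nt → 12; 31–32 nt
→ 13; a pass-through mode accepts precomputed P-sites). Per ORF and
condition: frame counts by (position − start) mod 3; periodicity = f0/total;
uniformity = Shannon entropy of per-codon counts over min(10, codons) equal
bins divided by log(bins), 0 when no reads; score = periodicity ×
uniformity. Called iff score ≥ 0.7 ∧ reads ≥ 10 ∧ protein ≥ 9 aa in at
least one condition, independent of which condition passed the expression
filter. The published classifier this replaces is an opaque model over the
same inputs; the transparent product score is validated by its operating
point on simulated profiles (sensitivity/FPR at ≥ 50 reads) rather than by
numeric identity. Near the 10-read floor sensitivity is soft — the score is
noisy at low depth — which is exactly what `sensitivity_by_expression`
characterizes.

## ORF enumeration and properties

Per frame, each stop codon yields at most one ORF, starting at the most
upstream valid start since the previous stop (ATG, plus the nine
single-substitution near-cognate starts by default) with > 3 codons
counting the stop; no emitted ORF is fully contained in a longer same-frame
ORF. A consequence worth knowing: a planted ORF preceded in-frame by a
near-cognate codon is reported with the longer, upstream-extended
boundaries.

The hexamer table scores `log2((f_cod(h)+ε)/(f_noncod(h)+ε))` with
frequencies counted in-frame (step 3) and additive smoothing
(ε = pseudocount / normalized); the coding score of a sequence is the mean
over hexamers at positions 0, 3, 6, …. The table is trained from data
(simulated conserved-gene CDS vs spacer sequence in the pipeline; any
user-supplied FASTA pair otherwise) — no precomputed species table ships.
Isoelectric point solves the Henderson–Hasselbalch net charge for zero by
bisection on [0, 14] to |charge| < 1e-4, on the EMBOSS pKa scale
(N-term 8.6, C-term 3.6, K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5,
Y 10.1).

## Pair statistics

Antisense overlap: opposite strands, genomic spans intersecting by ≥ 1 bp
(no minimum; an exonic-overlap mode exists). Divergent: opposite strands,
non-overlapping, head-to-head (the minus-strand transcript left of the
plus-strand one, 5′ ends facing the gap), gap 1–400 nt measured between the
facing boundaries. The two relations are mutually exclusive per pair; a
transcript may join several pairs.

Fold changes are `log2((TPM_stress+1)/(TPM_normal+1))`; the pseudocount is
second-order because correlations use ranks. Pair correlation is Spearman
with average ranks; p by the t approximation, replaced by the exact
permutation distribution for n < 10 (vectorized over all n! rank
permutations). The random-pairing null permutes partner assignments,
rejecting any permutation that recreates a true pair (or a caller-supplied
same-locus pairing), and reports the mean and 2.5/97.5 percentiles of the
permuted rhos; it is seeded and reproducible.

Fisher's exact test sums hypergeometric point probabilities ≤ the observed
one (two-sided point-probability rule, with a 1e-7 relative slack against
floating-point ties); the odds ratio is the sample OR with a Haldane 0.5
correction when a cell is zero.

## Origination routes

For each de novo transcript with a translated ORF, the locus window
(span ± 150 nt) is projected into each sister species (ranks 1–2). When the
window does not fit inside one block — typically because a diverged ORF
interior is a MUM desert that splits the block — the two window boundaries
are anchored in their own blocks and combined, provided orientations agree
and the projected region stays commensurate (within 2 kb of the window
size); progressively smaller windows down to the ORF interval are tried.
The focal region and the projected region, both oriented to the transcript
strand, are globally aligned (match 1, mismatch −1, affine gaps where a
length-k gap costs −4 − k; deterministic tie-break match > gap-in-other >
gap-in-focal). The focal ORF's aligned span is then compared against all
ATG→stop ORFs of the sister region: *conserved* requires overlap of at
least half of max(mapped span, focal ORF length) **and** candidate length
at least half the focal ORF's. The overlap floor matters: with a bare
≥ 1-position overlap rule, random sister sequence declares "conservation"
almost always, because chance ORFs of half the focal length are common in
random DNA — the rule as implemented recovers planted route labels
essentially perfectly at default divergence.

`transcript_first_fraction` = shared de novo transcripts (deepest rank 1–2)
with a translated ORF whose ORF is *not* conserved, over all such
transcripts with a resolved sister region; `orf_first_fraction` =
focal-specific de novo transcripts whose sister region already holds a
qualifying ORF, over resolved focal-specific ones. Unresolvable regions are
excluded from both denominators rather than silently counted as
non-conserved.

## The synthetic clade (stated world)

Six species — focal, four ladder relatives (ranks 1–4), one outgroup
(rank 5) — share one ancestral chromosome (default ~95 kb). Defaults, set
once:

* 40 conserved genes (plus 2 paralog copies), all plus-strand, 120–180
  codons, codon usage biased 3:1 toward pyrimidine-ending codons (so the
  hexamer score separates coding from non-coding); spacers 600–900 nt;
* 30 planted transcripts, all minus-strand, with birth branch ranks 0–4 and
  placements antisense (overlapping a host gene's 5′ end; a planted
  translated ORF sits in the non-overlapping portion so the host's coding
  sequence stays intact), divergent (head-to-head, gap U[1,400]), or
  intergenic (> 400 nt from any gene). 60% of planted transcripts are
  translated, with ORFs of 40–70 codons;
* evolution down the tree: per-branch substitution probability 0.05/site
  and Poisson indels (rate 5e-4/site, geometric length mean 3) confined to
  spacer DNA — gene and transcript loci are indel-protected so
  transcript-internal coordinates remain truth-consistent;
* DNA exists in every species; *transcription* is what is born: a rank-r
  transcript appears in the catalogs of the focal species and all species
  of rank ≤ r, novel provenance; conserved genes are annotated everywhere;
* coding integrity after evolution encodes route truth: conserved-gene
  CDSs and the focal copies of planted ORFs are stop-repaired; in rank-1/2
  species a planted translated ORF is stop-repaired when the truth says it
  is conserved there, and otherwise stop-disrupted by TAA codons
  interleaved every 9 nt with rotating frame offset, so no reading frame
  retains a stop-free run longer than 9 codons;
* expression: baseline log2 TPM ~ N(7, 1.5), renormalized to 1e6 per
  condition; stress log2 fold changes N(0, 1), with antisense partners
  drawn from a bivariate normal at Pearson 2·sin(π·ρ/6) so the Spearman
  correlation is ρ (default 0.7; divergent pairs 0.25);
* Ribo-Seq: reads ≈ Poisson(TPM × 0.02) per condition, placed multinomially
  over the ORF with P(frame 0) = 0.85 for translated ORFs and 1/3
  background on untranslated transcripts (at 0.3× depth).

What the simulator does **not** emulate: realistic yeast GC content or
codon usage, multi-exon transcripts, read-level sequencing noise,
rearrangements or inversions (all synteny blocks are forward), expression
condition-specificity structure beyond the copula, and mapping artifacts.
A green recovery test therefore establishes that the *inference machinery*
is correct under the stated generative model, not that the thresholds are
optimal for real data.

## Determinism and numerical choices

Every stochastic component flows from one integer seed (`rng_seed`; the
expression and Ribo streams derive from it by +1/+2). Two runs at one seed
produce byte-identical outputs, and `report.json` is a pure function of the
intermediate TSVs, so regeneration from saved tables is byte-identical too.
Gap-cost convention: a length-k gap costs open + k·extend (−4 − k);
equivalent Biopython settings are open −5 / extend −1. The alignment keeps
three int8 traceback matrices, so the 20 kb default length cap implies
~1.2 GB peak for worst-case inputs; pipeline alignments are ≤ ~1 kb.

## Known limitations

* The homology surrogate is ungapped; a homologue detectable only through a
  gapped alignment of many short segments can be missed where real BLAST
  would succeed. Imported hit tables are the escape hatch.
* E-values are calibrated by formula, not by empirical null fitting; they
  are conservative for ranking but not exchangeable with BLAST's numbers.
* The outgroup screen's chance-hit rate means a small fraction of genuine
  young transcripts is conservatively reclassified, as in the original
  screen's design.
* Synteny block chaining under the 100-base gap rule fragments at high
  divergence (≳ 0.2 substitutions/site); homology evidence, not synteny,
  carries age assignment for distant ranks.
* The translation caller's sensitivity degrades near the 10-read floor;
  conclusions about poorly expressed transcripts should consult
  `sensitivity_by_expression`.
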