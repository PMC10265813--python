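# Methods

## Editing-site calling model

A candidate editing site is a genomic position where, on the coding strand
of an overlapping CDS, the reference base is C and RNA reads carry T. On
the plus-strand pileup this means: plus-strand genes — reference C with T
reads; minus-strand genes — reference G with A reads. Candidates must pass
four screening thresholds (`CallerParams`):

| parameter | default | rationale |
|---|---|---|
| `min_rna_depth` | 5 | admits the shallowest well-supported sites (the packaged table's shallowest row has depth 5) |
| `min_edited_reads` | 2 | removes singleton noise at any depth |
| `min_efficiency` | 0.10 | generous margin under the lowest efficiency seen in practice (~0.39) |
| `max_dna_alt_fraction` | 0.05 | DNA alternate fraction above this marks a genomic variant |
| `cds_only` | true | organellar editing surveys find sites almost exclusively in protein-coding regions; a flag lifts the restriction |

Genomic subtraction removes a candidate when the DNA pileup shows the
alternate base above `max_dna_alt_fraction`, or — conservatively — when DNA
depth at the position is zero (the site cannot be verified);
`keep_unverified` reverses the latter. Sites are reported one record per
(gene, genomic position); a position inside two opposite-strand genes is
emitted per gene and flagged ambiguous. U-to-C (reverse) editing is not
called by default, reflecting its effective absence in angiosperm
organelles; symmetric calling is a flag away for other taxa.

Efficiency is the maximum-likelihood binomial estimate `edited / depth`
with N bases excluded from depth. Each read overlapping a site is an
independent Bernoulli draw in the generator, so the estimator is unbiased;
the calibration analysis (200 replicates at 0.92 planned efficiency, ~50x
depth) confirms the mean estimate sits within ±0.04 of truth.

Consequence annotation maps the genomic position into spliced-CDS
coordinates in transcription order (minus-strand genes read right-to-left
with complementation): `codon_index = ceil(gene_pos/3)`,
`codon_pos = ((gene_pos−1) mod 3) + 1`. Codons spanning exon junctions are
assembled from the spliced sequence, never the raw genome. Translation
uses the standard genetic code; start-codon special-casing is not applied
(no known organellar editing site sits in an initiator codon, and C→U
consequences are identical under the bacterial-style code for internal
codons). Stop gains translate to `*` and count as nonsynonymous.
Conserved-site matching compares (gene, codon_index) against a catalogue
in the field's gene-AAindex notation (e.g. `rps14-27`); the packaged
six-entry catalogue lists the sites shared with the Arabidopsis
chloroplast editotype.

## Pileup and read placement

The pileup engine counts every aligned (CIGAR M) base into per-position,
per-strand, per-base counters; soft-clipped bases are ignored and N bases
are counted but excluded from depth. Reads can arrive from a text SAM
subset (primary, ungapped alignments; indel-containing reads are skipped
and counted) or from the built-in exact placer, which seeds each read's
first 25-mer against the genome (both orientations), verifies the full
ungapped alignment at ≤10 % mismatches, and keeps only unique placements.
Multi-mapping reads — in particular reads wholly inside an inverted
repeat, which occurs twice — are dropped rather than assigned; editing
sites inside the IRs therefore need truth placements or single-copy
flanking evidence. Reads spanning the circular origin are split into two
placement segments. No base-quality weighting is applied (a minimum-quality
knob exists but defaults off); counts are raw.

## Synthetic data generator

The generator emulates the study conditions the analyses assume:

- **Genome**: circular `LSC + IRb + SSC + IRa`, with IRa the exact reverse
  complement of IRb. Defaults: 20 kb total, 9 kb LSC, 3 kb IRs, 5 kb SSC —
  a 1:8-scale plastome that preserves the architecture while keeping tests
  fast. The two bases flanking the IR pair are forced non-complementary so
  the planted IR lengths are exactly recoverable (otherwise maximal
  extension would grow them by chance in ~25 % of seeds).
- **Annotation**: eleven CDS (including one- and two-intron genes and
  minus-strand genes), two tRNAs, one rRNA; an rpl2-like CDS straddles the
  LSC/IRb junction and ycf1-like CDS straddle IRb/SSC and SSC/IRa,
  mirroring the canonical junction-gene layout. No gene is planted across
  the IRa/LSC junction: a mirrored wrap-around CDS cannot be made
  sequence-consistent with a random LSC head, so that junction is simply
  empty on synthetic genomes.
- **Reads**: 100-bp single-end reads (paired-end structure is modelled as
  independent ends), RNA at 52x mean transcript coverage with per-gene
  lognormal depth multipliers (uneven library representation), DNA uniform
  over the circle. At the default depth, coverage breadth over transcripts
  exceeds 99 %. RNA reads are drawn from spliced transcripts; reads
  crossing exon junctions or the origin are emitted as per-segment truth
  placements.
- **Edits and SNPs**: each read base over a planted edit flips C→T on the
  coding strand independently with probability = efficiency (binomial
  ground truth). Planted genomic SNPs appear at `dna_fraction` in **both**
  samples — transcripts are copied from the individual's SNP-carrying
  genome — which is precisely why the DNA-subtraction step exists and what
  makes the SNP decoys detectable-then-excludable in tests.
- **Sequencing error**: uniform per-base substitution at `seq_error`
  (default 0.001, in [0, 0.05)).
- **Mito background**: a uniform-random sequence twice the plastome length
  with plastome fragments copied in at a chosen identity (uniform
  mutations, same or inverted orientation), positions recorded as truth.

What the generator does **not** model: realistic error profiles and
quality scores, GC content and composition bias, poly-A selection bias on
editing efficiency (acknowledged as a real-data caveat; transcript
coverage here is uneven but unbiased at edited positions), isoforms,
duplicate reads, and gapped alignment. Passing tests therefore demonstrate
correctness of the counting, subtraction, annotation and detection logic
under clean mapping — not robustness to alignment artefacts of real
RNA-seq.

## Diversity statistics

π is the mean over all sequence pairs of (pairwise differences / pairwise
comparable sites); a column is comparable for a pair when both rows have
A/C/G/T there (pairwise deletion, not complete deletion — this keeps
partially gapped windows informative; both conventions are testable via
the column mask). A window with no comparable sites reports π as missing,
never 0. Sliding windows default to 600 bp with 200-bp step in alignment
coordinates, truncating the final window at the alignment end. A column is
variable with ≥2 distinct non-gap, non-N states and parsimony-informative
when ≥2 states each occur in ≥2 sequences. Hotspots are maximal merged
runs of windows with π above a threshold (default 0.013, the conventional
cut-off for plastome marker screening).

## Structure and transfer detection

Inverted-repeat detection anchors exact 25-mers between the doubled
circular sequence and its reverse complement, de-duplicates anchors per
anti-diagonal by explored extent (the same physical IR pair surfaces twice
in doubled coordinates), extends maximally, and keeps the longest disjoint
pair ≥ `min_ir` (default 1000 bp). The longer inter-IR arc is the LSC, the
shorter the SSC; the result is invariant to rotation and strand flip. A
gene is reported at a junction when its exon span covers the last base of
the upstream region and the first base of the downstream one.

Transfer detection is ungapped seed-and-extend: exact 21-mer anchors in
both orientations, X-drop extension (+1 match, −2 mismatch, drop 20)
trimmed to the best-scoring extent, per-diagonal merging of overlapping
hits with identity recomputed over the merged span, then length
(≥100 bp) and identity (≥0.90) filters. X-drop-with-trim was chosen over
"extend while running identity ≥ threshold" because the latter provably
drifts into flanking background until the running average hits the
threshold, biasing measured identity low (observed: 0.90 reported for a
0.95 fragment) and inflating the interval; trimmed X-drop recovers planted
identities within ±0.01. Gapped (Smith–Waterman) alignment is out of
scope: for ≥90 %-identity ungapped planted fragments the seed-and-extend
is exact enough, and a hook accepts external tabular hits where indel
tolerance matters.

## Numerical and edge-case choices

- All domain coordinates are 1-based inclusive; the only 0-based surface
  is BED output, flagged in its header.
- A CDS whose spliced length is not divisible by 3 is flagged
  non-translatable and excluded from calling rather than rejected at
  parse time.
- FASTA input is uppercased; U is converted to T with a warning.
- Deterministic everywhere: generators are pure functions of the seed;
  reports embed seed, config and version and are byte-identical across
  runs; file outputs are written atomically (temp-then-rename).
- Desk-scale problem sizes: validation analyses use 20-kb plastomes,
  20 seeds for caller recovery, 200 replicates for estimator calibration,
  and 50 random 5-kb alignments for the π oracle comparison — chosen as
  the smallest sizes at which the architecture (IR duplication, junction
  genes, multi-exon CDS) and the statistics (binomial efficiency bands)
  are all exercised meaningfully.

## Known limitations

- The exact placer is ungapped and unspliced; RNA reads over introns rely
  on truth placements (per-exon segments). Real spliced aligners are out
  of scope by design.
- IR-internal editing sites are invisible on the placer path because
  multi-mappers are dropped.
- Published genome-scale figures that require external accessions (the
  24-genome site counts and π profile; the cp-to-mt transfer inventory of
  a real mitogenome) are validated only through
  `scripts/validate_published_data.py` with locally supplied files.
- Statistical editing-significance models (binomial/beta-binomial tests),
  editing-QTL analysis and predictive editing models are non-goals.
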