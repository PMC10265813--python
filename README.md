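# plastedit

Chloroplast C-to-U RNA-editing detection and comparative plastome
statistics, with a ground-truth synthetic data generator.

## The problem

Land-plant chloroplast transcripts are post-transcriptionally edited:
specific cytidines are converted to uridines, so RNA-seq reads show a T
where the genome has a C on the coding strand. Calling these sites from
sequencing data means comparing an RNA-seq pileup against the genome,
rejecting positions where DNA-seq reads show the same variant (a genomic
SNP, not editing), and annotating each surviving site with its codon
consequence and editing efficiency

    efficiency = edited reads / coverage depth        (depth excludes N bases)

`plastedit` implements that pipeline end to end for organellar genomes,
together with the comparative statistics that usually accompany a plastome
study: sliding-window nucleotide diversity π (mean pairwise p-distance with
pairwise deletion), variable and parsimony-informative site counts,
quadripartite architecture detection (the LSC/IRb/SSC/IRa layout with its
junction genes such as *rpl2* and *ycf1*), and detection of
chloroplast-derived fragments inside a mitochondrial genome (MTPT) by
ungapped seed-and-extend local alignment at a ≥90 % identity threshold.

Because raw organellar sequencing runs are large and external, every stage
is validated against a synthetic generator that builds plastome-like
genomes with planted edits, SNPs, inverted repeats and transfer fragments —
so the whole analysis is reproducible at desk scale with known truth. A
published 19-row editing-site table for *Rosa hybrida* ships as a packaged
fixture and is re-analysed rather than trusted: consequences are re-derived
by translating each codon before and after the C→U edit.

## Worked example

Re-analyse the packaged published editing-site table:

```bash
plastedit table1-check
```

prints (abridged):

```json
{
  "n_sites": 19,
  "n_genes": 13,
  "n_synonymous": 3,
  "n_nonsynonymous": 16,
  "synonymous_fraction_pct": 15.79,
  "efficiency_min_pct": 38.89,
  "efficiency_mean_pct": 82.96,
  "efficiency_max_pct": 100.0,
  "n_conserved_matches": 6,
  "conserved_fraction_pct": 31.58,
  "conserved_ids": ["accD-264", "clpP1-187", "ndhD-128",
                    "rpoA-277", "rps14-27", "rps14-50"]
}
```

That is: 19 C-to-U sites across 13 genes; re-translating each printed codon
classifies 3 as silent (15.79 %) and 16 as amino-acid-changing; editing
efficiency spans 38.89–100 % with mean 82.96 %; and 6 sites (31.58 %) match
the packaged Arabidopsis-conserved catalogue on (gene, codon index).

A fully synthetic round trip:

```bash
plastedit simulate --seed 4 --out-prefix sim        # genome, GFF3, reads
plastedit call-editing \
    --genome sim.genome.fasta --genes sim.genes.gff3 \
    --rna sim.rna.sam --dna sim.dna.sam --out sites.tsv
plastedit summarize --sites sites.tsv
```

recovers exactly the planted edits listed in `sim.truth.tsv` (the three
planted genomic-SNP decoys are excluded by the DNA subtraction).

The numbered scripts under `analysis/` run the same stages as narrative
analyses and write their tables to `results/`:

```
01_table1_reanalysis.py          published-table summary + conserved match
02_synthetic_editing_recovery.py caller precision/recall over 20 seeds and
                                 efficiency-estimator calibration (0.92/50x)
03_sliding_diversity.py          600/200 sliding-window pi, site classes,
                                 hotspot calling on planted divergent blocks
04_structure_and_transfers.py    IR/LSC/SSC detection, junction genes,
                                 planted cp-to-mt transfer recovery
```

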