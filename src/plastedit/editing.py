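"""C-to-U editing-site calling from paired RNA/DNA pileups.

The computational core of the pipeline: extract candidate C-to-U positions
from the RNA pileup (coding-strand aware: ref C with T reads on plus-strand
genes, ref G with A reads on the plus-strand pileup for minus-strand genes),
subtract positions the DNA pileup shows to be genomic variants, annotate
codon consequences and compute per-site editing efficiency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .consequence import apply_edit, genome_to_cds
from .io_formats import GeneModel, SeqRecord
from .pileup import Pileup

log = logging.getLogger(__name__)


@dataclass
class CallerParams:
    """Screening thresholds for candidate editing sites.

    The defaults implement a stringent-but-permissive screen: minimum RNA
    depth 5 admits the shallowest well-supported sites, minimum edited-read
    count 2 removes singleton noise, minimum efficiency 0.10 leaves margin
    under the lowest efficiencies seen in practice (~0.39), and a DNA
    alternate fraction above 0.05 marks a position as a genomic variant.
    """

    min_rna_depth: int = 5
    min_edited_reads: int = 2
    min_efficiency: float = 0.10
    max_dna_alt_fraction: float = 0.05
    cds_only: bool = True
    keep_unverified: bool = False
    call_u_to_c: bool = False

    def __post_init__(self):
        if min(self.min_rna_depth, self.min_edited_reads) < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0 <= self.min_efficiency < 1:
            raise ValueError("min_efficiency must be in [0, 1)")


@dataclass
class Candidate:
    pos: int
    gene: str
    strand: str
    depth: int
    edited: int
    ambiguous: bool = False

    @property
    def efficiency(self) -> float:
        return self.edited / self.depth


@dataclass
class EditingSite:
    """One called C-to-U editing event (the row type of the site table)."""

    genome_pos: int
    gene: str
    strand: str
    gene_pos: int
    codon_index: int
    codon_pos: int
    ref_codon: str
    edited_codon: str
    aa_ref: str
    aa_alt: str
    consequence: str
    depth: int
    edited: int
    efficiency: float
    ref_id: str = ""
    ambiguous: bool = False

    def __post_init__(self):
        if not 0 < self.efficiency <= 1:
            raise ValueError("efficiency must be in (0, 1]")
        if self.edited > self.depth:
            raise ValueError("edited reads cannot exceed depth")


# edited-strand pairs: coding ref base -> (plus-strand ref, plus-strand alt)
_EDIT_BASES = {"+": ("C", "T"), "-": ("G", "A")}


def extract_candidates(
    rna: Pileup,
    genome: SeqRecord,
    genes: list[GeneModel],
    params: CallerParams,
) -> list[Candidate]:
    """Positions where the coding strand shows C with U(T)-carrying reads.

    A position overlapped by two genes on opposite strands yields one
    candidate per gene, flagged ambiguous. With ``cds_only`` false,
    positions outside any CDS are scanned on both strands (gene "").
    """
    cands: list[Candidate] = []
    claimed: dict[int, list[str]] = {}
    for g in genes:
        if g.ftype != "CDS" or not g.translatable:
            continue
        ref_base, alt_base = _EDIT_BASES[g.strand]
        for s, e in g.exons:
            for pos in range(s, e + 1):
                col = rna.get(pos)
                if col is None or col.ref != ref_base:
                    continue
                depth = col.depth()
                edited = col.base_count(alt_base)
                if _passes(depth, edited, params):
                    cands.append(
                        Candidate(pos, g.gene, g.strand, depth, edited)
                    )
                    claimed.setdefault(pos, []).append(g.strand)
    for pos, strands in claimed.items():
        if len(set(strands)) > 1:
            for c in cands:
                if c.pos == pos:
                    c.ambiguous = True
                    log.warning(
                        "position %d lies in overlapping genes on opposite "
                        "strands; candidate flagged ambiguous", pos,
                    )
    if not params.cds_only:
        in_cds = {
            pos
            for g in genes
            if g.ftype == "CDS"
            for s, e in g.exons
            for pos in range(s, e + 1)
        }
        for pos, col in rna.columns.items():
            if pos in in_cds:
                continue
            for strand in "+-":
                ref_base, alt_base = _EDIT_BASES[strand]
                if col.ref != ref_base:
                    continue
                depth = col.depth()
                edited = col.base_count(alt_base)
                if _passes(depth, edited, params):
                    cands.append(Candidate(pos, "", strand, depth, edited))
    cands.sort(key=lambda c: (c.pos, c.gene))
    return cands


def _passes(depth: int, edited: int, params: CallerParams) -> bool:
    return (
        depth >= params.min_rna_depth
        and edited >= params.min_edited_reads
        and edited / depth >= params.min_efficiency
    )


def subtract_genomic(
    candidates: list[Candidate],
    dna: Pileup,
    params: CallerParams,
) -> list[Candidate]:
    """Remove candidates the DNA pileup shows to be genomic variants.

    A candidate is dropped when the DNA alternate-base fraction exceeds
    ``max_dna_alt_fraction``, or (conservatively) when DNA depth is zero so
    the site cannot be verified; ``keep_unverified`` reverses the latter.
    """
    kept = []
    for c in candidates:
        _, alt_base = _EDIT_BASES[c.strand]
        col = dna.get(c.pos)
        depth = col.depth() if col else 0
        if depth == 0:
            if params.keep_unverified:
                kept.append(c)
            else:
                log.info("position %d: no DNA coverage, removed as "
                         "unverifiable", c.pos)
            continue
        if col.base_count(alt_base) / depth > params.max_dna_alt_fraction:
            log.info("position %d: genomic variant, excluded", c.pos)
            continue
        kept.append(c)
    return kept


def call_sites(
    rna: Pileup,
    dna: Pileup,
    genome: SeqRecord,
    genes: list[GeneModel],
    params: CallerParams | None = None,
) -> list[EditingSite]:
    """Full calling pipeline: extract, subtract genomic, annotate.

    One record per (gene, genomic position), sorted by genome position;
    efficiency = edited / depth where depth excludes N bases.
    """
    params = params or CallerParams()
    by_name = {g.gene: g for g in genes}
    cands = extract_candidates(rna, genome, genes, params)
    cands = subtract_genomic(cands, dna, params)
    sites = []
    for c in cands:
        if not c.gene:
            continue  # non-CDS candidates carry no codon annotation
        gene = by_name[c.gene]
        gene_pos, codon_index, codon_pos, ref_codon = genome_to_cds(
            c.pos, gene, genome
        )
        edited_codon, aa_ref, aa_alt, consequence = apply_edit(
            ref_codon, codon_pos
        )
        sites.append(
            EditingSite(
                genome_pos=c.pos, gene=c.gene, strand=c.strand,
                gene_pos=gene_pos, codon_index=codon_index,
                codon_pos=codon_pos, ref_codon=ref_codon,
                edited_codon=edited_codon.replace("U", "T"),
                aa_ref=aa_ref, aa_alt=aa_alt,
                consequence=consequence, depth=c.depth, edited=c.edited,
                efficiency=c.efficiency, ref_id=rna.ref_id,
                ambiguous=c.ambiguous,
            )
        )
    sites.sort(key=lambda s: (s.genome_pos, s.gene))
    return sites


def summarize(sites) -> dict:
    """Summary statistics over called sites (or printed-table rows).

    Works on any objects exposing ``gene``, ``efficiency``, ``consequence``
    and ``codon_pos``. Efficiencies are reported as percentages.
    """
    n = len(sites)
    if n == 0:
        return {
            "n_sites": 0, "n_genes": 0, "per_gene": {},
            "n_synonymous": 0, "n_nonsynonymous": 0,
            "synonymous_fraction_pct": 0.0,
            "efficiency_min_pct": 0.0, "efficiency_mean_pct": 0.0,
            "efficiency_max_pct": 0.0,
            "codon_position_counts": {1: 0, 2: 0, 3: 0},
        }
    per_gene: dict[str, int] = {}
    for s in sites:
        per_gene[s.gene] = per_gene.get(s.gene, 0) + 1
    effs = [s.efficiency * 100 for s in sites]
    n_syn = sum(1 for s in sites if s.consequence == "synonymous")
    cpos = {1: 0, 2: 0, 3: 0}
    for s in sites:
        cpos[s.codon_pos] += 1
    return {
        "n_sites": n,
        "n_genes": len(per_gene),
        "per_gene": dict(sorted(per_gene.items())),
        "n_synonymous": n_syn,
        "n_nonsynonymous": n - n_syn,
        "synonymous_fraction_pct": round(100.0 * n_syn / n, 2),
        "efficiency_min_pct": round(min(effs), 2),
        "efficiency_mean_pct": round(sum(effs) / n, 2),
        "efficiency_max_pct": round(max(effs), 2),
        "codon_position_counts": cpos,
    }
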