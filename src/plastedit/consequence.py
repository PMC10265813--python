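"""Codon-level consequence annotation for C-to-U edits.

Maps genomic positions into spliced-CDS coordinates (transcription order,
strand-aware), applies the edit to the codon and classifies the amino-acid
change with the standard genetic code. Conserved-site comparison uses the
field's gene-AAindex naming scheme (e.g. rps14-27).
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import GeneModel, SeqRecord, translate_codon


class NonExonicError(ValueError):
    """Position does not fall in an exon of the gene."""


@dataclass(frozen=True)
class ConservedSiteRef:
    gene: str
    aa_index: int  # 1-based amino-acid position
    source_label: str = ""


def genome_to_cds(
    pos: int, gene: GeneModel, genome: SeqRecord
) -> tuple[int, int, int, str]:
    """Map a genomic position to spliced-CDS coordinates.

    Returns ``(gene_pos, codon_index, codon_pos, ref_codon)`` where
    ``gene_pos`` is 1-based along the spliced CDS in transcription order
    (minus-strand genes read right-to-left with complementation),
    ``codon_index = ceil(gene_pos / 3)`` and
    ``codon_pos = ((gene_pos - 1) mod 3) + 1``. The reference codon is read
    from the spliced sequence, so codons spanning exon junctions are
    assembled correctly.
    """
    if gene.ftype == "CDS" and not gene.translatable:
        raise ValueError(f"gene {gene.gene} is flagged non-translatable")
    offset = 0  # 0-based index into the plus-strand spliced concatenation
    found = False
    for s, e in gene.exons:
        if s <= pos <= e:
            offset += pos - s
            found = True
            break
        offset += e - s + 1
    if not found:
        raise NonExonicError(f"position {pos} is non-exonic in {gene.gene}")
    if gene.strand == "+":
        gene_pos = offset + 1
    else:
        gene_pos = gene.spliced_length - offset
    codon_index = (gene_pos + 2) // 3
    codon_pos = (gene_pos - 1) % 3 + 1
    spliced = gene.spliced_sequence(genome)
    ref_codon = spliced[(codon_index - 1) * 3 : codon_index * 3]
    return gene_pos, codon_index, codon_pos, ref_codon


def cds_to_genome(gene_pos: int, gene: GeneModel) -> int:
    """Inverse of :func:`genome_to_cds`: spliced coordinate -> genomic."""
    if not 1 <= gene_pos <= gene.spliced_length:
        raise ValueError(f"gene_pos {gene_pos} outside {gene.gene}")
    if gene.strand == "+":
        offset = gene_pos - 1
    else:
        offset = gene.spliced_length - gene_pos
    for s, e in gene.exons:
        n = e - s + 1
        if offset < n:
            return s + offset
        offset -= n
    raise AssertionError("unreachable")


def apply_edit(ref_codon: str, codon_pos: int) -> tuple[str, str, str, str]:
    """Apply a C-to-U edit at ``codon_pos`` (1-3) of a codon.

    Accepts DNA or RNA alphabet (T treated as U). Returns
    ``(edited_codon, aa_ref, aa_alt, consequence)`` with consequence
    ``synonymous`` iff the amino acid is unchanged; stop gains translate
    to ``*`` and are nonsynonymous.
    """
    codon = ref_codon.upper().replace("U", "T")
    if len(codon) != 3 or codon_pos not in (1, 2, 3):
        raise ValueError(f"bad codon {ref_codon!r} / position {codon_pos}")
    if codon[codon_pos - 1] != "C":
        raise ValueError(
            f"base at codon position {codon_pos} of {ref_codon} is not C"
        )
    edited = codon[: codon_pos - 1] + "T" + codon[codon_pos:]
    aa_ref = translate_codon(codon)
    aa_alt = translate_codon(edited)
    consequence = "synonymous" if aa_ref == aa_alt else "nonsynonymous"
    # the edited codon is an RNA molecule: report it in the RNA alphabet
    return edited.replace("T", "U"), aa_ref, aa_alt, consequence


def read_conserved_catalogue(path: str) -> list[ConservedSiteRef]:
    """Read a 3-column (gene, aa_index, source) TSV catalogue."""
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene"):
            fh.seek(0)
        for line in fh:
            if not line.strip():
                continue
            gene, aa_index, *rest = line.rstrip("\n").split("\t")
            out.append(
                ConservedSiteRef(gene, int(aa_index), rest[0] if rest else "")
            )
    return out


def match_conserved(sites, catalogue: list[ConservedSiteRef]):
    """Match sites against a conserved catalogue on (gene, codon_index).

    Returns ``(matched_sites, fraction)`` with the fraction computed over
    all input sites (table-row convention).
    """
    keys = {(c.gene, c.aa_index) for c in catalogue}
    matched = [s for s in sites if (s.gene, s.codon_index) in keys]
    fraction = len(matched) / len(sites) if sites else 0.0
    return matched, fraction
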