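"""Readers and writers for the external formats the pipeline touches.

All coordinates in domain types are 1-based inclusive (GFF3/SAM convention);
any conversion to other conventions happens inside this module. Downstream
modules only ever see :class:`SeqRecord`, :class:`GeneModel` and
:class:`AlignedRead`.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

_IUPAC = set("ACGTN")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class SeqRecord:
    """A named nucleotide sequence (plastome, mitogenome or read)."""

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)

    def base(self, pos: int) -> str:
        """1-based lookup, wrapping the origin on circular sequences."""
        if self.circular:
            return self.seq[(pos - 1) % len(self.seq)]
        return self.seq[pos - 1]


@dataclass
class GeneModel:
    """A gene with strand, feature type and ordered plus-strand exons.

    Exons are stored ascending on the plus strand regardless of
    transcription direction; minus-strand transcription order is derived
    when mapping coordinates. ``translatable`` is cleared when a CDS
    spliced length is not a multiple of three.
    """

    gene: str
    ftype: str  # CDS | tRNA | rRNA
    strand: str  # + | -
    exons: list[tuple[int, int]]
    translatable: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.ftype not in ("CDS", "tRNA", "rRNA"):
            raise ValueError(f"bad feature type {self.ftype!r}")
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping exons in {self.gene}")
        self.exons = ex

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def contains(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def spliced_sequence(self, genome: SeqRecord) -> str:
        """Coding-strand spliced sequence (revcomp'd for minus strand)."""
        s = "".join(genome.seq[s - 1 : e] for s, e in self.exons)
        return revcomp(s) if self.strand == "-" else s


@dataclass
class AlignedRead:
    """An ungapped read placement; ``seq`` is reference-forward oriented.

    ``match_ops`` is a simplified CIGAR restricted to M (aligned) and
    S (soft-clip) operations.
    """

    read_id: str
    ref_id: str
    pos: int  # 1-based leftmost reference coordinate
    strand_of_alignment: str
    seq: str
    match_ops: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if not self.match_ops:
            self.match_ops = [(len(self.seq), "M")]

    @property
    def aligned_span(self) -> int:
        return sum(n for n, op in self.match_ops if op == "M")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str, circular: bool = False) -> list[SeqRecord]:
    """Read a FASTA file into :class:`SeqRecord` objects.

    Sequences are uppercased; U is converted to T with a warning. Non-IUPAC
    characters raise :class:`FormatError` naming the record.
    """
    records = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            if "U" in seq:
                log.warning("record %s: converting U to T", rec.id)
                seq = seq.replace("U", "T")
            bad = set(seq) - _IUPAC
            if bad:
                raise FormatError(
                    f"record {rec.id}: non-IUPAC characters {sorted(bad)}"
                )
            if not seq:
                raise FormatError(f"record {rec.id}: empty sequence")
            records.append(SeqRecord(rec.id, seq, circular=circular))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[SeqRecord], path: str, width: int = 70) -> None:
    with _atomic_open(path) as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path: str, genome: SeqRecord) -> list[GeneModel]:
    """Parse a GFF3 annotation into :class:`GeneModel` objects.

    CDS segments sharing a parent (or, failing that, a gene name) are merged
    into one model. A CDS whose spliced length is not divisible by three is
    flagged non-translatable with a warning; an exon outside the genome is
    an error.
    """
    by_key: dict[tuple[str, str], GeneModel] = {}
    order: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            _, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype not in ("CDS", "tRNA", "rRNA"):
                continue
            start_i, end_i = int(start), int(end)
            if start_i < 1 or end_i > len(genome.seq):
                raise FormatError(
                    f"{path}:{lineno}: feature {start_i}-{end_i} outside "
                    f"genome of length {len(genome.seq)}"
                )
            adict = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            name = (
                adict.get("gene")
                or adict.get("Parent")
                or adict.get("ID")
                or f"feat{lineno}"
            )
            key = (name, ftype)
            if key in by_key:
                by_key[key].exons.append((start_i, end_i))
            else:
                by_key[key] = GeneModel(name, ftype, strand, [(start_i, end_i)])
                order.append(key)
    models = []
    for key in order:
        m = by_key[key]
        # re-validate after exon accumulation
        m = GeneModel(m.gene, m.ftype, m.strand, m.exons)
        if m.ftype == "CDS" and m.spliced_length % 3 != 0:
            log.warning(
                "gene %s: spliced CDS length %d not divisible by 3; "
                "flagged non-translatable", m.gene, m.spliced_length,
            )
            m.translatable = False
        models.append(m)
    return models


def write_gff3(genes: list[GeneModel], genome: SeqRecord, path: str) -> None:
    """Emit the GFF3 subset read back by :func:`read_gff3`."""
    with _atomic_open(path) as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome.seq)}\n")
        for g in genes:
            s, e = g.span
            fh.write(
                f"{genome.id}\tplastedit\tgene\t{s}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.gene}\n"
            )
            for es, ee in g.exons:
                fh.write(
                    f"{genome.id}\tplastedit\t{g.ftype}\t{es}\t{ee}\t.\t"
                    f"{g.strand}\t.\tParent={g.gene};gene={g.gene}\n"
                )


# ---------------------------------------------------------------------------
# SAM subset


def read_sam_subset(path: str) -> tuple[list[AlignedRead], dict[str, int]]:
    """Read primary, mapped, ungapped alignments from a text SAM file.

    Reads with insertion/deletion/skip CIGAR operations are skipped and
    counted; secondary/supplementary and unmapped records are dropped.
    Returns ``(reads, counters)`` where counters report the drops.
    """
    import pysam

    counters = {"indel_skipped": 0, "unmapped": 0, "secondary": 0}
    reads: list[AlignedRead] = []
    try:
        sam = pysam.AlignmentFile(path, "r", check_sq=True)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    with sam:
        refs = set(sam.references)
        for rec in _iter_sam(sam, path):
            if rec.is_unmapped:
                if rec.cigartuples or rec.reference_start >= 0:
                    # htslib downgrades a record whose RNAME is absent from
                    # @SQ to "unmapped" but keeps its POS/CIGAR; that is a
                    # header defect, not an unmapped read
                    raise FormatError(
                        f"read {rec.query_name}: reference missing from "
                        f"@SQ header"
                    )
                counters["unmapped"] += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                counters["secondary"] += 1
                continue
            if rec.reference_name not in refs:
                raise FormatError(
                    f"read {rec.query_name}: reference "
                    f"{rec.reference_name!r} missing from @SQ header"
                )
            ops = []
            bad = False
            for op, n in rec.cigartuples or []:
                if op == 0:  # M
                    ops.append((n, "M"))
                elif op == 4:  # S
                    ops.append((n, "S"))
                elif op == 5:  # H, consumes nothing we store
                    continue
                else:  # I/D/N and friends
                    bad = True
                    break
            if bad:
                counters["indel_skipped"] += 1
                continue
            reads.append(
                AlignedRead(
                    read_id=rec.query_name,
                    ref_id=rec.reference_name,
                    pos=rec.reference_start + 1,
                    strand_of_alignment="-" if rec.is_reverse else "+",
                    seq=rec.query_sequence or "",
                    match_ops=ops,
                )
            )
    return reads, counters


def _iter_sam(sam, path):
    """Iterate a pysam file, converting parse errors (e.g. a record whose
    reference is missing from @SQ) into FormatError."""
    it = iter(sam)
    while True:
        try:
            yield next(it)
        except StopIteration:
            return
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc


def write_sam(
    reads: list[AlignedRead], refs: list[SeqRecord], path: str
) -> None:
    """Write ungapped placements as text SAM (FLAG, POS, CIGAR nM, SEQ)."""
    with _atomic_open(path) as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for r in refs:
            fh.write(f"@SQ\tSN:{r.id}\tLN:{len(r.seq)}\n")
        for rd in reads:
            flag = 16 if rd.strand_of_alignment == "-" else 0
            cigar = "".join(f"{n}{op}" for n, op in rd.match_ops)
            fh.write(
                f"{rd.read_id}\t{flag}\t{rd.ref_id}\t{rd.pos}\t60\t{cigar}"
                f"\t*\t0\t0\t{rd.seq}\t*\n"
            )


# ---------------------------------------------------------------------------
# Editing-site tables


def format_efficiency(frac: float) -> str:
    """Render an efficiency fraction the way the site tables print it."""
    return f"{frac * 100:.2f}%"


SITE_COLUMNS = [
    "gene", "genome_pos", "gene_pos", "codon_pos", "edit_type",
    "codon_change", "aa_change", "depth", "efficiency",
]


def write_sites(sites, path: str, dialect: str = "tsv") -> None:
    """Write called editing sites as TSV or a VCF 4.2-like file.

    ``sites`` must be sorted by genome position (ValueError otherwise).
    The TSV dialect mirrors the canonical per-site table (positions, codon
    change, amino-acid change, depth, efficiency as ``NN.NN%``); the
    vcf-like dialect carries GENE, CPOS, AAC, EF, DP INFO keys.
    """
    pos = [s.genome_pos for s in sites]
    if pos != sorted(pos):
        raise ValueError("sites must be sorted by genome position")
    if dialect == "tsv":
        with _atomic_open(path) as fh:
            fh.write("\t".join(SITE_COLUMNS) + "\n")
            for s in sites:
                fh.write(
                    f"{s.gene}\t{s.genome_pos}\t{s.gene_pos}\t{s.codon_pos}\t"
                    f"C->U\t{_rna(s.ref_codon)}->{_rna(s.edited_codon)}\t"
                    f"{s.aa_ref}->{s.aa_alt}\t{s.depth}\t"
                    f"{format_efficiency(s.efficiency)}\n"
                )
    elif dialect == "vcf-like":
        with _atomic_open(path) as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene">\n')
            fh.write('##INFO=<ID=CPOS,Number=1,Type=Integer,Description="Position in codon">\n')
            fh.write('##INFO=<ID=AAC,Number=1,Type=String,Description="Amino acid change">\n')
            fh.write('##INFO=<ID=EF,Number=1,Type=Float,Description="Editing efficiency">\n')
            fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Coverage depth">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for s in sites:
                ref, alt = ("C", "T") if s.strand == "+" else ("G", "A")
                fh.write(
                    f"{s.ref_id}\t{s.genome_pos}\t.\t{ref}\t{alt}\t.\tPASS\t"
                    f"GENE={s.gene};CPOS={s.codon_pos};"
                    f"AAC={s.aa_ref}->{s.aa_alt};"
                    f"EF={s.efficiency:.4f};DP={s.depth}\n"
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _rna(codon: str) -> str:
    return codon.replace("T", "U")


# ---------------------------------------------------------------------------


class _atomic_open:
    """Write to a temp file and rename into place on success."""

    def __init__(self, path: str):
        self.path = path
        d = os.path.dirname(os.path.abspath(path))
        fd, self.tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
        self.fh = os.fdopen(fd, "w")

    def __enter__(self):
        return self.fh

    def __exit__(self, exc_type, exc, tb):
        self.fh.close()
        if exc_type is None:
            os.replace(self.tmp, self.path)
        else:
            os.unlink(self.tmp)
        return False


def translate_codon(codon: str) -> str:
    """Translate one codon (DNA or RNA alphabet) with the standard code."""
    return str(Seq(codon.replace("U", "T")).translate())
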