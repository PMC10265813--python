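"""Plastome-like synthetic data with known ground truth.

Generates a circular quadripartite genome (LSC + IRb + SSC + IRa, IRa the
reverse complement of IRb), a gene annotation with multi-exon and
minus-strand CDS and junction-spanning genes, RNA reads carrying planted
C-to-U edits at configured per-site efficiencies, DNA reads with optional
true genomic SNPs, and a mitochondrial background with planted plastome
fragments — everything the editing/structure/transfer analyses consume,
at desk scale and deterministic under a fixed seed.

Planted genomic SNPs are applied to RNA reads as well as DNA reads (at the
same ``dna_fraction``): transcripts are copied from the individual's
SNP-carrying genome, which is exactly why genomic-SNP subtraction is needed
downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .consequence import apply_edit
from .io_formats import AlignedRead, GeneModel, SeqRecord, revcomp
from .structure import QuadripartiteMap

_OTHER = {ord(b): np.array([ord(c) for c in "ACGT" if c != b]) for b in "ACGT"}


@dataclass
class PlannedEdit:
    genome_pos: int
    efficiency: float
    expected_gene: str = ""

    def __post_init__(self):
        if not 0 < self.efficiency <= 1:
            raise ValueError("efficiency must be in (0, 1]")


@dataclass
class PlannedSnp:
    genome_pos: int
    alt_base: str
    dna_fraction: float = 1.0


@dataclass
class SimConfig:
    """Study conditions for one synthetic experiment.

    Defaults mirror the sequencing design the analyses assume: 100-bp reads
    and ~52x mean transcript coverage, which keeps coverage breadth over
    the transcripts above 99%.
    """

    seed: int = 0
    genome_len: int = 20_000
    ir_len: int = 3_000
    lsc_len: int = 9_000
    read_len: int = 100
    rna_depth: float = 52.0
    dna_depth: float = 52.0
    seq_error: float = 0.001
    sites: list[PlannedEdit] = field(default_factory=list)
    snps: list[PlannedSnp] = field(default_factory=list)

    def __post_init__(self):
        if self.lsc_len + 2 * self.ir_len >= self.genome_len:
            raise ValueError("lsc_len + 2*ir_len must be < genome_len")
        if not 0 <= self.seq_error < 0.05:
            raise ValueError("seq_error must be in [0, 0.05)")
        if self.rna_depth <= 0 or self.dna_depth <= 0:
            raise ValueError("depths must be positive")

    @property
    def ssc_len(self) -> int:
        return self.genome_len - self.lsc_len - 2 * self.ir_len

    def to_yaml(self, path: str) -> None:
        d = dict(
            seed=self.seed, genome_len=self.genome_len, ir_len=self.ir_len,
            lsc_len=self.lsc_len, read_len=self.read_len,
            rna_depth=self.rna_depth, dna_depth=self.dna_depth,
            seq_error=self.seq_error,
            sites=[vars(s) for s in self.sites],
            snps=[vars(s) for s in self.snps],
        )
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["sites"] = [PlannedEdit(**s) for s in d.get("sites", [])]
        d["snps"] = [PlannedSnp(**s) for s in d.get("snps", [])]
        return cls(**d)


# ---------------------------------------------------------------------------
# Genome + annotation

# (name, ftype, strand, alternating exon/intron lengths starting with exon)
_LSC_GENES = [
    ("psbA", "CDS", "-", [900]),
    ("atpA", "CDS", "+", [1200]),
    ("rpoC1", "CDS", "+", [600, 300, 600]),        # one intron
    ("clpP1", "CDS", "-", [210, 250, 291, 250, 300]),  # two introns
    ("rps14", "CDS", "+", [303]),
    ("petB", "CDS", "-", [648]),
    ("trnH", "tRNA", "+", [75]),
    ("trnK", "tRNA", "-", [72]),
]


def build_plastome(
    config: SimConfig,
) -> tuple[SeqRecord, list[GeneModel], QuadripartiteMap]:
    """Build a circular quadripartite genome with a planted annotation.

    The annotation contains >= 8 CDS (two or more on the minus strand, one
    with one intron and one with two), >= 2 tRNA and >= 1 rRNA; an
    rpl2-like CDS straddles the LSC/IRb junction and ycf1-like CDS straddle
    IRb/SSC and SSC/IRa, mirroring the canonical junction-gene layout.
    """
    if config.ir_len < 2500:
        raise ValueError("ir_len too small to place junction genes (>=2500)")
    if config.ssc_len < 2900:
        raise ValueError("ssc_len too small to place genes (>=2900)")

    lsc_end = config.lsc_len
    irb_end = lsc_end + config.ir_len
    ssc_end = irb_end + config.ssc_len

    genes: list[GeneModel] = []
    gap = max(50, config.lsc_len // 50)
    cursor = gap + 1
    for name, ftype, strand, pieces in _LSC_GENES:
        exons = []
        p = cursor
        for i, n in enumerate(pieces):
            if i % 2 == 0:
                exons.append((p, p + n - 1))
            p += n
        genes.append(GeneModel(name, ftype, strand, exons))
        cursor = p + gap
    if cursor > lsc_end - 450:
        raise ValueError("lsc_len too small to place genes")
    # junction genes
    genes.append(GeneModel("rpl2", "CDS", "+", [(lsc_end - 449, lsc_end + 450)]))
    genes.append(GeneModel("rrn16", "rRNA", "+",
                           [(lsc_end + 551, lsc_end + 551 + 1489)]))
    genes.append(GeneModel("ycf1b", "CDS", "+", [(irb_end - 299, irb_end + 300)]))
    genes.append(GeneModel("ndhF", "CDS", "-",
                           [(irb_end + 400, irb_end + 400 + 1499)]))
    genes.append(GeneModel("ycf1", "CDS", "-", [(ssc_end - 899, ssc_end + 300)]))

    rng = np.random.default_rng(config.seed)
    core = rng.integers(0, 4, size=irb_end + config.ssc_len)
    core_seq = list("ACGT"[i] for i in core)
    # crisp IR boundaries: the bases flanking the IR pair must not be
    # complementary, or maximal extension would grow the IRs by chance
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if core_seq[lsc_end - 1] == comp[core_seq[0]]:
        core_seq[0] = "ACGT"[("ACGT".index(core_seq[0]) + 1) % 4]
    if core_seq[irb_end] == comp[core_seq[-1]]:
        core_seq[-1] = "ACGT"[("ACGT".index(core_seq[-1]) + 1) % 4]
    core_seq = "".join(core_seq)
    irb_seq = core_seq[lsc_end:irb_end]
    genome_seq = core_seq + revcomp(irb_seq)
    assert len(genome_seq) == config.genome_len
    genome = SeqRecord("synthetic_plastome", genome_seq, circular=True)

    for g in genes:
        if g.ftype == "CDS" and g.spliced_length % 3:
            raise AssertionError(f"planted CDS {g.gene} not divisible by 3")
    qmap = QuadripartiteMap(
        lsc=(1, lsc_end),
        irb=(lsc_end + 1, irb_end),
        ssc=(irb_end + 1, ssc_end),
        ira=(ssc_end + 1, config.genome_len),
        junction_genes={
            "LSC/IRb": ["rpl2"],
            "IRb/SSC": ["ycf1b"],
            "SSC/IRa": ["ycf1"],
            "IRa/LSC": [],
        },
    )
    return genome, genes, qmap


def coding_c_positions(
    genome: SeqRecord, genes: list[GeneModel], margin: int = 30
) -> list[tuple[int, str]]:
    """Exonic positions whose coding-strand base is C, as (pos, gene).

    ``margin`` spliced bases at each transcript end are excluded so planted
    sites sit in the well-covered interior of their transcript.
    """
    out = []
    for g in genes:
        if g.ftype != "CDS" or not g.translatable:
            continue
        want = "C" if g.strand == "+" else "G"
        offset = 0
        for s, e in g.exons:
            for pos in range(s, e + 1):
                spliced = offset + pos - s + 1
                if (
                    genome.seq[pos - 1] == want
                    and margin < spliced <= g.spliced_length - margin
                ):
                    out.append((pos, g.gene))
            offset += e - s + 1
    return out


def plan_edits(
    genome: SeqRecord,
    genes: list[GeneModel],
    n: int,
    rng: np.random.Generator,
    eff_range: tuple[float, float] = (0.3, 1.0),
    exclude: set[int] | None = None,
) -> list[PlannedEdit]:
    """Pick ``n`` coding-C positions and assign evenly spread efficiencies."""
    cands = [
        (p, g) for p, g in coding_c_positions(genome, genes)
        if not exclude or p not in exclude
    ]
    idx = rng.choice(len(cands), size=n, replace=False)
    effs = np.linspace(eff_range[0], eff_range[1], n)
    rng.shuffle(effs)
    return [
        PlannedEdit(cands[i][0], float(e), cands[i][1])
        for i, e in zip(idx, effs)
    ]


def plan_snps(
    genome: SeqRecord,
    genes: list[GeneModel],
    n: int,
    rng: np.random.Generator,
    exclude: set[int] | None = None,
    dna_fraction: float = 1.0,
) -> list[PlannedSnp]:
    """Pick ``n`` coding-C positions and plant the C-to-U-mimicking SNP.

    The alternate base is the plus-strand image of a coding-strand C>T
    change (T on plus-strand genes, A on minus-strand genes), so each SNP
    is a decoy the genomic-subtraction step must remove.
    """
    by_gene = {g.gene: g for g in genes}
    cands = [
        (p, g) for p, g in coding_c_positions(genome, genes)
        if not exclude or p not in exclude
    ]
    idx = rng.choice(len(cands), size=n, replace=False)
    out = []
    for i in idx:
        pos, gname = cands[i]
        alt = "T" if by_gene[gname].strand == "+" else "A"
        out.append(PlannedSnp(pos, alt, dna_fraction))
    return out


# ---------------------------------------------------------------------------
# Read simulation


def simulate_reads(
    genome: SeqRecord,
    genes: list[GeneModel],
    config: SimConfig,
    sample: str,
    fastq_path: str | None = None,
) -> list[AlignedRead]:
    """Simulate reads with known truth placements.

    RNA reads are drawn from spliced transcripts of the annotated genes
    (per-gene depth multipliers model uneven library representation); each
    read base over a planned edit flips C->T on the coding strand
    independently with probability = efficiency. DNA reads are drawn
    uniformly from the circular genome. Planned SNPs appear at
    ``dna_fraction`` in both samples; per-base errors at ``seq_error``.
    Reads spanning exon junctions or the origin are emitted as per-segment
    placements.
    """
    if sample not in ("RNA", "DNA"):
        raise ValueError("sample must be RNA or DNA")
    rng = np.random.default_rng((config.seed, 1 if sample == "RNA" else 2))
    garr = np.frombuffer(genome.seq.encode(), dtype=np.uint8).copy()
    L = len(garr)
    snp_pos = np.array([s.genome_pos - 1 for s in config.snps], dtype=int)
    snp_alt = np.array([ord(s.alt_base) for s in config.snps], dtype=np.uint8)
    snp_frac = np.array([s.dna_fraction for s in config.snps])

    reads: list[AlignedRead] = []
    if sample == "RNA":
        by_gene: dict[str, list[PlannedEdit]] = {}
        placed_sites = set()
        for g in genes:
            for site in config.sites:
                if g.ftype == "CDS" and g.contains(site.genome_pos):
                    by_gene.setdefault(g.gene, []).append(site)
                    placed_sites.add(site.genome_pos)
        for site in config.sites:
            if site.genome_pos not in placed_sites:
                import logging
                logging.getLogger(__name__).warning(
                    "planned edit at %d lies outside every transcript; "
                    "it will be undetectable", site.genome_pos,
                )
        for g in genes:
            splice = np.concatenate(
                [np.arange(s - 1, e) for s, e in g.exons]
            )
            tlen = len(splice)
            rl = min(config.read_len, tlen)
            mult = float(np.clip(rng.lognormal(0.0, 0.3), 0.6, 1.8))
            n_reads = int(round(config.rna_depth * mult * tlen / rl))
            edits = by_gene.get(g.gene, [])
            edited_base = ord("T") if g.strand == "+" else ord("A")
            starts = rng.integers(0, tlen - rl + 1, size=n_reads)
            site_idx = {
                s.genome_pos - 1: s.efficiency for s in edits
            }
            for ri, st in enumerate(starts):
                block = splice[st : st + rl]
                seq = garr[block].copy()
                for j, p0 in enumerate(block):
                    eff = site_idx.get(int(p0))
                    if eff is not None and rng.random() < eff:
                        seq[j] = edited_base
                _apply_snps(seq, block, snp_pos, snp_alt, snp_frac, rng)
                _apply_errors(seq, config.seq_error, rng)
                strand = "+" if rng.random() < 0.5 else "-"
                reads.extend(
                    _segments(f"{g.gene}_r{ri}", genome.id, block, seq, strand)
                )
    else:
        rl = config.read_len
        n_reads = int(round(config.dna_depth * L / rl))
        hi = L if genome.circular else L - rl + 1
        starts = rng.integers(0, hi, size=n_reads)
        for ri, st in enumerate(starts):
            block = (st + np.arange(rl)) % L
            seq = garr[block].copy()
            _apply_snps(seq, block, snp_pos, snp_alt, snp_frac, rng)
            _apply_errors(seq, config.seq_error, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            reads.extend(
                _segments(f"dna_r{ri}", genome.id, block, seq, strand)
            )
    if fastq_path:
        write_fastq(reads, fastq_path)
    return reads


def _apply_snps(seq, block, snp_pos, snp_alt, snp_frac, rng) -> None:
    for p, alt, frac in zip(snp_pos, snp_alt, snp_frac):
        hits = np.nonzero(block == p)[0]
        for h in hits:
            if rng.random() < frac:
                seq[h] = alt


def _apply_errors(seq, rate: float, rng) -> None:
    if rate <= 0:
        return
    mask = np.nonzero(rng.random(len(seq)) < rate)[0]
    for j in mask:
        seq[j] = rng.choice(_OTHER[int(seq[j])])


def _segments(read_id, ref_id, block, seq, strand) -> list[AlignedRead]:
    """Split a (possibly junction- or origin-spanning) read into M-only
    per-segment placements in plus-strand orientation."""
    breaks = np.nonzero(np.diff(block) != 1)[0] + 1
    pieces = np.split(np.arange(len(block)), breaks)
    out = []
    for i, piece in enumerate(pieces):
        sub = seq[piece]
        rid = read_id if len(pieces) == 1 else f"{read_id}/seg{i}"
        out.append(
            AlignedRead(
                rid, ref_id, int(block[piece[0]]) + 1, strand,
                sub.tobytes().decode(),
            )
        )
    return out


def write_fastq(reads: list[AlignedRead], path: str, qual: str = "?") -> None:
    """Phred-33 FASTQ with constant Q30 quality; minus-strand reads are
    reverse-complemented back to read orientation."""
    with open(path, "w") as fh:
        for r in reads:
            seq = revcomp(r.seq) if r.strand_of_alignment == "-" else r.seq
            fh.write(f"@{r.read_id}\n{seq}\n+\n{qual * len(seq)}\n")


# ---------------------------------------------------------------------------
# Printed-table fixture


@dataclass(frozen=True)
class Table1Row:
    """One printed editing-site row, with the consequence re-derived by
    translation rather than read from the amino-acid column."""

    gene: str
    genome_pos: int
    gene_pos: int
    codon_pos: int
    ref_codon: str
    edited_codon: str
    aa_ref: str
    aa_alt: str
    depth: int
    efficiency: float
    consequence: str

    @property
    def codon_index(self) -> int:
        return math.ceil(self.gene_pos / 3)


def table1_fixture() -> list[Table1Row]:
    """The 19 published R. hybrida chloroplast editing sites, verbatim."""
    from importlib.resources import files

    rows = []
    text = (files("plastedit") / "data" / "table1_sites.tsv").read_text()
    lines = text.strip().split("\n")
    for line in lines[1:]:
        (gene, gpos, gene_pos, codon_pos, _etype, cchange, achange,
         depth, eff) = line.split("\t")
        ref_codon, printed_edited = cchange.split("->")
        edited, aa_ref, aa_alt, consequence = apply_edit(
            ref_codon, int(codon_pos)
        )
        edited = edited.replace("T", "U")
        if edited != printed_edited:
            raise ValueError(
                f"printed codon change {cchange} inconsistent with C->U "
                f"edit at position {codon_pos}"
            )
        rows.append(
            Table1Row(
                gene=gene, genome_pos=int(gpos), gene_pos=int(gene_pos),
                codon_pos=int(codon_pos), ref_codon=ref_codon,
                edited_codon=edited, aa_ref=aa_ref, aa_alt=aa_alt,
                depth=int(depth), efficiency=float(eff) / 100.0,
                consequence=consequence,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# Mitochondrial background with planted transfers


def build_mito_with_insert(
    plastome: SeqRecord,
    insert_intervals: list[tuple[int, int]],
    identity: float,
    seed: int,
    orientations: list[str] | None = None,
    length_factor: float = 2.0,
) -> tuple[SeqRecord, list[dict]]:
    """Plant plastome fragments in a random mitochondrial background.

    The background is ``length_factor`` times the plastome length (the
    mitogenome is roughly twice the plastome in the system modelled);
    fragments are copied at the given identity with uniform mutations.
    Returns the mito record and a ground-truth list of placements with
    realized identities.
    """
    if not 0.75 <= identity <= 1.0:
        raise ValueError("identity must be in [0.75, 1.0]")
    iv = sorted(insert_intervals)
    for (s1, e1), (s2, e2) in zip(iv, iv[1:]):
        if s2 <= e1:
            raise ValueError("overlapping insert intervals")
    for s, e in iv:
        if s < 1 or e > len(plastome.seq) or s > e:
            raise ValueError(f"interval {s}-{e} outside plastome")
    rng = np.random.default_rng(seed)
    mlen = int(length_factor * len(plastome.seq))
    mito = list("ACGT"[i] for i in rng.integers(0, 4, size=mlen))
    n = len(insert_intervals)
    orientations = orientations or ["same"] * n
    slot = mlen // (n + 1) if n else mlen
    truth = []
    for i, ((s, e), orient) in enumerate(zip(insert_intervals, orientations)):
        frag = list(plastome.seq[s - 1 : e])
        muts = np.nonzero(rng.random(len(frag)) < (1.0 - identity))[0]
        for j in muts:
            frag[j] = "ACGT"[
                rng.choice([k for k in range(4) if "ACGT"[k] != frag[j]])
            ]
        realized = 1.0 - len(muts) / len(frag)
        if orient == "inverted":
            frag = list(revcomp("".join(frag)))
        mstart = (i + 1) * slot - len(frag) // 2
        mito[mstart : mstart + len(frag)] = frag
        truth.append(
            dict(
                cp_interval=(s, e),
                mt_interval=(mstart + 1, mstart + len(frag)),
                identity=realized,
                orientation=orient,
            )
        )
    return SeqRecord("synthetic_mito", "".join(mito), circular=True), truth
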