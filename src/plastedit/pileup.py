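"""Read placement and per-position, per-strand base counting.

The exact seed placer replaces a spliced aligner for the synthetic path:
reads are placed at the unique genome position where a k-mer seed from the
read start matches (either orientation) and the full ungapped alignment has
at most 10% mismatches. Reads with zero or several candidate placements are
dropped and counted — inverted-repeat reads are therefore legitimately
dropped as multi-mappers.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .io_formats import AlignedRead, SeqRecord, revcomp

BASES = "ACGTN"


@dataclass
class PileupColumn:
    """Per-strand base counts for one sample class at one position."""

    pos: int
    ref: str
    counts: dict = field(
        default_factory=lambda: {"+": Counter(), "-": Counter()}
    )

    def depth(self) -> int:
        """Coverage over both strands, excluding N bases."""
        return sum(
            self.counts[st][b] for st in "+-" for b in "ACGT"
        )

    def base_count(self, base: str) -> int:
        return self.counts["+"][base] + self.counts["-"][base]


@dataclass
class Pileup:
    """Sparse pileup: only covered positions are present."""

    ref_id: str
    sample: str  # RNA | DNA
    columns: dict[int, PileupColumn] = field(default_factory=dict)

    def positions(self) -> list[int]:
        return sorted(self.columns)

    def get(self, pos: int) -> PileupColumn | None:
        return self.columns.get(pos)


def place_reads_exact(
    reads: list[SeqRecord], genome: SeqRecord, k: int = 25,
    max_mismatch_frac: float = 0.10,
) -> tuple[list[AlignedRead], dict[str, int]]:
    """Place reads by unique exact k-mer seed + full ungapped check.

    Returns ``(placements, counters)``; counters report ``unplaced`` (no
    candidate) and ``multimapped`` (several candidates, e.g. IR reads).
    """
    if k < 15:
        raise ValueError("seed length k must be >= 15")
    g = genome.seq
    L = len(g)
    search = g + g[: k - 1] if genome.circular else g
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(search) - k + 1):
        if i < L:
            index[search[i : i + k]].append(i)
    counters = {"unplaced": 0, "multimapped": 0, "placed": 0}
    placements: list[AlignedRead] = []
    for read in reads:
        seq = read.seq
        if len(seq) < k:
            counters["unplaced"] += 1
            continue
        candidates = []
        # forward: seed from read start
        for i in index.get(seq[:k], []):
            if _ungapped_ok(seq, g, i, genome.circular, max_mismatch_frac):
                candidates.append((i, "+"))
        # reverse: the read aligns as its revcomp; seed from rc start
        rc = revcomp(seq)
        for i in index.get(rc[:k], []):
            if _ungapped_ok(rc, g, i, genome.circular, max_mismatch_frac):
                candidates.append((i, "-"))
        if not candidates:
            counters["unplaced"] += 1
        elif len(candidates) > 1:
            counters["multimapped"] += 1
        else:
            i, strand = candidates[0]
            aligned = seq if strand == "+" else rc
            counters["placed"] += 1
            placements.extend(
                _split_wrap(read.id, genome, i + 1, strand, aligned)
            )
    return placements, counters


def _ungapped_ok(
    seq: str, g: str, start0: int, circular: bool, max_mm: float
) -> bool:
    L = len(g)
    if start0 + len(seq) > L:
        if not circular:
            return False
        ref = (g + g)[start0 : start0 + len(seq)]
    else:
        ref = g[start0 : start0 + len(seq)]
    mm = sum(a != b for a, b in zip(seq, ref))
    return mm <= max_mm * len(seq)


def _split_wrap(
    read_id: str, genome: SeqRecord, pos: int, strand: str, aligned_seq: str
) -> list[AlignedRead]:
    """Split a placement spanning the circular origin into two segments."""
    L = len(genome.seq)
    end = pos + len(aligned_seq) - 1
    if end <= L:
        return [AlignedRead(read_id, genome.id, pos, strand, aligned_seq)]
    if not genome.circular:
        raise ValueError(
            f"read {read_id} extends past the end of linear genome"
        )
    head = L - pos + 1
    return [
        AlignedRead(read_id, genome.id, pos, strand, aligned_seq[:head]),
        AlignedRead(
            f"{read_id}/wrap", genome.id, 1, strand, aligned_seq[head:]
        ),
    ]


def build_pileup(
    placements: list[AlignedRead], genome: SeqRecord, sample: str
) -> Pileup:
    """Reduce placements to per-position, per-strand base counts.

    Every M-op base increments exactly one counter; soft-clipped bases are
    ignored; N bases are counted under N but excluded from the depth used
    for efficiency.
    """
    pile = Pileup(ref_id=genome.id, sample=sample)
    L = len(genome.seq)
    cols = pile.columns
    for read in placements:
        if read.ref_id != genome.id:
            raise ValueError(
                f"read {read.read_id} aligned to {read.ref_id}, "
                f"not {genome.id}"
            )
        pos = read.pos
        ri = 0
        for n, op in read.match_ops:
            if op == "S":
                ri += n
                continue
            for j in range(n):
                p = pos + j
                if p > L:
                    if not genome.circular:
                        raise ValueError(
                            f"read {read.read_id} extends past end of "
                            f"linear genome {genome.id}"
                        )
                    p = (p - 1) % L + 1
                col = cols.get(p)
                if col is None:
                    col = cols[p] = PileupColumn(p, genome.seq[p - 1])
                col.counts[read.strand_of_alignment][read.seq[ri + j]] += 1
            pos += n
            ri += n
    return pile


def write_mpileup_tsv(pile: Pileup, path: str) -> None:
    """Emit a samtools-mpileup-like TSV for inspection."""
    from .io_formats import _atomic_open

    with _atomic_open(path) as fh:
        fh.write("ref\tpos\tref_base\tdepth\t" +
                 "\t".join(f"{st}{b}" for st in "+-" for b in BASES) + "\n")
        for pos in pile.positions():
            col = pile.columns[pos]
            row = [pile.ref_id, str(pos), col.ref, str(col.depth())]
            row += [str(col.counts[st][b]) for st in "+-" for b in BASES]
            fh.write("\t".join(row) + "\n")
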