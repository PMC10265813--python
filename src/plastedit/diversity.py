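"""Sliding-window nucleotide diversity and alignment site classes.

Nucleotide diversity pi is the mean over all sequence pairs of
(pairwise differences / pairwise comparable sites), with pairwise deletion
of gap/N columns. Windows follow the classic 600-bp/200-step scheme by
default; divergence hotspots are maximal runs of windows above a pi
threshold (default 0.013).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .io_formats import FormatError

_STATES = "ACGT"


@dataclass
class Alignment:
    """A gapped multiple sequence alignment over {A,C,G,T,N,-}."""

    names: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.rows) < 2:
            raise ValueError("alignment needs >= 2 rows")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows must have equal length")
        self.rows = [r.upper() for r in self.rows]

    def __len__(self) -> int:
        return len(self.rows[0])

    @property
    def matrix(self) -> np.ndarray:
        m = getattr(self, "_matrix", None)
        if m is None:
            m = np.array(
                [np.frombuffer(r.encode(), dtype=np.uint8) for r in self.rows]
            )
            object.__setattr__(self, "_matrix", m)
        return m


def read_alignment(path: str) -> Alignment:
    """Read a multi-FASTA alignment."""
    from Bio import SeqIO

    names, rows = [], []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            names.append(rec.id)
            rows.append(str(rec.seq).upper())
    if len(rows) < 2:
        raise FormatError(f"{path}: alignment needs >= 2 sequences")
    return Alignment(names, rows)


@dataclass
class WindowStat:
    start: int  # 1-based alignment coordinates
    end: int
    pi: float | None  # None when no comparable sites
    n_sites: int  # ungapped comparable positions actually used


def nucleotide_diversity(aln: Alignment, cols: slice | None = None):
    """Average pairwise p-distance with pairwise deletion.

    Returns ``(pi, n_sites)``; pi is None (missing, not zero) when no pair
    has comparable sites. ``n_sites`` is the maximum number of comparable
    sites over pairs within the selected columns.
    """
    m = aln.matrix
    if cols is not None:
        m = m[:, cols]
    good = np.isin(m, np.frombuffer(b"ACGT", dtype=np.uint8))
    pis = []
    n_used = 0
    for i, j in combinations(range(m.shape[0]), 2):
        ok = good[i] & good[j]
        n = int(ok.sum())
        if n == 0:
            continue
        diffs = int((m[i][ok] != m[j][ok]).sum())
        pis.append(diffs / n)
        n_used = max(n_used, n)
    if not pis:
        return None, 0
    return float(np.mean(pis)), n_used


def sliding_pi(
    aln: Alignment, window: int = 600, step: int = 200
) -> list[WindowStat]:
    """Sliding-window pi over alignment coordinates.

    Windows start at 1, 1+step, ...; a final truncated window is appended
    when the last full window does not reach the alignment end. A window
    longer than the alignment collapses to a single whole-alignment window.
    """
    if not 1 <= step <= window:
        raise ValueError("need window >= step >= 1")
    L = len(aln)
    if window > L:
        pi, n = nucleotide_diversity(aln)
        return [WindowStat(1, L, pi, n)]
    out = []
    start = 1
    while start + window - 1 <= L:
        pi, n = nucleotide_diversity(aln, slice(start - 1, start + window - 1))
        out.append(WindowStat(start, start + window - 1, pi, n))
        start += step
    if out[-1].end < L:
        pi, n = nucleotide_diversity(aln, slice(start - 1, L))
        out.append(WindowStat(start, L, pi, n))
    return out


def site_classes(aln: Alignment) -> dict:
    """Count variable and parsimony-informative columns.

    A column is variable iff it has >= 2 distinct non-gap, non-N states;
    parsimony-informative iff >= 2 distinct states each occur in >= 2
    sequences. Fractions are over all alignment columns.
    """
    m = aln.matrix
    L = m.shape[1]
    n_var = n_pi = 0
    counts = np.zeros((4, L), dtype=np.int32)
    for bi, b in enumerate(_STATES):
        counts[bi] = (m == ord(b)).sum(axis=0)
    n_states = (counts > 0).sum(axis=0)
    n_var = int((n_states >= 2).sum())
    n_pi = int(((counts >= 2).sum(axis=0) >= 2).sum())
    return {
        "n_variable": n_var,
        "n_parsimony_informative": n_pi,
        "variable_fraction_pct": round(100.0 * n_var / L, 2),
        "parsimony_informative_fraction_pct": round(100.0 * n_pi / L, 2),
        "n_columns": L,
    }


def call_hotspots(
    windows: list[WindowStat],
    threshold: float = 0.013,
) -> list[tuple[int, int]]:
    """Merge overlapping windows with pi > threshold into intervals."""
    qual = [
        (w.start, w.end) for w in windows
        if w.pi is not None and w.pi > threshold
    ]
    merged: list[list[int]] = []
    for s, e in sorted(qual):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(iv) for iv in merged]


def write_windows_tsv(windows: list[WindowStat], path: str) -> None:
    from .io_formats import _atomic_open

    with _atomic_open(path) as fh:
        fh.write("start\tend\tpi\tn_sites\n")
        for w in windows:
            pi = "NA" if w.pi is None else f"{w.pi:.6f}"
            fh.write(f"{w.start}\t{w.end}\t{pi}\t{w.n_sites}\n")


def write_hotspots_bed(
    hotspots: list[tuple[int, int]], name: str, path: str
) -> None:
    """BED (0-based half-open — the only 0-based surface, flagged here)."""
    from .io_formats import _atomic_open

    with _atomic_open(path) as fh:
        fh.write("# BED: 0-based half-open intervals\n")
        for s, e in hotspots:
            fh.write(f"{name}\t{s - 1}\t{e}\thotspot\n")
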