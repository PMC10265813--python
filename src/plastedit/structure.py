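"""Quadripartite plastome architecture and plastid-to-mito transfers.

IR detection anchors exact 25-mers between the genome and its reverse
complement on the doubled (circular) sequence, de-duplicates anchors by
anti-diagonal, and extends greedily; transfer detection is an ungapped
seed-and-extend (k = 21, both orientations) that keeps extending while the
running identity stays at or above the threshold.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .io_formats import COMPLEMENT, SeqRecord, revcomp


@dataclass
class QuadripartiteMap:
    """LSC/IRb/SSC/IRa intervals (1-based inclusive; start > end wraps the
    origin) plus the genes found at each junction."""

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    junction_genes: dict[str, list[str]] = field(default_factory=dict)
    genome_len: int = 0

    def region_length(self, region: str) -> int:
        s, e = getattr(self, region)
        if e >= s:
            return e - s + 1
        return self.genome_len - s + 1 + e  # wrapped

    def lengths(self) -> dict[str, int]:
        return {r: self.region_length(r) for r in ("lsc", "irb", "ssc", "ira")}


@dataclass
class TransferFragment:
    """A homologous plastome fragment found in the mitogenome."""

    cp_interval: tuple[int, int]
    mt_interval: tuple[int, int]
    identity: float
    length: int
    orientation: str  # same | inverted


class NoQuadripartiteError(ValueError):
    pass


def detect_quadripartite(
    genome: SeqRecord,
    min_ir: int = 1000,
    k: int = 25,
    genes: list | None = None,
) -> QuadripartiteMap:
    """Locate the IR pair and derive the LSC/SSC arcs.

    Finds the longest pair of disjoint intervals whose sequences are exact
    reverse complements (k-mer anchoring, maximal extension); the longer
    inter-IR arc is the LSC, the shorter the SSC. Works on the doubled
    sequence so the result is invariant to rotation of the circular input.
    """
    g = genome.seq
    L = len(g)
    D = g + g if genome.circular else g
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(D) - k + 1):
        index[D[i : i + k]].append(i)
    comp = COMPLEMENT
    # per anti-diagonal, the extents already explored (the same physical IR
    # pair can surface twice in doubled coordinates, once truncated at the
    # array edge, so a bare diagonal-level dedupe would lose the full copy)
    seen: dict[int, list[tuple[int, int]]] = defaultdict(list)
    best: tuple[int, int, int] | None = None  # (length, p_lo, c)
    for i in range(L):
        kmer = D[i : i + k]
        for j in index.get(revcomp(kmer), []):
            # D[i:i+k] == revcomp(D[j:j+k]); pairing p <-> c - p
            if j <= i:
                continue  # canonical orientation: first interval on the left
            c = i + j + k - 1
            if any(lo <= i <= hi for lo, hi in seen[c]):
                continue
            lo, hi = i, i + k - 1
            # positions pair as (p, c-p); intervals [lo,hi] and [c-hi,c-lo]
            while (
                lo > 0
                and c - (lo - 1) < len(D)
                and hi < c - hi - 2  # keep intervals disjoint
                and D[lo - 1] == D[c - lo + 1].translate(comp)
            ):
                lo -= 1
            while (
                hi + 1 < len(D)
                and c - (hi + 1) >= 0
                and hi + 1 < c - hi - 1
                and D[hi + 1] == D[c - hi - 1].translate(comp)
            ):
                hi += 1
            seen[c].append((lo, hi))
            length = hi - lo + 1
            if length > L // 2:
                length = L // 2
                hi = lo + length - 1
            if length < min_ir:
                continue
            if _circ_overlap((lo % L, hi % L), ((c - hi) % L, (c - lo) % L), L):
                continue  # palindromic self-pairing, not an IR pair
            if best is None or length > best[0]:
                best = (length, lo, c)
    if best is None:
        raise NoQuadripartiteError(
            f"no inverted repeat of length >= {min_ir} found"
        )
    length, lo, c = best
    a_start, a_end = lo, lo + length - 1           # first IR (doubled coords)
    b_start, b_end = c - a_end, c - a_start        # partner IR
    ir1 = (a_start % L, a_end % L)
    ir2 = (b_start % L, b_end % L)
    # order the two IRs by start along the circle from origin
    if ir1[0] > ir2[0]:
        ir1, ir2 = ir2, ir1
    # the two arcs between IRs (circular)
    arc1 = ((ir1[1] + 1) % L, (ir2[0] - 1) % L)    # between ir1 end, ir2 start
    arc2 = ((ir2[1] + 1) % L, (ir1[0] - 1) % L)    # wraps the origin or not
    len1 = _arc_len(arc1, L)
    len2 = _arc_len(arc2, L)
    if len1 >= len2:
        lsc, ssc, irb, ira = arc1, arc2, ir2, ir1
        # LSC precedes IRb in circular order: arc1 runs ir1->ir2, so the IR
        # following the LSC is ir2 (IRb) and ir1 is IRa.
    else:
        lsc, ssc, irb, ira = arc2, arc1, ir1, ir2
    qmap = QuadripartiteMap(
        lsc=_to1(lsc), irb=_to1(irb), ssc=_to1(ssc), ira=_to1(ira),
        genome_len=L,
    )
    if genes is not None:
        qmap.junction_genes = junction_report(qmap, genes)
    return qmap


def _circ_overlap(a: tuple[int, int], b: tuple[int, int], L: int) -> bool:
    """Do two circular 0-based intervals (start may exceed end) overlap?"""

    def arcs(iv):
        s, e = iv
        return [(s, e)] if s <= e else [(s, L - 1), (0, e)]

    return any(
        s1 <= e2 and s2 <= e1
        for s1, e1 in arcs(a)
        for s2, e2 in arcs(b)
    )


def _arc_len(arc: tuple[int, int], L: int) -> int:
    s, e = arc
    return (e - s) % L + 1


def _to1(iv0: tuple[int, int]) -> tuple[int, int]:
    return (iv0[0] + 1, iv0[1] + 1)


def junction_report(qmap: QuadripartiteMap, genes) -> dict[str, list[str]]:
    """Genes whose exon span contains a region boundary.

    A gene sits at a junction iff its span covers the last base of the
    upstream region and the first base of the downstream region.
    """
    L = qmap.genome_len or max(e for _, e in
                               (qmap.lsc, qmap.irb, qmap.ssc, qmap.ira))
    junctions = {
        "LSC/IRb": (qmap.lsc[1], qmap.irb[0]),
        "IRb/SSC": (qmap.irb[1], qmap.ssc[0]),
        "SSC/IRa": (qmap.ssc[1], qmap.ira[0]),
        "IRa/LSC": (qmap.ira[1], qmap.lsc[0]),
    }
    out: dict[str, list[str]] = {j: [] for j in junctions}
    for g in genes:
        s, e = g.span
        for jname, (up, down) in junctions.items():
            if _span_contains(s, e, up, L) and _span_contains(s, e, down, L):
                out[jname].append(g.gene)
    return out


def _span_contains(s: int, e: int, pos: int, L: int) -> bool:
    if s <= e:
        return s <= pos <= e
    return pos >= s or pos <= e  # wrapped span


# ---------------------------------------------------------------------------
# cp -> mt transfer detection


def find_transfers(
    cp: SeqRecord,
    mt: SeqRecord,
    min_identity: float = 0.90,
    min_length: int = 100,
    k: int = 21,
) -> list[TransferFragment]:
    """Find plastome fragments in the mitogenome by ungapped seed-extend.

    Exact k-mer anchors (both orientations) are extended ungapped in both
    directions with X-drop scoring (+1 match, -2 mismatch, drop 20) and
    trimmed to the best-scoring extent; hits sharing a diagonal and
    orientation whose intervals overlap are merged with identity recomputed
    over the merged span, and fragments shorter than ``min_length`` or
    below ``min_identity`` over the merged span are discarded.
    """
    cpseq, mtseq = cp.seq, mt.seq
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(cpseq) - k + 1):
        index[cpseq[i : i + k]].append(i)
    # hits keyed by (diag, orientation): list of (cp_lo, cp_hi, mt_lo, mt_hi)
    raw: dict[tuple[int, str], list[tuple[int, int, int, int]]] = defaultdict(list)
    comp = COMPLEMENT
    for m in range(len(mtseq) - k + 1):
        kmer = mtseq[m : m + k]
        for c in index.get(kmer, []):
            diag = c - m
            if _claimed(raw[(diag, "same")], m):
                continue
            lo, hi = _extend(
                lambda p: cpseq[p + diag] == mtseq[p],
                m, m + k - 1, 0, len(mtseq) - 1,
                lambda p: 0 <= p + diag < len(cpseq),
            )
            raw[(diag, "same")].append((lo + diag, hi + diag, lo, hi))
        for c in index.get(revcomp(kmer), []):
            # cpseq[c:c+k] == revcomp(mtseq[m:m+k]): cp pos pairs with
            # mt pos as cp = anti - mt, anti = c + m + k - 1
            anti = c + m + k - 1
            if _claimed(raw[(anti, "inverted")], m):
                continue
            lo, hi = _extend(
                lambda p: cpseq[anti - p] == mtseq[p].translate(comp),
                m, m + k - 1, 0, len(mtseq) - 1,
                lambda p: 0 <= anti - p < len(cpseq),
            )
            raw[(anti, "inverted")].append((anti - hi, anti - lo, lo, hi))
    frags: list[TransferFragment] = []
    for (key, orient), hits in (
        ((d, o), raw[(d, o)]) for (d, o) in list(raw)
    ):
        for cplo, cphi, mtlo, mthi in _merge(hits):
            length = mthi - mtlo + 1
            if length < min_length:
                continue
            ident = _identity(cpseq, mtseq, key, orient, mtlo, mthi)
            if ident < min_identity:
                continue
            frags.append(
                TransferFragment(
                    cp_interval=(cplo + 1, cphi + 1),
                    mt_interval=(mtlo + 1, mthi + 1),
                    identity=ident,
                    length=length,
                    orientation=orient,
                )
            )
    frags.sort(key=lambda f: (f.cp_interval, f.mt_interval))
    return frags


def _claimed(hits, m) -> bool:
    return any(lo <= m and m + 20 <= hi for _, _, lo, hi in hits)


def _extend(match, lo, hi, lim_lo, lim_hi, in_range,
            mismatch_penalty: int = 2, xdrop: int = 20):
    """Ungapped bidirectional X-drop extension from an exact seed.

    Scores +1 per match and -``mismatch_penalty`` per mismatch, stops a
    direction once the score falls ``xdrop`` below its running maximum,
    and returns the extent trimmed to the best-scoring endpoints (so the
    hit never drifts into unrelated sequence).
    """
    best_lo, best_hi = lo, hi
    score = best_score = 0
    p = hi + 1
    while p <= lim_hi and in_range(p):
        score += 1 if match(p) else -mismatch_penalty
        if score > best_score:
            best_score, best_hi = score, p
        elif score <= best_score - xdrop:
            break
        p += 1
    score = best_score = 0
    p = lo - 1
    while p >= lim_lo and in_range(p):
        score += 1 if match(p) else -mismatch_penalty
        if score > best_score:
            best_score, best_lo = score, p
        elif score <= best_score - xdrop:
            break
        p -= 1
    return best_lo, best_hi


def _merge(hits):
    """Merge hits (same diagonal/orientation) whose mt intervals overlap."""
    hits = sorted(hits, key=lambda h: h[2])
    merged = []
    for h in hits:
        if merged and h[2] <= merged[-1][3] + 1:
            last = merged[-1]
            merged[-1] = (
                min(last[0], h[0]), max(last[1], h[1]),
                min(last[2], h[2]), max(last[3], h[3]),
            )
        else:
            merged.append(h)
    return merged


def _identity(cpseq, mtseq, key, orient, mtlo, mthi) -> float:
    comp = COMPLEMENT
    n = mthi - mtlo + 1
    if orient == "same":
        diag = key
        m = sum(
            1 for p in range(mtlo, mthi + 1) if cpseq[p + diag] == mtseq[p]
        )
    else:
        anti = key
        m = sum(
            1 for p in range(mtlo, mthi + 1)
            if cpseq[anti - p] == mtseq[p].translate(comp)
        )
    return m / n


def transfer_summary(
    frags: list[TransferFragment], cp_len: int
) -> dict:
    """Fragment count, union of cp coverage in bp, and percent of genome."""
    iv = sorted(f.cp_interval for f in frags)
    covered = 0
    cur_s = cur_e = None
    for s, e in iv:
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s + 1
    return {
        "n_fragments": len(frags),
        "total_cp_bp": covered,
        "percent_of_cp": 100.0 * covered / cp_len if cp_len else 0.0,
    }
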