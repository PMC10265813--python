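from collections import Counter

import numpy as np
import pytest

from plastedit.editing import (
    CallerParams, call_sites, extract_candidates, subtract_genomic, summarize,
)
from plastedit.pileup import Pileup, PileupColumn, build_pileup
from plastedit.synthetic_data import (
    PlannedSnp, SimConfig, build_plastome, plan_edits, plan_snps,
    simulate_reads,
)


def _column(genome, pos, plus_counts, minus_counts=None):
    col = PileupColumn(pos, genome.seq[pos - 1])
    col.counts["+"] = Counter(plus_counts)
    col.counts["-"] = Counter(minus_counts or {})
    return col


def _pileup(genome, sample, cols):
    pile = Pileup(ref_id=genome.id, sample=sample)
    for c in cols:
        pile.columns[c.pos] = c
    return pile


def _pos_with_coding_base(genome, genes, gene_name, base):
    g = next(x for x in genes if x.gene == gene_name)
    want = base if g.strand == "+" else {"C": "G", "G": "C"}[base]
    for s, e in g.exons:
        for pos in range(s + 40, e - 40):
            if genome.seq[pos - 1] == want:
                return pos, g
    raise AssertionError("no such base")


class TestExtractCandidates:
    def test_plus_strand_c_to_t(self, default_plastome):
        _, genome, genes, _ = default_plastome
        pos, _ = _pos_with_coding_base(genome, genes, "atpA", "C")
        rna = _pileup(genome, "RNA", [_column(genome, pos, {"T": 46, "C": 4})])
        (cand,) = extract_candidates(rna, genome, genes, CallerParams())
        assert cand.pos == pos and cand.depth == 50 and cand.edited == 46
        assert cand.efficiency == pytest.approx(0.92)

    def test_minus_strand_gene_reads_g_to_a(self, default_plastome):
        _, genome, genes, _ = default_plastome
        pos, g = _pos_with_coding_base(genome, genes, "psbA", "C")
        assert genome.seq[pos - 1] == "G"  # plus-strand image of coding C
        rna = _pileup(genome, "RNA", [_column(genome, pos, {"A": 10})])
        (cand,) = extract_candidates(rna, genome, genes, CallerParams())
        assert cand.strand == "-" and cand.efficiency == 1.0

    def test_min_edited_reads_threshold(self, default_plastome):
        _, genome, genes, _ = default_plastome
        pos, _ = _pos_with_coding_base(genome, genes, "atpA", "C")
        rna = _pileup(genome, "RNA", [_column(genome, pos, {"T": 1, "C": 49})])
        assert extract_candidates(rna, genome, genes, CallerParams()) == []

    def test_non_c_reference_not_candidate(self, default_plastome):
        _, genome, genes, _ = default_plastome
        pos, _ = _pos_with_coding_base(genome, genes, "atpA", "A")
        rna = _pileup(genome, "RNA", [_column(genome, pos, {"T": 20, "A": 30})])
        assert extract_candidates(rna, genome, genes, CallerParams()) == []


class TestSubtractGenomic:
    def _candidate(self, genome, genes):
        pos, _ = _pos_with_coding_base(genome, genes, "atpA", "C")
        rna = _pileup(genome, "RNA", [_column(genome, pos, {"T": 46, "C": 4})])
        (cand,) = extract_candidates(rna, genome, genes, CallerParams())
        return cand

    def test_clean_dna_keeps_candidate(self, default_plastome):
        _, genome, genes, _ = default_plastome
        c = self._candidate(genome, genes)
        dna = _pileup(genome, "DNA", [_column(genome, c.pos, {"C": 30})])
        assert subtract_genomic([c], dna, CallerParams()) == [c]

    def test_heterozygous_dna_removes_candidate(self, default_plastome):
        _, genome, genes, _ = default_plastome
        c = self._candidate(genome, genes)
        dna = _pileup(genome, "DNA",
                      [_column(genome, c.pos, {"C": 15, "T": 15})])
        assert subtract_genomic([c], dna, CallerParams()) == []

    def test_zero_dna_depth_removed_unless_keep_unverified(
        self, default_plastome
    ):
        _, genome, genes, _ = default_plastome
        c = self._candidate(genome, genes)
        empty = _pileup(genome, "DNA", [])
        assert subtract_genomic([c], empty, CallerParams()) == []
        keep = CallerParams(keep_unverified=True)
        assert subtract_genomic([c], empty, keep) == [c]


def _simulate(seed, n_edits=12, n_snps=3):
    cfg = SimConfig(seed=seed, seq_error=0.0)
    genome, genes, _ = build_plastome(cfg)
    rng = np.random.default_rng((seed, 99))
    cfg.sites = plan_edits(genome, genes, n_edits, rng)
    cfg.snps = plan_snps(
        genome, genes, n_snps, rng,
        exclude={s.genome_pos for s in cfg.sites},
    )
    rna = build_pileup(simulate_reads(genome, genes, cfg, "RNA"), genome, "RNA")
    dna = build_pileup(simulate_reads(genome, genes, cfg, "DNA"), genome, "DNA")
    return cfg, genome, genes, rna, dna


class TestCallSites:
    def test_planted_sites_recovered_exactly(self):
        cfg, genome, genes, rna, dna = _simulate(seed=17)
        sites = call_sites(rna, dna, genome, genes)
        assert {s.genome_pos for s in sites} == {
            e.genome_pos for e in cfg.sites
        }
        assert {s.genome_pos for s in sites}.isdisjoint(
            {s.genome_pos for s in cfg.snps}
        )

    def test_no_planned_edits_no_calls(self):
        cfg, genome, genes, rna, dna = _simulate(seed=19, n_edits=0, n_snps=0)
        assert call_sites(rna, dna, genome, genes) == []

    def test_snp_colocated_with_candidate_is_excluded(self):
        """A homozygous genomic variant at a coding C shows up in RNA too,
        and must be removed by the DNA subtraction."""
        cfg, genome, genes, rna, dna = _simulate(seed=23, n_edits=0, n_snps=3)
        without_dna = call_sites(
            rna, _pileup(genome, "DNA", []), genome, genes,
            CallerParams(keep_unverified=True),
        )
        assert {s.genome_pos for s in without_dna} == {
            s.genome_pos for s in cfg.snps
        }
        assert call_sites(rna, dna, genome, genes) == []

    def test_output_sorted_and_annotated(self):
        cfg, genome, genes, rna, dna = _simulate(seed=29)
        sites = call_sites(rna, dna, genome, genes)
        pos = [s.genome_pos for s in sites]
        assert pos == sorted(pos)
        for s in sites:
            assert s.ref_codon[s.codon_pos - 1] == "C"
            assert s.edited_codon[s.codon_pos - 1] == "T"
            assert s.codon_index == (s.gene_pos + 2) // 3

    def test_matches_brute_force_recount(self):
        """Depth/edited of every call equal an independent per-position
        recount straight from the truth placements."""
        cfg, genome, genes, rna, dna = _simulate(seed=31)
        reads = simulate_reads(genome, genes, cfg, "RNA")
        sites = call_sites(rna, dna, genome, genes)
        strand_of = {g.gene: g.strand for g in genes}
        for s in sites:
            counts = Counter()
            for r in reads:
                if r.pos <= s.genome_pos < r.pos + len(r.seq):
                    counts[r.seq[s.genome_pos - r.pos]] += 1
            alt = "T" if strand_of[s.gene] == "+" else "A"
            assert s.depth == sum(counts[b] for b in "ACGT")
            assert s.edited == counts[alt]
            assert s.efficiency == pytest.approx(counts[alt] / s.depth)

    def test_threshold_monotonicity(self):
        """Raising any caller threshold never adds a site."""
        cfg, genome, genes, rna, dna = _simulate(seed=37)
        base = {
            s.genome_pos
            for s in call_sites(rna, dna, genome, genes, CallerParams())
        }
        stricter = [
            CallerParams(min_rna_depth=30),
            CallerParams(min_edited_reads=10),
            CallerParams(min_efficiency=0.5),
            CallerParams(max_dna_alt_fraction=0.0),
        ]
        for params in stricter:
            got = {
                s.genome_pos
                for s in call_sites(rna, dna, genome, genes, params)
            }
            assert got <= base


class TestSummarize:
    def test_empty_input_all_zero(self):
        s = summarize([])
        assert s["n_sites"] == 0 and s["efficiency_mean_pct"] == 0.0

    def test_single_site_min_mean_max_coincide(self):
        from plastedit.synthetic_data import table1_fixture

        row = table1_fixture()[1]  # rps14, 92.00%
        s = summarize([row])
        assert (
            s["efficiency_min_pct"]
            == s["efficiency_mean_pct"]
            == s["efficiency_max_pct"]
            == 92.0
        )
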