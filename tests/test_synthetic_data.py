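import logging

import numpy as np
import pytest

from plastedit.io_formats import revcomp
from plastedit.pileup import build_pileup
from plastedit.synthetic_data import (
    PlannedEdit, PlannedSnp, SimConfig, build_mito_with_insert,
    build_plastome, coding_c_positions, plan_edits, plan_snps,
    simulate_reads, table1_fixture,
)


class TestBuildPlastome:
    def test_region_lengths_and_ir_mirror(self, default_plastome):
        cfg, genome, _, qmap = default_plastome
        assert qmap.lengths() == {
            "lsc": 9000, "irb": 3000, "ssc": 5000, "ira": 3000
        }
        irb = genome.seq[qmap.irb[0] - 1 : qmap.irb[1]]
        ira = genome.seq[qmap.ira[0] - 1 : qmap.ira[1]]
        assert ira == revcomp(irb)

    def test_deterministic_under_seed(self):
        g1, genes1, _ = build_plastome(SimConfig(seed=42))
        g2, genes2, _ = build_plastome(SimConfig(seed=42))
        assert g1.seq == g2.seq
        assert [(g.gene, g.exons) for g in genes1] == [
            (g.gene, g.exons) for g in genes2
        ]

    def test_no_ir_is_an_error(self):
        with pytest.raises(ValueError):
            build_plastome(SimConfig(seed=1, ir_len=0))

    def test_annotation_census(self, default_plastome):
        _, _, genes, _ = default_plastome
        cds = [g for g in genes if g.ftype == "CDS"]
        assert len(cds) >= 8
        assert sum(1 for g in cds if g.strand == "-") >= 2
        n_exons = [len(g.exons) for g in cds]
        assert 2 in n_exons and 3 in n_exons  # one- and two-intron genes
        assert sum(1 for g in genes if g.ftype == "tRNA") >= 2
        assert sum(1 for g in genes if g.ftype == "rRNA") >= 1
        assert all(g.spliced_length % 3 == 0 for g in cds)

    def test_junction_genes_straddle_boundaries(self, default_plastome):
        _, _, genes, qmap = default_plastome
        by_name = {g.gene: g for g in genes}
        for gname, junction in [
            ("rpl2", (qmap.lsc[1], qmap.irb[0])),
            ("ycf1b", (qmap.irb[1], qmap.ssc[0])),
            ("ycf1", (qmap.ssc[1], qmap.ira[0])),
        ]:
            s, e = by_name[gname].span
            assert s <= junction[0] and e >= junction[1]


class TestSimulateReads:
    def test_full_efficiency_edits_every_overlapping_read(
        self, default_plastome
    ):
        cfg, genome, genes, _ = default_plastome
        pos, gname = coding_c_positions(genome, genes)[0]
        cfg = SimConfig(seed=3, seq_error=0.0,
                        sites=[PlannedEdit(pos, 1.0, gname)])
        genome, genes, _ = build_plastome(cfg)
        reads = simulate_reads(genome, genes, cfg, "RNA")
        strand = next(g.strand for g in genes if g.gene == gname)
        edited_base = "T" if strand == "+" else "A"
        n_cover = 0
        for r in reads:
            if r.pos <= pos < r.pos + len(r.seq):
                n_cover += 1
                assert r.seq[pos - r.pos] == edited_base
        assert n_cover > 10

    def test_dna_without_snps_matches_reference(self, default_plastome):
        cfg, genome, genes, _ = default_plastome
        cfg = SimConfig(seed=5, seq_error=0.0, dna_depth=10.0)
        genome, genes, _ = build_plastome(cfg)
        reads = simulate_reads(genome, genes, cfg, "DNA")
        pile = build_pileup(reads, genome, "DNA")
        for pos, col in pile.columns.items():
            assert col.base_count(col.ref) == col.depth()

    def test_snp_appears_at_dna_fraction_one(self, default_plastome):
        cfg, genome, genes, _ = default_plastome
        pos, gname = coding_c_positions(genome, genes)[5]
        strand = next(g.strand for g in genes if g.gene == gname)
        alt = "T" if strand == "+" else "A"
        cfg = SimConfig(seed=5, seq_error=0.0,
                        snps=[PlannedSnp(pos, alt, 1.0)])
        genome, genes, _ = build_plastome(cfg)
        for sample in ("DNA", "RNA"):
            pile = build_pileup(
                simulate_reads(genome, genes, cfg, sample), genome, sample
            )
            col = pile.get(pos)
            assert col is not None and col.base_count(alt) == col.depth()

    def test_rna_coverage_breadth_over_transcripts(self, default_plastome):
        cfg, genome, genes, _ = default_plastome
        reads = simulate_reads(genome, genes, cfg, "RNA")
        pile = build_pileup(reads, genome, "RNA")
        transcript_pos = {
            p for g in genes for s, e in g.exons for p in range(s, e + 1)
        }
        covered = sum(1 for p in transcript_pos if pile.get(p))
        assert covered / len(transcript_pos) >= 0.99

    def test_site_outside_transcripts_warns(self, caplog):
        cfg = SimConfig(seed=7, sites=[PlannedEdit(1, 0.5, "none")])
        genome, genes, _ = build_plastome(cfg)
        with caplog.at_level(logging.WARNING):
            simulate_reads(genome, genes, cfg, "RNA")
        assert any("undetectable" in m for m in caplog.messages)

    def test_deterministic_under_seed(self, default_plastome):
        cfg, genome, genes, _ = default_plastome
        r1 = simulate_reads(genome, genes, cfg, "DNA")
        r2 = simulate_reads(genome, genes, cfg, "DNA")
        assert [(r.read_id, r.pos, r.seq) for r in r1] == [
            (r.read_id, r.pos, r.seq) for r in r2
        ]


class TestPlanners:
    def test_planned_edit_sites_are_coding_c(self, default_plastome):
        _, genome, genes, _ = default_plastome
        rng = np.random.default_rng(0)
        by_name = {g.gene: g for g in genes}
        for e in plan_edits(genome, genes, 12, rng):
            g = by_name[e.expected_gene]
            want = "C" if g.strand == "+" else "G"
            assert genome.seq[e.genome_pos - 1] == want
            assert g.contains(e.genome_pos)

    def test_snps_avoid_excluded_positions(self, default_plastome):
        _, genome, genes, _ = default_plastome
        rng = np.random.default_rng(0)
        edits = plan_edits(genome, genes, 12, rng)
        excl = {e.genome_pos for e in edits}
        snps = plan_snps(genome, genes, 3, rng, exclude=excl)
        assert not excl & {s.genome_pos for s in snps}


class TestSimConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, genome_len=10000, lsc_len=9000, ir_len=3000)
        with pytest.raises(ValueError):
            SimConfig(seed=1, seq_error=0.5)
        with pytest.raises(ValueError):
            SimConfig(seed=1, rna_depth=0)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimConfig(seed=9, sites=[PlannedEdit(100, 0.5, "g")],
                        snps=[PlannedSnp(200, "T", 1.0)])
        p = str(tmp_path / "c.yaml")
        cfg.to_yaml(p)
        assert SimConfig.from_yaml(p) == cfg


class TestTable1Fixture:
    def test_row_and_gene_counts(self):
        rows = table1_fixture()
        assert len(rows) == 19
        assert len({r.gene for r in rows}) == 13

    def test_efficiency_extremes(self):
        rows = table1_fixture()
        effs = [r.efficiency for r in rows]
        assert min(effs) == pytest.approx(0.3889)
        assert max(effs) == 1.0

    def test_consequence_re_derived_matches_printed_aa(self):
        for r in table1_fixture():
            assert (r.aa_ref == r.aa_alt) == (r.consequence == "synonymous")


class TestMitoWithInsert:
    def test_exact_fragment_is_substring(self, default_plastome):
        _, genome, _, _ = default_plastome
        mito, truth = build_mito_with_insert(genome, [(1000, 1499)], 1.0, 7)
        assert genome.seq[999:1499] in mito.seq
        s, e = truth[0]["mt_interval"]
        assert mito.seq[s - 1 : e] == genome.seq[999:1499]

    def test_planted_identity_within_binomial_band(self, default_plastome):
        _, genome, _, _ = default_plastome
        _, truth = build_mito_with_insert(genome, [(2000, 2999)], 0.95, 13)
        assert 0.93 <= truth[0]["identity"] <= 0.97

    def test_overlapping_intervals_rejected(self, default_plastome):
        _, genome, _, _ = default_plastome
        with pytest.raises(ValueError):
            build_mito_with_insert(genome, [(100, 300), (200, 400)], 1.0, 1)

    def test_background_is_twice_plastome(self, default_plastome):
        _, genome, _, _ = default_plastome
        mito, _ = build_mito_with_insert(genome, [], 1.0, 1)
        assert len(mito.seq) == 2 * len(genome.seq)
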