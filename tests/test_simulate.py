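import numpy as np
import pytest

from retpanel import GeneModel, build_targets, panel_stats
from retpanel.segregation import Pedigree, PedMember
from retpanel.simulate import (SimulationConfig, TruthSet, TruthVariant,
                               random_reference, sample_exon_depth,
                               sample_read_lengths, sample_variant_reads,
                               simulate_cohort, read_truth_json, write_truth_json)


class TestReadLengths:
    def test_mean_and_sd_at_defaults(self):
        cfg = SimulationConfig(seed=1)
        rng = np.random.default_rng(1)
        x = sample_read_lengths(100_000, cfg, rng)
        assert abs(x.mean() - 408) <= 1.0
        assert abs(x.std(ddof=1) - 48) <= 1.0

    def test_zero_sd_is_constant(self):
        cfg = SimulationConfig(read_len_sd=0.0)
        assert set(sample_read_lengths(100, cfg)) == {408}

    def test_truncation_respects_minimum(self):
        cfg = SimulationConfig(seed=2, read_len_mean=60, read_len_sd=30, read_len_min=50)
        x = sample_read_lengths(20_000, cfg, np.random.default_rng(2))
        assert x.min() >= 50


class TestExonDepth:
    def test_mean_depth_without_dropout(self):
        cfg = SimulationConfig()
        rng = np.random.default_rng(3)
        d = sample_exon_depth(0.4, cfg, rng, size=10_000)
        assert abs(d.mean() - 17) <= 0.5

    def test_total_dropout_gives_zero(self):
        cfg = SimulationConfig(gc_dropout_factor=0.0)
        rng = np.random.default_rng(4)
        assert sample_exon_depth(0.9, cfg, rng, size=100).max() == 0

    def test_partial_dropout_scales_mean(self):
        cfg = SimulationConfig(gc_dropout_factor=0.2)
        rng = np.random.default_rng(5)
        d = sample_exon_depth(0.75, cfg, rng, size=10_000)
        assert abs(d.mean() - 3.4) <= 0.3


class TestVariantReads:
    def test_het_fraction(self):
        cfg = SimulationConfig()
        rng = np.random.default_rng(6)
        fracs = [sample_variant_reads(47, "het", cfg, rng)[0] / 47
                 for _ in range(100_000)]
        assert abs(np.mean(fracs) - 0.50) <= 0.01

    def test_hom_fraction(self):
        cfg = SimulationConfig()
        rng = np.random.default_rng(7)
        fracs = [sample_variant_reads(30, "hom", cfg, rng)[0] / 30
                 for _ in range(100_000)]
        assert abs(np.mean(fracs) - 0.99) <= 0.005

    def test_zero_depth(self):
        cfg = SimulationConfig()
        assert sample_variant_reads(0, "het", cfg, np.random.default_rng(0)) == (0, 0)


def _trio():
    return Pedigree(members=[
        PedMember("fa", None, None, "M", False),
        PedMember("mo", None, None, "F", True),
        PedMember("ch", "fa", "mo", "F", True)])


@pytest.fixture
def trio_setup(toy_multi_exon_gene, toy_reference):
    gene, panel = toy_multi_exon_gene
    pos = gene.exons[1][0] + 10
    ref_base = toy_reference["chr1"][pos]
    alt = "T" if ref_base != "T" else "A"
    tv = TruthVariant("chr1", pos, ref_base, alt, "SNV", "het", ("mo", "ch"))
    return gene, panel, tv


class TestSimulateCohort:
    def test_coverage_enumerates_panel(self, trio_setup, toy_reference):
        gene, panel, tv = trio_setup
        cfg = SimulationConfig(seed=3)
        sims = simulate_cohort(panel, [gene], toy_reference,
                               TruthSet([tv], _trio(), cfg), cfg)
        total_bp = panel_stats(panel, [gene]).total_target_bp
        for sim in sims.values():
            assert len(sim.coverage) == total_bp
            assert (sim.coverage["unique_depth"] >= 0).all()

    def test_child_het_variant_row(self, trio_setup, toy_reference):
        gene, panel, tv = trio_setup
        cfg = SimulationConfig(seed=3, sub_error_rate=0.0,
                               homopolymer_indel_slope=0.0, mean_exon_depth=30)
        sims = simulate_cohort(panel, [gene], toy_reference,
                               TruthSet([tv], _trio(), cfg), cfg)
        child = sims["ch"].variants
        assert len(child) == 1
        row = child.iloc[0]
        assert row["position"] == tv.position
        frac = row["variant_reads"] / row["total_reads"]
        assert 0.2 <= frac <= 0.8  # 99th-percentile binomial band at depth >= 10
        assert sims["fa"].variants.empty  # non-carrier

    def test_roundtrip_identity_with_zero_error_rates(self, trio_setup, toy_reference):
        gene, panel, tv = trio_setup
        cfg = SimulationConfig(seed=8, sub_error_rate=0.0,
                               homopolymer_indel_slope=0.0, mean_exon_depth=40)
        sims = simulate_cohort(panel, [gene], toy_reference,
                               TruthSet([tv], _trio(), cfg), cfg)
        for sid, sim in sims.items():
            expected = [(tv.contig, tv.position, tv.ref_allele, tv.alt_allele)] \
                if sid in tv.carrier_samples else []
            got = list(sim.variants[["contig", "position", "ref_allele",
                                     "alt_allele"]].itertuples(index=False, name=None))
            assert got == expected

    def test_empty_table_with_no_truth_and_no_errors(self, toy_multi_exon_gene,
                                                     toy_reference):
        gene, panel = toy_multi_exon_gene
        cfg = SimulationConfig(seed=1, sub_error_rate=0.0, homopolymer_indel_slope=0.0)
        sims = simulate_cohort(panel, [gene], toy_reference,
                               TruthSet([], _trio(), cfg), cfg)
        assert all(sim.variants.empty for sim in sims.values())

    def test_truth_variant_outside_panel_rejected(self, toy_multi_exon_gene,
                                                  toy_reference):
        gene, panel = toy_multi_exon_gene
        cfg = SimulationConfig()
        bad = TruthVariant("chr1", 4990, toy_reference["chr1"][4990], "T"
                           if toy_reference["chr1"][4990] != "T" else "A",
                           "SNV", "het", ("ch",))
        with pytest.raises(ValueError, match="outside the panel"):
            simulate_cohort(panel, [gene], toy_reference,
                            TruthSet([bad], _trio(), cfg), cfg)

    def test_multi_exon_deletion_zeroes_exons(self, toy_reference):
        exons = tuple((200 + i * 90, 200 + i * 90 + 60) for i in range(50))
        gene = GeneModel("BIG", "chr1", "+", exons)
        panel = build_targets([gene], flank_bp=10, promoter_bp=0,
                              contig_lengths={"chr1": 5000})
        ped = Pedigree(members=[PedMember(f"s{i}", None, None, "F", i == 0)
                                for i in range(2)])
        tv = TruthVariant("chr1", 0, "", "", "multi_exon_deletion", "het",
                          ("s0",), gene_symbol="BIG", exon_span=(45, 47))
        cfg = SimulationConfig(seed=5, sub_error_rate=0.0, homopolymer_indel_slope=0.0)
        sims = simulate_cohort(panel, [gene], toy_reference,
                               TruthSet([tv], ped, cfg), cfg)
        from retpanel import summarize_exons
        summ = summarize_exons(sims["s0"].coverage, [gene])
        zero = [s.exon_index for s in summ if s.zero_covered]
        assert zero == [45, 46, 47]
        assert sims["s0"].variants.empty  # no variant row for the deletion
        # non-carrier: no zero exons (P(all-zero exon) ~ e^-17 per bp)
        assert not any(s.zero_covered for s in summarize_exons(sims["s1"].coverage, [gene]))

    def test_sample_substreams_independent_of_cohort_order(self, trio_setup,
                                                           toy_reference):
        gene, panel, tv = trio_setup
        cfg = SimulationConfig(seed=12)
        sims = simulate_cohort(panel, [gene], toy_reference,
                               TruthSet([tv], _trio(), cfg), cfg)
        again = simulate_cohort(panel, [gene], toy_reference,
                                TruthSet([tv], _trio(), cfg), cfg)
        for sid in sims:
            assert sims[sid].coverage["unique_depth"].equals(
                again[sid].coverage["unique_depth"])


def test_truth_json_roundtrip(tmp_path, trio_setup):
    gene, panel, tv = trio_setup
    cfg = SimulationConfig(seed=4)
    truth = TruthSet([tv], _trio(), cfg)
    write_truth_json(truth, tmp_path / "truth.json")
    back = read_truth_json(tmp_path / "truth.json")
    assert back.config == cfg
    assert back.variants == [tv]
    assert back.pedigree.genotype("ch", tv.key()) == "het"
    assert back.pedigree.genotype("fa", tv.key()) == "ref"
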