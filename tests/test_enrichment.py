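"""Fold enrichment, chi-squared, t-tests, QTL and cross-population ANOVA."""

import numpy as np
import pandas as pd
import pytest

from svscape import enrichment
from svscape.intervals import IntervalSet
from svscape.model import FeatureTrack, GenomeModel, PopulationMap

from .conftest import make_catalog, make_record
from .oracles import chi2_2x2_bruteforce


@pytest.fixture
def genome():
    return GenomeModel({"1": 1_000_000})


class TestFoldEnrichment:
    def test_fold_formula(self, genome):
        # feature 5% of the genome, 10% of SV bp -> fold 2
        svs = IntervalSet([("1", 1, 100_000)])
        feature = IntervalSet([("1", 1, 10_000), ("1", 500_001, 540_000)])
        res = enrichment.fold_enrichment(svs, feature, genome)
        assert res.fold == pytest.approx(2.0)
        assert res.bp_in_sv == 10_000

    def test_whole_genome_feature_is_identity(self, genome):
        svs = IntervalSet([("1", 1, 100_000)])
        feature = IntervalSet([("1", 1, 1_000_000)])
        res = enrichment.fold_enrichment(svs, feature, genome)
        assert res.fold == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_zero_bp_feature_is_error(self, genome):
        with pytest.raises(ValueError):
            enrichment.fold_enrichment(IntervalSet([("1", 1, 10)]),
                                       IntervalSet([]), genome)

    def test_empty_sv_set_is_error(self, genome):
        with pytest.raises(ValueError):
            enrichment.fold_enrichment(IntervalSet([]),
                                       IntervalSet([("1", 1, 10)]), genome)

    def test_merging_makes_duplicates_irrelevant(self, genome):
        a = IntervalSet([("1", 1, 1000), ("1", 1, 1000), ("1", 500, 1500)])
        b = IntervalSet([("1", 1, 1500)])
        feature = IntervalSet([("1", 1, 50_000)])
        ra = enrichment.fold_enrichment(a, feature, genome)
        rb = enrichment.fold_enrichment(b, feature, genome)
        assert ra.fold == rb.fold and ra.chi2 == rb.chi2

    def test_bp_accounting_consistent_with_complement(self, genome):
        svs = IntervalSet([("1", 10_001, 60_000)])
        feature = IntervalSet([("1", 40_001, 90_000)])
        res = enrichment.fold_enrichment(svs, feature, genome)
        # four cells of the 2x2 table tile the genome exactly
        a = res.bp_in_sv
        b = res.sv_total_bp - a
        c = res.bp_in_genome - a
        d = res.genome_bp - a - b - c
        assert a + b + c + d == genome.total_length
        assert (a, b, c, d) == (20_000, 30_000, 30_000, 920_000)


def test_chi2_matches_textbook_formula_on_random_tables(rng):
    specific = [(100, 900, 50, 950)]
    tables = specific + [tuple(rng.integers(1, 10_000, 4)) for _ in range(100)]
    for a, b, c, d in tables:
        got, _ = enrichment._chi2_2x2(a, b, c, d)
        assert got == pytest.approx(chi2_2x2_bruteforce(a, b, c, d), abs=1e-10)


class TestGenicPartitions:
    def build_genes(self):
        from .test_impact import gene
        return [gene(start=100_000 + 50_000 * k, gene_id=f"G{k}") for k in range(8)]

    def test_partitions_cover_genome(self, genome):
        genes = self.build_genes()
        parts = enrichment.genome_partitions(genes, genome)
        inter = parts["intergenic"].total_length()
        intron = parts["intron"].total_length()
        exon = parts["exon"].total_length()
        assert inter + intron + exon == genome.total_length

    def test_intergenic_only_svs_give_reciprocal_fold(self, genome):
        genes = self.build_genes()
        parts = enrichment.genome_partitions(genes, genome)
        inter_frac = parts["intergenic"].total_length() / genome.total_length
        svs = make_catalog([make_record(start=600_000 + 1000 * k,
                                        end=600_000 + 1000 * k + 499, id=f"s{k}")
                            for k in range(5)])
        res = {r.label: r for r in enrichment.genic_partition_enrichment(
            svs, genes, genome)}
        assert res["intergenic"].fold == pytest.approx(1 / inter_frac)

    def test_uniform_svs_on_half_genic_genome_near_one(self, rng):
        # genes cover exactly half the genome; uniform SV placement -> folds ~ 1
        genome = GenomeModel({"1": 200_000})
        from svscape.model import GeneModel, Transcript
        genes = [GeneModel(f"G{k}", "1", 1 + 20_000 * k, 20_000 * k + 10_000, "+",
                           transcripts=[Transcript(
                               "t", exons=[(1 + 20_000 * k, 20_000 * k + 10_000)],
                               cds=[(1 + 20_000 * k, 20_000 * k + 10_000)])])
                 for k in range(10)]
        starts = rng.integers(1, 199_000, 400)
        svs = make_catalog([make_record(start=int(s), end=int(s) + 49, id=f"s{i}")
                            for i, s in enumerate(starts)])
        res = {r.label: r.fold for r in enrichment.genic_partition_enrichment(
            svs, genes, genome)}
        assert res["intergenic"] == pytest.approx(1.0, abs=0.12)
        assert res["exon"] == pytest.approx(1.0, abs=0.12)


class TestSingletonProportionTests:
    def frame(self, cat_values, ref_values):
        rows = [{"sample": f"S{i}", "category": "cat", "proportion": v}
                for i, v in enumerate(cat_values)]
        rows += [{"sample": f"S{i}", "category": "intergenic", "proportion": v}
                 for i, v in enumerate(ref_values)]
        return pd.DataFrame(rows)

    def test_identical_distributions_not_significant(self, rng):
        v = rng.uniform(0.2, 0.3, 30)
        res = enrichment.singleton_proportion_tests(self.frame(v, v))[0]
        assert res.p == pytest.approx(1.0)
        assert not res.significant

    def test_shifted_category_detected(self, rng):
        ref = rng.normal(0.25, 0.01, 50)
        res = enrichment.singleton_proportion_tests(
            self.frame(ref + 0.3, ref))[0]
        from scipy import stats
        t_ref, p_ref = stats.ttest_ind(ref + 0.3, ref, equal_var=True)
        assert res.statistic == pytest.approx(float(t_ref))
        assert res.significant

    def test_single_sample_flagged_undefined(self):
        res = enrichment.singleton_proportion_tests(
            self.frame([0.5], [0.1, 0.2, 0.3]))[0]
        assert np.isnan(res.statistic) and not res.significant


class TestChromatinStates:
    def test_proportion_limits(self):
        track = FeatureTrack("states", ("EnhA", "Qui"), [
            ("1", 1_000, 2_000, "EnhA", "liver"),
            ("1", 50_000, 60_000, "Qui", "liver"),
        ])
        inside = IntervalSet([("1", 500, 2_500)])
        df = enrichment.chromatin_state_overlap(track, inside)
        by_state = dict(zip(df["state"], df["proportion"]))
        assert by_state["EnhA"] == pytest.approx(1.0)  # state fully inside SVs
        assert by_state["Qui"] == pytest.approx(0.0)   # disjoint

    def test_random_layout_matches_per_base_oracle(self, rng):
        ivs = []
        for t in ("a", "b"):
            pos = 1
            while pos < 50_000:
                end = pos + int(rng.integers(500, 2_000))
                ivs.append(("1", pos, end, ("EnhA", "Qui")[int(rng.integers(2))], t))
                pos = end + 1
        track = FeatureTrack("states", ("EnhA", "Qui"), ivs)
        sv_ivs = [(int(s), int(s) + int(l)) for s, l in
                  zip(rng.integers(1, 45_000, 30), rng.integers(100, 2_000, 30))]
        footprint = IntervalSet(("1", s, e) for s, e in sv_ivs)
        df = enrichment.chromatin_state_overlap(track, footprint)
        from .oracles import base_set
        sv_bases = base_set(sv_ivs)
        for _, row in df.iterrows():
            state_bases = base_set(
                [(s, e) for c, s, e, lab, t in ivs
                 if lab == row["state"] and t == row["tissue"]])
            assert row["overlap_bp"] == len(state_bases & sv_bases)
            assert row["proportion"] == pytest.approx(
                len(state_bases & sv_bases) / len(state_bases))


class TestRegulatorRatios:
    def test_limits_and_enumeration(self, rng):
        from .test_impact import gene
        genes = [gene(start=100_000, gene_id="G0")]
        elements = FeatureTrack("regulators", ("enhancer",), [
            ("1", 100_050, 100_149, "enhancer", "liver"),   # 5'UTR
            ("1", 101_950, 102_049, "enhancer", "liver"),   # exon (CDS)
            ("1", 103_000, 103_100, "enhancer", "liver"),   # intron
            ("1", 98_000, 98_100, "enhancer", "liver"),     # gene flanking
            ("1", 500_000, 500_100, "enhancer", "liver"),   # intergenic
        ])
        all_sv = IntervalSet([("1", 1, 1_000_000)])
        df = enrichment.regulator_location_ratios(elements, all_sv, genes)
        assert (df["ratio"] == 1.0).all()  # everything SV-overlapped
        none_sv = IntervalSet([("2", 1, 10)])
        df0 = enrichment.regulator_location_ratios(elements, none_sv, genes)
        assert (df0["ratio"] == 0.0).all()
        # mixed case matches direct enumeration
        some = IntervalSet([("1", 100_000, 104_000)])
        df1 = enrichment.regulator_location_ratios(elements, some, genes)
        got = dict(zip(df1["location"], df1["n_sv"]))
        assert got == {"UTR5": 1, "exon": 1, "intron": 1, "gene_flanking": 0,
                       "intergenic": 0, "all": 3}


class TestQTLEnrichment:
    def test_length_filter_and_fold_algebra(self):
        genome = GenomeModel({"1": 10_000_000})
        qtls = FeatureTrack("qtls", ("t1", "t2"), [
            ("1", 1_000_001, 1_100_000, "t1", None),     # 100 kb, fully tiled below
            ("1", 3_000_001, 4_200_000, "t2", None),     # 1.2 Mb -> excluded
            ("1", 5_000_001, 5_050_000, "t2", None),
        ])
        # SV footprint = 10% of the genome including all of t1's QTL
        svs = IntervalSet([("1", 700_001, 1_700_000)])
        results, tallies = enrichment.qtl_enrichment(qtls, svs, genome)
        assert tallies["n_qtls_dropped_length"] == 1
        by = {r.label: r for r in results}
        assert by["t1"].fold == pytest.approx(10.0)  # fully covered on a 10% genome
        assert by["t2"].fold == pytest.approx(0.0)

    def test_overlap_fractions_match_hand_enumeration(self):
        genome = GenomeModel({"1": 10_000_000})
        ivs = [("1", 100_000 * (k + 1), 100_000 * (k + 1) + 9_999,
                f"t{k % 3}", None) for k in range(12)]
        qtls = FeatureTrack("qtls", ("t0", "t1", "t2"), ivs)
        svs = IntervalSet([("1", 100_000, 100_001), ("1", 200_000, 200_001),
                           ("1", 300_000, 300_001)])  # hits QTLs 1..3 only
        _, tallies = enrichment.qtl_enrichment(qtls, svs, genome)
        assert tallies["frac_qtls_overlapped"] == pytest.approx(3 / 12)
        assert tallies["frac_traits_overlapped"] == pytest.approx(3 / 3)


class TestPopulationAnova:
    def make_pop_map(self, n_per_group=10):
        main = {}
        for g in ("ASW", "ASD", "EUC", "EUD", "EUW", "ASxEU"):
            for i in range(n_per_group):
                main[f"{g}_{i}"] = g
        return PopulationMap(main=main)

    def frame(self, values_by_group, trait="t"):
        rows = []
        for g, vals in values_by_group.items():
            for i, v in enumerate(vals):
                rows.append({"sample": f"{g}_{i}", "trait": trait, "log2_fold": v})
        return pd.DataFrame(rows)

    def test_identical_groups_null(self):
        pmap = self.make_pop_map()
        df = self.frame({g: [1.0] * 10 for g in
                         ("ASW", "ASD", "EUC", "EUD", "EUW", "ASxEU")})
        res = enrichment.population_anova(df, pmap)[0]
        assert res.p == pytest.approx(1.0)
        assert res.cv_group_means == pytest.approx(0.0)
        assert not res.reported

    def test_shifted_group_detected_against_textbook_f(self, rng):
        pmap = self.make_pop_map()
        groups = ("ASW", "ASD", "EUC", "EUD", "EUW", "ASxEU")
        data = {g: rng.normal(0.1, 0.05, 10) for g in groups}
        data["EUC"] = rng.normal(3.0, 0.05, 10)
        res = enrichment.population_anova(self.frame(data), pmap)[0]
        from scipy import stats
        f_ref, p_ref = stats.f_oneway(*[data[g] for g in sorted(groups)])
        assert res.f_statistic == pytest.approx(float(f_ref))
        assert res.p == pytest.approx(float(p_ref))
        assert res.reported  # adjusted p < 0.01 and CV of group means > 1

    def test_fewer_than_two_groups_is_error(self):
        pmap = PopulationMap(main={"EUC_0": "EUC", "EUC_1": "EUC"})
        df = self.frame({"EUC": [1.0, 2.0]})
        with pytest.raises(ValueError):
            enrichment.population_anova(df, pmap)


def test_individual_qtl_fold_definition():
    genome = GenomeModel({"1": 1_000_000})
    qtls = FeatureTrack("qtls", ("t0",), [("1", 1, 100_000, "t0", None)])
    rec = make_record(start=50_001, end=60_000,
                      genotypes=np.array([2, 0], dtype=np.int8))
    catalog = make_catalog([rec], n_samples=2)
    df = enrichment.individual_qtl_folds(catalog, qtls, genome)
    # carrier: overlap 10_000 bp (+1 pseudo) over 10_000 SV bp vs 10% genome
    expected = np.log2((10_001 / 10_000) / 0.1)
    assert df.loc[df["sample"] == "S0", "log2_fold"].iloc[0] == pytest.approx(expected)
    assert (df["sample"] == "S1").sum() == 0  # no SV bp -> no fold defined
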