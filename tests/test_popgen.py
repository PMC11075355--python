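"""Allele frequencies, FST, LD tiers, thinning, and the functional network."""

import numpy as np
import pytest

from svscape import popgen
from svscape.model import (
    FunctionalVariantCatalog,
    GenotypeMatrix,
    PopulationMap,
)
from svscape.simulate import balding_nichols_panel

from .conftest import make_catalog, make_record
from .oracles import pearson_r2_bruteforce, wc_theta_bruteforce


def matrix_from(dosages, pops, kinds=None, positions=None, chroms=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    samples = tuple(f"{pops[i]}_{i}" for i in range(n))
    return GenotypeMatrix(
        dosages, samples,
        variant_ids=tuple(f"1:{1000 * (j + 1)}:SNP" for j in range(m)),
        chroms=tuple(chroms or ["1"] * m),
        positions=np.array(positions if positions is not None
                           else [1000 * (j + 1) for j in range(m)]),
        kinds=tuple(kinds or ["SNP"] * m),
    ), PopulationMap(main={s: pops[i] for i, s in enumerate(samples)})


class TestGroupAF:
    def test_all_het_group(self):
        m, pmap = matrix_from(np.ones((10, 1)), ["ASD"] * 10)
        af = popgen.group_allele_frequencies(m, pmap)[0]
        assert af.af == pytest.approx(0.5)
        assert (af.ac, af.an) == (10, 20)

    def test_all_missing_group_flagged_nan(self):
        m, pmap = matrix_from([[-1], [-1], [1], [1]],
                              ["ASD", "ASD", "EUC", "EUC"])
        res = {g.group: g for g in popgen.group_allele_frequencies(m, pmap)}
        assert np.isnan(res["ASD"].af)
        assert res["EUC"].af == pytest.approx(0.5)

    def test_maf_filter_enumeration(self):
        # 200 haplotypes per column: AFs 0.005 (drop), 0.01 (keep), 0.5 (keep)
        d = np.zeros((100, 3), dtype=np.int8)
        d[0, 0] = 1
        d[0, 1] = 2
        d[:50, 2] = 2
        m, pmap = matrix_from(d, ["ASD"] * 100)
        kept = {g.variant_id for g in popgen.group_allele_frequencies(
            m, pmap, maf_min=0.01)}
        assert kept == {m.variant_ids[1], m.variant_ids[2]}


class TestGroupSpecific:
    def build(self):
        pops = ["ASD"] * 3 + ["EUC"] * 3
        recs = [
            make_record(start=1_000, end=1_999, id="as_only",
                        genotypes=np.array([0, 1, 0, 0, 0, 0], dtype=np.int8)),
            make_record(start=3_000, end=3_999, id="shared",
                        genotypes=np.array([1, 0, 0, 1, 0, 0], dtype=np.int8)),
            make_record(start=5_000, end=5_999, id="nobody",
                        genotypes=np.zeros(6, dtype=np.int8)),
            make_record(start=7_000, end=7_999, id="eu_missing_as",
                        genotypes=np.array([-1, -1, -1, 2, 2, 0], dtype=np.int8)),
        ]
        catalog = make_catalog(recs, n_samples=6)
        catalog = type(catalog)(catalog.records, tuple(f"{p}_{i}"
                                                       for i, p in enumerate(pops)))
        pmap = PopulationMap(main={s: s.rsplit("_", 1)[0] for s in catalog.samples})
        return catalog, pmap

    def test_partition(self):
        catalog, pmap = self.build()
        out = popgen.group_specific_svs(catalog, pmap, "AS", "EU")
        assert out["a_specific"] == ["as_only"]
        assert out["shared"] == ["shared"]
        # missing is not absence, but with zero AS calls the SV is EU-only
        assert out["b_specific"] == ["eu_missing_as"]
        assert "nobody" not in out["a_specific"] + out["b_specific"] + out["shared"]

    def test_common_subsets_require_af(self):
        catalog, pmap = self.build()
        out = popgen.group_specific_svs(catalog, pmap, "AS", "EU",
                                        common_af_min=0.01)
        assert out["common_a_specific"] == ["as_only"]   # AF 1/6 within AS
        out_strict = popgen.group_specific_svs(catalog, pmap, "AS", "EU",
                                               common_af_min=0.5)
        assert out_strict["common_a_specific"] == []


class TestWeirCockerham:
    def test_fixed_difference_is_one(self):
        d = np.vstack([np.zeros((50, 1)), np.full((50, 1), 2)])
        m, pmap = matrix_from(d, ["ASD"] * 50 + ["EUC"] * 50)
        res = popgen.weir_cockerham_fst(m, pmap, ("AS", "EU"))
        assert res[0].fst == pytest.approx(1.0)

    def test_identical_frequencies_near_zero(self, rng):
        p = rng.uniform(0.3, 0.7, 500)
        d = rng.binomial(2, p[None, :], size=(200, 500)).astype(np.int8)
        m, pmap = matrix_from(d, ["ASD"] * 100 + ["EUC"] * 100)
        res = popgen.weir_cockerham_fst(m, pmap, ("AS", "EU"))
        assert abs(np.mean([r.fst for r in res])) <= 0.02

    def test_monomorphic_skipped(self):
        m, pmap = matrix_from(np.zeros((10, 1)), ["ASD"] * 5 + ["EUC"] * 5)
        assert popgen.weir_cockerham_fst(m, pmap, ("AS", "EU")) == []

    def test_matches_scalar_oracle_with_missingness(self, rng):
        d = rng.binomial(2, 0.4, size=(40, 30)).astype(np.int8)
        d[rng.random(d.shape) < 0.1] = -1
        m, pmap = matrix_from(d, ["ASD"] * 20 + ["EUC"] * 20)
        res = {r.variant_id: r.fst for r in
               popgen.weir_cockerham_fst(m, pmap, ("AS", "EU"))}
        for j, vid in enumerate(m.variant_ids):
            g1 = [None if v == -1 else int(v) for v in d[:20, j]]
            g2 = [None if v == -1 else int(v) for v in d[20:, j]]
            expected = wc_theta_bruteforce(g1, g2)
            if expected is None:
                assert vid not in res
            else:
                assert res[vid] == pytest.approx(expected, abs=1e-12)

    def test_allele_label_swap_invariance(self, rng):
        d = rng.binomial(2, 0.3, size=(60, 50)).astype(np.int8)
        m1, pmap = matrix_from(d, ["ASD"] * 30 + ["EUC"] * 30)
        m2, _ = matrix_from(2 - d, ["ASD"] * 30 + ["EUC"] * 30)
        f1 = [r.fst for r in popgen.weir_cockerham_fst(m1, pmap, ("AS", "EU"))]
        f2 = [r.fst for r in popgen.weir_cockerham_fst(m2, pmap, ("AS", "EU"))]
        assert f1 == pytest.approx(f2, abs=1e-12)
        assert all(f <= 1.0 + 1e-12 for f in f1)

    @pytest.mark.parametrize("f", [0.05, 0.2, 0.5])
    def test_balding_nichols_recovery(self, f):
        m, pmap, _ = balding_nichols_panel(seed=11, f=f, n_per_group=100,
                                           n_variants=2000)
        theta = popgen.weir_cockerham_fst_global(m, pmap, ("ASD", "EUC"),
                                                 level="main")
        assert theta == pytest.approx(f, abs=0.03)


class TestTopPercentile:
    def test_distinct_values_nearest_rank(self):
        vals = np.arange(100, dtype=float)
        threshold, flags = popgen.top_percentile(vals, q=0.01)
        assert threshold == 99.0
        assert flags.sum() == 1  # exactly the single largest

    def test_ties_at_threshold_all_flagged(self):
        vals = np.array([1.0] * 98 + [5.0, 5.0])
        threshold, flags = popgen.top_percentile(vals, q=0.01)
        assert threshold == 5.0 and flags.sum() == 2

    def test_large_sample_count_within_tie_bound(self, rng):
        vals = rng.normal(size=10_000)
        threshold, flags = popgen.top_percentile(vals, q=0.01)
        ties = int((vals == threshold).sum())
        assert 100 <= flags.sum() <= 100 + ties


class TestLD:
    def test_self_and_anticorrelated_r2(self, rng):
        x = rng.integers(0, 3, 50).astype(float)
        assert popgen._pairwise_r2(x.astype(np.int8), x.astype(np.int8)) \
            == pytest.approx(1.0)
        assert popgen._pairwise_r2(x.astype(np.int8), (2 - x).astype(np.int8)) \
            == pytest.approx(1.0)  # r2 is sign-free

    def test_recode_invariance(self, rng):
        x = rng.integers(0, 3, 50).astype(np.int8)
        y = rng.integers(0, 3, 50).astype(np.int8)
        assert popgen._pairwise_r2(x, y) == pytest.approx(
            popgen._pairwise_r2((2 - x).astype(np.int8), y), abs=1e-12)

    def test_window_pairs_match_bruteforce(self, rng):
        n, m = 30, 60
        d = rng.integers(0, 3, (n, m)).astype(np.int8)
        d[rng.random(d.shape) < 0.05] = -1
        positions = np.sort(rng.choice(np.arange(1, 200_000), m, replace=False))
        matrix, _ = matrix_from(d, ["ASD"] * n, positions=positions)
        window = 50_000
        records = popgen.ld_r2_window(matrix, window=window)
        got = {(r.id_a, r.id_b): r.r2 for r in records}
        for i in range(m):
            for j in range(i + 1, m):
                if abs(int(positions[j]) - int(positions[i])) > window:
                    continue
                mask = (d[:, i] != -1) & (d[:, j] != -1)
                x, y = d[mask, i].astype(float), d[mask, j].astype(float)
                if len(x) < 2 or x.std() == 0 or y.std() == 0:
                    continue
                expected = pearson_r2_bruteforce(list(x), list(y))
                key = (matrix.variant_ids[i], matrix.variant_ids[j])
                if expected > 0:
                    assert got[key] == pytest.approx(expected, abs=1e-12)

    def test_tiers(self):
        assert popgen.assign_tier(0.19) == "none"
        assert popgen.assign_tier(0.2) == "linked"
        assert popgen.assign_tier(0.5) == "tagged"
        assert popgen.assign_tier(0.8) == "highly_tagged"

    def test_tier_sets_nested(self, rng):
        records = [popgen.LinkageRecord("a", f"b{i}", 100, float(r),
                                        popgen.assign_tier(float(r)))
                   for i, r in enumerate(rng.random(200))]
        tiers = popgen.tier_sets(records)
        assert tiers["highly_tagged"] <= tiers["tagged"] <= tiers["linked"]


class TestThinning:
    def test_rule_trace(self):
        kept = popgen.thin_variants(np.array([100, 900, 1100, 2200]))
        assert kept.tolist() == [0, 2, 3]  # keep 100, 1100, 2200

    def test_single_variant_kept(self):
        assert popgen.thin_variants(np.array([42])).tolist() == [0]

    def test_dense_grid(self):
        kept = popgen.thin_variants(np.arange(1, 5001))
        assert len(kept) == 5

    def test_min_gap_property(self, rng):
        pos = np.sort(rng.choice(np.arange(1, 100_000), 500, replace=False))
        chroms = ["1"] * 250 + ["2"] * 250
        kept = popgen.thin_variants(pos, chroms=chroms, min_gap=1000)
        for c in ("1", "2"):
            p = sorted(int(pos[i]) for i in kept if chroms[i] == c)
            assert all(b - a >= 1000 for a, b in zip(p, p[1:]))


class TestFunctionalNetwork:
    def build(self):
        sv = make_record(start=10_000, end=12_000, id="1:10000-12000:DEL",
                         genotypes=np.array([1, 1, 0, 0], dtype=np.int8))
        catalog = make_catalog([sv])
        links = [
            popgen.LinkageRecord("1:10000-12000:DEL", "1:50000:SNP", 40_000, 0.3,
                                 "linked"),
            popgen.LinkageRecord("1:10000-12000:DEL", "1:60000:SNP", 50_000, 0.3,
                                 "linked"),
            popgen.LinkageRecord("1:10000-12000:DEL", "1:70000:SNP", 60_000, 0.1,
                                 "none"),
        ]
        from .test_impact import gene
        genes = [gene(start=9_000, gene_id="EG1")]
        functional = FunctionalVariantCatalog([
            {"kind": "eQTL", "id": "1:50000:SNP", "chrom": "1", "pos": 50_000,
             "gene_id": "EG1", "tissue": "liver"},
            {"kind": "GWAS", "id": "1:60000:SNP", "chrom": "1", "pos": 60_000,
             "trait": "growth", "p": 1e-7},   # above 5e-8: excluded
            {"kind": "TWAS", "gene_id": "EG1", "trait": "growth", "fdr": 0.01},
            {"kind": "TWAS", "gene_id": "EG_NOT_ES", "trait": "growth", "fdr": 0.01},
        ])
        return catalog, links, functional, genes

    def test_edges_and_thresholds(self):
        catalog, links, functional, genes = self.build()
        g = popgen.build_functional_network(catalog, links, functional, genes)
        sv, snp = "1:10000-12000:DEL", "1:50000:SNP"
        assert g.has_edge(sv, snp) and g[sv][snp]["kind"] == "LD"
        assert g.has_edge(snp, "EG1")                   # eQTL -> eGene
        assert g.has_edge(sv, "EG1")                    # direct overlap
        assert g[sv]["EG1"]["relation"] == "direct"
        assert not g.has_node("1:60000:SNP")            # GWAS p = 1e-7 excluded
        assert not g.has_node("1:70000:SNP")            # below linked tier
        assert g.has_edge("EG1", "growth")              # TWAS FDR<=0.05 and eGene
        assert not g.has_node("EG_NOT_ES")              # TWAS but not an e/sGene
        summary = popgen.network_summary(g)
        assert summary["n_svs_linked_functional"] == 1
        assert summary["n_svs_eqtl"] == 1 and summary["n_svs_gwas"] == 0

    def test_empty_functional_catalog_gives_sv_only_network(self):
        catalog, links, _, genes = self.build()
        g = popgen.build_functional_network(catalog, links,
                                            FunctionalVariantCatalog([]), genes)
        kinds = {d["kind"] for _, d in g.nodes(data=True)}
        assert kinds == {"SV"}

    def test_extended_overlap_uses_five_kb_flank(self):
        catalog, links, functional, genes = self.build()
        # move the SV 3 kb upstream of the gene body: extended overlap only
        far = make_record(start=2_000, end=5_999, id="1:10000-12000:DEL",
                          genotypes=np.array([1, 0, 0, 0], dtype=np.int8))
        catalog = make_catalog([far])
        g = popgen.build_functional_network(catalog, links, functional, genes)
        assert g["1:10000-12000:DEL"]["EG1"]["relation"] == "extended"
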