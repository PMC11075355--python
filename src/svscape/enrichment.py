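"""Overlap-proportion and enrichment statistics.

Fold enrichment of a feature inside the (merged, nonredundant) SV footprint
relative to the whole genome, tested with a Pearson chi-squared on the 2x2
base-pair contingency table without continuity correction; family-wise
control is Bonferroni. Cross-sample comparisons (singleton proportions,
chromatin-state proportions, regulator location ratios) use a two-sided
pooled-variance Student's t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import IntervalSet, merge_intervals, subtract_intervals
from .model import FeatureTrack, GeneModel, GenomeModel, PopulationMap, SVCatalog


@dataclass
class EnrichmentResult:
    label: str
    bp_in_sv: int
    sv_total_bp: int
    bp_in_genome: int
    genome_bp: int
    fold: float
    chi2: float
    p: float
    p_adjusted: float
    significant: bool


def _chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-squared without continuity correction on [[a,b],[c,d]]."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def fold_enrichment(sv_footprint: IntervalSet, feature: IntervalSet,
                    genome: GenomeModel, label: str = "feature",
                    family_size: int = 1, alpha: float = 0.01) -> EnrichmentResult:
    """Fold = (feature bp in SV / SV bp) / (feature bp in genome / genome bp),
    with a chi-squared test of the 2x2 bp table {in/out SV} x {in/out feature}."""
    genome_bp = genome.total_length
    sv_bp = sv_footprint.total_length()
    feat_bp = feature.total_length()
    if feat_bp == 0:
        raise ValueError(f"feature {label!r} covers zero genome bp")
    if sv_bp == 0:
        raise ValueError("SV footprint is empty")
    in_both = sv_footprint.intersection_length(feature)
    fold = (in_both / sv_bp) / (feat_bp / genome_bp)
    chi2, p = _chi2_2x2(in_both, sv_bp - in_both,
                        feat_bp - in_both, genome_bp - sv_bp - feat_bp + in_both)
    p_adj = min(1.0, p * family_size)
    return EnrichmentResult(label, in_both, sv_bp, feat_bp, genome_bp,
                            fold, chi2, p, p_adj, p_adj <= alpha)


def fold_enrichment_by_count(catalog: SVCatalog, feature: IntervalSet,
                             genome: GenomeModel, label: str = "feature",
                             family_size: int = 1, alpha: float = 0.01
                             ) -> EnrichmentResult:
    """Count-unit variant: SVs overlapping/not overlapping the feature versus
    the feature's bp share of the genome. Calibrated for point-scale events;
    for long intervals the bp mode is the default reported statistic."""
    recs = [r for r in catalog.records if r.svtype != "BND"]
    n = len(recs)
    if n == 0:
        raise ValueError("empty SV set")
    feat_bp = feature.total_length()
    if feat_bp == 0:
        raise ValueError(f"feature {label!r} covers zero genome bp")
    genome_bp = genome.total_length
    k = sum(feature.overlaps(*r.interval) for r in recs)
    fold = (k / n) / (feat_bp / genome_bp)
    chi2, p = _chi2_2x2(k, n - k, feat_bp, genome_bp - feat_bp)
    p_adj = min(1.0, p * family_size)
    return EnrichmentResult(label, k, n, feat_bp, genome_bp,
                            fold, chi2, p, p_adj, p_adj <= alpha)


def feature_family_enrichment(sv_footprint: IntervalSet, track: FeatureTrack,
                              genome: GenomeModel, alpha: float = 0.01
                              ) -> list[EnrichmentResult]:
    """One fold test per label in the track, Bonferroni over the family."""
    labels = track.labels()
    return [fold_enrichment(sv_footprint, track.interval_set(label=lab), genome,
                            label=lab, family_size=len(labels), alpha=alpha)
            for lab in labels]


def genome_partitions(genes: list[GeneModel], genome: GenomeModel
                      ) -> dict[str, IntervalSet]:
    """Partition-style genomic strata from gene models: intergenic, intron,
    exon, CDS, 5'UTR, 3'UTR (exonic strata overlap by construction)."""
    bodies: dict[str, list] = {}
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    utr5: dict[str, list] = {}
    utr3: dict[str, list] = {}
    for g in genes:
        bodies.setdefault(g.chrom, []).append((g.start, g.end))
        exons.setdefault(g.chrom, []).extend(g.exon_union())
        cds.setdefault(g.chrom, []).extend(g.cds_union())
        utr5.setdefault(g.chrom, []).extend(g.utr5_union())
        utr3.setdefault(g.chrom, []).extend(g.utr3_union())
    out: dict[str, IntervalSet] = {}
    inter, intron = [], []
    for chrom, length in genome.lengths.items():
        b = merge_intervals(bodies.get(chrom, []))
        inter.extend((chrom, s, e) for s, e in subtract_intervals([(1, length)], b))
        intron.extend((chrom, s, e)
                      for s, e in subtract_intervals(b, exons.get(chrom, [])))
    out["intergenic"] = IntervalSet(inter)
    out["intron"] = IntervalSet(intron)
    out["exon"] = IntervalSet((c, s, e) for c, ivs in exons.items() for s, e in ivs)
    out["CDS"] = IntervalSet((c, s, e) for c, ivs in cds.items() for s, e in ivs)
    out["UTR5"] = IntervalSet((c, s, e) for c, ivs in utr5.items() for s, e in ivs)
    out["UTR3"] = IntervalSet((c, s, e) for c, ivs in utr3.items() for s, e in ivs)
    return {k: v for k, v in out.items() if v.total_length() > 0}


def genic_partition_enrichment(catalog: SVCatalog, genes: list[GeneModel],
                               genome: GenomeModel, alpha: float = 0.01,
                               mode: str = "bp") -> list[EnrichmentResult]:
    """Per-partition fold tests of the SV footprint against gene strata."""
    parts = genome_partitions(genes, genome)
    fam = len(parts)
    if mode == "bp":
        fp = catalog.merged_intervals()
        return [fold_enrichment(fp, iv, genome, label=lab, family_size=fam, alpha=alpha)
                for lab, iv in parts.items()]
    if mode == "count":
        return [fold_enrichment_by_count(catalog, iv, genome, label=lab,
                                         family_size=fam, alpha=alpha)
                for lab, iv in parts.items()]
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class TTestResult:
    label: str
    reference: str
    statistic: float
    p: float
    p_adjusted: float
    significant: bool
    n_label: int
    n_reference: int


def _pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided pooled-variance Student's t (not Welch)."""
    res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def singleton_proportion_tests(per_sample: pd.DataFrame,
                               reference: str = "intergenic",
                               alpha: float = 0.01) -> list[TTestResult]:
    """t-test each category's per-sample singleton proportion against the
    reference category. `per_sample` columns: sample, category, proportion.

    Categories with fewer than two finite values on either side are flagged
    undefined (NaN statistic)."""
    ref = per_sample.loc[per_sample["category"] == reference, "proportion"].dropna().values
    cats = [c for c in per_sample["category"].unique() if c != reference]
    results = []
    fam = len(cats)
    for cat in cats:
        x = per_sample.loc[per_sample["category"] == cat, "proportion"].dropna().values
        if len(x) < 2 or len(ref) < 2:
            results.append(TTestResult(cat, reference, float("nan"), float("nan"),
                                       float("nan"), False, len(x), len(ref)))
            continue
        t, p = _pooled_t(x, ref)
        p_adj = min(1.0, p * fam)
        results.append(TTestResult(cat, reference, t, p, p_adj, p_adj <= alpha,
                                   len(x), len(ref)))
    return results


def per_sample_category_summaries(catalog: SVCatalog, calls,
                                  singleton_ids: set[str]) -> pd.DataFrame:
    """Per-sample count-per-genome and singleton proportion by impact category.

    `calls` are ImpactCalls; an SV contributes to every category it was
    called in, once per carrier sample."""
    cat_by_sv: dict[str, set[str]] = {}
    for c in calls:
        cat_by_sv.setdefault(c.sv_id, set()).add(c.category)
    rows = []
    n = len(catalog.samples)
    carried = {r.id: r.carriers() for r in catalog.records if r.genotypes is not None}
    categories = sorted({c.category for c in calls})
    for cat in categories:
        total = np.zeros(n, dtype=np.int64)
        singles = np.zeros(n, dtype=np.int64)
        for sv_id, cats in cat_by_sv.items():
            if cat not in cats or sv_id not in carried:
                continue
            mask = carried[sv_id]
            total += mask
            if sv_id in singleton_ids:
                singles += mask
        for i, s in enumerate(catalog.samples):
            prop = singles[i] / total[i] if total[i] else float("nan")
            rows.append({"sample": s, "category": cat,
                         "count_per_genome": int(total[i]),
                         "proportion": prop})
    return pd.DataFrame(rows)


def chromatin_state_overlap(states: FeatureTrack, sv_footprint: IntervalSet
                            ) -> pd.DataFrame:
    """Per (tissue, state): overlapped-length proportion of the state covered
    by the SV footprint. Columns: tissue, state, state_bp, overlap_bp,
    proportion."""
    rows = []
    for tissue in states.tissues() or [None]:
        for state in states.labels():
            iv = states.interval_set(label=state, tissue=tissue)
            state_bp = iv.total_length()
            if state_bp == 0:
                continue
            ov = sv_footprint.intersection_length(iv)
            rows.append({"tissue": tissue, "state": state, "state_bp": state_bp,
                         "overlap_bp": ov, "proportion": ov / state_bp})
    return pd.DataFrame(rows)


def chromatin_state_tests(per_tissue: pd.DataFrame, reference: str = "Qui",
                          alpha: float = 0.01) -> list[TTestResult]:
    """t-test each state's across-tissue proportions against the reference
    (quiescent) state."""
    renamed = per_tissue.rename(columns={"state": "category"})
    return singleton_proportion_tests(renamed[["tissue", "category", "proportion"]]
                                      .rename(columns={"tissue": "sample"}),
                                      reference=reference, alpha=alpha)


REGULATOR_LOCATIONS = ("gene_flanking", "exon", "UTR5", "UTR3", "intron", "intergenic")


def classify_element_location(chrom: str, start: int, end: int,
                              genes: list[GeneModel], flank: int = 5000) -> str:
    """Genomic location of a regulatory element relative to gene models.

    Precedence: UTR5/UTR3 > exon > intron > gene_flanking (+-5 kb) >
    intergenic; among UTRs the larger overlap wins, ties to 5'."""
    best = "intergenic"
    for g in genes:
        if g.chrom != chrom:
            continue
        if start <= g.end and end >= g.start:
            u5 = intersect_len_pairs(start, end, g.utr5_union())
            u3 = intersect_len_pairs(start, end, g.utr3_union())
            if u5 or u3:
                return "UTR5" if u5 >= u3 else "UTR3"
            if intersect_len_pairs(start, end, g.exon_union()):
                return "exon"
            best = "intron"
        elif best == "intergenic" and start <= g.end + flank and end >= g.start - flank:
            best = "gene_flanking"
    return best


def intersect_len_pairs(start: int, end: int, ivs: list[tuple[int, int]]) -> int:
    from .intervals import intersect_length
    return intersect_length([(start, end)], ivs) if ivs else 0


def regulator_location_ratios(elements: FeatureTrack, sv_footprint: IntervalSet,
                              genes: list[GeneModel], flank: int = 5000
                              ) -> pd.DataFrame:
    """Per (tissue, label, location): SV-overlapped element count over total
    element count. Columns: tissue, label, location, n_total, n_sv, ratio."""
    rows = []
    for tissue in elements.tissues() or [None]:
        for label in elements.labels():
            sub = elements.subset(label=label, tissue=tissue)
            tall: dict[str, int] = {loc: 0 for loc in REGULATOR_LOCATIONS}
            hit: dict[str, int] = {loc: 0 for loc in REGULATOR_LOCATIONS}
            for chrom, s, e, _, _ in sub.intervals:
                loc = classify_element_location(chrom, s, e, genes, flank)
                tall[loc] += 1
                if sv_footprint.overlaps(chrom, s, e):
                    hit[loc] += 1
            # overall row for the test reference
            tall["all"] = sum(tall.values())
            hit["all"] = sum(hit.values())
            for loc in (*REGULATOR_LOCATIONS, "all"):
                if tall[loc]:
                    rows.append({"tissue": tissue, "label": label, "location": loc,
                                 "n_total": tall[loc], "n_sv": hit[loc],
                                 "ratio": hit[loc] / tall[loc]})
    return pd.DataFrame(rows)


def regulator_location_tests(ratios: pd.DataFrame, alpha: float = 0.01
                             ) -> list[TTestResult]:
    """t-test each location's across-tissue ratio against the overall ratio,
    per element label, Bonferroni over locations."""
    out = []
    for label in ratios["label"].unique():
        sub = ratios[ratios["label"] == label]
        df = sub.rename(columns={"tissue": "sample", "location": "category",
                                 "ratio": "proportion"})
        out.extend(singleton_proportion_tests(
            df[["sample", "category", "proportion"]], reference="all", alpha=alpha))
    return out


def qtl_enrichment(qtls: FeatureTrack, sv_footprint: IntervalSet,
                   genome: GenomeModel, max_qtl_len: int = 1_000_000,
                   fold_min: float = 2.0, alpha: float = 0.01
                   ) -> tuple[list[EnrichmentResult], dict]:
    """Per-trait QTL enrichment after dropping QTLs longer than 1 Mb.

    Significant iff fold > `fold_min` AND Bonferroni-adjusted p < `alpha`.
    Also reports fractions of QTLs and traits with >= 1 bp SV overlap."""
    kept = [(c, s, e, lab, t) for c, s, e, lab, t in qtls.intervals
            if e - s + 1 <= max_qtl_len]
    track = FeatureTrack(qtls.name, qtls.vocabulary, kept)
    traits = track.labels()
    fam = len(traits)
    results = []
    n_qtl_overlap = sum(sv_footprint.overlaps(c, s, e) for c, s, e, _, _ in kept)
    traits_overlap = {lab for c, s, e, lab, _ in kept if sv_footprint.overlaps(c, s, e)}
    for lab in traits:
        res = fold_enrichment(sv_footprint, track.interval_set(label=lab), genome,
                              label=lab, family_size=fam, alpha=alpha)
        res.significant = res.fold > fold_min and res.p_adjusted < alpha
        results.append(res)
    tallies = {
        "n_qtls": len(kept),
        "n_qtls_dropped_length": len(qtls) - len(kept),
        "n_traits": fam,
        "frac_qtls_overlapped": n_qtl_overlap / len(kept) if kept else float("nan"),
        "frac_traits_overlapped": len(traits_overlap) / fam if fam else float("nan"),
        "n_traits_enriched": sum(r.significant for r in results),
    }
    return results, tallies


def individual_qtl_folds(catalog: SVCatalog, qtls: FeatureTrack,
                         genome: GenomeModel, pseudocount: float = 1.0
                         ) -> pd.DataFrame:
    """Per-individual, per-trait log2 fold of trait-QTL coverage by that
    individual's SVs relative to the genomic expectation (reconstruction of
    the per-genome QTL enrichment; 1 bp pseudocount stabilises zeros).

    Columns: sample, trait, log2_fold."""
    genome_bp = genome.total_length
    trait_sets = {lab: qtls.interval_set(label=lab) for lab in qtls.labels()}
    rows = []
    for i, s in enumerate(catalog.samples):
        ivs = [r.interval for r in catalog.records
               if r.svtype != "BND" and r.genotypes is not None
               and r.genotypes[i] >= 1]
        fp = IntervalSet(ivs)
        sv_bp = fp.total_length()
        for lab, tset in trait_sets.items():
            qtl_bp = tset.total_length()
            if sv_bp == 0 or qtl_bp == 0:
                continue
            ov = fp.intersection_length(tset)
            fold = ((ov + pseudocount) / sv_bp) / (qtl_bp / genome_bp)
            rows.append({"sample": s, "trait": lab,
                         "log2_fold": math.log2(fold)})
    return pd.DataFrame(rows)


@dataclass
class AnovaResult:
    trait: str
    f_statistic: float
    p: float
    p_adjusted: float
    cv_group_means: float
    reported: bool


def population_anova(folds: pd.DataFrame, pop_map: PopulationMap,
                     level: str = "main", alpha: float = 0.01,
                     cv_min: float = 1.0) -> list[AnovaResult]:
    """One-way ANOVA of per-individual log2 folds across populations, per
    trait; a trait is reported iff Bonferroni-adjusted p < alpha AND the
    coefficient of variation of group means exceeds `cv_min`."""
    df = folds.copy()
    df["group"] = [pop_map.group_of(s, level) for s in df["sample"]]
    groups_all = sorted(df["group"].unique())
    if len(groups_all) < 2:
        raise ValueError("ANOVA needs at least two populations")
    traits = sorted(df["trait"].unique())
    fam = len(traits)
    out = []
    for trait in traits:
        sub = df[df["trait"] == trait]
        samples = [sub.loc[sub["group"] == g, "log2_fold"].values
                   for g in groups_all if (sub["group"] == g).sum() >= 2]
        if len(samples) < 2:
            out.append(AnovaResult(trait, float("nan"), float("nan"),
                                   float("nan"), float("nan"), False))
            continue
        if all(np.allclose(x, samples[0][0]) for x in samples):
            f, p = 0.0, 1.0
        else:
            f, p = stats.f_oneway(*samples)
        means = np.array([x.mean() for x in samples])
        mean_of_means = means.mean()
        cv = (float(means.std(ddof=1) / abs(mean_of_means))
              if mean_of_means != 0 else float("inf"))
        p_adj = min(1.0, float(p) * fam)
        out.append(AnovaResult(trait, float(f), float(p), p_adj, cv,
                               p_adj < alpha and cv > cv_min))
    return out
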