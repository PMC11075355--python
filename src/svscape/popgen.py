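"""Population differentiation and SV-SNP linkage disequilibrium.

Per-group allele frequencies, group-specific/shared SV labels, the Weir &
Cockerham (1984) two-population FST estimator theta-hat with top-percentile
calls, pairwise dosage r-squared within a genomic window, the
linked/tagged/highly-tagged tier scheme (r2 >= 0.2 / 0.5 / 0.8, nested),
greedy positional thinning, and assembly of the SV-functional-variant
network (SVs, e/sQTLs, GWAS loci, TWAS genes, target genes, traits).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .model import MISSING, FunctionalVariantCatalog, GeneModel, GenotypeMatrix, \
    PopulationMap, SVCatalog

log = logging.getLogger(__name__)

TIER_THRESHOLDS = {"linked": 0.2, "tagged": 0.5, "highly_tagged": 0.8}


@dataclass(frozen=True)
class GroupAF:
    variant_id: str
    group: str
    ac: int
    an: int  # non-missing allele number
    af: float


@dataclass
class FstResult:
    variant_id: str
    pair: tuple[str, str]
    fst: float
    percentile: float | None = None
    flagged: bool = False


@dataclass(frozen=True)
class LinkageRecord:
    id_a: str
    id_b: str
    distance: int
    r2: float
    tier: str  # none | linked | tagged | highly_tagged


def variant_filters(matrix: GenotypeMatrix, maf_min: float = 0.01,
                    genotype_rate_min: float = 0.95) -> np.ndarray:
    """Boolean keep-mask: minor allele frequency >= `maf_min` and per-variant
    genotyping rate > `genotype_rate_min` over the full roster."""
    d = matrix.dosages
    nonmiss = (d != MISSING)
    an = 2 * nonmiss.sum(axis=0)
    ac = np.where(d == MISSING, 0, d).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(an > 0, ac / an, np.nan)
        maf = np.minimum(af, 1 - af)
        rate = nonmiss.mean(axis=0)
    return (maf >= maf_min) & (rate > genotype_rate_min) & ~np.isnan(af)


def group_allele_frequencies(matrix: GenotypeMatrix, pop_map: PopulationMap,
                             level: str = "main", maf_min: float | None = None,
                             genotype_rate_min: float | None = None
                             ) -> list[GroupAF]:
    """Per-group AC/AN/AF over non-missing alleles; optional MAF and
    genotyping-rate filters (applied over the full roster first).

    A group with all calls missing at a variant gets AF = NaN, flagged by the
    NaN itself."""
    keep = np.ones(matrix.n_variants, dtype=bool)
    if maf_min is not None or genotype_rate_min is not None:
        keep = variant_filters(matrix, maf_min or 0.0, genotype_rate_min or 0.0)
    groups = sorted({pop_map.group_of(s, level) for s in matrix.samples})
    out: list[GroupAF] = []
    for g in groups:
        rows = [i for i, s in enumerate(matrix.samples)
                if pop_map.group_of(s, level) == g]
        d = matrix.dosages[rows, :]
        nonmiss = d != MISSING
        an = 2 * nonmiss.sum(axis=0)
        ac = np.where(nonmiss, d, 0).sum(axis=0)
        for j in np.nonzero(keep)[0]:
            af = ac[j] / an[j] if an[j] else float("nan")
            out.append(GroupAF(matrix.variant_ids[j], g, int(ac[j]), int(an[j]), af))
    return out


def group_specific_svs(catalog: SVCatalog, pop_map: PopulationMap,
                       group_a: str, group_b: str, level: str = "ancestral",
                       common_af_min: float = 0.01
                       ) -> dict[str, list[str]]:
    """Partition SVs into A-specific, B-specific and shared by carrier status.

    "Carried" means a non-missing dosage >= 1; missing is not absence. The
    ``common_*`` lists additionally require AF >= `common_af_min` within the
    carrier group."""
    idx_a = [i for i, s in enumerate(catalog.samples)
             if pop_map.group_of(s, level) == group_a]
    idx_b = [i for i, s in enumerate(catalog.samples)
             if pop_map.group_of(s, level) == group_b]
    out = {"a_specific": [], "b_specific": [], "shared": [],
           "common_a_specific": [], "common_b_specific": []}
    for r in catalog.records:
        if r.genotypes is None:
            continue
        g = r.genotypes
        in_a = bool((g[idx_a] >= 1).any())
        in_b = bool((g[idx_b] >= 1).any())
        if in_a and in_b:
            out["shared"].append(r.id)
        elif in_a or in_b:
            rows, key = (idx_a, "a") if in_a else (idx_b, "b")
            out[f"{key}_specific"].append(r.id)
            sub = g[rows]
            nonmiss = sub != MISSING
            an = 2 * int(nonmiss.sum())
            af = int(sub[nonmiss].sum()) / an if an else 0.0
            if af >= common_af_min:
                out[f"common_{key}_specific"].append(r.id)
    return out


def _wc_theta_components(n1, p1, h1, n2, p2, h2):
    """Weir & Cockerham (1984) variance components a, b, c for two
    populations at one biallelic locus (vectorised over loci).

    n_i: diploid sample sizes; p_i: ALT allele frequencies; h_i: observed
    heterozygote frequencies."""
    r = 2.0
    nbar = (n1 + n2) / r
    # squared-coefficient-of-variation correction term
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def _wc_abc(matrix: GenotypeMatrix, pop_map: PopulationMap,
            pair: tuple[str, str], level: str):
    rows = {g: [i for i, s in enumerate(matrix.samples)
                if pop_map.group_of(s, level) == g] for g in pair}
    d1 = matrix.dosages[rows[pair[0]], :].astype(float)
    d2 = matrix.dosages[rows[pair[1]], :].astype(float)
    d1[matrix.dosages[rows[pair[0]], :] == MISSING] = np.nan
    d2[matrix.dosages[rows[pair[1]], :] == MISSING] = np.nan
    n1 = np.sum(~np.isnan(d1), axis=0).astype(float)
    n2 = np.sum(~np.isnan(d2), axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.nansum(d1, axis=0) / (2 * n1)
        p2 = np.nansum(d2, axis=0) / (2 * n2)
        h1 = np.sum(d1 == 1, axis=0) / n1
        h2 = np.sum(d2 == 1, axis=0) / n2
        a, b, c = _wc_theta_components(n1, p1, h1, n2, p2, h2)
    return a, b, c, n1, n2


def weir_cockerham_fst(matrix: GenotypeMatrix, pop_map: PopulationMap,
                       pair: tuple[str, str], level: str = "ancestral",
                       min_samples: int = 2) -> list[FstResult]:
    """Per-variant Weir & Cockerham (1984) theta-hat between two groups.

    Variants monomorphic across both groups, or with fewer than
    `min_samples` non-missing genotypes in either group, are skipped with a
    log entry. Estimates may be slightly negative at low differentiation."""
    a, b, c, n1, n2 = _wc_abc(matrix, pop_map, pair, level)
    denom = a + b + c
    out: list[FstResult] = []
    skipped = 0
    for j in range(matrix.n_variants):
        if n1[j] < min_samples or n2[j] < min_samples:
            skipped += 1
            continue
        if not np.isfinite(denom[j]) or denom[j] == 0:
            skipped += 1  # monomorphic across both groups
            continue
        out.append(FstResult(matrix.variant_ids[j], pair, float(a[j] / denom[j])))
    if skipped:
        log.info("weir_cockerham_fst: skipped %d undefined variants", skipped)
    return out


def weir_cockerham_fst_global(matrix: GenotypeMatrix, pop_map: PopulationMap,
                              pair: tuple[str, str], level: str = "ancestral",
                              min_samples: int = 2) -> float:
    """Multi-locus Weir & Cockerham theta-hat: the ratio of the summed
    variance components over all defined loci (the combination the
    estimator's authors prescribe; a per-locus average of ratios is biased
    toward zero, increasingly so at high differentiation)."""
    a, b, c, n1, n2 = _wc_abc(matrix, pop_map, pair, level)
    denom = a + b + c
    ok = ((n1 >= min_samples) & (n2 >= min_samples)
          & np.isfinite(denom) & (denom != 0))
    if not ok.any():
        return float("nan")
    return float(a[ok].sum() / denom[ok].sum())


def top_percentile(values: np.ndarray, q: float = 0.01
                   ) -> tuple[float, np.ndarray]:
    """Empirical top-q cut by nearest rank; returns (threshold, flag mask).

    All values >= the threshold are flagged, so ties at the cut are all
    included."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values")
    order = np.sort(values)
    idx = min(values.size - 1, math.ceil(values.size * (1 - q)))
    threshold = float(order[idx])
    return threshold, values >= threshold


def flag_top_fst(results: list[FstResult], q: float = 0.01) -> float:
    """Attach percentile ranks and top-q flags in place; returns the cut."""
    vals = np.array([r.fst for r in results])
    threshold, flags = top_percentile(vals, q)
    ranks = vals.argsort().argsort() / max(1, len(vals) - 1)
    for r, f, pc in zip(results, flags, ranks):
        r.flagged = bool(f)
        r.percentile = float(pc)
    return threshold


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float | None:
    """Squared Pearson correlation of two dosage vectors over samples
    non-missing at both; None if either is constant there."""
    mask = (x != MISSING) & (y != MISSING)
    if mask.sum() < 2:
        return None
    xa = x[mask].astype(float)
    ya = y[mask].astype(float)
    if xa.std() == 0 or ya.std() == 0:
        return None
    r = np.corrcoef(xa, ya)[0, 1]
    return float(r * r)


def assign_tier(r2: float) -> str:
    if r2 >= TIER_THRESHOLDS["highly_tagged"]:
        return "highly_tagged"
    if r2 >= TIER_THRESHOLDS["tagged"]:
        return "tagged"
    if r2 >= TIER_THRESHOLDS["linked"]:
        return "linked"
    return "none"


def ld_r2_window(matrix: GenotypeMatrix, window: int = 1_000_000,
                 min_r2: float = 0.0, kinds_a: tuple[str, ...] | None = None,
                 kinds_b: tuple[str, ...] | None = None) -> list[LinkageRecord]:
    """All same-chromosome pairwise r2 within `window` bp, over samples
    non-missing at both variants; pairs with r2 > `min_r2` are emitted with
    their tier. `kinds_a`/`kinds_b` restrict the two sides (e.g. SV vs SNP);
    zero-variance vectors skip the pair."""
    order = np.lexsort((matrix.positions, np.array(matrix.chroms, dtype=object)))
    out: list[LinkageRecord] = []
    chroms = [matrix.chroms[i] for i in order]
    pos = matrix.positions[order]
    for ii in range(len(order)):
        i = order[ii]
        for jj in range(ii + 1, len(order)):
            j = order[jj]
            if chroms[jj] != chroms[ii]:
                break
            dist = int(pos[jj] - pos[ii])
            if dist > window:
                break
            ka, kb = matrix.kinds[i], matrix.kinds[j]
            fwd = (kinds_a is None or ka in kinds_a) and (kinds_b is None or kb in kinds_b)
            rev = (kinds_a is None or kb in kinds_a) and (kinds_b is None or ka in kinds_b)
            if not (fwd or rev):
                continue
            r2 = _pairwise_r2(matrix.dosages[:, i], matrix.dosages[:, j])
            if r2 is None or not r2 > min_r2:
                continue
            a, b = (i, j) if fwd else (j, i)
            out.append(LinkageRecord(matrix.variant_ids[a], matrix.variant_ids[b],
                                     dist, r2, assign_tier(r2)))
    return out


def tier_sets(records: list[LinkageRecord]) -> dict[str, set[tuple[str, str]]]:
    """Nested pair sets by tier: highly_tagged <= tagged <= linked."""
    out = {t: set() for t in TIER_THRESHOLDS}
    for rec in records:
        for tier, thr in TIER_THRESHOLDS.items():
            if rec.r2 >= thr:
                out[tier].add((rec.id_a, rec.id_b))
    return out


def thin_variants(positions: np.ndarray, chroms: list[str] | None = None,
                  min_gap: int = 1000) -> np.ndarray:
    """Greedy first-kept positional thinning, per chromosome in position
    order: keep a variant iff it lies >= `min_gap` from the last kept one.
    Returns indices into the input arrays."""
    positions = np.asarray(positions)
    if chroms is None:
        chroms = ["_"] * len(positions)
    kept: list[int] = []
    order = np.lexsort((positions, np.array(chroms, dtype=object)))
    last: dict[str, int] = {}
    for i in order:
        c = chroms[i]
        if c not in last or positions[i] - last[c] >= min_gap:
            kept.append(int(i))
            last[c] = int(positions[i])
    return np.array(sorted(kept), dtype=int)


def build_functional_network(catalog: SVCatalog, linkage: list[LinkageRecord],
                             functional: FunctionalVariantCatalog,
                             genes: list[GeneModel], *,
                             r2_min: float = 0.2, max_distance: int = 1_000_000,
                             gwas_p_max: float = 5e-8, twas_fdr_max: float = 0.05,
                             gene_flank: int = 5000) -> nx.Graph:
    """Assemble the SV / functional-SNP / gene / trait network.

    LD edges keep only SV-SNP pairs with r2 >= 0.2 within 1 Mb whose SNP is a
    functional variant passing its threshold (GWAS p <= 5e-8; e/sQTLs are
    lead variants as given). TWAS genes need FDR <= 0.05 and must also be an
    e/sGene. SV-gene edges record direct or +-5 kb-extended body overlap."""
    g = nx.Graph()
    for r in catalog.records:
        g.add_node(r.id, kind="SV", svtype=r.svtype)

    by_pos: dict[tuple[str, int], list[dict]] = {}
    for rec in functional.records:
        if rec["kind"] in ("eQTL", "sQTL", "GWAS"):
            by_pos.setdefault((str(rec["chrom"]), int(rec["pos"])), []).append(rec)

    snp_coords: dict[str, tuple[str, int]] = {}
    sv_ids = set(catalog.ids())
    for lr in linkage:
        if lr.r2 < r2_min or lr.distance > max_distance:
            continue
        sv_id, snp_id = (lr.id_a, lr.id_b) if lr.id_a in sv_ids else (lr.id_b, lr.id_a)
        if sv_id not in sv_ids:
            continue
        # SNP ids in this package are "chrom:pos:SNP"
        parts = snp_id.split(":")
        key = (parts[0], int(parts[1]))
        snp_coords[snp_id] = key
        funcs = [rec for rec in by_pos.get(key, ())
                 if rec["kind"] != "GWAS" or rec["p"] <= gwas_p_max]
        if not funcs:
            continue
        g.add_node(snp_id, kind="SNP",
                   functional_kinds=sorted({f["kind"] for f in funcs}))
        g.add_edge(sv_id, snp_id, kind="LD", r2=lr.r2,
                   distance=lr.distance, tier=assign_tier(lr.r2))
        for f in funcs:
            if f["kind"] in ("eQTL", "sQTL"):
                gid = f["gene_id"]
                g.add_node(gid, kind="gene")
                g.add_edge(snp_id, gid, kind=f["kind"], tissue=f.get("tissue"))
            elif f["kind"] == "GWAS":
                trait = f["trait"]
                g.add_node(trait, kind="trait")
                g.add_edge(snp_id, trait, kind="GWAS", p=f["p"])

    esgenes = {f["gene_id"] for f in functional.records if f["kind"] in ("eQTL", "sQTL")}
    for f in functional.of_kind("TWAS"):
        if f["fdr"] <= twas_fdr_max and f["gene_id"] in esgenes:
            g.add_node(f["gene_id"], kind="gene")
            g.add_node(f["trait"], kind="trait")
            g.add_edge(f["gene_id"], f["trait"], kind="TWAS", fdr=f["fdr"])

    network_genes = {n for n, data in g.nodes(data=True) if data.get("kind") == "gene"}
    gene_models = {gm.gene_id: gm for gm in genes}
    for gid in network_genes:
        gm = gene_models.get(gid)
        if gm is None:
            continue
        for r in catalog.records:
            if (r.chrom == gm.chrom and r.start <= gm.end + gene_flank
                    and r.end >= gm.start - gene_flank):
                direct = r.start <= gm.end and r.end >= gm.start
                g.add_edge(r.id, gid, kind="overlap",
                           relation="direct" if direct else "extended")
    return g


def network_summary(g: nx.Graph) -> dict:
    """Tallies mirroring the published reporting: SVs with >= 1 linked
    functional SNP, split by functional kind, and multi-kind SVs."""
    svs = [n for n, d in g.nodes(data=True) if d.get("kind") == "SV"]
    by_kind = {"eQTL": set(), "sQTL": set(), "GWAS": set()}
    linked_svs = set()
    for sv in svs:
        for nb in g.neighbors(sv):
            if g.nodes[nb].get("kind") != "SNP":
                continue
            linked_svs.add(sv)
            for k in g.nodes[nb].get("functional_kinds", ()):
                by_kind[k].add(sv)
    multi = {sv for sv in linked_svs
             if sum(sv in s for s in by_kind.values()) > 1}
    return {
        "n_svs": len(svs),
        "n_svs_linked_functional": len(linked_svs),
        "n_svs_eqtl": len(by_kind["eQTL"]),
        "n_svs_sqtl": len(by_kind["sQTL"]),
        "n_svs_gwas": len(by_kind["GWAS"]),
        "n_svs_multi_kind": len(multi),
    }
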