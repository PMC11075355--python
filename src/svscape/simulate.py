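"""Synthetic multi-population SV+SNP worlds with known ground truth.

The generator emulates the structure of a short-read pig SV catalog at desk
scale: a small multi-chromosome genome with assembly gaps; non-overlapping
gene models with exon/CDS/UTR structure (a fraction non-coding); repeat,
chromatin-state and QTL tracks; a seven-population panel whose allele
frequencies follow the Balding-Nichols model (Beta-distributed around an
ancestral frequency with differentiation parameter F); SVs planted to
realise specific impact categories; SNPs coupled to chosen SVs by allele
copying with distance-decaying fidelity (an LD stand-in, not a coalescent);
a 100-bp copy-number window matrix with planted high-CN "bad bins"; and a
functional-variant catalog with known pass/fail records.

Every random draw flows from one seed through named SeedSequence children,
so identical configurations give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import (
    FeatureTrack,
    FunctionalVariantCatalog,
    GeneModel,
    GenomeModel,
    GenotypeMatrix,
    PopulationMap,
    SVCatalog,
    SVRecord,
    Transcript,
)
from .qc import CNWindowMatrix

CHROMATIN_STATES = (
    "TssA", "TssAHet", "TxFlnk", "TxFlnkWk", "TxFlnkHet", "EnhA", "EnhAMe",
    "EnhAWk", "EnhAHet", "EnhPois", "ATAC_Is", "TssBiv", "Repr", "ReprWk", "Qui",
)
REPEAT_CLASSES = ("SINE", "LINE", "LTR", "satellite")

# gene geometry (bp offsets from the gene start); four exons, three introns
_EXON = 400
_INTRON = 1500
_GENE_SPAN = 4 * _EXON + 3 * _INTRON  # 6100


@dataclass
class SimulationConfig:
    """Tunable world description; defaults are the package's stated scale.

    SV counts default to the published per-type proportions (DEL : MEI :
    DUP : INV : BND of roughly 42k:38k:3k:2k:45k) scaled to a 200-event
    desk catalog; the panel is the seven main populations scaled to 100
    individuals at their published shares; F defaults to 0.2, a typical
    Asian/European pig differentiation level."""

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"1": 4_000_000, "2": 4_000_000})
    n_genes: int = 160
    noncoding_gene_fraction: float = 0.125
    gene_spacing: int = 40_000
    first_gene_start: int = 100_000
    population_sizes: dict[str, int] = field(default_factory=lambda: {
        "ASW": 5, "ASD": 41, "ASxEU": 2, "EUC": 39, "EUD": 8, "EUW": 2, "OTG": 3})
    bn_f: float = 0.2
    sv_counts: dict[str, int] = field(default_factory=lambda: {
        "DEL": 65, "MEI": 58, "DUP": 5, "INV": 2, "BND": 70})
    n_snps: int = 200
    n_coupled_svs: int = 10
    coupling_offsets: tuple[int, ...] = (500, 5_000, 50_000)
    coupling_fidelity: float = 0.95
    coupling_decay: float | None = 100_000.0
    n_group_specific: int = 6
    cn_window: int = 100
    n_bad_bins: int = 3
    bad_bin_sample_fraction: float = 0.95
    n_tissues: int = 3
    state_segment: int = 2_000
    n_repeats_random: int = 30
    n_traits: int = 8
    qtls_per_trait: int = 6
    n_large_qtls: int = 2
    eqtl_fraction: float = 0.25
    sqtl_fraction: float = 0.15
    gwas_fraction: float = 0.30
    include_qc_victims: bool = True
    include_reclass_cases: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.bn_f < 1.0):
            raise ValueError("Balding-Nichols F must lie in [0, 1)")
        for name, v in (("gene_spacing", self.gene_spacing),
                        ("n_genes", self.n_genes), ("cn_window", self.cn_window)):
            if v <= 0:
                raise ValueError(f"{name} must be positive")

    def rngs(self, *names: str) -> dict[str, np.random.Generator]:
        """Named child generators off the single master seed."""
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class GroundTruth:
    """Everything the pipeline is expected to recover."""

    impact: dict[tuple[str, str | None], str] = field(default_factory=dict)
    group_specific: dict[str, str] = field(default_factory=dict)  # sv_id -> AS|EU
    f_per_population: dict[str, float] = field(default_factory=dict)
    bad_bins: list[tuple[str, int, int]] = field(default_factory=list)
    coupling: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    mei_reclass: dict[str, bool] = field(default_factory=dict)  # DEL id -> becomes MEI
    qc_fail: dict[str, str] = field(default_factory=dict)       # sv_id -> reason
    masked: list[str] = field(default_factory=list)             # fully masked sv ids


@dataclass
class SimulatedWorld:
    config: SimulationConfig
    genome: GenomeModel
    genes: list[GeneModel]
    repeats: FeatureTrack
    states: FeatureTrack
    qtls: FeatureTrack
    catalog: SVCatalog
    snps: GenotypeMatrix
    pop_map: PopulationMap
    cn: CNWindowMatrix
    functional: FunctionalVariantCatalog
    truth: GroundTruth


# ----------------------------------------------------------------------
# genome, genes, tracks


def _make_gene(gene_id: str, chrom: str, start: int, coding: bool) -> GeneModel:
    s = start
    if not coding:
        exons = [(s, s + _EXON - 1), (s + 1900, s + 1900 + _EXON - 1)]
        return GeneModel(gene_id, chrom, s, s + 2299, "+", biotype="lncRNA",
                         transcripts=[Transcript(f"{gene_id}.t1", exons=exons)])
    exons = [(s + k * (_EXON + _INTRON), s + k * (_EXON + _INTRON) + _EXON - 1)
             for k in range(4)]
    utr5 = [(s, s + 199)]
    cds = [(s + 200, s + 399), exons[1], exons[2], (exons[3][0], exons[3][0] + 199)]
    utr3 = [(exons[3][0] + 200, exons[3][1])]
    return GeneModel(gene_id, chrom, s, s + _GENE_SPAN - 1, "+",
                     transcripts=[Transcript(f"{gene_id}.t1", exons=exons,
                                             cds=cds, utr5=utr5, utr3=utr3)])


def simulate_genome_and_tracks(config: SimulationConfig
                               ) -> tuple[GenomeModel, list[GeneModel],
                                          FeatureTrack, FeatureTrack, FeatureTrack]:
    """Genome + gaps, gene models, repeat / chromatin-state / QTL tracks."""
    rng = config.rngs("tracks")["tracks"]
    gaps = [(c, 5_000, 6_000) for c in config.chrom_lengths]
    genome = GenomeModel(dict(config.chrom_lengths), gaps=gaps)

    chroms = list(config.chrom_lengths)
    slots: list[tuple[str, int]] = []  # candidate gene starts
    for c in chroms:
        pos = config.first_gene_start
        while pos + _GENE_SPAN + config.gene_spacing < config.chrom_lengths[c] - 50_000:
            slots.append((c, pos))
            pos += config.gene_spacing
    if config.n_genes > len(slots):
        raise ValueError(f"n_genes={config.n_genes} exceeds {len(slots)} gene slots")
    n_nc = int(round(config.noncoding_gene_fraction * config.n_genes))
    # non-coding genes occupy the first slots so they are easy to find again
    genes = [_make_gene(f"G{i:04d}", c, s, coding=i >= n_nc)
             for i, (c, s) in enumerate(slots[: config.n_genes])]

    repeats = _repeat_track(config, rng)
    states = _state_track(config, rng)
    qtls = _qtl_track(config, rng)
    return genome, genes, repeats, states, qtls


def _repeat_track(config: SimulationConfig, rng: np.random.Generator) -> FeatureTrack:
    ivs: list[tuple[str, int, int, str, str | None]] = []
    # fixed repeat zone on the first chromosome: substrate for the DEL->MEI cases
    c0 = next(iter(config.chrom_lengths))
    ivs += [
        (c0, 41_001, 41_250, "SINE", None),
        (c0, 50_001, 57_500, "LINE", None),
        (c0, 60_001, 61_000, "LTR", None),
        (c0, 65_001, 66_500, "satellite", None),
    ]
    # scattered repeats in intergenic space, SINE ~250 bp / LINE ~7.5 kb modes
    chroms = list(config.chrom_lengths)
    for _ in range(config.n_repeats_random):
        c = chroms[rng.integers(len(chroms))]
        base = int(rng.integers(config.first_gene_start,
                                config.chrom_lengths[c] - 60_000))
        # snap into the +25..+32.5 kb window of a gene-spacing block (intergenic)
        block = (base - config.first_gene_start) // config.gene_spacing
        start = config.first_gene_start + block * config.gene_spacing + _GENE_SPAN + 19_000
        cls = REPEAT_CLASSES[int(rng.integers(len(REPEAT_CLASSES)))]
        length = {"SINE": 250, "LINE": 7_500, "LTR": 1_000, "satellite": 1_500}[cls]
        length = max(50, int(length * float(rng.lognormal(0.0, 0.1))))
        ivs.append((c, start, min(start + length - 1, config.chrom_lengths[c]), cls, None))
    return FeatureTrack("repeats", REPEAT_CLASSES, ivs)


def _state_track(config: SimulationConfig, rng: np.random.Generator) -> FeatureTrack:
    """Per-tissue 15-state segmentation tiling every base exactly once."""
    ivs = []
    p = np.full(len(CHROMATIN_STATES), 0.5 / (len(CHROMATIN_STATES) - 1))
    p[CHROMATIN_STATES.index("Qui")] = 0.5  # quiescent dominates real segmentations
    for t in range(config.n_tissues):
        tissue = f"tissue_{t}"
        for c, length in config.chrom_lengths.items():
            pos = 1
            while pos <= length:
                end = min(pos + config.state_segment - 1, length)
                lab = CHROMATIN_STATES[int(rng.choice(len(CHROMATIN_STATES), p=p))]
                ivs.append((c, pos, end, lab, tissue))
                pos = end + 1
    return FeatureTrack("chromatin_states", CHROMATIN_STATES, ivs)


def _qtl_track(config: SimulationConfig, rng: np.random.Generator) -> FeatureTrack:
    traits = tuple(f"trait_{k}" for k in range(config.n_traits))
    ivs = []
    chroms = list(config.chrom_lengths)
    for k, trait in enumerate(traits):
        for _ in range(config.qtls_per_trait):
            c = chroms[int(rng.integers(len(chroms)))]
            length = int(np.clip(rng.lognormal(math.log(50_000), 0.8), 10_000, 900_000))
            start = int(rng.integers(50_000, config.chrom_lengths[c] - length - 50_000))
            ivs.append((c, start, start + length - 1, trait, None))
    for j in range(config.n_large_qtls):  # exercise the 1 Mb filter
        c = chroms[j % len(chroms)]
        ivs.append((c, 200_000, 200_000 + 1_200_000 - 1, traits[j % len(traits)], None))
    return FeatureTrack("qtls", traits, ivs)


# ----------------------------------------------------------------------
# SV planting

# per-type category schedules; cycled to fill the configured counts
_SCHEDULES = {
    "DEL": ("intergenic", "intron", "pLoF_St", "intergenic", "Rglt3_Wk", "pLoF_Wk",
            "intergenic", "Rglt5_St", "WlGnDel", "intron", "Rglt5_Wk", "intergenic",
            "Rglt3_St", "noncoding"),
    "MEI": ("intron", "intergenic", "Rglt3_St", "intergenic", "pLoF_St", "intergenic"),
    "DUP": ("intergenic", "CpGn_St", "CpGn_Wk", "WlGnDup", "intron"),
    "INV": ("codInv", "WlGnInv", "intron", "intergenic"),
    "BND": ("intergenic", "codBnd", "intron"),
}

_GENE_TARGETED = {"WlGnDel", "WlGnDup", "WlGnInv", "pLoF_St", "pLoF_Wk", "CpGn_St",
                  "CpGn_Wk", "codInv", "codBnd", "Rglt5_St", "Rglt5_Wk", "Rglt3_St",
                  "Rglt3_Wk", "intron", "noncoding"}


def _placement(svtype: str, category: str, gene: GeneModel | None,
               slot: tuple[str, int] | None,
               rng: np.random.Generator) -> tuple[str, int, int, int | None]:
    """Coordinates (chrom, start, end, mate_pos) realising a category."""
    if category == "intergenic":
        chrom, base = slot
        if svtype == "BND":
            return chrom, base, base, base + 5_000
        length = int(np.clip(rng.lognormal(math.log(700), 1.0), 60, 7_000))
        return chrom, base, base + length - 1, None
    s = gene.start
    if category in ("WlGnDel", "WlGnDup", "WlGnInv"):
        return gene.chrom, s - 500, gene.end + 500, None
    if category in ("pLoF_St", "CpGn_St"):
        return gene.chrom, s + 1900, s + 2299, None          # 400 bp, all CDS
    if category in ("pLoF_Wk", "CpGn_Wk"):
        return gene.chrom, s + 1000, s + 2099, None          # 200/1100 = 18.2% CDS
    if category == "codInv":
        return gene.chrom, s + 1850, s + 2350, None
    if category == "codBnd":
        return gene.chrom, s + 2000, s + 2000, s + 7_000
    if category == "Rglt5_St":
        return gene.chrom, s - 100, s + 99, None             # 100/200 = 50% 5'UTR
    if category == "Rglt5_Wk":
        return gene.chrom, s - 900, s + 99, None             # 100/1000 = 10%
    if category == "Rglt3_St":
        return gene.chrom, s + 6000, s + 6199, None          # 100/200 = 50% 3'UTR
    if category == "Rglt3_Wk":
        return gene.chrom, s + 6000, s + 7099, None          # 100/1100 = 9.1%
    if category == "intron":
        if svtype == "BND":
            return gene.chrom, s + 2500, s + 2500, s + 7_500
        return gene.chrom, s + 2400, s + 2899, None          # inside intron 2
    if category == "noncoding":
        return gene.chrom, s + 100, s + 299, None            # exon of a lncRNA gene
    raise ValueError(f"no placement rule for {category}")


_MSQ = {"DEL": 200.0, "MEI": 200.0, "DUP": 150.0, "INV": 200.0, "BND": 300.0}


@dataclass
class _PlannedSV:
    chrom: str
    start: int
    end: int
    svtype: str
    category: str | None
    gene_id: str | None
    mate_pos: int | None = None
    group: str | None = None          # AS | EU for planted group-specific events
    qc_fail: str | None = None
    masked: bool = False
    min_size_95: int | None = None
    msq: float | None = None
    ab_override: float | None = None
    no_sr: bool = False
    mei_truth: bool | None = None     # for repeat-zone DELs

    @property
    def sv_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.svtype}"


def _plan_svs(config: SimulationConfig, genes: list[GeneModel]) -> list[_PlannedSV]:
    rng = config.rngs("plant")["plant"]
    coding = [g for g in genes if g.biotype == "protein_coding"]
    noncoding = [g for g in genes if g.biotype != "protein_coding"]
    gene_iter = iter(coding)
    nc_iter = iter(noncoding)
    # intergenic slots: one per gene-spacing block, offset +12 kb past the gene
    slots = [(g.chrom, g.start + _GENE_SPAN + 6_000) for g in genes]
    slot_iter = iter(slots)

    planned: list[_PlannedSV] = []
    for svtype, n in config.sv_counts.items():
        schedule = _SCHEDULES[svtype]
        for k in range(n):
            category = schedule[k % len(schedule)]
            gene = None
            slot = None
            if category == "intergenic":
                slot = next(slot_iter, None)
                if slot is None:
                    raise ValueError("ran out of intergenic slots; enlarge the genome")
            elif category == "noncoding":
                gene = next(nc_iter, None)
                if gene is None:
                    category = "intron"
                    gene = next(gene_iter)
            else:
                gene = next(gene_iter, None)
                if gene is None:
                    raise ValueError("ran out of genes; raise n_genes or shrink sv_counts")
            chrom, start, end, mate = _placement(svtype, category, gene, slot, rng)
            planned.append(_PlannedSV(
                chrom, start, end, svtype, category,
                gene.gene_id if gene is not None and category != "intergenic" else None,
                mate_pos=mate, msq=_MSQ[svtype]))

    c0 = next(iter(config.chrom_lengths))
    if config.include_reclass_cases:
        # inside the fixed LINE (100% covered) -> reclassifies; 83% covered -> stays
        planned.append(_PlannedSV(c0, 50_100, 50_399, "DEL", "intergenic", None,
                                  msq=_MSQ["DEL"], mei_truth=True))
        planned.append(_PlannedSV(c0, 40_956, 41_255, "DEL", "intergenic", None,
                                  msq=_MSQ["DEL"], mei_truth=False))
    if config.include_qc_victims:
        planned += [
            _PlannedSV(c0, 4_900, 5_050, "DEL", None, None, msq=200.0,
                       qc_fail="gap_overlap"),
            _PlannedSV(c0, 30_050, 30_400, "DEL", None, None, msq=200.0,
                       qc_fail="bad_bin_overlap"),
            _PlannedSV(c0, 8_000, 8_030, "DEL", None, None, msq=200.0,
                       qc_fail="min_length"),
            _PlannedSV(c0, 9_000, 9_800, "DEL", None, None, msq=120.0, no_sr=True,
                       qc_fail="type_filters"),
            _PlannedSV(c0, 10_000, 10_000, "BND", None, None, mate_pos=12_000,
                       msq=250.0, qc_fail="type_filters"),
            _PlannedSV(c0, 12_000, 13_000, "INV", None, None, msq=200.0,
                       ab_override=0.05, qc_fail="type_filters"),
            _PlannedSV(c0, 15_000, 15_119, "DEL", None, None, msq=200.0,
                       min_size_95=150, masked=True),
        ]
    return planned


# ----------------------------------------------------------------------
# genotypes


def balding_nichols_frequencies(p_ancestral: np.ndarray, f: float,
                                rng: np.random.Generator) -> np.ndarray:
    """Population allele frequencies ~ Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    p = np.asarray(p_ancestral, dtype=float)
    if f == 0.0:
        return p.copy()
    a = p * (1 - f) / f
    b = (1 - p) * (1 - f) / f
    return rng.beta(a, b)


def balding_nichols_panel(seed: int, f: float, n_per_group: int, n_variants: int,
                          groups: tuple[str, str] = ("ASD", "EUC")
                          ) -> tuple[GenotypeMatrix, PopulationMap, np.ndarray]:
    """Two-population Balding-Nichols panel with known F; returns the
    genotype matrix, population map and the ancestral frequencies."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    p_anc = rng.uniform(0.05, 0.95, size=n_variants)
    dosages = np.zeros((2 * n_per_group, n_variants), dtype=np.int8)
    for k in range(2):
        p_pop = balding_nichols_frequencies(p_anc, f, rng)
        dosages[k * n_per_group:(k + 1) * n_per_group, :] = rng.binomial(
            2, p_pop[None, :], size=(n_per_group, n_variants)).astype(np.int8)
    samples = tuple(f"{groups[k]}_{i:04d}" for k in range(2) for i in range(n_per_group))
    pmap = PopulationMap(main={s: s.split("_")[0] for s in samples})
    matrix = GenotypeMatrix(
        dosages, samples,
        variant_ids=tuple(f"1:{1000 * (j + 1)}:SNP" for j in range(n_variants)),
        chroms=tuple("1" for _ in range(n_variants)),
        positions=np.arange(1, n_variants + 1) * 1000,
        kinds=tuple("SNP" for _ in range(n_variants)))
    return matrix, pmap, p_anc


def _simulate_genotype_rows(planned: list[_PlannedSV], config: SimulationConfig,
                            samples: list[str], pop_of: dict[str, str],
                            rng: np.random.Generator,
                            truth: GroundTruth) -> dict[str, np.ndarray]:
    """Dosages per planted SV under Balding-Nichols, with group-specific
    events forced absent outside their carrier group."""
    pops = list(config.population_sizes)
    rows: dict[str, np.ndarray] = {}
    # choose group-specific candidates among robust intron/intergenic DEL/MEI
    candidates = [p for p in planned
                  if p.qc_fail is None and not p.masked and p.mei_truth is None
                  and p.category in ("intron", "intergenic")
                  and p.svtype in ("DEL", "MEI")]
    n_gs = min(config.n_group_specific, len(candidates))
    gs_targets = {candidates[i].sv_id: ("AS" if i % 2 == 0 else "EU")
                  for i in range(n_gs)}
    as_pops, eu_pops = {"ASW", "ASD"}, {"EUC", "EUD", "EUW"}
    for p in planned:
        g = np.zeros(len(samples), dtype=np.int8)
        group = gs_targets.get(p.sv_id)
        p_anc = float(rng.uniform(0.05, 0.95))
        for pop in pops:
            idx = [i for i, s in enumerate(samples) if pop_of[s] == pop]
            if not idx:
                continue
            if group is not None:
                allowed = as_pops if group == "AS" else eu_pops
                if pop not in allowed:
                    continue  # forced absent (dosage 0)
                p_pop = float(rng.uniform(0.15, 0.45))
            else:
                p_pop = float(balding_nichols_frequencies(
                    np.array([p_anc]), config.bn_f, rng)[0])
            g[idx] = rng.binomial(2, p_pop, size=len(idx)).astype(np.int8)
        if not (g >= 1).any():  # every event must have a carrier
            i = 0
            if group is not None:
                allowed = as_pops if group == "AS" else eu_pops
                i = next(i for i, s in enumerate(samples) if pop_of[s] in allowed)
            g[i] = 1
        if group is not None:
            truth.group_specific[p.sv_id] = group
            p.group = group
        rows[p.sv_id] = g
    return rows


def simulate_population_genotypes(config: SimulationConfig,
                                  genes: list[GeneModel],
                                  truth: GroundTruth
                                  ) -> tuple[SVCatalog, GenotypeMatrix, PopulationMap]:
    """Planted SV catalog with genotypes, coupled+background SNP matrix,
    population map. Fills `truth` in place."""
    rngs = config.rngs("genotypes", "snps")
    rng = rngs["genotypes"]
    samples = [f"{pop}_{i:03d}" for pop, n in config.population_sizes.items()
               for i in range(n)]
    pop_of = {s: s.rsplit("_", 1)[0] for s in samples}
    pop_map = PopulationMap(main=pop_of)
    truth.f_per_population = {p: config.bn_f for p in config.population_sizes}

    planned = _plan_svs(config, genes)
    rows = _simulate_genotype_rows(planned, config, samples, pop_of, rng, truth)

    records = []
    for p in planned:
        g = rows[p.sv_id]
        carriers = g >= 1
        sr = np.where(carriers, 2, 0).astype(np.int64)
        if p.no_sr:
            sr[:] = 0
        ab = np.where(carriers, 0.5 if p.ab_override is None else p.ab_override,
                      np.nan)
        records.append(SVRecord(
            id=p.sv_id, chrom=p.chrom, start=p.start, end=p.end, svtype=p.svtype,
            msq=p.msq, genotypes=g, sr_support=sr, allele_balance=ab,
            min_size_95=p.min_size_95,
            mate_chrom=p.chrom if p.mate_pos is not None else None,
            mate_pos=p.mate_pos))
        if p.qc_fail is not None:
            truth.qc_fail[p.sv_id] = p.qc_fail
        elif p.masked:
            truth.masked.append(p.sv_id)
        elif p.mei_truth is not None:
            truth.mei_reclass[p.sv_id] = p.mei_truth
            # reclassification rewrites the id suffix DEL -> MEI
            final_id = p.sv_id[:-3] + "MEI" if p.mei_truth else p.sv_id
            truth.impact[(final_id, None)] = "intergenic"
        elif p.category is not None:
            truth.impact[(p.sv_id, p.gene_id)] = p.category
    catalog = SVCatalog(records, tuple(samples), notes=["synthetic catalog"])

    snps = _simulate_snps(config, catalog, samples, pop_of, rngs["snps"], truth)
    return catalog, snps, pop_map


def _simulate_snps(config: SimulationConfig, catalog: SVCatalog,
                   samples: list[str], pop_of: dict[str, str],
                   rng: np.random.Generator, truth: GroundTruth) -> GenotypeMatrix:
    pops = list(config.population_sizes)
    ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    cols: list[np.ndarray] = []
    used: set[tuple[str, int]] = set()

    def bn_column() -> np.ndarray:
        g = np.zeros(len(samples), dtype=np.int8)
        p_anc = float(rng.uniform(0.05, 0.95))
        for pop in pops:
            idx = [i for i, s in enumerate(samples) if pop_of[s] == pop]
            p_pop = float(balding_nichols_frequencies(
                np.array([p_anc]), config.bn_f, rng)[0])
            g[idx] = rng.binomial(2, p_pop, size=len(idx)).astype(np.int8)
        return g

    # SNPs coupled to chosen SVs: each haplotype copies the SV allele with
    # fidelity decaying over distance, else falls back to a background draw
    coupled_svs = [r for r in catalog.records
                   if r.svtype in ("DEL", "MEI") and r.id in
                   {k[0] for k in truth.impact} and r.id not in truth.group_specific]
    coupled_svs = coupled_svs[: config.n_coupled_svs]
    for sv in coupled_svs:
        truth.coupling[sv.id] = []
        for off in config.coupling_offsets:
            pos = sv.start + off
            key = (sv.chrom, pos)
            if key in used:
                continue
            used.add(key)
            fid = config.coupling_fidelity
            if config.coupling_decay is not None:
                fid *= math.exp(-off / config.coupling_decay)
            bg = bn_column()
            g_sv = sv.genotypes
            snp = np.zeros(len(samples), dtype=np.int8)
            for i in range(len(samples)):
                sv_alleles = (1 if g_sv[i] >= 1 else 0, 1 if g_sv[i] == 2 else 0)
                bg_alleles = (1 if bg[i] >= 1 else 0, 1 if bg[i] == 2 else 0)
                snp[i] = sum(sv_alleles[h] if rng.random() < fid else bg_alleles[h]
                             for h in range(2))
            snp_id = f"{sv.chrom}:{pos}:SNP"
            ids.append(snp_id)
            chroms.append(sv.chrom)
            positions.append(pos)
            cols.append(snp)
            truth.coupling[sv.id].append((snp_id, fid))

    chrom_names = list(config.chrom_lengths)
    n_target = len(cols) + config.n_snps  # coupled SNPs plus background SNPs
    while len(cols) < n_target:
        c = chrom_names[int(rng.integers(len(chrom_names)))]
        pos = int(rng.integers(100_000, config.chrom_lengths[c] - 100_000))
        if (c, pos) in used:
            continue
        used.add((c, pos))
        ids.append(f"{c}:{pos}:SNP")
        chroms.append(c)
        positions.append(pos)
        cols.append(bn_column())

    dosages = np.stack(cols, axis=1) if cols else np.zeros((len(samples), 0), np.int8)
    return GenotypeMatrix(dosages, tuple(samples), tuple(ids), tuple(chroms),
                          np.array(positions, dtype=np.int64),
                          tuple("SNP" for _ in ids))


# ----------------------------------------------------------------------
# copy-number windows, functional catalog, assembly truth


def simulate_cn_matrix(config: SimulationConfig, genome: GenomeModel,
                       samples: tuple[str, ...], truth: GroundTruth
                       ) -> CNWindowMatrix:
    """Background CN ~ Normal(2, 0.3) truncated at 0, with `n_bad_bins`
    windows set above the detection threshold in >= 90% of samples."""
    rng = config.rngs("cn")["cn"]
    w = config.cn_window
    chroms: list[str] = []
    starts: list[int] = []
    for c, length in genome.lengths.items():
        n = math.ceil(length / w)
        chroms.extend([c] * n)
        starts.extend(range(1, n * w, w))
    values = np.clip(rng.normal(2.0, 0.3, size=(len(chroms), len(samples))),
                     0.0, None).astype(np.float32)
    c0 = next(iter(genome.lengths))
    n_high = math.ceil(config.bad_bin_sample_fraction * len(samples))
    first = 30_000 // w  # windows covering 30_001.. on the first chromosome
    offset = chroms.index(c0)
    for b in range(config.n_bad_bins):
        i = offset + first + b
        values[i, :n_high] = 12.0
        truth.bad_bins.append((c0, int(starts[i]), int(starts[i]) + w - 1))
    return CNWindowMatrix(window_size=w, chroms=tuple(chroms),
                          starts=np.array(starts), values=values,
                          samples=tuple(samples))


def simulate_functional_catalog(config: SimulationConfig, snps: GenotypeMatrix,
                                genes: list[GeneModel]
                                ) -> FunctionalVariantCatalog:
    """Label SNP subsets as e/sQTLs (target = nearest gene), GWAS loci with a
    spiked sub-threshold p-value subset, and TWAS records for a subset of
    e/sGenes with FDR on both sides of 0.05."""
    rng = config.rngs("functional")["functional"]
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    def nearest_gene(chrom: str, pos: int) -> str | None:
        cands = by_chrom.get(chrom)
        if not cands:
            return None
        return min(cands, key=lambda g: min(abs(g.start - pos), abs(g.end - pos))).gene_id

    tissues = [f"tissue_{t}" for t in range(config.n_tissues)]
    traits = [f"trait_{k}" for k in range(config.n_traits)]
    records: list[dict] = []
    esgenes: set[str] = set()
    for j in range(snps.n_variants):
        u = rng.random()
        chrom, pos = snps.chroms[j], int(snps.positions[j])
        gid = nearest_gene(chrom, pos)
        if u < config.eqtl_fraction and gid:
            records.append({"kind": "eQTL", "id": snps.variant_ids[j], "chrom": chrom,
                            "pos": pos, "gene_id": gid,
                            "tissue": tissues[int(rng.integers(len(tissues)))]})
            esgenes.add(gid)
        elif u < config.eqtl_fraction + config.sqtl_fraction and gid:
            records.append({"kind": "sQTL", "id": snps.variant_ids[j], "chrom": chrom,
                            "pos": pos, "gene_id": gid,
                            "tissue": tissues[int(rng.integers(len(tissues)))]})
            esgenes.add(gid)
        if rng.random() < config.gwas_fraction:
            p = 1e-9 if rng.random() < 0.5 else float(rng.uniform(1e-5, 1.0))
            records.append({"kind": "GWAS", "id": snps.variant_ids[j], "chrom": chrom,
                            "pos": pos, "trait": traits[int(rng.integers(len(traits)))],
                            "p": p})
    for k, gid in enumerate(sorted(esgenes)):
        records.append({"kind": "TWAS", "gene_id": gid,
                        "trait": traits[k % len(traits)],
                        "tissue": tissues[k % len(tissues)],
                        "fdr": 0.01 if k % 2 == 0 else 0.30})
    return FunctionalVariantCatalog(records)


def simulate_assembly_truth(catalog: SVCatalog, seed: int,
                            detect_fraction: float = 0.8,
                            length_jitter: float = 0.01) -> list[SVRecord]:
    """Assembly-comparison truth set: a fraction of the catalog re-observed
    with +-`length_jitter` relative length noise at the end coordinate."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    out = []
    for k, r in enumerate(catalog.records):
        if r.svtype == "BND" or rng.random() > detect_fraction:
            continue
        delta = int(round(r.length * rng.uniform(-length_jitter, length_jitter)))
        end = max(r.start, r.end + delta)
        out.append(SVRecord(id=f"asm_{k:05d}", chrom=r.chrom, start=r.start,
                            end=end, svtype=r.svtype))
    return out


def simulate_world(config: SimulationConfig) -> SimulatedWorld:
    """Generate the complete synthetic world with its ground truth."""
    genome, genes, repeats, states, qtls = simulate_genome_and_tracks(config)
    truth = GroundTruth()
    catalog, snps, pop_map = simulate_population_genotypes(config, genes, truth)
    cn = simulate_cn_matrix(config, genome, catalog.samples, truth)
    functional = simulate_functional_catalog(config, snps, genes)
    return SimulatedWorld(config, genome, genes, repeats, states, qtls,
                          catalog, snps, pop_map, cn, functional, truth)
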