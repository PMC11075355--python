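"""Stage orchestration as a Python API.

``PipelineConfig`` carries every stage threshold (defaults are the published
analysis constants) plus the seed and output directory; ``run_all`` executes
the stages in dependency order on a seeded synthetic world, writing each
stage's TSV/JSON outputs and a run manifest with full threshold provenance
and input checksums. Individual ``stage_*`` functions are composable: no
stage mutates another stage's outputs, and ``run_all`` is their composition.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import enrichment, impact, io, popgen, qc, validation
from .model import SVCatalog
from .simulate import SimulatedWorld, SimulationConfig, simulate_assembly_truth, \
    simulate_world

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage thresholds; defaults reproduce the published constants."""

    seed: int = 0
    out_dir: str = "svscape_out"
    # QC
    cn_threshold: float = 10.0
    bad_bin_sample_fraction: float = 0.90
    min_sv_length: int = 50
    msq_del_mei: float = 100.0
    msq_inv: float = 150.0
    msq_bnd: float = 250.0
    small_del_max: int = 1000
    inv_support_min: float = 0.10
    sample_max_missing: float = 0.15
    sample_min_sv_count: int = 10_000
    # classification
    mei_repeat_cover: float = 0.90
    strong_fraction: float = 0.20
    regulator_flank: int = 5_000
    rare_ac_max: int = 10
    # enrichment
    alpha: float = 0.01
    qtl_max_length: int = 1_000_000
    qtl_fold_min: float = 2.0
    anova_cv_min: float = 1.0
    # population genetics / LD
    maf_min: float = 0.01
    genotype_rate_min: float = 0.95
    fst_top_q: float = 0.01
    ld_window: int = 1_000_000
    tier_linked: float = 0.2
    tier_tagged: float = 0.5
    tier_highly_tagged: float = 0.8
    thin_gap: int = 1000
    gwas_p_max: float = 5e-8
    twas_fdr_max: float = 0.05
    # validation
    validation_min_overlap: int = 1
    consistency_threshold: float = 0.98
    # simulation (overrides the generator defaults where set)
    simulation: SimulationConfig | None = None
    write_cn_matrix: bool = False

    def sim_config(self) -> SimulationConfig:
        return self.simulation or SimulationConfig(seed=self.seed)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def stage_simulate(cfg: PipelineConfig) -> SimulatedWorld:
    """Generate the synthetic world and write its inputs as standard files."""
    out = Path(cfg.out_dir) / "inputs"
    out.mkdir(parents=True, exist_ok=True)
    world = simulate_world(cfg.sim_config())
    io.write_catalog_vcf(world.catalog, out / "svs.vcf", genome=world.genome)
    io.write_snp_vcf(world.snps, out / "snps.vcf", genome=world.genome)
    io.write_population_map(world.pop_map, out / "populations.tsv")
    io.write_gene_models_gff3(world.genes, out / "genes.gff3")
    io.write_feature_track(world.repeats, out / "repeats.bed")
    io.write_feature_track(world.states, out / "chromatin_states.bed")
    io.write_feature_track(world.qtls, out / "qtls.bed")
    if cfg.write_cn_matrix:
        io.write_cn_matrix(world.cn, out / "cn_windows.tsv")
    pd.DataFrame(world.functional.records).to_csv(out / "functional.tsv",
                                                  sep="\t", index=False)
    return world


def stage_qc(cfg: PipelineConfig, world: SimulatedWorld) -> tuple[SVCatalog, qc.QCReport]:
    out = Path(cfg.out_dir) / "qc"
    out.mkdir(parents=True, exist_ok=True)
    bad = qc.detect_bad_bins(world.cn, cn_threshold=cfg.cn_threshold,
                             sample_fraction=cfg.bad_bin_sample_fraction)
    io.write_feature_track(bad, out / "bad_bins.bed")
    catalog, report = qc.run_qc(world.catalog, world.genome, bad_bins=bad,
                                min_len=cfg.min_sv_length)
    (out / "qc_report.json").write_text(json.dumps(report.as_dict(), indent=2))
    return catalog, report


def stage_classify(cfg: PipelineConfig, world: SimulatedWorld,
                   catalog: SVCatalog) -> tuple[SVCatalog, list, dict]:
    out = Path(cfg.out_dir) / "classify"
    out.mkdir(parents=True, exist_ok=True)
    catalog = impact.reclassify_catalog(catalog, world.repeats,
                                        cover_threshold=cfg.mei_repeat_cover)
    calls, summary = impact.classify_catalog(catalog, world.genes)
    io.write_table(pd.DataFrame([{
        "sv_id": c.sv_id, "gene_id": c.gene_id or ".", "category": c.category,
        "cds_fraction": c.cds_fraction, "utr5_fraction": c.utr5_fraction,
        "utr3_fraction": c.utr3_fraction} for c in calls]), out / "impact_calls.tsv")
    freq = impact.catalog_frequency_classes(catalog, rare_ac_max=cfg.rare_ac_max)
    io.write_table(pd.DataFrame([{"sv_id": f.sv_id, "ac": f.ac, "af": f.af,
                                  "class": f.label} for f in freq]),
                   out / "frequency_classes.tsv")
    (out / "category_summary.json").write_text(json.dumps(summary, indent=2))
    return catalog, calls, summary


def stage_enrich(cfg: PipelineConfig, world: SimulatedWorld,
                 catalog: SVCatalog) -> dict:
    out = Path(cfg.out_dir) / "enrich"
    out.mkdir(parents=True, exist_ok=True)
    footprint = catalog.merged_intervals()
    repeat_res = enrichment.feature_family_enrichment(
        footprint, world.repeats, world.genome, alpha=cfg.alpha)
    genic_res = enrichment.genic_partition_enrichment(
        catalog, world.genes, world.genome, alpha=cfg.alpha)
    states = enrichment.chromatin_state_overlap(world.states, footprint)
    state_tests = enrichment.chromatin_state_tests(states, alpha=cfg.alpha)
    qtl_res, qtl_tallies = enrichment.qtl_enrichment(
        world.qtls, footprint, world.genome, max_qtl_len=cfg.qtl_max_length,
        fold_min=cfg.qtl_fold_min, alpha=cfg.alpha)
    folds = enrichment.individual_qtl_folds(catalog, world.qtls, world.genome)
    anova = enrichment.population_anova(folds, world.pop_map, alpha=cfg.alpha,
                                        cv_min=cfg.anova_cv_min)
    for name, results in (("repeat_enrichment", repeat_res),
                          ("genic_enrichment", genic_res),
                          ("qtl_enrichment", qtl_res)):
        io.write_table(pd.DataFrame([vars(r) for r in results]), out / f"{name}.tsv")
    io.write_table(states, out / "chromatin_state_overlap.tsv")
    io.write_table(pd.DataFrame([vars(t) for t in state_tests]),
                   out / "chromatin_state_tests.tsv")
    io.write_table(pd.DataFrame([vars(a) for a in anova]), out / "qtl_anova.tsv")
    return {"qtl_tallies": qtl_tallies,
            "n_anova_reported": sum(a.reported for a in anova)}


def stage_popgen(cfg: PipelineConfig, world: SimulatedWorld,
                 catalog: SVCatalog) -> dict:
    out = Path(cfg.out_dir) / "popgen"
    out.mkdir(parents=True, exist_ok=True)
    specific = popgen.group_specific_svs(catalog, world.pop_map, "AS", "EU",
                                         level="ancestral")
    matrix = catalog.genotype_matrix()
    fst = popgen.weir_cockerham_fst(matrix, world.pop_map, ("AS", "EU"),
                                    level="ancestral")
    threshold = popgen.flag_top_fst(fst, q=cfg.fst_top_q) if fst else float("nan")
    io.write_table(pd.DataFrame([{"sv_id": r.variant_id, "fst": r.fst,
                                  "top": r.flagged} for r in fst]),
                   out / "fst.tsv")
    (out / "group_specific.json").write_text(json.dumps(specific, indent=2))
    return {"group_specific": specific, "fst_threshold": threshold,
            "n_top_fst": sum(r.flagged for r in fst)}


def stage_ld(cfg: PipelineConfig, world: SimulatedWorld,
             catalog: SVCatalog) -> list[popgen.LinkageRecord]:
    out = Path(cfg.out_dir) / "ld"
    out.mkdir(parents=True, exist_ok=True)
    from .model import GenotypeMatrix
    combined = GenotypeMatrix.concatenate([catalog.genotype_matrix(), world.snps])
    links = popgen.ld_r2_window(combined, window=cfg.ld_window, min_r2=0.0,
                                kinds_a=("SV",), kinds_b=("SNP",))
    io.write_table(pd.DataFrame([{"id_a": l.id_a, "id_b": l.id_b,
                                  "distance": l.distance, "r2": l.r2,
                                  "tier": l.tier} for l in links]),
                   out / "sv_snp_ld.tsv")
    return links


def stage_network(cfg: PipelineConfig, world: SimulatedWorld, catalog: SVCatalog,
                  links: list[popgen.LinkageRecord]) -> dict:
    out = Path(cfg.out_dir) / "network"
    out.mkdir(parents=True, exist_ok=True)
    g = popgen.build_functional_network(
        catalog, links, world.functional, world.genes,
        r2_min=cfg.tier_linked, max_distance=cfg.ld_window,
        gwas_p_max=cfg.gwas_p_max, twas_fdr_max=cfg.twas_fdr_max,
        gene_flank=cfg.regulator_flank)
    nodes = pd.DataFrame([{"node": n, **d} for n, d in g.nodes(data=True)])
    edges = pd.DataFrame([{"a": a, "b": b, **d} for a, b, d in g.edges(data=True)])
    io.write_table(nodes.astype(str), out / "nodes.tsv")
    io.write_table(edges.astype(str), out / "edges.tsv")
    summary = popgen.network_summary(g)
    (out / "network_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def stage_validate(cfg: PipelineConfig, world: SimulatedWorld,
                   catalog: SVCatalog) -> validation.ValidationReport:
    out = Path(cfg.out_dir) / "validate"
    out.mkdir(parents=True, exist_ok=True)
    truth = simulate_assembly_truth(world.catalog, seed=cfg.seed)
    pairs = validation.match_sv_sets(catalog, truth,
                                     min_overlap=cfg.validation_min_overlap)
    report = validation.validation_rates(pairs, catalog)
    (out / "validation.json").write_text(json.dumps(report.as_dict(), indent=2))
    return report


def run_all(cfg: PipelineConfig) -> dict:
    """Simulate, QC, classify, enrich, popgen, LD, network, validate.

    Returns a results dictionary and writes a manifest with the seed, all
    thresholds, and SHA-256 checksums of every emitted input file."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    world = stage_simulate(cfg)
    catalog, qc_report = stage_qc(cfg, world)
    catalog, calls, summary = stage_classify(cfg, world, catalog)
    enrich_info = stage_enrich(cfg, world, catalog)
    pop_info = stage_popgen(cfg, world, catalog)
    links = stage_ld(cfg, world, catalog)
    net_info = stage_network(cfg, world, catalog, links)
    val_report = stage_validate(cfg, world, catalog)

    thresholds = {k: v for k, v in asdict(cfg).items()
                  if k not in ("simulation",) and not isinstance(v, dict)}
    manifest = {
        "seed": cfg.seed,
        "thresholds": thresholds,
        "inputs_sha256": {p.name: _sha256(p)
                          for p in sorted((out / "inputs").glob("*"))},
        "n_svs_input": len(world.catalog),
        "n_svs_after_qc": qc_report.filters.get("type_filters", {}).get("retained"),
        "category_summary": summary,
        "validation": val_report.as_dict(),
        "network": net_info,
        "enrichment": enrich_info,
        "fst_threshold": pop_info["fst_threshold"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return {"world": world, "catalog": catalog, "calls": calls,
            "summary": summary, "qc_report": qc_report, "links": links,
            "network": net_info, "validation": val_report,
            "popgen": pop_info, "enrichment": enrich_info,
            "manifest": manifest}
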