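"""Gene-impact classification of structural variants.

Each gene-overlapping SV is assigned one of 15 categories per (SV, gene)
pair: whole-gene DEL/DUP/INV, pLoF or copy-gain (strong/weak by whether the
CDS overlap reaches 20% of the SV's own length), coding INV/BND, 5'/3'
regulatory (strong/weak by the same 20% rule on UTR overlap), intron, and
noncoding exon. SVs touching no gene are intergenic. Precedence within one
gene: whole-gene engulfment > CDS > UTR > noncoding exon > intron.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .intervals import intersect_length
from .model import FeatureTrack, GeneModel, SVCatalog, SVRecord

CATEGORIES = (
    "WlGnDel", "WlGnDup", "WlGnInv",
    "pLoF_St", "pLoF_Wk", "CpGn_St", "CpGn_Wk", "codInv", "codBnd",
    "Rglt5_St", "Rglt5_Wk", "Rglt3_St", "Rglt3_Wk",
    "intron", "noncoding",
)
INTERGENIC = "intergenic"

#: minimum fraction of the SV's own length inside CDS/UTR for a "strong" call
STRONG_FRACTION = 0.20


@dataclass(frozen=True)
class ImpactCall:
    sv_id: str
    gene_id: str | None
    category: str
    cds_fraction: float = 0.0
    utr5_fraction: float = 0.0
    utr3_fraction: float = 0.0


@dataclass(frozen=True)
class FrequencyClass:
    sv_id: str
    ac: int
    af: float
    label: str  # singleton | rare | common | absent


@dataclass(frozen=True)
class RegulatorCall:
    sv_id: str
    element_label: str
    tissue: str | None
    relation: str  # overlapped | flanking | none


def reclassify_del_to_mei(record: SVRecord, repeats: FeatureTrack,
                          cover_threshold: float = 0.90) -> SVRecord:
    """Reclassify a DEL as a (reference) MEI when the deduplicated union of
    repeat elements covers strictly more than 90% of its length.

    Coordinates are never altered; non-DEL records are returned unchanged.
    """
    if record.svtype != "DEL":
        return record
    covered = repeats.interval_set().overlap_length(record.chrom, record.start, record.end)
    if covered > cover_threshold * record.length:
        new_id = (record.id[: -len("DEL")] + "MEI"
                  if record.id.endswith(":DEL") else record.id)
        return replace(record, svtype="MEI", id=new_id)
    return record


def reclassify_catalog(catalog: SVCatalog, repeats: FeatureTrack,
                       cover_threshold: float = 0.90) -> SVCatalog:
    return SVCatalog([reclassify_del_to_mei(r, repeats, cover_threshold)
                      for r in catalog.records],
                     catalog.samples, notes=catalog.notes + ["DEL->MEI reclassification"])


def _fraction(sv: SVRecord, feature_intervals: list[tuple[int, int]]) -> float:
    if not feature_intervals or sv.length in (None, 0):
        return 0.0
    return intersect_length([(sv.start, sv.end)], feature_intervals) / sv.length


def classify_sv_gene(sv: SVRecord, gene: GeneModel) -> ImpactCall:
    """Classify one (SV, gene) pair; the SV must overlap the gene body."""
    if min(sv.end, gene.end) - max(sv.start, gene.start) < 0:
        raise ValueError(f"{sv.id} does not overlap gene {gene.gene_id}")
    exons = gene.exon_union()  # raises for a gene with no exons
    cds_frac = _fraction(sv, gene.cds_union())
    utr5_frac = _fraction(sv, gene.utr5_union())
    utr3_frac = _fraction(sv, gene.utr3_union())

    def call(category: str) -> ImpactCall:
        return ImpactCall(sv.id, gene.gene_id, category,
                          cds_fraction=cds_frac, utr5_fraction=utr5_frac,
                          utr3_fraction=utr3_frac)

    engulfs = sv.start <= gene.start and sv.end >= gene.end
    if engulfs and sv.svtype in ("DEL", "MEI"):
        return call("WlGnDel")   # reference-MEI deletions act as whole-gene loss
    if engulfs and sv.svtype == "DUP":
        return call("WlGnDup")
    if engulfs and sv.svtype == "INV":
        return call("WlGnInv")

    if cds_frac > 0:
        if sv.svtype in ("DEL", "MEI"):
            return call("pLoF_St" if cds_frac >= STRONG_FRACTION else "pLoF_Wk")
        if sv.svtype == "DUP":
            return call("CpGn_St" if cds_frac >= STRONG_FRACTION else "CpGn_Wk")
        if sv.svtype == "INV":
            return call("codInv")
        return call("codBnd")

    if utr5_frac > 0 or utr3_frac > 0:
        # larger overlapped length wins; ties go to the 5' class
        if utr5_frac >= utr3_frac:
            return call("Rglt5_St" if utr5_frac >= STRONG_FRACTION else "Rglt5_Wk")
        return call("Rglt3_St" if utr3_frac >= STRONG_FRACTION else "Rglt3_Wk")

    exonic = intersect_length([(sv.start, sv.end)], exons) > 0
    if exonic and gene.biotype != "protein_coding":
        return call("noncoding")
    return call("intron")


def classify_catalog(catalog: SVCatalog, genes: Sequence[GeneModel]
                     ) -> tuple[list[ImpactCall], dict[str, dict[str, int]]]:
    """One ImpactCall per overlapping (SV, gene) pair; SVs with no gene get a
    single intergenic call. Returns calls plus per-category counts of
    distinct SVs and distinct genes."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for gl in by_chrom.values():
        gl.sort(key=lambda g: g.start)
    calls: list[ImpactCall] = []
    for sv in catalog.records:
        hits = [g for g in by_chrom.get(sv.chrom, ())
                if g.start <= sv.end and g.end >= sv.start]
        if not hits:
            calls.append(ImpactCall(sv.id, None, INTERGENIC))
        else:
            calls.extend(classify_sv_gene(sv, g) for g in hits)
    counts: dict[str, dict[str, set]] = {}
    for c in calls:
        slot = counts.setdefault(c.category, {"svs": set(), "genes": set()})
        slot["svs"].add(c.sv_id)
        if c.gene_id is not None:
            slot["genes"].add(c.gene_id)
    summary = {cat: {"n_svs": len(v["svs"]), "n_genes": len(v["genes"])}
               for cat, v in counts.items()}
    return calls, summary


def frequency_class(ac: int, n_samples_nonmissing: int,
                    rare_ac_max: int = 10) -> FrequencyClass:
    """Allele-count classes: singleton (AC=1), rare (1 < AC <= 10), common
    (AC > 10); AF is reported alongside but does not set the boundary."""
    if ac < 0 or n_samples_nonmissing < 0:
        raise ValueError("negative allele or sample count")
    af = ac / (2 * n_samples_nonmissing) if n_samples_nonmissing else float("nan")
    if ac == 0:
        label = "absent"
    elif ac == 1:
        label = "singleton"
    elif ac <= rare_ac_max:
        label = "rare"
    else:
        label = "common"
    return FrequencyClass(sv_id="", ac=ac, af=af, label=label)


def catalog_frequency_classes(catalog: SVCatalog,
                              rare_ac_max: int = 10) -> list[FrequencyClass]:
    out = []
    for r in catalog.records:
        fc = frequency_class(r.allele_count(), r.n_nonmissing(), rare_ac_max)
        out.append(replace(fc, sv_id=r.id))
    return out


def regulator_relation(sv: SVRecord, element: tuple[str, int, int],
                       label: str = "", tissue: str | None = None,
                       flank: int = 5000) -> RegulatorCall:
    """Overlapped if the element intersects the SV by >= 1 bp; flanking if it
    intersects either 5-kb flank; none otherwise. Overlap takes precedence."""
    chrom, es, ee = element
    if chrom == sv.chrom and es <= sv.end and ee >= sv.start:
        rel = "overlapped"
    elif chrom == sv.chrom and (
        (es <= sv.start - 1 and ee >= max(1, sv.start - flank))
        or (es <= sv.end + flank and ee >= sv.end + 1)
    ):
        rel = "flanking"
    else:
        rel = "none"
    return RegulatorCall(sv.id, label, tissue, rel)
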