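"""Readers and writers for the standard formats every stage touches.

Internal coordinates are 1-based both-inclusive. BED is 0-based half-open
and converted at this boundary; VCF ``END`` is interpreted as the last
affected base, and ``SVLEN`` in the dialect written here is the positive
inclusive span (``end - start + 1``).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd
import pysam

from .model import (
    MISSING,
    FeatureTrack,
    GeneModel,
    GenomeModel,
    GenotypeMatrix,
    ParseError,
    PopulationMap,
    SVCatalog,
    SVRecord,
    Transcript,
    parse_sv_identifier,
)

log = logging.getLogger(__name__)

_VCF_HEADER = """\
##fileformat=VCFv4.2
{contigs}##ALT=<ID=DEL,Description="Deletion">
##ALT=<ID=DUP,Description="Duplication">
##ALT=<ID=INV,Description="Inversion">
##ALT=<ID=INS:ME,Description="Mobile element insertion (reference MEI deletion)">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=END,Number=1,Type=Integer,Description="Last affected base (1-based inclusive)">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Inclusive span end-start+1">
##INFO=<ID=MSQ,Number=1,Type=Float,Description="Mean sample quality">
##INFO=<ID=MINSIZE95,Number=1,Type=Integer,Description="Genotyper 95%-confidence minimum size">
##INFO=<ID=MATEID,Number=1,Type=String,Description="BND mate record id">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=SR,Number=1,Type=Integer,Description="Split-read support">
##FORMAT=<ID=PE,Number=1,Type=Integer,Description="Paired-end support">
##FORMAT=<ID=AB,Number=1,Type=Float,Description="Allele balance">
##FORMAT=<ID=CN,Number=1,Type=Float,Description="Copy number">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _alt_for(record: SVRecord) -> str:
    if record.svtype == "MEI":
        return "<INS:ME>"
    if record.svtype == "BND":
        mc = record.mate_chrom or record.chrom
        mp = record.mate_pos if record.mate_pos is not None else record.end
        return f"N[{mc}:{mp}["
    return f"<{record.svtype}>"


def write_catalog_vcf(catalog: SVCatalog, path: str | Path,
                      genome: GenomeModel | None = None) -> None:
    """Write the catalog in the symbolic-allele VCF 4.2 dialect of this package."""
    contigs = ""
    if genome is not None:
        contigs = "".join(f"##contig=<ID={c},length={n}>\n"
                          for c, n in genome.lengths.items())
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contigs, samples="\t".join(catalog.samples)))
        for r in catalog.records:
            info = [f"SVTYPE={r.svtype}", f"END={r.end}"]
            if r.svtype != "BND":
                info.append(f"SVLEN={r.length}")
            if r.msq is not None:
                info.append(f"MSQ={r.msq:g}")
            if r.min_size_95 is not None:
                info.append(f"MINSIZE95={r.min_size_95}")
            fmt_keys = ["GT"]
            columns: list[list[str]] = [
                [_GT_STRINGS[int(g)] for g in (
                    r.genotypes if r.genotypes is not None
                    else [MISSING] * len(catalog.samples))]
            ]
            for key, arr, fmt in (("SR", r.sr_support, "{:d}"),
                                  ("PE", r.pe_support, "{:d}"),
                                  ("AB", r.allele_balance, "{:.4g}"),
                                  ("CN", r.copy_number, "{:.4g}")):
                if arr is not None:
                    fmt_keys.append(key)
                    columns.append([
                        "." if (isinstance(v, float) and np.isnan(v))
                        else fmt.format(int(v) if fmt == "{:d}" else float(v))
                        for v in arr
                    ])
            per_sample = [":".join(vals) for vals in zip(*columns)]
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.id}\tN\t{_alt_for(r)}\t.\tPASS\t"
                f"{';'.join(info)}\t{':'.join(fmt_keys)}\t" + "\t".join(per_sample) + "\n"
            )


def _raw_info_end(rec) -> int | None:
    """INFO END parsed from the raw line: htslib recomputes ``rec.stop`` from
    SVLEN under VCF 4.4 semantics (END = POS + |SVLEN|), which is off by one
    against the inclusive convention used here."""
    info = str(rec).rstrip("\n").split("\t")[7]
    for field in info.split(";"):
        if field.startswith("END="):
            return int(field[4:])
    return None


def _dosage_from_gt(gt: tuple | None) -> int:
    if gt is None or any(a is None for a in gt):
        return MISSING
    return int(sum(1 for a in gt if a and a > 0))


def read_sv_vcf(path: str | Path, samples: Sequence[str] | None = None) -> SVCatalog:
    """Read a symbolic-allele SV VCF into a catalog.

    Records without ``SVTYPE`` are rejected with a logged reason; an ``END``
    inconsistent with ``SVLEN`` under the inclusive convention is an error.
    BND mate coordinates are taken from breakend ALT notation.
    """
    notes: list[str] = []
    records: list[SVRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        roster = tuple(samples) if samples is not None else tuple(vcf.header.samples)
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            try:
                svtype = rec.info.get("SVTYPE")
            except ValueError:  # SVTYPE not declared in the header at all
                svtype = None
            if svtype is None:
                notes.append(f"rejected {rec.chrom}:{rec.pos}: missing SVTYPE")
                log.warning(notes[-1])
                continue
            start = rec.pos
            info_end = _raw_info_end(rec)
            end = info_end if info_end is not None else rec.stop
            svlen = rec.info.get("SVLEN")
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            if svtype != "BND" and svlen is not None:
                if info_end is not None and abs(int(svlen)) != end - start + 1:
                    raise ParseError(
                        f"{rec.id or rec.chrom + ':' + str(rec.pos)}: SVLEN {svlen} "
                        f"inconsistent with END ({end - start + 1} bp inclusive)"
                    )
                end = start + abs(int(svlen)) - 1
            mate_chrom = mate_pos = None
            if svtype == "BND":
                alt = rec.alts[0] if rec.alts else ""
                for sep in "[]":
                    if sep in alt:
                        inner = alt.split(sep)[1]
                        mate_chrom, mate_pos = inner.rsplit(":", 1)
                        mate_pos = int(mate_pos)
                        break
            sv_id = rec.id or f"{rec.chrom}:{start}-{end}:{svtype}"
            try:
                skeleton = parse_sv_identifier(sv_id)
                if skeleton.svtype != svtype:
                    raise ParseError(
                        f"id suffix {skeleton.svtype} disagrees with SVTYPE={svtype} for {sv_id}"
                    )
            except ParseError as exc:
                if "malformed" not in str(exc):
                    raise
            n = len(roster)
            geno = np.full(n, MISSING, dtype=np.int8)
            sr = pe = ab = cn = None
            fmt_keys = rec.format.keys()
            if "SR" in fmt_keys:
                sr = np.zeros(n, dtype=np.int64)
            if "PE" in fmt_keys:
                pe = np.zeros(n, dtype=np.int64)
            if "AB" in fmt_keys:
                ab = np.full(n, np.nan)
            if "CN" in fmt_keys:
                cn = np.full(n, np.nan)
            for i, s in enumerate(roster):
                call = rec.samples[s]
                geno[i] = _dosage_from_gt(call.get("GT"))
                for key, arr in (("SR", sr), ("PE", pe), ("AB", ab), ("CN", cn)):
                    if arr is not None and call.get(key) is not None:
                        arr[i] = call[key]
            records.append(SVRecord(
                id=sv_id, chrom=rec.chrom, start=start, end=end, svtype=svtype,
                msq=float(rec.info["MSQ"]) if "MSQ" in rec.info else None,
                min_size_95=int(rec.info["MINSIZE95"]) if "MINSIZE95" in rec.info else None,
                genotypes=geno, sr_support=sr, pe_support=pe,
                allele_balance=ab, copy_number=cn,
                mate_chrom=mate_chrom, mate_pos=mate_pos,
            ))
    return SVCatalog(records, roster, notes=notes)


def write_snp_vcf(matrix: GenotypeMatrix, path: str | Path,
                  genome: GenomeModel | None = None) -> None:
    """Write a biallelic SNP dosage matrix as a minimal VCF."""
    contigs = ""
    if genome is not None:
        contigs = "".join(f"##contig=<ID={c},length={n}>\n"
                          for c, n in genome.lengths.items())
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n" + contigs)
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        for j in range(matrix.n_variants):
            gts = "\t".join(_GT_STRINGS[int(g)] for g in matrix.dosages[:, j])
            fh.write(f"{matrix.chroms[j]}\t{int(matrix.positions[j])}\t"
                     f"{matrix.variant_ids[j]}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def read_snp_vcf(path: str | Path) -> GenotypeMatrix:
    ids: list[str] = []
    chroms: list[str] = []
    pos: list[int] = []
    rows: list[np.ndarray] = []
    with pysam.VariantFile(str(path)) as vcf:
        roster = tuple(vcf.header.samples)
        for rec in vcf:
            ids.append(rec.id or f"{rec.chrom}:{rec.pos}:SNP")
            chroms.append(rec.chrom)
            pos.append(rec.pos)
            rows.append(np.array(
                [_dosage_from_gt(rec.samples[s].get("GT")) for s in roster],
                dtype=np.int8))
    dosages = (np.stack(rows, axis=1) if rows
               else np.zeros((len(roster), 0), dtype=np.int8))
    return GenotypeMatrix(dosages, roster, tuple(ids), tuple(chroms),
                          np.array(pos, dtype=np.int64),
                          tuple("SNP" for _ in ids))


def read_gene_models(
    gff_path: str | Path,
    retired_ids: Iterable[str] = (),
    placed_chroms: Iterable[str] | None = None,
) -> tuple[list[GeneModel], dict[str, int]]:
    """Read GFF3 gene models, dropping retired-version and unplaced-sequence genes.

    Returns the retained models plus a report with ``total`` / ``retired`` /
    ``unplaced`` / ``invalid`` / ``retained`` counts. A gene whose CDS falls
    outside its exons is flagged invalid and excluded with a log entry.
    """
    retired = set(retired_ids)
    placed = set(placed_chroms) if placed_chroms is not None else None
    try:
        db = gffutils.create_db(str(gff_path), ":memory:", force=True,
                                keep_order=True, merge_strategy="create_unique")
    except gffutils.exceptions.EmptyInputError:
        log.warning("no gene features found in %s", gff_path)
        return [], {"total": 0, "retired": 0, "unplaced": 0, "invalid": 0,
                    "retained": 0}
    report = {"total": 0, "retired": 0, "unplaced": 0, "invalid": 0, "retained": 0}
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        report["total"] += 1
        gid = g.id
        if gid in retired:
            report["retired"] += 1
            continue
        if placed is not None and g.seqid not in placed:
            report["unplaced"] += 1
            continue
        biotype = g.attributes.get("biotype", g.attributes.get("gene_biotype", ["other"]))[0]
        transcripts = []
        for t in db.children(g, featuretype=("mRNA", "transcript"), order_by="start"):
            transcripts.append(Transcript(
                transcript_id=t.id,
                exons=[(e.start, e.end) for e in db.children(t, featuretype="exon")],
                cds=[(c.start, c.end) for c in db.children(t, featuretype="CDS")],
                utr5=[(u.start, u.end)
                      for u in db.children(t, featuretype="five_prime_UTR")],
                utr3=[(u.start, u.end)
                      for u in db.children(t, featuretype="three_prime_UTR")],
            ))
        try:
            genes.append(GeneModel(gene_id=gid, chrom=g.seqid, start=g.start, end=g.end,
                                   strand=g.strand or ".", biotype=biotype,
                                   transcripts=transcripts))
        except ValueError as exc:
            report["invalid"] += 1
            log.warning("excluded invalid gene model %s: %s", gid, exc)
    report["retained"] = len(genes)
    if report["total"] == 0:
        log.warning("no gene features found in %s", gff_path)
    return genes, report


def read_feature_track(path: str | Path, name: str,
                       vocabulary: Sequence[str]) -> FeatureTrack:
    """Read a BED-like table (0-based half-open) into a 1-based inclusive track.

    Columns: chrom, start, end, label[, tissue]. Labels outside the declared
    vocabulary raise with the offending labels listed.
    """
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            chrom, s0, e0, label = parts[0], int(parts[1]), int(parts[2]), parts[3]
            tissue = parts[4] if len(parts) > 4 and parts[4] != "." else None
            intervals.append((chrom, s0 + 1, e0, label, tissue))
    return FeatureTrack(name=name, vocabulary=tuple(vocabulary), intervals=intervals)


def write_feature_track(track: FeatureTrack, path: str | Path) -> None:
    """Write a track back to BED (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, s, e, label, tissue in track.intervals:
            cols = [chrom, str(s - 1), str(e), label]
            if tissue is not None:
                cols.append(tissue)
            fh.write("\t".join(cols) + "\n")


def read_population_map(path: str | Path,
                        roster: Sequence[str] | None = None) -> PopulationMap:
    """Read sample->population TSV (columns: sample, main_pop[, sub_pop])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    main = dict(zip(df[cols["sample"]], df[cols["main_pop"]]))
    sub = (dict(zip(df[cols["sample"]], df[cols["sub_pop"]]))
           if "sub_pop" in cols else {})
    pmap = PopulationMap(main=main, sub=sub)
    if roster is not None:
        pmap.check_roster(roster)
    return pmap


def write_population_map(pmap: PopulationMap, path: str | Path) -> None:
    pd.DataFrame({
        "sample": list(pmap.main),
        "main_pop": [pmap.main[s] for s in pmap.main],
        "sub_pop": [pmap.sub.get(s, pmap.main[s]) for s in pmap.main],
    }).to_csv(path, sep="\t", index=False)


def write_gene_models_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Emit gene models as GFF3 (gene / mRNA / exon / CDS / UTR features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};biotype={g.biotype}"
            fh.write(f"{g.chrom}\tsvscape\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            for t in g.transcripts:
                fh.write(f"{g.chrom}\tsvscape\tmRNA\t{min(s for s, _ in t.exons)}\t"
                         f"{max(e for _, e in t.exons)}\t.\t{g.strand}\t.\t"
                         f"ID={t.transcript_id};Parent={g.gene_id}\n")
                for ftype, ivs, phase in (("exon", t.exons, "."),
                                          ("CDS", t.cds, "0"),
                                          ("five_prime_UTR", t.utr5, "."),
                                          ("three_prime_UTR", t.utr3, ".")):
                    for s, e in ivs:
                        fh.write(f"{g.chrom}\tsvscape\t{ftype}\t{s}\t{e}\t.\t"
                                 f"{g.strand}\t{phase}\tParent={t.transcript_id}\n")


def write_cn_matrix(cn, path: str | Path) -> None:
    """Copy-number window matrix as TSV: chrom, start, end, one column per sample."""
    coords = pd.DataFrame({
        "chrom": cn.chroms,
        "start": cn.starts,
        "end": cn.starts + cn.window_size - 1,
    })
    vals = pd.DataFrame(cn.values, columns=list(cn.samples))
    pd.concat([coords, vals], axis=1).to_csv(path, sep="\t", index=False,
                                             float_format="%.3f")


def read_cn_matrix(path: str | Path):
    from .qc import CNWindowMatrix
    df = pd.read_csv(path, sep="\t")
    samples = tuple(df.columns[3:])
    starts = df["start"].to_numpy(dtype=np.int64)
    window = int(df["end"].iloc[0] - df["start"].iloc[0] + 1)
    return CNWindowMatrix(window_size=window, chroms=tuple(df["chrom"].astype(str)),
                          starts=starts,
                          values=df[list(samples)].to_numpy(dtype=float),
                          samples=samples)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
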