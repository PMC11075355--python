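"""Catalog quality control.

The filter stack, applied in this fixed order (the source pipelines give no
explicit one): high-copy-number "bad bin" overlap removal, assembly-gap
overlap removal, minimum length, per-type evidence filters, per-sample
genotype masking. All threshold comparisons are literal: copy number > 10
strict, MSQ > 100/150/250 strict, "<= 1000 bp" inclusive, "< 50 bp" strict.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .intervals import IntervalSet, merge_intervals
from .model import MISSING, FeatureTrack, GenomeModel, SVCatalog

log = logging.getLogger(__name__)


@dataclass
class CNWindowMatrix:
    """Fixed-size window tiling of the genome with per-sample copy number."""

    window_size: int
    chroms: tuple[str, ...]            # chromosome of each window
    starts: np.ndarray                 # 1-based inclusive window starts
    values: np.ndarray                 # windows x samples, real >= 0
    samples: tuple[str, ...]

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.chroms), len(self.samples)):
            raise ValueError("CN matrix shape does not match windows x samples")
        if self.window_size <= 0:
            raise ValueError("window size must be positive")
        # windows must tile each chromosome contiguously with one uniform size
        for chrom in set(self.chroms):
            idx = [i for i, c in enumerate(self.chroms) if c == chrom]
            pos = np.sort(self.starts[idx])
            if pos[0] != 1 or np.any(np.diff(pos) != self.window_size):
                raise ValueError(f"windows on {chrom} are not a uniform tiling")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def window_interval(self, i: int) -> tuple[str, int, int]:
        s = int(self.starts[i])
        return self.chroms[i], s, s + self.window_size - 1


@dataclass
class QCReport:
    """Per-filter removed/retained tallies plus masking counts."""

    filters: dict[str, dict[str, int]] = field(default_factory=dict)
    bad_bins: list[tuple[str, int, int]] = field(default_factory=list)
    masked_genotypes: int = 0
    removed_ids: dict[str, list[str]] = field(default_factory=dict)

    def record(self, name: str, n_in: int, n_out: int, removed: list[str]) -> None:
        self.filters[name] = {"input": n_in, "removed": n_in - n_out, "retained": n_out}
        self.removed_ids[name] = removed
        log.info("filter %s: removed %d of %d", name, n_in - n_out, n_in)

    def as_dict(self) -> dict:
        return {
            "filters": self.filters,
            "n_bad_bins": len(self.bad_bins),
            "masked_genotypes": self.masked_genotypes,
        }


def detect_bad_bins(cn: CNWindowMatrix, cn_threshold: float = 10.0,
                    sample_fraction: float = 0.90, merge: bool = True) -> FeatureTrack:
    """Flag windows whose copy number exceeds `cn_threshold` (strictly) in at
    least ``ceil(sample_fraction * n_samples)`` samples.

    The default reproduces the published rule: CN > 10 (five times diploid)
    in >= 90% of samples. Adjacent flagged windows are merged for reporting.
    """
    if cn.n_samples < 1:
        raise ValueError("CN matrix has no samples")
    need = math.ceil(sample_fraction * cn.n_samples)
    high = (cn.values > cn_threshold).sum(axis=1)
    flagged = [cn.window_interval(i) for i in np.nonzero(high >= need)[0]]
    if merge:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in flagged:
            by_chrom.setdefault(chrom, []).append((s, e))
        flagged = [(chrom, s, e) for chrom in sorted(by_chrom)
                   for s, e in merge_intervals(by_chrom[chrom])]
    return FeatureTrack(
        name="bad_bins", vocabulary=("bad_bin",),
        intervals=[(c, s, e, "bad_bin", None) for c, s, e in flagged],
    )


def _filter_by_overlap(catalog: SVCatalog, regions: IntervalSet,
                       name: str, report: QCReport) -> SVCatalog:
    kept, removed = [], []
    for r in catalog.records:
        if regions.overlaps(r.chrom, r.start, r.end):
            removed.append(r.id)
        else:
            kept.append(r)
    report.record(name, len(catalog), len(kept), removed)
    return SVCatalog(kept, catalog.samples, notes=catalog.notes + [f"{name} applied"])


def filter_bad_bin_overlap(catalog: SVCatalog, bad_bins: FeatureTrack,
                           report: QCReport | None = None) -> tuple[SVCatalog, QCReport]:
    """Remove any SV overlapping a flagged high-CN window by >= 1 bp."""
    report = report or QCReport()
    report.bad_bins = [(c, s, e) for c, s, e, _, _ in bad_bins.intervals]
    out = _filter_by_overlap(catalog, bad_bins.interval_set(), "bad_bin_overlap", report)
    return out, report


def filter_gap_overlap(catalog: SVCatalog, genome: GenomeModel,
                       report: QCReport | None = None) -> tuple[SVCatalog, QCReport]:
    """Remove any SV overlapping a reference assembly gap by >= 1 bp."""
    report = report or QCReport()
    out = _filter_by_overlap(catalog, genome.gap_set(), "gap_overlap", report)
    return out, report


def filter_min_length(catalog: SVCatalog, min_len: int = 50,
                      report: QCReport | None = None) -> tuple[SVCatalog, QCReport]:
    """Remove events shorter than `min_len` (strictly; 50 bp is retained).

    BNDs without a defined length (inter-chromosomal) are retained: the
    length rule only applies where a length exists.
    """
    report = report or QCReport()
    kept, removed = [], []
    for r in catalog.records:
        if r.length is not None and r.length < min_len:
            removed.append(r.id)
        else:
            kept.append(r)
    report.record("min_length", len(catalog), len(kept), removed)
    return SVCatalog(kept, catalog.samples, notes=catalog.notes + ["min_length applied"]), report


def apply_type_filters(catalog: SVCatalog, *, msq_del_mei: float = 100.0,
                       msq_inv: float = 150.0, msq_bnd: float = 250.0,
                       small_del_max: int = 1000, inv_support_min: float = 0.10,
                       report: QCReport | None = None) -> tuple[SVCatalog, QCReport]:
    """Type-specific evidence filters.

    DEL/MEI need MSQ > 100; DELs <= 1000 bp additionally need split-read
    support in at least one sample; INV needs MSQ > 150 and mean allele
    balance across carriers >= 10%; BND needs MSQ > 250; DUP passes
    untouched. A record subject to an MSQ rule but lacking MSQ is removed
    (conservative) and logged.
    """
    report = report or QCReport()
    kept, removed = [], []
    for r in catalog.records:
        ok = True
        if r.svtype in ("DEL", "MEI"):
            if r.msq is None:
                log.warning("removing %s: MSQ required but missing", r.id)
                ok = False
            elif not r.msq > msq_del_mei:
                ok = False
            elif (r.svtype == "DEL" and r.length is not None
                  and r.length <= small_del_max):
                sr = r.sr_support
                if sr is None or not np.any(np.asarray(sr) >= 1):
                    ok = False
        elif r.svtype == "INV":
            if r.msq is None or not r.msq > msq_inv:
                ok = False
            else:
                if r.allele_balance is None or r.genotypes is None:
                    ok = False
                else:
                    ab = np.asarray(r.allele_balance, dtype=float)
                    mask = r.carriers() & ~np.isnan(ab)
                    ok = bool(mask.any()) and float(ab[mask].mean()) >= inv_support_min
        elif r.svtype == "BND":
            ok = r.msq is not None and r.msq > msq_bnd
        # DUP: no evidence rule
        if ok:
            kept.append(r)
        else:
            removed.append(r.id)
    report.record("type_filters", len(catalog), len(kept), removed)
    return SVCatalog(kept, catalog.samples, notes=catalog.notes + ["type_filters applied"]), report


def mask_sample_genotypes(catalog: SVCatalog,
                          capture_flags: dict[str, np.ndarray] | None = None,
                          report: QCReport | None = None) -> tuple[SVCatalog, QCReport]:
    """Set DEL/MEI genotypes to missing per sample where the site was poorly
    captured by split reads (capture flag False) or the event is shorter than
    the genotyper's 95%-confidence minimum size.

    `capture_flags` maps record id -> boolean per-sample array (True = well
    captured). With no annotations at all the catalog is returned unchanged
    with a warning.
    """
    report = report or QCReport()
    has_minsize = any(r.min_size_95 is not None for r in catalog.records)
    if not capture_flags and not has_minsize:
        log.warning("mask_sample_genotypes: no capture flags or min-size annotations; "
                    "catalog unchanged")
        return catalog, report
    out = []
    masked = 0
    for r in catalog.records:
        if r.svtype not in ("DEL", "MEI") or r.genotypes is None:
            out.append(r)
            continue
        geno = r.genotypes.copy()
        mask = np.zeros(len(geno), dtype=bool)
        if capture_flags and r.id in capture_flags:
            mask |= ~np.asarray(capture_flags[r.id], dtype=bool)
        if r.min_size_95 is not None and r.length is not None and r.length < r.min_size_95:
            mask[:] = True
        masked += int((mask & (geno != MISSING)).sum())
        geno[mask] = MISSING
        out.append(replace(r, genotypes=geno))
    report.masked_genotypes += masked
    log.info("masked %d genotype calls", masked)
    return SVCatalog(out, catalog.samples, notes=catalog.notes + ["genotype masking applied"]), report


def allele_balance(alt_reads: float, ref_reads: float) -> float:
    """ALT-supporting reads over ALT+REF reads; NaN when no reads at all."""
    total = alt_reads + ref_reads
    if total <= 0:
        return float("nan")
    return alt_reads / total


def sample_level_filters(catalog: SVCatalog, max_missing: float = 0.15,
                         min_sv_count: int = 10000) -> list[str]:
    """List samples to exclude: genotype missing rate strictly above
    `max_missing`, or carried-SV count strictly below `min_sv_count`."""
    n = len(catalog.samples)
    missing = np.zeros(n)
    carried = np.zeros(n, dtype=np.int64)
    total = 0
    for r in catalog.records:
        if r.genotypes is None:
            continue
        total += 1
        missing += (r.genotypes == MISSING)
        carried += (r.genotypes >= 1)
    excluded = []
    for i, s in enumerate(catalog.samples):
        rate = missing[i] / total if total else 0.0
        if rate > max_missing or carried[i] < min_sv_count:
            excluded.append(s)
    return excluded


def run_qc(catalog: SVCatalog, genome: GenomeModel, cn: CNWindowMatrix | None = None,
           bad_bins: FeatureTrack | None = None,
           capture_flags: dict[str, np.ndarray] | None = None,
           min_len: int = 50) -> tuple[SVCatalog, QCReport]:
    """Full QC stack in the fixed order; returns the surviving catalog and report."""
    report = QCReport()
    if bad_bins is None and cn is not None:
        bad_bins = detect_bad_bins(cn)
    if bad_bins is not None:
        catalog, report = filter_bad_bin_overlap(catalog, bad_bins, report)
    catalog, report = filter_gap_overlap(catalog, genome, report)
    catalog, report = filter_min_length(catalog, min_len=min_len, report=report)
    catalog, report = apply_type_filters(catalog, report=report)
    catalog, report = mask_sample_genotypes(catalog, capture_flags, report=report)
    return catalog, report
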