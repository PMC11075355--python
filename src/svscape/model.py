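"""Domain types for a multi-population structural-variant catalog.

Coordinates are 1-based and both-inclusive throughout: an event printed as
``1:119154722-119155024:DEL`` spans ``119155024 - 119154722 + 1 = 303`` bases.
Genotypes are dosages in {0, 1, 2} with -1 encoding a missing call, kept
distinct from homozygous-reference 0 everywhere.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .intervals import IntervalSet, merge_intervals

SV_TYPES = ("DEL", "MEI", "DUP", "INV", "BND")
MISSING = -1

MAIN_POPULATIONS = ("ASW", "ASD", "ASxEU", "EUC", "EUD", "EUW", "OTG")
#: main population -> ancestral group (Asian / European / other)
ANCESTRAL_GROUP = {
    "ASW": "AS", "ASD": "AS",
    "EUC": "EU", "EUD": "EU", "EUW": "EU",
    "ASxEU": "other", "OTG": "other",
}


class ParseError(ValueError):
    """Raised when a record or identifier cannot be parsed."""


@dataclass
class GenomeModel:
    """Reference chromosomes, their lengths, and assembly-gap intervals."""

    lengths: dict[str, int]
    gaps: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, n in self.lengths.items():
            if n <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {n}")
        for chrom, s, e in self.gaps:
            if chrom not in self.lengths:
                raise ValueError(f"gap on unknown chromosome {chrom}")
            if not (1 <= s <= e <= self.lengths[chrom]):
                raise ValueError(f"gap {chrom}:{s}-{e} outside chromosome bounds")

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def gap_set(self) -> IntervalSet:
        return IntervalSet(self.gaps)


_ID_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)[-–](?P<end>\d+):(?P<svtype>[A-Za-z]+)$")


def parse_sv_identifier(identifier: str) -> "SVRecord":
    """Parse a ``chrom:start-end:TYPE`` identifier into an SVRecord skeleton.

    Both the ASCII hyphen and the typographic en-dash are accepted as the
    span separator. Length is the inclusive span ``end - start + 1``.
    """
    m = _ID_RE.match(identifier.strip())
    if not m:
        raise ParseError(f"malformed SV identifier: {identifier!r}")
    svtype = m.group("svtype").upper()
    if svtype not in SV_TYPES:
        raise ParseError(f"unknown SV type token {m.group('svtype')!r} in {identifier!r}")
    start, end = int(m.group("start")), int(m.group("end"))
    if start > end:
        raise ParseError(f"start {start} > end {end} in {identifier!r}")
    return SVRecord(
        id=identifier.strip().replace("–", "-"),
        chrom=m.group("chrom"),
        start=start,
        end=end,
        svtype=svtype,
    )


@dataclass
class SVRecord:
    """One structural variant with evidence metrics and per-sample genotypes.

    `length` defaults to the inclusive span for non-BND types; for BND it is
    the absolute mate-position difference when the mate is on the same
    chromosome and None otherwise.
    """

    id: str
    chrom: str
    start: int
    end: int
    svtype: str
    length: int | None = None
    msq: float | None = None
    genotypes: np.ndarray | None = None        # int8 dosage, -1 missing
    sr_support: np.ndarray | None = None       # per-sample split-read counts
    pe_support: np.ndarray | None = None
    allele_balance: np.ndarray | None = None   # per-sample, NaN where undefined
    copy_number: np.ndarray | None = None
    min_size_95: int | None = None
    mate_chrom: str | None = None
    mate_pos: int | None = None

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ParseError(f"unknown SV type {self.svtype!r} for {self.id}")
        if self.end < self.start:
            raise ParseError(f"end < start for {self.id}")
        if self.length is None:
            if self.svtype != "BND":
                self.length = self.end - self.start + 1
            elif self.mate_chrom is not None and self.mate_chrom == self.chrom:
                self.length = abs(int(self.mate_pos) - self.start)
        if self.svtype != "BND" and self.length != self.end - self.start + 1:
            raise ParseError(
                f"length {self.length} inconsistent with inclusive span "
                f"{self.end - self.start + 1} for {self.id}"
            )
        if self.genotypes is not None:
            self.genotypes = np.asarray(self.genotypes, dtype=np.int8)

    @property
    def interval(self) -> tuple[str, int, int]:
        return self.chrom, self.start, self.end

    def allele_count(self) -> int:
        """ALT allele count over non-missing genotypes."""
        if self.genotypes is None:
            return 0
        g = self.genotypes
        return int(g[g != MISSING].sum())

    def n_nonmissing(self) -> int:
        if self.genotypes is None:
            return 0
        return int((self.genotypes != MISSING).sum())

    def allele_frequency(self) -> float:
        n = self.n_nonmissing()
        return self.allele_count() / (2 * n) if n else float("nan")

    def carriers(self) -> np.ndarray:
        """Boolean mask of samples with non-missing dosage >= 1."""
        if self.genotypes is None:
            raise ValueError(f"record {self.id} has no genotypes")
        return self.genotypes >= 1


@dataclass
class SVCatalog:
    """Ordered collection of SVRecords sharing one sample roster."""

    records: list[SVRecord]
    samples: tuple[str, ...]
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = tuple(self.samples)
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate SV ids in catalog: {dupes[:5]}")
        n = len(self.samples)
        for r in self.records:
            for arr in (r.genotypes, r.sr_support, r.pe_support,
                        r.allele_balance, r.copy_number):
                if arr is not None and len(arr) != n:
                    raise ValueError(
                        f"record {r.id}: per-sample array length {len(arr)} != roster size {n}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SVRecord]:
        return iter(self.records)

    def __getitem__(self, sv_id: str) -> SVRecord:
        for r in self.records:
            if r.id == sv_id:
                return r
        raise KeyError(sv_id)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def subset(self, keep: Iterable[str]) -> "SVCatalog":
        keep = set(keep)
        return SVCatalog([r for r in self.records if r.id in keep], self.samples,
                         notes=list(self.notes))

    def type_counts(self) -> dict[str, int]:
        out = {t: 0 for t in SV_TYPES}
        for r in self.records:
            out[r.svtype] += 1
        return out

    def merged_intervals(self) -> IntervalSet:
        """Nonredundant genomic footprint of all non-BND records."""
        return IntervalSet(r.interval for r in self.records if r.svtype != "BND")

    def genotype_matrix(self) -> "GenotypeMatrix":
        recs = [r for r in self.records if r.genotypes is not None]
        dosages = (np.stack([r.genotypes for r in recs], axis=1)
                   if recs else np.zeros((len(self.samples), 0), dtype=np.int8))
        return GenotypeMatrix(
            dosages=dosages,
            samples=self.samples,
            variant_ids=tuple(r.id for r in recs),
            chroms=tuple(r.chrom for r in recs),
            positions=np.array([r.start for r in recs], dtype=np.int64),
            kinds=tuple("SV" for _ in recs),
        )


@dataclass
class Transcript:
    transcript_id: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class GeneModel:
    """Gene with per-transcript structure; classification uses the unions."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self) -> None:
        for t in self.transcripts:
            if not t.exons:
                raise ValueError(f"gene {self.gene_id}: transcript {t.transcript_id} has no exons")
            ex = merge_intervals(t.exons)
            for sub, name in ((t.cds, "CDS"), (t.utr5, "5'UTR"), (t.utr3, "3'UTR")):
                for s, e in sub:
                    if not any(xs <= s and e <= xe for xs, xe in ex):
                        raise ValueError(
                            f"gene {self.gene_id}: {name} {s}-{e} outside exons of "
                            f"{t.transcript_id}"
                        )

    @property
    def body(self) -> tuple[int, int]:
        return self.start, self.end

    def exon_union(self) -> list[tuple[int, int]]:
        ivs = [iv for t in self.transcripts for iv in t.exons]
        if not ivs:
            raise ValueError(f"gene {self.gene_id} has no exons")
        return merge_intervals(ivs)

    def cds_union(self) -> list[tuple[int, int]]:
        return merge_intervals(iv for t in self.transcripts for iv in t.cds)

    def utr5_union(self) -> list[tuple[int, int]]:
        return merge_intervals(iv for t in self.transcripts for iv in t.utr5)

    def utr3_union(self) -> list[tuple[int, int]]:
        return merge_intervals(iv for t in self.transcripts for iv in t.utr3)


@dataclass
class FeatureTrack:
    """Labeled genomic intervals: repeats, chromatin states, QTLs, regulators."""

    name: str
    vocabulary: tuple[str, ...]
    intervals: list[tuple[str, int, int, str, str | None]] = field(default_factory=list)
    # each entry: (chrom, start, end, label, tissue-or-None)

    def __post_init__(self) -> None:
        vocab = set(self.vocabulary)
        bad = sorted({lab for _, _, _, lab, _ in self.intervals if lab not in vocab})
        if bad:
            raise ValueError(f"track {self.name}: labels outside vocabulary: {bad}")
        for chrom, s, e, lab, _ in self.intervals:
            if s > e:
                raise ValueError(f"track {self.name}: start > end at {chrom}:{s}-{e} ({lab})")

    def __len__(self) -> int:
        return len(self.intervals)

    def labels(self) -> list[str]:
        return sorted({lab for _, _, _, lab, _ in self.intervals})

    def tissues(self) -> list[str]:
        return sorted({t for _, _, _, _, t in self.intervals if t is not None})

    def subset(self, label: str | None = None, tissue: str | None = None) -> "FeatureTrack":
        ivs = [iv for iv in self.intervals
               if (label is None or iv[3] == label) and (tissue is None or iv[4] == tissue)]
        return FeatureTrack(self.name, self.vocabulary, ivs)

    def interval_set(self, label: str | None = None, tissue: str | None = None) -> IntervalSet:
        return IntervalSet((c, s, e) for c, s, e, lab, t in self.intervals
                           if (label is None or lab == label)
                           and (tissue is None or t == tissue))


@dataclass
class PopulationMap:
    """sample -> (main population, sub-population); ancestral group is derived."""

    main: dict[str, str]
    sub: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = sorted({p for p in self.main.values() if p not in MAIN_POPULATIONS})
        if bad:
            raise ValueError(f"unknown main populations: {bad}")

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.main)

    def ancestral(self, sample: str) -> str:
        return ANCESTRAL_GROUP[self.main[sample]]

    def group_of(self, sample: str, level: str = "main") -> str:
        if level == "main":
            return self.main[sample]
        if level == "ancestral":
            return self.ancestral(sample)
        if level == "sub":
            return self.sub.get(sample, self.main[sample])
        raise ValueError(f"unknown grouping level {level!r}")

    def members(self, group: str, level: str = "main") -> list[str]:
        return [s for s in self.main if self.group_of(s, level) == group]

    def check_roster(self, roster: Sequence[str]) -> None:
        missing = [s for s in roster if s not in self.main]
        if missing:
            raise ValueError(f"samples absent from population map: {missing}")


@dataclass
class GenotypeMatrix:
    """samples x variants dosage matrix ({0,1,2}, -1 missing) with coordinates."""

    dosages: np.ndarray
    samples: tuple[str, ...]
    variant_ids: tuple[str, ...]
    chroms: tuple[str, ...]
    positions: np.ndarray
    kinds: tuple[str, ...]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        n, m = self.dosages.shape
        if n != len(self.samples):
            raise ValueError("dosage rows != sample roster size")
        if not (m == len(self.variant_ids) == len(self.chroms)
                == len(self.positions) == len(self.kinds)):
            raise ValueError("dosage columns != variant annotation lengths")
        bad = sorted(set(self.kinds) - {"SV", "SNP"})
        if bad:
            raise ValueError(f"unknown variant kinds: {bad}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.variant_ids.index(variant_id)]

    def sample_rows(self, samples: Iterable[str]) -> np.ndarray:
        idx = [self.samples.index(s) for s in samples]
        return self.dosages[idx, :]

    @staticmethod
    def concatenate(parts: Sequence["GenotypeMatrix"]) -> "GenotypeMatrix":
        """Column-wise combination over an identical sample roster."""
        roster = parts[0].samples
        for p in parts[1:]:
            if p.samples != roster:
                raise ValueError("sample rosters differ between matrices")
        return GenotypeMatrix(
            dosages=np.concatenate([p.dosages for p in parts], axis=1),
            samples=roster,
            variant_ids=tuple(v for p in parts for v in p.variant_ids),
            chroms=tuple(c for p in parts for c in p.chroms),
            positions=np.concatenate([p.positions for p in parts]),
            kinds=tuple(k for p in parts for k in p.kinds),
        )


@dataclass
class FunctionalVariantCatalog:
    """e/sQTL, GWAS and TWAS records consumed as an input annotation set."""

    records: list[dict] = field(default_factory=list)
    # keys: kind (eQTL|sQTL|GWAS|TWAS), id, chrom, pos, gene_id, tissue, trait, p, fdr

    KINDS = ("eQTL", "sQTL", "GWAS", "TWAS")

    def __post_init__(self) -> None:
        for rec in self.records:
            kind = rec.get("kind")
            if kind not in self.KINDS:
                raise ValueError(f"unknown functional-variant kind {kind!r}")
            if kind in ("eQTL", "sQTL") and not rec.get("gene_id"):
                raise ValueError(f"{kind} record without target gene: {rec}")
            if kind == "GWAS" and rec.get("p") is None:
                raise ValueError(f"GWAS record without p-value: {rec}")
            if kind == "TWAS" and rec.get("fdr") is None:
                raise ValueError(f"TWAS record without FDR: {rec}")
            if kind != "TWAS" and (rec.get("chrom") is None or rec.get("pos") is None):
                raise ValueError(f"{kind} record without a position: {rec}")

    def __len__(self) -> int:
        return len(self.records)

    def of_kind(self, kind: str) -> list[dict]:
        return [r for r in self.records if r["kind"] == kind]
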