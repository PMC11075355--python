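"""Validation of short-read SVs against an assembly-comparison truth set.

A query SV is validated if it overlaps a truth SV by at least 1 bp on the
same chromosome; the matched pair's length consistency is the min/max length
ratio (a reconstruction: the source analysis reports ">98% length
consistency" without a formula). Best match per query is by largest
reciprocal overlap, ties broken by smaller length difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .intervals import overlap_length
from .model import SVCatalog, SVRecord


@dataclass(frozen=True)
class MatchedPair:
    query_id: str
    truth_id: str
    overlap_bp: int
    reciprocal_overlap: float     # min(ov/len_q, ov/len_t)
    consistency: float            # min(len_q, len_t) / max(len_q, len_t)


@dataclass
class ValidationReport:
    n_query: int
    n_validated: int
    query_bp: int
    validated_bp: int
    pairs: list[MatchedPair] = field(default_factory=list)

    @property
    def rate_by_count(self) -> float:
        return self.n_validated / self.n_query if self.n_query else float("nan")

    @property
    def rate_by_length(self) -> float:
        return self.validated_bp / self.query_bp if self.query_bp else float("nan")

    def high_consistency_fraction(self, threshold: float = 0.98) -> float:
        """Fraction of matched pairs with length consistency above `threshold`."""
        if not self.pairs:
            return float("nan")
        return sum(p.consistency > threshold for p in self.pairs) / len(self.pairs)

    def as_dict(self) -> dict:
        return {
            "n_query": self.n_query,
            "n_validated": self.n_validated,
            "rate_by_count": self.rate_by_count,
            "rate_by_length": self.rate_by_length,
            "high_consistency_fraction": self.high_consistency_fraction(),
        }


def _intervals(records) -> list[SVRecord]:
    return [r for r in records if r.svtype != "BND"]


def match_sv_sets(query: SVCatalog | list[SVRecord],
                  truth: SVCatalog | list[SVRecord],
                  min_overlap: int = 1) -> list[MatchedPair]:
    """Best >=`min_overlap` bp same-chromosome match per query record.

    Every overlapping truth record is a candidate; the retained match
    maximises reciprocal overlap, then minimises |length difference|."""
    truth_by_chrom: dict[str, list[SVRecord]] = {}
    for t in _intervals(truth.records if isinstance(truth, SVCatalog) else truth):
        truth_by_chrom.setdefault(t.chrom, []).append(t)
    pairs: list[MatchedPair] = []
    for q in _intervals(query.records if isinstance(query, SVCatalog) else query):
        best: MatchedPair | None = None
        best_key: tuple[float, int] | None = None
        for t in truth_by_chrom.get(q.chrom, ()):
            ov = overlap_length((q.start, q.end), (t.start, t.end))
            if ov < min_overlap:
                continue
            recip = min(ov / q.length, ov / t.length)
            cons = min(q.length, t.length) / max(q.length, t.length)
            key = (-recip, abs(q.length - t.length))
            if best_key is None or key < best_key:
                best_key = key
                best = MatchedPair(q.id, t.id, ov, recip, cons)
        if best is not None:
            pairs.append(best)
    return pairs


def validation_rates(pairs: list[MatchedPair],
                     query: SVCatalog | list[SVRecord],
                     length_mode: str = "query_bp") -> ValidationReport:
    """Aggregate validated fractions by count and by length.

    `length_mode` fixes the by-length numerator: "query_bp" (full span of
    each validated query record; the default) or "overlap_bp" (only the
    overlapped bases) — the source reporting is ambiguous between the two.
    """
    records = _intervals(query.records if isinstance(query, SVCatalog) else query)
    by_id = {r.id: r for r in records}
    matched = {p.query_id: p for p in pairs}
    total_bp = sum(r.length for r in records)
    if length_mode == "query_bp":
        val_bp = sum(by_id[qid].length for qid in matched if qid in by_id)
    elif length_mode == "overlap_bp":
        val_bp = sum(p.overlap_bp for p in matched.values())
    else:
        raise ValueError(f"unknown length_mode {length_mode!r}")
    return ValidationReport(
        n_query=len(records),
        n_validated=sum(1 for r in records if r.id in matched),
        query_bp=total_bp,
        validated_bp=val_bp,
        pairs=pairs,
    )
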