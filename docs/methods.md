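# Methods

## Coordinates and conventions

All internal coordinates are 1-based and both-inclusive; an event
`chrom:start-end:TYPE` spans `end − start + 1` bases (so
`1:119154722-119155024:DEL` is 303 bp). BED I/O converts from 0-based
half-open at the boundary. VCF `END` is read as the last affected base from
the raw INFO field rather than through htslib's record length, because
current htslib applies VCF 4.4 semantics (`END = POS + |SVLEN|`) when both
keys are present, which is off by one against this convention. The dialect
written by `svscape.io` stores `SVLEN = end − start + 1` (positive inclusive
span). SV-caller output using the base-before-the-event convention can
therefore disagree with printed identifiers by 1 bp; the convention here is
fixed and the discrepancy is documented, not silently reconciled. Both the
ASCII hyphen and the typographic en-dash are accepted in identifiers.

Genotypes are dosages in {0, 1, 2} with −1 for missing, and missing is
never counted in allele-number denominators. BND records carry a length
only when the mate breakend is on the same chromosome (absolute position
difference); inter-chromosomal BNDs have none and are exempt from the
length filter.

## Quality control

Filters run in a fixed order — bad-bin overlap, gap overlap, minimum
length, type-specific evidence, per-sample masking — because the source
procedures state no order; each filter is idempotent and order-independent
as a set operation, so the choice only affects per-filter attribution in
the report. Threshold comparisons are literal: copy number strictly > 10,
MSQ strictly > 100/150/250, DELs ≤ 1000 bp inclusive need split-read
support, events < 50 bp strictly are removed, bad-bin flagging needs
`ceil(0.90 · n)` samples. "At least 10% read support" for inversions is
operationalized as mean allele balance across carrier samples ≥ 0.10 — the
denominator is undefined in the source — and is configurable. "Poorly
captured by split reads" is likewise never defined quantitatively upstream
and is accepted as a per-(record, sample) boolean input annotation rather
than guessed. A record subject to an MSQ rule but lacking MSQ is removed
(conservative) and logged.

## Impact classification

Canonical CDS/UTR/exon sets are unions over all transcripts of a gene.
Category precedence within one gene is whole-gene engulfment > CDS > UTR >
noncoding exon > intron; the source enumerates the categories but not their
precedence, and this ordering mirrors decreasing severity. Strong vs weak
uses fraction ≥ 0.20 of the SV's own length (the boundary value is strong;
the source defines weak as "less than 20%"). When one SV touches both UTRs
of a gene the larger overlap wins, ties to 5′ (arbitrary, documented).
Multi-gene SVs yield one call per gene, which is why per-category SV
tallies can exceed the SV total. MEIs in a reference-based catalog are
deletions where the reference carries the element, so an MEI engulfing a
gene is treated as whole-gene loss (WlGnDel); BND has no whole-gene class
and falls through to the coding/intron logic. DEL→MEI reclassification
requires the deduplicated repeat union to cover strictly more than 90% of
the event and rewrites only the type (and id suffix), never coordinates.

Frequency classes are allele-count based: singleton AC = 1, rare
1 < AC ≤ 10, common AC > 10. The alternative AF < 0.01 phrasing is
internally inconsistent at large 2N, so AF is reported but never sets the
boundary.

## Enrichment statistics

Fold enrichment merges the SV set first, making results invariant to
duplicated or overlapping input records. The test is Pearson χ² without
continuity correction on the 2×2 base-pair table (the source names only
"Chi-squared Test"); cross-sample contrasts use the two-sided
pooled-variance Student's t (not Welch, per the source's naming); families
are Bonferroni-corrected over the labels tested in the same call.

Base-pair-resolution χ² treats every base as an independent trial. For
point-scale events that is exact, and the null-calibration suite verifies
it: on 1000 uniform-placement replicates with unit-length variants the
adjusted-significance rate at p ≤ 0.01 stays ≤ 0.02. For multi-kilobase
intervals the within-event correlation inflates the statistic — a known
property of bp-unit enrichment tests generally, shared with the published
analysis this reproduces — so an interval-count mode
(`fold_enrichment_by_count`) is provided alongside the default bp mode.

The per-individual QTL fold underlying the cross-population ANOVA is never
formally defined upstream and is reconstructed as: (trait-QTL bp overlapped
by the individual's carried SVs / the individual's SV bp) / (trait-QTL bp /
genome bp), log2-transformed with a 1 bp pseudocount. The ANOVA is one-way
across main populations; a trait is reported iff Bonferroni-adjusted
p < 0.01 and the coefficient of variation of group means exceeds 1.

## Population genetics and LD

FST is the Weir & Cockerham (1984) two-population estimator from the
a/b/c variance components, computed per variant for outlier ranking and as
the multi-locus ratio of summed components for genome-wide values. The
multi-locus form is the combination the estimator's authors prescribe: the
per-locus average of ratios is biased toward zero (≈ 0.31 at a true
F = 0.5 on the recovery panels), while the ratio of sums recovers F within
±0.01 at n = 100/group, 2000 variants. The upstream software's default
estimator on its version is not stated; Weir–Cockerham is that software's
documented default and the choice is recorded, not asserted. Top-percentile
calls use the nearest-rank (1−q) quantile with all ties at the threshold
included.

LD r² is the squared Pearson correlation of genotype dosages over samples
non-missing at both variants (composite r²), not EM-phased haplotype r² —
deterministic and matching common usage of the cited command, with the
divergence risk for strongly structured samples noted. Tiers are nested by
construction: linked (≥ 0.2) ⊇ tagged (≥ 0.5) ⊇ highly-tagged (≥ 0.8).
Variant thinning is greedy first-kept in position order per chromosome,
reproducible without randomness. "Carried" means a non-missing dosage ≥ 1;
missingness is never treated as absence. The functional network admits LD
edges only to SNPs with a passing functional record (e/sQTLs are lead
variants as given — no clumping is re-implemented; GWAS p ≤ 5×10⁻⁸), TWAS
genes need FDR ≤ 0.05 and e/sGene status, and SV–gene edges record direct
or ±5 kb-extended body overlap.

## Assembly validation

"Length consistency" has no published formula and is reconstructed as
min/max of the two matched lengths; best match per query is by largest
reciprocal overlap, ties by smaller length difference. The by-length
validation rate uses the full span of validated query records in the
numerator (the published description is ambiguous between query bp and
overlapped bp; the alternative is available via `length_mode`).

## Synthetic worlds

The generator emulates the *structure* of a population SV catalog at desk
scale, not its size: defaults are a 2 × 4 Mb genome, 160 gene models
(12.5% non-coding), a 100-individual panel at the seven main populations'
published shares (ASW 5, ASD 41, ASxEU 2, EUC 39, EUD 8, EUW 2, OTG 3),
and 200 SVs at the published per-type proportions (65 DEL, 58 MEI, 5 DUP,
2 INV, 70 BND). Balding–Nichols differentiation (population AF ~
Beta(p(1−F)/F, (1−p)(1−F)/F) around an ancestral p ~ U(0.05, 0.95)) was
chosen because it gives a closed-form ground-truth F for recovery tests;
F defaults to 0.2, a typical Asian/European pig differentiation level.
Repeat lengths follow the SINE ≈ 250 bp / LINE ≈ 7.5 kb modes of real MEI
size distributions. SV–SNP LD is induced by per-haplotype allele copying
with distance-decaying fidelity rather than coalescent simulation —
sufficient to produce target r² tiers, but non-genealogical: it yields no
realistic decay curve or allele-age structure, so a green LD test
establishes correctness of the r² machinery, not population realism.
Likewise the planted impact categories make classifier recovery a sharp
100% target rather than a statistical one. Copy-number windows are
Normal(2, 0.3) truncated at zero with planted bad bins at CN 12 in 95% of
samples. All randomness flows from a single seed through named
`SeedSequence` children; identical configurations are byte-identical.

What the generator does *not* emulate: sequencing evidence (MSQ, split
reads and allele balance are assigned, not simulated from reads), overlap
between planted SVs, linkage between SVs themselves, mutation/recombination
processes, and genuine genome sequence (all tracks are intervals; no stage
needs FASTA).

## Known limitations

- The χ² bp-mode anticonservatism for long intervals described above.
- Group-specific SV calls depend on carrier observation only; at small
  group sizes absence of evidence is weak evidence of absence.
- The LD scan is a quadratic in-window pass suitable for desk-scale panels,
  not an optimized genome-wide engine.
- Assembly validation assumes the truth set shares the catalog's reference
  coordinates; no liftover is provided.
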