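"""Independent brute-force reference implementations used only by tests.

Everything here works per base via Python sets, or via textbook formulas
written out explicitly, deliberately sharing no code with the package paths
they check.
"""

from __future__ import annotations

import math


def base_set(intervals) -> set[int]:
    out: set[int] = set()
    for s, e in intervals:
        out |= set(range(s, e + 1))
    return out


def union_length_bruteforce(intervals) -> int:
    return len(base_set(intervals))


def intersect_length_bruteforce(a, b) -> int:
    return len(base_set(a) & base_set(b))


def classify_pair_bruteforce(sv, gene, strong=0.20) -> str:
    """Per-base re-derivation of the 15-category call for one (SV, gene) pair."""
    sv_bases = set(range(sv.start, sv.end + 1))
    cds = base_set(iv for t in gene.transcripts for iv in t.cds)
    utr5 = base_set(iv for t in gene.transcripts for iv in t.utr5)
    utr3 = base_set(iv for t in gene.transcripts for iv in t.utr3)
    exons = base_set(iv for t in gene.transcripts for iv in t.exons)
    n = len(sv_bases)
    if sv.start <= gene.start and sv.end >= gene.end:
        if sv.svtype in ("DEL", "MEI"):
            return "WlGnDel"
        if sv.svtype == "DUP":
            return "WlGnDup"
        if sv.svtype == "INV":
            return "WlGnInv"
    cds_f = len(sv_bases & cds) / n
    if cds_f > 0:
        if sv.svtype in ("DEL", "MEI"):
            return "pLoF_St" if cds_f >= strong else "pLoF_Wk"
        if sv.svtype == "DUP":
            return "CpGn_St" if cds_f >= strong else "CpGn_Wk"
        if sv.svtype == "INV":
            return "codInv"
        return "codBnd"
    u5 = len(sv_bases & utr5) / n
    u3 = len(sv_bases & utr3) / n
    if u5 > 0 or u3 > 0:
        if u5 >= u3:
            return "Rglt5_St" if u5 >= strong else "Rglt5_Wk"
        return "Rglt3_St" if u3 >= strong else "Rglt3_Wk"
    if sv_bases & exons and gene.biotype != "protein_coding":
        return "noncoding"
    return "intron"


def chi2_2x2_bruteforce(a, b, c, d) -> float:
    """Pearson chi-squared from the textbook O/E formula."""
    n = a + b + c + d
    chi2 = 0.0
    for obs, row, col in ((a, a + b, a + c), (b, a + b, b + d),
                          (c, c + d, a + c), (d, c + d, b + d)):
        exp = row * col / n
        chi2 += (obs - exp) ** 2 / exp
    return chi2


def pearson_r2_bruteforce(x, y) -> float:
    """Squared correlation via explicit sums."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return (num / den) ** 2


def wc_theta_bruteforce(g1, g2) -> float | None:
    """Weir-Cockerham (1984) two-population theta-hat for one biallelic
    locus from genotype lists (dosages 0/1/2, None = missing)."""
    g1 = [g for g in g1 if g is not None]
    g2 = [g for g in g2 if g is not None]
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        return None
    p1 = sum(g1) / (2 * n1)
    p2 = sum(g2) / (2 * n2)
    h1 = sum(1 for g in g1 if g == 1) / n1
    h2 = sum(1 for g in g2 if g == 1) / n2
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = nbar / nc * (s2 - 1 / (nbar - 1)
                     * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    if a + b + c == 0:
        return None
    return a / (a + b + c)
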