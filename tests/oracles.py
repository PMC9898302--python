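"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own primitives (encoding helpers,
vectorized window views, scipy shortcuts) so each check is a genuinely
separate route to the same answer.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_COMP.get(b, "N") for b in reversed(seq))


# ------------------------------------------------------------------- mapper


def oracle_hits(seq: str, reference: dict, max_mm: int):
    """(contig, offset, strand, mismatches) for every placement, both
    strands, by positionwise counting."""
    hits = []
    for contig, ref in reference.items():
        ref_bytes = np.frombuffer(ref.encode(), dtype=np.uint8)
        for strand, q in (("+", seq), ("-", oracle_revcomp(seq))):
            L = len(q)
            n = len(ref) - L + 1
            if n <= 0:
                continue
            qb = np.frombuffer(q.encode(), dtype=np.uint8)
            mm = np.zeros(n, dtype=np.int64)
            for i in range(L):
                mm += ref_bytes[i:i + n] != qb[i]
            for off in np.nonzero(mm <= max_mm)[0]:
                hits.append((contig, int(off), strand, int(mm[off])))
    return hits


def oracle_map(seq: str, reference: dict, max_mm: int = 1, trim3: int = 2):
    """Unique-in-best-stratum mapping decision for one read sequence.

    Returns ('mapped', contig, offset, strand, nm) or ('no_hit',) or
    ('multimapped',).
    """
    eff = seq[:-trim3] if trim3 else seq
    if not eff:
        return ("no_hit",)
    hits = oracle_hits(eff, reference, max_mm)
    if not hits:
        return ("no_hit",)
    best = min(h[3] for h in hits)
    stratum = [h for h in hits if h[3] == best]
    if len(stratum) > 1:
        return ("multimapped",)
    contig, off, strand, nm = stratum[0]
    return ("mapped", contig, off, strand, nm)


# ----------------------------------------------------------------- binomial


def oracle_binomial_tail(g: int, n: int, p: Fraction) -> Fraction:
    """Exact upper-tail P(X >= g), arbitrary precision."""
    if g <= 0:
        return Fraction(1)
    if g > n:
        return Fraction(0)
    q = 1 - p
    return sum(comb(n, k) * p**k * q**(n - k) for k in range(g, n + 1))


# ---------------------------------------------------------------- seed scan


def oracle_window_match(utr: str, i: int, seed: str, site_type: str) -> bool:
    """Test one UTR window against one site-type definition, base by base.

    ``seed`` is the DNA 7-mer of miRNA positions 2-8 (index 0 = position 2).
    """
    core = seed if site_type in ("8mer", "7mer-m8") else seed[:6]
    k = len(core)
    if i + k > len(utr):
        return False
    for j in range(k):
        # UTR runs 5'->3'; the miRNA pairs antiparallel, so UTR base j of the
        # window faces seed base k-1-j and must be its complement
        if utr[i + j] != _COMP.get(core[k - 1 - j]):
            return False
    if site_type in ("8mer", "7mer-A1"):
        return i + k < len(utr) and utr[i + k] == "A"
    return True


def oracle_scan(seed: str, utr: str):
    """(start, site_type) list with the same priority rule, independently."""
    out = []
    for i in range(len(utr)):
        for t in ("8mer", "7mer-m8", "7mer-A1", "6mer"):
            if oracle_window_match(utr, i, seed, t):
                out.append((i, t))
                break
    return out


# -------------------------------------------------------------------- ranks


def oracle_midranks(values):
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def oracle_spearman(x, y) -> float:
    rx, ry = oracle_midranks(x), oracle_midranks(y)
    mx = sum(rx) / len(rx)
    my = sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = sum((a - mx) ** 2 for a in rx) ** 0.5
    dy = sum((b - my) ** 2 for b in ry) ** 0.5
    return num / (dx * dy)


def oracle_auc(scores, labels) -> float:
    """Pairwise concordance count with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def oracle_ranksum_permutation_p(group_a, group_b) -> float:
    """Exact two-sided permutation p-value of the rank-sum statistic."""
    pooled = list(group_a) + list(group_b)
    ranks = oracle_midranks(pooled)
    na = len(group_a)
    obs = sum(ranks[:na])
    mean = sum(ranks) * na / len(pooled)
    dev = abs(obs - mean)
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), na):
        stat = sum(ranks[i] for i in idx)
        if abs(stat - mean) >= dev - 1e-12:
            count += 1
        total += 1
    return count / total


# ------------------------------------------------------------------- pileup


def oracle_pileup_tally(alignments):
    """{(contig, pos): {base: count}} from (contig, start, seq) tuples."""
    tally = {}
    for contig, start, seq in alignments:
        for i, base in enumerate(seq):
            d = tally.setdefault((contig, start + i), {})
            d[base] = d.get(base, 0) + 1
    return tally
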