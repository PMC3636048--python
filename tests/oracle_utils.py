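"""Independent brute-force oracles used by the test suite.

Everything here works on explicit per-base sets or exhaustive enumeration
and deliberately shares no code with the implementation it checks.
"""

from itertools import combinations

import numpy as np
from scipy import stats


def bitmap(intervals, size):
    """Boolean per-base occupancy array for intervals on one chromosome."""
    arr = np.zeros(size, dtype=bool)
    for s, e in intervals:
        arr[s:e] = True
    return arr


def bitmap_classify(te_span, transcript, exon_idx, min_overlap=10):
    """Per-base feature category for one TE against one exon, or None.

    Uses python sets of base positions and re-derives roles and boundary
    bases from first principles.
    """
    te = set(range(*te_span))
    s, e = transcript.exons[exon_idx]
    exon = set(range(s, e))
    if len(te & exon) < min_overlap:
        return None
    order = sorted(exon) if transcript.strand == "+" else sorted(exon, reverse=True)
    five_base, three_base = order[0], order[-1]
    n = len(transcript.exons)
    ordinal = exon_idx + 1 if transcript.strand == "+" else n - exon_idx
    if n == 1:
        role = "single"
    elif ordinal == 1:
        role = "first"
    elif ordinal == n:
        role = "last"
    else:
        role = "internal"
    if exon <= te:
        return {"single": "FULL_SINGLE", "first": "TSS_SPL",
                "internal": "BOTH_SPL", "last": "POLYA_SPL"}[role]
    has5 = five_base in te
    has3 = three_base in te
    if role == "single":
        return "TSS" if has5 else "POLYA" if has3 else "EXONIZED"
    if role == "first":
        return "TSS" if has5 else "SPL" if has3 else "EXONIZED"
    if role == "last":
        return "POLYA" if has3 else "SPL" if has5 else "EXONIZED"
    return "SPL" if (has5 or has3) else "EXONIZED"


def enumerate_pair_prob(kappa):
    """3x3 enumeration of double substitutions on an A:U pair."""
    transition = {"A": "G", "G": "A", "C": "U", "U": "C"}
    wc = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
    tot = hit = 0.0
    for x in "CGU":
        wx = kappa if transition["A"] == x else 1.0
        for y in "ACG":
            wy = kappa if transition["U"] == y else 1.0
            tot += wx * wy
            if (x, y) in wc:
                hit += wx * wy
    return hit / tot


def enumerate_stem_tail(N, m, n, c, kappa):
    """P(>= c compensatory pairs) by exhaustive placement enumeration."""
    if c == 0:
        return 1.0
    p = enumerate_pair_prob(kappa)
    count = 0
    acc = 0.0
    for a in combinations(range(N), m):
        for b in combinations(range(N), n):
            j = len(set(a) & set(b))
            count += 1
            acc += float(stats.binom.sf(c - 1, j, p))
    return acc / count
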