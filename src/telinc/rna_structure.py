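"""Compensatory-mutation statistics for TE-derived RNA stems, and editing
density by segment class.

An exonised TE with long inverted repeats can fold back on itself into a
stem-loop. If the stem is under structural constraint, substitutions on one
arm tend to be accompanied by substitutions on the other arm that restore
Watson-Crick pairing (compensatory mutations). Given a stem of N base
pairs with m observed substitutions on one arm and n on the other
(relative to the family consensus), the number of co-mutated pairs J
follows a hypergeometric distribution; conditional on J = j, the number of
compensatory pairs is Binomial(j, p), where p is the probability that two
independent substitutions on a Watson-Crick pair restore pairing under a
transition/transversion-weighted substitution model:

    p(kappa) = (kappa^2 + 2) / (kappa + 2)^2

(each base mutates to its transition partner with weight kappa and to each
transversion with weight 1; of the nine joint outcomes, the
transition-transition one and two transversion pairings are again
Watson-Crick). The stem p-value is the tail probability of observing at
least c compensatory pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .intervals import IntervalSet

WATSON_CRICK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}
TRANSITION = {"A": "G", "G": "A", "C": "U", "U": "C"}


@dataclass
class StemModel:
    """Paired positions of one stem with per-arm substitution counts."""

    name: str
    pairs: Tuple[Tuple[int, int], ...]  # (i, j) 0-based positions, i < j
    m: int  # substitutions on the 5' arm
    n: int  # substitutions on the 3' arm
    c: int  # compensatory (pair-restoring) co-substitutions
    kappa: float = 1.2

    def __post_init__(self):
        N = len(self.pairs)
        if not (0 <= self.c <= min(self.m, self.n) and self.m <= N and self.n <= N):
            raise ValueError(
                f"inconsistent stem counts N={N}, m={self.m}, n={self.n}, c={self.c}"
            )
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")

    @property
    def N(self) -> int:
        return len(self.pairs)


def pair_compensation_prob(kappa: float) -> float:
    """Probability two substitutions on a Watson-Crick pair restore pairing."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    return (kappa**2 + 2) / (kappa + 2) ** 2


def stem_pvalue(stem: StemModel) -> float:
    """P(at least c compensatory pairs | N, m, n, kappa).

    Composes the hypergeometric co-placement of the two arms' substitutions
    with the binomial compensation probability per co-mutated pair.
    """
    N, m, n, c = stem.N, stem.m, stem.n, stem.c
    if c == 0:
        return 1.0
    p = pair_compensation_prob(stem.kappa)
    j_min = max(0, m + n - N)
    j_max = min(m, n)
    total = 0.0
    for j in range(j_min, j_max + 1):
        pj = stats.hypergeom.pmf(j, N, m, n)
        total += pj * float(stats.binom.sf(c - 1, j, p))
    return float(min(1.0, total))


def bonferroni(pvals: Sequence[float], n_tests: Optional[int] = None) -> List[float]:
    """min(1, p * n_tests); n_tests defaults to the number of p-values."""
    n = n_tests if n_tests is not None else len(pvals)
    return [min(1.0, p * n) for p in pvals]


def parse_dotbracket(structure: str) -> List[Tuple[int, int]]:
    """Base pairs (i, j), i < j, from a dot-bracket string."""
    stack: List[int] = []
    pairs: List[Tuple[int, int]] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            pairs.append((stack.pop(), i))
        elif ch != ".":
            raise ValueError(f"unexpected character {ch!r} in dot-bracket string")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    pairs.sort()
    return pairs


def call_stem_mutations(
    element_seq: str,
    consensus_seq: str,
    structure: str,
    kappa: float = 1.2,
    name: str = "stem",
    count_wobble: bool = False,
) -> StemModel:
    """Compare an element to its consensus over the paired stem positions.

    The structure describes the element; sequences must be aligned and of
    equal length (gap-free positions only). m and n count positions on the
    5' and 3' arms where the element differs from consensus; c counts pairs
    where both arms differ and the element still forms a Watson-Crick pair
    (or, with ``count_wobble``, a G:U wobble).
    """
    element = element_seq.upper().replace("T", "U")
    consensus = consensus_seq.upper().replace("T", "U")
    if len(element) != len(consensus):
        raise ValueError(
            f"element ({len(element)} nt) and consensus ({len(consensus)} nt) "
            "lengths differ after alignment"
        )
    if len(structure) != len(element):
        raise ValueError("structure length does not match sequence length")
    pairs = parse_dotbracket(structure)
    good = WATSON_CRICK | WOBBLE if count_wobble else WATSON_CRICK
    m = n = c = 0
    for i, j in pairs:
        mut_i = element[i] != consensus[i]
        mut_j = element[j] != consensus[j]
        m += mut_i
        n += mut_j
        if mut_i and mut_j and (element[i], element[j]) in good:
            c += 1
    return StemModel(name=name, pairs=tuple(pairs), m=m, n=n, c=c, kappa=kappa)


# ---------------------------------------------------------------------------
# RNA editing density by segment class


def editing_density(
    segments: Dict[str, "IntervalSet"],
    sites: "IntervalSet",
) -> Dict[str, float]:
    """Editing sites per base for each segment class (Alu / other_TE / non_TE).

    ``segments`` maps class label to the interval set of exonic bases of
    that class; a site is attributed to the class whose intervals contain
    its (single-base) position.
    """
    out = {}
    for label, ivset in segments.items():
        bp = ivset.covered_bp()
        n_sites = sites.intersection(ivset).covered_bp()
        out[label] = n_sites / bp if bp else 0.0
    return out


# -- independent enumeration oracles (used by the test-suite contracts) ------


def enumerate_compensation_prob(kappa: float) -> float:
    """Brute-force 3x3 enumeration of double-substitution outcomes."""
    total = comp = 0.0
    base5, base3 = "A", "U"
    for b5 in "ACGU":
        if b5 == base5:
            continue
        w5 = kappa if TRANSITION[base5] == b5 else 1.0
        for b3 in "ACGU":
            if b3 == base3:
                continue
            w3 = kappa if TRANSITION[base3] == b3 else 1.0
            total += w5 * w3
            if (b5, b3) in WATSON_CRICK:
                comp += w5 * w3
    return comp / total


def enumerate_stem_pvalue(N: int, m: int, n: int, c: int, kappa: float) -> float:
    """Exhaustive placement enumeration of P(>= c compensatory pairs)."""
    from itertools import combinations

    if c == 0:
        return 1.0
    p = pair_compensation_prob(kappa)
    placements = 0
    prob_sum = 0.0
    for arm5 in combinations(range(N), m):
        for arm3 in combinations(range(N), n):
            j = len(set(arm5) & set(arm3))
            placements += 1
            prob_sum += float(stats.binom.sf(c - 1, j, p)) if j else (1.0 if c == 0 else 0.0)
    return prob_sum / placements
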