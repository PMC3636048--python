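"""TE-family over-representation in a target interval set.

For each repeat family the observed number of distinct fragments
overlapping the target (k) is compared with the expectation under random
scattering, M*f, where M is the total number of overlapping fragments and
f the family's genome-wide share of fragments in the filtered TE universe.
Significance is the exact upper-tail binomial P(X >= k | X ~ Bin(M, f));
the reported flag additionally requires the observed/expected ratio to
exceed ``min_ratio`` and k >= ``min_fragments``, mirroring the common
practice of pairing a count test with a fold-change floor. No
multiple-testing correction is applied by default (Benjamini-Hochberg is
available and recommended for large family universes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

from scipy import stats

from .genome_io import TEFragment, te_interval_set
from .intervals import IntervalSet

log = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    family: str
    te_class: str
    k: int  # observed fragments overlapping the target
    M: int  # total overlapping fragments
    f: float  # genome-wide family fraction (by fragment count)
    pvalue: float
    significant: bool

    @property
    def expected(self) -> float:
        return self.M * self.f

    @property
    def ratio(self) -> float:
        return self.k / self.expected if self.expected > 0 else float("inf")


def overlapping_fragments(
    tes: Sequence[TEFragment],
    target: IntervalSet,
    min_overlap: int = 10,
) -> List[TEFragment]:
    """Distinct fragments overlapping the target projection by >= min_overlap."""
    target = target.union()
    te_set = te_interval_set(tes)
    pairs = target.intersect_pairs(te_set, min_overlap=min_overlap)
    hit_spans = {b for _, b, _ in pairs}
    seen = set()
    out = []
    for f in tes:
        if (f.chrom, f.start, f.end) in hit_spans and f.id not in seen:
            seen.add(f.id)
            out.append(f)
    return out


def family_enrichment(
    target_fragments: Sequence[TEFragment],
    universe: "Sequence[TEFragment] | Dict[str, int]",
    min_fragments: int = 5,
    min_ratio: float = 2.0,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> List[EnrichmentResult]:
    """Per-family count enrichment of target fragments against the universe.

    ``universe`` is either the genome-wide fragment list or, for very large
    universes, a precomputed mapping family -> fragment count.
    """
    if min_fragments < 1:
        raise ValueError("min_fragments must be >= 1")
    M = len({f.id for f in target_fragments})
    if M == 0:
        log.warning("no fragments overlap the target set; empty enrichment result")
        return []
    fam_class: Dict[str, str] = {}
    if isinstance(universe, dict):
        fam_universe: Dict[str, int] = dict(universe)
        n_universe = sum(fam_universe.values())
    else:
        fam_universe = {}
        for f in universe:
            fam_universe[f.family] = fam_universe.get(f.family, 0) + 1
            fam_class[f.family] = f.te_class
        n_universe = len(universe)
    fam_target: Dict[str, int] = {}
    for f in target_fragments:
        fam_target[f.family] = fam_target.get(f.family, 0) + 1

    results = []
    for family, k in sorted(fam_target.items()):
        if k < min_fragments:
            continue
        f_share = fam_universe.get(family, 0) / n_universe
        p = float(stats.binom.sf(k - 1, M, f_share)) if f_share > 0 else 0.0
        results.append(
            EnrichmentResult(
                family=family,
                te_class=fam_class.get(family, "NA"),
                k=k,
                M=M,
                f=f_share,
                pvalue=p,
                significant=False,
            )
        )
    pvals = [r.pvalue for r in results]
    adjusted = _bh(pvals) if bh_correct else pvals
    for r, p_adj in zip(results, adjusted):
        r.pvalue = p_adj
        r.significant = p_adj < alpha and r.ratio > min_ratio
    return results


def _bh(pvals: List[float]) -> List[float]:
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank, i in zip(range(m, 0, -1), reversed(order)):
        prev = min(prev, pvals[i] * m / rank)
        adj[i] = prev
    return adj


@dataclass
class CoverageEnrichment:
    family: str
    observed_bp: int
    expected_bp: float

    @property
    def ratio(self) -> float:
        return self.observed_bp / self.expected_bp if self.expected_bp > 0 else float("inf")


def coverage_enrichment(
    target: IntervalSet,
    tes: Sequence[TEFragment],
    min_overlap: int = 10,
) -> List[CoverageEnrichment]:
    """Observed vs expected family bp in the target, f defined by bp share.

    Expected bp = (total TE bp overlapping the target) x (family's share of
    genome-wide TE bp). Significance is assessed on counts by
    :func:`family_enrichment`; this view reports the base-pair ratios only.
    """
    target = target.union()
    fam_bp_genome: Dict[str, int] = {}
    fam_bp_target: Dict[str, int] = {}
    for f in tes:
        fam_bp_genome[f.family] = fam_bp_genome.get(f.family, 0) + f.length
        ov = target.overlap_bp(f.chrom, f.start, f.end)
        if ov >= min_overlap:
            fam_bp_target[f.family] = fam_bp_target.get(f.family, 0) + ov
    total_genome = sum(fam_bp_genome.values())
    total_target = sum(fam_bp_target.values())
    out = []
    for family in sorted(fam_bp_target):
        share = fam_bp_genome[family] / total_genome
        out.append(
            CoverageEnrichment(
                family=family,
                observed_bp=fam_bp_target[family],
                expected_bp=total_target * share,
            )
        )
    return out


def age_partition(
    fragments: Sequence[TEFragment],
    age_table: Dict[str, str],
) -> Dict[str, float]:
    """Base-pair shares by age label (lineage_specific / ancient / NA).

    ``age_table`` maps family name to label; unknown families fall in NA.
    Shares sum to 1 when any fragments are supplied.
    """
    bp = {"lineage_specific": 0, "ancient": 0, "NA": 0}
    for f in fragments:
        label = age_table.get(f.family, "NA")
        if label not in bp:
            raise ValueError(f"unknown age label {label!r} for {f.family}")
        bp[label] += f.length
    total = sum(bp.values())
    if total == 0:
        return {k: 0.0 for k in bp}
    return {k: v / total for k, v in bp.items()}
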