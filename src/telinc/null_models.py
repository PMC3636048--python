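"""Shuffle nulls, empirical p-values, Jaccard statistic, permutation tests.

The feature-category null keeps transcript models fixed and re-places every
TE uniformly at random within its own chromosome, avoiding assembly gaps
and mutual overlap, preserving each fragment's length, family and class.
Category counts are recomputed on each of K replicates; the empirical
p-value of a category is the fraction of replicates with a strictly lower
count than observed, so a small p flags depletion of the observed count
relative to random TE placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .feature_annot import category_counts, classify_all
from .genome_io import GenomeLayout, TEFragment, TranscriptModel, te_interval_set
from .intervals import IntervalSet, place_nonoverlapping


@dataclass
class NullDistribution:
    observed: Dict[str, int]
    replicates: Dict[str, np.ndarray]  # category -> length-K count vector
    K: int
    conservative: bool = False

    @property
    def pvalues(self) -> Dict[str, float]:
        out = {}
        for cat, obs in self.observed.items():
            reps = self.replicates[cat]
            lower = int((reps < obs).sum())
            if self.conservative:
                out[cat] = (lower + 1) / (self.K + 1)
            else:
                out[cat] = lower / self.K
        return out


@dataclass
class JaccardResult:
    statistic: float
    p_enrichment: float  # fraction of permutations with statistic >= observed
    p_depletion: float
    n_permutations: int


def shuffle_tes(
    layout: GenomeLayout,
    tes: Sequence[TEFragment],
    seed: int,
    max_rejects: int = 500,
    max_restarts: int = 50,
) -> List[TEFragment]:
    """Uniformly re-place TEs within chromosomes, avoiding gaps and overlap.

    Each fragment keeps chromosome, length, family, class, subpart and age;
    only position changes. Raises on a chromosome where non-overlapping
    placement fails after bounded restarts.
    """
    rng = np.random.default_rng(seed)
    by_chrom: Dict[str, List[TEFragment]] = {}
    for f in tes:
        by_chrom.setdefault(f.chrom, []).append(f)
    out: List[TEFragment] = []
    for chrom in sorted(by_chrom):
        frags = by_chrom[chrom]
        chrom_len = layout.chrom_sizes[chrom]
        forbidden = layout.gaps.intervals(chrom)
        lengths = [f.length for f in frags]
        try:
            placed = place_nonoverlapping(
                lengths, chrom_len, forbidden, rng,
                max_rejects=max_rejects, max_restarts=max_restarts,
            )
        except ValueError as exc:
            raise ValueError(f"shuffle infeasible on chromosome {chrom}: {exc}") from exc
        for f, (s, e) in zip(frags, placed):
            out.append(replace(f, start=s, end=e))
    return out


def feature_null(
    layout: GenomeLayout,
    transcripts: Sequence[TranscriptModel],
    tes: Sequence[TEFragment],
    K: int = 5000,
    seed: int = 0,
    min_overlap: int = 10,
    conservative: bool = False,
) -> NullDistribution:
    """Category-count null from K TE shuffles with transcripts held fixed."""
    _, obs_summary = classify_all(tes, transcripts, min_overlap)
    observed = category_counts(obs_summary)
    reps: Dict[str, List[int]] = {c: [] for c in observed}
    child_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=K)
    for k in range(K):
        shuffled = shuffle_tes(layout, tes, int(child_seeds[k]))
        _, summary = classify_all(shuffled, transcripts, min_overlap)
        counts = category_counts(summary)
        for c in reps:
            reps[c].append(counts.get(c, 0))
    return NullDistribution(
        observed=observed,
        replicates={c: np.array(v) for c, v in reps.items()},
        K=K,
        conservative=conservative,
    )


def jaccard(A: IntervalSet, B: IntervalSet) -> float:
    """|A intersect B| / |A union B| in distinct bases."""
    inter = A.intersection(B).covered_bp()
    union = A.covered_bp() + B.covered_bp() - inter
    return inter / union if union else 0.0


def jaccard_test(
    A_tes: Sequence[TEFragment],
    B: IntervalSet,
    layout: GenomeLayout,
    n_perm: int = 1000,
    seed: int = 0,
) -> JaccardResult:
    """Permutation test of spatial overlap: shuffle the TE set, re-measure."""
    A = te_interval_set(A_tes)
    obs = jaccard(A, B)
    child_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_perm)
    ge = le = 0
    for k in range(n_perm):
        shuffled = shuffle_tes(layout, A_tes, int(child_seeds[k]))
        stat = jaccard(te_interval_set(shuffled), B)
        if stat >= obs:
            ge += 1
        if stat <= obs:
            le += 1
    return JaccardResult(
        statistic=obs,
        p_enrichment=ge / n_perm,
        p_depletion=le / n_perm,
        n_permutations=n_perm,
    )


def score_permutation_test(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    n_perm: int = 1000,
    statistic: str = "mean_diff",
    seed: int = 0,
    alternative: str = "two-sided",
) -> Tuple[float, float]:
    """Label-permutation test for a difference in mean or variance.

    Returns (observed statistic, p). The p-value includes the observed
    labelling in the numerator and denominator, giving a valid test with
    resolution 1/(n_perm+1).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if statistic == "mean_diff":
        stat = lambda x, y: x.mean() - y.mean()
    elif statistic == "var_diff":
        stat = lambda x, y: x.var(ddof=1) - y.var(ddof=1)
    else:
        raise ValueError("statistic must be 'mean_diff' or 'var_diff'")
    obs = stat(a, b)
    pooled = np.concatenate([a, b])
    n_a = a.size
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        s = stat(perm[:n_a], perm[n_a:])
        if alternative == "two-sided":
            hits += abs(s) >= abs(obs)
        elif alternative == "greater":
            hits += s >= obs
        else:
            hits += s <= obs
    p = (hits + 1) / (n_perm + 1)
    return float(obs), float(p)


def neutral_intronic_te_set(
    tes: Sequence[TEFragment],
    transcripts: Sequence[TranscriptModel],
    chromatin_marks: IntervalSet,
    splice_pad: int = 10,
) -> IntervalSet:
    """Putatively neutral TE bases: intronic, away from splice sites and marks.

    Intronic TE bases of the supplied transcripts minus a ``splice_pad``-bp
    pad inside each splice boundary and minus all supplied chromatin-mark
    intervals; exonic bases of any transcript are excluded too.
    """
    introns = IntervalSet.from_records(
        (t.chrom, s, e) for t in transcripts for s, e in t.introns()
    )
    all_exons = IntervalSet.from_records(
        (t.chrom, s, e) for t in transcripts for s, e in t.exons
    )
    pads = []
    for t in transcripts:
        for s, e in t.introns():
            pads.append((t.chrom, s, min(s + splice_pad, e)))
            pads.append((t.chrom, max(e - splice_pad, s), e))
    pad_set = IntervalSet.from_records(pads) if pads else IntervalSet()
    te_set = te_interval_set(tes)
    neutral = introns.intersection(te_set).subtract(all_exons)
    neutral = neutral.subtract(pad_set).subtract(chromatin_marks)
    return neutral


def matched_random_regions(
    layout: GenomeLayout,
    template: IntervalSet,
    seed: int,
) -> IntervalSet:
    """Count- and length-matched random regions in ungapped sequence.

    Lengths are re-placed uniformly without mutual overlap across the whole
    genome: chromosomes are chosen with probability proportional to
    ungapped length, then placement follows the shuffle machinery.
    """
    rng = np.random.default_rng(seed)
    lengths = [e - s for _, s, e in template.records()]
    chroms = sorted(layout.chrom_sizes)
    weights = np.array(
        [
            layout.chrom_sizes[c] - layout.gaps.overlap_bp(c, 0, layout.chrom_sizes[c])
            for c in chroms
        ],
        dtype=float,
    )
    weights /= weights.sum()
    per_chrom: Dict[str, List[int]] = {c: [] for c in chroms}
    for length in lengths:
        c = chroms[int(rng.choice(len(chroms), p=weights))]
        per_chrom[c].append(length)
    recs = []
    for c in chroms:
        if not per_chrom[c]:
            continue
        placed = place_nonoverlapping(
            per_chrom[c], layout.chrom_sizes[c], layout.gaps.intervals(c), rng
        )
        recs.extend((c, s, e) for s, e in placed)
    return IntervalSet.from_records(recs) if recs else IntervalSet()
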