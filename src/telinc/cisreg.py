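"""TE-derived open-chromatin elements and cell-type-specific regulation.

A TE overlapping a DNaseI-hypersensitivity cluster by strictly more than
10 bp is a candidate cis-regulatory element (a "TE-DHS"). Accessibility of
a TE-DHS in a cell type is the summed per-base DNase tag count over the TE
span, normalised per million library reads. A lncRNA is called specific to
a cell type when its expression there is at least ``fold`` (default 10)
times the mean of its expression in the other cell types (with a small
pseudocount guarding zero means). For each lncRNA the single most active
TE-DHS within 10 kb upstream of its TSS is retained; coupling between
accessibility and expression is then the one-sided rank-sum comparison of
matched-cell vs other-cell signals over the specific lncRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .genome_io import ScoreTrack, TEFragment, TranscriptModel
from .intervals import IntervalSet


@dataclass
class DHSTE:
    te: TEFragment
    dhs_overlap_bp: int
    signal: Dict[str, float] = field(default_factory=dict)  # cell -> normalized tags


@dataclass
class CellTypeCall:
    lnc_id: str
    expression: Dict[str, float]
    specific_to: Optional[str]


def dhs_te_set(
    tes: Sequence[TEFragment],
    dhs_clusters: IntervalSet,
    min_overlap_exclusive: int = 10,
) -> List[DHSTE]:
    """TEs overlapping a DHS cluster by strictly more than the threshold."""
    clusters = dhs_clusters.union()
    out = []
    for f in tes:
        ov = clusters.overlap_bp(f.chrom, f.start, f.end)
        if ov > min_overlap_exclusive:
            out.append(DHSTE(te=f, dhs_overlap_bp=ov))
    return out


def normalized_signal(
    track: ScoreTrack,
    chrom: str,
    start: int,
    end: int,
    library_size: float,
) -> float:
    """Summed per-base tag count over [start, end), per million library reads."""
    region = IntervalSet({chrom: [(start, end)]})
    values = track.values_in(region)
    return float(values.sum()) / library_size * 1e6


def attach_signals(
    dhstes: Sequence[DHSTE],
    tracks: Dict[str, ScoreTrack],
    library_sizes: Dict[str, float],
) -> None:
    for d in dhstes:
        for cell, track in tracks.items():
            d.signal[cell] = normalized_signal(
                track, d.te.chrom, d.te.start, d.te.end, library_sizes[cell]
            )


def cell_specific_lnc(
    expr_table: Dict[str, Dict[str, float]],
    fold: float = 10.0,
    pseudocount: float = 0.1,
) -> List[CellTypeCall]:
    """Call at most one specific cell type per lncRNA by the fold rule.

    Specific to cell c iff expr(c) >= fold * (mean of other cells +
    pseudocount). The pseudocount (normalised expression units) prevents
    division-by-zero calls on all-but-silent genes.
    """
    calls = []
    for lnc_id in sorted(expr_table):
        expr = expr_table[lnc_id]
        cells = sorted(expr)
        specific = None
        for c in cells:
            others = [expr[o] for o in cells if o != c]
            if expr[c] >= fold * (float(np.mean(others)) + pseudocount):
                specific = c
                break
        calls.append(CellTypeCall(lnc_id=lnc_id, expression=dict(expr), specific_to=specific))
    return calls


def most_active_proximal_dhste(
    lnc: TranscriptModel,
    dhstes: Sequence[DHSTE],
    cell: str,
    max_dist: int = 10_000,
    symmetric: bool = False,
) -> Optional[DHSTE]:
    """Most active TE-DHS within max_dist upstream of the lncRNA TSS.

    Upstream is strand-aware; ``symmetric`` widens the window to both sides
    of the TSS. Ties break by proximity to the TSS, then by TE id.
    """
    tss = lnc.tss
    candidates: List[Tuple[float, int, str, DHSTE]] = []
    for d in dhstes:
        if d.te.chrom != lnc.chrom:
            continue
        if lnc.strand == "+":
            in_window = tss - max_dist <= d.te.end - 1 <= tss
        else:
            in_window = tss <= d.te.start <= tss + max_dist
        if symmetric:
            dist_edge = min(abs(d.te.start - tss), abs(d.te.end - 1 - tss))
            in_window = in_window or dist_edge <= max_dist
        if not in_window:
            continue
        dist = min(abs(d.te.start - tss), abs(d.te.end - 1 - tss))
        candidates.append((-d.signal.get(cell, 0.0), dist, d.te.id, d))
    if not candidates:
        return None
    candidates.sort(key=lambda x: x[:3])
    return candidates[0][3]


def coupling_test(
    lnc_models: Dict[str, TranscriptModel],
    calls: Sequence[CellTypeCall],
    dhstes: Sequence[DHSTE],
    cells: Sequence[str],
    max_dist: int = 10_000,
) -> Tuple[float, int]:
    """Rank-sum test: matched-cell vs other-cell signal of most-active TE-DHS.

    For every cell-type-specific lncRNA, take the most active proximal
    TE-DHS in each cell; compare the distribution of signals in the
    matched cell against the pooled signals in the other cells
    (one-sided, matched > others). Returns (p, n_specific_lnc_used).
    """
    matched: List[float] = []
    others: List[float] = []
    n_used = 0
    for call in calls:
        if call.specific_to is None or call.lnc_id not in lnc_models:
            continue
        lnc = lnc_models[call.lnc_id]
        used = False
        for cell in cells:
            d = most_active_proximal_dhste(lnc, dhstes, cell, max_dist)
            if d is None:
                continue
            used = True
            if cell == call.specific_to:
                matched.append(d.signal.get(cell, 0.0))
            else:
                others.append(d.signal.get(cell, 0.0))
        if used:
            n_used += 1
    if not matched or not others:
        return float("nan"), n_used
    stat = stats.mannwhitneyu(matched, others, alternative="greater")
    return float(stat.pvalue), n_used
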