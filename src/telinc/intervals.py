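"""Strand-aware interval algebra on half-open genomic intervals.

All coordinates are 0-based half-open ``[start, end)``. Interval sets are
kept per chromosome as lists sorted by start; normalization (merging of
overlapping or book-ended intervals) is always explicit via
:meth:`IntervalSet.union`, never implicit, so record multiplicity survives
round trips.

Transposable elements are treated as strandless throughout: strand enters
only through transcript orientation (first/last exon, TSS/polyA, flanks).
"""

from __future__ import annotations

from bisect import bisect_left, insort
from typing import Dict, Iterable, Iterator, List, Tuple

Interval = Tuple[int, int]


class IntervalSet:
    """A multiset of half-open intervals grouped by chromosome."""

    def __init__(self, data: Dict[str, List[Interval]] | None = None):
        self._data: Dict[str, List[Interval]] = {}
        if data:
            for chrom, ivs in data.items():
                self._data[chrom] = sorted((int(s), int(e)) for s, e in ivs)

    @classmethod
    def from_records(cls, records: Iterable[Tuple[str, int, int]]) -> "IntervalSet":
        data: Dict[str, List[Interval]] = {}
        for chrom, start, end in records:
            if start >= end:
                raise ValueError(f"empty or inverted interval {chrom}:{start}-{end}")
            data.setdefault(chrom, []).append((int(start), int(end)))
        return cls(data)

    def records(self) -> Iterator[Tuple[str, int, int]]:
        for chrom in sorted(self._data):
            for s, e in self._data[chrom]:
                yield chrom, s, e

    def chroms(self) -> List[str]:
        return sorted(self._data)

    def intervals(self, chrom: str) -> List[Interval]:
        return list(self._data.get(chrom, []))

    def __len__(self) -> int:
        return sum(len(v) for v in self._data.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._data == other._data

    def __repr__(self) -> str:
        n = len(self)
        return f"IntervalSet({n} intervals on {len(self._data)} chroms)"

    # -- algebra ---------------------------------------------------------

    def union(self) -> "IntervalSet":
        """Genomic projection: merge overlapping and book-ended intervals."""
        out: Dict[str, List[Interval]] = {}
        for chrom, ivs in self._data.items():
            merged: List[Interval] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    if e > merged[-1][1]:
                        merged[-1] = (merged[-1][0], e)
                else:
                    merged.append((s, e))
            out[chrom] = merged
        res = IntervalSet()
        res._data = out
        return res

    def covered_bp(self) -> int:
        """Number of distinct bases covered (projection length)."""
        return sum(e - s for _, s, e in self.union().records())

    def total_bp(self) -> int:
        """Multiset base count (overlaps counted once per record)."""
        return sum(e - s for _, s, e in self.records())

    def intersect_pairs(
        self, other: "IntervalSet", min_overlap: int = 1
    ) -> List[Tuple[Tuple[str, int, int], Tuple[str, int, int], int]]:
        """Exhaustive pairs (a, b, overlap_bp) with overlap >= min_overlap.

        Sorted sweep per chromosome; record multiplicity is preserved on
        both sides.
        """
        if min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        pairs = []
        for chrom in self._data:
            a_ivs = self._data[chrom]
            b_ivs = other._data.get(chrom)
            if not b_ivs:
                continue
            b_starts = [s for s, _ in b_ivs]
            b_maxend = _running_max([e for _, e in b_ivs])
            for a_s, a_e in a_ivs:
                # first b whose running max end could still reach a_s
                i = _first_reaching(b_maxend, a_s + min_overlap)
                for j in range(i, len(b_ivs)):
                    b_s, b_e = b_ivs[j]
                    if b_s > a_e - min_overlap:
                        break
                    ov = min(a_e, b_e) - max(a_s, b_s)
                    if ov >= min_overlap:
                        pairs.append(((chrom, a_s, a_e), (chrom, b_s, b_e), ov))
        return pairs

    def intersection(self, other: "IntervalSet") -> "IntervalSet":
        """Projection of bases present in both sets (normalized output)."""
        a = self.union()
        b = other.union()
        out: Dict[str, List[Interval]] = {}
        for chrom in a._data:
            if chrom not in b._data:
                continue
            res: List[Interval] = []
            ai, bi = a._data[chrom], b._data[chrom]
            i = j = 0
            while i < len(ai) and j < len(bi):
                s = max(ai[i][0], bi[j][0])
                e = min(ai[i][1], bi[j][1])
                if s < e:
                    res.append((s, e))
                if ai[i][1] < bi[j][1]:
                    i += 1
                else:
                    j += 1
            if res:
                out[chrom] = res
        r = IntervalSet()
        r._data = out
        return r

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Remove every base of ``other`` from this set (normalized output)."""
        a = self.union()
        b = other.union()
        out: Dict[str, List[Interval]] = {}
        for chrom, ivs in a._data.items():
            cuts = b._data.get(chrom, [])
            res: List[Interval] = []
            for s, e in ivs:
                cur = s
                i = bisect_left(cuts, (cur,)) - 1
                i = max(i, 0)
                for c_s, c_e in cuts[i:]:
                    if c_e <= cur:
                        continue
                    if c_s >= e:
                        break
                    if c_s > cur:
                        res.append((cur, c_s))
                    cur = max(cur, c_e)
                    if cur >= e:
                        break
                if cur < e:
                    res.append((cur, e))
            if res:
                out[chrom] = res
        r = IntervalSet()
        r._data = out
        return r

    def overlap_bp(self, chrom: str, start: int, end: int) -> int:
        """Distinct bases of this set falling inside [start, end)."""
        probe = IntervalSet({chrom: [(start, end)]})
        return self.intersection(probe).covered_bp()

    def contains_point(self, chrom: str, pos: int) -> bool:
        ivs = self._data.get(chrom)
        if not ivs:
            return False
        i = bisect_left(ivs, (pos + 1,)) - 1
        while i >= 0:
            s, e = ivs[i]
            if s <= pos < e:
                return True
            # earlier records may still span pos (set not normalized)
            if e <= pos and i == 0:
                break
            i -= 1
        return False


def _running_max(values: List[int]) -> List[int]:
    out, m = [], 0
    for v in values:
        m = max(m, v)
        out.append(m)
    return out


def _first_reaching(running_max: List[int], threshold: int) -> int:
    """Smallest index i with running_max[i] >= threshold (len if none)."""
    lo, hi = 0, len(running_max)
    while lo < hi:
        mid = (lo + hi) // 2
        if running_max[mid] >= threshold:
            hi = mid
        else:
            lo = mid + 1
    return lo


def flank(
    chrom: str,
    gene_start: int,
    gene_end: int,
    strand: str,
    side: str,
    max_len: int,
    blockers: IntervalSet,
    chrom_len: int,
) -> Tuple[str, int, int]:
    """Longest clear run between a transcript end and the next feature.

    ``side`` is 'up' (off the TSS) or 'down' (off the polyA); strand decides
    which genomic direction that is. The run is truncated at the first
    blocker base, at ``max_len``, or at the chromosome edge, whichever comes
    first. A zero-length result (blocker adjacent) is legal.
    """
    if side not in ("up", "down"):
        raise ValueError("side must be 'up' or 'down'")
    if strand not in ("+", "-"):
        raise ValueError("strand must be '+' or '-'")
    leftward = (side == "up") == (strand == "+")
    if leftward:
        end = gene_start
        start = max(0, end - max_len)
        for b_s, b_e in blockers.union().intervals(chrom):
            if b_s >= end:
                break
            if b_e > start:
                start = min(b_e, end)
        return (chrom, start, end)
    start = gene_end
    end = min(chrom_len, start + max_len)
    for b_s, b_e in blockers.union().intervals(chrom):
        if b_e <= start:
            continue
        if b_s < end:
            end = max(b_s, start)
            break
    return (chrom, start, end)


def transcript_flank(transcript, side, max_len, blockers, chrom_len):
    """Flank of a transcript model (see :func:`flank`); excludes its own exons."""
    own = IntervalSet({transcript.chrom: list(transcript.exons)})
    merged = IntervalSet.from_records(
        list(blockers.records()) + list(own.records())
    )
    return flank(
        transcript.chrom,
        transcript.start,
        transcript.end,
        transcript.strand,
        side,
        max_len,
        merged,
        chrom_len,
    )


def place_nonoverlapping(
    lengths: List[int],
    chrom_len: int,
    forbidden: List[Interval],
    rng,
    max_rejects: int = 200,
    max_restarts: int = 20,
) -> List[Interval]:
    """Uniform non-overlapping placement by rejection sampling.

    Each length gets a start drawn uniformly from [0, chrom_len - length];
    draws hitting ``forbidden`` intervals or previously placed intervals are
    rejected. After ``max_rejects`` consecutive rejections the chromosome is
    restarted from scratch; after ``max_restarts`` restarts a ValueError is
    raised (infeasible chromosome).
    """
    base = sorted(forbidden)
    for _ in range(max_restarts):
        occupied: List[Interval] = list(base)
        placed: List[Interval] = []
        ok = True
        for length in lengths:
            if length > chrom_len:
                raise ValueError(f"length {length} exceeds chromosome ({chrom_len} bp)")
            hi = chrom_len - length
            rejects = 0
            while True:
                s = int(rng.integers(0, hi + 1))
                if not _hits(occupied, s, s + length):
                    insort(occupied, (s, s + length))
                    placed.append((s, s + length))
                    break
                rejects += 1
                if rejects > max_rejects:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return placed
    raise ValueError(
        f"cannot place {len(lengths)} intervals on a {chrom_len}-bp chromosome "
        "without overlap (infeasible or too dense)"
    )


def _hits(sorted_ivs: List[Interval], start: int, end: int) -> bool:
    i = bisect_left(sorted_ivs, (start,))
    if i < len(sorted_ivs) and sorted_ivs[i][0] < end:
        return True
    return i > 0 and sorted_ivs[i - 1][1] > start
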