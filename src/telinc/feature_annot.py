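"""Classification of TE-exon overlaps into gene-feature categories.

Every TE fragment overlapping an exon by at least 10 bp receives exactly
one category per exon it hits, reflecting which biogenesis signals of the
transcript the TE could supply:

====================  =====================================================
TSS                   covers the transcription start base of a first exon
TSS_SPL               covers an entire first exon (TSS plus donor site)
SPL                   covers one splice-boundary base of an exon
BOTH_SPL              covers an entire internal exon (both splice sites)
POLYA                 covers the polyadenylation base of a last exon
POLYA_SPL             covers an entire last exon (acceptor plus polyA)
EXONIZED              interior overlap only, no boundary base covered
FULL_SINGLE           covers an entire single-exon transcript
====================  =====================================================

Full-exon categories take precedence over single-boundary ones, which take
precedence over EXONIZED. Since a TE fragment is one contiguous interval,
it can cover both terminal bases of an exon only by covering the whole
exon, so the assignment is unambiguous. First/last exons are resolved by
strand, never by coordinate; TEs themselves are strandless.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .genome_io import TEFragment, TranscriptModel

CATEGORIES = (
    "TSS",
    "TSS_SPL",
    "SPL",
    "BOTH_SPL",
    "POLYA",
    "POLYA_SPL",
    "EXONIZED",
    "FULL_SINGLE",
)


@dataclass(frozen=True)
class FeatureCall:
    te_id: str
    transcript_id: str
    exon_ordinal: int  # 1 = 5'-most exon by strand
    overlap_bp: int
    category: str
    exon_role: str  # first / internal / last / single


@dataclass(frozen=True)
class SiteRecord:
    kind: str  # TSS / polyA / splice
    chrom: str
    pos: int  # the terminal exonic base itself
    strand: str
    te_derived: bool
    te_family: Optional[str] = None
    te_class: Optional[str] = None
    transcript_ids: Tuple[str, ...] = ()


@dataclass
class ClassificationSummary:
    category_exons: Dict[str, int]  # exons with >= 1 call in category
    unhit_exons: int
    total_exons: int
    n_calls: int


def _exon_role(t: TranscriptModel, idx: int) -> str:
    if t.n_exons == 1:
        return "single"
    ordinal = t.exon_ordinal(idx)
    if ordinal == 1:
        return "first"
    if ordinal == t.n_exons:
        return "last"
    return "internal"


def classify_te_exon(
    te: TEFragment,
    t: TranscriptModel,
    exon_idx: int,
    min_overlap: int = 10,
) -> Optional[FeatureCall]:
    """Classify one TE against one exon (coordinate index ``exon_idx``)."""
    s, e = t.exons[exon_idx]
    ov = min(e, te.end) - max(s, te.start)
    if te.chrom != t.chrom or ov < min_overlap:
        return None
    role = _exon_role(t, exon_idx)
    full = te.start <= s and te.end >= e
    covers_left = te.start <= s < te.end  # exon's leftmost base
    covers_right = te.start <= e - 1 < te.end  # exon's rightmost base

    if full:
        category = {
            "single": "FULL_SINGLE",
            "first": "TSS_SPL",
            "internal": "BOTH_SPL",
            "last": "POLYA_SPL",
        }[role]
    else:
        # Which boundary base carries which signal depends on strand.
        five_prime_is_left = t.strand == "+"
        covers_5p = covers_left if five_prime_is_left else covers_right
        covers_3p = covers_right if five_prime_is_left else covers_left
        if role == "single":
            category = "TSS" if covers_5p else "POLYA" if covers_3p else "EXONIZED"
        elif role == "first":
            category = "TSS" if covers_5p else "SPL" if covers_3p else "EXONIZED"
        elif role == "last":
            category = "POLYA" if covers_3p else "SPL" if covers_5p else "EXONIZED"
        else:
            category = "SPL" if (covers_left or covers_right) else "EXONIZED"
    return FeatureCall(
        te_id=te.id,
        transcript_id=t.transcript_id,
        exon_ordinal=t.exon_ordinal(exon_idx),
        overlap_bp=ov,
        category=category,
        exon_role=role,
    )


def classify_all(
    tes: Sequence[TEFragment],
    transcripts: Sequence[TranscriptModel],
    min_overlap: int = 10,
) -> Tuple[List[FeatureCall], ClassificationSummary]:
    """All TE-exon calls plus per-category exon counts.

    A TE hitting several exons yields one call per exon; an exon hit by
    several TEs can belong to several categories but is counted once per
    category. Unhit exons have no overlap of at least ``min_overlap``.
    """
    from bisect import bisect_left

    by_chrom: Dict[str, List[Tuple[int, int, TEFragment]]] = {}
    for f in tes:
        by_chrom.setdefault(f.chrom, []).append((f.start, f.end, f))
    for lst in by_chrom.values():
        lst.sort(key=lambda x: (x[0], x[1]))
    max_len: Dict[str, int] = {
        c: max((e - s for s, e, _ in lst), default=0) for c, lst in by_chrom.items()
    }

    calls: List[FeatureCall] = []
    cat_exons: Dict[str, Set[Tuple[str, int]]] = {c: set() for c in CATEGORIES}
    total_exons = 0
    hit_exons: Set[Tuple[str, int]] = set()
    for t in transcripts:
        lst = by_chrom.get(t.chrom, [])
        starts = [x[0] for x in lst]
        for idx, (s, e) in enumerate(t.exons):
            total_exons += 1
            lo = bisect_left(starts, s - max_len.get(t.chrom, 0) - 1)
            for j in range(lo, len(lst)):
                f_s, f_e, frag = lst[j]
                if f_s > e - min_overlap:
                    break
                call = classify_te_exon(frag, t, idx, min_overlap)
                if call is not None:
                    calls.append(call)
                    key = (t.transcript_id, call.exon_ordinal)
                    cat_exons[call.category].add(key)
                    hit_exons.add(key)
    summary = ClassificationSummary(
        category_exons={c: len(v) for c, v in cat_exons.items()},
        unhit_exons=total_exons - len(hit_exons),
        total_exons=total_exons,
        n_calls=len(calls),
    )
    return calls, summary


def category_counts(summary: ClassificationSummary) -> Dict[str, int]:
    counts = dict(summary.category_exons)
    counts["unhit"] = summary.unhit_exons
    return counts


def site_inventory(
    transcripts: Sequence[TranscriptModel],
    tes: Sequence[TEFragment],
    min_overlap: int = 10,
) -> List[SiteRecord]:
    """Non-redundant TSS/polyA/splice sites with TE-derived attribution.

    A site is TE-derived iff some TE passes the 10-bp overlap filter with
    the exon owning the site AND covers the site's base; grazing contacts
    covering the base with <10 bp exon overlap do not count.
    """
    sites: Dict[Tuple[str, str, int, str], dict] = {}

    def _register(kind: str, t: TranscriptModel, pos: int, exon: Tuple[int, int]):
        key = (kind, t.chrom, pos, t.strand)
        rec = sites.setdefault(
            key, {"te": None, "tx": []}
        )
        rec["tx"].append(t.transcript_id)
        if rec["te"] is None:
            s, e = exon
            for f in tes:
                if f.chrom != t.chrom:
                    continue
                ov = min(e, f.end) - max(s, f.start)
                if ov >= min_overlap and f.start <= pos < f.end:
                    rec["te"] = f
                    break

    for t in transcripts:
        first_idx = 0 if t.strand == "+" else t.n_exons - 1
        last_idx = t.n_exons - 1 if t.strand == "+" else 0
        for idx, (s, e) in enumerate(t.exons):
            left, right = s, e - 1
            if idx == first_idx and t.strand == "+":
                _register("TSS", t, left, (s, e))
            elif idx == first_idx:
                _register("TSS", t, right, (s, e))
            else:
                _register("splice", t, left if t.strand == "+" else right, (s, e))
            if idx == last_idx and t.strand == "+":
                _register("polyA", t, right, (s, e))
            elif idx == last_idx:
                _register("polyA", t, left, (s, e))
            else:
                _register("splice", t, right if t.strand == "+" else left, (s, e))

    out = []
    for (kind, chrom, pos, strand), rec in sorted(sites.items()):
        f = rec["te"]
        out.append(
            SiteRecord(
                kind=kind,
                chrom=chrom,
                pos=pos,
                strand=strand,
                te_derived=f is not None,
                te_family=f.family if f else None,
                te_class=f.class_label if f else None,
                transcript_ids=tuple(sorted(set(rec["tx"]))),
            )
        )
    return out


def te_derived_site_fractions(inventory: Sequence[SiteRecord]) -> Dict[str, float]:
    """Fraction of non-redundant sites of each kind that are TE-derived."""
    out = {}
    for kind in ("TSS", "polyA", "splice"):
        recs = [r for r in inventory if r.kind == kind]
        out[kind] = (
            sum(r.te_derived for r in recs) / len(recs) if recs else float("nan")
        )
    return out


def fully_te_first_exons(
    transcripts: Sequence[TranscriptModel],
    tes: Sequence[TEFragment],
    min_overlap: int = 10,
) -> List[str]:
    """Transcripts whose entire first exon lies under (a union of) TEs."""
    from .intervals import IntervalSet

    out = []
    for t in transcripts:
        idx = 0 if t.strand == "+" else t.n_exons - 1
        s, e = t.exons[idx]
        qual = [
            (f.chrom, max(s, f.start), min(e, f.end))
            for f in tes
            if f.chrom == t.chrom and min(e, f.end) - max(s, f.start) >= min_overlap
        ]
        if qual and IntervalSet.from_records(qual).covered_bp() == e - s:
            out.append(t.transcript_id)
    return out
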