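"""TE content of transcripts and TE coverage of genomic compartments.

Per-transcript TE content is the fraction of the genomic projection of a
transcript's exons covered by transposable-element fragments, counting only
fragment-exon overlaps of at least ``min_overlap`` (default 10) bp. A TE
overlapping two exons is counted once via the projection. Compartment
coverage expresses, for each genomic compartment (whole ungapped genome,
exons per biotype, introns, 1/10-kb flanks, UTRs, CDS), the fraction of
bases derived from each TE class, with the ERV split into LTR (long
terminal repeat) and internal portions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

from .genome_io import GenomeLayout, TEFragment, TranscriptModel, te_interval_set
from .intervals import IntervalSet, transcript_flank

CLASS_LABELS = ("LTR/LTR", "LTR/int", "LINE", "SINE", "DNA")


@dataclass
class TranscriptTEContent:
    transcript_id: str
    exonic_bp: int
    te_bp: int
    fragments: List[Tuple[str, str, str, int]]  # (te id, family, class label, overlap bp)

    @property
    def percent_te(self) -> float:
        return 100.0 * self.te_bp / self.exonic_bp if self.exonic_bp else 0.0

    @property
    def has_te(self) -> bool:
        return bool(self.fragments)


@dataclass
class CompartmentCoverage:
    compartment: str
    denominator_bp: int
    class_bp: Dict[str, int] = field(default_factory=dict)
    class_fragments: Dict[str, int] = field(default_factory=dict)

    @property
    def te_bp(self) -> int:
        return sum(self.class_bp.values())

    @property
    def percent_te(self) -> float:
        return 100.0 * self.te_bp / self.denominator_bp if self.denominator_bp else 0.0

    def percent_class(self, label: str) -> float:
        if not self.denominator_bp:
            return 0.0
        return 100.0 * self.class_bp.get(label, 0) / self.denominator_bp


def transcript_te_content(
    t: TranscriptModel,
    tes: Sequence[TEFragment],
    min_overlap: int = 10,
) -> TranscriptTEContent:
    """TE-derived share of a transcript's exonic (genomic-projection) bases."""
    exon_set = IntervalSet({t.chrom: list(t.exons)})
    frags: List[Tuple[str, str, str, int]] = []
    qual_records = []  # exon-clipped pieces of qualifying fragment-exon pairs
    for f in tes:
        if f.chrom != t.chrom or f.end <= t.start or f.start >= t.end:
            continue
        total_ov = 0
        for s, e in t.exons:
            ov = min(e, f.end) - max(s, f.start)
            if ov >= min_overlap:  # the 10-bp rule applies per fragment-exon pair
                total_ov += ov
                qual_records.append((f.chrom, max(s, f.start), min(e, f.end)))
        if total_ov:
            frags.append((f.id, f.family, f.class_label, total_ov))
    te_bp = (
        IntervalSet.from_records(qual_records).covered_bp() if qual_records else 0
    )
    return TranscriptTEContent(
        transcript_id=t.transcript_id,
        exonic_bp=exon_set.covered_bp(),
        te_bp=te_bp,
        fragments=frags,
    )


def content_histogram(
    contents: Iterable[TranscriptTEContent],
    thresholds: Sequence[float] = (50.0, 80.0),
) -> Dict[float, int]:
    """Cumulative "> x% TE-derived" transcript counts for each threshold."""
    pcts = [c.percent_te for c in contents]
    return {x: sum(p > x for p in pcts) for x in thresholds}


def split_genic_intergenic(
    transcripts: Sequence[TranscriptModel],
) -> Tuple[List[TranscriptModel], List[TranscriptModel]]:
    """Partition lncRNAs into intergenic vs genic by protein-coding span overlap."""
    pc_spans = IntervalSet.from_records(
        (t.chrom, t.start, t.end)
        for t in transcripts
        if t.biotype == "protein_coding"
    ).union()
    intergenic, genic = [], []
    for t in transcripts:
        if not t.biotype.startswith("lncRNA"):
            continue
        if pc_spans.overlap_bp(t.chrom, t.start, t.end) > 0:
            genic.append(t)
        else:
            intergenic.append(t)
    return intergenic, genic


def build_compartments(
    layout: GenomeLayout,
    transcripts: Sequence[TranscriptModel],
    flank_lengths: Tuple[int, int] = (1_000, 10_000),
    nested_flanks: bool = True,
) -> Dict[str, IntervalSet]:
    """Standard compartment map keyed by label.

    Exon projections are built per biotype group; introns and flanks have
    every annotated exon (of any set) subtracted; UTR/CDS compartments come
    from protein-coding transcripts carrying both UTRs. With
    ``nested_flanks`` the 1-kb flank is a subset of the 10-kb one;
    otherwise the long flank is the disjoint annulus.
    """
    all_exons = IntervalSet.from_records(
        (t.chrom, s, e) for t in transcripts for s, e in t.exons
    )
    lnc = [t for t in transcripts if t.biotype.startswith("lncRNA")]
    pc = [t for t in transcripts if t.biotype == "protein_coding" and t.has_both_utrs]

    comp: Dict[str, IntervalSet] = {}
    comp["genome"] = layout.ungapped()
    comp["exon"] = IntervalSet.from_records(
        (t.chrom, s, e) for t in lnc for s, e in t.exons
    ).union()
    comp["exon_pc"] = IntervalSet.from_records(
        (t.chrom, s, e) for t in pc for s, e in t.exons
    ).union()

    introns = IntervalSet.from_records(
        (t.chrom, s, e) for t in lnc for s, e in t.introns()
    )
    comp["intron"] = introns.subtract(all_exons)

    for side, prefix in (("up", "up"), ("down", "dw")):
        short, long_ = flank_lengths
        for label, max_len in ((f"{prefix}1k", short), (f"{prefix}10k", long_)):
            recs = []
            for t in lnc:
                chrom_len = layout.chrom_sizes[t.chrom]
                c, s, e = transcript_flank(t, side, max_len, all_exons, chrom_len)
                if e > s:
                    recs.append((c, s, e))
            comp[label] = IntervalSet.from_records(recs).union() if recs else IntervalSet()
        if not nested_flanks:
            comp[f"{prefix}10k"] = comp[f"{prefix}10k"].subtract(comp[f"{prefix}1k"])

    comp["utr5"] = IntervalSet.from_records(
        (t.chrom, s, e) for t in pc for s, e in t.utr5
    ).union()
    comp["utr3"] = IntervalSet.from_records(
        (t.chrom, s, e) for t in pc for s, e in t.utr3
    ).union()
    comp["cds"] = IntervalSet.from_records(
        (t.chrom, s, e) for t in pc for s, e in t.cds
    ).union()
    return comp


def compartment_coverage(
    layout: GenomeLayout,
    tes: Sequence[TEFragment],
    compartments: Dict[str, IntervalSet],
    min_overlap: int = 10,
) -> List[CompartmentCoverage]:
    """Per-compartment TE coverage split by class label.

    The genome compartment denominator excludes assembly gaps. Fragment
    counts use the >= min_overlap rule; base counts use the projection of
    qualifying fragments (classes partition TEs, so per-class bp sums to
    all-TE bp).
    """
    by_label: Dict[str, List[TEFragment]] = {lab: [] for lab in CLASS_LABELS}
    for f in tes:
        by_label.setdefault(f.class_label, []).append(f)

    out = []
    for name, region in compartments.items():
        region = region.union()
        denom = region.covered_bp()
        cov = CompartmentCoverage(compartment=name, denominator_bp=denom)
        for label, frags in by_label.items():
            if not frags:
                cov.class_bp[label] = 0
                cov.class_fragments[label] = 0
                continue
            fs = te_interval_set(frags)
            pairs = region.intersect_pairs(fs, min_overlap=min_overlap)
            qualifying = {b for _, b, _ in pairs}
            bp = 0
            if qualifying:
                qual = IntervalSet.from_records(qualifying)
                bp = region.intersection(qual).covered_bp()
            cov.class_bp[label] = bp
            # distinct fragments with a qualifying overlap
            frag_ids = set()
            for f in frags:
                key = (f.chrom, f.start, f.end)
                if key in qualifying:
                    frag_ids.add(f.id)
            cov.class_fragments[label] = len(frag_ids)
        out.append(cov)
    return out
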