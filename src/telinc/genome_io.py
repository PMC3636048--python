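"""Readers/writers for RepeatMasker `.out`, GTF, BED, bedGraph and chrom.sizes.

Filtering and fragment-merge conventions are applied at parse time:
RepeatMasker rows of non-TE repeat classes (low complexity, satellites,
simple repeats, structural ncRNA) are dropped, and consecutive pieces of
the same repeat family on one chromosome separated by fewer than
``min_merge_gap`` bases are merged into a single fragment, compensating for
the artificial fragmentation of old copies in RepeatMasker output.

Internal coordinates are 0-based half-open everywhere; RepeatMasker input
(1-based inclusive) and GTF (1-based inclusive) are converted on read.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .intervals import Interval, IntervalSet

log = logging.getLogger(__name__)

TE_CLASSES = ("LTR", "LINE", "SINE", "DNA")

#: RepeatMasker repeat classes discarded as non-TE.
NON_TE_CLASSES = frozenset(
    {
        "Low_complexity",
        "Satellite",
        "Simple_repeat",
        "rRNA",
        "scRNA",
        "snRNA",
        "srpRNA",
        "tRNA",
        "RNA",
        "ncRNA",
    }
)

#: RepeatMasker class/family prefix -> internal four-class vocabulary.
CLASS_MAP = {
    "LTR": "LTR",
    "LINE": "LINE",
    "SINE": "SINE",
    "DNA": "DNA",
    "RC": "DNA",  # rolling-circle (Helitron) transposons grouped with DNA
    "Retroposon": "SINE",  # SVA-like composite retroposons
}


@dataclass(frozen=True)
class TEFragment:
    """One repeat-annotated interval; strandless for all overlap purposes."""

    id: str
    chrom: str
    start: int
    end: int
    family: str
    te_class: str
    subpart: str = "NA"  # LTR / internal / NA (LTR-class elements only)
    age_label: str = "NA"  # lineage_specific / ancient / NA
    divergence: Optional[float] = None

    def __post_init__(self):
        if self.te_class not in TE_CLASSES:
            raise ValueError(f"unknown TE class {self.te_class!r}")
        if self.end - self.start < 1:
            raise ValueError(f"empty fragment {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def class_label(self) -> str:
        """Coverage class with the ERV LTR/internal split (LTR/LTR, LTR/int)."""
        if self.te_class == "LTR":
            return "LTR/int" if self.subpart == "internal" else "LTR/LTR"
        return self.te_class


@dataclass(frozen=True)
class TranscriptModel:
    """Stranded multi-exon gene model with biotype and optional CDS/UTRs."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Interval, ...]  # sorted by coordinate, pairwise disjoint
    biotype: str
    cds: Tuple[Interval, ...] = ()
    utr5: Tuple[Interval, ...] = ()
    utr3: Tuple[Interval, ...] = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.transcript_id}")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in {self.transcript_id}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exonic_bp(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def tss(self) -> int:
        """5'-most transcribed base (genomic position of the base itself)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def polya(self) -> int:
        """3'-most transcribed base."""
        return self.end - 1 if self.strand == "+" else self.start

    def exon_ordinal(self, idx: int) -> int:
        """1-based ordinal of coordinate-index ``idx`` (1 = 5'-most exon)."""
        return idx + 1 if self.strand == "+" else self.n_exons - idx

    def introns(self) -> List[Interval]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1
        ]

    @property
    def has_both_utrs(self) -> bool:
        return bool(self.utr5) and bool(self.utr3)


@dataclass
class GenomeLayout:
    """Chromosome lengths plus normalized assembly-gap intervals."""

    chrom_sizes: Dict[str, int]
    gaps: IntervalSet = field(default_factory=IntervalSet)

    def __post_init__(self):
        self.gaps = self.gaps.union()
        for chrom, s, e in self.gaps.records():
            if chrom not in self.chrom_sizes:
                raise ValueError(f"gap on unknown chromosome {chrom}")
            if s < 0 or e > self.chrom_sizes[chrom]:
                raise ValueError(f"gap {chrom}:{s}-{e} outside chromosome")

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_sizes.values())

    @property
    def ungapped_bp(self) -> int:
        return self.total_bp - self.gaps.covered_bp()

    def ungapped(self) -> IntervalSet:
        whole = IntervalSet({c: [(0, n)] for c, n in self.chrom_sizes.items()})
        return whole.subtract(self.gaps)


class ScoreTrack:
    """Per-base score lookup over the covered intervals of a bedGraph."""

    def __init__(self, records: Iterable[Tuple[str, int, int, float]]):
        by_chrom: Dict[str, List[Tuple[int, int, float]]] = {}
        for chrom, s, e, v in records:
            if s >= e:
                raise ValueError(f"empty bedGraph record {chrom}:{s}-{e}")
            by_chrom.setdefault(chrom, []).append((s, e, float(v)))
        self._starts: Dict[str, np.ndarray] = {}
        self._ends: Dict[str, np.ndarray] = {}
        self._values: Dict[str, np.ndarray] = {}
        for chrom, recs in by_chrom.items():
            recs.sort()
            for (s1, e1, _), (s2, _, _) in zip(recs, recs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping bedGraph records on {chrom}")
            self._starts[chrom] = np.array([r[0] for r in recs])
            self._ends[chrom] = np.array([r[1] for r in recs])
            self._values[chrom] = np.array([r[2] for r in recs])

    def covered_bp(self) -> int:
        return int(
            sum((e - s).sum() for s, e in zip(self._starts.values(), self._ends.values()))
        )

    def values_in(self, regions: IntervalSet) -> np.ndarray:
        """Per-base scores over covered bases of ``regions`` (uncovered skipped)."""
        chunks = []
        for chrom, q_s, q_e in regions.union().records():
            if chrom not in self._starts:
                continue
            starts, ends, vals = self._starts[chrom], self._ends[chrom], self._values[chrom]
            lo = int(np.searchsorted(ends, q_s, side="right"))
            hi = int(np.searchsorted(starts, q_e, side="left"))
            for i in range(lo, hi):
                ov = min(q_e, ends[i]) - max(q_s, starts[i])
                if ov > 0:
                    chunks.append(np.full(int(ov), vals[i]))
        if not chunks:
            return np.array([], dtype=float)
        return np.concatenate(chunks)

    def mean_in(self, regions: IntervalSet) -> float:
        v = self.values_in(regions)
        return float(v.mean()) if v.size else float("nan")


# ---------------------------------------------------------------------------
# RepeatMasker


def parse_repeatmasker(
    path,
    min_merge_gap: int = 10,
    family_blacklist: Sequence[str] = (),
) -> List[TEFragment]:
    """Parse a RepeatMasker ``.out`` file into merged, filtered fragments.

    Non-TE repeat classes are dropped, as is any family in
    ``family_blacklist`` (species-specific; e.g. MutSatRep1 for mouse).
    Consecutive same-family fragments on one chromosome separated by fewer
    than ``min_merge_gap`` bp are merged (gap of min_merge_gap-1 merges,
    gap of min_merge_gap does not).
    """
    if min_merge_gap < 0:
        raise ValueError("min_merge_gap must be >= 0")
    blacklist = set(family_blacklist)
    raw: List[TEFragment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            # header lines start with "SW"/"score" or are non-numeric
            if not fields[0].replace(".", "").isdigit():
                continue
            try:
                chrom = fields[4]
                begin = int(fields[5])
                end = int(fields[6])
                family = fields[9]
                rm_class = fields[10]
                divergence = float(fields[1])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed RepeatMasker row at line {lineno}") from exc
            base_class = rm_class.split("/")[0].rstrip("?")
            if base_class in NON_TE_CLASSES or family in blacklist:
                continue
            te_class = CLASS_MAP.get(base_class)
            if te_class is None:
                log.warning(
                    "%s line %d: unmappable repeat class %r, fragment dropped",
                    path, lineno, rm_class,
                )
                continue
            subpart = "NA"
            if te_class == "LTR":
                subpart = "internal" if family.endswith(("-int", "_I", "-I")) else "LTR"
            raw.append(
                TEFragment(
                    id=f"te{lineno}",
                    chrom=chrom,
                    start=begin - 1,  # 1-based inclusive -> half-open
                    end=end,
                    family=family,
                    te_class=te_class,
                    subpart=subpart,
                    divergence=divergence,
                )
            )
    return merge_fragments(raw, min_merge_gap)


def merge_fragments(fragments: Sequence[TEFragment], min_merge_gap: int) -> List[TEFragment]:
    """Merge same-family fragments on one chromosome with gap < min_merge_gap."""
    out: List[TEFragment] = []
    keyed: Dict[Tuple[str, str], List[TEFragment]] = {}
    for f in fragments:
        keyed.setdefault((f.chrom, f.family), []).append(f)
    for (_, _), group in sorted(keyed.items()):
        group.sort(key=lambda f: (f.start, f.end))
        cur = group[0]
        for nxt in group[1:]:
            if nxt.start - cur.end < min_merge_gap:
                cur = replace(cur, end=max(cur.end, nxt.end))
            else:
                out.append(cur)
                cur = nxt
        out.append(cur)
    out.sort(key=lambda f: (f.chrom, f.start, f.end, f.family))
    return [replace(f, id=f"te{i}") for i, f in enumerate(out)]


_RM_HEADER = (
    "   SW  perc perc perc  query     position in query              matching"
    "  repeat        position in repeat\n"
    "score  div. del. ins.  sequence  begin  end      (left)  repeat"
    "  class/family  begin  end  (left)  ID\n"
    "\n"
)


def write_repeatmasker(fragments: Iterable[TEFragment], path) -> None:
    """Write fragments back to RepeatMasker `.out` layout (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, f in enumerate(sorted(fragments, key=lambda x: (x.chrom, x.start)), 1):
            rm_class = f.te_class
            div = f.divergence if f.divergence is not None else 0.0
            fh.write(
                f"1000 {div:5.1f} 0.0 0.0 {f.chrom} {f.start + 1} {f.end} "
                f"(0) + {f.family} {rm_class} 1 {f.length} (0) {i}\n"
            )


def te_interval_set(fragments: Iterable[TEFragment]) -> IntervalSet:
    return IntervalSet.from_records((f.chrom, f.start, f.end) for f in fragments)


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')

_BIOTYPE_MAP = {
    "lincRNA": "lncRNA_intergenic",
    "lncRNA_intergenic": "lncRNA_intergenic",
    "lncRNA": "lncRNA_genic",
    "lncRNA_genic": "lncRNA_genic",
    "antisense": "lncRNA_genic",
    "processed_transcript": "lncRNA_genic",
    "protein_coding": "protein_coding",
    "miRNA": "small_ncRNA",
    "snRNA": "small_ncRNA",
    "snoRNA": "small_ncRNA",
    "small_ncRNA": "small_ncRNA",
    "pseudogene": "pseudogene",
    "processed_pseudogene": "pseudogene",
}

_UTR5_FEATURES = {"five_prime_utr", "5UTR", "five_prime_UTR"}
_UTR3_FEATURES = {"three_prime_utr", "3UTR", "three_prime_UTR"}


def parse_transcripts(
    path,
    one_isoform_per_gene: bool = False,
    seed: int = 0,
) -> List[TranscriptModel]:
    """Parse transcript models from a GTF (exon + optional CDS/UTR features).

    Exons are grouped per transcript id, sorted, and book-ended or duplicate
    exon records merged; a transcript spanning several chromosomes or
    strands is rejected and logged. With ``one_isoform_per_gene`` one
    transcript per gene is retained, chosen at random with ``seed``.
    """
    per_tx: Dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise ValueError(f"{path}: malformed GTF row at line {lineno}")
            chrom, _, feature, start, end, _, strand, _, attrs = cols[:9]
            if feature not in ("exon", "CDS") and feature not in _UTR5_FEATURES | _UTR3_FEATURES:
                continue
            a = dict(_ATTR_RE.findall(attrs))
            tid = a.get("transcript_id")
            if tid is None:
                raise ValueError(f"{path}: missing transcript_id at line {lineno}")
            rec = per_tx.setdefault(
                tid,
                {
                    "gene_id": a.get("gene_id", tid),
                    "chrom": chrom,
                    "strand": strand,
                    "biotype": a.get("gene_biotype")
                    or a.get("transcript_biotype")
                    or a.get("gene_type")
                    or "lncRNA",
                    "exons": [],
                    "cds": [],
                    "utr5": [],
                    "utr3": [],
                    "bad": False,
                },
            )
            if rec["chrom"] != chrom or rec["strand"] != strand:
                rec["bad"] = True
                continue
            iv = (int(start) - 1, int(end))
            if feature == "exon":
                rec["exons"].append(iv)
            elif feature == "CDS":
                rec["cds"].append(iv)
            elif feature in _UTR5_FEATURES:
                rec["utr5"].append(iv)
            else:
                rec["utr3"].append(iv)

    models: List[TranscriptModel] = []
    for tid, rec in per_tx.items():
        if rec["bad"]:
            log.warning("transcript %s spans chromosomes/strands, rejected", tid)
            continue
        if not rec["exons"]:
            continue
        exons = _merge_bookended(sorted(rec["exons"]))
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=tuple(exons),
                biotype=_BIOTYPE_MAP.get(rec["biotype"], rec["biotype"]),
                cds=tuple(sorted(rec["cds"])),
                utr5=tuple(sorted(rec["utr5"])),
                utr3=tuple(sorted(rec["utr3"])),
            )
        )
    models.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    if one_isoform_per_gene:
        models = select_one_isoform(models, seed)
    return models


def _merge_bookended(ivs: List[Interval]) -> List[Interval]:
    merged: List[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def select_one_isoform(models: Sequence[TranscriptModel], seed: int) -> List[TranscriptModel]:
    """Keep one transcript per gene, drawn at random but reproducibly."""
    rng = np.random.default_rng(seed)
    by_gene: Dict[str, List[TranscriptModel]] = {}
    for t in models:
        by_gene.setdefault(t.gene_id, []).append(t)
    kept = []
    for gene in sorted(by_gene):
        group = sorted(by_gene[gene], key=lambda t: t.transcript_id)
        kept.append(group[int(rng.integers(len(group)))])
    kept.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    return kept


def feature_analysis_view(models: Sequence[TranscriptModel]) -> List[TranscriptModel]:
    """Drop protein-coding transcripts lacking either UTR (feature analyses)."""
    return [
        t
        for t in models
        if t.biotype != "protein_coding" or t.has_both_utrs
    ]


def write_gtf(models: Iterable[TranscriptModel], path) -> None:
    inv_biotype = {
        "lncRNA_intergenic": "lincRNA",
        "lncRNA_genic": "lncRNA",
    }
    with open(path, "w") as fh:
        for t in sorted(models, key=lambda t: (t.chrom, t.start, t.transcript_id)):
            bt = inv_biotype.get(t.biotype, t.biotype)
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'gene_biotype "{bt}";'
            )
            rows = [("exon", s, e) for s, e in t.exons]
            rows += [("CDS", s, e) for s, e in t.cds]
            rows += [("five_prime_utr", s, e) for s, e in t.utr5]
            rows += [("three_prime_utr", s, e) for s, e in t.utr3]
            for feat, s, e in rows:
                fh.write(
                    f"{t.chrom}\ttelinc\t{feat}\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# BED / bedGraph / chrom.sizes


def read_intervals(path) -> IntervalSet:
    """Read BED3+ into an IntervalSet; overlapping records are preserved."""
    recs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            if start >= end:
                raise ValueError(f"{path}: start >= end at line {lineno}")
            recs.append((chrom, start, end))
    return IntervalSet.from_records(recs) if recs else IntervalSet()


def write_intervals(ivset: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in ivset.records():
            fh.write(f"{chrom}\t{s}\t{e}\n")


def read_score_track(path) -> ScoreTrack:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "value"],
        comment="#",
        dtype={"chrom": str, "start": int, "end": int, "value": float},
    )
    return ScoreTrack(df.itertuples(index=False, name=None))


def write_score_track(records: Iterable[Tuple[str, int, int, float]], path) -> None:
    df = pd.DataFrame(records, columns=["chrom", "start", "end", "value"])
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.4f")


def read_chrom_sizes(path) -> Dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, n = line.split()[:2]
                sizes[chrom] = int(n)
    return sizes


def write_chrom_sizes(sizes: Dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def read_layout(chrom_sizes_path, gaps_bed_path=None) -> GenomeLayout:
    gaps = read_intervals(gaps_bed_path) if gaps_bed_path else IntervalSet()
    return GenomeLayout(read_chrom_sizes(chrom_sizes_path), gaps)
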