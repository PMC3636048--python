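"""Synthetic genomes with known ground truth for every pipeline stage.

The generator emulates the statistical structure of a real TE/lncRNA
analysis without any sequence-level realism: a small multi-chromosome
genome with assembly gaps; a TE complement drawn from a family table
(class, length distribution, genomic fraction, optional planted exonic
enrichment); multi-exon transcripts on both strands (lncRNA, intergenic
and genic, plus protein-coding genes with UTRs); a per-base conservation
track with a planted shift on exonised TE bases; DNase peaks and per-cell
signal tracks with an optional planted expression/accessibility coupling;
A-to-I editing sites at class-specific densities; and short stem-loop
elements with substitutions under a transition/transversion (kappa) model,
a subset carrying planted compensatory pairs.

Exonic enrichment factors are target observed/expected ratios: the family
shares among exon-assigned fragments are set to fraction x factor, with
unplanted families rescaled so shares sum to one. Background fragments are
placed rejecting exon overlap, so realized enrichment matches the factor
rather than being diluted by incidental overlaps.

Everything is a deterministic function of the spec seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import genome_io
from .genome_io import GenomeLayout, TEFragment, TranscriptModel
from .intervals import IntervalSet

RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
TRANSITION = {"A": "G", "G": "A", "C": "U", "U": "C"}


@dataclass
class TEFamilySpec:
    name: str
    te_class: str
    mean_len: int
    genomic_fraction: float
    subpart: str = "NA"
    exon_enrichment: float = 1.0
    age_label: str = "NA"
    len_sigma: float = 0.35  # lognormal shape
    min_len: int = 40


@dataclass
class SynthSpec:
    seed: int = 0
    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    gap_fraction: float = 0.02
    te_families: List[TEFamilySpec] = field(default_factory=list)
    n_lncrna: int = 200
    n_coding: int = 100
    frac_genic_lnc: float = 0.15
    exon_assign_rate: float = 0.12  # marginal prob a TE is targeted at a lnc exon
    mean_exons_lnc: float = 3.0
    mean_exons_pc: float = 5.0
    exon_len_mean: int = 230
    intron_len_mean: int = 1200
    # conservation model
    cons_baseline_mean: float = -0.1
    cons_baseline_sd: float = 1.0
    cons_te_exon_shift: float = 1.0
    cons_bg_run: int = 25
    write_conservation: bool = True  # the track dominates bundle size/time
    # DHS / expression model
    cells: Tuple[str, ...] = ("GM", "H1", "K562")
    dhs_prob: float = 0.7
    n_background_dhs: int = 150
    dhs_coupling_factor: float = 3.0
    library_size: float = 1e6
    expr_frac_specific: float = 0.25
    expr_fold: float = 10.0
    # editing model
    alu_families: Tuple[str, ...] = ("AluSyn",)
    editing_density_alu: float = 1e-3
    editing_density_other: float = 1e-5
    # stem model
    n_stems: int = 12
    stem_pairs: int = 40
    stem_loop: int = 8
    stem_sub_rate: float = 0.02
    stem_planted_frac: float = 0.33
    stem_planted_pairs: int = 3
    kappa: float = 1.2

    def validate(self) -> None:
        genome_bp = sum(self.chrom_lengths.values())
        te_bp = sum(f.genomic_fraction for f in self.te_families) * genome_bp
        if te_bp > 0.6 * genome_bp * (1 - self.gap_fraction):
            raise ValueError(
                "infeasible spec: TE content exceeds 60% of ungapped genome"
            )
        for fam in self.te_families:
            if not 0 <= fam.genomic_fraction <= 1:
                raise ValueError(f"bad genomic fraction for {fam.name}")
            if fam.exon_enrichment < 0:
                raise ValueError(f"negative enrichment for {fam.name}")


def default_family_table() -> List[TEFamilySpec]:
    return [
        TEFamilySpec("L1Syn", "LINE", 600, 0.08, age_label="lineage_specific"),
        TEFamilySpec("L2Syn", "LINE", 300, 0.04, age_label="ancient"),
        TEFamilySpec("AluSyn", "SINE", 280, 0.06, age_label="lineage_specific"),
        TEFamilySpec("MIRSyn", "SINE", 180, 0.03, age_label="ancient"),
        TEFamilySpec("ERVSyn", "LTR", 350, 0.04, subpart="LTR", age_label="lineage_specific"),
        TEFamilySpec("ERVSyn-int", "LTR", 900, 0.04, subpart="internal", age_label="lineage_specific"),
        TEFamilySpec("TcMarSyn", "DNA", 250, 0.02, age_label="ancient"),
        TEFamilySpec("hATSyn", "DNA", 200, 0.02, age_label="ancient"),
    ]


def default_desk_spec(seed: int = 0) -> SynthSpec:
    """Desk-scale study conditions: 2 x 1 Mb, ~2,000 TEs, ~300 transcripts."""
    return SynthSpec(seed=seed, te_families=default_family_table())


@dataclass
class Bundle:
    spec: SynthSpec
    layout: GenomeLayout
    tes: List[TEFragment]
    transcripts: List[TranscriptModel]
    paths: Dict[str, Path]
    truth: pd.DataFrame

    @property
    def lncrnas(self) -> List[TranscriptModel]:
        return [t for t in self.transcripts if t.biotype.startswith("lncRNA")]

    @property
    def coding(self) -> List[TranscriptModel]:
        return [t for t in self.transcripts if t.biotype == "protein_coding"]


# ---------------------------------------------------------------------------


def generate(spec: SynthSpec, outdir) -> Bundle:
    """Generate the full bundle and write every artifact under ``outdir``."""
    spec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    truth_rows: List[Tuple[str, str, str, str]] = []

    layout = _make_layout(spec, rng)
    transcripts = _make_transcripts(spec, layout, rng)
    tes, fam_truth = _place_tes(spec, layout, transcripts, rng)
    truth_rows.extend(fam_truth)

    paths: Dict[str, Path] = {}
    paths["chrom_sizes"] = outdir / "genome.chrom.sizes"
    genome_io.write_chrom_sizes(layout.chrom_sizes, paths["chrom_sizes"])
    paths["gaps"] = outdir / "gaps.bed"
    genome_io.write_intervals(layout.gaps, paths["gaps"])
    paths["repeatmasker"] = outdir / "tes.out"
    genome_io.write_repeatmasker(tes, paths["repeatmasker"])
    paths["gtf"] = outdir / "transcripts.gtf"
    genome_io.write_gtf(transcripts, paths["gtf"])

    if spec.write_conservation:
        paths["conservation"] = outdir / "conservation.bedGraph"
        _write_conservation(spec, layout, transcripts, tes, rng, paths["conservation"])

    dhs_rows, signal_rows, expr_df, dhs_truth = _make_dhs(
        spec, layout, transcripts, tes, rng
    )
    truth_rows.extend(dhs_truth)
    paths["dhs"] = outdir / "dhs.bed"
    with open(paths["dhs"], "w") as fh:
        for chrom, s, e in dhs_rows:
            fh.write(f"{chrom}\t{s}\t{e}\n")
    for cell in spec.cells:
        p = outdir / f"dhs_signal_{cell}.bedGraph"
        paths[f"signal_{cell}"] = p
        genome_io.write_score_track(signal_rows[cell], p)
    paths["expression"] = outdir / "expression.tsv"
    expr_df.to_csv(paths["expression"], sep="\t")

    paths["editing"] = outdir / "editing.bed"
    _write_editing(spec, transcripts, tes, rng, paths["editing"])

    paths["stems_fasta"] = outdir / "stems.fa"
    paths["stems_structure"] = outdir / "stems.db"
    stem_truth = _write_stems(spec, rng, paths["stems_fasta"], paths["stems_structure"])
    truth_rows.extend(stem_truth)

    truth = pd.DataFrame(truth_rows, columns=["entity", "id", "key", "value"])
    paths["truth"] = outdir / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False)

    return Bundle(
        spec=spec,
        layout=layout,
        tes=tes,
        transcripts=transcripts,
        paths=paths,
        truth=truth,
    )


def _make_layout(spec: SynthSpec, rng) -> GenomeLayout:
    gaps = []
    for chrom, length in spec.chrom_lengths.items():
        gap_bp = int(length * spec.gap_fraction)
        n_blocks = max(1, gap_bp // 10_000) if gap_bp else 0
        for _ in range(n_blocks):
            block = gap_bp // n_blocks
            s = int(rng.integers(0, length - block))
            gaps.append((chrom, s, s + block))
    gap_set = IntervalSet.from_records(gaps) if gaps else IntervalSet()
    return GenomeLayout(dict(spec.chrom_lengths), gap_set)


def _sample_exon_chain(spec: SynthSpec, rng, mean_exons: float, min_exons: int) -> List[Tuple[int, int]]:
    n_exons = min_exons + int(rng.poisson(max(mean_exons - min_exons, 0.1)))
    n_exons = min(n_exons, 10)
    exons = []
    pos = 0
    for i in range(n_exons):
        elen = max(60, int(rng.lognormal(math.log(spec.exon_len_mean), 0.45)))
        exons.append((pos, pos + elen))
        ilen = max(200, int(rng.lognormal(math.log(spec.intron_len_mean), 0.6)))
        pos += elen + ilen
    return exons


def _make_transcripts(spec: SynthSpec, layout: GenomeLayout, rng) -> List[TranscriptModel]:
    chroms = sorted(spec.chrom_lengths)
    n_genic = int(spec.n_lncrna * spec.frac_genic_lnc)
    kinds = ["pc"] * spec.n_coding + ["lnc"] * (spec.n_lncrna - n_genic)
    rng.shuffle(kinds)
    per_chrom = {c: [] for c in chroms}
    for i, kind in enumerate(kinds):
        per_chrom[chroms[i % len(chroms)]].append(kind)

    models: List[TranscriptModel] = []
    idx = 0
    pc_spans: List[Tuple[str, int, int]] = []
    for chrom in chroms:
        length = spec.chrom_lengths[chrom]
        gap_ivs = layout.gaps.intervals(chrom)
        cursor = int(rng.integers(1_000, 5_000))
        for kind in per_chrom[chrom]:
            if kind == "pc":
                chain = _sample_exon_chain(spec, rng, spec.mean_exons_pc, 3)
            else:
                chain = _sample_exon_chain(spec, rng, spec.mean_exons_lnc, 1)
            span = chain[-1][1]
            # skip past any gap the gene would touch
            moved = True
            while moved:
                moved = False
                for g_s, g_e in gap_ivs:
                    if cursor < g_e and cursor + span > g_s:
                        cursor = g_e + 100
                        moved = True
            if cursor + span > length - 1_000:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            exons = tuple((cursor + s, cursor + e) for s, e in chain)
            idx += 1
            if kind == "pc":
                first, last = exons[0], exons[-1]
                utr5_iv, utr3_iv = (first, last) if strand == "+" else (last, first)
                models.append(
                    TranscriptModel(
                        transcript_id=f"PC{idx:04d}.1",
                        gene_id=f"PCG{idx:04d}",
                        chrom=chrom,
                        strand=strand,
                        exons=exons,
                        biotype="protein_coding",
                        cds=exons[1:-1],
                        utr5=(utr5_iv,),
                        utr3=(utr3_iv,),
                    )
                )
                pc_spans.append((chrom, exons[0][0], exons[-1][1]))
            else:
                models.append(
                    TranscriptModel(
                        transcript_id=f"LNC{idx:04d}.1",
                        gene_id=f"LNCG{idx:04d}",
                        chrom=chrom,
                        strand=strand,
                        exons=exons,
                        biotype="lncRNA_intergenic",
                    )
                )
            cursor += span + 500 + int(rng.exponential(2_000))

    # genic lncRNAs: dropped inside protein-coding gene spans
    for j in range(n_genic):
        if not pc_spans:
            break
        chrom, g_s, g_e = pc_spans[int(rng.integers(len(pc_spans)))]
        chain = _sample_exon_chain(spec, rng, max(spec.mean_exons_lnc - 1, 1), 1)
        span = chain[-1][1]
        if g_e - g_s <= span + 20:
            offset = g_s
        else:
            offset = g_s + int(rng.integers(0, g_e - g_s - span))
        strand = "+" if rng.random() < 0.5 else "-"
        idx += 1
        models.append(
            TranscriptModel(
                transcript_id=f"LNC{idx:04d}.1",
                gene_id=f"LNCG{idx:04d}",
                chrom=chrom,
                strand=strand,
                exons=tuple((offset + s, offset + e) for s, e in chain),
                biotype="lncRNA_genic",
            )
        )
    models.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    return models


def _normalized_exon_weights(families: Sequence[TEFamilySpec], counts: Dict[str, int]) -> Dict[str, float]:
    """Per-family exon-assignment multiplier so shares = fraction x factor."""
    total = sum(counts.values())
    shares = {f.name: counts[f.name] / total for f in families}
    planted = [f for f in families if f.exon_enrichment != 1.0]
    if not planted:
        return {f.name: 1.0 for f in families}
    planted_mass = sum(shares[f.name] * f.exon_enrichment for f in planted)
    rest_mass = sum(shares[f.name] for f in families if f.exon_enrichment == 1.0)
    if planted_mass >= 1.0 or rest_mass == 0:
        raise ValueError("planted enrichment factors leave no mass for other families")
    scale_rest = (1.0 - planted_mass) / rest_mass
    return {
        f.name: (f.exon_enrichment if f.exon_enrichment != 1.0 else scale_rest)
        for f in families
    }


def _place_tes(
    spec: SynthSpec,
    layout: GenomeLayout,
    transcripts: Sequence[TranscriptModel],
    rng,
) -> Tuple[List[TEFragment], List[Tuple[str, str, str, str]]]:
    from bisect import bisect_left, insort

    genome_bp = layout.total_bp
    chroms = sorted(spec.chrom_lengths)
    counts = {
        f.name: max(1, int(round(f.genomic_fraction * genome_bp / f.mean_len)))
        for f in spec.te_families
    }
    weights = _normalized_exon_weights(spec.te_families, counts)

    lnc_exons = [
        (t.chrom, s, e)
        for t in transcripts
        if t.biotype.startswith("lncRNA")
        for s, e in t.exons
    ]
    all_exons = IntervalSet.from_records(
        (t.chrom, s, e) for t in transcripts for s, e in t.exons
    ).union()
    exon_ivs = {c: all_exons.intervals(c) for c in chroms}

    occupied: Dict[str, list] = {c: list(layout.gaps.intervals(c)) for c in chroms}

    def hits(chrom, s, e, ivs=None):
        lst = occupied[chrom] if ivs is None else ivs
        i = bisect_left(lst, (s,))
        if i < len(lst) and lst[i][0] < e:
            return True
        return i > 0 and lst[i - 1][1] > s

    fragments: List[TEFragment] = []
    truth: List[Tuple[str, str, str, str]] = []
    frag_no = 0
    fam_order = []
    for fam in spec.te_families:
        fam_order.extend([fam] * counts[fam.name])
    rng.shuffle(fam_order)

    n_exonic = {f.name: 0 for f in spec.te_families}
    n_placed = {f.name: 0 for f in spec.te_families}
    for fam in fam_order:
        length = max(fam.min_len, int(rng.lognormal(math.log(fam.mean_len), fam.len_sigma)))
        q = min(0.95, spec.exon_assign_rate * weights[fam.name])
        placed = None
        if lnc_exons and rng.random() < q:
            # target a random lncRNA exon with >= 10 bp overlap
            for _ in range(30):
                chrom, e_s, e_e = lnc_exons[int(rng.integers(len(lnc_exons)))]
                ov_min = min(10, length, e_e - e_s)
                lo = max(0, e_s - length + ov_min)
                hi = min(spec.chrom_lengths[chrom] - length, e_e - ov_min)
                if hi < lo:
                    continue
                s = int(rng.integers(lo, hi + 1))
                if not hits(chrom, s, s + length):
                    placed = (chrom, s, s + length)
                    n_exonic[fam.name] += 1
                    break
        if placed is None:
            # background placement rejecting exon overlap
            for _ in range(200):
                chrom = chroms[int(rng.integers(len(chroms)))]
                hi = spec.chrom_lengths[chrom] - length
                if hi <= 0:
                    continue
                s = int(rng.integers(0, hi + 1))
                if hits(chrom, s, s + length) or hits(chrom, s, s + length, exon_ivs[chrom]):
                    continue
                placed = (chrom, s, s + length)
                break
        if placed is None:
            continue  # dense region; realized counts recorded in truth
        chrom, s, e = placed
        insort(occupied[chrom], (s, e))
        frag_no += 1
        n_placed[fam.name] += 1
        fragments.append(
            TEFragment(
                id=f"te{frag_no}",
                chrom=chrom,
                start=s,
                end=e,
                family=fam.name,
                te_class=fam.te_class,
                subpart=fam.subpart,
                age_label=fam.age_label,
                divergence=float(np.round(rng.uniform(1, 30), 1)),
            )
        )
    for fam in spec.te_families:
        truth.append(("te_family", fam.name, "spec_fraction", str(fam.genomic_fraction)))
        truth.append(("te_family", fam.name, "exon_enrichment", str(fam.exon_enrichment)))
        truth.append(("te_family", fam.name, "n_placed", str(n_placed[fam.name])))
        truth.append(("te_family", fam.name, "n_exon_assigned", str(n_exonic[fam.name])))
    fragments.sort(key=lambda f: (f.chrom, f.start, f.end))
    return fragments, truth


def _write_conservation(spec, layout, transcripts, tes, rng, path) -> None:
    """Per-base scores on exons and TEs, run-compressed background elsewhere.

    Exonised TE bases get the planted shift; scores are truncated to the
    phyloP-like range [-20, 10]. The background run length mimics the local
    autocorrelation of real conservation tracks while keeping files small.
    """
    lnc_exons = IntervalSet.from_records(
        (t.chrom, s, e)
        for t in transcripts
        if t.biotype.startswith("lncRNA")
        for s, e in t.exons
    ).union()
    all_exons = IntervalSet.from_records(
        (t.chrom, s, e) for t in transcripts for s, e in t.exons
    ).union()
    te_set = genome_io.te_interval_set(tes).union()
    special = IntervalSet.from_records(
        list(all_exons.records()) + list(te_set.records())
    ).union()
    shifted = lnc_exons.intersection(te_set)

    records = []

    def emit_per_base(chrom, s, e, shift_ivs):
        vals = rng.normal(spec.cons_baseline_mean, spec.cons_baseline_sd, e - s)
        for sh_s, sh_e in shift_ivs:
            a, b = max(s, sh_s) - s, min(e, sh_e) - s
            if b > a:
                vals[a:b] += spec.cons_te_exon_shift * spec.cons_baseline_sd
        np.clip(vals, -20, 10, out=vals)
        for off, v in enumerate(vals):
            records.append((chrom, s + off, s + off + 1, float(v)))

    ungapped = layout.ungapped()
    for chrom in sorted(layout.chrom_sizes):
        sh = shifted.intervals(chrom)
        for s, e in special.intervals(chrom):
            emit_per_base(chrom, s, e, sh)
        for s, e in ungapped.subtract(special).intervals(chrom):
            pos = s
            while pos < e:
                run = min(spec.cons_bg_run, e - pos)
                v = float(
                    np.clip(
                        rng.normal(spec.cons_baseline_mean, spec.cons_baseline_sd),
                        -20,
                        10,
                    )
                )
                records.append((chrom, pos, pos + run, v))
                pos += run
    records.sort()
    genome_io.write_score_track(records, path)


def _make_dhs(spec, layout, transcripts, tes, rng):
    lnc = [t for t in transcripts if t.biotype.startswith("lncRNA")]
    cells = list(spec.cells)

    # expression with planted cell specificity
    expr: Dict[str, Dict[str, float]] = {}
    specific: Dict[str, Optional[str]] = {}
    truth = []
    for t in lnc:
        base = rng.lognormal(1.0, 0.8, len(cells))
        row = dict(zip(cells, base))
        if rng.random() < spec.expr_frac_specific:
            cell = cells[int(rng.integers(len(cells)))]
            others = [row[c] for c in cells if c != cell]
            row[cell] = spec.expr_fold * 1.5 * (float(np.mean(others)) + 0.1)
            specific[t.transcript_id] = cell
        else:
            specific[t.transcript_id] = None
        expr[t.transcript_id] = row
        truth.append(
            ("lncrna", t.transcript_id, "specific_cell", str(specific[t.transcript_id]))
        )
    expr_df = pd.DataFrame(expr).T
    expr_df.index.name = "lnc_id"

    # upstream TE-DHS peaks with planted coupling
    te_by_chrom: Dict[str, List[TEFragment]] = {}
    for f in tes:
        te_by_chrom.setdefault(f.chrom, []).append(f)
    dhs_rows: List[Tuple[str, int, int]] = []
    signal: Dict[str, List[Tuple[str, int, int, float]]] = {c: [] for c in cells}

    def add_peak(chrom, s, e, boosted_cell=None):
        s, e = max(0, s), min(layout.chrom_sizes[chrom], e)
        if e - s < 20:
            return
        dhs_rows.append((chrom, s, e))
        for c in cells:
            v = rng.gamma(2.0, 5.0)
            if boosted_cell is not None and c == boosted_cell:
                v *= spec.dhs_coupling_factor
            signal[c].append((chrom, s, e, v))

    for t in lnc:
        if rng.random() > spec.dhs_prob:
            continue
        tss = t.tss
        if t.strand == "+":
            window = (tss - 10_000, tss)
            upstream = [
                f for f in te_by_chrom.get(t.chrom, [])
                if window[0] <= f.end - 1 <= window[1]
            ]
        else:
            window = (tss, tss + 10_000)
            upstream = [
                f for f in te_by_chrom.get(t.chrom, [])
                if window[0] <= f.start <= window[1]
            ]
        if not upstream:
            continue
        f = upstream[int(rng.integers(len(upstream)))]
        pad_l, pad_r = int(rng.integers(20, 80)), int(rng.integers(20, 80))
        add_peak(t.chrom, f.start - pad_l, f.end + pad_r, boosted_cell=specific[t.transcript_id])

    chroms = sorted(layout.chrom_sizes)
    for _ in range(spec.n_background_dhs):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(150, 400))
        s = int(rng.integers(0, layout.chrom_sizes[chrom] - length))
        add_peak(chrom, s, s + length)

    dhs_rows.sort()
    for c in cells:
        signal[c].sort()
    # overlapping peaks would break the bedGraph contract; keep first of any clash
    for c in cells:
        cleaned, last_end, last_chrom = [], -1, None
        for chrom, s, e, v in signal[c]:
            if chrom == last_chrom and s < last_end:
                continue
            cleaned.append((chrom, s, e, v))
            last_chrom, last_end = chrom, e
        signal[c] = cleaned
    dedup_rows, last = [], (None, -1)
    for chrom, s, e in dhs_rows:
        if chrom == last[0] and s < last[1]:
            continue
        dedup_rows.append((chrom, s, e))
        last = (chrom, e)
    return dedup_rows, signal, expr_df, truth


def _write_editing(spec, transcripts, tes, rng, path) -> None:
    lnc_exons = IntervalSet.from_records(
        (t.chrom, s, e)
        for t in transcripts
        if t.biotype.startswith("lncRNA")
        for s, e in t.exons
    ).union()
    alu = genome_io.te_interval_set(
        [f for f in tes if f.family in spec.alu_families]
    )
    te_all = genome_io.te_interval_set(tes)
    classes = {
        "Alu": lnc_exons.intersection(alu),
        "other_TE": lnc_exons.intersection(te_all).subtract(alu),
        "non_TE": lnc_exons.subtract(te_all),
    }
    densities = {
        "Alu": spec.editing_density_alu,
        "other_TE": spec.editing_density_other,
        "non_TE": spec.editing_density_other,
    }
    sites = []
    for label, ivset in classes.items():
        for chrom, s, e in ivset.records():
            n = rng.binomial(e - s, densities[label])
            if n:
                pos = rng.choice(e - s, size=n, replace=False) + s
                sites.extend((chrom, int(p), int(p) + 1) for p in pos)
    sites.sort()
    with open(path, "w") as fh:
        for chrom, s, e in sites:
            fh.write(f"{chrom}\t{s}\t{e}\n")


def _mutate_base(base: str, rng, kappa: float) -> str:
    others = [b for b in "ACGU" if b != base]
    w = np.array([kappa if TRANSITION[base] == b else 1.0 for b in others])
    return others[int(rng.choice(3, p=w / w.sum()))]


def _write_stems(spec, rng, fasta_path, structure_path):
    n_planted = int(round(spec.n_stems * spec.stem_planted_frac))
    truth = []
    fasta_lines = []
    struct_lines = []
    N, loop = spec.stem_pairs, spec.stem_loop
    structure = "(" * N + "." * loop + ")" * N
    for i in range(spec.n_stems):
        name = f"stem{i + 1:02d}"
        arm5 = "".join(rng.choice(list("ACGU"), N))
        loop_seq = "".join(rng.choice(list("ACGU"), loop))
        arm3 = "".join(RNA_COMPLEMENT[b] for b in reversed(arm5))
        consensus = arm5 + loop_seq + arm3
        element = list(consensus)
        for pos in range(len(element)):
            if rng.random() < spec.stem_sub_rate:
                element[pos] = _mutate_base(element[pos], rng, spec.kappa)
        planted = i < n_planted
        if planted:
            pair_idx = rng.choice(N, size=min(spec.stem_planted_pairs, N), replace=False)
            for k in pair_idx:
                p5, p3 = k, 2 * N + loop - 1 - k
                new5 = _mutate_base(consensus[p5], rng, spec.kappa)
                element[p5] = new5
                element[p3] = RNA_COMPLEMENT[new5]
        fasta_lines.append(f">{name}\n{''.join(element)}\n")
        fasta_lines.append(f">{name}_consensus\n{consensus}\n")
        struct_lines.append(f"{name}\t{structure}\n")
        truth.append(("stem", name, "planted_compensatory", str(planted)))
    with open(fasta_path, "w") as fh:
        fh.writelines(fasta_lines)
    with open(structure_path, "w") as fh:
        fh.writelines(struct_lines)
    return truth


# ---------------------------------------------------------------------------
# Fragment-level universe sampler (fast path for calibration studies)


def sample_fragment_universe(
    seed: int,
    n_universe: int,
    family_fractions: Dict[str, float],
    exon_rate: float,
    enrichment: Optional[Dict[str, float]] = None,
    as_counts: bool = False,
) -> Tuple["List[TEFragment] | Dict[str, int]", List[TEFragment]]:
    """Sample (universe, exon-overlapping subset) at the fragment level.

    Family identities are multinomial with the given fractions; membership
    in the exon-overlapping subset is Bernoulli with a per-family rate of
    ``exon_rate`` scaled by the normalised enrichment factors (families not
    listed share the remaining mass). Coordinates are placeholders: this
    sampler feeds count-based statistics only. With ``as_counts`` the
    universe composition is fixed at the exact expected counts and returned
    as a family -> count mapping (the cheap representation for large
    universes); only target fragments are materialised.
    """
    rng = np.random.default_rng(seed)
    names = sorted(family_fractions)
    fracs = np.array([family_fractions[n] for n in names], dtype=float)
    fracs /= fracs.sum()
    enrichment = enrichment or {}
    planted_mass = sum(fracs[i] * enrichment[n] for i, n in enumerate(names) if n in enrichment)
    rest_mass = sum(fracs[i] for i, n in enumerate(names) if n not in enrichment)
    scale_rest = (1.0 - planted_mass) / rest_mass if rest_mass else 0.0
    weight = {n: enrichment.get(n, scale_rest) for n in names}
    if as_counts:
        counts = {n: int(round(f * n_universe)) for n, f in zip(names, fracs)}
        target: List[TEFragment] = []
        fid = 0
        for name in names:
            q = min(0.95, exon_rate * weight[name])
            n_target = int(rng.binomial(counts[name], q))
            for _ in range(n_target):
                fid += 1
                target.append(
                    TEFragment(id=f"u{fid}", chrom="chrU", start=fid * 10,
                               end=fid * 10 + 5, family=name, te_class="SINE")
                )
        return counts, target
    counts_arr = rng.multinomial(n_universe, fracs)
    universe: List[TEFragment] = []
    target = []
    fid = 0
    for name, k in zip(names, counts_arr):
        q = min(0.95, exon_rate * weight[name])
        n_target = rng.binomial(k, q)
        for j in range(k):
            fid += 1
            frag = TEFragment(
                id=f"u{fid}",
                chrom="chrU",
                start=fid * 10,
                end=fid * 10 + 5,
                family=name,
                te_class="SINE",
            )
            universe.append(frag)
            if j < n_target:
                target.append(frag)
    return universe, target
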