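"""Downstream annotation of fusion calls.

Covers reading-frame prediction across the junction (over all transcript
pairs containing the fused exons), RPKM expression of the partner genes,
junction-read fusion expression, intra/inter-chromosomal classification,
association with copy-number transitions and amplifications, per-base exonic
coverage, and the summary report.

Frame convention: the coding phase at the junction is the number of CDS bases
of the transcript retained on that side, modulo 3. A fusion is in-frame if
any 5'-transcript x 3'-transcript combination matches phases. Junctions
falling outside the CDS are handled by position: a junction downstream of the
5' CDS retains a complete open reading frame (in-frame); a junction upstream
of both CDSs is a promoter swap that leaves the 3' ORF intact (in-frame); a
promoter fused into the middle of a CDS leaves no start codon (out-of-frame).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import Alignment, GENOME, SPLICE_JUNCTION
from .discovery import DetectionParams
from .gene_model import Gene, GeneModel, SpliceJunction, Transcript
from .junctions import FusionCall

__all__ = [
    "FramePrediction",
    "FusionAnnotation",
    "CopyNumberSegment",
    "CopyNumberProfile",
    "CoverageTrack",
    "predict_frame",
    "compute_rpkm",
    "fusion_expression",
    "classify_chromosomal",
    "copy_number_association",
    "compute_coverage",
    "summarize_report",
    "annotate_calls",
    "write_report",
    "load_cn_profile",
]


# ---------------------------------------------------------------------------
# Frame prediction
# ---------------------------------------------------------------------------

UTR5 = "utr5"  # junction upstream of the CDS
UTR3 = "utr3"  # junction downstream of the CDS


@dataclass
class FramePrediction:
    in_frame: bool
    reason: str
    combinations: list[tuple[str, str, object, object, bool]] = field(
        default_factory=list
    )

    def __bool__(self) -> bool:
        return self.in_frame


def _exon_coords(gene: Gene, exon_id: str) -> tuple[int, int]:
    for e in gene.exons:
        if e.exon_id == exon_id:
            return (e.start, e.end)
    raise ValueError(f"exon {exon_id} not found in gene {gene.gene_id}")


def _transcripts_with_exon(gene: Gene, coords: tuple[int, int]) -> list[Transcript]:
    out = []
    for t in gene.transcripts:
        if any((e.start, e.end) == coords for e in t.exons):
            out.append(t)
    return out


def _phase_5(t: Transcript, coords: tuple[int, int]):
    """Coding phase immediately after the fused 5' exon's last base."""
    offs = t.exon_offsets()
    for e, off in zip(t.exons, offs):
        if (e.start, e.end) == coords:
            end_t = off + len(e)
            if end_t <= t.cds_start:
                return UTR5
            if end_t >= t.cds_end:
                return UTR3
            return (end_t - t.cds_start) % 3
    raise ValueError("exon not in transcript")


def _phase_3(t: Transcript, coords: tuple[int, int]):
    """Coding phase of the fused 3' exon's first base."""
    offs = t.exon_offsets()
    for e, off in zip(t.exons, offs):
        if (e.start, e.end) == coords:
            start_t = off
            if start_t <= t.cds_start:
                return UTR5
            if start_t >= t.cds_end:
                return UTR3
            return (start_t - t.cds_start) % 3
    raise ValueError("exon not in transcript")


def _combo_in_frame(s5, s3) -> bool:
    if s5 == UTR3:  # complete 5' ORF retained, new 3' UTR
        return True
    if s3 == UTR3:  # 5' CDS truncated into a new 3' UTR
        return s5 != UTR5
    if s5 == UTR5:  # promoter swap: needs the complete 3' ORF
        return s3 == UTR5
    return s5 == s3


def _skip_variants(t: Transcript, keep: tuple[int, int]) -> list[Transcript]:
    """Transcripts with one internal exon dropped (fused exon retained)."""
    variants = []
    for i in range(1, len(t.exons) - 1):
        e = t.exons[i]
        if (e.start, e.end) == keep:
            continue
        exons = t.exons[:i] + t.exons[i + 1 :]
        new_len = sum(len(x) for x in exons)
        lo = min(t.cds_start, new_len - 1) if t.cds_start is not None else None
        hi = min(t.cds_end, new_len) if t.cds_end is not None else None
        if lo is not None and hi is not None and lo >= hi:
            continue
        variants.append(
            Transcript(f"{t.transcript_id}.skip{i}", t.gene_id, exons, lo, hi)
        )
    return variants


def predict_frame(
    call: FusionCall, model: GeneModel, allow_exon_skip: bool = False
) -> FramePrediction:
    """Is any transcript-transcript fusion across this junction in-frame?

    Every coding 5'-partner transcript containing the fused 5' exon is paired
    with every coding 3'-partner transcript containing the fused 3' exon; the
    fusion is in-frame if any pairing matches coding phase at the junction.
    With ``allow_exon_skip`` the search additionally considers splice
    variants dropping one internal exon on either side.
    """
    g5, g3 = model[call.five_gene], model[call.three_gene]
    c5 = _exon_coords(g5, call.five_exon)
    c3 = _exon_coords(g3, call.three_exon)
    t5s = [t for t in _transcripts_with_exon(g5, c5) if t.is_coding]
    t3s = [t for t in _transcripts_with_exon(g3, c3) if t.is_coding]
    if not t5s or not t3s:
        return FramePrediction(False, "no CDS on a transcript containing the fused exon")
    if allow_exon_skip:
        t5s = t5s + [v for t in t5s for v in _skip_variants(t, c5)]
        t3s = t3s + [v for t in t3s for v in _skip_variants(t, c3)]
    combos = []
    in_frame = False
    for t5 in t5s:
        s5 = _phase_5(t5, c5)
        for t3 in t3s:
            s3 = _phase_3(t3, c3)
            ok = _combo_in_frame(s5, s3)
            combos.append((t5.transcript_id, t3.transcript_id, s5, s3, ok))
            in_frame = in_frame or ok
    return FramePrediction(in_frame, "phase match" if in_frame else "no phase match",
                           combos)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def compute_rpkm(gene: Gene, unique_read_count: int, total_mapped: int) -> float:
    """Uniquely mapped reads per kb of merged exonic sequence per million mapped."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    kb = gene.merged_exonic_length() / 1000.0
    return unique_read_count / (kb * (total_mapped / 1_000_000.0))


def fusion_expression(call: FusionCall, total_mapped: int) -> tuple[int, float]:
    """Junction-read count, raw and RPKM-style normalised by junction length."""
    raw = call.n_junction_reads
    if total_mapped <= 0 or not call.junction_seq:
        return raw, 0.0
    kb = len(call.junction_seq) / 1000.0
    return raw, raw / (kb * (total_mapped / 1_000_000.0))


def classify_chromosomal(call: FusionCall, model: GeneModel) -> str:
    return "intra" if model[call.five_gene].chrom == model[call.three_gene].chrom else "inter"


# ---------------------------------------------------------------------------
# Copy number
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CopyNumberSegment:
    chrom: str
    start: int
    end: int
    log2_ratio: float


class CopyNumberProfile:
    """Segmented log2-ratio profile, non-overlapping and sorted per chromosome."""

    def __init__(self, segments: Iterable[CopyNumberSegment]):
        self.by_chrom: dict[str, list[CopyNumberSegment]] = {}
        for s in segments:
            self.by_chrom.setdefault(s.chrom, []).append(s)
        for chrom, segs in self.by_chrom.items():
            segs.sort(key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping copy-number segments on {chrom}: "
                        f"[{a.start},{a.end}) and [{b.start},{b.end})"
                    )

    def transitions(self, chrom: str, min_delta: float) -> list[int]:
        """Positions of boundaries between abutting segments with |delta log2| >= min_delta."""
        out = []
        segs = self.by_chrom.get(chrom, [])
        for a, b in zip(segs, segs[1:]):
            if a.end == b.start and abs(b.log2_ratio - a.log2_ratio) >= min_delta:
                out.append(a.end)
        return out

    def max_log2_over(self, chrom: str, start: int, end: int) -> float | None:
        vals = [
            s.log2_ratio
            for s in self.by_chrom.get(chrom, [])
            if s.start < end and start < s.end
        ]
        return max(vals) if vals else None


def copy_number_association(
    call: FusionCall,
    profile: CopyNumberProfile | None,
    model: GeneModel,
    params: DetectionParams,
) -> tuple[bool | None, bool | None]:
    """(at a copy-number transition?, overlapping a high-level amplification?)

    A transition counts when a segment boundary with |delta log2| >=
    ``transition_min_delta`` falls within either gene's span extended by
    ``transition_window`` bp; amplification when either gene overlaps a
    segment at log2 >= ``amplification_log2``. ``None`` flags mean no profile
    data for the genes.
    """
    if profile is None:
        return None, None
    genes = [model[call.five_gene], model[call.three_gene]]
    if not any(g.chrom in profile.by_chrom for g in genes):
        return None, None
    at_transition = False
    amplified = False
    for g in genes:
        lo, hi = g.start - params.transition_window, g.end + params.transition_window
        for pos in profile.transitions(g.chrom, params.transition_min_delta):
            if lo <= pos < hi:
                at_transition = True
        mx = profile.max_log2_over(g.chrom, g.start, g.end)
        if mx is not None and mx >= params.amplification_log2:
            amplified = True
    return at_transition, amplified


def load_cn_profile(path) -> CopyNumberProfile:
    """TSV with chrom, start, end, log2 columns ('#' comments allowed)."""
    segs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#") or line.startswith("chrom\t"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 columns")
            segs.append(
                CopyNumberSegment(parts[0], int(parts[1]), int(parts[2]), float(parts[3]))
            )
    return CopyNumberProfile(segs)


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

@dataclass
class CoverageTrack:
    gene_id: str
    intervals: list[tuple[int, int]]  # merged exonic intervals, genomic
    counts: np.ndarray  # concatenated over intervals

    def depth_at(self, gpos: int) -> int:
        off = 0
        for s, e in self.intervals:
            if s <= gpos < e:
                return int(self.counts[off + gpos - s])
            off += e - s
        raise IndexError(f"{gpos} not exonic in {self.gene_id}")

    def interval_means(self) -> list[float]:
        out, off = [], 0
        for s, e in self.intervals:
            out.append(float(self.counts[off : off + e - s].mean()))
            off += e - s
        return out


def compute_coverage(
    gene: Gene,
    alignments: Sequence[Alignment],
    junctions: Mapping[str, SpliceJunction] | None = None,
    read_len: int = 50,
) -> CoverageTrack:
    """Per-base sequencing depth over the gene's merged exonic intervals.

    Genomic placements add depth where they intersect exons; splice-junction
    placements of the gene's transcripts are projected onto both exon flanks.
    Only uniquely aligned reads should be supplied.
    """
    intervals = gene.merged_exonic_intervals()
    length = sum(e - s for s, e in intervals)
    counts = np.zeros(length, dtype=np.int64)
    offsets = np.cumsum([0] + [e - s for s, e in intervals])

    def add(gstart: int, gend: int) -> None:
        for (s, e), off in zip(intervals, offsets):
            lo, hi = max(gstart, s), min(gend, e)
            if lo < hi:
                counts[off + lo - s : off + hi - s] += 1

    for a in alignments:
        if a.ref_class == GENOME:
            if a.ref_id == gene.chrom:
                add(a.start, a.start + read_len)
        elif a.ref_class == SPLICE_JUNCTION and junctions is not None:
            sj = junctions.get(a.ref_id)
            if sj is None or sj.gene_id != gene.gene_id:
                continue
            s, e = a.start, a.start + read_len
            for span, lo, hi in (
                (sj.donor_span, 0, sj.offset),
                (sj.acceptor_span, sj.offset, sj.offset + (sj.acceptor_span[1] - sj.acceptor_span[0])),
            ):
                ov_lo, ov_hi = max(s, lo), min(e, hi)
                if ov_lo >= ov_hi:
                    continue
                if sj.strand == "+":
                    add(span[0] + (ov_lo - lo), span[0] + (ov_hi - lo))
                else:
                    add(span[1] - (ov_hi - lo), span[1] - (ov_lo - lo))
    return CoverageTrack(gene.gene_id, intervals, counts)


def write_coverage_bedgraph(track: CoverageTrack, gene: Gene, path) -> None:
    with open(path, "w") as fh:
        off = 0
        for s, e in track.intervals:
            for i in range(s, e):
                fh.write(f"{gene.chrom}\t{i}\t{i + 1}\t{track.counts[off + i - s]}\n")
            off += e - s


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

@dataclass
class FusionAnnotation:
    call: FusionCall
    sample: str
    five_name: str
    three_name: str
    five_chrom: str
    three_chrom: str
    in_frame: bool
    chromosomal_class: str
    rpkm_5: float
    rpkm_3: float
    fusion_reads: int
    fusion_rpkm: float
    at_cn_transition: bool | None
    amplified: bool | None


def annotate_calls(
    calls: Sequence[FusionCall],
    model: GeneModel,
    params: DetectionParams,
    unique_reads_per_gene: Mapping[str, int],
    total_mapped: int,
    cn_profile: CopyNumberProfile | None = None,
    sample: str = "sample",
) -> list[FusionAnnotation]:
    out = []
    for call in calls:
        g5, g3 = model[call.five_gene], model[call.three_gene]
        frame = predict_frame(call, model, allow_exon_skip=params.allow_exon_skip)
        raw, norm = fusion_expression(call, total_mapped)
        at_tr, amp = copy_number_association(call, cn_profile, model, params)
        out.append(
            FusionAnnotation(
                call=call,
                sample=sample,
                five_name=g5.name,
                three_name=g3.name,
                five_chrom=g5.chrom,
                three_chrom=g3.chrom,
                in_frame=bool(frame),
                chromosomal_class=classify_chromosomal(call, model),
                rpkm_5=compute_rpkm(g5, unique_reads_per_gene.get(g5.gene_id, 0), total_mapped),
                rpkm_3=compute_rpkm(g3, unique_reads_per_gene.get(g3.gene_id, 0), total_mapped),
                fusion_reads=raw,
                fusion_rpkm=norm,
                at_cn_transition=at_tr,
                amplified=amp,
            )
        )
    return out


REPORT_COLUMNS = [
    "sample", "five_gene", "five_chrom", "three_gene", "three_chrom",
    "n_pairs", "n_junction_reads", "in_frame", "amplified",
    "tiling_class", "distinct_starts", "at_cn_transition",
    "five_exon", "three_exon", "rpkm_5", "rpkm_3", "fusion_rpkm",
]


def _yn(flag: bool | None) -> str:
    return "NA" if flag is None else ("Yes" if flag else "No")


def write_report(annotations: Sequence[FusionAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for a in annotations:
            fh.write(
                "\t".join(
                    [
                        a.sample, a.five_name, a.five_chrom, a.three_name,
                        a.three_chrom, str(a.call.n_pairs),
                        str(a.call.n_junction_reads), _yn(a.in_frame),
                        _yn(a.amplified), a.call.tiling_class,
                        str(a.call.distinct_starts), _yn(a.at_cn_transition),
                        a.call.five_exon, a.call.three_exon,
                        f"{a.rpkm_5:.3f}", f"{a.rpkm_3:.3f}", f"{a.fusion_rpkm:.3f}",
                    ]
                )
                + "\n"
            )


def bundled_fusion_table_path() -> str:
    """Path of the packaged table of validated breast-cancer fusions."""
    from importlib.resources import files

    return str(files("tilefuse.data") / "validated_breast_fusions.tsv")


def summarize_fusion_table(path) -> dict:
    """Tallies over a fusion report TSV (bundled table or pipeline output).

    Requires columns five_chrom / three_chrom / in_frame / amplified / sample;
    intra vs inter is recomputed from the chromosome columns rather than
    trusted from any precomputed field.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample", "five_chrom", "three_chrom", "in_frame", "amplified"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    per_sample = df["sample"].value_counts().to_dict()
    intra = int((df["five_chrom"] == df["three_chrom"]).sum())
    return {
        "total": len(df),
        "intra": intra,
        "inter": len(df) - intra,
        "in_frame": int((df["in_frame"] == "Yes").sum()),
        "amplified": int((df["amplified"] == "Yes").sum()),
        "per_sample": dict(sorted(per_sample.items())),
    }


def summarize_report(annotations: Sequence[FusionAnnotation]) -> dict:
    """Tallies over an annotated fusion set (total, class, frame, CN flags)."""
    per_sample: dict[str, int] = {}
    for a in annotations:
        per_sample[a.sample] = per_sample.get(a.sample, 0) + 1
    return {
        "total": len(annotations),
        "intra": sum(a.chromosomal_class == "intra" for a in annotations),
        "inter": sum(a.chromosomal_class == "inter" for a in annotations),
        "in_frame": sum(bool(a.in_frame) for a in annotations),
        "amplified": sum(a.amplified is True for a in annotations),
        "at_cn_transition": sum(a.at_cn_transition is True for a in annotations),
        "per_sample": dict(sorted(per_sample.items())),
    }
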