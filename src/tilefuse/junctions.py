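"""Fusion-junction resolution and the tiling-pattern artifact filter.

For each candidate gene pair an artificial junction database is built from
all exon-exon combinations in both orientations (A->B and B->A). Reads that
failed to place on the genome or the normal splice-junction reference are
aligned against it; a placement only counts as junction evidence when it
spans the breakpoint with a minimum anchor on *both* sides. The orientation
of the supported junction sequence fixes which gene is the 5' partner.

The tiling classifier then separates genuine fusions from misalignment
artifacts: real junctions collect reads whose alignment start positions tile
across the breakpoint, whereas artifacts stack at one position (give or take
a base or two) and hang almost entirely off one exon. A call is flagged
``artifact`` when the start positions span no more than ``artifact_span``
bases, when there are fewer than ``min_distinct_starts`` distinct starts, or
when fewer than ``min_two_sided_anchor_reads`` reads anchor adequately on
both sides; otherwise it is ``genuine``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .align import ReferenceIndex, align_read, FUSION_JUNCTION
from .discovery import DetectionParams, FusionCandidate
from .gene_model import GeneModel, revcomp

__all__ = [
    "FusionJunctionSeq",
    "JunctionHit",
    "FusionCall",
    "enumerate_fusion_junctions",
    "align_unmapped_to_junctions",
    "call_junctions",
    "tiling_classify",
    "prioritize_calls",
    "write_junction_fasta",
]

GENUINE = "genuine"
ARTIFACT = "artifact"


@dataclass
class FusionJunctionSeq:
    """One candidate exon-exon fusion junction in fused-transcript orientation.

    Bases ``[0, junction_offset)`` come from the 3' end of the 5'-partner
    exon; the remainder from the 5' start of the 3'-partner exon. Identical
    sequences arising from coordinate-identical exons in several transcripts
    are deduplicated with their labels merged.
    """

    five_gene: str
    three_gene: str
    five_exon: str
    three_exon: str
    seq: str
    junction_offset: int
    merged_labels: list[str] = field(default_factory=list)

    @property
    def name(self) -> str:
        return (
            f"FJ|{self.five_gene}|{self.five_exon}|"
            f"{self.three_gene}|{self.three_exon}|{self.junction_offset}"
        )


@dataclass(frozen=True)
class JunctionHit:
    read_id: str
    junction: str  # FusionJunctionSeq.name
    start_offset: int  # read start relative to the breakpoint (negative: 5' exon)
    overhang_5: int
    overhang_3: int
    mismatches: int
    strand: str


@dataclass
class FusionCall:
    five_gene: str
    three_gene: str
    five_exon: str
    three_exon: str
    n_pairs: int
    n_junction_reads: int
    hits: list[JunctionHit]
    tiling_class: str = ""
    distinct_starts: int = 0
    tiling_detail: dict = field(default_factory=dict)
    junction_seq: str = ""
    junction_offset: int = 0


def _donor_fragment(genome: Mapping[str, str], exon, flank: int) -> str:
    """Up to ``flank`` bases of the exon's 3' end, in transcript orientation."""
    f = min(flank, exon.end - exon.start)
    if exon.strand == "+":
        return genome[exon.chrom][exon.end - f : exon.end]
    return revcomp(genome[exon.chrom][exon.start : exon.start + f])


def _acceptor_fragment(genome: Mapping[str, str], exon, flank: int) -> str:
    """Up to ``flank`` bases of the exon's 5' start, in transcript orientation."""
    f = min(flank, exon.end - exon.start)
    if exon.strand == "+":
        return genome[exon.chrom][exon.start : exon.start + f]
    return revcomp(genome[exon.chrom][exon.end - f : exon.end])


def enumerate_fusion_junctions(
    candidate: FusionCandidate,
    model: GeneModel,
    genome: Mapping[str, str],
    flank: int = 49,
) -> list[FusionJunctionSeq]:
    """All exon-exon junction sequences between the two genes, both orders.

    For every exon e_a of gene A and e_b of gene B two sequences are emitted:
    3'-end of e_a joined to 5'-start of e_b (A is the 5' partner) and the
    converse, each read in the donor transcript's orientation.
    """
    out: dict[str, FusionJunctionSeq] = {}
    for five, three in (
        (model[candidate.gene_a], model[candidate.gene_b]),
        (model[candidate.gene_b], model[candidate.gene_a]),
    ):
        if not five.exons or not three.exons:
            raise ValueError(
                f"gene without exons in candidate {candidate.gene_a}-{candidate.gene_b}"
            )
        for e5 in five.exons:
            donor = _donor_fragment(genome, e5, flank)
            for e3 in three.exons:
                seq = donor + _acceptor_fragment(genome, e3, flank)
                fj = FusionJunctionSeq(
                    five_gene=five.gene_id,
                    three_gene=three.gene_id,
                    five_exon=e5.exon_id,
                    three_exon=e3.exon_id,
                    seq=seq,
                    junction_offset=len(donor),
                )
                if seq in out:
                    out[seq].merged_labels.append(fj.name)
                else:
                    out[seq] = fj
    return list(out.values())


def align_unmapped_to_junctions(
    reads: Iterable[tuple[str, str]],
    junctions: list[FusionJunctionSeq],
    params: DetectionParams,
) -> list[JunctionHit]:
    """Place previously unmapped reads on the junction database.

    Only breakpoint-spanning placements with both overhangs of at least
    ``min_anchor`` bases qualify; a read hitting several junction sequences
    keeps only its minimum-mismatch hits.
    """
    if not junctions:
        return []
    by_name = {fj.name: fj for fj in junctions}
    index = ReferenceIndex(
        [(fj.name, fj.seq) for fj in junctions],
        seed_len=min(12, params.trim_len // (params.max_mismatches + 1)),
        ref_class=FUSION_JUNCTION,
    )
    hits: list[JunctionHit] = []
    for read_id, seq in reads:
        alns = align_read(seq, index, params.max_mismatches, read_id=read_id)
        read_hits = []
        for a in alns:
            fj = by_name[a.ref_id]
            over5 = fj.junction_offset - a.start
            over3 = len(seq) - over5
            if min(over5, over3) < params.min_anchor:
                continue
            read_hits.append(
                JunctionHit(
                    read_id=read_id,
                    junction=fj.name,
                    start_offset=a.start - fj.junction_offset,
                    overhang_5=over5,
                    overhang_3=over3,
                    mismatches=a.mismatches,
                    strand=a.strand,
                )
            )
        if read_hits:
            best = min(h.mismatches for h in read_hits)
            hits.extend(h for h in read_hits if h.mismatches == best)
    return hits


def tiling_classify(
    hits: list[JunctionHit], params: DetectionParams
) -> tuple[str, int, dict]:
    """Classify one junction's spanning reads as genuine tiling or artifact.

    Returns (class, distinct start count, per-criterion detail). All hits
    must be on the same junction sequence.
    """
    if not hits:
        raise ValueError("tiling_classify requires at least one hit")
    starts = sorted({h.start_offset for h in hits})
    span = starts[-1] - starts[0]
    two_sided = sum(
        1
        for h in hits
        if h.overhang_5 >= params.min_anchor and h.overhang_3 >= params.min_anchor
    )
    detail = {
        "start_span": span,
        "span_artifact": span <= params.artifact_span,
        "distinct_starts": len(starts),
        "too_few_starts": len(starts) < params.min_distinct_starts,
        "two_sided_anchor_reads": two_sided,
        "too_few_two_sided": two_sided < params.min_two_sided_anchor_reads,
    }
    is_artifact = (
        detail["span_artifact"]
        or detail["too_few_starts"]
        or detail["too_few_two_sided"]
    )
    return (ARTIFACT if is_artifact else GENUINE), len(starts), detail


def call_junctions(
    candidate: FusionCandidate,
    hits: list[JunctionHit],
    junctions: list[FusionJunctionSeq],
    params: DetectionParams,
) -> list[FusionCall]:
    """Turn junction hits into fusion calls with tiling classification.

    One call per junction sequence with at least ``min_junction_reads``
    distinct spanning reads; the junction's orientation names the 5' partner.
    Several surviving junctions for a pair (alternative splicing at the
    breakpoint, or reciprocal A->B / B->A evidence) are all reported.
    """
    by_name = {fj.name: fj for fj in junctions}
    grouped: dict[str, list[JunctionHit]] = {}
    for h in hits:
        grouped.setdefault(h.junction, []).append(h)
    calls = []
    for name, jhits in sorted(grouped.items()):
        n_reads = len({h.read_id for h in jhits})
        if n_reads < params.min_junction_reads:
            continue
        fj = by_name[name]
        cls, distinct, detail = tiling_classify(jhits, params)
        calls.append(
            FusionCall(
                five_gene=fj.five_gene,
                three_gene=fj.three_gene,
                five_exon=fj.five_exon,
                three_exon=fj.three_exon,
                n_pairs=candidate.pair_count,
                n_junction_reads=n_reads,
                hits=sorted(jhits, key=lambda h: (h.start_offset, h.read_id)),
                tiling_class=cls,
                distinct_starts=distinct,
                tiling_detail=detail,
                junction_seq=fj.seq,
                junction_offset=fj.junction_offset,
            )
        )
    return calls


def prioritize_calls(calls: list[FusionCall]) -> list[FusionCall]:
    """Rank calls for follow-up: genuine first, then by tiling richness.

    Within a class: descending distinct start positions, then junction-read
    count, then bridging-pair count, with gene ids as the deterministic
    tiebreak.
    """
    return sorted(
        calls,
        key=lambda c: (
            c.tiling_class != GENUINE,
            -c.distinct_starts,
            -c.n_junction_reads,
            -c.n_pairs,
            c.five_gene,
            c.three_gene,
            c.five_exon,
            c.three_exon,
        ),
    )


def write_junction_fasta(junctions: list[FusionJunctionSeq], path) -> None:
    with open(path, "w") as fh:
        for fj in junctions:
            fh.write(f">{fj.name}\n{fj.seq}\n")
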