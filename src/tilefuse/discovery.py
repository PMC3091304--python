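"""Discordant-pair clustering into fusion gene-pair candidates.

A read pair whose two mates are uniquely and unambiguously assigned to two
different genes is evidence of a bridging cDNA fragment. Candidates are
unordered gene pairs accumulated over all such pairs, then pruned by the
biological exclusion filters: overlapping or adjacent partners (readthrough),
paralogous partners (cross-mapping), and a minimum number of supporting
pairs. Which partner is 5' is decided later, by the junction stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .gene_model import (
    GeneModel,
    ParalogTable,
    genes_adjacent,
    genes_overlap,
    is_paralog_pair,
)

__all__ = ["DetectionParams", "FusionCandidate", "find_discordant_pairs",
           "filter_candidates", "write_candidate_table"]


@dataclass
class DetectionParams:
    """Tunable thresholds of the detection pipeline.

    ``min_pair_support`` defaults to 2 bridging read pairs; deeper libraries
    (rule of thumb: more than 8M filtered pairs) warrant 3 to keep the
    false-positive proportion comparable across samples. ``min_anchor`` is the
    minimum read overhang on each side of a fusion junction; the tiling
    parameters control the misalignment-artifact classifier.
    """

    min_pair_support: int = 2
    min_junction_reads: int = 2
    min_anchor: int = 10
    max_mismatches: int = 3
    trim_len: int = 50
    # tiling-pattern classifier
    min_distinct_starts: int = 3
    artifact_span: int = 2
    min_two_sided_anchor_reads: int = 1
    # copy-number association
    amplification_log2: float = 1.0
    transition_window: int = 100_000
    transition_min_delta: float = 0.3
    # frame prediction
    allow_exon_skip: bool = False

    def __post_init__(self) -> None:
        for name in ("min_pair_support", "min_junction_reads", "min_anchor",
                     "min_distinct_starts", "min_two_sided_anchor_reads",
                     "trim_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.min_anchor > self.trim_len // 2:
            raise ValueError("min_anchor must be <= trim_len / 2")


@dataclass
class FusionCandidate:
    gene_a: str
    gene_b: str
    supporting_pairs: list[str] = field(default_factory=list)

    @property
    def pair_count(self) -> int:
        return len(self.supporting_pairs)

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.gene_a, self.gene_b)))  # type: ignore[return-value]


def find_discordant_pairs(
    assignments: Mapping[str, str],
    pair_ids: list[str],
) -> dict[tuple[str, str], FusionCandidate]:
    """Cluster pairs whose mates land in two different genes.

    ``assignments`` maps read ids (``<pair_id>/1`` and ``/2``) to gene ids for
    uniquely, unambiguously assigned mates only; pairs with a missing mate
    contribute nothing here (their junction-spanning mate is picked up by the
    junction stage instead).
    """
    out: dict[tuple[str, str], FusionCandidate] = {}
    for pid in pair_ids:
        g1 = assignments.get(f"{pid}/1")
        g2 = assignments.get(f"{pid}/2")
        if g1 is None or g2 is None or g1 == g2:
            continue
        key = tuple(sorted((g1, g2)))
        cand = out.get(key)
        if cand is None:
            cand = out[key] = FusionCandidate(key[0], key[1])
        cand.supporting_pairs.append(pid)
    return out


def filter_candidates(
    candidates: Mapping[tuple[str, str], FusionCandidate],
    model: GeneModel,
    paralogs: ParalogTable,
    params: DetectionParams,
) -> list[FusionCandidate]:
    """Apply support threshold and readthrough/paralog exclusion filters.

    A candidate survives iff it has >= ``min_pair_support`` bridging pairs and
    its genes neither overlap, nor are adjacent (no third gene entirely in
    between), nor are annotated paralogs. Output is sorted by descending
    support then gene ids.
    """
    kept = []
    for cand in candidates.values():
        if cand.pair_count < params.min_pair_support:
            continue
        a, b = model[cand.gene_a], model[cand.gene_b]
        if genes_overlap(a, b):
            continue
        if a.chrom == b.chrom and genes_adjacent(a, b, model):
            continue
        if is_paralog_pair(a, b, paralogs):
            continue
        kept.append(cand)
    kept.sort(key=lambda c: (-c.pair_count, c.gene_a, c.gene_b))
    return kept


def write_candidate_table(candidates: list[FusionCandidate], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tpair_count\tpair_ids\n")
        for c in candidates:
            fh.write(
                f"{c.gene_a}\t{c.gene_b}\t{c.pair_count}\t"
                f"{';'.join(c.supporting_pairs)}\n"
            )
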