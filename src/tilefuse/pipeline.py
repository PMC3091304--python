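"""End-to-end detection pipeline: trim -> decontaminate -> align/categorise ->
discordant candidates -> junction resolution -> tiling filter -> annotation.

The pipeline is deterministic for fixed inputs; the seed is only recorded in
the run manifest (no stage draws random numbers). Per-stage read and
candidate counts are logged and conserved: reads in == removed + kept at
every step.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import align as al
from .align import (
    AlignmentCategory,
    ReadPair,
    ReferenceIndex,
    align_read,
    categorize_reads,
    filter_contaminants,
    read_fastq_pairs,
    trim_reads,
)
from .characterize import (
    FusionAnnotation,
    annotate_calls,
    load_cn_profile,
    summarize_report,
    write_report,
)
from .discovery import (
    DetectionParams,
    FusionCandidate,
    filter_candidates,
    find_discordant_pairs,
    write_candidate_table,
)
from .gene_model import (
    GeneModel,
    ParalogTable,
    build_splice_junction_reference,
    load_annotation,
    load_genome,
    load_paralogs,
)
from .junctions import (
    FusionCall,
    GENUINE,
    align_unmapped_to_junctions,
    call_junctions,
    enumerate_fusion_junctions,
    prioritize_calls,
    write_junction_fasta,
)

log = logging.getLogger("tilefuse")

__all__ = ["RunConfig", "DetectionResult", "run_detection"]


@dataclass
class RunConfig:
    reads1: str
    reads2: str
    gtf: str
    genome: str
    out_dir: str
    contaminants: str | None = None
    paralogs: str | None = None
    cn_profile: str | None = None
    sample: str = "sample"
    params: DetectionParams = field(default_factory=DetectionParams)
    seed: int = 0
    keep_intermediates: bool = False


@dataclass
class DetectionResult:
    annotations: list[FusionAnnotation]
    calls: list[FusionCall]  # all calls, genuine and artifact, prioritized
    candidates: list[FusionCandidate]
    stage_counts: dict
    summary: dict
    report_path: str


def _sha256(path: str | None) -> str:
    if path is None:
        return "-"
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_detection(config: RunConfig) -> DetectionResult:
    params = config.params
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    model = load_annotation(config.gtf)
    genome = load_genome(config.genome)
    paralogs = (
        load_paralogs(config.paralogs) if config.paralogs else ParalogTable()
    )
    cn = load_cn_profile(config.cn_profile) if config.cn_profile else None

    # --- reads: trim and decontaminate
    pairs = read_fastq_pairs(config.reads1, config.reads2)
    counts["pairs_input"] = len(pairs)
    pairs = trim_reads(pairs, params.trim_len)
    if config.contaminants:
        from .gene_model import load_genome as _load_fa

        contam = _load_fa(config.contaminants)
        pairs, removed = filter_contaminants(pairs, contam, params.max_mismatches)
        counts["pairs_contaminant"] = removed
    else:
        counts["pairs_contaminant"] = 0
    counts["pairs_kept"] = len(pairs)
    assert counts["pairs_input"] == counts["pairs_kept"] + counts["pairs_contaminant"]
    log.info("reads: %(pairs_input)d pairs in, %(pairs_contaminant)d contaminant, "
             "%(pairs_kept)d kept", counts)

    # --- first alignment pass: genome + normal splice junctions
    flank = params.trim_len - 1
    sjs = build_splice_junction_reference(model, genome, flank=flank)
    sj_by_name = {sj.name: sj for sj in sjs}
    seed_len = min(12, params.trim_len // (params.max_mismatches + 1))
    genome_index = ReferenceIndex(genome, seed_len=seed_len, ref_class=al.GENOME)
    sj_index = (
        ReferenceIndex(
            [(sj.name, sj.seq) for sj in sjs], seed_len=seed_len,
            ref_class=al.SPLICE_JUNCTION,
        )
        if sjs
        else None
    )

    alignments_by_read: dict[str, list] = {}
    read_seqs: dict[str, str] = {}
    for p in pairs:
        for rid, seq in p.mates():
            read_seqs[rid] = seq
            alns = align_read(seq, genome_index, params.max_mismatches, read_id=rid)
            if sj_index is not None:
                alns += align_read(seq, sj_index, params.max_mismatches, read_id=rid)
            alignments_by_read[rid] = alns

    categories = categorize_reads(alignments_by_read, sj_by_name, params.trim_len)
    counts["reads_unaligned"] = sum(c.category == "unaligned" for c in categories.values())
    counts["reads_unique"] = sum(c.category == "unique" for c in categories.values())
    counts["reads_multi"] = sum(c.category == "multi" for c in categories.values())
    assert (
        counts["reads_unaligned"] + counts["reads_unique"] + counts["reads_multi"]
        == 2 * counts["pairs_kept"]
    )
    log.info("alignment: %(reads_unique)d unique, %(reads_multi)d multi, "
             "%(reads_unaligned)d unaligned", counts)

    # --- gene assignment of unique reads
    assignments: dict[str, str] = {}
    unique_per_gene: dict[str, int] = {}
    for rid, cat in categories.items():
        if cat.category != "unique":
            continue
        votes: set[str] = set()
        for aln in alignments_by_read[rid]:
            if aln.ref_class == al.SPLICE_JUNCTION:
                votes.add(sj_by_name[aln.ref_id].gene_id)
            else:
                votes.update(
                    model.genes_with_exon_at(
                        aln.ref_id, aln.start, aln.start + params.trim_len
                    )
                )
        if len(votes) == 1:
            gid = votes.pop()
            assignments[rid] = gid
            unique_per_gene[gid] = unique_per_gene.get(gid, 0) + 1
    total_mapped = counts["reads_unique"]

    # --- candidates from discordant pairs
    pair_ids = [p.pair_id for p in pairs]
    raw_candidates = find_discordant_pairs(assignments, pair_ids)
    counts["candidates_raw"] = len(raw_candidates)
    candidates = filter_candidates(raw_candidates, model, paralogs, params)
    counts["candidates_filtered"] = len(candidates)
    log.info("candidates: %(candidates_raw)d raw, %(candidates_filtered)d after "
             "filters", counts)

    # --- junction resolution on previously unmapped reads
    unmapped = sorted(
        (rid, read_seqs[rid])
        for rid, cat in categories.items()
        if cat.category == "unaligned"
    )
    all_calls: list[FusionCall] = []
    for cand in candidates:
        fjs = enumerate_fusion_junctions(cand, model, genome, flank=flank)
        hits = align_unmapped_to_junctions(unmapped, fjs, params)
        calls = call_junctions(cand, hits, fjs, params)
        all_calls.extend(calls)
        if config.keep_intermediates:
            write_junction_fasta(
                fjs, out / f"junctions_{cand.gene_a}_{cand.gene_b}.fa"
            )
    all_calls = prioritize_calls(all_calls)
    genuine = [c for c in all_calls if c.tiling_class == GENUINE]
    counts["calls_total"] = len(all_calls)
    counts["calls_genuine"] = len(genuine)
    log.info("junctions: %(calls_total)d calls, %(calls_genuine)d genuine", counts)

    # --- characterization and report
    annotations = annotate_calls(
        genuine, model, params, unique_per_gene, max(total_mapped, 1),
        cn_profile=cn, sample=config.sample,
    )
    report_path = out / "fusion_report.tsv"
    write_report(annotations, report_path)
    if config.keep_intermediates:
        write_candidate_table(candidates, out / "candidates.tsv")
    summary = summarize_report(annotations)

    manifest = {
        "seed": config.seed,
        "sample": config.sample,
        "params": asdict(params),
        "inputs": {
            name: _sha256(getattr(config, name))
            for name in ("reads1", "reads2", "gtf", "genome", "contaminants",
                         "paralogs", "cn_profile")
        },
        "stage_counts": counts,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    return DetectionResult(
        annotations=annotations,
        calls=all_calls,
        candidates=candidates,
        stage_counts=counts,
        summary=summary,
        report_path=str(report_path),
    )
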