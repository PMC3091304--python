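"""Read trimming, contaminant filtering and bounded-mismatch ungapped alignment.

The alignment contract is deliberately simple and exhaustive: a read is placed
at every reference position (both strands) where the end-to-end Hamming
distance is at most ``max_mismatches``; there are no gaps and an ``N`` in the
read always counts as a mismatch. This is implemented with pigeonhole k-mer
seeding — a read with at most k mismatches must contain at least one of k+1
equal-length segments matching the reference exactly — followed by vectorised
mismatch counting, and is verified in the test suite against a brute-force
sliding-window scan.

Reads are then categorised (unaligned / unique / multi) over genome plus
normal splice-junction references, collapsing a splice-junction placement with
its equivalent genomic footprint so exon-end reads are not spuriously "multi".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .gene_model import GeneModel, SpliceJunction, revcomp

__all__ = [
    "ReadPair",
    "Alignment",
    "AlignmentCategory",
    "TrimStats",
    "ReferenceIndex",
    "trim_reads",
    "filter_contaminants",
    "align_read",
    "categorize_reads",
    "assign_read_to_gene",
    "read_fastq_pairs",
    "write_sam",
]

log = logging.getLogger(__name__)

GENOME = "genome"
SPLICE_JUNCTION = "splice_junction"
FUSION_JUNCTION = "fusion_junction"


@dataclass
class ReadPair:
    pair_id: str
    seq1: str
    seq2: str
    qual1: str | None = None
    qual2: str | None = None

    def mates(self) -> list[tuple[str, str]]:
        return [(f"{self.pair_id}/1", self.seq1), (f"{self.pair_id}/2", self.seq2)]


@dataclass(frozen=True, order=True)
class Alignment:
    ref_id: str
    start: int
    strand: str
    mismatches: int
    read_id: str
    ref_class: str = GENOME


@dataclass(frozen=True)
class AlignmentCategory:
    read_id: str
    category: str  # unaligned | unique | multi


@dataclass
class TrimStats:
    trimmed: int = 0
    passed_short: int = 0


def trim_reads(
    pairs: Iterable[ReadPair], target_len: int, stats: TrimStats | None = None
) -> list[ReadPair]:
    """Truncate every mate to its first ``target_len`` bases.

    Mates already at or below the target pass through unchanged, counted in
    ``stats.passed_short`` when shorter.
    """
    if target_len <= 0:
        raise ValueError(f"target_len must be positive, got {target_len}")
    out = []
    for p in pairs:
        short = (len(p.seq1) < target_len) + (len(p.seq2) < target_len)
        if stats is not None:
            if short:
                stats.passed_short += short
            else:
                stats.trimmed += 1
        out.append(
            ReadPair(
                p.pair_id,
                p.seq1[:target_len],
                p.seq2[:target_len],
                p.qual1[:target_len] if p.qual1 else None,
                p.qual2[:target_len] if p.qual2 else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# k-mer seeded exhaustive ungapped alignment
# ---------------------------------------------------------------------------

class ReferenceIndex:
    """Exact k-mer index over a set of labelled reference sequences.

    Seeds are non-overlapping read segments; by the pigeonhole principle a
    placement with <= max_mismatches mismatches has at least one exact
    segment, so looking up max_mismatches + 1 segments finds every placement.
    """

    def __init__(
        self,
        references: Mapping[str, str] | Sequence[tuple[str, str]],
        seed_len: int,
        ref_class: str = GENOME,
    ):
        items = (
            list(references.items())
            if isinstance(references, Mapping)
            else list(references)
        )
        if not items:
            raise ValueError("empty reference set")
        self.ref_class = ref_class
        self.seed_len = seed_len
        self.names: list[str] = [name for name, _ in items]
        self.seqs: list[bytes] = [seq.upper().encode() for _, seq in items]
        self.arrays: list[np.ndarray] = [
            np.frombuffer(s, dtype=np.uint8) for s in self.seqs
        ]
        self._index: dict[bytes, list[tuple[int, int]]] = {}
        for ridx, s in enumerate(self.seqs):
            for pos in range(0, len(s) - seed_len + 1):
                self._index.setdefault(s[pos : pos + seed_len], []).append((ridx, pos))

    def candidate_positions(self, seq: bytes, max_mismatches: int):
        """Candidate (ref_idx, start) placements for an oriented read.

        Exhaustive whenever the read can be cut into ``max_mismatches + 1``
        disjoint seed-length segments; shorter reads fall back to scanning
        every position so the all-placements contract always holds.
        """
        n_seeds = max_mismatches + 1
        L = len(seq)
        step = L // n_seeds
        if step < self.seed_len:  # pigeonhole does not apply: full scan
            return {
                (ridx, start)
                for ridx, s in enumerate(self.seqs)
                for start in range(0, len(s) - L + 1)
            }
        cands: set[tuple[int, int]] = set()
        for i in range(n_seeds):
            off = i * step
            for ridx, pos in self._index.get(seq[off : off + self.seed_len], ()):
                start = pos - off
                if 0 <= start and start + L <= len(self.seqs[ridx]):
                    cands.add((ridx, start))
        return cands


_N = ord("N")


def _mismatches(ref_arr: np.ndarray, start: int, read_arr: np.ndarray) -> int:
    window = ref_arr[start : start + len(read_arr)]
    return int(np.count_nonzero((window != read_arr) | (read_arr == _N)))


def align_read(
    seq: str,
    index: ReferenceIndex,
    max_mismatches: int = 3,
    read_id: str = "read",
) -> list[Alignment]:
    """All ungapped end-to-end placements of ``seq`` with bounded mismatches.

    Both strands are searched; results are sorted by (ref_id, start, strand)
    for determinism. Placements running off a reference end are not reported.
    """
    out: list[Alignment] = []
    fwd = seq.upper().encode()
    for strand, oriented in (("+", fwd), ("-", revcomp(seq).upper().encode())):
        read_arr = np.frombuffer(oriented, dtype=np.uint8)
        for ridx, start in index.candidate_positions(oriented, max_mismatches):
            mm = _mismatches(index.arrays[ridx], start, read_arr)
            if mm <= max_mismatches:
                out.append(
                    Alignment(
                        ref_id=index.names[ridx],
                        start=start,
                        strand=strand,
                        mismatches=mm,
                        read_id=read_id,
                        ref_class=index.ref_class,
                    )
                )
    out.sort(key=lambda a: (a.ref_id, a.start, a.strand))
    return out


def filter_contaminants(
    pairs: Iterable[ReadPair],
    contaminant_refs: Mapping[str, str],
    max_mismatches: int = 3,
    seed_len: int = 12,
) -> tuple[list[ReadPair], int]:
    """Remove whole pairs with either mate placing on a contaminant sequence.

    Used for ribosomal RNA and adaptor screening; a single contaminated mate
    condemns the pair. Returns (kept pairs, removed count).
    """
    index = ReferenceIndex(contaminant_refs, seed_len=seed_len, ref_class="contaminant")
    kept, removed = [], 0
    for p in pairs:
        hit = any(
            align_read(seq, index, max_mismatches, read_id=rid)
            for rid, seq in p.mates()
        )
        if hit:
            removed += 1
        else:
            kept.append(p)
    return kept, removed


# ---------------------------------------------------------------------------
# Categorisation over genome + splice junctions
# ---------------------------------------------------------------------------

def _locus_key(
    aln: Alignment, junctions: Mapping[str, SpliceJunction], read_len: int
) -> tuple:
    """Collapse equivalent placements to one genomic locus.

    A placement entirely inside one flank of a splice-junction sequence is the
    same locus as the corresponding genomic placement; a boundary-spanning
    placement is keyed by the genomic identity of the splice boundary, shared
    by transcripts using the same intron.
    """
    if aln.ref_class == GENOME:
        return ("g", aln.ref_id, aln.start, aln.strand)
    sj = junctions[aln.ref_id]
    start, end = aln.start, aln.start + read_len
    if end <= sj.offset:  # entirely in donor flank -> genomic
        return ("g", sj.chrom) + _flank_genomic(sj, "donor", start, end, aln.strand)
    if start >= sj.offset:  # entirely in acceptor flank -> genomic
        return ("g", sj.chrom) + _flank_genomic(
            sj, "acceptor", start - sj.offset, end - sj.offset, aln.strand
        )
    return ("sj",) + sj.boundary_key + (start - sj.offset, aln.strand)


def _flank_genomic(
    sj: SpliceJunction, side: str, s: int, e: int, strand: str
) -> tuple:
    span = sj.donor_span if side == "donor" else sj.acceptor_span
    if sj.strand == "+":
        gstart = span[0] + s
        gstrand = strand
    else:  # sequence is revcomp of genomic
        gstart = span[1] - e
        gstrand = "-" if strand == "+" else "+"
    return (gstart, gstrand)


def categorize_reads(
    alignments_by_read: Mapping[str, list[Alignment]],
    junctions: Mapping[str, SpliceJunction],
    read_len: int = 50,
) -> dict[str, AlignmentCategory]:
    """Partition reads into unaligned / unique / multi by distinct locus count."""
    out: dict[str, AlignmentCategory] = {}
    for read_id, alns in alignments_by_read.items():
        loci = {_locus_key(a, junctions, read_len) for a in alns}
        if not loci:
            cat = "unaligned"
        elif len(loci) == 1:
            cat = "unique"
        else:
            cat = "multi"
        out[read_id] = AlignmentCategory(read_id, cat)
    return out


def assign_read_to_gene(
    aln: Alignment,
    model: GeneModel,
    junctions: Mapping[str, SpliceJunction],
    read_len: int = 50,
) -> str | None:
    """Gene carrying a uniquely placed read, or None when ambiguous.

    Genomic placements must intersect exons of exactly one gene; intronic or
    intergenic placements, and exons shared by two genes, assign nothing.
    Splice-junction placements inherit the junction's gene.
    """
    if aln.ref_class == SPLICE_JUNCTION:
        return junctions[aln.ref_id].gene_id
    gids = model.genes_with_exon_at(aln.ref_id, aln.start, aln.start + read_len)
    if len(gids) == 1:
        return gids[0]
    return None


# ---------------------------------------------------------------------------
# FASTQ / SAM I/O
# ---------------------------------------------------------------------------

def read_fastq_pairs(path1, path2) -> list[ReadPair]:
    """Read two synchronised FASTQ files into paired records.

    Pair ids are taken from mate-1 headers with a trailing /1 or /2 stripped.
    """
    from Bio import SeqIO

    recs1 = list(SeqIO.parse(str(path1), "fastq"))
    recs2 = list(SeqIO.parse(str(path2), "fastq"))
    if len(recs1) != len(recs2):
        raise ValueError(
            f"mate files differ in length: {len(recs1)} vs {len(recs2)}"
        )
    pairs = []
    for r1, r2 in zip(recs1, recs2):
        pid = r1.id.rsplit("/", 1)[0]
        pairs.append(
            ReadPair(
                pid,
                str(r1.seq).upper(),
                str(r2.seq).upper(),
                "".join(chr(q + 33) for q in r1.letter_annotations.get("phred_quality", [])) or None,
                "".join(chr(q + 33) for q in r2.letter_annotations.get("phred_quality", [])) or None,
            )
        )
    return pairs


def write_sam(
    alignments: Iterable[Alignment],
    ref_lengths: Mapping[str, int],
    read_seqs: Mapping[str, str],
    path,
    read_len: int = 50,
) -> None:
    """Export alignments as a minimal SAM file for inspection."""
    alns = sorted(alignments, key=lambda a: (a.ref_id, a.start, a.read_id))
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name in sorted(ref_lengths):
            fh.write(f"@SQ\tSN:{name}\tLN:{ref_lengths[name]}\n")
        for a in alns:
            seq = read_seqs.get(a.read_id, "*")
            flag = 16 if a.strand == "-" else 0
            if a.strand == "-" and seq != "*":
                seq = revcomp(seq)
            fh.write(
                f"{a.read_id}\t{flag}\t{a.ref_id}\t{a.start + 1}\t255\t"
                f"{len(seq) if seq != '*' else read_len}M\t*\t0\t0\t{seq}\t*\t"
                f"NM:i:{a.mismatches}\n"
            )
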