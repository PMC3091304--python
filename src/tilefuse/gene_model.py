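"""Gene annotation model: genes, transcripts, exons and the queries that drive
fusion-candidate filtering.

Internally every coordinate is 0-based half-open; GTF input/output is 1-based
inclusive. A :class:`GeneModel` indexes gene and exon spans per chromosome with
interval trees so that overlap/adjacency queries and read-to-gene assignment
stay O(log n).

The splice-junction reference built here is the "normal" transcriptome side of
the alignment step: for every pair of consecutive exons of a transcript, a
short sequence reading across the splice in transcript orientation. A read
spanning a normal exon-exon boundary aligns to one of these sequences even
though it has no contiguous genomic placement.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from intervaltree import IntervalTree

__all__ = [
    "Exon",
    "Transcript",
    "Gene",
    "GeneModel",
    "ParalogTable",
    "SpliceJunction",
    "AnnotationError",
    "load_annotation",
    "write_annotation",
    "load_genome",
    "load_paralogs",
    "genes_overlap",
    "genes_adjacent",
    "is_paralog_pair",
    "build_splice_junction_reference",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Raised for malformed or structurally inconsistent annotation."""


@dataclass(frozen=True)
class Exon:
    exon_id: str
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise AnnotationError(
                f"exon {self.exon_id}: start {self.start} >= end {self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Transcript:
    """A transcript with exons ordered 5'->3' in transcript orientation.

    ``cds_start``/``cds_end`` are *transcript-level* coordinates (offsets into
    the spliced sequence) of the coding region; ``None`` for non-coding
    transcripts. The CDS length need not be a multiple of three (an annotated
    stop may be excluded); frame logic only uses the phase relative to
    ``cds_start``.
    """

    transcript_id: str
    gene_id: str
    exons: list[Exon]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id} has no exons")
        strands = {e.strand for e in self.exons}
        if len(strands) != 1:
            raise AnnotationError(f"transcript {self.transcript_id}: mixed strands")
        if self.cds_start is not None and self.cds_end is not None:
            if not 0 <= self.cds_start < self.cds_end <= self.length:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: CDS "
                    f"[{self.cds_start},{self.cds_end}) outside transcript"
                )

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    def exon_offsets(self) -> list[int]:
        """Transcript coordinate of each exon's first base."""
        offs, pos = [], 0
        for e in self.exons:
            offs.append(pos)
            pos += len(e)
        return offs

    def exon_index(self, exon_id: str) -> int:
        for i, e in enumerate(self.exons):
            if e.exon_id == exon_id:
                return i
        raise KeyError(exon_id)

    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        parts = []
        for e in self.exons:
            s = genome[e.chrom][e.start : e.end]
            parts.append(s if e.strand == "+" else revcomp(s))
        return "".join(parts)


@dataclass
class Gene:
    gene_id: str
    name: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def exons(self) -> list[Exon]:
        """All distinct exons of the gene (by coordinates)."""
        seen: dict[tuple[int, int], Exon] = {}
        for t in self.transcripts:
            for e in t.exons:
                seen.setdefault((e.start, e.end), e)
        return sorted(seen.values(), key=lambda e: (e.start, e.end))

    def merged_exonic_length(self) -> int:
        """Length of the union of exonic intervals, in bp."""
        ivs = sorted((e.start, e.end) for e in self.exons)
        total, cur_s, cur_e = 0, None, None
        for s, e in ivs:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += cur_e - cur_s
        return total

    def merged_exonic_intervals(self) -> list[tuple[int, int]]:
        ivs = sorted((e.start, e.end) for e in self.exons)
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [(s, e) for s, e in merged]


class GeneModel:
    """Indexed collection of genes with positional lookup."""

    def __init__(self, genes: Iterable[Gene]):
        self.genes: dict[str, Gene] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise AnnotationError(f"duplicate gene_id {g.gene_id}")
            self.genes[g.gene_id] = g
        self._gene_trees: dict[str, IntervalTree] = {}
        self._exon_trees: dict[str, IntervalTree] = {}
        for g in self.genes.values():
            self._gene_trees.setdefault(g.chrom, IntervalTree()).addi(
                g.start, g.end, g.gene_id
            )
            for e in g.exons:
                self._exon_trees.setdefault(e.chrom, IntervalTree()).addi(
                    e.start, e.end, g.gene_id
                )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> Gene:
        return self.genes[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def genes_at(self, chrom: str, start: int, end: int | None = None) -> list[Gene]:
        """Genes whose span intersects [start, end) (point query if end omitted)."""
        tree = self._gene_trees.get(chrom)
        if tree is None:
            return []
        hits = tree[start] if end is None else tree[start:end]
        return sorted((self.genes[iv.data] for iv in hits), key=lambda g: g.gene_id)

    def genes_with_exon_at(self, chrom: str, start: int, end: int) -> list[str]:
        """gene_ids with >=1 exon intersecting [start, end)."""
        tree = self._exon_trees.get(chrom)
        if tree is None:
            return []
        return sorted({iv.data for iv in tree[start:end]})

    def transcripts(self) -> Iterator[Transcript]:
        for g in self:
            yield from g.transcripts


class ParalogTable:
    """Symmetric set of unordered gene-id pairs related by duplication."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()):
        self._pairs: set[frozenset[str]] = set()
        for a, b in pairs:
            self.add(a, b)

    def add(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError(f"self-paralog pair {a}")
        self._pairs.add(frozenset((a, b)))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return frozenset(pair) in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)

    def pairs(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(p)) for p in self._pairs)


# ---------------------------------------------------------------------------
# Queries driving candidate filtering
# ---------------------------------------------------------------------------

def genes_overlap(a: Gene, b: Gene) -> bool:
    """True iff the genomic spans intersect (strand ignored)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def genes_adjacent(a: Gene, b: Gene, model: GeneModel) -> bool:
    """True iff no third gene lies entirely inside the gap between a and b.

    Two genes on the same chromosome are "adjacent" — and a chimera between
    them is treated as likely transcriptional readthrough — unless some other
    gene, of any biotype, has both its start and end strictly inside the gap.
    Genes only partially overlapping the gap do not separate. Different
    chromosomes are never adjacent; overlapping genes are trivially adjacent.
    """
    if a.chrom != b.chrom:
        return False
    if genes_overlap(a, b):
        return True
    gap_start = min(a.end, b.end)
    gap_end = max(a.start, b.start)
    for g in model.genes_at(a.chrom, gap_start, gap_end):
        if g.gene_id in (a.gene_id, b.gene_id):
            continue
        if g.start > gap_start and g.end < gap_end:
            return False
    return True


def is_paralog_pair(a: Gene, b: Gene, table: ParalogTable) -> bool:
    return (a.gene_id, b.gene_id) in table


# ---------------------------------------------------------------------------
# Splice-junction reference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpliceJunction:
    """One normal exon-exon junction sequence in transcript orientation.

    ``offset`` bases come from the 3' end of the upstream exon; the rest from
    the 5' start of the downstream exon. ``donor_span``/``acceptor_span`` are
    the genomic (chrom, start, end) footprints of the two halves, used to
    collapse a junction placement with its equivalent genomic placement when
    counting loci.
    """

    name: str
    transcript_id: str
    gene_id: str
    up_exon: str
    down_exon: str
    seq: str
    offset: int
    strand: str
    chrom: str
    donor_span: tuple[int, int]
    acceptor_span: tuple[int, int]

    @property
    def boundary_key(self) -> tuple:
        """Genomic identity of the splice boundary (shared across transcripts)."""
        if self.strand == "+":
            return (self.chrom, self.donor_span[1], self.acceptor_span[0])
        return (self.chrom, self.donor_span[0], self.acceptor_span[1])


def build_splice_junction_reference(
    model: GeneModel, genome: Mapping[str, str], flank: int = 49
) -> list[SpliceJunction]:
    """All consecutive exon-exon junction sequences, one per transcript pair.

    Each sequence is up to ``flank`` bases of upstream-exon 3' end followed by
    up to ``flank`` bases of downstream-exon 5' start, reverse-complemented as
    needed so the string reads in transcript orientation. Exons shorter than
    ``flank`` contribute their full length. Single-exon transcripts yield
    nothing. A flank of read_length - 1 guarantees every junction-spanning
    read placement is representable.
    """
    out: list[SpliceJunction] = []
    for t in model.transcripts():
        for up, dn in itertools.pairwise(t.exons):
            f_up = min(flank, len(up))
            f_dn = min(flank, len(dn))
            if t.strand == "+":
                donor = (up.end - f_up, up.end)
                acceptor = (dn.start, dn.start + f_dn)
                seq = (
                    genome[t.chrom][donor[0] : donor[1]]
                    + genome[t.chrom][acceptor[0] : acceptor[1]]
                )
            else:
                donor = (up.start, up.start + f_up)
                acceptor = (dn.end - f_dn, dn.end)
                seq = revcomp(genome[t.chrom][donor[0] : donor[1]]) + revcomp(
                    genome[t.chrom][acceptor[0] : acceptor[1]]
                )
            name = f"SJ|{t.transcript_id}|{up.exon_id}|{dn.exon_id}|{f_up}"
            out.append(
                SpliceJunction(
                    name=name,
                    transcript_id=t.transcript_id,
                    gene_id=t.gene_id,
                    up_exon=up.exon_id,
                    down_exon=dn.exon_id,
                    seq=seq,
                    offset=f_up,
                    strand=t.strand,
                    chrom=t.chrom,
                    donor_span=donor,
                    acceptor_span=acceptor,
                )
            )
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_attributes(field9: str) -> dict[str, str]:
    attrs = {}
    for part in field9.strip().rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        attrs[key] = val.strip().strip('"')
    return attrs


def load_annotation(gtf_path) -> GeneModel:
    """Parse a GTF file into a :class:`GeneModel`.

    Expects gene/transcript/exon (and optional CDS) feature lines with 1-based
    inclusive coordinates; internal coordinates become 0-based half-open.
    Transcript-level CDS boundaries are reconstructed from the genomic CDS
    chunks. Malformed lines raise :class:`AnnotationError` naming the line.
    """
    gene_rows: dict[str, dict] = {}
    tx_rows: dict[str, dict] = {}
    exon_rows: list[dict] = []
    cds_rows: list[dict] = []

    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{gtf_path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, frame, attr9 = fields
            try:
                start0, end1 = int(start) - 1, int(end)
            except ValueError:
                raise AnnotationError(
                    f"{gtf_path}: line {lineno}: non-integer coordinates"
                ) from None
            if strand not in "+-":
                raise AnnotationError(f"{gtf_path}: line {lineno}: bad strand {strand!r}")
            attrs = _parse_attributes(attr9)
            row = dict(
                chrom=chrom, start=start0, end=end1, strand=strand,
                attrs=attrs, lineno=lineno,
            )
            if feature == "gene":
                gene_rows[attrs["gene_id"]] = row
            elif feature == "transcript":
                tx_rows[attrs["transcript_id"]] = row
            elif feature == "exon":
                exon_rows.append(row)
            elif feature == "CDS":
                cds_rows.append(row)
            # other feature types are ignored

    # assemble transcripts
    tx_exons: dict[str, list[Exon]] = {}
    for row in exon_rows:
        tid = row["attrs"].get("transcript_id")
        if tid is None or tid not in tx_rows:
            raise AnnotationError(
                f"{gtf_path}: line {row['lineno']}: exon without parent transcript"
            )
        exon_id = row["attrs"].get(
            "exon_id", f"{tid}.e{len(tx_exons.get(tid, [])) + 1}"
        )
        tx_exons.setdefault(tid, []).append(
            Exon(exon_id, row["chrom"], row["start"], row["end"], row["strand"])
        )

    tx_cds: dict[str, list[tuple[int, int]]] = {}
    for row in cds_rows:
        tid = row["attrs"].get("transcript_id")
        if tid is None or tid not in tx_rows:
            raise AnnotationError(
                f"{gtf_path}: line {row['lineno']}: CDS without parent transcript"
            )
        tx_cds.setdefault(tid, []).append((row["start"], row["end"]))

    genes: dict[str, Gene] = {}
    for gid, row in gene_rows.items():
        genes[gid] = Gene(
            gene_id=gid,
            name=row["attrs"].get("gene_name", gid),
            chrom=row["chrom"],
            start=row["start"],
            end=row["end"],
            strand=row["strand"],
            biotype=row["attrs"].get("gene_biotype", "protein_coding"),
        )

    for tid, row in tx_rows.items():
        gid = row["attrs"].get("gene_id")
        if gid not in genes:
            raise AnnotationError(
                f"{gtf_path}: line {row['lineno']}: transcript without parent gene"
            )
        exons = tx_exons.get(tid)
        if not exons:
            raise AnnotationError(f"{gtf_path}: transcript {tid} has no exons")
        exons.sort(key=lambda e: e.start, reverse=(row["strand"] == "-"))
        t = Transcript(tid, gid, exons)
        if tid in tx_cds:
            t.cds_start, t.cds_end = _cds_to_transcript_coords(t, tx_cds[tid])
            t.__post_init__()  # re-validate with CDS set
        genes[gid].transcripts.append(t)

    return GeneModel(genes.values())


def _cds_to_transcript_coords(
    t: Transcript, cds_chunks: list[tuple[int, int]]
) -> tuple[int, int]:
    """Transcript-level [cds_start, cds_end) from genomic CDS intervals."""
    gmin = min(s for s, _ in cds_chunks)
    gmax = max(e for _, e in cds_chunks)
    # genomic first/last CDS base -> transcript coordinate
    first_g = gmin if t.strand == "+" else gmax - 1
    last_g = gmax - 1 if t.strand == "+" else gmin
    return _genomic_to_transcript(t, first_g), _genomic_to_transcript(t, last_g) + 1


def _genomic_to_transcript(t: Transcript, gpos: int) -> int:
    off = 0
    for e in t.exons:
        if e.start <= gpos < e.end:
            return off + (gpos - e.start if t.strand == "+" else e.end - 1 - gpos)
        off += len(e)
    raise AnnotationError(
        f"genomic position {gpos} not exonic in transcript {t.transcript_id}"
    )


def transcript_to_genomic(t: Transcript, tpos: int) -> int:
    """Genomic coordinate of transcript position ``tpos`` (0-based)."""
    off = 0
    for e in t.exons:
        if off <= tpos < off + len(e):
            d = tpos - off
            return e.start + d if t.strand == "+" else e.end - 1 - d
        off += len(e)
    raise IndexError(tpos)


def write_annotation(model: GeneModel, gtf_path) -> None:
    """Write a GeneModel back to GTF (1-based inclusive), round-trip safe."""
    with open(gtf_path, "w") as fh:
        for g in sorted(model, key=lambda g: (g.chrom, g.start, g.gene_id)):
            attrs = (
                f'gene_id "{g.gene_id}"; gene_name "{g.name}"; '
                f'gene_biotype "{g.biotype}";'
            )
            fh.write(
                f"{g.chrom}\ttilefuse\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for t in g.transcripts:
                tmin = min(e.start for e in t.exons)
                tmax = max(e.end for e in t.exons)
                tattrs = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{g.chrom}\ttilefuse\ttranscript\t{tmin + 1}\t{tmax}\t.\t"
                    f"{t.strand}\t.\t{tattrs}\n"
                )
                for e in t.exons:
                    fh.write(
                        f"{e.chrom}\ttilefuse\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{e.strand}\t.\t{tattrs} exon_id \"{e.exon_id}\";\n"
                    )
                if t.is_coding:
                    for gs, ge in _cds_genomic_chunks(t):
                        fh.write(
                            f"{e.chrom}\ttilefuse\tCDS\t{gs + 1}\t{ge}\t.\t"
                            f"{t.strand}\t.\t{tattrs}\n"
                        )


def _cds_genomic_chunks(t: Transcript) -> list[tuple[int, int]]:
    """Genomic intervals covered by the transcript-level CDS."""
    chunks: list[tuple[int, int]] = []
    off = 0
    for e in t.exons:
        lo = max(t.cds_start, off)
        hi = min(t.cds_end, off + len(e))
        if lo < hi:
            if t.strand == "+":
                chunks.append((e.start + (lo - off), e.start + (hi - off)))
            else:
                chunks.append((e.end - (hi - off), e.end - (lo - off)))
        off += len(e)
    return sorted(chunks)


def load_genome(fasta_path) -> dict[str, str]:
    """Load a (small) genome FASTA into a chrom -> sequence dict."""
    import pyfaidx

    fa = pyfaidx.Fasta(str(fasta_path))
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def load_paralogs(tsv_path) -> ParalogTable:
    """Two-column TSV of paralogous gene_id pairs; '#' comments allowed."""
    table = ParalogTable()
    with open(tsv_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise AnnotationError(
                    f"{tsv_path}: line {lineno}: expected two gene ids"
                )
            table.add(parts[0], parts[1])
    return table
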