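"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they verify: the aligner oracle is a
dense sliding-window Hamming scan, and the frame oracle literally translates
the fused transcript and looks for the acceptor protein in the product.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

from tilefuse.gene_model import Transcript, revcomp


def bruteforce_align(
    seq: str, references: dict[str, str], max_mismatches: int
) -> list[tuple[str, int, str, int]]:
    """Every (ref, start, strand, mismatches) placement by exhaustive scan."""
    out = []
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        arr = np.frombuffer(oriented.upper().encode(), dtype=np.uint8)
        L = len(arr)
        for name, ref in references.items():
            r = np.frombuffer(ref.upper().encode(), dtype=np.uint8)
            if len(r) < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(r, L)
            mm = ((windows != arr) | (arr == ord("N"))).sum(axis=1)
            for p in np.nonzero(mm <= max_mismatches)[0]:
                out.append((name, int(p), strand, int(mm[p])))
    return sorted(out)


def translation_in_frame(
    t5: Transcript,
    five_exon_coords: tuple[int, int],
    t3: Transcript,
    three_exon_coords: tuple[int, int],
    genome: dict[str, str],
    min_tag: int = 8,
) -> bool:
    """Translate-and-check frame oracle for junctions inside both CDSs.

    Builds the fused transcript, translates it from the donor's annotated
    start codon, and declares the fusion in-frame iff a tag of the acceptor's
    wild-type protein (downstream of the junction) appears in the product.
    """
    five_tx = t5.spliced_sequence(genome)
    three_tx = t3.spliced_sequence(genome)
    off5 = 0
    for e in t5.exons:
        off5 += len(e)
        if (e.start, e.end) == five_exon_coords:
            break
    else:
        raise ValueError("five exon not in transcript")
    off3 = 0
    for e in t3.exons:
        if (e.start, e.end) == three_exon_coords:
            break
        off3 += len(e)
    else:
        raise ValueError("three exon not in transcript")
    fused = five_tx[:off5] + three_tx[off3:]
    coding = fused[t5.cds_start :]
    coding = coding[: 3 * (len(coding) // 3)]
    product = str(Seq(coding).translate())
    acceptor_cds = three_tx[t3.cds_start : t3.cds_end]
    acceptor_protein = str(
        Seq(acceptor_cds[: 3 * (len(acceptor_cds) // 3)]).translate()
    )
    # first acceptor codon fully downstream of the junction
    o = off3 - t3.cds_start
    first_codon = -(-o // 3) + 1
    tag = acceptor_protein[first_codon : first_codon + min_tag]
    if len(tag) < min_tag:
        raise ValueError("acceptor CDS too short for a protein tag")
    return tag in product
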