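from __future__ import annotations

import numpy as np
import pytest

from tilefuse.discovery import DetectionParams
from tilefuse.gene_model import Exon, Gene, GeneModel, Transcript
from tilefuse.pipeline import RunConfig, run_detection
from tilefuse.simulate import flagship_config, generate_universe, write_universe

FLAGSHIP_SEED = 7


def make_gene(
    gene_id: str,
    chrom: str,
    exon_spans: list[tuple[int, int]],
    strand: str = "+",
    cds: tuple[int, int] | None = None,
    biotype: str = "protein_coding",
) -> Gene:
    """A single-transcript gene from genomic exon spans (given in genomic order)."""
    spans = sorted(exon_spans)
    if strand == "-":
        spans = spans[::-1]
    tid = f"{gene_id}.t1"
    exons = [Exon(f"{tid}.e{i + 1}", chrom, s, e, strand) for i, (s, e) in enumerate(spans)]
    t = Transcript(tid, gene_id, exons, *(cds or (None, None)))
    return Gene(
        gene_id, gene_id, chrom,
        min(s for s, _ in exon_spans), max(e for _, e in exon_spans),
        strand, biotype, [t],
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def flagship_universe():
    return generate_universe(flagship_config(seed=FLAGSHIP_SEED))


@pytest.fixture(scope="session")
def flagship_run(tmp_path_factory, flagship_universe):
    """Universe files + a full detection run over them (shared, read-only)."""
    outdir = tmp_path_factory.mktemp("flagship")
    paths = write_universe(flagship_universe, outdir / "sim")
    result = run_detection(
        RunConfig(
            reads1=paths["reads1"],
            reads2=paths["reads2"],
            gtf=paths["annotation"],
            genome=paths["genome"],
            contaminants=paths["contaminants"],
            paralogs=paths["paralogs"],
            cn_profile=paths["cn_profile"],
            out_dir=str(outdir / "out"),
            sample="synthetic",
            params=DetectionParams(),
            seed=FLAGSHIP_SEED,
        )
    )
    return flagship_universe, paths, result
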