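import numpy as np
import pytest

from conftest import make_gene
from tilefuse.discovery import DetectionParams, FusionCandidate
from tilefuse.gene_model import GeneModel, revcomp
from tilefuse.junctions import (
    ARTIFACT,
    GENUINE,
    FusionCall,
    JunctionHit,
    align_unmapped_to_junctions,
    enumerate_fusion_junctions,
    prioritize_calls,
    tiling_classify,
)


def make_hit(start, read_len=50, junction="J", mm=0):
    return JunctionHit(
        read_id=f"r{start}",
        junction=junction,
        start_offset=start,
        overhang_5=-start,
        overhang_3=read_len + start,
        mismatches=mm,
        strand="+",
    )


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestEnumerate:
    def test_two_by_two_exons_give_eight_sequences(self, rng):
        genome = {"chr1": random_dna(rng, 3_000), "chr2": random_dna(rng, 3_000)}
        a = make_gene("A", "chr1", [(100, 300), (600, 800)])
        b = make_gene("B", "chr2", [(100, 300), (600, 800)])
        model = GeneModel([a, b])
        fjs = enumerate_fusion_junctions(FusionCandidate("A", "B"), model, genome)
        assert len(fjs) == 8  # 2 exons x 2 exons x 2 orientations, all distinct
        assert {fj.five_gene for fj in fjs} == {"A", "B"}

    def test_minus_strand_donor_fragment_is_reverse_complement(self):
        genome = {"chr1": "ACGTACGTTTGCAGCATGCATTCCGGAATTAC"}
        a = make_gene("A", "chr1", [(0, 10), (14, 24)], strand="-")
        b = make_gene("B", "chr1", [(26, 32)])
        model = GeneModel([a, b])
        fjs = enumerate_fusion_junctions(
            FusionCandidate("A", "B"), model, genome, flank=10
        )
        # A minus strand: transcript-level 3' end of genomic exon (0,10) is
        # the reverse complement of its left edge
        by_pair = {
            (fj.five_gene, fj.five_exon, fj.three_exon): fj.seq for fj in fjs
        }
        seq = by_pair[("A", "A.t1.e2", "B.t1.e1")]
        assert seq == revcomp(genome["chr1"][0:10]) + genome["chr1"][26:32]

    def test_coordinate_identical_exons_deduplicated(self, rng):
        genome = {"chr1": random_dna(rng, 2_000)}
        a = make_gene("A", "chr1", [(100, 200)])
        # second transcript with the same exon coordinates
        from tilefuse.gene_model import Exon, Transcript

        a.transcripts.append(
            Transcript("A.t2", "A", [Exon("A.t2.e1", "chr1", 100, 200, "+")])
        )
        b = make_gene("B", "chr1", [(900, 1_000)])
        model = GeneModel([a, b])
        fjs = enumerate_fusion_junctions(FusionCandidate("A", "B"), model, genome)
        assert len(fjs) == 2  # A->B and B->A only

    def test_gene_without_exons_is_structural_error(self, rng):
        genome = {"chr1": random_dna(rng, 500)}
        a = make_gene("A", "chr1", [(0, 100)])
        a.transcripts.clear()
        b = make_gene("B", "chr1", [(300, 400)])
        model = GeneModel([a, b])
        with pytest.raises(ValueError, match="without exons"):
            enumerate_fusion_junctions(FusionCandidate("A", "B"), model, genome)


class TestJunctionAlignment:
    @pytest.fixture()
    def junction_db(self, rng):
        genome = {"chr1": random_dna(rng, 2_000), "chr2": random_dna(rng, 2_000)}
        a = make_gene("A", "chr1", [(100, 400), (700, 1_000)])
        b = make_gene("B", "chr2", [(200, 500), (800, 1_100)])
        model = GeneModel([a, b])
        fjs = enumerate_fusion_junctions(FusionCandidate("A", "B"), model, genome)
        return genome, fjs

    @pytest.mark.parametrize("o5,expect_hit", [(25, True), (9, False), (41, False)])
    def test_anchor_threshold(self, junction_db, o5, expect_hit):
        genome, fjs = junction_db
        fj = next(f for f in fjs if f.five_gene == "A")
        read = fj.seq[fj.junction_offset - o5 : fj.junction_offset - o5 + 50]
        hits = align_unmapped_to_junctions([("r", read)], fjs, DetectionParams())
        spanning = [h for h in hits if h.junction == fj.name]
        if expect_hit:
            assert len(spanning) == 1
            assert (spanning[0].overhang_5, spanning[0].overhang_3) == (o5, 50 - o5)
            assert spanning[0].start_offset == -o5
        else:
            assert spanning == []

    def test_read_inside_one_exon_not_spanning(self, junction_db):
        genome, fjs = junction_db
        fj = next(f for f in fjs if f.five_gene == "A")
        read = genome["chr1"][300:350]  # matches the donor exon genomically
        hits = align_unmapped_to_junctions([("r", read)], fjs, DetectionParams())
        assert hits == []

    def test_overhang_conservation(self, flagship_run):
        _, _, result = flagship_run
        for call in result.calls:
            for h in call.hits:
                assert h.overhang_5 + h.overhang_3 == 50
                assert min(h.overhang_5, h.overhang_3) >= 10


class TestTilingClassifier:
    def test_staggered_starts_are_genuine(self):
        hits = [make_hit(s) for s in (-25, -20, -15, -12, -5)]
        cls, distinct, detail = tiling_classify(hits, DetectionParams())
        assert (cls, distinct) == (GENUINE, 5)
        assert detail["start_span"] == 20

    def test_stacked_starts_are_artifact(self):
        hits = [make_hit(s) for s in (-40, -40, -41, -39, -40, -40)]
        # overhangs for these starts are still two-sided (read length 50)
        cls, distinct, _ = tiling_classify(hits, DetectionParams())
        assert cls == ARTIFACT
        assert distinct == 3  # span 2 triggers the artifact rule regardless

    def test_too_few_distinct_starts_is_artifact(self):
        hits = [make_hit(-30), make_hit(-10)]
        cls, distinct, detail = tiling_classify(hits, DetectionParams())
        assert (cls, distinct) == (ARTIFACT, 2)
        assert detail["too_few_starts"]

    def test_empty_hit_list_rejected(self):
        with pytest.raises(ValueError):
            tiling_classify([], DetectionParams())

    def test_stacked_replicates_always_artifact(self):
        """Artifact stacks (one start +/-1 bp) are never called genuine."""
        params = DetectionParams()
        rng = np.random.default_rng(0)
        for _ in range(100):
            base = -int(rng.integers(12, 38))
            starts = base + rng.integers(-1, 2, size=8)
            cls, _, _ = tiling_classify([make_hit(int(s)) for s in starts], params)
            assert cls == ARTIFACT

    def test_tiled_replicates_nearly_always_genuine(self):
        params = DetectionParams()
        rng = np.random.default_rng(1)
        genuine = 0
        n = 200
        for _ in range(n):
            starts = -rng.integers(10, 41, size=5)
            cls, _, _ = tiling_classify([make_hit(int(s)) for s in starts], params)
            genuine += cls == GENUINE
        assert genuine / n >= 0.99


class TestCallsAndPriority:
    def test_single_spanning_read_is_no_call(self, rng):
        from tilefuse.junctions import call_junctions, FusionJunctionSeq

        fj = FusionJunctionSeq("A", "B", "e1", "e2", random_dna(rng, 98), 49)
        hits = [make_hit(-25, junction=fj.name)]
        calls = call_junctions(FusionCandidate("A", "B"), hits, [fj], DetectionParams())
        assert calls == []

    def test_planted_fusions_called_with_orientation(self, flagship_run):
        universe, _, result = flagship_run
        genuine = {
            (c.five_gene, c.three_gene, c.five_exon, c.three_exon)
            for c in result.calls
            if c.tiling_class == GENUINE
        }
        expected = {
            (r.five_gene, r.three_gene, r.five_exon, r.three_exon)
            for r in universe.truth
            if r.event_type == "fusion"
        }
        assert genuine == expected

    def test_priority_order(self):
        def call(five, distinct, n_reads, n_pairs, cls):
            return FusionCall(five, "Z", "e", "e", n_pairs, n_reads, [],
                              tiling_class=cls, distinct_starts=distinct)

        a = call("A", 7, 3, 2, GENUINE)
        b = call("B", 3, 9, 9, GENUINE)
        c = call("C", 12, 99, 99, ARTIFACT)
        d = call("A0", 3, 9, 9, GENUINE)  # ties with b except gene id
        ordered = prioritize_calls([c, b, a, d])
        assert ordered == [a, d, b, c]
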