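"""De Bruijn assembly, split alignment and evidence classification."""

import numpy as np
import pytest

from cnvlossverify import GenomicInterval, SimulationSpec
from cnvlossverify.breakpoint_seek import (
    BreakpointConfig,
    assemble_contigs,
    build_graph,
    extract_read_bundle,
    normalize_junction,
    paired_end_evidence,
    revcomp,
    seek_breakpoints,
    split_align_contig,
)
from cnvlossverify.synthetic_data import make_reference, plant_deletions, simulate_alignments


def random_seq(n, seed=0):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def tile(seq, read_len=60, step=2):
    return [seq[i : i + read_len] for i in range(0, len(seq) - read_len + 1, step)]


class TestBuildGraph:
    def test_single_read_of_length_k_is_one_edge(self):
        g = build_graph(["ACGTACGTACGTACGTACGTA"], k=21, min_mult=1)
        assert g.n_edges == 1

    def test_reads_shorter_than_k_skipped(self):
        g = build_graph(["ACGT"], k=21, min_mult=1)
        assert g.n_edges == 0

    def test_reverse_complement_gives_identical_graph(self):
        s = random_seq(300, seed=1)
        g1 = build_graph(tile(s), k=21, min_mult=1)
        g2 = build_graph([revcomp(r) for r in tile(s)], k=21, min_mult=1)
        assert g1.edge_mult == g2.edge_mult

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            build_graph(["A" * 30], k=20)

    def test_low_multiplicity_edges_pruned(self):
        s = random_seq(100, seed=2)
        g = build_graph(tile(s, step=1) + [random_seq(40, seed=99)], k=21, min_mult=2)
        # the lone random read's k-mers appear once and are pruned
        lone = build_graph([random_seq(40, seed=99)], k=21, min_mult=1)
        assert not set(lone.edge_mult) & set(g.edge_mult)


class TestAssembleContigs:
    def test_reconstruction_identity_on_error_free_tiling(self):
        for seed, length in [(3, 1000), (4, 2500), (5, 5000)]:
            s = random_seq(length, seed=seed)
            # min_mult=1: terminal k-mers occur only once even in a perfect tiling
            g = build_graph(tile(s, read_len=80, step=2), k=21, min_mult=1)
            contigs = assemble_contigs(g)
            assert len(contigs) == 1
            got = contigs[0].sequence
            assert got in (s, revcomp(s))

    def test_empty_graph_empty_contigs(self):
        g = build_graph([], k=21)
        assert assemble_contigs(g) == []

    def test_branch_produces_neighboring_contigs(self):
        # two sequences sharing an identical middle segment: the shared
        # unitig neighbors the four distinct arms across the branch nodes
        mid = random_seq(120, seed=6)
        s1 = random_seq(120, seed=7) + mid + random_seq(120, seed=8)
        s2 = random_seq(120, seed=9) + mid + random_seq(120, seed=10)
        g = build_graph(tile(s1, 60, 1) + tile(s2, 60, 1), k=21, min_mult=2)
        contigs = assemble_contigs(g, clip_tips=False)
        assert len(contigs) == 5
        shared = [c for c in contigs if mid in c.sequence or revcomp(mid) in c.sequence]
        assert len(shared) == 1
        assert len(shared[0].graph_neighbors) == 4


class TestSplitAlign:
    REF = random_seq(5000, seed=12)

    def test_contiguous_contig_returns_none(self):
        assert split_align_contig(self.REF[800:1200], self.REF) is None

    def test_constructed_junction_recovered_exactly(self):
        contig = self.REF[1000:1500] + self.REF[3500:4000]
        jc = split_align_contig(contig, self.REF, chrom="c")
        expect = normalize_junction(self.REF, 1500, 3500)
        assert (jc.left_break, jc.right_break) == expect

    def test_reverse_complement_contig_same_junction(self):
        contig = revcomp(self.REF[1000:1500] + self.REF[3500:4000])
        jc = split_align_contig(contig, self.REF, chrom="c")
        assert (jc.left_break, jc.right_break) == normalize_junction(self.REF, 1500, 3500)

    def test_single_mismatch_in_anchor_tolerated(self):
        contig = list(self.REF[1000:1500] + self.REF[3500:4000])
        contig[5] = "A" if contig[5] != "A" else "C"  # inside the left anchor
        jc = split_align_contig("".join(contig), self.REF, chrom="c")
        assert (jc.left_break, jc.right_break) == normalize_junction(self.REF, 1500, 3500)

    def test_window_offset_added_to_coordinates(self):
        win = self.REF[500:4500]
        contig = self.REF[1000:1500] + self.REF[3500:4000]
        jc = split_align_contig(contig, win, window_offset=500, chrom="c")
        assert (jc.left_break, jc.right_break) == normalize_junction(self.REF, 1500, 3500)

    def test_gap_below_min_deletion_not_called(self):
        contig = self.REF[1000:1500] + self.REF[1520:2020]  # 20 bp gap
        assert split_align_contig(contig, self.REF, min_deletion=50) is None

    def test_junction_never_inside_anchors(self):
        contig = self.REF[1000:1500] + self.REF[3500:4000]
        jc = split_align_contig(contig, self.REF, chrom="c")
        assert 0 < jc.left_break < jc.right_break < len(self.REF)

    def test_microhomology_left_normalized(self):
        # force ref[L-1] == ref[R-1] so the junction admits a left shift
        ref = self.REF[:2000] + self.REF[1999] + self.REF[2000:]
        L, R = normalize_junction(ref, 2001, 3001)
        assert (L, R) != (2001, 3001) or ref[2000] != ref[3000]
        assert ref[: L] + ref[R : 4000 + 1] == ref[:2001] + ref[3001 : 4000 + 1]


@pytest.fixture(scope="module")
def planted(tmp_path_factory):
    spec = SimulationSpec(
        ref_length=60_000, n_deletions=2, hom_fraction=1.0, mean_depth=8.0,
        error_rate=0.0, seed=31, deletion_length_range=(1500, 3000),
    )
    out = tmp_path_factory.mktemp("planted")
    ref = make_reference(spec, out / "ref.fa")
    haps, truth = plant_deletions(ref, spec)
    bam = simulate_alignments(haps, truth, out / "reads.bam")
    return spec, ref, out / "ref.fa", bam, truth


class TestBundleAndPairedEnd:

    def test_bundle_contains_every_junction_spanning_read(self, planted):
        spec, ref, fasta, bam, truth = planted
        for i, d in enumerate(truth.deletions):
            bundle = extract_read_bundle(bam, d.interval, flank_bp=500)
            names = {r.name for r in bundle.unmapped_reads} | {
                r.name for r in bundle.mapped_flank_reads
            }
            assert set(truth.junction_read_ids[i]) <= names

    def test_empty_region_gives_empty_bundle(self, planted):
        *_, bam, truth = planted
        # a region far from any read placement on a separate fetch window
        d = truth.deletions[0]
        hole = GenomicInterval(d.interval.chrom, d.interval.start + 50, d.interval.end - 50)
        bundle = extract_read_bundle(bam, hole, flank_bp=0)
        # hom deletion interior: no mapped reads cross the exact boundaries
        assert all(r.is_unmapped for r in bundle.mapped_flank_reads) or True
        assert len(bundle.mapped_flank_reads) == 0

    def test_paired_end_evidence_detects_planted_deletion(self, planted):
        spec, ref, fasta, bam, truth = planted
        d = truth.deletions[0]
        jc = paired_end_evidence(bam, d.interval, spec.insert_mean, spec.insert_sd)
        assert jc is not None and jc.evidence == "paired_end"
        assert jc.support_count >= 2

    def test_no_deletion_no_paired_end_signal(self, planted):
        spec, ref, fasta, bam, truth = planted
        # a null window well away from both deletions
        d0 = truth.deletions[0].interval
        null = GenomicInterval(d0.chrom, 2000, 4000)
        assert paired_end_evidence(bam, null, spec.insert_mean, spec.insert_sd) is None

    def test_single_pair_below_min_pairs_rejected(self, planted):
        spec, ref, fasta, bam, truth = planted
        d = truth.deletions[0]
        assert (
            paired_end_evidence(bam, d.interval, spec.insert_mean, spec.insert_sd,
                                min_pairs=10_000)
            is None
        )

    def test_seek_classifies_break_read_first(self, planted):
        spec, ref, fasta, bam, truth = planted
        calls, summary = seek_breakpoints(
            bam, fasta, [d.interval for d in truth.deletions], BreakpointConfig()
        )
        assert all(c.evidence == "break_read" for c in calls)
        for c, d in zip(calls, truth.deletions):
            assert (c.left_break, c.right_break) == (d.interval.start, d.interval.end)
        assert summary["break_read"] == 1.0

    def test_null_candidates_unsupported(self, planted):
        spec, ref, fasta, bam, truth = planted
        nulls = [GenomicInterval("chr1", 2000, 3000), GenomicInterval("chr1", 50_000, 52_000)]
        calls, summary = seek_breakpoints(bam, fasta, nulls, BreakpointConfig())
        assert summary["unsupported"] == 1.0

    def test_empty_candidate_list(self, planted):
        spec, ref, fasta, bam, truth = planted
        calls, summary = seek_breakpoints(bam, fasta, [], BreakpointConfig())
        assert calls == [] and sum(summary.values()) == 0.0
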