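"""Directional 50% overlap matching, filters, tables and overlap statistics.

The brute-force oracle used throughout is a quadratic scan over all call
pairs with plain max/min interval arithmetic — independent of the indexed
implementation.
"""

import numpy as np
import pytest

from cnvlossverify import (
    Callset,
    CNVCall,
    GenomicInterval,
    ProbeMap,
    concordance_table,
    gene_region_filter,
    matches,
    overlap_bp,
    overlap_length_stats,
    probe_count_filter,
)
from cnvlossverify.concordance import ConcordanceRow


def mk(chrom, start, end, sample="S1", source="x"):
    return CNVCall(GenomicInterval(chrom, start, end), sample, source)


def brute_matched(a, B, threshold=0.5):
    """Oracle: single-partner directional rule by exhaustive pair scan."""
    for b in B.calls:
        if b.interval.chrom != a.interval.chrom:
            continue
        if a.sample_id != "*" and b.sample_id != "*" and b.sample_id != a.sample_id:
            continue
        ov = max(
            0,
            min(a.interval.end, b.interval.end) - max(a.interval.start, b.interval.start),
        )
        if ov >= threshold * a.interval.length:
            return True
    return False


def random_callset(rng, n, source, samples=("S1", "S2"), span=100_000):
    calls = []
    for _ in range(n):
        s = int(rng.integers(0, span - 10))
        ln = int(rng.integers(10, 5000))
        calls.append(
            mk("chr1", s, min(span, s + ln), sample=str(rng.choice(samples)), source=source)
        )
    return Callset(source, calls)


class TestOverlapBp:
    def test_partial_disjoint_and_nested(self):
        a = GenomicInterval("chr1", 0, 100)
        assert overlap_bp(a, GenomicInterval("chr1", 50, 150)) == 50
        assert overlap_bp(a, GenomicInterval("chr1", 200, 300)) == 0
        assert overlap_bp(a, GenomicInterval("chr1", 20, 60)) == 40
        assert overlap_bp(a, GenomicInterval("chr2", 0, 100)) == 0


class TestMatches:
    def test_threshold_boundary_inclusive(self):
        a = mk("chr1", 0, 1000)
        just_under = Callset("y", [mk("chr1", 501, 1500, source="y")])
        at = Callset("y", [mk("chr1", 500, 1500, source="y")])
        assert not matches(a, just_under)  # 499 bp < 500
        assert matches(a, at)  # exactly 50%

    def test_two_partial_partners_do_not_combine(self):
        # 30% + 30% coverage by two partners, neither alone >= 50%
        a = mk("chr1", 0, 1000)
        B = Callset("y", [mk("chr1", 0, 300, source="y"), mk("chr1", 700, 1000, source="y")])
        assert not matches(a, B)
        assert not brute_matched(a, B)  # oracle agrees on single-partner semantics

    def test_identical_intervals_match(self):
        a = mk("chr1", 10, 500)
        assert matches(a, Callset("y", [mk("chr1", 10, 500, source="y")]))

    def test_sample_pairing_respected(self):
        a = mk("chr1", 0, 1000, sample="S1")
        other_sample = Callset("y", [mk("chr1", 0, 1000, sample="S2", source="y")])
        assert not matches(a, other_sample)

    def test_sites_only_matches_any_sample(self):
        a = mk("chr1", 0, 1000, sample="S1")
        sites = Callset("y", [mk("chr1", 0, 1000, sample="*", source="y")])
        assert matches(a, sites)

    def test_invariant_to_partner_splitting_below_threshold(self):
        a = mk("chr1", 0, 1000)
        whole = Callset("y", [mk("chr1", 0, 1000, source="y")])
        halves = Callset(
            "y", [mk("chr1", 0, 499, source="y"), mk("chr1", 499, 1000, source="y")]
        )
        assert matches(a, whole)
        assert matches(a, halves)  # one piece still covers >= 50%
        thirds = Callset(
            "y",
            [mk("chr1", i, i + 334, source="y") for i in (0, 333, 666)],
        )
        assert not matches(a, thirds)


class TestFilters:
    def test_probe_count_boundary(self):
        pm = ProbeMap({"chr1": [100, 200, 300, 400, 500, 600]})
        cs4 = Callset("x", [mk("chr1", 150, 550)])  # probes 200..500 -> 4
        cs5 = Callset("x", [mk("chr1", 100, 550)])  # probes 100..500 -> 5
        assert len(probe_count_filter(cs4, pm)) == 0
        assert len(probe_count_filter(cs5, pm)) == 1

    def test_probe_filter_matches_brute_force(self):
        rng = np.random.default_rng(7)
        probes = sorted(rng.choice(50_000, size=400, replace=False).tolist())
        pm = ProbeMap({"chr1": probes})
        cs = random_callset(rng, 150, "x", span=50_000)
        kept = probe_count_filter(cs, pm, min_probes=5)
        expect = [
            c
            for c in cs.calls
            if sum(c.interval.start <= p < c.interval.end for p in probes) >= 5
        ]
        assert kept.calls == sorted(expect, key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end, c.sample_id))

    def test_gene_filter_half_open_boundary(self):
        genes = [GenomicInterval("chr1", 1000, 2000)]
        touching = Callset("x", [mk("chr1", 500, 1001)])  # 1 bp overlap
        abutting = Callset("x", [mk("chr1", 500, 1000)])  # end == gene start
        assert len(gene_region_filter(touching, genes)) == 1
        assert len(gene_region_filter(abutting, genes)) == 0

    def test_gene_filter_matches_brute_force(self):
        rng = np.random.default_rng(8)
        genes = [
            GenomicInterval("chr1", int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 49_000, 60), rng.integers(100, 2000, 60))
        ]
        cs = random_callset(rng, 150, "x", span=50_000)
        kept = gene_region_filter(cs, genes)
        expect = [
            c
            for c in cs.calls
            if any(
                g.start < c.interval.end and c.interval.start < g.end for g in genes
            )
        ]
        assert kept.calls == sorted(expect, key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end, c.sample_id))


class TestConcordanceTable:
    def test_identical_callsets_are_fully_concordant(self):
        A = Callset("x", [mk("chr1", 0, 100), mk("chr1", 500, 900)])
        B = Callset("y", [mk("chr1", 0, 100, source="y"), mk("chr1", 500, 900, source="y")])
        row = concordance_table(A, B)
        assert (row.a_pct, row.b_pct) == (100.0, 100.0)

    def test_disjoint_callsets(self):
        A = Callset("x", [mk("chr1", 0, 100)])
        B = Callset("y", [mk("chr1", 5000, 6000, source="y")])
        row = concordance_table(A, B)
        assert (row.a_overlapped, row.b_overlapped) == (0, 0)

    def test_counts_agree_with_quadratic_oracle(self):
        rng = np.random.default_rng(42)
        A = random_callset(rng, 200, "x")
        B = random_callset(rng, 200, "y")
        row = concordance_table(A, B)
        assert row.a_overlapped == sum(brute_matched(a, B) for a in A.calls)
        assert row.b_overlapped == sum(brute_matched(b, A) for b in B.calls)

    def test_direction_symmetry(self):
        rng = np.random.default_rng(43)
        A = random_callset(rng, 120, "x")
        B = random_callset(rng, 120, "y")
        ab = concordance_table(A, B)
        ba = concordance_table(B, A)
        assert ab.a_overlapped == ba.b_overlapped
        assert ab.b_overlapped == ba.a_overlapped

    def test_percentages_round_half_up(self):
        row = ConcordanceRow("s", a_total=800, a_overlapped=1, b_total=3, b_overlapped=1)
        assert row.a_pct == 0.13  # 0.125 rounds up, not to even
        assert row.b_pct == 33.33

    def test_assembly_mismatch_rejected(self):
        A = Callset("x", [mk("chr1", 0, 100)], assembly_tag="hg18")
        B = Callset("y", [mk("chr1", 0, 100, source="y")], assembly_tag="hg19")
        with pytest.raises(ValueError, match="assemblies"):
            concordance_table(A, B)


class TestOverlapStats:
    def test_single_identical_pair(self):
        A = Callset("x", [mk("chr1", 100, 600)])
        B = Callset("y", [mk("chr1", 100, 600, source="y")])
        st = overlap_length_stats(A, B)
        assert st.mean_overlap_bp == st.mode_overlap_bp == 500
        assert st.ratio_to_length == [1.0]

    def test_no_matches_gives_empty_stats(self):
        A = Callset("x", [mk("chr1", 0, 100)])
        B = Callset("y", [mk("chr1", 9000, 9100, source="y")])
        st = overlap_length_stats(A, B)
        assert st.n_pairs == 0 and st.mean_overlap_bp is None

    def test_against_brute_force(self):
        rng = np.random.default_rng(44)
        A = random_callset(rng, 80, "x")
        B = random_callset(rng, 80, "y")
        st = overlap_length_stats(A, B)
        expect = []
        for a in A.calls:
            if not brute_matched(a, B):
                continue
            best = 0
            for b in B.calls:
                if b.interval.chrom != a.interval.chrom or b.sample_id != a.sample_id:
                    continue
                ov = max(
                    0,
                    min(a.interval.end, b.interval.end)
                    - max(a.interval.start, b.interval.start),
                )
                best = max(best, ov)
            expect.append(best)
        assert sorted(st.overlap_lengths) == sorted(expect)
        assert all(0 < r <= 1 for r in st.ratio_to_length)
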