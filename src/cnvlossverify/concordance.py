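"""Callset comparison under the directional 50% base-pair overlap rule.

Two calls from different platforms are "the same" call when a single
partner covers at least half of the query call's own base pairs.  The rule
is directional — measured against the query's length — which is why the
two overlap counts of a comparison can differ: several calls from one
source may each match one large call from the other.

Matching is within-sample: calls are only compared between identical
sample ids; a sites-only callset (sample id ``"*"``) is compared against
the union of the other side's calls.
"""

from __future__ import annotations

import bisect
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .model import Callset, CNVCall, GenomicInterval, ProbeMap

__all__ = [
    "overlap_bp",
    "matches",
    "best_partner",
    "probe_count_filter",
    "gene_region_filter",
    "concordance_table",
    "overlap_length_stats",
    "ConcordanceRow",
    "OverlapStats",
]


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Base pairs shared by two intervals (0 on different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _round_pct(num: int, den: int) -> float:
    """Percentage rounded half-up to 2 decimals, matching printed reports."""
    if den == 0:
        return 0.0
    pct = Decimal(100 * num) / Decimal(den)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class ConcordanceRow:
    """One row of a two-callset comparison table."""

    scope: str
    a_total: int
    a_overlapped: int
    b_total: int
    b_overlapped: int
    a_pct: float = field(init=False)
    b_pct: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0 <= self.a_overlapped <= self.a_total):
            raise ValueError("a_overlapped out of range")
        if not (0 <= self.b_overlapped <= self.b_total):
            raise ValueError("b_overlapped out of range")
        self.a_pct = _round_pct(self.a_overlapped, self.a_total)
        self.b_pct = _round_pct(self.b_overlapped, self.b_total)


@dataclass
class OverlapStats:
    """Overlap-length statistics over matched (query, best-partner) pairs."""

    overlap_lengths: List[int]
    ratio_to_length: List[float]

    @property
    def n_pairs(self) -> int:
        return len(self.overlap_lengths)

    @property
    def mean_overlap_bp(self) -> Optional[float]:
        if not self.overlap_lengths:
            return None
        return sum(self.overlap_lengths) / len(self.overlap_lengths)

    @property
    def mode_overlap_bp(self) -> Optional[int]:
        """Most frequent observed overlap length; smallest value on ties."""
        if not self.overlap_lengths:
            return None
        counts = Counter(self.overlap_lengths)
        top = max(counts.values())
        return min(v for v, c in counts.items() if c == top)


class _PartnerIndex:
    """Per (sample, chrom) sorted interval lists for fast overlap scans.

    Sites-only semantics: if either side of a comparison uses sample id
    ``"*"``, the index is queried across all samples.
    """

    def __init__(self, cs: Callset):
        self._by_key: Dict[Tuple[str, str], List[Tuple[int, int]]] = defaultdict(list)
        self._by_chrom: Dict[str, List[Tuple[int, int]]] = defaultdict(list)
        self.sites_only = all(c.sample_id == "*" for c in cs.calls) and len(cs) > 0
        for c in cs.calls:
            iv = (c.interval.start, c.interval.end)
            self._by_key[(c.sample_id, c.interval.chrom)].append(iv)
            self._by_chrom[c.interval.chrom].append(iv)
        for lst in self._by_key.values():
            lst.sort()
        for lst in self._by_chrom.values():
            lst.sort()

    def candidates(self, call: CNVCall) -> List[Tuple[int, int]]:
        chrom = call.interval.chrom
        if self.sites_only or call.sample_id == "*":
            lst = self._by_chrom.get(chrom, [])
        else:
            lst = self._by_key.get((call.sample_id, chrom), [])
        # intervals with start < query end; of those, keep end > query start
        hi = bisect.bisect_left(lst, (call.interval.end, -1))
        return [iv for iv in lst[:hi] if iv[1] > call.interval.start]


def matches(a: CNVCall, B: Callset, threshold: float = 0.5) -> bool:
    """True iff a single call in ``B`` covers >= ``threshold`` of ``a``'s bases."""
    return _matches_indexed(a, _PartnerIndex(B), threshold)


def _matches_indexed(a: CNVCall, idx: _PartnerIndex, threshold: float) -> bool:
    need = threshold * a.interval.length
    for s, e in idx.candidates(a):
        if min(e, a.interval.end) - max(s, a.interval.start) >= need:
            return True
    return False


def best_partner(a: CNVCall, B: Callset) -> Optional[Tuple[GenomicInterval, int]]:
    """The partner with maximal overlap (earlier-sorted wins ties), or None."""
    idx = _PartnerIndex(B)
    best: Optional[Tuple[GenomicInterval, int]] = None
    for s, e in idx.candidates(a):
        ov = min(e, a.interval.end) - max(s, a.interval.start)
        if ov > 0 and (best is None or ov > best[1]):
            best = (GenomicInterval(a.interval.chrom, s, e), ov)
    return best


def probe_count_filter(cs: Callset, probes: ProbeMap, min_probes: int = 5) -> Callset:
    """Keep calls whose interval contains at least ``min_probes`` array probes.

    Microarray callers need several consecutive probes to call a region, so
    sequencing calls spanning fewer probes cannot have an array counterpart
    and are removed before comparison.
    """
    kept = [c for c in cs.calls if probes.count_in(c.interval) >= min_probes]
    return Callset(cs.source, kept, cs.assembly_tag)


def gene_region_filter(cs: Callset, genes: Sequence[GenomicInterval]) -> Callset:
    """Keep calls sharing >= 1 base with any gene interval (half-open)."""
    trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        trees[g.chrom][g.start:g.end] = True
    kept = [
        c
        for c in cs.calls
        if c.interval.chrom in trees
        and trees[c.interval.chrom].overlaps(c.interval.start, c.interval.end)
    ]
    return Callset(cs.source, kept, cs.assembly_tag)


def concordance_table(
    A: Callset, B: Callset, scope: str = "whole genome", threshold: float = 0.5
) -> ConcordanceRow:
    """Count, in each direction, calls matched by the 50% single-partner rule.

    Callers restrict both callsets to shared samples/scope and apply the
    probe and gene filters first; counts here are per-call per-sample.
    """
    A.check_comparable(B)
    idx_b = _PartnerIndex(B)
    idx_a = _PartnerIndex(A)
    a_overlapped = sum(1 for a in A.calls if _matches_indexed(a, idx_b, threshold))
    b_overlapped = sum(1 for b in B.calls if _matches_indexed(b, idx_a, threshold))
    return ConcordanceRow(scope, len(A), a_overlapped, len(B), b_overlapped)


def overlap_length_stats(
    A: Callset, B: Callset, threshold: float = 0.5
) -> OverlapStats:
    """Overlap lengths and overlap/length ratios for matched A-calls.

    For each A-call matched under the rule, the best (maximal-overlap)
    partner contributes one overlap length and one overlap/length(a)
    fraction.  No matches yields empty stats, not an error.
    """
    idx_b = _PartnerIndex(B)
    lengths: List[int] = []
    ratios: List[float] = []
    for a in A.calls:
        if not _matches_indexed(a, idx_b, threshold):
            continue
        best = 0
        for s, e in idx_b.candidates(a):
            ov = min(e, a.interval.end) - max(s, a.interval.start)
            if ov > best:
                best = ov
        lengths.append(best)
        ratios.append(best / a.interval.length)
    return OverlapStats(lengths, ratios)
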