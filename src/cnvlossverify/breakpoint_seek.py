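"""Breakpoint discovery for candidate copy-number losses.

A deletion joins two reference loci (left_break, right_break) into one
junction in the sample genome.  Reads spanning that junction fail to map
contiguously, so the search works from the reads near a candidate:

1. extract reads covering the candidate's boundary neighbourhoods plus
   unmapped reads anchored there by a mapped mate;
2. assemble them with a de Bruijn graph (nodes (k-1)-mers, edges observed
   k-mers, canonical over reverse complements, odd k);
3. split-align each contig to the local reference window: a contig that
   decomposes into a prefix matching up to position L and a suffix matching
   from position R, with R - L >= min_deletion and adequate anchors, is
   direct *break-read* evidence of the junction (L, R);
4. contigs failing that, split-align the unmapped reads individually —
   an unmapped read may itself contain the breakpoint;
5. failing both, look for read pairs straddling the candidate whose
   apparent insert is stretched by roughly the candidate length
   (*paired-end* evidence, imprecise breakpoints); otherwise the candidate
   is *unsupported*.

Junctions with microhomology at the breakpoint admit several equivalent
coordinates; the lowest-coordinate (left-shifted) representation is
reported.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pysam

from .model import GenomicInterval

__all__ = [
    "BreakpointConfig",
    "SeqRead",
    "ReadBundle",
    "DeBruijnGraph",
    "Contig",
    "JunctionCall",
    "extract_read_bundle",
    "build_graph",
    "assemble_contigs",
    "split_align_contig",
    "paired_end_evidence",
    "seek_breakpoints",
    "normalize_junction",
    "revcomp",
]

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class BreakpointConfig:
    k: int = 21
    flank_bp: int = 500
    min_anchor: Optional[int] = None  # default k - 1
    min_deletion: int = 50
    min_edge_mult: Optional[int] = None  # None = auto from local coverage
    min_pairs: int = 2
    insert_mean: float = 400.0
    insert_sd: float = 40.0
    max_anchor_mismatch: int = 1  # fixed mismatch allowance per aligned piece
    mismatch_rate: float = 0.03  # plus this fraction of the aligned length
    include_fully_unmapped: bool = False

    def __post_init__(self) -> None:
        if self.k % 2 == 0 or not (11 <= self.k <= 63):
            raise ValueError("k must be odd and within [11, 63]")
        if self.min_anchor is None:
            self.min_anchor = self.k - 1


@dataclass
class SeqRead:
    name: str
    sequence: str
    is_unmapped: bool
    ref_start: Optional[int] = None
    ref_end: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - set("ACGTN"):
            raise ValueError(f"read {self.name}: sequence must be non-empty over ACGTN")


@dataclass
class ReadBundle:
    mapped_flank_reads: List[SeqRead] = field(default_factory=list)
    unmapped_reads: List[SeqRead] = field(default_factory=list)

    @property
    def all_sequences(self) -> List[str]:
        return [r.sequence for r in self.mapped_flank_reads + self.unmapped_reads]

    def __len__(self) -> int:
        return len(self.mapped_flank_reads) + len(self.unmapped_reads)


def extract_read_bundle(
    bam_path,
    candidate: GenomicInterval,
    flank_bp: int,
    include_fully_unmapped: bool = False,
    extra_fetch_windows: Sequence[Tuple[int, int]] = (),
) -> ReadBundle:
    """Reads near the candidate's boundaries plus locally anchored unmapped reads.

    The windows are ``[start-flank, start+flank)`` and ``[end-flank,
    end+flank)``, clipped to the contig.  Unmapped reads are placed at
    their mapped mate's coordinate, so fetching the windows collects the
    junction-read material; ``extra_fetch_windows`` lets callers pull in
    unmapped reads whose mates map across a neighbouring deletion (mates of
    a junction read sit within one insert in *sample* coordinates, which an
    intervening deletion displaces arbitrarily far in reference
    coordinates).  Fully unmapped pairs are optional.
    """
    bundle = ReadBundle()
    seen: set = set()
    with pysam.AlignmentFile(str(bam_path)) as bam:
        if candidate.chrom not in bam.references:
            raise ValueError(f"contig {candidate.chrom!r} absent from BAM header")
        clen = bam.get_reference_length(candidate.chrom)
        windows = [
            (max(0, candidate.start - flank_bp), min(clen, candidate.start + flank_bp)),
            (max(0, candidate.end - flank_bp), min(clen, candidate.end + flank_bp)),
        ] + [(max(0, ws), min(clen, we)) for ws, we in extra_fetch_windows]
        for ws, we in windows:
            if we <= ws:
                continue
            for r in bam.fetch(candidate.chrom, ws, we):
                key = (r.query_name, r.is_read1, r.is_unmapped)
                if key in seen or r.is_secondary or r.is_supplementary or r.is_duplicate:
                    continue
                if r.query_sequence is None:
                    continue
                seen.add(key)
                if r.is_unmapped:
                    # placed at its mate's coordinate, hence locally anchored
                    bundle.unmapped_reads.append(
                        SeqRead(r.query_name, r.query_sequence.upper(), True)
                    )
                else:
                    bundle.mapped_flank_reads.append(
                        SeqRead(
                            r.query_name,
                            r.query_sequence.upper(),
                            False,
                            r.reference_start,
                            r.reference_end,
                        )
                    )
        if include_fully_unmapped:
            try:
                for r in bam.fetch("*"):
                    if r.query_sequence:
                        bundle.unmapped_reads.append(
                            SeqRead(r.query_name, r.query_sequence.upper(), True)
                        )
            except (ValueError, KeyError):
                pass
    return bundle


# ---------------------------------------------------------------------------
# de Bruijn assembly


class DeBruijnGraph:
    """Canonical k-mer multigraph: nodes are (k-1)-mers, edges observed k-mers."""

    def __init__(self, k: int):
        if k % 2 == 0:
            raise ValueError("k must be odd (no self-reverse-complement k-mers)")
        self.k = k
        self.edge_mult: Dict[str, int] = {}

    def add_sequence(self, seq: str) -> None:
        k = self.k
        for part in seq.upper().split("N"):  # reads are split at ambiguity codes
            for i in range(len(part) - k + 1):
                km = canonical(part[i : i + k])
                self.edge_mult[km] = self.edge_mult.get(km, 0) + 1

    def prune(self, min_mult: int) -> None:
        if min_mult > 1:
            self.edge_mult = {
                km: m for km, m in self.edge_mult.items() if m >= min_mult
            }

    def directed_edges(self) -> Iterable[Tuple[str, str, str, int]]:
        """Both orientations of every surviving canonical k-mer: (u, v, kmer, mult)."""
        for km in sorted(self.edge_mult):
            m = self.edge_mult[km]
            for e in (km, revcomp(km)):
                yield e[:-1], e[1:], e, m

    @property
    def n_edges(self) -> int:
        return len(self.edge_mult)


def build_graph(reads: Union[Sequence[str], ReadBundle], k: int, min_mult: int = 2) -> DeBruijnGraph:
    """K-merize reads (canonical over strands) and prune low-multiplicity edges.

    Multiplicity counts observed read k-mers (a read and its reverse
    complement produce the identical graph).  Reads shorter than k are
    skipped.
    """
    seqs = reads.all_sequences if isinstance(reads, ReadBundle) else list(reads)
    g = DeBruijnGraph(k)
    for s in seqs:
        if len(s) >= k:
            g.add_sequence(s)
    g.prune(min_mult)
    return g


@dataclass
class Contig:
    id: int
    sequence: str
    mean_kmer_coverage: float
    graph_neighbors: set = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.sequence)


def _clip_tips(adj, radj, mult, k, max_tip_len):
    """Remove short dead-end branches (assembly tip clipping).

    A tip is a chain starting at a source/sink of length < max_tip_len that
    attaches to a branching node; clipping restores contiguity around
    isolated sequencing errors.  Both orientations are removed together.
    """
    def kmers_of_chain(chain_nodes):
        return [chain_nodes[i] + chain_nodes[i + 1][-1] for i in range(len(chain_nodes) - 1)]

    removed = True
    while removed:
        removed = False
        for node in sorted(adj):
            if radj[node] or not adj[node]:
                continue  # only true sources start a forward tip
            chain = [node]
            cur = node
            while len(chain) <= max_tip_len:
                outs = adj[cur]
                if len(outs) != 1:
                    break
                nxt = next(iter(outs))
                if len(radj[nxt]) != 1:
                    chain.append(nxt)
                    break
                chain.append(nxt)
                cur = nxt
            else:
                continue
            end = chain[-1]
            attaches = len(radj[end]) > 1 or len(adj[end]) > 1
            if attaches and len(chain) - 1 < max_tip_len:
                for km in kmers_of_chain(chain):
                    c = canonical(km)
                    if c in mult:
                        del mult[c]
                removed = True
        if removed:
            adj.clear()
            radj.clear()
            return False  # caller rebuilds adjacency
    return True


def assemble_contigs(g: DeBruijnGraph, clip_tips: bool = True) -> List[Contig]:
    """Maximal non-branching paths (unitigs), deduplicated over strands.

    Iteration order is lexicographic throughout, so output is reproducible
    with no seed.  ``graph_neighbors`` links contigs sharing a branch node.
    """
    k = g.k
    max_tip = k  # tips shorter than k edges are sequencing-error artifacts

    def build_adj():
        adj: Dict[str, set] = defaultdict(set)
        radj: Dict[str, set] = defaultdict(set)
        einfo: Dict[Tuple[str, str], Tuple[str, int]] = {}
        for u, v, kmer, m in g.directed_edges():
            adj[u].add(v)
            radj[v].add(u)
            adj.setdefault(v, set())
            radj.setdefault(u, set())
            einfo[(u, v)] = (kmer, m)
        return adj, radj, einfo

    adj, radj, einfo = build_adj()
    if clip_tips:
        for _ in range(10):
            if _clip_tips(adj, radj, g.edge_mult, k, max_tip):
                break
            adj, radj, einfo = build_adj()

    def is_internal(n: str) -> bool:
        return len(adj[n]) == 1 and len(radj[n]) == 1

    unitigs: List[Tuple[List[str], float]] = []
    used: set = set()
    starts = [n for n in sorted(adj) if not is_internal(n)]
    for s in starts:
        for t in sorted(adj[s]):
            if (s, t) in used:
                continue
            path = [s, t]
            used.add((s, t))
            while is_internal(path[-1]):
                nxt = next(iter(adj[path[-1]]))
                if (path[-1], nxt) in used:
                    break
                used.add((path[-1], nxt))
                path.append(nxt)
            cov = float(np.mean([einfo[(path[i], path[i + 1])][1] for i in range(len(path) - 1)]))
            unitigs.append((path, cov))
    # isolated cycles: every node internal
    for n in sorted(adj):
        if is_internal(n) and (n, next(iter(adj[n]))) not in used:
            path = [n]
            cur = n
            while True:
                nxt = next(iter(adj[cur]))
                if (cur, nxt) in used:
                    break
                used.add((cur, nxt))
                path.append(nxt)
                cur = nxt
                if cur == n:
                    break
            if len(path) > 1:
                cov = float(
                    np.mean([einfo[(path[i], path[i + 1])][1] for i in range(len(path) - 1)])
                )
                unitigs.append((path, cov))

    # strand dedupe: keep the lexicographically smaller of (seq, revcomp)
    by_canon: Dict[str, Tuple[List[str], float, str]] = {}
    for path, cov in unitigs:
        seq = path[0] + "".join(n[-1] for n in path[1:])
        canon = min(seq, revcomp(seq))
        if canon not in by_canon:
            by_canon[canon] = (path, cov, seq)

    contigs: List[Contig] = []
    end_nodes: Dict[str, List[int]] = defaultdict(list)
    for i, canon in enumerate(sorted(by_canon)):
        path, cov, seq = by_canon[canon]
        contigs.append(Contig(i, canon, cov))
        for endpoint in (path[0], path[-1]):
            end_nodes[canonical_node(endpoint)].append(i)
    for ids in end_nodes.values():
        if len(ids) > 1:
            for i in ids:
                contigs[i].graph_neighbors.update(j for j in ids if j != i)
    return contigs


def canonical_node(node: str) -> str:
    rc = revcomp(node)
    return node if node <= rc else rc


# ---------------------------------------------------------------------------
# split alignment


def _mismatch_cumsum(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    n = min(len(a), len(b))
    out = np.zeros(n + 1, dtype=np.int64)
    if n:
        np.cumsum(a[:n] != b[:n], out=out[1:])
    return out


def _max_extent(cum_mm: np.ndarray, fixed: int, rate: float) -> int:
    """Longest prefix length j with cum_mm[j] <= fixed + rate*j."""
    j = np.arange(len(cum_mm))
    ok = cum_mm <= fixed + rate * j
    idx = np.nonzero(ok)[0]
    return int(idx[-1]) if len(idx) else 0


def _seed_positions(query: str, target: str, offsets: Sequence[int], seed_len: int) -> List[int]:
    """Implied query-start positions in target from exact seed hits."""
    hits = []
    for off in offsets:
        if off + seed_len > len(query):
            continue
        seed = query[off : off + seed_len]
        p = target.find(seed)
        while p != -1 and len(hits) < 200:
            hits.append(p - off)
            p = target.find(seed, p + 1)
    return sorted(set(hits))


@dataclass
class JunctionCall:
    chrom: str
    left_break: int
    right_break: int
    evidence: str  # break_read / paired_end / unsupported
    support_count: int = 0
    contig_id: Optional[int] = None
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.evidence not in ("break_read", "paired_end", "unsupported"):
            raise ValueError(f"unknown evidence class {self.evidence!r}")
        if self.evidence != "unsupported":
            if self.right_break <= self.left_break:
                raise ValueError("right_break must exceed left_break")
            if self.support_count < 1:
                raise ValueError("supported calls need support_count >= 1")

    @property
    def deletion_length(self) -> int:
        return self.right_break - self.left_break


def normalize_junction(ref: str, left: int, right: int) -> Tuple[int, int]:
    """Left-shift a junction through breakpoint microhomology.

    Deleting ``[left, right)`` and ``[left-1, right-1)`` yield the same
    sample sequence when ``ref[left-1] == ref[right-1]``; the
    lowest-coordinate representation is canonical.
    """
    while left > 0 and ref[left - 1] == ref[right - 1]:
        left -= 1
        right -= 1
    return left, right


def split_align_contig(
    contig: Union[Contig, str],
    reference_window: str,
    window_offset: int = 0,
    min_anchor: int = 20,
    min_deletion: int = 50,
    max_anchor_mismatch: int = 1,
    mismatch_rate: float = 0.03,
    chrom: str = "",
) -> Optional[JunctionCall]:
    """Decompose a contig into prefix + suffix matches across a deletion.

    Searches both orientations for a decomposition where the prefix matches
    the window ending at L and the suffix matches starting at R with
    ``R - L >= min_deletion`` and both pieces >= ``min_anchor`` bases.
    Mismatch budget per piece is ``max_anchor_mismatch + mismatch_rate *
    piece_length``.  A contig that aligns contiguously within budget yields
    ``None``.  Equal-scoring decompositions resolve to the lowest
    left coordinate (flagged ambiguous when they disagree on the junction).
    """
    seq0 = contig.sequence if isinstance(contig, Contig) else contig
    cid = contig.id if isinstance(contig, Contig) else None
    win = reference_window.upper()
    wa = np.frombuffer(win.encode(), dtype=np.uint8)
    best: Optional[Tuple[int, int, int, bool]] = None  # (score, L, R, ambiguous)

    for seq in (seq0, revcomp(seq0)):
        if len(seq) < 2 * min_anchor:
            continue
        qa = np.frombuffer(seq.encode(), dtype=np.uint8)
        n = len(seq)
        seed_len = min(min_anchor, 18)
        pre_starts = _seed_positions(seq, win, (0, seed_len, 2 * seed_len), seed_len)
        suf_offsets = (n - seed_len, n - 2 * seed_len, n - 3 * seed_len)
        suf_starts = _seed_positions(seq, win, [o for o in suf_offsets if o >= 0], seed_len)

        prefixes = []  # (p0, max_prefix_len, cum_mm)
        for p0 in pre_starts:
            if p0 < 0 or p0 >= len(win):
                continue
            cum = _mismatch_cumsum(qa, wa[p0:])
            ext = _max_extent(cum, max_anchor_mismatch, mismatch_rate)
            if ext >= min_anchor:
                prefixes.append((p0, ext, cum))
                if ext >= n and cum[n] <= max_anchor_mismatch + mismatch_rate * n:
                    return None  # maps contiguously
        suffixes = []  # (q0_full, max_suffix_len, cum_mm_rev)
        for q0 in suf_starts:
            qend = q0 + n  # window position just past the contig if fully aligned here
            if qend <= 0 or qend > len(win):
                continue  # contig tail would overhang the window
            ra = qa[::-1]
            wrev = wa[:qend][::-1]
            cum = _mismatch_cumsum(ra, wrev)
            ext = _max_extent(cum, max_anchor_mismatch, mismatch_rate)
            if ext >= min_anchor:
                suffixes.append((q0, ext, cum))
                if ext >= n and cum[n] <= max_anchor_mismatch + mismatch_rate * n:
                    return None

        for p0, plen, pcum in prefixes:
            for q0, slen, scum in suffixes:
                gap = q0 - p0  # deletion length, independent of the split point
                if gap < min_deletion:
                    continue
                lo = max(min_anchor, n - slen)
                hi = min(plen, n - min_anchor)
                if hi < lo:
                    continue
                s_range = np.arange(lo, hi + 1)
                scores = pcum[s_range] + scum[n - s_range]
                budget = (
                    max_anchor_mismatch
                    + mismatch_rate * s_range
                    + max_anchor_mismatch
                    + mismatch_rate * (n - s_range)
                )
                valid = scores <= budget
                if not valid.any():
                    continue
                vi = np.nonzero(valid)[0]
                smin = int(scores[vi].min())
                cands = vi[scores[vi] == smin]
                s = int(s_range[cands[0]])
                L, R = p0 + s, q0 + s
                L, R = normalize_junction(win, L, R)
                amb = len(cands) > 1 and not all(
                    normalize_junction(win, p0 + int(s_range[c]), q0 + int(s_range[c]))
                    == (L, R)
                    for c in cands
                )
                cand = (smin, L, R, amb)
                if best is None or (cand[0], cand[1]) < (best[0], best[1]):
                    best = cand
    if best is None:
        return None
    score, L, R, amb = best
    return JunctionCall(
        chrom,
        window_offset + L,
        window_offset + R,
        "break_read",
        support_count=1,
        contig_id=cid,
        ambiguous=amb,
    )


# ---------------------------------------------------------------------------
# paired-end fallback


def paired_end_evidence(
    bam_path,
    candidate: GenomicInterval,
    insert_mean: float,
    insert_sd: float,
    min_pairs: int = 2,
) -> Optional[JunctionCall]:
    """Deletion evidence from straddling pairs with stretched apparent inserts.

    Counts read pairs with one mate ending at or before the candidate start
    and the other starting at or after its end, whose reference-coordinate
    insert exceeds the library mean by >3 SD and is consistent with a
    deletion of roughly the candidate's length.  Breakpoints are reported
    at the candidate boundaries (imprecise).
    """
    names = set()
    fetch_start = max(0, int(candidate.start - insert_mean - 4 * insert_sd))
    with pysam.AlignmentFile(str(bam_path)) as bam:
        if candidate.chrom not in bam.references:
            raise ValueError(f"contig {candidate.chrom!r} absent from BAM header")
        for r in bam.fetch(candidate.chrom, fetch_start, candidate.start):
            if (
                r.is_unmapped
                or r.mate_is_unmapped
                or r.is_secondary
                or r.is_supplementary
                or r.is_duplicate
                or r.next_reference_id != r.reference_id
            ):
                continue
            if r.reference_end is None or r.reference_end > candidate.start:
                continue
            if r.next_reference_start < candidate.end:
                continue
            apparent = abs(r.template_length)
            if apparent == 0:
                continue
            if apparent <= insert_mean + 3 * insert_sd:
                continue
            implied_del = apparent - insert_mean
            if abs(implied_del - candidate.length) > max(
                4 * insert_sd, 0.5 * candidate.length
            ):
                continue
            names.add(r.query_name)
    if len(names) >= min_pairs:
        return JunctionCall(
            candidate.chrom,
            candidate.start,
            candidate.end,
            "paired_end",
            support_count=len(names),
        )
    return None


# ---------------------------------------------------------------------------
# orchestration


def _count_junction_support(bundle: ReadBundle, win: str, L: int, R: int, anchor: int = 12) -> int:
    """Reads containing the junction-spanning 2*anchor-mer (either strand).

    The probe is short (24 bp by default) so reads with modest overhang
    past the junction still register; it stays specific within a local
    window of a few kb.
    """
    a = min(anchor, L, len(win) - R)
    if a < 8:
        return 1
    jseq = win[L - a : L] + win[R : R + a]
    jrc = revcomp(jseq)
    return sum(1 for s in bundle.all_sequences if jseq in s or jrc in s)


def seek_breakpoints(
    bam_path,
    reference,
    candidates: Sequence[GenomicInterval],
    cfg: Optional[BreakpointConfig] = None,
) -> Tuple[List[JunctionCall], Dict[str, float]]:
    """Classify each candidate loss as break_read / paired_end / unsupported.

    ``reference`` is a FASTA path or an open :class:`pysam.FastaFile`.
    Break-read evidence is sought first (split-aligned contigs, then
    split-aligned unmapped reads); paired-end evidence only for candidates
    without it; the summary gives the three-way proportions.
    """
    cfg = cfg or BreakpointConfig()
    own = False
    if not isinstance(reference, pysam.FastaFile):
        reference = pysam.FastaFile(str(reference))
        own = True
    calls: List[JunctionCall] = []
    try:
        for cand in candidates:
            extra = _neighbor_fetch_windows(cand, candidates, cfg)
            calls.append(_seek_one(bam_path, reference, cand, cfg, extra))
    finally:
        if own:
            reference.close()
    n = len(calls)
    summary = {
        cls: (sum(1 for c in calls if c.evidence == cls) / n if n else 0.0)
        for cls in ("break_read", "paired_end", "unsupported")
    }
    return calls, summary


def _neighbor_fetch_windows(
    cand: GenomicInterval, candidates: Sequence[GenomicInterval], cfg: BreakpointConfig
) -> List[Tuple[int, int]]:
    """Fetch windows recovering junction reads displaced by clustered deletions.

    When another candidate deletion sits within one library insert of this
    candidate's boundary, the mapped mates of this junction's crossing
    reads land in the *far* flank of that neighbour; fetch there too.
    """
    slack = int(cfg.insert_mean + 4 * cfg.insert_sd)
    extra: List[Tuple[int, int]] = []
    left_edge, right_edge = cand.start, cand.end
    for _ in range(4):  # follow short chains of clustered deletions
        moved = False
        for other in candidates:
            if other == cand or other.chrom != cand.chrom:
                continue
            if 0 <= left_edge - other.end <= slack:
                extra.append((other.start - slack, other.start + cfg.flank_bp))
                if other.start < left_edge:
                    left_edge = other.start
                    moved = True
            if 0 <= other.start - right_edge <= slack:
                extra.append((other.end - cfg.flank_bp, other.end + slack))
                if other.end > right_edge:
                    right_edge = other.end
                    moved = True
        if not moved:
            break
    return sorted(set(extra))


def _estimate_depth(bundle: ReadBundle, window_bp: int) -> float:
    bases = sum(len(s) for s in bundle.all_sequences)
    return bases / max(1, window_bp)


def _seek_one(
    bam_path,
    ref: pysam.FastaFile,
    cand: GenomicInterval,
    cfg: BreakpointConfig,
    extra_fetch_windows: Sequence[Tuple[int, int]] = (),
) -> JunctionCall:
    clen = ref.get_reference_length(cand.chrom)
    ws = max(0, cand.start - cfg.flank_bp)
    we = min(clen, cand.end + cfg.flank_bp)
    win = ref.fetch(cand.chrom, ws, we).upper()
    bundle = extract_read_bundle(
        bam_path,
        cand,
        cfg.flank_bp,
        include_fully_unmapped=cfg.include_fully_unmapped,
        extra_fetch_windows=extra_fetch_windows,
    )
    if len(bundle) == 0:
        return JunctionCall(cand.chrom, cand.start, cand.end, "unsupported")

    min_mult = cfg.min_edge_mult
    if min_mult is None:
        min_mult = 2 if _estimate_depth(bundle, 4 * cfg.flank_bp) >= 8 else 1

    votes: Counter = Counter()
    contig_of: Dict[Tuple[int, int], int] = {}
    g = build_graph(bundle, cfg.k, min_mult)
    for contig in sorted(assemble_contigs(g), key=lambda c: (-len(c.sequence), c.id)):
        jc = split_align_contig(
            contig,
            win,
            window_offset=ws,
            min_anchor=cfg.min_anchor,
            min_deletion=cfg.min_deletion,
            max_anchor_mismatch=cfg.max_anchor_mismatch,
            mismatch_rate=cfg.mismatch_rate,
            chrom=cand.chrom,
        )
        if jc is not None:
            key = (jc.left_break, jc.right_break)
            votes[key] += 1
            contig_of.setdefault(key, contig.id)
    if not votes:
        # an unmapped read may itself contain the breakpoint; a shorter
        # anchor (still unique within the local window) keeps reads with
        # modest overhang usable at low coverage
        read_anchor = max(12, cfg.min_anchor // 2)
        for r in bundle.unmapped_reads:
            jc = split_align_contig(
                r.sequence,
                win,
                window_offset=ws,
                min_anchor=read_anchor,
                min_deletion=cfg.min_deletion,
                max_anchor_mismatch=cfg.max_anchor_mismatch,
                mismatch_rate=cfg.mismatch_rate,
                chrom=cand.chrom,
            )
            if jc is not None:
                votes[(jc.left_break, jc.right_break)] += 1
    if votes:
        # rank competing junctions by direct read evidence: reads carrying
        # the junction-spanning sequence distinguish the true join from a
        # mismatch-tolerated shifted decomposition
        read_support = {
            key: _count_junction_support(bundle, win, key[0] - ws, key[1] - ws)
            for key in votes
        }
        (L, R) = min(votes, key=lambda key: (-read_support[key], -votes[key], key))
        support = max(votes[(L, R)], read_support[(L, R)])
        return JunctionCall(
            cand.chrom, L, R, "break_read", support_count=support,
            contig_id=contig_of.get((L, R)),
        )
    pe = paired_end_evidence(
        bam_path, cand, cfg.insert_mean, cfg.insert_sd, cfg.min_pairs
    )
    if pe is not None:
        return pe
    return JunctionCall(cand.chrom, cand.start, cand.end, "unsupported")
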