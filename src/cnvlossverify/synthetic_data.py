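"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates the study's data regime end to end: a reference
contig, planted homozygous/heterozygous deletions, paired-end reads at low
depth (default 4x — the coverage of released 1000 Genomes chromosome-11
mappings) with substitution errors, an irregular SNP-array probe grid, and
three mutually discordant callsets derived from the truth by boundary
jitter, missed calls and spurious calls.

Alignment records are emitted by construction from the known donor-to-
reference coordinate map rather than by running an aligner: reads lying
inside retained segments are mapped with full-match CIGARs; reads crossing
a deletion junction are emitted unmapped with a mapped mate (probability
``unmapped_junction_prob``, default 1) or soft-clipped at the junction
otherwise.  This gives every read an exact truth label.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pysam

from .model import Callset, CNVCall, GenomicInterval, ProbeMap

__all__ = [
    "SimulationSpec",
    "PlantedDeletion",
    "TruthSet",
    "JitterProfile",
    "make_reference",
    "plant_deletions",
    "simulate_alignments",
    "jitter_callsets",
    "make_probe_grid",
    "make_gene_tiling",
    "simulate_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationSpec:
    ref_length: int = 200_000
    n_deletions: int = 10
    deletion_length_range: Tuple[int, int] = (500, 5000)
    hom_fraction: float = 0.5  # zygosity mix: fraction of deletions homozygous
    read_length: int = 100
    mean_depth: float = 4.0
    insert_mean: float = 400.0
    insert_sd: float = 40.0
    error_rate: float = 0.01
    probe_spacing_mean: float = 1000.0
    unmapped_junction_prob: float = 1.0
    diploid: bool = True
    chrom: str = "chr1"
    sample_id: str = "S1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0 or self.ref_length <= 0 or self.read_length <= 0:
            raise ValueError("lengths and depth must be positive")
        if self.deletion_length_range[0] > self.deletion_length_range[1]:
            raise ValueError("bad deletion length range")


@dataclass
class PlantedDeletion:
    interval: GenomicInterval
    zygosity: str  # "hom" or "het"
    hap_indices: Tuple[int, ...]  # haplotypes carrying the deletion


@dataclass
class TruthSet:
    spec: SimulationSpec
    deletions: List[PlantedDeletion] = field(default_factory=list)
    junction_read_ids: Dict[int, List[str]] = field(default_factory=dict)

    def expected_depth(self, zygosity: Optional[str]) -> float:
        """Expected per-base depth for a segment class (None = no deletion)."""
        if zygosity is None:
            return self.spec.mean_depth
        if zygosity == "hom":
            return 0.0
        if zygosity == "het":
            return self.spec.mean_depth / 2 if self.spec.diploid else 0.0
        raise ValueError(zygosity)

    def truth_callset(self, source: str = "truth") -> Callset:
        calls = [
            CNVCall(d.interval, self.spec.sample_id, source, copy_state=d.zygosity)
            for d in self.deletions
        ]
        return Callset(source, calls)

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "spec": asdict(self.spec),
            "deletions": [
                {
                    "chrom": d.interval.chrom,
                    "start": d.interval.start,
                    "end": d.interval.end,
                    "zygosity": d.zygosity,
                    "hap_indices": list(d.hap_indices),
                }
                for d in self.deletions
            ],
            "junction_read_ids": {str(k): v for k, v in self.junction_read_ids.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def make_reference(
    spec: SimulationSpec, fasta_path: Optional[Union[str, Path]] = None
) -> str:
    """I.i.d. uniform A/C/G/T sequence; written (with .fai) when a path is given."""
    rng = np.random.default_rng(spec.seed)
    seq = _random_seq(spec.ref_length, rng)
    if fasta_path is not None:
        fasta_path = Path(fasta_path)
        with open(fasta_path, "w") as fh:
            fh.write(f">{spec.chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
        pysam.faidx(str(fasta_path))
    return seq


def plant_deletions(
    reference: str, spec: SimulationSpec, rng: Optional[np.random.Generator] = None
) -> Tuple[List[str], TruthSet]:
    """Plant non-overlapping deletions; return haplotype sequences + truth.

    Deletions keep >= 2 read lengths apart from each other and a library
    margin from the contig ends so every junction is coverable by ordinary
    fragments.  Junction coordinates are left-normalized through chance
    microhomology so truth and caller agree on a canonical representation.
    """
    from .breakpoint_seek import normalize_junction

    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    n_hap = 2 if spec.diploid else 1
    margin = int(spec.insert_mean + 4 * spec.insert_sd + 2 * spec.read_length)
    gap = 2 * spec.read_length
    lo, hi = spec.deletion_length_range
    intervals: List[Tuple[int, int]] = []
    attempts = 0
    while len(intervals) < spec.n_deletions and attempts < 200 * max(1, spec.n_deletions):
        attempts += 1
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(margin, max(margin + 1, spec.ref_length - margin - length)))
        s, e = normalize_junction(reference, start, start + length)
        if s < margin:
            continue
        if all(s - gap >= ee or e + gap <= ss for ss, ee in intervals):
            intervals.append((s, e))
    if len(intervals) < spec.n_deletions:
        raise ValueError(
            f"could not place {spec.n_deletions} deletions of {lo}-{hi} bp "
            f"on a {spec.ref_length} bp reference"
        )
    intervals.sort()
    truth = TruthSet(spec)
    for s, e in intervals:
        hom = bool(rng.random() < spec.hom_fraction) or n_hap == 1
        haps = tuple(range(n_hap)) if hom else (int(rng.integers(n_hap)),)
        truth.deletions.append(
            PlantedDeletion(
                GenomicInterval(spec.chrom, s, e), "hom" if hom else "het", haps
            )
        )
    haplotypes = []
    for h in range(n_hap):
        dels = [d.interval for d in truth.deletions if h in d.hap_indices]
        pieces, cur = [], 0
        for iv in dels:
            pieces.append(reference[cur : iv.start])
            cur = iv.end
        pieces.append(reference[cur:])
        haplotypes.append("".join(pieces))
    return haplotypes, truth


def _segment_map(ref_length: int, deletions: Sequence[GenomicInterval]):
    """Retained-segment table for one haplotype: (donor_start, ref_start, length).

    Also returns, per junction, the (donor position, deletion index) of the
    join so junction-crossing reads can be labeled.
    """
    segs = []
    junctions = []  # (donor_pos, ref_left, ref_right)
    cur_ref = 0
    cur_donor = 0
    for iv in deletions:
        seg_len = iv.start - cur_ref
        segs.append((cur_donor, cur_ref, seg_len))
        cur_donor += seg_len
        junctions.append((cur_donor, iv.start, iv.end))
        cur_ref = iv.end
    segs.append((cur_donor, cur_ref, ref_length - cur_ref))
    return segs, junctions


def simulate_alignments(
    haplotypes: Sequence[str],
    truth: TruthSet,
    bam_path: Union[str, Path],
    rng: Optional[np.random.Generator] = None,
) -> Path:
    """Emit a coordinate-sorted, indexed BAM of paired reads at the spec depth.

    Pair starts are uniform on each haplotype (approximately Poisson
    per-base coverage), inserts normal, substitution errors i.i.d. at
    ``error_rate``.  Junction-crossing reads become unmapped-with-mapped-
    mate (probability ``unmapped_junction_prob``) or soft-clipped, and
    their names are recorded in ``truth.junction_read_ids``.
    """
    spec = truth.spec
    if rng is None:
        rng = np.random.default_rng(spec.seed + 2)
    bam_path = Path(bam_path)
    rl = spec.read_length
    del_index = {
        (d.interval.start, d.interval.end): i for i, d in enumerate(truth.deletions)
    }
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": spec.chrom, "LN": spec.ref_length}],
            "RG": [{"ID": "sim", "SM": spec.sample_id}],
        }
    )
    records = []
    qual = pysam.qualitystring_to_array("I" * rl)

    def add_errors(seq: str) -> str:
        if spec.error_rate <= 0:
            return seq
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        hit = np.nonzero(rng.random(len(arr)) < spec.error_rate)[0]
        for i in hit:
            choices = _BASES[_BASES != arr[i]]
            arr[i] = choices[rng.integers(3)]
        return arr.tobytes().decode()

    def locate(d_start: int, segs, junctions):
        """Map a donor-coordinate read to reference placement.

        Returns (ref_pos, cigar, junction) where junction is None for a
        contiguous read and (del_idx, left, right) for a crossing read.
        """
        si = bisect_right(segs, (d_start, float("inf"), float("inf"))) - 1
        d0, r0, slen = segs[si]
        offset = d_start - d0
        if offset + rl <= slen or si == len(segs) - 1:
            return r0 + offset, [(0, rl)], None  # 0 = BAM_CMATCH
        jpos, jleft, jright = junctions[si]
        di = del_index[(jleft, jright)]
        return r0 + offset, None, (di, jpos - d_start)

    from .breakpoint_seek import revcomp as _rc

    for h, hap in enumerate(haplotypes):
        segs, junctions = _segment_map(spec.ref_length, [
            d.interval for d in truth.deletions if h in d.hap_indices
        ])
        hap_len = len(hap)
        depth_per_hap = spec.mean_depth / len(haplotypes)
        n_pairs = int(round(depth_per_hap * hap_len / (2 * rl)))
        min_insert = 2 * rl + 2
        for p in range(n_pairs):
            insert = max(min_insert, int(round(rng.normal(spec.insert_mean, spec.insert_sd))))
            if insert >= hap_len:
                insert = hap_len - 1
            f = int(rng.integers(0, hap_len - insert + 1))
            name = f"sim:h{h}:p{p}"
            ends = []
            for mate, (d_start, strand) in enumerate(
                [(f, "+"), (f + insert - rl, "-")]
            ):
                raw = hap[d_start : d_start + rl]
                seq = add_errors(raw)
                pos, cigar, junction = locate(d_start, segs, junctions)
                ends.append(
                    {"d_start": d_start, "seq": seq, "pos": pos, "cigar": cigar,
                     "junction": junction, "strand": strand}
                )
            for mate, end in enumerate(ends):
                a = pysam.AlignedSegment(header)
                a.query_name = name
                other = ends[1 - mate]
                seq = end["seq"] if end["strand"] == "+" else _rc(end["seq"])
                a.query_sequence = seq
                a.query_qualities = qual
                a.is_paired = True
                a.is_read1 = mate == 0
                a.is_read2 = mate == 1
                a.is_reverse = end["strand"] == "-"
                a.mate_is_reverse = other["strand"] == "-"
                a.set_tag("RG", "sim")
                junction = end["junction"]
                unmapped = False
                if junction is not None:
                    di, split = junction
                    truth.junction_read_ids.setdefault(di, []).append(name)
                    if rng.random() < spec.unmapped_junction_prob:
                        unmapped = True
                    else:
                        left = split
                        right = rl - left
                        jleft, jright = (
                            truth.deletions[di].interval.start,
                            truth.deletions[di].interval.end,
                        )
                        if left >= right:
                            end["cigar"] = [(0, left), (4, right)]  # 4 = soft clip
                        else:
                            end["cigar"] = [(4, left), (0, right)]
                            end["pos"] = jright
                if unmapped:
                    a.is_unmapped = True
                    a.reference_id = 0
                    a.reference_start = other["pos"]  # placed at the mate
                    a.cigar = None
                else:
                    a.is_unmapped = False
                    a.reference_id = 0
                    a.reference_start = end["pos"]
                    a.cigar = end["cigar"]
                    a.mapping_quality = 60
                records.append((a, mate))
            # mate coordinates and tlen once both placements are known
            r0, r1 = records[-2][0], records[-1][0]
            for a, b in ((r0, r1), (r1, r0)):
                a.next_reference_id = 0
                a.next_reference_start = b.reference_start
                a.mate_is_unmapped = b.is_unmapped
            if not r0.is_unmapped and not r1.is_unmapped:
                left = min(r0.reference_start, r1.reference_start)
                right = max(
                    r0.reference_start + rl, r1.reference_start + rl
                )
                span = right - left
                r0.template_length = span if r0.reference_start <= r1.reference_start else -span
                r1.template_length = -r0.template_length

    records.sort(key=lambda t: (t[0].reference_start, t[0].query_name, t[1]))
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as out:
        for a, _ in records:
            out.write(a)
    pysam.index(str(bam_path))
    return bam_path


@dataclass
class JitterProfile:
    """Degradation profile turning the truth into a discordant callset."""

    name: str
    jitter_bp: int = 0
    drop_rate: float = 0.0
    spurious_rate: float = 0.0
    min_size: int = 0  # censors calls smaller than this (probe-grid blindness)


def jitter_callsets(
    truth: TruthSet,
    profiles: Sequence[JitterProfile],
    rng: Optional[np.random.Generator] = None,
) -> List[Callset]:
    """Derive discordant callsets from the truth, one per profile."""
    spec = truth.spec
    if rng is None:
        rng = np.random.default_rng(spec.seed + 3)
    out: List[Callset] = []
    lo, hi = spec.deletion_length_range
    for prof in profiles:
        calls: List[CNVCall] = []
        for d in truth.deletions:
            if rng.random() < prof.drop_rate:
                continue
            s, e = d.interval.start, d.interval.end
            if prof.jitter_bp > 0:
                s += int(rng.integers(-prof.jitter_bp, prof.jitter_bp + 1))
                e += int(rng.integers(-prof.jitter_bp, prof.jitter_bp + 1))
            s = max(0, s)
            e = min(spec.ref_length, e)
            if e - s < max(1, prof.min_size):
                continue
            calls.append(
                CNVCall(GenomicInterval(spec.chrom, s, e), spec.sample_id, prof.name)
            )
        n_spurious = rng.poisson(prof.spurious_rate * max(1, len(truth.deletions)))
        for _ in range(n_spurious):
            length = int(rng.integers(max(prof.min_size, lo // 2) + 1, hi + 1))
            s = int(rng.integers(0, max(1, spec.ref_length - length)))
            calls.append(
                CNVCall(
                    GenomicInterval(spec.chrom, s, s + length), spec.sample_id, prof.name
                )
            )
        out.append(Callset(prof.name, calls))
    return out


def make_probe_grid(
    ref_length: int,
    spacing_mean: float,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
    chrom: str = "chr1",
) -> ProbeMap:
    """Probe positions with exponential gaps (irregular array spacing)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    # draw enough gaps in one shot, then trim to the contig
    n_guess = int(ref_length / spacing_mean * 1.5) + 20
    gaps = rng.exponential(spacing_mean, size=n_guess)
    pos = np.cumsum(gaps)
    pos = np.unique(pos[pos < ref_length].astype(np.int64))
    return ProbeMap({chrom: pos.tolist()})


def make_gene_tiling(
    ref_length: int, gene_len: int = 2000, gap: int = 2000, chrom: str = "chr1"
) -> List[GenomicInterval]:
    """Alternating gene/intergenic tiling covering half the contig."""
    out = []
    pos = 0
    while pos + gene_len <= ref_length:
        out.append(GenomicInterval(chrom, pos, pos + gene_len))
        pos += gene_len + gap
    return out


DEFAULT_PROFILES = (
    JitterProfile("arrayA", jitter_bp=300, drop_rate=0.25, spurious_rate=0.25, min_size=800),
    JitterProfile("seqB", jitter_bp=100, drop_rate=0.10, spurious_rate=0.15, min_size=0),
    JitterProfile("arrayC", jitter_bp=400, drop_rate=0.35, spurious_rate=0.35, min_size=1000),
)


def simulate_dataset(
    spec: SimulationSpec,
    out_dir: Union[str, Path],
    profiles: Sequence[JitterProfile] = DEFAULT_PROFILES,
) -> Dict[str, Path]:
    """Write the full input bundle for a pipeline run; returns the paths.

    FASTA+fai, BAM+bai, truth BED/JSON, three discordant callset BEDs, a
    probe BED and a gene BED — everything the validation workflow consumes.
    """
    from . import cnv_io

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    ref = make_reference(spec, out_dir / "ref.fa")
    paths["fasta"] = out_dir / "ref.fa"
    haps, truth = plant_deletions(ref, spec)
    paths["bam"] = simulate_alignments(haps, truth, out_dir / "reads.bam")
    truth_cs = truth.truth_callset()
    cnv_io.write_bed_callset(truth_cs, out_dir / "truth.bed")
    paths["truth_bed"] = out_dir / "truth.bed"
    truth.to_json(out_dir / "truth.json")
    paths["truth_json"] = out_dir / "truth.json"
    rng = np.random.default_rng(spec.seed + 3)
    for cs in jitter_callsets(truth, profiles, rng):
        p = out_dir / f"callset_{cs.source}.bed"
        cnv_io.write_bed_callset(cs, p)
        paths[f"callset_{cs.source}"] = p
    probes = make_probe_grid(
        spec.ref_length, spec.probe_spacing_mean, seed=spec.seed + 4, chrom=spec.chrom
    )
    cnv_io.write_probe_map(probes, out_dir / "probes.bed")
    paths["probes"] = out_dir / "probes.bed"
    cnv_io.write_gene_regions(
        make_gene_tiling(spec.ref_length, chrom=spec.chrom), out_dir / "genes.bed"
    )
    paths["genes"] = out_dir / "genes.bed"
    return paths
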