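"""Readers and writers for every external format the pipeline touches.

Coordinate dialects
-------------------
Internally everything is 0-based half-open.  Input tables declare a dialect:

``"bed"``
    chrom/start/end already 0-based half-open (UCSC BED).
``"1-based"``
    1-based inclusive rows, as supplementary report tables are typically
    printed; ``[s, e]`` becomes ``[s-1, e)``.

VCF is always 1-based; a symbolic deletion record with POS/END spans
``(POS, END]`` which converts to 0-based half-open ``[POS, END)``.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Union

import numpy as np
import pysam

from .model import Callset, CNVCall, DepthProfile, GenomicInterval, ProbeMap

logger = logging.getLogger(__name__)

LOSS_ALTS = {"<CN0>", "<DEL>", "CN0", "DEL"}

__all__ = [
    "read_bed_callset",
    "write_bed_callset",
    "read_vcf_losses",
    "read_probe_map",
    "read_gene_regions",
    "write_probe_map",
    "write_gene_regions",
    "extract_depth",
    "extract_chromosome_depth",
    "xlsx_to_tsv",
    "LOSS_ALTS",
]


def _convert_coords(start: int, end: int, dialect: str) -> tuple[int, int]:
    if dialect == "bed":
        return start, end
    if dialect == "1-based":
        return start - 1, end
    raise ValueError(f"unknown coordinate dialect {dialect!r}")


def read_bed_callset(
    path: Union[str, Path],
    source_label: str,
    sample_col: Optional[int] = 3,
    dialect: str = "bed",
    default_sample: str = "*",
    assembly_tag: str = "",
) -> Callset:
    """Read a tab-separated interval table into a sorted :class:`Callset`.

    ``sample_col`` is the 0-based column holding the sample id; ``None``
    (or a missing column) assigns ``default_sample`` — ``"*"`` marks a
    sites-only callset.  Overlapping rows are retained verbatim; the reader
    never merges.
    """
    calls: List[CNVCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinates") from exc
            start, end = _convert_coords(start, end, dialect)
            if end <= start:
                raise ValueError(f"{path}:{lineno}: empty interval after conversion")
            sample = default_sample
            if sample_col is not None and len(fields) > sample_col and fields[sample_col]:
                sample = fields[sample_col]
            calls.append(
                CNVCall(GenomicInterval(fields[0], start, end), sample, source_label)
            )
    return Callset(source_label, calls, assembly_tag)


def write_bed_callset(cs: Callset, path: Union[str, Path], dialect: str = "bed") -> None:
    """Write a callset back to tab text under the declared dialect."""
    with open(path, "w") as fh:
        for c in cs.calls:
            s, e = c.interval.start, c.interval.end
            if dialect == "1-based":
                s += 1
            elif dialect != "bed":
                raise ValueError(f"unknown coordinate dialect {dialect!r}")
            fh.write(f"{c.interval.chrom}\t{s}\t{e}\t{c.sample_id}\n")


def _vcf_loss_state(alts: Iterable[str]) -> Optional[str]:
    hits = [a.strip("<>") for a in alts if a in LOSS_ALTS]
    return hits[0] if hits else None


def read_vcf_losses(path: Union[str, Path], source_label: str = "vcf") -> Callset:
    """Extract copy-number-loss records (ALT intersecting {<CN0>, <DEL>}) from a VCF.

    With genotype columns, one call is emitted per carrier sample (any
    genotype allele pointing at a loss ALT); a sites-only file yields one
    sample-agnostic call per record.  Records whose END cannot be resolved
    (no END and no SVLEN) are skipped with a warning.
    """
    calls: List[CNVCall] = []
    with pysam.VariantFile(str(path)) as vf:
        has_samples = len(vf.header.samples) > 0
        for rec in vf:
            alts = rec.alts or ()
            state = _vcf_loss_state(alts)
            if state is None:
                continue
            start = rec.start + 1  # span is (POS, END] in 1-based terms
            end = rec.stop
            if end <= start:
                svlen = rec.info.get("SVLEN", None) if "SVLEN" in vf.header.info else None
                if svlen is not None:
                    v = svlen[0] if isinstance(svlen, tuple) else svlen
                    end = start + abs(int(v))
            if end <= start:
                logger.warning(
                    "skipping loss record %s:%s — no resolvable END", rec.chrom, rec.pos
                )
                continue
            interval = GenomicInterval(rec.chrom, start, end)
            loss_idx = {i + 1 for i, a in enumerate(alts) if a in LOSS_ALTS}
            if has_samples:
                for sample, sdata in rec.samples.items():
                    gt = sdata.get("GT", None)
                    if gt and any(a in loss_idx for a in gt if a is not None):
                        calls.append(
                            CNVCall(interval, sample, source_label, copy_state=state)
                        )
            else:
                calls.append(CNVCall(interval, "*", source_label, copy_state=state))
    return Callset(source_label, calls)


def _read_bedlike_rows(path: Union[str, Path]) -> List[tuple[str, int, int]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                start = int(f[1])
                end = int(f[2]) if len(f) > 2 else start + 1
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinates") from exc
            rows.append((f[0], start, end))
    return rows


def read_probe_map(path: Union[str, Path]) -> ProbeMap:
    """BED-like probe positions (probe locus = start column); duplicates dropped."""
    by_chrom: Dict[str, List[int]] = {}
    for chrom, start, _end in _read_bedlike_rows(path):
        by_chrom.setdefault(chrom, []).append(start)
    return ProbeMap(by_chrom)


def read_gene_regions(path: Union[str, Path]) -> List[GenomicInterval]:
    """BED-like gene spans, sorted, duplicates dropped."""
    seen = set()
    out: List[GenomicInterval] = []
    for chrom, start, end in _read_bedlike_rows(path):
        key = (chrom, start, end)
        if key in seen:
            continue
        seen.add(key)
        out.append(GenomicInterval(chrom, start, end))
    return sorted(out)


def write_probe_map(pm: ProbeMap, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for chrom in pm.chroms:
            for p in pm.positions(chrom):
                fh.write(f"{chrom}\t{p}\t{p + 1}\n")


def write_gene_regions(genes: Iterable[GenomicInterval], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\n")


def _depth_read_ok(read, min_mapq: int) -> bool:
    return (
        not read.is_unmapped
        and not read.is_secondary
        and not read.is_supplementary
        and not read.is_duplicate
        and not read.is_qcfail
        and read.mapping_quality >= min_mapq
    )


def extract_depth(
    bam_path: Union[str, Path], interval: GenomicInterval, min_mapq: int = 0
) -> DepthProfile:
    """Per-base count of aligned reads covering each position of ``interval``.

    A read covers a base when its alignment consumes the reference there
    (CIGAR M/=/X).  Duplicates, secondary and supplementary alignments are
    excluded; ``min_mapq`` filters on mapping quality.
    """
    with pysam.AlignmentFile(str(bam_path)) as bam:
        if interval.chrom not in bam.references:
            raise ValueError(f"contig {interval.chrom!r} absent from BAM header")
        clen = bam.get_reference_length(interval.chrom)
        if interval.end > clen:
            raise ValueError(
                f"interval {interval} extends past contig end ({clen})"
            )
        cov = bam.count_coverage(
            interval.chrom,
            interval.start,
            interval.end,
            quality_threshold=0,
            read_callback=lambda r: _depth_read_ok(r, min_mapq),
        )
    depths = np.sum(np.asarray(cov, dtype=np.int64), axis=0)
    return DepthProfile(interval, depths)


def extract_chromosome_depth(
    bam_path: Union[str, Path], chrom: str, min_mapq: int = 0
) -> DepthProfile:
    """Depth over a full contig — the whole-chromosome background source."""
    with pysam.AlignmentFile(str(bam_path)) as bam:
        if chrom not in bam.references:
            raise ValueError(f"contig {chrom!r} absent from BAM header")
        clen = bam.get_reference_length(chrom)
    return extract_depth(bam_path, GenomicInterval(chrom, 0, clen), min_mapq=min_mapq)


def xlsx_to_tsv(xlsx_path: Union[str, Path], out_dir: Union[str, Path]) -> List[Path]:
    """Dump each worksheet of a workbook to ``<out_dir>/<sheet>.tsv``.

    Helper for supplementary-report-shaped workbooks (one sheet per
    callset source); values are written as tab text, empty trailing cells
    dropped.
    """
    import openpyxl

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    wb = openpyxl.load_workbook(str(xlsx_path), read_only=True, data_only=True)
    written: List[Path] = []
    for ws in wb.worksheets:
        out = out_dir / f"{ws.title}.tsv"
        with open(out, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            for row in ws.iter_rows(values_only=True):
                vals = ["" if v is None else str(v) for v in row]
                while vals and vals[-1] == "":
                    vals.pop()
                if vals:
                    w.writerow(vals)
        written.append(out)
    return written
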