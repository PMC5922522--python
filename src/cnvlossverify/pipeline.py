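"""End-to-end workflows: validate a callset against alignments, and the
three-way callset concordance study.

``run_full_validation`` mirrors the full validation of one callset: every
candidate loss region gets both read-depth tests against a whole-chromosome
background, both tests against each flank (the concavity check), and a
breakpoint search with evidence classification; the report bundles
per-candidate rows with rejection-rate and evidence-class summaries.

``run_concordance_study`` compares callsets pairwise under the directional
50% rule after the probe-count and gene-region filters, producing one
two-direction table row per scope plus overlap-length statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from statistics import median
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import cnv_io
from .breakpoint_seek import BreakpointConfig, JunctionCall, seek_breakpoints
from .concordance import (
    ConcordanceRow,
    OverlapStats,
    concordance_table,
    gene_region_filter,
    overlap_length_stats,
    probe_count_filter,
)
from .depth_tests import (
    DepthTestConfig,
    adjacency_tests,
    batch_summary,
    chi2_depth_test,
    permutation_depth_test,
    sample_background,
)
from .model import Callset, GenomicInterval, ProbeMap

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationReport",
    "run_full_validation",
    "run_concordance_study",
    "exclude_outlier_samples",
    "reproduce_s2_concordance",
]


@dataclass
class ValidationReport:
    table: pd.DataFrame
    summary: Dict[str, object]

    def write(self, out_dir: Union[str, Path]) -> Dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "table": out_dir / "per_candidate.tsv",
            "summary": out_dir / "summary.json",
            "report": out_dir / "report.txt",
        }
        self.table.to_csv(paths["table"], sep="\t", index=False, float_format="%.6g")
        paths["summary"].write_text(json.dumps(self.summary, indent=1, sort_keys=True))
        paths["report"].write_text(self._human_readable())
        return paths

    def _human_readable(self) -> str:
        lines = [
            f"candidates tested: {len(self.table)}",
            "",
            "rejection fractions (whole-chromosome background):",
        ]
        for test in ("chi2", "permutation"):
            s = self.summary.get(f"{test}_whole", {})
            lines.append(
                f"  {test:12s} " + "  ".join(f"{k}={v:.2%}" for k, v in s.items())
            )
        lines.append("")
        lines.append("breakpoint evidence classes:")
        for cls, frac in self.summary.get("evidence_proportions", {}).items():
            lines.append(f"  {cls:12s} {frac:.2%}")
        return "\n".join(lines) + "\n"


def run_full_validation(
    bam_path: Union[str, Path],
    fasta_path: Union[str, Path],
    candidates: Union[Callset, str, Path],
    depth_cfg: Optional[DepthTestConfig] = None,
    bp_cfg: Optional[BreakpointConfig] = None,
    exclude_all_candidates: bool = True,
) -> ValidationReport:
    """Depth-test and breakpoint-classify every candidate loss region.

    ``candidates`` is a Callset or a BED path.  Background stretches never
    overlap the tested region; with ``exclude_all_candidates`` they avoid
    every candidate, keeping the sampled null clean.  Per-candidate seeds
    derive from ``depth_cfg.seed`` + candidate index, so reruns with the
    same seed are byte-identical.
    """
    depth_cfg = depth_cfg or DepthTestConfig()
    bp_cfg = bp_cfg or BreakpointConfig()
    if not isinstance(candidates, Callset):
        candidates = cnv_io.read_bed_callset(candidates, "candidates")
    logger.info(
        "validation: %d candidates, seed=%d, resamples=%d, k=%d",
        len(candidates), depth_cfg.seed, depth_cfg.n_resamples, bp_cfg.k,
    )

    chrom_depths: Dict[str, object] = {}
    for chrom in {c.interval.chrom for c in candidates}:
        chrom_depths[chrom] = cnv_io.extract_chromosome_depth(bam_path, chrom)

    intervals = [c.interval for c in candidates.calls]
    junctions, evidence_prop = seek_breakpoints(bam_path, fasta_path, intervals, bp_cfg)

    rows = []
    whole_perm, whole_chi = [], []
    flank_results: Dict[str, Dict[str, list]] = {
        s: {"chi2": [], "perm": []} for s in ("upstream", "downstream")
    }
    for i, (call, jc) in enumerate(zip(candidates.calls, junctions)):
        iv = call.interval
        cd = chrom_depths[iv.chrom]
        region = cd.depths[iv.start : iv.end]
        excl = intervals if exclude_all_candidates else [iv]
        seed_i = depth_cfg.seed + i
        try:
            bg = sample_background(cd, iv.length, excl, seed=seed_i)
        except ValueError:
            bg = None
        cfg_i = DepthTestConfig(
            n_resamples=depth_cfg.n_resamples,
            seed=seed_i,
            alphas=depth_cfg.alphas,
            flank_factor=depth_cfg.flank_factor,
            min_expected=depth_cfg.min_expected,
            exhaustive=depth_cfg.exhaustive,
        )
        if bg is not None:
            perm = permutation_depth_test(region, bg, cfg_i)
            chi = chi2_depth_test(region, bg, cfg_i)
        else:  # no permissible background placement on this contig
            from .depth_tests import Chi2Result, PermutationResult

            perm = PermutationResult(float(region.mean()), np.empty(0), float("nan"), "NA")
            chi = Chi2Result(float("nan"), 0, float("nan"), [], "NA")
        whole_perm.append(perm)
        whole_chi.append(chi)
        adj = adjacency_tests(cd, iv, cfg_i)
        for side in ("upstream", "downstream"):
            flank_results[side]["chi2"].append(adj[side][0])
            flank_results[side]["perm"].append(adj[side][1])
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "sample": call.sample_id,
                "mean_depth": float(np.mean(region)),
                "perm_p": perm.p_value,
                "perm_status": perm.status,
                "chi2_stat": chi.statistic,
                "chi2_dof": chi.dof,
                "chi2_p": chi.p_value,
                "chi2_status": chi.status,
                "up_perm_p": adj["upstream"][1].p_value,
                "up_chi2_p": adj["upstream"][0].p_value,
                "down_perm_p": adj["downstream"][1].p_value,
                "down_chi2_p": adj["downstream"][0].p_value,
                "evidence": jc.evidence,
                "left_break": jc.left_break if jc.evidence != "unsupported" else "",
                "right_break": jc.right_break if jc.evidence != "unsupported" else "",
                "support": jc.support_count,
            }
        )

    summary: Dict[str, object] = {"n_candidates": len(rows)}
    if rows:
        summary["permutation_whole"] = batch_summary(whole_perm, depth_cfg.alphas)
        summary["chi2_whole"] = batch_summary(whole_chi, depth_cfg.alphas)
        for side in ("upstream", "downstream"):
            summary[f"permutation_{side}"] = batch_summary(
                flank_results[side]["perm"], depth_cfg.alphas
            )
            summary[f"chi2_{side}"] = batch_summary(
                flank_results[side]["chi2"], depth_cfg.alphas
            )
    summary["evidence_proportions"] = evidence_prop
    return ValidationReport(pd.DataFrame(rows), summary)


# ---------------------------------------------------------------------------
# concordance study


def exclude_outlier_samples(cs: Callset, factor: float = 10.0) -> Callset:
    """Drop samples whose call count exceeds ``factor`` times the median.

    Optional guard against samples with pathologically many calls, which
    otherwise dominate pairwise counts.
    """
    counts: Dict[str, int] = {}
    for c in cs.calls:
        counts[c.sample_id] = counts.get(c.sample_id, 0) + 1
    if not counts:
        return cs
    med = median(counts.values())
    keep = {s for s, n in counts.items() if n <= factor * med}
    return cs.restrict_samples(keep)


def run_concordance_study(
    callsets: Sequence[Callset],
    probes: Optional[ProbeMap] = None,
    genes: Optional[Sequence[GenomicInterval]] = None,
    scopes: Sequence[str] = ("whole genome",),
    min_probes: int = 5,
    threshold: float = 0.5,
    filter_sources: Optional[Sequence[str]] = None,
    outlier_factor: Optional[float] = None,
) -> Dict[Tuple[str, str], Dict[str, object]]:
    """Pairwise concordance tables + overlap stats for a set of callsets.

    ``filter_sources`` limits the probe/gene filters to the named sources
    (default: applied to all when probes/genes are given).  A scope is a
    chromosome name or ``"whole genome"``.  Samples are restricted to each
    pair's shared samples unless one side is sites-only.
    """
    prepared: List[Callset] = []
    for cs in callsets:
        if outlier_factor:
            cs = exclude_outlier_samples(cs, outlier_factor)
        if (filter_sources is None or cs.source in filter_sources):
            if probes is not None:
                cs = probe_count_filter(cs, probes, min_probes)
            if genes is not None:
                cs = gene_region_filter(cs, genes)
        prepared.append(cs)

    results: Dict[Tuple[str, str], Dict[str, object]] = {}
    for i in range(len(prepared)):
        for j in range(i + 1, len(prepared)):
            A, B = prepared[i], prepared[j]
            a_sites = all(c.sample_id == "*" for c in A.calls)
            b_sites = all(c.sample_id == "*" for c in B.calls)
            if not (a_sites or b_sites):
                shared = set(A.samples) & set(B.samples)
                A2, B2 = A.restrict_samples(shared), B.restrict_samples(shared)
            else:
                A2, B2 = A, B
            rows: List[ConcordanceRow] = []
            for scope in scopes:
                As = A2 if scope == "whole genome" else A2.restrict_chrom(scope)
                Bs = B2 if scope == "whole genome" else B2.restrict_chrom(scope)
                rows.append(concordance_table(As, Bs, scope, threshold))
            results[(A.source, B.source)] = {
                "rows": rows,
                "stats": overlap_length_stats(A2, B2, threshold),
            }
    return results


def concordance_frame(
    results: Dict[Tuple[str, str], Dict[str, object]]
) -> pd.DataFrame:
    """Flatten a concordance study into a printable table."""
    recs = []
    for (a, b), payload in sorted(results.items()):
        for row in payload["rows"]:
            recs.append(
                {
                    "a_source": a,
                    "b_source": b,
                    "scope": row.scope,
                    "a_total": row.a_total,
                    "a_overlapped": row.a_overlapped,
                    "a_pct": f"{row.a_pct:.2f}",
                    "b_total": row.b_total,
                    "b_overlapped": row.b_overlapped,
                    "b_pct": f"{row.b_pct:.2f}",
                }
            )
    return pd.DataFrame(recs)


S2_SOURCES = ("hapmap", "1000g", "cnvhac")


def reproduce_s2_concordance(
    data_dir: Union[str, Path],
    dialect: str = "1-based",
    outlier_factor: Optional[float] = 10.0,
) -> Dict[Tuple[str, str], Dict[str, object]]:
    """Chromosome-11 concordance from supplementary-report-shaped TSVs.

    Expects ``<data_dir>/{hapmap,1000g,cnvhac}.tsv`` (chrom/start/end/sample
    columns; convert a three-sheet workbook with
    :func:`cnvlossverify.cnv_io.xlsx_to_tsv`).  The published lists are
    taken as post-filter, so no probe/gene filtering is reapplied here.
    """
    data_dir = Path(data_dir)
    callsets = []
    for src in S2_SOURCES:
        path = data_dir / f"{src}.tsv"
        if not path.exists():
            raise FileNotFoundError(
                f"missing {path}: place the chromosome-11 loss lists as "
                f"{'/'.join(S2_SOURCES)}.tsv under {data_dir}"
            )
        callsets.append(
            cnv_io.read_bed_callset(path, src, dialect=dialect, assembly_tag="hg19")
        )
    return run_concordance_study(
        callsets, scopes=("11",), outlier_factor=outlier_factor
    )
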