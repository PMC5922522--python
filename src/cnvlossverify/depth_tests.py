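"""Read-depth validation of candidate copy-number-loss regions.

A true deletion depresses aligned read depth, so a candidate region can be
checked against sequencing data with two tests:

* a two-sample chi-square test of H0: F = G, where F is the depth
  distribution inside the candidate and G the background distribution; and
* a one-sided permutation test of H0: mu >= sigma, where mu is the mean
  depth of the candidate and sigma the mean depth of an equally long
  background stretch.  The pooled 2L per-base depths are resampled without
  replacement R times (default 999); with sigma_i the resampled means,

      p = (1 + #{sigma_i <= mu}) / (R + 1).

  A small p rejects H0 (the region is depth-depleted); p = 1 arises
  naturally when mu is at least every resampled mean and flags a region of
  relatively *high* depth.  The add-one form keeps p >= 1/(R+1) and handles
  total ties without producing p = 0.

Background is either a uniformly placed contiguous stretch of the whole
chromosome or the immediate upstream/downstream flank (the "concavity"
variant: a real loss should be a depth valley against both flanks).

When the pooled vector holds 12 or fewer values the permutation null is
enumerated exhaustively over all C(2L, L) subsets instead of resampled.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats as sps

from .model import DepthProfile, GenomicInterval

__all__ = [
    "DepthTestConfig",
    "PermutationResult",
    "Chi2Result",
    "sample_background",
    "permutation_depth_test",
    "chi2_depth_test",
    "adjacency_tests",
    "batch_summary",
    "depth_plot",
]

EXHAUSTIVE_POOL_MAX = 12


@dataclass
class DepthTestConfig:
    n_resamples: int = 999
    seed: int = 0
    alphas: Tuple[float, ...] = (0.01, 0.05)
    background_mode: str = "whole_chromosome"  # or upstream_flank / downstream_flank
    flank_factor: float = 1.0  # flank length as a multiple of region length
    min_expected: float = 5.0  # chi-square bin-merging floor
    exhaustive: Optional[bool] = None  # None = auto when pool size <= 12

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if self.flank_factor <= 0:
            raise ValueError("flank_factor must be positive")


@dataclass
class PermutationResult:
    mu: float
    sigma_samples: np.ndarray
    p_value: float
    status: str  # "ok" or "NA"
    method: str = "monte_carlo"

    @property
    def is_na(self) -> bool:
        return self.status == "NA"


@dataclass
class Chi2Result:
    statistic: float
    dof: int
    p_value: float
    bins: List[Tuple[int, int]]  # merged integer-depth bins [lo, hi)
    status: str = "ok"

    @property
    def is_na(self) -> bool:
        return self.status == "NA"


def _as_depths(x: Union[DepthProfile, np.ndarray, Sequence[int]]) -> np.ndarray:
    if isinstance(x, DepthProfile):
        return x.depths
    return np.asarray(x, dtype=np.int64)


# ---------------------------------------------------------------------------
# background sampling


def sample_background(
    chrom_depth: Union[DepthProfile, np.ndarray],
    region_length: int,
    exclusions: Iterable[Union[GenomicInterval, Tuple[int, int]]] = (),
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Draw one contiguous depth stretch of ``region_length`` from a chromosome.

    The start is uniform over all placements whose span intersects neither
    the tested region nor any other exclusion (coordinates are offsets into
    ``chrom_depth`` when a bare array is given, chromosome coordinates when
    a :class:`DepthProfile` is given).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    offset = chrom_depth.interval.start if isinstance(chrom_depth, DepthProfile) else 0
    depths = _as_depths(chrom_depth)
    n = len(depths)
    if region_length <= 0:
        raise ValueError("region_length must be positive")
    excl: List[Tuple[int, int]] = []
    for e in exclusions:
        s, t = (e.start, e.end) if isinstance(e, GenomicInterval) else (int(e[0]), int(e[1]))
        excl.append((s - offset, t - offset))
    # forbidden start positions: any s with [s, s+L) meeting an exclusion
    forbidden = sorted(
        (max(0, s - region_length + 1), min(t, n - region_length + 1))
        for s, t in excl
        if t > 0 and s < n
    )
    allowed: List[Tuple[int, int]] = []
    cur = 0
    limit = n - region_length + 1
    for s, t in forbidden:
        if s > cur:
            allowed.append((cur, min(s, limit)))
        cur = max(cur, t)
        if cur >= limit:
            break
    if cur < limit:
        allowed.append((cur, limit))
    allowed = [(s, t) for s, t in allowed if t > s]
    total = sum(t - s for s, t in allowed)
    if total <= 0:
        raise ValueError("no permissible background placement of this length")
    pick = int(rng.integers(total))
    for s, t in allowed:
        if pick < t - s:
            start = s + pick
            break
        pick -= t - s
    return depths[start : start + region_length].copy()


# ---------------------------------------------------------------------------
# permutation test


def _resampled_means(
    pool: np.ndarray, take: int, n_resamples: int, rng: np.random.Generator
) -> np.ndarray:
    """Means of ``n_resamples`` without-replacement draws of size ``take``."""
    # chunk so the shuffle workspace stays ~tens of MB even for long regions
    chunk = max(1, int(2e7 // max(1, len(pool))))
    out = np.empty(n_resamples, dtype=np.float64)
    done = 0
    while done < n_resamples:
        m = min(chunk, n_resamples - done)
        mat = np.tile(pool, (m, 1))
        rng.permuted(mat, axis=1, out=mat)
        out[done : done + m] = mat[:, :take].mean(axis=1)
        done += m
    return out


def permutation_depth_test(
    region: Union[DepthProfile, np.ndarray],
    background: Union[np.ndarray, Sequence[int]],
    cfg: Optional[DepthTestConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> PermutationResult:
    """One-sided permutation test of H0: mean region depth >= background mean."""
    cfg = cfg or DepthTestConfig()
    r = _as_depths(region)
    b = _as_depths(background)
    if len(r) == 0:
        raise ValueError("zero-length region")
    if len(b) != len(r):
        raise ValueError(f"background length {len(b)} != region length {len(r)}")
    mu = float(r.mean())
    # sorting makes the result a function of the pooled multiset alone:
    # permuting either input changes nothing, including the MC draw sequence
    pool = np.sort(np.concatenate([r, b]))
    if pool[0] == pool[-1]:
        return PermutationResult(mu, np.empty(0), float("nan"), "NA")
    exhaustive = cfg.exhaustive
    if exhaustive is None:
        exhaustive = len(pool) <= EXHAUSTIVE_POOL_MAX
    if exhaustive:
        sigmas = np.array(
            [np.mean(c) for c in itertools.combinations(pool, len(r))], dtype=np.float64
        )
        method = "exhaustive"
    else:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        sigmas = _resampled_means(pool, len(r), cfg.n_resamples, rng)
        method = "monte_carlo"
    # tolerate float fuzz in the <= comparison on tied means
    count = int(np.sum(sigmas <= mu + 1e-12))
    p = (1 + count) / (len(sigmas) + 1)
    return PermutationResult(mu, sigmas, p, "ok", method)


# ---------------------------------------------------------------------------
# chi-square test


def _merge_bins(
    obs: np.ndarray, min_expected: float
) -> Tuple[np.ndarray, List[Tuple[int, int]]]:
    """Greedily merge adjacent depth bins until every expected count >= floor.

    ``obs`` is a 2 x B table (region row, background row); bins are the
    integer depth values 0..B-1 initially.  Returns the merged table and
    the [lo, hi) depth span of each merged bin.
    """
    cols = [obs[:, j].copy() for j in range(obs.shape[1])]
    spans = [(j, j + 1) for j in range(obs.shape[1])]
    row = obs.sum(axis=1).astype(float)
    total = row.sum()

    def expected_ok(c: np.ndarray) -> bool:
        colsum = c.sum()
        return all(row[i] * colsum / total >= min_expected for i in range(2))

    j = 0
    while j < len(cols):
        if expected_ok(cols[j]) or len(cols) == 1:
            j += 1
            continue
        # merge into the right neighbor (left for the last bin)
        k = j + 1 if j + 1 < len(cols) else j - 1
        lo, hi = min(spans[j][0], spans[k][0]), max(spans[j][1], spans[k][1])
        cols[min(j, k)] = cols[j] + cols[k]
        spans[min(j, k)] = (lo, hi)
        del cols[max(j, k)]
        del spans[max(j, k)]
        j = min(j, max(0, k - 1))
    return np.column_stack(cols), spans


def chi2_depth_test(
    region: Union[DepthProfile, np.ndarray],
    background: Union[np.ndarray, Sequence[int]],
    cfg: Optional[DepthTestConfig] = None,
) -> Chi2Result:
    """Two-sample chi-square test of H0: region and background depth distributions agree.

    Depths are histogrammed over shared integer bins 0..d_cap with d_cap
    the 99th percentile of the pooled depths (higher values clamp into the
    top bin); adjacent bins are merged until every expected count reaches
    ``cfg.min_expected``; dof = merged bins - 1.
    """
    cfg = cfg or DepthTestConfig()
    r = _as_depths(region)
    b = _as_depths(background)
    if len(r) == 0 or len(b) == 0:
        raise ValueError("both depth vectors must be non-empty")
    pool = np.concatenate([r, b])
    d_cap = int(np.percentile(pool, 99))
    obs = np.vstack(
        [
            np.bincount(np.minimum(r, d_cap), minlength=d_cap + 1),
            np.bincount(np.minimum(b, d_cap), minlength=d_cap + 1),
        ]
    ).astype(float)
    merged, spans = _merge_bins(obs, cfg.min_expected)
    if merged.shape[1] < 2:
        return Chi2Result(float("nan"), 0, float("nan"), spans, "NA")
    rowsum = merged.sum(axis=1, keepdims=True)
    colsum = merged.sum(axis=0, keepdims=True)
    total = merged.sum()
    expected = rowsum @ colsum / total
    stat = float(((merged - expected) ** 2 / expected).sum())
    dof = merged.shape[1] - 1
    p = float(sps.chi2.sf(stat, dof))
    return Chi2Result(stat, dof, p, spans, "ok")


# ---------------------------------------------------------------------------
# flank (concavity) tests and batch summaries


def adjacency_tests(
    chrom_depth: DepthProfile,
    region: GenomicInterval,
    cfg: Optional[DepthTestConfig] = None,
) -> Dict[str, Tuple[Chi2Result, PermutationResult]]:
    """Run both tests against the upstream and the downstream flank.

    Flank length is ``cfg.flank_factor`` times the region length.  A flank
    that does not fit inside the contig yields NA results for that side; a
    region (plus flank) of constant depth likewise comes back NA from the
    permutation test.  Depth valleys at real losses reject on both sides.
    """
    cfg = cfg or DepthTestConfig()
    if not (
        chrom_depth.interval.chrom == region.chrom
        and chrom_depth.interval.start <= region.start
        and region.end <= chrom_depth.interval.end
    ):
        raise ValueError("region not contained in the supplied chromosome depth")
    off = chrom_depth.interval.start
    depths = chrom_depth.depths
    rlen = region.length
    flen = max(1, int(round(cfg.flank_factor * rlen)))
    rvec = depths[region.start - off : region.end - off]
    out: Dict[str, Tuple[Chi2Result, PermutationResult]] = {}
    windows = {
        "upstream": (region.start - flen, region.start),
        "downstream": (region.end, region.end + flen),
    }
    for i, (side, (ws, we)) in enumerate(windows.items()):
        if ws < chrom_depth.interval.start or we > chrom_depth.interval.end:
            na_perm = PermutationResult(float(rvec.mean()), np.empty(0), float("nan"), "NA")
            na_chi = Chi2Result(float("nan"), 0, float("nan"), [], "NA")
            out[side] = (na_chi, na_perm)
            continue
        fvec = depths[ws - off : we - off]
        # flank may differ in length from the region; the permutation test
        # needs equal lengths, so trim/tile the flank to region length
        bg = _fit_length(fvec, rlen, seed=cfg.seed + i)
        chi = chi2_depth_test(rvec, fvec, cfg)
        perm = permutation_depth_test(
            rvec, bg, cfg, rng=np.random.default_rng(cfg.seed + i)
        )
        out[side] = (chi, perm)
    return out


def _fit_length(vec: np.ndarray, target: int, seed: int) -> np.ndarray:
    if len(vec) == target:
        return vec
    if len(vec) > target:
        start = np.random.default_rng(seed).integers(len(vec) - target + 1)
        return vec[start : start + target]
    reps = -(-target // len(vec))
    return np.tile(vec, reps)[:target]


def batch_summary(
    results: Sequence[Union[PermutationResult, Chi2Result]],
    alphas: Tuple[float, ...] = (0.01, 0.05),
) -> Dict[str, float]:
    """Fractions of non-NA results rejecting at each alpha, plus the NA fraction."""
    if len(results) == 0:
        raise ValueError("no results to summarise")
    ok = [r for r in results if not r.is_na]
    out: Dict[str, float] = {}
    for a in alphas:
        out[f"p<{a:g}"] = (
            sum(1 for r in ok if r.p_value < a) / len(ok) if ok else float("nan")
        )
    out["NA"] = (len(results) - len(ok)) / len(results)
    return out


def depth_plot(
    chrom_depth: DepthProfile,
    region: GenomicInterval,
    probes=None,
    out_path=None,
    window_factor: float = 2.0,
):
    """Diagnostic scatter of per-base depth around a candidate loss.

    Depth dots over a window ``window_factor`` region-lengths on each side,
    vertical lines at the reported boundaries, dashed lines at array probe
    loci.  Returns the matplotlib figure; writes ``out_path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    off = chrom_depth.interval.start
    pad = int(window_factor * region.length)
    ws = max(chrom_depth.interval.start, region.start - pad)
    we = min(chrom_depth.interval.end, region.end + pad)
    x = np.arange(ws, we)
    y = chrom_depth.depths[ws - off : we - off]
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.scatter(x, y, s=2, color="purple", label="read depth")
    for bx in (region.start, region.end):
        ax.axvline(bx, color="orange", lw=1.5)
    if probes is not None:
        for p in probes.positions(region.chrom):
            if ws <= p < we:
                ax.axvline(p, color="pink", ls="--", lw=0.8)
    ax.set_xlim(ws, we)
    ax.set_xlabel(f"{region.chrom} position")
    ax.set_ylabel("read depth")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig
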