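"""Core domain types shared across the pipeline.

All coordinates are 0-based half-open ``[start, end)`` internally; readers
convert from each input dialect at the boundary (see :mod:`cnvlossverify.cnv_io`).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "CNVCall",
    "Callset",
    "ProbeMap",
    "DepthProfile",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A span on a chromosome, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class CNVCall:
    """One copy-number-loss call for one sample from one source."""

    interval: GenomicInterval
    sample_id: str
    source: str
    cnv_type: str = "loss"
    copy_state: Optional[str] = None  # one of CN0/DEL/het/hom when known

    def __post_init__(self) -> None:
        if self.cnv_type != "loss":
            raise ValueError(f"only loss calls are supported, got {self.cnv_type!r}")
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")


def _call_key(c: CNVCall):
    return (c.interval.chrom, c.interval.start, c.interval.end, c.sample_id)


@dataclass
class Callset:
    """A named, sorted collection of loss calls from a single source."""

    source: str
    calls: List[CNVCall] = field(default_factory=list)
    assembly_tag: str = ""

    def __post_init__(self) -> None:
        for c in self.calls:
            if c.source != self.source:
                raise ValueError(
                    f"call source {c.source!r} differs from callset source {self.source!r}"
                )
        self.calls = sorted(self.calls, key=_call_key)

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[CNVCall]:
        return iter(self.calls)

    @property
    def samples(self) -> List[str]:
        return sorted({c.sample_id for c in self.calls})

    def restrict_samples(self, samples: Iterable[str]) -> "Callset":
        keep = set(samples)
        return Callset(
            self.source,
            [c for c in self.calls if c.sample_id in keep],
            self.assembly_tag,
        )

    def restrict_chrom(self, chrom: str) -> "Callset":
        return Callset(
            self.source,
            [c for c in self.calls if c.interval.chrom == chrom],
            self.assembly_tag,
        )

    def check_comparable(self, other: "Callset") -> None:
        if self.assembly_tag and other.assembly_tag and self.assembly_tag != other.assembly_tag:
            raise ValueError(
                f"callsets on different assemblies: {self.assembly_tag} vs {other.assembly_tag}"
            )


class ProbeMap:
    """Sorted SNP-array probe positions per chromosome (0-based)."""

    def __init__(self, positions: Dict[str, Sequence[int]]):
        self._pos: Dict[str, List[int]] = {}
        for chrom, pos in positions.items():
            uniq = sorted(set(int(p) for p in pos))
            self._pos[chrom] = uniq

    @property
    def chroms(self) -> List[str]:
        return sorted(self._pos)

    def positions(self, chrom: str) -> List[int]:
        return self._pos.get(chrom, [])

    def count_in(self, interval: GenomicInterval) -> int:
        """Number of probes inside the half-open interval (start counts, end does not)."""
        pos = self._pos.get(interval.chrom, [])
        lo = bisect.bisect_left(pos, interval.start)
        hi = bisect.bisect_left(pos, interval.end)
        return hi - lo

    def __len__(self) -> int:
        return sum(len(v) for v in self._pos.values())


@dataclass
class DepthProfile:
    """Per-base read depth over an interval; the unit both depth tests consume."""

    interval: GenomicInterval
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if len(self.depths) != self.interval.length:
            raise ValueError(
                f"depth vector length {len(self.depths)} != interval length {self.interval.length}"
            )
        if (self.depths < 0).any():
            raise ValueError("depths must be non-negative")

    @property
    def mean(self) -> float:
        return float(self.depths.mean())
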