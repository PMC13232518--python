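"""Genomic interval primitives and coordinate utilities.

All coordinates are 0-based, half-open (BED convention). Inputs that use
1-based coordinates (VCF POS, FIMO start/stop) are converted once, at the
I/O boundary, never here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneAnnotation",
    "CREClass",
    "MergedRegion",
    "resize_center",
    "resize_on_summit",
    "merge_overlapping",
    "distance_to_nearest_tss",
    "classify_cre",
    "default_promoter",
    "PROMOTER_HALF_WIDTH",
]

#: Half-width of the default promoter window around a TSS (bp). Annotations
#: may supply an explicit promoter interval that overrides this.
PROMOTER_HALF_WIDTH = 500


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        # floor midpoint: deterministic tie-break for even lengths
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (half-open semantics)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Peak:
    """An accessibility peak with its summit and total read count."""

    interval: GenomicInterval
    summit: int
    read_count: float

    def __post_init__(self) -> None:
        if not self.interval.contains(self.summit):
            raise ValueError(
                f"summit {self.summit} outside {self.interval.chrom}:"
                f"{self.interval.start}-{self.interval.end}"
            )
        if self.read_count < 0:
            raise ValueError("read_count must be >= 0")


def default_promoter(chrom: str, tss: int, half_width: int = PROMOTER_HALF_WIDTH) -> GenomicInterval:
    """Promoter window TSS +/- half_width, clipped at the chromosome start."""
    return GenomicInterval(chrom, max(0, tss - half_width), tss + half_width)


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"
    promoter: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.promoter is None:
            object.__setattr__(self, "promoter", default_promoter(self.chrom, self.tss))
        if not (self.promoter.chrom == self.chrom and self.promoter.contains(self.tss)):
            raise ValueError(f"promoter of {self.gene_id} does not contain its TSS")


class CREClass(str, enum.Enum):
    PROMOTER = "promoter"
    GENIC_ENHANCER = "genic_enhancer"
    INTERGENIC_ENHANCER = "intergenic_enhancer"


@dataclass(frozen=True)
class MergedRegion:
    """A maximal run of >=1 bp-overlapping intervals and its contributors."""

    interval: GenomicInterval
    labels: frozenset = field(default_factory=frozenset)


def resize_center(
    interval: GenomicInterval, target_len: int, sizes: Mapping[str, int]
) -> GenomicInterval:
    """Resize an interval to ``target_len`` bp around its floor midpoint.

    Windows that would run past a chromosome boundary are shifted inward so
    the output always has exactly ``target_len`` bp. Raises ``ValueError``
    when the chromosome is shorter than ``target_len``.
    """
    if target_len < 1:
        raise ValueError("target_len must be >= 1")
    chrom_len = sizes[interval.chrom]
    if chrom_len < target_len:
        raise ValueError(
            f"chromosome {interval.chrom} ({chrom_len} bp) shorter than "
            f"target length {target_len}"
        )
    start = interval.midpoint - target_len // 2
    start = min(max(start, 0), chrom_len - target_len)
    return GenomicInterval(interval.chrom, start, start + target_len)


def resize_on_summit(
    peak: Peak, target_len: int, sizes: Mapping[str, int]
) -> tuple[GenomicInterval, int, int]:
    """Window of ``target_len`` bp centered on the peak summit.

    Unlike :func:`resize_center` the window is *truncated* at chromosome
    boundaries and the clipped amounts are returned as ``(left_pad,
    right_pad)`` so the caller can N-pad extracted sequence. Always
    satisfies ``truncated_length + left_pad + right_pad == target_len``.
    """
    if target_len < 1:
        raise ValueError("target_len must be >= 1")
    chrom = peak.interval.chrom
    chrom_len = sizes[chrom]
    start = peak.summit - target_len // 2
    end = start + target_len
    left_pad = max(0, -start)
    right_pad = max(0, end - chrom_len)
    return GenomicInterval(chrom, start + left_pad, end - right_pad), left_pad, right_pad


def merge_overlapping(
    labeled: Iterable[tuple[GenomicInterval, object]],
) -> list[MergedRegion]:
    """Merge intervals that overlap by >= 1 bp on the same chromosome.

    Abutting half-open intervals ([0,10) and [10,20)) do NOT merge. Each
    output region carries the union of contributing labels. Output is
    sorted by (chrom, start) and independent of input order.
    """
    by_chrom: dict[str, list[tuple[GenomicInterval, object]]] = {}
    for iv, label in labeled:
        by_chrom.setdefault(iv.chrom, []).append((iv, label))
    out: list[MergedRegion] = []
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom], key=lambda t: (t[0].start, t[0].end))
        cur_start, cur_end = items[0][0].start, items[0][0].end
        cur_labels = {items[0][1]}
        for iv, label in items[1:]:
            if iv.start < cur_end:  # strict: >=1 bp shared
                cur_end = max(cur_end, iv.end)
                cur_labels.add(label)
            else:
                out.append(
                    MergedRegion(GenomicInterval(chrom, cur_start, cur_end), frozenset(cur_labels))
                )
                cur_start, cur_end, cur_labels = iv.start, iv.end, {label}
        out.append(
            MergedRegion(GenomicInterval(chrom, cur_start, cur_end), frozenset(cur_labels))
        )
    return out


def distance_to_nearest_tss(
    point: int, chrom: str, genes: Sequence[GeneAnnotation]
) -> int:
    """Minimum |point - TSS| over genes on the same chromosome."""
    tss = np.array([g.tss for g in genes if g.chrom == chrom])
    if tss.size == 0:
        raise ValueError(f"no gene annotated on chromosome {chrom!r}")
    return int(np.min(np.abs(tss - point)))


def classify_cre(
    interval: GenomicInterval,
    genes: Sequence[GeneAnnotation],
    gene_bodies: Mapping[str, GenomicInterval] | None = None,
) -> CREClass:
    """Classify a CRE as promoter, genic enhancer, or intergenic enhancer.

    Priority is promoter > genic > intergenic. Gene bodies are optional
    (annotations often carry only the TSS); when absent the body is
    approximated by the promoter interval, so the genic class only arises
    when explicit bodies are supplied.
    """
    for g in genes:
        if interval.overlaps(g.promoter):
            return CREClass.PROMOTER
    if gene_bodies:
        for body in gene_bodies.values():
            if interval.overlaps(body):
                return CREClass.GENIC_ENHANCER
    return CREClass.INTERGENIC_ENHANCER
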