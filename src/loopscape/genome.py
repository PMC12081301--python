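"""Core genomic data types and interval operations.

All coordinates are 0-based, half-open. Formats that use 1-based inclusive
coordinates (SEG, GTF-lite) are converted exactly once at the IO boundary
(see :mod:`loopscape.io`). Chromosome names are matched as exact strings;
no "chr" aliasing is performed, so mixed naming in inputs surfaces as
missing overlaps rather than being silently patched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: Loop annotation labels, in canonical display order (P before E before N).
LOOP_CLASSES = ("P-P", "E-P", "P-N", "E-E", "E-N", "N-N")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to(self, pos: int) -> int:
        """Distance from a base offset to the nearest base of the interval."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - self.end + 1
        return 0


@dataclass(frozen=True)
class GeneModel:
    """Gene body with a strand-aware transcription start site."""

    gene_id: str
    interval: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def tss(self) -> int:
        """TSS base: interval start on '+', last base (end - 1) on '-'."""
        if self.strand == "+":
            return self.interval.start
        return self.interval.end - 1


@dataclass
class LoopRecord:
    """A significant chromatin interaction between two same-chromosome anchors.

    Anchors are stored sorted so ``anchor1.start <= anchor2.start``. ``signal``
    is the (non-negative) interaction count; ``qvalue`` the loop caller's
    adjusted P; ``annotation`` one of :data:`LOOP_CLASSES` once classified.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    signal: float
    qvalue: Optional[float] = None
    # derived metadata: excluded from equality so written/recomputed loops
    # compare by their genomic content
    annotation: Optional[str] = field(default=None, compare=False)
    loop_id: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError(
                "loop anchors must be on the same chromosome: "
                f"{self.anchor1.chrom} vs {self.anchor2.chrom}"
            )
        if self.anchor2.start < self.anchor1.start:
            self.anchor1, self.anchor2 = self.anchor2, self.anchor1
        if self.signal < 0:
            raise ValueError(f"signal must be non-negative, got {self.signal}")
        if self.qvalue is not None and not (0.0 <= self.qvalue <= 1.0):
            raise ValueError(f"qvalue must be in [0, 1], got {self.qvalue}")

    @property
    def chrom(self) -> str:
        return self.anchor1.chrom

    @property
    def span(self) -> int:
        """Anchor midpoint separation in bases."""
        mid1 = (self.anchor1.start + self.anchor1.end) // 2
        mid2 = (self.anchor2.start + self.anchor2.end) // 2
        return abs(mid2 - mid1)

    def validate_resolution(self, resolution: int) -> None:
        for anchor in (self.anchor1, self.anchor2):
            if len(anchor) != resolution:
                raise ValueError(
                    f"anchor width {len(anchor)} != declared resolution "
                    f"{resolution}: {anchor}"
                )


def promoter_window(gene: GeneModel, flank: int = 1000) -> GenomicInterval:
    """Symmetric window of width 2*flank + 1 around the strand-aware TSS base.

    The window is clipped at position 0. With ``flank=0`` this is the
    single-base interval containing the TSS.
    """
    if flank < 0:
        raise ValueError(f"flank must be >= 0, got {flank}")
    start = max(0, gene.tss - flank)
    end = gene.tss + flank + 1
    return GenomicInterval(gene.chrom, start, end)


def _build_trees(
    intervals: Sequence[GenomicInterval],
) -> Mapping[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
    return trees


def overlap_map(
    query: Sequence[GenomicInterval],
    subject: Sequence[GenomicInterval],
) -> dict[int, set[int]]:
    """Map each query index to the set of subject indices it overlaps.

    Overlap is half-open: (q, s) is reported iff they share a chromosome and
    ``q.start < s.end and s.start < q.end``.
    """
    trees = _build_trees(subject)
    result: dict[int, set[int]] = {}
    for qi, q in enumerate(query):
        tree = trees.get(q.chrom)
        if tree is None:
            continue
        hits = {hit.data for hit in tree.overlap(q.start, q.end)}
        if hits:
            result[qi] = hits
    return result


def overlapping_indices(
    query: GenomicInterval, subject: Sequence[GenomicInterval]
) -> set[int]:
    """Indices of ``subject`` intervals overlapping a single query interval."""
    return {
        i for i, s in enumerate(subject) if query.overlaps(s)
    }
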