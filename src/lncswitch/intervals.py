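"""Genomic intervals with strand-aware arithmetic.

All coordinates in this package are 0-based, half-open ``[start, end)``
(the BED convention).  GTF input is converted at the parsing boundary and
converted back on write, so off-by-one drift cannot accumulate between
pipeline stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a named chromosome.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded).  Ordering is
    lexicographic on (chrom, start, end, strand), which gives the standard
    genome sort.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return intervals_overlap(self, other)

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def gap_to(self, other: "GenomicInterval") -> Optional[int]:
        """Minimum number of bases separating two intervals.

        Returns 0 when they overlap or abut, ``None`` when they lie on
        different chromosomes.  Strand is ignored.
        """
        if self.chrom != other.chrom:
            return None
        if intervals_overlap(self, other):
            return 0
        if other.start >= self.end:
            return other.start - self.end
        return self.start - other.end


def intervals_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share >= 1 base.

    Abutting intervals ([10,20) vs [20,30)) do not overlap.  Strand is
    ignored: ChIP-seq peaks and miRNA target sites are intersected with
    promoters/exons regardless of orientation.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


@dataclass
class LabelledInterval:
    """A genomic interval with an optional feature name (BED name column)."""

    interval: GenomicInterval
    label: Optional[str] = None


@dataclass
class PeakCollection:
    """All ChIP-seq peaks for one transcription factor.

    Peaks are unstranded; they are kept sorted by (chrom, start) so that
    downstream interval queries can rely on genome order.
    """

    tf_name: str
    peaks: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.tf_name:
            raise ValueError("tf_name must be non-empty")
        self.peaks = sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end))

    def __len__(self) -> int:
        return len(self.peaks)
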