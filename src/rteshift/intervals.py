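"""Genomic interval primitives.

All coordinates inside the package are 0-based, half-open ([start, end)),
the BED convention. 1-based inclusive formats (RepeatMasker ``.out``, GTF)
are converted at the I/O boundary and nowhere else.
"""
from __future__ import annotations

from dataclasses import dataclass

VALID_STRANDS = ("+", "-", ".")


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open.

    Attributes
    ----------
    chrom : str
        Sequence (chromosome/contig) name; must be non-empty.
    start, end : int
        0-based half-open coordinates with ``start < end``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if self.start >= self.end:
            raise ValidationError(
                f"start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, pos: int) -> bool:
        """Whether base ``pos`` (0-based) lies inside the interval."""
        return self.start <= pos < self.end

    def gap_to(self, other: "GenomicInterval") -> int:
        """Gap in bp to ``other`` on the same chrom; 0 when touching/overlapping."""
        if self.chrom != other.chrom:
            raise ValidationError("gap undefined across chromosomes")
        if self.start < other.start:
            return max(0, other.start - self.end)
        return max(0, self.start - other.end)
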