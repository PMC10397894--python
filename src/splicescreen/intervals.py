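"""1-based inclusive genomic intervals with strand-aware coordinate helpers.

All coordinates in this package are 1-based and inclusive on both ends,
matching the VCF convention. An interval is always stored with
``low <= high`` regardless of strand; the *transcript order* rendering
(start > end on the reverse strand) is produced on demand for reports.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

STRANDS = ("+", "-")


class CoordinateError(ValueError):
    """Raised for malformed or out-of-range genomic coordinates."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed interval [low, high] on one strand of a chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome / contig name.
    low, high : int
        1-based inclusive bounds, ``low <= high``.
    strand : str
        ``"+"`` or ``"-"``.
    """

    chrom: str
    low: int
    high: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise CoordinateError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if self.low < 1:
            raise CoordinateError(f"coordinates are 1-based; got low={self.low}")
        if self.low > self.high:
            raise CoordinateError(f"low > high: [{self.low}, {self.high}]")

    @property
    def length(self) -> int:
        return self.high - self.low + 1

    def contains(self, pos: int) -> bool:
        return self.low <= pos <= self.high

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.low <= other.low
            and other.high <= self.high
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and not (
            self.high < other.low or other.high < self.low
        )

    def transcript_order(self) -> tuple[int, int]:
        """(start, end) in transcript 5'->3' direction, as printed in reports."""
        return (self.high, self.low) if self.strand == "-" else (self.low, self.high)

    def offset_of(self, pos: int) -> int:
        """Transcript-orientation offset of ``pos``; 0 is the 5'-most base."""
        if not self.contains(pos):
            raise CoordinateError(f"{pos} not in [{self.low}, {self.high}]")
        return self.high - pos if self.strand == "-" else pos - self.low

    def pos_at_offset(self, offset: int) -> int:
        """Inverse of :meth:`offset_of`."""
        if not 0 <= offset < self.length:
            raise CoordinateError(f"offset {offset} outside window of length {self.length}")
        return self.high - offset if self.strand == "-" else self.low + offset

    def shifted(self, delta: int) -> "GenomicInterval":
        return replace(self, low=self.low + delta, high=self.high + delta)

    def mirrored(self, axis_low: int, axis_high: int) -> "GenomicInterval":
        """Reflect the interval across a containing axis and flip strand.

        Maps position p to ``axis_low + axis_high - p``.  Used by
        strand-symmetry checks: a gene mirrored onto the opposite strand of a
        reverse-complemented reference must give identical derived features.
        """
        new_low = axis_low + axis_high - self.high
        new_high = axis_low + axis_high - self.low
        flipped = "-" if self.strand == "+" else "+"
        return GenomicInterval(self.chrom, new_low, new_high, flipped)
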