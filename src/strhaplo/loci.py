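"""Genomic locus and window definitions for repeat-expansion screening.

The default locus is the intronic GGCCTG hexanucleotide repeat in NOP56
(chr20:2,652,733-2,652,775, GRCh38), whose expansion causes spinocerebellar
ataxia type 36.  All public coordinates are 1-based inclusive (VCF
convention); internal half-open conversions happen at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class InvalidParameterError(ValueError):
    """A parameter violates its documented domain."""


@dataclass(frozen=True)
class GenomicWindow:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InvalidParameterError(
                f"window end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def span(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class RepeatLocus:
    """Definition of a short-tandem-repeat locus and its clinical thresholds.

    Parameters
    ----------
    chrom, region_start, region_end
        Repeat tract coordinates, 1-based inclusive.
    unit
        Repeat motif; ``unit_len`` is derived from it.
    expansion_threshold
        Unit count at or above which an allele is classified expanded.
    normal_max
        Largest unit count still classified normal; counts strictly
        between ``normal_max`` and ``expansion_threshold`` are
        intermediate.
    """

    chrom: str = "chr20"
    region_start: int = 2_652_733
    region_end: int = 2_652_775
    unit: str = "GGCCTG"
    expansion_threshold: int = 30
    normal_max: int = 14
    unit_len: int = field(init=False, default=6)

    def __post_init__(self) -> None:
        object.__setattr__(self, "unit_len", len(self.unit))
        if self.unit_len < 1:
            raise InvalidParameterError("repeat unit must be non-empty")
        if self.region_end <= self.region_start:
            raise InvalidParameterError("region_end must exceed region_start")
        if self.expansion_threshold <= self.normal_max:
            raise InvalidParameterError(
                "expansion_threshold must exceed normal_max"
            )

    def window(self, flank_bp: int = 1_000_000) -> GenomicWindow:
        """The analysis window of ``flank_bp`` on each side of the repeat."""
        return GenomicWindow(
            self.chrom,
            max(1, self.region_start - flank_bp),
            self.region_end + flank_bp,
        )
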