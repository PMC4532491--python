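"""Genomic coordinate primitives shared by every stage of the pipeline.

All coordinates are 0-based, half-open (BED-native).  Any 1-based display is
formatting only, done at the I/O boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Mapping, Optional

__all__ = [
    "GenomeInterval",
    "Tag",
    "ChromSizes",
    "extend_from_center",
]

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomeInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded).  The interval is
    validated on construction: ``0 <= start < end`` must hold; validation
    against a chromosome length is deferred to :meth:`validate`.
    """

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def validate(self, chrom_sizes: "ChromSizes") -> None:
        """Raise if the interval falls outside ``chrom_sizes``."""
        size = chrom_sizes[self.chrom]
        if self.end > size:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds "
                f"chromosome length {size}"
            )

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def with_name(self, name: str) -> "GenomeInterval":
        return replace(self, name=name)


@dataclass(frozen=True)
class Tag:
    """One aligned sequencing read, reduced to its 5' end and strand.

    On the plus strand the read extends rightward from ``five_prime_pos``; on
    the minus strand it extends leftward.
    """

    chrom: str
    five_prime_pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"tag strand must be + or -, got {self.strand!r}")
        if self.five_prime_pos < 0:
            raise ValueError("tag position must be >= 0")


class ChromSizes(Mapping[str, int]):
    """Chromosome name -> length (bp).  All lengths must be positive."""

    def __init__(self, sizes: Mapping[str, int] | Iterable[tuple[str, int]]):
        self._sizes = dict(sizes)
        for chrom, size in self._sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {size}")

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __contains__(self, chrom: object) -> bool:
        return chrom in self._sizes

    def __repr__(self) -> str:
        return f"ChromSizes({self._sizes!r})"

    def total_length(self) -> int:
        return sum(self._sizes.values())


def extend_from_center(
    interval: GenomeInterval,
    flank: int = 1000,
    chrom_sizes: Optional[ChromSizes] = None,
) -> GenomeInterval:
    """Return ``[center - flank, center + flank)`` clamped to the chromosome.

    ``center`` is ``floor((start + end) / 2)``.  Clamping shortens the
    interval at chromosome edges rather than shifting it, so un-clamped
    results always have length ``2 * flank``.
    """
    if flank <= 0:
        raise ValueError("flank must be a positive number of bp")
    center = interval.center
    start = max(0, center - flank)
    end = center + flank
    if chrom_sizes is not None:
        end = min(end, chrom_sizes[interval.chrom])
    return GenomeInterval(
        interval.chrom, start, end, name=interval.name, strand=interval.strand
    )
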