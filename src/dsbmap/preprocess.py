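"""Tag-library container and the steps between alignment and peak calling.

A :class:`TagLibrary` stores the 5' ends of aligned reads per chromosome and
strand as sorted numpy arrays (duplicates appear as repeated values).  The
operations here cover duplicate capping, fragment-length estimation by strand
cross-correlation, and interval tag counting.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional

import numpy as np

from .intervals import ChromSizes, GenomeInterval, Tag

__all__ = [
    "TagLibrary",
    "deduplicate",
    "estimate_fragment_length",
    "count_tags",
    "FragmentLengthError",
]

STRANDS = ("+", "-")


class FragmentLengthError(ValueError):
    """Raised when a library is too sparse for cross-correlation estimation."""


@dataclass
class TagLibrary:
    """Strand-oriented aligned-read 5' positions for one ChIP sample.

    ``tags[chrom][strand]`` is a sorted int64 array of 5' end positions;
    duplicate tags are repeated values.  ``library_size`` always equals the
    total number of retained tags.
    """

    tags: Dict[str, Dict[str, np.ndarray]] = field(default_factory=dict)
    fragment_length: Optional[int] = None
    max_duplicates: Optional[int] = None
    read_length: int = 36

    def __post_init__(self) -> None:
        for chrom, by_strand in self.tags.items():
            for strand in STRANDS:
                arr = np.asarray(by_strand.get(strand, ()), dtype=np.int64)
                by_strand[strand] = np.sort(arr)

    @classmethod
    def from_tags(cls, records: Iterable[Tag], **kwargs) -> "TagLibrary":
        grouped: Dict[str, Dict[str, list]] = {}
        for tag in records:
            grouped.setdefault(tag.chrom, {"+": [], "-": []})[tag.strand].append(
                tag.five_prime_pos
            )
        return cls(tags=grouped, **kwargs)

    @property
    def library_size(self) -> int:
        return sum(
            arr.size for by_strand in self.tags.values() for arr in by_strand.values()
        )

    @property
    def chroms(self) -> list[str]:
        return sorted(self.tags)

    def positions(self, chrom: str, strand: str) -> np.ndarray:
        if strand not in STRANDS:
            raise ValueError(f"strand must be + or -, got {strand!r}")
        return self.tags.get(chrom, {}).get(strand, np.empty(0, dtype=np.int64))

    def strand_count(self, strand: str) -> int:
        return sum(self.positions(chrom, strand).size for chrom in self.tags)

    def count(
        self, chrom: str, start: int, end: int, strand: Optional[str] = None
    ) -> int:
        """Number of tags whose 5' end lies in ``[start, end)``."""
        total = 0
        for s in STRANDS if strand is None else (strand,):
            pos = self.positions(chrom, s)
            total += int(
                np.searchsorted(pos, end, "left") - np.searchsorted(pos, start, "left")
            )
        return total

    def iter_tags(self) -> Iterable[Tag]:
        for chrom in self.chroms:
            for strand in STRANDS:
                for pos in self.positions(chrom, strand):
                    yield Tag(chrom, int(pos), strand)


def deduplicate(library: TagLibrary, max_per_position: int = 1) -> TagLibrary:
    """Cap tags at ``max_per_position`` per (chrom, 5' position, strand) key.

    Retention is deterministic; since capped duplicates share an identical
    key, any choice of which copies to keep yields the same library.
    Idempotent for a fixed cap.
    """
    if max_per_position < 1:
        raise ValueError("max_per_position must be >= 1")
    capped: Dict[str, Dict[str, np.ndarray]] = {}
    for chrom, by_strand in library.tags.items():
        capped[chrom] = {}
        for strand, pos in by_strand.items():
            uniq, counts = np.unique(pos, return_counts=True)
            capped[chrom][strand] = np.repeat(
                uniq, np.minimum(counts, max_per_position)
            )
    return TagLibrary(
        tags=capped,
        fragment_length=library.fragment_length,
        max_duplicates=max_per_position,
        read_length=library.read_length,
    )


def count_tags(
    library: TagLibrary,
    interval: GenomeInterval,
    strand_filter: Optional[str] = None,
) -> int:
    """Tags with 5' end in ``[interval.start, interval.end)``, optionally
    restricted to one strand."""
    return library.count(interval.chrom, interval.start, interval.end, strand_filter)


def _binned_density(pos: np.ndarray, length: int, bin_size: int) -> np.ndarray:
    n_bins = -(-length // bin_size)
    return np.bincount(pos // bin_size, minlength=n_bins).astype(np.float64)


def estimate_fragment_length(
    library: TagLibrary,
    chrom_sizes: ChromSizes,
    max_shift: int = 500,
    min_tags: int = 1000,
    min_tags_per_chrom: int = 10_000,
    bin_size: int = 1,
    smooth_bp: int = 1,
) -> int:
    """Estimate the mean sequenced-fragment length by strand cross-correlation.

    For each shift ``d`` in ``[read_length, max_shift]`` the plus-strand 5'
    end density is correlated (Pearson, mean-centered) against the
    minus-strand density shifted left by ``d``; the maximizing shift is the
    fragment-length estimate.  Correlations are computed per chromosome on
    1-bp bins (``bin_size`` allows coarser, subsampled densities for very
    large genomes) over chromosomes holding at least ``min_tags_per_chrom``
    tags, falling back to all chromosomes when none qualify, and summed.
    Ties go to the smallest shift.  ``smooth_bp > 1`` applies a boxcar to the
    correlation curve before the argmax (off by default).
    """
    n_plus = library.strand_count("+")
    n_minus = library.strand_count("-")
    if n_plus < min_tags or n_minus < min_tags:
        raise FragmentLengthError(
            f"too few tags for cross-correlation ({n_plus} +, {n_minus} -; "
            f"need >= {min_tags} per strand); set fragment_length manually"
        )
    lo = library.read_length // bin_size
    hi = max_shift // bin_size
    if hi <= lo:
        raise ValueError("max_shift must exceed the read length")

    eligible = [
        c
        for c in library.chroms
        if library.positions(c, "+").size + library.positions(c, "-").size
        >= min_tags_per_chrom
    ]
    if not eligible:
        eligible = library.chroms

    corr_sum = np.zeros(hi + 1)
    for chrom in eligible:
        length = chrom_sizes[chrom]
        plus = _binned_density(library.positions(chrom, "+"), length, bin_size)
        minus = _binned_density(library.positions(chrom, "-"), length, bin_size)
        plus -= plus.mean()
        minus -= minus.mean()
        # corr[d] = sum_x plus[x] * minus[x + d], via FFT with zero padding
        from scipy.fft import irfft, next_fast_len, rfft

        n = next_fast_len(plus.size + hi + 1)
        f_plus = rfft(plus, n)
        f_minus = rfft(minus, n)
        cross = irfft(np.conj(f_plus) * f_minus, n)
        corr_sum += cross[: hi + 1]

    if smooth_bp > 1:
        kernel = np.ones(smooth_bp) / smooth_bp
        corr_sum = np.convolve(corr_sum, kernel, mode="same")
    window = corr_sum[lo : hi + 1]
    return int((lo + int(np.argmax(window))) * bin_size)
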