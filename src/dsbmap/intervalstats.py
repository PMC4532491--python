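"""Interval merging, intersection counting, and matched-random permutation
significance for break-site co-occurrence questions.

The permutation test redraws the target set ``n_trials`` times, preserving
each target interval's length and chromosome and placing it uniformly;
the empirical p-value uses the +1-corrected tail formula so p is never 0.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np

from .intervals import ChromSizes, GenomeInterval, extend_from_center

__all__ = [
    "MergedInterval",
    "IntersectionResult",
    "merge_overlapping",
    "reproducible_sites",
    "intersect_count",
    "randomization_test",
    "extend_from_center",
]


@dataclass(frozen=True)
class MergedInterval:
    """A coalesced interval recording which source sets contributed."""

    interval: GenomeInterval
    sources: frozenset

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass
class IntersectionResult:
    observed: int
    n_trials: int
    null_counts: np.ndarray
    p_value: float
    enrichment: float
    n_query: int


def merge_overlapping(
    sets: Mapping[str, Sequence[GenomeInterval]],
    slop: int = 0,
) -> List[MergedInterval]:
    """Union of one or more labelled interval sets with provenance.

    Intervals overlapping by >= 1 bp (or within ``slop`` bp) coalesce into a
    single merged interval whose ``sources`` records every contributing set.
    Idempotent and independent of input order; output sorted by
    (chromosome, start).
    """
    tagged: List[Tuple[GenomeInterval, str]] = [
        (iv, label) for label, ivs in sets.items() for iv in ivs
    ]
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end, t[1]))
    merged: List[MergedInterval] = []
    cur_chrom: Optional[str] = None
    cur_start = cur_end = 0
    cur_sources: Set[str] = set()
    for iv, label in tagged:
        touches = iv.start < cur_end if slop == 0 else iv.start <= cur_end + slop
        if iv.chrom == cur_chrom and touches:
            cur_end = max(cur_end, iv.end)
            cur_sources.add(label)
        else:
            if cur_chrom is not None:
                merged.append(
                    MergedInterval(
                        GenomeInterval(cur_chrom, cur_start, cur_end),
                        frozenset(cur_sources),
                    )
                )
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
            cur_sources = {label}
    if cur_chrom is not None:
        merged.append(
            MergedInterval(
                GenomeInterval(cur_chrom, cur_start, cur_end), frozenset(cur_sources)
            )
        )
    return merged


def reproducible_sites(
    exp1: Sequence[GenomeInterval],
    exp2: Sequence[GenomeInterval],
    labels: Tuple[str, str] = ("exp1", "exp2"),
) -> List[MergedInterval]:
    """Merged intervals supported by BOTH experiments' (extended) site sets."""
    merged = merge_overlapping({labels[0]: exp1, labels[1]: exp2})
    return [m for m in merged if set(labels) <= m.sources]


def _by_chrom(intervals: Sequence[GenomeInterval]) -> Dict[str, np.ndarray]:
    grouped: Dict[str, List[Tuple[int, int]]] = {}
    for iv in intervals:
        grouped.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {c: np.array(v, dtype=np.int64) for c, v in grouped.items()}


def _count_overlapping(
    query: Dict[str, np.ndarray], target: Dict[str, np.ndarray]
) -> int:
    """Number of query intervals overlapping >= 1 target interval by >= 1 bp."""
    total = 0
    for chrom, q in query.items():
        t = target.get(chrom)
        if t is None or t.size == 0:
            continue
        order = np.argsort(t[:, 0], kind="stable")
        starts = t[order, 0]
        ends_runmax = np.maximum.accumulate(t[order, 1])
        # query overlaps a target iff some target with start < q.end has end > q.start
        idx = np.searchsorted(starts, q[:, 1], "left")
        hit = (idx > 0) & (ends_runmax[np.maximum(idx - 1, 0)] > q[:, 0])
        total += int(hit.sum())
    return total


def intersect_count(
    query: Sequence[GenomeInterval], target: Sequence[GenomeInterval]
) -> int:
    """Query intervals with >= 1 bp overlap to any target (each counted once).

    Invariant under splitting any target interval into adjacent pieces.
    """
    return _count_overlapping(_by_chrom(query), _by_chrom(target))


def randomization_test(
    query: Sequence[GenomeInterval],
    target: Sequence[GenomeInterval],
    chrom_sizes: ChromSizes,
    n_trials: int = 1000,
    seed: Union[int, np.random.Generator, None] = 0,
    randomize: str = "target",
) -> IntersectionResult:
    """Permutation significance of query/target interval co-occurrence.

    Each trial redraws the randomized set (the target by default, mirroring
    a matched-to-target design; ``randomize='query'`` flips it) preserving
    every interval's length and chromosome, with uniform start positions.
    ``p = (1 + #{null >= observed}) / (n_trials + 1)``;
    ``enrichment = observed / mean(null)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if randomize not in ("target", "query"):
        raise ValueError("randomize must be 'target' or 'query'")
    q_dict = _by_chrom(query)
    t_dict = _by_chrom(target)
    rand_dict = t_dict if randomize == "target" else q_dict
    fixed_dict = q_dict if randomize == "target" else t_dict

    lengths: Dict[str, np.ndarray] = {}
    max_starts: Dict[str, np.ndarray] = {}
    for chrom, arr in rand_dict.items():
        ln = arr[:, 1] - arr[:, 0]
        limit = chrom_sizes[chrom] - ln
        if np.any(limit < 0):
            raise ValueError(f"interval longer than chromosome {chrom}")
        lengths[chrom] = ln
        max_starts[chrom] = limit

    observed = _count_overlapping(q_dict, t_dict)
    null_counts = np.empty(n_trials, dtype=np.int64)
    for trial in range(n_trials):
        randomized = {}
        for chrom, ln in lengths.items():
            starts = rng.integers(0, max_starts[chrom] + 1)
            randomized[chrom] = np.column_stack([starts, starts + ln])
        if randomize == "target":
            null_counts[trial] = _count_overlapping(fixed_dict, randomized)
        else:
            null_counts[trial] = _count_overlapping(randomized, fixed_dict)

    p_value = (1 + int((null_counts >= observed).sum())) / (n_trials + 1)
    mean_null = float(null_counts.mean())
    enrichment = observed / mean_null if mean_null > 0 else float("inf")
    return IntersectionResult(
        observed=observed,
        n_trials=n_trials,
        null_counts=null_counts,
        p_value=p_value,
        enrichment=enrichment,
        n_query=len(query),
    )
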