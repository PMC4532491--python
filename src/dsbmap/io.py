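"""Readers and writers for the external text formats used by the pipeline.

Formats: tagAlign/BED6 (tags), BED6 (sites, annotations), bedGraph (coverage),
two-column chrom.sizes, TSV site tables, FASTA (genome, via pyfaidx).  All
files are plain text; coordinates are BED-native 0-based half-open throughout.

Note on alignments: BAM/SAM input is out of scope; convert with
``samtools view -F 4 in.bam | awk -v OFS='\\t' '{...}'`` or
``bedtools bamtobed`` to BED6/tagAlign first.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np

from .intervals import ChromSizes, GenomeInterval
from .preprocess import TagLibrary

__all__ = [
    "TagFileError",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_tags",
    "write_tags",
    "read_bed",
    "write_bed",
    "write_coverage_bedgraph",
    "read_fasta",
]

PathLike = Union[str, Path]


class TagFileError(ValueError):
    """Malformed tagAlign/BED input, reported with a line number."""


def read_chrom_sizes(path: PathLike) -> ChromSizes:
    sizes = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise TagFileError(f"{path}: line {lineno}: expected 2 columns")
            sizes[fields[0]] = int(fields[1])
    return ChromSizes(sizes)


def write_chrom_sizes(chrom_sizes: ChromSizes, path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in chrom_sizes:
            fh.write(f"{chrom}\t{chrom_sizes[chrom]}\n")


def read_tags(
    path: PathLike,
    chrom_sizes: Optional[ChromSizes] = None,
    read_length: int = 36,
) -> TagLibrary:
    """Read a tagAlign/BED6 file into a :class:`TagLibrary`.

    The tag 5' end is the BED start for plus-strand records and
    ``BED end - 1`` for minus-strand records.  Records on chromosomes absent
    from ``chrom_sizes`` (when given) are rejected; the rejected count is
    emitted as a single warning.
    """
    by_chrom: Dict[str, Dict[str, List[int]]] = {}
    rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise TagFileError(
                    f"{path}: line {lineno}: expected >= 6 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, start_s, end_s, _name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise TagFileError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if strand not in ("+", "-"):
                raise TagFileError(
                    f"{path}: line {lineno}: strand must be + or -, got {strand!r}"
                )
            if start < 0 or end <= start:
                raise TagFileError(f"{path}: line {lineno}: invalid interval")
            if chrom_sizes is not None and chrom not in chrom_sizes:
                rejected += 1
                continue
            pos = start if strand == "+" else end - 1
            by_chrom.setdefault(chrom, {"+": [], "-": []})[strand].append(pos)
    if rejected:
        warnings.warn(
            f"{path}: rejected {rejected} records on chromosomes absent from "
            "the chrom.sizes table",
            stacklevel=2,
        )
    library = TagLibrary(
        tags={c: {s: np.array(p, dtype=np.int64) for s, p in d.items()} for c, d in by_chrom.items()},
        read_length=read_length,
    )
    return library


def write_tags(library: TagLibrary, path: PathLike, read_length: Optional[int] = None) -> None:
    """Write a library back to tagAlign (BED6 with score 0, name 'tag').

    Round-trips with :func:`read_tags`: intervals are reconstructed from the
    5' end and the read length, so coordinates are reproduced exactly.
    """
    rl = read_length or library.read_length
    with open(path, "w") as fh:
        for tag in library.iter_tags():
            if tag.strand == "+":
                start, end = tag.five_prime_pos, tag.five_prime_pos + rl
            else:
                start, end = max(0, tag.five_prime_pos + 1 - rl), tag.five_prime_pos + 1
            fh.write(f"{tag.chrom}\t{start}\t{end}\ttag\t0\t{tag.strand}\n")


def read_bed(path: PathLike) -> List[GenomeInterval]:
    """Read BED3+ into a list of intervals (name/strand kept when present)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise TagFileError(f"{path}: line {lineno}: expected >= 3 columns")
            name = fields[3] if len(fields) > 3 else None
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            intervals.append(
                GenomeInterval(fields[0], int(fields[1]), int(fields[2]), name, strand)
            )
    return intervals


def write_bed(
    intervals: Iterable[GenomeInterval],
    path: PathLike,
    scores: Optional[Sequence[float]] = None,
) -> None:
    intervals = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            score = 0 if scores is None else scores[i]
            name = iv.name if iv.name is not None else f"iv{i:05d}"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )


def _coverage_runs(
    starts: np.ndarray, ends: np.ndarray, chrom_len: int
) -> Iterable[tuple[int, int, int]]:
    """Merge extended-read intervals into (start, end, depth) bedGraph runs.

    Equal adjacent values merge; zero-coverage runs are omitted.
    """
    if starts.size == 0:
        return
    edges = np.concatenate([starts, ends])
    deltas = np.concatenate([np.ones_like(starts), -np.ones_like(ends)])
    order = np.argsort(edges, kind="stable")
    edges, deltas = edges[order], deltas[order]
    # collapse coincident edges
    uniq, idx = np.unique(edges, return_index=True)
    depth_changes = np.add.reduceat(deltas, idx)
    depths = np.cumsum(depth_changes)
    for i in range(uniq.size - 1):
        d = int(depths[i])
        if d > 0:
            yield int(uniq[i]), int(min(uniq[i + 1], chrom_len)), d


def write_coverage_bedgraph(
    library: TagLibrary,
    chrom_sizes: ChromSizes,
    path: PathLike,
    fragment_length: Optional[int] = None,
    stranded: bool = False,
    extend: bool = True,
) -> List[Path]:
    """Write per-base fragment coverage as bedGraph.

    Reads are extended from their 5' end to ``fragment_length`` in the read
    direction (clamped at chromosome edges, never an error).  With
    ``stranded=True`` two files are written (``.plus.bedGraph`` /
    ``.minus.bedGraph``); ``extend=False`` emits unextended read-length runs
    (the usual dialect for stranded break-orientation tracks).
    """
    frag = fragment_length or library.fragment_length
    if frag is None:
        raise ValueError("fragment_length not set; estimate or pass it explicitly")
    if frag < library.read_length:
        raise ValueError("fragment_length must be >= read length")
    ext = frag if extend else library.read_length

    path = Path(path)
    if stranded:
        base = path.name
        for suffix in (".bedGraph", ".bedgraph"):
            if base.endswith(suffix):
                base = base[: -len(suffix)]
        targets = {
            "+": path.with_name(base + ".plus.bedGraph"),
            "-": path.with_name(base + ".minus.bedGraph"),
        }
    else:
        targets = {None: path}

    written = []
    for strand, target in targets.items():
        with open(target, "w") as fh:
            for chrom in library.chroms:
                chrom_len = chrom_sizes[chrom]
                segs = []
                for s in ("+", "-") if strand is None else (strand,):
                    pos = library.positions(chrom, s)
                    if s == "+":
                        starts = pos
                        ends = np.minimum(pos + ext, chrom_len)
                    else:
                        starts = np.maximum(pos + 1 - ext, 0)
                        ends = pos + 1
                    segs.append((starts, ends))
                starts = np.concatenate([a for a, _ in segs])
                ends = np.concatenate([b for _, b in segs])
                for run_start, run_end, depth in _coverage_runs(starts, ends, chrom_len):
                    fh.write(f"{chrom}\t{run_start}\t{run_end}\t{depth}\n")
        written.append(target)
    return written


def read_fasta(path: PathLike):
    """Open an indexed FASTA (pyfaidx); returns a mapping-like Fasta object."""
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=True)
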