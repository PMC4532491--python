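"""Control-referenced break-site calling with tiered empirical filtering.

The caller slides a fixed window (default 500 bp) across each chromosome and
counts WT tag 5' ends, both strands, after shifting each tag half a fragment
length toward its fragment midpoint (so the two strand piles flanking a break
fall in the same window).  Local maxima are accepted greedily by descending
count with >= window spacing between centers.  Candidates are then screened
against the control (knockout) library and the local background, and an
experiment-specific tier filter on raw window tag counts produces the final
AID-dependent site list.  A no-control path calls AID-independent sites by
local enrichment and a WT:control ratio ceiling.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .intervals import ChromSizes, GenomeInterval, extend_from_center
from .preprocess import TagLibrary

__all__ = [
    "CandidatePeak",
    "FilterTier",
    "NbsSite",
    "EXP1_TIERS",
    "EXP2_TIERS",
    "tier_profile",
    "read_tier_table",
    "write_tier_table",
    "call_candidates",
    "local_background",
    "apply_tier_filter",
    "call_aid_dependent",
    "call_aid_independent",
    "write_sites_bed",
    "read_sites_bed",
    "sites_to_frame",
    "frame_to_sites",
    "write_sites_table",
    "read_sites_table",
]


@dataclass(frozen=True)
class CandidatePeak:
    """A windowed local maximum of WT tag density, before tier filtering."""

    window: GenomeInterval
    center: int
    wt_tags: int
    control_tags_norm: float
    fold_vs_control: float
    local_background_ratio: float


@dataclass(frozen=True)
class FilterTier:
    """One row of the empirical retention scheme.

    A candidate whose raw window tag count falls in ``[min_tags, max_tags]``
    (``max_tags=None`` for unbounded) is retained iff its WT:control ratio
    and local-background ratio satisfy the tier's thresholds under the
    ``combine`` rule ('and' requires both, 'or' requires either).
    """

    min_tags: int
    max_tags: Optional[int]
    ratio_threshold: float
    background_threshold: float
    combine: str = "and"

    def __post_init__(self) -> None:
        if self.combine not in ("and", "or"):
            raise ValueError(f"combine must be 'and' or 'or', got {self.combine!r}")
        if self.max_tags is not None and self.max_tags < self.min_tags:
            raise ValueError("max_tags must be >= min_tags")

    def contains(self, tags: int) -> bool:
        return tags >= self.min_tags and (
            self.max_tags is None or tags <= self.max_tags
        )

    def passes(self, ratio: float, background: float) -> bool:
        a = ratio >= self.ratio_threshold
        b = background >= self.background_threshold
        return (a or b) if self.combine == "or" else (a and b)


# Retention schemes for the two experiments: (tag-count range,
# WT:control ratio, local-background ratio, combine rule).
EXP1_TIERS: Tuple[FilterTier, ...] = (
    FilterTier(18, None, 2.0, 6.0, "or"),
    FilterTier(16, 17, 2.5, 4.0, "and"),
    FilterTier(14, 15, 3.6, 4.0, "and"),
    FilterTier(13, 13, 9.0, 8.0, "and"),
)
EXP2_TIERS: Tuple[FilterTier, ...] = (
    FilterTier(53, None, 2.2, 6.0, "or"),
    FilterTier(22, 52, 2.2, 6.0, "and"),
    FilterTier(19, 21, 4.0, 10.0, "and"),
)

_PROFILES = {"exp1": EXP1_TIERS, "exp2": EXP2_TIERS}


def tier_profile(name_or_path: Union[str, Path, Sequence[FilterTier]]) -> Tuple[FilterTier, ...]:
    """Resolve 'exp1'/'exp2', a tier-table TSV path, or a tier sequence."""
    if isinstance(name_or_path, (list, tuple)):
        return tuple(name_or_path)
    key = str(name_or_path).lower()
    if key in _PROFILES:
        return _PROFILES[key]
    path = Path(name_or_path)
    if path.exists():
        return read_tier_table(path)
    raise ValueError(
        f"unknown tier profile {name_or_path!r}: expected 'exp1', 'exp2', or a TSV path"
    )


def read_tier_table(path: Union[str, Path]) -> Tuple[FilterTier, ...]:
    df = pd.read_csv(path, sep="\t")
    tiers = []
    for _, row in df.iterrows():
        max_tags = None if pd.isna(row["max_tags"]) else int(row["max_tags"])
        tiers.append(
            FilterTier(
                int(row["min_tags"]),
                max_tags,
                float(row["ratio"]),
                float(row["background"]),
                str(row["combine"]).lower(),
            )
        )
    return tuple(tiers)


def write_tier_table(tiers: Sequence[FilterTier], path: Union[str, Path]) -> None:
    pd.DataFrame(
        {
            "min_tags": [t.min_tags for t in tiers],
            "max_tags": [t.max_tags for t in tiers],
            "ratio": [t.ratio_threshold for t in tiers],
            "background": [t.background_threshold for t in tiers],
            "combine": [t.combine for t in tiers],
        }
    ).to_csv(path, sep="\t", index=False)


@dataclass
class NbsSite:
    """A called break site: 500-bp window plus the 2-kb center extension."""

    called_window: GenomeInterval
    extended: GenomeInterval
    wt_tags: int
    wt_plus: int
    wt_minus: int
    control_tags_norm: float
    fold_vs_control: float
    local_background_ratio: float
    aid_dependent: bool = False
    aid_independent: bool = False
    one_ended: Optional[bool] = None
    orientation: Optional[str] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.aid_dependent == self.aid_independent:
            raise ValueError(
                "exactly one of aid_dependent/aid_independent must be set"
            )

    @property
    def chrom(self) -> str:
        return self.called_window.chrom

    @property
    def center(self) -> int:
        return self.called_window.center


def _validate_tiers(tiers: Sequence[FilterTier]) -> None:
    ranges = sorted(
        (t.min_tags, np.inf if t.max_tags is None else t.max_tags) for t in tiers
    )
    for (lo1, hi1), (lo2, _hi2) in zip(ranges, ranges[1:]):
        if lo2 <= hi1:
            raise ValueError(
                f"tier tag-count ranges overlap: [{lo1},{hi1}] and [{lo2},...]"
            )


def _shifted_positions(library: TagLibrary, chrom: str, chrom_len: int) -> np.ndarray:
    """Tag 5' ends shifted half a fragment toward the fragment midpoint."""
    if library.fragment_length is None:
        raise ValueError(
            "fragment_length not set on the tag library; run "
            "estimate_fragment_length (or set it) before calling peaks"
        )
    half = library.fragment_length // 2
    plus = library.positions(chrom, "+") + half
    minus = library.positions(chrom, "-") - half
    return np.sort(np.clip(np.concatenate([plus, minus]), 0, chrom_len - 1))


def _count_sorted(pos: np.ndarray, start: int, end: int) -> int:
    return int(np.searchsorted(pos, end, "left") - np.searchsorted(pos, start, "left"))


def _background_ratio(
    shifted: np.ndarray,
    window_start: int,
    window_len: int,
    window_tags: int,
    chrom_len: int,
    span: int,
    pseudocount: float,
) -> float:
    center = window_start + window_len // 2
    region_start = max(0, center - span // 2)
    region_end = min(chrom_len, center + span // 2)
    outside_len = (region_end - region_start) - window_len
    if outside_len <= 0:
        return 1.0
    outside = _count_sorted(shifted, region_start, region_end) - window_tags
    window_density = window_tags / window_len
    outside_density = (outside + pseudocount) / outside_len
    return window_density / outside_density


def _greedy_maxima(
    wsum: np.ndarray,
    shifted: np.ndarray,
    chrom_len: int,
    window: int,
    tag_floor: int,
) -> List[Tuple[int, int]]:
    """Greedy selection of local maxima by descending window count with
    >= window spacing between accepted centers.

    Ties break to the leftmost start; each accepted window is then
    re-anchored on the centroid of the tags it contains (a tie plateau of
    equal-count windows collapses to one call centered on the pile), and the
    tag count re-evaluated on the re-anchored window.  Returns
    (start, count) pairs sorted by start.
    """
    starts = np.flatnonzero(wsum >= tag_floor)
    if starts.size == 0:
        return []
    counts = wsum[starts]
    order = np.lexsort((starts, -counts))
    accepted_centers: List[int] = []
    accepted: List[Tuple[int, int]] = []
    for idx in order:
        s = int(starts[idx])
        lo = np.searchsorted(shifted, s, "left")
        hi = np.searchsorted(shifted, s + window, "left")
        centroid = int(round(shifted[lo:hi].mean()))
        s_ref = min(max(centroid - window // 2, 0), chrom_len - window)
        c = s_ref + window // 2
        i = bisect.bisect_left(accepted_centers, c)
        if i > 0 and c - accepted_centers[i - 1] < window:
            continue
        if i < len(accepted_centers) and accepted_centers[i] - c < window:
            continue
        accepted_centers.insert(i, c)
        accepted.append((s_ref, _count_sorted(shifted, s_ref, s_ref + window)))
    return sorted(accepted)


def _window_sums(shifted: np.ndarray, chrom_len: int, window: int) -> np.ndarray:
    counts = np.bincount(shifted, minlength=chrom_len)
    csum = np.concatenate([[0], np.cumsum(counts)])
    return (csum[window:] - csum[: chrom_len - window + 1]).astype(np.int64)


def call_candidates(
    wt: TagLibrary,
    control: Optional[TagLibrary],
    chrom_sizes: ChromSizes,
    window: int = 500,
    fold_threshold: float = 2.0,
    tag_floor: int = 10,
    pseudocount: float = 0.5,
    background_span: int = 10_000,
) -> List[CandidatePeak]:
    """Call candidate peaks in the WT library against a control library.

    The control tag count per window is scaled to the WT library size and a
    pseudocount is added before the fold ratio; windows with
    ``wt_tags >= tag_floor`` and ``fold >= fold_threshold`` survive.
    """
    if control is None:
        raise ValueError(
            "control library required for AID-dependent calling; use "
            "call_aid_independent for the no-control procedure"
        )
    if control.library_size == 0:
        raise ValueError("control library is empty")
    scale = wt.library_size / control.library_size
    candidates: List[CandidatePeak] = []
    for chrom in sorted(chrom_sizes):
        chrom_len = chrom_sizes[chrom]
        if chrom not in wt.tags or chrom_len <= window:
            continue
        shifted_wt = _shifted_positions(wt, chrom, chrom_len)
        if shifted_wt.size == 0:
            continue
        shifted_ctrl = _shifted_positions(control, chrom, chrom_len)
        wsum = _window_sums(shifted_wt, chrom_len, window)
        for start, wt_tags in _greedy_maxima(wsum, shifted_wt, chrom_len, window, tag_floor):
            ctrl = _count_sorted(shifted_ctrl, start, start + window)
            ctrl_norm = ctrl * scale
            fold = wt_tags / (ctrl_norm + pseudocount)
            if fold < fold_threshold:
                continue
            bg = _background_ratio(
                shifted_wt, start, window, wt_tags, chrom_len,
                background_span, pseudocount,
            )
            candidates.append(
                CandidatePeak(
                    window=GenomeInterval(chrom, start, start + window),
                    center=start + window // 2,
                    wt_tags=wt_tags,
                    control_tags_norm=ctrl_norm,
                    fold_vs_control=fold,
                    local_background_ratio=bg,
                )
            )
    return candidates


def local_background(
    peak: CandidatePeak,
    wt: TagLibrary,
    chrom_sizes: ChromSizes,
    span: int = 10_000,
    pseudocount: float = 0.5,
) -> float:
    """WT tag density in the window over density in the surrounding span.

    The surrounding region is ``[center - span/2, center + span/2)`` minus
    the window, clamped at chromosome edges (the denominator renormalizes by
    the available length).
    """
    chrom_len = chrom_sizes[peak.window.chrom]
    shifted = _shifted_positions(wt, peak.window.chrom, chrom_len)
    return _background_ratio(
        shifted, peak.window.start, peak.window.length, peak.wt_tags,
        chrom_len, span, pseudocount,
    )


def _make_site(
    window: GenomeInterval,
    wt: TagLibrary,
    chrom_sizes: ChromSizes,
    flank: int,
    **kwargs,
) -> NbsSite:
    extended = extend_from_center(window, flank, chrom_sizes)
    wt_plus = wt.count(extended.chrom, extended.start, extended.end, "+")
    wt_minus = wt.count(extended.chrom, extended.start, extended.end, "-")
    return NbsSite(
        called_window=window,
        extended=extended,
        wt_plus=wt_plus,
        wt_minus=wt_minus,
        **kwargs,
    )


def apply_tier_filter(
    candidates: Iterable[CandidatePeak],
    tiers: Sequence[FilterTier],
    wt: TagLibrary,
    chrom_sizes: ChromSizes,
    flank: int = 1000,
) -> List[NbsSite]:
    """Retain candidates passing their tag-count tier; survivors become
    AID-dependent sites with 1-kb center extension.

    Candidates whose tag count falls below every tier are rejected.
    """
    _validate_tiers(tiers)
    sites = []
    for cand in candidates:
        tier = next((t for t in tiers if t.contains(cand.wt_tags)), None)
        if tier is None:
            continue
        if not tier.passes(cand.fold_vs_control, cand.local_background_ratio):
            continue
        sites.append(
            _make_site(
                cand.window,
                wt,
                chrom_sizes,
                flank,
                wt_tags=cand.wt_tags,
                control_tags_norm=cand.control_tags_norm,
                fold_vs_control=cand.fold_vs_control,
                local_background_ratio=cand.local_background_ratio,
                aid_dependent=True,
            )
        )
    sites.sort(key=lambda s: (s.chrom, s.called_window.start))
    for i, site in enumerate(sites):
        if site.name is None:
            site.name = f"dep{i:05d}"
    return sites


def call_aid_dependent(
    wt: TagLibrary,
    control: TagLibrary,
    chrom_sizes: ChromSizes,
    tiers: Union[str, Sequence[FilterTier]] = "exp1",
    window: int = 500,
    fold_threshold: float = 2.0,
    tag_floor: int = 10,
    pseudocount: float = 0.5,
    flank: int = 1000,
) -> List[NbsSite]:
    """Candidate calling plus tier filtering in one step."""
    cands = call_candidates(
        wt, control, chrom_sizes, window, fold_threshold, tag_floor, pseudocount
    )
    return apply_tier_filter(cands, tier_profile(tiers), wt, chrom_sizes, flank)


def call_aid_independent(
    wt: TagLibrary,
    control: TagLibrary,
    chrom_sizes: ChromSizes,
    window: int = 500,
    max_ratio: float = 1.4,
    tag_floor: int = 10,
    background_threshold: float = 4.0,
    pseudocount: float = 0.5,
    flank: int = 1000,
) -> List[NbsSite]:
    """Call sites enriched over local background in WT but NOT over control.

    Peaks are called against local background only (no control in the
    enrichment test); intervals whose library-normalized WT:control tag
    ratio exceeds ``max_ratio`` are then removed, leaving sites present in
    both libraries: the AID-independent set.
    """
    if control is None or control.library_size == 0:
        raise ValueError("control library required for the ratio filter")
    scale = wt.library_size / control.library_size
    sites = []
    for chrom in sorted(chrom_sizes):
        chrom_len = chrom_sizes[chrom]
        if chrom not in wt.tags or chrom_len <= window:
            continue
        shifted_wt = _shifted_positions(wt, chrom, chrom_len)
        if shifted_wt.size == 0:
            continue
        shifted_ctrl = _shifted_positions(control, chrom, chrom_len)
        wsum = _window_sums(shifted_wt, chrom_len, window)
        for start, wt_tags in _greedy_maxima(wsum, shifted_wt, chrom_len, window, tag_floor):
            bg = _background_ratio(
                shifted_wt, start, window, wt_tags, chrom_len, 10_000, pseudocount
            )
            if bg < background_threshold:
                continue
            ctrl = _count_sorted(shifted_ctrl, start, start + window)
            ctrl_norm = ctrl * scale
            ratio = wt_tags / (ctrl_norm + pseudocount)
            if ratio > max_ratio:
                continue
            sites.append(
                _make_site(
                    GenomeInterval(chrom, start, start + window),
                    wt,
                    chrom_sizes,
                    flank,
                    wt_tags=wt_tags,
                    control_tags_norm=ctrl_norm,
                    fold_vs_control=ratio,
                    local_background_ratio=bg,
                    aid_independent=True,
                )
            )
    sites.sort(key=lambda s: (s.chrom, s.called_window.start))
    for i, site in enumerate(sites):
        site.name = f"indep{i:05d}"
    return sites


# ---------------------------------------------------------------------------
# site serialization


def write_sites_bed(
    sites: Sequence[NbsSite],
    path: Union[str, Path],
    chrom_sizes: Optional[ChromSizes] = None,
) -> None:
    """BED6 of called 500-bp windows; score = WT tag count; flags in name.

    Name tokens: AID-dep|AID-indep, one-ended, orientation label.  Round
    trips through :func:`read_sites_bed` (coordinates and flags preserved).
    """
    with open(path, "w") as fh:
        for i, site in enumerate(sites):
            if chrom_sizes is not None:
                site.called_window.validate(chrom_sizes)
            tokens = [site.name or f"site{i:05d}"]
            tokens.append("AID-dep" if site.aid_dependent else "AID-indep")
            if site.one_ended:
                tokens.append("one-ended")
            if site.orientation:
                tokens.append(site.orientation)
            w = site.called_window
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{'|'.join(tokens)}\t{site.wt_tags}\t.\n")


def read_sites_bed(path: Union[str, Path], flank: int = 1000,
                   chrom_sizes: Optional[ChromSizes] = None) -> List[NbsSite]:
    sites = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, score, _strand = line.split("\t")[:6]
            tokens = name.split("|")
            window = GenomeInterval(chrom, int(start), int(end))
            aid_dep = "AID-indep" not in tokens
            orientation = next(
                (t for t in tokens if t in ("dsb_like", "tf_like", "indeterminate")),
                None,
            )
            sites.append(
                NbsSite(
                    called_window=window,
                    extended=extend_from_center(window, flank, chrom_sizes),
                    wt_tags=int(float(score)),
                    wt_plus=0,
                    wt_minus=0,
                    control_tags_norm=float("nan"),
                    fold_vs_control=float("nan"),
                    local_background_ratio=float("nan"),
                    aid_dependent=aid_dep,
                    aid_independent=not aid_dep,
                    one_ended="one-ended" in tokens or None,
                    orientation=orientation,
                    name=tokens[0],
                )
            )
    return sites


_TABLE_COLUMNS = [
    "name", "chrom", "window_start", "window_end", "ext_start", "ext_end",
    "wt_tags", "wt_plus", "wt_minus", "control_tags_norm", "fold_vs_control",
    "local_background_ratio", "aid_dependent", "aid_independent",
    "one_ended", "orientation",
]


def sites_to_frame(sites: Sequence[NbsSite]) -> pd.DataFrame:
    """One row per site; column semantics documented in the methods note."""
    rows = []
    for site in sites:
        rows.append(
            {
                "name": site.name,
                "chrom": site.chrom,
                "window_start": site.called_window.start,
                "window_end": site.called_window.end,
                "ext_start": site.extended.start,
                "ext_end": site.extended.end,
                "wt_tags": site.wt_tags,
                "wt_plus": site.wt_plus,
                "wt_minus": site.wt_minus,
                "control_tags_norm": site.control_tags_norm,
                "fold_vs_control": site.fold_vs_control,
                "local_background_ratio": site.local_background_ratio,
                "aid_dependent": site.aid_dependent,
                "aid_independent": site.aid_independent,
                "one_ended": site.one_ended,
                "orientation": site.orientation,
            }
        )
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def frame_to_sites(df: pd.DataFrame) -> List[NbsSite]:
    sites = []
    for _, row in df.iterrows():
        one_ended = row["one_ended"]
        if pd.isna(one_ended):
            one_ended = None
        else:
            one_ended = bool(one_ended)
        sites.append(
            NbsSite(
                called_window=GenomeInterval(
                    row["chrom"], int(row["window_start"]), int(row["window_end"])
                ),
                extended=GenomeInterval(
                    row["chrom"], int(row["ext_start"]), int(row["ext_end"])
                ),
                wt_tags=int(row["wt_tags"]),
                wt_plus=int(row["wt_plus"]),
                wt_minus=int(row["wt_minus"]),
                control_tags_norm=float(row["control_tags_norm"]),
                fold_vs_control=float(row["fold_vs_control"]),
                local_background_ratio=float(row["local_background_ratio"]),
                aid_dependent=bool(row["aid_dependent"]),
                aid_independent=bool(row["aid_independent"]),
                one_ended=one_ended,
                orientation=None if pd.isna(row["orientation"]) else row["orientation"],
                name=row["name"],
            )
        )
    return sites


def write_sites_table(sites: Sequence[NbsSite], path: Union[str, Path]) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)


def read_sites_table(path: Union[str, Path]) -> List[NbsSite]:
    return frame_to_sites(pd.read_csv(path, sep="\t"))
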