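"""Synthetic genomes, planted break sites, and ChIP-Seq tag libraries with
known truth, for end-to-end validation of the calling pipeline.

The generator emulates the statistical structure the pipeline assumes:

* a random-background genome (i.i.d. bases at a chosen GC content) carrying
  planted WGCW-pentamer arrays and CA dinucleotide arrays;
* nonspecific sonication background reads in both the WT and the control
  (knockout) library, the control sequenced deeper (default 3x);
* break-anchored reads: a two-ended break at position ``b`` piles
  minus-strand 5' ends at ``b - 1`` and plus-strand 5' ends at ``b``
  (small positional jitter), with a minority of reads coming from the
  sonicated fragment end roughly a fragment length away on the opposite
  strand; one-ended breaks emit a single side's pile only;
* AID-independent sites emitting reads into both libraries at matched
  enrichment, and transcription-factor-like sites with the mirrored
  orientation signature (plus tags left, minus tags right of the midpoint).

Tags are emitted directly as aligned genomic 5' positions: read alignment is
upstream of this pipeline, so no sequencing-error or mapping model is
applied.  Every artifact is a deterministic function of (config, seed).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .intervals import ChromSizes, GenomeInterval
from .peakcalling import NbsSite
from .preprocess import TagLibrary

__all__ = [
    "AID_DEP_TWO_ENDED",
    "AID_DEP_ONE_ENDED",
    "AID_INDEPENDENT",
    "TF_LIKE",
    "PlantedSite",
    "PlantedRepeat",
    "SimulationConfig",
    "SimulationTruth",
    "default_config",
    "simulate_genome",
    "simulate_reads",
    "write_genome_fasta",
    "write_truth",
    "load_truth_sites",
    "evaluate_recovery",
    "RecoveryReport",
]

AID_DEP_TWO_ENDED = "aid_dep_two_ended"
AID_DEP_ONE_ENDED = "aid_dep_one_ended"
AID_INDEPENDENT = "aid_independent"
TF_LIKE = "tf_like"
SITE_TYPES = (AID_DEP_TWO_ENDED, AID_DEP_ONE_ENDED, AID_INDEPENDENT, TF_LIKE)


@dataclass(frozen=True)
class PlantedSite:
    site_type: str
    chrom: str
    position: int
    expected_reads: float
    strand: Optional[str] = None  # strand carrying the pile, one-ended sites only

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if self.site_type == AID_DEP_ONE_ENDED and self.strand not in ("+", "-"):
            raise ValueError("one-ended sites need strand '+' or '-'")


@dataclass(frozen=True)
class PlantedRepeat:
    chrom: str
    start: int
    motif: str
    n_copies: int
    repeat_class: str
    mutation_rate: float = 0.02

    @property
    def length(self) -> int:
        return len(self.motif) * self.n_copies

    @property
    def interval(self) -> GenomeInterval:
        return GenomeInterval(
            self.chrom, self.start, self.start + self.length, name=self.repeat_class
        )


def _default_chroms() -> Dict[str, int]:
    return {"chr1": 5_000_000, "chr2": 5_000_000, "chr3": 5_000_000}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated experiment (defaults documented in
    the methods note)."""

    seed: int = 1
    chrom_lengths: Dict[str, int] = field(default_factory=_default_chroms)
    gc_content: float = 0.42
    background_rate: float = 0.002  # WT tags per bp
    control_depth_factor: float = 3.0
    fragment_length_mean: float = 200.0
    fragment_length_sd: float = 50.0
    read_length: int = 36
    jitter_sd: float = 5.0
    sonication_end_fraction: float = 0.1
    exact_split: bool = False
    min_site_separation: int = 5000
    sites: List[PlantedSite] = field(default_factory=list)
    repeats: List[PlantedRepeat] = field(default_factory=list)

    def chrom_sizes(self) -> ChromSizes:
        return ChromSizes(self.chrom_lengths)

    def validate(self) -> None:
        sizes = self.chrom_sizes()
        for site in self.sites:
            if not (0 <= site.position < sizes[site.chrom]):
                raise ValueError(f"site position outside chromosome: {site}")
        by_chrom: Dict[str, List[PlantedRepeat]] = {}
        for rep in self.repeats:
            if rep.start < 0 or rep.start + rep.length > sizes[rep.chrom]:
                raise ValueError(f"repeat outside chromosome: {rep}")
            by_chrom.setdefault(rep.chrom, []).append(rep)
        for chrom, reps in by_chrom.items():
            reps = sorted(reps, key=lambda r: r.start)
            for a, b in zip(reps, reps[1:]):
                if b.start < a.start + a.length:
                    raise ValueError(
                        f"planted repeats overlap on {chrom}: "
                        f"{a.start}+{a.length} and {b.start}"
                    )


@dataclass
class SimulationTruth:
    """Planted features keyed to the generating seed, for recovery scoring."""

    seed: int
    sites: List[PlantedSite]
    repeats: List[PlantedRepeat]

    def site_intervals(self, flank: int = 250) -> List[GenomeInterval]:
        return [
            GenomeInterval(
                s.chrom,
                max(0, s.position - flank),
                s.position + flank,
                name=s.site_type,
            )
            for s in self.sites
        ]


def _place_positions(
    rng: np.random.Generator,
    chrom_lengths: Dict[str, int],
    n: int,
    min_separation: int,
    edge_margin: int = 20_000,
    occupied: Optional[Dict[str, List[int]]] = None,
) -> List[Tuple[str, int]]:
    chroms = sorted(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    taken: Dict[str, List[int]] = {c: list(v) for c, v in (occupied or {}).items()}
    placed: List[Tuple[str, int]] = []
    while len(placed) < n:
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        pos = int(rng.integers(edge_margin, chrom_lengths[chrom] - edge_margin))
        if all(abs(pos - p) >= min_separation for p in taken.get(chrom, ())):
            taken.setdefault(chrom, []).append(pos)
            placed.append((chrom, pos))
    return placed


def default_config(
    seed: int = 1,
    n_two_ended: int = 100,
    n_one_ended: int = 10,
    n_independent: int = 20,
    n_tf_like: int = 10,
    site_reads: float = 30.0,
    **overrides,
) -> SimulationConfig:
    """The default study conditions: 100 AID-dependent two-ended sites, 10
    one-ended, 20 AID-independent and 10 TF-pattern sites (lambda = 30 WT
    site reads each) on a 3 x 5 Mb genome, with WGCW pentamer arrays planted
    at 40% and CA arrays at 25% of the two-ended sites plus unplanted-site
    (standalone) arrays elsewhere.
    """
    cfg = SimulationConfig(seed=seed, **overrides)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    total = n_two_ended + n_one_ended + n_independent + n_tf_like
    spots = _place_positions(
        rng, cfg.chrom_lengths, total, cfg.min_site_separation
    )
    sites: List[PlantedSite] = []
    i = 0
    for _ in range(n_two_ended):
        chrom, pos = spots[i]; i += 1
        sites.append(PlantedSite(AID_DEP_TWO_ENDED, chrom, pos, site_reads))
    for _ in range(n_one_ended):
        chrom, pos = spots[i]; i += 1
        strand = "+" if rng.random() < 0.5 else "-"
        sites.append(PlantedSite(AID_DEP_ONE_ENDED, chrom, pos, site_reads, strand))
    for _ in range(n_independent):
        chrom, pos = spots[i]; i += 1
        sites.append(PlantedSite(AID_INDEPENDENT, chrom, pos, site_reads))
    for _ in range(n_tf_like):
        chrom, pos = spots[i]; i += 1
        sites.append(PlantedSite(TF_LIKE, chrom, pos, site_reads))
    cfg.sites = sites

    repeats: List[PlantedRepeat] = []
    two_ended = [s for s in sites if s.site_type == AID_DEP_TWO_ENDED]
    n_wgcw = int(0.40 * len(two_ended))
    n_ca = int(0.25 * len(two_ended))
    for s in two_ended[:n_wgcw]:
        repeats.append(
            PlantedRepeat(s.chrom, s.position - 225, "CAGCA", 90, "WGCW")
        )
    for s in two_ended[n_wgcw : n_wgcw + n_ca]:
        repeats.append(PlantedRepeat(s.chrom, s.position - 160, "CA", 160, "CA"))
    indep = [s for s in sites if s.site_type == AID_INDEPENDENT]
    for s in indep[:2]:
        repeats.append(PlantedRepeat(s.chrom, s.position - 60, "CA", 60, "CA"))
    # standalone arrays at unplanted locations
    occupied = {}
    for chrom, pos in spots:
        occupied.setdefault(chrom, []).append(pos)
    standalone = _place_positions(
        rng, cfg.chrom_lengths, 20, cfg.min_site_separation, occupied=occupied
    )
    for j, (chrom, pos) in enumerate(standalone):
        if j % 2 == 0:
            repeats.append(PlantedRepeat(chrom, pos, "CAGCA", 90, "WGCW"))
        else:
            repeats.append(PlantedRepeat(chrom, pos, "CA", 160, "CA"))
    cfg.repeats = repeats
    cfg.validate()
    return cfg


def config_from_yaml(path: Union[str, Path], seed: Optional[int] = None) -> SimulationConfig:
    """Build a configuration from a YAML mapping of scalar overrides.

    Recognized keys: any :class:`SimulationConfig` scalar field plus the
    site-count keys of :func:`default_config` (``n_two_ended``,
    ``n_one_ended``, ``n_independent``, ``n_tf_like``, ``site_reads``) and
    ``chrom_lengths``.  A ``--seed`` given on the command line overrides a
    seed in the file.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    if seed is not None:
        raw["seed"] = seed
    file_seed = raw.pop("seed", 1)
    counts = {
        k: raw.pop(k)
        for k in ("n_two_ended", "n_one_ended", "n_independent", "n_tf_like", "site_reads")
        if k in raw
    }
    valid = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return default_config(seed=file_seed, **counts, **raw)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_genome(config: SimulationConfig) -> Tuple[Dict[str, str], SimulationTruth]:
    """Generate the genome sequence and the truth record.

    Background bases are i.i.d. at the configured GC content; planted arrays
    are written at their recorded positions with per-base point mutations at
    each array's mutation rate.  Byte-identical for a fixed config.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome: Dict[str, str] = {}
    arrays: Dict[str, np.ndarray] = {}
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        codes = rng.choice(4, size=length, p=probs)
        arrays[chrom] = _BASES[codes]
    for rep in config.repeats:
        motif = np.frombuffer(rep.motif.upper().encode(), dtype=np.uint8)
        tract = np.tile(motif, rep.n_copies)
        if rep.mutation_rate > 0:
            hit = np.flatnonzero(rng.random(tract.size) < rep.mutation_rate)
            for i in hit:
                others = _BASES[_BASES != tract[i]]
                tract[i] = others[int(rng.integers(0, others.size))]
        arrays[rep.chrom][rep.start : rep.start + tract.size] = tract
    for chrom, arr in arrays.items():
        genome[chrom] = arr.tobytes().decode("ascii")
    truth = SimulationTruth(
        seed=config.seed, sites=list(config.sites), repeats=list(config.repeats)
    )
    return genome, truth


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lower: float, n: int
) -> np.ndarray:
    draws = rng.normal(mean, sd, n)
    bad = draws < lower
    while np.any(bad):
        draws[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = draws < lower
    return draws


class _TagSink:
    def __init__(self) -> None:
        self.chunks: Dict[str, Dict[str, List[np.ndarray]]] = {}

    def add(self, chrom: str, strand: str, pos: np.ndarray) -> None:
        if pos.size:
            self.chunks.setdefault(chrom, {"+": [], "-": []})[strand].append(
                pos.astype(np.int64)
            )

    def library(self, read_length: int) -> TagLibrary:
        tags = {
            chrom: {
                s: np.concatenate(v) if v else np.empty(0, dtype=np.int64)
                for s, v in by_strand.items()
            }
            for chrom, by_strand in self.chunks.items()
        }
        return TagLibrary(tags=tags, read_length=read_length)


def _emit_break_side(
    rng: np.random.Generator,
    sink: _TagSink,
    cfg: SimulationConfig,
    chrom: str,
    b: int,
    side: str,
    n: int,
    chrom_len: int,
) -> None:
    """Reads for one side of a break: sharp DSB-end pile plus a minority of
    sonicated-end reads on the opposite strand ~1 fragment away."""
    if n <= 0:
        return
    sonic = rng.random(n) < cfg.sonication_end_fraction
    n_dsb = int((~sonic).sum())
    n_son = n - n_dsb
    if cfg.jitter_sd > 0:
        jitter = np.rint(rng.normal(0, cfg.jitter_sd, n_dsb)).astype(np.int64)
    else:
        jitter = np.zeros(n_dsb, dtype=np.int64)
    frag = np.rint(
        _truncated_normal(
            rng, cfg.fragment_length_mean, cfg.fragment_length_sd,
            cfg.read_length, n_son,
        )
    ).astype(np.int64)
    if side == "left":
        dsb_pos = b - 1 + jitter
        son_pos = b - frag
        dsb_strand, son_strand = "-", "+"
    else:
        dsb_pos = b + jitter
        son_pos = b + frag - 1
        dsb_strand, son_strand = "+", "-"
    sink.add(chrom, dsb_strand, np.clip(dsb_pos, 0, chrom_len - 1))
    sink.add(chrom, son_strand, np.clip(son_pos, 0, chrom_len - 1))


def _emit_site(
    rng: np.random.Generator,
    sink: _TagSink,
    cfg: SimulationConfig,
    site: PlantedSite,
    lam: float,
    chrom_len: int,
) -> None:
    if lam <= 0:
        return
    n = int(rng.poisson(lam)) if not cfg.exact_split else int(round(lam))
    if n == 0:
        return
    b = site.position
    if site.site_type == TF_LIKE:
        left = rng.random(n) < 0.5
        n_left = int(left.sum())
        frag_l = np.rint(
            _truncated_normal(rng, cfg.fragment_length_mean, cfg.fragment_length_sd,
                              cfg.read_length, n_left)
        ).astype(np.int64)
        frag_r = np.rint(
            _truncated_normal(rng, cfg.fragment_length_mean, cfg.fragment_length_sd,
                              cfg.read_length, n - n_left)
        ).astype(np.int64)
        sink.add(site.chrom, "+", np.clip(b - frag_l, 0, chrom_len - 1))
        sink.add(site.chrom, "-", np.clip(b + frag_r - 1, 0, chrom_len - 1))
        return
    if site.site_type == AID_DEP_ONE_ENDED:
        side = "right" if site.strand == "+" else "left"
        _emit_break_side(rng, sink, cfg, site.chrom, b, side, n, chrom_len)
        return
    # two-ended: reads split between the two fragment sides
    if cfg.exact_split:
        n_left = n // 2
    else:
        n_left = int(rng.binomial(n, 0.5))
    _emit_break_side(rng, sink, cfg, site.chrom, b, "left", n_left, chrom_len)
    _emit_break_side(rng, sink, cfg, site.chrom, b, "right", n - n_left, chrom_len)


def _emit_background(
    rng: np.random.Generator,
    sink: _TagSink,
    cfg: SimulationConfig,
    rate: float,
) -> None:
    """Nonspecific reads: one read from a random end of a uniformly placed
    sonication fragment, at ``rate`` tags per bp."""
    for chrom in sorted(cfg.chrom_lengths):
        length = cfg.chrom_lengths[chrom]
        n = int(rng.poisson(rate * length))
        if n == 0:
            continue
        starts = rng.integers(0, length, n)
        frag = np.rint(
            _truncated_normal(rng, cfg.fragment_length_mean, cfg.fragment_length_sd,
                              cfg.read_length, n)
        ).astype(np.int64)
        from_left = rng.random(n) < 0.5
        sink.add(chrom, "+", starts[from_left])
        sink.add(
            chrom, "-", np.clip(starts[~from_left] + frag[~from_left] - 1, 0, length - 1)
        )


def simulate_reads(
    config: SimulationConfig, truth: Optional[SimulationTruth] = None
) -> Tuple[TagLibrary, TagLibrary]:
    """Draw the WT and control tag libraries for a configured experiment.

    AID-dependent and TF-pattern sites emit reads into the WT library only;
    AID-independent sites emit into both, scaled by the control's depth
    factor so library-normalized enrichment matches.  Deterministic for a
    fixed config.
    """
    config.validate()
    sites = truth.sites if truth is not None else config.sites
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    wt_sink, ctrl_sink = _TagSink(), _TagSink()
    _emit_background(rng, wt_sink, config, config.background_rate)
    _emit_background(
        rng, ctrl_sink, config, config.background_rate * config.control_depth_factor
    )
    for site in sites:
        chrom_len = config.chrom_lengths[site.chrom]
        _emit_site(rng, wt_sink, config, site, site.expected_reads, chrom_len)
        if site.site_type == AID_INDEPENDENT:
            _emit_site(
                rng, ctrl_sink, config, site,
                site.expected_reads * config.control_depth_factor, chrom_len,
            )
    return (
        wt_sink.library(config.read_length),
        ctrl_sink.library(config.read_length),
    )


# ---------------------------------------------------------------------------
# artifacts


def write_genome_fasta(genome: Dict[str, str], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_truth(truth: SimulationTruth, out_dir: Union[str, Path]) -> None:
    """truth_sites.tsv + truth_repeats.bed, losslessly reloadable."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "chrom": [s.chrom for s in truth.sites],
            "position": [s.position for s in truth.sites],
            "site_type": [s.site_type for s in truth.sites],
            "strand": [s.strand or "." for s in truth.sites],
            "expected_reads": [s.expected_reads for s in truth.sites],
        }
    ).to_csv(out_dir / "truth_sites.tsv", sep="\t", index=False)
    with open(out_dir / "truth_repeats.bed", "w") as fh:
        for rep in truth.repeats:
            iv = rep.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"{rep.repeat_class}|{rep.motif}|{rep.n_copies}\t0\t.\n"
            )


def load_truth_sites(path: Union[str, Path]) -> List[PlantedSite]:
    df = pd.read_csv(path, sep="\t")
    return [
        PlantedSite(
            row["site_type"],
            row["chrom"],
            int(row["position"]),
            float(row["expected_reads"]),
            None if row["strand"] == "." else row["strand"],
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# recovery scoring


@dataclass
class RecoveryReport:
    n_called: int
    n_matched: int
    precision: float
    no_calls: bool
    recall_by_type: Dict[str, float]
    n_truth_by_type: Dict[str, int]
    confusion: pd.DataFrame  # truth type x called flag counts
    one_ended_accuracy: Optional[float]
    orientation_accuracy: Dict[str, float]
    matches: List[Tuple[int, int]]  # (called index, truth index)


def evaluate_recovery(
    called_sites: Sequence[NbsSite],
    truth: Union[SimulationTruth, Sequence[PlantedSite]],
    match_distance: int = 500,
    min_expected_reads: float = 0.0,
) -> RecoveryReport:
    """Score called sites against the planted truth.

    A called site matches a planted site when their centers are within
    ``match_distance`` bp; matching is one-to-one, greedy by distance.
    Recall is reported per planted type (restricted to sites with
    ``expected_reads >= min_expected_reads``), precision over all calls
    (reported as 1 with a flag when there are no calls).  Among matched
    sites, classification flags already present on the calls
    (``one_ended``, ``orientation``) are scored against the planted type.
    """
    planted = truth.sites if isinstance(truth, SimulationTruth) else list(truth)
    eligible = [s for s in planted if s.expected_reads >= min_expected_reads]
    pairs = []
    for ci, called in enumerate(called_sites):
        for ti, ts in enumerate(eligible):
            if ts.chrom != called.chrom:
                continue
            d = abs(called.center - ts.position)
            if d <= match_distance:
                pairs.append((d, ci, ti))
    pairs.sort()
    matched_called: Dict[int, int] = {}
    matched_truth: Dict[int, int] = {}
    for d, ci, ti in pairs:
        if ci in matched_called or ti in matched_truth:
            continue
        matched_called[ci] = ti
        matched_truth[ti] = ci

    n_called = len(called_sites)
    n_matched = len(matched_called)
    no_calls = n_called == 0
    precision = 1.0 if no_calls else n_matched / n_called

    recall_by_type: Dict[str, float] = {}
    n_truth_by_type: Dict[str, int] = {}
    for site_type in SITE_TYPES:
        idx = [i for i, t in enumerate(eligible) if t.site_type == site_type]
        n_truth_by_type[site_type] = len(idx)
        if idx:
            recall_by_type[site_type] = sum(i in matched_truth for i in idx) / len(idx)

    rows = []
    for ci, ti in matched_called.items():
        called = called_sites[ci]
        flag = "aid_dependent" if called.aid_dependent else "aid_independent"
        rows.append(
            {
                "truth_type": eligible[ti].site_type,
                "called_flag": flag,
                "one_ended": called.one_ended,
                "orientation": called.orientation,
            }
        )
    matched_df = pd.DataFrame(
        rows, columns=["truth_type", "called_flag", "one_ended", "orientation"]
    )
    confusion = (
        matched_df.groupby(["truth_type", "called_flag"]).size().unstack(fill_value=0)
        if len(matched_df)
        else pd.DataFrame()
    )

    one_ended_accuracy = None
    classified = matched_df[matched_df["one_ended"].notna()]
    if len(classified):
        expect = classified["truth_type"] == AID_DEP_ONE_ENDED
        one_ended_accuracy = float(
            (classified["one_ended"].astype(bool) == expect).mean()
        )

    # orientation is only diagnosed for sites not flagged one-ended (its
    # contract presumes a two-ended site); a spurious one-ended flag is
    # penalized in one_ended_accuracy, not double-counted here
    orientation_accuracy: Dict[str, float] = {}
    not_one_ended = matched_df["one_ended"].map(lambda v: v is not True)
    oriented = matched_df[matched_df["orientation"].notna() & not_one_ended]
    for truth_type, want in (
        (AID_DEP_TWO_ENDED, "dsb_like"),
        (AID_INDEPENDENT, "dsb_like"),
        (TF_LIKE, "tf_like"),
    ):
        sub = oriented[oriented["truth_type"] == truth_type]
        if len(sub):
            orientation_accuracy[truth_type] = float(
                (sub["orientation"] == want).mean()
            )

    return RecoveryReport(
        n_called=n_called,
        n_matched=n_matched,
        precision=precision,
        no_calls=no_calls,
        recall_by_type=recall_by_type,
        n_truth_by_type=n_truth_by_type,
        confusion=confusion,
        one_ended_accuracy=one_ended_accuracy,
        orientation_accuracy=orientation_accuracy,
        matches=sorted((ci, ti) for ci, ti in matched_called.items()),
    )
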