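"""End-to-end orchestration: dedup -> fragment length -> call -> filter ->
extend -> classify -> repeats -> intersections, with a single report.

Two entry points: :func:`run_pipeline` drives the stages over user-supplied
files, and :func:`run_simulation_study` runs the full loop on a synthetic
experiment with known truth and reports recovery metrics alongside the
biological summaries.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np

from .io import read_chrom_sizes, read_tags, write_chrom_sizes
from .peakcalling import (
    NbsSite,
    call_aid_dependent,
    call_aid_independent,
    call_candidates,
    write_sites_bed,
    write_sites_table,
)
from .preprocess import deduplicate, estimate_fragment_length, FragmentLengthError
from .repeats import genome_background, summarize_site
from .simulate import (
    SimulationConfig,
    default_config,
    evaluate_recovery,
    simulate_genome,
    simulate_reads,
    write_genome_fasta,
    write_truth,
)
from .strand import bias_distribution, classify_sites
from .intervalstats import randomization_test

logger = logging.getLogger("dsbmap")

__all__ = ["PipelineConfig", "run_pipeline", "run_simulation_study"]


@dataclass
class PipelineConfig:
    """Paths and thresholds for a file-driven run."""

    wt_path: Union[str, Path]
    control_path: Union[str, Path]
    chrom_sizes_path: Union[str, Path]
    out_dir: Union[str, Path]
    genome_path: Optional[Union[str, Path]] = None
    tiers: str = "exp1"
    mode: str = "both"  # dependent | independent | both
    max_duplicates: int = 1
    fragment_length: Optional[int] = None
    window: int = 500
    fold_threshold: float = 2.0
    tag_floor: int = 10
    max_ratio: float = 1.4
    bias_threshold_log2: float = 1.5
    flank: int = 1000

    def validate(self) -> None:
        if self.mode not in ("dependent", "independent", "both"):
            raise ValueError(f"mode must be dependent/independent/both, not {self.mode!r}")
        for label, p in (
            ("wt", self.wt_path),
            ("control", self.control_path),
            ("chrom.sizes", self.chrom_sizes_path),
        ):
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"missing {label} input: {p}")


def _prepare_library(path, chrom_sizes, max_duplicates, fragment_length):
    lib = deduplicate(read_tags(path, chrom_sizes), max_duplicates)
    if fragment_length is not None:
        lib.fragment_length = fragment_length
    else:
        lib.fragment_length = estimate_fragment_length(lib, chrom_sizes)
    return lib


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Run the calling stages over input files; returns the stage report.

    Outputs (site tables, BED, report.json) land in ``config.out_dir``.
    Any stage failure propagates with the stage named in the log.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: Dict[str, object] = {}

    logger.info("stage=read inputs")
    chrom_sizes = read_chrom_sizes(config.chrom_sizes_path)
    wt = _prepare_library(
        config.wt_path, chrom_sizes, config.max_duplicates, config.fragment_length
    )
    control = _prepare_library(
        config.control_path, chrom_sizes, config.max_duplicates, config.fragment_length
    )
    report["wt_library_size"] = wt.library_size
    report["control_library_size"] = control.library_size
    report["wt_fragment_length"] = wt.fragment_length
    logger.info(
        "stage=preprocess wt=%d control=%d fragment=%d",
        wt.library_size, control.library_size, wt.fragment_length,
    )

    sites: List[NbsSite] = []
    if config.mode in ("dependent", "both"):
        candidates = call_candidates(
            wt, control, chrom_sizes, config.window,
            config.fold_threshold, config.tag_floor,
        )
        report["n_candidates"] = len(candidates)
        dep = call_aid_dependent(
            wt, control, chrom_sizes, tiers=config.tiers, window=config.window,
            fold_threshold=config.fold_threshold, tag_floor=config.tag_floor,
            flank=config.flank,
        )
        report["n_aid_dependent"] = len(dep)
        logger.info("stage=call-dependent candidates=%d sites=%d", len(candidates), len(dep))
        sites.extend(dep)
    if config.mode in ("independent", "both"):
        indep = call_aid_independent(
            wt, control, chrom_sizes, window=config.window,
            max_ratio=config.max_ratio, tag_floor=config.tag_floor,
            flank=config.flank,
        )
        report["n_aid_independent"] = len(indep)
        logger.info("stage=call-independent sites=%d", len(indep))
        sites.extend(indep)

    classify_sites(sites, wt, bias_threshold_log2=config.bias_threshold_log2)
    if sites:
        _ratios, summary = bias_distribution(sites, wt, config.bias_threshold_log2)
        report["fraction_one_ended"] = summary["fraction_one_ended"]

    if config.genome_path is not None:
        from .io import read_fasta

        genome = read_fasta(config.genome_path)
        summaries = [summarize_site(s, genome) for s in sites]
        report["fraction_sites_wgcw"] = (
            float(np.mean([s.has_wgcw for s in summaries])) if summaries else 0.0
        )
        report["fraction_sites_ca"] = (
            float(np.mean([s.has_ca for s in summaries])) if summaries else 0.0
        )
        logger.info("stage=repeats sites=%d", len(summaries))

    write_sites_table(sites, out_dir / "sites.tsv")
    write_sites_bed(sites, out_dir / "sites.bed", chrom_sizes)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def run_simulation_study(
    sim_config: Optional[SimulationConfig] = None,
    seed: int = 1,
    tiers: str = "exp1",
    max_duplicates: int = 3,
    n_trials: int = 1000,
    n_background_intervals: int = 1000,
    out_dir: Optional[Union[str, Path]] = None,
) -> Dict[str, object]:
    """Simulate an experiment, run every pipeline stage, score against truth.

    Returns a flat report with site counts, recall/precision against the
    planted truth, the one-ended fraction and classifier accuracies, repeat
    class fractions at called sites vs the matched-random genome background,
    the WGCW-array co-occurrence permutation test, and the WT-vs-WT null
    call count.
    """
    cfg = sim_config if sim_config is not None else default_config(seed)
    chrom_sizes = cfg.chrom_sizes()
    logger.info("stage=simulate seed=%d", cfg.seed)
    genome, truth = simulate_genome(cfg)
    wt_raw, ctrl_raw = simulate_reads(cfg, truth)

    wt = deduplicate(wt_raw, max_duplicates)
    control = deduplicate(ctrl_raw, max_duplicates)
    wt.fragment_length = estimate_fragment_length(wt, chrom_sizes)
    try:
        control.fragment_length = estimate_fragment_length(control, chrom_sizes)
    except FragmentLengthError:
        control.fragment_length = wt.fragment_length
    logger.info(
        "stage=preprocess wt=%d control=%d fragment=%d",
        wt.library_size, control.library_size, wt.fragment_length,
    )

    dep = call_aid_dependent(wt, control, chrom_sizes, tiers=tiers)
    indep = call_aid_independent(wt, control, chrom_sizes)
    classify_sites(dep, wt)
    classify_sites(indep, wt)
    logger.info("stage=call dependent=%d independent=%d", len(dep), len(indep))

    recovery_dep = evaluate_recovery(dep, truth)
    recovery_all = evaluate_recovery(dep + indep, truth)
    _ratios, bias_summary = bias_distribution(dep, wt)

    summaries = [summarize_site(s, genome) for s in dep]
    frac_wgcw = float(np.mean([s.has_wgcw for s in summaries])) if summaries else 0.0
    frac_ca = float(np.mean([s.has_ca for s in summaries])) if summaries else 0.0
    frac_either = (
        float(np.mean([s.has_either for s in summaries])) if summaries else 0.0
    )

    templates = [(s.extended.chrom, s.extended.length) for s in dep] or None
    bg_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    background = genome_background(
        genome, chrom_sizes, n_intervals=n_background_intervals,
        templates=templates, seed=bg_rng,
    )

    wgcw_targets = [r.interval for r in truth.repeats if r.repeat_class == "WGCW"]
    dep_extended = [s.extended for s in dep]
    if dep_extended and wgcw_targets:
        stat_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
        co = randomization_test(
            dep_extended, wgcw_targets, chrom_sizes, n_trials=n_trials, seed=stat_rng
        )
        co_observed, co_p, co_enrichment = co.observed, co.p_value, co.enrichment
    else:
        co_observed, co_p, co_enrichment = 0, 1.0, float("nan")

    null_dep = call_aid_dependent(wt, wt, chrom_sizes, tiers=tiers)

    indep_in_dep = 0
    if len(recovery_dep.confusion) and "aid_independent" in recovery_dep.confusion.index:
        indep_in_dep = int(recovery_dep.confusion.loc["aid_independent"].sum())
    report: Dict[str, object] = {
        "seed": cfg.seed,
        "wt_library_size": wt.library_size,
        "control_library_size": control.library_size,
        "fragment_length_estimate": wt.fragment_length,
        "n_aid_dependent_sites": len(dep),
        "n_aid_independent_sites": len(indep),
        "recall_two_ended": recovery_all.recall_by_type.get("aid_dep_two_ended", 0.0),
        "recall_one_ended": recovery_all.recall_by_type.get("aid_dep_one_ended", 0.0),
        "recall_independent": recovery_all.recall_by_type.get("aid_independent", 0.0),
        "precision_dep": recovery_dep.precision,
        "independent_sites_in_dep_set": indep_in_dep,
        "one_ended_fraction": bias_summary["fraction_one_ended"],
        "one_ended_accuracy": recovery_all.one_ended_accuracy,
        "orientation_dsb_accuracy": recovery_all.orientation_accuracy.get(
            "aid_dep_two_ended", float("nan")
        ),
        "orientation_tf_accuracy": recovery_all.orientation_accuracy.get(
            "tf_like", float("nan")
        ),
        "fraction_sites_wgcw": frac_wgcw,
        "fraction_sites_ca": frac_ca,
        "fraction_sites_either": frac_either,
        "background_fraction_wgcw": background["fraction_wgcw"],
        "background_fraction_ca": background["fraction_ca"],
        "wgcw_overlap_observed": co_observed,
        "wgcw_overlap_p": co_p,
        "wgcw_overlap_enrichment": co_enrichment,
        "wt_vs_wt_null_sites": len(null_dep),
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_genome_fasta(genome, out_dir / "genome.fa")
        write_chrom_sizes(chrom_sizes, out_dir / "chrom.sizes")
        write_truth(truth, out_dir)
        write_sites_table(dep + indep, out_dir / "sites.tsv")
        write_sites_bed(dep + indep, out_dir / "sites.bed", chrom_sizes)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report
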