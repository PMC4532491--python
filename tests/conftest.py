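"""Shared fixtures: a full-size default simulation (session-scoped, used by
the end-to-end and classifier tests) and a small fast simulation for the
cheaper pipeline mechanics."""
from types import SimpleNamespace

import pytest

from dsbmap.peakcalling import call_aid_dependent, call_aid_independent
from dsbmap.preprocess import deduplicate, estimate_fragment_length
from dsbmap.simulate import default_config, simulate_genome, simulate_reads
from dsbmap.strand import classify_sites


def _run_study(cfg):
    genome, truth = simulate_genome(cfg)
    wt, control = simulate_reads(cfg, truth)
    wt = deduplicate(wt, 3)
    control = deduplicate(control, 3)
    chrom_sizes = cfg.chrom_sizes()
    wt.fragment_length = estimate_fragment_length(wt, chrom_sizes)
    control.fragment_length = wt.fragment_length
    dep = call_aid_dependent(wt, control, chrom_sizes)
    indep = call_aid_independent(wt, control, chrom_sizes)
    classify_sites(dep, wt)
    classify_sites(indep, wt)
    return SimpleNamespace(
        cfg=cfg,
        genome=genome,
        truth=truth,
        wt=wt,
        control=control,
        chrom_sizes=chrom_sizes,
        dep=dep,
        indep=indep,
    )


@pytest.fixture(scope="session")
def study():
    """The default study conditions at seed 1, run through every stage."""
    return _run_study(default_config(1))


def make_small_config(seed=5, **kwargs):
    defaults = dict(
        n_two_ended=15,
        n_one_ended=3,
        n_independent=4,
        n_tf_like=3,
        chrom_lengths={"chrA": 1_000_000, "chrB": 800_000},
    )
    defaults.update(kwargs)
    return default_config(seed, **defaults)


@pytest.fixture(scope="session")
def small_study():
    """A 1.8 Mb, 25-site simulation for fast mechanics tests."""
    return _run_study(make_small_config())
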