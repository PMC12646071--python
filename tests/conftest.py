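"""Shared fixtures: a tiny fast coalescent dataset for unit tests and the
desk-scale scenario replicate sets used by the validation tests.

All simulated inputs are generated at test time from fixed seeds; nothing
is stored on disk.
"""

from types import SimpleNamespace

import numpy as np
import pytest

import doubrcr as d

#: base seed for all fixture randomness
BASE_SEED = 90901

#: per-scenario seeds for the repeated estimator-coverage runs
N_COVERAGE_RUNS = 5


@pytest.fixture(scope="session")
def tiny_cfg():
    """A minutes-to-nothing panmictic scenario for unit-level checks."""
    return d.ScenarioConfig(
        name="tiny",
        n_demes=1,
        deme_size_initial=2e3,
        deme_size_current=2e3,
        expansion_time=0.0,
        migration_rate=0.0,
        samples_per_deme=20,
        genome_length=2e4,
        recombination_rate=1.8e-5,
        mutation_rate=1.125e-6,
        n_replicates=1,
    )


@pytest.fixture(scope="session")
def tiny_sim(tiny_cfg):
    return d.simulate_scenario(tiny_cfg, BASE_SEED)


@pytest.fixture(scope="session")
def tiny_pipeline(tiny_sim):
    gt, truth = tiny_sim
    classes = d.classify_sites(gt)
    bi = d.restrict_biallelic(gt)
    segs_d, stats_d = d.doubleton_segments(bi, classes)
    segs_nd, stats_nd = d.random_pair_segments(bi, classes, seed=7)
    return SimpleNamespace(
        gt=gt,
        truth=truth,
        classes=classes,
        bi=bi,
        segs_d=segs_d,
        segs_nd=segs_nd,
        stats_d=stats_d,
        stats_nd=stats_nd,
    )


def coverage_run_seeds(scenario_name: str) -> list:
    """Deterministic per-scenario seeds for the repeated validation runs."""
    offset = sorted(d.ESTIMATOR_SCENARIOS).index(scenario_name)
    return [BASE_SEED + 1000 * offset + k for k in range(N_COVERAGE_RUNS)]


@pytest.fixture(scope="session")
def desk_replicate_sets():
    """One simulated replicate set per desk scenario, shared across the
    pipeline-level validation tests.

    Maps scenario name -> (seed, replicates) where ``replicates`` is the
    pooled list of (GenotypeTable, truth) pairs that
    ``validate_calibration`` would simulate for that seed.
    """
    out = {}
    for i, name in enumerate(sorted(d.DESK_SCENARIOS)):
        cfg = d.DESK_SCENARIOS[name]
        seed = BASE_SEED + 77 * (i + 1)
        out[name] = (seed, d.simulate_replicates(cfg, seed))
    return out
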