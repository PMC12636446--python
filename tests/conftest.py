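"""Shared fixtures: small simulated cohorts, reused across test modules."""

import numpy as np
import pytest

from behaveseq.expression_io import drop_dead_genes, rpm_normalize
from behaveseq.synthetic_data import (
    BehaviorSimConfig,
    ExpressionSimConfig,
    gen_expression_cohort,
    gen_locomotion_track,
)

#: quick behavioral config: short stages keep per-track frame counts low
FAST_BEHAVIOR = dict(
    stage_durations=(60.0, 60.0, 60.0, 120.0),
    bout_durations=(15.0, 15.0, 15.0),
    hatch_delay=15.0,
)


@pytest.fixture(scope="session")
def fast_track():
    cfg = BehaviorSimConfig(seed=42, **FAST_BEHAVIOR)
    track, truth = gen_locomotion_track(cfg, 0)
    return cfg, track, truth


@pytest.fixture(scope="session")
def default_cohort():
    """Default cohort: 8 archetypes x 50 genes, NB dispersion 0.1, n=150."""
    cfg = ExpressionSimConfig(n_individuals=150, seed=9)
    counts, samples, truth = gen_expression_cohort(cfg)
    return cfg, counts, samples, truth


@pytest.fixture(scope="session")
def default_rpm(default_cohort):
    _, counts, samples, truth = default_cohort
    return rpm_normalize(drop_dead_genes(counts)), samples, truth


@pytest.fixture(scope="session")
def jittered_cohort():
    """Cohort with pre-stage jitter: hatch alignment strictly noisier."""
    cfg = ExpressionSimConfig(n_individuals=150, seed=3, prestage_jitter_sd=0.2)
    counts, samples, truth = gen_expression_cohort(cfg)
    return cfg, rpm_normalize(drop_dead_genes(counts)), samples, truth


@pytest.fixture(scope="session")
def noisefree_grid_cohort():
    """Noise-free, grid-sampled, parameter-diverse cohort (monotone gap curve)."""
    cfg = ExpressionSimConfig(
        n_individuals=193,
        seed=7,
        dispersion=0.0,
        param_diversity=True,
        sampling="grid",
        n_genes_per_archetype=500,
    )
    counts, samples, truth = gen_expression_cohort(cfg)
    return cfg, counts, samples, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
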