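"""Shared fixtures: one default synthetic study per session, written to disk
and pushed through every pipeline stage once, so tests can interrogate both
the raw artifacts and the stage outputs without re-simulating."""

from pathlib import Path

import pytest

from cistro.pipeline import STAGES, RunConfig, load_inputs
from cistro.simulate import SimulationConfig, simulate_study, write_study

SESSION_SEED = 11


@pytest.fixture(scope="session")
def study():
    """Default-condition synthetic study (500 genes, noise peaks off)."""
    return simulate_study(SimulationConfig(seed=SESSION_SEED))


@pytest.fixture(scope="session")
def study_dir(study, tmp_path_factory) -> Path:
    d = tmp_path_factory.mktemp("study")
    write_study(study, d)
    return d


@pytest.fixture(scope="session")
def pipeline_run(study, study_dir, tmp_path_factory):
    """All stages executed once; returns (config, inputs, ctx, out_dir)."""
    out = tmp_path_factory.mktemp("run")
    cfg = RunConfig(data_dir=str(study_dir), seed=SESSION_SEED)
    inputs = load_inputs(study_dir)
    ctx: dict = {}
    for _name, fn in STAGES:
        fn(cfg, inputs, ctx, out)
    return cfg, inputs, ctx, out


@pytest.fixture(scope="session")
def small_study():
    """A fast 80-gene study for tests that re-run the whole pipeline."""
    return simulate_study(SimulationConfig(seed=7, n_genes=80))
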