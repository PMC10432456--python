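"""Shared fixtures: miniature benchmarks and one full paper-like run."""

from __future__ import annotations

import numpy as np
import pytest

from maskstack.pipeline import PipelineResult, RunConfig, run_paper_like, simulate


@pytest.fixture(scope="session")
def fixture_config() -> RunConfig:
    return RunConfig.fixture(seed=0)


@pytest.fixture(scope="session")
def fixture_benchmarks(fixture_config):
    """Miniature 5-protein x 60-residue train/eval benchmark pair."""
    return simulate(fixture_config)


@pytest.fixture(scope="session")
def paper_run() -> PipelineResult:
    """One complete paper-like pipeline run (simulate, train, evaluate).

    Session-scoped: the 150-epoch training run is the most expensive step
    in the suite and every end-to-end check shares it.
    """
    return run_paper_like(seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_probability_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.dirichlet(np.full(20, 0.5))
    return v / v.sum()
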