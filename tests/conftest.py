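"""Shared fixtures.

The expensive artifacts — the thermoneutral steady state, the shared
chain evaluator (which caches repeated operating conditions), and the
full 60-point study — are session-scoped so every test reuses them.
"""

from __future__ import annotations

import pytest

from cabtherm import (
    ChainEvaluator,
    Microclimate,
    StudyConfig,
    load_cabin_params,
    load_physio_params,
    load_sensation_coeffs,
    run_study,
    steady_state,
)


@pytest.fixture(scope="session")
def params():
    return load_physio_params()


@pytest.fixture(scope="session")
def coeffs():
    return load_sensation_coeffs()


@pytest.fixture(scope="session")
def cabin_params():
    return load_cabin_params()


@pytest.fixture(scope="session")
def chain():
    """Default-configuration chain evaluator with a shared cache."""
    return ChainEvaluator(StudyConfig())


@pytest.fixture(scope="session")
def thermoneutral_env():
    return Microclimate.uniform(25.0, 0.1, rh=0.5)


@pytest.fixture(scope="session")
def thermoneutral_state(params, thermoneutral_env):
    state, converged = steady_state(thermoneutral_env, params)
    assert converged
    return state


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """The full 60-point study with the default configuration."""
    outdir = tmp_path_factory.mktemp("study")
    summary = run_study(StudyConfig(), outdir)
    return summary, outdir
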