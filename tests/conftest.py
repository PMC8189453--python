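"""Shared fixtures: wild-type and mutant steady states are expensive, so they
are computed once per session and reused across unit, property and acceptance
tests."""

from __future__ import annotations

import numpy as np
import pytest

from dorsalgrad import (
    ModelParameters,
    PRESET_SCENARIOS,
    SolverConfig,
    SpatialGrid,
    apply_scenario,
    integrate_to_steady_state,
)


@pytest.fixture(scope="session")
def wt_params() -> ModelParameters:
    """The calibrated wild-type dimensionless parameter set."""
    return ModelParameters()


@pytest.fixture(scope="session")
def grid50() -> SpatialGrid:
    return SpatialGrid(50)


@pytest.fixture(scope="session")
def solver_config() -> SolverConfig:
    return SolverConfig(method="bdf")


@pytest.fixture(scope="session")
def fast_solver() -> SolverConfig:
    return SolverConfig(method="pseudo")


@pytest.fixture(scope="session")
def wt_steady(wt_params, grid50, solver_config):
    """Wild-type steady state via the reference (BDF) route."""
    return integrate_to_steady_state(wt_params, grid50, solver_config)


@pytest.fixture(scope="session")
def mutant_steady(wt_params, grid50, fast_solver):
    """Steady states of the three quantified genotypes, keyed by preset name."""
    out = {}
    for name in ("dl6_heterozygote", "cactA2_cact011", "dl6_cactA2"):
        params = apply_scenario(wt_params, PRESET_SCENARIOS[name])
        out[name] = integrate_to_steady_state(params, grid50, fast_solver)
    return out
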