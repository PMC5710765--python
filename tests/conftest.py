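"""Shared fixtures: one default synthetic parameter set and the runs
derived from it, computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from medretain.params import build_hazard_schedule
from medretain.runmodel import evaluate_scenarios, results_frame
from medretain.states import build_state_space
from medretain.synthetic import generate_default_params
from medretain.uncertainty import run_psa

DEFAULT_SEED = 0


@pytest.fixture(scope="session")
def bundle():
    return generate_default_params(DEFAULT_SEED)


@pytest.fixture(scope="session")
def space():
    return build_state_space()


@pytest.fixture(scope="session")
def schedule(bundle):
    return build_hazard_schedule(bundle, n_cycles=52,
                                 n_cohorts=bundle.entry_plan.n_cohorts)


@pytest.fixture(scope="session")
def results_wp(bundle):
    """Deterministic evaluation of baseline + all 15 interventions,
    whole-population uptake."""
    return evaluate_scenarios(bundle)


@pytest.fixture(scope="session")
def frame_wp(results_wp):
    return results_frame(results_wp)


@pytest.fixture(scope="session")
def results_pp(bundle):
    return evaluate_scenarios(bundle, subgroup="pliant_patriots")


@pytest.fixture(scope="session")
def psa_draws(bundle):
    """A modest Monte-Carlo run shared by the CEA and acceptance tests."""
    return run_psa(bundle, n_draws=120, seed=11)
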