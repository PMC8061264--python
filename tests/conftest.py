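"""Shared fixtures: one full-scale simulated study reused across tests."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from perchmon import simulate_dataset
from perchmon.pipeline import run_pipeline
from perchmon.simdata import SeasonPlan, SimConfig


def small_config(**overrides) -> SimConfig:
    """A fast, reduced-scale study for unit tests (seconds, not minutes)."""
    base = dict(
        n_loci=300,
        n_founders_per_source=40,
        seasons=[
            SeasonPlan("2013/14", {"DxD": 3, "DxY": 0, "YxY": 2}, 3000),
            SeasonPlan("2014/15", {"DxD": 2, "DxY": 2, "YxY": 0}, 2000),
        ],
        translocations={2015: {"D": 60}},
        monitoring_years=(2016, 2017, 2018),
        n_reference_per_source=25,
        recruitment_rate=4.0,
        capture_prob_by_age=(0.002, 0.02, 0.02, 0.02, 0.02, 0.02),
        seed=1234,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def study():
    """The default full-scale synthetic study (the reference conditions)."""
    return simulate_dataset()


@pytest.fixture(scope="session")
def analysis(study):
    """Full pipeline run on the default study."""
    return run_pipeline(study, seed=7, n_sim_parentage=4000)


@pytest.fixture(scope="session")
def truth_index(study):
    """Convenience lookups from the truth ledger."""
    sample_to_fish = study.truth.sample_map.set_index("sample_id")["fish_id"]
    individuals = study.truth.individuals.set_index("fish_id")
    return sample_to_fish, individuals
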