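import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from spaceclock import (
    AgeMetricTable,
    compute_eaa,
    compute_ieaa,
    default_registry,
    simulate_cohort,
)

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def sim():
    """One default-condition synthetic mission cohort (seed 7)."""
    return simulate_cohort(7)


def year_table(sim, registry):
    return sim.clock_table[
        [c for c in sim.clock_table.columns if registry.units_of(c) == "years"]
    ]


def eaa_of(sim, registry) -> AgeMetricTable:
    return compute_eaa(year_table(sim, registry), sim.metadata)


def ieaa_of(sim, registry) -> AgeMetricTable:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return compute_ieaa(year_table(sim, registry), sim.metadata, sim.cell_fractions)


def write_inputs(sim, tmp_path):
    """Write a simulated cohort as the CSV inputs the pipeline reads."""
    from spaceclock.pipeline import write_simulation

    return write_simulation(sim, tmp_path, with_truth=False)


@pytest.fixture()
def small_meta():
    """Hand-built metadata: 2 subjects x 2 timepoints."""
    frame = pd.DataFrame(
        {
            "subject": ["A1", "A1", "A2", "A2"],
            "sex": [0, 0, 1, 1],
            "age": [67.7, 67.8, 34.6, 34.7],
            "timepoint": ["L-45", "FD+4", "L-45", "FD+4"],
        },
        index=["A1_L-45", "A1_FD+4", "A2_L-45", "A2_FD+4"],
    )
    frame.index.name = "sample_id"
    frame["timepoint"] = pd.Categorical(
        frame["timepoint"], categories=["L-45", "FD+4", "FD+7", "R+1", "R+7"], ordered=True
    )
    return frame
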