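import numpy as np
import pandas as pd
import pytest

from contambench import SimulationConfig, simulate_dilution_series
from contambench.community_data import AsvTable, SampleMetadata, SampleType


@pytest.fixture(scope="session")
def default_experiment():
    """The default seeded dilution-series experiment (shared, read-only)."""
    return simulate_dilution_series(SimulationConfig(seed=0))


@pytest.fixture
def tiny_table():
    """3 ASVs x 2 samples with column sums (6, 9)."""
    return AsvTable.from_arrays(
        ["a", "b", "c"], ["s1", "s2"], [[5, 0], [1, 2], [0, 7]]
    )


def make_metadata(sample_ids, concentrations, control_ids=()):
    records = []
    for i, (s, c) in enumerate(zip(sample_ids, concentrations)):
        is_control = s in control_ids
        records.append(
            SampleMetadata(
                sample_id=s,
                dilution_round=None if is_control else i,
                dna_concentration=c,
                sample_type=(
                    SampleType.NEGATIVE_CONTROL
                    if is_control
                    else SampleType.DILUTION_SAMPLE
                ),
            )
        )
    return records
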