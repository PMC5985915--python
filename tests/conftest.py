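import numpy as np
import pytest

from staterank import EstimateTable, StateEstimate


@pytest.fixture
def tiny_table() -> EstimateTable:
    """Three well-separated states (gaps far beyond the SEs)."""
    return EstimateTable(
        entries=(
            StateEstimate(state="Alpha", prevalence=30.0, se=0.5),
            StateEstimate(state="Beta", prevalence=20.0, se=0.5),
            StateEstimate(state="Gamma", prevalence=10.0, se=0.5),
        )
    )


@pytest.fixture
def degenerate_table() -> EstimateTable:
    """Zero-SE table: ranking should be exactly deterministic."""
    return EstimateTable(
        entries=(
            StateEstimate(state="Alpha", prevalence=12.0, se=0.0),
            StateEstimate(state="Beta", prevalence=9.0, se=0.0),
            StateEstimate(state="Gamma", prevalence=11.0, se=0.0),
            StateEstimate(state="Delta", prevalence=7.0, se=0.0),
        )
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
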