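import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from csflipidomics import FeatureTable, PipelineConfig, SimulationSpec, generate

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def tiny_table() -> FeatureTable:
    """3 compounds x 6 samples (2 control, 2 case, 2 qc), hand-built."""
    intensities = pd.DataFrame(
        {
            "S1": [10.0, 100.0, 1.0],
            "S2": [12.0, 110.0, np.nan],
            "S3": [20.0, 90.0, 2.0],
            "S4": [22.0, 95.0, 3.0],
            "Q1": [1.0, 4.0, 2.0],
            "Q2": [4.0, 16.0, 2.0],
        },
        index=pd.Index(["C1", "C2", "C3"], name="compound_id"),
    )
    samples = pd.DataFrame(
        {
            "role": ["control", "control", "case", "case", "qc", "qc"],
            "age": [50.0, 60.0, 55.0, 65.0, np.nan, np.nan],
            "sex": ["F", "M", "F", "M", None, None],
        },
        index=pd.Index(["S1", "S2", "S3", "S4", "Q1", "Q2"], name="sample_id"),
    )
    compounds = pd.DataFrame(
        {
            "name": ["PC 32:0", "TG 52:2", "SM 34:1"],
            "main_class": ["phosphatidylcholine", "triacylglycerol", "sphingomyelin"],
            "annotation_level": ["1", "1", "2a"],
            "is_biological": [True, True, True],
            "total_carbons": [32, 52, 34],
            "total_double_bonds": [0, 2, 1],
        },
        index=pd.Index(["C1", "C2", "C3"], name="compound_id"),
    )
    return FeatureTable(intensities, samples, compounds)


@pytest.fixture
def default_table():
    """A clean generated table (no injections) with its ground truth."""
    return generate(SimulationSpec(seed=42))


def make_table(seed: int = 0, **kwargs) -> tuple:
    return generate(SimulationSpec(seed=seed, **kwargs))
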