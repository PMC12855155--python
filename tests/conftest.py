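import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from rumencm import CountMatrix, SampleMetadata, simulate_neutral_slice

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """2 SGBs x 2 samples, the worked arithmetic example used throughout."""
    return CountMatrix(["sgb1", "sgb2"], ["S1", "S2"], np.array([[2, 3], [0, 5]]))


@pytest.fixture
def design_metadata() -> SampleMetadata:
    """2 groups x 4 timepoints x 10 animals (5 F + 5 G per group)."""
    rows = []
    for g in ("HFE", "LFE"):
        for k in range(10):
            for tp in ("D1", "D80", "D100", "D180"):
                rows.append({
                    "sample_id": f"{g}_A{k:02d}_{tp}",
                    "animal_id": f"{g}_A{k:02d}",
                    "diet": "F" if k < 5 else "G",
                    "fe_group": g,
                    "timepoint": tp,
                })
    df = pd.DataFrame(rows).set_index("sample_id")
    return SampleMetadata(df)


@pytest.fixture(scope="session")
def neutral_slice():
    """One medium neutral slice shared by read-only tests (Nm_true=1e4)."""
    cm, truth = simulate_neutral_slice(
        n_sgb=800, n_animals=10, Nm_true=1e4, depth_mean=1e5, seed=7)
    return cm, truth
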