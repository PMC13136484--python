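import numpy as np
import pandas as pd
import pytest

from nichemark import CellTable, GeneratorConfig, generate_sample, generate_study


@pytest.fixture()
def small_table() -> CellTable:
    """Hand-built 10-cell single-sample table with two mark channels."""
    n = 10
    df = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "sample_id": "s1",
            "x_um": [3.0, 10.0, 20.0, 33.0, 41.0, 8.0, 27.0, 38.0, 15.0, 45.0],
            "y_um": [4.0, 18.0, 7.0, 30.0, 12.0, 36.0, 22.0, 40.0, 28.0, 25.0],
            "volume_um3": np.linspace(100.0, 300.0, n),
            "marks_a": np.arange(1.0, n + 1),
            "marks_b": [5.0, 2.0, 9.0, 1.0, 7.0, 3.0, 8.0, 4.0, 10.0, 6.0],
        }
    )
    return CellTable(df, mark_channels=("marks_a", "marks_b"))


@pytest.fixture(scope="session")
def li_study():
    """Two-sample lateral-inhibition study at generator defaults."""
    cfg = GeneratorConfig(mark_model="lateral_inhibition", seed=7)
    return generate_study(cfg, n_samples=2, seed=7)


@pytest.fixture(scope="session")
def null_sample():
    """Single iid-null field at generator defaults."""
    return generate_sample(GeneratorConfig(mark_model="iid_null", seed=3))
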