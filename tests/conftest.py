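import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("default", deadline=None, max_examples=40, derandomize=True)
settings.load_profile("default")


@pytest.fixture
def noiseless_line_points() -> pd.DataFrame:
    """Exact points on engraftment = -50 + 50 * log10(t), crossing 50 % at t = 100 d."""
    days = np.array([10.0, 10**1.5, 100.0, 10**2.5, 1000.0])
    return pd.DataFrame(
        {
            "compartment": "LM",
            "days_post_transplant": days,
            "corrected_pct": -50.0 + 50.0 * np.log10(days),
        }
    )


@pytest.fixture
def control_table() -> pd.DataFrame:
    """Three male control samples with Y+ fractions 0.6, 0.7, 0.8 (mean 0.7)."""
    return pd.DataFrame(
        {
            "patient_id": ["M1", "M2", "M3"],
            "compartment": "LM",
            "marker": "Iba1",
            "days_post_transplant": [np.nan] * 3,
            "n_marker_pos": [10, 10, 10],
            "n_y_pos": [6, 7, 8],
            "is_male_control": True,
        }
    )
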