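import numpy as np
import pandas as pd
import pytest

from adjauc.dose_response import DoseResponseCurve, LogisticParams, predict_response

#: 8-point half-log dilution series topping at 8 uM (ascending, nM).
EIGHT_POINT = 8000.0 / 3.1623 ** np.arange(7, -1, -1)


def make_curve(params: LogisticParams, x=None, noise_sd=0.0, rng=None,
               ids=("S", "D", "C")) -> DoseResponseCurve:
    """Curve sampled from a known sigmoid, optionally with Gaussian noise."""
    x = EIGHT_POINT if x is None else np.asarray(x, dtype=float)
    y = predict_response(params, x)
    if noise_sd > 0:
        y = y + (rng or np.random.default_rng(0)).normal(0, noise_sd, x.size)
    return DoseResponseCurve(*ids, x, y)


@pytest.fixture
def rng():
    return np.random.default_rng(20160614)


@pytest.fixture
def screen_frame():
    """Minimal valid screen table: one curve, 5 concentrations."""
    return pd.DataFrame(
        {
            "study": ["S1"] * 5,
            "drug": ["DRUGX"] * 5,
            "cell_line": ["CL1"] * 5,
            "concentration_nM": [10.0, 100.0, 1000.0, 4000.0, 8000.0],
            "response": [2.0, 20.0, 55.0, 80.0, 92.0],
        }
    )
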