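import numpy as np
import pandas as pd
import pytest

from bloqreg.censoring import CensoredVector, apply_lloq


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def toy_cv():
    """Small censored vector: values 0.1c, 0.7, 0.59c, 0.9, 0.61 at LLOQ 0.6."""
    return apply_lloq(np.array([0.1, 0.7, 0.59, 0.9, 0.61]), 0.6)


@pytest.fixture
def toy_regression(rng):
    """A clean linear dataset y = 1 + 2x + 0.5z + noise with a censorable x."""
    n = 120
    x = rng.beta(8, 2, n)
    z = rng.normal(0, 1, n)
    y = 1.0 + 2.0 * x + 0.5 * z + rng.normal(0, 0.3, n)
    return pd.DataFrame({"y": y, "x": x, "z": z})


def make_censored_frame(df, var, lloq):
    cv = apply_lloq(df[var].to_numpy(), lloq)
    out = df.copy()
    out[var] = cv.values
    out[f"{var}_censored"] = cv.censored
    return out, cv
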