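import numpy as np
import pandas as pd
import pytest

from dsskit.curves import DoseResponseCurve, PlateControls
from dsskit.logistic import LogisticFit, predict_response


@pytest.fixture
def controls():
    return PlateControls(negative_mean=10000.0, positive_mean=2000.0)


@pytest.fixture
def reference_fit():
    """The canonical active curve: 0-100 %, IC50 = 100 nM, unit slope."""
    return LogisticFit(r_min=0.0, r_max=100.0, log_ic50=2.0, slope=1.0)


def make_curve(fit: LogisticFit, x=None, sample="s1", drug="d1") -> DoseResponseCurve:
    """Noiseless curve realized from a true 4PL on a log10 dose grid."""
    x = np.arange(5.0) if x is None else np.asarray(x, dtype=float)
    return DoseResponseCurve(sample, drug, 10.0 ** x, predict_response(fit, x))


@pytest.fixture
def drt_frame():
    """Long table: 2 samples x 3 drugs x 5 doses, noiseless active curves."""
    fit = LogisticFit(0.0, 100.0, 2.0, 1.0)
    rows = []
    for s in ("s1", "s2"):
        for d in ("d1", "d2", "d3"):
            for x in np.arange(5.0):
                rows.append((s, d, 10.0 ** x, predict_response(fit, x)))
    return pd.DataFrame(rows, columns=["sample_id", "drug_id", "concentration_nM", "response"])
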