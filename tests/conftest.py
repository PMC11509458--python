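import numpy as np
import pytest

from microstab.datasets import load_reference_tables
from microstab.stability import percent_remaining


@pytest.fixture(scope="session")
def ref():
    """Bundled reference tables of the dovitinib study."""
    return load_reference_tables()


@pytest.fixture(scope="session")
def depletion_profile(ref):
    """Reference depletion time-course normalized to time zero."""
    return percent_remaining(
        ref["depletion"][["time_min", "mean_conc_ng_per_ml"]]
    )


def wls_normal_equations(x, y, w):
    """Independent brute-force weighted least squares.

    Solves the 2x2 weighted normal equations directly and propagates the
    intercept standard error from the inverse matrix; used as the oracle
    against the fitted calibration line.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    A = np.array(
        [[np.sum(w), np.sum(w * x)], [np.sum(w * x), np.sum(w * x**2)]]
    )
    b = np.array([np.sum(w * y), np.sum(w * x * y)])
    intercept, slope = np.linalg.solve(A, b)
    resid = y - (intercept + slope * x)
    dof = len(x) - 2
    s2 = np.sum(w * resid**2) / dof if dof > 0 else np.nan
    cov = s2 * np.linalg.inv(A)
    return {
        "intercept": intercept,
        "slope": slope,
        "sd_intercept": np.sqrt(cov[0, 0]),
    }
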