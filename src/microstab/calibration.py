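"""Weighted linear calibration for LC-MS/MS response ratios.

A calibration curve maps nominal analyte concentration x (ng/mL) to the
measured response ratio y (analyte peak area / internal-standard peak
area).  Bioanalytical curves spanning three decades (here 1-3000 ng/mL)
have strongly heteroscedastic noise, so the fit supports the standard
weighting schemes ``1/x`` and ``1/x**2`` alongside ordinary least squares:
the weight w_i multiplies the squared residual of point i.

Detection and quantification limits follow the ICH convention based on
the standard error of the intercept:

    LOD = 3.3 * SD(intercept) / |slope|
    LOQ = 10  * SD(intercept) / |slope|

so LOQ/LOD = 10/3.3 identically whenever both derive from the same fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import (
    DegenerateDesignError,
    InputError,
    InvalidWeightingError,
    NonInvertibleFitError,
)

__all__ = [
    "WEIGHTINGS",
    "CalibrationStandard",
    "CalibrationCurve",
    "fit_calibration",
    "back_calculate",
    "lod_loq",
]

#: Canonical weighting-scheme names and their accepted aliases.
WEIGHTINGS = ("none", "1/x", "1/x2")

_WEIGHTING_ALIASES = {
    "none": "none",
    "ols": "none",
    "1/x": "1/x",
    "one_over_x": "1/x",
    "1/x2": "1/x2",
    "1/x^2": "1/x2",
    "1/x**2": "1/x2",
    "one_over_x2": "1/x2",
}


def _resolve_weighting(weighting: str) -> str:
    try:
        return _WEIGHTING_ALIASES[str(weighting).strip().lower()]
    except KeyError:
        raise InvalidWeightingError(
            f"unknown weighting {weighting!r}; expected one of {WEIGHTINGS}"
        ) from None


@dataclass(frozen=True)
class CalibrationStandard:
    """One calibration level: a nominal concentration and its replicate
    response ratios.

    Parameters
    ----------
    nominal_conc : float
        Nominal concentration in ng/mL; must be positive.
    responses : sequence of float
        Response ratio (analyte area / IS area) per replicate;
        finite and non-negative.
    """

    nominal_conc: float
    responses: tuple[float, ...] = field(default=())

    def __post_init__(self):
        object.__setattr__(self, "responses", tuple(float(r) for r in self.responses))
        if not np.isfinite(self.nominal_conc) or self.nominal_conc <= 0:
            raise InputError(
                f"nominal_conc must be finite and > 0, got {self.nominal_conc}"
            )
        if len(self.responses) == 0:
            raise InputError("a calibration standard needs at least one response")
        arr = np.asarray(self.responses, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise InputError("responses must be finite and >= 0")


def _expand_standards(
    standards: Iterable[CalibrationStandard],
) -> tuple[np.ndarray, np.ndarray]:
    """Flatten standards so each replicate is its own regression point."""
    xs, ys = [], []
    for std in standards:
        for r in std.responses:
            xs.append(std.nominal_conc)
            ys.append(r)
    return np.asarray(xs, dtype=float), np.asarray(ys, dtype=float)


class CalibrationCurve(RegressorMixin, BaseEstimator):
    """Weighted least-squares calibration line ``response = slope*x + intercept``.

    Parameters
    ----------
    weighting : {"none", "1/x", "1/x2"}, default "1/x"
        Weight applied to each squared residual.  ``1/x`` is the common
        choice for bioanalytical curves with proportional noise.

    Attributes
    ----------
    slope_ : float
        Response ratio per ng/mL.
    intercept_ : float
        Response ratio at zero concentration.
    r_squared_ : float
        Weighted coefficient of determination (about the weighted mean);
        reduces to the OLS r**2 when all weights are equal.
    sd_intercept_ : float
        Standard error of the intercept from the weighted normal equations.
    lod_ : float
        Limit of detection, 3.3 * sd_intercept / |slope| (ng/mL).
    loq_ : float
        Limit of quantification, 10 * sd_intercept / |slope| (ng/mL).
    n_points_ : int
        Number of replicate points entering the regression.

    Examples
    --------
    >>> stds = [CalibrationStandard(c, (2.0 * c,)) for c in (1, 10, 100)]
    >>> fit = CalibrationCurve(weighting="1/x").fit(stds)
    >>> round(fit.slope_, 12), round(fit.intercept_, 12)
    (2.0, 0.0)
    >>> fit.back_calculate(20.0)
    10.0
    """

    def __init__(self, weighting: str = "1/x"):
        self.weighting = weighting

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y=None) -> "CalibrationCurve":
        """Fit the line.

        ``X`` may be a list of :class:`CalibrationStandard` (with ``y``
        omitted), or an array of concentrations with ``y`` the matching
        response ratios.
        """
        scheme = _resolve_weighting(self.weighting)
        if y is None:
            stds = list(X)
            if not all(isinstance(s, CalibrationStandard) for s in stds):
                raise InputError(
                    "without y, X must be a list of CalibrationStandard"
                )
            x, resp = _expand_standards(stds)
        else:
            x = np.asarray(X, dtype=float).reshape(-1)
            resp = np.asarray(y, dtype=float).reshape(-1)
            if x.shape != resp.shape:
                raise InputError("X and y must have matching lengths")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(resp))):
            raise InputError("calibration data must be finite")

        if len(np.unique(x)) < 3:
            raise DegenerateDesignError(
                f"need >= 3 distinct concentration levels, got {len(np.unique(x))}"
            )
        if np.var(x) == 0:
            raise DegenerateDesignError("zero variance in nominal concentrations")
        if scheme != "none" and np.any(x <= 0):
            raise InvalidWeightingError(
                f"weighting {scheme!r} requires all concentrations > 0"
            )

        if scheme == "none":
            w = np.ones_like(x)
        elif scheme == "1/x":
            w = 1.0 / x
        else:  # 1/x2
            w = 1.0 / x**2

        design = sm.add_constant(x)
        res = sm.WLS(resp, design, weights=w).fit()
        self.weighting_ = scheme
        self.intercept_ = float(res.params[0])
        self.slope_ = float(res.params[1])
        self.r_squared_ = float(res.rsquared)
        self.sd_intercept_ = float(res.bse[0])
        self.lod_, self.loq_ = lod_loq(self.sd_intercept_, self.slope_)
        self.n_points_ = int(len(x))
        return self

    # -- prediction --------------------------------------------------------

    def predict(self, X) -> np.ndarray:
        """Predict response ratios from concentrations."""
        self._check_fitted()
        x = np.asarray(X, dtype=float)
        return self.slope_ * x + self.intercept_

    def back_calculate(self, response):
        """Invert the line: concentration = (response - intercept) / slope.

        Sub-blank responses yield negative concentrations, returned as-is
        so accuracy statistics stay unbiased; truncation is the caller's
        decision.
        """
        self._check_fitted()
        if self.slope_ == 0:
            raise NonInvertibleFitError("slope is zero; curve is not invertible")
        response = np.asarray(response, dtype=float)
        out = (response - self.intercept_) / self.slope_
        return float(out) if out.ndim == 0 else out

    def _check_fitted(self):
        if not hasattr(self, "slope_"):
            raise NonInvertibleFitError("calibration curve is not fitted")


def fit_calibration(
    standards: Sequence[CalibrationStandard], weighting: str = "1/x"
) -> CalibrationCurve:
    """Fit a weighted calibration line; thin wrapper over
    :class:`CalibrationCurve`."""
    return CalibrationCurve(weighting=weighting).fit(standards)


def back_calculate(fit: CalibrationCurve, response):
    """Back-calculate concentration(s) from response ratio(s)."""
    return fit.back_calculate(response)


def lod_loq(sd_intercept: float, slope: float) -> tuple[float, float]:
    """ICH detection and quantification limits from the intercept SE and slope.

    Returns ``(3.3*sd/|slope|, 10*sd/|slope|)`` in concentration units.
    """
    if slope == 0:
        raise NonInvertibleFitError("slope is zero; LOD/LOQ undefined")
    if sd_intercept < 0:
        raise InputError("sd_intercept must be >= 0")
    return 3.3 * sd_intercept / abs(slope), 10.0 * sd_intercept / abs(slope)
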