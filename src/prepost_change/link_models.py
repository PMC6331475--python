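"""Link functions between average-based and individual-based change.

Within one simulation condition, each simulated sample yields a pair
(abc, ibc): an effect size on the horizontal axis (d or omega-squared) and a
percentage of reliable individual changes on the vertical axis.  Four
families are fit to these pairs, always with the percentage as the response:

* linear, quadratic, cubic — ordinary least squares on polynomial terms;
* logistic — ``ibc = 100 / (1 + exp(-(b0 + b1*abc)))``, a two-parameter
  curve with asymptotes pinned at 0 and 100, fit by nonlinear least squares
  with multi-start initialization.

Goodness of fit is reported as ``R^2 = 1 - SSE/SST`` on the raw percentage
scale for every family, so families are directly comparable.  Predictions
are clipped to the attainable range of the response: [0, 100] for a single
group percentage, [-100, 100] for a net percentage.

``LinkFunctionRegressor`` is a scikit-learn estimator (fit/predict,
get_params/set_params, clone- and pipeline-compatible); the module-level
functions are thin wrappers around it.  ``convert_effect_to_percentage``
applies a packaged table of published linear coefficients so an effect size
can be translated into an approximate percentage without raw data.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from ._exceptions import FitError
from .synthetic_cohorts import MomentSpec, SHAPE_NAMES

__all__ = [
    "FAMILIES",
    "LinkFunctionFit",
    "LinkFunctionRegressor",
    "fit_link",
    "predict_percentage",
    "convert_effect_to_percentage",
    "load_coefficient_table",
    "select_coefficients",
]

FAMILIES = ("linear", "quadratic", "cubic", "logistic")
_N_COEF = {"linear": 2, "quadratic": 3, "cubic": 4, "logistic": 2}


@dataclass(frozen=True)
class LinkFunctionFit:
    """A fitted link function: family, coefficients (B0, B1, ...), classical
    standard errors, R^2 on the percentage scale, and the number of points."""

    family: str
    coefficients: tuple[float, ...]
    standard_errors: tuple[float, ...] = field(default=())
    r_squared: float = float("nan")
    n_points: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if len(self.coefficients) != _N_COEF[self.family]:
            raise ValueError(
                f"{self.family} needs {_N_COEF[self.family]} coefficients, "
                f"got {len(self.coefficients)}"
            )

    def predict(self, abc) -> np.ndarray:
        """Evaluate the family at abc (unclipped)."""
        x = np.asarray(abc, dtype=float)
        b = self.coefficients
        if self.family == "logistic":
            return 100.0 / (1.0 + np.exp(-(b[0] + b[1] * x)))
        return sum(bk * x**k for k, bk in enumerate(b))

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "coefficients": list(self.coefficients),
            "standard_errors": list(self.standard_errors),
            "r_squared": self.r_squared,
            "n_points": self.n_points,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinkFunctionFit":
        return cls(
            family=d["family"],
            coefficients=tuple(d["coefficients"]),
            standard_errors=tuple(d.get("standard_errors", ())),
            r_squared=d.get("r_squared", float("nan")),
            n_points=d.get("n_points", 0),
        )


def _logistic(x, b0, b1):
    return 100.0 / (1.0 + np.exp(-(b0 + b1 * x)))


class LinkFunctionRegressor(RegressorMixin, BaseEstimator):
    """Regression of an IBC percentage on an ABC effect size.

    Parameters
    ----------
    family : {"linear", "quadratic", "cubic", "logistic"}
        Functional form; polynomial families are fit by OLS, the logistic
        family by nonlinear least squares.
    clip : tuple of (low, high) or None
        Range the predictions are clipped to; (0, 100) for single-group
        percentages, (-100, 100) for net percentages, None to disable.

    Attributes
    ----------
    coefficients_ : ndarray, (B0, B1, ...).
    standard_errors_ : ndarray, classical standard errors.
    r_squared_ : float, 1 - SSE/SST on the percentage scale.
    n_points_ : int, number of (abc, ibc) pairs fit.
    """

    def __init__(self, family: str = "linear", clip: tuple | None = (0.0, 100.0)):
        self.family = family
        self.clip = clip

    # -- sklearn plumbing ---------------------------------------------------
    def _validate_xy(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2 or X.shape[1] != 1:
            raise ValueError("X must be a single column of effect sizes")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        if y is None:
            return X.ravel()
        y = np.asarray(y, dtype=float)
        if y.shape != (X.shape[0],):
            raise ValueError("y must be one percentage per row of X")
        if not np.all(np.isfinite(y)):
            raise ValueError("y contains non-finite values")
        return X.ravel(), y

    def fit(self, X, y):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        x, y = self._validate_xy(X, y)
        k = _N_COEF[self.family]
        if x.size < k:
            raise FitError(f"{self.family} fit needs at least {k} points, got {x.size}")
        sst = float(np.sum((y - y.mean()) ** 2))
        if sst <= 0.0:
            raise FitError("response is constant; R^2 is undefined")
        if self.family == "logistic":
            coef, se, fitted = self._fit_logistic(x, y)
        else:
            coef, se, fitted = self._fit_polynomial(x, y, degree=k - 1)
        sse = float(np.sum((y - fitted) ** 2))
        self.coefficients_ = coef
        self.standard_errors_ = se
        self.r_squared_ = 1.0 - sse / sst
        self.n_points_ = int(x.size)
        self.n_features_in_ = 1
        return self

    @staticmethod
    def _fit_polynomial(x, y, degree):
        design = np.vander(x, degree + 1, increasing=True)
        if np.linalg.matrix_rank(design) < degree + 1:
            raise FitError(
                f"rank-deficient design for degree-{degree} polynomial "
                "(effect sizes do not span enough distinct values)"
            )
        res = sm.OLS(y, design).fit()
        return np.asarray(res.params), np.asarray(res.bse), res.fittedvalues

    @staticmethod
    def _fit_logistic(x, y):
        # Multi-start over plausible midpoints/slopes; keep the best SSE.
        best = None
        spread = float(x.std()) or 1.0
        for b1 in (0.5 / spread, 1.0, 2.0):
            for mid in (x.mean(), np.median(x), x.mean() + spread):
                try:
                    popt, pcov = curve_fit(
                        _logistic, x, y, p0=[-b1 * mid, b1], maxfev=20000
                    )
                except RuntimeError:
                    continue
                sse = float(np.sum((y - _logistic(x, *popt)) ** 2))
                if best is None or sse < best[2]:
                    best = (popt, pcov, sse)
        if best is None:
            raise FitError(
                "logistic fit did not converge from any starting point; "
                "the response may not span the 0-100 range"
            )
        popt, pcov, _ = best
        se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(2, np.nan)
        return np.asarray(popt), se, _logistic(x, *popt)

    def predict(self, X):
        x = self._validate_xy(X)
        raw = self.to_fit().predict(x)
        if self.clip is not None:
            raw = np.clip(raw, self.clip[0], self.clip[1])
        return raw

    def to_fit(self) -> LinkFunctionFit:
        """Export the fitted state as an immutable :class:`LinkFunctionFit`."""
        if not hasattr(self, "coefficients_"):
            raise FitError("regressor is not fitted")
        return LinkFunctionFit(
            family=self.family,
            coefficients=tuple(float(c) for c in self.coefficients_),
            standard_errors=tuple(float(s) for s in self.standard_errors_),
            r_squared=float(self.r_squared_),
            n_points=self.n_points_,
        )


def fit_link(points, family: str = "linear", clip=None) -> LinkFunctionFit:
    """Fit one family to (abc, ibc) pairs and return the immutable result."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an iterable of (abc, ibc) pairs")
    reg = LinkFunctionRegressor(family=family, clip=clip)
    reg.fit(pts[:, 0], pts[:, 1])
    return reg.to_fit()


def predict_percentage(
    fit: LinkFunctionFit, abc: float, clip_range: tuple = (0.0, 100.0)
) -> float:
    """Evaluate a fitted link at one effect size, clipped to the attainable
    percentage range (values below/above are replaced by the limits)."""
    raw = float(fit.predict(abc))
    return float(min(max(raw, clip_range[0]), clip_range[1]))


def load_coefficient_table() -> pd.DataFrame:
    """Packaged linear-link coefficients keyed by (design, shape, rho)."""
    ref = importlib.resources.files("prepost_change").joinpath(
        "data/linear_coefficients.csv"
    )
    with ref.open() as fh:
        return pd.read_csv(fh, comment="#")


def _as_shape(shape) -> MomentSpec:
    if isinstance(shape, MomentSpec):
        return shape
    if isinstance(shape, str):
        try:
            return SHAPE_NAMES[shape]
        except KeyError:
            raise ValueError(
                f"unknown shape name {shape!r}; choose from {sorted(SHAPE_NAMES)}"
            ) from None
    g1, g2 = shape
    return MomentSpec(0.0, 1.0, float(g1), float(g2))


def select_coefficients(
    statistic: str,
    shape=(0.0, 0.0),
    rho: float = 0.5,
    table: pd.DataFrame | None = None,
) -> pd.Series:
    """Row of the coefficient table nearest to the requested condition.

    The estimate degrades gracefully: coefficients vary little across
    conditions, so a neighbouring row still gives a close percentage.
    """
    if statistic == "d":
        design = "single_group"
    elif statistic == "omega_squared":
        design = "control_group"
    else:
        raise ValueError(f"statistic must be 'd' or 'omega_squared', got {statistic!r}")
    if table is None:
        table = load_coefficient_table()
    spec = _as_shape(shape)
    rows = table[table["design"] == design]
    if rows.empty:
        raise ValueError(f"coefficient table has no rows for design {design!r}")
    dist = (
        (rows["skewness"] - spec.skewness) ** 2
        + ((rows["excess_kurtosis"] - spec.excess_kurtosis) / 6.0) ** 2
        + (rows["rho"] - rho) ** 2
    )
    return rows.loc[dist.idxmin()]


def convert_effect_to_percentage(
    abc_value: float,
    statistic: str = "d",
    shape=(0.0, 0.0),
    rho: float = 0.5,
    table: pd.DataFrame | None = None,
) -> float:
    """Translate a published effect size into an approximate percentage of
    reliable individual changes via the packaged linear coefficients.

    d maps to the single-group percentage (clipped to [0, 100]);
    omega-squared maps to the net percentage (clipped to [-100, 100]).
    """
    row = select_coefficients(statistic, shape=shape, rho=rho, table=table)
    fit = LinkFunctionFit(
        family="linear", coefficients=(float(row["b0"]), float(row["b1"]))
    )
    clip = (0.0, 100.0) if statistic == "d" else (-100.0, 100.0)
    return predict_percentage(fit, abc_value, clip_range=clip)
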