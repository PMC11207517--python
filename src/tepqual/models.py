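"""TEP-response models for fruit-quality indices and their validation statistics.

Three fixed model forms relate a quality index y to cumulative TEP X:

* ``log``       y = a ln(X) + b          (soluble sugar, sugar-acid ratio)
* ``linear``    y = a X + b              (organic acid, decreasing)
* ``logistic``  y = K / (1 + exp(-r (X - X0)))   (comprehensive quality)

Goodness of fit is reported as the coefficient of determination
R^2 = 1 - SS_res/SS_tot and the root mean square error with denominator n
(the population form, matching how crop models are conventionally validated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import FittingError, InputError

FORMS = ("log", "linear", "logistic")

_PARAM_NAMES = {
    "log": ("a", "b"),
    "linear": ("a", "b"),
    "logistic": ("K", "r", "X0"),
}


def rmse(simulated, observed) -> float:
    """Root mean square error sqrt(sum((SIM - OBS)^2) / n)."""
    sim = np.asarray(simulated, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if sim.shape != obs.shape:
        raise InputError(f"length mismatch: {sim.shape} vs {obs.shape}")
    if sim.size == 0:
        raise InputError("need at least one pair")
    return float(np.sqrt(np.mean((sim - obs) ** 2)))


def r_squared(simulated, observed) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot about the observed mean."""
    sim = np.asarray(simulated, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if sim.shape != obs.shape:
        raise InputError("length mismatch")
    if obs.size < 2:
        raise InputError("need at least two pairs")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise InputError("observed values are constant; R^2 undefined")
    ss_res = float(np.sum((sim - obs) ** 2))
    return 1.0 - ss_res / ss_tot


def pearson_r(x, y) -> float:
    """Sample Pearson product-moment correlation in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("length mismatch")
    if x.size < 3:
        raise InputError("need at least three pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("constant input; correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def _logistic(x, k, r, x0):
    return k / (1.0 + np.exp(np.clip(-r * (x - x0), -500.0, 500.0)))


@dataclass(frozen=True)
class FittedModel:
    """A fitted response-model form with resubstitution fit statistics."""

    form: str
    params: np.ndarray
    r_squared: float
    rmse: float
    n: int

    @property
    def param_names(self) -> tuple:
        return _PARAM_NAMES[self.form]

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        if self.form == "log":
            a, b = self.params
            return a * np.log(x) + b
        if self.form == "linear":
            a, b = self.params
            return a * x + b
        return _logistic(x, *self.params)

    def to_dict(self) -> dict:
        return {
            "form": self.form,
            "params": dict(zip(self.param_names, map(float, self.params))),
            "r_squared": self.r_squared,
            "rmse": self.rmse,
            "n": self.n,
        }


class TepResponseRegressor(RegressorMixin, BaseEstimator):
    """Least-squares regressor for the fixed TEP-response forms.

    The ``log`` and ``linear`` forms reduce to ordinary linear regression on
    the (transformed) regressor.  The ``logistic`` form is fitted by
    nonlinear least squares from the deterministic initialization
    K0 = 1.05 max(y), r0 = 4 / range(x), X0_0 = median(x), with up to
    ``max_restarts`` seeded jittered restarts on non-convergence.

    Fitted attributes: ``params_``, ``r_squared_``, ``rmse_``, ``n_``.
    """

    def __init__(self, form: str = "log", max_restarts: int = 20, random_state: int = 0):
        self.form = form
        self.max_restarts = max_restarts
        self.random_state = random_state

    @staticmethod
    def _as_1d(X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise InputError("expected a single regressor column")
            x = x[:, 0]
        if x.ndim != 1:
            raise InputError("X must be 1-D or a single column")
        return x

    def fit(self, X, y):
        if self.form not in FORMS:
            raise InputError(f"unknown form {self.form!r}; choose from {FORMS}")
        x = self._as_1d(X)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise InputError("X and y lengths differ")
        n_params = len(_PARAM_NAMES[self.form])
        if len(x) < n_params + 1:
            raise InputError(f"need at least {n_params + 1} points for the {self.form} form")

        if self.form in ("log", "linear"):
            if self.form == "log":
                if np.any(x <= 0):
                    raise InputError("log form requires positive X")
                regressor = np.log(x)
            else:
                regressor = x
            design = np.column_stack([regressor, np.ones_like(regressor)])
            params, *_ = np.linalg.lstsq(design, y, rcond=None)
        else:
            params = self._fit_logistic(x, y)

        self.params_ = params
        pred = FittedModel(self.form, params, 0.0, 0.0, len(x)).predict(x)
        self.r_squared_ = r_squared(pred, y)
        self.rmse_ = rmse(pred, y)
        self.n_ = len(x)
        self.n_features_in_ = 1
        return self

    def _fit_logistic(self, x, y) -> np.ndarray:
        span = np.ptp(x)
        if span == 0:
            raise InputError("x has zero range; logistic fit undefined")
        p0 = np.array([1.05 * y.max(), 4.0 / span, np.median(x)])
        rng = np.random.default_rng(self.random_state)
        last_error = None
        for attempt in range(self.max_restarts + 1):
            start = p0 if attempt == 0 else p0 * rng.uniform(0.5, 1.5, size=3)
            try:
                params, _ = optimize.curve_fit(_logistic, x, y, p0=start, maxfev=20_000)
                return params
            except (RuntimeError, optimize.OptimizeWarning) as exc:  # pragma: no cover
                last_error = exc
        raise FittingError(
            f"logistic fit failed after {self.max_restarts} restarts "
            f"(n={len(x)}, last error: {last_error})"
        )

    def predict(self, X):
        if not hasattr(self, "params_"):
            raise InputError("regressor is not fitted")
        x = self._as_1d(X)
        return self.fitted_model_.predict(x)

    @property
    def fitted_model_(self) -> FittedModel:
        return FittedModel(self.form, self.params_, self.r_squared_, self.rmse_, self.n_)


def fit_curve(form: str, x, y, max_restarts: int = 20, random_state: int = 0) -> FittedModel:
    """Fit one of the fixed forms and return it with resubstitution R^2 and RMSE."""
    reg = TepResponseRegressor(form=form, max_restarts=max_restarts, random_state=random_state)
    reg.fit(x, y)
    return reg.fitted_model_


def fit_comprehensive_model(tep, comprehensive, random_state: int = 0) -> FittedModel:
    """Three-parameter logistic fit of comprehensive quality scores against TEP."""
    return fit_curve("logistic", tep, comprehensive, random_state=random_state)


def correlation_table(records) -> pd.Series:
    """Pearson r of each quality index against TEP over a set of records.

    An index that is constant (correlation undefined) is reported as NaN
    without affecting the others.
    """
    from .quality import CRITERIA, records_to_frame

    frame = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records
    if "tep" not in frame.columns:
        raise InputError("records carry no TEP values")
    tep = frame["tep"].to_numpy(dtype=float)
    if len(tep) < 3:
        raise InputError("need at least three records")
    out = {}
    for name in CRITERIA:
        try:
            out[name] = pearson_r(tep, frame[name].to_numpy(dtype=float))
        except InputError:
            out[name] = np.nan
    return pd.Series(out, name="r")
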