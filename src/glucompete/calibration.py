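"""Glucose calibration: response fitting, inverse prediction, accuracy.

The assay's anisotropy falls monotonically with glucose as the labeled
ligand is displaced from the receptor.  The response is fit with a
monotone four-parameter log-logistic,

    r(g) = r_inf + (r_0 - r_inf) / (1 + (g / g_50)**h),

chosen because it matches the mechanistic curve shape and inverts
analytically,

    g(r) = g_50 * ((r_0 - r_inf) / (r - r_inf) - 1)**(1/h),

so glucose prediction from a measured anisotropy is exact.  Accuracy
against reference glucose is scored with MARD (mean absolute relative
difference, percent), RMSE, and SEC (standard error of calibration,
sqrt(SSres / (n - p)) with p fitted parameters), restricted by default
to the 50-400 mg/dL reporting range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .titration import FitError

__all__ = [
    "GlucoseResponseCurve",
    "CalibrationModel",
    "EvaluationReport",
    "GlucoseCalibration",
    "fit_calibration",
    "predict_glucose",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class GlucoseResponseCurve:
    """Anisotropy vs glucose (mg/dL) for a fixed assay composition."""

    glucose_mgdl: np.ndarray
    r_values: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.glucose_mgdl, dtype=float)
        r = np.asarray(self.r_values, dtype=float)
        if g.size != r.size:
            raise ValueError("glucose_mgdl and r_values must have equal length")
        if np.any(g < 0) or not np.all(np.isfinite(g)):
            raise ValueError("glucose_mgdl must be finite and >= 0")
        if g.size > 1 and not np.all(np.diff(g) > 0):
            raise ValueError("glucose_mgdl must be strictly ascending")
        if not np.all(np.isfinite(r)):
            raise ValueError("r_values must be finite")
        object.__setattr__(self, "glucose_mgdl", g)
        object.__setattr__(self, "r_values", r)


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted log-logistic calibration parameters."""

    r_0: float
    r_inf: float
    g_50: float
    h: float
    residual_rms: float
    monotone_warning: bool = False


@dataclass(frozen=True)
class EvaluationReport:
    """Prediction-accuracy summary over a glucose range."""

    n: int
    mard_percent: float
    rmse_mgdl: float
    sec_mgdl: float | None
    range_low_mgdl: float
    range_high_mgdl: float
    n_params: int


def _loglogistic(g, r_0, r_inf, g_50, h):
    return r_inf + (r_0 - r_inf) / (1.0 + (g / g_50) ** h)


class GlucoseCalibration(RegressorMixin, BaseEstimator):
    """Four-parameter log-logistic calibration of anisotropy vs glucose.

    fit(X, y) takes glucose levels (mg/dL) and anisotropy; predict(X)
    evaluates the fitted response; inverse_predict(r) returns the glucose
    concentration producing anisotropy r, clamping out-of-range readings
    to just inside the fitted asymptotes and flagging them.

    Attributes (after fit)
    ----------------------
    r_0_ : anisotropy at zero glucose (upper asymptote).
    r_inf_ : anisotropy at saturating glucose (lower asymptote).
    g_50_ : glucose at the half-transition, mg/dL.
    h_ : shape exponent (> 0).
    residual_rms_ : RMS fit residual, anisotropy units.
    monotone_warning_ : True if the data trend was not monotone
        decreasing beyond noise (fit still performed).
    """

    #: relative shrink applied to the open (r_inf, r_0) interval on clamping
    CLAMP_EPS = 1e-9

    def __init__(self, maxfev: int = 20000):
        self.maxfev = maxfev

    def fit(self, X, y):
        g = np.asarray(X, dtype=float)
        if g.ndim == 2 and g.shape[1] == 1:
            g = g[:, 0]
        r = np.asarray(y, dtype=float)
        if g.shape != r.shape or g.ndim != 1:
            raise ValueError("X and y must be equal-length 1-d arrays")
        if g.size < 5:
            raise FitError("need at least 5 glucose levels to calibrate")
        if np.any(g < 0) or not np.all(np.isfinite(g)) or not np.all(np.isfinite(r)):
            raise ValueError("inputs must be finite, glucose >= 0")
        order = np.argsort(g)
        g, r = g[order], r[order]

        span = r.max() - r.min()
        self.monotone_warning_ = bool(r[-1] > r[0] - 0.1 * span)
        if self.monotone_warning_:
            warnings.warn(
                "glucose response is not monotone decreasing beyond noise",
                stacklevel=2,
            )

        g50_init = float(np.interp((r[0] + r[-1]) / 2.0, r[::-1], g[::-1]))
        g50_init = max(g50_init, max(g[g > 0].min() if np.any(g > 0) else 1.0, 1e-6))
        p0 = [float(r.max()), float(r.min()), g50_init, 1.0]
        try:
            popt, _ = curve_fit(
                _loglogistic,
                g,
                r,
                p0=p0,
                bounds=([-0.2, -0.2, 1e-9, 1e-3], [1.0, 1.0, 1e9, 20.0]),
                maxfev=self.maxfev,
            )
        except RuntimeError as exc:
            raise FitError(f"calibration fit did not converge: {exc}") from exc
        r_0, r_inf, g_50, h = (float(v) for v in popt)
        if not r_0 > r_inf:
            raise FitError("fit collapsed: r_0 <= r_inf")
        resid = r - _loglogistic(g, r_0, r_inf, g_50, h)
        self.r_0_, self.r_inf_, self.g_50_, self.h_ = r_0, r_inf, g_50, h
        self.residual_rms_ = float(np.sqrt(np.mean(resid**2)))
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        """Fitted anisotropy at glucose levels X (mg/dL)."""
        check_is_fitted(self, "g_50_")
        g = np.asarray(X, dtype=float)
        if g.ndim == 2 and g.shape[1] == 1:
            g = g[:, 0]
        return _loglogistic(g, self.r_0_, self.r_inf_, self.g_50_, self.h_)

    def inverse_predict(self, r):
        """Glucose (mg/dL) producing anisotropy r, with clamp flags.

        Returns (glucose, clamped): arrays matching r's shape; clamped
        marks readings outside the open (r_inf, r_0) interval that were
        pulled just inside it before inversion.
        """
        check_is_fitted(self, "g_50_")
        r = np.asarray(r, dtype=float)
        scalar = r.ndim == 0
        r = np.atleast_1d(r)
        span = self.r_0_ - self.r_inf_
        lo = self.r_inf_ + self.CLAMP_EPS * span
        hi = self.r_0_ - self.CLAMP_EPS * span
        clamped = (r <= lo) | (r >= hi)
        rc = np.clip(r, lo, hi)
        g = self.g_50_ * (span / (rc - self.r_inf_) - 1.0) ** (1.0 / self.h_)
        if scalar:
            return float(g[0]), bool(clamped[0])
        return g, clamped


def fit_calibration(curve: GlucoseResponseCurve) -> CalibrationModel:
    """Fit the log-logistic calibration to a glucose-response curve."""
    est = GlucoseCalibration().fit(curve.glucose_mgdl, curve.r_values)
    return CalibrationModel(
        r_0=est.r_0_,
        r_inf=est.r_inf_,
        g_50=est.g_50_,
        h=est.h_,
        residual_rms=est.residual_rms_,
        monotone_warning=est.monotone_warning_,
    )


def predict_glucose(model: CalibrationModel, r):
    """Invert a fitted calibration: anisotropy -> glucose (mg/dL).

    Returns (glucose, clamped_flag); see
    :meth:`GlucoseCalibration.inverse_predict`.
    """
    est = GlucoseCalibration()
    est.r_0_, est.r_inf_, est.g_50_, est.h_ = model.r_0, model.r_inf, model.g_50, model.h
    est.n_features_in_ = 1
    return est.inverse_predict(r)


def evaluate_predictions(
    predicted,
    actual,
    range_low: float = 50.0,
    range_high: float = 400.0,
    n_params: int = 4,
) -> EvaluationReport:
    """Score glucose predictions against reference values.

    Pairs whose reference value falls outside [range_low, range_high]
    mg/dL are excluded (relative error explodes at very low glucose).
    MARD = 100 * mean(|pred - actual| / actual); RMSE over the same
    pairs; SEC divides the residual sum of squares by (n - n_params)
    and is omitted (None) when n <= n_params.
    """
    pred = np.asarray(predicted, dtype=float)
    act = np.asarray(actual, dtype=float)
    if pred.shape != act.shape or pred.ndim != 1:
        raise ValueError("predicted and actual must be equal-length 1-d arrays")
    keep = (act >= range_low) & (act <= range_high)
    pred, act = pred[keep], act[keep]
    n = int(pred.size)
    if n == 0:
        raise ValueError(
            f"no reference values within [{range_low:g}, {range_high:g}] mg/dL"
        )
    if np.any(act <= 0):
        raise ValueError("reference glucose must be > 0 within the range")
    err = pred - act
    mard = float(100.0 * np.mean(np.abs(err) / act))
    rmse = float(np.sqrt(np.mean(err**2)))
    sec = float(np.sqrt(np.sum(err**2) / (n - n_params))) if n > n_params else None
    return EvaluationReport(
        n=n,
        mard_percent=mard,
        rmse_mgdl=rmse,
        sec_mgdl=sec,
        range_low_mgdl=float(range_low),
        range_high_mgdl=float(range_high),
        n_params=n_params,
    )
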