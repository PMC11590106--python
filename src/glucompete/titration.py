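"""Dissociation-constant estimation from anisotropy titration curves.

A fixed, low concentration of labeled ligand is titrated with receptor;
anisotropy rises sigmoidally on a log-concentration axis as the ligand
partitions into the slowly tumbling bound state.  The curve is fit with
the four-parameter Boltzmann sigmoid

    r(x) = r_max + (r_min - r_max) / (1 + exp((x - x0) / dx)),
    x = log10([protein] / M)

and the dissociation constant read off the midpoint: K_d = 10**x0
("naive" mode, the conventional semilog-plot procedure) or
K_d = 10**x0 - ligand_total/2 ("depletion" mode, which corrects the
midpoint for the ligand consumed in complexes — material when the
ligand total is comparable to K_d).  K_a = 1/K_d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .equilibrium import BindingConstants, AssayMixture, solve_equilibrium

__all__ = [
    "TitrationCurve",
    "SigmoidFit",
    "FitError",
    "BoltzmannTitration",
    "fit_titration",
    "isotherm_bound_fraction",
]

_KD_FLOOR = 1e-300


class FitError(RuntimeError):
    """Nonlinear fit failed to converge or inputs cannot support a fit."""


@dataclass(frozen=True)
class TitrationCurve:
    """Anisotropy vs total protein at fixed ligand concentration."""

    ligand_total: float
    protein_concs: np.ndarray
    r_values: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.protein_concs, dtype=float)
        r = np.asarray(self.r_values, dtype=float)
        if p.size != r.size:
            raise ValueError("protein_concs and r_values must have equal length")
        if np.any(p <= 0) or not np.all(np.isfinite(p)):
            raise ValueError("protein_concs must be finite and > 0")
        if p.size > 1 and not np.all(np.diff(p) > 0):
            raise ValueError("protein_concs must be strictly ascending")
        if not np.all(np.isfinite(r)):
            raise ValueError("r_values must be finite")
        object.__setattr__(self, "protein_concs", p)
        object.__setattr__(self, "r_values", r)


@dataclass(frozen=True)
class SigmoidFit:
    """Fitted Boltzmann parameters and the derived binding constants."""

    r_min: float
    r_max: float
    x0: float
    dx: float
    K_d: float
    K_a: float
    residual_rms: float
    correction_mode: str


def boltzmann(x: np.ndarray, r_min: float, r_max: float, x0: float, dx: float):
    """Boltzmann sigmoid in log10 concentration."""
    return r_max + (r_min - r_max) / (1.0 + np.exp((x - x0) / dx))


def isotherm_bound_fraction(
    K_d: float, ligand_total: float, protein_total: float
) -> float:
    """Exact two-component bound-ligand fraction (no competing sugar).

    Solves the quadratic mass action for the complex concentration,
    CM = (b - sqrt(b^2 - 4*P0*L0)) / 2 with b = P0 + L0 + K_d, and
    returns CM / L0.  Agrees with the full competitive solver at G0 = 0.
    """
    if K_d <= 0:
        raise ValueError("K_d must be > 0")
    if ligand_total <= 0:
        raise ValueError("bound fraction undefined for ligand_total <= 0")
    if protein_total < 0:
        raise ValueError("protein_total must be >= 0")
    if protein_total == 0:
        return 0.0
    b = protein_total + ligand_total + K_d
    disc = b * b - 4.0 * protein_total * ligand_total
    CM = (b - math.sqrt(max(disc, 0.0))) / 2.0
    return min(max(CM / ligand_total, 0.0), 1.0)


class BoltzmannTitration(RegressorMixin, BaseEstimator):
    """Sigmoid titration fit exposing K_d as a fitted attribute.

    Parameters
    ----------
    ligand_total : float or None
        Total labeled-ligand concentration (molar).  Required for the
        depletion-corrected K_d; ignored in naive mode.
    correction : {"naive", "depletion"}
        "naive" takes K_d as the midpoint concentration 10**x0;
        "depletion" subtracts half the ligand total from the midpoint.
    maxfev : int
        Iteration budget for the Levenberg-Marquardt solve.

    Attributes (after fit)
    ----------------------
    r_min_, r_max_, x0_, dx_ : Boltzmann parameters (x in log10 molar).
    K_d_ : dissociation constant, molar.
    K_a_ : association constant, 1/K_d_, per molar.
    residual_rms_ : root-mean-square fit residual, anisotropy units.
    """

    def __init__(
        self,
        ligand_total: float | None = None,
        correction: str = "naive",
        maxfev: int = 20000,
    ):
        self.ligand_total = ligand_total
        self.correction = correction
        self.maxfev = maxfev

    def _validate(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("X must be 1-d protein concentrations (molar)")
        y = np.asarray(y, dtype=float)
        if y.shape != X.shape:
            raise ValueError("X and y must have the same length")
        if np.any(X <= 0) or not np.all(np.isfinite(X)):
            raise ValueError("protein concentrations must be finite and > 0")
        if not np.all(np.isfinite(y)):
            raise ValueError("anisotropy values must be finite")
        return X, y

    def fit(self, X, y):
        """Fit anisotropy y against protein concentration X (molar)."""
        if self.correction not in ("naive", "depletion"):
            raise ValueError("correction must be 'naive' or 'depletion'")
        if self.correction == "depletion" and (
            self.ligand_total is None or self.ligand_total <= 0
        ):
            raise ValueError("depletion correction requires ligand_total > 0")
        X, y = self._validate(X, y)
        if X.size < 5:
            raise FitError("need at least 5 titration points")
        order = np.argsort(X)
        x = np.log10(X[order])
        r = y[order]

        # initialization: asymptotes from percentiles, midpoint from the
        # half-rise crossing, width a quarter of the titrated log-range
        r_lo, r_hi = np.percentile(r, [5.0, 95.0])
        if r_hi - r_lo <= 0:
            raise FitError("no anisotropy rise to fit")
        half = (r_lo + r_hi) / 2.0
        above = np.nonzero(r >= half)[0]
        below = np.nonzero(r < half)[0]
        if above.size == 0 or below.size == 0:
            raise FitError(
                "titration does not span the transition "
                "(need points below and above the half-rise)"
            )
        x0_init = float(np.interp(half, r, x)) if np.all(np.diff(r) >= 0) else float(
            x[above[0]]
        )
        dx_init = max((x[-1] - x[0]) / 4.0, 1e-3)

        try:
            popt, _ = curve_fit(
                boltzmann,
                x,
                r,
                p0=[r_lo, r_hi, x0_init, dx_init],
                maxfev=self.maxfev,
            )
        except RuntimeError as exc:
            raise FitError(f"Boltzmann fit did not converge: {exc}") from exc
        r_min, r_max, x0, dx = (float(v) for v in popt)
        if dx < 0:  # equivalent curve with swapped asymptotes
            r_min, r_max, dx = r_max, r_min, -dx
        if not r_max > r_min:
            raise FitError("fit collapsed: r_max <= r_min")

        midpoint = 10.0 ** x0
        if self.correction == "depletion":
            K_d = max(midpoint - self.ligand_total / 2.0, _KD_FLOOR)
        else:
            K_d = midpoint
        resid = r - boltzmann(x, r_min, r_max, x0, dx)

        self.r_min_, self.r_max_, self.x0_, self.dx_ = r_min, r_max, x0, dx
        self.K_d_ = K_d
        self.K_a_ = 1.0 / K_d
        self.residual_rms_ = float(np.sqrt(np.mean(resid**2)))
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        """Fitted anisotropy at protein concentrations X (molar)."""
        check_is_fitted(self, "K_d_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        return boltzmann(np.log10(X), self.r_min_, self.r_max_, self.x0_, self.dx_)


def fit_titration(curve: TitrationCurve, correction_mode: str = "naive") -> SigmoidFit:
    """Fit a titration curve and return the sigmoid parameters + K_d."""
    est = BoltzmannTitration(
        ligand_total=curve.ligand_total, correction=correction_mode
    )
    est.fit(curve.protein_concs, curve.r_values)
    return SigmoidFit(
        r_min=est.r_min_,
        r_max=est.r_max_,
        x0=est.x0_,
        dx=est.dx_,
        K_d=est.K_d_,
        K_a=est.K_a_,
        residual_rms=est.residual_rms_,
        correction_mode=correction_mode,
    )
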