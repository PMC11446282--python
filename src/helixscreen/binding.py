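"""One-site saturation binding: prediction and nonlinear least-squares fit.

The model is the one-site specific binding equation

    Y = Bmax * X / (Kd + X)

with X the titrated receptor concentration (nM), Y the response
(e.g. fluorescence polarization in mP), Bmax the saturating response and
Kd the half-saturation concentration.  Fitting is unweighted nonlinear
least squares; standard errors come from the local curvature of the
objective at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "BindingCurve",
    "FitResult",
    "OneSiteBindingModel",
    "predict_one_site",
    "fit_one_site",
]


@dataclass
class BindingCurve:
    """A concentration/response titration (concentrations in nM)."""

    concentrations: np.ndarray
    responses: np.ndarray
    replicate: str | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses must have equal length")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")

    def __len__(self) -> int:
        return len(self.concentrations)


@dataclass(frozen=True)
class FitResult:
    kd: float  # nM
    bmax: float  # response units
    kd_se: float
    bmax_se: float
    rss: float
    converged: bool


def predict_one_site(kd: float, bmax: float, X: np.ndarray | float) -> np.ndarray | float:
    """Specific one-site binding response Y = Bmax * X / (Kd + X)."""
    if kd <= 0 or bmax <= 0:
        raise ValueError("kd and bmax must be positive")
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("concentrations must be non-negative")
    y = bmax * X / (kd + X)
    return float(y) if y.ndim == 0 else y


class OneSiteBindingModel:
    """Scikit-learn style estimator for the one-site binding equation.

    Parameters
    ----------
    kd_init, bmax_init : float or None
        Optional starting values; by default Kd starts at the
        concentration whose response is nearest half the maximum and
        Bmax at the maximum response.
    max_nfev : int
        Evaluation budget for the optimizer.

    Attributes (after :meth:`fit`)
    ------------------------------
    kd_, bmax_ : float — fitted parameters (nM, response units)
    kd_se_, bmax_se_ : float — asymptotic standard errors
    rss_ : float — residual sum of squares
    converged_ : bool — optimizer status
    """

    def __init__(
        self,
        kd_init: float | None = None,
        bmax_init: float | None = None,
        max_nfev: int = 10000,
    ) -> None:
        self.kd_init = kd_init
        self.bmax_init = bmax_init
        self.max_nfev = max_nfev

    # minimal get/set_params so the estimator composes with sklearn tooling
    def get_params(self, deep: bool = True) -> dict:
        return {
            "kd_init": self.kd_init,
            "bmax_init": self.bmax_init,
            "max_nfev": self.max_nfev,
        }

    def set_params(self, **params) -> "OneSiteBindingModel":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y) -> "OneSiteBindingModel":
        X = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if X.shape != y.shape:
            raise ValueError("X and y must have equal length")
        if len(np.unique(X)) < 3:
            raise ValueError("fitting needs at least 3 distinct concentrations")
        if np.allclose(y, y[0]):
            raise ValueError("responses are all equal; the curve carries no signal")
        ymax = float(y.max())
        if ymax <= 0:
            raise ValueError("responses must contain positive values")
        bmax0 = self.bmax_init if self.bmax_init is not None else ymax
        if self.kd_init is not None:
            kd0 = self.kd_init
        else:
            half = ymax / 2.0
            positive = X[X > 0]
            if positive.size == 0:
                raise ValueError("all concentrations are zero")
            kd0 = float(X[np.argmin(np.abs(y - half))])
            if kd0 <= 0:
                kd0 = float(positive.min())

        def func(x, kd, bmax):
            return bmax * x / (kd + x)

        try:
            popt, pcov = curve_fit(
                func,
                X,
                y,
                p0=[kd0, bmax0],
                bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                max_nfev=self.max_nfev,
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
            converged = True
        except (RuntimeError, ValueError):
            popt = np.array([np.nan, np.nan])
            pcov = np.full((2, 2), np.nan)
            converged = False

        self.kd_ = float(popt[0])
        self.bmax_ = float(popt[1])
        se = np.sqrt(np.diag(pcov))
        self.kd_se_ = float(se[0])
        self.bmax_se_ = float(se[1])
        if converged:
            self.rss_ = float(np.sum((func(X, *popt) - y) ** 2))
        else:
            self.rss_ = float("nan")
        self.converged_ = converged
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "kd_"):
            raise RuntimeError("estimator is not fitted")
        if not self.converged_:
            raise RuntimeError("fit did not converge; no predictions available")
        return predict_one_site(self.kd_, self.bmax_, np.asarray(X, dtype=float))


def fit_one_site(curve: BindingCurve) -> FitResult:
    """Fit Kd and Bmax to a titration by unweighted least squares."""
    est = OneSiteBindingModel().fit(curve.concentrations, curve.responses)
    return FitResult(
        kd=est.kd_,
        bmax=est.bmax_,
        kd_se=est.kd_se_,
        bmax_se=est.bmax_se_,
        rss=est.rss_,
        converged=est.converged_,
    )
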