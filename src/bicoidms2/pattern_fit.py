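"""Sigmoid fits of AP expression patterns and their Hill-function readout.

The fraction-expressing pattern along the AP axis is fitted with the
decreasing sigmoid

    f(x) = fmax * e^{-x*eta} / (e^{-x*eta} + e^{-x0*eta})
         = fmax / (1 + e^{(x - x0)*eta}),

where ``x0`` is the boundary position (f(x0) = fmax/2) and ``eta`` (%EL^-1)
the pattern sharpness — the magnitude of the derivative at the boundary
divided by fmax is eta/4 in this parametrisation; eta itself is the scaling
coefficient of the AP axis.  The boundary width, defined as the distance
between the 95% and 5% levels of fmax, is ``2*ln(19)/eta``.

Substituting an exponential Bicoid gradient ``c(x) = c0*e^{-x/lambda}``
turns the sigmoid of position into a Hill function of concentration with
Hill coefficient ``H = lambda * eta`` and EC50 ``c(x0)``: the pattern
sharpness and the gradient decay length jointly set the effective
cooperativity of the concentration readout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import log

import numpy as np
from scipy.optimize import least_squares

from .promoter_model import (
    BcdGradient,
    PromoterModel,
    SignalKernel,
    predicted_steady_profile,
    steady_state_p_on,
    steady_state_spot_probability,
)
from .trace_analysis import ExpressionPattern

__all__ = [
    "SigmoidFit",
    "HillReadout",
    "FitFailureError",
    "sigmoid",
    "fit_sigmoid",
    "fit_sigmoid_xy",
    "boundary_width",
    "hill_from_sharpness",
    "sigmoid_to_hill",
    "numeric_hill_from_model",
]

#: Width of the 5%-95% transition zone in units of 1/eta: 2*ln(0.95/0.05).
WIDTH_CONSTANT = 2.0 * log(19.0)


class FitFailureError(RuntimeError):
    """Raised when a pattern has no fittable expression boundary."""


def sigmoid(x, fmax: float, x0: float, eta: float):
    """Decreasing boundary sigmoid f(x) = fmax / (1 + exp((x - x0) * eta))."""
    z = np.clip((np.asarray(x, float) - x0) * eta, -500.0, 500.0)
    return fmax / (1.0 + np.exp(z))


@dataclass(frozen=True)
class SigmoidFit:
    """Fitted boundary sigmoid: plateau, boundary position and sharpness."""

    fmax: float
    x0: float
    eta: float
    covariance: np.ndarray | None = None
    residual: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.fmax <= 1 + 1e-9):
            raise ValueError("fmax must lie in (0, 1]")
        if self.eta <= 0:
            raise ValueError("eta must be positive")

    def __call__(self, x):
        return sigmoid(x, self.fmax, self.x0, self.eta)

    def confidence_intervals(self, z: float = 1.96) -> dict[str, tuple[float, float]]:
        if self.covariance is None:
            raise ValueError("fit has no covariance estimate")
        se = np.sqrt(np.diag(self.covariance))
        vals = [self.fmax, self.x0, self.eta]
        return {name: (v - z * s, v + z * s)
                for name, v, s in zip(("fmax", "x0", "eta"), vals, se)}


@dataclass(frozen=True)
class HillReadout:
    """Hill function of Bicoid concentration implied by a pattern fit."""

    hill_coefficient: float
    ec50_concentration: float
    fmax: float

    def __call__(self, c):
        c = np.asarray(c, float)
        h, k = self.hill_coefficient, self.ec50_concentration
        return self.fmax * c ** h / (c ** h + k ** h)


def fit_sigmoid_xy(x: np.ndarray, f: np.ndarray,
                   n: np.ndarray | None = None,
                   n_starts: int = 5) -> SigmoidFit:
    """Weighted least-squares sigmoid fit to (position, fraction) samples.

    Weights are binomial, ``n / (f (1 - f) + eps)``.  Multi-start from
    quantile-based boundary initialisations; bounded so that
    ``fmax in (0, 1]`` and ``eta > 0``.
    """
    x = np.asarray(x, float)
    f = np.asarray(f, float)
    n = np.ones_like(x) if n is None else np.asarray(n, float)
    if len(x) < 4:
        raise FitFailureError("need at least 4 bins to fit a sigmoid")
    order = np.argsort(x)
    x, f, n = x[order], f[order], n[order]

    anterior = float(f[: max(1, len(f) // 4)].mean())
    if f.max() < 0.8 * max(anterior, 1e-12) or f.min() > 0.2 or anterior <= 0.05:
        raise FitFailureError(
            "pattern does not span both plateaus; no boundary to fit"
        )
    w = np.sqrt(n / (f * (1.0 - f) + 1e-2))

    def make_resid(weights):
        def resid(theta):
            fmax, x0, log_eta = theta
            return weights * (sigmoid(x, fmax, x0, np.exp(log_eta)) - f)
        return resid

    resid = make_resid(w)

    # initial boundary guesses from quantiles of the transition region
    span = x.max() - x.min()
    qs = np.linspace(0.2, 0.8, n_starts)
    below = np.nonzero(f <= anterior / 2)[0]
    x0_data = x[below[0]] if below.size else x.min() + 0.5 * span
    inits = [x0_data] + [x.min() + q * span for q in qs]
    lb = [1e-6, x.min() - span, np.log(1e-4)]
    ub = [1.0, x.max() + span, np.log(1e3)]
    best = None
    for x0_init in inits:
        sol = least_squares(resid, [min(max(anterior, 0.05), 1.0), x0_init, np.log(0.3)],
                            bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
    # one reweighting pass with model-based binomial variances: weights from
    # the fitted curve rather than the noisy observations, which calibrates
    # the covariance estimate
    f_hat = sigmoid(x, best.x[0], best.x[1], np.exp(best.x[2]))
    w2 = np.sqrt(n / (f_hat * (1.0 - f_hat) + 1e-3))
    best = least_squares(make_resid(w2), best.x, bounds=(lb, ub),
                         xtol=1e-14, ftol=1e-14, gtol=1e-14)
    fmax, x0, log_eta = best.x
    eta = float(np.exp(log_eta))
    # Gauss-Newton covariance in (fmax, x0, eta); scale by residual variance
    jac = best.jac.copy()
    jac[:, 2] *= 1.0 / eta  # d/d(log eta) -> d/d(eta)
    dof = max(len(x) - 3, 1)
    s2 = 2.0 * best.cost / dof
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
    except np.linalg.LinAlgError:
        cov = None
    return SigmoidFit(float(fmax), float(x0), eta, cov,
                      residual=float(2.0 * best.cost))


def fit_sigmoid(pattern: ExpressionPattern) -> SigmoidFit:
    """Fit the boundary sigmoid to a binned fraction-expressing pattern."""
    return fit_sigmoid_xy(pattern.ap_bins, pattern.fraction, pattern.n_nuclei)


def boundary_width(fit: SigmoidFit) -> float:
    """Distance (%EL) between the 95% and 5% levels: 2*ln(19)/eta."""
    return WIDTH_CONSTANT / fit.eta


def hill_from_sharpness(lambda_decay: float, eta: float) -> float:
    """Hill coefficient implied by pattern sharpness: H = lambda * eta."""
    if lambda_decay < 0 or eta < 0:
        raise ValueError("lambda_decay and eta must be nonnegative")
    return lambda_decay * eta


def sigmoid_to_hill(fit: SigmoidFit, gradient: BcdGradient) -> HillReadout:
    """Re-express a fitted position sigmoid as a Hill function of [Bcd].

    With c(x) = c0*e^{-x/lambda}, the sigmoid of position becomes a Hill
    function with H = lambda*eta and EC50 = c(x0); composing the readout
    with the gradient reproduces the original sigmoid pointwise.
    """
    h = hill_from_sharpness(gradient.lambda_decay, fit.eta)
    ec50 = float(gradient.concentration(fit.x0))
    return HillReadout(h, ec50, fit.fmax)


def numeric_hill_from_model(model: PromoterModel, gradient: BcdGradient,
                            kernel: SignalKernel | None = None,
                            x_grid: np.ndarray | None = None) -> float:
    """Hill coefficient of the model's stationary spatial profile.

    Computes the steady-state activity profile along AP (spot probability if
    a signal kernel is given, ON probability otherwise), fits the boundary
    sigmoid, and returns ``lambda * eta``.  Raises FitFailureError when the
    profile has no boundary in frame.
    """
    if x_grid is None:
        x_grid = np.arange(10.0, 80.0, 2.0)
    profile = predicted_steady_profile(model, gradient, x_grid, kernel)
    # normalise by the model's true saturation level (activity at
    # saturating concentration) so a window that does not reach the
    # anterior plateau does not bias the fitted sharpness
    with warnings.catch_warnings():
        # at saturating concentration the low-occupancy states are
        # unreachable and the chain is flagged reducible; the absorbing
        # (fully bound) component is exactly the limit we want
        warnings.simplefilter("ignore", RuntimeWarning)
        if kernel is None:
            saturation = steady_state_p_on(model, 1e9)
        else:
            saturation = steady_state_spot_probability(model, 1e9, kernel)
    if saturation < 1e-3 or profile.max() < 1e-3 * saturation:
        raise FitFailureError("profile is flat; no boundary")
    fit = fit_sigmoid_xy(x_grid, profile / saturation)
    return hill_from_sharpness(gradient.lambda_decay, fit.eta)
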