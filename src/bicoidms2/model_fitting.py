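"""Likelihood-based fitting of the promoter model to fraction-active data.

The observable is a kymograph of the fraction of nuclei with a visible
spot per (time, AP) cell.  Each cell is treated as a binomial draw —
``active ~ Binom(n_nuclei, p_model(t, x))`` — with ``p_model`` the
mean-field spot probability of the promoter chain at the local Bicoid
concentration, so the objective is the summed binomial log-likelihood.

Fitting follows a nested parameter-freeing protocol: a baseline reporter
fixes the full parameter set, and each variant construct is fitted by
freeing only a named subset (e.g. three unbinding rates for a longer
binding-site array, the two promoter switching rates for added Hunchback
sites, or the Bicoid binding rate alone for added Zelda sites).  Search is
in log10 parameter space with a seeded differential-evolution global stage
and a local polish, so refits with one seed are reproducible.

The decay-length scan refits the model for a grid of gradient decay
lengths and flags values whose best log-likelihood falls below the 5th
percentile of a parametric bootstrap of the likelihood under the overall
best model (a likelihood-ratio test is not justified for this non-nested
comparison).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import differential_evolution
from scipy.special import gammaln

from .promoter_model import (
    BcdGradient,
    KineticRates,
    PromoterModel,
    SignalKernel,
    predicted_kymograph,
)
from .trace_analysis import Kymograph

__all__ = [
    "FitSpec",
    "FitResult",
    "LambdaScanResult",
    "binomial_log_likelihood",
    "fit_parameters",
    "lambda_scan",
    "reporter_preset_free_params",
    "apply_parameters",
    "parameter_value",
]

#: Parameter subsets freed for each reporter construct in the nested
#: fitting protocol (baseline reporter: all of them, fitted first).
_REPORTER_PRESETS = {
    "B6": (),  # baseline: parameters fixed by the initial full fit
    "B9": ("k_off_site_1", "k_off_site_2", "k_off_site_6"),
    "B12": ("k_off_site_1", "k_off_site_2", "k_off_site_6"),
    "H6B6": ("k_on_base", "k_off_promoter"),
    "H6B6-full": ("k_on_base", "k_off_promoter",
                  "k_off_site_1", "k_off_site_2", "k_off_site_6"),
    "Z2B6": ("kb",),
}


def reporter_preset_free_params(name: str) -> tuple[str, ...]:
    """Free-parameter subset for a named reporter fitting preset."""
    if name not in _REPORTER_PRESETS:
        raise KeyError(f"unknown preset {name!r}; valid: {sorted(_REPORTER_PRESETS)}")
    return _REPORTER_PRESETS[name]


# ---------------------------------------------------------------------------
# Parameter (de)serialisation
# ---------------------------------------------------------------------------

def parameter_value(model: PromoterModel, name: str) -> float:
    """Read one named rate from a model (k_off_site_i is 1-based)."""
    if name.startswith("k_off_site_"):
        i = int(name.rsplit("_", 1)[1])
        if not (1 <= i <= len(model.rates.k_off_site)):
            raise KeyError(f"{name}: site index outside "
                           f"1..{len(model.rates.k_off_site)}")
        return model.rates.k_off_site[i - 1]
    if name not in ("kb", "k_on_base", "k_off_promoter", "rnap_rate"):
        raise KeyError(f"unknown parameter {name!r}")
    return getattr(model.rates, name)


def apply_parameters(model: PromoterModel, params: dict[str, float]) -> PromoterModel:
    """Return a model with the named rates replaced."""
    k_off = list(model.rates.k_off_site)
    scalars: dict[str, float] = {}
    for name, v in params.items():
        if name.startswith("k_off_site_"):
            i = int(name.rsplit("_", 1)[1])
            if not (1 <= i <= len(k_off)):
                raise KeyError(f"{name}: site index outside 1..{len(k_off)}")
            k_off[i - 1] = float(v)
        elif name in ("kb", "k_on_base", "k_off_promoter", "rnap_rate"):
            scalars[name] = float(v)
        else:
            raise KeyError(f"unknown parameter {name!r}")
    rates = model.rates.replace(k_off_site=tuple(k_off), **scalars)
    return PromoterModel(model.architecture, rates)


@dataclass(frozen=True)
class FitSpec:
    """What to fit: base model, gradient, freed parameters and bounds."""

    model: PromoterModel
    gradient: BcdGradient
    kernel: SignalKernel = SignalKernel()
    free_params: tuple[str, ...] = ()
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    seed: int = 0
    maxiter: int = 40
    popsize: int = 12
    tol: float = 0.005
    internal_dt: float = 4.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "free_params", tuple(self.free_params))
        for name in self.free_params:
            parameter_value(self.model, name)  # raises on unknown names
            lo, hi = self.bounds_for(name)
            if not (0 < lo < hi and np.isfinite(hi)):
                raise ValueError(f"bounds for {name} must be finite and positive")

    def bounds_for(self, name: str) -> tuple[float, float]:
        if name in self.bounds:
            return self.bounds[name]
        v = parameter_value(self.model, name)
        if v <= 0:
            raise ValueError(f"cannot derive default bounds for {name}=0; "
                             "give explicit bounds")
        return (v / 30.0, v * 30.0)

    def config_hash(self) -> str:
        payload = {
            "n_sites": self.model.architecture.n_sites,
            "k_threshold": self.model.architecture.k_threshold,
            "scaling": self.model.architecture.activation_scaling,
            "rates": {n: parameter_value(self.model, n)
                      for n in ("kb", "k_on_base", "k_off_promoter", "rnap_rate")},
            "k_off_site": list(self.model.rates.k_off_site),
            "gradient": [self.gradient.c0, self.gradient.lambda_decay,
                         self.gradient.dosage_factor],
            "free": list(self.free_params),
            "bounds": {n: list(self.bounds_for(n)) for n in self.free_params},
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass(frozen=True)
class FitResult:
    best_params: dict[str, float]
    log_likelihood: float
    predicted: np.ndarray
    observed: np.ndarray
    counts: np.ndarray
    converged: bool
    n_evaluations: int
    seed: int
    config_hash: str
    profile_widths: dict[str, tuple[float, float]] = field(default_factory=dict)
    non_identifiable: tuple[str, ...] = ()

    def fitted_model(self, spec: FitSpec) -> PromoterModel:
        return apply_parameters(spec.model, self.best_params)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def binomial_log_likelihood(active: np.ndarray, total: np.ndarray,
                            p_model: np.ndarray,
                            clip: float = 1e-6) -> float:
    """Sum of log Binom(active | total, p_model) over kymograph cells.

    Cells with no nuclei (or NaN fraction) contribute nothing; p is clipped
    to [clip, 1-clip] so structural zeros cannot produce -inf.
    """
    active = np.asarray(active, float)
    total = np.asarray(total, float)
    p = np.asarray(p_model, float)
    if active.shape != total.shape or p.shape != total.shape:
        raise ValueError("kymograph and prediction grids do not match")
    mask = (total > 0) & np.isfinite(active)
    if np.any(active[mask] > total[mask] + 1e-9):
        raise ValueError("active counts exceed totals")
    a, n = active[mask], total[mask]
    pm = np.clip(p[mask], clip, 1.0 - clip)
    ll = (gammaln(n + 1) - gammaln(a + 1) - gammaln(n - a + 1)
          + a * np.log(pm) + (n - a) * np.log1p(-pm))
    return float(ll.sum())


def _kymograph_counts(data: Kymograph) -> tuple[np.ndarray, np.ndarray]:
    active = data.fraction_active * data.counts
    return active, data.counts


def _predict(spec: FitSpec, model: PromoterModel, data: Kymograph) -> np.ndarray:
    return predicted_kymograph(model, spec.gradient, data.ap_bins, data.t_bins,
                               spec.kernel, internal_dt=spec.internal_dt)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_parameters(data: Kymograph, spec: FitSpec) -> FitResult:
    """Maximum-likelihood fit of the freed parameters to a kymograph.

    Global bounded search (differential evolution in log10 space, seeded)
    followed by the optimizer's local polish.  With an empty free set the
    base parameters are returned unchanged, with their likelihood.
    """
    active, total = _kymograph_counts(data)
    names = spec.free_params
    if not names:
        pred = _predict(spec, spec.model, data)
        ll = binomial_log_likelihood(active, total, pred)
        return FitResult({}, ll, pred, data.fraction_active, total, True, 1,
                         spec.seed, spec.config_hash())

    log_bounds = [tuple(np.log10(spec.bounds_for(n))) for n in names]
    n_eval = 0

    def neg_ll(theta: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        model = apply_parameters(spec.model,
                                 {n: 10.0 ** t for n, t in zip(names, theta)})
        pred = _predict(spec, model, data)
        return -binomial_log_likelihood(active, total, pred)

    result = differential_evolution(
        neg_ll, log_bounds, seed=spec.seed, maxiter=spec.maxiter,
        popsize=spec.popsize, tol=spec.tol, polish=True, init="sobol",
        updating="deferred",
    )
    best = {n: float(10.0 ** t) for n, t in zip(names, result.x)}
    best_model = apply_parameters(spec.model, best)
    pred = _predict(spec, best_model, data)
    ll = binomial_log_likelihood(active, total, pred)

    # profile-likelihood identifiability diagnostics per freed parameter
    widths: dict[str, tuple[float, float]] = {}
    flat: list[str] = []
    for j, n in enumerate(names):
        grid = np.sort(np.append(np.linspace(log_bounds[j][0], log_bounds[j][1], 9),
                                 result.x[j]))
        lls = []
        for g in grid:
            theta = result.x.copy()
            theta[j] = g
            lls.append(-neg_ll(theta))
        lls = np.array(lls)
        # interpolate the LL_max - 2 crossings on either side of the best
        # point so the interval has nonzero width even when the coarse grid
        # drops below threshold within one step
        cut = lls.max() - 2.0
        k = int(np.argmax(lls))
        lo = grid[0]
        for m in range(k, 0, -1):
            if lls[m - 1] < cut:
                frac = (lls[m] - cut) / (lls[m] - lls[m - 1])
                lo = grid[m] - frac * (grid[m] - grid[m - 1])
                break
        hi = grid[-1]
        for m in range(k, len(grid) - 1):
            if lls[m + 1] < cut:
                frac = (lls[m] - cut) / (lls[m] - lls[m + 1])
                hi = grid[m] + frac * (grid[m + 1] - grid[m])
                break
        widths[n] = (float(10.0 ** lo), float(10.0 ** hi))
        if lls.max() - lls.min() < 2.0:
            flat.append(n)

    return FitResult(best, ll, pred, data.fraction_active, total,
                     bool(result.success), n_eval, spec.seed,
                     spec.config_hash(), widths, tuple(flat))


# ---------------------------------------------------------------------------
# Decay-length scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LambdaScanResult:
    lambda_grid: np.ndarray
    results: tuple[FitResult, ...]
    best_lambda: float
    threshold: float
    significantly_worse: np.ndarray  # boolean per lambda

    @property
    def log_likelihoods(self) -> np.ndarray:
        return np.array([r.log_likelihood for r in self.results])


def lambda_scan(data: Kymograph, spec: FitSpec,
                lambda_grid: Sequence[float] = (10.0, 12.5, 15.0, 17.5, 20.0),
                n_bootstrap: int = 200) -> LambdaScanResult:
    """Refit the model for each gradient decay length and test significance.

    The significance threshold is the 5th percentile of the log-likelihood
    under the best model (parametric bootstrap: counts redrawn binomially
    from the best predicted surface, B draws); decay lengths whose best-fit
    log-likelihood falls below it are flagged significantly worse.
    """
    lambda_grid = np.asarray(lambda_grid, float)
    if len(lambda_grid) < 3:
        raise ValueError("need at least 3 decay lengths to scan")
    results = []
    for lam in lambda_grid:
        s = replace(spec, gradient=replace(spec.gradient, lambda_decay=float(lam)))
        results.append(fit_parameters(data, s))
    lls = np.array([r.log_likelihood for r in results])
    k_best = int(np.argmax(lls))
    best = results[k_best]

    rng = np.random.default_rng(spec.seed)
    total = best.counts
    mask = (total > 0) & np.isfinite(best.observed)
    p = np.clip(best.predicted, 1e-6, 1 - 1e-6)
    boot = np.empty(n_bootstrap)
    n_int = np.round(total[mask]).astype(int)
    for b in range(n_bootstrap):
        draws = rng.binomial(n_int, p[mask])
        sim_active = np.where(mask, 0.0, np.nan).copy()
        sim_active[mask] = draws
        boot[b] = binomial_log_likelihood(sim_active, np.where(mask, total, 0.0), p)
    threshold = float(np.percentile(boot, 5.0))
    return LambdaScanResult(lambda_grid, tuple(results),
                            float(lambda_grid[k_best]), threshold,
                            lls < threshold)
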