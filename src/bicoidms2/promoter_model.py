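"""Stochastic model of Bicoid-driven transcription at a single promoter.

The promoter carries an array of ``N`` identical Bicoid binding sites and a
bursty two-state (OFF/ON) transcription switch, giving a continuous-time
Markov chain on ``2*N + 2`` states ``(i, a)`` where ``i`` is the number of
bound Bicoid molecules and ``a`` the promoter activity.  Bicoid binds each
free site at rate ``kb * c`` (so the total binding rate out of occupancy
``i`` is ``(N - i) * kb * c``), unbinds at the aggregate per-state rates
``k_-i``, and the promoter switches ON at a rate that depends on the number
of bound activators: zero below a threshold ``K``, and
``k_on_base * w(i)`` at or above it.  Switching OFF happens at a constant
rate ``k_off_promoter`` independent of occupancy.  While ON, RNA polymerases
initiate as a Poisson process with rate ``rnap_rate``; each elongating
polymerase carries a growing MS2 stem-loop signal, which is what a live
imaging experiment observes as a fluorescent spot.

Concentrations are dimensionless, normalised so the wild-type (2X) anterior
amplitude of the Bicoid gradient is 1; ``kb`` therefore carries the
concentration scale.  All rates are per second, positions in percent egg
length (%EL, 0 = anterior pole).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb, log
from typing import Literal, Sequence

import numpy as np
from scipy.linalg import expm, null_space

__all__ = [
    "OFF",
    "ON",
    "BcdGradient",
    "PromoterArchitecture",
    "KineticRates",
    "PromoterModel",
    "PromoterStateSpace",
    "SignalKernel",
    "Trajectory",
    "enumerate_states",
    "binding_rate",
    "activation_rate",
    "build_generator",
    "propagate",
    "p_on_from_probabilities",
    "steady_state_distribution",
    "steady_state_p_on",
    "initiation_survival",
    "steady_state_spot_probability",
    "gillespie_simulate",
    "ms2_signal_from_events",
    "spot_probability_from_p_on",
    "predicted_kymograph",
    "predicted_steady_profile",
]

OFF = 0
ON = 1


class InvalidArchitectureError(ValueError):
    """Raised for an inconsistent binding-array architecture."""


class ConfigurationError(ValueError):
    """Raised when rates and architecture do not fit together."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BcdGradient:
    """Static exponential Bicoid concentration profile along the AP axis.

    ``c(x) = c0 * dosage_factor * exp(-x / lambda_decay)``.

    Parameters
    ----------
    c0 : float
        Amplitude at the anterior pole, normalised to 1 for wild type (2X).
    lambda_decay : float
        Exponential decay length in %EL.
    dosage_factor : float
        Multiplier on the amplitude: 1.0 for 2X embryos, 0.5 for 1X.
    """

    c0: float = 1.0
    lambda_decay: float = 15.0
    dosage_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.c0 <= 0:
            raise ValueError("c0 must be positive")
        if self.lambda_decay <= 0:
            raise ValueError("lambda_decay must be positive")
        if self.dosage_factor <= 0:
            raise ValueError("dosage_factor must be positive")

    def concentration(self, x):
        """Concentration at AP position ``x`` (%EL); accepts arrays."""
        return self.c0 * self.dosage_factor * np.exp(-np.asarray(x, float) / self.lambda_decay)

    def with_dosage(self, dosage_factor: float) -> "BcdGradient":
        return BcdGradient(self.c0, self.lambda_decay, dosage_factor)

    @property
    def halving_distance(self) -> float:
        """Distance over which the concentration halves: ``lambda * ln 2``."""
        return self.lambda_decay * log(2.0)


ActivationScaling = Literal["binomial", "linear", "table"]


@dataclass(frozen=True)
class PromoterArchitecture:
    """Binding-array geometry and activation scaling of the promoter.

    ``weight_table`` is only used for ``activation_scaling="table"`` and must
    then give one weight per occupancy ``i = 0..N`` (entries below the
    threshold are forced to zero; the entry at ``i = K`` must be 1).
    """

    n_sites: int
    k_threshold: int = 3
    activation_scaling: ActivationScaling = "binomial"
    weight_table: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_sites < 0:
            raise InvalidArchitectureError("n_sites must be >= 0")
        if not (0 <= self.k_threshold <= self.n_sites):
            raise InvalidArchitectureError(
                f"k_threshold must lie in [0, n_sites], got {self.k_threshold}"
            )
        if self.activation_scaling not in ("binomial", "linear", "table"):
            raise InvalidArchitectureError(
                f"unknown activation_scaling {self.activation_scaling!r}"
            )
        if self.activation_scaling == "table":
            if self.weight_table is None or len(self.weight_table) != self.n_sites + 1:
                raise InvalidArchitectureError(
                    "table scaling needs one weight per occupancy 0..N"
                )

    def activation_weight(self, i: int) -> float:
        """Dimensionless scaling w(i) of the switching-ON rate; w(K) = 1."""
        k = self.k_threshold
        if i < k:
            return 0.0
        if self.activation_scaling == "binomial":
            return float(comb(i, k))
        if self.activation_scaling == "linear":
            return i / k if k > 0 else 1.0
        return float(self.weight_table[i])  # type: ignore[index]


@dataclass(frozen=True)
class KineticRates:
    """Kinetic rate constants of the promoter model (all s^-1).

    ``k_off_site[i-1]`` is the aggregate unbinding rate out of occupancy
    state ``S_i`` (not per bound molecule).  ``kb`` is the binding rate per
    free site per unit concentration.
    """

    kb: float
    k_off_site: tuple[float, ...]
    k_on_base: float
    k_off_promoter: float
    rnap_rate: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "k_off_site", tuple(float(v) for v in self.k_off_site))
        for name in ("kb", "k_on_base", "k_off_promoter", "rnap_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 for v in self.k_off_site):
            raise ValueError("k_off_site rates must be >= 0")

    def replace(self, **kwargs) -> "KineticRates":
        d = dict(
            kb=self.kb,
            k_off_site=self.k_off_site,
            k_on_base=self.k_on_base,
            k_off_promoter=self.k_off_promoter,
            rnap_rate=self.rnap_rate,
        )
        d.update(kwargs)
        return KineticRates(**d)


@dataclass(frozen=True)
class PromoterModel:
    """Architecture plus rates: everything needed to build the generator."""

    architecture: PromoterArchitecture
    rates: KineticRates

    def __post_init__(self) -> None:
        if len(self.rates.k_off_site) != self.architecture.n_sites:
            raise ConfigurationError(
                f"k_off_site has length {len(self.rates.k_off_site)}, "
                f"expected n_sites={self.architecture.n_sites}"
            )


@dataclass(frozen=True)
class PromoterStateSpace:
    """Ordered list of promoter states (i, a) with a state -> row index map."""

    states: tuple[tuple[int, int], ...]
    index: dict[tuple[int, int], int] = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.index is None:
            object.__setattr__(
                self, "index", {s: r for r, s in enumerate(self.states)}
            )

    def __len__(self) -> int:
        return len(self.states)

    def on_mask(self) -> np.ndarray:
        return np.array([a == ON for _, a in self.states])


@dataclass(frozen=True)
class SignalKernel:
    """How elongating polymerases map to MS2 spot intensity.

    Each RNAP initiated at ``t0`` contributes
    ``intensity_per_rnap * min(1, (t - t0) / loop_ramp_time)`` while it is on
    the gene (``t0 <= t <= t0 + elongation_time``); contributions add.  A spot
    is called visible when the summed intensity reaches
    ``detection_threshold``.
    """

    elongation_time: float = 180.0
    loop_ramp_time: float = 60.0
    intensity_per_rnap: float = 1.0
    detection_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.loop_ramp_time <= self.elongation_time):
            raise ValueError("need 0 < loop_ramp_time <= elongation_time")
        if self.detection_threshold < 0:
            raise ValueError("detection_threshold must be >= 0")


@dataclass(frozen=True)
class Trajectory:
    """One stochastic realisation of the promoter chain.

    ``switch_times[j]`` is when the chain jumped into ``states[j + 1]``;
    ``states[0]`` holds from time 0.  ``initiation_times`` are the RNAP
    initiation instants, all lying inside ON dwells.
    """

    switch_times: np.ndarray
    states: tuple[tuple[int, int], ...]
    initiation_times: np.ndarray
    duration: float
    seed: int | None = None

    def on_intervals(self) -> list[tuple[float, float]]:
        """Closed intervals during which the promoter was ON."""
        times = np.concatenate([[0.0], self.switch_times, [self.duration]])
        out = []
        for j, (_, a) in enumerate(self.states):
            if a == ON and times[j] < self.duration:
                out.append((times[j], min(times[j + 1], self.duration)))
        return out

    def total_on_time(self) -> float:
        return float(sum(b - a for a, b in self.on_intervals()))


# ---------------------------------------------------------------------------
# State space and generator
# ---------------------------------------------------------------------------

def enumerate_states(arch: PromoterArchitecture) -> PromoterStateSpace:
    """All ``2*N + 2`` states ``(i, a)``, i ascending, OFF before ON."""
    states = tuple((i, a) for i in range(arch.n_sites + 1) for a in (OFF, ON))
    return PromoterStateSpace(states)


def binding_rate(i_from: int, arch: PromoterArchitecture, rates: KineticRates,
                 c: float) -> float:
    """Total Bicoid binding rate out of occupancy ``i_from`` at concentration c.

    Equals ``(N - i_from) * kb * c``: each of the remaining free sites is
    found at rate ``kb * c``.  Zero when the array is full.
    """
    if c < 0:
        raise ValueError("concentration must be >= 0")
    if not (0 <= i_from <= arch.n_sites):
        raise ValueError(f"occupancy {i_from} outside 0..{arch.n_sites}")
    return (arch.n_sites - i_from) * rates.kb * c


def activation_rate(i: int, arch: PromoterArchitecture, rates: KineticRates) -> float:
    """Switching-ON rate at occupancy ``i``: 0 below threshold, scaled above."""
    if not (0 <= i <= arch.n_sites):
        raise ValueError(f"occupancy {i} outside 0..{arch.n_sites}")
    return rates.k_on_base * arch.activation_weight(i)


def build_generator(arch: PromoterArchitecture, rates: KineticRates,
                    c: float) -> np.ndarray:
    """Rate matrix Q of the ``2N + 2``-state chain; row sums are zero.

    Convention: ``Q[r, s]`` is the rate from state ``r`` to state ``s``.
    """
    if len(rates.k_off_site) != arch.n_sites:
        raise ConfigurationError(
            f"k_off_site has length {len(rates.k_off_site)}, "
            f"expected {arch.n_sites}"
        )
    space = enumerate_states(arch)
    n = len(space)
    q = np.zeros((n, n))
    for r, (i, a) in enumerate(space.states):
        if i < arch.n_sites:
            q[r, space.index[(i + 1, a)]] += binding_rate(i, arch, rates, c)
        if i > 0:
            q[r, space.index[(i - 1, a)]] += rates.k_off_site[i - 1]
        if a == OFF:
            q[r, space.index[(i, ON)]] += activation_rate(i, arch, rates)
        else:
            q[r, space.index[(i, OFF)]] += rates.k_off_promoter
    np.fill_diagonal(q, q.diagonal() - q.sum(axis=1))
    return q


# ---------------------------------------------------------------------------
# Master equation
# ---------------------------------------------------------------------------

def propagate(generator: np.ndarray, p0: Sequence[float],
              times: Sequence[float]) -> np.ndarray:
    """Solve the master equation dp/dt = Q^T p on the given time grid.

    Uses the matrix exponential stepwise between grid points (exact for a
    time-homogeneous chain; the state spaces here are at most a few dozen
    states).  Returns an array of shape ``(len(times), n_states)``; ``p0``
    applies at ``times[0]``.
    """
    p0 = np.asarray(p0, float)
    times = np.asarray(times, float)
    if p0.ndim != 1 or p0.shape[0] != generator.shape[0]:
        raise ValueError("p0 has wrong length")
    if np.any(p0 < -1e-12) or abs(p0.sum() - 1.0) > 1e-8:
        raise ValueError("p0 must be a probability vector")
    if times.ndim != 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")

    qt = generator.T
    out = np.empty((len(times), len(p0)))
    out[0] = p0
    # cache the exponential for repeated identical steps (uniform grids)
    cache: dict[float, np.ndarray] = {}
    p = p0
    for j in range(1, len(times)):
        dt = round(float(times[j] - times[j - 1]), 12)
        step = cache.get(dt)
        if step is None:
            step = expm(qt * dt)
            cache[dt] = step
        p = step @ p
        out[j] = p
    np.clip(out, 0.0, None, out=out)
    out /= out.sum(axis=1, keepdims=True)
    return out


def p_on_from_probabilities(probabilities: np.ndarray,
                            space: PromoterStateSpace) -> np.ndarray:
    """Marginal probability of the ON promoter state at each time point."""
    return probabilities[..., space.on_mask()].sum(axis=-1)


def steady_state_distribution(generator: np.ndarray) -> np.ndarray:
    """Stationary distribution pi with Q^T pi = 0, nonnegative, normalised.

    For a degenerate chain (e.g. zero concentration with an activation
    threshold, where high-occupancy states are unreachable) the returned
    vector is the absorbing distribution and a warning is issued.
    """
    ns = null_space(generator.T, rcond=1e-10)
    if ns.shape[1] == 0:
        raise np.linalg.LinAlgError("no stationary distribution found")
    if ns.shape[1] > 1:
        warnings.warn(
            "generator is reducible; returning one stationary distribution "
            "(absorbing component)", RuntimeWarning, stacklevel=2,
        )
    pi = None
    for k in range(ns.shape[1]):
        v = ns[:, k]
        if abs(v.sum()) < 1e-12:
            continue
        v = v / v.sum()
        if np.all(v > -1e-9):
            pi = v
            break
    if pi is None:
        # fall back: long-time propagation from the uniform distribution
        n = generator.shape[0]
        rate_scale = max(np.abs(generator.diagonal()).max(), 1e-12)
        pi = propagate(generator, np.full(n, 1.0 / n),
                       [0.0, 1e4 / rate_scale])[-1]
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def steady_state_p_on(model: PromoterModel, c: float) -> float:
    """Stationary ON probability at concentration ``c``."""
    q = build_generator(model.architecture, model.rates, c)
    pi = steady_state_distribution(q)
    return float(p_on_from_probabilities(pi, enumerate_states(model.architecture)))


def spot_probability_from_p_on(p_on: np.ndarray, times: np.ndarray,
                               rnap_rate: float,
                               kernel: SignalKernel) -> np.ndarray:
    """Mean-field probability that a spot is visible at each time.

    A spot is visible when at least one polymerase initiated within the last
    ``elongation_time`` is still on the gene; initiations are Poisson with
    intensity ``rnap_rate * p_on(t)``, hence
    ``P_spot(t) = 1 - exp(-rnap_rate * int_{t - tau}^{t} p_on(s) ds)``.
    This ignores the detection threshold and loop ramp (it counts any
    elongating RNAP); the simulation path applies the full kernel.
    """
    p_on = np.asarray(p_on, float)
    times = np.asarray(times, float)
    # cumulative integral of p_on from times[0]
    cum = np.concatenate([[0.0], np.cumsum(np.diff(times) * 0.5 * (p_on[1:] + p_on[:-1]))])
    lower = np.interp(times - kernel.elongation_time, times, cum,
                      left=0.0, right=cum[-1])
    integral = cum - lower
    return 1.0 - np.exp(-rnap_rate * integral)


def initiation_survival(model: PromoterModel, c: float, duration: float,
                        p0: np.ndarray | None = None) -> float:
    """Exact probability that no RNAP initiates within ``duration``.

    Feynman-Kac: with D the indicator of ON states, the probability of zero
    initiations over a window of length t starting from state distribution
    p0 is ``1^T exp((Q^T - rho*D) t) p0``.  This accounts for burst
    clumping, which the Poisson mean-field formula ignores (Jensen:
    E[exp(-rho*T_on)] >= exp(-rho*E[T_on])).
    """
    arch, rates = model.architecture, model.rates
    q = build_generator(arch, rates, c)
    space = enumerate_states(arch)
    if p0 is None:
        p0 = steady_state_distribution(q)
    sub = q.T - rates.rnap_rate * np.diag(space.on_mask().astype(float))
    v = expm(sub * duration) @ np.asarray(p0, float)
    return float(np.clip(v.sum(), 0.0, 1.0))


def steady_state_spot_probability(model: PromoterModel, c: float,
                                  kernel: SignalKernel,
                                  method: str = "exact") -> float:
    """Stationary probability that an MS2 spot is visible.

    A spot is visible when at least one polymerase initiated within the
    last ``elongation_time`` is still elongating.  ``method='exact'``
    evaluates the Feynman-Kac survival of the stationary chain over that
    window; ``method='poisson'`` is the mean-field formula
    ``1 - exp(-rho * tau * p_on)``, an upper bound that neglects burst
    clumping.  Neither accounts for the detection threshold on summed
    intensity, which only the simulation path applies.
    """
    if method == "poisson":
        p_on = steady_state_p_on(model, c)
        return 1.0 - float(np.exp(
            -model.rates.rnap_rate * kernel.elongation_time * p_on))
    if method != "exact":
        raise ValueError("method must be 'exact' or 'poisson'")
    return 1.0 - initiation_survival(model, c, kernel.elongation_time)


# ---------------------------------------------------------------------------
# Exact stochastic simulation
# ---------------------------------------------------------------------------

def gillespie_simulate(arch: PromoterArchitecture, rates: KineticRates,
                       c: float, duration: float,
                       seed: int | np.random.Generator | None = None) -> Trajectory:
    """Exact stochastic sample of the chain from the post-mitotic (0, OFF) state.

    RNAP initiation instants are drawn as a Poisson process with rate
    ``rnap_rate`` restricted to ON dwells.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = build_generator(arch, rates, c)
    space = enumerate_states(arch)

    state = space.index[(0, OFF)]
    t = 0.0
    switch_times: list[float] = []
    visited = [space.states[state]]
    out_rates = q.copy()
    np.fill_diagonal(out_rates, 0.0)

    while True:
        total = out_rates[state].sum()
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t >= duration:
            break
        state = int(rng.choice(len(space), p=out_rates[state] / total))
        switch_times.append(t)
        visited.append(space.states[state])

    traj = Trajectory(
        switch_times=np.asarray(switch_times),
        states=tuple(visited),
        initiation_times=np.empty(0),
        duration=float(duration),
        seed=seed if isinstance(seed, int) else None,
    )
    inits: list[np.ndarray] = []
    for a, b in traj.on_intervals():
        n = rng.poisson(rates.rnap_rate * (b - a))
        if n:
            inits.append(np.sort(rng.uniform(a, b, size=n)))
    initiation_times = np.concatenate(inits) if inits else np.empty(0)
    return Trajectory(traj.switch_times, traj.states, initiation_times,
                      traj.duration, traj.seed)


def ms2_signal_from_events(traj: Trajectory, kernel: SignalKernel,
                           times: Sequence[float]) -> np.ndarray:
    """Summed MS2 spot intensity (AU) at the requested times."""
    times = np.asarray(times, float)
    if len(times) and (times.min() < -1e-9 or times.max() > traj.duration + 1e-9):
        raise ValueError("times must lie within [0, duration]")
    t0 = traj.initiation_times
    if t0.size == 0:
        return np.zeros_like(times)
    dt = times[:, None] - t0[None, :]
    contrib = np.clip(dt / kernel.loop_ramp_time, 0.0, 1.0)
    contrib[(dt < 0) | (dt > kernel.elongation_time)] = 0.0
    return kernel.intensity_per_rnap * contrib.sum(axis=1)


# ---------------------------------------------------------------------------
# Spatial predictions
# ---------------------------------------------------------------------------

def predicted_kymograph(model: PromoterModel, gradient: BcdGradient,
                        x_grid: Sequence[float], t_grid: Sequence[float],
                        kernel: SignalKernel, *,
                        internal_dt: float = 2.0) -> np.ndarray:
    """Mean-field fraction of nuclei with a visible spot over (t, x).

    For each AP position the master equation is solved from the post-mitotic
    (0, OFF) state at the local concentration, and the ON-probability is
    converted to a spot-visibility probability via the Poisson mean-field
    formula.  Returns an array of shape ``(len(t_grid), len(x_grid))`` with
    values in [0, 1].
    """
    x_grid = np.asarray(x_grid, float)
    t_grid = np.asarray(t_grid, float)
    if np.any(np.diff(t_grid) <= 0) or np.any(np.diff(x_grid) <= 0):
        raise ValueError("grids must be strictly increasing")
    t_end = t_grid[-1]
    fine = np.arange(0.0, t_end + internal_dt, internal_dt)
    if fine[-1] < t_end:
        fine = np.append(fine, t_end)
    arch, rates = model.architecture, model.rates
    space = enumerate_states(arch)
    p0 = np.zeros(len(space))
    p0[space.index[(0, OFF)]] = 1.0
    surface = np.empty((len(t_grid), len(x_grid)))
    for j, x in enumerate(x_grid):
        q = build_generator(arch, rates, float(gradient.concentration(x)))
        probs = propagate(q, p0, fine)
        p_on = p_on_from_probabilities(probs, space)
        p_spot = spot_probability_from_p_on(p_on, fine, rates.rnap_rate, kernel)
        surface[:, j] = np.interp(t_grid, fine, p_spot)
    return np.clip(surface, 0.0, 1.0)


def predicted_steady_profile(model: PromoterModel, gradient: BcdGradient,
                             x_grid: Sequence[float],
                             kernel: SignalKernel | None = None) -> np.ndarray:
    """Stationary spot probability (or ON probability if kernel is None) vs x."""
    x_grid = np.asarray(x_grid, float)
    out = np.empty(len(x_grid))
    for j, x in enumerate(x_grid):
        c = float(gradient.concentration(x))
        if kernel is None:
            out[j] = steady_state_p_on(model, c)
        else:
            out[j] = steady_state_spot_probability(model, c, kernel)
    return out
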