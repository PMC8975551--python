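"""Synthetic LiveFly-style embryos for end-to-end pipeline testing.

Generates per-nucleus MS2 traces with the statistical structure the
analysis assumes: nuclei scattered along the AP axis, a static exponential
Bicoid gradient, independent promoter chains simulated exactly
(Gillespie), spot intensities built from RNAP initiation events through
the elongation/MS2-loop kernel with detection thresholding, an optional
anterior-to-posterior mitotic birth-time wave, and dosage-halved (1X)
replicates.  Output tables use the same schema the ingestion code
validates, so every generated dataset is a valid pipeline input.

The named fixtures approximate the qualitative behaviour of the study's
reporter constructs (6/9/12 Bicoid sites, added Hunchback or Zelda sites).
Their parameter values are synthetic — invented for this package and
calibrated only against coarse published anchors (anterior spot
probability bands, boundary-shift ordering) — not fitted values from any
dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .promoter_model import (
    BcdGradient,
    KineticRates,
    PromoterArchitecture,
    PromoterModel,
    SignalKernel,
    build_generator,
    enumerate_states,
    gillespie_simulate,
    initiation_survival,
    ms2_signal_from_events,
    p_on_from_probabilities,
    propagate,
)
from .trace_analysis import ExpressionPattern, NucleusRecord, table_from_records

__all__ = [
    "EmbryoConfig",
    "sample_embryo_traces",
    "sample_embryo_records",
    "expressing_probability_profile",
    "sample_pattern_pair",
    "fixture_params",
    "FIXTURE_NAMES",
]


@dataclass(frozen=True)
class EmbryoConfig:
    """Study conditions for one synthetic embryo.

    Defaults mirror a nuclear-cycle-13 interphase: 1000 s duration (so the
    600-800 s steady-state window exists), 10 s confocal frame cadence,
    synchronous mitosis (wave speed 0 %EL/s means all nuclei are born at
    t = 0; a positive speed delays birth linearly toward the posterior).
    """

    model: PromoterModel
    gradient: BcdGradient
    kernel: SignalKernel = SignalKernel()
    n_nuclei: int = 200
    ap_range: tuple[float, float] = (10.0, 80.0)
    cycle_duration: float = 1000.0
    mitotic_wave_speed: float = 0.0
    frame_interval: float = 10.0
    intensity_noise_sigma: float = 0.0
    cycle: int = 13
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycle_duration <= 0 or self.frame_interval <= 0:
            raise ValueError("durations and intervals must be positive")
        lo, hi = self.ap_range
        if not (0 <= lo < hi <= 100):
            raise ValueError("ap_range must lie within [0, 100]")
        if self.n_nuclei <= 0:
            raise ValueError("n_nuclei must be positive")


def sample_embryo_records(cfg: EmbryoConfig, embryo_id: str = "sim-0",
                          rng: np.random.Generator | None = None,
                          ) -> list[NucleusRecord]:
    """Simulate one embryo and return per-nucleus records.

    Each nucleus gets a uniform AP position, a birth time set by the
    mitotic wave, an exact stochastic promoter trajectory at its local
    Bicoid concentration, and an intensity trace sampled at the frame
    cadence; intensities below the detection threshold are recorded as 0
    (no spot), emulating upstream spot calling.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.ap_range
    positions = np.sort(rng.uniform(lo, hi, cfg.n_nuclei))
    records = []
    arch, rates = cfg.model.architecture, cfg.model.rates
    for k, x in enumerate(positions):
        birth = (x - lo) / cfg.mitotic_wave_speed if cfg.mitotic_wave_speed > 0 else 0.0
        duration = cfg.cycle_duration - birth
        if duration <= cfg.frame_interval:
            continue
        c = float(cfg.gradient.concentration(x))
        traj = gillespie_simulate(arch, rates, c, duration, rng)
        times = np.arange(cfg.frame_interval, duration + 1e-9, cfg.frame_interval)
        intensity = ms2_signal_from_events(traj, cfg.kernel, times)
        if cfg.intensity_noise_sigma > 0:
            noise = rng.lognormal(0.0, cfg.intensity_noise_sigma, intensity.shape)
            intensity = intensity * noise
        intensity = np.where(intensity >= cfg.kernel.detection_threshold,
                             intensity, 0.0)
        records.append(NucleusRecord(
            embryo_id=embryo_id,
            nucleus_id=f"n{k:04d}",
            ap_position=float(x),
            cycle=cfg.cycle,
            birth_time=float(birth),
            times=times,
            intensity=intensity,
        ))
    return records


def sample_embryo_traces(cfg: EmbryoConfig, embryo_id: str = "sim-0") -> pd.DataFrame:
    """Simulate one embryo as a long-format trace table (ingestion schema)."""
    return table_from_records(sample_embryo_records(cfg, embryo_id))


def expressing_probability_profile(model: PromoterModel, gradient: BcdGradient,
                                   x, duration: float = 1000.0,
                                   method: str = "exact") -> np.ndarray:
    """Probability that a nucleus shows any spot during the cycle.

    A nucleus (born unbound and OFF) expresses if at least one RNAP
    initiates before the cycle ends.  ``method='exact'`` evaluates the
    Feynman-Kac survival of the promoter chain under killing at the
    initiation rate on ON states, which accounts for burst clumping;
    ``method='poisson'`` is the mean-field upper bound
    ``1 - exp(-rnap_rate * int_0^T p_on(t) dt)``.
    """
    x = np.atleast_1d(np.asarray(x, float))
    arch, rates = model.architecture, model.rates
    space = enumerate_states(arch)
    p0 = np.zeros(len(space))
    p0[space.index[(0, 0)]] = 1.0
    out = np.empty(len(x))
    if method == "exact":
        for j, xx in enumerate(x):
            c = float(gradient.concentration(xx))
            out[j] = 1.0 - initiation_survival(model, c, duration, p0)
        return out
    if method != "poisson":
        raise ValueError("method must be 'exact' or 'poisson'")
    dt = 5.0
    times = np.arange(0.0, duration + dt, dt)
    for j, xx in enumerate(x):
        q = build_generator(arch, rates, float(gradient.concentration(xx)))
        p_on = p_on_from_probabilities(propagate(q, p0, times), space)
        integral = np.trapezoid(p_on, times)
        out[j] = 1.0 - np.exp(-rates.rnap_rate * integral)
    return out


def sample_pattern_pair(cfg: EmbryoConfig, n_embryos_2x: int = 3,
                        n_embryos_1x: int = 3, bin_width: float = 2.5,
                        n_per_bin: int | None = None,
                        method: str = "binomial",
                        ) -> tuple[ExpressionPattern, ExpressionPattern]:
    """Fraction-expressing patterns for a 2X / dosage-halved (1X) pair.

    The 1X gradient is the 2X gradient with its amplitude halved and the
    same decay length, so in the infinite-sample limit the 1X pattern is
    the 2X pattern translated anterior by ``lambda * ln 2``.

    ``method='binomial'`` (default) draws per-bin binomial counts around
    the model's analytic expressing probability — fast and exactly
    translation-consistent; ``method='traces'`` simulates full embryos and
    runs the trace-analysis path.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.ap_range
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if n_per_bin is None:
        n_per_bin = max(1, round(cfg.n_nuclei / len(centers)))

    if method == "binomial":
        out = []
        for n_emb, dosage in ((n_embryos_2x, 1.0), (n_embryos_1x, 0.5)):
            grad = cfg.gradient.with_dosage(cfg.gradient.dosage_factor * dosage)
            p = expressing_probability_profile(cfg.model, grad, centers,
                                               cfg.cycle_duration)
            n_tot = n_per_bin * n_emb
            s = rng.binomial(n_tot, p)
            out.append(ExpressionPattern(centers, s / n_tot,
                                         np.full(len(centers), float(n_tot)),
                                         n_emb))
        return out[0], out[1]

    if method != "traces":
        raise ValueError("method must be 'binomial' or 'traces'")
    from .trace_analysis import fraction_expressing_pattern
    out = []
    for tag, n_emb, dosage in (("2x", n_embryos_2x, 1.0), ("1x", n_embryos_1x, 0.5)):
        grad = cfg.gradient.with_dosage(cfg.gradient.dosage_factor * dosage)
        records = []
        for e in range(n_emb):
            emb_cfg = replace(cfg, gradient=grad)
            records.extend(sample_embryo_records(emb_cfg, f"{tag}-{e}", rng))
        out.append(fraction_expressing_pattern(records, bin_width, (lo, hi)))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Named fixtures
# ---------------------------------------------------------------------------

#: Shared defaults: dimensionless concentration with c0 = 1 at the 2X
#: anterior pole; kb carries the concentration scale (kb * c0 = 0.07 /s per
#: site, a synthetic stand-in for a diffusion-limited search rate).
_KB = 0.07
_KU = 0.005          # per-molecule unbinding rate, s^-1 (synthetic)
_K_ON_BASE = 0.0021  # switching-ON rate with exactly K bound, s^-1
_K_OFF = 0.05        # switching-OFF rate, s^-1 (20 s mean burst)
_RNAP = 0.018        # RNAP initiation rate while ON, s^-1


def _rates(n_sites: int, kb: float = _KB, ku: float = _KU,
           k_on_base: float = _K_ON_BASE, k_off: float = _K_OFF,
           rnap: float = _RNAP) -> KineticRates:
    # aggregate unbinding out of S_i: i independent bound molecules
    return KineticRates(kb=kb,
                        k_off_site=tuple(i * ku for i in range(1, n_sites + 1)),
                        k_on_base=k_on_base, k_off_promoter=k_off,
                        rnap_rate=rnap)


def _model(n_sites: int, **kw) -> PromoterModel:
    return PromoterModel(PromoterArchitecture(n_sites=n_sites, k_threshold=3),
                         _rates(n_sites, **kw))


_GRADIENT = BcdGradient(c0=1.0, lambda_decay=15.0, dosage_factor=1.0)

_FIXTURES: dict[str, dict] = {
    # Baseline six-site reporter: bursty, anterior spot probability ~0.47.
    "B6-like": dict(model=_model(6), anchors={
        "anterior_p_spot": (0.4, 0.55)}),
    # Nine sites: higher activation synergy (binomial weight C(9,3)/C(6,3)
    # = 4.2-fold over B6 at full occupancy), spot probability ~0.8.
    "B9-like": dict(model=_model(9), anchors={
        "anterior_p_spot": (0.7, 0.9)}),
    "B12-like": dict(model=_model(12), anchors={}),
    # Added Hunchback sites: less bursty (higher k_on, lower k_off) and a
    # roughly doubled firing rate.
    "H6B6-like": dict(model=_model(6, k_on_base=10 * _K_ON_BASE,
                                   k_off=_K_OFF / 2, rnap=2 * _RNAP),
                      anchors={"anterior_p_spot": (0.9, 1.0)}),
    # Added Zelda sites: faster Bicoid capture only (kb up ~3.2x), which
    # moves the boundary posterior by about lambda * ln(3.2) ~ 17.5 %EL.
    "Z2B6-like": dict(model=_model(6, kb=3.2 * _KB), anchors={}),
    # Endogenous-promoter stand-in: six sites with Hunchback-like promoter
    # kinetics and stickier high-occupancy states (sharper boundary).
    "hbP2-like": dict(model=PromoterModel(
        PromoterArchitecture(n_sites=6, k_threshold=3),
        KineticRates(kb=_KB,
                     k_off_site=tuple(i * _KU * (0.6 ** max(0, i - 3))
                                      for i in range(1, 7)),
                     k_on_base=10 * _K_ON_BASE, k_off_promoter=_K_OFF / 2,
                     rnap_rate=2 * _RNAP)),
        anchors={"anterior_p_spot": (0.9, 1.0)}),
}

FIXTURE_NAMES = tuple(_FIXTURES)


def boundary_centered_model(lambda_decay: float, x_center: float = 52.0,
                            unbinding_cooperativity: float = 0.4,
                            ) -> tuple[PromoterModel, BcdGradient]:
    """Nine-site cooperative test construct with its boundary at ``x_center``.

    High-occupancy states unbind more slowly (each occupancy step beyond
    the activation threshold scales the per-molecule unbinding rate by
    ``unbinding_cooperativity``), which sharpens the expression boundary;
    the Bicoid capture rate is scaled so the fraction-expressing boundary
    sits at ``x_center`` %EL for the requested gradient decay length.
    Intended for dosage-shift recovery studies, where the boundary must
    stay inside the shift-fitting window for every decay length.
    """
    n, ku = 9, _KU
    k_off_site = tuple(i * ku * unbinding_cooperativity ** max(0, i - 3)
                       for i in range(1, n + 1))
    arch = PromoterArchitecture(n_sites=n, k_threshold=3)
    gradient = BcdGradient(c0=1.0, lambda_decay=lambda_decay, dosage_factor=1.0)

    def half_gap(log_kb: float) -> float:
        rates = KineticRates(kb=float(np.exp(log_kb)), k_off_site=k_off_site,
                             k_on_base=_K_ON_BASE, k_off_promoter=_K_OFF,
                             rnap_rate=_RNAP)
        p = expressing_probability_profile(PromoterModel(arch, rates), gradient,
                                           x_center)
        return float(p[0]) - 0.5

    lo, hi = np.log(_KB) - 4.0, np.log(_KB) + x_center / lambda_decay
    from scipy.optimize import brentq
    log_kb = brentq(half_gap, lo, hi, xtol=1e-4)
    rates = KineticRates(kb=float(np.exp(log_kb)), k_off_site=k_off_site,
                         k_on_base=_K_ON_BASE, k_off_promoter=_K_OFF,
                         rnap_rate=_RNAP)
    return PromoterModel(arch, rates), gradient


def fixture_params(name: str) -> tuple[PromoterModel, BcdGradient, dict]:
    """Named synthetic parameter set emulating one reporter construct.

    Returns ``(model, gradient, metadata)``; metadata carries the anchor
    bands the fixture was calibrated against.  All values are invented for
    this package (see module docstring).
    """
    if name not in _FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; valid names: {', '.join(FIXTURE_NAMES)}"
        )
    entry = _FIXTURES[name]
    return entry["model"], _GRADIENT, {"name": name, "anchors": dict(entry["anchors"]),
                                       "synthetic": True}
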