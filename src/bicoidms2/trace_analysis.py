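"""Per-nucleus feature extraction from MS2 spot-intensity traces.

Input is a table of live-imaging traces, one row per frame, exported per
nucleus with its AP position (%EL), nuclear cycle and post-mitotic birth
time.  Detection thresholding is assumed to have happened upstream (at
trace generation or ingestion): a frame with ``intensity > 0`` carries a
visible spot, ``intensity == 0`` means no spot.

Extracted features per nucleus:

* ``expressed`` — whether any spot was seen during the cycle;
* ``t0`` — onset time of the first spot, relative to the nucleus's birth;
* ``p_spot`` — fraction of frames with a spot within the steady-state
  window (600-800 s into the cycle by default), a burstiness readout;
* ``mu_i`` — mean spot intensity over active frames only.

Ensemble statistics: the fraction-expressing pattern along the AP axis,
time-resolved kymographs of the fraction of active loci, and the time for
the expression boundary to converge to its final position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NucleusRecord",
    "TraceFeatures",
    "ExpressionPattern",
    "Kymograph",
    "records_from_table",
    "table_from_records",
    "onset_time",
    "p_spot_steady",
    "trace_features",
    "mean_active_intensity",
    "fraction_expressing_pattern",
    "kymograph_from_traces",
    "boundary_convergence_time",
    "STEADY_WINDOW",
    "ANTERIOR_WINDOW",
]

#: Steady-state window for the spot probability, seconds into the cycle.
STEADY_WINDOW = (600.0, 800.0)

#: Anterior analysis window, %EL (20 +/- 2.5).
ANTERIOR_WINDOW = (17.5, 22.5)

TRACE_COLUMNS = ["embryo_id", "nucleus_id", "ap_percent_el", "cycle",
                 "birth_time_s", "time_s", "intensity_au"]


@dataclass(frozen=True)
class NucleusRecord:
    """One nucleus: AP position, birth time and its intensity time series.

    ``times`` are seconds relative to the nucleus's post-mitotic birth;
    ``birth_time`` is in the embryo clock of the cycle.
    """

    embryo_id: str
    nucleus_id: str
    ap_position: float
    cycle: int
    birth_time: float
    times: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        y = np.asarray(self.intensity, float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensity", y)
        if t.size == 0:
            raise ValueError("empty trace")
        if t.shape != y.shape:
            raise ValueError("times and intensity must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("intensity must be >= 0")
        if not (0.0 <= self.ap_position <= 100.0):
            raise ValueError(f"ap_position {self.ap_position} outside [0, 100]")


@dataclass(frozen=True)
class TraceFeatures:
    expressed: bool
    t0: float | None
    p_spot: float | None
    mu_i: float | None


@dataclass(frozen=True)
class ExpressionPattern:
    """Fraction of expressing nuclei per AP bin (bin centers in %EL)."""

    ap_bins: np.ndarray
    fraction: np.ndarray
    n_nuclei: np.ndarray
    n_embryos: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "ap_bins", np.asarray(self.ap_bins, float))
        object.__setattr__(self, "fraction", np.asarray(self.fraction, float))
        object.__setattr__(self, "n_nuclei", np.asarray(self.n_nuclei, float))
        if np.any(self.fraction < -1e-12) or np.any(self.fraction > 1 + 1e-12):
            raise ValueError("fractions must lie in [0, 1]")
        if np.any(self.n_nuclei < 0):
            raise ValueError("counts must be >= 0")

    @property
    def successes(self) -> np.ndarray:
        return self.fraction * self.n_nuclei


@dataclass(frozen=True)
class Kymograph:
    """Fraction of loci with a visible spot per (time bin, AP bin)."""

    t_bins: np.ndarray
    ap_bins: np.ndarray
    fraction_active: np.ndarray  # shape (n_t, n_x); NaN where no nuclei
    counts: np.ndarray           # nuclei observed per cell

    def __post_init__(self) -> None:
        f = np.asarray(self.fraction_active, float)
        ok = f[np.isfinite(f)]
        if ok.size and (ok.min() < -1e-12 or ok.max() > 1 + 1e-12):
            raise ValueError("fraction_active must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Table <-> records
# ---------------------------------------------------------------------------

def records_from_table(table: pd.DataFrame) -> list[NucleusRecord]:
    """Group a long-format trace table into per-nucleus records."""
    missing = [c for c in TRACE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trace table missing columns: {missing}")
    records = []
    for (emb, nuc), g in table.groupby(["embryo_id", "nucleus_id"], sort=True):
        g = g.sort_values("time_s")
        records.append(NucleusRecord(
            embryo_id=str(emb),
            nucleus_id=str(nuc),
            ap_position=float(g["ap_percent_el"].iloc[0]),
            cycle=int(g["cycle"].iloc[0]),
            birth_time=float(g["birth_time_s"].iloc[0]),
            times=g["time_s"].to_numpy(float),
            intensity=g["intensity_au"].to_numpy(float),
        ))
    return records


def table_from_records(records: Iterable[NucleusRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(pd.DataFrame({
            "embryo_id": r.embryo_id,
            "nucleus_id": r.nucleus_id,
            "ap_percent_el": r.ap_position,
            "cycle": r.cycle,
            "birth_time_s": r.birth_time,
            "time_s": r.times,
            "intensity_au": r.intensity,
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Per-nucleus features
# ---------------------------------------------------------------------------

def onset_time(record: NucleusRecord) -> float | None:
    """Time of the first visible spot relative to birth; None if never seen."""
    active = record.intensity > 0
    if not active.any():
        return None
    return float(record.times[active][0])


def p_spot_steady(record: NucleusRecord,
                  window: tuple[float, float] = STEADY_WINDOW) -> float | None:
    """Fraction of frames with a spot inside the steady-state window.

    Computed on whatever frames overlap the window; returns None (with no
    frames to count) when the trace does not reach the window at all.
    """
    sel = (record.times >= window[0]) & (record.times <= window[1])
    if not sel.any():
        return None
    return float(np.mean(record.intensity[sel] > 0))


def trace_features(record: NucleusRecord,
                   steady_window: tuple[float, float] = STEADY_WINDOW) -> TraceFeatures:
    t0 = onset_time(record)
    active = record.intensity > 0
    mu = float(record.intensity[active].mean()) if active.any() else None
    return TraceFeatures(
        expressed=t0 is not None,
        t0=t0,
        p_spot=p_spot_steady(record, steady_window),
        mu_i=mu,
    )


def mean_active_intensity(records: Iterable[NucleusRecord],
                          anterior_window: tuple[float, float] = ANTERIOR_WINDOW,
                          steady_window: tuple[float, float] = STEADY_WINDOW,
                          ) -> float | None:
    """Mean spot intensity over active frames, anterior nuclei, steady state.

    Only frames with a detected spot enter the mean (zero-intensity frames
    are excluded by definition).  Returns None when no active frame exists
    in the window.
    """
    vals: list[np.ndarray] = []
    for r in records:
        if not (anterior_window[0] <= r.ap_position <= anterior_window[1]):
            continue
        sel = ((r.times >= steady_window[0]) & (r.times <= steady_window[1])
               & (r.intensity > 0))
        if sel.any():
            vals.append(r.intensity[sel])
    if not vals:
        return None
    return float(np.concatenate(vals).mean())


# ---------------------------------------------------------------------------
# Ensemble statistics
# ---------------------------------------------------------------------------

def _bin_edges(positions: np.ndarray, bin_width: float,
               ap_range: tuple[float, float] | None) -> np.ndarray:
    if ap_range is None:
        lo = np.floor(positions.min() / bin_width) * bin_width
        hi = np.ceil(positions.max() / bin_width) * bin_width
    else:
        lo, hi = ap_range
    n = max(1, int(round((hi - lo) / bin_width)))
    return lo + bin_width * np.arange(n + 1)


def fraction_expressing_pattern(records: Sequence[NucleusRecord],
                                bin_width: float = 2.5,
                                ap_range: tuple[float, float] | None = None,
                                ) -> ExpressionPattern:
    """Per-AP-bin fraction of nuclei with any spot during the cycle.

    Empty bins are omitted from the returned pattern.
    """
    if not records:
        raise ValueError("no records")
    pos = np.array([r.ap_position for r in records])
    expressed = np.array([(r.intensity > 0).any() for r in records])
    edges = _bin_edges(pos, bin_width, ap_range)
    idx = np.clip(np.digitize(pos, edges) - 1, 0, len(edges) - 2)
    n = np.bincount(idx, minlength=len(edges) - 1).astype(float)
    s = np.bincount(idx, weights=expressed.astype(float), minlength=len(edges) - 1)
    keep = n > 0
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_embryos = len({r.embryo_id for r in records})
    return ExpressionPattern(centers[keep], s[keep] / n[keep], n[keep], n_embryos)


def kymograph_from_traces(records: Sequence[NucleusRecord],
                          t_bin: float = 10.0, ap_bin: float = 2.5,
                          align: str = "cycle",
                          t_range: tuple[float, float] | None = None,
                          ap_range: tuple[float, float] | None = None,
                          ) -> Kymograph:
    """Fraction of nuclei with a visible spot per (time, AP) cell.

    ``align='cycle'`` (default) places each frame on the embryo clock
    (birth time + frame time); ``align='birth'`` uses times relative to
    each nucleus's birth.  A nucleus counts toward a time bin only if it
    has a frame there; the fraction is over frames with a spot.
    """
    if align not in ("cycle", "birth"):
        raise ValueError("align must be 'cycle' or 'birth'")
    if not records:
        raise ValueError("no records")
    pos = np.array([r.ap_position for r in records])
    ap_edges = _bin_edges(pos, ap_bin, ap_range)
    all_t = [r.times + (r.birth_time if align == "cycle" else 0.0) for r in records]
    tmin = min(t.min() for t in all_t)
    tmax = max(t.max() for t in all_t)
    if t_range is not None:
        tmin, tmax = t_range
    t0 = np.floor(tmin / t_bin) * t_bin
    n_t = max(1, int(np.ceil((tmax - t0) / t_bin)))
    t_edges = t0 + t_bin * np.arange(n_t + 1)

    active = np.zeros((n_t, len(ap_edges) - 1))
    counts = np.zeros_like(active)
    for r, t_abs in zip(records, all_t):
        j = int(np.clip(np.digitize(r.ap_position, ap_edges) - 1, 0, len(ap_edges) - 2))
        ti = np.clip(np.digitize(t_abs, t_edges) - 1, 0, n_t - 1)
        spot = r.intensity > 0
        # one vote per nucleus per time bin: spot if any frame in the bin has one
        for b in np.unique(ti):
            counts[b, j] += 1
            if spot[ti == b].any():
                active[b, j] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(counts > 0, active / np.maximum(counts, 1), np.nan)
    t_centers = 0.5 * (t_edges[:-1] + t_edges[1:])
    ap_centers = 0.5 * (ap_edges[:-1] + ap_edges[1:])
    return Kymograph(t_centers, ap_centers, frac, counts)


def _halfmax_boundary(x: np.ndarray, f: np.ndarray, n: np.ndarray) -> float | None:
    """Boundary position of one kymograph row: sigmoid fit with fixed plateau.

    The anterior plateau ``fmax`` is fixed to the mean of the most anterior
    bins of the row, which stabilises early-cycle fits with few active
    nuclei; only (x0, eta) are free.  Returns None when the row has no
    boundary in frame (plateau too low or no half-max crossing).
    """
    from scipy.optimize import least_squares

    ok = np.isfinite(f) & (n > 0)
    x, f, n = x[ok], f[ok], n[ok]
    if len(x) < 4:
        return None
    n_ant = max(1, min(3, len(x) // 4))
    fmax = float(f[:n_ant].mean())
    if fmax < 0.2 or f.min() > 0.6 * fmax:
        return None  # no boundary visible in this row
    below = np.nonzero(f <= fmax / 2)[0]
    x0_init = x[below[0]] if below.size else x[len(x) // 2]

    def resid(theta):
        x0, log_eta = theta
        eta = np.exp(log_eta)
        z = np.clip((x - x0) * eta, -500, 500)
        model = fmax / (1.0 + np.exp(z))
        w = np.sqrt(n / (f * (1 - f) + 0.05))
        return w * (model - f)

    best = None
    for eta0 in (0.1, 0.3, 1.0):
        sol = least_squares(resid, [x0_init, np.log(eta0)],
                            bounds=([x.min() - 20, np.log(1e-3)],
                                    [x.max() + 20, np.log(1e2)]))
        if best is None or sol.cost < best.cost:
            best = sol
    x0 = float(best.x[0])
    if not (x.min() - 5 <= x0 <= x.max() + 5):
        return None
    return x0


def boundary_convergence_time(kymo: Kymograph,
                              final_window: float = 100.0,
                              tolerance: float = 2.0) -> float:
    """Earliest time after which the boundary stays within +/- tolerance
    (%EL) of its final position (mean over the last ``final_window`` s).

    The per-time-bin boundary is the half-max position of a sigmoid fit to
    that bin's fraction-active profile.  Time bins without a visible
    boundary are skipped; a boundary must exist in at least 80% of bins.
    """
    boundaries = np.array([
        b if (b := _halfmax_boundary(kymo.ap_bins, kymo.fraction_active[i],
                                     kymo.counts[i])) is not None else np.nan
        for i in range(len(kymo.t_bins))
    ])
    valid = np.isfinite(boundaries)
    if valid.mean() < 0.8:
        raise ValueError(
            f"boundary found in only {valid.mean():.0%} of time bins (<80%)"
        )
    t = kymo.t_bins[valid]
    b = boundaries[valid]
    final = b[t >= t[-1] - final_window]
    target = float(final.mean())
    inside = np.abs(b - target) <= tolerance
    # earliest time from which the boundary never leaves the band
    conv_idx = 0
    for i in range(len(b) - 1, -1, -1):
        if not inside[i]:
            conv_idx = i + 1
            break
    if conv_idx >= len(t):
        raise ValueError("boundary never settles within the tolerance band")
    return float(t[conv_idx])
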