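"""Trace features, expression patterns, kymographs, boundary convergence."""

from __future__ import annotations

import numpy as np
import pytest

from bicoidms2.trace_analysis import (
    ExpressionPattern,
    Kymograph,
    NucleusRecord,
    boundary_convergence_time,
    fraction_expressing_pattern,
    kymograph_from_traces,
    mean_active_intensity,
    onset_time,
    p_spot_steady,
    records_from_table,
    table_from_records,
    trace_features,
)


def nucleus(intensity, times=None, ap=20.0, nid="n0", emb="e0", birth=0.0):
    intensity = np.asarray(intensity, float)
    if times is None:
        times = 10.0 * np.arange(1, len(intensity) + 1)
    return NucleusRecord(embryo_id=emb, nucleus_id=nid, ap_position=ap,
                         cycle=13, birth_time=birth, times=np.asarray(times, float),
                         intensity=intensity)


# ---------------------------------------------------------------------------
# Record validation
# ---------------------------------------------------------------------------

def test_record_rejects_bad_inputs():
    with pytest.raises(ValueError):
        nucleus([])
    with pytest.raises(ValueError):
        nucleus([1.0, 1.0], times=[10.0, 10.0])
    with pytest.raises(ValueError):
        nucleus([-1.0])
    with pytest.raises(ValueError):
        nucleus([1.0], ap=120.0)


def test_table_round_trip():
    records = [nucleus([0.0, 1.0, 2.0], nid="a"), nucleus([3.0], nid="b", ap=40.0)]
    back = records_from_table(table_from_records(records))
    assert len(back) == 2
    np.testing.assert_allclose(back[0].intensity, [0.0, 1.0, 2.0])
    assert back[1].ap_position == 40.0


# ---------------------------------------------------------------------------
# Per-nucleus features
# ---------------------------------------------------------------------------

def test_onset_time_none_when_silent_and_exact_when_injected():
    assert onset_time(nucleus(np.zeros(50))) is None
    y = np.zeros(50)
    y[11] = 2.0  # frame at t = 120 s
    assert onset_time(nucleus(y)) == pytest.approx(120.0)


def test_p_spot_steady_values():
    always = nucleus(np.ones(100))        # frames every 10 s up to 1000 s
    assert p_spot_steady(always) == 1.0
    alt = nucleus(np.tile([1.0, 0.0], 50))
    assert p_spot_steady(alt) == pytest.approx(0.5, abs=0.05)
    short = nucleus(np.ones(5))           # never reaches the 600-800 s window
    assert p_spot_steady(short) is None


def test_p_spot_invariant_to_intensity_rescaling():
    rng = np.random.default_rng(2)
    y = np.where(rng.random(100) < 0.4, rng.uniform(0.5, 3.0, 100), 0.0)
    assert p_spot_steady(nucleus(y)) == p_spot_steady(nucleus(10.0 * y))


def test_trace_features_bundle():
    y = np.zeros(100)
    y[60:80] = 3.0   # frames 610-800 s
    feats = trace_features(nucleus(y))
    assert feats.expressed
    assert feats.t0 == pytest.approx(610.0)
    assert feats.mu_i == pytest.approx(3.0)
    assert 0.9 <= feats.p_spot <= 1.0


def test_mean_active_intensity_excludes_zero_frames_and_window():
    y = np.zeros(100)
    y[59:80] = 3.0
    inside = nucleus(y, ap=20.0)
    outside = nucleus(np.full(100, 9.0), ap=50.0)  # not anterior
    assert mean_active_intensity([inside, outside]) == pytest.approx(3.0)
    assert mean_active_intensity([nucleus(np.zeros(100))]) is None


# ---------------------------------------------------------------------------
# Ensemble patterns
# ---------------------------------------------------------------------------

def test_all_expressing_gives_flat_ones():
    records = [nucleus(np.ones(10), ap=a, nid=f"n{j}")
               for j, a in enumerate(np.linspace(15, 60, 20))]
    pattern = fraction_expressing_pattern(records)
    np.testing.assert_allclose(pattern.fraction, 1.0)


def test_pattern_invariant_under_record_permutation():
    rng = np.random.default_rng(5)
    records = [nucleus(np.where(rng.random(10) < 0.5, 1.0, 0.0),
                       ap=float(rng.uniform(10, 70)), nid=f"n{j}")
               for j in range(60)]
    p1 = fraction_expressing_pattern(records)
    shuffled = list(records)
    rng.shuffle(shuffled)
    p2 = fraction_expressing_pattern(shuffled)
    np.testing.assert_array_equal(p1.ap_bins, p2.ap_bins)
    np.testing.assert_array_equal(p1.fraction, p2.fraction)


def test_pattern_validation():
    with pytest.raises(ValueError):
        ExpressionPattern(np.array([20.0]), np.array([1.5]), np.array([10.0]))
    with pytest.raises(ValueError):
        fraction_expressing_pattern([])


# ---------------------------------------------------------------------------
# Kymographs
# ---------------------------------------------------------------------------

def test_single_always_on_nucleus_gives_unit_column():
    kymo = kymograph_from_traces([nucleus(np.ones(30))])
    col = kymo.fraction_active[:, 0]
    np.testing.assert_allclose(col[np.isfinite(col)], 1.0)
    assert kymo.counts.sum() > 0


def test_kymograph_masks_empty_regions():
    records = [nucleus(np.ones(10), ap=20.0), nucleus(np.ones(10), ap=60.0, nid="n1")]
    kymo = kymograph_from_traces(records, ap_range=(10.0, 70.0))
    assert np.isnan(kymo.fraction_active[:, 10]).all()  # bin at 35-37.5 %EL empty


def test_kymograph_invariant_under_record_permutation():
    rng = np.random.default_rng(8)
    records = [nucleus((rng.random(20) < 0.5).astype(float),
                       ap=float(rng.uniform(10, 70)), nid=f"n{j}")
               for j in range(40)]
    k1 = kymograph_from_traces(records)
    shuffled = list(records)
    rng.shuffle(shuffled)
    k2 = kymograph_from_traces(shuffled)
    np.testing.assert_array_equal(k1.fraction_active, k2.fraction_active)


def test_birth_alignment_shifts_time_axis():
    r = nucleus(np.ones(10), birth=200.0)
    k_cycle = kymograph_from_traces([r], align="cycle")
    k_birth = kymograph_from_traces([r], align="birth")
    assert k_cycle.t_bins[0] == pytest.approx(k_birth.t_bins[0] + 200.0)


# ---------------------------------------------------------------------------
# Boundary convergence
# ---------------------------------------------------------------------------

def _kymo_with_moving_boundary(x0_of_t, t_grid, x_grid, n=400):
    frac = np.empty((len(t_grid), len(x_grid)))
    for i, t in enumerate(t_grid):
        frac[i] = 1.0 / (1.0 + np.exp((x_grid - x0_of_t(t)) * 0.8))
    counts = np.full_like(frac, float(n))
    return Kymograph(t_grid, x_grid, frac, counts)


def test_static_boundary_converges_at_first_bin():
    t = np.arange(5.0, 1000.0, 10.0)
    x = np.arange(11.25, 80.0, 2.5)
    kymo = _kymo_with_moving_boundary(lambda t: 45.0, t, x)
    assert boundary_convergence_time(kymo) == pytest.approx(t[0])


def test_moving_boundary_convergence_time_recovered():
    # boundary moves posterior from 35 to 50 %EL, stopping at t* = 400 s
    t_star = 400.0
    t = np.arange(5.0, 1000.0, 10.0)
    x = np.arange(11.25, 80.0, 2.5)
    kymo = _kymo_with_moving_boundary(
        lambda t: 35.0 + 15.0 * min(t, t_star) / t_star, t, x)
    conv = boundary_convergence_time(kymo)
    # within one time bin of the moment the boundary enters the +/-2 band
    expected = t_star * (1.0 - 2.0 / 15.0)
    assert abs(conv - expected) <= 10.0 + 1e-9


def test_boundary_absent_raises():
    t = np.arange(5.0, 1000.0, 10.0)
    x = np.arange(11.25, 80.0, 2.5)
    flat = Kymograph(t, x, np.full((len(t), len(x)), 0.02),
                     np.full((len(t), len(x)), 100.0))
    with pytest.raises(ValueError):
        boundary_convergence_time(flat)
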