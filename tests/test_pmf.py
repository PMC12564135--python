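"""Forward–reverse work bookkeeping and PMF estimation."""

import numpy as np
import pytest

from ligmem.dynamics import LangevinParams, PullProtocol, WorkTrace
from ligmem.pmf import (
    MeanWorkProfile,
    average_works,
    bin_work,
    default_grid,
    estimate_dissipation,
    estimate_friction_diffusion,
    estimate_pmf,
    read_work_trace,
    write_work_trace,
)

from conftest import DW, FLAT, DW_PARAMS, make_pullset


def synthetic_trace(direction, lam, W, v=0.1, k=10.0):
    z0, z1 = (lam[0], lam[-1])
    proto = PullProtocol(direction, v, k, z0, z1, record_stride=1)
    n = len(lam)
    return WorkTrace(direction=direction, times=np.abs(lam - lam[0]) / v,
                     lam=np.asarray(lam, float), z=np.asarray(lam, float),
                     f=np.zeros(n), W=np.asarray(W, float), protocol=proto, seed=0)


# ------------------------------------------------------------------ bin_work

def test_bin_work_identity_when_lambda_hits_nodes():
    grid = default_grid(0.0, 10.0, 0.5)
    tr = synthetic_trace("F", grid, 0.3 * grid)
    assert np.allclose(bin_work(tr, grid), 0.3 * grid, atol=1e-12)


def test_bin_work_quadratic_closed_form():
    lam = np.linspace(0.0, 19.0, 3801)
    c = 0.17
    tr = synthetic_trace("F", lam, c * lam**2)
    grid = default_grid(0.0, 19.0, 0.5)
    assert np.allclose(bin_work(tr, grid), c * grid**2, atol=1e-9)


def test_bin_work_refine_coarsen_consistency():
    lam = np.linspace(0.0, 19.0, 1901)
    tr = synthetic_trace("F", lam, np.sin(lam))
    coarse = default_grid(0.0, 19.0, 1.0)
    fine = default_grid(0.0, 19.0, 0.5)
    assert np.allclose(bin_work(tr, fine)[::2], bin_work(tr, coarse), atol=1e-12)


def test_bin_work_reverse_reindexes_to_segment_work():
    # reverse pull from 10 to 0 with W(lambda) known analytically
    lam = np.linspace(10.0, 0.0, 1001)
    W = 0.2 * (10.0 - lam)  # cumulative work grows along the pull
    tr = synthetic_trace("R", lam, W)
    grid = default_grid(0.0, 10.0, 1.0)
    got = bin_work(tr, grid)
    # segment work from z to the end (z=0): W_total - W(z)
    assert np.allclose(got, 2.0 - 0.2 * (10.0 - grid), atol=1e-12)


def test_bin_work_grid_outside_traversal_rejected():
    tr = synthetic_trace("F", np.linspace(2.0, 8.0, 101), np.zeros(101))
    with pytest.raises(ValueError, match="outside traversed"):
        bin_work(tr, default_grid(0.0, 10.0, 1.0))


# -------------------------------------------------------------- average_works

def test_single_trace_mean_and_undefined_se():
    grid = default_grid(0.0, 10.0, 1.0)
    f = synthetic_trace("F", np.linspace(0, 10, 101), np.linspace(0, 3, 101))
    r = synthetic_trace("R", np.linspace(10, 0, 101), np.linspace(0, 1, 101))
    mw = average_works([f, r], grid)
    assert np.allclose(mw.mean_F, bin_work(f, grid))
    assert mw.se_F is None and mw.se_R is None


def test_duplicated_traces_zero_se():
    grid = default_grid(0.0, 10.0, 1.0)
    f = synthetic_trace("F", np.linspace(0, 10, 101), np.linspace(0, 3, 101))
    r = synthetic_trace("R", np.linspace(10, 0, 101), np.linspace(0, 1, 101))
    mw = average_works([f, f, f, r, r], grid)
    assert np.allclose(mw.se_F, 0.0)
    assert np.allclose(mw.se_R, 0.0)


def test_mixed_protocols_rejected():
    grid = default_grid(0.0, 10.0, 1.0)
    f = synthetic_trace("F", np.linspace(0, 10, 101), np.zeros(101), v=0.1)
    r = synthetic_trace("R", np.linspace(10, 0, 101), np.zeros(101), v=0.2)
    with pytest.raises(ValueError, match="mixed protocols"):
        average_works([f, r], grid)


def test_missing_direction_rejected():
    grid = default_grid(0.0, 10.0, 1.0)
    f = synthetic_trace("F", np.linspace(0, 10, 101), np.zeros(101))
    with pytest.raises(ValueError, match="each direction"):
        average_works([f], grid)


# -------------------------------------------------------------- estimate_pmf

def test_symmetric_works_give_zero_pmf():
    grid = default_grid(0.0, 10.0, 1.0)
    m = np.linspace(0, 2, len(grid))
    mw = MeanWorkProfile(z=grid, mean_F=m, mean_R=m.copy(), se_F=None, se_R=None,
                         n_F=3, n_R=3, v=0.1)
    prof = estimate_pmf(mw, anchor=None)
    assert np.allclose(prof.dU, 0.0)


def test_swapping_mean_work_columns_negates_unanchored_pmf():
    grid = default_grid(0.0, 10.0, 1.0)
    rng = np.random.default_rng(0)
    mF, mR = rng.normal(size=len(grid)), rng.normal(size=len(grid))
    a = estimate_pmf(MeanWorkProfile(grid, mF, mR, None, None, 2, 2, 0.1), anchor=None)
    b = estimate_pmf(MeanWorkProfile(grid, mR, mF, None, None, 2, 2, 0.1), anchor=None)
    assert np.allclose(a.dU, -b.dU, atol=1e-14)


def test_anchoring_shifts_by_constant_only():
    grid = default_grid(0.0, 19.0, 0.5)
    rng = np.random.default_rng(1)
    mw = MeanWorkProfile(grid, rng.normal(size=len(grid)), rng.normal(size=len(grid)),
                         None, None, 2, 2, 0.1)
    a = estimate_pmf(mw, anchor=19.0).dU
    b = estimate_pmf(mw, anchor=0.0).dU
    diff = a - b
    assert np.allclose(diff, diff[0])
    with pytest.raises(ValueError, match="anchor"):
        estimate_pmf(mw, anchor=40.0)


def test_trace_label_swap_leaves_anchored_pmf_invariant(flat_nullset):
    # the estimator is direction-symmetric: relabelling F<->R changes only
    # the unanchored reference constant
    grid = default_grid(0.0, 19.0, 0.5)
    a = estimate_pmf(average_works(flat_nullset, grid), anchor=9.5).dU
    swapped = []
    for t in flat_nullset:
        d = "R" if t.direction == "F" else "F"
        swapped.append(WorkTrace(direction=d, times=t.times, lam=t.lam, z=t.z,
                                 f=t.f, W=t.W, protocol=t.protocol, seed=t.seed))
    b = estimate_pmf(average_works(swapped, grid), anchor=9.5).dU
    assert np.allclose(a, b, atol=1e-10)


# ------------------------------------------------------- physics (generator)

def test_double_well_recovery_rmse(dw_pullset):
    grid = default_grid(0.0, 19.0, 0.5)
    mw = average_works(dw_pullset, grid)
    prof = estimate_pmf(mw, anchor=19.0)
    true = DW.energy(grid) - DW.energy(19.0)
    rmse = float(np.sqrt(np.mean((prof.dU - true) ** 2)))
    assert rmse <= 0.5


def test_rmse_decreases_with_pull_count():
    grid = default_grid(0.0, 19.0, 0.5)
    true = DW.energy(grid) - DW.energy(19.0)
    rmses = {}
    for n, base in ((5, 61000), (20, 62000), (80, 63000)):
        traces = make_pullset(DW, DW_PARAMS, v=0.1, k=10.0,
                              n_per_direction=n, seed_base=base)
        prof = estimate_pmf(average_works(traces, grid), anchor=19.0)
        rmses[n] = float(np.sqrt(np.mean((prof.dU - true) ** 2)))
    assert rmses[5] > rmses[20] > rmses[80]


def test_flat_null_and_second_law(flat_nullset):
    grid = default_grid(0.0, 19.0, 0.5)
    mw = average_works(flat_nullset, grid)
    prof = estimate_pmf(mw, anchor=None)
    assert np.all(np.abs(prof.dU) <= 3 * np.maximum(prof.se, 1e-12))
    Wd = estimate_dissipation(mw)
    se_wd = 0.5 * np.sqrt(mw.se_F**2 + mw.se_R**2)
    assert np.all(Wd >= -3 * se_wd)


def test_jensen_bounds_nodewise(dw_pullset):
    grid = default_grid(0.0, 19.0, 0.5)
    mw = average_works(dw_pullset, grid)
    dU = estimate_pmf(mw, anchor=None).dU  # referenced at the forward start
    assert np.all(mw.mean_F - dU >= -3 * np.maximum(mw.se_F, 1e-12))
    assert np.all(mw.mean_R + dU >= -3 * np.maximum(mw.se_R, 1e-12))


def test_diffusion_profile_recovered_on_flat_potential():
    par = LangevinParams(D=20.0, T=300.0, dt=2e-4)
    grid = default_grid(0.0, 19.0, 0.5)
    traces = make_pullset(FLAT, par, v=5.0, k=10.0, n_per_direction=50,
                          seed_base=71000, stride=20)
    mw = average_works(traces, grid)
    D = estimate_friction_diffusion(mw, T=300.0)
    valid = D[np.isfinite(D)]
    assert len(valid) > len(grid) // 2
    assert np.median(valid) == pytest.approx(20.0, rel=0.2)
    # reversible limit: slow pull at the same friction dissipates ~ v
    assert np.all(np.isnan(D) | (D > 0))


def test_doubling_speed_doubles_dissipation_slope():
    par = LangevinParams(D=20.0, T=300.0, dt=2e-4)
    grid = default_grid(0.0, 19.0, 0.5)
    totals = {}
    for v, stride, base in ((5.0, 20, 72000), (10.0, 10, 73000)):
        traces = make_pullset(FLAT, par, v=v, k=10.0, n_per_direction=50,
                              seed_base=base, stride=stride)
        mw = average_works(traces, grid)
        Wd = estimate_dissipation(mw)
        se = 0.5 * np.sqrt(mw.se_F**2 + mw.se_R**2)
        totals[v] = (Wd[-1] - Wd[0], se[-1])
    (w1, s1), (w2, s2) = totals[5.0], totals[10.0]
    ratio = w2 / w1
    se_ratio = ratio * np.sqrt((s1 / w1) ** 2 + (s2 / w2) ** 2)
    assert ratio == pytest.approx(2.0, abs=max(3 * se_ratio, 0.05))


def test_quasi_static_limit_dissipation_vanishes():
    # dissipation per Å is kB*T*v/D: at v=0.05 it is ~1e-4 kcal/mol/Å
    par = LangevinParams(D=100.0, T=300.0, dt=5e-5)
    grid = default_grid(0.0, 4.0, 0.5)
    traces = make_pullset(FLAT, par, v=0.05, k=10.0, n_per_direction=12,
                          seed_base=74000, stride=200, z_lo=0.0, z_hi=4.0)
    mw = average_works(traces, grid)
    Wd = estimate_dissipation(mw)
    se_wd = 0.5 * np.sqrt(mw.se_F**2 + mw.se_R**2)
    assert np.all(np.abs(Wd) <= np.maximum(3 * se_wd, 0.01))


def test_quasi_static_linear_ramp_slope(dw_pullset):
    # slow pulls on a linear ramp: the anchored PMF slope matches the ramp
    from ligmem.potentials import PotentialSpec

    c = 0.3
    ramp = PotentialSpec.linear(c, (-3.0, 22.0))
    par = LangevinParams(D=100.0, T=300.0, dt=4e-5)
    grid = default_grid(0.0, 19.0, 0.5)
    traces = make_pullset(ramp, par, v=0.1, k=10.0, n_per_direction=8, seed_base=75000)
    prof = estimate_pmf(average_works(traces, grid), anchor=0.0)
    slope = np.polyfit(grid, prof.dU, 1)[0]
    assert slope == pytest.approx(c, rel=0.02)


# ------------------------------------------------------------------ trace IO

def test_work_trace_roundtrip(tmp_path):
    par = LangevinParams(D=50.0, T=300.0, dt=1e-4)
    traces = make_pullset(FLAT, par, v=1.0, k=10.0, n_per_direction=1,
                          seed_base=76000, stride=50)
    for t in traces:
        p = tmp_path / f"pull_{t.direction}.csv"
        write_work_trace(p, t)
        back = read_work_trace(p)
        assert back.direction == t.direction
        assert np.allclose(back.W, t.W)
        assert np.allclose(back.lam, t.lam)
        assert back.protocol == t.protocol
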