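"""Modulus, proportional-limit yield, and energy metrics against hand oracles."""

import numpy as np
import pytest

from silkmech.errors import DomainError
from silkmech.kinematics import TrueCurve
from silkmech.metrics import (
    absorbed_energy,
    dissipated_energy,
    elastic_modulus,
    recovered_energy,
    shoelace_area,
    yield_stress,
)
from silkmech.segmentation import Cycle

from conftest import make_curve


def _cycle(load_eps, load_sig, unl_eps, unl_sig, index=1):
    loading = make_curve(load_eps, load_sig)
    unloading = make_curve(unl_eps, unl_sig)
    return Cycle(
        index=index,
        loading=loading,
        unloading=unloading,
        eps_init=float(load_eps[0]),
        eps_max=float(max(np.max(load_eps), np.max(unl_eps))),
        sigma_max=float(max(np.max(load_sig), np.max(unl_sig))),
    )


# ---------------------------------------------------------------- modulus

def test_modulus_exact_line():
    eps = np.linspace(0.2, 0.25, 40)
    branch = make_curve(eps, 3000.0 * (eps - 0.2))
    slope, r2 = elastic_modulus(branch, 0.01)
    assert slope == pytest.approx(3000.0, rel=1e-9)
    assert r2 == pytest.approx(1.0, abs=1e-12)


def _bilinear(e_knee=0.04, slope1=3000.0, slope2=300.0, eps_end=0.12, n=600):
    eps = np.linspace(0.0, eps_end, n)
    sig = np.where(eps <= e_knee, slope1 * eps, slope1 * e_knee + slope2 * (eps - e_knee))
    return make_curve(eps, sig)


def test_modulus_bilinear_inside_elastic_window():
    slope, r2 = elastic_modulus(_bilinear(), 0.01)
    assert slope == pytest.approx(3000.0, rel=1e-6)
    assert r2 > 0.999999


def test_modulus_window_spanning_knee_is_flagged():
    """Fitting across the knee gives an intermediate slope with depressed r2."""
    slope, r2 = elastic_modulus(_bilinear(), 0.10)
    assert 300.0 < slope < 3000.0
    # least-squares oracle on the same points
    branch = _bilinear()
    eps0 = branch.strain[np.flatnonzero(branch.stress > 0)[0]]
    m = (branch.strain >= eps0) & (branch.strain <= eps0 + 0.10)
    ref = np.polyfit(branch.strain[m], branch.stress[m], 1)[0]
    assert slope == pytest.approx(ref, rel=1e-9)
    assert r2 < 0.999


def test_modulus_requires_enough_points():
    branch = make_curve([0.0, 0.01, 0.02], [0.0, 30.0, 60.0])
    with pytest.raises(DomainError):
        elastic_modulus(branch, 0.01)


# ------------------------------------------------------------------ yield

def test_yield_bilinear_plateau():
    """Slope-3000 line to 120 MPa then flat: the 95% line meets the plateau
    at sigma = 120 exactly, at strain 120 / (0.95 * 3000)."""
    eps = np.linspace(0.0, 0.12, 2401)
    sig = np.minimum(3000.0 * eps, 120.0)
    branch = make_curve(eps, sig)
    out = yield_stress(branch, 3000.0, eps_init=0.0)
    assert out is not None
    sig_y, eps_y = out
    assert sig_y == pytest.approx(120.0, rel=2e-3)
    assert eps_y == pytest.approx(120.0 / (0.95 * 3000.0), rel=2e-3)


def test_yield_absent_for_pure_line():
    eps = np.linspace(0.0, 0.1, 200)
    branch = make_curve(eps, 3000.0 * eps)
    assert yield_stress(branch, 3000.0, eps_init=0.0) is None


def test_yield_saturating_curve_matches_grid_oracle():
    a, e_mod = 200.0, 3000.0
    eps = np.linspace(0.0, 0.5, 5001)
    sig = a * (1.0 - np.exp(-e_mod * eps / a))
    branch = make_curve(eps, sig)
    out = yield_stress(branch, e_mod, eps_init=0.0)
    assert out is not None
    # brute-force fine-grid sign-change oracle
    grid = np.linspace(1e-6, 0.5, 2_000_001)
    diff = a * (1.0 - np.exp(-e_mod * grid / a)) - 0.95 * e_mod * grid
    i = np.flatnonzero((diff[:-1] > 0) & (diff[1:] <= 0))[0]
    eps_ref = grid[i]
    assert out[1] == pytest.approx(eps_ref, abs=1e-6)


# --------------------------------------------------------------- energies

def test_absorbed_triangle():
    branch = make_curve([0.0, 0.2], [0.0, 100.0])
    assert absorbed_energy(branch) == pytest.approx(10.0, rel=1e-12)


def test_absorbed_piecewise_linear():
    branch = make_curve([0.0, 0.1, 0.3], [0.0, 80.0, 120.0])
    assert absorbed_energy(branch) == pytest.approx(24.0, rel=1e-12)


def test_absorbed_zero_prefix_contributes_nothing():
    with_prefix = make_curve([0.0, 0.1, 0.2, 0.3, 0.5], [0.0, 0.0, 0.0, 80.0, 120.0])
    without = make_curve([0.2, 0.3, 0.5], [0.0, 80.0, 120.0])
    assert absorbed_energy(with_prefix) == pytest.approx(absorbed_energy(without), rel=1e-12)


def test_dissipated_triangle_loop():
    c = _cycle([0.0, 0.2], [0.0, 100.0], [0.2, 0.1], [100.0, 0.0])
    assert dissipated_energy(c) == pytest.approx(5.0, rel=1e-12)


def test_dissipated_zero_when_unloading_retraces_loading():
    eps = np.linspace(0.0, 0.2, 50)
    sig = 500.0 * eps
    c = _cycle(eps, sig, eps[::-1], sig[::-1])
    assert dissipated_energy(c) == pytest.approx(0.0, abs=1e-12)


def test_dissipated_parallelogram_two_independent_routes():
    """Shoelace loop area must equal absorbed minus the unloading area."""
    c = _cycle([0.0, 0.2], [0.0, 100.0], [0.2, 0.05], [100.0, 0.0])
    shoelace = dissipated_energy(c)
    trap = absorbed_energy(c.loading) - np.trapezoid([0.0, 100.0], [0.05, 0.2])
    assert shoelace == pytest.approx(trap, abs=1e-10)


def test_dissipated_absent_for_incomplete_cycle():
    c = Cycle(1, make_curve([0.0, 0.1], [0.0, 50.0]), make_curve([0.1], [50.0]),
              eps_init=0.0, eps_max=0.1, sigma_max=50.0, complete=False)
    assert dissipated_energy(c) is None


def test_trapezoid_and_shoelace_agree_on_random_loops():
    """Independent area routes agree to 1e-10 on piecewise-linear loops."""
    rng = np.random.default_rng(42)
    for _ in range(20):
        n = rng.integers(3, 12)
        load_eps = np.sort(rng.uniform(0.0, 0.5, n))
        load_eps[0] = 0.0
        load_sig = np.concatenate([[0.0], np.sort(rng.uniform(1.0, 300.0, n - 1))])
        eps_u = rng.uniform(0.0, load_eps[-1] * 0.8)
        unl_eps = np.linspace(load_eps[-1], eps_u, 7)
        x = (unl_eps - eps_u) / (load_eps[-1] - eps_u)
        unl_sig = load_sig[-1] * x**2
        c = _cycle(load_eps, load_sig, unl_eps, unl_sig)
        shoelace = dissipated_energy(c)
        trap = abs(absorbed_energy(c.loading) - abs(np.trapezoid(unl_sig, unl_eps)))
        assert shoelace == pytest.approx(trap, abs=1e-10)


# --------------------------------------------------------------- recovery

def test_recovered_triangle_between_cycles():
    prev = _cycle([0.0, 0.2], [0.0, 100.0], [0.2, 0.15], [100.0, 0.0])
    nxt = _cycle([0.10, 0.2], [0.0, 100.0], [0.2, 0.18], [100.0, 0.0], index=2)
    rec = recovered_energy(prev, nxt)
    assert rec.value == pytest.approx(2.5, rel=1e-12)
    assert not rec.concur


def test_recovered_zero_and_concur_for_identical_branches():
    eps = np.linspace(0.2, 0.1, 30)
    sig = 1000.0 * (eps - 0.1)
    prev = _cycle(np.linspace(0.0, 0.2, 30), np.linspace(0.0, 100.0, 30), eps, sig)
    nxt = _cycle(eps[::-1], sig[::-1], eps, sig, index=2)
    rec = recovered_energy(prev, nxt)
    assert rec.value == pytest.approx(0.0, abs=1e-12)
    assert rec.concur


def test_recovered_warns_when_branches_do_not_overlap():
    prev = _cycle([0.0, 0.1], [0.0, 100.0], [0.1, 0.05], [100.0, 0.0])
    nxt = _cycle([0.2, 0.3], [0.0, 100.0], [0.3, 0.25], [100.0, 0.0], index=2)
    nxt.eps_init = 0.2
    with pytest.warns(UserWarning):
        rec = recovered_energy(prev, nxt)
    assert rec.value == 0.0


# --------------------------------------------------- simulator conformance

def test_modulus_matches_generator_exactly_without_noise(default_run):
    _, truth, result = default_run
    measured = result.table.frame["modulus_MPa"].to_numpy()
    np.testing.assert_allclose(measured, truth.modulus, rtol=0.01)


def test_modulus_under_noise_median_within_5pct():
    from dataclasses import replace

    from silkmech.pipeline import analyze_record
    from silkmech.simulate import FiberModelParams, generate_test

    params = replace(FiberModelParams(), noise_sd=2.0, seed=11)
    record, truth = generate_test(params)
    result = analyze_record(record, params.geometry)
    measured = result.table.frame["modulus_MPa"].to_numpy()
    median_err = np.median(np.abs(measured / truth.modulus - 1.0))
    assert median_err < 0.05


def test_yield_matches_generator_schedule_within_3pct(default_run):
    _, truth, result = default_run
    measured = result.table.frame["yield_MPa"].to_numpy()
    has = ~np.isnan(measured)
    assert has[1:].all()  # only cycle 1 stays elastic
    np.testing.assert_allclose(measured[has], truth.yield_schedule[has], rtol=0.03)


def test_energy_inequality_on_default_run(default_run):
    _, _, result = default_run
    df = result.table.frame
    w_abs = df["absorbed_MJm3"].to_numpy()
    w_dis = df["dissipated_MJm3"].to_numpy()
    assert np.all(w_dis >= 0.0)
    assert np.all(w_dis <= w_abs + 1e-9)
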