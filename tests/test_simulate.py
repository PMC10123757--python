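"""Synthetic fiber generator: calibration, schedules, reproducibility."""

from dataclasses import replace

import numpy as np
import pytest

from silkmech.errors import DomainError
from silkmech.kinematics import engineering_from_record, true_from_engineering
from silkmech.pipeline import analyze_record
from silkmech.simulate import EnvelopeModel, FiberModelParams, generate_test, write_fixture_suite


def test_hardening_coefficient_is_rederived_from_the_closed_form(default_params, default_envelope):
    """K follows from E1, sigma_y1, n_h and the 270 MJ/m^3 target; the
    closed-form integral evaluated back at K reproduces the target exactly."""
    k = default_params.hardening_coefficient
    eps_y = default_params.eps_yield_envelope
    span = default_params.calibration_strain - eps_y
    integral = 0.5 * default_params.e1 * eps_y**2 + default_params.sigma_y1 * span + k * span**2.5 / 2.5
    assert integral == pytest.approx(270.0, rel=1e-12)
    assert default_envelope.integral(default_params.calibration_strain) == pytest.approx(270.0, rel=1e-12)


def test_envelope_model_values(default_envelope):
    assert default_envelope(0.0) == 0.0
    assert default_envelope(0.04) == pytest.approx(120.0, rel=1e-12)
    # high-precision evaluation of the hardening branch at the final strain
    assert default_envelope(0.875) == pytest.approx(621.1976, abs=1e-3)
    with pytest.raises(DomainError):
        default_envelope(0.9)


def test_envelope_trapezoid_integration_converges(default_envelope):
    grid = np.arange(0.0, 0.875 + 1e-12, 1e-4)
    num = np.trapezoid(default_envelope(grid), grid)
    assert num == pytest.approx(270.0, rel=1e-3)


def test_ground_truth_schedules(default_run, default_params):
    _, truth, _ = default_run
    p = default_params
    assert len(truth.modulus) == 35
    assert truth.modulus[0] == pytest.approx(p.e1)
    assert truth.modulus[-1] == pytest.approx(p.en)
    assert np.all(np.diff(truth.modulus) >= 0)
    # modulus is linear in the residual (onset) strain by construction
    expected = p.e1 + (p.en - p.e1) * truth.eps_residual / truth.eps_residual[-1]
    np.testing.assert_allclose(truth.modulus, expected, rtol=1e-9)
    np.testing.assert_allclose(truth.yield_schedule, np.linspace(120.0, 140.0, 35), rtol=1e-12)
    assert np.all(np.diff(truth.eps_residual) >= 0)


def test_residual_strain_recursion_recovers_partially(default_run):
    """With rho > 0 the next onset lies strictly below the unload terminus
    whenever the cycle accumulated any unloading gap."""
    _, truth, _ = default_run
    gap = truth.eps_unload[:-1] - truth.eps_residual[:-1]
    nxt = truth.eps_residual[1:]
    strict = gap > 0
    assert np.all(nxt[strict] < truth.eps_unload[:-1][strict])
    assert np.all(nxt <= truth.eps_unload[:-1] + 1e-15)


def test_rho_zero_means_no_strain_recovery(default_params):
    params = replace(default_params, relax_recovery_fraction=0.0, n_cycles=8)
    record, truth = generate_test(params)
    np.testing.assert_allclose(truth.eps_residual[1:], truth.eps_unload[:-1], atol=1e-15)
    result = analyze_record(record, params.geometry)
    df = result.table.frame
    # the reloading line and the unloading tail still enclose a small lens,
    # but without strain recovery it stays far below the dissipated loop
    rec = df["recovered_MJm3"].to_numpy()[1:]
    dis = df["dissipated_MJm3"].to_numpy()[1:]
    assert np.all(rec < 0.5 * dis)


def test_single_cycle_loads_along_the_envelope(default_params, default_envelope):
    params = replace(default_params, n_cycles=1)
    record, truth = generate_test(params)
    curve = true_from_engineering(engineering_from_record(record, params.geometry))
    loading = curve.strain <= 0.025
    np.testing.assert_allclose(
        curve.stress[loading][curve.strain[loading] > 0][:100],
        default_envelope(curve.strain[loading][curve.strain[loading] > 0][:100]),
        rtol=1e-9, atol=1e-9,
    )
    result = analyze_record(record, params.geometry)
    assert result.table.frame["modulus_MPa"].iloc[0] == pytest.approx(3000.0, rel=1e-6)


def test_history_independence_of_loading_branches(default_run, default_envelope):
    """Beyond the previous maximum strain every loading branch rides the
    envelope (within 0.5% stress)."""
    record, truth, result = default_run
    for i, c in enumerate(result.cycles):
        eps_h = truth.eps_max[i - 1] if i else 0.0
        m = c.loading.strain >= eps_h
        model = default_envelope(c.loading.strain[m])
        np.testing.assert_allclose(c.loading.stress[m], model, rtol=0.005, atol=1e-9)


def test_envelope_integral_from_pipeline_matches_closed_form(default_run):
    _, truth, result = default_run
    assert result.work_to_fracture == pytest.approx(truth.envelope_integral, rel=0.01)


def test_same_seed_is_byte_identical(tmp_path, default_params):
    params = replace(default_params, noise_sd=2.0, seed=5, n_cycles=6)
    a, b = tmp_path / "a.csv", tmp_path / "b.csv"
    generate_test(params)[0].write(a)
    generate_test(params)[0].write(b)
    assert a.read_bytes() == b.read_bytes()


def test_noise_perturbs_only_the_force_channel(default_params):
    quiet = replace(default_params, n_cycles=4)
    noisy = replace(quiet, noise_sd=2.0, seed=9)
    rec_q, _ = generate_test(quiet)
    rec_n, _ = generate_test(noisy)
    np.testing.assert_array_equal(rec_q.displacement, rec_n.displacement)
    np.testing.assert_array_equal(rec_q.time, rec_n.time)
    assert not np.array_equal(rec_q.force, rec_n.force)


def test_energy_convergence_under_denser_sampling(default_params):
    """Halving the strain step changes per-cycle energies by < 0.1%."""
    coarse = replace(default_params, n_cycles=12)
    fine = replace(coarse, sample_deps=coarse.sample_deps / 2)
    res_c = analyze_record(*_run(coarse))
    res_f = analyze_record(*_run(fine))
    for col in ("absorbed_MJm3", "dissipated_MJm3"):
        a = res_c.table.frame[col].to_numpy()
        b = res_f.table.frame[col].to_numpy()
        np.testing.assert_allclose(a, b, rtol=1e-3)


def _run(params):
    record, _ = generate_test(params)
    return record, params.geometry


def test_fixture_suite_counts_and_determinism(tmp_path, default_params):
    small = replace(default_params, n_cycles=3)
    manifest = write_fixture_suite(tmp_path / "s1", seeds=(1, 2), params=small)
    # per seed: noiseless + noisy records and truths, plus one geometry file
    assert len(manifest["files"]) == 2 * 2 * 2 + 1
    manifest2 = write_fixture_suite(tmp_path / "s2", seeds=(1, 2), params=small)
    assert manifest == manifest2


def test_parameter_validation():
    with pytest.raises(DomainError):
        FiberModelParams(e1=5000.0, en=3000.0)
    with pytest.raises(DomainError):
        FiberModelParams(relax_recovery_fraction=1.5)
    with pytest.raises(DomainError):
        FiberModelParams(unload_shape=0.5)
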