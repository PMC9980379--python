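"""Fitting the mass parametrization and checking its fidelity."""

import numpy as np
import pytest

import mnm
from mnm.mass_builder import fit_parametrization, fidelity_report, DEFAULT_ORDERS
from mnm.mass_core import MassInput, evaluate_mass
from mnm.steady_state import BoundaryCurves


def _synthetic_curves(kind="I"):
    """Boundary data generated exactly from a known coefficient set."""
    nu = np.linspace(-90.0, -70.0, 9)
    th1 = 0.014 * nu + 1.746
    th2 = -0.85 * nu - 51.0
    m1 = -6.0 * nu - 80.0 if kind == "I" else 0.01 * nu ** 2 - 2.0 * nu + 100.0
    q = np.full_like(nu, 0.81)
    p_fr = 0.5
    c1 = -60.0 if kind == "I" else -65.0
    c2 = 0.0 if kind == "I" else 0.1
    p_vm = 0.5 if kind == "I" else 0.62
    p_kf = 0.5 if kind == "I" else 0.28
    a2 = 0.3 * nu + 1.0
    a3 = -0.5 * nu - 25.0
    return BoundaryCurves(
        nu_k=nu, iss_f=th1, iss_db=th2,
        delta=(1 - q) * (th2 - th1),
        m1=m1 * q ** p_fr,                  # raw measurements at Q = q
        m2=c1 - a2 * q ** p_vm,
        m3=a3 * q ** p_kf + c2,
        q_meas=q,
    ), dict(th1=(0.014, 1.746), th2=(-0.85, -51.0), a2=a2, a3=a3)


def test_exact_fit_round_trip_recovers_coefficients():
    curves, truth = _synthetic_curves("I")
    p = fit_parametrization(curves, "I")
    assert np.allclose(p.th1_coeffs, truth["th1"], rtol=1e-8)
    assert np.allclose(p.th2_coeffs, truth["th2"], rtol=1e-8)
    # cubic fit of an exactly linear amplitude: leading terms ~ 0
    m1_at = np.polyval(p.m1_coeffs, curves.nu_k)
    assert np.allclose(m1_at, -6.0 * curves.nu_k - 80.0, rtol=1e-7)


def test_fit_orders_follow_mass_kind():
    for kind in ("I", "E"):
        curves, _ = _synthetic_curves(kind)
        p = fit_parametrization(curves, kind)
        o = DEFAULT_ORDERS[kind]
        assert len(p.m1_coeffs) == o[2] + 1
        assert len(p.m3_coeffs) == o[4] + 1


def test_too_few_samples_rejected():
    curves, _ = _synthetic_curves("I")
    short = BoundaryCurves(nu_k=curves.nu_k[:3], iss_f=curves.iss_f[:3],
                           iss_db=curves.iss_db[:3], delta=curves.delta[:3],
                           m1=curves.m1[:3], m2=curves.m2[:3], m3=curves.m3[:3],
                           q_meas=curves.q_meas[:3])
    with pytest.raises(ValueError, match="at least"):
        fit_parametrization(short, "I")


def test_wb_threshold_fit_matches_published_coefficients(i_mass):
    a, b = i_mass.th1_coeffs
    assert a == pytest.approx(0.014, rel=0.20)
    assert b == pytest.approx(1.746, rel=0.20)


def test_fit_residuals_small_relative_to_curve_range(i_mass, e_mass):
    for p in (i_mass, e_mass):
        res = p.provenance["residual_rms"]
        grid = np.array(p.provenance["nu_k_grid"])
        window = np.polyval(p.th2_coeffs, grid) - np.polyval(p.th1_coeffs, grid)
        # threshold residuals are small against the firing-window width
        assert res["th1"] < 0.02 * window.mean()
        assert res["th2"] < 0.02 * window.mean()
        # amplitude residuals are small against the curve itself
        for name, coeffs in (("m1", p.m1_coeffs), ("m2", p.m2_coeffs),
                             ("m3", p.m3_coeffs)):
            vals = np.polyval(coeffs, grid)
            scale = max(vals.max() - vals.min(), 0.2 * np.abs(vals).mean())
            assert res[name] < 0.05 * scale, name


def test_functional_interpolates_measured_anchor(wb, i_mass):
    """With the amplitude correction the functional reproduces the measured
    mean firing rate at the measurement point, up to the nu_K-fit residual."""
    grid = np.array(i_mass.provenance["nu_k_grid"])
    deltas = np.array(i_mass.provenance["delta"])
    k = 0
    curves = mnm.trace_boundaries(wb, grid[[k]])
    curves = mnm.maxima_along_shifted_db(wb, curves, delta=float(deltas[k]),
                                         duration=1600.0, transient_ms=400.0)
    x_meas = curves.iss_db[0] - deltas[k]
    out = evaluate_mass(i_mass, MassInput(float(x_meas), float(grid[k] - wb.nu_k_hat)))
    assert out.fr == pytest.approx(curves.m1[0], rel=0.05)


def test_fidelity_within_ten_percent_on_reduced_grid(i_mass, wb):
    df, summary = fidelity_report(i_mass, wb, [0.0, 15.0], n_currents=6,
                                  duration=1500.0, transient_ms=400.0)
    assert summary.median["fr"] <= 0.10
    assert summary.median["vm"] <= 0.10
    assert summary.n_points >= 8


def test_table_lookup_errors_bounded_by_fitted_errors(wb, wb_boundaries):
    """Evaluating on the per-row measured amplitudes (no nu_K fit) is at
    least as accurate as the fitted parametrization at a grid row."""
    curves = mnm.maxima_along_shifted_db(wb, wb_boundaries,
                                         duration=1600.0, transient_ms=400.0)
    fitted = fit_parametrization(curves, "I", spec=wb)
    k = 2   # interior grid row: constant "fits" pinned to the measured row
    q = curves.q_meas[k]
    table = mnm.MassParametrization(
        mass_kind="I", nu_k_hat=wb.nu_k_hat,
        th1_coeffs=(0.0, curves.iss_f[k]), th2_coeffs=(0.0, curves.iss_db[k]),
        m1_coeffs=(curves.m1[k] / q ** 0.5,),
        m2_coeffs=((-60.0 - curves.m2[k]) / q ** 0.5,),
        m3_coeffs=(curves.m3[k] / q ** 0.5,),
        fit_window=(0.0, 20.0), neuron=wb)
    dnu = float(curves.nu_k[k] - wb.nu_k_hat)
    _, s_fit = fidelity_report(fitted, wb, [dnu], n_currents=5,
                               duration=1200.0, transient_ms=400.0)
    _, s_tab = fidelity_report(table, wb, [dnu], n_currents=5,
                               duration=1200.0, transient_ms=400.0)
    assert s_tab.median["fr"] <= s_fit.median["fr"] + 0.02


def test_serialize_load_evaluate_round_trip_is_bit_identical(tmp_path, i_mass):
    path = tmp_path / "mass.yaml"
    mnm.dump_mass(i_mass, path)
    back = mnm.load_mass(path)
    assert back.th1_coeffs == i_mass.th1_coeffs
    assert back.m1_coeffs == i_mass.m1_coeffs
    for dnu in (0.0, 11.3):
        a = evaluate_mass(i_mass, MassInput(8.0, dnu))
        b = evaluate_mass(back, MassInput(8.0, dnu))
        assert a.fr == b.fr and a.q == b.q
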