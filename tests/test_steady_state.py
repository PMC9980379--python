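"""Fixed-point analysis: ISS, Jacobian spectra, boundary tracing, maxima."""

import math

import numpy as np
import pytest

import mnm
from mnm.neuron_models import gate_steady_states, simulate, summarize
from mnm.steady_state import (
    fixed_point_record, iss_of_vm, jacobian, jacobian_fd, jacobian_spectrum,
    maxima_along_shifted_db, trace_boundaries,
)


def test_iss_with_all_driving_forces_zero_is_pump_only():
    # degenerate spec where every reversal equals V_m
    spec = mnm.wb_spec(nu_k_hat=-60.0, nu_na=-60.0, nu_l=-60.0)
    val = float(iss_of_vm(spec, -60.0, -60.0))
    assert val == pytest.approx(spec.rho / 4.0, rel=1e-12)


def test_iss_passive_membrane_is_linear(wb):
    spec = mnm.wb_spec(g_na=1e-12, g_k=1e-12)
    v = np.array([-80.0, -60.0, -40.0])
    got = np.asarray(iss_of_vm(spec, v, -90.0))
    expected = spec.g_l * (v - spec.nu_l) + spec.rho / 4.0
    assert np.allclose(got, expected, rtol=1e-9)


def test_iss_matches_term_by_term_hand_evaluation(wb):
    v, nu_k = -60.0, -90.0
    n, m, h = gate_steady_states(wb, v)
    expected = (wb.g_k * n ** 4 * (v - nu_k)
                + wb.g_na * m ** 3 * h * (v - wb.nu_na)
                + wb.g_l * (v - wb.nu_l) + wb.rho / 4.0)
    assert float(iss_of_vm(wb, v, nu_k)) == pytest.approx(float(expected), rel=1e-12)


@pytest.mark.parametrize("v", [-75.0, -55.0, -30.0])
def test_analytic_jacobian_matches_finite_differences(wb, sean, v):
    for spec in (wb, sean):
        j = jacobian(spec, v, spec.nu_k_hat)
        jfd = jacobian_fd(spec, v, spec.nu_k_hat)
        assert np.max(np.abs(j - jfd) / np.maximum(np.abs(j), 1e-6)) < 1e-6


def test_stability_trichotomy_along_voltage_scan(wb):
    # deep NF fixed point stable, firing-window fixed point unstable,
    # deep DB fixed point stable again: sign pattern (-, +, -)
    rec_nf = fixed_point_record(wb, -64.0, -90.0)
    rec_f = fixed_point_record(wb, -50.0, -90.0)
    rec_db = fixed_point_record(wb, -25.0, -90.0)
    assert rec_nf.stable and rec_nf.max_re_eig < 0
    assert not rec_f.stable and rec_f.max_re_eig > 0
    assert rec_db.stable and rec_db.max_re_eig < 0


def test_bistable_upper_triangle_has_two_stable_fixed_points(wb):
    # at strongly elevated nu_K a hyperpolarized (NF) and a depolarized (DB)
    # stable fixed point coexist at the same input current
    closure = mnm.FixedPointClosure(wb)
    v_nf, kf_nf = closure(0.5, 45.0, "NF")
    v_db, kf_db = closure(0.5, 45.0, "DB")
    assert v_nf < -55.0 and v_db > -35.0
    assert kf_nf < 0.0 < kf_db


def test_boundary_ordering_and_determinism(wb_boundaries, wb):
    c = wb_boundaries
    ok = np.isfinite(c.iss_f)
    assert ok.all()
    assert (c.iss_f[ok] < c.iss_db[ok]).all()
    # bit-reproducible given spec + grid
    c2 = trace_boundaries(wb, c.nu_k)
    assert np.array_equal(c.iss_f, c2.iss_f) and np.array_equal(c.iss_db, c2.iss_db)


def test_wb_onset_fit_recovers_printed_line(wb_boundaries):
    """Linear fit of ISS_F(nu_K) for the interneuron: slope ~0.014,
    intercept ~1.746 (canonical parameters re-derive the published fit)."""
    a, b = np.polyfit(wb_boundaries.nu_k, wb_boundaries.iss_f, 1)
    assert a == pytest.approx(0.014, rel=0.20)
    assert b == pytest.approx(1.746, rel=0.20)


def test_simulation_brackets_analytic_boundaries(wb, wb_boundaries):
    """ODE cross-check: silent just below ISS_F, spiking just above, and
    spiking collapses within the thin incomplete-spike layer below ISS_DB."""
    f, db = wb_boundaries.iss_f[0], wb_boundaries.iss_db[0]
    w = db - f
    eps = 0.05 * w
    below = summarize(simulate(wb, f - eps, 0.0, duration=2000.0), transient_ms=400.0)
    above = summarize(simulate(wb, f + eps, 0.0, duration=2000.0), transient_ms=400.0)
    assert below.n_spikes == 0 and above.n_spikes > 0
    past_db = summarize(simulate(wb, db + eps, 0.0, duration=1000.0), transient_ms=400.0)
    assert past_db.n_spikes == 0
    inside = summarize(simulate(wb, db - 0.25 * w, 0.0, duration=1000.0),
                       transient_ms=400.0)
    assert inside.n_spikes > 0


def test_maxima_line_values_and_flux_sign(wb, i_mass):
    curves_meta = i_mass.provenance
    assert all(np.isfinite(curves_meta["delta"]))
    # rebuild one row and check the definitional identity M = summarize output
    grid = np.array([wb.nu_k_hat])
    c = trace_boundaries(wb, grid)
    c = maxima_along_shifted_db(wb, c, duration=1200.0, transient_ms=400.0)
    s = summarize(simulate(wb, c.iss_db[0] - c.delta[0], 0.0, duration=1200.0),
                  transient_ms=400.0)
    assert c.m1[0] == pytest.approx(s.mean_fr, rel=1e-9)
    assert c.m2[0] == pytest.approx(s.mean_vm, rel=1e-9)
    assert c.m3[0] == pytest.approx(s.mean_kflux, rel=1e-9)
    assert c.m3[0] > 0          # positive mean K flux near DB
    assert 0 < c.q_meas[0] < 1


def test_firing_rate_grows_toward_db_boundary(wb):
    # M1 decreases as the shift off ISS_DB is increased
    grid = np.array([wb.nu_k_hat])
    c = trace_boundaries(wb, grid)
    w = c.iss_db[0] - c.iss_f[0]
    near = maxima_along_shifted_db(wb, c, delta=0.22 * w,
                                   duration=1200.0, transient_ms=400.0)
    far = maxima_along_shifted_db(wb, c, delta=0.45 * w,
                                  duration=1200.0, transient_ms=400.0)
    assert near.m1[0] > far.m1[0]


def test_csv_round_trip(tmp_path, wb_boundaries):
    path = tmp_path / "curves.csv"
    wb_boundaries.to_csv(path)
    back = mnm.BoundaryCurves.from_csv(path)
    assert np.allclose(back.iss_f, wb_boundaries.iss_f)
    assert np.allclose(back.iss_db, wb_boundaries.iss_db)
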