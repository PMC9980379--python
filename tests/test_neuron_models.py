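"""Membrane models: rate functions, pump, derivatives, simulation, reduction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mnm
from mnm.neuron_models import (
    MembraneState, count_spikes, derivatives, gate_steady_states,
    k_flux, pump_current, pump_at_shift, rate_functions, simulate, summarize,
)
from mnm.steady_state import iss_of_vm


# ---------------------------------------------------------------------------
# rate functions
# ---------------------------------------------------------------------------

def test_removable_singularity_evaluated_by_limit(wb):
    # alpha_n has its singularity at V = -34 mV; the limit is a*b
    am, bm, an, bn, ah, bh = rate_functions(wb, -34.0)
    assert an == pytest.approx(0.01 * 10.0, rel=1e-9)
    # alpha_m singularity at V = -35 mV
    am2 = rate_functions(wb, -35.0)[0]
    assert am2 == pytest.approx(0.1 * 10.0, rel=1e-9)


def test_logistic_tail_vanishes_at_hyperpolarization(wb):
    bh = rate_functions(wb, -500.0)[5]
    assert bh == pytest.approx(0.0, abs=1e-12)


def test_wb_steady_gates_match_scalar_oracle(wb):
    # independent scalar evaluation of the canonical WB rate formulas
    v = -64.0
    an = 0.01 * (v + 34) / (1 - math.exp(-(v + 34) / 10))
    bn = 0.125 * math.exp(-(v + 44) / 80)
    ah = 0.07 * math.exp(-(v + 58) / 20)
    bh = 1 / (1 + math.exp(-(v + 28) / 10))
    n_inf, m_inf, h_inf = gate_steady_states(wb, v)
    assert 0 < n_inf < 1 and 0 < h_inf < 1
    assert n_inf == pytest.approx(an / (an + bn), rel=1e-10)
    assert h_inf == pytest.approx(ah / (ah + bh), rel=1e-10)


@settings(deadline=None, max_examples=60)
@given(st.floats(-120.0, 60.0))
def test_rates_nonnegative_and_finite_everywhere(v):
    for spec in (mnm.wb_spec(), mnm.sean_spec()):
        for r in rate_functions(spec, v):
            assert np.isfinite(r) and r >= 0.0


def test_nonfinite_voltage_rejected(wb):
    with pytest.raises(ValueError):
        rate_functions(wb, float("nan"))


# ---------------------------------------------------------------------------
# pump current
# ---------------------------------------------------------------------------

def test_pump_at_nominal_concentrations_is_quarter_rho(wb, sean):
    for spec in (wb, sean):
        assert pump_current(spec, spec.na_i_hat, spec.k_o_hat) == \
            pytest.approx(spec.rho / 4.0, rel=1e-12)


def test_pump_saturates_at_half_rho_for_high_potassium(wb):
    assert pump_current(wb, wb.na_i_hat, 1e6) == pytest.approx(wb.rho / 2.0, rel=1e-9)


def test_pump_monotone_in_both_concentrations(wb):
    base = pump_current(wb, 25.0, 4.77)
    assert pump_current(wb, 26.0, 4.77) > base
    assert pump_current(wb, 25.0, 5.77) > base
    assert base > 0


def test_pump_at_15mv_shift_matches_direct_evaluation(wb):
    k_o = wb.k_o_hat * math.exp(15.0 / wb.rt_over_f)
    direct = wb.rho / ((1 + math.exp(0.0)) * (1 + math.exp(wb.k_o_hat - k_o)))
    assert pump_at_shift(wb, 15.0) == pytest.approx(direct, rel=1e-12)


def test_pump_rejects_nonpositive_concentration(wb):
    with pytest.raises(ValueError):
        pump_current(wb, -1.0, 4.77)


# ---------------------------------------------------------------------------
# derivatives
# ---------------------------------------------------------------------------

def test_derivatives_vanish_at_fixed_point(wb, sean):
    for spec, v in ((wb, -62.0), (sean, -58.0), (wb, -40.0)):
        n, _, h = gate_steady_states(spec, v)
        i_ss = float(iss_of_vm(spec, v, spec.nu_k_hat))
        d = derivatives(spec, MembraneState(v, n, h), i_ss, 0.0)
        assert np.allclose(d, 0.0, atol=1e-10)


def test_sean_without_accommodation_matches_term_removal(sean):
    bare = mnm.sean_spec(g_k_ahp=0.0, q_hat=0.0)
    st_ = MembraneState(-50.0, 0.3, 0.5)
    d_full = derivatives(sean, st_, 2.0, 0.0)
    d_bare = derivatives(bare, st_, 2.0, 0.0)
    ahp = sean.g_k_ahp * sean.q_hat * (-50.0 - sean.nu_k_hat) / sean.c_m
    assert d_full[0] == pytest.approx(d_bare[0] + (-ahp), rel=1e-9)
    assert np.allclose(d_full[1:], d_bare[1:])


def test_resting_derivative_matches_term_by_term_oracle(wb):
    # independent summation of the four current terms at rest, I_inj = 0
    v = -64.0
    n, m, h = gate_steady_states(wb, v)
    i_k = wb.g_k * n ** 4 * (v - wb.nu_k_hat)
    i_na = wb.g_na * m ** 3 * h * (v - wb.nu_na)
    i_l = wb.g_l * (v - wb.nu_l)
    i_p = wb.rho / 4.0
    expected = (0.0 - i_k - i_na - i_l - i_p) / wb.c_m
    d = derivatives(wb, MembraneState(v, float(n), float(h)), 0.0, 0.0)
    assert d[0] == pytest.approx(expected, rel=1e-10)


def test_slow_current_hook_shifts_effective_drive(sean):
    st_ = MembraneState(-55.0, 0.2, 0.6)
    d0 = derivatives(sean, st_, 2.0, 0.0)
    d1 = derivatives(sean, st_, 1.0, 0.0, i_extra=1.0)
    assert d0[0] == pytest.approx(d1[0], rel=1e-12)


# ---------------------------------------------------------------------------
# simulation and reduction
# ---------------------------------------------------------------------------

def test_subthreshold_drive_settles_to_fixed_point(wb):
    tr = simulate(wb, 0.2, 0.0, duration=1200.0)
    s = summarize(tr, transient_ms=400.0)
    assert s.n_spikes == 0 and s.regime == "NF"
    assert abs(tr.v_m[-1] - tr.v_m[-100]) < 1e-3   # converged
    assert s.mean_kflux < 0.1


def test_spiking_just_above_fitted_onset(wb):
    # the fitted onset line gives i_th1(-90) = 0.014*(-90) + 1.746 ~ 0.486
    tr = simulate(wb, 0.55, 0.0, duration=2000.0)
    s = summarize(tr, transient_ms=200.0)
    assert s.n_spikes >= 1


def test_depolarization_block_plateau_with_positive_kflux(wb):
    tr = simulate(wb, 30.0, 0.0, duration=1200.0)
    s = summarize(tr, transient_ms=400.0)
    assert s.regime == "DB" and s.n_spikes == 0
    assert s.mean_kflux > 0
    assert s.mean_vm > -40.0


def test_gates_bounded_in_accepted_simulations(wb, sean):
    for spec, i in ((wb, 8.0), (sean, 20.0)):
        tr = simulate(spec, i, 0.0, duration=600.0)
        for g in (tr.n, tr.h):
            assert g.min() >= -1e-9 and g.max() <= 1 + 1e-9


def test_rk4_and_lsoda_agree_on_mean_outputs(wb):
    means = {}
    for method in ("rk4", "lsoda"):
        tr = simulate(wb, 8.0, 0.0, duration=1500.0, method=method)
        s = summarize(tr, transient_ms=500.0)
        means[method] = (s.mean_fr, s.mean_vm)
    assert means["rk4"][0] == pytest.approx(means["lsoda"][0], rel=0.01)
    assert means["rk4"][1] == pytest.approx(means["lsoda"][1], abs=0.05)


def test_synthetic_trace_spike_counting_definition(wb):
    # k threshold crossings in window T -> FR = k/T
    t = np.arange(0.0, 1000.0, 0.05)
    v = np.full_like(t, -65.0)
    for t0 in (100.0, 300.0, 500.0, 700.0):   # 4 spikes
        mask = (t >= t0) & (t < t0 + 1.0)
        v[mask] = 20.0
    spikes = count_spikes(t, v)
    assert len(spikes) == 4


def test_mean_kflux_matches_trapezoid_oracle(wb):
    tr = simulate(wb, 5.0, 0.0, duration=900.0)
    s = summarize(tr, transient_ms=300.0)
    mask = tr.t >= 300.0
    # independent quadrature of the instantaneous flux
    flux = k_flux(wb, tr.v_m[mask], tr.n[mask], 0.0)
    oracle = np.trapezoid(flux, tr.t[mask]) / (tr.t[mask][-1] - tr.t[mask][0])
    assert s.mean_kflux == pytest.approx(float(oracle), rel=1e-9)


def test_sweep_row_orders_nf_f_db(wb):
    # along a fixed-dnu_K row the regimes appear as NF* F* DB*
    df = mnm.sweep(wb, [0.2, 1.0, 8.0, 18.0, 27.0, 35.0], [0.0],
                   duration=900.0, transient_ms=300.0)
    labels = df.sort_values("i_inj").regime.tolist()
    order = {"NF": 0, "F": 1, "DB": 2}
    ranks = [order[l] for l in labels]
    assert ranks == sorted(ranks)
    assert set(labels) == {"NF", "F", "DB"}
    # NF rows have non-positive flux (within tolerance), DB rows positive
    assert (df[df.regime == "NF"].mean_kflux < 0.1).all()
    assert (df[df.regime == "DB"].mean_kflux > 0).all()
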