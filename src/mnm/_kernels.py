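"""Compiled numerical cores (numba) for membrane and network integration.

Everything here is private.  The membrane right-hand side is written once,
parametrized by a 6x5 rate-coefficient table and scalar model constants, so
the same kernel integrates both the WB and the SEAN model.  Rate-table row
layout: (form_code, a, v_half, b, sign) with form codes 0 = linexp,
1 = exp, 2 = logistic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

FORM_CODE = {"linexp": 0.0, "exp": 1.0, "logistic": 2.0}


def rate_table(spec) -> np.ndarray:
    """6x5 float array encoding the rate functions of a NeuronModelSpec."""
    return np.array(
        [[FORM_CODE[r.form], r.a, r.v_half, r.b, r.sign] for r in spec.rates],
        dtype=np.float64,
    )


def model_params(spec, i_inj, nu_k, i_pump, i_extra=0.0) -> tuple:
    """Scalar argument pack consumed by the membrane kernels."""
    return (
        spec.g_k, spec.g_na, spec.g_l, spec.g_k_ahp * spec.q_hat,
        spec.nu_na, spec.nu_l, float(nu_k), spec.c_m, spec.psi,
        spec.k_power, spec.na_power, float(i_inj - i_pump + i_extra),
    )


@njit(cache=True)
def _rates6(v, tab):
    out = np.empty(6)
    for i in range(6):
        form = tab[i, 0]
        a = tab[i, 1]
        x = tab[i, 4] * (v + tab[i, 2])
        b = tab[i, 3]
        if form == 0.0:
            u = x / b
            if abs(u) < 1e-6:
                out[i] = a * b * (1.0 + 0.5 * u + u * u / 12.0)
            else:
                out[i] = a * x / (1.0 - np.exp(-u))
        elif form == 1.0:
            out[i] = a * np.exp(x / b)
        else:
            out[i] = a / (1.0 + np.exp(-x / b))
    return out


@njit(cache=True)
def _membrane_deriv(y, tab, g_k, g_na, g_l, g_ahp, nu_na, nu_l, nu_k,
                    c_m, psi, k_pow, na_pow, i_const):
    v, n, h = y[0], y[1], y[2]
    r = _rates6(v, tab)
    m = r[0] / (r[0] + r[1])
    ionic = (g_k * n ** k_pow * (v - nu_k)
             + g_na * m ** na_pow * h * (v - nu_na)
             + g_l * (v - nu_l)
             + g_ahp * (v - nu_k))
    out = np.empty(3)
    out[0] = (i_const - ionic) / c_m
    out[1] = psi * (r[2] * (1.0 - n) - r[3] * n)
    out[2] = psi * (r[4] * (1.0 - h) - r[5] * h)
    return out


@njit(cache=True)
def _rk4_membrane(y0, tab, g_k, g_na, g_l, g_ahp, nu_na, nu_l, nu_k,
                  c_m, psi, k_pow, na_pow, i_const, dt, n_steps, stride):
    """Fixed-step RK4 with gate clamping; returns (n_out, 3) state samples."""
    y = y0.copy()
    n_out = n_steps // stride + 1
    out = np.empty((n_out, 3))
    out[0] = y
    k = 1
    for i in range(1, n_steps + 1):
        k1 = _membrane_deriv(y, tab, g_k, g_na, g_l, g_ahp, nu_na, nu_l,
                             nu_k, c_m, psi, k_pow, na_pow, i_const)
        k2 = _membrane_deriv(y + 0.5 * dt * k1, tab, g_k, g_na, g_l, g_ahp,
                             nu_na, nu_l, nu_k, c_m, psi, k_pow, na_pow, i_const)
        k3 = _membrane_deriv(y + 0.5 * dt * k2, tab, g_k, g_na, g_l, g_ahp,
                             nu_na, nu_l, nu_k, c_m, psi, k_pow, na_pow, i_const)
        k4 = _membrane_deriv(y + dt * k3, tab, g_k, g_na, g_l, g_ahp,
                             nu_na, nu_l, nu_k, c_m, psi, k_pow, na_pow, i_const)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        for j in (1, 2):
            if y[j] < 0.0:
                y[j] = 0.0
            elif y[j] > 1.0:
                y[j] = 1.0
        if i % stride == 0:
            out[k] = y
            k += 1
    return out


@njit(cache=True)
def _phi_fr(x_tot, th1, th2, m1):
    """Firing-rate functional: M1 * sqrt(Q) inside the window, else 0."""
    w = th2 - th1
    if w <= 0.0:
        return 0.0
    q = (x_tot - th1) / w
    if q < 0.0 or q > 1.0:
        return 0.0
    return m1 * np.sqrt(q)


@njit(cache=True)
def _integrate_couplet(stim_half, i_i_inj, dt, n_steps,
                       th1_e, th2_e, m1_e, th1_i, th2_i, m1_i,
                       pump_e, pump_i, g_ei, g_ie, lam_e, lam_i,
                       tau_e, tau_i, d_ie_steps, d_ei_steps,
                       y0, out_stride):
    """RK4 integration of the two-mass E-I firing-rate network.

    State: (FR_E, FR_I, h_E, h'_E, h_I, h'_I).  ``stim_half`` samples the
    excitatory injected current at half-step resolution (length
    2*n_steps + 1).  Delays are expressed in whole steps; 0 means the
    instantaneous (state-variable) synaptic output is used.

    Returns arrays sampled every ``out_stride`` steps:
    (fr_e, fr_i, h_e, h_i, q_e, q_i, i_e_inj).
    """
    y = y0.copy()
    n_out = n_steps // out_stride + 1
    fr_e = np.empty(n_out)
    fr_i = np.empty(n_out)
    h_e_o = np.empty(n_out)
    h_i_o = np.empty(n_out)
    q_e_o = np.empty(n_out)
    q_i_o = np.empty(n_out)
    stim_o = np.empty(n_out)

    hist_e = np.empty(n_steps + 1)
    hist_i = np.empty(n_steps + 1)
    hist_e[0] = y[2]
    hist_i[0] = y[4]

    w_e = th2_e - th1_e
    w_i = th2_i - th1_i

    k = 0
    for i in range(n_steps + 1):
        # delayed synaptic reads (frozen across RK4 stages; delays >> dt)
        if d_ie_steps > 0:
            j = i - d_ie_steps
            h_i_read = hist_i[j] if j >= 0 else hist_i[0]
        else:
            h_i_read = y[4]
        if d_ei_steps > 0:
            j = i - d_ei_steps
            h_e_read = hist_e[j] if j >= 0 else hist_e[0]
        else:
            h_e_read = y[2]

        if i % out_stride == 0:
            x_e = stim_half[2 * i] + pump_e - g_ie * h_i_read
            x_i = i_i_inj + pump_i + g_ei * h_e_read
            fr_e[k] = y[0]
            fr_i[k] = y[1]
            h_e_o[k] = y[2]
            h_i_o[k] = y[4]
            q_e_o[k] = (x_e - th1_e) / w_e
            q_i_o[k] = (x_i - th1_i) / w_i
            stim_o[k] = stim_half[2 * i]
            k += 1
        if i == n_steps:
            break

        # RK4 step
        acc = np.zeros(6)
        yy = y
        for stage in range(4):
            if stage == 0:
                t_idx = 2 * i
                w = 1.0
            elif stage == 3:
                t_idx = 2 * i + 2
                w = 1.0
            else:
                t_idx = 2 * i + 1
                w = 2.0
            if d_ie_steps > 0:
                hi_s = h_i_read
            else:
                hi_s = yy[4]
            if d_ei_steps > 0:
                he_s = h_e_read
            else:
                he_s = yy[2]
            x_e = stim_half[t_idx] + pump_e - g_ie * hi_s
            x_i = i_i_inj + pump_i + g_ei * he_s
            d = np.empty(6)
            d[0] = (_phi_fr(x_e, th1_e, th2_e, m1_e) - yy[0]) / lam_e
            d[1] = (_phi_fr(x_i, th1_i, th2_i, m1_i) - yy[1]) / lam_i
            d[2] = yy[3]
            d[3] = (yy[0] - yy[2]) / (tau_e * tau_e) - 2.0 * yy[3] / tau_e
            d[4] = yy[5]
            d[5] = (yy[1] - yy[4]) / (tau_i * tau_i) - 2.0 * yy[5] / tau_i
            acc += w * d
            if stage == 0 or stage == 1:
                yy = y + 0.5 * dt * d
            elif stage == 2:
                yy = y + dt * d
        y = y + (dt / 6.0) * acc
        if y[0] < 0.0:
            y[0] = 0.0
        if y[1] < 0.0:
            y[1] = 0.0
        hist_e[i + 1] = y[2]
        hist_i[i + 1] = y[4]

    return fr_e, fr_i, h_e_o, h_i_o, q_e_o, q_i_o, stim_o
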