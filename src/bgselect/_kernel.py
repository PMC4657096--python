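"""Compiled inner loop for trial simulation.

A single numba-jitted Euler loop over all populations. The step it takes is
identical to composing :func:`bgselect.network.net_inputs` with
:func:`bgselect.core.euler_step` and the sigmoid; the pure-numpy path stays
in ``network.py`` as the readable reference and the two are asserted equal
in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# population codes for failure reporting
POP_CODES = ("C", "L", "Go", "NoGo", "GPe", "GPi", "T", "STN", "ChI")


@njit(cache=True)
def _sig(u, a, u0):
    z = -a * (u - u0)
    if z > 500.0:
        z = 500.0
    elif z < -500.0:
        z = -500.0
    return 1.0 / (1.0 + np.exp(z))


@njit(cache=True)
def run_trial_kernel(
    n_steps, dt, tau, tau_L, a, u0, N,
    l_mat, cs_s, gs_s, ns_s,
    w_ct, w_gc, w_nc, w_en, w_ie, w_ig, w_tc, w_ti, w_stne,
    w_estn, w_istn, k_e, w_gh, w_nh,
    alpha, beta, gamma, theta_G, I_E, I_I, I_H,
    tonic, has_event, ev_on, ev_end, ev_level,
    stn_off, chi_clamped, chi_clamp_level,
):
    uC = np.zeros(N)
    uL = np.zeros(N)
    uG = np.zeros(N)
    uN = np.zeros(N)
    uE = np.zeros(N)
    uI = np.zeros(N)
    uT = np.zeros(N)
    uSTN = 0.0
    uH = 0.0

    rec = np.empty((6, n_steps + 1, N))
    rec_stn = np.empty(n_steps + 1)
    rec_h = np.empty(n_steps + 1)
    E_series = np.empty(n_steps + 1)
    DA_series = np.empty(n_steps + 1)

    kd = dt / tau
    ad = dt / tau_L

    yC = np.empty(N)
    yG = np.empty(N)
    yN = np.empty(N)
    yE = np.empty(N)
    yI = np.empty(N)
    yT = np.empty(N)
    for i in range(N):
        yC[i] = _sig(uC[i], a, u0)
        yG[i] = _sig(uG[i], a, u0)
        yN[i] = _sig(uN[i], a, u0)
        yE[i] = _sig(uE[i], a, u0)
        yI[i] = _sig(uI[i], a, u0)
        yT[i] = _sig(uT[i], a, u0)
    ySTN = 0.0 if stn_off else _sig(uSTN, a, u0)
    yH = chi_clamp_level if chi_clamped else _sig(uH, a, u0)

    fail_pop = -1
    fail_t = -1.0

    for k in range(n_steps + 1):
        t = k * dt
        DA = tonic
        if has_event and ev_on <= t < ev_end:
            DA = ev_level
        sC = 0.0
        s2 = 0.0
        for i in range(N):
            sC += yC[i]
            s2 += yC[i] * yC[i]
        E = sC * sC - s2
        if E < 0.0:
            E = 0.0

        for i in range(N):
            rec[0, k, i] = yC[i]
            rec[1, k, i] = yG[i]
            rec[2, k, i] = yN[i]
            rec[3, k, i] = yE[i]
            rec[4, k, i] = yI[i]
            rec[5, k, i] = yT[i]
        rec_stn[k] = ySTN
        rec_h[k] = yH
        E_series[k] = E
        DA_series[k] = DA
        if k == n_steps:
            break

        stn_in = k_e * E
        for i in range(N):
            stn_in += w_stne[i] * yE[i]

        for i in range(N):
            xL = 0.0
            for j in range(N):
                xL += l_mat[i, j] * yC[j]
            xC = cs_s[i] + uL[i] + w_ct[i] * yT[i]
            xG = gs_s[i] + w_gc[i] * yC[i] + alpha * DA * (yG[i] - theta_G) + w_gh * yH
            xN = ns_s[i] + w_nc[i] * yC[i] + beta * DA + w_nh * yH
            xE = w_en[i] * yN[i] + w_estn * ySTN + I_E
            xI = w_ig[i] * yG[i] + w_ie[i] * yE[i] + w_istn * ySTN + I_I
            xT = w_ti[i] * yI[i] + w_tc[i] * yC[i]

            uL[i] += ad * (xL - uL[i])
            uC[i] += kd * (xC - uC[i])
            uG[i] += kd * (xG - uG[i])
            uN[i] += kd * (xN - uN[i])
            uE[i] += kd * (xE - uE[i])
            uI[i] += kd * (xI - uI[i])
            uT[i] += kd * (xT - uT[i])
        uSTN += kd * (stn_in - uSTN)
        uH += kd * ((I_H + gamma * DA) - uH)

        for i in range(N):
            if not (np.isfinite(uC[i]) and np.isfinite(uL[i]) and np.isfinite(uG[i])
                    and np.isfinite(uN[i]) and np.isfinite(uE[i])
                    and np.isfinite(uI[i]) and np.isfinite(uT[i])):
                if not np.isfinite(uC[i]):
                    fail_pop = 0
                elif not np.isfinite(uL[i]):
                    fail_pop = 1
                elif not np.isfinite(uG[i]):
                    fail_pop = 2
                elif not np.isfinite(uN[i]):
                    fail_pop = 3
                elif not np.isfinite(uE[i]):
                    fail_pop = 4
                elif not np.isfinite(uI[i]):
                    fail_pop = 5
                else:
                    fail_pop = 6
                fail_t = (k + 1) * dt
                break
        if fail_pop < 0 and not np.isfinite(uSTN):
            fail_pop = 7
            fail_t = (k + 1) * dt
        if fail_pop < 0 and not np.isfinite(uH):
            fail_pop = 8
            fail_t = (k + 1) * dt
        if fail_pop >= 0:
            break

        for i in range(N):
            yC[i] = _sig(uC[i], a, u0)
            yG[i] = _sig(uG[i], a, u0)
            yN[i] = _sig(uN[i], a, u0)
            yE[i] = _sig(uE[i], a, u0)
            yI[i] = _sig(uI[i], a, u0)
            yT[i] = _sig(uT[i], a, u0)
        ySTN = 0.0 if stn_off else _sig(uSTN, a, u0)
        yH = chi_clamp_level if chi_clamped else _sig(uH, a, u0)

    return rec, rec_stn, rec_h, E_series, DA_series, fail_pop, fail_t
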