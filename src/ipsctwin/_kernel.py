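"""Right-hand side of the iPSC-CM membrane/Ca-handling ODE system.

Numba-compiled scalar kernel.  The state layout, parameter-vector layout and
current ordering defined here are frozen; the public names live in
:mod:`ipsctwin.constants`.

Units: time ms, voltage mV, concentrations mM, current densities pA/pF.
Sign convention: outward membrane current is positive, dV/dt = -(I_ion + I_stim).
"""

import numpy as np
from numba import njit

# state indices
IV, ICAI, ICASR, INAI, IKI = 0, 1, 2, 3, 4
IM, IH, IJ = 5, 6, 7
ID, IF_, IFCA = 8, 9, 10
IDT, IFT = 11, 12
IXR1, IXR2, IXS = 13, 14, 15
IR, IS = 16, 17
IXF, IG = 18, 19
N_STATES = 20

# parameter-vector layout: p[0:16] effective conductances (canonical order),
# p[16]=Cao, p[17]=Nao, p[18]=Ko, p[19]=stim amplitude (pA/pF),
# p[20]=stim pulse duration (ms), p[21]=stim period (ms, <=0 means unpaced),
# p[22]=stim-active flag.  The integrator splits the time axis at pulse edges
# and sets the flag per segment, keeping the RHS continuous in t; only
# derivatives() evaluated at an arbitrary t derives the flag from t itself.
N_COND = 16
IP_CAO, IP_NAO, IP_KO = 16, 17, 18
IP_AMP, IP_DUR, IP_PER, IP_ON = 19, 20, 21, 22
N_PARAMS = 23

# currents/fluxes output layout
C_NA, C_CAL, C_CAT, C_TO, C_KR, C_KS, C_K1, C_F = 0, 1, 2, 3, 4, 5, 6, 7
C_NAK, C_NACA, C_PCA, C_BNA, C_BCA, C_STIM = 8, 9, 10, 11, 12, 13
C_JUP, C_JREL, C_JLEAK = 14, 15, 16
N_CURRENTS = 17

# physical constants
F_CONST = 96.4853415  # C/mmol
RTF = 26.713761  # mV at 310 K
CM = 60.0  # pF
V_CYT = 6500.0  # um^3
V_SR = 580.0  # um^3
CONV = CM / (F_CONST * V_CYT)  # (pA/pF) -> mM/ms in cytosol
VC_OVER_VSR = V_CYT / V_SR

# cytosolic / SR Ca buffering (rapid-buffer approximation)
BUF_C, K_BUF_C = 0.20, 0.001
BUF_SR, K_BUF_SR = 10.0, 0.3

# SR release shape constants (scaled by G_rel)
A_REL, B_REL, C_REL = 0.016464, 0.25, 0.008232
K_UP = 0.00025

# funny-current Na fraction
F_NA_FRAC = 0.37


@njit(cache=False)
def compute(t, y, p, cur):
    """Fill ``cur`` with current densities/fluxes and return dy/dt."""
    v = y[IV]
    cai = y[ICAI]
    casr = y[ICASR]
    nai = y[INAI]
    ki = y[IKI]
    if cai < 1e-9:
        cai = 1e-9
    if casr < 1e-9:
        casr = 1e-9
    if nai < 1e-3:
        nai = 1e-3
    if ki < 1e-3:
        ki = 1e-3

    cao = p[IP_CAO]
    nao = p[IP_NAO]
    ko = p[IP_KO]

    e_na = RTF * np.log(nao / nai)
    e_k = RTF * np.log(ko / ki)
    e_ks = RTF * np.log((ko + 0.03 * nao) / (ki + 0.03 * nai))
    e_ca = 0.5 * RTF * np.log(cao / cai)

    dy = np.zeros(N_STATES)

    # ---- fast Na+ current (Luo-Rudy 1991 kinetics) ----
    dv47 = v + 47.13
    if abs(dv47) < 1e-6:
        a_m = 3.2  # limit of 0.32*x/(1-exp(-0.1 x))
    else:
        a_m = 0.32 * dv47 / (1.0 - np.exp(-0.1 * dv47))
    b_m = 0.08 * np.exp(-v / 11.0)
    if v >= -40.0:
        a_h = 0.0
        b_h = 1.0 / (0.13 * (1.0 + np.exp((v + 10.66) / -11.1)))
        a_j = 0.0
        b_j = 0.3 * np.exp(-2.535e-7 * v) / (1.0 + np.exp(-0.1 * (v + 32.0)))
    else:
        a_h = 0.135 * np.exp((80.0 + v) / -6.8)
        b_h = 3.56 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.35 * v)
        a_j = ((-1.2714e5 * np.exp(0.2444 * v) - 3.474e-5 * np.exp(-0.04391 * v))
               * (v + 37.78) / (1.0 + np.exp(0.311 * (v + 79.23))))
        b_j = 0.1212 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14)))
    m, h, j = y[IM], y[IH], y[IJ]
    dy[IM] = a_m * (1.0 - m) - b_m * m
    dy[IH] = a_h * (1.0 - h) - b_h * h
    dy[IJ] = a_j * (1.0 - j) - b_j * j
    i_na = p[0] * m * m * m * h * j * (v - e_na)

    # ---- L-type Ca2+ current (GHK-type driving force) ----
    d, f, fca = y[ID], y[IF_], y[IFCA]
    d_inf = 1.0 / (1.0 + np.exp((-8.0 - v) / 7.5))
    a_d = 1.4 / (1.0 + np.exp((-35.0 - v) / 13.0)) + 0.25
    b_d = 1.4 / (1.0 + np.exp((v + 5.0) / 5.0))
    g_d = 1.0 / (1.0 + np.exp((50.0 - v) / 20.0))
    tau_d = a_d * b_d + g_d
    f_inf = 1.0 / (1.0 + np.exp((v + 20.0) / 7.0))
    tau_f = (1102.5 * np.exp(-((v + 27.0) ** 2) / 225.0)
             + 200.0 / (1.0 + np.exp((13.0 - v) / 10.0))
             + 180.0 / (1.0 + np.exp((v + 30.0) / 10.0)) + 20.0)
    a_fca = 1.0 / (1.0 + (cai / 0.000325) ** 8)
    b_fca = 0.1 / (1.0 + np.exp((cai - 0.0005) / 0.0001))
    g_fca = 0.2 / (1.0 + np.exp((cai - 0.00075) / 0.0008))
    fca_inf = (a_fca + b_fca + g_fca + 0.23) / 1.46
    if fca_inf > 1.0:  # keep fCa a true [0,1] gate
        fca_inf = 1.0
    dy[ID] = (d_inf - d) / tau_d
    dy[IF_] = (f_inf - f) / tau_f
    # Ca-dependent inactivation speeds up with Cai; recovery at diastolic Cai
    # is slow.  Smooth in state so the Jacobian stays continuous.
    tau_fca = 2.0 + 58.0 / (1.0 + (cai / 0.0003) ** 4)
    dy[IFCA] = (fca_inf - fca) / tau_fca
    vn = v / RTF
    if abs(vn) < 1e-5:
        ghk = RTF * (cai - 0.341 * cao)  # V/(exp(2V/RTF)-1) -> RTF/2
    else:
        e2v = np.exp(2.0 * vn)
        ghk = v * (cai * e2v - 0.341 * cao) / (e2v - 1.0)
    i_cal = p[1] * d * f * fca * ghk

    # ---- T-type Ca2+ current ----
    dt_, ft = y[IDT], y[IFT]
    dt_inf = 1.0 / (1.0 + np.exp(-(v + 26.3) / 6.0))
    tau_dt = 1.0 / (1.068 * np.exp((v + 26.3) / 30.0)
                    + 1.068 * np.exp(-(v + 26.3) / 30.0)) + 0.2
    ft_inf = 1.0 / (1.0 + np.exp((v + 61.7) / 5.6))
    tau_ft = 1.0 / (0.0153 * np.exp(-(v + 61.7) / 83.3)
                    + 0.015 * np.exp((v + 61.7) / 15.38))
    dy[IDT] = (dt_inf - dt_) / tau_dt
    dy[IFT] = (ft_inf - ft) / tau_ft
    i_cat = p[2] * dt_ * ft * (v - e_ca)

    # ---- transient outward K+ current ----
    r, s = y[IR], y[IS]
    r_inf = 1.0 / (1.0 + np.exp((20.0 - v) / 6.0))
    tau_r = 9.5 * np.exp(-((v + 40.0) ** 2) / 1800.0) + 0.8
    s_inf = 1.0 / (1.0 + np.exp((v + 20.0) / 5.0))
    tau_s = (85.0 * np.exp(-((v + 45.0) ** 2) / 320.0)
             + 5.0 / (1.0 + np.exp((v - 20.0) / 5.0)) + 3.0)
    dy[IR] = (r_inf - r) / tau_r
    dy[IS] = (s_inf - s) / tau_s
    i_to = p[3] * r * s * (v - e_k)

    # ---- rapid delayed rectifier K+ current ----
    # activation shifted negative (sinus-like hERG gating) so that IKr keeps
    # a small standing component at the maximum diastolic potential; blocking
    # it then depolarizes the MDP and can silence automaticity, the dominant
    # hERG-block arrhythmia mode of spontaneously beating iPSC-CMs
    xr1, xr2 = y[IXR1], y[IXR2]
    u = v + 20.0
    xr1_inf = 1.0 / (1.0 + np.exp((-26.0 - u) / 7.0))
    a_xr1 = 450.0 / (1.0 + np.exp((-45.0 - u) / 10.0))
    b_xr1 = 6.0 / (1.0 + np.exp((u + 30.0) / 11.5))
    xr2_inf = 1.0 / (1.0 + np.exp((v + 88.0) / 24.0))
    a_xr2 = 3.0 / (1.0 + np.exp((-60.0 - v) / 20.0))
    b_xr2 = 1.12 / (1.0 + np.exp((v - 60.0) / 20.0))
    dy[IXR1] = (xr1_inf - xr1) / (a_xr1 * b_xr1)
    dy[IXR2] = (xr2_inf - xr2) / (a_xr2 * b_xr2)
    i_kr = p[4] * np.sqrt(ko / 5.4) * xr1 * xr2 * (v - e_k)

    # ---- slow delayed rectifier K+ current ----
    xs = y[IXS]
    xs_inf = 1.0 / (1.0 + np.exp((-5.0 - v) / 14.0))
    a_xs = 1400.0 / np.sqrt(1.0 + np.exp((5.0 - v) / 6.0))
    b_xs = 1.0 / (1.0 + np.exp((v - 35.0) / 15.0))
    dy[IXS] = (xs_inf - xs) / (a_xs * b_xs + 80.0)
    i_ks = p[5] * xs * xs * (v - e_ks)

    # ---- inward rectifier K+ current (instantaneous) ----
    dvk = v - e_k
    a_k1 = 1.02 / (1.0 + np.exp(0.2385 * (dvk - 59.215)))
    b_k1 = ((0.49124 * np.exp(0.08032 * (dvk + 5.476))
             + np.exp(0.06175 * (dvk - 594.31)))
            / (1.0 + np.exp(-0.5143 * (dvk + 4.753))))
    k1_inf = a_k1 / (a_k1 + b_k1)
    i_k1 = p[6] * np.sqrt(ko / 5.4) * k1_inf * dvk

    # ---- hyperpolarization-activated funny current ----
    xf = y[IXF]
    xf_inf = 1.0 / (1.0 + np.exp((v + 77.0) / 5.0))
    tau_xf = 1900.0 / (1.0 + np.exp((v + 15.0) / 10.0)) + 15.0
    dy[IXF] = (xf_inf - xf) / tau_xf
    i_f_na = p[7] * F_NA_FRAC * xf * (v - e_na)
    i_f_k = p[7] * (1.0 - F_NA_FRAC) * xf * (v - e_k)
    i_f = i_f_na + i_f_k

    # ---- Na+/K+ pump ----
    i_nak = (p[8] * (ko / (ko + 1.0)) * (nai / (nai + 40.0))
             / (1.0 + 0.1245 * np.exp(-0.1 * vn) + 0.0353 * np.exp(-vn)))

    # ---- Na+/Ca2+ exchanger ----
    e1 = np.exp(0.35 * vn)
    e2 = np.exp(-0.65 * vn)
    i_naca = (p[9] * (e1 * nai ** 3 * cao - e2 * nao ** 3 * cai * 2.5)
              / ((87.5 ** 3 + nao ** 3) * (1.38 + cao) * (1.0 + 0.1 * e2)))

    # ---- sarcolemmal Ca2+ pump, background currents ----
    i_pca = p[10] * cai / (cai + 0.0005)
    i_bna = p[11] * (v - e_na)
    i_bca = p[12] * (v - e_ca)

    # ---- SR fluxes (per cytosolic volume, mM/ms) ----
    j_up = p[13] / (1.0 + (K_UP / cai) ** 2)
    j_leak = p[15] * (casr - cai)
    g = y[IG]
    ratio6 = (cai / 0.00035) ** 6
    g_inf = 1.0 / (1.0 + ratio6)
    tau_g = 2.0 + 58.0 / (1.0 + (cai / 0.00035) ** 4)
    dy[IG] = (g_inf - g) / tau_g
    j_rel = p[14] * (A_REL * casr * casr / (B_REL * B_REL + casr * casr)
                     + C_REL) * d * g

    # ---- stimulus (square pulse; gating decided outside the integrator) ----
    i_stim = -p[IP_AMP] if p[IP_ON] > 0.5 else 0.0

    # ---- balance equations ----
    i_ion = (i_na + i_cal + i_cat + i_to + i_kr + i_ks + i_k1 + i_f
             + i_nak + i_naca + i_pca + i_bna + i_bca)
    dy[IV] = -(i_ion + i_stim)

    buf_i = 1.0 / (1.0 + BUF_C * K_BUF_C / ((cai + K_BUF_C) ** 2))
    buf_sr = 1.0 / (1.0 + BUF_SR * K_BUF_SR / ((casr + K_BUF_SR) ** 2))
    dy[ICAI] = buf_i * (j_leak - j_up + j_rel
                        - (i_cal + i_cat + i_bca + i_pca - 2.0 * i_naca)
                        * CONV * 0.5)
    dy[ICASR] = buf_sr * VC_OVER_VSR * (j_up - j_leak - j_rel)
    dy[INAI] = -(i_na + i_bna + i_f_na + 3.0 * i_nak + 3.0 * i_naca) * CONV
    dy[IKI] = -(i_to + i_kr + i_ks + i_k1 + i_f_k - 2.0 * i_nak + i_stim) * CONV

    cur[C_NA] = i_na
    cur[C_CAL] = i_cal
    cur[C_CAT] = i_cat
    cur[C_TO] = i_to
    cur[C_KR] = i_kr
    cur[C_KS] = i_ks
    cur[C_K1] = i_k1
    cur[C_F] = i_f
    cur[C_NAK] = i_nak
    cur[C_NACA] = i_naca
    cur[C_PCA] = i_pca
    cur[C_BNA] = i_bna
    cur[C_BCA] = i_bca
    cur[C_STIM] = i_stim
    cur[C_JUP] = j_up
    cur[C_JREL] = j_rel
    cur[C_JLEAK] = j_leak
    return dy


@njit(cache=False)
def rhs(t, y, p):
    cur = np.empty(N_CURRENTS)
    return compute(t, y, p, cur)


@njit(cache=False)
def rhs_odeint(y, t, p):
    cur = np.empty(N_CURRENTS)
    return compute(t, y, p, cur)
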