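"""Independent well-mixed (0-D) oracle for the delivery model.

A deliberately separate implementation of the same kinetic scheme with
no radial dimension: one well-mixed ECS compartment exchanging with the
blood through the total vessel-wall area.  In the limit of fast
intratissue diffusion the radial model must agree with this one; the
comparison is a cross-check, so this module intentionally rebuilds the
equations from the rate constants instead of importing the simulator's
right-hand side.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import expit

N_A = 6.02214076e23


def run_well_mixed(params, schedule, V0_mm3, t_end_hr, equilibrate=True,
                   rtol=1e-8):
    """Integrate the 0-D analogue; returns dict of time series."""
    g = params.geometry
    rb, ro, phi = g.r_b_cm, g.r_o_cm, g.phi_e
    ka, kd = params.binding.k_a, params.binding.k_d
    rc = params.receptor
    ks, ke, kt, xce, xcc = rc.k_s, rc.k_e, rc.k_t, rc.chi_ce, rc.chi_cc
    Rstar = rc.R_star
    cl = params.cells
    rho_star = cl.rho_star
    bridge = 1e12 / (N_A * phi)
    deg = params.ecs_deg
    lamT = params.molecule.lambda_it_blood
    lamR = params.chi_bfR
    lamC = params.lambda_complex_blood
    Vb = params.blood.V_blood_ml
    pm = params.permeability
    # wall area per ECS volume (cm⁻¹) and per blood volume scale
    kx = 2.0 * rb / ((ro**2 - rb**2) * phi)
    aw_fac = 2.0 * rb * 1e-3 / ro**2

    def perm(V):
        S = expit(-pm.a_per_mm3 * (V - pm.V_c_mm3))
        return (pm.P_low_cm_s + (pm.P_high_cm_s - pm.P_low_cm_s) * S) * 3600.0

    # state: CT, CR, CC, CbT, CbR, CbC, rho1, rho2, rho3,
    #        B1, Ten1, Tcc1, W2R, W2B, W2en, W2cc, W3R, W3B, V
    def rhs(t, y):
        (CT, CR, CC, CbT, CbR, CbC, r1, r2, r3,
         B1, Te1, Tc1, W2R, W2B, W2en, W2cc, W3R, W3B, V) = y
        P = perm(V)
        PC = P if pm.backperm_complex else 0.0
        fT = P * CbT - P * CT
        fR = P * CbR - P * CR
        fC = PC * CbC - PC * CC
        Rf1 = Rstar - B1
        Rtot = r1 * Rf1 + W2R + W3R
        Btot = r1 * B1 + W2B + W3B
        net = ka * CT * CR - kd * CC
        dCT = kx * fT - net - bridge * (ka * CT * Rtot - kd * Btot) \
            - deg.chi_efT * CT
        dCR = kx * fR - net + bridge * ks * Rtot - deg.chi_efR * CR
        dCC = kx * fC + net + bridge * ks * Btot - deg.chi_ecR * CC
        dB1 = ka * CT * Rf1 - (kd + ke + ks) * B1
        dTe1 = ke * B1 - (xce + kt) * Te1
        dTc1 = kt * Te1 - xcc * Tc1
        kap = cl.kappa_max * max(Tc1, 0.0) / (cl.T_0 + max(Tc1, 0.0))
        Gam = cl.Gamma_0 * math.exp(-cl.alpha * V)
        gg = (Gam * r1 - cl.Chi_clear * r3) / rho_star
        dr1 = Gam * r1 - kap * r1 - gg * r1
        dr2 = kap * r1 - cl.Delta * r2 - gg * r2
        dr3 = cl.Delta * r2 - cl.Chi_clear * r3 - gg * r3
        l2 = cl.Delta + gg
        dW2R = kap * r1 * Rf1 - (ke + ks) * W2R + kd * W2B - ka * CT * W2R \
            - l2 * W2R
        dW2B = kap * r1 * B1 + ka * CT * W2R - (kd + ke + ks) * W2B - l2 * W2B
        dW2en = kap * r1 * Te1 + ke * W2B - (xce + kt) * W2en - l2 * W2en
        dW2cc = kap * r1 * Tc1 + kt * W2en - xcc * W2cc - l2 * W2cc
        l3 = cl.Chi_clear + gg
        dW3R = cl.Delta * W2R - ks * W3R + kd * W3B - ka * CT * W3R - l3 * W3R
        dW3B = cl.Delta * W2B + ka * CT * W3R - (kd + ks) * W3B - l3 * W3B
        dV = gg * V
        exch = aw_fac * V / Vb
        dCbT = -lamT * CbT - exch * fT
        dCbR = -lamR * CbR - exch * fR
        dCbC = -lamC * CbC - exch * fC
        if params.blood.blood_binding:
            nb = ka * CbT * CbR - kd * CbC
            dCbT -= nb
            dCbR -= nb
            dCbC += nb
        return [dCT, dCR, dCC, dCbT, dCbR, dCbC, dr1, dr2, dr3,
                dB1, dTe1, dTc1, dW2R, dW2B, dW2en, dW2cc, dW3R, dW3B, dV]

    y0 = np.zeros(19)
    y0[6] = rho_star
    y0[18] = V0_mm3
    if equilibrate and ks > 0:
        # closed-form 0-D steady state of the no-toxin antigen subsystem
        S = ks * Rstar * rho_star * bridge
        P0 = perm(V0_mm3)
        exch0 = aw_fac * V0_mm3 / Vb
        # [chi+kx P, -kx P; -exch P, lam+exch P] [CR, CbR] = [S, 0]
        A = np.array([[deg.chi_efR + kx * P0, -kx * P0],
                      [-exch0 * P0, lamR + exch0 * P0]])
        CR0, CbR0 = np.linalg.solve(A, [S, 0.0])
        y0[1], y0[4] = CR0, CbR0

    sched = sorted(schedule or [])
    breaks = sorted({0.0, t_end_hr, *(t for t, _ in sched)})
    dose_at = {}
    for t, d in sched:
        dose_at[t] = dose_at.get(t, 0.0) + d
    times, states = [], []
    y = y0
    for a, b in zip(breaks[:-1], breaks[1:]):
        if a in dose_at:
            y = y.copy()
            y[3] += dose_at[a]
        te = np.linspace(a, b, max(2, int(b - a) + 1))
        sol = solve_ivp(rhs, (a, b), y, method="BDF", rtol=rtol, atol=1e-10,
                        t_eval=te)
        assert sol.success, sol.message
        times.append(sol.t if not times else sol.t[1:])
        states.append(sol.y.T if len(states) == 0 else sol.y.T[1:])
        y = sol.y[:, -1]
    T = np.concatenate(times)
    Y = np.vstack(states)
    return {"t": T, "V": Y[:, 18], "C_bT": Y[:, 3], "C_efT": Y[:, 0],
            "C_efR": Y[:, 1], "C_ecR": Y[:, 2], "Y": Y}
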