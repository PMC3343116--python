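"""Numba kernel for the branched-cable integration.

One call advances the whole cell over ``nsteps`` of size ``dt`` using a
Crank-Nicolson step on the cable equation (Hines-ordered tree solve) with
staggered exponential-Euler gate updates.  Voltage-dependent gate kinetics
are table-driven (linear interpolation on a 0.05 mV grid); calcium- and
synapse-state updates are exact exponential steps.

All quantities use the (mV, ms, nA, uS, nF, mM) unit system.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .channels import N_GATES, V_MIN, DV

# channel indices in the conductance array (see channels.CHANNELS)
_NAF, _NAP, _KDR, _KA, _KD, _FAHP, _SAHP, _H, _CAT, _CAN_CA, _CAR, _CAL, _CAN = range(13)
# gate indices (see channels.GATE_LAYOUT)
(_G_NAF_M, _G_NAF_H, _G_NAP_M, _G_KDR_N, _G_KA_A, _G_KA_B, _G_KD_A, _G_KD_B,
 _G_H_M, _G_CAT_M, _G_CAT_H, _G_CANCA_M, _G_CANCA_H, _G_CAR_M, _G_CAR_H,
 _G_CAL_M, _G_FAHP_M) = range(N_GATES)

OK = 0
DIVERGED = 1


@njit(cache=True, fastmath=True)
def integrate(
    # topology / passive
    parent, g_ax, cm, g_leak, e_leak,
    # channel conductances, uS per compartment: shape (13, nc)
    gch,
    # gate tables
    inf_tab, fac_tab,
    # reversals and mechanism constants
    e_na, e_k, e_h, e_ca,
    fahp_kd, sahp_kd, sahp_fac,
    can_beta, can_cac, can_phi, e_can, nmda_ca_frac,
    kca, tau_ca, kca2, tau_ca2, cai0,
    # state (modified in place)
    v, gates, cai, cai2, q_sahp, m_can,
    # synapses
    syn_comp, syn_w, syn_kind,
    k_dec_r, k_dec_d, k_e, k_norm, k_is_nmda,
    mg_a, mg_slope,
    ev_t, ev_kind,
    syn_a, syn_b,
    # stimuli
    ic_comp, ic_t0, ic_t1, ic_amp,
    noise_comp, noise_i,
    clamp_comp, clamp_v, clamp_g,
    # control
    t0, dt, nsteps,
    # recording
    rec_comps, rec_v, rec_cai, rec_ican, rec_iclamp,
):
    nc = v.shape[0]
    nu = syn_comp.shape[0]
    ne = ev_t.shape[0]
    nr = rec_comps.shape[0]
    inv_dv = 1.0 / DV
    nv = inf_tab.shape[1]

    d = np.empty(nc)
    rhs = np.empty(nc)
    a_off = np.empty(nc)
    g_syn = np.zeros(nc)
    ge_syn = np.zeros(nc)
    g_nmda_c = np.zeros(nc)
    v_old = np.empty(nc)
    g_ca_tot = np.zeros(nc)
    g_ca_slow = np.zeros(nc)

    for i in range(nc):
        a_off[i] = -0.5 * g_ax[i]

    # initial sample
    for r in range(nr):
        rec_v[r, 0] = v[rec_comps[r]]
    rec_cai[0] = cai[rec_comps[0]]
    rec_ican[0] = gch[_CAN, rec_comps[0]] * m_can[rec_comps[0]] * (v[rec_comps[0]] - e_can)
    if clamp_comp >= 0:
        rec_iclamp[0] = clamp_g * (clamp_v - v[clamp_comp])

    ev_i = 0
    soma_can = rec_comps[0]
    k_dec_r_h = np.sqrt(k_dec_r)
    k_dec_d_h = np.sqrt(k_dec_d)
    dec_fast = np.exp(-dt / tau_ca)
    dec_slow = np.exp(-dt / tau_ca2)
    syn_check = 1 if nu > 0 else 0

    for step in range(nsteps):
        t_new = t0 + (step + 1) * dt

        # ---- gate updates (staggered, exponential Euler) ----
        for i in range(nc):
            vi = v[i]
            x = (vi - V_MIN) * inv_dv
            if x < 0.0:
                x = 0.0
            elif x > nv - 1.001:
                x = nv - 1.001
            j = int(x)
            fr = x - j
            for g in range(N_GATES):
                inf = inf_tab[g, j] + fr * (inf_tab[g, j + 1] - inf_tab[g, j])
                fac = fac_tab[g, j] + fr * (fac_tab[g, j + 1] - fac_tab[g, j])
                if g == _G_FAHP_M:
                    inf = inf * cai[i] / (cai[i] + fahp_kd)
                gates[g, i] += fac * (inf - gates[g, i])
            ci2 = cai[i] * cai[i]
            q_inf = ci2 / (ci2 + sahp_kd * sahp_kd)
            q_sahp[i] += sahp_fac * (q_inf - q_sahp[i])
            if gch[_CAN, i] > 0.0:
                r = cai2[i] / can_cac
                alpha = can_beta * r * r
                m_inf = alpha / (alpha + can_beta)
                fac_can = 1.0 - np.exp(-dt * can_phi * (alpha + can_beta))
                m_can[i] += fac_can * (m_inf - m_can[i])

        # ---- synapses ----
        while ev_i < ne and ev_t[ev_i] <= t_new + 1e-9:
            k = ev_kind[ev_i]
            for u in range(nu):
                if syn_kind[u] == k:
                    inc = syn_w[u] * k_norm[k]
                    syn_a[u] += inc
                    syn_b[u] += inc
            ev_i += 1
            syn_check = 1
        if syn_check == 1 and step % 4000 == 0 and ev_i >= ne:
            # synaptic states decay to nothing long before the recording
            # ends; skip the per-unit work once they are negligible
            tot = 0.0
            for u in range(nu):
                tot += syn_b[u]
            if tot < 1e-10:
                syn_check = 1 if nu > 0 else 0
                for i in range(nc):
                    g_syn[i] = 0.0
                    ge_syn[i] = 0.0
        if syn_check == 1:
            for i in range(nc):
                g_syn[i] = 0.0
                ge_syn[i] = 0.0
                g_nmda_c[i] = 0.0
            for u in range(nu):
                k = syn_kind[u]
                syn_a[u] *= k_dec_r_h[k]
                syn_b[u] *= k_dec_d_h[k]
                g = syn_b[u] - syn_a[u]
                syn_a[u] *= k_dec_r_h[k]
                syn_b[u] *= k_dec_d_h[k]
                if g > 0.0:
                    c = syn_comp[u]
                    if k_is_nmda[k] == 1:
                        g *= 1.0 / (1.0 + mg_a * np.exp(-mg_slope * v[c]))
                        g_nmda_c[c] += g
                    g_syn[c] += g
                    ge_syn[c] += g * k_e[k]

        # ---- assemble & Crank-Nicolson solve ----
        for i in range(nc):
            v_old[i] = v[i]
            m3 = gates[_G_NAF_M, i]
            g_naf = gch[_NAF, i] * m3 * m3 * m3 * gates[_G_NAF_H, i]
            g_nap = gch[_NAP, i] * gates[_G_NAP_M, i]
            nn = gates[_G_KDR_N, i]
            g_kdr = gch[_KDR, i] * nn * nn
            aa = gates[_G_KA_A, i]
            g_ka = gch[_KA, i] * aa * aa * gates[_G_KA_B, i]
            g_kd = gch[_KD, i] * gates[_G_KD_A, i] * gates[_G_KD_B, i]
            g_fahp = gch[_FAHP, i] * gates[_G_FAHP_M, i]
            g_sahp = gch[_SAHP, i] * q_sahp[i]
            g_hc = gch[_H, i] * gates[_G_H_M, i]
            mc = gates[_G_CAT_M, i]
            g_cat = gch[_CAT, i] * mc * mc * gates[_G_CAT_H, i]
            mc = gates[_G_CANCA_M, i]
            g_canca = gch[_CAN_CA, i] * mc * mc * gates[_G_CANCA_H, i]
            mc = gates[_G_CAR_M, i]
            g_car = gch[_CAR, i] * mc * mc * gates[_G_CAR_H, i]
            mc = gates[_G_CAL_M, i]
            g_cal = gch[_CAL, i] * mc * mc
            g_can = gch[_CAN, i] * m_can[i]

            g_ca = g_cat + g_canca + g_car + g_cal
            g_ca_tot[i] = g_ca
            # the slow (CAN-coupled) pool is fed by the high-voltage-activated
            # N- and L-type channels only (spike-driven microdomain); the
            # low-threshold T window and the R-type current are excluded
            g_ca_slow[i] = g_canca + g_cal
            g_k = g_kdr + g_ka + g_kd + g_fahp + g_sahp
            g_na = g_naf + g_nap
            g_tot = g_leak[i] + g_na + g_k + g_hc + g_ca + g_can + g_syn[i]
            ge = (g_leak[i] * e_leak + g_na * e_na + g_k * e_k + g_hc * e_h
                  + g_ca * e_ca + g_can * e_can + ge_syn[i])

            d[i] = cm[i] / dt + 0.5 * g_tot
            rhs[i] = (cm[i] / dt - 0.5 * g_tot) * v[i] + ge

        # axial contributions
        for i in range(1, nc):
            p = parent[i]
            gh = 0.5 * g_ax[i]
            d[i] += gh
            d[p] += gh
            rhs[i] += gh * (v[p] - v[i])
            rhs[p] += gh * (v[i] - v[p])

        # external currents
        for s in range(ic_comp.shape[0]):
            if ic_t0[s] <= t_new <= ic_t1[s]:
                rhs[ic_comp[s]] += ic_amp[s]
        if noise_i.shape[0] > 0:
            rhs[noise_comp] += noise_i[step]
        if clamp_comp >= 0:
            # clamp handled fully implicitly (backward Euler): the series
            # conductance is stiff and would ring under the CN half-step
            d[clamp_comp] += clamp_g
            rhs[clamp_comp] += clamp_g * clamp_v

        # Hines solve (parents precede children)
        for i in range(nc - 1, 0, -1):
            p = parent[i]
            f = a_off[i] / d[i]
            d[p] -= f * a_off[i]
            rhs[p] -= f * rhs[i]
        v[0] = rhs[0] / d[0]
        for i in range(1, nc):
            v[i] = (rhs[i] - a_off[i] * v[parent[i]]) / d[i]

        # ---- calcium pools (midpoint voltage: second-order coupling) ----
        for i in range(nc):
            if kca[i] > 0.0:
                vmid = 0.5 * (v_old[i] + v[i])
                i_ca = g_ca_tot[i] * (vmid - e_ca)  # nA, inward negative
                influx = -i_ca * kca[i]
                if influx < 0.0:
                    influx = 0.0
                target = cai0 + influx * tau_ca
                cai[i] = target + (cai[i] - target) * dec_fast
                if cai[i] < cai0:
                    cai[i] = cai0
                # NMDA receptors carry a calcium fraction that feeds the
                # CAN-coupled microdomain directly
                i_ca_s = (g_ca_slow[i] + nmda_ca_frac * g_nmda_c[i]) * (vmid - e_ca)
                influx2 = -i_ca_s * kca2[i]
                if influx2 < 0.0:
                    influx2 = 0.0
                target2 = cai0 + influx2 * tau_ca2
                cai2[i] = target2 + (cai2[i] - target2) * dec_slow
                if cai2[i] < cai0:
                    cai2[i] = cai0

        # ---- record & checks ----
        for r in range(nr):
            rec_v[r, step + 1] = v[rec_comps[r]]
        rec_cai[step + 1] = cai[soma_can]
        rec_ican[step + 1] = gch[_CAN, soma_can] * m_can[soma_can] * (v[soma_can] - e_can)
        if clamp_comp >= 0:
            rec_iclamp[step + 1] = clamp_g * (clamp_v - v[clamp_comp])

        for i in range(nc):
            if not (-200.0 < v[i] < 200.0) or v[i] != v[i]:
                return DIVERGED, step + 1
    return OK, nsteps
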