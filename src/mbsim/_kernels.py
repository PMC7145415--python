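"""Numba kernels: Hines-ordered cable solves and the coupled network loop.

All kernels assume compartments in Hines order (parent index < child index),
units mV / ms / uS / nF / nA.  Synaptic conductances enter the implicit
voltage step through the diagonal (evaluated at the current step's conductance
state), so the cable update is unconditionally stable.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# KC parameter-array layout (see kc_channels.py for the constants fixture)
# ---------------------------------------------------------------------------
KCP_C, KCP_GL, KCP_EL, KCP_GNAF, KCP_GNAS, KCP_GKDR, KCP_GKA, KCP_GKST, \
    KCP_ENA, KCP_EK = range(10)
# per-gate triplets (Vhalf, slope, tau) appended in this order:
# m, h (fast Na); p, q (slow Na); n (K-DR); a, b (K-A); c, d (K-ST)
KCP_GATES = 10
N_GATES = 9
KCP_LEN = KCP_GATES + 3 * N_GATES


@njit(cache=True, inline="always")
def _hines_solve(parent, gax, diag, rhs, v, clamped, clamp_v):
    """Solve the tree-tridiagonal system in place; result in ``v``."""
    n = parent.shape[0]
    for i in range(n - 1, 0, -1):
        p = parent[i]
        if clamped[i]:
            rhs[p] += gax[i] * clamp_v[i]
        else:
            f = gax[i] / diag[i]
            diag[p] -= gax[i] * f
            rhs[p] += rhs[i] * f
    if clamped[0]:
        v[0] = clamp_v[0]
    else:
        v[0] = rhs[0] / diag[0]
    for i in range(1, n):
        if clamped[i]:
            v[i] = clamp_v[i]
        else:
            v[i] = (rhs[i] + gax[i] * v[parent[i]]) / diag[i]


@njit(cache=True)
def passive_transient(parent, gax, gleak, cap, diag_static, e_rest, dt, n_steps,
                      clamp_idx, clamp_wave, inj_idx, inj_wave,
                      syn_idx, syn_wave, syn_e, rec_idx, v0):
    """Backward-Euler transient of a passive tree.

    ``diag_static`` must hold gleak + gax[i] + sum_children gax (no C/dt term).
    Waveforms are (k, n_steps) arrays.  Returns recorded voltages with the
    initial state in column 0, shape (len(rec_idx), n_steps + 1).
    """
    n = parent.shape[0]
    v = v0.copy()
    out = np.empty((rec_idx.shape[0], n_steps + 1))
    for r in range(rec_idx.shape[0]):
        out[r, 0] = v[rec_idx[r]]
    clamped = np.zeros(n, dtype=np.bool_)
    for k in range(clamp_idx.shape[0]):
        clamped[clamp_idx[k]] = True
    clamp_v = np.zeros(n)
    diag = np.empty(n)
    rhs = np.empty(n)
    cdt = cap / dt
    for t in range(n_steps):
        for i in range(n):
            diag[i] = diag_static[i] + cdt[i]
            rhs[i] = cdt[i] * v[i] + gleak[i] * e_rest
        for k in range(syn_idx.shape[0]):
            i = syn_idx[k]
            g = syn_wave[k, t]
            diag[i] += g
            rhs[i] += g * syn_e[k]
        for k in range(inj_idx.shape[0]):
            rhs[inj_idx[k]] += inj_wave[k, t]
        for k in range(clamp_idx.shape[0]):
            clamp_v[clamp_idx[k]] = clamp_wave[k, t]
        _hines_solve(parent, gax, diag, rhs, v, clamped, clamp_v)
        for r in range(rec_idx.shape[0]):
            out[r, t + 1] = v[rec_idx[r]]
    return out


# ---------------------------------------------------------------------------
# KC Hodgkin-Huxley update
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _gate_step(x, v, vh, k, tau, dt):
    xinf = 1.0 / (1.0 + np.exp((vh - v) / k))
    return xinf + (x - xinf) * np.exp(-dt / tau)


@njit(cache=True, inline="always")
def _kc_cell_step(v, g9, g_exc, e_exc, g_inh, e_inh, i_inj, dt, kcp):
    """Advance one KC by dt: exponential-Euler gates, implicit voltage."""
    for j in range(N_GATES):
        base = KCP_GATES + 3 * j
        g9[j] = _gate_step(g9[j], v, kcp[base], kcp[base + 1], kcp[base + 2], dt)
    g_naf = kcp[KCP_GNAF] * g9[0] ** 3 * g9[1]
    g_nas = kcp[KCP_GNAS] * g9[2] ** 3 * g9[3]
    g_kdr = kcp[KCP_GKDR] * g9[4] ** 4
    g_ka = kcp[KCP_GKA] * g9[5] ** 3 * g9[6]
    g_kst = kcp[KCP_GKST] * g9[7] ** 3 * g9[8]
    g_na = g_naf + g_nas
    g_k = g_kdr + g_ka + g_kst
    cdt = kcp[KCP_C] / dt
    num = (cdt * v + kcp[KCP_GL] * kcp[KCP_EL] + g_na * kcp[KCP_ENA]
           + g_k * kcp[KCP_EK] + g_exc * e_exc + g_inh * e_inh + i_inj)
    den = cdt + kcp[KCP_GL] + g_na + g_k + g_exc + g_inh
    return num / den


@njit(cache=True)
def kc_simulate(kcp, v0, gates0, dt, n_steps, i_inj, syn_g, syn_e):
    """Single-compartment KC driven by current and conductance waveforms.

    ``i_inj``: (n_steps,) nA; ``syn_g``: (k, n_steps) uS with reversals
    ``syn_e``.  Returns the voltage trace (n_steps + 1,).
    """
    v = v0
    g9 = gates0.copy()
    out = np.empty(n_steps + 1)
    out[0] = v
    for t in range(n_steps):
        g_exc = 0.0
        g_exc_drive = 0.0
        g_inh = 0.0
        g_inh_drive = 0.0
        for k in range(syn_g.shape[0]):
            g = syn_g[k, t]
            if syn_e[k] > -30.0:
                g_exc += g
                g_exc_drive += g * syn_e[k]
            else:
                g_inh += g
                g_inh_drive += g * syn_e[k]
        e_exc = g_exc_drive / g_exc if g_exc > 0 else 0.0
        e_inh = g_inh_drive / g_inh if g_inh > 0 else -80.0
        v = _kc_cell_step(v, g9, g_exc, e_exc, g_inh, e_inh, i_inj[t], dt, kcp)
        out[t + 1] = v
    return out


@njit(cache=True)
def kc_steady_gates(kcp, v):
    g9 = np.empty(N_GATES)
    for j in range(N_GATES):
        base = KCP_GATES + 3 * j
        g9[j] = 1.0 / (1.0 + np.exp((kcp[base] - v) / kcp[base + 1]))
    return g9


# ---------------------------------------------------------------------------
# Full-network co-simulation
# ---------------------------------------------------------------------------

@njit(cache=True)
def network_sim(
    n_steps, dt, ds,
    # GGN cable (Hines order)
    parent, gax, gleak, cap, diag_static, e_rest,
    # KC->GGN double-exponential synapse kinetics (E_rev 0 mV)
    fd_exc, fr_exc, norm_exc,
    # KC population
    kcp, kc_v, kc_gates, kc_alive,
    # PN->KC spike-arrival events sorted by step
    ev_step, ev_kc, ev_w,
    fd_pn, fr_pn, norm_pn,
    # GGN->KC graded inhibition
    kc_comp, kc_gbar, gr_vhalf, gr_slope, gr_tau, e_inh,
    # KC->GGN wiring
    kc_target, kc_w,
    # aggregate-kernel mode (single-KC experiment); empty kernel disables.
    # the smeared conductance is split evenly over ``agg_comps`` so no single
    # thin neurite saturates on its axial conductance
    agg_kernel, agg_comps,
    # current injection into every KC (nA)
    i_kc,
    # IG (0: absent, 1: reciprocal, 2: +KC drive, 3: +PN drive)
    ig_mode, ig_a, ig_b, ig_c, ig_d, ig_ibase, ig_comp,
    fd_ig2ggn, fr_ig2ggn, norm_ig2ggn, w_ig2ggn,
    ggn_ig_gbar, ig_gr_tau,
    kc_ig_delay_steps, kc_ig_w, pn_ig_inc,
    fd_igsyn, fr_igsyn, norm_igsyn,
    # recording
    rec_comp, win0, win1,
    spk_t, spk_kc,
):
    """Coupled PN->KC->GGN(->IG) simulation; returns (n_spikes, records...).

    Coupling is staggered by one step: KCs read the GGN compartment voltages
    of the previous step through their graded synapses, then GGN is advanced
    with the KC spikes just emitted.
    """
    n_comp = parent.shape[0]
    n_kc = kc_v.shape[0]
    n_rec = n_steps // ds + 1
    ggn_rec = np.empty(n_rec)
    ig_rec = np.zeros(n_rec)
    comp_vsum = np.zeros(n_comp)
    kc_vsum = np.zeros(n_kc)
    n_win = 0

    v = np.full(n_comp, e_rest)
    a_exc = np.zeros(n_comp)
    b_exc = np.zeros(n_comp)
    diag = np.empty(n_comp)
    rhs = np.empty(n_comp)
    clamped = np.zeros(n_comp, dtype=np.bool_)
    clamp_v = np.zeros(n_comp)

    # KC synaptic state
    kc_ae = np.zeros(n_kc)
    kc_be = np.zeros(n_kc)
    kc_s = np.full(n_kc, 1.0 / (1.0 + np.exp((gr_vhalf - e_rest) / gr_slope)))
    refrac = np.zeros(n_kc, dtype=np.int64)
    refrac_steps = int(2.0 / dt)
    gr_decay = np.exp(-dt / gr_tau)

    # aggregate-kernel ring buffer
    klen = agg_kernel.shape[0]
    g_ring = np.zeros(max(klen, 1))
    ring_pos = 0

    # IG state
    ig_v = -65.0
    ig_u = ig_b * ig_v
    a_ig2ggn = 0.0
    b_ig2ggn = 0.0
    ig_s = 1.0 / (1.0 + np.exp((gr_vhalf - e_rest) / gr_slope))
    a_igsyn = 0.0
    b_igsyn = 0.0
    ig_ring = np.zeros(max(kc_ig_delay_steps + 1, 1))
    ig_pos = 0
    ig_gr_decay = np.exp(-dt / ig_gr_tau)

    max_spikes = spk_t.shape[0]
    n_spk = 0
    ev_ptr = 0
    n_ev = ev_step.shape[0]

    ggn_rec[0] = v[rec_comp]
    ig_rec[0] = ig_v

    for t in range(n_steps):
        # ---- KC population (reads GGN voltages from previous step) -------
        for k in range(n_kc):
            kc_ae[k] *= fd_pn
            kc_be[k] *= fr_pn
        while ev_ptr < n_ev and ev_step[ev_ptr] == t:
            k = ev_kc[ev_ptr]
            w = ev_w[ev_ptr] * norm_pn
            kc_ae[k] += w
            kc_be[k] += w
            ev_ptr += 1
        for k in range(n_kc):
            if not kc_alive[k]:
                continue
            vpre = v[kc_comp[k]]
            sinf = 1.0 / (1.0 + np.exp((gr_vhalf - vpre) / gr_slope))
            kc_s[k] = sinf + (kc_s[k] - sinf) * gr_decay
            g_exc = kc_ae[k] - kc_be[k]
            g_inh = kc_gbar[k] * kc_s[k]
            vold = kc_v[k]
            vnew = _kc_cell_step(vold, kc_gates[k], g_exc, 0.0, g_inh, e_inh,
                                 i_kc[t], dt, kcp)
            kc_v[k] = vnew
            if refrac[k] > 0:
                refrac[k] -= 1
            elif vold < 0.0 <= vnew:
                refrac[k] = refrac_steps
                if n_spk < max_spikes:
                    spk_t[n_spk] = t * dt
                    spk_kc[n_spk] = k
                    n_spk += 1
                if klen > 0:
                    for j in range(klen):
                        g_ring[(ring_pos + j) % klen] += agg_kernel[j]
                else:
                    w = kc_w[k] * norm_exc
                    a_exc[kc_target[k]] += w
                    b_exc[kc_target[k]] += w
                if ig_mode >= 2:
                    ig_ring[(ig_pos + kc_ig_delay_steps) % ig_ring.shape[0]] += kc_ig_w[k]

        # ---- IG (reads GGN voltage from previous step) -------------------
        ig_spiked = False
        if ig_mode >= 1:
            a_igsyn *= fd_igsyn
            b_igsyn *= fr_igsyn
            inc = ig_ring[ig_pos] * norm_igsyn
            ig_ring[ig_pos] = 0.0
            ig_pos = (ig_pos + 1) % ig_ring.shape[0]
            if ig_mode == 3 and pn_ig_inc.shape[0] > 0:
                inc += pn_ig_inc[t] * norm_igsyn
            a_igsyn += inc
            b_igsyn += inc
            vpre = v[ig_comp]
            sinf = 1.0 / (1.0 + np.exp((gr_vhalf - vpre) / gr_slope))
            ig_s = sinf + (ig_s - sinf) * ig_gr_decay
            g_exc_ig = a_igsyn - b_igsyn
            # conductance-based currents in Izhikevich units (dimensionless g)
            i_syn = g_exc_ig * (0.0 - ig_v) + ggn_ig_gbar * ig_s * (-80.0 - ig_v)
            dv = 0.04 * ig_v * ig_v + 5.0 * ig_v + 140.0 - ig_u + ig_ibase + i_syn
            ig_v += dt * dv
            ig_u += dt * ig_a * (ig_b * ig_v - ig_u)
            if ig_v >= 30.0:
                ig_v = ig_c
                ig_u += ig_d
                ig_spiked = True
                w = w_ig2ggn * norm_ig2ggn
                a_ig2ggn += w
                b_ig2ggn += w

        # ---- GGN cable ---------------------------------------------------
        for i in range(n_comp):
            a_exc[i] *= fd_exc
            b_exc[i] *= fr_exc
        a_ig2ggn *= fd_ig2ggn
        b_ig2ggn *= fr_ig2ggn
        cdt_scale = 1.0 / dt
        for i in range(n_comp):
            g_syn = a_exc[i] - b_exc[i]
            diag[i] = diag_static[i] + cap[i] * cdt_scale + g_syn
            rhs[i] = cap[i] * cdt_scale * v[i] + gleak[i] * e_rest
            # excitatory reversal 0 mV: no rhs contribution
        if klen > 0:
            g = g_ring[ring_pos] / agg_comps.shape[0]
            g_ring[ring_pos] = 0.0
            # ring slot is consumed this step; kernel values are total
            # conductances (uS) sampled at dt, split across the target set
            for j in range(agg_comps.shape[0]):
                diag[agg_comps[j]] += g
            ring_pos = (ring_pos + 1) % klen
        if ig_mode >= 1:
            g = a_ig2ggn - b_ig2ggn
            diag[ig_comp] += g
            rhs[ig_comp] += g * (-80.0)
        _hines_solve(parent, gax, diag, rhs, v, clamped, clamp_v)

        # ---- recording ---------------------------------------------------
        if (t + 1) % ds == 0:
            ggn_rec[(t + 1) // ds] = v[rec_comp]
            ig_rec[(t + 1) // ds] = ig_v
        if win0 <= t < win1:
            n_win += 1
            for i in range(n_comp):
                comp_vsum[i] += v[i]
            for k in range(n_kc):
                kc_vsum[k] += kc_v[k]

    if n_win > 0:
        for i in range(n_comp):
            comp_vsum[i] /= n_win
        for k in range(n_kc):
            kc_vsum[k] /= n_win
    return n_spk, ggn_rec, ig_rec, comp_vsum, kc_vsum
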