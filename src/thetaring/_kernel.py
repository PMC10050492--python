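"""Compiled integration core.

The network is advanced with Heun's method (explicit trapezoidal RK2) at a
fixed step, with spike-delta increments applied at step boundaries and the
Ornstein-Uhlenbeck noise held constant within each step.

The expensive quantities are the weighted gating sums

    A = W_EI @ S_NMDA,   B = W_IE @ S_GABA,   C = W_II @ S_GABA

(dense mat-vecs every step would dominate the run time).  Between spikes
the gating variables obey linear ODEs, so each sum can be advanced by the
same Heun update applied directly to the sum: a scalar decay factor per
step, plus

* rank-one column additions when a presynaptic neuron spikes (GABA), and
* a sparse correction restricted to the set of principal cells with a
  non-negligible intermediate gating variable x (the only place the NMDA
  ODE couples nonlinearly).

This reproduces the dense Heun arithmetic exactly up to float round-off;
the sums are additionally recomputed densely every ``REFRESH_EVERY`` steps
so round-off cannot accumulate over long runs.  A plain dense NumPy
implementation of the same scheme lives in :mod:`thetaring.dynamics` and
the two are compared in the test suite.

The integration is driven in chunks: the Python wrapper pre-generates the
OU noise innovations for each chunk in bulk (NumPy bit generators are much
faster than drawing normals one by one inside compiled code) and calls
:func:`run_chunk`, which mutates the state arrays in place.  Integer /
float side registers carry the scalar state across chunk calls.
"""
from __future__ import annotations

import numpy as np
from numba import njit

# x below this is dynamically indistinguishable from zero and its carrier
# is dropped from the active set (x is forced to exactly 0 so the
# elementwise state stays consistent with the recurrence-tracked sums)
X_FLOOR = 1e-14
REFRESH_EVERY = 25000  # steps between dense recomputations of the sums

ERR_OK = 0
ERR_NAN = 1
ERR_SPIKE_OVERFLOW = 2

# integer register layout
R_N_ACTIVE = 0
R_N_SPIKES = 1
R_N_SPK_E = 2
R_N_SPK_I = 3
R_SAMPLE = 4
R_ERR = 5
# float register layout
F_C_UNI = 0


@njit(cache=True, inline="always")
def _mg_block(v, mg):
    return 1.0 / (1.0 + mg * np.exp(-0.062 * v) / 3.57)


@njit(cache=True)
def run_chunk(
    step0, n_sub, dt, record_every,
    # LIF constants (C_m in pF so that pA / pF = mV / ms)
    cm_e, gl_e, vl_e, vth_e, vreset_e, ref_steps_e,
    cm_i, gl_i, vl_i, vth_i, vreset_i, ref_steps_i,
    # synapses
    g_nmda_ei, g_gaba_ie, g_gaba_ii, g_nmda_ee, g_ampa_ei,
    v_exc, v_inh, mg,
    tau_nmda, alpha_nmda, tau_x, tau_gaba, tau_ampa, ampa_fraction,
    # weights (dense + transposed for contiguous column access)
    w_ei, w_ei_t, w_ie, w_ie_t, w_ii_uniform, w_ii, w_ii_t,
    ee_on, w_ee, w_ee_t,
    # external input
    i_back_e, i_back_i, i_ms0, a_ms, f_ms,
    noise_on, alpha_ou, innov_e, innov_i,
    poisson_on, pois_rate_e, pois_rate_i, pois_rate_ms,
    j_pois_e, j_pois_i, j_pois_ms,
    cue_current_e, cue_t_off, supp_current_i,
    # mutable state
    v_e, v_i, s_n, x, s_a, s_g, ref_e, ref_i, noise_e, noise_i,
    y_e, y_i_exc, y_i_ms,
    a_sum, b_sum, c_vec, ba_sum, aee_sum,
    active, is_active, spk_e, spk_i,
    # spike / trace output
    spike_pop, spike_idx, spike_t,
    igaba_e_rec, record_igaba, mean_rec, vm_e_rec, vm_i_rec, sn_range_rec,
    rec_vm_e_idx, rec_vm_i_idx,
    # scalar registers
    regs_i, regs_f,
):
    n_e = v_e.shape[0]
    n_i = v_i.shape[0]
    spike_cap = spike_pop.shape[0]

    n_active = regs_i[R_N_ACTIVE]
    n_spikes = regs_i[R_N_SPIKES]
    n_spk_e = regs_i[R_N_SPK_E]
    n_spk_i = regs_i[R_N_SPK_I]
    sample = regs_i[R_SAMPLE]
    c_uni = regs_f[F_C_UNI]

    # Heun factors for the linear decays
    r_n = dt / tau_nmda
    lam_n_half = 1.0 - r_n
    lam_n_full = 1.0 - r_n + 0.5 * r_n * r_n
    r_x = dt / tau_x
    lam_x_half = 1.0 - r_x
    lam_x_full = 1.0 - r_x + 0.5 * r_x * r_x
    r_g = dt / tau_gaba
    lam_g_half = 1.0 - r_g
    lam_g_full = 1.0 - r_g + 0.5 * r_g * r_g
    r_a = dt / tau_ampa
    lam_a_half = 1.0 - r_a
    lam_a_full = 1.0 - r_a + 0.5 * r_a * r_a

    g_ei_nmda_eff = g_nmda_ei * (1.0 - ampa_fraction)
    g_ei_ampa_eff = g_ampa_ei * ampa_fraction
    two_pi_f = 2.0 * np.pi * f_ms * 1e-3  # rad per ms
    # A' = A(1 - r + r^2/2) + (dt a/2)(1 - r) P1 + (dt a/2) P2, from Heun on
    # dS/dt = -S/tau + a x(1-S) applied to the weighted sum
    dt_al = dt * alpha_nmda
    coef_p1 = 0.5 * dt_al * (1.0 - r_n)
    coef_p2 = 0.5 * dt_al
    lam_pois_exc = np.exp(-dt / tau_ampa)
    lam_pois_inh = np.exp(-dt / tau_gaba)

    p1 = np.zeros(n_i)
    p2 = np.zeros(n_i)
    p1_ee = np.zeros(n_e)
    p2_ee = np.zeros(n_e)
    sn_new_active = np.zeros(n_e)

    for sub in range(n_sub):
        step = step0 + sub
        t1 = step * dt
        t2 = t1 + dt

        # ---- 1. apply pending spike increments to gating -------------------
        for k in range(n_spk_e):
            j = spk_e[k]
            x[j] += 1.0
            if not is_active[j]:
                is_active[j] = True
                active[n_active] = j
                n_active += 1
            if ampa_fraction > 0.0:
                s_a[j] += 1.0
                col = w_ei_t[j]
                for i in range(n_i):
                    ba_sum[i] += col[i]
        for k in range(n_spk_i):
            j = spk_i[k]
            s_g[j] += 1.0
            col = w_ie_t[j]
            for i in range(n_e):
                b_sum[i] += col[i]
            if w_ii_uniform:
                c_uni += 1.0
            else:
                col2 = w_ii_t[j]
                for i in range(n_i):
                    c_vec[i] += col2[i]
        n_spk_e = 0
        n_spk_i = 0

        # ---- 2. external input update (held constant within the step) ------
        if noise_on:
            for i in range(n_e):
                noise_e[i] = alpha_ou * noise_e[i] + innov_e[sub, i]
            for i in range(n_i):
                noise_i[i] = alpha_ou * noise_i[i] + innov_i[sub, i]
        if poisson_on:
            lam_e_step = pois_rate_e * 1e-3 * dt
            lam_i_step = pois_rate_i * 1e-3 * dt
            lam_ms_step = pois_rate_ms * 1e-3 * dt
            for i in range(n_e):
                y_e[i] = lam_pois_exc * y_e[i] \
                    + j_pois_e * np.random.poisson(lam_e_step)
            for i in range(n_i):
                y_i_exc[i] = lam_pois_exc * y_i_exc[i] \
                    + j_pois_i * np.random.poisson(lam_i_step)
                y_i_ms[i] = lam_pois_inh * y_i_ms[i] \
                    + j_pois_ms * np.random.poisson(lam_ms_step)

        # ---- 3. NMDA sparse corrections (stage values of the sums) ---------
        for i in range(n_i):
            p1[i] = 0.0
            p2[i] = 0.0
        if ee_on:
            for i in range(n_e):
                p1_ee[i] = 0.0
                p2_ee[i] = 0.0
        for k in range(n_active):
            j = active[k]
            xj = x[j]
            snj = s_n[j]
            u1 = xj * (1.0 - snj)
            d1 = -snj / tau_nmda + alpha_nmda * u1
            s2 = snj + dt * d1
            x2 = xj * lam_x_half
            u2 = x2 * (1.0 - s2)
            d2 = -s2 / tau_nmda + alpha_nmda * u2
            sn_new_active[j] = snj + 0.5 * dt * (d1 + d2)
            col = w_ei_t[j]
            for i in range(n_i):
                p1[i] += col[i] * u1
                p2[i] += col[i] * u2
            if ee_on:
                cole = w_ee_t[j]
                for i in range(n_e):
                    p1_ee[i] += cole[i] * u1
                    p2_ee[i] += cole[i] * u2

        # ---- 4. membrane stages --------------------------------------------
        if f_ms > 0.0:
            ms1 = i_ms0 + a_ms * np.cos(two_pi_f * t1)
            ms2 = i_ms0 + a_ms * np.cos(two_pi_f * t2)
        else:
            ms1 = i_ms0 + a_ms
            ms2 = ms1
        cue1_on = t1 < cue_t_off
        cue2_on = t2 < cue_t_off

        # principal cells
        for i in range(n_e):
            if ref_e[i] > 0:
                continue
            v = v_e[i]
            iext1 = noise_e[i]
            if poisson_on:
                iext1 += y_e[i]
            else:
                iext1 += i_back_e
            if cue1_on:
                iext1 += cue_current_e[i]
            isyn1 = g_gaba_ie * (v - v_inh) * b_sum[i]
            if ee_on:
                isyn1 += g_nmda_ee * (v - v_exc) * _mg_block(v, mg) * aee_sum[i]
            dv1 = (-gl_e * (v - vl_e) - isyn1 + iext1) / cm_e
            vm = v + dt * dv1
            iext2 = iext1 if cue2_on == cue1_on else iext1 \
                - cue_current_e[i] * (1.0 if cue1_on else -1.0)
            b2 = b_sum[i] * lam_g_half
            isyn2 = g_gaba_ie * (vm - v_inh) * b2
            if ee_on:
                aee2 = aee_sum[i] * lam_n_half + dt_al * p1_ee[i]
                isyn2 += g_nmda_ee * (vm - v_exc) * _mg_block(vm, mg) * aee2
            dv2 = (-gl_e * (vm - vl_e) - isyn2 + iext2) / cm_e
            v_e[i] = v + 0.5 * dt * (dv1 + dv2)

        # interneurons
        for i in range(n_i):
            if ref_i[i] > 0:
                continue
            v = v_i[i]
            iext1 = noise_i[i] + supp_current_i[i]
            iext2 = iext1
            if poisson_on:
                iext1 += y_i_exc[i] + y_i_ms[i]
                iext2 = iext1
            else:
                iext1 += i_back_i + ms1
                iext2 += i_back_i + ms2
            c1 = c_uni if w_ii_uniform else c_vec[i]
            isyn1 = g_ei_nmda_eff * (v - v_exc) * _mg_block(v, mg) * a_sum[i] \
                + g_gaba_ii * (v - v_inh) * c1
            if ampa_fraction > 0.0:
                isyn1 += g_ei_ampa_eff * (v - v_exc) * ba_sum[i]
            dv1 = (-gl_i * (v - vl_i) - isyn1 + iext1) / cm_i
            vm = v + dt * dv1
            a2 = a_sum[i] * lam_n_half + dt_al * p1[i]
            c2 = c1 * lam_g_half
            isyn2 = g_ei_nmda_eff * (vm - v_exc) * _mg_block(vm, mg) * a2 \
                + g_gaba_ii * (vm - v_inh) * c2
            if ampa_fraction > 0.0:
                isyn2 += g_ei_ampa_eff * (vm - v_exc) * ba_sum[i] * lam_a_half
            dv2 = (-gl_i * (vm - vl_i) - isyn2 + iext2) / cm_i
            v_i[i] = v + 0.5 * dt * (dv1 + dv2)

        # ---- 5. advance gating and the tracked sums ------------------------
        for i in range(n_e):
            s_n[i] *= lam_n_full
            x[i] *= lam_x_full
        for k in range(n_active):
            j = active[k]
            s_n[j] = sn_new_active[j]
        if ampa_fraction > 0.0:
            for i in range(n_e):
                s_a[i] *= lam_a_full
            for i in range(n_i):
                ba_sum[i] *= lam_a_full
        for i in range(n_i):
            s_g[i] *= lam_g_full
        for i in range(n_e):
            b_sum[i] *= lam_g_full
        if w_ii_uniform:
            c_uni *= lam_g_full
        else:
            for i in range(n_i):
                c_vec[i] *= lam_g_full
        for i in range(n_i):
            a_sum[i] = a_sum[i] * lam_n_full + coef_p1 * p1[i] + coef_p2 * p2[i]
        if ee_on:
            for i in range(n_e):
                aee_sum[i] = aee_sum[i] * lam_n_full \
                    + coef_p1 * p1_ee[i] + coef_p2 * p2_ee[i]

        # prune the active set
        k = 0
        while k < n_active:
            j = active[k]
            if x[j] < X_FLOOR:
                x[j] = 0.0
                is_active[j] = False
                n_active -= 1
                active[k] = active[n_active]
            else:
                k += 1

        # ---- 6. threshold, reset, refractory -------------------------------
        for i in range(n_e):
            if ref_e[i] > 0:
                ref_e[i] -= 1
                continue
            if v_e[i] >= vth_e:
                if n_spikes >= spike_cap:
                    regs_i[R_ERR] = ERR_SPIKE_OVERFLOW
                    regs_i[R_N_SPIKES] = n_spikes
                    return
                spike_pop[n_spikes] = 0
                spike_idx[n_spikes] = i
                spike_t[n_spikes] = t2
                n_spikes += 1
                spk_e[n_spk_e] = i
                n_spk_e += 1
                v_e[i] = vreset_e
                ref_e[i] = ref_steps_e
        for i in range(n_i):
            if ref_i[i] > 0:
                ref_i[i] -= 1
                continue
            if v_i[i] >= vth_i:
                if n_spikes >= spike_cap:
                    regs_i[R_ERR] = ERR_SPIKE_OVERFLOW
                    regs_i[R_N_SPIKES] = n_spikes
                    return
                spike_pop[n_spikes] = 1
                spike_idx[n_spikes] = i
                spike_t[n_spikes] = t2
                n_spikes += 1
                spk_i[n_spk_i] = i
                n_spk_i += 1
                v_i[i] = vreset_i
                ref_i[i] = ref_steps_i

        # ---- 7. periodic dense refresh of the tracked sums -----------------
        if (step + 1) % REFRESH_EVERY == 0:
            tmp = np.dot(w_ei, s_n)
            for i in range(n_i):
                a_sum[i] = tmp[i]
            tmpb = np.dot(w_ie, s_g)
            for i in range(n_e):
                b_sum[i] = tmpb[i]
            if w_ii_uniform:
                c_uni = s_g.sum()
            else:
                tmpc = np.dot(w_ii, s_g)
                for i in range(n_i):
                    c_vec[i] = tmpc[i]
            if ampa_fraction > 0.0:
                tmpa = np.dot(w_ei, s_a)
                for i in range(n_i):
                    ba_sum[i] = tmpa[i]
            if ee_on:
                tmpe = np.dot(w_ee, s_n)
                for i in range(n_e):
                    aee_sum[i] = tmpe[i]

        # ---- 8. recording ---------------------------------------------------
        if (step + 1) % record_every == 0:
            ok = True
            for i in range(n_e):
                if not np.isfinite(v_e[i]):
                    ok = False
            for i in range(n_i):
                if not np.isfinite(v_i[i]):
                    ok = False
            if not ok:
                regs_i[R_ERR] = ERR_NAN
                regs_i[R_N_SPIKES] = n_spikes
                return
            ig_sum = 0.0
            itot_e = 0.0
            iext_e_sum = 0.0
            for i in range(n_e):
                ig = g_gaba_ie * (v_e[i] - v_inh) * b_sum[i]
                ig_sum += ig
                if record_igaba:
                    igaba_e_rec[sample, i] = ig
                ie = noise_e[i]
                if poisson_on:
                    ie += y_e[i]
                else:
                    ie += i_back_e
                if t2 < cue_t_off:
                    ie += cue_current_e[i]
                iext_e_sum += ie
                itot_e += -gl_e * (v_e[i] - vl_e) - ig + ie
            inm_sum = 0.0
            igii_sum = 0.0
            iext_i_sum = 0.0
            itot_i = 0.0
            if f_ms > 0.0:
                ms_now = i_ms0 + a_ms * np.cos(two_pi_f * t2)
            else:
                ms_now = i_ms0 + a_ms
            for i in range(n_i):
                inm = g_ei_nmda_eff * (v_i[i] - v_exc) \
                    * _mg_block(v_i[i], mg) * a_sum[i]
                if ampa_fraction > 0.0:
                    inm += g_ei_ampa_eff * (v_i[i] - v_exc) * ba_sum[i]
                c1 = c_uni if w_ii_uniform else c_vec[i]
                igii = g_gaba_ii * (v_i[i] - v_inh) * c1
                inm_sum += inm
                igii_sum += igii
                ie = noise_i[i] + supp_current_i[i]
                if poisson_on:
                    ie += y_i_exc[i] + y_i_ms[i]
                else:
                    ie += i_back_i + ms_now
                iext_i_sum += ie
                itot_i += -gl_i * (v_i[i] - vl_i) - inm - igii + ie
            mean_rec[sample, 0] = inm_sum / n_i
            mean_rec[sample, 1] = ig_sum / n_e
            mean_rec[sample, 2] = igii_sum / n_i
            mean_rec[sample, 3] = iext_e_sum / n_e
            mean_rec[sample, 4] = iext_i_sum / n_i
            mean_rec[sample, 5] = itot_e / n_e
            mean_rec[sample, 6] = itot_i / n_i
            mean_rec[sample, 7] = ms_now
            for k in range(rec_vm_e_idx.shape[0]):
                vm_e_rec[sample, k] = v_e[rec_vm_e_idx[k]]
            for k in range(rec_vm_i_idx.shape[0]):
                vm_i_rec[sample, k] = v_i[rec_vm_i_idx[k]]
            smin = 1.0
            smax = 0.0
            for i in range(n_e):
                if s_n[i] < smin:
                    smin = s_n[i]
                if s_n[i] > smax:
                    smax = s_n[i]
            sn_range_rec[sample, 0] = smin
            sn_range_rec[sample, 1] = smax
            sample += 1

    regs_i[R_N_ACTIVE] = n_active
    regs_i[R_N_SPIKES] = n_spikes
    regs_i[R_N_SPK_E] = n_spk_e
    regs_i[R_N_SPK_I] = n_spk_i
    regs_i[R_SAMPLE] = sample
    regs_i[R_ERR] = ERR_OK
    regs_f[F_C_UNI] = c_uni


@njit(cache=True)
def seed_rng(seed):
    """Seed the compiled code's RNG (Poisson input variant)."""
    np.random.seed(seed)
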