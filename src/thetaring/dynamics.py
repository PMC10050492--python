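"""Network dynamics: LIF membranes, synaptic gating, external drive.

Two integration paths share one scheme (Heun / explicit-trapezoid RK2 on
the smooth ODEs, spike deltas at step boundaries, OU noise frozen within a
step):

* :func:`run_trial` — the production path, a compiled kernel that advances
  the weighted gating sums by exact linear recurrences (see
  :mod:`thetaring._kernel`);
* :func:`rk2_step` / :func:`run_trial_reference` — a transparent dense
  NumPy implementation of the same arithmetic, used as the oracle in
  equivalence tests and for small networks.

Conventions: a spike is detected when the post-step membrane potential
reaches threshold and is stamped with the end-of-step time; it increments
presynaptic gating at the start of the next step; a refractory neuron sits
at the reset potential while its gating continues to evolve.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernel
from .connectivity import (ConnectivityMatrices, RingGeometry,
                           angular_difference, build_connectivity)
from .params import (ExternalInputParams, ModelParameters, Protocol,
                     SynapseParams)
from .results import POP_E, POP_I, SimulationResult

__all__ = [
    "NetworkState",
    "mg_block_factor",
    "synaptic_currents",
    "gating_step",
    "ou_noise_update",
    "external_currents",
    "rk2_step",
    "run_trial",
    "run_trial_reference",
]


def mg_block_factor(v_m, mg: float = 1.0):
    """Voltage dependence of the NMDA conductance under Mg2+ block.

    ``1 / (1 + [Mg] exp(-0.062 V) / 3.57)`` — approaches 1 at depolarized
    potentials and suppresses the current near rest (about 0.08 at -60 mV
    with 1 mM Mg2+); monotonically increasing in V.
    """
    return 1.0 / (1.0 + mg * np.exp(-0.062 * np.asarray(v_m, float)) / 3.57)


@dataclass
class NetworkState:
    """Full dynamical state of the network at one time point."""

    v_e: np.ndarray
    v_i: np.ndarray
    s_nmda: np.ndarray  # NMDA gating per principal cell, in [0, 1]
    x: np.ndarray       # NMDA intermediate gating per principal cell
    s_gaba: np.ndarray  # GABA gating per interneuron
    s_ampa: np.ndarray  # AMPA gating per principal cell (variant)
    ref_e: np.ndarray   # refractory steps remaining, int
    ref_i: np.ndarray
    noise_e: np.ndarray  # OU noise current, pA
    noise_i: np.ndarray
    t: float = 0.0  # ms
    # spikes fired on the previous step, pending application to gating
    pending_e: np.ndarray = field(default=None)  # type: ignore[assignment]
    pending_i: np.ndarray = field(default=None)  # type: ignore[assignment]

    @classmethod
    def initial(cls, model: ModelParameters, v0_e, v0_i) -> "NetworkState":
        n_e, n_i = model.n_e, model.n_i
        return cls(
            v_e=np.asarray(v0_e, float).copy(),
            v_i=np.asarray(v0_i, float).copy(),
            s_nmda=np.zeros(n_e), x=np.zeros(n_e), s_gaba=np.zeros(n_i),
            s_ampa=np.zeros(n_e),
            ref_e=np.zeros(n_e, int), ref_i=np.zeros(n_i, int),
            noise_e=np.zeros(n_e), noise_i=np.zeros(n_i),
            pending_e=np.zeros(n_e, bool), pending_i=np.zeros(n_i, bool),
        )


def synaptic_currents(state: NetworkState, mats: ConnectivityMatrices,
                      p: SynapseParams) -> dict[str, np.ndarray]:
    """Per-neuron recurrent synaptic currents (pA) in the present state.

    Sign convention: currents enter the membrane equation with a minus
    sign, so positive values hyperpolarize.  Returns the components and the
    per-population totals ``i_syn_e`` / ``i_syn_i``.
    """
    if mats.w_ei.shape != (state.v_i.size, state.v_e.size):
        raise ValueError("state / connectivity dimension mismatch")
    i_gaba_e = p.g_gaba_ie * (state.v_e - p.v_inh) * (mats.w_ie @ state.s_gaba)
    i_nmda_i = (p.g_nmda_ei * (1.0 - p.ampa_fraction)
                * (state.v_i - p.v_exc) * mg_block_factor(state.v_i, p.mg)
                * (mats.w_ei @ state.s_nmda))
    i_gaba_i = p.g_gaba_ii * (state.v_i - p.v_inh) * (mats.w_ii @ state.s_gaba)
    out = {
        "i_gaba_e": i_gaba_e,
        "i_nmda_i": i_nmda_i,
        "i_gaba_i": i_gaba_i,
    }
    i_syn_e = i_gaba_e.copy()
    i_syn_i = i_nmda_i + i_gaba_i
    if p.ampa_fraction > 0.0:
        i_ampa_i = (p.g_ampa_ei * p.ampa_fraction * (state.v_i - p.v_exc)
                    * (mats.w_ei @ state.s_ampa))
        out["i_ampa_i"] = i_ampa_i
        i_syn_i = i_syn_i + i_ampa_i
    if mats.w_ee is not None and p.g_nmda_ee > 0.0:
        i_nmda_e = (p.g_nmda_ee * (state.v_e - p.v_exc)
                    * mg_block_factor(state.v_e, p.mg)
                    * (mats.w_ee @ state.s_nmda))
        out["i_nmda_e"] = i_nmda_e
        i_syn_e = i_syn_e + i_nmda_e
    out["i_syn_e"] = i_syn_e
    out["i_syn_i"] = i_syn_i
    return out


def _gating_derivs(s_nmda, x, s_gaba, s_ampa, p: SynapseParams):
    ds_n = -s_nmda / p.tau_nmda + p.alpha_nmda * x * (1.0 - s_nmda)
    dx = -x / p.tau_x
    ds_g = -s_gaba / p.tau_gaba
    ds_a = -s_ampa / p.tau_ampa
    return ds_n, dx, ds_g, ds_a


def gating_step(state: NetworkState, spikes_e, spikes_i,
                p: SynapseParams, dt: float) -> NetworkState:
    """Advance the gating variables one Heun step.

    ``spikes_e`` / ``spikes_i`` are boolean masks of presynaptic neurons
    whose spikes (from the previous step) are applied as instantaneous
    increments before the smooth update: x += 1 and S_AMPA += 1 per
    principal-cell spike, S_GABA += 1 per interneuron spike.
    """
    s_n = state.s_nmda.copy()
    x = state.x.copy()
    s_g = state.s_gaba.copy()
    s_a = state.s_ampa.copy()
    x[np.asarray(spikes_e, bool)] += 1.0
    s_a[np.asarray(spikes_e, bool)] += 1.0
    s_g[np.asarray(spikes_i, bool)] += 1.0
    d1 = _gating_derivs(s_n, x, s_g, s_a, p)
    stage2 = (s_n + dt * d1[0], x + dt * d1[1],
              s_g + dt * d1[2], s_a + dt * d1[3])
    d2 = _gating_derivs(*stage2, p)
    new = dataclasses.replace(
        state,
        s_nmda=s_n + 0.5 * dt * (d1[0] + d2[0]),
        x=x + 0.5 * dt * (d1[1] + d2[1]),
        s_gaba=s_g + 0.5 * dt * (d1[2] + d2[2]),
        s_ampa=s_a + 0.5 * dt * (d1[3] + d2[3]),
    )
    return new


def ou_noise_update(i_noise: np.ndarray, p: ExternalInputParams,
                    dt: float, rng: np.random.Generator) -> np.ndarray:
    """One exact-discretization step of the OU noise current.

    ``I' = a I + s sqrt(1 - a^2) N(0, 1)`` with ``a = exp(-dt/tau)`` and
    ``s`` the stationary SD, which reproduces the OU covariance at any dt.
    """
    a = np.exp(-dt / p.tau_noise)
    s = p.stationary_noise_sd
    return a * i_noise + s * np.sqrt(1.0 - a * a) \
        * rng.standard_normal(np.shape(i_noise))


def _cue_mask(geom: RingGeometry, protocol: Protocol) -> np.ndarray:
    cue = np.zeros(geom.n_e)
    if protocol.cue is not None:
        th = geom.theta_e
        for lo, hi in protocol.cue.windows:
            cue[(th >= lo) & (th <= hi)] = protocol.cue.amplitude
    return cue


def _suppression_current(geom: RingGeometry, protocol: Protocol) -> np.ndarray:
    sup = np.zeros(geom.n_i)
    s = protocol.suppression
    if s is not None and s.half_width > 0:
        th = geom.theta_i
        for c in s.centers:
            sup[angular_difference(th, c) <= s.half_width] = s.amplitude
    return sup


def external_currents(t: float, population: str, p: ExternalInputParams,
                      protocol: Protocol, geom: RingGeometry,
                      noise: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-neuron external current (pA) at time t (ms).

    Principal cells: background + cue (inside the cue windows, before the
    cue offset time) + noise.  Interneurons: background + MS input +
    suppression current + noise.
    """
    if population == "E":
        out = np.full(geom.n_e, p.i_back_e)
        if protocol.cue is not None and t < protocol.cue.t_off:
            out += _cue_mask(geom, protocol)
    elif population == "I":
        ms = p.i_ms0 + p.a_ms * np.cos(2e-3 * np.pi * p.f_ms * t)
        out = np.full(geom.n_i, p.i_back_i + ms)
        out += _suppression_current(geom, protocol)
    else:
        raise ValueError(f"unknown population {population!r}")
    if noise is not None:
        out = out + noise
    return out


def rk2_step(state: NetworkState, mats: ConnectivityMatrices,
             model: ModelParameters, protocol: Protocol,
             dt: float) -> tuple[NetworkState, np.ndarray, np.ndarray]:
    """One reference Heun step of the coupled network.

    Returns the new state plus boolean spike masks for this step.  Noise
    currents in ``state`` are treated as constant over the step (the caller
    updates them between steps).  Aborts on non-finite membrane potentials.
    """
    p = model.syn
    exc, inh = model.exc, model.inh
    geom = RingGeometry(model.n_e, model.n_i)

    # spike increments from the previous step, then gating stages
    s_n = state.s_nmda.copy()
    x = state.x.copy()
    s_g = state.s_gaba.copy()
    s_a = state.s_ampa.copy()
    x[state.pending_e] += 1.0
    s_a[state.pending_e] += 1.0
    s_g[state.pending_i] += 1.0
    d1g = _gating_derivs(s_n, x, s_g, s_a, p)
    s_n2 = s_n + dt * d1g[0]
    s_g2 = s_g + dt * d1g[2]
    s_a2 = s_a + dt * d1g[3]
    d2g = _gating_derivs(s_n2, x + dt * d1g[1], s_g2, s_a2, p)

    active_e = state.ref_e == 0
    active_i = state.ref_i == 0

    def dv(v_e, v_i, sn, sg, sa, t):
        st = dataclasses.replace(state, v_e=v_e, v_i=v_i, s_nmda=sn,
                                 s_gaba=sg, s_ampa=sa)
        syn = synaptic_currents(st, mats, p)
        iext_e = external_currents(t, "E", model.ext, protocol, geom,
                                   state.noise_e)
        iext_i = external_currents(t, "I", model.ext, protocol, geom,
                                   state.noise_i)
        # currents are in pA and V in mV, so C_m enters in pF (hence 1e3)
        dv_e = (-exc.g_l * (v_e - exc.v_leak) - syn["i_syn_e"] + iext_e) \
            / (exc.c_m * 1e3)
        dv_i = (-inh.g_l * (v_i - inh.v_leak) - syn["i_syn_i"] + iext_i) \
            / (inh.c_m * 1e3)
        return dv_e, dv_i

    dv1_e, dv1_i = dv(state.v_e, state.v_i, s_n, s_g, s_a, state.t)
    vm_e = np.where(active_e, state.v_e + dt * dv1_e, state.v_e)
    vm_i = np.where(active_i, state.v_i + dt * dv1_i, state.v_i)
    dv2_e, dv2_i = dv(vm_e, vm_i, s_n2, s_g2, s_a2, state.t + dt)
    v_e = np.where(active_e,
                   state.v_e + 0.5 * dt * (dv1_e + dv2_e), state.v_e)
    v_i = np.where(active_i,
                   state.v_i + 0.5 * dt * (dv1_i + dv2_i), state.v_i)
    if not (np.all(np.isfinite(v_e)) and np.all(np.isfinite(v_i))):
        raise FloatingPointError(
            f"non-finite membrane potential at t = {state.t:.3f} ms")

    spikes_e = active_e & (v_e >= exc.v_th)
    spikes_i = active_i & (v_i >= inh.v_th)
    v_e = np.where(spikes_e, exc.v_reset, v_e)
    v_i = np.where(spikes_i, inh.v_reset, v_i)
    ref_e = np.where(spikes_e, int(round(exc.tau_ref / dt)),
                     np.maximum(state.ref_e - 1, 0))
    ref_i = np.where(spikes_i, int(round(inh.tau_ref / dt)),
                     np.maximum(state.ref_i - 1, 0))

    new = dataclasses.replace(
        state,
        v_e=v_e, v_i=v_i,
        s_nmda=s_n + 0.5 * dt * (d1g[0] + d2g[0]),
        x=(x + dt * 0.5 * (d1g[1] + d2g[1])),
        s_gaba=s_g + 0.5 * dt * (d1g[2] + d2g[2]),
        s_ampa=s_a + 0.5 * dt * (d1g[3] + d2g[3]),
        ref_e=ref_e, ref_i=ref_i,
        t=state.t + dt,
        pending_e=spikes_e, pending_i=spikes_i,
    )
    return new, spikes_e, spikes_i


def _initial_vm(model: ModelParameters, protocol: Protocol,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    if protocol.init_vm == "fixed":
        return (np.full(model.n_e, -60.0), np.full(model.n_i, -60.0))
    v_e = rng.uniform(-60.0, -50.0, model.n_e)
    v_i = rng.uniform(-60.0, -50.0, model.n_i)
    return v_e, v_i


def _default_record_indices(model: ModelParameters,
                            protocol: Protocol) -> tuple[np.ndarray, np.ndarray]:
    """Principal cell and interneuron V_m recording sets (90-deg cells first)."""
    e90 = int(round(model.n_e * 90.0 / 360.0)) % model.n_e
    i90 = int(round(model.n_i * 90.0 / 360.0)) % model.n_i
    idx_e = [e90] + [i for i in protocol.record_vm_e if i != e90]
    idx_i = [i90] + [i for i in protocol.record_vm_i if i != i90]
    return (np.asarray(idx_e, dtype=np.int64),
            np.asarray(idx_i, dtype=np.int64))


def run_trial(model: ModelParameters, protocol: Protocol, seed: int,
              mats: Optional[ConnectivityMatrices] = None,
              spike_cap: Optional[int] = None,
              _v0: Optional[tuple[np.ndarray, np.ndarray]] = None,
              ) -> SimulationResult:
    """Simulate one trial with the compiled kernel.

    Deterministic given ``seed``: the initial membrane potentials and every
    noise innovation derive from it.  ``mats`` may be passed to reuse
    prebuilt connectivity across trials.
    """
    geom = RingGeometry(model.n_e, model.n_i)
    if mats is None:
        mats = build_connectivity(geom, model.conn)

    ss = np.random.SeedSequence(seed)
    init_seed, kernel_seed = (int(s) & 0x7FFFFFFF
                              for s in ss.generate_state(2))
    rng = np.random.default_rng(init_seed)
    if _v0 is not None:
        v0_e = np.asarray(_v0[0], float)
        v0_i = np.asarray(_v0[1], float)
    else:
        v0_e, v0_i = _initial_vm(model, protocol, rng)

    rec_e_idx, rec_i_idx = _default_record_indices(model, protocol)
    cue_current = _cue_mask(geom, protocol)
    cue_t_off = (protocol.cue.t_off if protocol.cue is not None else -1.0)
    supp = _suppression_current(geom, protocol)

    ext = model.ext
    noise_on = protocol.noise_enabled and ext.eta_noise > 0 \
        and ext.input_mode == "current"
    poisson_on = ext.input_mode == "poisson"

    uniform_ii = model.conn.w_ii_mode == "uniform"
    dummy = np.zeros((1, 1))
    w_ii = dummy if uniform_ii else np.ascontiguousarray(mats.w_ii)
    w_ii_t = dummy if uniform_ii else np.ascontiguousarray(mats.w_ii.T)
    ee_on = mats.w_ee is not None and model.syn.g_nmda_ee > 0.0
    w_ee = np.ascontiguousarray(mats.w_ee) if ee_on else dummy
    w_ee_t = np.ascontiguousarray(mats.w_ee.T) if ee_on else dummy

    if spike_cap is None:
        dur_s = protocol.duration
        spike_cap = int(2e5 + 80 * model.n_e * dur_s + 180 * model.n_i * dur_s)

    n_e, n_i = model.n_e, model.n_i
    n_steps = protocol.n_steps
    dt = protocol.dt
    # SFC64: fastest high-quality bit generator; innovations are consumed
    # in bulk, float32 (their round-off is far below the noise scale)
    rng_noise = np.random.Generator(np.random.SFC64(kernel_seed))
    noise_sd = ext.stationary_noise_sd if noise_on else 0.0
    alpha_ou = float(np.exp(-dt / ext.tau_noise))
    innov_scale = np.float32(noise_sd * np.sqrt(1.0 - alpha_ou**2))

    # state arrays (mutated in place by the kernel)
    v_e = v0_e.copy()
    v_i = v0_i.copy()
    s_n = np.zeros(n_e)
    x = np.zeros(n_e)
    s_a = np.zeros(n_e)
    s_g = np.zeros(n_i)
    ref_e = np.zeros(n_e, np.int64)
    ref_i = np.zeros(n_i, np.int64)
    noise_e = (noise_sd * rng_noise.standard_normal(n_e) if noise_on
               else np.zeros(n_e))  # stationary initial condition
    noise_i = (noise_sd * rng_noise.standard_normal(n_i) if noise_on
               else np.zeros(n_i))
    y_e = np.full(n_e, ext.i_back_e) if poisson_on else np.zeros(n_e)
    y_i_exc = np.full(n_i, ext.i_back_i) if poisson_on else np.zeros(n_i)
    y_i_ms = np.full(n_i, ext.i_ms0) if poisson_on else np.zeros(n_i)
    a_sum = np.zeros(n_i)
    b_sum = np.zeros(n_e)
    c_vec = np.zeros(n_i)
    ba_sum = np.zeros(n_i)
    aee_sum = np.zeros(n_e)
    active = np.zeros(n_e, np.int64)
    is_active = np.zeros(n_e, np.bool_)
    spk_e = np.zeros(n_e, np.int64)
    spk_i = np.zeros(n_i, np.int64)

    # output buffers
    n_samples = n_steps // protocol.record_every + 1
    record_igaba = bool(protocol.record_igaba_per_cell)
    igaba_e = np.zeros((n_samples, n_e) if record_igaba else (1, 1),
                       dtype=np.float32)
    mean_rec = np.zeros((n_samples, 8))
    vm_e_rec = np.zeros((n_samples, rec_e_idx.size))
    vm_i_rec = np.zeros((n_samples, rec_i_idx.size))
    sn_range = np.zeros((n_samples, 2))
    spike_pop = np.zeros(spike_cap, np.int8)
    spike_idx = np.zeros(spike_cap, np.int32)
    spike_t = np.zeros(spike_cap, np.float64)
    regs_i = np.zeros(8, np.int64)
    regs_f = np.zeros(2, np.float64)
    regs_i[_kernel.R_SAMPLE] = 1  # sample 0 is the initial state

    # sample 0: gating is zero, so synaptic currents vanish
    mean_rec[0, 3] = ext.i_back_e
    mean_rec[0, 4] = ext.i_back_i + ext.i_ms0 + ext.a_ms
    mean_rec[0, 7] = ext.i_ms0 + ext.a_ms
    vm_e_rec[0] = v_e[rec_e_idx]
    vm_i_rec[0] = v_i[rec_i_idx]

    if poisson_on:
        _kernel.seed_rng(kernel_seed)
        j_pois_e = ext.i_back_e / (ext.poisson_rate_e * 1e-3 * model.syn.tau_ampa)
        j_pois_i = ext.i_back_i / (ext.poisson_rate_i * 1e-3 * model.syn.tau_ampa)
        j_pois_ms = ext.i_ms0 / (ext.poisson_rate_ms * 1e-3 * model.syn.tau_gaba)
    else:
        j_pois_e = j_pois_i = j_pois_ms = 0.0

    chunk = 5000
    dummy_innov = np.zeros((1, 1), np.float32)
    w_ei_c = np.ascontiguousarray(mats.w_ei)
    w_ei_tc = np.ascontiguousarray(mats.w_ei.T)
    w_ie_c = np.ascontiguousarray(mats.w_ie)
    w_ie_tc = np.ascontiguousarray(mats.w_ie.T)
    for step0 in range(0, n_steps, chunk):
        n_sub = min(chunk, n_steps - step0)
        if noise_on:
            innov_e = innov_scale * rng_noise.standard_normal(
                (n_sub, n_e), dtype=np.float32)
            innov_i = innov_scale * rng_noise.standard_normal(
                (n_sub, n_i), dtype=np.float32)
        else:
            innov_e = innov_i = dummy_innov
        _kernel.run_chunk(
            step0, n_sub, dt, protocol.record_every,
            # C_m converted nF -> pF so that pA / pF = mV / ms
            model.exc.c_m * 1e3, model.exc.g_l, model.exc.v_leak,
            model.exc.v_th, model.exc.v_reset,
            int(round(model.exc.tau_ref / dt)),
            model.inh.c_m * 1e3, model.inh.g_l, model.inh.v_leak,
            model.inh.v_th, model.inh.v_reset,
            int(round(model.inh.tau_ref / dt)),
            model.syn.g_nmda_ei, model.syn.g_gaba_ie, model.syn.g_gaba_ii,
            model.syn.g_nmda_ee, model.syn.g_ampa_ei,
            model.syn.v_exc, model.syn.v_inh, model.syn.mg,
            model.syn.tau_nmda, model.syn.alpha_nmda, model.syn.tau_x,
            model.syn.tau_gaba, model.syn.tau_ampa, model.syn.ampa_fraction,
            w_ei_c, w_ei_tc, w_ie_c, w_ie_tc,
            uniform_ii, w_ii, w_ii_t, ee_on, w_ee, w_ee_t,
            ext.i_back_e, ext.i_back_i, ext.i_ms0, ext.a_ms, ext.f_ms,
            noise_on, alpha_ou, innov_e, innov_i,
            poisson_on, ext.poisson_rate_e, ext.poisson_rate_i,
            ext.poisson_rate_ms, j_pois_e, j_pois_i, j_pois_ms,
            cue_current, cue_t_off, supp,
            v_e, v_i, s_n, x, s_a, s_g, ref_e, ref_i, noise_e, noise_i,
            y_e, y_i_exc, y_i_ms,
            a_sum, b_sum, c_vec, ba_sum, aee_sum,
            active, is_active, spk_e, spk_i,
            spike_pop, spike_idx, spike_t,
            igaba_e, record_igaba, mean_rec, vm_e_rec, vm_i_rec, sn_range,
            rec_e_idx, rec_i_idx,
            regs_i, regs_f,
        )
        err = regs_i[_kernel.R_ERR]
        if err == _kernel.ERR_NAN:
            raise FloatingPointError(
                "non-finite membrane potential during trial")
        if err == _kernel.ERR_SPIKE_OVERFLOW:
            raise RuntimeError("spike buffer overflow; raise spike_cap")

    n_spikes = int(regs_i[_kernel.R_N_SPIKES])
    t = np.arange(n_samples) * protocol.record_every_ms
    return SimulationResult(
        spike_pop=spike_pop[:n_spikes].copy(),
        spike_idx=spike_idx[:n_spikes].copy(),
        spike_t=spike_t[:n_spikes].copy(),
        t=t,
        igaba_e=igaba_e if record_igaba else None,
        mean_currents=mean_rec,
        vm_e=vm_e_rec, vm_i=vm_i_rec,
        vm_e_idx=rec_e_idx, vm_i_idx=rec_i_idx,
        sn_range=sn_range,
        model=model, protocol=protocol, seed=seed,
    )


def run_trial_reference(model: ModelParameters, protocol: Protocol,
                        seed: int = 0, n_steps: Optional[int] = None,
                        mats: Optional[ConnectivityMatrices] = None,
                        _v0: Optional[tuple[np.ndarray, np.ndarray]] = None,
                        ) -> dict:
    """Dense NumPy integration of the same scheme (short runs / oracles).

    Returns a dict with spike lists, sampled membrane potentials and the
    final state.  Noise draws use a NumPy generator and are NOT
    stream-compatible with the kernel; for kernel-equivalence tests run
    noise-free with an explicit ``_v0``.
    """
    geom = RingGeometry(model.n_e, model.n_i)
    if mats is None:
        mats = build_connectivity(geom, model.conn)
    if n_steps is None:
        n_steps = protocol.n_steps
    dt = protocol.dt

    ss = np.random.SeedSequence(seed)
    init_seed, noise_seed = (int(s) & 0x7FFFFFFF
                             for s in ss.generate_state(2))
    rng_init = np.random.default_rng(init_seed)
    rng_noise = np.random.default_rng(noise_seed)
    if _v0 is not None:
        v0_e, v0_i = (np.asarray(a, float) for a in _v0)
    else:
        v0_e, v0_i = _initial_vm(model, protocol, rng_init)
    state = NetworkState.initial(model, v0_e, v0_i)
    noise_on = protocol.noise_enabled and model.ext.eta_noise > 0

    rec_every = protocol.record_every
    n_samples = n_steps // rec_every + 1
    vm_e = np.zeros((n_samples, model.n_e))
    vm_i = np.zeros((n_samples, model.n_i))
    vm_e[0] = state.v_e
    vm_i[0] = state.v_i
    spikes: list[tuple[int, int, float]] = []
    sample = 1
    for step in range(n_steps):
        if noise_on:
            state.noise_e = ou_noise_update(state.noise_e, model.ext, dt,
                                            rng_noise)
            state.noise_i = ou_noise_update(state.noise_i, model.ext, dt,
                                            rng_noise)
        state, spk_e, spk_i = rk2_step(state, mats, model, protocol, dt)
        for i in np.flatnonzero(spk_e):
            spikes.append((POP_E, int(i), state.t))
        for i in np.flatnonzero(spk_i):
            spikes.append((POP_I, int(i), state.t))
        if (step + 1) % rec_every == 0:
            vm_e[sample] = state.v_e
            vm_i[sample] = state.v_i
            sample += 1
    return {
        "spikes": spikes,
        "t": np.arange(n_samples) * protocol.record_every_ms,
        "vm_e": vm_e,
        "vm_i": vm_i,
        "state": state,
    }
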