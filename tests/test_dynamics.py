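"""Dynamics: single operators, LIF closed forms, path equivalence."""
from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest

import thetaring as tr
from thetaring.dynamics import _gating_derivs
from tests.conftest import mini_model, safe_v0


# -- Mg block ----------------------------------------------------------------

def test_mg_block_no_block():
    v = np.linspace(-90, 10, 11)
    np.testing.assert_allclose(tr.mg_block_factor(v, mg=0.0), 1.0)


def test_mg_block_value_at_rest():
    # direct evaluation of 1 / (1 + exp(0.062*60)/3.57)
    expected = 1.0 / (1.0 + math.exp(0.062 * 60.0) / 3.57)
    assert tr.mg_block_factor(-60.0, mg=1.0) == pytest.approx(expected,
                                                              rel=1e-12)
    assert expected == pytest.approx(0.0796, abs=2e-4)


def test_mg_block_monotone_increasing():
    v = np.linspace(-100, 20, 500)
    b = tr.mg_block_factor(v, mg=1.0)
    assert np.all(np.diff(b) > 0)
    assert np.all((b > 0) & (b < 1))


# -- synaptic currents against a double-loop oracle --------------------------

def test_synaptic_currents_toy_oracle():
    geom = tr.RingGeometry(n_e=4, n_i=2)
    p = tr.SynapseParams()
    mats = tr.build_connectivity(geom, tr.ConnectivityParams())
    rng = np.random.default_rng(0)
    state = tr.NetworkState.initial(
        tr.ModelParameters(n_e=4, n_i=2),
        rng.uniform(-70, -50, 4), rng.uniform(-70, -50, 2))
    state.s_nmda = rng.uniform(0, 1, 4)
    state.s_gaba = rng.uniform(0, 2, 2)

    cur = tr.synaptic_currents(state, mats, p)

    for i in range(2):  # interneurons: NMDA with Mg block + uniform I-I GABA
        acc = 0.0
        for j in range(4):
            acc += mats.w_ei[i, j] * state.s_nmda[j]
        block = 1.0 / (1.0 + math.exp(-0.062 * state.v_i[i]) / 3.57)
        i_nmda = p.g_nmda_ei * (state.v_i[i] - p.v_exc) * block * acc
        acc_g = sum(mats.w_ii[i, j] * state.s_gaba[j] for j in range(2))
        i_gaba = p.g_gaba_ii * (state.v_i[i] - p.v_inh) * acc_g
        assert cur["i_syn_i"][i] == pytest.approx(i_nmda + i_gaba, rel=1e-12)
    for i in range(4):  # principal cells: GABA only
        acc = sum(mats.w_ie[i, j] * state.s_gaba[j] for j in range(2))
        expected = p.g_gaba_ie * (state.v_e[i] - p.v_inh) * acc
        assert cur["i_syn_e"][i] == pytest.approx(expected, rel=1e-12)


def test_synaptic_currents_trivial_cases():
    geom = tr.RingGeometry(n_e=4, n_i=2)
    model = tr.ModelParameters(n_e=4, n_i=2)
    mats = tr.build_connectivity(geom, model.conn)
    state = tr.NetworkState.initial(model, np.full(4, -55.0), np.full(2, -55.0))
    cur = tr.synaptic_currents(state, mats, model.syn)
    np.testing.assert_array_equal(cur["i_syn_e"], 0.0)  # all gating zero
    np.testing.assert_array_equal(cur["i_syn_i"], 0.0)

    state.s_gaba[:] = 1.5
    state.v_e[:] = model.syn.v_inh  # at the reversal potential
    cur = tr.synaptic_currents(state, mats, model.syn)
    np.testing.assert_allclose(cur["i_gaba_e"], 0.0, atol=1e-12)


def test_synaptic_currents_dimension_mismatch():
    geom = tr.RingGeometry(n_e=4, n_i=2)
    model = tr.ModelParameters(n_e=8, n_i=2)
    mats = tr.build_connectivity(geom, model.conn)
    state = tr.NetworkState.initial(model, np.full(8, -55.0), np.full(2, -55.0))
    with pytest.raises(ValueError):
        tr.synaptic_currents(state, mats, model.syn)


# -- gating ------------------------------------------------------------------

def test_gating_decay_closed_forms():
    model = tr.ModelParameters(n_e=4, n_i=2)
    state = tr.NetworkState.initial(model, np.full(4, -60.0), np.full(2, -60.0))
    state.s_nmda[:] = 0.5
    state.s_gaba[:] = 0.8
    dt = 0.02
    n = 5000  # 100 ms
    no_e = np.zeros(4, bool)
    no_i = np.zeros(2, bool)
    for _ in range(n):
        state = tr.gating_step(state, no_e, no_i, model.syn, dt)
    t = n * dt
    np.testing.assert_allclose(state.s_nmda,
                               0.5 * np.exp(-t / model.syn.tau_nmda),
                               rtol=1e-8)
    np.testing.assert_allclose(state.s_gaba,
                               0.8 * np.exp(-t / model.syn.tau_gaba),
                               rtol=2e-5)  # Heun: O((dt/tau)^3) per step


def test_single_spike_nmda_against_fine_step_oracle():
    """S_NMDA after one presynaptic spike matches a dt/10 integration."""
    p = tr.SynapseParams()

    def integrate(dt, n_steps, apply_spike_first):
        s, xv = 0.0, 0.0
        if apply_spike_first:
            xv += 1.0
        for _ in range(n_steps):
            ds1, dx1, _, _ = _gating_derivs(s, xv, 0.0, 0.0, p)
            s2, x2 = s + dt * ds1, xv + dt * dx1
            ds2, dx2, _, _ = _gating_derivs(s2, x2, 0.0, 0.0, p)
            s += 0.5 * dt * (ds1 + ds2)
            xv += 0.5 * dt * (dx1 + dx2)
        return s

    coarse = integrate(0.02, 10000, True)   # 200 ms
    fine = integrate(0.002, 100000, True)
    assert coarse == pytest.approx(fine, abs=1e-4)
    assert 0.0 < coarse < 1.0


def test_snmda_bounded_in_default_trial(short_default_trial):
    res = short_default_trial
    assert np.all(res.sn_range[:, 0] >= 0.0)
    assert np.all(res.sn_range[:, 1] <= 1.0)


# -- OU noise ----------------------------------------------------------------

def test_ou_decays_without_noise():
    p = tr.ExternalInputParams(eta_noise=0.0)
    rng = np.random.default_rng(0)
    i = np.full(16, 30.0)
    for _ in range(2000):
        i = tr.ou_noise_update(i, p, 0.02, rng)
    np.testing.assert_allclose(i, 30.0 * np.exp(-2000 * 0.02 / p.tau_noise),
                               rtol=1e-10)


def test_ou_autocorrelation_time():
    """Lag-tau autocovariance is e^-1 of the variance."""
    p = tr.ExternalInputParams()
    rng = np.random.default_rng(42)
    dt = 0.02
    n_proc, n_steps = 400, 4000  # 80 ms per process, 32 s total
    lag = int(round(p.tau_noise / dt))
    traj = np.empty((n_steps, n_proc))
    i = p.stationary_noise_sd * rng.standard_normal(n_proc)
    for k in range(n_steps):
        i = tr.ou_noise_update(i, p, dt, rng)
        traj[k] = i
    x = traj[500:]
    x = x - x.mean()
    c0 = np.mean(x * x)
    ct = np.mean(x[:-lag] * x[lag:])
    assert ct / c0 == pytest.approx(np.exp(-1.0), abs=0.05)


def test_ou_convention_switch():
    printed = tr.ExternalInputParams()
    target = tr.ExternalInputParams(noise_convention="target_sd")
    assert printed.stationary_noise_sd == pytest.approx(150.0 / math.sqrt(2))
    assert target.stationary_noise_sd == pytest.approx(150.0)


# -- external currents -------------------------------------------------------

def test_external_currents_values():
    geom = tr.RingGeometry()
    model, protocol = tr.default_protocol()
    e = tr.external_currents(600.0, "E", model.ext, protocol, geom)
    np.testing.assert_array_equal(e, 750.0)  # cue is off after 500 ms
    e = tr.external_currents(100.0, "E", model.ext, protocol, geom)
    in_cue = e == 950.0
    assert in_cue.sum() == 2 * 129  # two 45-deg windows, inclusive bounds
    assert np.all(e[~in_cue] == 750.0)

    i = tr.external_currents(0.0, "I", model.ext, protocol, geom)
    np.testing.assert_array_equal(i, 325.0 - 100.0)

    ext = dataclasses.replace(model.ext, a_ms=40.0, f_ms=8.0)
    i = tr.external_currents(0.0, "I", ext, protocol, geom)
    np.testing.assert_allclose(i, 325.0 - 100.0 + 40.0)

    with pytest.raises(ValueError):
        tr.external_currents(0.0, "X", model.ext, protocol, geom)


def test_suppression_current_geometry():
    model, protocol = tr.suppression_protocol(half_width=22.5)
    geom = tr.RingGeometry()
    i = tr.external_currents(0.0, "I", model.ext, protocol, geom)
    suppressed = i < 200.0
    th = geom.theta_i
    inside = (tr.angular_difference(th, 0.0) <= 22.5) \
        | (tr.angular_difference(th, 180.0) <= 22.5)
    np.testing.assert_array_equal(suppressed, inside)


# -- LIF closed forms ---------------------------------------------------------

def _isolated_model(i_back_e):
    """Synaptically silent network: every neuron integrates its own drive."""
    model = tr.ModelParameters(n_e=4, n_i=2)
    model.syn = dataclasses.replace(model.syn, g_nmda_ei=0.0, g_gaba_ie=0.0,
                                    g_gaba_ii=0.0)
    model.ext = dataclasses.replace(model.ext, i_back_e=i_back_e, i_ms0=0.0)
    return model


def lif_rate_hz(p: tr.NeuronParams, i_pa: float) -> float:
    """Closed-form stationary LIF firing rate for constant suprathreshold
    drive: 1 / (tau_ref + tau_m ln((V_inf - V_reset)/(V_inf - V_th)))."""
    v_inf = p.v_leak + i_pa / p.g_l
    if v_inf <= p.v_th:
        return 0.0
    isi = p.tau_ref + p.tau_m * math.log((v_inf - p.v_reset)
                                         / (v_inf - p.v_th))
    return 1000.0 / isi


def test_isolated_principal_cell_rate_matches_closed_form():
    model = _isolated_model(750.0)
    protocol = tr.Protocol(duration=2.0, cue=None, noise_enabled=False,
                           init_vm="fixed")
    res = tr.run_trial(model, protocol, seed=0)
    spikes = res.spikes_of(tr.POP_E, 0)
    assert spikes.size > 50
    rate = 1000.0 / np.mean(np.diff(spikes))  # stationary from the first ISI
    expected = lif_rate_hz(model.exc, 750.0)
    assert expected == pytest.approx(63.04, abs=0.05)
    assert rate == pytest.approx(expected, rel=0.01)


def test_subthreshold_input_never_spikes():
    model = _isolated_model(499.0)  # just below the 500-pA rheobase
    protocol = tr.Protocol(duration=1.0, cue=None, noise_enabled=False,
                           init_vm="uniform")
    res = tr.run_trial(model, protocol, seed=3)
    assert res.spikes_of(tr.POP_E, 0).size == 0


# -- full-network integration -------------------------------------------------

def test_refractory_and_isi(short_default_trial):
    res = short_default_trial
    for pop, tau_ref in ((tr.POP_E, 2.0), (tr.POP_I, 1.0)):
        idx, t = res.population_spikes(pop)
        for i in np.unique(idx)[:50]:
            ts = np.sort(t[idx == i])
            if ts.size > 1:
                assert np.min(np.diff(ts)) >= tau_ref - 1e-9


def test_same_seed_bit_identical():
    model, protocol = tr.default_protocol(duration=0.5)
    r1 = tr.run_trial(model, protocol, seed=77)
    r2 = tr.run_trial(model, protocol, seed=77)
    np.testing.assert_array_equal(r1.spike_t, r2.spike_t)
    np.testing.assert_array_equal(r1.spike_idx, r2.spike_idx)
    np.testing.assert_array_equal(r1.spike_pop, r2.spike_pop)
    np.testing.assert_array_equal(r1.vm_e, r2.vm_e)


def test_kernel_matches_dense_reference():
    """The recurrence-tracked kernel and the dense NumPy path produce the
    same trajectory (same spikes, Vm to float round-off) over 100 ms."""
    model, protocol = tr.default_protocol(duration=0.1)
    protocol = dataclasses.replace(protocol, noise_enabled=False)
    v0 = safe_v0(np.random.default_rng(7), model.n_e, model.n_i)
    ref = tr.run_trial_reference(model, protocol, seed=1, _v0=v0)
    res = tr.run_trial(model, protocol, seed=1, _v0=v0)
    assert [(p, i) for p, i, _ in ref["spikes"]] \
        == list(zip(res.spike_pop.tolist(), res.spike_idx.tolist()))
    np.testing.assert_allclose(res.spike_t,
                               [t for _, _, t in ref["spikes"]], atol=1e-9)
    np.testing.assert_allclose(res.vm_e[:, 0], ref["vm_e"][:, 256],
                               atol=1e-9)
    np.testing.assert_allclose(res.vm_i[:, 0], ref["vm_i"][:, 64],
                               atol=1e-9)


def test_rk2_spike_time_convergence():
    """Halving dt moves early spike times by less than 0.1 ms per neuron."""
    model, protocol = tr.default_protocol(duration=0.4)
    p1 = dataclasses.replace(protocol, noise_enabled=False, dt=0.02)
    p2 = dataclasses.replace(protocol, noise_enabled=False, dt=0.01)
    v0 = safe_v0(np.random.default_rng(11), model.n_e, model.n_i)
    r1 = tr.run_trial(model, p1, seed=1, _v0=v0)
    r2 = tr.run_trial(model, p2, seed=1, _v0=v0)
    checked = 0
    for i in range(model.n_e):
        t1 = r1.spikes_of(tr.POP_E, i)
        t2 = r2.spikes_of(tr.POP_E, i)
        if t1.size and t2.size:
            assert abs(t1[0] - t2[0]) < 0.1
            checked += 1
    assert checked > 100


def test_mini_network_variants_run():
    """AMPA mixing, E-E recurrence, structured I-I and Poisson input all
    integrate without error on a scaled-down ring."""
    base = mini_model()
    protocol = tr.Protocol(duration=0.3)
    # AMPA mixing
    m = dataclasses.replace(base)
    m.syn = dataclasses.replace(base.syn, ampa_fraction=0.3,
                                g_ampa_ei=base.syn.g_nmda_ei)
    tr.run_trial(m, protocol, seed=1)
    # E-E NMDA
    m = dataclasses.replace(base)
    m.conn = dataclasses.replace(base.conn, ee_enabled=True)
    m.syn = dataclasses.replace(base.syn, g_nmda_ee=0.05)
    tr.run_trial(m, protocol, seed=1)
    # structured I-I
    m = dataclasses.replace(base)
    m.conn = dataclasses.replace(base.conn, w_ii_mode="bimodal")
    tr.run_trial(m, protocol, seed=1)
    # Poisson input
    m = dataclasses.replace(base)
    m.ext = dataclasses.replace(base.ext, input_mode="poisson")
    res = tr.run_trial(m, protocol, seed=1)
    assert np.isclose(res.mean_current("i_ext_e")[-10:].mean(),
                      base.ext.i_back_e, rtol=0.25)


def test_result_roundtrip(tmp_path, short_default_trial):
    path = tmp_path / "res.h5"
    short_default_trial.save(path)
    back = tr.SimulationResult.load(path)
    np.testing.assert_array_equal(back.spike_t, short_default_trial.spike_t)
    np.testing.assert_allclose(back.igaba_e, short_default_trial.igaba_e)
    assert back.model.to_dict() == short_default_trial.model.to_dict()
    csv = tmp_path / "spikes.csv"
    short_default_trial.spikes_to_csv(csv)
    header = csv.read_text().splitlines()[0]
    assert header == "population,neuron_index,angle_deg,time_ms"
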