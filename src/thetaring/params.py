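"""Model, input and protocol parameters for the ring attractor network.

All quantities carry the units conventional for conductance-based LIF
network models: capacitance in nF, conductance in nS, voltage in mV,
current in pA, time in ms.  nS * mV = pA, and the integrators convert
C_m to pF internally so that pA / pF = mV / ms.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence


@dataclass
class NeuronParams:
    """Leaky integrate-and-fire single-neuron constants for one population.

    The membrane obeys  C_m dV/dt = -g_L (V - V_L) - I_syn + I_ext ; when V
    reaches ``v_th`` a spike is emitted and V is clamped at ``v_reset`` for
    ``tau_ref`` ms.
    """

    c_m: float  # membrane capacitance, nF
    g_l: float  # leak conductance, nS
    v_leak: float  # resting (leak reversal) potential, mV
    v_th: float  # spike threshold, mV
    v_reset: float  # post-spike reset potential, mV
    tau_ref: float  # absolute refractory period, ms

    def __post_init__(self) -> None:
        if not self.v_reset < self.v_th:
            raise ValueError("v_reset must lie below v_th")
        if self.c_m <= 0 or self.g_l <= 0 or self.tau_ref < 0:
            raise ValueError("c_m, g_l must be positive and tau_ref >= 0")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C_m / g_L in ms (nF/nS = s, hence the 1e3)."""
        return self.c_m / self.g_l * 1e3

    @property
    def rheobase(self) -> float:
        """Minimal constant current (pA) that can ever bring V to threshold."""
        return self.g_l * (self.v_th - self.v_leak)


def principal_defaults() -> NeuronParams:
    """Principal (excitatory) cell constants: tau_m = 20 ms, rheobase 500 pA."""
    return NeuronParams(c_m=0.5, g_l=25.0, v_leak=-70.0, v_th=-50.0,
                        v_reset=-60.0, tau_ref=2.0)


def interneuron_defaults() -> NeuronParams:
    """Interneuron constants: tau_m = 10 ms, rheobase 400 pA."""
    return NeuronParams(c_m=0.2, g_l=20.0, v_leak=-70.0, v_th=-50.0,
                        v_reset=-60.0, tau_ref=1.0)


@dataclass
class SynapseParams:
    """Synaptic conductances, reversal potentials and gating kinetics.

    E->I excitation is NMDAR-mediated by default (slow, saturating gating
    with a voltage-dependent Mg2+ block); inhibition is GABAR-mediated
    (first-order gating).  ``ampa_fraction`` > 0 mixes in a fast AMPA
    component at E->I synapses; ``g_nmda_ee`` > 0 enables recurrent E->E
    NMDA excitation (both are model variants, off by default).
    """

    g_nmda_ei: float = 0.4  # nS, maximal NMDA conductance E->I
    g_gaba_ie: float = 2.4  # nS, maximal GABA conductance I->E
    g_gaba_ii: float = 0.04  # nS, maximal GABA conductance I->I
    g_nmda_ee: float = 0.0  # nS, recurrent E->E NMDA (variant)
    g_ampa_ei: float = 0.4  # nS, AMPA conductance used when ampa_fraction > 0
    v_exc: float = 0.0  # mV, excitatory reversal potential
    v_inh: float = -70.0  # mV, inhibitory reversal potential
    mg: float = 1.0  # mM, extracellular [Mg2+] for the NMDA block
    tau_nmda: float = 100.0  # ms, NMDA gating decay
    alpha_nmda: float = 0.5  # kHz (1/ms), NMDA channel-opening rate
    tau_x: float = 2.0  # ms, decay of the NMDA intermediate gating variable
    tau_gaba: float = 10.0  # ms, GABA gating decay
    tau_ampa: float = 2.0  # ms, AMPA gating decay (variant)
    ampa_fraction: float = 0.0  # in [0, 1]; fraction of E->I drive that is AMPA

    def __post_init__(self) -> None:
        for name in ("g_nmda_ei", "g_gaba_ie", "g_gaba_ii", "g_nmda_ee",
                     "g_ampa_ei", "mg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("tau_nmda", "tau_x", "tau_gaba", "tau_ampa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.ampa_fraction <= 1.0:
            raise ValueError("ampa_fraction must lie in [0, 1]")


@dataclass
class ConnectivityParams:
    """Angular connectivity profiles on the ring.

    E->I: W(dth) = J- + (J+ - J-) exp(-dth^2 / (2 sigma^2)), peaked at
    dth = 0.  I->E: W(dth) = G exp(-(dth - mu)^2 / (2 sigma^2)); with
    mu = 90 deg the profile has maxima at signed offsets of +-90 deg, which
    is what spaces two bump attractors 180 deg apart.  J- and G follow from
    the normalization <W> = 1 over the angular-difference grid.
    """

    j_plus_ei: float = 1.6  # peak E->I strength (dimensionless)
    sigma_ei: float = 30.0  # deg
    mu_ie: float = 90.0  # deg, offset of the I->E peak
    sigma_ie: float = 30.0  # deg
    w_ii_mode: str = "uniform"  # one of {uniform, unimodal, bimodal}
    w_ii_sigma: float = 30.0  # deg, width of structured I-I profiles
    ee_enabled: bool = False  # build W_EE (recurrent excitation variant)
    sigma_ee: float = 30.0  # deg, width of the E-E profile
    normalization: str = "discrete"  # {discrete, integral}, see connectivity module

    def __post_init__(self) -> None:
        if self.sigma_ei <= 0 or self.sigma_ie <= 0 or self.w_ii_sigma <= 0 \
                or self.sigma_ee <= 0:
            raise ValueError("all sigma values must be strictly positive")
        if self.w_ii_mode not in ("uniform", "unimodal", "bimodal"):
            raise ValueError(f"unknown w_ii_mode {self.w_ii_mode!r}")
        if self.normalization not in ("discrete", "integral"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


@dataclass
class ExternalInputParams:
    """Constant background drive, medial-septum (MS) input and noise.

    Principal cells receive ``i_back_e`` plus independent Ornstein-Uhlenbeck
    noise; interneurons additionally receive the (inhibitory) MS current
    I_MS(t) = i_ms0 + a_ms cos(2 pi f_ms t).  The OU process follows
    tau dI/dt = -I + eta sqrt(tau) n(t), whose stationary standard deviation
    is eta / sqrt(2); set ``noise_convention="target_sd"`` to rescale so the
    stationary SD equals eta instead.
    """

    i_back_e: float = 750.0  # pA
    i_back_i: float = 325.0  # pA
    i_ms0: float = -100.0  # pA, constant (GABAergic, negative) MS input
    a_ms: float = 0.0  # pA, amplitude of the rhythmic MS component
    f_ms: float = 0.0  # Hz, frequency of the rhythmic MS component
    eta_noise: float = 150.0  # pA, OU noise strength parameter
    tau_noise: float = 2.0  # ms, OU correlation time
    noise_convention: str = "as_printed"  # {as_printed, target_sd}
    input_mode: str = "current"  # {current, poisson}
    poisson_rate_e: float = 1000.0  # Hz, excitatory background train rate (variant)
    poisson_rate_i: float = 1000.0  # Hz
    poisson_rate_ms: float = 500.0  # Hz, inhibitory MS train rate (variant)

    def __post_init__(self) -> None:
        if self.tau_noise <= 0:
            raise ValueError("tau_noise must be > 0")
        if self.a_ms < 0:
            raise ValueError("a_ms must be >= 0")
        if self.noise_convention not in ("as_printed", "target_sd"):
            raise ValueError(f"unknown noise_convention {self.noise_convention!r}")
        if self.input_mode not in ("current", "poisson"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")

    @property
    def stationary_noise_sd(self) -> float:
        """Stationary SD of the OU noise current in pA."""
        import math
        if self.noise_convention == "as_printed":
            return self.eta_noise / math.sqrt(2.0)
        return self.eta_noise


@dataclass
class CueParams:
    """Brief depolarizing current steering where the bumps form.

    200 pA to principal cells inside the two 45-deg windows centred on
    90 and 270 deg during the first 500 ms.
    """

    amplitude: float = 200.0  # pA
    windows: Sequence[tuple[float, float]] = (
        (67.5, 112.5),
        (247.5, 292.5),
    )
    t_off: float = 500.0  # ms


@dataclass
class SuppressionParams:
    """Constant hyperpolarizing current silencing interneurons between bumps.

    Interneurons with angle in [0, w] u [180 - w, 180 + w] u [360 - w, 360)
    receive ``amplitude`` (negative) pA for the whole run.
    """

    amplitude: float = -200.0  # pA
    half_width: float = 0.0  # w, deg, in [0, 90]
    centers: Sequence[float] = (0.0, 180.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.half_width <= 90.0:
            raise ValueError("half_width must lie in [0, 90] deg")


@dataclass
class Protocol:
    """Stimulation protocol and integration settings for one trial."""

    duration: float = 8.0  # s
    dt: float = 0.02  # ms
    cue: Optional[CueParams] = field(default_factory=CueParams)
    suppression: Optional[SuppressionParams] = None
    noise_enabled: bool = True
    init_vm: str = "uniform"  # {uniform, fixed}: U(-60, -50) mV or all -60 mV
    record_every_ms: float = 5.0  # trace sampling period (200 Hz)
    record_vm_e: Sequence[int] = ()  # extra principal cells to record V_m from
    record_vm_i: Sequence[int] = ()  # extra interneurons to record V_m from
    record_igaba_per_cell: bool = True  # keep per-E-cell GABA current traces

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")
        if self.init_vm not in ("uniform", "fixed"):
            raise ValueError(f"unknown init_vm {self.init_vm!r}")
        steps = self.record_every_ms / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("record_every_ms must be an integer multiple of dt")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration * 1000.0 / self.dt))

    @property
    def record_every(self) -> int:
        return int(round(self.record_every_ms / self.dt))


@dataclass
class ModelParameters:
    """Complete parameter set of the network model."""

    n_e: int = 1024  # number of principal cells
    n_i: int = 256  # number of interneurons
    exc: NeuronParams = field(default_factory=principal_defaults)
    inh: NeuronParams = field(default_factory=interneuron_defaults)
    syn: SynapseParams = field(default_factory=SynapseParams)
    conn: ConnectivityParams = field(default_factory=ConnectivityParams)
    ext: ExternalInputParams = field(default_factory=ExternalInputParams)

    def __post_init__(self) -> None:
        if self.n_e < 1 or self.n_i < 1:
            raise ValueError("population sizes must be >= 1")

    # -- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        d = dict(d)
        for key, sub in (("exc", NeuronParams), ("inh", NeuronParams),
                         ("syn", SynapseParams), ("conn", ConnectivityParams),
                         ("ext", ExternalInputParams)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)


def protocol_to_dict(p: Protocol) -> dict:
    return dataclasses.asdict(p)


def protocol_from_dict(d: dict) -> Protocol:
    d = dict(d)
    if d.get("cue") is not None and isinstance(d["cue"], dict):
        cue = dict(d["cue"])
        cue["windows"] = [tuple(w) for w in cue.get("windows", [])]
        d["cue"] = CueParams(**cue)
    if d.get("suppression") is not None and isinstance(d["suppression"], dict):
        sup = dict(d["suppression"])
        sup["centers"] = tuple(sup.get("centers", (0.0, 180.0)))
        d["suppression"] = SuppressionParams(**sup)
    for key in ("record_vm_e", "record_vm_i"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return Protocol(**d)


def load_config(path: str | Path) -> dict:
    """Read a configuration mapping from a JSON, YAML or TOML file."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".json":
        return json.loads(path.read_text())
    if suffix in (".yaml", ".yml"):
        import yaml
        return yaml.safe_load(path.read_text())
    if suffix == ".toml":
        import tomllib
        return tomllib.loads(path.read_text())
    raise ValueError(f"unsupported config format: {path.suffix!r}")


def config_to_objects(cfg: dict) -> tuple[ModelParameters, Protocol]:
    """Split a loaded config mapping into model parameters and protocol."""
    model = ModelParameters.from_dict(cfg.get("model", {}))
    protocol = protocol_from_dict(cfg.get("protocol", {}))
    return model, protocol


# -- canonical protocols -----------------------------------------------------

def default_protocol(duration: float = 8.0) -> tuple[ModelParameters, Protocol]:
    """Default stochastic two-attractor protocol (cue at 90/270 deg)."""
    return ModelParameters(), Protocol(duration=duration)


def deterministic_protocol(duration: float = 8.0,
                           i_back_e: float = 325.0,
                           i_back_i: float = 100.0,
                           ) -> tuple[ModelParameters, Protocol]:
    """Noise-free synchronous scenario with reduced constant drive.

    All membrane potentials start at -60 mV, the noise and the MS input are
    off, and no cue is applied, so every neuron within a population follows
    an identical trajectory.  Note that the reduced principal-cell drive of
    325 pA lies below the principal-cell rheobase g_L (V_th - V_L) = 500 pA,
    and principal cells receive no recurrent excitation, so with these
    values the network settles into a silent fixed point (see the methods
    note).
    """
    model = ModelParameters()
    model.ext = dataclasses.replace(
        model.ext, i_back_e=i_back_e, i_back_i=i_back_i, i_ms0=0.0)
    protocol = Protocol(duration=duration, cue=None, noise_enabled=False,
                        init_vm="fixed")
    return model, protocol


def suppression_protocol(half_width: float,
                         duration: float = 8.0) -> tuple[ModelParameters, Protocol]:
    """Default protocol plus constant -200 pA to interneurons between bumps."""
    model = ModelParameters()
    protocol = Protocol(
        duration=duration,
        suppression=SuppressionParams(half_width=half_width))
    return model, protocol


def rhythmic_protocol(a_ms: float, f_ms: float,
                      duration: float = 8.0) -> tuple[ModelParameters, Protocol]:
    """Default protocol with a rhythmic MS input component."""
    model = ModelParameters()
    model.ext = dataclasses.replace(model.ext, a_ms=a_ms, f_ms=f_ms)
    return model, Protocol(duration=duration)
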