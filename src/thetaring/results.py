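"""Simulation result container with HDF5 / CSV persistence."""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .params import (ModelParameters, Protocol, protocol_from_dict,
                     protocol_to_dict)

POP_E = 0
POP_I = 1

# column layout of the population-mean current traces
MEAN_CURRENT_COLUMNS = (
    "i_nmda_i",   # mean NMDA current onto interneurons
    "i_gaba_e",   # mean GABA current onto principal cells
    "i_gaba_i",   # mean I->I GABA current
    "i_ext_e",    # mean external current, principal cells
    "i_ext_i",    # mean external current, interneurons
    "i_tot_e",    # mean total membrane current, principal cells
    "i_tot_i",    # mean total membrane current, interneurons
    "ms_input",   # MS input waveform
)


@dataclass
class SimulationResult:
    """Spikes and sampled traces from one trial.

    Spike times are in ms and strictly increasing per neuron with gaps of
    at least the population refractory period; traces are sampled on an
    exact ``record_every_ms`` grid (200 Hz by default).
    """

    spike_pop: np.ndarray  # int8, 0 = principal cell, 1 = interneuron
    spike_idx: np.ndarray  # int32 neuron index within its population
    spike_t: np.ndarray    # float64 ms
    t: np.ndarray          # sample times, ms
    igaba_e: Optional[np.ndarray]  # (n_samples, n_e) float32, GABA current per E cell
    mean_currents: np.ndarray      # (n_samples, 8), see MEAN_CURRENT_COLUMNS
    vm_e: np.ndarray       # (n_samples, n_rec_e) membrane potentials, mV
    vm_i: np.ndarray
    vm_e_idx: np.ndarray   # which principal cells vm_e columns belong to
    vm_i_idx: np.ndarray
    sn_range: np.ndarray   # (n_samples, 2) min/max of S_NMDA at each sample
    model: ModelParameters = field(default_factory=ModelParameters)
    protocol: Protocol = field(default_factory=Protocol)
    seed: int = 0

    # -- convenience ---------------------------------------------------------
    @property
    def n_e(self) -> int:
        return self.model.n_e

    @property
    def n_i(self) -> int:
        return self.model.n_i

    @property
    def fs(self) -> float:
        """Trace sampling rate in Hz."""
        return 1000.0 / self.protocol.record_every_ms

    def spikes_of(self, pop: int, idx: int) -> np.ndarray:
        """Spike times (ms) of one neuron."""
        m = (self.spike_pop == pop) & (self.spike_idx == idx)
        return self.spike_t[m]

    def population_spikes(self, pop: int) -> tuple[np.ndarray, np.ndarray]:
        """(neuron indices, spike times) for one population."""
        m = self.spike_pop == pop
        return self.spike_idx[m], self.spike_t[m]

    def mean_current(self, name: str) -> np.ndarray:
        return self.mean_currents[:, MEAN_CURRENT_COLUMNS.index(name)]

    def vm_trace(self, pop: int, idx: int) -> np.ndarray:
        """Sampled membrane potential of a recorded neuron."""
        rec = self.vm_e_idx if pop == POP_E else self.vm_i_idx
        cols = np.flatnonzero(rec == idx)
        if cols.size == 0:
            raise KeyError(f"membrane potential of neuron {idx} "
                           f"(pop {pop}) was not recorded")
        return (self.vm_e if pop == POP_E else self.vm_i)[:, cols[0]]

    def angle_of(self, pop: int, idx) -> np.ndarray:
        n = self.n_e if pop == POP_E else self.n_i
        return np.asarray(idx) * (360.0 / n)

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            g = f.create_group("spikes")
            g.create_dataset("pop", data=self.spike_pop)
            g.create_dataset("idx", data=self.spike_idx)
            g.create_dataset("t", data=self.spike_t)
            tr = f.create_group("traces")
            tr.create_dataset("t", data=self.t)
            if self.igaba_e is not None:
                tr.create_dataset("igaba_e", data=self.igaba_e,
                                  compression="gzip", compression_opts=4)
            tr.create_dataset("mean_currents", data=self.mean_currents)
            tr.create_dataset("vm_e", data=self.vm_e)
            tr.create_dataset("vm_i", data=self.vm_i)
            tr.create_dataset("vm_e_idx", data=self.vm_e_idx)
            tr.create_dataset("vm_i_idx", data=self.vm_i_idx)
            tr.create_dataset("sn_range", data=self.sn_range)
            f.attrs["model"] = json.dumps(self.model.to_dict())
            f.attrs["protocol"] = json.dumps(protocol_to_dict(self.protocol))
            f.attrs["seed"] = self.seed

    @classmethod
    def load(cls, path: str | Path) -> "SimulationResult":
        import h5py

        with h5py.File(path, "r") as f:
            igaba = (np.asarray(f["traces/igaba_e"])
                     if "igaba_e" in f["traces"] else None)
            return cls(
                spike_pop=np.asarray(f["spikes/pop"]),
                spike_idx=np.asarray(f["spikes/idx"]),
                spike_t=np.asarray(f["spikes/t"]),
                t=np.asarray(f["traces/t"]),
                igaba_e=igaba,
                mean_currents=np.asarray(f["traces/mean_currents"]),
                vm_e=np.asarray(f["traces/vm_e"]),
                vm_i=np.asarray(f["traces/vm_i"]),
                vm_e_idx=np.asarray(f["traces/vm_e_idx"]),
                vm_i_idx=np.asarray(f["traces/vm_i_idx"]),
                sn_range=np.asarray(f["traces/sn_range"]),
                model=ModelParameters.from_dict(json.loads(f.attrs["model"])),
                protocol=protocol_from_dict(json.loads(f.attrs["protocol"])),
                seed=int(f.attrs["seed"]),
            )

    def spikes_to_csv(self, path: str | Path) -> None:
        """Write spikes as CSV: population, neuron_index, angle_deg, time_ms."""
        import pandas as pd

        angles = np.where(self.spike_pop == POP_E,
                          self.spike_idx * (360.0 / self.n_e),
                          self.spike_idx * (360.0 / self.n_i))
        pd.DataFrame({
            "population": np.where(self.spike_pop == POP_E, "E", "I"),
            "neuron_index": self.spike_idx,
            "angle_deg": angles,
            "time_ms": self.spike_t,
        }).to_csv(path, index=False)
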