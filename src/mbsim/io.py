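"""Result container and hierarchical (NSDF-style HDF5) persistence.

Layout: /ggn/t, /ggn/Vm, /ggn/comp_mean_dv, /ig/Vm, /kc/spike_index +
/kc/spike_times (ragged raster as index+value arrays), /kc/mean_v and a
/provenance group holding the config snapshot (JSON), seed and library
versions.  All metrics in :mod:`mbsim.analysis` are pure functions of this
container, so results are recomputable offline from the file alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = ["SimulationResult", "save_result", "load_result"]


@dataclass
class SimulationResult:
    """Recorded traces, KC raster and provenance of one network run.

    ``t`` is the shared recording grid in ms; ``kc_spikes`` holds per-KC
    spike times in ms.  ``comp_mean_dv`` is the odor-window mean
    depolarization of every GGN compartment; ``kc_mean_v`` the odor-window
    mean KC membrane potential.
    """

    t: np.ndarray
    ggn_vm: np.ndarray
    kc_spikes: list[np.ndarray]
    ig_vm: np.ndarray | None = None
    comp_mean_dv: np.ndarray | None = None
    kc_mean_v: np.ndarray | None = None
    config: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def n_kc(self) -> int:
        return len(self.kc_spikes)

    def spike_counts(self, window: tuple[float, float] | None = None) -> np.ndarray:
        """Per-KC spike count, optionally restricted to a (ms, ms) window."""
        if window is None:
            return np.array([len(s) for s in self.kc_spikes])
        t0, t1 = window
        return np.array([int(np.sum((s >= t0) & (s < t1)))
                         for s in self.kc_spikes])

    def raster(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat (kc_index, spike_time_ms) arrays."""
        idx = np.concatenate([np.full(len(s), i, dtype=np.int64)
                              for i, s in enumerate(self.kc_spikes)]) \
            if self.kc_spikes else np.empty(0, dtype=np.int64)
        times = np.concatenate(self.kc_spikes) if self.kc_spikes else np.empty(0)
        return idx, times


def save_result(res: SimulationResult, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("ggn")
        g.create_dataset("t", data=res.t)
        g.create_dataset("Vm", data=res.ggn_vm)
        if res.comp_mean_dv is not None:
            g.create_dataset("comp_mean_dv", data=res.comp_mean_dv)
        kc = f.create_group("kc")
        idx, times = res.raster()
        kc.create_dataset("spike_index", data=idx)
        kc.create_dataset("spike_times", data=times)
        kc.attrs["n_kc"] = res.n_kc
        if res.kc_mean_v is not None:
            kc.create_dataset("mean_v", data=res.kc_mean_v)
        if res.ig_vm is not None:
            f.create_group("ig").create_dataset("Vm", data=res.ig_vm)
        prov = f.create_group("provenance")
        prov.attrs["config"] = json.dumps(res.config, default=str)
        prov.attrs["seed"] = res.seed
        prov.attrs["numpy_version"] = np.__version__
        prov.attrs["h5py_version"] = h5py.__version__


def load_result(path) -> SimulationResult:
    with h5py.File(path, "r") as f:
        t = f["ggn/t"][()]
        vm = f["ggn/Vm"][()]
        comp_dv = f["ggn/comp_mean_dv"][()] if "comp_mean_dv" in f["ggn"] else None
        n_kc = int(f["kc"].attrs["n_kc"])
        idx = f["kc/spike_index"][()]
        times = f["kc/spike_times"][()]
        spikes = [times[idx == i] for i in range(n_kc)]
        mean_v = f["kc/mean_v"][()] if "mean_v" in f["kc"] else None
        ig = f["ig/Vm"][()] if "ig" in f else None
        cfg = json.loads(f["provenance"].attrs["config"])
        seed = int(f["provenance"].attrs["seed"])
    return SimulationResult(t=t, ggn_vm=vm, kc_spikes=spikes, ig_vm=ig,
                            comp_mean_dv=comp_dv, kc_mean_v=mean_v,
                            config=cfg, seed=seed)
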