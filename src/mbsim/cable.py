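"""Passive electrical simulation of a compartmentalized neurite tree.

Steady-state solves under voltage clamps / current injections and implicit
(backward-Euler) transient integration with conductance-based synaptic
inputs.  GGN is a non-spiking neuron: strong current injections elicit only
passive responses, so no active conductances are modeled here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._kernels import passive_transient
from .morphology import CompartmentalModel, RegionLabel

__all__ = [
    "BiophysicsParams",
    "StimulusSet",
    "VoltageTrace",
    "steady_state",
    "transient",
    "attenuation_map",
    "conductance_matrix",
]


@dataclass(frozen=True)
class BiophysicsParams:
    """Passive membrane parameters of GGN.

    RM: membrane resistivity (kOhm.cm^2); RA: axial resistivity (Ohm.cm);
    Cm: specific capacitance (uF/cm^2); E_rest: leak reversal (mV).
    Defaults follow published locust non-spiking-neuron values (RM 33
    kOhm.cm^2, RA 100 Ohm.cm, Cm 1 uF/cm^2) with the in vivo resting
    potential of -51 mV.
    """

    RM: float = 33.0
    RA: float = 100.0
    Cm: float = 1.0
    E_rest: float = -51.0

    def __post_init__(self):
        if self.RM <= 0 or self.RA <= 0 or self.Cm <= 0:
            raise ValueError("RM, RA and Cm must be positive")


@dataclass
class StimulusSet:
    """Clamps (mV), current injections (nA) and conductance inputs (uS).

    Waveforms may be scalars (constant) or 1-D arrays sampled at the
    integration step.  A compartment may carry at most one clamp.
    """

    clamps: list[tuple[int, float | np.ndarray]] = field(default_factory=list)
    currents: list[tuple[int, float | np.ndarray]] = field(default_factory=list)
    conductances: list[tuple[int, float | np.ndarray, float]] = field(default_factory=list)

    def validate(self, n_comp: int) -> None:
        seen = set()
        for c, _ in self.clamps:
            if c in seen:
                raise ValueError(f"compartment {c} clamped twice")
            seen.add(c)
        for c in [c for c, *_ in self.clamps + self.currents + self.conductances]:
            if not 0 <= c < n_comp:
                raise IndexError(f"compartment {c} out of range")


@dataclass
class VoltageTrace:
    """Recorded voltages on a uniform time grid (ms, mV)."""

    compartments: np.ndarray
    t: np.ndarray
    v: np.ndarray  # (n_compartments, n_times)

    def delta(self, e_rest: float) -> np.ndarray:
        return self.v - e_rest


def conductance_matrix(model: CompartmentalModel) -> sp.csr_matrix:
    """Symmetric (leak + axial) conductance matrix G, uS; G v = injected nA."""
    n = model.n_comp
    rows, cols, vals = [], [], []
    for i in range(n):
        diag = model.g_leak[i]
        p = model.parent[i]
        if p >= 0:
            g = model.g_axial[i]
            diag += g
            rows += [i, p]
            cols += [p, i]
            vals += [-g, -g]
        for j in np.flatnonzero(model.parent == i):
            diag += model.g_axial[j]
        rows.append(i)
        cols.append(i)
        vals.append(diag)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def _static_diag(model: CompartmentalModel) -> np.ndarray:
    child_sum = np.bincount(
        model.parent[model.parent >= 0],
        weights=model.g_axial[model.parent >= 0],
        minlength=model.n_comp,
    )
    return model.g_leak + model.g_axial + child_sum


def steady_state(model: CompartmentalModel, stim: StimulusSet) -> np.ndarray:
    """Per-compartment steady voltage (mV) under constant stimuli.

    Solves the linear leak/axial balance with clamped compartments held
    exactly at their command value (ideal clamp, Dirichlet row replacement).
    With no stimulus every compartment sits at E_rest.
    """
    stim.validate(model.n_comp)
    n = model.n_comp
    G = conductance_matrix(model).tolil()
    b = model.g_leak * model.e_rest
    for c, i in stim.currents:
        b[c] += float(np.asarray(i).ravel()[0])
    for c, g, e in stim.conductances:
        gval = float(np.asarray(g).ravel()[0])
        G[c, c] += gval
        b[c] += gval * e
    for c, vcmd in stim.clamps:
        G.rows[c] = [c]
        G.data[c] = [1.0]
        b[c] = float(np.asarray(vcmd).ravel()[0])
    try:
        v = spla.spsolve(G.tocsr(), b)
    except RuntimeError as exc:  # pragma: no cover - singular system
        raise ValueError(f"singular cable system: {exc}") from exc
    if not np.all(np.isfinite(v)):
        raise ValueError("singular cable system (disconnected model?)")
    return v


def _as_wave(w, n_steps: int) -> np.ndarray:
    arr = np.asarray(w, dtype=float)
    if arr.ndim == 0:
        return np.full(n_steps, float(arr))
    if len(arr) < n_steps:
        out = np.zeros(n_steps)
        out[: len(arr)] = arr
        return out
    return arr[:n_steps]


def transient(model: CompartmentalModel, stim: StimulusSet, dt: float,
              duration: float, record: np.ndarray | list[int]) -> VoltageTrace:
    """Backward-Euler transient from rest; unconditionally stable.

    Converges to :func:`steady_state` for constant stimuli.  Conductance
    inputs enter the diagonal at t+dt (fully implicit in voltage).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    stim.validate(model.n_comp)
    record = np.asarray(record, dtype=np.int64)
    if np.any(record >= model.n_comp):
        raise IndexError("recorded compartment out of range")
    n_steps = int(round(duration / dt))

    def pack(entries, with_e=False):
        if not entries:
            idx = np.zeros(0, dtype=np.int64)
            wave = np.zeros((0, n_steps))
            e = np.zeros(0)
        else:
            idx = np.array([c for c, *_ in entries], dtype=np.int64)
            wave = np.stack([_as_wave(w, n_steps) for _, w, *_ in entries])
            e = np.array([r[2] for r in entries]) if with_e else np.zeros(len(entries))
        return idx, wave, e

    cl_idx, cl_wave, _ = pack(stim.clamps)
    in_idx, in_wave, _ = pack(stim.currents)
    sy_idx, sy_wave, sy_e = pack(stim.conductances, with_e=True)

    v0 = np.full(model.n_comp, model.e_rest)
    out = passive_transient(
        model.parent, model.g_axial, model.g_leak, model.cap,
        _static_diag(model), model.e_rest, dt, n_steps,
        cl_idx, cl_wave, in_idx, in_wave, sy_idx, sy_wave, sy_e,
        record, v0,
    )
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("cable transient diverged (NaN in trace)")
    t = np.arange(n_steps + 1) * dt
    return VoltageTrace(compartments=record, t=t, v=out)


def attenuation_map(model: CompartmentalModel, clamp_site: int,
                    command: float) -> dict[RegionLabel, np.ndarray]:
    """Steady-state depolarization (V - E_rest) of terminal compartments,
    grouped by region, under a single voltage clamp."""
    v = steady_state(model, StimulusSet(clamps=[(clamp_site, command)]))
    dv = v - model.e_rest
    out: dict[RegionLabel, np.ndarray] = {}
    term = model.terminal_mask()
    for label in RegionLabel:
        idx = np.flatnonzero((model.region == int(label)) & term)
        if len(idx):
            out[label] = dv[idx]
    return out
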