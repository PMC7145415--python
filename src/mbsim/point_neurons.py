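"""Point-neuron models: Hodgkin-Huxley-type Kenyon cells and the Izhikevich
regular-spiking neuron used for IG ('Inhibitor of GGN').

KCs are simulated as single compartments (their small, simple morphologies do
not differentially shape odor coding).  IG is a spiking neuron in reciprocal
inhibition with GGN, modeled with canonical regular-spiking Izhikevich
parameters plus a calibrated baseline current that sets its spontaneous rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import kc_channels
from ._kernels import kc_simulate, kc_steady_gates

__all__ = [
    "KCParams",
    "IGParams",
    "simulate_kc",
    "simulate_ig",
    "calibrate_ig_current",
    "detect_spikes",
]

SPIKE_THRESHOLD_MV = 0.0
SPIKE_REFRACTORY_MS = 2.0


@dataclass
class KCParams:
    """KC parameter vector wrapper; constants live in kc_channels.py."""

    vector: np.ndarray = field(default_factory=kc_channels.default_kc_params)

    def __post_init__(self):
        if np.any(self.vector[[1, 3, 4, 5, 6, 7]] < 0):
            raise ValueError("conductances must be non-negative")
        e_k, e_l, e_na = self.vector[9], self.vector[2], self.vector[8]
        if not (e_k < e_l < e_na):
            raise ValueError("reversals must satisfy E_K < E_leak < E_Na")


@dataclass(frozen=True)
class IGParams:
    """Izhikevich regular-spiking parameters (canonical RS values)."""

    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 8.0
    i_base: float = 0.0


def detect_spikes(t: np.ndarray, v: np.ndarray,
                  threshold: float = SPIKE_THRESHOLD_MV,
                  refractory: float = SPIKE_REFRACTORY_MS) -> np.ndarray:
    """Spike times: upward threshold crossings with a refractory period."""
    up = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold))
    times = []
    last = -np.inf
    for i in up:
        ti = t[i + 1]
        if ti - last >= refractory:
            times.append(ti)
            last = ti
    return np.array(times)


def simulate_kc(params: KCParams, i_inj, dt: float, duration: float,
                conductances: list[tuple[np.ndarray, float]] | None = None,
                v0: float | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate a single KC; returns (t, v, spike_times).

    ``i_inj`` is a scalar or waveform in nA; ``conductances`` is a list of
    (g waveform uS, reversal mV) synaptic inputs.  Deterministic.  Requires
    dt <= 0.025 ms for accuracy of the HH kinetics.
    """
    if dt > 0.025 + 1e-12:
        raise ValueError("KC integration requires dt <= 0.025 ms")
    n_steps = int(round(duration / dt))
    i_wave = np.asarray(i_inj, dtype=float)
    if i_wave.ndim == 0:
        i_wave = np.full(n_steps, float(i_wave))
    elif len(i_wave) < n_steps:
        i_wave = np.pad(i_wave, (0, n_steps - len(i_wave)))
    conductances = conductances or []
    if conductances:
        syn_g = np.stack([np.broadcast_to(np.asarray(g, dtype=float),
                                          (n_steps,)).copy()
                          if np.asarray(g).ndim else np.full(n_steps, float(g))
                          for g, _ in conductances])
        syn_e = np.array([e for _, e in conductances], dtype=float)
    else:
        syn_g = np.zeros((0, n_steps))
        syn_e = np.zeros(0)
    vec = params.vector
    if v0 is None:
        v0 = float(vec[2])
    gates0 = kc_steady_gates(vec, v0)
    v = kc_simulate(vec, v0, gates0, dt, n_steps, i_wave[:n_steps], syn_g, syn_e)
    if np.any(~np.isfinite(v)):
        raise FloatingPointError("KC simulation diverged")
    t = np.arange(n_steps + 1) * dt
    return t, v, detect_spikes(t, v)


def simulate_ig(params: IGParams, i_inj=0.0, dt: float = 0.1,
                duration: float = 1000.0,
                conductances: list[tuple[np.ndarray, float]] | None = None,
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate IG; returns (t, v, spike_times).

    Standard two-variable Izhikevich update with conductance-based synaptic
    currents (``i_syn = g * (E - v)``) added to the injected current.
    """
    if dt > 0.1 + 1e-12:
        raise ValueError("IG integration requires dt <= 0.1 ms")
    n_steps = int(round(duration / dt))
    i_wave = np.asarray(i_inj, dtype=float)
    if i_wave.ndim == 0:
        i_wave = np.full(n_steps, float(i_wave))
    conductances = conductances or []
    gs = [(np.broadcast_to(np.asarray(g, dtype=float), (n_steps,)), e)
          for g, e in conductances]
    v = params.c
    u = params.b * v
    vtr = np.empty(n_steps + 1)
    vtr[0] = v
    spikes = []
    for t in range(n_steps):
        i_syn = sum(g[t] * (e - v) for g, e in gs)
        v += dt * (0.04 * v * v + 5.0 * v + 140.0 - u
                   + params.i_base + i_wave[t] + i_syn)
        u += dt * params.a * (params.b * v - u)
        if v >= 30.0:
            vtr[t + 1] = 30.0
            v = params.c
            u += params.d
            spikes.append((t + 1) * dt)
        else:
            vtr[t + 1] = v
    tgrid = np.arange(n_steps + 1) * dt
    return tgrid, vtr, np.array(spikes)


def ig_rate(params: IGParams, current: float, duration: float = 10_000.0,
            dt: float = 0.1,
            tonic: tuple[float, float] | None = None) -> float:
    """Mean firing rate (spikes/s) at a given baseline current.

    ``tonic`` optionally adds a constant synaptic conductance (g, E_rev),
    e.g. the resting graded inhibition from GGN.
    """
    conductances = [tonic] if tonic is not None else None
    _, _, spikes = simulate_ig(
        IGParams(params.a, params.b, params.c, params.d, current),
        0.0, dt, duration, conductances=conductances)
    return len(spikes) / (duration * 1e-3)


def calibrate_ig_current(params: IGParams, target_rate: float,
                         tol: float = 0.5, bracket: tuple[float, float] = (0.0, 30.0),
                         duration: float = 10_000.0,
                         tonic: tuple[float, float] | None = None) -> float:
    """Bisect the baseline current until the spontaneous rate matches.

    The rate is measured over a ``duration`` ms simulation; raises if the
    bracket does not contain the target (f-I is monotone for the RS cell).
    """
    lo, hi = bracket
    if target_rate <= 0:
        return lo
    r_lo = ig_rate(params, lo, duration, tonic=tonic)
    r_hi = ig_rate(params, hi, duration, tonic=tonic)
    if not (r_lo <= target_rate <= r_hi):
        raise ValueError(
            f"target rate {target_rate}/s outside bracket rates "
            f"[{r_lo}, {r_hi}]")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        r = ig_rate(params, mid, duration, tonic=tonic)
        if abs(r - target_rate) <= tol:
            return mid
        if r < target_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
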