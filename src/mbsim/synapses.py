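"""Synapse models: graded (voltage-dependent release) and spike-triggered
conductances, lognormal weight sampling, and equivalent-synapse aggregation.

GGN is non-spiking: its output onto KCs and IG is a graded synapse whose
release is a sigmoid of presynaptic voltage.  Spiking projections (PN->KC,
KC->GGN, KC/PN->IG) use normalized double-exponential conductance kernels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GradedSynapseParams",
    "SpikeSynapseParams",
    "WeightDistributionSpec",
    "graded_release",
    "spike_conductance",
    "double_exp_kernel",
    "sample_weights",
    "equivalent_synapse",
]


@dataclass(frozen=True)
class GradedSynapseParams:
    """Sigmoidal graded-release synapse.

    ``s_inf(V) = 1/(1 + exp((V_half - V)/slope))`` and
    ``ds/dt = (s_inf(V_pre) - s)/tau``; conductance is ``gbar * s``.
    Defaults place half-activation at -45 mV with a 3 mV slope so a small
    tonic release exists at GGN's -51 mV rest (the baseline inhibition KCs
    receive from spontaneous GGN activity), and -80 mV reversal.
    """

    gbar: float = 1e-3
    E_rev: float = -80.0
    V_half: float = -45.0
    slope: float = 3.0
    tau: float = 4.0

    def __post_init__(self):
        if self.gbar < 0 or self.slope <= 0 or self.tau <= 0:
            raise ValueError("invalid graded synapse parameters")

    def s_inf(self, v):
        return 1.0 / (1.0 + np.exp((self.V_half - np.asarray(v)) / self.slope))


@dataclass(frozen=True)
class SpikeSynapseParams:
    """Double-exponential conductance synapse; ``weight`` is the peak (uS)."""

    weight: float = 1e-3
    E_rev: float = 0.0
    tau_rise: float = 1.0
    tau_decay: float = 5.0
    delay: float = 0.0

    def __post_init__(self):
        if not (self.tau_decay > self.tau_rise > 0) or self.delay < 0:
            raise ValueError("require tau_decay > tau_rise > 0 and delay >= 0")


@dataclass(frozen=True)
class WeightDistributionSpec:
    """Synaptic-weight distribution: uniform-constant or lognormal.

    For the lognormal family the natural-scale standard deviation equals the
    mean by default (the model's heterogeneity assumption).
    """

    family: str = "lognormal"
    mean: float = 1e-3
    sd: float | None = None

    def __post_init__(self):
        if self.family not in ("uniform-constant", "lognormal"):
            raise ValueError(f"unknown weight family {self.family!r}")
        if self.mean <= 0:
            raise ValueError("mean must be positive")


def graded_release(v_pre: np.ndarray, params: GradedSynapseParams,
                   dt: float, s0: float | None = None) -> np.ndarray:
    """Conductance trace of a graded synapse driven by ``v_pre`` (mV).

    Exponential-Euler update of the release variable s in [0, 1];
    returns ``gbar * s`` sampled on the same grid as ``v_pre``.
    """
    v_pre = np.asarray(v_pre, dtype=float)
    sinf = params.s_inf(v_pre)
    decay = math.exp(-dt / params.tau)
    s = np.empty_like(v_pre)
    cur = sinf[0] if s0 is None else s0
    for i in range(len(v_pre)):
        cur = sinf[i] + (cur - sinf[i]) * decay
        s[i] = cur
    return params.gbar * s


def _kernel_norm(tau_rise: float, tau_decay: float) -> tuple[float, float]:
    """Peak time and normalization of exp(-t/td) - exp(-t/tr)."""
    tp = (tau_rise * tau_decay / (tau_decay - tau_rise)
          * math.log(tau_decay / tau_rise))
    norm = 1.0 / (math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise))
    return tp, norm


def double_exp_kernel(params: SpikeSynapseParams, dt: float,
                      support: float | None = None) -> np.ndarray:
    """Sampled unit-response kernel (peak = weight), including the delay."""
    if support is None:
        support = params.delay + 8.0 * params.tau_decay
    n = int(round(support / dt)) + 1
    t = np.arange(n) * dt - params.delay
    _, norm = _kernel_norm(params.tau_rise, params.tau_decay)
    g = np.where(
        t >= 0,
        params.weight * norm * (np.exp(-np.maximum(t, 0) / params.tau_decay)
                                - np.exp(-np.maximum(t, 0) / params.tau_rise)),
        0.0,
    )
    return g


def spike_conductance(spikes: np.ndarray, params: SpikeSynapseParams,
                      dt: float, duration: float) -> np.ndarray:
    """Conductance trace from a spike train: linear superposition of
    double-exponential kernels, each peaking at ``weight`` uS after
    ``delay + t_peak``."""
    n = int(round(duration / dt))
    g = np.zeros(n)
    kern = double_exp_kernel(params, dt)
    for ts in np.asarray(spikes, dtype=float):
        i0 = int(round(ts / dt))
        if i0 >= n:
            continue
        k = min(len(kern), n - i0)
        g[i0:i0 + k] += kern[:k]
    return g


def sample_weights(spec: WeightDistributionSpec, n: int,
                   seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw ``n`` positive weights; deterministic for a fixed seed.

    For the lognormal family the underlying normal parameters are solved
    from the natural-scale (mean, sd): ``sigma^2 = ln(1 + sd^2/mean^2)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if spec.family == "uniform-constant":
        return np.full(n, spec.mean)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = spec.mean if spec.sd is None else spec.sd
    sigma2 = math.log(1.0 + (sd / spec.mean) ** 2)
    mu = math.log(spec.mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)


def equivalent_synapse(n_syn: int, delay_range: tuple[float, float],
                       unit_params: SpikeSynapseParams, dt: float) -> np.ndarray:
    """Aggregate kernel of ``n_syn`` unit synapses with uniform delays.

    The expected summed conductance for one presynaptic spike equals the unit
    kernel convolved with a boxcar over ``delay_range`` and scaled by
    ``n_syn``; its time-integral is exactly n_syn times the unit integral.
    Used to collapse e.g. 50,000 KC->GGN synapses with 0-60 ms delays into a
    single smeared conductance waveform.
    """
    if n_syn < 1:
        raise ValueError("n_syn must be >= 1")
    d0, d1 = delay_range
    if d1 < d0 or d0 < 0:
        raise ValueError("invalid delay range")
    unit = double_exp_kernel(unit_params, dt)
    if d1 == d0:
        kern = n_syn * unit
        if d0 > 0:
            kern = np.concatenate([np.zeros(int(round(d0 / dt))), kern])
        return kern
    n_box = max(1, int(round((d1 - d0) / dt)))
    box = np.full(n_box, 1.0 / n_box)
    kern = n_syn * np.convolve(unit, box)
    if d0 > 0:
        kern = np.concatenate([np.zeros(int(round(d0 / dt))), kern])
    return kern
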