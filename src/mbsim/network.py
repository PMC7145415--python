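"""Full mushroom-body circuit: PN drive -> KC population -> GGN cable ->
graded feedback to KCs, with optional IG in several wiring variants.

Every KC receives input from half of the PN population, sends one excitatory
synapse to a random alpha-lobe terminal of GGN, and receives one graded
inhibitory synapse from a random calyceal compartment.  A conductance
multiplier (50,000 / n_kc) applied to the KC->GGN weights preserves the total
excitatory drive onto GGN when the KC population is scaled down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernels
from .io import SimulationResult
from .kc_channels import default_kc_params
from .morphology import CompartmentalModel, RegionLabel, CALYX_REGIONS
from .point_neurons import IGParams, calibrate_ig_current
from .synapses import (GradedSynapseParams, SpikeSynapseParams,
                       WeightDistributionSpec, sample_weights, _kernel_norm)

__all__ = [
    "NetworkConfig",
    "Network",
    "build_network",
    "calibrate_kc_inhibition",
    "run_network",
    "expected_shared_inputs",
    "pn_kc_delay_ceiling",
    "shared_input_counts",
]

FULL_KC_COUNT = 50_000

IG_ABSENT = "absent"
IG_RECIPROCAL = "reciprocal"
IG_KC_DRIVE = "reciprocal+KC_drive"
IG_PN_DRIVE = "reciprocal+PN_drive"
_IG_MODES = {IG_ABSENT: 0, IG_RECIPROCAL: 1, IG_KC_DRIVE: 2, IG_PN_DRIVE: 3}


def expected_shared_inputs(m: int, n: int, q: int) -> float:
    """Expected intersection of two independent uniform subsets of sizes m, n
    drawn from q elements: s = m*n/q.  With 800 PNs and 400 per KC this gives
    200 shared PNs, i.e. two KCs share about half their inputs."""
    return m * n / q


def pn_kc_delay_ceiling(axon_length_um: float = 1500.0,
                        speed_m_per_s: float = 0.2) -> float:
    """Upper bound on the PN->KC conduction delay in ms.

    A conservative dendritic propagation speed of 0.2 m/s (= 200 um/ms) over
    the ~1500 um PN axon bounds the delay at 7.5 ms, motivating the
    normal(7.5, 3) ms delay distribution of the delay-diversity variant.
    """
    return axon_length_um / (speed_m_per_s * 1e3)


@dataclass
class NetworkConfig:
    """Wiring, weight and delay specification of the circuit.

    Synaptic weights are peak conductances in uS.  ``weight_family``
    ("uniform-constant" or "lognormal", sd = mean) applies to the PN->KC and
    GGN->KC projections — the heterogeneity the sustained-response result
    depends on.  ``kc_scaling`` defaults to 50,000 / n_kc.
    """

    n_kc: int = 5000
    pn_per_kc_fraction: float = 0.5
    weight_family: str = "lognormal"
    w_pn_kc_mean: float = 1.2e-4          # uS, peak EPSG per PN spike
    w_kc_ggn_unit: float = 3.0e-4         # uS, per-KC synapse before scaling
    ggn_kc_gbar_mean: float = 4.5e-2      # uS, graded gbar (calibrated)
    pn_kc_delay: tuple[float, float] | None = None  # normal(mean, sd) ms
    kc_scaling: float | None = None
    # synapse kinetics (ms); one set for all spiking projections
    tau_rise: float = 1.0
    tau_decay: float = 10.0
    graded: GradedSynapseParams = field(default_factory=GradedSynapseParams)
    # IG
    ig_variant: str = IG_ABSENT
    ig_params: IGParams = field(default_factory=IGParams)
    ig_target_rate: float = 7.0           # spontaneous spikes/s
    ig_to_ggn_weight: float = 0.03        # uS, ~1 mV IPSP at the rec. site
    ig_to_ggn_tau: float = 10.0           # ms decay
    ggn_to_ig_gbar: float = 0.5           # Izhikevich conductance units
    kc_ig_delay: float = 200.0            # ms
    kc_ig_weight_mean: float = 2.0e-3     # Izhikevich units, lognormal
    pn_ig_weight: float = 5.0e-3          # Izhikevich units
    ig_syn_tau_rise: float = 1.0
    ig_syn_tau_decay: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_kc < 1:
            raise ValueError("n_kc must be >= 1")
        if not 0.0 < self.pn_per_kc_fraction <= 1.0:
            raise ValueError("pn_per_kc_fraction must lie in (0, 1]")
        if self.ig_variant not in _IG_MODES:
            raise ValueError(f"unknown ig_variant {self.ig_variant!r}")
        if self.kc_scaling is None:
            self.kc_scaling = FULL_KC_COUNT / self.n_kc
        if self.kc_scaling <= 0:
            raise ValueError("kc_scaling must be positive")

    def snapshot(self) -> dict:
        d = asdict(self)
        return d


class NetworkBuildError(RuntimeError):
    pass


@dataclass
class Network:
    """Assembled circuit: GGN compartmental model plus wiring tables."""

    config: NetworkConfig
    model: CompartmentalModel
    pn_targets: np.ndarray       # (n_kc, k) presynaptic PN ids per KC
    pn_kc_w: np.ndarray          # (n_kc, k) per-synapse weights, uS
    pn_kc_delay_ms: np.ndarray   # (n_kc, k) per-synapse delays, ms
    kc_target: np.ndarray        # (n_kc,) GGN alpha-lobe compartment per KC
    kc_w_ggn: np.ndarray         # (n_kc,) scaled KC->GGN weight, uS
    kc_comp: np.ndarray          # (n_kc,) assigned calyceal compartment
    kc_gbar: np.ndarray          # (n_kc,) graded GGN->KC gbar, uS
    kc_alive: np.ndarray         # (n_kc,) bool, False once ablated
    rec_comp: int                # base of the alpha-lobe branch
    ig_comp: int = -1            # basal compartment hosting the IG synapses
    ig_i_base: float | None = None
    kc_ig_w: np.ndarray | None = None

    @property
    def n_kc(self) -> int:
        return len(self.kc_target)

    @property
    def n_pn(self) -> int:
        return int(self.pn_targets.max()) + 1 if self.pn_targets.size else 0


def _alpha_lobe_stem(model: CompartmentalModel) -> int:
    """First alpha-lobe compartment on the path from the basal branch
    (the in vivo recording site at the base of the alpha-lobe branch)."""
    alpha = int(RegionLabel.ALPHA_LOBE)
    for i in range(model.n_comp):
        if model.region[i] == alpha:
            p = model.parent[i]
            if p < 0 or model.region[p] != alpha:
                return i
    raise NetworkBuildError("model has no ALPHA_LOBE compartments")


def build_network(config: NetworkConfig, model: CompartmentalModel,
                  n_pn: int = 830, seed: int | None = None) -> Network:
    """Wire the circuit; deterministic for fixed (config, seed).

    Each KC's presynaptic PN set is an independent uniform sample of exactly
    ``round(fraction * n_pn)`` PNs; KC->GGN synapses sit uniformly at random
    on alpha-lobe terminal compartments and GGN->KC graded sources uniformly
    over calyceal compartments.  IG, when present, shares one basal
    compartment for its inhibitory synapse onto GGN (E_rev -80 mV) and the
    graded GGN->IG synapse.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    alpha_term = model.region_indices(RegionLabel.ALPHA_LOBE, terminal_only=True)
    calyx = np.concatenate([model.region_indices(r) for r in CALYX_REGIONS])
    if len(alpha_term) == 0 or len(calyx) == 0:
        raise NetworkBuildError("GGN model lacks alpha-lobe or calyceal regions")

    n_kc = config.n_kc
    k = round(config.pn_per_kc_fraction * n_pn)
    pn_targets = np.empty((n_kc, k), dtype=np.int64)
    for i in range(n_kc):
        pn_targets[i] = rng.choice(n_pn, size=k, replace=False)

    wspec = WeightDistributionSpec(config.weight_family, config.w_pn_kc_mean)
    pn_kc_w = sample_weights(wspec, n_kc * k, rng).reshape(n_kc, k)
    if config.pn_kc_delay is not None:
        mu, sd = config.pn_kc_delay
        delays = np.clip(rng.normal(mu, sd, size=(n_kc, k)), 0.0, None)
    else:
        delays = np.zeros((n_kc, k))

    kc_target = rng.choice(alpha_term, size=n_kc)
    kc_w_ggn = np.full(n_kc, config.w_kc_ggn_unit * config.kc_scaling)
    kc_comp = rng.choice(calyx, size=n_kc)
    gspec = WeightDistributionSpec(config.weight_family, config.ggn_kc_gbar_mean)
    kc_gbar = sample_weights(gspec, n_kc, rng)

    ig_comp = -1
    kc_ig_w = None
    if config.ig_variant != IG_ABSENT:
        basal = model.region_indices(RegionLabel.BASAL)
        if len(basal) == 0:
            raise NetworkBuildError("IG wiring requires BASAL compartments")
        ig_comp = int(basal[len(basal) // 2])
        # lognormal per-KC weights; kc_scaling preserves total drive onto IG
        # when the KC population is scaled down
        kc_ig_w = sample_weights(
            WeightDistributionSpec("lognormal", config.kc_ig_weight_mean),
            n_kc, rng) * config.kc_scaling

    return Network(
        config=config, model=model,
        pn_targets=pn_targets, pn_kc_w=pn_kc_w, pn_kc_delay_ms=delays,
        kc_target=kc_target, kc_w_ggn=kc_w_ggn,
        kc_comp=kc_comp, kc_gbar=kc_gbar,
        kc_alive=np.ones(n_kc, dtype=bool),
        rec_comp=_alpha_lobe_stem(model),
        ig_comp=ig_comp, kc_ig_w=kc_ig_w,
    )


def shared_input_counts(network: Network, n_pairs: int = 1000,
                        seed: int = 0) -> np.ndarray:
    """Shared-presynaptic-PN counts over random KC pairs (Monte Carlo check
    of the s = m*n/q connectivity expectation)."""
    rng = np.random.default_rng(seed)
    n_kc = network.n_kc
    counts = np.empty(n_pairs, dtype=np.int64)
    sets = [set(row) for row in network.pn_targets]
    for p in range(n_pairs):
        i, j = rng.choice(n_kc, size=2, replace=False)
        counts[p] = len(sets[i] & sets[j])
    return counts


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _build_events(network: Network, pn_trains, dt: float,
                  n_steps: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten PN spikes into per-(spike, KC) arrival events sorted by step."""
    n_pn = len(pn_trains.spikes)
    targets_of_pn: list[list[int]] = [[] for _ in range(n_pn)]
    slot_of_pn: list[list[int]] = [[] for _ in range(n_pn)]
    for kc in range(network.n_kc):
        if not network.kc_alive[kc]:
            continue
        for slot, pn in enumerate(network.pn_targets[kc]):
            targets_of_pn[pn].append(kc)
            slot_of_pn[pn].append(slot)
    steps_l, kcs_l, ws_l = [], [], []
    for pn in range(n_pn):
        tg = np.asarray(targets_of_pn[pn], dtype=np.int64)
        if len(tg) == 0 or len(pn_trains.spikes[pn]) == 0:
            continue
        sl = np.asarray(slot_of_pn[pn], dtype=np.int64)
        t_ms = pn_trains.spikes[pn] * 1e3
        d_ms = network.pn_kc_delay_ms[tg, sl]
        arr = (t_ms[:, None] + d_ms[None, :]) / dt
        steps = np.rint(arr).astype(np.int64).ravel()
        kcs = np.broadcast_to(tg, (len(t_ms), len(tg))).ravel()
        ws = np.broadcast_to(network.pn_kc_w[tg, sl], (len(t_ms), len(tg))).ravel()
        ok = steps < n_steps
        steps_l.append(steps[ok])
        kcs_l.append(kcs[ok])
        ws_l.append(ws[ok])
    if not steps_l:
        return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64),
                np.empty(0))
    steps = np.concatenate(steps_l)
    order = np.argsort(steps, kind="stable")
    return (steps[order],
            np.concatenate(kcs_l)[order].astype(np.int64),
            np.concatenate(ws_l)[order].astype(float))


def run_network(network: Network, pn_trains, duration: float,
                dt: float = 0.025, record_ds: int = 20,
                window: tuple[float, float] | None = None,
                i_kc=None, agg_kernel: np.ndarray | None = None,
                pn_ig_trains=None) -> SimulationResult:
    """Co-simulate the circuit for ``duration`` ms; returns traces + raster.

    Per-step coupling contract: PN spikes drive KC conductances; KC spikes
    drive GGN alpha-lobe conductances; each KC's graded inhibition reads its
    assigned calyceal compartment's voltage from the previous step; IG
    exchanges graded/spiking input with GGN according to the wiring variant.
    ``window`` (ms) bounds the averaging window for per-compartment and
    per-KC mean voltages (defaults to the full run).
    """
    if dt > 0.025 + 1e-12:
        raise ValueError("network integration requires dt <= 0.025 ms")
    cfg = network.config
    model = network.model
    n_steps = int(round(duration / dt))
    if window is None:
        window = (0.0, duration)
    win0, win1 = int(window[0] / dt), int(window[1] / dt)

    ev_step, ev_kc, ev_w = _build_events(network, pn_trains, dt, n_steps)

    child_sum = np.bincount(model.parent[model.parent >= 0],
                            weights=model.g_axial[model.parent >= 0],
                            minlength=model.n_comp)
    diag_static = model.g_leak + model.g_axial + child_sum

    kcp = default_kc_params()
    kc_v = np.full(network.n_kc, kcp[2])
    g0 = _kernels.kc_steady_gates(kcp, kcp[2])
    kc_gates = np.tile(g0, (network.n_kc, 1))

    def dexp(tr, td):
        _, norm = _kernel_norm(tr, td)
        return math.exp(-dt / td), math.exp(-dt / tr), norm

    fd_exc, fr_exc, norm_exc = dexp(cfg.tau_rise, cfg.tau_decay)
    fd_pn, fr_pn, norm_pn = dexp(cfg.tau_rise, cfg.tau_decay)
    fd_ig2ggn, fr_ig2ggn, norm_ig2ggn = dexp(1.0, cfg.ig_to_ggn_tau)
    fd_igsyn, fr_igsyn, norm_igsyn = dexp(cfg.ig_syn_tau_rise, cfg.ig_syn_tau_decay)

    gr = cfg.graded

    if i_kc is None:
        i_kc_arr = np.zeros(n_steps)
    else:
        i_kc_arr = np.broadcast_to(np.asarray(i_kc, dtype=float), (n_steps,)).copy()

    if agg_kernel is None:
        agg_kernel = np.empty(0)
        agg_comps = np.zeros(1, dtype=np.int64)
    else:
        # spread the equivalent synapse over the whole alpha-lobe terminal set
        agg_comps = model.region_indices(RegionLabel.ALPHA_LOBE,
                                         terminal_only=True)

    ig_mode = _IG_MODES[cfg.ig_variant]
    if ig_mode >= 1 and network.ig_i_base is None:
        # calibrate against the tonic graded inhibition GGN exerts at rest
        tonic_g = cfg.ggn_to_ig_gbar * float(gr.s_inf(model.e_rest))
        network.ig_i_base = calibrate_ig_current(
            cfg.ig_params, cfg.ig_target_rate, tonic=(tonic_g, gr.E_rev))
    igp = cfg.ig_params
    kc_ig_delay_steps = int(round(cfg.kc_ig_delay / dt))
    kc_ig_w = network.kc_ig_w if network.kc_ig_w is not None \
        else np.zeros(network.n_kc)

    pn_ig_inc = np.zeros(0)
    if ig_mode == 3 and pn_ig_trains is not None:
        pn_ig_inc = np.zeros(n_steps)
        for s in pn_ig_trains.spikes:
            steps = np.rint(s * 1e3 / dt).astype(np.int64)
            steps = steps[steps < n_steps]
            np.add.at(pn_ig_inc, steps, cfg.pn_ig_weight)

    max_spikes = network.n_kc * 64 + 4096
    spk_t = np.empty(max_spikes)
    spk_kc = np.empty(max_spikes, dtype=np.int64)

    n_spk, ggn_rec, ig_rec, comp_vsum, kc_vsum = _kernels.network_sim(
        n_steps, dt, record_ds,
        model.parent, model.g_axial, model.g_leak, model.cap, diag_static,
        model.e_rest,
        fd_exc, fr_exc, norm_exc,
        kcp, kc_v, kc_gates, network.kc_alive,
        ev_step, ev_kc, ev_w,
        fd_pn, fr_pn, norm_pn,
        network.kc_comp, network.kc_gbar, gr.V_half, gr.slope, gr.tau, gr.E_rev,
        network.kc_target, network.kc_w_ggn,
        agg_kernel, agg_comps,
        i_kc_arr,
        ig_mode, igp.a, igp.b, igp.c, igp.d,
        network.ig_i_base if network.ig_i_base is not None else 0.0,
        max(network.ig_comp, 0),
        fd_ig2ggn, fr_ig2ggn, norm_ig2ggn, cfg.ig_to_ggn_weight,
        cfg.ggn_to_ig_gbar, gr.tau,
        kc_ig_delay_steps, kc_ig_w, pn_ig_inc,
        fd_igsyn, fr_igsyn, norm_igsyn,
        network.rec_comp, win0, win1,
        spk_t, spk_kc,
    )
    if not np.all(np.isfinite(ggn_rec)):
        raise FloatingPointError("network simulation diverged")

    spikes_per_kc: list[np.ndarray] = [np.empty(0)] * network.n_kc
    if n_spk:
        order = np.argsort(spk_kc[:n_spk], kind="stable")
        kcs = spk_kc[:n_spk][order]
        ts = spk_t[:n_spk][order]
        bounds = np.searchsorted(kcs, np.arange(network.n_kc + 1))
        spikes_per_kc = [ts[bounds[i]:bounds[i + 1]]
                         for i in range(network.n_kc)]

    t = np.arange(len(ggn_rec)) * dt * record_ds
    return SimulationResult(
        t=t, ggn_vm=ggn_rec,
        kc_spikes=spikes_per_kc,
        ig_vm=ig_rec if ig_mode >= 1 else None,
        comp_mean_dv=comp_vsum - model.e_rest,
        kc_mean_v=kc_vsum,
        config=network.config.snapshot(), seed=cfg.seed,
    )


def calibrate_kc_inhibition(network: Network, pn_trains, duration: float = 2000.0,
                            target: tuple[float, float] = (-61.0, -59.0),
                            max_iter: int = 12) -> float:
    """Bisection on the mean graded gbar until the median KC membrane
    potential under spontaneous PN drive falls in ``target`` (mV).

    Scales ``network.kc_gbar`` in place and returns the applied scale.
    Establishes the bracket from the uninhibited run (gbar = 0 leaves the
    median above -60 mV under spontaneous bombardment).
    """
    base = network.kc_gbar.copy()
    lo_t, hi_t = target
    mid_t = 0.5 * (lo_t + hi_t)

    def median_v(scale: float) -> float:
        network.kc_gbar = base * scale
        res = run_network(network, pn_trains, duration,
                          window=(duration * 0.25, duration))
        return float(np.median(res.kc_mean_v))

    lo, hi = 0.0, 1.0
    v_hi = median_v(hi)
    guard = 0
    while v_hi > mid_t:
        lo, hi = hi, hi * 4.0
        v_hi = median_v(hi)
        guard += 1
        if guard > 6:
            raise RuntimeError("KC inhibition calibration: bracket failure")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        v = median_v(mid)
        if lo_t <= v <= hi_t:
            network.kc_gbar = base * mid
            return mid
        if v > mid_t:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    network.kc_gbar = base * mid
    return mid
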