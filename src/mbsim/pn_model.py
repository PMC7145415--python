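"""Synthetic projection-neuron (PN) population activity.

PNs are the model's only input: spike trains with the firing statistics of
locust antennal-lobe PNs.  77% of PNs are spontaneously active at 2.6
spikes/s; during an odor, 20% are excited to 20 spikes/s modulated by the
20 Hz LFP oscillation (modulation amplitude 0.4 x rate) and 10% of the
spontaneously active PNs are inhibited (silenced).  A second, "shifting"
scheme splits the responsive PNs into four groups with epoch sequences
EEI / EIE / IEI / IIE and per-LFP-cycle recruitment, so the active set
evolves over the odor presentation.  Spike trains are sampled with an
inhomogeneous-Poisson thinning algorithm, deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "PNPopulationConfig",
    "PNRates",
    "SpikeTrainSet",
    "rates_fixed",
    "rates_shifting",
    "sample_poisson",
    "CLASS_SILENT",
    "CLASS_SPONTANEOUS",
    "CLASS_EXCITED",
    "CLASS_INHIBITED",
    "CLASS_SHIFTING",
]

CLASS_SILENT = 0       # never spikes
CLASS_SPONTANEOUS = 1  # background rate throughout
CLASS_EXCITED = 2      # odor-excited (fixed scheme)
CLASS_INHIBITED = 3    # silenced during odor
CLASS_SHIFTING = 4     # member of a shifting responsive group

GROUP_PATTERNS = ("EEI", "EIE", "IEI", "IIE")


@dataclass(frozen=True)
class PNPopulationConfig:
    """Population statistics of the PN drive (rates in spikes/s, times in s)."""

    n_pn: int = 830
    frac_spontaneous: float = 0.77
    spont_rate: float = 2.6
    frac_excited: float = 0.20
    odor_rate: float = 20.0
    frac_inhibited: float = 0.10   # fraction of the spontaneously active pool
    lfp_freq: float = 20.0
    lfp_mod: float = 0.4           # fraction of the odor rate
    odor_window: tuple[float, float] = (1.0, 2.0)
    off_epoch: float = 0.5
    scheme: str = "fixed"
    frac_unresponsive: float = 0.30  # shifting scheme only

    def __post_init__(self):
        for f in (self.frac_spontaneous, self.frac_excited,
                  self.frac_inhibited, self.frac_unresponsive):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.spont_rate < 0 or self.odor_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.scheme not in ("fixed", "shifting"):
            raise ValueError("scheme must be 'fixed' or 'shifting'")

    @property
    def counts(self) -> dict[str, int]:
        """Deterministic class counts (rounded to nearest integer)."""
        n_spont = round(self.frac_spontaneous * self.n_pn)
        n_exc = round(self.frac_excited * self.n_pn)
        n_inh = round(self.frac_inhibited * n_spont)
        return {
            "spontaneous": n_spont,
            "excited": n_exc,
            "inhibited": n_inh,
            "silent": self.n_pn - n_spont,
        }


@dataclass
class PNRates:
    """Per-PN rate functions with population metadata.

    ``rate(i, t)`` evaluates PN i's instantaneous rate (spikes/s) at times t
    (s, array); ``max_rate`` bounds it for Poisson thinning.
    """

    config: PNPopulationConfig
    response_class: np.ndarray            # (n_pn,) class codes
    group_id: np.ndarray                  # (n_pn,) -1 or group 0..3
    recruit_cycle: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    # recruit_cycle[(group, epoch)] -> per-member recruitment cycle index
    member_index: np.ndarray | None = None  # (n_pn,) position within own group

    @property
    def n_pn(self) -> int:
        return self.config.n_pn

    @property
    def max_rate(self) -> float:
        c = self.config
        return max(c.spont_rate, c.odor_rate * (1.0 + c.lfp_mod))

    def _lfp_rate(self, t: np.ndarray) -> np.ndarray:
        c = self.config
        onset = c.odor_window[0]
        return c.odor_rate * (1.0 + c.lfp_mod
                              * np.sin(2.0 * np.pi * c.lfp_freq * (t - onset)))

    def _epochs(self) -> list[tuple[float, float]]:
        on, off = self.config.odor_window
        mid = 0.5 * (on + off)
        return [(on, mid), (mid, off), (off, off + self.config.off_epoch)]

    def rate(self, i: int, t: np.ndarray) -> np.ndarray:
        c = self.config
        t = np.asarray(t, dtype=float)
        cls = self.response_class[i]
        on, off = c.odor_window
        in_odor = (t >= on) & (t < off)
        if cls == CLASS_SILENT:
            return np.zeros_like(t)
        if cls == CLASS_SPONTANEOUS:
            return np.full_like(t, c.spont_rate)
        if cls == CLASS_EXCITED:
            r = np.full_like(t, c.spont_rate)
            r[in_odor] = self._lfp_rate(t[in_odor])
            return r
        if cls == CLASS_INHIBITED:
            r = np.full_like(t, c.spont_rate)
            r[in_odor] = 0.0
            return r
        # shifting-group member
        g = int(self.group_id[i])
        pattern = GROUP_PATTERNS[g]
        member = int(self.member_index[i])
        r = np.full_like(t, c.spont_rate)
        cycle_len = 1.0 / c.lfp_freq
        for e, (t0, t1) in enumerate(self._epochs()):
            sel = (t >= t0) & (t < t1)
            if not sel.any():
                continue
            if pattern[e] == "I":
                r[sel] = 0.0
            else:
                cyc = np.floor((t[sel] - t0) / cycle_len).astype(int)
                active = self.recruit_cycle[(g, e)][member] <= cyc
                re = np.where(active, self._lfp_rate(t[sel]), 0.0)
                r[sel] = re
        return r


def _assign_classes(config: PNPopulationConfig, rng: np.random.Generator):
    counts = config.counts
    cls = np.full(config.n_pn, CLASS_SILENT, dtype=np.int64)
    perm = rng.permutation(config.n_pn)
    spont = perm[: counts["spontaneous"]]
    cls[spont] = CLASS_SPONTANEOUS
    resp = rng.permutation(spont)
    cls[resp[: counts["excited"]]] = CLASS_EXCITED
    cls[resp[counts["excited"]: counts["excited"] + counts["inhibited"]]] = CLASS_INHIBITED
    return cls


def rates_fixed(config: PNPopulationConfig, seed: int = 0) -> PNRates:
    """Fixed-responsive-population scheme.

    Class counts are exact: round(0.77 n) spontaneous, round(0.20 n) excited
    and round(0.10 x spontaneous) inhibited, the latter two drawn from the
    spontaneous pool.  Excited PNs fire at the LFP-modulated odor rate during
    the odor window and at the spontaneous rate outside it.
    """
    if config.scheme != "fixed":
        raise ValueError("config.scheme must be 'fixed'")
    rng = np.random.default_rng(seed)
    cls = _assign_classes(config, rng)
    return PNRates(config, cls, np.full(config.n_pn, -1, dtype=np.int64))


def rates_shifting(config: PNPopulationConfig, seed: int = 0) -> PNRates:
    """Shifting-responsive-population scheme.

    ~30% of PNs are unresponsive (spontaneous rate throughout); the rest are
    split into four equal groups with odor-epoch sequences EEI, EIE, IEI and
    IIE (epoch 3 begins at stimulus offset).  Within an excitatory epoch a
    group starts with 70% of its members active and recruits 10% per LFP
    cycle over the next three cycles; recruitment is cumulative within an
    epoch and reshuffled between epochs, so the active composition shifts.
    """
    if config.scheme != "shifting":
        raise ValueError("config.scheme must be 'shifting'")
    rng = np.random.default_rng(seed)
    n = config.n_pn
    group_size = int(round((1.0 - config.frac_unresponsive) * n / 4.0))
    cls = np.full(n, CLASS_SPONTANEOUS, dtype=np.int64)
    gid = np.full(n, -1, dtype=np.int64)
    perm = rng.permutation(n)
    member_index = np.full(n, -1, dtype=np.int64)
    for g in range(4):
        members = perm[g * group_size: (g + 1) * group_size]
        cls[members] = CLASS_SHIFTING
        gid[members] = g
        member_index[members] = np.arange(group_size)
    rates = PNRates(config, cls, gid, member_index=member_index)
    for g in range(4):
        for e, code in enumerate(GROUP_PATTERNS[g]):
            if code != "E":
                continue
            order = rng.permutation(group_size)
            rc = np.full(group_size, 0, dtype=np.int64)
            n0 = int(round(0.7 * group_size))
            n_step = int(round(0.1 * group_size))
            rc[order[:n0]] = 0
            for c in range(1, 4):
                lo = n0 + (c - 1) * n_step
                hi = group_size if c == 3 else n0 + c * n_step
                rc[order[lo:hi]] = c
            rates.recruit_cycle[(g, e)] = rc
    return rates


@dataclass
class SpikeTrainSet:
    """Per-PN spike-time lists (seconds) plus population metadata."""

    spikes: list[np.ndarray]
    response_class: np.ndarray
    group_id: np.ndarray
    config: PNPopulationConfig
    seed: int
    duration: float

    @property
    def n_trains(self) -> int:
        return len(self.spikes)

    def pooled_rate(self, classes=None, window=None) -> float:
        """Mean rate (spikes/s) pooled over trains, optionally by class/window."""
        idx = range(self.n_trains) if classes is None else \
            np.flatnonzero(np.isin(self.response_class, list(classes)))
        t0, t1 = window if window is not None else (0.0, self.duration)
        total = sum(int(np.sum((self.spikes[i] >= t0) & (self.spikes[i] < t1)))
                    for i in idx)
        n = len(list(idx))
        return total / (n * (t1 - t0)) if n else 0.0

    def as_config_snapshot(self) -> dict:
        return asdict(self.config)


def sample_poisson(rates: PNRates, seed: int, duration: float) -> SpikeTrainSet:
    """Sample independent spike trains by Poisson thinning.

    Candidate events are drawn at the rate bound and kept with probability
    ``rate(t)/bound``; deterministic for a fixed seed, spike times sorted.
    """
    rng = np.random.default_rng(seed)
    bound = rates.max_rate
    trains: list[np.ndarray] = []
    for i in range(rates.n_pn):
        if bound <= 0:
            trains.append(np.empty(0))
            continue
        n_cand = rng.poisson(bound * duration)
        t_cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
        u = rng.uniform(0.0, 1.0, size=n_cand)
        keep = u < rates.rate(i, t_cand) / bound
        trains.append(t_cand[keep])
    return SpikeTrainSet(
        spikes=trains,
        response_class=rates.response_class.copy(),
        group_id=rates.group_id.copy(),
        config=rates.config,
        seed=seed,
        duration=duration,
    )
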