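"""Spike and voltage analysis: PSTHs, rate smoothing, sustainedness and
synchrony of the GGN response, IPSP detection, and dynamic-range slopes."""

from __future__ import annotations

import numpy as np
import scipy.signal

__all__ = [
    "population_psth",
    "gaussian_rate",
    "sustainedness_index",
    "synchrony_index",
    "lowpass_49hz",
    "detect_ipsps",
    "dynamic_range_slope",
    "kc_ggn_local_correlation",
]


def population_psth(spike_times: np.ndarray, bin_ms: float,
                    t_range: tuple[float, float] | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Population spike-time histogram; returns (bin_edges, counts).

    Total spike count is preserved: counts sum to the raster size within
    ``t_range``.
    """
    if bin_ms <= 0:
        raise ValueError("bin width must be positive")
    spike_times = np.asarray(spike_times, dtype=float)
    if t_range is None:
        hi = spike_times.max() if len(spike_times) else bin_ms
        t_range = (0.0, hi)
    n_bins = max(1, int(np.ceil((t_range[1] - t_range[0]) / bin_ms)))
    edges = t_range[0] + np.arange(n_bins + 1) * bin_ms
    counts, _ = np.histogram(spike_times, bins=edges)
    return edges, counts


def gaussian_rate(spike_times: np.ndarray, sigma_ms: float,
                  t_grid: np.ndarray) -> np.ndarray:
    """Gaussian-smoothed rate function (events/ms on ``t_grid``).

    Each spike contributes a unit-integral Gaussian kernel of SD
    ``sigma_ms``, so the integral of the rate equals the spike count.
    """
    if sigma_ms <= 0:
        raise ValueError("sigma must be positive")
    spike_times = np.asarray(spike_times, dtype=float)
    rate = np.zeros_like(t_grid, dtype=float)
    norm = 1.0 / (sigma_ms * np.sqrt(2.0 * np.pi))
    for ts in spike_times:
        rate += norm * np.exp(-0.5 * ((t_grid - ts) / sigma_ms) ** 2)
    return rate


def sustainedness_index(t: np.ndarray, vm: np.ndarray,
                        odor_window: tuple[float, float],
                        baseline_window: tuple[float, float] | None = None,
                        threshold: float = 2.0, bin_ms: float = 100.0) -> float:
    """Fraction of 100 ms bins in the odor window depolarized >= threshold.

    Quantifies 'sustained depolarization' versus 'isolated peaks': a GGN
    trace continuously >= 2 mV above baseline through the odor scores 1.0; a
    single 100 ms peak in a 1 s window scores 0.1.  The 2 mV default is the
    depolarization sufficient for graded transmission.
    """
    t = np.asarray(t, dtype=float)
    vm = np.asarray(vm, dtype=float)
    if baseline_window is None:
        baseline_window = (0.0, odor_window[0])
    bsel = (t >= baseline_window[0]) & (t < baseline_window[1])
    base = vm[bsel].mean() if bsel.any() else vm[0]
    t0, t1 = odor_window
    n_bins = max(1, int(round((t1 - t0) / bin_ms)))
    hits = 0
    for b in range(n_bins):
        sel = (t >= t0 + b * bin_ms) & (t < t0 + (b + 1) * bin_ms)
        if sel.any() and (vm[sel].mean() - base) >= threshold:
            hits += 1
    return hits / n_bins


def synchrony_index(spike_times: np.ndarray,
                    window: tuple[float, float], bin_ms: float = 50.0) -> float:
    """Fraction of the window's spikes falling in its single busiest bin.

    High for a few synchronized population bouts, low for temporally diffuse
    spiking.  Returns 0 for an empty raster.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    sel = (spike_times >= window[0]) & (spike_times < window[1])
    if not sel.any():
        return 0.0
    _, counts = population_psth(spike_times[sel], bin_ms, window)
    return float(counts.max() / counts.sum())


def lowpass_49hz(t_ms: np.ndarray, vm: np.ndarray,
                 cutoff_hz: float = 49.0) -> np.ndarray:
    """Zero-phase low-pass at 49 Hz (the in vivo trace conditioning)."""
    dt_s = (t_ms[1] - t_ms[0]) * 1e-3
    nyq = 0.5 / dt_s
    if cutoff_hz >= nyq:
        return vm.copy()
    b, a = scipy.signal.butter(4, cutoff_hz / nyq)
    return scipy.signal.filtfilt(b, a, vm)


def detect_ipsps(t_ms: np.ndarray, vm: np.ndarray,
                 min_amplitude: float = 0.5, refractory: float = 20.0,
                 baseline_ms: float = 200.0) -> np.ndarray:
    """IPSP peak times (ms): median-filter detrended negative deflections.

    The trace is detrended with a running-median baseline (``baseline_ms``
    window); local minima deeper than ``min_amplitude`` below baseline are
    time-stamped, with a ``refractory`` dead time between events.
    """
    t_ms = np.asarray(t_ms, dtype=float)
    vm = np.asarray(vm, dtype=float)
    dt = t_ms[1] - t_ms[0]
    if t_ms[-1] - t_ms[0] <= refractory:
        raise ValueError("trace shorter than refractory period")
    k = max(3, int(round(baseline_ms / dt)) | 1)
    base = scipy.signal.medfilt(vm, kernel_size=min(k, len(vm) - (len(vm) + 1) % 2))
    resid = vm - base
    dist = max(1, int(round(refractory / dt)))
    peaks, _ = scipy.signal.find_peaks(-resid, height=min_amplitude,
                                       distance=dist)
    return t_ms[peaks]


def dynamic_range_slope(amplitudes: np.ndarray, counts: np.ndarray,
                        ref_slope: float | None = None) -> float:
    """Least-squares slope of the contiguous rising branch of a
    spike-count-versus-current curve, optionally normalized by a reference
    (isolated-KC) slope.

    The rising branch runs from the first nonzero count to the maximum-count
    amplitude.  Raises ``ValueError`` if fewer than 3 points lie on it.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    counts = np.asarray(counts, dtype=float)
    nz = np.flatnonzero(counts > 0)
    if len(nz) == 0:
        raise ValueError("no spiking anywhere on the curve")
    i0 = nz[0]
    i1 = int(np.argmax(counts))
    if i1 - i0 + 1 < 3:
        raise ValueError("fewer than 3 points on the rising branch")
    x = amplitudes[i0:i1 + 1]
    y = counts[i0:i1 + 1]
    slope = float(np.polyfit(x, y, 1)[0])
    return slope / ref_slope if ref_slope else slope


def kc_ggn_local_correlation(spike_counts: np.ndarray,
                             local_dv: np.ndarray) -> float:
    """Pearson correlation between per-KC spike count and the mean
    depolarization of its assigned GGN compartment.

    Near zero in the heterogeneous network (GGN's inhibition is effectively
    uniform), negative when all KCs receive identical input.
    """
    spike_counts = np.asarray(spike_counts, dtype=float)
    local_dv = np.asarray(local_dv, dtype=float)
    if len(spike_counts) < 10:
        raise ValueError("need at least 10 KCs")
    if spike_counts.std() == 0 or local_dv.std() == 0:
        raise ValueError("zero-variance input")
    return float(np.corrcoef(spike_counts, local_dv)[0, 1])
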