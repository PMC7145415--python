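"""Kenyon-cell channel constants — single substitution point.

CONSTANTS FIXTURE.  The KC is a single compartment carrying five
voltage-gated currents (fast Na, slow Na, delayed-rectifier K, transient
A-type K, slow transient outward K) in the style of published insect-KC
Hodgkin-Huxley models.  Gate kinetics use Boltzmann steady states
``x_inf(V) = 1/(1 + exp((Vh - V)/k))`` (k < 0 for inactivation gates) with
fixed time constants.  The numbers below were calibrated in-package to the
behaviours the circuit model relies on: rest near -70 mV, spiking only for
strong synchronized input, and spike counts that rise and then fall
(depolarization block) with increasing step current.  To substitute a
published constants set, edit this file only.

Units: conductances uS, capacitance nF, voltages mV, times ms.
"""

from __future__ import annotations

import numpy as np

from ._kernels import KCP_LEN, KCP_GATES

#: membrane area of the equivalent single compartment, cm^2
KC_AREA_CM2 = 2.5e-5

_DENSITY_MS_CM2 = {
    "leak": 0.093,
    "na_fast": 35.0,
    "na_slow": 3.0,
    "k_dr": 7.0,
    "k_a": 4.0,
    "k_st": 28.0,
}

E_NA = 58.0
E_K = -81.0
E_LEAK = -70.0  # passive reversal; resting potential sits near -70 mV
CM_UF_CM2 = 1.0

# (Vhalf mV, slope mV, tau ms) per gate, order matching _kernels layout:
# m, h (fast Na); p, q (slow Na); n (K-DR); a, b (K-A); c, d (K-ST)
_GATES = [
    (-35.0, 5.5, 0.1),    # m : fast Na activation
    (-53.0, -4.5, 4.0),   # h : fast Na inactivation (drives depol. block)
    (-32.0, 6.5, 2.0),    # p : slow Na activation
    (-55.0, -6.0, 20.0),  # q : slow Na inactivation
    (-35.0, 9.0, 2.5),    # n : delayed rectifier activation
    (-50.0, 9.0, 0.5),    # a : A-type activation
    (-70.0, -7.0, 10.0),  # b : A-type inactivation
    (-45.0, 9.0, 5.0),    # c : slow transient outward activation
    (-65.0, -8.0, 150.0), # d : slow transient outward inactivation
]


def default_kc_params() -> np.ndarray:
    """Parameter vector for the numba kernels (see _kernels.py layout)."""
    p = np.zeros(KCP_LEN)
    to_us = KC_AREA_CM2 * 1e3  # mS/cm^2 * cm^2 -> mS -> uS
    p[0] = CM_UF_CM2 * KC_AREA_CM2 * 1e3          # nF
    p[1] = _DENSITY_MS_CM2["leak"] * to_us
    p[2] = E_LEAK
    p[3] = _DENSITY_MS_CM2["na_fast"] * to_us
    p[4] = _DENSITY_MS_CM2["na_slow"] * to_us
    p[5] = _DENSITY_MS_CM2["k_dr"] * to_us
    p[6] = _DENSITY_MS_CM2["k_a"] * to_us
    p[7] = _DENSITY_MS_CM2["k_st"] * to_us
    p[8] = E_NA
    p[9] = E_K
    for j, (vh, k, tau) in enumerate(_GATES):
        p[KCP_GATES + 3 * j: KCP_GATES + 3 * j + 3] = (vh, k, tau)
    return p
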