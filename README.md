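# mbsim

A biophysical model of the locust mushroom-body olfactory circuit, centered
on **GGN**, the giant GABAergic neuron that receives excitatory input from
the entire Kenyon-cell (KC) population in the mushroom body's α lobe and
returns graded feedback inhibition to all KCs in the calyx.

The package is for computational neuroscientists studying feedback
inhibition and sparse coding in insect olfaction. It provides:

- **Morphology** — SWC I/O, morphometry (total neurite length, tree-diameter
  path length, branch points), region labeling (α lobe, lateral/medial
  calyx, lateral horn, basal), electrical discretization into isopotential
  compartments (`length ≤ 0.1·λ`, `λ = √(R_M d / 4 R_A)`), and a seeded
  generator that emulates the traced GGN (~65 mm total neurite length,
  ~2 mm maximum path length, diameters tapering from ~20 µm).
- **Cable electrics** — exact steady-state solves and backward-Euler
  transients of the passive branched cable (Hines-ordered tree elimination),
  with voltage clamps, current injections and conductance inputs. Defaults:
  `R_M = 33 kΩ·cm²`, `R_A = 100 Ω·cm`, `C_m = 1 µF/cm²`, rest −51 mV.
- **Point neurons** — a single-compartment Hodgkin–Huxley-type KC with five
  voltage-gated currents (fast/slow Na⁺; delayed-rectifier, transient
  A-type and slow transient outward K⁺), and an Izhikevich regular-spiking
  model of IG ("Inhibitor of GGN") with bisection calibration of its
  spontaneous rate.
- **Synapses** — graded (sigmoidal voltage-dependent release, as GGN is
  non-spiking), double-exponential spike-triggered conductances, lognormal
  weight sampling (SD = mean), and an equivalent-synapse kernel that
  collapses e.g. 50,000 KC→GGN synapses with 0–60 ms delays into one
  smeared conductance waveform.
- **PN drive** — synthetic projection-neuron spike trains: 77 % of PNs
  spontaneously active at 2.6 spikes/s; during odor, 20 % excited at
  20 spikes/s with 20 Hz sinusoidal (LFP) modulation of amplitude 0.4×rate
  and 10 % of the spontaneously active PNs silenced; plus a
  shifting-population scheme (groups EEI/EIE/IEI/IIE with per-LFP-cycle
  recruitment). Inhomogeneous-Poisson sampling by thinning.
- **Network** — PN→KC (each KC samples 50 % of 830 PNs) → KC→GGN (α-lobe
  terminals) → graded GGN→KC feedback (calyx), with optional IG wiring
  variants, conductance scaling (50,000 / n_KC) for desk-scale runs, and a
  numba co-simulation kernel (dt = 0.025 ms).
- **Experiments & analysis** — scripted voltage-clamp attenuation maps,
  R_A/R_M sweeps, distributed-synapse drive, the single-KC dynamic-range
  loop, the 2×2 weight-scheme × PN-scheme comparison, iterative ablation of
  high-spike-rate KCs, IG wiring hypotheses; PSTHs, Gaussian rate
  smoothing, sustainedness/synchrony indices, IPSP detection, dynamic-range
  slopes. Results round-trip through an NSDF-style HDF5 layout.

## Worked example

Passive signal spread: clamp the base of the α-lobe branch of a synthetic
GGN from its −51 mV rest to −40 mV and measure the steady-state
depolarization of the terminal neurites per region:

```bash
$ mbsim clamp-map --seed 1
{
  "ALPHA_LOBE":   {"median_mV": 9.51, "min_mV": 9.31, "max_mV": 9.66},
  "CALYX_LATERAL":{"median_mV": 8.53, "min_mV": 8.13, "max_mV": 8.90},
  "CALYX_MEDIAL": {"median_mV": 8.46, "min_mV": 8.10, "max_mV": 8.68},
  "LATERAL_HORN": {"median_mV": 7.02, "min_mV": 6.51, "max_mV": 7.56}
}
```

An 11 mV command at the α lobe arrives in the calyx attenuated but still
several millivolts strong — well above the ~2 mV needed for graded synaptic
transmission, supporting global feedback inhibition of KCs from a single
input site. In Python:

```python
from mbsim.cable import BiophysicsParams
from mbsim.morphology import compartmentalize, generate_synthetic_ggn
from mbsim.experiments import exp_clamp_attenuation

model = compartmentalize(generate_synthetic_ggn(seed=1), BiophysicsParams())
per_region = exp_clamp_attenuation(model)   # RegionLabel -> ΔV array (mV)
```

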