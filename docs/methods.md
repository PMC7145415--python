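# Model and methods

## The circuit

The locust mushroom body transforms dense antennal-lobe odor codes into a
sparse Kenyon-cell (KC) representation. Three elements shape that
transformation here: structured excitatory drive from ~830 projection
neurons (PNs); the intrinsic spike threshold dynamics of the ~50,000 KCs;
and global feedback inhibition from GGN, a single giant non-spiking
GABAergic neuron per hemisphere. GGN collects excitation from every KC in
the α lobe and inhibits every KC in the calyx through graded (non-spiking)
synapses, several hundred micrometers away. A spiking neuron, IG, is in
reciprocal inhibition with GGN; its spikes appear as IPSPs in GGN's
membrane potential.

The package asks, in simulation: does a passive neuron of GGN's size
conduct α-lobe depolarization to the calyx strongly enough for global
inhibition; what does that feedback do to a KC's dynamic range; which
network properties produce the sustained odor-evoked GGN depolarization
seen in vivo; what role do rare high-firing KCs play; and which IG wiring
can produce odor-evoked *hyper*polarization of GGN.

## GGN: morphology and passive cable

GGN is modeled as a passive branched cable (strong current injections into
the real neuron produce only passive responses). The synthetic morphology
generator emulates the traced cell's morphometry — ~65 mm total neurite
length, maximum along-tree path on the order of 2 mm, thickest processes
~20 µm tapering to sub-micrometer terminals, with the calyceal subtrees
holding most of the arbor — by recursive stochastic binary branching within
per-region length budgets (BASAL 2 %, ALPHA_LOBE 21 %, each calyx 34 %,
LATERAL_HORN 9 %). It is deterministic per seed and hits the configured
total length within 10 %.

Passive parameters: membrane resistivity R_M = 33 kΩ·cm², axial
resistivity R_A = 100 Ω·cm, specific capacitance C_m = 1 µF/cm², resting
potential −51 mV. Discretization splits every parent–child segment so no
compartment exceeds 0.1·λ(d) at DC, λ(d) = √(R_M·d/(4·R_A)); compartment
membrane area is the cylinder lateral area (conserved to <1 % of the
analytic sum) and axial conductances combine facing half-compartment
resistances. The default synthetic cell yields ~1,400 compartments.

Steady states solve the (leak + axial) linear balance with ideal Dirichlet
clamps (no series resistance); transients use backward Euler (Hines-ordered
tree elimination, exact and O(N) per step), with synaptic conductances on
the diagonal — unconditionally stable and convergent to the steady state
for constant stimuli. Verified against the sealed-end finite-cable closed
form (1 %), a dense brute-force solve (1e−9), RC charging (1 %) and the
passive reciprocity/maximum principles.

## Kenyon cells

Single-compartment Hodgkin–Huxley-type model with fast and slow Na⁺,
delayed-rectifier, transient A-type, and slow transient outward K⁺
currents; Boltzmann steady states with fixed time constants, exponential-
Euler gating and an implicit voltage update at dt = 0.025 ms. The published
model this follows does not travel with its constants, so the densities and
gate parameters live in one marked fixture (`kc_channels.py`) and were
calibrated in-package to the behaviours the circuit results depend on:

- rest near −70 mV (leak reversal −70 mV), E_Na = 58 mV, E_K = −81 mV;
- spiking only for strong, synchronized input — a 10 ms conductance volley
  fires the cell while the same conductance-time spread over 500 ms does
  not;
- a rheobase near 0.35 nA with spike counts that first grow with step
  current and then collapse into depolarization block above ~1.2 nA (fast
  Na inactivation, half-voltage −53 mV, is the dominant mechanism).

Spikes are upward crossings of 0 mV with a 2 ms refractory.

## IG

Izhikevich regular-spiking model (a = 0.02, b = 0.2, c = −65, d = 8) with
conductance-based synaptic currents. Its baseline injected current is not a
free parameter: a bisection calibrates it so the cell fires ~7 spikes/s
spontaneously (within 0.5 spikes/s over a 10 s run), including the tonic
graded inhibition GGN exerts at rest when the reciprocal synapse is wired.

## Synapses

- Graded GGN output: release s with ds/dt = (s∞(V_pre) − s)/τ,
  s∞ = 1/(1+exp((V_half − V)/slope)), V_half = −45 mV, slope = 3 mV,
  τ = 4 ms, reversal −80 mV. At GGN's −51 mV rest s∞ ≈ 0.12, giving the
  tonic "spontaneous" inhibition of KCs.
- Spiking synapses: peak-normalized double-exponential kernels
  (τ_rise 1 ms, τ_decay 10 ms network-wide default).
- Weight heterogeneity: lognormal with SD = mean on the natural scale
  (PN→KC and GGN→KC), solved to underlying normal parameters.
- Equivalent synapse: the expected sum of n unit kernels with delays
  uniform on [0, 60] ms equals the unit kernel convolved with a boxcar and
  scaled by n; used only for the single-KC dynamic-range loop, spread over
  all α-lobe terminal compartments (a point synapse on one thin terminal
  saturates on its ~4 nS axial conductance and caps the deliverable
  current).

## PN drive (the model's only input)

Fixed scheme: of n = 830 PNs, round(0.77·n) = 639 are spontaneously active
at 2.6 spikes/s; during the odor, round(0.20·n) = 166 of them fire at
20 spikes/s modulated by 1 + 0.4·sin(2π·20 Hz·t) (phase 0 at odor onset),
and round(0.10·639) = 64 are silenced. Shifting scheme: ~30 % unresponsive,
the rest in four equal groups with epoch sequences EEI, EIE, IEI, IIE over
two odor half-epochs plus a 0.5 s off-epoch; each excitatory epoch starts
with 70 % of the group active and recruits 10 % per LFP cycle for three
cycles (cumulative within an epoch, reshuffled between epochs), keeping
≤ ~30–35 % of PNs excited at any instant. Trains are sampled by Poisson
thinning, deterministic per seed; empirical rates recover the configured
ones within 3 SE and the population PSTH spectrum peaks at 20 Hz.

## Network assembly and co-simulation

Each KC draws round(0.5·830) = 415 presynaptic PNs independently and
uniformly (expected overlap between two KCs: m·n/q), sends one excitatory
synapse to a uniformly chosen α-lobe terminal compartment, and receives one
graded synapse from a uniformly chosen calyceal compartment. The standard
protocol is 1 s baseline, 1 s odor, 0.5 s off-response window. GGN's
voltage is recorded at the first α-lobe compartment on the path from the
basal branch (the in vivo recording site); IG attaches to the middle basal
compartment.

The co-simulation staggers coupling by one step: KCs read their assigned
calyceal voltages from the previous step, then GGN advances with the KC
spikes just emitted; dt = 0.025 ms bounds the induced error. When the KC
population is scaled down, KC→GGN (and KC→IG) weights are multiplied by
50,000/n_KC, preserving total drive.

Calibration follows the biology: the mean graded conductance is bisected
until the median KC membrane potential under spontaneous PN bombardment
lies in [−61, −59] mV (without inhibition the median rides above −60 mV,
which brackets the search).

### Desk-scale defaults and their calibration

Full-scale (50,000 KC) runs are supported but slow; the shipped experiments
and tests run at n_KC = 400–1,000 with conductance scaling. Free synaptic
scales were fixed once against the stated physiological targets, at
n_KC = 500, seed 1:

- PN→KC mean 1.2e-4 µS (lognormal condition): after calibration, the
  shifting-PN/lognormal network sustains GGN depolarization through the
  odor (sustainedness index 0.8–0.9 at a 2 mV / 100 ms-bin criterion), with
  ~15 % of KCs spiking and >80 % of spiking KCs below five spikes. This
  sits slightly above the ~10 %-spiking target the calibration aims for;
  at this population size the weakly-inhibited lognormal tail is relatively
  heavier, and we record the measured value rather than retuning per size.
- PN→KC mean 3.3e-4 µS (uniform-weight condition): with no strong-synapse
  tail a uniform population needs a larger mean to spike at all; the value
  is set so the homogeneous/fixed-PN condition produces a few highly
  synchronized bouts and isolated GGN peaks (sustainedness 0) — the
  qualitative contrast of interest — rather than silence.
- KC→GGN unit weight 3e-4 µS (before scaling): yields odor-evoked GGN
  depolarization of ~10–15 mV at the recording site, matching the ~10 mV
  scale of strong odor responses.
- IG→GGN weight 0.03 µS at τ = 10 ms: a single IG spike produces a ~1 mV
  IPSP at the recording site. KC→IG lognormal weights (mean 2e-3,
  Izhikevich conductance units, 200 ms delay) make the KC-drive variant
  hyperpolarize GGN by >1 mV during/after the odor while the
  reciprocal-only variant cannot hyperpolarize it for any tested strength,
  time constant, or IG baseline rate.

For the single-KC dynamic-range experiment the graded feedback uses
gbar = 4e-2 µS with a slower τ = 20 ms so that the KC's own spiking,
smeared through the 50,000-synapse/0–60 ms equivalent kernel, integrates
into quasi-tonic feedback. Outcomes: the closed loop raises the spiking
threshold (0.6 vs 0.4 nA), extends sustained spiking to larger steps
(1.2 vs 1.15 nA; "sustained" means ≥2 spikes, since a single onset spike
survives past the block boundary in every configuration), and halves the
normalized rising slope.

## Analysis conventions

GGN traces are low-pass filtered at 49 Hz (zero-phase) before trace
metrics, mirroring the in vivo processing. Sustainedness is the fraction of
100 ms odor-window bins with mean depolarization ≥ 2 mV above the pre-odor
baseline (2 mV being the graded-transmission floor); synchrony is the
fraction of window spikes in the busiest 50 ms bin. IPSPs are detected on a
200 ms running-median detrended trace as negative deflections ≥ 0.5 mV with
a 20 ms dead time (recall ≥ 95 %, timing error < 5 ms on injected
ground-truth events). The dynamic-range slope is the least-squares slope of
the contiguous rising branch (first nonzero count to the maximum),
normalized by the isolated-KC slope.

## What the synthetic data do and do not show

The generator reproduces the *statistics* the circuit results depend on —
population fractions, rates, LFP phase locking, epoch structure, lognormal
weights — not real odor codes: there is no antennal-lobe dynamics, no odor
identity beyond activity templates, no trial-to-trial correlation between
PNs, and the synthetic GGN matches the real cell's morphometry, not its
geometry. Passing tests therefore demonstrate the mechanisms (passive
conduction sufficiency, dynamic-range expansion, the heterogeneity
requirement, emergent high-rate KCs, the need for an extra excitatory
pathway to IG) at desk scale, not quantitative agreement with any
particular animal.

## Numerical choices and limitations

- Backward Euler throughout the cable (dt 0.1 ms passive-only, 0.025 ms
  coupled); exponential Euler for HH gating; Izhikevich stepped at the
  network dt.
- Zero-length SWC segments merge into their parent compartment; node ids
  are remapped to 1..N on write.
- The synthetic morphology's maximum path length lands near 2.5 mm for the
  default seed — the right order, somewhat above the ~2 mm target; only
  total length is treated as a hard target.
- Ablation rounds re-run the identical network (same seeds) minus removed
  cells; a KC is disconnected at most once; limits step > 5 → ≥ 3 → ≥ 1.
- KC channel constants are behavioural calibrations, not measurements;
  substituting a published set is a one-file edit (`kc_channels.py`).
- No synaptic plasticity, no mushroom-body output neurons, no bilateral
  GGN pair, no active conductances in GGN.
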