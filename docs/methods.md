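# Methods

## The K_Na channel model

The KCNT1 (Slack) conductance is a Hodgkin–Huxley mechanism with two
multiplicative gates sharing one activation variable:

- **Sodium gate** — Hill function of the intracellular Na⁺ concentration,
  `f_Na(x) = xʰ/(xʰ + EC₅₀ʰ)` with EC₅₀ = 40 mM and Hill coefficient
  h = 3.5 in the wild-type configuration. Gain of function is a pure
  left-shift of this curve: EC₅₀ 35 mM (moderate) or 30 mM (strong). The
  Hill form is the conventional reading of an EC₅₀-plus-slope
  parameterization of ligand activation.
- **Voltage gate** — Boltzmann function `f_V(V) = 1/(1+exp(−(V−V₅₀)/k))`,
  with per-class parameters (below).
- **Kinetics** — first-order relaxation of the combined activation
  `dm/dt = (m∞ − m)/τ_act` with `m∞ = f_Na·f_V` and τ_act = 30 ms by
  default, so a voltage step produces a single-exponential current onset.
  τ_act is voltage- and Na⁺-independent and configurable per class.

The current is `I = ḡ·m·(V − E_K)` with ḡ = 0.03 S/cm² in every
compartment and E_K = −90 mV (E_Na = +60 mV; both configurable). The
channel has no inactivation and no temperature scaling.

### Per-class voltage dependence

The class-specific (V₅₀, k) pairs are free parameters: the underlying
activation-curve measurements are published only graphically, so the
values here are calibrated to reproduce the qualitative pattern — SST/PV
curves left-shifted and shallow (subthreshold K_Na), VIP/glutamatergic
curves right-shifted and steep (suprathreshold K_Na only):

| class          | V₅₀ (mV) | k (mV) |
|----------------|---------:|-------:|
| SST            |      −35 |     14 |
| PV             |      −35 |     14 |
| glutamatergic  |      −10 |      6 |
| VIP            |      +25 |      4 |

The VIP curve is placed at the top of the voltage-clamp step range so
that, combined with the VIP model's low-amplitude spikes, its K_Na
current is recruited by voltage-clamp steps (visible suprathreshold
difference current) but essentially never by the cell's own action
potentials. This is the package's mechanistic account of why VIP
physiology is insensitive to GOF; with milder right-shifts the VIP
models' firing was visibly altered by GOF, contrary to the experimental
observation.

## Companion conductances

Transient Na⁺ (m³h), delayed-rectifier K⁺ (n⁴) and persistent Na⁺ use
Traub-style alpha/beta rate kinetics with a class-specific threshold
shift `vt`. Two deliberate modifications:

- The transient-Na⁺ activation gate is right-shifted by 6 mV relative to
  inactivation (`nat_m_shift`), keeping the subthreshold window current
  small, as for native channels. Without it, the window current rather
  than the persistent conductance dominated slow-ramp TTX differences.
- The persistent Na⁺ gate is a non-inactivating Boltzmann
  (midpoint `vt + 3` mV, slope 5 mV, τ = 1 ms) whose maximal conductance
  is tied to the local transient conductance at 0.001 ×
  `nap_scale_factor` in every compartment; `nap_scale_factor = 2`
  reproduces the experimentally observed two-fold I_NaP increase in PV
  neurons. With this tie the peak persistent current in a voltage-step
  family is about 0.7% of the peak transient current (reported by the
  acceptance script), consistent with the targeted ~1%.

## Neuron models

Three cylindrical compartments — soma, dendritic cable, axon initial
segment — in a star topology around the soma, rather than full
morphological reconstructions; the scientific claims rest on conductance
interplay, not morphometry. Calibration targets the qualitative class
physiology: VIP large R_in / small rheobase / wide APs; PV small R_in /
large rheobase / narrow APs / fast spiking (> 60 Hz); SST intermediate
with the most hyperpolarized threshold; glutamatergic regular spiking.
Key densities (S/cm², soma values; dendrites carry 0.1 ×, the axon
2 × — 20 × for PV, emulating an AIS-like Na⁺ density, which also makes
the tied persistent current a realistic fraction of the perithreshold
current balance):

| class | g_leak | g_NaT | g_Kdr | vt (mV) |
|-------|-------:|------:|------:|--------:|
| glut  | 1.0e−4 | 0.050 | 0.006 | −55 |
| VIP   | 0.7e−4 | 0.012 | 0.003 | −54 |
| SST   | 0.9e−4 | 0.035 | 0.003 | −58 |
| PV    | 4.0e−4 | 0.150 | 0.020 | −50 |

Instance variability: ±10% seeded multiplicative jitter on conductance
densities and geometry, ten instances per class emulating a model
population.

**Intracellular Na⁺** is either clamped (10 or 0 mM, for subtraction
protocols) or a dynamic submembrane shell (depth 0.1 µm, first-order
extrusion τ = 100 ms back to 10 mM) filled by the transient and
persistent Na⁺ currents. The Na⁺-loading of this shell during firing is
what couples spiking to K_Na activation in current clamp.

**Integration** is fixed-step backward Euler on the voltages (the star
topology is solved by exact elimination of the child compartments) with
staggered exponential-Euler gate updates, dt = 0.025 ms. Halving dt
changes subthreshold somatic voltage by well under 0.5 mV RMS;
suprathreshold traces differ only by spike-timing jitter, as expected
for chaotic spike trains. A numba-compiled kernel is the default
execution path; the pure-numpy engine is the reference implementation
and the test suite asserts both agree to near machine precision.
Voltage clamp is an ideal space clamp — every compartment follows the
command — so the clamp current is exactly the summed ionic current and
pharmacological difference currents are exact; an experimental series
resistance is deliberately not modelled.

**Pharmacology** is instantaneous condition toggling: `ttx` zeroes both
Na⁺ conductances, `vu170` zeroes KCNT1, `na_clamp_10/0` fix the shell
concentration. Solution-exchange kinetics and partial block are not
modelled.

## Protocols

Current clamp: 500-ms steps, 20-pA increments from −100 pA, 100-ms
baselines. The number of steps is per class — up to +140 pA for
VIP/glutamatergic, +500 pA for SST, +700 pA for PV — spanning each
class's dynamic range up to depolarization block, mirroring the
experimental practice of injecting current until the AP count plateaus.
Voltage clamp: 1-s steps, −80 to +50 mV in 10-mV increments from a
−70 mV hold. Ramps: 5 s at 20 mV/s from −80 mV; only the first
repetition is analysed (the simulation is stationary).

## Analysis conventions

- AP threshold: first sample of the contiguous dV/dt ≥ 20 V/s run before
  the peak (a robust surrogate for the inflection point); APs must peak
  above −10 mV (excludes spikelets). Half-width at half-maximal
  amplitude with linear interpolation; AHP = threshold minus the minimum
  within 50 ms of the peak, floored at zero.
- R_in: through-origin regression of steady-state deflection (mean of the
  last 100 ms of the step) on injected current over hyperpolarizing
  steps; τ_m: single-exponential fit over 1–200 ms after stimulus offset
  of the most hyperpolarized sweep; C_m = τ_m/R_in by construction.
- FS/NFS: FS iff max mean rate > 60 Hz and the half-width broadening
  from the first AP to the mean of the last three APs in a 1-s sustained
  window stays below 25%.
- Activation fits use chord conductance G = I/(V − E_K), bounded least
  squares, initialized at the half-max voltage with k = 10 mV.
- Ramp I-V bins are centred on absolute multiples of 5 mV, so the grid
  does not move with the ramp's start voltage.
- Event detection is a scaled-template (Clements–Bekkers style) matcher:
  the kernel (0.5-ms rise, 3-ms decay) is optimally scaled at every
  offset and an event is called where the fitted amplitude exceeds 3 ×
  the baseline SD (re-estimated after excluding detected events), with a
  2-ms merge refractory. Charge = fitted amplitude × the analytic kernel
  integral over 10 decay constants.
- Pair motifs: electrical iff the steady-state coupling coefficient on a
  −100 pA step reaches 0.005 in either direction; chemical per direction
  iff a PSC follows ≥ 50% of presynaptic APs within 4 ms with no
  step-evoked deflection; spikelets (low-pass-filtered attenuated
  spikes) are reported as supporting evidence. These thresholds are
  conventions, all configurable.
- Group comparisons use exact tests (Clopper–Pearson intervals, Fisher's
  exact test) instead of mixed-model regression; raw counts are
  preserved so any external statistics can be rerun.

## Synthetic data

Seeded generators produce every input class with known ground truth:
passive RC step families, spiking sweeps with a piecewise-linear AP
waveform whose threshold/amplitude/half-width/AHP are exact by
construction, Poisson PSC trains convolved with the template kernel, and
paired recordings for all four coupling motifs. Defaults mirror the
acquisition conditions the analyses assume (20 kHz sampling, Gaussian
noise). The generators emulate waveform shape and event statistics, not
biological variability across cells, channel noise, drift or seal
artifacts — so passing round-trips demonstrate correctness of the
analysis logic at realistic SNR, not robustness to every property of
real recordings.

## Known limitations

- Reduced three-compartment models with four conductances cannot match
  every quantitative feature of full-morphology multi-conductance
  models; calibration is to qualitative class physiology, and absolute
  firing rates (especially VIP's narrow pre-block dynamic range and the
  PV somatic threshold, which reads hyperpolarized because spikes
  initiate in the high-density axon) should not be over-interpreted.
- The VIP GOF insensitivity is achieved by placing its activation curve
  above the voltages its own spikes reach; this is one sufficient
  mechanism, not evidence against others.
- Liquid-junction-potential correction is exposed as a configurable
  offset on the activation-curve parameters and defaults to 0 mV.
- The slow-ramp TTX difference contains a small transient-channel window
  current above about −50 mV in addition to the persistent current, as
  in the experimental measurement.
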