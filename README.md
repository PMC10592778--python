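# slacksim

Sodium-activated potassium (K_Na / Slack / KCNT1) conductance modelling in
reduced cortical neuron models, with the matching patch-clamp-style analysis
stack.

Gain-of-function (GOF) variants of *KCNT1* cause severe developmental and
epileptic encephalopathies, yet the same variant can push closely related
interneuron classes in opposite directions: somatostatin (SST) interneurons
become hypoexcitable while parvalbumin (PV) interneurons become
hyperexcitable, and VIP and glutamatergic neurons are spared. `slacksim`
reimplements the computational machinery behind that result so the whole
chain — channel model, neuron models, in-silico experiments, and the
analysis procedures applied to the resulting traces — can be run, tested
and extended on a desk.

## The model

The K_Na conductance is a Hodgkin–Huxley channel with one sodium- and one
voltage-dependent gate, combined multiplicatively into a single activation
variable *m* with first-order kinetics:

```
I_KNa   = ḡ · m · (V − E_K)                       ḡ = 0.03 S/cm², E_K = −90 mV
m∞      = f_Na([Na]i) · f_V(V)
f_Na(x) = xʰ / (xʰ + EC₅₀ʰ)                        EC₅₀ = 40 mM, h = 3.5
f_V(V)  = 1 / (1 + exp(−(V − V₅₀)/k))
dm/dt   = (m∞ − m) / τ_act                         τ_act = 30 ms
```

GOF is modelled by lowering the sodium-gate EC₅₀ (40 → 35 → 30 mM). The
voltage gate differs by neuron class: SST/PV carry a left-shifted, shallow
curve (V₅₀ = −35 mV, k = 14 mV — active at subthreshold voltages), while
VIP/glutamatergic carry a right-shifted, steep one, so their K_Na current is
recruited only at strongly depolarized (suprathreshold) voltages.

The channel is inserted at 0.03 S/cm² into soma, dendrite and axon of
three-compartment models of four cortical classes (glutamatergic, VIP, SST,
PV) alongside transient Na⁺ (m³h), persistent Na⁺ (tied at 0.001 × the
transient conductance), delayed-rectifier K⁺ (n⁴) and leak conductances,
with intracellular Na⁺ tracked in a submembrane shell or clamped for
subtraction protocols.

On the analysis side the package implements the standard whole-cell
procedures: intrinsic/AP feature extraction (rheobase, R_in, τ_m, C_m,
threshold, amplitude, half-width, AHP, F-I), the fast-spiking rule
(max mean rate > 60 Hz with < 25% half-width broadening over 1 s),
difference-current I-V construction with Boltzmann activation fits and
onset-kinetics fits, 5-mV-binned ramp I-V for the persistent Na⁺ current,
scaled-template PSC detection (0.5-ms rise / 3-ms decay, 3× baseline SD),
the E/I ratio f_E·q_E / (f_E·q_E + f_I·q_I), paired-recording coupling
motifs, and exact connection-probability statistics.

## A worked example

`examples/03_pv_inap_rescue.py` runs a PV model through 500-ms current
steps under control, GOF, and GOF plus a doubled persistent Na⁺ current:

```
control               : rheobase    80 pA, AP amplitude 106.1 mV, total APs 712
GOF 30 mM             : rheobase   120 pA, AP amplitude 105.9 mV, total APs 399
GOF 30 mM + 2x I_NaP  : rheobase    60 pA, AP amplitude 109.0 mV, total APs 873
```

GOF alone makes the PV model fire less; doubling I_NaP — the change
measured experimentally in PV neurons — overcomes the extra K_Na current,
lowering rheobase and raising AP height above control. The other examples
cover the channel itself, SST vs VIP GOF effects, voltage-clamp
subtraction and activation fitting, ramp I_NaP isolation, feature
extraction and FS/NFS classification, synaptic event detection with the
E/I ratio, and pair-motif classification.

A thin CLI mirrors the library (`slacksim simulate|gof-report|features|
ivcurve|activationfit|inap|events|eiratio|pairs|synth`); every entry point
takes `--seed` and logs its parameters to stderr.

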