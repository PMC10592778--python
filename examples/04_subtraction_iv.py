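"""Pharmacological subtraction: isolating K_Na and fitting its activation.

Runs the 1-s voltage-step family (-80..+50 mV from a -70 mV hold) on an
SST model with [Na]i clamped at 10 mM, subtracts the simulated VU170
(KCNT1 blocked) traces from control, builds the steady-state I-V from
the last 100 ms of each step, converts to chord conductance and fits a
Boltzmann activation curve, and fits the onset time constant.
"""

import numpy as np

from slacksim.current_analysis import fit_activation, fit_onset_tau, steady_state_iv
from slacksim.neuron_models import NA_CLAMP_10, VU170, apply_condition, build_subtype_model
from slacksim.protocols import VOLTAGE_STEPS, run_subtraction

model = apply_condition(build_subtype_model("SST", jitter=0.0), NA_CLAMP_10)
diff = run_subtraction(model, VU170, VOLTAGE_STEPS, dt=0.05)

iv = steady_state_iv(diff)
print("Steady-state K_Na difference current (last 100 ms of each step):")
for v, i in zip(iv.voltages, iv.currents):
    print(f"  {v:6.0f} mV -> {i:8.1f} pA")

fit = fit_activation(iv, erev=-90.0)
print(f"\nBoltzmann fit of the chord conductance: V50 = {fit.v50:.1f} mV, "
      f"k = {fit.k:.1f} mV, gmax = {fit.gmax:.1f} nS")
print("(the SST model is built with V50 = -35 mV, k = 14 mV)")

# onset kinetics of the +10 mV step
sweep = next(s for s in diff if s.meta["step_mV"] == 10.0)
tau = fit_onset_tau(sweep, onset_ms=sweep.meta["onset_ms"], fit_span_ms=200.0)
print(f"Single-exponential onset time constant: {tau:.1f} ms "
      f"(model tau_act = 30 ms)")
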