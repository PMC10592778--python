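"""The KCNT1 (Slack) conductance: sodium and voltage gates, and GOF levels.

Evaluates the Hill sodium gate and Boltzmann voltage gate of the K_Na
channel, and shows how lowering the sodium-gate EC50 (the gain-of-function
manipulation, 40 -> 35 -> 30 mM) raises the steady-state current at a
fixed physiological operating point.
"""

import numpy as np

from slacksim.channels import (
    build_channel_library,
    kcnt1_steady_state,
    na_gate_activation,
    voltage_gate_activation,
    with_ec50,
)

kcnt1 = build_channel_library()["kcnt1"]

print("Sodium gate (EC50 40 mM, Hill 3.5):")
for na in (5.0, 10.0, 20.0, 40.0, 80.0):
    f = na_gate_activation(na, kcnt1.sodium_gate)
    print(f"  [Na]i = {na:5.1f} mM -> open fraction {f:.4f}")

print("\nVoltage gate (V50 = -35 mV, k = 14 mV; SST/PV configuration):")
for v in (-80.0, -60.0, -40.0, -20.0, 0.0):
    f = voltage_gate_activation(v, kcnt1.voltage_gate)
    print(f"  V = {v:6.1f} mV -> open fraction {f:.4f}")

print("\nSteady-state K_Na current density at V = -40 mV, [Na]i = 10 mM:")
for ec50 in (40.0, 35.0, 30.0):
    i = kcnt1_steady_state(-40.0, 10.0, with_ec50(kcnt1, ec50))
    print(f"  EC50 = {ec50:.0f} mM -> {i * 1000:.2f} uA/cm^2 (outward)")
print("Lower EC50 (stronger GOF) -> more K_Na current at the same operating point.")
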