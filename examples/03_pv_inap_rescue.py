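"""A two-fold persistent-Na+ increase flips the GOF effect in PV models.

Runs a PV model in three conditions: control, GOF alone (EC50 30 mM),
and GOF plus a doubled persistent Na+ conductance (the experimental
observation in PV neurons), then compares firing, rheobase and AP height.
"""

from slacksim import ephys_features as ef
from slacksim.channels import ChannelLibraryConfig
from slacksim.neuron_models import build_subtype_model, set_gof
from slacksim.protocols import GOF_STEP_COUNTS, StepProtocol, run_current_steps

proto = StepProtocol(n_steps=GOF_STEP_COUNTS["PV"])
conditions = [
    ("control", 40.0, 1.0),
    ("GOF 30 mM", 30.0, 1.0),
    ("GOF 30 mM + 2x I_NaP", 30.0, 2.0),
]
for label, ec50, nap_scale in conditions:
    cfg = ChannelLibraryConfig(nap_scale_factor=nap_scale)
    model = set_gof(build_subtype_model("PV", config=cfg, instance_seed=1), ec50)
    feats = ef.extract_features(run_current_steps(model, proto))
    total = sum(c for _, c in feats.fi_curve)
    print(f"{label:22s}: rheobase {feats.rheobase:5.0f} pA, "
          f"AP amplitude {feats.ap_amplitude:5.1f} mV, total APs {total}")

print("\nGOF alone reduces PV firing; doubling I_NaP overcomes it, lowering")
print("rheobase and raising AP height above control (hyperexcitable).")
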