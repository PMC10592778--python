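"""Template-based PSC detection and the E/I ratio.

Generates spontaneous EPSC- and IPSC-like traces (Poisson events
convolved with a 0.5-ms-rise/3-ms-decay kernel on Gaussian noise),
detects events with the scaled-template matcher at 3x the baseline SD,
and combines frequency and charge into the excitation/inhibition ratio
E/I = f_E q_E / (f_E q_E + f_I q_I).
"""

from slacksim.synaptic_analysis import detect_events, ei_ratio
from slacksim.synthetic_data import synth_psc_trace

epsc_trace, gt_e = synth_psc_trace(rate_hz=5.0, amplitude_pA=20.0, duration_s=30.0,
                                   noise_sd_pA=2.0, seed=11)
ipsc_trace, gt_i = synth_psc_trace(rate_hz=2.0, amplitude_pA=35.0, duration_s=30.0,
                                   noise_sd_pA=2.0, seed=12)

epsc = detect_events(epsc_trace)
ipsc = detect_events(ipsc_trace)
print(f"sEPSC: {epsc.frequency_hz:.2f} Hz detected "
      f"({len(gt_e.params['event_times_ms']) / 30.0:.2f} Hz generated), "
      f"mean charge {epsc.mean_charge_pC:.3f} pC")
print(f"sIPSC: {ipsc.frequency_hz:.2f} Hz detected "
      f"({len(gt_i.params['event_times_ms']) / 30.0:.2f} Hz generated), "
      f"mean charge {ipsc.mean_charge_pC:.3f} pC")
print(f"E/I ratio = {ei_ratio(epsc, ipsc):.3f}")
print("\nValues near 1 mean excitation-dominated input; near 0, inhibition.")
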