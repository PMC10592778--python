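"""Stimulus protocols, subtraction experiments, and the GOF driver."""

import numpy as np
import pytest

from slacksim import ephys_features as ef
from slacksim.channels import ChannelLibraryConfig
from slacksim.neuron_models import (
    CONTROL,
    NA_CLAMP_0,
    NA_CLAMP_10,
    TTX,
    VU170,
    apply_condition,
    build_subtype_model,
)
from slacksim.protocols import (
    CURRENT_STEPS,
    RAMP,
    VOLTAGE_STEPS,
    RampProtocol,
    StepProtocol,
    run_current_steps,
    run_gof_experiment,
    run_ramp_inap,
    run_subtraction,
    run_voltage_steps,
)
from slacksim.trace import Trace


class TestProtocolDefaults:
    def test_current_clamp_family(self):
        assert CURRENT_STEPS.duration_ms == 500.0
        assert CURRENT_STEPS.increment == 20.0
        assert CURRENT_STEPS.start == -100.0

    def test_voltage_clamp_family(self):
        amps = VOLTAGE_STEPS.amplitudes
        assert len(amps) == 14
        assert amps[0] == -80.0 and amps[-1] == 50.0
        assert np.all(np.diff(amps) == 10.0)
        assert VOLTAGE_STEPS.duration_ms == 1000.0
        assert VOLTAGE_STEPS.holding == -70.0

    def test_ramp_defaults(self):
        assert RAMP.rate_mV_per_s == 20.0
        assert RAMP.duration_s == 5.0
        assert RAMP.start_mV == -80.0
        assert RAMP.interval_s == 10.0

    def test_waveform_shape(self):
        w = CURRENT_STEPS.waveforms(0.025)
        assert w.shape == (CURRENT_STEPS.n_steps, int(700.0 / 0.025))
        # baseline is the holding level
        assert np.all(w[:, :10] == 0.0)


class TestCurrentSteps:
    def test_subthreshold_step_is_ohmic(self):
        m = build_subtype_model("SST", jitter=0.0)
        bundle = run_current_steps(m, StepProtocol(n_steps=1))  # -100 pA only
        feats = ef.extract_features(bundle)
        sweep = bundle.sweeps[0]
        base = np.mean(sweep.slice_ms(50.0, 100.0))
        steady = np.mean(sweep.slice_ms(500.0, 600.0))
        assert steady - base == pytest.approx(-100.0 * feats.rin / 1000.0, rel=0.05)

    def test_ap_counts_rise_to_a_peak(self):
        m = build_subtype_model("SST", jitter=0.0)
        bundle = run_current_steps(m)
        counts = np.array([len(ef.detect_aps(s)) for s in bundle])
        peak = counts.argmax()
        assert np.all(np.diff(counts[:peak + 1]) >= 0)


class TestSubtraction:
    def test_noop_condition_gives_zero_difference(self):
        m = build_subtype_model("SST", jitter=0.0)
        proto = StepProtocol(mode="vclamp", holding=-70.0, start=-40.0, increment=20.0,
                             n_steps=3, duration_ms=200.0)
        diff = run_subtraction(m, CONTROL, proto)
        for s in diff:
            assert np.allclose(s.data, 0.0)

    def test_subtraction_linearity(self):
        # (control - vu170) + (vu170 - ttx) == (control - ttx) sample-wise
        m = apply_condition(build_subtype_model("SST", jitter=0.0), NA_CLAMP_10)
        proto = StepProtocol(mode="vclamp", holding=-70.0, start=-20.0, increment=30.0,
                             n_steps=2, duration_ms=300.0)
        c = run_voltage_steps(m, proto, CONTROL)
        vu = run_voltage_steps(m, proto, VU170)
        tt = run_voltage_steps(m, proto, TTX)
        for sc, sv, st in zip(c, vu, tt):
            lhs = (sc.data - sv.data) + (sv.data - st.data)
            assert np.allclose(lhs, sc.data - st.data, atol=1e-9)

    def test_na_clamp_difference_grows_with_depolarization(self):
        # the K_Na difference current rises with step voltage above threshold
        from slacksim.current_analysis import steady_state_iv

        base = build_subtype_model("SST", jitter=0.0)
        c10 = run_voltage_steps(apply_condition(base, NA_CLAMP_10), VOLTAGE_STEPS,
                                dt=0.05)
        c0 = run_voltage_steps(apply_condition(base, NA_CLAMP_0), VOLTAGE_STEPS,
                               dt=0.05)
        diff = [Trace(a.data - b.data, a.dt_ms, "pA", dict(a.meta))
                for a, b in zip(c10, c0)]
        from slacksim.io import SweepBundle

        iv = steady_state_iv(SweepBundle(meta=dict(c10.meta), sweeps=diff))
        above = iv.currents[iv.voltages >= -10.0]
        assert np.all(np.diff(above) > 0)

    def test_mismatched_protocols_rejected(self):
        m = build_subtype_model("SST", jitter=0.0)
        with pytest.raises(ValueError):
            run_current_steps(m, VOLTAGE_STEPS)


class TestRampInap:
    def test_zero_nap_flat_below_transient_window(self):
        # without the persistent conductance the difference vanishes over
        # the subthreshold range (the transient-channel window current only
        # appears above about -50 mV)
        cfg = ChannelLibraryConfig(nap_to_nat_ratio=0.0)
        m = build_subtype_model("SST", config=cfg, jitter=0.0)
        trace = run_ramp_inap(m, RampProtocol(duration_s=2.0), dt=0.1)
        v = -80.0 + 20.0 * trace.time_ms / 1000.0
        assert np.abs(trace.data[v <= -55.0]).max() < 0.5  # pA

    def test_difference_scales_with_nap_factor_at_fixed_voltage(self):
        # at -50 mV, where the persistent conductance dominates the
        # difference, doubling the NaP scale doubles the current
        vals = {}
        for scale in (1.0, 2.0):
            cfg = ChannelLibraryConfig(nap_scale_factor=scale)
            m = build_subtype_model("PV", config=cfg, jitter=0.0)
            trace = run_ramp_inap(m, RampProtocol(duration_s=2.0), dt=0.1)
            v = -80.0 + 20.0 * trace.time_ms / 1000.0
            mask = (v >= -51.0) & (v <= -49.0)
            vals[scale] = float(trace.data[mask].mean())
        assert vals[2.0] < vals[1.0] < 0
        assert vals[2.0] / vals[1.0] == pytest.approx(2.0, rel=0.1)


class TestGofExperiment:
    def test_summary_shape_and_columns(self):
        df = run_gof_experiment(subtypes=("SST",), ec50_levels=(40.0, 30.0),
                                n_instances=1, seed=3)
        assert len(df) == 2
        assert {"subtype", "instance", "ec50_mM", "nap_scale", "rheobase_pA",
                "rin_MOhm", "ap_amplitude_mV", "fi_counts"} <= set(df.columns)
        assert all(isinstance(c, int) and c >= 0
                   for counts in df["fi_counts"] for c in counts)

    def test_deterministic_given_seed(self):
        df1 = run_gof_experiment(subtypes=("VIP",), ec50_levels=(40.0,),
                                 n_instances=1, seed=5)
        df2 = run_gof_experiment(subtypes=("VIP",), ec50_levels=(40.0,),
                                 n_instances=1, seed=5)
        assert df1["rheobase_pA"].equals(df2["rheobase_pA"])
        assert df1["fi_counts"].iloc[0] == df2["fi_counts"].iloc[0]
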