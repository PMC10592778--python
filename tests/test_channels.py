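"""Gating-law and channel-library tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slacksim.channels import (
    ChannelLibraryConfig,
    ChannelSpec,
    GateSpec,
    build_channel_library,
    gate_kinetics_step,
    kcnt1_steady_state,
    load_channel_library,
    na_gate_activation,
    save_channel_library,
    voltage_gate_activation,
    with_ec50,
)


def na_gate(ec50=40.0, hill=3.5, tau=30.0):
    return GateSpec(kind="sodium-hill", ec50=ec50, hill=hill, tau_act=tau)


def v_gate(v50=-30.0, k=10.0, tau=30.0):
    return GateSpec(kind="voltage-boltzmann", v50=v50, k=k, tau_act=tau)


def kcnt1(gbar=0.03, erev=-90.0, **kw):
    return ChannelSpec(
        name="kcnt1", gbar=gbar, erev=erev, mechanism="kcnt1",
        gates=(na_gate(**{k: v for k, v in kw.items() if k in ("ec50", "hill")}),
               v_gate(**{k: v for k, v in kw.items() if k in ("v50", "k")})),
    )


class TestSodiumGate:
    def test_half_activation_at_ec50(self):
        for ec50 in (40.0, 35.0, 30.0, 7.3):
            assert na_gate_activation(ec50, na_gate(ec50=ec50)) == pytest.approx(0.5)

    def test_zero_concentration_closes_gate(self):
        assert na_gate_activation(0.0, na_gate()) == 0.0

    def test_hill_closed_form(self):
        # 10 mM against EC50 40, hill 3.5: 1 / (1 + 4**3.5) = 1/129
        assert na_gate_activation(10.0, na_gate()) == pytest.approx(1.0 / 129.0, rel=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            na_gate_activation(-1.0, na_gate())

    @given(st.floats(0.0, 200.0), st.floats(1.0, 100.0), st.floats(0.5, 6.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounded_and_monotone(self, x, ec50, hill):
        g = na_gate(ec50=ec50, hill=hill)
        a = na_gate_activation(x, g)
        assert 0.0 <= a <= 1.0
        assert na_gate_activation(x + 1.0, g) >= a


class TestVoltageGate:
    def test_midpoint(self):
        assert voltage_gate_activation(-30.0, v_gate()) == pytest.approx(0.5)

    def test_ninety_percent_point(self):
        g = v_gate(v50=-30.0, k=10.0)
        assert voltage_gate_activation(-30.0 + 10.0 * np.log(9.0), g) == pytest.approx(0.9)

    def test_boltzmann_closed_form(self):
        g = v_gate(v50=-30.0, k=10.0)
        assert voltage_gate_activation(-70.0, g) == pytest.approx(1.0 / (1.0 + np.e**4), rel=1e-12)

    def test_invalid_slope_rejected(self):
        with pytest.raises(ValueError):
            GateSpec(kind="voltage-boltzmann", v50=-30.0, k=0.0)

    def test_steeper_curve_narrower_span(self):
        wide = v_gate(k=14.0)
        steep = v_gate(k=6.0)
        span = lambda g: 2 * g.k * np.log(9.0)  # V(0.9) - V(0.1)
        assert span(steep) < span(wide)

    @given(st.floats(-120.0, 60.0), st.floats(-60.0, 0.0), st.floats(1.0, 20.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounded_monotone_increasing(self, v, v50, k):
        g = v_gate(v50=v50, k=k)
        a = voltage_gate_activation(v, g)
        assert 0.0 <= a <= 1.0
        assert voltage_gate_activation(v + 0.5, g) >= a


class TestKcnt1SteadyState:
    def test_zero_at_reversal(self):
        assert kcnt1_steady_state(-90.0, 40.0, kcnt1()) == 0.0

    def test_zero_sodium_closes_channel(self):
        for v in (-80.0, -30.0, 20.0):
            assert kcnt1_steady_state(v, 0.0, kcnt1()) == 0.0

    def test_closed_form_product(self):
        # gbar 0.03, m = 0.5 * 1/(1+e^-3), driving force 90 mV
        i = kcnt1_steady_state(0.0, 40.0, kcnt1())
        expect = 0.03 * 0.5 * (1.0 / (1.0 + np.exp(-3.0))) * 90.0
        assert i == pytest.approx(expect, rel=1e-12)
        assert i == pytest.approx(1.286, abs=2e-3)

    def test_sign_flips_at_reversal(self):
        ch = kcnt1()
        assert kcnt1_steady_state(-89.0, 40.0, ch) > 0
        assert kcnt1_steady_state(-91.0, 40.0, ch) < 0

    def test_gof_monotone_in_ec50(self):
        # lowering EC50 never decreases |I| away from the reversal
        v, na = -40.0, 10.0
        currents = [
            abs(kcnt1_steady_state(v, na, with_ec50(kcnt1(), e))) for e in (40.0, 35.0, 30.0)
        ]
        assert currents[0] <= currents[1] <= currents[2]


class TestKinetics:
    def test_fixed_point(self):
        ch = kcnt1()
        v, na = -20.0, 40.0
        m_inf = 0.5 * voltage_gate_activation(v, ch.voltage_gate)
        assert gate_kinetics_step(m_inf, v, na, 0.5, ch) == pytest.approx(m_inf, rel=1e-12)

    def test_exponential_relaxation_from_zero(self):
        ch = kcnt1()
        v, na = -20.0, 40.0
        tau = ch.voltage_gate.tau_act
        m_inf = 0.5 * voltage_gate_activation(v, ch.voltage_gate)
        m = 0.0
        # integrate exactly one time constant in small steps
        for _ in range(1000):
            m = gate_kinetics_step(m, v, na, tau / 1000.0, ch)
        assert m == pytest.approx(m_inf * (1.0 - np.exp(-1.0)), rel=1e-6)

    def test_m_stays_in_unit_interval(self):
        ch = kcnt1()
        for m0 in (0.0, 0.5, 1.0):
            m = gate_kinetics_step(m0, 50.0, 500.0, 1e6, ch)
            assert 0.0 <= m <= 1.0

    def test_onset_fit_recovers_tau(self):
        # simulated voltage-step onset is single-exponential with tau_act
        from slacksim.current_analysis import fit_onset_tau
        from slacksim.trace import Trace

        ch = kcnt1()
        dt = 0.05
        m = 0.006  # steady state at the holding potential
        vals = []
        for _ in range(int(200 / dt)):
            m = gate_kinetics_step(m, 0.0, 40.0, dt, ch)
            vals.append(ch.gbar * m * (0.0 - ch.erev))
        tr = Trace(np.array(vals) * 1e3, dt_ms=dt, units="pA")
        tau = fit_onset_tau(tr, onset_ms=0.0)
        assert tau == pytest.approx(ch.voltage_gate.tau_act, rel=0.02)


class TestChannelLibrary:
    def test_nap_tied_to_nat(self):
        cfg = ChannelLibraryConfig(gnat=0.1, nap_to_nat_ratio=0.001, nap_scale_factor=1.0)
        lib = build_channel_library(cfg)
        assert lib["nap"].gbar == pytest.approx(1.0e-4)

    def test_nap_scale_doubles(self):
        cfg = ChannelLibraryConfig(gnat=0.1, nap_scale_factor=2.0)
        lib = build_channel_library(cfg)
        assert lib["nap"].gbar == pytest.approx(2.0e-4)

    def test_zero_ratio_zero_conductance(self):
        lib = build_channel_library(ChannelLibraryConfig(nap_to_nat_ratio=0.0))
        assert lib["nap"].gbar == 0.0

    def test_gof_levels_must_decrease(self):
        with pytest.raises(ValueError):
            ChannelLibraryConfig(gof_ec50_levels=(40.0, 45.0))

    def test_yaml_round_trip_lossless(self, tmp_path):
        lib = build_channel_library()
        path = tmp_path / "channels.yaml"
        save_channel_library(lib, path)
        back = load_channel_library(path)
        assert set(back) == set(lib)
        for name in lib:
            assert back[name] == lib[name]
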