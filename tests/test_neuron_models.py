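"""Model construction, pharmacology transforms, and integrator contracts."""

from dataclasses import replace

import numpy as np
import pytest

from slacksim.neuron_models import (
    CONTROL,
    NA_CLAMP_0,
    NA_CLAMP_10,
    TTX,
    VU170,
    NaHandling,
    NeuronModel,
    PharmacologyCondition,
    apply_condition,
    build_subtype_model,
    integrate,
    set_gof,
    swap_activation_curve,
)


def passive_only(model: NeuronModel) -> NeuronModel:
    """Zero every conductance except the leak."""
    comps = tuple(
        replace(c, channels={
            n: (ch if n == "leak" else replace(ch, gbar=0.0)) for n, ch in c.channels.items()
        })
        for c in model.compartments
    )
    return replace(model, compartments=comps)


def step_stim(amp_nA, n_pre=2000, n_on=12000, n_post=2000):
    out = np.zeros((1, n_pre + n_on + n_post))
    out[0, n_pre:n_pre + n_on] = amp_nA
    return out


class TestConstruction:
    def test_same_seed_is_bit_identical(self):
        m1 = build_subtype_model("SST", instance_seed=7)
        m2 = build_subtype_model("SST", instance_seed=7)
        assert m1 == m2

    def test_different_seeds_differ(self):
        m1 = build_subtype_model("SST", instance_seed=1)
        m2 = build_subtype_model("SST", instance_seed=2)
        assert m1 != m2

    def test_unknown_subtype_rejected(self):
        with pytest.raises(ValueError):
            build_subtype_model("granule")

    def test_kcnt1_in_all_compartments(self):
        m = build_subtype_model("PV")
        for c in m.compartments:
            assert c.channels["kcnt1"].gbar == pytest.approx(0.03)


class TestPharmacology:
    def test_ttx_zeroes_both_na_conductances(self):
        m = apply_condition(build_subtype_model("SST"), TTX)
        for c in m.compartments:
            assert c.channels["nat"].gbar == 0.0
            assert c.channels["nap"].gbar == 0.0
            assert c.channels["kdr"].gbar > 0.0

    def test_vu170_zeroes_kcnt1_only(self):
        m0 = build_subtype_model("SST")
        m = apply_condition(m0, VU170)
        for c0, c in zip(m0.compartments, m.compartments):
            assert c.channels["kcnt1"].gbar == 0.0
            assert c.channels["nat"] == c0.channels["nat"]

    def test_conditions_idempotent_and_pure(self):
        m0 = build_subtype_model("SST")
        m1 = apply_condition(m0, TTX)
        m2 = apply_condition(m1, TTX)
        assert m1.compartments == m2.compartments
        assert m0.compartments[0].channels["nat"].gbar > 0.0  # original untouched

    def test_condition_commutes_with_gof(self):
        m = build_subtype_model("PV")
        a = set_gof(apply_condition(m, VU170), 30.0)
        b = apply_condition(set_gof(m, 30.0), VU170)
        assert a.compartments == b.compartments

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            PharmacologyCondition("caffeine")


class TestGofAndSwap:
    def test_gof_at_control_level_is_identity(self):
        m = build_subtype_model("SST")
        assert set_gof(m, 40.0).compartments == m.compartments

    def test_gof_changes_only_sodium_gate(self):
        m = build_subtype_model("SST")
        g = set_gof(m, 30.0)
        kc0, kc1 = m.soma.channels["kcnt1"], g.soma.channels["kcnt1"]
        assert kc1.sodium_gate.ec50 == 30.0
        assert kc1.voltage_gate == kc0.voltage_gate
        assert g.soma.channels["nat"] == m.soma.channels["nat"]

    def test_swap_to_self_is_identity(self):
        m = build_subtype_model("SST")
        assert swap_activation_curve(m, "SST").compartments == m.compartments

    def test_swap_replaces_voltage_gate_only(self):
        vip = build_subtype_model("VIP")
        swapped = swap_activation_curve(vip, "SST")
        sst = build_subtype_model("SST")
        assert (swapped.soma.channels["kcnt1"].voltage_gate.v50
                == sst.soma.channels["kcnt1"].voltage_gate.v50)
        assert swapped.soma.channels["nat"] == vip.soma.channels["nat"]
        assert (swapped.soma.channels["kcnt1"].sodium_gate
                == vip.soma.channels["kcnt1"].sodium_gate)


class TestIntegrator:
    def test_rest_is_stable(self):
        m = build_subtype_model("SST", jitter=0.0)
        res = integrate(m, {"mode": "iclamp", "i_nA": np.zeros((1, 8000))}, settle_ms=500.0)
        dvdt = np.abs(np.diff(res.v_soma[0])) / res.dt_ms
        assert dvdt.max() < 0.01  # mV/ms

    def test_passive_rc_charging_matches_analytics(self):
        # single-compartment passive cell: tau = cm/gleak, Rin = 1/(gleak*A)
        m = passive_only(build_subtype_model("SST", jitter=0.0))
        m = replace(m, compartments=(m.compartments[0],))
        soma = m.compartments[0]
        gleak = soma.channels["leak"].gbar
        tau_true = soma.cm * 1e-3 / gleak  # (uF/cm2)/(S/cm2) -> ms
        rin_true = 1.0 / (gleak * soma.area_cm2) / 1e6  # MOhm
        res = integrate(m, {"mode": "iclamp", "i_nA": step_stim(-0.05)}, backend="numpy")
        v = res.v_soma[0]
        deflect = v[13900] - v[1900]
        assert deflect == pytest.approx(-0.05 * rin_true, rel=0.01)  # nA * MOhm = mV
        # charge to 63.2% of the deflection after one time constant
        i_tau = 2000 + int(round(tau_true / res.dt_ms))
        assert v[i_tau] - v[1900] == pytest.approx(deflect * (1 - np.exp(-1)), rel=0.02)

    def test_dt_halving_convergence_subthreshold(self):
        m = build_subtype_model("SST", jitter=0.0)
        stim = {"mode": "iclamp", "i_nA": step_stim(-0.1)}
        r1 = integrate(m, stim, dt=0.025)
        stim2 = {"mode": "iclamp", "i_nA": np.repeat(step_stim(-0.1), 2, axis=1)}
        r2 = integrate(m, stim2, dt=0.0125)
        rms = np.sqrt(np.mean((r1.v_soma[0] - r2.v_soma[0, ::2]) ** 2))
        assert rms < 0.5

    def test_backends_agree_subthreshold(self):
        m = build_subtype_model("PV", jitter=0.0)
        stim = {"mode": "iclamp", "i_nA": step_stim(-0.1)}
        r1 = integrate(m, stim, backend="numba")
        r2 = integrate(m, stim, backend="numpy")
        assert np.abs(r1.v_soma - r2.v_soma).max() < 1e-9

    def test_current_balance_residual(self):
        # backward-Euler solution satisfies the discrete current balance
        m = build_subtype_model("SST", jitter=0.0)
        res = integrate(m, {"mode": "iclamp", "i_nA": step_stim(0.1, n_on=4000)},
                        backend="numpy", record_currents=True)
        assert res.balance_residual_nA < 1e-6

    def test_unbounded_stimulus_rejected(self):
        m = build_subtype_model("SST")
        stim = step_stim(0.1)
        stim[0, 10] = np.inf
        with pytest.raises(ValueError):
            integrate(m, {"mode": "iclamp", "i_nA": stim})

    def test_vclamp_is_ideal(self):
        m = build_subtype_model("SST", jitter=0.0)
        cmd = np.full((1, 4000), -70.0)
        cmd[0, 1000:] = 0.0
        res = integrate(m, {"mode": "vclamp", "v_mV": cmd}, dt=0.05)
        assert np.array_equal(res.v_soma, cmd)

    def test_na_clamp_zero_silences_kcnt1(self):
        m = apply_condition(build_subtype_model("SST", jitter=0.0), NA_CLAMP_0)
        cmd = np.full((1, 8000), -70.0)
        cmd[0, 2000:] = 20.0
        res = integrate(m, {"mode": "vclamp", "v_mV": cmd}, dt=0.05, record_currents=True)
        assert np.abs(res.currents["kcnt1"]).max() == 0.0

    def test_control_minus_na_clamp_0_recovers_kcnt1_current(self):
        # with [Na]i clamped, the subtraction difference equals the channel
        # current exactly (ideal space clamp)
        base = build_subtype_model("SST", jitter=0.0)
        cmd = np.full((1, 20000), -70.0)
        cmd[0, 2000:] = 10.0
        res_c = integrate(apply_condition(base, NA_CLAMP_10),
                          {"mode": "vclamp", "v_mV": cmd}, dt=0.05, record_currents=True)
        res_0 = integrate(apply_condition(base, NA_CLAMP_0),
                          {"mode": "vclamp", "v_mV": cmd}, dt=0.05)
        diff = res_c.i_clamp - res_0.i_clamp
        kcnt1 = res_c.currents["kcnt1"]
        rms_err = np.sqrt(np.mean((diff - kcnt1) ** 2))
        rms_sig = np.sqrt(np.mean(kcnt1**2))
        assert rms_err < 0.01 * rms_sig

    def test_dynamic_na_relaxes_to_rest_after_firing(self):
        m = build_subtype_model("SST", jitter=0.0)
        stim = np.zeros((1, 28000))
        stim[0, 2000:10000] = 0.3  # strong step, then 450 ms of rest
        res = integrate(m, {"mode": "iclamp", "i_nA": stim}, dt=0.025)
        na = res.na_soma[0]
        assert na[9999] > na[0] + 0.5  # loaded during firing
        # decays most of the way back within ~4 tau_na
        assert abs(na[-1] - na[0]) < 0.2 * (na[9999] - na[0])


class TestNaHandling:
    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            NaHandling(mode="diffusive")

    def test_clamped_mode_holds_concentration(self):
        m = build_subtype_model("PV", jitter=0.0,
                                na_mode=NaHandling(mode="clamped", clamp_mM=10.0))
        stim = step_stim(0.5, n_on=8000)
        res = integrate(m, {"mode": "iclamp", "i_nA": stim})
        assert np.all(res.na_soma == 10.0)
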