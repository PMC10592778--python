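"""In-silico experiment drivers: step families, ramps, subtractions, GOF runs.

The stimulus defaults mirror standard whole-cell protocols: 500-ms
current steps incrementing by 20 pA from -100 pA; 1-s voltage steps from
-80 to +50 mV in 10-mV increments from a -70 mV hold; and 5-s voltage
ramps at 20 mV/s from -80 mV for persistent-Na+ isolation.

Pharmacological "application" is instantaneous condition toggling, and
subtractions pair runs with identical stimuli and initial state, so the
difference currents are exact in the sense the experimental subtraction
only approximates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import ephys_features
from .io import SweepBundle
from .neuron_models import (
    CONTROL,
    NaHandling,
    NeuronModel,
    PharmacologyCondition,
    apply_condition,
    build_subtype_model,
    integrate,
    set_gof,
)
from .trace import Trace

__all__ = [
    "StepProtocol",
    "RampProtocol",
    "run_current_steps",
    "run_voltage_steps",
    "run_subtraction",
    "run_ramp_inap",
    "run_gof_experiment",
    "CURRENT_STEPS",
    "VOLTAGE_STEPS",
    "RAMP",
]


@dataclass(frozen=True)
class StepProtocol:
    """A family of square steps in current- or voltage-clamp."""

    mode: str = "iclamp"              # iclamp | vclamp
    holding: float = 0.0              # pA (iclamp) or mV (vclamp)
    start: float = -100.0             # first step amplitude (pA or mV)
    increment: float = 20.0
    n_steps: int = 31
    duration_ms: float = 500.0
    pre_ms: float = 100.0
    post_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.duration_ms <= 0 or self.n_steps < 1:
            raise ValueError("invalid protocol")
        if self.mode not in ("iclamp", "vclamp"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def amplitudes(self) -> np.ndarray:
        return self.start + self.increment * np.arange(self.n_steps)

    @property
    def total_ms(self) -> float:
        return self.pre_ms + self.duration_ms + self.post_ms

    def waveforms(self, dt: float) -> np.ndarray:
        """(n_steps, nt) stimulus array on the hold baseline."""
        nt = int(round(self.total_ms / dt))
        i0 = int(round(self.pre_ms / dt))
        i1 = i0 + int(round(self.duration_ms / dt))
        out = np.full((self.n_steps, nt), float(self.holding))
        out[:, i0:i1] = self.amplitudes[:, None]
        return out


CURRENT_STEPS = StepProtocol()

# per-subtype step ranges span each model's dynamic range up to
# depolarization block, mirroring the practice of injecting current
# "until the number of APs per stimulus reached a plateau"
GOF_STEP_COUNTS = {"glutamatergic": 31, "VIP": 13, "SST": 31, "PV": 41}

VOLTAGE_STEPS = StepProtocol(
    mode="vclamp", holding=-70.0, start=-80.0, increment=10.0, n_steps=14,
    duration_ms=1000.0, pre_ms=100.0, post_ms=100.0,
)


@dataclass(frozen=True)
class RampProtocol:
    """Slow voltage ramp for persistent-Na+ isolation."""

    start_mV: float = -80.0
    rate_mV_per_s: float = 20.0
    duration_s: float = 5.0
    interval_s: float = 10.0
    pre_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.rate_mV_per_s == 0:
            raise ValueError("invalid ramp")

    def waveform(self, dt: float) -> np.ndarray:
        n_pre = int(round(self.pre_ms / dt))
        n_ramp = int(round(self.duration_s * 1000.0 / dt))
        t = np.arange(n_ramp) * dt
        ramp = self.start_mV + self.rate_mV_per_s * t / 1000.0
        return np.concatenate([np.full(n_pre, self.start_mV), ramp])[None, :]

    def voltage_at(self, t_ms: np.ndarray) -> np.ndarray:
        """Command voltage at times measured from ramp onset (ms)."""
        return self.start_mV + self.rate_mV_per_s * np.asarray(t_ms) / 1000.0


RAMP = RampProtocol()


def _bundle_meta(model: NeuronModel, protocol, units: str, dt: float) -> dict:
    return {
        "id": f"{model.subtype}-seed{model.instance_seed}",
        "units": units,
        "sampling_rate_hz": 1000.0 / dt,
        "protocol": {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in vars(protocol).items()} | {"type": type(protocol).__name__},
        "condition": model.condition_label,
        "subtype": model.subtype,
    }


def run_current_steps(
    model: NeuronModel,
    protocol: StepProtocol = CURRENT_STEPS,
    dt: float = 0.025,
    settle_ms: float = 200.0,
) -> SweepBundle:
    """Run a current-step family; one somatic voltage sweep per step (mV)."""
    if protocol.mode != "iclamp":
        raise ValueError("run_current_steps needs a current-clamp protocol")
    stim = protocol.waveforms(dt) / 1000.0  # pA -> nA
    res = integrate(model, {"mode": "iclamp", "i_nA": stim}, dt=dt, settle_ms=settle_ms)
    sweeps = [
        Trace(
            res.v_soma[i],
            dt_ms=dt,
            units="mV",
            meta={
                "step_pA": float(a),
                "onset_ms": protocol.pre_ms,
                "duration_ms": protocol.duration_ms,
            },
        )
        for i, a in enumerate(protocol.amplitudes)
    ]
    return SweepBundle(meta=_bundle_meta(model, protocol, "mV", dt), sweeps=sweeps)


def run_voltage_steps(
    model: NeuronModel,
    protocol: StepProtocol = VOLTAGE_STEPS,
    condition: PharmacologyCondition = CONTROL,
    dt: float = 0.025,
    settle_ms: float = 200.0,
) -> SweepBundle:
    """Run a voltage-step family under a condition; clamp current sweeps (pA)."""
    if protocol.mode != "vclamp":
        raise ValueError("run_voltage_steps needs a voltage-clamp protocol")
    m = apply_condition(model, condition)
    cmd = protocol.waveforms(dt)
    res = integrate(m, {"mode": "vclamp", "v_mV": cmd}, dt=dt, settle_ms=settle_ms)
    sweeps = [
        Trace(
            res.i_clamp[i] * 1000.0,  # nA -> pA
            dt_ms=dt,
            units="pA",
            meta={
                "step_mV": float(a),
                "onset_ms": protocol.pre_ms,
                "duration_ms": protocol.duration_ms,
            },
        )
        for i, a in enumerate(protocol.amplitudes)
    ]
    return SweepBundle(meta=_bundle_meta(m, protocol, "pA", dt), sweeps=sweeps)


def run_subtraction(
    model: NeuronModel,
    blocker: PharmacologyCondition,
    protocol: StepProtocol = VOLTAGE_STEPS,
    dt: float = 0.025,
    settle_ms: float = 200.0,
) -> SweepBundle:
    """Difference sweep set: control minus blocker, sample-aligned.

    Both runs use identical stimuli and initial state, mirroring the
    experimental subtraction of TTX/VU170 traces from control traces.
    """
    control = run_voltage_steps(model, protocol, CONTROL, dt=dt, settle_ms=settle_ms)
    blocked = run_voltage_steps(model, protocol, blocker, dt=dt, settle_ms=settle_ms)
    if len(control) != len(blocked):
        raise ValueError("mismatched protocols between control and blocked runs")
    sweeps = [
        Trace(c.data - b.data, dt_ms=c.dt_ms, units="pA", meta=dict(c.meta))
        for c, b in zip(control, blocked)
    ]
    meta = dict(control.meta)
    meta["condition"] = f"control-minus-{blocker.label}"
    return SweepBundle(meta=meta, sweeps=sweeps)


def run_ramp_inap(
    model: NeuronModel,
    protocol: RampProtocol = RAMP,
    dt: float = 0.05,
    settle_ms: float = 200.0,
) -> Trace:
    """Ramp difference trace (control minus TTX), isolating persistent Na+.

    TTX application is instantaneous, so a single control ramp and a
    single TTX ramp suffice (the experimental averaging guards against
    drift that the simulation does not have).  Only the ramp segment
    (after the pre-ramp hold) is returned.
    """
    cmd = protocol.waveform(dt)
    from .neuron_models import TTX  # local import to avoid cycle noise

    res_c = integrate(model, {"mode": "vclamp", "v_mV": cmd}, dt=dt, settle_ms=settle_ms)
    res_t = integrate(
        apply_condition(model, TTX), {"mode": "vclamp", "v_mV": cmd}, dt=dt,
        settle_ms=settle_ms,
    )
    n_pre = int(round(protocol.pre_ms / dt))
    diff = (res_c.i_clamp[0] - res_t.i_clamp[0])[n_pre:] * 1000.0  # pA
    return Trace(
        diff,
        dt_ms=dt,
        units="pA",
        meta={
            "ramp_start_mV": protocol.start_mV,
            "ramp_rate_mV_per_s": protocol.rate_mV_per_s,
            "condition": "control-minus-ttx",
        },
    )


def run_gof_experiment(
    subtypes=("VIP", "SST", "PV"),
    ec50_levels=(40.0, 35.0, 30.0),
    nap_scale: float = 1.0,
    n_instances: int = 10,
    seed: int = 0,
    protocol: StepProtocol | None = None,
    dt: float = 0.025,
) -> pd.DataFrame:
    """Full-factorial GOF simulation summary.

    For every (subtype, instance, EC50 level) the model is driven through
    the current-step family and summarised by its F-I curve, rheobase,
    input resistance, and AP amplitude.  ``nap_scale`` rescales the
    persistent-Na+ conductance (2.0 models the observed two-fold I_NaP
    increase).  Returns one row per (instance, condition).
    """
    from .channels import ChannelLibraryConfig

    rows = []
    for subtype in subtypes:
        proto = protocol or StepProtocol(n_steps=GOF_STEP_COUNTS.get(subtype, 31))
        for inst in range(n_instances):
            inst_seed = seed * 1000 + inst
            for ec50 in ec50_levels:
                cfg = ChannelLibraryConfig(nap_scale_factor=nap_scale)
                model = build_subtype_model(subtype, config=cfg, instance_seed=inst_seed)
                model = set_gof(model, ec50)
                bundle = run_current_steps(model, proto, dt=dt)
                feats = ephys_features.extract_features(bundle)
                rows.append(
                    {
                        "subtype": subtype,
                        "instance": inst,
                        "instance_seed": inst_seed,
                        "ec50_mM": float(ec50),
                        "nap_scale": float(nap_scale),
                        "rheobase_pA": feats.rheobase,
                        "rin_MOhm": feats.rin,
                        "ap_amplitude_mV": feats.ap_amplitude,
                        "max_rate_Hz": feats.max_rate,
                        "fi_steps_pA": [s for s, _ in feats.fi_curve],
                        "fi_counts": [c for _, c in feats.fi_curve],
                    }
                )
    return pd.DataFrame(rows)


def fi_long(summary: pd.DataFrame) -> pd.DataFrame:
    """Explode a GOF summary into tidy (step, count) rows."""
    recs = []
    for _, row in summary.iterrows():
        for step, count in zip(row["fi_steps_pA"], row["fi_counts"]):
            recs.append(
                {
                    "subtype": row["subtype"],
                    "instance": row["instance"],
                    "ec50_mM": row["ec50_mM"],
                    "nap_scale": row["nap_scale"],
                    "step_pA": step,
                    "ap_count": count,
                }
            )
    return pd.DataFrame(recs)
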