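"""Reduced compartmental models of four cortical neuron types.

Each model has three cylindrical compartments (soma, dendritic cable,
axon initial segment) in a star topology around the soma, carrying the
standard conductance set (transient Na+, persistent Na+, delayed
rectifier K+, leak) plus the KCNT1 K_Na conductance in all three
compartments at 0.03 S/cm^2.

The four subtypes (glutamatergic, VIP, SST, PV) differ in geometry,
passive leak, spike-conductance densities and kinetics shift, and in the
voltage dependence of their KCNT1 channel: SST/PV carry a left-shifted,
shallow activation curve (active at subthreshold voltages), while
VIP/glutamatergic carry a right-shifted, steep one (recruited only during
spikes).  These voltage-gate defaults are free parameters calibrated to
reproduce the qualitative subtype physiology; they are fully configurable.

Intracellular Na+ is handled either clamped (fixed mM, for subtraction
protocols) or as a dynamic submembrane shell (depth 0.1 um) filled by Na+
influx and cleared by first-order extrusion back to the resting 10 mM.

Integration is fixed-step: backward Euler on the coupled voltage
equations (the star topology is solved by exact elimination of the child
compartments) with staggered exponential-Euler gate updates, dt = 0.025 ms
by default.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .channels import (
    ChannelLibraryConfig,
    ChannelSpec,
    build_channel_library,
    hh_steady_tau,
    kcnt1_open_fraction,
    na_gate_activation,
    voltage_gate_activation,
    with_ec50,
    with_voltage_gate,
)

__all__ = [
    "Compartment",
    "NaHandling",
    "NeuronModel",
    "PharmacologyCondition",
    "SimResult",
    "SUBTYPES",
    "build_subtype_model",
    "integrate",
    "apply_condition",
    "set_gof",
    "swap_activation_curve",
    "IntegrationError",
]

SUBTYPES = ("glutamatergic", "VIP", "SST", "PV")

FARADAY = 96485.332  # C/mol


class IntegrationError(RuntimeError):
    """Raised when the membrane-potential solution diverges."""


@dataclass(frozen=True)
class Compartment:
    """One cylindrical compartment with its channel densities."""

    role: str                     # soma | dendrite | axon
    length: float                 # um
    diameter: float               # um
    cm: float = 1.0               # uF/cm^2
    ra: float = 150.0             # ohm*cm
    channels: dict[str, ChannelSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError("compartment geometry must be positive")

    @property
    def area_cm2(self) -> float:
        # lateral cylinder surface; um^2 -> cm^2
        return np.pi * self.length * self.diameter * 1e-8


@dataclass(frozen=True)
class NaHandling:
    """Intracellular Na+ handling mode.

    ``clamped``: [Na]i held at ``clamp_mM`` regardless of influx (used for
    the subtraction protocols run "with 10 mM and 0 mM internal Na+").
    ``dynamic``: submembrane shell of ``shell_depth_um`` filled by Na+
    influx and relaxing to ``resting_mM`` with time constant ``tau_na_ms``.
    """

    mode: str = "dynamic"
    clamp_mM: float = 10.0
    shell_depth_um: float = 0.1
    tau_na_ms: float = 100.0
    resting_mM: float = 10.0

    def __post_init__(self) -> None:
        if self.mode not in ("dynamic", "clamped"):
            raise ValueError(f"unknown Na handling mode {self.mode!r}")
        if self.clamp_mM < 0 or self.resting_mM < 0:
            raise ValueError("Na concentrations must be >= 0")
        if self.shell_depth_um <= 0 or self.tau_na_ms <= 0:
            raise ValueError("shell depth and tau must be > 0")


@dataclass(frozen=True)
class NeuronModel:
    subtype: str
    compartments: tuple[Compartment, ...]   # soma first; others attach to it
    na_mode: NaHandling = field(default_factory=NaHandling)
    instance_seed: int = 0
    condition_label: str = "control"

    def __post_init__(self) -> None:
        roles = [c.role for c in self.compartments]
        if roles.count("soma") != 1 or roles[0] != "soma":
            raise ValueError("exactly one soma required, listed first")

    @property
    def soma(self) -> Compartment:
        return self.compartments[0]

    def kcnt1(self) -> ChannelSpec:
        return self.soma.channels["kcnt1"]


@dataclass(frozen=True)
class PharmacologyCondition:
    """A simulated bath/internal manipulation.

    ``ttx`` zeroes both the transient and persistent Na+ conductances,
    ``vu170`` zeroes only KCNT1, ``na_clamp_10``/``na_clamp_0`` fix
    intracellular Na+.  Conditions are idempotent and leave the input
    model untouched.
    """

    label: str

    _KNOWN = ("control", "ttx", "vu170", "na_clamp_10", "na_clamp_0")

    def __post_init__(self) -> None:
        if self.label not in self._KNOWN:
            raise ValueError(f"unknown condition {self.label!r}")


CONTROL = PharmacologyCondition("control")
TTX = PharmacologyCondition("ttx")
VU170 = PharmacologyCondition("vu170")
NA_CLAMP_10 = PharmacologyCondition("na_clamp_10")
NA_CLAMP_0 = PharmacologyCondition("na_clamp_0")


# ---------------------------------------------------------------------------
# subtype calibration
#
# Geometry and densities are calibrated against the qualitative subtype
# physiology: VIP large Rin / small rheobase / wide APs / low max rate;
# PV small Rin / large rheobase / narrow APs / large AHP / fast spiking;
# SST intermediate with the most hyperpolarized AP threshold;
# glutamatergic regular spiking.

SUBTYPE_CALIBRATION: dict[str, dict] = {
    "glutamatergic": dict(
        soma=(25.0, 25.0), dend=(250.0, 2.5), axon=(60.0, 1.0),
        gleak=1.0e-4, eleak=-70.0, gnat=0.05, gkdr=0.006, vt=-55.0,
        kcnt1_v50=-10.0, kcnt1_k=6.0,
    ),
    # VIP: small cell with a strongly right-shifted, steep KCNT1 curve and
    # low-amplitude spikes, so K_Na is recruited by voltage-clamp steps but
    # barely by its own action potentials (suprathreshold current with no
    # effect on excitability)
    "VIP": dict(
        soma=(15.0, 15.0), dend=(150.0, 1.5), axon=(50.0, 1.0),
        gleak=0.7e-4, eleak=-70.0, gnat=0.012, gkdr=0.003, vt=-54.0,
        kcnt1_v50=25.0, kcnt1_k=4.0,
    ),
    "SST": dict(
        soma=(18.0, 18.0), dend=(200.0, 2.0), axon=(55.0, 1.0),
        gleak=0.9e-4, eleak=-70.0, gnat=0.035, gkdr=0.003, vt=-58.0,
        kcnt1_v50=-35.0, kcnt1_k=14.0,
    ),
    # PV: large leak (small Rin) and an AIS-like axon with dense Na+
    # conductance, so the tied persistent Na+ current is a substantial
    # fraction of the perithreshold current balance
    "PV": dict(
        soma=(25.0, 25.0), dend=(250.0, 2.5), axon=(60.0, 1.0),
        gleak=4.0e-4, eleak=-70.0, gnat=0.15, gkdr=0.02, vt=-50.0,
        kcnt1_v50=-35.0, kcnt1_k=14.0, axon_scale=20.0,
    ),
}

# spike conductances are scaled down in dendrites and up in the axon initial
# segment; the axon factor is per-subtype (cal key "axon_scale", default 2)
_ROLE_SCALE = {"soma": 1.0, "dendrite": 0.1, "axon": 2.0}


def build_subtype_model(
    subtype: str,
    config: ChannelLibraryConfig | None = None,
    instance_seed: int = 0,
    jitter: float = 0.10,
    na_mode: NaHandling | None = None,
) -> NeuronModel:
    """Build one calibrated model instance of the given subtype.

    ``instance_seed`` draws a deterministic +-``jitter`` multiplicative
    perturbation of conductance densities and geometry, emulating the
    cell-to-cell variability of a population of ~10 model neurons per
    class.  Seed 0 with jitter 0 gives the calibration midpoint.
    """
    if subtype not in SUBTYPES:
        raise ValueError(f"unknown subtype {subtype!r}; expected one of {SUBTYPES}")
    cal = SUBTYPE_CALIBRATION[subtype]
    cfg = config or ChannelLibraryConfig()
    cfg = replace(
        cfg,
        gleak=cal["gleak"],
        eleak=cal["eleak"],
        gnat=cal["gnat"],
        gkdr=cal["gkdr"],
        vt=cal["vt"],
        kcnt1_v50=cal["kcnt1_v50"],
        kcnt1_k=cal["kcnt1_k"],
        kcnt1_tau=cal.get("kcnt1_tau", cfg.kcnt1_tau),
    )
    rng = np.random.default_rng(
        np.random.SeedSequence([SUBTYPES.index(subtype), int(instance_seed)])
    )

    def jit() -> float:
        return 1.0 + jitter * (2.0 * rng.random() - 1.0) if jitter > 0 else 1.0

    geom_jit = jit()
    comps = []
    for role, key in (("soma", "soma"), ("dendrite", "dend"), ("axon", "axon")):
        length, diam = cal[key]
        lib = build_channel_library(cfg)
        scale = _ROLE_SCALE[role]
        if role == "axon":
            scale = cal.get("axon_scale", scale)
        channels = {}
        for name, ch in lib.items():
            g = ch.gbar
            if name in ("nat", "nap", "kdr"):
                g = g * scale * jit()
            elif name == "leak":
                g = g * jit()
            # KCNT1 density is uniform across compartments (0.03 S/cm^2)
            channels[name] = replace(ch, gbar=g)
        comps.append(
            Compartment(
                role=role,
                length=length * geom_jit,
                diameter=diam * geom_jit,
                ra=cal.get("ra", 150.0),
                channels=channels,
            )
        )
    return NeuronModel(
        subtype=subtype,
        compartments=tuple(comps),
        na_mode=na_mode or NaHandling(),
        instance_seed=instance_seed,
    )


# ---------------------------------------------------------------------------
# pure model transformations


def _map_channels(model: NeuronModel, fn) -> NeuronModel:
    comps = tuple(
        replace(c, channels={name: fn(name, ch) for name, ch in c.channels.items()})
        for c in model.compartments
    )
    return replace(model, compartments=comps)


def apply_condition(model: NeuronModel, condition: PharmacologyCondition) -> NeuronModel:
    """Return a copy of the model under the given pharmacology condition."""
    label = condition.label
    if label == "control":
        return replace(model, condition_label="control")
    if label == "ttx":
        out = _map_channels(
            model, lambda n, ch: replace(ch, gbar=0.0) if n in ("nat", "nap") else ch
        )
    elif label == "vu170":
        out = _map_channels(model, lambda n, ch: replace(ch, gbar=0.0) if n == "kcnt1" else ch)
    elif label in ("na_clamp_10", "na_clamp_0"):
        value = 10.0 if label == "na_clamp_10" else 0.0
        out = replace(model, na_mode=replace(model.na_mode, mode="clamped", clamp_mM=value))
    else:  # pragma: no cover - guarded by PharmacologyCondition
        raise ValueError(label)
    return replace(out, condition_label=label)


def set_gof(model: NeuronModel, ec50: float) -> NeuronModel:
    """Return a copy with the KCNT1 sodium-gate EC50 set to ``ec50`` (mM)."""
    if ec50 <= 0:
        raise ValueError("ec50 must be > 0")
    return _map_channels(
        model, lambda n, ch: with_ec50(ch, ec50) if n == "kcnt1" else ch
    )


def swap_activation_curve(model: NeuronModel, donor_subtype: str) -> NeuronModel:
    """Replace the KCNT1 voltage-gate (V50, k) with the donor subtype's."""
    if donor_subtype not in SUBTYPES:
        raise ValueError(f"unknown donor subtype {donor_subtype!r}")
    cal = SUBTYPE_CALIBRATION[donor_subtype]
    v50, k = cal["kcnt1_v50"], cal["kcnt1_k"]
    return _map_channels(
        model, lambda n, ch: with_voltage_gate(ch, v50, k) if n == "kcnt1" else ch
    )


# ---------------------------------------------------------------------------
# integration engine


@dataclass
class SimResult:
    """Vectorized simulation output.

    Arrays are indexed (sweep, time) except ``v_all``/``na_all`` which are
    (sweep, compartment, time).  Currents are whole-cell sums in nA
    (outward positive); ``i_clamp`` is the voltage-clamp current when in
    clamp mode.
    """

    dt_ms: float
    t_ms: np.ndarray
    v_soma: np.ndarray
    na_soma: np.ndarray
    v_all: np.ndarray | None = None
    na_all: np.ndarray | None = None
    currents: dict[str, np.ndarray] | None = None
    i_clamp: np.ndarray | None = None
    balance_residual_nA: float | None = None


class _Engine:
    """Precompiled arrays for one model; integrates batches of sweeps."""

    CHANNELS = ("nat", "nap", "kdr", "leak", "kcnt1")

    def __init__(self, model: NeuronModel):
        self.model = model
        comps = model.compartments
        self.nc = len(comps)
        self.area = np.array([c.area_cm2 for c in comps])                 # cm^2
        self.cap = np.array([c.cm * c.area_cm2 * 1e3 for c in comps])     # nF
        # absolute conductances, uS
        self.g = {}
        self.erev = {}
        self.gates = {}
        for name in self.CHANNELS:
            chans = [c.channels[name] for c in comps]
            self.g[name] = np.array([ch.gbar * a * 1e6 for ch, a in zip(chans, self.area)])
            self.erev[name] = np.array([ch.erev for ch in chans])
            # kinetics are shared across compartments (densities differ);
            # gate updates are vectorized on the compartment-0 specs
            self.gates[name] = chans[0]
        # axial conductances child<->soma, uS
        self.gax = np.zeros(self.nc)
        soma = comps[0]
        for i, c in enumerate(comps[1:], start=1):
            r = 0.0
            for part in (soma, c):
                a_cm = part.diameter * 1e-4 / 2.0
                l_cm = part.length * 1e-4
                r += part.ra * (l_cm / 2.0) / (np.pi * a_cm**2)           # ohm
            self.gax[i] = 1e6 / r
        # Na shell factor: mM/ms per (nA of Na current) in each compartment
        d_cm = model.na_mode.shell_depth_um * 1e-4
        # I[nA] -> mA/cm^2: /(area*1e6); mA/cm^2 -> mM/ms: 1/(F*d_cm)
        self.na_factor = 1.0 / (self.area * 1e6) / (FARADAY * d_cm)

    # -- gate helpers ------------------------------------------------------

    def init_state(self, nsw: int, v0: float):
        v = np.full((nsw, self.nc), v0)
        na0 = (
            self.model.na_mode.clamp_mM
            if self.model.na_mode.mode == "clamped"
            else self.model.na_mode.resting_mM
        )
        na = np.full((nsw, self.nc), float(na0))
        state = {}
        for name in ("nat", "nap", "kdr"):
            state[name] = [hh_steady_tau(g, v)[0] for g in self.gates[name].gates]
        state["kcnt1"] = [kcnt1_open_fraction(v, na, self.gates["kcnt1"])]
        return v, na, state

    def _update_gates(self, state, v, na, dt):
        for name in ("nat", "nap", "kdr"):
            for gi, gate in enumerate(self.gates[name].gates):
                m = state[name][gi]
                minf, tau = hh_steady_tau(gate, v)
                np.add(minf, (m - minf) * np.exp(-dt / tau), out=m)
        kc = self.gates["kcnt1"]
        m = state["kcnt1"][0]
        minf = kcnt1_open_fraction(v, na, kc)
        decay = np.exp(-dt / kc.voltage_gate.tau_act)
        np.add(minf, (m - minf) * decay, out=m)

    def _open_fractions(self, state):
        """Product of gate states (with powers) per channel, (nsw, nc)."""
        out = {}
        for name in ("nat", "nap", "kdr"):
            prod = None
            for gi, gate in enumerate(self.gates[name].gates):
                m = state[name][gi] ** gate.power
                prod = m if prod is None else prod * m
            out[name] = prod
        out["leak"] = 1.0
        out["kcnt1"] = state["kcnt1"][0]
        return out

    def _conductances(self, state):
        op = self._open_fractions(state)
        return {name: self.g[name] * op[name] for name in self.CHANNELS}  # uS, (nsw,nc)

    def _na_step(self, na, g_na_channels, v, dt):
        """Advance the submembrane shell [Na]i by one explicit Euler step."""
        mode = self.model.na_mode
        if mode.mode == "clamped":
            return na
        i_na = np.zeros_like(na)
        for name in ("nat", "nap"):
            i_na += g_na_channels[name] * (v - self.erev[name][None, :])  # nA, inward < 0
        influx = -i_na * self.na_factor[None, :]                          # mM/ms
        dna = influx - (na - mode.resting_mM) / mode.tau_na_ms
        out = na + dt * dna
        return np.maximum(out, 0.0)

    # -- current clamp -----------------------------------------------------

    def run_iclamp(
        self,
        i_inj_nA: np.ndarray,          # (nsw, nt) injected at the soma
        dt: float,
        v0: float = -70.0,
        settle_ms: float = 200.0,
        record_all: bool = False,
        record_currents: bool = False,
    ) -> SimResult:
        nsw, nt = i_inj_nA.shape
        v, na, state = self.init_state(nsw, v0)
        n_settle = int(round(settle_ms / dt))
        cap_dt = self.cap / dt                                            # nF/ms = uS*mV? (nA/mV)
        gax = self.gax

        v_soma = np.empty((nsw, nt))
        na_soma = np.empty((nsw, nt))
        v_all = np.empty((nsw, self.nc, nt)) if record_all else None
        na_all = np.empty((nsw, self.nc, nt)) if record_all else None
        currents = (
            {name: np.empty((nsw, nt)) for name in self.CHANNELS} if record_currents else None
        )
        residual = 0.0

        for step in range(-n_settle, nt):
            i_stim = i_inj_nA[:, step] if step >= 0 else np.zeros(nsw)
            self._update_gates(state, v, na, dt)
            cond = self._conductances(state)
            gtot = sum(cond.values())                                     # (nsw, nc)
            gesum = sum(cond[name] * self.erev[name][None, :] for name in self.CHANNELS)
            # backward Euler: (C/dt + G + Gax) Vnew - coupling = C/dt V + sum gE + Istim
            a = cap_dt[None, :] + gtot + gax[None, :]
            a[:, 0] += gax[1:].sum() - gax[0]
            b = cap_dt[None, :] * v + gesum
            b[:, 0] += i_stim
            # eliminate children (star topology)
            denom = a[:, 0].copy()
            rhs = b[:, 0].copy()
            for ci in range(1, self.nc):
                denom -= gax[ci] ** 2 / a[:, ci]
                rhs += gax[ci] * b[:, ci] / a[:, ci]
            v_new = np.empty_like(v)
            v_new[:, 0] = rhs / denom
            for ci in range(1, self.nc):
                v_new[:, ci] = (b[:, ci] + gax[ci] * v_new[:, 0]) / a[:, ci]
            if np.any(np.abs(v_new) > 200.0):
                raise IntegrationError("membrane potential diverged beyond +-200 mV")
            na = self._na_step(na, cond, v_new, dt)
            if record_currents and step >= 0:
                for name in self.CHANNELS:
                    i_ch = cond[name] * (v_new - self.erev[name][None, :])
                    currents[name][:, step] = i_ch.sum(axis=1)
                # discrete current balance of the solved system
                i_cap = (cap_dt[None, :] * (v_new - v)).sum(axis=1)
                i_ion = sum(
                    (cond[name] * (v_new - self.erev[name][None, :])).sum(axis=1)
                    for name in self.CHANNELS
                )
                residual = max(residual, float(np.abs(i_cap + i_ion - i_stim).max()))
            v = v_new
            if step >= 0:
                v_soma[:, step] = v[:, 0]
                na_soma[:, step] = na[:, 0]
                if record_all:
                    v_all[:, :, step] = v
                    na_all[:, :, step] = na

        return SimResult(
            dt_ms=dt,
            t_ms=np.arange(nt) * dt,
            v_soma=v_soma,
            na_soma=na_soma,
            v_all=v_all,
            na_all=na_all,
            currents=currents,
            balance_residual_nA=residual if record_currents else None,
        )

    # -- voltage clamp (ideal space clamp) ----------------------------------

    def run_vclamp(
        self,
        v_cmd_mV: np.ndarray,          # (nsw, nt)
        dt: float,
        settle_ms: float = 200.0,
        record_currents: bool = True,
    ) -> SimResult:
        nsw, nt = v_cmd_mV.shape
        v0 = float(v_cmd_mV[0, 0])
        v, na, state = self.init_state(nsw, v0)
        n_settle = int(round(settle_ms / dt))

        na_soma = np.empty((nsw, nt))
        i_clamp = np.empty((nsw, nt))
        currents = (
            {name: np.empty((nsw, nt)) for name in self.CHANNELS} if record_currents else None
        )

        for step in range(-n_settle, nt):
            vc = v_cmd_mV[:, max(step, 0)]
            v = np.repeat(vc[:, None], self.nc, axis=1)
            self._update_gates(state, v, na, dt)
            cond = self._conductances(state)
            na = self._na_step(na, cond, v, dt)
            if step >= 0:
                total = np.zeros(nsw)
                for name in self.CHANNELS:
                    i_ch = (cond[name] * (v - self.erev[name][None, :])).sum(axis=1)
                    total += i_ch
                    if record_currents:
                        currents[name][:, step] = i_ch
                i_clamp[:, step] = total
                na_soma[:, step] = na[:, 0]

        return SimResult(
            dt_ms=dt,
            t_ms=np.arange(nt) * dt,
            v_soma=v_cmd_mV.copy(),
            na_soma=na_soma,
            currents=currents,
            i_clamp=i_clamp,
        )

    # -- compiled fast paths -------------------------------------------------

    def run_iclamp_numba(self, i_inj_nA, dt, settle_ms=200.0, record_all=False,
                         record_currents=False, v0=-70.0) -> SimResult:
        from ._kernels import iclamp_kernel

        n_settle = int(round(settle_ms / dt))
        nt = i_inj_nA.shape[1]
        v_all, na_all, cur, diverged = iclamp_kernel(
            np.ascontiguousarray(i_inj_nA, dtype=float), dt, n_settle,
            *_kernel_args(self), float(v0),
        )
        if diverged:
            raise IntegrationError("membrane potential diverged beyond +-200 mV")
        currents = None
        if record_currents:
            currents = {name: cur[i] for i, name in enumerate(self.CHANNELS)}
        return SimResult(
            dt_ms=dt,
            t_ms=np.arange(nt) * dt,
            v_soma=v_all[:, 0, :].copy(),
            na_soma=na_all[:, 0, :].copy(),
            v_all=v_all if record_all else None,
            na_all=na_all if record_all else None,
            currents=currents,
        )

    def run_vclamp_numba(self, v_cmd_mV, dt, settle_ms=200.0,
                         record_currents=True) -> SimResult:
        from ._kernels import vclamp_kernel

        n_settle = int(round(settle_ms / dt))
        nt = v_cmd_mV.shape[1]
        na_all, cur, i_clamp = vclamp_kernel(
            np.ascontiguousarray(v_cmd_mV, dtype=float), dt, n_settle,
            *_kernel_args(self),
        )
        currents = None
        if record_currents:
            currents = {name: cur[i] for i, name in enumerate(self.CHANNELS)}
        return SimResult(
            dt_ms=dt,
            t_ms=np.arange(nt) * dt,
            v_soma=np.asarray(v_cmd_mV, dtype=float).copy(),
            na_soma=na_all[:, 0, :].copy(),
            currents=currents,
            i_clamp=i_clamp,
        )


def _kernel_args(eng: "_Engine") -> tuple:
    kc = eng.gates["kcnt1"]
    na_gate = kc.sodium_gate
    v_gate = kc.voltage_gate
    mode = eng.model.na_mode
    return (
        eng.cap, eng.gax,
        eng.g["nat"], eng.g["nap"], eng.g["kdr"], eng.g["leak"], eng.g["kcnt1"],
        float(eng.erev["nat"][0]), float(eng.erev["kdr"][0]), float(eng.erev["leak"][0]),
        float(eng.gates["kdr"].gates[0].vshift),
        float(eng.gates["nat"].gates[0].vshift - eng.gates["kdr"].gates[0].vshift),
        float(eng.gates["nat"].gates[1].rate_scale),
        float(na_gate.ec50), float(na_gate.hill),
        float(v_gate.v50), float(v_gate.k), float(v_gate.tau_act),
        mode.mode == "clamped", float(mode.clamp_mM), float(mode.resting_mM),
        float(mode.tau_na_ms), eng.na_factor,
    )


def _numba_compatible(eng: "_Engine") -> bool:
    """The compiled kernels assume the standard channel-library kinetics."""
    try:
        nat, nap, kdr = eng.gates["nat"], eng.gates["nap"], eng.gates["kdr"]
        fns = [g.rate_fn for g in nat.gates] + [g.rate_fn for g in nap.gates] + [
            g.rate_fn for g in kdr.gates
        ]
        if fns != ["nat_m", "nat_h", "nap_m", "kdr_n"]:
            return False
        # h, nap and kdr share the base shift; the nat m gate may carry an
        # extra activation offset handled explicitly by the kernels
        shifts = {nat.gates[1].vshift, nap.gates[0].vshift, kdr.gates[0].vshift}
        if len(shifts) != 1:
            return False
        kc = eng.gates["kcnt1"]
        return kc.mechanism == "kcnt1"
    except (KeyError, AttributeError, StopIteration):
        return False


def integrate(
    model: NeuronModel,
    stimulus: dict,
    dt: float = 0.025,
    settle_ms: float = 200.0,
    record_all: bool = False,
    record_currents: bool = False,
    backend: str = "auto",
) -> SimResult:
    """Integrate the model under a stimulus description.

    ``stimulus`` is a dict with ``mode`` of ``"iclamp"`` (keys:
    ``i_nA`` array (nsw, nt) injected at the soma) or ``"vclamp"``
    (keys: ``v_mV`` array (nsw, nt) command voltage).  Current clamp
    solves the full cable equations; voltage clamp is an ideal space
    clamp (every compartment follows the command), so the clamp current
    is exactly the summed ionic current.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    eng = _Engine(model)
    from ._kernels import HAVE_NUMBA

    use_numba = backend == "numba" or (
        backend == "auto" and HAVE_NUMBA and _numba_compatible(eng)
    )
    mode = stimulus.get("mode")
    if mode == "iclamp":
        i = np.atleast_2d(np.asarray(stimulus["i_nA"], dtype=float))
        if not np.all(np.isfinite(i)):
            raise ValueError("stimulus must be bounded")
        if use_numba:
            return eng.run_iclamp_numba(
                i, dt, settle_ms=settle_ms, record_all=record_all,
                record_currents=record_currents,
            )
        return eng.run_iclamp(
            i, dt, settle_ms=settle_ms, record_all=record_all, record_currents=record_currents
        )
    if mode == "vclamp":
        vc = np.atleast_2d(np.asarray(stimulus["v_mV"], dtype=float))
        if not np.all(np.isfinite(vc)):
            raise ValueError("stimulus must be bounded")
        if use_numba:
            return eng.run_vclamp_numba(vc, dt, settle_ms=settle_ms,
                                        record_currents=record_currents)
        return eng.run_vclamp(vc, dt, settle_ms=settle_ms, record_currents=record_currents)
    raise ValueError(f"unknown stimulus mode {mode!r}")
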