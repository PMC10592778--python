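"""Conductance models: the KCNT1 (Slack) K_Na channel and its companions.

The centrepiece is a Hodgkin–Huxley-style KCNT1 conductance with two
multiplicative gates: a sodium gate following a Hill function of the
intracellular Na+ concentration (EC50 = 40 mM, Hill coefficient 3.5 in the
wild-type configuration) and a voltage gate following a Boltzmann function
of membrane potential.  The two steady states combine into a single
activation variable with first-order kinetics (time constant ``tau_act``).

Gain of function (GOF) is modelled by lowering the sodium-gate EC50
(40 -> 35 -> 30 mM), which increases channel open probability at any given
intracellular Na+.

The companion conductances (transient Na+ m3h, persistent Na+, delayed
rectifier K+ n4, leak) use classic alpha/beta rate kinetics of the kind
used in minimal cortical neuron models.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "GateSpec",
    "ChannelSpec",
    "ChannelLibraryConfig",
    "na_gate_activation",
    "voltage_gate_activation",
    "kcnt1_steady_state",
    "gate_kinetics_step",
    "build_channel_library",
    "save_channel_library",
    "load_channel_library",
]

VOLTAGE_BOLTZMANN = "voltage-boltzmann"
SODIUM_HILL = "sodium-hill"
HH_RATE = "hh-rate"

_HH_RATE_FNS = ("nat_m", "nat_h", "kdr_n", "nap_m")


@dataclass(frozen=True)
class GateSpec:
    """One activation (or inactivation) gate of a conductance.

    ``kind`` selects the gating law:

    - ``voltage-boltzmann``: steady state 1/(1 + exp(-(V - v50)/k)); set
      ``inverted`` for inactivation gates (1 minus the Boltzmann).
    - ``sodium-hill``: steady state x**hill / (x**hill + ec50**hill) in the
      intracellular Na+ concentration x.
    - ``hh-rate``: classic alpha/beta kinetics selected by ``rate_fn``
      (transient-Na m/h, delayed-rectifier n), shifted by ``vshift``.

    ``tau_act`` (ms) is the fixed activation time constant for the first
    two kinds; hh-rate gates derive tau from their rate functions.
    ``power`` is the exponent the gate enters the conductance with.
    """

    kind: str
    v50: float | None = None          # mV
    k: float | None = None            # mV, slope factor (> 0)
    ec50: float | None = None         # mM
    hill: float | None = None         # dimensionless
    tau_act: float = 1.0              # ms
    power: int = 1
    inverted: bool = False
    rate_fn: str | None = None
    vshift: float = 0.0               # mV, shifts hh-rate kinetics
    rate_scale: float = 1.0           # multiplies both rates (1/tau scale)

    def __post_init__(self) -> None:
        if self.kind == VOLTAGE_BOLTZMANN:
            if self.v50 is None or self.k is None:
                raise ValueError("voltage-boltzmann gate needs v50 and k")
            if self.k <= 0:
                raise ValueError(f"slope factor k must be > 0, got {self.k}")
        elif self.kind == SODIUM_HILL:
            if self.ec50 is None or self.hill is None:
                raise ValueError("sodium-hill gate needs ec50 and hill")
            if self.ec50 <= 0 or self.hill <= 0:
                raise ValueError("ec50 and hill must be > 0")
        elif self.kind == HH_RATE:
            if self.rate_fn not in _HH_RATE_FNS:
                raise ValueError(f"unknown rate_fn {self.rate_fn!r}")
        else:
            raise ValueError(f"unknown gate kind {self.kind!r}")
        if self.tau_act <= 0:
            raise ValueError("tau_act must be > 0")
        if self.power < 1:
            raise ValueError("power must be >= 1")


@dataclass(frozen=True)
class ChannelSpec:
    """A conductance: maximal density, reversal, and its gates.

    Gate steady states combine multiplicatively (``gating_combination ==
    'product'``).  ``mechanism`` tells the integrator how many state
    variables the channel carries: ``'kcnt1'`` channels collapse their two
    gates into a single first-order activation variable; ``'hh'`` channels
    integrate one state per gate; ``'passive'`` channels are ungated.
    """

    name: str
    gbar: float                       # S/cm^2
    erev: float                       # mV
    gates: tuple[GateSpec, ...] = ()
    gating_combination: str = "product"
    mechanism: str = "hh"

    def __post_init__(self) -> None:
        if self.gbar < 0:
            raise ValueError("gbar must be >= 0")
        if self.gating_combination != "product":
            raise ValueError("only product gating is supported")
        if self.mechanism == "kcnt1":
            kinds = sorted(g.kind for g in self.gates)
            if kinds != [SODIUM_HILL, VOLTAGE_BOLTZMANN]:
                raise ValueError(
                    "kcnt1 mechanism needs exactly one sodium-hill and one "
                    "voltage-boltzmann gate"
                )

    @property
    def sodium_gate(self) -> GateSpec:
        return next(g for g in self.gates if g.kind == SODIUM_HILL)

    @property
    def voltage_gate(self) -> GateSpec:
        return next(g for g in self.gates if g.kind == VOLTAGE_BOLTZMANN)


@dataclass(frozen=True)
class ChannelLibraryConfig:
    """Parameters shared across the standard channel set.

    ``nap_to_nat_ratio`` ties the persistent Na+ conductance to the
    transient one (default 0.001, i.e. I_NaP roughly 1% of peak transient
    current); ``nap_scale_factor`` is the experimental I_NaP manipulation
    (2.0 models the observed two-fold increase).  ``gof_ec50_levels`` are
    the sodium-gate EC50 levels used for control and the two GOF grades.
    """

    nap_to_nat_ratio: float = 0.001
    nap_scale_factor: float = 1.0
    gof_ec50_levels: tuple[float, ...] = (40.0, 35.0, 30.0)
    ek: float = -90.0                 # mV
    ena: float = 60.0                 # mV
    eleak: float = -70.0              # mV
    gnat: float = 0.05                # S/cm^2
    gkdr: float = 0.01                # S/cm^2
    gleak: float = 5e-5               # S/cm^2
    gkcnt1: float = 0.03              # S/cm^2
    vt: float = -55.0                 # mV, spike-threshold shift of rate kinetics
    kcnt1_ec50: float = 40.0          # mM
    kcnt1_hill: float = 3.5
    kcnt1_v50: float = -35.0          # mV
    kcnt1_k: float = 14.0             # mV
    kcnt1_tau: float = 30.0           # ms
    nat_h_rate_scale: float = 1.0     # optional speed-up of Na+ inactivation
    nat_m_shift: float = 6.0          # mV; right-shifts NaT activation relative
                                      # to inactivation, keeping the window
                                      # current small as for native channels

    def __post_init__(self) -> None:
        if self.nap_to_nat_ratio < 0:
            raise ValueError("nap_to_nat_ratio must be >= 0")
        levels = tuple(self.gof_ec50_levels)
        if any(b >= a for a, b in zip(levels, levels[1:])):
            raise ValueError("gof_ec50_levels must be strictly decreasing")
        for name in ("ek", "ena", "eleak"):
            if getattr(self, name) is None:
                raise ValueError(f"missing reversal potential {name}")


# ---------------------------------------------------------------------------
# gating laws


def na_gate_activation(na_conc, gate: GateSpec):
    """Hill activation of the sodium gate: x^h / (x^h + EC50^h).

    ``na_conc`` is the intracellular Na+ concentration in mM (scalar or
    array); the result is the open fraction in [0, 1].
    """
    if gate.kind != SODIUM_HILL:
        raise ValueError("gate is not a sodium-hill gate")
    x = np.asarray(na_conc, dtype=float)
    if np.any(x < 0):
        raise ValueError("na_conc must be >= 0")
    xh = x**gate.hill
    out = xh / (xh + gate.ec50**gate.hill)
    return out if out.ndim else float(out)


def voltage_gate_activation(v, gate: GateSpec):
    """Boltzmann activation of a voltage gate: 1 / (1 + exp(-(V - V50)/k))."""
    if gate.kind != VOLTAGE_BOLTZMANN:
        raise ValueError("gate is not a voltage-boltzmann gate")
    v = np.asarray(v, dtype=float)
    z = (v - gate.v50) / gate.k
    out = 1.0 / (1.0 + np.exp(-z))
    if gate.inverted:
        out = 1.0 - out
    return out if out.ndim else float(out)


def kcnt1_open_fraction(v, na_conc, channel: ChannelSpec):
    """Steady-state open probability m_inf = f_Na([Na]i) * f_V(V)."""
    return na_gate_activation(na_conc, channel.sodium_gate) * voltage_gate_activation(
        v, channel.voltage_gate
    )


def kcnt1_steady_state(v, na_conc, channel: ChannelSpec):
    """Steady-state KCNT1 current density, mA/cm^2 (outward positive).

    I = gbar * m_inf * (V - E_rev) with m_inf the product of the sodium
    (Hill) and voltage (Boltzmann) gate steady states.
    """
    if channel.mechanism != "kcnt1":
        raise ValueError("channel is not a kcnt1 mechanism")
    m = kcnt1_open_fraction(v, na_conc, channel)
    out = channel.gbar * m * (np.asarray(v, dtype=float) - channel.erev)
    return out if np.ndim(out) else float(out)


def gate_kinetics_step(m, v, na_conc, dt: float, channel: ChannelSpec):
    """Advance the KCNT1 activation variable by one time step.

    First-order relaxation dm/dt = (m_inf - m)/tau_act, integrated exactly
    over ``dt`` (exponential update), so m stays in [0, 1] for any dt.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    m = np.asarray(m, dtype=float)
    if np.any(m < 0) or np.any(m > 1):
        raise ValueError("gate state m must lie in [0, 1]")
    m_inf = kcnt1_open_fraction(v, na_conc, channel)
    tau = channel.voltage_gate.tau_act
    out = m_inf + (m - m_inf) * np.exp(-dt / tau)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# classic alpha/beta rate kinetics for the companion conductances
#
# Traub-style rate functions with a threshold-shift parameter vt; the
# persistent Na+ gate uses a Boltzmann steady state with a fixed tau.


def _vtrap(x, y):
    """x / (exp(x/y) - 1) with the removable singularity at x = 0 handled."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / y) < 1e-6
    safe = np.where(small, 1.0, x)
    out = np.where(small, y * (1.0 - x / (2.0 * y)), safe / np.expm1(safe / y))
    return out


def hh_rates(rate_fn: str, v, vt: float = -55.0):
    """(alpha, beta) in 1/ms for the named gate at membrane potential v."""
    v = np.asarray(v, dtype=float)
    u = v - vt
    if rate_fn == "nat_m":
        a = 0.32 * _vtrap(13.0 - u, 4.0)
        b = 0.28 * _vtrap(u - 40.0, 5.0)
    elif rate_fn == "nat_h":
        a = 0.128 * np.exp(-(u - 17.0) / 18.0)
        b = 4.0 / (1.0 + np.exp(-(u - 40.0) / 5.0))
    elif rate_fn == "kdr_n":
        a = 0.032 * _vtrap(15.0 - u, 5.0)
        b = 0.5 * np.exp(-(u - 10.0) / 40.0)
    elif rate_fn == "nap_m":
        # Boltzmann steady state (v50 = -52 mV, k = 5 mV re. vt = -55),
        # fixed tau of 1 ms, expressed as equivalent rates.
        minf = 1.0 / (1.0 + np.exp(-(u - 3.0) / 5.0))
        tau = np.full_like(np.asarray(u, dtype=float), 1.0)
        return minf / tau, (1.0 - minf) / tau
    else:
        raise ValueError(f"unknown rate_fn {rate_fn!r}")
    return a, b


def hh_steady_tau(gate: GateSpec, v):
    """Steady state and time constant (ms) of an hh-rate gate."""
    a, b = hh_rates(gate.rate_fn, v, vt=gate.vshift)
    tau = 1.0 / (a + b) / gate.rate_scale
    return a / (a + b), tau


# ---------------------------------------------------------------------------
# channel library


def build_channel_library(config: ChannelLibraryConfig | None = None) -> dict[str, ChannelSpec]:
    """Build the standard five-conductance set used by the neuron models.

    Returns a dict keyed by channel name: transient Na+ (m3h), persistent
    Na+ (non-inactivating, gbar tied to the transient conductance by
    ``nap_to_nat_ratio * nap_scale_factor``), delayed-rectifier K+ (n4),
    leak, and the KCNT1 K_Na conductance.
    """
    cfg = config or ChannelLibraryConfig()
    gnap = cfg.nap_to_nat_ratio * cfg.nap_scale_factor * cfg.gnat
    lib = {
        "nat": ChannelSpec(
            name="nat",
            gbar=cfg.gnat,
            erev=cfg.ena,
            gates=(
                GateSpec(kind=HH_RATE, rate_fn="nat_m", power=3,
                         vshift=cfg.vt + cfg.nat_m_shift),
                GateSpec(kind=HH_RATE, rate_fn="nat_h", power=1, vshift=cfg.vt,
                         rate_scale=cfg.nat_h_rate_scale),
            ),
        ),
        "nap": ChannelSpec(
            name="nap",
            gbar=gnap,
            erev=cfg.ena,
            gates=(GateSpec(kind=HH_RATE, rate_fn="nap_m", power=1, vshift=cfg.vt),),
        ),
        "kdr": ChannelSpec(
            name="kdr",
            gbar=cfg.gkdr,
            erev=cfg.ek,
            gates=(GateSpec(kind=HH_RATE, rate_fn="kdr_n", power=4, vshift=cfg.vt),),
        ),
        "leak": ChannelSpec(name="leak", gbar=cfg.gleak, erev=cfg.eleak, mechanism="passive"),
        "kcnt1": ChannelSpec(
            name="kcnt1",
            gbar=cfg.gkcnt1,
            erev=cfg.ek,
            mechanism="kcnt1",
            gates=(
                GateSpec(
                    kind=SODIUM_HILL,
                    ec50=cfg.kcnt1_ec50,
                    hill=cfg.kcnt1_hill,
                    tau_act=cfg.kcnt1_tau,
                ),
                GateSpec(
                    kind=VOLTAGE_BOLTZMANN,
                    v50=cfg.kcnt1_v50,
                    k=cfg.kcnt1_k,
                    tau_act=cfg.kcnt1_tau,
                ),
            ),
        ),
    }
    return lib


# ---------------------------------------------------------------------------
# serialization (lossless YAML round trip)


def _gate_to_dict(g: GateSpec) -> dict:
    d = dataclasses.asdict(g)
    return {k: v for k, v in d.items() if v is not None}


def channel_to_dict(ch: ChannelSpec) -> dict:
    return {
        "name": ch.name,
        "gbar": ch.gbar,
        "erev": ch.erev,
        "gating_combination": ch.gating_combination,
        "mechanism": ch.mechanism,
        "gates": [_gate_to_dict(g) for g in ch.gates],
    }


def channel_from_dict(d: dict) -> ChannelSpec:
    gates = tuple(GateSpec(**g) for g in d.get("gates", []))
    return ChannelSpec(
        name=d["name"],
        gbar=d["gbar"],
        erev=d["erev"],
        gates=gates,
        gating_combination=d.get("gating_combination", "product"),
        mechanism=d.get("mechanism", "hh"),
    )


def save_channel_library(lib: dict[str, ChannelSpec], path) -> None:
    doc = {name: channel_to_dict(ch) for name, ch in lib.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_channel_library(path) -> dict[str, ChannelSpec]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return {name: channel_from_dict(d) for name, d in doc.items()}


def with_ec50(channel: ChannelSpec, ec50: float) -> ChannelSpec:
    """Copy of a KCNT1 channel with the sodium-gate EC50 replaced (GOF)."""
    gates = tuple(
        replace(g, ec50=float(ec50)) if g.kind == SODIUM_HILL else g for g in channel.gates
    )
    return replace(channel, gates=gates)


def with_voltage_gate(channel: ChannelSpec, v50: float, k: float) -> ChannelSpec:
    """Copy of a KCNT1 channel with the voltage-gate (V50, k) replaced."""
    gates = tuple(
        replace(g, v50=float(v50), k=float(k)) if g.kind == VOLTAGE_BOLTZMANN else g
        for g in channel.gates
    )
    return replace(channel, gates=gates)
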