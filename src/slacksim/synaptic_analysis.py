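"""Spontaneous PSC detection, E/I ratio, and paired-recording motifs.

Event detection follows the scaled-template (Clements-Bekkers style)
approach: a kernel with 0.5-ms rise and 3-ms decay is slid along the
trace, optimally scaled at every offset, and an event is called where
the fitted amplitude exceeds three times the baseline noise SD.  The
E/I ratio is (f_E q_E) / (f_E q_E + f_I q_I) over sEPSC/sIPSC frequency
and charge.  Pair classification assigns one of four coupling motifs
(not coupled, chemical one-way, chemical two-way, electrical) from
step-evoked coupling coefficients and AP-evoked time-locked PSCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve, find_peaks
from scipy.stats import binomtest, fisher_exact

from . import ephys_features
from .trace import Trace

__all__ = [
    "EventTemplate",
    "EventSummary",
    "MotifResult",
    "PairConfig",
    "Direction",
    "PairRecording",
    "psc_kernel",
    "detect_events",
    "ei_ratio",
    "classify_pair",
    "connection_stats",
]

MOTIF_LABELS = ("not coupled", "chemical: one-way", "chemical: two-way", "electrical")


@dataclass(frozen=True)
class EventTemplate:
    """PSC template: double-exponential with 0.5-ms rise, 3-ms decay.

    ``threshold`` is the detection criterion in multiples of the baseline
    noise SD applied to the fitted event amplitude; events closer than
    ``refractory_ms`` are merged.  ``polarity`` is -1 for inward (downward)
    events, +1 for outward.
    """

    rise_ms: float = 0.5
    decay_ms: float = 3.0
    threshold: float = 3.0
    refractory_ms: float = 2.0
    polarity: int = -1
    window_factor: float = 4.0   # matching window = rise + window_factor * decay

    def __post_init__(self) -> None:
        if self.rise_ms >= self.decay_ms:
            raise ValueError("rise must be shorter than decay")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +-1")

    def kernel(self, dt_ms: float) -> np.ndarray:
        """Unit-peak difference-of-exponentials kernel."""
        return psc_kernel(self.rise_ms, self.decay_ms, dt_ms,
                          span_ms=self.rise_ms + self.window_factor * self.decay_ms)

    def charge_per_unit_amplitude_pC(self) -> float:
        """Integral of the unit-peak kernel over 10 decay constants (pA*ms -> pC)."""
        tr, td = self.rise_ms, self.decay_ms
        t_peak = np.log(td / tr) * tr * td / (td - tr)
        peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
        span = 10.0 * td
        integral = td * (1 - np.exp(-span / td)) - tr * (1 - np.exp(-span / tr))
        return integral / peak / 1000.0  # pA*ms -> pC


def psc_kernel(rise_ms: float, decay_ms: float, dt_ms: float, span_ms: float) -> np.ndarray:
    t = np.arange(0.0, span_ms, dt_ms)
    w = np.exp(-t / decay_ms) - np.exp(-t / rise_ms)
    return w / w.max()


@dataclass
class EventSummary:
    """Detected synaptic events of one polarity on one cell."""

    frequency_hz: float
    mean_charge_pC: float     # magnitude
    times_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    amplitudes_pA: np.ndarray = field(default_factory=lambda: np.empty(0))
    baseline_sd_pA: float = 0.0

    def __post_init__(self) -> None:
        if self.frequency_hz < 0 or self.mean_charge_pC < 0:
            raise ValueError("frequency and charge must be >= 0")


def _sliding_scale(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Optimal template scale s_i for y ~ s*w + c at every offset i."""
    n = w.size
    sw = w.sum()
    sww = (w**2).sum()
    ones = np.ones(n)
    swy = fftconvolve(x, w[::-1], mode="valid")
    sy = fftconvolve(x, ones, mode="valid")
    denom = n * sww - sw**2
    return (n * swy - sw * sy) / denom


def detect_events(trace: Trace, template: EventTemplate = EventTemplate()) -> EventSummary:
    """Template-matched event detection on a continuous current trace.

    The detection statistic is the optimally scaled template amplitude;
    the threshold is ``template.threshold`` times the baseline SD, with
    the baseline SD re-estimated after excluding detected events (two
    passes).  Event charge is the fitted amplitude times the analytic
    kernel integral.  Deterministic: identical traces give identical
    event lists.
    """
    w = template.kernel(trace.dt_ms)
    if trace.n < w.size:
        raise ValueError("trace shorter than the detection template")
    x = trace.data * template.polarity
    s = _sliding_scale(x, w)

    sd = _robust_sd(x)
    min_dist = max(1, int(round(template.refractory_ms / trace.dt_ms)))
    for _ in range(2):
        peaks, _props = find_peaks(s, height=template.threshold * sd, distance=min_dist)
        mask = np.ones(x.size, dtype=bool)
        for p in peaks:
            mask[p: p + w.size] = False
        if mask.sum() > 100:
            sd = _robust_sd(x[mask])
    peaks, _props = find_peaks(s, height=template.threshold * sd, distance=min_dist)

    amps = s[peaks]
    times = peaks * trace.dt_ms
    dur_s = trace.duration_ms / 1000.0
    q_unit = template.charge_per_unit_amplitude_pC()
    mean_q = float(np.mean(np.abs(amps)) * q_unit) if amps.size else 0.0
    return EventSummary(
        frequency_hz=len(peaks) / dur_s,
        mean_charge_pC=mean_q,
        times_ms=times,
        amplitudes_pA=amps * template.polarity,
        baseline_sd_pA=float(sd),
    )


def _robust_sd(x: np.ndarray) -> float:
    med = np.median(x)
    return float(1.4826 * np.median(np.abs(x - med))) or float(np.std(x)) or 1e-12


def ei_ratio(epsc: EventSummary, ipsc: EventSummary) -> float:
    """(f_E q_E) / (f_E q_E + f_I q_I); NaN when both products are zero."""
    e = epsc.frequency_hz * epsc.mean_charge_pC
    i = ipsc.frequency_hz * ipsc.mean_charge_pC
    if e + i == 0:
        return float("nan")
    return e / (e + i)


# ---------------------------------------------------------------------------
# paired recordings


@dataclass(frozen=True)
class PairConfig:
    """Motif-classification thresholds (conservative conventions).

    Electrical coupling: steady-state coupling coefficient >= 0.005 in
    either direction on a hyperpolarizing step.  Chemical coupling per
    direction: a time-locked PSC (latency <= 4 ms) follows >= 50% of
    presynaptic APs, with no step-evoked deflection.
    """

    cc_threshold: float = 0.005
    latency_ms: float = 4.0
    reliability: float = 0.5
    template: EventTemplate = field(default_factory=EventTemplate)


@dataclass
class Direction:
    """Everything recorded for one direction of a pair (pre -> post)."""

    step_pre: Trace       # mV, presynaptic voltage during current step
    step_post: Trace      # mV, postsynaptic voltage during the same step
    ap_pre: Trace         # mV, presynaptic AP train
    ap_post_i: Trace      # pA, postsynaptic current during the AP train
    ap_post_v: Trace | None = None  # mV, optional (spikelet evidence)


@dataclass
class PairRecording:
    a_to_b: Direction | None = None
    b_to_a: Direction | None = None


@dataclass
class MotifResult:
    label: str
    coupling_coefficients: dict = field(default_factory=dict)
    chemical: dict = field(default_factory=dict)
    spikelet_evidence: dict = field(default_factory=dict)
    partial: bool = False

    def __post_init__(self) -> None:
        if self.label not in MOTIF_LABELS:
            raise ValueError(f"label must be one of {MOTIF_LABELS}")


def _steady_deflection(trace: Trace, window_ms: float = 100.0) -> float:
    onset = trace.meta["onset_ms"]
    dur = trace.meta["duration_ms"]
    base = np.mean(trace.slice_ms(max(0.0, onset - 50.0), onset))
    steady = np.mean(trace.slice_ms(onset + dur - window_ms, onset + dur))
    return float(steady - base)


def coupling_coefficient(direction: Direction) -> float:
    """Steady-state dV_post / dV_pre on the current step."""
    dv_pre = _steady_deflection(direction.step_pre)
    dv_post = _steady_deflection(direction.step_post)
    if dv_pre == 0.0:
        return 0.0
    return dv_post / dv_pre


def _chemical_evidence(direction: Direction, config: PairConfig) -> tuple[bool, float]:
    """(is chemical, AP-follow reliability) for one direction."""
    aps = ephys_features.detect_aps(direction.ap_pre)
    if not aps:
        return False, 0.0
    events = detect_events(direction.ap_post_i, config.template)
    if events.times_ms.size == 0:
        return False, 0.0
    followed = 0
    for ap in aps:
        dt_to_events = events.times_ms - ap.t_peak
        if np.any((dt_to_events >= 0) & (dt_to_events <= config.latency_ms)):
            followed += 1
    reliability = followed / len(aps)
    return reliability >= config.reliability, reliability


def _spikelet_evidence(direction: Direction) -> bool:
    """Attenuated, low-pass-filtered spikes in the postsynaptic voltage."""
    if direction.ap_post_v is None:
        return False
    aps = ephys_features.detect_aps(direction.ap_pre)
    if not aps:
        return False
    post = direction.ap_post_v.data
    base = np.median(post)
    sd = _robust_sd(post - base)
    dt = direction.ap_post_v.dt_ms
    hits = 0
    for ap in aps:
        i0 = int(ap.t_peak / dt)
        i1 = min(post.size, i0 + int(5.0 / dt))
        if i1 > i0 and np.max(post[i0:i1] - base) > 3.0 * sd:
            hits += 1
    return hits >= max(1, len(aps) // 2)


def classify_pair(pair: PairRecording, config: PairConfig = PairConfig()) -> MotifResult:
    """Assign one of the four coupling motifs to a recorded pair.

    Electrical coupling (either direction) takes precedence; otherwise
    the pair is chemical one-way / two-way according to the per-direction
    AP-evoked evidence; otherwise not coupled.  A missing direction
    yields a partial result flagged as such.
    """
    ccs: dict[str, float] = {}
    chem: dict[str, bool] = {}
    spikelets: dict[str, bool] = {}
    partial = False
    for name in ("a_to_b", "b_to_a"):
        direction = getattr(pair, name)
        if direction is None:
            partial = True
            continue
        ccs[name] = coupling_coefficient(direction)
        is_chem, rel = _chemical_evidence(direction, config)
        # a step-evoked deflection rules out a purely chemical explanation
        chem[name] = is_chem and abs(ccs[name]) < config.cc_threshold
        spikelets[name] = _spikelet_evidence(direction)

    electrical = any(cc >= config.cc_threshold for cc in ccs.values())
    n_chem = sum(chem.values())
    if electrical:
        label = "electrical"
    elif n_chem == 2:
        label = "chemical: two-way"
    elif n_chem == 1:
        label = "chemical: one-way"
    else:
        label = "not coupled"
    return MotifResult(
        label=label,
        coupling_coefficients=ccs,
        chemical=chem,
        spikelet_evidence=spikelets,
        partial=partial,
    )


# ---------------------------------------------------------------------------
# connection-probability statistics


def connection_stats(
    connected_a: int,
    tested_a: int,
    connected_b: int | None = None,
    tested_b: int | None = None,
    ci_level: float = 0.95,
) -> dict:
    """Connection-probability estimate(s) with exact CI and Fisher test.

    With one group: point estimate k/n and an exact (Clopper-Pearson)
    binomial CI.  With two groups: both estimates plus the two-sided
    Fisher exact p for the 2x2 table.
    """
    if connected_a > tested_a or (connected_b or 0) > (tested_b or np.inf):
        raise ValueError("connected count exceeds tested count")
    out: dict = {}
    if tested_a == 0:
        out["p_a"] = None
    else:
        bt = binomtest(connected_a, tested_a)
        ci = bt.proportion_ci(confidence_level=ci_level, method="exact")
        out["p_a"] = connected_a / tested_a
        out["ci_a"] = (ci.low, ci.high)
    if connected_b is not None and tested_b is not None:
        if tested_b == 0:
            out["p_b"] = None
        else:
            bt = binomtest(connected_b, tested_b)
            ci = bt.proportion_ci(confidence_level=ci_level, method="exact")
            out["p_b"] = connected_b / tested_b
            out["ci_b"] = (ci.low, ci.high)
        table = [
            [connected_a, tested_a - connected_a],
            [connected_b, tested_b - connected_b],
        ]
        _, p = fisher_exact(table, alternative="two-sided")
        out["fisher_p"] = float(p)
    return out
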