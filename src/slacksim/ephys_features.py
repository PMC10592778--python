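"""Intrinsic-membrane and action-potential feature extraction.

Implements the standard whole-cell current-clamp analysis: resting
potential from a 50-ms pre-stimulus average; input resistance from the
steady-state voltage response to hyperpolarizing steps; membrane time
constant from a single-exponential fit at stimulus offset; capacitance
as tau/R; rheobase as the smallest step evoking an AP; per-AP threshold
(dV/dt criterion), amplitude, half-width and AHP; the F-I curve; and the
fast-spiking (FS) vs non-fast-spiking (NFS) classification rule: FS iff
the maximum mean firing rate exceeds 60 Hz and AP half-width broadens by
less than 25% during 1 s of sustained firing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .io import SweepBundle
from .trace import Trace

__all__ = [
    "APMetrics",
    "FeatureSet",
    "ClassifierConfig",
    "resting_potential",
    "passive_properties",
    "detect_aps",
    "rheobase",
    "fi_and_classify",
    "extract_features",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """FS/NFS rule parameters: rate threshold (Hz), allowed half-width
    broadening (fraction), and the sustained-firing window (ms)."""

    fs_rate_threshold: float = 60.0
    broadening_threshold: float = 0.25
    sustained_window_ms: float = 1000.0

    def __post_init__(self) -> None:
        if self.fs_rate_threshold <= 0 or self.broadening_threshold <= 0:
            raise ValueError("classifier thresholds must be > 0")


@dataclass
class APMetrics:
    """Per-AP measurements (times in ms from sweep start)."""

    t_peak: float
    threshold: float      # mV
    peak: float           # mV
    amplitude: float      # mV (peak - threshold)
    halfwidth: float      # ms at half-maximal amplitude
    ahp: float            # mV below threshold within 50 ms, floored at 0


@dataclass
class FeatureSet:
    """The intrinsic/AP feature summary of one cell or model instance."""

    v_rest: float | None = None       # mV
    rin: float | None = None          # MOhm
    tau_m: float | None = None        # ms
    cm: float | None = None           # pF
    rheobase: float | None = None     # pA
    ap_threshold: float | None = None # mV
    ap_amplitude: float | None = None # mV
    ap_halfwidth: float | None = None # ms
    ahp: float | None = None          # mV
    max_rate: float | None = None     # Hz
    fi_curve: list = field(default_factory=list)  # [(step_pA, count), ...]
    firing_class: str = "n/a"         # FS | NFS | n/a


# ---------------------------------------------------------------------------


def resting_potential(sweep: Trace) -> float:
    """Mean of the 50 ms immediately preceding stimulus onset (mV)."""
    onset = sweep.meta.get("onset_ms")
    if onset is None or onset < 50.0:
        raise ValueError("sweep needs >= 50 ms of pre-stimulus baseline")
    return float(np.mean(sweep.slice_ms(onset - 50.0, onset)))


def _exp_offset(t, v_inf, a, tau):
    return v_inf + a * np.exp(-t / tau)


def passive_properties(
    sweeps: list[Trace],
    steady_window_ms: float = 100.0,
    tau_fit_window_ms: tuple[float, float] = (1.0, 200.0),
) -> tuple[float | None, float | None, float | None]:
    """(Rin MOhm, tau_m ms, Cm pF) from hyperpolarizing step sweeps.

    Rin is the through-origin regression slope of steady-state deflection
    against injected current across all hyperpolarizing steps; tau_m is a
    single-exponential fit of the relaxation after stimulus offset on the
    most hyperpolarized sweep; Cm = tau_m / Rin.
    """
    hyper = [s for s in sweeps if s.meta.get("step_pA", 0.0) < 0.0]
    if not hyper:
        return None, None, None
    dv = []
    di = []
    for s in hyper:
        onset = s.meta["onset_ms"]
        dur = s.meta["duration_ms"]
        base = np.mean(s.slice_ms(max(0.0, onset - 50.0), onset))
        steady = np.mean(s.slice_ms(onset + dur - steady_window_ms, onset + dur))
        dv.append(steady - base)
        di.append(s.meta["step_pA"])
    dv = np.asarray(dv)
    di = np.asarray(di)
    rin = float(np.dot(dv, di) / np.dot(di, di)) * 1e3  # mV/pA -> MOhm

    s = min(hyper, key=lambda x: x.meta["step_pA"])
    onset, dur = s.meta["onset_ms"], s.meta["duration_ms"]
    off = onset + dur
    t0, t1 = tau_fit_window_ms
    seg = s.slice_ms(off + t0, min(off + t1, s.duration_ms))
    if seg.size < 10:
        return rin, None, None
    t = np.arange(seg.size) * s.dt_ms
    v_inf0 = seg[-1]
    a0 = seg[0] - v_inf0
    try:
        popt, _ = curve_fit(
            _exp_offset, t, seg, p0=(v_inf0, a0, 20.0),
            bounds=([-150.0, -150.0, 0.1], [50.0, 150.0, 500.0]), maxfev=5000,
        )
        tau = float(popt[2])
    except RuntimeError:
        return rin, None, None
    cm = tau / rin * 1e3  # ms/MOhm -> nF -> pF
    return rin, tau, cm


def detect_aps(
    sweep: Trace,
    dvdt_threshold: float = 20.0,   # V/s == mV/ms
    peak_min: float = -10.0,        # mV; excludes spikelets
    ahp_window_ms: float = 50.0,
) -> list[APMetrics]:
    """Detect APs and measure threshold, amplitude, half-width, AHP.

    Threshold is the voltage at the first sample of the contiguous run of
    dV/dt >= ``dvdt_threshold`` preceding each peak (a robust surrogate
    for the inflection point of the rising phase).  Half-width is
    measured at half-maximal amplitude with linear interpolation of the
    level crossings.  AHP is threshold minus the voltage minimum within
    ``ahp_window_ms`` after the peak, floored at zero.
    """
    v = sweep.data
    dt = sweep.dt_ms
    dvdt = np.gradient(v, dt)
    fast = dvdt >= dvdt_threshold

    from scipy.signal import find_peaks

    min_dist = max(1, int(round(1.0 / dt)))
    peaks, _ = find_peaks(v, height=peak_min, distance=min_dist, prominence=10.0)
    out: list[APMetrics] = []
    for p in peaks:
        # walk back from the peak to the start of the fast-depolarizing run
        i = p
        while i > 0 and not fast[i]:
            i -= 1
        if not fast[i]:
            continue  # no fast upstroke: not a regenerative spike
        while i > 0 and fast[i - 1]:
            i -= 1
        thr_idx = i
        threshold = float(v[thr_idx])
        peak = float(v[p])
        amplitude = peak - threshold
        if amplitude <= 0:
            continue
        half = threshold + amplitude / 2.0
        hw = _halfwidth(v, dt, thr_idx, p, half)
        j1 = min(v.size, p + int(round(ahp_window_ms / dt)))
        vmin = float(np.min(v[p:j1])) if j1 > p else peak
        ahp = max(0.0, threshold - vmin)
        out.append(
            APMetrics(
                t_peak=p * dt,
                threshold=threshold,
                peak=peak,
                amplitude=amplitude,
                halfwidth=hw,
                ahp=ahp,
            )
        )
    return out


def _halfwidth(v, dt, thr_idx, p, level) -> float:
    """Width at ``level`` around peak index p, with linear interpolation."""
    i = p
    while i > thr_idx and v[i - 1] > level:
        i -= 1
    if i == 0:
        t_rise = i * dt
    else:
        frac = (level - v[i - 1]) / (v[i] - v[i - 1]) if v[i] != v[i - 1] else 0.0
        t_rise = (i - 1 + frac) * dt
    j = p
    while j < v.size - 1 and v[j + 1] > level:
        j += 1
    if j >= v.size - 1:
        t_fall = j * dt
    else:
        frac = (v[j] - level) / (v[j] - v[j + 1]) if v[j] != v[j + 1] else 0.0
        t_fall = (j + frac) * dt
    return float(t_fall - t_rise)


def rheobase(sweeps: list[Trace], **detect_kwargs) -> float | None:
    """Smallest step amplitude whose sweep contains >= 1 AP (pA); None if none."""
    best = None
    for s in sorted(sweeps, key=lambda x: x.meta.get("step_pA", 0.0)):
        if detect_aps(s, **detect_kwargs):
            best = float(s.meta["step_pA"])
            break
    return best


def fi_and_classify(
    sweeps: list[Trace],
    sustained_sweep: Trace | None = None,
    config: ClassifierConfig = ClassifierConfig(),
    **detect_kwargs,
) -> tuple[list[tuple[float, int]], float | None, str]:
    """(F-I curve, maximum mean rate Hz, FS/NFS class).

    The F-I curve counts APs per step; the maximum mean rate is the
    largest count divided by the step duration.  Classification follows
    the sustained sweep (>= 1 s of suprathreshold firing): FS iff
    max rate > threshold AND the half-width broadening from the first AP
    to the mean of the last three APs stays below the broadening
    threshold; NFS otherwise; n/a if no APs anywhere.
    """
    fi = []
    max_rate = None
    for s in sorted(sweeps, key=lambda x: x.meta.get("step_pA", 0.0)):
        step = float(s.meta["step_pA"])
        dur_s = s.meta["duration_ms"] / 1000.0
        count = len(detect_aps(s, **detect_kwargs))
        fi.append((step, count))
        rate = count / dur_s
        if max_rate is None or rate > max_rate:
            max_rate = rate
    if all(c == 0 for _, c in fi) and (
        sustained_sweep is None or not detect_aps(sustained_sweep, **detect_kwargs)
    ):
        return fi, max_rate, "n/a"
    if max_rate is None or max_rate <= config.fs_rate_threshold:
        return fi, max_rate, "NFS"
    if sustained_sweep is None:
        return fi, max_rate, "NFS"
    aps = [
        a
        for a in detect_aps(sustained_sweep, **detect_kwargs)
        if a.t_peak >= sustained_sweep.meta.get("onset_ms", 0.0)
        and a.t_peak
        <= sustained_sweep.meta.get("onset_ms", 0.0) + config.sustained_window_ms
    ]
    if len(aps) < 4:
        return fi, max_rate, "NFS"
    first_hw = aps[0].halfwidth
    last_hw = float(np.mean([a.halfwidth for a in aps[-3:]]))
    broadening = (last_hw - first_hw) / first_hw
    label = "FS" if broadening < config.broadening_threshold else "NFS"
    return fi, max_rate, label


def extract_features(
    bundle: SweepBundle,
    sustained_sweep: Trace | None = None,
    config: ClassifierConfig = ClassifierConfig(),
    **detect_kwargs,
) -> FeatureSet:
    """Full FeatureSet from a current-step sweep bundle."""
    sweeps = sorted(bundle, key=lambda s: s.meta.get("step_pA", 0.0))
    fs = FeatureSet()
    if sweeps:
        fs.v_rest = resting_potential(sweeps[0])
    fs.rin, fs.tau_m, fs.cm = passive_properties(sweeps)

    aps_per_sweep = [detect_aps(s, **detect_kwargs) for s in sweeps]
    for s, aps in zip(sweeps, aps_per_sweep):
        if aps:
            fs.rheobase = float(s.meta["step_pA"])
            fs.ap_threshold = aps[0].threshold
            fs.ap_amplitude = aps[0].amplitude
            fs.ap_halfwidth = aps[0].halfwidth
            fs.ahp = aps[0].ahp
            break

    fs.fi_curve = [
        (float(s.meta["step_pA"]), len(aps)) for s, aps in zip(sweeps, aps_per_sweep)
    ]
    rates = [n / (s.meta["duration_ms"] / 1000.0) for s, n in
             [(s, len(a)) for s, a in zip(sweeps, aps_per_sweep)]]
    fs.max_rate = max(rates) if rates else None
    if all(n == 0 for _, n in fs.fi_curve):
        fs.firing_class = "n/a"
    elif fs.max_rate <= config.fs_rate_threshold or sustained_sweep is None:
        fs.firing_class = "NFS"
    else:
        _, _, fs.firing_class = fi_and_classify(
            sweeps, sustained_sweep, config, **detect_kwargs
        )
    return fs
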