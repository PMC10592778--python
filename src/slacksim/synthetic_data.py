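"""Seeded generators of synthetic patch-clamp-style traces with ground truth.

Every analysis stage in the package has a matching generator here that
produces its input with known generating parameters, so parameter
recovery and classification can be tested round-trip without any
recorded data.  Defaults mirror the acquisition conditions the analyses
assume: 20 kHz sampling, Gaussian noise, PSC kernel with 0.5-ms rise and
3-ms decay, 500-ms/20-pA current-step families.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .io import SweepBundle
from .synaptic_analysis import Direction, EventTemplate, PairRecording, psc_kernel
from .trace import Trace

__all__ = [
    "GroundTruth",
    "SpikeShape",
    "synth_passive_sweeps",
    "synth_spiking_sweeps",
    "synth_psc_trace",
    "synth_pair",
]

DEFAULT_DT_MS = 0.05  # 20 kHz


@dataclass
class GroundTruth:
    """Generator name, all generating parameters, and the seed."""

    generator: str
    params: dict
    seed: int

    def to_dict(self) -> dict:
        return {"generator": self.generator, "params": self.params, "seed": self.seed}


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# passive RC sweeps


def synth_passive_sweeps(
    r_MOhm: float = 200.0,
    tau_ms: float = 20.0,
    v_rest: float = -65.0,
    steps_pA=(-100.0, -80.0, -60.0, -40.0, -20.0),
    onset_ms: float = 100.0,
    duration_ms: float = 500.0,
    post_ms: float = 300.0,
    noise_sd_mV: float = 0.0,
    dt_ms: float = DEFAULT_DT_MS,
    seed: int = 0,
) -> tuple[SweepBundle, GroundTruth]:
    """RC step responses: V = V_rest + R*I*(1 - exp(-t/tau)) plus noise."""
    if r_MOhm <= 0 or tau_ms <= 0:
        raise ValueError("R and tau must be positive")
    rng = _rng(seed)
    nt = int(round((onset_ms + duration_ms + post_ms) / dt_ms))
    t = np.arange(nt) * dt_ms
    i0, i1 = int(round(onset_ms / dt_ms)), int(round((onset_ms + duration_ms) / dt_ms))
    sweeps = []
    for amp in steps_pA:
        v = np.full(nt, v_rest)
        dv = r_MOhm * amp / 1000.0  # MOhm * pA -> mV
        v[i0:i1] += dv * (1.0 - np.exp(-(t[i0:i1] - t[i0]) / tau_ms))
        v_off = v[i1 - 1] - v_rest
        v[i1:] += v_off * np.exp(-(t[i1:] - t[i1]) / tau_ms)
        if noise_sd_mV > 0:
            v = v + rng.normal(0.0, noise_sd_mV, nt)
        sweeps.append(
            Trace(v, dt_ms=dt_ms, units="mV",
                  meta={"step_pA": float(amp), "onset_ms": onset_ms,
                        "duration_ms": duration_ms})
        )
    gt = GroundTruth(
        "synth_passive_sweeps",
        dict(r_MOhm=r_MOhm, tau_ms=tau_ms, v_rest=v_rest, steps_pA=list(steps_pA),
             noise_sd_mV=noise_sd_mV, dt_ms=dt_ms),
        seed,
    )
    bundle = SweepBundle(
        meta={"id": f"synth-passive-{seed}", "units": "mV",
              "sampling_rate_hz": 1000.0 / dt_ms,
              "protocol": {"type": "StepProtocol", "mode": "iclamp"},
              "condition": "synthetic", "ground_truth": gt.to_dict()},
        sweeps=sweeps,
    )
    return bundle, gt


# ---------------------------------------------------------------------------
# spiking sweeps with a stereotyped, fully specified AP waveform


@dataclass(frozen=True)
class SpikeShape:
    """Piecewise-linear AP waveform with exactly known metrics.

    A slow pre-depolarization (below the 20 V/s detection criterion)
    climbs from the local baseline to ``threshold``; a steep linear rise
    reaches ``peak``; a linear fall descends to threshold - ``ahp``; an
    exponential recovery returns to baseline.  The fall time is chosen so
    the width at half-maximal amplitude equals ``halfwidth_ms`` exactly.
    """

    threshold: float = -45.0      # mV
    peak: float = 30.0            # mV
    halfwidth_ms: float = 1.0
    ahp: float = 25.0             # mV below threshold (dips below a -65 baseline)
    rise_rate: float = 300.0      # V/s
    foot_ms: float = 2.0          # slow approach duration
    recovery_tau_ms: float = 8.0

    def render(self, baseline: float, dt_ms: float) -> np.ndarray:
        amp = self.peak - self.threshold
        if amp <= 0:
            raise ValueError("peak must exceed threshold")
        t_rise = amp / self.rise_rate          # ms
        half = self.threshold + amp / 2.0
        v_end = self.threshold - self.ahp
        frac_fall = (self.peak - half) / (self.peak - v_end)
        t_fall = (self.halfwidth_ms - t_rise / 2.0) / frac_fall
        if t_fall <= 0:
            raise ValueError("halfwidth too small for the requested rise rate")
        t_rec = 6.0 * self.recovery_tau_ms
        n_foot = max(2, int(round(self.foot_ms / dt_ms)))
        n_rise = max(2, int(round(t_rise / dt_ms)))
        n_fall = max(2, int(round(t_fall / dt_ms)))
        n_rec = int(round(t_rec / dt_ms))
        foot = np.linspace(baseline, self.threshold, n_foot, endpoint=False)
        rise = np.linspace(self.threshold, self.peak, n_rise, endpoint=False)
        fall = np.linspace(self.peak, v_end, n_fall, endpoint=False)
        rec = baseline + (v_end - baseline) * np.exp(
            -np.arange(n_rec) * dt_ms / self.recovery_tau_ms
        )
        return np.concatenate([foot, rise, fall, rec])

    @property
    def peak_offset_ms(self) -> float:
        return self.foot_ms + (self.peak - self.threshold) / self.rise_rate


def _place_spikes(
    v: np.ndarray,
    dt_ms: float,
    spike_times_ms: np.ndarray,
    shape: SpikeShape,
    halfwidth_scale: np.ndarray | None = None,
) -> None:
    from dataclasses import replace as _replace

    for idx, t0 in enumerate(spike_times_ms):
        sh = shape
        if halfwidth_scale is not None:
            sh = _replace(shape, halfwidth_ms=shape.halfwidth_ms * halfwidth_scale[idx])
        i0 = int(round(t0 / dt_ms))
        base = v[i0] if i0 < v.size else shape.threshold
        wav = sh.render(base, dt_ms)
        i1 = min(v.size, i0 + wav.size)
        v[i0:i1] = wav[: i1 - i0]


def synth_spiking_sweeps(
    rheobase_pA: float = 120.0,
    rate_slope_hz_per_pA: float = 0.5,
    rate_at_rheobase_hz: float = 4.0,
    shape: SpikeShape = SpikeShape(),
    broadening_frac: float = 0.0,
    sustained_rate_hz: float | None = None,
    r_MOhm: float = 150.0,
    tau_ms: float = 15.0,
    v_rest: float = -65.0,
    steps_pA=None,
    onset_ms: float = 100.0,
    duration_ms: float = 500.0,
    noise_sd_mV: float = 0.0,
    dt_ms: float = DEFAULT_DT_MS,
    seed: int = 0,
) -> tuple[SweepBundle, Trace, GroundTruth]:
    """Current-step family plus a 1-s sustained sweep of stereotyped spikes.

    Suprathreshold steps carry evenly spaced spikes at
    rate = rate_at_rheobase + slope * (I - rheobase); the sustained sweep
    fires at ``sustained_rate_hz`` (default: the top-step rate) with AP
    half-width growing linearly by ``broadening_frac`` across the window.
    Returns (step bundle, sustained sweep, ground truth).
    """
    rng = _rng(seed)
    if steps_pA is None:
        steps_pA = np.arange(-100.0, 301.0, 20.0)
    nt = int(round((onset_ms + duration_ms + 200.0) / dt_ms))
    t = np.arange(nt) * dt_ms
    i0, i1 = int(round(onset_ms / dt_ms)), int(round((onset_ms + duration_ms) / dt_ms))
    sweeps = []
    for amp in steps_pA:
        v = np.full(nt, v_rest)
        dv = r_MOhm * min(amp, 0.0) / 1000.0  # passive response only below threshold
        sub_amp = amp if amp < rheobase_pA else 0.3 * amp
        dv = r_MOhm * sub_amp / 1000.0
        v[i0:i1] += dv * (1.0 - np.exp(-(t[i0:i1] - t[i0]) / tau_ms))
        v[i1:] += (v[i1 - 1] - v_rest) * np.exp(-(t[i1:] - t[i1]) / tau_ms)
        if amp >= rheobase_pA:
            rate = rate_at_rheobase_hz + rate_slope_hz_per_pA * (amp - rheobase_pA)
            n_spikes = max(1, int(np.floor(rate * duration_ms / 1000.0)))
            times = onset_ms + 5.0 + np.arange(n_spikes) * (1000.0 / rate)
            times = times[times < onset_ms + duration_ms - 20.0]
            if times.size == 0:
                times = np.array([onset_ms + 5.0])
            _place_spikes(v, dt_ms, times, shape)
        if noise_sd_mV > 0:
            v = v + rng.normal(0.0, noise_sd_mV, nt)
        sweeps.append(
            Trace(v, dt_ms=dt_ms, units="mV",
                  meta={"step_pA": float(amp), "onset_ms": onset_ms,
                        "duration_ms": duration_ms})
        )

    # sustained 1-s sweep
    top_rate = rate_at_rheobase_hz + rate_slope_hz_per_pA * (steps_pA[-1] - rheobase_pA)
    sus_rate = sustained_rate_hz if sustained_rate_hz is not None else top_rate
    sus_dur = 1000.0
    nts = int(round((onset_ms + sus_dur + 200.0) / dt_ms))
    vs = np.full(nts, v_rest)
    n_spk = max(1, int(np.floor(sus_rate * sus_dur / 1000.0)))
    times = onset_ms + 5.0 + np.arange(n_spk) * (1000.0 / sus_rate)
    times = times[times < onset_ms + sus_dur - 20.0]
    scale = 1.0 + broadening_frac * np.linspace(0.0, 1.0, times.size)
    _place_spikes(vs, dt_ms, times, shape, halfwidth_scale=scale)
    if noise_sd_mV > 0:
        vs = vs + rng.normal(0.0, noise_sd_mV, nts)
    sustained = Trace(
        vs, dt_ms=dt_ms, units="mV",
        meta={"step_pA": float(steps_pA[-1]), "onset_ms": onset_ms,
              "duration_ms": sus_dur},
    )
    gt = GroundTruth(
        "synth_spiking_sweeps",
        dict(rheobase_pA=rheobase_pA, rate_slope_hz_per_pA=rate_slope_hz_per_pA,
             rate_at_rheobase_hz=rate_at_rheobase_hz, shape=asdict(shape),
             broadening_frac=broadening_frac, sustained_rate_hz=sus_rate,
             noise_sd_mV=noise_sd_mV, dt_ms=dt_ms),
        seed,
    )
    bundle = SweepBundle(
        meta={"id": f"synth-spiking-{seed}", "units": "mV",
              "sampling_rate_hz": 1000.0 / dt_ms,
              "protocol": {"type": "StepProtocol", "mode": "iclamp"},
              "condition": "synthetic", "ground_truth": gt.to_dict()},
        sweeps=sweeps,
    )
    return bundle, sustained, gt


# ---------------------------------------------------------------------------
# spontaneous PSC traces


def synth_psc_trace(
    rate_hz: float = 5.0,
    amplitude_pA: float = 20.0,
    template: EventTemplate = EventTemplate(),
    duration_s: float = 30.0,
    noise_sd_pA: float = 2.0,
    dt_ms: float = DEFAULT_DT_MS,
    seed: int = 0,
) -> tuple[Trace, GroundTruth]:
    """Homogeneous-Poisson PSC train convolved with the template kernel.

    Events are placed with exponential inter-event intervals at
    ``rate_hz``, each a unit-peak kernel scaled to ``amplitude_pA`` with
    the template's polarity, on Gaussian noise of ``noise_sd_pA``.
    """
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    rng = _rng(seed)
    nt = int(round(duration_s * 1000.0 / dt_ms))
    impulses = np.zeros(nt)
    times = []
    if rate_hz > 0:
        t = rng.exponential(1000.0 / rate_hz)
        while t < duration_s * 1000.0 - 50.0:
            idx = int(round(t / dt_ms))
            impulses[idx] += 1.0
            times.append(idx * dt_ms)
            t += rng.exponential(1000.0 / rate_hz)
    kernel = psc_kernel(template.rise_ms, template.decay_ms, dt_ms,
                        span_ms=template.rise_ms + 10.0 * template.decay_ms)
    from scipy.signal import fftconvolve

    signal = fftconvolve(impulses, kernel, mode="full")[:nt]
    signal *= amplitude_pA * template.polarity
    data = signal + rng.normal(0.0, noise_sd_pA, nt)
    gt = GroundTruth(
        "synth_psc_trace",
        dict(rate_hz=rate_hz, amplitude_pA=amplitude_pA, duration_s=duration_s,
             noise_sd_pA=noise_sd_pA, dt_ms=dt_ms, event_times_ms=times,
             rise_ms=template.rise_ms, decay_ms=template.decay_ms),
        seed,
    )
    trace = Trace(data, dt_ms=dt_ms, units="pA",
                  meta={"condition": "synthetic", "ground_truth_n_events": len(times)})
    return trace, gt


# ---------------------------------------------------------------------------
# paired recordings


def _passive_step_trace(v_rest, r_MOhm, tau_ms, step_pA, onset_ms, duration_ms,
                        total_ms, dt_ms, noise, rng) -> np.ndarray:
    nt = int(round(total_ms / dt_ms))
    t = np.arange(nt) * dt_ms
    i0, i1 = int(round(onset_ms / dt_ms)), int(round((onset_ms + duration_ms) / dt_ms))
    v = np.full(nt, float(v_rest))
    dv = r_MOhm * step_pA / 1000.0
    v[i0:i1] += dv * (1.0 - np.exp(-(t[i0:i1] - t[i0]) / tau_ms))
    v[i1:] += (v[i1 - 1] - v_rest) * np.exp(-(t[i1:] - t[i1]) / tau_ms)
    if noise > 0:
        v = v + rng.normal(0.0, noise, nt)
    return v


def _lowpass(x: np.ndarray, dt_ms: float, tau_ms: float) -> np.ndarray:
    """First-order low-pass (the electrical-synapse filtering)."""
    alpha = dt_ms / (tau_ms + dt_ms)
    out = np.empty_like(x)
    acc = x[0]
    b = 1.0 - alpha
    # IIR y[i] = (1-a) y[i-1] + a x[i], vectorized via lfilter
    from scipy.signal import lfilter

    out = lfilter([alpha], [1.0, -b], x, zi=[b * x[0]])[0]
    return out


def synth_pair(
    motif: str,
    coupling_coefficient: float = 0.05,
    ipsc_amplitude_pA: float = 30.0,
    noise_frac: float = 0.0,
    directions: tuple[bool, bool] = (True, True),
    v_rest: float = -65.0,
    r_MOhm: float = 200.0,
    tau_ms: float = 20.0,
    step_pA: float = -100.0,
    n_aps: int = 5,
    ap_rate_hz: float = 20.0,
    dt_ms: float = DEFAULT_DT_MS,
    seed: int = 0,
) -> tuple[PairRecording, GroundTruth]:
    """Generate both directions of a pair consistent with a labelled motif.

    ``motif`` is one of "not coupled", "chemical: one-way",
    "chemical: two-way", "electrical".  ``noise_frac`` scales additive
    Gaussian noise relative to the signal size (postsynaptic deflection
    or IPSC amplitude).  Electrical pairs transmit the step deflection
    with the given coupling coefficient and AP-evoked spikelets shaped by
    first-order low-pass filtering.
    """
    from .synaptic_analysis import MOTIF_LABELS

    if motif not in MOTIF_LABELS:
        raise ValueError(f"unknown motif {motif!r}")
    rng = _rng(seed)
    onset, dur, total = 100.0, 500.0, 800.0
    shape = SpikeShape()
    chem_dirs = {
        "not coupled": (False, False),
        "chemical: one-way": (True, False),
        "chemical: two-way": (True, True),
        "electrical": (False, False),
    }[motif]
    electrical = motif == "electrical"

    def make_direction(is_chem: bool) -> Direction:
        v_noise = noise_frac * abs(r_MOhm * step_pA / 1000.0) * abs(
            coupling_coefficient if electrical else 0.02
        )
        i_noise = noise_frac * ipsc_amplitude_pA
        pre_step = _passive_step_trace(v_rest, r_MOhm, tau_ms, step_pA, onset, dur,
                                       total, dt_ms, 0.0, rng)
        if electrical:
            post_step = v_rest + coupling_coefficient * _lowpass(
                pre_step - v_rest, dt_ms, 2.0
            )
        else:
            post_step = np.full(pre_step.size, v_rest)
        if v_noise > 0 or noise_frac > 0:
            post_step = post_step + rng.normal(
                0.0, max(v_noise, noise_frac * 0.5), post_step.size
            )
        # AP train in the presynaptic cell
        nt = int(round(total / dt_ms))
        pre_ap = np.full(nt, v_rest)
        ap_times = onset + np.arange(n_aps) * 1000.0 / ap_rate_hz
        _place_spikes(pre_ap, dt_ms, ap_times, shape)
        post_i = np.zeros(nt)
        if is_chem:
            kernel = psc_kernel(0.5, 3.0, dt_ms, span_ms=30.5)
            for t0 in ap_times:
                idx = int(round((t0 + shape.peak_offset_ms + 1.0) / dt_ms))
                if idx < nt:
                    seg = kernel[: nt - idx]
                    post_i[idx: idx + seg.size] += -ipsc_amplitude_pA * seg
        if i_noise > 0 or noise_frac > 0:
            post_i = post_i + rng.normal(0.0, max(i_noise, noise_frac * 2.0), nt)
        post_v = None
        if electrical:
            pv = v_rest + coupling_coefficient * _lowpass(pre_ap - v_rest, dt_ms, 2.0)
            if noise_frac > 0:
                pv = pv + rng.normal(0.0, noise_frac * 0.5, nt)
            post_v = Trace(pv, dt_ms=dt_ms, units="mV", meta={"onset_ms": onset})
        meta_step = {"step_pA": step_pA, "onset_ms": onset, "duration_ms": dur}
        return Direction(
            step_pre=Trace(pre_step, dt_ms=dt_ms, units="mV", meta=dict(meta_step)),
            step_post=Trace(post_step, dt_ms=dt_ms, units="mV", meta=dict(meta_step)),
            ap_pre=Trace(pre_ap, dt_ms=dt_ms, units="mV", meta={"onset_ms": onset}),
            ap_post_i=Trace(post_i, dt_ms=dt_ms, units="pA", meta={"onset_ms": onset}),
            ap_post_v=post_v,
        )

    pair = PairRecording(
        a_to_b=make_direction(chem_dirs[0]) if directions[0] else None,
        b_to_a=make_direction(chem_dirs[1]) if directions[1] else None,
    )
    gt = GroundTruth(
        "synth_pair",
        dict(motif=motif, coupling_coefficient=coupling_coefficient,
             ipsc_amplitude_pA=ipsc_amplitude_pA, noise_frac=noise_frac,
             dt_ms=dt_ms),
        seed,
    )
    return pair, gt
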