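"""Voltage-clamp analysis of difference currents.

Builds steady-state I-V curves from subtraction sweep families (the mean
over the final 100 ms of each step is taken as the steady-state K_Na
current), converts them to chord conductance and fits a Boltzmann
activation curve, fits single-exponential onset kinetics, and bins ramp
difference currents at 5-mV intervals to extract the peak persistent
Na+ current.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .io import SweepBundle
from .trace import Trace

__all__ = [
    "IVCurve",
    "ActivationFit",
    "RampIV",
    "steady_state_iv",
    "fit_activation",
    "fit_onset_tau",
    "inap_iv",
    "FitError",
]


class FitError(RuntimeError):
    """Raised when a curve fit is degenerate (flat trace, all-zero currents)."""


@dataclass
class IVCurve:
    voltages: np.ndarray      # mV, step commands
    currents: np.ndarray      # pA, steady-state means (sign preserved)
    steady_window_ms: float = 100.0

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.voltages.shape != self.currents.shape:
            raise ValueError("voltages and currents must align")


@dataclass
class ActivationFit:
    v50: float                # mV
    k: float                  # mV (> 0)
    gmax: float               # nS
    residual_norm: float

    def curve(self, v) -> np.ndarray:
        """Normalized Boltzmann activation at voltages v."""
        return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - self.v50) / self.k))


@dataclass
class RampIV:
    bin_centers: np.ndarray   # mV
    mean_current: np.ndarray  # pA per bin
    peak_negative: float      # pA (most negative bin mean)


def steady_state_iv(bundle: SweepBundle, steady_window_ms: float = 100.0) -> IVCurve:
    """Steady-state I-V from a (difference) voltage-step sweep family."""
    volts, curr = [], []
    for s in bundle:
        onset = s.meta["onset_ms"]
        dur = s.meta["duration_ms"]
        if dur < steady_window_ms:
            raise ValueError("step shorter than the steady-state window")
        volts.append(s.meta["step_mV"])
        curr.append(float(np.mean(s.slice_ms(onset + dur - steady_window_ms, onset + dur))))
    return IVCurve(np.asarray(volts), np.asarray(curr), steady_window_ms)


def _boltzmann(v, gmax, v50, k):
    return gmax / (1.0 + np.exp(-(v - v50) / k))


def fit_activation(iv: IVCurve, erev: float = -90.0, exclude_mV: float = 2.0) -> ActivationFit:
    """Boltzmann fit of the chord-conductance activation curve.

    G(V) = I / (V - E_rev) in nS (pA/mV); points within ``exclude_mV`` of
    the reversal are dropped.  Least-squares fit of
    G = gmax / (1 + exp(-(V - V50)/k)) with bounded parameters.
    """
    mask = np.abs(iv.voltages - erev) > exclude_mV
    v = iv.voltages[mask]
    g = iv.currents[mask] / (v - erev)
    if v.size < 5:
        raise ValueError("need >= 5 points away from the reversal potential")
    gmax0 = float(np.max(g))
    if gmax0 <= 0 or np.allclose(iv.currents, 0.0):
        raise FitError("all-zero or non-positive conductances; nothing to fit")
    half = gmax0 / 2.0
    above = v[g >= half]
    v50_0 = float(above.min()) if above.size else float(v[np.argmax(g)])
    try:
        popt, _ = curve_fit(
            _boltzmann, v, g, p0=(gmax0, v50_0, 10.0),
            bounds=([0.0, -120.0, 0.5], [np.inf, 60.0, 60.0]), maxfev=10000,
        )
    except RuntimeError as e:
        raise FitError(f"activation fit failed: {e}") from e
    resid = g - _boltzmann(v, *popt)
    return ActivationFit(
        v50=float(popt[1]), k=float(popt[2]), gmax=float(popt[0]),
        residual_norm=float(np.linalg.norm(resid)),
    )


def _exp_onset(t, a, tau, c):
    return c + a * (1.0 - np.exp(-t / tau))


def fit_onset_tau(
    trace: Trace,
    onset_ms: float,
    fit_span_ms: float | None = None,
    min_amplitude_pA: float = 1.0,
) -> float:
    """Single-exponential time constant (ms) of a current onset.

    Fits I(t) = C + A (1 - exp(-t/tau)) from ``onset_ms``.  Raises
    :class:`FitError` for flat traces or clearly non-monotone onsets.
    """
    t_end = trace.duration_ms if fit_span_ms is None else min(
        trace.duration_ms, onset_ms + fit_span_ms
    )
    seg = trace.slice_ms(onset_ms, t_end)
    if seg.size < 10:
        raise ValueError("onset segment too short to fit")
    t = np.arange(seg.size) * trace.dt_ms
    a0 = seg[-1] - seg[0]
    if abs(a0) < min_amplitude_pA:
        raise FitError("flat trace: no onset to fit")
    # crude monotonicity guard on a smoothed copy
    n_smooth = max(1, seg.size // 50)
    sm = np.convolve(seg, np.ones(n_smooth) / n_smooth, mode="valid")
    drift = np.sign(a0) * np.diff(sm)
    if np.mean(drift < -0.02 * abs(a0) / sm.size * 50) > 0.25:
        raise FitError("onset is not monotone; refusing single-exponential fit")
    try:
        popt, _ = curve_fit(
            _exp_onset, t, seg, p0=(a0, max(1.0, t[-1] / 5.0), seg[0]),
            bounds=([-np.inf, trace.dt_ms / 10.0, -np.inf], [np.inf, 10 * t[-1], np.inf]),
            maxfev=10000,
        )
    except RuntimeError as e:
        raise FitError(f"onset fit failed: {e}") from e
    return float(popt[1])


def inap_iv(
    diff_trace: Trace,
    bin_mV: float = 5.0,
) -> RampIV:
    """Bin a ramp difference current at 5-mV intervals; extract the peak.

    The trace's metadata must carry ``ramp_start_mV`` and
    ``ramp_rate_mV_per_s`` to map sample times to command voltage.
    ``peak_negative`` is the most negative bin mean (inward peak of the
    persistent Na+ current).
    """
    meta = diff_trace.meta
    try:
        v0 = meta["ramp_start_mV"]
        rate = meta["ramp_rate_mV_per_s"]
    except KeyError as e:
        raise ValueError(f"ramp metadata missing {e.args[0]!r}") from e
    v = v0 + rate * diff_trace.time_ms / 1000.0
    # bin centers sit on absolute multiples of bin_mV (-40, -35, ...), so the
    # grid does not move with the ramp's start voltage
    lo = np.floor(v.min() / bin_mV) * bin_mV
    hi = np.ceil(v.max() / bin_mV) * bin_mV
    edges = np.arange(lo - bin_mV / 2.0, hi + bin_mV, bin_mV)
    centers = (edges[:-1] + edges[1:]) / 2.0
    idx = np.clip(np.digitize(v, edges) - 1, 0, centers.size - 1)
    sums = np.bincount(idx, weights=diff_trace.data, minlength=centers.size)
    counts = np.bincount(idx, minlength=centers.size)
    keep = counts > 0
    means = sums[keep] / counts[keep]
    centers = centers[keep]
    return RampIV(
        bin_centers=centers,
        mean_current=means,
        peak_negative=float(means.min()) if means.size else 0.0,
    )
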