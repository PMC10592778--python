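"""Uniformly sampled trace container shared by simulation and analysis."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trace"]


@dataclass
class Trace:
    """A uniformly sampled series (voltage or current) with stimulus metadata.

    ``data`` is in the units named by ``units`` ("mV", "pA", "nA", "mM");
    ``dt_ms`` is the sampling interval.  ``meta`` carries stimulus
    annotations (step amplitude, onset/duration, condition label) that the
    analysis stages need to interpret the sweep.
    """

    data: np.ndarray
    dt_ms: float
    units: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 1:
            raise ValueError("Trace data must be one-dimensional")
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be > 0")

    @property
    def n(self) -> int:
        return self.data.size

    @property
    def duration_ms(self) -> float:
        return self.n * self.dt_ms

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.n) * self.dt_ms

    @property
    def sampling_rate_hz(self) -> float:
        return 1000.0 / self.dt_ms

    def slice_ms(self, t0: float, t1: float) -> np.ndarray:
        """Samples with t0 <= t < t1 (ms)."""
        i0 = max(0, int(round(t0 / self.dt_ms)))
        i1 = min(self.n, int(round(t1 / self.dt_ms)))
        return self.data[i0:i1]
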