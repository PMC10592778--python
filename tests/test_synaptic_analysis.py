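"""Event detection, E/I ratio, pair motifs, and connection statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slacksim.synaptic_analysis import (
    EventSummary,
    EventTemplate,
    classify_pair,
    connection_stats,
    detect_events,
    ei_ratio,
)
from slacksim.synthetic_data import synth_pair, synth_psc_trace
from slacksim.trace import Trace

MOTIFS = ("not coupled", "chemical: one-way", "chemical: two-way", "electrical")


class TestDetectEvents:
    def test_noise_only_low_false_positive_rate(self):
        # 60 s of pure Gaussian noise: < 0.1 Hz false positives
        rng = np.random.default_rng(11)
        tr = Trace(rng.normal(0.0, 3.0, int(60e3 / 0.05)), dt_ms=0.05, units="pA")
        ev = detect_events(tr)
        assert ev.frequency_hz < 0.1

    def test_poisson_rate_recovered_within_ci(self):
        tr, gt = synth_psc_trace(rate_hz=5.0, amplitude_pA=20.0, noise_sd_pA=2.0,
                                 duration_s=30.0, seed=5)
        ev = detect_events(tr)
        n_true = gt.params["event_times_ms"]
        n = len(n_true)
        # Poisson 95% band around the true generated count
        lo, hi = n - 1.96 * math.sqrt(n), n + 1.96 * math.sqrt(n)
        assert lo <= ev.frequency_hz * 30.0 <= hi

    def test_high_snr_recall(self):
        # events at 5x noise SD: recall >= 95%
        tr, gt = synth_psc_trace(rate_hz=2.0, amplitude_pA=10.0, noise_sd_pA=2.0,
                                 duration_s=30.0, seed=9)
        ev = detect_events(tr)
        true_times = np.array(gt.params["event_times_ms"])
        hit = sum(np.any(np.abs(ev.times_ms - t) < 5.0) for t in true_times)
        assert hit / len(true_times) >= 0.95

    def test_deterministic(self):
        tr, _ = synth_psc_trace(seed=3)
        e1 = detect_events(tr)
        e2 = detect_events(tr)
        assert np.array_equal(e1.times_ms, e2.times_ms)
        assert np.array_equal(e1.amplitudes_pA, e2.amplitudes_pA)

    def test_short_trace_rejected(self):
        tr = Trace(np.zeros(10), dt_ms=0.05, units="pA")
        with pytest.raises(ValueError):
            detect_events(tr)


class TestEIRatio:
    def summary(self, f, q):
        return EventSummary(frequency_hz=f, mean_charge_pC=q)

    def test_symmetric_case_half(self):
        assert ei_ratio(self.summary(4.0, 2.0), self.summary(2.0, 4.0)) == 0.5

    def test_no_inhibition_gives_one(self):
        assert ei_ratio(self.summary(3.0, 1.0), self.summary(0.0, 0.0)) == 1.0

    def test_worked_arithmetic(self):
        # (4*2) / (4*2 + 2*2) = 8/12
        assert ei_ratio(self.summary(4.0, 2.0), self.summary(2.0, 2.0)) == pytest.approx(8 / 12)

    def test_degenerate_nan(self):
        assert math.isnan(ei_ratio(self.summary(0.0, 0.0), self.summary(0.0, 0.0)))

    @given(st.floats(0.01, 100.0), st.floats(0.01, 100.0), st.floats(0.01, 100.0),
           st.floats(0.01, 100.0), st.floats(0.1, 10.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounded_and_scale_invariant(self, fe, qe, fi, qi, c):
        r = ei_ratio(self.summary(fe, qe), self.summary(fi, qi))
        assert 0.0 <= r <= 1.0
        r2 = ei_ratio(self.summary(c * fe, c * qe), self.summary(c * fi, c * qi))
        assert r2 == pytest.approx(r, rel=1e-9)


class TestClassifyPair:
    @pytest.mark.parametrize("motif", MOTIFS)
    def test_noise_free_round_trip(self, motif):
        pair, _ = synth_pair(motif, seed=0)
        assert classify_pair(pair).label == motif

    def test_noise_robustness(self):
        # >= 90% accuracy at noise 20% of signal across motifs and seeds
        correct = total = 0
        for motif in MOTIFS:
            for seed in range(5):
                pair, _ = synth_pair(motif, noise_frac=0.2, seed=100 + seed)
                correct += classify_pair(pair).label == motif
                total += 1
        assert correct / total >= 0.90

    def test_missing_direction_flagged_partial(self):
        pair, _ = synth_pair("not coupled", directions=(True, False), seed=1)
        res = classify_pair(pair)
        assert res.partial

    def test_electrical_shows_spikelet_evidence(self):
        pair, _ = synth_pair("electrical", coupling_coefficient=0.05, seed=2)
        res = classify_pair(pair)
        assert res.label == "electrical"
        assert any(res.spikelet_evidence.values())


class TestConnectionStats:
    def test_point_estimate(self):
        out = connection_stats(30, 40)
        assert out["p_a"] == pytest.approx(0.75)

    def test_zero_connections_ci_floor(self):
        out = connection_stats(0, 20)
        assert out["p_a"] == 0.0
        assert out["ci_a"][0] == 0.0

    def test_fisher_matches_brute_force_enumeration(self):
        # two-sided Fisher exact on 30/40 vs 15/40 by exhaustive
        # hypergeometric enumeration of all tables with fixed margins
        out = connection_stats(30, 40, 15, 40)

        k1, n1, k2, n2 = 30, 40, 15, 40
        total_success = k1 + k2
        total = n1 + n2

        def log_hyper(a):
            return (
                math.lgamma(total_success + 1) - math.lgamma(a + 1)
                - math.lgamma(total_success - a + 1)
                + math.lgamma(total - total_success + 1) - math.lgamma(n1 - a + 1)
                - math.lgamma(total - total_success - (n1 - a) + 1)
                - (math.lgamma(total + 1) - math.lgamma(n1 + 1) - math.lgamma(n2 + 1))
            )

        lo = max(0, total_success - n2)
        hi = min(n1, total_success)
        probs = {a: math.exp(log_hyper(a)) for a in range(lo, hi + 1)}
        p_obs = probs[k1]
        p_two = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))
        assert out["fisher_p"] == pytest.approx(p_two, rel=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            connection_stats(5, 3)
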