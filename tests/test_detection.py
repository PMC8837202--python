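"""Event detection: centering, noise, Viterbi vs changepoint oracle,
extraction and screens."""

import numpy as np
import pytest

import forcejump as fj
from forcejump.detection import (
    DetectionConfig,
    EventRejected,
    NoiseEstimate,
    StatePath,
    center_plateau,
    estimate_noise,
    extract_event,
    truncate_for_drift,
    viterbi_decode,
)


def scan_oracle(segment, esd, p_trans, sep=4.0):
    """Exhaustive single-changepoint maximum-likelihood scan.

    The one-way two-state chain is exactly a single-changepoint model, so
    the Viterbi path can be checked against a brute-force scan over every
    candidate changepoint (including the transition log-penalty).
    """
    z = np.asarray(segment, float) / esd
    e0 = -0.5 * z**2
    e1 = -0.5 * (z - sep) ** 2
    n = len(z)
    log_stay = np.log1p(-p_trans)
    log_go = np.log(p_trans)
    c0 = np.concatenate([[0.0], np.cumsum(e0)])
    c1 = np.concatenate([[0.0], np.cumsum(e1)])
    ll_null = c0[n] + (n - 1) * log_stay
    lls = np.array(
        [c0[k] + (k - 1) * log_stay + log_go + (c1[n] - c1[k]) for k in range(1, n)]
    )
    k_best = int(np.argmax(lls)) + 1
    return k_best if lls[k_best - 1] > ll_null else None


class TestCentering:
    def test_constant_series_becomes_zero(self):
        assert np.allclose(center_plateau(np.full(50, 7.3)), 0.0)

    def test_subtracts_first_five_mean(self):
        seg = np.array([1.0, 2.0, 3.0, 2.0, 2.0, 9.0])
        out = center_plateau(seg)
        assert np.allclose(out, seg - 2.0)
        assert out[:5].mean() == pytest.approx(0.0)

    def test_idempotent(self, rng):
        seg = rng.normal(5.0, 1.0, 100)
        once = center_plateau(seg)
        assert np.allclose(center_plateau(once), once)

    def test_too_short_rejected(self):
        with pytest.raises(EventRejected):
            center_plateau(np.ones(4))


class TestNoiseEstimate:
    def test_constant_series_zero(self):
        assert estimate_noise(np.ones(100)).eSD == 0.0

    def test_gaussian_matches_monte_carlo_median(self, rng):
        # oracle: Monte-Carlo median of the 10-sample sd estimator
        sigma = 2.0
        mc = np.median(rng.normal(0, 1, (100_000, 10)).std(axis=1, ddof=1))
        seg = rng.normal(0.0, sigma, 10_000)
        est = estimate_noise(seg)
        assert est.eSD / sigma == pytest.approx(mc, abs=0.02)
        assert est.eSD / sigma == pytest.approx(0.97, abs=0.03)

    def test_robust_to_single_step(self, rng):
        sigma = 1.0
        seg = rng.normal(0, sigma, 2000)
        seg[1000:] += 8.0  # large step; median of window sds barely moves
        assert estimate_noise(seg).eSD == pytest.approx(sigma * 0.97, rel=0.10)

    def test_too_short_rejected(self):
        with pytest.raises(EventRejected):
            estimate_noise(np.ones(5))


class TestViterbi:
    def test_pure_noise_has_no_transition(self, rng):
        seg = rng.normal(0, 1.0, 1000)
        path = viterbi_decode(seg, NoiseEstimate(1.0), 1e-3)
        assert path.changepoint is None
        assert np.all(path.states == 0)

    def test_noiseless_step_located_exactly(self):
        esd = 1.0
        seg = np.concatenate([np.zeros(137), np.full(200, 4.0 * esd)])
        path = viterbi_decode(seg, NoiseEstimate(esd), 1e-3)
        assert path.changepoint == 137
        assert np.sum(np.diff(path.states.astype(int)) != 0) == 1

    def test_degenerate_emission_rejected(self):
        with pytest.raises(EventRejected):
            viterbi_decode(np.zeros(50), NoiseEstimate(0.0), 1e-3)

    def test_matches_exhaustive_scan_oracle(self, rng):
        # mixed null and single-step segments, exact index agreement
        for _ in range(200):
            n = int(rng.integers(50, 400))
            esd = float(rng.uniform(0.5, 3.0))
            seg = rng.normal(0, esd, n)
            if rng.random() < 0.6:
                k = int(rng.integers(1, n))
                seg[k:] += esd * rng.uniform(2.0, 8.0)
            p = float(10 ** rng.uniform(-5, -2))
            got = viterbi_decode(seg, NoiseEstimate(esd), p).changepoint
            assert got == scan_oracle(seg, esd, p)

    def test_offset_invariance(self, rng):
        seg = rng.normal(0, 1.0, 500)
        seg[300:] += 5.0
        centered = center_plateau(seg)
        a = viterbi_decode(centered, NoiseEstimate(1.0), 1e-3).changepoint
        b = viterbi_decode(center_plateau(seg + 123.4), NoiseEstimate(1.0), 1e-3).changepoint
        assert a == b == 300

    def test_joint_scale_invariance(self, rng):
        seg = rng.normal(0, 1.0, 400)
        seg[250:] += 4.5
        for c in (0.1, 7.0):
            a = viterbi_decode(seg, NoiseEstimate(1.0), 1e-3)
            b = viterbi_decode(c * seg, NoiseEstimate(c * 1.0), 1e-3)
            assert a.changepoint == b.changepoint

    def test_changepoint_location_insensitive_to_penalty(self, rng):
        # the penalty moves the detection threshold, not the location,
        # for well-separated states
        seg = rng.normal(0, 1.0, 600)
        seg[412:] += 3.5
        cps = {
            viterbi_decode(seg, NoiseEstimate(1.0), p).changepoint
            for p in (1e-5, 1e-4, 1e-3, 1e-2)
        }
        assert len(cps) == 1


class TestExtraction:
    def test_lifetime_from_changepoint(self):
        seg = np.concatenate([np.zeros(100), np.full(100, 5.0)])
        path = StatePath(np.zeros(0, np.uint8), 100)
        tau, dx, n_pre = extract_event(seg, path, 200.0)
        assert tau == pytest.approx(0.5)
        assert dx == pytest.approx(5.0)
        assert n_pre == 100

    def test_short_event_rejected(self):
        seg = np.concatenate([np.zeros(3), np.full(100, 5.0)])
        with pytest.raises(EventRejected):
            extract_event(seg, StatePath(np.zeros(0, np.uint8), 3), 200.0)

    def test_no_post_samples_rejected(self):
        seg = np.zeros(50)
        with pytest.raises(EventRejected):
            extract_event(seg, StatePath(np.zeros(0, np.uint8), 50), 200.0)

    def test_noiseless_step_height_exact(self):
        h = 7.31
        seg = np.concatenate([np.zeros(40), np.full(10, h)])
        _, dx, _ = extract_event(seg, StatePath(np.zeros(0, np.uint8), 40), 200.0)
        assert dx == pytest.approx(h)


class TestDriftHandling:
    def test_drift_free_segment_unchanged(self, rng):
        seg = rng.normal(0, 1.0, 1000)
        seg[500:] += 5.0
        out, offset = truncate_for_drift(seg, 500, NoiseEstimate(1.0), 200.0)
        assert offset == 0
        assert out is seg or np.array_equal(out, seg)

    def test_truncation_keeps_changepoint(self, rng):
        seg = rng.normal(0, 1.0, 1000)
        seg[600:] += 5.0
        seg += np.arange(1000) * 0.02  # 4 nm/s drift at 200 Hz
        out, offset = truncate_for_drift(seg, 600, NoiseEstimate(1.0), 200.0)
        assert offset <= 600 < offset + out.size

    def test_truncated_delta_x_within_ten_percent(self, rng):
        # drift of 5 eSD over the plateau; detection after truncation
        # still recovers the step height
        from forcejump.detection import _detect_one

        esd, h, cp = 1.0, 6.0, 700
        errs = []
        n_rejected = 0
        for _ in range(20):
            seg = rng.normal(0, esd, 1000)
            seg[cp:] += h
            seg += np.arange(1000) * (5.0 * esd / 1000.0)
            try:
                tau, dx, n_pre, flags = _detect_one(seg + 3.0, 200.0, DetectionConfig())
            except EventRejected:
                n_rejected += 1  # borderline slope screens may fire on 5 eSD drift
                continue
            errs.append(abs(dx - h) / h)
        assert n_rejected <= 5
        assert np.median(errs) < 0.10


class TestDetectEvents:
    def test_negative_control_no_events(self, rng, geom55):
        cfg = fj.SimulationConfig(
            bell=fj.RSA4_BELL, p_bind=0.0, n_molecules=2, cycles_per_molecule=20
        )
        traces = fj.simulate_corpus(cfg, seed=11, constructs=(55,))
        for tr in traces:
            events, _ = fj.detect_events(tr, geom55)
            assert events == []

    def test_recall_at_four_esd_step(self, geom55):
        # one event per plateau; recall >= 0.95 for tau >= 5 samples at
        # a rupture step of exactly 4 eSD
        dx = fj.predict_delta_x(6.0, geom55)
        cfg = fj.SimulationConfig(
            bell=fj.RSA4_BELL, p_bind=1.0, high_forces=(6.0,),
            n_molecules=4, cycles_per_molecule=40, noise_sd=dx / 4.0,
        )
        traces = fj.simulate_corpus(cfg, seed=5, constructs=(55,))
        n_rec = n_hit = 0
        for tr in traces:
            events, _ = fj.detect_events(tr, geom55)
            found = {e.plateau_id for e in events}
            for g in tr.ground_truth:
                if g.bound_at_jump and not g.censored and 5 / 200 <= g.tau <= 4.8:
                    n_rec += 1
                    n_hit += g.plateau_id in found
        assert n_rec > 100
        assert n_hit / n_rec >= 0.95

    def test_no_sub_minimum_lifetimes_in_output(self, geom55):
        cfg = fj.SimulationConfig(
            bell=fj.RSA4_BELL, p_bind=1.0, n_molecules=3, cycles_per_molecule=30
        )
        traces = fj.simulate_corpus(cfg, seed=3, constructs=(55,))
        for tr in traces:
            events, _ = fj.detect_events(tr, geom55)
            for e in events:
                assert e.tau >= 4 / 200.0
                assert 0.0 < e.F_Load < e.F_Tot

    def test_geometry_mismatch_is_structural_error(self, geom70):
        cfg = fj.SimulationConfig(
            bell=fj.RSA4_BELL, n_molecules=1, cycles_per_molecule=5
        )
        trace = fj.simulate_corpus(cfg, seed=1, constructs=(55,))[0]
        with pytest.raises(ValueError):
            fj.detect_events(trace, geom70)
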