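"""Generator contracts: geometry, trial statistics, Poisson spiking, LFP."""

import numpy as np
import pytest
from scipy import stats

from popdyn.efficiency import band_power
from popdyn.session import UnitTruth
from popdyn.simulate import (
    SimConfig,
    _rng,
    encoding_vector_for_truth,
    make_array_geometry,
    rate_segments,
    simulate_lfp,
    simulate_session,
    simulate_spikes,
    simulate_trial,
)


class TestGeometry:
    def test_eccentricities_within_range(self, geometry):
        ecc = geometry.eccentricities()
        assert np.all(ecc >= 5.0) and np.all(ecc <= 11.0)

    def test_mirror_pairs_and_midline(self, geometry):
        coords = geometry.coordinates
        mid = coords[np.isclose(coords[:, 0], 0.0)]
        assert len(mid) == 2
        right = coords[coords[:, 0] > 0]
        assert len(right) == 9
        for x, y in right:
            assert np.any(np.all(np.isclose(coords, [-x, y]), axis=1))

    def test_deterministic(self):
        assert np.array_equal(make_array_geometry(1).coordinates,
                              make_array_geometry(2).coordinates)


class TestTrials:
    def test_timeline_and_target_hold(self):
        cfg = SimConfig()
        for i in range(50):
            t = simulate_trial(cfg, i, _rng(0, 1, i))
            assert 0.0 < t.cue_on < t.cue_off < t.array_on < t.trial_end
            assert 500.0 <= t.cue_off - t.cue_on <= 1300.0
            assert t.array_on - t.cue_off == pytest.approx(cfg.delay_ms)
            if t.correct:
                last = t.fixations[-1]
                assert last.is_target
                assert last.offset - last.onset >= cfg.target_hold_ms - 1e-9
            t.validate()

    def test_no_refixations_when_prob_zero(self):
        cfg = SimConfig(refixation_prob=0.0)
        for i in range(200):
            t = simulate_trial(cfg, i, _rng(1, 1, i))
            assert not any(f.is_refixation for f in t.fixations)

    def test_return_fixation_rate_matches_behavioral_calibration(self):
        """~13.46% of correct trials contain a return fixation (+-3 pp)."""
        cfg = SimConfig()
        trials = [simulate_trial(cfg, i, _rng(2, 1, i)) for i in range(3000)]
        corr = [t for t in trials if t.correct]
        frac = np.mean([any(f.is_refixation for f in t.fixations) for t in corr])
        assert abs(frac - 0.1346) < 0.03

    def test_fixation_durations_near_mean(self):
        cfg = SimConfig()
        durs = []
        for i in range(400):
            t = simulate_trial(cfg, i, _rng(3, 1, i))
            durs += [f.offset - f.onset for f in t.fixations if not
                     (f.is_target and
                      f.offset - f.onset >= cfg.target_hold_ms - 1e-6)]
        assert abs(np.mean(durs) - cfg.fix_duration_mean_ms) < 15.0


def _flat_truth(rate=20.0, rf="nonresponsive", **kw) -> UnitTruth:
    return UnitTruth(baseline_rate=rate, rf_class=rf, **kw)


class TestSpikes:
    def test_untuned_unit_rate_matches_baseline(self, geometry):
        cfg = SimConfig()
        truth = _flat_truth()
        counts, total_s = [], 0.0
        for i in range(400):
            t = simulate_trial(cfg, i, _rng(4, 1, i))
            st = simulate_spikes(truth, t, geometry, _rng(4, 2, 0, i))
            counts.append(len(st) / (t.trial_end / 1000.0))
        mean = np.mean(counts)
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(mean - truth.baseline_rate) < 3 * se + 0.3

    def test_attention_gain_doubles_target_fixation_rate(self, geometry):
        cfg = SimConfig()
        truth = _flat_truth(rate=20.0, rf="focal_foveal", attention_gain=2.0)
        tgt, dst = [], []
        for i in range(600):
            t = simulate_trial(cfg, i, _rng(5, 1, i))
            st = simulate_spikes(truth, t, geometry, _rng(5, 2, 0, i))
            for fx in t.fixations:
                n = np.count_nonzero((st >= fx.onset + 50) & (st < fx.offset + 50))
                dur_s = (fx.offset - fx.onset) / 1000.0
                (tgt if fx.is_target else dst).append(n / dur_s)
        ratio = np.mean(tgt) / np.mean(dst)
        assert abs(ratio - 2.0) < 0.25

    def test_isi_exponential_at_constant_rate(self, geometry):
        """Refractory-free Poisson: ISIs match the exponential law (KS)."""
        cfg = SimConfig()
        truth = _flat_truth(rate=40.0)
        isis = []
        for i in range(200):
            t = simulate_trial(cfg, i, _rng(6, 1, i))
            st = simulate_spikes(truth, t, geometry, _rng(6, 2, 0, i))
            isis.append(np.diff(st))
        isis = np.concatenate(isis)
        p = stats.kstest(isis, "expon", args=(0, 1000.0 / truth.baseline_rate)).pvalue
        assert p > 0.01

    def test_rate_segments_cover_trial_without_negative_rates(self, geometry):
        cfg = SimConfig()
        truth = UnitTruth(baseline_rate=10.0, rf_class="peripheral_localized",
                          rf_center=(5.5, 0.0), rf_sigma=2.5, evoked_rate=8.0,
                          attention_gain=2.0, state_gain=1.5)
        for i in range(20):
            t = simulate_trial(cfg, i, _rng(7, 1, i))
            segs = rate_segments(truth, t, geometry)
            assert all(r >= 0 for _, _, r in segs)
            assert segs[0][0] == 0.0

    def test_encoding_vector_matches_tuning(self):
        truth = UnitTruth(baseline_rate=10.0, rf_class="peripheral_localized",
                          evoked_rate=6.0, category_gain=2.0, attention_gain=1.5,
                          state_gain=2.0, category_pref="face")
        beta = encoding_vector_for_truth(truth)
        # face target, on-target block: evoked * g_cat * g_att * state
        assert beta[0] == pytest.approx(6.0 * 2.0 * 1.5 * 2.0)
        # house distractor, on-distractor block: evoked / g_cat
        assert beta[6 + 3] == pytest.approx(6.0 / 2.0)
        # flower distractor never gets category or attention gain
        assert beta[6 + 4] == pytest.approx(6.0)


class TestReproducibility:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig(n_units={"V4": 4, "IT": 0, "OFC": 0, "LPFC": 0}, n_trials=10)
        a = simulate_session(cfg)
        b = simulate_session(cfg)
        for ua, ub in zip(a.units, b.units):
            for tid in ua.spikes:
                assert np.array_equal(ua.spikes[tid], ub.spikes[tid])
        for ca, cb in zip(a.lfp, b.lfp):
            for tid in ca.samples:
                assert np.array_equal(ca.samples[tid], cb.samples[tid])

    def test_adding_units_preserves_existing_streams(self):
        """Counter-based substreams: unit 0's spikes do not depend on how
        many units the session contains."""
        small = SimConfig(n_units={"V4": 2, "IT": 0, "OFC": 0, "LPFC": 0}, n_trials=8)
        big = SimConfig(n_units={"V4": 6, "IT": 0, "OFC": 0, "LPFC": 0}, n_trials=8)
        a, b = simulate_session(small), simulate_session(big)
        for ua, ub in zip(a.units[:2], b.units[:2]):
            assert ua.unit_id == ub.unit_id
            for tid in ua.spikes:
                assert np.array_equal(ua.spikes[tid], ub.spikes[tid])


class TestLfp:
    def test_zero_theta_amplitude_gives_background_power(self):
        cfg = SimConfig(theta_base=0.0)
        from popdyn.session import GroundTruth

        gt = GroundTruth(theta_base=0.0)
        gt_on = GroundTruth(theta_base=1.0)
        p0, p1 = [], []
        for i in range(60):
            t = simulate_trial(cfg, i, _rng(8, 1, i))
            x0 = simulate_lfp(cfg, t, gt, _rng(8, 3, 0, i))
            x1 = simulate_lfp(cfg, t, gt_on, _rng(8, 3, 0, i))
            seg0 = x0[int(t.cue_on):int(t.cue_off)]
            seg1 = x1[int(t.cue_on):int(t.cue_off)]
            p0.append(band_power(seg0, 1000.0, (4, 12)))
            p1.append(band_power(seg1, 1000.0, (4, 12)))
        assert np.mean(p1) > 2.0 * np.mean(p0)

    def test_doubling_amplitude_quadruples_band_power(self):
        """Parseval: sinusoid power scales with amplitude squared."""
        from popdyn.session import GroundTruth

        cfg = SimConfig(lfp_noise_sd=0.0)
        g1 = GroundTruth(theta_base=1.0)
        g2 = GroundTruth(theta_base=2.0)
        ratios = []
        for i in range(20):
            t = simulate_trial(cfg, i, _rng(9, 1, i))
            x1 = simulate_lfp(cfg, t, g1, _rng(9, 3, 0, i))
            x2 = simulate_lfp(cfg, t, g2, _rng(9, 3, 0, i))
            seg = slice(int(t.cue_on), int(t.cue_off))
            ratios.append(band_power(x2[seg], 1000.0, (4, 12))
                          / band_power(x1[seg], 1000.0, (4, 12)))
        assert abs(np.mean(ratios) - 4.0) < 0.2
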