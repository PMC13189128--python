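"""dPCA: PSTH assembly, axis recovery, PCA equivalence, shuffle statistics."""

import numpy as np
import pytest

from popdyn.dpca import (
    PSTHMatrix,
    binned_samples,
    build_psth_matrix,
    demixing_from_reference,
    fit_dpca,
    psth_from_samples,
    trajectory_separation_test,
)


def make_psth(values, n_time, conditions, unit_ids=None):
    T = n_time
    return PSTHMatrix(values=values, n_time=T, conditions=conditions,
                      times=np.arange(T, dtype=float),
                      unit_ids=unit_ids or [f"u{i}" for i in range(values.shape[1])])


def synthetic_samples(n_per_cond=40, T=20, N=12, cond_vec=None, noise=0.3, seed=0):
    """Per-sample rates: shared temporal mode + optional condition offset."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, T)
    temporal = np.outer(np.sin(2 * np.pi * t), rng.standard_normal(N))
    samples, labels = [], []
    for ci, cond in enumerate(("face", "house")):
        for _ in range(n_per_cond):
            x = temporal.copy()
            if cond_vec is not None and ci == 0:
                x = x + cond_vec[None, :]
            samples.append(x + noise * rng.standard_normal((T, N)))
            labels.append(cond)
    return np.array(samples), np.array(labels), np.arange(T, dtype=float)


class TestPsthMatrix:
    def test_cue_epoch_bin_arithmetic(self, tuned_session):
        ids = [u.unit_id for u in tuned_session.units[:8]]
        psth = build_psth_matrix(tuned_session, ids, "cue")
        assert psth.n_time == 50  # 500 ms / 10 ms
        assert psth.values.shape[0] == 50 * psth.n_conditions

    def test_shape_two_conditions(self):
        samples, labels, times = synthetic_samples()
        psth = psth_from_samples(samples, labels, times, [f"u{i}" for i in range(12)])
        assert psth.values.shape == (2 * 20, 12)
        assert psth.conditions == ["face", "house"]

    def test_condition_means_match_naive_loop(self, tuned_session):
        """Fast assembly equals a brute-force per-unit trial average."""
        ids = [u.unit_id for u in tuned_session.units[:6]]
        samples, labels, times, kept = binned_samples(tuned_session, ids, "cue")
        psth = psth_from_samples(samples, labels, times, kept)
        for ci, cond in enumerate(psth.conditions):
            naive = np.zeros((len(times), len(kept)))
            count = 0
            for s, lab in zip(samples, labels):
                if lab == cond:
                    naive += s
                    count += 1
            naive /= count
            block = psth.values[ci * len(times):(ci + 1) * len(times)]
            assert np.max(np.abs(block - naive)) < 1e-12

    def test_empty_condition_raises(self):
        samples, labels, times = synthetic_samples(n_per_cond=5)
        with pytest.raises(ValueError, match="flower"):
            psth_from_samples(samples, labels, times,
                              [f"u{i}" for i in range(12)],
                              condition_order=["face", "flower"])


class TestFitDpca:
    def test_zero_condition_dependence(self):
        samples, labels, times = synthetic_samples(cond_vec=None, noise=0.0)
        psth = psth_from_samples(samples, labels, times, [f"u{i}" for i in range(12)])
        fit = fit_dpca(psth)
        assert fit.explained_variance["condition"].sum() < 0.01

    def test_planted_condition_axis_recovered(self):
        rng = np.random.default_rng(3)
        v = rng.standard_normal(12)
        v /= np.linalg.norm(v)
        samples, labels, times = synthetic_samples(cond_vec=2.0 * v, noise=0.2, seed=3)
        psth = psth_from_samples(samples, labels, times, [f"u{i}" for i in range(12)])
        fit = fit_dpca(psth)
        axis = fit.encoders["condition"][:, 0]
        cos = abs(axis @ v) / np.linalg.norm(axis)
        assert cos >= 0.95

    def test_single_condition_reduces_to_pca(self):
        rng = np.random.default_rng(4)
        T, N = 30, 10
        X = rng.standard_normal((T, 3)) @ rng.standard_normal((3, N))
        psth = make_psth(X, T, ["only"])
        fit = fit_dpca(psth, n_components=3)
        Xc = X - X.mean(axis=0)
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        for j in range(3):
            e = fit.encoders["time"][:, j]
            cos = abs(e @ vt[j]) / np.linalg.norm(e)
            assert cos >= 0.99

    def test_explained_variance_fractions_bounded(self):
        samples, labels, times = synthetic_samples(cond_vec=np.ones(12), seed=5)
        psth = psth_from_samples(samples, labels, times, [f"u{i}" for i in range(12)])
        fit = fit_dpca(psth)
        total = sum(ev.sum() for ev in fit.explained_variance.values())
        assert 0.0 < total <= 1.0 + 1e-9

    def test_projection_is_linear(self):
        samples, labels, times = synthetic_samples(cond_vec=np.ones(12), seed=6)
        psth = psth_from_samples(samples, labels, times, [f"u{i}" for i in range(12)])
        fit = fit_dpca(psth)
        pts = fit.project(psth)
        mean_rows = psth.values.reshape(2, 20, 12).mean(axis=0)
        mean_psth = make_psth(mean_rows, 20, ["mean"], psth.unit_ids)
        pts_mean = fit.project(mean_psth)
        assert np.allclose(pts.mean(axis=0), pts_mean[0], atol=1e-9)

    def test_too_few_units_raises(self):
        psth = make_psth(np.random.default_rng(0).standard_normal((20, 2)), 10,
                         ["a", "b"])
        with pytest.raises(ValueError, match="components"):
            fit_dpca(psth, n_components=3)


class TestReferenceProjection:
    def test_reference_equals_apply_matches_fit_project(self):
        samples, labels, times = synthetic_samples(cond_vec=np.ones(12), seed=7)
        psth = psth_from_samples(samples, labels, times, [f"u{i}" for i in range(12)])
        fit = fit_dpca(psth)
        traj = demixing_from_reference(psth, psth)
        assert np.allclose(traj.points, fit.project(psth), atol=1e-9)

    def test_unit_mismatch_raises(self):
        samples, labels, times = synthetic_samples()
        ids = [f"u{i}" for i in range(12)]
        a = psth_from_samples(samples, labels, times, ids)
        b = psth_from_samples(samples, labels, times, list(reversed(ids)))
        with pytest.raises(ValueError, match="unit"):
            demixing_from_reference(a, b)

    def test_shared_axis_transfers_across_epochs(self):
        """Axes fit on one epoch separate conditions in another epoch that
        uses the same coding direction."""
        rng = np.random.default_rng(8)
        v = rng.standard_normal(12)
        v /= np.linalg.norm(v)
        s1, l1, t1 = synthetic_samples(cond_vec=2.0 * v, noise=0.2, seed=8)
        s2, l2, t2 = synthetic_samples(cond_vec=1.5 * v, noise=0.2, seed=9)
        ids = [f"u{i}" for i in range(12)]
        ref = psth_from_samples(s1, l1, t1, ids)
        app = psth_from_samples(s2, l2, t2, ids)
        traj = demixing_from_reference(ref, app)
        sep = np.linalg.norm(traj.points[0] - traj.points[1], axis=1)
        # separation clearly above the within-condition noise scale
        assert sep.mean() > 1.0


class TestSeparationTest:
    def test_exact_null_zero_significant_bins(self):
        """Duplicated condition data: label shuffles change nothing."""
        rng = np.random.default_rng(10)
        base = rng.standard_normal((30, 15, 8))
        samples = np.concatenate([base, base])
        labels = np.array(["face"] * 30 + ["house"] * 30)
        traj = trajectory_separation_test(samples, labels, np.arange(15.0),
                                          [f"u{i}" for i in range(8)],
                                          n_perm=100,
                                          rng=np.random.default_rng(0))
        assert traj.significant.sum() == 0

    def test_planted_difference_detected_after_latency(self):
        rng = np.random.default_rng(11)
        T, N = 20, 10
        v = rng.standard_normal(N)
        v /= np.linalg.norm(v)
        samples, labels = [], []
        for cond in ("face", "house"):
            for _ in range(40):
                x = 0.3 * rng.standard_normal((T, N))
                if cond == "face":
                    x[8:] += 2.0 * v  # difference appears at bin 8
                samples.append(x)
                labels.append(cond)
        traj = trajectory_separation_test(np.array(samples), np.array(labels),
                                          np.arange(float(T)),
                                          [f"u{i}" for i in range(N)],
                                          n_perm=200,
                                          rng=np.random.default_rng(1))
        assert traj.significant[10:].mean() >= 0.8
        assert traj.significant[:6].sum() == 0

    def test_shuffle_null_exchangeable(self):
        """On label-shuffled data the observed statistic sits at a uniform
        rank within its own null distribution."""
        rng = np.random.default_rng(12)
        ranks = []
        for rep in range(30):
            samples = rng.standard_normal((40, 6, 6))
            labels = np.array(["face"] * 20 + ["house"] * 20)
            traj = trajectory_separation_test(samples, labels, np.arange(6.0),
                                              [f"u{i}" for i in range(6)],
                                              n_perm=60,
                                              rng=np.random.default_rng(rep))
            ranks.extend(traj.pvalues.tolist())
        from scipy import stats

        # p-values approximately uniform under the null
        assert stats.kstest(ranks, "uniform").pvalue > 0.005

    def test_small_n_perm_warns(self):
        rng = np.random.default_rng(13)
        samples = rng.standard_normal((20, 5, 5))
        labels = np.array(["a"] * 10 + ["b"] * 10)
        with pytest.warns(UserWarning, match="n_perm"):
            trajectory_separation_test(samples, labels, np.arange(5.0),
                                       [f"u{i}" for i in range(5)], n_perm=50)
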