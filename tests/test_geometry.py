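"""Representational geometry: distances, angles, hyperplanes, Procrustes."""

import numpy as np
import pytest
from scipy.stats import special_ortho_group

from popdyn.geometry import (
    context_comparison,
    fixation_rate_table,
    hyperplane_angle,
    mean_pairwise_distance,
    representational_distance,
    rpca_align,
    vector_angle,
)


class TestDistanceAndAngle:
    def test_identical_vectors_zero(self):
        v = np.arange(5.0)
        assert representational_distance(v, v) == 0.0
        assert vector_angle(v + 1, v + 1) == pytest.approx(0.0, abs=1e-6)

    def test_single_coordinate_offset(self):
        v = np.ones(4)
        w = v.copy()
        w[0] += 3.0
        assert representational_distance(v, w) == pytest.approx(3.0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal(30), rng.standard_normal(30)
        oracle = np.sqrt(np.sum((a - b) ** 2))
        assert abs(representational_distance(a, b) - oracle) < 1e-12

    @pytest.mark.parametrize("a,b,expected", [
        ([1, 0], [0, 1], 90.0),
        ([1, 1], [-1, -1], 180.0),
        ([2, 0], [5, 0], 0.0),
    ])
    def test_canonical_angles(self, a, b, expected):
        assert vector_angle(np.array(a, float), np.array(b, float)) == pytest.approx(expected)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            vector_angle(np.zeros(3), np.ones(3))
        with pytest.raises(ValueError, match="mismatch"):
            representational_distance(np.ones(3), np.ones(4))

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b, c = rng.standard_normal((3, 8))
            dab = representational_distance(a, b)
            assert dab == representational_distance(b, a)
            assert dab <= (representational_distance(a, c)
                           + representational_distance(c, b) + 1e-12)


def planted_rate_matrix(n_fix=400, n_units=24, seed=0, orthogonal=True):
    """Fixation x unit rates with category and attention codes planted along
    two chosen directions."""
    rng = np.random.default_rng(seed)
    w_cat = rng.standard_normal(n_units)
    w_cat /= np.linalg.norm(w_cat)
    if orthogonal:
        w_att = rng.standard_normal(n_units)
        w_att -= (w_att @ w_cat) * w_cat
        w_att /= np.linalg.norm(w_att)
    else:
        w_att = w_cat
    cats = rng.choice(["face", "house"], size=n_fix)
    tgts = rng.random(n_fix) < 0.4
    X = rng.standard_normal((n_fix, n_units)) * 0.5
    X += np.where(cats == "face", 1.0, -1.0)[:, None] * w_cat
    X += np.where(tgts, 1.0, -1.0)[:, None] * w_att
    return X, cats, tgts, w_cat, w_att


class TestHyperplaneAngle:
    def test_planted_orthogonal_codes_near_ninety(self):
        X, cats, tgts, _, _ = planted_rate_matrix(orthogonal=True)
        mask_a = ~tgts  # category trained on distractor fixations
        labels_b = np.where(tgts, "target", "distractor")
        pair = hyperplane_angle(X, cats, labels_b,
                                mask_a, np.ones(len(X), bool),
                                n_subsamples=20, n_shuffles=50,
                                rng=np.random.default_rng(0))
        assert 80.0 <= pair.angle <= 100.0
        assert 70.0 <= pair.null_angles.mean() <= 110.0

    def test_identical_label_schemes_small_angle(self):
        X, cats, tgts, _, _ = planted_rate_matrix(seed=1)
        mask = np.ones(len(X), bool)
        pair = hyperplane_angle(X, cats, cats, mask, mask,
                                n_subsamples=20, n_shuffles=10,
                                rng=np.random.default_rng(1))
        assert pair.angle < 10.0

    def test_random_labels_inside_own_null(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((300, 15))
        la = rng.choice(["face", "house"], size=300)
        lb = rng.choice(["target", "distractor"], size=300)
        mask = np.ones(300, bool)
        pair = hyperplane_angle(X, la, lb, mask, mask,
                                n_subsamples=10, n_shuffles=100,
                                rng=np.random.default_rng(2))
        lo, hi = np.percentile(pair.null_angles, [2.5, 97.5])
        assert lo <= pair.angle <= hi

    def test_invariance_to_unit_permutation_and_rate_scaling(self):
        X, cats, tgts, _, _ = planted_rate_matrix(n_fix=200, seed=3)
        mask = np.ones(len(X), bool)
        labels_b = np.where(tgts, "target", "distractor")

        def angle(M):
            return hyperplane_angle(M, cats, labels_b, mask, mask,
                                    n_subsamples=10, n_shuffles=2,
                                    rng=np.random.default_rng(3)).angle

        base = angle(X)
        perm = np.random.default_rng(3).permutation(X.shape[1])
        assert angle(X[:, perm]) == pytest.approx(base, abs=2.0)
        assert angle(3.0 * X) == pytest.approx(base, abs=2.0)

    def test_class_imbalance_reported(self):
        X = np.random.default_rng(4).standard_normal((20, 5))
        labels = np.array(["a"] * 19 + ["b"])
        mask = np.ones(20, bool)
        with pytest.raises(ValueError, match="imbalance"):
            hyperplane_angle(X, labels, labels, mask, mask, n_subsamples=2,
                             n_shuffles=1)


class TestRpcaAlign:
    def test_recovers_known_rotation_and_scale(self):
        rng = np.random.default_rng(5)
        ref = rng.standard_normal((8, 3))
        R = special_ortho_group.rvs(3, random_state=6)
        s = 2.5
        sub = (ref - ref.mean(0)) @ R / s  # rotated + shrunk layout
        out = rpca_align([sub], ref)
        assert out.residuals[0] < 1e-6
        assert out.scales[0] == pytest.approx(s, abs=1e-6)
        assert np.allclose(out.rotations[0], R.T, atol=1e-6) or out.residuals[0] < 1e-6

    def test_reference_aligns_to_itself_identity(self):
        ref = np.random.default_rng(7).standard_normal((6, 2))
        out = rpca_align([ref], ref)
        assert out.residuals[0] < 1e-12
        assert np.allclose(out.rotations[0], np.eye(2), atol=1e-9)
        assert out.scales[0] == pytest.approx(1.0)

    def test_reflection_disabled_flags_and_large_residual(self):
        rng = np.random.default_rng(8)
        ref = rng.standard_normal((10, 2))
        flipped = (ref - ref.mean(0)) @ np.diag([1.0, -1.0])
        out = rpca_align([flipped], ref, allow_reflection=False)
        assert out.reflection_needed[0]
        out2 = rpca_align([flipped], ref, allow_reflection=True)
        assert out2.residuals[0] < 1e-9
        assert out.residuals[0] > out2.residuals[0]

    def test_too_few_conditions_rejected(self):
        with pytest.raises(ValueError, match="3"):
            rpca_align([np.ones((2, 2))], np.ones((2, 2)))

    def test_residual_zero_iff_similarity_transform(self):
        rng = np.random.default_rng(9)
        ref = rng.standard_normal((7, 2))
        R = np.array([[0.0, -1.0], [1.0, 0.0]])
        sim = 0.5 * (ref - ref.mean(0)) @ R + 3.0
        assert rpca_align([sim], ref).residuals[0] < 1e-9
        warped = sim + rng.standard_normal(sim.shape)
        assert rpca_align([warped], ref).residuals[0] > 1e-3


class TestContextComparison:
    def test_planted_refixation_attenuation_detected(self, tuned_session):
        """V4/IT foveal units carry a planted 0.8 refixation gain."""
        ids = [u.unit_id for u in tuned_session.units
               if u.area in ("V4", "IT")
               and tuned_session.ground_truth.units[u.unit_id].rf_class
               in ("focal_foveal", "broad_foveal")]
        cc = context_comparison(tuned_session, ids, "refixation")
        assert cc.t_stat > 0  # first fixations stronger than refixations
        assert cc.p_value < 0.01

    def test_target_found_split_runs(self, tuned_session):
        ids = [u.unit_id for u in tuned_session.units
               if u.area in ("V4", "IT")
               and tuned_session.ground_truth.units[u.unit_id].rf_class
               in ("focal_foveal", "broad_foveal")]
        cc = context_comparison(tuned_session, ids, "target_found",
                                min_fixations=2)
        assert len(cc.unit_ids) >= 5
        assert np.isfinite(cc.p_value)

    def test_unknown_split_rejected(self, tuned_session):
        with pytest.raises(ValueError, match="split"):
            context_comparison(tuned_session,
                               [tuned_session.units[0].unit_id], "bogus")


class TestFixationRateTable:
    def test_shape_and_alignment(self, tuned_session):
        ids = [u.unit_id for u in tuned_session.units[:6]]
        rates, fixations, kept = fixation_rate_table(tuned_session, ids)
        assert rates.shape == (len(fixations), len(kept))
        assert np.all(np.isfinite(rates))
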