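import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

from covarkit.matrix_stats import (
    autonomy,
    compare_vrel,
    constraints,
    covariance_space_pca,
    draw_skewers,
    flexibility,
    integration_vrel,
    matrix_stats_report,
    mean_squared_correlation,
    pca_similarity,
    respondability,
    trait_coupling_table,
)
from covarkit.pmatrix import PMatrix
from conftest import naive_skewer_stats, random_psd

SK = 10_000


def pmat(m, n=100, label=""):
    m = np.asarray(m, dtype=float)
    names = [f"t{i}" for i in range(m.shape[0])]
    return PMatrix(m, names, n=n, df=n - 1, group_label=label)


def mc_se(values_spread, count=SK):
    return values_spread / np.sqrt(count)


class TestSkewerEnsemble:
    def test_unit_length_and_seed_reproducibility(self):
        a = draw_skewers(5, 1000, seed=3)
        b = draw_skewers(5, 1000, seed=3)
        assert np.allclose(np.linalg.norm(a.vectors, axis=1), 1.0, atol=1e-12)
        assert np.array_equal(a.vectors, b.vectors)


class TestClosedFormOracles:
    """Identity and 2x2 diagonal matrices have analytic skewer statistics."""

    def test_identity_matrix_statistics_are_exactly_one(self):
        sk = draw_skewers(7, 2000, seed=1)
        eye = np.eye(7)
        assert respondability(eye, sk) == pytest.approx(1.0, abs=1e-12)
        assert flexibility(eye, sk) == pytest.approx(1.0, abs=1e-12)
        assert autonomy(eye, sk) == pytest.approx(1.0, abs=1e-12)

    def test_respondability_diag_4_0_is_8_over_pi(self):
        # response norm = 4|cos(theta)|, mean over the circle = 8/pi
        sk = draw_skewers(2, SK, seed=2)
        P = np.diag([4.0, 0.0])
        vals = 4.0 * np.abs(sk.vectors[:, 0])
        se = vals.std(ddof=1) / np.sqrt(SK)
        assert abs(respondability(P, sk) - 8.0 / np.pi) < 3 * se

    def test_flexibility_rank_one_is_2_over_pi(self):
        sk = draw_skewers(2, SK, seed=3)
        P = np.diag([1.0, 0.0])
        vals = np.abs(sk.vectors[:, 0])
        se = vals.std(ddof=1) / np.sqrt(SK)
        assert abs(flexibility(P, sk) - 2.0 / np.pi) < 3 * se

    def test_constraints_rank_one_is_exactly_one(self, rng):
        v = rng.standard_normal(5)
        P = np.outer(v, v)
        sk = draw_skewers(5, 1000, seed=4)
        assert constraints(P, sk) == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("diag", [(2.0, 1.0), (4.0, 0.5)])
    def test_constraints_matches_circle_integral(self, diag):
        # response to beta = (cos t, sin t) is (a cos t, b sin t); PC1 = e1
        a, b = diag
        sk = draw_skewers(2, SK, seed=5)
        integrand = lambda t: abs(a * np.cos(t)) / np.hypot(a * np.cos(t), b * np.sin(t))
        expected = quad(integrand, 0, 2 * np.pi)[0] / (2 * np.pi)
        got = constraints(np.diag([a, b]), sk)
        theta = np.arctan2(sk.vectors[:, 1], sk.vectors[:, 0])
        vals = np.abs(a * np.cos(theta)) / np.hypot(a * np.cos(theta), b * np.sin(theta))
        se = vals.std(ddof=1) / np.sqrt(SK)
        assert abs(got - expected) < 3 * se

    def test_autonomy_matches_circle_integral_for_high_correlation(self):
        r = 0.9
        P = np.array([[1.0, r], [r, 1.0]])
        pinv = np.linalg.inv(P)

        def val(t):
            beta = np.array([np.cos(t), np.sin(t)])
            return 1.0 / (beta @ pinv @ beta) / (beta @ P @ beta)

        expected = quad(val, 0, 2 * np.pi)[0] / (2 * np.pi)
        sk = draw_skewers(2, SK, seed=6)
        got = autonomy(P, sk)
        theta = np.arctan2(sk.vectors[:, 1], sk.vectors[:, 0])
        vals = np.array([val(t) for t in theta[:2000]])
        se = vals.std(ddof=1) / np.sqrt(SK)
        assert abs(got - expected) < max(3 * se, 1e-3)


class TestBruteForceEquivalence:
    def test_skewer_statistics_match_naive_implementation(self, rng):
        """All four skewer statistics vs an independent naive loop on random matrices."""
        for k in range(3):
            P = random_psd(8, rng)
            sk = draw_skewers(8, SK, seed=100 + k)
            oracle = naive_skewer_stats(P, 6000, seed=200 + k)
            impl = {
                "respondability": respondability(P, sk),
                "flexibility": flexibility(P, sk),
                "autonomy": autonomy(P, sk),
                "constraints": constraints(P, sk),
            }
            for name, (mean, se_naive) in oracle.items():
                se = np.sqrt(se_naive**2 + (se_naive * np.sqrt(6000 / SK)) ** 2)
                assert abs(impl[name] - mean) < 3 * se, name

    def test_monte_carlo_convergence_on_18x18(self, rng):
        P = random_psd(18, rng)
        s1 = matrix_stats_report(pmat(P), draw_skewers(18, SK, seed=1))
        s2 = matrix_stats_report(pmat(P), draw_skewers(18, 2 * SK, seed=2))
        for name in ("respondability", "flexibility", "autonomy", "constraints"):
            assert abs(s1[name] - s2[name]) / abs(s2[name]) < 0.01


class TestScaleBehaviour:
    @pytest.mark.parametrize("c", [0.1, 3.0])
    def test_respondability_scales_linearly_others_invariant(self, rng, c):
        P = random_psd(5, rng)
        sk = draw_skewers(5, 2000, seed=9)
        assert respondability(c * P, sk) == pytest.approx(c * respondability(P, sk), rel=1e-10)
        assert flexibility(c * P, sk) == pytest.approx(flexibility(P, sk), rel=1e-10)
        assert autonomy(c * P, sk) == pytest.approx(autonomy(P, sk), rel=1e-8)
        assert constraints(c * P, sk) == pytest.approx(constraints(P, sk), rel=1e-10)
        assert mean_squared_correlation(c * P) == pytest.approx(
            mean_squared_correlation(P), abs=1e-12
        )
        assert integration_vrel(c * P) == pytest.approx(integration_vrel(P), abs=1e-12)
        assert pca_similarity(c * P, P) == pytest.approx(1.0, abs=1e-10)

    def test_skewer_statistics_invariant_under_joint_permutation(self, rng):
        # permuting the matrix and the skewer coordinates together changes nothing
        P = random_psd(6, rng)
        perm = np.array([3, 1, 5, 0, 2, 4])
        Pp = P[np.ix_(perm, perm)]
        sk = draw_skewers(6, 3000, seed=10)
        skp = type(sk)(vectors=sk.vectors[:, perm], seed=None)
        assert respondability(Pp, skp) == pytest.approx(respondability(P, sk), rel=1e-12)
        assert flexibility(Pp, skp) == pytest.approx(flexibility(P, sk), rel=1e-12)
        assert autonomy(Pp, skp) == pytest.approx(autonomy(P, sk), rel=1e-9)
        assert constraints(Pp, skp) == pytest.approx(constraints(P, sk), rel=1e-9)


class TestCorrelationStatistics:
    def test_mean_squared_correlation_identities(self, rng):
        assert mean_squared_correlation(np.diag([1.0, 2.0, 3.0])) == 0.0
        P = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert mean_squared_correlation(P) == pytest.approx(0.25, abs=1e-14)

    def test_mean_squared_correlation_matches_pairwise_loop(self, rng):
        P = random_psd(6, rng)
        c = P / np.sqrt(np.outer(np.diag(P), np.diag(P)))
        acc, pairs = 0.0, 0
        for i in range(6):
            for j in range(i + 1, 6):
                acc += c[i, j] ** 2
                pairs += 1
        assert mean_squared_correlation(P) == pytest.approx(acc / pairs, abs=1e-14)

    def test_vrel_identities(self):
        assert integration_vrel(np.eye(4)) == pytest.approx(0.0, abs=1e-14)
        ones = np.ones((3, 3))
        assert integration_vrel(ones + 1e-12 * np.eye(3)) == pytest.approx(1.0, abs=1e-9)
        for r in (0.2, 0.7):
            P = np.array([[1.0, r], [r, 1.0]])
            assert integration_vrel(P) == pytest.approx(r**2, abs=1e-12)

    def test_vrel_equals_mean_squared_correlation_in_any_dimension(self, rng):
        # tr(C^2) - d = 2 sum r_ij^2 makes the two definitions identical
        for d in (2, 5, 12):
            P = random_psd(d, rng)
            assert integration_vrel(P) == pytest.approx(
                mean_squared_correlation(P), abs=1e-12
            )

    def test_small_sample_correction_shrinks_toward_zero(self, rng):
        P = pmat(random_psd(5, rng), n=20)
        raw = integration_vrel(P)
        adj = integration_vrel(P, corrected=True)
        assert adj < raw

    def test_zero_variance_trait_named_in_error(self):
        P = np.diag([1.0, 0.0, 2.0])
        with pytest.raises(ValueError, match="zero-variance"):
            mean_squared_correlation(pmat(P))


class TestCompareVrel:
    def test_identical_matrices_give_zero_z_unit_p(self, rng):
        P = pmat(random_psd(4, rng), n=50)
        res = compare_vrel(P, P)
        assert res.z == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_strong_integration_difference_is_significant(self):
        lo = pmat(np.eye(6) + 0.05, n=200)
        r = 0.8
        hi_m = np.full((6, 6), r)
        np.fill_diagonal(hi_m, 1.0)
        hi = pmat(hi_m, n=200)
        res = compare_vrel(hi, lo)
        assert res.p_value < 1e-6 and res.z > 0

    def test_small_samples_rejected(self, rng):
        P = pmat(random_psd(3, rng), n=3)
        with pytest.raises(ValueError, match="n > 3"):
            compare_vrel(P, P)


class TestPcaSimilarity:
    def test_self_similarity_is_one(self, rng):
        for _ in range(20):
            P = pmat(random_psd(5, rng))
            assert pca_similarity(P, P) == pytest.approx(1.0, abs=1e-10)

    def test_disjoint_eigenspaces_give_zero(self):
        assert pca_similarity(np.diag([1.0, 0.0]), np.diag([0.0, 1.0])) == pytest.approx(
            0.0, abs=1e-14
        )

    def test_trait_name_mismatch_rejected(self, rng):
        A = pmat(random_psd(3, rng))
        B = PMatrix(random_psd(3, rng), ["x", "y", "z"], n=10, df=9)
        with pytest.raises(ValueError, match="trait"):
            pca_similarity(A, B)


class TestCovarianceSpacePca:
    def test_identical_matrices_coincide_in_score_space(self, rng):
        P = random_psd(4, rng)
        Q = random_psd(4, rng)
        mats = [pmat(P, label="a"), pmat(Q, label="b"), pmat(P, label="c")]
        res = covariance_space_pca(mats)
        assert np.allclose(res.scores.loc["a"], res.scores.loc["c"], atol=1e-10)

    def test_round_trip_reconstruction(self, rng):
        mats = [pmat(random_psd(5, rng), label=f"m{i}") for i in range(4)]
        res = covariance_space_pca(mats)
        iu = np.triu_indices(5)
        x = np.vstack([m.matrix[iu] for m in mats])
        assert np.allclose(res.reconstruct(), x, atol=1e-10)

    def test_explained_variance_sums_to_100(self, rng):
        mats = [pmat(random_psd(3, rng), label=f"m{i}") for i in range(3)]
        res = covariance_space_pca(mats)
        assert res.explained.sum() == pytest.approx(100.0)


class TestTraitCoupling:
    def test_hand_calculated_regressions(self):
        P = pmat([[1.0, 0.5], [0.5, 4.0]])
        table = trait_coupling_table(P).set_index(["trait_a", "trait_b"])
        assert table.loc[("t0", "t1"), "b_a_to_b"] == pytest.approx(0.5)
        assert table.loc[("t1", "t0"), "b_a_to_b"] == pytest.approx(0.125)
        assert table.loc[("t0", "t1"), "r2"] == pytest.approx(0.0625)

    def test_independent_traits_have_zero_coupling(self):
        table = trait_coupling_table(pmat(np.diag([1.0, 2.0, 3.0])))
        assert np.allclose(table["b_a_to_b"], 0.0)
        assert np.allclose(table["r2"], 0.0)

    @given(st.integers(0, 2**31 - 1))
    def test_r2_is_product_of_forward_and_backward_slopes(self, seed):
        P = random_psd(4, np.random.default_rng(seed))
        table = trait_coupling_table(pmat(P)).set_index(["trait_a", "trait_b"])
        for a in range(4):
            for b in range(4):
                if a == b:
                    continue
                fwd = table.loc[(f"t{a}", f"t{b}")]
                bwd = table.loc[(f"t{b}", f"t{a}")]
                assert fwd["r2"] == pytest.approx(fwd["b_a_to_b"] * bwd["b_a_to_b"], abs=1e-12)


class TestDegenerateInputs:
    def test_autonomy_rejects_singular_matrix_without_ridge(self):
        sk = draw_skewers(2, 500, seed=11)
        with pytest.raises(ValueError, match="singular"):
            autonomy(np.diag([1.0, 0.0]), sk)
        # ridge bending makes it computable
        val = autonomy(np.diag([1.0, 0.0]), sk, ridge=1e-6)
        assert 0.0 < val <= 1.0

    def test_constraints_rejects_tied_leading_eigenvalues(self):
        sk = draw_skewers(2, 500, seed=12)
        with pytest.raises(ValueError, match="tied"):
            constraints(np.eye(2), sk)

    def test_dimension_mismatch_rejected(self, rng):
        sk = draw_skewers(3, 100, seed=13)
        with pytest.raises(ValueError, match="dimension"):
            respondability(random_psd(4, rng), sk)
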