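"""LPSI / RLPSI coefficient math, selection intensity and index evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selindex import (
    EconomicWeights,
    RestrictionSpec,
    evaluate_index,
    index_values,
    lpsi_coefficients,
    mallard_D,
    net_merit_variance,
    restricted_coefficients,
    selection_intensity,
)
from conftest import random_psd_pair


class TestNetMeritVariance:
    def test_identity_covariance_is_squared_norm(self):
        assert net_merit_variance(np.eye(2), [3.0, 4.0]) == pytest.approx(25.0)

    def test_zero_weights_give_zero(self):
        assert net_merit_variance(np.eye(3), np.zeros(3)) == 0.0

    def test_matches_double_sum_oracle(self, rng):
        C, _ = random_psd_pair(rng, 5)
        w = rng.standard_normal(5)
        brute = sum(w[i] * C[i, j] * w[j] for i in range(5) for j in range(5))
        assert net_merit_variance(C, w) == pytest.approx(brute)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            net_merit_variance(np.eye(3), [1.0, 2.0])


class TestLpsiCoefficients:
    def test_p_equal_c_gives_b_equal_w(self, rng):
        C, _ = random_psd_pair(rng, 4)
        C += 0.1 * np.eye(4)
        w = rng.standard_normal(4)
        np.testing.assert_allclose(lpsi_coefficients(C, C, w), w, atol=1e-10)

    def test_single_trait_is_heritability_shrunk_weight(self):
        b = lpsi_coefficients(np.array([[2.0]]), np.array([[0.5]]), [4.0])
        assert b[0] == pytest.approx(0.5 / 2.0 * 4.0)

    def test_optimality_against_random_indices(self, rng):
        C, P = random_psd_pair(rng, 4)
        w = rng.standard_normal(4)
        b = lpsi_coefficients(P, C, w)
        sh = np.sqrt(w @ C @ w)

        def rho(a):
            return (w @ C @ a) / (sh * np.sqrt(a @ P @ a))

        best = rho(b)
        alts = rng.standard_normal((10_000, 4))
        rhos = (alts @ C @ w) / (sh * np.sqrt(np.einsum("ij,jk,ik->i", alts, P, alts)))
        assert best >= rhos.max() - 1e-10

    def test_singular_p_rejected_with_advice(self):
        P = np.zeros((2, 2))
        with pytest.raises(np.linalg.LinAlgError, match="positive definite"):
            lpsi_coefficients(P, np.eye(2), [1.0, 1.0])


class TestMallardD:
    def test_equal_gains_contrast(self):
        np.testing.assert_array_equal(mallard_D([1.0, 1.0]), [[1.0, -1.0]])

    def test_three_gain_pattern(self):
        D_t = mallard_D([2.0, 3.0, 5.0])
        np.testing.assert_array_equal(D_t, [[5.0, 0.0, -2.0], [0.0, 5.0, -3.0]])

    def test_single_gain_gives_empty_matrix(self):
        assert mallard_D([2.0]).shape == (0, 1)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-10, 10).filter(lambda v: abs(v) > 1e-3),
                    min_size=2, max_size=6))
    def test_d_transpose_annihilates_d(self, d):
        np.testing.assert_allclose(mallard_D(d) @ np.asarray(d), 0.0, atol=1e-9)


class TestRestrictedCoefficients:
    def test_empty_restriction_equals_lpsi_exactly(self, rng):
        C, P = random_psd_pair(rng, 4)
        w = rng.standard_normal(4)
        beta = lpsi_coefficients(P, C, w)
        model = restricted_coefficients(P, C, w, RestrictionSpec())
        np.testing.assert_array_equal(model.b, beta)
        assert model.scenario == "LPSI"

    def test_null_restriction_zeroes_genetic_covariance_with_index(self, rng):
        C, P = random_psd_pair(rng, 4)
        w = rng.standard_normal(4)
        r = RestrictionSpec(restricted=("trait_2",))
        model = restricted_coefficients(P, C, w, r)
        assert abs((C @ model.b)[1]) < 1e-8

    def test_projector_idempotent(self, rng):
        for _ in range(10):
            C, P = random_psd_pair(rng, 5)
            w = rng.standard_normal(5)
            r = RestrictionSpec(restricted=("trait_1", "trait_4"))
            U_t = r.u_transpose([f"trait_{i+1}" for i in range(5)])
            M = (U_t @ C).T
            Pinv = np.linalg.inv(P)
            Q = Pinv @ M @ np.linalg.inv(M.T @ Pinv @ M) @ M.T
            K = np.eye(5) - Q
            np.testing.assert_allclose(Q @ Q, Q, atol=1e-8)
            np.testing.assert_allclose(K @ K, K, atol=1e-8)
            # package coefficients live in the K-projected space
            model = restricted_coefficients(P, C, w, r)
            np.testing.assert_allclose(K @ model.b, model.b, atol=1e-8)

    def test_redundant_restrictions_rejected(self, rng):
        _, P = random_psd_pair(rng, 4)
        C = np.ones((4, 4))  # rank one: two restriction rows collinear
        r = RestrictionSpec(restricted=("trait_1", "trait_2"))
        with pytest.raises(ValueError, match="rank deficient"):
            restricted_coefficients(P, C, [1.0, 1.0, 1.0, 1.0], r)

    def test_proportional_mode_enforces_gain_ratios(self, rng):
        C, P = random_psd_pair(rng, 5)
        w = rng.standard_normal(5)
        d = (2.0, 3.0)
        r = RestrictionSpec(restricted=("trait_1", "trait_3"),
                            mode="proportional", d=d)
        model = restricted_coefficients(P, C, w, r)
        gains = C @ model.b
        # restricted gains proportional to d: cross ratio vanishes
        assert d[1] * gains[0] - d[0] * gains[2] == pytest.approx(0.0, abs=1e-8)


class TestIndexValues:
    def test_unit_coefficient_recovers_trait_column(self, rng):
        frame = pd.DataFrame(rng.standard_normal((6, 3)),
                             columns=["x", "y", "z"],
                             index=[f"G{i}" for i in range(6)])
        from selindex.indices import IndexModel

        model = IndexModel(scenario="LPSI", b=np.array([0.0, 1.0, 0.0]),
                           trait_names=("x", "y", "z"), C=np.eye(3),
                           P=np.eye(3), w=np.ones(3))
        np.testing.assert_array_equal(index_values(model, frame).to_numpy(),
                                      frame["y"].to_numpy())

    def test_matches_brute_force_dot_products(self, rng):
        frame = pd.DataFrame(rng.standard_normal((5, 4)),
                             columns=[f"t{i}" for i in range(4)])
        from selindex.indices import IndexModel

        b = rng.standard_normal(4)
        model = IndexModel(scenario="LPSI", b=b,
                           trait_names=tuple(frame.columns), C=np.eye(4),
                           P=np.eye(4), w=np.ones(4))
        scores = index_values(model, frame)
        for i in range(5):
            assert scores.iloc[i] == pytest.approx(
                sum(b[j] * frame.iloc[i, j] for j in range(4)))

    def test_missing_trait_column_rejected(self, rng):
        from selindex.indices import IndexModel

        model = IndexModel(scenario="LPSI", b=np.ones(2),
                           trait_names=("x", "missing"), C=np.eye(2),
                           P=np.eye(2), w=np.ones(2))
        frame = pd.DataFrame({"x": [1.0]})
        with pytest.raises(ValueError, match="missing"):
            index_values(model, frame)


class TestSelectionIntensity:
    def test_weak_selection_tends_to_zero(self):
        assert selection_intensity(0.999) < 0.01

    def test_half_selected_closed_form(self):
        from scipy.stats import norm

        assert selection_intensity(0.5) == pytest.approx(2 * norm.pdf(0.0))
        assert selection_intensity(0.5) == pytest.approx(0.7979, abs=1e-4)

    def test_ten_percent_value(self):
        assert selection_intensity(0.10) == pytest.approx(1.755, abs=1e-3)

    def test_finite_population_is_smaller(self):
        assert selection_intensity(0.10, n=196) < selection_intensity(0.10)

    def test_invalid_fraction_rejected(self):
        for p in (0.0, 1.0, -0.1, 2.0):
            with pytest.raises(ValueError):
                selection_intensity(p)


class TestEvaluateIndex:
    def test_single_trait_reduces_to_breeders_equation(self):
        s2_g, s2_p, k = 0.6, 1.5, 1.755
        model = restricted_coefficients(np.array([[s2_p]]), np.array([[s2_g]]),
                                        [1.0])
        ev = evaluate_index(model, k)
        h2 = s2_g / s2_p
        assert ev.expected_gain.iloc[0] == pytest.approx(k * h2 * np.sqrt(s2_p))

    def test_unrestricted_response_is_k_sigma_i(self, rng):
        C, P = random_psd_pair(rng, 4)
        w = rng.standard_normal(4)
        model = restricted_coefficients(P, C, w)
        ev = evaluate_index(model, k=1.4)
        assert ev.response == pytest.approx(1.4 * ev.sigma_i)

    def test_null_restricted_gain_entries_are_zero(self, rng):
        C, P = random_psd_pair(rng, 4)
        w = rng.standard_normal(4)
        r = RestrictionSpec(restricted=("trait_3",))
        ev = evaluate_index(restricted_coefficients(P, C, w, r), k=1.755)
        assert abs(ev.expected_gain["trait_3"]) < 1e-8

    def test_restriction_cannot_improve_correlation(self, rng):
        for _ in range(20):
            C, P = random_psd_pair(rng, 4)
            w = rng.standard_normal(4)
            free = evaluate_index(restricted_coefficients(P, C, w), k=1.0)
            restr = evaluate_index(
                restricted_coefficients(P, C, w,
                                        RestrictionSpec(restricted=("trait_1",))),
                k=1.0)
            assert restr.rho_hi <= free.rho_hi + 1e-10

    @settings(derandomize=True, max_examples=30)
    @given(scale=st.floats(0.1, 50), seed=st.integers(0, 10_000))
    def test_scale_equivariance_in_weights(self, scale, seed):
        rng = np.random.default_rng(seed)
        C, P = random_psd_pair(rng, 3)
        w = rng.standard_normal(3)
        k = 1.4
        base = evaluate_index(restricted_coefficients(P, C, w), k)
        scaled = evaluate_index(restricted_coefficients(P, C, scale * w), k)
        assert scaled.sigma_h == pytest.approx(scale * base.sigma_h, rel=1e-9)
        assert scaled.sigma_i == pytest.approx(scale * base.sigma_i, rel=1e-9)
        assert scaled.response == pytest.approx(scale * base.response, rel=1e-9)
        assert scaled.rho_hi == pytest.approx(base.rho_hi, rel=1e-9)
        np.testing.assert_allclose(scaled.expected_gain, base.expected_gain,
                                   rtol=1e-8)

    def test_zero_variance_index_rejected(self):
        from selindex.indices import IndexModel

        model = IndexModel(scenario="LPSI", b=np.zeros(2),
                           trait_names=("a", "b"), C=np.eye(2), P=np.eye(2),
                           w=np.array([1.0, 0.0]))
        with pytest.raises(ValueError, match="zero-variance"):
            evaluate_index(model, k=1.0)


class TestEconomicWeights:
    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            EconomicWeights(values=(0.0, 0.0))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            EconomicWeights(values=(1.0, np.nan))
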