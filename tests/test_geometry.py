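"""Feasibility-domain geometry: equilibrium, feasibility, centroid,
angular distance."""

import numpy as np
import pytest

import metacoex as mx

A22 = np.array([[1.0, 2.0], [2.0, 1.0]])


class TestEquilibrium:
    def test_identity_matrix(self):
        np.testing.assert_allclose(mx.equilibrium(np.eye(2), [1.0, 1.0]), [1.0, 1.0])

    @pytest.mark.parametrize("K, expected", [
        ([1.0, 1.0], [1.0 / 3.0, 1.0 / 3.0]),
        ([1.0, 5.0], [3.0, -1.0]),
    ])
    def test_two_by_two_by_hand(self, K, expected):
        np.testing.assert_allclose(mx.equilibrium(A22, K), expected, rtol=1e-12)

    def test_singular_matrix_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            mx.equilibrium(np.ones((2, 2)), [1.0, 1.0])

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            mx.equilibrium(A22, [1.0, 2.0, 3.0])


class TestFeasibility:
    def test_interior_and_exterior_directions(self):
        assert mx.is_feasible(A22, [1.0, 1.0])
        assert not mx.is_feasible(A22, [1.0, 5.0])

    def test_column_of_A_is_boundary(self, random_community):
        """K equal to a spanning column solves to a unit basis vector:
        on the cone boundary, not strictly interior."""
        A = random_community.A
        status = mx.feasibility_status(A, A[:, 2])
        assert status in ("boundary", "infeasible")
        N = mx.equilibrium(A, A[:, 2])
        expected = np.zeros(random_community.S)
        expected[2] = 1.0
        np.testing.assert_allclose(N, expected, atol=1e-10)

    def test_scale_invariance(self, random_community):
        A = random_community.A
        K = mx.metabolic_K_vector(random_community.masses, 0.25)
        for lam in (1e-6, 1.0, 1e6):
            assert mx.is_feasible(A, lam * K) == mx.is_feasible(A, K)

    def test_two_species_angular_oracle(self, rng):
        """For S=2 the feasibility cone is the angular sector between the
        two column directions; the linear-solve test must agree with the
        direct angle comparison for random K directions."""
        comm = mx.build_interaction_matrix([1.0, 16.0])
        A = comm.A
        th1 = np.arctan2(A[1, 0], A[0, 0])
        th2 = np.arctan2(A[1, 1], A[0, 1])
        lo, hi = min(th1, th2), max(th1, th2)
        for _ in range(200):
            K = np.abs(rng.standard_normal(2)) + 1e-9
            theta = np.arctan2(K[1], K[0])
            assert mx.is_feasible(A, K) == bool(lo < theta < hi)


class TestCentroid:
    def test_identity_matrix_centroid(self):
        np.testing.assert_allclose(mx.centroid(np.eye(2)), [0.5, 0.5])

    def test_two_species_worked_example(self, two_species):
        np.testing.assert_allclose(
            mx.centroid(two_species.A), [0.676777, 1.207107], atol=1e-6)

    def test_equilibrium_at_centroid_is_uniform(self, random_community):
        A = random_community.A
        N = mx.equilibrium(A, mx.centroid(A))
        np.testing.assert_allclose(N, 1.0 / random_community.S, rtol=1e-12)
        assert N.max() - N.min() < 1e-10

    def test_equal_biomass_constant_is_one_over_S(self, random_community):
        assert mx.equal_biomass_constant(random_community.A) == pytest.approx(
            1.0 / random_community.S, rel=1e-12)
        assert mx.equal_biomass_constant(A22) == pytest.approx(0.5)

    def test_normalized_variant_differs_for_asymmetric_matrix(self, two_species):
        raw = mx.centroid(two_species.A)
        normed = mx.centroid(two_species.A, normalize=True)
        assert not np.allclose(raw / np.linalg.norm(raw),
                               normed / np.linalg.norm(normed))


class TestAngularDistance:
    def test_collinear_is_zero(self):
        assert mx.angular_distance([2.0, 4.0], [1.0, 2.0]) == 0.0

    def test_unit_axes_45_degrees(self):
        assert mx.angular_distance([1.0, 0.0], [1.0, 1.0]) == pytest.approx(45.0)

    def test_two_species_worked_example(self, two_species):
        d = mx.angular_distance(
            mx.metabolic_K_vector(two_species.masses, 0.25),
            mx.centroid(two_species.A))
        assert d == pytest.approx(2.7126, abs=1e-3)

    def test_bounds_on_random_positive_pairs(self, rng):
        for _ in range(1000):
            S = rng.integers(2, 20)
            u = np.abs(rng.standard_normal(S)) + 1e-12
            v = np.abs(rng.standard_normal(S)) + 1e-12
            d = mx.angular_distance(u, v)
            assert 0.0 <= d <= 90.0

    def test_scale_invariance(self, rng):
        u = np.abs(rng.standard_normal(5)) + 0.1
        v = np.abs(rng.standard_normal(5)) + 0.1
        d = mx.angular_distance(u, v)
        for lam in (1e-6, 1.0, 1e6):
            assert mx.angular_distance(lam * u, v) == pytest.approx(d, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            mx.angular_distance([0.0, 0.0], [1.0, 1.0])


class TestAssessAndSampling:
    def test_assess_bundles_all_quantities(self, two_species):
        result = mx.assess(two_species.A, mx.centroid(two_species.A))
        assert result.feasible
        assert result.distance_deg == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(result.N_star, 0.5, rtol=1e-12)

    def test_identity_cone_is_whole_orthant(self, rng):
        _, labels = mx.sample_feasible_directions(np.eye(4), 50, rng)
        assert labels.all()

    def test_centroid_direction_feasible(self, random_community, rng):
        A = random_community.A
        assert mx.is_feasible(A, mx.centroid(A))

    def test_negated_column_infeasible(self, random_community):
        A = random_community.A
        assert not mx.is_feasible(A, -A[:, 0])

    def test_feasible_labels_verified_by_solve(self, random_community, rng):
        directions, labels = mx.sample_feasible_directions(
            random_community.A, 100, rng)
        for d, lab in zip(directions, labels):
            N = mx.equilibrium(random_community.A, d)
            assert lab == bool(np.min(N) > 0)
            if lab:  # feasible direction = positive combination of columns
                np.testing.assert_allclose(random_community.A @ N, d, atol=1e-10)

    def test_stronger_a0_shrinks_feasible_fraction(self, rng):
        """Raising a0 intensifies competition and narrows the cone: the
        Monte-Carlo feasible fraction must not increase."""
        masses = rng.lognormal(0, 2, size=6)
        weak = mx.build_interaction_matrix(masses, a0_rule=0.2).A
        strong = mx.build_interaction_matrix(masses, a0_rule=0.8).A
        rng_a, rng_b = np.random.default_rng(5), np.random.default_rng(5)
        _, lw = mx.sample_feasible_directions(weak, 400, rng_a)
        _, ls = mx.sample_feasible_directions(strong, 400, rng_b)
        assert ls.mean() <= lw.mean()
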