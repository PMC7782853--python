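import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.spatial.distance import canberra as scipy_canberra

from tknet.glv import (
    GLVModel,
    canberra,
    klemm_eguiluz_adjacency,
    make_hub_model,
    pool_size_for_similarity,
    random_glv_model,
    sample_community,
    sample_interaction_matrix,
    scale_keystoneness,
    simulate_to_steady_state,
    true_keystoneness,
)


class TestInteractionMatrix:
    def test_zero_connectivity_gives_empty_matrix(self, rng):
        A = sample_interaction_matrix(20, 0.0, 50.0, rng=rng)
        assert np.all(A == 0)

    def test_full_negative_percentage(self, rng):
        A = sample_interaction_matrix(30, 0.5, 100.0, rng=rng, strength=0.1)
        off = A[~np.eye(30, dtype=bool)]
        assert np.all(off[off != 0] < 0)

    def test_realized_connectivity_tracks_target(self, rng):
        for topology in ("uniform", "klemm_eguiluz"):
            A = sample_interaction_matrix(80, 0.2, 50.0, topology, rng, strength=0.1)
            realized = np.count_nonzero(A[~np.eye(80, dtype=bool)]) / (80 * 79)
            assert realized == pytest.approx(0.2, abs=0.08)

    def test_diagonal_always_zero(self, rng):
        A = sample_interaction_matrix(25, 0.6, 30.0, rng=rng)
        assert np.all(np.diag(A) == 0)

    def test_klemm_eguiluz_has_heavier_degree_tail(self):
        # scale-free generators concentrate degree on hubs
        ratios = {"uniform": [], "klemm_eguiluz": []}
        for seed in range(6):
            rng = np.random.default_rng(seed)
            for topology in ratios:
                A = sample_interaction_matrix(100, 0.05, 0.0, topology, rng, strength=0.1)
                deg = (A != 0).sum(axis=1)
                ratios[topology].append(deg.max() / max(deg.mean(), 1e-9))
        assert np.mean(ratios["klemm_eguiluz"]) > np.mean(ratios["uniform"])

    def test_klemm_eguiluz_adjacency_is_symmetric(self, rng):
        adj = klemm_eguiluz_adjacency(40, 3, 0.1, rng)
        assert np.array_equal(adj, adj.T)
        assert not adj.diagonal().any()


class TestSteadyState:
    def test_single_species_logistic_fixed_point(self):
        x, ok, bad = simulate_to_steady_state(
            np.array([1.0]), np.array([10.0]), np.zeros((1, 1)), np.array([1.0]), tol=1e-8
        )
        assert ok and not bad
        assert x[0] == pytest.approx(10.0, rel=1e-4)

    def test_two_species_interior_equilibrium_closed_form(self):
        r = np.array([0.5, 0.8])
        K = np.array([10.0, 20.0])
        A = np.array([[0.0, -0.01], [-0.02, 0.0]])
        x, ok, bad = simulate_to_steady_state(r, K, A, np.array([1.0, 1.0]), tol=1e-8)
        # interior equilibrium solves r_i(1 - x_i/K_i) + sum_j A_ij x_j = 0
        want = np.linalg.solve(np.diag(r / K) - A, r)
        assert ok
        np.testing.assert_allclose(x, want, rtol=1e-3)

    def test_zero_state_is_absorbing(self):
        x, ok, bad = simulate_to_steady_state(
            np.array([0.9, 0.9]), np.array([5.0, 5.0]), np.zeros((2, 2)), np.array([0.0, 0.0])
        )
        assert ok and np.all(x == 0.0)

    def test_matches_adaptive_ode_solver_on_random_community(self, rng):
        S = 6
        r = rng.uniform(0.3, 1.0, S)
        K = rng.uniform(5.0, 50.0, S)
        A = sample_interaction_matrix(S, 0.4, 70.0, rng=rng, strength=0.01)
        x0 = rng.uniform(0.5, 1.0, S) * K

        def f(t, x):
            return x * (r * (1 - x / K) + A @ x)

        ours, ok, bad = simulate_to_steady_state(r, K, A, x0, tol=1e-7)
        ref = solve_ivp(f, (0.0, 2000.0), x0, rtol=1e-10, atol=1e-12).y[:, -1]
        assert ok and not bad
        np.testing.assert_allclose(ours, ref, rtol=1e-3, atol=1e-3)

    def test_batch_columns_are_independent(self, rng):
        r, K = np.array([0.5, 0.7]), np.array([10.0, 15.0])
        A = np.array([[0.0, -0.005], [-0.01, 0.0]])
        X0 = rng.uniform(0.5, 5.0, size=(2, 7))
        batch, ok, bad = simulate_to_steady_state(r, K, A, X0)
        for j in range(7):
            single, _, _ = simulate_to_steady_state(r, K, A, X0[:, j])
            np.testing.assert_allclose(batch[:, j], single, rtol=1e-6)

    def test_negative_initial_state_rejected(self):
        with pytest.raises(ValueError):
            simulate_to_steady_state(
                np.array([1.0]), np.array([1.0]), np.zeros((1, 1)), np.array([-0.1])
            )


class TestCommunitySampling:
    def test_pool_size_formula(self):
        assert pool_size_for_similarity(20, 1.0) == 20  # identical sets at the limit
        assert pool_size_for_similarity(20, 0.5) == 30

    def test_expected_jaccard_overlap_near_target(self, rng):
        n, s = 20, 0.5
        P = pool_size_for_similarity(n, s)
        overlaps = []
        for _ in range(200):
            a = set(rng.choice(P, n, replace=False))
            b = set(rng.choice(P, n, replace=False))
            overlaps.append(len(a & b) / len(a | b))
        assert np.mean(overlaps) == pytest.approx(s, abs=0.1)

    def test_same_seed_identical_sample(self):
        model, n = random_glv_model(np.random.default_rng(3))
        s1 = sample_community(model, n, np.random.default_rng(9))
        s2 = sample_community(model, n, np.random.default_rng(9))
        np.testing.assert_array_equal(s1.species_idx, s2.species_idx)
        np.testing.assert_allclose(s1.abundance, s2.abundance)


class TestCanberra:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 0], [2, 2, 0], 1.0 / 3.0),
            ([3, 1, 4], [3, 1, 4], 0.0),
            ([1, 0], [0, 1], 2.0),
        ],
    )
    def test_known_values(self, x, y, expected):
        assert canberra(x, y) == pytest.approx(expected)

    def test_matches_scipy_on_positive_vectors(self, rng):
        for _ in range(20):
            x, y = rng.random(10) + 0.1, rng.random(10) + 0.1
            assert canberra(x, y) == pytest.approx(scipy_canberra(x, y))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            canberra([1, 2], [1, 2, 3])


class TestKeystoneness:
    def test_isolated_zero_species_has_zero_keystoneness(self):
        # no interactions: unique attractor, removal of an extinct species
        # changes nothing
        S = 4
        model = GLVModel(r=np.full(S, 0.8), K=np.full(S, 10.0), A=np.zeros((S, S)))
        sample = sample_community(model, S, np.random.default_rng(0))
        sample.abundance[2] = 0.0  # treat species 2 as extinct
        recs = true_keystoneness(model, sample, n_iter=5, rng=np.random.default_rng(1))
        by_id = {r.species_id: r for r in recs}
        assert by_id[2].keystoneness == pytest.approx(0.0, abs=1e-3)

    def test_seed_determinism(self):
        model, n = random_glv_model(np.random.default_rng(5), n_species=12)
        sample = sample_community(model, n, np.random.default_rng(5))
        r1 = true_keystoneness(model, sample, n_iter=3, rng=np.random.default_rng(2))
        r2 = true_keystoneness(model, sample, n_iter=3, rng=np.random.default_rng(2))
        np.testing.assert_allclose(
            [r.keystoneness for r in r1], [r.keystoneness for r in r2]
        )

    def test_engineered_hub_dominates_its_community(self):
        hits = 0
        for seed in range(10):
            model = make_hub_model(S=12, rng=np.random.default_rng(seed))
            sample = sample_community(model, 12, np.random.default_rng(seed))
            recs = true_keystoneness(model, sample, n_iter=10, rng=np.random.default_rng(seed))
            scores = {r.species_id: r.keystoneness for r in recs}
            hits += max(scores, key=scores.get) == 0
        assert hits >= 9

    def test_scaling_into_unit_interval(self):
        model = make_hub_model(S=10, rng=np.random.default_rng(4))
        sample = sample_community(model, 10, np.random.default_rng(4))
        recs = scale_keystoneness(
            true_keystoneness(model, sample, n_iter=5, rng=np.random.default_rng(4))
        )
        scaled = [r.scaled_keystoneness for r in recs]
        assert min(scaled) == pytest.approx(0.0)
        assert max(scaled) == pytest.approx(1.0)
        raw_order = np.argsort([r.keystoneness for r in recs])
        np.testing.assert_array_equal(raw_order, np.argsort(scaled))

    def test_converged_states_satisfy_fixed_point_criterion(self):
        model, n = random_glv_model(np.random.default_rng(8), n_species=15)
        sample = sample_community(model, n, np.random.default_rng(8))
        idx = sample.species_idx
        r, K, A = model.r[idx], model.K[idx], model.A[np.ix_(idx, idx)]
        x = sample.abundance
        drift = x * (r * (1 - x / K) + A @ x)
        assert np.abs(drift).max() < 1e-4 * max(x.max(), 1e-8)


class TestRandomModelRanges:
    def test_parameters_within_study_ranges(self):
        for seed in range(10):
            model, n = random_glv_model(np.random.default_rng(seed))
            assert 10 <= n <= 100
            assert 0.005 <= model.connectivity <= 0.7
            assert 0 <= model.neg_pct <= 100
            assert 0.4 <= model.pool_similarity <= 0.95
            assert np.all((model.r > 0) & (model.r <= 1.0))
            assert np.all((model.K > 0) & (model.K <= 100.0))
            assert model.topology in ("uniform", "klemm_eguiluz")
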