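import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from radpipe.gan import (
    EdgePosteriorModel,
    build_network,
    dynamical_correlation,
    first_neighborhood,
    fit_edge_posteriors,
    partial_correlations,
    reconstruct_network,
    shrink_correlation,
    trapezoid_weights,
)
from radpipe.synthetic import SimulationConfig, gen_network_timeseries


class TestTrapezoidWeights:
    def test_equally_spaced_formula(self):
        np.testing.assert_allclose(
            trapezoid_weights([1.0, 2.0, 3.0, 4.0]), [1 / 6, 2 / 6, 2 / 6, 1 / 6]
        )

    def test_two_points(self):
        np.testing.assert_allclose(trapezoid_weights([0.0, 5.0]), [0.5, 0.5])

    def test_study_grid_normalized_positive(self):
        w = trapezoid_weights([0.25, 2, 7, 12, 24, 48, 72, 96])
        assert w.sum() == pytest.approx(1.0)
        assert np.all(w > 0)

    def test_duplicate_times_raise(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            trapezoid_weights([1.0, 1.0, 2.0])


class TestDynamicalCorrelation:
    def test_self_correlation_one_and_negation_minus_one(self):
        times = [1.0, 2.0, 4.0, 8.0]
        traj = pd.DataFrame(
            [[1.0, 3.0, 2.0, 5.0], [-1.0, -3.0, -2.0, -5.0]],
            index=["g", "neg"],
            columns=times,
        )
        R = dynamical_correlation(traj)
        assert R.loc["g", "g"] == pytest.approx(1.0)
        assert R.loc["g", "neg"] == pytest.approx(-1.0)

    def test_matches_hand_weighted_formula(self):
        times = np.array([1.0, 2.0, 4.0, 8.0])
        w = trapezoid_weights(times)
        vals = np.array(
            [[0.1, 0.9, 0.4, 0.7], [1.0, 0.2, 0.5, 0.3], [0.6, 0.6, 0.1, 0.8]]
        )
        traj = pd.DataFrame(vals, index=["a", "b", "c"], columns=times)
        R = dynamical_correlation(traj)
        # spreadsheet-style direct evaluation
        for i, j in itertools.combinations(range(3), 2):
            xi = vals[i] - np.sum(w * vals[i])
            xj = vals[j] - np.sum(w * vals[j])
            r = np.sum(w * xi * xj) / np.sqrt(np.sum(w * xi**2) * np.sum(w * xj**2))
            assert R.iloc[i, j] == pytest.approx(r, abs=1e-12)

    def test_zero_variance_gene_warns_and_zeroes(self):
        times = [1.0, 2.0, 3.0]
        traj = pd.DataFrame(
            [[1.0, 1.0, 1.0], [0.2, 0.5, 0.9]], index=["flat", "g"], columns=times
        )
        with pytest.warns(UserWarning, match="zero weighted variance"):
            R = dynamical_correlation(traj)
        assert R.loc["flat", "g"] == 0.0


class TestShrinkage:
    def brute_force_lambda(self, X):
        """Direct evaluation of the variance/sum-of-squares ratio."""
        n, p = X.shape
        w = np.full(n, 1.0 / n)
        sw = np.sum(w**2)
        m = X.mean(axis=0)
        v = ((X - m) ** 2).mean(axis=0)
        Xs = (X - m) / np.sqrt(v)
        num = den = 0.0
        for i in range(p):
            for j in range(p):
                if i == j:
                    continue
                c = Xs[:, i] * Xs[:, j]
                r = np.sum(w * c)
                var_hat = sw / (1 - sw) * np.sum(w * (c - r) ** 2)
                num += var_hat
                den += r**2
        return min(1.0, num / den)

    def test_lambda_matches_brute_force(self, rng):
        X = rng.normal(size=(20, 5))
        R_star, lam = shrink_correlation(X)
        assert lam == pytest.approx(self.brute_force_lambda(X), abs=1e-10)

    def test_full_shrinkage_gives_identity_and_zero_pcors(self):
        # lambda* = 1 -> R* = I -> downstream partial correlations all 0
        P = partial_correlations(np.eye(4))
        np.testing.assert_allclose(P[~np.eye(4, dtype=bool)], 0.0, atol=1e-12)

    def test_all_zero_offdiagonals_fully_shrunk(self):
        # perfectly uncorrelated columns by construction
        X = np.array([[1.0, 1.0], [-1.0, 1.0], [1.0, -1.0], [-1.0, -1.0]])
        _, lam = shrink_correlation(X)
        assert lam == 1.0

    def test_lambda_interpolates(self, rng):
        X = rng.normal(size=(30, 6))
        R_star, lam = shrink_correlation(X)
        assert 0.0 <= lam <= 1.0
        # off-diagonals shrunk by exactly (1 - lambda)
        Xs = (X - X.mean(0)) / X.std(0)
        R_emp = (Xs.T @ Xs) / len(X)
        off = ~np.eye(6, dtype=bool)
        np.testing.assert_allclose(R_star[off], (1 - lam) * R_emp[off], atol=1e-10)


class TestPartialCorrelations:
    def test_two_genes_pcor_equals_correlation(self):
        R = np.array([[1.0, 0.6], [0.6, 1.0]])
        P = partial_correlations(R)
        assert P[0, 1] == pytest.approx(0.6)

    def test_identity_gives_zero(self):
        P = partial_correlations(np.eye(5))
        assert np.allclose(P[~np.eye(5, dtype=bool)], 0.0)

    def test_chain_partial_vanishes_while_marginal_does_not(self):
        omega = np.array([[1.0, -0.5, 0.0], [-0.5, 1.0, -0.5], [0.0, -0.5, 1.0]])
        sigma = np.linalg.inv(omega)
        d = np.sqrt(np.diag(sigma))
        R = sigma / np.outer(d, d)
        P = partial_correlations(R)
        assert abs(R[0, 2]) > 0.1
        assert P[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert P[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_regression_residual_oracle(self, rng):
        """pcor(i,j) equals the correlation of residuals after regressing
        both variables on all remaining ones."""
        X = rng.normal(size=(200, 5))
        X[:, 1] += 0.5 * X[:, 0]
        Xs = (X - X.mean(0)) / X.std(0)
        R = (Xs.T @ Xs) / len(X)
        P = partial_correlations(R)
        for i, j in [(0, 1), (2, 4)]:
            others = [k for k in range(5) if k not in (i, j)]
            Z = np.column_stack([np.ones(len(X)), X[:, others]])
            ri = X[:, i] - Z @ np.linalg.lstsq(Z, X[:, i], rcond=None)[0]
            rj = X[:, j] - Z @ np.linalg.lstsq(Z, X[:, j], rcond=None)[0]
            oracle = np.corrcoef(ri, rj)[0, 1]
            assert P[i, j] == pytest.approx(oracle, abs=1e-10)

    def test_round_trip_through_inverse_map(self, rng):
        """partial_to_correlation inverts partial_correlations exactly."""
        from radpipe.gan import partial_to_correlation

        A = rng.normal(size=(6, 6))
        R = A @ A.T + 6 * np.eye(6)
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        np.testing.assert_allclose(
            partial_to_correlation(partial_correlations(R)), R, atol=1e-10
        )


class TestEdgePosteriors:
    def test_null_density_normalizes(self):
        m = EdgePosteriorModel(eta0=1.0, kappa=20.0)
        grid = np.linspace(-1, 1, 20001)
        assert np.trapezoid(m.null_density(grid), grid) == pytest.approx(1.0, abs=1e-4)

    def test_posterior_even_and_monotone_in_magnitude(self):
        m = EdgePosteriorModel(eta0=0.8, kappa=30.0)
        p = np.linspace(0, 0.99, 100)
        post = m.posterior(p)
        np.testing.assert_allclose(m.posterior(-p), post, atol=1e-12)
        assert np.all(np.diff(post) >= -1e-12)

    def test_zero_pcor_has_minimal_posterior(self):
        m = EdgePosteriorModel(eta0=0.9, kappa=25.0)
        grid = np.linspace(-0.99, 0.99, 999)
        assert m.posterior(0.0) == pytest.approx(m.posterior(grid).min())

    def test_mixture_recovery_simulation(self, rng):
        kappa = 50.0
        n = 5050  # number of off-diagonal pairs of a 101-node matrix
        null = 2.0 * rng.beta((kappa - 1) / 2, (kappa - 1) / 2, int(0.8 * n)) - 1.0
        alt = rng.uniform(-1, 1, n - len(null))
        p = np.concatenate([null, alt])
        P = np.eye(101)  # wrap the draws into a symmetric matrix
        iu = np.triu_indices(101, k=1)
        P[iu] = p[: len(iu[0])]
        P = P + P.T - np.diag(np.diag(P))
        model = fit_edge_posteriors(P)
        assert 0.7 <= model.eta0 <= 0.9
        assert 35.0 <= model.kappa <= 70.0


class TestNetworkConstruction:
    def test_threshold_above_max_gives_isolated_nodes(self, rng):
        P = pd.DataFrame(np.eye(4) * 1.0, index=list("abcd"), columns=list("abcd"))
        P.iloc[0, 1] = P.iloc[1, 0] = 0.4
        model = EdgePosteriorModel(eta0=0.5, kappa=10.0)
        G = build_network(P, model, threshold=1.1)
        assert G.number_of_edges() == 0
        assert all(G.nodes[n]["isolated"] for n in G)

    def test_edge_list_invariant_to_gene_relabeling(self):
        cfg = SimulationConfig(network_n_nodes=30, network_n_edges=15, seed=6)
        expr, _ = gen_network_timeseries(cfg, n_samples=120)
        G1, P1, _, m1 = reconstruct_network(expr)
        perm = np.random.default_rng(0).permutation(len(expr))
        expr2 = expr.iloc[perm]
        G2, P2, _, m2 = reconstruct_network(expr2)
        e1 = {tuple(sorted(e)) for e in G1.edges}
        e2 = {tuple(sorted(e)) for e in G2.edges}
        assert e1 == e2

    def test_true_edge_pcors_dominate_null(self):
        cfg = SimulationConfig(
            network_n_nodes=50, network_n_edges=25, pcor_magnitude=0.35, seed=8
        )
        expr, truth = gen_network_timeseries(cfg, n_samples=150)
        _, P, _, _ = reconstruct_network(expr)
        genes = list(expr.index)
        vals_true, vals_null = [], []
        for i, j in itertools.combinations(range(len(genes)), 2):
            mag = abs(P.iloc[i, j])
            if tuple(sorted((genes[i], genes[j]))) in truth.true_edges:
                vals_true.append(mag)
            else:
                vals_null.append(mag)
        from scipy.stats import mannwhitneyu

        stat = mannwhitneyu(vals_true, vals_null, alternative="greater")
        assert stat.pvalue < 0.01


class TestFirstNeighborhood:
    def test_isolated_focal_gene(self):
        G = nx.Graph()
        G.add_nodes_from("abc")
        sub = first_neighborhood(G, "a")
        assert sub.number_of_nodes() == 1 and sub.number_of_edges() == 0

    def test_star_center(self):
        G = nx.star_graph(29)  # center 0, 29 leaves
        sub = first_neighborhood(G, 0)
        assert sub.number_of_nodes() == 30
        assert sub.number_of_edges() == 29

    def test_induced_subgraph_property(self, rng):
        G = nx.gnp_random_graph(25, 0.2, seed=42)
        sub = first_neighborhood(G, 3)
        nodes = set(sub.nodes)
        assert all(a in nodes and b in nodes for a, b in sub.edges)
        # all edges among the closed neighborhood are present
        for a in nodes:
            for b in nodes:
                if G.has_edge(a, b):
                    assert sub.has_edge(a, b)

    def test_unknown_gene_raises(self):
        with pytest.raises(ValueError, match="not in network"):
            first_neighborhood(nx.Graph([("a", "b")]), "zzz")
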