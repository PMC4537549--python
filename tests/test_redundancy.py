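import math

import numpy as np
import pytest

from sphingoflux import (
    canonical_correlations,
    cluster_parameters,
    fisher_information,
    functional_redundancy,
    identifiability_filter,
    make_random_network,
)
from sphingoflux.redundancy import FisherInformation

from conftest import finite_difference_sensitivities


def _fim(matrix, names=None):
    matrix = np.asarray(matrix, dtype=float)
    names = names or [f"p{i}" for i in range(matrix.shape[0])]
    return FisherInformation(matrix=matrix, param_names=names,
                             theta=np.ones(matrix.shape[0]))


class TestFisherInformation:
    def test_unobservable_parameter_zero_row(self, chain):
        """Observing only the upstream species, the efflux rate carries no
        information: its FIM row and diagonal vanish."""
        fim = fisher_information(chain, x0=np.array([1.0, 1.0]),
                                 grid=np.linspace(0, 5, 21), observed=["A"],
                                 normalize=False)
        i = fim.param_names.index("efflux.k")
        assert np.allclose(fim.matrix[i], 0.0, atol=1e-12)
        assert fim.matrix[i, i] == pytest.approx(0.0, abs=1e-15)

    def test_product_confounded_pair_rank_one(self, redundant_pair):
        """Parameters entering only through their product have proportional
        log-scale sensitivities: the pair block is rank 1 with off-diagonal
        equal to the geometric mean of the diagonals."""
        fim = fisher_information(redundant_pair, grid=np.linspace(0, 10, 41),
                                 scale="log", normalize=False)
        ia = fim.param_names.index("prod.ka")
        ib = fim.param_names.index("prod.kb")
        block = fim.matrix[np.ix_([ia, ib], [ia, ib])]
        assert np.linalg.matrix_rank(block, tol=1e-8 * block.max()) == 1
        assert block[0, 1] == pytest.approx(
            math.sqrt(block[0, 0] * block[1, 1]), rel=1e-9
        )

    def test_matches_finite_difference_oracle(self, chain):
        grid = np.linspace(0.0, 5.0, 21)
        x0 = np.array([1.0, 1.0])
        fim = fisher_information(chain, x0=x0, grid=grid, scale="raw",
                                 normalize=False)
        fd = finite_difference_sensitivities(chain, x0, grid)
        ref = np.einsum("tnl,tnm->lm", fd, fd)
        assert np.allclose(fim.matrix, ref, rtol=1e-3)

    def test_symmetric_psd(self, random_net):
        fim = fisher_information(random_net, grid=np.linspace(0, 5, 21))
        assert np.allclose(fim.matrix, fim.matrix.T)
        assert np.min(np.linalg.eigvalsh(fim.matrix)) >= -1e-10


class TestCanonicalCorrelations:
    def test_two_by_two_reduces_to_correlation(self):
        for r in (0.0, 0.3, -0.7, 0.95):
            fim = _fim([[1.0, r], [r, 1.0]])
            rho = canonical_correlations(fim, [0], [1])
            assert rho[0] == pytest.approx(abs(r), abs=1e-12)

    def test_block_diagonal_zero(self):
        fim = _fim(np.diag([1.0, 2.0, 3.0, 4.0]))
        rho = canonical_correlations(fim, [0, 1], [2, 3])
        assert np.allclose(rho, 0.0)

    def test_rank_one_perfectly_confounded(self):
        v = np.array([1.0, 2.0])
        fim = _fim(np.outer(v, v))
        assert canonical_correlations(fim, [0], [1])[0] == pytest.approx(1.0)

    def test_overlapping_sets_rejected(self):
        fim = _fim(np.eye(3))
        with pytest.raises(ValueError):
            canonical_correlations(fim, [0, 1], [1, 2])


class TestFunctionalRedundancy:
    def test_zero_for_orthogonal_blocks(self):
        assert functional_redundancy(_fim(np.eye(4)), [0, 1], [2, 3]) == 0.0

    def test_single_correlation_value(self):
        fim = _fim([[1.0, 0.8], [0.8, 1.0]])
        assert functional_redundancy(fim, [0], [1]) == pytest.approx(
            -0.5 * math.log(0.36), rel=1e-12
        )

    def test_perfect_confounding_infinite(self):
        v = np.array([1.0, 2.0])
        assert functional_redundancy(_fim(np.outer(v, v)), [0], [1]) == math.inf

    def test_symmetry_and_reorder_invariance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 6))
        fim = _fim(X.T @ X)
        a, b = [0, 3, 1], [5, 2]
        val = functional_redundancy(fim, a, b)
        assert functional_redundancy(fim, b, a) == pytest.approx(val, rel=1e-12)
        assert functional_redundancy(fim, [3, 0, 1], [2, 5]) == pytest.approx(val, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_gaussian_mutual_information_oracle(self, seed):
        """For Gaussian parameters with covariance FIM^-1 the redundancy is
        the block mutual information -1/2 ln det(C)/(det C_AA det C_BB)."""
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(10, 4))
        F = X.T @ X + 0.1 * np.eye(4)
        fim = _fim(F)
        a, b = [0, 1], [2, 3]
        C = np.linalg.inv(F)
        mi = -0.5 * math.log(
            np.linalg.det(C)
            / (np.linalg.det(C[np.ix_(a, a)]) * np.linalg.det(C[np.ix_(b, b)]))
        )
        assert functional_redundancy(fim, a, b) == pytest.approx(mi, rel=1e-6)


class TestIdentifiabilityFilter:
    def test_zero_diagonal_fails_zeta(self):
        fim = _fim(np.diag([1.0, 0.0, 2.0]))
        keep, removed = identifiability_filter(fim, delta=0.01, zeta=1e-6)
        assert dict(removed) == {1: "zeta"}
        assert keep == [0, 2]

    def test_diagonal_fim_all_identifiable(self):
        fim = _fim(np.diag([1.0, 2.0, 3.0]))
        keep, removed = identifiability_filter(fim, delta=0.01, zeta=1e-6)
        assert keep == [0, 1, 2] and removed == []

    def test_confounded_pair_fails_delta(self, redundant_pair):
        fim = fisher_information(redundant_pair, grid=np.linspace(0, 10, 41))
        keep, removed = identifiability_filter(fim, delta=0.01, zeta=1e-9)
        removed_names = {fim.param_names[i] for i, _ in removed}
        assert removed_names == {"prod.ka", "prod.kb"}
        assert all(reason == "delta" for _, reason in removed)
        assert {fim.param_names[i] for i in keep} == {"decay.k"}

    def test_invalid_thresholds_rejected(self):
        fim = _fim(np.eye(2))
        with pytest.raises(ValueError):
            identifiability_filter(fim, delta=0.0, zeta=1e-6)
        with pytest.raises(ValueError):
            identifiability_filter(fim, delta=0.5, zeta=0.0)


class TestClusterParameters:
    def test_correlated_pair_merges_first(self):
        F = np.eye(3)
        F[0, 1] = F[1, 0] = 0.9
        tree = cluster_parameters(_fim(F), delta=0.05, zeta=1e-9)
        assert not tree.removed_params
        step, a, b, height = tree.merges[0]
        assert a | b == {"p0", "p1"}
        assert height == pytest.approx(-0.5 * math.log(1 - 0.81), rel=1e-9)
        # the independent parameter never merges (zero redundancy) and
        # survives as its own cluster
        assert {"p2"} in tree.clusters

    def test_confounded_pair_removed_before_merging(self, redundant_pair):
        fim = fisher_information(redundant_pair, grid=np.linspace(0, 10, 41))
        tree = cluster_parameters(fim, delta=0.01, zeta=1e-9)
        assert set(tree.removed_params) == {"prod.ka", "prod.kb"}
        merged_names = set().union(*[a | b for _, a, b, _ in tree.merges]) if tree.merges else set()
        assert "prod.ka" not in merged_names and "prod.kb" not in merged_names

    def test_partition_covers_survivors_exactly_once(self, random_net):
        fim = fisher_information(random_net, grid=np.linspace(0, 5, 21))
        tree = cluster_parameters(fim, delta=1e-4, zeta=1e-10)
        clustered = [p for cl in tree.clusters for p in cl]
        assert len(clustered) == len(set(clustered))
        assert set(clustered) | set(tree.removed_params) == set(fim.param_names)
        assert not set(clustered) & set(tree.removed_params)

    def test_fully_nonidentifiable_rejected(self):
        fim = _fim(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="non-identifiable"):
            cluster_parameters(fim, delta=0.01, zeta=1e-6)

    def test_stable_under_small_parameter_jitter(self):
        """Cluster count and membership survive a 1 % multiplicative jitter
        of the evaluation point (regression on a fixed seed)."""
        net = make_random_network(4, 7, mm_fraction=0.5, seed=3)
        grid = np.linspace(0, 5, 21)
        base = fisher_information(net, grid=grid)
        tree_a = cluster_parameters(base, delta=1e-4, zeta=1e-10)
        jittered = net.copy()
        rng = np.random.default_rng(0)
        for key, value in net.parameter_registry().items():
            jittered.set_parameter(key, value * (1 + 0.01 * rng.uniform(-1, 1)))
        tree_b = cluster_parameters(
            fisher_information(jittered, grid=grid), delta=1e-4, zeta=1e-10
        )
        assert tree_a.n_clusters == tree_b.n_clusters
        assert sorted(map(sorted, tree_a.clusters)) == sorted(map(sorted, tree_b.clusters))

    def test_newick_export_parses(self, random_net):
        import dendropy

        fim = fisher_information(random_net, grid=np.linspace(0, 5, 21))
        tree = cluster_parameters(fim, delta=1e-4, zeta=1e-10)
        newick = tree.to_newick()
        parsed = dendropy.Tree.get(data=newick, schema="newick")
        leaves = {leaf.taxon.label for leaf in parsed.leaf_node_iter() if leaf.taxon}
        survivors = set().union(*tree.clusters) if tree.clusters else set()
        assert leaves <= {s.replace("_", " ") for s in survivors} | survivors
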