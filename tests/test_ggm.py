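"""Network estimation: correlation input, penalty path, EBIC selection,
non-regularized fallback, centrality and layout."""

import numpy as np
import pandas as pd
import pytest

import symptomnet as sn
from symptomnet.exceptions import (
    DegenerateItemError,
    InvalidArgumentError,
    TooSmallSampleError,
)
from symptomnet.ggm import (
    GGMConfig,
    NetworkModel,
    PathPoint,
    glasso_path,
    layout_fr,
    nonreg_network,
    sample_correlation,
    select_ebic,
    strength_centrality,
    subsample_for_profile,
)

from tests.oracles import exhaustive_ebic_support


def mvn_from_pcor(pcor, n, seed):
    """Ordinal-free latent draws with the given partial correlations."""
    K = sn.pcor_to_precision(pcor)
    sigma = np.linalg.inv(K)
    d = np.sqrt(np.diag(sigma))
    sigma = sigma / np.outer(d, d)
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(np.zeros(pcor.shape[0]), sigma, size=n)


class TestSampleCorrelation:
    def test_collinear_columns_correlate_fully(self):
        x = np.arange(20.0)
        S = sample_correlation(np.column_stack([x, 2 * x + 1]))
        assert S[0, 1] == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(0)
        S = sample_correlation(rng.standard_normal((10000, 4)))
        off = S[np.triu_indices(4, 1)]
        assert np.all(np.abs(off) < 0.05)

    def test_constant_column_rejected_by_name(self):
        data = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 2, 2, 2]})
        with pytest.raises(DegenerateItemError, match="'b'"):
            sample_correlation(data)


class TestGlassoPath:
    def test_full_shrinkage_limit_is_diagonal(self):
        X = mvn_from_pcor(np.array([[0, 0.4], [0.4, 0]]), 200, 1)
        path = glasso_path(sample_correlation(X), 200, GGMConfig(n_lambda=10))
        assert path[0].n_edges == 0
        assert np.count_nonzero(path[0].precision - np.diag(np.diag(path[0].precision))) == 0

    def test_identity_correlation_stays_empty_everywhere(self):
        path = glasso_path(np.eye(4), 500, GGMConfig(n_lambda=15))
        assert all(pt.n_edges == 0 for pt in path)
        net = select_ebic(path, n=500)
        assert np.count_nonzero(net.pcor) == 0

    def test_single_strong_pair_selected_and_matches_oracle(self):
        """3 variables, one true edge (pcor 0.6): the minimum-EBIC model
        contains exactly that edge, agreeing with the exhaustive
        constrained-ML support search."""
        pcor = np.zeros((3, 3))
        pcor[0, 1] = pcor[1, 0] = 0.6
        X = mvn_from_pcor(pcor, 500, 7)
        S = sample_correlation(X)
        net = sn.estimate_network(X)
        iu = np.triu_indices(3, 1)
        support = frozenset(
            (int(i), int(j)) for i, j in zip(*iu) if net.pcor[i, j] != 0
        )
        assert support == frozenset({(0, 1)})
        assert support == exhaustive_ebic_support(S, 500)

    def test_edge_count_mostly_monotone_along_path(self):
        """Edge count is non-decreasing as the penalty relaxes in >= 95%
        of adjacent path steps over randomized datasets."""
        good = total = 0
        for s in range(20):
            rng = np.random.default_rng(300 + s)
            pcor = sn.random_network(6, 4, (0.2, 0.35), rng)
            X = mvn_from_pcor(pcor, 300, 600 + s)
            path = glasso_path(sample_correlation(X), 300, GGMConfig(n_lambda=30))
            diffs = np.diff([pt.n_edges for pt in path])
            good += int(np.sum(diffs >= 0))
            total += len(diffs)
        assert good / total >= 0.95

    def test_small_sample_guard(self):
        with pytest.raises(TooSmallSampleError):
            glasso_path(np.eye(5), 4, GGMConfig())


class TestSelectEbic:
    def test_two_by_two_sign_flip(self):
        K = np.array([[1.0, -0.5], [-0.5, 1.0]])
        point = PathPoint(lambda_=0.1, precision=K, ebic=1.0, n_edges=1)
        net = select_ebic([point], items=("a", "b"), n=100)
        assert net.pcor[0, 1] == pytest.approx(0.5)

    def test_diagonal_precision_gives_empty_network(self):
        point = PathPoint(lambda_=0.5, precision=np.eye(3), ebic=2.0, n_edges=0)
        net = select_ebic([point], n=50)
        assert np.count_nonzero(net.pcor) == 0

    def test_ebic_tie_resolved_toward_sparser_model(self):
        dense = np.array([[1.0, -0.3], [-0.3, 1.0]])
        sparse = np.eye(2)
        path = [
            PathPoint(lambda_=0.9, precision=sparse, ebic=5.0, n_edges=0),
            PathPoint(lambda_=0.1, precision=dense, ebic=5.0, n_edges=1),
        ]
        net = select_ebic(path, n=100)
        assert net.lambda_ == 0.9
        assert net.n_edges == 0

    def test_empty_path_rejected(self):
        with pytest.raises(InvalidArgumentError):
            select_ebic([])


class TestNonregNetwork:
    def test_alpha_one_equals_matrix_inversion(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((200, 5))
        net = nonreg_network(X, GGMConfig(method="nonreg_threshold", alpha=1.0))
        S = sample_correlation(X)
        K = np.linalg.inv(S)
        d = np.sqrt(np.diag(K))
        expected = -K / np.outer(d, d)
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(net.pcor, expected, atol=1e-10)

    def test_planted_edge_survives_threshold(self):
        pcor = np.zeros((5, 5))
        pcor[0, 1] = pcor[1, 0] = 0.4
        X = mvn_from_pcor(pcor, 300, 2)
        net = nonreg_network(X, GGMConfig(method="nonreg_threshold", alpha=0.05))
        assert net.pcor[0, 1] != 0

    def test_type_one_error_rate_near_alpha(self):
        """Independent data: ~5% of edges survive at alpha = 0.05."""
        rng = np.random.default_rng(99)
        rates = []
        iu = np.triu_indices(6, 1)
        for _ in range(300):
            X = rng.standard_normal((800, 6))
            net = nonreg_network(X, GGMConfig(method="nonreg_threshold", alpha=0.05))
            rates.append(np.mean(net.pcor[iu] != 0))
        assert 0.03 < np.mean(rates) < 0.07

    def test_sample_size_guard(self):
        with pytest.raises(TooSmallSampleError):
            nonreg_network(np.random.default_rng(0).standard_normal((7, 5)))


class TestStrengthCentrality:
    def make_net(self, pcor, items=None):
        pcor = np.asarray(pcor, dtype=float)
        items = items or tuple(f"i{k}" for k in range(pcor.shape[0]))
        return NetworkModel(items=items, pcor=pcor, method="nonreg_threshold", n=100)

    def test_sums_absolute_incident_weights(self):
        pcor = np.array(
            [[0, 0.3, -0.2, 0.1],
             [0.3, 0, 0, 0],
             [-0.2, 0, 0, 0],
             [0.1, 0, 0, 0]]
        )
        cent = strength_centrality(self.make_net(pcor)).table
        assert cent.loc[cent["item"] == "i0", "strength"].iloc[0] == pytest.approx(0.6)
        assert cent.loc[cent["item"] == "i0", "rank"].iloc[0] == 1

    def test_empty_network_flags_undefined_standardization(self):
        cent = strength_centrality(self.make_net(np.zeros((3, 3))))
        assert (cent.table["strength"] == 0).all()
        assert not cent.standardized_defined

    def test_equal_strengths_ranked_by_item_order(self):
        pcor = np.full((3, 3), 0.2)
        np.fill_diagonal(pcor, 0.0)
        cent = strength_centrality(self.make_net(pcor)).table
        assert list(cent["rank"]) == [1, 2, 3]
        assert np.allclose(cent["strength"], 0.4)

    def test_standardized_scores_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(4)
        X = mvn_from_pcor(sn.random_network(5, 4, (0.2, 0.3), rng), 500, 8)
        cent = strength_centrality(sn.estimate_network(X)).table
        assert cent["z_strength"].mean() == pytest.approx(0.0, abs=1e-12)
        assert cent["z_strength"].std(ddof=0) == pytest.approx(1.0)

    def test_invariant_under_node_permutation(self):
        rng = np.random.default_rng(10)
        pcor = sn.random_network(6, 5, (0.15, 0.3), rng)
        net = self.make_net(pcor)
        perm = rng.permutation(6)
        permuted = self.make_net(
            pcor[np.ix_(perm, perm)], items=tuple(f"i{k}" for k in perm)
        )
        a = strength_centrality(net).table.set_index("item")["strength"]
        b = strength_centrality(permuted).table.set_index("item")["strength"]
        assert np.allclose(a.sort_index(), b.sort_index())


class TestLayout:
    def make_net(self, pcor):
        return NetworkModel(
            items=tuple(f"i{k}" for k in range(pcor.shape[0])),
            pcor=np.asarray(pcor, dtype=float),
            method="nonreg_threshold",
            n=50,
        )

    def test_single_node_centered(self):
        net = NetworkModel(items=("solo",), pcor=np.zeros((1, 1)),
                           method="nonreg_threshold", n=10)
        coords = layout_fr(net)
        assert coords[["x", "y"]].iloc[0].tolist() == [0.5, 0.5]

    def test_two_nodes_symmetric_about_center(self):
        pcor = np.array([[0, 0.5], [0.5, 0]])
        coords = layout_fr(self.make_net(pcor), seed=3)
        center = coords[["x", "y"]].mean()
        assert center["x"] == pytest.approx(0.5)
        assert center["y"] == pytest.approx(0.5)

    def test_deterministic_given_seed_and_unit_square(self):
        rng = np.random.default_rng(2)
        pcor = sn.random_network(7, 6, (0.2, 0.3), rng)
        net = self.make_net(pcor)
        a = layout_fr(net, seed=11)
        b = layout_fr(net, seed=11)
        pd.testing.assert_frame_equal(a, b)
        assert a[["x", "y"]].min().min() >= 0.0
        assert a[["x", "y"]].max().max() <= 1.0


class TestNetworkModelInvariants:
    def test_estimates_satisfy_contract_on_random_inputs(self):
        """Symmetry, zero diagonal, bounded weights for both estimators."""
        for s in range(6):
            rng = np.random.default_rng(40 + s)
            pcor = sn.random_network(5, 3, (0.2, 0.35), rng)
            X = mvn_from_pcor(pcor, 400, 70 + s)
            for method in ("ebic_glasso", "nonreg_threshold"):
                net = sn.estimate_network(X, GGMConfig(method=method, n_lambda=20))
                assert np.allclose(net.pcor, net.pcor.T)
                assert np.all(np.diag(net.pcor) == 0)
                assert np.all(np.abs(net.pcor) <= 1)

    def test_asymmetric_matrix_rejected(self):
        bad = np.array([[0, 0.2], [0.3, 0]])
        with pytest.raises(InvalidArgumentError):
            NetworkModel(items=("a", "b"), pcor=bad, method="x", n=10)


class TestSubsampleForProfile:
    def test_all_present_profile_keeps_nine_items(
        self, three_profile_cohort, phq_catalog
    ):
        data, dropped = subsample_for_profile(three_profile_cohort, 1, phq_catalog)
        assert data.shape[1] == 9
        assert dropped == ()
        assert (data.to_numpy() >= 1).all()

    def test_absent_item_dropped_and_recorded(
        self, three_profile_cohort, phq_catalog
    ):
        data, dropped = subsample_for_profile(three_profile_cohort, 2, phq_catalog)
        assert data.shape[1] == 8
        assert dropped == ("phq9",)

    def test_floor_refuses_small_profiles(self, three_profile_cohort, phq_catalog):
        with pytest.raises(TooSmallSampleError):
            subsample_for_profile(
                three_profile_cohort, 1, phq_catalog, min_members=10**6
            )

    def test_unmatched_profile_id_rejected(self, three_profile_cohort, phq_catalog):
        with pytest.raises(InvalidArgumentError):
            subsample_for_profile(three_profile_cohort, 382, phq_catalog)
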