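import numpy as np
import pytest

from glysense.model_selection import (consistency_select, fit_with_selection,
                                      loo_bandwidth, loo_bandwidth_per_dim)
from glysense.occ.core import OneClassModel, calibrate_threshold


class _StubModel(OneClassModel):
    """Model whose held-out rejection rate is dialled in directly: it scores
    a preset fraction of any test set above its fixed threshold."""

    name = "stub"

    def __init__(self, rejection):
        self.rejection = rejection

    def fit(self, X):
        self._X = np.asarray(X, float)
        return self

    def train_scores(self):
        return np.zeros(len(self._X))

    def score(self, Z):
        Z = np.asarray(Z, float)
        n = len(Z)
        scores = np.zeros(n)
        n_reject = int(round(self.rejection * n))
        scores[:n_reject] = 1.0
        return scores


class TestConsistency:
    def test_most_complex_consistent_candidate_chosen(self, rng):
        """Simple-to-complex rejections [0.005, 0.009, 0.030] at beta=0.01,
        n=100: the second candidate is the most complex consistent one."""
        X = rng.random((100, 2))
        value, rates = consistency_select(
            lambda r: _StubModel(r), [0.005, 0.009, 0.030], X, beta=0.01
        )
        assert value == 0.009
        assert rates[2] > 0.01 + np.sqrt(0.01 * 0.99 / 100)

    def test_all_consistent_picks_most_complex(self, rng):
        X = rng.random((100, 2))
        value, _ = consistency_select(
            lambda r: _StubModel(r), [0.0, 0.0, 0.0], X, beta=0.01
        )
        assert value == 0.0  # the last grid entry (all identical here)

    def test_none_consistent_falls_back_to_least_complex(self, rng):
        X = rng.random((100, 2))
        value, _ = consistency_select(
            lambda r: _StubModel(r), [0.5, 0.8], X, beta=0.01
        )
        assert value == 0.5

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            consistency_select(lambda r: _StubModel(r), [], rng.random((30, 2)),
                               beta=0.01)

    def test_deterministic_given_seed(self, rng):
        from glysense.occ.density import KNNOCC

        X = rng.normal(size=(80, 2))
        a = consistency_select(lambda k: KNNOCC(k=k), [9, 5, 3, 1], X, 0.05,
                               seed=4)
        b = consistency_select(lambda k: KNNOCC(k=k), [9, 5, 3, 1], X, 0.05,
                               seed=4)
        assert a[0] == b[0]
        np.testing.assert_array_equal(a[1], b[1])

    def test_chosen_training_rejection_within_two_se(self, rng):
        """Post hoc: the chosen candidate's full-data training rejection
        stays within beta + 2 binomial SE."""
        from glysense.occ.density import KNNOCC

        X = rng.normal(size=(150, 2))
        beta = 0.05
        k, _ = consistency_select(lambda k: KNNOCC(k=k), [15, 9, 5, 3, 1], X,
                                  beta, seed=0)
        m = KNNOCC(k=k).fit(X)
        thr = calibrate_threshold(m.train_scores(), beta)
        rate = np.mean(m.train_scores() > thr)
        assert rate <= beta + 2 * np.sqrt(beta * (1 - beta) / len(X))


class TestLOOBandwidth:
    def test_two_point_optimum_matches_closed_form(self):
        """For points {0, 1} the LOO log-likelihood 2(-1/(2h^2) - ln h) + c
        peaks at h = 1: each excluded point sits on the other's kernel
        shoulder.  The grid search must find it."""
        X = np.array([[0.0], [1.0]])
        fine = np.geomspace(0.05, 5.0, 2000)

        def loo_ll(h):
            return 2 * (-0.5 / h**2 - 0.5 * np.log(2 * np.pi * h**2))

        best = fine[np.argmax([loo_ll(h) for h in fine])]
        assert best == pytest.approx(1.0, rel=0.01)  # closed-form optimum
        got = loo_bandwidth(X, grid=fine)
        assert got == pytest.approx(best, rel=1e-6)

    def test_scale_equivariance(self, rng):
        X = rng.normal(size=(60, 1))
        h1 = loo_bandwidth(X)
        h2 = loo_bandwidth(X * 10.0)
        assert h2 == pytest.approx(10.0 * h1, rel=0.15)

    def test_bandwidth_shrinks_with_sample_size(self):
        rng = np.random.default_rng(0)
        small = loo_bandwidth(rng.normal(size=(50, 1)))
        large = loo_bandwidth(rng.normal(size=(500, 1)))
        assert large < small

    def test_silverman_sanity_band(self):
        """LOO bandwidth on N(0,1) tracks the Silverman reference rate
        (n = 200, 20 seeds).  LOO maximum likelihood is known to undersmooth
        on samples containing near-duplicate pairs, so the factor-3 band is
        asserted for the large majority of seeds and for the median."""
        ratios = []
        for seed in range(20):
            x = np.random.default_rng(seed).normal(size=(200, 1))
            silverman = 1.06 * x.std() * 200 ** (-1 / 5)
            ratios.append(loo_bandwidth(x) / silverman)
        ratios = np.array(ratios)
        assert 1 / 3 < np.median(ratios) < 3
        assert np.mean((ratios > 1 / 3) & (ratios < 3)) >= 0.9

    def test_per_dim_variant_tracks_marginal_scales(self, rng):
        X = np.column_stack([rng.normal(size=100), rng.normal(size=100) * 20])
        h = loo_bandwidth_per_dim(X)
        assert h[1] > 5 * h[0]

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            loo_bandwidth(np.zeros((10, 1)))


def test_fit_with_selection_dispatch(rng):
    X = rng.normal(size=(60, 2)) * 0.1 + 0.5
    for name, attr in [("gaussian", "mean_"), ("nn_d", "_own_nn_dist"),
                       ("mst", "edges_"), ("pca", "n_components_")]:
        est = fit_with_selection(name, X, beta=0.05, seed=0)
        assert hasattr(est, attr)
    est = fit_with_selection("knn", X, beta=0.05, seed=0, params={"k": 3})
    assert est.k == 3
    with pytest.raises(ValueError, match="unknown model"):
        fit_with_selection("isolation_forest", X, beta=0.05)
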