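import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from pestmap.bayes import (
    Draws,
    MCMCSettings,
    SpatialModelSpec,
    build_adjacency,
    detect_hotspots,
    fit,
    fit_zero_inflated,
    information_criteria,
    summarize,
)
from pestmap.grids import DistrictGeometry
from scipy.special import gammaln


def _mcmc(iterations=1500, burn_in=500, chains=2, seed=0):
    return MCMCSettings(iterations=iterations, burn_in=burn_in,
                        chains=chains, seed=seed)


class TestAdjacency:
    def test_queen_2x2_grid_corners_have_3_neighbours(self, square_districts):
        graph = build_adjacency(square_districts)
        # queen contiguity: diagonal touch at the shared corner counts
        assert np.all(graph.degree == 3)
        assert graph.n_components == 1

    def test_disjoint_squares_flagged_as_two_components(self):
        d = [DistrictGeometry("A", box(0, 0, 1, 1)),
             DistrictGeometry("B", box(5, 5, 6, 6))]
        graph = build_adjacency(d)
        assert graph.n_components == 2
        assert graph.isolated.all()

    def test_single_district_isolated(self):
        graph = build_adjacency([DistrictGeometry("A", box(0, 0, 1, 1))])
        assert graph.adjacency.sum() == 0 and graph.isolated[0]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_adjacency([])

    def test_colour_classes_are_independent_sets(self, district_scene):
        _, _, _, graph = district_scene
        for cls in graph.colour_classes():
            sub = graph.adjacency[np.ix_(cls, cls)]
            assert sub.sum() == 0


class TestFit:
    def test_seed_determinism_bit_identical(self, district_scene):
        _, _, pops, graph = district_scene
        rng = np.random.default_rng(0)
        e = pops.sum(axis=1).to_numpy() / 2000
        data = pd.DataFrame({"Y": rng.poisson(e), "E": e})
        d1 = fit(SpatialModelSpec(), data, graph, _mcmc(seed=9))
        d2 = fit(SpatialModelSpec(), data, graph, _mcmc(seed=9))
        np.testing.assert_array_equal(d1.beta, d2.beta)
        np.testing.assert_array_equal(d1.u, d2.u)
        np.testing.assert_array_equal(d1.tau_v, d2.tau_v)

    def test_single_district_matches_conjugate_oracle(self):
        # intercept-only, no random effects: posterior of lambda = exp(b0)
        # under a near-flat prior approximates Gamma(Y, E): mean Y/E
        d = [DistrictGeometry("A", box(0, 0, 1, 1))]
        graph = build_adjacency(d)
        data = pd.DataFrame({"Y": [20.0], "E": [10.0]})
        spec = SpatialModelSpec(include_structured=False,
                                include_unstructured=False)
        draws = fit(spec, data, graph, _mcmc(iterations=4000, burn_in=1000,
                                             seed=2))
        post_mean = draws.theta.mean()
        gamma_mean = 20.0 / 10.0
        assert post_mean == pytest.approx(gamma_mean, rel=0.1)

    def test_zero_expected_rejected(self, square_districts):
        graph = build_adjacency(square_districts)
        data = pd.DataFrame({"Y": [1.0] * 4, "E": [1.0, 1.0, 0.0, 1.0]})
        with pytest.raises(ValueError, match="E must be > 0"):
            fit(SpatialModelSpec(), data, graph)

    def test_rank_deficient_covariates_rejected(self, square_districts):
        graph = build_adjacency(square_districts)
        data = pd.DataFrame({"Y": [1.0] * 4, "E": [1.0] * 4,
                             "c": [1.0] * 4})  # collinear with intercept
        with pytest.raises(ValueError, match="rank"):
            fit(SpatialModelSpec(), data, graph, covariates=["c"])


class TestSummarize:
    @staticmethod
    def _draws_from_theta(theta, y=None, e=None):
        s, n = theta.shape
        e = np.ones(n) if e is None else e
        y = np.ones(n) if y is None else y
        mu = e * theta
        ll = y * np.log(mu) - mu - gammaln(y + 1)
        return Draws(beta=np.log(theta[:, :1]), u=np.zeros((s, n)),
                     v=np.zeros((s, n)), tau_u=np.ones(s), tau_v=np.ones(s),
                     loglik=ll, chain=np.zeros(s, dtype=int), theta=theta,
                     y=y, e=e, x=np.ones((n, 1)))

    def test_constant_draws(self):
        theta = np.full((200, 3), 2.0)
        summ = summarize(self._draws_from_theta(theta))
        assert (summ.table["rr_mean"] == 2.0).all()
        assert (summ.table["rr_lo"] == 2.0).all()
        assert summ.table["hotspot"].all()

    def test_draws_symmetric_around_one_not_hotspot(self):
        rng = np.random.default_rng(1)
        theta = np.exp(rng.normal(0, 0.5, size=(1000, 2)))
        summ = summarize(self._draws_from_theta(theta))
        assert not summ.table["hotspot"].any()

    def test_percentiles_match_sorted_order_oracle(self):
        rng = np.random.default_rng(2)
        theta = rng.uniform(0.5, 3.0, size=(200, 1))
        summ = summarize(self._draws_from_theta(theta))
        srt = np.sort(theta[:, 0])
        assert summ.table["rr_lo"].iloc[0] == pytest.approx(
            np.percentile(srt, 2.5), abs=1e-12)
        assert summ.table["rr_hi"].iloc[0] == pytest.approx(
            np.percentile(srt, 97.5), abs=1e-12)

    def test_too_few_draws_rejected(self):
        theta = np.ones((50, 2))
        with pytest.raises(ValueError):
            summarize(self._draws_from_theta(theta))

    def test_hotspot_rule_strict_boundary(self):
        table = pd.DataFrame({"rr_mean": [2.0, 2.0, 0.5],
                              "rr_lo": [1.0, 1.001, 0.2],
                              "rr_hi": [3.0, 3.0, 0.9]})
        table["hotspot"] = table["rr_lo"] > 1.0
        hot = detect_hotspots(type("S", (), {"table": table})())
        assert len(hot) == 1
        assert hot.index.tolist() == [1]

    def test_empty_summary_gives_empty_hotspots(self):
        table = pd.DataFrame(columns=["rr_mean", "rr_lo", "rr_hi", "hotspot"])
        hot = detect_hotspots(type("S", (), {"table": table})())
        assert len(hot) == 0


class TestInformationCriteria:
    def test_degenerate_posterior_pd_zero(self):
        theta = np.full((150, 4), 1.5)
        y = np.array([3.0, 1.0, 2.0, 0.0])
        draws = TestSummarize._draws_from_theta(theta, y=y)
        dic, waic = information_criteria(draws)
        mu = 1.5
        dev = -2 * np.sum(y * np.log(mu) - mu - gammaln(y + 1))
        assert dic == pytest.approx(dev, abs=1e-8)  # p_D = 0

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(3)
        s, n = 50, 3
        theta = np.exp(rng.normal(0, 0.3, size=(s, n)))
        y = np.array([4.0, 2.0, 7.0])
        e = np.array([3.0, 2.0, 5.0])
        draws = TestSummarize._draws_from_theta(theta, y=y, e=e)
        dic, waic = information_criteria(draws)

        # brute-force oracle
        ll = np.empty((s, n))
        for si in range(s):
            for i in range(n):
                mu = e[i] * theta[si, i]
                ll[si, i] = y[i] * np.log(mu) - mu - gammaln(y[i] + 1)
        dbar = -2 * np.mean([ll[si].sum() for si in range(s)])
        theta_bar = theta.mean(axis=0)
        dhat = -2 * sum(y[i] * np.log(e[i] * theta_bar[i])
                        - e[i] * theta_bar[i] - gammaln(y[i] + 1)
                        for i in range(n))
        dic_oracle = dbar + (dbar - dhat)
        lppd = sum(np.log(np.mean(np.exp(ll[:, i]))) for i in range(n))
        p_waic = sum(np.var(ll[:, i], ddof=1) for i in range(n))
        waic_oracle = -2 * (lppd - p_waic)
        assert dic == pytest.approx(dic_oracle, abs=1e-8)
        assert waic == pytest.approx(waic_oracle, abs=1e-8)


class TestZeroInflated:
    def test_pi_small_on_pure_poisson_data(self, square_districts):
        graph = build_adjacency(square_districts)
        rng = np.random.default_rng(4)
        e = np.full(4, 20.0)
        data = pd.DataFrame({"Y": rng.poisson(e).astype(float), "E": e})
        draws = fit_zero_inflated(SpatialModelSpec(), data, graph,
                                  _mcmc(seed=5))
        assert draws.pi.mean() < 0.35  # prior mean 0.5 pulled toward 0

    def test_all_zero_counts_push_pi_up(self, square_districts):
        graph = build_adjacency(square_districts)
        e = np.full(4, 20.0)
        data = pd.DataFrame({"Y": np.zeros(4), "E": e})
        draws = fit_zero_inflated(SpatialModelSpec(), data, graph,
                                  _mcmc(seed=6))
        assert draws.pi.mean() > 0.5

    def test_seed_determinism(self, square_districts):
        graph = build_adjacency(square_districts)
        data = pd.DataFrame({"Y": [0.0, 2.0, 0.0, 5.0], "E": [2.0] * 4})
        d1 = fit_zero_inflated(SpatialModelSpec(), data, graph, _mcmc(seed=7))
        d2 = fit_zero_inflated(SpatialModelSpec(), data, graph, _mcmc(seed=7))
        np.testing.assert_array_equal(d1.pi, d2.pi)
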