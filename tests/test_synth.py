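import numpy as np
import pandas as pd
import pytest

from pestmap import synth
from pestmap.lineage import curate, load_crosswalk, stratify
from pestmap.moran import morans_i_bivariate, morans_i_global, rook_grid_weights
from pestmap.sir import STRATA


class TestLandscape:
    def test_seed_determinism(self):
        g1 = synth.make_landscape(16, 16, 2, seed=5)
        g2 = synth.make_landscape(16, 16, 2, seed=5)
        for name in g1.layers:
            np.testing.assert_array_equal(g1.layer(name), g2.layer(name))

    def test_runoff_bounded_by_precip_all_months(self, landscape):
        for m in range(landscape.n_months):
            assert np.all(landscape.runoff(m) <= landscape.precip(m) + 1e-9)

    def test_invariants_hold(self, landscape):
        landscape.validate()
        slope = landscape.layer("slope_deg")
        assert slope.min() >= 0 and slope.max() <= 90
        soc = landscape.layer("soc_percent")
        assert soc.min() >= 0.1 and soc.max() <= 8.0

    def test_degenerate_dims_rejected(self):
        with pytest.raises(ValueError):
            synth.make_landscape(4, 4, 1)


class TestAiTable:
    def test_31_ais_have_printed_class_split(self):
        ais = synth.make_ai_table(31, seed=1)
        counts = pd.Series([a.ai_class for a in ais]).value_counts()
        assert counts["insecticide"] == 19
        assert counts["fungicide"] == 7
        assert counts["herbicide"] == 5

    def test_single_ai_in_valid_ranges(self):
        (ai,) = synth.make_ai_table(1, seed=2)
        assert 10 <= ai.koc <= 1e5
        assert 1 <= ai.dt50_soil_days <= 365

    def test_seed_determinism(self):
        a = synth.make_ai_table(5, seed=3)
        b = synth.make_ai_table(5, seed=3)
        assert a == b


class TestDistricts:
    def test_2x2_on_10x10_grid_has_25_cells_each(self):
        from pestmap.grids import rasterize_districts
        g = synth.make_landscape(10, 10, 1, seed=4)
        districts, _ = synth.make_districts(g, 2, 2, seed=4)
        labels = rasterize_districts(districts, g)
        for k in range(4):
            assert (labels == k).sum() == 25

    def test_stratum_populations_sum_to_district_totals(self, district_scene):
        _, _, pops, _ = district_scene
        assert list(pops.columns) == list(STRATA)
        assert (pops.sum(axis=1) >= 100).all()
        assert (pops > 0).all().all()

    def test_seed_determinism(self, district_scene):
        grid, districts, pops, _ = district_scene
        d2, p2 = synth.make_districts(grid, 10, 10, seed=7)
        pd.testing.assert_frame_equal(pops, p2)
        assert [d.district_id for d in districts] == [d.district_id for d in d2]


class TestSimulateCounts:
    def test_poisson_moment_check_null_model(self, district_scene):
        # beta1=0, no random effects: Y ~ Po(E*exp(b0))
        _, _, pops, graph = district_scene
        e = np.full(graph.n, 50.0)
        expo = np.zeros(graph.n)
        b0 = 0.3
        y, truth = synth.simulate_counts(e, expo, beta0=b0, beta1=0.0,
                                         tau_u=np.inf, tau_v=np.inf,
                                         graph=graph, seed=8)
        ratio = (y / e).mean()
        # Var(mean of Y_i/E_i) = exp(b0) * sum(1/E_i) / n^2
        se = np.sqrt(np.exp(b0) * np.sum(1.0 / e)) / graph.n
        assert abs(ratio - np.exp(b0)) < 3 * se

    def test_positive_beta1_induces_positive_correlation(self, district_scene):
        _, _, _, graph = district_scene
        e = np.full(graph.n, 30.0)
        rng = np.random.default_rng(9)
        expo = rng.standard_normal(graph.n)
        hits = 0
        for rep in range(20):
            y, _ = synth.simulate_counts(e, expo, beta0=0.0, beta1=1.0,
                                         tau_u=4.0, tau_v=16.0,
                                         graph=graph, seed=100 + rep)
            if np.corrcoef(expo, y / e)[0, 1] > 0:
                hits += 1
        assert hits >= 19

    def test_icar_sample_sums_to_zero(self, district_scene):
        _, _, _, graph = district_scene
        u = synth.icar_sample(graph, 2.0, np.random.default_rng(10))
        assert abs(u.sum()) < 1e-9

    def test_truth_round_trip(self, district_scene, tmp_path):
        _, _, _, graph = district_scene
        e = np.full(graph.n, 10.0)
        _, truth = synth.simulate_counts(e, np.zeros(graph.n), 0.1, 0.5,
                                         2.0, 8.0, graph, seed=11)
        p = tmp_path / "truth.json"
        truth.to_json(p)
        back = synth.SyntheticTruth.from_json(p)
        assert back == truth

    def test_seed_determinism(self, district_scene):
        _, _, _, graph = district_scene
        e = np.full(graph.n, 10.0)
        y1, _ = synth.simulate_counts(e, np.zeros(graph.n), 0.0, 0.0,
                                      1.0, 1.0, graph, seed=12)
        y2, _ = synth.simulate_counts(e, np.zeros(graph.n), 0.0, 0.0,
                                      1.0, 1.0, graph, seed=12)
        np.testing.assert_array_equal(y1, y2)


@pytest.fixture(scope="module")
def scene():
    g = synth.make_landscape(16, 16, 1, seed=13)
    return synth.make_districts(g, 4, 4, seed=13)


class TestRegistry:
    def test_duplicate_rate_drops_as_expected(self, scene):
        districts, pops = scene
        reg = synth.make_registry(districts, pops, {"endo_ecto_surface": 1.0},
                                  n_cases=1000, seed=14, duplicate_rate=0.1)
        _, dropped = curate(reg)
        n_dup = (dropped["reason"] == "duplicate").sum()
        # binomial(999, 0.1): allow 4 sd
        assert abs(n_dup - 100) < 4 * np.sqrt(1000 * 0.1 * 0.9)

    def test_lineage_mix_recovered_within_rounding(self, scene):
        districts, pops = scene
        mix = {"endo_ecto_surface": 0.366, "endo_ecto_parenchymal": 0.207,
               "non_mesenchymal_mesoderm": 0.202, "mesenchyme": 0.136,
               "neuroectoderm": 0.050, "primitive": 0.014,
               "EXCLUDED_undetermined": 0.023, "EXCLUDED_trophoblastic": 0.002}
        reg = synth.make_registry(districts, pops, mix, n_cases=20000, seed=15)
        table = stratify(reg, load_crosswalk())
        got = dict(zip(table["group"], table["percent"]))
        for g, share in mix.items():
            assert got[g] == pytest.approx(100 * share, abs=1.0)

    def test_seed_determinism(self, scene):
        districts, pops = scene
        r1 = synth.make_registry(districts, pops, {"mesenchyme": 1.0},
                                 n_cases=50, seed=16)
        r2 = synth.make_registry(districts, pops, {"mesenchyme": 1.0},
                                 n_cases=50, seed=16)
        pd.testing.assert_frame_equal(r1, r2)


class TestBiomonitoring:
    def test_noise_free_proxy_reproduces_univariate_moran(self):
        w = rook_grid_weights(6, 6)
        rng = np.random.default_rng(17)
        from scipy.ndimage import uniform_filter
        risk = uniform_filter(rng.normal(size=(6, 6)), 3).ravel()
        conc = synth.simulate_biomonitoring(36, risk + 10, noise_sd=0.0,
                                            seed=18, intercept=0.0, slope=2.0)
        i_bi = morans_i_bivariate(risk, conc, w)
        i_uni = morans_i_global(risk, w)
        assert i_bi == pytest.approx(i_uni, abs=1e-9)

    def test_concentrations_nonnegative(self):
        conc = synth.simulate_biomonitoring(100, np.zeros(100), noise_sd=50.0,
                                            seed=19)
        assert conc.min() >= 0.0

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            synth.simulate_biomonitoring(10, np.zeros(10), noise_sd=-1.0)
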