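"""Vertexwise GLM, cluster finding, and Monte Carlo clusterwise inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lobewise.design import RankDeficientError, build_design
from lobewise.glm import (
    ClusterConfig,
    extract_cluster_mean_spc,
    find_clusters,
    fit_vertexwise,
    monte_carlo_cluster_p,
)
from lobewise.mesh import icosphere, path_mesh
from lobewise.spc import ThicknessPair, symmetrized_percent_change
from lobewise.synthetic import CohortSimConfig, default_planted_cluster, simulate_cohort


def random_design(rng, n, names=("intercept", "x", "z1", "z2")):
    X = rng.standard_normal((n, len(names)))
    X[:, 0] = 1.0
    return pd.DataFrame(X, columns=list(names))


class TestFitVertexwise:
    def test_matches_normal_equations_and_statsmodels(self):
        """Closed-form oracle and statsmodels agree with the vectorized fit."""
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        for _ in range(10):
            n, V = 40, 7
            design = random_design(rng, n)
            Y = rng.standard_normal((n, V))
            fit = fit_vertexwise(Y, design, "x")
            X = design.to_numpy()
            for v in range(V):
                beta_ne = np.linalg.solve(X.T @ X, X.T @ Y[:, v])
                np.testing.assert_allclose(fit.beta[:, v], beta_ne, atol=1e-10)
                res = sm.OLS(Y[:, v], X).fit()
                np.testing.assert_allclose(fit.se[:, v], res.bse, atol=1e-10)
                np.testing.assert_allclose(fit.t[:, v], res.tvalues, atol=1e-10)
                np.testing.assert_allclose(fit.p[:, v], res.pvalues, atol=1e-10)

    def test_noiseless_planted_effect_recovered_exactly(self, ico162):
        pc = default_planted_cluster(ico162, seed_vertex=5, wmh_slope=-0.05)
        cfg = CohortSimConfig(n_subjects=100, seed=3, residual_sd=0.0,
                              planted_clusters={"c": pc})
        coh = simulate_cohort(cfg, ico162)
        design = build_design(coh.table, "wmh_parietal")
        fit = fit_vertexwise(coh.spc_true, design, "wmh_parietal")
        j = fit.focal_index()
        np.testing.assert_allclose(fit.beta[j][pc.vertices], -0.05, atol=1e-10)
        others = np.setdiff1d(np.arange(ico162.n_vertices), pc.vertices)
        np.testing.assert_allclose(fit.beta[j][others], 0.0, atol=1e-10)
        np.testing.assert_allclose(fit.se[j][pc.vertices], 0.0, atol=1e-8)

    def test_pure_predictor_outcome(self):
        rng = np.random.default_rng(1)
        design = random_design(rng, 30, ("intercept", "x"))
        y = (2.0 * design["x"].to_numpy())[:, None]
        fit = fit_vertexwise(y, design, "x")
        assert fit.beta[1, 0] == pytest.approx(2.0, abs=1e-12)
        assert fit.se[1, 0] == pytest.approx(0.0, abs=1e-10)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(2)
        design = random_design(rng, 30)
        design["dup"] = design["x"]
        with pytest.raises(RankDeficientError, match="dup"):
            fit_vertexwise(rng.standard_normal((30, 3)), design, "x")

    def test_global_null_pvalues_calibrated(self):
        # i.i.d. noise, beta = 0: per-vertex p uniform, so the fraction below
        # .01 lies within binomial error of .01
        rng = np.random.default_rng(7)
        n, V = 80, 4000
        design = random_design(rng, n)
        fit = fit_vertexwise(rng.standard_normal((n, V)), design, "x")
        frac = float(np.mean(fit.p[fit.focal_index()] < 0.01))
        assert abs(frac - 0.01) < 3 * np.sqrt(0.01 * 0.99 / V)


class TestFindClusters:
    def test_path_mesh_hand_example(self):
        mesh = path_mesh(5)
        t = np.array([3.0, 3.0, 0.0, 3.0, 0.0])
        cfg = ClusterConfig(iterations=100)
        clusters = find_clusters(t, mesh, cfg, dof=50, critical_value=2.0)
        got = sorted(tuple(c.vertices.tolist()) for c in clusters)
        assert got == [(0, 1), (3,)]
        by_extent = {tuple(c.vertices.tolist()): c.extent for c in clusters}
        assert by_extent[(0, 1)] == 2.0 and by_extent[(3,)] == 1.0

    def test_all_zero_map_has_no_clusters(self, ico162):
        cfg = ClusterConfig(iterations=100)
        assert find_clusters(np.zeros(ico162.n_vertices), ico162, cfg, 50) == []

    def test_opposite_signs_never_merge(self):
        mesh = path_mesh(2)
        cfg = ClusterConfig(iterations=100)
        clusters = find_clusters(np.array([3.0, -3.0]), mesh, cfg, 50,
                                 critical_value=2.0)
        assert len(clusters) == 2
        assert sorted(c.sign for c in clusters) == [-1, 1]

    def test_matches_networkx_bruteforce_on_random_meshes(self, ico162):
        import networkx as nx

        rng = np.random.default_rng(4)
        cfg = ClusterConfig(iterations=100, cluster_forming_p=0.05)
        g = nx.Graph()
        coo = ico162.adjacency.tocoo()
        g.add_edges_from(zip(coo.row.tolist(), coo.col.tolist()))
        for _ in range(5):
            t = rng.standard_normal(ico162.n_vertices) * 1.5
            crit = float(stats.t.ppf(1 - 0.05 / 2, 60))
            clusters = find_clusters(t, ico162, cfg, dof=60)
            expected = []
            for sign in (1, -1):
                supra = set(np.flatnonzero(sign * t > crit).tolist())
                sub = g.subgraph(supra)
                comps = [frozenset(c) for c in nx.connected_components(sub)]
                comps += [frozenset({v}) for v in supra if v not in g]
                expected.extend(comps)
            got = [frozenset(c.vertices.tolist()) for c in clusters]
            assert sorted(map(sorted, got)) == sorted(map(sorted, expected))


class TestMonteCarlo:
    @staticmethod
    def _cohort_fit(ico162, seed, planted):
        cfg = CohortSimConfig(n_subjects=120, seed=seed, planted_clusters=planted)
        coh = simulate_cohort(cfg, ico162)
        ivs = coh.table["interval_years"].to_numpy()
        spc = np.vstack([
            symmetrized_percent_change(
                ThicknessPair(coh.thickness_t1[i], coh.thickness_t2[i], ivs[i])
            )
            for i in range(len(ivs))
        ])
        design = build_design(coh.table, "wmh_parietal")
        return coh, spc, design

    def test_same_seed_identical_p_values(self, ico162):
        pc = default_planted_cluster(ico162, seed_vertex=2, wmh_slope=-0.2)
        _, spc, design = self._cohort_fit(ico162, 11, {"c": pc})
        fit = fit_vertexwise(spc, design, "wmh_parietal")
        cfg = ClusterConfig(iterations=120, seed=5)
        clusters = find_clusters(fit.focal_t, ico162, cfg, fit.dof)
        p1 = [c.p for c in monte_carlo_cluster_p(clusters, spc, design,
                                                 "wmh_parietal", ico162, cfg)]
        p2 = [c.p for c in monte_carlo_cluster_p(clusters, spc, design,
                                                 "wmh_parietal", ico162, cfg)]
        assert p1 == p2

    def test_p_floor_is_one_over_iterations_plus_one(self, ico162):
        # a strongly planted cluster beats every null maximum
        pc = default_planted_cluster(ico162, seed_vertex=2, n_rings=3,
                                     wmh_slope=-1.0)
        _, spc, design = self._cohort_fit(ico162, 13, {"c": pc})
        fit = fit_vertexwise(spc, design, "wmh_parietal")
        cfg = ClusterConfig(iterations=199, seed=1)
        clusters = find_clusters(fit.focal_t, ico162, cfg, fit.dof)
        out = monte_carlo_cluster_p(clusters, spc, design, "wmh_parietal",
                                    ico162, cfg)
        assert min(c.p for c in out) == pytest.approx(1 / 200)

    def test_smooth_noise_variant_runs_and_is_seeded(self, ico162):
        pc = default_planted_cluster(ico162, seed_vertex=2, wmh_slope=-0.3)
        _, spc, design = self._cohort_fit(ico162, 17, {"c": pc})
        fit = fit_vertexwise(spc, design, "wmh_parietal")
        cfg = ClusterConfig(iterations=120, seed=8, method="smooth-noise")
        clusters = find_clusters(fit.focal_t, ico162, cfg, fit.dof)
        out1 = monte_carlo_cluster_p(clusters, spc, design, "wmh_parietal",
                                     ico162, cfg)
        out2 = monte_carlo_cluster_p(clusters, spc, design, "wmh_parietal",
                                     ico162, cfg)
        assert [c.p for c in out1] == [c.p for c in out2]
        assert all(0 < c.p <= 1 for c in out1)

    def test_too_few_iterations_refused(self):
        with pytest.raises(ValueError):
            ClusterConfig(iterations=99)


class TestExtractClusterMean:
    def test_constant_and_two_vertex_examples(self, ico162):
        from lobewise.glm import Cluster

        maps = np.full((4, ico162.n_vertices), 1.5)
        cl = Cluster(vertices=np.array([0, 1]), sign=-1, peak_t=-3.0,
                     extent=2.0, area_mm2=1.0)
        np.testing.assert_allclose(extract_cluster_mean_spc(maps, cl), 1.5)
        maps2 = np.zeros((1, ico162.n_vertices))
        maps2[0, 0], maps2[0, 1] = -2.0, -4.0
        assert extract_cluster_mean_spc(maps2, cl)[0] == pytest.approx(-3.0)

    def test_empty_cluster_fails(self):
        from lobewise.glm import Cluster

        cl = Cluster(vertices=np.array([], dtype=int), sign=1, peak_t=0.0,
                     extent=0.0, area_mm2=0.0)
        with pytest.raises(ValueError):
            extract_cluster_mean_spc(np.zeros((2, 5)), cl)

    def test_noiseless_cluster_mean_equals_planted_predictor(self, ico162):
        from lobewise.glm import Cluster

        pc = default_planted_cluster(ico162, seed_vertex=9, wmh_slope=-0.08)
        cfg = CohortSimConfig(n_subjects=60, seed=21, residual_sd=0.0,
                              planted_clusters={"c": pc})
        coh = simulate_cohort(cfg, ico162)
        cl = Cluster(vertices=pc.vertices, sign=-1, peak_t=0.0,
                     extent=float(len(pc.vertices)), area_mm2=0.0)
        got = extract_cluster_mean_spc(coh.spc_true, cl)
        t = coh.table
        lin = (cfg.spc_intercept - 0.08 * t["wmh_parietal"] - 0.01 * t["age"]
               + 0.10 * t["female"] - 0.15 * t["apoe4"]
               + 0.10 * t["entorhinal_baseline"])
        np.testing.assert_allclose(got, lin, atol=1e-10)
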