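"""Quadrat statistics, cross-PCF estimator, bootstrap calls, networks."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from imctme.io import (ConfigError, InsufficientDataError, PipelineError,
                       RoiGeometry)
from imctme.neighbourhoods import build_spatial_graph
from imctme.spatial import (CrossPCFResult, adjacency_network, bh_adjust,
                            bootstrap_pcf, bootstrap_pcf_pooled, cross_pcf,
                            disc_window_area, pct_connections,
                            qcm_significant_pairs,
                            quadrat_correlation_matrix, quadrat_counts,
                            topographical_correlation_map)

WINDOW = (1000.0, 1000.0)
GEOM = RoiGeometry("r1", "c1", 1000.0, 1000.0)


def make_obs(points: dict) -> pd.DataFrame:
    rows = []
    for pop, xy in points.items():
        for x, y in xy:
            rows.append({"cell_id": f"{pop}{len(rows)}", "case_id": "c1",
                         "roi_id": "r1", "x_um": float(x), "y_um": float(y),
                         "population_label": pop})
    return pd.DataFrame(rows)


class TestQuadratCounts:
    def test_grid_size_full_quadrats_only(self):
        obs = make_obs({"A": [(5, 5)]})
        counts = quadrat_counts(obs, GEOM, side_um=100)
        assert len(counts) == 100
        geom = RoiGeometry("r1", "c1", 950.0, 1000.0)  # partial column drops
        assert len(quadrat_counts(obs, geom, side_um=100)) == 90

    def test_half_open_boundary_assignment(self):
        obs = make_obs({"A": [(100.0, 0.0)]})  # exactly on interior boundary
        counts = quadrat_counts(obs, GEOM, side_um=100)
        assert counts.loc[(1, 0), "A"] == 1
        assert counts.loc[(0, 0), "A"] == 0

    def test_hand_binned_toy_layout(self):
        obs = make_obs({"A": [(10, 10), (150, 20), (150, 30)],
                        "B": [(10, 10), (990, 990)]})
        counts = quadrat_counts(obs, GEOM, side_um=100)
        assert counts.loc[(0, 0), "A"] == 1
        assert counts.loc[(1, 0), "A"] == 2
        assert counts.loc[(0, 0), "B"] == 1
        assert counts.loc[(9, 9), "B"] == 1
        assert counts.to_numpy().sum() == 5

    def test_roi_smaller_than_quadrat_warns_empty(self, caplog):
        geom = RoiGeometry("r1", "c1", 50.0, 50.0)
        counts = quadrat_counts(make_obs({"A": [(10, 10)]}), geom,
                                side_um=100)
        assert counts.empty


class TestQuadratCorrelation:
    def test_duplicated_population_fully_correlated(self, rng):
        base = rng.poisson(5, 36)
        counts = pd.DataFrame({"A": base, "B": base,
                               "C": rng.poisson(5, 36)})
        res = quadrat_correlation_matrix(counts)
        assert res.r.loc["A", "B"] == pytest.approx(1.0)
        assert res.gated.loc["A", "B"] == pytest.approx(1.0)

    def test_matrix_symmetric_and_gating_consistent(self, rng):
        counts = pd.DataFrame(rng.poisson(4, (50, 4)), columns=list("ABCD"))
        res = quadrat_correlation_matrix(counts)
        np.testing.assert_allclose(res.r, res.r.T)
        sig = res.gated.to_numpy() != 0
        np.fill_diagonal(sig, False)
        assert (res.p_adj.to_numpy()[sig] < res.alpha).all()

    def test_pearson_matches_formula_oracle(self, rng):
        counts = pd.DataFrame({"A": rng.poisson(6, 12).astype(float),
                               "B": rng.poisson(6, 12).astype(float)})
        res = quadrat_correlation_matrix(counts)
        x, y = counts["A"], counts["B"]
        r_oracle = (((x - x.mean()) * (y - y.mean())).sum() /
                    np.sqrt(((x - x.mean()) ** 2).sum() *
                            ((y - y.mean()) ** 2).sum()))
        assert res.r.loc["A", "B"] == pytest.approx(r_oracle, abs=1e-12)

    def test_zero_variance_population_noted(self, rng):
        counts = pd.DataFrame({"A": np.full(20, 3.0),
                               "B": rng.poisson(5, 20)})
        res = quadrat_correlation_matrix(counts)
        assert res.r.loc["A", "B"] == 0.0
        assert any("zero variance" in n for n in res.notes)

    def test_too_few_quadrats_raises(self):
        with pytest.raises(InsufficientDataError):
            quadrat_correlation_matrix(pd.DataFrame({"A": [1, 2]}))

    def test_independent_populations_rarely_gated(self, rng):
        fp = []
        for rep in range(10):
            counts = pd.DataFrame(
                np.random.default_rng(rep).poisson(5, (500, 6)),
                columns=list("ABCDEF"))
            res = quadrat_correlation_matrix(counts)
            sig = res.gated.to_numpy()[np.triu_indices(6, 1)] != 0
            fp.append(sig.mean())
        assert np.mean(fp) <= 0.05


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), 0.2)

    def test_hand_step_up_m4(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_matches_reference_implementation_exhaustively(self, rng):
        from statsmodels.stats.multitest import multipletests
        for n in range(1, 13):
            p = rng.uniform(0, 1, n)
            np.testing.assert_allclose(
                bh_adjust(p), multipletests(p, method="fdr_bh")[1])

    def test_order_preserving(self, rng):
        p = np.sort(rng.uniform(0, 1, 10))
        adj = bh_adjust(p)
        assert (np.diff(adj) >= -1e-15).all()

    def test_out_of_range_raises(self):
        with pytest.raises(PipelineError):
            bh_adjust([0.5, 1.2])


class TestCrossPCF:
    def test_matches_brute_force_oracle_interior(self, rng):
        # points kept ≥ 100 µm from every border so annuli (r ≤ 80) are
        # whole: the oracle uses exact π-annulus areas
        S = rng.uniform(300, 700, (8, 2))
        R = rng.uniform(300, 700, (11, 2))
        dr, r_max = 10.0, 80.0
        edges = np.arange(0, r_max + dr / 2, dr)
        oracle = np.zeros(len(edges) - 1)
        for b in range(len(edges) - 1):
            total = 0.0
            for a in S:
                d = np.linalg.norm(R - a, axis=1)
                n = ((d >= edges[b]) & (d < edges[b + 1])).sum()
                total += n / (np.pi * (edges[b + 1] ** 2 - edges[b] ** 2))
            oracle[b] = 1e6 / (len(S) * len(R)) * total
        _, g = cross_pcf(S, R, WINDOW, r_max=r_max, dr=dr)
        np.testing.assert_allclose(g, oracle, atol=1e-9)

    def test_border_correction_matches_polygon_oracle(self, rng):
        from shapely.geometry import Point, box
        S = rng.uniform(0, 1000, (6, 2))
        R = rng.uniform(0, 1000, (9, 2))
        dr, r_max = 20.0, 100.0
        edges = np.arange(0, r_max + dr / 2, dr)
        win = box(0, 0, *WINDOW)
        oracle = np.zeros(len(edges) - 1)
        for b in range(len(edges) - 1):
            total = 0.0
            for a in S:
                d = np.linalg.norm(R - a, axis=1)
                n = ((d >= edges[b]) & (d < edges[b + 1])).sum()
                ann = (Point(a).buffer(edges[b + 1], quad_segs=256)
                       .difference(Point(a).buffer(edges[b], quad_segs=256)))
                total += n / ann.intersection(win).area
            oracle[b] = 1e6 / (len(S) * len(R)) * total
        _, g = cross_pcf(S, R, WINDOW, r_max=r_max, dr=dr)
        np.testing.assert_allclose(g, oracle, rtol=1e-4)

    def test_receivers_at_fixed_15um_spike_in_second_bin(self, rng):
        S = rng.uniform(200, 800, (50, 2))
        angles = rng.uniform(0, 2 * np.pi, 50)
        R = S + 15.0 * np.column_stack([np.cos(angles), np.sin(angles)])
        r, g = cross_pcf(S, R, WINDOW, r_max=50, dr=10)
        spike_bin = int(np.argmax(g))
        assert r[spike_bin] == 10.0  # [10, 20) contains 15 µm
        assert g[spike_bin] > 3 * np.delete(g, spike_bin).max()

    def test_csr_estimate_near_one(self):
        gs = []
        for s in range(5):
            rng = np.random.default_rng(s)
            A = rng.uniform(0, 1000, (1500, 2))
            B = rng.uniform(0, 1000, (1500, 2))
            _, g = cross_pcf(A, B, WINDOW)
            gs.append(g)
        mean_g = np.mean(gs, axis=0)
        assert (np.abs(mean_g[1:] - 1.0) < 0.1).all()

    def test_auto_pcf_excludes_self_pairs(self, rng):
        A = rng.uniform(0, 1000, (400, 2))
        _, g = cross_pcf(A, A, WINDOW, r_max=100)
        assert (np.abs(g[2:] - 1.0) < 0.4).all()  # CSR-like, no self spike

    def test_empty_set_and_bad_dr_raise(self, rng):
        A = rng.uniform(0, 10, (5, 2))
        with pytest.raises(InsufficientDataError):
            cross_pcf(np.empty((0, 2)), A, WINDOW)
        with pytest.raises(ConfigError):
            cross_pcf(A, A, WINDOW, dr=0)

    def test_disc_window_area_quarter_circle_corner(self):
        # disc centred in a corner: only a quarter lies inside
        area = disc_window_area(np.array([[0.0, 0.0]]), np.array(50.0),
                                WINDOW)
        assert float(area[0]) == pytest.approx(np.pi * 50 ** 2 / 4)


class TestBootstrapPCF:
    def test_deterministic_given_seed(self, rng):
        A = rng.uniform(0, 1000, (150, 2))
        B = rng.uniform(0, 1000, (150, 2))
        r1 = bootstrap_pcf(A, B, WINDOW, n_boot=60, seed=3)
        r2 = bootstrap_pcf(A, B, WINDOW, n_boot=60, seed=3)
        np.testing.assert_array_equal(r1.ci_low, r2.ci_low)
        assert r1.call == r2.call

    def test_low_n_boot_warns(self, rng, caplog):
        A = rng.uniform(0, 1000, (50, 2))
        bootstrap_pcf(A, A.copy(), WINDOW, n_boot=20, seed=0)
        assert any("unstable" in rec.message for rec in caplog.records)

    def test_pooled_single_roi_equals_plain_bootstrap(self, rng):
        A = rng.uniform(0, 1000, (120, 2))
        B = rng.uniform(0, 1000, (130, 2))
        plain = bootstrap_pcf(A, B, WINDOW, n_boot=80, seed=9)
        pooled = bootstrap_pcf_pooled([(A, B, WINDOW)], n_boot=80, seed=9)
        np.testing.assert_allclose(plain.g, pooled.g)
        np.testing.assert_allclose(plain.ci_low, pooled.ci_low)
        assert plain.call == pooled.call

    def test_call_invariants(self, rng):
        A = rng.uniform(0, 1000, (200, 2))
        B = rng.uniform(0, 1000, (200, 2))
        res = bootstrap_pcf(A, B, WINDOW, n_boot=100, seed=1)
        bin20 = 2  # [20, 30) contains r = 20 at dr = 10
        if res.call == "positive":
            assert res.ci_low[bin20] > 1
        elif res.call == "negative":
            assert res.ci_high[bin20] < 1


class TestTopographicalMap:
    def test_colocalized_pair_scores_positive_in_their_tile(self, rng):
        # S and R concentrate together in one tile of an ROI otherwise
        # occupied by a background population
        pts = [(50 + rng.uniform(-20, 20), 50 + rng.uniform(-20, 20))
               for _ in range(20)]
        background = [tuple(p) for p in rng.uniform(0, 1000, (200, 2))]
        obs = make_obs({"S": pts[:10], "R": pts[10:], "O": background})
        z = topographical_correlation_map(obs, GEOM, "S", "R", seed=0)
        assert z[0, 0] > 2.0
        far = z.copy()
        far[0, 0] = 0.0
        assert np.abs(far).max() < z[0, 0]

    def test_random_labels_score_near_zero(self, rng):
        obs = make_obs({"S": rng.uniform(0, 1000, (100, 2)),
                        "R": rng.uniform(0, 1000, (100, 2))})
        z = topographical_correlation_map(obs, GEOM, "S", "R", seed=1)
        assert abs(z.mean()) < 0.3

    def test_matches_exhaustive_permutation_oracle(self):
        # 4 cells in 2 tiles; enumerate every label arrangement
        geom = RoiGeometry("r1", "c1", 200.0, 100.0)
        obs = make_obs({"S": [(10, 10), (110, 10)], "R": [(20, 20),
                                                          (120, 20)]})
        labels = obs["population_label"].to_numpy()
        tile = (obs["x_um"] // 100).astype(int).to_numpy()

        def co_counts(lab):
            out = np.zeros(2)
            for t in (0, 1):
                out[t] = ((lab == "S") & (tile == t)).sum() * \
                         ((lab == "R") & (tile == t)).sum()
            return out

        obs_counts = co_counts(labels)
        perms = np.array([co_counts(np.array(p))
                          for p in set(permutations(labels))])
        mean, sd = perms.mean(axis=0), perms.std(axis=0)
        oracle = np.where(sd > 0, (obs_counts - mean) / sd, 0.0)
        z = topographical_correlation_map(obs, geom, "S", "R",
                                          n_perm=40000, seed=2)
        np.testing.assert_allclose(z[0], oracle, atol=0.05)

    def test_absent_population_zero_map(self, rng, caplog):
        obs = make_obs({"S": rng.uniform(0, 1000, (10, 2))})
        z = topographical_correlation_map(obs, GEOM, "S", "missing", seed=0)
        assert (z == 0).all()


class TestAdjacencyNetwork:
    def two_type_graph(self):
        # 6 cells alternating types on a line, chain edges only
        xy = np.column_stack([np.arange(6) * 10.0, np.zeros(6)])
        ids = [str(i) for i in range(6)]
        g = build_spatial_graph(xy, ids, prune_percentile=100)
        # keep only consecutive edges (Delaunay on collinear → complete)
        keep = np.array([abs(i - j) == 1 for i, j in g.edges])
        g.edges, g.lengths = g.edges[keep], g.lengths[keep]
        labels = np.array(["A", "B"] * 3)
        return g, labels

    def test_alternating_chain_pct_connections(self):
        g, labels = self.two_type_graph()
        pct = pct_connections([g], [labels])
        # chain 0-1-2-3-4-5: every edge joins A to B
        assert pct.loc["A", "B"] == pytest.approx(100.0)
        assert pct.loc["B", "A"] == pytest.approx(100.0)
        assert pct.loc["A", "A"] == 0.0

    def test_hand_counted_mixed_graph(self):
        xy = np.array([[0, 0], [10, 0], [5, 8], [20, 0], [25, 8], [30, 0.0]])
        g = build_spatial_graph(xy, [str(i) for i in range(6)],
                                prune_percentile=100)
        labels = np.array(["A", "A", "A", "B", "B", "B"])
        pct = pct_connections([g], [labels])
        a, b = (np.array([labels[i] for i in g.edges[:, 0]]),
                np.array([labels[j] for j in g.edges[:, 1]]))
        n_ab = ((a == "A") & (b == "B") | (a == "B") & (b == "A")).sum()
        n_aa = ((a == "A") & (b == "A")).sum()
        incident_a = ((a == "A") | (b == "A")).sum()
        assert pct.loc["A", "B"] == pytest.approx(100 * n_ab / incident_a)
        assert pct.loc["A", "A"] == pytest.approx(100 * n_aa / incident_a)

    def test_pct_connections_rows_sum_to_at_most_100(self, rng):
        xy = rng.uniform(0, 500, (200, 2))
        g = build_spatial_graph(xy, [str(i) for i in range(200)])
        labels = rng.choice(["A", "B", "C"], 200)
        pct = pct_connections([g], [labels])
        assert (pct.sum(axis=1) <= 100 + 1e-9).all()

    def fake_pcf(self, s, r, call):
        return CrossPCFResult(s, r, np.arange(0, 300, 10.0), np.ones(30),
                              np.ones(30) * 0.9, np.ones(30) * 1.1, 1.5,
                              call, 100)

    def test_edges_require_joint_significance(self):
        g, labels = self.two_type_graph()
        pcf = {("A", "B"): self.fake_pcf("A", "B", "positive"),
               ("B", "A"): self.fake_pcf("B", "A", "none")}
        net = adjacency_network({frozenset(("A", "B"))}, pcf, [g], [labels])
        assert net.has_edge("A", "B")
        assert not net.has_edge("B", "A")
        empty = adjacency_network(set(), pcf, [g], [labels])
        assert empty.number_of_edges() == 0

    def test_qcm_pair_without_pcf_skipped(self, caplog):
        g, labels = self.two_type_graph()
        net = adjacency_network({frozenset(("A", "B"))}, {}, [g], [labels])
        assert net.number_of_edges() == 0


class TestQcmSignificantPairs:
    def test_majority_fraction_rule(self, rng):
        results = []
        for rep in range(4):
            base = rng.poisson(5, 40)
            counts = pd.DataFrame({
                "A": base, "B": base + rng.poisson(1, 40),
                "C": rng.poisson(5, 40)})
            results.append(quadrat_correlation_matrix(counts))
        pairs = qcm_significant_pairs(results)
        assert frozenset(("A", "B")) in pairs
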