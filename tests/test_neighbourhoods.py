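"""Spatial graphs, l-step features, FMI, stability clustering, proximity."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from imctme.io import CaseMetadata, InsufficientDataError, RoiGeometry
from imctme.neighbourhoods import (annotate_neighbourhood_clusters,
                                   build_spatial_graph,
                                   cluster_neighbourhoods, fowlkes_mallows,
                                   l_step_neighbourhood,
                                   neighbourhood_features,
                                   neighbourhood_group_comparison,
                                   neighbourhood_proportions,
                                   neighbourhood_proximity)
from imctme.synthetic import plant_neighbourhood_mosaic


def graph_of(coords, prune=99.0):
    coords = np.asarray(coords, dtype=float)
    return build_spatial_graph(coords, [str(i) for i in range(len(coords))],
                               prune_percentile=prune)


class TestSpatialGraph:
    def test_triangle_has_three_edges(self):
        g = graph_of([[0, 0], [10, 0], [5, 8]])
        assert g.n_edges == 3

    def test_pruning_removes_long_edges(self, rng):
        xy = rng.uniform(0, 100, (100, 2))
        g = graph_of(xy, prune=90)
        assert (g.lengths <= g.prune_threshold_um).all()

    def test_pruning_at_100th_percentile_keeps_all(self, rng):
        xy = rng.uniform(0, 100, (50, 2))
        g_full = graph_of(xy, prune=100)
        g_cut = graph_of(xy, prune=99)
        assert g_cut.n_edges <= g_full.n_edges

    def test_duplicate_coordinates_jittered(self, caplog):
        xy = np.array([[0, 0], [0, 0], [10, 0], [5, 8.0]])
        g = graph_of(xy)
        assert g.n_nodes == 4

    def test_two_cells_fall_back_to_single_edge(self):
        g = graph_of([[0, 0], [3, 4.0]])
        assert g.n_edges == 1
        assert g.lengths[0] == pytest.approx(5.0)


class TestLStepNeighbourhood:
    def test_three_steps_on_path(self):
        # path A–B–C–D–E as an explicit adjacency list
        adj = [np.array([1]), np.array([0, 2]), np.array([1, 3]),
               np.array([2, 4]), np.array([3])]
        assert l_step_neighbourhood(adj, 0, 3) == {0, 1, 2, 3}

    def test_isolated_node_is_itself(self):
        adj = [np.array([], dtype=int)]
        assert l_step_neighbourhood(adj, 0, 3) == {0}

    @pytest.mark.parametrize("l", [1, 2, 3, 5])
    def test_matches_bfs_oracle_on_random_graph(self, l, rng):
        import networkx as nx
        xy = rng.uniform(0, 200, (80, 2))
        g = graph_of(xy)
        adj = g.adjacency()
        nxg = nx.Graph()
        nxg.add_nodes_from(range(g.n_nodes))
        nxg.add_edges_from(map(tuple, g.edges))
        for node in range(0, 80, 7):
            oracle = {n for n, d in
                      nx.single_source_shortest_path_length(nxg, node,
                                                            cutoff=l).items()}
            assert l_step_neighbourhood(adj, node, l) == oracle


class TestNeighbourhoodFeatures:
    def test_single_population_composition_is_one(self, rng):
        xy = rng.uniform(0, 100, (30, 2))
        g = graph_of(xy)
        feats = neighbourhood_features(g, ["A"] * 30, ["A", "B"])
        assert (feats["comp_A"] == 1.0).all()
        assert (feats["comp_B"] == 0.0).all()

    def test_unit_square_hand_geometry(self):
        xy = np.array([[0, 0], [1, 0], [0, 1], [1, 1.0]])
        g = graph_of(xy, prune=100)
        feats = neighbourhood_features(g, list("AAAA"), ["A"], l=3)
        # all four corners reachable: hull area 1 µm², centroid dist √2/2
        assert feats["hull_area_um2"].iloc[0] == pytest.approx(1.0)
        assert feats["dist_mean_um"].iloc[0] == pytest.approx(np.sqrt(2) / 2)
        assert feats["dist_sd_um"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_composition_sums_to_one(self, rng):
        xy = rng.uniform(0, 300, (120, 2))
        labels = rng.choice(["A", "B", "C"], 120)
        g = graph_of(xy)
        feats = neighbourhood_features(g, labels, ["A", "B", "C"])
        sums = feats[["comp_A", "comp_B", "comp_C"]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_tiny_neighbourhood_degenerate_shape(self):
        xy = np.array([[0, 0], [5, 0.0]])
        g = graph_of(xy)
        feats = neighbourhood_features(g, ["A", "A"], ["A"], l=1)
        assert (feats["hull_area_um2"] == 0).all()
        assert (feats["circularity"] == 1).all()


class TestFowlkesMallows:
    def test_identical_partitions_score_one(self):
        assert fowlkes_mallows([0, 0, 1, 1, 2], [5, 5, 9, 9, 7]) == 1.0

    def test_crossed_pairs_score_zero(self):
        # {12|34} vs {13|24}: no co-clustered pair shared
        assert fowlkes_mallows([0, 0, 1, 1], [0, 1, 0, 1]) == 0.0

    def test_hand_enumerated_value(self):
        # {123|4} vs {12|34} over all 6 item pairs: (1,2) co-clustered in
        # both (TP=1); (1,3), (2,3) only in the first (FP=2); (3,4) only in
        # the second (FN=1) → FMI = 1/√((1+2)(1+1)) = 1/√6
        assert fowlkes_mallows([0, 0, 0, 1], [0, 0, 1, 1]) == pytest.approx(
            1 / np.sqrt(6))

    def test_symmetric_and_matches_sklearn(self, rng):
        from sklearn.metrics import fowlkes_mallows_score
        a = rng.integers(0, 4, 50)
        b = rng.integers(0, 3, 50)
        assert fowlkes_mallows(a, b) == pytest.approx(fowlkes_mallows(b, a))
        assert fowlkes_mallows(a, b) == pytest.approx(
            fowlkes_mallows_score(a, b))

    def test_fewer_than_two_items_raises(self):
        with pytest.raises(InsufficientDataError):
            fowlkes_mallows([0], [0])


class TestStabilityClustering:
    def test_trivial_single_k(self, rng):
        feats = pd.DataFrame({"comp_A": rng.uniform(0, 1, 40),
                              "hull_area_um2": rng.uniform(0, 1, 40)})
        model = cluster_neighbourhoods(feats, K_range=[1], seed=0)
        assert model.K == 1
        assert set(model.labels) == {0}

    def test_deterministic_given_seed(self, rng):
        feats = pd.DataFrame(rng.normal(size=(80, 4)),
                             columns=["comp_A", "comp_B", "x", "y"])
        m1 = cluster_neighbourhoods(feats, K_range=[2, 3], seed=5)
        m2 = cluster_neighbourhoods(feats, K_range=[2, 3], seed=5)
        assert m1.K == m2.K
        assert (m1.labels == m2.labels).all()

    def test_infeasible_k_skipped(self, rng, caplog):
        feats = pd.DataFrame(rng.normal(size=(8, 2)),
                             columns=["comp_A", "comp_B"])
        model = cluster_neighbourhoods(feats, K_range=[2, 50], seed=0)
        assert 50 not in model.stability_by_K

    def test_mosaic_domains_recovered(self):
        from sklearn.metrics import adjusted_rand_score
        geom = RoiGeometry("m", "case", 700.0, 700.0)
        table, truth = plant_neighbourhood_mosaic(
            3, geom, [{"A": 1.0}, {"B": 1.0}, {"C": 1.0}], seed=2)
        g = build_spatial_graph(table.coords(),
                                table.obs["cell_id"].to_numpy())
        feats = neighbourhood_features(
            g, table.obs["population_label"].to_numpy(), ["A", "B", "C"])
        model = cluster_neighbourhoods(feats, K_range=range(2, 7), seed=3)
        assert model.K == 3
        ari = adjusted_rand_score(truth.cell["true_domain"], model.labels)
        assert ari >= 0.8


class TestNeighbourhoodAnnotation:
    HIER = {"schwann": "neoplastic", "tam": "myeloid", "vessel": "vascular",
            "ki67": "proliferative"}

    def test_global_composition_gives_unit_fold_change(self):
        pops = np.array(["schwann"] * 6 + ["tam"] * 6)
        nbhd = np.array([0, 1] * 6)
        ann = annotate_neighbourhood_clusters(nbhd, pops, self.HIER)
        for a in ann.values():
            assert all(fc == pytest.approx(1.0) for fc in
                       a.fold_change.values())

    def test_pure_schwann_cluster_is_tumour_enriched(self):
        pops = np.array(["schwann"] * 5 + ["tam"] * 5)
        nbhd = np.array([0] * 5 + [1] * 5)
        ann = annotate_neighbourhood_clusters(nbhd, pops, self.HIER)
        assert ann[0].category == "tumour_enriched"
        assert not ann[0].proliferative
        assert ann[1].category == "immune_enriched"

    def test_fold_changes_match_hand_ratios(self):
        pops = np.array(["schwann", "schwann", "tam", "ki67",
                         "schwann", "tam", "tam", "tam"])
        nbhd = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        ann = annotate_neighbourhood_clusters(nbhd, pops, self.HIER)
        # cluster 0: schwann 2/4 vs overall 3/8 → FC = 4/3
        assert ann[0].fold_change["schwann"] == pytest.approx((2 / 4) / (3 / 8))
        assert ann[0].fold_change["ki67"] == pytest.approx((1 / 4) / (1 / 8))
        assert ann[0].proliferative
        assert not ann[1].proliferative


class TestNeighbourhoodProximity:
    def test_single_label_oe_near_one(self, rng):
        xy = rng.uniform(0, 500, (200, 2))
        g = graph_of(xy)
        oe = neighbourhood_proximity([g], [np.zeros(200, dtype=int)],
                                     n_perm=100, seed=0)
        assert oe.iloc[0, 0] == pytest.approx(1.0)

    def test_labels_split_by_component_gives_zero_cross(self, rng):
        # two clusters 10 mm apart; the few bridging Delaunay edges are the
        # longest links and pruning removes them all
        xy = np.vstack([rng.uniform(0, 50, (15, 2)),
                        rng.uniform(10000, 10050, (15, 2))])
        g = graph_of(xy, prune=80)
        assert g.lengths.max() < 5000  # no bridge survived
        labels = np.repeat([0, 1], 15)
        oe = neighbourhood_proximity([g], [labels], n_perm=200, seed=0)
        assert oe.loc[0, 1] == 0.0
        assert oe.loc[1, 0] == 0.0

    def test_expected_matches_exhaustive_permutation_oracle(self, rng):
        xy = rng.uniform(0, 100, (6, 2))
        g = graph_of(xy, prune=100)
        labels = np.array([0, 0, 0, 1, 1, 1])

        def tally(codes):
            m = np.zeros((2, 2))
            for i, j in g.edges:
                m[codes[i], codes[j]] += 1
                m[codes[j], codes[i]] += 1
            return m

        obs = tally(labels)
        perms = {p: None for p in permutations(labels)}
        exp = np.mean([tally(np.array(p)) for p in perms], axis=0)
        oracle = np.where(exp > 0, obs / exp, 0.0)
        oe = neighbourhood_proximity([g], [labels], n_perm=30000, seed=1)
        np.testing.assert_allclose(oe.to_numpy(), oracle, atol=0.02)

    def test_random_labels_oe_within_tolerance(self, rng):
        xy = rng.uniform(0, 800, (400, 2))
        g = graph_of(xy)
        assert g.n_edges >= 500
        labels = rng.choice(["a", "b", "c"], 400)
        oe = neighbourhood_proximity([g], [labels], n_perm=1000, seed=2)
        assert np.abs(oe.to_numpy() - 1.0).max() <= 0.1


class TestGroupComparison:
    def cases(self):
        return ([CaseMetadata(f"s{i}", "F", 40, 1.0, 0.0) for i in range(4)]
                + [CaseMetadata(f"g{i}", "M", 50, 1.0, 100.0)
                   for i in range(4)])

    def test_proportions_sum_to_one_per_case(self, rng):
        obs = pd.DataFrame({
            "case_id": rng.choice([c.case_id for c in self.cases()], 400),
            "nbhd_label": rng.integers(0, 5, 400)})
        props = neighbourhood_proportions(obs)
        np.testing.assert_allclose(props.sum(axis=1), 1.0)

    def test_identical_groups_not_significant(self, rng):
        from imctme.neighbourhoods import NeighbourhoodAnnotation
        cases = self.cases()
        rows = []
        for c in cases:
            rows += [{"case_id": c.case_id, "nbhd_label": k}
                     for k in range(3) for _ in range(20)]
        obs = pd.DataFrame(rows)
        ann = {k: NeighbourhoodAnnotation({}, "tumour_enriched", False, ())
               for k in range(3)}
        out = neighbourhood_group_comparison(obs, ann, cases)
        assert (out["per_cluster"]["p"] > 0.9).all()

    def test_planted_immune_shift_detected(self):
        """Growing cases with doubled immune-neighbourhood occupancy are
        flagged by the per-cluster comparison and by the group × category
        interaction at n = 8 cases, in ≥ 80% of replicates."""
        from imctme.neighbourhoods import NeighbourhoodAnnotation
        ann = {0: NeighbourhoodAnnotation({}, "tumour_enriched", False, ()),
               1: NeighbourhoodAnnotation({}, "immune_enriched", True, ()),
               2: NeighbourhoodAnnotation({}, "vasculature_enriched",
                                          False, ())}
        cases = self.cases()
        cls = {c.case_id: c.classification for c in cases}
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            rng = np.random.default_rng(rep)
            rows = []
            for c in cases:
                # immune cluster doubled in growing: 0.25 → 0.50 occupancy
                p_immune = 0.5 if cls[c.case_id] == "growing" else 0.25
                probs = [0.85 - p_immune, p_immune, 0.15]
                counts = rng.multinomial(800, probs)
                for k, n in enumerate(counts):
                    rows += [{"case_id": c.case_id, "nbhd_label": k}] * n
            out = neighbourhood_group_comparison(pd.DataFrame(rows), ann,
                                                 cases)
            per = out["per_cluster"].set_index("nbhd")
            immune_hit = (per.loc[1, "p"] < 0.05 and
                          per.loc[1, "mean_growing"] > per.loc[1,
                                                              "mean_static"])
            anova = out["category_anova"]
            hits += immune_hit and anova is not None and anova.p < 0.05
        assert hits >= 16
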