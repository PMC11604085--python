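"""Cell-type neighbourhood analysis.

Each ROI's cells are joined by a Delaunay triangulation whose long links are
removed at the 99th percentile of that ROI's edge lengths.  A cell's
*neighbourhood* is every cell within l = 3 graph steps (inclusive of the
target).  Neighbourhoods are summarized by four feature groups —

* composition: fraction of each population among the members,
* shape: convex-hull area (µm²) and circularity 4πA/P² ∈ (0, 1],
* distribution: mean and sd of member distances to the neighbourhood centroid,
* proximity: mean length of graph edges internal to the neighbourhood —

and clustered with a full-covariance Gaussian mixture model.  The number of
clusters K is selected by stability: for every candidate K the model is
refitted on random 80% subsamples and the mean pairwise Fowlkes–Mallows
index of the fits (on shared cells) is the stability score; the most stable
K wins, ties to the smaller K.  Clusters are annotated by population
fold-change enrichment (FC ≥ 1 = enriched) into tumour-, vasculature- or
immune-enriched, and proliferative or not.  Spatial affinity between
neighbourhood clusters is scored as observed/expected edge counts against a
within-ROI label-permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay, QhullError

from .io import CellTable, ConfigError, InsufficientDataError, PipelineError
from .quantify import GroupComparisonResult, two_way_anova

logger = logging.getLogger("imctme")

DEFAULT_PRUNE_PERCENTILE = 99.0
DEFAULT_STEPS = 3
CATEGORY_OF_HIERARCHY = {"neoplastic": "tumour_enriched",
                         "vascular": "vasculature_enriched",
                         "myeloid": "immune_enriched",
                         "lymphoid": "immune_enriched"}


# ---------------------------------------------------------------------------
# Spatial graph
# ---------------------------------------------------------------------------

@dataclass
class SpatialGraph:
    roi_id: str
    cell_ids: np.ndarray          # per node
    coords: np.ndarray            # n × 2 µm
    edges: np.ndarray             # m × 2 node indices, i < j
    lengths: np.ndarray           # m edge lengths µm
    prune_threshold_um: float

    @property
    def n_nodes(self) -> int:
        return len(self.cell_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> list[np.ndarray]:
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for (i, j) in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return [np.array(a, dtype=int) for a in adj]

    def to_edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "roi_id": self.roi_id,
            "cell_a": self.cell_ids[self.edges[:, 0]],
            "cell_b": self.cell_ids[self.edges[:, 1]],
            "length_um": self.lengths})


def build_spatial_graph(coords: np.ndarray, cell_ids: Sequence[str],
                        roi_id: str = "roi",
                        prune_percentile: float = DEFAULT_PRUNE_PERCENTILE
                        ) -> SpatialGraph:
    """Delaunay adjacency with long links pruned at the given percentile
    of this ROI's edge lengths (per-ROI, since densities differ)."""
    coords = np.asarray(coords, dtype=float)
    cell_ids = np.asarray(cell_ids)
    n = len(coords)
    if n != len(cell_ids):
        raise PipelineError("coords and cell_ids differ in length")

    uniq, counts = np.unique(coords, axis=0, return_counts=True)
    if n and (counts > 1).any():
        logger.warning("build_spatial_graph %s: duplicate coordinates jittered "
                       "by ≤ 1e−6 µm", roi_id)
        jitter = np.random.default_rng(0).uniform(-1e-6, 1e-6, coords.shape)
        coords = coords + jitter

    if n <= 2:
        edges = np.array([[0, 1]]) if n == 2 else np.empty((0, 2), dtype=int)
    else:
        try:
            tri = Delaunay(coords)
            pairs = set()
            for simplex in tri.simplices:
                for a in range(3):
                    for b in range(a + 1, 3):
                        i, j = int(simplex[a]), int(simplex[b])
                        pairs.add((min(i, j), max(i, j)))
            edges = np.array(sorted(pairs), dtype=int)
        except QhullError:
            logger.warning("build_spatial_graph %s: degenerate geometry; "
                           "falling back to complete graph", roi_id)
            edges = np.array([(i, j) for i in range(n) for j in range(i + 1, n)],
                             dtype=int)

    if len(edges):
        lengths = np.linalg.norm(coords[edges[:, 0]] - coords[edges[:, 1]],
                                 axis=1)
        # 'higher' order statistic: only edges strictly beyond the
        # percentile are long links; small graphs keep all their edges
        threshold = float(np.percentile(lengths, prune_percentile,
                                        method="higher"))
        keep = lengths <= threshold
        edges, lengths = edges[keep], lengths[keep]
    else:
        lengths = np.empty(0)
        threshold = 0.0
    return SpatialGraph(roi_id=roi_id, cell_ids=cell_ids, coords=coords,
                        edges=edges, lengths=lengths,
                        prune_threshold_um=threshold)


def build_spatial_graphs(table: CellTable,
                         prune_percentile: float = DEFAULT_PRUNE_PERCENTILE
                         ) -> list[SpatialGraph]:
    graphs = []
    for roi_id in table.obs["roi_id"].unique():
        sub = table.obs[table.obs["roi_id"] == roi_id]
        graphs.append(build_spatial_graph(
            sub[["x_um", "y_um"]].to_numpy(), sub["cell_id"].to_numpy(),
            roi_id=str(roi_id), prune_percentile=prune_percentile))
    return graphs


def l_step_neighbourhood(adjacency: Sequence[np.ndarray], node: int,
                         l: int = DEFAULT_STEPS) -> set[int]:
    """All nodes within graph distance ≤ l of ``node`` (inclusive)."""
    visited = {node}
    frontier = {node}
    for _ in range(l):
        nxt = set()
        for u in frontier:
            for v in adjacency[u]:
                v = int(v)
                if v not in visited:
                    visited.add(v)
                    nxt.add(v)
        if not nxt:
            break
        frontier = nxt
    return visited


# ---------------------------------------------------------------------------
# Neighbourhood features
# ---------------------------------------------------------------------------

def _hull_shape(points: np.ndarray) -> tuple[float, float]:
    """(hull area µm², circularity 4πA/P²); degenerate hulls → (0, 1)."""
    if len(points) < 3:
        return 0.0, 1.0
    try:
        hull = ConvexHull(points)
    except QhullError:
        return 0.0, 1.0
    area, perimeter = hull.volume, hull.area  # 2-D: volume=area, area=perimeter
    if perimeter <= 0 or area <= 0:
        return 0.0, 1.0
    return float(area), float(min(1.0, 4.0 * np.pi * area / perimeter ** 2))


def neighbourhood_features(graph: SpatialGraph, labels: Sequence[str],
                           populations: Sequence[str],
                           l: int = DEFAULT_STEPS) -> pd.DataFrame:
    """Per-cell l-step neighbourhood feature vectors for one ROI."""
    labels = np.asarray(labels, dtype=object)
    if len(labels) != graph.n_nodes:
        raise PipelineError("labels must cover all graph nodes")
    pop_index = {p: i for i, p in enumerate(populations)}
    codes = np.array([pop_index[lab] for lab in labels], dtype=int)
    adjacency = graph.adjacency()

    # edges incident to each node, for internal-edge proximity
    incident: list[list[int]] = [[] for _ in range(graph.n_nodes)]
    for e, (i, j) in enumerate(graph.edges):
        incident[i].append(e)
        incident[j].append(e)

    rows = []
    for node in range(graph.n_nodes):
        members = sorted(l_step_neighbourhood(adjacency, node, l))
        m = np.array(members, dtype=int)
        pts = graph.coords[m]
        comp = np.bincount(codes[m], minlength=len(populations)) / len(m)
        centroid = pts.mean(axis=0)
        dists = np.linalg.norm(pts - centroid, axis=1)
        area, circ = _hull_shape(pts)
        member_set = set(members)
        internal = {e for u in members for e in incident[u]
                    if int(graph.edges[e, 0]) in member_set
                    and int(graph.edges[e, 1]) in member_set}
        proximity = (float(np.mean(graph.lengths[sorted(internal)]))
                     if internal else 0.0)
        rows.append((*comp, area, circ, float(dists.mean()),
                     float(dists.std()), proximity, len(m)))
    cols = ([f"comp_{p}" for p in populations] +
            ["hull_area_um2", "circularity", "dist_mean_um", "dist_sd_um",
             "proximity_um", "n_members"])
    return pd.DataFrame(rows, columns=cols)


def cohort_neighbourhood_features(graphs: Sequence[SpatialGraph],
                                  table: CellTable,
                                  l: int = DEFAULT_STEPS,
                                  label_col: str = "population_label"
                                  ) -> pd.DataFrame:
    """Features for every cell of every ROI, in the cell table's row order."""
    if label_col not in table.obs.columns:
        raise ConfigError(f"{label_col} required for neighbourhood features")
    populations = sorted(table.obs[label_col].dropna().unique())
    parts = []
    for graph in graphs:
        sub = table.obs[table.obs["roi_id"] == graph.roi_id]
        labels = sub.set_index("cell_id")[label_col].loc[graph.cell_ids].to_numpy()
        feats = neighbourhood_features(graph, labels, populations, l)
        feats.insert(0, "roi_id", graph.roi_id)
        feats.insert(0, "cell_id", graph.cell_ids)
        parts.append(feats)
    out = pd.concat(parts, ignore_index=True)
    order = table.obs[["roi_id", "cell_id"]].reset_index(drop=True)
    out = order.merge(out, on=["roi_id", "cell_id"], how="left")
    return out


# ---------------------------------------------------------------------------
# Fowlkes–Mallows index
# ---------------------------------------------------------------------------

def fowlkes_mallows(labels_a: Sequence, labels_b: Sequence) -> float:
    """Pair-counting partition similarity TP/√((TP+FP)(TP+FN)).

    TP counts item pairs co-clustered in both partitions, FP pairs
    co-clustered only in the first, FN only in the second.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise PipelineError("partitions must cover the same items")
    if len(a) < 2:
        raise InsufficientDataError("FMI undefined on < 2 items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(contingency, (ai, bi), 1)

    def pairs(x):
        return (x * (x - 1) // 2).sum()

    tp = pairs(contingency)
    tp_fp = pairs(contingency.sum(axis=1))
    tp_fn = pairs(contingency.sum(axis=0))
    if tp_fp == 0 or tp_fn == 0:
        return 0.0
    return float(tp / np.sqrt(tp_fp * tp_fn))


# ---------------------------------------------------------------------------
# Stability-selected Gaussian mixture clustering
# ---------------------------------------------------------------------------

@dataclass
class NeighbourhoodAnnotation:
    fold_change: Mapping[str, float]
    category: str                  # tumour/vasculature/immune_enriched
    proliferative: bool
    enriched: tuple[str, ...]      # populations with FC ≥ 1


@dataclass
class NeighbourhoodModel:
    K: int
    labels: np.ndarray
    stability_by_K: Mapping[int, float]
    feature_names: tuple[str, ...]
    annotations: dict[int, NeighbourhoodAnnotation] = field(default_factory=dict)


def _standardize(features: pd.DataFrame,
                 aux_weight: float = 1.0) -> tuple[np.ndarray, list[str]]:
    """Z-score features; non-composition (geometry) features are scaled by
    ``aux_weight`` so they refine rather than dominate the clustering."""
    X = features.to_numpy(dtype=float)
    keep = X.std(axis=0) > 0
    X = X[:, keep]
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    kept = [c for c, k in zip(features.columns, keep) if k]
    aux = np.array([not c.startswith("comp_") for c in kept])
    X[:, aux] *= aux_weight
    return X, kept


DEFAULT_AUX_WEIGHT = 0.25
DEFAULT_REG_COVAR = 0.1


def cluster_neighbourhoods(features: pd.DataFrame,
                           K_range: Sequence[int] = range(2, 11),
                           n_repeats: int = 10, subsample: float = 0.8,
                           seed: int = 0,
                           aux_weight: float = DEFAULT_AUX_WEIGHT,
                           reg_covar: float = DEFAULT_REG_COVAR
                           ) -> NeighbourhoodModel:
    """Select K by Fowlkes–Mallows stability over subsampled GMM fits, then
    refit on all cells at the chosen K.

    For each candidate K, ``n_repeats`` full-covariance GMMs (k-means
    initialized) are fitted on random ``subsample`` fractions; stability is
    the mean pairwise FMI of their labellings restricted to shared cells.
    Ties are broken toward smaller K (parsimony).  Composition features are
    the primary discriminator; the geometry features (shape, distribution,
    proximity) enter at weight ``aux_weight``, and ``reg_covar`` floors each
    component's covariance so near-degenerate geometry directions cannot
    dominate the likelihood.  The final model is refit on all cells with a
    fixed seed and the best of 10 k-means-initialized restarts.
    """
    from sklearn.mixture import GaussianMixture

    numeric = features.select_dtypes(include=[np.number])
    numeric = numeric.drop(columns=[c for c in ("n_members",)
                                    if c in numeric.columns])
    X, kept = _standardize(numeric, aux_weight)
    n = len(X)
    rng = np.random.default_rng(seed)
    n_sub = max(2, int(round(subsample * n)))

    stability: dict[int, float] = {}
    for K in K_range:
        if K >= n_sub:
            logger.warning("cluster_neighbourhoods: K=%d ≥ subsample size %d; "
                           "skipped", K, n_sub)
            continue
        if K == 1:
            stability[1] = 1.0  # single cluster is trivially stable
            continue
        fits = []
        for rep in range(n_repeats):
            idx = np.sort(rng.choice(n, size=n_sub, replace=False))
            gmm = GaussianMixture(n_components=K, covariance_type="full",
                                  init_params="kmeans", n_init=1,
                                  reg_covar=reg_covar,
                                  random_state=int(rng.integers(2 ** 31)))
            lab = gmm.fit_predict(X[idx])
            fits.append((idx, lab))
        scores = []
        for i in range(len(fits)):
            for j in range(i + 1, len(fits)):
                ia, la = fits[i]
                ib, lb = fits[j]
                shared, pa, pb = np.intersect1d(ia, ib, return_indices=True)
                if len(shared) >= 2:
                    scores.append(fowlkes_mallows(la[pa], lb[pb]))
        stability[K] = float(np.mean(scores)) if scores else 0.0

    if not stability:
        raise InsufficientDataError("no feasible K in K_range")
    best = max(stability.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    final = GaussianMixture(n_components=best, covariance_type="full",
                            init_params="kmeans", n_init=10,
                            reg_covar=reg_covar, random_state=int(seed))
    labels = final.fit_predict(X)
    return NeighbourhoodModel(K=best, labels=labels,
                              stability_by_K=stability,
                              feature_names=tuple(kept))


# ---------------------------------------------------------------------------
# Annotation and group comparison
# ---------------------------------------------------------------------------

def annotate_neighbourhood_clusters(
        nbhd_labels: np.ndarray, population_labels: Sequence[str],
        hierarchy_of: Mapping[str, str]) -> dict[int, NeighbourhoodAnnotation]:
    """Fold-change enrichment of populations per neighbourhood cluster.

    FC(pop, cluster) = frequency in cluster / overall frequency; a cluster's
    category is the hierarchy (tumour / vasculature / immune) with the
    largest summed enriched (FC ≥ 1) fold change, and it is proliferative if
    any proliferative population has FC ≥ 1.
    """
    nbhd_labels = np.asarray(nbhd_labels)
    pops = np.asarray(population_labels, dtype=object)
    overall = pd.Series(pops).value_counts(normalize=True)
    annotations = {}
    for cluster in np.unique(nbhd_labels):
        inside = pd.Series(pops[nbhd_labels == cluster]).value_counts(
            normalize=True)
        fc = {p: float(inside.get(p, 0.0) / overall[p]) for p in overall.index}
        enriched = tuple(sorted(p for p, v in fc.items() if v >= 1.0))
        sums = {"tumour_enriched": 0.0, "vasculature_enriched": 0.0,
                "immune_enriched": 0.0}
        proliferative = False
        for p in enriched:
            h = hierarchy_of.get(p, "other")
            if h == "proliferative":
                proliferative = True
            cat = CATEGORY_OF_HIERARCHY.get(h)
            if cat:
                sums[cat] += fc[p]
        category = max(sums.items(), key=lambda kv: kv[1])[0]
        annotations[int(cluster)] = NeighbourhoodAnnotation(
            fold_change=fc, category=category, proliferative=proliferative,
            enriched=enriched)
    return annotations


def neighbourhood_proximity(graphs: Sequence[SpatialGraph],
                            labels_per_graph: Sequence[np.ndarray],
                            n_perm: int = 1000, seed: int = 0
                            ) -> pd.DataFrame:
    """Observed/expected inter-neighbourhood edge counts.

    Observed(a, b) counts retained edges joining clusters a and b, pooled
    over ROIs; expected is the mean of the same count under ``n_perm``
    random permutations of labels within each ROI.  The matrix is symmetric.
    """
    all_labels = np.concatenate([np.asarray(l) for l in labels_per_graph])
    clusters = np.unique(all_labels)
    k = len(clusters)
    code = {c: i for i, c in enumerate(clusters)}
    rng = np.random.default_rng(seed)

    observed = np.zeros((k, k))
    expected = np.zeros((k, k))
    for graph, labels in zip(graphs, labels_per_graph):
        labels = np.asarray(labels)
        if len(labels) != graph.n_nodes:
            raise PipelineError("labels must cover all graph nodes")
        codes = np.array([code[l] for l in labels], dtype=int)
        u, v = graph.edges[:, 0], graph.edges[:, 1]

        def tally(c):
            m = np.zeros((k, k))
            np.add.at(m, (c[u], c[v]), 1.0)
            np.add.at(m, (c[v], c[u]), 1.0)
            return m  # off-diagonal symmetric; diagonal double-counted

        observed += tally(codes)
        acc = np.zeros((k, k))
        for _ in range(n_perm):
            acc += tally(rng.permutation(codes))
        expected += acc / n_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(expected > 0, observed / expected, 0.0)
    return pd.DataFrame(oe, index=clusters, columns=clusters)


def neighbourhood_proportions(obs: pd.DataFrame,
                              label_col: str = "nbhd_label") -> pd.DataFrame:
    """Per-case proportions of cells in each neighbourhood cluster
    (rows sum to 1)."""
    counts = obs.groupby(["case_id", label_col]).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)


def neighbourhood_group_comparison(
        obs: pd.DataFrame,
        annotations: Mapping[int, NeighbourhoodAnnotation],
        metadata, label_col: str = "nbhd_label") -> dict:
    """Static-versus-growing comparison of neighbourhood occupancy.

    Per-cluster proportions are compared by two-tailed Mann–Whitney; the
    category-level (tumour/vasculature/immune) and proliferative /
    non-proliferative proportions by 2-way ANOVA (group × category) with
    interaction.
    """
    from scipy import stats

    cls = {c.case_id: c.classification for c in metadata}
    props = neighbourhood_proportions(obs, label_col)
    props = props.loc[[c for c in props.index if c in cls]]
    group = pd.Series({c: cls[c] for c in props.index})

    per_cluster = []
    for cluster in props.columns:
        a = props.loc[group == "static", cluster].to_numpy()
        b = props.loc[group == "growing", cluster].to_numpy()
        if len(a) == 0 or len(b) == 0:
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        per_cluster.append({"nbhd": cluster, "U": float(res.statistic),
                            "p": float(res.pvalue),
                            "mean_static": float(a.mean()),
                            "mean_growing": float(b.mean())})
    per_cluster = pd.DataFrame(per_cluster)

    cat_of = {c: ann.category for c, ann in annotations.items()}
    prolif_of = {c: ("proliferative" if ann.proliferative else
                     "non_proliferative") for c, ann in annotations.items()}

    def _tidy(mapping):
        rows = []
        for case in props.index:
            sums: dict[str, float] = {}
            for cluster in props.columns:
                key = mapping.get(cluster)
                if key is None:
                    continue
                sums[key] = sums.get(key, 0.0) + float(props.loc[case, cluster])
            for key, v in sums.items():
                rows.append({"case_id": case, "group": group[case],
                             "category": key, "proportion": v})
        return pd.DataFrame(rows)

    cat_df = _tidy(cat_of)
    prolif_df = _tidy(prolif_of)
    out = {"per_cluster": per_cluster, "category_proportions": cat_df,
           "proliferative_proportions": prolif_df}
    try:
        out["category_anova"] = two_way_anova(cat_df, "proportion", "group",
                                              "category")
    except (InsufficientDataError, ValueError):
        out["category_anova"] = None
    try:
        out["proliferative_anova"] = two_way_anova(prolif_df, "proportion",
                                                   "group", "category")
    except (InsufficientDataError, ValueError):
        out["proliferative_anova"] = None
    return out
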