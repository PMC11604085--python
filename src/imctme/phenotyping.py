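"""Cell phenotyping: Leiden clustering of normalized expression plus
declarative rule-based annotation.

Clustering runs on a union-symmetrized k-nearest-neighbour graph of the
cells' normalized marker vectors.  "Manual annotation" is mechanized as a
rule table: every cluster's mean normalized profile is z-scored per marker
across clusters, and a rule matches when all of its marker expectations hold

* ``high`` — z ≥ +0.5 (default), ``low`` — z ≤ −0.5,
* ``pos`` — cluster mean strictly above the across-cluster median,
  ``neg`` — strictly below, ``any`` — no constraint.

Among the rules that fully match, the one with the most non-``any``
expectations wins; ties go to the earlier rule in the table.  Unmatched
clusters are labelled ``other``, and clusters that receive the same label
are merged.  Default tables transcribe the vestibular-schwannoma marker
signatures (e.g. alternatively activated TAMs: CD16-high CX3CR1-high
CD163+ CD11b+); users may supply their own YAML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import igraph
import leidenalg
import numpy as np
import pandas as pd
import yaml

from .io import CellTable, ConfigError, InsufficientDataError, SchemaError

logger = logging.getLogger("imctme")

DEFAULT_K_NEIGHBOURS = 15
DEFAULT_RESOLUTION = 1.0
HIGH_Z = 0.5
LOW_Z = -0.5

LEVELS = ("high", "low", "pos", "neg", "any")


@dataclass(frozen=True)
class AnnotationRule:
    population: str
    hierarchy: str
    expectations: Mapping[str, str]

    def __post_init__(self):
        bad = {v for v in self.expectations.values()} - set(LEVELS)
        if bad:
            raise SchemaError(f"unknown expectation levels {sorted(bad)}")
        if not any(v != "any" for v in self.expectations.values()):
            raise SchemaError(
                f"rule {self.population!r} needs a non-'any' expectation")

    @property
    def n_constraints(self) -> int:
        return sum(1 for v in self.expectations.values() if v != "any")


def load_rules(path: str | Path) -> list[AnnotationRule]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    rules = [AnnotationRule(r["population"], r["hierarchy"],
                            dict(r["expectations"])) for r in doc["rules"]]
    names = [r.population for r in rules]
    if len(set(names)) != len(names):
        raise SchemaError("duplicate population names in rule table")
    return rules


def default_rules(which: str = "population") -> list[AnnotationRule]:
    """Packaged rule tables: ``hierarchy``, ``population`` or ``proliferative``."""
    fname = {"hierarchy": "hierarchy_rules.yaml",
             "population": "population_rules.yaml",
             "proliferative": "proliferative_rules.yaml"}[which]
    with resources.as_file(resources.files("imctme.data") / fname) as p:
        return load_rules(p)


@dataclass
class ClusterAssignment:
    labels: np.ndarray                    # per-cell integer cluster id
    mean_profiles: pd.DataFrame           # cluster × marker mean normalized
    population_label: dict[int, str] = field(default_factory=dict)
    hierarchy_label: dict[int, str] = field(default_factory=dict)
    merged_from: dict[int, list[int]] = field(default_factory=dict)

    def population_of_cells(self) -> np.ndarray:
        return np.array([self.population_label.get(c, "other")
                         for c in self.labels], dtype=object)

    def hierarchy_of_cells(self) -> np.ndarray:
        return np.array([self.hierarchy_label.get(c, "other")
                         for c in self.labels], dtype=object)


# ---------------------------------------------------------------------------
# Graph construction and Leiden clustering
# ---------------------------------------------------------------------------

def build_expression_graph(X: np.ndarray, k_neighbours: int = DEFAULT_K_NEIGHBOURS
                           ) -> igraph.Graph:
    """Union-symmetrized Euclidean kNN graph over cells (rows of ``X``)."""
    from sklearn.neighbors import NearestNeighbors

    X = np.asarray(X, dtype=float)
    n = len(X)
    if n == 0:
        return igraph.Graph(n=0)
    k = k_neighbours
    if n <= k:
        k = max(1, n - 1)
        logger.warning("build_expression_graph: only %d cells; k reduced to %d",
                       n, k)
    if n == 1:
        return igraph.Graph(n=1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    edges = set()
    for i in range(n):
        for j in idx[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    g = igraph.Graph(n=n, edges=sorted(edges))
    return g


def leiden_cluster(graph: igraph.Graph, resolution: float = DEFAULT_RESOLUTION,
                   seed: int = 0) -> np.ndarray:
    """Leiden community detection; deterministic for a given seed."""
    if graph.vcount() == 0:
        return np.array([], dtype=int)
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=int(seed))
    return np.asarray(part.membership, dtype=int)


def cluster_mean_profiles(labels: np.ndarray, norm: pd.DataFrame) -> pd.DataFrame:
    return norm.groupby(pd.Series(labels, name="cluster")).mean()


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _z_and_median(profiles: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    mu = profiles.mean(axis=0)
    sd = profiles.std(axis=0, ddof=0)
    z = (profiles - mu) / sd.replace(0.0, np.nan)
    return z.fillna(0.0), profiles.median(axis=0)


def _rule_matches(rule: AnnotationRule, z: pd.Series, means: pd.Series,
                  medians: pd.Series, high_z: float, low_z: float) -> bool:
    for marker, level in rule.expectations.items():
        if level == "any":
            continue
        if marker not in z.index:
            return False
        if level == "high" and not z[marker] >= high_z:
            return False
        if level == "low" and not z[marker] <= low_z:
            return False
        if level == "pos" and not means[marker] > medians[marker]:
            return False
        if level == "neg" and not means[marker] < medians[marker]:
            return False
    return True


def annotate_clusters(labels: np.ndarray, norm: pd.DataFrame,
                      rules: Sequence[AnnotationRule],
                      high_z: float = HIGH_Z,
                      low_z: float = LOW_Z) -> ClusterAssignment:
    """Assign each cluster the best-matching annotation rule and merge
    identically labelled clusters."""
    profiles = cluster_mean_profiles(labels, norm)
    z, medians = _z_and_median(profiles)

    pop_label: dict[int, str] = {}
    hier_label: dict[int, str] = {}
    for cluster in profiles.index:
        best: AnnotationRule | None = None
        for rule in rules:  # earlier rules win ties
            if _rule_matches(rule, z.loc[cluster], profiles.loc[cluster],
                             medians, high_z, low_z):
                if best is None or rule.n_constraints > best.n_constraints:
                    best = rule
        pop_label[int(cluster)] = best.population if best else "other"
        hier_label[int(cluster)] = best.hierarchy if best else "other"

    merged_from: dict[int, list[int]] = {}
    for c, lab in pop_label.items():
        canonical = min(k for k, v in pop_label.items() if v == lab)
        merged_from.setdefault(canonical, [])
        if c != canonical:
            merged_from[canonical].append(c)
    return ClusterAssignment(labels=np.asarray(labels), mean_profiles=profiles,
                             population_label=pop_label,
                             hierarchy_label=hier_label,
                             merged_from=merged_from)


# ---------------------------------------------------------------------------
# End-to-end phenotyping
# ---------------------------------------------------------------------------

def phenotype(table: CellTable,
              hierarchy_rules: Sequence[AnnotationRule] | None = None,
              population_rules: Sequence[AnnotationRule] | None = None,
              k_neighbours: int = DEFAULT_K_NEIGHBOURS,
              resolution: float = DEFAULT_RESOLUTION,
              seed: int = 0) -> tuple[CellTable, ClusterAssignment]:
    """Cluster all cells once, then apply the hierarchy- and population-level
    rule tables to the same clustering (two views of one partition)."""
    if table.norm is None:
        raise ConfigError("normalize_expression must run before phenotyping")
    if hierarchy_rules is None:
        hierarchy_rules = default_rules("hierarchy")
    if population_rules is None:
        population_rules = default_rules("population")

    graph = build_expression_graph(table.norm.to_numpy(), k_neighbours)
    labels = leiden_cluster(graph, resolution=resolution, seed=seed)
    hier = annotate_clusters(labels, table.norm, hierarchy_rules)
    pop = annotate_clusters(labels, table.norm, population_rules)

    out = CellTable(obs=table.obs.copy(), raw=table.raw.copy(),
                    norm=table.norm.copy())
    out.obs["cluster_id"] = labels
    out.obs["hierarchy_label"] = hier.hierarchy_of_cells()
    out.obs["population_label"] = pop.population_of_cells()
    return out, pop


def subcluster_population(table: CellTable, target_hierarchy: str,
                          rules: Sequence[AnnotationRule] | None = None,
                          k_neighbours: int = DEFAULT_K_NEIGHBOURS,
                          resolution: float = DEFAULT_RESOLUTION,
                          seed: int = 0) -> CellTable:
    """Re-run Leiden on one hierarchy's cells only (e.g. the proliferative
    fraction) and annotate the sub-clusters with a second rule table."""
    if "hierarchy_label" not in table.obs.columns:
        raise ConfigError("phenotype must run before subclustering")
    mask = (table.obs["hierarchy_label"] == target_hierarchy).to_numpy()
    if not mask.any():
        raise InsufficientDataError(f"no cells labelled {target_hierarchy!r}")
    if rules is None:
        rules = default_rules("proliferative")

    sub_norm = table.norm.loc[mask].reset_index(drop=True)
    if mask.sum() <= k_neighbours:
        logger.warning("subcluster_population: %d cells ≤ k; single subcluster",
                       int(mask.sum()))
        sub_labels = np.zeros(int(mask.sum()), dtype=int)
    else:
        graph = build_expression_graph(sub_norm.to_numpy(), k_neighbours)
        sub_labels = leiden_cluster(graph, resolution=resolution, seed=seed)
    assignment = annotate_clusters(sub_labels, sub_norm, rules)

    out = CellTable(obs=table.obs.copy(), raw=table.raw.copy(),
                    norm=table.norm.copy())
    sub_pop = assignment.population_of_cells()
    col = np.full(table.n_cells, None, dtype=object)
    col[np.flatnonzero(mask)] = sub_pop
    out.obs["subpopulation_label"] = col
    # fold sub-labels into the granular population labels
    if "population_label" in out.obs.columns:
        pops = out.obs["population_label"].to_numpy(dtype=object)
        pops[np.flatnonzero(mask)] = sub_pop
        out.obs["population_label"] = pops
    return out
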