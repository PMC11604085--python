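"""Pipeline orchestration: staged, seeded, manifest-driven runs.

Stages run in order simulate/load → quantify → phenotype → neighbourhoods →
spatial → report, each writing CSV artifacts into the output directory and
recording them in a JSON manifest together with the config hash and the
global seed.  A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence((seed, stage_index))``, so every randomized
procedure (simulator, Leiden, GMM, bootstrap, permutations) consumes only
derived seeds and identical configs reproduce identical outputs byte for
byte.  Re-running a completed stage with an unchanged config is a no-op.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as iio
from . import neighbourhoods as nb
from . import phenotyping as ph
from . import quantify as qt
from . import spatial as sp
from . import synthetic as syn

logger = logging.getLogger("imctme")

STAGES = ("simulate", "quantify", "phenotype", "neighbourhoods", "spatial",
          "report")


@dataclass
class PipelineConfig:
    outdir: str
    seed: int
    # input: either a cell-table path (+ panel/metadata/geometry) or simulate
    cell_table: str | None = None
    panel: str | None = None
    metadata: str | None = None
    geometry: str | None = None
    simulate: bool = True
    scenario: str | None = None            # YAML path; default scenario if None
    intensity_scale: float = 1.0
    roi_width_um: float = 1000.0
    roi_height_um: float = 1000.0
    rois_per_case: int = 6
    stages: tuple[str, ...] = STAGES
    # stage parameters
    q: float = 99.9
    k_neighbours: int = 15
    resolution: float = 1.0
    l: int = 3
    prune_percentile: float = 99.0
    K_min: int = 2
    K_max: int = 10
    n_repeats: int = 10
    subsample: float = 0.8
    side_um: float = 100.0
    r_max: float = 300.0
    dr: float = 10.0
    n_boot: int = 200
    n_perm: int = 1000
    alpha: float = 0.05

    def __post_init__(self):
        if self.seed is None:
            raise iio.ConfigError("seed is mandatory")
        checks = [self.q > 0 and self.q <= 100, self.k_neighbours >= 1,
                  self.resolution > 0, self.l >= 1,
                  0 < self.prune_percentile <= 100,
                  1 <= self.K_min <= self.K_max,
                  self.n_repeats >= 2, 0 < self.subsample <= 1,
                  self.side_um > 0, self.r_max > 0, self.dr > 0,
                  self.n_boot >= 1, self.n_perm >= 1, 0 < self.alpha < 1]
        if not all(checks):
            raise iio.ConfigError("pipeline parameter outside its domain")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise iio.ConfigError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "stages" in doc:
            doc["stages"] = tuple(doc["stages"])
        return cls(**doc)

    def hash(self) -> str:
        doc = asdict(self)
        doc["stages"] = list(doc["stages"])
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence((self.seed, STAGES.index(stage)))
        return int(ss.generate_state(1)[0] % (2 ** 31))


def _write(df: pd.DataFrame, path: Path, **kw) -> str:
    df.to_csv(path, **kw)
    return str(path)


class PipelineRun:
    """Mutable run state shared between stages."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        self.manifest: dict[str, Any] = {
            "config_hash": config.hash(), "seed": config.seed,
            "versions": _versions(), "outputs": {}}
        if self.manifest_path.exists():
            old = json.loads(self.manifest_path.read_text())
            if old.get("config_hash") == self.manifest["config_hash"]:
                self.manifest = old
        self.table: iio.CellTable | None = None
        self.cases: list[iio.CaseMetadata] | None = None
        self.geometry: list[iio.RoiGeometry] | None = None
        self.panel: iio.PanelDefinition | None = None
        self.graphs: list[nb.SpatialGraph] | None = None
        self.nbhd_model: nb.NeighbourhoodModel | None = None
        self.nbhd_annotations = None

    # -- persistence helpers ------------------------------------------------
    def record(self, stage: str, outputs: Mapping[str, str]) -> None:
        self.manifest["outputs"][stage] = dict(outputs)
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2,
                                                 sort_keys=True))

    def done(self, stage: str) -> bool:
        outs = self.manifest["outputs"].get(stage)
        return bool(outs) and all(Path(p).exists() for p in outs.values())

    def _load_state(self) -> None:
        """Reload core artifacts from disk (resume support)."""
        if self.panel is None:
            ppath = self.outdir / "panel.csv"
            self.panel = (iio.read_panel(ppath) if ppath.exists()
                          else iio.default_panel())
        if self.table is None and (self.outdir / "cells.csv").exists():
            self.geometry = iio.read_roi_geometry(self.outdir / "geometry.csv")
            self.table = iio.read_cell_table(self.outdir / "cells.csv",
                                             self.panel, self.geometry)
            self.cases = iio.read_case_metadata(self.outdir / "cases.csv")


def _versions() -> dict[str, str]:
    import scipy
    import sklearn
    return {"numpy": np.__version__, "pandas": pd.__version__,
            "scipy": scipy.__version__, "scikit-learn": sklearn.__version__}


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(run: PipelineRun) -> None:
    cfg = run.config
    if cfg.simulate:
        if cfg.scenario:
            scenario = syn.scenario_from_yaml(cfg.scenario)
        else:
            scenario = syn.default_scenario(
                seed=cfg.stage_seed("simulate"),
                roi_width_um=cfg.roi_width_um, roi_height_um=cfg.roi_height_um,
                rois_per_case=cfg.rois_per_case,
                intensity_scale=cfg.intensity_scale)
        table, cases, geometry, truth = syn.simulate_cohort(scenario)
        panel = scenario.panel()
        truth.to_csv(run.outdir / "truth.csv")
    else:
        panel = (iio.read_panel(cfg.panel) if cfg.panel
                 else iio.default_panel())
        geometry = iio.read_roi_geometry(cfg.geometry)
        table = iio.read_cell_table(cfg.cell_table, panel, geometry)
        cases = (iio.read_case_metadata(cfg.metadata) if cfg.metadata
                 else iio.default_case_metadata())
    run.table, run.cases, run.geometry, run.panel = table, cases, geometry, panel
    outputs = {
        "cells": _write(table.obs.join(table.raw.add_prefix("raw_")),
                        run.outdir / "cells.csv", index=False),
        "cases": str(run.outdir / "cases.csv"),
        "geometry": str(run.outdir / "geometry.csv"),
        "panel": str(run.outdir / "panel.csv")}
    iio.write_case_metadata(cases, run.outdir / "cases.csv")
    iio.write_roi_geometry(geometry, run.outdir / "geometry.csv")
    iio.write_panel(panel, run.outdir / "panel.csv")
    run.record("simulate", outputs)


def stage_quantify(run: PipelineRun) -> None:
    cfg = run.config
    run._load_state()
    if run.table is None:
        raise iio.PipelineError("quantify requires the simulate/load stage")
    run.table = qt.normalize_expression(run.table, q=cfg.q)
    density = qt.cell_density(run.table, run.geometry, stratum="case")
    corr = {}
    try:
        corr["total_density"] = qt.correlate_with_growth(density, run.cases,
                                                         alpha=cfg.alpha)
    except iio.PipelineError:
        pass
    outputs = {
        "density": _write(pd.DataFrame(
            [{"case_id": k, "cells_per_mm2": v} for k, v in density.items()]),
            run.outdir / "density_case.csv", index=False),
        "correlations": _write(qt.correlation_results_to_frame(corr),
                               run.outdir / "growth_correlations.csv",
                               index=False)}
    run.record("quantify", outputs)


def stage_phenotype(run: PipelineRun) -> None:
    cfg = run.config
    run._load_state()
    if run.table is None:
        raise iio.PipelineError("phenotype requires earlier stages")
    if run.table.norm is None:
        run.table = qt.normalize_expression(run.table, q=cfg.q)
    table, assignment = ph.phenotype(
        run.table, k_neighbours=cfg.k_neighbours, resolution=cfg.resolution,
        seed=cfg.stage_seed("phenotype"))
    run.table = table
    density = qt.cell_density(table, run.geometry, stratum="case×population")
    rows = [{"case_id": c, "population": p, "cells_per_mm2": v}
            for (c, p), v in density.items()]
    corr = {}
    for pop in sorted({r["population"] for r in rows}):
        vals = {r["case_id"]: r["cells_per_mm2"] for r in rows
                if r["population"] == pop}
        try:
            corr[pop] = qt.correlate_with_growth(vals, run.cases,
                                                 alpha=cfg.alpha)
        except iio.PipelineError:
            continue
    outputs = {
        "labelled_cells": str(run.outdir / "cells_labelled.csv"),
        "cluster_profiles": _write(assignment.mean_profiles,
                                   run.outdir / "cluster_profiles.csv"),
        "population_density": _write(pd.DataFrame(rows),
                                     run.outdir / "density_population.csv",
                                     index=False),
        "population_growth_correlations": _write(
            qt.correlation_results_to_frame(corr),
            run.outdir / "population_growth_correlations.csv", index=False)}
    iio.write_cell_table(table, run.outdir / "cells_labelled.csv")
    run.record("phenotype", outputs)


def _load_labelled(run: PipelineRun) -> None:
    run._load_state()
    path = run.outdir / "cells_labelled.csv"
    need = run.table is None or "population_label" not in run.table.obs.columns
    if need:
        if not path.exists():
            raise iio.PipelineError("stage requires the phenotype stage")
        run.table = iio.read_cell_table(path, run.panel, run.geometry)


def stage_neighbourhoods(run: PipelineRun) -> None:
    cfg = run.config
    _load_labelled(run)
    table = run.table
    seed = cfg.stage_seed("neighbourhoods")
    run.graphs = nb.build_spatial_graphs(table,
                                         prune_percentile=cfg.prune_percentile)
    feats = nb.cohort_neighbourhood_features(run.graphs, table, l=cfg.l)
    model = nb.cluster_neighbourhoods(
        feats.drop(columns=["cell_id", "roi_id"]),
        K_range=range(cfg.K_min, cfg.K_max + 1),
        n_repeats=cfg.n_repeats, subsample=cfg.subsample, seed=seed)
    run.nbhd_model = model
    hierarchy_of = dict(zip(table.obs["population_label"],
                            table.obs.get("hierarchy_label",
                                          table.obs["population_label"])))
    annotations = nb.annotate_neighbourhood_clusters(
        model.labels, table.obs["population_label"].to_numpy(), hierarchy_of)
    run.nbhd_annotations = annotations
    table.obs["nbhd_label"] = model.labels

    labels_per_graph = []
    for g in run.graphs:
        sub = table.obs[table.obs["roi_id"] == g.roi_id]
        labels_per_graph.append(
            sub.set_index("cell_id")["nbhd_label"].loc[g.cell_ids].to_numpy())
    proximity = nb.neighbourhood_proximity(run.graphs, labels_per_graph,
                                           n_perm=min(cfg.n_perm, 200),
                                           seed=seed + 1)
    comparison = nb.neighbourhood_group_comparison(table.obs, annotations,
                                                   run.cases)
    fc_rows = [{"nbhd": c, "category": a.category,
                "proliferative": a.proliferative,
                **{f"fc_{p}": v for p, v in a.fold_change.items()}}
               for c, a in annotations.items()]
    outputs = {
        "nbhd_cells": str(run.outdir / "cells_neighbourhoods.csv"),
        "stability": _write(pd.DataFrame(
            sorted(model.stability_by_K.items()), columns=["K", "mean_fmi"]),
            run.outdir / "nbhd_stability.csv", index=False),
        "annotations": _write(pd.DataFrame(fc_rows),
                              run.outdir / "nbhd_annotations.csv", index=False),
        "proximity": _write(proximity, run.outdir / "nbhd_proximity.csv"),
        "group_comparison": _write(comparison["per_cluster"],
                                   run.outdir / "nbhd_group_comparison.csv",
                                   index=False),
        "category_proportions": _write(
            comparison["category_proportions"],
            run.outdir / "nbhd_category_proportions.csv", index=False),
        "proliferative_proportions": _write(
            comparison["proliferative_proportions"],
            run.outdir / "nbhd_proliferative_proportions.csv", index=False)}
    iio.write_cell_table(table, run.outdir / "cells_neighbourhoods.csv")
    run.record("neighbourhoods", outputs)


def stage_spatial(run: PipelineRun) -> None:
    cfg = run.config
    _load_labelled(run)
    table = run.table
    seed = cfg.stage_seed("spatial")
    geo = {g.roi_id: g for g in run.geometry}
    cls = {c.case_id: c.classification for c in run.cases}

    networks = {}
    call_rows = []
    for group in ("static", "growing"):
        case_ids = [c for c, k in cls.items() if k == group]
        sub = table.obs[table.obs["case_id"].isin(case_ids)]
        if sub.empty:
            continue
        qcms = []
        for roi_id, roi_obs in sub.groupby("roi_id"):
            counts = quadrats = sp.quadrat_counts(roi_obs, geo[roi_id],
                                                  side_um=cfg.side_um)
            if len(counts) >= 10:
                qcms.append(sp.quadrat_correlation_matrix(counts,
                                                          alpha=cfg.alpha))
        sig = sp.qcm_significant_pairs(qcms) if qcms else set()

        graphs = nb.build_spatial_graphs(
            iio.CellTable(obs=sub.reset_index(drop=True),
                          raw=table.raw.loc[sub.index].reset_index(drop=True)),
            prune_percentile=cfg.prune_percentile)
        labels_per_graph = []
        for g in graphs:
            s = sub[sub["roi_id"] == g.roi_id]
            labels_per_graph.append(
                s.set_index("cell_id")["population_label"]
                .loc[g.cell_ids].to_numpy())

        pcf_results = {}
        for idx, pair in enumerate(sorted(sig, key=sorted)):
            members = tuple(sorted(pair))
            ordered = ([(members[0], members[0])] if len(members) == 1 else
                       [(members[0], members[1]), (members[1], members[0])])
            for s_pop, r_pop in ordered:
                rois = []
                for roi_id, roi_obs in sub.groupby("roi_id"):
                    g = geo[roi_id]
                    senders = roi_obs.loc[
                        roi_obs["population_label"] == s_pop,
                        ["x_um", "y_um"]].to_numpy()
                    receivers = roi_obs.loc[
                        roi_obs["population_label"] == r_pop,
                        ["x_um", "y_um"]].to_numpy()
                    rois.append((senders, receivers,
                                 (g.width_um, g.height_um)))
                try:
                    res = sp.bootstrap_pcf_pooled(
                        rois, r_max=cfg.r_max, dr=cfg.dr, n_boot=cfg.n_boot,
                        seed=seed + idx, auto=(s_pop == r_pop),
                        sender_name=s_pop, receiver_name=r_pop)
                except iio.InsufficientDataError:
                    continue
                pcf_results[(s_pop, r_pop)] = res
                call_rows.append({"group": group, "sender": s_pop,
                                  "receiver": r_pop, "gr20": res.gr20,
                                  "ci_low": float(res.ci_low[min(
                                      int(20 // cfg.dr),
                                      len(res.ci_low) - 1)]),
                                  "ci_high": float(res.ci_high[min(
                                      int(20 // cfg.dr),
                                      len(res.ci_high) - 1)]),
                                  "call": res.call})
        networks[group] = sp.adjacency_network(sig, pcf_results, graphs,
                                               labels_per_graph)

    import networkx as nx
    outputs = {"pcf_calls": _write(pd.DataFrame(call_rows),
                                   run.outdir / "pcf_calls.csv", index=False)}
    for group, net in networks.items():
        gml = run.outdir / f"network_{group}.graphml"
        nx.write_graphml(net, gml)
        edges = pd.DataFrame([
            {"sender": u, "receiver": v, **d} for u, v, d in
            net.edges(data=True)])
        outputs[f"network_{group}"] = str(gml)
        outputs[f"edges_{group}"] = _write(
            edges, run.outdir / f"network_edges_{group}.csv", index=False)
    run.record("spatial", outputs)


def stage_report(run: PipelineRun) -> None:
    run._load_state()
    lines = ["# Run report", "",
             f"config hash: {run.manifest['config_hash']}",
             f"seed: {run.manifest['seed']}", ""]
    for stage, outs in run.manifest["outputs"].items():
        lines.append(f"## {stage}")
        for name, path in outs.items():
            lines.append(f"- {name}: {Path(path).name}")
        lines.append("")
    report = run.outdir / "report.md"
    report.write_text("\n".join(lines))
    run.record("report", {"report": str(report)})


STAGE_FN = {"simulate": stage_simulate, "quantify": stage_quantify,
            "phenotype": stage_phenotype,
            "neighbourhoods": stage_neighbourhoods,
            "spatial": stage_spatial, "report": stage_report}


def run_pipeline(config: PipelineConfig, resume: bool = True) -> dict:
    """Execute the configured stages in order; returns the manifest."""
    run = PipelineRun(config)
    for stage in STAGES:
        if stage not in config.stages:
            continue
        if resume and run.done(stage):
            logger.info("stage %s already complete; skipping", stage)
            continue
        logger.info("running stage %s", stage)
        STAGE_FN[stage](run)
    return run.manifest
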