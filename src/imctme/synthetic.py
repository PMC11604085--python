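"""Synthetic cohorts of marked spatial point patterns with known ground truth.

The simulator emulates the statistical structure of a segmented IMC cohort:
multi-ROI marked point patterns with ~15 cell populations, population-specific
marker mean vectors under multiplicative lognormal noise, spatial aggregation
(Thomas/Neyman–Scott cluster processes), cross-type attraction (linked
processes), a proliferative sub-fraction, and case-level growth rates with
planted density–growth associations.

Three point-process families are available per population:

``poisson``
    Homogeneous Poisson at intensity ``base + slope · growth_rate`` per mm².
``thomas``
    Poisson parents with Poisson(``mean_offspring``) offspring scattered
    isotropically with Gaussian sd ``thomas_sigma_um``.  Parents are drawn in
    a 3σ-padded window and offspring outside the ROI are discarded, so the
    realised intensity is calibrated only approximately near edges.
``linked``
    Each point sits at a uniformly chosen point of a partner population plus
    an isotropic Gaussian(``link_sigma_um``) displacement — cross-type
    attraction at a controlled spatial scale.

Marker values are ``mean_expr × LogNormal(0, σ)`` with σ chosen so the
multiplicative coefficient of variation equals ``noise_cv``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import (CaseMetadata, CellTable, ConfigError, PanelDefinition,
                 RoiGeometry, Marker, classify_growth)

logger = logging.getLogger("imctme")

# Printed ranges of the clinical cohort's growth rates (% volume change/yr).
STATIC_RATE_RANGE = (-40.0, 16.0)
GROWING_RATE_RANGE = (28.0, 267.0)


# ---------------------------------------------------------------------------
# Scenario specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationSpec:
    name: str
    hierarchy: str  # myeloid | neoplastic | lymphoid | vascular | proliferative | other
    mean_expr: Mapping[str, float]
    noise_cv: float = 0.3
    process: str = "poisson"  # poisson | thomas | linked
    intensity_per_mm2: float = 100.0
    thomas_parent_per_mm2: float | None = None
    thomas_mean_offspring: float | None = None
    thomas_sigma_um: float | None = None
    link_partner: str | None = None
    link_sigma_um: float | None = None

    def __post_init__(self):
        if self.noise_cv <= 0:
            raise ConfigError("noise_cv must be positive")
        if self.intensity_per_mm2 < 0:
            raise ConfigError("intensity must be non-negative")
        if any(v < 0 for v in self.mean_expr.values()):
            raise ConfigError("mean expression must be non-negative")
        if self.process == "thomas":
            if self.thomas_mean_offspring is None or self.thomas_sigma_um is None:
                raise ConfigError(f"{self.name}: thomas process needs "
                                  "thomas_mean_offspring and thomas_sigma_um")
        elif self.process == "linked":
            if self.link_partner is None or self.link_sigma_um is None:
                raise ConfigError(f"{self.name}: linked process needs "
                                  "link_partner and link_sigma_um")
        elif self.process != "poisson":
            raise ConfigError(f"unknown process {self.process!r}")


@dataclass(frozen=True)
class ScenarioConfig:
    populations: tuple[PopulationSpec, ...]
    n_static: int = 4
    n_growing: int = 5
    rois_per_case: int = 6          # six Iba1+ ROIs imaged per case
    roi_width_um: float = 1000.0
    roi_height_um: float = 1000.0
    growth_effect: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_static < 0 or self.n_growing < 0:
            raise ConfigError("case counts must be non-negative")
        if self.rois_per_case < 1:
            raise ConfigError("rois_per_case must be positive")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate population names")
        for pop, slope in self.growth_effect.items():
            if pop not in names:
                raise ConfigError(f"growth_effect for unknown population {pop!r}")
            spec = next(p for p in self.populations if p.name == pop)
            lo, hi = min(STATIC_RATE_RANGE[0], GROWING_RATE_RANGE[0]), GROWING_RATE_RANGE[1]
            for rate in (lo, hi):
                if spec.intensity_per_mm2 + slope * rate < -1e-9:
                    raise ConfigError(
                        f"growth_effect slope for {pop!r} produces negative "
                        f"intensity at growth rate {rate}")

    @property
    def population_names(self) -> list[str]:
        return [p.name for p in self.populations]

    def markers(self) -> list[str]:
        names: list[str] = []
        for p in self.populations:
            for m in p.mean_expr:
                if m not in names:
                    names.append(m)
        return names

    def panel(self) -> PanelDefinition:
        """A panel covering every marker named in the scenario."""
        hier_to_comp = {"neoplastic": "neoplastic", "myeloid": "immune",
                        "lymphoid": "immune", "vascular": "vascular",
                        "proliferative": "proliferative", "other": "other"}
        comp: dict[str, str] = {}
        for p in self.populations:
            for m in p.mean_expr:
                comp.setdefault(m, hier_to_comp[p.hierarchy])
        return PanelDefinition(tuple(Marker(m, comp[m]) for m in self.markers()))


@dataclass
class GroundTruth:
    """Planted truth aligned row-for-row with the emitted cell table."""
    cell: pd.DataFrame                      # true_population, true_hierarchy, (domain)
    case_slopes: Mapping[str, float] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.cell.to_csv(path, index=False)


def scenario_to_yaml(scenario: ScenarioConfig, path) -> None:
    doc = {
        "n_static": scenario.n_static, "n_growing": scenario.n_growing,
        "rois_per_case": scenario.rois_per_case,
        "roi_width_um": scenario.roi_width_um,
        "roi_height_um": scenario.roi_height_um,
        "seed": scenario.seed,
        "growth_effect": dict(scenario.growth_effect),
        "populations": [
            {k: (dict(v) if isinstance(v, Mapping) else v)
             for k, v in vars(p).items() if v is not None}
            for p in scenario.populations],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def scenario_from_yaml(path) -> ScenarioConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    pops = tuple(PopulationSpec(**p) for p in doc.pop("populations"))
    return ScenarioConfig(populations=pops, **doc)


# ---------------------------------------------------------------------------
# Case metadata
# ---------------------------------------------------------------------------

def generate_case_metadata(n_static: int, n_growing: int,
                           seed: int = 0) -> list[CaseMetadata]:
    """Draw growth rates uniformly on the cohort's printed ranges.

    Static cases on [−40, 16] %/yr, growing cases on [28, 267] %/yr; the
    classification is consistent with the ≥ 20 %/yr rule by construction.
    """
    rng = np.random.default_rng(seed)
    cases: list[CaseMetadata] = []
    for i in range(n_static):
        rate = rng.uniform(*STATIC_RATE_RANGE)
        cases.append(CaseMetadata(
            case_id=f"S{i + 1:02d}", sex=("F" if rng.random() < 0.25 else "M"),
            age_years=int(rng.integers(25, 70)),
            tumour_volume_cm3=float(np.round(rng.uniform(0.1, 12.5), 2)),
            growth_rate_pct_per_year=float(np.round(rate, 2))))
    for i in range(n_growing):
        rate = rng.uniform(*GROWING_RATE_RANGE)
        cases.append(CaseMetadata(
            case_id=f"G{i + 1:02d}", sex=("F" if rng.random() < 0.25 else "M"),
            age_years=int(rng.integers(25, 70)),
            tumour_volume_cm3=float(np.round(rng.uniform(0.1, 12.5), 2)),
            growth_rate_pct_per_year=float(np.round(rate, 2))))
    assert all(classify_growth(c.growth_rate_pct_per_year) == c.classification
               for c in cases)
    return cases


# ---------------------------------------------------------------------------
# Point-pattern simulation
# ---------------------------------------------------------------------------

def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def _draw_markers(n: int, spec: PopulationSpec, markers: Sequence[str],
                  rng: np.random.Generator) -> np.ndarray:
    sigma = _lognormal_sigma(spec.noise_cv)
    means = np.array([spec.mean_expr.get(m, 0.0) for m in markers])
    factors = rng.lognormal(mean=0.0, sigma=sigma, size=(n, len(markers)))
    return means[None, :] * factors


def _simulate_points(spec: PopulationSpec, intensity: float, width: float,
                     height: float, rng: np.random.Generator,
                     partner_xy: np.ndarray | None) -> np.ndarray:
    """Point locations (n × 2, µm) for one population in one ROI window."""
    area_mm2 = width * height / 1e6
    if spec.process == "poisson":
        n = rng.poisson(intensity * area_mm2)
        return np.column_stack([rng.uniform(0, width, n),
                                rng.uniform(0, height, n)])
    if spec.process == "thomas":
        sigma = spec.thomas_sigma_um
        mu = spec.thomas_mean_offspring
        parent_rate = (spec.thomas_parent_per_mm2 if spec.thomas_parent_per_mm2
                       is not None else intensity / mu)
        pad = 3.0 * sigma
        pw, ph = width + 2 * pad, height + 2 * pad
        n_parents = rng.poisson(parent_rate * pw * ph / 1e6)
        px = rng.uniform(-pad, width + pad, n_parents)
        py = rng.uniform(-pad, height + pad, n_parents)
        counts = rng.poisson(mu, n_parents)
        cx = np.repeat(px, counts) + rng.normal(0, sigma, counts.sum())
        cy = np.repeat(py, counts) + rng.normal(0, sigma, counts.sum())
        keep = (cx >= 0) & (cx <= width) & (cy >= 0) & (cy <= height)
        return np.column_stack([cx[keep], cy[keep]])
    # linked
    if partner_xy is None or len(partner_xy) == 0:
        logger.warning("linked population %s: partner %r absent from ROI; "
                       "emitting empty population", spec.name, spec.link_partner)
        return np.empty((0, 2))
    n = rng.poisson(intensity * area_mm2)
    idx = rng.integers(0, len(partner_xy), n)
    pts = partner_xy[idx] + rng.normal(0, spec.link_sigma_um, (n, 2))
    keep = ((pts[:, 0] >= 0) & (pts[:, 0] <= width) &
            (pts[:, 1] >= 0) & (pts[:, 1] <= height))
    return pts[keep]


def simulate_roi(scenario: ScenarioConfig, case: CaseMetadata, roi_id: str,
                 seed: int) -> tuple[CellTable, GroundTruth]:
    """Simulate one ROI of one case: points, populations and marker values."""
    rng = np.random.default_rng(seed)
    width, height = scenario.roi_width_um, scenario.roi_height_um
    markers = scenario.markers()
    rate = case.growth_rate_pct_per_year

    # linked populations need their partner simulated first
    ordered = ([p for p in scenario.populations if p.process != "linked"]
               + [p for p in scenario.populations if p.process == "linked"])
    located: dict[str, np.ndarray] = {}
    for spec in ordered:
        slope = scenario.growth_effect.get(spec.name, 0.0)
        intensity = max(0.0, spec.intensity_per_mm2 + slope * rate)
        located[spec.name] = _simulate_points(
            spec, intensity, width, height, rng,
            located.get(spec.link_partner) if spec.process == "linked" else None)

    obs_parts, raw_parts, truth_parts = [], [], []
    counter = 0
    for spec in scenario.populations:
        xy = located[spec.name]
        n = len(xy)
        if n == 0:
            continue
        obs_parts.append(pd.DataFrame({
            "cell_id": [f"{roi_id}_c{counter + i}" for i in range(n)],
            "case_id": case.case_id, "roi_id": roi_id,
            "x_um": xy[:, 0], "y_um": xy[:, 1]}))
        raw_parts.append(pd.DataFrame(_draw_markers(n, spec, markers, rng),
                                      columns=markers))
        truth_parts.append(pd.DataFrame({
            "cell_id": [f"{roi_id}_c{counter + i}" for i in range(n)],
            "roi_id": roi_id, "true_population": spec.name,
            "true_hierarchy": spec.hierarchy}))
        counter += n

    if not obs_parts:
        empty_obs = pd.DataFrame(columns=["cell_id", "case_id", "roi_id",
                                          "x_um", "y_um"])
        return (CellTable(obs=empty_obs, raw=pd.DataFrame(columns=markers)),
                GroundTruth(cell=pd.DataFrame(
                    columns=["cell_id", "roi_id", "true_population",
                             "true_hierarchy"])))
    table = CellTable(obs=pd.concat(obs_parts, ignore_index=True),
                      raw=pd.concat(raw_parts, ignore_index=True))
    truth = GroundTruth(cell=pd.concat(truth_parts, ignore_index=True))
    return table, truth


def simulate_cohort(scenario: ScenarioConfig,
                    cases: Sequence[CaseMetadata] | None = None
                    ) -> tuple[CellTable, list[CaseMetadata],
                               list[RoiGeometry], GroundTruth]:
    """Simulate every ROI of every case; deterministic given ``scenario.seed``.

    Per-ROI seeds are derived from the scenario seed through
    ``np.random.SeedSequence((seed, case_index, roi_index))`` so individual
    ROIs are independently reproducible.
    """
    if cases is None:
        cases = generate_case_metadata(scenario.n_static, scenario.n_growing,
                                       seed=scenario.seed)
    tables, truths, geometry = [], [], []
    for ci, case in enumerate(cases):
        for ri in range(scenario.rois_per_case):
            roi_id = f"{case.case_id}_roi{ri + 1}"
            geometry.append(RoiGeometry(roi_id, case.case_id,
                                        scenario.roi_width_um,
                                        scenario.roi_height_um))
            roi_seed = np.random.SeedSequence((scenario.seed, ci, ri))
            t, g = simulate_roi(scenario, case, roi_id,
                                seed=roi_seed.generate_state(1)[0])
            if t.n_cells:
                tables.append(t)
                truths.append(g.cell)
    table = CellTable(
        obs=pd.concat([t.obs for t in tables], ignore_index=True),
        raw=pd.concat([t.raw for t in tables], ignore_index=True))
    truth = GroundTruth(cell=pd.concat(truths, ignore_index=True),
                        case_slopes=dict(scenario.growth_effect))
    return table, list(cases), geometry, truth


# ---------------------------------------------------------------------------
# Planted neighbourhood mosaics
# ---------------------------------------------------------------------------

def plant_neighbourhood_mosaic(K: int, geometry: RoiGeometry,
                               compositions: Sequence[Mapping[str, float]],
                               seed: int, intensity_per_mm2: float = 2000.0,
                               case_id: str = "mosaic"
                               ) -> tuple[CellTable, GroundTruth]:
    """Tile an ROI into K contiguous Voronoi domains with planted compositions.

    K random domain centres partition the window; each cell's population is
    drawn from its domain's composition vector.  The true domain label is
    recorded per cell, giving known ground truth for neighbourhood-cluster
    recovery experiments.
    """
    if K < 1:
        raise ConfigError("K must be ≥ 1")
    if len(compositions) != K:
        raise ConfigError("need one composition per domain")
    pops: list[str] = []
    for comp in compositions:
        total = sum(comp.values())
        if total <= 0:
            raise ConfigError("degenerate composition (all zeros)")
        if abs(total - 1.0) > 1e-6:
            raise ConfigError("compositions must sum to 1")
        for p in comp:
            if p not in pops:
                pops.append(p)

    rng = np.random.default_rng(seed)
    w, h = geometry.width_um, geometry.height_um
    centres = np.column_stack([rng.uniform(0, w, K), rng.uniform(0, h, K)])
    n = rng.poisson(intensity_per_mm2 * geometry.area_mm2)
    xy = np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])
    d2 = ((xy[:, None, :] - centres[None, :, :]) ** 2).sum(axis=2)
    domain = d2.argmin(axis=1)

    labels = np.empty(n, dtype=object)
    for k in range(K):
        members = np.flatnonzero(domain == k)
        probs = np.array([compositions[k].get(p, 0.0) for p in pops])
        probs = probs / probs.sum()
        labels[members] = rng.choice(pops, size=len(members), p=probs)

    obs = pd.DataFrame({
        "cell_id": [f"{geometry.roi_id}_c{i}" for i in range(n)],
        "case_id": case_id, "roi_id": geometry.roi_id,
        "x_um": xy[:, 0], "y_um": xy[:, 1],
        "population_label": labels})
    raw = pd.DataFrame({"intensity": np.ones(n)})
    truth = GroundTruth(cell=pd.DataFrame({
        "cell_id": obs["cell_id"], "roi_id": geometry.roi_id,
        "true_population": labels, "true_hierarchy": "other",
        "true_domain": domain}))
    return CellTable(obs=obs, raw=raw), truth


# ---------------------------------------------------------------------------
# Default scenario — the cohort the package's experiments emulate
# ---------------------------------------------------------------------------

_BG = 0.1  # background raw intensity for markers a population does not express

# Population marker signatures (raw means; unlisted markers sit at background).
_PROFILES: dict[str, dict[str, float]] = {
    "schwann": {"S100B": 3, "PanCytokeratin": 3, "Vimentin": 3, "MHC1": 1},
    "pdl1_schwann": {"S100B": 3, "PanCytokeratin": 3, "Vimentin": 3,
                     "PD-L1": 3, "MHC1": 1},
    "perk_schwann": {"S100B": 3, "PanCytokeratin": 3, "Vimentin": 3,
                     "pERK1/2": 3, "MHC1": 1},
    "alt_act_tam": {"CD16": 3, "CX3CR1": 3, "CD163": 2, "CD11b": 2, "CD68": 2,
                    "Iba1": 2, "CD206": 2, "CD14": 1, "HLA-DR": 1.5},
    "class_act_tam": {"CD68": 2, "Iba1": 2, "CD56": 2, "CD74": 2.5,
                      "HLA-DR": 2},
    "trans_monocyte": {"CD14": 3, "CD16": 2, "CD11c": 2, "CD68": 1.5,
                       "HLA-DR": 1.5},
    "neutrophil": {"CD66b": 3, "CD11b": 2, "CD68": 1},
    "cd8_tem": {"CD8a": 3, "CD3": 3, "CD45": 2, "CD45RO": 2.5,
                "GranzymeB": 1.5, "CX3CR1": 1.5},
    "cd4_t": {"CD4": 3, "CD3": 3, "CD45": 2, "CD45RA": 2, "CX3CR1": 1.5},
    "vasculature": {"SMA": 3, "CD31": 3, "vWF": 2.5},
    "erythrocyte": {"CD235ab": 3},
    "prolif_alt_act_tam": {"Ki-67": 3, "CD16": 3, "CX3CR1": 3, "CD163": 2,
                           "CD11b": 2, "CD68": 2, "Iba1": 2, "CD206": 2,
                           "CD14": 1, "HLA-DR": 1.5},
    "prolif_trans_monocyte": {"Ki-67": 3, "CD14": 3, "CD16": 2, "CD11c": 2,
                              "CD68": 1.5, "HLA-DR": 1.5},
    "prolif_pdl1_schwann": {"Ki-67": 3, "S100B": 3, "PanCytokeratin": 3,
                            "Vimentin": 3, "PD-L1": 3, "MHC1": 1},
    "other": {"Fibrinogen": 2, "Vimentin": 1.5, "MCT4": 1},
}

_HIERARCHY: dict[str, str] = {
    "schwann": "neoplastic", "pdl1_schwann": "neoplastic",
    "perk_schwann": "neoplastic",
    "alt_act_tam": "myeloid", "class_act_tam": "myeloid",
    "trans_monocyte": "myeloid", "neutrophil": "myeloid",
    "cd8_tem": "lymphoid", "cd4_t": "lymphoid",
    "vasculature": "vascular", "erythrocyte": "vascular",
    "prolif_alt_act_tam": "proliferative",
    "prolif_trans_monocyte": "proliferative",
    "prolif_pdl1_schwann": "proliferative",
    "other": "other",
}

def population_profiles(markers: Sequence[str] | None = None
                        ) -> dict[str, dict[str, float]]:
    """Mean raw-expression vectors per population (background filled in)."""
    if markers is None:
        markers = sorted({m for prof in _PROFILES.values() for m in prof})
    return {pop: {m: prof.get(m, _BG) for m in markers}
            for pop, prof in _PROFILES.items()}


def default_scenario(seed: int = 0, noise_cv: float = 0.3,
                     roi_width_um: float = 1000.0,
                     roi_height_um: float = 1000.0,
                     rois_per_case: int = 6,
                     intensity_scale: float = 1.0) -> ScenarioConfig:
    """The default nine-case cohort (four static, five growing).

    Baseline intensities total ≈ 4100 cells/mm² — the density implied by a
    223k-cell cohort over 9 cases × 6 ROIs of 1 mm².  Alternatively activated
    TAMs (and their proliferative fraction) carry planted positive
    density–growth slopes; everything else is growth-neutral.
    ``intensity_scale`` shrinks all densities proportionally for desk-scale
    experiments without changing relative structure.
    """
    profiles = population_profiles()

    base_intensity = {
        "schwann": 1700.0, "pdl1_schwann": 150.0, "perk_schwann": 200.0,
        "alt_act_tam": 500.0, "class_act_tam": 300.0,
        "trans_monocyte": 150.0, "neutrophil": 80.0,
        "cd8_tem": 120.0, "cd4_t": 80.0,
        "vasculature": 200.0, "erythrocyte": 100.0,
        "prolif_alt_act_tam": 60.0, "prolif_trans_monocyte": 30.0,
        "prolif_pdl1_schwann": 30.0, "other": 150.0,
    }
    spatial = {
        # clustered stroma and immune infiltrate
        "schwann": ("thomas", {"thomas_mean_offspring": 20.0,
                               "thomas_sigma_um": 30.0}),
        "pdl1_schwann": ("thomas", {"thomas_mean_offspring": 10.0,
                                    "thomas_sigma_um": 25.0}),
        "perk_schwann": ("thomas", {"thomas_mean_offspring": 10.0,
                                    "thomas_sigma_um": 25.0}),
        "alt_act_tam": ("thomas", {"thomas_mean_offspring": 15.0,
                                   "thomas_sigma_um": 25.0}),
        "class_act_tam": ("thomas", {"thomas_mean_offspring": 10.0,
                                     "thomas_sigma_um": 25.0}),
        "vasculature": ("thomas", {"thomas_mean_offspring": 15.0,
                                   "thomas_sigma_um": 10.0}),
        # cross-type attraction
        "erythrocyte": ("linked", {"link_partner": "vasculature",
                                   "link_sigma_um": 8.0}),
        "cd8_tem": ("linked", {"link_partner": "alt_act_tam",
                               "link_sigma_um": 20.0}),
        "prolif_alt_act_tam": ("linked", {"link_partner": "alt_act_tam",
                                          "link_sigma_um": 10.0}),
        "prolif_pdl1_schwann": ("linked", {"link_partner": "pdl1_schwann",
                                           "link_sigma_um": 10.0}),
    }
    pops = []
    for name, profile in profiles.items():
        process, extra = spatial.get(name, ("poisson", {}))
        pops.append(PopulationSpec(
            name=name, hierarchy=_HIERARCHY[name], mean_expr=profile,
            noise_cv=noise_cv, process=process,
            intensity_per_mm2=base_intensity[name] * intensity_scale,
            **extra))
    growth_effect = {
        "alt_act_tam": 1.5 * intensity_scale,
        "prolif_alt_act_tam": 0.2 * intensity_scale,
    }
    return ScenarioConfig(populations=tuple(pops), n_static=4, n_growing=5,
                          rois_per_case=rois_per_case,
                          roi_width_um=roi_width_um,
                          roi_height_um=roi_height_um,
                          growth_effect=growth_effect, seed=seed)
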