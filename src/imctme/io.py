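"""Reading, writing and validation of the pipeline's external data.

Data model
----------
A cohort is a set of *cases* (patients), each imaged over several rectangular
*ROIs* (regions of interest).  Cell segmentation upstream of this package
yields one record per cell: identifiers, centroid coordinates in micrometres
and the raw mean intensity of every marker in the antibody panel.

Coordinate convention: continuous µm, origin at the ROI top-left corner,
y increasing downward (image convention).  ROI geometry is supplied
explicitly rather than inferred from coordinate extrema, so sparse edges do
not bias per-mm² densities.

Cases are classified *growing* when the preoperative volumetric growth rate
is ≥ 20 %/year and *static* otherwise; stored classification fields are
always recomputed from this rule and discrepancies logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("imctme")

GROWTH_RATE_THRESHOLD = 20.0  # % volume change per year

HIERARCHIES = ("myeloid", "neoplastic", "lymphoid", "vascular", "proliferative", "other")
COMPARTMENTS = ("neoplastic", "immune", "vascular", "proliferative", "other")


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PipelineError):
    """A file does not have the expected layout (missing columns, bad values)."""


class SchemaError(PipelineError):
    """Contents violate the data model (duplicates, unknown markers)."""


class DimensionError(PipelineError):
    """Array shapes are inconsistent."""


class ReferenceError_(PipelineError):
    """A record refers to an entity (ROI, case) that does not exist."""


class ConfigError(PipelineError):
    """A configuration value is outside its documented domain."""


class InsufficientDataError(PipelineError):
    """Too few observations for the requested statistic."""


# ---------------------------------------------------------------------------
# Panel and metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Marker:
    name: str
    compartment: str  # one of COMPARTMENTS
    metal_tag: str = ""

    def __post_init__(self):
        if not self.name:
            raise SchemaError("marker name must be non-empty")
        if self.compartment not in COMPARTMENTS:
            raise SchemaError(f"unknown compartment {self.compartment!r}")


@dataclass(frozen=True)
class PanelDefinition:
    """The antibody panel: marker names, compartments and metal tags."""

    markers: tuple[Marker, ...]

    def __post_init__(self):
        if not self.markers:
            raise SchemaError("panel must contain at least one marker")
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate marker names in panel")

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.markers]

    def __len__(self) -> int:
        return len(self.markers)

    def __contains__(self, name: str) -> bool:
        return name in self.names


def classify_growth(rate_pct_per_year: float) -> str:
    """Growth classification: ``growing`` iff rate ≥ 20 %/year, else ``static``."""
    return "growing" if rate_pct_per_year >= GROWTH_RATE_THRESHOLD else "static"


@dataclass(frozen=True)
class CaseMetadata:
    case_id: str
    sex: str  # F or M
    age_years: int
    tumour_volume_cm3: float
    growth_rate_pct_per_year: float
    classification: str = ""

    def __post_init__(self):
        if self.sex not in ("F", "M"):
            raise SchemaError(f"sex must be F or M, got {self.sex!r}")
        if self.tumour_volume_cm3 < 0:
            raise SchemaError("tumour volume must be non-negative")
        expected = classify_growth(self.growth_rate_pct_per_year)
        if self.classification and self.classification != expected:
            logger.warning(
                "case %s: stored classification %r disagrees with the ≥ 20%%/yr "
                "rule; recomputed to %r", self.case_id, self.classification, expected
            )
        object.__setattr__(self, "classification", expected)


@dataclass(frozen=True)
class RoiGeometry:
    roi_id: str
    case_id: str
    width_um: float
    height_um: float

    def __post_init__(self):
        if self.width_um <= 0 or self.height_um <= 0:
            raise SchemaError("ROI dimensions must be positive")

    @property
    def area_mm2(self) -> float:
        return self.width_um * self.height_um / 1e6


# ---------------------------------------------------------------------------
# Cell table
# ---------------------------------------------------------------------------

OBS_COLUMNS = ("cell_id", "case_id", "roi_id", "x_um", "y_um")
LABEL_COLUMNS = ("hierarchy_label", "population_label", "subpopulation_label")


@dataclass
class CellTable:
    """One record per segmented cell.

    ``obs`` holds identifiers, coordinates and (optional) phenotype labels;
    ``raw`` the raw mean marker intensities; ``norm`` the percentile-scaled
    intensities in [0, 1] once :func:`imctme.quantify.normalize_expression`
    has run.  The three frames share a positional index.
    """

    obs: pd.DataFrame
    raw: pd.DataFrame
    norm: pd.DataFrame | None = None

    def __post_init__(self):
        for col in OBS_COLUMNS:
            if col not in self.obs.columns:
                raise FormatError(f"cell table missing mandatory column {col!r}")
        if len(self.obs) != len(self.raw):
            raise DimensionError("obs and raw frames differ in length")
        self.obs = self.obs.reset_index(drop=True)
        self.raw = self.raw.reset_index(drop=True)
        if self.norm is not None:
            self.norm = self.norm.reset_index(drop=True)

    @property
    def n_cells(self) -> int:
        return len(self.obs)

    @property
    def markers(self) -> list[str]:
        return list(self.raw.columns)

    def validate(self, panel: PanelDefinition | None = None,
                 geometry: Sequence[RoiGeometry] | None = None) -> None:
        if (self.raw.to_numpy() < 0).any():
            raise SchemaError("raw intensities must be non-negative")
        if self.norm is not None:
            vals = self.norm.to_numpy()
            if ((vals < -1e-12) | (vals > 1 + 1e-12)).any():
                raise SchemaError("normalized intensities must lie in [0, 1]")
        dup = self.obs.duplicated(subset=["roi_id", "cell_id"])
        if dup.any():
            raise SchemaError("(roi_id, cell_id) pairs must be unique")
        if panel is not None:
            unknown = set(self.markers) - set(panel.names)
            if unknown:
                raise SchemaError(f"markers absent from panel: {sorted(unknown)}")
        if geometry is not None:
            geo = {g.roi_id: g for g in geometry}
            for roi_id, sub in self.obs.groupby("roi_id", sort=False):
                if roi_id not in geo:
                    raise ReferenceError_(f"no geometry for ROI {roi_id!r}")
                g = geo[roi_id]
                bad = ((sub["x_um"] < 0) | (sub["x_um"] > g.width_um) |
                       (sub["y_um"] < 0) | (sub["y_um"] > g.height_um))
                if bad.any():
                    raise SchemaError(
                        f"{int(bad.sum())} cells outside ROI {roi_id!r} window")

    def subset(self, mask) -> "CellTable":
        mask = np.asarray(mask)
        return CellTable(
            obs=self.obs.loc[mask].copy(),
            raw=self.raw.loc[mask].copy(),
            norm=None if self.norm is None else self.norm.loc[mask].copy(),
        )

    def roi(self, roi_id: str) -> "CellTable":
        return self.subset((self.obs["roi_id"] == roi_id).to_numpy())

    def coords(self) -> np.ndarray:
        return self.obs[["x_um", "y_um"]].to_numpy(dtype=float)


def concat_cell_tables(tables: Iterable[CellTable]) -> CellTable:
    tables = [t for t in tables if t.n_cells > 0]
    if not tables:
        raise InsufficientDataError("nothing to concatenate")
    has_norm = all(t.norm is not None for t in tables)
    return CellTable(
        obs=pd.concat([t.obs for t in tables], ignore_index=True),
        raw=pd.concat([t.raw for t in tables], ignore_index=True),
        norm=(pd.concat([t.norm for t in tables], ignore_index=True)
              if has_norm else None),
    )


# ---------------------------------------------------------------------------
# Delimited-text readers/writers
# ---------------------------------------------------------------------------

def write_cell_table(table: CellTable, path: str | Path) -> None:
    """Write a cell table as a single wide CSV (``raw_``/``norm_`` prefixes)."""
    wide = table.obs.copy()
    for m in table.markers:
        wide[f"raw_{m}"] = table.raw[m].to_numpy()
    if table.norm is not None:
        for m in table.norm.columns:
            wide[f"norm_{m}"] = table.norm[m].to_numpy()
    wide.to_csv(path, index=False)


def read_cell_table(path: str | Path, panel: PanelDefinition,
                    geometry: Sequence[RoiGeometry] | None = None,
                    return_report: bool = False):
    """Read and validate a cell-table CSV.

    Rows whose coordinates fall outside their ROI window are rejected; the
    number rejected is logged (and returned when ``return_report`` is set).
    """
    df = pd.read_csv(path, dtype={"cell_id": str, "case_id": str, "roi_id": str})
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cell table missing mandatory columns {missing}")
    raw_cols = [c for c in df.columns if c.startswith("raw_")]
    norm_cols = [c for c in df.columns if c.startswith("norm_")]
    markers = [c[4:] for c in raw_cols]
    unknown = set(markers) - set(panel.names)
    if unknown:
        raise SchemaError(f"marker columns absent from panel: {sorted(unknown)}")

    n_rejected = 0
    if geometry is not None:
        geo = {g.roi_id: g for g in geometry}
        missing_geo = set(df["roi_id"]) - set(geo)
        if missing_geo:
            raise ReferenceError_(f"no geometry for ROIs {sorted(missing_geo)}")
        w = df["roi_id"].map(lambda r: geo[r].width_um)
        h = df["roi_id"].map(lambda r: geo[r].height_um)
        ok = ((df["x_um"] >= 0) & (df["x_um"] <= w) &
              (df["y_um"] >= 0) & (df["y_um"] <= h))
        n_rejected = int((~ok).sum())
        if n_rejected:
            logger.warning("read_cell_table: rejected %d rows outside their ROI window",
                           n_rejected)
        df = df.loc[ok].reset_index(drop=True)

    obs_cols = [c for c in df.columns if c in OBS_COLUMNS + LABEL_COLUMNS]
    table = CellTable(
        obs=df[obs_cols].copy(),
        raw=df[raw_cols].rename(columns=dict(zip(raw_cols, markers))),
        norm=(df[norm_cols].rename(columns={c: c[5:] for c in norm_cols})
              if norm_cols else None),
    )
    table.validate(panel=panel)
    if return_report:
        return table, {"n_rejected": n_rejected, "n_cells": table.n_cells}
    return table


def read_panel(path: str | Path) -> PanelDefinition:
    """Read a panel definition from CSV (name, compartment, metal_tag) or YAML."""
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        spec = yaml.safe_load(path.read_text())
        rows = spec["markers"] if isinstance(spec, dict) else spec
        markers = [Marker(r["name"], r["compartment"], r.get("metal_tag", ""))
                   for r in rows]
    else:
        df = pd.read_csv(path)
        for col in ("name", "compartment"):
            if col not in df.columns:
                raise FormatError(f"panel file missing column {col!r}")
        markers = [Marker(str(r["name"]), str(r["compartment"]),
                          str(r.get("metal_tag", "")))
                   for _, r in df.iterrows()]
    return PanelDefinition(tuple(markers))


def write_panel(panel: PanelDefinition, path: str | Path) -> None:
    pd.DataFrame([{"name": m.name, "compartment": m.compartment,
                   "metal_tag": m.metal_tag} for m in panel.markers]
                 ).to_csv(path, index=False)


def read_case_metadata(path: str | Path) -> list[CaseMetadata]:
    """Read case metadata from CSV; growth classification is recomputed."""
    df = pd.read_csv(path, dtype={"case_id": str})
    needed = {"case_id", "sex", "age_years", "tumour_volume_cm3",
              "growth_rate_pct_per_year"}
    missing = needed - set(df.columns)
    if missing:
        raise FormatError(f"case metadata missing columns {sorted(missing)}")
    if df["case_id"].duplicated().any():
        raise SchemaError("duplicate case ids")
    return [CaseMetadata(
        case_id=str(r["case_id"]), sex=str(r["sex"]),
        age_years=int(r["age_years"]),
        tumour_volume_cm3=float(r["tumour_volume_cm3"]),
        growth_rate_pct_per_year=float(r["growth_rate_pct_per_year"]),
        classification=str(r.get("classification", "") or ""),
    ) for _, r in df.iterrows()]


def write_case_metadata(cases: Sequence[CaseMetadata], path: str | Path) -> None:
    pd.DataFrame([{
        "case_id": c.case_id, "sex": c.sex, "age_years": c.age_years,
        "tumour_volume_cm3": c.tumour_volume_cm3,
        "growth_rate_pct_per_year": c.growth_rate_pct_per_year,
        "classification": c.classification,
    } for c in cases]).to_csv(path, index=False)


def read_roi_geometry(path: str | Path) -> list[RoiGeometry]:
    df = pd.read_csv(path, dtype={"roi_id": str, "case_id": str})
    return [RoiGeometry(str(r["roi_id"]), str(r["case_id"]),
                        float(r["width_um"]), float(r["height_um"]))
            for _, r in df.iterrows()]


def write_roi_geometry(geometry: Sequence[RoiGeometry], path: str | Path) -> None:
    pd.DataFrame([{"roi_id": g.roi_id, "case_id": g.case_id,
                   "width_um": g.width_um, "height_um": g.height_um}
                  for g in geometry]).to_csv(path, index=False)


def default_panel() -> PanelDefinition:
    """The packaged 35-marker vestibular-schwannoma IMC panel."""
    with resources.as_file(resources.files("imctme.data") / "panel.csv") as p:
        return read_panel(p)


def default_case_metadata() -> list[CaseMetadata]:
    """The packaged nine-case clinical cohort (four static, five growing)."""
    with resources.as_file(resources.files("imctme.data") / "cases.csv") as p:
        return read_case_metadata(p)


# ---------------------------------------------------------------------------
# Image extraction
# ---------------------------------------------------------------------------

def extract_cell_table(image_stack: np.ndarray, label_mask: np.ndarray,
                       panel: PanelDefinition, pixel_size_um: float = 1.0,
                       case_id: str = "case", roi_id: str = "roi") -> CellTable:
    """Extract per-cell mean intensities and centroids from a labelled image.

    ``image_stack`` is (channels × rows × cols), channels ordered as the
    panel; ``label_mask`` an integer mask where 0 is background and each
    positive label is one cell.  Raw intensity is the mean over the cell's
    pixels; the centroid is converted to µm at ``pixel_size_um``.
    """
    from skimage.measure import regionprops_table

    image_stack = np.asarray(image_stack)
    label_mask = np.asarray(label_mask)
    if image_stack.ndim != 3:
        raise DimensionError("image stack must be 3-D (channels, rows, cols)")
    if label_mask.shape != image_stack.shape[1:]:
        raise DimensionError("label mask shape must equal image spatial dims")
    if image_stack.shape[0] != len(panel):
        raise DimensionError(
            f"stack has {image_stack.shape[0]} channels but panel has {len(panel)}")
    if pixel_size_um <= 0:
        raise ConfigError("pixel_size_um must be positive")

    if not (label_mask > 0).any():
        logger.warning("extract_cell_table: mask contains no cells")
        return CellTable(
            obs=pd.DataFrame(columns=list(OBS_COLUMNS)),
            raw=pd.DataFrame(columns=panel.names),
        )

    props = regionprops_table(
        label_mask, intensity_image=np.moveaxis(image_stack, 0, -1),
        properties=("label", "centroid", "intensity_mean"))
    labels = props["label"]
    obs = pd.DataFrame({
        "cell_id": [str(int(l)) for l in labels],
        "case_id": case_id,
        "roi_id": roi_id,
        "x_um": props["centroid-1"] * pixel_size_um,
        "y_um": props["centroid-0"] * pixel_size_um,
    })
    raw = pd.DataFrame({m: props[f"intensity_mean-{i}"]
                        for i, m in enumerate(panel.names)})
    return CellTable(obs=obs, raw=raw)


def read_image_stack(path: str | Path) -> np.ndarray:
    import tifffile
    return tifffile.imread(path)


def write_image_stack(arr: np.ndarray, path: str | Path) -> None:
    import tifffile
    tifffile.imwrite(path, np.asarray(arr))
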