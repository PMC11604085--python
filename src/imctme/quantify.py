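"""Expression normalization, per-case summaries and cohort statistics.

Raw mean intensities are scaled marker-by-marker to the cohort-wide 99.9th
percentile and clipped into [0, 1].  Percentiles pool all cells of the
cohort (not per ROI) so that per-case averages remain comparable, and use
linear interpolation between order statistics.

Hypothesis tests follow a normality-gated scheme: Shapiro–Wilk at α = 0.05
on each variable, then Pearson correlation (both normal) or Spearman
otherwise, and unpaired two-tailed t-test (both groups normal) or
Mann–Whitney otherwise; two-way designs use a 2-way ANOVA with interaction.
A simple linear regression is always fitted on the raw pairs so slopes are
reported regardless of which correlation branch ran.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import (CaseMetadata, CellTable, InsufficientDataError, PipelineError,
                 ReferenceError_, RoiGeometry)

logger = logging.getLogger("imctme")

DEFAULT_PERCENTILE = 99.9
ALPHA = 0.05


@dataclass(frozen=True)
class CorrelationResult:
    method: str                  # pearson | spearman
    r: float
    p_two_tailed: float
    slope: float
    intercept: float
    normality_p_x: float
    normality_p_y: float
    n: int


@dataclass(frozen=True)
class GroupComparisonResult:
    test: str                    # t_test | mann_whitney | anova_2way
    statistic: float
    p: float
    group_summaries: Mapping[str, Mapping[str, float]]
    effects: Mapping[str, float] | None = None   # per-term p for 2-way ANOVA


# ---------------------------------------------------------------------------
# Normalization and summaries
# ---------------------------------------------------------------------------

def normalize_expression(table: CellTable,
                         q: float = DEFAULT_PERCENTILE) -> CellTable:
    """Scale each marker to its cohort-wide q-th percentile, clipped to [0, 1].

    Per marker, P = q-th percentile of the pooled raw values (linear
    interpolation); norm = min(raw, P) / P.  A marker whose percentile is 0
    is set to 0 everywhere and a warning logged.
    """
    if table.n_cells == 0:
        return CellTable(obs=table.obs.copy(), raw=table.raw.copy(),
                         norm=table.raw.copy())
    norm = {}
    for m in table.markers:
        vals = table.raw[m].to_numpy(dtype=float)
        p = np.percentile(vals, q, method="linear")
        if p <= 0:
            logger.warning("normalize_expression: marker %s has zero %gth "
                           "percentile; normalized values set to 0", m, q)
            norm[m] = np.zeros(len(vals))
        else:
            norm[m] = np.minimum(vals, p) / p
    return CellTable(obs=table.obs.copy(), raw=table.raw.copy(),
                     norm=pd.DataFrame(norm))


def case_mean_expression(table: CellTable, marker: str) -> dict[str, float]:
    """Mean normalized marker value per case, all ROIs pooled."""
    if table.norm is None:
        raise PipelineError("normalized values required; "
                            "run normalize_expression first")
    if marker not in table.norm.columns:
        raise ReferenceError_(f"unknown marker {marker!r}")
    grouped = table.norm[marker].groupby(table.obs["case_id"]).mean()
    return {str(k): float(v) for k, v in grouped.items()}


def cell_density(table: CellTable, geometry: Sequence[RoiGeometry],
                 stratum: str = "case") -> dict:
    """Cells per mm², pooled over each case's ROIs.

    ``stratum`` is ``case``, ``case×population`` or ``case×hierarchy``.
    The denominator is the summed area of the case's ROIs (all ROIs with
    geometry, whether or not they contain cells); strata with zero cells
    report density 0.
    """
    geo = {g.roi_id: g for g in geometry}
    unknown = set(table.obs["roi_id"]) - set(geo)
    if unknown:
        raise ReferenceError_(f"no geometry for ROIs {sorted(unknown)}")
    case_area = {}
    for g in geometry:
        case_area[g.case_id] = case_area.get(g.case_id, 0.0) + g.area_mm2

    if stratum == "case":
        counts = table.obs.groupby("case_id").size()
        return {c: float(counts.get(c, 0)) / a for c, a in case_area.items()}

    if stratum == "case×population":
        label_col = "population_label"
    elif stratum == "case×hierarchy":
        label_col = "hierarchy_label"
    else:
        raise PipelineError(f"unknown stratum {stratum!r}")
    if label_col not in table.obs.columns:
        raise PipelineError(f"{label_col} labels required for stratum {stratum!r}")
    labels = sorted(table.obs[label_col].dropna().unique())
    counts = table.obs.groupby(["case_id", label_col]).size()
    out = {}
    for c, a in case_area.items():
        for lab in labels:
            out[(c, lab)] = float(counts.get((c, lab), 0)) / a
    return out


# ---------------------------------------------------------------------------
# Normality-gated statistics
# ---------------------------------------------------------------------------

def _shapiro_p(x: np.ndarray) -> float:
    if len(x) < 3 or np.ptp(x) == 0:
        return np.nan
    return float(stats.shapiro(x).pvalue)


def correlate_with_growth(values: Mapping[str, float],
                          metadata: Sequence[CaseMetadata],
                          alpha: float = ALPHA) -> CorrelationResult:
    """Correlate a per-case quantity with volumetric growth rate.

    Shapiro–Wilk on both variables; two-tailed Pearson if both pass at
    ``alpha``, otherwise two-tailed Spearman.  A simple linear regression is
    fitted on the raw pairs regardless of the branch taken.
    """
    rates = {c.case_id: c.growth_rate_pct_per_year for c in metadata}
    pairs = [(rates[k], v) for k, v in values.items() if k in rates]
    if len(pairs) < 4:
        raise InsufficientDataError(
            f"need ≥ 4 paired observations, got {len(pairs)}")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise PipelineError("zero variance: correlation undefined")

    px, py = _shapiro_p(x), _shapiro_p(y)
    reg = stats.linregress(x, y)
    if not np.isnan(px) and not np.isnan(py) and px >= alpha and py >= alpha:
        r, p = stats.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = stats.spearmanr(x, y)
        method = "spearman"
    return CorrelationResult(method=method, r=float(r), p_two_tailed=float(p),
                             slope=float(reg.slope),
                             intercept=float(reg.intercept),
                             normality_p_x=px, normality_p_y=py, n=len(x))


def _summaries(groups: Mapping[str, np.ndarray]) -> dict:
    return {name: {"n": int(len(v)), "mean": float(np.mean(v)),
                   "median": float(np.median(v))}
            for name, v in groups.items()}


def compare_two_groups(a: Sequence[float], b: Sequence[float],
                       names: tuple[str, str] = ("a", "b"),
                       alpha: float = ALPHA) -> GroupComparisonResult:
    """Two-tailed unpaired comparison, normality-gated.

    t-test when both groups pass Shapiro–Wilk at ``alpha``; otherwise
    Mann–Whitney U.  Groups too small for Shapiro–Wilk (n < 3) fall back to
    Mann–Whitney with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InsufficientDataError("both groups must be non-empty")
    pa, pb = _shapiro_p(a), _shapiro_p(b)
    if np.isnan(pa) or np.isnan(pb):
        if min(len(a), len(b)) < 3:
            logger.warning("compare_two_groups: group too small for "
                           "Shapiro–Wilk; using Mann–Whitney")
        normal = False
    else:
        normal = pa >= alpha and pb >= alpha
    if normal:
        res = stats.ttest_ind(a, b)
        test = "t_test"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann_whitney"
    return GroupComparisonResult(
        test=test, statistic=float(res.statistic), p=float(res.pvalue),
        group_summaries=_summaries({names[0]: a, names[1]: b}))


def compare_groups(values: Mapping[str, float],
                   metadata: Sequence[CaseMetadata],
                   alpha: float = ALPHA) -> GroupComparisonResult:
    """Static-versus-growing comparison of a per-case quantity."""
    cls = {c.case_id: c.classification for c in metadata}
    a = [v for k, v in values.items() if cls.get(k) == "static"]
    b = [v for k, v in values.items() if cls.get(k) == "growing"]
    return compare_two_groups(a, b, names=("static", "growing"), alpha=alpha)


def two_way_anova(data: pd.DataFrame, value: str, factor_a: str,
                  factor_b: str) -> GroupComparisonResult:
    """2-way ANOVA with interaction on a tidy frame of normally distributed data."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = data[[value, factor_a, factor_b]].dropna().copy()
    df.columns = ["value", "fa", "fb"]
    if df.groupby(["fa", "fb"]).size().min() < 1:
        raise InsufficientDataError("incomplete factor crossing")
    model = smf.ols("value ~ C(fa) * C(fb)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    inter = "C(fa):C(fb)"
    effects = {str(ix): float(row["PR(>F)"])
               for ix, row in table.iterrows() if ix != "Residual"}
    groups = {f"{fa}|{fb}": sub["value"].to_numpy()
              for (fa, fb), sub in df.groupby(["fa", "fb"])}
    return GroupComparisonResult(
        test="anova_2way", statistic=float(table.loc[inter, "F"]),
        p=float(table.loc[inter, "PR(>F)"]),
        group_summaries=_summaries(groups), effects=effects)


def correlation_results_to_frame(results: Mapping[str, CorrelationResult]
                                 ) -> pd.DataFrame:
    """Tidy CSV-ready frame of correlation results keyed by stratum."""
    return pd.DataFrame([{
        "stratum": k, "method": v.method, "r": v.r, "p": v.p_two_tailed,
        "slope": v.slope, "intercept": v.intercept, "n": v.n}
        for k, v in results.items()])
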