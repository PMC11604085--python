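"""Single-cell spatial association statistics.

Two complementary screens identify co-occurring cell-type pairs:

* **Quadrat correlation matrices (QCM)** — each ROI is divided into
  100 µm-sided square quadrats; per-quadrat population counts are correlated
  pairwise (Pearson), p-values Benjamini–Hochberg adjusted over all pairs,
  and non-significant correlations set to zero.
* **Cross-pair correlation functions (cross-PCF)** — for an ordered
  (sender, receiver) pair, ĝ(r) measures the density of receivers at
  distance r from senders relative to complete spatial randomness:

      ĝ(bin) = |W| / (n_A · n_B) · Σ_{a∈A} N_b(a) / area_W(a; r, r+dr)

  where N_b(a) counts receivers in the annulus [r, r+dr) around sender a and
  area_W is the annulus∩window area.  Senders always lie inside the
  rectangular window, so that area has an exact closed form (four-quadrant
  circle-in-rectangle decomposition).  g = 1 under independence; g > 1
  attraction; g < 1 repulsion.  A 95% bootstrap confidence interval
  (independent resampling of senders and receivers) at the bin containing
  r = 20 µm yields the association call: positive (CI low > 1), negative
  (CI high < 1) or none.

Pairs significant under *both* screens are assembled into a directed
adjacency network whose edges carry g(r=20 µm) and the percentage of
retained spatial-graph contacts the sender type makes with the receiver type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import (ConfigError, InsufficientDataError, PipelineError,
                 RoiGeometry)
from .neighbourhoods import SpatialGraph

logger = logging.getLogger("imctme")

DEFAULT_QUADRAT_SIDE = 100.0   # µm
DEFAULT_R_MAX = 300.0          # µm
DEFAULT_DR = 10.0              # µm
DEFAULT_N_BOOT = 200
ALPHA = 0.05


# ---------------------------------------------------------------------------
# Quadrat counts and correlation matrices
# ---------------------------------------------------------------------------

def quadrat_counts(obs: pd.DataFrame, geometry: RoiGeometry,
                   side_um: float = DEFAULT_QUADRAT_SIDE,
                   label_col: str = "population_label") -> pd.DataFrame:
    """Per-quadrat population counts for one ROI.

    The grid is axis-aligned from the ROI origin; only fully contained
    quadrats are kept and cells are assigned by the half-open rule
    [x0, x0+side) × [y0, y0+side).
    """
    if side_um <= 0:
        raise ConfigError("side_um must be positive")
    nx = int(geometry.width_um // side_um)
    ny = int(geometry.height_um // side_um)
    populations = sorted(obs[label_col].dropna().unique())
    if nx == 0 or ny == 0:
        logger.warning("quadrat_counts %s: ROI smaller than one quadrat",
                       geometry.roi_id)
        return pd.DataFrame(columns=populations)
    ix = np.floor(obs["x_um"].to_numpy() / side_um).astype(int)
    iy = np.floor(obs["y_um"].to_numpy() / side_um).astype(int)
    inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)

    index = pd.MultiIndex.from_product([range(nx), range(ny)],
                                       names=["qx", "qy"])
    counts = pd.DataFrame(0, index=index, columns=populations, dtype=int)
    sub = pd.DataFrame({"qx": ix[inside], "qy": iy[inside],
                        "pop": obs[label_col].to_numpy()[inside]})
    tallied = sub.groupby(["qx", "qy", "pop"]).size()
    for (qx, qy, pop), v in tallied.items():
        counts.loc[(qx, qy), pop] = v
    return counts


@dataclass
class QCMResult:
    r: pd.DataFrame
    p_raw: pd.DataFrame
    p_adj: pd.DataFrame
    gated: pd.DataFrame            # non-significant entries set to 0
    alpha: float = ALPHA
    notes: tuple[str, ...] = ()


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment (monotone, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise PipelineError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def quadrat_correlation_matrix(counts: pd.DataFrame,
                               alpha: float = ALPHA) -> QCMResult:
    """Pairwise Pearson correlation of per-quadrat counts, BH-gated."""
    if len(counts) < 10:
        raise InsufficientDataError(
            f"need ≥ 10 quadrats, got {len(counts)}")
    pops = list(counts.columns)
    k = len(pops)
    r = pd.DataFrame(np.eye(k), index=pops, columns=pops)
    p_raw = pd.DataFrame(np.zeros((k, k)), index=pops, columns=pops)
    notes = []
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    pvec = []
    for i, j in pairs:
        x = counts[pops[i]].to_numpy(dtype=float)
        y = counts[pops[j]].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rij, pij = 0.0, 1.0
            notes.append(f"zero variance: {pops[i]}–{pops[j]}")
        else:
            rij, pij = stats.pearsonr(x, y)
        r.iloc[i, j] = r.iloc[j, i] = rij
        p_raw.iloc[i, j] = p_raw.iloc[j, i] = pij
        pvec.append(pij)
    adj = bh_adjust(pvec)
    p_adj = pd.DataFrame(np.zeros((k, k)), index=pops, columns=pops)
    gated = r.copy()
    for (i, j), a in zip(pairs, adj):
        p_adj.iloc[i, j] = p_adj.iloc[j, i] = a
        if a >= alpha:
            gated.iloc[i, j] = gated.iloc[j, i] = 0.0
    return QCMResult(r=r, p_raw=p_raw, p_adj=p_adj, gated=gated, alpha=alpha,
                     notes=tuple(notes))


def qcm_significant_pairs(results: Sequence[QCMResult],
                          min_fraction: float = 0.5) -> set[frozenset]:
    """Pairs significant (gated ≠ 0) in at least ``min_fraction`` of the
    per-ROI matrices in which both populations occur."""
    seen: dict[frozenset, int] = {}
    hits: dict[frozenset, int] = {}
    for res in results:
        pops = list(res.gated.columns)
        for i in range(len(pops)):
            for j in range(i + 1, len(pops)):
                key = frozenset((pops[i], pops[j]))
                seen[key] = seen.get(key, 0) + 1
                if res.gated.iloc[i, j] != 0:
                    hits[key] = hits.get(key, 0) + 1
    return {k for k, n in seen.items()
            if hits.get(k, 0) / n >= min_fraction}


# ---------------------------------------------------------------------------
# Cross-pair correlation function
# ---------------------------------------------------------------------------

def _quadrant_area(a: np.ndarray, b: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Area of the disc quadrant {x∈[0,a], y∈[0,b], x²+y²≤r²} for a, b ≥ 0."""
    qa = np.minimum(a, r)
    qb = np.minimum(b, r)
    with np.errstate(invalid="ignore"):
        xc = np.sqrt(np.maximum(r * r - qb * qb, 0.0))

        def F(x):
            return 0.5 * (x * np.sqrt(np.maximum(r * r - x * x, 0.0)) +
                          r * r * np.arcsin(np.clip(np.divide(
                              x, r, out=np.zeros_like(x), where=r > 0), -1, 1)))

        full = qa * qb
        clipped = xc * qb + F(qa) - F(xc)
    return np.where(qa <= xc, full, clipped)


def disc_window_area(centres: np.ndarray, radius: np.ndarray,
                     window: tuple[float, float]) -> np.ndarray:
    """Exact area of disc∩window for disc centres inside the rectangle.

    ``centres`` is (n, 2); ``radius`` broadcasts against n (or n × k for k
    radii per centre)."""
    W, H = window
    x, y = centres[:, 0], centres[:, 1]
    r = np.asarray(radius, dtype=float)
    if r.ndim == 2:
        x, y = x[:, None], y[:, None]
    area = np.zeros(np.broadcast_shapes(x.shape, r.shape))
    for dx in (x, W - x):
        for dy in (y, H - y):
            area += _quadrant_area(np.broadcast_to(dx, area.shape),
                                   np.broadcast_to(dy, area.shape),
                                   np.broadcast_to(r, area.shape))
    return area


def _annulus_areas(senders: np.ndarray, edges: np.ndarray,
                   window: tuple[float, float], correction: str) -> np.ndarray:
    """(n_senders × n_bins) annulus∩window areas."""
    n_bins = len(edges) - 1
    if correction == "area":
        disc = disc_window_area(senders, edges[None, :], window)
        return np.diff(disc, axis=1)
    plain = np.pi * np.diff(edges ** 2)
    return np.broadcast_to(plain, (len(senders), n_bins)).copy()


def _bin_matrix(senders: np.ndarray, receivers: np.ndarray,
                window: tuple[float, float], edges: np.ndarray,
                correction: str, auto: bool) -> np.ndarray:
    """Bin index of each sender–receiver distance (sentinel n_bins if out of
    range or a self-pair)."""
    diff = senders[:, None, :] - receivers[None, :, :]
    if correction == "torus":
        W, H = window
        diff = np.abs(diff)
        diff[..., 0] = np.minimum(diff[..., 0], W - diff[..., 0])
        diff[..., 1] = np.minimum(diff[..., 1], H - diff[..., 1])
    d = np.sqrt((diff ** 2).sum(axis=2))
    n_bins = len(edges) - 1
    idx = np.searchsorted(edges, d, side="right") - 1
    idx[(d < edges[0]) | (d >= edges[-1])] = n_bins
    if auto:
        np.fill_diagonal(idx, n_bins)
    return idx.astype(np.int32)


def cross_pcf(senders: np.ndarray, receivers: np.ndarray,
              window: tuple[float, float], r_max: float = DEFAULT_R_MAX,
              dr: float = DEFAULT_DR, correction: str = "area",
              auto: bool | None = None
              ) -> tuple[np.ndarray, np.ndarray]:
    """Border-corrected cross-PCF estimate.

    Returns (bin left edges, ĝ per bin).  ``auto`` marks sender == receiver
    (self-pairs excluded); inferred from object identity when None.
    """
    senders = np.asarray(senders, dtype=float)
    receivers = np.asarray(receivers, dtype=float)
    if len(senders) == 0 or len(receivers) == 0:
        raise InsufficientDataError("both point sets must be non-empty")
    if dr <= 0 or r_max <= 0:
        raise ConfigError("r_max and dr must be positive")
    if correction not in ("area", "torus", "none"):
        raise ConfigError(f"unknown correction {correction!r}")
    if auto is None:
        auto = senders is receivers or (senders.shape == receivers.shape and
                                        np.array_equal(senders, receivers))
    edges = np.arange(0.0, r_max + dr / 2, dr)
    n_bins = len(edges) - 1
    bins = _bin_matrix(senders, receivers, window, edges, correction, auto)
    counts = np.zeros((len(senders), n_bins + 1))
    rows = np.repeat(np.arange(len(senders)), len(receivers))
    np.add.at(counts, (rows, bins.ravel()), 1.0)
    counts = counts[:, :n_bins]
    areas = _annulus_areas(senders, edges, window, correction)
    W, H = window
    n_b = len(receivers) - 1 if auto else len(receivers)
    per_sender = np.divide(counts, areas, out=np.zeros_like(counts),
                           where=areas > 0)
    g = (W * H) / (len(senders) * max(n_b, 1)) * per_sender.sum(axis=0)
    return edges[:-1], g


@dataclass
class CrossPCFResult:
    sender: str
    receiver: str
    r_left_edges: np.ndarray
    g: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    gr20: float
    call: str                     # positive | negative | none
    n_boot: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sender": self.sender, "receiver": self.receiver,
            "r": self.r_left_edges, "g": self.g,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "call": self.call})


def bootstrap_pcf(senders: np.ndarray, receivers: np.ndarray,
                  window: tuple[float, float], r_max: float = DEFAULT_R_MAX,
                  dr: float = DEFAULT_DR, n_boot: int = DEFAULT_N_BOOT,
                  seed: int = 0, correction: str = "area",
                  sender_name: str = "sender", receiver_name: str = "receiver",
                  r_call: float = 20.0) -> CrossPCFResult:
    """Cross-PCF with a percentile bootstrap CI and the g(r=20 µm) call.

    Senders and receivers are resampled independently with replacement
    (original sizes); the call is positive when the 95% CI at the bin
    containing ``r_call`` lies above 1, negative when below 1, else none.
    """
    senders = np.asarray(senders, dtype=float)
    receivers = np.asarray(receivers, dtype=float)
    if n_boot < 50:
        logger.warning("bootstrap_pcf: n_boot=%d gives unstable CIs", n_boot)
    auto = senders.shape == receivers.shape and np.array_equal(senders,
                                                               receivers)
    edges = np.arange(0.0, r_max + dr / 2, dr)
    n_bins = len(edges) - 1
    n_a, n_r = len(senders), len(receivers)
    if n_a == 0 or n_r == 0:
        raise InsufficientDataError("both point sets must be non-empty")
    W, H = window

    bins = _bin_matrix(senders, receivers, window, edges, correction, auto)
    areas = _annulus_areas(senders, edges, window, correction)
    inv_area = np.divide(1.0, areas, out=np.zeros_like(areas),
                         where=areas > 0)
    flat = (np.arange(n_a)[:, None] * (n_bins + 1) + bins).ravel()
    n_b_eff = max(n_r - 1 if auto else n_r, 1)

    def estimate(u: np.ndarray, w: np.ndarray) -> np.ndarray:
        weights = np.broadcast_to(w[None, :], (n_a, n_r)).ravel()
        per = np.bincount(flat, weights=weights,
                          minlength=n_a * (n_bins + 1))
        per = per.reshape(n_a, n_bins + 1)[:, :n_bins]
        return (W * H) / (n_a * n_b_eff) * (u @ (per * inv_area))

    g = estimate(np.ones(n_a), np.ones(n_r))
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, n_bins))
    for b in range(n_boot):
        u = np.bincount(rng.integers(0, n_a, n_a), minlength=n_a).astype(float)
        w = np.bincount(rng.integers(0, n_r, n_r), minlength=n_r).astype(float)
        boots[b] = estimate(u, w)
    ci_low = np.percentile(boots, 2.5, axis=0)
    ci_high = np.percentile(boots, 97.5, axis=0)

    call_bin = min(int(r_call // dr), n_bins - 1)
    if ci_low[call_bin] > 1.0:
        call = "positive"
    elif ci_high[call_bin] < 1.0:
        call = "negative"
    else:
        call = "none"
    return CrossPCFResult(sender=sender_name, receiver=receiver_name,
                          r_left_edges=edges[:-1], g=g, ci_low=ci_low,
                          ci_high=ci_high, gr20=float(g[call_bin]), call=call,
                          n_boot=n_boot)


def bootstrap_pcf_pooled(rois: Sequence[tuple[np.ndarray, np.ndarray,
                                              tuple[float, float]]],
                         r_max: float = DEFAULT_R_MAX, dr: float = DEFAULT_DR,
                         n_boot: int = DEFAULT_N_BOOT, seed: int = 0,
                         correction: str = "area",
                         sender_name: str = "sender",
                         receiver_name: str = "receiver",
                         auto: bool = False,
                         r_call: float = 20.0) -> CrossPCFResult:
    """Cross-PCF pooled over several ROIs of one group.

    Each ROI contributes its senders' border-corrected annulus counts within
    its own window; normalization uses the pooled point totals and the
    summed window area, so ĝ = 1 under independence in every ROI.  The
    bootstrap resamples senders and receivers independently with
    replacement within each ROI.  With a single ROI this reduces exactly to
    :func:`bootstrap_pcf`.
    """
    edges = np.arange(0.0, r_max + dr / 2, dr)
    n_bins = len(edges) - 1
    parts = []
    n_a_tot = n_r_tot = 0
    area_tot = 0.0
    for senders, receivers, window in rois:
        senders = np.asarray(senders, dtype=float)
        receivers = np.asarray(receivers, dtype=float)
        n_a_tot += len(senders)
        n_r_tot += len(receivers)
        area_tot += window[0] * window[1]
        if len(senders) == 0 or len(receivers) == 0:
            continue
        bins = _bin_matrix(senders, receivers, window, edges, correction, auto)
        areas = _annulus_areas(senders, edges, window, correction)
        inv_area = np.divide(1.0, areas, out=np.zeros_like(areas),
                             where=areas > 0)
        flat = (np.arange(len(senders))[:, None] * (n_bins + 1) + bins).ravel()
        parts.append((len(senders), len(receivers), flat, inv_area))
    if n_a_tot == 0 or n_r_tot == 0:
        raise InsufficientDataError("both point sets must be non-empty")
    n_b_eff = max(n_r_tot - 1 if auto else n_r_tot, 1)

    def estimate(weight_fn) -> np.ndarray:
        total = np.zeros(n_bins)
        for n_a, n_r, flat, inv_area in parts:
            u, w = weight_fn(n_a, n_r)
            weights = np.broadcast_to(w[None, :], (n_a, n_r)).ravel()
            per = np.bincount(flat, weights=weights,
                              minlength=n_a * (n_bins + 1))
            per = per.reshape(n_a, n_bins + 1)[:, :n_bins]
            total += u @ (per * inv_area)
        return area_tot / (n_a_tot * n_b_eff) * total

    g = estimate(lambda n_a, n_r: (np.ones(n_a), np.ones(n_r)))
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, n_bins))
    for b in range(n_boot):
        boots[b] = estimate(lambda n_a, n_r: (
            np.bincount(rng.integers(0, n_a, n_a), minlength=n_a).astype(float),
            np.bincount(rng.integers(0, n_r, n_r), minlength=n_r).astype(float)))
    ci_low = np.percentile(boots, 2.5, axis=0)
    ci_high = np.percentile(boots, 97.5, axis=0)
    call_bin = min(int(r_call // dr), n_bins - 1)
    if ci_low[call_bin] > 1.0:
        call = "positive"
    elif ci_high[call_bin] < 1.0:
        call = "negative"
    else:
        call = "none"
    return CrossPCFResult(sender=sender_name, receiver=receiver_name,
                          r_left_edges=edges[:-1], g=g, ci_low=ci_low,
                          ci_high=ci_high, gr20=float(g[call_bin]), call=call,
                          n_boot=n_boot)


# ---------------------------------------------------------------------------
# Topographical correlation map
# ---------------------------------------------------------------------------

def topographical_correlation_map(obs: pd.DataFrame, geometry: RoiGeometry,
                                  sender: str, receiver: str,
                                  scale_um: float = 100.0, n_perm: int = 500,
                                  seed: int = 0,
                                  label_col: str = "population_label"
                                  ) -> np.ndarray:
    """Permutation-z map of local sender–receiver co-occurrence.

    On a grid of ``scale_um``-sided tiles, the score is the observed
    sender·receiver co-count in the tile minus its mean under within-ROI
    label permutation, divided by the permutation sd (signed; 0 where the
    permutation sd is 0)."""
    labels = obs[label_col].to_numpy(dtype=object)
    nx = max(int(geometry.width_um // scale_um), 1)
    ny = max(int(geometry.height_um // scale_um), 1)
    if sender not in labels or receiver not in labels:
        logger.warning("topographical map: population absent; zero map")
        return np.zeros((ny, nx))
    ix = np.clip(np.floor(obs["x_um"].to_numpy() / scale_um).astype(int),
                 0, nx - 1)
    iy = np.clip(np.floor(obs["y_um"].to_numpy() / scale_um).astype(int),
                 0, ny - 1)
    tile = iy * nx + ix

    def co_counts(lab):
        s = np.bincount(tile[lab == sender], minlength=nx * ny)
        r = np.bincount(tile[lab == receiver], minlength=nx * ny)
        return (s * r).astype(float)

    observed = co_counts(labels)
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, nx * ny))
    for p in range(n_perm):
        perms[p] = co_counts(rng.permutation(labels))
    mean = perms.mean(axis=0)
    sd = perms.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (observed - mean) / sd, 0.0)
    return z.reshape(ny, nx)


# ---------------------------------------------------------------------------
# Adjacency cell network
# ---------------------------------------------------------------------------

def pct_connections(graphs: Sequence[SpatialGraph],
                    labels_per_graph: Sequence[np.ndarray]) -> pd.DataFrame:
    """Percentage of a sender type's retained graph contacts made with each
    receiver type, pooled over ROIs."""
    pops: list[str] = sorted({str(l) for labels in labels_per_graph
                              for l in labels})
    idx = {p: i for i, p in enumerate(pops)}
    k = len(pops)
    joint = np.zeros((k, k))      # edges joining type a to type b
    incident = np.zeros(k)        # edges incident to ≥1 cell of the type
    for graph, labels in zip(graphs, labels_per_graph):
        labels = np.asarray(labels, dtype=object)
        codes = np.array([idx[str(l)] for l in labels])
        a = codes[graph.edges[:, 0]]
        b = codes[graph.edges[:, 1]]
        np.add.at(joint, (a, b), 1.0)
        off = a != b
        np.add.at(joint, (b[off], a[off]), 1.0)
        for c in range(k):
            incident[c] += ((a == c) | (b == c)).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(incident[:, None] > 0,
                       100.0 * joint / incident[:, None], 0.0)
    return pd.DataFrame(pct, index=pops, columns=pops)


def adjacency_network(qcm_pairs: set[frozenset],
                      pcf_results: Mapping[tuple[str, str], CrossPCFResult],
                      graphs: Sequence[SpatialGraph],
                      labels_per_graph: Sequence[np.ndarray]):
    """Directed network of populations gated on joint QCM + cross-PCF
    significance.  Edge sender→receiver exists iff the unordered pair is
    QCM-significant and the PCF call is not none; edges carry g(r=20 µm)
    and % connections; nodes carry relative abundance."""
    import networkx as nx

    all_labels = np.concatenate([np.asarray(l, dtype=object)
                                 for l in labels_per_graph])
    abundance = pd.Series(all_labels).value_counts(normalize=True)
    pct = pct_connections(graphs, labels_per_graph)

    net = nx.DiGraph()
    for pop, ab in abundance.items():
        net.add_node(str(pop), abundance=float(ab))
    for pair in qcm_pairs:
        members = tuple(sorted(pair))
        ordered = ([(members[0], members[0])] if len(members) == 1 else
                   [(members[0], members[1]), (members[1], members[0])])
        for s, r in ordered:
            res = pcf_results.get((s, r))
            if res is None:
                logger.warning("adjacency_network: no PCF for QCM-significant "
                               "pair (%s, %s); skipped", s, r)
                continue
            if res.call == "none":
                continue
            net.add_edge(s, r, gr20=float(res.gr20), call=res.call,
                         pct_connections=float(pct.loc[s, r])
                         if s in pct.index and r in pct.columns else 0.0)
    return net
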