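"""Spatial graph construction, raster sampling along edges, covariate screens.

The graph is individual-based: nodes are sampled animals with projected
coordinates and a site label; edges are straight segments between pairs of
nodes within a pruning distance.  Edges sample the landscape between
observations — they are not movement paths — so every ordered pair within
range gets a directed edge and edge statistics are direction-symmetric.

Raster values along an edge are collected with a supercover traversal:
every cell whose interior the open segment crosses contributes exactly
once, so thin diagonal features are never skipped (unlike Bresenham).
Between-site covariates are summarized by the median (robust to skew);
other moments and nearest-rank quantiles are available.  Buffered sampling
collects all cells whose centers lie within a half-width of the segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .raster import RasterGrid

__all__ = [
    "SpatialGraph",
    "build_graph",
    "extract_node_values",
    "supercover_cells",
    "buffered_cells",
    "sample_edge",
    "percent_class_along_edge",
    "attach_edge_covariates",
    "correlation_screen",
    "buffer_sensitivity",
]

EDGE_STATS = ["mean", "median", "min", "max", "variance", "kurtosis", "skewness", "q75", "q90", "q95"]


@dataclass
class SpatialGraph:
    """Directed spatial graph over individuals.

    ``nodes``: DataFrame (id, x, y, site, at-site covariate columns).
    ``edges``: DataFrame (from, to, length, between-site covariate columns,
    optional flow response).  Every edge length <= prune distance; no
    self-edges.
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame
    prune_distance: float
    provenance: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def isolated_nodes(self) -> list:
        connected = set(self.edges["from"]) | set(self.edges["to"])
        return [i for i in self.nodes["id"] if i not in connected]

    def to_networkx(self):
        import networkx as nx

        gr = nx.DiGraph()
        for _, row in self.nodes.iterrows():
            gr.add_node(row["id"], **row.drop("id").to_dict())
        for _, row in self.edges.iterrows():
            gr.add_edge(row["from"], row["to"], **row.drop(["from", "to"]).to_dict())
        return gr


def build_graph(nodes: pd.DataFrame, prune_km: float) -> SpatialGraph:
    """Directed edges i->j for all ordered pairs within ``prune_km`` kilometers.

    Lengths are planar Euclidean distances in meters on the projected
    coordinates.  Nodes left without any neighbour under the prune are
    retained and reported in the provenance.
    """
    if len(nodes) < 2:
        raise ValueError("need >= 2 nodes")
    if prune_km <= 0:
        raise ValueError("prune_km must be > 0")
    xy = nodes[["x", "y"]].to_numpy(float)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    limit = prune_km * 1000.0
    ii, jj = np.where((d <= limit) & ~np.eye(len(nodes), dtype=bool))
    ids = nodes["id"].to_numpy()
    edges = pd.DataFrame({"from": ids[ii], "to": ids[jj], "length": d[ii, jj]})
    graph = SpatialGraph(nodes.reset_index(drop=True), edges, prune_distance=limit)
    iso = graph.isolated_nodes()
    graph.provenance["isolated_nodes"] = iso
    graph.provenance["prune_km"] = prune_km
    return graph


def extract_node_values(nodes: pd.DataFrame, rasters: dict[str, RasterGrid], prefix: str = "at_") -> pd.DataFrame:
    """Point value of the cell containing each node, per at-site raster.

    Nodata cells yield NaN (flagged missing); a node outside any raster's
    extent is an error.
    """
    out = nodes.copy()
    x = nodes["x"].to_numpy(float)
    y = nodes["y"].to_numpy(float)
    for code, grid in rasters.items():
        if not np.all(grid.contains(x, y)):
            raise ValueError(f"node outside extent of raster {code!r}")
        out[prefix + code] = grid.value_at(x, y)
    return out


def supercover_cells(grid: RasterGrid, x0: float, y0: float, x1: float, y1: float) -> np.ndarray:
    """(row, col) of every cell whose interior the open segment crosses.

    Computed by slicing the segment at every grid-line crossing and
    indexing each sub-segment midpoint; each touched cell appears exactly
    once.  Degenerate (zero-length) segments return the containing cell.
    """
    s = grid.cell_size
    gx0, gy0 = grid.origin
    # parametric positions of vertical / horizontal grid-line crossings
    ts = np.array([0.0, 1.0])
    for p0, p1, g0 in ((x0, x1, gx0), (y0, y1, gy0)):
        if p1 != p0:
            k0 = np.ceil(min(p0, p1) / s - g0 / s)
            k1 = np.floor(max(p0, p1) / s - g0 / s)
            lines = (np.arange(k0, k1 + 1) * s) + g0
            ts = np.concatenate([ts, (lines - p0) / (p1 - p0)])
    ts = np.unique(np.clip(ts, 0.0, 1.0))
    mid = (ts[:-1] + ts[1:]) / 2
    mid = mid[ts[1:] > ts[:-1]]
    mx = x0 + mid * (x1 - x0)
    my = y0 + mid * (y1 - y0)
    if mid.size == 0:  # degenerate point
        mx, my = np.array([x0]), np.array([y0])
    row, col = grid.rowcol(mx, my)
    nrow, ncol = grid.shape
    keep = (row >= 0) & (row < nrow) & (col >= 0) & (col < ncol)
    cells = np.unique(np.stack([row[keep], col[keep]], axis=1), axis=0)
    return cells


def buffered_cells(grid: RasterGrid, x0: float, y0: float, x1: float, y1: float, width: float) -> np.ndarray:
    """Cells whose centers lie within ``width`` meters of the segment."""
    s = grid.cell_size
    nrow, ncol = grid.shape
    xmin, xmax = min(x0, x1) - width - s, max(x0, x1) + width + s
    ymin, ymax = min(y0, y1) - width - s, max(y0, y1) + width + s
    r0 = max(0, int(np.floor((grid.origin[1] - ymax) / s)))
    r1 = min(nrow - 1, int(np.floor((grid.origin[1] - ymin) / s)))
    c0 = max(0, int(np.floor((xmin - grid.origin[0]) / s)))
    c1 = min(ncol - 1, int(np.floor((xmax - grid.origin[0]) / s)))
    if r1 < r0 or c1 < c0:
        return np.empty((0, 2), dtype=int)
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    cx, cy = grid.cell_center(rr, cc)
    # distance from cell centers to the segment
    dx, dy = x1 - x0, y1 - y0
    seg2 = dx * dx + dy * dy
    if seg2 == 0:
        dist = np.hypot(cx - x0, cy - y0)
    else:
        t = np.clip(((cx - x0) * dx + (cy - y0) * dy) / seg2, 0.0, 1.0)
        dist = np.hypot(cx - (x0 + t * dx), cy - (y0 + t * dy))
    keep = dist <= width
    return np.stack([rr[keep], cc[keep]], axis=1)


def _nearest_rank_quantile(sorted_vals: np.ndarray, p: float) -> float:
    n = len(sorted_vals)
    k = max(1, int(np.ceil(p * n)))
    return float(sorted_vals[k - 1])


def _compute_stats(vals: np.ndarray, stats_list) -> dict[str, float]:
    out = {}
    sv = np.sort(vals)
    for stat in stats_list:
        if stat == "mean":
            out[stat] = float(np.mean(vals))
        elif stat == "median":
            out[stat] = float(np.median(vals))
        elif stat == "min":
            out[stat] = float(np.min(vals))
        elif stat == "max":
            out[stat] = float(np.max(vals))
        elif stat == "variance":
            out[stat] = float(np.var(vals))
        elif stat == "kurtosis":
            out[stat] = float(sstats.kurtosis(vals))
        elif stat == "skewness":
            out[stat] = float(sstats.skew(vals))
        elif stat in ("q75", "q90", "q95"):
            out[stat] = _nearest_rank_quantile(sv, int(stat[1:]) / 100.0)
        else:
            raise ValueError(f"unknown statistic {stat!r}")
    return out


def sample_edge(
    grid: RasterGrid,
    x0: float, y0: float, x1: float, y1: float,
    stats_list=("median",),
    width: float | None = None,
) -> dict[str, float]:
    """Statistics of raster cells traversed by (or buffered around) an edge.

    Nodata cells are dropped; all traversed cells being nodata is an error.
    Quantiles use the nearest-rank (type-1) rule.
    """
    if width is None:
        cells = supercover_cells(grid, x0, y0, x1, y1)
    else:
        cells = buffered_cells(grid, x0, y0, x1, y1, width)
    if len(cells) == 0:
        raise ValueError("edge does not intersect the raster extent")
    vals = grid.values[cells[:, 0], cells[:, 1]]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("all traversed cells are nodata")
    return _compute_stats(vals, stats_list)


def percent_class_along_edge(
    grid: RasterGrid,
    x0: float, y0: float, x1: float, y1: float,
    class_id: float,
    width: float | None = None,
) -> float:
    """100 x (traversed cells equal to class_id) / (traversed valid cells)."""
    if not grid.categorical:
        raise ValueError("percent-class sampling requires a categorical raster")
    if width is None:
        cells = supercover_cells(grid, x0, y0, x1, y1)
    else:
        cells = buffered_cells(grid, x0, y0, x1, y1, width)
    vals = grid.values[cells[:, 0], cells[:, 1]] if len(cells) else np.array([])
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("zero valid traversed cells")
    return float(100.0 * np.mean(vals == class_id))


def attach_edge_covariates(
    graph: SpatialGraph,
    rasters: dict[str, RasterGrid],
    class_rasters: dict[str, tuple[RasterGrid, float]] | None = None,
    stat: str = "median",
    width: float | None = None,
    prefix: str = "btw_",
) -> SpatialGraph:
    """Attach between-site covariates to every edge.

    Continuous rasters get the ``stat`` summary (median by default) of the
    supercover traversal; ``class_rasters`` maps a code to
    ``(categorical raster, class id)`` and yields percent-of-class columns.
    """
    node_xy = graph.nodes.set_index("id")[["x", "y"]]
    p0 = node_xy.loc[graph.edges["from"]].to_numpy(float)
    p1 = node_xy.loc[graph.edges["to"]].to_numpy(float)
    edges = graph.edges.copy()
    for code, grid in rasters.items():
        col = np.empty(len(edges))
        for k in range(len(edges)):
            col[k] = sample_edge(grid, p0[k, 0], p0[k, 1], p1[k, 0], p1[k, 1], (stat,), width)[stat]
        edges[prefix + code] = col
    for code, (grid, class_id) in (class_rasters or {}).items():
        col = np.empty(len(edges))
        for k in range(len(edges)):
            col[k] = percent_class_along_edge(grid, p0[k, 0], p0[k, 1], p1[k, 0], p1[k, 1], class_id, width)
        edges[prefix + code] = col
    out = SpatialGraph(graph.nodes, edges, graph.prune_distance, dict(graph.provenance))
    out.provenance.update({"edge_stat": stat, "buffer_width": width, "rasters": sorted(rasters)})
    return out


def correlation_screen(design: pd.DataFrame, columns=None, threshold: float = 0.70, priority: dict[str, int] | None = None):
    """Pearson correlation screen over covariate columns.

    Pairs with ``|r| >= threshold`` are flagged; of a flagged pair the
    covariate with the lower priority (fewer registered hypotheses) is
    dropped.  Zero-variance columns are excluded from r and flagged.
    Returns ``(retained, dropped, corr_matrix, flagged_pairs)``.
    """
    if columns is None:
        columns = [c for c in design.columns if c not in ("from", "to", "flow")]
    if len(design) < 3:
        raise ValueError("need >= 3 edges for a correlation screen")
    sub = design[list(columns)].astype(float)
    variances = sub.var(ddof=0)
    zero_var = list(variances.index[variances == 0])
    usable = [c for c in columns if c not in zero_var]
    corr = sub[usable].corr()
    priority = priority or {}
    flagged = []
    dropped: set[str] = set()
    for i, a in enumerate(usable):
        for b in usable[i + 1:]:
            r = corr.loc[a, b]
            if abs(r) >= threshold:
                flagged.append((a, b, float(r)))
                pa, pb = priority.get(a, 0), priority.get(b, 0)
                loser = b if (pa > pb or (pa == pb and a <= b)) else a
                dropped.add(loser)
    retained = [c for c in usable if c not in dropped]
    return retained, sorted(dropped) + zero_var, corr, flagged


def buffer_sensitivity(
    graph: SpatialGraph,
    rasters: dict[str, RasterGrid],
    widths=(30.0, 90.0, 250.0, 500.0),
    stat: str = "median",
) -> pd.DataFrame:
    """Pearson r of per-edge summaries between buffer widths, per covariate.

    Zero-variance covariates are reported with NaN correlations.
    """
    node_xy = graph.nodes.set_index("id")[["x", "y"]]
    p0 = node_xy.loc[graph.edges["from"]].to_numpy(float)
    p1 = node_xy.loc[graph.edges["to"]].to_numpy(float)
    rows = []
    for code, grid in rasters.items():
        per_width = {}
        for w in widths:
            col = np.empty(len(graph.edges))
            for k in range(len(graph.edges)):
                col[k] = sample_edge(grid, p0[k, 0], p0[k, 1], p1[k, 0], p1[k, 1], (stat,), width=w)[stat]
            per_width[w] = col
        for i, wa in enumerate(widths):
            for wb in widths[i + 1:]:
                a, b = per_width[wa], per_width[wb]
                if np.std(a) == 0 or np.std(b) == 0:
                    r = np.nan
                else:
                    r = float(np.corrcoef(a, b)[0, 1])
                rows.append({"covariate": code, "width_a": wa, "width_b": wb, "r": r})
    return pd.DataFrame(rows)
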