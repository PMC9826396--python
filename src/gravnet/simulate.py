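"""Synthetic landscapes, individuals, genotypes and gravity-consistent flows.

Everything downstream of raw data is testable against known ground truth:

* **Landscape** — spatially autocorrelated surfaces built from
  Gaussian-kernel-smoothed white noise (DEM, monthly temperature,
  precipitation, percent sand) plus patch-structured urban imperviousness,
  fire history and a land-cover class grid containing a shrub class.  All
  grids share one 30 m grid spec.
* **Individuals** — site centroids laid out on a jittered lattice inside
  the grid, with individuals scattered around their centroid.
* **Genotypes** — Balding–Nichols island model: ancestral frequency
  p_l ~ U(0.05, 0.95), site frequency Beta(p(1-F)/F, (1-p)(1-F)/F) with a
  per-site divergence target F, diploid dosages Binomial(2, p_sl), and
  uniform random missingness.  The Beta parameterization makes the expected
  pairwise differentiation between two sites with targets F_a, F_b equal
  (F_a + F_b)/2, so the estimator calibration has a closed-form target.
* **Flows** — generated directly from the gravity equation on the log
  scale, with a random intercept per origin site and i.i.d. edge noise.
  The generator shares :func:`gravnet.model.log_offset_transform` with the
  fitter, so with zero noise a refit recovers the coefficients exactly.

The generator is deterministic: one seed drives independent child streams
(one per surface / stage), so regenerating with the same config is
bit-identical and adding a stage never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import terrain
from .model import log_offset_transform
from .network import SpatialGraph, build_graph, extract_node_values, percent_class_along_edge, supercover_cells
from .popgen import GenotypeMatrix
from .raster import RasterGrid

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "generate_landscape",
    "generate_individuals",
    "generate_genotypes_bn",
    "generate_true_flows",
    "simulate_dataset",
    "SimulatedDataset",
    "DEFAULT_COEFFICIENTS",
    "SHRUB_CLASS",
]

#: land-cover class codes (NLCD-flavoured)
SHRUB_CLASS = 52.0
GRASS_CLASS = 71.0
FOREST_CLASS = 42.0
DEVELOPED_CLASS = 23.0

#: fire-year value for never-burned cells
UNBURNED_SENTINEL = 0.0
FIRE_RECORD_START = 1950.0
FIRE_REFERENCE_YEAR = 2020.0

#: generating coefficients: signs follow the registered ecological predictions
DEFAULT_COEFFICIENTS: dict[str, float] = {
    "(intercept)": 0.0,
    "length": -0.5,
    "at_srr3": -0.3,
    "at_adi": 0.3,
    "at_sand": 0.3,
    "at_shrub": 0.3,
    "at_cti": 0.3,
    "at_hli": 0.3,
    "btw_shrub": 0.3,
    "btw_cti": 0.3,
    "btw_hli": 0.3,
    "btw_imperv": -0.3,
    "btw_fire": -0.3,
    "btw_srr27": -0.3,
}

REQUIRED_LANDSCAPE_CODES = ("dem", "tmean", "precip", "sand", "imperv", "fire_year", "landcover")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate the study scale: 9 sites x 15 individuals on a 30 m
    grid, thousands of biallelic SNPs with hierarchical structure, and
    gravity-generated flows with origin-site random effects.
    """

    seed: int = 0
    n_sites: int = 9
    inds_per_site: int = 15
    n_loci: int = 2000
    fst_target: float | list[float] = 0.2
    grid_shape: tuple[int, int] = (100, 100)
    cell_size: float = 30.0
    true_coefficients: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    noise_sd: float = 0.1
    site_sd: float = 0.1          # sd of the origin-site random intercept
    missing_rate: float = 0.05
    scatter_sd: float = 120.0     # meters around the site centroid
    urban_fraction: float = 0.15  # target fraction of cells with imperviousness > 50%
    smooth_sigma: float = 5.0     # Gaussian kernel length, cells
    relief: float = 300.0         # DEM amplitude, meters
    latitude_deg: float = 34.0
    prune_km: float = 10.0

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        f = np.atleast_1d(np.asarray(self.fst_target, dtype=float))
        if not ((f > 0) & (f < 1)).all():
            raise ValueError("fst_target must be in (0, 1)")
        if len(f) not in (1, self.n_sites):
            raise ValueError("fst_target must be scalar or one per site")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_sd < 0 or self.site_sd < 0:
            raise ValueError("noise sds must be >= 0")
        if min(self.grid_shape) < 1:
            raise ValueError("grid_shape must be positive")

    @property
    def site_fst(self) -> np.ndarray:
        f = np.atleast_1d(np.asarray(self.fst_target, dtype=float))
        return np.full(self.n_sites, f[0]) if len(f) == 1 else f

    @property
    def site_names(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_sites)]

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,)))


@dataclass
class TruthRecord:
    """Ground truth retained for recovery tests."""

    ancestral_freqs: np.ndarray | None = None
    site_freqs: np.ndarray | None = None           # n_sites x n_loci
    true_coefficients: dict[str, float] = field(default_factory=dict)
    true_flows: np.ndarray | None = None
    site_effects: dict[str, float] = field(default_factory=dict)   # u_i per origin site
    edge_noise: np.ndarray | None = None
    urban_fraction_realized: float | None = None


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Standardized Gaussian-smoothed white noise (mean 0, sd 1)."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


def _patches(rng: np.random.Generator, shape, target_fraction: float, radius_range=(3, 9)):
    """Disk patches until ``target_fraction`` of cells are covered; returns mask."""
    nrow, ncol = shape
    mask = np.zeros(shape, dtype=bool)
    target = target_fraction * nrow * ncol
    guard = 0
    rr, cc = np.mgrid[0:nrow, 0:ncol]
    while mask.sum() < target and guard < 10_000:
        r0 = rng.integers(0, nrow)
        c0 = rng.integers(0, ncol)
        rad = rng.integers(*radius_range)
        mask |= (rr - r0) ** 2 + (cc - c0) ** 2 <= rad ** 2
        guard += 1
    return mask


def generate_landscape(config: SimulationConfig, return_info: bool = False):
    """All raw landscape grids on one shared 30 m grid spec.

    Returns a mapping with codes ``dem, tmean (12-band), precip, sand,
    imperv, fire_year, landcover``.  With ``return_info=True`` also returns
    the generator's own patch-placement bookkeeping (realized urban
    fraction).
    """
    nrow, ncol = config.grid_shape
    origin = (0.0, nrow * config.cell_size)

    def mk(values, categorical=False):
        return RasterGrid(values, config.cell_size, origin, crs_tag="synthetic-utm", categorical=categorical)

    dem = 500.0 + config.relief * _smooth_field(config.rng(1), (nrow, ncol), config.smooth_sigma)

    month = np.arange(12)
    seasonal = 17.0 - 5.0 * np.cos(2 * np.pi * month / 12.0)
    tfield = _smooth_field(config.rng(2), (nrow, ncol), config.smooth_sigma)
    tmean = seasonal[:, None, None] + 1.5 * tfield[None, :, :]

    precip = np.clip(400.0 + 150.0 * _smooth_field(config.rng(3), (nrow, ncol), config.smooth_sigma), 50.0, None)
    sand = np.clip(50.0 + 25.0 * _smooth_field(config.rng(4), (nrow, ncol), config.smooth_sigma), 0.0, 100.0)

    rng_urban = config.rng(5)
    urban_mask = _patches(rng_urban, (nrow, ncol), config.urban_fraction)
    imperv = np.clip(2.0 + 1.5 * config.rng(6).standard_normal((nrow, ncol)), 0.0, 5.0)
    imperv[urban_mask] = rng_urban.uniform(60.0, 95.0, size=int(urban_mask.sum()))
    realized_urban = float((imperv > 50.0).mean())

    rng_fire = config.rng(7)
    fire_year = np.full((nrow, ncol), UNBURNED_SENTINEL)
    burn_mask = _patches(rng_fire, (nrow, ncol), 0.35)
    # burn patches get a shared recent year per connected blob
    labels, nlab = ndimage.label(burn_mask)
    years = rng_fire.integers(1970, 2020, size=nlab + 1).astype(float)
    fire_year[burn_mask] = years[labels[burn_mask]]

    veg = _smooth_field(config.rng(8), (nrow, ncol), config.smooth_sigma)
    landcover = np.full((nrow, ncol), SHRUB_CLASS)
    landcover[veg < -0.8] = GRASS_CLASS
    landcover[veg > 1.2] = FOREST_CLASS
    landcover[imperv > 50.0] = DEVELOPED_CLASS

    rasters = {
        "dem": mk(dem),
        "tmean": mk(tmean),
        "precip": mk(precip),
        "sand": mk(sand),
        "imperv": mk(imperv),
        "fire_year": mk(fire_year, categorical=True),
        "landcover": mk(landcover, categorical=True),
    }
    for code in REQUIRED_LANDSCAPE_CODES:
        if code not in rasters:
            raise RuntimeError(f"required landscape code missing: {code}")
    if return_info:
        return rasters, {"urban_fraction_realized": realized_urban}
    return rasters


def generate_individuals(config: SimulationConfig, max_retries: int = 100) -> pd.DataFrame:
    """Individuals clustered around site centroids inside the grid.

    Centroids sit on a jittered lattice with a 15% margin; individuals are
    Gaussian-scattered (``scatter_sd`` meters) with bounded redraws for
    points that would fall outside the grid.
    """
    nrow, ncol = config.grid_shape
    width = ncol * config.cell_size
    height = nrow * config.cell_size
    margin = 0.15
    rng = config.rng(10)
    k = int(np.ceil(np.sqrt(config.n_sites)))
    xs = np.linspace(margin * width, (1 - margin) * width, k)
    ys = np.linspace(margin * height, (1 - margin) * height, k)
    lattice = [(x, y) for y in ys for x in xs]
    order = rng.permutation(len(lattice))[: config.n_sites]
    jitter = min(width, height) * 0.03
    centroids = [(lattice[i][0] + rng.uniform(-jitter, jitter),
                  lattice[i][1] + rng.uniform(-jitter, jitter)) for i in order]

    rows = []
    for s, (cx, cy) in enumerate(centroids):
        site = config.site_names[s]
        for i in range(config.inds_per_site):
            for attempt in range(max_retries + 1):
                x = cx + config.scatter_sd * rng.standard_normal()
                y = cy + config.scatter_sd * rng.standard_normal()
                if 0 <= x < width and 0 <= y < height:
                    break
            else:
                raise RuntimeError("could not place individual inside grid")
            rows.append({"id": f"{site}_{i + 1:02d}", "site": site, "x": x, "y": y,
                         "site_x": cx, "site_y": cy})
    return pd.DataFrame(rows)


def generate_genotypes_bn(config: SimulationConfig, nodes: pd.DataFrame | None = None):
    """Balding–Nichols genotypes for all individuals.

    Returns ``(GenotypeMatrix, TruthRecord)`` with ancestral and per-site
    allele frequencies recorded.
    """
    if nodes is None:
        nodes = generate_individuals(config)
    rng = config.rng(20)
    L = config.n_loci
    p_anc = rng.uniform(0.05, 0.95, size=L)
    F = config.site_fst
    site_freqs = np.empty((config.n_sites, L))
    for s in range(config.n_sites):
        a = p_anc * (1 - F[s]) / F[s]
        b = (1 - p_anc) * (1 - F[s]) / F[s]
        site_freqs[s] = rng.beta(a, b)
    site_index = {name: i for i, name in enumerate(config.site_names)}
    dosages = np.empty((len(nodes), L), dtype=np.int64)
    for row_i, site in enumerate(nodes["site"]):
        dosages[row_i] = rng.binomial(2, site_freqs[site_index[site]])
    if config.missing_rate > 0:
        miss = config.rng(21).random(dosages.shape) < config.missing_rate
        # keep the no-locus-entirely-missing invariant
        dead = miss.all(axis=0)
        if dead.any():
            miss[0, dead] = False
        dosages = np.where(miss, -1, dosages)
    g = GenotypeMatrix(dosages, nodes["id"].tolist(), nodes["site"].tolist())
    truth = TruthRecord(ancestral_freqs=p_anc, site_freqs=site_freqs,
                        true_coefficients=dict(config.true_coefficients))
    return g, truth


def generate_true_flows(graph: SpatialGraph, truth: TruthRecord, config: SimulationConfig) -> np.ndarray:
    """Per-edge gene-flow response from the gravity equation.

    ln(flow) = b0 + b_w ln(d) + sum b_k ln(v) + sum b_l ln(c) + u_origin + e,
    using the same log-offset transform the fitter applies, so a zero-noise
    refit inverts the generator exactly.  The generating u and e are stored
    on ``truth`` for recovery tests.
    """
    edges = graph.edges
    beta = dict(config.true_coefficients)
    b0 = beta.pop("(intercept)", 0.0)
    lnflow = np.full(len(edges), b0, dtype=float)
    for code, b in beta.items():
        if b == 0.0:
            continue
        if code not in edges.columns:
            raise ValueError(f"coefficient {code!r} has no matching edge covariate")
        t, _, _ = log_offset_transform(edges[code].to_numpy())
        lnflow += b * t
    rng = config.rng(30)
    sites = sorted(set(graph.nodes["site"]))
    u = {s: config.site_sd * rng.standard_normal() for s in sites}
    eps = config.noise_sd * rng.standard_normal(len(edges))
    lnflow += np.array([u[s] for s in edges["from_site"]]) + eps
    flows = np.exp(lnflow)
    truth.true_flows = flows
    truth.site_effects = u
    truth.edge_noise = eps
    truth.true_coefficients = dict(config.true_coefficients)
    return flows


@dataclass
class SimulatedDataset:
    """One full synthetic study: rasters, derived surfaces, graph, genotypes, truth."""

    config: SimulationConfig
    rasters: dict[str, RasterGrid]
    derived: dict[str, RasterGrid]
    nodes: pd.DataFrame
    graph: SpatialGraph
    edge_table: pd.DataFrame
    genotypes: GenotypeMatrix | None
    truth: TruthRecord


def _derive_surfaces(config: SimulationConfig, rasters: dict[str, RasterGrid]) -> dict[str, RasterGrid]:
    dem = rasters["dem"]
    derived = {
        "srr3": terrain.surface_relief_ratio(dem, 3),
        "srr27": terrain.surface_relief_ratio(dem, 27),
        "cti": terrain.compound_topographic_index(dem),
        "hli": terrain.heat_load_index(dem, config.latitude_deg),
        "adi": terrain.annual_dryness_index(rasters["tmean"], rasters["precip"]),
        "sand": rasters["sand"],
        "imperv": rasters["imperv"],
    }
    # time since last fire (years); never-burned cells get time since record start
    fy = rasters["fire_year"].values
    tsf = np.where(fy == UNBURNED_SENTINEL, FIRE_REFERENCE_YEAR - FIRE_RECORD_START, FIRE_REFERENCE_YEAR - fy)
    derived["fire"] = rasters["fire_year"].like(tsf, categorical=False)
    # continuous percent-shrub surface for at-site point sampling (5x5 window);
    # clip: uniform_filter on a binary field leaks tiny negative round-off
    shrub_frac = np.clip(
        ndimage.uniform_filter((rasters["landcover"].values == SHRUB_CLASS).astype(float), size=5),
        0.0, 1.0)
    derived["shrub"] = rasters["landcover"].like(100.0 * shrub_frac, categorical=False)
    return derived


AT_CODES = ("srr3", "adi", "sand", "shrub", "cti", "hli")
BTW_CODES = ("srr27", "imperv", "fire", "hli", "cti")  # shrub handled as percent-of-class


def build_edge_table(config: SimulationConfig, rasters, derived, nodes) -> tuple[SpatialGraph, pd.DataFrame]:
    """Graph + design table: at-site values at the destination node, medians along edges.

    All derived grids share one spec, so each edge's supercover traversal is
    computed once and reused across rasters.
    """
    nodes_at = extract_node_values(nodes, {c: derived[c] for c in AT_CODES}, prefix="at_")
    graph = build_graph(nodes_at, config.prune_km)
    edges = graph.edges.copy()
    node_ix = nodes_at.set_index("id")
    edges["from_site"] = node_ix.loc[edges["from"], "site"].to_numpy()
    for c in AT_CODES:
        edges[f"at_{c}"] = node_ix.loc[edges["to"], f"at_{c}"].to_numpy()

    p0 = node_ix.loc[edges["from"], ["x", "y"]].to_numpy(float)
    p1 = node_ix.loc[edges["to"], ["x", "y"]].to_numpy(float)
    grid0 = derived["srr27"]
    # i->j and j->i share one traversal: compute per unordered pair
    key = pd.DataFrame(np.sort(edges[["from", "to"]].to_numpy(), axis=1), columns=["a", "b"])
    pair_id, pair_index = pd.factorize(key["a"] + "|" + key["b"])
    first = np.full(len(pair_index), -1, dtype=int)
    for k, pid in enumerate(pair_id):
        if first[pid] < 0:
            first[pid] = k
    stack = np.stack([derived[c].values for c in BTW_CODES] + [rasters["landcover"].values])
    pair_vals = np.empty((len(pair_index), len(BTW_CODES) + 1))
    for pid, k in enumerate(first):
        cells = supercover_cells(grid0, p0[k, 0], p0[k, 1], p1[k, 0], p1[k, 1])
        vals = stack[:, cells[:, 0], cells[:, 1]]
        pair_vals[pid, :-1] = np.median(vals[:-1], axis=1)
        pair_vals[pid, -1] = 100.0 * np.mean(vals[-1] == SHRUB_CLASS)
    for j, c in enumerate(BTW_CODES):
        edges[f"btw_{c}"] = pair_vals[pair_id, j]
    edges["btw_shrub"] = pair_vals[pair_id, -1]
    graph = SpatialGraph(nodes_at, edges, graph.prune_distance, dict(graph.provenance))
    graph.provenance.update({"edge_stat": "median", "buffer_width": None})
    return graph, edges


def simulate_dataset(config: SimulationConfig, with_genotypes: bool = True) -> SimulatedDataset:
    """Run the full generator: landscape -> surfaces -> graph -> flows (-> genotypes)."""
    rasters, info = generate_landscape(config, return_info=True)
    derived = _derive_surfaces(config, rasters)
    nodes = generate_individuals(config)
    graph, edges = build_edge_table(config, rasters, derived, nodes)
    if with_genotypes:
        genotypes, truth = generate_genotypes_bn(config, nodes)
    else:
        genotypes, truth = None, TruthRecord(true_coefficients=dict(config.true_coefficients))
    truth.urban_fraction_realized = info["urban_fraction_realized"]
    flows = generate_true_flows(graph, truth, config)
    edges = edges.copy()
    edges["flow"] = flows
    graph.edges = edges
    return SimulatedDataset(config, rasters, derived, nodes, graph, edges, genotypes, truth)
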