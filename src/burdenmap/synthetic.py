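"""Synthetic prevalence studies with known ground truth.

Emulates the statistical structure of a national cluster household survey of
a rare condition laid over gridded covariates: smooth covariate surfaces on
a lon/lat grid, a log-normal population-density surface with a few
high-density urban cores, a Voronoi partition into administrative regions
with i.i.d. Gaussian region effects, population-weighted cluster placement,
and binomial outcome counts observed through an imperfect questionnaire
(sensitivity/specificity fold).  Defaults put the crude prevalence at a few
per 1000 women — the low-count regime the estimation pipeline must survive.

All randomness flows from one integer seed through named substreams (fields,
regions, clusters, outcomes), so regenerating one artifact never perturbs
the others.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import expit
from shapely.geometry import MultiPoint, Point, box
from shapely.ops import voronoi_diagram

from .misclassification import TestAccuracy, fold
from .raster import (
    CovariateStack,
    Grid,
    GridTransform,
    classify_urbanicity,
    write_ascii_grid,
    write_zones,
)
from .survey_io import ClusterRecord, write_clusters


@dataclass(frozen=True)
class Scenario:
    """Ground-truth description of a synthetic survey."""

    seed: int = 0
    n_regions: int = 11
    n_clusters: int = 600
    mean_cluster_size: int = 25
    min_cluster_size: int = 5
    beta0: float = -5.2
    betas: tuple[float, ...] = (0.6, -0.4, 0.3, 0.0)
    sigma: float = 0.3
    sensitivity: float = 0.97
    specificity: float = 0.99
    untreated_given_lifetime: float = 0.5
    extent: tuple[float, float, float, float] = (36.0, 6.0, 40.0, 10.0)  # W,S,E,N
    cell_size: float = 0.05
    covariate_names: tuple[str, ...] = (
        "literacy",
        "facility_delivery",
        "accessibility",
        "night_lights",
    )
    year: int = 2016
    n_bumps: int = 5
    field_amplitude: float = 1.0
    n_urban_cores: int = 3

    def __post_init__(self) -> None:
        w, s, e, n = self.extent
        if not (e > w and n > s):
            raise ValueError("degenerate extent")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.sensitivity + self.specificity <= 1:
            raise ValueError("need sensitivity + specificity > 1")
        if self.n_clusters < self.n_regions:
            raise ValueError("need n_clusters >= n_regions")
        if len(self.betas) != len(self.covariate_names):
            raise ValueError("betas and covariate_names must have equal length")

    @property
    def accuracy(self) -> TestAccuracy:
        return TestAccuracy(self.sensitivity, self.specificity)

    def rng(self, stream: str) -> np.random.Generator:
        key = zlib.crc32(stream.encode())
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))

    def grid_transform(self) -> GridTransform:
        w, s, e, n = self.extent
        return GridTransform(west=w, north=n, dx=self.cell_size, dy=self.cell_size)

    def grid_shape(self) -> tuple[int, int]:
        w, s, e, n = self.extent
        return (
            int(round((n - s) / self.cell_size)),
            int(round((e - w) / self.cell_size)),
        )


@dataclass
class TruthBundle:
    """Everything the generator knows that an analyst would not."""

    region_ids: list[str]
    region_effects: np.ndarray            # Z_k ~ N(0, sigma^2)
    true_prevalence_grid: Grid            # expit(beta0 + beta.d + Z_region) per cell
    region_id_grid: np.ndarray            # object array of region ids per cell
    cluster_true_p: np.ndarray
    cluster_observed_p: np.ndarray        # fold(cluster_true_p)
    cluster_region_index: np.ndarray


def _smooth_field(rng: np.random.Generator, X: np.ndarray, Y: np.ndarray,
                  extent, n_bumps: int, amplitude: float) -> np.ndarray:
    """Linear trend plus Gaussian bumps; deterministic given the generator state."""
    w, s, e, n = extent
    span = max(e - w, n - s)
    theta = rng.uniform(0, 2 * np.pi)
    # trend de-weighted: linear trends span only a 2-D family, so
    # trend-dominated fields would make distinct covariates near-duplicates
    f = 0.5 * amplitude * (np.cos(theta) * (X - w) + np.sin(theta) * (Y - s)) / span
    for _ in range(int(n_bumps)):
        cx = rng.uniform(w, e)
        cy = rng.uniform(s, n)
        width = rng.uniform(0.1, 0.35) * span
        amp = amplitude * rng.uniform(-1.5, 1.5)
        f += amp * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * width**2))
    return f


def _rescale01(f: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(f)), float(np.max(f))
    if hi - lo < 1e-12:
        return np.full_like(f, 0.5)
    return (f - lo) / (hi - lo)


def generate_covariates(scenario: Scenario) -> CovariateStack:
    """Aligned covariate grids in [0, 1] plus a ``population`` density grid.

    Covariate surfaces are smooth (trend + bumps) and rescaled to [0, 1];
    population density (women 15-49 per km²) is log-normal in space with
    ``n_urban_cores`` high-density cores exceeding the urban threshold.
    Deterministic given the scenario seed.
    """
    transform = scenario.grid_transform()
    nrow, ncol = scenario.grid_shape()
    cols = np.arange(ncol)
    rows = np.arange(nrow)
    x, _ = transform.xy(cols, 0)
    _, y = transform.xy(0, rows)
    X, Y = np.meshgrid(x, y)

    rng = scenario.rng("fields")
    grids: dict[str, Grid] = {}
    for name in scenario.covariate_names:
        f = _smooth_field(rng, X, Y, scenario.extent, scenario.n_bumps,
                          scenario.field_amplitude)
        grids[name] = Grid(_rescale01(f), transform)

    # population: smooth log-density around ~50 women/km^2 with urban cores
    logpop = np.log(50.0) + _smooth_field(rng, X, Y, scenario.extent,
                                          scenario.n_bumps,
                                          scenario.field_amplitude)
    w, s, e, n = scenario.extent
    for _ in range(scenario.n_urban_cores):
        cx = rng.uniform(w + 0.1 * (e - w), e - 0.1 * (e - w))
        cy = rng.uniform(s + 0.1 * (n - s), n - 0.1 * (n - s))
        # narrow, high cores: peak density clears the urban threshold while
        # the urban population share stays realistic (~a fifth, not a half)
        width = rng.uniform(0.02, 0.06) * max(e - w, n - s)
        logpop += rng.uniform(3.2, 4.0) * np.exp(
            -((X - cx) ** 2 + (Y - cy) ** 2) / (2 * width**2)
        )
    grids["population"] = Grid(np.exp(logpop), transform)
    return CovariateStack(grids)


def region_partition(scenario: Scenario) -> tuple[list[str], np.ndarray, list]:
    """Voronoi partition of seeded centroids: ids, per-cell id array, polygons."""
    rng = scenario.rng("regions")
    w, s, e, n = scenario.extent
    cx = rng.uniform(w, e, size=scenario.n_regions)
    cy = rng.uniform(s, n, size=scenario.n_regions)
    ids = [f"R{k + 1:02d}" for k in range(scenario.n_regions)]

    transform = scenario.grid_transform()
    nrow, ncol = scenario.grid_shape()
    gx, _ = transform.xy(np.arange(ncol), 0)
    _, gy = transform.xy(0, np.arange(nrow))
    X, Y = np.meshgrid(gx, gy)
    d2 = (X[..., None] - cx) ** 2 + (Y[..., None] - cy) ** 2
    nearest = np.argmin(d2, axis=-1)
    id_grid = np.asarray(ids, dtype=object)[nearest]

    hull = box(w, s, e, n)
    cells = voronoi_diagram(MultiPoint(list(zip(cx, cy))), envelope=hull)
    polys: list = [None] * scenario.n_regions
    for poly in cells.geoms:
        clipped = poly.intersection(hull)
        for k in range(scenario.n_regions):
            if polys[k] is None and clipped.contains(Point(cx[k], cy[k])):
                polys[k] = clipped
                break
    return ids, id_grid, polys


def simulate_survey(
    scenario: Scenario, covs: CovariateStack
) -> tuple[list[ClusterRecord], TruthBundle]:
    """Draw one synthetic cluster survey with full ground-truth bookkeeping.

    Clusters are placed by population-weighted cell sampling with uniform
    within-cell jitter; cluster sizes are Poisson(mean_cluster_size)
    truncated at ``min_cluster_size``; lifetime counts are binomial at the
    folded (observed-scale) prevalence and untreated counts an independent
    binomial thinning of lifetime counts.
    """
    names = list(scenario.covariate_names)
    pop = covs["population"]
    transform = pop.transform
    nrow, ncol = pop.values.shape

    region_ids, id_grid, _ = region_partition(scenario)
    rng_reg = scenario.rng("region_effects")
    Z = rng_reg.normal(0.0, scenario.sigma, size=scenario.n_regions)
    z_by_id = dict(zip(region_ids, Z))

    # truth surface: linear predictor + realized region effect, true scale
    eta = np.full((nrow, ncol), scenario.beta0)
    for name, b in zip(names, scenario.betas):
        eta += b * covs[name].values
    eta += np.vectorize(z_by_id.__getitem__)(id_grid).astype(float)
    truth_grid = Grid(expit(eta), transform)

    rng_cl = scenario.rng("clusters")
    weights = np.clip(pop.values.ravel(), 0, None)
    weights = weights / weights.sum()
    cell_idx = rng_cl.choice(weights.size, size=scenario.n_clusters, p=weights)
    rr, cc = np.unravel_index(cell_idx, (nrow, ncol))
    cx, cy = transform.xy(cc, rr)
    lon = cx + rng_cl.uniform(-0.5, 0.5, scenario.n_clusters) * transform.dx
    lat = cy + rng_cl.uniform(-0.5, 0.5, scenario.n_clusters) * transform.dy

    urb = classify_urbanicity(pop)
    strata = np.where(urb.values[rr, cc] == 2.0, "urban", "rural")
    cluster_regions = id_grid[rr, cc]
    region_index = np.array([region_ids.index(r) for r in cluster_regions])

    p_true = truth_grid.values[rr, cc]
    p_obs = np.asarray(fold(p_true, scenario.accuracy))

    rng_out = scenario.rng("outcomes")
    n_exam = rng_out.poisson(scenario.mean_cluster_size, scenario.n_clusters)
    while np.any(n_exam < scenario.min_cluster_size):
        redo = n_exam < scenario.min_cluster_size
        n_exam[redo] = rng_out.poisson(scenario.mean_cluster_size, int(redo.sum()))
    y_life = rng_out.binomial(n_exam, p_obs)
    y_untr = rng_out.binomial(y_life, scenario.untreated_given_lifetime)

    records = [
        ClusterRecord(
            cluster_id=f"c{i + 1:04d}",
            region_id=str(cluster_regions[i]),
            stratum=str(strata[i]),
            lon=float(lon[i]),
            lat=float(lat[i]),
            year=scenario.year,
            n_examined=int(n_exam[i]),
            n_lifetime=int(y_life[i]),
            n_untreated=int(y_untr[i]),
        )
        for i in range(scenario.n_clusters)
    ]
    truth = TruthBundle(
        region_ids=region_ids,
        region_effects=Z,
        true_prevalence_grid=truth_grid,
        region_id_grid=id_grid,
        cluster_true_p=p_true,
        cluster_observed_p=p_obs,
        cluster_region_index=region_index,
    )
    return records, truth


def write_study(scenario: Scenario, outdir: str | Path) -> dict[str, Path]:
    """Generate and write a complete study to disk; returns artifact paths.

    Artifacts: cluster CSV, one ASCII grid per covariate plus population and
    the true prevalence surface, region polygons as GeoJSON, and a JSON truth
    file echoing the scenario and the realized region effects.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    covs = generate_covariates(scenario)
    records, truth = simulate_survey(scenario, covs)
    _, _, polys = region_partition(scenario)

    paths: dict[str, Path] = {}
    paths["clusters"] = outdir / "clusters.csv"
    write_clusters(records, paths["clusters"])
    for name, grid in covs.grids.items():
        paths[name] = outdir / f"{name}.asc"
        write_ascii_grid(grid, paths[name])
    paths["true_prevalence"] = outdir / "true_prevalence.asc"
    write_ascii_grid(truth.true_prevalence_grid, paths["true_prevalence"])
    paths["regions"] = outdir / "regions.geojson"
    write_zones(zip(truth.region_ids, polys), paths["regions"])
    paths["truth"] = outdir / "truth.json"
    payload = {
        "scenario": asdict(scenario),
        "region_ids": truth.region_ids,
        "region_effects": truth.region_effects.tolist(),
        "total_examined": int(sum(r.n_examined for r in records)),
        "total_lifetime": int(sum(r.n_lifetime for r in records)),
        "total_untreated": int(sum(r.n_untreated for r in records)),
    }
    paths["truth"].write_text(json.dumps(payload, indent=1))
    return paths
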