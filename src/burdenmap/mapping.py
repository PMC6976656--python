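"""Prediction surfaces, burden surfaces, and zonal aggregation.

A converged mixed-model fit is pushed through the covariate stack to give
pixel-level prevalence with 95% uncertainty bands: each Monte-Carlo draw
samples the fixed effects from their asymptotic normal N(beta_hat, vcov) and
each region's random intercept from its conditional (empirical-Bayes) normal
— cells outside every surveyed region draw Z ~ N(0, sigma_hat^2) — then maps
cells through the inverse logit.  The interval is the 2.5-97.5 percentile
band of the draws.  Prevalence is always on the true (unfolded) scale: maps
describe disease, not questionnaire positives.

Burden multiplies prevalence by the female-population surface; zonal
aggregation assigns each cell to the polygon containing its center and sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .glmm import FitResult
from .raster import CovariateStack, Grid, zone_id_grid


@dataclass
class PredictionSurfaces:
    """Mean/lower/upper prevalence grids plus the burden grid."""

    mean: Grid
    lower: Grid
    upper: Grid
    burden: Grid | None
    n_draws: int
    seed: int


@dataclass
class ZoneSummary:
    """Population-weighted prevalence and case burden of one zone."""

    zone_id: str
    population: float
    prevalence_per_1000: float | None
    prevalence_lower: float | None
    prevalence_upper: float | None
    cases: float
    cases_lower: float
    cases_upper: float


def predict_surface(
    fit: FitResult,
    covs: CovariateStack,
    zones: Sequence[tuple[str, object]] | None = None,
    n_draws: int = 1000,
    seed: int = 0,
    force: bool = False,
) -> PredictionSurfaces:
    """Monte-Carlo prevalence surfaces with percentile intervals.

    ``zones`` supplies the surveyed-region polygons keyed by the region ids
    seen at fit time; cells falling in a surveyed region use that region's
    conditional Z distribution, all other cells the marginal N(0, sigma^2).
    Deterministic given ``seed``.
    """
    if not fit.converged and not force:
        raise RuntimeError("refusing to predict from an unconverged fit (use force)")
    template = covs.template
    names = list(fit.spec.covariates)
    D = np.stack([covs[n].values for n in names]) if names else None
    valid = template.mask.copy()
    for n in names:
        valid &= covs[n].mask

    region_idx = np.full(template.values.shape, -1, dtype=int)
    if zones is not None and fit.sigma > 0:
        zid = zone_id_grid(template, list(zones))
        lookup = {rid: i for i, rid in enumerate(fit.region_ids)}
        for rid, i in lookup.items():
            region_idx[zid == rid] = i

    rng = np.random.default_rng(seed)
    p = len(fit.beta)
    # PSD square root; an exactly-zero vcov must give exactly-equal draws
    evals, evecs = np.linalg.eigh((fit.vcov_beta + fit.vcov_beta.T) / 2)
    L = evecs * np.sqrt(np.clip(evals, 0.0, None))
    cond_sd = np.where(
        np.isinf(fit.region_curvatures), 0.0, 1.0 / np.sqrt(fit.region_curvatures)
    )

    nrow, ncol = template.values.shape
    draws = np.empty((n_draws, nrow, ncol), dtype=np.float32)
    for s in range(n_draws):
        beta_s = fit.beta + L @ rng.standard_normal(p)
        eta = np.full((nrow, ncol), beta_s[0])
        if D is not None:
            eta += np.tensordot(beta_s[1:], D, axes=1)
        if fit.sigma > 0:
            z_regions = fit.region_modes + cond_sd * rng.standard_normal(len(fit.region_ids))
            z_out = rng.normal(0.0, fit.sigma)
            zmap = np.where(region_idx >= 0,
                            z_regions[np.clip(region_idx, 0, None)], z_out)
            eta = eta + zmap
        draws[s] = expit(eta)

    mean = draws.mean(axis=0, dtype=np.float64)
    lower, upper = np.percentile(draws, [2.5, 97.5], axis=0)
    for arr in (mean, lower, upper):
        arr[~valid] = np.nan
    return PredictionSurfaces(
        mean=template.copy_with(mean),
        lower=template.copy_with(lower.astype(float)),
        upper=template.copy_with(upper.astype(float)),
        burden=None,
        n_draws=n_draws,
        seed=seed,
    )


def burden_surface(prev: Grid, pop: Grid) -> Grid:
    """Cellwise expected cases: prevalence times female population; nodata propagates."""
    if prev.values.shape != pop.values.shape or prev.transform != pop.transform:
        raise ValueError("prevalence and population grids are not aligned")
    if np.nanmin(pop.values) < 0:
        raise ValueError("population must be non-negative")
    return prev.copy_with(prev.values * pop.values)


def with_burden(surfaces: PredictionSurfaces, pop: Grid) -> PredictionSurfaces:
    surfaces.burden = burden_surface(surfaces.mean, pop)
    return surfaces


def zonal_aggregate(
    surfaces: PredictionSurfaces,
    pop: Grid,
    zones: Sequence[tuple[str, object]],
    population_weighted: bool = True,
) -> list[ZoneSummary]:
    """Aggregate surfaces to zones by cell-center containment.

    Zone cases are the sum of cell burden (prevalence x population) over the
    zone's cells, for the mean, lower and upper surfaces alike; zone
    prevalence per 1000 is 1000 * cases / population (the population-weighted
    pixel mean).  With ``population_weighted=False`` the prevalence is the
    unweighted pixel mean instead, cases unchanged.  Cells whose center lies
    in no zone are dropped; a zero-population zone reports missing prevalence
    and zero cases.
    """
    template = surfaces.mean
    zid = zone_id_grid(template, list(zones))
    out = []
    for zone_id, _ in zones:
        sel = (zid == zone_id) & template.mask & pop.mask
        zpop = float(np.sum(pop.values[sel])) if sel.any() else 0.0
        sums = {}
        means = {}
        for key, grid in (("mean", surfaces.mean), ("lower", surfaces.lower),
                          ("upper", surfaces.upper)):
            prev_vals = grid.values[sel]
            sums[key] = float(np.sum(prev_vals * pop.values[sel]))
            means[key] = float(np.mean(prev_vals)) if prev_vals.size else None
        if zpop > 0:
            if population_weighted:
                prevs = {k: 1000.0 * sums[k] / zpop for k in sums}
            else:
                prevs = {k: (1000.0 * means[k] if means[k] is not None else None)
                         for k in means}
        else:
            prevs = {"mean": None, "lower": None, "upper": None}
            sums = {k: 0.0 for k in sums}
        out.append(
            ZoneSummary(
                zone_id=zone_id,
                population=zpop,
                prevalence_per_1000=prevs["mean"],
                prevalence_lower=prevs["lower"],
                prevalence_upper=prevs["upper"],
                cases=sums["mean"],
                cases_lower=sums["lower"],
                cases_upper=sums["upper"],
            )
        )
    return out


def threshold_count(summaries: Sequence[ZoneSummary], threshold: float) -> int:
    """Number of zones whose mean case burden strictly exceeds ``threshold``."""
    return sum(1 for s in summaries if s.cases > threshold)


def summaries_to_csv(summaries: Sequence[ZoneSummary], path: str | Path) -> None:
    rows = [s.__dict__ for s in summaries]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
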