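"""Model checks: residual variograms and simulation-based goodness of fit.

Two diagnostics justify and validate the non-spatial mixed model:

* an empirical variogram of standardized cluster residuals with a
  permutation envelope — a flat variogram inside the envelope indicates no
  residual spatial structure, supporting i.i.d. region effects over a
  spatially correlated process;
* a parametric-bootstrap check that simulates many datasets from the fitted
  model and compares the observed mean and SD of cluster-level empirical
  prevalence with their simulated distributions (two-sided Monte-Carlo
  p-values).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .glmm import FitResult, GroupedData, _observed_prob, simulate_from_fit
from .raster import point_distance_km
from .survey_io import ClusterRecord


@dataclass
class VariogramResult:
    bin_centers: np.ndarray          # km
    semivariance: np.ndarray         # NaN for empty bins
    pair_counts: np.ndarray
    envelope_lower: np.ndarray
    envelope_upper: np.ndarray
    n_permutations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center_km": self.bin_centers,
                "semivariance": self.semivariance,
                "pair_count": self.pair_counts,
                "envelope_lower": self.envelope_lower,
                "envelope_upper": self.envelope_upper,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)


@dataclass
class PpcResult:
    observed_mean: float
    observed_sd: float
    simulated_means: np.ndarray
    simulated_sds: np.ndarray
    p_mean: float
    p_sd: float

    @property
    def n_sims(self) -> int:
        return len(self.simulated_means)

    def to_csv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"simulated_mean": self.simulated_means, "simulated_sd": self.simulated_sds}
        ).to_csv(path, index=False)


def _pairwise_semivariance(values: np.ndarray, iu, ju, dist, edges):
    diffs2 = (values[iu] - values[ju]) ** 2
    nbins = len(edges) - 1
    which = np.digitize(dist, edges) - 1
    gamma = np.full(nbins, np.nan)
    counts = np.zeros(nbins, dtype=int)
    for b in range(nbins):
        sel = which == b
        counts[b] = int(sel.sum())
        if counts[b]:
            gamma[b] = diffs2[sel].mean() / 2.0
    return gamma, counts


def empirical_variogram(
    residuals: np.ndarray,
    lons: np.ndarray,
    lats: np.ndarray,
    bins: np.ndarray | None = None,
    n_permutations: int = 99,
    seed: int = 0,
    crs: str = "EPSG:4326",
    envelope: tuple[float, float] = (2.5, 97.5),
) -> VariogramResult:
    """Empirical semivariogram with a permutation envelope.

    gamma(h) = (1 / 2|N(h)|) * sum over pairs in bin h of (r_i - r_j)^2,
    pairs binned by great-circle distance.  The envelope permutes residual
    labels over the fixed locations; an empirical curve inside the envelope
    is consistent with spatially unstructured residuals.  Default bins: 10
    equal-width bins up to half the maximum inter-point distance.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size < 2:
        raise ValueError("variogram needs at least 2 locations")
    if not np.all(np.isfinite(r)):
        raise ValueError("residuals must be finite")
    lons = np.asarray(lons, float)
    lats = np.asarray(lats, float)
    iu, ju = np.triu_indices(r.size, k=1)
    dist = np.asarray(
        point_distance_km(crs, lons[iu], lats[iu], lons[ju], lats[ju])
    )
    if bins is None:
        bins = np.linspace(0.0, dist.max() / 2.0, 11)
    edges = np.asarray(bins, dtype=float)
    centers = (edges[:-1] + edges[1:]) / 2

    gamma, counts = _pairwise_semivariance(r, iu, ju, dist, edges)
    rng = np.random.default_rng(seed)
    perms = np.empty((n_permutations, len(centers)))
    for s in range(n_permutations):
        perm = rng.permutation(r)
        perms[s], _ = _pairwise_semivariance(perm, iu, ju, dist, edges)
    lo, hi = np.nanpercentile(perms, list(envelope), axis=0)
    return VariogramResult(
        bin_centers=centers,
        semivariance=gamma,
        pair_counts=counts,
        envelope_lower=lo,
        envelope_upper=hi,
        n_permutations=n_permutations,
    )


def residuals(
    fit: FitResult, data: GroupedData, kind: str = "pearson"
) -> np.ndarray:
    """Per-cluster standardized residuals under the fitted model.

    Pearson: (y/n - pi_hat) / sqrt(pi_hat (1 - pi_hat) / n), with pi_hat the
    fitted observed-scale probability including the region's conditional
    mode.  Deviance residuals available via ``kind="deviance"``.  Fitted
    probabilities of exactly 0 or 1 give NaN with no error (callers filter).
    """
    if not fit.converged:
        raise RuntimeError("residuals require a converged fit")
    out = []
    for g, (y, n, X) in enumerate(zip(data.y, data.n, data.X)):
        mode = fit.region_modes[g] if fit.sigma > 0 else 0.0
        pi = _observed_prob(X @ fit.beta + mode, fit.spec)
        phat = y / n
        if kind == "pearson":
            denom = np.sqrt(pi * (1 - pi) / n)
            res = np.where(denom > 0, (phat - pi) / denom, np.nan)
        elif kind == "deviance":
            with np.errstate(divide="ignore", invalid="ignore"):
                term1 = np.where(y > 0, y * np.log(y / (n * pi)), 0.0)
                term2 = np.where(
                    y < n, (n - y) * np.log((n - y) / (n * (1 - pi))), 0.0
                )
            res = np.sign(phat - pi) * np.sqrt(2 * np.clip(term1 + term2, 0, None))
        else:
            raise ValueError(f"unknown residual kind {kind!r}")
        out.append(res)
    return np.concatenate(out)


def posterior_predictive_check(
    fit: FitResult,
    data: GroupedData,
    n_sims: int = 500,
    seed: int = 0,
) -> PpcResult:
    """Simulation-based goodness of fit on the mean and SD of cluster prevalence.

    Simulates ``n_sims`` datasets from the fitted model, computes the mean
    and SD over clusters of y_i / n_i for each, and reports two-sided
    Monte-Carlo p-values for the observed statistics relative to the
    simulated distributions (distance from the simulation median, with the
    +1 correction so p is in (0, 1]).
    """
    y_obs = np.concatenate(data.y)
    n = np.concatenate(data.n)
    obs = y_obs / n
    obs_mean = float(obs.mean())
    obs_sd = float(obs.std(ddof=1))

    sims = simulate_from_fit(fit, data, n_sims, seed)
    prev = sims / n
    sim_means = prev.mean(axis=1)
    sim_sds = prev.std(axis=1, ddof=1)

    def mc_p(sim: np.ndarray, observed: float) -> float:
        # center on the pooled median so (observed, sims) stays exchangeable
        # under the null; the rank-based p is then exactly super-uniform
        center = float(np.median(np.append(sim, observed)))
        extreme = np.abs(sim - center) >= abs(observed - center)
        return (1 + int(extreme.sum())) / (len(sim) + 1)

    return PpcResult(
        observed_mean=obs_mean,
        observed_sd=obs_sd,
        simulated_means=sim_means,
        simulated_sds=sim_sds,
        p_mean=mc_p(sim_means, obs_mean),
        p_sd=mc_p(sim_sds, obs_sd),
    )
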