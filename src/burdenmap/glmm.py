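"""Binomial mixed model with a region-level Gaussian random intercept.

The model for cluster i in region k with n_ki women examined and y_ki
positives is

    y_ki | Z_k ~ Binomial(n_ki, pi_ki),
    logit(p_ki) = beta_0 + sum_j beta_j d_j(x_ki) + Z_k,
    Z_k ~ Normal(0, sigma^2)  i.i.d.,

where d_j are covariate values at the cluster location.  Two adjustment
modes connect the modelled true prevalence p to the observed questionnaire
positives:

* ``pre_adjust`` — counts were already corrected for sensitivity/specificity
  upstream (:func:`burdenmap.misclassification.adjust_counts`), so
  pi = expit(eta);
* ``embedded`` — Se/Sp enter the likelihood, pi = Se*p + (1-Sp)*(1-p) with
  p = expit(eta).  This keeps the binomial variance structure intact, which
  matters at prevalences of a few per 1000.

The marginal likelihood integrates Z_k out of each region's contribution by
adaptive Gauss-Hermite quadrature centered at the conditional mode of Z_k
(order 1 recovers the Laplace approximation).  Maximization is quasi-Newton
over (beta, log sigma); the covariance of the estimates comes from the
numerically differentiated observed information.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import brentq, minimize
from scipy.special import expit, gammaln, logsumexp

from .misclassification import AdjustmentMode, TestAccuracy
from .survey_io import ClusterRecord, Outcome

_ETA_CLIP = 35.0
_SIGMA_ZERO = 1e-4


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one mixed-model fit."""

    covariates: tuple[str, ...] = ()
    mode: AdjustmentMode = "embedded"
    accuracy: TestAccuracy = TestAccuracy()
    quadrature_order: int = 21
    outcome: Outcome = "lifetime"
    random_effect: Literal["region", "cluster"] = "region"

    def __post_init__(self) -> None:
        q = self.quadrature_order
        if q < 1 or q % 2 == 0:
            raise ValueError("quadrature order must be odd and >= 1")

    @property
    def fold_slope(self) -> float:
        """Slope of the observed-on-true probability map (1 when pre-adjusted)."""
        if self.mode == "embedded":
            return self.accuracy.sensitivity + self.accuracy.specificity - 1
        return 1.0

    @property
    def fold_floor(self) -> float:
        """False-positive floor of the observed probability (0 when pre-adjusted)."""
        if self.mode == "embedded":
            return 1 - self.accuracy.specificity
        return 0.0


@dataclass
class FitResult:
    """Maximum-likelihood estimates of the misclassification-adjusted GLMM."""

    beta: np.ndarray                 # intercept first, logit scale
    beta_names: list[str]
    sigma: float                     # random-effect SD (0 if at boundary)
    log_sigma: float
    vcov: np.ndarray                 # over (beta, log_sigma)
    loglik: float
    converged: bool
    region_ids: list[str]
    region_modes: np.ndarray         # conditional mode of Z_k
    region_curvatures: np.ndarray    # -d2/dz2 of the joint log density at the mode
    spec: ModelSpec
    n_clusters: int = 0

    @property
    def vcov_beta(self) -> np.ndarray:
        p = len(self.beta)
        return self.vcov[:p, :p]

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.vcov_beta), 0, None))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "beta": self.beta.tolist(),
            "beta_names": self.beta_names,
            "sigma": self.sigma,
            "log_sigma": self.log_sigma,
            "vcov": self.vcov.tolist(),
            "loglik": self.loglik,
            "converged": self.converged,
            "region_ids": self.region_ids,
            "region_modes": self.region_modes.tolist(),
            "region_curvatures": self.region_curvatures.tolist(),
            "n_clusters": self.n_clusters,
            "spec": {
                "covariates": list(self.spec.covariates),
                "mode": self.spec.mode,
                "sensitivity": self.spec.accuracy.sensitivity,
                "specificity": self.spec.accuracy.specificity,
                "quadrature_order": self.spec.quadrature_order,
                "outcome": self.spec.outcome,
                "random_effect": self.spec.random_effect,
            },
        }
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FitResult":
        d = json.loads(Path(path).read_text())
        s = d["spec"]
        spec = ModelSpec(
            covariates=tuple(s["covariates"]),
            mode=s["mode"],
            accuracy=TestAccuracy(s["sensitivity"], s["specificity"]),
            quadrature_order=s["quadrature_order"],
            outcome=s["outcome"],
            random_effect=s["random_effect"],
        )
        return cls(
            beta=np.asarray(d["beta"]),
            beta_names=d["beta_names"],
            sigma=d["sigma"],
            log_sigma=d["log_sigma"],
            vcov=np.asarray(d["vcov"]),
            loglik=d["loglik"],
            converged=d["converged"],
            region_ids=d["region_ids"],
            region_modes=np.asarray(d["region_modes"]),
            region_curvatures=np.asarray(d["region_curvatures"]),
            spec=spec,
            n_clusters=d.get("n_clusters", 0),
        )


# --------------------------------------------------------------------------
# data marshalling

@dataclass
class GroupedData:
    """Outcome counts and design matrices grouped by random-effect level."""

    group_ids: list[str]
    y: list[np.ndarray]
    n: list[np.ndarray]
    X: list[np.ndarray]          # includes leading intercept column
    logC: list[float]            # sum of log binomial coefficients per group

    @property
    def n_params(self) -> int:
        return self.X[0].shape[1]


def build_design(
    records: Sequence[ClusterRecord],
    covariate_values: Mapping[str, np.ndarray] | None,
    spec: ModelSpec,
) -> GroupedData:
    """Group cluster counts and covariates by the random-effect level.

    ``covariate_values`` maps covariate name to an array aligned with
    ``records``; pass None (or {}) for an intercept-only model.
    """
    covariate_values = covariate_values or {}
    n_obs = len(records)
    cols = [np.ones(n_obs)]
    for name in spec.covariates:
        v = np.asarray(covariate_values[name], dtype=float)
        if v.shape != (n_obs,):
            raise ValueError(f"covariate {name!r} not aligned with records")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"covariate {name!r} has non-finite values")
        cols.append(v)
    X = np.column_stack(cols)
    y = np.array([r.count(spec.outcome) for r in records], dtype=float)
    n = np.array([r.n_examined for r in records], dtype=float)

    if spec.random_effect == "cluster":
        keys = [r.cluster_id for r in records]
    else:
        keys = [r.region_id for r in records]
    order: dict[str, list[int]] = {}
    for i, k in enumerate(keys):
        order.setdefault(k, []).append(i)
    gids, ys, ns, Xs, logCs = [], [], [], [], []
    for k, idx in order.items():
        idx = np.asarray(idx)
        gids.append(k)
        ys.append(y[idx])
        ns.append(n[idx])
        Xs.append(X[idx])
        logCs.append(float(np.sum(
            gammaln(n[idx] + 1) - gammaln(y[idx] + 1) - gammaln(n[idx] - y[idx] + 1)
        )))
    return GroupedData(gids, ys, ns, Xs, logCs)


# --------------------------------------------------------------------------
# likelihood internals

def _observed_prob(eta: np.ndarray, spec: ModelSpec) -> np.ndarray:
    mu = expit(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
    pi = spec.fold_floor + spec.fold_slope * mu
    return np.clip(pi, 1e-300, 1 - 1e-16)


def _binom_lp(y, n, eta, spec: ModelSpec) -> float:
    """Sum of y*log(pi) + (n-y)*log(1-pi); binomial coefficients excluded."""
    pi = _observed_prob(eta, spec)
    return float(np.sum(y * np.log(pi) + (n - y) * np.log1p(-pi)))


def _binom_lp_grad_z(y, n, eta, spec: ModelSpec) -> float:
    """d/dz of the summed binomial log-probability (z enters eta additively)."""
    mu = expit(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
    pi = _observed_prob(eta, spec)
    dpi = spec.fold_slope * mu * (1 - mu)
    return float(np.sum((y / pi - (n - y) / (1 - pi)) * dpi))


def _conditional_mode(y, n, eta0, sigma2: float, spec: ModelSpec) -> tuple[float, float]:
    """Mode and curvature of z -> log f(y|z) + log phi(z; 0, sigma2).

    Returns (z_hat, H) with H = -h''(z_hat) > 0.
    """
    def g(z: float) -> float:
        return _binom_lp_grad_z(y, n, eta0 + z, spec) - z / sigma2

    # the prior term dominates for large |z|; expand a bracket until sign change
    b = 5.0 * np.sqrt(sigma2) + 5.0
    for _ in range(60):
        if g(-b) > 0 and g(b) < 0:
            break
        b *= 2.0
    else:  # pragma: no cover - g is monotone-dominated; bracket always found
        raise RuntimeError("could not bracket the conditional mode")
    z_hat = brentq(g, -b, b, xtol=1e-12, rtol=8.9e-16)
    step = 1e-5 * (1 + abs(z_hat))
    h2 = (g(z_hat + step) - g(z_hat - step)) / (2 * step)
    H = -h2
    if not np.isfinite(H) or H <= 0:
        H = 1.0 / sigma2
    return z_hat, H


def _group_loglik(y, n, X, beta, sigma: float, spec: ModelSpec,
                  nodes, logweights) -> tuple[float, float, float]:
    """Marginal log-likelihood contribution of one group (coefficients excluded).

    Returns (loglik, z_hat, H).
    """
    eta0 = X @ beta
    sigma2 = sigma * sigma
    if sigma < _SIGMA_ZERO:
        # degenerate mixture: random effect pinned at 0
        return _binom_lp(y, n, eta0, spec), 0.0, np.inf

    z_hat, H = _conditional_mode(y, n, eta0, sigma2, spec)
    tau = 1.0 / np.sqrt(H)
    z_q = z_hat + tau * nodes
    log_prior = -0.5 * np.log(2 * np.pi * sigma2) - 0.5 * z_q**2 / sigma2
    h_q = np.array([
        _binom_lp(y, n, eta0 + z, spec) for z in z_q
    ]) + log_prior
    # Gauss-Hermite (probabilists') reweighting of exp(h) against the
    # Gaussian kernel centered at the mode with scale tau
    log_int = logsumexp(h_q + 0.5 * nodes**2 + logweights) + np.log(tau)
    return float(log_int), z_hat, H


def marginal_loglik(
    beta: np.ndarray, log_sigma: float, data: GroupedData, spec: ModelSpec
) -> float:
    """Marginal log-likelihood of (beta, log_sigma), binomial coefficients included."""
    sigma = float(np.exp(log_sigma))
    nodes, weights = hermegauss(spec.quadrature_order)
    logw = np.log(weights)
    total = 0.0
    for y, n, X, logC in zip(data.y, data.n, data.X, data.logC):
        ll, _, _ = _group_loglik(y, n, X, beta, sigma, spec, nodes, logw)
        total += ll + logC
    return total


# --------------------------------------------------------------------------
# fixed-effects logit fit (no random effect) — also the GLMM starting point

def fit_fixed_logit(
    y: np.ndarray, n: np.ndarray, X: np.ndarray, spec: ModelSpec
) -> tuple[np.ndarray, float, bool]:
    """ML fit of the no-random-effect binomial logit model.

    Returns (beta_hat, maximized log-likelihood including coefficients,
    converged flag).  Non-convergence (e.g. perfect separation) is flagged,
    not raised.
    """
    y = np.asarray(y, float)
    n = np.asarray(n, float)
    logC = float(np.sum(gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)))

    def nll_grad(beta):
        eta = X @ beta
        mu = expit(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        pi = _observed_prob(eta, spec)
        lp = np.sum(y * np.log(pi) + (n - y) * np.log1p(-pi))
        dpi = spec.fold_slope * mu * (1 - mu)
        score = X.T @ ((y / pi - (n - y) / (1 - pi)) * dpi)
        return -lp, -score

    p = X.shape[1]
    start = np.zeros(p)
    pbar = np.clip(np.sum(y) / np.sum(n), 1e-6, 1 - 1e-6)
    if spec.mode == "embedded":
        from .misclassification import unfold
        pbar = np.clip(unfold(pbar, spec.accuracy, warn=False), 1e-6, 1 - 1e-6)
    start[0] = np.log(pbar / (1 - pbar))
    res = minimize(nll_grad, start, jac=True, method="BFGS",
                   options={"gtol": 1e-8, "maxiter": 500})
    converged = bool(res.success or np.linalg.norm(res.jac) < 1e-4)
    if np.any(np.abs(res.x) > 15):
        converged = False  # separation: estimates diverging along a direction
    return res.x, float(-res.fun + logC), converged


# --------------------------------------------------------------------------
# full fit

def fit(
    records: Sequence[ClusterRecord],
    spec: ModelSpec,
    covariate_values: Mapping[str, np.ndarray] | None = None,
) -> FitResult:
    """Maximum-likelihood fit of the binomial mixed model.

    Optimizes (beta, log sigma) by L-BFGS from a deterministic start (beta
    from the fixed-effects logit fit, log sigma = log 0.1), with up to two
    jittered restarts if the first attempt fails to converge.  With fewer
    than 2 random-effect groups, sigma is fixed at 0.
    """
    data = build_design(records, covariate_values, spec)
    p = data.n_params
    y_all = np.concatenate(data.y)
    n_all = np.concatenate(data.n)
    X_all = np.vstack(data.X)

    beta0, _, _ = fit_fixed_logit(y_all, n_all, X_all, spec)
    n_groups = len(data.group_ids)
    fix_sigma = n_groups < 2

    nodes, weights = hermegauss(spec.quadrature_order)
    logw = np.log(weights)
    logC_total = float(np.sum(data.logC))

    def nll(theta):
        beta, log_sigma = theta[:p], theta[p]
        sigma = float(np.exp(log_sigma))
        total = 0.0
        for y, n, X in zip(data.y, data.n, data.X):
            ll, _, _ = _group_loglik(y, n, X, beta, sigma, spec, nodes, logw)
            total += ll
        return -(total + logC_total)

    if fix_sigma:
        def nll_beta(beta):
            eta = X_all @ beta
            return -(_binom_lp(y_all, n_all, eta, spec) + logC_total)
        res = minimize(nll_beta, beta0, method="BFGS", options={"gtol": 1e-8})
        theta_hat = np.append(res.x, -np.inf)
        best = res
    else:
        start = np.append(beta0, np.log(0.1))
        restart_rng = np.random.default_rng(202406)
        best = None
        for attempt in range(3):
            s = start if attempt == 0 else start + np.append(
                restart_rng.normal(0, 0.5, size=p), restart_rng.normal(0, 0.5)
            )
            res = minimize(nll, s, method="L-BFGS-B",
                           options={"maxiter": 300, "ftol": 1e-12, "gtol": 1e-7})
            if best is None or res.fun < best.fun:
                best = res
            if _converged(best):
                break
        theta_hat = best.x

    beta_hat = theta_hat[:p]
    log_sigma_hat = float(theta_hat[p])
    sigma_hat = float(np.exp(log_sigma_hat)) if np.isfinite(log_sigma_hat) else 0.0
    if sigma_hat < _SIGMA_ZERO:
        sigma_hat = 0.0
    loglik = marginal_loglik(beta_hat, log_sigma_hat if not fix_sigma else -50.0,
                             data, spec)

    # observed information by central finite differences of the neg-loglik
    dim = p if fix_sigma else p + 1
    theta = theta_hat[:dim].copy()
    if fix_sigma:
        f = lambda t: -marginal_loglik(t, -50.0, data, spec)
    else:
        f = lambda t: -marginal_loglik(t[:p], t[p], data, spec)
    hess = _fd_hessian(f, theta)
    vcov_small = _robust_inverse(hess)
    vcov = np.zeros((p + 1, p + 1))
    vcov[:dim, :dim] = vcov_small

    sigma_for_modes = max(sigma_hat, 0.0)
    modes = np.zeros(n_groups)
    curvs = np.full(n_groups, np.inf)
    if sigma_for_modes >= _SIGMA_ZERO:
        for g, (y, n, X) in enumerate(zip(data.y, data.n, data.X)):
            modes[g], curvs[g] = _conditional_mode(
                y, n, X @ beta_hat, sigma_for_modes**2, spec
            )

    converged = fix_sigma and bool(best.success) or (not fix_sigma and _converged(best))
    names = ["(intercept)", *spec.covariates]
    return FitResult(
        beta=beta_hat, beta_names=names, sigma=sigma_hat,
        log_sigma=log_sigma_hat, vcov=vcov, loglik=float(loglik),
        converged=bool(converged), region_ids=data.group_ids,
        region_modes=modes, region_curvatures=curvs, spec=spec,
        n_clusters=len(records),
    )


def _converged(res) -> bool:
    if res is None:
        return False
    grad = np.asarray(res.jac if res.jac is not None else np.inf)
    scale = 1.0 + abs(float(res.fun))
    return bool(res.success) and float(np.max(np.abs(grad))) < 1e-5 * scale


def _fd_hessian(f, theta: np.ndarray) -> np.ndarray:
    dim = theta.size
    steps = 1e-4 * (1 + np.abs(theta))
    H = np.zeros((dim, dim))
    f0 = f(theta)
    for i in range(dim):
        for j in range(i, dim):
            ei = np.zeros(dim); ei[i] = steps[i]
            ej = np.zeros(dim); ej[j] = steps[j]
            if i == j:
                H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / steps[i] ** 2
            else:
                fpp = f(theta + ei + ej)
                fpm = f(theta + ei - ej)
                fmp = f(theta - ei + ej)
                fmm = f(theta - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return H


def _robust_inverse(H: np.ndarray) -> np.ndarray:
    """Symmetric PSD (pseudo-)inverse of an observed-information estimate."""
    H = (H + H.T) / 2
    vals, vecs = np.linalg.eigh(H)
    inv_vals = np.where(vals > 1e-10, 1 / np.clip(vals, 1e-10, None), 0.0)
    V = vecs @ np.diag(inv_vals) @ vecs.T
    return (V + V.T) / 2


# --------------------------------------------------------------------------
# simulation and prediction from a fit

def simulate_from_fit(
    fit_result: FitResult,
    data: GroupedData,
    n_sims: int,
    seed: int,
    force: bool = False,
) -> np.ndarray:
    """Parametric-bootstrap outcome replicates from the fitted model.

    Each replicate draws fresh region effects Z_k ~ N(0, sigma_hat^2) and
    binomial counts at the fitted observed-scale probabilities.  Returns an
    array of shape (n_sims, n_clusters) in the grouped-data cluster order.
    """
    if not fit_result.converged and not force:
        raise RuntimeError("refusing to simulate from an unconverged fit")
    rng = np.random.default_rng(seed)
    spec = fit_result.spec
    n_clusters = sum(len(y) for y in data.y)
    out = np.zeros((n_sims, n_clusters), dtype=int)
    eta0s = [X @ fit_result.beta for X in data.X]
    ns = np.concatenate(data.n).astype(int)
    for s in range(n_sims):
        pieces = []
        for eta0 in eta0s:
            z = rng.normal(0.0, fit_result.sigma) if fit_result.sigma > 0 else 0.0
            pieces.append(_observed_prob(eta0 + z, spec))
        pi = np.concatenate(pieces)
        out[s] = rng.binomial(ns, pi)
    return out


def predict_linpred(
    fit_result: FitResult,
    covariate_values: Mapping[str, float | np.ndarray],
    region_id: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Logit-scale prediction with variance.

    Returns (eta, var).  With a known region the conditional mode of Z_k is
    added and its conditional variance (inverse curvature) enters the
    variance; otherwise Z is integrated at 0 with variance sigma_hat^2.
    """
    names = fit_result.spec.covariates
    for name in names:
        if name not in covariate_values:
            raise KeyError(f"missing covariate {name!r}")
    cols = [np.atleast_1d(np.asarray(covariate_values[n], float)) for n in names]
    n_pts = cols[0].size if cols else 1
    X = np.column_stack([np.ones(n_pts), *cols]) if cols else np.ones((1, 1))
    eta = X @ fit_result.beta
    var = np.einsum("ij,jk,ik->i", X, fit_result.vcov_beta, X)
    if region_id is not None:
        k = fit_result.region_ids.index(region_id)
        eta = eta + fit_result.region_modes[k]
        curv = fit_result.region_curvatures[k]
        var = var + (0.0 if np.isinf(curv) else 1.0 / curv)
    else:
        var = var + fit_result.sigma**2
    return eta, var
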