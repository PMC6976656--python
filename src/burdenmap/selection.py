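"""Grouped univariate covariate screening by AIC.

Candidate covariates are organized into thematic groups (e.g. several
urbanization-related surfaces in one group) to limit collinearity; within
each group every member is screened with a univariate binomial logit model
(intercept + one slope, no random effect) and the member with the lowest

    AIC = -2 * loglik + 2 * k

wins its group.  Covariates are standardized over clusters before fitting —
an affine change the selection is invariant to — so slopes are comparable
and the optimizer is well-scaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .glmm import ModelSpec, fit_fixed_logit
from .survey_io import ClusterRecord


@dataclass(frozen=True)
class VariableGroup:
    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"group {self.name!r} has no members")


@dataclass
class UnivariateFit:
    group: str
    member: str
    loglik: float
    k: int
    converged: bool

    @property
    def aic_value(self) -> float:
        return aic(self.loglik, self.k)


@dataclass
class SelectionReport:
    fits: list[UnivariateFit]
    chosen: dict[str, str]          # group name -> winning member

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group": f.group,
                "member": f.member,
                "loglik": f.loglik,
                "k": f.k,
                "aic": f.aic_value,
                "converged": f.converged,
                "chosen": self.chosen.get(f.group) == f.member,
            }
            for f in self.fits
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion; lower is better."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return -2.0 * loglik + 2.0 * k


def fit_univariate(
    records: Sequence[ClusterRecord],
    values: np.ndarray,
    spec: ModelSpec,
) -> UnivariateFit:
    """Intercept + single-slope binomial logit ML fit (k = 2), no random effect.

    ``values`` is the covariate sampled at every cluster.  Fitting honours
    the spec's adjustment mode (the slope refers to true-scale prevalence in
    embedded mode).  A non-converged fit (e.g. perfect separation) is
    returned flagged, never raised.
    """
    v = np.asarray(values, dtype=float)
    if v.shape != (len(records),):
        raise ValueError("covariate not aligned with records")
    sd = v.std()
    vstd = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
    y = np.array([r.count(spec.outcome) for r in records], dtype=float)
    n = np.array([r.n_examined for r in records], dtype=float)
    X = np.column_stack([np.ones(len(records)), vstd])
    beta, loglik, converged = fit_fixed_logit(y, n, X, spec)
    return UnivariateFit("", "", float(loglik), 2, converged)


def select(
    groups: Sequence[VariableGroup],
    records: Sequence[ClusterRecord],
    covariate_values: Mapping[str, np.ndarray],
    spec: ModelSpec,
) -> SelectionReport:
    """Screen every group member and pick the per-group AIC minimizer.

    Ties break to the first-listed member.  A group with no converged member
    raises, naming the group.
    """
    fits: list[UnivariateFit] = []
    chosen: dict[str, str] = {}
    for group in groups:
        best: UnivariateFit | None = None
        for member in group.members:
            if member not in covariate_values:
                raise KeyError(f"group {group.name!r}: unknown covariate {member!r}")
            f = fit_univariate(records, covariate_values[member], spec)
            f.group, f.member = group.name, member
            fits.append(f)
            if not f.converged:
                continue
            if best is None or f.aic_value < best.aic_value:
                best = f
        if best is None:
            raise ValueError(f"no univariate fit converged in group {group.name!r}")
        chosen[group.name] = best.member
    return SelectionReport(fits=fits, chosen=chosen)
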