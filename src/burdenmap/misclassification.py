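"""Diagnostic-accuracy adjustment of prevalence and counts.

A symptom questionnaire with sensitivity Se and specificity Sp observes, for
true prevalence p, an expected positive proportion

    p_obs = Se * p + (1 - Sp) * (1 - p)

(``fold``).  When Se + Sp > 1 the map is strictly increasing and invertible
on its attainable band [1 - Sp, Se]; ``unfold`` applies the inverse

    p_true = (p_obs + Sp - 1) / (Se + Sp - 1)

clamped to [0, 1] (observed proportions below the false-positive floor carry
no information about p beyond "small", hence the clamp with a warning flag).
``adjust_counts`` applies ``unfold`` to cluster count data before model
fitting; the alternative of embedding Se/Sp in the model likelihood lives in
:mod:`burdenmap.glmm`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .survey_io import ClusterRecord

AdjustmentMode = Literal["pre_adjust", "embedded"]


class ClampWarning(UserWarning):
    """An unfolded proportion fell outside [0, 1] and was clamped."""


@dataclass(frozen=True)
class TestAccuracy:
    """Questionnaire sensitivity and specificity.

    Se + Sp > 1 is required for identifiability (the fold map must be
    increasing in true prevalence).
    """

    sensitivity: float = 0.97
    specificity: float = 0.99

    def __post_init__(self) -> None:
        if not (0 <= self.sensitivity <= 1 and 0 <= self.specificity <= 1):
            raise ValueError("sensitivity and specificity must be in [0, 1]")
        if self.sensitivity + self.specificity <= 1:
            raise ValueError("need Se + Sp > 1 for an informative test")

    @property
    def is_perfect(self) -> bool:
        return self.sensitivity == 1.0 and self.specificity == 1.0


def fold(p_true, acc: TestAccuracy):
    """Expected observed-positive proportion for true prevalence ``p_true``."""
    p = np.asarray(p_true, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p_true must lie in [0, 1]")
    out = acc.sensitivity * p + (1 - acc.specificity) * (1 - p)
    return out if out.ndim else float(out)


def unfold(p_obs, acc: TestAccuracy, warn: bool = True):
    """Invert ``fold``; values outside the attainable band clamp to 0 or 1."""
    p = np.asarray(p_obs, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p_obs must lie in [0, 1]")
    denom = acc.sensitivity + acc.specificity - 1
    raw = (p + acc.specificity - 1) / denom
    clamped = np.clip(raw, 0.0, 1.0)
    if warn and np.any(raw != clamped):
        warnings.warn(
            "observed proportion outside the attainable band; clamped",
            ClampWarning,
            stacklevel=2,
        )
    return clamped if clamped.ndim else float(clamped)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # low-count cells are sensitive to the rounding rule; bankers' rounding
    # would bias even counts, so round half away from zero
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def adjust_counts(
    records: list[ClusterRecord],
    acc: TestAccuracy,
    rounding: Literal["half_away", "floor"] = "half_away",
) -> list[ClusterRecord]:
    """Replace observed outcome counts with accuracy-adjusted true-scale counts.

    Each count becomes ``round(n_examined * unfold(count / n_examined))``;
    the nesting invariant is re-enforced by capping the untreated count at the
    lifetime count.  With a perfect test the records are returned unchanged.
    """
    if acc.is_perfect:
        return list(records)
    rounder = _round_half_away if rounding == "half_away" else np.floor
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ClampWarning)
        for rec in records:
            n = rec.n_examined
            life = int(rounder(np.asarray(n * unfold(rec.n_lifetime / n, acc))))
            untr = int(rounder(np.asarray(n * unfold(rec.n_untreated / n, acc))))
            untr = min(untr, life)
            out.append(replace(rec, n_lifetime=life, n_untreated=untr))
    return out
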