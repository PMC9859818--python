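"""Synthetic patient-cohort generator.

Emulates the statistical structure of the reference cohort: the per-score
STOL distribution, the outcome distribution conditional on score, and a
Magnin index that is linear-Gaussian in the score, calibrated so that the
marginal mean/sd and the score-Magnin correlation hit their targets.  The
generator makes each record independently; it does not simulate labor
physiology, time-to-delivery, or any within-patient dependence beyond the
single score-Magnin correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from . import reference
from .cohort import OUTCOME_ORDER, Cohort, JointTable, PatientRecord

__all__ = ["GeneratorParams", "default_params", "CohortGenerator", "generate_cohort"]

_SCORES = np.arange(1, 9)


@dataclass(frozen=True)
class GeneratorParams:
    """Calibration of the synthetic cohort generator.

    ``score_probs`` is the marginal distribution of the STOL score (length 8,
    scores 1..8); ``outcome_given_score`` is an (8, 6) row-stochastic matrix
    of outcome probabilities conditional on score (rows for scores with zero
    marginal probability may be NaN — they are never sampled).  The Magnin
    index is drawn as ``a + b*score + eps`` with the slope set from the
    target correlation and ``eps`` Gaussian, so the marginal mean/sd and the
    correlation are exact in the large-sample limit.
    """

    score_probs: np.ndarray
    outcome_given_score: np.ndarray
    magnin_mean: float = reference.MAGNIN_MEAN
    magnin_sd: float = reference.MAGNIN_SD
    stol_magnin_corr: float = reference.STOL_MAGNIN_CORR
    emit_diameters: bool = False
    conjugate_mean: float = reference.CONJUGATE_MEDIAN
    conjugate_sd: float = reference.CONJUGATE_SD
    transverse_mean: float = reference.TRANSVERSE_MEDIAN
    transverse_sd: float = reference.TRANSVERSE_SD
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        p = np.asarray(self.score_probs, dtype=float)
        q = np.asarray(self.outcome_given_score, dtype=float)
        if p.shape != (8,):
            raise ValueError(f"score_probs must have shape (8,), got {p.shape}")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("score_probs must be non-negative and sum to 1")
        if q.shape != (8, len(OUTCOME_ORDER)):
            raise ValueError(f"outcome_given_score must be (8, 6), got {q.shape}")
        for s in range(8):
            row = q[s]
            if p[s] > 0:
                if np.any(np.isnan(row)) or np.any(row < 0) or abs(row.sum() - 1.0) > 1e-12:
                    raise ValueError(
                        f"conditional outcome distribution for score {s + 1} must be a "
                        "probability vector"
                    )
        if not -1.0 < self.stol_magnin_corr < 1.0:
            raise ValueError("stol_magnin_corr must lie strictly in (-1, 1)")
        if self.magnin_sd <= 0:
            raise ValueError("magnin_sd must be positive")
        object.__setattr__(self, "score_probs", p)
        object.__setattr__(self, "outcome_given_score", q)

    def score_moments(self) -> tuple[float, float]:
        mu = float(np.dot(self.score_probs, _SCORES))
        var = float(np.dot(self.score_probs, (_SCORES - mu) ** 2))
        return mu, var

    def magnin_line(self) -> tuple[float, float, float]:
        """Intercept, slope and residual sd of the Magnin model given score."""
        mu, var = self.score_moments()
        if var == 0:
            if self.stol_magnin_corr != 0:
                raise ValueError(
                    "cannot target a nonzero score-Magnin correlation with a "
                    "degenerate score distribution"
                )
            b = 0.0
        else:
            b = self.stol_magnin_corr * self.magnin_sd / np.sqrt(var)
        eps_sd = self.magnin_sd * np.sqrt(1.0 - self.stol_magnin_corr**2)
        a = self.magnin_mean - b * mu
        return a, b, eps_sd


def default_params(joint_table: JointTable, **overrides) -> GeneratorParams:
    """Calibrate generator parameters to a by-score joint table.

    Score marginals are the table's row totals over its grand total; outcome
    conditionals are the within-row relative frequencies (NaN where a row is
    empty, flagged with a warning).  Magnin targets default to the reference
    values (mean 24 cm, sd 1.4 cm, correlation -0.742 with the score).
    """
    if joint_table.axis != "by_score":
        raise ValueError("default_params requires a by_score joint table")
    counts = joint_table.counts.astype(float)
    n = counts.sum()
    if n == 0:
        raise ValueError("cannot calibrate to an empty table")
    row_totals = counts.sum(axis=1)
    score_probs = row_totals / n
    with np.errstate(invalid="ignore", divide="ignore"):
        conditionals = counts / row_totals[:, None]
    if np.any(row_totals == 0):
        warnings.warn(
            "joint table has empty score rows; their outcome conditionals are "
            "undefined (NaN) and will never be sampled",
            stacklevel=2,
        )
    return GeneratorParams(
        score_probs=score_probs, outcome_given_score=conditionals, **overrides
    )


class CohortGenerator(BaseEstimator):
    """Sampler for synthetic delivery cohorts (sklearn-style parameter surface).

    Parameters mirror :class:`GeneratorParams`; ``sample(n, seed)`` draws a
    cohort.  Identical ``(params, n, seed)`` give identical cohorts.
    """

    def __init__(self, params: Optional[GeneratorParams] = None):
        self.params = params

    def _resolved(self) -> GeneratorParams:
        if self.params is not None:
            return self.params
        return default_params(reference.reference_joint_by_score())

    def sample(self, n: int, seed: Optional[int] = None) -> Cohort:
        if not isinstance(n, (int, np.integer)) or n < 0:
            raise ValueError(f"n must be a non-negative integer, got {n!r}")
        params = self._resolved()
        if seed is None:
            seed = params.seed
        if seed is None and n > 0:
            raise ValueError("a seed is required for any non-empty sample")
        rng = np.random.default_rng(seed)
        if n == 0:
            return Cohort(records=(), provenance="synthetic")
        scores = rng.choice(_SCORES, size=n, p=params.score_probs)
        outcomes = np.empty(n, dtype=int)
        for s in _SCORES:
            mask = scores == s
            k = int(mask.sum())
            if k:
                outcomes[mask] = rng.choice(
                    len(OUTCOME_ORDER), size=k, p=params.outcome_given_score[s - 1]
                )
        records = []
        if params.emit_diameters:
            conj = rng.normal(params.conjugate_mean, params.conjugate_sd, size=n)
            trans = rng.normal(params.transverse_mean, params.transverse_sd, size=n)
            conj = np.maximum(conj, 0.1)
            trans = np.maximum(trans, 0.1)
            magnin = conj + trans
            for i in range(n):
                records.append(
                    PatientRecord(
                        stol=int(scores[i]),
                        outcome=OUTCOME_ORDER[outcomes[i]],
                        magnin_cm=float(magnin[i]),
                        conjugate_cm=float(conj[i]),
                        transverse_cm=float(trans[i]),
                    )
                )
        else:
            a, b, eps_sd = params.magnin_line()
            magnin = a + b * scores + rng.normal(0.0, eps_sd, size=n)
            magnin = np.maximum(magnin, 1e-6)
            for i in range(n):
                records.append(
                    PatientRecord(
                        stol=int(scores[i]),
                        outcome=OUTCOME_ORDER[outcomes[i]],
                        magnin_cm=float(magnin[i]),
                    )
                )
        return Cohort(records=tuple(records), provenance="synthetic")


def generate_cohort(params: GeneratorParams, n: int, seed: Optional[int] = None) -> Cohort:
    """Draw ``n`` independent records under ``params`` (see :class:`CohortGenerator`)."""
    return CohortGenerator(params=params).sample(n, seed=seed)
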