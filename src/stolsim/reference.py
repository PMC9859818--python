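"""Reference cohort tables and deterministic cohort reconstruction.

The reference study cohort (N = 401 term singleton pregnancies referred for
MRI pelvimetry) is published only as summary tables: a category-by-outcome
percentage table and, per scheduling threshold, cumulative trial-of-labor and
emergency-cesarean counts.  This module holds those tables as constants and
rebuilds a patient-level cohort from them:

* category-by-outcome counts come from the percentages (x401, rounded half
  away from zero), which is internally consistent with every printed margin;
* per-score marginals and per-score emergency-cesarean counts come from
  differencing the cumulative threshold rows;
* the remaining outcomes (scheduled CS, normal, instrumental) are allocated
  within each category proportionally to the residual per-score capacity with
  largest-remainder rounding, deterministic by (score, outcome) order.  Policy
  results are invariant to this allocation because only emergency counts and
  score marginals enter the threshold arithmetic.

Patient-level Magnin values are not published; ``reconstruct_cohort`` can
attach synthetic ones drawn from the calibrated linear-Gaussian model.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .cohort import (
    CATEGORY_ORDER,
    CATEGORY_SCORES,
    OUTCOME_ORDER,
    Cohort,
    DeliveryOutcome,
    JointTable,
    PatientRecord,
    StolCategory,
    counts_from_percent,
    score_marginals_from_cumulative,
)

__all__ = [
    "N_TOTAL",
    "CATEGORY_OUTCOME_PERCENT",
    "CUMULATIVE_TOL",
    "CUMULATIVE_EMERGENCY_CS",
    "CUMULATIVE_EMERGENCY_CS_CPD",
    "OBSERVED_SCHEDULED_CS",
    "MAGNIN_MEAN",
    "MAGNIN_SD",
    "STOL_MAGNIN_CORR",
    "CONJUGATE_MEDIAN",
    "CONJUGATE_SD",
    "TRANSVERSE_MEDIAN",
    "TRANSVERSE_SD",
    "reference_joint_by_category",
    "reference_score_marginals",
    "reference_joint_by_score",
    "reconstruct_cohort",
]

N_TOTAL = 401

#: Category-by-outcome cell percentages of N_TOTAL; rows favorable/neutral/
#: unfavorable, columns in OUTCOME_ORDER (scheduled CS, normal, instrumental
#: CPD-related, instrumental other, emergency CS CPD-related, emergency CS other).
CATEGORY_OUTCOME_PERCENT = np.array(
    [
        [4.5, 26.9, 3.7, 2.2, 1.5, 4.7],
        [5.2, 10.7, 3.0, 1.2, 4.0, 1.0],
        [12.0, 8.0, 2.5, 0.5, 7.5, 0.7],
    ]
)

#: Cumulative number of patients with STOL score strictly below threshold
#: t = 1..8 (equivalently, trials of labor under the policy "schedule a CS
#: whenever score >= t").
CUMULATIVE_TOL = (0, 93, 144, 175, 188, 223, 276, 300)

#: Cumulative observed emergency cesareans (all causes) among scores below t.
CUMULATIVE_EMERGENCY_CS = (0, 13, 21, 25, 26, 33, 45, 52)

#: Cumulative observed emergency cesareans related to cephalopelvic
#: disproportion among scores below t.
CUMULATIVE_EMERGENCY_CS_CPD = (0, 2, 4, 6, 7, 11, 22, 26)

#: Actually scheduled cesareans in the observed cohort.
OBSERVED_SCHEDULED_CS = 87

# Marginal Magnin index distribution and its correlation with the STOL score.
MAGNIN_MEAN = 24.0
MAGNIN_SD = 1.4
STOL_MAGNIN_CORR = -0.742

# Pelvic diameter medians/spreads (cm) for optional diameter simulation.
CONJUGATE_MEDIAN = 11.7
CONJUGATE_SD = 1.1
TRANSVERSE_MEDIAN = 12.3
TRANSVERSE_SD = 0.8


def reference_joint_by_category() -> JointTable:
    """Category-by-outcome counts recovered from the printed percentages."""
    counts = counts_from_percent(CATEGORY_OUTCOME_PERCENT, N_TOTAL)
    return JointTable(axis="by_category", counts=counts)


def reference_score_marginals() -> np.ndarray:
    """Per-score patient counts from differencing the cumulative TOL row."""
    return score_marginals_from_cumulative(CUMULATIVE_TOL, N_TOTAL)


def _largest_remainder(quota: np.ndarray, total: int, cap: np.ndarray) -> np.ndarray:
    """Integerize ``quota`` (summing to ``total``) respecting per-cell caps.

    Floor each quota, then hand out remaining units by descending fractional
    part (ties broken by position) to cells with spare capacity.
    """
    base = np.minimum(np.floor(quota).astype(int), cap)
    short = total - base.sum()
    if short < 0:
        raise ValueError("quota exceeds total")  # pragma: no cover - defensive
    frac = quota - np.floor(quota)
    order = np.lexsort((np.arange(len(quota)), -frac))
    out = base.copy()
    while short > 0:
        progressed = False
        for idx in order:
            if short == 0:
                break
            if out[idx] < cap[idx]:
                out[idx] += 1
                short -= 1
                progressed = True
        if not progressed:
            raise ValueError("insufficient capacity for allocation")
    return out


def reference_joint_by_score() -> JointTable:
    """Score-by-outcome counts for the reference cohort.

    Emergency-cesarean columns are exact per score (from the cumulative
    threshold rows); the remaining outcomes are allocated within category
    proportionally to residual capacity with largest-remainder rounding.
    """
    per_score = reference_score_marginals()
    by_cat_counts = reference_joint_by_category().counts
    n_emergency = int(by_cat_counts[:, 4:6].sum())
    n_emergency_cpd = int(by_cat_counts[:, 4].sum())
    emer_all = score_marginals_from_cumulative(CUMULATIVE_EMERGENCY_CS, n_emergency)
    emer_cpd = score_marginals_from_cumulative(CUMULATIVE_EMERGENCY_CS_CPD, n_emergency_cpd)
    emer_other = emer_all - emer_cpd
    if np.any(emer_other < 0):
        raise ValueError("CPD emergency counts exceed total emergency counts")

    by_cat = by_cat_counts
    counts = np.zeros((8, len(OUTCOME_ORDER)), dtype=int)
    i_cpd = OUTCOME_ORDER.index(DeliveryOutcome.EMERGENCY_CS_CPD)
    i_oth = OUTCOME_ORDER.index(DeliveryOutcome.EMERGENCY_CS_OTHER)
    counts[:, i_cpd] = emer_cpd
    counts[:, i_oth] = emer_other

    non_emergency = [
        DeliveryOutcome.SCHEDULED_CS,
        DeliveryOutcome.NORMAL,
        DeliveryOutcome.INSTRUMENTAL_CPD,
        DeliveryOutcome.INSTRUMENTAL_OTHER,
    ]
    for ci, cat in enumerate(CATEGORY_ORDER):
        scores = np.array(CATEGORY_SCORES[cat]) - 1
        capacity = per_score[scores] - emer_all[scores]
        if np.any(capacity < 0):
            raise ValueError("emergency counts exceed per-score marginals")
        remaining = capacity.astype(float).copy()
        for outcome in non_emergency:
            oi = OUTCOME_ORDER.index(outcome)
            total = int(by_cat[ci, oi])
            pool = remaining.sum()
            quota = total * remaining / pool if pool > 0 else np.zeros_like(remaining)
            alloc = _largest_remainder(quota, total, remaining.astype(int))
            counts[scores, oi] += alloc
            remaining -= alloc
        if remaining.sum() != 0:
            raise ValueError("allocation did not exhaust category capacity")

    table = JointTable(axis="by_score", counts=counts)
    assert np.array_equal(table.by_category().counts, by_cat)
    return table


def _attach_magnin(
    scores: np.ndarray,
    rng: np.random.Generator,
    mean: float = MAGNIN_MEAN,
    sd: float = MAGNIN_SD,
    corr: float = STOL_MAGNIN_CORR,
) -> np.ndarray:
    """Draw Magnin values linear-Gaussian in the STOL score.

    The slope is calibrated so the marginal mean/sd and the score-Magnin
    correlation hit their targets given the empirical score distribution.
    """
    mu_s = scores.mean()
    sd_s = scores.std()
    if sd_s == 0:
        b = 0.0
    else:
        b = corr * sd / sd_s
    eps_sd = sd * np.sqrt(1.0 - corr**2)
    a = mean - b * mu_s
    return a + b * scores + rng.normal(0.0, eps_sd, size=scores.shape)


def reconstruct_cohort(
    with_magnin: bool = False, seed: Optional[int] = None
) -> Cohort:
    """Rebuild a 401-record patient-level cohort from the reference tables.

    Records are emitted in deterministic order (score ascending, outcome in
    table-column order).  With ``with_magnin=True`` a synthetic Magnin index
    is attached to each record (requires ``seed``); the scores and outcomes
    themselves involve no randomness.
    """
    table = reference_joint_by_score()
    records = []
    for s in range(1, 9):
        for oi, outcome in enumerate(OUTCOME_ORDER):
            records.extend(
                PatientRecord(stol=s, outcome=outcome) for _ in range(table.counts[s - 1, oi])
            )
    if with_magnin:
        if seed is None:
            raise ValueError("seed is required to attach synthetic Magnin values")
        rng = np.random.default_rng(seed)
        scores = np.array([r.stol for r in records])
        magnin = _attach_magnin(scores, rng)
        magnin = np.maximum(magnin, 1e-6)  # guard: Magnin must stay positive
        records = [
            PatientRecord(stol=r.stol, outcome=r.outcome, magnin_cm=float(m))
            for r, m in zip(records, magnin)
        ]
    return Cohort(records=tuple(records), provenance="reconstructed")
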