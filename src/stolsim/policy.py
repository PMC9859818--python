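"""Counterfactual cesarean-scheduling policy: "schedule a CS whenever STOL >= t".

Every patient with a score at or above the threshold is scheduled for
cesarean; everyone below attempts a trial of labor (TOL) and is assumed to
experience their actually observed outcome.  Actually-scheduled cesareans
below the threshold are counted in the TOL arm and contribute no cesarean —
the implicit assumption of the published sensitivity analysis, which cannot
know what outcome a scheduled-CS patient would have had under labor.
Emergency cesareans under the policy are therefore exactly the observed
emergency cesareans among below-threshold scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import DeliveryOutcome, JointTable, OUTCOME_ORDER

__all__ = ["PolicyResult", "SensitivityTable", "apply_policy", "sensitivity_table"]

_I_EMER_CPD = OUTCOME_ORDER.index(DeliveryOutcome.EMERGENCY_CS_CPD)
_I_EMER_OTH = OUTCOME_ORDER.index(DeliveryOutcome.EMERGENCY_CS_OTHER)
_I_SCHED = OUTCOME_ORDER.index(DeliveryOutcome.SCHEDULED_CS)


def _pct(numer: float, denom: float) -> Optional[float]:
    """Percentage rounded half away from zero to 1 decimal; None for 0 denominator."""
    if denom == 0:
        return None
    x = 100.0 * numer / denom
    return float(np.floor(np.abs(x) * 10 + 0.5) / 10 * np.sign(x) if x else 0.0)


@dataclass(frozen=True)
class PolicyResult:
    """Counterfactual allocation at one scheduling threshold.

    ``threshold`` is None for the observed (actual-allocation) row.
    Percentages are rounded to one decimal; ``pct_emergency_of_tol`` is None
    when nobody labors.
    """

    threshold: Optional[int]
    n_total: int
    n_tol: int
    n_scheduled_cs: int
    n_emergency_cs: int
    n_emergency_cs_cpd: int
    n_total_cs: int
    reduction_emergency: int
    reduction_emergency_cpd: int
    pct_emergency_of_all: Optional[float]
    pct_emergency_of_tol: Optional[float]
    pct_emergency_of_cs: Optional[float]
    pct_reduction_emergency: Optional[float]
    pct_reduction_emergency_cpd: Optional[float]
    pct_cs_of_all: Optional[float]
    pct_scheduled_of_all: Optional[float]


def _make_result(
    threshold: Optional[int],
    n_total: int,
    n_tol: int,
    n_scheduled: int,
    n_emer: int,
    n_emer_cpd: int,
    observed_emergency: int,
    observed_emergency_cpd: int,
) -> PolicyResult:
    n_total_cs = n_scheduled + n_emer
    red = observed_emergency - n_emer
    red_cpd = observed_emergency_cpd - n_emer_cpd
    return PolicyResult(
        threshold=threshold,
        n_total=n_total,
        n_tol=n_tol,
        n_scheduled_cs=n_scheduled,
        n_emergency_cs=n_emer,
        n_emergency_cs_cpd=n_emer_cpd,
        n_total_cs=n_total_cs,
        reduction_emergency=red,
        reduction_emergency_cpd=red_cpd,
        pct_emergency_of_all=_pct(n_emer, n_total),
        pct_emergency_of_tol=_pct(n_emer, n_tol),
        pct_emergency_of_cs=_pct(n_emer, n_total_cs),
        pct_reduction_emergency=_pct(red, observed_emergency),
        pct_reduction_emergency_cpd=_pct(red_cpd, observed_emergency_cpd),
        pct_cs_of_all=_pct(n_total_cs, n_total),
        pct_scheduled_of_all=_pct(n_scheduled, n_total),
    )


def apply_policy(joint_by_score: JointTable, threshold: int) -> PolicyResult:
    """Evaluate the scheduling rule "CS iff score >= threshold" on a cohort table.

    Threshold 9 schedules nobody (pure trial of labor for all).
    """
    if joint_by_score.axis != "by_score":
        raise ValueError("apply_policy requires a by_score joint table")
    if not isinstance(threshold, (int, np.integer)) or not 1 <= threshold <= 9:
        raise ValueError(f"threshold must be an integer in 1..9, got {threshold!r}")
    counts = joint_by_score.counts
    n_total = joint_by_score.n_total
    below = counts[: threshold - 1]
    n_tol = int(below.sum())
    n_scheduled = n_total - n_tol
    n_emer_cpd = int(below[:, _I_EMER_CPD].sum())
    n_emer = n_emer_cpd + int(below[:, _I_EMER_OTH].sum())
    observed_emer_cpd = int(counts[:, _I_EMER_CPD].sum())
    observed_emer = observed_emer_cpd + int(counts[:, _I_EMER_OTH].sum())
    return _make_result(
        int(threshold), n_total, n_tol, n_scheduled, n_emer, n_emer_cpd,
        observed_emer, observed_emer_cpd,
    )


@dataclass(frozen=True)
class SensitivityTable:
    """The observed allocation plus one policy row per threshold 1..8."""

    observed: PolicyResult
    policies: tuple[PolicyResult, ...]

    _COUNT_ROWS = [
        ("n_tol", "Trials of labor"),
        ("n_emergency_cs", "Emergency CS, all"),
        ("n_emergency_cs_cpd", "Emergency CS, CPD-related"),
        ("reduction_emergency", "Reduction, emergency CS"),
        ("reduction_emergency_cpd", "Reduction, emergency CS CPD-related"),
        ("n_total_cs", "Total CS"),
        ("n_scheduled_cs", "Scheduled CS"),
    ]
    _PCT_ROWS = [
        ("pct_emergency_of_all", "Emergency CS/all deliveries"),
        ("pct_emergency_of_tol", "Emergency CS/trial of labor"),
        ("pct_emergency_of_cs", "Emergency CS/all CS"),
        ("pct_reduction_emergency", "% reduction emergency CS"),
        ("pct_reduction_emergency_cpd", "% reduction emergency CS CPD-related"),
        ("pct_cs_of_all", "All CS/all deliveries"),
        ("pct_scheduled_of_all", "Scheduled CS/all deliveries"),
    ]

    def to_frame(self) -> pd.DataFrame:
        cols = {"Observed": self.observed}
        cols.update({f"t{p.threshold}": p for p in self.policies})
        rows = {}
        for attr, label in self._COUNT_ROWS + self._PCT_ROWS:
            rows[label] = [getattr(p, attr) for p in cols.values()]
        return pd.DataFrame(rows, index=list(cols.keys())).T

    def to_json(self) -> str:
        return json.dumps(
            {
                "observed": asdict(self.observed),
                "policies": [asdict(p) for p in self.policies],
            },
            indent=2,
        )


def sensitivity_table(
    joint_by_score: JointTable, observed_scheduled_count: int
) -> SensitivityTable:
    """Full threshold sweep (t = 1..8) plus the observed-allocation column.

    ``observed_scheduled_count`` must equal the table's scheduled-CS column
    sum; the observed row uses the actual allocation rather than any rule.
    """
    if joint_by_score.axis != "by_score":
        raise ValueError("sensitivity_table requires a by_score joint table")
    counts = joint_by_score.counts
    table_scheduled = int(counts[:, _I_SCHED].sum())
    if observed_scheduled_count != table_scheduled:
        raise ValueError(
            f"observed scheduled-CS count {observed_scheduled_count} inconsistent "
            f"with table column sum {table_scheduled}"
        )
    n_total = joint_by_score.n_total
    observed_emer_cpd = int(counts[:, _I_EMER_CPD].sum())
    observed_emer = observed_emer_cpd + int(counts[:, _I_EMER_OTH].sum())
    observed = _make_result(
        None,
        n_total,
        n_total - observed_scheduled_count,
        observed_scheduled_count,
        observed_emer,
        observed_emer_cpd,
        observed_emer,
        observed_emer_cpd,
    )
    policies = tuple(apply_policy(joint_by_score, t) for t in range(1, 9))
    return SensitivityTable(observed=observed, policies=policies)
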