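"""Domain types for delivery cohorts and score/pelvimetry classification rules.

A cohort is a collection of delivery records, each carrying a simulated
trial-of-labor (STOL) score (integer 1-8, higher = greater predicted risk of
cephalopelvic disproportion), optional pelvimetric measurements (the Magnin
index is the obstetric conjugate plus the median transverse diameter, in cm),
and the observed delivery outcome in six classes.  Contingency tables of
score (or score category) against outcome drive every downstream analysis.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "DeliveryOutcome",
    "StolCategory",
    "MagninClass",
    "PatientRecord",
    "Cohort",
    "JointTable",
    "compute_magnin",
    "classify_magnin",
    "categorize_stol",
    "joint_from_cohort",
    "counts_from_percent",
    "score_marginals_from_cumulative",
    "read_cohort_csv",
    "write_cohort_csv",
]


class DeliveryOutcome(enum.Enum):
    """Observed delivery route, in the column order of the joint table.

    Instrumental deliveries and emergency cesareans are flagged as related
    (``_CPD``) or unrelated (``_OTHER``) to cephalopelvic disproportion.
    """

    SCHEDULED_CS = "SCHEDULED_CS"
    NORMAL = "NORMAL"
    INSTRUMENTAL_CPD = "INSTRUMENTAL_CPD"
    INSTRUMENTAL_OTHER = "INSTRUMENTAL_OTHER"
    EMERGENCY_CS_CPD = "EMERGENCY_CS_CPD"
    EMERGENCY_CS_OTHER = "EMERGENCY_CS_OTHER"

    @property
    def is_cpd_related(self) -> bool:
        return self in (DeliveryOutcome.INSTRUMENTAL_CPD, DeliveryOutcome.EMERGENCY_CS_CPD)

    @property
    def is_vaginal(self) -> bool:
        return self in (
            DeliveryOutcome.NORMAL,
            DeliveryOutcome.INSTRUMENTAL_CPD,
            DeliveryOutcome.INSTRUMENTAL_OTHER,
        )

    @property
    def is_emergency_cs(self) -> bool:
        return self in (DeliveryOutcome.EMERGENCY_CS_CPD, DeliveryOutcome.EMERGENCY_CS_OTHER)


OUTCOME_ORDER: tuple[DeliveryOutcome, ...] = tuple(DeliveryOutcome)
OUTCOME_INDEX = {o: i for i, o in enumerate(OUTCOME_ORDER)}


class StolCategory(enum.Enum):
    """Clinical grouping of STOL scores: 1-3 favorable, 4-6 neutral, 7-8 unfavorable."""

    FAVORABLE = "FAVORABLE"
    NEUTRAL = "NEUTRAL"
    UNFAVORABLE = "UNFAVORABLE"


CATEGORY_ORDER: tuple[StolCategory, ...] = tuple(StolCategory)
CATEGORY_SCORES = {
    StolCategory.FAVORABLE: (1, 2, 3),
    StolCategory.NEUTRAL: (4, 5, 6),
    StolCategory.UNFAVORABLE: (7, 8),
}


class MagninClass(enum.Enum):
    """Classical pelvimetric prognosis classes of the Magnin index (cm)."""

    NORMAL = "NORMAL"            # > 23
    FAVORABLE = "FAVORABLE"      # (22, 23]
    UNCERTAIN = "UNCERTAIN"      # [21, 22]
    POOR = "POOR"                # [20, 21)
    VERY_POOR = "VERY_POOR"      # < 20


def compute_magnin(conjugate_cm: float, transverse_cm: float) -> float:
    """Magnin index: obstetric conjugate plus median transverse diameter (cm)."""
    if not (conjugate_cm > 0 and transverse_cm > 0):
        raise ValueError(
            f"pelvic diameters must be positive, got conjugate={conjugate_cm}, "
            f"transverse={transverse_cm}"
        )
    return conjugate_cm + transverse_cm


def classify_magnin(magnin_cm: float) -> MagninClass:
    """Map a Magnin index to its prognosis class.

    Boundaries are taken half-open with the higher class given priority where
    the conventional verbal thresholds overlap: > 23 normal, (22, 23]
    favorable, [21, 22] uncertain, [20, 21) poor, < 20 very poor.
    """
    if not magnin_cm > 0:
        raise ValueError(f"Magnin index must be positive, got {magnin_cm}")
    if magnin_cm > 23:
        return MagninClass.NORMAL
    if magnin_cm > 22:
        return MagninClass.FAVORABLE
    if magnin_cm >= 21:
        return MagninClass.UNCERTAIN
    if magnin_cm >= 20:
        return MagninClass.POOR
    return MagninClass.VERY_POOR


def categorize_stol(score: int) -> StolCategory:
    """Group a STOL score into favorable (1-3), neutral (4-6) or unfavorable (7-8)."""
    if not isinstance(score, (int, np.integer)) or isinstance(score, bool):
        raise ValueError(f"STOL score must be an integer, got {score!r}")
    if not 1 <= score <= 8:
        raise ValueError(f"STOL score must be in 1..8, got {score}")
    if score <= 3:
        return StolCategory.FAVORABLE
    if score <= 6:
        return StolCategory.NEUTRAL
    return StolCategory.UNFAVORABLE


@dataclass(frozen=True)
class PatientRecord:
    """One delivery: STOL score, pelvimetry, and the observed outcome."""

    stol: int
    outcome: DeliveryOutcome
    magnin_cm: Optional[float] = None
    conjugate_cm: Optional[float] = None
    transverse_cm: Optional[float] = None
    bisciatic_cm: Optional[float] = None
    biparietal_cm: Optional[float] = None

    def __post_init__(self) -> None:
        categorize_stol(self.stol)  # validates 1..8 integral
        if not isinstance(self.outcome, DeliveryOutcome):
            raise ValueError(f"outcome must be a DeliveryOutcome, got {self.outcome!r}")
        for name in ("magnin_cm", "conjugate_cm", "transverse_cm", "bisciatic_cm", "biparietal_cm"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if (
            self.magnin_cm is not None
            and self.conjugate_cm is not None
            and self.transverse_cm is not None
        ):
            if abs(self.magnin_cm - (self.conjugate_cm + self.transverse_cm)) > 0.05:
                raise ValueError(
                    "magnin_cm inconsistent with conjugate + transverse: "
                    f"{self.magnin_cm} vs {self.conjugate_cm + self.transverse_cm}"
                )

    @property
    def category(self) -> StolCategory:
        return categorize_stol(self.stol)


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of delivery records with a provenance tag."""

    records: tuple[PatientRecord, ...]
    provenance: str = "observed"

    _PROVENANCES = ("observed", "reconstructed", "synthetic")

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if self.provenance not in self._PROVENANCES:
            raise ValueError(
                f"provenance must be one of {self._PROVENANCES}, got {self.provenance!r}"
            )

    @property
    def n(self) -> int:
        return len(self.records)

    def stol_scores(self) -> np.ndarray:
        return np.array([r.stol for r in self.records], dtype=int)

    def outcomes(self) -> list[DeliveryOutcome]:
        return [r.outcome for r in self.records]

    def magnin(self) -> np.ndarray:
        """Magnin indices as a float array (NaN where missing)."""
        return np.array(
            [r.magnin_cm if r.magnin_cm is not None else np.nan for r in self.records]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stol": [r.stol for r in self.records],
                "magnin_cm": [r.magnin_cm for r in self.records],
                "conjugate_cm": [r.conjugate_cm for r in self.records],
                "transverse_cm": [r.transverse_cm for r in self.records],
                "bisciatic_cm": [r.bisciatic_cm for r in self.records],
                "biparietal_cm": [r.biparietal_cm for r in self.records],
                "outcome": [r.outcome.name for r in self.records],
            }
        )


@dataclass(frozen=True)
class JointTable:
    """Integer counts of STOL score (or category) by delivery outcome.

    ``axis`` is ``"by_score"`` (8 rows, scores 1..8) or ``"by_category"``
    (3 rows, favorable/neutral/unfavorable).  Columns follow
    ``OUTCOME_ORDER``.
    """

    axis: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[1] != len(OUTCOME_ORDER):
            raise ValueError(f"counts must be (rows, 6), got shape {counts.shape}")
        expected_rows = {"by_score": 8, "by_category": 3}
        if self.axis not in expected_rows:
            raise ValueError(f"axis must be 'by_score' or 'by_category', got {self.axis!r}")
        if counts.shape[0] != expected_rows[self.axis]:
            raise ValueError(
                f"axis {self.axis!r} requires {expected_rows[self.axis]} rows, "
                f"got {counts.shape[0]}"
            )
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ValueError("counts must be non-negative integers")
            counts = counts.astype(int)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(int))

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_labels(self) -> list[str]:
        if self.axis == "by_score":
            return [str(s) for s in range(1, 9)]
        return [c.name for c in CATEGORY_ORDER]

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def outcome_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def by_category(self) -> "JointTable":
        """Aggregate a by-score table through the STOL category grouping."""
        if self.axis == "by_category":
            return self
        out = np.zeros((3, len(OUTCOME_ORDER)), dtype=int)
        for s in range(1, 9):
            cat = categorize_stol(s)
            out[CATEGORY_ORDER.index(cat)] += self.counts[s - 1]
        return JointTable(axis="by_category", counts=out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.row_labels, columns=[o.name for o in OUTCOME_ORDER]
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "axis": self.axis,
                "rows": self.row_labels,
                "outcomes": [o.name for o in OUTCOME_ORDER],
                "counts": self.counts.tolist(),
                "n_total": self.n_total,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "JointTable":
        obj = json.loads(text)
        table = cls(axis=obj["axis"], counts=np.array(obj["counts"], dtype=int))
        if table.n_total != obj["n_total"]:
            raise ValueError("n_total in JSON inconsistent with counts")
        return table


def joint_from_cohort(cohort: Cohort, axis: str = "by_score") -> JointTable:
    """Tabulate a cohort into a score-by-outcome (or category-by-outcome) table."""
    if cohort.n == 0:
        raise ValueError("cannot tabulate an empty cohort")
    counts = np.zeros((8, len(OUTCOME_ORDER)), dtype=int)
    for r in cohort.records:
        counts[r.stol - 1, OUTCOME_INDEX[r.outcome]] += 1
    table = JointTable(axis="by_score", counts=counts)
    if axis == "by_category":
        return table.by_category()
    if axis != "by_score":
        raise ValueError(f"axis must be 'by_score' or 'by_category', got {axis!r}")
    return table


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def counts_from_percent(
    percent_cells: Union[float, Sequence, np.ndarray],
    n_total: int,
    rounding: str = "half_away",
):
    """Convert printed percentages of ``n_total`` back to integer counts.

    Cells are rounded half away from zero by default, the rule under which
    the reference category-by-outcome table is internally consistent.
    Returns an integer scalar for scalar input, otherwise an integer array.
    """
    if n_total <= 0:
        raise ValueError(f"n_total must be positive, got {n_total}")
    if rounding != "half_away":
        raise ValueError(f"unknown rounding rule {rounding!r}")
    pct = np.asarray(percent_cells, dtype=float)
    if np.any(pct < 0):
        raise ValueError("percentages must be non-negative")
    counts = _round_half_away(pct / 100.0 * n_total).astype(int)
    if counts.ndim == 0:
        return int(counts)
    return counts


def score_marginals_from_cumulative(
    cumulative_tol_counts: Sequence[int], n_total: int
) -> np.ndarray:
    """Recover per-score counts from cumulative below-threshold counts.

    ``cumulative_tol_counts[t-1]`` is the number of patients with score < t,
    for thresholds t = 1..8; the count at score 8 is the remainder to
    ``n_total``.
    """
    cum = np.asarray(cumulative_tol_counts, dtype=int)
    if cum.shape != (8,):
        raise ValueError(f"expected 8 cumulative counts, got shape {cum.shape}")
    if np.any(np.diff(cum) < 0):
        raise ValueError("cumulative counts must be non-decreasing")
    if np.any(cum > n_total) or np.any(cum < 0):
        raise ValueError("cumulative counts must lie in [0, n_total]")
    per_score = np.empty(8, dtype=int)
    per_score[:7] = np.diff(cum)
    per_score[7] = n_total - cum[7]
    return per_score


_CSV_COLUMNS = ["stol", "magnin_cm", "outcome"]
_OPTIONAL_COLUMNS = ["conjugate_cm", "transverse_cm", "bisciatic_cm", "biparietal_cm"]


def write_cohort_csv(cohort: Cohort, path: Union[str, Path]) -> None:
    """Write a cohort to CSV (UTF-8, comma-separated, header, one record per row)."""
    df = cohort.to_frame()
    # drop optional columns that are entirely absent to keep files minimal
    for col in _OPTIONAL_COLUMNS:
        if df[col].isna().all():
            df = df.drop(columns=col)
    df.to_csv(path, index=False, lineterminator="\n")


def read_cohort_csv(path: Union[str, Path], provenance: str = "observed") -> Cohort:
    """Read a cohort CSV written by :func:`write_cohort_csv` (or hand-made)."""
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing required columns: {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            outcome_token = str(row["outcome"])
            try:
                outcome = DeliveryOutcome[outcome_token]
            except KeyError:
                raise ValueError(f"unknown outcome token {outcome_token!r}")
            kwargs = {}
            for col in _OPTIONAL_COLUMNS + ["magnin_cm"]:
                if col in df.columns and pd.notna(row[col]):
                    kwargs[col] = float(row[col])
            stol_raw = row["stol"]
            stol = int(stol_raw)
            if stol != stol_raw:
                raise ValueError(f"non-integer STOL score {stol_raw!r}")
            records.append(PatientRecord(stol=stol, outcome=outcome, **kwargs))
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    return Cohort(records=tuple(records), provenance=provenance)
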