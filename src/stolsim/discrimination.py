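"""Discrimination analysis: successful vs failed trial of labor.

A trial of labor (TOL) is *successful* when it ends in any vaginal delivery
and *failed* when it ends in an emergency cesarean; scheduled cesareans never
labored and are always excluded.  Optionally, emergency cesareans unrelated to
cephalopelvic disproportion are excluded as well, focusing the comparison on
the mechanical failure the scores are meant to predict.

ROC curves are built over the score thresholds (operating points at midpoints
between distinct score values), summarised by AUC, Youden's J, and the
Matthews correlation coefficient (phi) at the Youden-optimal threshold, and the
STOL score is compared against the Magnin index by a case-resampling bootstrap
of refitted univariate logistic models.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, DeliveryOutcome
from .models import FitResult, MultinomialLogit, fit_outcome_model, _design_from_cohort

__all__ = [
    "TrialLabel",
    "label_trial",
    "trial_data",
    "RocCurve",
    "RocSummary",
    "roc_curve",
    "roc_summary",
    "MulticlassRoc",
    "multiclass_roc",
    "fit_tol_model",
    "BootstrapComparison",
    "MetricComparison",
    "bootstrap_roc_compare",
]


class TrialLabel(enum.Enum):
    SUCCESS = "SUCCESS"
    FAILURE = "FAILURE"
    EXCLUDED = "EXCLUDED"


def label_trial(outcome: DeliveryOutcome, exclude_non_cpd: bool = False) -> TrialLabel:
    """Label a delivery outcome as a successful/failed trial of labor.

    Any vaginal delivery is a success; any emergency cesarean is a failure;
    scheduled cesareans are excluded (no labor was attempted).  With
    ``exclude_non_cpd``, emergency cesareans unrelated to cephalopelvic
    disproportion are excluded too.
    """
    if outcome is DeliveryOutcome.SCHEDULED_CS:
        return TrialLabel.EXCLUDED
    if outcome.is_vaginal:
        return TrialLabel.SUCCESS
    if outcome is DeliveryOutcome.EMERGENCY_CS_OTHER and exclude_non_cpd:
        return TrialLabel.EXCLUDED
    return TrialLabel.FAILURE


def trial_data(
    cohort: Cohort, exclude_non_cpd: bool = False, require_magnin: bool = False
):
    """Scores and failure indicators for the included (labored) records.

    Returns ``(stol, magnin, failure)`` arrays over records not excluded.
    """
    labels = [label_trial(r.outcome, exclude_non_cpd) for r in cohort.records]
    keep = [i for i, lab in enumerate(labels) if lab is not TrialLabel.EXCLUDED]
    stol = np.array([cohort.records[i].stol for i in keep], dtype=float)
    magnin = np.array(
        [
            cohort.records[i].magnin_cm if cohort.records[i].magnin_cm is not None else np.nan
            for i in keep
        ]
    )
    failure = np.array([labels[i] is TrialLabel.FAILURE for i in keep])
    if require_magnin and np.any(np.isnan(magnin)):
        raise ValueError("Magnin index required for every included record")
    return stol, magnin, failure


@dataclass(frozen=True)
class RocCurve:
    """Operating points (threshold-descending) of a binary failure classifier.

    ``orientation`` records which direction of the score indicates failure;
    thresholds are on the oriented scale (score negated for ``lower_fails``).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    orientation: str


def _orient(scores: np.ndarray, orientation: str) -> np.ndarray:
    if orientation == "higher_fails":
        return scores
    if orientation == "lower_fails":
        return -scores
    raise ValueError(f"orientation must be 'higher_fails' or 'lower_fails', got {orientation!r}")


def roc_curve(
    scores: Sequence[float], labels: Sequence[bool], orientation: str = "higher_fails"
) -> RocCurve:
    """ROC curve of a score against failure labels.

    One operating point per distinct score value ("predict failure when the
    oriented score >= threshold", thresholds at midpoints between adjacent
    distinct values) plus the all-negative endpoint.  AUC by the trapezoid
    rule, which equals the tie-corrected Mann-Whitney probability.
    """
    s = _orient(np.asarray(scores, dtype=float), orientation)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one failure and one success")
    values = np.unique(s)[::-1]  # descending
    pos_at = np.array([(y & (s == v)).sum() for v in values], dtype=float)
    neg_at = np.array([(~y & (s == v)).sum() for v in values], dtype=float)
    tp = np.concatenate([[0.0], np.cumsum(pos_at)])
    fp = np.concatenate([[0.0], np.cumsum(neg_at)])
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg
    mids = np.empty(len(values) + 1)
    mids[0] = values[0] + 1.0  # above everything: nobody predicted to fail
    mids[1:-1] = (values[:-1] + values[1:]) / 2.0
    mids[-1] = values[-1] - 1.0  # below everything: everyone predicted to fail
    auc = float(np.trapezoid(sens, 1.0 - spec))
    return RocCurve(
        thresholds=mids, sensitivity=sens, specificity=spec, auc=auc, orientation=orientation
    )


@dataclass(frozen=True)
class RocSummary:
    auc: float
    youden_j: float
    j_threshold: float
    mcc_at_j: float


def _mcc(tp: float, fp: float, fn: float, tn: float) -> float:
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def roc_summary(
    roc: RocCurve, scores: Sequence[float], labels: Sequence[bool]
) -> RocSummary:
    """Youden's J (max sens + spec - 1) and the phi/Matthews coefficient of the
    2x2 confusion table at the Youden-optimal threshold."""
    j_all = roc.sensitivity + roc.specificity - 1.0
    idx = int(np.argmax(j_all))
    j = float(j_all[idx])
    thr = float(roc.thresholds[idx])
    s = _orient(np.asarray(scores, dtype=float), roc.orientation)
    y = np.asarray(labels, dtype=bool)
    pred = s >= thr
    tp = float((pred & y).sum())
    fp = float((pred & ~y).sum())
    fn = float((~pred & y).sum())
    tn = float((~pred & ~y).sum())
    return RocSummary(auc=roc.auc, youden_j=j, j_threshold=thr, mcc_at_j=_mcc(tp, fp, fn, tn))


@dataclass(frozen=True)
class MulticlassRoc:
    """One-vs-rest ROC analysis of a fitted multinomial model."""

    per_class: dict  # class -> RocCurve or None when the class is absent
    micro_auc: float
    macro_auc: float
    skipped: tuple


def multiclass_roc(
    fitted_probabilities: np.ndarray, outcomes: Sequence, class_order: Sequence
) -> MulticlassRoc:
    """Micro- and macro-averaged one-vs-rest ROC over outcome classes.

    The macro average is the unweighted mean of per-class AUCs (absent
    classes are skipped with a warning); the micro average pools all
    (probability, indicator) pairs before building one curve.
    """
    P = np.asarray(fitted_probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=object)
    if P.ndim != 2 or P.shape[1] != len(class_order):
        raise ValueError("probability matrix must be (n, n_classes)")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("probability rows must sum to 1")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two outcome levels")
    per_class = {}
    aucs = []
    skipped = []
    for j, cls in enumerate(class_order):
        indicator = y == cls
        if indicator.all() or not indicator.any():
            warnings.warn(
                f"class {cls!r} absent (or exhaustive); excluded from the macro average",
                stacklevel=2,
            )
            per_class[cls] = None
            skipped.append(cls)
            continue
        curve = roc_curve(P[:, j], indicator, orientation="higher_fails")
        per_class[cls] = curve
        aucs.append(curve.auc)
    if not aucs:
        raise ValueError("no class had both positive and negative instances")
    micro = roc_curve(
        P.reshape(-1),
        np.column_stack([y == cls for cls in class_order]).reshape(-1),
        orientation="higher_fails",
    )
    return MulticlassRoc(
        per_class=per_class,
        micro_auc=micro.auc,
        macro_auc=float(np.mean(aucs)),
        skipped=tuple(skipped),
    )


# ---------------------------------------------------------------------------
# Binomial trial-of-labor models (used for AICc ranking and the bootstrap)


def fit_tol_model(
    cohort: Cohort, predictor: str = "score", exclude_non_cpd: bool = False
) -> FitResult:
    """Binomial logistic model of failed TOL on the chosen predictor.

    Scheduled cesareans (and optionally non-CPD emergency cesareans) are
    excluded before fitting; the reference level is SUCCESS so coefficients
    describe the log-odds of failure.
    """
    labels = [label_trial(r.outcome, exclude_non_cpd) for r in cohort.records]
    keep = tuple(
        r for r, lab in zip(cohort.records, labels) if lab is not TrialLabel.EXCLUDED
    )
    sub = Cohort(records=keep, provenance=cohort.provenance)
    y = np.array(
        [
            label_trial(r.outcome, exclude_non_cpd).value
            for r in keep
        ],
        dtype=object,
    )
    if len(set(y)) < 2:
        raise ValueError("included records contain a single trial label")
    X, names = _design_from_cohort(sub, predictor)
    model = MultinomialLogit(reference=TrialLabel.SUCCESS.value).fit(X, y)
    design_columns = ("intercept",) + names
    nonref = [c for c in model.classes_ if c != model.reference_]
    coef = pd.DataFrame(model.coef_, index=nonref, columns=list(design_columns))
    return FitResult(
        predictor=predictor,
        model=model,
        classes=tuple(model.classes_),
        reference=model.reference_,
        design_columns=design_columns,
        coef=coef,
        log_likelihood=model.loglik_,
        n_obs=int(model.n_obs_),
        k_params=model.k_params_,
        fitted=model.predict_proba(X),
        y=y,
        X=X,
    )


# ---------------------------------------------------------------------------
# Bootstrap comparison of STOL vs Magnin discrimination


@dataclass(frozen=True)
class MetricComparison:
    metric: str
    stol: float
    magnin: float
    diff: float
    ci_low: float
    ci_high: float
    offset_plus: float
    offset_minus: float
    excludes_zero: bool

    def formatted(self) -> str:
        return (
            f"{self.metric}: {self.diff:+.3f} "
            f"+{self.offset_plus:.3f}/−{self.offset_minus:.3f} CI"
        )


@dataclass(frozen=True)
class BootstrapComparison:
    B: int
    seed: int
    n_redraws: int
    metrics: dict  # name -> MetricComparison

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(m) for m in self.metrics.values()]).set_index("metric")


def _logit_metrics(x: np.ndarray, failure: np.ndarray) -> tuple[float, float, float]:
    """AUC / Youden J / MCC of a refitted univariate logistic failure model."""
    model = MultinomialLogit(reference="ok").fit(
        x[:, None], np.where(failure, "fail", "ok").astype(object)
    )
    p_fail = model.predict_proba(x[:, None])[:, list(model.classes_).index("fail")]
    curve = roc_curve(p_fail, failure, orientation="higher_fails")
    summ = roc_summary(curve, p_fail, failure)
    return summ.auc, summ.youden_j, summ.mcc_at_j


def bootstrap_roc_compare(
    cohort: Cohort,
    exclude_non_cpd: bool = False,
    B: int = 2000,
    seed: Optional[int] = None,
    max_redraw_factor: int = 100,
) -> BootstrapComparison:
    """Bootstrap comparison of STOL vs Magnin failed-TOL discrimination.

    Per resample, both univariate logistic models are refitted and AUC,
    Youden's J and the MCC at the Youden threshold recomputed; reported are
    percentile CIs of the STOL-minus-Magnin differences with asymmetric
    (+upper/-lower) offsets from the point difference.  Resamples with a
    single outcome class are redrawn.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if seed is None:
        raise ValueError("bootstrap_roc_compare requires an explicit seed")
    stol, magnin, failure = trial_data(cohort, exclude_non_cpd, require_magnin=True)
    n = len(failure)
    if failure.all() or not failure.any():
        raise ValueError("included records contain a single trial label")

    point = {}
    for name, x in (("stol", stol), ("magnin", magnin)):
        point[name] = _logit_metrics(x, failure)

    rng = np.random.default_rng(seed)
    diffs = {"auc": np.empty(B), "youden_j": np.empty(B), "mcc": np.empty(B)}
    redraws = 0
    for b in range(B):
        for _ in range(max_redraw_factor):
            idx = rng.integers(0, n, size=n)
            f = failure[idx]
            if f.any() and not f.all():
                break
            redraws += 1
        else:
            raise RuntimeError("could not draw a two-class resample")
        ms = _logit_metrics(stol[idx], f)
        mm = _logit_metrics(magnin[idx], f)
        for k, name in enumerate(("auc", "youden_j", "mcc")):
            diffs[name][b] = ms[k] - mm[k]

    metrics = {}
    for k, name in enumerate(("auc", "youden_j", "mcc")):
        d0 = point["stol"][k] - point["magnin"][k]
        lo, hi = np.percentile(diffs[name], [2.5, 97.5])
        metrics[name] = MetricComparison(
            metric=name,
            stol=point["stol"][k],
            magnin=point["magnin"][k],
            diff=float(d0),
            ci_low=float(lo),
            ci_high=float(hi),
            offset_plus=float(hi - d0),
            offset_minus=float(d0 - lo),
            excludes_zero=not (lo <= 0.0 <= hi),
        )
    return BootstrapComparison(B=B, seed=seed, n_redraws=redraws, metrics=metrics)
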