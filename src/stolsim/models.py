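"""Multinomial outcome models and the inference built on them.

The central object is :class:`MultinomialLogit`, a maximum-likelihood
multinomial logistic regression fitted by Newton-Raphson on the full
observed-information matrix, with coefficients expressed relative to a
reference outcome (here conventionally NORMAL delivery, the most frequent
outcome).  On top of it sit likelihood-ratio tests, the McFadden/Nagelkerke/
count pseudo-R² trio, Tukey-adjusted marginal means, bootstrap comparison of
per-outcome slopes, small-sample AIC (AICc) Akaike weights, and the
Kruskal-Wallis rank test.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .cohort import Cohort, DeliveryOutcome, OUTCOME_ORDER, StolCategory

__all__ = [
    "MultinomialLogit",
    "FitResult",
    "TestResult",
    "PseudoR2",
    "ModelComparison",
    "MarginalMeansResult",
    "SlopeComparison",
    "fit_outcome_model",
    "lr_test",
    "pseudo_r2",
    "aicc_weights",
    "marginal_means_tukey",
    "slope_bootstrap",
    "kruskal_wallis",
]


class ConvergenceError(RuntimeError):
    """Newton iteration failed to reach the gradient tolerance."""


class MultinomialLogit(BaseEstimator):
    """Multinomial logistic regression by Newton-Raphson maximum likelihood.

    Parameters
    ----------
    reference : label, optional
        Outcome level whose coefficients are pinned at zero.  Defaults to the
        most frequent level.
    fit_intercept : bool
        Prepend an intercept column to the design.
    tol : float
        Convergence when the maximum absolute score (gradient) entry falls
        below this value.
    max_iter : int
        Newton iteration cap.
    ridge : float
        Optional L2 penalty on all coefficients.  When the unpenalized fit
        diverges (complete separation), the model is refitted with a small
        ridge and a warning is emitted.

    Attributes
    ----------
    classes_ : ndarray of outcome levels in prediction-column order.
    reference_ : the resolved reference level.
    coef_ : ndarray (n_classes - 1, n_features [+1]) relative to the reference,
        rows in the order of ``classes_`` with the reference omitted.
    loglik_ : unpenalized log-likelihood at the optimum.
    cov_params_ : inverse observed information of the stacked coefficients.
    n_iter_ : Newton iterations used.
    converged_ : whether the gradient tolerance was met.
    """

    def __init__(
        self,
        reference=None,
        fit_intercept: bool = True,
        tol: float = 1e-8,
        max_iter: int = 200,
        ridge: float = 0.0,
    ):
        self.reference = reference
        self.fit_intercept = fit_intercept
        self.tol = tol
        self.max_iter = max_iter
        self.ridge = ridge

    # -- internals ---------------------------------------------------------
    def _design(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.fit_intercept:
            X = np.hstack([np.ones((X.shape[0], 1)), X])
        return X

    @staticmethod
    def _probs(Xb: np.ndarray, B: np.ndarray) -> np.ndarray:
        """Softmax probabilities; last (reference) class has linear predictor 0."""
        eta = Xb @ B.T
        eta = np.hstack([eta, np.zeros((eta.shape[0], 1))])
        eta -= eta.max(axis=1, keepdims=True)
        expeta = np.exp(eta)
        return expeta / expeta.sum(axis=1, keepdims=True)

    def _newton(self, Xb, Y, w, ridge):
        n, p = Xb.shape
        J = Y.shape[1]
        B = np.zeros((J - 1, p))
        ll_prev = -np.inf
        for it in range(1, self.max_iter + 1):
            P = self._probs(Xb, B)
            ll = float(np.sum(w[:, None] * Y * np.log(np.clip(P, 1e-300, None))))
            ll_pen = ll - 0.5 * ridge * np.sum(B**2)
            grad = (Xb * w[:, None]).T @ (Y[:, :-1] - P[:, :-1])  # (p, J-1)
            grad = grad.T.reshape(-1) - ridge * B.reshape(-1)
            if np.max(np.abs(grad)) < self.tol:
                return B, ll, it, True
            H = self._hessian(Xb, P, w)
            if ridge:
                H = H + ridge * np.eye(H.shape[0])
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            # step-halving line search on the (penalized) likelihood
            scale = 1.0
            for _ in range(30):
                B_new = B + scale * step.reshape(J - 1, p)
                P_new = self._probs(Xb, B_new)
                ll_new = float(
                    np.sum(w[:, None] * Y * np.log(np.clip(P_new, 1e-300, None)))
                )
                if ll_new - 0.5 * ridge * np.sum(B_new**2) >= ll_pen - 1e-12:
                    break
                scale *= 0.5
            B = B + scale * step.reshape(J - 1, p)
            ll_prev = ll
        P = self._probs(Xb, B)
        ll = float(np.sum(w[:, None] * Y * np.log(np.clip(P, 1e-300, None))))
        return B, ll, self.max_iter, False

    @staticmethod
    def _hessian(Xb, P, w):
        """Observed information of the stacked (class-major) coefficients."""
        n, p = Xb.shape
        Jm1 = P.shape[1] - 1
        H = np.empty((Jm1 * p, Jm1 * p))
        for j in range(Jm1):
            for k in range(j, Jm1):
                wjk = w * P[:, j] * ((j == k) - P[:, k])
                block = Xb.T @ (wjk[:, None] * Xb)
                H[j * p : (j + 1) * p, k * p : (k + 1) * p] = block
                if k != j:
                    H[k * p : (k + 1) * p, j * p : (j + 1) * p] = block.T
        return H

    # -- sklearn surface ---------------------------------------------------
    def fit(self, X, y, sample_weight=None):
        Xb = self._design(X)
        y = np.asarray(y)
        n = Xb.shape[0]
        if y.shape[0] != n:
            raise ValueError("X and y length mismatch")
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("need at least two outcome levels to fit")
        if self.reference is not None:
            if self.reference not in classes:
                raise ValueError(f"reference level {self.reference!r} not present in y")
            reference = self.reference
        else:
            totals = [w[y == c].sum() for c in classes]
            reference = classes[int(np.argmax(totals))]
        nonref = [c for c in classes if c != reference]
        order = nonref + [reference]
        Y = np.column_stack([(y == c).astype(float) for c in order])

        if np.linalg.matrix_rank(Xb) < Xb.shape[1]:
            raise ValueError("design matrix is rank deficient")

        B, ll, n_iter, ok = self._newton(Xb, Y, w, self.ridge)
        if not ok or np.max(np.abs(B)) > 30:
            if self.ridge == 0.0:
                warnings.warn(
                    "multinomial fit unstable (possible complete separation); "
                    "refitting with a small ridge penalty",
                    stacklevel=2,
                )
                B, ll, n_iter, ok = self._newton(Xb, Y, w, 1e-4)
            if not ok:
                raise ConvergenceError(
                    f"Newton did not converge in {self.max_iter} iterations "
                    f"(max |coef| = {np.max(np.abs(B)):.3g})"
                )

        self.classes_ = np.array(order, dtype=object)
        self.reference_ = reference
        self.coef_ = B
        self.loglik_ = ll
        self.n_iter_ = n_iter
        self.converged_ = ok
        self.n_obs_ = float(w.sum())
        self.k_params_ = B.size
        P = self._probs(Xb, B)
        H = self._hessian(Xb, P, w)
        try:
            self.cov_params_ = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            self.cov_params_ = np.linalg.pinv(H)
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        return self._probs(self._design(X), self.coef_)

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


# ---------------------------------------------------------------------------
# Domain-level fitting


PREDICTOR_SPECS = (
    "intercept",
    "category",
    "score",
    "magnin",
    "score+magnin",
    "score*magnin",
)


@dataclass(frozen=True)
class FitResult:
    """A fitted outcome model plus the bookkeeping the tests need."""

    predictor: str
    model: MultinomialLogit
    classes: tuple
    reference: str
    design_columns: tuple
    coef: pd.DataFrame
    log_likelihood: float
    n_obs: int
    k_params: int
    fitted: np.ndarray
    y: np.ndarray
    X: np.ndarray

    @property
    def data_fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(np.asarray(self.y).astype(str).tobytes())
        return h.hexdigest()


def _design_from_cohort(cohort: Cohort, predictor: str):
    scores = cohort.stol_scores().astype(float)
    if predictor == "intercept":
        return np.empty((cohort.n, 0)), ()
    if predictor == "category":
        cats = np.array([r.category for r in cohort.records])
        cols = []
        names = []
        for cat in (StolCategory.NEUTRAL, StolCategory.UNFAVORABLE):
            cols.append((cats == cat).astype(float))
            names.append(f"category[{cat.name}]")
        return np.column_stack(cols), tuple(names)
    if predictor == "score":
        return scores[:, None], ("stol",)
    magnin = cohort.magnin()
    if np.any(np.isnan(magnin)):
        raise ValueError(f"predictor {predictor!r} requires Magnin for every record")
    if predictor == "magnin":
        return magnin[:, None], ("magnin",)
    if predictor == "score+magnin":
        return np.column_stack([scores, magnin]), ("stol", "magnin")
    if predictor == "score*magnin":
        return (
            np.column_stack([scores, magnin, scores * magnin]),
            ("stol", "magnin", "stol:magnin"),
        )
    raise ValueError(f"unknown predictor spec {predictor!r}; choose from {PREDICTOR_SPECS}")


def fit_outcome_model(
    cohort: Cohort,
    predictor: str = "category",
    reference: str = DeliveryOutcome.NORMAL.name,
    **estimator_kwargs,
) -> FitResult:
    """Fit a multinomial model of delivery outcome on the chosen predictor."""
    if cohort.n == 0:
        raise ValueError("cannot fit on an empty cohort")
    X, names = _design_from_cohort(cohort, predictor)
    y = np.array([r.outcome.name for r in cohort.records], dtype=object)
    if reference is not None and reference not in set(y):
        reference = None  # fall back to most frequent
    model = MultinomialLogit(reference=reference, **estimator_kwargs).fit(X, y)
    design_columns = (("intercept",) if model.fit_intercept else ()) + names
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
# Inference on fitted models


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float


def _check_nested(full: FitResult, null: FitResult) -> None:
    if full.n_obs != null.n_obs or full.data_fingerprint != null.data_fingerprint:
        raise ValueError("models were fitted to different data")
    if not set(null.design_columns) <= set(full.design_columns):
        raise ValueError(
            f"null design {null.design_columns} is not nested in {full.design_columns}"
        )
    if full.k_params < null.k_params:
        raise ValueError("full model has fewer parameters than the null")


def lr_test(full_fit: FitResult, null_fit: FitResult) -> TestResult:
    """Likelihood-ratio chi-square test of nested multinomial models."""
    _check_nested(full_fit, null_fit)
    stat = 2.0 * (full_fit.log_likelihood - null_fit.log_likelihood)
    stat = max(stat, 0.0)
    df = full_fit.k_params - null_fit.k_params
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return TestResult(statistic=float(stat), df=int(df), p_value=p)


@dataclass(frozen=True)
class PseudoR2:
    mcfadden: float
    nagelkerke: float
    count: float


def pseudo_r2(full_fit: FitResult, null_fit: FitResult) -> PseudoR2:
    """McFadden, Nagelkerke and count (modal-prediction accuracy) pseudo-R²."""
    _check_nested(full_fit, null_fit)
    llf, lln, n = full_fit.log_likelihood, null_fit.log_likelihood, full_fit.n_obs
    if lln == 0.0:
        raise ValueError("null log-likelihood is zero (degenerate single-class data)")
    mcfadden = 1.0 - llf / lln
    cox_snell = 1.0 - np.exp(2.0 * (lln - llf) / n)
    max_cs = 1.0 - np.exp(2.0 * lln / n)
    nagelkerke = cox_snell / max_cs if max_cs > 0 else 0.0
    # count R²: a record scores only when its observed outcome is the unique
    # modal fitted outcome (ties count as incorrect)
    P = full_fit.fitted
    top = P.max(axis=1)
    is_tie = (np.abs(P - top[:, None]) < 1e-12).sum(axis=1) > 1
    modal = np.asarray(full_fit.classes, dtype=object)[np.argmax(P, axis=1)]
    correct = (modal == full_fit.y) & ~is_tie
    return PseudoR2(
        mcfadden=float(mcfadden),
        nagelkerke=float(nagelkerke),
        count=float(correct.mean()),
    )


@dataclass(frozen=True)
class ModelComparison:
    """AICc model ranking with Akaike weights (relative model probabilities)."""

    table: pd.DataFrame  # columns: name, loglik, k, n, aicc, delta_aicc, weight

    @property
    def weights(self) -> np.ndarray:
        return self.table["weight"].to_numpy()


def aicc(ll: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: n - k - 1 = {n - k - 1} <= 0")
    return -2.0 * ll + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def aicc_weights(fits: Sequence[FitResult], names: Optional[Sequence[str]] = None) -> ModelComparison:
    """Small-sample AIC comparison of models fitted to identical records."""
    if len(fits) < 2:
        raise ValueError("need at least two models to compare")
    fps = {f.data_fingerprint for f in fits}
    if len(fps) != 1:
        raise ValueError("all models must be fitted to identical records")
    if names is None:
        names = [f.predictor for f in fits]
    vals = np.array([aicc(f.log_likelihood, f.k_params, f.n_obs) for f in fits])
    delta = vals - vals.min()
    raw = np.exp(-delta / 2.0)
    weights = raw / raw.sum()
    table = pd.DataFrame(
        {
            "name": list(names),
            "loglik": [f.log_likelihood for f in fits],
            "k": [f.k_params for f in fits],
            "n": [f.n_obs for f in fits],
            "aicc": vals,
            "delta_aicc": delta,
            "weight": weights,
        }
    )
    return ModelComparison(table=table)


# ---------------------------------------------------------------------------
# Marginal means with Tukey-adjusted within-category comparisons


@dataclass(frozen=True)
class MarginalMeansResult:
    probabilities: pd.DataFrame  # categories x outcomes
    std_errors: pd.DataFrame
    pairwise_p: dict  # category -> outcomes x outcomes DataFrame of adjusted p
    letters: dict  # category -> {outcome: letter string}


def _tukey_sf(z: np.ndarray, k: int) -> np.ndarray:
    """Studentized-range adjusted p for |z| differences, infinite-df normal case."""
    q = np.abs(z) * np.sqrt(2.0)
    df = 1e7  # effectively infinite; multinomial MLE covariance is asymptotic
    return stats.studentized_range.sf(q, k, df)


def _letter_groups(order: list, sig: "pd.DataFrame") -> dict:
    """Compact letter display: maximal runs (in sorted order) with no
    significant pair inside share a letter."""
    m = len(order)
    intervals = []
    for i in range(m):
        j = i
        while j + 1 < m and not any(
            sig.loc[order[a], order[b]]
            for a in range(i, j + 2)
            for b in range(a + 1, j + 2)
        ):
            j += 1
        intervals.append((i, j))
    # keep only maximal intervals
    maximal = [
        (i, j)
        for (i, j) in intervals
        if not any((i2 <= i and j <= j2) and (i2, j2) != (i, j) for (i2, j2) in intervals)
    ]
    maximal = sorted(set(maximal))
    symbols = "abcdefghijklmnopqrstuvwxyz"
    letters = {o: "" for o in order}
    for idx, (i, j) in enumerate(maximal):
        for t in range(i, j + 1):
            letters[order[t]] += symbols[idx % len(symbols)]
    return letters


def marginal_means_tukey(categorical_fit: FitResult, alpha: float = 0.05) -> MarginalMeansResult:
    """Per-category outcome probabilities with delta-method standard errors and
    Tukey (studentized-range) adjusted within-category pairwise comparisons.

    Two outcomes that share a letter within a category do not differ
    significantly at ``alpha``.
    """
    if categorical_fit.predictor != "category":
        raise ValueError("marginal means require the categorical-STOL fit")
    model = categorical_fit.model
    cov = model.cov_params_
    if not np.all(np.isfinite(cov)):
        raise ValueError("singular information matrix; cannot form standard errors")
    classes = list(model.classes_)
    J = len(classes)
    p = len(categorical_fit.design_columns)

    cat_rows = {
        StolCategory.FAVORABLE: np.array([1.0, 0.0, 0.0]),
        StolCategory.NEUTRAL: np.array([1.0, 1.0, 0.0]),
        StolCategory.UNFAVORABLE: np.array([1.0, 0.0, 1.0]),
    }
    probs, ses, pairwise, letters = {}, {}, {}, {}
    for cat, x in cat_rows.items():
        eta = np.concatenate([model.coef_ @ x, [0.0]])
        expeta = np.exp(eta - eta.max())
        P = expeta / expeta.sum()
        # Jacobian of P wrt stacked coefficients (class-major, p per class)
        Jac = np.zeros((J, (J - 1) * p))
        for j in range(J):
            for k in range(J - 1):
                Jac[j, k * p : (k + 1) * p] = P[j] * ((j == k) - P[k]) * x
        cov_p = Jac @ cov @ Jac.T
        se = np.sqrt(np.clip(np.diag(cov_p), 0.0, None))
        probs[cat.name] = dict(zip(classes, P))
        ses[cat.name] = dict(zip(classes, se))
        padj = pd.DataFrame(np.ones((J, J)), index=classes, columns=classes)
        for a in range(J):
            for b in range(a + 1, J):
                var = cov_p[a, a] + cov_p[b, b] - 2 * cov_p[a, b]
                if var <= 0:
                    pv = 1.0
                else:
                    z = (P[a] - P[b]) / np.sqrt(var)
                    pv = float(_tukey_sf(np.array([z]), J)[0])
                padj.iloc[a, b] = padj.iloc[b, a] = pv
        pairwise[cat.name] = padj
        order = sorted(classes, key=lambda c: -P[classes.index(c)])
        sig = padj < alpha
        letters[cat.name] = _letter_groups(order, sig)

    idx = [c.name for c in cat_rows]
    prob_df = pd.DataFrame(probs).T.loc[idx, classes]
    se_df = pd.DataFrame(ses).T.loc[idx, classes]
    return MarginalMeansResult(
        probabilities=prob_df, std_errors=se_df, pairwise_p=pairwise, letters=letters
    )


# ---------------------------------------------------------------------------
# Bootstrap comparison of continuous-score slopes


@dataclass(frozen=True)
class SlopeComparison:
    """Per-outcome score slopes (linear-predictor scale, centered to mean 0)
    with percentile bootstrap CIs of all pairwise differences."""

    slopes: pd.Series
    pairwise: pd.DataFrame  # columns a, b, diff, ci_low, ci_high, excludes_zero
    groups: tuple
    B: int
    seed: int
    n_redraws: int


def _slope_vector(fit: FitResult) -> pd.Series:
    col = list(fit.design_columns).index("stol")
    raw = {c: 0.0 for c in fit.classes}
    nonref = [c for c in fit.classes if c != fit.reference]
    for i, c in enumerate(nonref):
        raw[c] = fit.model.coef_[i, col]
    s = pd.Series(raw)
    return s - s.mean()


def slope_bootstrap(
    cohort: Cohort,
    B: int = 2000,
    seed: Optional[int] = None,
    reference: str = DeliveryOutcome.NORMAL.name,
    max_redraw_factor: int = 100,
) -> SlopeComparison:
    """Case-resampling bootstrap of per-outcome slopes in the continuous-score model.

    Each resample refits the multinomial model; resamples missing an outcome
    level are redrawn (counted in ``n_redraws``).  Outcomes are partitioned
    into groups whose mutual slope-difference CIs contain zero (connected
    components of the non-significant-pair graph).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if seed is None:
        raise ValueError("slope_bootstrap requires an explicit seed")
    point = fit_outcome_model(cohort, predictor="score", reference=reference)
    classes = list(point.classes)
    levels_needed = set(classes)
    scores = cohort.stol_scores().astype(float)
    y = point.y
    rng = np.random.default_rng(seed)
    n = cohort.n
    boot = np.empty((B, len(classes)))
    redraws = 0
    for b in range(B):
        for _ in range(max_redraw_factor):
            idx = rng.integers(0, n, size=n)
            if set(y[idx]) == levels_needed:
                break
            redraws += 1
        else:
            raise RuntimeError("could not draw a resample containing all outcome levels")
        w = np.bincount(idx, minlength=n).astype(float)
        keep = w > 0
        m = MultinomialLogit(reference=reference).fit(
            scores[keep, None], y[keep], sample_weight=w[keep]
        )
        raw = {c: 0.0 for c in classes}
        nonref = [c for c in m.classes_ if c != m.reference_]
        for i, c in enumerate(nonref):
            raw[c] = m.coef_[i, 1]  # column 1 = score (0 is intercept)
        vec = np.array([raw[c] for c in classes])
        boot[b] = vec - vec.mean()

    slopes = _slope_vector(point)
    rows = []
    sig = {}
    for a in range(len(classes)):
        for bb in range(a + 1, len(classes)):
            diffs = boot[:, a] - boot[:, bb]
            lo, hi = np.percentile(diffs, [2.5, 97.5])
            excl = not (lo <= 0.0 <= hi)
            rows.append(
                {
                    "a": classes[a],
                    "b": classes[bb],
                    "diff": slopes[classes[a]] - slopes[classes[bb]],
                    "ci_low": lo,
                    "ci_high": hi,
                    "excludes_zero": excl,
                }
            )
            sig[(classes[a], classes[bb])] = excl
    pairwise = pd.DataFrame(rows)

    # connected components of the "difference CI contains zero" graph
    remaining = set(classes)
    groups = []
    while remaining:
        seed_node = max(remaining, key=lambda c: slopes[c])
        comp = {seed_node}
        frontier = [seed_node]
        while frontier:
            u = frontier.pop()
            for v in list(remaining - comp):
                key = (u, v) if (u, v) in sig else (v, u)
                if not sig[key]:
                    comp.add(v)
                    frontier.append(v)
        groups.append(tuple(sorted(comp, key=lambda c: -slopes[c])))
        remaining -= comp
    return SlopeComparison(
        slopes=slopes,
        pairwise=pairwise,
        groups=tuple(groups),
        B=B,
        seed=seed,
        n_redraws=redraws,
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis


def kruskal_wallis(values: Sequence[float], groups: Sequence) -> TestResult:
    """Tie-corrected Kruskal-Wallis H test of ``values`` across ``groups``."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("Kruskal-Wallis requires at least two groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    if np.all(values == values[0]):
        # fully tied data carry no rank information: H = 0 by convention
        return TestResult(statistic=0.0, df=len(levels) - 1, p_value=1.0)
    res = stats.kruskal(*samples)
    return TestResult(
        statistic=float(res.statistic), df=len(levels) - 1, p_value=float(res.pvalue)
    )
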