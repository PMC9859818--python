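# Methods

This document records the statistical model behind `stolsim`, the algebra
used to reconstruct the bundled reference cohort, the assumptions of the
synthetic generator, and the numerical conventions the implementation
commits to. Everything stated here is either a definition or a computed,
test-verified property of the code; no empirical claim is made that the
package does not itself compute.

## 1. Cohort model

A patient record carries:

- `stol` — integer STOL score in 1–8. Scores 1–3 form the *favorable*
  category, 4–6 *neutral*, 7–8 *unfavorable*.
- `outcome` — one of six delivery outcomes, in canonical column order:
  scheduled CS, normal vaginal, instrumental CPD-related, instrumental
  other, emergency CS CPD-related, emergency CS other.
- optional pelvimetry: obstetric conjugate, median transverse, bisciatic and
  biparietal diameters, and the Magnin index (conjugate + transverse, cm).
  When both diameters and a Magnin value are present they must agree within
  0.05 cm.

**Magnin classification** uses half-open intervals, closed where stated:
strictly above 23 cm is NORMAL; (22, 23] FAVORABLE; [21, 22] UNCERTAIN;
[20, 21) POOR; strictly below 20 VERY_POOR. The boundary convention (22 and
21 both fall in UNCERTAIN, 23 in FAVORABLE, 20 in POOR) is a package
convention fixed by test.

Joint tables are 8×6 (`by_score`) or 3×6 (`by_category`) integer count
matrices; a `by_score` table aggregates exactly to its `by_category`
counterpart.

## 2. Reconstruction of the reference cohort

The package bundles two reference summaries as code constants:

- a 3×6 table of outcome percentages within each STOL category, for a
  cohort of n = 401;
- cumulative counts by score threshold of trials of labor, emergency
  cesareans, and CPD-related emergency cesareans.

Reconstruction proceeds in three deterministic steps:

1. **Category × outcome counts.** Each percentage is multiplied by 401 and
   rounded half away from zero. This yields category margins (175, 101, 125)
   and outcome margins (87, 183, 37, 16, 52, 26) — 401 in total, 78
   emergency cesareans of which 52 CPD-related.
2. **Score margins.** First-differencing the cumulative trial-of-labor
   counts gives the number of patients per score,
   (93, 51, 31, 13, 35, 53, 24, 101); the same differencing applied to the
   emergency-CS cumulatives gives exact per-score emergency counts (all and
   CPD-related).
3. **Per-score outcome assignment.** Emergency outcomes are placed exactly
   from step 2. The remaining four outcomes are only known at category
   level, so within each category they are allocated across that category's
   scores proportionally to residual row capacity, using largest-remainder
   rounding with ties broken by (score, outcome) lexical order. Records are
   emitted sorted by score, then outcome column order, so reconstruction is
   reproducible byte for byte.

The allocation in step 3 is the one modelling choice without a unique
answer. It is harmless for the policy analysis: every quantity in the
threshold-sensitivity sweep depends only on score margins and per-score
emergency counts, which are exact. A test asserts this invariance by
permuting the within-category allocation and checking the sweep is
unchanged.

The reconstructed cohort has no patient-level pelvimetry. When an analysis
needs a Magnin column (discrimination, AICc comparison), one can be attached
by drawing from the calibrated linear-Gaussian model of §4 under an explicit
seed; such values are synthetic and are labelled as such.

One inconsistency in narrative summaries of this design is worth flagging:
at the threshold-7 policy the bundled tables give 45 counterfactual
emergency cesareans (26.5% of all cesareans), yet a figure of 54 (implying
30.1%) circulates in prose summaries of the same comparison against the 78
observed. The 54 cannot be derived from the cumulative counts, which are
internally consistent; this package uses the tables throughout.

## 3. Counterfactual scheduling policy

The policy "schedule a CS iff STOL ≥ t" partitions the cohort by score. The
below-threshold arm attempts labor and is assumed to experience its actually
observed outcome; patients who actually received a scheduled CS but fall
below the threshold are counted in the trial-of-labor arm and contribute no
cesarean, because their labor outcome is unobservable. Emergency cesareans
under the policy are therefore exactly the observed emergency cesareans at
below-threshold scores. Threshold 1 schedules everyone; a sentinel
threshold 9 schedules nobody. Percentages are reported to one decimal,
rounded half away from zero, with `None` for zero denominators (e.g.
emergency CS per trial of labor when nobody labors).

## 4. Synthetic cohort generator

Generation is hierarchical and fully seeded through
`numpy.random.default_rng` (no global state):

1. score ~ Categorical(p₁…p₈), defaulting to the reference score margins;
2. outcome | score ~ Categorical over the six outcomes, defaulting to the
   reference per-score conditionals (rows with zero probability carry NaN
   conditionals and are never drawn);
3. Magnin | score = a + b·score + ε, ε ~ N(0, σ_ε), with
   b = ρ·σ_m/σ_s, a = μ_m − b·μ_s and σ_ε = σ_m·√(1−ρ²), so the targets
   μ_m = 24, σ_m = 1.4 and corr(score, Magnin) = ρ = −0.742 hold exactly in
   the large-sample limit (verified within ±0.02 at n = 10⁵).

Limits: the Magnin model is linear-Gaussian around a discrete score, so it
cannot reproduce patient-level pelvimetric detail, skewness, or any
nonlinear score–pelvis relationship; outcomes are conditionally independent
of Magnin given the score by construction. In diameter-emission mode the
conjugate and transverse are drawn to sum to the Magnin value, not from
their own joint anatomy.

## 5. Fitting and inference

**Multinomial logistic regression** is fitted by Newton–Raphson on the full
log-likelihood (reference level: NORMAL by default; coefficients for the
other five classes). Convergence requires a gradient max-norm below 1e-8
(default), with step-halving on non-increasing steps. The observed
information matrix is inverted for coefficient covariances. On detected
quasi-separation (diverging coefficients or singular information) the model
is refitted with an L2 ridge of 1e-4 and a warning; this is a documented
stabilization, not silent behavior. With a categorical predictor the fit is
saturated and reproduces within-group frequencies to numerical precision,
so the LR statistic of the categorical model against the intercept-only
model equals the closed-form contingency-table G²; on the reconstructed
cohort this is 89.512 with 10 degrees of freedom.

**Pseudo-R²**: McFadden 1 − ℓ₁/ℓ₀; Nagelkerke (Cragg–Uhler) normalized
Cox–Snell; count-R² is the fraction of records whose true class attains the
maximal fitted probability, with ties counted as incorrect (a conservative,
deterministic convention).

**AICc** = −2ℓ + 2k + 2k(k+1)/(n−k−1); Akaike weights are
exp(−Δᵢ/2) normalized over the candidate set.

**Marginal means with Tukey adjustment**: fitted category-level outcome
probabilities with delta-method standard errors; pairwise comparisons use
the studentized-range distribution with effectively infinite degrees of
freedom (df = 10⁷ passed to `scipy.stats.studentized_range`, which does not
accept df = ∞); a compact letter display is built by the maximal-interval
sweep. The infinite-df choice reflects that the variance is estimated from
a likelihood, not from a residual mean square.

**Slope comparison**: per-outcome linear slopes on the score are made
identifiable by centering to sum zero across outcome classes; a case
bootstrap (resampling records, refitting) yields percentile intervals for
all pairwise slope differences, and outcomes are grouped by connected
components of "difference CI contains zero".

**Kruskal–Wallis** is delegated to `scipy.stats.kruskal` (tie-corrected),
with an early return of H = 0, p = 1 when all values are identical.

## 6. Discrimination

A trial of labor *fails* if it ends in emergency CS; scheduled cesareans are
excluded. A flag restricts failures to CPD-related emergency cesareans and
excludes the non-CPD ones. ROC curves use midpoint thresholds between
distinct score values (plus sentinels beyond the extremes); the trapezoid
AUC then equals the tie-corrected Mann–Whitney statistic exactly. Youden's J
is the maximal sensitivity + specificity − 1 over thresholds, and the
Matthews correlation coefficient is evaluated at the J-maximizing threshold.
Multiclass discrimination of the outcome model is summarized by one-vs-rest
micro (pooled) and macro (per-class averaged) AUC.

The STOL-vs-Magnin comparison refits a univariate logistic model for each
predictor on every bootstrap resample and reports percentile intervals for
the paired differences in AUC, J and MCC, formatted with asymmetric +/−
offsets around the point estimate. Defaults: B = 2000 resamples, explicit
seed required; resamples that lose a class are redrawn (bounded by a redraw
budget). These sizes are package choices balancing Monte Carlo error
against runtime; the zero-difference coverage of the AUC interval was
measured at ≈94.6% in a dedicated design (n = 400, B = 299) before the
corresponding test was frozen.

## 7. Known limitations

- The reconstructed cohort is exact at the level of the published margins
  it is built from, but the within-category allocation of non-emergency
  outcomes to individual scores is a modelling convention (§2); analyses
  that depend on per-score composition of non-emergency outcomes (e.g.
  score-linear models) inherit it.
- Patient-level Magnin values are synthetic wherever they appear alongside
  the reconstructed cohort; discrimination comparisons on such data support
  directional conclusions under the calibrated model, not point estimates
  of any external dataset.
- The counterfactual policy assumes outcomes are invariant to the policy
  (no behavioral or clinical feedback) and that scheduled-CS patients'
  hypothetical labor outcomes are unknowable; both are assumptions, not
  findings.
- The Kruskal–Wallis H depends on how outcomes are coded to ranks; with the
  documented coding (outcome column order 1–6) the package computes
  H = 4.425 on the reconstructed cohort. Other codings give other values;
  none is privileged.
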