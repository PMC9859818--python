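"""Multinomial MLE, likelihood-ratio tests, pseudo-R², marginal means,
slope bootstrap, AICc weights and the Kruskal-Wallis test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stolsim import (
    Cohort,
    DeliveryOutcome,
    MultinomialLogit,
    aicc_weights,
    fit_outcome_model,
    kruskal_wallis,
    lr_test,
    marginal_means_tukey,
    pseudo_r2,
    slope_bootstrap,
)
from stolsim.cohort import PatientRecord
from stolsim.models import FitResult, _tukey_sf

OUT = DeliveryOutcome


def cohort_from_counts(counts: dict) -> Cohort:
    """Expand {(stol, outcome): n} into a cohort."""
    records = []
    for (s, o), n in counts.items():
        records.extend(PatientRecord(stol=s, outcome=o) for _ in range(n))
    return Cohort(records=tuple(records))


def g_squared(table: np.ndarray) -> float:
    """Independence G² of a contingency table (brute-force oracle)."""
    table = table.astype(float)
    rows = table.sum(1, keepdims=True)
    cols = table.sum(0, keepdims=True)
    expected = rows * cols / table.sum()
    mask = table > 0
    return float(2 * np.sum(table[mask] * np.log(table[mask] / expected[mask])))


class TestMultinomialLogit:
    def test_intercept_only_recovers_outcome_frequencies(self, ref_cohort):
        fit = fit_outcome_model(ref_cohort, "intercept")
        freqs = pd.Series(fit.y).value_counts(normalize=True)
        for j, cls in enumerate(fit.classes):
            assert fit.fitted[0, j] == pytest.approx(freqs[cls], abs=1e-9)
        assert np.allclose(fit.fitted.sum(axis=1), 1.0, atol=1e-10)

    def test_saturated_categorical_fit_equals_group_frequencies(self, ref_cohort):
        fit = fit_outcome_model(ref_cohort, "category")
        # first favorable record: fitted P(NORMAL | FAVORABLE) = 108/175
        fav_idx = next(
            i for i, r in enumerate(ref_cohort.records) if r.category.name == "FAVORABLE"
        )
        j = fit.classes.index(OUT.NORMAL.name)
        assert fit.fitted[fav_idx, j] == pytest.approx(108 / 175, abs=1e-8)

    def test_duplicated_cohort_doubles_loglik_not_coefficients(self, ref_cohort):
        single = fit_outcome_model(ref_cohort, "category")
        doubled = fit_outcome_model(
            Cohort(records=ref_cohort.records * 2), "category"
        )
        assert np.allclose(doubled.coef.values, single.coef.values, atol=1e-6)
        assert doubled.log_likelihood == pytest.approx(2 * single.log_likelihood, rel=1e-9)

    def test_matches_statsmodels_mnlogit(self, ref_cohort):
        sm = pytest.importorskip("statsmodels.api")
        fit = fit_outcome_model(ref_cohort, "score")
        codes = pd.Categorical(
            fit.y, categories=[fit.reference] + [c for c in fit.classes if c != fit.reference]
        ).codes
        X = sm.add_constant(ref_cohort.stol_scores().astype(float))
        res = sm.MNLogit(codes, X).fit(disp=0)
        assert fit.log_likelihood == pytest.approx(res.llf, abs=1e-5)
        # statsmodels parameterizes relative to code 0 = our reference
        ours = fit.coef.loc[[c for c in fit.classes if c != fit.reference]].values
        assert np.allclose(ours, np.asarray(res.params).T, atol=1e-4)

    def test_rank_deficient_design_rejected(self):
        records = tuple(
            PatientRecord(stol=s, outcome=o)
            for s, o in [(1, OUT.NORMAL), (1, OUT.SCHEDULED_CS), (1, OUT.NORMAL)]
        )
        X = np.column_stack([np.ones(3), np.ones(3)])
        y = np.array([r.outcome.name for r in records], dtype=object)
        with pytest.raises(ValueError, match="rank"):
            MultinomialLogit(fit_intercept=True).fit(X, y)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            MultinomialLogit().fit(np.arange(4.0)[:, None], np.array(["a"] * 4, dtype=object))

    def test_separation_triggers_ridge_with_warning(self):
        # outcome perfectly determined by the category: unpenalized MLE diverges
        cohort = cohort_from_counts(
            {
                (1, OUT.NORMAL): 20,
                (4, OUT.SCHEDULED_CS): 20,
                (7, OUT.EMERGENCY_CS_CPD): 20,
            }
        )
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_outcome_model(cohort, "category")
        null = fit_outcome_model(cohort, "intercept")
        assert pseudo_r2(fit, null).count == 1.0


class TestLikelihoodRatio:
    def test_model_against_itself_is_zero(self, ref_cohort):
        fit = fit_outcome_model(ref_cohort, "category")
        res = lr_test(fit, fit)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.df == 0

    def test_category_model_statistic_equals_contingency_g2(self, ref_cohort):
        full = fit_outcome_model(ref_cohort, "category")
        null = fit_outcome_model(ref_cohort, "intercept")
        res = lr_test(full, null)
        table = np.zeros((3, 6))
        cats = ["FAVORABLE", "NEUTRAL", "UNFAVORABLE"]
        for r in ref_cohort.records:
            table[cats.index(r.category.name), list(OUT).index(r.outcome)] += 1
        assert res.statistic == pytest.approx(g_squared(table), abs=1e-6)
        assert res.df == 10
        assert res.p_value < 0.001

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_tables_match_g2_oracle(self, seed):
        rng = np.random.default_rng(seed)
        outcomes = [OUT.NORMAL, OUT.SCHEDULED_CS, OUT.EMERGENCY_CS_CPD, OUT.INSTRUMENTAL_CPD]
        counts = {}
        table = np.zeros((3, 4))
        for ci, s in enumerate((1, 4, 7)):  # one score per category
            for oj, o in enumerate(outcomes):
                n = int(rng.integers(1, 9))
                counts[(s, o)] = n
                table[ci, oj] = n
        cohort = cohort_from_counts(counts)
        res = lr_test(
            fit_outcome_model(cohort, "category"), fit_outcome_model(cohort, "intercept")
        )
        assert res.statistic == pytest.approx(g_squared(table), abs=1e-6)

    def test_mismatched_data_rejected(self, ref_cohort):
        other = Cohort(records=ref_cohort.records[:100], provenance="reconstructed")
        with pytest.raises(ValueError, match="different data"):
            lr_test(
                fit_outcome_model(ref_cohort, "category"),
                fit_outcome_model(other, "intercept"),
            )


class TestPseudoR2:
    def test_null_against_null_is_zero(self, ref_cohort):
        null = fit_outcome_model(ref_cohort, "intercept")
        r2 = pseudo_r2(null, null)
        assert r2.mcfadden == pytest.approx(0.0, abs=1e-10)
        assert r2.nagelkerke == pytest.approx(0.0, abs=1e-10)

    def test_formula_oracle_from_loglikelihoods(self, ref_cohort):
        full = fit_outcome_model(ref_cohort, "category")
        null = fit_outcome_model(ref_cohort, "intercept")
        r2 = pseudo_r2(full, null)
        llf, lln, n = full.log_likelihood, null.log_likelihood, full.n_obs
        assert r2.mcfadden == pytest.approx(1 - llf / lln)
        expected_nag = (1 - np.exp(2 * (lln - llf) / n)) / (1 - np.exp(2 * lln / n))
        assert r2.nagelkerke == pytest.approx(expected_nag)
        # count R²: modal prediction accuracy computed by hand
        modal = np.asarray(full.classes, dtype=object)[np.argmax(full.fitted, axis=1)]
        assert r2.count == pytest.approx((modal == full.y).mean())
        assert 0 <= r2.mcfadden <= 1 and 0 <= r2.nagelkerke <= 1 and 0 <= r2.count <= 1


def _dummy_fit(ll: float, k: int, y: np.ndarray) -> FitResult:
    return FitResult(
        predictor="dummy",
        model=None,
        classes=("a", "b"),
        reference="a",
        design_columns=("intercept",),
        coef=None,
        log_likelihood=ll,
        n_obs=len(y),
        k_params=k,
        fitted=np.empty((0, 2)),
        y=y,
        X=np.empty((len(y), 0)),
    )


class TestAiccWeights:
    y = np.array(["a", "b"] * 30, dtype=object)

    def test_equal_models_split_weight(self):
        comp = aicc_weights([_dummy_fit(-40.0, 2, self.y), _dummy_fit(-40.0, 2, self.y)])
        assert np.allclose(comp.weights, [0.5, 0.5])

    def test_delta_pattern_gives_exponential_weights(self):
        # equal k so AICc differences equal -2*loglik differences: deltas 0, 2, 4
        fits = [_dummy_fit(-40.0, 2, self.y), _dummy_fit(-41.0, 2, self.y),
                _dummy_fit(-42.0, 2, self.y)]
        comp = aicc_weights(fits)
        expected = np.array([1.0, np.exp(-1.0), np.exp(-2.0)])
        assert np.allclose(comp.weights, expected / expected.sum())

    def test_weights_sum_to_one_and_shift_invariant(self):
        fits = [_dummy_fit(ll, k, self.y) for ll, k in ((-40, 2), (-38, 3), (-37, 5))]
        shifted = [_dummy_fit(f.log_likelihood + 7.5, f.k_params, self.y) for f in fits]
        w0 = aicc_weights(fits).weights
        w1 = aicc_weights(shifted).weights
        assert w0.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(w0, w1)

    def test_small_sample_guard(self):
        y = np.array(["a", "b", "a"], dtype=object)
        with pytest.raises(ValueError, match="AICc"):
            aicc_weights([_dummy_fit(-1.0, 2, y), _dummy_fit(-1.0, 4, y)])

    def test_different_data_rejected(self):
        other = np.array(["a", "b"] * 31, dtype=object)[:60]
        other[0] = "b"
        with pytest.raises(ValueError, match="identical records"):
            aicc_weights([_dummy_fit(-40.0, 2, self.y), _dummy_fit(-40.0, 2, other)])


class TestMarginalMeans:
    def test_favorable_category_singles_out_normal_delivery(self, ref_cohort):
        fit = fit_outcome_model(ref_cohort, "category")
        mm = marginal_means_tukey(fit)
        fav = mm.probabilities.loc["FAVORABLE"]
        assert fav.idxmax() == OUT.NORMAL.name
        letters = mm.letters["FAVORABLE"]
        normal_letters = set(letters[OUT.NORMAL.name])
        for outcome, lset in letters.items():
            if outcome != OUT.NORMAL.name:
                assert normal_letters.isdisjoint(set(lset))
        # within-category probabilities are a distribution
        assert mm.probabilities.sum(axis=1).values == pytest.approx([1, 1, 1])

    def test_unfavorable_high_group_contains_cpd_outcomes(self, ref_cohort):
        mm = marginal_means_tukey(fit_outcome_model(ref_cohort, "category"))
        letters = mm.letters["UNFAVORABLE"]
        top = set(letters[OUT.SCHEDULED_CS.name]) & set(letters[OUT.NORMAL.name]) & set(
            letters[OUT.EMERGENCY_CS_CPD.name]
        )
        assert top  # the three share a letter

    def test_single_comparison_reduces_to_two_sided_normal(self):
        for z in (0.5, 1.0, 1.96, 3.0):
            adjusted = _tukey_sf(np.array([z]), 2)[0]
            assert adjusted == pytest.approx(2 * stats.norm.sf(z), rel=1e-3)

    def test_null_configuration_rarely_significant(self):
        rng = np.random.default_rng(5)
        outcomes = list(OUT)
        records = tuple(
            PatientRecord(stol=int(rng.integers(1, 9)), outcome=outcomes[int(rng.integers(6))])
            for _ in range(600)
        )
        mm = marginal_means_tukey(fit_outcome_model(Cohort(records=records), "category"))
        n_sig = sum(
            (mm.pairwise_p[cat].values[np.triu_indices(6, 1)] < 0.05).sum()
            for cat in mm.pairwise_p
        )
        assert n_sig <= 2  # type-I allowance over 45 adjusted comparisons

    def test_requires_categorical_fit(self, ref_cohort):
        with pytest.raises(ValueError, match="categorical"):
            marginal_means_tukey(fit_outcome_model(ref_cohort, "score"))


class TestSlopeBootstrap:
    def test_determinism(self, ref_cohort):
        a = slope_bootstrap(ref_cohort, B=50, seed=3)
        b = slope_bootstrap(ref_cohort, B=50, seed=3)
        assert a.pairwise.equals(b.pairwise)
        assert a.groups == b.groups

    def test_cpd_outcomes_group_apart_with_positive_slopes(self, ref_cohort):
        sc = slope_bootstrap(ref_cohort, B=400, seed=17)
        top = set(sc.groups[0])
        assert top == {OUT.SCHEDULED_CS.name, OUT.EMERGENCY_CS_CPD.name}
        assert sc.slopes[OUT.SCHEDULED_CS.name] > 0
        assert sc.slopes[OUT.EMERGENCY_CS_CPD.name] > 0

    def test_relabelled_twin_outcomes_have_centred_difference_ci(self):
        # two outcomes constructed with identical score distributions
        rng = np.random.default_rng(2)
        records = []
        for _ in range(150):
            s = int(rng.integers(1, 9))
            records.append(PatientRecord(stol=s, outcome=OUT.NORMAL))
            records.append(PatientRecord(stol=s, outcome=OUT.SCHEDULED_CS))
        for _ in range(60):  # a third outcome so the model is multinomial
            records.append(PatientRecord(stol=int(rng.integers(1, 9)), outcome=OUT.EMERGENCY_CS_CPD))
        sc = slope_bootstrap(Cohort(records=tuple(records)), B=200, seed=4)
        row = sc.pairwise[
            (sc.pairwise.a.isin(["NORMAL", "SCHEDULED_CS"]))
            & (sc.pairwise.b.isin(["NORMAL", "SCHEDULED_CS"]))
        ].iloc[0]
        assert row.ci_low <= 0.0 <= row.ci_high

    def test_known_slope_recovery(self):
        # synthetic outcomes from a 3-class multinomial logit with known slopes
        rng = np.random.default_rng(11)
        beta = {"NORMAL": 0.0, "SCHEDULED_CS": 0.5, "EMERGENCY_CS_CPD": -0.4}
        alphas = {"NORMAL": 0.0, "SCHEDULED_CS": -1.0, "EMERGENCY_CS_CPD": 0.5}
        classes = list(beta)
        records = []
        for _ in range(2500):
            s = int(rng.integers(1, 9))
            logits = np.array([alphas[c] + beta[c] * s for c in classes])
            p = np.exp(logits - logits.max())
            p /= p.sum()
            records.append(PatientRecord(stol=s, outcome=OUT[rng.choice(classes, p=p)]))
        sc = slope_bootstrap(Cohort(records=tuple(records)), B=200, seed=12)
        centred_truth = pd.Series(beta) - pd.Series(beta).mean()
        boot_se = (sc.pairwise.ci_high - sc.pairwise.ci_low) / (2 * 1.96)
        se = boot_se.mean()  # conservative scalar scale for the per-class check
        for c in classes:
            assert abs(sc.slopes[c] - centred_truth[c]) < 3 * se

    def test_seed_required(self, ref_cohort):
        with pytest.raises(ValueError, match="seed"):
            slope_bootstrap(ref_cohort, B=10)


class TestKruskalWallis:
    def test_all_equal_values_give_zero_statistic(self):
        res = kruskal_wallis([2.0] * 9, ["a", "a", "a", "b", "b", "b", "c", "c", "c"])
        assert res.statistic == 0.0

    def test_hand_computed_no_tie_example(self):
        res = kruskal_wallis([1, 2, 3, 4, 5, 6], ["A", "A", "B", "B", "C", "C"])
        assert res.statistic == pytest.approx(32 / 7)
        assert res.df == 2

    def test_matches_midrank_oracle_on_tied_data(self):
        rng = np.random.default_rng(8)
        values = rng.integers(0, 4, size=60).astype(float)  # heavy ties
        groups = rng.integers(0, 3, size=60)
        res = kruskal_wallis(values, groups)
        # independent midrank implementation
        order = np.argsort(values, kind="stable")
        ranks = np.empty(60)
        i = 0
        sv = values[order]
        while i < 60:
            j = i
            while j + 1 < 60 and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        N = 60.0
        H = 12 / (N * (N + 1)) * sum(
            ranks[groups == g].sum() ** 2 / (groups == g).sum() for g in range(3)
        ) - 3 * (N + 1)
        _, tie_counts = np.unique(values, return_counts=True)
        H /= 1 - (tie_counts**3 - tie_counts).sum() / (N**3 - N)
        assert res.statistic == pytest.approx(H, abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2, 3], ["a", "a", "a"])
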