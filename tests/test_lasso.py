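import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from sklearn.metrics import roc_curve

from ntcpkit import cohort as syn
from ntcpkit.errors import (
    DataError,
    DegenerateOutcomeError,
    ParameterError,
    UndefinedStatisticError,
)
from ntcpkit.lasso import (
    LambdaRule,
    bootstrap_ensemble,
    evaluate_auc,
    final_model,
    fit_lasso_logistic,
    odds_ratio,
    stratified_split,
)


def _toy_data(seed=0, n=200, p=3, beta=None, intercept=-0.5):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{i}" for i in range(p)])
    beta = np.array(beta if beta is not None else [1.0, -0.7, 0.0][:p])
    eta = intercept + X.to_numpy() @ beta
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return X, y


class TestStratifiedSplit:
    def test_nine_patients_six_three(self):
        ids = [f"p{i}" for i in range(9)]
        plan = stratified_split(ids, {i: "s" for i in ids}, {i: 0 for i in ids}, seed=0)
        assert len(plan.train_ids) == 6 and len(plan.validation_ids) == 3

    def test_divisible_strata_exact_thirds(self):
        ids = [f"p{i}" for i in range(30)]
        subtype = {i: ("A" if int(i[1:]) < 12 else "B") for i in ids}
        outcome = {i: int(int(i[1:]) % 2 == 0 and int(i[1:]) < 6) for i in ids}
        # strata sizes: A/1: 3 ... craft divisible-by-3 strata instead
        subtype = {i: "A" for i in ids}
        outcome = {i: int(int(i[1:]) < 9) for i in ids}  # 9 events, 21 non-events
        plan = stratified_split(ids, subtype, outcome, seed=1)
        assert len(plan.train_ids) == 20 and len(plan.validation_ids) == 10

    def test_single_patient_stratum_goes_to_training(self):
        ids = [f"p{i}" for i in range(11)]
        subtype = {i: "A" for i in ids}
        subtype["p0"] = "rare"
        outcome = {i: 0 for i in ids}
        with pytest.warns(UserWarning, match="single patient"):
            plan = stratified_split(ids, subtype, outcome, seed=0)
        assert "p0" in plan.train_ids

    def test_balance_property_random_cohorts(self):
        # per stratum the train share is within one patient of 2/3
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(30, 120))
            ids = [f"p{i}" for i in range(n)]
            subtype = {i: rng.choice(["A", "B", "C"]) for i in ids}
            outcome = {i: int(rng.random() < 0.25) for i in ids}
            plan = stratified_split(ids, subtype, outcome, seed=int(rng.integers(1000)))
            assert set(plan.train_ids) | set(plan.validation_ids) == set(ids)
            for key in {(subtype[i], outcome[i]) for i in ids}:
                members = [i for i in ids if (subtype[i], outcome[i]) == key]
                n_train = sum(i in plan.train_ids for i in members)
                assert abs(n_train - 2 * len(members) / 3) <= 1.0

    def test_missing_labels(self):
        with pytest.raises(DataError):
            stratified_split(["a", "b"], {"a": "s"}, {"a": 0, "b": 0})


class TestFitLasso:
    def test_full_shrinkage_limit(self):
        X, y = _toy_data(seed=1, n=300)
        fit = fit_lasso_logistic(X, y, LambdaRule(kind="fixed", lam=1e4))
        assert all(abs(c) < 1e-8 for c in fit.coefficients.values())
        rate = y.mean()
        assert fit.intercept == pytest.approx(np.log(rate / (1 - rate)), abs=0.02)

    def test_unpenalized_matches_newton_raphson(self):
        # statsmodels Logit (Newton-Raphson) is the independent MLE oracle
        X, y = _toy_data(seed=2, n=400)
        fit = fit_lasso_logistic(X, y, LambdaRule(kind="fixed", lam=0.0))
        ref = sm.Logit(y, sm.add_constant(X.to_numpy())).fit(disp=0)
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-4)
        for j, c in enumerate(X.columns):
            assert fit.coefficients[c] == pytest.approx(ref.params[j + 1], abs=1e-4)

    def test_two_by_two_closed_form(self):
        # events 30/100 at x=1 and 10/100 at x=0: slope = log[(30/70)/(10/90)]
        x = np.repeat([1.0, 0.0], 100)
        y = np.concatenate([np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)]).astype(int)
        fit = fit_lasso_logistic(pd.DataFrame({"x": x}), y, LambdaRule(kind="fixed", lam=0.0))
        expected = np.log((30 / 70) / (10 / 90))
        assert fit.coefficients["x"] == pytest.approx(expected, abs=1e-4)

    def test_single_class_rejected(self):
        X, _ = _toy_data(seed=3, n=50)
        with pytest.raises(DegenerateOutcomeError):
            fit_lasso_logistic(X, np.zeros(50, dtype=int))

    def test_cv_rule_is_seed_deterministic(self):
        X, y = _toy_data(seed=4, n=150)
        a = fit_lasso_logistic(X, y, LambdaRule(kind="cv", folds=5), seed=7)
        b = fit_lasso_logistic(X, y, LambdaRule(kind="cv", folds=5), seed=7)
        assert a == b

    def test_invalid_rule(self):
        with pytest.raises(ParameterError):
            LambdaRule(kind="fixed", lam=-1.0)
        with pytest.raises(ParameterError):
            LambdaRule(kind="ridge")


class TestAUC:
    def test_perfect_separation(self):
        assert evaluate_auc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0

    def test_enumerated_pairs(self):
        # pairs ordered correctly: 3 of 4 -> 0.75
        assert evaluate_auc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_uninformative_scores(self):
        assert evaluate_auc(np.ones(10), [1, 0] * 5) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            evaluate_auc([0.1, 0.2], [1, 1])

    def test_matches_trapezoidal_roc(self, rng):
        # trapezoidal integration of the ROC curve is the independent oracle
        for _ in range(100):
            n = int(rng.integers(10, 60))
            scores = np.round(rng.normal(size=n), 1)  # induces ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            fpr, tpr, _ = roc_curve(labels, scores)
            assert evaluate_auc(scores, labels) == pytest.approx(
                np.trapezoid(tpr, fpr), abs=1e-10
            )

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, size=80)
        a = evaluate_auc(scores, labels)
        b = evaluate_auc(1 / (1 + np.exp(-scores)), labels)
        assert a == pytest.approx(b, abs=1e-12)


@pytest.fixture(scope="module")
def small_problem():
    X, y = _toy_data(seed=5, n=180, p=4, beta=[1.2, -0.8, 0.0, 0.0])
    return X.iloc[:120], y[:120], X.iloc[120:], y[120:]


class TestEnsemble:
    def test_singleton_ensemble_mean(self, small_problem):
        Xtr, ytr, Xva, yva = small_problem
        ens = bootstrap_ensemble(Xtr, ytr, Xva, yva, n_boot=1,
                                 lambda_rule=LambdaRule(kind="fixed", lam=1.0), seed=0)
        assert ens.mean_auc == pytest.approx(ens.validation_aucs[0])
        assert ens.sd_auc == 0.0

    def test_pair_diagonal_identity(self, small_problem):
        Xtr, ytr, Xva, yva = small_problem
        ens = bootstrap_ensemble(Xtr, ytr, Xva, yva, n_boot=30,
                                 lambda_rule=LambdaRule(kind="fixed", lam=1.0), seed=1)
        pair = ens.pair_counts
        for f in ens.features:
            assert pair.loc[f, f] == ens.selection_counts[f]

    def test_pair_bounded_by_marginals(self, small_problem):
        Xtr, ytr, Xva, yva = small_problem
        ens = bootstrap_ensemble(Xtr, ytr, Xva, yva, n_boot=30,
                                 lambda_rule=LambdaRule(kind="fixed", lam=1.0), seed=2)
        pair, counts = ens.pair_counts, ens.selection_counts
        for f in ens.features:
            for g in ens.features:
                assert pair.loc[f, g] <= min(counts[f], counts[g])

    def test_seed_determinism(self, small_problem):
        Xtr, ytr, Xva, yva = small_problem
        kw = dict(n_boot=15, lambda_rule=LambdaRule(kind="fixed", lam=1.0))
        a = bootstrap_ensemble(Xtr, ytr, Xva, yva, seed=9, **kw)
        b = bootstrap_ensemble(Xtr, ytr, Xva, yva, seed=9, **kw)
        assert np.array_equal(a.coef_matrix, b.coef_matrix)
        assert a.selection_counts.equals(b.selection_counts)
        assert np.array_equal(a.validation_aucs, b.validation_aucs)

    def test_degenerate_replicates_redrawn(self):
        rng = np.random.default_rng(11)
        n = 25
        X = pd.DataFrame({"x": rng.normal(size=n)})
        y = np.zeros(n, dtype=int)
        y[:2] = 1  # rare events: empty-event resamples occur and are redrawn
        Xv = pd.DataFrame({"x": rng.normal(size=20)})
        yv = np.array([1, 0] * 10)
        ens = bootstrap_ensemble(X, y, Xv, yv, n_boot=50,
                                 lambda_rule=LambdaRule(kind="fixed", lam=1.0), seed=3)
        assert ens.n_boot == 50
        assert ens.n_redrawn > 0

    def test_null_selected_less_than_driver(self):
        rng = np.random.default_rng(13)
        n = 400
        X = pd.DataFrame(rng.normal(size=(n, 4)), columns=["driver", "n1", "n2", "n3"])
        model = syn.OutcomeModel(endpoint="e", coefficients={"driver": 1.2}, intercept=-1.0)
        y = (syn.assign_outcomes(X, model, rng) >= 2).astype(int)
        ens = bootstrap_ensemble(
            X.iloc[:260], y[:260], X.iloc[260:], y[260:],
            n_boot=40, lambda_rule=LambdaRule(kind="fixed", lam=3.0), seed=5,
        )
        counts = ens.selection_counts
        assert counts["driver"] > max(counts["n1"], counts["n2"], counts["n3"])


class TestFinalModel:
    def test_odds_ratio_examples(self):
        assert odds_ratio(0.012) == pytest.approx(1.012, abs=1e-9)
        assert odds_ratio(0.0) == 1.0
        assert odds_ratio(-3.880) == pytest.approx(0.021, abs=1e-9)

    def test_rows_consistent(self):
        X, y = _toy_data(seed=6, n=240, p=3, beta=[1.0, -0.8, 0.0])
        Xv, yv = _toy_data(seed=7, n=80, p=3, beta=[1.0, -0.8, 0.0])
        rule = LambdaRule(kind="fixed", lam=1.0)
        ens = bootstrap_ensemble(X, y, Xv, yv, n_boot=60, lambda_rule=rule, seed=0)
        rows, fit = final_model(X, y, ens, rule, seed=0)
        assert rows[-1].variable == "Constant"
        for row in rows:
            assert row.odds_ratio == pytest.approx(round(np.exp(row.coefficient), 3))
            assert row.std >= 0.0
            assert row.ci95[0] <= row.ci95[1]
        assert {r.variable for r in rows[:-1]} == set(fit.selected)

    def test_empty_retained_warns(self):
        X, y = _toy_data(seed=8, n=150, p=2, beta=[0.0, 0.0])
        rule = LambdaRule(kind="fixed", lam=500.0)
        ens = bootstrap_ensemble(X, y, X, y, n_boot=10, lambda_rule=rule, seed=0)
        with pytest.warns(UserWarning, match="intercept-only"):
            rows, _ = final_model(X, y, ens, rule, seed=0)
        assert [r.variable for r in rows] == ["Constant"]

    def test_feature_mismatch_rejected(self):
        X, y = _toy_data(seed=9, n=100, p=2)
        rule = LambdaRule(kind="fixed", lam=1.0)
        ens = bootstrap_ensemble(X, y, X, y, n_boot=5, lambda_rule=rule, seed=0)
        with pytest.raises(DataError):
            final_model(X[["x1", "x0"]], y, ens, rule, seed=0)
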