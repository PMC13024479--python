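import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier

import alscreen as als
from alscreen.metrics import (
    MetricError,
    aggregate_permutation_importance,
    ap_lift,
    auc,
    average_precision,
    fit_baselines,
    permutation_importance,
    score_table,
)
from alscreen.teacher import make_fold_plan


def brute_force_auc(scores, labels):
    """Exhaustive pair-counting oracle: wins + half-ties over all pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_worked_example(self):
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            auc([0.1, 0.2], [1, 1])

    def test_matches_pair_counting_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.integers(2, 13))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            s = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=n)
            assert auc(s, y) == pytest.approx(brute_force_auc(s, y), abs=1e-12)

    def test_invariant_under_strictly_increasing_transform(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        y[0], y[1] = 0, 1
        assert auc(np.exp(s), y) == pytest.approx(auc(s, y), abs=1e-12)
        assert auc(3 * s + 7, y) == pytest.approx(auc(s, y), abs=1e-12)


class TestAveragePrecision:
    def test_single_positive_ranked_first(self):
        assert average_precision([0.9, 0.1, 0.2, 0.3], [1, 0, 0, 0]) == 1.0

    def test_matches_reference_implementation_with_ties(self):
        import sklearn.metrics as skm

        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(4, 40))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            s = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            assert average_precision(s, y) == pytest.approx(
                skm.average_precision_score(y, s), abs=1e-12
            )

    def test_invariant_under_strictly_increasing_transform(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=30)
        y = rng.integers(0, 2, 30)
        y[0], y[1] = 0, 1
        assert average_precision(np.exp(s), y) == pytest.approx(
            average_precision(s, y), abs=1e-12
        )


class TestApLift:
    def test_lift_prevalence_product_recovers_ap(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            ap = rng.random()
            prev = rng.uniform(0.01, 0.99)
            assert ap_lift(ap, prev) * prev == pytest.approx(ap, abs=1e-12)

    def test_degenerate_prevalence_rejected(self):
        for prev in (0.0, 1.0):
            with pytest.raises(MetricError):
                ap_lift(0.5, prev)

    def test_score_table_reports_exact_prevalence(self):
        y = np.array([1, 0, 0, 0, 1, 0, 0, 0])
        tab = score_table({"m": np.linspace(0, 1, 8)}, y)
        assert tab.loc["m", "prevalence"] == 0.25
        assert tab.loc["m", "ap_lift"] * 0.25 == pytest.approx(tab.loc["m", "ap"], abs=1e-12)


@pytest.fixture(scope="module")
def linear_problem():
    rng = np.random.default_rng(5)
    n = 200
    X = pd.DataFrame(rng.normal(size=(n, 5)), columns=[f"f{i}" for i in range(5)])
    margin = 1.5 * X["f0"] - X["f1"]
    y = (margin + 0.1 * rng.normal(size=n) > 0).astype(int)
    return X, y.to_numpy()


class TestBaselines:
    def test_all_models_emit_probabilities(self, linear_problem):
        X, y = linear_problem
        plan = make_fold_plan(y, k=3, seed=0)
        oof = fit_baselines(X, y, plan)
        assert set(oof) == {"rf_m3", "logit_l2", "elastic_net", "mlp_direct"}
        for scores in oof.values():
            assert len(scores) == len(y)
            assert ((0 <= scores) & (scores <= 1)).all()

    def test_logit_separates_linear_problem(self, linear_problem):
        X, y = linear_problem
        plan = make_fold_plan(y, k=3, seed=0)
        oof = fit_baselines(X, y, plan, include_mlp=False)
        assert auc(oof["logit_l2"], y) > 0.95


@pytest.fixture(scope="module")
def one_signal_model():
    rng = np.random.default_rng(6)
    n = 400
    X = pd.DataFrame(
        {"signal": rng.normal(size=n), "junk1": rng.normal(size=n),
         "junk2": rng.normal(size=n)}
    )
    y = (X["signal"] + 0.3 * rng.normal(size=n) > 0).astype(int).to_numpy()
    model = RandomForestClassifier(n_estimators=100, random_state=0).fit(X, y)
    return model, X, y


class TestPermutationImportance:
    def test_sole_informative_feature_has_large_drop(self, one_signal_model):
        model, X, y = one_signal_model
        imp = permutation_importance(model, X, y, n_repeats=5, seed=0)
        assert imp.loc["signal", "delta_auc"] > 0.1

    def test_noise_features_have_null_drop(self, one_signal_model):
        model, X, y = one_signal_model
        imp = permutation_importance(model, X, y, n_repeats=5, seed=0)
        assert abs(imp.loc["junk1", "delta_auc"]) < 0.02
        assert abs(imp.loc["junk2", "delta_auc"]) < 0.02

    def test_unknown_feature_rejected(self, one_signal_model):
        model, X, y = one_signal_model
        with pytest.raises(MetricError, match="absent"):
            permutation_importance(model, X, y, features=["ghost"])

    def test_aggregation_is_plain_mean_and_std(self):
        rng = np.random.default_rng(7)
        variants = {}
        vals = {}
        for i in range(9):
            v = rng.random(3)
            vals[f"v{i}"] = v
            variants[f"v{i}"] = pd.DataFrame(
                {"delta_auc": v, "delta_auc_std": 0.0},
                index=["a", "b", "c"],
            )
        agg = aggregate_permutation_importance(variants)
        mat = np.column_stack([vals[f"v{i}"] for i in range(9)])
        for j, feat in enumerate(["a", "b", "c"]):
            assert agg.loc[feat, "mean_delta_auc"] == pytest.approx(mat[j].mean(), abs=1e-12)
            assert agg.loc[feat, "std_delta_auc"] == pytest.approx(mat[j].std(), abs=1e-12)
        assert (agg.filter(like="in_").to_numpy().sum(axis=1) > 0).all()
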