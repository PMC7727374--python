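"""Training schemes, under-sampling, grid search and the Model/Results
facade."""

import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeClassifier

from mapqcal import calibration as C
from mapqcal import models as M

from conftest import make_gaussian_problem


def separable_problem(n=400, seed=0):
    return make_gaussian_problem(n, prevalence=0.5, separation=8.0,
                                 n_features=2, seed=seed)


class TestSplitTrainTest:
    def test_stratified_sizes(self):
        X = pd.DataFrame({"a": np.arange(1000.0)})
        y = np.array([1] * 100 + [0] * 900)
        X_tr, y_tr, X_te, y_te = M.split_train_test(X, y, 0.2, seed=0)
        assert len(X_tr) == 200 and len(X_te) == 800
        assert abs(y_tr.sum() - 20) <= 1

    def test_deterministic_partition(self):
        X = pd.DataFrame({"a": np.arange(100.0)})
        y = np.array([1] * 10 + [0] * 90)
        a = M.split_train_test(X, y, 0.3, seed=4)
        b = M.split_train_test(X, y, 0.3, seed=4)
        assert a[0].equals(b[0])
        combined = sorted(a[0]["a"].tolist() + a[2]["a"].tolist())
        assert combined == X["a"].tolist()

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            M.split_train_test(pd.DataFrame({"a": [1.0, 2.0]}),
                               np.array([0, 1]), 1.5, 0)


class TestRusSubsets:
    def test_count_rule_and_balance(self):
        y = np.array([1] * 50 + [0] * 1000)
        subsets = M.rus_subsets(y, seed=0)
        assert len(subsets) == 20  # ceil(1000 / 50)
        minority = set(np.flatnonzero(y == 1))
        for idx in subsets:
            assert len(idx) == 100
            labels = y[idx]
            assert labels.sum() == 50  # exactly balanced
            assert minority <= set(idx)  # minority rows in every subset

    def test_majority_sampled_without_replacement(self):
        y = np.array([1] * 10 + [0] * 40)
        for idx in M.rus_subsets(y, seed=1):
            assert len(set(idx)) == len(idx)

    def test_minority_larger_than_majority_rejected(self):
        with pytest.raises(ValueError):
            M.rus_subsets(np.array([1] * 5 + [0] * 3), seed=0)

    def test_max_subsets_cap(self):
        y = np.array([1] * 5 + [0] * 1000)
        assert len(M.rus_subsets(y, seed=0, max_subsets=7)) == 7


class TestGridSearchCV:
    def test_single_point_grid_returned(self):
        X, y = separable_problem()
        best, table = M.grid_search_cv("logistic", {"C": [1.0]}, 5, X, y, 0)
        assert best == {"C": 1.0}

    def test_returned_point_maximises_cv_table(self):
        X, y = separable_problem(seed=2)
        best, table = M.grid_search_cv("logistic",
                                       {"C": [0.001, 0.1, 10.0]}, 5, X, y, 0)
        scores = {tuple(p.items()): s for p, s in table}
        assert scores[tuple(best.items())] == max(scores.values())

    def test_cv_prefers_less_overfit_parameters(self):
        # heavy class overlap: a huge-C RBF SVM memorises its folds and
        # generalises worse than a regularised one
        X, y = make_gaussian_problem(120, prevalence=0.5, separation=0.8,
                                     n_features=2, seed=5)
        best, table = M.grid_search_cv("svm-rbf", {"C": [1.0, 100000.0]},
                                       5, X, y, 0)
        assert best == {"C": 1.0}

    def test_empty_grid_rejected(self):
        X, y = separable_problem()
        with pytest.raises(ValueError):
            M.grid_search_cv("logistic", {}, 5, X, y, 0)


class TestRusBestSchemes:
    def test_separable_fixture_reaches_perfect_f1(self):
        X, y = separable_problem(seed=1)
        cfg = M.ModelConfig("RUSVM", grid={"C": [10]}, seed=0)
        model = M.train_rus_best(cfg, X, y, X, y)
        assert model.metadata["eval_f1"] == 1.0
        assert not model.produces_probabilities

    def test_single_subset_reduces_to_one_fit(self):
        X, y = make_gaussian_problem(200, 0.5, 4.0, seed=3)
        cfg = M.ModelConfig("RULR", grid={"C": [1.0]}, seed=0, max_subsets=1)
        model = M.train_rus_best(cfg, X, y, X, y)
        assert model.metadata["subset_count"] == 1
        assert model.produces_probabilities

    def test_scheme_mismatch_rejected(self):
        cfg = M.ModelConfig("DTBAG", seed=0)
        with pytest.raises(ValueError):
            M.train_rus_best(cfg, *separable_problem(), None, None)


class TestTpfpSchemes:
    def test_refit_reduces_false_positives_on_hard_fixture(self):
        # overlapping classes at low prevalence: the balanced-subset
        # model fires on a large slab of the majority; retraining on
        # FP+TP pushes the boundary into the minority side
        X, y = make_gaussian_problem(6000, prevalence=0.02, separation=1.5,
                                     n_features=4, seed=7)
        half = len(y) // 2
        X_tr, y_tr, X_ev, y_ev = X[:half], y[:half], X[half:], y[half:]
        grid = {"C": [1.0]}
        plain = M.train_rus_best(M.ModelConfig("RULR", grid=grid, seed=0,
                                               max_subsets=5),
                                 X_tr, y_tr, X_ev, y_ev)
        staged = M.train_rus_tpfp(M.ModelConfig("RULRS", grid=grid, seed=0,
                                                max_subsets=5),
                                  X_tr, y_tr, X_ev, y_ev)
        fp_plain = int(((plain.clf.predict(X_ev) == 1) & (y_ev == 0)).sum())
        fp_staged = int(((staged.clf.predict(X_ev) == 1) & (y_ev == 0)).sum())
        assert fp_staged < fp_plain
        assert staged.metadata["eval_f1"] >= plain.metadata["eval_f1"]

    def test_zero_fp_iteration_keeps_first_stage_model(self):
        X, y = separable_problem(seed=4)
        cfg = M.ModelConfig("RUSVMS", grid={"C": [10]}, seed=0, max_subsets=2)
        model = M.train_rus_tpfp(cfg, X, y, X, y)
        assert model.metadata["refits_skipped"] >= 1
        assert model.metadata["eval_f1"] == 1.0


class TestBalancedBagging:
    def test_one_member_ensemble_equals_single_tree(self):
        X, y = make_gaussian_problem(300, 0.5, 3.0, seed=6)
        cfg = M.ModelConfig("DTBAG", grid={"max_depth": [3]}, seed=0,
                            max_subsets=1)
        model = M.train_balanced_bagging(cfg, X, y)
        tree = model.clf.trees[0]
        assert np.allclose(model.clf.predict_proba(X)[:, 1],
                           M.BalancedBaggingEnsemble([tree])
                           .predict_proba(X)[:, 1])

    def test_ensemble_probability_is_mean_of_members(self):
        X, y = make_gaussian_problem(500, 0.1, 2.0, seed=8)
        cfg = M.ModelConfig("DTBAG", grid={"max_depth": [3]}, seed=0,
                            max_subsets=5)
        model = M.train_balanced_bagging(cfg, X, y)
        members = np.array([M.BalancedBaggingEnsemble._member_p1(t, X)
                            for t in model.clf.trees])
        assert np.allclose(model.clf.predict_proba(X)[:, 1],
                           members.mean(axis=0))

    def test_ensemble_brier_not_worse_than_worst_member(self):
        X, y = make_gaussian_problem(800, 0.1, 2.0, seed=9)
        half = len(y) // 2
        cfg = M.ModelConfig("DTBAG", grid={"max_depth": [3]}, seed=0,
                            max_subsets=6)
        model = M.train_balanced_bagging(cfg, X[:half], y[:half])
        X_ev, y_ev = X[half:], y[half:]
        ens = C.brier(model.clf.predict_proba(X_ev)[:, 1], y_ev)
        worst = max(C.brier(M.BalancedBaggingEnsemble._member_p1(t, X_ev),
                            y_ev) for t in model.clf.trees)
        assert ens <= worst + 1e-12


class TestAdaBoost:
    def test_one_round_equals_best_stump(self):
        X, y = make_gaussian_problem(300, 0.3, 2.0, seed=10)
        cfg = M.ModelConfig("ADABST", grid={"n_estimators": [1],
                                            "learning_rate": [1.0]}, seed=0)
        model = M.train_adaboost(cfg, X, y)
        stump = DecisionTreeClassifier(max_depth=1).fit(X, y)
        assert np.array_equal(model.clf.predict(X), stump.predict(X))

    def test_separable_fixture_perfect_within_50_rounds(self):
        X, y = separable_problem(seed=11)
        cfg = M.ModelConfig("ADABST", grid={"n_estimators": [50],
                                            "learning_rate": [1.0]}, seed=0)
        model = M.train_adaboost(cfg, X, y)
        from sklearn.metrics import f1_score
        assert f1_score(y, model.clf.predict(X)) == 1.0

    def test_training_error_non_increasing_on_fixture(self):
        X, y = make_gaussian_problem(500, 0.3, 2.5, seed=12)
        cfg = M.ModelConfig("ADABST", grid={"n_estimators": [40],
                                            "learning_rate": [1.0]}, seed=0)
        model = M.train_adaboost(cfg, X, y)
        errors = [1 - s for s in model.clf.staged_score(X, y)]
        # overall trend must be downward, ending at its minimum range
        assert errors[-1] <= errors[0]
        assert min(errors[-5:]) <= min(errors[:5])


class TestRusBoost:
    def test_rounds_use_balanced_sets_and_model_beats_single_stump(self):
        X, y = make_gaussian_problem(8000, prevalence=0.005, separation=2.5,
                                     n_features=4, seed=13)
        cfg = M.ModelConfig("RUBST", grid={"n_estimators": [80],
                                           "learning_rate": [1.0]}, seed=0)
        model = M.train_rusboost(cfg, X, y)
        from sklearn.metrics import f1_score
        stump = DecisionTreeClassifier(max_depth=1).fit(X, y)
        f1_boost = f1_score(y, model.clf.predict(X), zero_division=0)
        f1_stump = f1_score(y, stump.predict(X), zero_division=0)
        assert f1_boost > f1_stump

    def test_balanced_input_behaves_like_adaboost(self):
        X, y = make_gaussian_problem(400, prevalence=0.5, separation=2.0,
                                     n_features=2, seed=14)
        cfg = M.ModelConfig("RUBST", grid={"n_estimators": [60],
                                           "learning_rate": [1.0]}, seed=0)
        ru = M.train_rusboost(cfg, X, y)
        cfg2 = M.ModelConfig("ADABST", grid={"n_estimators": [60],
                                             "learning_rate": [1.0]}, seed=0)
        ada = M.train_adaboost(cfg2, X, y)
        agree = (ru.clf.predict(X) == ada.clf.predict(X)).mean()
        assert agree > 0.9


class TestPredictAndClassify:
    def test_strict_threshold(self):
        assert M.classify([0.51, 0.50, 0.0]).tolist() == [1, 0, 0]

    def test_unscaled_matrix_warns(self):
        X, y = separable_problem()
        cfg = M.ModelConfig("RULR", grid={"C": [1.0]}, seed=0, max_subsets=1)
        model = M.train_rus_best(cfg, X, y, X, y)
        with pytest.warns(UserWarning, match="unscaled"):
            M.predict_scores(model, X * 100)

    def test_svm_distance_pipeline_consistency(self):
        """Class labels from thresholding isotonic-calibrated SVM
        distances agree with classify() on the calibrated probabilities."""
        X, y = make_gaussian_problem(600, 0.3, 2.0, seed=15)
        cfg = M.ModelConfig("RUSVM", grid={"C": [10]}, seed=0, max_subsets=2)
        model = M.train_rus_best(cfg, X, y, X, y)
        model.fit_calibrator(X, y)
        p = model.predict_calibrated(X)
        assert np.array_equal(M.classify(p, 0.5), model.predict_labels(X))


class TestAllSchemesBeatTrivialClassifier:
    @pytest.mark.parametrize("scheme", M.SCHEMES)
    def test_f1_above_zero_at_low_prevalence(self, scheme):
        X, y = make_gaussian_problem(4000, prevalence=0.01, separation=3.5,
                                     n_features=4, seed=20)
        half = len(y) // 2
        grid = {"svm-rbf": {"C": [10]}, "logistic": {"C": [1.0]},
                "decision-tree": {"max_depth": [3]},
                "decision-stump": {"n_estimators": [60],
                                   "learning_rate": [1.0]}}[
            M._BASE_ALGORITHM[scheme]]
        cfg = M.ModelConfig(scheme, grid=grid, seed=0, max_subsets=5)
        model = M.train_scheme(cfg, X[:half], y[:half],
                               X[half:], y[half:])
        from sklearn.metrics import f1_score
        assert f1_score(y[half:], model.clf.predict(X[half:]),
                        zero_division=0) > 0.0


class TestParameterRecovery:
    """On fabricated alignments (0.5% mislocation, ~50k reads) the
    misaligned class is recoverable: the two best published schemes
    reach F1 >= 0.9 in this easy synthetic regime."""

    @pytest.mark.parametrize("scheme,grid,kw", [
        ("ADABST", {"n_estimators": [200], "learning_rate": [1.0]}, {}),
        ("RUSVMS", {"C": [10]}, {"max_subsets": 10}),
    ])
    def test_best_schemes_reach_f1_090(self, training_universe, scheme,
                                       grid, kw):
        model = M.MisalignmentModel.from_dataframe(
            training_universe["table"], scheme=scheme, grid=grid,
            train_fraction=0.2, seed=1, **kw)
        res = model.fit()
        from sklearn.metrics import f1_score
        pred = res.model.clf.predict(res.Xs_test)
        assert f1_score(res.y_test, pred, zero_division=0) >= 0.9


class TestFacade:
    def test_fit_summary_and_recalibration_path(self, small_universe,
                                                small_feature_table):
        model = M.MisalignmentModel.from_dataframe(
            small_feature_table, scheme="DTBAG",
            grid={"max_depth": [3]}, train_fraction=0.5, seed=0,
            max_subsets=10)
        res = model.fit()
        assert 0.0 <= res.f1 <= 1.0
        assert res.brier is not None and res.brier < 0.25
        text = res.summary()
        assert "DTBAG" in text and "Brier" in text
        mapping, table = res.recalibrate(small_universe["records"],
                                         small_universe["ref"])
        assert set(table.columns) == {"READ_KEY", "P_MISALIGN", "MAPQ_OLD",
                                      "MAPQ_NEW"}
        assert all(0 <= q <= 60 for q in mapping.values())
        # multi-mapped reads keep their MAPQ: absent from the mapping
        from mapqcal import features as F
        multi = {r.key() for r in small_universe["records"]
                 if r.is_primary_mapped and F.is_multimapped(r)}
        assert not (multi & set(mapping))

    def test_determinism(self, small_feature_table):
        kw = dict(scheme="RULR", grid={"C": [1.0]}, train_fraction=0.5,
                  seed=3, max_subsets=3)
        r1 = M.MisalignmentModel.from_dataframe(small_feature_table, **kw).fit()
        r2 = M.MisalignmentModel.from_dataframe(small_feature_table, **kw).fit()
        assert r1.f1 == r2.f1
        assert np.array_equal(r1.prob_iso, r2.prob_iso)

    def test_svm_without_calibrator_rejected_for_recalibration(self):
        X, y = separable_problem()
        cfg = M.ModelConfig("RUSVM", grid={"C": [10]}, seed=0, max_subsets=1)
        model = M.train_rus_best(cfg, X, y, X, y)
        with pytest.raises(ValueError, match="calibrator"):
            model.predict_calibrated(X)
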