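"""Scaffold/time splits, the stacked ensemble, isotonic calibration,
evaluation metrics, and hyperparameter search."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from masldscreen.models import (
    assert_scaffold_disjoint, calibrate_isotonic, evaluate_predictions,
    hosmer_lemeshow, make_splits, murcko_scaffold, pick_threshold,
    train_stacked_model, tune_hyperparameters,
)


class _Constant:
    """Degenerate base learner: p = 0.5 everywhere."""

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        n = len(X)
        return np.column_stack([np.full(n, 0.5), np.full(n, 0.5)])


def _cheap_factory(seed):
    return {
        "lr": LogisticRegression(max_iter=500),
        "c1": _Constant(),
        "c2": _Constant(),
    }


class TestSplits:
    def test_two_scaffolds_two_folds(self):
        smiles = ["c1ccccc1O", "c1ccccc1N", "C1CCCCC1O", "C1CCCCC1N"]
        plan = make_splits(smiles, k=2, kind="scaffold")
        assert_scaffold_disjoint(plan)
        assert plan.fold_of[0] == plan.fold_of[1]
        assert plan.fold_of[2] == plan.fold_of[3]
        assert plan.fold_of[0] != plan.fold_of[2]

    def test_salt_free_duplicate_shares_fold(self):
        smiles = ["CCOc1ccccc1", "CCOc1ccccc1", "C1CCNCC1", "c1ccncc1"]
        plan = make_splits(smiles, k=2, kind="scaffold")
        assert plan.fold_of[0] == plan.fold_of[1]

    def test_scaffolds_intact_and_balanced(self, small_dataset):
        lib = small_dataset["library"]
        plan = make_splits(list(lib["smiles"]), k=5, kind="scaffold")
        assert_scaffold_disjoint(plan)
        sizes = np.bincount(plan.fold_of, minlength=5)
        # greedy packing: within the largest scaffold-group size of balance
        groups = {}
        for s in lib["smiles"]:
            key = murcko_scaffold(s)
            groups[key] = groups.get(key, 0) + 1
        assert sizes.max() - sizes.min() <= max(groups.values())

    def test_fewer_scaffolds_than_folds_errors(self):
        with pytest.raises(ValueError, match="smaller k"):
            make_splits(["CCO", "CCC"], k=3, kind="scaffold")

    def test_time_splits_monotone(self):
        ts = [5, 3, 1, 4, 2, 0]
        plan = make_splits(["CCO"] * 6, k=3, kind="time", timestamps=ts)
        order = np.asarray(ts)
        for fold in range(2):
            assert order[plan.fold_of == fold].max() < \
                order[plan.fold_of == fold + 1].min()

    def test_tied_timestamps_stable(self):
        plan = make_splits(["CCO"] * 6, k=2, kind="time", timestamps=[1] * 6)
        assert list(plan.fold_of) == [0, 0, 0, 1, 1, 1]


class TestStackedModel:
    def _separable(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        y = np.arange(n) % 2
        X = rng.normal(size=(n, 4))
        X[:, 0] += 8 * y
        fold = np.arange(n) % 3
        from masldscreen.models import SplitPlan
        return X, y, SplitPlan(fold_of=fold, kind="time")

    def test_separable_oof_auc_is_one(self):
        X, y, plan = self._separable()
        model = train_stacked_model(X, y, plan, learner_factory=_cheap_factory)
        assert model.metrics["oof_roc_auc"] == 1.0

    def test_permuted_labels_auc_near_half(self):
        # features carry no information: AUC concentrates at 0.5
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(80, 5))
            y = rng.permutation(np.arange(80) % 2)
            from masldscreen.models import SplitPlan
            plan = SplitPlan(fold_of=np.arange(80) % 4, kind="time")
            m = train_stacked_model(X, y, plan, learner_factory=_cheap_factory)
            aucs.append(m.metrics["oof_roc_auc"])
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_meta_prefers_informative_learner(self):
        X, y, plan = self._separable()
        model = train_stacked_model(X, y, plan, learner_factory=_cheap_factory)
        w = model.meta_weights
        assert abs(w["lr"]) > abs(w["c1"])
        assert abs(w["lr"]) > abs(w["c2"])

    def test_calibrated_outputs_in_unit_interval(self):
        X, y, plan = self._separable()
        model = train_stacked_model(X, y, plan, learner_factory=_cheap_factory)
        p = model.predict_proba(X)
        assert np.all((p >= 0) & (p <= 1))

    def test_single_class_training_fold_skipped_with_warning(self):
        from masldscreen.models import SplitPlan
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3))
        plan = SplitPlan(fold_of=np.repeat([0, 1], 20), kind="time")
        y = np.r_[np.ones(20, dtype=int), np.arange(20) % 2]
        # fold 1's training part (fold 0) is all-active -> skipped
        with pytest.warns(UserWarning, match="single-class"):
            with pytest.raises(ValueError, match="single-class"):
                train_stacked_model(X, y, plan, learner_factory=_cheap_factory)

    def test_all_folds_single_class_errors(self):
        from masldscreen.models import SplitPlan
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3))
        plan = SplitPlan(fold_of=np.repeat([0, 1], 20), kind="time")
        y = np.repeat([0, 1], 20)
        with pytest.warns(UserWarning, match="single-class"):
            with pytest.raises(ValueError, match="every fold"):
                train_stacked_model(X, y, plan, learner_factory=_cheap_factory)


class TestIsotonic:
    def test_perfectly_calibrated_input_near_identity(self):
        scores = np.repeat([0.2, 0.5, 0.8], 50)
        rng = np.random.default_rng(0)
        labels = (rng.random(150) < scores).astype(int)
        iso = calibrate_isotonic(scores, labels)
        for s in (0.2, 0.5, 0.8):
            emp = labels[scores == s].mean()
            assert iso.predict([s])[0] == pytest.approx(emp, abs=1e-9)

    def test_brier_non_increasing_on_fit_set(self, rng):
        scores = rng.random(200)
        labels = (rng.random(200) < scores ** 2).astype(int)
        iso = calibrate_isotonic(scores, labels)
        before = np.mean((scores - labels) ** 2)
        after = np.mean((iso.predict(scores) - labels) ** 2)
        assert after <= before + 1e-12

    def test_pav_pools_anti_monotone_block(self):
        # hand PAV trace: y = [1,1,1,0,0,0] against increasing scores pools
        # everything into a single 0.5 block
        iso = calibrate_isotonic([1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 0, 0])
        np.testing.assert_allclose(iso.predict([1, 2, 3, 4, 5, 6]), 0.5)

    def test_monotone_output(self, rng):
        scores = rng.random(100)
        labels = (rng.random(100) < scores).astype(int)
        iso = calibrate_isotonic(scores, labels)
        grid = np.linspace(0, 1, 50)
        out = iso.predict(grid)
        assert np.all(np.diff(out) >= -1e-12)

    def test_single_class_identity_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            iso = calibrate_isotonic([0.2, 0.8], [1, 1])
        assert iso.predict([0.3])[0] == pytest.approx(0.3)


class TestEvaluation:
    def test_perfect_predictions(self):
        m = evaluate_predictions([0.0, 1.0, 0.0, 1.0], [0, 1, 0, 1])
        assert m["brier"] == 0.0
        assert m["mcc"] == 1.0
        assert m["f1"] == 1.0

    def test_uninformative_half_probabilities(self):
        m = evaluate_predictions([0.5] * 4, [0, 1, 0, 1])
        assert m["brier"] == 0.25

    def test_single_class_test_set_missing_auc(self):
        m = evaluate_predictions([0.2, 0.4, 0.6], [1, 1, 1])
        assert np.isnan(m["roc_auc"])

    def test_hosmer_lemeshow_perfect_bins(self):
        # every bin's mean prediction equals its event rate -> stat 0, p -> 1
        probs = np.repeat(np.linspace(0.1, 0.9, 5), 10)
        labels = np.concatenate([
            np.r_[np.ones(int(round(p * 10))), np.zeros(10 - int(round(p * 10)))]
            for p in np.linspace(0.1, 0.9, 5)])
        stat, p = hosmer_lemeshow(probs, labels, bins=5)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_threshold_rules(self):
        probs = [0.1, 0.4, 0.6, 0.9]
        labels = [0, 0, 1, 1]
        assert 0.4 < pick_threshold(probs, labels, "f1") <= 0.6
        assert 0.4 < pick_threshold(probs, labels, "youden") <= 0.6


class TestTuning:
    def test_budget_one_returns_single_point(self):
        res = tune_hyperparameters(lambda p: p["x"], {"x": ("uniform", 0, 1)},
                                   budget=1, seed=4)
        assert len(res["trials"]) == 1
        assert res["best_params"]["x"] == res["trials"][0][0]["x"]

    def test_deterministic_given_seed(self):
        space = {"x": ("uniform", 0, 1), "n": ("int", 1, 10)}
        a = tune_hyperparameters(lambda p: p["x"] + p["n"], space, 25, seed=9)
        b = tune_hyperparameters(lambda p: p["x"] + p["n"], space, 25, seed=9)
        assert a["trials"] == b["trials"]

    def test_grid_enumeration_finds_monotone_endpoint(self):
        res = tune_hyperparameters(lambda p: p["x"],
                                   {"x": ("choice", [1, 2, 3, 4, 5])},
                                   budget=1, method="grid")
        assert res["best_params"]["x"] == 5
        assert len(res["trials"]) == 5

    def test_tpe_beats_startup_on_smooth_objective(self):
        obj = lambda p: -(p["x"] - 0.7) ** 2
        res = tune_hyperparameters(obj, {"x": ("uniform", 0, 1)}, budget=40,
                                   seed=2, n_startup=8)
        assert abs(res["best_params"]["x"] - 0.7) < 0.15
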