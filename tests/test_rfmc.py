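import numpy as np
import pandas as pd
import pytest

from benthicmap.rfmc import (
    MCParams,
    RFParams,
    SimulationResult,
    extract_training_table,
    oob_indices,
    run_monte_carlo,
    summarize_ensemble,
    tune_hyperparameters,
)


def toy_table(n=160, p=6, seed=0, separable=True, n_classes=4):
    """Feature table with class defined by thresholds on the first feature
    (perfectly separable when ``separable``), plus noise features."""
    g = np.random.default_rng(seed)
    X = g.normal(size=(n, p))
    qs = np.quantile(X[:, 0], np.linspace(0, 1, n_classes + 1)[1:-1])
    labels = np.array(["bare", "kelp", "mixed", "red"])[:n_classes]
    y = labels[np.searchsorted(qs, X[:, 0])]
    if not separable:
        y = g.permutation(y)
    table = pd.DataFrame(X, columns=[f"f{i}" for i in range(p)])
    table["class"] = y
    table["drop_id"] = np.arange(n) // 3
    return table


FAST = dict(rf=RFParams(ntree=40, mtry=2), mc=MCParams(n_sim=6, base_seed=3))


class TestTrainingTable:
    def test_row_per_observation_on_valid_cells(self, small_run):
        res = small_run
        truth = res.truth
        on_mask = res.screened.mask[truth["row"], truth["col"]]
        table = extract_training_table(res.screened, truth[on_mask])
        assert len(table) == int(on_mask.sum())
        assert set(res.screened.names) < set(table.columns)

    def test_masked_observations_dropped_with_warning(self, small_run):
        res = small_run
        truth = res.truth.copy()
        r0, c0 = np.argwhere(~res.screened.mask)[0]
        bad = pd.DataFrame(
            [{"drop_id": 999, "row": r0, "col": c0, "class": "kelp"}]
        )
        with pytest.warns(UserWarning, match="dropped 1"):
            table = extract_training_table(
                res.screened, pd.concat([truth, bad], ignore_index=True)
            )
        assert len(table) == int(res.screened.mask[truth["row"], truth["col"]].sum())

    def test_out_of_grid_observation_rejected(self, small_run):
        truth = pd.DataFrame(
            [{"drop_id": 0, "row": 10_000, "col": 0, "class": "kelp"}]
        )
        with pytest.raises(ValueError):
            extract_training_table(small_run.screened, truth)


class TestMonteCarlo:
    def test_same_base_seed_reproduces_metric_sequences(self):
        table = toy_table()
        a = run_monte_carlo(table, **FAST)
        b = run_monte_carlo(table, **FAST)
        assert [r.validation_accuracy for r in a] == [
            r.validation_accuracy for r in b
        ]
        assert [r.train_accuracy for r in a] == [r.train_accuracy for r in b]
        pd.testing.assert_frame_equal(a[0].importance, b[0].importance)

    def test_separable_threshold_rule_is_learned(self):
        # noiseless single-threshold rule: effectively error-free
        results = run_monte_carlo(toy_table(separable=True, n_classes=2), **FAST)
        summary = summarize_ensemble(results)
        assert summary.mean_validation_accuracy >= 0.95
        # four thresholds on one feature: still close to perfect
        results4 = run_monte_carlo(toy_table(separable=True), **FAST)
        assert summarize_ensemble(results4).mean_validation_accuracy >= 0.9

    def test_permutation_null_matches_majority_baseline(self):
        table = toy_table(separable=False)
        results = run_monte_carlo(table, **FAST)
        summary = summarize_ensemble(results)
        majority = table["class"].value_counts(normalize=True).max()
        sd = max(summary.sd_validation_accuracy, 1e-6)
        assert summary.mean_validation_accuracy <= majority + 3 * sd

    def test_separable_rule_tops_importance_ranking(self):
        results = run_monte_carlo(toy_table(separable=True), **FAST)
        summary = summarize_ensemble(results)
        assert summary.importance["model"].idxmax() == "f0"

    def test_oob_reconstruction_reproduces_sklearn_oob_score(self):
        table = toy_table(n=120)
        res = run_monte_carlo(
            table, RFParams(ntree=80, mtry=2), MCParams(n_sim=1, base_seed=5)
        )[0]
        forest = res.model
        X = table[res.feature_names].to_numpy()
        classes = list(res.per_class.index)
        y = np.array([classes.index(c) for c in table["class"]])
        # the training rows for sim 0 are recoverable from the seed
        rng = np.random.default_rng(5)
        order = rng.permutation(len(table))
        train_idx = np.sort(order[: round(0.7 * len(table))])
        Xt, yt = X[train_idx], y[train_idx]

        votes = np.zeros((len(train_idx), len(classes)))
        for tree in forest.estimators_:
            oob = oob_indices(tree, len(train_idx))
            pred = tree.predict(Xt[oob]).astype(int)
            votes[oob, pred] += 1
        seen = votes.sum(axis=1) > 0
        acc = (votes[seen].argmax(axis=1) == yt[seen]).mean()
        assert acc == pytest.approx(forest.oob_score_, abs=1e-12)

    def test_mtry_beyond_predictor_count_rejected(self):
        with pytest.raises(ValueError):
            run_monte_carlo(toy_table(p=4), RFParams(mtry=10), MCParams(n_sim=1))

    def test_single_class_table_rejected(self):
        table = toy_table()
        table["class"] = "kelp"
        with pytest.raises(ValueError):
            run_monte_carlo(table, **FAST)

    def test_stratified_split_keeps_every_class_in_training(self):
        table = toy_table(n=40)
        results = run_monte_carlo(
            table, RFParams(ntree=20, mtry=2),
            MCParams(n_sim=4, base_seed=0, stratified=True),
        )
        assert len(results) == 4


class TestSummaries:
    def fake_result(self, sim_id, acc, f1, prec, rec):
        per_class = pd.DataFrame(
            {"precision": [prec], "recall": [rec], "f1": [f1]}, index=["kelp"]
        )
        imp = pd.DataFrame({"kelp": [1.0], "model": [1.0]}, index=["depth"])
        return SimulationResult(
            sim_id=sim_id, train_accuracy=acc, validation_accuracy=acc,
            per_class=per_class, importance=imp, model=None, feature_names=["depth"],
        )

    def test_mean_of_two_accuracies(self):
        summary = summarize_ensemble(
            [self.fake_result(0, 0.6, 1, 1, 1), self.fake_result(1, 0.8, 1, 1, 1)]
        )
        assert summary.mean_validation_accuracy == pytest.approx(0.7)

    def test_identical_results_have_zero_spread(self):
        summary = summarize_ensemble([self.fake_result(i, 0.7, 1, 1, 1) for i in range(3)])
        assert summary.sd_validation_accuracy == pytest.approx(0.0, abs=1e-12)
        assert summary.overfit_gap == pytest.approx(0.0, abs=1e-12)

    def test_f1_is_mean_of_per_simulation_f1_not_f1_of_means(self):
        # per-sim F1s {1.0, 0.0} with mean P = mean R = 0.75:
        # the reported value must be 0.5, not 2*.75*.75/1.5 = 0.75
        results = [
            self.fake_result(0, 0.7, f1=1.0, prec=1.0, rec=1.0),
            self.fake_result(1, 0.7, f1=0.0, prec=0.5, rec=0.5),
        ]
        summary = summarize_ensemble(results)
        assert summary.per_class.loc["kelp", "f1"] == pytest.approx(0.5)
        assert summary.per_class.loc["kelp", "precision"] == pytest.approx(0.75)


class TestTuning:
    def test_single_point_grid_matches_direct_run(self):
        table = toy_table()
        mc = MCParams(n_sim=4, base_seed=2)
        rf = RFParams(ntree=30, mtry=2)
        curve = tune_hyperparameters(table, {"ntree": [30]}, mc=mc, base_rf=rf)
        direct = summarize_ensemble(run_monte_carlo(table, rf, mc))
        assert len(curve) == 1
        assert curve.loc[0, "mean_validation_accuracy"] == pytest.approx(
            direct.mean_validation_accuracy
        )

    def test_mtry_sweep_3_to_14_yields_12_points(self):
        table = toy_table(p=14, n=80)
        curve = tune_hyperparameters(
            table, {"mtry": list(range(3, 15))},
            mc=MCParams(n_sim=2, base_seed=0), base_rf=RFParams(ntree=15),
        )
        assert len(curve) == 12

    def test_more_trees_never_hurt_beyond_noise(self):
        table = toy_table(seed=4)
        curve = tune_hyperparameters(
            table, {"ntree": [50, 350]},
            mc=MCParams(n_sim=4, base_seed=1), base_rf=RFParams(mtry=2),
        ).set_index("ntree")
        assert (
            curve.loc[350, "mean_validation_accuracy"]
            >= curve.loc[50, "mean_validation_accuracy"]
            - 2 * curve.loc[50, "sd_validation_accuracy"]
        )

    def test_unknown_hyperparameter_rejected(self):
        with pytest.raises(ValueError):
            tune_hyperparameters(toy_table(), {"depth_of_wisdom": [1]})
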