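"""Classifier training, evaluation metrics, maps, infection augmentation."""

import numpy as np
import pandas as pd
import pytest

from cuscuta_hsi import (EvaluationReport, MLPClassifier, NNConfig, PixelTable,
                         RFConfig, augment_with_infection_pixels,
                         default_scene_spec, evaluate, fit_minmax,
                         ndvi_segment, predict_map, render_scene,
                         train_neural_network, train_random_forest,
                         tune_hyperparameters)


def brute_force_report(y_true, y_pred, classes):
    """Independent tally of accuracy / per-class F1 / confusion matrix."""
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    accuracy = sum(t == p for t, p in zip(y_true, y_pred)) / len(y_true)
    f1s = []
    for c in classes:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1s.append(2 * precision * recall / (precision + recall)
                   if precision + recall else 0.0)
    return accuracy, cm, sum(f1s) / len(f1s)


def separable_table(n=200, seed=0, labels=("a", "b")):
    rng = np.random.default_rng(seed)
    half = n // 2
    spectra = np.vstack([rng.normal(0.2, 0.02, (half, 8)),
                         rng.normal(0.8, 0.02, (half, 8))])
    meta = pd.DataFrame({"label": [labels[0]] * half + [labels[1]] * half})
    return PixelTable(spectra, meta)


class TestEvaluationReport:
    def test_hand_oracle_binary_counts(self):
        # TP=2, FP=1, FN=1, TN=6 for class "pos"
        y_true = ["pos"] * 3 + ["neg"] * 7
        y_pred = ["pos", "pos", "neg", "pos"] + ["neg"] * 6
        report = EvaluationReport.from_predictions(y_true, y_pred,
                                                   ["neg", "pos"])
        row = report.per_class.loc["pos"]
        assert row["precision"] == pytest.approx(2 / 3)
        assert row["recall"] == pytest.approx(2 / 3)
        assert row["f1"] == pytest.approx(2 / 3)

    def test_constant_predictor_on_balanced_data(self):
        y_true = ["a"] * 5 + ["b"] * 5
        y_pred = ["a"] * 10
        report = EvaluationReport.from_predictions(y_true, y_pred, ["a", "b"])
        assert report.accuracy == pytest.approx(0.5)
        assert report.macro_f1 == pytest.approx((2 / 3 + 0.0) / 2)

    def test_perfect_predictions(self):
        y = ["a", "b", "c"] * 4
        report = EvaluationReport.from_predictions(y, y, ["a", "b", "c"])
        assert report.accuracy == 1.0 and report.macro_f1 == 1.0
        assert np.all(report.confusion == np.diag(np.diag(report.confusion)))

    @pytest.mark.parametrize("seed", range(10))
    def test_consistency_against_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        classes = ["a", "b", "c", "d"][: rng.integers(2, 5)]
        n = int(rng.integers(5, 200))
        y_true = rng.choice(classes, n)
        y_pred = rng.choice(classes, n)
        report = EvaluationReport.from_predictions(y_true, y_pred, classes)
        acc, cm, macro = brute_force_report(y_true, y_pred, classes)
        assert report.accuracy == pytest.approx(acc)
        assert report.macro_f1 == pytest.approx(macro)
        np.testing.assert_array_equal(report.confusion, cm)
        assert report.confusion.sum() == n
        assert report.accuracy == pytest.approx(
            np.trace(report.confusion) / report.n)
        assert report.macro_f1 == pytest.approx(report.per_class["f1"].mean())

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        y_true = rng.choice(["a", "b", "c"], 300)
        y_pred = rng.choice(["a", "b", "c"], 300)
        base = EvaluationReport.from_predictions(y_true, y_pred, ["a", "b", "c"])
        swap = {"a": "b", "b": "a", "c": "c"}
        permuted = EvaluationReport.from_predictions(
            [swap[v] for v in y_true], [swap[v] for v in y_pred],
            ["a", "b", "c"])
        perm = [1, 0, 2]
        np.testing.assert_array_equal(permuted.confusion,
                                      base.confusion[np.ix_(perm, perm)])
        assert permuted.macro_f1 == pytest.approx(base.macro_f1)


class TestRandomForest:
    def test_separable_data_perfect_training_accuracy(self):
        table = separable_table()
        model = train_random_forest(table, RFConfig(n_trees=20, max_depth=10))
        assert evaluate(model, table).accuracy == 1.0

    def test_capacity_monotonicity(self):
        table = separable_table(seed=1)
        tiny = train_random_forest(table, RFConfig(n_trees=1, max_depth=1, seed=0))
        full = train_random_forest(table, RFConfig(n_trees=20, max_depth=10, seed=0))
        assert evaluate(tiny, table).accuracy <= evaluate(full, table).accuracy

    def test_deterministic_under_seed(self, multiclass_dataset):
        train, test = multiclass_dataset["train"], multiclass_dataset["test"]
        config = RFConfig(n_trees=15, max_depth=10, seed=9)
        p1 = train_random_forest(train, config).predict(test.spectra)
        p2 = train_random_forest(train, config).predict(test.spectra)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self):
        table = separable_table(labels=("a", "a"))
        with pytest.raises(ValueError, match="2 classes"):
            train_random_forest(table)


class TestNeuralNetwork:
    def test_separable_data_high_val_f1(self):
        train = separable_table(400, seed=2)
        val = separable_table(100, seed=3)
        model = train_neural_network(
            train, NNConfig(hidden_sizes=(32, 16), learning_rate=3e-3,
                            epochs=40, batch_size=64, seed=0), val)
        assert evaluate(model, val).macro_f1 >= 0.99

    def test_zero_learning_rate_keeps_chance_level(self):
        train = separable_table(200, seed=4)
        config = NNConfig(hidden_sizes=(16, 8), learning_rate=0.0, epochs=3,
                          batch_size=64, seed=1)
        model = train_neural_network(train, config)
        untrained = MLPClassifier(config)
        rng = np.random.default_rng(config.seed)
        init = untrained._init_params(train.n_bands, 2, rng)
        for key, value in init.items():
            np.testing.assert_array_equal(model._params[key], value)

    def test_heavy_dropout_raises_training_loss(self):
        train = separable_table(300, seed=5)
        def loss_with(dropout):
            config = NNConfig(hidden_sizes=(32, 16), dropout_rates=dropout,
                              learning_rate=1e-3, epochs=10, batch_size=64,
                              seed=2)
            model = train_neural_network(train, config)
            return model.history_[-1]["train_loss"]
        assert loss_with((0.9, 0.9)) > loss_with((0.0, 0.0))

    def test_deterministic_under_seed(self):
        train = separable_table(200, seed=6)
        config = NNConfig(hidden_sizes=(16, 8), epochs=5, batch_size=64, seed=3)
        m1 = train_neural_network(train, config)
        m2 = train_neural_network(train, config)
        probe = np.random.default_rng(0).random((10, 8))
        np.testing.assert_array_equal(m1.predict_proba(probe),
                                      m2.predict_proba(probe))

    def test_unnormalized_input_warns(self, caplog):
        import logging

        table = separable_table(100, seed=7)
        table.spectra *= 50
        with caplog.at_level(logging.WARNING, logger="cuscuta_hsi.classify"):
            train_neural_network(table, NNConfig(hidden_sizes=(8, 4), epochs=1,
                                                 batch_size=64))
        assert "unnormalized" in caplog.text


class TestTuning:
    def test_singleton_space_returned(self):
        train = separable_table(100, seed=8)
        val = separable_table(50, seed=9)
        def trainer(config, t):
            return train_random_forest(t, RFConfig(n_trees=config["n_trees"],
                                                   max_depth=5))
        best, log = tune_hyperparameters(trainer, {"n_trees": [7]}, train, val,
                                         budget=3)
        assert best == {"n_trees": 7}
        assert len(log) == 3

    def test_best_dominates_all_trials(self, multiclass_dataset):
        train, val = multiclass_dataset["train"], multiclass_dataset["val"]
        space = {"n_trees": [3, 10, 25], "max_depth": [2, 8]}
        def trainer(config, t):
            return train_random_forest(t, RFConfig(seed=0, **config))
        best, log = tune_hyperparameters(trainer, space, train, val,
                                         budget=6, seed=1)
        best_row = log.loc[log["val_macro_f1"].idxmax()]
        assert (log["val_macro_f1"] <= best_row["val_macro_f1"] + 1e-12).all()
        assert best["n_trees"] == best_row["n_trees"]

    def test_zero_budget_rejected(self):
        with pytest.raises(ValueError):
            tune_hyperparameters(lambda c, t: None, {"a": [1]}, None, None,
                                 budget=0)


class TestPredictMap:
    def test_trained_model_maps_species_correctly(self, multiclass_dataset):
        train = multiclass_dataset["train"]
        scaler = multiclass_dataset["scaler"]
        model = train_random_forest(train, RFConfig(n_trees=30, max_depth=15))
        cube, truth = render_scene(default_scene_spec(
            seed=77, classes=[m for m in
                              __import__("cuscuta_hsi").default_species_models()
                              if m.name == "reflexa"], lines=64, samples=64))
        mask = ndvi_segment(cube)
        label_map, tallies, class_names = predict_map(model, cube, mask, scaler)
        plant = mask.mask & (truth.label_map > 0)
        correct_code = class_names.index("reflexa") + 1
        assert (label_map[plant] == correct_code).mean() >= 0.99
        assert set(np.unique(label_map)) <= set(range(len(class_names) + 1))

    def test_empty_mask_all_background(self, multiclass_dataset, vnir_scene):
        from cuscuta_hsi.segmentation import SegmentationMask

        cube, _ = vnir_scene
        model = train_random_forest(multiclass_dataset["train"],
                                    RFConfig(n_trees=5, max_depth=5))
        mask = SegmentationMask(np.zeros((cube.lines, cube.samples), bool), "t")
        label_map, tallies, _ = predict_map(model, cube, mask,
                                            multiclass_dataset["scaler"])
        assert (label_map == 0).all()
        assert all(v == 0 for v in tallies.values())


class TestInfectionAugmentation:
    def test_zero_rows_identity(self, multiclass_dataset):
        train = multiclass_dataset["train"]
        empty = train.select(np.zeros(len(train), dtype=bool))
        out = augment_with_infection_pixels(train, empty)
        assert len(out) == len(train)

    def test_row_count_additive(self, multiclass_dataset):
        train = multiclass_dataset["train"]
        extra = train.select(np.arange(len(train)) < 50)
        assert len(augment_with_infection_pixels(train, extra)) == len(train) + 50

    def test_inconsistent_labels_rejected(self, multiclass_dataset):
        train = multiclass_dataset["train"]
        bad = train.select(np.arange(len(train)) < 5)
        bad.meta["label"] = "unknown_species"
        with pytest.raises(ValueError, match="unknown_species"):
            augment_with_infection_pixels(train, bad)

    def test_retraining_with_infection_pixels_reduces_their_errors(self):
        from cuscuta_hsi import (SceneSpec, cloth_background, concat_tables,
                                 default_species_models, load_profile,
                                 make_pixel_dataset)

        cal = load_profile("vnir")
        host, campestris = [m for m in default_species_models()
                            if m.name in ("host", "campestris")]
        pure, infected = [], []
        for s in range(6):
            pure.append(render_scene(SceneSpec(
                64, 64, cal, (host, campestris),
                background_model=cloth_background(0.01), seed=s)))
            infected.append(render_scene(SceneSpec(
                64, 64, cal, (host, campestris),
                background_model=cloth_background(0.01),
                include_infection_sites=True, n_stems_per_class=5,
                seed=100 + s)))
        train = make_pixel_dataset(pure, [f"p{i}" for i in range(6)])
        inf_table = make_pixel_dataset(infected, [f"x{i}" for i in range(6)])
        infection_rows = inf_table.select(inf_table.meta["infection"].to_numpy())
        assert len(infection_rows) > 0
        scaler = fit_minmax(train)
        train_n = scaler.transform(train)
        target_n = scaler.transform(infection_rows)
        config = RFConfig(n_trees=40, max_depth=20, seed=0)
        base = train_random_forest(train_n, config)
        augmented_half = infection_rows.select(
            np.arange(len(infection_rows)) % 2 == 0)
        holdout = infection_rows.select(np.arange(len(infection_rows)) % 2 == 1)
        retrained = train_random_forest(
            augment_with_infection_pixels(train_n, scaler.transform(augmented_half)),
            config)
        holdout_n = scaler.transform(holdout)
        base_err = 1 - evaluate(base, holdout_n).accuracy
        retrained_err = 1 - evaluate(retrained, holdout_n).accuracy
        assert retrained_err < base_err
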