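import itertools

import numpy as np
import pandas as pd
import pytest

import prostasig as ps
from prostasig.classifier import (
    common_genes,
    evaluate,
    fold_change_filter,
    forward_stepwise_select,
    lda_fit,
    predict,
    train_mini_classifier,
    wilks_lambda,
    PUBLISHED_TEN_GENES,
)
from prostasig.phenotype import BINARY_LOW, BINARY_NONLOW, quartile_stratify


def _matrix(rows, genes, samples, scale="log2"):
    return ps.ExpressionMatrix(
        pd.DataFrame(rows, index=genes, columns=samples), scale=scale
    )


def _labels(low_samples, all_samples):
    return pd.Series(
        [BINARY_LOW if s in low_samples else BINARY_NONLOW for s in all_samples],
        index=all_samples,
    )


class TestCommonGenes:
    def test_identical_universes(self, tiny_expr):
        assert common_genes([tiny_expr, tiny_expr]) == sorted(tiny_expr.gene_ids)

    def test_three_way_intersection(self):
        mats = [
            _matrix(np.ones((3, 2)), list(g), ["s1", "s2"])
            for g in ("ABC", "BCD", "CBE")
        ]
        assert common_genes(mats) == ["B", "C"]

    def test_disjoint_universes_rejected(self):
        a = _matrix(np.ones((2, 2)), ["A", "B"], ["s1", "s2"])
        b = _matrix(np.ones((2, 2)), ["C", "D"], ["s1", "s2"])
        with pytest.raises(ValueError, match="share no genes"):
            common_genes([a, b])


class TestFoldChangeFilter:
    def _setting(self, low_vals, nonlow_vals):
        genes = [f"g{i}" for i in range(len(low_vals))]
        samples = ["l1", "l2", "n1", "n2"]
        rows = [[lv, lv, nv, nv] for lv, nv in zip(low_vals, nonlow_vals)]
        expr = _matrix(rows, genes, samples, scale="linear")
        return expr, _labels({"l1", "l2"}, samples)

    def test_boundary_is_strict(self):
        # g0 sFC exactly 1.25 -> excluded (strict); g1 well above -> kept
        expr, labels = self._setting([4.0, 1.0], [5.0, 2.0])
        assert fold_change_filter(expr, labels, threshold=1.25) == ["g1"]

    def test_up_and_down_regulated_kept(self):
        expr, labels = self._setting([5.0, 5.2, 10.0], [6.3, 4.0, 10.1])
        kept = fold_change_filter(expr, labels, threshold=1.25)
        assert kept == ["g0", "g1"]  # +1.26 and -1.30; g2 at +1.01 excluded

    def test_log2_input_exponentiated_first(self):
        expr, labels = self._setting([2.0, 1.0], [3.2, 1.1])
        log_expr = ps.ExpressionMatrix(np.log2(expr.data), scale="log2")
        assert fold_change_filter(log_expr, labels) == fold_change_filter(expr, labels)

    def test_nonpositive_mean_gene_dropped(self):
        expr_data = pd.DataFrame(
            [[-1.0, -1.0, 5.0, 5.0], [1.0, 1.0, 5.0, 5.0]],
            index=["bad", "good"],
            columns=["l1", "l2", "n1", "n2"],
        )
        expr = ps.ExpressionMatrix(expr_data, scale="linear")
        labels = _labels({"l1", "l2"}, list(expr_data.columns))
        assert fold_change_filter(expr, labels) == ["good"]


class TestLDA:
    def test_axis_aligned_hand_example(self):
        # class low at x1 ~ {0,1}, class nonlow at x1 ~ {3,4}; x2 pure noise
        rows = np.array(
            [[0, 1, 0, 1, 3, 4, 3, 4],
             [0, 1, 1, 0, 0, 1, 1, 0]],
            dtype=float,
        )
        samples = [f"s{i}" for i in range(8)]
        expr = _matrix(rows, ["g1", "g2"], samples)
        labels = _labels(set(samples[:4]), samples)
        model = lda_fit(expr, labels, ["g1", "g2"])
        w = np.array(model.coefficients)
        # S_pooled = diag(1/3, 1/3); w = 3 * (3, 0)
        assert w == pytest.approx([9.0, 0.0], abs=1e-9)
        # equal priors: boundary at first-gene value 2
        assert model.threshold / w[0] == pytest.approx(2.0)
        assert model.training_accuracy == 100.0

    def test_coefficient_sign_convention_diagonal_case(self):
        rng = np.random.default_rng(5)
        n = 60
        x = rng.normal(size=(3, n))
        labels_arr = np.array([BINARY_LOW] * 20 + [BINARY_NONLOW] * 40)
        x[0, 20:] += 2.0  # up in non-low
        x[1, 20:] -= 2.0  # down in non-low
        samples = [f"s{i}" for i in range(n)]
        expr = _matrix(x, ["up", "down", "noise"], samples)
        model = lda_fit(expr, pd.Series(labels_arr, index=samples), ["up", "down", "noise"])
        assert model.coefficients[0] > 0
        assert model.coefficients[1] < 0

    def test_agrees_with_reference_lda(self):
        sklearn_lda = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(11)
        n, p = 120, 5
        x = rng.normal(size=(n, p))
        y = np.array([0] * 40 + [1] * 80)
        x[y == 1] += rng.normal(0.8, 0.2, size=p)
        samples = [f"s{i}" for i in range(n)]
        genes = [f"g{j}" for j in range(p)]
        expr = _matrix(x.T, genes, samples)
        labels = pd.Series(np.where(y == 0, BINARY_LOW, BINARY_NONLOW), index=samples)
        model = lda_fit(expr, labels, genes)
        ref = sklearn_lda.LinearDiscriminantAnalysis(solver="svd").fit(x, y)
        w = np.array(model.coefficients)
        cos = w @ ref.coef_[0] / (np.linalg.norm(w) * np.linalg.norm(ref.coef_[0]))
        assert cos == pytest.approx(1.0, abs=1e-6)
        ours = predict(model, expr)["label"].map({BINARY_LOW: 0, BINARY_NONLOW: 1})
        assert (ours.to_numpy() == ref.predict(x)).all()

    def test_singleton_class_rejected(self):
        samples = ["a", "b", "c", "d"]
        expr = _matrix(np.random.default_rng(0).normal(size=(2, 4)), ["g1", "g2"], samples)
        with pytest.raises(ValueError, match=">=2 samples per class"):
            lda_fit(expr, _labels({"a"}, samples), ["g1", "g2"])


class TestForwardStepwise:
    def test_dominant_signal_selected_first(self):
        rng = np.random.default_rng(2)
        n = 40
        x = rng.normal(size=(6, n))
        x[3, 20:] += 3.0
        samples = [f"s{i}" for i in range(n)]
        genes = [f"g{j}" for j in range(6)]
        expr = _matrix(x, genes, samples)
        labels = _labels(set(samples[:20]), samples)
        assert forward_stepwise_select(expr, labels, genes, n_features=2)[0] == "g3"

    def test_path_matches_exhaustive_wilks_oracle(self):
        rng = np.random.default_rng(6)
        n = 50
        x = rng.normal(size=(6, n))
        x[1, 25:] += 1.0
        x[4, 25:] -= 0.7
        samples = [f"s{i}" for i in range(n)]
        genes = [f"g{j}" for j in range(6)]
        expr = _matrix(x, genes, samples)
        labels = _labels(set(samples[:25]), samples)
        y_low = np.array([s in set(samples[:25]) for s in samples])

        def oracle_lambda(subset):
            sub = x[list(subset)].T
            xl, xn = sub[y_low], sub[~y_low]
            w = sum(
                (g - g.mean(axis=0)).T @ (g - g.mean(axis=0)) for g in (xl, xn)
            )
            t = (sub - sub.mean(axis=0)).T @ (sub - sub.mean(axis=0))
            return np.linalg.det(w) / np.linalg.det(t)

        first = min(range(6), key=lambda j: (oracle_lambda([j]), genes[j]))
        second = min(
            (j for j in range(6) if j != first),
            key=lambda j: (oracle_lambda([first, j]), genes[j]),
        )
        expected = [genes[first], genes[second]]
        assert forward_stepwise_select(expr, labels, genes, n_features=2) == expected

    def test_planted_informative_genes_recovered(self):
        rng = np.random.default_rng(10)
        n = 300
        n_noise = 200
        planted = [f"info{j:02d}" for j in range(10)]
        noise = [f"noise{j:03d}" for j in range(n_noise)]
        y_low = np.zeros(n, dtype=bool)
        y_low[:75] = True
        x = rng.normal(size=(10 + n_noise, n))
        for j in range(10):
            x[j, ~y_low] += 1.0 + 0.1 * j
        samples = [f"s{i}" for i in range(n)]
        expr = _matrix(x, planted + noise, samples)
        labels = _labels(set(samples[:75]), samples)
        selected = forward_stepwise_select(expr, labels, planted + noise, n_features=10)
        assert len(set(selected) & set(planted)) >= 8

    def test_too_many_features_rejected(self, tiny_expr):
        labels = _labels({"s1", "s2"}, tiny_expr.sample_ids)
        with pytest.raises(ValueError, match="exceeds"):
            forward_stepwise_select(tiny_expr, labels, ["a", "b"], n_features=3)


class TestTrainPredictEvaluate:
    def test_end_to_end_training_accuracy(self, classifier_setting):
        cfg, panel, family = classifier_setting
        train, _ = family[0]
        others = [e for e, _ in family[1:]]
        scores = ps.score_pipeline(train, panel.panel)
        panel_genes = {g for _, gs in panel.panel for g in gs}
        model, report, labels = train_mini_classifier(
            train, scores, "luminal", other_datasets=others, exclude_genes=panel_genes
        )
        assert len(model.genes) == 10
        assert not set(model.genes) & panel_genes
        assert report.percent_correct >= 90.0
        # predict on training data reproduces training accuracy
        assert model.training_accuracy == pytest.approx(report.percent_correct)

    def test_sibling_cohort_within_fifteen_points(self, classifier_setting):
        from dataclasses import replace

        cfg, panel, family = classifier_setting
        train, _ = family[0]
        others = [e for e, _ in family[1:]]
        scores = ps.score_pipeline(train, panel.panel)
        panel_genes = {g for _, gs in panel.panel for g in gs}
        model, report, _ = train_mini_classifier(
            train, scores, "luminal", other_datasets=others, exclude_genes=panel_genes
        )
        sib, _ = ps.simulate_bulk_cohort(replace(cfg, seed=cfg.seed + 101))
        sib_scores = ps.score_pipeline(sib, panel.panel)
        sib_labels = quartile_stratify(sib_scores.zlog2.loc["luminal"]).binary
        rep = evaluate(predict(model, sib)["label"], sib_labels)
        assert abs(rep.percent_correct - report.percent_correct) <= 15.0

    def test_training_is_deterministic(self, classifier_setting):
        cfg, panel, family = classifier_setting
        train, _ = family[0]
        scores = ps.score_pipeline(train, panel.panel)
        runs = [
            train_mini_classifier(train, scores, "luminal")[0] for _ in range(2)
        ]
        assert runs[0].genes == runs[1].genes
        assert runs[0].coefficients == runs[1].coefficients

    def test_missing_gene_raises_then_retrain_without_it(self, classifier_setting):
        cfg, panel, family = classifier_setting
        train, _ = family[0]
        scores = ps.score_pipeline(train, panel.panel)
        model, _, labels = train_mini_classifier(train, scores, "luminal")
        dropped = model.genes[0]
        reduced = train.subset_genes([g for g in train.gene_ids if g != dropped])
        with pytest.raises(ValueError, match=dropped):
            predict(model, reduced)
        # supported fallback: retrain on the remaining genes
        fallback = lda_fit(
            reduced.to_log2(pseudocount=1.0), labels, [g for g in model.genes if g != dropped]
        )
        assert len(fallback.genes) == 9
        predict(fallback, reduced)  # applies cleanly

    def test_confusion_counts_hand_example(self):
        pred = pd.Series(
            [BINARY_LOW] * 3 + [BINARY_NONLOW] * 7, index=[f"s{i}" for i in range(10)]
        )
        truth = pd.Series(
            [BINARY_LOW, BINARY_LOW, BINARY_NONLOW, BINARY_LOW] + [BINARY_NONLOW] * 6,
            index=[f"s{i}" for i in range(10)],
        )
        rep = evaluate(pred, truth)
        assert (rep.tp, rep.fp, rep.fn, rep.tn) == (2, 1, 1, 6)
        assert rep.percent_correct == 80.0
        assert evaluate(pred, pred).percent_correct == 100.0

    def test_model_json_round_trip(self, tmp_path):
        model = ps.DiscriminantModel(
            genes=list(PUBLISHED_TEN_GENES),
            coefficients=[0.1 * i - 0.4 for i in range(10)],
            threshold=1.5,
            priors=(0.25, 0.75),
            training_accuracy=93.0,
            params={"fc_threshold": 1.25},
        )
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ps.DiscriminantModel.from_json(path)
        assert back == model
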