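import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plantar.classifiers import (
    CartClassifier,
    CartConfig,
    DEFAULT_RANGES,
    FinetuneConfig,
    ImageClassifier,
    KnnConfig,
    KNNClassifier,
    PretrainedWeightsUnavailable,
    SplitCandidate,
    best_split,
    cnn_classify,
    euclidean_distance,
    finetune_preset,
    gini_impurity,
    tune_hyperparameter,
)


class TestEuclideanDistance:
    @pytest.mark.parametrize(
        "x,y,expected",
        [((0, 0), (3, 4), 5.0), ((1, 2, 3), (1, 2, 3), 0.0), ((0, 0, 0), (1, 2, 2), 3.0)],
    )
    def test_closed_form_cases(self, x, y, expected):
        assert euclidean_distance(x, y) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            euclidean_distance([1, 2], [1, 2, 3])


class TestKnn:
    def test_default_k_is_seven(self):
        assert KnnConfig().k == 7

    def test_query_on_training_point_returns_its_label(self):
        x = np.array([[0.0], [5.0], [9.0]])
        y = np.array(["a", "b", "c"])
        model = KNNClassifier(KnnConfig(k=1)).fit(x, y)
        assert model.predict([[5.0]])[0] == "b"

    def test_hand_enumerated_vote(self):
        # distances from 0.4: |0.4|, |0.6|, |9.6| -> neighbors A, A, B
        x = np.array([[0.0], [1.0], [10.0]])
        y = np.array(["A", "A", "B"])
        model = KNNClassifier(KnnConfig(k=3)).fit(x, y)
        assert model.predict([[0.4]])[0] == "A"
        probs = model.predict_proba([[0.4]])[0]
        assert dict(zip(model.classes_, probs)) == {"A": pytest.approx(2 / 3), "B": pytest.approx(1 / 3)}

    def test_k_larger_than_training_set_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            KNNClassifier(KnnConfig(k=5)).fit(np.zeros((3, 1)), np.array(["a", "b", "a"]))

    def test_agrees_with_brute_force_sort(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 50))
            x = rng.normal(size=(n, 3))
            y = rng.choice(["u", "v", "w"], size=n)
            k = int(rng.integers(1, 6))
            model = KNNClassifier(KnnConfig(k=k)).fit(x, y)
            queries = rng.normal(size=(5, 3))
            for q in queries:
                d = np.array([euclidean_distance(q, xi) for xi in x])
                order = sorted(range(n), key=lambda i: (d[i], i))[:k]
                votes = list(y[order])
                counts = {c: votes.count(c) for c in set(votes)}
                top = max(counts.values())
                tied = sorted(c for c, v in counts.items() if v == top)
                if len(tied) > 1:
                    means = {
                        c: np.mean([d[i] for i in order if y[i] == c]) for c in tied
                    }
                    best = min(means.values())
                    tied = sorted(c for c in tied if means[c] == best)
                assert model.predict([q])[0] == tied[0]

    def test_vote_tie_broken_by_mean_distance(self):
        # k=2: one neighbor of each class; "near" class has smaller distance
        x = np.array([[1.0], [-2.0], [50.0]])
        y = np.array(["near", "far", "far"])
        model = KNNClassifier(KnnConfig(k=2)).fit(x, y)
        assert model.predict([[0.0]])[0] == "near"

    def test_distance_tie_at_kth_neighbor_uses_index_order(self):
        # both candidates at distance 1; training index 0 wins the last slot
        x = np.array([[1.0], [-1.0], [0.1]])
        y = np.array(["a", "b", "c"])
        model = KNNClassifier(KnnConfig(k=2)).fit(x, y)
        probs = dict(zip(model.classes_, model.predict_proba([[0.0]])[0]))
        assert probs["c"] == pytest.approx(0.5)
        assert probs["a"] == pytest.approx(0.5)  # index 0 beats index 1
        assert probs["b"] == 0.0

    def test_round_trip_serialization(self, tmp_path, rng):
        x = rng.normal(size=(20, 4))
        y = rng.choice(["a", "b"], size=20)
        model = KNNClassifier().fit(x, y)
        back = KNNClassifier.load(model.save(tmp_path / "knn.json"))
        q = rng.normal(size=(5, 4))
        assert np.array_equal(back.predict(q), model.predict(q))


class TestGini:
    @pytest.mark.parametrize(
        "props,expected",
        [((1.0,), 0.0), ((0.5, 0.5), 0.5), ((1 / 3, 1 / 3, 1 / 3), 2 / 3)],
    )
    def test_closed_form(self, props, expected):
        assert gini_impurity(props) == pytest.approx(expected)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            gini_impurity([0.5, 0.6])
        with pytest.raises(ValueError):
            gini_impurity([-0.1, 1.1])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6))
    def test_bounded_and_maximized_at_uniform(self, weights):
        p = np.array(weights) / sum(weights)
        g = gini_impurity(p)
        n = p.size
        assert 0.0 <= g <= 1 - 1 / n + 1e-12
        assert g <= gini_impurity(np.full(n, 1 / n)) + 1e-12


class TestCart:
    def test_default_depth_is_nine(self):
        assert CartConfig().max_depth == 9

    def test_single_class_data_is_a_root_leaf(self):
        model = CartClassifier().fit(np.arange(6).reshape(-1, 1), np.array(["a"] * 6))
        assert model.tree_["leaf"] and model.depth == 0

    def test_one_dimensional_split_found_by_enumeration(self):
        x = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array(["A", "A", "B", "B"])
        cand = best_split(x, np.array([0, 0, 1, 1]), 2)
        assert cand.threshold_tk == pytest.approx(1.5)
        assert cand.cost_J == pytest.approx(0.0)
        assert (cand.m_left, cand.m_right) == (2, 2)
        model = CartClassifier().fit(x, y)
        assert model.tree_["threshold"] == pytest.approx(1.5)
        assert np.array_equal(model.predict(x), y)

    def test_split_candidate_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            SplitCandidate(
                feature_index=0, threshold_tk=1.0, cost_J=0.9,
                m_left=2, m_right=2, g_left=0.0, g_right=0.0,
            )

    def test_unlimited_depth_fits_consistent_data_exactly(self, rng):
        x = rng.normal(size=(60, 3))
        y = rng.choice(["p", "q", "r"], size=60)
        model = CartClassifier(CartConfig(max_depth=1000)).fit(x, y)
        assert np.array_equal(model.predict(x), y)

    def test_costs_match_sklearn_quality(self, rng):
        """Same training accuracy as sklearn's Gini tree at equal depth."""
        from sklearn.tree import DecisionTreeClassifier

        x = rng.normal(size=(80, 4))
        y = rng.choice(["a", "b"], size=80)
        ours = CartClassifier(CartConfig(max_depth=3)).fit(x, y)
        theirs = DecisionTreeClassifier(max_depth=3, criterion="gini", random_state=0).fit(x, y)
        acc_ours = (ours.predict(x) == y).mean()
        acc_theirs = (theirs.predict(x) == y).mean()
        assert acc_ours == pytest.approx(acc_theirs, abs=0.05)

    def test_round_trip_serialization(self, tmp_path, rng):
        x = rng.normal(size=(40, 2))
        y = rng.choice(["a", "b"], size=40)
        model = CartClassifier().fit(x, y)
        back = CartClassifier.load(model.save(tmp_path / "tree.json"))
        q = rng.normal(size=(10, 2))
        assert np.array_equal(back.predict(q), model.predict(q))


class TestImageBranch:
    def test_vgg_style_preset_carries_published_settings(self):
        cfg = finetune_preset("vgg16_style")
        assert cfg.input_size == 224
        assert cfg.fc_nodes == 1000
        assert cfg.dropout_rate == 0.6
        assert cfg.freeze_boundary == "block4"
        assert cfg.optimizer == "rmsprop"
        assert cfg.learning_rate == pytest.approx(1e-5)
        assert cfg.n_classes == 9

    def test_inception_style_preset(self):
        cfg = finetune_preset("inception_style")
        assert cfg.fc_nodes == 1024
        assert cfg.dropout_rate == 0.6

    def test_pretrained_backbones_require_local_weights(self):
        with pytest.raises(PretrainedWeightsUnavailable, match="pretrained"):
            ImageClassifier(finetune_preset("vgg16_style"))

    def test_dropout_layer_present_in_head(self):
        from plantar.nn import Dropout

        model = ImageClassifier(finetune_preset("tiny_test", dropout_rate=0.6))
        net = model._build((16, 16, 1))
        drops = [l for l in net.layers if isinstance(l, Dropout)]
        assert len(drops) == 1 and drops[0].rate == 0.6

    def test_tiny_backbone_overfits_separable_images(self, rng):
        """20 linearly separable synthetic images reach training f1 = 1
        within a 50-epoch budget."""
        images = rng.normal(0, 0.1, size=(20, 16, 16))
        labels = np.array(["bright"] * 10 + ["dark"] * 10)
        images[:10, 4:12, 4:12] += 3.0
        images[10:, 4:12, 4:12] -= 3.0
        cfg = finetune_preset("tiny_test", n_classes=2, epochs=50, batch_size=10, seed=0)
        model = cnn_classify(images, labels, cfg)
        from plantar.ensemble import confusion_and_macro_f1

        _, f1 = confusion_and_macro_f1(model.predict(images), labels)
        assert f1 == 1.0

    def test_probabilities_sum_to_one(self, rng):
        images = rng.normal(size=(12, 16, 16))
        labels = np.array(["a", "b", "c"] * 4)
        cfg = finetune_preset("tiny_test", n_classes=3, epochs=2, seed=1)
        model = cnn_classify(images, labels, cfg)
        probs = model.predict_proba(rng.normal(size=(7, 16, 16)))
        assert probs.shape == (7, 3)
        assert probs.sum(axis=1) == pytest.approx(np.ones(7), abs=1e-6)


class TestTuneHyperparameter:
    def test_published_search_ranges(self):
        assert DEFAULT_RANGES["knn"] == (1, 1000)
        assert DEFAULT_RANGES["cart"] == (0, 10)

    def test_single_candidate_range(self):
        best, trace = tune_hyperparameter(lambda k: 0.5, (7, 7), strategy="grid")
        assert best == 7 and trace == [(7, 0.5)]

    def test_grid_search_maximizes_its_own_trace(self, rng):
        from sklearn.model_selection import train_test_split

        x = np.concatenate([rng.normal(-3, 0.5, 60), rng.normal(3, 0.5, 60)])[:, None]
        y = np.array(["lo"] * 60 + ["hi"] * 60)
        tr, va = train_test_split(np.arange(120), test_size=0.3, random_state=0, stratify=y)

        def objective(k):
            from plantar.ensemble import confusion_and_macro_f1

            model = KNNClassifier(KnnConfig(k=k)).fit(x[tr], y[tr])
            _, f1 = confusion_and_macro_f1(model.predict(x[va]), y[va])
            return f1

        best, trace = tune_hyperparameter(objective, (1, 9), strategy="grid")
        assert max(s for _, s in trace) == dict(trace)[best]

    def test_ties_resolve_to_smallest_candidate(self):
        best, _ = tune_hyperparameter(lambda k: 1.0, (3, 8), strategy="grid")
        assert best == 3

    def test_random_strategy_is_seeded(self):
        a = tune_hyperparameter(lambda k: k % 5, (1, 100), strategy="random", seed=3)
        b = tune_hyperparameter(lambda k: k % 5, (1, 100), strategy="random", seed=3)
        assert a == b

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            tune_hyperparameter(lambda k: 0.0, (5, 1))
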