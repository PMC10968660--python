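"""Naive-Bayes wrapper: fitting rules, posteriors, CV fitness, fast route."""

import math

import numpy as np
import pandas as pd
import pytest

from metaselect import (
    CVFitnessEvaluator,
    FeatureMask,
    InvalidInputError,
    SynthSpec,
    cv_fitness,
    dataset_from_frame,
    generate_survey,
    nb_fit,
    nb_predict,
    nb_predict_proba,
    nb_predict_proba_many,
    stratified_kfold,
)
from metaselect.data import NEGATIVE, POSITIVE, apply_mask
from metaselect.naive_bayes import apply_mask_rows

from conftest import make_labeled_ds


def two_class_binary_feature():
    """Class A sees {1,1,0}; class B sees {0,0,1}: with add-one smoothing
    over the 2 observed categories P(1|A) = 3/5 and P(1|B) = 2/5."""
    frame = pd.DataFrame({"f": ["1", "1", "0", "0", "0", "1"]})
    labels = np.array(["A", "A", "A", "B", "B", "B"], dtype=object)
    return dataset_from_frame(
        frame, labels=labels, classes=["A", "B"], feature_kinds=["nominal"]
    )


class TestFit:
    def test_laplace_smoothing_hand_count(self):
        ds = two_class_binary_feature()
        model = nb_fit(ds, FeatureMask.ones(1))
        s = model.stats[0]
        i1 = s.categories.index("1")
        assert math.exp(s.log_probs[0, i1]) == pytest.approx(0.6)
        assert math.exp(s.log_probs[1, i1]) == pytest.approx(0.4)

    def test_priors_are_class_frequencies(self):
        ds = make_labeled_ds(6, 18, seed=0)
        model = nb_fit(ds, FeatureMask.ones(1))
        assert model.class_priors == pytest.approx([0.25, 0.75])

    def test_empty_mask_gives_prior_only_model(self):
        ds = make_labeled_ds(4, 12, seed=1)
        model = nb_fit(ds, FeatureMask.zeros(1))
        assert model.stats == []
        post = nb_predict_proba(model, [])
        assert post == pytest.approx([0.25, 0.75])

    def test_empty_training_set_rejected(self, tiny_mixed_ds):
        empty = tiny_mixed_ds.take([])
        with pytest.raises(InvalidInputError):
            nb_fit(empty, FeatureMask.ones(3))

    def test_model_serializes_to_json(self, tiny_mixed_ds):
        model = nb_fit(tiny_mixed_ds, FeatureMask.ones(3))
        import json

        doc = json.loads(model.to_json())
        assert doc["classes"] == [POSITIVE, NEGATIVE]
        assert len(doc["features"]) == 3


class TestPredict:
    def test_direct_bayes_arithmetic(self):
        ds = two_class_binary_feature()
        model = nb_fit(ds, FeatureMask.ones(1))
        post = nb_predict_proba(model, ["1"])
        # equal priors, P(1|A)=0.6, P(1|B)=0.4 -> posterior(A)=0.6
        assert post == pytest.approx([0.6, 0.4])

    def test_all_missing_instance_returns_priors(self):
        ds = two_class_binary_feature()
        model = nb_fit(ds, FeatureMask.ones(1))
        assert nb_predict_proba(model, [np.nan]) == pytest.approx([0.5, 0.5])

    def test_unseen_category_uses_smoothed_denominator(self):
        ds = two_class_binary_feature()
        model = nb_fit(ds, FeatureMask.ones(1))
        post = nb_predict_proba(model, ["never-seen"])
        # both classes get 1/(3+2): posterior falls back to priors
        assert post == pytest.approx([0.5, 0.5])

    def test_posterior_normalization_many(self, small_survey):
        ds, _ = small_survey
        model = nb_fit(ds, FeatureMask.ones(ds.n_features))
        reps = 10_000 // ds.n_instances + 1
        big = ds.take(np.tile(np.arange(ds.n_instances), reps)[:10_000])
        proba = nb_predict_proba_many(model, big)
        assert proba.shape == (10_000, 2)
        assert np.abs(proba.sum(axis=1) - 1.0).max() < 1e-9

    def test_log_space_matches_direct_product(self):
        """Independent oracle: direct probability products, no logs."""
        ds = two_class_binary_feature()
        frame = ds.frame.copy()
        frame["g"] = ["a", "b", "a", "b", "a", "b"]
        ds2 = dataset_from_frame(
            frame, labels=ds.labels, classes=["A", "B"],
            feature_kinds=["nominal", "nominal"],
        )
        model = nb_fit(ds2, FeatureMask.ones(2))

        def direct(instance):
            probs = []
            for c in range(2):
                p = model.class_priors[c]
                for value, s in zip(instance, model.stats):
                    idx = s.categories.index(value)
                    p *= math.exp(s.log_probs[c, idx])
                probs.append(p)
            total = sum(probs)
            return [x / total for x in probs]

        for instance in (["1", "a"], ["0", "b"], ["1", "b"]):
            assert nb_predict_proba(model, instance) == pytest.approx(
                direct(instance), abs=1e-9
            )


class TestCVFitness:
    def test_label_copy_feature_is_perfect(self):
        n = 40
        labels = np.array([POSITIVE, NEGATIVE] * (n // 2), dtype=object)
        frame = pd.DataFrame({"copy": labels.astype(object)})
        ds = dataset_from_frame(frame, labels=labels, classes=[POSITIVE, NEGATIVE])
        assert cv_fitness(ds, FeatureMask.ones(1), seed=0).fitness == 1.0

    def test_empty_mask_equals_prior_only_oracle(self):
        """Oracle: majority-class rate per fold, computed by hand."""
        ds = make_labeled_ds(24, 36, seed=2)
        result = cv_fitness(ds, FeatureMask.zeros(1), k=5, seed=3)
        codes = ds.label_codes()
        expected = []
        for _, valid in stratified_kfold(ds, k=5, seed=3):
            # prior-only model predicts the majority class (negative)
            expected.append(float(np.mean(codes[valid] == 1)))
        assert result.per_fold_accuracy == pytest.approx(expected)
        assert result.fitness == pytest.approx(np.mean(expected))

    def test_matches_hand_rolled_fold_loop(self, tiny_mixed_ds):
        """Oracle: independent re-implementation of the CV loop."""
        ds = tiny_mixed_ds
        mask = FeatureMask([1, 1, 0])
        result = cv_fitness(ds, mask, k=5, seed=11)
        accs = []
        for tr, va in stratified_kfold(ds, k=5, seed=11):
            model = nb_fit(ds.take(tr), mask)
            pred = nb_predict(model, apply_mask_rows(ds, mask, va))
            accs.append(float(np.mean(pred == ds.labels[va])))
        assert result.per_fold_accuracy == pytest.approx(accs)

    def test_pure_function_of_inputs(self, small_survey):
        ds, _ = small_survey
        mask = FeatureMask([i % 2 for i in range(ds.n_features)])
        a = cv_fitness(ds, mask, k=5, seed=5)
        b = cv_fitness(ds, mask, k=5, seed=5)
        assert a.fitness == b.fitness and a.per_fold_accuracy == b.per_fold_accuracy

    def test_adding_label_copy_never_hurts(self):
        """On noiseless nominal data a perfectly informative feature can
        only help the wrapper (100 random masks/datasets)."""
        rng = np.random.default_rng(0)
        for trial in range(100):
            n = 30
            labels = np.array(
                [POSITIVE] * 15 + [NEGATIVE] * 15, dtype=object
            )
            rng.shuffle(labels)
            frame = pd.DataFrame({
                f"noise{j}": rng.choice(["a", "b", "c"], n).astype(object)
                for j in range(3)
            })
            frame["copy"] = labels.astype(object)
            ds = dataset_from_frame(
                frame, labels=labels, classes=[POSITIVE, NEGATIVE]
            )
            ev = CVFitnessEvaluator(ds, k=5, seed=trial)
            base_bits = list(rng.integers(0, 2, 3)) + [0]
            with_copy = list(base_bits)
            with_copy[3] = 1
            assert ev(FeatureMask(with_copy)) >= ev(FeatureMask(base_bits))


class TestFastEvaluator:
    def test_agrees_with_reference_route(self, small_survey):
        ds, _ = small_survey
        ev = CVFitnessEvaluator(ds, k=5, seed=13)
        rng = np.random.default_rng(99)
        for _ in range(10):
            mask = FeatureMask(rng.integers(0, 2, ds.n_features))
            ref = cv_fitness(ds, mask, k=5, seed=13)
            fast = ev.fitness(mask)
            assert fast.per_fold_accuracy == pytest.approx(
                ref.per_fold_accuracy, abs=1e-12
            )

    def test_caches_by_mask_bits(self, small_survey):
        ds, _ = small_survey
        ev = CVFitnessEvaluator(ds, k=5, seed=0)
        m = FeatureMask.ones(ds.n_features)
        ev(m)
        ev(FeatureMask(list(m.bits)))
        assert ev.n_evaluations == 1
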