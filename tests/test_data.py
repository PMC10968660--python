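"""Dataset construction, diagnosis labelling, screening and partitioning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metaselect import (
    ConfigurationError,
    DiagnosisRule,
    FeatureMask,
    InvalidInputError,
    SplitSpec,
    apply_mask,
    dataset_from_frame,
    drop_unreliable_features,
    label_by_grip,
    stratified_kfold,
    stratified_split,
)
from metaselect.data import NEGATIVE, POSITIVE

from conftest import make_labeled_ds


class TestLabelByGrip:
    def table(self, rows):
        return pd.DataFrame(rows, columns=["sex", "grip_kg", "extra"])

    def test_thresholds_strictly_below(self):
        t = self.table([
            ("male", 27.9, "a"),    # below 28 -> positive
            ("male", 28.0, "a"),    # at threshold -> negative
            ("female", 16.0, "b"),  # at threshold -> negative
            ("female", 15.9, "b"),  # below 16 -> positive
        ])
        ds, n_dropped = label_by_grip(t)
        assert n_dropped == 0
        assert list(ds.labels) == [POSITIVE, NEGATIVE, NEGATIVE, POSITIVE]

    def test_missing_grip_and_bad_sex_dropped_and_counted(self):
        t = self.table([
            ("male", np.nan, "a"),
            ("unknown", 20.0, "a"),
            ("female", 10.0, "a"),
        ])
        ds, n_dropped = label_by_grip(t)
        assert n_dropped == 2
        assert ds.n_instances == 1 and ds.labels[0] == POSITIVE

    def test_grip_column_removed_from_features(self):
        t = self.table([("male", 20.0, "a"), ("female", 20.0, "b")])
        ds, _ = label_by_grip(t)
        assert "grip_kg" not in ds.feature_names
        assert "sex" in ds.feature_names and "extra" in ds.feature_names

    def test_missing_required_column_names_it(self):
        with pytest.raises(ConfigurationError, match="grip_kg"):
            label_by_grip(pd.DataFrame({"sex": ["male"]}))

    def test_rule_invariants(self):
        with pytest.raises(InvalidInputError):
            DiagnosisRule(male_threshold_kg=10.0, female_threshold_kg=16.0)


class TestDropUnreliable:
    def make(self, col, kind_hint=None, n=12):
        frame = pd.DataFrame({"f": col, "keep": np.arange(n, dtype=float)})
        return dataset_from_frame(frame)

    def test_five_or_fewer_responses_dropped_six_kept(self):
        five = [f"v{i}" for i in range(5)] + [np.nan] * 7
        six = [f"v{i % 2}" for i in range(6)] + [np.nan] * 6
        ds5, dropped5 = drop_unreliable_features(self.make(five))
        assert dropped5 == ["f"]
        ds6, dropped6 = drop_unreliable_features(self.make(six))
        assert dropped6 == []
        assert ds6.n_features == 2

    def test_id_like_nominal_dropped(self):
        ids = [f"id{i:03d}" for i in range(12)]
        ds, dropped = drop_unreliable_features(self.make(ids))
        assert dropped == ["f"]

    def test_numeric_unique_values_not_id_like(self):
        # distinct numeric measurements are not IDs
        ds = self.make(np.linspace(0, 1, 12))
        out, dropped = drop_unreliable_features(ds)
        assert dropped == []


class TestStratifiedSplit:
    def test_printed_cohort_counts(self):
        ds = make_labeled_ds(2564, 3924, seed=1)
        train, test = stratified_split(ds, SplitSpec(0.8, seed=3))
        assert train.class_counts() == {POSITIVE: 2051, NEGATIVE: 3139}
        assert test.class_counts() == {POSITIVE: 513, NEGATIVE: 785}

    def test_exact_small_arithmetic(self):
        ds = make_labeled_ds(5, 5)
        train, test = stratified_split(ds, SplitSpec(0.8, seed=0))
        assert train.class_counts() == {POSITIVE: 4, NEGATIVE: 4}
        assert test.class_counts() == {POSITIVE: 1, NEGATIVE: 1}

    def test_deterministic_under_seed(self):
        ds = make_labeled_ds(30, 50, seed=2)
        a = stratified_split(ds, SplitSpec(0.8, seed=9))
        b = stratified_split(ds, SplitSpec(0.8, seed=9))
        assert a[0].frame.equals(b[0].frame)
        assert (a[1].labels == b[1].labels).all()

    @given(
        n_pos=st.integers(2, 60),
        n_neg=st.integers(2, 60),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_conservation_and_floor_stratification(self, n_pos, n_neg, seed):
        ds = make_labeled_ds(n_pos, n_neg, seed=0)
        train, test = stratified_split(ds, SplitSpec(0.8, seed=seed))
        assert train.n_instances + test.n_instances == ds.n_instances
        tc, xc = train.class_counts(), test.class_counts()
        assert tc[POSITIVE] == int(np.floor(0.8 * n_pos))
        assert tc[NEGATIVE] == int(np.floor(0.8 * n_neg))
        assert tc[POSITIVE] + xc[POSITIVE] == n_pos

    def test_empty_class_rejected(self):
        ds = make_labeled_ds(4, 4)
        ds.classes.append("ghost")
        with pytest.raises(InvalidInputError):
            stratified_split(ds, SplitSpec(0.8, seed=0))


class TestStratifiedKFold:
    def test_balanced_ten_instances(self):
        ds = make_labeled_ds(5, 5, seed=3)
        codes = ds.label_codes()
        for _, valid in stratified_kfold(ds, k=5, seed=0):
            assert len(valid) == 2
            assert codes[valid].sum() == 1  # exactly one of each class

    def test_partition_property(self):
        ds = make_labeled_ds(23, 41, seed=4)
        folds = stratified_kfold(ds, k=5, seed=1)
        all_valid = np.concatenate([v for _, v in folds])
        assert sorted(all_valid) == list(range(ds.n_instances))
        for tr, va in folds:
            assert set(tr) & set(va) == set()
            assert len(tr) + len(va) == ds.n_instances

    def test_cohort_scale_fold_sizes(self):
        # integer division with remainder spread: 2051 = 411 + 4*410,
        # 3139 = 4*628 + 627
        ds = make_labeled_ds(2051, 3139, seed=5)
        codes = ds.label_codes()
        pos_sizes, neg_sizes = [], []
        for _, valid in stratified_kfold(ds, k=5, seed=0):
            pos_sizes.append(int((codes[valid] == 0).sum()))
            neg_sizes.append(int((codes[valid] == 1).sum()))
        assert set(pos_sizes) <= {410, 411} and sum(pos_sizes) == 2051
        assert set(neg_sizes) <= {627, 628} and sum(neg_sizes) == 3139

    @given(
        n_pos=st.integers(5, 50),
        n_neg=st.integers(5, 80),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_partition_random_configs(self, n_pos, n_neg, seed):
        ds = make_labeled_ds(n_pos, n_neg, seed=0)
        folds = stratified_kfold(ds, k=5, seed=seed)
        union = np.sort(np.concatenate([v for _, v in folds]))
        assert (union == np.arange(ds.n_instances)).all()
        codes = ds.label_codes()
        per_class = [[int((codes[v] == c).sum()) for _, v in folds] for c in (0, 1)]
        for sizes in per_class:
            assert max(sizes) - min(sizes) <= 1

    def test_class_smaller_than_k_rejected(self):
        ds = make_labeled_ds(3, 10)
        with pytest.raises(InvalidInputError):
            stratified_kfold(ds, k=5, seed=0)


class TestApplyMask:
    def test_identity_empty_and_partial(self, tiny_mixed_ds):
        ds = tiny_mixed_ds
        full = apply_mask(ds, FeatureMask.ones(3))
        assert full.feature_names == ds.feature_names
        empty = apply_mask(ds, FeatureMask.zeros(3))
        assert empty.n_features == 0
        assert (empty.labels == ds.labels).all()
        part = apply_mask(ds, FeatureMask([1, 0, 1]))
        assert part.feature_names == ["color", "smoker"]
        assert part.feature_kinds == ["nominal", "nominal"]

    def test_length_mismatch_rejected(self, tiny_mixed_ds):
        with pytest.raises(InvalidInputError):
            apply_mask(tiny_mixed_ds, FeatureMask([1, 0]))


def test_mask_bitstring_roundtrip_and_popcount():
    m = FeatureMask([1, 0, 1, 1, 0])
    assert m.popcount == 3
    assert FeatureMask.from_bitstring(m.to_bitstring()) == m
    with pytest.raises(InvalidInputError):
        FeatureMask([0, 2, 1])
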