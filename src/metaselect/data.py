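"""Core tabular data types for mixed-type survey data.

The central container is :class:`Dataset`: an instances × features grid of
mixed nominal/numeric cells with first-class missing values, plus an optional
binary diagnosis label.  Missingness is represented as NaN (numeric columns)
or NaN/None (object columns) and is *never* imputed — downstream components
(the naive-Bayes wrapper, the entropy filters) skip missing cells instead.

Also here: the handgrip-strength diagnosis rule, the unreliable-feature
screen, and deterministic stratified partitioning (hold-out split and k-fold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

NOMINAL = "nominal"
NUMERIC = "numeric"

#: Label tokens used throughout: positive class first (declaration order
#: matters for prediction tie-breaks).
POSITIVE = "sarcopenia"
NEGATIVE = "normal"


class InvalidInputError(ValueError):
    """Raised when an operation's structural precondition is violated."""


class ConfigurationError(ValueError):
    """Raised when a named column or option is missing or inconsistent."""


def is_missing(value) -> bool:
    """True for the missing-cell sentinel (None or NaN)."""
    if value is None:
        return True
    if isinstance(value, float):
        return np.isnan(value)
    return False


def _missing_mask(column: pd.Series) -> np.ndarray:
    return column.isna().to_numpy()


@dataclass
class Dataset:
    """Instances × mixed-type features, optionally labelled.

    Parameters
    ----------
    frame
        Feature values; columns are features.  Nominal columns hold category
        tokens (object dtype), numeric columns hold floats; NaN is missing.
    feature_kinds
        ``"nominal"`` or ``"numeric"`` per column, aligned with ``frame``.
    labels
        Per-instance binary label, or None before labelling.
    classes
        Class declaration order (ties at prediction go to the first).
        Defaults to order of first appearance in ``labels``.
    """

    frame: pd.DataFrame
    feature_kinds: list[str]
    labels: np.ndarray | None = None
    classes: list | None = None

    def __post_init__(self):
        self.frame = self.frame.reset_index(drop=True)
        if len(self.feature_kinds) != self.frame.shape[1]:
            raise InvalidInputError(
                f"feature_kinds has {len(self.feature_kinds)} entries for "
                f"{self.frame.shape[1]} feature columns"
            )
        bad = [k for k in self.feature_kinds if k not in (NOMINAL, NUMERIC)]
        if bad:
            raise InvalidInputError(f"unknown feature kinds: {bad}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != len(self.frame):
                raise InvalidInputError(
                    f"{len(self.labels)} labels for {len(self.frame)} instances"
                )
            if self.classes is None:
                seen: dict = {}
                for y in self.labels:
                    seen.setdefault(y, None)
                self.classes = list(seen)
        self._cache: dict = {}

    # -- basic geometry -------------------------------------------------
    @property
    def n_instances(self) -> int:
        return len(self.frame)

    @property
    def n_features(self) -> int:
        return self.frame.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.frame.columns)

    def label_codes(self) -> np.ndarray:
        """Labels as integer codes in class declaration order."""
        if self.labels is None:
            raise InvalidInputError("dataset has no labels")
        lut = {c: i for i, c in enumerate(self.classes)}
        return np.array([lut[y] for y in self.labels], dtype=np.int64)

    def class_counts(self) -> dict:
        codes = self.label_codes()
        return {c: int((codes == i).sum()) for i, c in enumerate(self.classes)}

    def take(self, indices: Sequence[int]) -> "Dataset":
        """Row subset (preserving order of ``indices``)."""
        idx = np.asarray(indices, dtype=np.int64)
        labels = self.labels[idx] if self.labels is not None else None
        return Dataset(
            self.frame.iloc[idx].reset_index(drop=True),
            list(self.feature_kinds),
            labels=labels,
            classes=list(self.classes) if self.classes else None,
        )


@dataclass(frozen=True)
class FeatureMask:
    """Binary inclusion vector over a dataset's features.

    Bit i = 1 means feature i is selected.  Immutable; hash/equality are by
    bit content so masks can key fitness caches.
    """

    bits: tuple

    def __init__(self, bits: Iterable[int]):
        arr = np.asarray(list(bits) if not isinstance(bits, np.ndarray) else bits)
        arr = arr.astype(np.int8)
        if arr.ndim != 1 or not np.isin(arr, (0, 1)).all():
            raise InvalidInputError("mask bits must be a flat 0/1 vector")
        object.__setattr__(self, "bits", tuple(int(b) for b in arr))

    def __len__(self) -> int:
        return len(self.bits)

    @property
    def popcount(self) -> int:
        return sum(self.bits)

    def asarray(self) -> np.ndarray:
        return np.array(self.bits, dtype=np.int8)

    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.asarray())

    def to_bitstring(self) -> str:
        return "".join(str(b) for b in self.bits)

    @classmethod
    def from_bitstring(cls, s: str) -> "FeatureMask":
        return cls([int(ch) for ch in s.strip()])

    @classmethod
    def ones(cls, n: int) -> "FeatureMask":
        return cls(np.ones(n, dtype=np.int8))

    @classmethod
    def zeros(cls, n: int) -> "FeatureMask":
        return cls(np.zeros(n, dtype=np.int8))


@dataclass(frozen=True)
class DiagnosisRule:
    """Sex-specific handgrip-strength thresholds (kg); diagnosis is
    *strictly below* threshold, so a grip exactly at threshold is negative."""

    male_threshold_kg: float = 28.0
    female_threshold_kg: float = 16.0

    def __post_init__(self):
        if self.female_threshold_kg <= 0 or self.male_threshold_kg <= 0:
            raise InvalidInputError("grip thresholds must be positive")
        if self.male_threshold_kg <= self.female_threshold_kg:
            raise InvalidInputError(
                "male threshold must exceed female threshold"
            )

    def threshold_for(self, sex: str) -> float:
        return self.male_threshold_kg if sex == "male" else self.female_threshold_kg


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/test hold-out specification."""

    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise InvalidInputError("train_fraction must be in (0, 1)")


_SEX_TOKENS = {
    "male": "male", "m": "male", "man": "male", "1": "male",
    "female": "female", "f": "female", "woman": "female", "2": "female",
}


def _normalize_sex(token) -> str | None:
    if is_missing(token):
        return None
    return _SEX_TOKENS.get(str(token).strip().lower())


def infer_feature_kinds(frame: pd.DataFrame) -> list[str]:
    """Numeric iff every non-missing cell parses as a float; else nominal.

    Survey ordinal codes therefore stay nominal unless the whole column is
    numeric — no scaling or recoding is ever applied.
    """
    kinds = []
    for col in frame.columns:
        s = frame[col]
        if pd.api.types.is_numeric_dtype(s):
            kinds.append(NUMERIC)
            continue
        nonmiss = s.dropna()
        if len(nonmiss) == 0:
            kinds.append(NOMINAL)
            continue
        parsed = pd.to_numeric(nonmiss, errors="coerce")
        kinds.append(NUMERIC if not parsed.isna().any() else NOMINAL)
    return kinds


def _parse_float(v) -> float:
    if pd.isna(v):
        return np.nan
    try:
        return float(v)  # exact round trip, unlike pandas' fast parser
    except (TypeError, ValueError):
        return np.nan


def _coerce_columns(frame: pd.DataFrame, kinds: list[str]) -> pd.DataFrame:
    out = {}
    for col, kind in zip(frame.columns, kinds):
        if kind == NUMERIC:
            out[col] = frame[col].map(_parse_float).astype(float)
        else:
            s = frame[col].astype(object)
            s = s.where(~frame[col].isna(), np.nan)
            out[col] = s
    return pd.DataFrame(out)


def dataset_from_frame(
    frame: pd.DataFrame,
    labels: np.ndarray | None = None,
    classes: list | None = None,
    feature_kinds: list[str] | None = None,
) -> Dataset:
    """Build a Dataset from a raw DataFrame, inferring kinds if not given."""
    kinds = feature_kinds or infer_feature_kinds(frame)
    return Dataset(_coerce_columns(frame, kinds), kinds, labels=labels, classes=classes)


def label_by_grip(
    records: pd.DataFrame,
    rule: DiagnosisRule = DiagnosisRule(),
    sex_col: str = "sex",
    grip_col: str = "grip_kg",
    drop_columns: Sequence[str] = (),
) -> tuple[Dataset, int]:
    """Derive the binary diagnosis from sex + handgrip strength.

    A record is positive iff its grip is strictly below the sex-specific
    threshold.  Records with missing grip or unmappable sex are dropped and
    counted.  The grip column and any other diagnosis-determining columns
    (``drop_columns``) are removed from the output feature set.

    Returns (labelled Dataset, number of dropped records).
    """
    for col in (sex_col, grip_col):
        if col not in records.columns:
            raise ConfigurationError(f"required column {col!r} not in table")

    sex = records[sex_col].map(_normalize_sex)
    grip = pd.to_numeric(records[grip_col], errors="coerce")
    keep = (~grip.isna()) & (~sex.isna())
    n_dropped = int((~keep).sum())

    kept = records.loc[keep].reset_index(drop=True)
    sex_k = sex.loc[keep].reset_index(drop=True)
    grip_k = grip.loc[keep].reset_index(drop=True)
    thresholds = np.where(sex_k == "male", rule.male_threshold_kg, rule.female_threshold_kg)
    labels = np.where(grip_k.to_numpy() < thresholds, POSITIVE, NEGATIVE).astype(object)

    removed = {grip_col, *drop_columns}
    feat = kept.drop(columns=[c for c in removed if c in kept.columns])
    # normalized sex token replaces the raw encoding so the rule's input
    # column survives as an ordinary nominal feature
    if sex_col in feat.columns:
        feat[sex_col] = sex_k.astype(object)
    ds = dataset_from_frame(feat, labels=labels, classes=[POSITIVE, NEGATIVE])
    return ds, n_dropped


def drop_unreliable_features(
    ds: Dataset,
    min_responses: int = 6,
    id_distinct_fraction: float = 0.99,
) -> tuple[Dataset, list[str]]:
    """Remove features with too few responses or ID-like uniqueness.

    A feature is dropped when it has fewer than ``min_responses`` non-missing
    cells (i.e. five or fewer under the default), or when it is nominal and
    its distinct non-missing tokens number at least ``id_distinct_fraction``
    of the instance count (a respondent-ID signature).  Scan is left-to-right.
    """
    dropped: list[str] = []
    n = ds.n_instances
    keep_idx = []
    for j, (name, kind) in enumerate(zip(ds.feature_names, ds.feature_kinds)):
        col = ds.frame[name]
        nonmiss = col.dropna()
        if len(nonmiss) < min_responses:
            dropped.append(name)
            continue
        if kind == NOMINAL and nonmiss.nunique() >= id_distinct_fraction * n:
            dropped.append(name)
            continue
        keep_idx.append(j)
    if not dropped:
        return ds, []
    out = Dataset(
        ds.frame.iloc[:, keep_idx].reset_index(drop=True),
        [ds.feature_kinds[j] for j in keep_idx],
        labels=None if ds.labels is None else ds.labels.copy(),
        classes=list(ds.classes) if ds.classes else None,
    )
    return out, dropped


def _per_class_indices(ds: Dataset) -> list[np.ndarray]:
    codes = ds.label_codes()
    return [np.flatnonzero(codes == i) for i in range(len(ds.classes))]


def stratified_split(ds: Dataset, spec: SplitSpec) -> tuple[Dataset, Dataset]:
    """Stratified hold-out split: per class, exactly
    floor(train_fraction · n_c) instances go to train (uniformly at random
    under ``spec.seed``), the remainder to test."""
    rng = np.random.default_rng(spec.seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for cls, idx in zip(ds.classes, _per_class_indices(ds)):
        if len(idx) == 0:
            raise InvalidInputError(f"class {cls!r} has no instances")
        perm = rng.permutation(idx)
        n_train = int(np.floor(spec.train_fraction * len(idx)))
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    tr = np.sort(np.concatenate(train_idx))
    te = np.sort(np.concatenate(test_idx))
    return ds.take(tr), ds.take(te)


def stratified_kfold(
    ds: Dataset, k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partition: per class, shuffled indices are split
    into k chunks whose sizes differ by at most one (remainder spread over
    the leading folds).  Returns k (train_idx, valid_idx) pairs."""
    rng = np.random.default_rng(seed)
    per_class_chunks: list[list[np.ndarray]] = []
    for cls, idx in zip(ds.classes, _per_class_indices(ds)):
        if len(idx) < k:
            raise InvalidInputError(
                f"class {cls!r} has {len(idx)} instances, fewer than k={k}"
            )
        perm = rng.permutation(idx)
        per_class_chunks.append(np.array_split(perm, k))
    folds = []
    all_idx = np.arange(ds.n_instances)
    for i in range(k):
        valid = np.sort(np.concatenate([chunks[i] for chunks in per_class_chunks]))
        mask = np.ones(ds.n_instances, dtype=bool)
        mask[valid] = False
        folds.append((all_idx[mask], valid))
    return folds


def apply_mask(ds: Dataset, mask: FeatureMask) -> Dataset:
    """Project the dataset onto the selected features (labels untouched)."""
    if len(mask) != ds.n_features:
        raise InvalidInputError(
            f"mask length {len(mask)} != feature count {ds.n_features}"
        )
    sel = mask.indices()
    return Dataset(
        ds.frame.iloc[:, sel].reset_index(drop=True),
        [ds.feature_kinds[j] for j in sel],
        labels=None if ds.labels is None else ds.labels.copy(),
        classes=list(ds.classes) if ds.classes else None,
    )
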