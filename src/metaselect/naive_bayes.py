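"""Naive-Bayes wrapper fitness for feature masks.

The classifier handles the survey data as-is: nominal likelihoods are
category frequencies with add-one (Laplace) smoothing over the categories
observed in training; numeric likelihoods are single Gaussians with a
floored standard deviation; missing cells are skipped in both fitting and
prediction (no imputation).  Priors are class frequencies.

A mask's fitness is its mean accuracy over a stratified 5-fold
cross-validation.  Two routes compute it:

* :func:`cv_fitness` — the plain route: fit/predict per fold.
* :class:`CVFitnessEvaluator` — precomputes, per fold and per feature, the
  log-likelihood contribution of every validation cell under every class.
  Because naive Bayes factorizes over features, any mask's score is then a
  slice-sum; this is what makes metaheuristic runs with thousands of
  evaluations cheap.  The two routes agree (tested).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    NOMINAL,
    NUMERIC,
    Dataset,
    FeatureMask,
    InvalidInputError,
    is_missing,
    stratified_kfold,
)

#: Std-dev floor: this fraction of the feature's training range,
#: never below the absolute floor.
VAR_FLOOR_FRACTION = 1e-6
VAR_FLOOR_ABS = 1e-9

_LOG_2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# dataset encoding (cached per Dataset)
# ---------------------------------------------------------------------------

class _Encoded:
    """Integer/float column views of a Dataset for fast counting."""

    def __init__(self, ds: Dataset):
        self.kinds = list(ds.feature_kinds)
        self.columns = []       # int codes (-1 missing) or float (nan missing)
        self.categories = []    # category token arrays for nominal, None else
        for name, kind in zip(ds.feature_names, ds.feature_kinds):
            col = ds.frame[name]
            if kind == NUMERIC:
                self.columns.append(col.to_numpy(dtype=float))
                self.categories.append(None)
            else:
                cat = pd.Categorical(col)
                self.columns.append(cat.codes.astype(np.int64))
                self.categories.append(np.asarray(cat.categories, dtype=object))
        self.y = ds.label_codes() if ds.labels is not None else None
        self.n_classes = len(ds.classes) if ds.classes else 0


def _encoded(ds: Dataset) -> _Encoded:
    enc = ds._cache.get("nb_encoded")
    if enc is None:
        enc = _Encoded(ds)
        ds._cache["nb_encoded"] = enc
    return enc


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class _NominalStats:
    categories: list            # tokens observed in training (universe)
    log_probs: np.ndarray       # (n_classes, n_categories) smoothed log P(cat|c)
    log_unseen: np.ndarray      # (n_classes,) log of 1/(n_c + V) for unseen tokens
    active: np.ndarray          # (n_classes,) False where the class had no data


@dataclass
class _NumericStats:
    mean: np.ndarray            # (n_classes,)
    std: np.ndarray             # (n_classes,) floored
    active: np.ndarray          # (n_classes,)


@dataclass
class NBModel:
    """Fitted naive-Bayes model over a masked feature set."""

    classes: list
    class_priors: np.ndarray
    feature_names: list
    feature_kinds: list
    stats: list                 # _NominalStats | _NumericStats per feature

    def __post_init__(self):
        if abs(float(self.class_priors.sum()) - 1.0) > 1e-12:
            raise InvalidInputError("class priors must sum to 1")
        self._lookups = [
            {tok: i for i, tok in enumerate(s.categories)}
            if isinstance(s, _NominalStats) else None
            for s in self.stats
        ]

    @property
    def log_priors(self) -> np.ndarray:
        return np.log(self.class_priors)

    def to_dict(self) -> dict:
        """JSON-serializable summary (priors, counts-derived log-probs, moments)."""
        feats = []
        for name, kind, s in zip(self.feature_names, self.feature_kinds, self.stats):
            if isinstance(s, _NominalStats):
                feats.append({
                    "name": name, "kind": kind,
                    "categories": [str(c) for c in s.categories],
                    "log_probs": s.log_probs.tolist(),
                    "log_unseen": s.log_unseen.tolist(),
                    "active": s.active.tolist(),
                })
            else:
                feats.append({
                    "name": name, "kind": kind,
                    "mean": s.mean.tolist(), "std": s.std.tolist(),
                    "active": s.active.tolist(),
                })
        return {
            "classes": [str(c) for c in self.classes],
            "class_priors": self.class_priors.tolist(),
            "features": feats,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


@dataclass
class FitnessResult:
    """Cross-validated wrapper score of one feature mask."""

    fitness: float
    per_fold_accuracy: list
    mask_popcount: int

    def __post_init__(self):
        mean = float(np.mean(self.per_fold_accuracy))
        if abs(mean - self.fitness) > 1e-12:
            raise InvalidInputError("fitness must equal the mean fold accuracy")


# ---------------------------------------------------------------------------
# fitting / prediction (reference route)
# ---------------------------------------------------------------------------

def _nominal_stats(codes, y, n_classes, tokens) -> _NominalStats:
    ok = codes >= 0
    m = len(tokens)
    counts = np.zeros((n_classes, m))
    if m and ok.any():
        np.add.at(counts, (y[ok], codes[ok]), 1.0)
    observed = counts.sum(axis=0) > 0
    V = int(observed.sum())
    n_c = counts.sum(axis=1)
    active = n_c > 0
    denom = np.where(active, n_c + V, 1.0)
    log_probs = np.log(counts[:, observed] + 1.0) - np.log(denom)[:, None]
    log_unseen = -np.log(denom)
    log_probs[~active, :] = 0.0
    log_unseen[~active] = 0.0
    return _NominalStats(
        categories=[tokens[i] for i in np.flatnonzero(observed)],
        log_probs=log_probs, log_unseen=log_unseen, active=active,
    )


def _numeric_stats(x, y, n_classes) -> _NumericStats:
    ok = ~np.isnan(x)
    if ok.any():
        rng = float(np.max(x[ok]) - np.min(x[ok]))
    else:
        rng = 0.0
    floor = max(VAR_FLOOR_FRACTION * rng, VAR_FLOOR_ABS)
    mean = np.zeros(n_classes)
    std = np.full(n_classes, floor)
    active = np.zeros(n_classes, dtype=bool)
    for c in range(n_classes):
        xc = x[ok & (y == c)]
        if len(xc):
            active[c] = True
            mean[c] = float(xc.mean())
            std[c] = max(float(xc.std()), floor)
    return _NumericStats(mean=mean, std=std, active=active)


def nb_fit(train: Dataset, mask: FeatureMask) -> NBModel:
    """Fit the naive-Bayes wrapper on the masked training features."""
    if train.n_instances == 0:
        raise InvalidInputError("cannot fit on an empty training set")
    if len(mask) != train.n_features:
        raise InvalidInputError("mask length does not match feature count")
    enc = _encoded(train)
    if enc.y is None:
        raise InvalidInputError("training set has no labels")
    C = enc.n_classes
    priors = np.bincount(enc.y, minlength=C).astype(float) / len(enc.y)

    names, kinds, stats = [], [], []
    for j in mask.indices():
        names.append(train.feature_names[j])
        kinds.append(train.feature_kinds[j])
        if enc.kinds[j] == NOMINAL:
            stats.append(
                _nominal_stats(enc.columns[j], enc.y, C, list(enc.categories[j]))
            )
        else:
            stats.append(_numeric_stats(enc.columns[j], enc.y, C))
    return NBModel(list(train.classes), priors, names, kinds, stats)


def _log_posterior_one(model: NBModel, instance) -> np.ndarray:
    if len(instance) != len(model.stats):
        raise InvalidInputError(
            f"instance width {len(instance)} != model feature count {len(model.stats)}"
        )
    log_post = model.log_priors.copy()
    for value, s, lut in zip(instance, model.stats, model._lookups):
        if is_missing(value):
            continue
        if isinstance(s, _NominalStats):
            idx = lut.get(value)
            contrib = s.log_probs[:, idx] if idx is not None else s.log_unseen
            log_post = log_post + np.where(s.active, contrib, 0.0)
        else:
            x = float(value)
            z = (x - s.mean) / s.std
            contrib = -0.5 * z * z - np.log(s.std) - 0.5 * _LOG_2PI
            log_post = log_post + np.where(s.active, contrib, 0.0)
    return log_post


def nb_predict_proba(model: NBModel, instance) -> np.ndarray:
    """Posterior over classes for one instance (values aligned with the
    model's masked feature set; missing values are skipped).  Normalized to
    sum to 1; with all features missing it equals the priors."""
    log_post = _log_posterior_one(model, instance)
    log_post -= log_post.max()
    p = np.exp(log_post)
    return p / p.sum()


def nb_predict_proba_many(model: NBModel, ds: Dataset) -> np.ndarray:
    """Posterior matrix (n_instances, n_classes) for a masked dataset whose
    columns align with the model's feature set."""
    rows = ds.frame.to_numpy(dtype=object)
    return np.vstack([nb_predict_proba(model, row) for row in rows])


def nb_predict(model: NBModel, ds: Dataset) -> np.ndarray:
    """Argmax-posterior labels (ties go to the first declared class)."""
    proba = nb_predict_proba_many(model, ds)
    idx = np.argmax(proba, axis=1)
    return np.array([model.classes[i] for i in idx], dtype=object)


def cv_fitness(ds: Dataset, mask: FeatureMask, k: int = 5, seed: int = 0) -> FitnessResult:
    """Mean accuracy of the masked naive-Bayes classifier over a stratified
    k-fold cross-validation.  Pure function of (ds, mask, k, seed)."""
    folds = stratified_kfold(ds, k=k, seed=seed)
    accs = []
    for tr, va in folds:
        model = nb_fit(ds.take(tr), mask)
        valid = apply_mask_rows(ds, mask, va)
        pred = nb_predict(model, valid)
        accs.append(float(np.mean(pred == ds.labels[va])))
    return FitnessResult(float(np.mean(accs)), accs, mask.popcount)


def apply_mask_rows(ds: Dataset, mask: FeatureMask, rows) -> Dataset:
    """Row + column subset in one step (helper for fold evaluation)."""
    from .data import apply_mask

    return apply_mask(ds.take(rows), mask)


# ---------------------------------------------------------------------------
# precomputing evaluator (fast route)
# ---------------------------------------------------------------------------

class CVFitnessEvaluator:
    """Callable mask → CV accuracy with per-fold per-feature precomputation.

    For every fold and feature, the log-likelihood of each validation cell
    under each class is computed once from the fold's training statistics
    (same smoothing, variance floor and skip-on-missing rules as
    :func:`nb_fit`).  A mask's score then costs O(popcount · n_valid) per
    fold.  Results are cached by mask bits.
    """

    def __init__(self, ds: Dataset, k: int = 5, seed: int = 0):
        self.ds = ds
        self.k = k
        self.seed = seed
        enc = _encoded(ds)
        if enc.y is None:
            raise InvalidInputError("dataset has no labels")
        self.n_features = ds.n_features
        C = enc.n_classes
        self._folds = stratified_kfold(ds, k=k, seed=seed)
        self._log_priors = []
        self._contrib = []      # per fold: (p, C, n_valid)
        self._y_valid = []
        y = enc.y
        for tr, va in self._folds:
            priors = np.bincount(y[tr], minlength=C).astype(float) / len(tr)
            with np.errstate(divide="ignore"):
                self._log_priors.append(np.log(priors))
            contrib = np.zeros((self.n_features, C, len(va)))
            for j in range(self.n_features):
                if enc.kinds[j] == NOMINAL:
                    contrib[j] = self._nominal_contrib(enc.columns[j], y, tr, va, C)
                else:
                    contrib[j] = self._numeric_contrib(enc.columns[j], y, tr, va, C)
            self._contrib.append(contrib)
            self._y_valid.append(y[va])
        self._cache: dict = {}
        self.n_evaluations = 0      # distinct masks scored

    @staticmethod
    def _nominal_contrib(codes, y, tr, va, C) -> np.ndarray:
        out = np.zeros((C, len(va)))
        ctr = codes[tr]
        ok = ctr >= 0
        m = int(codes.max()) + 1 if (codes >= 0).any() else 0
        if m == 0:
            return out
        counts = np.zeros((C, m))
        np.add.at(counts, (y[tr][ok], ctr[ok]), 1.0)
        V = int((counts.sum(axis=0) > 0).sum())
        if V == 0:
            return out
        n_c = counts.sum(axis=1)
        active = n_c > 0
        denom = np.where(active, n_c + V, 1.0)
        logp = np.log(counts + 1.0) - np.log(denom)[:, None]
        logp[~active, :] = 0.0
        cva = codes[va]
        present = cva >= 0
        out[:, present] = logp[:, cva[present]]
        return out

    @staticmethod
    def _numeric_contrib(x, y, tr, va, C) -> np.ndarray:
        out = np.zeros((C, len(va)))
        xtr = x[tr]
        ok = ~np.isnan(xtr)
        if not ok.any():
            return out
        rng = float(xtr[ok].max() - xtr[ok].min())
        floor = max(VAR_FLOOR_FRACTION * rng, VAR_FLOOR_ABS)
        xva = x[va]
        present = ~np.isnan(xva)
        ytr = y[tr]
        for c in range(C):
            xc = xtr[ok & (ytr == c)]
            if len(xc) == 0:
                continue
            mu = float(xc.mean())
            sd = max(float(xc.std()), floor)
            z = (xva[present] - mu) / sd
            out[c, present] = -0.5 * z * z - math.log(sd) - 0.5 * _LOG_2PI
        return out

    def fitness(self, mask: FeatureMask) -> FitnessResult:
        if len(mask) != self.n_features:
            raise InvalidInputError("mask length does not match feature count")
        key = mask.bits
        cached = self._cache.get(key)
        if cached is None:
            sel = mask.indices()
            accs = []
            for lp, contrib, yv in zip(self._log_priors, self._contrib, self._y_valid):
                scores = lp[:, None] + contrib[sel].sum(axis=0)
                pred = np.argmax(scores, axis=0)
                accs.append(float(np.mean(pred == yv)))
            cached = FitnessResult(float(np.mean(accs)), accs, mask.popcount)
            self._cache[key] = cached
            self.n_evaluations += 1
        return cached

    def __call__(self, mask: FeatureMask) -> float:
        return self.fitness(mask).fitness
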