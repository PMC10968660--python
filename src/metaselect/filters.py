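"""Filter-method baselines: information-gain ranking and correlation-based
feature-subset selection (CFS) with forward best-first search.

Both work on discrete columns; numeric features are discretized by
equal-frequency binning first.  Missing cells are excluded pairwise from
all contingency counts.  The CFS subset score is the Ghiselli merit

    merit(S) = k * mean(SU(f, y)) / sqrt(k + k (k-1) * mean(SU(f, f'))),

where SU is symmetrical uncertainty 2*I(X;Y)/(H(X)+H(Y)) — relevance in the
numerator, redundancy in the denominator.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import NOMINAL, NUMERIC, Dataset, FeatureMask, InvalidInputError


@dataclass(frozen=True)
class DiscretizationSpec:
    """Equal-frequency binning for numeric columns."""

    n_bins: int = 10

    def __post_init__(self):
        if self.n_bins < 2:
            raise InvalidInputError("need at least 2 bins")


def entropy(x) -> float:
    """Shannon entropy (bits) of a discrete column, over non-missing cells."""
    s = pd.Series(np.asarray(x, dtype=object)).dropna()
    if len(s) == 0:
        raise InvalidInputError("entropy of an all-missing column is undefined")
    p = s.value_counts(normalize=True).to_numpy(dtype=float)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _joint_entropy(x, y) -> float:
    pairs = pd.Series(list(zip(x, y)))
    p = pairs.value_counts(normalize=True).to_numpy(dtype=float)
    return float(-(p * np.log2(p)).sum())


def _pairwise_complete(x, y):
    xs = pd.Series(np.asarray(x, dtype=object))
    ys = pd.Series(np.asarray(y, dtype=object))
    keep = ~(xs.isna() | ys.isna())
    if not keep.any():
        raise InvalidInputError("no pairwise-complete observations")
    return xs[keep].to_numpy(), ys[keep].to_numpy()


def info_gain(feature, labels) -> float:
    """Mutual information H(y) - H(y|x) in bits over pairwise-complete rows."""
    x, y = _pairwise_complete(feature, labels)
    gain = entropy(y) + entropy(x) - _joint_entropy(x, y)
    return max(0.0, float(gain))  # clip float round-off


def symmetrical_uncertainty(x, y) -> float:
    """Normalized mutual information 2*I(X;Y)/(H(X)+H(Y)) in [0, 1];
    defined as 0 when both entropies vanish."""
    xc, yc = _pairwise_complete(x, y)
    hx, hy = entropy(xc), entropy(yc)
    if hx + hy == 0.0:
        return 0.0
    su = 2.0 * (hx + hy - _joint_entropy(xc, yc)) / (hx + hy)
    return float(min(1.0, max(0.0, su)))


def discretize_column(values, kind: str, disc: DiscretizationSpec) -> np.ndarray:
    """Numeric columns become equal-frequency bin labels; nominal columns
    pass through.  Missing stays missing."""
    if kind == NOMINAL:
        return np.asarray(values, dtype=object)
    s = pd.Series(np.asarray(values, dtype=float))
    nonmiss = s.dropna()
    if nonmiss.nunique() <= 1:
        out = np.where(s.isna(), None, "b0")
        return out.astype(object)
    binned = pd.qcut(s, q=min(disc.n_bins, nonmiss.nunique()), duplicates="drop")
    codes = binned.cat.codes.to_numpy()
    out = np.array([f"b{c}" if c >= 0 else None for c in codes], dtype=object)
    return out


class CorrelationCache:
    """Lazy store of symmetrical uncertainties for CFS.

    Feature-class SUs are computed eagerly; feature-feature SUs on demand.
    """

    def __init__(self, ds: Dataset, disc: DiscretizationSpec = DiscretizationSpec()):
        if ds.labels is None:
            raise InvalidInputError("CFS needs labels")
        self.columns = [
            discretize_column(ds.frame[name], kind, disc)
            for name, kind in zip(ds.feature_names, ds.feature_kinds)
        ]
        self.labels = ds.labels
        self.su_cf = np.array([
            self._su_or_zero(col, self.labels) for col in self.columns
        ])
        self._ff: dict = {}

    @staticmethod
    def _su_or_zero(x, y) -> float:
        try:
            return symmetrical_uncertainty(x, y)
        except InvalidInputError:
            return 0.0

    def su_ff(self, i: int, j: int) -> float:
        if i == j:
            return 1.0
        key = (i, j) if i < j else (j, i)
        if key not in self._ff:
            self._ff[key] = self._su_or_zero(self.columns[key[0]], self.columns[key[1]])
        return self._ff[key]


def cfs_merit(subset, cache: CorrelationCache) -> float:
    """Ghiselli merit of a feature subset (indices or FeatureMask);
    the empty subset has merit 0."""
    if isinstance(subset, FeatureMask):
        idx = list(subset.indices())
    else:
        idx = sorted(subset)
    k = len(idx)
    if k == 0:
        return 0.0
    r_cf = float(np.mean(cache.su_cf[idx]))
    if k == 1:
        return r_cf
    pairs = list(itertools.combinations(idx, 2))
    r_ff = float(np.mean([cache.su_ff(i, j) for i, j in pairs]))
    return k * r_cf / np.sqrt(k + k * (k - 1) * r_ff)


def best_first_cfs(
    ds: Dataset,
    disc: DiscretizationSpec = DiscretizationSpec(),
    stale_limit: int = 5,
    cache: CorrelationCache | None = None,
) -> FeatureMask:
    """Forward best-first search over subsets by CFS merit.

    Expands the best open subset by single-feature additions; stops after
    ``stale_limit`` consecutive expansions without improving the global
    best.  Deterministic: merit ties prefer the lexicographically smaller
    subset.
    """
    cache = cache or CorrelationCache(ds, disc)
    p = ds.n_features
    start: tuple = ()
    best_subset, best_merit = start, 0.0
    # heap orders by (-merit, subset): larger merit first, then lexicographic
    open_heap = [(-0.0, start)]
    closed = {start}
    stale = 0
    while open_heap and stale < stale_limit:
        neg_merit, subset = heapq.heappop(open_heap)
        improved = False
        members = set(subset)
        for j in range(p):
            if j in members:
                continue
            child = tuple(sorted(members | {j}))
            if child in closed:
                continue
            closed.add(child)
            merit = cfs_merit(child, cache)
            heapq.heappush(open_heap, (-merit, child))
            if merit > best_merit:
                best_subset, best_merit = child, merit
                improved = True
        stale = 0 if improved else stale + 1
    bits = np.zeros(p, dtype=np.int8)
    bits[list(best_subset)] = 1
    return FeatureMask(bits)


def ig_select(
    ds: Dataset,
    threshold: float = 0.1,
    disc: DiscretizationSpec = DiscretizationSpec(),
) -> FeatureMask:
    """Select every feature whose information gain with the label is at
    least ``threshold`` bits (inclusive).  All-missing features score 0."""
    if ds.labels is None:
        raise InvalidInputError("information-gain selection needs labels")
    bits = []
    for name, kind in zip(ds.feature_names, ds.feature_kinds):
        col = discretize_column(ds.frame[name], kind, disc)
        try:
            gain = info_gain(col, ds.labels)
        except InvalidInputError:
            gain = 0.0
        bits.append(1 if gain >= threshold else 0)
    return FeatureMask(bits)
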