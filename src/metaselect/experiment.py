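"""Experiment harness: select on train, evaluate on held-out test.

Feature selection only ever sees the training partition — the selection
helpers take the train Dataset and cannot touch the test set by
construction.  Evaluation classifiers (a decision tree, a random forest, a
linear-kernel SVM, and the native naive Bayes) are plugged in behind a
name-keyed registry; the scikit-learn ones receive an ordinal encoding of
the mixed-type data (missing nominal cells become their own category,
missing numeric cells take the training median) — an adapter detail, not a
preprocessing step of the dataset itself.

Also here: the exhaustive mask-enumeration oracle used as ground truth in
small-problem benchmarks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import (
    NOMINAL,
    Dataset,
    FeatureMask,
    InvalidInputError,
    ConfigurationError,
    SplitSpec,
    apply_mask,
    drop_unreliable_features,
    label_by_grip,
    stratified_split,
)
from .filters import DiscretizationSpec, best_first_cfs, ig_select
from .ga import GAParams, ga_run
from .harmony import HSParams, hs_run
from .io import read_table, write_mask
from .metrics import EvalReport, Stopwatch, accuracy, auc, weighted_f1
from .naive_bayes import CVFitnessEvaluator, nb_fit, nb_predict_proba_many
from .schedules import ScheduleParams
from .synth import SynthSpec, generate_survey


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------

def exhaustive_oracle(
    ds: Dataset,
    max_features: int = 20,
    k: int = 5,
    seed: int = 0,
    evaluator=None,
) -> tuple[FeatureMask, float]:
    """Enumerate all 2^p masks and return the fitness-optimal one.

    Ties prefer the lowest popcount, then the lexicographically smallest
    bit vector.  Refuses problems wider than ``max_features``.
    """
    p = ds.n_features if ds is not None else evaluator.n_features
    if p > max_features:
        raise InvalidInputError(
            f"{p} features exceeds the exhaustive-search cap of {max_features}; "
            "use a metaheuristic instead"
        )
    evaluator = evaluator or CVFitnessEvaluator(ds, k=k, seed=seed)
    best_key = None
    best_mask, best_fit = None, -np.inf
    for bits in itertools.product((0, 1), repeat=p):
        mask = FeatureMask(bits)
        fit = evaluator(mask)
        key = (-fit, mask.popcount, mask.bits)
        if best_key is None or key < best_key:
            best_key, best_mask, best_fit = key, mask, fit
    return best_mask, float(best_fit)


# ---------------------------------------------------------------------------
# classifier registry
# ---------------------------------------------------------------------------

class _SKLearnAdapter:
    """Ordinal-encodes mixed-type data for a scikit-learn estimator."""

    def __init__(self, factory, use_decision_function: bool = False):
        self._factory = factory
        self._use_df = use_decision_function

    def fit(self, train: Dataset, seed: int):
        self._kinds = list(train.feature_kinds)
        self._classes = list(train.classes)
        self._cats = []
        self._medians = []
        for name, kind in zip(train.feature_names, train.feature_kinds):
            col = train.frame[name]
            if kind == NOMINAL:
                self._cats.append({v: i for i, v in enumerate(pd.unique(col.dropna()))})
                self._medians.append(None)
            else:
                self._cats.append(None)
                med = col.dropna().median()
                self._medians.append(0.0 if pd.isna(med) else float(med))
        X = self._encode(train)
        y = train.label_codes()
        self._clf = self._factory(seed)
        self._clf.fit(X, y)
        return self

    def _encode(self, ds: Dataset) -> np.ndarray:
        cols = []
        for j, name in enumerate(ds.feature_names):
            col = ds.frame[name]
            if self._kinds[j] == NOMINAL:
                lut = self._cats[j]
                cols.append(np.array([
                    lut.get(v, -1) if not pd.isna(v) else -1 for v in col
                ], dtype=float))
            else:
                x = col.to_numpy(dtype=float).copy()
                x[np.isnan(x)] = self._medians[j]
                cols.append(x)
        return np.column_stack(cols) if cols else np.zeros((ds.n_instances, 0))

    def predict(self, ds: Dataset) -> np.ndarray:
        idx = self._clf.predict(self._encode(ds)).astype(int)
        return np.array([self._classes[i] for i in idx], dtype=object)

    def positive_scores(self, ds: Dataset) -> np.ndarray:
        """Score for the first declared class (the positive one)."""
        X = self._encode(ds)
        if self._use_df:
            df = self._clf.decision_function(X)
            # decision_function is for the label coded 1 = second class
            return -df if df.ndim == 1 else df[:, 0]
        proba = self._clf.predict_proba(X)
        col = list(self._clf.classes_).index(0)
        return proba[:, col]


class _NaiveBayesAdapter:
    """The package's own classifier behind the same interface."""

    def fit(self, train: Dataset, seed: int):
        self._model = nb_fit(train, FeatureMask.ones(train.n_features))
        return self

    def predict(self, ds: Dataset) -> np.ndarray:
        proba = nb_predict_proba_many(self._model, ds)
        idx = np.argmax(proba, axis=1)
        return np.array([self._model.classes[i] for i in idx], dtype=object)

    def positive_scores(self, ds: Dataset) -> np.ndarray:
        return nb_predict_proba_many(self._model, ds)[:, 0]


def _make_tree(seed):
    from sklearn.tree import DecisionTreeClassifier

    return DecisionTreeClassifier(random_state=seed)


def _make_forest(seed):
    from sklearn.ensemble import RandomForestClassifier

    return RandomForestClassifier(n_estimators=100, random_state=seed)


def _make_svm(seed):
    from sklearn.svm import SVC

    return SVC(kernel="linear", random_state=seed)


CLASSIFIER_REGISTRY = {
    "nb": lambda: _NaiveBayesAdapter(),
    "tree": lambda: _SKLearnAdapter(_make_tree),
    "forest": lambda: _SKLearnAdapter(_make_forest),
    "svm": lambda: _SKLearnAdapter(_make_svm, use_decision_function=True),
}


# ---------------------------------------------------------------------------
# configuration and result rows
# ---------------------------------------------------------------------------

METHODS = ("ga", "hs", "cfs", "ig", "none")


@dataclass
class RunConfig:
    """Everything a reproducible experiment run needs."""

    method: str = "none"
    input_path: str | None = None
    input_format: str | None = None
    label_col: str = "label"
    sex_col: str | None = None
    grip_col: str | None = None
    synth: SynthSpec | None = None

    generations: int = 100
    iterations: int = 1000
    mutation_rate: float = 0.01
    hmcr: float = 0.85
    par: float = 0.7
    par_mode: str = "per_harmony"
    dynamic: bool = False
    schedule: ScheduleParams = field(default_factory=ScheduleParams)
    ig_threshold: float = 0.1
    n_bins: int = 10

    classifiers: tuple = ("nb", "tree", "forest", "svm")
    seeds: tuple = (0,)
    train_fraction: float = 0.8
    split_seed: int = 0
    min_responses: int = 6
    outdir: str | None = None

    def __post_init__(self):
        if self.method not in METHODS:
            raise ConfigurationError(f"unknown method {self.method!r}")
        unknown = [c for c in self.classifiers if c not in CLASSIFIER_REGISTRY]
        if unknown:
            raise ConfigurationError(f"unknown classifier names: {unknown}")
        if self.method in ("ga", "hs") and not self.seeds:
            raise ConfigurationError("metaheuristic methods require seeds")

    @property
    def budget(self) -> int | None:
        if self.method == "ga":
            return self.generations
        if self.method == "hs":
            return self.iterations
        return None


@dataclass
class ResultRow:
    """One (method, budget, classifier) line of a results table, averaged
    over replicate seeds."""

    method: str
    budget: int | None
    classifier: str
    accuracy: float
    weighted_f1: float
    auc: float
    n_selected: float
    seconds: float


# ---------------------------------------------------------------------------
# selection dispatch (receives *only* the training partition)
# ---------------------------------------------------------------------------

def select_features(train: Dataset, cfg: RunConfig, seed: int) -> tuple[FeatureMask, float]:
    """Run the configured selection method on the training set only.

    Returns (mask, selection wall-clock seconds).
    """
    schedule = cfg.schedule if cfg.dynamic else None
    with Stopwatch() as sw:
        if cfg.method == "none":
            mask = FeatureMask.ones(train.n_features)
        elif cfg.method == "ga":
            params = GAParams(
                mutation_rate=cfg.mutation_rate,
                generations=cfg.generations,
                seed=seed,
            )
            mask, _ = ga_run(train, params, schedule=schedule)
        elif cfg.method == "hs":
            params = HSParams(
                hmcr=cfg.hmcr, par=cfg.par, par_mode=cfg.par_mode,
                iterations=cfg.iterations, seed=seed,
            )
            mask, _ = hs_run(train, params, schedule=schedule)
        elif cfg.method == "cfs":
            mask = best_first_cfs(train, DiscretizationSpec(cfg.n_bins))
        elif cfg.method == "ig":
            mask = ig_select(train, cfg.ig_threshold, DiscretizationSpec(cfg.n_bins))
        else:  # pragma: no cover - guarded in RunConfig
            raise ConfigurationError(cfg.method)
    return mask, sw.seconds


def evaluate_mask(
    train: Dataset, test: Dataset, mask: FeatureMask, classifier: str,
    seed: int = 0, selection_seconds: float = 0.0,
) -> EvalReport:
    """Train one registry classifier on the masked train set and score the
    masked test set."""
    adapter = CLASSIFIER_REGISTRY[classifier]()
    tr = apply_mask(train, mask)
    te = apply_mask(test, mask)
    adapter.fit(tr, seed)
    pred = adapter.predict(te)
    scores = adapter.positive_scores(te)
    return EvalReport(
        accuracy=accuracy(test.labels, pred),
        weighted_f1=weighted_f1(test.labels, pred),
        auc=auc(test.labels, scores, positive=test.classes[0]),
        n_selected=mask.popcount,
        seconds=selection_seconds,
    )


def load_dataset(cfg: RunConfig) -> Dataset:
    """Resolve the input: synthetic spec, raw sex+grip table, or labelled file."""
    if cfg.synth is not None:
        ds, _ = generate_survey(cfg.synth)
        return ds
    if cfg.input_path is None:
        raise ConfigurationError("need input_path or a synth spec")
    if cfg.sex_col and cfg.grip_col:
        raw = pd.read_csv(
            cfg.input_path, dtype=str, keep_default_na=False, na_values=["", "NA"]
        )
        ds, _ = label_by_grip(raw, sex_col=cfg.sex_col, grip_col=cfg.grip_col)
        return ds
    return read_table(cfg.input_path, format=cfg.input_format, label=cfg.label_col)


def run_experiment(cfg: RunConfig) -> list[ResultRow]:
    """Full pipeline: preprocess, split, select per replicate seed on the
    training partition, evaluate each classifier on the held-out test set,
    average replicates into one row per classifier.  Artifacts (results
    CSV, mask files, resolved-parameter log) land in ``cfg.outdir``."""
    ds = load_dataset(cfg)
    ds, dropped = drop_unreliable_features(ds, min_responses=cfg.min_responses)
    train, test = stratified_split(
        ds, SplitSpec(train_fraction=cfg.train_fraction, seed=cfg.split_seed)
    )

    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    per_seed: dict[str, list[EvalReport]] = {c: [] for c in cfg.classifiers}
    for seed in cfg.seeds:
        mask, seconds = select_features(train, cfg, seed)
        if outdir:
            write_mask(outdir / f"mask_{cfg.method}_seed{seed}.txt", mask, ds.feature_names)
        for name in cfg.classifiers:
            per_seed[name].append(
                evaluate_mask(train, test, mask, name, seed=seed,
                              selection_seconds=seconds)
            )

    rows = [
        ResultRow(
            method=cfg.method,
            budget=cfg.budget,
            classifier=name,
            accuracy=float(np.mean([r.accuracy for r in reports])),
            weighted_f1=float(np.mean([r.weighted_f1 for r in reports])),
            auc=float(np.mean([r.auc for r in reports])),
            n_selected=float(np.mean([r.n_selected for r in reports])),
            seconds=float(np.mean([r.seconds for r in reports])),
        )
        for name, reports in per_seed.items()
    ]

    if outdir:
        pd.DataFrame([asdict(r) for r in rows]).to_csv(
            outdir / "results.csv", index=False
        )
        log = {
            "config": _cfg_log(cfg),
            "n_dropped_features": len(dropped),
            "train_instances": train.n_instances,
            "test_instances": test.n_instances,
        }
        with open(outdir / "run_log.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(log, fh, sort_keys=True)
    return rows


def _cfg_log(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    d["seeds"] = list(cfg.seeds)
    d["classifiers"] = list(cfg.classifiers)
    if cfg.synth is not None:
        d["synth"] = asdict(cfg.synth)
    d["schedule"] = asdict(cfg.schedule)
    return d


def plot_convergence(history, path=None, title="convergence"):
    """Best/mean fitness curves over the run (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(history.best_fitness, label="best")
    ax.plot(history.mean_fitness, label="mean")
    ax.set_xlabel("step")
    ax.set_ylabel("CV accuracy")
    ax.set_title(title)
    ax.legend()
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
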