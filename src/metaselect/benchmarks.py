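"""Desk-scale benchmark harnesses for the optimizers.

These bundle the package's own verification experiments: bookkeeping
identities (offspring totals, stratified-split counts), oracle equivalence
on exhaustively enumerable problems, ground-truth recovery on synthetic
surveys with planted signal, and the fixed-vs-dynamic schedule parity
check.  Problem sizes are chosen so each harness runs in seconds to a few
minutes on one CPU; docs/methods.md records the choices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .data import SplitSpec, stratified_split
from .experiment import exhaustive_oracle
from .ga import GAParams, ga_run
from .harmony import HSParams, hs_run
from .naive_bayes import CVFitnessEvaluator
from .schedules import ScheduleParams
from .synth import SynthSpec, generate_survey


def _sub_seed(base: int, k: int) -> int:
    """Derive independent child seeds below 2^31."""
    return int(np.random.SeedSequence([base, k]).generate_state(1)[0] % (2**31))


def offspring_totals(generations: int, seed: int = 0) -> int:
    """Total offspring bred by a GA run of the given length on a small
    synthetic problem (population 30, half replaced per generation)."""
    spec = SynthSpec(n_instances=150, n_positive=60, n_features=8,
                     n_informative=2, effect=0.4, missing_rate=0.05,
                     seed=_sub_seed(seed, 1))
    ds, _ = generate_survey(spec)
    evaluator = CVFitnessEvaluator(ds, k=5, seed=_sub_seed(seed, 2))
    _, history = ga_run(
        None, GAParams(generations=generations, seed=_sub_seed(seed, 3)),
        evaluator=evaluator, n_features=ds.n_features,
    )
    return history.n_offspring


def cohort_split_counts(seed: int = 0) -> dict:
    """Class counts of the 80/20 stratified split when the generator
    reproduces the study cohort's label totals (2,564 / 3,924)."""
    spec = SynthSpec(n_features=20, n_informative=4, seed=_sub_seed(seed, 4))
    ds, _ = generate_survey(spec)
    train, test = stratified_split(ds, SplitSpec(0.8, seed=_sub_seed(seed, 5)))
    tc, xc = train.class_counts(), test.class_counts()
    pos, neg = ds.classes
    return {
        "train_pos": tc[pos], "train_neg": tc[neg],
        "test_pos": xc[pos], "test_neg": xc[neg],
    }


@dataclass
class OracleBenchResult:
    optimum: float
    ga_hits: int
    hs_hits: int
    n_runs: int
    ga_gaps: list
    hs_gaps: list


def oracle_equivalence(
    n_runs: int = 20,
    seed: int = 0,
    tolerance: float = 0.02,
    n_features: int = 10,
) -> OracleBenchResult:
    """How often GA (1,500 offspring) and HS (1,000 iterations) reach the
    exhaustively enumerated optimum within ``tolerance`` CV accuracy.

    One fixed problem (shared CV folds), ``n_runs`` optimizer seeds.
    """
    spec = SynthSpec(n_instances=150, n_positive=60, n_features=n_features,
                     n_informative=3, effect=0.3, missing_rate=0.05,
                     seed=_sub_seed(seed, 6))
    ds, _ = generate_survey(spec)
    evaluator = CVFitnessEvaluator(ds, k=5, seed=_sub_seed(seed, 7))
    _, optimum = exhaustive_oracle(ds, max_features=n_features, evaluator=evaluator)

    ga_gaps, hs_gaps = [], []
    for r in range(n_runs):
        best_ga, _ = ga_run(
            None, GAParams(generations=100, seed=_sub_seed(seed, 100 + r)),
            evaluator=evaluator, n_features=n_features,
        )
        ga_gaps.append(optimum - evaluator(best_ga))
        best_hs, _ = hs_run(
            None, HSParams(iterations=1000, seed=_sub_seed(seed, 200 + r)),
            evaluator=evaluator, n_features=n_features,
        )
        hs_gaps.append(optimum - evaluator(best_hs))
    return OracleBenchResult(
        optimum=float(optimum),
        ga_hits=sum(g <= tolerance for g in ga_gaps),
        hs_hits=sum(g <= tolerance for g in hs_gaps),
        n_runs=n_runs,
        ga_gaps=ga_gaps,
        hs_gaps=hs_gaps,
    )


@dataclass
class RecoveryResult:
    ga_successes: int
    hs_successes: int
    n_seeds: int
    ga_overlaps: list       # (observed, chance expectation) per seed
    hs_overlaps: list


def recovery_benchmark(n_seeds: int = 5, seed: int = 0) -> RecoveryResult:
    """Enrichment of selected masks for planted informative features.

    Survey: 2,000 instances, 50 features, 5 informative at tilt 0.3.  A
    seed succeeds when the selected mask's overlap with the planted set
    strictly exceeds the hypergeometric chance expectation at the same
    mask size.
    """
    spec = SynthSpec(n_instances=2000, n_positive=790, n_features=50,
                     n_informative=5, effect=0.3, missing_rate=0.05,
                     seed=_sub_seed(seed, 8))
    ds, truth = generate_survey(spec)
    informative = set(truth.informative_indices)
    evaluator = CVFitnessEvaluator(ds, k=5, seed=_sub_seed(seed, 9))

    def enrichment(mask):
        overlap = len(set(mask.indices()) & informative)
        chance = float(hypergeom.mean(50, len(informative), mask.popcount))
        return overlap, chance

    ga_overlaps, hs_overlaps = [], []
    for r in range(n_seeds):
        best_ga, _ = ga_run(
            None, GAParams(generations=100, seed=_sub_seed(seed, 300 + r)),
            evaluator=evaluator, n_features=50,
        )
        ga_overlaps.append(enrichment(best_ga))
        best_hs, _ = hs_run(
            None, HSParams(iterations=1000, seed=_sub_seed(seed, 400 + r)),
            evaluator=evaluator, n_features=50,
        )
        hs_overlaps.append(enrichment(best_hs))
    return RecoveryResult(
        ga_successes=sum(obs > exp for obs, exp in ga_overlaps),
        hs_successes=sum(obs > exp for obs, exp in hs_overlaps),
        n_seeds=n_seeds,
        ga_overlaps=ga_overlaps,
        hs_overlaps=hs_overlaps,
    )


def schedule_parity(seed: int = 0) -> dict:
    """Degenerate schedules (min = max) must reproduce fixed-parameter runs
    bit-for-bit on real wrapper fitness under the same seed."""
    spec = SynthSpec(n_instances=200, n_positive=80, n_features=12,
                     n_informative=3, effect=0.3, missing_rate=0.05,
                     seed=_sub_seed(seed, 10))
    ds, _ = generate_survey(spec)
    evaluator = CVFitnessEvaluator(ds, k=5, seed=_sub_seed(seed, 11))

    ga_params = GAParams(mutation_rate=0.01, generations=25,
                         seed=_sub_seed(seed, 12))
    ga_sched = ScheduleParams(mut_min=0.01, mut_max=0.01)
    ga_fixed = ga_run(None, ga_params, evaluator=evaluator, n_features=12)
    ga_dyn = ga_run(None, ga_params, schedule=ga_sched,
                    evaluator=evaluator, n_features=12)
    ga_ok = (
        ga_fixed[0] == ga_dyn[0]
        and ga_fixed[1].best_fitness == ga_dyn[1].best_fitness
        and ga_fixed[1].mean_fitness == ga_dyn[1].mean_fitness
    )

    hs_params = HSParams(hmcr=0.85, iterations=300, seed=_sub_seed(seed, 13))
    hs_sched = ScheduleParams(hmcr_min=0.85, hmcr_max=0.85)
    hs_fixed = hs_run(None, hs_params, evaluator=evaluator, n_features=12)
    hs_dyn = hs_run(None, hs_params, schedule=hs_sched,
                    evaluator=evaluator, n_features=12)
    hs_ok = (
        hs_fixed[0] == hs_dyn[0]
        and hs_fixed[1].best_fitness == hs_dyn[1].best_fitness
    )
    return {"ga_identical": ga_ok, "hs_identical": hs_ok}
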