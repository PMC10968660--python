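"""Binary harmony search for feature-subset search.

A harmony memory of HMS masks is improvised from bit by bit: with
probability HMCR a bit is copied from a uniformly chosen stored harmony
(chosen independently per bit), otherwise drawn uniformly at random.  Pitch
adjustment then perturbs the candidate; in binary encoding this is bit
flipping, offered in two dialects:

* ``per_harmony`` (default): with probability PAR flip exactly one
  uniformly chosen bit of the candidate — a gentle, mutation-like nudge
  that preserves convergence even at PAR = 0.7.
* ``per_bit``: flip each memory-derived bit independently with probability
  PAR — the literal per-variable reading, which at 0.7 randomizes most of
  the inherited information; retained for comparison.

A candidate replaces the worst stored harmony only on strict fitness
improvement, so memory size and best-so-far monotonicity are invariants.
The HMCR is either fixed or follows the rising linear schedule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Dataset, FeatureMask, InvalidInputError
from .ga import RunHistory
from .naive_bayes import CVFitnessEvaluator
from .schedules import ScheduleParams, hmcr_at

PAR_MODES = ("per_harmony", "per_bit")


@dataclass(frozen=True)
class HSParams:
    """Harmony-search settings (defaults are the study configuration)."""

    hms: int = 30
    hmcr: float = 0.85
    par: float = 0.7
    iterations: int = 1000
    par_mode: str = "per_harmony"
    seed: int = 0

    def __post_init__(self):
        if self.hms < 2:
            raise InvalidInputError("harmony memory size must be >= 2")
        for name in ("hmcr", "par"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"{name}={v} outside [0, 1]")
        if self.par_mode not in PAR_MODES:
            raise InvalidInputError(f"par_mode must be one of {PAR_MODES}")
        if self.iterations < 1:
            raise InvalidInputError("iterations must be >= 1")


@dataclass
class HarmonyMemory:
    """Fixed-size pool of candidate masks with their fitness."""

    masks: list
    fitness: np.ndarray

    def __post_init__(self):
        self.fitness = np.asarray(self.fitness, dtype=float)
        if len(self.masks) != len(self.fitness):
            raise InvalidInputError("masks and fitness lengths differ")

    @property
    def hms(self) -> int:
        return len(self.masks)

    @property
    def worst_index(self) -> int:
        return int(np.argmin(self.fitness))

    @property
    def best_index(self) -> int:
        return int(np.argmax(self.fitness))

    def matrix(self) -> np.ndarray:
        return np.stack([m.asarray() for m in self.masks])


def improvise(
    memory: HarmonyMemory,
    hmcr: float,
    par: float,
    par_mode: str = "per_harmony",
    rng: np.random.Generator | None = None,
) -> FeatureMask:
    """Generate one candidate mask from the memory.

    The random stream is consumed in a fixed order (memory-consideration
    uniforms, source-harmony indices, random bits, then pitch adjustment)
    so runs are reproducible across fixed and scheduled HMCR values.
    """
    if par_mode not in PAR_MODES:
        raise InvalidInputError(f"par_mode must be one of {PAR_MODES}")
    rng = rng if rng is not None else np.random.default_rng()
    mat = memory.matrix()
    L = mat.shape[1]
    from_memory = rng.random(L) < hmcr
    source = rng.integers(0, memory.hms, L)
    random_bits = rng.integers(0, 2, L).astype(np.int8)
    bits = np.where(from_memory, mat[source, np.arange(L)], random_bits).astype(np.int8)

    if par_mode == "per_harmony":
        if rng.random() < par:
            flip = int(rng.integers(0, L))
            bits[flip] ^= 1
    else:  # per_bit: adjust only the memory-derived positions
        flips = (rng.random(L) < par) & from_memory
        bits[flips] ^= 1
    return FeatureMask(bits)


def hs_replace(memory: HarmonyMemory, candidate: FeatureMask, fitness: float) -> bool:
    """Replace the worst stored harmony iff the candidate is strictly
    better; returns whether it was accepted.  Memory size never changes."""
    w = memory.worst_index
    if fitness > memory.fitness[w]:
        memory.masks[w] = candidate
        memory.fitness[w] = fitness
        return True
    return False


def hs_run(
    ds: Dataset | None,
    params: HSParams,
    schedule: ScheduleParams | None = None,
    evaluator=None,
    n_features: int | None = None,
):
    """Full harmony-search run; returns (best mask, RunHistory).

    Exactly one candidate is improvised and evaluated per iteration after
    the initial memory evaluation.
    """
    if evaluator is None:
        if ds is None:
            raise InvalidInputError("need a dataset or an evaluator")
        evaluator = CVFitnessEvaluator(ds, k=5, seed=params.seed)
    if n_features is None:
        if ds is None:
            raise InvalidInputError("need a dataset or n_features")
        n_features = ds.n_features

    rng = np.random.default_rng(params.seed)
    masks = [FeatureMask(rng.integers(0, 2, n_features)) for _ in range(params.hms)]
    memory = HarmonyMemory(masks, np.array([evaluator(m) for m in masks]))

    history = RunHistory()
    history.record(memory.fitness, memory.masks)
    for t in range(params.iterations):
        hmcr = (
            hmcr_at(t, params.iterations, schedule)
            if schedule is not None
            else params.hmcr
        )
        candidate = improvise(memory, hmcr, params.par, params.par_mode, rng)
        hs_replace(memory, candidate, evaluator(candidate))
        history.n_offspring += 1
        history.record(memory.fitness, memory.masks)

    b = memory.best_index
    return memory.masks[b], history
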