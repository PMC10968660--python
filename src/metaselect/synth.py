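"""Synthetic survey-style data with known informative features.

The generator emulates the statistical shape of a large aging-cohort
survey: thousands of respondents, hundreds of mixed nominal/numeric items
arranged in contiguous blocks (survey categories), scattered missing
responses, a ~40% positive binary diagnosis label, and a small planted
subset of label-associated features.  Defaults mirror that shape: 6,488
instances (2,564 positive), 778 features.

Informative nominal features are binary with the signal category's
probability tilted to 0.5 + delta in the positive class and 0.5 - delta in
the negative class; informative numeric features have their positive-class
mean shifted by ``effect`` standard deviations.  Noise features are
independent of the label.  The planted indices are returned as ground
truth so recovery can be measured.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import (
    NEGATIVE,
    POSITIVE,
    Dataset,
    DiagnosisRule,
    InvalidInputError,
    dataset_from_frame,
)


@dataclass(frozen=True)
class SynthSpec:
    """Shape and signal parameters of the generated survey."""

    n_instances: int = 6488
    n_positive: int = 2564
    n_features: int = 778
    n_informative: int = 20
    effect: float = 0.3          # nominal: probability tilt; numeric: SD shift
    missing_rate: float = 0.05
    nominal_fraction: float = 0.8
    n_blocks: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.n_positive < self.n_instances:
            raise InvalidInputError("need 0 < n_positive < n_instances")
        if not 0 <= self.n_informative <= self.n_features:
            raise InvalidInputError("n_informative must be <= n_features")
        if not 0.0 <= self.missing_rate < 1.0:
            raise InvalidInputError("missing_rate must be in [0, 1)")
        if not 0.0 < self.effect <= 0.5:
            raise InvalidInputError("effect must be in (0, 0.5] (nominal tilt)")
        if not 0.0 <= self.nominal_fraction <= 1.0:
            raise InvalidInputError("nominal_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """Which features carry signal, and how much."""

    informative_indices: list
    effects: dict = field(default_factory=dict)

    def to_json(self, **kw) -> str:
        return json.dumps(
            {
                "informative_indices": [int(i) for i in self.informative_indices],
                "effects": {str(k): float(v) for k, v in self.effects.items()},
            },
            **kw,
        )


def generate_survey(spec: SynthSpec) -> tuple[Dataset, GroundTruth]:
    """Generate a labelled Dataset plus its ground truth, reproducibly."""
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_instances, spec.n_features

    labels = np.array(
        [POSITIVE] * spec.n_positive + [NEGATIVE] * (n - spec.n_positive),
        dtype=object,
    )
    rng.shuffle(labels)
    pos = labels == POSITIVE

    informative = np.sort(rng.choice(p, size=spec.n_informative, replace=False))
    informative_set = set(int(i) for i in informative)
    is_nominal = rng.random(p) < spec.nominal_fraction

    # contiguous blocks emulate survey categories: each block shares a
    # category-count range for its nominal items
    block_of = np.minimum((np.arange(p) * spec.n_blocks) // max(p, 1), spec.n_blocks - 1)
    block_cats = rng.integers(2, 7, size=spec.n_blocks)  # 2..6 categories

    columns: dict = {}
    kinds: list[str] = []
    effects: dict = {}
    for j in range(p):
        name = f"q{j:04d}"
        if is_nominal[j]:
            kinds.append("nominal")
            if j in informative_set:
                # binary item with tilted signal-category probability
                p_pos = 0.5 + spec.effect
                p_neg = 0.5 - spec.effect
                u = rng.random(n)
                thresholds = np.where(pos, p_pos, p_neg)
                col = np.where(u < thresholds, "v1", "v0").astype(object)
                effects[int(j)] = spec.effect
            else:
                m = int(block_cats[block_of[j]])
                col = np.array(
                    [f"v{c}" for c in rng.integers(0, m, n)], dtype=object
                )
            columns[name] = col
        else:
            kinds.append("numeric")
            col = rng.standard_normal(n)
            if j in informative_set:
                # mean shift chosen so the midpoint threshold separates the
                # classes with probability 0.5 + effect — the same tilt the
                # nominal informative features carry
                shift = 2.0 * norm.ppf(0.5 + spec.effect)
                col = col + np.where(pos, shift, 0.0)
                effects[int(j)] = spec.effect
            columns[name] = col

    frame = pd.DataFrame(columns)
    if spec.missing_rate > 0:
        miss = rng.random((n, p)) < spec.missing_rate
        values = frame.to_numpy(dtype=object)
        values[miss] = np.nan
        frame = pd.DataFrame(values, columns=frame.columns)

    ds = dataset_from_frame(
        frame, labels=labels, classes=[POSITIVE, NEGATIVE], feature_kinds=kinds
    )
    truth = GroundTruth([int(i) for i in informative], effects)
    return ds, truth


def make_grip_table(
    spec: SynthSpec,
    rule: DiagnosisRule = DiagnosisRule(),
    missing_fraction: float | None = None,
    n_extra_features: int = 3,
) -> pd.DataFrame:
    """Raw table with sex + handgrip columns (plus a few survey-like
    extras) whose grip distributions put roughly ``n_positive/n_instances``
    of respondents below the sex-specific thresholds."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_instances
    q = spec.n_positive / spec.n_instances
    if missing_fraction is None:
        missing_fraction = spec.missing_rate

    sex = np.where(rng.random(n) < 0.5, "male", "female").astype(object)
    # choose per-sex means so P(grip < threshold) = q under realistic spreads
    sd_m, sd_f = 8.0, 6.0
    mu_m = rule.male_threshold_kg - sd_m * norm.ppf(q)
    mu_f = rule.female_threshold_kg - sd_f * norm.ppf(q)
    grip = np.where(
        sex == "male",
        rng.normal(mu_m, sd_m, n),
        rng.normal(mu_f, sd_f, n),
    ).astype(object)
    if missing_fraction > 0:
        grip[rng.random(n) < missing_fraction] = np.nan

    table = {"sex": sex, "grip_kg": grip}
    for e in range(n_extra_features):
        if e % 2 == 0:
            table[f"item{e}"] = np.array(
                [f"v{c}" for c in rng.integers(0, 4, n)], dtype=object
            )
        else:
            table[f"item{e}"] = rng.normal(50, 10, n)
    return pd.DataFrame(table)
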