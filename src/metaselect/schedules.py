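"""Linear dynamic-parameter schedules shared by both optimizers.

The harmony memory consideration rate (HMCR) rises linearly over the run so
early iterations explore (more random bits) and late iterations exploit the
memory; the GA mutation rate falls linearly but is floored so mutation never
vanishes entirely.  Setting min = max in either pair reproduces the
fixed-parameter algorithm bit-for-bit under the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .data import InvalidInputError


@dataclass(frozen=True)
class ScheduleParams:
    """Endpoints of the linear schedules (all probabilities)."""

    hmcr_min: float = 0.7
    hmcr_max: float = 1.0
    mut_min: float = 0.001
    mut_max: float = 0.1

    def __post_init__(self):
        for lo, hi, name in (
            (self.hmcr_min, self.hmcr_max, "hmcr"),
            (self.mut_min, self.mut_max, "mutation"),
        ):
            if not (0.0 <= lo <= hi <= 1.0):
                raise InvalidInputError(
                    f"{name} schedule needs 0 <= min <= max <= 1, got [{lo}, {hi}]"
                )


def _check_index(i: int, total: int, what: str):
    if total < 1:
        raise InvalidInputError(f"total {what} count must be >= 1")
    if not 0 <= i < total:
        raise InvalidInputError(f"{what} index {i} outside [0, {total})")


def hmcr_at(t: int, T: int, p: ScheduleParams = ScheduleParams()) -> float:
    """HMCR at iteration t of T: linear from hmcr_min (t=0) to hmcr_max
    (t=T-1); a single-iteration run uses hmcr_min."""
    _check_index(t, T, "iteration")
    if T == 1:
        return p.hmcr_min
    return p.hmcr_min + (p.hmcr_max - p.hmcr_min) * t / (T - 1)


def mutation_at(g: int, G: int, p: ScheduleParams = ScheduleParams()) -> float:
    """Mutation rate at generation g of G: linear from mut_max (g=0) down to
    mut_min (g=G-1), floored at mut_min to prevent premature convergence."""
    _check_index(g, G, "generation")
    if G == 1:
        return p.mut_max
    value = p.mut_max - (p.mut_max - p.mut_min) * g / (G - 1)
    return max(p.mut_min, value)
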