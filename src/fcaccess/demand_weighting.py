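"""Age-adjusted demand weighting.

Service need is not uniform across ages: for strongly age-graded
conditions (end-stage kidney disease being the motivating example, with
incidence rising from ~11 per million/year in children to ~2080 per
million/year above 75), raw population is a poor demand proxy. This
module converts per-age-group incidence rates into integer weights
relative to a baseline group and replaces each demand unit's population
with the weighted sum of its age-group counts:

    adjusted_demand_i = sum_g weight(g) * N_{i,g}

Weights are incidence-rate ratios rounded to the nearest integer (half
away from zero), baseline weight 1; an ``integer=False`` flag keeps the
raw ratios for sensitivity analyses. Group labels are opaque strings
matched exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ValidationError
from .geodata_io import DemandLayer


@dataclass(frozen=True)
class AgeRateTable:
    """Ordered incidence rates (cases per million per year) per age group."""

    groups: tuple  # group labels, ordered
    rates: tuple  # incidence rates, same order
    baseline: str  # label of the reference group

    def __post_init__(self):
        if len(self.groups) != len(set(self.groups)):
            raise ValidationError("age-group labels must be unique")
        if len(self.groups) != len(self.rates):
            raise ValidationError("groups and rates differ in length")
        if any(r <= 0 for r in self.rates):
            raise DomainError("incidence rates must be positive")
        if self.baseline not in self.groups:
            raise DomainError(f"baseline group {self.baseline!r} not in table")

    @property
    def baseline_rate(self) -> float:
        return self.rates[self.groups.index(self.baseline)]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def compute_age_weights(rates: AgeRateTable, integer: bool = True) -> dict:
    """Incidence-rate-ratio weight per group, baseline mapped to 1.

    Ratios rate(g)/rate(baseline) are rounded half-away-from-zero to
    integers unless ``integer=False``.
    """
    base = rates.baseline_rate
    if base <= 0:
        raise DomainError("baseline incidence rate must be positive")
    weights = {}
    for grp, rate in zip(rates.groups, rates.rates):
        ratio = rate / base
        weights[grp] = _round_half_away(ratio) if integer else ratio
    weights[rates.baseline] = 1 if integer else 1.0
    return weights


def apply_age_adjustment(demand: DemandLayer, weights: dict) -> DemandLayer:
    """Demand layer whose population is the age-weighted count sum.

    Every group in ``weights`` must be present in ``demand.age_counts``;
    original counts (and all other attributes) are retained.
    """
    if not demand.age_counts:
        raise ValidationError("demand layer carries no age-group counts")
    missing = [g for g in weights if g not in demand.age_counts]
    if missing:
        raise ValidationError(
            f"age groups {missing} not present in demand layer "
            f"(available: {sorted(demand.age_counts, key=str)})"
        )
    adjusted = np.zeros(len(demand), dtype=float)
    for grp, w in weights.items():
        counts = demand.age_counts[grp]
        bad = np.flatnonzero(~np.isfinite(counts))
        if bad.size:
            raise ValidationError(
                f"record {demand.demand_id[bad[0]]!r} has invalid count for group {grp!r}"
            )
        adjusted += float(w) * counts
    return demand.with_population(adjusted)


def read_age_rate_table(path, baseline: str) -> AgeRateTable:
    """Read a ``group,rate_per_million`` CSV into an :class:`AgeRateTable`."""
    import pandas as pd

    df = pd.read_csv(path)
    for col in ("group", "rate_per_million"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return AgeRateTable(
        tuple(str(g) for g in df["group"]),
        tuple(float(r) for r in df["rate_per_million"]),
        baseline,
    )
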