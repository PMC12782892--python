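"""Storability phenotyping from monthly cold-storage series.

Flesh firmness retainability (FFR) and flesh crispness retainability
(FCR) are defined as the maximum time, in months of cold storage, for
which the fruit maintained acceptable flesh firmness (>= 7.0 kg/cm²) or
crispness (>= 0.7 kg/cm²).  Fruit are sampled monthly starting one month
after harvest; "maintained" is read as uninterrupted, so a single
sub-threshold month ends the retention period.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .core import AlignmentError, ConfigError, DegenerateDataError

#: default acceptability thresholds, kg/cm²
FIRMNESS_THRESHOLD = 7.0
CRISPNESS_THRESHOLD = 0.7

__all__ = [
    "FIRMNESS_THRESHOLD",
    "CRISPNESS_THRESHOLD",
    "StorageTrait",
    "StorageSeries",
    "RetainabilityResult",
    "retainability",
    "aggregate_replicates",
]


class StorageTrait(str, Enum):
    firmness = "firmness"
    crispness = "crispness"


@dataclass(frozen=True)
class StorageSeries:
    """Monthly measurements of one fruit lot during cold storage.

    ``values[t-1]`` is the measurement at month ``t`` of storage
    (month 1 = first monthly sampling after harvest); the at-harvest
    measurement is the FF/FC phenotype, not part of the series.
    """

    trait: StorageTrait
    values: tuple[float, ...]
    replicate_id: str = ""
    unit: str = "kg/cm2"

    def __post_init__(self) -> None:
        object.__setattr__(self, "trait", StorageTrait(self.trait))
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if any(v < 0 for v in self.values):
            raise ConfigError("storage measurements must be >= 0")

    @property
    def n_months(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class RetainabilityResult:
    """Retainability in months plus a right-censoring flag.

    ``censored`` is True when every observed month passed the threshold,
    i.e. the true retainability is only known to be >= ``months``.
    """

    months: int
    censored: bool

    def __int__(self) -> int:
        return self.months

    def __eq__(self, other: object) -> bool:
        if isinstance(other, int):
            return self.months == other
        if isinstance(other, RetainabilityResult):
            return (self.months, self.censored) == (other.months, other.censored)
        return NotImplemented

    def __hash__(self) -> int:
        return hash((self.months, self.censored))


def retainability(series: StorageSeries, threshold: float) -> RetainabilityResult:
    """Largest month ``t`` such that months 1..t all meet the threshold.

    Returns 0 if the month-1 value already fails, and the full series
    length with ``censored=True`` if every month passes.

    Parameters
    ----------
    series : StorageSeries
    threshold : float
        Acceptability threshold in the series' unit; must be positive
        (7.0 kg/cm² for firmness, 0.7 kg/cm² for crispness by default).
    """
    if series.n_months == 0:
        raise DegenerateDataError("empty storage series")
    if threshold <= 0:
        raise ConfigError(f"threshold must be > 0 (got {threshold})")
    months = 0
    for v in series.values:
        if v >= threshold:
            months += 1
        else:
            return RetainabilityResult(months=months, censored=False)
    return RetainabilityResult(months=months, censored=True)


def aggregate_replicates(
    series_set: Sequence[StorageSeries], method: str = "mean"
) -> StorageSeries:
    """Combine biological replicates into one per-month mean series.

    All replicates must share the trait and the number of observed
    months; mixed lengths raise :class:`AlignmentError` rather than
    being truncated, since a short replicate usually means a lost fruit,
    not an aligned shorter series.
    """
    if method != "mean":
        raise ValueError(f"unknown aggregation method {method!r}")
    if not series_set:
        raise DegenerateDataError("no replicate series given")
    trait = series_set[0].trait
    n = series_set[0].n_months
    for s in series_set:
        if s.trait is not trait:
            raise AlignmentError(f"mixed traits: {s.trait} vs {trait}")
        if s.n_months != n:
            raise AlignmentError(
                f"replicate {s.replicate_id!r} has {s.n_months} months, expected {n}"
            )
    mat = np.array([s.values for s in series_set], dtype=float)
    return StorageSeries(
        trait=trait,
        values=tuple(mat.mean(axis=0)),
        replicate_id="mean",
        unit=series_set[0].unit,
    )
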