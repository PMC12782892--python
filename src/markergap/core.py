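"""Shared domain types for marker-based storability prediction.

The objects here model a targeted genotyping panel (a few hundred
QTL-derived SNP/InDel markers assayed on apple germplasm and hybrid
lines), diploid genotype calls with explicit missingness, phenotype
tables for harvest firmness/crispness and their retainabilities, and
genomic intervals used when narrowing QTL windows.

Genotype calls are stored as canonical ``"X/Y"`` strings where ``X`` and
``Y`` are alleles of the marker ordered by their index in the marker's
allele list, so ``"A/T"`` and ``"T/A"`` compare equal after
canonicalization.  The missing call is the single symbol ``"."``.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum

import numpy as np
import pandas as pd

MISSING = "."

__all__ = [
    "MISSING",
    "MarkerGapError",
    "ParseError",
    "GenotypeError",
    "ConfigError",
    "DegenerateDataError",
    "AlignmentError",
    "EmptyJoinError",
    "MarkerClass",
    "Marker",
    "GenotypeMatrix",
    "PhenotypeTable",
    "GenomicInterval",
    "IntervalConvention",
    "CompositionTable",
    "canonical_call",
    "interval_length_kb",
    "deletion_length_bp",
    "genotype_frequencies",
    "segregation_ratio",
]


class MarkerGapError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(MarkerGapError):
    """A file could not be parsed (malformed row, bad header...)."""


class GenotypeError(MarkerGapError):
    """A genotype call is inconsistent with its marker definition."""


class ConfigError(MarkerGapError):
    """A simulation or model configuration value is invalid."""


class DegenerateDataError(MarkerGapError):
    """Input is structurally valid but degenerate (empty series, all-zero counts...)."""


class AlignmentError(MarkerGapError):
    """Series or tables that must align (same length/trait) do not."""


class EmptyJoinError(MarkerGapError):
    """Genotype and phenotype tables share no usable individuals."""


class MarkerClass(str, Enum):
    """Whether a marker tags a validated causal variant or is merely linked."""

    functional = "functional"
    linkage = "linkage"


@dataclass(frozen=True)
class Marker:
    """One assayed variant: identity, location, alleles and class.

    Parameters
    ----------
    marker_id : str
        Unique identifier within a panel (e.g. ``"Chr16_9127269"``).
    chrom : str
        Chromosome name.
    pos : int
        1-based position of the variant.
    alleles : tuple of str
        At least two distinct allele strings.  An allele may be a
        multi-base string or a named deletion symbol such as
        ``"Del216"``.
    marker_class : MarkerClass
        ``functional`` (on a validated causal variant) or ``linkage``.
    """

    marker_id: str
    chrom: str
    pos: int
    alleles: tuple[str, ...]
    marker_class: MarkerClass = MarkerClass.linkage

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", tuple(self.alleles))
        object.__setattr__(self, "marker_class", MarkerClass(self.marker_class))
        if self.pos < 1:
            raise GenotypeError(
                f"marker {self.marker_id!r}: pos must be >= 1 (got {self.pos})"
            )
        if len(self.alleles) < 2:
            raise GenotypeError(
                f"marker {self.marker_id!r}: needs >= 2 alleles (got {self.alleles!r})"
            )
        if len(set(self.alleles)) != len(self.alleles):
            raise GenotypeError(
                f"marker {self.marker_id!r}: alleles must be distinct ({self.alleles!r})"
            )
        if MISSING in self.alleles:
            raise GenotypeError(
                f"marker {self.marker_id!r}: {MISSING!r} is the missing symbol, not an allele"
            )

    def allele_index(self, allele: str) -> int:
        try:
            return self.alleles.index(allele)
        except ValueError:
            raise GenotypeError(
                f"allele {allele!r} not defined for marker {self.marker_id!r} "
                f"(alleles: {'/'.join(self.alleles)})"
            ) from None

    def genotype(self, a: str, b: str) -> str:
        """Canonical call string for the unordered allele pair ``(a, b)``."""
        i, j = sorted((self.allele_index(a), self.allele_index(b)))
        return f"{self.alleles[i]}/{self.alleles[j]}"

    @property
    def genotype_classes(self) -> list[str]:
        """All possible canonical diploid genotypes at this marker."""
        n = len(self.alleles)
        return [
            f"{self.alleles[i]}/{self.alleles[j]}"
            for i in range(n)
            for j in range(i, n)
        ]


def canonical_call(call: str, marker: Marker, *, individual: str | None = None) -> str:
    """Canonicalize a raw ``"X/Y"`` call against a marker definition.

    Allele order in the input never matters; the returned heterozygote is
    ordered by allele index.  ``"."`` and ``"./."`` both map to the
    missing symbol.  An allele absent from the marker raises
    :class:`GenotypeError` naming the marker and, when given, the
    individual.
    """
    call = call.strip()
    if call in (MISSING, "./.", ""):
        return MISSING
    parts = call.split("/")
    if len(parts) != 2:
        raise GenotypeError(
            f"call {call!r} at marker {marker.marker_id!r} is not of the form 'X/Y'"
        )
    try:
        return marker.genotype(parts[0], parts[1])
    except GenotypeError as exc:
        if individual is not None:
            raise GenotypeError(f"individual {individual!r}: {exc}") from None
        raise


@dataclass
class GenotypeMatrix:
    """Diploid calls for individuals x markers with explicit missingness.

    ``calls`` is a pandas DataFrame indexed by individual id with one
    column per marker id; every non-missing cell is a canonical call
    using only that marker's alleles.  ``populations`` optionally labels
    individuals with a free-string population/species name.
    """

    markers: list[Marker]
    calls: pd.DataFrame
    populations: pd.Series | None = None

    def __post_init__(self) -> None:
        ids = [m.marker_id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise GenotypeError("duplicate marker ids in panel")
        if list(self.calls.columns) != ids:
            raise GenotypeError(
                "calls columns do not match marker panel "
                f"({list(self.calls.columns)} vs {ids})"
            )
        if self.calls.index.has_duplicates:
            raise GenotypeError("duplicate individual ids")
        self._by_id = {m.marker_id: m for m in self.markers}

    @classmethod
    def from_raw(
        cls,
        markers: Sequence[Marker],
        raw_calls: pd.DataFrame,
        populations: pd.Series | None = None,
    ) -> "GenotypeMatrix":
        """Validate and canonicalize a DataFrame of raw call strings."""
        markers = list(markers)
        calls = raw_calls.copy()
        for m in markers:
            col = calls[m.marker_id]
            calls[m.marker_id] = [
                canonical_call("." if pd.isna(c) else str(c), m, individual=str(ind))
                for ind, c in col.items()
            ]
        return cls(markers=markers, calls=calls, populations=populations)

    @property
    def individuals(self) -> list[str]:
        return list(self.calls.index)

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    @property
    def n_individuals(self) -> int:
        return len(self.calls.index)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker(self, marker_id: str) -> Marker:
        try:
            return self._by_id[marker_id]
        except KeyError:
            raise KeyError(f"marker {marker_id!r} not in panel") from None

    def missingness_summary(self) -> pd.Series:
        """Per-marker count of missing calls."""
        return (self.calls == MISSING).sum(axis=0)

    def subset(self, individuals: Iterable[str]) -> "GenotypeMatrix":
        idx = list(individuals)
        pops = self.populations.loc[idx] if self.populations is not None else None
        return GenotypeMatrix(self.markers, self.calls.loc[idx], pops)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return self.markers == other.markers and self.calls.equals(other.calls)


@dataclass
class PhenotypeTable:
    """Trait values per individual; missing individuals simply absent.

    ``trait`` is one of the canonical codes (FF, FC in kg/cm²; FFR, FCR
    in months) or any user-defined name.  Retainabilities must be
    non-negative.
    """

    trait: str
    values: pd.Series
    unit: str = ""

    def __post_init__(self) -> None:
        self.values = pd.Series(self.values, dtype=float)
        self.values = self.values.dropna()
        if self.trait in ("FFR", "FCR") and (self.values < 0).any():
            bad = self.values[self.values < 0].index[0]
            raise ConfigError(
                f"{self.trait} must be >= 0 months (individual {bad!r})"
            )

    def __len__(self) -> int:
        return len(self.values)


class IntervalConvention(str, Enum):
    difference = "difference"
    inclusive = "inclusive"


@dataclass(frozen=True)
class GenomicInterval:
    """1-based genomic interval with an explicit length convention.

    Under ``difference`` (the default for QTL windows) the length is
    ``end - start``; under ``inclusive`` (used for deletions whose both
    endpoints are deleted bases) it is ``end - start + 1``.
    """

    chrom: str
    start: int
    end: int
    convention: IntervalConvention = IntervalConvention.difference

    def __post_init__(self) -> None:
        object.__setattr__(self, "convention", IntervalConvention(self.convention))
        if self.end < self.start:
            raise ConfigError(
                f"interval {self.chrom}:{self.start}-{self.end}: end < start"
            )

    @property
    def length_bp(self) -> int:
        n = self.end - self.start
        if self.convention is IntervalConvention.inclusive:
            n += 1
        return n


def _round_half_up(x: float, ndigits: int = 1) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("1." + "0" * ndigits), ROUND_HALF_UP))


def interval_length_kb(iv: GenomicInterval) -> float:
    """Interval length in kb, rounded half-up to one decimal.

    Matches how narrowed QTL windows are reported, e.g. a window from
    28,907,974 to 29,398,499 bp prints as 490.5 kb.
    """
    return _round_half_up(iv.length_bp / 1000.0, 1)


def deletion_length_bp(start: int, end: int) -> int:
    """Length of a deletion whose first and last deleted bases are ``start``/``end``."""
    if end < start:
        raise ConfigError(f"deletion {start}-{end}: end < start")
    return end - start + 1


@dataclass
class CompositionTable:
    """Genotype-frequency composition per group, missing counted separately.

    ``frequencies`` rows (groups) sum to 1 over non-missing genotype
    classes; groups whose calls are all missing have an all-zero row.
    """

    marker_id: str
    frequencies: pd.DataFrame
    missing: pd.Series


def genotype_frequencies(
    gm: GenotypeMatrix,
    marker_id: str,
    grouping: Mapping[str, str] | None = None,
) -> CompositionTable:
    """Per-group genotype frequencies at one marker.

    Parameters
    ----------
    gm : GenotypeMatrix
    marker_id : str
        Marker to tabulate; raises ``KeyError`` if absent.
    grouping : mapping individual id -> group label, optional
        Individuals absent from the mapping are dropped.  When omitted,
        all individuals form one group ``"all"``.

    Returns
    -------
    CompositionTable
        Frequencies over non-missing calls (rows sum to 1 within 1e-12)
        plus a separate per-group missing count.
    """
    gm.marker(marker_id)  # raises if absent
    col = gm.calls[marker_id]
    if grouping is None:
        groups = pd.Series("all", index=col.index)
    else:
        groups = pd.Series({i: g for i, g in grouping.items() if i in col.index})
        col = col.loc[groups.index]
    if groups.empty:
        raise DegenerateDataError("no individuals in any group")

    rows: dict[str, pd.Series] = {}
    missing: dict[str, int] = {}
    for g, sub in col.groupby(groups, sort=True):
        n_miss = int((sub == MISSING).sum())
        called = sub[sub != MISSING]
        counts = called.value_counts()
        rows[g] = counts / counts.sum() if len(called) else counts.astype(float)
        missing[g] = n_miss
    freq = pd.DataFrame(rows).T.fillna(0.0)
    freq = freq.reindex(sorted(freq.columns), axis=1)
    return CompositionTable(
        marker_id=marker_id,
        frequencies=freq,
        missing=pd.Series(missing, name="n_missing"),
    )


def segregation_ratio(
    counts: Mapping[str, int],
    order: Sequence[str] | None = None,
) -> str:
    """Reduce genotype counts by their gcd and render as ``"a:b:c"``.

    ``order`` fixes the genotype order in the output (defaults to the
    mapping's own order).  All-zero counts are degenerate.
    """
    if order is None:
        order = list(counts)
    vals = []
    for g in order:
        c = int(counts.get(g, 0))
        if c < 0:
            raise ConfigError(f"negative count for genotype {g!r}")
        vals.append(c)
    if not any(vals):
        raise DegenerateDataError("all genotype counts are zero")
    g = 0
    for v in vals:
        g = math.gcd(g, v)
    return ":".join(str(v // g) for v in vals)
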