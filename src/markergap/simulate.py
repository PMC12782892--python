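"""Synthetic populations with known genetic architecture.

The genotype–phenotype training data behind the storability models (612
germplasm accessions plus 1,191 biparental hybrids) are not publicly
deposited, so every downstream stage — effect estimation, additive and
non-additive prediction, cross-validation — is exercised against
populations simulated here with a fully known truth: Mendelian
biparental segregation or Hardy–Weinberg accession sampling, per-marker
genotype effects (directly specified or via an additive value ``a`` and
dominance degree ``d``), joint effects for declared interacting marker
sets, i.i.d. Gaussian residual noise, and random missingness.

Markers segregate independently: the prediction method treats markers
as exchangeable predictors, so a linkage map adds nothing testable.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    ConfigError,
    GenotypeMatrix,
    Marker,
    PhenotypeTable,
)
from .phenotyping import StorageSeries, StorageTrait

__all__ = [
    "MarkerArchitecture",
    "InteractingSetTruth",
    "TrueEffectConfig",
    "SimulatedCohort",
    "simulate_biparental_genotypes",
    "simulate_accession_genotypes",
    "genetic_value",
    "genetic_values",
    "simulate_phenotypes",
    "inject_missing",
    "simulate_softening_series",
    "simulate_cohort",
]


@dataclass(frozen=True)
class MarkerArchitecture:
    """True genotype→effect map for one marker (trait units)."""

    marker: Marker
    effects: Mapping[str, float]

    def __post_init__(self) -> None:
        valid = set(self.marker.genotype_classes)
        bad = set(self.effects) - valid
        if bad:
            raise ConfigError(
                f"marker {self.marker.marker_id!r}: effects for unknown genotypes {sorted(bad)}"
            )
        object.__setattr__(self, "effects", dict(self.effects))

    @classmethod
    def additive_dominance(
        cls, marker: Marker, a: float, d: float = 0.0
    ) -> "MarkerArchitecture":
        """Biallelic (a, d) parameterization.

        Maps to genotype effects ``{ref-hom: +a, het: d*a, alt-hom: -a}``:
        ``d = 0`` is purely additive, ``|d| = 1`` dominant, and
        ``0 < |d| < 1`` the partial-dominant action that functional
        storability markers typically show.
        """
        if len(marker.alleles) != 2:
            raise ConfigError(
                f"(a, d) parameterization needs a biallelic marker "
                f"({marker.marker_id!r} has {len(marker.alleles)} alleles)"
            )
        ref, alt = marker.alleles
        return cls(
            marker,
            {
                f"{ref}/{ref}": +a,
                f"{ref}/{alt}": d * a,
                f"{alt}/{alt}": -a,
            },
        )


@dataclass(frozen=True)
class InteractingSetTruth:
    """Total combination→joint-effect map for one interacting marker set."""

    set_id: str
    member_ids: tuple[str, ...]
    combos: Mapping[tuple[str, ...], float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "member_ids", tuple(self.member_ids))
        object.__setattr__(self, "combos", dict(self.combos))
        for combo in self.combos:
            if len(combo) != len(self.member_ids):
                raise ConfigError(
                    f"set {self.set_id!r}: combo {combo!r} length != number of members"
                )


def build_joint_map(
    members: Sequence[MarkerArchitecture],
    epistasis: Mapping[tuple[str, ...], float] | None = None,
) -> dict[tuple[str, ...], float]:
    """Total joint map = sum of member effects plus optional epistatic extras.

    Enumerates every genotype-class combination of the members so the
    truth map is total by construction.
    """
    epistasis = dict(epistasis or {})
    combos: list[tuple[str, ...]] = [()]
    for arch in members:
        combos = [c + (g,) for c in combos for g in arch.marker.genotype_classes]
    out = {}
    for combo in combos:
        base = sum(
            arch.effects.get(g, 0.0) for arch, g in zip(members, combo)
        )
        out[combo] = base + epistasis.get(combo, 0.0)
    return out


@dataclass
class TrueEffectConfig:
    """Simulation truth: mean, per-marker effects, joint effects, noise.

    Also reusable as a hand-built prediction model in tests, since the
    genetic-value sum mirrors how predicted values are formed: markers
    inside an interacting set contribute only through the set's joint
    effect (no double counting); all other markers contribute their
    per-genotype effect; the population mean anchors the scale.
    """

    population_mean: float
    markers: list[MarkerArchitecture] = field(default_factory=list)
    interacting_sets: list[InteractingSetTruth] = field(default_factory=list)
    residual_sd: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ConfigError(f"residual_sd must be >= 0 (got {self.residual_sd})")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigError(f"missing_rate must be in [0, 1] (got {self.missing_rate})")
        ids = {a.marker.marker_id for a in self.markers}
        for s in self.interacting_sets:
            missing = set(s.member_ids) - ids
            if missing:
                raise ConfigError(
                    f"interacting set {s.set_id!r}: members {sorted(missing)} not in marker list"
                )

    @property
    def marker_ids(self) -> list[str]:
        return [a.marker.marker_id for a in self.markers]

    @property
    def set_member_ids(self) -> set[str]:
        out: set[str] = set()
        for s in self.interacting_sets:
            out.update(s.member_ids)
        return out


@dataclass
class SimulatedCohort:
    """A simulated population plus everything needed to score recovery."""

    genotypes: GenotypeMatrix
    phenotypes: dict[str, PhenotypeTable]
    truth: TrueEffectConfig
    genetic_values: dict[str, pd.Series]
    signal_fraction: dict[str, float]


def _check_parent(parent: Mapping[str, str], markers: Sequence[Marker], name: str):
    for m in markers:
        call = parent.get(m.marker_id)
        if call is None or call == MISSING:
            raise ConfigError(
                f"parent {name!r} is not fully genotyped (marker {m.marker_id!r})"
            )


def simulate_biparental_genotypes(
    markers: Sequence[Marker],
    parent1: Mapping[str, str],
    parent2: Mapping[str, str],
    n_offspring: int,
    seed: int,
    id_prefix: str = "F1",
) -> GenotypeMatrix:
    """F1 offspring of a biparental cross, no linkage.

    Each offspring inherits one allele drawn uniformly from each
    parent's pair, independently across markers (mirroring how the
    hybrid populations behind the training data were produced, minus
    linkage).  Deterministic under the seed.
    """
    markers = list(markers)
    _check_parent(parent1, markers, "parent1")
    _check_parent(parent2, markers, "parent2")
    rng = np.random.default_rng(seed)
    cols = {}
    for m in markers:
        p1 = m.genotype(*parent1[m.marker_id].split("/")).split("/")
        p2 = m.genotype(*parent2[m.marker_id].split("/")).split("/")
        a = np.where(rng.integers(0, 2, n_offspring) == 0, p1[0], p1[1])
        b = np.where(rng.integers(0, 2, n_offspring) == 0, p2[0], p2[1])
        idx_a = np.vectorize(m.allele_index)(a)
        idx_b = np.vectorize(m.allele_index)(b)
        lo = np.minimum(idx_a, idx_b)
        hi = np.maximum(idx_a, idx_b)
        alleles = np.array(m.alleles)
        cols[m.marker_id] = np.char.add(
            np.char.add(alleles[lo], "/"), alleles[hi]
        )
    index = [f"{id_prefix}-{i + 1:04d}" for i in range(n_offspring)]
    return GenotypeMatrix(markers, pd.DataFrame(cols, index=index))


def simulate_accession_genotypes(
    markers: Sequence[Marker],
    allele_freqs: Mapping[str, Sequence[float]],
    n: int,
    seed: int,
    id_prefix: str = "ACC",
) -> GenotypeMatrix:
    """Unrelated accessions under Hardy–Weinberg proportions per marker."""
    markers = list(markers)
    rng = np.random.default_rng(seed)
    cols = {}
    for m in markers:
        freqs = np.asarray(allele_freqs[m.marker_id], dtype=float)
        if len(freqs) != len(m.alleles):
            raise ConfigError(
                f"marker {m.marker_id!r}: {len(freqs)} frequencies for "
                f"{len(m.alleles)} alleles"
            )
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ConfigError(
                f"marker {m.marker_id!r}: allele frequencies sum to {freqs.sum()!r}, not 1"
            )
        idx = rng.choice(len(m.alleles), size=(n, 2), p=freqs)
        lo = idx.min(axis=1)
        hi = idx.max(axis=1)
        alleles = np.array(m.alleles)
        cols[m.marker_id] = np.char.add(np.char.add(alleles[lo], "/"), alleles[hi])
    index = [f"{id_prefix}-{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(markers, pd.DataFrame(cols, index=index))


def genetic_value(cfg: TrueEffectConfig, calls: Mapping[str, str]) -> float:
    """Noiseless genetic value of one fully genotyped individual.

    population mean + per-marker effects for markers outside every
    interacting set + the joint effect of each set's observed member
    combination.  Truth maps must be total: an unlisted combination is a
    configuration error, never silently zero.
    """
    in_set = cfg.set_member_ids
    total = cfg.population_mean
    for arch in cfg.markers:
        mid = arch.marker.marker_id
        call = calls.get(mid)
        if call is None or call == MISSING:
            raise ConfigError(f"genetic value needs a call at every marker ({mid!r})")
        if mid in in_set:
            continue
        total += arch.effects.get(call, 0.0)
    for s in cfg.interacting_sets:
        combo = tuple(calls[mid] for mid in s.member_ids)
        if combo not in s.combos:
            raise ConfigError(
                f"interacting set {s.set_id!r}: no joint effect for combination {combo!r}"
            )
        total += s.combos[combo]
    return total


def genetic_values(cfg: TrueEffectConfig, gm: GenotypeMatrix) -> pd.Series:
    """Vectorized :func:`genetic_value` over a cohort (must be fully called)."""
    vals = pd.Series(cfg.population_mean, index=gm.calls.index, dtype=float)
    in_set = cfg.set_member_ids
    for arch in cfg.markers:
        mid = arch.marker.marker_id
        col = gm.calls[mid]
        if (col == MISSING).any():
            raise ConfigError(f"genetic values need full calls at marker {mid!r}")
        if mid in in_set:
            continue
        vals += col.map(arch.effects).fillna(0.0)
    for s in cfg.interacting_sets:
        combos = list(zip(*(gm.calls[mid] for mid in s.member_ids)))
        joint = []
        for combo in combos:
            if combo not in s.combos:
                raise ConfigError(
                    f"interacting set {s.set_id!r}: no joint effect for {combo!r}"
                )
            joint.append(s.combos[combo])
        vals += np.asarray(joint)
    return vals


def simulate_phenotypes(
    cfg: TrueEffectConfig,
    gm: GenotypeMatrix,
    trait: str,
    seed: int,
    unit: str = "",
) -> tuple[PhenotypeTable, pd.Series, float]:
    """Genetic value plus i.i.d. Gaussian noise for every individual.

    Returns the phenotype table, the noiseless genetic values, and the
    realized signal fraction var(genetic) / var(phenotype) (1.0 when
    ``residual_sd`` is 0 and the genetic values vary).
    """
    gv = genetic_values(cfg, gm)
    rng = np.random.default_rng(seed)
    noise = (
        rng.normal(0.0, cfg.residual_sd, len(gv)) if cfg.residual_sd > 0 else 0.0
    )
    values = gv + noise
    var_p = float(values.var(ddof=1)) if len(values) > 1 else 0.0
    frac = float(gv.var(ddof=1)) / var_p if var_p > 0 else float("nan")
    table = PhenotypeTable(trait=trait, values=values, unit=unit)
    return table, gv, frac


def inject_missing(gm: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Independently mask each call missing with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ConfigError(f"missing rate must be in [0, 1] (got {rate})")
    if rate == 0.0:
        return GenotypeMatrix(gm.markers, gm.calls.copy(), gm.populations)
    rng = np.random.default_rng(seed)
    mask = rng.random(gm.calls.shape) < rate
    calls = gm.calls.mask(pd.DataFrame(mask, index=gm.calls.index, columns=gm.calls.columns), MISSING)
    return GenotypeMatrix(gm.markers, calls, gm.populations)


def simulate_softening_series(
    initial: float,
    monthly_decay: float,
    n_months: int,
    noise_sd: float,
    seed: int,
    trait: StorageTrait | str = StorageTrait.firmness,
) -> StorageSeries:
    """Linear softening during storage: month t = max(0, initial - t*decay + noise).

    Month indexing starts at 1 (the first monthly sampling after
    harvest); callers model genotype-dependent storability by making the
    decay rate depend on genotype.
    """
    if n_months < 1:
        raise ConfigError(f"n_months must be >= 1 (got {n_months})")
    if monthly_decay < 0:
        raise ConfigError(f"monthly_decay must be >= 0 (got {monthly_decay})")
    rng = np.random.default_rng(seed)
    t = np.arange(1, n_months + 1)
    noise = rng.normal(0.0, noise_sd, n_months) if noise_sd > 0 else np.zeros(n_months)
    values = np.maximum(0.0, initial - t * monthly_decay + noise)
    return StorageSeries(trait=trait, values=tuple(values))


def simulate_cohort(
    cfg: TrueEffectConfig,
    gm: GenotypeMatrix,
    traits: Mapping[str, str] | Sequence[str] = ("trait",),
    seed: int | None = None,
) -> SimulatedCohort:
    """Bundle genotypes, noisy phenotypes and truth into one cohort.

    ``traits`` maps trait name -> unit (or is a bare sequence of names);
    each trait gets an independent noise realization.  Missingness, if
    configured, is injected after the genetic values are computed.
    """
    if seed is None:
        seed = cfg.seed
    if not isinstance(traits, Mapping):
        traits = {t: "" for t in traits}
    phenos: dict[str, PhenotypeTable] = {}
    gvs: dict[str, pd.Series] = {}
    fracs: dict[str, float] = {}
    for k, (trait, unit) in enumerate(traits.items()):
        table, gv, frac = simulate_phenotypes(cfg, gm, trait, seed + 1000 * (k + 1), unit)
        phenos[trait] = table
        gvs[trait] = gv
        fracs[trait] = frac
    observed = inject_missing(gm, cfg.missing_rate, seed + 99) if cfg.missing_rate else gm
    return SimulatedCohort(
        genotypes=observed,
        phenotypes=phenos,
        truth=cfg,
        genetic_values=gvs,
        signal_fraction=fracs,
    )
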