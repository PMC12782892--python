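"""Deviation-based marker effect estimation and the GAP regressor.

The method: for every marker, the effect of a genotype class is the
deviation of the mean observed phenotype value (OPV) of individuals
carrying that genotype from the grand mean of the training population.
Joint effects of an interacting marker set are the analogous deviations
for multi-marker genotype combinations and carry allelic dominance and
non-allelic epistasis that per-marker effects cannot.  The genotype
predicted value (GPV) of an individual is the population mean plus the
sum of its genotype effects and joint effects.

:class:`GapRegressor` packages this as a scikit-learn estimator
(``fit``/``predict`` on a DataFrame of diploid call strings), so it
composes with sklearn model selection; the module-level functions mirror
the underlying operations for direct use.
"""

from __future__ import annotations

import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .core import (
    MISSING,
    EmptyJoinError,
    GenotypeMatrix,
    Marker,
    PhenotypeTable,
)

__all__ = [
    "EffectEntry",
    "EstimatedEffects",
    "JointEffects",
    "InteractionLabel",
    "AllelicInteractionCall",
    "GapRegressor",
    "estimate_genotype_effects",
    "estimate_joint_effects",
    "classify_allelic_interaction",
    "marker_effect_magnitude",
    "train_gap_model",
    "compute_gpv",
    "predict_cohort",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class EffectEntry:
    """Effect estimate for one genotype class or combination.

    ``low_support`` marks classes observed fewer than ``min_class_n``
    times; their effect is forced to 0 and they never contribute to
    prediction.
    """

    effect: float
    n: int
    low_support: bool = False


@dataclass
class EstimatedEffects:
    """Per-marker genotype effects as deviations from the grand mean."""

    trait: str
    grand_mean: float
    min_class_n: int
    per_marker: dict[str, dict[str, EffectEntry]]

    def effect(self, marker_id: str, genotype: str) -> float:
        """Prediction-side effect: 0 for unseen or low-support classes."""
        entry = self.per_marker.get(marker_id, {}).get(genotype)
        if entry is None or entry.low_support:
            return 0.0
        return entry.effect


@dataclass
class JointEffects:
    """Joint effects for one interacting marker set.

    Combination tuples are ordered by ``member_marker_ids``.
    """

    set_id: str
    member_marker_ids: tuple[str, ...]
    min_class_n: int
    per_combo: dict[tuple[str, ...], EffectEntry]

    def effect(self, combo: tuple[str, ...]) -> float | None:
        """Joint effect, or None when the combo is unseen/low-support (fallback)."""
        entry = self.per_combo.get(combo)
        if entry is None or entry.low_support:
            return None
        return entry.effect


def _join(calls: pd.DataFrame, y: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
    y = pd.Series(y, dtype=float).dropna()
    shared = calls.index.intersection(y.index)
    if len(shared) == 0:
        raise EmptyJoinError("no individuals shared between genotypes and phenotypes")
    return calls.loc[shared], y.loc[shared]


def _effects_from_frame(
    calls: pd.DataFrame,
    y: pd.Series,
    trait: str,
    min_class_n: int,
) -> EstimatedEffects:
    """Deviation effects on an already-joined calls frame / phenotype vector."""
    if min_class_n < 1:
        raise ValueError(f"min_class_n must be >= 1 (got {min_class_n})")
    grand_mean = float(y.mean())
    per_marker: dict[str, dict[str, EffectEntry]] = {}
    for mid in calls.columns:
        col = calls[mid]
        ok = col != MISSING
        entries: dict[str, EffectEntry] = {}
        if ok.any():
            grouped = y[ok].groupby(col[ok])
            means = grouped.mean()
            counts = grouped.size()
            for g in means.index:
                n = int(counts[g])
                if n < min_class_n:
                    entries[g] = EffectEntry(0.0, n, low_support=True)
                else:
                    entries[g] = EffectEntry(float(means[g] - grand_mean), n)
        per_marker[mid] = entries
    return EstimatedEffects(
        trait=trait, grand_mean=grand_mean, min_class_n=min_class_n, per_marker=per_marker
    )


def _joint_from_frame(
    calls: pd.DataFrame,
    y: pd.Series,
    member_ids: Sequence[str],
    min_class_n: int,
    grand_mean: float,
    set_id: str,
) -> JointEffects:
    member_ids = list(member_ids)
    for mid in member_ids:
        if mid not in calls.columns:
            raise KeyError(f"interacting-set member {mid!r} not in genotype table")
    sub = calls[member_ids]
    fully_called = (sub != MISSING).all(axis=1)
    per_combo: dict[tuple[str, ...], EffectEntry] = {}
    if fully_called.any():
        keys = pd.MultiIndex.from_frame(sub[fully_called])
        grouped = y[fully_called].groupby(keys)
        means = grouped.mean()
        counts = grouped.size()
        for key, m in means.items():
            combo = tuple(key) if isinstance(key, tuple) else (key,)
            n = int(counts[key])
            if n < min_class_n:
                per_combo[combo] = EffectEntry(0.0, n, low_support=True)
            else:
                per_combo[combo] = EffectEntry(float(m - grand_mean), n)
    return JointEffects(
        set_id=set_id,
        member_marker_ids=tuple(member_ids),
        min_class_n=min_class_n,
        per_combo=per_combo,
    )


class GapRegressor(RegressorMixin, BaseEstimator):
    """Genomics-assisted prediction from a fixed marker panel.

    Fits deviation-from-grand-mean genotype effects (and, in
    non-additive mode, joint effects of declared interacting marker
    sets) on a training population, then predicts GPV = grand mean +
    sum of effects.

    Parameters
    ----------
    mode : {"additive", "nonadditive"}
        In additive mode interacting sets are stored but inert.
    interacting_sets : list of list of str, optional
        Marker-id sets whose joint genotype combinations get their own
        deviation effects (non-additive mode only).
    min_class_n : int, default 3
        Genotype classes or combinations observed fewer times are
        flagged and contribute 0.
    fallback_policy : {"additive_sum", "zero"}, default "additive_sum"
        What a set contributes when a member is missing or the observed
        combination was unseen/flagged in training: the sum of the
        members' individual effects, or nothing.
    include_set_members_additively : bool, default False
        By default markers inside an interacting set contribute only
        through the set's joint effect (no double counting).  True adds
        their individual effects as well — the literal reading of
        "genotype effects and joint effects of all markers" — offered
        for sensitivity analysis.
    trait : str, optional
        Label carried through to reports.

    Attributes
    ----------
    grand_mean_ : float
    effects_ : EstimatedEffects
    joint_ : list of JointEffects  (empty in additive mode)
    marker_ids_ : list of str
    n_features_in_ : int

    Examples
    --------
    >>> import pandas as pd
    >>> X = pd.DataFrame({"m1": ["A/A", "A/T", "T/T", "A/A"]},
    ...                  index=list("abcd"))
    >>> y = pd.Series([11.0, 8.0, 5.0, 11.0], index=list("abcd"))
    >>> model = GapRegressor(min_class_n=1).fit(X, y)
    >>> round(model.grand_mean_, 3)
    8.75
    """

    def __init__(
        self,
        mode: str = "additive",
        interacting_sets: list[list[str]] | None = None,
        min_class_n: int = 3,
        fallback_policy: str = "additive_sum",
        include_set_members_additively: bool = False,
        trait: str | None = None,
    ):
        self.mode = mode
        self.interacting_sets = interacting_sets
        self.min_class_n = min_class_n
        self.fallback_policy = fallback_policy
        self.include_set_members_additively = include_set_members_additively
        self.trait = trait

    # -- fitting ---------------------------------------------------------

    def fit(self, X, y) -> "GapRegressor":
        """Fit effects on a calls DataFrame (or GenotypeMatrix) and phenotypes."""
        if self.mode not in ("additive", "nonadditive"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.fallback_policy not in ("additive_sum", "zero"):
            raise ValueError(f"unknown fallback_policy {self.fallback_policy!r}")
        calls = X.calls if isinstance(X, GenotypeMatrix) else pd.DataFrame(X)
        if not isinstance(y, pd.Series):
            y = pd.Series(np.asarray(y, dtype=float), index=calls.index)
        calls, y = _join(calls, y)
        trait = self.trait or ""
        self.effects_ = _effects_from_frame(calls, y, trait, self.min_class_n)
        self.grand_mean_ = self.effects_.grand_mean
        self.marker_ids_ = list(calls.columns)
        self.n_features_in_ = len(self.marker_ids_)
        self.joint_ = []
        if self.mode == "nonadditive" and self.interacting_sets:
            for k, members in enumerate(self.interacting_sets):
                self.joint_.append(
                    _joint_from_frame(
                        calls, y, members, self.min_class_n, self.grand_mean_, f"set{k + 1}"
                    )
                )
        self._set_member_ids_ = set()
        for j in self.joint_:
            self._set_member_ids_.update(j.member_marker_ids)
        return self

    # -- prediction ------------------------------------------------------

    def _additive_marker_ids(self) -> list[str]:
        if self.include_set_members_additively:
            return self.marker_ids_
        return [m for m in self.marker_ids_ if m not in self._set_member_ids_]

    def predict_frame(self, X) -> pd.DataFrame:
        """Per-individual GPV plus the number of markers that used a fallback.

        Markers absent from ``X`` are treated as missing calls; markers
        in ``X`` but not in the model are ignored here (strict checking
        lives in :func:`compute_gpv`).  A missing, unseen, or
        low-support genotype contributes 0 and counts one fallback
        marker; an interacting set falling back counts all its members.
        """
        calls = X.calls if isinstance(X, GenotypeMatrix) else pd.DataFrame(X)
        overlap = [m for m in self.marker_ids_ if m in calls.columns]
        if not overlap:
            raise EmptyJoinError("no overlap between model panel and genotype table")
        n = len(calls.index)
        gpv = np.full(n, self.grand_mean_)
        n_fallback = np.zeros(n, dtype=int)

        for mid in self._additive_marker_ids():
            if mid not in calls.columns:
                n_fallback += 1
                continue
            col = calls[mid]
            eff_map = {
                g: e.effect
                for g, e in self.effects_.per_marker.get(mid, {}).items()
                if not e.low_support
            }
            contrib = col.map(eff_map)
            used = contrib.notna() & (col != MISSING)
            gpv += contrib.fillna(0.0).to_numpy()
            n_fallback += (~used).to_numpy()

        if self.mode == "nonadditive":
            for joint in self.joint_:
                members = list(joint.member_marker_ids)
                size = len(members)
                present = [m for m in members if m in calls.columns]
                if len(present) < size:
                    cols = {m: calls[m] if m in calls.columns else pd.Series(MISSING, index=calls.index) for m in members}
                else:
                    cols = {m: calls[m] for m in members}
                sub = pd.DataFrame(cols, index=calls.index)
                fully = (sub != MISSING).all(axis=1).to_numpy()
                joint_map = {
                    combo: e.effect
                    for combo, e in joint.per_combo.items()
                    if not e.low_support
                }
                keys = list(map(tuple, sub.to_numpy()))
                jvals = np.array(
                    [joint_map.get(k, np.nan) if f else np.nan for k, f in zip(keys, fully)]
                )
                hit = ~np.isnan(jvals)
                gpv += np.where(hit, jvals, 0.0)
                if self.fallback_policy == "additive_sum":
                    fb = np.zeros(n)
                    for m in members:
                        eff_map = {
                            g: e.effect
                            for g, e in self.effects_.per_marker.get(m, {}).items()
                            if not e.low_support
                        }
                        fb += sub[m].map(eff_map).fillna(0.0).to_numpy()
                    gpv += np.where(hit, 0.0, fb)
                n_fallback += np.where(hit, 0, size)

        return pd.DataFrame({"gpv": gpv, "n_fallback": n_fallback}, index=calls.index)

    def predict(self, X) -> np.ndarray:
        """Genotype predicted values, one per row of ``X``."""
        return self.predict_frame(X)["gpv"].to_numpy()


# -- module-level operations ---------------------------------------------


def estimate_genotype_effects(
    gm: GenotypeMatrix,
    ph: PhenotypeTable,
    trait: str | None = None,
    min_class_n: int = 3,
) -> EstimatedEffects:
    """Per-marker genotype effects as deviations from the grand mean.

    The grand mean is taken over every phenotyped individual in the
    joined cohort; an individual missing a call at one marker is
    excluded from that marker's classes but still counts toward the
    grand mean.
    """
    calls, y = _join(gm.calls, ph.values)
    return _effects_from_frame(calls, y, trait or ph.trait, min_class_n)


def estimate_joint_effects(
    gm: GenotypeMatrix,
    ph: PhenotypeTable,
    member_ids: Sequence[str],
    trait: str | None = None,
    min_class_n: int = 3,
    set_id: str = "set1",
) -> JointEffects:
    """Joint effects of one interacting marker set.

    Only individuals fully called at every member contribute to
    combination classes; the grand mean is shared with
    :func:`estimate_genotype_effects`.
    """
    calls, y = _join(gm.calls, ph.values)
    grand_mean = float(y.mean())
    return _joint_from_frame(calls, y, member_ids, min_class_n, grand_mean, set_id)


class InteractionLabel(str, Enum):
    additive = "additive"
    partial_dominant = "partial_dominant"
    dominant = "dominant"
    overdominant = "overdominant"
    undetermined = "undetermined"


@dataclass(frozen=True)
class AllelicInteractionCall:
    """Dominance classification of one biallelic marker.

    ``dominance_ratio`` is d/a: the heterozygote's deviation from the
    homozygote midpoint over half the homozygote spread.
    """

    marker_id: str
    dominance_ratio: float
    label: InteractionLabel


def classify_allelic_interaction(
    effects: Mapping[str, EffectEntry | float],
    marker_id: str = "",
) -> AllelicInteractionCall:
    """Classify allelic interaction from three genotype-class effects.

    Genotype keys must be of the biallelic forms ``X/X``, ``X/Y``,
    ``Y/Y``.  With ``a = (effect_XX - effect_YY)/2`` and ``d`` the
    heterozygote effect minus the homozygote midpoint, |d/a| <= 0.2 is
    additive, < 0.8 partial dominant, <= 1.2 dominant, larger
    overdominant.  Fewer than three usable classes (or a = d = 0) is
    undetermined.
    """
    usable: dict[str, float] = {}
    for g, e in effects.items():
        if isinstance(e, EffectEntry):
            if not e.low_support:
                usable[g] = e.effect
        else:
            usable[g] = float(e)
    if len(usable) != 3:
        return AllelicInteractionCall(marker_id, float("nan"), InteractionLabel.undetermined)

    homs, het = {}, None
    for g, v in usable.items():
        a1, a2 = g.split("/")
        if a1 == a2:
            homs[a1] = v
        else:
            het = v
    if len(homs) != 2 or het is None:
        return AllelicInteractionCall(marker_id, float("nan"), InteractionLabel.undetermined)

    e1, e2 = homs.values()
    a = (e1 - e2) / 2.0
    midpoint = (e1 + e2) / 2.0
    d = het - midpoint
    if a == 0.0:
        if d == 0.0:
            return AllelicInteractionCall(marker_id, float("nan"), InteractionLabel.undetermined)
        return AllelicInteractionCall(
            marker_id, float("inf") if d > 0 else float("-inf"), InteractionLabel.overdominant
        )
    ratio = d / a
    mag = abs(ratio)
    if mag <= 0.2:
        label = InteractionLabel.additive
    elif mag < 0.8:
        label = InteractionLabel.partial_dominant
    elif mag <= 1.2:
        label = InteractionLabel.dominant
    else:
        label = InteractionLabel.overdominant
    return AllelicInteractionCall(marker_id, ratio, label)


def marker_effect_magnitude(
    effects: Mapping[str, EffectEntry | float],
) -> float | None:
    """Scalar marker effect as the range (max - min) over usable classes.

    This range definition is this package's convention for summarizing a
    marker's per-genotype signed effects into one number; returns None
    (undetermined) with fewer than two usable classes.
    """
    vals = []
    for e in effects.values():
        if isinstance(e, EffectEntry):
            if not e.low_support:
                vals.append(e.effect)
        else:
            vals.append(float(e))
    if len(vals) < 2:
        return None
    return max(vals) - min(vals)


def train_gap_model(
    gm: GenotypeMatrix,
    ph: PhenotypeTable,
    trait: str | None = None,
    sets: Sequence[Sequence[str]] | None = None,
    mode: str = "additive",
    min_class_n: int = 3,
    fallback_policy: str = "additive_sum",
) -> GapRegressor:
    """Fit a :class:`GapRegressor` from domain objects."""
    model = GapRegressor(
        mode=mode,
        interacting_sets=[list(s) for s in sets] if sets else None,
        min_class_n=min_class_n,
        fallback_policy=fallback_policy,
        trait=trait or ph.trait,
    )
    return model.fit(gm.calls, ph.values)


def compute_gpv(model: GapRegressor, calls: Mapping[str, str]) -> float:
    """GPV for one individual given calls per marker id.

    Strict: a marker in ``calls`` that the model does not know raises
    ``KeyError``.  Markers the model knows but ``calls`` omits are
    treated as missing.
    """
    unknown = set(calls) - set(model.marker_ids_)
    if unknown:
        raise KeyError(f"markers not in model: {sorted(unknown)}")
    row = {mid: calls.get(mid, MISSING) for mid in model.marker_ids_}
    frame = pd.DataFrame([row], index=["_"])
    return float(model.predict_frame(frame)["gpv"].iloc[0])


def predict_cohort(model: GapRegressor, gm: GenotypeMatrix) -> pd.DataFrame:
    """Vectorized GPV over a cohort; columns ``gpv`` and ``n_fallback``."""
    return model.predict_frame(gm)


# -- persistence ----------------------------------------------------------

_COMBO_SEP = "|"


def _model_to_dict(model: GapRegressor) -> dict:
    return {
        "trait": model.trait,
        "mode": model.mode,
        "min_class_n": model.min_class_n,
        "fallback_policy": model.fallback_policy,
        "include_set_members_additively": model.include_set_members_additively,
        "grand_mean": model.grand_mean_,
        "marker_ids": model.marker_ids_,
        "effects": {
            mid: {
                g: {"effect": e.effect, "n": e.n, "low_support": e.low_support}
                for g, e in entries.items()
            }
            for mid, entries in model.effects_.per_marker.items()
        },
        "joint": [
            {
                "set_id": j.set_id,
                "members": list(j.member_marker_ids),
                "combos": {
                    _COMBO_SEP.join(combo): {
                        "effect": e.effect,
                        "n": e.n,
                        "low_support": e.low_support,
                    }
                    for combo, e in j.per_combo.items()
                },
            }
            for j in model.joint_
        ],
    }


def save_model(model: GapRegressor, path: str | Path) -> None:
    """Serialize a fitted model to JSON."""
    Path(path).write_text(json.dumps(_model_to_dict(model), indent=1))


def load_model(path: str | Path) -> GapRegressor:
    """Rebuild a fitted model from :func:`save_model` output."""
    d = json.loads(Path(path).read_text())
    model = GapRegressor(
        mode=d["mode"],
        interacting_sets=[j["members"] for j in d["joint"]] or None,
        min_class_n=d["min_class_n"],
        fallback_policy=d["fallback_policy"],
        include_set_members_additively=d["include_set_members_additively"],
        trait=d["trait"],
    )
    model.grand_mean_ = d["grand_mean"]
    model.marker_ids_ = list(d["marker_ids"])
    model.n_features_in_ = len(model.marker_ids_)
    model.effects_ = EstimatedEffects(
        trait=d["trait"] or "",
        grand_mean=d["grand_mean"],
        min_class_n=d["min_class_n"],
        per_marker={
            mid: {
                g: EffectEntry(v["effect"], v["n"], v["low_support"])
                for g, v in entries.items()
            }
            for mid, entries in d["effects"].items()
        },
    )
    model.joint_ = [
        JointEffects(
            set_id=j["set_id"],
            member_marker_ids=tuple(j["members"]),
            min_class_n=d["min_class_n"],
            per_combo={
                tuple(k.split(_COMBO_SEP)): EffectEntry(
                    v["effect"], v["n"], v["low_support"]
                )
                for k, v in j["combos"].items()
            },
        )
        for j in d["joint"]
    ]
    model._set_member_ids_ = set()
    for j in model.joint_:
        model._set_member_ids_.update(j.member_marker_ids)
    return model
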