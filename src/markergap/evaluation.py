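"""Prediction accuracy, cross-validation, and truth-recovery metrics.

Prediction accuracy is the Pearson correlation between genotype
predicted values (GPV) and observed phenotype values (OPV) on held-out
individuals; models are assessed by seeded k-fold (default 5-fold)
cross-validation.  For simulated cohorts, recovery of the known truth
is scored as bias/RMSE between estimated deviation effects and the true
effects re-centered under the cohort's realized genotype frequencies.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .core import (
    MISSING,
    EmptyJoinError,
    GenotypeMatrix,
    MarkerGapError,
    PhenotypeTable,
)
from .estimation import EstimatedEffects, GapRegressor, JointEffects
from .simulate import TrueEffectConfig

__all__ = [
    "UndefinedCorrelationError",
    "CVResult",
    "RecoveryReport",
    "prediction_accuracy",
    "kfold_cv",
    "repeated_kfold_cv",
    "parameter_recovery",
]


class UndefinedCorrelationError(MarkerGapError):
    """Pearson correlation undefined (zero variance or too few points)."""


def prediction_accuracy(
    gpv: Mapping[str, float] | pd.Series,
    opv: Mapping[str, float] | pd.Series,
) -> float:
    """Sample Pearson correlation between GPV and OPV over shared individuals.

    Raises :class:`UndefinedCorrelationError` with fewer than 3 shared
    individuals or zero variance in either vector, rather than
    propagating NaN.
    """
    gpv = pd.Series(gpv, dtype=float)
    opv = pd.Series(opv, dtype=float)
    shared = gpv.index.intersection(opv.index)
    if len(shared) < 3:
        raise UndefinedCorrelationError(
            f"need >= 3 shared individuals (got {len(shared)})"
        )
    x = gpv.loc[shared].to_numpy()
    y = opv.loc[shared].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in GPV or OPV")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class CVResult:
    """Per-fold and mean prediction accuracy of one seeded CV run.

    ``mean_r`` averages the defined per-fold correlations;
    ``n_undefined`` counts folds whose correlation was undefined (zero
    test-fold variance) and therefore excluded from the mean.
    """

    trait: str
    mode: str
    k: int
    seed: int
    fold_assignment: pd.Series
    per_fold_r: list[float]
    n_undefined: int = 0

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.per_fold_r)) if self.per_fold_r else float("nan")


def kfold_cv(
    gm: GenotypeMatrix,
    ph: PhenotypeTable,
    trait: str | None = None,
    sets: Sequence[Sequence[str]] | None = None,
    mode: str = "additive",
    k: int = 5,
    seed: int = 0,
    min_class_n: int = 3,
    fallback_policy: str = "additive_sum",
) -> CVResult:
    """Seeded k-fold cross-validation of a GAP model.

    Individuals with both genotypes and a phenotype are shuffled by the
    seed and split into k near-equal unstratified folds (sizes differ by
    at most 1); for each fold the model is trained on the complement and
    scored on the fold.  Fully reproducible under the seed.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2 (got {k})")
    y = ph.values
    shared = gm.calls.index.intersection(y.index)
    if len(shared) == 0:
        raise EmptyJoinError("no individuals shared between genotypes and phenotypes")
    if len(shared) < k:
        raise ValueError(f"n = {len(shared)} < k = {k}")
    calls = gm.calls.loc[shared]
    y = y.loc[shared]

    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = pd.Series(-1, index=shared, dtype=int)
    per_fold_r: list[float] = []
    n_undefined = 0
    for fold, (train_idx, test_idx) in enumerate(splitter.split(calls)):
        fold_of.iloc[test_idx] = fold
        model = GapRegressor(
            mode=mode,
            interacting_sets=[list(s) for s in sets] if sets else None,
            min_class_n=min_class_n,
            fallback_policy=fallback_policy,
            trait=trait or ph.trait,
        ).fit(calls.iloc[train_idx], y.iloc[train_idx])
        gpv = pd.Series(model.predict(calls.iloc[test_idx]), index=calls.index[test_idx])
        try:
            per_fold_r.append(prediction_accuracy(gpv, y.iloc[test_idx]))
        except UndefinedCorrelationError:
            n_undefined += 1
    return CVResult(
        trait=trait or ph.trait,
        mode=mode,
        k=k,
        seed=seed,
        fold_assignment=fold_of,
        per_fold_r=per_fold_r,
        n_undefined=n_undefined,
    )


def repeated_kfold_cv(
    gm: GenotypeMatrix,
    ph: PhenotypeTable,
    repeats: int,
    seed: int = 0,
    **kwargs,
) -> list[CVResult]:
    """Independent CV repetitions with derived seeds ``seed, seed+1, ...``."""
    return [kfold_cv(gm, ph, seed=seed + r, **kwargs) for r in range(repeats)]


@dataclass
class RecoveryReport:
    """Bias/RMSE of estimated effects against re-centered simulation truth."""

    per_marker: pd.DataFrame
    per_set: pd.DataFrame
    overall_rmse: float


def _realized_freqs(calls: pd.Series) -> pd.Series:
    called = calls[calls != MISSING]
    counts = called.value_counts()
    return counts / counts.sum()


def parameter_recovery(
    truth: TrueEffectConfig,
    est: EstimatedEffects,
    gm: GenotypeMatrix,
    joint_est: Sequence[JointEffects] = (),
) -> RecoveryReport:
    """Score effect estimates against the simulation truth.

    True per-marker effects are re-centered to deviations under the
    cohort's realized genotype frequencies (the estimand of the
    deviation method); likewise for joint-effect maps under realized
    combination frequencies.  Low-support estimate classes are skipped.
    Markers inside interacting sets are scored through their set, not
    per-marker.
    """
    in_set = truth.set_member_ids
    marker_rows = []
    sq_errors: list[float] = []
    for arch in truth.markers:
        mid = arch.marker.marker_id
        if mid in in_set:
            continue
        if mid not in est.per_marker:
            raise KeyError(f"marker {mid!r} missing from estimates")
        if mid not in gm.calls.columns:
            raise KeyError(f"marker {mid!r} missing from cohort")
        freqs = _realized_freqs(gm.calls[mid])
        centered_mean = float(sum(freqs.get(g, 0.0) * e for g, e in arch.effects.items()))
        errors = []
        for g, entry in est.per_marker[mid].items():
            if entry.low_support:
                continue
            true_dev = arch.effects.get(g, 0.0) - centered_mean
            errors.append(entry.effect - true_dev)
        if errors:
            marker_rows.append(
                {
                    "marker_id": mid,
                    "n_classes": len(errors),
                    "bias": float(np.mean(errors)),
                    "rmse": float(np.sqrt(np.mean(np.square(errors)))),
                }
            )
            sq_errors.extend(np.square(errors).tolist())

    set_rows = []
    joint_by_id = {tuple(j.member_marker_ids): j for j in joint_est}
    for s in truth.interacting_sets:
        j = joint_by_id.get(tuple(s.member_ids))
        if j is None:
            continue
        sub = gm.calls[list(s.member_ids)]
        fully = (sub != MISSING).all(axis=1)
        combos = pd.Series(list(map(tuple, sub[fully].to_numpy())))
        freqs = combos.value_counts(normalize=True)
        centered_mean = float(
            sum(freqs.get(c, 0.0) * e for c, e in s.combos.items())
        )
        errors = []
        for combo, entry in j.per_combo.items():
            if entry.low_support:
                continue
            true_dev = s.combos.get(combo, 0.0) - centered_mean
            errors.append(entry.effect - true_dev)
        if errors:
            set_rows.append(
                {
                    "set_id": s.set_id,
                    "n_combos": len(errors),
                    "bias": float(np.mean(errors)),
                    "rmse": float(np.sqrt(np.mean(np.square(errors)))),
                }
            )
            sq_errors.extend(np.square(errors).tolist())

    overall = float(np.sqrt(np.mean(sq_errors))) if sq_errors else float("nan")
    return RecoveryReport(
        per_marker=pd.DataFrame(marker_rows),
        per_set=pd.DataFrame(set_rows),
        overall_rmse=overall,
    )
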