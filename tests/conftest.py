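"""Shared fixtures: tiny hand-checkable cohorts and a random-cohort factory."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from markergap.core import MISSING, GenotypeMatrix, Marker, PhenotypeTable


@pytest.fixture
def snp() -> Marker:
    """Biallelic A/T SNP."""
    return Marker("m1", "Chr01", 100, ("A", "T"))


@pytest.fixture
def toy_cohort(snp):
    """One marker, five individuals: AA {10, 12}, AT {8}, TT {4, 6}.

    Grand mean 8; deviation effects AA +3, AT 0, TT -3.
    """
    calls = pd.DataFrame(
        {"m1": ["A/A", "A/A", "A/T", "T/T", "T/T"]},
        index=["i1", "i2", "i3", "i4", "i5"],
    )
    gm = GenotypeMatrix([snp], calls)
    ph = PhenotypeTable(
        trait="FF",
        values=pd.Series([10.0, 12.0, 8.0, 4.0, 6.0], index=calls.index),
        unit="kg/cm2",
    )
    return gm, ph


@pytest.fixture
def epistasis_cohort():
    """Two markers, four combos with phenotypes 10/6/6/10: pure epistasis.

    Grand mean 8; every per-marker effect is 0 while each combination
    deviates by +/-2.
    """
    m1 = Marker("m1", "Chr01", 100, ("A", "a"))
    m2 = Marker("m2", "Chr02", 200, ("B", "b"))
    calls = pd.DataFrame(
        {
            "m1": ["A/A", "A/A", "A/a", "A/a"],
            "m2": ["B/B", "B/b", "B/B", "B/b"],
        },
        index=["i1", "i2", "i3", "i4"],
    )
    gm = GenotypeMatrix([m1, m2], calls)
    ph = PhenotypeTable(
        trait="FFR",
        values=pd.Series([10.0, 6.0, 6.0, 10.0], index=calls.index),
        unit="months",
    )
    return gm, ph


def make_random_cohort(
    rng: np.random.Generator,
    n: int,
    n_markers: int = 3,
    missing_prob: float = 0.1,
) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Random cohort for oracle-equivalence and invariant checks."""
    markers = []
    cols = {}
    for j in range(n_markers):
        n_alleles = int(rng.integers(2, 4))
        alleles = tuple("ACGT"[:n_alleles])
        m = Marker(f"m{j + 1}", f"Chr{j + 1:02d}", 10 * (j + 1), alleles)
        markers.append(m)
        classes = m.genotype_classes
        col = rng.choice(classes, size=n)
        mask = rng.random(n) < missing_prob
        col = np.where(mask, MISSING, col)
        cols[m.marker_id] = col
    index = [f"i{k}" for k in range(n)]
    gm = GenotypeMatrix(markers, pd.DataFrame(cols, index=index))
    y = pd.Series(rng.normal(8.0, 2.0, n), index=index)
    return gm, PhenotypeTable(trait="trait", values=y)


def naive_effects(
    gm: GenotypeMatrix,
    ph: PhenotypeTable,
    min_class_n: int = 1,
) -> tuple[float, dict[str, dict[str, tuple[float, int]]]]:
    """Independent re-implementation of deviation effects with plain loops.

    Returns (grand_mean, {marker: {genotype: (effect, n)}}), flagged
    classes carrying effect 0.
    """
    shared = [i for i in gm.calls.index if i in ph.values.index]
    y = {i: float(ph.values[i]) for i in shared}
    grand = sum(y.values()) / len(y)
    out: dict[str, dict[str, tuple[float, int]]] = {}
    for mid in gm.calls.columns:
        groups: dict[str, list[float]] = {}
        for i in shared:
            call = gm.calls.at[i, mid]
            if call == MISSING:
                continue
            groups.setdefault(call, []).append(y[i])
        out[mid] = {
            g: ((sum(vals) / len(vals) - grand) if len(vals) >= min_class_n else 0.0,
                len(vals))
            for g, vals in groups.items()
        }
    return grand, out


def naive_joint_effects(
    gm: GenotypeMatrix,
    ph: PhenotypeTable,
    member_ids: list[str],
    min_class_n: int = 1,
) -> dict[tuple[str, ...], tuple[float, int]]:
    """Loop-based joint effects over fully-called member combinations."""
    shared = [i for i in gm.calls.index if i in ph.values.index]
    y = {i: float(ph.values[i]) for i in shared}
    grand = sum(y.values()) / len(y)
    groups: dict[tuple[str, ...], list[float]] = {}
    for i in shared:
        combo = tuple(gm.calls.at[i, m] for m in member_ids)
        if MISSING in combo:
            continue
        groups.setdefault(combo, []).append(y[i])
    return {
        c: ((sum(vals) / len(vals) - grand) if len(vals) >= min_class_n else 0.0,
            len(vals))
        for c, vals in groups.items()
    }
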