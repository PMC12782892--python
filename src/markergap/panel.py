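"""Default marker panel and study-scale synthetic training population.

The default panel mirrors the functional variants validated for apple
fruit storability — the MdNAC83 promoter deletion (Del216) and promoter
SNP934 T/C, the MdNAC83 coding SNP388 G/A, MdBPM2 SNP657 T/A, and
MdRGLG3 SNP167 C/G — plus eight QTL-linked markers, each with
partial-dominant effects on flesh firmness (FF), crispness (FC) and
their retainabilities (FFR, FCR).  The default interacting sets follow
the documented functional relationships: the MdNAC83 promoter/CDS
variant group, and the pairs of the MdNAC83 CDS variant with each of
its two E3-ligase regulators (MdBPM2, MdRGLG3).

``simulate_study_cohort`` emulates the structure of the (undeposited)
training population: 612 germplasm accessions under Hardy–Weinberg
sampling plus 1,191 F1 hybrids from three biparental crosses
('Zisai Pearl' × 'Red Fuji', 'Zisai Pearl' × 'Golden Delicious',
'Jonathan' × 'Golden Delicious'), with per-trait phenotype availability
matching the study (1,382 / 1,370 / 1,182 / 1,187 individuals for
FF / FC / FFR / FCR out of 1,803).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, Marker, MarkerClass, PhenotypeTable
from .simulate import (
    InteractingSetTruth,
    MarkerArchitecture,
    TrueEffectConfig,
    build_joint_map,
    genetic_values,
    inject_missing,
    simulate_accession_genotypes,
    simulate_biparental_genotypes,
)

__all__ = [
    "DEFAULT_MARKERS",
    "DEFAULT_INTERACTING_SETS",
    "TRAIT_UNITS",
    "StudyCohort",
    "study_truth_config",
    "simulate_study_cohort",
]

F = MarkerClass.functional
L = MarkerClass.linkage

#: Functional markers carry the validated variant; the first allele listed
#: is the storability-favorable one (positive effect homozygote).
DEFAULT_MARKERS: list[Marker] = [
    Marker("MdNAC83_Del216", "Chr16", 9126219, ("Del216", "del216"), F),
    Marker("MdNAC83_SNP934", "Chr16", 9127269, ("C", "T"), F),
    Marker("MdNAC83_SNP388", "Chr16", 9128903, ("A", "G"), F),
    Marker("MdBPM2_SNP657", "Chr03", 35391111, ("A", "T"), F),
    Marker("MdRGLG3_SNP167", "Chr16", 38704799, ("G", "C"), F),
    Marker("Chr03_27276582", "Chr03", 27276582, ("T", "C"), L),
    Marker("Chr03_29398499", "Chr03", 29398499, ("G", "A"), L),
    Marker("Chr15_40410846", "Chr15", 40410846, ("A", "G"), L),
    Marker("Chr16_3059544", "Chr16", 3059544, ("C", "T"), L),
    Marker("Chr02_10434413", "Chr02", 10434413, ("G", "T"), L),
    Marker("Chr03_25532731", "Chr03", 25532731, ("A", "C"), L),
    Marker("Chr10_40756571", "Chr10", 40756571, ("T", "A"), L),
    Marker("Chr16_38546603", "Chr16", 38546603, ("C", "G"), L),
]

#: additive value a (storability units = FFR months) and dominance degree d
#: per marker; all functional markers act partial-dominantly.
_BASE_AD: dict[str, tuple[float, float]] = {
    "MdNAC83_Del216": (0.60, 0.45),
    "MdNAC83_SNP934": (0.50, 0.40),
    "MdNAC83_SNP388": (1.30, 0.50),
    "MdBPM2_SNP657": (0.70, 0.45),
    "MdRGLG3_SNP167": (1.10, 0.55),
    "Chr03_27276582": (0.85, 0.35),
    "Chr03_29398499": (0.60, 0.30),
    "Chr15_40410846": (0.40, 0.40),
    "Chr16_3059544": (0.35, 0.30),
    "Chr02_10434413": (0.25, 0.25),
    "Chr03_25532731": (0.30, 0.35),
    "Chr10_40756571": (0.20, 0.30),
    "Chr16_38546603": (0.30, 0.40),
}

DEFAULT_INTERACTING_SETS: list[list[str]] = [
    ["MdNAC83_Del216", "MdNAC83_SNP934", "MdNAC83_SNP388"],
    ["MdNAC83_SNP388", "MdBPM2_SNP657"],
    ["MdNAC83_SNP388", "MdRGLG3_SNP167"],
]

#: epistatic extras (storability units) on top of the members' additive
#: effects; keyed by canonical genotype combinations in set order.
_BASE_EPISTASIS: list[dict[tuple[str, ...], float]] = [
    {
        ("Del216/Del216", "C/C", "A/A"): +0.90,
        ("del216/del216", "T/T", "G/G"): -0.60,
    },
    {("A/A", "A/A"): +0.60, ("G/G", "T/T"): -0.40},
    {("A/A", "G/G"): +0.60, ("G/G", "C/C"): -0.40},
]

TRAIT_UNITS = {"FF": "kg/cm2", "FC": "kg/cm2", "FFR": "months", "FCR": "months"}

#: per-trait (population mean, effect scale multiplier, residual SD); the
#: residual SDs put the marker-explained fraction of phenotypic variance
#: near 0.35-0.40, reflecting the low-to-moderate heritability of
#: storability traits
_TRAIT_PARAMS: dict[str, tuple[float, float, float]] = {
    "FF": (8.2, 0.40, 1.80),
    "FC": (0.95, 0.040, 0.18),
    "FFR": (5.0, 0.70, 3.20),
    "FCR": (4.5, 0.60, 2.80),
}

#: favorable-allele frequency among germplasm accessions
_ACCESSION_FREQ: dict[str, float] = {
    "MdNAC83_Del216": 0.40,
    "MdNAC83_SNP934": 0.45,
    "MdNAC83_SNP388": 0.35,
    "MdBPM2_SNP657": 0.50,
    "MdRGLG3_SNP167": 0.30,
    "Chr03_27276582": 0.55,
    "Chr03_29398499": 0.45,
    "Chr15_40410846": 0.60,
    "Chr16_3059544": 0.35,
    "Chr02_10434413": 0.50,
    "Chr03_25532731": 0.40,
    "Chr10_40756571": 0.55,
    "Chr16_38546603": 0.45,
}

# founder genotypes (favorable/unfavorable allele per marker); heterozygous
# where segregation in the corresponding cross is documented or plausible
_FOUNDERS: dict[str, dict[str, str]] = {
    "Zisai Pearl": {
        "MdNAC83_Del216": "Del216/del216",
        "MdNAC83_SNP934": "C/T",
        "MdNAC83_SNP388": "G/G",
        "MdBPM2_SNP657": "A/T",
        "MdRGLG3_SNP167": "G/C",
        "Chr03_27276582": "T/C",
        "Chr03_29398499": "G/A",
        "Chr15_40410846": "A/G",
        "Chr16_3059544": "C/T",
        "Chr02_10434413": "G/T",
        "Chr03_25532731": "A/A",
        "Chr10_40756571": "T/A",
        "Chr16_38546603": "C/G",
    },
    "Red Fuji": {
        "MdNAC83_Del216": "Del216/del216",
        "MdNAC83_SNP934": "C/T",
        "MdNAC83_SNP388": "A/G",
        "MdBPM2_SNP657": "T/T",
        "MdRGLG3_SNP167": "G/C",
        "Chr03_27276582": "T/C",
        "Chr03_29398499": "A/A",
        "Chr15_40410846": "A/G",
        "Chr16_3059544": "C/C",
        "Chr02_10434413": "G/T",
        "Chr03_25532731": "A/C",
        "Chr10_40756571": "T/T",
        "Chr16_38546603": "C/G",
    },
    "Golden Delicious": {
        "MdNAC83_Del216": "del216/del216",
        "MdNAC83_SNP934": "T/T",
        "MdNAC83_SNP388": "A/G",
        "MdBPM2_SNP657": "A/A",
        "MdRGLG3_SNP167": "C/C",
        "Chr03_27276582": "T/T",
        "Chr03_29398499": "G/A",
        "Chr15_40410846": "G/G",
        "Chr16_3059544": "C/T",
        "Chr02_10434413": "T/T",
        "Chr03_25532731": "A/C",
        "Chr10_40756571": "T/A",
        "Chr16_38546603": "G/G",
    },
    "Jonathan": {
        "MdNAC83_Del216": "Del216/Del216",
        "MdNAC83_SNP934": "C/C",
        "MdNAC83_SNP388": "G/G",
        "MdBPM2_SNP657": "A/T",
        "MdRGLG3_SNP167": "G/G",
        "Chr03_27276582": "T/C",
        "Chr03_29398499": "G/G",
        "Chr15_40410846": "A/A",
        "Chr16_3059544": "T/T",
        "Chr02_10434413": "G/G",
        "Chr03_25532731": "C/C",
        "Chr10_40756571": "A/A",
        "Chr16_38546603": "C/C",
    },
}

_CROSSES: list[tuple[str, str, str, int]] = [
    ("ZPxRF", "Zisai Pearl", "Red Fuji", 409),
    ("ZPxGD", "Zisai Pearl", "Golden Delicious", 490),
    ("JxGD", "Jonathan", "Golden Delicious", 292),
]

#: per-trait phenotyped fraction of the training population (study counts
#: 1,382 / 1,370 / 1,182 / 1,187 out of 1,803 individuals)
_TRAIT_PHENOTYPED: dict[str, float] = {
    "FF": 1382 / 1803,
    "FC": 1370 / 1803,
    "FFR": 1182 / 1803,
    "FCR": 1187 / 1803,
}


def study_truth_config(
    trait: str,
    seed: int = 0,
    missing_rate: float = 0.02,
    epistasis_scale: float = 1.0,
) -> TrueEffectConfig:
    """Simulation truth for one trait under the default architecture.

    Effects are the base (a, d) values scaled to the trait's units; the
    three interacting sets carry both their members' effects and an
    epistatic extra (scaled by ``epistasis_scale``).
    """
    if trait not in _TRAIT_PARAMS:
        raise KeyError(f"unknown trait {trait!r} (have {sorted(_TRAIT_PARAMS)})")
    mean, scale, residual_sd = _TRAIT_PARAMS[trait]
    archs = {
        m.marker_id: MarkerArchitecture.additive_dominance(
            m, a=_BASE_AD[m.marker_id][0] * scale, d=_BASE_AD[m.marker_id][1]
        )
        for m in DEFAULT_MARKERS
    }
    sets = []
    for k, (members, epi) in enumerate(zip(DEFAULT_INTERACTING_SETS, _BASE_EPISTASIS)):
        scaled_epi = {c: v * scale * epistasis_scale for c, v in epi.items()}
        sets.append(
            InteractingSetTruth(
                set_id=f"set{k + 1}",
                member_ids=tuple(members),
                combos=build_joint_map([archs[m] for m in members], scaled_epi),
            )
        )
    return TrueEffectConfig(
        population_mean=mean,
        markers=list(archs.values()),
        interacting_sets=sets,
        residual_sd=residual_sd,
        missing_rate=missing_rate,
        seed=seed,
    )


@dataclass
class StudyCohort:
    """Synthetic training population with per-trait truth."""

    genotypes: GenotypeMatrix
    phenotypes: dict[str, PhenotypeTable]
    truth: dict[str, TrueEffectConfig]
    genetic_values: dict[str, pd.Series]
    interacting_sets: list[list[str]]


def simulate_study_cohort(
    seed: int,
    n_accessions: int = 612,
    cross_scale: float = 1.0,
    missing_rate: float = 0.02,
    traits: tuple[str, ...] = ("FF", "FC", "FFR", "FCR"),
    epistasis_scale: float = 1.0,
) -> StudyCohort:
    """Simulate the full training population at study scale.

    612 accessions (Hardy–Weinberg) + 1,191 hybrids from three crosses
    (409 / 490 / 292, scalable by ``cross_scale``); each trait gets
    genetic values from the shared architecture plus trait-specific
    noise, retainabilities floored at 0 months, and the study's
    per-trait phenotyped fractions applied.  Fully reproducible under
    the seed.
    """
    rng = np.random.default_rng(seed)
    freqs = {
        m.marker_id: [p, 1.0 - p]
        for m, p in ((m, _ACCESSION_FREQ[m.marker_id]) for m in DEFAULT_MARKERS)
    }
    parts = [
        simulate_accession_genotypes(
            DEFAULT_MARKERS, freqs, n_accessions, seed=int(rng.integers(2**31)), id_prefix="ACC"
        )
    ]
    pops = ["accession"] * n_accessions
    for name, p1, p2, n in _CROSSES:
        n_off = max(1, int(round(n * cross_scale)))
        parts.append(
            simulate_biparental_genotypes(
                DEFAULT_MARKERS,
                _FOUNDERS[p1],
                _FOUNDERS[p2],
                n_off,
                seed=int(rng.integers(2**31)),
                id_prefix=name,
            )
        )
        pops.extend([name] * n_off)
    calls = pd.concat([p.calls for p in parts])
    gm_full = GenotypeMatrix(
        DEFAULT_MARKERS, calls, populations=pd.Series(pops, index=calls.index)
    )

    truth: dict[str, TrueEffectConfig] = {}
    phenos: dict[str, PhenotypeTable] = {}
    gvs: dict[str, pd.Series] = {}
    for trait in traits:
        cfg = study_truth_config(
            trait, seed=seed, missing_rate=missing_rate, epistasis_scale=epistasis_scale
        )
        gv = genetic_values(cfg, gm_full)
        noise = rng.normal(0.0, cfg.residual_sd, len(gv))
        values = gv + noise
        if TRAIT_UNITS.get(trait) == "months":
            values = values.clip(lower=0.0)  # retainability cannot be negative
        n_pheno = int(round(_TRAIT_PHENOTYPED.get(trait, 1.0) * len(values)))
        keep = rng.choice(values.index.to_numpy(), size=n_pheno, replace=False)
        truth[trait] = cfg
        gvs[trait] = gv
        phenos[trait] = PhenotypeTable(
            trait=trait, values=values.loc[sorted(keep)], unit=TRAIT_UNITS.get(trait, "")
        )
    observed = (
        inject_missing(gm_full, missing_rate, seed=seed + 7) if missing_rate else gm_full
    )
    return StudyCohort(
        genotypes=observed,
        phenotypes=phenos,
        truth=truth,
        genetic_values=gvs,
        interacting_sets=[list(s) for s in DEFAULT_INTERACTING_SETS],
    )
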