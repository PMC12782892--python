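# Methods

## The prediction model

`markergap` implements fixed-panel genomics-assisted prediction: the
phenotype of an individual is predicted as the training-population
grand mean plus the sum of deviation-based genotype effects over a
small panel of QTL-derived markers, optionally replacing the individual
effects of declared interacting marker sets by joint effects of their
multi-marker genotype combinations.

Assumptions worth stating explicitly:

- **Effects are class means, not regression coefficients.** A genotype
  effect is `mean(OPV | class) − grand mean`, estimated independently
  per marker. The per-marker sums are exactly orthogonal only in
  balanced designs; in unbalanced populations the summed GPV double
  counts shared variance between correlated markers. This is inherent
  to the method, not an implementation artifact.
- **The grand mean is pooled** over the entire training population
  (accessions and all crosses). An individual missing a call at one
  marker still contributes to the grand mean, just not to that
  marker's classes.
- **Interacting sets replace, not augment.** In the non-additive model
  a marker belonging to a set contributes only through the set's joint
  effect; the literal both-terms reading would count the marker twice
  and is available behind `include_set_members_additively=True` for
  sensitivity analysis only. Sets may overlap; an overlapping marker
  then influences several joint terms.
- **Prediction degrades gracefully.** A missing call, an unseen class,
  or a low-support class contributes 0 (the expected value of a
  deviation); a set whose observed combination is unusable falls back
  to the sum of its members' individual effects (`fallback_policy=
  "additive_sum"`, default) or to nothing (`"zero"`). Per-individual
  fallback counts are reported by `predict_frame`.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| `min_class_n` | 3 | individuals | a class mean from 1–2 individuals is noise; flagged classes predict 0 |
| `k` (CV folds) | 5 | — | standard for populations of hundreds to thousands |
| firmness threshold | 7.0 | kg/cm² | acceptability bound defining FFR |
| crispness threshold | 0.7 | kg/cm² | acceptability bound defining FCR |
| `fallback_policy` | additive_sum | — | graceful degradation for unseen combinations |
| dominance-ratio class bounds | 0.2 / 0.8 / 1.2 | \|d/a\| | this package's convention for additive / partial dominant / dominant / overdominant; the class names are standard, the numeric bounds are ours |

Dominance ratio: for a biallelic marker with usable effects for both
homozygotes and the heterozygote, `a = (e_hom1 − e_hom2)/2`,
`d = e_het − (e_hom1 + e_hom2)/2`, and the ratio is `d/a`; `a = 0` with
`d ≠ 0` is classified overdominant with an infinite ratio.

The scalar "marker effect" reported by `marker_effect_magnitude` is the
**range** (max − min) over usable genotype-class effects. This is a
package convention for collapsing signed per-class effects to one
number; other definitions (e.g. half-range, absolute homozygote
contrast) exist and none is canonical.

## The synthetic-population generator

The generator is the package's stand-in for the real training data and
defines the conditions under which everything is tested:

- **Structure**: 612 Hardy–Weinberg accessions plus 1,191 F1 hybrids
  from three biparental crosses (409 / 490 / 292), matching the study
  population's composition; per-trait phenotype availability of
  1,382 / 1,370 / 1,182 / 1,187 of the 1,803 individuals for
  FF / FC / FFR / FCR; 2% random missing calls.
- **Panel**: 13 markers — the five validated functional variants
  (MdNAC83 Del216, SNP934, SNP388; MdBPM2 SNP657; MdRGLG3 SNP167) and
  eight QTL-linked markers — each with an additive value `a` and
  dominance degree `d` mapping to effects `{+a, d·a, −a}`; functional
  markers are partial dominant (0.4 ≤ d ≤ 0.55).
- **Interacting sets**: the MdNAC83 promoter/CDS group and the
  MdNAC83×MdBPM2 and MdNAC83×MdRGLG3 pairs, each carrying an epistatic
  extra on top of the members' effects (favorable-homozygote
  combinations boosted, unfavorable depressed).
- **Noise**: i.i.d. homoscedastic Gaussian. Trait means and residual
  SDs (FF 8.2 ± 1.8 kg/cm², FC 0.95 ± 0.18 kg/cm², FFR 5.0 ± 3.2
  months, FCR 4.5 ± 2.8 months) were chosen so the marker-explained
  fraction of phenotypic variance is ≈ 0.35–0.40, consistent with the
  low-to-moderate heritability of storability traits; no quantitative
  heritability was available to calibrate against, so these are free
  parameters fixed once. Retainability phenotypes are floored at 0
  months.

What the generator does **not** emulate — and hence what passing tests
cannot show about real data: linkage and LD between panel markers
(markers segregate independently; the prediction method treats them as
exchangeable predictors), population structure beyond the
accession/cross labels, genotype-by-year and genotype-by-environment
variation (the real phenotypes are multi-year), genotyping error (only
missingness), and selection. CV accuracies on synthetic cohorts are in
the same broad range as published values for these traits but are
properties of the simulated architecture, not reproductions of them.

## Storability phenotyping

Retainability of a monthly storage series is the largest month *t*
such that months 1..*t* all meet the threshold — "maintained" read as
uninterrupted, so a single sub-threshold month ends retention even if
later values recover. Month indexing starts at 1 (first monthly
sampling after harvest); the at-harvest measurement is the FF/FC
phenotype, not part of the series. A series that never fails is
returned as its full length with an explicit right-censoring flag
rather than a sentinel value. Replicates are averaged per month before
thresholding (threshold-per-fruit-then-average is the documented
alternative; averaging first is the default because monthly means are
what texture-analyzer protocols report).

For a noiseless linear-decay series (initial F₀, monthly decay δ),
retainability equals `floor((F₀ − threshold)/δ)` clipped to `[0, T]`;
this closed form cross-checks the phenotyper against the decay
simulator in the tests.

## Numerical choices

- Coordinates are 1-based. QTL interval length defaults to the
  difference convention (`end − start`), which matches the printed kb
  values of the narrowed windows; the inclusive convention
  (`end − start + 1`) is used for deletions whose endpoints are both
  deleted bases (the 216-bp promoter deletion requires it). kb values
  are rounded half-up to one decimal (`decimal`-based, not banker's
  rounding).
- Heterozygotes are canonicalized by allele index, so `A/T` and `T/A`
  in input files are the same genotype; `.` (and `./.` from VCF) is
  the missing call, never an allele.
- Segregation ratios are reduced by the gcd of the class counts;
  all-zero counts are a degenerate-input error.
- Undefined per-fold correlations (zero test-fold variance, < 3
  individuals) are excluded from the CV mean with an explicit count,
  never imputed as 0.
- Effect estimation with fully called markers satisfies the identity
  Σ n_g · effect_g = 0 exactly (weighted deviations from a common
  mean); low-support flagging intentionally breaks it by zeroing small
  classes.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to make the
statistical properties sharp: oracle equivalence on 100 random cohorts
of ≤ 50 individuals; invariant checks on 200 random cohorts; the
superiority experiment on 20 replicates of n = 1,800 with joint-effect
SD twice the residual SD; consistency at n = 200 vs n = 2,000 over 10
replicates; Mendelian/HWE sampling oracles at n = 10,000–20,000. The
full suite runs in well under a minute.

## Known limitations

- No linkage map, LD, or pedigree beyond F1; no GBLUP or whole-genome
  regression baselines (GAP is deliberately a fixed-panel effect-sum
  method).
- Effects are estimated from a single phenotype value per individual;
  per-year estimation and genotype-by-year interaction are out of
  scope.
- No significance testing of effects and no multiple-testing
  machinery; `min_class_n` is the only guard against over-fitting
  small classes.
- Which markers compose the interacting sets is user input; the
  defaults in `markergap.panel` are an interpretation of the validated
  functional relationships, not a deposited list.
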