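# Methods

This note records the scientific and numerical choices behind the package:
the model and its assumptions, the defaults and why they were chosen, what
the synthetic-data generator emulates, and the known limitations.

## Speciation and the charge-density descriptor

Species abundances are closed-form Henderson–Hasselbalch fractions
(monoprotic) or the standard α₀/α₁/α₂ diprotic fractions computed from
[H⁺], K₁ and K₂ in linear space; over pH 0–14 with pKa values in the
environmental range this is numerically safe (no log-space tricks needed)
and the three diprotic terms are normalized by their sum, so abundance
closure holds to machine precision. The charge density is
F·(Σ Aᵢzᵢ)/MW_eff with the Faraday constant fixed at 96 485 C mol⁻¹
(CODATA, rounded). With the trifluoroacetate anion mass of 113.014 g mol⁻¹
(standard atomic weights to three decimals) this gives −853.7 C g⁻¹, the
descriptor's lower bound over the registry.

Species molecular weights are bookkept, not recomputed: each ionization
species stores the most-protonated (formula) mass minus 1.008 g mol⁻¹ per
dissociated proton. This needs no structural chemistry and is validated at
load time against the empirical formula.

**Registry caveats.** Identities, formulas and the ionization schemes of the
common anionic subfamilies are well established. For the cationic and
zwitterionic compounds (betaines, sulfonamide amines, quaternary ammonium
amides) the per-species charge assignments, pKa values, log KOW and
solubility entries rest on structural analogy and are marked
`provisional=True`; curators can override any entry by loading their own
JSON/CSV registry. Nothing in the package estimates properties — the
registry is an input.

## Harmonization rules

* KOC→Kd uses fOC = Corg/100.
* Isotherm→Kd evaluates Cs/Cw at Cw = 10% of the compound's aqueous
  solubility: Freundlich Kd = K_F·(0.1S)^(n−1); Langmuir
  Kd = Q_max·K_L/(1+0.1·K_L·S). The 10%-of-solubility concentration is
  interpreted as an aqueous-phase concentration; for Freundlich data (the
  dominant case) the two conventions coincide.
* When several routes are available for a record: direct > from KOC >
  from isotherm, reflecting the preference for directly reported
  low-concentration Kd.
* Textures must close to 100 ± 2% and are renormalized to exactly 100;
  worse closure rejects the record. pH outside [0, 14], negative CEC, or
  percentages outside [0, 100] also reject.
* Outlier screening replaces case-by-case expert judgment with two
  reproducible, configurable rules: (i) compound level — OLS of
  per-compound mean log KOC on log KOW, flag |residual| > 2× residual RMSE
  (with an absolute RMSE floor of 1e−9 so an exact fit yields no flags);
  (ii) entry level — flag |log KOC − compound median| > 1.5 log units.
  Every flag carries a machine-readable reason; dropping flagged entries is
  a separate, explicit step (the trainer drops them by default).

## KNN soil-property imputation

Missing values among {pH, CEC, Corg, sand, silt, clay} are filled from a
complete reference soil table: min–max scaling by reference bounds,
missing-aware Euclidean distance (squared distance over observed
coordinates rescaled by the fraction observed), uniform mean over the k
nearest rows. Defaults k = 5, uniform weights — the conventional KNN
imputer settings. Distance computation and neighbor averaging are delegated
to scikit-learn's `KNNImputer`, which implements exactly this metric; the
unit tests verify it against an exhaustive brute-force neighbor search.
Imputation is deterministic; coordinates are metadata only, never distance
features. Imputed values are convex combinations of reference values and
therefore stay inside the reference hull; textures are renormalized to
100% after imputation.

## Stacking ensemble

Base learners and defaults (all exposed in `PSSMConfig`, overridable via
YAML):

| learner | defaults | rationale |
|---|---|---|
| ridge | α = 1.0 | standard shrinkage default |
| random forest | 500 trees, unrestricted depth | robust at ~10³ samples |
| extra trees | 500 trees, unrestricted depth | decorrelated variance reduction |
| gradient boosting | 500 estimators, lr 0.05, depth 3 | conservative boosting |
| meta-model (MLP) | 1 hidden layer × 16 ReLU units, ≤ 2000 iterations | smallest network that earns the name |

The meta-model is trained on out-of-fold base predictions (internal 5-fold
CV), then the base learners are refit on the full training split. Training
the meta-model on in-sample base predictions would let it reward whichever
base learner memorizes the training data best; the out-of-fold variant
removes that leakage. The literal in-sample variant remains available
(`stacking: insample`) for comparison. A label-shuffling test verifies
that the stack cannot beat its own honest error on permuted targets.

Only features are min–max scaled (bounds from the training split; test
values outside the bounds extrapolate with a warning). The target log₁₀ Kd
is left unscaled. The holdout split takes floor(n·0.2) test rows by a
seeded permutation. A constant training target short-circuits to a
constant predictor. Everything is bit-for-bit reproducible under a fixed
seed (single-threaded learners, seeded KFold and MLP).

Feature ablation refits on the identical split and seed with the feature
removed from the model's feature list, so metric differences are
attributable to the missing information alone. Note that the compound
descriptors are correlated (effective MW, log KOW and charge density all
track chain length and head group), so ablating one descriptor measures
its marginal, not total, contribution.

## Evaluation metrics

NRMSE normalizes RMSE by the observed range by default; the normalizer is
a config enum {range, mean, sd} so alternative conventions can be checked.
Range normalization is consistent with the printed performance pair of the
reference dataset (NRMSE ≈ 0.07 with RPD ≈ 3.16 over ~5.4 log units of
observed range). RPD uses the sample (n−1) SD. Predicted-vs-observed slope
and intercept come from OLS of predicted on observed; residual skewness is
the adjusted Fisher–Pearson sample coefficient. CV-NRMSE refits the entire
stack per fold (default 10 folds) and averages fold NRMSEs. The identity
RPD·NRMSE = sd(o)/range(o) is exploited as a cross-check in the tests.

## Sensitivity analysis

Shapley values are computed exactly: the coalition value is the
interventional expectation (absent features drawn from a background
sample, predictions averaged), enumerated over all 2⁹ = 512 coalitions of
the nine features, with the exact permutation weights. No sampling
approximation is involved, so local accuracy holds to float precision; the
implementation refuses more than 12 features. The background defaults to a
seed-fixed 100-row subsample of training data in the CLI. The
interventional (marginal) expectation was chosen over the conditional one
because it is the standard, tractable convention for model explanation.
Partial dependence is the plain average-prediction curve over a grid within
the observed feature range.

## Group comparisons (KOC analyses)

Chain-length and functional-group populations of log KOC are compared with
Welch's ANOVA and Games–Howell pairwise tests at α = 0.05 —
heteroscedasticity-robust defaults chosen because sorption-study group
variances differ widely. Homogeneous subsets are rendered as compact
letter displays via maximal cliques of the non-significance graph, which
guarantees that significantly different groups never share a letter. The
test choice is an assumption of this package, configurable by calling the
underlying functions with different pairwise p-values.

## Synthetic-data generator

The generator exists so every stage is testable offline with a known
ground truth. Reference soils emulate the structure of worldwide topsoil
samples: Corg log-normal (median < 2%, skewed low) truncated to
[0.03, 54]%; textures Dirichlet(2.4, 2.4, 1.2) scaled to 100% with clay
resampled above 69%; pH normal around 6.3 − 1.2·log₁₀(Corg) +
0.03·(clay−24), truncated to [2.8, 9.0], giving the pedologically expected
acidic-organic/alkaline-clay pattern and an SD near 1; CEC =
0.5 + 1.7·Corg + 0.12·clay + noise, clipped to [0.1, 140] cmol₊ kg⁻¹ —
CEC's two real-world drivers. These cross-correlations are what make KNN
gap-filling meaningful; a generator with independent marginals would make
soil properties mutually uninformative, which real soils are not.

Sorption entries draw compounds from the bundled registry and follow

    log Kd = 0.2 + 0.45·log KOW + 0.55·log₁₀(Corg) + 8·10⁻⁴·charge density
             − 0.15·pH + compound offset + ε,  ε ~ N(0, 0.3²)

with effect directions and rough magnitudes as reported across the
sorption literature: hydrophobicity and organic carbon dominant and
positive, pH weaker and negative, charge density minor (≈0.8 log units
across its −854…+188 C g⁻¹ span). Soil-property gaps are masked at 15%
per entry for pH, CEC and the texture triple (textures jointly, as they
are reported); Corg is always kept, mirroring its near-universal
availability. Outlier planting adds a stated log-unit offset to chosen
compounds.

**What passing synthetic tests shows — and does not.** They establish that
the pipeline recovers a known monotone rule at realistic noise (holdout
RPD > 2.5 at σ = 0.3, n = 1200), that planted outliers are isolated, and
that sensitivity attributions point in the planted directions. They do not
establish real-data accuracy: the generator's truth is additive and smooth,
its compound effects enter only through registry descriptors, and it has
no study-level heterogeneity, measurement error in soil properties, or
correlated replicates — all present in compiled literature data.

## Problem sizes in the default runs

Unit tests run the ensemble with reduced sizes (100–150 trees); the
acceptance-tier pipeline run uses the full default configuration at
n = 1200 with a 2039-row reference table, matching the scale of the
compiled-literature use case. The exact-Shapley tier uses 50-row
backgrounds and a handful of explained samples, ample for 512-coalition
enumeration.

## Known limitations

* Saturated-zone batch sorption only: no air–water interface partitioning,
  no temperature dependence, no ionic-strength corrections.
* Applicability is bounded by training feature ranges; out-of-range
  predictions are emitted but flagged `out_of_domain`.
* Cationic/zwitterionic registry entries are provisional (see above).
* The Langmuir 10%-of-solubility convention assumes an aqueous-phase
  concentration (see Harmonization).
* Mapping is tabular; rasterization and cartography are out of scope.
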