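# Methods

## Carbonate-system isotope model

### Model

Dissolved inorganic carbon (DIC) is partitioned among CO₂(aq), HCO₃⁻ and
CO₃²⁻ by mass action: with a_H = 10^(−pH),

    x_CO2 : x_HCO3 : x_CO3 = 1 : K1/a_H : K1·K2/a_H²,  normalized to sum 1.

pH is treated as hydrogen-ion activity and the activity coefficients of the
carbonate species are absorbed into apparent constants — no Pitzer or
Davies model. Assuming carbon-isotope equilibrium among the species, the
measured bulk δ¹³C_DIC constrains the bicarbonate value through

    δ_DIC = Σᵢ xᵢ·δᵢ,   δᵢ = αᵢ·(δ_HCO3 + 1000) − 1000,  αᵢ = 1 + εᵢ(T)/1000,

which is solved exactly: δ_HCO3 = (δ_DIC + 1000)/Σᵢ xᵢαᵢ − 1000. All δ
arithmetic uses the exact multiplicative α form rather than the additive ε
approximation; the difference is < 0.05‰ here but exactness costs nothing.
The equilibrium aragonite value applies ε(aragonite−HCO₃⁻)(T) the same way.

### Parameters and provenance

* **Dissociation constants.** Default `freshwater`: the classic
  zero-ionic-strength temperature polynomials for K₁ and K₂ (pK₁ = 6.35,
  pK₂ = 10.33 at 25 °C). Variant `saline`: apparent seawater-scale
  constants (Mehrbach-style refit, default S = 35). The study lake is
  hypersaline (≈86–139 g/L TDS, beyond any parameterization's calibrated
  range) and the original analysis does not state its choice; the
  freshwater default is what reproduces the published equilibrium value.
  Sensitivity: switching to the saline constants lowers apparent pK₁ by
  ≈0.5, shrinks the CO₂(aq) fraction, and lowers the maximum equilibrium
  prediction by ≈0.54‰ (5.37 → 4.83‰). This exceeds the ±0.3‰ spread of
  the documented *fractionation* coefficient sets and is why the constants
  choice is exposed as an explicit switch.
* **Fractionation factors** (`DEFAULT_FRACTIONATION`).
  ε(aragonite−CO₂ gas) = 13.88 − 0.13·T(°C);
  ε(HCO₃⁻−CO₂ gas) = 9483/T(K) − 23.89;
  ε(aragonite−HCO₃⁻) formed as their difference (2.714‰ at 25 °C, the
  2.70 ± 0.05‰ anchor);
  ε(CO₂aq−HCO₃⁻) = −9866/T(K) + 24.12;
  ε(CO₃²⁻−HCO₃⁻) = −867/T(K) + 2.52 (small, < 0.6‰ over 0–50 °C).
  An alternate `LINEAR_FRACTIONATION` set using the textbook linear-in-°C
  approximations is provided for sensitivity analysis; it shifts the
  maximum equilibrium prediction by < 0.05‰.
* **Temperature grid.** Water temperatures at collection are typically
  unpublished, so the "maximum possible" equilibrium prediction scans
  10–40 °C at 0.1 °C (inclusive). Both δ_HCO3 (larger CO₂(aq) fraction,
  stronger CO₂–HCO₃ fractionation) and the aragonite enrichment increase
  toward cold temperatures, so the maximum sits at the low end of the grid.
  A sample with a recorded temperature is evaluated there only.
* **Classification tolerance.** Offsets within ±0.1‰ of zero are called
  "equilibrium"; analytical reproducibility of the underlying measurements
  is ±0.01–0.03‰ (1σ), so 0.1‰ is a conservative margin.
* **Salinity regression.** TDS(g/L) = 0.4665·SC(mS/cm)^1.0878, the log–log
  power-law regression for Australian salt lakes. It reproduces the
  published endpoint estimates (86.3 and 139.1 g/L at 121.4 and
  188.2 mS/cm) to < 0.1 g/L.

### Numerical notes

With the default coefficients and the published inputs (δ¹³C_DIC = 1.55‰,
pH 7.54, 10–40 °C grid) the model gives a maximum equilibrium aragonite
δ¹³C of 5.37‰ against the published 5.49‰. The 0.12‰ gap is within the
coefficient-set tolerance; the published value likely reflects an unstated
temperature/pH pairing (measured field temperatures were used there but
never printed). No constant here was tuned toward 5.49.

## Count-table statistics

* **Depth normalization** is deterministic total-sum scaling to a target
  depth (default 221,168 counts/sample); seeded rarefying (multivariate
  hypergeometric subsampling) is available behind `rarefy_counts` for
  workflows that require integer counts.
* **Rarefaction** uses the closed-form hypergeometric expectation
  E[S_n] = Σᵢ (1 − C(N−Nᵢ, n)/C(N, n)) computed with log-gamma functions,
  not Monte-Carlo.
* **PCoA** Gower-centers −d²/2 and eigendecomposes. Bray–Curtis matrices
  are semimetric, so negative eigenvalues occur: they are retained in the
  result for inspection, axes are built from positive eigenvalues only,
  and variance fractions are relative to the positive-eigenvalue sum. No
  Lingoes/Cailliez correction is applied.
* **UPGMA** merges the pair with the smallest average-linkage distance,
  breaking ties by the lexicographically smallest index pair (determinism);
  node heights are half the merge distance, so cophenetic distances equal
  the linkage distances.
* **PERMANOVA** partitions Σd²/n sums of squares; pseudo-F =
  (SS_between/(a−1))/(SS_within/(N−a)), R² = SS_between/SS_total, and
  p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm) under seeded label permutation
  (default n_perm = 999, matching a floor p of 0.001). `exact=True`
  enumerates all distinct label assignments for small designs. Note the
  granularity at tiny n: a 3+3 design has only 10 distinct partitions, so
  the smallest attainable exact p is 0.1.

## Differential abundance

A transparent reimplementation of the negative-binomial Wald framework:

* **Size factors**: median-of-ratios over features positive in all
  samples, rescaled to unit geometric mean. An all-sparse table (no such
  feature) raises rather than silently switching reference.
* **Dispersions**: per-feature method of moments on size-factor-normalized
  counts, pooling within-group variances:
  α = max((pooled_var − mean)/mean², 10⁻⁸).
* **Wald test**: group means fit by NB maximum likelihood at fixed α
  (Newton on log μ, expected information m/(1+αm)); log2FC =
  log₂(μ_focal/μ_other) with a 0.5 pseudo-count applied to a group mean
  only when that group is all-zero; SE from the inverse information of the
  two group means mapped to the log₂ scale; p from the two-sided normal
  tail. Features zero in both groups get log2FC = 0, p = 1.
* **Multiplicity**: Benjamini–Hochberg step-up (via statsmodels).
* **Enrichment filters**: padj < 0.05 AND |log2FC| > 1 AND baseMean > 2000,
  strict inequalities for the magnitude thresholds.

Omitted relative to the full framework: empirical-Bayes dispersion
shrinkage, log-fold-change shrinkage, independent filtering, and outlier
(Cook's distance) handling. Consequence: per-feature dispersion estimates
at n = 3 vs 3 are noisy, and individual small-count features can be
anti-conservative; the stringent magnitude/abundance filters absorb most
of this in practice (null calibration at known dispersion is within
Monte-Carlo error of nominal, see the test suite).

## Synthetic data

`simulate_count_table` draws log-normal feature means (μ = 6, σ = 2 on the
log scale — spanning the baseMean > 2000 filter regime), splits a true
log2FC symmetrically across the two groups (each mean scaled by
2^(±log2FC/2)), applies per-sample depth multipliers uniform in [0.5, 2],
and draws NB counts (Poisson at α = 0). `simulate_isotope_study` draws
lake (δ¹³C_DIC ∈ [−4.30, 1.55]‰) and groundwater ([−13.35, −7.97]‰)
samples with pH in [7.18, 7.63], computes the equilibrium prediction with
the geochemistry module, and adds a configurable true offset (+4‰ default)
plus Gaussian noise (0.3‰) to 18 carbonate samples in 5 cm depth intervals
over two cores. Defaults mirror the 3+3 study design.

What the generators do **not** emulate: taxonomic correlation structure,
compositional closure of real annotated counts, annotation bias between
groups, spatial autocorrelation of cores, or pH/temperature covariance in
water chemistry. A green closure test therefore establishes that the
pipeline recovers injected effects under an idealized NB/Gaussian world,
not that the published biological findings are reproduced.

## Known limitations

* The isotope model is a single-sample equilibrium bound, not a reactive
  transport or Rayleigh model; it cannot apportion the offset among
  photoautotrophy, CO₂ degassing, or evaporative effects.
* Apparent-constant parameterizations are extrapolated when applied at
  hypersaline ionic strengths.
* The Wald stage supports exactly two groups with ≥2 samples each; no GLM
  designs, no continuous covariates.
* PERMANOVA is one-factor, sequential sums of squares.
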