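# Methods

This note documents the models implemented in `dustbiome`, their
assumptions, the tunable parameters that matter, and what the synthetic
generators do and do not emulate.

## Effective-variance CMB receptor model (`dustbiome.cmb`)

**Model.** For each sample, measured element concentrations (ng/m³) are a
non-negative linear mixture of source profiles: C_i = Σ_j F_ij S_j + e_i,
where F_ij is the element mass fraction of source j and S_j its ambient
contribution (µg/m³; a factor of 1000 links the units internally).
Both C and F carry measurement error, so weights use the *effective
variance* V_i = σ²_Ci + Σ_j S_j² σ²_Fij, which depends on the solution.
The solver iterates: weighted least squares with the current V, recompute
V from the new S, repeat.

**Numerical choices.**

- Initialization: S = 0, i.e. the first pass weights by σ²_Ci alone.
- Convergence: max |ΔS| / max |S| < 1e-4 (default), 50 iterations max;
  non-convergence raises an error that carries the last iterate. The
  change is scaled by the overall solution magnitude so that sources with
  near-zero contributions cannot stall convergence on meaningless
  relative wiggle.
- Uncertainties: square roots of the diagonal of (Fᵀ W F)⁻¹ at the
  converged weights.
- Diagnostics: r² is the weighted *uncentered* explained variance
  1 − Σw r²/Σw C² (the model has no intercept); χ² is the weighted
  residual sum of squares over (n_elements − n_sources) degrees of
  freedom. These follow common receptor-modeling conventions.
- Conditioning: the column-normalized profile matrix must have condition
  number below 1e8 or fitting refuses and names the most collinear source
  pair.
- Negative contributions are physically meaningless but statistically
  possible; they are reported with a warning by default, and
  `drop_negative=True` refits without the offending sources (standard
  practice).
- Elements missing (NaN) in a sample are dropped from that sample's fit;
  the default fit-element list excludes elements missing in more than
  half the samples.

**Mineral mass reconstruction.** RMMM = 1.89·Al + 2.14·Si + 1.40·Ca +
1.43·Fe + 1.67·Ti (concentrations → common crustal oxides). Agreement
between RMMM and the summed mineral-source contributions validates the
apportionment; for a pure mineral-dust sample the two agree to within the
profile's oxide closure (≈ 0.95–1.0).

**Dust-day classification.** Apportioned dust < 10 µg/m³ is "low",
> 30 µg/m³ "peak", otherwise "medium". The thresholds reproduce the
campaign's printed labels and are configurable.

## Ternary mixing analysis (`dustbiome.ternary`)

Element triples (default La–Ni–V) are multiplied by per-element factors
chosen so the upper-continental-crust reference plots at the centroid:
factor_e = ref[anchor]/ref[e], anchor V at 1. With the packaged UCC table
(Rudnick & Gao 2003 compilation: V 97, Ni 47, La 31 µg/g) the factors are
1, 2.06, 3.13. After this common linear scaling, closure to sum 1 maps
binary mass mixtures onto straight segments, so position along the
Ni-apex→centroid line reads off the crustal (dust) fraction. Geometry
(projection fraction and perpendicular deviation) is computed in the
standard equilateral-triangle embedding; projection fractions outside
[0, 1] are reported unclamped and flagged. Whether raw or per-sample
normalized concentrations enter makes no difference: closure removes any
per-sample scale.

## Diversity and screens (`dustbiome.diversity`)

- **Chao1**: S_obs + F1²/(2F2) when doubletons exist; bias-corrected
  S_obs + F1(F1−1)/2 when F2 = 0. Implemented directly because the two
  branch conventions matter; cross-checked against scikit-bio in tests.
- **Shannon**: −Σ p ln p in nats. Natural log is consistent with the
  magnitude of published airborne-community values (ln of a few hundred
  OTUs ≈ 6–7).
- **Bray–Curtis**: Σ|x−y|/Σ(x+y) on raw counts by default (proportions
  optional). Pairs of all-zero samples are undefined and flagged.
- **PCoA**: Gower-centered −½D² eigen-decomposition; coordinates scaled
  by √eigenvalue; percent explained uses the sum of *positive* eigenvalues
  as denominator, with negative eigenvalues reported but excluded. This
  differs from some implementations that divide by the full trace;
  scikit-bio's PCoA serves as the independent cross-check in tests.
- **Correlation screen**: Pearson r between per-OTU relative abundance and
  each covariate, two-sided t test with n−2 df, uncorrected p < 0.05 by
  default (Benjamini–Hochberg optional). With a 9-day campaign the test
  has 7 df — a real limitation, documented rather than hidden. Constant
  OTUs or covariates are skipped with a warning. Per OTU, the largest-|r|
  significant hit within a covariate class is flagged "strongest".
- **No rarefaction by default**; diversity operates on raw counts, an
  explicit design choice since depth normalization before diversity is
  contested and the screens use relative abundances anyway.

## Pagel's λ (`dustbiome.phylosig`)

**Model.** Tip traits are multivariate normal, mean μ·1, covariance
σ²·C(λ), where C is the Brownian tip covariance (MRCA depths) and C(λ)
multiplies off-diagonals by λ. μ and σ² are profiled by GLS, leaving a
1-D likelihood in λ.

**Numerical choices.**

- λ search: 21-point grid pre-scan (avoids local optima) followed by
  bounded Brent refinement to 1e-6. Bounds are [0, 1] for ultrametric
  trees; for non-ultrametric trees the upper bound is the largest λ
  keeping C(λ) positive definite, found by bisection.
- Star phylogenies (or any flat likelihood) are detected and reported as
  non-identifiable (λ̂ = NaN, warning) instead of returning an arbitrary
  optimum.
- **Monte-Carlo test**: trait values are permuted across tips (999 by
  default); the statistic is the likelihood-ratio improvement of the
  grid-maximized λ over λ = 0, computed identically for observed and
  permuted traits (grid maximization keeps the statistic exchangeable and
  lets all permutations share each λ's Cholesky factor, which makes the
  test fast). p = (1 + exceedances)/(n_sims + 1). A χ²₁ likelihood-ratio
  test is available as `method="lr"`. Under λ = 0 on an ultrametric tree
  tips are exchangeable, so the permutation test is exact.
- Abundance traits default to log(x + c) with pseudo-count c = half the
  smallest nonzero proportion.

## Generalized dissimilarity modeling (`dustbiome.gdm`)

**Model.** Pairwise dissimilarities d_ij ∈ [0, 1) regress on
η_ij = β₀ + Σ_km β_km |I_m(x_ik) − I_m(x_jk)| through μ = 1 − exp(−η),
with all β ≥ 0. Each predictor gets three quadratic I-splines with knots
at its 0/50/100th percentiles (I-splines are reversed cumulative sums of
degree-2 B-splines on the clamped knot vector); because every I-spline is
monotone and coefficients non-negative, each fitted transform f_k is
monotone non-decreasing with maximum height Σ_m β_km.

**Numerical choices.**

- Fitting: iteratively reweighted non-negative least squares on the
  binomial-type deviance (working response and weights from the
  exponential link), tolerance 1e-8, 100 iterations max.
- Observed dissimilarities of exactly 1 are shrunk to 1 − 1e-6 before
  link inversion (the deviance itself uses the observed values).
- Null model: intercept-only, fitted by 1-D deviance minimization;
  deviance explained = 100(1 − D_res/D_null). An all-equal response makes
  this undefined and is rejected.
- Importance: permute one predictor's site values across sites, rebuild
  its pair-table columns (knots are quantiles of the unchanged value
  multiset, so the basis is reused), refit, average the drop in percent
  deviance explained over n_perm (default 100) refits, floor at 0.
- Quantile knots make the fit exactly invariant to positive affine
  rescaling of any predictor. Under general nonlinear monotone
  transforms the three-knot basis can shift slightly (the spline space
  itself is not rank-based); tests pin the affine property.
- pGDM vs cGDM is purely a labeling of which covariate table enters
  (apportioned source contributions vs element concentrations). With few
  sites and many elements a cGDM is heavily overparameterized; predictor
  subsets are always explicit, never guessed.

## Synthetic data (`dustbiome.simulate`)

The generators state a world with known truth; every generator is
deterministic given (parameters, seed) and emits a `SynthTruth` sidecar.

- **Profiles**: seven urban-plus-dust sources with literature-like
  signatures (Saharan dust with ≈1.0 oxide closure on Al/Si/Ca/Fe/Ti;
  V/Ni-rich oil combustion; Ca-rich concrete; Na-rich sea salt; etc.),
  trace elements randomized, redrawn until the column-normalized
  condition number is < 100.
- **Panels**: C = F·S with multiplicative lognormal noise at the stated
  CV (mean-one parameterization); reported uncertainties are
  max(CV, 0.05)·C — the floor keeps uncertainties positive when
  simulating noise-free data, which does not affect recovery since
  equal-relative weights leave the exact solution unchanged. PM₁₀ adds a
  default 18% secondary (unapportionable) mass.
- **OTU tables**: log-normal baseline abundances; linked OTUs' expected
  proportions scale by (1 + effect·z) with z the standardized covariate
  (floored at 0.05); multinomial counts at the stated depth. Default
  depths mirror sequencing campaigns (3×10⁴–10⁵ reads).
- **Trees/traits**: dendropy pure-birth trees observed a random waiting
  time after the n-th speciation (keeps them ultrametric and the tip
  covariance nonsingular); traits drawn from N(0, rate·C(λ)).
- **Turnover communities**: Markov species replacement along the sorted
  gradient — survival probability exp(−rate·Δg) between sites — gives
  expected shared-mass fraction exp(−rate·d) and hence expected
  Bray–Curtis ≈ 1 − exp(−rate·d). Finite depth and abundance jitter add
  a dissimilarity floor at zero distance; `estimate_decay_rate` therefore
  fits 1 − (1−b)exp(−rate·d) with a nugget b so the decay parameter is
  estimated without that bias.

**What a green test establishes.** The generators emulate the *structure*
of real campaign data (mixture linearity, noise scales, link shapes,
phylogenetic covariance), not its content: no taxonomic realism beyond
lineage formatting, no sequence-level effects (chimeras, copy-number), no
compositional closure effects between elements and sources, and no
spatial/meteorological structure. Parameter-recovery results therefore
validate the estimators, not any claim about a particular real dataset;
published dataset-dependent values (OTU inventories, diversity means,
deviance percentages) are out of reach without the raw data and are
covered only qualitatively by the `houston9` demo scenario.

## Known limitations

- The CMB assumes profile uncertainties are uncorrelated across elements
  and sources; correlated profile error would need a full covariance.
- The permutation λ test loses exactness on non-ultrametric trees (tips
  are then not exchangeable under the null); the LR test is the fallback.
- GDM importance inherits collinearity dilution: predictors sharing
  signal split their importance.
- With 9 samples the correlation screen's power and calibration rest on
  7-df t tests; treat single-OTU hits as screening, not inference.
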