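# Methods

`syndromekit` quantifies how much four functional traits — body mass (g),
metabolic rate (mg O₂ hr⁻¹), ammonium excretion rate (µg NH₄⁺ L⁻¹ hr⁻¹) and
boldness (seconds outside a shelter, 0–900) — and their pairwise covariations
("functional syndromes") differ among wild populations, and whether that
differentiation exceeds what genetic drift alone would produce. This note
documents the models, the numerical choices, and what the synthetic data do
and do not establish.

## Trait preprocessing

Mass, metabolic rate and excretion rate are natural-log transformed; boldness
is square-root transformed (it is a bounded, right-skewed duration). Rows
with nonpositive values of a log trait are excluded for that trait and
counted. One-way fixed-effects ANOVA on the transformed values tests
among-population differences per trait; populations without data for a trait
are dropped for that trait only.

## Per-population syndromes and their homogeneity

Traits are z-scored within each population (mean 0, SD 1, denominator n−1).
A saturated path model over four variables has zero degrees of freedom and
reproduces the sample covariance matrix exactly, so each population's
syndrome is summarised directly by its ML covariance matrix of the
standardized traits, rescaled to unit diagonal (the correlation matrix).
Each off-diagonal entry gets a normal-theory test, z = atanh(r)·√(n−3), the
standard equivalent of the SEM z-test for a saturated correlation model.
Listwise deletion within population is the default; pairwise is available
because real data sets often have trait-specific missingness.

Homogeneity of the G matrices is tested by fitting the constrained model
Σ_g ≡ Σ by multivariate-normal ML. The pooled estimate is the n_g-weighted
average, and

    chi² = Σ_g n_g [ ln|Σ̂| − ln|S_g| + tr(S_g Σ̂⁻¹) − p ],
    df = (G−1)·p(p+1)/2.

RMSEA uses the multi-group correction √G·√(max(chi²−df,0)/(df·N)) with N the
total observation count; CFI uses a per-group diagonal (independence)
baseline; SRMR is the root-mean-square difference between each group's
correlation matrix and the pooled one, averaged over groups. The verdict
"heterogeneous" fires when RMSEA > 0.06, SRMR > 0.09, or CFI < 0.96.
Conventions for RMSEA/CFI differ across software by O(1) factors, so raw
chi², df and the baseline statistics are always reported alongside.

**SRMR caveat.** SRMR compares raw matrices and therefore inherits the
sampling noise of each S_g: with n ≈ 30 per population its expected value
under a perfectly shared covariance is about 0.10–0.13 (correlation
residuals scale as 1/√n). At that sample size SRMR cannot distinguish noise
from real heterogeneity, and the OR-combined verdict is effectively driven
by it; chi², RMSEA and CFI, which account for sampling variability, are the
calibrated indices. The false-positive calibration test of the verdict
therefore uses n = 300 per population.

## Heterogeneity of pairwise covariations

Each population contributes one effect per trait pair: the covariance of the
standardized traits (a correlation-scale quantity) transformed to Fisher z =
0.5·ln((1+r)/(1−r)) with sampling SE 1/√(n−3). Cochran's Q with
fixed-effects weights 1/se² tests heterogeneity against chi-square(k−1). The
between-population variance τ² is estimated by REML (bounded 1-D
maximisation of the restricted likelihood on τ² ∈ [0, 10], tolerance 1e-10),
and the percentage of heterogeneity is reported as

    I² = 100·τ²/(τ² + s̃²),   s̃² = (k−1)Σw / ((Σw)² − Σw²),

the τ²-based form standard in REML meta-analysis toolchains; the raw
max(Q−df, 0)/Q form is reported alongside, since the two differ and
published values are usually the former.

## Phylogeny and environment

Nei's standard genetic distance is computed from microsatellite allele
frequencies as D = −ln(Jxy/√(Jx·Jy)), averaging the raw identities over loci
before the single log. Complete-linkage clustering of the distance matrix
(ties broken by lexicographically smallest cluster label, a cluster labelled
by its smallest member) yields an ultrametric dendrogram; a merge at
cophenetic height h places the node at depth h/2, so tree distance equals
cophenetic distance. The Brownian covariance C has C[i,j] = shared
root-to-MRCA path length, with the dendrogram root as the root.

PGLS with Pagel's λ multiplies the off-diagonal of C by λ ∈ [0, 1], leaving
the diagonal untouched; λ = 0 is OLS, λ = 1 the full Brownian expectation.
λ is estimated by profile ML (bounded scalar optimisation plus explicit
endpoint checks); its p-value is a likelihood-ratio test against λ = 0 on
chi-square(1) (a halved boundary p is available by flag). AIC counts the
fixed coefficients plus σ² and λ. For each response (4 trait means, 6
per-population Fisher-z covariations) five candidate models are ranked:
null, temperature, predation, temperature+predation, temperature×predation
(with main effects); the best set is ΔAIC < 4. Fisher-z responses enter
unweighted.

λ estimation on 13 tips is intrinsically noisy, and the information content
depends strongly on tree shape: on near-star trees (which weakly
differentiated populations, e.g. F_ST ≈ 0.05, tend to produce) the
[0,1]-truncated MLE of λ under a Brownian truth has a mean near 0.5, while
on deeply structured trees (the balanced 13-tip tree used in the recovery
test, cherry depth 0.85 of total depth 1) the mean is ≈ 0.88. The
implementation was verified to match `phytools::phylosig` exactly on shared
data wherever the R optimum falls inside [0, 1].

## F_ST and P_ST

Global F_ST is the Weir–Cockerham variance-component estimator θ: per locus
and allele, among-population (a) and within-population (b, c) components are
formed from allele frequencies and observed heterozygote frequencies, and θ
is the ratio of sums over all loci and alleles. Negative estimates are
reported as computed. The 95% CI comes from a cluster bootstrap: the
populations themselves are resampled with replacement (duplicates relabelled
as distinct clusters), 1,000 iterations, percentile bounds.

P_ST for a trait is σ²_B/(σ²_B + σ²_W) from the random-intercept model
y_ij = µ + b_j + ε_ij fitted by REML; the restricted likelihood is profiled
to the single ratio γ = σ²_B/σ²_W (log-scale grid plus bounded refinement,
closed-form inner GLS). No heritability scaling is applied: P_ST measures
total phenotypic differentiation, mixing genetic and developmental
components by design.

P_ST for a covariation adds a random slope: y_ij = β0 + β1·x_ij + u0_j +
u1_j·x_ij + ε_ij with correlated (u0, u1) ~ N(0, Ψ). σ²_B := Var(u1) (the
among-population variance of the slope) and σ²_W := σ²_ε, the residual
variance — the within-population analogue of a slope is not unique, and
residual variance is the transparent default. Traits enter globally
standardized (grand mean 0, SD 1) so slopes are on a correlation scale;
within-population standardization would remove the among-population signal
the trait P_ST needs. REML maximises over the Cholesky factor of Ψ/σ²_ε
(Nelder-Mead from two fixed starts; bootstrap refits warm-start at the
full-data optimum), with per-group 2×2 Woodbury algebra so a fit costs
milliseconds. The fit was verified against `statsmodels` MixedLM to four
decimals; near-zero slope variance is flagged as a boundary fit.

The P_ST cluster bootstrap mirrors the F_ST one (same resampling unit, the
population), and the drift verdict compares closed intervals: `exceeds_drift`
iff the P_ST CI lies entirely above the F_ST CI; touching endpoints count as
overlap. A full run produces exactly 10 P_ST values (4 traits, 6
covariations) plus the global F_ST.

## Synthetic data

The generator emulates the study design, not any particular river system:

* **Genotypes** — Balding–Nichols: ancestral frequencies per locus ~
  Dirichlet(1,…,1) over 8 alleles; population frequencies ~
  Dirichlet(p·(1−F)/F) at the target F (default 0.05); HWE within
  populations; 13 populations (A..M) × 30 individuals × 17 loci. F = 0 means
  exactly shared frequencies. This targets F_ST directly — the only genetic
  quantity the pipeline consumes — at the cost of any demographic realism
  (no bottlenecks, migration, or mutation model).
* **Environment** — temperature ~ U(15.5, 21.5) °C (the study's observed
  range), predation ~ U(0, 0.1) predators/m², optionally rank-correlated via
  a Gaussian copula to emulate the temperature–predation collinearity real
  rivers show.
* **Traits** — latent Gaussian scale = the transformed scale. Defaults:
  means (1.0, −0.5, 3.0) on the ln scale for mass/metabolism/excretion and
  15 √s for boldness, within-population SDs (0.35, 0.35, 0.45, 4.0) —
  magnitudes of an adult European minnow. Population means add
  tree-correlated Brownian deviations (scale in within-SD units at unit tree
  depth) and optional environmental effects (per-trait coefficients on
  standardized temperature/predation). Within-population correlation is a
  fixed base matrix (positive mass–metabolism and mass–excretion allometry,
  weak boldness links), mixed with population-specific random correlation
  matrices by the heterogeneity knob δ. Observation scale: exp() for the
  three rates, clamped square for boldness, so the pipeline's transforms
  recover the latent scale exactly except at the boldness bounds.
* **Scenarios** — `drift_only` sets the Brownian scale to √(F/(1−F)) so the
  expected trait P_ST equals the genetic target F (the defining neutral
  calibration); `selection` adds a −1.5 SD/SD temperature effect on body
  mass; `heterogeneous_cov` sets δ = 0.8.

Passing tests on these data show the estimators recover the quantities the
models define, under exactly the distributional assumptions the models make
(Gaussian latent traits, HWE, no missing data, no measurement error beyond
the observation transform). They do not show robustness to assay error,
trait-specific missingness patterns, null alleles, or non-Gaussian trait
distributions — on real data those must be screened with the QC tools
(validation errors, HWE screen, discard lists) the package provides.

## Problem sizes in the test suite

Simulation-based checks are sized to run in minutes: Q type-I error uses
2,000 replicates (k = 13, n = 28); parameter-recovery checks use 100–200
replicates at study dimensions; the drift-null and selection calibrations
use 24 seeded datasets with 200-iteration bootstraps. Production defaults
(1,000 bootstrap iterations) are used everywhere outside those loops,
including `scripts/acceptance.py` and the analysis drivers.

## Known limitations

* The HWE screen is a Monte-Carlo conditional exact test; it does not
  implement homozygote-excess null-allele inference — known-bad loci are
  supplied via the manual discard list.
* Gametic-disequilibrium tests are not implemented; their only downstream
  consequence (locus removal) goes through the same discard list.
* RMSEA/CFI conventions in multi-group models vary across software; values
  are comparable within this package, and raw chi²/df are reported for
  recomputation under any convention.
* AIC counts λ as a free parameter; toolchains that condition on λ̂ will
  differ by a constant 2 per model, which cancels in ΔAIC within this
  package but not across packages.
* With 13 populations, P_ST bootstrap CIs and λ estimates are wide; single
  verdicts should be read together with the CI widths the reports include.
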