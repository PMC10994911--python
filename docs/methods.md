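# Methods

## The susceptibility network model

Quantitative susceptibility mapping (QSM) assigns every brain voxel a
magnetic susceptibility value, a proxy for local iron content.  `suscnet`
treats each atlas region's in-mask voxel values as a sample from a
regional susceptibility distribution and defines the connectivity of two
regions as the similarity of those distributions:

1. each region's probability density function (PDF) is estimated by
   Gaussian-kernel KDE;
2. the symmetric Kullback–Leibler divergence between two regional PDFs
   *I* and *J* is

   D_KL(I, J) = ∫ I(x) log(I(x)/J(x)) + J(x) log(J(x)/I(x)) dx ;

3. the edge weight is KLSE(I, J) = exp(−D_KL(I, J)) ∈ (0, 1], with 1
   exactly for identical distributions.

This is an individual-level (single-subject) network: no cross-subject
covariance is involved.  The weighted N×N matrix (N = 90 for AAL-style,
246 for BNA-style parcellations, any N ≥ 2 accepted) is thresholded into
binary networks across sparsities 0.05–0.40 in steps of 0.01 (36
networks), where sparsity S keeps the round(S·N(N−1)/2) strongest edges.

Because an edge is a deterministic functional of its two *marginal*
region distributions, group effects can only enter through regions: any
manipulation of a region's distribution moves **all** of that region's
edges.  Several design choices below follow from this.

## Numerical choices

**Bandwidth.** The KDE bandwidth uses the Botev diffusion (improved
Sheather–Jones) fixed point, computed from a 4096-bin DCT of the data
histogram, with the number of *unique* values as the effective n (so the
rule is invariant to duplicating every sample).  For n < 20 or when the
fixed point fails to bracket a root, Silverman's robust rule
0.9·min(SD, IQR/1.349)·n^(−1/5) is used and flagged; Silverman is
count-sensitive.

**Grids and quadrature.** Each PDF lives on a 512-point regular grid
spanning its data range padded by max(10% of the range, 4 bandwidths);
the bandwidth term guarantees the pre-floor density integrates to 1
within 10⁻³ (a 10%-of-range pad alone truncates kernel tails for
moderate samples).  For a divergence, both PDFs are re-evaluated on one
512-point grid spanning the union of the two padded ranges — this keeps
D_KL invariant to a common shift of both samples.  Integrals use the
trapezoid rule; doubling the grid changes D_KL by < 0.5% on smooth
densities.

**Density floor.** Densities are floored at ε = 10⁻¹⁰ and renormalized
before the log ratio, so disjoint supports give a large but finite
divergence (a warning is emitted when two PDFs share < 10⁻⁶ probability
mass).  Zero-spread regions either abort (default) or, under the
`delta` policy, are approximated by a Gaussian of bandwidth 10⁻³ × the
subject's value scale.

**Thresholding.** Edge counts round half-up; ties in weight break by
lexicographic (i, j) order, which makes the binary networks nested
across sparsities and runs reproducible (ties do occur — identical
regions give KLSE exactly 1).

## Graph analysis conventions

* Cp: mean local clustering over all nodes, degree < 2 contributing 0.
* Lp: mean shortest-path length over *connected* pairs only (binary
  networks at sparsity 0.05 are usually fragmented); efficiency metrics,
  which handle disconnection by definition, are reported alongside.
* E_glob: mean of 1/d over all pairs (0 for disconnected pairs); E_loc:
  mean over nodes of E_glob of the neighbourhood subgraph.
* Betweenness: unnormalized pair counts, endpoints excluded.
* Weighted networks: path lengths 1/w, Onnela geometric-mean triangle
  clustering with weights scaled by the maximum weight.
* γ = Cp/⟨Cp_rand⟩ and λ = Lp/⟨Lp_rand⟩ average over 100 (configurable)
  Maslov–Sneppen degree-preserving rewired surrogates with 10×E
  attempted swaps each; σ = γ/λ, small-world if σ > 1.  Rich-club
  normalization uses 1000 surrogates; for the weighted coefficient the
  observed weight multiset is reshuffled onto the rewired topology.
* Hubs: top round(0.12·N) nodes by reference degree (ties by strength,
  then index), by default the degrees of a reference-group mean network
  at sparsity 0.20 (the mid-range sparsity; the hub-defining sparsity is
  a config parameter).  Edges partition into rich-club / feeder / local.
* AUC of a metric-versus-sparsity curve: trapezoid over the grid.

## Statistics

Group comparisons fit value ~ group + age + gender + education by OLS
(t for 2 groups, partial F for ≥ 3).  Edgewise inference uses
Freedman–Lane permutations (5000 by default): nuisance covariates are
regressed out, residuals permuted, the full-model statistic recomputed;
p = (1 + #{perm ≥ obs})/(1 + n_perm).  Default edge threshold is
p < 0.001 uncorrected and p < 0.05 for nodal metrics; FDR/Bonferroni are
available but off by default.  Mediation uses the three-regression
decomposition with bias-corrected (BC, no acceleration) percentile
bootstrap intervals, 5000 resamples; with identical covariate sets
a·b + c′ = c exactly.  Test–retest reliability reports the Pearson
correlation of session-mean matrix upper triangles and the per-connection
two-way mixed, single-measures, consistency ICC
(MS_B − MS_E)/(MS_B + (k−1)·MS_E), summarized as mean ± SD.

The classifier minimizes (1/n)Σ log(1+exp(−yᵢ(Wᵀxᵢ+b))) + λ‖W‖₁ with
λ = 0.01 and an unpenalized intercept, solved by FISTA with adaptive
restart (soft-thresholding yields exact zeros; "selected" means
|W_j| > 10⁻⁸).  Features are the upper-triangle KLSE values, which share
the (0, 1] scale, so no standardization is applied by default.
Evaluation is leave-one-out: decision threshold 0, ROC-AUC from pooled
left-out scores, per-feature selection frequency across folds.  The
positive class is the patient group.

## What the synthetic cohorts emulate — and what they do not

The generator reproduces the statistical structure the method consumes:
per-region voxel-value samples whose means follow a community model
(8 functional-network communities, centers SD 1.0, within-community
scatter SD 0.3, in units of the voxel SD), per-subject mean jitter
(SD 0.1), anatomically fixed voxel counts per region (uniform 50–500 by
default, stressing the KDE across sample sizes), Gaussian or
skew-normal voxel noise, demographics (age ~ N(68, 8²) years, gender
Bernoulli(0.5), education ~ N(12, 3²) years) with optional group shifts
and age confounding, and paired retest sessions whose region means are
perturbed by a chosen SD.  Community structure makes same-community
regions distributionally similar, which is what gives the synthetic
networks clustering above degree-matched surrogates (σ > 1) and, with a
tightly clustered hub community, rich-club organization.

It does **not** emulate voxel spatial autocorrelation, lesion geometry,
scanner artifacts, or non-stationary within-region distributions; passing
tests show the pipeline's statistical machinery is correct under its own
model, not that real QSM data satisfy that model.

**Planted effects and collateral.** A "2-SD mean-shift on edge (i, j)"
moves the two endpoint means apart by one voxel-SD each, in opposite
directions, in the affected group only.  Endpoints are chosen disjoint
across planted edges and within one community (a between-community pair
is already dissimilar, so an extra shift barely changes its KLSE).
Every other edge of a shifted region inevitably carries half the
displacement; the ground-truth record therefore lists both the planted
pairs and all `shifted_regions`, and recovery analyses score collateral
edges as genuine (they are causally affected), while fully unaffected
edges must behave as null.

## Problem sizes used by tests and the acceptance script

The test suite runs scaled versions (3 subjects × 5 sparsities × 20
surrogates for small-worldness; 100 rich-club surrogates; 1000
permutations; 50 recovery cohorts of 40 subjects × 20 regions on a
256-point KDE grid).  `scripts/acceptance.py` runs the full-size
analyses: 20 subjects × 36 sparsities × 100 surrogates for the
small-world minimum, and 1000 rich-club rewirings.  These sizes are the
package's standard desk-scale configuration; every stochastic step is
seeded and reproducible.

## Known limitations

* KLSE compares marginal distributions only; two regions with identical
  histograms but different spatial patterns are indistinguishable.
* Edge-localized group effects cannot exist under the model (see
  collateral discussion); interpretation of edgewise tests should be in
  terms of region-pair distributional divergence.
* The BC bootstrap interval for an indirect effect is mildly
  anti-conservative at small n (measured ≈ 92–93% coverage at n = 50 for
  a nominal 95%), a known property of the interval type.
* The ISJ bandwidth assumes a reasonably smooth underlying density;
  heavy ties push it to the Silverman fallback, which over-smooths
  multimodal data.
* Weighted rich-club surrogates reshuffle the weight multiset on the
  rewired topology; weight-degree correlations are not preserved.
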