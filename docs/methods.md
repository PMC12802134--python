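# Methods

`mmrules` predicts a binary host label (case / control) from paired
microbial relative-abundance and metabolite-level tables, using an
intrinsically interpretable rule network, and ships the matching
semi-synthetic benchmark generator.  This note documents the model, its
priors and inference, the generator, and the design decisions taken
where the design was genuinely open.

## The rule network

Inputs per subject s: taxa relative abundances X^T_si and standardized
log metabolite levels X^M_si.  Prior biological structure enters through
Euclidean embeddings of the features: taxa are embedded from patristic
(tree) distances, metabolites from chemical fingerprint distances, both
by classical PCoA (see below).

The network has four layers:

1. **Feature aggregation.**  Each detector owns a center γ and radius κ
   in its modality's embedding.  Feature i is softly included with
   weight u_i = σ((κ − ε_i)/τ_u), ε_i the Euclidean distance from the
   center.  Metabolite detectors output the u-weighted *mean* of
   standardized levels; taxa detectors the u-weighted *sum* of relative
   abundances.
2. **Detector activation.**  g = σ((a − η)/τ_g): a soft test of whether
   the aggregate a exceeds the learned threshold η.
3. **Detector selection and soft AND.**  Per rule,
   r = Π_d (1 − z_d (1 − g_d)) over the rule's J metabolite and L taxa
   detectors, with relaxed Bernoulli selectors z ∈ (0,1).
4. **Rule selection and weighted OR.**
   P(case) = σ(Σ_k q_k β_k r_k + β_0) with rule selectors q and weights
   β.

Capacity defaults: K = 10 rules, J = L = 10 detectors per rule.

### Priors

* centers γ: Normal(0, 10⁴) per coordinate (diffuse);
* radii κ: log κ ~ Normal(log median_c(h_c), var_c(h_c)), where h_c is
  the median pairwise embedded distance within biological group c
  (chemical sub-classes for metabolites, taxonomic families for taxa;
  groups with fewer than 3 members excluded).  The location is the log
  of the median-of-medians, so the prior's median radius equals the
  typical group spread; the variance of the group medians is used
  directly on the log scale (population convention, floored at 1e-4);
* thresholds: η^T ~ Uniform(0, 1); η^M ~ Uniform over the observed
  standardized range padded by 1% of the range on each side;
* weights β, bias β₀: Normal(0, 10⁴);
* selectors: BinaryConcrete with locations 1/J, 1/L (detectors) and 1/K
  (rules) — a prior expectation of about one active detector per
  modality per rule and one active rule.

### Selector parameterization (an open design point, resolved)

The BinaryConcrete relaxation admits two MAP treatments.  Evaluating the
z-space density at the relaxed value σ(logit/τ) makes the prior's score
unbounded near the poles; empirically the sparsity pull then wins every
race against the likelihood and all selectors collapse before any
detector can prove useful (intercept-only fits).  We instead do MAP in
logit space with the change-of-variables Jacobian: if
z = σ(w/τ) with z ~ BinaryConcrete(α, τ), the induced law of w is
Logistic(log α, 1) *for every τ*.  The resulting score is bounded by 1
and vanishes at w = log α, so selection is decided by the likelihood
while annealing τ sharpens the committed decisions.  The z-space density
itself is retained (`binary_concrete_log_pdf`) and unit-tested against
its closed form.

An optional straight-through mode (binarized selectors in the forward
pass, soft gradients) and a sampled-relaxation mode (logistic noise on
the logits) are implemented behind `FitConfig` flags; both are off by
default — under the benchmark conditions they destabilized training.

### Inference

MAP by full-batch Adam, learning rate 0.001 for all parameters except
taxa thresholds (0.0001).  Radii are optimized as log κ (positivity);
thresholds are clamped back into their uniform supports after each step.
Five temperatures anneal linearly between 5% and 95% of the epoch
budget (flat outside that window): τ_u 1e-2→1e-3, τ_g^T 1e-2→1e-3,
τ_g^M 1→0.1, τ_z and τ_q 1→0.1.  Default 5000 epochs; convergence is
recorded when the loss decrease over the trailing 100 epochs is below
0.01.  Because local minima vary across initializations, fitting is
restarted from multiple seeds (default 10) and the lowest final loss is
reported.  Gradients are analytic (hand-derived backward pass, validated
against central finite differences to 1e-4 relative error); a
numba-compiled kernel computes the likelihood pass, with a pure-numpy
reference implementation kept in lockstep by the test suite.

Initialization: each rule's detectors come from an independently seeded
k-means run on the embedding (k = number of detectors); centers are the
centroids, radii the mean member distance to the centroid (singleton
clusters reach to their nearest neighbor), thresholds the cohort mean of
each initial group's aggregate.  β ~ N(0,1), β₀ = 0, detector logits 0
(selector value 0.5), rule logits 0.1·N(0,1).

### Geometry

Patristic distances are computed with dendropy.  Embeddings use
classical PCoA (eigendecomposition of the double-centered squared
distance matrix); axes with non-positive eigenvalues are discarded, and
each axis's sign is fixed so its first nonzero coordinate is positive.
Taxa dimensionality is the smallest at which a two-sample KS test no
longer distinguishes pre- from post-embedding pairwise distances
(p ≥ 0.05), searched up to 30 dimensions with an argmax-p fallback —
raw tree metrics are strongly non-Euclidean, and at the pair-count power
of the test no truncation may pass.  Metabolite dimensionality is the
smallest explaining 95% of the positive-eigenvalue variance.  Final
embeddings are uniformly rescaled to a fixed coordinate range (0.7) so
radii, their priors and τ_u act on a common scale across modalities and
datasets.

### Rule read-out

After training, rule k is kept when σ(q-logit) > 0.5, a detector when
σ(z-logit) > 0.5, and feature i is a member when its inclusion weight
exceeds 0.5 at the final τ_u.  Each rule renders as "IF (aggregate of
members) > threshold AND ... THEN odds of case ×exp(β_k)".  In the
fully annealed (zero-temperature) limit the network's decisions coincide
with the boolean evaluation of this rule set; the suite checks ≥95%
agreement on benchmark fits (typically exact).

## The semi-synthetic benchmark generator

The generator emulates perturbation experiments on a baseline (all
control) cohort.  A fully synthetic baseline fabricator removes any need
for external data: 67 subjects; 120 taxa on a random Kingman coalescent
tree with counts from a log-normal-composition + multinomial model at
depth 10,000; 200 metabolites as correlated log-normal intensities with
partial detection (zeros), whose "chemistry" is a 5-dimensional latent
space with Gaussian sub-class clusters (~15 members each) standing in
for fingerprint geometry.  These sizes mirror a shotgun metagenomics +
HPLC-MS/MS cohort of the kind the generator is meant to emulate; the
fabricated chemistry is synthetic and cannot capture real fingerprint
structure, so passing benchmarks demonstrate recovery of
geometrically coherent group effects, not performance on real data.

Generation steps (scenario 1; others analogous):

1. subjects are resampled from the baseline (without replacement up to
   the baseline size, then with replacement) via one nested index
   sequence per seed, and split evenly into cases and controls;
2. a metabolite group H is a ball around a uniformly drawn metabolite
   with Log-Normal radius (calibrated like the model's radius prior),
   rejection-sampled to at most 15% of metabolites; a taxa clade is a
   uniform draw over tree nodes with 5–30 leaves;
3. for m ∈ H, the standardized log value is redrawn:
   Normal(−0.203, 1.5) for controls, Normal(0.724, 1.5) for cases
   (effect sizes calibrated from rules learned on real data); other
   metabolites keep their baseline values; all entries receive
   measurement noise Normal(0, 0.024) and are mapped back to raw levels
   via exp(y'·√v_m + u_m);
4. for a clade C, the clade's total relative abundance is redrawn
   log-normally (log mean −6 controls / −3 cases, sd 1.5), allocated
   within C proportionally to the subject's baseline composition (equal
   split if absent), renormalized, jittered with
   TruncatedNormal(γ, (0.3γ)², 0, 1), renormalized, and counts drawn
   Dirichlet-multinomial (concentration 286) at the original depth.

Scenarios 2/4 use two disjoint groups with the controls split into two
subgroups, each receiving a doubled perturbation (2μ₁) in one group and
the control draw in the other; scenario 5 combines one clade and one
metabolite group, control subgroups receiving one perturbation each and
cases both.  Ground-truth member sets and subgroup assignments are
recorded.

## Scaled-down benchmark configuration

The test suite runs the end-to-end recovery benchmark at 10 scenario-1
datasets of 64 subjects with 5-fold cross-validation, 3000 epochs and 2
restart seeds per fold, plus a permuted-label control; the full-data
fits used for rule-fidelity and group-recovery checks use the complete
schedule (5000 epochs) with 4 restart seeds.  These sizes are the
package's own desk-scale configuration; the full schedule (5000 epochs,
10 restart seeds) is the library default.  Fold-level restarts are the
main driver of the remaining run-to-run variance.

## Numerical choices and degenerate inputs

* aggregation denominators add 1e-10 so a detector whose soft support
  vanishes yields aggregate 0 rather than 0/0;
* center-to-feature distances are floored at 1e-12 (gradient of the
  norm at zero distance);
* soft-AND factors are clipped to [1e-12, 1] before the product;
* zero metabolite levels are replaced per metabolite by half its
  smallest positive observed level before the log;
* standardization uses the population (n-denominator) deviation, is
  re-fit on each training fold inside cross-validation, and stores
  (u_m, v_m) so tables can be un-transformed exactly;
* filter boundaries are inclusive on the keep side (a taxon reaching
  count 10 in exactly 10% of subjects is kept; a metabolite present in
  exactly 15% is kept);
* Tanimoto distance between two all-zero fingerprints is 0 (1 against
  any non-zero vector); user-supplied similarity tables convert via
  d = 1 − s clipped to [0, 1].

## Known limitations

* The fabricated baseline is a geometric idealization: real fingerprint
  spaces are non-Euclidean (negative PCoA eigenvalues), sub-classes
  overlap, and real metabolomics has batch structure none of which is
  emulated.
* Time-series designs and covariates are out of scope.
* MAP point estimates carry no uncertainty; rule stability across
  restarts (Jaccard-matched detectors) is the provided robustness
  check.
* The MAP4/InfoMax fingerprints require optional backends that are not
  bundled; calls fail with a clear error rather than degrading.
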