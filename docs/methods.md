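# Methods

## Fuzzy numbers on finite δ-grids

A fuzzy number is stored as its δ-cuts on a finite ascending grid of
levels (default 20 levels, 0.05 … 1.00).  Cuts are finite unions of
closed bounded intervals and must nest (the cut at a higher level lies
inside any lower level's cut); the support is a closed interval holding
them all.  The membership function is reconstructed as
ξ(t) = max{δ · 1_{C_δ}(t)} over the grid, so it is a step approximation
that is exact at grid levels and conservative between them.  Querying a
level off the grid returns the stored cut at the nearest grid level ≥ δ.

Arithmetic (⊕, ⊗, arithmetic mean) is restricted to *fuzzy intervals*
(one interval per cut) and operates per level on endpoints: sums add
endpoints, products take the extrema of the four endpoint products
(the bilinear map attains its extrema at box corners), and the mean
averages endpoints.  These per-level rules coincide with the sup–min
extension principle for fuzzy intervals; the test suite checks them
against a direct sup–min computation on 200-point discretizations.
Multi-interval cuts are supported for storage and membership queries
only — the arithmetic of disconnected cuts is out of scope.

Lower and upper expectations of a fuzzy number described by sides
(flat top [t_l1, t_r1], non-decreasing left side f, non-increasing
right side g) are

    E_l = t_l1 − ∫ f over [t_l0, t_l1],   E_u = t_r1 + ∫ g over [t_r1, t_r0],

by adaptive quadrature; the fuzzy correlation is
C(x, y) = E_l(x)E_l(y) + E_u(x)E_u(y) with coefficient
ρ = C(x,y)/√(C(x,x)C(y,y)).

## Distribution families and estimation

Five families are supported — normal(mean, sd), gamma(shape k,
scale θ) with mean kθ and variance kθ², exponential(rate), uniform,
lognormal — all backed by scipy.stats.  Estimation is deliberately
method-of-moments (gamma: k = x̄²/s², θ = s²/x̄), matching the
estimator the family-selection procedure prescribes; maximum-likelihood
variants are a non-goal.  A family is *applicable* to a sample only if
the sample lies in its support (positive for gamma/lognormal,
non-negative for exponential); inapplicable families are skipped with
the violation recorded.

## Extended KL divergence and family selection

The discretized divergence compares model interval probabilities
(cdf increments) with empirical ones (count fractions) over the
partition induced by the sorted sample; tied values merge into one
breakpoint with summed count, and the left end extends ε below the
minimum (ε defaults to one sample standard deviation / 100).  Empirical
probabilities are floored at 1e-12 inside the logarithm and zero model
probabilities contribute zero (p log p → 0); both conventions are
needed for finiteness and are otherwise inconsequential.  Because mass
outside [x₀, x_T] is ignored, the model-weighted sum can be negative;
it is reported unadjusted.  A `normalize_partition_mass` switch
renormalizes both probability vectors over the partition, restoring
strict non-negativity.

Family selection fits every applicable candidate by moments and keeps
the family with the smallest model-weighted extended divergence (ties
break by candidate order).  This criterion is statistically weak at
separating similar families: on G(3; 2) data the normal fit often wins
below n ≈ 20 000, and gamma wins reliably only around n ≈ 50 000.  The
consequence for the classifier is benign — what matters there is that
each class's fitted law approximates its pooled descriptor
distribution, not that the "true" family label is found.

## Two directions of the divergence

`extended_kld` and `fuzzy_extended_kld` expose a `direction` option.

* `"model"` (default): Σ P_f log(P_f/P_emp), the definitional form, with the
  model in the weighting slot.  Used for family selection, where all
  candidates are moment-fitted to the *same* sample and the comparison
  is meaningful.
* `"empirical"`: Σ P_emp log(P_emp/P_f), which equals a constant minus
  the multinomial log-likelihood of the observed interval counts under
  the model.  The classifier uses this direction (un-normalized): as a
  decision statistic over *different* candidate models the
  model-weighted direction is degenerate — a model that parks its mass
  away from the data drives every term toward zero (or negative), so
  the widest model wins regardless of the query, and renormalizing
  instead rewards models with mass outside the data range.  The
  empirical direction is the standard goodness-of-fit orientation and
  makes "smallest divergence" equivalent to maximum likelihood.

## Fuzzy extended divergence: locating the cut endpoints

For each level δ the cut of the fuzzy divergence is the [min, max] of
the divergence over the box formed by the parameters' δ-cuts.  The
objective is smooth but not monotone or bilinear in the parameters, so
corner evaluation is insufficient.  The implementation lays a dense
grid (`grid_res` points per free parameter, default 21; the classifier
uses 11) over the *widest* box once, evaluates all points vectorized
(cdf increments broadcast over the parameter grid), then for each level
restricts to the grid points inside that level's box, always adding the
level box's corners and centre, and optionally polishes both extrema
with bounded Nelder–Mead (`refine=True`, the module default; the
classifier disables it for throughput).  A final envelope pass from
δ = 1 downward takes running min/max, guaranteeing nested cuts even
when refinement quality varies between levels.  Endpoints agree with a
10×-denser brute-force grid to ~1e-3 on one- and two-parameter boxes
in the test suite.

## Gaussian mixture EM

The mixture model is fitted by EM with responsibilities computed in
log-space.  The M-step divides the weighted squared deviations by
n_g − 1 (with n_g = Σ_i ẑ_ig), the unbiased-variance convention; this is
a small deviation from the maximizer of the expected complete-data
log-likelihood (denominator n_g), so strict monotonicity of the
observed log-likelihood is only asserted in the `variance_mode="ng"`
setting, which is also available.  Initialization is unstated in the
procedure this implements, so the package uses k-quantile means with
pooled variance and uniform weights, plus mean-perturbed random
restarts (default 10) with the best observed log-likelihood winning;
components are reported sorted by mean.  A variance floor of
1e-10 · var(x) prevents singular collapse.  Component counts are chosen
by BIC (AIC available) over G = 1..G_max.

## Bayesian posteriors and fuzzification

Posteriors are computed on regular per-parameter grids (default 201
points per parameter, jointly for two-parameter families) spanning the
moment estimate ± 6 rough standard errors — crude delta-method SEs are
good enough because they only size the grid, and a coverage failure
raises rather than silently truncating.  The log-likelihood is
evaluated from sufficient statistics, so grid cost does not scale with
n.  The prior is flat by default or a `ParameterGrid` whose axes are
reused; the density is normalized to trapezoid-integral 1.  Against the
conjugate normal(known σ) closed form the grid posterior's mean and sd
agree within two grid steps.

Each parameter is fuzzified through its *marginal* posterior:
f̃ = f/f(mode) (maximum exactly 1 at the mode; a non-unique mode takes
the smallest θ with a warning), and the δ-cut is the superlevel set
{f̃ ≥ δ} reported as the interval from its first to its last grid point.
A disconnected superlevel set (multimodal marginal) is collapsed to its
convex hull with a warning, consistent with the single-family
assumption.  Nesting holds by construction, and cut widths shrink with
sample size (checked at n = 50, 500, 5000).

## Image descriptors

Gradients are central differences with replicate padding; orientation
is atan2-based, folded to [0°, 180°), and defined as 0° where both
gradients vanish.  HOG uses 8×8-pixel cells, 9 unsigned orientation
bins with linear interpolation between bin centres at 0°, 20°, …, and
2×2-cell blocks flattened and L2-normalized — the cell/bin/block sizes
are the descriptor family's conventional defaults and are configurable.
LBP thresholds the 8 square neighbours against the centre with
difference ≥ 0 mapping to bit 1 (a constant image codes 255
everywhere), bit i = 2^i assigned clockwise from the top-left
neighbour, and reports the normalized 256-bin code histogram.  Both
descriptors are deterministic; HOG is invariant to additive intensity
shifts, LBP to positive-slope affine maps.

The class-level summaries sort each descriptor vector ascending and
take position-wise means (average profile) or position-wise min/max
(fuzzy interval profile, the lower/upper envelope).

## Classifier

Training pools each class's descriptor values into one sample, runs
family selection → grid posterior → fuzzification, and stores the fuzzy
distribution plus the class's interval profile.  A query's descriptor
vector is treated as a sample: its partition is built, the fuzzy
extended divergence (empirical direction, grid only) between each class
model and the partition is computed, and each is defuzzified as the
mean of δ-cut midpoints — a centroid-like score that reduces to the
crisp divergence for degenerate cuts; a pessimistic variant (mean of
upper endpoints) is available.  Smallest score wins; ties break by the
δ=1 midpoint, then label order.  Classification is per image by
default; classifying a group of images jointly amounts to
concatenating their descriptor vectors into one query sample, as the
self-consistency test does with each class's pooled training values.

## Synthetic data

The mixture sampler draws component labels by weight and values from
the named family, with helper specs for the balanced and 90/10
two-component normal mixture N(−1, 1²)/N(2, 2²) and the gamma pair
G(3; 2)/G(4; 7) used throughout the examples and recovery checks.

The leaf generator rasterizes a superellipse blade (rotation, scale and
shape jittered per image) with a sinusoidal margin, a midrib with
angled side veins, optional corrugation shading, and Gaussian pixel
noise on a dark background; images are 64×64 uint8 and byte-identical
for a fixed seed.  The four default classes — matte, toothed, veined,
corrugated — were designed to be well separated in the statistic that
drives the classifier: because block-normalized gradient histograms are
contrast-invariant, class identity must come from the *composition* of
silent, isotropic, oriented and edge-dominated blocks, and the presets
are spaced along that axis.  The generator emulates per-class shape and
texture variation, not botanical realism: real leaf photographs carry
backgrounds, lighting and perspective variation the generator omits, so
passing the synthetic classification check demonstrates that the
pipeline separates distributionally distinct texture classes, not
field-ready species recognition.

## Problem sizes and tolerances

Recovery checks use the stated simulation sizes (20 000 mixture draws,
50 000 gamma/exponential draws); at these sizes the sampling error of
the recovered component means is a few hundredths, though for the
overlapping higher-variance component the maximum-likelihood estimate
can occasionally sit ~0.15 from the generating mean — that is sampling
variance of the MLE, not an optimizer failure (verified by comparing
log-likelihoods).  The end-to-end classification check trains on 30
images per class and tests on 100; the quadrature tolerance for the
continuous divergence is 1e-6 against Gaussian closed forms, and the
conjugate-posterior agreement threshold is two grid steps.

## Known limitations

* Divergence-based family selection needs very large samples to discriminate
  similar families; with small samples it effectively picks "a family
  that fits", not "the family".
* The model-weighted extended divergence can be negative and is not a
  metric; inference-grade comparisons should use the normalized or
  empirical-direction variants.
* Fuzzy divergence cuts are outer approximations: grid resolution and
  the nesting envelope can widen cuts slightly, never narrow them.
* Multi-interval (disconnected) fuzzy numbers are storage-only; fuzzy
  arithmetic assumes interval cuts.
* The leaf generator's classes are separable by design; accuracy on it
  says nothing quantitative about photographic databases.
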